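"""Phylogeny handling: Newick I/O, grafting, pruning and tree summary statistics.

Trees are represented as :class:`dendropy.Tree` objects throughout; this
module adds the validation, congeneric grafting, site-level pruning and the
summary statistics (Faith's PD, Pybus–Harvey gamma, Colless and Sackin
imbalance) the dominance analysis needs.  :class:`TreeIndex` caches the
per-tip root-path edge incidence used by the dispersion and beta-diversity
stages, so the cophenetic matrix and branch sets come from a single matmul.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "read_newick",
    "write_newick",
    "validate_tree",
    "TreeIndex",
    "graft_species",
    "prune_to_site",
    "faith_pd",
    "gamma_statistic",
    "colless_index",
    "sackin_index",
    "topology_indices",
    "site_tree_stats",
]


class NewickError(ValueError):
    """Raised when a Newick file cannot be parsed or violates tree invariants."""


def read_newick(path) -> dendropy.Tree:
    """Read a rooted, branch-length-bearing Newick tree and validate it.

    Parameters
    ----------
    path : str or os.PathLike
        Newick file with branch lengths; tip labels must be unique.

    Returns
    -------
    dendropy.Tree
        The tree, rooted, with ``None`` branch lengths replaced by 0 only on
        the root edge.

    Raises
    ------
    NewickError
        On malformed Newick (message includes the parser's position report),
        duplicate tip labels, or negative/non-finite branch lengths.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickError(f"malformed Newick in {path!s}: {exc}") from exc
    tree.is_rooted = True
    validate_tree(tree)
    return tree


def write_newick(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)


def validate_tree(tree: dendropy.Tree) -> None:
    """Check the structural invariants: unique tips, finite non-negative lengths."""
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    if any(lbl is None or lbl == "" for lbl in labels):
        raise NewickError("unlabelled tip encountered")
    seen: set[str] = set()
    for lbl in labels:
        if lbl in seen:
            raise NewickError(f"duplicate tip label: {lbl!r}")
        seen.add(lbl)
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        bl = node.edge.length
        if bl is None:
            raise NewickError(
                f"missing branch length above node {node.taxon.label if node.taxon else node!r}"
            )
        if not math.isfinite(bl) or bl < 0:
            raise NewickError(f"invalid branch length {bl!r}")


def _tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def total_branch_length(tree: dendropy.Tree) -> float:
    return sum(
        node.edge.length or 0.0
        for node in tree.preorder_node_iter()
        if node.parent_node is not None
    )


@dataclass
class TreeIndex:
    """Edge-incidence index of a tree for vectorised PD / distance computations.

    Attributes
    ----------
    tree : dendropy.Tree
    tips : list of str
        Tip labels, in a fixed leaf-iteration order.
    edge_lengths : ndarray, shape (E,)
        One entry per non-root node (the edge to its parent).
    tip_edges : ndarray of bool, shape (n_tips, E)
        ``tip_edges[i, e]`` is True when edge ``e`` lies on the path from tip
        ``i`` to the root.
    """

    tree: dendropy.Tree
    tips: list[str] = field(init=False)
    tip_index: dict[str, int] = field(init=False)
    edge_lengths: np.ndarray = field(init=False)
    tip_edges: np.ndarray = field(init=False)
    edge_nodes: list[dendropy.Node] = field(init=False)
    _coph: np.ndarray | None = field(init=False, default=None, repr=False)

    def __post_init__(self) -> None:
        tree = self.tree
        edge_nodes = [n for n in tree.preorder_node_iter() if n.parent_node is not None]
        e_index = {id(n): i for i, n in enumerate(edge_nodes)}
        lengths = np.array([n.edge.length or 0.0 for n in edge_nodes], dtype=float)
        leaves = list(tree.leaf_node_iter())
        tips = [lf.taxon.label for lf in leaves]
        mat = np.zeros((len(leaves), len(edge_nodes)), dtype=bool)
        for i, leaf in enumerate(leaves):
            node = leaf
            while node.parent_node is not None:
                mat[i, e_index[id(node)]] = True
                node = node.parent_node
        self.tips = tips
        self.tip_index = {t: i for i, t in enumerate(tips)}
        self.edge_lengths = lengths
        self.tip_edges = mat
        self.edge_nodes = edge_nodes

    @property
    def n_tips(self) -> int:
        return len(self.tips)

    def indices(self, species) -> np.ndarray:
        missing = [s for s in species if s not in self.tip_index]
        if missing:
            raise KeyError(f"species not in tree: {sorted(missing)}")
        return np.array([self.tip_index[s] for s in species], dtype=np.intp)

    def depths(self) -> np.ndarray:
        """Root-to-tip path lengths."""
        return self.tip_edges @ self.edge_lengths

    def cophenetic(self) -> np.ndarray:
        """Full pairwise patristic distance matrix (tips × tips).

        d(i, j) = depth_i + depth_j − 2·(shared root-path length); a single
        matrix product over the edge incidence.
        """
        if self._coph is None:
            w = self.tip_edges * self.edge_lengths
            shared = w @ self.tip_edges.T
            d = self.depths()
            self._coph = d[:, None] + d[None, :] - 2.0 * shared
            np.fill_diagonal(self._coph, 0.0)
        return self._coph

    def cophenetic_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.cophenetic(), index=self.tips, columns=self.tips)

    def branch_mask(self, species) -> np.ndarray:
        """Boolean edge membership of the minimal root-connected subtree."""
        idx = self.indices(species)
        if idx.size == 0:
            raise ValueError("empty species set")
        return self.tip_edges[idx].any(axis=0)

    def pd_of(self, species) -> float:
        return float(self.edge_lengths[self.branch_mask(species)].sum())


def faith_pd(tree, species) -> float:
    """Faith's phylogenetic diversity of ``species``: total branch length of the
    minimal subtree connecting them, including the path to the tree's root.

    ``tree`` may be a :class:`dendropy.Tree` or a prebuilt :class:`TreeIndex`.
    """
    index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    species = list(species)
    if not species:
        raise ValueError("species set is empty")
    try:
        return index.pd_of(species)
    except KeyError as exc:
        raise ValueError(str(exc)) from exc


def prune_to_site(tree: dendropy.Tree, species) -> dendropy.Tree:
    """Prune ``tree`` to ``species``, suppressing degree-2 nodes.

    Cophenetic distances among the retained tips are unchanged; the root path
    (stem) above the retained clade is kept so PD conventions carry over.
    """
    species = set(species)
    if not species:
        raise ValueError("cannot prune to an empty species set")
    tips = set(_tip_labels(tree))
    missing = species - tips
    if missing:
        raise ValueError(f"species not in tree: {sorted(missing)}")
    sub = tree.extract_tree(
        node_filter_fn=lambda nd: (not nd.is_leaf()) or (nd.taxon.label in species),
        suppress_unifurcations=True,
    )
    sub.is_rooted = True
    return sub


# ---------------------------------------------------------------------------
# grafting


def _genus_from_name(name: str) -> str:
    return name.split("_", 1)[0].split(" ", 1)[0]


def _mrca(nodes) -> dendropy.Node:
    """MRCA by root-path intersection (robust to prior tree mutation)."""
    paths = []
    for node in nodes:
        path = []
        nd = node
        while nd is not None:
            path.append(nd)
            nd = nd.parent_node
        paths.append(path[::-1])
    mrca = paths[0][0]
    for depth in range(min(len(p) for p in paths)):
        candidate = paths[0][depth]
        if all(p[depth] is candidate for p in paths):
            mrca = candidate
        else:
            break
    return mrca


def _node_mean_tip_depth(node: dendropy.Node) -> float:
    """Mean path length from ``node`` down to its descendant tips."""
    depths = []
    stack = [(node, 0.0)]
    while stack:
        nd, depth = stack.pop()
        if nd.is_leaf():
            depths.append(depth)
        for ch in nd.child_nodes():
            stack.append((ch, depth + (ch.edge.length or 0.0)))
    return float(np.mean(depths)) if depths else 0.0


def graft_species(
    tree: dendropy.Tree,
    species,
    genus_of=None,
    family_of=None,
) -> tuple[dendropy.Tree, pd.DataFrame]:
    """Attach missing species to a megaphylogeny at congeneric or family nodes.

    Species already in the tree are untouched.  A species with ≥2 congeners in
    the tree becomes a new pendant at the most recent common ancestor of those
    congeners, with pendant length equal to the mean tip depth below that node
    (preserving near-ultrametricity).  With a single congener, that congener's
    terminal edge is split at its midpoint and the new tip attached there.
    Otherwise, if the species' family has genera in the tree, the pendant goes
    to the family MRCA; species with neither are reported as ungraftable and
    left out.

    Parameters
    ----------
    tree : dendropy.Tree
        Modified copy is returned; the input is not mutated.
    species : iterable of str
        Species required in the output tree.
    genus_of : mapping or None
        species → genus; defaults to the leading ``Genus_`` name component.
    family_of : mapping or None
        genus → family, used for family-level grafts.

    Returns
    -------
    (tree, report) : (dendropy.Tree, pandas.DataFrame)
        ``report`` has one row per requested species with columns
        ``species``, ``level`` ∈ {present, congener, family, ungraftable}.
    """
    tree = tree.clone(depth=1)
    genus_of = dict(genus_of) if genus_of else {}
    family_of = dict(family_of) if family_of else {}

    def genus(name: str) -> str:
        return genus_of.get(name, _genus_from_name(name))

    rows = []
    for sp in species:
        present = {lf.taxon.label: lf for lf in tree.leaf_node_iter()}
        if sp in present:
            rows.append({"species": sp, "level": "present"})
            continue
        g = genus(sp)
        congeners = [lf for lbl, lf in present.items() if genus(lbl) == g]
        if len(congeners) >= 2:
            mrca = _mrca(congeners)
            pendant = _node_mean_tip_depth(mrca)
            _attach_tip(tree, mrca, sp, pendant)
            rows.append({"species": sp, "level": "congener"})
        elif len(congeners) == 1:
            leaf = congeners[0]
            half = (leaf.edge.length or 0.0) / 2.0
            parent = leaf.parent_node
            new_node = dendropy.Node(edge_length=half)
            parent.remove_child(leaf)
            parent.add_child(new_node)
            leaf.edge.length = half
            new_node.add_child(leaf)
            _attach_tip(tree, new_node, sp, half)
            rows.append({"species": sp, "level": "congener"})
        else:
            fam = family_of.get(g)
            fam_tips = [
                lf for lbl, lf in present.items()
                if fam is not None and family_of.get(genus(lbl)) == fam
            ]
            if len(fam_tips) >= 2:
                mrca = _mrca(fam_tips)
                _attach_tip(tree, mrca, sp, _node_mean_tip_depth(mrca))
                rows.append({"species": sp, "level": "family"})
            elif len(fam_tips) == 1:
                leaf = fam_tips[0]
                half = (leaf.edge.length or 0.0) / 2.0
                parent = leaf.parent_node
                new_node = dendropy.Node(edge_length=half)
                parent.remove_child(leaf)
                parent.add_child(new_node)
                leaf.edge.length = half
                new_node.add_child(leaf)
                _attach_tip(tree, new_node, sp, half)
                rows.append({"species": sp, "level": "family"})
            else:
                rows.append({"species": sp, "level": "ungraftable"})
    report = pd.DataFrame(rows, columns=["species", "level"])
    return tree, report


def _attach_tip(tree: dendropy.Tree, node: dendropy.Node, label: str, length: float) -> None:
    taxon = tree.taxon_namespace.require_taxon(label=label)
    node.add_child(dendropy.Node(taxon=taxon, edge_length=max(length, 0.0)))


# ---------------------------------------------------------------------------
# summary statistics


def _internal_node_times(tree: dendropy.Tree) -> tuple[np.ndarray, np.ndarray, float]:
    """(times, n_new_lineages_per_node, tip depth) for an ultrametric tree."""
    tree.calc_node_root_distances()
    times, added = [], []
    for node in tree.preorder_node_iter():
        if node.is_leaf():
            continue
        nch = len(node.child_nodes())
        times.append(node.root_distance)
        added.append(nch - 1)
    depth = max(lf.root_distance for lf in tree.leaf_node_iter())
    order = np.argsort(times, kind="stable")
    return np.asarray(times, float)[order], np.asarray(added, int)[order], depth


def gamma_statistic(tree: dendropy.Tree, *, rel_tol: float = 1e-6) -> float:
    """Pybus–Harvey gamma: the standardized temporal distribution of internal
    nodes in an ultrametric tree.  Negative values indicate deeper (earlier)
    nodes than a pure-birth expectation; positive values shallower nodes.

    Raises
    ------
    ValueError
        If the tree has <3 tips or is not ultrametric within
        ``rel_tol × max depth``.
    """
    n = sum(1 for _ in tree.leaf_node_iter())
    if n < 3:
        raise ValueError("gamma statistic requires at least 3 tips")
    tree.calc_node_root_distances()
    tip_depths = np.array([lf.root_distance for lf in tree.leaf_node_iter()])
    depth = tip_depths.max()
    if depth <= 0 or (tip_depths.max() - tip_depths.min()) > rel_tol * depth:
        raise ValueError(
            "tree is not ultrametric within tolerance; extend or ultrametricize "
            "branch lengths before computing gamma"
        )
    times, added, depth = _internal_node_times(tree)
    # Internode intervals g_k: time during which exactly k lineages exist,
    # k = 2..n.  Polytomies contribute zero-length intervals.
    g = np.zeros(n + 1)
    count = 1
    t_prev = 0.0
    for t, a in zip(times, added):
        if count >= 2:
            g[count] += t - t_prev
        elif count == 1:
            pass  # the root itself: no interval before 2 lineages exist
        t_prev = t
        count += a
    g[count] += depth - t_prev
    # Pybus & Harvey (2000): T_j = sum_{k=2}^{j} k*g_k
    ks = np.arange(2, n + 1)
    kg = ks * g[2: n + 1]
    T_cum = np.cumsum(kg)         # T_2 .. T_n
    T = T_cum[-1]
    mean_inner = T_cum[:-1].mean()  # (1/(n-2)) * sum_{j=2}^{n-1} T_j
    return float((mean_inner - T / 2.0) / (T * math.sqrt(1.0 / (12.0 * (n - 2)))))


def _tips_below(node: dendropy.Node, cache: dict) -> int:
    key = id(node)
    if key not in cache:
        if node.is_leaf():
            cache[key] = 1
        else:
            cache[key] = sum(_tips_below(ch, cache) for ch in node.child_nodes())
    return cache[key]


def colless_index(tree: dendropy.Tree) -> int:
    """Colless imbalance; polytomies resolved as maximally unbalanced
    caterpillars (children ordered by descending subtree size), which is
    deterministic and reduces to |L − R| on binary nodes."""
    cache: dict = {}
    total = 0
    for node in tree.preorder_internal_node_iter():
        counts = sorted((_tips_below(ch, cache) for ch in node.child_nodes()),
                        reverse=True)
        if len(counts) < 2:
            continue
        remaining = sum(counts)
        for c in counts[:-1]:
            remaining -= c
            total += abs(c - remaining)
    return total


def sackin_index(tree: dendropy.Tree) -> int:
    """Sackin index: sum over tips of the number of edges to the root."""
    total = 0
    for leaf in tree.leaf_node_iter():
        d = 0
        node = leaf
        while node.parent_node is not None:
            d += 1
            node = node.parent_node
        total += d
    return total


def topology_indices(tree: dendropy.Tree) -> dict:
    """Gamma, Colless and Sackin indices for a (site) tree.

    Gamma is ``nan`` when undefined (<3 tips or non-ultrametric).
    """
    n = sum(1 for _ in tree.leaf_node_iter())
    if n < 2:
        raise ValueError("topology indices require at least 2 tips")
    try:
        gamma = gamma_statistic(tree)
    except ValueError:
        gamma = float("nan")
    return {
        "gamma": gamma,
        "colless": colless_index(tree),
        "sackin": sackin_index(tree),
    }


def site_tree_stats(tree, species, site_id=None) -> dict:
    """Per-site phylogenetic summary: richness, Faith's PD and topology indices
    of the pruned site tree."""
    species = list(species)
    base = tree.tree if isinstance(tree, TreeIndex) else tree
    pruned = prune_to_site(base, species)
    stats = {
        "site": site_id,
        "n_species": len(species),
        "pd": faith_pd(base if not isinstance(tree, TreeIndex) else tree, species),
    }
    stats.update(topology_indices(pruned))
    return stats
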