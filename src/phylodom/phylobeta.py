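"""Phylogenetic Sørensen beta diversity with turnover/nestedness decomposition,
per dominance partition, against a partition-shuffle null.

Sites are compared through the branch lengths of the minimal root-connected
subtrees their species span on the megaphylogeny.  With ``a`` the shared
branch length of two sites and ``b``, ``c`` the branch lengths unique to each:

    SOR = (b + c) / (2a + b + c)           total dissimilarity
    SIM = min(b, c) / (a + min(b, c))      turnover fraction
    SNE = SOR − SIM                        nestedness fraction

and the multiple-site generalisation uses the pairwise unique-branch sums
Σ min(b_ij, b_ji), Σ max(b_ij, b_ji) and the shared-branch total
Σᵢ PDᵢ − PD(union).  The null shuffles species among the three dominance
partitions within each site (group sizes preserved by default), recomputes
every index for each of 499 shuffled datasets, and pools the three
partitions' null values (3 × 499 = 1497) for the empirical p-values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trees import TreeIndex

__all__ = [
    "branch_set", "pairwise_phylosor", "multisite_phylosor",
    "partition_shuffle_null", "empirical_p", "region_sensitivity",
    "run_beta_stage", "BetaResult",
]

PARTITIONS = ("dominant", "intermediate", "nondominant")
INDEX_NAMES = ("multisite_sor", "multisite_sim", "multisite_sne",
               "pairwise_sor", "pairwise_sim", "pairwise_sne")


def branch_set(tree, species) -> dict[int, float]:
    """Branches (edge index → length) of the minimal root-connected subtree
    spanned by ``species``; the summed lengths equal Faith's PD."""
    index = tree if isinstance(tree, TreeIndex) else TreeIndex(tree)
    mask = index.branch_mask(list(species))
    return {int(e): float(index.edge_lengths[e]) for e in np.nonzero(mask)[0]}


def _abc(b1: dict, b2: dict) -> tuple[float, float, float]:
    k1, k2 = set(b1), set(b2)
    a = sum(b1[k] for k in k1 & k2)
    b = sum(b1[k] for k in k1 - k2)
    c = sum(b2[k] for k in k2 - k1)
    return a, b, c


def _sor_sim_sne(a: float, b: float, c: float) -> tuple[float, float, float]:
    denom = 2 * a + b + c
    if denom == 0:
        return 0.0, 0.0, 0.0
    sor = (b + c) / denom
    m = min(b, c)
    sim = m / (a + m) if (a + m) > 0 else 0.0
    return sor, sim, sor - sim


def pairwise_phylosor(b1: dict, b2: dict) -> tuple[float, float, float]:
    """(SOR, SIM, SNE) between two branch sets."""
    if not b1 or not b2:
        raise ValueError("branch sets must be non-empty")
    return _sor_sim_sne(*_abc(b1, b2))


def multisite_phylosor(branch_sets) -> tuple[float, float, float]:
    """Multiple-site (SOR, SIM, SNE) over ≥2 branch sets.

    Reduces exactly to :func:`pairwise_phylosor` for two sites.
    """
    branch_sets = list(branch_sets)
    if len(branch_sets) < 2:
        raise ValueError("need at least 2 sites")
    lengths: dict[int, float] = {}
    for bs in branch_sets:
        lengths.update(bs)
    pd_tot = sum(lengths.values())
    pds = [sum(bs.values()) for bs in branch_sets]
    sum_min = sum_max = 0.0
    for i in range(len(branch_sets)):
        for j in range(i + 1, len(branch_sets)):
            a, b, c = _abc(branch_sets[i], branch_sets[j])
            sum_min += min(b, c)
            sum_max += max(b, c)
    a_tot = sum(pds) - pd_tot
    denom = 2 * a_tot + sum_min + sum_max
    if denom == 0:
        return 0.0, 0.0, 0.0
    sor = (sum_min + sum_max) / denom
    sim = sum_min / (a_tot + sum_min) if (a_tot + sum_min) > 0 else 0.0
    return sor, sim, sor - sim


# ---------------------------------------------------------------------------
# vectorised machinery over boolean edge-membership matrices


def _membership(index: TreeIndex, species_lists) -> np.ndarray:
    """Boolean (n_sets × E) edge membership for a list of species lists."""
    m = np.zeros((len(species_lists), index.edge_lengths.size), dtype=bool)
    for i, sp in enumerate(species_lists):
        if sp:
            m[i] = index.tip_edges[index.indices(sp)].any(axis=0)
    return m


def _beta_from_membership(B: np.ndarray, lengths: np.ndarray) -> dict[str, float]:
    """All six indices from a site × edge membership matrix."""
    W = B * lengths
    pds = W.sum(axis=1)
    shared = W @ B.T
    b_unique = pds[:, None] - shared          # b_ij: unique to i w.r.t. j
    iu = np.triu_indices(B.shape[0], k=1)
    bij, bji = b_unique[iu], b_unique.T[iu]
    bmin = np.minimum(bij, bji)
    bmax = np.maximum(bij, bji)
    a_pair = shared[iu]
    # pairwise means
    denom = 2 * a_pair + bmin + bmax
    with np.errstate(invalid="ignore", divide="ignore"):
        sor_p = np.where(denom > 0, (bmin + bmax) / denom, 0.0)
        sim_p = np.where(a_pair + bmin > 0, bmin / (a_pair + bmin), 0.0)
    # multisite
    pd_tot = (lengths * B.any(axis=0)).sum()
    a_tot = pds.sum() - pd_tot
    smin, smax = bmin.sum(), bmax.sum()
    ms_denom = 2 * a_tot + smin + smax
    ms_sor = (smin + smax) / ms_denom if ms_denom > 0 else 0.0
    ms_sim = smin / (a_tot + smin) if (a_tot + smin) > 0 else 0.0
    return {
        "multisite_sor": float(ms_sor),
        "multisite_sim": float(ms_sim),
        "multisite_sne": float(ms_sor - ms_sim),
        "pairwise_sor": float(sor_p.mean()),
        "pairwise_sim": float(sim_p.mean()),
        "pairwise_sne": float((sor_p - sim_p).mean()),
    }


def _partition_lists(partitions: pd.DataFrame) -> tuple[list, dict]:
    """sites in order, and {partition: [species list per site]}."""
    sites = sorted(partitions["site"].unique().tolist())
    lists = {p: [] for p in PARTITIONS}
    for site in sites:
        sub = partitions[partitions["site"] == site]
        for p in PARTITIONS:
            lists[p].append(sub.loc[sub["group"] == p, "species"].tolist())
    return sites, lists


def observed_beta(partitions: pd.DataFrame, index: TreeIndex) -> pd.DataFrame:
    """Observed beta indices per partition from a k=3 partition table
    (columns site, species, group)."""
    sites, lists = _partition_lists(partitions)
    if len(sites) < 2:
        raise ValueError("need at least 2 sites")
    rows = []
    for p in PARTITIONS:
        vals = _beta_from_membership(_membership(index, lists[p]),
                                     index.edge_lengths)
        for name, v in vals.items():
            rows.append({"partition": p, "index": name, "observed": v})
    return pd.DataFrame(rows)


def partition_shuffle_null(
    partitions: pd.DataFrame,
    index: TreeIndex,
    n_iter: int = 499,
    seed: int | None = None,
    size_preserving: bool = True,
) -> pd.DataFrame:
    """Null distributions of every beta index under within-site partition
    shuffling.

    Each iteration relabels every site's species among the three partitions —
    preserving the observed group sizes by default, or multinomially with
    equal probabilities when ``size_preserving=False`` — and recomputes all
    indices per partition.  The three partitions' values are returned
    separately (callers pool them: 3 × n_iter values per index).
    """
    sites, lists = _partition_lists(partitions)
    rng = np.random.default_rng(seed)
    site_species = []
    site_sizes = []
    for i_site in range(len(sites)):
        sp = [s for p in PARTITIONS for s in lists[p][i_site]]
        site_species.append(sp)
        site_sizes.append([len(lists[p][i_site]) for p in PARTITIONS])
    rows = []
    lengths = index.edge_lengths
    for it in range(n_iter):
        shuffled = {p: [] for p in PARTITIONS}
        for sp, sizes in zip(site_species, site_sizes):
            perm = rng.permutation(len(sp))
            if size_preserving:
                bounds = np.cumsum([0] + sizes)
                for pi, p in enumerate(PARTITIONS):
                    shuffled[p].append([sp[j] for j in
                                        perm[bounds[pi]:bounds[pi + 1]]])
            else:
                labels = rng.integers(0, 3, size=len(sp))
                for pi, p in enumerate(PARTITIONS):
                    shuffled[p].append([sp[j] for j in range(len(sp))
                                        if labels[j] == pi])
        for p in PARTITIONS:
            vals = _beta_from_membership(_membership(index, shuffled[p]),
                                         lengths)
            for name, v in vals.items():
                rows.append({"iteration": it, "partition": p,
                             "index": name, "value": v})
    return pd.DataFrame(rows)


def empirical_p(observed: float, null_values) -> float:
    """Two-sided add-one empirical p-value of ``observed`` against a null
    sample: 2·min(P(null ≤ obs), P(null ≥ obs)) with the observation counted,
    capped at 1."""
    null = np.asarray(list(null_values), dtype=float)
    if null.size == 0:
        raise ValueError("need at least one null value")
    n = null.size
    p_low = (np.count_nonzero(null <= observed) + 1) / (n + 1)
    p_high = (np.count_nonzero(null >= observed) + 1) / (n + 1)
    return float(min(1.0, 2 * min(p_low, p_high)))


@dataclass
class BetaResult:
    partition: str
    index: str
    observed: float
    null_mean: float
    null_sd: float
    p: float
    n_null: int


def run_beta_stage(
    partitions: pd.DataFrame,
    index: TreeIndex,
    n_iter: int = 499,
    seed: int | None = None,
    size_preserving: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Observed beta indices per partition plus pooled-null empirical p-values.

    Returns (results, null) where ``results`` has one row per
    partition × index with the observed value, pooled-null moments and the
    two-sided empirical p against the pooled 3·n_iter null values.
    """
    obs = observed_beta(partitions, index)
    null = partition_shuffle_null(partitions, index, n_iter=n_iter, seed=seed,
                                  size_preserving=size_preserving)
    rows = []
    for _, r in obs.iterrows():
        pool = null.loc[null["index"] == r["index"], "value"].to_numpy()
        rows.append(BetaResult(
            partition=r["partition"], index=r["index"], observed=r["observed"],
            null_mean=float(pool.mean()), null_sd=float(pool.std(ddof=1)),
            p=empirical_p(r["observed"], pool), n_null=pool.size,
        ).__dict__)
    return pd.DataFrame(rows), null


def region_sensitivity(
    partitions: pd.DataFrame,
    index: TreeIndex,
    regions: dict,
    exclude=(),
    n_iter: int = 499,
    seed: int | None = None,
) -> pd.DataFrame:
    """Re-run the beta stage after dropping sites in the excluded regions."""
    exclude = set(exclude)
    keep = [s for s in partitions["site"].unique()
            if regions.get(s) not in exclude]
    if len(keep) < 2:
        raise ValueError("fewer than 2 sites remain after region exclusion")
    sub = partitions[partitions["site"].isin(keep)]
    results, _ = run_beta_stage(sub, index, n_iter=n_iter, seed=seed)
    return results
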