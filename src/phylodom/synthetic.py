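"""Synthetic metacommunities with controllable dominance–phylogeny coupling.

The generator emulates the data layout of a global grassland survey: a dated
megaphylogeny of the species pool, ≥30 1 m² quadrats per site with percent
cover per species, per-plot functional-group biomass, site covariates and a
Brownian trait table with dominance-biased missingness.  Three named
scenarios control who the high-cover species are:

* ``neutral`` — the high-cover tier is a uniform random subset of each
  site's species: dominance carries no phylogenetic signal.
* ``clustered_dominants`` — the high-cover tier is drawn from one focal
  clade (operationally "the graminoids"), so dominants are more closely
  related than a random draw.
* ``overdispersed_dominants`` — the high-cover tier is picked by greedy
  maximin phylogenetic distance, so dominants are more distantly related
  than a random draw.

Per-plot data are built so the dominance identity cover = frequency ×
cover-presence-only holds by construction: presence is Bernoulli(frequency)
and cover in occupied plots is lognormal around the species' cover-PO tier.
The high tier has size ⌈richness/3⌉, aligning the generator's "true
dominants" with the k = 3 partition used downstream.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
from dendropy.model import birthdeath

from .community import CommunityTable
from .trees import TreeIndex, write_newick

__all__ = [
    "ScenarioConfig", "simulate_tree", "simulate_metacommunity",
    "simulate_traits", "simulate_dataset", "SimulatedTree", "SyntheticDataset",
    "write_dataset",
]

SCENARIOS = ("neutral", "clustered_dominants", "overdispersed_dominants")
REGIONS = ("NorthAmerica", "Europe", "Australia", "SouthAmerica")
TRAITS = ("seed_mass", "height", "ldmc", "leaf_n")


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic metacommunity.

    Defaults mirror the survey design the pipeline targets: 30 quadrats per
    site, site richness spanning a few dozen species, graminoid prevalence
    spanning 0.14–1 of live biomass, mean annual temperature −8–27 °C and
    annual precipitation 216–2224 mm.
    """

    scenario: str = "neutral"
    n_sites: int = 50
    n_species_pool: int = 200
    richness_range: tuple = (20, 60)
    n_plots: int = 30
    focal_clade_fraction: float = 0.3
    # lognormal cover-PO tiers (percent cover in occupied plots)
    dominant_cover_mu: float = np.log(25.0)
    dominant_cover_sigma: float = 0.4
    background_cover_mu: float = np.log(4.0)
    background_cover_sigma: float = 0.5
    dominant_freq_range: tuple = (0.6, 0.95)
    background_freq_range: tuple = (0.1, 0.6)
    plot_cover_sigma: float = 0.3
    graminoid_prevalence_range: tuple = (0.14, 1.0)
    prevalence_coupling: bool = False
    mean_plot_biomass: float = 300.0
    mat_range: tuple = (-8.0, 27.0)
    precip_range: tuple = (216.0, 2224.0)
    elevation_range: tuple = (0.0, 3000.0)
    diurnal_range_range: tuple = (5.0, 20.0)
    annual_range_range: tuple = (10.0, 45.0)
    management_p: float = 0.3
    trait_rate: float = 1.0
    trait_missingness: dict = field(default_factory=lambda: {
        "dominant": 0.1, "intermediate": 0.25, "nondominant": 0.4})
    region_weights: tuple = (0.5, 0.25, 0.15, 0.1)
    seed: int | None = None

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.n_plots < 1:
            raise ValueError("n_plots must be >= 1")
        if not (0 < self.focal_clade_fraction < 1):
            raise ValueError("focal_clade_fraction must be in (0, 1)")
        if self.richness_range[1] > self.n_species_pool:
            raise ValueError("richness_range exceeds the species pool")


@dataclass
class SimulatedTree:
    tree: dendropy.Tree
    genus_of: dict
    family_of: dict


def simulate_tree(n_tips: int, birth_rate: float = 1.0, death_rate: float = 0.0,
                  seed: int | None = None, genus_size: int = 5,
                  family_size: int = 25, max_retries: int = 20) -> SimulatedTree:
    """Simulate an ultrametric birth–death tree with genus/family structure.

    Tips are renamed ``G###_sp###`` where maximal clades of at most
    ``genus_size`` tips share a genus and maximal clades of at most
    ``family_size`` tips share a family, so congeneric grafting and
    genus-level scans have derivable taxonomy maps.  Sampling uses the
    general sampling approach (simulate past the target size, then draw a
    uniform time slice with exactly ``n_tips`` lineages), which keeps the
    pure-birth gamma statistic unbiased.
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = random.Random(seed)
    tree = None
    for _ in range(max_retries):
        try:
            tree = birthdeath.birth_death_tree(
                birth_rate=birth_rate, death_rate=death_rate,
                num_extant_tips=n_tips, gsa_ntax=2 * n_tips, rng=rng)
            break
        except birthdeath.TreeSimTotalExtinctionException:
            continue
    if tree is None:
        raise RuntimeError("birth-death simulation went extinct repeatedly")
    tree.is_rooted = True
    genus_of, family_of = _assign_taxonomy(tree, genus_size, family_size)
    return SimulatedTree(tree=tree, genus_of=genus_of, family_of=family_of)


def _clade_chunks(tree: dendropy.Tree, max_size: int) -> list[list]:
    """Maximal clades with at most ``max_size`` tips, in preorder."""
    counts: dict = {}
    for node in tree.postorder_node_iter():
        counts[id(node)] = 1 if node.is_leaf() else sum(
            counts[id(ch)] for ch in node.child_nodes())
    chunks = []
    stack = [tree.seed_node]
    while stack:
        node = stack.pop()
        if counts[id(node)] <= max_size:
            chunks.append(node.leaf_nodes())
        else:
            stack.extend(reversed(node.child_nodes()))
    return chunks


def _assign_taxonomy(tree, genus_size, family_size) -> tuple[dict, dict]:
    fam_chunks = _clade_chunks(tree, family_size)
    leaf_family = {}
    for fi, leaves in enumerate(fam_chunks):
        for lf in leaves:
            leaf_family[id(lf)] = f"F{fi:02d}"
    genus_of: dict = {}
    family_of: dict = {}
    sp_counter = 0
    for gi, leaves in enumerate(_clade_chunks(tree, genus_size)):
        genus = f"G{gi:03d}"
        family_of[genus] = leaf_family[id(leaves[0])]
        for lf in leaves:
            sp_counter += 1
            label = f"{genus}_sp{sp_counter:03d}"
            lf.taxon.label = label
            genus_of[label] = genus
    return genus_of, family_of


def _focal_clade(index: TreeIndex, fraction: float) -> list[str]:
    """Tips of the clade whose size is closest to ``fraction`` of the pool."""
    target = fraction * index.n_tips
    sizes = index.tip_edges.sum(axis=0)
    best_edge = int(np.argmin(np.abs(sizes - target)))
    return [index.tips[i] for i in
            np.nonzero(index.tip_edges[:, best_edge])[0]]


def _greedy_maximin(D: np.ndarray, candidates: np.ndarray, k: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Select k of ``candidates`` maximising the minimum pairwise distance."""
    sub = D[np.ix_(candidates, candidates)]
    start = np.unravel_index(np.argmax(sub), sub.shape)
    chosen = [start[0], start[1]]
    while len(chosen) < k:
        mind = sub[:, chosen].min(axis=1)
        mind[chosen] = -np.inf
        chosen.append(int(np.argmax(mind)))
    return candidates[np.array(chosen[:k])]


def simulate_metacommunity(sim_tree: SimulatedTree,
                           config: ScenarioConfig) -> "SyntheticDataset":
    """Generate the community, biomass, covariate and region tables.

    See the module docstring for the scenario semantics.  With
    ``prevalence_coupling=True`` (clustered scenario) the share of a site's
    high-cover tier drawn from the focal clade equals the site's graminoid
    prevalence, planting a true prevalence → clustering effect for the
    drivers stage to recover.
    """
    rng = np.random.default_rng(config.seed)
    index = TreeIndex(sim_tree.tree)
    pool = index.tips
    n_pool = len(pool)
    D = index.cophenetic()
    focal = _focal_clade(index, config.focal_clade_fraction)
    focal_idx = np.array([index.tip_index[s] for s in focal])
    nonfocal_idx = np.array([i for i in range(n_pool)
                             if pool[i] not in set(focal)])
    cover_rows, biomass_rows, cov_rows, region_rows = [], [], [], []
    truth_rows = []
    lo, hi = config.richness_range
    for si in range(config.n_sites):
        site = f"site{si:03d}"
        richness = int(rng.integers(lo, hi + 1))
        tier = int(np.ceil(richness / 3))
        prevalence = float(rng.uniform(*config.graminoid_prevalence_range))
        dominants, others = _draw_site_species(
            config, rng, D, richness, tier, prevalence,
            focal_idx, nonfocal_idx, n_pool)
        species_idx = np.concatenate([dominants, others])
        is_dom = np.zeros(species_idx.size, dtype=bool)
        is_dom[:dominants.size] = True
        # species-level cover tiers and occupancy
        cover_po = np.where(
            is_dom,
            rng.lognormal(config.dominant_cover_mu, config.dominant_cover_sigma,
                          species_idx.size),
            rng.lognormal(config.background_cover_mu,
                          config.background_cover_sigma, species_idx.size))
        freq = np.where(
            is_dom,
            rng.uniform(*config.dominant_freq_range, species_idx.size),
            rng.uniform(*config.background_freq_range, species_idx.size))
        present = rng.random((species_idx.size, config.n_plots)) < freq[:, None]
        none = ~present.any(axis=1)
        if none.any():  # guarantee every sampled species occurs at the site
            cols = rng.integers(0, config.n_plots, size=none.sum())
            present[np.nonzero(none)[0], cols] = True
        sigma = config.plot_cover_sigma
        plot_cover = cover_po[:, None] * rng.lognormal(
            -sigma ** 2 / 2, sigma, (species_idx.size, config.n_plots))
        for sp_i, sp_idx in enumerate(species_idx):
            name = pool[sp_idx]
            for pl in np.nonzero(present[sp_i])[0]:
                cover_rows.append((site, f"plot{pl:02d}", name,
                                   round(float(plot_cover[sp_i, pl]), 4)))
            truth_rows.append((site, name,
                               "dominant" if is_dom[sp_i] else "background"))
        # biomass: graminoid share set exactly by the prevalence target
        totals = rng.lognormal(np.log(config.mean_plot_biomass), 0.4,
                               config.n_plots)
        rest = rng.dirichlet(np.ones(3), size=config.n_plots)
        for pl in range(config.n_plots):
            plot = f"plot{pl:02d}"
            biomass_rows.append((site, plot, "graminoid",
                                 round(prevalence * totals[pl], 3)))
            for gi, gname in enumerate(("forb", "legume", "other")):
                biomass_rows.append((site, plot, gname,
                                     round((1 - prevalence) * totals[pl]
                                           * rest[pl, gi], 3)))
        cov_rows.append({
            "site": site,
            "elevation": round(float(rng.uniform(*config.elevation_range)), 1),
            "mat": round(float(rng.uniform(*config.mat_range)), 2),
            "precip": round(float(np.exp(rng.uniform(
                np.log(config.precip_range[0]),
                np.log(config.precip_range[1])))), 1),
            "diurnal_range": round(float(rng.uniform(
                *config.diurnal_range_range)), 2),
            "annual_range": round(float(rng.uniform(
                *config.annual_range_range)), 2),
            "anthropogenic": int(rng.random() < config.management_p),
            "grazed": int(rng.random() < config.management_p),
            "burned": int(rng.random() < config.management_p),
            "recent": int(rng.random() < config.management_p),
        })
        region_rows.append((site, REGIONS[int(rng.choice(
            len(REGIONS), p=np.array(config.region_weights)
            / sum(config.region_weights)))]))
    cover = pd.DataFrame(cover_rows, columns=["site", "plot", "species", "cover"])
    biomass = pd.DataFrame(biomass_rows,
                           columns=["site", "plot", "functional_group", "mass"])
    covariates = pd.DataFrame(cov_rows).set_index("site")
    regions = dict(region_rows)
    table = CommunityTable(cover=cover, biomass=biomass,
                           covariates=covariates, regions=regions)
    truth = pd.DataFrame(truth_rows, columns=["site", "species", "true_tier"])
    return SyntheticDataset(tree=sim_tree, table=table, truth=truth,
                            config=config, traits=None)


def _draw_site_species(config, rng, D, richness, tier, prevalence,
                       focal_idx, nonfocal_idx, n_pool):
    """(dominant tip indices, other tip indices) for one site."""
    if config.scenario == "clustered_dominants":
        n_focal = tier
        if config.prevalence_coupling:
            # prevalence sets how much of the high tier comes from the clade
            n_focal = max(1, int(round(tier * prevalence)))
        if n_focal > focal_idx.size:
            raise ValueError(
                f"focal clade ({focal_idx.size} species) smaller than the "
                f"high-cover tier ({n_focal})")
        dom_focal = rng.choice(focal_idx, size=n_focal, replace=False)
        dom_rest = rng.choice(nonfocal_idx, size=tier - n_focal, replace=False)
        dominants = np.concatenate([dom_focal, dom_rest])
        remaining = np.setdiff1d(np.arange(n_pool), dominants)
        others = rng.choice(remaining, size=richness - tier, replace=False)
        return dominants, others
    site_idx = rng.choice(n_pool, size=richness, replace=False)
    if config.scenario == "neutral":
        return site_idx[:tier], site_idx[tier:]
    # overdispersed_dominants: greedy maximin over the site's species
    dominants = _greedy_maximin(D, site_idx, tier, rng)
    others = np.setdiff1d(site_idx, dominants)
    return dominants, others


def simulate_traits(sim_tree: SimulatedTree, rate: float = 1.0,
                    missingness=None, seed: int | None = None,
                    tiers: dict | None = None) -> pd.DataFrame:
    """Brownian-motion traits on the tree, with dominance-biased missingness.

    Four traits are generated; seed mass and height are exponentiated (so the
    stored values are lognormal-like and the analysis log10-transforms them),
    LDMC and leaf N stay on the Brownian scale around field-typical means.
    ``missingness`` is either a float or a dict per dominance tier (requires
    ``tiers``: species → tier), emulating the thinner trait coverage of
    nondominant species in real databases.
    """
    if rate <= 0:
        raise ValueError("trait_rate must be > 0")
    rng = np.random.default_rng(seed)
    tree = sim_tree.tree
    values = {t: {} for t in TRAITS}
    roots = {"seed_mass": 0.0, "height": -0.5, "ldmc": 250.0, "leaf_n": 20.0}
    scales = {"seed_mass": rate, "height": 0.5 * rate,
              "ldmc": 40.0 * rate, "leaf_n": 4.0 * rate}
    node_vals: dict = {id(tree.seed_node): {t: roots[t] for t in TRAITS}}
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        parent = node_vals[id(node.parent_node)]
        bl = node.edge.length or 0.0
        node_vals[id(node)] = {
            t: parent[t] + rng.normal(0.0, scales[t] * np.sqrt(bl))
            for t in TRAITS}
        if node.is_leaf():
            for t in TRAITS:
                values[t][node.taxon.label] = node_vals[id(node)][t]
    df = pd.DataFrame(values)
    df.index.name = "species"
    df["seed_mass"] = 10.0 ** df["seed_mass"]
    df["height"] = 10.0 ** df["height"]
    if missingness is not None:
        for sp in df.index:
            if isinstance(missingness, dict):
                tier = (tiers or {}).get(sp, "intermediate")
                p_miss = missingness.get(tier, 0.25)
            else:
                p_miss = float(missingness)
            mask = rng.random(len(TRAITS)) < p_miss
            df.loc[sp, mask] = np.nan
    return df


@dataclass
class SyntheticDataset:
    tree: SimulatedTree
    table: CommunityTable
    truth: pd.DataFrame
    config: ScenarioConfig
    traits: pd.DataFrame | None = None


def simulate_dataset(config: ScenarioConfig) -> SyntheticDataset:
    """Tree + metacommunity + traits under one seed, ready for the pipeline."""
    ss = np.random.SeedSequence(config.seed)
    tree_seed, comm_seed, trait_seed = (int(s.generate_state(1)[0] % (2**31))
                                        for s in ss.spawn(3))
    sim_tree = simulate_tree(config.n_species_pool, seed=tree_seed)
    ds = simulate_metacommunity(sim_tree,
                                replace(config, seed=comm_seed))
    tiers = {}
    for _, r in ds.truth.iterrows():
        cur = tiers.get(r["species"])
        if r["true_tier"] == "dominant" or cur is None:
            tiers[r["species"]] = ("dominant" if r["true_tier"] == "dominant"
                                   else "nondominant")
    ds.traits = simulate_traits(sim_tree, rate=config.trait_rate,
                                missingness=config.trait_missingness,
                                seed=trait_seed, tiers=tiers)
    ds.config = config
    return ds


def write_dataset(ds: SyntheticDataset, outdir) -> None:
    """Write megatree.nwk, community.csv, biomass.csv, covariates.csv,
    traits.csv and regions.csv; byte-identical under a fixed seed."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_newick(ds.tree.tree, outdir / "megatree.nwk")
    ds.table.cover.to_csv(outdir / "community.csv", index=False)
    ds.table.biomass.to_csv(outdir / "biomass.csv", index=False)
    ds.table.covariates.to_csv(outdir / "covariates.csv")
    if ds.traits is not None:
        ds.traits.to_csv(outdir / "traits.csv")
    pd.DataFrame(sorted(ds.table.regions.items()),
                 columns=["site", "region"]).to_csv(
        outdir / "regions.csv", index=False)
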