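"""Dominant-vs-nondominant phylogenetic dispersion: MNTD/MPD, pooled tip-shuffle
nulls, standardized effect sizes, relatedness disparity, and local/global tests.

For each site the species ranked into the dominant and nondominant partitions
get an observed MNTD (mean distance of each member to its nearest co-member)
and MPD (mean over all pairs).  The null model reassigns species to partitions
uniformly at random within the site — equivalent to shuffling tree tips —
999 times; the observed and the random values are pooled and both partitions
are standardized by the *same* pool moments:

    D_SES  = (D_obs  − pool mean) / pool SD
    ND_SES = (ND_obs − pool mean) / pool SD
    Δ_SES  = D_SES − ND_SES            (relatedness disparity)

Negative SES means a partition is phylogenetically clustered, positive
overdispersed; negative Δ_SES means dominants are more closely related than
nondominants.  Local significance uses the ±1.96·s rule (s = 1 per partition,
√2 for the disparity, since Δ is a difference of two unit-variance scores);
global significance across sites uses a KS goodness-of-fit test against
N(0, s) when the values pass Shapiro–Wilk normality, otherwise a Wilcoxon
signed-rank test against zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .community import CommunityTable
from .dominance import dominance_metrics, partition_species, METRICS
from .trees import TreeIndex

__all__ = [
    "mntd", "mpd", "NullPool", "build_null_pool", "ses_disparity",
    "local_test", "global_test", "trait_distance_matrix",
    "run_dispersion_stage", "GlobalTestResult", "DispersionResult",
]


def _as_matrix(dist, subset):
    """Accept an ndarray + integer indices or a labelled DataFrame + labels."""
    if isinstance(dist, pd.DataFrame):
        idx = [dist.index.get_loc(s) for s in subset]
        return dist.to_numpy(), np.asarray(idx, dtype=np.intp)
    return np.asarray(dist, dtype=float), np.asarray(list(subset), dtype=np.intp)


def mntd(dist, subset) -> float:
    """Mean nearest taxon distance: for each member of ``subset``, its smallest
    distance to another member, averaged."""
    D, idx = _as_matrix(dist, subset)
    if idx.size < 2:
        raise ValueError("MNTD needs at least 2 species")
    sub = D[np.ix_(idx, idx)].copy()
    np.fill_diagonal(sub, np.inf)
    return float(sub.min(axis=1).mean())


def mpd(dist, subset) -> float:
    """Mean pairwise distance over all unordered pairs in ``subset``."""
    D, idx = _as_matrix(dist, subset)
    n = idx.size
    if n < 2:
        raise ValueError("MPD needs at least 2 species")
    sub = D[np.ix_(idx, idx)]
    return float(sub.sum() / (n * (n - 1)))


def _mntd_many(D: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """MNTD for many equal-sized subsets at once; idx has shape (m, s)."""
    sub = D[idx[:, :, None], idx[:, None, :]].copy()
    s = idx.shape[1]
    sub[:, np.arange(s), np.arange(s)] = np.inf
    return sub.min(axis=2).mean(axis=1)


def _mpd_many(D: np.ndarray, idx: np.ndarray) -> np.ndarray:
    sub = D[idx[:, :, None], idx[:, None, :]]
    s = idx.shape[1]
    return sub.sum(axis=(1, 2)) / (s * (s - 1))


_METRIC_FNS = {"mntd": (mntd, _mntd_many), "mpd": (mpd, _mpd_many)}


@dataclass
class NullPool:
    """Observed + randomly generated dispersion values for one site × metric.

    With ``pool='both'`` (default) the pool holds the two observed values and
    both partitions' random values from every iteration (2·n_iter + 2 values);
    with ``pool='per-partition'`` each partition is standardized against its
    own observed-plus-random values (n_iter + 1 each).
    """

    metric: str
    d_obs: float
    nd_obs: float
    d_random: np.ndarray
    nd_random: np.ndarray
    n_iter: int
    seed: int | None
    pool: str = "both"

    @property
    def values(self) -> np.ndarray:
        if self.pool == "both":
            return np.concatenate(
                [[self.d_obs, self.nd_obs], self.d_random, self.nd_random])
        return np.concatenate([[self.d_obs], self.d_random])

    def moments(self) -> tuple[float, float, float, float]:
        """(d_mean, d_sd, nd_mean, nd_sd) of the standardizing pools."""
        if self.pool == "both":
            v = self.values
            m, s = float(v.mean()), float(v.std(ddof=1))
            return m, s, m, s
        dv = np.concatenate([[self.d_obs], self.d_random])
        nv = np.concatenate([[self.nd_obs], self.nd_random])
        return (float(dv.mean()), float(dv.std(ddof=1)),
                float(nv.mean()), float(nv.std(ddof=1)))


def build_null_pool(
    dist,
    species,
    n_dominant: int,
    n_nondominant: int,
    dominant=None,
    nondominant=None,
    n_iter: int = 999,
    seed: int | None = None,
    metric: str = "mntd",
    pool: str = "both",
) -> NullPool:
    """Draw the partition-shuffle null for one site.

    Each of the ``n_iter`` iterations samples a disjoint random
    (n_dominant, n_nondominant) assignment from the site's species without
    replacement — the unweighted tip shuffle — and records both partitions'
    metric values.  ``dominant`` / ``nondominant`` give the observed partitions
    (defaults: the first/last species, mainly for calibration use).
    """
    if metric not in _METRIC_FNS:
        raise ValueError(f"unknown metric {metric!r}")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    D, all_idx = _as_matrix(dist, species)
    n = all_idx.size
    if n_dominant + n_nondominant > n:
        raise ValueError("partition sizes exceed site richness")
    if n_dominant < 2 or n_nondominant < 2:
        raise ValueError("each partition needs at least 2 species")
    single, many = _METRIC_FNS[metric]
    if dominant is None:
        dominant = list(species)[:n_dominant]
    if nondominant is None:
        nondominant = list(species)[-n_nondominant:]
    d_obs = single(dist, dominant)
    nd_obs = single(dist, nondominant)
    rng = np.random.default_rng(seed)
    perms = np.empty((n_iter, n), dtype=np.intp)
    base = np.arange(n)
    for i in range(n_iter):
        perms[i] = rng.permutation(base)
    site_idx = all_idx
    d_idx = site_idx[perms[:, :n_dominant]]
    nd_idx = site_idx[perms[:, n_dominant:n_dominant + n_nondominant]]
    d_random = many(D, d_idx)
    nd_random = many(D, nd_idx)
    return NullPool(metric=metric, d_obs=float(d_obs), nd_obs=float(nd_obs),
                    d_random=d_random, nd_random=nd_random,
                    n_iter=n_iter, seed=seed, pool=pool)


@dataclass
class DispersionResult:
    site: object
    dominance_metric: str
    metric: str
    k: int
    n_dominant: int
    n_nondominant: int
    d_obs: float
    nd_obs: float
    pool_mean: float
    pool_sd: float
    d_ses: float
    nd_ses: float
    delta_ses: float
    d_flag: str = "random"
    nd_flag: str = "random"
    delta_flag: str = "random"
    valid: bool = True
    reason: str = ""


def ses_disparity(pool: NullPool) -> dict:
    """Standardized effect sizes and the relatedness disparity from a pool.

    Raises
    ------
    ZeroDivisionError-like ValueError when the pool SD is 0 (degenerate
    distance structure, e.g. an equal-branch star tree); callers exclude such
    sites with a warning.
    """
    d_mean, d_sd, nd_mean, nd_sd = pool.moments()
    if d_sd <= 0 or nd_sd <= 0:
        raise ValueError("null pool has zero variance; SES undefined")
    d_ses = (pool.d_obs - d_mean) / d_sd
    nd_ses = (pool.nd_obs - nd_mean) / nd_sd
    return {
        "d_obs": pool.d_obs, "nd_obs": pool.nd_obs,
        "pool_mean": d_mean, "pool_sd": d_sd,
        "d_ses": float(d_ses), "nd_ses": float(nd_ses),
        "delta_ses": float(d_ses - nd_ses),
    }


def local_test(ses: float, role: str = "partition",
               multiplier: float = 1.96) -> str:
    """Classify one SES value against the ±multiplier·s band.

    ``role='partition'`` uses s = 1 (each SES has unit null variance);
    ``role='disparity'`` uses s = √2, the SD of a difference of two
    independent unit-variance scores.
    """
    if not np.isfinite(ses):
        raise ValueError("SES must be finite")
    s = {"partition": 1.0, "disparity": np.sqrt(2.0)}[role]
    bound = multiplier * s
    if ses < -bound:
        return "clustered"
    if ses > bound:
        return "overdispersed"
    return "random"


@dataclass
class GlobalTestResult:
    variable: str
    n: int
    mean: float
    sd: float
    shapiro_p: float
    normal: bool
    location_test: str
    location_p: float
    t_p: float | None = None
    variance_p: float | None = None
    expected_variance: float = 1.0


def global_test(values, expected_variance: float = 1.0,
                alpha: float = 0.05, variable: str = "") -> GlobalTestResult:
    """Across-site test of whether SES values are centred on zero.

    Shapiro–Wilk at ``alpha`` gates the branch: normal-looking samples get a
    Kolmogorov–Smirnov goodness-of-fit test against N(0, √expected_variance)
    plus a two-sided chi-square test of the variance (and a one-sample t-test
    for transparency); otherwise a two-sided Wilcoxon signed-rank test vs 0.
    """
    v = np.asarray(list(values), dtype=float)
    v = v[np.isfinite(v)]
    n = v.size
    if n < 8:
        raise ValueError(f"global test needs at least 8 sites, got {n}")
    if np.ptp(v) == 0:
        raise ValueError("degenerate input: all values identical")
    sw_stat, sw_p = stats.shapiro(v)
    normal = sw_p >= alpha
    mean, sd = float(v.mean()), float(v.std(ddof=1))
    t_p = None
    var_p = None
    if normal:
        ks = stats.kstest(v, "norm", args=(0.0, np.sqrt(expected_variance)))
        name, loc_p = "KS-goodness-of-fit", float(ks.pvalue)
        t_p = float(stats.ttest_1samp(v, 0.0).pvalue)
        chi2 = (n - 1) * v.var(ddof=1) / expected_variance
        lower = stats.chi2.cdf(chi2, n - 1)
        var_p = float(2 * min(lower, 1 - lower))
    else:
        w = stats.wilcoxon(v, alternative="two-sided")
        name, loc_p = "Wilcoxon signed-rank", float(w.pvalue)
    return GlobalTestResult(variable=variable, n=n, mean=mean, sd=sd,
                            shapiro_p=float(sw_p), normal=normal,
                            location_test=name, location_p=loc_p,
                            t_p=t_p, variance_p=var_p,
                            expected_variance=expected_variance)


DEFAULT_TRAIT_TRANSFORMS = {
    "seed_mass": "log10",
    "height": "log10",
    "ldmc": "identity",
    "leaf_n": "identity",
}


def trait_distance_matrix(traits: pd.DataFrame, trait: str,
                          transform: str | None = None
                          ) -> tuple[pd.DataFrame, float]:
    """Absolute-difference distance matrix for one trait.

    ``transform`` is ``'log10'`` or ``'identity'``; by default size-like traits
    (seed mass, plant height) are log10-transformed and ratio-like traits
    (LDMC, leaf N) left as-is.  Species missing the trait are dropped; the
    second return value is the coverage fraction.
    """
    if trait not in traits.columns:
        raise KeyError(f"trait {trait!r} not in table")
    if transform is None:
        transform = DEFAULT_TRAIT_TRANSFORMS.get(trait, "identity")
    x = pd.to_numeric(traits[trait], errors="coerce").dropna()
    coverage = len(x) / len(traits) if len(traits) else 0.0
    if len(x) < 2:
        raise ValueError(f"fewer than 2 species have trait {trait!r}")
    vals = np.log10(x.to_numpy()) if transform == "log10" else x.to_numpy()
    D = np.abs(vals[:, None] - vals[None, :])
    return pd.DataFrame(D, index=x.index, columns=x.index), coverage


def run_dispersion_stage(
    table: CommunityTable,
    tree_index: TreeIndex,
    dominance_metrics_used=METRICS,
    metrics=("mntd", "mpd"),
    ks=(3, 2),
    n_iter: int = 999,
    seed: int | None = None,
    traits: pd.DataFrame | None = None,
    trait_names=(),
    pool: str = "both",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full per-site dispersion stage.

    For every site × dominance metric × dispersion metric × k, partitions the
    site, draws the null pool, and records SES values and local flags; then
    runs the global tests per combination (expected variance 1 for partition
    SES, 2 for the disparity).  Sites that fail a combination (too few species,
    zero-variance pool) are skipped for it, with the reason recorded.

    Returns (per-site results, global tests) as DataFrames.
    """
    coph = tree_index.cophenetic_frame()
    trait_mats = {}
    for tname in trait_names:
        if traits is None:
            raise ValueError("trait_names given without a trait table")
        trait_mats[f"trait-{tname}"] = trait_distance_matrix(traits, tname)[0]
    rows = []
    ss = np.random.SeedSequence(seed)
    site_seeds = {}
    for site in table.sites:
        site_seeds[site] = ss.spawn(1)[0]
    for dom_metric in dominance_metrics_used:
        for k in ks:
            for metric_label in list(metrics) + list(trait_mats):
                for site in table.sites:
                    row = _site_dispersion(
                        table, coph, trait_mats, site, dom_metric, k,
                        metric_label, n_iter, site_seeds[site], pool)
                    if row is not None:
                        rows.append(row)
    results = pd.DataFrame([r.__dict__ for r in rows])
    gl_rows = []
    if not results.empty:
        for (dm, k, metric), grp in results[results["valid"]].groupby(
                ["dominance_metric", "k", "metric"]):
            for var, col, ev in (("d_ses", "d_ses", 1.0),
                                 ("nd_ses", "nd_ses", 1.0),
                                 ("delta_ses", "delta_ses", 2.0)):
                vals = grp[col].to_numpy()
                if vals.size < 8:
                    continue
                res = global_test(vals, expected_variance=ev,
                                  variable=f"{var}.{metric}.{dm}.k{k}")
                d = res.__dict__.copy()
                d.update({"dominance_metric": dm, "k": k, "metric": metric,
                          "component": var})
                gl_rows.append(d)
    return results, pd.DataFrame(gl_rows)


def _site_dispersion(table, coph, trait_mats, site, dom_metric, k,
                     metric_label, n_iter, seed_seq, pool):
    dm = dominance_metrics(table, site)
    if len(dm) < k:
        return None
    part = partition_species(dm, metric=dom_metric, k=k)
    dom = part.index[part["group"] == "dominant"].tolist()
    nd = part.index[part["group"] == "nondominant"].tolist()
    if metric_label.startswith("trait-"):
        dist = trait_mats[metric_label]
        avail = set(dist.index)
        dom = [s for s in dom if s in avail]
        nd = [s for s in nd if s in avail]
        # trait analogue of MNTD (nearest-neighbour trait distance)
        metric = "mntd"
        base_metric = metric_label
    else:
        dist = coph
        avail = set(dist.index)
        dom = [s for s in dom if s in avail]
        nd = [s for s in nd if s in avail]
        metric = metric_label
        base_metric = metric_label
    species = [s for s in part.index if s in avail]
    if len(dom) < 2 or len(nd) < 2:
        return DispersionResult(
            site=site, dominance_metric=dom_metric, metric=base_metric, k=k,
            n_dominant=len(dom), n_nondominant=len(nd),
            d_obs=np.nan, nd_obs=np.nan, pool_mean=np.nan, pool_sd=np.nan,
            d_ses=np.nan, nd_ses=np.nan, delta_ses=np.nan,
            valid=False, reason="partition<2 usable species")
    child_seed = int(seed_seq.generate_state(1)[0] % (2**31))
    np_pool = build_null_pool(
        dist, species, len(dom), len(nd), dominant=dom, nondominant=nd,
        n_iter=n_iter, seed=child_seed, metric=metric, pool=pool)
    try:
        frag = ses_disparity(np_pool)
    except ValueError as exc:
        return DispersionResult(
            site=site, dominance_metric=dom_metric, metric=base_metric, k=k,
            n_dominant=len(dom), n_nondominant=len(nd),
            d_obs=np_pool.d_obs, nd_obs=np_pool.nd_obs,
            pool_mean=np.nan, pool_sd=np.nan,
            d_ses=np.nan, nd_ses=np.nan, delta_ses=np.nan,
            valid=False, reason=str(exc))
    return DispersionResult(
        site=site, dominance_metric=dom_metric, metric=base_metric, k=k,
        n_dominant=len(dom), n_nondominant=len(nd),
        d_flag=local_test(frag["d_ses"], "partition"),
        nd_flag=local_test(frag["nd_ses"], "partition"),
        delta_flag=local_test(frag["delta_ses"], "disparity"),
        **frag)
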