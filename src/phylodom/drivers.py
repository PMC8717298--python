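"""Drivers of relatedness disparity: backward-stepwise AIC model selection,
graminoid-prevalence-mediated d-separation tests and grouped R² attribution.

The relatedness responses (Δ_SES, D_SES, ND_SES for MNTD or MPD) are modelled
with ordinary least squares against site descriptors.  A backward-stepwise
pass under AIC finds the preferred predictor subset; each retained predictor
is then tested for conditional independence from the response given graminoid
prevalence (the assumed mediator) by refitting ``response ~ predictor +
prevalence`` and examining the predictor's partial t-test.  Grouped ΔR²
attributes explained variance to descriptor categories by refitting the final
model without each category's retained variables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "backward_stepwise_aic", "dsep_test", "grouped_r2", "residual_normality",
    "run_drivers_stage", "site_descriptors", "StepwiseResult",
    "DEFAULT_GROUPS",
]

# Descriptor categories used for the grouped variance attribution.
DEFAULT_GROUPS = {
    "location": ["elevation", "latitude", "longitude"],
    "climate": ["mat", "precip_log", "diurnal_range", "annual_range"],
    "management": ["anthropogenic", "grazed", "burned", "recent"],
    "topology": ["gamma", "richness", "site_mpd", "site_mntd"],
    "biomass": ["graminoid_prevalence", "biomass_log", "legume_biomass_log"],
}


def _design(X: pd.DataFrame, cols) -> pd.DataFrame:
    return sm.add_constant(X[list(cols)], has_constant="add")


def _fit(y, X: pd.DataFrame, cols):
    return sm.OLS(np.asarray(y, float), _design(X, cols)).fit()


@dataclass
class StepwiseResult:
    retained: list
    params: pd.Series
    pvalues: pd.Series
    aic: float
    r2: float
    aic_trace: list = field(default_factory=list)
    model: object = None


def backward_stepwise_aic(y, X: pd.DataFrame) -> StepwiseResult:
    """Backward-stepwise OLS selection under AIC.

    Starts from the full model; at each step refits with every single
    predictor removed and drops the one whose removal lowers AIC most (ties
    broken alphabetically); stops when no removal lowers AIC.  Deterministic
    and invariant to column order.

    Raises
    ------
    ValueError
        When the design is rank-deficient (lists the collinear columns) or
        n ≤ p + 2.
    """
    X = X.copy()
    cols = sorted(X.columns)
    y = np.asarray(y, dtype=float)
    if len(y) <= len(cols) + 2:
        raise ValueError("too few observations for the number of predictors")
    design = _design(X, cols).to_numpy()
    if np.linalg.matrix_rank(design) < design.shape[1]:
        bad = _collinear_columns(X[cols])
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    current = list(cols)
    model = _fit(y, X, current)
    trace = [(tuple(current), float(model.aic))]
    while current:
        candidates = []
        for c in sorted(current):
            reduced = [x for x in current if x != c]
            m = _fit(y, X, reduced)
            candidates.append((float(m.aic), c, m))
        best_aic, best_col, best_model = min(candidates, key=lambda t: (t[0], t[1]))
        if best_aic < model.aic:
            current = [x for x in current if x != best_col]
            model = best_model
            trace.append((tuple(current), best_aic))
        else:
            break
    return StepwiseResult(
        retained=sorted(current),
        params=model.params,
        pvalues=model.pvalues,
        aic=float(model.aic),
        r2=float(model.rsquared),
        aic_trace=trace,
        model=model,
    )


def _collinear_columns(X: pd.DataFrame) -> list:
    bad = []
    cols: list = []
    for c in X.columns:
        trial = cols + [c]
        m = sm.add_constant(X[trial], has_constant="add").to_numpy()
        if np.linalg.matrix_rank(m) < m.shape[1]:
            bad.append(c)
        else:
            cols.append(c)
    return bad


def dsep_test(y, x, mediator) -> dict:
    """Independence-claim test: is ``y`` d-separated from ``x`` given the
    mediator?

    Fits ``y ~ x + mediator`` by OLS and returns the predictor's partial
    coefficient test as a dict with keys estimate, se, t, p, n, plus the
    Shapiro–Wilk p of the residuals.  A small p rejects conditional
    independence (a direct path beyond the mediator).
    """
    df = pd.DataFrame({"y": np.asarray(y, float),
                       "x": np.asarray(x, float),
                       "m": np.asarray(mediator, float)}).dropna()
    if len(df) < 10:
        raise ValueError(f"need >=10 complete cases, got {len(df)}")
    if df["m"].nunique() <= 1:
        raise ValueError("mediator is constant")
    model = sm.OLS(df["y"], sm.add_constant(df[["x", "m"]])).fit()
    return {
        "estimate": float(model.params["x"]),
        "se": float(model.bse["x"]),
        "t": float(model.tvalues["x"]),
        "p": float(model.pvalues["x"]),
        "n": int(len(df)),
        "df_resid": int(model.df_resid),
        "residual_normality_p": residual_normality(model),
    }


def grouped_r2(y, X: pd.DataFrame, retained, groups=None) -> pd.Series:
    """ΔR² per descriptor category: R² of the final model minus the R² of the
    same model with that category's retained variables removed.

    Categories with no retained variables get ΔR² = 0.  Under collinearity
    the ΔR² need not sum to the full R².
    """
    groups = DEFAULT_GROUPS if groups is None else groups
    retained = sorted(retained)
    full = _fit(y, X, retained)
    out = {}
    for gname, members in groups.items():
        drop = [c for c in retained if c in set(members)]
        if not drop:
            out[gname] = 0.0
            continue
        reduced = [c for c in retained if c not in set(members)]
        r2_reduced = _fit(y, X, reduced).rsquared if reduced else \
            _fit(y, X, []).rsquared
        out[gname] = float(full.rsquared - r2_reduced)
    return pd.Series(out, name="delta_r2")


def residual_normality(model) -> float:
    """Shapiro–Wilk p-value of a fitted model's residuals (n ≥ 8 required)."""
    resid = np.asarray(model.resid, dtype=float)
    if resid.size < 8:
        raise ValueError("need at least 8 residuals for Shapiro-Wilk")
    return float(stats.shapiro(resid).pvalue)


def site_descriptors(table, tree_index) -> pd.DataFrame:
    """Assemble the per-site descriptor table used by the driver models.

    Combines the covariates (elevation, climate, management flags), biomass
    descriptors (graminoid prevalence, log₁₀ total and legume biomass),
    community descriptors (richness, site-level MPD/MNTD) and the gamma
    statistic of the pruned site tree.  Precipitation is log₁₀-transformed.
    """
    from .dispersion import mntd, mpd
    from .trees import gamma_statistic, prune_to_site

    desc = table.covariates.copy() if table.covariates is not None \
        else pd.DataFrame(index=pd.Index(table.sites, name="site"))
    if "precip" in desc.columns:
        desc["precip_log"] = np.log10(desc.pop("precip"))
    if table.biomass is not None:
        desc["graminoid_prevalence"] = table.graminoid_prevalence()
        desc["biomass_log"] = np.log10(
            table.biomass.groupby("site")["mass"].sum())
        legume = (table.biomass[table.biomass["functional_group"] == "legume"]
                  .groupby("site")["mass"].sum())
        desc["legume_biomass_log"] = np.log10(
            legume.reindex(desc.index).fillna(0.0) + 1.0)
    coph = tree_index.cophenetic_frame()
    rich, smpd, smntd, gam = {}, {}, {}, {}
    for site in desc.index:
        sp = [s for s in table.site_species(site) if s in coph.index]
        rich[site] = len(sp)
        if len(sp) >= 2:
            smpd[site] = mpd(coph, sp)
            smntd[site] = mntd(coph, sp)
        if len(sp) >= 3:
            try:
                gam[site] = gamma_statistic(
                    prune_to_site(tree_index.tree, sp))
            except ValueError:
                pass
    desc["richness"] = pd.Series(rich)
    desc["site_mpd"] = pd.Series(smpd)
    desc["site_mntd"] = pd.Series(smntd)
    desc["gamma"] = pd.Series(gam)
    return desc


def run_drivers_stage(
    descriptors: pd.DataFrame,
    responses: pd.DataFrame,
    mediator: str = "graminoid_prevalence",
    groups=None,
) -> dict:
    """Model every response column against the descriptor table.

    Listwise deletion is applied per response (count reported).  For each
    response: backward-AIC selection over all descriptors, Shapiro–Wilk on
    the final residuals, d-separation tests of each retained predictor other
    than the mediator (controlling for the mediator), and grouped ΔR².

    Returns a dict response → {stepwise, dsep (DataFrame), grouped_r2,
    residual_normality_p, n, n_dropped}.
    """
    groups = DEFAULT_GROUPS if groups is None else groups
    if mediator not in descriptors.columns:
        raise ValueError(f"mediator {mediator!r} not among descriptors")
    out = {}
    for resp in responses.columns:
        joined = descriptors.join(responses[resp], how="inner").dropna()
        n_dropped = len(descriptors) - len(joined)
        y = joined[resp]
        X = joined[descriptors.columns]
        step = backward_stepwise_aic(y, X)
        dsep_rows = []
        for pred in step.retained:
            if pred == mediator:
                continue
            res = dsep_test(y, X[pred], X[mediator])
            res["predictor"] = pred
            dsep_rows.append(res)
        out[resp] = {
            "stepwise": step,
            "dsep": pd.DataFrame(dsep_rows),
            "grouped_r2": grouped_r2(y, X, step.retained, groups),
            "residual_normality_p": residual_normality(step.model),
            "n": len(joined),
            "n_dropped": n_dropped,
        }
    return out
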