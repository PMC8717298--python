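"""What drives relatedness disparity across sites?

Plants a graminoid-prevalence → dominant-clustering effect in the generator
(prevalence_coupling=True), then models per-site Δ_SES.MNTD against the site
descriptors: backward-AIC selection, d-separation tests controlled by
graminoid prevalence, and grouped ΔR² attribution.
"""

from phylodom import (ScenarioConfig, TreeIndex, run_dispersion_stage,
                      run_drivers_stage, simulate_dataset, site_descriptors)

ds = simulate_dataset(ScenarioConfig(
    scenario="clustered_dominants", n_sites=62, seed=42,
    prevalence_coupling=True))
idx = TreeIndex(ds.tree.tree)
res, _ = run_dispersion_stage(ds.table, idx, dominance_metrics_used=("cover",),
                              metrics=("mntd",), ks=(3,), n_iter=999, seed=42)

desc = site_descriptors(ds.table, idx)
models = run_drivers_stage(desc, res.set_index("site")[["delta_ses"]])
m = models["delta_ses"]
step = m["stepwise"]
print("retained predictors:", step.retained)
print("model R² = %.2f   residual normality p = %.2f" % (
    step.r2, m["residual_normality_p"]))
print("\nΔR² by descriptor category:")
print(m["grouped_r2"].round(3).to_string())
# biomass (which contains graminoid prevalence) should carry a large share:
# the generator made prevalence the true driver of dominant clustering.
if not m["dsep"].empty:
    print("\nd-separation tests (controlling for graminoid prevalence):")
    print(m["dsep"][["predictor", "estimate", "se", "t", "p"]]
          .round(3).to_string(index=False))
    # large p: the predictor's correlation with Δ_SES is mediated by
    # prevalence (conditional independence holds).
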