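"""Simulate a grassland metacommunity and partition each site by dominance.

Builds a 40-site clustered-dominants metacommunity (one clade supplies the
high-cover species), computes each species' cover / frequency / cover-PO at
one site, and splits the site into equal dominance thirds.
"""

from phylodom import ScenarioConfig, dominance_metrics, partition_species, simulate_dataset

ds = simulate_dataset(ScenarioConfig(
    scenario="clustered_dominants", n_sites=40, seed=42))
site = ds.table.sites[0]

metrics = dominance_metrics(ds.table, site)
print(f"{site}: {len(metrics)} species over {metrics['n_plots'].iloc[0]} plots")
print(metrics.sort_values('cover', ascending=False).head(5).round(3))
# 'cover' is the mean % cover over all plots (zeros included) and always
# equals frequency x cover_po; the top rows are the site's dominants.

part = partition_species(metrics, metric="cover", k=3)
print(part.groupby("group").size().to_string())
# equal thirds: the dominant and nondominant groups are always the same size.
print("top-ranked dominant:", part.index[0])
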