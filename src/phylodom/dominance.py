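"""Dominance metrics and the equal-thirds partitioning of site species lists.

For each site, every species has three linked dominance measures over the
site's quadrats:

* ``cover`` — mean percent cover across all plots, zeros included;
* ``frequency`` — the proportion of plots the species occupies (0–1);
* ``cover_po`` — its mean cover in the plots where it is present;

with the exact identity ``cover = frequency × cover_po``.  Ranking by one of
these and splitting into k equal groups defines the dominant / (intermediate) /
nondominant partitions the rest of the pipeline compares.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .community import CommunityTable

__all__ = ["dominance_metrics", "partition_species", "partition_all_sites",
           "METRICS", "GROUPS_K3", "GROUPS_K2"]

METRICS = ("cover", "frequency", "cover_po")
GROUPS_K3 = ("dominant", "intermediate", "nondominant")
GROUPS_K2 = ("dominant", "nondominant")


def dominance_metrics(table: CommunityTable, site) -> pd.DataFrame:
    """Per-species cover, frequency and cover-presence-only for one site.

    Species with zero cover in every plot are treated as absent.  Returns a
    DataFrame indexed by species with columns cover, frequency, cover_po and
    n_plots; the identity cover = frequency · cover_po holds to float precision.
    """
    sub = table.cover[table.cover["site"] == site]
    if sub.empty:
        raise KeyError(f"unknown site: {site!r}")
    n_plots = sub["plot"].nunique()
    present = sub[sub["cover"] > 0]
    grp = present.groupby("species")["cover"]
    cover_po = grp.mean()
    freq = grp.size() / n_plots
    out = pd.DataFrame({
        "cover": freq * cover_po,
        "frequency": freq,
        "cover_po": cover_po,
    })
    out["n_plots"] = n_plots
    out.index.name = "species"
    return out.sort_index()


def partition_species(metrics: pd.DataFrame, metric: str = "cover",
                      k: int = 3) -> pd.DataFrame:
    """Rank species by a dominance metric and split into k equal groups.

    Ranks descend by ``metric``; ties are broken by frequency, then cover_po
    (both descending), then species name ascending, so the assignment is a
    deterministic function of the table's content.  Groups fill dominant-first;
    when the species count is not divisible by k the remainder goes to the
    intermediate group (k=3) or the nondominant group (k=2), keeping the two
    compared extremes equal-sized for k=3.

    Returns a DataFrame indexed by species with columns rank (1 = most
    dominant), value, and group.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown dominance metric {metric!r}; choose from {METRICS}")
    if k not in (2, 3):
        raise ValueError("k must be 2 or 3")
    n = len(metrics)
    if n < k:
        raise ValueError(f"site has {n} species; need at least k={k}")
    order = metrics.reset_index().sort_values(
        by=[metric, "frequency", "cover_po", "species"],
        ascending=[False, False, False, True],
        kind="mergesort",
    )["species"].tolist()
    base, rem = divmod(n, k)
    if k == 3:
        sizes = [base, base + rem, base]
        groups = GROUPS_K3
    else:
        sizes = [base, base + rem]
        groups = GROUPS_K2
    labels = []
    for g, s in zip(groups, sizes):
        labels.extend([g] * s)
    out = pd.DataFrame(
        {
            "rank": np.arange(1, n + 1),
            "value": metrics.loc[order, metric].to_numpy(),
            "group": labels,
        },
        index=pd.Index(order, name="species"),
    )
    return out


def partition_all_sites(table: CommunityTable, metric: str = "cover",
                        k: int = 3, min_species: int | None = None) -> pd.DataFrame:
    """Partition every site; returns long DataFrame (site, species, rank, value,
    group).  Sites with fewer species than ``min_species`` (default k) are
    skipped."""
    min_species = k if min_species is None else min_species
    frames = []
    for site in table.sites:
        m = dominance_metrics(table, site)
        if len(m) < max(min_species, k):
            continue
        part = partition_species(m, metric=metric, k=k).reset_index()
        part.insert(0, "site", site)
        frames.append(part)
    if not frames:
        return pd.DataFrame(columns=["site", "species", "rank", "value", "group"])
    return pd.concat(frames, ignore_index=True)
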