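"""Binomial dominance scans over phylogeny branches and genera.

Every species × site occurrence falls in exactly one dominance partition.
For a lineage (the clade below any branch of the megaphylogeny, or a genus),
the occurrences of its descendant species are aggregated over all sites; if
partition membership were unrelated to phylogeny, each occurrence would land
in each of the three partitions with probability 1/3.  An exact two-sided
binomial test (minimum-likelihood summation) per branch × partition flags
lineages enriched or depleted in dominants, run only on branches with at
least 10 occurrences; the genus-level scan keeps every genus regardless of
count.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .trees import TreeIndex

__all__ = ["lineage_counts", "binomial_scan", "genus_scan"]

PARTITIONS = ("dominant", "intermediate", "nondominant")


def lineage_counts(index: TreeIndex, partitions: pd.DataFrame) -> pd.DataFrame:
    """Per-branch occurrence counts by dominance partition.

    ``partitions`` is the long k=3 assignment table (site, species, group).
    Each branch of the tree defines the lineage of tips below it; a species'
    occurrences (one per site where it is present) count toward every branch
    on its root path.  Returns one row per branch × partition with ``k_hits``
    (occurrences in that partition), ``n_total`` (occurrences in any
    partition), the clade size and a tip sample for reporting.
    """
    missing = set(partitions["species"]) - set(index.tip_index)
    if missing:
        raise ValueError(
            f"species absent from tree (graft them first): {sorted(missing)[:5]}")
    occ = (partitions.groupby(["species", "group"]).size()
           .unstack(fill_value=0)
           .reindex(columns=list(PARTITIONS), fill_value=0))
    tip_occ = np.zeros((index.n_tips, len(PARTITIONS)), dtype=np.int64)
    rows_idx = index.indices(occ.index.tolist())
    tip_occ[rows_idx] = occ.to_numpy()
    branch_counts = index.tip_edges.T.astype(np.int64) @ tip_occ  # (E, 3)
    n_total = branch_counts.sum(axis=1)
    tips_arr = np.array(index.tips)
    records = []
    for e in range(branch_counts.shape[0]):
        if n_total[e] == 0:
            continue
        below = tips_arr[index.tip_edges[:, e]]
        sample = ",".join(below[:3])
        for pi, p in enumerate(PARTITIONS):
            records.append({
                "node": e,
                "clade_size": int(below.size),
                "tip_sample": sample,
                "partition": p,
                "k_hits": int(branch_counts[e, pi]),
                "n_total": int(n_total[e]),
            })
    return pd.DataFrame(records)


def binomial_scan(counts: pd.DataFrame, p0: float = 1 / 3,
                  min_count: int = 10, bh_correct: bool = False) -> pd.DataFrame:
    """Exact binomial test per lineage × partition against ``p0``.

    Rows with ``n_total < min_count`` are kept but flagged untested (no p).
    Two-sided p-values use the exact minimum-likelihood summation (scipy's
    ``binomtest``).  Optional Benjamini–Hochberg correction over the tested
    rows adds a ``p_adj`` column.
    """
    out = counts.copy()
    out["tested"] = out["n_total"] >= min_count
    pvals = np.full(len(out), np.nan)
    for i, (_, r) in enumerate(out.iterrows()):
        if r["tested"]:
            pvals[i] = stats.binomtest(int(r["k_hits"]), int(r["n_total"]),
                                       p0).pvalue
    out["proportion"] = out["k_hits"] / out["n_total"]
    out["p"] = pvals
    out["direction"] = np.where(out["proportion"] >= p0, "enriched", "depleted")
    if bh_correct:
        tested = out["tested"].to_numpy()
        padj = np.full(len(out), np.nan)
        if tested.any():
            from statsmodels.stats.multitest import multipletests
            padj[tested] = multipletests(out.loc[tested, "p"], method="fdr_bh")[1]
        out["p_adj"] = padj
    return out


def genus_scan(partitions: pd.DataFrame, genus_of=None,
               p0: float = 1 / 3) -> pd.DataFrame:
    """Genus-level binomial scan, including all genera regardless of count.

    ``genus_of`` maps species → genus; by default the leading ``Genus_``
    component of the species name is used.
    """
    part = partitions.copy()
    if genus_of is None:
        part["genus"] = part["species"].str.split("_").str[0]
    else:
        genus_of = dict(genus_of)
        unknown = set(part["species"]) - set(genus_of)
        if unknown:
            raise ValueError(f"no genus for species: {sorted(unknown)[:5]}")
        part["genus"] = part["species"].map(genus_of)
    counts = (part.groupby(["genus", "group"]).size()
              .unstack(fill_value=0)
              .reindex(columns=list(PARTITIONS), fill_value=0))
    records = []
    for genus, row in counts.iterrows():
        n = int(row.sum())
        for p in PARTITIONS:
            records.append({"node": genus, "clade_size": np.nan,
                            "tip_sample": genus, "partition": p,
                            "k_hits": int(row[p]), "n_total": n})
    return binomial_scan(pd.DataFrame(records), p0=p0, min_count=0)
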