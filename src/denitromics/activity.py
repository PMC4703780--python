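"""Per-gene transcriptional activity, normalized within each bin.

RNA reads mapped to the contigs are counted per gene (a read counts toward
the gene containing its alignment midpoint).  The activity of gene g is its
read-count density (count / gene length) divided by the mean density of all
genes of its bin, so that the average activity within every bin equals 1: a
value above 1 means above-average transcription for that population, below
1 below-average.  Bins without any mapped read have undefined activities,
emitted as missing.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

ACTIVITY_COLUMNS = ["gene_id", "bin", "length", "rna_count", "density", "activity"]


def count_rna(assignments: pd.DataFrame, genes: pd.DataFrame) -> pd.Series:
    """Per-gene RNA read counts by the alignment-midpoint rule.

    ``assignments`` is the mapper output (contig_id, position, length);
    ``genes`` needs columns gene_id, contig, start, end (1-based inclusive).
    A read whose midpoint falls exactly on a gene boundary base counts to
    that gene.  If genes overlap, the midpoint is credited to the gene with
    the lexicographically smaller id (flagged with a warning).  Reads whose
    midpoint is outside every gene are intergenic and not counted.
    """
    counts = pd.Series(0, index=pd.Index(genes["gene_id"], name="gene_id"), dtype=int)
    assigned = assignments.dropna(subset=["contig_id"])
    overlap_flagged = False
    by_contig: dict[str, pd.DataFrame] = {}
    for contig, grp in genes.groupby("contig"):
        g = grp.sort_values(["start", "gene_id"]).reset_index(drop=True)
        if np.any(g["start"].to_numpy()[1:] <= g["end"].to_numpy()[:-1]):
            overlap_flagged = True
        by_contig[contig] = g
    if overlap_flagged:
        warnings.warn(
            "overlapping genes: midpoints credited to the smaller gene_id",
            stacklevel=2,
        )
    for _, read in assigned.iterrows():
        g = by_contig.get(read["contig_id"])
        if g is None:
            continue
        mid = int(read["position"]) + (int(read["length"]) - 1) // 2
        hits = g[(g["start"] <= mid) & (mid <= g["end"])]
        if len(hits):
            gid = sorted(hits["gene_id"])[0]
            counts[gid] += 1
    return counts


def normalize_activity(
    counts: pd.Series,
    lengths: pd.Series | dict[str, int],
    bins: pd.Series | dict[str, str],
    expressed_only: bool = False,
) -> pd.DataFrame:
    """Normalize per-gene densities to the bin average.

    activity(g) = density(g) / mean(density over genes of bin(g)), density
    being count/length.  With ``expressed_only`` the bin mean is taken over
    genes with at least one read instead of all annotated genes.  Bins whose
    genes have no reads at all get missing activities.  The defined
    activities of every bin average to 1 exactly (up to float rounding).
    """
    lengths = pd.Series(lengths)
    bins = pd.Series(bins)
    if (lengths <= 0).any():
        raise ValueError("zero or negative gene length")
    idx = counts.index
    df = pd.DataFrame(
        {
            "gene_id": idx,
            "bin": bins.reindex(idx).to_numpy(),
            "length": lengths.reindex(idx).to_numpy(),
            "rna_count": counts.to_numpy(),
        }
    )
    if df["bin"].isna().any():
        raise ValueError("every gene must belong to exactly one bin")
    df["density"] = df["rna_count"] / df["length"]
    activities = np.full(len(df), np.nan)
    for b, grp in df.groupby("bin"):
        sel = grp
        if expressed_only:
            sel = grp[grp["rna_count"] > 0]
        mean_density = sel["density"].mean() if len(sel) else 0.0
        if mean_density > 0:
            activities[grp.index] = grp["density"] / mean_density
    df["activity"] = activities
    return df[ACTIVITY_COLUMNS]
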