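"""Functional guild classification of bins and guild abundance aggregation.

A bin is a *denitrifier* when it carries any of the denitrification genes
(nirS, nirK, nosZ), *fermentative* when it carries the pyruvate formate
lyase gene pflB, *both* when it carries genes of both kinds, and
*unclassified* otherwise.  Note pflB is the only unambiguous fermentation
marker assessed (genes like acetate kinase are bidirectional), so
"denitrifier" bins may still ferment by other pathways; the report carries
this caveat as a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

DENITRIFICATION_GENES = frozenset({"nirS", "nirK", "nosZ"})
FERMENTATION_GENES = frozenset({"pflB"})

GUILD_LABELS = ("denitrifier", "fermentative", "both", "unclassified")


@dataclass
class GuildProfile:
    bin_id: str
    has_denitrification: bool
    has_fermentation: bool
    label: str
    sublabel: str = ""  # informational: partial-denitrifier subtype


def _sublabel(families: set[str]) -> str:
    """Informational denitrification subtype (not part of the guild rule)."""
    nir = bool(families & {"nirS", "nirK"})
    nos = "nosZ" in families
    if nir and nos:
        return "complete"
    if nir:
        return "nitrite_reducer"
    if nos:
        return "n2o_reducer"
    return ""


def classify_bin(bin_id: str, families: set[str] | list[str]) -> GuildProfile:
    """Classify one bin from the set of functional-gene families detected."""
    fams = set(families)
    deni = bool(fams & DENITRIFICATION_GENES)
    ferm = bool(fams & FERMENTATION_GENES)
    if deni and ferm:
        label = "both"
    elif deni:
        label = "denitrifier"
    elif ferm:
        label = "fermentative"
    else:
        label = "unclassified"
    return GuildProfile(
        bin_id=bin_id,
        has_denitrification=deni,
        has_fermentation=ferm,
        label=label,
        sublabel=_sublabel(fams),
    )


def classify_bins(
    gene_hits: pd.DataFrame,
    bin_of_contig: pd.Series | dict[str, str] | None = None,
    bins: list[str] | None = None,
    require_transcription: bool = False,
) -> pd.DataFrame:
    """Classify all bins from a gene-hit table.

    ``gene_hits`` needs ``family`` plus either a ``bin`` column or a
    ``contig`` column resolved through ``bin_of_contig``.  ``bins`` may list
    additional bins without any hit (classified "unclassified").  With
    ``require_transcription`` only hits with a positive ``activity`` count
    as presence.
    """
    warnings.warn(
        "pflB is the only fermentation marker assessed; 'denitrifier' bins "
        "may still ferment via other pathways",
        stacklevel=2,
    )
    hits = gene_hits.copy()
    if "bin" not in hits.columns:
        if bin_of_contig is None:
            raise ValueError("need a 'bin' column or bin_of_contig")
        mapping = pd.Series(bin_of_contig)
        hits["bin"] = hits["contig"].map(mapping)
    if require_transcription and "activity" in hits.columns:
        hits = hits[pd.to_numeric(hits["activity"], errors="coerce") > 0]
    fams_by_bin: dict[str, set] = {b: set() for b in (bins or [])}
    for _, row in hits.dropna(subset=["bin"]).iterrows():
        fams_by_bin.setdefault(row["bin"], set()).add(row["family"])
    rows = []
    for b in sorted(fams_by_bin):
        p = classify_bin(b, fams_by_bin[b])
        rows.append(
            dict(bin=b, has_denitrification=p.has_denitrification,
                 has_fermentation=p.has_fermentation, label=p.label,
                 sublabel=p.sublabel)
        )
    return pd.DataFrame(
        rows, columns=["bin", "has_denitrification", "has_fermentation",
                       "label", "sublabel"]
    ).set_index("bin")


def aggregate_guilds(
    profiles: pd.DataFrame, abundance: pd.DataFrame | pd.Series
) -> pd.DataFrame:
    """Sum bin abundances by guild label (per sample).

    ``abundance`` is bins x samples (a Series is treated as one sample);
    an ``unbinned`` row, if present, is carried through unchanged so each
    sample's guild sums plus unclassified plus unbinned total 1.  A bin with
    abundance but no profile raises an error naming the bin.
    """
    if isinstance(abundance, pd.Series):
        abundance = abundance.to_frame("sample")
    labels = {}
    for b in abundance.index:
        if b == "unbinned":
            labels[b] = "unbinned"
            continue
        if b not in profiles.index:
            raise KeyError(f"no guild profile for bin {b!r}")
        labels[b] = profiles.loc[b, "label"]
    grouped = abundance.groupby(abundance.index.map(labels)).sum()
    order = [l for l in (*GUILD_LABELS, "unbinned") if l in grouped.index]
    out = grouped.loc[order]
    out.index.name = "guild"
    return out
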