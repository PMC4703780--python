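"""Functional-gene detection on contigs by six-frame translation and
position-specific scoring-matrix (PSSM) scanning.

The target families are the key denitrification genes (*nirS*: cytochrome
cd1 nitrite reductase, *nirK*: copper nitrite reductase, *nosZ*: nitrous
oxide reductase) and the fermentation marker *pflB* (pyruvate formate
lyase).  For each family an ungapped log-odds profile is built from a seed
multiple alignment and slid over all six reading frames of every contig;
best windows are mapped back to 1-based inclusive DNA coordinates with the
correct strand.  Adjacent same-strand windows in different frames are merged
into a single hit, which recovers genes broken by artefactual frameshifts
(mono-nucleotide run indels typical of ion-semiconductor reads).

The bundled seed alignments under ``data/seed_alignments`` are *synthetic*
stand-ins generated from a seeded random model (one distinct consensus per
family); substitute curated alignments via :func:`build_profile` for real
data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import AlignIO

from ._seq import revcomp, translate

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
#: column index used for stops, X and any other non-standard symbol
_UNKNOWN = 20
#: fixed penalty (bits) for scoring a stop/ambiguous residue
UNKNOWN_SCORE = -4.0

DEFAULT_FAMILIES = ("nirS", "nirK", "nosZ", "pflB")

#: uniform amino-acid background; profile scores are relative to this
UNIFORM_BACKGROUND = np.full(20, 1.0 / 20.0)


@dataclass
class ProteinProfile:
    """Ungapped log-odds profile over the 20 amino acids.

    ``matrix`` has shape (length, 21): one log2-odds column per alignment
    position plus a constant penalty column for stops/ambiguity.
    """

    family: str
    matrix: np.ndarray
    consensus: str
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    score_threshold: float | None = None

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    @property
    def max_score(self) -> float:
        """Score of the best residue at every column (consensus score)."""
        return float(self.matrix[:, :20].max(axis=1).sum())

    def score_peptide(self, peptide: str) -> float:
        """Score a peptide of exactly profile length against the profile."""
        if len(peptide) != self.length:
            raise ValueError("peptide length must equal profile length")
        idx = encode_peptide(peptide)
        return float(self.matrix[np.arange(self.length), idx].sum())


def encode_peptide(peptide: str) -> np.ndarray:
    """Map a peptide string to column indices 0..20 (20 = stop/unknown)."""
    return np.array([_AA_INDEX.get(a, _UNKNOWN) for a in peptide], dtype=np.int64)


def build_profile(
    alignment: list[str] | dict[str, str],
    family: str = "profile",
    background: np.ndarray | None = None,
    pseudocount: float = 0.1,
    max_gap_fraction: float = 0.5,
) -> ProteinProfile:
    """Build a log-odds profile from an aligned set of protein sequences.

    Per column, the frequency of amino acid ``a`` is
    ``(count_a + pseudocount) / (n_nongap + 20 * pseudocount)`` and its score
    is ``log2(frequency / background_a)``.  Columns with more than
    ``max_gap_fraction`` gap characters are dropped; gaps in retained columns
    are simply excluded from the counts.
    """
    seqs = list(alignment.values()) if isinstance(alignment, dict) else list(alignment)
    if len(seqs) < 2:
        raise ValueError("need at least 2 aligned sequences")
    ncol = len(seqs[0])
    if any(len(s) != ncol for s in seqs):
        raise ValueError("ragged alignment: sequences differ in length")
    bg = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    if bg.shape != (20,) or not np.isclose(bg.sum(), 1.0):
        raise ValueError("background must be a length-20 probability vector")

    cols: list[np.ndarray] = []
    consensus: list[str] = []
    for j in range(ncol):
        column = [s[j].upper() for s in seqs]
        gaps = sum(1 for c in column if c in "-.")
        if gaps > max_gap_fraction * len(column):
            continue
        counts = np.zeros(20)
        for c in column:
            if c in _AA_INDEX:
                counts[_AA_INDEX[c]] += 1
        n = counts.sum()
        if n == 0:
            continue
        freqs = (counts + pseudocount) / (n + 20.0 * pseudocount)
        scores = np.log2(freqs / bg)
        col = np.empty(21)
        col[:20] = scores
        col[_UNKNOWN] = UNKNOWN_SCORE
        cols.append(col)
        consensus.append(AMINO_ACIDS[int(np.argmax(counts))])
    if not cols:
        raise ValueError("alignment has no usable columns")
    return ProteinProfile(
        family=family,
        matrix=np.vstack(cols),
        consensus="".join(consensus),
        background=bg.copy(),
    )


def calibrate_threshold(
    profile: ProteinProfile,
    n_decoys: int = 1000,
    seed: int = 0,
    margin_fraction: float = 0.25,
) -> float:
    """Empirical score threshold from random decoy windows.

    Draws ``n_decoys`` windows of profile length with residues sampled i.i.d.
    from the background, takes their maximum score, and places the threshold
    a fraction ``margin_fraction`` of the way from that maximum up to the
    consensus score.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    L = profile.length
    draws = rng.choice(20, size=(n_decoys, L), p=profile.background)
    scores = profile.matrix[np.arange(L), draws].sum(axis=1)
    decoy_max = float(scores.max())
    return decoy_max + margin_fraction * (profile.max_score - decoy_max)


def _seed_alignment_path(family: str) -> Path:
    res = resources.files("denitromics").joinpath(
        f"data/seed_alignments/{family}.synthetic.afa"
    )
    with resources.as_file(res) as p:
        return Path(p)


def load_seed_alignment(family: str) -> dict[str, str]:
    """Load a bundled (synthetic) seed alignment for one gene family."""
    if family not in DEFAULT_FAMILIES:
        raise KeyError(f"no bundled seed alignment for family {family!r}")
    aln = AlignIO.read(str(_seed_alignment_path(family)), "fasta")
    return {rec.id: str(rec.seq) for rec in aln}


def default_profiles(
    families: tuple[str, ...] = DEFAULT_FAMILIES,
    pseudocount: float = 0.1,
    calibration_decoys: int = 1000,
) -> dict[str, ProteinProfile]:
    """Profiles for the default families, with decoy-calibrated thresholds."""
    profiles: dict[str, ProteinProfile] = {}
    for fam in families:
        prof = build_profile(load_seed_alignment(fam), family=fam, pseudocount=pseudocount)
        prof.score_threshold = calibrate_threshold(prof, n_decoys=calibration_decoys)
        profiles[fam] = prof
    return profiles


def six_frame_translate(sequence: str) -> list[tuple[int, str]]:
    """Translate a DNA sequence in all six frames (translation table 11).

    Frames 1-3 read the forward strand at offsets 0/1/2; frames 4-6 read the
    reverse complement at offsets 0/1/2.  Stops are ``*``; codons containing
    non-ACGT symbols become ``X``.
    """
    if len(sequence) < 3:
        raise ValueError("sequence shorter than one codon")
    seq = sequence.upper()
    rc = revcomp(seq)
    out = []
    for f in range(3):
        out.append((f + 1, translate(seq[f:])))
    for f in range(3):
        out.append((f + 4, translate(rc[f:])))
    return out


def _window_dna_coords(frame: int, pep_start: int, pep_len: int, contig_len: int):
    """Map a peptide window in a frame to 1-based inclusive DNA coordinates."""
    if frame <= 3:
        offset = frame - 1
        start = offset + 3 * pep_start + 1
        end = offset + 3 * (pep_start + pep_len)
        return start, end, "+"
    offset = frame - 4
    rc_start = offset + 3 * pep_start + 1
    rc_end = offset + 3 * (pep_start + pep_len)
    return contig_len - rc_end + 1, contig_len - rc_start + 1, "-"


def _frame_candidates(
    scores: np.ndarray, floor: float, window: int, max_candidates: int = 10
) -> list[tuple[int, float]]:
    """Greedy non-overlapping local maxima above ``floor``."""
    work = scores.copy()
    out: list[tuple[int, float]] = []
    while len(out) < max_candidates:
        j = int(np.argmax(work))
        s = float(work[j])
        if not np.isfinite(s) or s < floor:
            break
        out.append((j, s))
        lo = max(0, j - window + 1)
        work[lo : j + window] = -np.inf
    return out


def scan(
    profiles: dict[str, ProteinProfile],
    contigs: dict[str, str],
    min_score: float | None = None,
    frameshift_gap: int = 30,
    candidate_floor_fraction: float = 0.5,
) -> pd.DataFrame:
    """Scan contigs for profile matches in all six frames.

    Returns one row per merged hit with columns ``family, contig,
    contig_length, start, end, strand, frame, score, frameshift`` (DNA
    coordinates 1-based inclusive).  Same-strand windows of one family whose
    spans lie within ``frameshift_gap`` bp are merged into a single hit; when
    the merged windows come from different frames the hit is flagged
    ``frameshift=True`` and scored as the sum of the per-frame windows (the
    prefix and suffix of a broken gene match in different frames, so their
    scores are complementary).
    """
    rows = []
    for cid, seq in contigs.items():
        n = len(seq)
        if n < 3:
            continue
        frames = six_frame_translate(seq)
        encoded = [(f, encode_peptide(pep)) for f, pep in frames]
        for fam, prof in profiles.items():
            thr = prof.score_threshold if min_score is None else min_score
            if thr is None:
                raise ValueError(
                    f"profile {fam!r} has no score_threshold and no min_score given"
                )
            floor = candidate_floor_fraction * thr
            L = prof.length
            cands = []  # (start, end, strand, frame, score)
            for f, idx in encoded:
                nw = idx.size - L + 1
                if nw <= 0:
                    continue
                sc = np.zeros(nw)
                for i in range(L):
                    sc += prof.matrix[i, idx[i : i + nw]]
                for j, s in _frame_candidates(sc, floor, L):
                    start, end, strand = _window_dna_coords(f, j, L, n)
                    cands.append((start, end, strand, f, s))
            for strand in "+-":
                group = sorted(c for c in cands if c[2] == strand)
                cluster: list[tuple] = []
                clusters = []
                for c in group:
                    if cluster and c[0] > max(x[1] for x in cluster) + frameshift_gap:
                        clusters.append(cluster)
                        cluster = []
                    cluster.append(c)
                if cluster:
                    clusters.append(cluster)
                for cl in clusters:
                    best_per_frame: dict[int, tuple] = {}
                    for c in cl:
                        f = c[3]
                        if f not in best_per_frame or c[4] > best_per_frame[f][4]:
                            best_per_frame[f] = c
                    members = list(best_per_frame.values())
                    frameshift = len(members) > 1
                    score = (
                        sum(m[4] for m in members)
                        if frameshift
                        else max(m[4] for m in members)
                    )
                    if score < thr:
                        continue
                    best = max(members, key=lambda m: m[4])
                    rows.append(
                        {
                            "family": fam,
                            "contig": cid,
                            "contig_length": n,
                            "start": min(m[0] for m in members),
                            "end": max(m[1] for m in members),
                            "strand": strand,
                            "frame": best[3],
                            "score": round(float(score), 2),
                            "frameshift": frameshift,
                        }
                    )
    cols = [
        "family",
        "contig",
        "contig_length",
        "start",
        "end",
        "strand",
        "frame",
        "score",
        "frameshift",
    ]
    if not rows:
        return pd.DataFrame(columns=cols)
    return (
        pd.DataFrame(rows, columns=cols)
        .sort_values(["contig", "family", "start"])
        .reset_index(drop=True)
    )


def hit_table(hits: pd.DataFrame, annotations: pd.DataFrame | None = None) -> pd.DataFrame:
    """Shape hits as a report table: Contig / Gene / Contig length / Gene
    position / Strand / Affiliation / Activity / Bin.

    ``annotations`` may supply per-contig ``bin``, ``affiliation`` and
    per-hit ``activity`` columns; missing values are emitted as "-".
    """
    out = pd.DataFrame(
        {
            "Contig": hits["contig"],
            "Gene": hits["family"],
            "Contig length": hits["contig_length"],
            "Gene position": hits["start"].astype(str) + "-" + hits["end"].astype(str),
            "Strand": hits["strand"],
            "Affiliation": "-",
            "Activity": "-",
            "Bin": "-",
        }
    )
    if annotations is not None:
        ann = annotations.set_index("contig")
        for col, label in (("bin", "Bin"), ("affiliation", "Affiliation")):
            if col in ann.columns:
                out[label] = [
                    ann[col].get(c, "-") for c in hits["contig"]
                ]
    return out


def write_hits(hits: pd.DataFrame, path: str | Path) -> None:
    hits.to_csv(path, sep="\t", index=False)
    if hits.empty:
        warnings.warn("no gene hits written", stacklevel=2)
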