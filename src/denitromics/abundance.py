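"""Read mapping, per-contig coverage and bin abundance estimation.

The mapper is a deliberately simple, deterministic k-mer-seeded ungapped
matcher: each read is anchored by exact k-mer seeds on either strand and
verified by counting matching bases over the full read span; the single
best placement above an identity threshold wins (ties break to the
lexicographically smallest contig id, then smallest position, then the plus
strand).  Coverage is assigned bases per contig position, and population
abundance is the assigned-base fraction of each bin, which makes abundance
estimates additive under contig splitting.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from ._seq import encode, read_fastq, revcomp_codes

ASSIGNMENT_COLUMNS = ["read_id", "contig_id", "position", "strand",
                      "matched_bases", "length"]


class _ContigIndex:
    """Sorted k-mer index over the concatenation of all contigs."""

    def __init__(self, contigs: dict[str, str], k: int):
        self.k = k
        self.ids = sorted(contigs)
        gap = np.full(k, 255, dtype=np.uint8)  # spacer blocks cross-contig kmers
        parts, offsets, lengths = [], [], []
        pos = 0
        for cid in self.ids:
            codes = encode(contigs[cid])
            offsets.append(pos)
            lengths.append(codes.size)
            parts.append(codes)
            parts.append(gap)
            pos += codes.size + k
        self.genome = np.concatenate(parts) if parts else np.empty(0, np.uint8)
        self.offsets = np.array(offsets, dtype=np.int64)
        self.lengths = np.array(lengths, dtype=np.int64)
        n = self.genome.size
        if n >= k:
            valid = self.genome <= 3
            codes64 = self.genome.astype(np.int64)
            kcodes = np.zeros(n - k + 1, dtype=np.int64)
            ok = np.ones(n - k + 1, dtype=bool)
            for j in range(k):
                kcodes = (kcodes << 2) | codes64[j : j + n - k + 1]
                ok &= valid[j : j + n - k + 1]
            starts = np.flatnonzero(ok)
            order = np.argsort(kcodes[starts], kind="stable")
            self.sorted_codes = kcodes[starts][order]
            self.sorted_starts = starts[order]
        else:
            self.sorted_codes = np.empty(0, dtype=np.int64)
            self.sorted_starts = np.empty(0, dtype=np.int64)

    def lookup(self, kcode: int) -> np.ndarray:
        lo = np.searchsorted(self.sorted_codes, kcode, side="left")
        hi = np.searchsorted(self.sorted_codes, kcode, side="right")
        return self.sorted_starts[lo:hi]

    def contig_of(self, gpos: int) -> int:
        """Index into self.ids of the contig containing global position gpos."""
        i = int(np.searchsorted(self.offsets, gpos, side="right")) - 1
        return i


def _read_kmer_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    n = codes.size
    kcodes = np.zeros(n - k + 1, dtype=np.int64)
    ok = np.ones(n - k + 1, dtype=bool)
    valid = codes <= 3
    c64 = codes.astype(np.int64)
    for j in range(k):
        kcodes = (kcodes << 2) | c64[j : j + n - k + 1]
        ok &= valid[j : j + n - k + 1]
    return kcodes, ok


def assign_reads(
    reads: Iterable[tuple[str, str]] | pd.DataFrame | str | Path,
    contigs: dict[str, str],
    k: int = 21,
    min_identity: float = 0.9,
    n_seeds: int = 8,
    max_candidates: int = 64,
) -> pd.DataFrame:
    """Map reads to contigs; one best assignment per read or unassigned.

    ``reads`` may be a FASTQ path, a DataFrame with ``id``/``sequence``
    columns, or an iterable of (id, sequence) pairs.  Returns a DataFrame
    with columns read_id, contig_id (NA if unassigned), position (1-based
    leftmost contig coordinate of the aligned window), strand, matched_bases
    and read length.
    """
    if isinstance(reads, (str, Path)):
        read_iter: Iterable[tuple[str, str]] = read_fastq(reads)
    elif isinstance(reads, pd.DataFrame):
        read_iter = zip(reads["id"], reads["sequence"])
    else:
        read_iter = reads
    if not contigs:
        warnings.warn("empty contig set: all reads unassigned", stacklevel=2)
        rows = [
            dict(read_id=rid, contig_id=pd.NA, position=pd.NA, strand=pd.NA,
                 matched_bases=0, length=len(seq))
            for rid, seq in read_iter
        ]
        return pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)

    index = _ContigIndex(contigs, k)
    genome = index.genome
    glen = genome.size
    rows = []
    for rid, seq in read_iter:
        L = len(seq)
        best = None  # (matched, contig_idx, position, strand_rank)
        if L >= k:
            fwd = encode(seq)
            rev = revcomp_codes(fwd)
            seen: set[tuple[int, int]] = set()
            for strand_rank, codes in ((0, fwd), (1, rev)):
                kcodes, ok = _read_kmer_codes(codes, k)
                n_off = kcodes.size
                for off in np.unique(
                    np.linspace(0, n_off - 1, num=min(n_seeds, n_off)).astype(int)
                ):
                    if not ok[off]:
                        continue
                    for g in index.lookup(int(kcodes[off])):
                        gstart = int(g) - int(off)
                        if gstart < 0 or gstart + L > glen:
                            continue
                        key = (strand_rank, gstart)
                        if key in seen or len(seen) > max_candidates:
                            continue
                        seen.add(key)
                        ci = index.contig_of(gstart)
                        coff = index.offsets[ci]
                        if gstart + L > coff + index.lengths[ci]:
                            continue  # would cross the contig end
                        window = genome[gstart : gstart + L]
                        matched = int(np.count_nonzero(window == codes))
                        if matched / L < min_identity:
                            continue
                        cand = (-matched, index.ids[ci], gstart - coff, strand_rank)
                        if best is None or cand < best:
                            best = cand
        if best is None:
            rows.append(dict(read_id=rid, contig_id=pd.NA, position=pd.NA,
                             strand=pd.NA, matched_bases=0, length=L))
        else:
            rows.append(
                dict(read_id=rid, contig_id=best[1], position=int(best[2]) + 1,
                     strand="+" if best[3] == 0 else "-",
                     matched_bases=-best[0], length=L)
            )
    return pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)


def assign_reads_bruteforce(
    reads: Iterable[tuple[str, str]],
    contigs: dict[str, str],
    min_identity: float = 0.9,
) -> pd.DataFrame:
    """Exhaustive ungapped aligner over all positions and strands.

    Independent oracle for :func:`assign_reads` on tiny inputs; same output
    contract and tie-breaking.
    """
    rows = []
    enc = {cid: encode(s) for cid, s in contigs.items()}
    for rid, seq in reads:
        L = len(seq)
        fwd = encode(seq)
        rev = revcomp_codes(fwd)
        best = None
        for cid in sorted(contigs):
            carr = enc[cid]
            for strand_rank, codes in ((0, fwd), (1, rev)):
                for pos in range(0, carr.size - L + 1):
                    matched = int(np.count_nonzero(carr[pos : pos + L] == codes))
                    if matched / L < min_identity:
                        continue
                    cand = (-matched, cid, pos, strand_rank)
                    if best is None or cand < best:
                        best = cand
        if best is None:
            rows.append(dict(read_id=rid, contig_id=pd.NA, position=pd.NA,
                             strand=pd.NA, matched_bases=0, length=L))
        else:
            rows.append(
                dict(read_id=rid, contig_id=best[1], position=best[2] + 1,
                     strand="+" if best[3] == 0 else "-",
                     matched_bases=-best[0], length=L)
            )
    return pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS)


def contig_coverage(
    assignments: pd.DataFrame, contig_lengths: dict[str, int]
) -> pd.Series:
    """Mean fold coverage per contig: assigned (matched) bases / length."""
    if any(l <= 0 for l in contig_lengths.values()):
        raise ValueError("contig lengths must be positive")
    assigned = assignments.dropna(subset=["contig_id"])
    bases = assigned.groupby("contig_id")["matched_bases"].sum()
    cov = pd.Series(
        {cid: float(bases.get(cid, 0)) / length
         for cid, length in sorted(contig_lengths.items())},
        name="coverage",
    )
    cov.index.name = "contig"
    return cov


def bin_abundance(
    coverage: pd.Series,
    assignment: pd.Series,
    contig_lengths: dict[str, int],
) -> pd.DataFrame:
    """Relative population abundance per bin from coverage and bin size.

    abundance(bin) = sum over member contigs of coverage*length, divided by
    the same sum over all contigs, i.e. the assigned-base fraction.  Returns
    a DataFrame indexed by bin (plus an ``unbinned`` row) with two columns:
    ``abundance`` (denominator includes unbinned contigs) and
    ``abundance_binned_only`` (denominator restricted to binned contigs).
    """
    mass: dict[str, float] = {}
    for cid, length in contig_lengths.items():
        b = assignment.get(cid, "unbinned")
        mass[b] = mass.get(b, 0.0) + float(coverage.get(cid, 0.0)) * length
    total = sum(mass.values())
    if total <= 0:
        raise ValueError("no signal: zero total assigned bases")
    mass.setdefault("unbinned", 0.0)
    binned_total = total - mass["unbinned"]
    rows = {}
    for b in sorted(mass):
        rows[b] = {
            "abundance": mass[b] / total,
            "abundance_binned_only": (
                mass[b] / binned_total if b != "unbinned" and binned_total > 0 else np.nan
            ),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "bin"
    return out
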