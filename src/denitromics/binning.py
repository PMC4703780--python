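"""Tetranucleotide-signature binning of contigs and bin statistics.

Contigs are represented by canonical 4-mer frequency vectors (136 entries
after merging each 4-mer with its reverse complement, so signatures are
strand-agnostic), reduced by PCA, combined with log-coverage and GC, and
clustered agglomeratively.  Bin summary tables report size, contig count,
N50, GC and coverage; a "blob table" gives the per-contig GC vs coverage
coordinates used to visualise bins as blobs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import AgglomerativeClustering
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from ._seq import encode

# --- canonical 4-mer machinery -------------------------------------------

_N_KMERS = 256


def _revcomp_code(code: int) -> int:
    rc = 0
    for _ in range(4):
        rc = (rc << 2) | (3 - (code & 3))
        code >>= 2
    return rc


#: map each of the 256 4-mer codes to a canonical index 0..135
_CANONICAL = np.empty(_N_KMERS, dtype=np.int64)
_canon_codes = sorted({min(c, _revcomp_code(c)) for c in range(_N_KMERS)})
_code_to_idx = {c: i for i, c in enumerate(_canon_codes)}
for _c in range(_N_KMERS):
    _CANONICAL[_c] = _code_to_idx[min(_c, _revcomp_code(_c))]

N_CANONICAL = len(_canon_codes)  # 136


def canonical_kmer_names() -> list[str]:
    """Lexicographically smallest representative of each canonical 4-mer."""
    bases = "ACGT"
    out = []
    for code in _canon_codes:
        k = "".join(bases[(code >> (2 * (3 - i))) & 3] for i in range(4))
        out.append(k)
    return out


@dataclass
class TetraSignature:
    contig_id: str
    values: np.ndarray  # length 136, sums to 1
    n_kmers: int


def tetra_signature(
    sequence: str, pseudocount: float = 1.0, contig_id: str = ""
) -> TetraSignature:
    """Canonical tetranucleotide frequency vector of a sequence.

    Overlapping 4-mer windows containing non-ACGT symbols are skipped.
    ``pseudocount`` is added to every canonical count before normalisation
    (stabilises signatures of short contigs); pass 0 for raw frequencies.
    """
    codes = encode(sequence)
    if codes.size < 4:
        raise ValueError("no countable 4-mers: sequence shorter than 4 bases")
    valid = codes <= 3
    win_ok = valid[:-3] & valid[1:-2] & valid[2:-1] & valid[3:]
    kcodes = (
        (codes[:-3].astype(np.int64) << 6)
        | (codes[1:-2].astype(np.int64) << 4)
        | (codes[2:-1].astype(np.int64) << 2)
        | codes[3:].astype(np.int64)
    )
    kcodes = kcodes[win_ok]
    if kcodes.size == 0 and pseudocount <= 0:
        raise ValueError("no countable 4-mers")
    counts = np.bincount(_CANONICAL[kcodes], minlength=N_CANONICAL).astype(float)
    counts += pseudocount
    total = counts.sum()
    if total <= 0:
        raise ValueError("no countable 4-mers")
    return TetraSignature(contig_id=contig_id, values=counts / total,
                          n_kmers=int(kcodes.size))


def gc_content(sequence: str) -> float:
    """GC content in percent, ignoring non-ACGT symbols."""
    codes = encode(sequence)
    acgt = codes <= 3
    n = int(acgt.sum())
    if n == 0:
        raise ValueError("empty sequence after removing ambiguous symbols")
    gc = int(((codes == 1) | (codes == 2)).sum())
    return 100.0 * gc / n


def fragment_for_profile(
    contigs: dict[str, str], fragment_length: int = 500
) -> dict[str, str]:
    """Cut contigs into consecutive non-overlapping fragments.

    The terminal remainder is kept as its own fragment when it is at least
    half the fragment length, otherwise dropped.  Used to build per-bin
    compositional/taxonomic profiles at uniform fragment size.
    """
    if fragment_length <= 0:
        raise ValueError("fragment_length must be positive")
    out: dict[str, str] = {}
    for cid, seq in contigs.items():
        n = len(seq)
        i = 0
        k = 0
        while i + fragment_length <= n:
            out[f"{cid}_f{k:04d}"] = seq[i : i + fragment_length]
            i += fragment_length
            k += 1
        if n - i >= fragment_length / 2 and n - i > 0:
            out[f"{cid}_f{k:04d}"] = seq[i:]
    return out


# --- clustering -----------------------------------------------------------


def cluster_contigs(
    contigs: dict[str, str],
    coverages: dict[str, float],
    min_contig_len: int = 1000,
    n_clusters: int | None = None,
    k_range: tuple[int, int] = (2, 12),
    n_components: int = 10,
    pseudocount: float = 1.0,
    coverage_weight: float = 1.0,
    gc_weight: float = 1.0,
) -> pd.Series:
    """Assign contigs to bins from tetra signatures, coverage and GC.

    Signatures are PCA-reduced, z-scored log10 coverage and GC are appended
    as extra features, and Ward agglomerative clustering is applied.  With
    ``n_clusters=None`` the cluster count is picked by silhouette score over
    ``k_range``.  Contigs shorter than ``min_contig_len`` are labelled
    ``"unbinned"``.  The result is independent of contig input order and
    deterministic; bins are labelled ``bin_01, bin_02, ...`` by decreasing
    total size.
    """
    ids = sorted(contigs)
    passing = [c for c in ids if len(contigs[c]) >= min_contig_len]
    if not passing:
        raise ValueError("no contig passes min_contig_len")
    assignment = pd.Series("unbinned", index=pd.Index(ids, name="contig"), dtype=object)

    X_sig = np.vstack(
        [tetra_signature(contigs[c], pseudocount=pseudocount).values for c in passing]
    )
    n_comp = min(n_components, X_sig.shape[0] - 1, X_sig.shape[1]) if len(passing) > 1 else 0

    kmax_possible = len(passing)
    if n_clusters is not None and n_clusters > kmax_possible:
        warnings.warn(
            "fewer contigs than requested clusters: one bin per contig",
            stacklevel=2,
        )
        labels = np.arange(len(passing))
    elif len(passing) == 1:
        labels = np.zeros(1, dtype=int)
    else:
        X_pca = PCA(n_components=n_comp, svd_solver="full").fit_transform(X_sig)
        scale = X_pca.std() if X_pca.std() > 0 else 1.0
        feats = [X_pca]
        cov = np.array([np.log10(coverages.get(c, 0.0) + 0.1) for c in passing])
        gc = np.array([gc_content(contigs[c]) for c in passing])
        for extra, wgt in ((cov, coverage_weight), (gc, gc_weight)):
            sd = extra.std()
            z = (extra - extra.mean()) / sd if sd > 0 else np.zeros_like(extra)
            feats.append(wgt * scale * z[:, None])
        X = np.hstack(feats)
        if n_clusters is not None:
            labels = AgglomerativeClustering(n_clusters=n_clusters).fit_predict(X)
        else:
            best, labels = -np.inf, np.zeros(len(passing), dtype=int)
            for k in range(k_range[0], min(k_range[1], kmax_possible - 1) + 1):
                lab = AgglomerativeClustering(n_clusters=k).fit_predict(X)
                score = silhouette_score(X, lab)
                if score > best:
                    best, labels = score, lab
    # stable bin labels: order clusters by total bp, ties by smallest member id
    sizes: dict[int, int] = {}
    first: dict[int, str] = {}
    for c, lab in zip(passing, labels):
        sizes[lab] = sizes.get(lab, 0) + len(contigs[c])
        first[lab] = min(first.get(lab, c), c)
    order = sorted(sizes, key=lambda l: (-sizes[l], first[l]))
    rename = {lab: f"bin_{i + 1:02d}" for i, lab in enumerate(order)}
    for c, lab in zip(passing, labels):
        assignment[c] = rename[lab]
    return assignment


# --- statistics -----------------------------------------------------------


def n50(lengths: list[int] | np.ndarray) -> int:
    """N50: largest member length L with sum(lengths >= L) >= half the total."""
    arr = np.sort(np.asarray(lengths, dtype=np.int64))[::-1]
    if arr.size == 0:
        raise ValueError("empty length set")
    half = arr.sum() / 2.0
    csum = np.cumsum(arr)
    return int(arr[np.searchsorted(csum, half, side="left")])


TABLE_COLUMNS = [
    "Bin",
    "Size (kb)",
    "Number of contigs (#)",
    "N50 contig length (kb)",
    "GC content (%)",
    "Mean coverage (x)",
    "Number of CSCGs (#)",
    "Number of tRNAs (#)",
]


def bin_stats(
    assignment: pd.Series,
    contigs: dict[str, str],
    coverages: dict[str, float] | None = None,
    census: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-bin summary table (sizes also given in bp as ``size_bp``).

    Published bin tables of this kind label sizes "(kb)" even where values
    are plausibly Mb; this table computes in bp and converts explicitly.
    ``census`` may supply ``total_marker_hits`` and ``trna_count`` per bin.
    """
    rows = []
    for b in sorted(set(assignment) - {"unbinned"}):
        members = assignment.index[assignment == b]
        lengths = [len(contigs[c]) for c in members]
        size = int(np.sum(lengths))
        seq_concat = "".join(contigs[c] for c in members)
        cov = np.nan
        if coverages is not None:
            cov = float(
                np.sum([coverages.get(c, 0.0) * len(contigs[c]) for c in members]) / size
            )
        cscg = trna = np.nan
        if census is not None and b in census.index:
            cscg = census.loc[b, "total_marker_hits"]
            trna = census.loc[b, "trna_count"]
        rows.append(
            {
                "Bin": b,
                "Size (kb)": round(size / 1000.0, 2),
                "Number of contigs (#)": len(members),
                "N50 contig length (kb)": round(n50(lengths) / 1000.0, 2),
                "GC content (%)": round(gc_content(seq_concat), 1),
                "Mean coverage (x)": round(cov, 2) if np.isfinite(cov) else np.nan,
                "Number of CSCGs (#)": cscg,
                "Number of tRNAs (#)": trna,
                "size_bp": size,
                "n50_bp": n50(lengths),
            }
        )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS + ["size_bp", "n50_bp"])


def blob_table(
    contigs: dict[str, str],
    coverages: dict[str, float],
    assignment: pd.Series | None = None,
) -> pd.DataFrame:
    """One record per contig: GC (%), coverage (x) and bin, for blob plots."""
    rows = []
    for cid in sorted(contigs):
        rows.append(
            {
                "contig": cid,
                "length": len(contigs[cid]),
                "gc": round(gc_content(contigs[cid]), 2),
                "coverage": coverages.get(cid, 0.0),
                "bin": assignment[cid] if assignment is not None else "unbinned",
            }
        )
    return pd.DataFrame(rows, columns=["contig", "length", "gc", "coverage", "bin"])
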