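"""Synthetic community, read-set and chemostat generators.

Everything downstream of sequencing/assembly in this package is exercised on
communities built here: 5-15 populations with distinct GC and tetranucleotide
signatures, log-spread abundances, planted single-copy marker genes, tRNA
genes and functional genes (nirS/nirK/nosZ/pflB) with per-gene expression
levels, plus steady-state chemostat chemistry obeying carbon and nitrogen
conservation and linear batch time series.  All generators are byte-identical
under a fixed seed, and every planted feature is recorded in a truth table
(1-based inclusive coordinates) so that recovery can be measured exactly.

Genome backbones are order-3 Markov chains: each population carries a seeded
per-context bias on the base transition probabilities, which yields the
population-specific 4-mer composition that tetranucleotide binning assumes.
Assembly is out of scope and is replaced by fragmentation of the genomes
into contigs with a tunable N50.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from . import genes as genes_mod
from ._seq import decode, encode, revcomp
from .massbalance import BatchSeries, BiomassModel, ChemostatState

_CODON_TABLE = unambiguous_dna_by_id[11]
_AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in _CODON_TABLE.forward_table.items():
    _AA_TO_CODONS.setdefault(_aa, []).append(_codon)
for _aa in _AA_TO_CODONS:
    _AA_TO_CODONS[_aa].sort()


@dataclass
class PopulationSpec:
    """One population of the synthetic community.

    ``signature_seed`` controls the population-specific 4-mer bias of the
    genome backbone; populations with different seeds get distinguishable
    tetranucleotide signatures.  ``functional_genes`` is a list of
    ``(family, expression_level)`` pairs with family one of nirS, nirK,
    nosZ, pflB.
    """

    id: str
    genome_length: int
    gc: float
    signature_seed: int
    abundance: float
    marker_genes: tuple[str, ...] = ()
    trna_count: int = 0
    functional_genes: tuple[tuple[str, float], ...] = ()
    background_gene_count: int = 0

    def validate(self) -> None:
        if not 0.0 < self.gc < 1.0:
            raise ValueError(f"population {self.id}: gc must be in (0,1)")
        if self.genome_length <= 0:
            raise ValueError(f"population {self.id}: genome_length must be positive")
        if self.abundance <= 0:
            raise ValueError(f"population {self.id}: abundance must be positive")
        for fam, expr in self.functional_genes:
            if expr < 0:
                raise ValueError(f"population {self.id}: negative expression for {fam}")


@dataclass
class CommunitySpec:
    """Community plus sequencing parameters for one synthetic experiment."""

    populations: tuple[PopulationSpec, ...]
    n_dna_reads: int = 0
    n_rna_reads: int = 0
    read_length_mean: float = 150.0
    read_length_sd: float = 20.0
    error_rate: float = 0.01
    homopolymer_indel_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.populations:
            raise ValueError("community must have at least one population")
        for p in self.populations:
            p.validate()
        total = sum(p.abundance for p in self.populations)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {total!r}, not 1 within 1e-9")
        if self.n_dna_reads < 0 or self.n_rna_reads < 0:
            raise ValueError("read counts must be non-negative")
        for rate in (self.error_rate, self.homopolymer_indel_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("error rates must be in [0,1]")


@dataclass
class ChemostatScenario:
    """True state of a steady-state chemostat used to generate observations.

    Concentrations are influent values: nitrite and nitrate in mM, organic
    carbon in mM-C, organic nitrogen in mM-N.  ``true_yield`` is C-mol
    assimilated per C-mol converted.  ``noise_sd`` is the relative standard
    deviation applied to measured quantities.
    """

    influent_nitrite: float = 20.0
    influent_nitrate: float = 1.0
    influent_organic_carbon: float = 28.0
    influent_organic_n: float = 5.3
    dilution_rate: float = 0.36
    temperature: float = 25.0
    true_yield: float = 0.4
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "influent_nitrite",
            "influent_nitrate",
            "influent_organic_carbon",
            "influent_organic_n",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.dilution_rate <= 0:
            raise ValueError("dilution_rate must be positive")
        if not 0.0 <= self.true_yield <= 1.0:
            raise ValueError("true_yield must be in [0,1]")


@dataclass
class Community:
    """Generated community: genomes, gene truth table and abundances."""

    genomes: dict[str, str]
    genes: pd.DataFrame
    abundances: dict[str, float]
    spec: CommunitySpec = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# genome backbone


def _markov_genome(length: int, gc: float, signature_seed: int, rng) -> np.ndarray:
    """Order-3 Markov genome with GC-weighted, signature-biased transitions."""
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bias = np.random.default_rng(signature_seed).normal(0.0, 0.4, size=(64, 4))
    probs = base_p[None, :] * np.exp(bias)
    probs /= probs.sum(axis=1, keepdims=True)
    cum = np.cumsum(probs, axis=1)
    cum[:, 3] = 1.0
    rows = cum.tolist()
    first = np.cumsum(base_p)
    first[3] = 1.0
    first = first.tolist()
    u = rng.random(length).tolist()
    out = np.empty(length, dtype=np.uint8)
    ctx = 0
    for i in range(length):
        row = rows[ctx] if i >= 3 else first
        x = u[i]
        b = 0 if x < row[0] else 1 if x < row[1] else 2 if x < row[2] else 3
        out[i] = b
        ctx = ((ctx << 2) | b) & 63
    return out


def _adjust_gc(
    codes: np.ndarray, target: float, exclude: list[tuple[int, int]], rng, tol: float = 0.008
) -> None:
    """Swap transitions (A<->G, T<->C) outside ``exclude`` until GC is within tol."""
    protected = np.zeros(codes.size, dtype=bool)
    for s, e in exclude:  # 1-based inclusive
        protected[s - 1 : e] = True
    gc_now = float(np.mean((codes == 1) | (codes == 2)))
    delta = target - gc_now
    if abs(delta) <= tol:
        return
    n_flip = int(round(abs(delta) * codes.size))
    if delta > 0:  # raise GC: A->G, T->C
        cand = np.flatnonzero(((codes == 0) | (codes == 3)) & ~protected)
    else:  # lower GC: G->A, C->T
        cand = np.flatnonzero(((codes == 1) | (codes == 2)) & ~protected)
    n_flip = min(n_flip, cand.size)
    pick = rng.choice(cand, size=n_flip, replace=False)
    if delta > 0:
        codes[pick] = np.where(codes[pick] == 0, 2, 1)  # A->G, T->C
    else:
        codes[pick] = np.where(codes[pick] == 2, 0, 3)  # G->A, C->T


def _reverse_translate(peptide: str, rng) -> str:
    return "".join(
        _AA_TO_CODONS[aa][rng.integers(len(_AA_TO_CODONS[aa]))] for aa in peptide
    )


def _diverge(peptide: str, divergence: float, rng) -> str:
    aas = genes_mod.AMINO_ACIDS
    out = list(peptide)
    for i, a in enumerate(out):
        if rng.random() < divergence:
            pool = [x for x in aas if x != a]
            out[i] = pool[rng.integers(len(pool))]
    return "".join(out)


def generate_community(
    spec: CommunitySpec,
    divergence: float = 0.10,
    profiles: dict[str, genes_mod.ProteinProfile] | None = None,
) -> Community:
    """Generate genomes and the planted-gene truth table for a community.

    Functional genes are sampled from the seed-alignment consensus of their
    family with ``divergence`` amino-acid substitutions, reverse-translated
    and written into the genome (reverse complement on the minus strand), so
    that profile detection is non-trivial but achievable.  Marker, tRNA and
    background genes are coordinate annotations on the backbone.  Raises if
    the requested genes cannot be placed without overlap.
    """
    spec.validate()
    if profiles is None:
        profiles = {
            fam: genes_mod.build_profile(genes_mod.load_seed_alignment(fam), family=fam)
            for fam in genes_mod.DEFAULT_FAMILIES
        }
    genomes: dict[str, str] = {}
    rows = []
    for pidx, pop in enumerate(spec.populations):
        rng = np.random.default_rng([spec.seed, pop.signature_seed, pidx])
        codes = _markov_genome(pop.genome_length, pop.gc, pop.signature_seed, rng)

        plan: list[dict] = []
        for fam, expr in pop.functional_genes:
            if fam not in profiles:
                raise KeyError(f"no profile for planted family {fam!r}")
            pep = _diverge(profiles[fam].consensus, divergence, rng)
            dna = _reverse_translate(pep, rng)
            plan.append(
                dict(kind="functional", family=fam, expression=float(expr),
                     length=len(dna), seq=dna)
            )
        for fam in pop.marker_genes:
            plan.append(
                dict(kind="marker", family=fam,
                     expression=float(rng.lognormal(0.0, 1.0)),
                     length=int(rng.integers(600, 1200)), seq=None)
            )
        for _ in range(pop.trna_count):
            plan.append(dict(kind="trna", family="tRNA", expression=0.0,
                             length=76, seq=None))
        for b in range(pop.background_gene_count):
            plan.append(
                dict(kind="background", family="",
                     expression=float(rng.lognormal(0.0, 1.0)),
                     length=int(np.clip(rng.lognormal(6.7, 0.4), 200, 3000)),
                     seq=None)
            )
        total_len = sum(g["length"] for g in plan)
        if total_len >= pop.genome_length:
            raise ValueError(
                f"population {pop.id}: planted genes ({total_len} bp) do not fit "
                f"in genome of {pop.genome_length} bp"
            )
        order = rng.permutation(len(plan))
        plan = [plan[i] for i in order]
        free = pop.genome_length - total_len
        w = rng.random(len(plan) + 1) + 0.1
        gaps = np.floor(free * w / w.sum()).astype(int)
        pos = 1
        exclude = []
        for gi, g in enumerate(plan):
            pos += int(gaps[gi])
            start, end = pos, pos + g["length"] - 1
            strand = "+" if rng.random() < 0.5 else "-"
            if g["seq"] is not None:
                ins = g["seq"] if strand == "+" else revcomp(g["seq"])
                codes[start - 1 : end] = encode(ins)
                exclude.append((start, end))
            rows.append(
                dict(population=pop.id,
                     gene_id=f"{pop.id}_g{gi:04d}",
                     kind=g["kind"], family=g["family"],
                     start=start, end=end, strand=strand,
                     length=g["length"], expression=g["expression"])
            )
            pos = end + 1

        _adjust_gc(codes, pop.gc, exclude, rng)
        genomes[pop.id] = decode(codes)

    genes = pd.DataFrame(
        rows,
        columns=["population", "gene_id", "kind", "family", "start", "end",
                 "strand", "length", "expression"],
    ).sort_values(["population", "start"]).reset_index(drop=True)
    # planted genes never overlap by construction; assert the invariant
    for _, grp in genes.groupby("population"):
        starts, ends = grp["start"].to_numpy(), grp["end"].to_numpy()
        if np.any(starts[1:] <= ends[:-1]):
            raise ValueError("internal error: overlapping planted genes")
    abundances = {p.id: p.abundance for p in spec.populations}
    return Community(genomes=genomes, genes=genes, abundances=abundances, spec=spec)


# ---------------------------------------------------------------------------
# fragmentation (stands in for assembly)


def fragment_genomes(
    genomes: dict[str, str],
    n50_target: int,
    min_len: int = 1000,
    seed: int = 0,
    protect: dict[str, list[tuple[int, int]]] | None = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Cut each genome into non-overlapping contigs with roughly the target N50.

    Fragment lengths are lognormal with the length-weighted median set to
    ``n50_target``.  Cut points falling inside a ``protect`` interval (e.g.
    a planted functional gene) are moved past it.  The union of contigs
    covers each genome exactly once; no contig is shorter than ``min_len``.
    Returns (contigs, contig_map) where contig_map has columns
    ``contig, population, genome_start, length`` (1-based start).
    """
    if n50_target < min_len:
        raise ValueError("n50_target must be >= min_len")
    sigma = 0.5
    mu = np.log(n50_target) - sigma**2
    contigs: dict[str, str] = {}
    rows = []
    for gidx, pop in enumerate(sorted(genomes)):
        genome = genomes[pop]
        n = len(genome)
        rng = np.random.default_rng([seed, gidx])
        if n < min_len:
            warnings.warn(f"genome {pop} shorter than min_len; kept as one contig",
                          stacklevel=2)
            cuts: list[int] = []
        elif n <= n50_target:
            cuts = []  # the whole genome already meets the target
        else:
            cuts = []
            pos = 0
            while True:
                step = max(min_len, int(rng.lognormal(mu, sigma)))
                pos += step
                if pos >= n - min_len:
                    break
                cuts.append(pos)
            if protect and pop in protect:
                fixed = []
                for c in cuts:
                    for s, e in protect[pop]:
                        if s <= c < e:  # cut between c and c+1 splits [s,e]
                            c = e
                            break
                    fixed.append(c)
                cuts = sorted(set(c for c in fixed if 0 < c < n))
            # merge fragments shorter than min_len into their predecessor
            merged = []
            prev = 0
            for c in cuts:
                if c - prev >= min_len and n - c >= min_len:
                    merged.append(c)
                    prev = c
            cuts = merged
        bounds = [0, *cuts, n]
        for i in range(len(bounds) - 1):
            s, e = bounds[i], bounds[i + 1]
            cid = f"{pop}_c{i:04d}"
            contigs[cid] = genome[s:e]
            rows.append(dict(contig=cid, population=pop,
                             genome_start=s + 1, length=e - s))
    contig_map = pd.DataFrame(rows, columns=["contig", "population",
                                             "genome_start", "length"])
    return contigs, contig_map


def project_genes_to_contigs(genes: pd.DataFrame, contig_map: pd.DataFrame) -> pd.DataFrame:
    """Re-express the genome-coordinate gene truth in contig coordinates.

    Genes split across a fragment boundary are dropped (with a warning);
    retained rows gain ``contig`` and contig-local 1-based ``start``/``end``.
    """
    out = []
    dropped = 0
    for pop, grp in genes.groupby("population"):
        cmap = contig_map[contig_map["population"] == pop]
        starts = cmap["genome_start"].to_numpy()
        lengths = cmap["length"].to_numpy()
        ids = cmap["contig"].to_numpy()
        order = np.argsort(starts)
        starts, lengths, ids = starts[order], lengths[order], ids[order]
        for _, g in grp.iterrows():
            i = int(np.searchsorted(starts, g["start"], side="right")) - 1
            if i < 0 or g["end"] > starts[i] + lengths[i] - 1:
                dropped += 1
                continue
            row = g.to_dict()
            row["contig"] = ids[i]
            row["start"] = int(g["start"] - starts[i] + 1)
            row["end"] = int(g["end"] - starts[i] + 1)
            out.append(row)
    if dropped:
        warnings.warn(f"{dropped} genes split by fragmentation were dropped",
                      stacklevel=2)
    cols = list(genes.columns) + ["contig"]
    return pd.DataFrame(out, columns=cols)


def write_truth_gff(genes_on_contigs: pd.DataFrame, path) -> None:
    """Write the gene truth table as GFF3 (marker_family=/trna=/family= tags)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for _, g in genes_on_contigs.iterrows():
            attrs = [f"ID={g['gene_id']}", f"kind={g['kind']}"]
            if g["kind"] == "marker":
                attrs.append(f"marker_family={g['family']}")
            elif g["kind"] == "trna":
                attrs.append("trna=1")
            elif g["kind"] == "functional":
                attrs.append(f"family={g['family']}")
            attrs.append(f"expression={g['expression']:.6g}")
            fh.write(
                "\t".join(
                    [str(g["contig"]), "denitromics", "gene", str(g["start"]),
                     str(g["end"]), ".", g["strand"], ".", ";".join(attrs)]
                ) + "\n"
            )


# ---------------------------------------------------------------------------
# read simulation


def _apply_substitutions(seq: str, error_rate: float, rng) -> str:
    if error_rate <= 0:
        return seq
    hits = np.flatnonzero(rng.random(len(seq)) < error_rate)
    if hits.size == 0:
        return seq
    out = list(seq)
    for i in hits:
        pool = [b for b in "ACGT" if b != out[i]]
        out[i] = pool[rng.integers(3)]
    return "".join(out)


def homopolymer_indels(seq: str, rate: float, rng) -> str:
    """Expand or contract mono-nucleotide runs (length >= 3) with prob ``rate``."""
    if rate <= 0:
        return seq
    out = []
    i = 0
    n = len(seq)
    while i < n:
        j = i
        while j < n and seq[j] == seq[i]:
            j += 1
        run = seq[i:j]
        if j - i >= 3 and rng.random() < rate:
            run = run + seq[i] if rng.random() < 0.5 else run[:-1]
        out.append(run)
        i = j
    return "".join(out)


def simulate_reads(
    genomes: dict[str, str], abundances: dict[str, float], spec: CommunitySpec
) -> pd.DataFrame:
    """Simulate shotgun DNA reads.

    A read is drawn from population p with probability proportional to
    ``abundance_p * genome_length_p``; positions are uniform, strands random,
    substitutions occur at ``error_rate`` per base and homopolymer indels at
    ``homopolymer_indel_rate`` per run when enabled.  Returns a DataFrame
    with columns ``id, sequence, quality, population, start, strand``
    (truth start is the 1-based leftmost genome coordinate).
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, 1])
    pops = sorted(genomes)
    w = np.array([abundances[p] * len(genomes[p]) for p in pops], float)
    w /= w.sum()
    n = spec.n_dna_reads
    pick = rng.choice(len(pops), size=n, p=w)
    lens = np.clip(
        np.rint(rng.normal(spec.read_length_mean, spec.read_length_sd, size=n)),
        30, None,
    ).astype(int)
    rows = []
    for i in range(n):
        pop = pops[pick[i]]
        genome = genomes[pop]
        L = min(lens[i], len(genome))
        start = int(rng.integers(0, len(genome) - L + 1))
        frag = genome[start : start + L]
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = revcomp(frag)
        frag = _apply_substitutions(frag, spec.error_rate, rng)
        frag = homopolymer_indels(frag, spec.homopolymer_indel_rate, rng)
        rows.append(
            dict(id=f"r{i:06d}", sequence=frag, quality="I" * len(frag),
                 population=pop, start=start + 1, strand=strand)
        )
    return pd.DataFrame(rows, columns=["id", "sequence", "quality",
                                       "population", "start", "strand"])


def simulate_transcriptome(
    genomes: dict[str, str], genes: pd.DataFrame, spec: CommunitySpec
) -> pd.DataFrame:
    """Simulate RNA reads from planted genes.

    Reads are drawn from gene g proportional to ``expression_g * length_g``
    (tRNA genes are excluded, emulating rRNA/tRNA depletion); within a gene
    the read position is uniform and the sequenced strand is random.  Returns
    a DataFrame like :func:`simulate_reads` plus a ``gene_id`` truth column.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, 2])
    pool = genes[(genes["kind"] != "trna") & (genes["expression"] > 0)].reset_index(drop=True)
    weights = (pool["expression"] * pool["length"]).to_numpy(float)
    cols = ["id", "sequence", "quality", "population", "start", "strand", "gene_id"]
    if pool.empty or weights.sum() <= 0:
        warnings.warn("zero total expression: empty transcriptome", stacklevel=2)
        return pd.DataFrame(columns=cols)
    weights /= weights.sum()
    n = spec.n_rna_reads
    pick = rng.choice(len(pool), size=n, p=weights)
    lens = np.clip(
        np.rint(rng.normal(spec.read_length_mean, spec.read_length_sd, size=n)),
        30, None,
    ).astype(int)
    rows = []
    for i in range(n):
        g = pool.iloc[pick[i]]
        genome = genomes[g["population"]]
        tx = genome[g["start"] - 1 : g["end"]]
        if g["strand"] == "-":
            tx = revcomp(tx)
        L = min(lens[i], len(tx))
        off = int(rng.integers(0, len(tx) - L + 1))
        frag = tx[off : off + L]
        # genome-coordinate start of the sequenced window
        if g["strand"] == "+":
            gstart = g["start"] + off
        else:
            gstart = g["end"] - off - L + 1
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            frag = revcomp(frag)
        frag = _apply_substitutions(frag, spec.error_rate, rng)
        frag = homopolymer_indels(frag, spec.homopolymer_indel_rate, rng)
        rows.append(
            dict(id=f"t{i:06d}", sequence=frag, quality="I" * len(frag),
                 population=g["population"], start=int(gstart), strand=strand,
                 gene_id=g["gene_id"])
        )
    return pd.DataFrame(rows, columns=cols)


# ---------------------------------------------------------------------------
# chemostat and batch observations


def simulate_chemostat(
    scenario: ChemostatScenario, model: BiomassModel | None = None
) -> tuple[ChemostatState, dict]:
    """Steady-state chemostat observations consistent with C and N conservation.

    With complete substrate conversion, biomass carbon equals
    ``true_yield * influent_organic_carbon``; the matching biomass nitrogen is
    drawn from the organic nitrogen pool and the remainder leaves as
    ammonium.  Measured quantities (effluent ammonium, effluent nitrite,
    protein) get multiplicative Gaussian noise of sd ``noise_sd``; negative
    values are clipped to zero and flagged.  Returns (observed state, truth).
    """
    scenario.validate()
    model = model or BiomassModel()
    rng = np.random.default_rng(scenario.seed)
    converted_c = scenario.influent_organic_carbon
    biomass_c = scenario.true_yield * converted_c  # mM-C
    assim_n = model.n_to_c * biomass_c  # mM-N
    if assim_n > scenario.influent_organic_n + 1e-12:
        raise ValueError(
            "true_yield requires more nitrogen than the influent organic N supplies"
        )
    nh4_out = scenario.influent_organic_n - assim_n
    protein = biomass_c / 1000.0 * model.formula_mass * model.protein_fraction
    truth = dict(converted_c=converted_c, biomass_c=biomass_c, assimilated_n=assim_n,
                 effluent_ammonium=nh4_out, protein=protein,
                 yield_=scenario.true_yield)

    def noisy(x: float) -> float:
        if scenario.noise_sd <= 0:
            return x
        v = x * (1.0 + rng.normal(0.0, scenario.noise_sd))
        if v < 0:
            warnings.warn("negative concentration after noise clipped to 0",
                          stacklevel=3)
            return 0.0
        return v

    state = ChemostatState(
        influent_nitrite=scenario.influent_nitrite,
        influent_nitrate=scenario.influent_nitrate,
        influent_organic_carbon=scenario.influent_organic_carbon,
        influent_organic_n=scenario.influent_organic_n,
        effluent_ammonium=noisy(nh4_out),
        effluent_nitrite=noisy(0.0),
        measured_protein=noisy(protein),
        dilution_rate=scenario.dilution_rate,
        temperature=scenario.temperature,
    )
    return state, truth


def simulate_batch(
    true_rate: float,
    n_samples: int = 7,
    interval_h: float = 1.0 / 3.0,
    noise_sd: float = 0.0,
    start_conc: float = 0.7,
    seed: int = 0,
    analyte: str = "nitrite",
) -> BatchSeries:
    """Linear batch time series: conc = start + rate * t, noisy, clipped at 0."""
    if n_samples < 3:
        raise ValueError("need at least 3 samples")
    rng = np.random.default_rng(seed)
    times = np.arange(n_samples) * interval_h
    conc = start_conc + true_rate * times
    if noise_sd > 0:
        conc = conc * (1.0 + rng.normal(0.0, noise_sd, size=n_samples))
    clipped = conc < 0
    if clipped.any():
        warnings.warn(
            f"{int(clipped.sum())} concentrations clipped to 0", stacklevel=2
        )
        conc = np.where(clipped, 0.0, conc)
    return BatchSeries(times=times, concentrations=conc, analyte=analyte)
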