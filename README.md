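# denitromics

Genome-centric metagenome and metatranscriptome analysis, plus chemostat
mass balances, for denitrifying/fermentative enrichment communities.

## Who this is for

Microbial ecologists running anoxic enrichment cultures (chemostats fed
nitrite/nitrate and mixed organic carbon) who want to go from assembled
contigs and shotgun DNA/RNA reads to *populations and what they do*:
provisional genomes (bins), their abundances, their completeness, the key
denitrification and fermentation genes they carry and transcribe, the
functional guilds they form, and whether the culture's chemistry balances.
Every stage also runs on built-in synthetic communities with full truth
tables, so the whole pipeline is testable without sequencing data.

## What it computes

- **Binning** — each contig is summarised by its canonical tetranucleotide
  signature (136 frequencies after merging each 4-mer with its reverse
  complement), GC and read coverage; PCA + agglomerative clustering groups
  contigs into bins. Bin tables report size, contig count, N50, GC and
  coverage; a blob table gives per-contig GC vs coverage.
- **Abundance** — a deterministic k-mer-seeded ungapped mapper assigns each
  read to its best contig; abundance of bin *b* is the assigned-base
  fraction Σ_{i∈b} cov_i·len_i / Σ_i cov_i·len_i.
- **Completeness census** — distinct hits among the 139 conserved
  single-copy gene (CSCG) families give completeness = distinct/139; total
  hits above 139 flag DNA from more than one population; tRNA counts are
  reported alongside.
- **Gene detection** — contigs are translated in all six frames (table 11)
  and scanned with per-family log-odds profiles for *nirS*, *nirK*, *nosZ*
  (denitrification) and *pflB* (fermentation); hits are mapped back to
  1-based DNA coordinates with strand, and adjacent windows in different
  frames merge so genes broken by homopolymer frameshifts are still found.
- **Transcriptional activity** — per-gene RNA read-count density c/L is
  divided by the mean density of the gene's bin, so mean activity within
  every bin is 1; values above 1 mean above-average transcription.
- **Guilds** — any of nirS/nirK/nosZ ⇒ denitrifier, pflB ⇒ fermentative,
  both ⇒ both; guild abundances are summed per sample.
- **Mass balance** — influent C:N (C-mol/N-mol); assimilated N = organic N
  in − NH₄⁺ out; predicted protein = (N_assim/n:C)·M_X·f_protein with
  biomass CH₁.₈O₀.₅N₀.₂ (n:C = 0.2, M_X = 24.6 g/C-mol, f_protein = 0.47);
  growth yield Y = C-mol assimilated / C-mol converted; medium carbon
  recipe (44/8/48% glucose/acetate/amino acids); OLS batch rates with 95%
  CIs in mM/h and µmol L⁻¹ day⁻¹.

## Worked example

`examples/` contains one short script per capability. Binning a five-
population synthetic community (`python examples/02_bin_contigs.py`)
prints:

```
   Bin  Size (kb)  Number of contigs (#)  N50 contig length (kb)  GC content (%)  Mean coverage (x)
bin_01       70.0                      7                   15.30            48.3               3.10
bin_02       65.0                      7                    9.78            40.5               5.96
bin_03       65.0                      9                    7.62            63.0               0.71
bin_04       60.0                      8                    9.07            33.0              12.03
bin_05       60.0                      6                   16.55            55.5               1.55

adjusted Rand index vs planted truth: 1.000
```

Every contig lands in the bin of its source population (ARI 1.0), and the
estimated abundances (0.493/0.264/0.148/0.063/0.031) recover the planted
log-spread series. The mass-balance example
(`python examples/05_mass_balance.py`) reproduces the culture bookkeeping:

```
10 degC culture: C:N = 1.79 C-mol/N-mol
  organic N in 5.3 mM - NH4+ out 2.5 mM = 2.8 mM-N assimilated
  predicted protein 0.162 g/L (measured: 0.12 g/L)

25 degC culture: C:N = 1.33 C-mol/N-mol
  growth yield from protein 0.14 g/L over 28.0 mM-C: 0.43 C-mol/C-mol
```

A C:N of 1.79 C-mol/N-mol is the nitrite-limited regime; the ~0.4 yield at
25 °C sits just above the 0.3 reported for model denitrifiers on acetate,
consistent with the richer substrate mix.

## Command line

The same stages are available as a thin CLI:

```bash
denitromics all --seed 1 --out-dir run1          # full synthetic pipeline
denitromics simulate --seed 1 --out-dir sim1     # community + reads + truth
denitromics bin --contigs contigs.fasta --coverage coverage.tsv --out-dir out
denitromics genes --contigs contigs.fasta --out gene_hits.tsv
denitromics balance --states states.csv --out balance.csv
denitromics rate --series nitrite.csv
```

`denitromics all` writes `bin_stats.tsv`, `gene_hits.tsv`, `activity.tsv`,
`abundance.tsv`, `guild_abundance.tsv`, `mass_balance.csv` and a
`manifest.json` recording seeds and parameters; reruns with the same seed
are byte-identical.

## Layout

```
src/denitromics/    library (synthetic, binning, abundance, markers, genes,
                    activity, guilds, massbalance, datasets, pipeline, cli)
examples/           one narrative script per capability
tests/              pytest suite (unit, property and acceptance tests)
docs/methods.md     models, parameters, defaults and their rationale
```
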