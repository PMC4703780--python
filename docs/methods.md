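# Methods

This note documents the models and procedures implemented in `denitromics`,
the parameters that matter, the defaults and why they were chosen, and what
the synthetic-data generator does and does not emulate.

## Scope and overall model

The package implements the desk half of a genome-centric analysis of
anoxic enrichment cultures in which denitrification (nitrite/nitrate
respiration via *nirS*/*nirK*/*nosZ*) and fermentation (via pyruvate
formate lyase, *pflB*) compete and cross-feed. Starting from contigs and
shotgun DNA/RNA reads, it reconstructs populations (bins), their
abundances, completeness, functional-gene complement, transcriptional
activity and guild structure, and closes the carbon/nitrogen books of the
chemostat cultures. Assembly, annotation pipelines, 16S reconstruction and
phylogenetics are out of scope: contigs and gene annotations are consumed,
not produced (the synthetic generator supplies both, with truth tables).

## Synthetic communities

The generator defines the conditions under which every downstream claim is
tested, so its structure matters more than its realism in detail.

**Genome backbones** are order-3 Markov chains over A/C/G/T. The
stationary base probabilities encode the requested GC; each population
additionally carries a seeded Gaussian perturbation (sd 0.4 in log space)
of all 64×4 context-transition probabilities. This produces the
population-specific tetranucleotide composition that signature-based
binning assumes — the same premise as tetranucleotide binners, generated
rather than learned. After gene planting, GC is corrected to the target by
transition swaps (A↔G, T↔C) at random intergenic positions; genomes land
within ±0.8% (absolute) of the requested GC, inside the ±1% contract.

**Planted genes.** Functional genes are drawn from the bundled seed
alignment consensus of their family with 10% random amino-acid
substitutions (default `divergence=0.1`), reverse-translated with uniform
codon choice and written into the genome (reverse-complemented on the
minus strand), so detection is non-trivial but achievable. Marker (CSCG),
tRNA and background genes are coordinate annotations on the backbone:
census and activity are annotation-driven, so their sequence content is
irrelevant. All coordinates are 1-based inclusive; genes never overlap by
construction and the generator raises if they cannot be placed.

**Fragmentation replaces assembly.** Fragment lengths are lognormal
(σ = 0.5) with the length-weighted median set to the target N50; realized
N50 is within a factor ~2 of the target. Cut points can be moved off
protected intervals (planted functional genes) so detection tests can
assert exact coordinates. A genome shorter than the target N50 stays
whole. The union of contigs tiles each genome exactly once.

**Reads.** DNA reads are drawn from population *p* with probability
∝ abundance_p × genome length_p, uniform positions, random strand, normal
lengths (default 150 ± 20 bp), i.i.d. substitutions (default 1%/base) and
optional homopolymer-run indels (off by default; when enabled, runs ≥ 3 bp
gain or lose one base with the configured per-run probability, emulating
ion-semiconductor chemistry). RNA reads are drawn from gene *g*
∝ expression_g × length_g, excluding tRNAs (emulating rRNA/tRNA
depletion). Qualities are constant Sanger-offset placeholders; no
base-caller error profile, paired ends or chimeras are modelled. Passing
tests therefore show the algorithms are correct under these error
processes, not that they are robust to every artefact of real platforms.

**Chemostat and batch observations.** Steady state with complete substrate
conversion: biomass C = yield × influent organic C; biomass N = 0.2 ×
biomass C; effluent ammonium = organic N in − biomass N; protein follows
the biomass model below. Measured quantities get multiplicative Gaussian
noise (`noise_sd`, default 0 — the source study reports no quantitative
noise model for its chemistry, so the level is config-exposed rather than
asserted); negatives are clipped to zero with a warning. Batch series are
strictly linear in time before noise (no Monod or ODE dynamics; the
incubations being emulated sample 7 points at 20-minute intervals over
which linearity is a good approximation).

## Binning

Signatures are canonical 4-mer frequency vectors: 256 4-mers collapse to
136 classes after merging each with its reverse complement, making
signatures strand-invariant (asserted by property test). Windows
containing non-ACGT symbols are skipped; a pseudocount (default 1) on the
counts keeps short-contig signatures finite; frequencies sum to 1.

Clustering: signatures → PCA (default 10 components, full SVD for
determinism), then z-scored log₁₀(coverage + 0.1) and GC appended as two
extra features scaled to the PCA coordinate spread (weights
config-exposed, default 1), then Ward agglomerative clustering. The
cluster count is fixed (`n_clusters`) or auto-selected by silhouette score
over k = 2..12. Contigs shorter than `min_contig_len` (default 1000 bp —
shorter contigs destabilise 4-mer signatures) are left unbinned. Contigs
are processed in sorted id order internally, so the partition is
independent of input order; bin labels are assigned by decreasing total
size with lexicographic tie-break. On well-separated synthetic communities
(GC gaps of a few points plus ≥3-fold coverage ratios) recovery is
ARI ≥ 0.95 against planted truth; no attempt is made to reproduce the bin
boundaries of any particular published binner.

N50 is the largest member length L such that contigs ≥ L hold at least
half the bin size; ties in the cumulative sum resolve to the larger
length. Bin tables compute sizes in bp and convert to kb explicitly
(published tables of this kind sometimes label Mb-scale values "(kb)").

## Read mapping and abundance

The mapper is a k-mer-seeded, ungapped, identity-thresholded matcher
(defaults k = 21, min_identity = 0.9, up to 8 evenly spaced seeds per
strand): seeds anchor candidate placements, each candidate is verified by
counting matching bases over the full read span, and the single best
placement wins with deterministic tie-breaking (most matched bases, then
smallest contig id, then smallest position, then plus strand). Indels in
reads are not aligned around — indel-containing reads either map with
reduced identity or go unassigned, which is acceptable because the
quantity of interest is coverage, not alignments. On tiny inputs the
mapper is tested for exact agreement with an exhaustive
all-positions/both-strands oracle; on synthetic reads at 1% error, ≥ 95%
map back to their source.

Coverage is assigned (matched) bases divided by contig length. Bin
abundance is the assigned-base fraction Σ cov·len over the bin divided by
the total — additive under contig splitting (tested). Because reads are
drawn ∝ abundance × genome length, this estimator recovers the DNA
fraction of each population; with equal genome lengths that equals the
planted abundance (max error ≤ 0.02 at 100k reads in the recovery test).
Both normalizations are emitted: `abundance` (denominator includes
unassigned-to-bin mass) and `abundance_binned_only`, since published
abundance figures do not always state which denominator is used.

## Marker census

Detection is annotation-driven (`marker_family=` / `trna=` GFF3
attributes): re-implementing 139 protein profile searches is out of
proportion when annotations are consumed anyway. The default catalogue is
139 placeholder family ids; the canonical published 139-family set can be
substituted as plain data. Completeness = distinct families / catalogue
size; total hits > catalogue size set the duplication flag (DNA from more
than one population). Counting is monotone under adding contigs and
additive under merging bins with disjoint markers (both tested).

## Gene detection

Full profile HMMs are replaced by ungapped position-specific scoring
matrices: per column, score(a) = log₂(((count_a + pc) / (n + 20·pc)) /
background_a) with pseudocount 0.1 and uniform background; columns with
more than 50% gaps are dropped; stops and ambiguous residues score a flat
−4 bits. This is transparent, deterministic, and sufficient at the
separation the families provide: planted genes at 10% amino-acid
divergence score ≈ +400 bits while the best random window in a 30 kb
contig scores ≈ −150.

Thresholds are calibrated per family on decoys: the maximum score of 1000
random background windows plus 25% of the gap up to the consensus score.
With the bundled profiles this lands near −10 bits — far above any decoy
maximum observed and far below real hits; 100 seeded random contigs
produce zero false positives in the test suite. The calibration seed is
fixed, so thresholds are deterministic; they are stored on the profile and
overridable (`min_score`).

Scanning evaluates all six frames (frames 1–3 forward at offsets 0/1/2,
frames 4–6 on the reverse complement), collects non-overlapping candidate
windows per frame above half the threshold, and merges same-strand
windows of one family whose spans lie within 30 bp. A merged cluster
spanning multiple frames is one hit flagged `frameshift=true`, scored as
the sum of the per-frame windows — for a gene broken by a single indel the
two windows match its prefix and suffix in different frames, so their
scores are complementary; ≥ 80% of synthetically frameshifted genes are
recovered this way (tested at 15/15 and 12/15 thresholds). Peptide window
coordinates are mapped back to 1-based inclusive DNA coordinates with
strand; extracting the span, reverse-complementing on minus and
translating reproduces the scored peptide exactly (round-trip test). All
non-overlapping clusters above threshold are reported (a contig can carry
two gene copies); overlapping same-family windows always merge to one hit.

The bundled seed alignments are **synthetic**: 8 members per family at 10%
divergence from a seeded random consensus (filenames `*.synthetic.afa`).
They give each family a distinct, detectable profile and make generator
and detector mutually consistent, but they are not curated biological
alignments — substitute real seed alignments via `build_profile` for real
data. Score magnitudes on real families will differ; the calibration
procedure, not the numbers, is the transferable part.

## Transcriptional activity

A read counts toward the gene containing its alignment midpoint
(boundary bases inclusive; overlapping genes resolve to the smaller gene
id with a warning). Density is count/length (an RPK-style measure; counts,
not base coverage, because the normalization contract is defined on reads
mapped per gene). Activity is density divided by the arithmetic mean
density over **all** annotated genes of the bin, including zero-count
genes — the simplest reading of "average transcriptional activity of the
bin"; `expressed_only=True` offers the mean-over-detected alternative,
since heavy-tailed published activity values (up to ~31) cannot
disambiguate the two conventions. By construction the defined activities
of every bin average to exactly 1 (asserted to 1e-9); bins with no mapped
reads have undefined (missing) activities, matching the "-" entries of
published activity tables. Activities are invariant to scaling all counts
in a bin and to bin relabeling.

## Guilds

Presence of ≥ 1 hit above threshold for any of nirS/nirK/nosZ marks
denitrification; pflB marks fermentation; both kinds give "both", neither
gives "unclassified". Presence, not transcription, is the default
criterion (activity is reported separately); `require_transcription`
restricts presence to transcribed hits. pflB is the only unambiguous
fermentation marker assessed — acetate-production genes are bidirectional
— so "denitrifier" bins may still ferment by other pathways; the
classifier emits this caveat as a warning. Informational sublabels
(`nitrite_reducer`, `n2o_reducer`, `complete`) distinguish partial from
complete denitrifiers without affecting the guild rule. Aggregation sums
bin abundances by label per sample and conserves total mass, carrying
`unbinned` through unchanged.

## Mass balance

All concentrations are mM; mM-C and mM-N count atoms. The biomass model
is CH₁.₈O₀.₅N₀.₂: n:C = 0.2 mol N per mol biomass C and 24.6 g per C-mol.
A biomass "C:N ratio of 0.2" quoted for such cultures is interpreted as
N:C = 0.2 — the literal reading (0.2 C per N) would be impossibly
nitrogen-rich and cannot reproduce observed protein levels. The protein
fraction of dry biomass defaults to 0.47, inside the standard 45–55%
range; within that range it is pinned by requiring the two observational
anchors to hold simultaneously — 2.8 mM assimilated N predicting ≈ 0.15
g/L protein, and 0.14 g/L protein over 28 mM-C giving a yield of ≈ 0.4 —
which a value of 0.45 narrowly misses on the yield side (0.452). All three
constants are config-exposed because the conversion constants used in any
particular study are rarely stated.

Formulas: C:N = organic C / (nitrite + nitrate), dimensionless in
C-mol/N-mol and invariant to scaling all concentrations. Assimilated N =
organic N in − NH₄⁺ out; a negative balance is returned as-is with a DNRA
warning (dissimilatory nitrate reduction to ammonium elevates effluent
ammonium). Predicted protein = (N_assim/1000 / 0.2) × 24.6 × 0.47 g/L,
linear in N_assim. Yield = (protein / 0.47 / 24.6 × 1000) / converted C,
rejected above 1. Converted carbon defaults to the full influent carbon
(complete consumption holds for the nitrite-limited 25 °C regime; partial
conversion can be passed explicitly — note that for cultures where the
converted fraction is unknown the yield basis is correspondingly
uncertain). The 0.3 C-mol/C-mol literature yield of model denitrifiers on
acetate ships as a named comparison constant. Batch rates are ordinary
least-squares slopes with t-based 95% CIs (n−2 df); 1 mM/h = 24 000
µmol L⁻¹ day⁻¹. Under 5% multiplicative noise the CI covers the planted
rate in ≈ 95% of simulations (tested over 200 seeds with an 88–99.5%
acceptance band, since multiplicative noise is mildly heteroscedastic).

## Pipeline, determinism and problem sizes

`run_all` chains simulate → map → bin → census → detect → activity →
guilds → mass balance from one flat config (YAML-loadable, CLI flags
override), logs per-stage record counts, aborts naming the failing stage,
and writes a manifest with seeds, parameters and units (bp, 1-based
inclusive coordinates, mM, g/L). Reruns with the same config and seed are
byte-identical (tested via file comparison). `--skip-rna` leaves activity
columns missing and everything else unchanged.

Default problem sizes are desk-scale by design: demo communities use 3–10
populations with 30–220 kb genomes and 10⁴–10⁵ reads, which exercise every
code path while keeping the full suite around a minute of compute for unit
and property tests plus a few minutes for the recovery studies. Real
communities (Mb genomes, 10⁶⁺ reads) change runtimes, not semantics; the
mapper and scanner are vectorised but single-threaded.

## Known limitations

- The mapper handles substitutions only; indel-rich reads are undercounted
  (conservative for coverage, harmless for the synthetic error model).
- The PSSM scanner has no gap states; a gene with two or more indels in
  different places may fall below threshold.
- The activity midpoint rule ignores reads straddling gene boundaries
  beyond their midpoint and does not model multi-mapping RNA reads.
- Guild classification is presence-based on four families; it cannot see
  fermentation pathways other than pyruvate/formate lyase, nor DNRA.
- The chemostat model is steady-state bookkeeping, not kinetics: no Monod
  terms, no dynamics, no electron balance.
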