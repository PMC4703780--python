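"""End-to-end pipeline: simulate -> bin -> abundance -> census -> genes ->
activity -> guilds -> mass balance, with a single config, seeded
reproducibility and a run manifest.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, abundance, activity, binning, genes, guilds, markers
from . import massbalance as mb
from . import synthetic
from ._seq import write_fasta, write_fastq

log = logging.getLogger("denitromics")

FLOAT_FORMAT = "%.6g"


@dataclass
class RunConfig:
    """Flat configuration for a full pipeline run.

    All module parameters in one place; the CLI exposes the same keys as a
    YAML file with flag overrides.  Units: lengths bp, coordinates 1-based
    inclusive, concentrations mM, protein g/L.
    """

    seed: int = 0
    out_dir: str = "denitromics_run"
    # synthetic community
    n_populations: int = 5
    genome_length: int = 220_000
    n_dna_reads: int = 30_000
    n_rna_reads: int = 15_000
    read_length_mean: float = 150.0
    read_length_sd: float = 20.0
    error_rate: float = 0.01
    homopolymer_indel_rate: float = 0.0
    # fragmentation
    n50_target: int = 15_000
    min_fragment_len: int = 1_000
    # binning
    min_contig_len: int = 1_000
    n_clusters: int | None = None
    fragment_length: int = 500
    # mapping
    k: int = 21
    min_identity: float = 0.9
    # gene detection
    families: tuple[str, ...] = genes.DEFAULT_FAMILIES
    min_score: float | None = None
    # activity
    expressed_only: bool = False
    # guilds
    require_transcription: bool = False
    # chemostat scenario
    influent_nitrite: float = 20.0
    influent_nitrate: float = 1.0
    influent_organic_carbon: float = 28.0
    influent_organic_n: float = 5.3
    dilution_rate: float = 0.36
    temperature: float = 25.0
    true_yield: float = 0.4
    chem_noise_sd: float = 0.0
    # biomass model
    n_to_c: float = 0.2
    formula_mass: float = 24.6
    protein_fraction: float = 0.47
    # stage toggles
    skip_rna: bool = False
    skip_mass_balance: bool = False

    def biomass_model(self) -> mb.BiomassModel:
        return mb.BiomassModel(
            n_to_c=self.n_to_c,
            formula_mass=self.formula_mass,
            protein_fraction=self.protein_fraction,
        )


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "families" in data:
        data["families"] = tuple(data["families"])
    return RunConfig(**data)


#: functional-gene layouts cycled over populations, with expression levels
_GUILD_CYCLE: tuple[tuple[tuple[str, float], ...], ...] = (
    (("nirS", 2.0), ("nosZ", 1.0)),       # denitrifier
    (("nosZ", 1.5), ("pflB", 0.8)),       # both
    (("nirK", 1.2),),                     # denitrifier
    (("pflB", 2.5),),                     # fermentative
    (),                                   # unclassified
)


def default_community_spec(
    seed: int = 0,
    n_populations: int = 5,
    genome_length: int = 220_000,
    n_dna_reads: int = 30_000,
    n_rna_reads: int = 15_000,
    read_length_mean: float = 150.0,
    read_length_sd: float = 20.0,
    error_rate: float = 0.01,
    homopolymer_indel_rate: float = 0.0,
) -> synthetic.CommunitySpec:
    """Demo community: well-separated GC, log-spread abundances, mixed guilds.

    Populations get GC values evenly spaced over 33-63% (pairwise gaps at
    least 8 points for up to ~4 populations, still well separated at 10-15),
    abundances proportional to 2^-i, per-population marker-catalogue subsets
    emulating completeness between 100% and ~55%, and functional genes
    cycling through denitrifier / both / denitrifier / fermentative /
    unclassified layouts.
    """
    if not 2 <= n_populations <= 15:
        raise ValueError("n_populations must be in 2..15")
    gcs = np.linspace(0.33, 0.63, n_populations)
    raw = 2.0 ** -np.arange(n_populations)
    abund = raw / raw.sum()
    cat = markers.DEFAULT_CATALOGUE
    pops = []
    for i in range(n_populations):
        completeness = 1.0 - 0.09 * (i % 6)
        glen = genome_length + 5_000 * (i % 3)
        trna = 15 + 5 * (i % 5)
        # planted genes must fit: cap marker count to ~75% gene density
        budget = 0.75 * glen - trna * 76 - 30 * 950 - 3 * 400
        n_mark = min(int(round(completeness * len(cat))), max(0, int(budget / 1200)))
        pops.append(
            synthetic.PopulationSpec(
                id=f"pop{i:02d}",
                genome_length=glen,
                gc=float(gcs[i]),
                signature_seed=1000 + i,
                abundance=float(abund[i]),
                marker_genes=cat[:n_mark],
                trna_count=trna,
                functional_genes=_GUILD_CYCLE[i % len(_GUILD_CYCLE)],
                background_gene_count=30,
            )
        )
    return synthetic.CommunitySpec(
        populations=tuple(pops),
        n_dna_reads=n_dna_reads,
        n_rna_reads=n_rna_reads,
        read_length_mean=read_length_mean,
        read_length_sd=read_length_sd,
        error_rate=error_rate,
        homopolymer_indel_rate=homopolymer_indel_rate,
        seed=seed,
    )


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT)


def run_all(config: RunConfig) -> dict:
    """Run every stage and write the report bundle to ``config.out_dir``.

    Produces bins.tsv, bin_stats.tsv, blobs.tsv, coverage.tsv,
    abundance.tsv, census.tsv, gene_hits.tsv, activity.tsv, guilds.tsv,
    guild_abundance.tsv, mass_balance.csv and manifest.json, plus the
    simulated FASTA/FASTQ/GFF inputs.  Returns the result tables in a dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}

    def stage(name):
        log.info("stage %s", name)

    try:
        stage("simulate")
        spec = default_community_spec(
            seed=config.seed,
            n_populations=config.n_populations,
            genome_length=config.genome_length,
            n_dna_reads=config.n_dna_reads,
            n_rna_reads=config.n_rna_reads,
            read_length_mean=config.read_length_mean,
            read_length_sd=config.read_length_sd,
            error_rate=config.error_rate,
            homopolymer_indel_rate=config.homopolymer_indel_rate,
        )
        community = synthetic.generate_community(spec)
        protect = {
            pop: [
                (int(r["start"]), int(r["end"]))
                for _, r in community.genes[
                    (community.genes["population"] == pop)
                    & (community.genes["kind"] == "functional")
                ].iterrows()
            ]
            for pop in community.genomes
        }
        contigs, contig_map = synthetic.fragment_genomes(
            community.genomes, config.n50_target, config.min_fragment_len,
            seed=config.seed, protect=protect,
        )
        genes_on_contigs = synthetic.project_genes_to_contigs(
            community.genes, contig_map
        )
        dna_reads = synthetic.simulate_reads(
            community.genomes, community.abundances, spec
        )
        write_fasta(contigs, out / "contigs.fasta")
        write_fastq(
            zip(dna_reads["id"], dna_reads["sequence"], dna_reads["quality"]),
            out / "reads_dna.fastq",
        )
        synthetic.write_truth_gff(genes_on_contigs, out / "genes.gff3")
        _write_tsv(contig_map, out / "truth_contigs.tsv")
        log.info("simulated %d contigs, %d DNA reads", len(contigs), len(dna_reads))
    except Exception as exc:
        raise RuntimeError(f"stage 'simulate' failed: {exc}") from exc

    try:
        stage("abundance")
        assignments = abundance.assign_reads(
            dna_reads, contigs, k=config.k, min_identity=config.min_identity
        )
        lengths = {c: len(s) for c, s in contigs.items()}
        coverage = abundance.contig_coverage(assignments, lengths)
        coverage.to_frame().to_csv(out / "coverage.tsv", sep="\t",
                                   float_format=FLOAT_FORMAT)
        results["coverage"] = coverage
    except Exception as exc:
        raise RuntimeError(f"stage 'abundance' failed: {exc}") from exc

    try:
        stage("bin")
        assignment = binning.cluster_contigs(
            contigs,
            coverage.to_dict(),
            min_contig_len=config.min_contig_len,
            n_clusters=config.n_clusters,
        )
        assignment.to_frame("bin").to_csv(out / "bins.tsv", sep="\t")
        blob = binning.blob_table(contigs, coverage.to_dict(), assignment)
        _write_tsv(blob, out / "blobs.tsv")
        results["bins"] = assignment
        results["blobs"] = blob
    except Exception as exc:
        raise RuntimeError(f"stage 'bin' failed: {exc}") from exc

    try:
        stage("census")
        ann = markers.read_annotations(out / "genes.gff3")
        census = markers.census(ann, assignment)
        census.to_csv(out / "census.tsv", sep="\t", float_format=FLOAT_FORMAT)
        stats = binning.bin_stats(assignment, contigs, coverage.to_dict(), census)
        _write_tsv(stats, out / "bin_stats.tsv")
        results["census"] = census
        results["bin_stats"] = stats
    except Exception as exc:
        raise RuntimeError(f"stage 'census' failed: {exc}") from exc

    try:
        stage("abundance-table")
        abtable = abundance.bin_abundance(coverage, assignment, lengths)
        abtable.to_csv(out / "abundance.tsv", sep="\t", float_format=FLOAT_FORMAT)
        results["abundance"] = abtable
    except Exception as exc:
        raise RuntimeError(f"stage 'abundance-table' failed: {exc}") from exc

    try:
        stage("genes")
        profiles = genes.default_profiles(config.families)
        hits = genes.scan(profiles, contigs, min_score=config.min_score)
        results["gene_hits"] = hits
    except Exception as exc:
        raise RuntimeError(f"stage 'genes' failed: {exc}") from exc

    act = None
    try:
        stage("activity")
        if config.skip_rna:
            log.info("RNA stage skipped")
        else:
            rna_reads = synthetic.simulate_transcriptome(
                community.genomes, community.genes, spec
            )
            write_fastq(
                zip(rna_reads["id"], rna_reads["sequence"], rna_reads["quality"]),
                out / "reads_rna.fastq",
            )
            rna_assign = abundance.assign_reads(
                rna_reads, contigs, k=config.k, min_identity=config.min_identity
            )
            counts = activity.count_rna(rna_assign, genes_on_contigs)
            gene_bins = genes_on_contigs.set_index("gene_id")["contig"].map(assignment)
            act = activity.normalize_activity(
                counts,
                genes_on_contigs.set_index("gene_id")["length"],
                gene_bins,
                expressed_only=config.expressed_only,
            )
            _write_tsv(act, out / "activity.tsv")
            results["activity"] = act
    except Exception as exc:
        raise RuntimeError(f"stage 'activity' failed: {exc}") from exc

    try:
        stage("report-genes")
        # join activity onto hits where a planted gene overlaps the hit
        hits = results["gene_hits"].copy()
        hits["activity"] = np.nan
        if act is not None and not hits.empty:
            planted = genes_on_contigs[genes_on_contigs["kind"] == "functional"]
            act_by_gene = act.set_index("gene_id")["activity"]
            for i, h in hits.iterrows():
                cand = planted[
                    (planted["contig"] == h["contig"])
                    & (planted["start"] <= h["end"])
                    & (h["start"] <= planted["end"])
                ]
                if len(cand):
                    hits.loc[i, "activity"] = act_by_gene.get(
                        cand.iloc[0]["gene_id"], np.nan
                    )
        hits["bin"] = hits["contig"].map(assignment)
        _write_tsv(hits, out / "gene_hits.tsv")
        results["gene_hits"] = hits
    except Exception as exc:
        raise RuntimeError(f"stage 'report-genes' failed: {exc}") from exc

    try:
        stage("guilds")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            profiles_df = guilds.classify_bins(
                results["gene_hits"],
                bins=sorted(set(assignment) - {"unbinned"}),
                require_transcription=config.require_transcription,
            )
        profiles_df.to_csv(out / "guilds.tsv", sep="\t")
        guild_ab = guilds.aggregate_guilds(profiles_df, abtable["abundance"])
        guild_ab.to_csv(out / "guild_abundance.tsv", sep="\t",
                        float_format=FLOAT_FORMAT)
        results["guilds"] = profiles_df
        results["guild_abundance"] = guild_ab
    except Exception as exc:
        raise RuntimeError(f"stage 'guilds' failed: {exc}") from exc

    if not config.skip_mass_balance:
        try:
            stage("mass-balance")
            scenario = synthetic.ChemostatScenario(
                influent_nitrite=config.influent_nitrite,
                influent_nitrate=config.influent_nitrate,
                influent_organic_carbon=config.influent_organic_carbon,
                influent_organic_n=config.influent_organic_n,
                dilution_rate=config.dilution_rate,
                temperature=config.temperature,
                true_yield=config.true_yield,
                noise_sd=config.chem_noise_sd,
                seed=config.seed,
            )
            state, truth = synthetic.simulate_chemostat(
                scenario, config.biomass_model()
            )
            result = mb.mass_balance(state, config.biomass_model())
            pd.DataFrame([{**asdict(state), **{
                "cn_ratio": result.cn_ratio,
                "assimilated_n": result.assimilated_n,
                "predicted_protein": result.predicted_protein,
                "yield": result.yield_,
            }}]).to_csv(out / "mass_balance.csv", index=False,
                        float_format=FLOAT_FORMAT)
            results["mass_balance"] = result
        except Exception as exc:
            raise RuntimeError(f"stage 'mass-balance' failed: {exc}") from exc

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "parameters": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "units": {
            "lengths": "bp", "coordinates": "1-based inclusive",
            "concentrations": "mM (mM-C / mM-N for atoms)", "protein": "g/L",
            "rates": "mM/h", "dilution_rate": "volume changes/day",
        },
        "counts": {
            "contigs": len(contigs),
            "dna_reads": len(dna_reads),
            "bins": int(results["bins"][results["bins"] != "unbinned"].nunique()),
            "binned_contigs": int((results["bins"] != "unbinned").sum()),
            "gene_hits": int(len(results["gene_hits"])),
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
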