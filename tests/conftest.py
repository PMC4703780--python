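import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def profiles():
    """Decoy-calibrated profiles for the four default gene families."""
    from denitromics import genes

    return genes.default_profiles()


@pytest.fixture(scope="session")
def small_community(profiles):
    """A 3-population community with contigs, reads and truth tables.

    Populations have well-separated GC (33/48/63%), log-spread abundances
    and planted marker/tRNA/functional/background genes; fragmentation
    protects functional genes so planted coordinates survive intact.
    """
    import warnings

    from denitromics import pipeline, synthetic

    spec = pipeline.default_community_spec(
        seed=11, n_populations=3, genome_length=40_000,
        n_dna_reads=6_000, n_rna_reads=5_000,
    )
    community = synthetic.generate_community(spec, profiles=profiles)
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
        community.genomes, n50_target=12_000, min_len=1_000, seed=11,
        protect=protect,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        genes_on_contigs = synthetic.project_genes_to_contigs(
            community.genes, contig_map
        )
    dna_reads = synthetic.simulate_reads(community.genomes, community.abundances, spec)
    rna_reads = synthetic.simulate_transcriptome(community.genomes, community.genes, spec)
    return dict(
        spec=spec,
        community=community,
        contigs=contigs,
        contig_map=contig_map,
        genes_on_contigs=genes_on_contigs,
        dna_reads=dna_reads,
        rna_reads=rna_reads,
    )
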