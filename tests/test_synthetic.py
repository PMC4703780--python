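"""Generator contracts: GC control, determinism, signature structure,
fragmentation conservation, read sampling statistics, chemostat/batch
construction."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist

from denitromics import binning, pipeline, synthetic
from denitromics.massbalance import BiomassModel


def one_pop_spec(gc=0.5, length=100_000, seed=0, **kw):
    pop = synthetic.PopulationSpec(
        id="p0", genome_length=length, gc=gc, signature_seed=1,
        abundance=1.0, **kw,
    )
    return synthetic.CommunitySpec(populations=(pop,), seed=seed)


class TestGenerateCommunity:
    def test_requested_gc_is_hit_within_one_percent(self):
        com = synthetic.generate_community(one_pop_spec(gc=0.5, length=100_000))
        gc = binning.gc_content(com.genomes["p0"])
        assert 49.0 <= gc <= 51.0

    def test_same_seed_is_byte_identical(self):
        a = synthetic.generate_community(one_pop_spec(seed=5))
        b = synthetic.generate_community(one_pop_spec(seed=5))
        assert a.genomes == b.genomes
        pd.testing.assert_frame_equal(a.genes, b.genes)

    def test_different_seed_differs(self):
        a = synthetic.generate_community(one_pop_spec(seed=5))
        b = synthetic.generate_community(one_pop_spec(seed=6))
        assert a.genomes != b.genomes

    def test_signatures_separate_populations(self):
        """Between-population 4-mer distance exceeds within-population
        (between-fragment) distance for GC 35/50/60% populations."""
        pops = tuple(
            synthetic.PopulationSpec(
                id=f"p{i}", genome_length=60_000, gc=gc, signature_seed=50 + i,
                abundance=1 / 3,
            )
            for i, gc in enumerate([0.35, 0.50, 0.60])
        )
        com = synthetic.generate_community(
            synthetic.CommunitySpec(populations=pops, seed=2)
        )
        sigs, labels = [], []
        for pid, genome in com.genomes.items():
            frags = [genome[i : i + 10_000] for i in range(0, 60_000, 10_000)]
            for f in frags:
                sigs.append(binning.tetra_signature(f).values)
                labels.append(pid)
        X = np.vstack(sigs)
        labels = np.array(labels)
        d = pdist(X)
        n = len(labels)
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
        same = np.array([labels[i] == labels[j] for i, j in pairs])
        dist_within = d[same].mean()
        dist_between = d[~same].mean()
        assert dist_between > dist_within

    def test_planted_genes_do_not_overlap_and_fit(self):
        spec = pipeline.default_community_spec(seed=3, n_populations=3,
                                               genome_length=50_000)
        com = synthetic.generate_community(spec)
        for _, grp in com.genes.groupby("population"):
            g = grp.sort_values("start")
            assert (g["start"].to_numpy()[1:] > g["end"].to_numpy()[:-1]).all()
            assert g["end"].max() <= len(com.genomes[g["population"].iloc[0]])

    def test_rejects_abundances_not_summing_to_one(self):
        pops = tuple(
            synthetic.PopulationSpec(
                id=f"p{i}", genome_length=10_000, gc=0.5, signature_seed=i,
                abundance=0.4,
            )
            for i in range(2)
        )
        with pytest.raises(ValueError, match="sum to"):
            synthetic.CommunitySpec(populations=pops).validate()

    def test_rejects_genes_that_do_not_fit(self):
        with pytest.raises(ValueError, match="do not fit"):
            synthetic.generate_community(
                one_pop_spec(length=5_000, background_gene_count=20)
            )


class TestFragmentGenomes:
    def test_single_fragment_when_target_equals_genome(self):
        genomes = {"g": "ACGT" * 2_500}
        contigs, cmap = synthetic.fragment_genomes(genomes, 10_000, 1_000, seed=0)
        assert len(contigs) == 1
        assert len(next(iter(contigs.values()))) == 10_000

    def test_fragmentation_conserves_sequence(self):
        com = synthetic.generate_community(one_pop_spec(length=80_000, seed=9))
        contigs, cmap = synthetic.fragment_genomes(com.genomes, 10_000, 1_000, seed=4)
        ordered = cmap.sort_values("genome_start")
        rebuilt = "".join(contigs[c] for c in ordered["contig"])
        assert rebuilt == com.genomes["p0"]
        assert cmap["length"].sum() == 80_000

    def test_no_contig_below_min_len(self):
        com = synthetic.generate_community(one_pop_spec(length=80_000, seed=9))
        contigs, _ = synthetic.fragment_genomes(com.genomes, 5_000, 2_000, seed=4)
        assert min(len(s) for s in contigs.values()) >= 2_000

    def test_short_genome_becomes_single_contig_with_warning(self):
        with pytest.warns(UserWarning, match="shorter than min_len"):
            contigs, _ = synthetic.fragment_genomes({"tiny": "ACGT" * 50}, 1_000,
                                                    1_000, seed=0)
        assert len(contigs) == 1

    def test_realized_n50_within_factor_two_of_target(self):
        com = synthetic.generate_community(one_pop_spec(length=1_000_000, seed=1))
        target = 20_000
        realized = []
        for seed in range(10):
            contigs, _ = synthetic.fragment_genomes(com.genomes, target, 1_000,
                                                    seed=seed)
            realized.append(binning.n50([len(s) for s in contigs.values()]))
        mean_n50 = np.mean(realized)
        assert target / 2 <= mean_n50 <= target * 2

    def test_protected_intervals_are_never_cut(self):
        com = synthetic.generate_community(one_pop_spec(length=100_000, seed=2))
        protect = {"p0": [(40_000, 41_000), (70_000, 72_000)]}
        _, cmap = synthetic.fragment_genomes(com.genomes, 5_000, 1_000, seed=3,
                                             protect=protect)
        bounds = cmap.sort_values("genome_start")
        cuts = (bounds["genome_start"] - 1).to_numpy()[1:]  # 0-based cut points
        for s, e in protect["p0"]:
            assert not np.any((cuts >= s) & (cuts < e))


class TestSimulateReads:
    def test_read_fractions_follow_abundance(self):
        pops = tuple(
            synthetic.PopulationSpec(id=f"p{i}", genome_length=50_000, gc=0.5,
                                     signature_seed=i, abundance=a)
            for i, a in enumerate([0.9, 0.1])
        )
        spec = synthetic.CommunitySpec(populations=pops, n_dna_reads=10_000,
                                       error_rate=0.0, seed=7)
        com = synthetic.generate_community(spec)
        reads = synthetic.simulate_reads(com.genomes, com.abundances, spec)
        frac = (reads["population"] == "p0").mean()
        sigma = np.sqrt(0.9 * 0.1 / 10_000)
        assert abs(frac - 0.9) <= 3 * sigma + 1e-12

    def test_error_free_reads_are_exact_substrings(self):
        spec = one_pop_spec(length=20_000, seed=3)
        spec = synthetic.CommunitySpec(populations=spec.populations,
                                       n_dna_reads=200, error_rate=0.0, seed=3)
        com = synthetic.generate_community(spec)
        reads = synthetic.simulate_reads(com.genomes, com.abundances, spec)
        from denitromics._seq import revcomp

        genome = com.genomes["p0"]
        for _, r in reads.iterrows():
            seq = r["sequence"] if r["strand"] == "+" else revcomp(r["sequence"])
            assert genome[r["start"] - 1 : r["start"] - 1 + len(seq)] == seq

    def test_seeded_repeat_identical(self):
        spec = pipeline.default_community_spec(seed=5, n_populations=2,
                                               genome_length=30_000,
                                               n_dna_reads=500)
        com = synthetic.generate_community(spec)
        a = synthetic.simulate_reads(com.genomes, com.abundances, spec)
        b = synthetic.simulate_reads(com.genomes, com.abundances, spec)
        pd.testing.assert_frame_equal(a, b)


class TestSimulateTranscriptome:
    def test_expression_ratio_reflected_in_read_counts(self):
        pop = synthetic.PopulationSpec(
            id="p0", genome_length=30_000, gc=0.5, signature_seed=1,
            abundance=1.0,
            functional_genes=(("nirS", 2.0), ("nosZ", 1.0)),
        )
        spec = synthetic.CommunitySpec(populations=(pop,), n_rna_reads=12_000,
                                       error_rate=0.0, seed=13)
        com = synthetic.generate_community(spec)
        rna = synthetic.simulate_transcriptome(com.genomes, com.genes, spec)
        fams = com.genes.set_index("gene_id")["family"]
        counts = rna["gene_id"].map(fams).value_counts()
        # equal lengths (same profile length), expression 2:1
        ratio = counts["nirS"] / counts["nosZ"]
        assert 1.8 <= ratio <= 2.25

    def test_zero_expression_warns_and_returns_empty(self):
        pop = synthetic.PopulationSpec(id="p0", genome_length=10_000, gc=0.5,
                                       signature_seed=1, abundance=1.0)
        spec = synthetic.CommunitySpec(populations=(pop,), n_rna_reads=100, seed=1)
        com = synthetic.generate_community(spec)
        with pytest.warns(UserWarning, match="zero total expression"):
            rna = synthetic.simulate_transcriptome(com.genomes, com.genes, spec)
        assert rna.empty


class TestChemostatAndBatch:
    def test_noiseless_chemostat_conserves_nitrogen(self):
        scen = synthetic.ChemostatScenario(true_yield=0.4, noise_sd=0.0, seed=0)
        model = BiomassModel()
        state, truth = synthetic.simulate_chemostat(scen, model)
        # organic N in = assimilated + ammonium out, exactly
        assert state.influent_organic_n == pytest.approx(
            truth["assimilated_n"] + state.effluent_ammonium, abs=1e-12
        )
        # biomass N consistent with biomass C through the model
        assert truth["assimilated_n"] == pytest.approx(
            model.n_to_c * truth["biomass_c"], abs=1e-12
        )

    def test_seeded_chemostat_repeatable(self):
        scen = synthetic.ChemostatScenario(noise_sd=0.05, seed=21)
        a, _ = synthetic.simulate_chemostat(scen)
        b, _ = synthetic.simulate_chemostat(scen)
        assert a == b

    def test_noiseless_batch_is_exactly_linear_and_clipped(self):
        with pytest.warns(UserWarning, match="clipped"):
            series = synthetic.simulate_batch(
                true_rate=-1.0, n_samples=7, interval_h=1 / 3, noise_sd=0.0,
                start_conc=0.7, seed=0,
            )
        expect = [0.7, 0.7 - 1 / 3, 0.7 - 2 / 3, 0.0, 0.0, 0.0, 0.0]
        assert np.allclose(series.concentrations, expect, atol=1e-12)

    def test_batch_requires_three_samples(self):
        with pytest.raises(ValueError, match="at least 3"):
            synthetic.simulate_batch(true_rate=-1.0, n_samples=2)
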