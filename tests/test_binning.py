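"""Tetranucleotide signatures, GC, fragment profiles, N50 and clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import adjusted_rand_score

from denitromics import binning, pipeline, synthetic
from denitromics._seq import revcomp

dna = st.text(alphabet="ACGT", min_size=4, max_size=300)


class TestTetraSignature:
    def test_homopolymer_has_single_canonical_kmer(self):
        sig = binning.tetra_signature("AAAA", pseudocount=0.0)
        assert sig.n_kmers == 1
        assert np.isclose(sig.values.max(), 1.0)
        assert np.isclose(sig.values.sum(), 1.0)

    def test_acgtacgt_enumeration(self):
        # windows: ACGT, CGTA, GTAC, TACG, ACGT; TACG canonicalizes to CGTA
        sig = binning.tetra_signature("ACGTACGT", pseudocount=0.0)
        names = binning.canonical_kmer_names()
        freq = dict(zip(names, sig.values))
        assert sig.n_kmers == 5
        assert freq["ACGT"] == pytest.approx(2 / 5)
        assert freq["CGTA"] == pytest.approx(2 / 5)
        assert freq["GTAC"] == pytest.approx(1 / 5)

    @given(dna)
    def test_reverse_complement_invariance(self, s):
        a = binning.tetra_signature(s).values
        b = binning.tetra_signature(revcomp(s)).values
        assert np.allclose(a, b)

    def test_ambiguous_windows_skipped(self):
        sig = binning.tetra_signature("AAAANAAAA", pseudocount=0.0)
        assert sig.n_kmers == 2  # only the two clean AAAA windows on each side

    def test_all_ambiguous_errors(self):
        with pytest.raises(ValueError, match="no countable 4-mers"):
            binning.tetra_signature("NNNNNNNN", pseudocount=0.0)

    def test_sums_to_one_with_pseudocount(self):
        sig = binning.tetra_signature("ACGTACGTAC", pseudocount=1.0)
        assert np.isclose(sig.values.sum(), 1.0)
        assert (sig.values > 0).all()


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected",
        [("ATGC", 50.0), ("GGCC", 100.0), ("AATGC", 40.0), ("AANNGC", 50.0)],
    )
    def test_values(self, seq, expected):
        assert binning.gc_content(seq) == pytest.approx(expected)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            binning.gc_content("NNN")


class TestFragmentForProfile:
    def test_remainder_kept_when_at_least_half(self):
        frags = binning.fragment_for_profile({"c": "A" * 1250}, 500)
        assert sorted(len(s) for s in frags.values()) == [250, 500, 500]

    def test_999_gives_500_plus_499(self):
        frags = binning.fragment_for_profile({"c": "A" * 999}, 500)
        assert sorted(len(s) for s in frags.values()) == [499, 500]

    def test_small_remainder_dropped(self):
        frags = binning.fragment_for_profile({"c": "A" * 1100}, 500)
        assert sorted(len(s) for s in frags.values()) == [500, 500]
        assert sum(len(s) for s in frags.values()) <= 1100


class TestN50:
    def test_worked_example(self):
        assert binning.n50([40, 30, 20, 10]) == 30

    def test_single_contig(self):
        assert binning.n50([777]) == 777

    @given(st.lists(st.integers(min_value=1, max_value=1000), min_size=1,
                    max_size=50))
    def test_matches_bruteforce_oracle(self, lengths):
        def oracle(ls):
            ls = sorted(ls, reverse=True)
            half = sum(ls) / 2
            run = 0
            for x in ls:
                run += x
                if run >= half:
                    return x

        assert binning.n50(lengths) == oracle(lengths)


class TestClustering:
    def test_single_genome_single_bin(self):
        com = synthetic.generate_community(
            synthetic.CommunitySpec(
                populations=(synthetic.PopulationSpec(
                    id="p0", genome_length=40_000, gc=0.5, signature_seed=1,
                    abundance=1.0),),
                seed=1,
            )
        )
        contigs, _ = synthetic.fragment_genomes(com.genomes, 8_000, 1_000, seed=1)
        assignment = binning.cluster_contigs(contigs, {}, n_clusters=1)
        assert assignment.nunique() == 1

    def test_three_well_separated_genomes_recovered(self):
        spec = pipeline.default_community_spec(seed=8, n_populations=3,
                                               genome_length=40_000)
        com = synthetic.generate_community(spec)
        contigs, cmap = synthetic.fragment_genomes(com.genomes, 8_000, 1_000, seed=8)
        cov = {
            r["contig"]: {"pop00": 5.0, "pop01": 20.0, "pop02": 80.0}[r["population"]]
            for _, r in cmap.iterrows()
        }
        assignment = binning.cluster_contigs(contigs, cov)
        truth = cmap.set_index("contig")["population"].reindex(assignment.index)
        ari = adjusted_rand_score(truth, assignment)
        assert ari >= 0.95

    def test_input_order_invariance(self):
        spec = pipeline.default_community_spec(seed=8, n_populations=3,
                                               genome_length=30_000)
        com = synthetic.generate_community(spec)
        contigs, _ = synthetic.fragment_genomes(com.genomes, 8_000, 1_000, seed=8)
        cov = {c: 10.0 for c in contigs}
        a = binning.cluster_contigs(contigs, cov, n_clusters=3)
        shuffled = dict(reversed(list(contigs.items())))
        b = binning.cluster_contigs(shuffled, cov, n_clusters=3)
        pd.testing.assert_series_equal(a.sort_index(), b.sort_index())

    def test_partition_property(self):
        spec = pipeline.default_community_spec(seed=4, n_populations=2,
                                               genome_length=30_000)
        com = synthetic.generate_community(spec)
        contigs, _ = synthetic.fragment_genomes(com.genomes, 6_000, 1_000, seed=4)
        assignment = binning.cluster_contigs(contigs, {}, n_clusters=2,
                                             min_contig_len=2_000)
        assert set(assignment.index) == set(contigs)
        binned = assignment[assignment != "unbinned"]
        total = sum(len(s) for s in contigs.values())
        by_bin = sum(len(contigs[c]) for c in binned.index)
        unbinned = sum(len(contigs[c]) for c in assignment.index
                       if assignment[c] == "unbinned")
        assert by_bin + unbinned == total
        # short contigs are unbinned
        for c in assignment.index:
            if len(contigs[c]) < 2_000:
                assert assignment[c] == "unbinned"

    def test_more_clusters_than_contigs_falls_back(self):
        contigs = {"a": "ACGT" * 500, "b": "TTGA" * 500}
        with pytest.warns(UserWarning, match="one bin per contig"):
            assignment = binning.cluster_contigs(contigs, {}, n_clusters=5)
        assert assignment.nunique() == 2


class TestBinStats:
    def test_table_columns_and_values(self):
        contigs = {"a": "ACGT" * 10, "b": "GGCC" * 10, "c": "ATAT" * 5}
        assignment = pd.Series({"a": "bin_01", "b": "bin_01", "c": "bin_02"})
        stats = binning.bin_stats(assignment, contigs, {"a": 2.0, "b": 4.0, "c": 1.0})
        for col in ["Size (kb)", "Number of contigs (#)", "N50 contig length (kb)",
                    "GC content (%)"]:
            assert col in stats.columns
        row = stats.set_index("Bin").loc["bin_01"]
        assert row["size_bp"] == 80
        assert row["n50_bp"] == 40
        assert row["GC content (%)"] == pytest.approx(75.0)
        assert row["Mean coverage (x)"] == pytest.approx(3.0)

    def test_single_contig_n50_is_its_length(self):
        contigs = {"x": "ACGT" * 100}
        assignment = pd.Series({"x": "bin_01"})
        stats = binning.bin_stats(assignment, contigs)
        assert stats["n50_bp"].iloc[0] == 400

    def test_blob_table_one_record_per_contig(self):
        contigs = {"a": "ACGT" * 300, "b": "GGCC" * 300}
        blob = binning.blob_table(contigs, {"a": 3.0}, pd.Series({"a": "bin_01",
                                                                  "b": "unbinned"}))
        assert len(blob) == 2
        assert set(blob["contig"]) == {"a", "b"}
        assert blob.set_index("contig").loc["b", "coverage"] == 0.0
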