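"""Six-frame translation, profile building and PSSM scanning."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from denitromics import genes, synthetic
from denitromics._seq import revcomp, translate

dna = st.text(alphabet="ACGT", min_size=3, max_size=120)


class TestSixFrameTranslate:
    def test_forward_frame_one(self):
        frames = dict(genes.six_frame_translate("ATGAAA"))
        assert frames[1] == "MK"

    def test_reverse_frame_four(self):
        # revcomp("ATGAAA") = "TTTCAT" -> TTT=F, CAT=H
        frames = dict(genes.six_frame_translate("ATGAAA"))
        assert frames[4] == "FH"

    def test_offsets_and_stops(self):
        frames = dict(genes.six_frame_translate("ATGTAAAT"))
        assert frames[1] == "M*"
        assert frames[2] == "CK"  # TGT AAA

    def test_ambiguous_codon_is_x(self):
        frames = dict(genes.six_frame_translate("ATGNNN"))
        assert frames[1] == "MX"

    def test_too_short_errors(self):
        with pytest.raises(ValueError):
            genes.six_frame_translate("AT")

    @given(dna)
    def test_reverse_complement_symmetry(self, s):
        f = dict(genes.six_frame_translate(s))
        g = dict(genes.six_frame_translate(revcomp(s)))
        assert g[1] == f[4] and g[2] == f[5] and g[3] == f[6]


class TestBuildProfile:
    def test_identical_sequences_score_log2_20_per_column(self):
        aln = ["MKV" * 10] * 4
        prof = genes.build_profile(aln, pseudocount=1e-9)
        per_col = prof.max_score / prof.length
        assert per_col == pytest.approx(np.log2(20), abs=1e-6)

    def test_consensus_beats_any_single_substitution(self, profiles):
        prof = profiles["nirS"]
        base = prof.score_peptide(prof.consensus)
        rng = np.random.default_rng(0)
        for _ in range(20):
            i = int(rng.integers(prof.length))
            alt = [a for a in genes.AMINO_ACIDS if a != prof.consensus[i]]
            var = (prof.consensus[:i] + alt[int(rng.integers(len(alt)))]
                   + prof.consensus[i + 1 :])
            assert prof.score_peptide(var) < base

    def test_order_invariance(self):
        aln = ["MKVA", "MRVA", "MKLA"]
        a = genes.build_profile(aln)
        b = genes.build_profile(list(reversed(aln)))
        assert np.allclose(a.matrix, b.matrix)

    def test_mostly_gap_columns_dropped(self):
        aln = ["MK-A", "MR-A", "M--A", "M-VA"]
        prof = genes.build_profile(aln)  # column 3 has 3/4 gaps -> dropped
        assert prof.length == 3

    def test_ragged_alignment_errors(self):
        with pytest.raises(ValueError, match="ragged"):
            genes.build_profile(["MKV", "MK"])

    def test_bundled_alignments_load(self):
        for fam in genes.DEFAULT_FAMILIES:
            aln = genes.load_seed_alignment(fam)
            assert len(aln) >= 2
            lens = {len(s) for s in aln.values()}
            assert len(lens) == 1


class TestScan:
    def _plant(self, prof, seed, strand, contig_len=9_000, pos=3_000,
               divergence=0.10, frameshift=False):
        rng = np.random.default_rng(seed)
        back = synthetic._markov_genome(contig_len, 0.45, seed, rng)
        from denitromics._seq import decode

        back = decode(back)
        pep = synthetic._diverge(prof.consensus, divergence, rng)
        dnaseq = synthetic._reverse_translate(pep, rng)
        if frameshift:
            cut = len(dnaseq) // 2
            dnaseq = dnaseq[:cut] + dnaseq[cut + 1 :]
        ins = dnaseq if strand == "+" else revcomp(dnaseq)
        contig = back[:pos] + ins + back[pos + len(ins) :]
        truth = (pos + 1, pos + len(ins))
        return contig, truth

    def test_planted_minus_strand_gene_found_at_exact_coordinates(self, profiles):
        prof = profiles["pflB"]
        contig, (s, e) = self._plant(prof, seed=5, strand="-")
        hits = genes.scan({"pflB": prof}, {"c": contig})
        assert len(hits) == 1
        h = hits.iloc[0]
        assert (h["start"], h["end"], h["strand"]) == (s, e, "-")
        assert (h["end"] - h["start"] + 1) % 3 == 0

    def test_coordinate_roundtrip_reproduces_scored_peptide(self, profiles):
        for strand in "+-":
            prof = profiles["nosZ"]
            contig, _ = self._plant(prof, seed=8, strand=strand)
            h = genes.scan({"nosZ": prof}, {"c": contig}).iloc[0]
            window = contig[h["start"] - 1 : h["end"]]
            if h["strand"] == "-":
                window = revcomp(window)
            pep = translate(window)
            assert len(pep) == prof.length
            assert prof.score_peptide(pep) == pytest.approx(h["score"], abs=0.01)

    def test_score_invariant_under_contig_reverse_complement(self, profiles):
        prof = profiles["nirK"]
        contig, _ = self._plant(prof, seed=9, strand="+")
        a = genes.scan({"nirK": prof}, {"c": contig}).iloc[0]
        b = genes.scan({"nirK": prof}, {"c": revcomp(contig)}).iloc[0]
        assert a["score"] == pytest.approx(b["score"], abs=0.01)
        assert a["strand"] != b["strand"]
        assert (a["start"], a["end"]) == (
            len(contig) - b["end"] + 1, len(contig) - b["start"] + 1)

    def test_frameshifted_genes_recovered_by_split_frame_merge(self, profiles):
        """Genes broken by a single indel are still detected (merged hit)."""
        prof = profiles["nirS"]
        found = 0
        for seed in range(15):
            strand = "+" if seed % 2 else "-"
            contig, _ = self._plant(prof, seed=100 + seed, strand=strand,
                                    frameshift=True)
            hits = genes.scan({"nirS": prof}, {"c": contig})
            if len(hits) and hits.iloc[0]["frameshift"]:
                found += 1
        assert found >= 12  # >= 80%

    def test_random_contigs_give_no_hits(self, profiles):
        from denitromics._seq import decode

        for seed in range(5):
            rng = np.random.default_rng(seed)
            contig = decode(synthetic._markov_genome(15_000, 0.5, seed + 77, rng))
            hits = genes.scan(profiles, {"c": contig})
            assert hits.empty

    def test_report_table_columns(self, profiles):
        prof = profiles["pflB"]
        contig, _ = self._plant(prof, seed=3, strand="+")
        hits = genes.scan({"pflB": prof}, {"c": contig})
        table = genes.hit_table(hits)
        assert list(table.columns) == [
            "Contig", "Gene", "Contig length", "Gene position", "Strand",
            "Affiliation", "Activity", "Bin",
        ]

    def test_planted_community_recovery(self, profiles, small_community):
        """Every intact planted gene is recovered with its true family,
        strand and coordinates."""
        hits = genes.scan(profiles, small_community["contigs"])
        gic = small_community["genes_on_contigs"]
        planted = gic[gic["kind"] == "functional"]
        hit_keys = set(zip(hits["contig"], hits["family"], hits["start"],
                           hits["end"], hits["strand"]))
        for _, g in planted.iterrows():
            assert (g["contig"], g["family"], g["start"], g["end"],
                    g["strand"]) in hit_keys
        assert len(hits) == len(planted)
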