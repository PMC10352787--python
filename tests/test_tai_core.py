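import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import adaptiveness_oracle, gene_tai_oracle, random_count_table
from gtai.sequence_io import CodonCountTable, TRNAGeneCopyTable, sense_codons
from gtai.tai_core import (
    OTAI_SIJ,
    SijWeights,
    WobbleRuleSet,
    absolute_adaptiveness,
    adaptiveness,
    gene_tai,
    recognition_matrix,
    relative_adaptiveness,
)

RULES = WobbleRuleSet()


class TestRecognizers:
    @pytest.mark.parametrize(
        "codon,expected",
        [
            ("GGC", [("GCC", "WC"), ("ACC", "I:C")]),
            ("GGT", [("ACC", "WC"), ("GCC", "G:U")]),
            ("GGA", [("TCC", "WC"), ("ACC", "I:A")]),
            ("GGG", [("CCC", "WC"), ("TCC", "U:G")]),
            ("ATG", [("CAT", "WC")]),
            ("TGG", [("CCA", "WC")]),
        ],
    )
    def test_rule_table(self, codon, expected):
        assert RULES.recognizers(codon) == expected

    def test_prokaryote_ata_gains_lysidine(self):
        euk = RULES.recognizers("ATA")
        prok = RULES.recognizers("ATA", prokaryote=True)
        assert ("CAT", "L:A") not in euk
        assert prok == euk + [("CAT", "L:A")]

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            RULES.recognizers("TGA")

    def test_every_sense_codon_has_wc_recognizer(self):
        for codon in sense_codons(1):
            classes = [cls for _, cls in RULES.recognizers(codon)]
            assert classes[0] == "WC"


class TestAbsoluteAdaptiveness:
    def test_hand_value_with_gu_wobble(self):
        tgcn = TRNAGeneCopyTable({"ACC": 1, "GCC": 2})
        amap = absolute_adaptiveness(tgcn, SijWeights({"G:U": 0.41}))
        assert amap.W["GGT"] == pytest.approx(1 * 1 + 0.59 * 2)

    def test_unrecognized_codon_gets_zero(self):
        tgcn = TRNAGeneCopyTable({"GCC": 2})
        amap = absolute_adaptiveness(tgcn, SijWeights({}))
        assert amap.W["TTT"] == 0.0

    def test_linear_in_tgcn(self):
        tgcn = TRNAGeneCopyTable({"GCC": 2, "AAT": 3, "CAT": 1})
        a1 = absolute_adaptiveness(tgcn, OTAI_SIJ)
        a2 = absolute_adaptiveness(tgcn.scaled(3), OTAI_SIJ)
        for c in a1.W:
            assert a2.W[c] == pytest.approx(3 * a1.W[c])

    def test_lysidine_uses_dedicated_count(self):
        tgcn = TRNAGeneCopyTable({"CAT": 5}, lysidine_count=2)
        s = SijWeights({"L:A": 0.5})
        amap = absolute_adaptiveness(tgcn, s, prokaryote=True)
        # ATA: no TAT/AAT copies; only lysidine contributes 0.5 * 2
        assert amap.W["ATA"] == pytest.approx(1.0)
        assert amap.W["ATG"] == pytest.approx(5.0)


class TestRelativeAdaptiveness:
    def test_normalization(self):
        from gtai.tai_core import AdaptivenessMap

        amap = relative_adaptiveness(AdaptivenessMap({"A": 2.0, "B": 1.0}))
        assert amap.w == {"A": 1.0, "B": 0.5}

    def test_zero_imputed_by_geometric_mean(self):
        from gtai.tai_core import AdaptivenessMap

        amap = relative_adaptiveness(AdaptivenessMap({"a": 1.0, "b": 0.25, "c": 0.0}))
        assert amap.w["c"] == pytest.approx(math.sqrt(1 * 0.25))
        assert amap.zero_substituted == ["c"]

    def test_all_equal_gives_ones(self):
        from gtai.tai_core import AdaptivenessMap

        amap = relative_adaptiveness(AdaptivenessMap({"a": 3.0, "b": 3.0}))
        assert set(amap.w.values()) == {1.0}

    def test_all_zero_rejected(self):
        from gtai.tai_core import AdaptivenessMap

        with pytest.raises(ValueError):
            relative_adaptiveness(AdaptivenessMap({"a": 0.0}))


class TestGeneTAI:
    def test_unit_weights_give_unit_tai(self):
        counts = CodonCountTable({"GCT": 5, "GGT": 2})
        assert gene_tai(counts, {"GCT": 1.0, "GGT": 1.0}) == pytest.approx(1.0)

    def test_single_codon_gene(self):
        assert gene_tai(CodonCountTable({"GCT": 1}), {"GCT": 0.37}) == pytest.approx(0.37)

    def test_hand_geometric_mean(self):
        counts = CodonCountTable({"GCT": 1, "GGT": 1})
        assert gene_tai(counts, {"GCT": 0.25, "GGT": 1.0}) == pytest.approx(0.5)

    def test_duplication_invariance(self):
        w = {"GCT": 0.3, "GGT": 0.9, "TTT": 0.5}
        g = CodonCountTable({"GCT": 2, "GGT": 1, "TTT": 4})
        gg = CodonCountTable({c: 2 * n for c, n in g.counts.items()})
        assert gene_tai(g, w) == pytest.approx(gene_tai(gg, w))

    def test_exclude_special_flag(self):
        w = {"ATG": 0.1, "GCT": 1.0}
        counts = CodonCountTable({"ATG": 1, "GCT": 1})
        with_atg = gene_tai(counts, w)
        without = gene_tai(counts, w, exclude_special=True)
        assert with_atg == pytest.approx(math.sqrt(0.1))
        assert without == pytest.approx(1.0)

    def test_no_scorable_codons_rejected(self):
        with pytest.raises(ValueError):
            gene_tai(CodonCountTable({"GCT": 1}), {"TTT": 1.0})


@st.composite
def tgcn_tables(draw):
    rng = np.random.default_rng(draw(st.integers(0, 2**31 - 1)))
    anticodons = sorted(
        {"".join(t) for t in itertools.product("ACGT", repeat=3)}
        - {"TTA", "CTA", "TCA"}
    )
    keep = rng.random(len(anticodons)) < 0.5
    entries = {
        a: int(rng.integers(1, 12))
        for a, k in zip(anticodons, keep)
        if k
    }
    if not entries:
        entries = {"GCC": 3}
    return TRNAGeneCopyTable(entries)


class TestInvariants:
    @given(tgcn_tables(), st.integers(2, 7), st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_tai_scale_free_in_tgcn(self, tgcn, k, seed):
        """Multiplying all gene copy numbers leaves w and every tAI unchanged."""
        amap1 = adaptiveness(tgcn, OTAI_SIJ)
        amap2 = adaptiveness(tgcn.scaled(k), OTAI_SIJ)
        for c in amap1.w:
            assert amap2.w[c] == pytest.approx(amap1.w[c], abs=1e-12)
        counts = CodonCountTable(random_count_table(np.random.default_rng(seed)))
        assert gene_tai(counts, amap1) == pytest.approx(gene_tai(counts, amap2))

    def test_equal_wc_pool_gives_unit_w(self):
        # every codon's WC anticodon present with equal copies, no wobble
        # credit: within the WC recognition class all w = 1
        from gtai.tai_core import reverse_complement

        entries = {reverse_complement(c): 4 for c in sense_codons(1)}
        amap = adaptiveness(TRNAGeneCopyTable(entries), SijWeights({
            "G:U": 1.0, "I:C": 1.0, "I:A": 1.0, "U:G": 1.0,
        }))
        assert all(v == pytest.approx(1.0) for v in amap.w.values())
        counts = CodonCountTable({"GCT": 3, "TTT": 2, "ATG": 1})
        assert gene_tai(counts, amap) == pytest.approx(1.0)

    @given(tgcn_tables(), st.booleans())
    @settings(max_examples=25, deadline=None)
    def test_otai_preset_matches_independent_transcription(self, tgcn, prokaryote):
        """W/w under the fixed literature S vector equal an anticodon-to-codon
        oracle transcription to 1e-12."""
        amap = adaptiveness(tgcn, OTAI_SIJ, prokaryote=prokaryote)
        w_oracle = adaptiveness_oracle(
            dict(tgcn.entries), OTAI_SIJ.as_dict(),
            tgcn.lysidine_count, prokaryote,
        )
        assert amap.w == pytest.approx(w_oracle, abs=1e-12)

    def test_gene_tai_matches_sequence_walk_oracle(self, small_genome, small_truth):
        from gtai.sequence_io import count_codons

        amap_w = small_truth.w_true
        for gene in list(small_genome)[:10]:
            ours = gene_tai(count_codons(gene), amap_w)
            assert ours == pytest.approx(
                gene_tai_oracle(gene.seq, amap_w), abs=1e-12
            )


class TestRecognitionMatrix:
    def test_matrix_reproduces_absolute_adaptiveness(self):
        tgcn = TRNAGeneCopyTable({"GCC": 2, "ACC": 1, "CAT": 3, "AAT": 2})
        codons, classes, T = recognition_matrix(tgcn)
        s = OTAI_SIJ
        one_minus = np.array([1 - s[c] for c in classes])
        W_fast = T @ one_minus
        amap = absolute_adaptiveness(tgcn, s)
        for codon, w in zip(codons, W_fast):
            assert w == pytest.approx(amap.W[codon], abs=1e-12)
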