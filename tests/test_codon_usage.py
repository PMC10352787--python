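import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import (
    cai_oracle,
    cai_weights_oracle,
    enc_oracle,
    fcf_oracle,
    random_count_table,
    rscu_oracle,
    scuo_oracle,
)
from gtai.codon_usage import (
    build_family_partition,
    cai,
    cai_weights,
    enc,
    family_fcf,
    gc_content,
    gene_gc_content,
    rscu,
    scuo,
)
from gtai.sequence_io import CodingSequence, CodonCountTable, GenomeCDSSet


def table(counts):
    return CodonCountTable(dict(counts))


def uniform_counts(partition, n=100):
    return table({c: n for f in partition.families for c in f.codons})


def concentrated_counts(partition, n=10_000):
    return table({f.codons[0]: n for f in partition.families})


class TestFamilyPartition:
    def test_standard_code_family_census(self, partition):
        assert (partition.Ns, partition.K2, partition.K3, partition.K4) == (2, 12, 1, 8)
        assert partition.max_enc == 61

    def test_families_disjoint_and_cover_sense_codons(self, partition):
        codons = [c for f in partition.families for c in f.codons]
        assert len(codons) == len(set(codons)) == 61

    def test_sixfold_families_split_by_box(self, partition):
        leu = [f for f in partition.families if f.amino_acid == "L"]
        assert sorted(f.fold for f in leu) == [2, 4]

    def test_unsplit_mode_keeps_sixfold(self):
        unsplit = build_family_partition(1, split_sixfold=False)
        assert max(f.fold for f in unsplit.families) == 6

    def test_unknown_table_id(self):
        with pytest.raises(ValueError):
            build_family_partition(999)


class TestRSCU:
    def test_hand_value_phe(self, partition):
        values = rscu(table({"TTT": 3, "TTC": 1}), partition)
        assert values["TTT"] == pytest.approx(1.5)
        assert values["TTC"] == pytest.approx(0.5)

    def test_uniform_usage_gives_ones(self, partition):
        values = rscu(uniform_counts(partition), partition)
        assert all(v == pytest.approx(1.0) for v in values.values())

    def test_single_codon_extreme_equals_family_size(self, partition):
        values = rscu(table({"GGA": 4}), partition)
        assert values["GGA"] == pytest.approx(4.0)
        assert values["GGC"] == 0.0

    def test_empty_families_omitted(self, partition):
        values = rscu(table({"TTT": 1}), partition)
        assert "GGA" not in values

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_family_sums_equal_family_size(self, partition, seed):
        counts = random_count_table(np.random.default_rng(seed))
        values = rscu(table(counts), partition)
        for fam in partition.families:
            if sum(counts[c] for c in fam.codons) > 0:
                assert sum(values[c] for c in fam.codons) == pytest.approx(
                    fam.fold, abs=1e-12
                )


class TestFamilyFCF:
    @pytest.mark.parametrize(
        "counts,expected",
        [
            ((3, 1), (4 / 6) ** 2 + (2 / 6) ** 2),
            ((0, 0), 0.5),
            ((10**6, 0), pytest.approx(1.0, abs=1e-5)),
        ],
    )
    def test_hand_values(self, counts, expected):
        assert family_fcf(counts) == pytest.approx(expected)

    def test_single_member_family_rejected(self):
        with pytest.raises(ValueError):
            family_fcf([5])


class TestENc:
    def test_uniform_limit_61(self, partition):
        assert enc(uniform_counts(partition, 10_000), partition) == pytest.approx(
            61, abs=0.5
        )

    def test_maximal_bias_limit_23(self, partition):
        assert enc(concentrated_counts(partition), partition) == pytest.approx(
            23, abs=0.1
        )

    def test_monotone_under_concentration(self, partition):
        # moving counts onto one codon per family lowers ENc
        mild = table({c: 10 for f in partition.families for c in f.codons})
        biased = table(
            {c: (30 if i == 0 else 3) for f in partition.families
             for i, c in enumerate(f.codons)}
        )
        assert enc(biased, partition) < enc(mild, partition)

    def test_all_families_empty_rejected(self, partition):
        with pytest.raises(ValueError):
            enc(table({"ATG": 5, "TGG": 1}), partition)

    def test_matches_independent_transcription(self, partition):
        rng = np.random.default_rng(123)
        for _ in range(100):
            counts = random_count_table(rng)
            assert enc(table(counts), partition) == pytest.approx(
                enc_oracle(counts), abs=1e-12
            )


class TestCAI:
    def test_weight_hand_ratio(self, partition):
        w = cai_weights(table({"TTT": 10, "TTC": 5}), partition)
        assert (w["TTT"], w["TTC"]) == (1.0, 0.5)

    def test_zero_count_pseudocount(self, partition):
        w = cai_weights(table({"TTT": 10, "TTC": 0}), partition)
        assert w["TTC"] == pytest.approx(0.05)

    def test_uniform_reference_gives_unit_weights(self, partition):
        w = cai_weights(uniform_counts(partition), partition)
        assert all(v == 1.0 for v in w.values())

    def test_geometric_mean_hand_value(self, partition):
        weights = {"TTT": 1.0, "TTC": 0.25}
        assert cai(table({"TTT": 1, "TTC": 1}), weights) == pytest.approx(0.5)

    def test_max_weight_gene_scores_one(self, partition):
        w = cai_weights(table({"TTT": 10, "TTC": 5}), partition)
        assert cai(table({"TTT": 7}), w) == pytest.approx(1.0)

    def test_invariant_to_duplication(self, partition):
        w = cai_weights(table({"TTT": 10, "TTC": 5, "GGA": 3, "GGC": 1}), partition)
        g = {"TTT": 2, "TTC": 1, "GGA": 4}
        doubled = {c: 2 * n for c, n in g.items()}
        assert cai(table(g), w) == pytest.approx(cai(table(doubled), w))

    def test_unscorable_gene_rejected(self, partition):
        w = cai_weights(table({"TTT": 10, "TTC": 5}), partition)
        with pytest.raises(ValueError):
            cai(table({"ATG": 3}), w)

    def test_matches_independent_transcription(self, partition):
        rng = np.random.default_rng(321)
        for _ in range(100):
            ref = random_count_table(rng)
            gene = random_count_table(rng)
            w = cai_weights(table(ref), partition)
            w_oracle = cai_weights_oracle(ref)
            assert w == pytest.approx(w_oracle, abs=1e-12)
            assert cai(table(gene), w) == pytest.approx(
                cai_oracle(gene, w_oracle), abs=1e-12
            )


class TestSCUO:
    def test_uniform_usage_is_zero(self, partition):
        assert scuo(uniform_counts(partition), partition) == pytest.approx(0.0)

    def test_single_codon_per_family_is_one(self, partition):
        assert scuo(concentrated_counts(partition), partition) == pytest.approx(1.0)

    def test_hand_entropy_value(self, partition):
        h = -(0.75 * math.log2(0.75) + 0.25 * math.log2(0.25))
        assert scuo(table({"TTT": 3, "TTC": 1}), partition) == pytest.approx(1 - h)

    def test_matches_independent_transcription(self, partition):
        rng = np.random.default_rng(99)
        for _ in range(100):
            counts = random_count_table(rng)
            assert scuo(table(counts), partition) == pytest.approx(
                scuo_oracle(counts), abs=1e-12
            )

    def test_bounds(self, partition):
        rng = np.random.default_rng(5)
        for _ in range(20):
            v = scuo(table(random_count_table(rng)), partition)
            assert 0.0 <= v <= 1.0


class TestGCContent:
    @pytest.mark.parametrize("seq,expected", [("ATGC", 50.0), ("GGCC", 100.0)])
    def test_single_sequences(self, seq, expected):
        assert gene_gc_content(seq) == pytest.approx(expected)

    def test_mean_of_per_gene_values(self):
        genes = GenomeCDSSet(
            [CodingSequence("a", "ATGC" * 3), CodingSequence("b", "GGCCGC" * 2)]
        )
        assert gc_content(genes) == pytest.approx(75.0)

    def test_pooled_mode_weights_by_length(self):
        genes = GenomeCDSSet(
            [CodingSequence("a", "AT" * 3), CodingSequence("b", "GCG")]
        )
        assert gc_content(genes, pooled=True) == pytest.approx(100 * 3 / 9)
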