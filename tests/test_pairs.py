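"""ChimeraARS (substring index vs naive oracle) and codon pair score."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codonuse.core import CodingSequence
from codonuse.genetics import standard_code
from codonuse.pairs import (
    CodonPairTable,
    PatternIndexError,
    SubstringReference,
    build_codon_pair_table,
    chimera_ars,
    cps_gene,
    cps_gene_detail,
    cps_pair,
    naive_match_lengths,
)

CODE = standard_code()


class TestChimeraArs:
    def test_worked_example(self):
        ref = SubstringReference([("r", "ATGGCC")], alphabet="nucleotide")
        assert ref.match_lengths("GGCCAA") == [4, 3, 2, 1, 1, 1]
        score = chimera_ars(CodingSequence("t", "GGCCAA"), ref)
        assert score == pytest.approx(2.0)

    def test_self_identity_without_exclusion(self):
        seq = "ATGGCTGCC"
        ref = SubstringReference([("t", seq)])
        score = chimera_ars(CodingSequence("other", seq), ref)
        assert score == pytest.approx((len(seq) + 1) / 2)

    def test_self_exclusion_by_id(self):
        ref = SubstringReference([("t", "ATGATG"), ("u", "CCCCCC")])
        score = chimera_ars(CodingSequence("t", "ATGATG"), ref, exclude_self=True)
        assert score == 0.0

    def test_disjoint_alphabet_scores_zero(self):
        ref = SubstringReference([("r", "CCCC")])
        assert chimera_ars(CodingSequence("t", "AAAA"), ref) == 0.0

    def test_codon_alphabet_counts_triplets(self):
        ref = SubstringReference([("r", "ATGGCTGCC")], alphabet="codon")
        lengths = ref.match_lengths("GCTGCCATG")
        assert lengths == [2, 1, 1]

    def test_empty_reference_after_exclusion_raises(self):
        ref = SubstringReference([("t", "ATG")])
        with pytest.raises(PatternIndexError):
            chimera_ars(CodingSequence("t", "ATG"), ref, exclude_self=True)

    @given(
        st.lists(st.text(alphabet="ACGT", min_size=1, max_size=30), min_size=1, max_size=4),
        st.text(alphabet="ACGT", min_size=1, max_size=50),
    )
    @settings(max_examples=100, deadline=None)
    def test_index_equals_naive_scan(self, ref_seqs, target):
        seqs = [(f"r{i}", s) for i, s in enumerate(ref_seqs)]
        ref = SubstringReference(seqs)
        assert ref.match_lengths(target) == naive_match_lengths(target, seqs, "nucleotide")

    @given(
        st.lists(st.text(alphabet="ACGT", min_size=1, max_size=20), min_size=1, max_size=3),
        st.text(alphabet="ACGT", min_size=1, max_size=20),
        st.text(alphabet="ACGT", min_size=1, max_size=25),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_reference(self, ref_seqs, extra, target):
        seqs = [(f"r{i}", s) for i, s in enumerate(ref_seqs)]
        before = chimera_ars(CodingSequence("t", target), SubstringReference(seqs))
        after = chimera_ars(
            CodingSequence("t", target), SubstringReference(seqs + [("extra", extra)])
        )
        assert after >= before


def seq_of(codons):
    return CodingSequence("g", "".join(codons))


class TestCodonPairTable:
    def test_single_gene_single_pair(self):
        table = build_codon_pair_table([seq_of(["ATG", "GCT"])])
        assert table.pair_freq == {("ATG", "GCT"): 1.0}

    def test_pairs_do_not_span_genes(self):
        genes = [seq_of(["ATG", "GCT"]), seq_of(["GCC", "GCA"])]
        table = build_codon_pair_table(genes)
        assert set(table.pair_freq) == {("ATG", "GCT"), ("GCC", "GCA")}

    def test_stop_containing_pairs_excluded(self):
        table = build_codon_pair_table([seq_of(["ATG", "GCT", "TAA", "GCC", "GCA"])])
        assert ("GCT", "TAA") not in table.pair_freq
        assert ("TAA", "GCC") not in table.pair_freq
        assert ("GCC", "GCA") in table.pair_freq

    def test_frequency_families_sum_to_one(self, small_genome):
        gen, _, _, _ = small_genome
        table = build_codon_pair_table(gen.genes)
        for fam in (table.pair_freq, table.codon_freq, table.aa_pair_freq, table.aa_freq):
            assert math.isclose(sum(fam.values()), 1.0, abs_tol=1e-12)

    def test_empty_corpus_raises(self):
        with pytest.raises(PatternIndexError):
            build_codon_pair_table([])


class TestCps:
    def test_arithmetic_forced_example(self):
        table = CodonPairTable(
            pair_freq={("GCT", "TTT"): 0.04},
            codon_freq={"GCT": 0.1, "TTT": 0.2},
            aa_pair_freq={("A", "F"): 0.08},
            aa_freq={"A": 0.2, "F": 0.4},
        )
        assert cps_pair(table, ("GCT", "TTT")) == pytest.approx(math.log(2))

    def test_independence_expectation_is_zero(self):
        table = CodonPairTable(
            pair_freq={("GCT", "TTT"): 0.02},  # exactly F(A)F(B)/(F(X)F(Y)) * F(XY)
            codon_freq={"GCT": 0.1, "TTT": 0.2},
            aa_pair_freq={("A", "F"): 0.08},
            aa_freq={"A": 0.2, "F": 0.4},
        )
        assert cps_pair(table, ("GCT", "TTT")) == pytest.approx(0.0)

    def test_zero_frequency_undefined(self):
        table = build_codon_pair_table([seq_of(["ATG", "GCT"])])
        with pytest.raises(PatternIndexError):
            cps_pair(table, ("GCT", "ATG"))

    def test_matches_literal_reevaluation_from_raw_counts(self, rng):
        """Randomized corpus: CPS equals the printed formula re-evaluated
        directly from raw pair counts."""
        codons = [c for c in CODE.sense_codons[:12]]
        genes = [
            seq_of([codons[i] for i in rng.integers(0, len(codons), size=20)])
            for _ in range(15)
        ]
        table = build_codon_pair_table(genes)

        # independent recount
        from collections import Counter

        pair_counts = Counter()
        for g in genes:
            cs = g.codons()
            pair_counts.update(zip(cs, cs[1:]))
        tot = sum(pair_counts.values())
        codon_counts, aa_counts, aa_pair = Counter(), Counter(), Counter()
        for (a, b), n in pair_counts.items():
            codon_counts[a] += n
            codon_counts[b] += n
            aa_counts[CODE.codon_to_aa[a]] += n
            aa_counts[CODE.codon_to_aa[b]] += n
            aa_pair[(CODE.codon_to_aa[a], CODE.codon_to_aa[b])] += n
        tot_c = sum(codon_counts.values())
        for pair, n in list(pair_counts.items())[:25]:
            a, b = pair
            x, y = CODE.codon_to_aa[a], CODE.codon_to_aa[b]
            expected = math.log(
                (n / tot)
                / (
                    (codon_counts[a] / tot_c)
                    * (codon_counts[b] / tot_c)
                    / ((aa_counts[x] / tot_c) * (aa_counts[y] / tot_c))
                    * (aa_pair[(x, y)] / tot)
                )
            )
            assert cps_pair(table, pair) == pytest.approx(expected, abs=1e-12)

    def test_gene_mean_and_skip_reporting(self):
        corpus = [seq_of(["ATG", "GCT", "GCC"]), seq_of(["GCT", "GCC", "GCA"])]
        table = build_codon_pair_table(corpus)
        gene = seq_of(["ATG", "GCT", "GCC", "GCA"])
        value, skipped = cps_gene_detail(gene, table)
        expected = (
            cps_pair(table, ("ATG", "GCT"))
            + cps_pair(table, ("GCT", "GCC"))
            + cps_pair(table, ("GCC", "GCA"))
        ) / 3
        assert value == pytest.approx(expected)
        assert skipped == 0

    def test_unscored_pairs_skipped(self):
        corpus = [seq_of(["ATG", "GCT"])]
        table = build_codon_pair_table(corpus)
        gene = seq_of(["ATG", "GCT", "TTT"])  # (GCT,TTT) absent from corpus
        value, skipped = cps_gene_detail(gene, table)
        assert skipped == 1
        assert value == pytest.approx(cps_pair(table, ("ATG", "GCT")))

    def test_no_scorable_pairs_raises(self):
        table = build_codon_pair_table([seq_of(["ATG", "GCT"])])
        with pytest.raises(PatternIndexError):
            cps_gene(seq_of(["TTT", "TTC"]), table)

    def test_corpus_order_invariance(self, small_genome):
        gen, _, _, _ = small_genome
        t1 = build_codon_pair_table(gen.genes)
        t2 = build_codon_pair_table(list(reversed(gen.genes)))
        g = gen.genes[0]
        assert cps_gene(g, t1) == pytest.approx(cps_gene(g, t2))
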