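"""Reference-set indices: CAI weights and scores, FOP, CBI, CEC."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codonuse.core import counts_from_codons
from codonuse.genetics import standard_code
from codonuse.reference import (
    ReferenceIndexError,
    ReferenceSet,
    cai,
    cai_weights,
    cbi,
    cec,
    cec_vectors,
    fop,
    preferred_codons,
    select_reference_set,
)
from codonuse.core import pool_counts

CODE = standard_code()
PHE = CODE.families["F"]  # ('TTC', 'TTT')
ALA = CODE.families["A"]


def ref_from_codons(codons):
    pooled = counts_from_codons("reference", codons)
    return ReferenceSet(gene_ids=["r"], pooled_counts=pooled, selection_rule="constructed")


class TestSelectReferenceSet:
    def genome(self, n):
        return [counts_from_codons(f"g{i:02d}", ["GCT", "GCC"]) for i in range(n)]

    def test_top_fraction(self):
        expr = {f"g{i:02d}": float(i) for i in range(10)}
        ref = select_reference_set(expr, self.genome(10), fraction=0.2)
        assert sorted(ref.gene_ids) == ["g08", "g09"]

    def test_fraction_one_pools_everything(self):
        expr = {f"g{i:02d}": float(i) for i in range(5)}
        ref = select_reference_set(expr, self.genome(5), fraction=1.0)
        assert len(ref.gene_ids) == 5
        assert ref.pooled_counts.get("GCT") == 5

    def test_tie_at_cutoff_resolved_by_gene_id(self):
        # two genes tied at the cutoff abundance: earlier id wins, size exact
        expr = {"g00": 5.0, "g01": 3.0, "g02": 3.0, "g03": 1.0, "g04": 0.5}
        ref = select_reference_set(expr, self.genome(5), fraction=0.4)
        assert ref.gene_ids == ["g00", "g01"]
        # reversing insertion order must not change the outcome
        ref2 = select_reference_set(dict(reversed(list(expr.items()))), self.genome(5), 0.4)
        assert ref2.gene_ids == ref.gene_ids

    def test_no_overlap_raises(self):
        with pytest.raises(ReferenceIndexError):
            select_reference_set({"zz": 1.0}, self.genome(3), 0.5)


class TestCaiWeights:
    def test_forced_ratio(self):
        ref = ref_from_codons([PHE[0]] * 10 + [PHE[1]] * 5)
        w = cai_weights(ref)
        assert w.weights[PHE[0]] == 1.0
        assert w.weights[PHE[1]] == pytest.approx(0.5)

    def test_zero_count_gets_pseudo(self):
        ref = ref_from_codons([PHE[0]] * 10)
        w = cai_weights(ref, pseudo=0.5)
        assert w.weights[PHE[1]] == pytest.approx(0.05)

    def test_family_maxima_are_one(self, small_genome):
        gen, expr, _, _ = small_genome
        from codonuse.core import count_codons

        ref = select_reference_set(dict(expr.items()), [count_codons(g) for g in gen.genes])
        w = cai_weights(ref)
        for aa, family in CODE.families.items():
            vals = [w.weights[c] for c in family if c in w.weights]
            if vals:
                assert max(vals) == pytest.approx(1.0)

    def test_met_trp_stops_excluded(self):
        ref = ref_from_codons(["ATG", "TGG"] + list(PHE))
        w = cai_weights(ref)
        assert {"ATG", "TGG"} <= w.excluded_codons
        assert CODE.stop_codons <= w.excluded_codons

    def test_absent_family_reported_undefined(self):
        ref = ref_from_codons(list(PHE))
        w = cai_weights(ref)
        assert "A" in w.undefined_families
        assert all(c not in w.weights for c in ALA)


class TestCai:
    def test_maximal_codons_score_one(self):
        ref = ref_from_codons([PHE[0]] * 10 + [PHE[1]] * 5 + [ALA[0]] * 4 + [ALA[1]])
        w = cai_weights(ref)
        gene = counts_from_codons("g", [PHE[0]] * 5 + [ALA[0]] * 5)
        assert cai(gene, w) == pytest.approx(1.0)

    def test_two_codon_closed_form(self):
        ref = ref_from_codons([PHE[0]] * 10 + [PHE[1]] * 5)
        w = cai_weights(ref)
        gene = counts_from_codons("g", [PHE[0], PHE[1]])
        assert cai(gene, w) == pytest.approx(math.sqrt(0.5))

    def test_permutation_invariance(self):
        ref = ref_from_codons([PHE[0]] * 10 + [PHE[1]] * 5 + [ALA[0]] * 3 + [ALA[2]] * 9)
        w = cai_weights(ref)
        a = cai(counts_from_codons("g", [PHE[0], ALA[2], PHE[1], ALA[0]]), w)
        b = cai(counts_from_codons("g", [ALA[0], PHE[1], ALA[2], PHE[0]]), w)
        assert a == pytest.approx(b)

    def test_all_excluded_codons_error(self):
        ref = ref_from_codons(list(PHE))
        w = cai_weights(ref)
        with pytest.raises(ReferenceIndexError):
            cai(counts_from_codons("g", ["ATG", "TGG"]), w)

    @given(st.lists(st.sampled_from(PHE + ALA), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_matches_log_space_accumulation(self, codons):
        ref = ref_from_codons([PHE[0]] * 10 + [PHE[1]] * 5 + [ALA[0]] * 8 + [ALA[1]] * 2)
        w = cai_weights(ref)
        gene = counts_from_codons("g", codons)
        acc, n = 0.0, 0
        for c in codons:
            acc += math.log(w.weights[c])
            n += 1
        assert cai(gene, w) == pytest.approx(math.exp(acc / n), abs=1e-12)


class TestFopCbi:
    def pref(self):
        ref = ref_from_codons([PHE[0]] * 3 + [ALA[0]] * 3 + [ALA[1]])
        return preferred_codons(ref)

    def test_all_optimal_is_one(self):
        gene = counts_from_codons("g", [PHE[0]] * 2 + [ALA[0]] * 2)
        assert fop(gene, self.pref()) == 1.0
        assert cbi(gene, self.pref()) == pytest.approx(1.0)

    def test_no_optimal_is_zero_fop(self):
        gene = counts_from_codons("g", [PHE[1]] * 2 + [ALA[2]] * 2)
        assert fop(gene, self.pref()) == 0.0

    def test_fop_partial_ratio(self):
        gene = counts_from_codons("g", [PHE[0]] * 3 + [PHE[1]])
        assert fop(gene, self.pref()) == pytest.approx(0.75)

    def test_cbi_uniform_usage_is_zero(self):
        gene = counts_from_codons("g", list(PHE) + list(ALA))
        assert cbi(gene, self.pref()) == pytest.approx(0.0)

    def test_cbi_avoided_preferred_is_minus_one(self):
        # one 2-fold amino acid, preferred used 0 of 4: (0-2)/(4-2) = -1
        gene = counts_from_codons("g", [PHE[1]] * 4)
        assert cbi(gene, self.pref()) == pytest.approx(-1.0)

    def test_cbi_excludes_single_codon_amino_acids(self):
        with_met = counts_from_codons("g", [PHE[0]] * 4 + ["ATG"] * 3)
        without = counts_from_codons("g", [PHE[0]] * 4)
        assert cbi(with_met, self.pref()) == pytest.approx(cbi(without, self.pref()))

    def test_preferred_tie_lexicographic_vs_all(self):
        ref = ref_from_codons([PHE[0]] * 3 + [PHE[1]] * 3)
        lex = preferred_codons(ref, ties="lexicographic")
        both = preferred_codons(ref, ties="all")
        assert lex.preferred["F"] == (min(PHE),)
        assert both.preferred["F"] == tuple(sorted(PHE))
        assert both.per_aa_count["F"] == 2


class TestCec:
    def test_matched_vectors_correlate_fully(self):
        # a gene whose enrichment pattern is an exact positive affine image of
        # the reference frequency pattern has Pearson correlation 1
        ref = ref_from_codons([PHE[0]] * 6 + [PHE[1]] * 2 + [ALA[0]] * 6 + [ALA[1]] * 2
                              + ["ATT"] * 6 + ["ATC"] * 2)
        gene = counts_from_codons("g", [PHE[0]] * 3 + [PHE[1]] + [ALA[0]] * 3 + [ALA[1]]
                                  + ["ATT"] * 3 + ["ATC"])
        codons, x, y = cec_vectors(gene, ref)
        assert np.corrcoef(x, y)[0, 1] == pytest.approx(cec(gene, ref))

    def test_hand_computed_small_vectors(self):
        ref = ref_from_codons([PHE[0]] * 8 + [PHE[1]] * 2 + [ALA[0]] * 5 + [ALA[1]] * 5
                              + ["TAT"] * 1 + ["TAC"] * 9)
        gene = counts_from_codons("g", [PHE[0]] * 4 + [PHE[1]] + [ALA[0]] * 2 + [ALA[1]] * 3
                                  + ["TAT"] * 2 + ["TAC"] * 3)
        _, x, y = cec_vectors(gene, ref)
        # textbook correlation formula as the independent oracle
        xm, ym = x - x.mean(), y - y.mean()
        r = (xm * ym).sum() / math.sqrt((xm**2).sum() * (ym**2).sum())
        assert cec(gene, ref) == pytest.approx(r, abs=1e-12)

    def test_uniform_target_zero_variance_raises(self):
        ref = ref_from_codons([PHE[0]] * 6 + [PHE[1]] * 2 + [ALA[0]] * 6 + [ALA[1]] * 2
                              + ["ATT"] * 6 + ["ATC"] * 2)
        # perfectly uniform target: enrichment is 1 everywhere (zero variance)
        gene = counts_from_codons("g", list(PHE) + list(ALA) + ["ATT", "ATC", "ATA"])
        with pytest.raises(ReferenceIndexError):
            cec(gene, ref)

    def test_too_few_shared_families_raises(self):
        ref = ref_from_codons([PHE[0]] * 6 + [PHE[1]] * 2 + [ALA[0]] * 6)
        gene = counts_from_codons("g", [PHE[0]] * 3 + [PHE[1]])
        with pytest.raises(ReferenceIndexError):
            cec(gene, ref)

    def test_anticorrelated_usage_is_negative(self):
        ref = ref_from_codons([PHE[0]] * 9 + [PHE[1]] + [ALA[0]] * 9 + [ALA[1]]
                              + ["TAT"] * 9 + ["TAC"])
        gene = counts_from_codons("g", [PHE[1]] * 9 + [PHE[0]] + [ALA[1]] * 9 + [ALA[0]]
                                  + ["TAC"] * 9 + ["TAT"])
        assert cec(gene, ref) < 0


def test_parameter_recovery_reference_matched_beats_uniform(code):
    """Genes drawn with the reference's codon distribution score higher CAI
    than uniformly drawn genes in nearly every seeded pair."""
    from codonuse.core import count_codons
    from codonuse.simulate import SyntheticGenomeSpec, simulate_genome

    biased = simulate_genome(SyntheticGenomeSpec(n_genes=40, length_codons=120, bias=0.8, seed=5))
    ref = select_reference_set(
        {g.gene_id: 1.0 for g in biased.genes[:10]},
        [count_codons(g) for g in biased.genes[:10]],
        fraction=1.0,
    )
    w = cai_weights(ref)
    wins = 0
    n = 100
    for s in range(n):
        matched = simulate_genome(
            SyntheticGenomeSpec(n_genes=1, length_codons=120, bias=0.8, seed=1000 + s)
        ).genes[0]
        uniform = simulate_genome(
            SyntheticGenomeSpec(n_genes=1, length_codons=120, bias=0.0, seed=2000 + s)
        ).genes[0]
        if cai(count_codons(matched), w) > cai(count_codons(uniform), w):
            wins += 1
    assert wins >= 95
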