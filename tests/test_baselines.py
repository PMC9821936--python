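"""Baseline scores, profiles (ratio / normalized bias), realizability."""

from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hyperhomophily import (
    BaselineSpec,
    affinity_from_counts,
    assemble_profile,
    asymptotic_baseline,
    asymptotic_baseline_vector,
    check_realizable,
    complete_uniform,
    composition_null,
    exact_baseline,
    exact_baseline_vector,
)
from hyperhomophily.scores import ScoreVector

F = Fraction


class TestExactBaseline:
    def test_balanced_six_node_values(self):
        assert exact_baseline_vector(6, 3, 3) == (F(3, 10), F(3, 5), F(1, 10))

    @pytest.mark.parametrize("n, size_x", [(6, 3), (10, 4), (50, 20)])
    def test_pair_baseline_is_relative_class_size(self, n, size_x):
        assert exact_baseline(n, size_x, 2, 2) == F(size_x - 1, n - 1)

    def test_type_exceeding_class_size_has_zero_probability(self):
        assert exact_baseline(6, 2, 4, 4) == 0

    @pytest.mark.parametrize("n, size_x, k", [(6, 3, 3), (9, 2, 4), (12, 7, 5), (30, 11, 6)])
    def test_sums_to_one(self, n, size_x, k):
        assert sum(exact_baseline_vector(n, size_x, k)) == 1

    def test_invalid_ranges(self):
        with pytest.raises(ValueError):
            exact_baseline(5, 3, 6, 2)
        with pytest.raises(ValueError):
            exact_baseline(5, 0, 3, 1)


class TestAsymptoticBaseline:
    def test_known_values(self):
        assert asymptotic_baseline(0.5, 4, 2) == pytest.approx(0.375)
        assert asymptotic_baseline(0.5, 2, 2) == pytest.approx(0.5)

    @settings(max_examples=40, derandomize=True)
    @given(st.floats(0.05, 0.95), st.integers(2, 8))
    def test_sums_to_one(self, alpha, k):
        assert sum(asymptotic_baseline_vector(alpha, k)) == pytest.approx(1.0)

    @pytest.mark.parametrize("k", [2, 3, 4, 5, 6])
    def test_large_n_exact_converges_to_asymptotic(self, k):
        n = 10**6
        size_x = int(0.37 * n)
        alpha = size_x / n
        for t in range(1, k + 1):
            exact = float(exact_baseline(n, size_x, k, t))
            assert exact == pytest.approx(asymptotic_baseline(alpha, k, t), abs=1e-4)

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            asymptotic_baseline(1.0, 3, 2)


def test_composition_null_two_children():
    # the classic two-child gender split: 25% / 50% / 25%
    assert composition_null(0.5, 2) == (0.25, 0.5, 0.25)


class TestCompleteHypergraphBaselineIdentity:
    @pytest.mark.parametrize("n_a, n_b, k", [(3, 3, 3), (2, 6, 4), (5, 4, 2), (4, 4, 6)])
    def test_complete_affinities_equal_exact_baselines(self, n_a, n_b, k):
        v = complete_uniform(n_a, n_b, k)
        n = n_a + n_b
        assert affinity_from_counts(v, "A").values == exact_baseline_vector(n, n_a, k)
        assert affinity_from_counts(v, "B").values == exact_baseline_vector(n, n_b, k)


class TestAssembleProfile:
    def make_profile(self, h, b, k=3):
        scores = ScoreVector(class_label="A", k=k, values=tuple(h))
        spec = BaselineSpec(k=k, b_A=tuple(b), b_B=tuple(b))
        return assemble_profile(scores, spec, side="A")

    def test_ratio_one_gives_zero_bias(self):
        p = self.make_profile([F(3, 10), F(3, 5), F(1, 10)], [F(3, 10), F(3, 5), F(1, 10)])
        assert p.ratio == (1, 1, 1)
        assert p.bias == (0, 0, 0)

    def test_maximal_overexpression_reaches_bias_one(self):
        p = self.make_profile([0, 0, 1], [F(45, 100), F(45, 100), F(1, 10)])
        assert p.bias[2] == 1

    def test_intermediate_bias_value(self):
        p = self.make_profile([F(1, 2), F(3, 10), F(1, 5)], [F(1, 5), F(3, 10), F(1, 2)])
        assert p.bias[0] == F(3, 8)  # 0.3 / 0.8

    def test_undefined_entries_propagate(self):
        scores = ScoreVector(class_label="A", k=2, values=(None, None))
        spec = BaselineSpec(k=2, b_A=(0.5, 0.5), b_B=(0.5, 0.5))
        p = assemble_profile(scores, spec, side="A")
        assert p.ratio == (None, None) and p.bias == (None, None)

    def test_mismatched_k_rejected(self):
        scores = ScoreVector(class_label="A", k=2, values=(F(1, 2), F(1, 2)))
        spec = BaselineSpec(k=3, b_A=(F(1, 3),) * 3, b_B=(F(1, 3),) * 3)
        with pytest.raises(ValueError):
            assemble_profile(scores, spec, side="A")

    @settings(max_examples=60, derandomize=True)
    @given(st.floats(0.001, 0.999), st.floats(0.001, 0.999), st.floats(0.001, 0.999))
    def test_bias_bounded_and_monotone_in_affinity(self, h1, h2, b):
        k = 2
        spec = BaselineSpec(k=k, b_A=(b, 1 - b), b_B=(b, 1 - b))
        lo, hi = sorted((h1, h2))
        p_lo = assemble_profile(ScoreVector("A", k, (lo, 1 - lo)), spec, "A")
        p_hi = assemble_profile(ScoreVector("A", k, (hi, 1 - hi)), spec, "A")
        for p in (p_lo, p_hi):
            assert -1 <= p.bias[0] <= 1
            assert (p.bias[0] > 0) == (p.h[0] > p.b[0])
        assert p_lo.bias[0] <= p_hi.bias[0]


class TestRealizability:
    def test_symmetric_baselines_with_binomial_witness(self):
        spec = BaselineSpec(k=3, b_A=(F(1, 4), F(1, 2), F(1, 4)), b_B=(F(1, 4), F(1, 2), F(1, 4)))
        res = check_realizable(spec)
        assert res.realizable
        w = res.witness
        scale = w[0]
        assert tuple(x / scale for x in w) == (1, 3, 3, 1)

    @pytest.mark.parametrize("n, n_a, k", [(6, 3, 3), (10, 4, 4), (12, 5, 5)])
    def test_exact_specs_are_realizable_and_witness_matches_complete(self, n, n_a, k):
        spec = BaselineSpec.exact(n, n_a, k)
        res = check_realizable(spec)
        assert res.realizable
        complete = complete_uniform(n_a, n - n_a, k).m
        # witness proportions match the complete hypergraph up to scale
        ratios = {F(w) / c for w, c in zip(res.witness, complete)}
        assert len(ratios) == 1

    def test_asymmetric_vectors_are_rejected(self):
        spec = BaselineSpec(
            k=3,
            b_A=(F(1, 10), F(1, 10), F(8, 10)),
            b_B=(F(8, 10), F(1, 10), F(1, 10)),
        )
        res = check_realizable(spec)
        assert not res.realizable

    def test_float_asymptotic_specs_are_realizable(self):
        for alpha in (0.2, 0.5, 0.8):
            for k in (2, 3, 4, 5):
                assert check_realizable(BaselineSpec.asymptotic(alpha, k)).realizable

    def test_nonpositive_entries_raise(self):
        spec = BaselineSpec(k=2, b_A=(0, 1), b_B=(0.5, 0.5))
        with pytest.raises(ValueError):
            check_realizable(spec)
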