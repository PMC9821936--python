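"""Feasibility LPs, duality, analytic certificates, dropped-constraint witnesses."""

import numpy as np
import pytest

from hyperhomophily import (
    BaselineSpec,
    CertificateError,
    affinity_from_counts,
    build_program,
    odd_k_dual_certificate,
    dropped_constraint_witness,
    ratio_threshold_rows,
    solve_dual,
    solve_program,
)
from hyperhomophily.feasibility import certificate_variables, verify_dual_feasible
from hyperhomophily.indices import strictly_greater

TOL = 1e-8


class TestProgramConstruction:
    def test_majority_constraint_count(self):
        spec = BaselineSpec.asymptotic(0.5, 3)
        program = build_program(3, spec)
        assert program.n_constraints == 4  # two classes x t in {2, 3}
        assert program.r == 2

    def test_dropped_constraint_is_removed(self):
        spec = BaselineSpec.asymptotic(0.5, 3)
        program = build_program(3, spec, drop=("A", 3))
        assert program.n_constraints == 3
        assert ("A", 3) not in program.labels

    def test_even_k_augmentation_adds_middle_row(self):
        spec = BaselineSpec.asymptotic(0.5, 4)
        program = build_program(4, spec, augment="A")
        assert program.n_constraints == 5
        assert ("A", 2) in program.labels

    def test_augmentation_rejected_for_odd_k(self):
        with pytest.raises(ValueError, match="even"):
            build_program(3, BaselineSpec.asymptotic(0.5, 3), augment="A")

    def test_unknown_drop_index_rejected(self):
        with pytest.raises(ValueError, match="drop"):
            build_program(3, BaselineSpec.asymptotic(0.5, 3), drop=("A", 1))

    def test_non_realizable_baselines_rejected(self):
        spec = BaselineSpec(k=3, b_A=(0.1, 0.1, 0.8), b_B=(0.8, 0.1, 0.1))
        with pytest.raises(ValueError, match="realizable"):
            build_program(3, spec)


class TestMajorityFeasibility:
    @pytest.mark.parametrize("k", [3, 5, 7])
    @pytest.mark.parametrize("alpha", [0.3, 0.5])
    def test_odd_k_strict_majority_is_infeasible(self, k, alpha):
        sol = solve_program(build_program(k, BaselineSpec.asymptotic(alpha, k)))
        assert abs(sol.gamma) <= TOL
        assert not sol.feasible

    @pytest.mark.parametrize("k", [4, 6])
    def test_even_k_majority_feasible_without_middle_condition(self, k):
        spec = BaselineSpec.asymptotic(0.5, k)
        assert solve_program(build_program(k, spec)).feasible
        aug = solve_program(build_program(k, spec, augment="A"))
        assert abs(aug.gamma) <= TOL

    def test_dropping_any_constraint_opens_the_region(self):
        spec = BaselineSpec.asymptotic(0.4, 3)
        for drop in [("A", 2), ("A", 3), ("B", 2), ("B", 3)]:
            sol = solve_program(build_program(3, spec, drop=drop))
            assert sol.gamma > TOL

    def test_optimal_x_is_a_distribution(self):
        sol = solve_program(build_program(3, BaselineSpec.asymptotic(0.5, 3), drop=("A", 3)))
        assert sol.x.min() >= -1e-12
        assert np.isclose(sol.x.sum(), 1.0)


class TestMonotonicFeasibility:
    @pytest.mark.parametrize("k", [3, 5, 7])
    def test_odd_k_strict_monotonic_is_infeasible(self, k):
        sol = solve_program(build_program(k, BaselineSpec.asymptotic(0.4, k), mode="monotonic"))
        assert abs(sol.gamma) <= TOL

    @pytest.mark.parametrize("k", [4, 6])
    def test_even_k_monotonic_feasible_only_without_middle_condition(self, k):
        spec = BaselineSpec.asymptotic(0.4, k)
        assert solve_program(build_program(k, spec, mode="monotonic")).feasible
        for side in ("A", "B"):
            aug = solve_program(build_program(k, spec, mode="monotonic", augment=side))
            assert abs(aug.gamma) <= TOL


class TestDuality:
    @pytest.mark.parametrize("k", [3, 4, 5, 6, 7])
    @pytest.mark.parametrize("alpha", [0.25, 0.4, 0.5, 0.65])
    def test_strong_duality(self, k, alpha):
        spec = BaselineSpec.asymptotic(alpha, k)
        primal = solve_program(build_program(k, spec))
        dual = solve_dual(k, spec)
        assert primal.gamma == pytest.approx(dual.objective, abs=1e-8)

    @pytest.mark.parametrize("k, spec", [
        (3, BaselineSpec.exact(6, 3, 3)),
        (5, BaselineSpec.asymptotic(0.4, 5)),
        (7, BaselineSpec.asymptotic(0.3, 7)),
    ])
    def test_analytic_certificate_verifies(self, k, spec):
        cert = odd_k_dual_certificate(k, spec)
        assert cert.objective == 0.0
        assert cert.max_violation <= 1e-9
        assert cert.Y == pytest.approx(k * k)
        total = sum(cert.y_A_norm.values()) + sum(cert.y_B_norm.values())
        assert total == pytest.approx(1.0)

    def test_perturbed_certificate_is_detected(self):
        spec = BaselineSpec.asymptotic(0.4, 5)
        delta, y_A, y_B = certificate_variables(5, spec)
        y_B[5] *= 1.10
        Y = sum(y_A.values()) + sum(y_B.values())
        worst = verify_dual_feasible(
            5, spec, {t: v / Y for t, v in y_A.items()}, {t: v / Y for t, v in y_B.items()}
        )
        assert worst > 1e-9

    def test_certificate_requires_odd_k(self):
        with pytest.raises(ValueError, match="odd"):
            odd_k_dual_certificate(4, BaselineSpec.asymptotic(0.5, 4))


class TestDroppedConstraintWitnesses:
    @pytest.mark.parametrize("drop", [("A", 2), ("A", 3), ("B", 2), ("B", 3)])
    def test_k3_integer_witness_for_every_drop(self, drop):
        spec = BaselineSpec.exact(20, 10, 3)
        w = dropped_constraint_witness(3, spec, drop)
        assert all(isinstance(c, int) and c >= 0 for c in w.counts)
        h = {"A": affinity_from_counts(w.view, "A"), "B": affinity_from_counts(w.view, "B")}
        for side, t in w.satisfied:
            assert strictly_greater(h[side][t], spec.side(side)[t - 1])
        # the witness cannot satisfy full two-class strict majority
        assert not all(
            strictly_greater(h[side][t], spec.side(side)[t - 1])
            for side in ("A", "B") for t in (2, 3)
        )

    def test_k5_every_drop_has_a_witness(self):
        spec = BaselineSpec.exact(30, 15, 5)
        for side in ("A", "B"):
            for t in (3, 4, 5):
                w = dropped_constraint_witness(5, spec, (side, t))
                assert len(w.satisfied) == 5
                assert sum(w.counts) > 0


class TestCustomMode:
    def test_top_ratio_threshold_query(self):
        # can both classes have their top-2 ratio scores above 1.05 at k=4?
        spec = BaselineSpec.asymptotic(0.5, 4)
        rows = ratio_threshold_rows(4, spec, "A", [3, 4], 1.05) + \
               ratio_threshold_rows(4, spec, "B", [3, 4], 1.05)
        sol = solve_program(build_program(4, spec, mode="custom", custom_rows=rows))
        assert sol.feasible
        # but demanding every ratio above 1 for one class alone is impossible
        rows_all = ratio_threshold_rows(4, spec, "A", [1, 2, 3, 4], 1.0)
        sol_all = solve_program(build_program(4, spec, mode="custom", custom_rows=rows_all))
        assert abs(sol_all.gamma) <= TOL
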