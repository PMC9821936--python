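"""Linear programs deciding which strict homophily notions are achievable.

Whether two classes can *simultaneously* exhibit strict majority (or strict
monotonic) homophily against given realizable baselines is a purely
combinatorial question about type-count proportions x_0..x_k.  The primal LP

    max gamma
    s.t.  sum_i x_i = 1,   x_i >= 0
          t*x_t     - b_t(A) * sum_i i*x_i     >= gamma   for t in {r..k}
          t*x_{k-t} - b_t(B) * sum_i (k-i)*x_i >= gamma   for t in {r..k}

with r = ceil((k+1)/2) (the smallest t with t > k-t) has optimum gamma* > 0
iff some hypergraph satisfies every strict-majority inequality for both
classes at once; gamma* = 0 is always attainable because the baselines are
realizable.  The monotonic variant replaces the margin rows with the
rearranged strict-increase conditions

    t*x_t*b_{t-1}(A) - (t-1)*x_{t-1}*b_t(A) >= gamma   (class B mirrored).

The dual of the majority LP (variables y_{A,t}, y_{B,t} >= 0, free objective
scalar) certifies impossibility: any dual-feasible point with objective 0
proves gamma* <= 0.  For odd k an analytic such point exists for *every*
realizable baseline pair; :func:`odd_k_dual_certificate` constructs it and
verifies each dual constraint numerically before returning it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from math import lcm

import numpy as np
from scipy.optimize import linprog

from .baselines import BaselineSpec, check_realizable
from .core import TwoClassUniformView
from .indices import strictly_greater
from .scores import affinity_from_counts

__all__ = [
    "FeasibilityProgram",
    "LPSolution",
    "DualSolution",
    "DualCertificate",
    "CertificateError",
    "build_program",
    "solve_program",
    "solve_dual",
    "odd_k_dual_certificate",
    "dropped_constraint_witness",
    "ratio_threshold_rows",
]

#: gamma* above this value declares the notion combinatorially feasible.
FEASIBILITY_TOL = 1e-8


def _majority_row(k: int, side: str, t: int, b) -> np.ndarray:
    row = np.zeros(k + 1)
    bt = float(b[t - 1])
    if side == "A":
        for i in range(k + 1):
            row[i] -= bt * i
        row[t] += t
    else:
        for i in range(k + 1):
            row[i] -= bt * (k - i)
        row[k - t] += t
    return row


def _monotonic_row(k: int, side: str, t: int, b) -> np.ndarray:
    row = np.zeros(k + 1)
    b_prev, b_t = float(b[t - 2]), float(b[t - 1])
    if side == "A":
        row[t] += t * b_prev
        row[t - 1] -= (t - 1) * b_t
    else:
        row[k - t] += t * b_prev
        row[k - t + 1] -= (t - 1) * b_t
    return row


@dataclass(frozen=True)
class FeasibilityProgram:
    """Margin LP over type proportions x_0..x_k with a shared margin gamma.

    ``rows[i] . x >= gamma`` for every labelled constraint row; additionally
    ``sum x = 1`` and ``x >= 0``.
    """

    k: int
    baselines: BaselineSpec
    mode: str
    r: int
    labels: tuple           # (side, t) per margin row; custom rows get (name, None)
    rows: np.ndarray        # shape (n_rows, k+1)
    augment: str | None = None
    drop: tuple | None = None

    @property
    def n_constraints(self) -> int:
        return len(self.labels)


def build_program(
    k: int,
    baselines: BaselineSpec,
    mode: str = "majority",
    drop: tuple | None = None,
    augment: str | None = None,
    custom_rows: list | None = None,
) -> FeasibilityProgram:
    """Assemble the feasibility LP for a homophily notion.

    Parameters
    ----------
    mode
        ``"majority"``, ``"monotonic"``, or ``"custom"`` (then ``custom_rows``
        supplies ``(name, coefficient_vector)`` pairs directly).
    drop
        Optional ``(side, t)`` naming one margin constraint to remove
        (the relaxation studied by the dropped-inequality witnesses).
    augment
        Optional class side (``"A"`` or ``"B"``); for even k adds the middle
        t = k/2 condition for that class, which restores impossibility.
    """
    if baselines.k != k:
        raise ValueError(f"baselines are for k={baselines.k}, program wants k={k}")
    res = check_realizable(baselines)
    if not res.realizable:
        raise ValueError(f"baselines are not realizable: {res.reason}")
    r = (k + 2) // 2
    labels: list = []
    rows: list = []
    if mode == "custom":
        for name, coeff in custom_rows or []:
            labels.append((name, None))
            rows.append(np.asarray(coeff, dtype=float))
    elif mode in ("majority", "monotonic"):
        maker = _majority_row if mode == "majority" else _monotonic_row
        for side in ("A", "B"):
            ts = list(range(r, k + 1))
            if augment == side:
                if k % 2 != 0:
                    raise ValueError("middle augmentation applies to even k only")
                ts.append(k // 2)
            for t in ts:
                labels.append((side, t))
                rows.append(maker(k, side, t, baselines.side(side)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if drop is not None:
        if tuple(drop) not in labels:
            raise ValueError(f"drop index {drop!r} not among constraints {labels!r}")
        i = labels.index(tuple(drop))
        del labels[i]
        rows = [row for j, row in enumerate(rows) if j != i]
    return FeasibilityProgram(
        k=k, baselines=baselines, mode=mode, r=r,
        labels=tuple(labels), rows=np.array(rows), augment=augment, drop=drop,
    )


def ratio_threshold_rows(k: int, baselines: BaselineSpec, side: str, ts, threshold: float) -> list:
    """Custom rows requiring ratio scores h_t/b_t >= threshold (+ margin) for given t.

    Useful with ``mode="custom"`` to ask e.g. whether the top-i ratio scores of
    both classes can simultaneously exceed a fixed threshold.
    """
    out = []
    b = baselines.side(side)
    for t in ts:
        row = np.zeros(k + 1)
        bt = float(b[t - 1]) * threshold
        if side == "A":
            for i in range(k + 1):
                row[i] -= bt * i
            row[t] += t
        else:
            for i in range(k + 1):
                row[i] -= bt * (k - i)
            row[k - t] += t
        out.append((f"{side},t={t},ratio>={threshold}", row))
    return out


@dataclass(frozen=True)
class LPSolution:
    gamma: float
    x: np.ndarray
    feasible: bool          # gamma > FEASIBILITY_TOL
    status: str


def solve_program(program: FeasibilityProgram, tol: float = FEASIBILITY_TOL) -> LPSolution:
    """Solve the margin LP to optimality (HiGHS); verdict is gamma* > tol."""
    k = program.k
    nv = k + 2  # x_0..x_k, gamma
    c = np.zeros(nv)
    c[-1] = -1.0
    n_rows = len(program.rows)
    A_ub = np.zeros((n_rows, nv))
    A_ub[:, : k + 1] = -program.rows
    A_ub[:, -1] = 1.0
    A_eq = np.zeros((1, nv))
    A_eq[0, : k + 1] = 1.0
    bounds = [(0, None)] * (k + 1) + [(None, None)]
    res = linprog(c, A_ub=A_ub, b_ub=np.zeros(n_rows), A_eq=A_eq, b_eq=[1.0],
                  bounds=bounds, method="highs")
    if res.status != 0:
        raise RuntimeError(f"LP solver failed: status={res.status} ({res.message})")
    gamma = -res.fun
    return LPSolution(gamma=gamma, x=res.x[: k + 1], feasible=gamma > tol, status=res.message)


@dataclass(frozen=True)
class DualSolution:
    objective: float
    y_A: dict
    y_B: dict
    status: str


def _dual_arrays(k: int, baselines: BaselineSpec, r: int):
    """Coefficient matrices of the majority-LP dual.

    Variables: y_{A,t}, y_{B,t} for t in {r..k} and a free objective scalar.
    Constraints: sum of all y equals 1, and for every hyperedge type
    i in {0..k}:

        [i>=r] i*y_{A,i} + [k-i>=r] (k-i)*y_{B,k-i}
            <= i*sum_t y_{A,t} b_t(A) + (k-i)*sum_t y_{B,t} b_t(B) + objective.
    """
    ts = list(range(r, k + 1))
    m = len(ts)
    nv = 2 * m + 1
    bA = [float(v) for v in baselines.b_A]
    bB = [float(v) for v in baselines.b_B]
    A_eq = np.zeros((1, nv))
    A_eq[0, : 2 * m] = 1.0
    A_ub = np.zeros((k + 1, nv))
    for i in range(k + 1):
        for j, t in enumerate(ts):
            A_ub[i, j] -= i * bA[t - 1]
            A_ub[i, m + j] -= (k - i) * bB[t - 1]
        if i >= r:
            A_ub[i, ts.index(i)] += i
        if k - i >= r:
            A_ub[i, m + ts.index(k - i)] += k - i
        A_ub[i, -1] = -1.0
    return ts, m, A_ub, A_eq


def solve_dual(k: int, baselines: BaselineSpec) -> DualSolution:
    """Solve the dual of the majority LP directly (independent of the primal)."""
    res_r = check_realizable(baselines)
    if not res_r.realizable:
        raise ValueError(f"baselines are not realizable: {res_r.reason}")
    r = (k + 2) // 2
    ts, m, A_ub, A_eq = _dual_arrays(k, baselines, r)
    nv = 2 * m + 1
    c = np.zeros(nv)
    c[-1] = 1.0
    bounds = [(0, None)] * (2 * m) + [(None, None)]
    res = linprog(c, A_ub=A_ub, b_ub=np.zeros(k + 1), A_eq=A_eq, b_eq=[1.0],
                  bounds=bounds, method="highs")
    if res.status != 0:
        raise RuntimeError(f"dual LP solver failed: status={res.status} ({res.message})")
    y = res.x
    return DualSolution(
        objective=res.fun,
        y_A={t: y[j] for j, t in enumerate(ts)},
        y_B={t: y[m + j] for j, t in enumerate(ts)},
        status=res.message,
    )


class CertificateError(RuntimeError):
    """The analytic dual certificate failed verification."""


@dataclass(frozen=True)
class DualCertificate:
    """Analytic dual-feasible point with objective 0 (odd k).

    ``y_A``/``y_B`` are the raw variables, ``Y`` their total (= k^2), and
    ``y_A_norm``/``y_B_norm`` the normalized point that is dual-feasible.
    ``max_violation`` is the largest residual over all dual constraints.
    """

    k: int
    delta: float
    y_A: dict
    y_B: dict
    Y: float
    y_A_norm: dict = field(default_factory=dict)
    y_B_norm: dict = field(default_factory=dict)
    objective: float = 0.0
    max_violation: float = 0.0


def certificate_variables(k: int, baselines: BaselineSpec):
    """The analytic dual variable assignment for odd k (unnormalized)."""
    r = (k + 1) // 2
    ts = list(range(r, k + 1))
    bB = [float(v) for v in baselines.b_B]
    delta = (2 / k) * sum(1 / t for t in ts)
    num = sum((k / i - 1) * bB[i - 1] for i in ts)
    den = 1 - sum((2 - k / i) * bB[i - 1] for i in ts)
    y_B = {k: (2 / delta) * num / den}
    for t in range(r, k):
        y_B[t] = (2 / delta) * (k / t - 1) + (2 - k / t) * y_B[k]
    y_A = {t: 2 * k / (delta * t) - y_B[t] for t in ts}
    return delta, y_A, y_B


def verify_dual_feasible(k: int, baselines: BaselineSpec, y_A: dict, y_B: dict,
                         objective: float = 0.0) -> float:
    """Max residual of the dual constraints at (y, objective); <= 0 means feasible."""
    r = (k + 2) // 2
    ts = list(range(r, k + 1))
    bA = [float(v) for v in baselines.b_A]
    bB = [float(v) for v in baselines.b_B]
    S_A = sum(y_A[t] * bA[t - 1] for t in ts)
    S_B = sum(y_B[t] * bB[t - 1] for t in ts)
    worst = max((-y_A[t] for t in ts), default=0.0)
    worst = max(worst, max((-y_B[t] for t in ts), default=0.0))
    for i in range(k + 1):
        lhs = 0.0
        if i >= r:
            lhs += i * y_A[i]
        if k - i >= r:
            lhs += (k - i) * y_B[k - i]
        worst = max(worst, lhs - i * S_A - (k - i) * S_B - objective)
    return worst


def odd_k_dual_certificate(k: int, baselines: BaselineSpec, tol: float = 1e-9) -> DualCertificate:
    """Construct and *verify* the analytic odd-k impossibility certificate.

    Raises :class:`CertificateError` if any dual constraint is violated, so a
    transcription error in the analytic formulas cannot pass silently.
    """
    if k % 2 == 0:
        raise ValueError("the analytic certificate covers odd k only")
    res = check_realizable(baselines)
    if not res.realizable:
        raise ValueError(f"baselines are not realizable: {res.reason}")
    delta, y_A, y_B = certificate_variables(k, baselines)
    Y = sum(y_A.values()) + sum(y_B.values())
    y_A_n = {t: v / Y for t, v in y_A.items()}
    y_B_n = {t: v / Y for t, v in y_B.items()}
    worst = verify_dual_feasible(k, baselines, y_A_n, y_B_n, objective=0.0)
    total = sum(y_A_n.values()) + sum(y_B_n.values())
    if abs(total - 1.0) > tol:
        raise CertificateError(f"normalized dual variables sum to {total}, expected 1")
    if worst > tol:
        raise CertificateError(f"dual constraint violated by {worst:.3e}")
    return DualCertificate(
        k=k, delta=delta, y_A=y_A, y_B=y_B, Y=Y,
        y_A_norm=y_A_n, y_B_norm=y_B_n, objective=0.0, max_violation=worst,
    )


@dataclass(frozen=True)
class WitnessResult:
    counts: tuple
    view: TwoClassUniformView
    gamma: float
    satisfied: tuple      # (side, t) inequalities that hold strictly


def dropped_constraint_witness(k: int, baselines: BaselineSpec, drop: tuple,
                  max_denominator: int = 10**6) -> WitnessResult:
    """Integer counts strictly satisfying all majority inequalities but one.

    Solves the majority LP with the ``drop`` constraint removed; its optimum
    is positive, and the optimal vertex is rationalized and scaled to integer
    counts, then every remaining inequality is re-verified in exact/strict
    arithmetic.  Raises ``RuntimeError`` if rounding cannot preserve
    strictness within the retry bound.
    """
    program = build_program(k, baselines, mode="majority", drop=tuple(drop))
    sol = solve_program(program)
    if not sol.feasible:
        raise RuntimeError(
            f"dropping {drop!r} does not open a feasible region (gamma*={sol.gamma:.3e})"
        )
    for cap in (10**4, max_denominator, 10**9):
        fracs = [Fraction(max(xi, 0.0)).limit_denominator(cap) for xi in sol.x]
        denoms = [f.denominator for f in fracs]
        scale = lcm(*denoms) if denoms else 1
        counts = tuple(int(f * scale) for f in fracs)
        if sum(counts) == 0:
            continue
        view = TwoClassUniformView(k=k, m=counts, focus="A", out_label="B")
        h = {"A": affinity_from_counts(view, "A"), "B": affinity_from_counts(view, "B")}
        ok = all(
            strictly_greater(h[side][t], baselines.side(side)[t - 1])
            for side, t in program.labels
        )
        if ok:
            return WitnessResult(counts=counts, view=view, gamma=sol.gamma,
                                 satisfied=program.labels)
    raise RuntimeError("could not round LP vertex to an integer witness preserving strictness")
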