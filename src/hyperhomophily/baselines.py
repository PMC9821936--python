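"""Null baseline scores, ratio and normalized-bias profiles, realizability.

The standard baseline b_t(X) is the probability that a class-X node joining a
size-k group ends up in a type-t group when its k-1 co-members are drawn
uniformly at random from the other n-1 nodes:

    b_t(X) = C(|X|-1, t-1) C(n-|X|, k-t) / C(n-1, k-1)            (exact)

With the class proportion alpha = |X|/n held fixed and n -> infinity this
converges to the Binomial(k-1, alpha) form

    b_t(A) = C(k-1, t-1) alpha^(t-1) (1-alpha)^(k-t),

with 1-alpha in place of alpha for the out class.  Exact baselines use
integer/rational arithmetic throughout, so no overflow occurs for large n.

A pair of baseline vectors (one per class) is *realizable* when some
hypergraph attains them exactly as affinity scores; the check inverts the
count-form affinity formula on count proportions.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb

__all__ = [
    "BaselineSpec",
    "AffinityProfile",
    "RealizabilityResult",
    "exact_baseline",
    "exact_baseline_vector",
    "asymptotic_baseline",
    "asymptotic_baseline_vector",
    "composition_null",
    "assemble_profile",
    "check_realizable",
]

from .scores import ScoreVector


def exact_baseline(n: int, size_x: int, k: int, t: int) -> Fraction:
    """Exact null probability of a type-t membership for a class of ``size_x`` nodes."""
    if not (1 <= t <= k <= n):
        raise ValueError(f"require 1 <= t <= k <= n, got t={t}, k={k}, n={n}")
    if not (0 < size_x <= n):
        raise ValueError(f"class size must be in 1..n, got {size_x}")
    return Fraction(comb(size_x - 1, t - 1) * comb(n - size_x, k - t), comb(n - 1, k - 1))


def exact_baseline_vector(n: int, size_x: int, k: int) -> tuple:
    return tuple(exact_baseline(n, size_x, k, t) for t in range(1, k + 1))


def asymptotic_baseline(alpha: float, k: int, t: int) -> float:
    """Large-n baseline C(k-1, t-1) alpha^(t-1) (1-alpha)^(k-t) for the focus class."""
    if not (0 < alpha < 1):
        raise ValueError(f"class proportion must be in (0, 1), got {alpha}")
    if not (1 <= t <= k):
        raise ValueError(f"require 1 <= t <= k, got t={t}, k={k}")
    if isinstance(alpha, Fraction):
        return comb(k - 1, t - 1) * alpha ** (t - 1) * (1 - alpha) ** (k - t)
    return comb(k - 1, t - 1) * alpha ** (t - 1) * (1.0 - alpha) ** (k - t)


def asymptotic_baseline_vector(alpha: float, k: int) -> tuple:
    return tuple(asymptotic_baseline(alpha, k, t) for t in range(1, k + 1))


def composition_null(alpha: float, k: int) -> tuple:
    """Null pmf over group compositions j = 0..k: Binomial(k, alpha).

    This is the chance that an anonymously observed size-k group contains
    exactly j focus-class members when each member is independently of the
    focus class with probability ``alpha`` (e.g. the classic two-child
    composition probabilities at k=2, alpha=1/2).
    """
    if not (0 <= alpha <= 1):
        raise ValueError("alpha must be in [0, 1]")
    return tuple(comb(k, j) * alpha ** j * (1 - alpha) ** (k - j) for j in range(k + 1))


@dataclass(frozen=True)
class BaselineSpec:
    """Baseline vectors b_t(A), b_t(B) for t = 1..k, with provenance."""

    k: int
    b_A: tuple
    b_B: tuple
    kind: str = "custom"          # exact | asymptotic | custom
    params: tuple = ()            # (n, n_A) for exact; (alpha,) for asymptotic

    def __post_init__(self):
        if len(self.b_A) != self.k or len(self.b_B) != self.k:
            raise ValueError("baseline vectors must have one entry per t in 1..k")
        for b in (*self.b_A, *self.b_B):
            if not (0 <= b <= 1):
                raise ValueError(f"baseline entries must lie in [0, 1], got {b}")

    @classmethod
    def exact(cls, n: int, n_A: int, k: int) -> "BaselineSpec":
        return cls(
            k=k,
            b_A=exact_baseline_vector(n, n_A, k),
            b_B=exact_baseline_vector(n, n - n_A, k),
            kind="exact",
            params=(n, n_A),
        )

    @classmethod
    def asymptotic(cls, alpha, k: int) -> "BaselineSpec":
        one = 1 if isinstance(alpha, Fraction) else 1.0
        return cls(
            k=k,
            b_A=asymptotic_baseline_vector(alpha, k),
            b_B=asymptotic_baseline_vector(one - alpha, k),
            kind="asymptotic",
            params=(alpha,),
        )

    def side(self, which: str) -> tuple:
        if which not in ("A", "B"):
            raise ValueError("side must be 'A' or 'B'")
        return self.b_A if which == "A" else self.b_B

    @property
    def is_rational(self) -> bool:
        return all(isinstance(b, (Fraction, int)) for b in (*self.b_A, *self.b_B))


@dataclass(frozen=True)
class AffinityProfile:
    """Affinity vs baseline for one class: h_t, b_t, ratio h_t/b_t, bias f_t.

    The normalized bias

        f_t = (h_t - b_t)/(1 - b_t)  if h_t >= b_t, else (h_t - b_t)/b_t

    lies in [-1, 1]; its sign matches sign(h_t - b_t) and |f_t| measures how
    close the deviation comes to its maximum possible magnitude.  Entries with
    undefined affinity or a degenerate baseline (b_t in {0, 1} where needed)
    are ``None``.
    """

    class_label: str
    k: int
    h: tuple
    b: tuple
    ratio: tuple
    bias: tuple
    D_t: tuple | None = None

    @property
    def defined(self) -> tuple:
        return tuple(h is not None and r is not None for h, r in zip(self.h, self.ratio))

    def ratio_at(self, t: int):
        return self.ratio[t - 1]

    def h_at(self, t: int):
        return self.h[t - 1]

    def b_at(self, t: int):
        return self.b[t - 1]


def _normalized_bias(h, b):
    if h >= b:
        return (h - b) / (1 - b) if b != 1 else None
    return (h - b) / b


def assemble_profile(
    scores: ScoreVector,
    baselines: BaselineSpec,
    side: str | None = None,
    D_t: tuple | None = None,
) -> AffinityProfile:
    """Combine affinity scores with baselines into ratio and bias profiles.

    ``side`` selects which baseline vector applies ('A' for the focus class,
    'B' for the out class); defaults to 'A'.
    """
    if baselines.k != scores.k:
        raise ValueError(f"baseline k={baselines.k} does not match score k={scores.k}")
    b = baselines.side(side or "A")
    h = scores.values
    ratio, bias = [], []
    for ht, bt in zip(h, b):
        if ht is None or bt == 0:
            ratio.append(None)
            bias.append(None)
            continue
        ratio.append(ht / bt)
        bias.append(_normalized_bias(ht, bt))
    return AffinityProfile(
        class_label=scores.class_label, k=scores.k,
        h=tuple(h), b=tuple(b), ratio=tuple(ratio), bias=tuple(bias), D_t=D_t,
    )


@dataclass(frozen=True)
class RealizabilityResult:
    realizable: bool
    witness: tuple | None      # count proportions M_0..M_k when realizable
    reason: str = ""


def check_realizable(spec: BaselineSpec, rel_tol: float = 1e-9) -> RealizabilityResult:
    """Decide whether baseline vectors are attainable as affinity scores.

    Works on count *proportions*: the vectors are realizable iff some
    nonnegative, not-all-zero (M_0..M_k) satisfies b_t(A) = t M_t / sum_i i M_i
    and b_t(B) = t M_{k-t} / sum_i i M_{k-i} for every t.  The A-side equations
    pin down M_1..M_k up to scale; the B-side equation at t=k pins down M_0;
    the remaining B-side equations are then consistency checks.  Rational
    inputs are checked exactly, floats to relative tolerance ``rel_tol``.
    Repeated hyperedges are implicitly allowed (the witness is a proportion
    vector, not an integer count vector).
    """
    k = spec.k
    for b in (*spec.b_A, *spec.b_B):
        if b <= 0:
            raise ValueError("realizability is defined for strictly positive baseline vectors")
    exact = spec.is_rational

    def close(x, y):
        if exact:
            return x == y
        return abs(x - y) <= rel_tol * max(1.0, abs(x), abs(y))

    # Affinity vectors always sum to 1, so each baseline vector must as well.
    if not close(sum(spec.b_A), 1):
        return RealizabilityResult(False, None, "b(A) does not sum to 1")
    if not close(sum(spec.b_B), 1):
        return RealizabilityResult(False, None, "b(B) does not sum to 1")
    # A-side inversion with D_A normalized to 1: M_t = b_t(A)/t for t >= 1.
    if exact:
        M = [Fraction(0)] + [Fraction(spec.b_A[t - 1]) / t for t in range(1, k + 1)]
    else:
        M = [0.0] + [spec.b_A[t - 1] / t for t in range(1, k + 1)]
    # B-side at t=k: b_k(B) = k M_0 / D_B with D_B = k M_0 + C.
    C = sum((k - j) * M[j] for j in range(1, k))
    bkB = spec.b_B[k - 1]
    if bkB >= 1:
        return RealizabilityResult(False, None, "b_k(B) >= 1 leaves no room for other types")
    M[0] = bkB * C / (k * (1 - bkB))
    D_B = sum((k - j) * M[j] for j in range(k + 1))
    if D_B <= 0:
        return RealizabilityResult(False, None, "out-class degree vanishes")

    for t in range(1, k + 1):
        implied = t * M[k - t] / D_B
        if not close(implied, spec.b_B[t - 1]):
            return RealizabilityResult(
                False, None,
                f"A-side witness implies b_{t}(B) = {float(implied):.6g}, "
                f"spec has {float(spec.b_B[t - 1]):.6g}",
            )
    return RealizabilityResult(True, tuple(M), "")
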