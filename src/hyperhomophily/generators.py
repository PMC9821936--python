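"""Synthetic hypergraph and count-vector generators.

These double as null models and as oracles for the impossibility results:

* :func:`complete_uniform` — the complete two-class k-uniform hypergraph,
  whose affinities equal the exact baseline scores;
* :func:`random_uniform` — the Erdos-Renyi-style k-uniform null model (each
  k-tuple a hyperedge with probability p), whose ratio scores converge to 1;
* :func:`even_monotonic_witness` — the even-k construction (complete minus
  the balanced middle type, extremes boosted by 1+epsilon) on which both
  classes satisfy strict monotonic homophily;
* :func:`planted_counts` — a hypergraph realizing a prescribed type-count
  vector exactly;
* :func:`enumerate_counts` — exhaustive small-instance oracle.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations, cycle, product
from math import comb
from collections.abc import Iterator

import numpy as np

from .core import LabeledHypergraph, TwoClassUniformView

__all__ = [
    "complete_uniform",
    "random_uniform",
    "even_monotonic_witness",
    "planted_counts",
    "enumerate_counts",
]


def complete_uniform(n_A: int, n_B: int, k: int) -> TwoClassUniformView:
    """Type counts of the complete k-uniform hypergraph: M_j = C(n_A,j) C(n_B,k-j)."""
    if k < 2 or k > n_A + n_B:
        raise ValueError(f"need 2 <= k <= n_A+n_B, got k={k}, n_A={n_A}, n_B={n_B}")
    if n_A < 0 or n_B < 0:
        raise ValueError("class sizes must be nonnegative")
    m = tuple(comb(n_A, j) * comb(n_B, k - j) for j in range(k + 1))
    return TwoClassUniformView(k=k, m=m, focus="A", out_label="B", n_A=n_A, n_B=n_B)


def random_uniform(
    n: int,
    k: int,
    p: float | None = None,
    m: int | None = None,
    alpha: float = 0.5,
    seed: int | None = None,
) -> LabeledHypergraph:
    """Uniform random k-uniform hypergraph with distinct hyperedges.

    The first ``floor(alpha*n)`` nodes are class ``A``, the rest ``B``
    (label assignment is deterministic; only the edge set is random).  When
    ``p`` is given, the number of edges is drawn Binomial(C(n,k), p) and that
    many distinct k-subsets are sampled uniformly — distributionally
    equivalent to flipping a p-coin per k-tuple, without enumerating tuples.
    """
    if (p is None) == (m is None):
        raise ValueError("give exactly one of p or m")
    total = comb(n, k)
    rng = np.random.default_rng(seed)
    if p is not None:
        if not (0 < p < 1):
            raise ValueError("p must be in (0, 1)")
        m = int(rng.binomial(total, p))
    if m > total:
        raise ValueError(f"requested {m} edges but only C({n},{k})={total} distinct k-subsets exist")
    width = len(str(n - 1))
    ids = [f"v{i:0{width}d}" for i in range(n)]
    n_a = int(alpha * n)
    labels = {ids[i]: ("A" if i < n_a else "B") for i in range(n)}
    # Rejection-sample distinct sorted k-tuples: uniform without replacement.
    chosen: dict[tuple, None] = {}
    while len(chosen) < m:
        batch = max(4 * (m - len(chosen)), 64)
        cand = rng.integers(0, n, size=(batch, k))
        for row in cand:
            s = np.unique(row)
            if len(s) != k:
                continue
            key = tuple(int(i) for i in s)
            if key not in chosen:
                chosen[key] = None
                if len(chosen) == m:
                    break
    edges = {frozenset(ids[i] for i in key): 1 for key in chosen}
    return LabeledHypergraph(class_of=labels, edges=edges)


def even_monotonic_witness(n_A: int, n_B: int, k: int, epsilon=0) -> TwoClassUniformView:
    """Even-k counts on which both classes can be strictly monotonically homophilous.

    Starts from the complete hypergraph, deletes every balanced (type-k/2)
    hyperedge, and inflates the two homogeneous extremes by a factor
    1 + epsilon.  With epsilon = 0 the two top ratio scores of each class tie,
    so *strict* monotonicity fails; any epsilon > 0 breaks the tie in favor of
    homophily.  epsilon is taken as a rational so counts stay integral.
    """
    if k % 2 != 0:
        raise ValueError("this construction needs even k")
    eps = Fraction(epsilon).limit_denominator(10**6)
    if eps < 0:
        raise ValueError("epsilon must be >= 0")
    base = complete_uniform(n_A, n_B, k)
    # 1 + eps = (q + p)/q; scale every count by q so the vector stays integral
    q, p_num = eps.denominator, eps.numerator
    boost = q + p_num
    m = [q * c for c in base.m]
    m[k // 2] = 0
    m[0] = boost * base.m[0]
    m[k] = boost * base.m[k]
    return TwoClassUniformView(k=k, m=tuple(m), focus="A", out_label="B", n_A=n_A, n_B=n_B)


def planted_counts(
    target_m,
    n_A: int,
    n_B: int,
    seed: int | None = None,
    allow_multiplicity: bool = True,
) -> LabeledHypergraph:
    """A two-class hypergraph whose type counts equal ``target_m`` exactly.

    For each type j, hyperedges combine j nodes of class A with k-j of class
    B.  In simple mode each combination may be used once, so m_j may not
    exceed C(n_A, j) * C(n_B, k-j); with multiplicity the combinations are
    reused cyclically.  ``seed`` shuffles which combinations are picked.
    """
    target_m = tuple(int(c) for c in target_m)
    k = len(target_m) - 1
    if k < 2:
        raise ValueError("target vector must cover types 0..k with k >= 2")
    if any(c < 0 for c in target_m):
        raise ValueError("target counts must be nonnegative")
    a_ids = [f"a{i}" for i in range(n_A)]
    b_ids = [f"b{i}" for i in range(n_B)]
    labels = {v: "A" for v in a_ids} | {v: "B" for v in b_ids}
    rng = np.random.default_rng(seed) if seed is not None else None
    edges: dict[frozenset, int] = {}
    for j, count in enumerate(target_m):
        if count == 0:
            continue
        cap = comb(n_A, j) * comb(n_B, k - j)
        if not allow_multiplicity and count > cap:
            raise ValueError(
                f"m_{j}={count} exceeds the {cap} distinct type-{j} hyperedges "
                f"available with n_A={n_A}, n_B={n_B}, k={k}"
            )
        if cap == 0:
            raise ValueError(f"no type-{j} hyperedge exists with n_A={n_A}, n_B={n_B}, k={k}")
        combos = [a + b for a, b in product(combinations(a_ids, j), combinations(b_ids, k - j))]
        if rng is not None:
            rng.shuffle(combos)
        for _, combo in zip(range(count), cycle(combos)):
            fs = frozenset(combo)
            edges[fs] = edges.get(fs, 0) + 1
    return LabeledHypergraph(class_of=labels, edges=edges)


def enumerate_counts(k: int, max_total: int, guard: int = 2_000_000) -> Iterator[TwoClassUniformView]:
    """Every nonzero count vector (m_0..m_k) with sum <= max_total.

    A brute-force oracle for the impossibility theorems on small instances;
    guarded against accidental combinatorial explosion.
    """
    n_vectors = comb(max_total + k + 1, k + 1)
    if n_vectors > guard:
        raise ValueError(f"{n_vectors} vectors exceed the enumeration guard of {guard}")

    def rec(prefix: list, remaining: int, slots: int):
        if slots == 0:
            if any(prefix):
                yield TwoClassUniformView(k=k, m=tuple(prefix), focus="A", out_label="B")
            return
        for c in range(remaining + 1):
            yield from rec(prefix + [c], remaining - c, slots - 1)

    yield from rec([], max_total, k + 1)
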