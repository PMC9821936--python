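"""Affinity scores for class-labeled hypergraphs.

The type-t affinity of class X at group size k,

    h_t(X) = D_t(X) / D(X),

is the fraction of class-X group memberships that occur in groups with exactly
t same-class members.  At k = t = 2 it reduces to the classical graph
homophily index (fraction of same-class links).  Equivalently, in terms of the
type counts m_j of a two-class view,

    h_t(A) = t m_t / sum_i i m_i,      h_t(B) = t m_{k-t} / sum_i i m_{k-i}.

An alternative, hyperedge-proportion-based score is also provided:

    h~_t(A) = m_t / sum_{i=1..k} m_i   (and mirrored for B),

which weights each group once rather than once per member.

Scores over integer count data are computed in exact rational arithmetic
(:class:`fractions.Fraction`), so downstream strict-inequality logic is exact.
Zero denominators yield explicitly *undefined* entries (``None``), never 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .core import LabeledHypergraph, DegreeTable, TwoClassUniformView, clique_expansion, typed_degrees, type_counts

__all__ = [
    "ScoreVector",
    "SubsampleResult",
    "affinity_scores",
    "affinity_from_counts",
    "alt_affinity_from_counts",
    "graph_homophily_index",
    "subsample_scores",
]


@dataclass(frozen=True)
class ScoreVector:
    """Per-type scores s_1..s_k for one class; ``None`` marks undefined entries."""

    class_label: str
    k: int
    values: tuple
    variant: str = "degree-affinity"

    def __post_init__(self):
        if len(self.values) != self.k:
            raise ValueError("score vector must have one entry per t in 1..k")

    @property
    def defined(self) -> tuple:
        return tuple(v is not None for v in self.values)

    @property
    def all_defined(self) -> bool:
        return all(v is not None for v in self.values)

    def __getitem__(self, t: int):
        """Score for type t (1-based)."""
        return self.values[t - 1]

    def as_floats(self) -> np.ndarray:
        return np.array([np.nan if v is None else float(v) for v in self.values])


def _undefined(label: str, k: int, variant: str) -> ScoreVector:
    return ScoreVector(class_label=label, k=k, values=(None,) * k, variant=variant)


def affinity_scores(degrees: DegreeTable, class_label: str) -> ScoreVector:
    """Degree-based affinities h_t(X) = D_t(X)/D(X); undefined when D(X)=0."""
    D = degrees.D(class_label)
    if D == 0:
        return _undefined(class_label, degrees.k, "degree-affinity")
    values = tuple(Fraction(degrees.D_t(class_label, t), D) for t in range(1, degrees.k + 1))
    return ScoreVector(class_label=class_label, k=degrees.k, values=values)


def _counts_for_side(view: TwoClassUniformView, class_label: str) -> tuple:
    """Counts seen from ``class_label``'s side: m for focus, reversed for out."""
    if class_label == view.focus:
        return tuple(view.m)
    if class_label == view.out_label:
        return tuple(reversed(view.m))
    raise ValueError(
        f"class {class_label!r} is neither the focus ({view.focus!r}) nor the out class ({view.out_label!r})"
    )


def affinity_from_counts(view: TwoClassUniformView, class_label: str) -> ScoreVector:
    """Count-based affinities, identical to the degree-based form on the same data."""
    m = _counts_for_side(view, class_label)
    denom = sum(i * m[i] for i in range(1, view.k + 1))
    if denom == 0:
        return _undefined(class_label, view.k, "degree-affinity")
    values = tuple(Fraction(t * m[t], denom) for t in range(1, view.k + 1))
    return ScoreVector(class_label=class_label, k=view.k, values=values)


def alt_affinity_from_counts(view: TwoClassUniformView, class_label: str) -> ScoreVector:
    """Hyperedge-proportion affinities h~_t; the type-0 count is excluded."""
    m = _counts_for_side(view, class_label)
    denom = sum(m[1:])
    if denom == 0:
        return _undefined(class_label, view.k, "alt-affinity")
    values = tuple(Fraction(m[t], denom) for t in range(1, view.k + 1))
    return ScoreVector(class_label=class_label, k=view.k, values=values, variant="alt-affinity")


def graph_homophily_index(H: LabeledHypergraph, class_label: str):
    """Graph homophily index of X: type-2 affinity on the clique expansion.

    Returns an exact :class:`~fractions.Fraction`, or ``None`` when class X
    has no incident edges after expansion.
    """
    G = clique_expansion(H)
    scores = affinity_scores(typed_degrees(G, 2), class_label)
    return scores[2] if scores.all_defined else None


@dataclass(frozen=True)
class SubsampleResult:
    """Mean and spread of affinity scores over hyperedge subsamples."""

    class_label: str
    k: int
    fraction: float
    replicates: int
    mean: np.ndarray          # nan where undefined in every replicate
    std: np.ndarray
    n_undefined: np.ndarray   # per-t count of undefined replicate entries
    per_replicate: np.ndarray  # shape (replicates, k), nan = undefined


def subsample_scores(
    H: LabeledHypergraph,
    k: int,
    class_label: str,
    fraction: float = 0.8,
    replicates: int = 100,
    seed: int | None = None,
) -> SubsampleResult:
    """Affinity scores under repeated uniform hyperedge subsampling.

    Each replicate retains ``round(fraction * M)`` of the M size-``k``
    hyperedges (sampled without replacement at the hyperedge level, repeated
    copies treated as distinct) and recomputes h_t for ``class_label``.
    A replicate in which the class degree vanishes is flagged undefined (NaN)
    for that replicate.  Reproducible given ``seed``.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    edges = [e for e, mult in sorted(H.edges.items(), key=lambda kv: tuple(sorted(kv[0]))) if len(e) == k
             for _ in range(mult)]
    M = len(edges)
    n_keep = max(1, round(fraction * M)) if M else 0
    rng = np.random.default_rng(seed)
    out = np.full((replicates, k), np.nan)
    focus = class_label
    for rep in range(replicates):
        if fraction == 1.0:
            chosen = edges
        else:
            idx = rng.choice(M, size=n_keep, replace=False)
            chosen = [edges[i] for i in idx]
        denom = 0
        num = [0] * (k + 1)
        for e in chosen:
            j = sum(1 for v in e if H.class_of[v] == focus)
            num[j] += 1
        # count-based affinity for the focus side
        denom = sum(i * num[i] for i in range(1, k + 1))
        if denom > 0:
            out[rep] = [t * num[t] / denom for t in range(1, k + 1)]
    mean = np.nanmean(out, axis=0) if len(out) else np.full(k, np.nan)
    std = np.nanstd(out, axis=0) if len(out) else np.full(k, np.nan)
    return SubsampleResult(
        class_label=class_label, k=k, fraction=fraction, replicates=replicates,
        mean=mean, std=std, n_undefined=np.isnan(out).sum(axis=0), per_replicate=out,
    )
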