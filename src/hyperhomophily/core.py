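"""Hypergraph data model and typed-degree accounting.

A hypergraph ``H = (V, E)`` models group interactions: each hyperedge is a set
of node identifiers of size >= 2, and every node carries a class label (e.g. a
gender, a political party, a product category).  All homophily measures in this
package are driven by two families of statistics computed here:

* typed degrees ``d_t(v)`` — the number of size-``k`` groups containing ``v``
  in which exactly ``t`` members (including ``v``) share ``v``'s class; and
* type counts ``m_j`` — the number of size-``k`` groups containing exactly
  ``j`` members of a designated focus class ``A``.

Repeated identical groups are kept as integer multiplicities; they contribute
to degrees and counts once per repetition.
"""

from __future__ import annotations

import itertools
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

__all__ = [
    "LabeledHypergraph",
    "TwoClassUniformView",
    "DegreeTable",
    "validate_and_build",
    "typed_degrees",
    "type_counts",
    "k_slices",
    "clique_expansion",
]

OUT_LABEL = "rest"


@dataclass(frozen=True)
class LabeledHypergraph:
    """A class-labeled hypergraph with hyperedge multiplicities.

    Attributes
    ----------
    class_of
        Mapping from node identifier to class label.  Every node that occurs
        in a hyperedge must appear here.
    edges
        Mapping from hyperedge (a frozenset of node ids, size >= 2) to its
        positive integer multiplicity.
    """

    class_of: Mapping[str, str]
    edges: Mapping[frozenset, int]

    @property
    def node_ids(self) -> tuple:
        return tuple(sorted(self.class_of))

    @property
    def num_edges(self) -> int:
        """Total number of hyperedges, counted with multiplicity."""
        return sum(self.edges.values())

    def classes(self) -> tuple:
        return tuple(sorted(set(self.class_of.values())))

    def class_members(self, label: str) -> tuple:
        return tuple(sorted(v for v, c in self.class_of.items() if c == label))

    def edge_sizes(self) -> tuple:
        return tuple(sorted({len(e) for e in self.edges}))


@dataclass(frozen=True)
class TwoClassUniformView:
    """Per-size composition summary of a two-class k-uniform (sub)hypergraph.

    ``m[j]`` is the number of size-``k`` hyperedges containing exactly ``j``
    members of the focus class ``A`` (all other labels collapsed to an out
    class ``B``), counted with multiplicity.  Class sizes may be ``None`` when
    the view comes from an anonymous composition table.
    """

    k: int
    m: tuple
    focus: str = "A"
    out_label: str = OUT_LABEL
    n_A: int | None = None
    n_B: int | None = None

    def __post_init__(self):
        if self.k < 2:
            raise ValueError(f"group size k must be >= 2, got {self.k}")
        if len(self.m) != self.k + 1:
            raise ValueError(f"type-count vector must have length k+1={self.k + 1}, got {len(self.m)}")
        if any(c < 0 for c in self.m):
            raise ValueError("type counts must be nonnegative")

    @property
    def total(self) -> int:
        return sum(self.m)

    def degree_sum(self, side: str = "A") -> int:
        """Class membership-weighted count: D(A) = sum_j j*m_j, D(B) mirrored."""
        if side == "A":
            return sum(j * c for j, c in enumerate(self.m))
        return sum((self.k - j) * c for j, c in enumerate(self.m))

    def swapped(self) -> "TwoClassUniformView":
        """The view with the two classes exchanged (m_j <-> m_{k-j})."""
        return TwoClassUniformView(
            k=self.k, m=tuple(reversed(self.m)), focus=self.out_label,
            out_label=self.focus, n_A=self.n_B, n_B=self.n_A,
        )


@dataclass(frozen=True)
class DegreeTable:
    """Total and typed degrees for the size-k slice of a hypergraph.

    ``typed[v][t-1]`` is d_t(v) for t in 1..k; class aggregates are sums over
    class members: D(X) and D_t(X).
    """

    k: int
    degree: Mapping[str, int]
    typed: Mapping[str, tuple]
    class_degree: Mapping[str, int] = field(default_factory=dict)
    class_typed: Mapping[str, tuple] = field(default_factory=dict)

    def d(self, v: str) -> int:
        return self.degree.get(v, 0)

    def d_t(self, v: str, t: int) -> int:
        return self.typed[v][t - 1]

    def D(self, label: str) -> int:
        return self.class_degree.get(label, 0)

    def D_t(self, label: str, t: int) -> int:
        return self.class_typed.get(label, (0,) * self.k)[t - 1]


def validate_and_build(
    nodes: Iterable[str],
    labels: Mapping[str, str],
    edges: Iterable[Sequence[str]],
) -> LabeledHypergraph:
    """Validate raw input and build a normalized :class:`LabeledHypergraph`.

    Repeated identical edges accumulate multiplicity.  Raises ``ValueError``
    for an edge of size < 2, a duplicated node within an edge, or a node used
    in an edge without a class label.
    """
    node_set = set(nodes) | set(labels)
    edge_mult: dict[frozenset, int] = {}
    for idx, edge in enumerate(edges):
        members = list(edge)
        if len(members) < 2:
            raise ValueError(f"edge #{idx} has fewer than 2 nodes: {members!r}")
        fs = frozenset(members)
        if len(fs) != len(members):
            raise ValueError(f"edge #{idx} repeats a node: {sorted(members)!r}")
        for v in members:
            if v not in labels:
                raise ValueError(f"node {v!r} in edge #{idx} has no class label")
        node_set.update(members)
        edge_mult[fs] = edge_mult.get(fs, 0) + 1
    unlabeled = node_set - set(labels)
    if unlabeled:
        raise ValueError(f"nodes without class labels: {sorted(unlabeled)!r}")
    return LabeledHypergraph(class_of=dict(labels), edges=edge_mult)


def typed_degrees(H: LabeledHypergraph, k: int) -> DegreeTable:
    """Typed degrees over the size-``k`` hyperedges of ``H``.

    ``d_t(v)`` counts (with multiplicity) size-k hyperedges containing ``v``
    with exactly ``t`` members of ``v``'s class, ``v`` included.  Nodes in no
    size-k hyperedge get zero rows.
    """
    degree = {v: 0 for v in H.class_of}
    typed = {v: [0] * k for v in H.class_of}
    for edge, mult in H.edges.items():
        if len(edge) != k:
            continue
        label_count: dict[str, int] = {}
        for v in edge:
            lab = H.class_of[v]
            label_count[lab] = label_count.get(lab, 0) + 1
        for v in edge:
            t = label_count[H.class_of[v]]
            degree[v] += mult
            typed[v][t - 1] += mult
    class_degree: dict[str, int] = {}
    class_typed: dict[str, list] = {}
    for v, lab in H.class_of.items():
        class_degree[lab] = class_degree.get(lab, 0) + degree[v]
        row = class_typed.setdefault(lab, [0] * k)
        for i in range(k):
            row[i] += typed[v][i]
    return DegreeTable(
        k=k,
        degree=degree,
        typed={v: tuple(row) for v, row in typed.items()},
        class_degree=class_degree,
        class_typed={lab: tuple(row) for lab, row in class_typed.items()},
    )


def type_counts(H: LabeledHypergraph, k: int, focus_class: str) -> TwoClassUniformView:
    """Type-count vector m_0..m_k of the size-``k`` slice for a focus class.

    Any label other than ``focus_class`` is collapsed into a single out class.
    """
    m = [0] * (k + 1)
    for edge, mult in H.edges.items():
        if len(edge) != k:
            continue
        j = sum(1 for v in edge if H.class_of[v] == focus_class)
        m[j] += mult
    n_A = sum(1 for c in H.class_of.values() if c == focus_class)
    others = set(H.class_of.values()) - {focus_class}
    out_label = next(iter(others)) if len(others) == 1 else OUT_LABEL
    return TwoClassUniformView(
        k=k, m=tuple(m), focus=focus_class, out_label=out_label,
        n_A=n_A, n_B=len(H.class_of) - n_A,
    )


def k_slices(H: LabeledHypergraph, focus_class: str) -> list:
    """One :class:`TwoClassUniformView` per distinct hyperedge size, ascending."""
    return [type_counts(H, k, focus_class) for k in H.edge_sizes()]


def clique_expansion(H: LabeledHypergraph) -> LabeledHypergraph:
    """The simple graph (2-uniform hypergraph) linking every co-occurring pair.

    Nodes u, v are adjacent iff they appear together in at least one
    hyperedge; multiplicities are not carried over.
    """
    pair_edges: dict[frozenset, int] = {}
    for edge in H.edges:
        for u, v in itertools.combinations(sorted(edge), 2):
            pair_edges[frozenset((u, v))] = 1
    return LabeledHypergraph(class_of=dict(H.class_of), edges=pair_edges)
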