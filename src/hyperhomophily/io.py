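"""Readers and writers for the package's plain-text formats.

* hyperedge list — one group per line, node ids separated by commas or
  whitespace; ``#`` starts a comment; repeated identical lines accumulate
  multiplicity;
* label table — two-column TSV ``node_id<TAB>class``;
* composition table — three-column TSV ``k<TAB>j<TAB>count`` giving, per group
  size k, the number of groups with exactly j focus-class members (usable when
  individuals are anonymous and only group compositions are known);
* score table — CSV with columns k, class, t, D_t, h_t, b_t, ratio, bias,
  defined.
"""

from __future__ import annotations

import csv
from pathlib import Path

from .baselines import AffinityProfile
from .core import LabeledHypergraph, TwoClassUniformView, validate_and_build

__all__ = [
    "read_hypergraph",
    "write_hypergraph",
    "read_composition_table",
    "write_profiles_csv",
    "read_profiles_csv",
]

SCORE_COLUMNS = ["k", "class", "t", "D_t", "h_t", "b_t", "ratio", "bias", "defined"]


def _split_edge_line(line: str) -> list:
    body = line.split("#", 1)[0].strip()
    if not body:
        return []
    sep = "," if "," in body else None
    return [tok.strip() for tok in body.split(sep) if tok.strip()]


def read_hypergraph(edges_path, labels_path) -> LabeledHypergraph:
    """Load and validate a hypergraph from an edge list and a label TSV."""
    labels: dict[str, str] = {}
    for lineno, raw in enumerate(Path(labels_path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 2:
            raise ValueError(f"{labels_path}:{lineno}: expected 'node<TAB>class', got {raw!r}")
        node, cls = parts
        if node in labels and labels[node] != cls:
            raise ValueError(
                f"{labels_path}:{lineno}: node {node!r} relabeled {labels[node]!r} -> {cls!r}"
            )
        labels[node] = cls
    edges = []
    for lineno, raw in enumerate(Path(edges_path).read_text().splitlines(), start=1):
        members = _split_edge_line(raw)
        if not members:
            continue
        if len(members) < 2:
            raise ValueError(f"{edges_path}:{lineno}: a group needs at least 2 nodes, got {raw!r}")
        if len(set(members)) != len(members):
            raise ValueError(f"{edges_path}:{lineno}: node repeated within a group: {raw!r}")
        for v in members:
            if v not in labels:
                raise ValueError(f"{edges_path}:{lineno}: node {v!r} has no label in {labels_path}")
        edges.append(members)
    return validate_and_build([], labels, edges)


def write_hypergraph(H: LabeledHypergraph, edges_path, labels_path) -> None:
    """Serialize a hypergraph; repeated multiplicities become repeated lines."""
    lines = []
    for edge in sorted(H.edges, key=lambda e: tuple(sorted(e))):
        line = ",".join(sorted(edge))
        lines.extend([line] * H.edges[edge])
    Path(edges_path).write_text("\n".join(lines) + ("\n" if lines else ""))
    rows = [f"{v}\t{c}" for v, c in sorted(H.class_of.items())]
    Path(labels_path).write_text("\n".join(rows) + ("\n" if rows else ""))


def read_composition_table(path, focus: str = "A", out_label: str = "rest") -> list:
    """Views from a (k, j, count) TSV; one view per distinct k, ascending.

    Class sizes are unknown here (anonymous data), so exact baselines need
    them supplied separately; asymptotic baselines work directly.
    """
    per_k: dict[int, dict[int, int]] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split("\t") if "\t" in line else line.split()
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 'k<TAB>j<TAB>count', got {raw!r}")
        try:
            k, j, count = (int(p) for p in parts)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-integer field in {raw!r}") from exc
        if j < 0 or j > k:
            raise ValueError(f"{path}:{lineno}: type j={j} outside 0..k={k}")
        if count < 0:
            raise ValueError(f"{path}:{lineno}: negative count {count}")
        per_k.setdefault(k, {})[j] = per_k.setdefault(k, {}).get(j, 0) + count
    views = []
    for k in sorted(per_k):
        m = tuple(per_k[k].get(j, 0) for j in range(k + 1))
        views.append(TwoClassUniformView(k=k, m=m, focus=focus, out_label=out_label))
    return views


def write_profiles_csv(profiles: list[AffinityProfile], path) -> None:
    """One row per (class, t); floats at full precision, blanks for undefined."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(SCORE_COLUMNS)
        for prof in profiles:
            for t in range(1, prof.k + 1):
                h, b = prof.h_at(t), prof.b_at(t)
                ratio, bias = prof.ratio[t - 1], prof.bias[t - 1]
                d_t = prof.D_t[t - 1] if prof.D_t is not None else ""
                defined = h is not None and ratio is not None
                writer.writerow([
                    prof.k, prof.class_label, t, d_t,
                    "" if h is None else repr(float(h)),
                    repr(float(b)),
                    "" if ratio is None else repr(float(ratio)),
                    "" if bias is None else repr(float(bias)),
                    int(defined),
                ])


def read_profiles_csv(path) -> list[dict]:
    """Parse a score table back into row dicts (floats where defined)."""
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            parsed = {
                "k": int(row["k"]), "class": row["class"], "t": int(row["t"]),
                "defined": bool(int(row["defined"])),
            }
            for col in ("D_t", "h_t", "b_t", "ratio", "bias"):
                parsed[col] = float(row[col]) if row[col] != "" else None
            out.append(parsed)
    return out
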