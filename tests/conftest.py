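import pytest

from hyperhomophily import validate_and_build

T1_LABELS = {f"a{i}": "A" for i in range(1, 4)} | {f"b{i}": "B" for i in range(1, 4)}
T1_EDGES = [
    ["a1", "a2", "a3"],
    ["a1", "a2", "b1"],
    ["a1", "b1", "b2"],
    ["b1", "b2", "b3"],
]


@pytest.fixture
def t1():
    """Six-node, four-edge 3-uniform toy hypergraph with balanced classes."""
    return validate_and_build([], T1_LABELS, T1_EDGES)


@pytest.fixture
def t1_files(tmp_path):
    """The same toy hypergraph serialized to an edge list and a label TSV."""
    edges = tmp_path / "edges.txt"
    labels = tmp_path / "labels.tsv"
    edges.write_text("".join(",".join(e) + "\n" for e in T1_EDGES))
    labels.write_text("".join(f"{v}\t{c}\n" for v, c in sorted(T1_LABELS.items())))
    return edges, labels
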