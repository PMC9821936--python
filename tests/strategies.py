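"""Shared hypothesis strategies."""

from hypothesis import strategies as st

from hyperhomophily import validate_and_build


def small_hypergraphs(max_nodes=7, max_edges=8, min_size=2, max_size=4):
    """Strategy: random two-class labeled hypergraphs over nodes v0..v{n-1}."""
    @st.composite
    def build(draw):
        n = draw(st.integers(3, max_nodes))
        ids = [f"v{i}" for i in range(n)]
        labels = {v: draw(st.sampled_from(["A", "B"])) for v in ids}
        n_edges = draw(st.integers(1, max_edges))
        edges = [
            sorted(draw(st.sets(st.sampled_from(ids), min_size=min_size,
                                max_size=min(max_size, n))))
            for _ in range(n_edges)
        ]
        return validate_and_build(ids, labels, edges)
    return build()
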