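"""Homophily from anonymous group compositions (no individual identifiers).

Affinity scores only need the size and class composition of each group, so a
(k, j, count) table suffices — e.g. gender counts in group photographs.  The
composition null also explains classic patterns: among two-child families the
split is 50% mixed / 25% two boys / 25% two girls.
"""

import tempfile
from pathlib import Path

from hyperhomophily import (
    BaselineSpec,
    affinity_from_counts,
    assemble_profile,
    composition_null,
    read_composition_table,
)

# four-person groups: mixed pairs slightly overexpressed, homogeneous groups
# strongly overexpressed (the wedding/group-photo pattern)
table = "4\t0\t30\n4\t1\t20\n4\t2\t45\n4\t3\t20\n4\t4\t30\n"
with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "compositions.tsv"
    path.write_text(table)
    (view,) = read_composition_table(path, focus="women", out_label="men")

spec = BaselineSpec.asymptotic(0.5, 4)
print("four-person groups, counts by number of women:", view.m)
for side, label in (("A", "women"), ("B", "men")):
    prof = assemble_profile(affinity_from_counts(view, label), spec, side)
    ratios = "  ".join(f"t={t}:{float(prof.ratio_at(t)):.2f}" for t in range(1, 5))
    print(f"  ratio scores ({label}): {ratios}")

pmf = composition_null(0.5, 2)
print("\ntwo-child composition null:",
      f"{100 * pmf[1]:.0f}% mixed, {100 * pmf[2]:.0f}% both in class, {100 * pmf[0]:.0f}% neither")
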