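"""Which strict homophily notions can two classes exhibit at once?

Solves the margin LP over type proportions x_0..x_k: the optimum gamma* is
positive iff some hypergraph satisfies every strict inequality of the notion
simultaneously for both classes.
"""

from hyperhomophily import BaselineSpec, build_program, dropped_constraint_witness, solve_program

print("strict MAJORITY homophily, both classes at once:")
for k in (3, 4, 5, 6):
    spec = BaselineSpec.asymptotic(0.5, k)
    sol = solve_program(build_program(k, spec))
    print(f"  k={k}: gamma*={sol.gamma:.4f} -> {'feasible' if sol.feasible else 'impossible'}")

print("\nstrict MONOTONIC homophily (strictly increasing top ratio scores):")
for k in (3, 4, 5, 6):
    spec = BaselineSpec.asymptotic(0.5, k)
    sol = solve_program(build_program(k, spec, mode="monotonic"))
    aug = solve_program(build_program(k, spec, mode="monotonic", augment="A")) if k % 2 == 0 else None
    note = f", with middle t=k/2 condition: gamma*={aug.gamma:.4f}" if aug else ""
    print(f"  k={k}: gamma*={sol.gamma:.4f} -> {'feasible' if sol.feasible else 'impossible'}{note}")

# Odd group sizes: both notions are combinatorially impossible (gamma* = 0).
# Even sizes: possible, but adding the middle strict-increase (or
# above-baseline) condition at t = k/2 for either class restores impossibility.

print("\ndropping one majority inequality opens the region (k=3, balanced):")
spec = BaselineSpec.exact(20, 10, 3)
for drop in [("A", 2), ("A", 3), ("B", 2), ("B", 3)]:
    w = dropped_constraint_witness(3, spec, drop)
    print(f"  drop {drop}: integer witness counts m={w.counts} (gamma*={w.gamma:.3f})")
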