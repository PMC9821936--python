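"""Impossibility certified by duality, not just by a solver.

For odd k there is a closed-form dual-feasible point with objective 0; by LP
duality it upper-bounds the primal margin, proving that two-class strict
majority homophily is impossible for *every* realizable baseline pair.  The
certificate is re-verified constraint by constraint before being returned.
"""

from hyperhomophily import BaselineSpec, odd_k_dual_certificate, solve_dual

for k, spec in [(3, BaselineSpec.exact(6, 3, 3)), (5, BaselineSpec.asymptotic(0.4, 5))]:
    cert = odd_k_dual_certificate(k, spec)
    dual = solve_dual(k, spec)
    print(f"k={k} ({spec.kind} baselines):")
    print(f"  solver dual optimum      : {dual.objective:.2e}")
    print(f"  analytic certificate     : objective {cert.objective}, "
          f"max constraint violation {cert.max_violation:.1e}")
    print(f"  normalization Y = {cert.Y:.6f} (= k^2)")
    ys = "  ".join(f"y_A,{t}={v:.3f}" for t, v in sorted(cert.y_A.items()))
    print(f"  {ys}")

# Both routes agree: the dual optimum is 0, so no hypergraph can give both
# classes above-baseline affinities for every majority group type.
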