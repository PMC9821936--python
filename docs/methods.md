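# Methods

## Model and statistics

A group-interaction dataset is modeled as a class-labeled hypergraph
H = (V, E): nodes are individuals with a class label, hyperedges are groups
(node sets of size ≥ 2) with integer multiplicities — repeated identical
groups are real observations and count once per repetition in every degree
and count. Analyses are per group size k: the size-k slice of H is
summarized either by typed degrees d_t(v) (groups containing v with exactly
t members of v's class, v included) or by the type-count vector m_0..m_k
(groups with exactly j members of a designated focus class A). Hypergraphs
with more than two labels are analyzed focus-vs-rest, collapsing all other
labels into a single out class.

The type-t affinity of class X is h_t(X) = D_t(X)/D(X), the fraction of the
class's memberships that are type-t; in count form h_t(A) = t·m_t/Σᵢ i·mᵢ
(the factor t because a type-t group contributes to t class-A memberships),
with the mirrored form for the out class. An alternative score
h̃_t(A) = m_t/Σ_{i≥1} m_i weights groups instead of memberships; note its
denominator excludes the groups with no class-A member (type 0), and the
mirrored out-class denominator excludes type k. Affinity vectors always sum
to 1 when defined.

Baselines are the uniform-recruitment null: b_t(X) is the probability a
class-X member's k−1 random co-members yield a type-t group — the
hypergeometric form for finite n, or its binomial limit at fixed class
proportion α. Both families sum to 1 over t, and the exact form equals the
affinity vector of the complete k-uniform hypergraph (verified in exact
arithmetic in the tests). Deviation from baseline is reported as the ratio
h_t/b_t and as the normalized bias f_t = (h_t−b_t)/(1−b_t) when h_t ≥ b_t,
(h_t−b_t)/b_t otherwise, which lies in [−1, 1].

The graph homophily index of class X is the type-2 affinity of the clique
expansion of H (the simple graph joining every co-occurring pair;
multiplicities and group sizes are deliberately discarded there, which is
exactly the information loss the hypergraph scores avoid).

## Homophily notions and indices

Simple homophily is h_k > b_k. Order-j majority homophily requires
h_t > b_t for the top j types; order-j monotonic homophily requires
h_t/b_t > h_{t−1}/b_{t−1} there. The strict notions are the
order-⌈k/2⌉ versions (all types where the class holds a majority). MaHI and
MoHI are the maximal such j. All comparisons are strict; ties break against
homophily, and an undefined entry (zero denominator) terminates an index.
MoHI is capped at k−1 since the order-k condition would need a type-0
ratio. Integer count data are scored with exact rationals
(`fractions.Fraction`), making strictness unambiguous; in floating-point
mode a > b means a − b > 1e−12·max(1, |a|, |b|).

## Realizability

Baseline vectors are *realizable* if strictly positive and attained as
affinity scores of some hypergraph. The check inverts the count-form
affinity map on proportions: the A-side equations force M_t ∝ b_t(A)/t for
t ≥ 1, the B-side equation at t = k fixes M_0, and the remaining B-side
equations are consistency conditions (exact equality for rational inputs,
relative 1e−9 otherwise). Witnesses are proportion vectors — repeated
hyperedges are implicitly allowed; integer feasibility against the
C(n_A, j)·C(n_B, k−j) caps is a separate concern handled by the planted
generator.

## The feasibility LP and its dual

Variables are type proportions x_0..x_k (simplex-constrained) and a shared
margin γ; each strict inequality of a homophily notion becomes a margin row
(majority: t·x_t − b_t(A)·Σ i·xᵢ ≥ γ and the B mirror, for t from
r = ⌈(k+1)/2⌉ to k; monotonic: the rearranged strict-increase form
t·x_t·b_{t−1}(A) − (t−1)·x_{t−1}·b_t(A) ≥ γ, equivalent up to positive
row scaling to the form in terms of witness counts). γ* > 0 iff a hypergraph
satisfies every inequality strictly (scale any positive-margin point); the
realizability witness itself attains γ = 0, so γ* ≥ 0 always. Options: drop
one named row (the relaxation behind the dropped-inequality witnesses), add
the middle t = k/2 row for one class (even k), or supply custom rows such as
ratio-threshold queries.

The dual is derived by Lagrangian duality: variables y_{A,t}, y_{B,t} ≥ 0
summing to 1 and a free scalar objective, with one constraint per hyperedge
type i:

    [i≥r]·i·y_{A,i} + [k−i≥r]·(k−i)·y_{B,k−i}
        ≤ i·Σ_t y_{A,t} b_t(A) + (k−i)·Σ_t y_{B,t} b_t(B) + objective.

Strong duality between the two independently solved programs is asserted to
1e−8 over a grid of k and α in the tests. For odd k the analytic certificate
sets δ = (2/k)·Σ_{t=r..k} 1/t,
y_{B,k} = (2/δ)·[Σ (k/i − 1)·b_i(B)] / [1 − Σ (2 − k/i)·b_i(B)],
y_{B,t} = (2/δ)(k/t − 1) + (2 − k/t)·y_{B,k}, and
y_{A,t} = 2k/(δt) − y_{B,t}; the pair sums y_{A,t}+y_{B,t} = 2k/(δt) give
the clean normalization Y = k². Because these closed forms are easy to
mistranscribe, the certificate routine re-verifies nonnegativity, the
normalization, and every dual constraint at objective 0 before returning,
and raises otherwise — an incorrect formula cannot be used silently.

Numerical choices: LPs are solved with HiGHS via `scipy.optimize.linprog`;
the feasibility verdict is γ* > 1e−8, and the γ* = 0 boundary for odd k is
additionally certified analytically rather than trusted to the solver.
Dropped-constraint witnesses rationalize the optimal vertex
(`Fraction.limit_denominator`, caps 10⁴ → 10⁶ → 10⁹), scale by the common
denominator to integers, and re-verify every remaining inequality strictly
in exact arithmetic, failing loudly if rounding breaks strictness.

## Generators and what they do (and do not) emulate

* `complete_uniform` — all C(n_A, j)·C(n_B, k−j) type-j groups; its
  affinities equal the exact baselines, anchoring the null.
* `random_uniform` — m distinct k-subsets chosen uniformly (when a
  per-tuple probability p is given, m ~ Binomial(C(n, k), p) first — the
  count-then-sample factorization of the per-tuple Bernoulli model, which
  avoids enumerating all tuples). Distinctness is enforced by rejection;
  sequential distinct uniform draws are exactly a uniform sample without
  replacement. Labels are assigned deterministically (first ⌊αn⌋ nodes);
  all randomness flows through one seed.
* `even_monotonic_witness` — complete hypergraph minus all balanced
  (t = k/2) groups, homogeneous extremes inflated by 1 + ε (ε rational so
  counts stay integral). With ε = 0 the two top ratio scores of each class
  tie exactly, so *strict* monotonicity fails; any ε > 0 breaks the tie.
  The ε boost is this package's minimal repair of the bare
  delete-the-middle construction, whose top ratios tie under strict
  comparison.
* `planted_counts` — constructive realization of a target count vector,
  used for round-trip identities.
* `enumerate_counts` — exhaustive oracle over all count vectors with
  Σm ≤ max_total (guarded), agreeing with every LP verdict tested.

These generators produce exchangeable, degree-homogeneous data; they do not
emulate heavy-tailed degree sequences, clustering, or size-composition
correlations of real corpora. Passing tests therefore validate the
*combinatorial* claims and the estimators' correctness, not any statement
about specific empirical datasets.

## Subsampling

Robustness is assessed by recomputing scores on uniform without-replacement
subsamples at the hyperedge level (copies of a repeated group are distinct
sampling units), defaulting to fraction 0.8 with 100 replicates; replicates
in which a class loses all membership are flagged undefined rather than
zeroed.

## Problem sizes

Acceptance-scale computations use k ≤ 7 for the LPs, a 300-node / 5000-edge
random hypergraph over 20 seeds for the null-model check, the full
n_A, n_B ≤ 8, k ≤ 6 grid for the complete-hypergraph identity, and
exhaustive enumeration at k = 3, Σm ≤ 20 (10 625 vectors, exact
arithmetic) — sizes chosen so the whole suite runs in seconds while leaving
the statistical margins wide (the null-model mean ratio concentrates within
~0.01 of 1 at these sizes, against an acceptance band of ±0.05).

## Known limitations

Two classes only (focus-vs-rest for multi-label data); no cross-k aggregate
index; no degree-corrected or clustered null models; the dual certificate
covers odd k (even-k impossibility with the middle condition is established
numerically by the LP, not analytically); subsampling reports spread, not
confidence intervals.
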