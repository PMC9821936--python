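# hyperhomophily

Homophily — the tendency of individuals to associate with similar others —
is classically measured on graphs, where only pairwise ties exist. Many real
interactions, however, happen in *groups*: coauthored papers, cosponsored
bills, co-reviewed hotels, shopping baskets, group photographs. This package
measures homophily directly on the hypergraph of group interactions, and
exposes the combinatorial limits that constrain what group homophily can
look like.

It is aimed at computational social scientists and network analysts; the
same machinery applies to any class-labeled co-occurrence data (including
biological group data such as protein-complex membership).

## The framework

For a k-uniform hypergraph with node classes, the **type-t affinity** of
class X is

    h_t(X) = D_t(X) / D(X),

the fraction of class-X group memberships occurring in groups with exactly
t same-class members. Equivalently, with m_j the number of hyperedges
containing exactly j members of class A,

    h_t(A) = t·m_t / Σᵢ i·mᵢ.

Affinities are compared against **baseline scores** — the null probability
of a type-t membership when co-members are drawn uniformly at random,

    b_t(X) = C(|X|−1, t−1)·C(n−|X|, k−t) / C(n−1, k−1),

or their large-n binomial limit b_t(A) = C(k−1, t−1)·α^{t−1}(1−α)^{k−t} with
α the class proportion. Ratio scores h_t/b_t above 1 mean type-t groups are
overexpressed; the normalized bias f_t ∈ [−1, 1] rescales the deviation by
its maximum possible magnitude. The **MaHI** (majority homophily index) is
the largest j such that the top-j affinities all exceed baseline; the
**MoHI** (monotonic homophily index) is the largest j such that the top-j
ratio scores strictly increase.

The package also answers a subtler question: *which* notions of group
homophily can two classes exhibit simultaneously? A margin linear program
over type proportions decides this for strict majority homophily (all
above-baseline affinities where the class holds a majority), strict
monotonic homophily (strictly increasing majority ratio scores), and custom
linear notions. For odd k both are impossible for two classes at once — a
fact certified here by an analytic dual-feasible point with objective 0,
verified constraint by constraint — while for even k they are possible but
collapse again under one extra middle (t = k/2) condition. Exhaustive
small-instance enumeration and generator-based null models (complete
hypergraph, uniform random hypergraph, planted counts) cross-check every
verdict.

## Worked example

```bash
python examples/affinity_profile.py
```

analyzes four three-person groups over two balanced classes (one all-A
group, one with two A's, one with one A, one all-B group) against exact
baselines (n = 6):

```
type counts m_0..m_3: (1, 1, 1, 1)

class A:
  t=1: h=  1/6  b= 3/10  ratio=0.556  bias=-0.444
  t=2: h=  1/3  b=  3/5  ratio=0.556  bias=-0.444
  t=3: h=  1/2  b= 1/10  ratio=5.000  bias=+0.444
  simple=True  strict_majority=False  MaHI=1  MoHI=1
```

Half of class A's memberships are in the all-A group against a null chance
of 1/10 (ratio 5.0): homogeneous groups are strongly overexpressed, so
simple homophily holds and MaHI = 1. But at t = 2 the affinity 1/3 falls
below its baseline 3/5, so strict majority homophily fails — as it must:
both classes here mirror each other, and for k = 3 no hypergraph lets both
satisfy it at once. `examples/impossibility_lp.py`,
`examples/dual_certificate.py`, `examples/random_null.py` and
`examples/anonymous_compositions.py` walk through the LP verdicts, the dual
certificate, the random null model, and identity-free composition tables.

A thin CLI wraps the same calls, e.g.:

```bash
hyperhomophily lp --mode majority --k 3 --alpha 0.5
hyperhomophily scores --edges groups.txt --labels labels.tsv --baseline exact --out scores.csv
```

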