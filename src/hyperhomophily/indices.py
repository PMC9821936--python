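"""Boolean homophily notions and the MaHI / MoHI summary indices.

For a class X at group size k, with affinities h_t and baselines b_t:

* *simple homophily* — h_k > b_k: fully homogeneous groups are overexpressed;
* *order-j majority homophily* — h_t > b_t for every t in {k-j+1, ..., k};
* *order-j monotonic homophily* — h_t/b_t > h_{t-1}/b_{t-1} for every
  t in {k-j+1, ..., k};
* *strict majority / strict monotonic homophily* — the order-ceil(k/2)
  versions, i.e. the respective conditions for every t with t > k - t.

MaHI (majority homophily index) and MoHI (monotonic homophily index) are the
largest j for which the order-j conditions hold.  All comparisons are strict;
ties and undefined entries count against homophily.  MoHI is capped at k-1
because the order-k monotonic condition would compare against a nonexistent
t = 0 ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import ceil

from .baselines import AffinityProfile

__all__ = ["HomophilySummary", "homophily_indices", "strictly_greater"]

#: Relative tolerance for strict comparisons in floating-point mode.
FLOAT_STRICT_RTOL = 1e-12


def strictly_greater(a, b, rtol: float = FLOAT_STRICT_RTOL) -> bool:
    """Strict ``a > b`` with exact semantics for rationals.

    Comparisons involving an undefined operand (``None``) fail.  When either
    operand is a float, ``a > b`` requires a - b > rtol * max(1, |a|, |b|) so
    that roundoff-scale differences do not register as strict.
    """
    if a is None or b is None:
        return False
    if isinstance(a, (Fraction, int)) and isinstance(b, (Fraction, int)):
        return a > b
    a, b = float(a), float(b)
    return a - b > rtol * max(1.0, abs(a), abs(b))


@dataclass(frozen=True)
class HomophilySummary:
    class_label: str
    k: int
    simple: bool
    strict_majority: bool
    strict_monotonic: bool
    mahi: int
    mohi: int


def homophily_indices(profile: AffinityProfile) -> HomophilySummary:
    """Summarize a class's affinity profile into homophily booleans and indices."""
    k = profile.k
    half = ceil(k / 2)

    mahi = 0
    for t in range(k, 0, -1):  # j = k - t + 1
        if strictly_greater(profile.h_at(t), profile.b_at(t)):
            mahi = k - t + 1
        else:
            break

    mohi = 0
    for t in range(k, 1, -1):  # j = k - t + 1, capped at k - 1
        if strictly_greater(profile.ratio_at(t), profile.ratio_at(t - 1)):
            mohi = k - t + 1
        else:
            break

    return HomophilySummary(
        class_label=profile.class_label,
        k=k,
        simple=mahi >= 1,
        strict_majority=mahi >= half,
        strict_monotonic=mohi >= half,
        mahi=mahi,
        mohi=mohi,
    )
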