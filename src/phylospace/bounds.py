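"""Closed-form counting and diameter bounds for tier spaces of networks.

Conventions used throughout (as in the underlying combinatorics):
``0! = 1``, ``log_a(0) = 0`` for any base ``a`` and ``ln 0 = 0``.  Lower
bounds obtained from asymptotic arguments can be negative at small sizes;
they are reported as-is and flagged *vacuous* by the report builder rather
than clipped.

Throughout, ``l`` is the number of leaves, ``i`` the tier, and
``n = 2(l + i - 1)`` the vertex count of a tier-``i`` network -- except for
the tier-0 SPR/TBR bounds of Ding et al., which are conventionally stated
with ``n = |X|`` (the leaf count); :func:`tier0_spr_tbr_bounds` keeps that
convention and says so.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional


def log0(x: float, base: float = 6.0) -> float:
    """``log_base(x)`` with the convention ``log(0) = 0``."""
    if x == 0:
        return 0.0
    return math.log(x) / math.log(base)


def ln0(x: float) -> float:
    """Natural log with ``ln 0 = 0``."""
    return 0.0 if x == 0 else math.log(x)


def double_factorial(k: int) -> int:
    """``k!!`` with ``(-1)!! = 1`` and ``1!! = 1``."""
    if k <= 0:
        return 1
    out = 1
    while k > 1:
        out *= k
        k -= 2
    return out


# ---------------------------------------------------------------------------
# Counting
# ---------------------------------------------------------------------------

def count_lower(ell: int, i: int) -> int:
    """Echidna lower bound ``(l + i - 3)!/(i - 1)!`` on ``|N_i(X)|``, i >= 1.

    For ``i = 0`` returns ``(l - 3)!``, which the exact tree count
    ``(2l - 5)!!`` dominates.
    """
    if ell < 3 or i < 0:
        raise ValueError("need ell >= 3 and i >= 0")
    if i == 0:
        return math.factorial(ell - 3)
    return math.factorial(ell + i - 3) // math.factorial(i - 1)


def tier0_count_exact(ell: int) -> int:
    """Number of unrooted binary trees on ``l`` leaves: ``(2l - 5)!!``."""
    if ell < 3:
        raise ValueError("need ell >= 3")
    return double_factorial(2 * ell - 5)


def tier1_count_exact(ell: int) -> int:
    """Exact number of unicyclic (tier-1) networks on ``l`` leaves.

    ``(l-1)! 2^(l-2) - (2l-2)! / ((l-1)! 2^(l-1))``.
    """
    if ell < 3:
        raise ValueError("need ell >= 3")
    a = math.factorial(ell - 1) * 2 ** (ell - 2)
    b = math.factorial(2 * ell - 2) // (math.factorial(ell - 1) * 2 ** (ell - 1))
    return a - b


def tier1_count_lower(ell: int) -> int:
    """Tier-1 echidna bound ``(l - 2)! 2^(l - 3)``."""
    if ell < 3:
        raise ValueError("need ell >= 3")
    return math.factorial(ell - 2) * 2 ** (ell - 3)


def corollary_stirling_tier1_lower(ell: int) -> float:
    """Stirling-smoothed tier-1 lower bound ``(l-2)^(l-3/2) / e^(l-1)``, l > 3."""
    if ell <= 3:
        raise ValueError("need ell > 3")
    return (ell - 2) ** (ell - 1.5) / math.e ** (ell - 1)


def stirling_bounds(m: int) -> tuple[float, float]:
    """Two-sided Stirling bracket: ``sqrt(2 pi) m^(m+1/2) e^-m <= m! <=
    sqrt(2 pi) m^(m+1/2) e^-(m-1)``, for m >= 1."""
    if m < 1:
        raise ValueError("need m >= 1")
    core = math.sqrt(2 * math.pi) * m ** (m + 0.5)
    return core * math.exp(-m), core * math.exp(-(m - 1))


# ---------------------------------------------------------------------------
# NNI diameter
# ---------------------------------------------------------------------------

def grammar_ball_bound(ell: int, i: int, m: int) -> int:
    """Upper bound ``6^(n + 10m)`` on the number of tier-``i`` networks within
    ``m`` NNI operations of any fixed network, via the graph-grammar counting
    argument (grammar constants c = 5 productions-side vertices, r = 2)."""
    if m < 0:
        raise ValueError("need m >= 0")
    n = 2 * (ell + i - 1)
    return 6 ** (n + 10 * m)


def nni_diameter_lower(n: int, i: int) -> float:
    """Information-theoretic lower bound on the NNI diameter of tier ``i``:

    ``(1/20) [ (n-3) log6(n/2 - 2) - (2i-1) log6(i-1) - (n-2i) log6(e) - 2n ]``

    with ``log6(0) = 0``.  May be negative (vacuous) at small ``n``.
    """
    if i < 1:
        raise ValueError("stated for i >= 1")
    return (1.0 / 20.0) * (
        (n - 3) * log0(n / 2 - 2)
        - (2 * i - 1) * log0(i - 1)
        - (n - 2 * i) * log0(math.e)
        - 2 * n
    )


def nni_diameter_upper(n: int, i: int) -> int:
    """Constructive upper bound ``3n + C(n/2 + i - 1, 2) - 2`` on the NNI
    diameter of tier ``i`` (i >= 1), realized by the simplify /
    pseudo-Hamiltonize / cycle-sort path."""
    if i < 1 or n % 2:
        raise ValueError("need i >= 1 and even n")
    return 3 * n + math.comb(n // 2 + i - 1, 2) - 2


def cross_tier_upper(ell: int, i: int, j: int) -> int:
    """Upper bound on the full-space distance between a tier-``i`` and a
    tier-``j`` network (i <= j): ``6l + 7j - i - 8 + C(l + 2j - 2, 2)``."""
    if i > j:
        raise ValueError("need i <= j")
    if ell < 3 or i < 0:
        raise ValueError("need ell >= 3 and i >= 0")
    return 6 * ell + 7 * j - i - 8 + math.comb(ell + 2 * j - 2, 2)


# ---------------------------------------------------------------------------
# SPR / TBR diameters
# ---------------------------------------------------------------------------

def spr_one_step_bound(n: int, i: int) -> int:
    """Upper bound ``2(n + i - 1)(n + i - 4)`` on the number of one-step SPR
    moves from a tier-``i`` network on ``n`` vertices."""
    return 2 * (n + i - 1) * (n + i - 4)


def spr_diameter_lower(n: int, i: int) -> float:
    """Lower bound on the SPR diameter of tier ``i`` (i >= 1, n >= 6):

    ``[(n-3) ln(n/2 - 2) - (2i-1) ln(i-1) - (n-2i)] / (4 ln2 (n+i))``

    with ``ln 0 = 0``.
    """
    if i < 1 or n < 6:
        raise ValueError("stated for i >= 1 and n >= 6")
    num = (n - 3) * ln0(n / 2 - 2) - (2 * i - 1) * ln0(i - 1) - (n - 2 * i)
    return num / (4 * math.log(2) * (n + i))


def tbr_diameter_lower(n: int, i: int) -> float:
    """``spr_diameter_lower / 2`` exactly (a TBR step subsumes an SPR step)."""
    return spr_diameter_lower(n, i) / 2


def spr_tbr_diameter_upper(n: int, i: int) -> int:
    """Upper bound ``n^2 + 4n`` on both the SPR and TBR diameters of tier i."""
    return n * n + 4 * n


def spr_tbr_bounds(n: int, i: int) -> tuple[float, float, int]:
    """``(tbr_lower, spr_lower, upper)`` for tier ``i >= 1``."""
    return tbr_diameter_lower(n, i), spr_diameter_lower(n, i), spr_tbr_diameter_upper(n, i)


def tier0_spr_tbr_bounds(n_leaves: int) -> tuple[float, float]:
    """Ding et al. tier-0 bracket, in the ``n = |X|`` convention:

    ``n/2 - sqrt(2n) <= Delta0_TBR <= Delta0_SPR <= (n-1)/2 - sqrt(n-2)/(2 sqrt 2)``

    for ``n >= 6``.
    """
    n = n_leaves
    if n < 6:
        raise ValueError("stated for n >= 6 leaves")
    lower = n / 2 - math.sqrt(2 * n)
    upper = (n - 1) / 2 - math.sqrt(n - 2) / (2 * math.sqrt(2))
    return lower, upper


# ---------------------------------------------------------------------------
# Aggregated report
# ---------------------------------------------------------------------------

@dataclass
class BoundsReport:
    """All closed-form bounds evaluated for one ``(l, i)`` (and optional j, m)."""

    ell: int
    i: int
    j: Optional[int] = None
    m: Optional[int] = None
    n: int = 0
    count_lower: int = 0
    tier0_exact: Optional[int] = None
    tier1_exact: Optional[int] = None
    tier1_lower: Optional[int] = None
    nni_diam_lower: Optional[float] = None
    nni_diam_lower_vacuous: Optional[bool] = None
    nni_diam_upper: Optional[int] = None
    cross_tier_upper: Optional[int] = None
    grammar_ball: Optional[int] = None
    spr_diam_lower: Optional[float] = None
    tbr_diam_lower: Optional[float] = None
    spr_tbr_diam_upper: Optional[int] = None
    spr_one_step: Optional[int] = None

    def as_dict(self) -> dict:
        return asdict(self)


def bounds_report(ell: int, i: int, j: Optional[int] = None,
                  m: Optional[int] = None) -> BoundsReport:
    """Evaluate every applicable bound for the given leaf count and tier."""
    n = 2 * (ell + i - 1)
    rep = BoundsReport(ell=ell, i=i, j=j, m=m, n=n, count_lower=count_lower(ell, i))
    rep.tier0_exact = tier0_count_exact(ell)
    rep.tier1_exact = tier1_count_exact(ell)
    rep.tier1_lower = tier1_count_lower(ell)
    if i >= 1:
        rep.nni_diam_lower = nni_diameter_lower(n, i)
        rep.nni_diam_lower_vacuous = rep.nni_diam_lower <= 0
        rep.nni_diam_upper = nni_diameter_upper(n, i)
        rep.spr_one_step = spr_one_step_bound(n, i)
        if n >= 6:
            rep.spr_diam_lower = spr_diameter_lower(n, i)
            rep.tbr_diam_lower = tbr_diameter_lower(n, i)
        rep.spr_tbr_diam_upper = spr_tbr_diameter_upper(n, i)
    if j is not None:
        rep.cross_tier_upper = cross_tier_upper(ell, min(i, j), max(i, j))
    if m is not None:
        rep.grammar_ball = grammar_ball_bound(ell, i, m)
    return rep
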