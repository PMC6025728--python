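"""Two-sample Kolmogorov-Smirnov testing and the two comparison types of
the layer-densitometry design.

The samples here are small — typically 6 to 9 pooled ROI means per group —
so p-values matter most exactly where the asymptotic KS distribution is
least reliable.  Three evaluation paths are used:

* **enumeration** of all C(n1+n2, n1) label assignments of the pooled
  values for very small samples (n1+n2 <= 16); this is the conditional
  permutation null and handles ties by the right-continuous empirical CDF
  convention;
* a **block-path counting** DP for moderate samples (n1+n2 <= 64): the
  classical lattice-path recursion generalized to tied values, so it is
  exact with or without ties and agrees with enumeration where both apply;
* the **asymptotic series** p = 2 sum_{k>=1} (-1)^(k-1) exp(-2 k^2 m D^2)
  with m = n1 n2/(n1+n2), truncated when terms fall below 1e-12 and clamped
  to (0, 1].

Two comparison types are built on top: GCL-versus-inner-layer *enrichment*
within a genotype, and wild-type-versus-knockout GCL *dependency*.  Both
gate their directional call on sample medians, and both grade significance
with the conventional star levels (* p<0.05, ** p<0.01, *** p<0.001,
strict inequalities).  No multiple-testing correction is applied; stars are
per-comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

ENUM_LIMIT = 16     # n1+n2 up to which full enumeration is used
LATTICE_LIMIT = 64  # exact block-path DP up to this pooled size

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class KsResult:
    d: float
    p: float
    n1: int
    n2: int
    method: str  # "exact" or "asymptotic"


def _as_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"empty sample {name}")
    return arr


def _ks_statistic(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    """D = sup_x |F_a(x) - F_b(x)| with right-continuous empirical CDFs.

    Also returns the integer numerator g such that D = g/(n1*n2), used by
    the exact lattice path count.
    """
    n1, n2 = len(a), len(b)
    xs = np.union1d(a, b)
    ca = np.searchsorted(np.sort(a), xs, side="right")
    cb = np.searchsorted(np.sort(b), xs, side="right")
    g = int(np.max(np.abs(ca * n2 - cb * n1)))
    return g / (n1 * n2), g


def _p_enumeration(pooled: np.ndarray, n1: int, d_obs: float) -> float:
    """P(D >= d_obs) over all equally likely splits of the pooled sample.

    This is the conditional permutation null given the pooled multiset, so
    ties are handled exactly (right-continuous ECDF convention).
    """
    n = len(pooled)
    n2 = n - n1
    order = np.sort(pooled)
    # rank of each pooled position among the unique values
    uniq, ranks = np.unique(order, return_inverse=True)
    k = len(uniq)
    cum_total = np.bincount(ranks, minlength=k).cumsum()
    total = math.comb(n, n1)
    # integer threshold: D >= d_obs  <=>  |ca*n2 - cb*n1| >= g_obs
    g_obs = int(round(d_obs * n1 * n2))
    hits = 0
    for a_idx in combinations(range(n), n1):
        ca = np.bincount(ranks[list(a_idx)], minlength=k).cumsum()
        g = int(np.max(np.abs(ca * n - cum_total * n1)))  # = |ca*n2 - cb*n1|
        if g >= g_obs:
            hits += 1
    return hits / total


def _p_exact_dp(pooled: np.ndarray, n1: int, g: int) -> float:
    """Exact P(D >= g/(n1 n2)) under the conditional permutation null,
    with ties handled exactly.

    Pooled values are grouped by distinct value; an assignment of group
    members to sample A corresponds to a monotone block path, and the ECDF
    deviation is evaluated at group boundaries (right-continuous
    convention).  Counting the assignments whose deviations all stay
    strictly inside the band |ca*n - cum*n1| < g gives P(D < d); with every
    multiplicity equal to one this reduces to the classical lattice-path
    recursion.  Integer arithmetic throughout, so the count is exact.
    """
    if g == 0:
        return 1.0
    n = len(pooled)
    n2 = n - n1
    _, counts = np.unique(pooled, return_counts=True)
    dp = {0: 1}
    cum = 0
    for m in counts:
        m = int(m)
        cum += m
        new: dict[int, int] = {}
        for ca, ways in dp.items():
            for k in range(0, m + 1):
                ca2 = ca + k
                if ca2 > n1 or (cum - ca2) > n2:
                    continue
                if abs(ca2 * n - cum * n1) >= g:
                    continue  # reached the observed deviation
                new[ca2] = new.get(ca2, 0) + ways * math.comb(m, k)
        dp = new
        if not dp:
            return 1.0
    inside = dp.get(n1, 0)
    return 1.0 - inside / math.comb(n, n1)


def _p_lattice(n1: int, n2: int, g: int) -> float:
    """Exact P(D >= g/(n1 n2)) for tie-free samples by counting monotone
    lattice paths that stay strictly inside the band |i n2 - j n1| < g."""
    if g == 0:
        return 1.0
    # integer path-count DP over the (n1+1) x (n2+1) grid
    col = [0] * (n2 + 1)
    col[0] = 1
    for j in range(1, n2 + 1):
        col[j] = col[j - 1] if abs(0 * n2 - j * n1) < g else 0
    for i in range(1, n1 + 1):
        new = [0] * (n2 + 1)
        new[0] = col[0] if abs(i * n2) < g else 0
        for j in range(1, n2 + 1):
            if abs(i * n2 - j * n1) < g:
                new[j] = new[j - 1] + col[j]
        col = new
    inside = col[n2]
    total = math.comb(n1 + n2, n1)
    return 1.0 - inside / total


def _p_asymptotic(d: float, n1: int, n2: int) -> float:
    m = n1 * n2 / (n1 + n2)
    s = 0.0
    for k in range(1, 1000):
        term = 2.0 * (-1.0) ** (k - 1) * math.exp(-2.0 * k * k * m * d * d)
        s += term
        if abs(term) < 1e-12:
            break
    return min(max(s, np.nextafter(0, 1)), 1.0)


def ks2(sample_a, sample_b, method: str = "auto") -> KsResult:
    """Two-sample two-sided Kolmogorov-Smirnov test.

    ``method`` is ``auto`` (exact where affordable, asymptotic otherwise),
    ``exact`` or ``asymptotic``.  Exact p-values come from enumeration for
    very small or tied samples and from lattice-path counting for tie-free
    samples up to moderate sizes.
    """
    a = _as_sample(sample_a, "a")
    b = _as_sample(sample_b, "b")
    n1, n2 = len(a), len(b)
    n = n1 + n2
    d, g = _ks_statistic(a, b)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < n

    if method not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown method {method!r}")
    want_exact = method == "exact" or (method == "auto" and n <= LATTICE_LIMIT)
    if want_exact:
        if n <= ENUM_LIMIT:
            return KsResult(d, _p_enumeration(pooled, n1, d), n1, n2, "exact")
        if n <= LATTICE_LIMIT:
            # block-path DP: exact for ties, identical to the classical
            # lattice recursion when all values are distinct
            return KsResult(d, _p_exact_dp(pooled, n1, g), n1, n2, "exact")
        if method == "exact":
            raise ValueError(f"exact method infeasible for n1+n2={n}")
    return KsResult(d, _p_asymptotic(d, n1, n2), n1, n2, "asymptotic")


def star_level(p: float) -> str:
    """Map a p-value to the figure-legend star convention (strict bounds)."""
    if not (0.0 < p <= 1.0):
        raise ValueError(f"p-value {p} outside (0, 1]")
    for threshold, stars in STAR_THRESHOLDS:
        if p < threshold:
            return stars
    return "ns"


@dataclass(frozen=True)
class CallRecord:
    """Outcome of one enrichment or dependency comparison."""

    comparison: str            # "enrichment" | "dependency"
    gene: str
    age: str
    genotype: str              # genotype tested (enrichment) or "WT_vs_KO"
    reference_layer: str       # inner layer (enrichment) or "GCL" (dependency)
    ks: KsResult
    direction: str             # higher_in_GCL/lower_in_GCL or higher_in_WT/...
    stars: str

    @property
    def significant_difference(self) -> bool:
        return self.stars != "ns"

    @property
    def call(self) -> bool:
        """True when the difference is significant *and* in the direction
        that defines the comparison (GCL above the inner layer; WT above
        KO)."""
        return self.stars != "ns" and self.direction in (
            "higher_in_GCL",
            "higher_in_WT",
        )


def _direction(first: np.ndarray, second: np.ndarray, pos: str, neg: str) -> str:
    m1, m2 = float(np.median(first)), float(np.median(second))
    if m1 > m2:
        return pos
    if m1 < m2:
        return neg
    return "none"


def enrichment_call(
    gcl_sample,
    inner_sample,
    gene: str = "",
    age: str = "",
    genotype: str = "",
    reference_layer: str = "",
    method: str = "auto",
) -> CallRecord:
    """Is the GCL signal higher than the inner reference layer (INL at P7+,
    NBL at P0/P3)?  Values are IPL-normalized where available, raw at P0."""
    a = _as_sample(gcl_sample, "GCL")
    b = _as_sample(inner_sample, "inner layer")
    ks = ks2(a, b, method=method)
    return CallRecord(
        comparison="enrichment",
        gene=gene,
        age=age,
        genotype=genotype,
        reference_layer=reference_layer,
        ks=ks,
        direction=_direction(a, b, "higher_in_GCL", "lower_in_GCL"),
        stars=star_level(ks.p),
    )


def dependency_call(
    wt_gcl_sample,
    ko_gcl_sample,
    gene: str = "",
    age: str = "",
    method: str = "auto",
) -> CallRecord:
    """Does the wild-type GCL signal exceed the knockout GCL signal?"""
    a = _as_sample(wt_gcl_sample, "WT GCL")
    b = _as_sample(ko_gcl_sample, "KO GCL")
    ks = ks2(a, b, method=method)
    return CallRecord(
        comparison="dependency",
        gene=gene,
        age=age,
        genotype="WT_vs_KO",
        reference_layer="GCL",
        ks=ks,
        direction=_direction(a, b, "higher_in_WT", "lower_in_WT"),
        stars=star_level(ks.p),
    )


def inner_reference_layer(age: str) -> str:
    """The inner comparison layer for enrichment at a given age."""
    return "NBL" if age in ("P0", "P3") else "INL"
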