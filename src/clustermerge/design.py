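"""Closed-form design calculations for two-arm cluster randomised trials.

Sample size, clusters required, analytic power and design effects for a
continuous outcome under the standard normal-approximation framework, plus
the post-merge cluster-size algebra needed when pairs of clusters combine
after randomisation: merging leaves fewer, larger, unequal clusters, which
inflates the design effect and (absent extra recruitment) reduces power.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy.stats import norm

__all__ = [
    "TrialDesign",
    "MergeCounts",
    "sample_size_individual",
    "design_effect",
    "clusters_required",
    "power",
    "merged_mean_size",
    "merged_size_variance",
    "post_merge_allocation_ratio",
]


@dataclass(frozen=True)
class TrialDesign:
    """Parameters of a two-arm parallel cluster RCT with a continuous outcome.

    Parameters
    ----------
    delta : float
        Difference in means to detect (outcome units); must be non-zero.
    sigma_b2, sigma_w2 : float
        Between- and within-cluster variance components. Total variance is
        ``sigma_b2 + sigma_w2`` and the intracluster correlation (ICC) is
        ``sigma_b2 / (sigma_b2 + sigma_w2)``.
    alpha : float
        Two-sided type I error probability.
    target_power : float
        Desired power 1 - beta.
    lam : float
        Allocation ratio of clusters between arms (intervention : control).
        Power is maximised at ``lam = 1``.
    m : int
        Planned individuals per cluster.
    c : int
        Total number of clusters across both arms.
    w : float
        Anticipated individual-level attrition proportion, in [0, 1).
    """

    delta: float
    sigma_b2: float = 0.05
    sigma_w2: float = 0.95
    alpha: float = 0.05
    target_power: float = 0.80
    lam: float = 1.0
    m: int = 20
    c: int = 80
    w: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_b2 < 0:
            raise ValueError("sigma_b2 must be non-negative")
        if self.sigma_w2 <= 0:
            raise ValueError("sigma_w2 must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.target_power < 1:
            raise ValueError("target_power must lie in (0, 1)")
        if self.lam <= 0:
            raise ValueError("allocation ratio lam must be positive")
        if self.m < 1:
            raise ValueError("cluster size m must be a positive integer")
        if self.c < 2:
            raise ValueError("need at least two clusters")
        if not 0 <= self.w < 1:
            raise ValueError("attrition w must lie in [0, 1)")

    @property
    def sigma2(self) -> float:
        """Total outcome variance."""
        return self.sigma_b2 + self.sigma_w2

    @property
    def rho(self) -> float:
        """Intracluster correlation coefficient."""
        return self.sigma_b2 / (self.sigma_b2 + self.sigma_w2)

    @property
    def arm_sizes(self) -> tuple[int, int]:
        """Cluster counts (control, intervention) implied by ``c`` and ``lam``."""
        c0 = round(self.c / (1.0 + self.lam))
        return c0, self.c - c0


@dataclass(frozen=True)
class MergeCounts:
    """Numbers of within-arm pair-merges per arm.

    Each cluster may take part in at most one merge, so ``2 * k_i`` cannot
    exceed the number of clusters in arm ``i``.
    """

    k0: int = 0
    k1: int = 0

    def __post_init__(self) -> None:
        if self.k0 < 0 or self.k1 < 0:
            raise ValueError("merge counts must be non-negative")

    @property
    def total(self) -> int:
        return self.k0 + self.k1


def _quantiles(design: TrialDesign) -> tuple[float, float]:
    # Upper-tail standard-normal quantiles xi_{alpha/2} and xi_beta.
    return norm.isf(design.alpha / 2.0), norm.isf(1.0 - design.target_power)


def sample_size_individual(design: TrialDesign) -> int:
    """Total individuals for an individually randomised trial, attrition-adjusted.

    Evaluates ``(1+lam)^2 (xi_{a/2}+xi_b)^2 sigma^2 / ((1-w) lam delta^2)``
    and rounds up.
    """
    if design.delta == 0:
        raise ValueError("delta must be non-zero")
    xa, xb = _quantiles(design)
    n = ((1.0 + design.lam) ** 2 * (xa + xb) ** 2 * design.sigma2) / (
        (1.0 - design.w) * design.lam * design.delta**2
    )
    return math.ceil(n)


def design_effect(m_bar: float, rho: float, size_var: float = 0.0) -> float:
    """Variance inflation factor for clustering with (possibly) unequal sizes.

    ``1 + ((size_var / m_bar^2 + 1) m_bar - 1) rho``; with ``size_var=0``
    this is the familiar ``1 + (m_bar - 1) rho``. Strictly increasing in the
    cluster-size variance whenever ``rho > 0``.
    """
    if m_bar < 1:
        raise ValueError("mean cluster size must be at least 1")
    if not 0 <= rho < 1:
        raise ValueError("rho must lie in [0, 1)")
    if size_var < 0:
        raise ValueError("cluster-size variance cannot be negative")
    return 1.0 + ((size_var / m_bar**2 + 1.0) * m_bar - 1.0) * rho


def clusters_required(design: TrialDesign) -> int:
    """Total clusters needed, rounded up compatibly with the allocation ratio.

    The individually randomised sample size is inflated by the
    attrition-adjusted design effect ``1 + (m(1-w) - 1) rho`` and divided by
    the post-attrition cluster size. Each arm's count is rounded up
    separately, so with ``lam=1`` the result is the next even integer.
    """
    if design.delta == 0:
        raise ValueError("delta must be non-zero")
    xa, xb = _quantiles(design)
    de = design_effect(design.m * (1.0 - design.w), design.rho)
    c_raw = ((1.0 + design.lam) ** 2 * (xa + xb) ** 2 * design.sigma2 * de) / (
        design.m * (1.0 - design.w) * design.lam * design.delta**2
    )
    c0 = math.ceil(c_raw / (1.0 + design.lam))
    c1 = math.ceil(c_raw * design.lam / (1.0 + design.lam))
    return c0 + c1


def merged_mean_size(m: int, c: int, k: int) -> float:
    """Mean cluster size after ``k`` pair-merges: ``c m / (c - k)``.

    Individuals are conserved: the result times ``c - k`` equals ``m c``.
    """
    if not 0 <= 2 * k <= c:
        raise ValueError("k pair-merges require 2k <= c clusters")
    return c * m / (c - k)


def merged_size_variance(m: int, c: int, k: int) -> float:
    """Sample variance of cluster sizes after ``k`` pair-merges.

    The post-merge size vector holds ``k`` entries of ``2m`` and ``c - 2k``
    of ``m``; its sample variance (divisor ``c-k-1``) collapses to
    ``m^2 k (c - 2k) / ((c-k)(c-k-1))``. Zero at ``k=0`` and ``k=c/2``,
    with an interior maximum in between.
    """
    if not 0 <= 2 * k <= c:
        raise ValueError("k pair-merges require 2k <= c clusters")
    if c - k < 2:
        raise ValueError("sample variance needs at least two post-merge clusters")
    return m**2 * k * (c - 2 * k) / ((c - k) * (c - k - 1))


def post_merge_allocation_ratio(c0: int, c1: int, k0: int, k1: int) -> float:
    """Cluster-count allocation ratio after unequal numbers of within-arm merges.

    Arm ``i`` retains ``c_i - k_i`` clusters, so the ratio becomes
    ``(c0 - k0) / (c1 - k1)``; symmetric merging of equal arms keeps it at 1.
    """
    if 2 * k0 > c0 or 2 * k1 > c1:
        raise ValueError("each cluster may participate in at most one merge")
    if c1 - k1 == 0:
        raise ValueError("post-merge allocation ratio undefined: empty arm")
    return (c0 - k0) / (c1 - k1)


def gamma(design: TrialDesign, merge: MergeCounts | None = None) -> float:
    """Non-centrality-style quantity driving power, before/after merges.

    No merges: ``m(1-w) c lam delta^2 / ((1+lam)^2 sigma^2 DE)`` with the
    equal-size design effect. After ``k0 + k1`` within-arm pair-merges the
    cluster count, mean size, size variance and allocation ratio are all
    recomputed and the variable-size design effect is used. Merging can
    only decrease this quantity (equality only at zero merges).
    """
    if design.delta == 0:
        raise ValueError("delta must be non-zero")
    retain = 1.0 - design.w
    if merge is None or merge.total == 0:
        de = design_effect(design.m * retain, design.rho)
        return (
            design.m * retain * design.c * design.lam * design.delta**2
        ) / ((1.0 + design.lam) ** 2 * design.sigma2 * de)
    c0, c1 = design.arm_sizes
    if 2 * merge.k0 > c0 or 2 * merge.k1 > c1:
        raise ValueError("merge counts exceed available clusters in an arm")
    k = merge.total
    c_post = design.c - k
    m_post = merged_mean_size(design.m, design.c, k)
    s2_post = merged_size_variance(design.m, design.c, k)
    lam_post = post_merge_allocation_ratio(c0, c1, merge.k0, merge.k1)
    # Uniform attrition scales every cluster by (1-w): the squared
    # coefficient of variation s2/m^2 is unchanged, the mean size shrinks.
    cv2 = s2_post / m_post**2
    de = 1.0 + ((cv2 + 1.0) * m_post * retain - 1.0) * design.rho
    return (
        m_post * retain * c_post * lam_post * design.delta**2
    ) / ((1.0 + lam_post) ** 2 * design.sigma2 * de)


def power(design: TrialDesign, merge: MergeCounts | None = None) -> float:
    """Analytic power ``Phi(sqrt(gamma) - xi_{alpha/2})``.

    With a ``MergeCounts`` the post-merge design (fewer clusters, larger
    mean size, non-zero size variance, possibly unbalanced allocation) is
    used; ``MergeCounts(0, 0)`` reproduces the no-merge value exactly.
    """
    xa = norm.isf(design.alpha / 2.0)
    return float(norm.cdf(math.sqrt(gamma(design, merge)) - xa))
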