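"""Analytic power for M-DISW-CRT designs via generalised least squares.

The treatment-effect variance is computed on cluster-period means, following
the classical stepped-wedge approach of Hussey & Hughes: with fixed effects
for period (month) and treatment, and a working covariance for the repeated
cluster-period means, the variance of the GLS effect estimator is the
treatment-coefficient entry of (X' V^-1 X)^-1.  Each audited standard within
a facility is treated as its own pseudo-cluster, so a trial with F facilities
each completing C audit cycles contributes F x C clusters spread over the
design's sequences.

The within-cluster covariance supports a discrete-time-decay structure:
two clients in the same cluster and month are correlated rho (the
within-period ICC), while the between-month correlation decays as
rho * r^{|j-k|}, r being the cluster autocorrelation (CAC).  r = 1 recovers
the exchangeable (Hussey-Hughes) structure.

Binary outcomes are handled on the proportion scale via a normal
approximation; the working residual variance defaults to the average of the
control- and intervention-arm Bernoulli variances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from .design_core import DesignMatrix

__all__ = [
    "CorrelationModel",
    "PowerSpec",
    "PowerResult",
    "InestimableError",
    "pseudo_cluster_expansion",
    "cluster_period_covariance",
    "gls_effect_variance",
    "power",
    "detectable_difference",
    "binary_sigma2",
]


class InestimableError(ValueError):
    """The treatment effect is confounded with the period effects."""


@dataclass(frozen=True)
class CorrelationModel:
    """Within-cluster correlation structure for cross-sectional sampling.

    Parameters
    ----------
    icc:
        Within-period intra-cluster correlation rho, in [0, 1).
    cac:
        Cluster autocorrelation r in (0, 1]: the factor by which the
        between-period within-cluster correlation decays per month of
        separation.  cac = 1 gives the exchangeable structure.
    """

    icc: float
    cac: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.icc < 1.0:
            raise ValueError("icc must lie in [0, 1)")
        if not 0.0 < self.cac <= 1.0:
            raise ValueError("cac must lie in (0, 1]")

    @property
    def structure(self) -> str:
        return "exchangeable" if self.cac == 1.0 else "discrete-time-decay"


@dataclass
class PowerSpec:
    """Inputs for a power calculation on a given design pattern."""

    design: DesignMatrix
    m: int = 25
    p0: float = 0.5
    delta: float = 0.1
    corr: CorrelationModel = field(default_factory=lambda: CorrelationModel(icc=0.05))
    alpha: float = 0.05
    sigma2_convention: str = "average"

    def __post_init__(self) -> None:
        if not 0.0 < self.p0 < 1.0:
            raise ValueError("p0 must lie in (0, 1)")
        if not 0.0 < self.p0 + self.delta < 1.0:
            raise ValueError("p0 + delta must lie in (0, 1)")
        if self.m < 1:
            raise ValueError("m must be at least 1")


@dataclass
class PowerResult:
    var_theta: float
    se: float
    power: float


def binary_sigma2(p0: float, p1: float, convention: str = "average") -> float:
    """Working residual variance for a binary outcome on the proportion scale.

    ``average`` (default) uses the mean of the two arms' Bernoulli variances;
    ``control`` uses p0(1-p0); ``pooled`` uses pbar(1-pbar) at the midpoint
    proportion.
    """
    if convention == "average":
        return 0.5 * (p0 * (1 - p0) + p1 * (1 - p1))
    if convention == "control":
        return p0 * (1 - p0)
    if convention == "pooled":
        pbar = 0.5 * (p0 + p1)
        return pbar * (1 - pbar)
    raise ValueError(f"unknown sigma2 convention {convention!r}")


def pseudo_cluster_expansion(
    n_facilities: int,
    cycles_per_facility: int,
    n_sequences: int,
    seed: int | None = 0,
) -> np.ndarray:
    """Spread F x C pseudo-clusters (facility x audit-cycle) over sequences.

    Returns per-sequence cluster counts summing to
    ``n_facilities * cycles_per_facility``.  When the total does not divide
    evenly, the remainder is distributed one per sequence in seeded random
    order.
    """
    if n_sequences < 1:
        raise ValueError("need at least one sequence")
    total = int(n_facilities) * int(cycles_per_facility)
    counts = np.full(n_sequences, total // n_sequences, dtype=int)
    remainder = total % n_sequences
    if remainder:
        rng = np.random.default_rng(seed)
        for j in rng.choice(n_sequences, size=remainder, replace=False):
            counts[int(j)] += 1
    return counts


def cluster_period_covariance(
    months: Sequence[int],
    m: int,
    sigma2: float,
    corr: CorrelationModel,
) -> np.ndarray:
    """Covariance of the cluster-period mean outcomes at the given months.

    Diagonal entries are sigma2 * (1 + (m-1) rho) / m — the variance of a
    mean of m equicorrelated clients — and the entry for months j, k is
    sigma2 * rho * r^{|j-k|}.
    """
    if m < 1:
        raise ValueError("m must be at least 1")
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    months = np.asarray(months, dtype=float)
    rho, r = corr.icc, corr.cac
    lag = np.abs(months[:, None] - months[None, :])
    cov = sigma2 * rho * r**lag
    np.fill_diagonal(cov, sigma2 * (1.0 + (m - 1) * rho) / m)
    # PD check: diagonal dominance does not hold in general, so test directly
    eigmin = np.linalg.eigvalsh(cov).min()
    if eigmin <= 0:
        raise ValueError("cluster-period covariance is not positive definite")
    return cov


def _design_rows(design: DesignMatrix):
    """Yield (observed month indices, treatment codes, cluster count) per sequence."""
    for row, count in zip(design.rows, design.clusters_per_sequence):
        obs = np.flatnonzero(row >= 0)
        if obs.size and count > 0:
            yield obs, row[obs].astype(float), int(count)


def gls_effect_variance(
    design: DesignMatrix,
    m: int,
    sigma2: float,
    corr: CorrelationModel,
) -> float:
    """Variance of the GLS treatment-effect estimator on cluster-period means.

    Fixed effects are an intercept, month indicators (reference coding; the
    result is invariant to the coding) and the treatment indicator.  Each
    sequence contributes ``clusters_per_sequence`` independent blocks with
    the discrete-time-decay covariance; months without data contribute no
    rows.  Raises :class:`InestimableError` when the treatment indicator is
    (numerically) a linear combination of the month effects — as happens for
    an unstratified variant-A design, where every facility steps in the same
    months.
    """
    rows = list(_design_rows(design))
    if not rows:
        raise InestimableError("design contains no observed cluster-periods")
    all_treat = np.concatenate([t for _, t, _ in rows])
    if not (np.any(all_treat == 0) and np.any(all_treat == 1)):
        raise InestimableError("design must contain both control and intervention periods")
    months_used = sorted({design.months[int(j)] for obs, _, _ in rows for j in obs})
    col = {mth: i for i, mth in enumerate(months_used[1:])}  # first month = reference
    p = 1 + len(col) + 1
    A = np.zeros((p, p))
    for obs, treat, count in rows:
        k = obs.size
        X = np.zeros((k, p))
        X[:, 0] = 1.0
        for i, j in enumerate(obs):
            mth = design.months[int(j)]
            if mth in col:
                X[i, 1 + col[mth]] = 1.0
        X[:, -1] = treat
        V = cluster_period_covariance(
            [design.months[int(j)] for j in obs], m, sigma2, corr
        )
        Vi = np.linalg.inv(V)
        A += count * X.T @ Vi @ X
    # Schur complement of the treatment entry measures its residual information
    A_oo = A[:-1, :-1]
    a_ot = A[:-1, -1]
    a_tt = A[-1, -1]
    sol = np.linalg.lstsq(A_oo, a_ot, rcond=None)[0]
    schur = a_tt - a_ot @ sol
    if schur <= a_tt * 1e-10:
        raise InestimableError(
            "treatment effect is confounded with month effects in this design"
        )
    return float(1.0 / schur)


def power(spec: PowerSpec) -> PowerResult:
    """Normal-approximation power for detecting a difference in proportions.

    The working variance is ``binary_sigma2(p0, p0 + delta)``; power is
    Phi(|delta| / se - z_{1-alpha/2}).
    """
    p1 = spec.p0 + spec.delta
    sigma2 = binary_sigma2(spec.p0, p1, spec.sigma2_convention)
    var_theta = gls_effect_variance(spec.design, spec.m, sigma2, spec.corr)
    se = float(np.sqrt(var_theta))
    z_crit = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    pwr = float(stats.norm.cdf(abs(spec.delta) / se - z_crit))
    return PowerResult(var_theta=var_theta, se=se, power=pwr)


def detectable_difference(
    design: DesignMatrix,
    m: int = 25,
    p0: float = 0.5,
    corr: CorrelationModel | None = None,
    alpha: float = 0.05,
    target_power: float = 0.8,
    sigma2_convention: str = "average",
    tol: float = 1e-6,
) -> float:
    """Smallest improvement in proportions detectable at the target power.

    Solved by bisection on delta in (0, 1 - p0); raises if even the largest
    admissible delta falls short of the target.
    """
    if corr is None:
        corr = CorrelationModel(icc=0.05)
    if not alpha < target_power < 1.0:
        raise ValueError("target power must lie in (alpha, 1)")

    def pw(delta: float) -> float:
        return power(
            PowerSpec(
                design=design, m=m, p0=p0, delta=delta, corr=corr, alpha=alpha,
                sigma2_convention=sigma2_convention,
            )
        ).power

    hi = (1.0 - p0) - 1e-9
    if pw(hi) < target_power:
        raise ValueError(
            "no detectable difference below 1 - p0 reaches the target power"
        )
    lo = 1e-12
    root = optimize.brentq(lambda d: pw(d) - target_power, lo, hi, xtol=tol)
    return float(root)
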