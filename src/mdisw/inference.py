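"""Estimation of the intervention odds ratio from client-level records.

The reference analysis is a logistic generalised linear mixed model on the
client-level binary outcome, aggregated to cluster-period binomial counts
(facility x month x standard), with

* fixed effects: intercept, study month (categorical, to absorb secular
  trend), standard (categorical, to absorb differing baseline compliance)
  and the intervention indicator;
* random effects: facility intercept and facility x month interaction
  (facility-specific secular fluctuation).

Sensitivity analyses may add intervention x standard or month x standard
fixed terms, a lag covariate (months since the cycle's intervention
assessment), and a facility x standard random term.

Fitting uses penalised quasi-likelihood (PQL, Breslow-Clayton): iterate a
working linear mixed model on the adjusted dependent variate, estimating the
variance components by REML at each step.  Because every random term is
nested within facility, the working covariance is block-diagonal by
facility, which keeps each REML evaluation cheap.  The approximation is
accurate here because the binomial denominators are sizeable (25 clients per
cluster-period by design).  On non-convergence a documented fallback ladder
is applied: first drop the facility x month random term; for specifications
with a facility x standard random term, refit without the month fixed
effect and the facility random intercept; otherwise report failure.

Confidence intervals are Wald-type on the log-odds scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .power_calc import CorrelationModel, cluster_period_covariance

__all__ = [
    "ModelSpec",
    "REFERENCE_SPEC",
    "FitResult",
    "FitError",
    "aggregate_cluster_periods",
    "fit_primary",
    "fit_sensitivity",
    "fit_per_standard",
    "gls_wald",
]

_FIXED_TERMS = {"intervention", "month", "standard", "intervention_x_standard",
                "month_x_standard", "lag"}
_RANDOM_TERMS = {"facility", "facility_month", "facility_standard"}


class FitError(ValueError):
    """Raised for data or model specifications that cannot be estimated."""


@dataclass(frozen=True)
class ModelSpec:
    """Fixed and random terms of a candidate analysis model."""

    fixed_terms: tuple[str, ...] = ("intervention", "month", "standard")
    random_terms: tuple[str, ...] = ("facility", "facility_month")

    def __post_init__(self) -> None:
        unknown = set(self.fixed_terms) - _FIXED_TERMS
        if unknown:
            raise FitError(f"unknown fixed terms: {sorted(unknown)}")
        unknown = set(self.random_terms) - _RANDOM_TERMS
        if unknown:
            raise FitError(f"unknown random terms: {sorted(unknown)}")
        if "intervention" not in self.fixed_terms:
            raise FitError("the intervention term is required")


REFERENCE_SPEC = ModelSpec()


@dataclass
class FitResult:
    """Estimated intervention effect with Wald 95% CI and variance components."""

    theta_hat: float
    se: float
    or_hat: float
    ci95: tuple[float, float]
    variance_components: dict[str, float]
    converged: bool
    method: str = "PQL (Breslow-Clayton, REML variance components)"
    fallback_applied: str | None = None
    spec: ModelSpec = field(default_factory=lambda: REFERENCE_SPEC)
    fixed_effects: dict[str, float] = field(default_factory=dict)
    fixed_effect_ses: dict[str, float] = field(default_factory=dict)

    @property
    def z(self) -> float:
        return self.theta_hat / self.se

    @property
    def p_value(self) -> float:
        return float(2.0 * stats.norm.sf(abs(self.z)))


def aggregate_cluster_periods(records: pd.DataFrame) -> pd.DataFrame:
    """Collapse client records to cluster-period binomial counts.

    One output row per (facility, month, standard) with the number of
    clients ``n`` and compliant clients ``n_compliant``; exposure, stratum
    and months-since-intervention are constant within a cell and carried
    through.
    """
    cols = ["facility_id", "month", "standard"]
    if records.empty:
        return pd.DataFrame(
            columns=cols + ["stratum", "exposure", "months_since_intervention",
                            "n", "n_compliant"]
        )
    grouped = records.groupby(cols, sort=True)
    agg = grouped.agg(
        stratum=("stratum", "first"),
        exposure=("exposure", "first"),
        months_since_intervention=("months_since_intervention", "first"),
        n=("compliant", "size"),
        n_compliant=("compliant", "sum"),
    ).reset_index()
    if (grouped["exposure"].nunique() > 1).any():
        raise FitError("exposure is not constant within a facility-month-standard cell")
    return agg


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------


def _build_fixed(agg: pd.DataFrame, spec: ModelSpec):
    """Return (X, column names, index of the intervention column)."""
    n = len(agg)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    months = sorted(agg["month"].unique())
    stds = sorted(agg["standard"].unique())
    if "month" in spec.fixed_terms:
        for mth in months[1:]:
            cols.append((agg["month"] == mth).to_numpy(dtype=float))
            names.append(f"month[{mth}]")
    if "standard" in spec.fixed_terms:
        for s in stds[1:]:
            cols.append((agg["standard"] == s).to_numpy(dtype=float))
            names.append(f"standard[{s}]")
    if "month_x_standard" in spec.fixed_terms:
        for mth in months[1:]:
            for s in stds[1:]:
                col = ((agg["month"] == mth) & (agg["standard"] == s)).to_numpy(dtype=float)
                if col.any():
                    cols.append(col)
                    names.append(f"month[{mth}]:standard[{s}]")
    expo = agg["exposure"].to_numpy(dtype=float)
    treat_idx = len(cols)
    cols.append(expo)
    names.append("intervention")
    if "intervention_x_standard" in spec.fixed_terms:
        for s in stds[1:]:
            cols.append(expo * (agg["standard"] == s).to_numpy(dtype=float))
            names.append(f"intervention:standard[{s}]")
    if "lag" in spec.fixed_terms:
        cols.append(agg["months_since_intervention"].to_numpy(dtype=float) * expo)
        names.append("lag")
    X = np.column_stack(cols)
    # drop numerically redundant columns (keeping intercept and intervention)
    keep = _independent_columns(X, protect={0, treat_idx})
    if treat_idx not in keep:
        raise FitError("intervention effect is confounded with the other fixed effects")
    X = X[:, keep]
    names = [names[i] for i in keep]
    return X, names, names.index("intervention")


def _independent_columns(X: np.ndarray, protect: set[int]) -> list[int]:
    """Greedy selection of a linearly independent column subset via QR."""
    keep: list[int] = []
    basis = np.zeros((X.shape[0], 0))
    order = sorted(range(X.shape[1]), key=lambda i: (i not in protect, i))
    chosen: set[int] = set()
    for i in order:
        col = X[:, i]
        if basis.shape[1]:
            resid = col - basis @ np.linalg.lstsq(basis, col, rcond=None)[0]
        else:
            resid = col
        if np.linalg.norm(resid) > 1e-8 * max(1.0, np.linalg.norm(col)):
            chosen.add(i)
            basis = np.column_stack([basis, col])
    return sorted(chosen)


def _random_blocks(agg_f: pd.DataFrame, terms: Sequence[str]) -> list[np.ndarray]:
    """Per-facility covariance structure matrix for each random term."""
    blocks = []
    k = len(agg_f)
    for term in terms:
        if term == "facility":
            blocks.append(np.ones((k, k)))
        elif term == "facility_month":
            mth = agg_f["month"].to_numpy()
            blocks.append((mth[:, None] == mth[None, :]).astype(float))
        elif term == "facility_standard":
            std = agg_f["standard"].to_numpy()
            blocks.append((std[:, None] == std[None, :]).astype(float))
    return blocks


# ---------------------------------------------------------------------------
# PQL core
# ---------------------------------------------------------------------------


class _NonConvergence(Exception):
    pass


_LOGV_LO, _LOGV_HI = -14.0, 3.0


def _pql_fit(agg: pd.DataFrame, spec: ModelSpec):
    """One PQL fit; raises _NonConvergence when the fit is unreliable."""
    agg = agg.reset_index(drop=True)
    X, names, treat_idx = _build_fixed(agg, spec)
    y = agg["n_compliant"].to_numpy(dtype=float)
    n = agg["n"].to_numpy(dtype=float)
    fac_slices = [np.asarray(idx) for _, idx in
                  agg.groupby("facility_id", sort=True).groups.items()]
    blocks = [
        _random_blocks(agg.iloc[idx], spec.random_terms) for idx in fac_slices
    ]
    n_vc = len(spec.random_terms)
    p = X.shape[1]

    def reml(log_v: np.ndarray, w: np.ndarray, z: np.ndarray):
        v = np.exp(log_v)
        logdet = 0.0
        XtViX = np.zeros((p, p))
        XtViz = np.zeros(p)
        ztViz = 0.0
        Vi_blocks = []
        for idx, bks in zip(fac_slices, blocks):
            Vf = np.diag(1.0 / w[idx])
            for vk, B in zip(v, bks):
                Vf = Vf + vk * B
            try:
                L = np.linalg.cholesky(Vf)
            except np.linalg.LinAlgError:
                return np.inf, None
            logdet += 2.0 * np.sum(np.log(np.diag(L)))
            Xf = X[idx]
            zf = z[idx]
            sol = np.linalg.solve(L, np.column_stack([Xf, zf]))
            XtViX += sol[:, :p].T @ sol[:, :p]
            XtViz += sol[:, :p].T @ sol[:, p]
            ztViz += sol[:, p] @ sol[:, p]
            Vi_blocks.append(L)
        sign, logdet_xvx = np.linalg.slogdet(XtViX)
        if sign <= 0:
            return np.inf, None
        try:
            beta = np.linalg.solve(XtViX, XtViz)
        except np.linalg.LinAlgError:
            return np.inf, None
        quad = ztViz - XtViz @ beta
        crit = logdet + logdet_xvx + quad
        return crit, (beta, XtViX, Vi_blocks)

    # initial values
    eta = np.clip(special.logit(np.clip((y + 0.5) / (n + 1.0), 1e-4, 1 - 1e-4)), -8, 8)
    log_v = np.full(n_vc, np.log(0.05))
    converged = False
    beta = None
    XtViX = None
    for _outer in range(60):
        mu = special.expit(eta)
        w = np.clip(n * mu * (1.0 - mu), 1e-8, None)
        z = eta + (y - n * mu) / w

        res = optimize.minimize(
            lambda lv: reml(lv, w, z)[0],
            log_v,
            method="L-BFGS-B",
            bounds=[(_LOGV_LO, _LOGV_HI)] * n_vc,
            options={"maxiter": 200, "ftol": 1e-10},
        )
        log_v = res.x
        crit, parts = reml(log_v, w, z)
        if not np.isfinite(crit) or parts is None:
            raise _NonConvergence("REML criterion not finite")
        beta, XtViX, L_blocks = parts
        v = np.exp(log_v)
        # new linear predictor: X beta + BLUP of the random part
        eta_new = X @ beta
        resid = z - eta_new
        for idx, bks, L in zip(fac_slices, blocks, L_blocks):
            rf = resid[idx]
            Vi_rf = np.linalg.solve(L.T, np.linalg.solve(L, rf))
            G = np.zeros((len(idx), len(idx)))
            for vk, B in zip(v, bks):
                G += vk * B
            eta_new[idx] += G @ Vi_rf
        eta_new = np.clip(eta_new, -12, 12)
        step = float(np.max(np.abs(eta_new - eta))) if len(eta) else 0.0
        eta = eta_new
        if step < 1e-6:
            converged = True
            break

    if beta is None or XtViX is None:
        raise _NonConvergence("no successful REML step")
    if not converged:
        raise _NonConvergence("PQL iterations did not stabilise")

    # identifiability: interior variance components must show curvature
    mu = special.expit(eta)
    w = np.clip(n * mu * (1.0 - mu), 1e-8, None)
    z = eta + (y - n * mu) / w
    f0, _ = reml(log_v, w, z)
    for k in range(n_vc):
        if log_v[k] <= _LOGV_LO + 1e-6:
            continue  # component at the zero boundary: dropped, not a failure
        h = 0.25
        lv_p, lv_m = log_v.copy(), log_v.copy()
        lv_p[k] = min(lv_p[k] + h, _LOGV_HI)
        lv_m[k] -= h
        fp, _ = reml(lv_p, w, z)
        fm, _ = reml(lv_m, w, z)
        curv = (fp + fm - 2.0 * f0) / h**2
        if not np.isfinite(curv) or curv < 1e-3:
            raise _NonConvergence(
                f"variance component {spec.random_terms[k]!r} is not identified"
            )

    cov_beta = np.linalg.inv(XtViX)
    vc = {term: float(np.exp(log_v[k])) for k, term in enumerate(spec.random_terms)}
    fixed = {nm: float(b) for nm, b in zip(names, beta)}
    ses = {nm: float(np.sqrt(cov_beta[i, i])) for i, nm in enumerate(names)}
    theta = float(beta[treat_idx])
    se = float(np.sqrt(cov_beta[treat_idx, treat_idx]))
    return theta, se, vc, fixed, ses


def _as_aggregated(records: pd.DataFrame) -> pd.DataFrame:
    if "n" in records.columns and "n_compliant" in records.columns:
        return records
    return aggregate_cluster_periods(records)


def _fallback_ladder(spec: ModelSpec) -> list[tuple[ModelSpec, str | None]]:
    ladder: list[tuple[ModelSpec, str | None]] = [(spec, None)]
    if "facility_month" in spec.random_terms:
        reduced = replace(
            spec,
            random_terms=tuple(t for t in spec.random_terms if t != "facility_month"),
        )
        if reduced.random_terms:
            ladder.append((reduced, "dropped facility x month random term"))
    if "facility_standard" in spec.random_terms:
        reduced = ModelSpec(
            fixed_terms=tuple(t for t in spec.fixed_terms if t != "month"),
            random_terms=tuple(
                t for t in spec.random_terms if t != "facility"
            ),
        )
        ladder.append(
            (
                reduced,
                "dropped month fixed effect and facility random intercept",
            )
        )
    return ladder


def _fit(records: pd.DataFrame, spec: ModelSpec) -> FitResult:
    agg = _as_aggregated(records)
    if agg.empty:
        raise FitError("no records supplied")
    expo = agg["exposure"].unique()
    if not (0 in expo and 1 in expo):
        raise FitError("records must contain both control and intervention periods")

    last_error: Exception | None = None
    for candidate, note in _fallback_ladder(spec):
        try:
            theta, se, vc, fixed, ses = _pql_fit(agg, candidate)
        except _NonConvergence as exc:
            last_error = exc
            continue
        ci = (float(np.exp(theta - 1.96 * se)), float(np.exp(theta + 1.96 * se)))
        return FitResult(
            theta_hat=theta,
            se=se,
            or_hat=float(np.exp(theta)),
            ci95=ci,
            variance_components=vc,
            converged=True,
            fallback_applied=note,
            spec=candidate,
            fixed_effects=fixed,
            fixed_effect_ses=ses,
        )
    return FitResult(
        theta_hat=float("nan"),
        se=float("nan"),
        or_hat=float("nan"),
        ci95=(float("nan"), float("nan")),
        variance_components={},
        converged=False,
        fallback_applied=f"all fallbacks failed: {last_error}",
        spec=spec,
    )


def fit_primary(records: pd.DataFrame) -> FitResult:
    """Fit the reference model and report the intervention odds ratio.

    ``records`` may be client-level (one row per client) or already
    aggregated to cluster-period counts.
    """
    return _fit(records, REFERENCE_SPEC)


def fit_sensitivity(records: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit a sensitivity model with the requested fixed and random terms."""
    return _fit(records, spec)


def fit_per_standard(records: pd.DataFrame, standard: str) -> FitResult:
    """Secondary analysis restricted to a single standard.

    Per-standard data are sparse in this design and prone to imbalance when
    facilities drop out; results should be interpreted with caution, which
    this function signals with a warning.
    """
    warnings.warn(
        "Per-standard analyses use sparse data and are prone to design "
        "imbalance; interpret with caution and only as a secondary analysis.",
        UserWarning,
        stacklevel=2,
    )
    agg = _as_aggregated(records)
    sub = agg[agg["standard"] == standard]
    if sub.empty:
        raise FitError(f"no records for standard {standard!r}")
    spec = ModelSpec(
        fixed_terms=("intervention", "month"),
        random_terms=("facility", "facility_month"),
    )
    return _fit(sub, spec)


# ---------------------------------------------------------------------------
# Gaussian-approximation (GLS) route
# ---------------------------------------------------------------------------


def gls_wald(
    records: pd.DataFrame,
    sigma2: float,
    corr: CorrelationModel,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Wald test of the intervention effect on cluster-period proportions.

    Fits intercept + month indicators + treatment by GLS, with each
    facility x standard pseudo-cluster given the known discrete-time-decay
    covariance (``sigma2``, ``corr``).  This is the Gaussian-approximation
    route used to cross-check the analytic power calculation; it is not the
    reference analysis.
    """
    agg = _as_aggregated(records).reset_index(drop=True)
    if agg.empty:
        raise FitError("no records supplied")
    months = sorted(agg["month"].unique())
    col = {mth: i for i, mth in enumerate(months[1:])}
    p = 1 + len(col) + 1
    A = np.zeros((p, p))
    b = np.zeros(p)
    for (_, _), idx in agg.groupby(["facility_id", "standard"], sort=True).groups.items():
        sub = agg.iloc[np.asarray(idx)]
        k = len(sub)
        X = np.zeros((k, p))
        X[:, 0] = 1.0
        for i, mth in enumerate(sub["month"]):
            if mth in col:
                X[i, 1 + col[mth]] = 1.0
        X[:, -1] = sub["exposure"].to_numpy(dtype=float)
        yf = (sub["n_compliant"] / sub["n"]).to_numpy(dtype=float)
        V = cluster_period_covariance(
            sub["month"].tolist(), int(sub["n"].iloc[0]), sigma2, corr
        )
        Vi = np.linalg.inv(V)
        A += X.T @ Vi @ X
        b += X.T @ Vi @ yf
    coef = np.linalg.solve(A, b)
    cov = np.linalg.inv(A)
    theta = float(coef[-1])
    se = float(np.sqrt(cov[-1, -1]))
    z = theta / se
    z_crit = float(stats.norm.ppf(1 - alpha / 2))
    return {
        "theta_hat": theta,
        "se": se,
        "z": z,
        "reject": float(abs(z) > z_crit),
        "p_value": float(2 * stats.norm.sf(abs(z))),
    }
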