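"""Client-level simulation of compliance outcomes for M-DISW-CRT schedules.

The generator mirrors the analysis model: for the client-level binary outcome
(care compliant with the audited standard or not), the log-odds of compliance
at a collection event are

    logit p = mu + month_effect + standard_effect + theta * exposure
              + lag_coef * months_since_intervention * exposure
              + u_facility + w_{facility, month} + b_{facility, standard}

with u, w, b independent centred normal random effects.  ``w`` captures
facility-specific secular fluctuation (month-by-facility interaction); it is
i.i.d. across months by default, with an optional AR(1) decay so simulated
data can match the discrete-time-decay correlation structure assumed in
power calculations.  Each collection event samples ``m`` independent clients
(cross-sectional sampling: clients are not followed over months).

A second generator, :func:`simulate_marginal_trial`, works directly on the
proportion scale with Gaussian cluster-period effects whose covariance is
exactly the discrete-time-decay model used by :mod:`mdisw.power_calc`; it is
the natural companion for validating analytic power against Monte-Carlo
rejection rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design_core import ExposureState, FacilitySchedule
from .power_calc import CorrelationModel, binary_sigma2

__all__ = [
    "GenerativeParams",
    "RECORD_COLUMNS",
    "event_table",
    "simulate_trial",
    "simulate_marginal_trial",
    "records_to_csv",
    "csv_to_records",
]

RECORD_COLUMNS = [
    "facility_id",
    "stratum",
    "month",
    "standard",
    "exposure",
    "months_since_intervention",
    "compliant",
]


@dataclass
class GenerativeParams:
    """Parameters of the generative logistic mixed model.

    All effects are on the log-odds scale.  ``month_effects`` and
    ``standard_effects`` map month / standard id to a fixed offset (absent
    keys mean 0).  The default random-effect SDs are illustrative values for
    a moderately heterogeneous set of facilities, not estimates from any
    particular trial.
    """

    mu: float = 0.0
    theta: float = 0.0
    month_effects: Mapping[int, float] = field(default_factory=dict)
    standard_effects: Mapping[str, float] = field(default_factory=dict)
    sigma_u: float = 0.3
    sigma_w: float = 0.2
    sigma_fs: float = 0.0
    lag_coef: float = 0.0
    w_decay: float | None = None
    m: int = 25

    def __post_init__(self) -> None:
        for name in ("sigma_u", "sigma_w", "sigma_fs"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.w_decay is not None and not 0.0 < self.w_decay <= 1.0:
            raise ValueError("w_decay must lie in (0, 1]")
        if self.m < 1:
            raise ValueError("m must be at least 1")


def event_table(schedules: Sequence[FacilitySchedule]) -> pd.DataFrame:
    """One row per collection event: facility, stratum, month, standard, exposure."""
    rows = []
    for sched in schedules:
        for ev in sched.collection_events():
            rows.append(
                (
                    sched.facility_id,
                    sched.stratum,
                    ev.month,
                    ev.standard,
                    ev.exposure,
                    ev.months_since_intervention,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "facility_id",
            "stratum",
            "month",
            "standard",
            "exposure",
            "months_since_intervention",
        ],
    )


def _ar1_effects(rng: np.random.Generator, months: np.ndarray, sigma: float, decay: float):
    """Stationary AR(1) sequence over integer months, marginal SD ``sigma``."""
    w = np.zeros(len(months))
    prev_month = None
    prev = 0.0
    for i, mth in enumerate(months):
        if prev_month is None:
            prev = sigma * rng.standard_normal()
        else:
            gap = int(mth - prev_month)
            phi = decay**gap
            prev = phi * prev + sigma * np.sqrt(1.0 - phi**2) * rng.standard_normal()
        w[i] = prev
        prev_month = mth
    return w


def simulate_trial(
    schedules: Sequence[FacilitySchedule],
    params: GenerativeParams,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Draw client-level compliance records under the logistic mixed model.

    Returns a DataFrame with one row per client
    (``m x number of collection events`` rows) and the columns of
    :data:`RECORD_COLUMNS`.  Fully reproducible from ``seed``.
    """
    rng = np.random.default_rng(seed)
    events = event_table(schedules)
    n_events = len(events)
    if n_events == 0:
        return pd.DataFrame(columns=RECORD_COLUMNS)

    eta = np.full(n_events, params.mu, dtype=float)
    eta += events["month"].map(lambda t: params.month_effects.get(t, 0.0)).to_numpy()
    eta += events["standard"].map(lambda s: params.standard_effects.get(s, 0.0)).to_numpy()
    exposure = events["exposure"].to_numpy()
    eta += params.theta * exposure
    eta += params.lag_coef * events["months_since_intervention"].to_numpy() * exposure

    # random effects, drawn facility by facility in a fixed order
    for fid, idx in events.groupby("facility_id", sort=True).groups.items():
        idx = np.asarray(idx)
        eta[idx] += params.sigma_u * rng.standard_normal()
        months = np.unique(events.loc[idx, "month"].to_numpy())
        if params.w_decay is None:
            w_vals = params.sigma_w * rng.standard_normal(len(months))
        else:
            w_vals = _ar1_effects(rng, months, params.sigma_w, params.w_decay)
        w_map = dict(zip(months.tolist(), w_vals))
        eta[idx] += events.loc[idx, "month"].map(w_map).to_numpy()
        if params.sigma_fs > 0:
            stds = np.unique(events.loc[idx, "standard"].to_numpy())
            b_map = dict(
                zip(stds.tolist(), params.sigma_fs * rng.standard_normal(len(stds)))
            )
            eta[idx] += events.loc[idx, "standard"].map(b_map).to_numpy()

    p = 1.0 / (1.0 + np.exp(-eta))
    compliant = rng.binomial(1, np.repeat(p, params.m))
    out = events.loc[events.index.repeat(params.m)].reset_index(drop=True)
    out["compliant"] = compliant
    return out[RECORD_COLUMNS]


def simulate_marginal_trial(
    schedules: Sequence[FacilitySchedule],
    p0: float,
    delta: float,
    corr: CorrelationModel,
    m: int = 25,
    seed: int | None = 0,
    sigma2_convention: str = "average",
) -> pd.DataFrame:
    """Draw client records from the proportion-scale (marginal) model.

    Each facility x standard pseudo-cluster receives a Gaussian effect
    process over its collection months with covariance
    sigma2 * rho * r^{|j-k|} — exactly the between-period block of the
    discrete-time-decay model — and clients are conditionally independent
    Bernoulli(p0 + delta * exposure + effect), with probabilities clipped to
    [0, 1].  The marginal client variance then matches the working sigma2 of
    the analytic power routine (up to clipping, negligible for moderate icc).
    """
    rng = np.random.default_rng(seed)
    events = event_table(schedules)
    if len(events) == 0:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    sigma2 = binary_sigma2(p0, p0 + delta, sigma2_convention)
    rho, r = corr.icc, corr.cac

    p = p0 + delta * events["exposure"].to_numpy(dtype=float)
    effects = np.zeros(len(events))
    for (_, _), idx in events.groupby(["facility_id", "standard"], sort=True).groups.items():
        idx = np.asarray(idx)
        months = events.loc[idx, "month"].to_numpy(dtype=float)
        lag = np.abs(months[:, None] - months[None, :])
        cov = sigma2 * rho * r**lag
        if rho > 0:
            chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(idx)))
            effects[idx] = chol @ rng.standard_normal(len(idx))
    p = np.clip(p + effects, 0.0, 1.0)
    compliant = rng.binomial(1, np.repeat(p, m))
    out = events.loc[events.index.repeat(m)].reset_index(drop=True)
    out["compliant"] = compliant
    return out[RECORD_COLUMNS]


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------


def records_to_csv(records: pd.DataFrame, path) -> None:
    """Write client records to CSV with the canonical header."""
    records = records[RECORD_COLUMNS]
    records.to_csv(path, index=False)


def csv_to_records(path) -> pd.DataFrame:
    """Read client records, validating the header and every row.

    Malformed rows are reported with their (1-based, header-inclusive) line
    numbers.
    """
    df = pd.read_csv(path, dtype={"facility_id": str, "standard": str})
    if list(df.columns) != RECORD_COLUMNS:
        raise ValueError(
            f"expected header {RECORD_COLUMNS}, found {list(df.columns)}"
        )
    bad: list[int] = []
    for col in ("exposure", "compliant"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad_mask = ~vals.isin([0, 1])
        bad.extend((df.index[bad_mask] + 2).tolist())
    for col in ("month", "stratum", "months_since_intervention"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad_mask = vals.isna() | (vals < 0) | (vals != vals.round())
        bad.extend((df.index[bad_mask] + 2).tolist())
    if bad:
        lines = ", ".join(str(b) for b in sorted(set(bad)))
        raise ValueError(f"malformed client records at line(s): {lines}")
    for col in ("month", "stratum", "exposure", "months_since_intervention", "compliant"):
        df[col] = df[col].astype(int)
    return df[RECORD_COLUMNS]
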