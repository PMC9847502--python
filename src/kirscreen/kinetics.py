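"""Population kinetics of proliferating cell cultures.

The model: a well holds ``N(t)`` live nuclei and ``M(t)`` cumulative dead
cells. The per-capita proliferation rate is ``p(t) = (dN/dt)/N`` and the
death rate ``d(t) = (dM/dt)/N``; the birth rate is their sum,
``b(t) = p(t) + d(t)``. When rates are constant the trajectory is
exponential, ``N(t) = N0 * exp(kP * t)``.

Endpoint estimators summarise a whole well in three numbers::

    kP = (N(tend) - N(t0)) / (Nbar * (tend - t0))
    kD = (M(tend) - M(t0)) / (Nbar * (tend - t0))
    kB = kP + kD

with ``Nbar`` the endpoint mean ``(N(t0) + N(tend)) / 2``. On exact
exponential data with rate ``r`` this estimator returns
``(2/dt) * tanh(r*dt/2)`` — it converges to ``r`` as the window shrinks,
with relative bias bounded by ``(r*dt)**2 / 12``. A compatibility flag
selects the endpoint-*sum* normalisation instead (which converges to
``r/2`` and is retained only for comparison with legacy analyses).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import savgol_filter

from .errors import MissingControlError, UndefinedRateError, ValidationError

__all__ = [
    "WellTrajectory",
    "RateEstimate",
    "RateTimeCourse",
    "ExponentialFit",
    "estimate_rates",
    "fit_exponential",
    "instantaneous_rates",
    "average_rate_timecourse",
    "delta_vs_control",
    "rates_table",
    "phenotype_table",
]


@dataclass
class WellTrajectory:
    """Time-stamped live and dead cell counts for one well.

    Parameters
    ----------
    well_id : str
        Identifier, unique within a screen.
    times : array-like of float
        Imaging times in hours, strictly increasing, length >= 2.
    nuclei : array-like
        Live-nucleus counts ``N(t)``, nonnegative.
    dead : array-like
        Cumulative dead-cell counts ``M(t)``, nonnegative. Expected
        non-decreasing; a violation (possible with noisy counting) raises a
        warning and sets :attr:`dead_monotone` to ``False`` rather than
        failing.
    condition : mapping, optional
        Platemap metadata (growth factor, doses, inhibitor, siRNA, ...).
    events : dict, optional
        Simulator-internal event log (birth/death times, noise-free counts);
        ``None`` for measured data.
    """

    well_id: str
    times: np.ndarray
    nuclei: np.ndarray
    dead: np.ndarray
    condition: Mapping | None = None
    events: dict | None = None
    dead_monotone: bool = field(init=False, default=True)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.nuclei = np.asarray(self.nuclei, dtype=float)
        self.dead = np.asarray(self.dead, dtype=float)
        n = len(self.times)
        if n < 2:
            raise ValidationError("trajectory needs at least two time points")
        if len(self.nuclei) != n or len(self.dead) != n:
            raise ValidationError("times, nuclei and dead must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(self.nuclei < 0) or np.any(self.dead < 0):
            raise ValidationError("counts must be nonnegative")
        if np.any(np.diff(self.dead) < 0):
            self.dead_monotone = False
            warnings.warn(
                f"well {self.well_id}: dead-cell count decreases over time "
                "(noisy input?); proceeding",
                stacklevel=2,
            )

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])


@dataclass(frozen=True)
class RateEstimate:
    """Endpoint rate summary of one well; ``k_b == k_p + k_d`` always."""

    k_p: float
    k_d: float
    k_b: float
    n_bar: float
    window: tuple[float, float]


@dataclass(frozen=True)
class ExponentialFit:
    """Least-squares exponential fit ``N(t) = n0 * exp(k_p * t)``."""

    n0: float
    k_p: float
    r_squared: float


@dataclass(frozen=True)
class RateTimeCourse:
    """Smoothed time-dependent rates; ``b_t == p_t + d_t`` pointwise.

    Points where the smoothed nucleus count is nonpositive carry NaN.
    """

    times: np.ndarray
    p_t: np.ndarray
    b_t: np.ndarray
    d_t: np.ndarray
    smoothing: str


def _window_indices(traj: WellTrajectory, window: tuple[float, float] | None) -> tuple[int, int]:
    if window is None:
        return 0, len(traj.times) - 1
    t0, t1 = window
    i0 = np.flatnonzero(np.isclose(traj.times, t0))
    i1 = np.flatnonzero(np.isclose(traj.times, t1))
    if i0.size == 0 or i1.size == 0:
        raise ValidationError(
            f"window endpoints ({t0}, {t1}) must coincide with sampled times"
        )
    a, b = int(i0[0]), int(i1[0])
    if a >= b:
        raise UndefinedRateError("window must have positive length")
    return a, b


def estimate_rates(
    traj: WellTrajectory,
    window: tuple[float, float] | None = None,
    nbar_convention: str = "endpoint_mean",
) -> RateEstimate:
    """Endpoint estimators kP, kD, kB over a time window.

    Parameters
    ----------
    traj : WellTrajectory
    window : (t0, tend), optional
        Endpoints must coincide with sampled times. Default: full span.
    nbar_convention : {"endpoint_mean", "endpoint_sum"}
        Normalisation of the count change. ``endpoint_mean`` (default) uses
        ``(N(t0)+N(tend))/2`` and is consistent with the exponential model;
        ``endpoint_sum`` divides by the raw sum (legacy compatibility; halves
        every rate).
    """
    a, b = _window_indices(traj, window)
    n0, n1 = traj.nuclei[a], traj.nuclei[b]
    m0, m1 = traj.dead[a], traj.dead[b]
    dt = traj.times[b] - traj.times[a]
    if nbar_convention == "endpoint_mean":
        n_bar = (n0 + n1) / 2.0
    elif nbar_convention == "endpoint_sum":
        n_bar = n0 + n1
    else:
        raise ValidationError(f"unknown nbar_convention {nbar_convention!r}")
    if n_bar <= 0:
        raise UndefinedRateError("mean nucleus count over the window is zero")
    k_p = (n1 - n0) / (n_bar * dt)
    k_d = (m1 - m0) / (n_bar * dt)
    return RateEstimate(
        k_p=float(k_p),
        k_d=float(k_d),
        k_b=float(k_p + k_d),
        n_bar=float(n_bar),
        window=(float(traj.times[a]), float(traj.times[b])),
    )


def fit_exponential(
    traj: WellTrajectory, window: tuple[float, float] | None = None
) -> ExponentialFit:
    """Fit ``N(t) = n0 * exp(k_p * t)`` by least squares on ``log N``."""
    a, b = _window_indices(traj, window)
    t = traj.times[a : b + 1]
    n = traj.nuclei[a : b + 1]
    if len(t) < 3:
        raise ValidationError("exponential fit needs at least three points")
    if np.any(n <= 0):
        raise ValidationError("exponential fit requires strictly positive counts")
    res = stats.linregress(t, np.log(n))
    return ExponentialFit(
        n0=float(np.exp(res.intercept)),
        k_p=float(res.slope),
        r_squared=float(res.rvalue**2) if len(t) > 2 else 1.0,
    )


def instantaneous_rates(
    traj: WellTrajectory, smoothing_hours: float = 10.0
) -> RateTimeCourse:
    """Smoothed time-dependent per-capita rates p(t), b(t), d(t).

    Counts are smoothed by a local quadratic (Savitzky-Golay) filter whose
    window spans ``smoothing_hours`` of samples (mirror-padded ends);
    derivatives are central differences on the smoothed series. Points where
    the smoothed nucleus count is nonpositive are masked with NaN.
    """
    if len(traj.times) < 5:
        raise ValidationError("instantaneous rates need at least five points")
    dt = float(np.median(np.diff(traj.times)))
    win = max(3, int(round(smoothing_hours / dt)) + 1)
    if win % 2 == 0:
        win += 1
    win = min(win, len(traj.times) if len(traj.times) % 2 else len(traj.times) - 1)
    n_s = savgol_filter(traj.nuclei, win, 2, mode="mirror")
    m_s = savgol_filter(traj.dead, win, 2, mode="mirror")
    dn = np.gradient(n_s, traj.times)
    dm = np.gradient(m_s, traj.times)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_t = np.where(n_s > 0, dn / n_s, np.nan)
        d_t = np.where(n_s > 0, dm / n_s, np.nan)
    return RateTimeCourse(
        times=traj.times.copy(),
        p_t=p_t,
        b_t=p_t + d_t,
        d_t=d_t,
        smoothing=f"savgol(window={win} samples, order=2, mode=mirror)",
    )


def average_rate_timecourse(
    trajectories: Sequence[WellTrajectory], smoothing_hours: float = 10.0
) -> RateTimeCourse:
    """Pointwise mean of per-well rate curves over replicate wells.

    All trajectories must share the same imaging grid.
    """
    if not trajectories:
        raise ValidationError("no trajectories supplied")
    ref = trajectories[0].times
    curves = []
    for traj in trajectories:
        if len(traj.times) != len(ref) or not np.allclose(traj.times, ref):
            raise ValidationError("replicate wells must share the imaging grid")
        curves.append(instantaneous_rates(traj, smoothing_hours))
    p = np.nanmean([c.p_t for c in curves], axis=0)
    d = np.nanmean([c.d_t for c in curves], axis=0)
    return RateTimeCourse(
        times=ref.copy(),
        p_t=p,
        b_t=p + d,
        d_t=d,
        smoothing=curves[0].smoothing + f"; mean of {len(curves)} wells",
    )


def delta_vs_control(case: RateEstimate, control: RateEstimate) -> float:
    """Proliferation-rate difference of a treated well vs its matched control."""
    return case.k_p - control.k_p


def rates_table(
    trajectories: Iterable[WellTrajectory],
    window: tuple[float, float] | None = None,
    nbar_convention: str = "endpoint_mean",
    include_fit: bool = True,
) -> pd.DataFrame:
    """Per-well rate summary table (one row per well).

    Columns: well_id, k_p, k_d, k_b, window_start_h, window_end_h, fit_r2.
    ``fit_r2`` is the r-squared of the exponential fit, NaN where the fit is
    undefined (nonpositive counts in the window).
    """
    rows = []
    for traj in trajectories:
        est = estimate_rates(traj, window=window, nbar_convention=nbar_convention)
        r2 = np.nan
        if include_fit:
            try:
                r2 = fit_exponential(traj, window=window).r_squared
            except ValidationError:
                pass
        rows.append(
            {
                "well_id": traj.well_id,
                "k_p": est.k_p,
                "k_d": est.k_d,
                "k_b": est.k_b,
                "window_start_h": est.window[0],
                "window_end_h": est.window[1],
                "fit_r2": r2,
            }
        )
    return pd.DataFrame(rows)


def phenotype_table(rates: pd.DataFrame, platemap: pd.DataFrame) -> pd.DataFrame:
    """Replicate-averaged Delta k_p of each (growth factor, inhibitor, dose).

    Each treated well is referenced to the mean k_p of the vehicle-control
    (DMSO) wells for the same growth factor on the same plate; replicate
    wells of a condition are then averaged.

    Returns columns: growth_factor, inhibitor_id, dose_uM, delta_kp,
    n_replicates.
    """
    merged = rates.merge(platemap, on="well_id", how="inner", validate="1:1")
    if len(merged) < len(rates):
        missing = set(rates["well_id"]) - set(platemap["well_id"])
        raise ValidationError(f"wells missing from platemap: {sorted(missing)[:5]} ...")
    controls = (
        merged[merged["is_control"]]
        .groupby(["plate_id", "growth_factor"])["k_p"]
        .mean()
    )
    treated = merged[
        (~merged["is_control"]) & merged["inhibitor_id"].notna()
    ].copy()
    key = list(zip(treated["plate_id"], treated["growth_factor"]))
    missing_plates = sorted({k for k in key if k not in controls.index})
    if missing_plates:
        raise MissingControlError(
            f"plates without matched vehicle controls: {missing_plates}"
        )
    treated["delta_kp"] = treated["k_p"].to_numpy() - controls.loc[key].to_numpy()
    out = (
        treated.groupby(["growth_factor", "inhibitor_id", "inhibitor_dose_uM"])
        .agg(delta_kp=("delta_kp", "mean"), n_replicates=("delta_kp", "size"))
        .reset_index()
        .rename(columns={"inhibitor_dose_uM": "dose_uM"})
    )
    return out
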