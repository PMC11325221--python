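"""First-order enzyme-inactivation kinetics from residual-activity series.

The workflow mirrors a plate-reader stability screen: raw NADH-formation
slopes become volumetric activities, activities become residual
activities A_R(t) in percent of the activity measured 20 min after
preparing each enzyme/solvent stock (time zero, defined as 100%), and
the decay of A_R is fitted with the first-order model

    A_R(t) = A_R,0 · exp(−k·t),    t_1/2 = ln 2 / k.

Residual activities above 100% occur routinely in viscous solvents
("overstabilization") during the first days of incubation; for kinetic
modelling those points are censored before fitting.

The canonical rate-constant unit is h⁻¹, with the day⁻¹ value carried
alongside (k_per_day = 24 · k_per_h): fits run on day-scaled time axes
but rate constants are typically quoted per hour, and keeping both
first-class avoids silent 24× unit errors.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ActivityAssay",
    "ActivityTimeSeries",
    "InactivationFit",
    "activity_from_slope",
    "residual_series",
    "censor_series",
    "fit_first_order",
    "half_life",
    "K_FAST_SENTINEL_PER_H",
]

logger = logging.getLogger(__name__)

#: Sentinel rate (h⁻¹) for series that are dead from the second point onward —
#: decay faster than the sampling cadence can resolve.
K_FAST_SENTINEL_PER_H = 51.0

HOURS_PER_DAY = 24.0


@dataclass(frozen=True)
class ActivityAssay:
    """One spectrophotometric activity measurement (NADH at 340 nm).

    ``slope`` is the absorbance change per minute; ``epsilon`` the NADH
    extinction coefficient (cm²·mmol⁻¹) and ``path_length`` the optical
    path of a 96-well plate well (cm).
    """

    slope: float
    epsilon: float = 6220.0
    path_length: float = 0.61

    def __post_init__(self) -> None:
        if not self.epsilon > 0:
            raise ValueError("extinction coefficient must be positive")
        if not self.path_length > 0:
            raise ValueError("path length must be positive")


def activity_from_slope(assay: ActivityAssay) -> float:
    """Volumetric activity A = (ΔA/Δt)·10⁶ / (ε·d) in µmol·min⁻¹·dm⁻³."""
    return assay.slope * 1e6 / (assay.epsilon * assay.path_length)


@dataclass(frozen=True)
class ActivityTimeSeries:
    """Residual activity (%) over time (days since time zero)."""

    times: np.ndarray
    residual: np.ndarray
    label: str = ""
    censored_n: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        r = np.asarray(self.residual, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "residual", r)
        if t.ndim != 1 or r.ndim != 1 or t.size != r.size:
            raise ValueError(f"{self.label}: times and residual must align")
        if t.size and t[0] < 0:
            raise ValueError(f"{self.label}: times must be non-negative")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"{self.label}: times must be strictly increasing")
        if not np.all(np.isfinite(r)):
            raise ValueError(f"{self.label}: residual values must be finite")

    @property
    def n_points(self) -> int:
        return int(self.times.size)


@dataclass(frozen=True)
class InactivationFit:
    """Fitted first-order inactivation parameters for one enzyme × solvent."""

    k_per_h: float
    k_per_day: float
    A_R0: float
    t_half_days: float
    k_stderr_per_day: float
    A_R0_stderr: float
    n_used: int
    label: str = ""
    flags: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.k_per_day < 0:
            raise ValueError(f"{self.label}: rate constant must be non-negative")
        if math.isfinite(self.k_per_day) and self.k_per_day > 0:
            if abs(self.t_half_days * self.k_per_day - math.log(2)) > 1e-12 * math.log(2):
                raise ValueError(f"{self.label}: t_half inconsistent with k")


def residual_series(
    raw: list[tuple[float, float]],
    t0_activity: float,
    label: str = "",
) -> ActivityTimeSeries:
    """Express raw activities as percent of the time-zero activity.

    ``raw`` holds (time_days, activity) pairs *after* time zero; the
    time-zero entry (exactly 100%) is prepended.
    """
    if not t0_activity > 0:
        raise ValueError(f"{label}: time-zero activity must be positive")
    times = [0.0] + [t for t, _ in raw]
    residual = [100.0] + [100.0 * a / t0_activity for _, a in raw]
    return ActivityTimeSeries(
        times=np.array(times), residual=np.array(residual), label=label
    )


def censor_series(
    series: ActivityTimeSeries,
    policy: str = "drop_over_100",
) -> ActivityTimeSeries:
    """Remove residual activities exceeding 100% before kinetic fitting.

    With ``drop_over_100`` every point with residual > 100 is removed;
    the time-zero point is exactly 100 by construction and is always
    retained.  ``keep_all`` returns the series unchanged.  Series left
    with fewer than 3 points are flagged unfittable by ``fit_first_order``.
    """
    if policy == "keep_all":
        return series
    if policy != "drop_over_100":
        raise ValueError(f"unknown censoring policy {policy!r}")
    keep = series.residual <= 100.0
    removed = int((~keep).sum())
    if removed:
        logger.info("%s: censored %d residual-activity points > 100%%",
                    series.label or "series", removed)
    return ActivityTimeSeries(
        times=series.times[keep],
        residual=series.residual[keep],
        label=series.label,
        censored_n=series.censored_n + removed,
    )


class FitError(RuntimeError):
    """Non-convergence of the inactivation fit; carries the best candidate."""

    def __init__(self, message: str, best: InactivationFit | None = None):
        super().__init__(message)
        self.best = best


def _loglinear_init(t: np.ndarray, r: np.ndarray) -> tuple[float, float]:
    """Initial (A_R0, k_day) from log-linear regression on positive residuals."""
    pos = r > 0
    if pos.sum() >= 2 and np.ptp(t[pos]) > 0:
        coeffs = np.polyfit(t[pos], np.log(r[pos]), 1)
        k0 = max(-coeffs[0], 0.0)
        a0 = float(np.exp(coeffs[1]))
    else:
        k0, a0 = 0.1, float(r.max(initial=100.0))
    return max(a0, 1e-6), k0


def fit_first_order(
    series: ActivityTimeSeries,
    fix_intercept: bool = False,
    max_restarts: int = 5,
) -> InactivationFit:
    """Fit A_R(t) = A_R,0·exp(−k·t) by bounded nonlinear least squares.

    Times are in days, so the optimized k is in day⁻¹ (constrained
    non-negative); the h⁻¹ value is derived.  Initialization comes from
    log-linear regression on the strictly positive residuals, with up to
    ``max_restarts`` jittered restarts on non-convergence.  Standard
    errors are asymptotic, from the Jacobian at the optimum.

    Zero residuals are retained (they witness fast decay), but a series
    that is zero from the second point onward decays faster than the
    sampling cadence can resolve: it is returned with the rate pinned to
    a large sentinel (≈51 h⁻¹) and a ``faster_than_resolvable`` flag
    rather than failing.
    """
    t = series.times
    r = series.residual
    n_min = 2 if fix_intercept else 3
    if series.n_points < n_min:
        raise FitError(
            f"{series.label}: {series.n_points} points after censoring, "
            f"need at least {n_min}"
        )
    flags: list[str] = []
    if series.censored_n:
        flags.append(f"censored_{series.censored_n}")

    if series.n_points >= 2 and np.all(r[1:] == 0.0):
        k_day = K_FAST_SENTINEL_PER_H * HOURS_PER_DAY
        return InactivationFit(
            k_per_h=K_FAST_SENTINEL_PER_H,
            k_per_day=k_day,
            A_R0=float(r[0]),
            t_half_days=math.log(2) / k_day,
            k_stderr_per_day=math.nan,
            A_R0_stderr=math.nan,
            n_used=series.n_points,
            label=series.label,
            flags=tuple(flags + ["faster_than_resolvable"]),
        )

    a0, k0 = _loglinear_init(t, r)

    if fix_intercept:
        a_fixed = float(r[0]) if t[0] == 0 else 100.0

        def resid(theta):
            return a_fixed * np.exp(-theta[0] * t) - r

        x0s = [np.array([k0])]
        lo, hi = np.array([0.0]), np.array([np.inf])
    else:

        def resid(theta):
            return theta[0] * np.exp(-theta[1] * t) - r

        x0s = [np.array([a0, k0])]
        lo, hi = np.array([1e-9, 0.0]), np.array([np.inf, np.inf])

    rng = np.random.default_rng(0)
    best = None
    for attempt in range(max_restarts + 1):
        x0 = x0s[0] if attempt == 0 else x0s[0] * np.exp(rng.normal(0, 0.3, x0s[0].size))
        x0 = np.clip(x0, lo + 1e-12, None)
        sol = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                            xtol=1e-10, ftol=1e-10, gtol=1e-10, max_nfev=200 * x0.size)
        if best is None or sol.cost < best.cost:
            best = sol
        if sol.success:
            best = sol if sol.cost <= best.cost else best
            break
    converged = best is not None and best.success

    if fix_intercept:
        k_day = float(best.x[0])
        A_R0 = a_fixed
        n_par = 1
    else:
        A_R0, k_day = float(best.x[0]), float(best.x[1])
        n_par = 2

    # asymptotic covariance from the Jacobian
    dof = series.n_points - n_par
    if dof > 0:
        s2 = 2.0 * best.cost / dof
        try:
            cov = s2 * np.linalg.inv(best.jac.T @ best.jac)
            errs = np.sqrt(np.maximum(np.diag(cov), 0.0))
        except np.linalg.LinAlgError:
            errs = np.full(n_par, np.nan)
    else:
        errs = np.full(n_par, np.nan)
    if fix_intercept:
        k_err, a_err = float(errs[0]), 0.0
    else:
        a_err, k_err = float(errs[0]), float(errs[1])

    if k_day <= 1e-10:  # below the fit's convergence tolerance: no decay
        k_day = 0.0
        t_half = math.inf
        flags.append("no_decay")
    else:
        t_half = math.log(2) / k_day

    fit = InactivationFit(
        k_per_h=k_day / HOURS_PER_DAY,
        k_per_day=k_day,
        A_R0=A_R0,
        t_half_days=t_half,
        k_stderr_per_day=k_err,
        A_R0_stderr=a_err,
        n_used=series.n_points,
        label=series.label,
        flags=tuple(flags),
    )
    if not converged:
        raise FitError(f"{series.label}: fit did not converge after "
                       f"{max_restarts} restarts", best=fit)
    return fit


def half_life(k: "float | InactivationFit", unit: str = "per_day") -> float:
    """Half-life in days from a first-order rate constant.

    ``k`` is either a rate constant (with ``unit`` naming its unit,
    ``per_day`` or ``per_h``) or an :class:`InactivationFit`, whose
    day⁻¹ rate is used.  A zero rate gives an infinite half-life.
    """
    if isinstance(k, InactivationFit):
        k, unit = k.k_per_day, "per_day"
    if k < 0:
        raise ValueError("rate constant must be non-negative")
    if k == 0:
        return math.inf
    if unit == "per_day":
        return math.log(2) / k
    if unit == "per_h":
        return math.log(2) / (k * HOURS_PER_DAY)
    raise ValueError(f"unknown unit {unit!r}")
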