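"""One-compartment oral pharmacokinetics.

The plasma model is the classical one-compartment disposition with
first-order absorption: after a dose ``D`` at time ``t_d``,

    Cp(t) = (D / (V/F)) * Ka/(Ka - Ke) * (exp(-Ke*dt) - exp(-Ka*dt)),

``dt = t - t_d``, with superposition over repeated doses.  The module also
provides the exact integral of that curve (used both for NCA cross-checks
and for interval-mean concentrations in the urate simulator), least-squares
fitting with the flip-flop resolved by the constraint Ka > Ke,
non-compartmental analysis (linear trapezoid, log-linear lambda_z), and the
dose-proportionality / ratio statistics used in phase-1 reporting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from . import units
from .errors import (
    DegenerateParameterError,
    FitConvergenceError,
    InsufficientDesignError,
    TerminalPhaseError,
    UninformativeDataError,
)

__all__ = [
    "PKParams",
    "DoseRegimen",
    "PlasmaProfile",
    "NCAResult",
    "PKFit",
    "PowerModelFit",
    "RatioResult",
    "AccumulationRatio",
    "concentration",
    "concentration_auc",
    "fit_pk",
    "nca",
    "auc_trapezoid",
    "accumulation_ratio",
    "theoretical_accumulation_ratio",
    "dose_proportionality",
    "geometric_mean_ratio",
]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class PKParams:
    """Oral one-compartment parameter triplet.

    v_f : apparent distribution volume V/F (mL)
    ka  : first-order absorption rate constant (1/h)
    ke  : first-order elimination rate constant (1/h)
    """

    v_f: float
    ka: float
    ke: float

    def __post_init__(self):
        if not (self.v_f > 0 and self.ka > 0 and self.ke > 0):
            raise ValueError("v_f, ka and ke must all be positive")
        if self.ka == self.ke:
            raise DegenerateParameterError(
                "ka == ke: one-compartment oral solution is degenerate"
            )

    @property
    def t_half(self) -> float:
        """Terminal half-life ln(2)/Ke (h)."""
        return math.log(2.0) / self.ke

    @property
    def cl_f(self) -> float:
        """Apparent oral clearance Ke * V/F (mL/h)."""
        return self.ke * self.v_f


@dataclass(frozen=True)
class DoseRegimen:
    """Repeated equal oral doses: ``dose_mg`` every ``interval_h`` hours,
    ``n_doses`` times, first dose at ``start_time_h``."""

    dose_mg: float
    interval_h: float = 24.0
    n_doses: int = 1
    start_time_h: float = 0.0

    def __post_init__(self):
        if self.dose_mg < 0:
            raise ValueError("dose_mg must be >= 0")
        if self.interval_h <= 0:
            raise ValueError("interval_h must be > 0")
        if self.n_doses < 1:
            raise ValueError("n_doses must be >= 1")

    @property
    def dose_ng(self) -> float:
        return units.mg_to_ng(self.dose_mg)

    def dose_times(self) -> np.ndarray:
        return self.start_time_h + self.interval_h * np.arange(self.n_doses)


@dataclass(frozen=True)
class PlasmaProfile:
    """Observed plasma concentration-time profile for one subject."""

    subject_id: str
    times: np.ndarray  # h, strictly increasing
    concentrations: np.ndarray  # ng/mL, >= 0
    regimen: DoseRegimen

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.shape != c.shape or t.ndim != 1:
            raise ValueError("times and concentrations must be equal-length 1-D")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("concentrations must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)


@dataclass(frozen=True)
class NCAResult:
    """Non-compartmental summary of a single-dose profile."""

    cmax: float  # ng/mL
    tmax: float  # h
    auc_0_24: float  # ng*h/mL
    auc_0_inf: float  # ng*h/mL
    t_half: float  # h
    cl_f: float  # mL/h
    lambda_z: float  # 1/h
    n_lambda_points: int
    interpolated_24h: bool = False


@dataclass(frozen=True)
class PKFit:
    """Least-squares compartmental fit with residual diagnostics."""

    params: PKParams
    rss: float
    cv_percent: dict[str, float]
    n_obs: int
    weighting: str
    converged: bool = True


@dataclass(frozen=True)
class PowerModelFit:
    """log(metric) = a + b*log(dose) with a 90% CI on the exponent b."""

    intercept: float
    slope: float
    slope_ci90: tuple[float, float]
    n: int

    def __post_init__(self):
        lo, hi = self.slope_ci90
        if not (lo <= self.slope <= hi):
            raise ValueError("CI must bracket the slope")


@dataclass(frozen=True)
class RatioResult:
    """Geometric mean ratio of paired observations with 90% CI."""

    gmr: float
    ci90: tuple[float, float]
    n_pairs: int

    def __post_init__(self):
        if self.gmr <= 0:
            raise ValueError("gmr must be positive")


@dataclass(frozen=True)
class AccumulationRatio:
    """R_AUC0-24: daily AUC on day N relative to day 1."""

    r_auc: float

    def __post_init__(self):
        if self.r_auc <= 0:
            raise ValueError("r_auc must be positive")


# ---------------------------------------------------------------------------
# model evaluation


def concentration(params: PKParams, regimen: DoseRegimen, t) -> np.ndarray | float:
    """Plasma concentration (ng/mL) at time(s) ``t`` under superposition.

    Zero before (and exactly at) each dose's administration time; continuous
    in ``t``; vectorized over array input.
    """
    t_arr = np.asarray(t, dtype=float)
    scalar = t_arr.ndim == 0
    t_arr = np.atleast_1d(t_arr)
    out = np.zeros_like(t_arr)
    amp = regimen.dose_ng / params.v_f * params.ka / (params.ka - params.ke)
    for td in regimen.dose_times():
        dt = t_arr - td
        m = dt > 0
        if np.any(m):
            out[m] += amp * (np.exp(-params.ke * dt[m]) - np.exp(-params.ka * dt[m]))
    return float(out[0]) if scalar else out


def _cum_single(params: PKParams, dose_ng: float, dt) -> np.ndarray:
    """Exact single-dose AUC from dose time to dose time + dt (dt >= 0)."""
    dt = np.maximum(np.asarray(dt, dtype=float), 0.0)
    amp = dose_ng / params.v_f * params.ka / (params.ka - params.ke)
    return amp * (
        (1.0 - np.exp(-params.ke * dt)) / params.ke
        - (1.0 - np.exp(-params.ka * dt)) / params.ka
    )


def concentration_auc(params: PKParams, regimen: DoseRegimen, t0, t1):
    """Exact integral of the concentration curve over [t0, t1] (ng*h/mL).

    ``t0``/``t1`` broadcast, so per-step interval means for a whole grid come
    from one call.
    """
    t0 = np.asarray(t0, dtype=float)
    t1 = np.asarray(t1, dtype=float)
    scalar = t0.ndim == 0 and t1.ndim == 0
    total = np.zeros(np.broadcast(t0, t1).shape)
    for td in regimen.dose_times():
        total += _cum_single(params, regimen.dose_ng, t1 - td) - _cum_single(
            params, regimen.dose_ng, t0 - td
        )
    return float(total) if scalar else total


def tmax_single_dose(params: PKParams) -> float:
    """Analytic time of the single-dose peak, ln(Ka/Ke)/(Ka-Ke)."""
    return math.log(params.ka / params.ke) / (params.ka - params.ke)


# ---------------------------------------------------------------------------
# non-compartmental analysis


def auc_trapezoid(times, conc, t0=None, t1=None) -> float:
    """Linear-trapezoid AUC of sampled data over [t0, t1].

    Window bounds need not coincide with samples; values there are linearly
    interpolated.  Bounds outside the sampled range raise.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t0 is None:
        t0 = t[0]
    if t1 is None:
        t1 = t[-1]
    if t0 < t[0] - 1e-9 or t1 > t[-1] + 1e-9:
        raise ValueError(f"window [{t0}, {t1}] extends beyond sampled range")
    inner = (t > t0) & (t < t1)
    grid = np.concatenate(([t0], t[inner], [t1]))
    vals = np.interp(grid, t, c)
    return float(np.trapezoid(vals, grid))


def _fit_lambda_z(t, c, min_points=3):
    """Greedy terminal log-linear regression.

    Starts from the last ``min_points`` positive post-peak samples and keeps
    extending one point back while the adjusted R^2 improves.
    Returns (lambda_z, n_points).
    """
    imax = int(np.argmax(c))
    idx = np.nonzero((np.arange(len(t)) > imax) & (c > 0))[0]
    if len(idx) < min_points:
        raise TerminalPhaseError(
            f"need >= {min_points} positive post-peak samples, have {len(idx)}"
        )

    def regress(k):
        sel = idx[-k:]
        res = stats.linregress(t[sel], np.log(c[sel]))
        r2adj = 1.0 - (1.0 - res.rvalue**2) * (k - 1) / (k - 2)
        return res.slope, r2adj

    k = min_points
    slope, r2adj = regress(k)
    while k < len(idx):
        slope_next, r2adj_next = regress(k + 1)
        if r2adj_next <= r2adj:
            break
        k, slope, r2adj = k + 1, slope_next, r2adj_next
    lam = -slope
    if lam <= 0:
        raise TerminalPhaseError("terminal slope is non-negative; lambda_z <= 0")
    return lam, k


def nca(profile: PlasmaProfile, regimen: DoseRegimen | None = None,
        min_lambda_points: int = 3) -> NCAResult:
    """Non-compartmental analysis of a single-dose profile.

    Cmax/Tmax by maximum (ties resolved to the earliest time), AUC0-24 by
    linear trapezoid (24 h value interpolated and flagged when not sampled),
    lambda_z by terminal log-linear regression, AUC0-inf by the Clast/lambda_z
    tail, CL/F = dose/AUC0-inf.
    """
    regimen = regimen or profile.regimen
    t = profile.times
    c = profile.concentrations
    imax = int(np.argmax(c))  # argmax returns the first (earliest) maximum
    cmax, tmax = float(c[imax]), float(t[imax])

    interpolated = not np.any(np.isclose(t, 24.0))
    if t[-1] < 24.0:
        raise InsufficientDesignError("profile does not extend to 24 h")
    auc24 = auc_trapezoid(t, c, t0=max(t[0], 0.0), t1=24.0)

    lam, n_lam = _fit_lambda_z(t, c, min_points=min_lambda_points)
    c_last_pos = c[c > 0][-1]
    auc_last = auc_trapezoid(t, c, t0=max(t[0], 0.0), t1=t[-1])
    auc_inf = auc_last + float(c_last_pos) / lam
    cl_f = regimen.dose_ng / auc_inf
    return NCAResult(
        cmax=cmax,
        tmax=tmax,
        auc_0_24=auc24,
        auc_0_inf=auc_inf,
        t_half=math.log(2.0) / lam,
        cl_f=cl_f,
        lambda_z=lam,
        n_lambda_points=n_lam,
        interpolated_24h=interpolated,
    )


# ---------------------------------------------------------------------------
# compartmental fitting


def _initial_guess(t, c, regimen: DoseRegimen) -> PKParams:
    """Heuristic start: Ka from observed Tmax, Ke from the terminal slope,
    V/F from dose/(AUC*Ke)."""
    imax = int(np.argmax(c))
    tmax_obs = max(t[imax] - regimen.start_time_h, 1e-3)
    ka0 = 3.0 / tmax_obs
    try:
        ke0, _ = _fit_lambda_z(t, c)
    except TerminalPhaseError:
        ke0 = 0.1
    ke0 = min(max(ke0, 1e-4), ka0 / 1.5)
    auc = np.trapezoid(c, t) + (c[c > 0][-1] / ke0 if np.any(c > 0) else 0.0)
    v0 = regimen.dose_ng / max(auc * ke0, 1e-12)
    return PKParams(v_f=v0, ka=ka0, ke=ke0)


def fit_pk(profile: PlasmaProfile, init: PKParams | None = None,
           weighting: str = "none") -> PKFit:
    """Least-squares fit of (V/F, Ka, Ke) to an observed profile.

    The flip-flop ambiguity of the oral one-compartment model is resolved by
    construction: the optimizer works in (log V/F, log Ke, log(Ka - Ke)), so
    Ka > Ke > 0 and V/F > 0 are structural.  Pre-dose samples are excluded
    from the objective.  ``weighting`` is "none" (unweighted, linear scale)
    or "inverse_y2" (residuals divided by the model prediction).

    Returns a :class:`PKFit` with the residual sum of squares and asymptotic
    per-parameter %CV from the numeric Jacobian.
    """
    if weighting not in ("none", "inverse_y2"):
        raise ValueError(f"unknown weighting {weighting!r}")
    reg = profile.regimen
    mask = profile.times > reg.start_time_h
    t = profile.times[mask]
    c = profile.concentrations[mask]
    if np.all(c == 0):
        raise UninformativeDataError("all post-dose concentrations are zero")
    if len(t) < 4:
        raise InsufficientDesignError("need >= 4 post-dose samples")
    imax = int(np.argmax(c))
    if np.sum(t < t[imax]) < 2 or np.sum(t > t[imax]) < 2:
        raise InsufficientDesignError(
            "need >= 2 samples on each of the ascending and descending limbs"
        )

    if init is None:
        init = _initial_guess(t, c, reg)
    if init.ka <= init.ke:
        init = PKParams(v_f=init.v_f, ka=init.ke * 2.0, ke=init.ke)
    x0 = np.log([init.v_f, init.ke, init.ka - init.ke])

    def unpack(x) -> PKParams:
        v_f, ke, dk = np.exp(x)
        return PKParams(v_f=v_f, ka=ke + dk, ke=ke)

    def residuals(x):
        pred = concentration(unpack(x), reg, t)
        r = pred - c
        if weighting == "inverse_y2":
            r = r / np.maximum(pred, 1e-6)
        return r

    sol = optimize.least_squares(
        residuals, x0, method="trf", xtol=1e-13, ftol=1e-13, gtol=1e-13,
        max_nfev=5000,
    )
    params = unpack(sol.x)
    rss = float(np.sum((concentration(params, reg, t) - c) ** 2))
    fit = PKFit(
        params=params,
        rss=rss,
        cv_percent=_asymptotic_cv(params, reg, t, rss, len(t)),
        n_obs=len(t),
        weighting=weighting,
        converged=bool(sol.success),
    )
    if not sol.success:
        raise FitConvergenceError("compartmental fit did not converge", best=fit)
    return fit


def _asymptotic_cv(params: PKParams, reg: DoseRegimen, t, rss, n) -> dict:
    """Asymptotic %CV of (v_f, ka, ke) from a central-difference Jacobian."""
    theta = np.array([params.v_f, params.ka, params.ke])
    dof = n - 3
    if dof <= 0:
        return {"v_f": float("nan"), "ka": float("nan"), "ke": float("nan")}
    J = np.empty((n, 3))
    for j in range(3):
        h = theta[j] * 1e-6
        up, dn = theta.copy(), theta.copy()
        up[j] += h
        dn[j] -= h
        J[:, j] = (
            concentration(PKParams(*up), reg, t) - concentration(PKParams(*dn), reg, t)
        ) / (2 * h)
    try:
        cov = rss / dof * np.linalg.pinv(J.T @ J)
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:  # pragma: no cover
        se = np.full(3, np.nan)
    cvs = 100.0 * se / theta
    return {"v_f": float(cvs[0]), "ka": float(cvs[1]), "ke": float(cvs[2])}


# ---------------------------------------------------------------------------
# summary statistics


def accumulation_ratio(auc_day1: float, auc_day_n: float) -> AccumulationRatio:
    """R_AUC0-24 = AUC0-24(day N) / AUC0-24(day 1)."""
    if auc_day1 <= 0 or auc_day_n <= 0:
        raise ValueError("both AUC values must be positive")
    return AccumulationRatio(r_auc=auc_day_n / auc_day1)


def theoretical_accumulation_ratio(ke: float, tau_h: float = 24.0) -> float:
    """Linear-PK steady-state accumulation, 1/(1 - exp(-Ke*tau))."""
    return 1.0 / (1.0 - math.exp(-ke * tau_h))


def dose_proportionality(points) -> PowerModelFit:
    """Power-model assessment: OLS of log(metric) on log(dose).

    ``points`` is an iterable of (dose_mg, metric) with metric > 0 and at
    least three distinct doses; the 90% CI for the exponent comes from the
    t distribution with n-2 degrees of freedom.
    """
    doses, metrics = map(np.asarray, zip(*points))
    if len(np.unique(doses)) < 3:
        raise InsufficientDesignError("power model needs >= 3 distinct doses")
    if np.any(metrics <= 0) or np.any(doses <= 0):
        raise ValueError("doses and metrics must be positive")
    res = stats.linregress(np.log(doses), np.log(metrics))
    n = len(doses)
    tcrit = stats.t.ppf(0.95, n - 2)
    half = tcrit * res.stderr
    return PowerModelFit(
        intercept=float(res.intercept),
        slope=float(res.slope),
        slope_ci90=(float(res.slope - half), float(res.slope + half)),
        n=n,
    )


def geometric_mean_ratio(paired) -> RatioResult:
    """Geometric mean ratio test/reference with a paired-t 90% CI on the log
    scale, back-transformed."""
    test, ref = map(np.asarray, zip(*paired))
    if len(test) < 2:
        raise InsufficientDesignError("need >= 2 pairs")
    if np.any(test <= 0) or np.any(ref <= 0):
        raise ValueError("paired values must be positive")
    d = np.log(test) - np.log(ref)
    n = len(d)
    mean = float(np.mean(d))
    se = float(np.std(d, ddof=1) / math.sqrt(n))
    tcrit = stats.t.ppf(0.95, n - 1)
    return RatioResult(
        gmr=math.exp(mean),
        ci90=(math.exp(mean - tcrit * se), math.exp(mean + tcrit * se)),
        n_pairs=n,
    )
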