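"""Serum-urate disposition physiology and the PD estimation cascade.

The body urate pool is treated as a single well-stirred compartment of
apparent volume Vd_UA: SUA = UA_pool / Vd_UA.  Urate enters at a constant
synthesis rate and leaves by two parallel first-order routes, renal
clearance CLR_UA and non-renal (gut) clearance CLGut_UA.  At baseline the
renal:non-renal split is 2:1, and renal handling is filtration minus
fractional tubular reabsorption:

    CLR_UA = GFR - f_reabs * GFR                       (baseline)
    CLR_UA = GFR - f_reabs * GFR * (1 - E(Cp))         (on drug)

where the drug relieves reabsorption through a simple Emax model
E(Cp) = Emax * Cp / (EC50 + Cp) in total plasma concentration.

The estimators here are the ones a phase-1 analysis runs on interval urine
collections and serum urate series: CLR_UA = Xu_UA/AUEC, the baseline
closure (Xf = Xu/2, CLGut = CLR/2, Synthesis = 3/2 Xu), the
delta-mass-balance volume Vd_UA = (dXu + dXf)/dSUA, the placebo-derived
f_reabs = 1 - CLR_UA/GFR, and the Emax fit to interval-mean effect points.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from . import units
from .errors import (
    InconsistentDeltaError,
    InsufficientDesignError,
    MissingIntervalError,
    NetSecretionError,
    NonIdentifiableError,
    FitConvergenceError,
)
from .pk import PlasmaProfile, auc_trapezoid

__all__ = [
    "UratePhysiology",
    "EmaxParams",
    "UrineInterval",
    "DeltaSummary",
    "EffectPoint",
    "BaselineRates",
    "EmaxFit",
    "clearance_from_excretion",
    "derive_baseline",
    "estimate_vd_ua",
    "estimate_freabs",
    "implied_gfr",
    "effect_fraction",
    "renal_clearance",
    "interval_means",
    "fit_emax",
    "DEFAULT_EFFECT_WINDOWS",
]

#: Evaluation windows for interval-mean effect points (h post-dose).
DEFAULT_EFFECT_WINDOWS = ((0.0, 6.0), (6.0, 12.0), (12.0, 24.0), (24.0, 48.0))

_CLOSURE_RTOL = 1e-6


@dataclass(frozen=True)
class EmaxParams:
    """Maximal fractional relief of reabsorption and the total plasma
    concentration at half-maximal effect."""

    emax: float  # dimensionless, (0, 1]
    ec50: float  # ng/mL

    def __post_init__(self):
        if not 0 < self.emax <= 1:
            raise ValueError("emax must be in (0, 1]")
        if self.ec50 <= 0:
            raise ValueError("ec50 must be positive")


@dataclass(frozen=True)
class UratePhysiology:
    """Urate mass-balance constants for one (possibly synthetic) subject.

    Clearances are stored in mL/min as printed clinically; the steady-state
    closure ``synthesis = (CLR + CLGut) * SUA`` and the 2:1 renal:gut split
    ``CLR = 2 * CLGut`` are enforced at construction (use
    :meth:`from_baseline` to build a consistent set).
    """

    vd_ua: float  # mL
    f_reabs: float  # dimensionless in [0, 1]
    gfr: float  # mL/min (BSA-normalized creatinine clearance)
    clgut_ua: float  # mL/min
    synthesis_rate: float  # mg/h
    baseline_sua: float  # mg/dL
    baseline_clr_ua: float  # mL/min

    def __post_init__(self):
        for name in ("vd_ua", "gfr", "clgut_ua", "synthesis_rate",
                     "baseline_sua", "baseline_clr_ua"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.f_reabs <= 1:
            raise ValueError("f_reabs must lie in [0, 1]")
        if not math.isclose(self.baseline_clr_ua, 2.0 * self.clgut_ua,
                            rel_tol=_CLOSURE_RTOL):
            raise ValueError("baseline renal:gut clearance ratio must be 2:1")
        expected = (
            units.ml_per_min_to_dl_per_h(self.baseline_clr_ua + self.clgut_ua)
            * self.baseline_sua
        )
        if not math.isclose(self.synthesis_rate, expected, rel_tol=_CLOSURE_RTOL):
            raise ValueError(
                "synthesis_rate must close the baseline steady state: "
                f"expected {expected:.6g} mg/h, got {self.synthesis_rate:.6g}"
            )
        base = self.gfr * (1.0 - self.f_reabs)
        if not math.isclose(self.baseline_clr_ua, base, rel_tol=_CLOSURE_RTOL):
            raise ValueError("baseline_clr_ua must equal GFR*(1 - f_reabs)")

    @classmethod
    def from_baseline(cls, sua_mg_dl: float, clr_ua_ml_min: float, *,
                      vd_ua_ml: float, f_reabs: float | None = None,
                      gfr_ml_min: float | None = None) -> "UratePhysiology":
        """Build a closed parameter set from the observable baselines.

        Exactly one of ``f_reabs`` / ``gfr_ml_min`` may be omitted; the other
        is implied through CLR_UA = GFR*(1 - f_reabs).
        """
        clgut = clr_ua_ml_min / 2.0
        if gfr_ml_min is None:
            if f_reabs is None:
                raise ValueError("supply f_reabs or gfr_ml_min")
            gfr_ml_min = implied_gfr(clr_ua_ml_min, f_reabs)
        elif f_reabs is None:
            f_reabs = estimate_freabs(clr_ua_ml_min, gfr_ml_min)
        synthesis = (
            units.ml_per_min_to_dl_per_h(clr_ua_ml_min + clgut) * sua_mg_dl
        )
        return cls(
            vd_ua=vd_ua_ml,
            f_reabs=f_reabs,
            gfr=gfr_ml_min,
            clgut_ua=clgut,
            synthesis_rate=synthesis,
            baseline_sua=sua_mg_dl,
            baseline_clr_ua=clr_ua_ml_min,
        )


@dataclass(frozen=True)
class UrineInterval:
    """One timed urine collection."""

    t_start: float  # h
    t_end: float  # h
    volume: float  # mL
    cu_ua: float  # urinary urate concentration, mg/mL

    def __post_init__(self):
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if self.volume < 0 or self.cu_ua < 0:
            raise ValueError("volume and concentration must be non-negative")

    @property
    def xu_ua(self) -> float:
        """Excreted urate amount over the interval (mg)."""
        return self.cu_ua * self.volume


@dataclass(frozen=True)
class DeltaSummary:
    """24 h changes versus baseline used by the volume estimator.

    d_xu_ua : increase in urinary urate excretion (mg, > 0 on drug)
    d_xf_ua : change in gut excretion (mg, signed; negative when SUA falls)
    d_sua   : magnitude of the SUA decrease (mg/dL, > 0)
    """

    d_xu_ua: float
    d_xf_ua: float
    d_sua: float


@dataclass(frozen=True)
class EffectPoint:
    """One interval-mean observation for the Emax fit."""

    cp_mean: float  # ng/mL
    clr_mean: float  # mL/min
    effect: float  # dimensionless, in [0, 1)

    def __post_init__(self):
        if self.cp_mean < 0:
            raise ValueError("cp_mean must be >= 0")
        if not 0 <= self.effect < 1:
            raise ValueError("effect must lie in [0, 1)")


@dataclass(frozen=True)
class BaselineRates:
    """Pre-dose quantities implied by the 2:1 renal:gut split."""

    xf_ua_mg_day: float
    clgut_ua_ml_min: float
    synthesis_mg_day: float


@dataclass(frozen=True)
class EmaxFit:
    params: EmaxParams
    cv_percent: dict[str, float]
    rss: float
    n: int


# ---------------------------------------------------------------------------
# estimators


def clearance_from_excretion(xu_ua_mg: float, auec_mg_h_dl: float) -> float:
    """CLR_UA = Xu_UA / AUEC, returned in mL/min.

    The ratio is natively in dL/h (mg per mg*h/dL); the factor 100/60
    converts to mL/min.
    """
    if auec_mg_h_dl <= 0:
        raise ValueError("auec must be positive")
    return units.dl_per_h_to_ml_per_min(xu_ua_mg / auec_mg_h_dl)


def derive_baseline(xu_ua_mg_day: float, clr_ua_ml_min: float) -> BaselineRates:
    """Pre-dose gut excretion, gut clearance and synthesis from the 2:1
    renal:non-renal split: Xf = Xu/2, CLGut = CLR/2, Synthesis = 3/2 Xu."""
    if xu_ua_mg_day < 0 or clr_ua_ml_min < 0:
        raise ValueError("inputs must be non-negative")
    return BaselineRates(
        xf_ua_mg_day=xu_ua_mg_day / 2.0,
        clgut_ua_ml_min=clr_ua_ml_min / 2.0,
        synthesis_mg_day=1.5 * xu_ua_mg_day,
    )


def estimate_vd_ua(delta: DeltaSummary) -> float:
    """Urate distribution volume (mL) from the 24 h delta mass balance,
    Vd_UA = (dXu_UA + dXf_UA) / dSUA with dSUA converted to mg/mL."""
    if delta.d_sua <= 0:
        raise ValueError("d_sua must be positive (SUA must fall)")
    num = delta.d_xu_ua + delta.d_xf_ua
    if num <= 0:
        raise InconsistentDeltaError(
            "net excretion change is non-positive while SUA fell"
        )
    return num / units.mg_per_dl_to_mg_per_ml(delta.d_sua)


def estimate_freabs(clr_ua_ml_min: float, gfr_ml_min: float) -> float:
    """Fractional tubular reabsorption, f_reabs = 1 - CLR_UA/GFR."""
    if gfr_ml_min <= 0:
        raise ValueError("gfr must be positive")
    if clr_ua_ml_min < 0:
        raise ValueError("clr_ua must be >= 0")
    if clr_ua_ml_min > gfr_ml_min:
        raise NetSecretionError(
            "renal urate clearance exceeds GFR (net secretion; outside model)"
        )
    return 1.0 - clr_ua_ml_min / gfr_ml_min


def implied_gfr(clr_ua_ml_min: float, f_reabs: float) -> float:
    """GFR implied by a baseline clearance and reabsorbed fraction,
    GFR = CLR_UA / (1 - f_reabs); used when no creatinine data accompany a
    simulation request."""
    if f_reabs >= 1:
        raise ValueError("f_reabs must be < 1 to imply a finite GFR")
    return clr_ua_ml_min / (1.0 - f_reabs)


def effect_fraction(emax_params: EmaxParams, cp) -> np.ndarray | float:
    """Fractional relief of reabsorption, E = Emax*Cp/(EC50 + Cp)."""
    cp_arr = np.asarray(cp, dtype=float)
    out = emax_params.emax * cp_arr / (emax_params.ec50 + cp_arr)
    return float(out) if out.ndim == 0 else out


def renal_clearance(phys: UratePhysiology, emax_params: EmaxParams,
                    cp) -> np.ndarray | float:
    """Drug-dependent renal urate clearance (mL/min),
    CLR_UA(Cp) = GFR - f_reabs*GFR*(1 - E(Cp)).

    Non-decreasing in Cp, bounded between the baseline GFR*(1 - f_reabs) and
    the asymptote GFR*(1 - f_reabs*(1 - Emax)).
    """
    e = effect_fraction(emax_params, cp)
    return phys.gfr - phys.f_reabs * phys.gfr * (1.0 - e)


def interval_means(profile: PlasmaProfile, urine, sua_times, sua_values, *,
                   gfr_ml_min: float, f_reabs: float,
                   windows=DEFAULT_EFFECT_WINDOWS) -> list[EffectPoint]:
    """Interval-mean effect points for the Emax fit.

    For each window: mean plasma concentration by trapezoid over the observed
    profile, AUEC likewise from the serum urate series, mean renal urate
    clearance as Xu_UA/AUEC from the urine collections tiling the window, and
    the observed effect back-calculated from the filtration-reabsorption
    relation, E = (CLR - GFR*(1 - f))/(f*GFR), clipped to [0, 1) with a
    warning when noise pushes it outside.
    """
    sua_times = np.asarray(sua_times, dtype=float)
    sua_values = np.asarray(sua_values, dtype=float)
    points = []
    for (w0, w1) in windows:
        width = w1 - w0
        if sua_times[0] > w0 + 1e-9 or sua_times[-1] < w1 - 1e-9:
            raise MissingIntervalError(f"SUA series does not cover [{w0}, {w1}] h")
        if profile.times[0] > w0 + 1e-9 or profile.times[-1] < w1 - 1e-9:
            raise MissingIntervalError(f"plasma profile does not cover [{w0}, {w1}] h")
        cp_mean = auc_trapezoid(profile.times, profile.concentrations, w0, w1) / width
        auec = auc_trapezoid(sua_times, sua_values, w0, w1)
        xu = _window_excretion(urine, w0, w1)
        clr = clearance_from_excretion(xu, auec)
        baseline = gfr_ml_min * (1.0 - f_reabs)
        effect = (clr - baseline) / (f_reabs * gfr_ml_min)
        if effect < 0 or effect >= 1:
            warnings.warn(
                f"back-calculated effect {effect:.3f} outside [0, 1) in window "
                f"[{w0}, {w1}] h; clipping", stacklevel=2,
            )
            effect = min(max(effect, 0.0), 1.0 - 1e-9)
        points.append(EffectPoint(cp_mean=cp_mean, clr_mean=clr, effect=effect))
    return points


def _window_excretion(urine, w0, w1, tol=1e-6) -> float:
    """Sum urate amounts over collections that exactly tile [w0, w1]."""
    inside = sorted(
        (u for u in urine if u.t_start >= w0 - tol and u.t_end <= w1 + tol),
        key=lambda u: u.t_start,
    )
    cursor = w0
    total = 0.0
    for u in inside:
        if abs(u.t_start - cursor) > tol:
            raise MissingIntervalError(
                f"urine collections do not tile [{w0}, {w1}] h (gap at {cursor} h)"
            )
        total += u.xu_ua
        cursor = u.t_end
    if abs(cursor - w1) > tol:
        raise MissingIntervalError(
            f"urine collections do not tile [{w0}, {w1}] h (end at {cursor} h)"
        )
    return total


def fit_emax(points, init: tuple[float, float] | None = None) -> EmaxFit:
    """Least-squares fit of the simple Emax model to effect points.

    ``points`` may be :class:`EffectPoint` objects or (cp, effect) pairs with
    at least three distinct concentrations.  ``init`` optionally overrides
    the data-driven (Emax0, EC50_0) starting values.  Reports estimates with
    asymptotic %CV; an estimate pinned at the Emax = 1 bound raises.
    """
    cp, eff = [], []
    for p in points:
        if isinstance(p, EffectPoint):
            cp.append(p.cp_mean)
            eff.append(p.effect)
        else:
            cp.append(p[0])
            eff.append(p[1])
    cp = np.asarray(cp, dtype=float)
    eff = np.asarray(eff, dtype=float)
    if len(np.unique(cp)) < 3:
        raise InsufficientDesignError("Emax fit needs >= 3 distinct concentrations")
    if np.all(eff <= 0):
        raise NonIdentifiableError("all effects are zero; EC50 is non-identifiable")

    if init is None:
        emax0 = min(float(np.max(eff)) * 1.2, 0.95)
        half = emax0 / 2.0
        above = cp[eff >= half]
        ec50_0 = float(np.min(above)) if len(above) else float(np.median(cp))
        init = (emax0, max(ec50_0, 1e-3))

    def model(c, emax, ec50):
        return emax * c / (ec50 + c)

    popt, pcov = optimize.curve_fit(
        model, cp, eff, p0=init, bounds=([1e-9, 1e-9], [1.0, np.inf]),
        xtol=1e-13, ftol=1e-13, maxfev=20000,
    )
    emax_hat, ec50_hat = popt
    if emax_hat > 1.0 - 1e-9:
        raise FitConvergenceError(
            "Emax estimate pinned at the upper bound 1",
            best=EmaxParams(emax=min(emax_hat, 1.0), ec50=ec50_hat),
        )
    rss = float(np.sum((model(cp, *popt) - eff) ** 2))
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, None))
    return EmaxFit(
        params=EmaxParams(emax=float(emax_hat), ec50=float(ec50_hat)),
        cv_percent={"emax": float(100 * se[0] / emax_hat),
                    "ec50": float(100 * se[1] / ec50_hat)},
        rss=rss,
        n=len(cp),
    )
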