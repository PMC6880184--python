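"""End-to-end "fit on single-dose, predict multiple-dose" pipeline.

Stage order: per-subject compartmental PK fits (pooled by averaging), NCA
per dose, dose-proportionality power model, baseline urate physiology from
pre-dose data, delta-mass-balance Vd_UA per dosed subject, f_reabs from the
placebo arms (GFR from urinary creatinine clearance normalized to 1.73 m2,
or implied from the baseline clearance), interval-mean effect points plus
the Emax fit, and finally the forward prediction of the multiple-dose SUA
curves with bias/RMSE against the observed values.  Each stage is an
importable function so the analysis drivers can run them individually;
:func:`run_pipeline` composes them and assembles a reproducible report.
"""

from __future__ import annotations

import logging
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import units, urate
from .errors import PipelineStageError, PKPDError, UninformativeDataError
from .io import config_hash
from .pk import (
    DoseRegimen,
    PKParams,
    PlasmaProfile,
    auc_trapezoid,
    dose_proportionality,
    fit_pk,
    nca,
)
from .simulate import predict_mad
from .synthetic import StudyDataset
from .urate import (
    DeltaSummary,
    EmaxFit,
    UrineInterval,
    clearance_from_excretion,
    estimate_freabs,
    estimate_vd_ua,
    fit_emax,
    interval_means,
)

logger = logging.getLogger("dotinurad_pkpd")

__all__ = [
    "PipelineConfig",
    "PipelineReport",
    "run_pipeline",
    "pk_stage",
    "nca_stage",
    "proportionality_stage",
    "baseline_stage",
    "vd_stage",
    "freabs_stage",
    "emax_stage",
    "mad_stage",
]


@dataclass(frozen=True)
class PipelineConfig:
    gfr_source: str = "creatinine"  # or "implied"
    effect_windows: tuple = urate.DEFAULT_EFFECT_WINDOWS
    pk_weighting: str = "none"
    mad_sim_dt_h: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.gfr_source not in ("creatinine", "implied"):
            raise ValueError("gfr_source must be 'creatinine' or 'implied'")


@dataclass
class PipelineReport:
    """Every number here is produced by one of the stage functions and the
    report is regenerable from (datasets, config)."""

    pk_params: PKParams | None
    pk_cv_percent: dict | None
    pk_by_subject: pd.DataFrame | None
    nca_by_dose: pd.DataFrame
    nca_by_subject: pd.DataFrame
    proportionality: dict
    baseline: dict
    vd_ua_l: float | None
    vd_by_subject: pd.DataFrame | None
    f_reabs: float | None
    f_reabs_by_subject: pd.DataFrame | None
    emax_fit: EmaxFit | None
    effect_points: pd.DataFrame
    mad_metrics: dict | None
    mad_prediction: pd.DataFrame | None
    stage_errors: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "pk": None,
            "nca_by_dose": self.nca_by_dose.to_dict(orient="records"),
            "proportionality": {
                k: {"slope": v.slope, "slope_ci90": list(v.slope_ci90),
                    "intercept": v.intercept, "n": v.n}
                for k, v in self.proportionality.items()
            },
            "baseline": self.baseline,
            "vd_ua_l": self.vd_ua_l,
            "f_reabs": self.f_reabs,
            "emax": None,
            "mad_metrics": self.mad_metrics,
            "stage_errors": {k: str(v) for k, v in self.stage_errors.items()},
            "provenance": self.provenance,
        }
        if self.pk_params is not None:
            d["pk"] = {
                "v_f_ml": self.pk_params.v_f,
                "ka_per_h": self.pk_params.ka,
                "ke_per_h": self.pk_params.ke,
                "t_half_h": self.pk_params.t_half,
                "cl_f_ml_h": self.pk_params.cl_f,
                "cv_percent": self.pk_cv_percent,
            }
        if self.emax_fit is not None:
            d["emax"] = {
                "emax": self.emax_fit.params.emax,
                "ec50_ng_ml": self.emax_fit.params.ec50,
                "cv_percent": self.emax_fit.cv_percent,
            }
        return d


# ---------------------------------------------------------------------------
# helpers


def _subject_profile(ds: StudyDataset, sid: str, n_doses: int = 1) -> PlasmaProfile:
    rows = ds.plasma[ds.plasma["subject_id"] == sid]
    dose = float(rows["dose_mg"].iloc[0])
    regimen = DoseRegimen(dose_mg=dose, interval_h=24.0, n_doses=n_doses)
    return PlasmaProfile(
        subject_id=sid,
        times=rows["time_h"].to_numpy(dtype=float),
        concentrations=rows["conc_ng_ml"].to_numpy(dtype=float),
        regimen=regimen,
    )


def _subject_sua(ds: StudyDataset, sid: str):
    rows = ds.sua[ds.sua["subject_id"] == sid]
    return rows["time_h"].to_numpy(dtype=float), rows["sua_mg_dl"].to_numpy(dtype=float)


def _subject_urine(ds: StudyDataset, sid: str) -> list[UrineInterval]:
    rows = ds.urine[ds.urine["subject_id"] == sid]
    return [
        UrineInterval(
            t_start=r.t_start_h, t_end=r.t_end_h, volume=r.volume_ml,
            cu_ua=units.mg_per_dl_to_mg_per_ml(r.urate_mg_dl),
        )
        for r in rows.itertuples()
    ]


def _window_sum(rows, col, w0, w1):
    m = (rows["t_start_h"] >= w0 - 1e-9) & (rows["t_end_h"] <= w1 + 1e-9)
    return float(rows.loc[m, col].sum()), rows.loc[m]


def gfr_from_creatinine(ds: StudyDataset, sid: str, window=(0.0, 24.0)) -> float:
    """BSA-normalized creatinine clearance (mL/min) over a window:
    Ccr = (Ucr x V)/(Scr x t), scaled by 1.73/BSA."""
    rows = ds.urine[ds.urine["subject_id"] == sid]
    m = (rows["t_start_h"] >= window[0] - 1e-9) & (rows["t_end_h"] <= window[1] + 1e-9)
    rows = rows.loc[m]
    if rows.empty:
        raise PKPDError(f"no urine collections for {sid} in {window}")
    amount_mg = float(
        (units.mg_per_dl_to_mg_per_ml(rows["creat_mg_dl"]) * rows["volume_ml"]).sum()
    )
    minutes = float((rows["t_end_h"] - rows["t_start_h"]).sum()) * units.MIN_PER_H
    scr = float(ds.sua.loc[ds.sua["subject_id"] == sid, "screat_mg_dl"].mean())
    ccr_raw = amount_mg / (units.mg_per_dl_to_mg_per_ml(scr) * minutes)
    bsa = float(ds.subjects.loc[ds.subjects["subject_id"] == sid, "bsa_m2"].iloc[0])
    return ccr_raw * 1.73 / bsa


# ---------------------------------------------------------------------------
# stages


def pk_stage(ds: StudyDataset, config: PipelineConfig):
    """Per-subject compartmental fits on the active arms; the pooled
    parameter set is the arithmetic mean with its between-subject %CV."""
    rows = []
    for sid in ds.subject_ids(active_only=True):
        profile = _subject_profile(ds, sid)
        try:
            fit = fit_pk(profile, weighting=config.pk_weighting)
        except UninformativeDataError:
            continue
        rows.append(
            {
                "subject_id": sid,
                "dose_mg": profile.regimen.dose_mg,
                "v_f_ml": fit.params.v_f,
                "ka_per_h": fit.params.ka,
                "ke_per_h": fit.params.ke,
                "rss": fit.rss,
            }
        )
    if not rows:
        raise UninformativeDataError("no active subject has a fittable profile")
    df = pd.DataFrame(rows)
    pooled = PKParams(
        v_f=float(df["v_f_ml"].mean()),
        ka=float(df["ka_per_h"].mean()),
        ke=float(df["ke_per_h"].mean()),
    )
    cv = {
        "v_f": float(100 * df["v_f_ml"].std(ddof=1) / df["v_f_ml"].mean()),
        "ka": float(100 * df["ka_per_h"].std(ddof=1) / df["ka_per_h"].mean()),
        "ke": float(100 * df["ke_per_h"].std(ddof=1) / df["ke_per_h"].mean()),
    } if len(df) > 1 else {"v_f": 0.0, "ka": 0.0, "ke": 0.0}
    return pooled, cv, df


def nca_stage(ds: StudyDataset):
    """Non-compartmental summaries per subject and dose-level means."""
    rows = []
    for sid in ds.subject_ids(active_only=True):
        profile = _subject_profile(ds, sid)
        res = nca(profile)
        rows.append(
            {
                "subject_id": sid,
                "dose_mg": profile.regimen.dose_mg,
                "cmax_ng_ml": res.cmax,
                "tmax_h": res.tmax,
                "auc_0_24_ng_h_ml": res.auc_0_24,
                "auc_0_inf_ng_h_ml": res.auc_0_inf,
                "t_half_h": res.t_half,
                "cl_f_l_h": res.cl_f / 1.0e3,
            }
        )
    by_subject = pd.DataFrame(rows)
    by_dose = (
        by_subject.drop(columns="subject_id").groupby("dose_mg").mean().reset_index()
    )
    return by_dose, by_subject


def proportionality_stage(nca_by_subject: pd.DataFrame):
    """Power-model exponents for Cmax and AUC0-inf across doses."""
    out = {}
    for metric, col in (("cmax", "cmax_ng_ml"), ("auc_0_inf", "auc_0_inf_ng_h_ml")):
        pts = list(zip(nca_by_subject["dose_mg"], nca_by_subject[col]))
        out[metric] = dose_proportionality(pts)
    return out


def baseline_stage(ds: StudyDataset):
    """Pre-dose urate physiology per subject and pooled.

    Baseline CLR_UA is Xu_UA/AUEC over the -24 to 0 h collection with the
    AUEC taken as the pre-dose SUA held for 24 h; the 2:1 renal:gut split
    then gives Xf, CLGut and Synthesis.
    """
    rows = []
    for sid in ds.subject_ids():
        sua_t, sua_v = _subject_sua(ds, sid)
        sua0 = float(np.mean(sua_v[sua_t <= 0])) if np.any(sua_t <= 0) else float(sua_v[0])
        urine_rows = ds.urine[ds.urine["subject_id"] == sid]
        xu_b = float(
            (
                units.mg_per_dl_to_mg_per_ml(urine_rows["urate_mg_dl"])
                * urine_rows["volume_ml"]
            )[
                (urine_rows["t_start_h"] >= -24.0 - 1e-9)
                & (urine_rows["t_end_h"] <= 0.0 + 1e-9)
            ].sum()
        )
        auec_b = sua0 * 24.0
        clr_b = clearance_from_excretion(xu_b, auec_b)
        rows.append(
            {"subject_id": sid, "sua0_mg_dl": sua0, "xu_baseline_mg_day": xu_b,
             "clr_ua_ml_min": clr_b}
        )
    df = pd.DataFrame(rows)
    pooled_xu = float(df["xu_baseline_mg_day"].mean())
    pooled_clr = float(df["clr_ua_ml_min"].mean())
    rates = urate.derive_baseline(pooled_xu, pooled_clr)
    pooled = {
        "sua0_mg_dl": float(df["sua0_mg_dl"].mean()),
        "xu_ua_mg_day": pooled_xu,
        "clr_ua_ml_min": pooled_clr,
        "xf_ua_mg_day": rates.xf_ua_mg_day,
        "clgut_ua_ml_min": rates.clgut_ua_ml_min,
        "synthesis_mg_day": rates.synthesis_mg_day,
    }
    return pooled, df


def vd_stage(ds: StudyDataset, baseline_df: pd.DataFrame):
    """Per-dosed-subject delta-mass-balance urate volumes, averaged
    arithmetically across all dosed subjects (per-dose means reported too)."""
    base = baseline_df.set_index("subject_id")
    rows = []
    for sid in ds.subject_ids(active_only=True):
        sua_t, sua_v = _subject_sua(ds, sid)
        urine_rows = ds.urine[ds.urine["subject_id"] == sid]
        xu_post, _ = _window_sum(
            urine_rows.assign(
                xu_mg=units.mg_per_dl_to_mg_per_ml(urine_rows["urate_mg_dl"])
                * urine_rows["volume_ml"]
            ),
            "xu_mg", 0.0, 24.0,
        )
        auec_post = auc_trapezoid(sua_t, sua_v, 0.0, 24.0)
        sua0 = base.loc[sid, "sua0_mg_dl"]
        auec_base = sua0 * 24.0
        clgut_dl_h = units.ml_per_min_to_dl_per_h(base.loc[sid, "clr_ua_ml_min"] / 2.0)
        d_xu = xu_post - base.loc[sid, "xu_baseline_mg_day"]
        d_xf = clgut_dl_h * (auec_post - auec_base)  # signed, negative when SUA falls
        d_sua = sua0 - float(np.interp(24.0, sua_t, sua_v))
        if d_sua <= 0:
            warnings.warn(f"{sid}: SUA did not fall over 0-24 h; skipped in Vd")
            continue
        try:
            vd_ml = estimate_vd_ua(DeltaSummary(d_xu_ua=d_xu, d_xf_ua=d_xf,
                                                d_sua=d_sua))
        except PKPDError as exc:
            warnings.warn(f"{sid}: {exc}; skipped in Vd")
            continue
        rows.append({"subject_id": sid,
                     "dose_mg": float(ds.plasma.loc[
                         ds.plasma["subject_id"] == sid, "dose_mg"].iloc[0]),
                     "vd_ua_l": vd_ml / 1.0e3})
    df = pd.DataFrame(rows)
    return float(df["vd_ua_l"].mean()), df


def freabs_stage(ds: StudyDataset, baseline_df: pd.DataFrame,
                 config: PipelineConfig):
    """Fractional reabsorption from the placebo arms over 0-24 h."""
    base = baseline_df.set_index("subject_id")
    placebo = ds.subjects.loc[ds.subjects["dose_mg"] == 0, "subject_id"]
    rows = []
    for sid in placebo:
        sua_t, sua_v = _subject_sua(ds, sid)
        urine_rows = ds.urine[ds.urine["subject_id"] == sid]
        xu, _ = _window_sum(
            urine_rows.assign(
                xu_mg=units.mg_per_dl_to_mg_per_ml(urine_rows["urate_mg_dl"])
                * urine_rows["volume_ml"]
            ),
            "xu_mg", 0.0, 24.0,
        )
        auec = auc_trapezoid(sua_t, sua_v, 0.0, 24.0)
        clr = clearance_from_excretion(xu, auec)
        if config.gfr_source == "creatinine":
            gfr = gfr_from_creatinine(ds, sid, window=(0.0, 24.0))
        else:
            gfr = urate.implied_gfr(base.loc[sid, "clr_ua_ml_min"], 0.943)
        rows.append({"subject_id": sid, "clr_ua_ml_min": clr,
                     "gfr_ml_min": gfr,
                     "f_reabs": estimate_freabs(clr, gfr)})
    df = pd.DataFrame(rows)
    return float(df["f_reabs"].mean()), df


def emax_stage(ds: StudyDataset, f_reabs: float, config: PipelineConfig):
    """Interval-mean effect points pooled over all dosed subjects, then the
    simple Emax fit."""
    rows = []
    points = []
    for sid in ds.subject_ids(active_only=True):
        profile = _subject_profile(ds, sid)
        sua_t, sua_v = _subject_sua(ds, sid)
        urine_iv = _subject_urine(ds, sid)
        if config.gfr_source == "creatinine":
            gfr = gfr_from_creatinine(ds, sid, window=(-24.0, 48.0))
        else:
            base_clr = clearance_from_excretion(
                sum(u.xu_ua for u in urine_iv if u.t_end <= 0),
                float(np.mean(sua_v[sua_t <= 0])) * 24.0,
            )
            gfr = urate.implied_gfr(base_clr, f_reabs)
        pts = interval_means(
            profile, urine_iv, sua_t, sua_v, gfr_ml_min=gfr, f_reabs=f_reabs,
            windows=config.effect_windows,
        )
        for (w, p) in zip(config.effect_windows, pts):
            rows.append(
                {"subject_id": sid, "window_start_h": w[0], "window_end_h": w[1],
                 "cp_mean_ng_ml": p.cp_mean, "clr_mean_ml_min": p.clr_mean,
                 "effect": p.effect}
            )
            points.append(p)
    df = pd.DataFrame(rows)
    return fit_emax(points), df


def mad_stage(mad: StudyDataset, pk_params: PKParams, phys, emax_params,
              config: PipelineConfig):
    """Forward-predict the multiple-dose SUA curves and score them against
    the observed arm means (bias and RMSE per dose); also the observed
    day-7/day-1 accumulation of daily AUC."""
    doses = sorted(d for d in mad.subjects["dose_mg"].unique() if d > 0)
    metrics = {}
    pred_parts = []
    for dose in doses:
        sids = mad.subjects.loc[mad.subjects["dose_mg"] == dose, "subject_id"]
        obs = (
            mad.sua[mad.sua["subject_id"].isin(sids)]
            .groupby("time_h")["sua_mg_dl"].mean().reset_index()
        )
        pred = predict_mad(
            phys, emax_params, pk_params, dose_mg=dose,
            days=int(mad.config.mad_days) if mad.config else 7,
            dt=config.mad_sim_dt_h, sample_times=obs["time_h"].to_numpy(),
        )
        err = pred["sua_mg_dl"].to_numpy() - obs["sua_mg_dl"].to_numpy()
        r_aucs = []
        for sid in sids:
            rows = mad.plasma[mad.plasma["subject_id"] == sid]
            t = rows["time_h"].to_numpy(dtype=float)
            c = rows["conc_ng_ml"].to_numpy(dtype=float)
            day1 = auc_trapezoid(t, c, 0.0, 24.0)
            day7 = auc_trapezoid(t, c, 144.0, 168.0)
            r_aucs.append(day7 / day1)
        metrics[dose] = {
            "bias_mg_dl": float(np.mean(err)),
            "rmse_mg_dl": float(np.sqrt(np.mean(err**2))),
            "r_auc_day7_day1": float(np.mean(r_aucs)),
        }
        pred_parts.append(
            pred.assign(dose_mg=dose, sua_obs_mg_dl=obs["sua_mg_dl"].to_numpy())
        )
    return metrics, pd.concat(pred_parts, ignore_index=True)


# ---------------------------------------------------------------------------
# composition


def run_pipeline(sad: StudyDataset, mad: StudyDataset | None,
                 config: PipelineConfig | None = None) -> PipelineReport:
    """Run the full estimation-and-prediction cascade.

    PK stages that fail on uninformative data (e.g. a placebo-only dataset)
    are recorded in ``stage_errors`` and the physiology stages still run;
    any other stage failure raises :class:`PipelineStageError`.
    """
    config = config or PipelineConfig()
    report_kwargs: dict = dict(
        pk_params=None, pk_cv_percent=None, pk_by_subject=None,
        nca_by_dose=pd.DataFrame(), nca_by_subject=pd.DataFrame(),
        proportionality={}, baseline={}, vd_ua_l=None, vd_by_subject=None,
        f_reabs=None, f_reabs_by_subject=None, emax_fit=None,
        effect_points=pd.DataFrame(), mad_metrics=None, mad_prediction=None,
    )
    stage_errors: dict = {}

    def run(name, func, *args, tolerate=()):
        t0 = time.perf_counter()
        try:
            result = func(*args)
        except tolerate as exc:
            logger.info("stage %s skipped: %s", name, exc)
            stage_errors[name] = exc
            return None
        except PKPDError as exc:
            raise PipelineStageError(name, exc) from exc
        logger.info("stage %s done in %.2f s", name, time.perf_counter() - t0)
        return result

    res = run("fit_pk", pk_stage, sad, config,
              tolerate=(UninformativeDataError,))
    if res is not None:
        report_kwargs["pk_params"], report_kwargs["pk_cv_percent"], \
            report_kwargs["pk_by_subject"] = res

    res = run("nca", nca_stage, sad, tolerate=(PKPDError, IndexError, KeyError))
    if res is not None and len(res[1]):
        report_kwargs["nca_by_dose"], report_kwargs["nca_by_subject"] = res
        report_kwargs["proportionality"] = run(
            "dose_proportionality", proportionality_stage, res[1]
        )

    baseline, baseline_df = run("derive_baseline", baseline_stage, sad)
    report_kwargs["baseline"] = baseline

    if report_kwargs["pk_params"] is not None:
        vd_l, vd_df = run("estimate_vd_ua", vd_stage, sad, baseline_df)
        report_kwargs["vd_ua_l"], report_kwargs["vd_by_subject"] = vd_l, vd_df

    f_reabs, f_df = run("estimate_freabs", freabs_stage, sad, baseline_df, config)
    report_kwargs["f_reabs"], report_kwargs["f_reabs_by_subject"] = f_reabs, f_df

    if report_kwargs["pk_params"] is not None:
        emax_fit, points = run("fit_emax", emax_stage, sad, f_reabs, config)
        report_kwargs["emax_fit"], report_kwargs["effect_points"] = emax_fit, points

        if mad is not None and report_kwargs["vd_ua_l"] is not None:
            phys = urate.UratePhysiology.from_baseline(
                baseline["sua0_mg_dl"], baseline["clr_ua_ml_min"],
                vd_ua_ml=report_kwargs["vd_ua_l"] * 1.0e3, f_reabs=f_reabs,
            )
            res = run("predict_mad", mad_stage, mad, report_kwargs["pk_params"],
                      phys, emax_fit.params, config)
            report_kwargs["mad_metrics"], report_kwargs["mad_prediction"] = res

    import dotinurad_pkpd

    report = PipelineReport(
        **report_kwargs,
        stage_errors=stage_errors,
        provenance={
            "config_hash": config_hash(config, sad.config),
            "seed": config.seed,
            "sad_seed": sad.seed,
            "mad_seed": mad.seed if mad is not None else None,
            "version": dotinurad_pkpd.__version__,
        },
    )
    return report
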