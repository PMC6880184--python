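"""Synthetic phase-1 study generation.

No raw clinical data accompany this analysis, so every estimator is
exercised against cohorts generated here with the statistical structure the
analysis assumes: a single-ascending-dose (SAD) design of six dose cohorts
(0.5/1/2/5/10/20 mg, n=6 active + 3 placebo each) with the dense blood
schedule and interval urine collections of a first-in-human study, and a
multiple-ascending-dose (MAD) design (2 or 5 mg once daily for 7 days).

Between-subject variability is multiplicative lognormal around the
population point estimates; each subject's plasma curve comes from the
analytic one-compartment model and their serum-urate / urine outputs from a
per-subject run of the conservative mass-balance simulator, with optional
lognormal residual error and a 1 ng/mL plasma quantitation floor.  With all
dispersions at zero the tables equal the deterministic models exactly,
which is what the whole-pipeline identity test relies on.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import units
from .pk import DoseRegimen, PKParams, concentration
from .simulate import (
    SimulationConfig,
    mad_blood_times,
    mad_urine_windows,
    simulate_sua,
)
from .urate import EmaxParams, UratePhysiology

__all__ = [
    "PopulationConfig",
    "NoiseConfig",
    "StudyConfig",
    "SubjectRecord",
    "StudyDataset",
    "generate_subject",
    "generate_sad",
    "generate_mad",
    "add_noise",
    "SAD_BLOOD_TIMES_H",
    "SAD_URINE_WINDOWS_H",
]

#: SAD blood sampling times (h; 0 is the pre-dose sample).
SAD_BLOOD_TIMES_H = (0.0, 0.25, 0.5, 1.0, 1.5, 2.0, 4.0, 6.0, 8.0, 12.0,
                     24.0, 36.0, 48.0)

#: SAD urine collections (h), including the 24 h pre-dose baseline.
SAD_URINE_WINDOWS_H = ((-24.0, 0.0), (0.0, 6.0), (6.0, 12.0), (12.0, 24.0),
                       (24.0, 36.0), (36.0, 48.0))

SAD_DOSES_MG = (0.5, 1.0, 2.0, 5.0, 10.0, 20.0)
MAD_DOSES_MG = (2.0, 5.0)


@dataclass(frozen=True)
class PopulationConfig:
    """Population point values and between-subject dispersions.

    Dispersions are lognormal CVs; where only an SD is printed for a
    baseline the CV is SD/mean.  PK and PD dispersions default to the
    printed estimation %CVs, a synthetic-population choice documented in the
    methods note.
    """

    v_f_ml: float = 10585.0
    ka_per_h: float = 0.770
    ke_per_h: float = 0.0795
    cv_v_f: float = 0.072
    cv_ka: float = 0.142
    cv_ke: float = 0.093

    sua_mg_dl: float = 5.71
    sua_sd: float = 0.75
    clr_ua_ml_min: float = 7.10
    clr_ua_sd: float = 1.51
    vd_ua_l: float = 16.0
    cv_vd_ua: float = 0.366
    f_reabs: float = 0.943
    cv_f_reabs: float = 0.006
    emax: float = 0.51
    cv_emax: float = 0.046
    ec50_ng_ml: float = 196.0
    cv_ec50: float = 0.119

    weight_kg: float = 60.0
    weight_sd: float = 5.0
    weight_bounds: tuple = (50.0, 80.0)
    height_cm: float = 170.0
    serum_creatinine_mg_dl: float = 0.9

    def zero_variability(self) -> "PopulationConfig":
        return dataclasses.replace(
            self, cv_v_f=0.0, cv_ka=0.0, cv_ke=0.0, sua_sd=0.0, clr_ua_sd=0.0,
            cv_vd_ua=0.0, cv_f_reabs=0.0, cv_emax=0.0, cv_ec50=0.0,
            weight_sd=0.0,
        )


@dataclass(frozen=True)
class NoiseConfig:
    """Residual (assay/within-subject) error: multiplicative lognormal CVs
    per table, plus the plasma lower limit of quantitation."""

    plasma_cv: float = 0.10
    sua_cv: float = 0.05
    urine_cv: float = 0.05
    lloq_plasma_ng_ml: float = 1.0

    def __post_init__(self):
        for name in ("plasma_cv", "sua_cv", "urine_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def zero(cls) -> "NoiseConfig":
        return cls(plasma_cv=0.0, sua_cv=0.0, urine_cv=0.0)


@dataclass(frozen=True)
class StudyConfig:
    population: PopulationConfig = field(default_factory=PopulationConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    n_active: int = 6
    n_placebo: int = 3
    sad_doses: tuple = SAD_DOSES_MG
    mad_doses: tuple = MAD_DOSES_MG
    mad_days: int = 7
    sim_dt_h: float = 0.25
    urine_flow_ml_h: float = 62.5  # ~1.5 L/day

    @classmethod
    def noise_free(cls, **kwargs) -> "StudyConfig":
        """All between-subject and residual variability off."""
        return cls(
            population=PopulationConfig().zero_variability(),
            noise=NoiseConfig.zero(),
            **kwargs,
        )


@dataclass(frozen=True)
class SubjectRecord:
    """One synthetic subject with their generating ("true") parameters."""

    subject_id: str
    arm_dose_mg: float  # 0 for placebo
    weight_kg: float
    bsa_m2: float
    fed: bool
    true_pk: PKParams
    true_phys: UratePhysiology
    true_emax: EmaxParams


@dataclass(frozen=True)
class StudyDataset:
    """Generated tables for one study arm set.

    plasma   : subject_id, dose_mg, time_h, conc_ng_ml, blq, fed, day
    urine    : subject_id, t_start_h, t_end_h, volume_ml, urate_mg_dl,
               creat_mg_dl, drug_ng_ml
    sua      : subject_id, time_h, sua_mg_dl, screat_mg_dl
    subjects : demographics and arm assignment
    truth    : the generating parameters per subject
    """

    design: str  # "SAD" | "MAD"
    seed: int
    plasma: pd.DataFrame
    urine: pd.DataFrame
    sua: pd.DataFrame
    subjects: pd.DataFrame
    truth: pd.DataFrame
    config: StudyConfig | None = None

    def subject_ids(self, active_only=False):
        df = self.subjects
        if active_only:
            df = df[df["dose_mg"] > 0]
        return list(df["subject_id"])


# ---------------------------------------------------------------------------
# draws


def _lognormal(rng, mean, cv):
    """Geometric-mean-preserving lognormal draw (returns ``mean`` if cv=0)."""
    if cv < 0:
        raise ValueError("CV must be >= 0")
    if cv == 0:
        return mean
    sigma = np.sqrt(np.log1p(cv**2))
    return mean * np.exp(rng.normal(0.0, sigma))


def du_bois_bsa(weight_kg: float, height_cm: float) -> float:
    """Du Bois body surface area (m^2)."""
    return 0.007184 * weight_kg**0.425 * height_cm**0.725


def generate_subject(rng, config: StudyConfig, subject_id: str,
                     arm_dose_mg: float, fed: bool = False) -> SubjectRecord:
    """Draw one subject: lognormal between-subject variability around the
    population values, derived quantities closed through the physiology
    invariants.  Deterministic given the generator state."""
    p = config.population
    ka = _lognormal(rng, p.ka_per_h, p.cv_ka)
    ke = _lognormal(rng, p.ke_per_h, p.cv_ke)
    while ka <= ke:  # flip-flop guard; essentially never triggers
        ka = _lognormal(rng, p.ka_per_h, p.cv_ka)
    pk = PKParams(v_f=_lognormal(rng, p.v_f_ml, p.cv_v_f), ka=ka, ke=ke)

    sua0 = _lognormal(rng, p.sua_mg_dl, p.sua_sd / p.sua_mg_dl)
    clr0 = _lognormal(rng, p.clr_ua_ml_min, p.clr_ua_sd / p.clr_ua_ml_min)
    f_reabs = min(_lognormal(rng, p.f_reabs, p.cv_f_reabs), 0.9999)
    vd_ml = _lognormal(rng, p.vd_ua_l * 1.0e3, p.cv_vd_ua)
    phys = UratePhysiology.from_baseline(
        sua0, clr0, vd_ua_ml=vd_ml, f_reabs=f_reabs
    )
    emax = EmaxParams(
        emax=min(_lognormal(rng, p.emax, p.cv_emax), 0.999),
        ec50=_lognormal(rng, p.ec50_ng_ml, p.cv_ec50),
    )
    if p.weight_sd == 0:
        weight = p.weight_kg
    else:
        weight = rng.normal(p.weight_kg, p.weight_sd)
        while not (p.weight_bounds[0] <= weight <= p.weight_bounds[1]):
            weight = rng.normal(p.weight_kg, p.weight_sd)
    return SubjectRecord(
        subject_id=subject_id,
        arm_dose_mg=arm_dose_mg,
        weight_kg=float(weight),
        bsa_m2=du_bois_bsa(weight, p.height_cm),
        fed=fed,
        true_pk=pk,
        true_phys=phys,
        true_emax=emax,
    )


def add_noise(values, cv: float, rng) -> np.ndarray:
    """Independent multiplicative lognormal residual on each record.

    ``cv = 0`` is the identity; negative inputs signal an upstream data
    error.  ``rng`` is a :class:`numpy.random.Generator` or a seed.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    vals = np.asarray(values, dtype=float)
    if np.any(vals < 0):
        raise ValueError("concentrations must be non-negative before noise")
    if cv == 0:
        return vals.copy()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sigma = np.sqrt(np.log1p(cv**2))
    return vals * np.exp(rng.normal(0.0, sigma, size=vals.shape))


# ---------------------------------------------------------------------------
# dataset assembly


def _subject_tables(subject: SubjectRecord, regimen: DoseRegimen,
                    blood_times, urine_windows, cfg: StudyConfig,
                    sim_horizon: float, noise_rng) -> tuple:
    """Plasma/SUA/urine rows for one subject (noise applied per table)."""
    phys, pk = subject.true_phys, subject.true_pk
    sim_cfg = SimulationConfig(
        dt=cfg.sim_dt_h, t_start=-24.0, horizon=sim_horizon,
        record_intervals=tuple(urine_windows),
    )
    course = simulate_sua(phys, subject.true_emax, pk, regimen, sim_cfg)

    blood_times = np.asarray(blood_times, dtype=float)
    conc = (np.zeros_like(blood_times) if regimen.dose_mg == 0
            else np.atleast_1d(concentration(pk, regimen, blood_times)))
    conc = add_noise(conc, cfg.noise.plasma_cv, noise_rng)
    blq = conc < cfg.noise.lloq_plasma_ng_ml
    conc = np.where(blq, 0.0, conc)
    plasma = pd.DataFrame(
        {
            "subject_id": subject.subject_id,
            "dose_mg": regimen.dose_mg,
            "time_h": blood_times,
            "conc_ng_ml": conc,
            "blq": blq.astype(int),
            "fed": int(subject.fed),
            "day": np.floor(np.maximum(blood_times, 0.0) / 24.0).astype(int),
        }
    )

    sua_vals = add_noise(course.sua_at(blood_times), cfg.noise.sua_cv, noise_rng)
    sua = pd.DataFrame(
        {
            "subject_id": subject.subject_id,
            "time_h": blood_times,
            "sua_mg_dl": sua_vals,
            "screat_mg_dl": cfg.population.serum_creatinine_mg_dl,
        }
    )

    iv = course.intervals
    widths = iv["window_end_h"] - iv["window_start_h"]
    volume = cfg.urine_flow_ml_h * widths
    urate_conc = iv["xu_mg"] / volume * units.ML_PER_DL  # mg/dL
    # creatinine bookkeeping: the subject's true GFR is BSA-normalized, so
    # the raw (measured) clearance is GFR * BSA/1.73
    ccr_raw = phys.gfr * subject.bsa_m2 / 1.73
    creat_mg = (
        ccr_raw * widths * units.MIN_PER_H
        * units.mg_per_dl_to_mg_per_ml(cfg.population.serum_creatinine_mg_dl)
    )
    creat_conc = creat_mg / volume * units.ML_PER_DL
    urine = pd.DataFrame(
        {
            "subject_id": subject.subject_id,
            "t_start_h": iv["window_start_h"],
            "t_end_h": iv["window_end_h"],
            "volume_ml": volume,
            "urate_mg_dl": add_noise(urate_conc, cfg.noise.urine_cv, noise_rng),
            "creat_mg_dl": add_noise(creat_conc, cfg.noise.urine_cv, noise_rng),
            "drug_ng_ml": 0.0,  # not modeled; column kept for the dialect
        }
    )
    return plasma, sua, urine


def _truth_row(s: SubjectRecord) -> dict:
    return {
        "subject_id": s.subject_id,
        "dose_mg": s.arm_dose_mg,
        "v_f_ml": s.true_pk.v_f,
        "ka_per_h": s.true_pk.ka,
        "ke_per_h": s.true_pk.ke,
        "vd_ua_ml": s.true_phys.vd_ua,
        "f_reabs": s.true_phys.f_reabs,
        "gfr_ml_min": s.true_phys.gfr,
        "clgut_ml_min": s.true_phys.clgut_ua,
        "synthesis_mg_h": s.true_phys.synthesis_rate,
        "baseline_sua_mg_dl": s.true_phys.baseline_sua,
        "baseline_clr_ua_ml_min": s.true_phys.baseline_clr_ua,
        "emax": s.true_emax.emax,
        "ec50_ng_ml": s.true_emax.ec50,
    }


def _generate(design: str, doses, days: int, blood_times, urine_windows,
              config: StudyConfig, seed: int, fed: bool) -> StudyDataset:
    root = np.random.SeedSequence(seed)
    horizon = urine_windows[-1][1]
    plasma_parts, sua_parts, urine_parts = [], [], []
    subjects, truth = [], []
    cohort_seqs = root.spawn(len(doses))
    for dose, seq in zip(doses, cohort_seqs):
        subj_seq, noise_seq = seq.spawn(2)
        subj_rngs = [np.random.default_rng(s)
                     for s in subj_seq.spawn(config.n_active + config.n_placebo)]
        noise_rngs = [np.random.default_rng(s)
                      for s in noise_seq.spawn(config.n_active + config.n_placebo)]
        for k in range(config.n_active + config.n_placebo):
            active = k < config.n_active
            arm_dose = dose if active else 0.0
            tag = "act" if active else "plc"
            sid = f"{design}-{dose:g}mg-{tag}{k + 1:02d}"
            subject = generate_subject(subj_rngs[k], config, sid, arm_dose,
                                       fed=fed)
            regimen = DoseRegimen(dose_mg=arm_dose, interval_h=24.0,
                                  n_doses=days)
            p, s, u = _subject_tables(subject, regimen, blood_times,
                                      urine_windows, config, horizon,
                                      noise_rngs[k])
            plasma_parts.append(p)
            sua_parts.append(s)
            urine_parts.append(u)
            subjects.append(
                {
                    "subject_id": sid,
                    "design": design,
                    "dose_mg": arm_dose,
                    "cohort_dose_mg": dose,
                    "weight_kg": subject.weight_kg,
                    "bsa_m2": subject.bsa_m2,
                    "fed": int(fed),
                }
            )
            truth.append(_truth_row(subject))
    return StudyDataset(
        design=design,
        seed=seed,
        plasma=pd.concat(plasma_parts, ignore_index=True),
        urine=pd.concat(urine_parts, ignore_index=True),
        sua=pd.concat(sua_parts, ignore_index=True),
        subjects=pd.DataFrame(subjects),
        truth=pd.DataFrame(truth),
        config=config,
    )


def generate_sad(config: StudyConfig | None = None, seed: int = 0) -> StudyDataset:
    """Single-ascending-dose cohorts: one oral dose per cohort at
    0.5-20 mg (n_active + n_placebo subjects each), dense 0-48 h blood
    sampling and interval urine collections."""
    config = config or StudyConfig()
    return _generate(
        "SAD", config.sad_doses, days=1, blood_times=SAD_BLOOD_TIMES_H,
        urine_windows=SAD_URINE_WINDOWS_H, config=config, seed=seed, fed=False,
    )


def generate_mad(config: StudyConfig | None = None, seed: int = 0) -> StudyDataset:
    """Multiple-ascending-dose cohorts: once-daily dosing for ``mad_days``
    with the day-indexed blood schedule and 24 h urine collections."""
    config = config or StudyConfig()
    return _generate(
        "MAD", config.mad_doses, days=config.mad_days,
        blood_times=mad_blood_times(config.mad_days),
        urine_windows=mad_urine_windows(config.mad_days),
        config=config, seed=seed, fed=True,
    )
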