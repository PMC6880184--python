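import numpy as np
import pytest

from dotinurad_pkpd import (
    DoseRegimen,
    EmaxParams,
    PKParams,
    PlasmaProfile,
    UratePhysiology,
    concentration,
)

#: SAD post-dose blood sampling times (h).
SAD_TIMES = np.array([0.25, 0.5, 1.0, 1.5, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0,
                      36.0, 48.0])


@pytest.fixture(scope="session")
def ref_pk() -> PKParams:
    """Fitted one-compartment parameters of the study drug."""
    return PKParams(v_f=10585.0, ka=0.770, ke=0.0795)


@pytest.fixture(scope="session")
def ref_emax() -> EmaxParams:
    """Fitted Emax model of the drug effect on urate reabsorption."""
    return EmaxParams(emax=0.51, ec50=196.0)


@pytest.fixture(scope="session")
def ref_phys() -> UratePhysiology:
    """Baseline urate physiology of the healthy-volunteer cohort: SUA
    5.71 mg/dL, renal urate clearance 7.10 mL/min, Vd 16 L, f_reabs 0.943
    (GFR implied)."""
    return UratePhysiology.from_baseline(
        5.71, 7.10, vd_ua_ml=16000.0, f_reabs=0.943
    )


@pytest.fixture()
def single_5mg() -> DoseRegimen:
    return DoseRegimen(dose_mg=5.0)


def make_profile(pk: PKParams, regimen: DoseRegimen, times=SAD_TIMES,
                 noise_cv: float = 0.0, rng=None,
                 subject_id: str = "s1") -> PlasmaProfile:
    conc = np.atleast_1d(concentration(pk, regimen, times))
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv**2))
        conc = conc * np.exp(rng.normal(0.0, sigma, size=conc.shape))
    return PlasmaProfile(subject_id, np.asarray(times, float), conc, regimen)
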