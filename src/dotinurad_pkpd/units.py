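"""Unit conventions and every cross-unit factor used in the package.

Canonical internal units:

========================  ==========
time                      h
drug amount               ng (oral doses are given in mg and converted here)
urate amount              mg
volume                    mL
drug concentration        ng/mL
serum urate (SUA)         mg/dL
clearance                 mL/min (as printed clinically); converted to dL/h
                          inside the urate mass balance
========================  ==========

No other module hard-codes a conversion factor.
"""

NG_PER_MG = 1.0e6
ML_PER_DL = 100.0
MIN_PER_H = 60.0
H_PER_DAY = 24.0

#: Molar mass of dotinurad (C14H9Cl2NO4S), g/mol.
DOTINURAD_MW = 358.19

#: Plasma protein binding of dotinurad (bound fraction).
DOTINURAD_BOUND_FRACTION = 0.993


def mg_to_ng(x):
    return x * NG_PER_MG


def ng_to_mg(x):
    return x / NG_PER_MG


def mg_per_dl_to_mg_per_ml(x):
    """SUA concentration, mg/dL -> mg/mL (for amount = conc x volume[mL])."""
    return x / ML_PER_DL


def mg_per_ml_to_mg_per_dl(x):
    return x * ML_PER_DL


def ml_per_min_to_ml_per_h(x):
    return x * MIN_PER_H


def ml_per_min_to_dl_per_h(x):
    """Clearance, mL/min -> dL/h; dL/h x mg/dL = mg/h in the mass balance."""
    return x * MIN_PER_H / ML_PER_DL


def dl_per_h_to_ml_per_min(x):
    return x * ML_PER_DL / MIN_PER_H


def ng_per_ml_to_nmol_per_l(x, mw=DOTINURAD_MW):
    """Mass to molar concentration: ng/mL == ug/L; (ug/L)/(g/mol) = umol/L."""
    return x * 1.0e3 / mw


def free_concentration(total, bound_fraction=DOTINURAD_BOUND_FRACTION):
    """Unbound concentration from total and the bound fraction."""
    return total * (1.0 - bound_fraction)
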