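# Methods

## Scope

This package reimplements, as tested library code, a phase-1 PK/PD analysis
of dotinurad, a selective uric-acid reabsorption inhibitor: the plasma
pharmacokinetic model, the physiological serum-urate (SUA) disposition
model, the cascade that estimates every model parameter from a
single-ascending-dose (SAD) study, and a forward simulator that predicts
SUA-time profiles under arbitrary regimens (used here to confirm the model
against a multiple-ascending-dose, MAD, design). Because no raw clinical
data are deposited, a synthetic-study generator reproduces the SAD/MAD
designs and is the substrate for every end-to-end test.

## Pharmacokinetic model

Plasma drug concentration follows a one-compartment model with first-order
absorption; after a dose D at time t_d,

    Cp(t) = (D / (V/F)) · Ka/(Ka−Ke) · (e^{−Ke·Δt} − e^{−Ka·Δt}),

with superposition over repeated doses. Canonical units are h, ng, mL
(oral mg doses are converted once, in `units.py`). Parameters and their
reference values (used as defaults throughout):

| parameter | meaning | value |
|---|---|---|
| V/F | apparent distribution volume | 10 585 mL |
| Ka | absorption rate constant | 0.770 /h |
| Ke | elimination rate constant | 0.0795 /h |

Derived: t½ = ln2/Ke ≈ 8.7 h, CL/F = Ke·V/F ≈ 0.84 L/h.

Fitting is unweighted least squares on the linear concentration scale
(optional 1/ŷ² weighting); the source analysis does not state its
objective, so the simplest choice is the default. The absorption/
elimination flip-flop is removed structurally: the optimizer works in
(log V/F, log Ke, log(Ka−Ke)), so Ka > Ke > 0 always holds. Starting
values are heuristic (Ka₀ = 3/Tmax_obs, Ke₀ from the terminal log-linear
slope, V/F₀ = dose/(AUC·Ke₀)); pre-dose samples are excluded from the
objective. Asymptotic %CV comes from a central-difference Jacobian at the
optimum.

NCA uses the linear trapezoid, λz by log-linear regression on the last
three positive post-peak samples extended while the adjusted R² improves
(the source does not state its rule), AUC0–inf = AUC0–last + Clast/λz,
ties in Cmax resolved to the earliest time, and a missing 24 h sample
interpolated linearly and flagged. Dose proportionality is the power model
log(metric) = a + b·log(dose) with a t-based 90% CI on b; food-effect
comparisons use the geometric mean ratio with a paired-t CI on the log
scale. No lag time and no fed-state model are implemented: the reported
food effects are small and fasted-state parameters predicted fed profiles
well, so one fasted parameter set serves all regimens.

A point worth recording: the steady-state accumulation of daily AUC under
once-daily dosing is exactly AUC0–inf/AUC0–24 ≈ 1.198 for these
parameters (superposition), while the elimination-only shortcut
1/(1−e^{−24·Ke}) ≈ 1.174 is a lower bound that ignores the absorption
tail. The exact value is the one inside the observed 1.18–1.22 range.

## Urate disposition model

The body urate pool is one well-stirred compartment: SUA = pool/Vd_UA.
Urate enters at a constant synthesis rate and leaves by renal and gut
clearances acting on SUA. Assumptions: synthesis constant; renal:gut
excretion 2:1 at baseline; the drug affects only renal clearance; Vd_UA,
GFR and gut clearance constant; the drug acts by concentration-dependent
relief of tubular reabsorption.

Renal handling is filtration minus fractional reabsorption,

    CLR_UA(Cp) = GFR − f_reabs·GFR·(1 − E(Cp)),   E(Cp) = Emax·Cp/(EC50+Cp),

so CLR_UA rises monotonically and concavely from GFR·(1−f_reabs) at
baseline to GFR·(1−f_reabs·(1−Emax)) at saturation. Reference values:
baseline SUA 5.71 mg/dL, baseline CLR_UA 7.10 mL/min, f_reabs 0.943
(implied GFR ≈ 124.6 mL/min), Vd_UA 16.0 L, Emax 0.51, EC50 196 ng/mL
(total concentration; ≈547 nmol/L, or 3.8 nmol/L free at 99.3% protein
binding).

Synthesis is closed from the baseline steady state,
Synthesis = (CLR_UA + CLGut_UA)·SUA₀ ≈ 36.5 mg/h (≈876 mg/day). The
printed cohort means are not exactly mutually consistent (575 mg/day
urinary excretion vs 7.10 mL/min × 5.71 mg/dL ≈ 584 mg/day); the
physiology container closes on (SUA₀, CLR_UA₀) and lets baseline urinary
excretion emerge, while the Xu-based arithmetic (Xf = Xu/2,
Synthesis = 3/2·Xu) remains available for data-driven baselines.

Estimation cascade, in order: baseline CLR_UA per subject as Xu_UA/AUEC
over the pre-dose day (AUEC = pre-dose SUA held for 24 h); Vd_UA per dosed
subject from the 24 h delta mass balance (ΔXu + ΔXf)/ΔSUA, averaged
arithmetically over all dosed subjects; f_reabs = 1 − CLR_UA/GFR from the
placebo arms, with GFR the urinary creatinine clearance normalized to
1.73 m² (or implied from baseline CLR_UA and f_reabs when no creatinine
data accompany a simulation request); and the Emax pair by least squares
on interval-mean effect points over the 0–6, 6–12, 12–24 and 24–48 h
windows, the observed effect back-calculated as
E = (CLR̄ − GFR(1−f_reabs))/(f_reabs·GFR), clipped to [0, 1) with a
warning when noise pushes it outside.

### A bias intrinsic to the interval-mean procedure

The back-calculated window effect is a SUA-weighted average of E(Cp(t)),
but it is plotted against the window-mean concentration. Because E is
concave, the average effect is below E(C̄p) (Jensen's inequality), so the
fitted EC50 is biased upward even on noise-free data: the whole-pipeline
identity run recovers ≈221 ng/mL against a generating 196 ng/mL (+12%),
with Emax essentially unbiased. This is a property of the estimation
procedure itself, faithfully reproduced; the identity test budgets 15% for
EC50 and 5% elsewhere. Direct refits of noise-free effect points recover
both parameters to optimizer precision.

## Forward simulator

The pool is advanced on a fixed grid (default 1 h, matching the hourly
update of the source procedure) by a conservative discrete mass balance:
per step, the drug concentration is the exact analytic mean of the
one-compartment curve over the step, clearances convert mL/min → dL/h, and

    pool ← pool + Synthesis·dt − CLR·SUA*·dt − CLGut·SUA*·dt.

Every milligram leaving the pool is booked into an excretion term, so the
residual |Δpool − Synthesis·T + ΣXu + ΣXf| is zero to rounding on every
simulation — which is also why the delta-volume estimator applied to
simulated intervals returns the generating Vd_UA to machine precision.

SUA* is, by default, a half-step (midpoint) predictor. The fully explicit
start-of-step value — the literal "use the value one hour earlier"
reading — is available via `sua_scheme="start"`, but at 1 h steps it
carries a ~3% discretization error through the steep 0–12 h SUA decline
(dt-halving check), whereas the midpoint predictor is second-order
accurate (~0.4% under the same check) and shares the same fixed points and
exact conservation; it is therefore the default. Under a constant
concentration the closed form SUA_ss = Synthesis/(CLR(Cp)+CLGut) is an
independent oracle: the discrete update has exactly that fixed point, and
trajectories reach it within 0.1% well inside ten urate half-lives. A
negative pool (physically inconsistent parameters/step) and a step that
does not divide dose or window boundaries raise immediately. Simulations
start 24 h before the first dose so the baseline interval is emitted.

## Synthetic studies

The generator emulates the SAD design (cohorts at 0.5/1/2/5/10/20 mg,
n=6 active + 3 placebo, blood at 0, 0.25, 0.5, 1, 1.5, 2, 4, 6, 8, 12, 24,
36, 48 h, urine at −24–0, 0–6, 6–12, 12–24, 24–36, 36–48 h) and the MAD
design (2 or 5 mg once daily × 7 days, day-indexed sampling, 24 h urine to
72 h after the last dose). Between-subject variability is multiplicative
lognormal (geometric-mean preserving) around the reference values; CVs use
printed SDs where a baseline SD exists (SUA 0.75 mg/dL, CLR_UA
1.51 mL/min) and the printed %CVs for the model parameters — the source
reports no true between-subject distributions, so these are declared
synthetic-population choices. Body weight is N(60, 5) kg truncated to
[50, 80], height fixed at 1.70 m, BSA by Du Bois. Residual error defaults
to 10% lognormal on plasma and 5% on serum/urine concentrations (declared,
not inferred — the source gives no residual magnitudes), with a 1 ng/mL
plasma quantitation floor (values below are emitted as 0 and flagged).
Each subject's true GFR is defined as the BSA-normalized creatinine
clearance and urinary creatinine amounts are emitted from the
un-normalized clearance, so the analysis-side normalization is an exact
inverse.

What the generator does not emulate — and hence what passing tests do not
establish about real data: assay-specific error structure, circadian or
food-driven urate variation, sampling-time deviations, dropout, fed-state
pharmacokinetics, and any renal secretion of urate. Identity tests show
the estimators invert the generating model; they cannot show the model is
right.

## Problem sizes and runtime choices

Cohort simulation uses 0.25 h steps (plasma itself is analytic); the
test-suite cohorts are shrunk to 1–2 subjects per arm where only the
identity matters, keeping the full suite in the tens of seconds. The
Monte-Carlo bias check uses 200 replicate fits at 10% noise; dispersion
checks use 4 000 subjects / 10⁵ noise draws.

## Known limitations

- One-compartment PK is fixed; no model ladder (AIC comparison) is
  re-run, and no BLQ handling exists in the fitter (the floor is applied
  by the generator only).
- The Emax fit inherits the window-aggregation bias described above; a
  continuous-time effect model would remove it but would no longer be the
  procedure under study.
- Population (mixed-effects) estimation, uncertainty propagation beyond
  point simulation, and patient-population extrapolation are out of scope.
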