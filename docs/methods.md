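# Methods

## Model overview

`gadopbpk` models the disposition of gadoxetate, an extracellular
gadolinium contrast agent with carrier-mediated hepatocyte uptake
(Oatp1a1) and biliary efflux (Mrp2), in a 0.25 kg rat. The model is
deliberately *reduced*: only the organs observed by DCE-MRI (blood,
spleen, liver) are resolved; everything else is lumped into splanchnic
and rest-of-body (ROB) compartments. All in vivo processes are linear in
concentration, so the whole-body system is a linear time-invariant ODE —
a property the test suite exploits through a matrix-exponential oracle
and dose-linearity checks.

### Compartments and fluxes

State variables (µmol/L): blood `c_b`; ROB vascular `c_rob,v` and
extravascular `c_rob,ev`, exchanging through a permeability–surface
product PS (the ROB is the one territory where a vascular–interstitial
permeability limitation is retained); spleen and splanchnic extracellular
spaces, flow-limited, draining into the portal vein; liver extracellular
space `c_liv,extr` (tissue blood + interstitium, fenestrated capillaries
assumed fast-exchanging) and hepatocytes `c_liv,cell`. Two amount states
accumulate urine (CL_r·c_b) and bile (CL_biliary·f_u,liv,cell·c_liv,cell).

Hepatocyte exchange is permeability-limited: uptake
(CL_active + CL_passive)·c_liv,extr/K_liv,extr-b, efflux
CL_passive·f_u,liv,cell·c_liv,cell. Only the unbound intracellular
fraction is available for efflux and biliary excretion. In vivo uptake is
linear (no Michaelis–Menten term): at a 25 µmol/kg dose, liver
extracellular concentrations stay well below the measured K_m,u
(~106 µM) for most of the experiment, and the linear form is what the
whole-body estimation uses.

The optional 5-subcompartment liver splits both liver spaces into five
serial units with volumes and clearances divided by five and the full
hepatic flow passed in series. At identical parameters this raises
hepatic extraction (a cascade of well-mixed units approaches plug flow),
so blood exposure is systematically a little lower than the lumped
model's (~15% in AUC at the default parameters); equivalence of the two
structures holds at the level of *data description after re-estimation*,
not at fixed parameters.

### Physiology

The study's own physiological tables are not published with the main
text, so defaults are reconstructed once from standard rat reference
values: cardiac output 110 mL/min (6.6 L/h), liver blood flow 18.3% of
cardiac output (hepatic artery 0.14, spleen 0.07, remaining splanchnic
1.00 L/h), blood volume 7.4% of body weight, liver 40 g/kg (10 mL,
matching the IVIVE liver weight), liver extracellular fraction 0.23 and
hepatocellular fraction 0.78, spleen 0.5 mL with extracellular fraction
0.35, ROB vascular 4 mL and interstitial 35 mL. Every value is a plain
dataclass field and can be overridden from config. Partition
coefficients default to 1 (gadoxetate distributes in extracellular
water; no erythrocyte partitioning is modeled). Renal elimination draws
directly from the blood compartment — no kidney sub-compartment.

With these values the forward simulation at the top-down estimates
routes ~81% of the dose to bile and ~19% to urine; the reported values
(83%/17%) depend on the unpublished physiology, which is why the
acceptance band for this quantity is ±5 percentage points.

### Signal model

ΔR1,τ(t) = r1,τ·c_τ(t) with ex vivo relaxivities (blood 6.4/6.2,
hepatocytes 7.6/6.0 L·mmol⁻¹·s⁻¹ at 4.7/7 T; spleen and extracellular
liver aliased to blood). Liver ΔR1 is the volume-fraction-weighted sum
of the extracellular and hepatocellular contributions over the
whole-organ volume; liver vascular plasma is lumped into the
extracellular space. PBPK states (µmol/L) are converted to mmol/L before
applying r1. Because each MRI frame integrates over 57 s, model
predictions are time-averages of ΔR1 over each frame, computed by
trapezoidal quadrature on the dense ODE output with ≥ 20 interior points
per frame (verified against brute-force quadrature to 1e-6 relative).
Field strengths are never mixed inside one residual: each profile is
predicted with its own relaxivities.

## In vitro model and fitting

The plated-hepatocyte assay is a closed two-compartment system: cells
(3.9 µL/10⁶ cells, 0.24 × 10⁶ cells per well at 1 mg protein per 10⁶
cells) and medium (default 500 µL for a 24-well plate — not stated in
the assay description, config-overridable). Saturable uptake is driven
by total medium concentration (medium binding was shown negligible);
only intracellular unbound drug effluxes. Fitting is per animal,
simultaneous across all nominal concentrations, unweighted on the
intracellular-concentration scale, with the nominal medium concentration
as the initial condition and c_cell(0) = 0 for synthetic data (an OLS
back-extrapolation utility estimates nonzero initial cell
concentrations from early timepoints, t ≤ 20 min inclusive, when real
data require it). Parameters are log-transformed for positivity;
censored (sub-LLOQ, 0.2 µM) records are excluded from the objective but
never altered in the data table.

## Estimation

The in vivo objective is the naïve-pooled sum of squared frame residuals
over all animals, organs and field strengths, with unit weights (no
organ- or field-specific weighting). Optimization runs in log10
parameter space with bounds [1e-4, 1e2] L/h via bounded trust-region
least squares, from 5 (default) Latin-hypercube starts. Starts are drawn
from the narrower range [1e-2, 1e1] L/h: clearances and permeabilities
of a 250 g rat live there, and starts at the extreme corners of the full
bound box occasionally stall the trust-region step and would contaminate
bootstrap dispersion with convergence artifacts. Simulation failures
inside the objective return a large penalty residual so the optimizer
survives pathological parameter draws.

The case bootstrap resamples whole animals with replacement within arm
(all of an animal's profiles move together), refitting every replicate
from the best of two fresh random starts. Replicates are *not*
warm-started at the point estimate: on a practically unidentifiable
direction the gradient is ~0 and a warm start would never move, hiding
exactly the dispersion the bootstrap is supposed to reveal. Parameters
with bootstrap CV > 100% are flagged practically unidentifiable; if more
than 5% of replicates fail, the result is flagged. The DDI analysis fits
both arms simultaneously with PS shared and CL_active/CL_biliary
arm-specific; percent inhibition is 100·(1 − CL_active,inh/CL_active).

## Uncertainty and sensitivity

Bottom-up uncertainty treats V_max, K_m,u, CL_passive,u, f_u,liv,cell,
PS and CL_biliary as independent uniforms over the per-animal min–max of
the in vitro estimates; PS and CL_biliary, which have no in vitro
measurement and are set equal to CL_passive in the bottom-up
parameterization, default to the IVIVE-scaled CL_passive,u range
(0.0066–0.0197 L/h) — a reconstruction, exposed in config. Each draw is
IVIVE-scaled and simulated; the sensitivity endpoint is the hepatocyte
AUC(0–100 h). SRC indices come from an OLS regression of the endpoint on
the inputs (SRC_i = b_i·sd(x_i)/sd(y)), with 95% CIs from 1000 row
bootstraps; results with regression R² < 0.7 are labeled unreliable
(the linear approximation is then too poor for SRC² to read as variance
fractions). At the defaults the regression achieves R² ≈ 0.93 and
CL_biliary and f_u,liv,cell carry the two largest SRC² — both parameters
gate removal of gadoxetate *from* the hepatocyte, which is what limits
liver exposure, while uptake-side uncertainty barely matters.

## Synthetic data: what it does and does not emulate

The generators reproduce the study design: in vitro, 8 nominal
concentrations (10–10 000 µM) × 11 timepoints (0.5–150 min) in
duplicate, mean-one proportional lognormal noise (default CV 10%), LLOQ
flag at 0.2 µM; in vivo, 57-s frames over a 1710-s scan (30 frames),
25 µmol/kg bolus, arm sizes {control: 33 @ 4.7 T, 43 @ 7 T; rifampicin:
7, 6}, lognormal inter-animal variability (default CV 20%) on CL_active,
CL_passive, CL_biliary and CL_r only, additive Gaussian frame noise
(default SD 0.1 s⁻¹, giving scatter comparable to observed profiles
whose peaks are ~1–3 s⁻¹). Noise structures are modeling choices — the
source data report neither — selected to match typical assay
(concentration-proportional) and MRI (signal-additive) error. Not
emulated: raw-signal/flip-angle effects and the resulting ΔR1 bias,
inter-site differences, repeat scans of the same animal, frame-timing
jitter, or body-weight variation. Passing recovery tests therefore show
the estimation machinery is correct and well-conditioned under the
assumed error model, not that the original study's estimates are
reproduced — those depend on the unavailable imaging dataset.

## Numerical choices

- Stiff-capable LSODA with analytic (constant-matrix) Jacobian,
  rtol 1e-8, atol 1e-10 µmol/L; mass balance is asserted at 1e-6
  relative at every output time.
- Bolus dosing as an initial condition in blood (duration 0); a
  zero-order infusion mode exists for solver robustness studies.
- Simulation grids use square-root time spacing (dense early); AUCs are
  trapezoidal with endpoint interpolation.
- Excretion-fraction runs double their horizon until ≥ 99% of the dose
  is excreted (error past 6400 h).
- Ties in the back-extrapolation window: t = 20 min is included.
- Problem sizes in the test suite are chosen to keep the full run on one
  CPU modest: recovery tests use 1–2 animals per field (noise-free
  recovery is scale-free), the identifiability contrast uses the full
  76-animal control arm with 100 bootstrap replicates, and the GSA uses
  2000 Monte Carlo samples (the analysis default is 10 000, which simply
  tightens the same indices).

## Known limitations

- Physiology defaults are literature reconstructions, not the study's
  own values; quantities that depend on flows (extraction ratios,
  urine/bile split) shift within a few percentage points under
  plausible alternatives.
- No nonlinear mixed-effects layer: the naïve-pooled estimator ignores
  inter-animal variability by construction, and its bootstrap CVs mix
  residual and between-animal components.
- No enterohepatic recirculation, no metabolism (gadoxetate is
  metabolically stable), no saturable in vivo uptake, no human scaling.
- The 5-compartment liver shares the single-liver parameter meaning
  only approximately; refitting is required before comparing estimates
  across liver structures.
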