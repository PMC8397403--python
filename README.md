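# gadopbpk

Physiologically based pharmacokinetic (PBPK) analysis of the hepatobiliary
MRI contrast agent **gadoxetate** in rat, built around dynamic
contrast-enhanced (DCE) MRI liver imaging.

Gadoxetate is taken up into hepatocytes by sinusoidal anion transporters
(rat Oatp1a1; human OATP1B1) and excreted into bile by Mrp2, with a
substantial parallel renal route. Because a transporter drug–drug
interaction (DDI) can change liver exposure without an obvious signature in
blood, liver-imaging data are uniquely informative for estimating hepatic
transporter kinetics. This package implements the full quantitative chain
needed to do that:

- **In vitro hepatocyte kinetics** (`gadopbpk.invitro`) — a mechanistic
  two-compartment (cell/medium) uptake model,

  dA_cell/dt = V_max·c_medium/(K_m,u + c_medium) + CL_passive,u·c_medium
  − CL_passive,u·f_u,cell·c_cell,

  fitted simultaneously across nominal medium concentrations
  (0.01–10 mM, duplicate wells, LLOQ 0.2 µM), with the derived
  CL_active,u = V_max/K_m,u.
- **IVIVE scaling** (`gadopbpk.ivive`) — µL/min/10⁶ cells →
  mL/min/kg → L/h using hepatocellularity (120 × 10⁶ cells/g liver),
  liver weight (40 g/kg) and body weight (0.25 kg).
- **PBPK core** (`gadopbpk.pbpk`) — a reduced 7-compartment model (blood,
  spleen, splanchnic organs, liver extracellular space, hepatocytes,
  rest-of-body vascular/extravascular joined by a permeability–surface
  product PS), permeability-limited liver with linear CL_active,
  CL_passive, CL_biliary, renal elimination CL_r from blood, urine/bile
  bookkeeping, and an optional 5-subcompartment serial liver variant.
- **ΔR1 signal model** (`gadopbpk.mri`) — organ ΔR1(t) = r1·c(t) with
  field-strength-dependent relaxivities (blood 6.4/6.2, hepatocytes
  7.6/6.0 L·mmol⁻¹·s⁻¹ at 4.7/7 T), liver as a volume-fraction-weighted
  mixture, and 57-s frame-interval means for residual computation.
- **Estimation** (`gadopbpk.estimation`) — naïve-pooled nonlinear least
  squares, simultaneous control+rifampicin fitting with shared PS, case
  (animal-level) bootstrap CVs, percent inhibition, and a blood-only
  ablation that exposes the practical non-identifiability of CL_biliary
  without liver data.
- **Uncertainty / sensitivity** (`gadopbpk.gsa`) — Monte Carlo propagation
  of uniform assay uncertainty and standardized-regression-coefficient
  (SRC) global sensitivity analysis of the hepatocyte AUC(0–100 h).
- **Synthetic data** (`gadopbpk.synthetic`) — generators for both input
  kinds with known ground truth, emulating the study design (33/43 control
  and 7/6 rifampicin animals at 4.7/7 T, 57-s frames, 25 µmol/kg bolus).

## Worked example

Generate a noise-free synthetic control study at the top-down clearances
and refit it:

```python
from gadopbpk import (GadoxetateParams, PhysiologyParams, InVivoDesign,
                      FitSpec, generate_dcemri_dataset, fit_control)

truth = GadoxetateParams(CL_active=2.17, CL_biliary=0.07, PS=0.62)
phys = PhysiologyParams()
design = InVivoDesign(n_animals_per_arm={"control": {4.7: 1, 7.0: 1}},
                      interanimal_cv=0.0, noise_sd=0.0, seed=202)
profiles, _ = generate_dcemri_dataset(truth, None, phys, design)
result = fit_control(profiles, FitSpec(seed=1, n_starts=3), phys)
print({k: round(v, 4) for k, v in result.estimates.items()})
```

prints

```
{'CL_active': 2.17, 'CL_biliary': 0.07, 'PS': 0.62}
```

i.e. the active uptake, biliary and rest-of-body permeability clearances
(L/h) are recovered exactly from blood+spleen+liver ΔR1 frames. The same
pipeline is available from the shell:

```
gadopbpk generate-synthetic --seed 7 --out data
gadopbpk fit-control --data data/deltaR1.csv --seed 7 --out fit
```

Forward-simulating the fitted model until the dose is fully excreted:

```python
from gadopbpk import DoseEvent, excretion_fractions
from gadopbpk.pbpk import simulate_to_excretion
urine, bile = excretion_fractions(
    simulate_to_excretion(truth, phys, DoseEvent.bolus_per_kg()))
print(f"{urine:.1f}% urine, {bile:.1f}% bile")
```

prints `19.0% urine, 81.0% bile` — gadoxetate elimination is dominated by
the biliary route at these clearances.

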