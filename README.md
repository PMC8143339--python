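# conapkpd

Semi-mechanistic PK/PD/disease-progression modelling of **GRMS-55** — a dual
PDE7A/PDE4B inhibitor — in concanavalin-A (ConA)-induced hepatitis, the most
widely used mouse model of autoimmune hepatitis.

The package is aimed at pharmacometricians and preclinical modellers who want
to simulate the model, refit it to their own serum time-course data, or test
estimation workflows on synthetic studies with the original trial's design.

## The model

**Pharmacokinetics** — one-compartment, first-order absorption and
elimination after IP dosing:

```
dA/dt = −ka·A,            A(0) = Dose          (per kg; F folded into Vd/F)
dX/dt = ka·A − ke·X,      C = X / (Vd/F)
```

GRMS-55 shows flip-flop kinetics in mice (ka = 1.49 h⁻¹ < ke = 4.59 h⁻¹), so
the terminal slope of the concentration profile reflects absorption.

**Cytokine cascade** — a hypothetical precursor T₁ is switched to 1 at the
ConA challenge (0.5 h after dosing) and decays with mean transit time τ.  It
feeds four transit-compartment pathways driving indirect-response models for
TNF-α (1 pathway compartment), IFN-γ (7), IL-6 (6) and IL-10 (1):

```
dT₁ₓ/dt = T₁·(1 − Imax·C/(IC50 + C)) − T₁ₓ/τ        (drug-sensitive input)
dTₙ₊₁/dt = (Tₙ − Tₙ₊₁)/τ                            (chain transfer)
dCₓ/dt  = (1 + Tlast·Sₓ)·kin_x − kout_x·Cₓ,          kin_x = R0_x·kout_x
```

IL-10 has no direct drug effect; after the challenge an extra zero-order
production `kin_IL10(dis)` switches on, stimulated by the precursor and
linearly inhibited by IFN-γ: `F = 1 + T₁c·S_IL10 − C_IFNγ·I_IL10(IFNγ)`.

**Disease progression** — ALT and AST turnover driven by the cytokine excess
over baseline, with power exponents α = β = 1.5 (fixed) on the ALT side:

```
dA_ALT/dt = (1 + (C_TNFα−R0)^α·S)·(1 + (C_IFNγ−R0)^β·S′)·kin_ALT − kout_ALT·A_ALT
dA_AST/dt = (1 + (C_TNFα−R0)·S)·(1 + (C_IFNγ−R0)·S′)·kin_AST − kout_AST·A_AST
```

**Estimation** is sequential weighted least squares on naively pooled
animal-level data (destructive sampling: one observation per mouse):
PK first, then the four cytokine pathways jointly with PK fixed, then the
six ALT/AST parameters with everything upstream fixed.  Weights default to
1/ŷ² (relative error); fits run in log-parameter space with bounded
trust-region least squares, and precision is reported as asymptotic CV%.

## Worked example

```python
import conapkpd as cp

params = cp.reference_parameters()          # packaged reported estimates

# vehicle-control simulation and predicted peak times (post-ConA)
traj = cp.simulate_group(params, dose=0.0, t_end=30.0)
for analyte in ("TNFa", "IL6", "IFNg", "ALT", "AST"):
    peak = cp.predicted_tmax(traj, analyte)
    print(f"{analyte:5s} tmax = {peak.time:5.2f} h   peak = {peak.value:8.1f}")

# synthetic study at the trial design, then sequential refit
table = cp.generate_study(cp.StudyDesign(), params, noise_cv=0.0, seed=1)
pk_fit, pd_fit, dis_fit, final = cp.fit_sequential(table)
print(f"Vd/F = {pk_fit.estimates['Vd_F']:.3f} L/kg,  "
      f"IC50(TNF-a) = {pd_fit.estimates['IC50_TNFa']:.3f} mg/L")
```

prints

```
TNFa  tmax =  1.70 h   peak =    126.7
IL6   tmax =  3.60 h   peak =   1984.2
IFNg  tmax =  4.58 h   peak =    688.1
ALT   tmax =  7.14 h   peak =    308.8
AST   tmax =  8.17 h   peak =   2039.1
Vd/F = 1.810 L/kg,  IC50(TNF-a) = 7.970 mg/L
```

The cytokine peaks fall in the reported 1.5–4.5 h post-ConA window, the
transaminases peak hours later (liver damage follows the cytokine wave), and
refitting noise-free synthetic data returns the generating parameters —
the package's core round-trip check.

A CLI mirrors the library: `conapkpd simulate|generate|fit-pk|fit-pd|
fit-disease|nca|recover --help`.

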