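# biokin

Mechanistic biokinetics for in vitro toxicology: a **virtual cell based
assay (VCBA)** simulator of chemical fate and cytotoxicity in multi-well
plates, a declarative **physiologically based kinetic (PBK)** engine
with oral and dermal exposure routes, and an **in vitro–in vivo
extrapolation (IVIVE)** layer that couples the two into
dose ↔ viability tables.

It is written for toxicologists and risk assessors who need to reason
about *internal* concentrations: what fraction of a nominal well
concentration actually reaches the cells once volatilization, plastic
binding and degradation have taken their share; what (NEC, kt) toxicity
parameters best explain a measured dose–response; and what external
dose in vivo would produce the internal exposure that killed cells in
vitro.

## The models

**Well model.** One well carries five chemical pools — dissolved,
headspace, plastic-bound, intracellular, degraded — and a four-stage
cell-cycle population N₁…N₄ with division doubling the stage-4 outflow:

    dNᵢ/dt = kᵢ₋₁Nᵢ₋₁ − (kᵢ + mᵢ + k_tox)Nᵢ,   dN₁/dt = 2k₄N₄ − (k₁ + m₁ + k_tox)N₁

Volatilization follows a two-film model (1/k_vol = 1/k_w + 1/(k_a·Kaw))
with diffusivities from the Fuller and Hayduk–Laudie correlations;
cell–water partitioning uses the composition sum
K_cw = f_water + f_lipid·Kow + f_protein·β·Kow. Toxicity is the hinge
law

    k_tox = kt · max(0, c_cell − NEC)

with c_cell the intracellular concentration in g chemical / g cell wet
weight, and viability the treated/control cell-count ratio.

**Fitting.** (NEC, kt) are estimated by bounded Nelder–Mead
minimisation of `error = Σᵢ (Viability_exp,i − Viability_sim,i)²`,
each simulated point being a full well run.

**PBK.** Perfusion-limited compartments, dAᵢ/dt = Qᵢ(C_art − Cᵢ/Pᵢ),
venous pooling C_ven = ΣQᵢ(Cᵢ/Pᵢ)/ΣQᵢ, first-pass oral absorption into
the liver, a finite dermal depot, Michaelis–Menten or linear hepatic
clearance, renal elimination from blood; Cmax, Tmax and trapezoid AUC
per compartment.

**IVIVE.** Each external dose is run through the PBK model; the
target-compartment concentration profile then drives the cell
population model over the exposure window, producing a monotone
dose → internal metric → predicted viability table supporting inverse
(viability → dose) lookup.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Simulate one synthetic chemical against the bundled 24 h-doubling cell
line, then refit the toxicity parameters from noisy data the model
itself generated:

```python
from biokin import fixtures as fx
from biokin.engine import core_model, mass_balance
from biokin.fitting import fit

ctx = fx.make_context()          # inert chemical, 24 h doubling line, 96-well
for c in (5e-8, 1.45e-7, 2.8e-7, 5.4e-7, 1e-6):   # mol/cm^3 nominal
    res = core_model(c, 0.0, 1e5, 5e-5, 500.0, ctx)
    print(f"{c:.2e}  viability={res.viability_end:.4f}  "
          f"c_cell_end={res.frame['c_cell'].iloc[-1]:.3e}  "
          f"drift={mass_balance(res):.1e}")

obs = fx.make_viability_observations(5e-5, 500.0, noise_sd=0.02, seed=3,
                                     context=ctx)
r = fit(1e-4, 1000.0, obs, ctx)
print(f"nec_hat={r.nec_hat:.3e}  kt_hat={r.kt_hat:.1f}  "
      f"error={r.error:.4f}  evals={r.n_evaluations}")
```

prints

```
5.00e-08  viability=1.0000  c_cell_end=1.777e-05  drift=1.8e-15
1.45e-07  viability=0.9571  c_cell_end=5.155e-05  drift=6.8e-16
2.80e-07  viability=0.2985  c_cell_end=1.004e-04  drift=1.1e-15
5.40e-07  viability=0.0316  c_cell_end=1.942e-04  drift=6.1e-16
1.00e-06  viability=0.0006  c_cell_end=3.598e-04  drift=1.7e-15
nec_hat=4.955e-05  kt_hat=508.9  error=0.0026  evals=183
```

Reading it: the lowest concentration never pushes the intracellular
concentration (1.8e-5 g/g ww) over the NEC of 5e-5, so viability stays
at 1; each 2× concentration step then cuts survival sharply as the kill
rate scales with the excess over NEC; total chemical mass is conserved
to ~1e-15 relative in every run. The fit recovers the generating
parameters (NEC 5e-5, kt 500) to within ~1–2 % from 2 %-noise data,
starting from a guess 2× off.

The same workflows are available from the shell — `biokin vcba-single`,
`vcba-repeat`, `vcba-fit`, `vcba-check`, `pbk`, `ivive` and
`make-fixtures` (which writes a complete ready-to-run input set); every
run directory gets a manifest with a config hash, and identical configs
produce byte-identical outputs.

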