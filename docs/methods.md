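# Methods

This note describes the models implemented in `biokin`, the choices made
where the design was genuinely open, and what the synthetic test inputs
do and do not establish about real assay data.

## The well model (virtual cell based assay)

One culture well is described by ten coupled states: five chemical pools
(dissolved in medium, headspace, sorbed to well plastic, inside cells,
and a cumulative degradation sink, all in mol; a sixth optional debris
sink holds the burden of dead cells when enabled) and four cell-cycle
stage counts. The coupled system is integrated with LSODA at relative
tolerance 1e-8 and mass-scaled absolute tolerances, which holds the
total-inventory drift far below the 1e-6 contract bound.

### Fate and transport

* **Volatilization** uses a two-film model across the air-water
  interface: `1/k_vol = 1/k_w + 1/(k_a·Kaw)`, with film conductances
  `k_w = D_water/δ_w` and `k_a = D_air/δ_a`. The stagnant-film
  thicknesses default to δ_w = 0.01 cm and δ_a = 0.5 cm, conventional
  orders of magnitude for unstirred plates; both are configuration
  values, not claims about any particular assay. `Kaw = 0` disables the
  term entirely instead of dividing by zero. The exchange area is the
  well bottom area (the free liquid surface of a vertical-walled well).
* **Diffusivities** come from the Fuller correlation (gas phase, using
  molecular weight and the atomic diffusion volume) and the
  Hayduk–Laudie correlation (aqueous, using the molar volume), both at
  37 °C and 1 atm with water viscosity 0.6913 cP. All constants live in
  `FateConfig`.
* **Plastic binding** is reversible first-order sorption to the wall
  area with equilibrium `log10 K_plastic = a·logKow + b`
  (defaults a = 0.97, b = −6.94, K in cm) split into on/off rates with a
  fixed desorption rate (0.1 /h). The linear-free-energy form and its
  constants are configuration, chosen to give weak sorption for neutral
  hydrophilic chemicals and appreciable sorption above logKow ≈ 4.
* **Degradation** is first order in the medium and in the headspace;
  both losses accumulate in the sink pool so the balance stays closed.
* A **sealed-plate** flag freezes the headspace (no volatilization, no
  headspace degradation).

### Cells, uptake, toxicity

The population is resolved into the four cell-cycle stages with exit
rates `k_i = 1/duration_i`; the stage-4 outflow doubles into stage 1
(division). Runs start at the dominant right eigenvector of the
stage-transition matrix (the asymptotic stage split), so a chemical-free
population grows exactly exponentially from t = 0; any other choice adds
a transient that would make growth-calibration statements ill-posed.
Because the toxic death rate is applied uniformly to all stages, the
stage split remains at this eigenvector throughout a run, which is what
makes the five-parameter core-model contract (medium concentration,
intracellular concentration, cell count, NEC, kt) a complete state for
chaining runs.

Intracellular partitioning uses a wet-weight composition sum,
`K_cw = f_water + f_lipid·Kow + f_protein·β·Kow` (β = 0.05), giving the
equilibrium `c_cell = K_cw · C_medium · MW / ρ_cell` in g/g wet weight.
Uptake is kinetic by default — first-order relaxation toward that
equilibrium with rate constant `k_up` (default 100 /h, i.e. fast against
every other time scale) — with an instantaneous-equilibrium switch that
re-partitions the combined medium+cell inventory algebraically at every
step. Dying cells release their burden back to the medium by default
(mass conservation); a debris-sink flag retains it instead.

Toxicity is the hinge law `k_tox = kt · max(0, c_cell − NEC)` added
identically to every stage's death rate. NEC is an intracellular
concentration in g chemical per g cell wet weight; kt has units
1/((g/g ww)·h). Viability is the treated/control cell-count ratio at
matched end times; the control is the matrix exponential of the linear
growth system, which is exact and keeps the whole engine deterministic.
When the killing term provably cannot switch on (kt = 0, or the
full-partition equilibrium of the entire inventory stays below NEC),
viability is reported as exactly 1 rather than as a solver-noise ratio.

### Exposure modes

Single exposure runs each nominal concentration independently from
identical fresh initial conditions. Repeated exposure restarts the
integrator at every dosing time; the medium is refreshed to the nominal
concentration, the headspace is vented (reset to zero), plastic-bound
chemical is retained (same physical plate), and cells with their burden
carry over. The mass ledger tracks the inventory added and discarded at
each reset so the balance check remains defined across doses. Both the
headspace and plastic behaviours are switchable, since assay practice
varies.

## NEC/kt fitting

The objective is the plain sum of squared viability residuals,
`error = Σ_i (viability_exp,i − viability_sim,i)²`, each simulated
viability coming from a full well simulation at the observation's
nominal concentration. Minimisation is bounded Nelder–Mead on
parameters scaled by the starting guess (scaling by the distant bounds
makes the simplex steps wildly anisotropic and strands the search on
the saturated-response plateau), with a budget of 500 objective
evaluations, convergence when the improvement falls below 1e-10, and a
deterministic restart from the incumbent while budget remains. A
regulariser at the 1e-13 scale breaks plateau ties toward small kt then
small NEC without moving any genuine optimum. If every observed
viability is ≥ 0.99 the data carry no toxicity signal and kt = 0 is
reported with a warning instead of an arbitrary number.

## The PBK engine

Perfusion-limited, fully declarative: a model is a list of compartments
(volume, blood flow, tissue:blood partition coefficient, liver/skin
flags), so different published body layouts are configurations rather
than code. Tissue equations are `dA_i/dt = Q_i(C_art − C_i/P_i)`; blood
is a flow-weighted mixing node with arterial equal to venous (no lung
compartment). Oral dosing is first-order absorption from a gut depot
directly into the liver (first-pass); the unabsorbed fraction goes to a
loss accumulator. Dermal dosing uses a finite skin-surface depot
transferred first-order at `kp·A/V_vehicle`, with a constant-flux
infinite-vehicle mode. Hepatic clearance is Michaelis–Menten or linear
intrinsic clearance on the liver free concentration; renal elimination
is first-order on venous blood with blood volume taken as 0.074 L/kg
body weight (a package convention — the spec of a model supplies only a
rate constant, and some blood volume is needed to turn it into a flux).
Metabolites are not simulated mechanistically; an optional
stoichiometric fraction of hepatically cleared mass is accumulated for
book-keeping only. Cmax/Tmax are read from the output grid (default
0.1 h) and AUC uses the trapezoid rule on that grid, so grid resolution
bounds the accuracy of peak capture; the closed-form checks use a finer
grid for exactly that reason.

## The extrapolation layer

For each external dose (mg/kg body weight) the PBK model produces the
target-compartment concentration time course; the four-stage population
model is then driven by the corresponding time-varying kill rate, i.e.
the dynamic effect model is applied to the in vivo profile rather than
to a scalar summary (a constant-at-Cmax mode exists for comparison).
The unit bridge from mg/L tissue to g/g wet weight assumes tissue
density 1 kg/L (1 mg/L = 1e-6 g/g ww) and is configurable; it is the
single largest modelling assumption in the chain. The resulting table
(dose, internal metric, predicted viability) is strictly increasing in
dose and non-increasing in viability; interpolation is piecewise linear
in both directions, and viability queries on flat segments return the
smallest consistent dose. Viability at dose 0 is exactly 1 by
construction.

## Synthetic inputs

All test data come from `biokin.fixtures`. The chemical profiles
(volatile / lipophilic / hydrophilic / inert), the 96-well geometry, the
toxicity defaults (NEC = 5e-5 g/g ww, kt = 500) and the concentration
grid (2e-8–2e-6 mol/cm³) were chosen once for conditioning — the
resulting viability curves span roughly 0.05–0.95 over the grid — and
are explicitly not literature values for any real chemical. The cell
line generator inverts the growth eigenvalue analytically
(λ = k(2^¼ − 1) for four equal stages), so a requested doubling time is
met exactly rather than tuned. Observation noise is Gaussian, seeded,
and clamped to [0, 1].

What passing tests show: the implementation solves its stated equations
correctly (conservation, closed forms, eigenvalue growth, linear-system
superposition, inverse-interpolation identities) and the fitting
machinery recovers parameters from data the model itself generated.
What they do not show: that the fate correlations, the partitioning
model, the uniform-stage toxicity law or the unit bridge describe any
particular real chemical, cell line or body — those are exactly the
parameters a user must supply from measurement or the literature.

## Problem sizes and numerical defaults

Default runs integrate 48 h wells (72 h for the conservation matrix) at
output grid 1–2 h; parameter-recovery studies use 8 concentrations and
20 parameter draws per noise level; PBK closed-form checks use a
240–400 h horizon on a 0.02–0.05 h grid. Integrator tolerances are
rtol 1e-8 with absolute tolerances scaled to the initial inventory
(mass pools) and population (stage counts). Degenerate inputs are
handled explicitly: zero Kaw disables volatilization, zero cells give
zero uptake and zero intracellular concentration, an extinct control
raises rather than dividing by zero, and a zero initial inventory makes
the mass-balance drift 0 by convention.

## Known limitations

No serum-protein binding, pH/ionisation corrections, metabolism in the
well, stage-specific toxicity, well-to-well variability or medium
evaporation; no enterohepatic recirculation, inhalation route,
population variability or mechanistic metabolite kinetics in the PBK
layer; no uncertainty quantification on fitted parameters. The
viability endpoint is a cell-count ratio, a deliberate simplification
of assay readouts such as ATP or enzyme leakage.
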