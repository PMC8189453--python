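# Methods

## The model

`dorsalgrad` simulates steady-state formation of the nuclear Dorsal (Dl)
gradient in the syncytial *Drosophila* blastoderm with a mass-action
reaction-diffusion network on a one-dimensional compartmental domain. The
domain is the ventral→dorsal half of a transverse embryo section, taken as
symmetric about both midlines: 50 equal compartments on [0, 1] (compartment
centers at (i + ½)/50), with zero-flux boundaries at both ends. Each
compartment is one well-mixed nucleo-cytoplasmic unit; no nuclear/cytoplasmic
volume ratio is modelled, so all species share one concentration unit system.

Nine species are tracked (Dl always as the dimer; DlC and DlCT carry one Dl
dimer and one Cactus unit each):

| symbol | meaning |
|---|---|
| cDl⁰ | free cytoplasmic Dl dimer |
| nDl⁰ | nuclear Dl entered by direct (Toll-independent) flow |
| C_f | free Cactus (IκB) |
| DlC | 2Dl–Cactus trimer |
| T | free activated Toll receptor |
| DlCT | Toll-bound signalling complex |
| C_ub | phosphorylated/ubiquitinated Cactus |
| cDl* | Toll-phosphorylated cytoplasmic Dl dimer |
| nDl* | nuclear Dl entered via the Toll route |

Reactions (k's are dimensionless rate constants per characteristic time;
k5, k7 bimolecular):

    ∅ → C_f            rate k1·cDl⁰      Dl-dependent Cactus synthesis
    C_f → ∅            rate k2·C_f       Toll-independent Cactus turnover
    cDl⁰ ⇌ nDl⁰        k3 / k4           direct nuclear flow
    cDl⁰ + C_f ⇌ DlC   k5 / k6
    DlC + T ⇌ DlCT     k7 / k8
    DlCT → cDl* + C_ub + T   k9          Toll-triggered dissociation
    C_ub → ∅           k10               proteasomal degradation
    cDl* → nDl*        k11               Toll-route nuclear import
    nDl* → cDl⁰        k12               nuclear export

cDl⁰, C_f and DlC diffuse along the axis (dimensionless diffusivities D_Dl,
D_C, D_DlC in half-embryo-lengths² per characteristic time); the other six
species are immobile. Activated Toll is initialized as a Gaussian
`toll_amp · exp(−x²/(2·toll_sigma²))` pinned at the ventral midline
(amplitude parameterization, evaluated at compartment centers) and is
conserved per compartment (T + DlCT is constant) because the Toll receptor
is recycled by the dissociation step. The initial condition is uniform
cDl⁰ = [Dl]_tot with every other Dl/Cactus species zero, so the total Dl
dimer count n_compartments × [Dl]_tot is an exact invariant of the dynamics.

The shipped defaults are the calibrated wild-type values ([Dl]_tot = 0.525,
toll_amp = 8.54, toll_sigma = 0.1995, k1…k12 and the three diffusivities as
in `ModelParameters`). Concentrations are expressed in units of the
ventral-most wild-type nuclear-Dl level, which is why the simulated
wild-type ventral peak sits near 1.

### Structural switches

Three points of the network are not forced by the reaction scheme itself and
are exposed on `StructuralOptions`, with the defaults chosen by an explicit
arbiter:

* **Cactus synthesis driver** — synthesis is first-order in a Dl pool; the
  default driver is free cytoplasmic Dl (k1·cDl⁰). The alternative
  (total cytoplasmic Dl) is selectable; the default is retained because it
  reproduces the mutant total-Cactus fractions (90.7 / 53.4 / 71.8% of wild
  type) to a fraction of a percentage point, while the alternative misses
  them by 3–19 points.
* **Nuclear-export destination** — nDl* exits to the free cytoplasmic pool
  (cDl⁰). Returning it to cDl* instead creates an absorbing loop under the
  irreversible dissociation step, which drains the Toll branch at steady
  state; the option exists for completeness.
* **Toll recycling** — the dissociation step returns T to the free activated
  pool (consumptive Toll is selectable but eliminates the persistent DlCT
  gradient at steady state).

Validation note: rate constants and concentrations may be zero (perturbation
sweeps use k9 = k10 = 0 and toll_amp = 0); only the Toll-profile width must
be strictly positive.

## Steady-state solution

Spatial discretization is the second-order central stencil with reflective
ghost values (zero-flux), which conserves each diffusing species' total
exactly. Two integration routes are provided:

* **`method="bdf"`** (reference): scipy's variable-order implicit multistep
  (BDF) integrator with an analytic sparse Jacobian, run in geometrically
  growing time chunks. Only the steady state is consumed downstream, so any
  stiff multistep family is equivalent here; this equivalence is tested, not
  assumed.
* **`method="pseudo"`** (fast path): pseudo-transient continuation —
  implicit-Euler steps, one modified-Newton sparse LU solve per step, with
  the time step governed by switched evolution relaxation (the step grows
  with the achieved residual reduction, bounded by ×1.2…×4 per step, and is
  cut ×0.25 when a step leaves the non-negative orthant or inflates the
  residual more than tenfold). As the residual falls the iteration turns
  into full Newton. This route solves a wild-type steady state in ~100
  linear solves and is the default for Genetic-Algorithm evaluations.

Steady state is declared when max|dy/dt| ≤ `steady_tol` × max(1, max|y|),
with `steady_tol = 1e-9` by default (1e-7 for GA evaluations, where the loss
is insensitive below that level). The time cap is t_max = 1e6 characteristic
times: the slowest constants (k4 = k12 = 0.0022) set a ~10³ relaxation
scale. Concentrations that undershoot zero by less than 1e-12 are clipped;
larger negatives abort with a diagnostic. The two routes agree to ~5e-8
relative on the wild type; a one-compartment algebraic oracle (the slaved
species eliminated in closed form, then a two-unknown root find in
log(cDl⁰), log(C_f)) agrees with the integrator to ~1e-9.

## Scenarios and metrics

Genotypes are parameter overrides/multipliers on the wild-type set; only
[Dl]_tot and/or k1 differ between the quantified genotypes (total Cactus is
an output, not an input). Comparison metrics: total Cactus fraction
(mutant/wild-type sum over Cf + C_ub + DlC + DlCT, spatially summed),
per-species percent change in a region ("ventral"/"dorsal" = the
corresponding extreme compartment, "mean" = unweighted spatial mean), and
gradient metrics (peak and basal read at the first and last position,
amplitude = peak − basal, slope by central differences with one-sided ends).
Percent-change tolerance against the published mutant table is ±1
percentage point.

## Calibration

The objective is the quadratic loss Σ_j (nDl_model(x_j) − nDl_data(x_j))²
with the model's total-nDl profile linearly interpolated onto the data
positions (data may be nucleus-indexed). The Genetic Algorithm uses binary
codification (16 bits per parameter), k-tournament selection (k = 3),
uniform bit-wise crossover (rate 0.9), bit-flip mutation (rate 1/genome
length), elitism (the best individual survives unchanged, making the
per-generation best cost non-increasing), and an epidemic restart that
keeps the top 5 individuals and re-randomizes the rest after 25 generations
without improvement. Default search bounds span four log-decades centred on
the wild-type values for kinetic constants and diffusivities (decoded in
log space) and fixed linear ranges [0, 1] / [0, 20] / [0.05, 0.5] for
[Dl]_tot / toll_amp / toll_sigma. Simulations that fail to converge receive
a penalty cost of 1e6 rather than aborting the run. Runs are fully
deterministic given the seed. Default scale is population 100 × 200
generations; the validated recovery experiment uses a reduced scale
(population 40, 60 generations) to keep a full run in the minutes range on
one CPU.

Elite analysis selects individuals with cost ≤ 0.069 and reports
per-parameter histograms (log-binned for log-bounded parameters) with an
IQR/median "narrow" flag for the parameters the data pin down.

## Dimensional analysis

The fit uses steady-state data only, so the characteristic time is anchored
to a process with a known time scale: Dl nuclear import (2–5 min from live
imaging). The effective dimensionless import constant is the concentration-
weighted mean k_eff = (k3·cDl⁰ + k11·cDl*)/(cDl⁰ + cDl*) at the ventral-most
compartment of the wild-type steady state (≈0.0373; bounded by k3 and k11
by construction). Matching k_eff/t_char to the 1/300–1/120 s⁻¹ window gives
t_char = k_eff × (120, 300) s ≈ (4.5, 11.2) s. Diffusivities convert via
D_phys = D_dimless · L²/t_char with L = 245 μm (half-embryo length), giving
0.18–0.45 μm²/s for DlC. Two length scales are deliberately separated: L
converts diffusivities, while the compartment width dx = 1/50 is used for
the transport-vs-reaction comparison D_DlC/dx² = 0.08475 ≪ k11, k6. The
lateral transport coefficient uses the 1-D diffusive length √(2Dt) per
compartment width and is an order-of-magnitude statement only.

## Synthetic data

The generator emulates embryo quantifications: ~50 positions on the half
axis, mean ± s.e.m. over replicate embryos. The model-based mode simulates
a steady state from truth parameters and adds per-measurement Gaussian
noise (default sd 0.05 in nDl units over 10 embryos — chosen so a perfect
model scores a residual of ~0.0125, the scale of the published best fit);
the phenomenological mode uses a Gaussian-plus-basal closed form. Noise is
additive and homoscedastic by default (the study reports mean ± s.e.m.
without a noise model); a proportional-noise option and a position-jitter
option (nucleus-indexed sampling) exist but are off by default. What the
generator does not emulate: imaging artefacts, nucleus segmentation error,
inter-embryo gradient-shape variability, and the true inter-embryo vs
inter-nucleus variance split — parameter-recovery results on synthetic data
therefore demonstrate the calibration machinery, not the identifiability of
the parameters from real embryo images.

## Known limitations

* The network is a reconstruction from the described reaction scheme; the
  three structural switches mark the points where more than one reading was
  possible. With the shipped constants the model reproduces the quantified
  mutant table, the effective import constant and the dimensional chain to
  within ~1%, but two prose-level claims about Dl-Cact trimer reductions in
  mutants (~30%/~50%) come out at roughly half that size under every
  switch setting; the package reports its computed values.
* Steady-state profile data do not identify all 18 parameters individually.
  In particular, at steady state nDl* = k9·DlCT/k12 while cDl* = k9·DlCT/k11,
  so k11 reaches the observable nuclear-Dl profile only through the
  negligible cDl* pool: calibration constrains combinations such as k9/k12
  and k3/k4 but leaves k11 (hence the ratio k11/k12) essentially free.
  Recovery experiments on synthetic data show exactly this pattern — loss at
  the floor and the profile reproduced to well under 2%, with k3/k4 inside
  25% but k11/k12 unconstrained.
* Nuclear-division-cycle dynamics, Toll receptor saturation, DlC shuttling
  and nuclear DlC import are outside the model by design.
* High fitted diffusivities for cDl⁰ and C_f (~10⁵–10⁶ μm²/s after
  dimensionalization) should be read as "fast enough to be uniform", not as
  physical estimates.
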