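# Methods

## The model

A chemotactic cell can read a chemoattractant gradient in two ways: by
comparing its signaling output at different points along its path
(*temporal sensing*) or by comparing the output between its leading and
trailing halves at one instant (*spatial sensing*). `chemosense` asks which
strategy yields the larger signaling output for a cell equipped with one of
the two canonical adaptive three-node circuits, as a function of a small
set of dimensionless groups.

### Circuits

Both circuits contain an activator A, an inactivator B and an output C
(activated fractions). In dimensionless time τ = t·l_BC (l_BC is the
deactivation rate of C, ≡ 1 internally; all other rates are ratios to it):

    dA/dτ = k_IA·I − l_FA·A
    dB/dτ = k_CB·C − l_FB              (NFB: negative integral feedback)
          = k_IB·I − l_FB·B            (IFF: incoherent feedforward)
    dC/dτ = k_AC·A·(1−C)/(K_AC+1−C) − l_BC·B·C/(L_BC+C)

The NFB decay of B is zero-order, which makes the feedback integral: the
only steady state has C* = l_FB/k_CB, independent of the input, so
adaptation is analytically perfect. B is clamped at zero (a pool cannot go
negative under zero-order decay). The IFF adapts because A* and B* are both
proportional to I, so the C nullcline is input-independent. C carries
saturable (Michaelis–Menten) activation and deactivation and stays in
[0, 1].

### Parameter screen

Rate constants are drawn log-uniformly over 10⁻¹–10³ and the two
equilibrium constants over 10⁻³–10, following the classic three-node
adaptation-screen methodology. Each set is scored on a step response
(I 0.5 → 0.6 at τ = 0, horizon τ = 50) by its sensitivity
S = (ΔC/C₀)/(ΔI/I₀) and precision P = (C₀/|C_end − C₀|)/(I₀/ΔI); sets with
S ≥ 1 and P ≥ 10 pass (P = +∞ when adaptation is numerically exact). The
screen is a pure filter in sampling order under a fixed seed, so results
are reproducible and selection needs no ranking function. Pass rates are
roughly 4% (IFF) and 9% (NFB) under these defaults, so screening stops as
soon as the requested number of sets has passed.

The step magnitude, horizon and thresholds are this package's own
defaults (a 20% step is a modest probe; S ≥ 1 / P ≥ 10 are the
conventional cutoffs of the screening literature). They matter: the
screen's admitted adaptation times θ_B feed directly into the size of the
temporal output downstream (see *Known limitations*).

### Ring cell in a gradient

The membrane is a ring of diameter d (circumference π·d), discretized into
N = 20 equal arc compartments with half-offset angles so that front and
back halves contain exactly N/2 compartments each. Species diffuse along
the ring (second-order central differences, periodic); each compartment
runs the circuit on the input at its own axial position. All physics enters
through

* β = v/(d·l_BC) — cell speed over (diameter × signaling rate),
* α = v·k/l_BC — rate of input change experienced by the moving cell,
* D′_X = D_X/(d²·l_BC) — diffusivity of species X relative to signaling,

with D′_C = 0 by default (a diffusible output erases spatial information).
The gradient region occupies axial x′ ∈ [0, β·T_s] (the center crosses it
in exactly T_s = 10); beyond it the field is flat at I_H. Shapes: linear
(I = I_L + (α/β)x′), exponential (matching the linear shape's logarithmic
slope at I_L), and a simple step. At τ = 0 the cell center sits at x′ = 0
and all compartments are at the I_L steady state; the run ends at
τ = T_s + 20, long enough for re-adaptation at the plateau.

N = 20 passes a grid-refinement check: doubling N changes both output
functionals by < 1% in the default scenario.

### Output functionals and decision

    O_T = (1/N) ∫₀^{τ_end} Σ_i (C_i(τ)/C_i(0) − 1) dτ
    O_S = ∫₀^{τ_end} (Σ_front C_i / Σ_back C_i − 1) dτ

integrated by the trapezoidal rule on the stored grid (spacing 0.05). The
integration horizon is the full simulated window — entry, transit and
exit/re-adaptation — for both functionals. Decision: if only one output is
positive, that strategy wins; if both, temporal wins iff O_T/O_S ≥ 1 (ties
to temporal); if neither, sensing has failed.

## Numerics

* Deterministic runs: LSODA (adaptive, stiff-capable), rtol 10⁻⁸,
  atol 10⁻¹¹. The tight tolerances matter because at α = 10⁻⁵ the signal in
  C is parts-in-10⁵ of baseline.
* Stochastic runs: fixed-step Strang splitting at Δτ = 0.01 so that noise
  realizations are independent of step-size control. Diffusion is applied
  exactly through the matrix exponential of the discrete ring Laplacian
  (unconditionally stable for any D′, which reaches 10³ in the sweeps);
  the reaction part uses an exponential-Euler update that is exact for the
  linear A/B kinetics and L-stable for the stiff C relaxation (screened
  sets reach |∂Ċ/∂C| ~ 10³). Against LSODA the scheme agrees to ~10⁻⁷ in C
  on noiseless runs.
* Steady states: NFB closed-form; IFF by bracketed root-finding of the
  (strictly decreasing) C nullcline on [0, 1] to near machine precision.
* Degenerate inputs raise explicit errors: a null step has no defined S or
  P; a zero back-half output makes O_S undefined (recorded as a failed
  replicate inside ensembles rather than raised).

## Noise models

**External (ligand) noise** is a frozen spatial texture: one truncated-
normal deviate (±3σ) per patch of length d along the track, fixed for the
whole run. The noisy field is I_det(x) + η·(I_H − I_L)·u(x), truncated at
zero. η is therefore the patch-to-patch fluctuation *in units of the total
signal swing the cell is trying to read*; η = 1 means noise as large as
the signal. A moving cell converts the frozen texture into slowly varying
input noise (timescale 1/β — low-frequency, unlike the internal noise
below). Adaptation filters the resulting common-mode drift of the whole
cell's input but cannot filter front/back contrast noise, which is why
temporal sensing degrades more gracefully than spatial sensing as η grows.

**Internal (kinetic) noise** redraws the seven rate constants every
Δτ_ν = 0.1 as Normal(p₀, ν·p₀²) truncated at zero (coefficient of
variation √ν; an absolute-variance mode Normal(p₀, ν) is available via
`fractional=False`). Equilibrium constants are not perturbed. Replicate
seeds derive deterministically from (base seed, replicate index), so
ensembles are reproducible and embarrassingly parallel.

**Viability and ensemble decision**: a strategy is viable for a parameter
set when all replicates (10 by default) give strictly positive output;
with both strategies viable the larger mean output wins, with neither the
set is scored as failed.

## Design choices where the design was open

* *Integration horizon of the functionals*: full window rather than
  gradient-transit only. The spatial functional's exit phase (its negative
  lobe) is part of the physics; cutting the window would discard it.
* *Entry convention*: cell center at the gradient's start at τ = 0. The
  front half is therefore already in the gradient at entry; all timing
  statements (e.g. when the back half starts responding) refer to this
  convention.
* *Exponential gradient parameterization*: initial logarithmic slope
  matched to the linear profile's relative slope at I_L, so the two shapes
  are comparable at small α·T_s/I_L.
* *External-noise amplitude unit*: the signal swing I_H − I_L (see above).
  Scaling noise by the absolute level instead makes the noise dwarf the
  ~2% signal at every η and inverts the viability phenomenology.
* *Tie-breaking*: O_TS = 1 exactly goes to temporal.

## What the simulations do and do not show

The screen, the ring and the noise ensembles are all synthetic: the
package's claims are about the model's parameter space, not about any
measured cell. Real membranes are two-dimensional, cells deform, receptor
binding is stochastic and signaling circuits are larger than three nodes;
none of that is represented. The cell-atlas classifier makes only the
dimensional argument β = v/(d·l_BC) with a user-supplied table; the
bundled table contains a single organism whose speed, size and signaling
rate are well characterized.

## Known limitations

* At the defaults (I_L = 0.5, T_s = 10) the relative input change is
  20·α/10⁻³ percent, so at α = 10⁻² the response leaves the linear regime
  and O/α drops by ~3–6% below its small-α value; strict 2% linearity
  holds for α ≤ 10⁻³. Decisions are α-invariant throughout.
* In the slow-cell LEGI cell (β = 0.125, D′_A = 1, D′_B = 100) the
  spatial-vs-temporal split across screened sets is close to 50/50 rather
  than strongly spatial: with mode-2 membrane diffusion decaying at 4D′ on
  the π-circumference ring, D′_A = 1 attenuates the activator's spatial
  contrast by l_FA/(l_FA + 4), and slowly adapting screened sets carry
  large temporal outputs. The regime *structure* (which side of the
  diagonal favors which strategy, negative O_S for IFF only) is robust;
  the margin in that one cell is not.
* Internal noise at ν = 0.25 (CV = 0.5 on every rate, including the
  reference rate l_BC) is not a perturbation for screened circuits whose
  output node relaxes much faster than the resample interval: C
  equilibrates to every redrawn rate set, and because the equilibrium is
  convex in the log-rates the temporal output rectifies upward (or the
  output collapses and the replicate is scored failed). Decision fractions
  under such noise are therefore *not* expected to match the noiseless
  ones in this implementation; they do for weak noise (ν ≲ 0.01).
* At η = 1 with a fast cell the spatial functional acquires a positive
  bias (a ratio of noisy sums), which keeps spatial viability artificially
  high at large β.
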