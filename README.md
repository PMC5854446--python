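# chemosense

**Temporal versus spatial gradient sensing in chemotactic cells.**

Cells climbing a chemoattractant gradient either compare receptor output at
different times along their path (temporal sensing — the *E. coli*
strategy) or between their front and back halves at one instant (spatial
sensing — the neutrophil/amoeba strategy). Which strategy pays is often
attributed to cell size alone. `chemosense` implements a dimensionless
reaction–diffusion model that makes the comparison quantitative: the two
canonical adaptive three-node circuits — negative integral feedback (NFB)
and the incoherent feedforward loop (IFF),

    dA/dτ = k_IA·I − l_FA·A
    dB/dτ = k_CB·C − l_FB            (NFB)   or   k_IB·I − l_FB·B   (IFF)
    dC/dτ = k_AC·A·(1−C)/(K_AC+1−C) − l_BC·B·C/(L_BC+C)

— run in every compartment of a one-dimensional ring cell (diameter d,
speed v) crossing a gradient, with the three species diffusing on the
membrane. Behavior is controlled entirely by dimensionless groups:
β = v/(d·l_BC) (speed over diameter × signaling rate),
α = v·k/l_BC (gradient steepness as experienced by the moving cell), and
D′_X = D_X/(d²·l_BC) (diffusivities). The temporal and spatial readouts

    O_T = (1/N) ∫ Σᵢ (Cᵢ(τ)/Cᵢ(0) − 1) dτ,
    O_S = ∫ (Σ_front Cᵢ / Σ_back Cᵢ − 1) dτ,        O_TS = O_T/O_S

decide the strategy: temporal when O_TS ≥ 1, spatial when 0 < O_TS < 1,
failure when neither output is positive. High β favors temporal sensing;
spatial sensing needs a slow cell, a non-diffusing output protein and an
inactivator that out-diffuses the activator (local excitation, global
inhibition). The package provides the parameter screen that finds
sensitive, precisely adapting circuits, the ring simulator, the output
functionals, factorial parameter sweeps, stochastic ensembles with
external (ligand) and internal (kinetic) noise, and a classifier placing
real cells relative to the β = 1 decision boundary. It is aimed at
systems-biology modelers studying gradient sensing and network motifs.

## Worked example

Screen for adaptive, sensitive IFF circuits, then ask how a slow cell with
a LEGI diffusivity pattern (D′_A = 1 ≪ D′_B = 100) should sense:

```python
from chemosense import (Topology, DimensionlessTransport, GradientProfile,
                        RingGrid, screen, simulate_ring, evaluate_trajectory)

selected, _ = screen(Topology.IFF, n_samples=20_000, seed=0, n_keep=10)
profile = GradientProfile(alpha=0.001, I_L=0.5, T_s=10.0)   # linear gradient
slow = DimensionlessTransport(beta=0.125, D_A=1.0, D_B=100.0, D_C=0.0)
fast = DimensionlessTransport(beta=8.0,   D_A=1.0, D_B=100.0, D_C=0.0)

for name, transport in [("slow cell", slow), ("fast cell", fast)]:
    out = evaluate_trajectory(simulate_ring(selected[0], Topology.IFF,
                                            transport, profile, RingGrid(20)))
    print(f"{name}: O_T={out.O_T:.4f}  O_S={out.O_S:.4f}  -> {out.decision.value}")
```

```
slow cell: O_T=0.0411  O_S=0.1091  -> spatial
fast cell: O_T=0.0410  O_S=0.0018  -> temporal
```

The temporal output is independent of β (the cell integrates the same
input history in time either way), while the spatial output collapses as
β grows — at β = 8 the front/back delay is too short to build a usable
front-to-back difference, so the fast cell must sense temporally; the slow
LEGI cell gets a larger spatial than temporal output. The same machinery
drives the full regime maps (`chemosense sweep`) and the noisy ensembles
(`chemosense noise-sweep`); with external ligand noise the spatial
strategy, which takes a difference, loses viability before the temporal
strategy, which takes an average.

A command-line interface mirrors the library:

```sh
chemosense screen --topology iff --n 20000 --seed 0 --keep 10 -o selected.json
chemosense simulate --topology iff --params selected.json --beta 0.125 \
    --da 1 --db 100 --alpha 0.001 -o traj.csv --summary summary.csv
chemosense sense --traj traj.csv -o outputs.json
chemosense atlas -o classified.csv    # β for real cells vs. the decision band
```

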