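# smkin

Single-molecule binding kinetics for ligand:receptor imaging at cell–
supported-bilayer junctions.

When a fluorescently labeled ligand in a supported lipid bilayer (for
example a peptide–MHC complex) binds a receptor on a cell surface (a T cell
receptor), the ligand's mobility collapses: free molecules diffuse fast
(D ≈ 0.44 µm²/s), bound complexes move slowly and are carried toward the
cell center by the cytoskeleton. Tracking individual molecules therefore
reads out binding directly — but every observed dwell ends either by true
unbinding **or** by photobleaching of the dye, and the two are
indistinguishable frame by frame. `smkin` implements the full analysis
chain for this class of experiment, driven entirely by a synthetic-data
generator with ground truth, so every stage is testable without microscopy
data:

- **`smkin.sim`** — two-state (free ⇌ bound → bleached) trajectory
  simulation, stepwise intensity traces, bleaching lifetimes, camera-frame
  rendering with Brownian-bridge motion blur, fiducial bead fields.
- **`smkin.tracking`** — difference-of-Gaussians spot detection with
  sub-pixel centroids, optimal-assignment track linking, step-size
  distributions, one/two-component Rayleigh mixture fits, and per-frame
  bound/free classification.
- **`smkin.kinetics`** — the photobleach-corrected dwell-time estimator
  (below), exponential fits with censoring, bleach-curve fits.
- **`smkin.changepoint`** — Bayesian change-point detection of intensity
  steps (step photobleaching, stepwise binding of labeled kinase).
- **`smkin.registration`** — polynomial two-channel registration from
  fiducial beads to well below one 105 nm pixel.
- **`smkin.stoichiometry`** — fluorophore counting: 315 nm (3 px) window
  integration, single-molecule intensity calibration, molecules per
  feature.
- **`smkin.escape`** — stochastic lattice simulation of serial rebinding
  within a receptor cluster and the escape time τ_esc.

## The observation model

For a constant unbinding rate and exponential photobleaching, observed
dwell times follow

```
f(τ_obs) = (1/τ_bl + 1/τ_off) · exp(−τ_obs · (1/τ_bl + 1/τ_off)),
⟨τ_obs⟩ = (1/τ_off + 1/τ_bl)⁻¹
```

so measuring the bleach time τ_bl on a bilayer standard (same dye, no
cells) recovers the molecular off time:

```
1/τ_off = 1/⟨τ_obs⟩ − 1/τ_bl        (valid while τ_obs < τ_bl)
```

with uncertainty by first-order propagation. The serial-rebinding question
— could an observed dwell be many short binding events to different
receptors in a cluster? — is addressed by the lattice simulation:
τ_esc = Σᵢτ_off,ᵢ + Σᵢτ_on,ᵢ + τ_exit, with exponential bound periods,
Gaussian diffusion hops of SD √(2·D·τ_on) per axis, and escape when a hop
lands off the cluster.

## Worked example

Run the default synthetic pipeline — simulate two-state trajectories
(τ_off = 5.2 s, τ_bl = 30 s, D_free = 0.44 µm²/s), classify bound
segments, and correct the dwell times:

```python
from smkin import run_pipeline
report = run_pipeline({"seed": 7, "out": "demo_out"})
print(report["mobility_fit"])
print(report["kinetics"])
```

prints (seed 7):

```
{'n_components': 2, 'd_slow': 0.0051, 'd_fast': 0.4168,
 'f_slow': 0.648, 'r_star': 0.1014}
{'tau_obs_mean': 4.674, 'tau_obs_sem': 0.345, 'tau_bl': 30.0,
 'tau_off': 5.536, 'tau_off_sem': 0.483, 'n_events': 184}
```

The step-size mixture finds the two mobility components (0.005 and
0.42 µm²/s, against generator values 0.005 and 0.44) and the crossover
r\* = 0.10 µm used for classification. The 184 extracted dwells average
4.67 s; inverting the competing-exponential model with τ_bl = 30 s gives
τ_off = 5.5 ± 0.5 s, consistent with the generator's 5.2 s. The
stoichiometry stage reports the worked example 136.0 / 47 = 2.9 visible
fluorophores per feature, i.e. ≈ 6 kinase molecules at 1:1 labeling.

A command-line interface mirrors the stages
(`smkin simulate | render | track | kinetics | register | stoich | escape | all`),
e.g.

```
smkin escape --tau-off 5.2 --cluster 100 --kon 0.17 --iters 10000 --seed 1
```

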