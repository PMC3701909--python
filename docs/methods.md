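# Methods

This note documents the models, defaults, and numerical choices behind
`smkin`, and what the synthetic-data generator does and does not emulate.

## The kinetic observation model

The package models a membrane-anchored ligand that alternates between a
fast freely diffusing state and a slow receptor-bound state, with
photobleaching removing bound molecules from observation:

```
free  ⇌(k_bind, k_off)  bound  →(k_bl)  bleached
```

All transitions are Markovian (exponential waiting times). The observable
dwell is therefore the minimum of the unbinding and bleaching clocks, with
density `f(t) = (1/τ_bl + 1/τ_off)·exp(−t(1/τ_bl + 1/τ_off))`, and the
molecular off time is recovered from the observed mean and an
independently measured bleach time via `1/τ_off = 1/⟨τ_obs⟩ − 1/τ_bl`
(`kinetics.correct_dwell_time`). The correction diverges as
⟨τ_obs⟩ → τ_bl; the implementation raises a dedicated error there, since
bleaching-limited data cannot constrain τ_off. Uncertainties propagate to
first order (delta method):
`SE(τ_off)² = ((τ_off/τ_obs)²·SE(τ_obs))² + ((τ_off/τ_bl)²·SE(τ_bl))²`.
A bootstrap SEM (1000 resamples) is available for small samples.

Censoring: the default policy drops censored events and uses the sample
mean of completed dwells, the exponential MLE (SEM = mean/√n). A
`survival_mle` policy (total time / completed events) handles
movie-boundary censoring when retaining it matters. An optional minimum
dwell `c` discards events below the detection floor and subtracts `c` from
the truncated mean — bias-free for exponential data by memorylessness.
This floor exists because classification noise can emit sub-resolution
"dwells" that are not binding events; the experiment it models has the
same floor (the fastest frame time bounds the shortest detectable
lifetime).

## Synthetic data

Parameters and defaults:

| parameter | default | meaning |
|---|---|---|
| `d_free` | 0.44 µm²/s | bilayer diffusion of the unbound ligand |
| `d_bound` | 0.005 µm²/s | residual diffusivity of the bound complex |
| `v_radial` | 0.05 µm/s | centripetal transport speed of bound complexes |
| `k_bind` | 0.5 s⁻¹ | binding rate while free |
| `k_off` | 1/5.2 s⁻¹ | unbinding rate |
| `k_bl` | 1/30 s⁻¹ | photobleach rate while bound |
| `pixel_size` | 0.105 µm | camera pixel at the sample |

`d_free`, `k_off`, `k_bl` defaults are the measured study conditions;
`v_radial` and `d_bound` are not quantified anywhere we know of, so the
defaults are order-of-magnitude choices (microcluster transport speed;
slow enough that the two mobility modes separate at a 500 ms lag). Both
are configurable and the simulation makes no qualitative use of their
exact values.

State paths are simulated in continuous time (exact exponential event
times), then positions are sampled at frame times by splitting each frame
interval at state-change events and accumulating the appropriate Gaussian
increments (variance 2·D·h per axis per sub-interval) plus, while bound,
drift of magnitude `v_radial·h` toward the transport center, capped so the
molecule never overshoots the center. Free molecules do not photobleach by
default (`bleach_free=False`): at the long exposures used for dwell
imaging only slow molecules accumulate appreciable excitation dose, and
only the bound state's bleaching enters the correction; the flag restores
bleaching of free molecules when wanted.

Rendering (`sim.render_frames`) deposits each visible emitter as a
pixel-integrated 2D Gaussian (error-function pixel integrals, so photons
are conserved exactly regardless of sub-stepping) at `substeps`
intra-exposure positions along a Brownian bridge between consecutive frame
positions. The bridge diffusivity comes from the track's own local
increment, so fast molecules smear into background at long exposure — the
"hardware filtering" that makes bound molecules pop out — without a
separate mobility parameter. Camera noise is offset + Gaussian read noise,
with optional Poisson shot noise; EM-register excess noise is not modeled.
Emitters outside the field are clipped with a log warning.

What the generator does **not** emulate: cell landing and spreading,
adhesion patterning, receptor clustering, membrane topography, dye
blinking/dark states, EM-CCD excess noise, and spatially varying
illumination. Tests passing on this generator therefore demonstrate the
correctness of the estimators under the stated model, not robustness to
every real-world artifact.

## Detection, linking, classification

Detection is a difference-of-Gaussians bandpass (defaults σ = 0.8 and
2.0 px, matched to a 0.8 px PSF; calibrated on synthetic frames), local
maxima above 4× a robust (MAD) noise floor, and an intensity-weighted
centroid over the positive bandpass support — accurate to ≲0.05 px at the
tested SNR, which is why no Gaussian PSF fitting is needed. Thresholds on
integrated intensity and apparent diameter are applied uniformly.

Linking is per-frame optimal assignment (Hungarian algorithm on squared
displacement) with a hard displacement cap and gap closing up to
`max_gap` frames; optimal assignment removes input-order dependence, so
linking is deterministic. Coordinates: pixel origin at the center of the
top-left pixel, 0-based frames, µm = px × pixel size.

The pooled step-size distribution is fit on squared magnitudes, which are
exponential with mean 4·D·Δt per Rayleigh component; a two-component
exponential-mixture EM provides the MLE, and a one-component model is
returned instead when BIC prefers it (the no-cell, single-population
case). The classification threshold r\* solves equal component
posteriors in closed form.

Per-frame classification compares r\* against the **minimum of the
trailing- and leading-window mean step** (window default 3 frames; steps
across linking gaps are rescaled by √gap). A single one-sided window
necessarily straddles every bind/unbind transition and erodes dwell edges
by 1–2 frames each — a 10–20% downward bias in ⟨τ_obs⟩ at 0.1–0.25 s
sampling — while the two-sided form lets a boundary sample be judged by
its clean side. Ties break to FREE (conservative for dwell times). Maximal
BOUND runs become dwell events with duration (run span + 1)·Δt; an event
is censored when it touches the movie boundary, and *uncensored* when the
track simply disappears, because disappearance is unbinding-or-bleaching
and the τ_bl correction resolves that ambiguity downstream. Tracks shorter
than window+1 samples are labeled UNKNOWN and excluded.

Known limitation: short free excursions (≲ window) between two bound
periods can be absorbed, merging dwells; this is the flip side of edge
protection. The end-to-end tests run in a sparse-rebinding regime
(k_bind = 0.06–0.6 s⁻¹) where the merge probability is small, and the
dwell floor removes the complementary spurious short events.

## Change-point detection

Gaussian observation model with a conjugate Normal-Inverse-Gamma prior:
µ₀ = trace mean, κ₀ = 0.01, α₀ = 1, β₀ = σ̂², with σ̂ estimated per trace
from the median absolute successive difference (robust to the steps being
sought). The evidence for "one mean shift somewhere" marginalizes the
change location over a uniform prior (log-sum-exp over candidate splits);
a split is accepted when the log₁₀ Bayes factor exceeds 2 (≈ "decisive"),
placed at the maximum-evidence location with ties to the earlier index,
and recursion proceeds into both halves (binary segmentation, minimum
segment 2 frames). A proper weak prior is used instead of reference priors
because improper priors leave an arbitrary constant in a
split-vs-constant Bayes factor. Constant zero-variance traces return no
changes; for noiseless staircases the scale floor β₀ keeps marginals
finite and detection exact. Measured null false-positive rate is below 1%
at the default threshold (n = 200 frames).

Step counting: downward changes in a trace terminating at background are
bleach steps; exactly one downward step to background and no upward steps
certifies a single molecule; two equal downward steps flag a dimer; upward
steps are binding events and are reported separately by sign.

## Registration and stoichiometry

The channel map is a per-axis polynomial (order 1 = affine, order 2 adds
xy, x², y²) fit by least squares to fiducial bead pairs; order 2 is the
default because dual-view registration error typically varies across the
field. Residual RMS is reported and a warning fires above one pixel
(105 nm), the colocalization criterion; with ≥25 beads at 10 nm
localization noise the residual is ≈5× below that criterion.

Recruitment intensity is integrated over a 315 nm square window — exactly
3 px at 105 nm/px; the implementation requires an odd pixel span — centered
on the mapped anchor, with a per-frame local background (median of a
3–6 px annulus) subtracted per pixel. Single-molecule calibration averages
the pre-bleach level of traces certified single-molecule by the
change-point module; multi-step traces are rejected and logged. Counts:
n_visible = feature/unit, n_total = n_visible / labeled fraction (default
0.5, an EGFP fusion expressed ~1:1 with the endogenous kinase), SEMs by
the delta method; reported values round to two significant figures. The
capture fraction of the 3×3 window varies by a few percent with the
emitter's sub-pixel phase; it cancels in the feature/unit ratio whenever
both are integrated the same way, and the linearity test controls for it
explicitly. Context for interpretation: each receptor complex offers 10
ITAM binding sites for the kinase; the package reports counts only.

## Escape simulation

A ligand starts on a uniformly chosen occupied site of a square lattice
(spacing 10 nm ≈ receptor footprint; density 10⁴ µm⁻²; `cluster_n` sites
occupied row-major within the smallest enclosing square, pad sites count
as off-cluster). Cycles alternate: bound period ~ Exp(τ_off); unbound
period τ_on ~ Exp(1/(k_on·ρ)); a single Gaussian hop of SD √(2·D·τ_on)
per axis — the exact endpoint distribution of Brownian motion over τ_on;
landing snaps to the nearest lattice site, rebinding unconditionally on an
occupied site and escaping otherwise (any landing beyond the lattice hull
is out). τ_esc sums every component, and the recorded components are
audited to add up exactly.

Two readings in the source description are fixed here: the unbound-time
mean is 1/(k_on·ρ) (the printed product is dimensionally a rate), and the
hop SD is √(2·D·τ_on) per axis (the only reading consistent with a
Rayleigh |Δr|). The fine-time-step validator integrates each unbound
excursion as an explicit 100-step random walk instead of one hop; a rule
that binds the instant a path touches a site would never terminate for a
recurrent 2D walk, so endpoint binding is the only self-consistent
brute-force form. At k_on = 0.17 µm²s⁻¹ the hop SD is 22.8 nm — past the
lattice spacing, so first-unbinding escape dominates realistic cluster
sizes; at k_on = 0.51 it is 13.1 nm, comparable to the spacing, the
fastest rate still allowing same-receptor rebinding.

Because τ_off ≫ τ_on, the entrapment ratio τ_esc/τ_off ≈ ⟨n⟩+1 depends on
cluster size and k_on but not on τ_off. Default iterations per condition:
100 (matching the original sweep); validation runs use 10⁴ for tighter
sampling error.

## Problem sizes in tests

The suite favors parameter-recovery simulations sized for stable
statistics at reasonable cost: 10⁴ draws for closed-form recoveries;
rendered round trips pool five 60 s movies of 8 molecules in a 10 µm
field at 0.1 s frames (≈0.08 µm⁻², the sparse single-molecule regime),
chosen so crowding and transport-driven pile-up at the field center stay
negligible; the dwell-recovery grid scales the frame interval to ≈35
frames per observed dwell so discretization bias stays well inside
sampling error. The full suite runs in well under a minute on one core.
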