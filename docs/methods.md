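# Methods

## Model structure and assumptions

The circuit is a deterministic, per-cell toggle switch: NANOG (Epi program)
and endogenous GATA (PrE program) repress each other through Hill functions
with no basal production and first-order degradation. Exogenous GATA `G_X`
is produced at a cell-specific constant rate `D` during the induction pulse
and decays first-order; it represses NANOG through the same term as
endogenous GATA (the two are summed into a total-GATA input), reflecting
that the induced factor substitutes functionally for the endogenous one.
`G_X` receives no feedback from the circuit, so it follows the closed-form
pulse solution exactly — this is used both as a test oracle and to convert
measured reporter thresholds back into dose units. Transcription and
translation are collapsed into a single production step with no delay.

FGF/MAPK signaling enters as a dimensionless level `s` through one of two
couplings: inhibition of NANOG production (`f_N(s) = 1/(1+(s/K_s)^m)`, the
default, which reproduces the observed signatures: the NANOG-positive peak
shifts up as signaling falls while GATA-positive expression stays put) or
promotion of GATA production (`f_G(s) = s^m/(K_s^m+s^m)`, kept for
comparison; it instead moves the GATA-positive peak). Cell division, spatial
coupling, stochastic kinetics and autoactivation are deliberately absent.

Fate is defined dynamically, not by an expression cutoff: after the chase,
integration is extended until the state converges (rate norm < 1e-6 *and*
within 1e-3 of a stable equilibrium — the rate norm alone is also tiny near
the saddle) and the attractor reached names the fate. Cells still unresolved
at 300 h are flagged rather than guessed.

## Parameters

All defaults live in `src/fateswitch/defaults.yaml`. Units: hours,
concentrations in arbitrary units scaled so steady-state levels are O(1).

| parameter | default | role |
|---|---|---|
| α_N, α_G | 5.0, 1.0 conc/h | maximal production rates |
| K_GN, K_NG | 0.3 conc | repression thresholds |
| h_N, h_G | 4 | Hill exponents of the repressive links |
| γ_N, γ_G, γ_X | 0.5 /h | degradation rates |
| s, K_s, m | 1.0, 0.5, 2 | signaling level, half-effect, steepness |
| pulse | 0–6 h, chase to 30 h | induction protocol |
| dose | lognormal(−1.05, 0.8) | per-cell `D` (log-mean, log-sd) |

The defaults were calibrated once against four structural constraints and
then frozen: (i) exactly three equilibria, two stable, at `s = 1`;
(ii) a 6 h pulse with heterogeneous doses splits a 2000-cell population
bimodally by 30 h; (iii) NANOG relaxes from its pre-culture level toward a
lower steady state before the fates diverge; (iv) under NANOG-inhibiting
signaling, lowering `s` raises the critical dose. Choosing
`α_N = (1+(1/K_s)^m)·α_G = 5 α_G` makes the *effective* production rates
equal at saturated signaling, so the toggle is symmetric there (the basins
split the state space evenly and the quasi-potential depths agree to three
digits, a useful internal check). Hill exponents of 4 — standard for
cooperatively acting transcription factors in toggle-switch models — keep
the system bistable over the whole sweep range `s ∈ [0.25, 1]` and pin the
GATA-high expression level to within 1% across that range; with exponents
of 2 the GATA state destabilises at low `s` under the required five-fold
signaling modulation of NANOG production. The dose log-mean −1.05 is
`log D*` at `s = 1` (critical dose 0.350), so about half of a default
population differentiates, and the log-sd 0.8 gives the long-tailed induced
expression typical of transactivator systems.

The pre-culture initial condition is `(α_N/γ_N, 0, 0)`: the NANOG steady
state *without* signaling inhibition, since cells are pre-cultured in a MEK
inhibitor. Restoring signaling at t = 0 makes NANOG relax toward its lower
steady state in all cells before the fates separate.

## Numerical choices

* Integration: LSODA (stiff-capable, adaptive), rtol 1e-8 / atol 1e-10,
  split at the pulse edges so the drive discontinuity never falls inside an
  adaptive step; the pulse interval is half-open `[t_start, t_end)`.
* Equilibria: both nullclines of the Hill circuit are explicit graphs, so
  roots of the one-dimensional composite map `N − N_null(G_null(N))` are
  bracketed on a dense scan (4001 points) and bisected, then polished by
  damped 2-D Newton iteration with the analytic Jacobian to residual
  < 1e-10. Stability is classified by Jacobian eigenvalues; real parts
  within 1e-9 of zero are treated as a misconfiguration (the model should
  never sit at a bifurcation) and raise an error.
* Separatrix: reverse-time integration from `saddle ± 1e-6·v_stable`,
  truncated at the analysis bounds (default
  `[0, 1.5 α_N/γ_N] × [0, 1.5 α_G/γ_G]`).
* Critical dose: log-scale bisection to relative width 1e-4; the bracket
  must straddle the flip or a bracket error reports both outcomes.
* Quasi-potential (path-integral construction): trajectories from a
  jittered uniform lattice accumulate `ΔU = −Σ‖v‖² Δt`, are anchored to 0
  at their attractor, and deposit per-cell minima on the grid. Trajectories
  terminate on a distance event (within 1e-3 of an attractor), not a
  rate-norm event, so paths grazing the saddle are not mistaken for
  arrivals. The two basin surfaces are aligned by two dedicated
  trajectories launched down either side of the saddle's unstable manifold
  (the canonical downhill path): each start value is its basin's depth
  below the ridge, and equating the ridge value fixes the offset. Cells no
  trajectory visits hold NaN, never a silent 0.
* Peak detection: Gaussian KDE (Silverman's rule unless a bandwidth is
  given) on a 512-point grid padded by three bandwidths (so edge modes
  keep their full prominence), local maxima with prominence ≥ 5% of the
  density maximum. The signaling sweep passes an explicit bandwidth of 5%
  of the sample range because noise-free end-point samples are
  near-degenerate two-point mixtures, for which Silverman's rule collapses.
* ROC: thresholds are midpoints of consecutive distinct values with ±∞
  sentinels; prediction rule `value ≥ threshold` (high reporter ⇒ PrE);
  AUC is the Mann–Whitney pair statistic with ties counting one half; the
  optimal threshold maximises Youden's J, ties broken toward the largest
  (most conservative) cutoff. Bootstrap resamples whole cells, never
  frames, since frames within a cell are strongly dependent; replicates
  that lose a class are redrawn up to 100 times, then the frame is flagged.
  A cumulative-exposure (time-integral) classifier series is provided as an
  alternative to instantaneous values.
* Clustering: Ward linkage on Euclidean distances of log-transformed traces
  (multiplicative noise becomes additive); cluster ids ordered by
  descending mean final value.

## Synthetic data

The generator emulates the two measurement modalities end to end:
time-lapse traces (every channel sampled at frame boundaries, default
0.25 h cadence) and single-timepoint flow-cytometry-like snapshots.
Measurement noise is multiplicative log-normal (`σ = 0.2`) plus an additive
Gaussian background (mean 0.5 ≈ 5% of the pre-culture NANOG level), and
end-point labels can be flipped with probability `label_flip` to emulate
staining/assignment errors. Each generator also returns the noise-free
tables so downstream tests can compare against the clean oracle, and
accepts explicit doses to pair populations across noise realisations.

What the generator does *not* emulate: photobleaching, focal drift,
segmentation/tracking errors, cell division and lineage structure,
signaling heterogeneity between cells, and any feedback of fate on
proliferation. Passing tests therefore demonstrate the analytics recover
ground truth under idealised, stationary multiplicative noise — not
robustness to the structured artefacts of real imaging data.

## Problem sizes

The test suite and the acceptance script run on one CPU in a few minutes.
Sizes were chosen as the smallest that make each check statistically
unambiguous: the headline ROC/accuracy study uses ten replicate 200-cell
experiments at 0.25 h cadence; sweeps use 150–300 cells per signaling
level; the bimodality check uses the full 2000-cell population; the
label-flip accuracy bound uses 400 perfectly separable cells (the binomial
2-s.e. band at n = 400 is ±3%, tight enough to resolve a 10% flip rate);
basin fractions use 16–24² lattices and quasi-potentials 225 trajectories
on an 80² grid.

## Known limitations

* The functional forms and parameter values are a minimal calibrated
  reconstruction satisfying the structural constraints above; other
  parameterisations can produce the same qualitative behaviour, and
  quantitative outputs (e.g. `D* = 0.35`) are in arbitrary units specific
  to this calibration.
* The quasi-potential is the path-integral variant (dissipation accumulated
  along deterministic trajectories); it is not the large-deviation
  potential of a stochastic model, and values between basins are comparable
  only through the ridge-alignment convention described above.
* With signaling promoting GATA, low `s` can make the system monostable
  (no PrE state); sweep summaries then report NaN peak positions rather
  than extrapolating.
* Bootstrap uncertainties resample cells; resampling (cell, frame) pairs
  is a documented alternative the package does not implement.
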