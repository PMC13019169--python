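# Methods

This note documents the model conventions, estimator designs, calibrated
constants and known limitations of `arraycrit`. Nothing here reports an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Lattice model and conventions

Each allosteric unit (a receptor team with its kinase) occupies one site of
an L x L square lattice with free boundaries (no wraparound; 2L(L−1)
nearest-neighbour bonds; coordination 2 at corners, 3 on edges, 4 in the
interior). Units carry a spin σ_i ∈ {−1, +1} related to the unit's kinase
activity by a_i = (σ_i + 1)/2. The configuration energy in units of k_BT is

    H = − Σ_<ij> J_ij σ_i σ_j + Σ_i (h_i / 2) σ_i ,
    h_i = H_b + H_b,i + H_L ,

so each anti-aligned bond costs 2J relative to an aligned one, and a
**positive** field favours the **inactive** state — a positive ligand step
ΔH therefore mimics attractant (kinase-inactivating) stimulation. Under
this convention the thermodynamic-limit critical coupling is the
Kramers–Wannier point J*(∞) = ln(1+√2)/2 ≈ 0.4407, and the finite-size
critical coupling for free boundaries is taken as
J*(L) = J*(∞)/(1 − 1.25 L⁻¹).

Flip rates are ω_i = ω₀ exp[−σ_i Σ_j J_ij σ_j + (h_i/2) σ_i], which satisfy
detailed balance against H exactly (a machine-precision property test).
ω₀, the flip attempt frequency of an isolated unit, defaults to 1: all
simulated times are in units of 1/ω₀. The calibration 1/ω₀ = 30 ms is used
only when results are reported in seconds.

### Kinetic Monte Carlo

The dynamics are rejection-free (BKL/Gillespie): one uniform variate draws
the exponential waiting time from the total rate, a second selects the
event proportionally to its rate. Rates are cached per site; after a flip
only the flipped site and its ≤4 neighbours are re-rated, and per-row rate
sums make event selection O(L) per event. Sampling is piecewise-constant on
a uniform grid (the value at the latest event at or before each grid
time), with optional integer decimation. The hot loop is numba-compiled;
a transparent pure-Python single step is kept and is cross-checked against
brute-force Boltzmann enumeration on 2x2 and 3x3 lattices (total-variation
distance < 0.01 after a few million events).

Seeding: one seed per simulation run drives the compiled RNG; species
assignment and analysis noise use separately derived numpy Generators.
Seeded runs are bit-reproducible.

### Adaptation feedback

Each unit has an integer methylation level 0 ≤ m_i ≤ M setting a local
bias field

    H_b,i = α (m₀ − m_i),       α = 1, M = 64, m₀ = M/8 = 8,

so methylation above the offset favours activity. Active units (σ = +1)
are demethylated at rate k_B (the CheB analogue) and inactive units
methylated at rate k_R (CheR); events that would leave [0, M] are silently
suppressed. This is a negative feedback with perfect adaptation to
a₀ = k_R/(k_B + k_R). Note the sign: writing the local field as
α(m_i − m₀) under the energy convention above would make methylation of
inactive units push them further inactive (positive feedback, no
adaptation); the implemented sign is the one that counteracts each unit's
activity. Methylation events share the continuous-time event queue with
spin flips, changing m_i by ±1 (fields therefore move in steps of α).
The literature operating point k_R = k_B = (n_R/L²)·V_R/ω₀ = 0.0015 ω₀
(n_R = 200 adaptation enzymes, V_R = 0.1 s⁻¹ at saturation, 1/ω₀ = 30 ms)
is the default.

### Bond disorder

Receptor-species mixing is modelled by i.i.d. site labels (Tar with
probability `tar_fraction`) with like-species bonds at `J_same` and
unlike-species bonds at `J_cross`; the simulator accepts arbitrary
per-bond couplings.

## FRET preprocessing

Per cell: R(t) = A(t)/D(t); photobleaching is corrected by dividing a
single exponential fitted on buffer (stimulus-free) samples. Because
two-state switching contributes large, strongly autocorrelated residuals
to that fit, a decay rate is only accepted when it is resolved against
them — positive (bleaching only darkens) and larger than three standard
errors, with the standard error inflated by the lag-1 autocorrelation of
the residuals. An unbleached trace therefore passes through exactly, at
the price that weak residual trends on heavily switching cells are left to
the two-state renormalization second pass (as in the experimental
pipeline). The FRET index is (R − R₀)/(R + α) with α = 0.3 and R₀ the mean
corrected ratio during the saturating-attractant window; activity is
FRET/FRET_max with FRET_max the mean index during the saturating-repellent
window. Window means trim two samples at each edge (flow-exchange
transients). Negative activity excursions are preserved; clipping would
bias dwell statistics near the rails. Receptor-cluster size from a 1D
intensity profile is ΔI = I_max − ⟨I⟩ with ⟨I⟩ the profile mean.

## Switch detection and event statistics

The detector mirrors the experimental chain: 3-s centred moving average
(truncated at the edges), switching events as prominence-filtered peaks of
the derivative of the filtered trace (both signs), strongest-first
resolution of candidates closer than the minimum separation, and a
minimum-amplitude gate on the difference of flanking 4-s medians.
Defaults (1 Hz sampling): prominence 0.10 per sample, minimum separation
5 s, minimum amplitude 0.35. The prominence and amplitude gate are not
experimental constants; they were chosen so that the null false-positive
rate on pure Gaussian noise of σ = 0.1 is below one event per 1,000 s
(measured ≈ 0.05/1,000 s) while full-amplitude switches are detected with
≈ 95% sensitivity. For traces sampled at a different interval,
`EventDetectionParams.scaled(dt)` keeps the same per-sample geometry.

Each event carries:

- **amplitude** — the plateau change Δa of the saturating-exponential fit
  (below), falling back to the flanking-median difference when the fit
  fails; with ~5-s transitions the flanking medians sit on the ramp and
  systematically underestimate the level change.
- **residence** — time to the next event. The terminal (censored) interval
  is dropped, as is the interval before the first event. Residences that
  span a stimulus window are censored.
- **transition time τ** — the time constant of
  a(t) = a_pre + Δa (1 − e^(−(t−t₀)/τ)) fitted around the event (mirrored
  for downward switches). Two details matter for accuracy: the fit is
  restarted from a small grid of (t₀, τ) initializations (the detected
  event time lags the true onset, and the likelihood surface trades a
  later onset against a steeper ramp), and the fit window keeps one
  amplitude-window margin from the neighbouring events (whose ramps and
  detection lag otherwise leak in). With both, generator transition times
  are recovered within ~3% at noise σ ∈ {0, 0.15}; without them the bias
  is 10–30% low.

A cell is two-state when ≥ 65% of its transitions have |Δa| ≥ 0.7 (and it
has ≥ 3 events; the experimental source states no minimum). Two-state
cells get a second pass: residual bleach refit on dominant-state dwell
segments, renormalization by the high-state histogram peak, and event
re-extraction. Derived statistics: ΔG = ln[(1−⟨a⟩)/⟨a⟩] (bias from buffer
samples), unweighted log-space Arrhenius fits of per-cell mean residences
vs ΔG with the characteristic ⟨Δt⟩ read at the crossing of the up/down
lines, maximum-likelihood exponential dwell fits with a KS
goodness-of-fit, landscapes −ln p(a) (min-shifted; the two deepest wells
and their depth difference reported), r = ⟨Δt⟩/⟨τ⟩ with
⟨τ⟩ = (⟨τ₊⟩+⟨τ₋⟩)/2, and η = σ_a/a₀.

## Sweep-level statistics and finite-size scaling

The absolute value of r is a property of the measurement chain as much as
of the dynamics: experimental recordings sample at 1 Hz while arrays
switch at ~10⁻² Hz, so a residence spans ~10² samples and a transition
only a few. Sweep points therefore emulate that chain: a pilot run
estimates the switching period with a Schmitt trigger; the production
trace is sampled so one residence spans ~60 samples (the characteristic
experimental residences are 47–65 s at 1 Hz); Gaussian noise of σ = 0.15
(an experiment-like signal-to-noise ratio) is added; the trace is filtered
with a 3-sample moving average; and residences/transition durations are
extracted deterministically: committed switches from a 0.25/0.75 Schmitt
trigger, and per-switch transition duration as the time between the last
departure from the originating band and the first arrival in the
destination band. This chain reproduces the experimental anchors —
residences of 50–80 samples, transition durations of 5–15 samples,
r ≈ 8–13 at J = J*(L) — and is the definition under which the r = 9 and
r = 12 isolines track J*(L) within ±3% over L ∈ {12, 16, 20, 24}
(the per-event exponential-constant τ of the 1−e fit is a factor ~2
smaller than the visible switch duration and would rescale all r values
accordingly; it is retained for experiment-style traces where the same
convention is applied to data and mock validation alike).

Scaling constants are fitted in two stages: b and c_τ from a log-log
regression of ⟨τ⟩ vs L using, at each L, the record with J closest to
J*(L); z likewise from ⟨Δt⟩ vs L; then c₀ as the slope of the collapse
ln r − (z−b) ln L vs εL (free intercept, restricted to J < 0.6). ε uses
J*(∞) as the reference by default. Isolines invert the per-L monotone
interpolation of ln r vs J; unbracketed targets are flagged, never
extrapolated. ω₀ calibration evaluates r c_τ L^b / Δt_exp over a
structural range of L. The polarized/non-polarized classifier uses the
peak-valley ratio of the activity histogram (threshold 3, not an
experimental constant; sanity-checked against J*(L)).

Problem sizes: sweeps default to ~100 detected events per point and the
isoline grid to L ∈ {12, 16, 20, 24} with J/J*(L) ∈ {0.97, 1.00, 1.03,
1.06}; these give r estimates with ~10% relative error, enough to place
isolines to ~1% in J.

## Response analysis

Attractant steps are ligand-field increments at t = 0 on replicate
ensembles. Non-adapting arrays start all-active; t_R is the mean first
crossing of a = 0.5 across replicates (never-crossing replicates censored
at the window end and flagged), and the post-response activity is the
late-window mean. Adapting arrays are burnt in to their set point; because
the ensemble mean is non-monotonic (response, then re-adaptation), the
exponential response fit sees only the declining phase, cropped just past
the trough of the lightly smoothed mean; t_R is the fitted time constant
and the response level the fitted plateau. Amplitude is 1 − ⟨a⟩/0.5
(clipped to [0, 1] at reporting). At couplings up to J ≈ 0.75 with the
calibrated adaptation rates, the adapting response time stays well below
the adaptation timescale, so the high-J amplitude loss expected from a
complete loss of timescale separation is not reached in the scanned range;
what the scans do show robustly is the non-adapting speed–amplitude
trade-off in J and the removal of near-critical slowdown by adaptation
(adapting t_R below the 1-s run–tumble bound at all tested stimuli).

## Synthetic data

The generators define the study conditions for every estimator test:
telegraph activity with alternating exponential dwells (means default
50 s/50 s; bias = Δt_up/(Δt_up+Δt_down)), deterministic
saturating-exponential transition ramps (τ₊ = 4.3 s, τ₋ = 6.1 s) that
start from the actual activity at the switch time (so short dwells do not
create discontinuities), clamping to attractant (a = 0) and repellent
(a = 1) windows, and additive Gaussian noise of σ = 0.15 by default.
Fluorescence-level cells invert the FRET index (R from FRET, donor and
acceptor channels with per-channel exponential bleaching and optional
proportional noise). Cohorts draw per-cell biases (or take imposed
Arrhenius structure: Δt_up = ⟨Δt⟩e^(−γ_up ΔG) etc.; note that an
equilibrium telegraph fixes γ_up − γ_down = 1 through its dwell ratio, so
recovery tests regress measured residences on the imposed design ΔG stored
in the truth record). What the generators do **not** emulate: stochastic
transition shapes (the simulator provides those), photophysics-accurate
shot noise, baseline drift other than exponential bleaching, and cell-size
or expression-level variability — passing recovery tests therefore
demonstrate estimator correctness under the stated noise model, not
robustness to every artefact of real recordings.

Mock-trace validation compares *matched* events (each detected event
paired with the nearest same-direction truth event): exponential dwells
shorter than the ~5-sample detector dead time are undetectable in
principle, which inflates raw mean residences by ~15% while matched means
agree within a few percent — the same resolution limit applies to the
experimental recordings.

## Numerical choices and degenerate inputs

- Waiting times use one uniform variate via −ln(u)/Σω; the total rate is
  refreshed from row sums every step to bound float drift.
- Methylation saturation is silent; zero adaptation rates freeze m.
- Correlation length: raw axial spin products c(r) fitted per state as
  e^(−r/ξ) over the decaying prefix above a noise floor of 0.05
  (≈ the finite-sample floor of an L x L state); c(1) at the floor ⇒ ξ = 0
  ("uncorrelated"); c ≡ 1 ⇒ "not measurable" (frozen); the ensemble ξ is
  the mean of per-state fits.
- Fits that fail to converge flag and fall back (bleach: no correction;
  τ: NaN, event retained) rather than raise; degenerate designs (all cells
  at one ΔG, parallel Arrhenius lines, unbracketed isoline targets) raise
  or flag explicitly.
- The activity histogram for landscapes spans [−0.15, 1.15] so noise
  excursions keep their mass; empty bins map to +inf.

## Known limitations

- The transition-time convention fixes the absolute scale of r; results
  quoted against r values from other pipelines must use the same
  convention (see the sweep section).
- One-pass bleach correction under strong differential bleaching of
  heavily switching cells leaves residual trend; the two-state second pass
  mitigates but does not eliminate it.
- The adapting response-amplitude estimator reads the trough of the
  ensemble mean; when replicate response times disperse widely (deep in
  the ordered phase) the ensemble trough underestimates per-replicate
  amplitudes.
- Finite-size scaling fits assume the operational scaling law; no attempt
  is made to estimate true Ising critical exponents.
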