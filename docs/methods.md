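# Methods

## Kinetic model

Cas9–RNA / DNA-target binding is a three-state continuous-time Markov chain
(CTMC) over unbound (U), sampling (S, mid-FRET) and heteroduplex (H,
high-FRET) states. Rates out of U are second order (per molar per second)
and scale with the Cas9–RNA concentration; all others are first order.
Photobleaching is a single exponential, trace-terminating event drawn
independently of the path: either fluorophore's loss ends the FRET
observable, so separate donor/acceptor bleach channels are not modeled.

State paths are sampled by exact (Gillespie-style) event simulation and only
then binned into camera frames. At 0.1 s frames with ~0.1 s sampling dwells,
simulating directly in discrete time would alias the short dwells; exact
event sampling keeps the ground truth free of discretization bias. Each
frame reports the occupancy-time-weighted mean FRET over its live
(pre-bleach) portion; the donor channel carries
`total_intensity × (1 − FRET)` plus background, the acceptor
`total_intensity × FRET` plus donor leakage and background, both with
additive Gaussian camera noise.

Leakage is applied to the background-free donor signal, so the standard
correction (`I_D = raw_D − bg_D`; `I_A = raw_A − bg_A − leakage·I_D`) inverts
the emission model exactly — noiseless frames recover state means to
machine precision, which the tests assert at 1e-6.

## Target presets

One versioned file (`src/casfret/presets.json`) holds the per-target
kinetics. Quantities pinned by the measured SpCas9 mismatch panel:

| quantity | value |
|---|---|
| association constant k_on | 6×10⁶ M⁻¹s⁻¹ (3×10⁶ without PAM) |
| sampling (mid) lifetime | 0.1 s |
| τ_avg bound: 5–20_mm / 8–20_mm / 9–20_mm | 0.5 / 8 / 16 s |
| cognate dissociation | 1/1800 s⁻¹ (photobleach-limited, < 0.006 s⁻¹ observed) |
| PAM-proximal (1–2_mm) dissociation | 2.5 s⁻¹ (> 2 s⁻¹) |
| photobleach lifetime | 180 s |
| FRET means (U/S/H) | 0 / 0.42 / 0.92 |
| frame interval | 0.1 s |

Free choices, made once:

* **Branching.** Binding is two-step (U→S→H). The S→H branch probability is
  0.90 / 0.85 / 0.75 for 9–20 / 8–20 / 5–20_mm — the mid state is observed
  more often as mismatches grow — and the H lifetime is then solved from
  `τ_avg = τ_S + p·τ_H`, so each preset's analytic amplitude-weighted bound
  lifetime equals its target value exactly (the package computes this from
  the phase-type sub-generator, `KineticScheme.mean_bound_lifetime`).
* **Cognate binding is direct U→H capture.** Cognate association appears as
  a single 0→0.92 step at 0.1 s resolution; any intermediate is
  unresolvable, so the preset omits it. Direct U→H entries are allowed in
  every scheme, so two-step and one-step models coexist without code
  changes.
* **1–2_mm sampling dwell = 0.3 s** with a 0.3 branch to a short-lived
  (0.4 s) heteroduplex. Weak binders show the sampling mode most clearly and
  somewhat longer sampling dwells; the cross-target average stays near
  0.1 s. This preset serves as the "weak binder rich in sampling events".
* **Roadblock presets** (9–12_mm, 5–8_mm) copy the kinetics of 9–20_mm and
  5–20_mm: dissociation is set by heteroduplex extension up to the first
  mismatch, so matches beyond a mismatch roadblock are irrelevant.
* **Emission defaults**: total intensity 500 counts/frame, channel noise SD
  30, backgrounds 50, leakage 0.07 — realistic for EMCCD TIRF and chosen so
  the three FRET states are separable yet overlapping.

Datasets can start `"stationary"` (steady-state imaging; used for
histograms and dissociation kinetics) or in `"U"` (flow-in association
experiments; used for k_on).

## HMM idealization

Each molecule is fitted with its own three-state Gaussian HMM
(per-molecule fits are what makes the log-mean aggregation of transition
probabilities meaningful), EM-refined from means (0, 0.42, 0.92) until the
log-likelihood improves by < 1e-6 or 500 iterations, then Viterbi-decoded.
Numerical choices that matter:

* **Initialization.** Start covariances are set to (0.1)² per state and the
  transition matrix to a sticky 0.85/0.075 split; library defaults (global
  trace variance, random transition matrix) make the first E-step nearly
  uniform and let states migrate across clusters.
* **Mean anchoring.** Free means carry a weak MAP anchor at the canonical
  levels (weight = 10 pseudo-frames). A state the molecule actually visits
  moves freely; a state with no data of its own stays at its level instead
  of splitting another state's cluster.
* **Canonical mapping.** Fitted states are mapped to zero/mid/high by band
  edges 0.21 and 0.67 (midpoints between canonical levels) and merged;
  levels with zero occupancy are flagged degenerate, never raised.
* **Reported state means** are re-estimated from transition-distal
  (dwell-interior) frames. Camera time-averaging dilutes boundary frames (a
  frame half-spent in a state shows half its FRET), biasing raw EM means of
  short-dwell states low by ~0.03–0.05; interior frames are free of this.
  Raw EM means remain available (`means_em_`).
* Viterbi ties resolve to the lower state index (deterministic output).

Transition-probability rates follow `k = T_p × sampling rate` with `T_p`
the geometric mean (exponential of the mean log) of per-molecule transition
probabilities; zeros are excluded from the log-mean and reported separately.
This linear conversion saturates at the sampling rate: for a true rate k the
per-frame probability is `1 − exp(−kΔt)`, not `kΔt`. The exact inversion
`k = −ln(1 − T_p)/Δt` is available (`conversion="log"`) and is the one that
recovers rates comparable to the sampling rate.

## Dwell-time kinetics

Bound dwells merge mid and high states (FRET > 0.2); dwells are maximal
frame runs, recorded as integer frame multiples (minimum one frame — dwells
shorter than a frame are unobservable and no missed-event correction is
applied). The first and last run of each trace are censored by the
observation window.

Survival fits are maximum likelihood on durations, not least squares on the
empirical survival curve (a least-squares-free cross-check exists via the
continuous/frame likelihood options):

* **Frame-discretized likelihood (default).** Durations are integer frame
  counts; for an exponential dwell observed through frame binning the run
  length is geometric with `q = exp(−Δt/τ)`. For lifetimes near the frame
  interval the continuous MLE on rounded durations is biased upward by
  ~50–60%; the geometric MLE is not. For explicitly single-exponential
  frame fits, the geometric ratio is estimated from run lengths ≥ 2 frames
  with shifted support: the one-frame bin depends on how the idealizer
  splits transition-boundary frames, while the ≥ 2 tail is offset-invariant.
* **Censoring.** Two documented routes. `censoring="observed"` (pipeline
  default) treats truncated dwells as complete and then applies the
  published arithmetic `k_actual = k_observed − k_photobleach`,
  `τ_avg = 1/k_actual`, with the photobleach rate itself fitted by
  censoring-aware exponential MLE from the detected bleach times.
  `censoring="likelihood"` lets censored dwells enter through their survival
  probability, needing no subtraction afterwards. Applying the subtraction
  on top of the censoring-aware fit would correct twice; the two routes are
  kept separate and agree within a few percent when bleaching is much
  slower than the dwell of interest (asserted in tests).
* **Model selection.** `auto` picks the double exponential when it improves
  the BIC by ≥ 6 (no selection criterion is prescribed by the source
  analysis, only the outcome). Amplitudes are constrained to sum to one.
  A fit whose short lifetime collapses onto the frame interval is flagged
  resolution-limited.
* **k_on** is the weighted least-squares slope of unbound decay rate versus
  concentration through the origin (binding vanishes at zero concentration);
  an intercept-allowed variant exists as a diagnostic. With one
  concentration the slope reduces to rate/concentration.

## Genome counting

Sliding exact match of an `{A,C,G,T,N}` query (N = wildcard) over both
strands, overlapping matches counted, records never spanned, ambiguous
genome bases never matching a specified query base. The random-sequence
expectation `(¼)ⁿ × L` is single-strand; when the actual count uses both
strands the expectation is doubled, and the convention used is recorded in
the result. Positions are reported 1-based, inclusive, forward-strand.

## What the simulator does and does not emulate

Emulated: the three-state binding scheme with concentration scaling,
exponential dwells, exact event timing with frame-averaged camera readout at
0.1 s, Gaussian channel noise, donor leakage, channel backgrounds, and
exponential photobleach truncation. Not emulated: dye photophysics
(blinking, protein-induced fluorescence enhancement), local-diffusion FRET
averaging within the sampling mode, donor-only species, gamma/detection
efficiency corrections, and laser geometry. Passing recovery tests therefore
shows the analysis chain is correct for the modeled physics; on real data,
additional photophysical artifacts could still bias lifetimes near the
frame interval.

## Problem sizes

The reproduction script (`scripts/acceptance.py`) uses 300 molecules per
kinetic target (500 for the sampling-lifetime target, 200 for the
high-state-mean target) with trace lengths of 60–600 s matched to the
lifetime being measured. The test suite runs the same recoveries at 60–250
molecules, which keeps estimator standard errors comfortably inside the
asserted tolerances while the whole suite stays fast.

## Known limitations

* The linear `T_p × sampling rate` conversion underestimates rates
  comparable to the sampling rate (use `conversion="log"` there).
* Idealized dwell boundaries carry ±1 frame of ambiguity from camera
  time-averaging; bound-lifetime estimates for dwells of a few frames are
  accurate to ~10% rather than ~2%.
* Equilibrium bound fractions follow from the preset kinetics; targets whose
  true lifetime greatly exceeds the photobleach lifetime have their
  occupancy under-sampled in finite traces, as in the modeled experiment.
* The genome counter is exact-match only; mismatch-tolerant (off-by-k)
  search is out of scope.
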