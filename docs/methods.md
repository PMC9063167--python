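# Methods

`megfc` re-implements, as a tested pipeline with a verifiable synthetic
cohort, a source-space MEG functional-connectivity analysis of familiar
vs. unfamiliar music listening in two groups of children (ASD and
typically developing controls). This note documents the models, the
tunable parameters, what the simulator does and does not emulate, and
the design choices made where the design was genuinely open.

## The analysis model

**Paradigm.** Each subject hears 8 familiar-liked, 8 familiar-disliked
and 24 unfamiliar 30-s excerpts over four task runs of ten, bracketed by
two 3-min resting runs (40 music trials in total). Familiar and
unfamiliar stimuli are matched on tempo class (slow 40–72, moderate
72–120, fast 120–208 bpm; half-open bins with the shared printed
boundary assigned to the upper class so classification is total and
deterministic), mode, genre, lyrics, and lyric language. The
familiarity label analysed is the subject's in-scanner response, not the
pre-selected stimulus label; liked/disliked are collapsed into
familiar/unfamiliar.

**Preprocessing.** 30-s trials are epoched into non-overlapping 10-s
chunks; trials with head motion strictly greater than 10 mm are
rejected; subjects need at least 3 trials per condition (and at least
one surviving resting trial, needed for baselining) to stay in the
analysis. Sensor-space data are cleaned by ICA: components whose
absolute correlation with an artifact reference trace exceeds r = 0.4
(default; up to 60 components considered) are zeroed. The correlation
criterion replaces visual component inspection, which is not
reproducible in an automated artifact.

**Filterbank.** A 60 Hz zero-phase IIR notch, then per band a
linear-phase FIR band-pass applied forward and backward (zero net phase
shift, output length preserved). Bands: theta 4–7, alpha 8–14, beta
15–29, gamma1 30–55, gamma2 65–80 Hz. FIR length is set by a transition
width of min(2 Hz, lo/2) (Hamming window, ~3.3/Δf·fs taps). A
cycles-based order (e.g. 3 cycles of the low edge) was considered and
rejected: at 600 Hz it yields transition bands wider than the narrow
bands themselves, so a mid-band tone would lose >20% amplitude and the
band-limited output would leak well outside [lo−1, hi+1] Hz; the
transition-width rule keeps passbands flat and ≥95% of output spectral
mass inside the nominal band, which the tests assert. The first and
last second of every 10-s epoch are excluded from connectivity
estimation (Hilbert/filter edge effects).

**Source reconstruction.** Scalar LCMV beamformer weights per parcel
centroid: `w_i = (l_i' C⁻¹ l_i)⁻¹ l_i' C⁻¹` with unit gain at the
target, covariance diagonally loaded by 5% of the mean sensor variance
(default) and estimated over all of a subject's epochs. The synthetic
leadfield has one column per parcel (no dipole-orientation search). The
pipeline can consume parcel-level input directly, making this stage
optional; the sensor-space path (forward projection → ICA → LCMV) is
exercised behind a configuration flag.

**Leakage correction.** Before AEC only, parcel series are replaced by
the mutually uncorrelated set closest in summed squared distance
("closest" orthogonalization): alternate an orthogonal-Procrustes
rotation (polar decomposition of X·diag(s)) with per-signal rescaling to
relative tolerance 1e−8 (max 100 iterations; non-convergence is an
error reporting the residual). Signals are demeaned for the iteration
and means are restored afterwards, so outputs have exactly zero pairwise
Pearson correlation. One correction is estimated per subject and band
over all concatenated epochs. wPLI is computed without correction — its
statistic ignores zero-lag coupling by construction.

**Connectivity.** Per 10-s epoch, from the Hilbert analytic signal:
wPLI = |Σ Im S| / Σ |Im S| with S(t) = z_A(t)·conj(z_B(t)) (an
imaginary sum at rounding-noise level, e.g. identical zero-lag signals,
is flagged degenerate and reported as 0); AEC = Pearson correlation of
the envelopes (zero-variance envelopes are flagged and excluded from
trial averages). Epochs are averaged within trial, trials within
condition; the resting average (10-s rest epochs, grouped in 30-s
triplets) is subtracted, giving one baselined matrix per subject,
condition, band and metric. Whole-brain mode gives 92×92 symmetric
matrices; ROI mode gives 92×13 matrices over the seed set, and ROI
entries equal the corresponding whole-brain entries exactly. The
debiased wPLI variant is deliberately not used; AEC uses raw (not
log-transformed) envelopes; unequal trial counts between conditions are
accepted as-is.

**Network statistics (NBS).** Edgewise statistics: pooled two-sample t
(between groups), paired t on familiar−unfamiliar (within group), and
F = t² of the two-sample t on per-subject condition differences (2×2
mixed-design interaction; under a purely additive condition effect the
differences are exchangeable and the interaction is null by
construction). Maps are thresholded (defaults t = 2.75/3.0/3.5 for AEC,
3.0 for wPLI, F = 7; one-sided contrasts run separately per direction),
connected suprathreshold components are scored by edge count (node count
reported alongside), and family-wise p-values come from the permutation
distribution of the maximal component under 5000 relabelings (group
labels for between/interaction, per-subject sign flips for paired), with
p = (1 + #{null ≥ observed}) / (1 + K) so p is never zero. Designs too
small for the requested permutation count fall back to exact enumeration
with a warning. ROI maps are embedded in the full 92-node graph before
component extraction, so components may span seed and non-seed nodes.
Bonferroni correction is applied within metric with family sizes 4
(between; per-test alpha 0.0125), 2 (within; 0.025) and 2 (interaction;
0.025 — consistent with an interaction p of 0.023 being reported
significant). The exact composition of the 4- and 2-test families is
pinned only by these printed thresholds and is exposed as configuration.

**Brain–behavior.** Network strength = sum of a subject's baselined edge
weights over a significant component's edges (each undirected edge
once), correlated (Pearson, two-sided, uncorrected) with SCQ and the
RBS-R sameness subscale across groups and with the ADOS calibrated
severity score within the ASD group; missing scores are dropped
pairwise. Cohort summary tables are replicated with the pooled-variance
two-sample t (df = n1+n2−2, matching the printed df = 46).

## The synthetic cohort

The generator's defaults are the study conditions: 2 × 24 subjects, 92
parcels, 600 Hz, 30-s trials, the five-band filterbank, a 151-sensor
forward model, and per-trial head motion drawn log-normally (median
4.5 mm, σ = 0.5 on the log scale, between the reported task-run group
means of 4.3 and 5.9 mm) so the 10 mm rejection rule is exercised at a
realistic few-percent rate. Every dataset is bit-reproducible from
(config, seed).

Each parcel carries one unit-variance narrowband component per band
(spectrally synthesized Gaussian noise) plus 1/f background. Planted
couplings, keyed by (band, metric, group, condition):

* **Phase (wPLI targets).** The pair shares a narrowband signal, the
  second copy delayed by a quarter period of the band's center
  frequency, amplitude-weighted by the effect size — this guarantees a
  non-zero imaginary cross-spectrum, exactly what wPLI detects.
* **Envelope (AEC targets).** Planted parcels carry a constant-modulus
  carrier — a center-frequency tone with a slow (< 0.4 Hz) random phase
  drift, so its spectrum stays inside the band and its envelope stays
  flat even after filtering — multiplied by a positive slow modulator
  1 + depth·l (depth 0.3; l is standardized < 1 Hz noise clipped at ±3
  SD, so depth < 1/3 guarantees positivity and larger depths are a
  configuration error). One shared slow factor per planted edge; a
  parcel's l mixes √ρ_e of each incident edge's factor plus a private
  remainder, so every planted pair meets its target correlation ρ_e and
  the per-parcel budget Σρ_e ≤ 1 (requesting more is rejected — the
  corresponding correlation matrix would not be positive
  semi-definite). The carrier is 3× the band-noise amplitude so the
  modulator, not the stochastic background, dominates the measured
  envelope.
* **Leakage.** Zero-lag mixing by a row-normalized identity-plus-
  symmetric-perturbation matrix (strength 0.1 by default, fixed per
  subject) — the mixing wPLI must ignore and uncorrected AEC must not.
* **Artifacts/forward model.** Gaussian leadfield (full column rank
  enforced), cardiac-like spike trains (~1.2 Hz) and ocular-like blink
  bumps with large loadings, returned as reference traces for the ICA
  criterion.

What the simulator does **not** emulate: realistic head geometry and
field physics (spherical/realistic head models are out of scope by
design), spatially correlated sensor noise, 1/f exponents varying across
the cortex, heterogeneous per-subject effect sizes, or genuine
anatomical parcel geometry (the shipped node table's coordinates are
approximate synthetic stand-ins for export/rendering only). Passing
recovery tests therefore demonstrate correctness of the estimators and
statistics under known ground truth — not performance on real MEG
recordings.

In-scanner familiarity responses disagree with pre-selected labels at a
configurable rate (default 0.1). The study does not report its
disagreement rate; 10% keeps condition counts realistically uneven
(unfamiliar > familiar, as reported) while rarely dropping subjects
below the 3-trial minimum.

## Verification experiments (`megfc.validation`)

* **Null calibration.** 100 replicate null cohorts (20/group, 92 nodes,
  500 permutations, t = 3.0): the fraction with any p_fwer < 0.05 must
  stay within 2 Monte-Carlo SEs of 0.05.
* **Between-group recovery.** A 6-edge effect of standardized size 1.2
  (n = 24/24, t = 3.0, 500 permutations) planted on a star anchored at a
  seed region, tested over the seed-anchored (ROI) edge universe where
  the reported between-group networks were found. A star rather than a
  path: seed-based effects are hub-anchored, and any surviving subset of
  a star's edges remains one connected component, so detection measures
  statistical power rather than topology luck. The experiment reports
  the median over 3 independent cohorts so the summary reflects the
  method, not a single draw.
* **Interaction recovery.** A standardized shift of 1.2 in one
  group×condition cell only, on a 15-edge seed-anchored star (the size
  of the reported alpha-band interaction network), with the two
  condition matrices of a subject sharing a subject-level random effect
  (within-subject correlation 0.5, as repeated measures do). The ROI
  edge universe matters here: at F = 7 (df 46) the two-sided
  suprathreshold density over all 4186 whole-brain edges puts the null
  graph at the percolation threshold, where giant noise components make
  small-component inference impossible under independent-edge noise;
  the ~1100-edge seed universe is comfortably subcritical, matching
  where the reported interaction was actually found.
* **Metric oracles.** Planted envelope correlation 0.6 recovered within
  ±0.1 over 100 trials; quarter-period lag gives wPLI = 1; zero-lag
  identical signals are degenerate; leakage mixing shifts mean wPLI by
  < 0.05 with and without orthogonalization.

## Problem sizes used by tests and the reproduction script

End-to-end runs use scaled cohorts (6/group, 10 parcels, one band,
12 music trials/subject, 400 permutations for the planted-recovery run;
4/group, 8 parcels, 100 permutations for null/determinism runs). These
sizes were chosen as the smallest at which the planted effects are
comfortably detectable and the permutation p floor (1/(K+1), or the
exact-enumeration floor for small groups) sits well below the Bonferroni
thresholds; the statistical machinery itself is validated at full study
scale (92 nodes, 24/group, 500 permutations) by the matrix-level
experiments above.

## Numerical choices and degenerate inputs

* wPLI degeneracy floor: Σ|Im S| ≤ 1e−12·Σ|z_A||z_B| → value 0, flagged.
* Zero-variance envelopes → NaN, excluded from trial averages (a fully
  degenerate trial average is reported as 0).
* Zero-variance edges in t-maps → statistic 0 (flagged by construction).
* LCMV with singular covariance and zero loading → error advising a
  regularization fraction; weights are invariant to uniform sensor
  rescaling.
* Orthogonalization requires more samples than signals and non-zero
  variance; already-orthogonal input is a fixed point.
* Greedy first-fit stimulus matching in input order (the matching
  algorithm is not otherwise specified); unmatched songs are reported,
  not raised.
* Motion rule uses strict `>` (a trial at exactly 10 mm is kept).
* All seeds derive from a single integer via `SeedSequence`; every
  output file (TSV, JSON with sorted keys, raw `.npy`) is timestamp-free
  so identical runs are byte-identical.

## Known limitations

* The closest-orthogonalization alternation converges to a local
  optimum; the brute-force cross-check is only feasible for the
  2-signal case.
* A parcel shared by many planted AEC edges approaches the Σρ ≤ 1
  budget; dense planted graphs with large targets are rejected rather
  than approximated.
* The ICA criterion removes whole components; with few sensors a
  component can mix brain and artifact signal, removing some brain
  variance (the planted-artifact test asserts ≥90% artifact-variance
  removal, not perfect separation).
* Behavioral scores are synthetic draws from the printed cohort
  summaries; brain–behavior correlations in pipeline runs exercise the
  code path but carry no scientific content.
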