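# megfc

Source-space MEG functional connectivity for a two-group music-familiarity
listening paradigm: band-limited **amplitude envelope correlation** (AEC,
with "closest" leakage orthogonalization) and **weighted phase lag index**
(wPLI) connectivity, resting-baselined per subject, tested with
**network-based statistics** (NBS) within groups, between groups and as a
2×2 group × familiarity interaction, and summarized per subject as network
strength for brain–behavior correlation. A synthetic-data generator with
planted, ground-truth couplings makes every stage verifiable without the
study's raw recordings.

It is written for researchers analysing task MEG/EEG connectivity in
clinical group comparisons (here: children with autism spectrum disorder
vs. typically developing controls listening to familiar vs. unfamiliar
songs), and for anyone who wants a self-validating reference
implementation of the AEC/wPLI/NBS stack.

## The statistics at the core

With `z_A(t), z_B(t)` the Hilbert analytic signals of two band-limited
parcel time series and `S(t) = z_A(t) · conj(z_B(t))` the per-sample
cross-spectral term:

```
wPLI = | Σ_t Im S(t) |  /  Σ_t |Im S(t)|            ∈ [0, 1]
AEC  = corr( |z_A(t)| , |z_B(t)| )                  ∈ [−1, 1]
```

wPLI weights each sample by the magnitude of its imaginary part, so
purely real (zero-lag, volume-conduction/leakage) coupling contributes
nothing. AEC is computed after replacing the parcel series by the
mutually uncorrelated set closest in summed squared distance
(orthogonal-Procrustes alternation), which removes zero-lag leakage
before envelope correlation. Both are estimated within 10-s epochs,
averaged over a trial's epochs and a condition's trials, then baselined
by subtracting the resting-state average.

NBS controls the family-wise error rate at the network level: edgewise
t (or F = t² of difference scores for the interaction) maps are
thresholded (t = 2.75/3.0/3.5 for AEC, 3.0 for wPLI, F = 7), connected
suprathreshold components are scored by edge count, and
`p_fwer = (1 + #{null max ≥ observed}) / (1 + K)` over K = 5000
relabelings, Bonferroni-corrected within metric (per-test alphas 0.0125
between groups, 0.025 within groups).

## Worked example

Plant a single phase-coupled edge, run the estimator, and check it
against the simulator's ground truth:

```python
import numpy as np
from megfc import (
    SimulationConfig, simulate_subject_timeseries, bandpass_filterbank,
    analytic_signal, wpli_matrix, summary_group_ttest, BandSpec,
)

alpha = BandSpec("alpha", 8.0, 14.0)
config = SimulationConfig(
    n_parcels=8, bands=(alpha,), trial_duration_s=10.0,
    planted_edges={("alpha", "wpli", "ASD", "familiar"): [(0, 1, 1.0)]},
    leakage_mixing_strength=0.0, seed=7,
)
ts, truth = simulate_subject_timeseries(config, "sub01", "ASD", "familiar", 30)

mats = []
for trial in ts.data:
    band = bandpass_filterbank(trial, ts.sfreq, bands=[alpha])[alpha.label]
    mats.append(wpli_matrix(analytic_signal(band, ts.sfreq, trim_s=1.0).z))
mean = np.mean(mats, axis=0)

others = [mean[i, j] for i in range(8) for j in range(i + 1, 8) if {i, j} != {0, 1}]
print(f"planted edge (0,1) wPLI: {mean[0, 1]:.3f}")
print(f"background edges:        {np.mean(others):.3f} +/- {np.std(others):.3f}")

t, df = summary_group_ttest(14.2, 11.6, 24, 1.9, 3.7, 24)
print(f"cohort RBS-R t-test:     t = {t:.2f}, df = {df}")
```

prints

```
planted edge (0,1) wPLI: 0.764
background edges:        0.170 +/- 0.021
cohort RBS-R t-test:     t = 4.95, df = 46
```

The planted edge stands far above the finite-sample null level of the
background edges (~0.17 for 8-s epochs of alpha-band noise), and the
pooled-variance t-test reproduces the printed cohort statistic
(t = 4.92, df = 46) within its rounding.

The full pipeline — simulate cohort → QC → filterbank → connectivity →
NBS → Bonferroni → behavior — runs from a YAML config:

```bash
megfc run-all --config config.yaml --seed 3 --out results/
```

and writes manifests, a QC report, baselined matrices, an NBS component
table, behavioral correlations, BrainNet-style `.node`/`.edge` exports
of significant networks, and a run log. Stage-wise subcommands
(`simulate`, `preprocess`, `beamform`, `connect`, `nbs`, `behavior`,
`export`) operate on the same on-disk artifacts.

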