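"""Epoching, motion/trial-count QC, filterbank and artifact removal."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

from megfc.preprocessing import (
    CANONICAL_BANDS,
    BandSpec,
    bandpass_filterbank,
    epoch_trials,
    notch_filter,
    qc_min_trials,
    reject_motion_trials,
    remove_artifact_components,
)

FS = 600.0


def _manifest(rows):
    records = []
    for subject, cond, motion in rows:
        records.append(
            {
                "subject": subject,
                "group": "TD",
                "run": 1,
                "trial": len(records) + 1,
                "stimulus": "x",
                "condition_stimulus": cond,
                "liking": "n/a",
                "condition_response": cond,
                "duration_s": 30.0,
                "is_rest": cond == "rest",
                "motion_mm": motion,
            }
        )
    return pd.DataFrame(records)


class TestEpoching:
    def test_thirty_second_trial_gives_three_epochs(self):
        x = np.zeros((5, 18000))
        eps = epoch_trials(x, FS, 10.0)
        assert eps.shape == (3, 5, 6000)

    def test_identity_case(self):
        assert epoch_trials(np.zeros(6000), FS, 10.0).shape == (1, 6000)

    def test_trailing_remainder_discarded(self):
        eps = epoch_trials(np.arange(15000.0), FS, 10.0)
        assert eps.shape == (2, 6000)
        # sample conservation up to the discarded remainder
        assert eps.ravel()[-1] == 11999.0

    def test_too_short_trial_raises(self):
        with pytest.raises(ValueError, match="shorter"):
            epoch_trials(np.zeros(5999), FS, 10.0)


class TestMotionRejection:
    @pytest.mark.parametrize(
        "motion,kept", [(12.0, False), (0.0, True), (10.0, True), (10.0001, False)]
    )
    def test_strict_threshold(self, motion, kept):
        manifest = _manifest([("s1", "familiar", motion)])
        out, report = reject_motion_trials(manifest, 10.0)
        assert (len(out) == 1) is kept
        assert report.dropped_motion["s1"] == (0 if kept else 1)

    def test_missing_motion_names_the_trial(self):
        manifest = _manifest([("s1", "familiar", np.nan)])
        with pytest.raises(ValueError, match="s1"):
            reject_motion_trials(manifest, 10.0)


class TestMinTrialsQC:
    def test_subject_below_minimum_excluded(self):
        rows = [("s1", "familiar", 1.0)] * 2 + [("s1", "unfamiliar", 1.0)] * 5
        rows += [("s2", "familiar", 1.0)] * 3 + [("s2", "unfamiliar", 1.0)] * 3
        included, report = qc_min_trials(_manifest(rows), 3)
        assert included == ["s2"]
        assert report.condition_counts["s1"] == {"familiar": 2, "unfamiliar": 5}

    def test_all_subjects_meeting_minimum_included(self):
        rows = []
        for s in ("a", "b", "c"):
            rows += [(s, "familiar", 1.0)] * 3 + [(s, "unfamiliar", 1.0)] * 4
        included, _ = qc_min_trials(_manifest(rows), 3)
        assert included == ["a", "b", "c"]

    def test_counts_match_independent_tally_and_order_invariance(self, rng):
        """Inclusion set equals a Counter-based oracle and ignores row order."""
        from collections import Counter

        rows = []
        for s in range(6):
            nf, nu = rng.integers(0, 6), rng.integers(0, 6)
            rows += [(f"s{s}", "familiar", 1.0)] * int(nf)
            rows += [(f"s{s}", "unfamiliar", 1.0)] * int(nu)
        manifest = _manifest(rows)
        shuffled = manifest.sample(frac=1.0, random_state=7).reset_index(drop=True)
        included, _ = qc_min_trials(shuffled, 3)

        tally = Counter(
            (r.subject, r.condition_response) for r in manifest.itertuples()
        )
        oracle = sorted(
            s
            for s in manifest["subject"].unique()
            if tally[(s, "familiar")] >= 3 and tally[(s, "unfamiliar")] >= 3
        )
        assert included == oracle


class TestFilterbank:
    def test_alpha_tone_passband_and_beta_stopband(self):
        t = np.arange(0, 10, 1 / FS)
        x = np.cos(2 * np.pi * 10 * t)
        out = bandpass_filterbank(x, FS)
        mid = slice(2000, 4000)
        assert 0.95 <= np.abs(out["alpha"][mid]).max() <= 1.05
        assert np.abs(out["beta"][mid]).max() < 0.05

    def test_notch_attenuates_line_frequency_by_20db(self):
        t = np.arange(0, 10, 1 / FS)
        x = np.cos(2 * np.pi * 60 * t)
        y = notch_filter(x, FS, 60.0)
        f, pxx_in = sps.periodogram(x, FS)
        _, pxx_out = sps.periodogram(y, FS)
        k = np.argmin(np.abs(f - 60.0))
        atten_db = 10 * np.log10(pxx_in[k] / pxx_out[k])
        assert atten_db >= 20.0

    @pytest.mark.parametrize("band", CANONICAL_BANDS, ids=lambda b: b.label)
    def test_white_noise_spectral_mass_concentrated_in_band(self, band, rng):
        """Periodogram oracle: >=95% of output power within [lo-1, hi+1] Hz."""
        x = rng.standard_normal(int(60 * FS))
        y = bandpass_filterbank(x, FS, bands=[band], notch_hz=None)[band.label]
        f, pxx = sps.periodogram(y, FS)
        total = pxx.sum()
        inside = pxx[(f >= band.lo - 1.0) & (f <= band.hi + 1.0)].sum()
        assert inside / total >= 0.95

    def test_two_pass_filtering_has_zero_net_phase_shift(self, rng):
        """Cross-correlation of a narrowband input and its filtered copy
        peaks at lag zero (group delay fully compensated)."""
        from megfc.simulate import narrowband_noise

        x = narrowband_noise(12000, FS, 9.0, 13.0, rng)
        y = bandpass_filterbank(x, FS, bands=[BandSpec("alpha", 8.0, 14.0)],
                                notch_hz=None)["alpha"]
        xc = sps.correlate(y[1000:-1000], x[1000:-1000], mode="full")
        lag = np.argmax(xc) - (len(x) - 2001)
        assert lag == 0

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_filterbank(np.zeros(6000), 100.0, bands=[BandSpec("g", 30, 80)])


class TestArtifactRemoval:
    def test_clean_input_passes_through(self, rng):
        epochs = rng.standard_normal((4, 6, 1200))
        refs = rng.standard_normal((2, 4 * 1200))  # unrelated references
        cleaned, report = remove_artifact_components(epochs, refs)
        assert report.components_removed["n"] == 0
        for ch in range(6):
            a = epochs[:, ch].ravel()
            b = cleaned[:, ch].ravel()
            assert np.corrcoef(a, b)[0, 1] > 0.99

    def test_planted_artifact_variance_mostly_removed(self, rng):
        """At least 90% of the planted component's variance disappears,
        measured against the known mixing vector and time course."""
        from megfc.simulate import make_artifact_signals

        n_ep, n_sens, n_samp = 6, 8, 1200
        brain = rng.standard_normal((n_ep, n_sens, n_samp))
        refs = make_artifact_signals(n_ep, n_samp, FS, 1, rng)
        loading = rng.standard_normal(n_sens)
        contaminated = brain + loading[None, :, None] * refs[:, 0][:, None, :]

        cleaned, report = remove_artifact_components(contaminated, refs)
        assert report.components_removed["n"] >= 1

        ref_flat = refs[:, 0].ravel()
        ref_flat = ref_flat / np.linalg.norm(ref_flat)

        def artifact_power(x):
            flat = np.moveaxis(x, 1, 0).reshape(n_sens, -1)
            proj = flat @ ref_flat
            return float(proj @ proj)

        assert artifact_power(cleaned) <= 0.1 * artifact_power(contaminated)
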