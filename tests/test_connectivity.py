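"""Analytic signal, wPLI, AEC, adjacency construction and baselining."""

import numpy as np
import pytest

from megfc.connectivity import (
    ConnectivityMatrix,
    aec_matrix,
    analytic_signal,
    average_and_baseline,
    build_adjacency,
    compute_aec,
    compute_wpli,
    wpli_matrix,
)

FS = 600.0
T = np.arange(0, 10, 1 / FS)


class TestAnalyticSignal:
    def test_unit_tone_envelope_is_flat(self):
        sig = analytic_signal(np.cos(2 * np.pi * 10 * T), FS, trim_s=1.0)
        assert np.max(np.abs(sig.envelope - 1.0)) < 0.01

    def test_am_demodulation_recovers_the_modulator(self):
        """(1 + 0.5 cos(2 pi 0.5 t)) cos(2 pi 20 t): the envelope tracks
        the slow modulator with correlation > 0.99."""
        mod = 1 + 0.5 * np.cos(2 * np.pi * 0.5 * T)
        x = mod * np.cos(2 * np.pi * 20 * T)
        sig = analytic_signal(x, FS, trim_s=1.0)
        k = int(FS)
        assert np.corrcoef(sig.envelope, mod[k:-k])[0, 1] > 0.99

    def test_instantaneous_frequency_of_tone(self):
        """Unwrapped phase derivative of a 10 Hz tone is 2 pi 10 rad/s."""
        sig = analytic_signal(np.cos(2 * np.pi * 10 * T), FS, trim_s=1.0)
        freq = np.diff(np.unwrap(sig.phase)) * FS / (2 * np.pi)
        assert abs(freq.mean() - 10.0) / 10.0 < 0.01

    def test_zero_input_flagged_degenerate(self):
        sig = analytic_signal(np.zeros(6000), FS)
        assert np.all(sig.envelope == 0)
        assert bool(sig.degenerate)


class TestWPLI:
    def test_quarter_period_lag_gives_one(self):
        a = np.cos(2 * np.pi * 10 * T)
        b = np.cos(2 * np.pi * 10 * (T - 1.0 / 40.0))  # quarter period of 10 Hz
        za = analytic_signal(a, FS, 1.0).z
        zb = analytic_signal(b, FS, 1.0).z
        value, degenerate = compute_wpli(za, zb)
        assert value == pytest.approx(1.0, abs=1e-9)
        assert not degenerate

    def test_zero_lag_identical_signals_flagged_degenerate(self):
        z = analytic_signal(np.cos(2 * np.pi * 10 * T), FS, 1.0).z
        value, degenerate = compute_wpli(z, z)
        assert value == 0.0
        assert degenerate

    def test_matches_naive_two_loop_formula(self, rng):
        """Brute-force per-sample evaluation of the defining formula."""
        za = rng.standard_normal(500) + 1j * rng.standard_normal(500)
        zb = rng.standard_normal(500) + 1j * rng.standard_normal(500)
        value, _ = compute_wpli(za, zb)
        num = 0.0
        den = 0.0
        for t in range(500):
            s = za[t] * np.conj(zb[t])
            num += s.imag
            den += abs(s.imag)
        assert value == pytest.approx(abs(num) / den, abs=1e-12)

    def test_zero_lag_mixture_stays_at_shuffled_null_level(self, rng):
        """B = 0.7 A + 0.3 independent: leakage-like mixing must not raise
        wPLI above its own trial-shuffled surrogate null."""
        from megfc.simulate import narrowband_noise

        n_trials = 30
        obs = []
        zs_a, zs_b = [], []
        for _ in range(n_trials):
            a = narrowband_noise(6000, FS, 8, 14, rng)
            c = narrowband_noise(6000, FS, 8, 14, rng)
            b = 0.7 * a + 0.3 * c
            za = analytic_signal(a, FS, 1.0).z
            zb = analytic_signal(b, FS, 1.0).z
            zs_a.append(za)
            zs_b.append(zb)
            obs.append(compute_wpli(za, zb)[0])
        observed = np.mean(obs)
        null_means = []
        for _ in range(99):
            perm = rng.permutation(n_trials)
            null_means.append(
                np.mean(
                    [compute_wpli(zs_a[i], zs_b[j])[0] for i, j in enumerate(perm)]
                )
            )
        assert observed < np.percentile(null_means, 95)

    @pytest.mark.parametrize("phi", [0.3, 1.1, 2.9])
    def test_invariances(self, rng, phi):
        """Symmetric under swap; invariant under global phase rotation."""
        za = rng.standard_normal(400) + 1j * rng.standard_normal(400)
        zb = rng.standard_normal(400) + 1j * rng.standard_normal(400)
        v, _ = compute_wpli(za, zb)
        assert compute_wpli(zb, za)[0] == pytest.approx(v, abs=1e-12)
        rot = np.exp(1j * phi)
        assert compute_wpli(rot * za, rot * zb)[0] == pytest.approx(v, abs=1e-12)
        assert 0.0 <= v <= 1.0


class TestAEC:
    def test_identical_envelopes_give_one(self, rng):
        env = np.abs(rng.standard_normal(1000)) + 0.1
        assert compute_aec(env, env)[0] == pytest.approx(1.0)

    def test_independent_envelopes_near_zero(self, rng):
        """Null Monte-Carlo: |AEC| < 0.05 in at least 95% of runs at n=6000."""
        hits = 0
        runs = 40
        for _ in range(runs):
            e1 = np.abs(rng.standard_normal(6000))
            e2 = np.abs(rng.standard_normal(6000))
            if abs(compute_aec(e1, e2)[0]) < 0.05:
                hits += 1
        assert hits / runs >= 0.95

    def test_zero_variance_envelope_flagged(self):
        value, degenerate = compute_aec(np.ones(100), np.arange(100.0))
        assert degenerate and np.isnan(value)

    def test_invariant_under_positive_rescaling(self, rng):
        e1 = np.abs(rng.standard_normal(500))
        e2 = np.abs(rng.standard_normal(500))
        v = compute_aec(e1, e2)[0]
        assert compute_aec(3.7 * e1, 0.2 * e2)[0] == pytest.approx(v, abs=1e-12)
        assert compute_aec(e2, e1)[0] == pytest.approx(v, abs=1e-12)


class TestAdjacency:
    def test_whole_brain_symmetric_zero_diagonal(self, rng):
        eps = rng.standard_normal((2, 3, 1200))
        m = build_adjacency(eps, "wpli", sfreq=FS, trim_s=0.1)
        assert m.values.shape == (3, 3)
        assert np.allclose(m.values, m.values.T)
        assert np.all(np.diag(m.values) == 0)

    def test_canonical_roi_shape_is_92_by_13(self, rng, node_table):
        seeds = node_table.index[node_table["is_seed"]].tolist()
        eps = rng.standard_normal((1, 92, 600))
        m = build_adjacency(eps, "aec", sfreq=FS, trim_s=0.1, mode="roi", seeds=seeds)
        assert m.values.shape == (92, 13)

    def test_roi_entries_equal_whole_brain_seed_columns(self, rng):
        eps = rng.standard_normal((2, 6, 1200))
        seeds = [1, 4]
        whole = build_adjacency(eps, "aec", sfreq=FS, trim_s=0.1)
        roi = build_adjacency(eps, "aec", sfreq=FS, trim_s=0.1, mode="roi", seeds=seeds)
        assert np.array_equal(roi.values, whole.values[:, seeds])

    def test_unknown_seed_named_in_error(self, rng):
        eps = rng.standard_normal((1, 4, 600))
        with pytest.raises(ValueError, match="7"):
            build_adjacency(eps, "aec", sfreq=FS, mode="roi", seeds=[1, 7])


class TestBaseline:
    def _mat(self, values, condition="familiar"):
        return ConnectivityMatrix(
            values=np.asarray(values, dtype=float), metric="aec", band="alpha",
            condition=condition,
        )

    def test_equal_task_and_rest_give_zero(self):
        m = self._mat([[0.0, 0.3], [0.3, 0.0]])
        r = self._mat([[0.0, 0.3], [0.3, 0.0]], "rest")
        out = average_and_baseline([m], [r])
        assert np.all(out.values == 0)
        assert out.baselined

    def test_trial_average_minus_rest(self):
        t1 = self._mat([[0.0, 0.4], [0.4, 0.0]])
        t2 = self._mat([[0.0, 0.6], [0.6, 0.0]])
        r = self._mat([[0.0, 0.3], [0.3, 0.0]], "rest")
        out = average_and_baseline([t1, t2], [r])
        assert out.values[0, 1] == pytest.approx(0.2)

    def test_linearity_in_scaling(self, rng):
        a = rng.standard_normal((4, 4))
        r = rng.standard_normal((4, 4))
        base = average_and_baseline([self._mat(a)], [self._mat(r, "rest")])
        scaled = average_and_baseline(
            [self._mat(2.5 * a)], [self._mat(2.5 * r, "rest")]
        )
        assert np.allclose(scaled.values, 2.5 * base.values)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            average_and_baseline(
                [self._mat(np.zeros((3, 3)))], [self._mat(np.zeros((4, 4)), "rest")]
            )


def test_wpli_matrix_agrees_with_pairwise_calls(rng):
    Z = rng.standard_normal((4, 800)) + 1j * rng.standard_normal((4, 800))
    M = wpli_matrix(Z)
    for i in range(4):
        for j in range(i + 1, 4):
            assert M[i, j] == pytest.approx(compute_wpli(Z[i], Z[j])[0], abs=1e-12)


def test_aec_matrix_agrees_with_pairwise_calls(rng):
    env = np.abs(rng.standard_normal((4, 800)))
    M = aec_matrix(env)
    for i in range(4):
        for j in range(i + 1, 4):
            assert M[i, j] == pytest.approx(compute_aec(env[i], env[j])[0], abs=1e-10)
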