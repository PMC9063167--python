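"""Synthetic multi-subject MEG-like data with known planted connectivity.

Each parcel carries one unit-variance narrowband oscillation per frequency
band (spectrally synthesized Gaussian noise) on top of 1/f background
noise. Couplings are planted per (band, metric, group, condition):

* phase coupling (wPLI target) — the two parcels share a common narrowband
  signal, the second copy delayed by a quarter period of the band's center
  frequency so the cross-spectrum has a non-zero imaginary part; the shared
  component's amplitude is the effect size (in units of the parcel's own
  band noise SD);
* envelope coupling (AEC target) — the two parcels' band components become
  constant-modulus carriers multiplied by slow (< 1 Hz) positive
  modulators whose shared-variance fraction is solved so the modulator
  correlation equals the effect size.

Zero-lag linear leakage is emulated by pre-multiplying the parcel signals
with a row-normalized near-identity mixing matrix; this is exactly the
kind of mixing the weighted phase lag index must ignore and that
amplitude-envelope correlation without orthogonalization must not.
Everything is bit-reproducible from (config, seed).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.signal import hilbert

from .preprocessing import CANONICAL_BANDS, BandSpec

#: planted-edge key: (band label, metric, group, condition)
EdgeKey = tuple[str, str, str, str]
EdgeList = Sequence[tuple[int, int, float]]

_METRICS = ("aec", "wpli")


def _stable_int(token: str) -> int:
    """Deterministic 32-bit key for seeding derived generators."""
    return zlib.crc32(token.encode("utf8")) & 0x7FFFFFFF


@dataclass
class SimulationConfig:
    """Study-scale defaults for the synthetic cohort.

    Defaults mirror the study conditions: two groups of 24 subjects, 92
    parcels, 600 Hz sampling, 30-s trials, the five-band filterbank, a
    151-sensor forward model, and per-trial head motion drawn log-normally
    with a median near the reported task-run head displacement so that the
    10 mm rejection rule is exercised.
    """

    n_subjects_per_group: int = 24
    n_parcels: int = 92
    sampling_rate_hz: float = 600.0
    trial_duration_s: float = 30.0
    bands: tuple[BandSpec, ...] = CANONICAL_BANDS
    planted_edges: Mapping[EdgeKey, EdgeList] = field(default_factory=dict)
    leakage_mixing_strength: float = 0.1
    envelope_depth: float = 0.3
    #: amplitude of planted envelope-coupled carriers relative to a parcel's
    #: unit-SD band noise; large enough that the modulator dominates the
    #: measured envelope rather than the stochastic background
    aec_carrier_gain: float = 3.0
    noise_sd: float = 1.0
    artifact_components: int = 2
    sensor_count: int = 151
    motion_median_mm: float = 4.5
    motion_sigma: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_parcels < 2:
            raise ValueError("need at least two parcels")
        if self.n_subjects_per_group < 1:
            raise ValueError("need at least one subject per group")
        if not 0.0 <= self.leakage_mixing_strength <= 1.0:
            raise ValueError("leakage_mixing_strength must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.envelope_depth:
            raise ValueError("envelope_depth must be non-negative")
        if self.envelope_depth * 3.0 >= 1.0:
            raise ValueError(
                "envelope_depth would produce non-positive envelopes: modulators "
                "are 1 + depth * l with l clipped to +/-3 SD, so depth must be < 1/3"
            )
        labels = {b.label for b in self.bands}
        for (band, metric, _group, _cond), edges in self.planted_edges.items():
            if band not in labels:
                raise ValueError(f"planted edge references unknown band {band!r}")
            if metric not in _METRICS:
                raise ValueError(f"unknown planted metric {metric!r}")
            for i, j, effect in edges:
                if not (0 <= i < self.n_parcels and 0 <= j < self.n_parcels) or i == j:
                    raise ValueError(f"planted edge ({i},{j}) has invalid node indices")
                if effect < 0:
                    raise ValueError("planted effect sizes must be non-negative")
                if metric == "aec" and effect > 1:
                    raise ValueError("aec effect size is a correlation, must be <= 1")
        # envelope couplings use one shared slow factor per edge; a parcel's
        # modulator mixes the factors of its incident edges, so its summed
        # target correlations must stay within the unit variance budget
        # (equivalently: the requested correlation matrix must be feasible)
        for (band, metric, g, c), edges in self.planted_edges.items():
            if metric != "aec":
                continue
            budget: dict[int, float] = {}
            for i, j, effect in edges:
                budget[i] = budget.get(i, 0.0) + effect
                budget[j] = budget.get(j, 0.0) + effect
            over = {p: b for p, b in budget.items() if b > 1.0 + 1e-9}
            if over:
                raise ValueError(
                    f"planted aec correlations for {(band, g, c)} exceed the "
                    f"feasible per-parcel budget (sum of incident effects > 1): {over}"
                )


@dataclass
class ParcelTimeSeries:
    """Trials x parcels x samples for one subject and one band label."""

    data: np.ndarray
    sfreq: float
    band: str = "broadband"
    subject: str = ""
    group: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_parcels, n_samples)")


@dataclass
class GroundTruth:
    """What the simulator planted, for use as a recovery oracle."""

    planted_edges: dict[EdgeKey, list[tuple[int, int, float]]]
    motion_mm: np.ndarray
    leakage_matrix: np.ndarray
    artifact_loadings: Optional[np.ndarray] = None
    seed_tokens: tuple = ()


# ---------------------------------------------------------------------------
# signal primitives

def narrowband_noise(
    n: int, sfreq: float, lo: float, hi: float, rng: np.random.Generator,
    taper_hz: float = 0.5,
) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [lo, hi] Hz.

    Spectral synthesis: white Gaussian noise is shaped in the frequency
    domain by a flat window with raised-cosine tapers of ``taper_hz``.
    """
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    spec = np.fft.rfft(rng.standard_normal(n))
    win = np.zeros_like(freqs)
    core = (freqs >= lo) & (freqs <= hi)
    win[core] = 1.0
    for edge, sign in ((lo, -1), (hi, +1)):
        ramp = (freqs - edge) * sign
        sel = (ramp > -taper_hz) & (ramp <= 0)
        win[sel] = 0.5 * (1 + np.cos(np.pi * ramp[sel] / taper_hz))
    x = np.fft.irfft(spec * win, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def pink_noise(n: int, rng: np.random.Generator, f_floor_hz: float = 1.0,
               sfreq: float = 600.0) -> np.ndarray:
    """Unit-variance 1/f background noise (flat below ``f_floor_hz``)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    spec = np.fft.rfft(rng.standard_normal(n))
    amp = 1.0 / np.sqrt(np.maximum(freqs, f_floor_hz))
    amp[0] = 0.0
    x = np.fft.irfft(spec * amp, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def constant_modulus_carrier(
    n: int, sfreq: float, lo: float, hi: float, rng: np.random.Generator,
    drift_hz: float = 0.4, drift_rad: float = 1.5,
) -> np.ndarray:
    """In-band carrier with a flat envelope: a tone with slow phase drift.

    ``sqrt(2) cos(2 pi f0 t + theta(t))`` with center frequency ``f0`` and a
    slow (< ``drift_hz``) random phase walk of SD ``drift_rad``. Its
    spectrum stays well inside [lo, hi], so the Hilbert envelope remains
    essentially flat even after band-pass filtering — a multiplicative
    slow modulator is then recovered as the envelope, undiluted by carrier
    envelope fluctuations. The drift decorrelates carriers of different
    parcels and trials.
    """
    f0 = 0.5 * (lo + hi)
    t = np.arange(n) / sfreq
    theta = drift_rad * narrowband_noise(n, sfreq, 0.02, drift_hz, rng, taper_hz=0.02)
    phi0 = rng.uniform(0, 2 * np.pi)
    return np.sqrt(2.0) * np.cos(2 * np.pi * f0 * t + theta + phi0)


def lowpass_standardized(
    n: int, sfreq: float, rng: np.random.Generator, cutoff_hz: float = 0.8
) -> np.ndarray:
    """Unit-variance slow (< 1 Hz) noise for envelope modulators."""
    return narrowband_noise(n, sfreq, 0.02, cutoff_hz, rng, taper_hz=0.02)


def lowpass_modulators(
    n: int,
    sfreq: float,
    rho: float,
    depth: float,
    rng: np.random.Generator,
    cutoff_hz: float = 0.8,
) -> tuple[np.ndarray, np.ndarray]:
    """Two positive slow modulators whose correlation equals ``rho``.

    Each is ``1 + depth * l`` with ``l`` standardized low-pass (< 1 Hz)
    noise built as sqrt(rho) * shared + sqrt(1-rho) * private, clipped at
    +/- 3 SD to guarantee positivity for depth < 1/3.
    """
    g = lowpass_standardized(n, sfreq, rng, cutoff_hz)
    h1 = lowpass_standardized(n, sfreq, rng, cutoff_hz)
    h2 = lowpass_standardized(n, sfreq, rng, cutoff_hz)
    l1 = np.clip(np.sqrt(rho) * g + np.sqrt(1 - rho) * h1, -3.0, 3.0)
    l2 = np.clip(np.sqrt(rho) * g + np.sqrt(1 - rho) * h2, -3.0, 3.0)
    return 1.0 + depth * l1, 1.0 + depth * l2


# ---------------------------------------------------------------------------
# subject-level simulation

def leakage_matrix(
    n_parcels: int, strength: float, rng: np.random.Generator
) -> np.ndarray:
    """Row-normalized near-identity mixing matrix emulating field spread."""
    if strength == 0:
        return np.eye(n_parcels)
    pert = rng.standard_normal((n_parcels, n_parcels))
    pert = (pert + pert.T) / 2.0
    np.fill_diagonal(pert, 0.0)
    M = np.eye(n_parcels) + strength * pert / np.sqrt(n_parcels)
    return M / np.linalg.norm(M, axis=1, keepdims=True)


def simulate_subject_timeseries(
    config: SimulationConfig,
    subject_id: str,
    group: str,
    condition: str,
    n_trials: int,
) -> tuple[ParcelTimeSeries, GroundTruth]:
    """Simulate parcel-space trials for one subject, group and condition.

    Deterministic given (config.seed, subject_id, group, condition): the
    same call always returns bit-identical data.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    config.validate()
    fs = config.sampling_rate_hz
    n = int(round(config.trial_duration_s * fs))
    p = config.n_parcels
    tokens = (config.seed, _stable_int(subject_id), _stable_int(group),
              _stable_int(condition))
    rng = np.random.default_rng(tokens)
    leak_rng = np.random.default_rng((config.seed, _stable_int(subject_id),
                                      _stable_int("leakage")))
    M = leakage_matrix(p, config.leakage_mixing_strength, leak_rng)

    planted: dict[EdgeKey, list[tuple[int, int, float]]] = {}
    for key, edges in config.planted_edges.items():
        band, metric, g, c = key
        if g == group and c == condition:
            planted[key] = [tuple(e) for e in edges]

    data = np.empty((n_trials, p, n))
    for trial in range(n_trials):
        X = np.vstack([config.noise_sd * pink_noise(n, rng, sfreq=fs) for _ in range(p)])
        for band in config.bands:
            f0 = 0.5 * (band.lo + band.hi)
            aec_edges = planted.get((band.label, "aec", group, condition), [])
            aec_parcels: dict[int, np.ndarray] = {}
            if aec_edges:
                # one shared slow factor per planted edge; each parcel mixes
                # sqrt(rho_e) of every incident edge's factor plus a private
                # remainder, so each pair meets its target correlation
                factors = [lowpass_standardized(n, fs, rng) for _ in aec_edges]
                incident: dict[int, list[tuple[int, float]]] = {}
                for k, (i, j, rho) in enumerate(aec_edges):
                    incident.setdefault(i, []).append((k, rho))
                    incident.setdefault(j, []).append((k, rho))
                for parcel in sorted(incident):
                    inc = incident[parcel]
                    shared = sum(np.sqrt(r) * factors[k] for k, r in inc)
                    rest = max(0.0, 1.0 - sum(r for _, r in inc))
                    l = shared + np.sqrt(rest) * lowpass_standardized(n, fs, rng)
                    modulator = 1.0 + config.envelope_depth * np.clip(l, -3.0, 3.0)
                    carrier = constant_modulus_carrier(n, fs, band.lo, band.hi, rng)
                    aec_parcels[parcel] = config.aec_carrier_gain * modulator * carrier
            comp = np.empty((p, n))
            for parcel in range(p):
                if parcel in aec_parcels:
                    comp[parcel] = aec_parcels[parcel]
                else:
                    comp[parcel] = narrowband_noise(n, fs, band.lo, band.hi, rng)
            X += comp
            for i, j, effect in planted.get((band.label, "wpli", group, condition), []):
                if effect == 0:
                    continue
                s = narrowband_noise(n, fs, band.lo, band.hi, rng)
                delay = max(1, int(round(fs / (4.0 * f0))))
                X[i] += effect * s
                X[j] += effect * np.roll(s, delay)
        data[trial] = M @ X

    motion = np.exp(
        np.log(config.motion_median_mm)
        + config.motion_sigma * rng.standard_normal(n_trials)
    )
    ts = ParcelTimeSeries(
        data=data, sfreq=fs, band="broadband",
        subject=subject_id, group=group, condition=condition,
    )
    truth = GroundTruth(
        planted_edges=planted, motion_mm=motion, leakage_matrix=M,
        seed_tokens=tokens,
    )
    return ts, truth


# ---------------------------------------------------------------------------
# synthetic forward model and artifacts

def make_leadfield(
    n_sensors: int, n_parcels: int, rng: np.random.Generator,
    kind: str = "gaussian",
) -> np.ndarray:
    """Random full-column-rank synthetic leadfield (sensors x parcels)."""
    if n_sensors < n_parcels:
        raise ValueError("sensor_count must be >= n_parcels for full column rank")
    if kind == "identity":
        L = np.zeros((n_sensors, n_parcels))
        L[:n_parcels, :n_parcels] = np.eye(n_parcels)
        return L
    if kind == "orthonormal":
        q, _ = np.linalg.qr(rng.standard_normal((n_sensors, n_parcels)))
        return q
    return rng.standard_normal((n_sensors, n_parcels)) / np.sqrt(n_sensors)


def make_artifact_signals(
    n_trials: int, n_samples: int, sfreq: float, n_components: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Cardiac- and ocular-like reference traces, (n_trials, k, n_samples).

    Odd components are ECG-like quasi-periodic spike trains (~1.2 Hz), even
    components EOG-like sparse smooth blinks; amplitudes are large relative
    to unit-variance brain signals, as real artifacts are.
    """
    t = np.arange(n_samples) / sfreq
    out = np.zeros((n_trials, n_components, n_samples))
    for trial in range(n_trials):
        for k in range(n_components):
            x = np.zeros(n_samples)
            if k % 2 == 0:  # cardiac-like
                period = 1.0 / (1.2 + 0.1 * rng.standard_normal())
                beat = period * (1 + 0.02 * rng.standard_normal(int(t[-1] / period) + 2))
                times = np.cumsum(beat)
                width = 0.04
                for bt in times[times < t[-1]]:
                    x += 5.0 * np.exp(-0.5 * ((t - bt) / width) ** 2)
            else:  # ocular-like blinks
                n_blinks = rng.poisson(0.25 * t[-1]) + 1
                for bt in rng.uniform(0, t[-1], size=n_blinks):
                    x += 8.0 * np.exp(-0.5 * ((t - bt) / 0.15) ** 2)
            out[trial, k] = x - x.mean()
    return out


def project_to_sensors(
    source: ParcelTimeSeries,
    leadfield: np.ndarray,
    artifact_loadings: Optional[np.ndarray] = None,
    artifact_signals: Optional[np.ndarray] = None,
    noise_sd: float = 0.0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, Optional[np.ndarray]]:
    """Forward-project parcel trials to synthetic sensors.

    ``sensors = leadfield @ sources + loadings @ artifacts + white noise``.
    Returns the sensor array (n_trials, n_sensors, n_samples) and the
    artifact reference traces (or None), for downstream ICA cleaning.
    """
    L = np.asarray(leadfield, dtype=float)
    n_trials, p, n = source.data.shape
    if L.shape[1] != p:
        raise ValueError("leadfield column count does not match parcels")
    if np.linalg.matrix_rank(L) < p:
        raise ValueError(
            "leadfield is rank deficient; regularize it or reduce parcel count"
        )
    sensors = np.einsum("sp,kpn->ksn", L, source.data)
    refs = None
    if artifact_loadings is not None:
        A = np.asarray(artifact_loadings, dtype=float)
        if artifact_signals is None:
            raise ValueError("artifact loadings given without artifact signals")
        refs = np.asarray(artifact_signals, dtype=float)
        if refs.shape[:2] != (n_trials, A.shape[1]):
            raise ValueError("artifact signals do not match loadings/trials")
        sensors = sensors + np.einsum("sk,tkn->tsn", A, refs)
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng(0)
        sensors = sensors + noise_sd * rng.standard_normal(sensors.shape)
    return sensors, refs
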