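"""Within-trial AEC and wPLI connectivity, trial averaging, rest baselining.

For each band-limited epoch the Hilbert transform yields the analytic
signal, whose magnitude is the instantaneous amplitude envelope and whose
angle is the instantaneous phase. From these:

* weighted phase lag index (wPLI) — with per-sample cross-spectral terms
  ``S(t) = z_A(t) conj(z_B(t))``, ``wPLI = |sum Im S| / sum |Im S|``; it
  weights each sample by the magnitude of its imaginary part, so
  zero-lag (leakage) coupling, which is purely real, contributes nothing;
* amplitude envelope correlation (AEC) — the Pearson correlation over time
  of the two envelopes, computed on leakage-orthogonalized signals.

Both are computed within each 10-s epoch, averaged over a trial's epochs,
then over a condition's trials, and finally baselined by subtracting the
average over resting-state epochs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.signal import hilbert


@dataclass
class AnalyticSignal:
    """Envelope, phase and the complex analytic signal per channel/epoch."""

    envelope: np.ndarray
    phase: np.ndarray
    z: np.ndarray
    degenerate: np.ndarray  # True where the input was identically zero

    @property
    def n_samples(self) -> int:
        return self.z.shape[-1]


def analytic_signal(
    x: np.ndarray, sfreq: Optional[float] = None, trim_s: float = 0.0
) -> AnalyticSignal:
    """Hilbert analytic extension of a band-limited epoch.

    ``trim_s`` seconds are dropped from each end (filter/Hilbert edge
    effects); requires ``sfreq`` when non-zero. Identically zero channels
    get a zero envelope and are flagged degenerate (their phase is
    undefined).
    """
    x = np.asarray(x, dtype=float)
    z = hilbert(x, axis=-1)
    if trim_s:
        if sfreq is None:
            raise ValueError("sfreq is required when trim_s > 0")
        k = int(round(trim_s * sfreq))
        if 2 * k >= x.shape[-1]:
            raise ValueError("trim longer than the epoch")
        if k:
            z = z[..., k:-k]
    env = np.abs(z)
    degenerate = np.all(env == 0, axis=-1)
    return AnalyticSignal(envelope=env, phase=np.angle(z), z=z, degenerate=degenerate)


def compute_wpli(zA: np.ndarray, zB: np.ndarray) -> tuple[float, bool]:
    """Weighted phase lag index of two analytic signals over one epoch.

    Returns ``(wpli, degenerate)``; a degenerate epoch (identically zero
    imaginary cross-spectrum, e.g. exactly zero-lag identical signals)
    yields 0.0 with the flag set.
    """
    zA = np.asarray(zA)
    zB = np.asarray(zB)
    if zA.shape != zB.shape:
        raise ValueError("epochs must have equal length")
    im = np.imag(zA * np.conj(zB))
    den = np.sum(np.abs(im))
    # an imaginary part at rounding-noise level (e.g. zero-lag identical
    # signals) carries no phase-lag information: flag it degenerate
    floor = 1e-12 * np.sum(np.abs(zA) * np.abs(zB))
    if den <= floor:
        return 0.0, True
    return float(np.abs(np.sum(im)) / den), False


def compute_aec(envA: np.ndarray, envB: np.ndarray) -> tuple[float, bool]:
    """Pearson correlation of two amplitude envelopes over one epoch.

    A zero-variance envelope makes the correlation undefined: NaN is
    returned with the flag set so the caller can exclude the epoch from
    trial averages.
    """
    envA = np.asarray(envA, dtype=float)
    envB = np.asarray(envB, dtype=float)
    if envA.shape != envB.shape:
        raise ValueError("envelopes must have equal length")
    a = envA - envA.mean()
    b = envB - envB.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        return float("nan"), True
    return float(np.dot(a, b) / (na * nb)), False


def wpli_matrix(Z: np.ndarray) -> np.ndarray:
    """All-pairs wPLI from analytic signals (n_parcels, n_samples).

    Degenerate pairs (zero imaginary cross-spectrum throughout) get 0.
    The diagonal is zero by convention.
    """
    p = Z.shape[0]
    mag = np.abs(Z)
    out = np.zeros((p, p))
    for i in range(p - 1):
        cross = Z[i][None, :] * np.conj(Z[i + 1 :])
        im = np.imag(cross)
        num = np.abs(im.sum(axis=1))
        den = np.abs(im).sum(axis=1)
        floor = 1e-12 * (mag[i][None, :] * mag[i + 1 :]).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(den > floor, num / den, 0.0)
        out[i, i + 1 :] = vals
        out[i + 1 :, i] = vals
    return out


def aec_matrix(env: np.ndarray) -> np.ndarray:
    """All-pairs envelope correlation from (n_parcels, n_samples) envelopes.

    Zero-variance parcels produce NaN rows/columns (excluded later from
    trial averages); the diagonal is zero.
    """
    env = np.asarray(env, dtype=float)
    centered = env - env.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = centered / norms[:, None]
    out = unit @ unit.T
    out[norms == 0, :] = np.nan
    out[:, norms == 0] = np.nan
    np.fill_diagonal(out, 0.0)
    return np.clip(out, -1.0, 1.0, out=out)


@dataclass
class ConnectivityMatrix:
    """An edge-weight matrix tagged with its provenance.

    ``values`` is parcels x parcels (whole_brain mode, symmetric, zero
    diagonal) or parcels x seeds (roi mode, columns ordered as ``seeds``).
    """

    values: np.ndarray
    metric: str  # "aec" | "wpli"
    band: str = ""
    condition: str = ""
    baselined: bool = False
    subject: str = ""
    mode: str = "whole_brain"
    seeds: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.metric not in ("aec", "wpli"):
            raise ValueError(f"unknown metric {self.metric!r}")
        if self.mode not in ("whole_brain", "roi"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "roi":
            if self.seeds is None:
                raise ValueError("roi mode requires the seed list")
            if self.values.shape[1] != len(self.seeds):
                raise ValueError("roi matrix columns must match the seed list")


def build_adjacency(
    epochs: np.ndarray,
    metric: str,
    sfreq: Optional[float] = None,
    trim_s: float = 1.0,
    mode: str = "whole_brain",
    seeds: Optional[Sequence[int]] = None,
    precomputed_analytic: bool = False,
    **tags,
) -> ConnectivityMatrix:
    """Per-trial adjacency: per-epoch matrices averaged over the trial's epochs.

    Parameters
    ----------
    epochs : array, shape (n_epochs, n_parcels, n_samples)
        Band-limited epochs of one trial (real), or analytic signals
        (complex) when ``precomputed_analytic``. For AEC the caller must
        supply leakage-orthogonalized signals.
    metric : "aec" or "wpli"
    mode : "whole_brain" (parcels x parcels) or "roi" (parcels x seeds)
    seeds : parcel indices for roi mode; the roi matrix equals the
        corresponding whole-brain columns exactly.
    trim_s : seconds discarded from each epoch end before estimation.
    """
    epochs = np.asarray(epochs)
    if epochs.ndim != 3:
        raise ValueError("epochs must be (n_epochs, n_parcels, n_samples)")
    p = epochs.shape[1]
    if mode == "roi":
        if seeds is None or len(seeds) == 0:
            raise ValueError("roi mode requires a non-empty seed list")
        for s in seeds:
            if not 0 <= s < p:
                raise ValueError(f"unknown seed id {s}")
    per_epoch = []
    for ep in epochs:
        if precomputed_analytic:
            z = ep
            env = np.abs(ep)
        else:
            sig = analytic_signal(np.real(ep), sfreq=sfreq, trim_s=trim_s)
            z, env = sig.z, sig.envelope
        if metric == "wpli":
            per_epoch.append(wpli_matrix(z))
        elif metric == "aec":
            per_epoch.append(aec_matrix(env))
        else:
            raise ValueError(f"unknown metric {metric!r}")
    stack = np.stack(per_epoch)
    with np.errstate(invalid="ignore"):
        values = np.nanmean(stack, axis=0)
    values = np.nan_to_num(values, nan=0.0)
    if mode == "roi":
        values = values[:, list(seeds)]
    return ConnectivityMatrix(
        values=values, metric=metric, mode=mode,
        seeds=tuple(seeds) if seeds is not None else None,
        **tags,
    )


def average_and_baseline(
    trial_matrices: Sequence[ConnectivityMatrix],
    rest_matrices: Sequence[ConnectivityMatrix],
) -> ConnectivityMatrix:
    """Elementwise trial average minus elementwise resting average.

    All matrices must share shape, metric and band; the result is tagged
    ``baselined`` and keeps the task matrices' condition label.
    """
    if len(trial_matrices) < 1 or len(rest_matrices) < 1:
        raise ValueError("need at least one task and one rest matrix")
    ref = trial_matrices[0]
    for m in list(trial_matrices) + list(rest_matrices):
        if m.values.shape != ref.values.shape:
            raise ValueError("matrix shape mismatch")
        if m.metric != ref.metric or m.band != ref.band:
            raise ValueError("metric/band mismatch")
    task = np.mean([m.values for m in trial_matrices], axis=0)
    rest = np.mean([m.values for m in rest_matrices], axis=0)
    return ConnectivityMatrix(
        values=task - rest,
        metric=ref.metric,
        band=ref.band,
        condition=ref.condition,
        baselined=True,
        subject=ref.subject,
        mode=ref.mode,
        seeds=ref.seeds,
    )
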