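"""Trial epoching, motion and trial-count QC, artifact removal, filterbank.

Continuous 30-s music trials are epoched into non-overlapping 10-s chunks;
trials with more than 10 mm of head motion are rejected; subjects need at
least three trials per (response-labelled) condition to stay in the
analysis; and the data are split into five canonical narrow bands with a
zero-phase (two-pass) FIR filterbank after a 60 Hz power-line notch.
Ocular/cardiac artifact components are identified by ICA and removed by an
automated correlation criterion against artifact reference channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal


class BandSpec(NamedTuple):
    """A named frequency band in Hz."""

    label: str
    lo: float
    hi: float


#: The canonical five-band filterbank.
CANONICAL_BANDS: tuple[BandSpec, ...] = (
    BandSpec("theta", 4.0, 7.0),
    BandSpec("alpha", 8.0, 14.0),
    BandSpec("beta", 15.0, 29.0),
    BandSpec("gamma1", 30.0, 55.0),
    BandSpec("gamma2", 65.0, 80.0),
)

#: Head-motion rejection threshold (mm); trials strictly above are dropped.
MOTION_THRESHOLD_MM = 10.0

#: Minimum number of trials per condition for a subject to be analysed.
MIN_TRIALS_PER_CONDITION = 3


@dataclass
class QCReport:
    """Per-subject bookkeeping of dropped trials and removed components."""

    kept: dict[str, int] = field(default_factory=dict)
    dropped_motion: dict[str, int] = field(default_factory=dict)
    excluded_subjects: list[str] = field(default_factory=list)
    condition_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    components_removed: dict[str, int] = field(default_factory=dict)


def epoch_trials(x: np.ndarray, sfreq: float, epoch_s: float) -> np.ndarray:
    """Cut one continuous trial into consecutive non-overlapping epochs.

    Parameters
    ----------
    x : array, shape (..., n_samples)
        Single- or multi-channel trial segment, time on the last axis.
    sfreq : float
        Sampling rate in Hz.
    epoch_s : float
        Epoch duration in seconds.

    Returns
    -------
    array, shape (n_epochs, ..., epoch_samples)
        A trailing remainder shorter than one epoch is discarded.
    """
    x = np.asarray(x)
    ep = int(round(epoch_s * sfreq))
    if ep <= 0:
        raise ValueError("epoch duration must be positive")
    n = x.shape[-1]
    if n < ep:
        raise ValueError(
            f"trial of {n} samples is shorter than one epoch of {ep} samples"
        )
    n_epochs = n // ep
    trimmed = x[..., : n_epochs * ep]
    split = trimmed.reshape(x.shape[:-1] + (n_epochs, ep))
    return np.moveaxis(split, -2, 0)


def reject_motion_trials(
    manifest: pd.DataFrame, threshold_mm: float = MOTION_THRESHOLD_MM
) -> tuple[pd.DataFrame, QCReport]:
    """Drop trials whose head motion strictly exceeds the threshold.

    Motion is the per-trial maximum head displacement in mm recorded in the
    manifest's ``motion_mm`` column; a trial at exactly the threshold is kept.
    """
    if "motion_mm" not in manifest.columns:
        raise ValueError("manifest has no motion_mm column")
    missing = manifest[manifest["motion_mm"].isna()]
    if len(missing):
        t = missing.iloc[0]
        raise ValueError(
            f"missing motion value for subject {t['subject']} trial {t['trial']}"
        )
    keep = manifest["motion_mm"] <= threshold_mm
    report = QCReport()
    for subject, grp in manifest.groupby("subject", sort=True):
        k = keep.loc[grp.index]
        report.kept[str(subject)] = int(k.sum())
        report.dropped_motion[str(subject)] = int((~k).sum())
    return manifest[keep].copy(), report


def qc_min_trials(
    manifest: pd.DataFrame, min_trials: int = MIN_TRIALS_PER_CONDITION
) -> tuple[list[str], QCReport]:
    """List subjects with at least ``min_trials`` music trials per condition.

    Conditions are the response-derived familiar/unfamiliar labels (liked and
    disliked are already collapsed); resting records are ignored. The result
    is independent of manifest row order.
    """
    music = manifest[~manifest["is_rest"].astype(bool)]
    report = QCReport()
    included = []
    for subject in sorted(manifest["subject"].unique()):
        rows = music[music["subject"] == subject]
        counts = {
            cond: int((rows["condition_response"] == cond).sum())
            for cond in ("familiar", "unfamiliar")
        }
        report.condition_counts[str(subject)] = counts
        if all(c >= min_trials for c in counts.values()):
            included.append(str(subject))
        else:
            report.excluded_subjects.append(str(subject))
    return included, report


def design_bandpass(
    lo: float, hi: float, sfreq: float, transition_hz: Optional[float] = None
) -> np.ndarray:
    """Design a linear-phase FIR band-pass (Hamming window).

    The filter length follows from the transition width (default
    ``min(2 Hz, lo/2)``), narrow enough that each canonical band's passband
    is flat over its interior and the two-pass stopband is deep within 1 Hz
    of the band edges.
    """
    nyq = sfreq / 2.0
    if not 0 < lo < hi < nyq:
        raise ValueError(f"band edges ({lo}, {hi}) must satisfy 0 < lo < hi < {nyq}")
    if transition_hz is None:
        transition_hz = min(2.0, lo / 2.0)
    numtaps = int(np.ceil(3.3 * sfreq / transition_hz))
    numtaps += 1 - numtaps % 2  # odd length, symmetric, integer group delay
    return signal.firwin(numtaps, [lo, hi], pass_zero=False, fs=sfreq, window="hamming")


def _filtfilt(taps: np.ndarray, x: np.ndarray) -> np.ndarray:
    padlen = min(3 * len(taps), x.shape[-1] - 1)
    return signal.filtfilt(taps, 1.0, x, axis=-1, padlen=padlen)


def notch_filter(x: np.ndarray, sfreq: float, notch_hz: float = 60.0, q: float = 30.0) -> np.ndarray:
    """Zero-phase IIR notch at the power-line frequency."""
    if not 0 < notch_hz < sfreq / 2:
        raise ValueError("notch frequency must lie below Nyquist")
    b, a = signal.iirnotch(notch_hz, q, fs=sfreq)
    padlen = min(3 * max(len(a), len(b)), x.shape[-1] - 1)
    return signal.filtfilt(b, a, x, axis=-1, padlen=padlen)


def bandpass_filterbank(
    x: np.ndarray,
    sfreq: float,
    bands: Sequence[BandSpec] = CANONICAL_BANDS,
    notch_hz: Optional[float] = 60.0,
) -> dict[str, np.ndarray]:
    """Split a broadband signal into zero-phase band-limited copies.

    The 60 Hz notch is applied once before band splitting; each band is then
    filtered forward and backward with its FIR kernel, so group delay is
    fully compensated and output length equals input length.
    """
    x = np.asarray(x, dtype=float)
    for band in bands:
        if band.hi >= sfreq / 2:
            raise ValueError(f"band {band.label} upper edge {band.hi} Hz >= Nyquist")
    if notch_hz is not None and notch_hz < sfreq / 2:
        x = notch_filter(x, sfreq, notch_hz)
    out = {}
    for band in bands:
        taps = design_bandpass(band.lo, band.hi, sfreq)
        out[band.label] = _filtfilt(taps, x)
    return out


def remove_artifact_components(
    epochs: np.ndarray,
    references: np.ndarray,
    max_components: int = 60,
    r_threshold: float = 0.4,
    random_state: int = 0,
) -> tuple[np.ndarray, QCReport]:
    """Estimate ICA components and zero those correlated with artifact references.

    Parameters
    ----------
    epochs : array, shape (n_epochs, n_sensors, n_samples)
        Sensor-space data for one subject; epochs are concatenated in time
        for the decomposition.
    references : array, shape (n_refs, n_epochs * n_samples) or (n_epochs, n_refs, n_samples)
        Artifact reference time series (e.g. simulated ocular/cardiac
        traces), time-aligned with the epochs.
    max_components : int
        Cap on the number of components considered for removal (the study
        inspected at most 60 per participant).
    r_threshold : float
        Components with absolute Pearson correlation above this value
        against any reference are removed.

    Returns
    -------
    cleaned : array, same shape as ``epochs``
    report : QCReport with ``components_removed['n']`` set.
    """
    from sklearn.decomposition import FastICA

    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 3:
        raise ValueError("epochs must be (n_epochs, n_sensors, n_samples)")
    n_ep, n_sens, n_samp = epochs.shape
    if n_sens < 2:
        raise ValueError("need at least two sensors for a decomposition")
    refs = np.asarray(references, dtype=float)
    if refs.ndim == 3:
        refs = np.moveaxis(refs, 1, 0).reshape(refs.shape[1], -1)
    if refs.shape[-1] != n_ep * n_samp:
        raise ValueError("references are not time-aligned with the epochs")
    if not 0.0 <= r_threshold <= 1.0:
        raise ValueError("r_threshold must be in [0, 1]")

    x = np.moveaxis(epochs, 0, 1).reshape(n_sens, n_ep * n_samp)
    mean = x.mean(axis=1, keepdims=True)
    n_comp = min(n_sens, max(2, max_components))
    ica = FastICA(
        n_components=n_comp, whiten="unit-variance", random_state=random_state,
        max_iter=1000, tol=1e-4,
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sources = ica.fit_transform((x - mean).T).T  # (n_comp, T)
    except np.linalg.LinAlgError as err:  # pragma: no cover - rare
        cond = np.linalg.cond(np.cov(x))
        raise RuntimeError(
            f"ICA decomposition failed (sensor covariance condition number {cond:.3g})"
        ) from err

    sd_s = sources.std(axis=1)
    sd_r = refs.std(axis=1)
    corr = np.zeros((sources.shape[0], refs.shape[0]))
    valid = np.outer(sd_s > 0, sd_r > 0)
    centered_s = sources - sources.mean(axis=1, keepdims=True)
    centered_r = refs - refs.mean(axis=1, keepdims=True)
    num = centered_s @ centered_r.T / sources.shape[1]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(valid, num / np.outer(sd_s, sd_r), 0.0)

    flagged = np.where(np.max(np.abs(corr), axis=1) > r_threshold)[0]
    # strongest correlations first if more than the removal cap
    flagged = flagged[np.argsort(-np.max(np.abs(corr[flagged]), axis=1))][:max_components]

    sources_clean = sources.copy()
    sources_clean[flagged] = 0.0
    x_clean = ica.mixing_ @ sources_clean + mean
    cleaned = np.moveaxis(x_clean.reshape(n_sens, n_ep, n_samp), 1, 0)

    report = QCReport(components_removed={"n": int(len(flagged))})
    return cleaned, report
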