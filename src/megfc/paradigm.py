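"""Experimental paradigm: stimulus matching and trial-manifest construction.

The listening task presents, per participant, 8 familiar liked (FL), 8
familiar disliked (FD) and 24 unfamiliar (UF) 30-s music excerpts across
four task runs of ten excerpts each, bracketed by two resting-state runs.
Familiar excerpts are matched one-to-one with unfamiliar ones on tempo
class, mode, genre, presence of lyrics and (when sung) lyric language.
The familiarity label actually analysed is the participant's in-scanner
response, which may disagree with the pre-selected stimulus label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: Admissible tempo range in beats per minute.
TEMPO_RANGE = (40.0, 208.0)

#: Tempo class boundaries, half-open [lo, hi) with the top bin closed at 208.
TEMPO_BINS = {
    "slow": (40.0, 72.0),
    "moderate": (72.0, 120.0),
    "fast": (120.0, 208.0),
}

MANIFEST_COLUMNS = [
    "subject",
    "group",
    "run",
    "trial",
    "stimulus",
    "condition_stimulus",
    "liking",
    "condition_response",
    "duration_s",
    "is_rest",
    "motion_mm",
]


def classify_tempo(tempo_bpm: float) -> str:
    """Assign a tempo in bpm to the slow / moderate / fast class.

    Bins are half-open on the left, so the shared printed boundaries (72 and
    120 bpm) belong to the upper class; 208 bpm closes the fast bin.
    """
    lo, hi = TEMPO_RANGE
    if not np.isfinite(tempo_bpm) or tempo_bpm < lo or tempo_bpm > hi:
        raise ValueError(
            f"tempo {tempo_bpm!r} bpm outside the admissible interval "
            f"[{lo:g}, {hi:g}] bpm"
        )
    if tempo_bpm < TEMPO_BINS["slow"][1]:
        return "slow"
    if tempo_bpm < TEMPO_BINS["moderate"][1]:
        return "moderate"
    return "fast"


@dataclass(frozen=True)
class StimulusRecord:
    """One music excerpt and the features used for familiar/unfamiliar matching."""

    id: str
    familiarity: str  # "familiar" | "unfamiliar"
    tempo_bpm: float
    mode: str  # "major" | "minor"
    genre: str
    has_lyrics: bool
    language: Optional[str] = None
    liking: str = "n/a"  # "liked" | "disliked" | "n/a"

    def __post_init__(self) -> None:
        if self.familiarity not in ("familiar", "unfamiliar"):
            raise ValueError(f"unknown familiarity {self.familiarity!r}")
        if self.liking not in ("liked", "disliked", "n/a"):
            raise ValueError(f"unknown liking {self.liking!r}")
        classify_tempo(self.tempo_bpm)  # range check
        if self.has_lyrics and self.language is None:
            raise ValueError(f"stimulus {self.id}: lyrics present but no language")

    @property
    def tempo_class(self) -> str:
        return classify_tempo(self.tempo_bpm)


@dataclass
class MatchReport:
    """Outcome of greedy familiar/unfamiliar matching."""

    pairs: list[tuple[str, str]] = field(default_factory=list)
    unmatched: list[str] = field(default_factory=list)


def _compatible(a: StimulusRecord, b: StimulusRecord) -> bool:
    if (
        a.tempo_class != b.tempo_class
        or a.mode != b.mode
        or a.genre != b.genre
        or a.has_lyrics != b.has_lyrics
    ):
        return False
    if a.has_lyrics and a.language != b.language:
        return False
    return True


def match_stimuli(
    familiar: Sequence[StimulusRecord], pool: Sequence[StimulusRecord]
) -> MatchReport:
    """Pair each familiar song with a distinct unfamiliar song of equal features.

    Matching is greedy first-fit in input order (both for the familiar list and
    the candidate pool); a familiar song with no remaining feature-compatible
    candidate is reported as unmatched rather than raising.
    """
    if len(pool) == 0:
        raise ValueError("unfamiliar candidate pool is empty")
    for s in pool:
        if s.familiarity != "unfamiliar":
            raise ValueError(f"pool entry {s.id} is not unfamiliar")
    report = MatchReport()
    used: set[str] = set()
    for fam in familiar:
        chosen = None
        for cand in pool:
            if cand.id in used:
                continue
            if _compatible(fam, cand):
                chosen = cand
                break
        if chosen is None:
            report.unmatched.append(fam.id)
        else:
            used.add(chosen.id)
            report.pairs.append((fam.id, chosen.id))
    return report


@dataclass(frozen=True)
class ParadigmSpec:
    """Counts and timing of the music-listening task.

    Defaults reproduce the study paradigm: 8 + 8 + 24 excerpts over 4 task
    runs of 10, 30-s trials sampled at 600 Hz, and two 3-min resting runs.
    """

    n_familiar_liked: int = 8
    n_familiar_disliked: int = 8
    n_unfamiliar: int = 24
    n_task_runs: int = 4
    excerpts_per_run: int = 10
    trial_duration_s: float = 30.0
    rest_duration_s: float = 180.0
    sampling_rate_hz: float = 600.0

    def __post_init__(self) -> None:
        counts = (
            self.n_familiar_liked,
            self.n_familiar_disliked,
            self.n_unfamiliar,
            self.n_task_runs,
            self.excerpts_per_run,
        )
        if any(c <= 0 for c in counts[3:]) or any(c < 0 for c in counts[:3]):
            raise ValueError("paradigm counts must be positive")
        total = self.n_familiar_liked + self.n_familiar_disliked + self.n_unfamiliar
        if total != self.n_task_runs * self.excerpts_per_run:
            raise ValueError(
                f"excerpt counts {total} != runs x per-run "
                f"({self.n_task_runs} x {self.excerpts_per_run})"
            )
        if self.trial_duration_s <= 0 or self.rest_duration_s <= 0:
            raise ValueError("durations must be positive")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_music_trials(self) -> int:
        return self.n_task_runs * self.excerpts_per_run


def build_paradigm(
    spec: ParadigmSpec,
    subject: str = "sub01",
    group: str = "TD",
    rng: Optional[np.random.Generator] = None,
    response_disagreement_rate: float = 0.0,
) -> pd.DataFrame:
    """Build the per-subject trial manifest for one session.

    Returns a DataFrame with one row per music trial plus two resting-state
    records (runs 0 and ``n_task_runs + 1``). ``condition_stimulus`` is the
    pre-selected familiarity label; ``condition_response`` is the in-scanner
    familiarity rating used in all downstream analyses. With a non-zero
    ``response_disagreement_rate`` each music trial's response label flips
    with that probability (requires ``rng``); liked/disliked labels are kept
    in the manifest but analyses collapse them into familiar/unfamiliar.
    Stimulus-to-run assignment is a shuffle when ``rng`` is given, otherwise
    a deterministic interleave. Motion magnitudes are filled downstream.
    """
    if not 0.0 <= response_disagreement_rate <= 1.0:
        raise ValueError("response_disagreement_rate must be in [0, 1]")
    if response_disagreement_rate > 0 and rng is None:
        raise ValueError("a random generator is required to simulate disagreement")

    stimuli: list[tuple[str, str, str]] = []  # (stimulus id, familiarity, liking)
    stimuli += [
        (f"FL{i + 1:02d}", "familiar", "liked") for i in range(spec.n_familiar_liked)
    ]
    stimuli += [
        (f"FD{i + 1:02d}", "familiar", "disliked")
        for i in range(spec.n_familiar_disliked)
    ]
    stimuli += [(f"UF{i + 1:02d}", "unfamiliar", "n/a") for i in range(spec.n_unfamiliar)]

    if rng is not None:
        order = rng.permutation(len(stimuli))
        stimuli = [stimuli[i] for i in order]
    else:
        # deterministic interleave: spread each stimulus type evenly over the
        # session by its fractional position within its own type list
        groups: dict[str, list] = {}
        for s in stimuli:
            groups.setdefault(s[2] + s[1], []).append(s)
        keyed = []
        for lst in groups.values():
            for k, s in enumerate(lst):
                keyed.append(((k + 0.5) / len(lst), s))
        keyed.sort(key=lambda ks: (ks[0], ks[1].__repr__()))
        stimuli = [s for _, s in keyed]

    rows = []
    rows.append(
        {
            "subject": subject,
            "group": group,
            "run": 0,
            "trial": 0,
            "stimulus": "rest",
            "condition_stimulus": "rest",
            "liking": "n/a",
            "condition_response": "rest",
            "duration_s": spec.rest_duration_s,
            "is_rest": True,
            "motion_mm": np.nan,
        }
    )
    trial_no = 0
    for run in range(1, spec.n_task_runs + 1):
        for _ in range(spec.excerpts_per_run):
            stim_id, fam, liking = stimuli[trial_no]
            trial_no += 1
            response = fam
            if response_disagreement_rate > 0 and rng.random() < response_disagreement_rate:
                response = "unfamiliar" if fam == "familiar" else "familiar"
            rows.append(
                {
                    "subject": subject,
                    "group": group,
                    "run": run,
                    "trial": trial_no,
                    "stimulus": stim_id,
                    "condition_stimulus": fam,
                    "liking": liking,
                    "condition_response": response,
                    "duration_s": spec.trial_duration_s,
                    "is_rest": False,
                    "motion_mm": np.nan,
                }
            )
    rows.append(
        {
            "subject": subject,
            "group": group,
            "run": spec.n_task_runs + 1,
            "trial": trial_no + 1,
            "stimulus": "rest",
            "condition_stimulus": "rest",
            "liking": "n/a",
            "condition_response": "rest",
            "duration_s": spec.rest_duration_s,
            "is_rest": True,
            "motion_mm": np.nan,
        }
    )
    return pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
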