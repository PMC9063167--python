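"""Network strength summaries and brain-behavior correlation.

Each significant network is summarized per subject as the sum of its edge
weights in that subject's baselined connectivity matrix; the strengths are
then correlated (Pearson, uncorrected) with behavioral scores: the Social
Communication Questionnaire (SCQ), the Repetitive Behavior Scale-Revised
(RBS-R, notably its ritualistic/sameness subscale) and, within the ASD
group, the ADOS calibrated severity score. Printed cohort summary
statistics are replicated with a pooled-variance two-sample t-test
(df = n1 + n2 - 2).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Cohort summary statistics (mean, SD, n) per (ASD, TD): behavioral inputs
#: for the summary-statistic t-test replication and the synthetic cohort.
COHORT_SUMMARIES = {
    "WASI_II": ((98.0, 15.0, 24), (109.0, 11.1, 24)),
    "SCQ": ((19.3, 6.3, 21), (4.2, 2.9, 21)),
    "RBS_R": ((14.2, 11.6, 24), (1.9, 3.7, 24)),
}
#: ADOS calibrated severity (ASD group only): mean, SD, n.
ADOS_SUMMARY = (6.8, 2.1, 20)


def network_strength(matrix: np.ndarray, edges: Sequence[tuple[int, int]]) -> float:
    """Sum of edge weights over an undirected edge set, each edge once."""
    m = np.asarray(matrix, dtype=float)
    total = 0.0
    seen = set()
    for i, j in edges:
        if not (0 <= i < m.shape[0] and 0 <= j < m.shape[1]):
            raise IndexError(f"edge ({i}, {j}) outside matrix bounds {m.shape}")
        key = (min(i, j), max(i, j))
        if key in seen:
            continue
        seen.add(key)
        total += float(m[i, j])
    return total


def correlate_with_behavior(
    strengths: Sequence[float], scores: Sequence[float]
) -> tuple[float, float, int]:
    """Pearson correlation of network strength with a behavioral score.

    Missing scores (NaN) are dropped pairwise; returns (r, two-sided p, n
    used). Uncorrected for multiple comparisons by design.
    """
    s = np.asarray(strengths, dtype=float)
    b = np.asarray(scores, dtype=float)
    if s.shape != b.shape:
        raise ValueError("strengths and scores must align")
    keep = ~(np.isnan(s) | np.isnan(b))
    s, b = s[keep], b[keep]
    n = int(keep.sum())
    if n < 3:
        raise ValueError(f"need at least 3 complete pairs, got {n}")
    if s.std() == 0 or b.std() == 0:
        raise ValueError("zero variance in strengths or scores")
    r, p = stats.pearsonr(s, b)
    return float(r), float(p), n


def summary_group_ttest(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int]:
    """Pooled-variance two-sample t from summary statistics.

    Returns (t, df) with df = n1 + n2 - 2, matching printed cohort tables.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    t = (mean1 - mean2) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return float(t), int(df)


def generate_behavior_table(
    subjects: Sequence[str],
    groups: Sequence[str],
    rng: np.random.Generator,
    missing_rate: float = 0.1,
) -> pd.DataFrame:
    """Synthetic behavioral scores drawn from the cohort summary statistics.

    ASD/TD rows draw from their group's (mean, SD); scores are floored at
    zero, ADOS is ASD-only, and SCQ values go missing at ``missing_rate``
    to exercise pairwise deletion (the printed table has n = 21 per group
    for SCQ).
    """
    if len(subjects) != len(groups):
        raise ValueError("subjects and groups must align")
    rows = []
    for subject, group in zip(subjects, groups):
        col = 0 if group == "ASD" else 1
        rec = {"subject": subject, "group": group}
        for name, summaries in COHORT_SUMMARIES.items():
            mean, sd, _n = summaries[col]
            val = max(0.0, mean + sd * rng.standard_normal())
            if name == "SCQ" and rng.random() < missing_rate:
                val = np.nan
            rec[name] = round(val, 1)
        # sameness subscale tracks the total with noise, scaled down
        total = rec["RBS_R"] if not np.isnan(rec["RBS_R"]) else 0.0
        rec["RBS_R_sameness"] = round(
            max(0.0, 0.4 * total + 1.0 * rng.standard_normal()), 1
        )
        if group == "ASD":
            mean, sd, _n = ADOS_SUMMARY
            rec["ADOS_css"] = float(np.clip(round(mean + sd * rng.standard_normal()), 1, 10))
        else:
            rec["ADOS_css"] = np.nan
        rows.append(rec)
    return pd.DataFrame(rows)
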