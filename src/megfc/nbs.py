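"""Network-Based Statistics: edgewise tests, components, permutation FWER.

NBS controls the family-wise error rate at the level of connected
subnetworks: a univariate statistic is computed at every edge, thresholded
by a primary component-forming cut-off, and the connected suprathreshold
components are scored by edge count. Significance comes from the
permutation distribution of the maximal component size under relabelling
(group labels for between-group and interaction contrasts; within-subject
condition sign flips for the paired contrast). Defaults follow the study:
primary thresholds t in {2.75, 3.0, 3.5} for AEC and t = 3.0 for wPLI,
F = 7 for the 2x2 interaction, 5000 permutations, and Bonferroni
correction within metric with family sizes 4 (between) and 2 (within),
i.e. per-test alphas 0.0125 and 0.025.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations, product
from typing import Optional, Sequence

import networkx as nx
import numpy as np

#: primary component-forming thresholds per metric (edgewise t units)
DEFAULT_T_THRESHOLDS = {"aec": (2.75, 3.0, 3.5), "wpli": (3.0,)}
#: primary threshold for the 2x2 mixed-design interaction (F units)
DEFAULT_F_THRESHOLD = 7.0
#: Bonferroni family sizes; alpha / size reproduces the 0.0125 / 0.025 cut-offs
FAMILY_SIZES = {"between": 4, "within": 2, "interaction": 2}

CONTRASTS = ("between_groups", "within_group_paired", "interaction_2x2")


@dataclass
class NBSDesign:
    """Contrast type, primary threshold and permutation settings."""

    contrast: str
    primary_threshold: float
    n_permutations: int = 5000
    alpha: float = 0.05
    seed: int = 0
    direction: str = "greater"  # for t contrasts: test a > b ("greater") or a < b

    def __post_init__(self) -> None:
        if self.contrast not in CONTRASTS:
            raise ValueError(f"unknown contrast {self.contrast!r}")
        if self.primary_threshold <= 0:
            raise ValueError("primary threshold must be positive")
        if self.n_permutations < 1:
            raise ValueError("need at least one permutation")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.direction not in ("greater", "less"):
            raise ValueError("direction must be 'greater' or 'less'")


@dataclass
class Component:
    """A connected suprathreshold subnetwork."""

    edges: list[tuple[int, int]]
    nodes: list[int]

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)


@dataclass
class NBSComponentResult:
    """A component with its permutation-based family-wise p-value."""

    edges: list[tuple[int, int]]
    nodes: list[int]
    n_edges: int
    n_nodes: int
    p_fwer: float
    stat_map: Optional[np.ndarray] = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# edge bookkeeping

def whole_brain_pairs(n_nodes: int) -> np.ndarray:
    """Upper-triangle (i < j) node pairs of the full graph, (n_edges, 2)."""
    iu = np.triu_indices(n_nodes, k=1)
    return np.column_stack(iu)


def roi_pairs(n_nodes: int, seeds: Sequence[int]) -> np.ndarray:
    """Unique unordered pairs touching at least one seed, (n_edges, 2).

    This is the edge set tested by the rectangular parcels-x-seeds matrix,
    symmetrized onto the full node set; non-seed pairs are absent, but
    components may still span seed and non-seed nodes.
    """
    seen = set()
    pairs = []
    for s in seeds:
        if not 0 <= s < n_nodes:
            raise ValueError(f"unknown seed id {s}")
        for i in range(n_nodes):
            if i == s:
                continue
            key = (min(i, s), max(i, s))
            if key not in seen:
                seen.add(key)
                pairs.append(key)
    return np.array(sorted(pairs), dtype=int)


def matrices_to_edges(
    matrices: Sequence[np.ndarray] | np.ndarray, pairs: np.ndarray
) -> np.ndarray:
    """Stack per-subject matrices into a (n_subjects, n_edges) array.

    Square symmetric input is read at (i, j); rectangular roi input
    (parcels x seeds) must come with ``pairs`` built by :func:`roi_pairs`
    over the same seed list and is read through the seed columns.
    """
    mats = [np.asarray(m, dtype=float) for m in matrices]
    out = np.empty((len(mats), len(pairs)))
    for k, m in enumerate(mats):
        if m.ndim != 2:
            raise ValueError("each subject matrix must be 2-D")
        out[k] = m[pairs[:, 0], pairs[:, 1]]
    return out


def roi_matrix_to_square(values: np.ndarray, seeds: Sequence[int], n_nodes: int) -> np.ndarray:
    """Embed a parcels-x-seeds matrix into a symmetric n_nodes square map."""
    values = np.asarray(values, dtype=float)
    if values.shape != (n_nodes, len(seeds)):
        raise ValueError("roi matrix shape does not match node/seed counts")
    out = np.zeros((n_nodes, n_nodes))
    for col, s in enumerate(seeds):
        out[:, s] = values[:, col]
        out[s, :] = values[:, col]
    np.fill_diagonal(out, 0.0)
    return out


# ---------------------------------------------------------------------------
# edgewise statistics

def two_sample_t(x1: np.ndarray, x2: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t per column; zero-variance edges get 0."""
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    n1, n2 = x1.shape[0], x2.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two subjects per group")
    sp2 = ((n1 - 1) * x1.var(axis=0, ddof=1) + (n2 - 1) * x2.var(axis=0, ddof=1)) / (
        n1 + n2 - 2
    )
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (x1.mean(axis=0) - x2.mean(axis=0)) / denom
    return np.where(denom > 0, t, 0.0)


def paired_t(diff: np.ndarray) -> np.ndarray:
    """One-sample t of paired differences per column; zero variance -> 0."""
    diff = np.atleast_2d(np.asarray(diff, dtype=float))
    n = diff.shape[0]
    if n < 2:
        raise ValueError("need at least two subjects")
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = diff.mean(axis=0) / (sd / math.sqrt(n))
    return np.where(sd > 0, t, 0.0)


def edgewise_stats(
    a: np.ndarray,
    b: np.ndarray,
    contrast: str,
) -> np.ndarray:
    """Per-edge statistic map for one contrast on (n_subjects, n_edges) data.

    ``between_groups``: pooled two-sample t of a vs b (independent groups).
    ``within_group_paired``: paired t of a - b (same subjects, row-aligned).
    ``interaction_2x2``: a and b are per-subject condition differences of
    the two groups; the statistic is F = t^2 of their two-sample t.
    """
    if contrast == "between_groups":
        return two_sample_t(a, b)
    if contrast == "within_group_paired":
        a = np.atleast_2d(a)
        b = np.atleast_2d(b)
        if a.shape != b.shape:
            raise ValueError("paired contrast needs row-aligned equal-shape arrays")
        return paired_t(a - b)
    if contrast == "interaction_2x2":
        return two_sample_t(a, b) ** 2
    raise ValueError(f"unknown contrast {contrast!r}")


# ---------------------------------------------------------------------------
# component extraction

def extract_components(
    stat_map: np.ndarray, threshold: float
) -> list[Component]:
    """Connected components of the suprathreshold (stat > threshold) graph.

    ``stat_map`` is a square symmetric per-edge statistic map (embed roi
    maps first with :func:`roi_matrix_to_square`). Components are returned
    largest (edge count) first; isolated nodes are never components.
    """
    m = np.asarray(stat_map, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("stat map must be square; embed roi maps first")
    iu = np.triu_indices(m.shape[0], k=1)
    mask = m[iu] > threshold
    g = nx.Graph()
    g.add_edges_from(zip(iu[0][mask].tolist(), iu[1][mask].tolist()))
    comps = []
    for nodes in nx.connected_components(g):
        sub = g.subgraph(nodes)
        comps.append(
            Component(
                edges=sorted(tuple(sorted(e)) for e in sub.edges()),
                nodes=sorted(nodes),
            )
        )
    comps.sort(key=lambda c: (-c.n_edges, c.nodes))
    return comps


def _max_component_edges(pairs: np.ndarray, supra: np.ndarray, n_nodes: int) -> int:
    """Edge count of the largest connected suprathreshold component.

    Union-find over the suprathreshold edge list; used inside the
    permutation loop (cross-checked against the networkx-based
    :func:`extract_components` in the test suite).
    """
    idx = np.flatnonzero(supra)
    if idx.size == 0:
        return 0
    parent = np.arange(n_nodes)

    def find(x: int) -> int:
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    for i, j in pairs[idx]:
        ri, rj = find(int(i)), find(int(j))
        if ri != rj:
            parent[rj] = ri
    counts: dict[int, int] = {}
    for i, _j in pairs[idx]:
        r = find(int(i))
        counts[r] = counts.get(r, 0) + 1
    return max(counts.values())


# ---------------------------------------------------------------------------
# permutation machinery

def _between_label_matrix(
    n1: int, n2: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Boolean (n_perm_used, n) membership-of-group-1 matrix.

    Falls back to exhaustive enumeration (with a warning) when fewer
    distinct relabelings exist than requested.
    """
    n = n1 + n2
    total = math.comb(n, n1)
    if total <= n_perm:
        warnings.warn(
            f"only {total} distinct relabelings exist; using exact enumeration",
            stacklevel=3,
        )
        B = np.zeros((total, n), dtype=bool)
        for k, idx in enumerate(combinations(range(n), n1)):
            B[k, list(idx)] = True
        return B
    B = np.zeros((n_perm, n), dtype=bool)
    for k in range(n_perm):
        B[k, rng.permutation(n)[:n1]] = True
    return B


def _sign_matrix(n: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    total = 2 ** n if n < 63 else np.inf
    if total <= n_perm:
        warnings.warn(
            f"only {total} distinct sign flips exist; using exact enumeration",
            stacklevel=3,
        )
        return np.array(list(product((1.0, -1.0), repeat=n)))
    return rng.choice([1.0, -1.0], size=(n_perm, n))


def _perm_two_sample_t(
    X: np.ndarray, B: np.ndarray, n1: int, n2: int
) -> np.ndarray:
    """Pooled t maps for every permutation row of B, vectorized."""
    Xf = np.asarray(X, dtype=float)
    S = Xf.sum(axis=0)
    S2 = (Xf**2).sum(axis=0)
    Bf = B.astype(float)
    s1 = Bf @ Xf
    s1sq = Bf @ (Xf**2)
    m1 = s1 / n1
    m2 = (S - s1) / n2
    v1 = (s1sq - n1 * m1**2) / (n1 - 1)
    v2 = ((S2 - s1sq) - n2 * m2**2) / (n2 - 1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    denom = np.sqrt(np.maximum(sp2, 0.0) * (1.0 / n1 + 1.0 / n2))
    with np.errstate(invalid="ignore", divide="ignore"):
        t = (m1 - m2) / denom
    return np.where(denom > 0, t, 0.0)


def nbs_permutation_test(
    a: np.ndarray,
    b: np.ndarray,
    design: NBSDesign,
    pairs: np.ndarray,
    n_nodes: int,
    chunk: int = 1000,
) -> list[NBSComponentResult]:
    """Full NBS for one contrast on edge-vectorized data.

    Parameters
    ----------
    a, b : arrays, shape (n_subjects, n_edges)
        Group (or per-subject condition-difference) edge data; see
        :func:`edgewise_stats` for each contrast's interpretation.
    pairs : (n_edges, 2) node pairs aligned with the columns of a and b.
    n_nodes : size of the graph the pairs live in.

    Returns
    -------
    list of NBSComponentResult, largest observed component first; the
    family-wise p-value is ``(1 + #{null max >= observed}) / (1 + K)``
    over the permutation (or exact enumeration) distribution of the
    maximal suprathreshold component edge count.
    """
    a = np.atleast_2d(np.asarray(a, dtype=float))
    b = np.atleast_2d(np.asarray(b, dtype=float))
    if a.shape[1] != len(pairs) or b.shape[1] != len(pairs):
        raise ValueError("edge columns do not match the pair list")
    rng = np.random.default_rng(design.seed)
    thr = design.primary_threshold
    sign = -1.0 if design.direction == "less" else 1.0

    # observed statistic and components
    if design.contrast == "within_group_paired":
        obs = sign * paired_t(a - b)
    elif design.contrast == "between_groups":
        obs = sign * two_sample_t(a, b)
    else:
        obs = two_sample_t(a, b) ** 2
    stat_map = np.zeros((n_nodes, n_nodes))
    stat_map[pairs[:, 0], pairs[:, 1]] = obs
    stat_map[pairs[:, 1], pairs[:, 0]] = obs
    observed = extract_components(stat_map, thr)

    # permutation null of the maximal component size
    if design.contrast == "within_group_paired":
        d = a - b
        S = _sign_matrix(d.shape[0], design.n_permutations, rng)
        n_used = S.shape[0]
        maxima = np.empty(n_used, dtype=int)
        ss = (d**2).sum(axis=0)
        n = d.shape[0]
        for start in range(0, n_used, chunk):
            Sc = S[start : start + chunk]
            m = (Sc @ d) / n
            v = (ss - n * m**2) / (n - 1)
            with np.errstate(invalid="ignore", divide="ignore"):
                t = m / np.sqrt(v / n)
            t = np.where(v > 0, t, 0.0) * sign
            for k, row in enumerate(t):
                maxima[start + k] = _max_component_edges(pairs, row > thr, n_nodes)
    else:
        n1, n2 = a.shape[0], b.shape[0]
        X = np.vstack([a, b])
        B = _between_label_matrix(n1, n2, design.n_permutations, rng)
        n_used = B.shape[0]
        maxima = np.empty(n_used, dtype=int)
        for start in range(0, n_used, chunk):
            t = _perm_two_sample_t(X, B[start : start + chunk], n1, n2)
            if design.contrast == "interaction_2x2":
                t = t**2
            else:
                t = t * sign
            for k, row in enumerate(t):
                maxima[start + k] = _max_component_edges(pairs, row > thr, n_nodes)

    results = []
    for comp in observed:
        k_ge = int(np.sum(maxima >= comp.n_edges))
        p = (1.0 + k_ge) / (1.0 + n_used)
        results.append(
            NBSComponentResult(
                edges=comp.edges,
                nodes=comp.nodes,
                n_edges=comp.n_edges,
                n_nodes=comp.n_nodes,
                p_fwer=p,
                stat_map=stat_map,
            )
        )
    return results


def bonferroni_band_correction(
    p_values: Sequence[float] | np.ndarray,
    family: str | int,
    alpha: float = 0.05,
) -> dict:
    """Bonferroni decisions for one analysis family within one metric.

    ``family`` is either a family name ("between", "within",
    "interaction") or an explicit family size. With alpha = 0.05 the
    between family (size 4) gives the 0.0125 per-test threshold and the
    within family (size 2) gives 0.025.
    """
    if isinstance(family, str):
        try:
            size = FAMILY_SIZES[family]
        except KeyError:
            raise ValueError(f"unknown family {family!r}") from None
    else:
        size = int(family)
    if size <= 0:
        raise ValueError("family size must be positive")
    threshold = alpha / size
    p = np.asarray(p_values, dtype=float)
    return {
        "threshold": threshold,
        "significant": p < threshold,
        "family_size": size,
        "alpha": alpha,
    }
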