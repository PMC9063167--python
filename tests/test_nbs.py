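"""Edgewise statistics, component extraction and permutation FWER."""

import numpy as np
import pytest

from megfc.nbs import (
    NBSDesign,
    bonferroni_band_correction,
    _max_component_edges,
    edgewise_stats,
    extract_components,
    nbs_permutation_test,
    paired_t,
    roi_matrix_to_square,
    roi_pairs,
    two_sample_t,
    whole_brain_pairs,
)


def _data_with_exact_summaries(mean, sd, n, n_edges, rng):
    """Samples whose empirical mean and SD are exactly the requested ones."""
    x = rng.standard_normal((n, n_edges))
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    return mean + sd * x


class TestEdgewiseStats:
    def test_identical_groups_give_zero(self, rng):
        x = rng.standard_normal((10, 20))
        assert np.allclose(two_sample_t(x, x.copy()), 0.0)

    def test_textbook_two_sample_value(self, rng):
        """Group means 0.5 vs 0.0, common SD 0.5, n = 24/24 -> t = 3.4641,
        the closed-form pooled-variance value."""
        a = _data_with_exact_summaries(0.5, 0.5, 24, 3, rng)
        b = _data_with_exact_summaries(0.0, 0.5, 24, 3, rng)
        expected = 0.5 / (0.5 * np.sqrt(2.0 / 24.0))  # = 3.46410...
        assert np.allclose(two_sample_t(a, b), expected, atol=1e-10)
        assert expected == pytest.approx(3.46, abs=0.005)

    def test_interaction_f_is_squared_difference_t(self, rng):
        d1 = rng.standard_normal((12, 30))
        d2 = rng.standard_normal((12, 30))
        f = edgewise_stats(d1, d2, "interaction_2x2")
        t = two_sample_t(d1, d2)
        assert np.allclose(f, t**2, atol=1e-10)

    def test_interaction_null_under_shared_additive_shift(self, rng):
        """A condition effect common to both groups cancels in the
        difference scores: the interaction map is unchanged by it."""
        d1 = rng.standard_normal((10, 15))
        d2 = rng.standard_normal((10, 15))
        shift = rng.standard_normal(15)
        base = edgewise_stats(d1, d2, "interaction_2x2")
        shifted = edgewise_stats(d1 + shift, d2 + shift, "interaction_2x2")
        assert np.allclose(base, shifted, atol=1e-10)

    def test_zero_variance_edge_statistic_is_zero(self):
        a = np.ones((5, 2))
        b = np.ones((5, 2))
        b[:, 1] = np.arange(5)
        t = two_sample_t(a, b)
        assert t[0] == 0.0
        assert paired_t(np.ones((4, 1)) * 3.0 - np.ones((4, 1)) * 3.0)[0] == 0.0


class TestComponents:
    def test_path_graph(self):
        m = np.zeros((6, 6))
        for i, j in [(1, 2), (2, 3), (3, 4)]:
            m[i, j] = m[j, i] = 5.0
        comps = extract_components(m, 3.0)
        assert len(comps) == 1
        assert comps[0].n_edges == 3 and comps[0].n_nodes == 4
        assert comps[0].edges == [(1, 2), (2, 3), (3, 4)]

    def test_no_suprathreshold_edges(self):
        assert extract_components(np.zeros((5, 5)), 1.0) == []

    def test_matches_union_find_oracle_on_random_maps(self, rng):
        """Independent union-find reimplementation agrees edge for edge."""
        for _ in range(10):
            m = rng.standard_normal((92, 92))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0.0)
            thr = 1.5
            comps = extract_components(m, thr)

            parent = list(range(92))

            def find(x):
                while parent[x] != x:
                    parent[x] = parent[parent[x]]
                    x = parent[x]
                return x

            edges = []
            for i in range(92):
                for j in range(i + 1, 92):
                    if m[i, j] > thr:
                        edges.append((i, j))
                        ri, rj = find(i), find(j)
                        if ri != rj:
                            parent[rj] = ri
            groups = {}
            for i, j in edges:
                groups.setdefault(find(i), []).append((i, j))
            oracle = sorted(
                (sorted(v) for v in groups.values()), key=lambda e: (-len(e), e)
            )
            assert [c.edges for c in comps] == [list(map(tuple, g)) for g in oracle]
            if edges:
                assert comps[0].n_edges == _max_component_edges(
                    np.array(edges), np.ones(len(edges), dtype=bool), 92
                )

    def test_raising_threshold_never_grows_components(self, rng):
        m = rng.standard_normal((30, 30))
        m = (m + m.T) / 2
        sizes = []
        for thr in (1.0, 1.5, 2.0, 2.5):
            comps = extract_components(m, thr)
            sizes.append(max((c.n_edges for c in comps), default=0))
        assert sizes == sorted(sizes, reverse=True)

    def test_roi_map_embedding_round_trip(self, rng):
        seeds = [0, 3]
        vals = rng.standard_normal((6, 2))
        square = roi_matrix_to_square(vals, seeds, 6)
        assert np.allclose(square, square.T)
        for col, s in enumerate(seeds):
            for i in range(6):
                if i != s and i not in seeds:
                    assert square[i, s] == vals[i, col]


class TestPermutationTest:
    def test_pvalue_formula(self, rng):
        """With k of K null maxima at least as large as the observed size,
        p = (1 + k) / (1 + K); exercised end to end on a constructed case."""
        assert (1 + 49) / (1 + 999) == pytest.approx(0.05)
        # tiny design, exact enumeration keeps the null fully deterministic
        a = np.array([[10.0, 10.0], [11.0, 11.0], [12.0, 12.0], [13.0, 13.0]])
        b = np.zeros((4, 2))
        pairs = np.array([[0, 1], [1, 2]])
        design = NBSDesign("between_groups", 3.0, n_permutations=500, seed=0)
        with pytest.warns(UserWarning, match="enumeration"):
            res = nbs_permutation_test(a, b, design, pairs, 3)
        assert len(res) == 1 and res[0].n_edges == 2
        # the fully separated labelling is unique among C(8,4)=70 relabelings
        assert res[0].p_fwer == pytest.approx((1 + 1) / (1 + 70))

    def test_reproducible_and_subject_order_invariant_under_enumeration(self, rng):
        a = rng.standard_normal((4, 10))
        b = rng.standard_normal((4, 10))
        pairs = whole_brain_pairs(5)
        design = NBSDesign("between_groups", 1.0, n_permutations=200, seed=3)
        with pytest.warns(UserWarning):
            r1 = nbs_permutation_test(a, b, design, pairs, 5)
        with pytest.warns(UserWarning):
            r2 = nbs_permutation_test(a[::-1], b[::-1], design, pairs, 5)
        assert [c.p_fwer for c in r1] == [c.p_fwer for c in r2]
        assert [c.edges for c in r1] == [c.edges for c in r2]

    def test_paired_contrast_uses_sign_flips(self, rng):
        fam = rng.standard_normal((5, 6))
        unf = fam + 0.1 * rng.standard_normal((5, 6))
        pairs = whole_brain_pairs(4)
        design = NBSDesign("within_group_paired", 2.0, n_permutations=100, seed=1)
        with pytest.warns(UserWarning, match="sign flips"):
            res = nbs_permutation_test(fam, unf, design, pairs, 4)
        for r in res:
            assert 0.0 <= r.p_fwer <= 1.0

    def test_quick_null_calibration_small_graph(self, rng):
        """Null data on a small graph: few replicates reject at alpha."""
        pairs = whole_brain_pairs(15)
        hits = 0
        for rep in range(20):
            a = rng.standard_normal((10, len(pairs)))
            b = rng.standard_normal((10, len(pairs)))
            design = NBSDesign("between_groups", 3.0, n_permutations=200,
                               seed=100 + rep)
            res = nbs_permutation_test(a, b, design, pairs, 15)
            if any(r.p_fwer < 0.05 for r in res):
                hits += 1
        assert hits <= 3


class TestBonferroni:
    def test_printed_thresholds(self):
        between = bonferroni_band_correction([0.01], "between")
        within = bonferroni_band_correction([0.02], "within")
        assert between["threshold"] == pytest.approx(0.0125)
        assert within["threshold"] == pytest.approx(0.025)
        assert between["significant"][0] and within["significant"][0]

    def test_family_of_one_is_identity(self):
        out = bonferroni_band_correction([0.04], 1)
        assert out["threshold"] == pytest.approx(0.05)

    def test_zero_family_size_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_band_correction([0.01], 0)


def test_roi_pairs_cover_only_seed_touching_edges():
    pairs = roi_pairs(6, [0, 2])
    as_set = set(map(tuple, pairs))
    for i, j in as_set:
        assert i < j
        assert i in (0, 2) or j in (0, 2)
    assert (1, 3) not in as_set
    assert len(as_set) == 2 * 5 - 1  # shared seed-seed pair counted once
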