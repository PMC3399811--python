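"""Thresholding, scoring, permutation null and the peel-off procedure."""

import itertools

import numpy as np
import pytest

from tagcna.io_formats import MarkerMap, RatioMatrix
from tagcna.significance import (
    NullDistribution,
    call_sces,
    null_distribution,
    p_values,
    peel_off,
    permute_tags,
    score_tags,
    split_by_threshold,
)
from tagcna.tag_selection import BlockPartition, TagMatrix

from conftest import make_markers


def tag_matrix(values, polarity="amp"):
    values = np.asarray(values, float)
    m = values.shape[1]
    part = BlockPartition(tuple((i, i + 1) for i in range(m)), np.arange(m), m)
    return TagMatrix(values, part, polarity)


def ratio_matrix(values):
    values = np.asarray(values, float)
    return RatioMatrix(values, [f"s{i}" for i in range(values.shape[0])],
                       make_markers(values.shape[1]))


class TestSplitByThreshold:
    def test_real_data_thresholds(self):
        # the standard call thresholds: 0.848 (3.6 copies), -0.737 (1.2 copies)
        X = ratio_matrix([[0.9, -0.8, 0.05], [0.0, 0.0, 0.0]])
        amp, dele = split_by_threshold(X, 0.848, -0.737)
        np.testing.assert_array_equal(amp.values[0], [0.9, 0, 0])
        np.testing.assert_array_equal(dele.values[0], [0, -0.8, 0])

    def test_all_zero_matrix(self):
        amp, dele = split_by_threshold(ratio_matrix(np.zeros((3, 4))), 0.1, -0.1)
        assert not amp.values.any() and not dele.values.any()

    def test_boundary_cell_is_retained(self):
        X = ratio_matrix([[0.848, -0.737], [0.0, 0.0]])
        amp, dele = split_by_threshold(X, 0.848, -0.737)
        assert amp.values[0, 0] == 0.848
        assert dele.values[0, 1] == -0.737

    def test_bad_threshold_signs_rejected(self):
        with pytest.raises(ValueError):
            split_by_threshold(ratio_matrix(np.zeros((2, 2))), -0.1, 0.1)


class TestScores:
    def test_single_column_sum(self):
        assert score_tags(tag_matrix([[0.5], [0.0], [1.0]]))[0] == 1.5

    def test_deletion_magnitudes(self):
        assert score_tags(tag_matrix([[-0.8], [-0.5]], "del"))[0] == pytest.approx(1.3)

    def test_matches_loop_summation(self, rng):
        v = np.where(rng.random((20, 5)) < 0.4, rng.normal(size=(20, 5)), 0.0)
        expect = [sum(abs(v[n, m]) for n in range(20)) for m in range(5)]
        np.testing.assert_allclose(score_tags(tag_matrix(v)), expect, atol=1e-12)

    def test_zero_iff_column_empty(self, rng):
        v = np.zeros((6, 3))
        v[:, 1] = 0.3
        s = score_tags(tag_matrix(v))
        assert s[0] == 0 and s[2] == 0 and s[1] > 0


class TestPermutation:
    def test_single_tag_unchanged(self):
        T = tag_matrix([[0.5], [0.7]])
        np.testing.assert_array_equal(permute_tags(T, 3).values, T.values)

    def test_rows_keep_their_multisets(self, rng):
        T = tag_matrix(rng.normal(size=(8, 6)))
        P = permute_tags(T, 1)
        np.testing.assert_allclose(np.sort(P.values, axis=1),
                                   np.sort(T.values, axis=1))
        # hence the total score is conserved
        assert score_tags(P).sum() == pytest.approx(score_tags(T).sum())

    def test_row_arrangements_uniform(self):
        T = tag_matrix([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        rng = np.random.default_rng(99)
        counts = {p: 0 for p in itertools.permutations((1.0, 2.0, 3.0))}
        n = 10_000
        for _ in range(n):
            counts[tuple(permute_tags(T, rng).values[0])] += 1
        se = np.sqrt((1 / 6) * (5 / 6) / n)
        for c in counts.values():
            assert abs(c / n - 1 / 6) < 3 * se + 1e-9


class TestNullDistribution:
    def test_all_zero_matrix(self):
        D = null_distribution(tag_matrix(np.zeros((4, 3))), E=25, seed=0)
        np.testing.assert_array_equal(D.maxima, np.zeros(25))

    def test_single_subject_invariance(self):
        T = tag_matrix([[0.3, -0.9, 0.5]])
        D = null_distribution(T, E=50, seed=1)
        np.testing.assert_allclose(D.maxima, 0.9)

    def test_maxima_nonnegative_validated(self):
        with pytest.raises(ValueError):
            NullDistribution(np.array([-0.1, 0.2]))


class TestPValues:
    def test_counting(self):
        D = NullDistribution(np.array([1.0, 2.0, 3.0]))
        assert p_values([2.5], D)[0] == pytest.approx(1 / 3)

    def test_zero_score_has_p_one(self):
        D = NullDistribution(np.array([0.0, 1.0, 2.0]))
        assert p_values([0.0], D)[0] == 1.0

    def test_boundary_and_add_one(self):
        D = NullDistribution(np.linspace(0.1, 1.0, 10))
        assert p_values([2.0], D)[0] == 0.0
        assert p_values([2.0], D, add_one=True)[0] == pytest.approx(1 / 11)

    def test_monotone_in_score(self, rng):
        D = NullDistribution(rng.uniform(0, 5, 200))
        s = np.sort(rng.uniform(0, 6, 20))
        p = p_values(s, D)
        assert np.all(np.diff(p) <= 0)


class TestPeelOff:
    def test_all_zero_matrix(self):
        res = peel_off(tag_matrix(np.zeros((5, 4))), E=30, alpha=0.05, seed=2)
        assert res.H == 1
        np.testing.assert_array_equal(res.p_values, np.ones(4))
        assert not res.removed_at.any()

    def test_overwhelming_column_peeled_then_null_collapses(self):
        v = np.zeros((20, 10))
        v[:, 3] = 2.0
        res = peel_off(tag_matrix(v), E=100, alpha=0.05, seed=5)
        assert res.removed_at[3] == 1
        assert res.H == 2
        assert res.p_values[3] == 0.0  # D_2 is all zeros, score is 40
        assert res.distributions[1].mean < res.distributions[0].mean

    def test_alpha_zero_removes_nothing(self):
        v = np.abs(np.random.default_rng(0).normal(size=(6, 5)))
        res = peel_off(tag_matrix(v), E=20, alpha=0.0, seed=1)
        assert res.H == 1 and not res.removed_at.any()

    def test_termination_bound(self, rng):
        v = np.where(rng.random((10, 7)) < 0.3, rng.uniform(0.2, 2, (10, 7)), 0)
        res = peel_off(tag_matrix(v), E=50, alpha=0.3, seed=3)
        assert 1 <= res.H <= 8
        # tags peeled in an iteration had p < alpha under that iteration's null
        for h in range(1, res.H):
            assert np.sum(res.removed_at == h) >= 1

    def test_min_score_tag_always_survives(self, rng):
        # the permuted maximum is always >= the mean column score, so the
        # weakest tag of the final matrix has p = 1 and peel-off can never
        # empty the matrix, however liberal the cutoff
        for s in range(5):
            r = np.random.default_rng(s)
            v = np.where(r.random((8, 5)) < 0.5, r.uniform(0.5, 3, (8, 5)), 0)
            res = peel_off(tag_matrix(v), E=60, alpha=0.999, seed=s)
            assert np.sum(res.removed_at == 0) >= 1

    def test_null_mean_drifts_left_with_embedded_signal(self, rng):
        drops = 0
        n_seeds = 30
        for s in range(n_seeds):
            r = np.random.default_rng(s)
            v = np.where(r.random((25, 12)) < 0.2, r.uniform(0.2, 0.8, (25, 12)), 0)
            v[:, 4] += 1.5  # strong consensus column
            res = peel_off(tag_matrix(v), E=150, alpha=0.05, seed=s)
            if res.H >= 2 and res.distributions[-1].mean <= res.distributions[0].mean:
                drops += 1
        assert drops >= int(0.9 * n_seeds)


def exhaustive_pvalues(values):
    """Exact peel-off-free p-values by enumerating all joint row permutations."""
    values = np.asarray(values, float)
    n, m = values.shape
    scores = np.abs(values).sum(axis=0)
    maxima = []
    for perms in itertools.product(itertools.permutations(range(m)), repeat=n):
        p = np.empty((n, m))
        for r, pr in enumerate(perms):
            p[r] = np.abs(values[r])[list(pr)]
        maxima.append(p.sum(axis=0).max())
    maxima = np.asarray(maxima)
    return np.array([(maxima >= s).mean() for s in scores])


def test_monte_carlo_matches_enumeration_2x3():
    T = tag_matrix([[0.9, 0.5, 0.0], [0.7, 0.0, 1.2]])
    exact = exhaustive_pvalues(T.values)
    D = null_distribution(T, E=20_000, seed=12)
    mc = p_values(score_tags(T), D)
    assert np.max(np.abs(mc - exact)) < 0.02


def test_call_sces_mapping_and_empty(markers10):
    part = BlockPartition(((0, 5), (5, 10)), np.array([2, 7]), 10)
    v = np.zeros((4, 2))
    v[:3, 0] = 0.9
    T = TagMatrix(v, part, "amp")
    from tagcna.significance import PeelOffResult

    res = PeelOffResult(
        p_values=np.array([0.001, 0.8]),
        scores=score_tags(T),
        removed_at=np.array([1, 0]),
        distributions=(NullDistribution(np.zeros(10)),),
        alpha=0.05,
        E=10,
        tag_matrix=T,
    )
    regions = call_sces(res, part, markers10, alpha=0.05)
    assert len(regions) == 1
    r = regions[0]
    assert (r.start_pos, r.end_pos) == (1, 4001)  # markers at 1..4001
    assert r.n_subjects_aberrant == 3
    assert r.tag_marker_id == "M000003"
    assert call_sces(res, part, markers10, alpha=0.0005) == []
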