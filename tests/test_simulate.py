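"""Cohort generator: mixture arithmetic, carriers, placement, null flatness."""

from dataclasses import replace

import numpy as np
import pytest

from tagcna.simulate import (
    SCESpec,
    SimConfig,
    contamination_config,
    null_config,
    power_config,
    simulate_cohort,
    simulate_contamination_sweep,
    simulate_null_cohort,
)


def small_power(seed=0, **kw):
    return power_config(n_subjects=20, n_markers=1000, seed=seed, **kw)


def test_carrier_counts_are_exact_fraction():
    raw, truth = simulate_cohort(power_config(n_subjects=100, n_markers=3000,
                                              frequency=0.15, seed=1))
    assert [len(c) for c in truth.carrier_sets] == [15, 15, 15]
    raw, truth = simulate_cohort(power_config(n_subjects=100, n_markers=3000,
                                              frequency=0.20, seed=1))
    assert [len(c) for c in truth.carrier_sets] == [20, 20, 20]


def test_pure_tumor_reads_exact_ratio():
    cfg = replace(small_power(), normal_fraction_model=None,
                  noise_sd_range=(0.0, 0.0), n_passenger_regions=0)
    raw, truth = simulate_cohort(cfg)
    (s1, e1), (s2, e2), (s3, e3) = truth.sce_intervals
    for (s, e), ratio, carriers in zip(truth.sce_intervals, (0.585, 1.0, 1.322),
                                       truth.carrier_sets):
        np.testing.assert_allclose(raw.values[np.ix_(carriers, range(s, e))],
                                   ratio, atol=1e-12)
    # non-carriers read exactly zero
    non = np.setdiff1d(np.arange(20), truth.carrier_sets[1])
    assert np.all(raw.values[np.ix_(non, range(s2, e2))] == 0)


def test_half_contamination_compresses_four_copies_to_0585():
    # (1-p)*c_t + 2p with p = 0.5, c_t = 4 gives 3 copies: log2(3/2) = 0.585
    spec = (SCESpec(1.0, 50, 0.5, "amp"),)
    cfg = SimConfig(n_subjects=4, n_markers=300, sce_specs=spec,
                    noise_sd_range=(0.0, 0.0),
                    normal_fraction_model=("uniform", 0.5, 0.5),
                    n_passenger_regions=0, seed=3)
    raw, truth = simulate_cohort(cfg)
    s, e = truth.sce_intervals[0]
    vals = raw.values[np.ix_(truth.carrier_sets[0], range(s, e))]
    np.testing.assert_allclose(vals, np.log2(3 / 2), atol=1e-12)


def test_mixture_monotone_in_contamination():
    ps = np.linspace(0, 0.95, 20)
    gain = np.log2(((1 - ps) * 4 + 2 * ps) / 2)
    loss = np.log2(((1 - ps) * 1 + 2 * ps) / 2)
    assert np.all(np.diff(gain) < 0)
    assert np.all(np.diff(loss) > 0)


def test_generation_is_deterministic():
    a, _ = simulate_cohort(small_power(seed=7))
    b, _ = simulate_cohort(small_power(seed=7))
    np.testing.assert_array_equal(a.values, b.values)


def test_perfect_signal_limit_recovers_truth():
    cfg = replace(small_power(), normal_fraction_model=None,
                  noise_sd_range=(0.0, 0.0))
    raw, truth = simulate_cohort(cfg)
    called = np.abs(raw.values) >= 0.1
    # markers called in any subject at SCE loci are exactly the carrier cells
    for (s, e), carriers in zip(truth.sce_intervals, truth.carrier_sets):
        got = np.flatnonzero(called[:, (s + e) // 2])
        np.testing.assert_array_equal(got, carriers)
    # per-subject calls = that subject's passenger + carried SCE intervals
    for n in range(20):
        expect = np.zeros(1000, dtype=bool)
        for s, e in truth.passenger_intervals[n]:
            expect[s:e] = True
        for (s, e), carriers in zip(truth.sce_intervals, truth.carrier_sets):
            if n in carriers:
                expect[s:e] = True
        np.testing.assert_array_equal(called[n], expect)


def test_sce_placement_disjoint_with_guard_gap():
    raw, truth = simulate_cohort(power_config(n_subjects=10, n_markers=2000,
                                              seed=12))
    iv = sorted(truth.sce_intervals)
    for (s1, e1), (s2, e2) in zip(iv[:-1], iv[1:]):
        assert s2 - e1 >= 100


def test_passengers_never_touch_sces():
    raw, truth = simulate_cohort(power_config(n_subjects=30, n_markers=2000,
                                              seed=5))
    blocked = truth.marker_labels
    for subject_iv in truth.passenger_intervals:
        for s, e in subject_iv:
            assert not blocked[s:e].any()


def test_infeasible_placement_errors():
    spec = tuple(SCESpec(1.0, 400, 0.5, "amp") for _ in range(3))
    with pytest.raises(ValueError):
        simulate_cohort(SimConfig(n_subjects=4, n_markers=1000, sce_specs=spec,
                                  seed=0))


class TestNullCohort:
    def test_requires_no_sces(self):
        with pytest.raises(ValueError):
            simulate_null_cohort(small_power())

    def test_truth_is_empty(self):
        raw, truth = simulate_null_cohort(
            null_config(n_subjects=10, n_markers=500, seed=2))
        assert truth.carrier_sets == ()
        assert not truth.marker_labels.any()

    def test_zero_noise_zero_passengers_is_zero_matrix(self):
        cfg = SimConfig(n_subjects=5, n_markers=200, sce_specs=(),
                        noise_sd_range=(0.0, 0.0), normal_fraction_model=None,
                        n_passenger_regions=0, seed=1)
        raw, _ = simulate_null_cohort(cfg)
        assert not raw.values.any()

    def test_aggregate_aberration_frequency_is_flat(self):
        # no marker's passenger coverage may exceed the binomial 99.9%
        # envelope around the cohort-mean rate
        cfg = null_config(n_subjects=200, n_markers=2000, seed=9)
        raw, truth = simulate_null_cohort(cfg)
        cover = np.zeros(2000)
        for subject_iv in truth.passenger_intervals:
            for s, e in subject_iv:
                cover[s:e] += 1
        rate = cover / 200
        mean = rate.mean()
        hi = mean + 3.29 * np.sqrt(mean * (1 - mean) / 200)
        assert rate.max() <= hi


class TestContaminationSweep:
    def test_cohorts_differ_only_in_spread(self):
        base = contamination_config(n_subjects=10, n_markers=1000, seed=4)
        out = simulate_contamination_sweep([0.1, 0.35], base)
        assert [sd for sd, _, _ in out] == [0.1, 0.35]
        t1, t2 = out[0][2], out[1][2]
        assert t1.sce_intervals == t2.sce_intervals
        assert all(np.array_equal(a, b)
                   for a, b in zip(t1.carrier_sets, t2.carrier_sets))

    def test_fraction_mean_and_truncation(self):
        rng = np.random.default_rng(0)
        draws = np.clip(rng.normal(0.6, 0.35, 10_000), 0.0, 0.99)
        raw_draws = rng.normal(0.6, 0.35, 10_000)
        se = 0.35 / np.sqrt(10_000)
        assert abs(raw_draws.mean() - 0.6) < 3 * se
        assert draws.min() >= 0.0 and draws.max() <= 0.99

    def test_degenerate_spread_pins_fraction(self):
        base = contamination_config(n_subjects=30, n_markers=1000, seed=4)
        out = simulate_contamination_sweep([1e-9], base)
        _, raw, truth = out[0]
        s, e = truth.sce_intervals[0]  # the amplification, ratio 1.322
        vals = raw.values[np.ix_(truth.carrier_sets[0], range(s, e))]
        expect = np.log2((0.4 * 5 + 1.2) / 2)  # p pinned at 0.6
        assert abs(np.median(vals) - expect) < 0.05

    def test_nonpositive_sd_rejected(self):
        base = contamination_config(n_subjects=5, n_markers=500, seed=1)
        with pytest.raises(ValueError):
            simulate_contamination_sweep([0.0], base)
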