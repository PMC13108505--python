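"""Onset detection, EZ classification, masks, metrics and statistics."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import precision_score, recall_score

from vepfield.ez import (
    EZ,
    HEALTHY,
    PROPAGATION,
    classify_ez,
    detect_onsets,
    ez_to_parcellation,
    implantation_coverage,
    implanted_regions,
    mask_to_highres,
    min_detectable_effect,
    paired_t,
    precision_recall,
    region_onsets,
)

TIMES = 0.1 * np.arange(1, 301)


class TestDetectOnsets:
    def test_silent_source_has_no_onset(self):
        x = np.full((300, 1), -2.0)
        assert np.isnan(detect_onsets(x, times_s=TIMES)[0])

    def test_step_crossing_at_frame_40(self):
        x = np.full((300, 1), -2.0)
        x[39:, 0] = 1.0  # frame index 39 -> time 4.0 s
        assert detect_onsets(x, times_s=TIMES)[0] == pytest.approx(4.0)

    def test_unsustained_blip_ignored(self):
        x = np.full((300, 1), -2.0)
        x[50, 0] = 1.0  # single-frame excursion
        assert np.isnan(detect_onsets(x, times_s=TIMES)[0])

    def test_agrees_with_exhaustive_scan(self, rng):
        x = rng.normal(-0.2, 1.0, size=(300, 40))
        got = detect_onsets(x, times_s=TIMES)
        for s in range(40):
            expected = np.nan
            for t in range(299):
                if x[t, s] > 0 and x[t + 1, s] > 0:
                    expected = TIMES[t]
                    break
            assert (np.isnan(got[s]) and np.isnan(expected)) or got[s] == expected


class TestClassify:
    def test_rule_on_three_onsets(self):
        pred = classify_ez(np.array([10.0, 15.0, 30.0]), t_eps_s=10.0)
        assert list(pred.labels) == [EZ, EZ, PROPAGATION]

    def test_infinite_tolerance_absorbs_all_seizing(self):
        pred = classify_ez(np.array([10.0, 99.0, np.nan]), t_eps_s=np.inf)
        assert list(pred.labels) == [EZ, EZ, HEALTHY]

    def test_no_onsets_all_healthy(self):
        pred = classify_ez(np.full(4, np.nan), t_eps_s=10.0)
        assert (pred.labels == HEALTHY).all()

    def test_ez_set_monotone_in_tolerance(self, rng):
        onsets = np.where(rng.random(60) < 0.7, rng.uniform(0, 40, 60), np.nan)
        previous = None
        for t_eps in (5.0, 10.0, 30.0):
            ez_mask = classify_ez(onsets, t_eps).ez_mask()
            if previous is not None:
                assert (previous <= ez_mask).all()
            previous = ez_mask

    def test_region_onsets_take_earliest(self):
        onsets = np.array([5.0, 3.0, np.nan, 7.0])
        labels = np.array([0, 0, 1, 1])
        out = region_onsets(onsets, labels, 3)
        assert out[0] == 3.0 and out[1] == 7.0 and np.isnan(out[2])

    def test_quantile_region_onset_ignores_strays(self):
        from vepfield.ez import quantile_region_onsets

        # region 0: one stray early source among 10, bulk seizes at 20 s
        onsets = np.array([2.0] + [20.0] * 4 + [np.nan] * 5)
        labels = np.zeros(10, dtype=int)
        early = quantile_region_onsets(onsets, labels, 1, fraction=0.2)
        assert early[0] == 20.0  # the 2nd of 10 (ceil(0.2*10)=2) smallest onset
        # a region where too few sources seize gets no onset
        sparse = quantile_region_onsets(
            np.array([5.0] + [np.nan] * 9), labels, 1, fraction=0.2
        )
        assert np.isnan(sparse[0])

    def test_sampled_candidates_gate_classification(self):
        from vepfield.ez import classify_sampled_regions

        onsets = np.array([5.0, 5.2, 30.0, 31.0])
        labels = np.array([0, 0, 1, 1])
        cand = np.array([False, True])  # region 0 not sampled by any electrode
        pred = classify_sampled_regions(onsets, labels, 2, 10.0, candidates=cand)
        # region 0 excluded -> region 1 anchors t_lambda and is EZ
        assert list(pred.labels) == [HEALTHY, HEALTHY, EZ, EZ]
        both = classify_sampled_regions(onsets, labels, 2, 10.0)
        assert list(both.labels) == [EZ, EZ, PROPAGATION, PROPAGATION]

    def test_region_mode_broadcasts_to_sources(self):
        from vepfield.ez import classify_sources_via_regions

        onsets = np.array([3.0, np.nan, 30.0, np.nan, np.nan])
        labels = np.array([0, 0, 1, 1, 2])
        pred = classify_sources_via_regions(onsets, labels, 3, t_eps_s=10.0)
        # region 0 seizes first -> both its sources EZ (even the silent one);
        # region 1 is late -> propagation; region 2 silent -> healthy
        assert list(pred.labels) == [EZ, EZ, PROPAGATION, PROPAGATION, HEALTHY]
        assert pred.onset_times_s[1] == 3.0 and np.isnan(pred.onset_times_s[4])


class TestResectionMask:
    def test_zero_and_single_region(self):
        labels = np.array([0, 0, 1, 2, 2])
        assert np.array_equal(mask_to_highres(np.zeros(3), labels), np.zeros(5))
        m = mask_to_highres(np.array([0, 1, 0]), labels)
        assert np.array_equal(m, [0, 0, 1, 0, 0])

    def test_matches_bruteforce_lookup(self, rng):
        labels = rng.integers(0, 9, size=200)
        mask = rng.integers(0, 2, size=9)
        got = mask_to_highres(mask, labels)
        assert np.array_equal(got, np.array([mask[r] for r in labels]))

    def test_region_majority_inverts_exactly(self, rng):
        labels = rng.integers(0, 9, size=200)
        mask = rng.integers(0, 2, size=9)
        high = mask_to_highres(mask, labels)
        recovered = np.array(
            [
                int(np.round(high[labels == r].mean())) if (labels == r).any() else 0
                for r in range(9)
            ]
        )
        present = np.isin(np.arange(9), labels)
        assert np.array_equal(recovered[present], mask[present])

    def test_unknown_region_rejected(self):
        with pytest.raises(ValueError):
            mask_to_highres(np.array([1]), np.array([0, 3]))


class TestParcellationMapping:
    def test_full_region_is_ez_at_any_threshold(self):
        labels = np.zeros(10, dtype=int)
        ez = np.ones(10, dtype=bool)
        for pct in (1.0, 50.0, 100.0):
            assert ez_to_parcellation(ez, labels, 1, pct)[0]

    def test_threshold_arithmetic(self):
        labels = np.zeros(10, dtype=int)
        ez = np.zeros(10, dtype=bool)
        ez[0] = True  # 10% of sources
        assert not ez_to_parcellation(ez, labels, 1, 20.0)[0]
        assert ez_to_parcellation(ez, labels, 1, 10.0)[0]

    def test_sweep_monotone_nonincreasing(self, rng):
        labels = rng.integers(0, 12, size=400)
        ez = rng.random(400) < 0.3
        counts = [
            ez_to_parcellation(ez, labels, 12, pct).sum()
            for pct in (5.0, 20.0, 50.0, 90.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            ez_to_parcellation(np.zeros(3, bool), np.zeros(3, int), 1, 0.0)


class TestPrecisionRecall:
    def test_perfect_and_subset(self):
        truth = np.array([1, 1, 1, 0], bool)
        assert precision_recall(truth, truth) == (1.0, 1.0)
        p, r = precision_recall(np.array([1, 0, 0, 0], bool), truth)
        assert p == 1.0 and r < 1.0

    def test_confusion_arithmetic(self):
        # TP=3, FP=1, FN=9
        truth = np.array([1] * 12 + [0] * 4, bool)
        pred = np.array([1] * 3 + [0] * 9 + [1] + [0] * 3, bool)
        assert precision_recall(pred, truth) == (0.75, 0.25)

    def test_empty_prediction_convention(self):
        p, r = precision_recall(np.zeros(5, bool), np.ones(5, bool))
        assert p == 0.0 and r == 0.0

    def test_matches_sklearn_oracle(self, rng):
        for _ in range(10):
            truth = rng.random(50) < 0.4
            pred = rng.random(50) < 0.4
            p, r = precision_recall(pred, truth)
            assert p == pytest.approx(precision_score(truth, pred, zero_division=0))
            assert r == pytest.approx(recall_score(truth, pred, zero_division=1))


class TestImplantation:
    def test_contact_at_source(self, small_scenario):
        sc = small_scenario
        region = sc.space.labels[0]
        from vepfield.forward import SensorSet

        sensors = SensorSet(
            contact_ids=["a0", "a1"],
            electrode_ids=["a", "a"],
            positions_mm=np.vstack([sc.space.positions_mm[0], sc.space.positions_mm[0] + 2.0]),
        )
        assert implanted_regions(sensors, sc.space, 3.0)[region]

    def test_infinite_radius_covers_everything(self, small_scenario, small_sensors):
        sc = small_scenario
        ez = np.zeros(sc.space.n_regions, bool)
        ez[sc.ez_regions] = True
        assert implantation_coverage(ez, small_sensors, sc.space, 1e9) == 0.0

    def test_matches_bruteforce(self, small_scenario, small_sensors):
        sc = small_scenario
        got = implanted_regions(small_sensors, sc.space, 3.0)
        for r in range(sc.space.n_regions):
            members = sc.space.region_members(r)
            if not len(members):
                assert not got[r]
                continue
            d = np.linalg.norm(
                sc.space.positions_mm[members][:, None]
                - small_sensors.positions_mm[None],
                axis=2,
            )
            assert got[r] == bool((d <= 3.0).any())

    def test_sampled_regions_include_electrode_targets(self, small_scenario, small_sensors):
        from vepfield.ez import sampled_regions

        sc = small_scenario
        got = sampled_regions(small_sensors, sc.space, 3.0)
        # the radius rule alone can miss a hosting region on a coarse grid;
        # the trajectory rule must keep every electrode's target region
        for target in (0, 1, 13):
            assert got[target]
        assert got.sum() <= sc.space.n_regions // 2  # far from everything

    def test_coverage_decreases_with_radius(self, small_scenario, small_sensors):
        sc = small_scenario
        ez = np.zeros(sc.space.n_regions, bool)
        ez[sc.ez_regions] = True
        sweep = [
            implantation_coverage(ez, small_sensors, sc.space, r)
            for r in np.arange(1.0, 11.0)
        ]
        assert sweep == sorted(sweep, reverse=True)


class TestPairedT:
    def test_identical_samples(self):
        t, dof, p = paired_t(np.arange(5.0), np.arange(5.0))
        assert t == 0.0 and dof == 4 and p == 1.0

    def test_constant_nonzero_difference_degenerate(self):
        with pytest.raises(ValueError):
            paired_t(np.array([2.0, 3.0, 4.0, 5.0]), np.array([1.0, 2.0, 3.0, 4.0]))

    def test_matches_scipy_oracle(self, rng):
        a = rng.normal(size=5)
        b = rng.normal(size=5)
        t, dof, p = paired_t(a, b)
        ref = stats.ttest_rel(a, b)
        assert t == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)
        assert dof == 4


class TestPowerAnalysis:
    def test_printed_value(self):
        assert round(min_detectable_effect(0.05, 0.8, 12), 2) == 0.89

    def test_monotone_in_n(self):
        assert min_detectable_effect(0.05, 0.8, 48) < min_detectable_effect(0.05, 0.8, 12)

    def test_matches_monte_carlo_power(self, rng):
        d = min_detectable_effect(0.05, 0.8, 12)
        n_sim = 100_000
        diffs = rng.normal(d, 1.0, size=(n_sim, 12))
        t = diffs.mean(axis=1) / (diffs.std(axis=1, ddof=1) / np.sqrt(12))
        crit = stats.t.ppf(0.975, 11)
        power = np.mean(np.abs(t) > crit)
        assert abs(power - 0.8) < 0.02

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            min_detectable_effect(0.0, 0.8, 12)
        with pytest.raises(ValueError):
            min_detectable_effect(0.05, 0.8, 1)
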