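import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import metastrat as ms
from metastrat.markers import MarkerItem, MarkerList
from metastrat.stability_fdr import (
    coidentification_percentage,
    compare_overlap_distributions,
    ef_report_from_sets,
    integrate_robustness,
)


def marker_list(keys):
    return MarkerList([MarkerItem(feature_key=k, p_value=0.01)
                       for k in keys])


class TestHalfSample:
    def test_floor_arithmetic(self):
        rng = np.random.default_rng(0)
        t = ms.PeakTable(
            mz=[100.0], rt=[1.0],
            intensities=rng.uniform(1, 2, size=(1, 44)),
            sample_ids=[f"s{i}" for i in range(44)],
            groups=["case"] * 20 + ["control"] * 24,
            experiments=["E"] * 44,
        )
        sub = ms.half_sample(t, seed=1)
        assert int(sub.case_mask.sum()) == 10
        assert int(sub.control_mask.sum()) == 12

    def test_odd_count_floors(self):
        rng = np.random.default_rng(0)
        t = ms.PeakTable(
            mz=[100.0], rt=[1.0],
            intensities=rng.uniform(1, 2, size=(1, 68)),
            sample_ids=[f"s{i}" for i in range(68)],
            groups=["case"] * 59 + ["control"] * 9,
            experiments=["E"] * 68,
        )
        sub = ms.half_sample(t, seed=1)
        assert int(sub.case_mask.sum()) == 29

    def test_deterministic(self, small_pair):
        _, a, _, _, _ = small_pair
        assert ms.half_sample(a, seed=3).sample_ids == \
            ms.half_sample(a, seed=3).sample_ids

    def test_too_few_samples_errors(self, tiny_table):
        with pytest.raises(ValueError, match=">= 4"):
            ms.half_sample(tiny_table, seed=0)


class TestOverlap:
    def test_identical_lists_give_one(self):
        a = marker_list([(float(i), 1.0) for i in range(50)])
        assert ms.overlap(a, a) == 1.0

    def test_disjoint_lists_give_zero(self):
        a = marker_list([(1.0, 1.0)])
        b = marker_list([(2.0, 1.0)])
        assert ms.overlap(a, b) == 0.0

    def test_direct_arithmetic(self):
        a = marker_list([(1.0, 1.0), (2.0, 1.0), (3.0, 1.0)])
        b = marker_list([(2.0, 1.0), (3.0, 1.0), (4.0, 1.0), (5.0, 1.0)])
        assert ms.overlap(a, b) == pytest.approx(4 / 7)

    def test_both_empty_defined_as_zero(self, caplog):
        with caplog.at_level("WARNING"):
            assert ms.overlap(marker_list([]), marker_list([])) == 0.0

    @settings(max_examples=50, deadline=None)
    @given(st.sets(st.integers(0, 30)), st.sets(st.integers(0, 30)))
    def test_symmetric_bounded_and_one_iff_equal(self, sa, sb):
        a = frozenset((float(i), 0.0) for i in sa)
        b = frozenset((float(i), 0.0) for i in sb)
        v = ms.overlap(a, b)
        assert v == ms.overlap(b, a)
        assert 0.0 <= v <= 1.0
        if sa or sb:
            assert (v == 1.0) == (a == b)


class TestRobustnessReport:
    def test_forty_five_overlaps(self, small_pair):
        _, a, _, _, _ = small_pair
        rep = ms.robustness_report(ms.pretreat(a), n_iter=10, seed=1)
        assert len(rep.overlaps) == 45
        assert rep.n_iterations == 10
        assert len(rep.marker_counts) == 10

    def test_coidentification_monotone(self, small_pair):
        _, a, _, _, _ = small_pair
        rep = ms.robustness_report(ms.pretreat(a), n_iter=10, seed=1)
        counts = [rep.coidentification[k][0]
                  for k in ("10", ">=9", ">=8", ">=7", ">=6")]
        assert counts == sorted(counts)
        assert counts[-1] <= rep.total_identified

    def test_percentage_convention(self):
        assert coidentification_percentage(5, 1226) == 0.41

    def test_deterministic(self, small_pair):
        _, a, _, _, _ = small_pair
        t = ms.pretreat(a)
        r1 = ms.robustness_report(t, seed=9)
        r2 = ms.robustness_report(t, seed=9)
        assert r1.overlaps == r2.overlaps
        assert r1.marker_counts == r2.marker_counts

    def test_perfectly_stable_markers_give_unit_overlaps(self):
        # one overwhelming marker, rest constant-ish noise: every
        # half-sample finds exactly that marker
        rng = np.random.default_rng(4)
        n = 40
        signal = np.concatenate([rng.normal(50, 0.1, 20),
                                 rng.normal(10, 0.1, 20)])
        noise = rng.normal(10, 0.001, size=(5, n))
        t = ms.PeakTable(
            mz=np.arange(1, 7) * 100.0, rt=np.arange(1, 7) * 1.0,
            intensities=np.vstack([signal, noise]),
            sample_ids=[f"s{i}" for i in range(n)],
            groups=["case"] * 20 + ["control"] * 20,
            experiments=["E"] * n,
        )
        rep = ms.robustness_report(t, n_iter=10, alpha=1e-20, seed=2)
        assert rep.overlaps == [1.0] * 45
        assert rep.median_overlap == 1.0


class TestIntegrateRobustness:
    def test_self_integration_is_identity(self, small_pair):
        _, a, _, _, _ = small_pair
        rep = ms.robustness_report(ms.pretreat(a), seed=5)
        combined = integrate_robustness(rep, rep)
        assert combined.overlaps == rep.overlaps
        assert combined.median_overlap == rep.median_overlap
        assert combined.total_identified == rep.total_identified

    def test_pairwise_average(self, small_pair):
        _, a, b, _, _ = small_pair
        ra = ms.robustness_report(ms.pretreat(a), seed=5)
        rb = ms.robustness_report(ms.pretreat(b), seed=5)
        combined = integrate_robustness(ra, rb)
        for x, y, z in zip(ra.overlaps, rb.overlaps, combined.overlaps):
            assert z == pytest.approx(0.5 * (x + y))


class TestCompareOverlapDistributions:
    def test_identical_distributions_p_large(self):
        x = list(np.linspace(0.1, 0.9, 45))
        p, degenerate = compare_overlap_distributions(x, x)
        assert p >= 0.5 and not degenerate

    def test_separated_distributions(self):
        p, _ = compare_overlap_distributions([0.9] * 45, [0.1] * 45)
        assert p < 1e-10

    def test_one_sided_reversal(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0.3, 0.6, 45).tolist()
        y = rng.uniform(0.2, 0.5, 45).tolist()
        p_fwd, _ = compare_overlap_distributions(x, y)
        p_rev, _ = compare_overlap_distributions(y, x)
        # oracle: scipy's two one-sided MWU p-values with ties
        u_fwd = stats.mannwhitneyu(x, y, alternative="greater").pvalue
        u_rev = stats.mannwhitneyu(y, x, alternative="greater").pvalue
        assert p_fwd == pytest.approx(u_fwd)
        assert p_rev == pytest.approx(u_rev)

    def test_degenerate_all_tied(self, caplog):
        with caplog.at_level("WARNING"):
            p, degenerate = compare_overlap_distributions([0.5] * 10,
                                                          [0.5] * 10)
        assert p == 1.0 and degenerate


class TestEnrichmentFactor:
    @pytest.mark.parametrize("args,expected", [
        ((4, 2523, 7, 34840), 7.89),
        ((5, 9709, 9, 42269), 2.42),
        ((5, 1862, 11, 19724), 4.81),
    ])
    def test_published_worked_examples(self, args, expected):
        assert round(ms.enrichment_factor(*args), 2) == expected

    def test_identified_equals_universe_gives_one(self):
        assert ms.enrichment_factor(7, 1000, 7, 1000) == 1.0

    def test_zero_denominators_error(self):
        with pytest.raises(ValueError):
            ms.enrichment_factor(1, 0, 1, 10)
        with pytest.raises(ValueError):
            ms.enrichment_factor(1, 10, 0, 10)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(1, 20), st.integers(1, 10))
    def test_scale_invariance(self, scale, base):
        ef1 = ms.enrichment_factor(base, base * 10, base * 2, base * 100)
        ef2 = ms.enrichment_factor(base * scale, base * 10 * scale,
                                   base * 2 * scale, base * 100 * scale)
        assert ef1 == pytest.approx(ef2)


class TestEfReport:
    def test_all_features_as_markers_gives_ef_one(self, small_pair):
        _, a, _, lib, gt = small_pair
        ann = ms.annotate(a.feature_keys, lib)
        all_markers = MarkerList([
            MarkerItem(feature_key=k, p_value=0.0) for k in a.feature_keys
        ])
        rep = ms.ef_report(all_markers, ann, gt.true_marker_set())
        assert rep.ef == pytest.approx(1.0)

    def test_perfect_selection_maximizes_ef(self, small_pair):
        _, a, _, lib, gt = small_pair
        truth = gt.true_marker_set()
        ann = ms.annotate(a.feature_keys, lib)
        true_keys = [k for k in a.feature_keys
                     if set(ann.mapping[k]) & truth.metabolite_ids]
        markers = MarkerList([MarkerItem(feature_key=k, p_value=0.0)
                              for k in true_keys])
        rep = ms.ef_report(markers, ann, truth)
        # substitution: all identified metabolites derive from true peaks
        expected = (rep.n_true_identified / rep.n_identified_annotated) / \
            (rep.n_true_detected / rep.n_detected_annotated)
        assert rep.ef == pytest.approx(expected)
        assert rep.ef > 1.0

    def test_truth_disjoint_flagged_undefined(self, small_pair):
        _, a, _, lib, _ = small_pair
        ann = ms.annotate(a.feature_keys, lib)
        markers = MarkerList([MarkerItem(feature_key=a.feature_keys[0],
                                         p_value=0.01)])
        rep = ms.ef_report(markers, ann,
                           ms.TrueMarkerSet(frozenset({"NOPE"})))
        assert "undefined" in rep.flags
        assert np.isnan(rep.ef)

    def test_low_support_flag(self):
        universe = frozenset(f"M{i}" for i in range(100)) | {"T1", "T2"}
        rep = ef_report_from_sets(universe, frozenset({"T1", "M1"}),
                                  ms.TrueMarkerSet(frozenset({"T1", "T2"})))
        assert "low_support" in rep.flags
        assert rep.n_true_identified == 1

    def test_random_selection_mean_ef_near_one(self):
        rng = np.random.default_rng(0)
        universe = [f"M{i}" for i in range(2000)]
        truth = ms.TrueMarkerSet(frozenset(universe[:12]))
        efs = []
        for _ in range(500):
            picked = frozenset(rng.choice(universe, size=100,
                                          replace=False))
            rep = ef_report_from_sets(frozenset(universe), picked, truth)
            efs.append(rep.ef)
        assert np.mean(efs) == pytest.approx(1.0, abs=0.1)
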