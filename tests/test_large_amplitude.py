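"""Large-amplitude detector: features, thresholds, criteria, merging."""

import numpy as np
import pytest

from neoqc import BurstEvent, DetectorConfig, Recording
from neoqc.large_amplitude import (
    ChannelThresholds,
    SelectionTable,
    WindowFeatures,
    analyze_large_amplitude,
    apply_criteria,
    channel_thresholds,
    compute_maa,
    compute_mafd,
    compute_rfc,
    detect_large_amplitude,
    merge_selected,
    segment_windows,
)
from neoqc.model import intervals_to_mask
from neoqc.preprocess import prepare_views
from neoqc.synthetic import SimulationSpec, generate_background, inject_burst

FS = 250.0


class TestSegmentWindows:
    def test_even_tiling(self):
        grid = segment_windows(int(60 * FS), FS, 3.0)
        assert grid.n_windows == 20
        assert grid.bounds_s(0) == (0.0, 3.0)
        assert grid.bounds_s(19) == (57.0, 60.0)

    def test_remainder_of_at_least_1s_stands_alone(self):
        grid = segment_windows(int(61.5 * FS), FS, 3.0)
        assert grid.n_windows == 21
        assert grid.bounds_s(20) == (60.0, 61.5)

    def test_remainder_below_1s_absorbed(self):
        grid = segment_windows(int(60.4 * FS), FS, 3.0)
        assert grid.n_windows == 20
        assert grid.bounds_s(19) == (57.0, 60.4)

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            segment_windows(1000, FS, 0.0)


class TestFeatures:
    def test_mafd_hand_values(self):
        assert compute_mafd(np.full(10, 3.3)) == 0.0
        assert compute_mafd([0.0, 5.0, -3.0]) == 8.0
        x = np.random.default_rng(0).standard_normal(100)
        assert compute_mafd(4.0 * x) == pytest.approx(4.0 * compute_mafd(x))

    def test_maa_hand_values(self):
        assert compute_maa(np.zeros(5)) == 0.0
        assert compute_maa([-120.0, 80.0]) == 120.0

    def test_maa_at_least_half_mafd(self, rng):
        for _ in range(50):
            x = rng.standard_normal(200) * rng.uniform(1, 100)
            assert compute_maa(x) >= compute_mafd(x) / 2

    def test_rfc_sinusoids(self):
        t = np.arange(750) / FS
        assert compute_rfc(np.sin(2 * np.pi * 10 * t), FS) < 0.01
        assert compute_rfc(np.sin(2 * np.pi * 70 * t), FS) > 0.9

    def test_rfc_white_noise_flat_spectrum(self, rng):
        x = rng.standard_normal(2500)
        assert compute_rfc(x, FS) == pytest.approx(0.6, abs=0.05)

    def test_rfc_zero_window(self):
        assert compute_rfc(np.zeros(750), FS) == 0.0

    def test_feature_errors(self):
        with pytest.raises(ValueError):
            compute_mafd([1.0])
        with pytest.raises(ValueError):
            compute_maa([])


def _features(mafd, maa=None, rfc=None):
    mafd = np.atleast_2d(np.asarray(mafd, dtype=float))
    maa = np.zeros_like(mafd) if maa is None else np.atleast_2d(np.asarray(maa, float))
    rfc = np.zeros_like(mafd) if rfc is None else np.atleast_2d(np.asarray(rfc, float))
    return WindowFeatures(mafd, maa, rfc)


class TestChannelThresholds:
    def test_hand_median_mad(self):
        th = channel_thresholds(_features([1, 1, 1, 1, 11]))
        assert th.mafd_cut[0] == pytest.approx(4.5)  # median 1, MAD 0

    def test_all_equal_windows(self):
        th = channel_thresholds(_features([2, 2, 2, 2]))
        assert th.mafd_cut[0] == pytest.approx(4.5 * 2)

    def test_window_permutation_invariance(self, rng):
        vals = rng.uniform(0, 50, size=40)
        th1 = channel_thresholds(_features(vals))
        th2 = channel_thresholds(_features(rng.permutation(vals)))
        assert th1.mafd_cut[0] == pytest.approx(th2.mafd_cut[0])

    def test_single_window_rejected(self):
        with pytest.raises(ValueError):
            channel_thresholds(_features([[3.0]]))


def _table(maa_row, mafd_row=None, rfc_row=None, config=None):
    W = len(maa_row)
    mafd = np.zeros((1, W)) if mafd_row is None else np.array([mafd_row], float)
    rfc = np.zeros((1, W)) if rfc_row is None else np.array([rfc_row], float)
    feats = WindowFeatures(mafd, np.array([maa_row], float), rfc)
    th = ChannelThresholds(np.array([50.0]), np.array([0.3]))
    return apply_criteria(feats, th, config)


class TestApplyCriteria:
    def test_pt150_fires_unconditionally(self):
        sel = _table([30, 160, 30])
        assert list(sel.selected) == [False, True, False]
        assert sel.criterion[1] == 2

    def test_isolated_doubtful_window_retained(self):
        sel = _table([30, 120, 30], rfc_row=[0, 0.1, 0])
        assert not sel.selected.any()

    def test_doubtful_plus_high_rfc_fires_criterion_3(self):
        sel = _table([30, 120, 30], rfc_row=[0, 0.5, 0])
        assert sel.criterion[1] == 3

    def test_mafd_fires_criterion_1(self):
        sel = _table([30, 30, 30], mafd_row=[0, 60, 0])
        assert sel.criterion[1] == 1

    def test_neighbor_rule_no_propagation(self):
        # windows: [doubtful, doubtful, doubtful, PT150]
        sel = _table([120, 120, 120, 200])
        assert list(sel.selected) == [False, False, True, True]
        assert sel.criterion[2] == 4

    def test_neighbor_rule_both_sides(self):
        sel = _table([200, 120, 30, 120, 200])
        assert list(sel.selected) == [True, True, False, True, True]

    def test_strict_boundaries(self):
        # equalities never select: MAA=150, MAA=100, MAFD=cut, RFC=cut
        sel = _table([150, 100, 30, 30], mafd_row=[0, 0, 50, 0],
                     rfc_row=[0, 0, 0, 0.3])
        assert not sel.selected.any()

    def test_all_criteria_disabled_selects_nothing(self):
        cfg = DetectorConfig(
            enable_criterion_1=False,
            enable_criterion_2=False,
            enable_criterion_3=False,
            enable_criterion_4=False,
        )
        sel = _table([200, 120, 300], mafd_row=[100, 0, 0],
                     rfc_row=[0.9, 0.9, 0.9], config=cfg)
        assert not sel.selected.any()

    def test_enabling_criteria_is_monotone(self, rng):
        feats = WindowFeatures(
            rng.uniform(0, 120, (3, 30)),
            rng.uniform(0, 250, (3, 30)),
            rng.uniform(0, 1, (3, 30)),
        )
        th = ChannelThresholds(np.full(3, 60.0), np.full(3, 0.4))
        partial = apply_criteria(
            feats, th, DetectorConfig(enable_criterion_1=False,
                                      enable_criterion_4=False)
        )
        full = apply_criteria(feats, th, DetectorConfig())
        assert np.all(full.selected | ~partial.selected)

    def test_doubtful_channel_may_differ_from_trigger_channel(self):
        # channel 0 provides the PT150 trigger in window 0; channel 1 is
        # doubtful in window 1 -> criterion 4 still fires
        feats = WindowFeatures(
            np.zeros((2, 2)),
            np.array([[200.0, 30.0], [30.0, 120.0]]),
            np.zeros((2, 2)),
        )
        th = ChannelThresholds(np.full(2, 50.0), np.full(2, 0.3))
        sel = apply_criteria(feats, th)
        assert list(sel.selected) == [True, True]
        assert sel.criterion[1] == 4 and sel.channels[1] == (1,)


def brute_force_criteria(feats, th, cfg):
    """Independent truth-table evaluation of the four criteria."""
    C, W = feats.mafd.shape
    pass_a = [False] * W
    for w in range(W):
        for c in range(C):
            c1 = cfg.enable_criterion_1 and feats.mafd[c, w] > th.mafd_cut[c]
            c2 = cfg.enable_criterion_2 and feats.maa[c, w] > cfg.pt150
            c3 = (
                cfg.enable_criterion_3
                and cfg.pt100 < feats.maa[c, w] < cfg.pt150
                and feats.rfc[c, w] > th.rfc_cut[c]
            )
            if c1 or c2 or c3:
                pass_a[w] = True
    selected = list(pass_a)
    for w in range(W):
        if selected[w] or not cfg.enable_criterion_4:
            continue
        doubt = any(cfg.pt100 < feats.maa[c, w] < cfg.pt150 for c in range(C))
        near = (w > 0 and pass_a[w - 1]) or (w < W - 1 and pass_a[w + 1])
        if doubt and near:
            selected[w] = True
    return selected


class TestCriteriaOracle:
    def test_random_tables_match_truth_table(self, rng):
        cfg = DetectorConfig()
        for _ in range(200):
            C = int(rng.integers(1, 5))
            W = int(rng.integers(2, 25))
            feats = WindowFeatures(
                rng.uniform(0, 150, (C, W)),
                rng.uniform(0, 250, (C, W)),
                rng.uniform(0, 1, (C, W)),
            )
            th = ChannelThresholds(
                rng.uniform(10, 120, C), rng.uniform(0.05, 0.9, C)
            )
            got = apply_criteria(feats, th, cfg)
            assert list(got.selected) == brute_force_criteria(feats, th, cfg)


class TestMergeSelected:
    def _selection(self, flags):
        sel = np.asarray(flags, dtype=bool)
        return SelectionTable(sel, np.where(sel, 2, 0), [()] * len(sel))

    def test_consecutive_windows_fuse(self):
        grid = segment_windows(int(30 * FS), FS, 3.0)
        out = merge_selected(self._selection([1, 1] + [0] * 8), grid)
        assert len(out) == 1 and (out[0].start_s, out[0].end_s) == (0.0, 6.0)

    def test_gap_of_exactly_6s_fuses(self):
        grid = segment_windows(int(30 * FS), FS, 3.0)
        # windows 0 and 3: [0,3) and [9,12), gap 6 s inclusive
        out = merge_selected(self._selection([1, 0, 0, 1] + [0] * 6), grid)
        assert len(out) == 1 and (out[0].start_s, out[0].end_s) == (0.0, 12.0)

    def test_gap_above_6s_stays_split(self):
        grid = segment_windows(int(40 * FS), FS, 3.5)
        # windows 0 and 3: [0,3.5) and [10.5,14), gap 7 s
        out = merge_selected(self._selection([1, 0, 0, 1] + [0] * 7), grid)
        assert len(out) == 2

    def test_nothing_selected(self):
        grid = segment_windows(int(30 * FS), FS, 3.0)
        assert len(merge_selected(self._selection([0] * 10), grid)) == 0


class TestDetectLargeAmplitude:
    def _views(self, seed, duration_s=600.0, bursts=()):
        rec = generate_background(
            SimulationSpec(duration_s=duration_s, seed=seed)
        )
        truth = []
        for ev in bursts:
            rec, iv = inject_burst(rec, ev, copy=False)
            truth.append(iv)
        return prepare_views(rec), truth

    def test_movement_burst_detected(self):
        views, truth = self._views(
            21, bursts=[BurstEvent(300.0, 5.0, peak_uv=300.0)]
        )
        out = detect_large_amplitude(views.band, views.notched)
        mask = intervals_to_mask(out, FS, views.band.n_samples)
        tmask = intervals_to_mask(truth, FS, views.band.n_samples)
        assert (mask & tmask).sum() / tmask.sum() > 0.9

    def test_background_mostly_retained(self):
        views, _ = self._views(22)
        out = detect_large_amplitude(views.band, views.notched)
        assert out.total_duration_s / views.band.duration_s < 0.05

    def test_amplitude_doubling_is_monotone_for_fixed_thresholds(self, rng):
        # fixed-threshold criteria (2 and 3) can only gain selections when
        # a sub-100 µV recording is scaled up
        data = rng.standard_normal((3, int(120 * FS))) * 15.0
        cfg = DetectorConfig(enable_criterion_1=False, enable_criterion_4=False)
        base = Recording(data, FS)
        doubled = Recording(4.0 * data, FS)
        sel_base = analyze_large_amplitude(base, base, cfg).selection.selected
        sel_doubled = analyze_large_amplitude(
            doubled, doubled, cfg
        ).selection.selected
        assert np.all(sel_doubled | ~sel_base)

    def test_criterion_counts_reported(self):
        views, _ = self._views(
            23, bursts=[BurstEvent(100.0, 5.0, peak_uv=300.0)]
        )
        res = analyze_large_amplitude(views.band, views.notched)
        assert (res.selection.criterion == 2).sum() >= 1
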