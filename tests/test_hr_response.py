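"""Pre/post HR extraction, fall and bigeminy detection, SE classification."""

import numpy as np
import pytest

from conftest import make_episode, suction, vent
from neosuction.config import AnalysisConfig
from neosuction.hr_response import (
    classify_cohort,
    classify_se,
    detect_bigeminy,
    detect_fall,
    pre_post_hr,
)
from neosuction.synthetic_cohort import ScenarioConfig, generate_cohort
from neosuction.types import BeatSeries, HRSample, ResponseLabel, SuctionEvent


def se_of(start, stop):
    return SuctionEvent.from_insertions([suction(start, stop)])


def series(pairs):
    return [HRSample(float(t), float(v)) for t, v in pairs]


class TestPrePostHR:
    def test_median_of_five_nearest(self, config):
        hr = series([(95, 150), (96, 148), (97, 152), (98, 151), (99, 149)])
        pre, post = pre_post_hr(hr, se_of(100, 110), config)
        assert pre == 150
        assert post is None

    def test_seven_in_window_uses_five_nearest_boundary(self, config):
        # two far-away low samples must be ignored in favour of the five
        # nearest the event start
        hr = series([(81, 10), (82, 10)] + [(t, 150) for t in range(95, 100)])
        pre, _ = pre_post_hr(hr, se_of(100, 110), config)
        assert pre == 150

    def test_below_minimum_sample_count_is_missing(self, config):
        hr = series([(98, 150), (99, 149), (115, 150), (116, 150)])
        pre, post = pre_post_hr(hr, se_of(100, 110), config)
        assert pre is None and post is None

    def test_three_samples_enough_for_median(self, config):
        hr = series([(97, 140), (98, 150), (99, 160), (111, 100), (112, 110), (113, 120)])
        pre, post = pre_post_hr(hr, se_of(100, 110), config)
        assert pre == 150 and post == 110


class TestDetectFall:
    def test_twenty_percent_dip_flags(self, config):
        hr = series([(t, 150) for t in range(95, 100)]
                    + [(102, 120), (103, 120), (104, 120)]
                    + [(t, 150) for t in range(106, 112)])
        flag, frac, interval = detect_fall(hr, se_of(100, 110), 150.0, [], config)
        assert flag and frac == pytest.approx(0.20)
        assert interval == (102, 104)

    def test_fall_below_threshold_not_flagged(self, config):
        # 14.7% fall: under the strict >15% rule
        hr = series([(102, 128), (103, 128), (104, 128)])
        flag, frac, _ = detect_fall(hr, se_of(100, 110), 150.0, [], config)
        assert not flag
        assert frac == pytest.approx((150 - 128) / 150)

    def test_concurrent_ventilation_suppresses(self, config):
        hr = series([(102, 110), (103, 110), (104, 110)])
        flag, _, _ = detect_fall(hr, se_of(100, 110), 150.0, [vent(101, 105)], config)
        assert not flag

    def test_single_sample_dip_is_not_a_fall(self, config):
        hr = series([(101, 150), (102, 110), (103, 150), (104, 150)])
        flag, _, _ = detect_fall(hr, se_of(100, 110), 150.0, [], config)
        assert not flag

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_window_scan(self, seed, config):
        """Without ventilation, the run detector must agree with an
        exhaustive scan over all contiguous sample windows."""
        rng = np.random.default_rng(seed)
        t = np.arange(90, 140.0)
        hr = series(zip(t, rng.uniform(100, 160, size=t.size)))
        se = se_of(100, 110)
        pre = 150.0
        flag, frac, _ = detect_fall(hr, se, pre, [], config)
        thresh = pre * (1 - config.fall_fraction)
        window = [s for s in hr if se.start_s <= s.t_s <= se.stop_s + 20]
        brute = False
        brute_depth = None
        for i in range(len(window)):
            for j in range(i + config.fall_min_samples - 1, len(window)):
                seg = window[i : j + 1]
                if all(s.hr_bpm < thresh for s in seg):
                    brute = True
                    depth = max((pre - s.hr_bpm) / pre for s in seg)
                    brute_depth = max(brute_depth or 0.0, depth)
        assert flag == brute
        if brute:
            assert frac == pytest.approx(brute_depth)


class TestBigeminy:
    @staticmethod
    def beats_from_rr(rr, t0=100.0):
        times = [t0]
        for d in rr:
            times.append(times[-1] + d)
        return BeatSeries(times)

    def test_alternating_ratio_two_detected(self):
        b = self.beats_from_rr([0.3, 0.6] * 5)
        assert detect_bigeminy(b, (100, 130))

    def test_constant_rr_not_detected(self):
        b = self.beats_from_rr([0.45] * 12)
        assert not detect_bigeminy(b, (100, 130))

    def test_ratio_below_threshold_not_detected(self):
        b = self.beats_from_rr([0.40, 0.50] * 6)
        assert not detect_bigeminy(b, (100, 130))

    def test_fewer_than_eight_beats_insufficient(self):
        b = self.beats_from_rr([0.3, 0.6] * 3)  # 7 beats
        assert not detect_bigeminy(b, (100, 130))

    def test_no_beats_is_false(self):
        assert not detect_bigeminy(None, (0, 100))


class TestClassifySE:
    def flat(self, level=150.0):
        return series([(t, level) for t in range(0, 200)])

    def test_vent_cessation_takes_precedence(self, config):
        hr = series(
            [(t, 150) for t in range(80, 100)]
            + [(t, 112) for t in range(100, 112)]
            + [(t, 150) for t in range(112, 140)]
        )
        ep = make_episode(events=[vent(60, 98), suction(100, 110)], hr=hr)
        resp = classify_se(ep, se_of(100, 110), config)
        assert resp.label is ResponseLabel.VENT_CESSATION_FALL
        assert resp.ventilation_prior

    def test_plain_fall_is_suction_related(self, config):
        hr = series(
            [(t, 150) for t in range(80, 100)]
            + [(t, 120) for t in range(100, 112)]
            + [(t, 150) for t in range(112, 140)]
        )
        ep = make_episode(events=[suction(100, 110)], hr=hr)
        resp = classify_se(ep, se_of(100, 110), config)
        assert resp.label is ResponseLabel.SUCTION_RELATED_FALL
        assert resp.fall_fraction_observed > config.fall_fraction

    def test_flat_hr_is_no_change(self, config):
        ep = make_episode(events=[suction(100, 110)], hr=self.flat())
        resp = classify_se(ep, se_of(100, 110), config)
        assert resp.label is ResponseLabel.NO_CHANGE
        assert resp.delta_hr_bpm == pytest.approx(0.0)

    def test_missing_pre_yields_indeterminate(self, config):
        ep = make_episode(events=[suction(100, 110)], hr=series([(150, 150)]))
        resp = classify_se(ep, se_of(100, 110), config)
        assert resp.label is ResponseLabel.INDETERMINATE

    def test_arrhythmia_detected_despite_missing_post(self, config):
        beats = TestBigeminy.beats_from_rr([0.3, 0.6] * 10, t0=101.0)
        hr = series([(t, 150) for t in range(80, 100)])
        ep = make_episode(events=[suction(100, 110)], hr=hr, beats=beats)
        resp = classify_se(ep, se_of(100, 110), config)
        assert resp.label is ResponseLabel.SUCTION_RELATED_ARRHYTHMIA

    def test_raising_fall_threshold_never_creates_falls(self, config):
        """Monotonicity: a stricter fall threshold cannot increase the
        number of detected suction-related falls."""
        episodes, _ = generate_cohort(ScenarioConfig(n_newborns=25, seed=5))
        counts = []
        for frac in (0.10, 0.15, 0.20, 0.30):
            cfg = AnalysisConfig(fall_fraction=frac)
            cls = classify_cohort(episodes, cfg)
            counts.append(
                sum(lab is ResponseLabel.SUCTION_RELATED_FALL for lab in cls.labels)
            )
        assert counts == sorted(counts, reverse=True)


class TestClassifyCohort:
    def test_complete_cohort_has_no_exclusions(self, small_cohort, config):
        episodes, _ = small_cohort
        cls = classify_cohort(episodes, config)
        assert cls.excluded_ids == []
        assert set(lab.value for lab in cls.labels) <= {
            l.value for l in ResponseLabel
        }

    def test_empty_hr_series_excludes_episode(self, config):
        ep = make_episode(events=[suction(100, 110)], hr=[])
        cls = classify_cohort([ep], config)
        assert cls.excluded_ids == [ep.newborn_id]
        assert cls.responses == []
        assert any("no usable HR coverage" in n for n in cls.notes)

    def test_truth_recovery_with_default_noise(self):
        """Detected labels must match planted truth with sensitivity and
        specificity >= 0.95 for suction-related changes."""
        episodes, truths = generate_cohort(ScenarioConfig(n_newborns=100, seed=31))
        cls = classify_cohort(episodes)
        truth_by = {
            (t.newborn_id, round(s.start_s, 6)): s.label
            for t in truths
            for s in t.se_truths
        }
        tp = fn = fp = tn = 0
        for nid, r in cls.responses:
            t = truth_by[(nid, round(r.se.start_s, 6))]
            if t.suction_related:
                tp += r.label.suction_related
                fn += not r.label.suction_related
            else:
                fp += r.label.suction_related
                tn += not r.label.suction_related
        assert tp + fn > 10
        assert tp / (tp + fn) >= 0.95
        assert tn / (tn + fp) >= 0.95

    def test_below_threshold_planted_falls_are_not_detected(self):
        """Falls planted at 10% (below the 15% rule) must yield zero
        suction-related fall detections on a noiseless cohort."""
        sc = ScenarioConfig(
            n_newborns=40, seed=8, planted_fall_fraction=0.10,
            hr_noise_sd_bpm=1e-9, p_missing_hr=0.0,
            p_vent_cessation_change=0.0,
        )
        episodes, truths = generate_cohort(sc)
        cls = classify_cohort(episodes)
        assert not any(
            lab is ResponseLabel.SUCTION_RELATED_FALL for lab in cls.labels
        )
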