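import itertools

import numpy as np
import pytest

from fetaltdi.core import ROISpec, VelocityTrace
from fetaltdi.events import (
    AnalysisConfig,
    EventTemplate,
    InsufficientShiftsError,
    ShiftCandidate,
    TemplateMismatchError,
    analyze_trace,
    assign_events,
    detect_shifts,
    segment_cycle,
)
from fetaltdi.core import AccelerationTrace
from fetaltdi.synthetic import HeartModelParams, generate_dataset, generate_trace


RATE = 190.0


def acc_from(samples, rate=200.0):
    return AccelerationTrace("a", rate, np.asarray(samples, float), source_trace_label="x")


class TestDetectShifts:
    def test_cosine_one_period(self):
        rate = 200.0
        t = np.arange(0, 1.0, 1 / rate)
        acc = acc_from(np.cos(2 * np.pi * t), rate)
        cands = detect_shifts(acc, (0.0, 1.0))
        crossings = [c for c in cands if c.kind == "zero_crossing"]
        extrema = [c for c in cands if c.kind == "local_extremum"]
        assert len(crossings) == 2
        assert len(extrema) == 2
        np.testing.assert_allclose(sorted(c.time for c in crossings), [0.25, 0.75], atol=1 / rate)

    def test_zero_acceleration_empty(self):
        acc = acc_from(np.zeros(100))
        assert detect_shifts(acc, (0.0, 0.4)) == []

    def test_empty_window_rejected(self):
        acc = acc_from(np.ones(100))
        with pytest.raises(ValueError):
            detect_shifts(acc, (0.3, 0.3))

    def test_candidates_cover_ground_truth(self, clean_trace, clean_pipeline):
        _, truth = clean_trace
        _, _, acc = clean_pipeline
        seg = truth[2]
        cands = detect_shifts(acc, (seg.cycle_start, seg.cycle_end))
        assert len(cands) >= 10
        times = np.array([c.time for c in cands])
        for b in seg.boundaries[1:]:
            assert np.min(np.abs(times - b)) <= 1.0 / RATE + 1e-9

    def test_time_ordered(self, clean_pipeline):
        _, _, acc = clean_pipeline
        cands = detect_shifts(acc, (0.1, 1.2))
        times = [c.time for c in cands]
        assert times == sorted(times)


def brute_force_assignment(cands, cycle_start, period, template):
    """Exhaustive minimum over all feasible ordered 5-subsets (events 2-6)."""
    fr = [(c.time - cycle_start) / period for c in cands]
    priors = template.prior_fractions[1:]
    tols = template.tolerance[1:]
    best = None
    for combo in itertools.combinations(range(len(cands)), 5):
        if any(not (0 < fr[j] < 1) for j in combo):
            continue
        if any(abs(fr[j] - priors[e]) > tols[e] for e, j in enumerate(combo)):
            continue
        times = [cands[j].time for j in combo]
        if any(b <= a for a, b in zip(times, times[1:])):
            continue
        cost = sum((fr[j] - priors[e]) ** 2 for e, j in enumerate(combo))
        if best is None or cost < best:
            best = cost
    return best


class TestAssignment:
    def _random_candidates(self, rng, n, start=0.0, period=1.0):
        times = np.sort(rng.uniform(start + 0.01, start + period - 0.01, n))
        times += np.arange(n) * 1e-9  # ensure strictly distinct
        return [
            ShiftCandidate(
                time=float(t),
                kind=rng.choice(["zero_crossing", "local_extremum"]),
                magnitude=float(rng.uniform(0, 10)),
                sign=int(rng.choice([-1, 1])),
                index=i,
            )
            for i, t in enumerate(times)
        ]

    def test_fixed_point_at_priors(self):
        template = EventTemplate()
        cands = [
            ShiftCandidate(time=f, kind="local_extremum", magnitude=1.0, sign=1, index=i)
            for i, f in enumerate(template.prior_fractions[1:])
        ]
        sel = assign_events(cands, 0.0, 1.0, template)
        assert sel == [0, 1, 2, 3, 4]
        cost = sum(
            ((cands[j].time - p) ** 2) for j, p in zip(sel, template.prior_fractions[1:])
        )
        assert cost == pytest.approx(0.0, abs=1e-18)

    @pytest.mark.parametrize("n", [6, 8, 10, 12])
    def test_matches_brute_force(self, n):
        template = EventTemplate(tolerance=(0.2,) * 6)
        rng = np.random.default_rng(n)
        agree = 0
        for _ in range(40):
            cands = self._random_candidates(rng, n)
            sel = assign_events(cands, 0.0, 1.0, template)
            brute = brute_force_assignment(cands, 0.0, 1.0, template)
            if sel is None:
                assert brute is None
            else:
                cost = sum(
                    (cands[j].time - p) ** 2
                    for j, p in zip(sel, template.prior_fractions[1:])
                )
                assert brute is not None
                assert cost == pytest.approx(brute, abs=1e-12)
                agree += 1
        assert agree > 0  # at least some feasible instances exercised

    def test_infeasible_returns_none(self):
        template = EventTemplate(tolerance=(0.01,) * 6)
        cands = [
            ShiftCandidate(time=0.5, kind="zero_crossing", magnitude=1.0, sign=1, index=0)
        ] * 6
        assert assign_events(cands, 0.0, 1.0, template) is None


class TestSegmentCycle:
    def test_noise_free_recovery(self, clean_trace, clean_pipeline):
        _, truth = clean_trace
        _, filt, acc = clean_pipeline
        for seg_gt in truth[1:6]:
            seg = segment_cycle(filt, acc, (seg_gt.cycle_start, seg_gt.cycle_end))
            errs = np.abs(np.array(seg.boundaries) - np.array(seg_gt.boundaries)) * RATE
            assert errs.max() <= 1.0 + 1e-6

    def test_insufficient_candidates(self):
        rate = 200.0
        t = np.arange(0, 1.0, 1 / rate)
        vel = VelocityTrace("x", rate, np.sin(2 * np.pi * t))
        acc = acc_from(np.cos(2 * np.pi * t), rate)  # only 4 candidates
        with pytest.raises(InsufficientShiftsError):
            segment_cycle(vel, acc, (0.0, 1.0))

    def test_template_mismatch(self, clean_trace, clean_pipeline):
        _, truth = clean_trace
        _, filt, acc = clean_pipeline
        seg_gt = truth[2]
        bad = EventTemplate(
            prior_fractions=(0.0, 0.4, 0.45, 0.5, 0.55, 0.6), tolerance=(0.001,) * 6
        )
        with pytest.raises(TemplateMismatchError):
            segment_cycle(filt, acc, (seg_gt.cycle_start, seg_gt.cycle_end), bad)

    def test_segmentation_invariants(self, clean_trace, clean_pipeline):
        _, truth = clean_trace
        _, filt, acc = clean_pipeline
        seg_gt = truth[3]
        seg = segment_cycle(filt, acc, (seg_gt.cycle_start, seg_gt.cycle_end))
        b = np.array(seg.boundaries)
        assert np.all(np.diff(b) > 0)
        assert seg.durations_s().sum() == pytest.approx(seg.cycle_length, abs=1e-12)


class TestAnalyzeTrace:
    def test_noise_free_success(self, clean_trace):
        trace, truth = clean_trace
        res = analyze_trace(trace)
        assert res.success
        assert res.filter_setting_used == 1
        assert len(res.segmentations) == len(truth)
        assert res.acceleration_score == 3

    def test_pure_noise_fails_no_periodicity(self):
        rng = np.random.default_rng(1)
        tr = VelocityTrace("x", RATE, rng.normal(0, 1, 700))
        res = analyze_trace(tr)
        assert not res.success
        assert res.failure_reason == "no_periodicity"
        assert res.segmentations == []

    def test_degenerate_input(self):
        tr = VelocityTrace("x", RATE, np.zeros(2))
        res = analyze_trace(tr)
        assert not res.success
        assert res.failure_reason == "degenerate_input"

    def test_success_fraction_non_increasing_in_noise(self):
        fracs = []
        for sd in (0.0, 2.0, 8.0):
            batch = generate_dataset(8, [sd], 38.0, seed=21)
            ok = sum(analyze_trace(t).success for t, _ in batch)
            fracs.append(ok / len(batch))
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_invert_flag_symmetry(self, clean_trace):
        trace, _ = clean_trace
        ref = analyze_trace(trace)
        flipped = trace.with_samples(-trace.samples)
        res = analyze_trace(flipped, AnalysisConfig(invert=True))
        assert res.success and ref.success
        assert res.peak_velocities == ref.peak_velocities
        assert [s.boundaries for s in res.segmentations] == [
            s.boundaries for s in ref.segmentations
        ]

    def test_config_from_yaml(self, tmp_path):
        cfg_file = tmp_path / "cfg.yaml"
        cfg_file.write_text(
            "smooth: {default_window: 5}\n"
            "filter: {windows: [3, 5, 7, 9]}\n"
            "cycle: {bpm_range: [90, 200], min_confidence: 0.4}\n"
            "template: {tolerance: 0.1}\n"
            "quality: {flat_threshold: 0.55}\n"
            "invert: true\n"
        )
        cfg = AnalysisConfig.from_yaml(str(cfg_file))
        assert cfg.smooth_window == 5
        assert cfg.bpm_range == (90.0, 200.0)
        assert cfg.template.tolerance == (0.1,) * 6
        assert cfg.quality.flat_threshold == 0.55
        assert cfg.invert is True
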