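"""Trial segmentation, stimulus reordering, latency, and QC flags."""

import numpy as np
import pytest

from mtpipe.errors import DataError
from mtpipe.raw_io import ExportDialect, RawSubjectRecord, join_stream
from mtpipe.simulate import SimConfig, simulate_dataset
from mtpipe.trial_builder import (
    Geometry,
    apply_exclusions,
    compute_latency,
    decode_alert_token,
    flag_subject,
    reorder_by_stimulus,
    segment_trials,
)

from conftest import make_trial


def record_from_streams(xs, ys, ts, on_ready, button_click, n_trials=None,
                        **kw):
    d = ExportDialect(n_trials_expected=n_trials or len(on_ready))
    n = len(on_ready)
    rec = RawSubjectRecord(
        subject_id="S1",
        x_stream=join_stream(xs, d),
        y_stream=join_stream(ys, d),
        t_stream=join_stream(ts, d),
        on_ready_times=join_stream(on_ready, d),
        button_click_times=join_stream(button_click, d),
        window_widths=join_stream([1500] * n, d),
        window_heights=join_stream([900] * n, d),
        alerts_stream=join_stream([0] * n, d),
        latency_stream=join_stream([100] * n, d),
        stimulus_order=";".join(f"T{j + 1}" for j in range(n)),
        **kw,
    )
    return rec, d


class TestSegmentation:
    def test_disjoint_windows_assign_their_own_samples(self):
        ts = [1000, 1500, 2000, 3000, 3500, 4000]
        rec, d = record_from_streams(
            xs=range(6), ys=range(6), ts=ts,
            on_ready=[1000, 3000], button_click=[2000, 4000])
        seg = segment_trials(rec, d)
        assert [t.n_samples for t in seg.trials] == [3, 3]
        assert seg.n_dropped_samples == 0
        assert seg.defects == []
        assert list(seg.trials[0].ts) == [1000, 1500, 2000]
        assert list(seg.trials[1].ts) == [3000, 3500, 4000]

    def test_sample_outside_every_window_is_dropped(self):
        rec, d = record_from_streams(
            xs=range(5), ys=range(5), ts=[1000, 2000, 2500, 3000, 4000],
            on_ready=[1000, 3000], button_click=[2000, 4000])
        seg = segment_trials(rec, d)
        assert seg.n_dropped_samples == 1
        assert sum(t.n_samples for t in seg.trials) + 1 == seg.n_parsed_samples

    def test_boundary_samples_belong_to_the_trial(self):
        rec, d = record_from_streams(
            xs=[0, 1], ys=[0, 1], ts=[1000, 2000],
            on_ready=[1000], button_click=[2000])
        seg = segment_trials(rec, d)
        assert seg.trials[0].n_samples == 2

    def test_segmentation_matches_simulator_counts(self, clean_cohort):
        cfg, records, truth = clean_cohort
        d = ExportDialect(n_trials_expected=cfg.n_trials)
        for rec in records:
            seg = segment_trials(rec, d)
            expected = truth.for_subject(rec.subject_id)
            assert [t.n_samples for t in seg.trials] == list(expected["n_samples"])
            assert seg.n_dropped_samples == 0

    def test_stream_length_mismatch_is_flagged_not_fatal(self):
        rec, d = record_from_streams(
            xs=range(4), ys=range(5), ts=[1000, 1200, 1400, 1600, 1800],
            on_ready=[1000], button_click=[1800])
        seg = segment_trials(rec, d)
        assert "stream_length_mismatch" in seg.defects

    def test_missing_streams_flag_missing_trajectory(self):
        rec, d = record_from_streams(
            xs=[], ys=[], ts=[], on_ready=[1000], button_click=[1800])
        seg = segment_trials(rec, d)
        assert "missing_trajectory" in seg.defects
        assert seg.trials[0].n_samples == 0

    def test_nonmonotone_time_is_flagged(self):
        rec, d = record_from_streams(
            xs=range(3), ys=range(3), ts=[1000, 1500, 1200],
            on_ready=[1000], button_click=[1600])
        seg = segment_trials(rec, d)
        assert "nonmonotone_time" in seg.defects

    def test_wrong_trial_count_is_flagged(self):
        rec, d = record_from_streams(
            xs=range(2), ys=range(2), ts=[1000, 1500],
            on_ready=[1000], button_click=[1500], n_trials=3)
        seg = segment_trials(rec, d)
        assert "wrong_trial_count" in seg.defects


class TestReorder:
    def _trials(self, order):
        return [make_trial([0, 1], [0, 1], [1000 * (i + 1), 1000 * (i + 1) + 10],
                           stimulus_id=s, presented_index=i + 1)
                for i, s in enumerate(order)]

    def test_permutation_inverse(self):
        trials = self._trials(["S3", "S1", "S2"])
        out = reorder_by_stimulus(trials, ["S1", "S2", "S3"])
        assert [t.stimulus_id for t in out] == ["S1", "S2", "S3"]
        assert [t.presented_index for t in out] == [2, 3, 1]

    def test_identity_order_unchanged(self):
        trials = self._trials(["S1", "S2", "S3"])
        out = reorder_by_stimulus(trials, ["S1", "S2", "S3"])
        assert [t.presented_index for t in out] == [1, 2, 3]

    def test_random_permutations_are_pure_permutations(self):
        rng = np.random.default_rng(4)
        canonical = [f"S{i}" for i in range(8)]
        for _ in range(25):
            order = list(rng.permutation(canonical))
            trials = self._trials(order)
            out = reorder_by_stimulus(trials, canonical)
            assert [t.stimulus_id for t in out] == canonical
            # same trial objects, just permuted
            assert sorted(id(t) for t in out) == sorted(id(t) for t in trials)
            # applying the recorded presentation order restores the input
            restored = reorder_by_stimulus(out, order)
            assert [t.presented_index for t in restored] == list(range(1, 9))

    def test_unknown_stimulus_raises(self):
        trials = self._trials(["S1", "S9"])
        with pytest.raises(DataError, match="S0001"):
            reorder_by_stimulus(trials, ["S1", "S2"])

    def test_duplicate_stimulus_raises(self):
        trials = self._trials(["S1", "S1"])
        with pytest.raises(DataError, match="duplicate"):
            reorder_by_stimulus(trials, ["S1", "S2"])


class TestLatency:
    def test_stationary_cursor_has_no_latency(self):
        trial = make_trial([5, 5, 5], [7, 7, 7], [1000, 1017, 1034])
        assert compute_latency(trial) is None

    def test_first_position_change_defines_latency(self):
        trial = make_trial([5, 5, 6], [7, 7, 7], [1000, 1221, 1442])
        assert compute_latency(trial) == 442

    def test_simulator_first_move_recovered_exactly(self, clean_cohort):
        cfg, records, truth = clean_cohort
        d = ExportDialect(n_trials_expected=cfg.n_trials)
        for rec in records:
            seg = segment_trials(rec, d)
            expected = list(truth.for_subject(rec.subject_id)["first_move_ms"])
            got = [compute_latency(t) for t in seg.trials]
            assert got == expected


class TestFlags:
    def _subject(self, dx_values, **kw):
        trials = [
            make_trial([500, 500 + dx], [600, 128], [1000 * i, 1000 * i + 900],
                       stimulus_id=f"T{i}", window_width=1500, window_height=900)
            for i, dx in enumerate(dx_values, start=1)
        ]
        from mtpipe.trial_builder import SegmentedSubject
        return SegmentedSubject(subject_id="S1", trials=trials,
                                n_parsed_samples=2 * len(trials), **kw)

    def test_expected_displacement_is_not_weird(self):
        flags = flag_subject(self._subject([285, -285]), Geometry())
        assert not flags.weird_scaling
        assert not flags.exclude

    def test_small_displacement_is_weird(self):
        flags = flag_subject(self._subject([285, 100]), Geometry())
        assert flags.weird_scaling
        # weird scaling alone never excludes
        assert not flags.exclude

    def test_band_edges_are_inclusive(self):
        g = Geometry()  # band is 285 * (1 +/- 0.25) = [213.75, 356.25]
        assert not flag_subject(self._subject([213.75]), g).weird_scaling
        assert not flag_subject(self._subject([356.25]), g).weird_scaling
        assert flag_subject(self._subject([213.7]), g).weird_scaling
        assert flag_subject(self._subject([356.3]), g).weird_scaling

    def test_small_window_sets_wts_not_exclude(self):
        seg = self._subject([285])
        seg.trials[0].window_width = 640
        flags = flag_subject(seg, Geometry())
        assert flags.wts and not flags.exclude

    def test_window_alert_code_sets_wts(self):
        seg = self._subject([285])
        seg.trials[0].alert_codes = frozenset({4})
        assert flag_subject(seg, Geometry()).wts

    def test_defects_exclude_under_conservative_policy(self):
        seg = self._subject([285])
        seg.defects.append("missing_trajectory")
        flags = flag_subject(seg, Geometry())
        assert flags.exclude and "missing_trajectory" in flags.reasons

    def test_adding_defective_trial_never_clears_flags(self):
        seg = self._subject([100])
        before = flag_subject(seg, Geometry())
        seg.trials.append(make_trial([5, 5], [5, 5], [9000, 9001]))
        seg.defects.append("missing_trajectory")
        after = flag_subject(seg, Geometry())
        assert after.weird_scaling >= before.weird_scaling
        assert set(before.reasons) <= set(after.reasons)

    def test_clean_simulated_cohort_has_no_flags(self, clean_cohort):
        cfg, records, truth = clean_cohort
        d = ExportDialect(n_trials_expected=cfg.n_trials)
        for rec in records:
            flags = flag_subject(segment_trials(rec, d), cfg.geometry)
            assert not flags.exclude
            assert not flags.weird_scaling
            assert not flags.wts


class TestExclusions:
    def _flags(self, n_clean, n_bad, intact_for_bad=8):
        from mtpipe.trial_builder import QCFlags
        return [
            QCFlags(subject_id=f"S{i}", exclude=False, reasons=[],
                    weird_scaling=False, wts=False, per_trial_alert_counts={},
                    n_intact_trials=10, n_trials=10)
            for i in range(n_clean)
        ] + [
            QCFlags(subject_id=f"B{i}", exclude=True,
                    reasons=["missing_trajectory"], weird_scaling=False,
                    wts=False, per_trial_alert_counts={},
                    n_intact_trials=intact_for_bad, n_trials=10)
            for i in range(n_bad)
        ]

    def test_conservative_drops_any_defect(self):
        report = apply_exclusions(self._flags(9, 1), "conservative")
        assert len(report.kept_ids) == 9
        assert report.excluded == {"B0": ["missing_trajectory"]}

    def test_permissive_keeps_subjects_with_intact_trials(self):
        report = apply_exclusions(self._flags(9, 1, intact_for_bad=8),
                                  "permissive")
        assert len(report.kept_ids) == 10

    def test_permissive_drops_fully_lost_subjects(self):
        report = apply_exclusions(self._flags(9, 1, intact_for_bad=0),
                                  "permissive")
        assert len(report.kept_ids) == 9


def test_decode_alert_token_handles_multi_codes():
    assert decode_alert_token(0) == frozenset()
    assert decode_alert_token(2) == frozenset({2})
    assert decode_alert_token(23) == frozenset({2, 3})
    assert decode_alert_token(124) == frozenset({1, 2, 4})
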