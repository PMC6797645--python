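"""Per-subject trial assembly and quality control.

Turns one subject's raw streams into per-trial trajectories by
assigning each (x, y, t) sample to the trial whose
``[onReady, buttonClick]`` window contains its timestamp, undoes the
randomized stimulus presentation order, and applies the QC rules that
flag subjects for exclusion or mark display idiosyncrasies
(``weird_scaling`` for non-standard pixel scaling such as browser zoom,
``wts`` for a too-small browser window).

QC never raises on bad data: defects become reasons on
:class:`QCFlags`, and the exclusion policy decides who is dropped.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

log = logging.getLogger("mtpipe")

from .errors import DataError
from .raw_io import (
    ExportDialect,
    RawSubjectRecord,
    parse_separated_stream,
    split_text_stream,
)

__all__ = [
    "Geometry",
    "TrialTrajectory",
    "SegmentedSubject",
    "QCFlags",
    "ExclusionReport",
    "segment_trials",
    "reorder_by_stimulus",
    "compute_latency",
    "flag_subject",
    "apply_exclusions",
    "decode_alert_token",
]

#: QC defect reason labels
MISSING_TRAJECTORY = "missing_trajectory"
STREAM_LENGTH_MISMATCH = "stream_length_mismatch"
NONMONOTONE_TIME = "nonmonotone_time"
WRONG_TRIAL_COUNT = "wrong_trial_count"

ALERT_STARTED_TOO_EARLY = 1
ALERT_STARTED_TOO_LATE = 2
ALERT_TIME_LIMIT = 3
ALERT_WINDOW_TOO_SMALL = 4


@dataclass(frozen=True)
class Geometry:
    """Pixel geometry of the experiment interface.

    The two category buttons sit ``button_separation_x`` px apart, and
    the Next button — where the cursor starts every trial — is centred
    between them, ``next_to_buttons_y`` px below.  A trial's expected
    horizontal displacement is therefore half the button separation;
    displacements outside ``(1 ± scaling_tolerance)`` of that value
    indicate non-standard pixel scaling (e.g. browser zoom).
    """

    button_separation_x: float = 570.0
    next_to_buttons_y: float = 472.0
    scaling_tolerance: float = 0.25
    min_window_width: float = 800.0
    min_window_height: float = 600.0

    def __post_init__(self):
        if min(self.button_separation_x, self.next_to_buttons_y,
               self.min_window_width, self.min_window_height) <= 0:
            raise ValueError("geometry dimensions must be positive")
        if not 0 < self.scaling_tolerance < 1:
            raise ValueError("scaling_tolerance must be in (0, 1)")

    @property
    def expected_half_separation(self) -> float:
        return self.button_separation_x / 2.0


@dataclass
class TrialTrajectory:
    """One trial's cursor samples in raw pixel / epoch-ms units."""

    subject_id: str
    presented_index: int  # 1-based position in presentation order
    stimulus_id: str
    xs: np.ndarray
    ys: np.ndarray
    ts: np.ndarray
    on_ready: float
    button_click: float
    chosen_category: str = ""
    alert_codes: frozenset[int] = frozenset()
    latency_recorded: float | None = None
    window_width: float | None = None
    window_height: float | None = None

    @property
    def n_samples(self) -> int:
        return len(self.ts)


@dataclass
class SegmentedSubject:
    """Segmentation output: trials in presented order plus bookkeeping."""

    subject_id: str
    trials: list[TrialTrajectory]
    n_parsed_samples: int = 0
    n_dropped_samples: int = 0
    defects: list[str] = field(default_factory=list)


@dataclass
class QCFlags:
    """Subject-level QC summary.

    ``exclude`` reflects the conservative default (any defect reason
    excludes); ``weird_scaling`` and ``wts`` are analysis covariates,
    not exclusion reasons.
    """

    subject_id: str
    exclude: bool
    reasons: list[str]
    weird_scaling: bool
    wts: bool
    per_trial_alert_counts: dict[int, int]
    n_intact_trials: int
    n_trials: int = 0
    n_trials_with_alerts: int = 0
    n_dropped_samples: int = 0

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "exclude": self.exclude,
            "reasons": list(self.reasons),
            "weird_scaling": self.weird_scaling,
            "wts": self.wts,
            "alert_counts": {str(k): v for k, v in
                             sorted(self.per_trial_alert_counts.items())},
            "n_intact_trials": self.n_intact_trials,
            "n_dropped_samples": self.n_dropped_samples,
        }


@dataclass
class ExclusionReport:
    policy: str
    kept_ids: list[str]
    excluded: dict[str, list[str]]

    def to_dict(self) -> dict:
        return {
            "policy": self.policy,
            "n_kept": len(self.kept_ids),
            "n_excluded": len(self.excluded),
            "kept_ids": list(self.kept_ids),
            "excluded": {k: list(v) for k, v in self.excluded.items()},
        }


def decode_alert_token(token: float) -> frozenset[int]:
    """Decode one per-trial alert token into a set of alert codes.

    A trial can trigger several alerts; they are recorded as the
    concatenated digits of the codes (``0`` = none, ``23`` = codes 2
    and 3).
    """
    digits = {int(d) for d in str(int(token))}
    return frozenset(d for d in digits if d != 0)


def encode_alert_codes(codes: Iterable[int]) -> int:
    codes = sorted(set(codes))
    if not codes:
        return 0
    return int("".join(str(c) for c in codes))


def _per_trial(values: list, j: int, default=None):
    return values[j] if j < len(values) else default


def segment_trials(
    record: RawSubjectRecord, dialect: ExportDialect | None = None
) -> SegmentedSubject:
    """Split one subject's streams into per-trial trajectories.

    Each parsed (x, y, t) triplet is assigned to the first trial ``j``
    with ``on_ready_j <= t <= button_click_j`` (closed interval: the
    boundary samples are the trial onset and the click itself).
    Samples falling in no window are dropped and counted.  Structural
    problems (missing streams, unequal stream lengths, wrong trial
    count, non-monotone timestamps) are recorded as defects, never
    raised.
    """
    dialect = dialect or ExportDialect()
    sid = record.subject_id
    defects: list[str] = []

    xs = parse_separated_stream(record.x_stream, dialect, subject_id=sid, column="x")
    ys = parse_separated_stream(record.y_stream, dialect, subject_id=sid, column="y")
    ts = parse_separated_stream(record.t_stream, dialect, subject_id=sid, column="t")
    if not (len(xs) == len(ys) == len(ts)):
        defects.append(STREAM_LENGTH_MISMATCH)
        n = min(len(xs), len(ys), len(ts))
        xs, ys, ts = xs[:n], ys[:n], ts[:n]
    xs_a, ys_a, ts_a = (np.asarray(v, dtype=float) for v in (xs, ys, ts))

    on_ready = parse_separated_stream(
        record.on_ready_times, dialect, subject_id=sid, column="on_ready")
    button_click = parse_separated_stream(
        record.button_click_times, dialect, subject_id=sid, column="button_click")
    widths = parse_separated_stream(
        record.window_widths, dialect, subject_id=sid, column="window_width")
    heights = parse_separated_stream(
        record.window_heights, dialect, subject_id=sid, column="window_height")
    alerts = parse_separated_stream(
        record.alerts_stream, dialect, subject_id=sid, column="alerts")
    latency = parse_separated_stream(
        record.latency_stream, dialect, subject_id=sid, column="latency")
    stimuli = split_text_stream(record.stimulus_order, dialect)
    categories = split_text_stream(record.chosen_categories, dialect)

    n_trials = min(len(on_ready), len(button_click))
    if (len(on_ready) != len(button_click)
            or n_trials != dialect.n_trials_expected
            or len(stimuli) not in (0, n_trials)):
        defects.append(WRONG_TRIAL_COUNT)

    trials: list[TrialTrajectory] = []
    assigned = np.zeros(len(ts_a), dtype=bool)
    for j in range(n_trials):
        t0, t1 = on_ready[j], button_click[j]
        mask = (ts_a >= t0) & (ts_a <= t1) & ~assigned
        assigned |= mask
        t_trial = ts_a[mask]
        if len(t_trial) == 0:
            if MISSING_TRAJECTORY not in defects:
                defects.append(MISSING_TRAJECTORY)
        elif np.any(np.diff(t_trial) < 0):
            if NONMONOTONE_TIME not in defects:
                defects.append(NONMONOTONE_TIME)
        tok = _per_trial(alerts, j, 0.0)
        trials.append(TrialTrajectory(
            subject_id=sid,
            presented_index=j + 1,
            stimulus_id=_per_trial(stimuli, j, f"trial{j + 1:02d}"),
            xs=xs_a[mask],
            ys=ys_a[mask],
            ts=t_trial,
            on_ready=t0,
            button_click=t1,
            chosen_category=_per_trial(categories, j, ""),
            alert_codes=decode_alert_token(tok),
            latency_recorded=_per_trial(latency, j),
            window_width=_per_trial(widths, j),
            window_height=_per_trial(heights, j),
        ))

    return SegmentedSubject(
        subject_id=sid,
        trials=trials,
        n_parsed_samples=len(ts_a),
        n_dropped_samples=int(len(ts_a) - assigned.sum()),
        defects=defects,
    )


def reorder_by_stimulus(
    trials: Sequence[TrialTrajectory], canonical_order: Sequence[str]
) -> list[TrialTrajectory]:
    """Undo presentation-order randomization.

    Returns trials sorted into ``canonical_order`` with each trial's
    ``presented_index`` untouched, so the permutation stays
    recoverable.  Presented stimuli must match the canonical set
    exactly (no duplicates, no unknowns).
    """
    presented = [t.stimulus_id for t in trials]
    if len(set(presented)) != len(presented):
        dupes = sorted({s for s in presented if presented.count(s) > 1})
        sid = trials[0].subject_id if trials else "?"
        raise DataError(f"subject {sid}: duplicate stimulus IDs {dupes}")
    if set(presented) != set(canonical_order):
        sid = trials[0].subject_id if trials else "?"
        raise DataError(
            f"subject {sid}: presented stimuli {sorted(presented)} do not "
            f"match canonical set {sorted(canonical_order)}"
        )
    by_id = {t.stimulus_id: t for t in trials}
    return [by_id[s] for s in canonical_order]


def compute_latency(trial: TrialTrajectory) -> float | None:
    """Time from trial onset to the first cursor movement, in ms.

    The first movement is the first sample whose (x, y) differs from
    the trial's initial cursor position.  Returns ``None`` when the
    cursor never moves (absence is a value, not an error).
    """
    if trial.n_samples == 0:
        return None
    x0, y0 = trial.xs[0], trial.ys[0]
    moved = (trial.xs != x0) | (trial.ys != y0)
    idx = np.flatnonzero(moved)
    if len(idx) == 0:
        return None
    return float(trial.ts[idx[0]] - trial.on_ready)


def flag_subject(
    segmented: SegmentedSubject,
    geometry: Geometry | None = None,
    dialect: ExportDialect | None = None,
) -> QCFlags:
    """Apply the QC rules to one segmented subject.

    ``weird_scaling`` is true iff on any trial the absolute horizontal
    displacement ``|x_last - x_first|`` falls outside
    ``E * (1 ± tolerance)`` with ``E`` the expected half button
    separation.  ``wts`` is true iff any trial ran in a window smaller
    than the interface minimum or carries the window-too-small alert.
    Neither implies exclusion by itself; structural defects do.
    """
    geometry = geometry or Geometry()
    e = geometry.expected_half_separation
    lo = e * (1.0 - geometry.scaling_tolerance)
    hi = e * (1.0 + geometry.scaling_tolerance)

    weird = False
    wts = False
    alert_counts: Counter[int] = Counter()
    n_intact = 0
    n_with_alerts = 0
    for trial in segmented.trials:
        if trial.alert_codes:
            n_with_alerts += 1
        for code in trial.alert_codes:
            alert_counts[code] += 1
        if ALERT_WINDOW_TOO_SMALL in trial.alert_codes:
            wts = True
        if trial.window_width is not None and trial.window_width < geometry.min_window_width:
            wts = True
        if trial.window_height is not None and trial.window_height < geometry.min_window_height:
            wts = True
        if trial.n_samples >= 2:
            dx = abs(float(trial.xs[-1] - trial.xs[0]))
            if not (lo <= dx <= hi):
                weird = True
            if not np.any(np.diff(trial.ts) < 0):
                n_intact += 1
            # recorded vs recomputed latency: browser event timing
            # jitters, so disagreement is a warning, never a defect
            recomputed = compute_latency(trial)
            if (trial.latency_recorded is not None and recomputed is not None
                    and abs(recomputed - trial.latency_recorded) > 50):
                log.warning(
                    "subject %s trial %d: recorded latency %.0f ms differs "
                    "from recomputed %.0f ms",
                    segmented.subject_id, trial.presented_index,
                    trial.latency_recorded, recomputed)

    reasons = list(segmented.defects)
    return QCFlags(
        subject_id=segmented.subject_id,
        exclude=bool(reasons),
        reasons=reasons,
        weird_scaling=weird,
        wts=wts,
        per_trial_alert_counts=dict(alert_counts),
        n_intact_trials=n_intact,
        n_trials=len(segmented.trials),
        n_trials_with_alerts=n_with_alerts,
        n_dropped_samples=segmented.n_dropped_samples,
    )


def apply_exclusions(
    flags: Sequence[QCFlags], policy: str = "conservative"
) -> ExclusionReport:
    """Decide which subjects to keep.

    ``conservative`` drops any subject with a defect on any trial;
    ``permissive`` drops only subjects with zero intact trials.
    """
    if policy not in ("conservative", "permissive"):
        raise ValueError(f"unknown exclusion policy {policy!r}")
    kept: list[str] = []
    excluded: dict[str, list[str]] = {}
    for f in flags:
        if policy == "conservative":
            drop = bool(f.reasons)
        else:
            drop = f.n_intact_trials == 0
        if drop:
            excluded[f.subject_id] = list(f.reasons) or ["no_intact_trials"]
        else:
            kept.append(f.subject_id)
    return ExclusionReport(policy=policy, kept_ids=kept, excluded=excluded)
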