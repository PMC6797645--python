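"""Category-competition outcome measures for cursor trajectories.

Five trial-level measures quantify the competition between the two
response categories:

``xflips``
    number of horizontal direction reversals;
``xdev``
    maximum horizontal deviation from the ideal (straight) trajectory;
``area``
    Riemann-integrated area between the actual and ideal trajectories;
``maxspeed``
    peak cursor speed in raw px/ms;
``rt``
    reaction time (trial onset to category click) in ms.

``xflips``, ``xdev`` and ``area`` are computed on trajectories rescaled
to unit length on each axis, so they are unitless and comparable across
window sizes, zoom levels and screen resolutions.  The ideal trajectory
is the straight line from the trial's start position to its end
position, parametrized by the vertical coordinate (progress toward the
buttons); deviations are unsigned, so excursions on either side of the
line accumulate rather than cancel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, MeasureUndefined
from .trial_builder import (
    Geometry,
    QCFlags,
    SegmentedSubject,
    TrialTrajectory,
    compute_latency,
    encode_alert_codes,
)

__all__ = [
    "NormalizedTrajectory",
    "rescale_space",
    "rescale_time",
    "count_xflips",
    "max_x_deviation",
    "riemann_area",
    "max_speed",
    "reaction_time",
    "trial_measures",
    "measures_long_table",
]

#: column order of the long-format measures table
MEASURE_COLUMNS = [
    "subject_id", "stimulus_id", "presented_index", "ambiguous",
    "xflips", "xdev", "area", "maxspeed", "rt", "latency",
    "weird_scaling", "wts", "alerts",
]


@dataclass
class NormalizedTrajectory:
    """A trajectory min–max rescaled to the unit square.

    ``degenerate_x`` / ``degenerate_y`` mark axes whose raw range was
    zero (all values map to 0); time, when rescaled, runs 0 at trial
    onset to 1 at the category click.
    """

    xs: np.ndarray
    ys: np.ndarray
    ts: np.ndarray | None = None
    degenerate_x: bool = False
    degenerate_y: bool = False
    trial: TrialTrajectory | None = None

    @property
    def start(self) -> tuple[float, float]:
        return float(self.xs[0]), float(self.ys[0])

    @property
    def end(self) -> tuple[float, float]:
        return float(self.xs[-1]), float(self.ys[-1])


def _minmax(v: np.ndarray) -> tuple[np.ndarray, bool]:
    lo, hi = float(v.min()), float(v.max())
    if hi == lo:
        return np.zeros_like(v, dtype=float), True
    return (v - lo) / (hi - lo), False


def rescale_space(trial: TrialTrajectory) -> NormalizedTrajectory:
    """Min–max rescale each spatial axis onto [0, 1].

    Idempotent, and invariant to any per-axis affine map of the raw
    coordinates (so browser zoom and window position drop out).
    """
    if trial.n_samples < 2:
        raise MeasureUndefined(
            f"subject {trial.subject_id} stimulus {trial.stimulus_id}: "
            f"{trial.n_samples} sample(s), need >= 2"
        )
    xs, dx = _minmax(np.asarray(trial.xs, dtype=float))
    ys, dy = _minmax(np.asarray(trial.ys, dtype=float))
    return NormalizedTrajectory(xs=xs, ys=ys, degenerate_x=dx, degenerate_y=dy,
                                trial=trial)


def rescale_time(trial: TrialTrajectory) -> NormalizedTrajectory:
    """Rescale space and standardize time to trial fraction.

    ``t_norm = (t - on_ready) / (button_click - on_ready)`` clipped to
    [0, 1]; needed when trajectories are averaged across trials of
    different durations.
    """
    if trial.button_click <= trial.on_ready:
        raise MeasureUndefined(
            f"subject {trial.subject_id}: zero or negative trial duration"
        )
    norm = rescale_space(trial)
    tt = (np.asarray(trial.ts, dtype=float) - trial.on_ready) / (
        trial.button_click - trial.on_ready)
    norm.ts = np.clip(tt, 0.0, 1.0)
    return norm


def count_xflips(xs: Sequence[float], jitter_threshold: float = 0.0) -> int:
    """Count reversals of horizontal motion direction.

    Successive differences with ``|dx| <= jitter_threshold`` are
    discarded (a stationary cursor is not changing direction); a flip
    is a sign change between consecutive retained differences.
    """
    xs = np.asarray(xs, dtype=float)
    if len(xs) < 2:
        return 0
    dx = np.diff(xs)
    dx = dx[np.abs(dx) > jitter_threshold]
    if len(dx) < 2:
        return 0
    signs = np.sign(dx)
    return int(np.sum(signs[1:] != signs[:-1]))


def _ideal_line_x(norm: NormalizedTrajectory) -> np.ndarray:
    """Horizontal position of the ideal trajectory at each sample's y.

    The ideal trajectory is the straight line from start to end,
    parametrized by the vertical coordinate and extended linearly for
    samples whose y lies beyond the start/end range.
    """
    x0, y0 = norm.start
    x1, y1 = norm.end
    if y0 == y1:
        raise MeasureUndefined(
            "start and end share the same vertical coordinate; the ideal "
            "line cannot be parametrized by vertical progress"
        )
    return x0 + (x1 - x0) * (norm.ys - y0) / (y1 - y0)


def max_x_deviation(norm: NormalizedTrajectory) -> float:
    """Maximum horizontal deviation from the ideal trajectory (unitless)."""
    return float(np.max(np.abs(norm.xs - _ideal_line_x(norm))))


def riemann_area(norm: NormalizedTrajectory, method: str = "trapezoid") -> float:
    """Area between the actual and ideal trajectories (unitless).

    Unsigned horizontal deviations are integrated against vertical
    progress with a Riemann sum over successive samples: trapezoidal by
    default, or ``method="left"`` for left-endpoint rectangles.
    """
    d = np.abs(norm.xs - _ideal_line_x(norm))
    dy = np.abs(np.diff(norm.ys))
    if method == "trapezoid":
        return float(np.sum((d[:-1] + d[1:]) / 2.0 * dy))
    if method == "left":
        return float(np.sum(d[:-1] * dy))
    raise ValueError(f"unknown Riemann method {method!r}")


def max_speed(trial: TrialTrajectory) -> float:
    """Peak cursor speed in raw px/ms.

    Euclidean displacement over time step, maximized over consecutive
    sample pairs; pairs with zero time step are skipped.  Raw pixels
    are used deliberately — only the unit-rescaled measures are
    unitless.
    """
    if trial.n_samples < 2:
        raise MeasureUndefined("need >= 2 samples for speed")
    dt = np.diff(np.asarray(trial.ts, dtype=float))
    disp = np.hypot(np.diff(np.asarray(trial.xs, dtype=float)),
                    np.diff(np.asarray(trial.ys, dtype=float)))
    ok = dt > 0
    if not np.any(ok):
        raise MeasureUndefined("no strictly positive time increment")
    return float(np.max(disp[ok] / dt[ok]))


def reaction_time(trial: TrialTrajectory) -> float:
    """Trial onset (page loaded) to category-button click, in ms."""
    rt = float(trial.button_click - trial.on_ready)
    if rt < 0:
        raise DataError(
            f"subject {trial.subject_id}: button click precedes trial onset"
        )
    return rt


def trial_measures(
    trial: TrialTrajectory,
    jitter_threshold: float = 0.0,
    riemann_method: str = "trapezoid",
) -> dict[str, float]:
    """All five outcome measures for one trial.

    Measures undefined for degenerate trials come back as NaN so the
    long table carries explicit missing values.
    """
    out: dict[str, float] = dict.fromkeys(
        ("xflips", "xdev", "area", "maxspeed", "rt", "latency"), np.nan)
    try:
        out["rt"] = reaction_time(trial)
    except DataError:
        pass
    lat = compute_latency(trial) if trial.n_samples else None
    out["latency"] = np.nan if lat is None else lat
    try:
        norm = rescale_space(trial)
    except MeasureUndefined:
        return out
    out["xflips"] = count_xflips(norm.xs, jitter_threshold)
    try:
        out["xdev"] = max_x_deviation(norm)
        out["area"] = riemann_area(norm, riemann_method)
    except MeasureUndefined:
        pass
    try:
        out["maxspeed"] = max_speed(trial)
    except MeasureUndefined:
        pass
    return out


def measures_long_table(
    subjects: Sequence[tuple[SegmentedSubject, QCFlags]]
    | Sequence[SegmentedSubject],
    ambiguity_map: Mapping[str, int] | None = None,
    geometry: Geometry | None = None,
    jitter_threshold: float = 0.0,
    riemann_method: str = "trapezoid",
) -> pd.DataFrame:
    """Build the analysis-ready long-format table: one row per trial.

    ``subjects`` is a sequence of segmented subjects, optionally paired
    with their :class:`QCFlags` (computed with ``geometry`` defaults
    otherwise).  ``ambiguity_map`` maps stimulus IDs to the 0/1
    ambiguity indicator; unmapped stimuli get a missing indicator.
    Subject-level ``weird_scaling`` and ``wts`` are attached to every
    row of the subject, as analysis covariates.
    """
    from .trial_builder import flag_subject  # local to avoid cycle at import

    rows = []
    for item in subjects:
        if isinstance(item, tuple):
            seg, flags = item
        else:
            seg = item
            flags = flag_subject(seg, geometry)
        for trial in seg.trials:
            m = trial_measures(trial, jitter_threshold, riemann_method)
            amb = np.nan
            if ambiguity_map is not None and trial.stimulus_id in ambiguity_map:
                amb = int(ambiguity_map[trial.stimulus_id])
            rows.append({
                "subject_id": seg.subject_id,
                "stimulus_id": trial.stimulus_id,
                "presented_index": trial.presented_index,
                "ambiguous": amb,
                "xflips": m["xflips"],
                "xdev": m["xdev"],
                "area": m["area"],
                "maxspeed": m["maxspeed"],
                "rt": m["rt"],
                "latency": m["latency"],
                "weird_scaling": int(flags.weird_scaling),
                "wts": int(flags.wts),
                "alerts": encode_alert_codes(trial.alert_codes),
            })
    return pd.DataFrame(rows, columns=MEASURE_COLUMNS)
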