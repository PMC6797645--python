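"""Synthetic cohorts of cursor trajectories with known ground truth.

The generator writes the same wide-format export dialect the real
collector produces, so every downstream stage (parsing, segmentation,
QC, measures, models) can be tested end to end without human data.

Cursor dynamics follow a two-attractor model of category competition:
the cursor starts on the Next button (the mandatory end point of the
previous trial), stays put for a latency period, then moves toward the
currently active category button at constant speed with Gaussian
positional noise.  On ambiguous trials the active attractor switches
between the two buttons as a Poisson process until a commit time, after
which the cursor heads to the finally chosen button; each switch also
produces a brief speed burst, reflecting the abrupt corrective motion a
category shift elicits.  Unambiguous trials commit immediately.  This
reproduces the qualitative signatures of competition — more x-flips,
larger deviation and area, higher peak speed, longer reaction times on
ambiguous trials — with interpretable knobs.

Realistic collection idiosyncrasies are injected independently per
subject: browser zoom (non-standard pixel scaling), too-small browser
windows, and complete coordinate-stream loss, at configurable rates.
Alert codes are assigned by applying the collector's rules to the
generated timings (started-too-early alerts are independent Bernoulli
events, since inter-trial cursor motion is not modelled).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import GenerationError
from .raw_io import ExportDialect, RawSubjectRecord, join_stream, join_text_stream
from .trial_builder import Geometry, encode_alert_codes

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_trajectory",
    "simulate_dataset",
    "simulate_measures_table",
]

#: browser / OS frequencies typical of a crowdsourced sample
_BROWSERS = (("Chrome", 0.81), ("Firefox", 0.18), ("Edge", 0.01))
_SYSTEMS = (("Windows", 0.824), ("Macintosh", 0.101),
            ("Chrome OS", 0.038), ("Linux", 0.037))


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for a synthetic cohort.

    Defaults emulate an uncontrolled crowdsourced collection: ~17 ms
    sampling, mean first-move latency a bit over 400 ms, cursor travel
    speeds giving reaction times around 1.1 s, roughly 40% of subjects
    with non-standard pixel scaling (browser zoom), 10% with a
    too-small window, and 10% losing coordinate data outright.
    ``clean()`` returns a copy with every idiosyncrasy switched off.
    """

    n_subjects: int = 50
    n_trials: int = 10
    ambiguous_fraction: float = 0.5
    geometry: Geometry = field(default_factory=Geometry)
    seed: int = 0

    # interface layout (px, browser coordinates: y grows downward)
    center_x: float = 660.0
    buttons_y: float = 200.0

    # sampling and kinematics
    dt_ms: int = 17
    dt_jitter_ms: int = 1
    speed_px_per_ms: float = 0.8
    noise_sd_px: float = 3.0
    click_radius_px: float = 15.0
    max_trial_ms: float = 60000.0

    # competition dynamics
    switch_hazard_per_ms: float = 0.002
    commit_time_mean_ms: float = 600.0
    commit_time_sd_ms: float = 250.0
    switch_speed_boost: float = 1.8
    boost_duration_ms: float = 150.0

    # latency (gamma) and inter-trial gaps
    latency_shape: float = 1.2
    latency_scale_ms: float = 350.0
    intertrial_gap_ms: tuple[float, float] = (500.0, 1500.0)

    # alert thresholds (collector defaults)
    max_latency_alert_ms: float = 700.0
    max_answer_time_ms: float = 5000.0
    p_started_too_early: float = 0.1

    # injected idiosyncrasies (per-subject probabilities)
    p_weird_zoom: float = 0.4
    zoom_choices: tuple[float, ...] = (0.5, 0.67, 1.5, 2.0)
    p_small_window: float = 0.1
    p_data_loss: float = 0.1

    epoch_origin_ms: int = 1_600_000_000_000

    def __post_init__(self):
        for name in ("ambiguous_fraction", "p_started_too_early",
                     "p_weird_zoom", "p_small_window", "p_data_loss"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.dt_ms <= 0 or self.dt_jitter_ms < 0:
            raise ValueError("sampling interval must be positive")

    def clean(self, **overrides) -> "SimConfig":
        """Copy with all injected idiosyncrasies disabled."""
        base = dict(p_weird_zoom=0.0, p_small_window=0.0,
                    p_data_loss=0.0, p_started_too_early=0.0)
        base.update(overrides)
        return replace(self, **base)

    @property
    def button_positions(self) -> dict[str, tuple[float, float]]:
        half = self.geometry.button_separation_x / 2.0
        return {
            "left": (self.center_x - half, self.buttons_y),
            "right": (self.center_x + half, self.buttons_y),
            "next": (self.center_x, self.buttons_y + self.geometry.next_to_buttons_y),
        }

    def stimulus_ids(self) -> list[str]:
        return [f"stim{i + 1:02d}" for i in range(self.n_trials)]

    def ambiguity_map(self) -> dict[str, int]:
        n_amb = round(self.n_trials * self.ambiguous_fraction)
        ids = self.stimulus_ids()
        return {s: int(i < n_amb) for i, s in enumerate(ids)}


@dataclass
class GroundTruth:
    """Per-trial generative truth plus cohort-level bookkeeping."""

    trials: pd.DataFrame
    ambiguity_map: dict[str, int]
    planted_effects: dict[str, float] = field(default_factory=dict)

    def for_subject(self, subject_id: str) -> pd.DataFrame:
        return self.trials[self.trials["subject_id"] == subject_id]


def simulate_trajectory(
    config: SimConfig,
    rng: np.random.Generator,
    ambiguous: bool,
    zoom: float = 1.0,
) -> dict:
    """Generate one trial's integer-pixel samples and metadata.

    Returns a dict with ``xs``, ``ys``, ``ts_rel`` (ms from trial
    onset, first sample at 0), ``chosen`` ("left"/"right"),
    ``first_move_ms`` (onset to first emitted position change, None if
    stationary), ``duration_ms`` and ``n_switches``.  All randomness
    comes from ``rng``.
    """
    buttons = config.button_positions
    start = buttons["next"]
    targets = {"left": buttons["left"], "right": buttons["right"]}

    latency = rng.gamma(config.latency_shape, config.latency_scale_ms)
    attractor = "left" if rng.random() < 0.5 else "right"
    if ambiguous:
        committed = False
        commit_t = latency + max(0.0, rng.normal(
            config.commit_time_mean_ms, config.commit_time_sd_ms))
    else:
        committed = True
        commit_t = latency
    chosen = attractor
    n_switches = 0
    boost_until = -math.inf

    px, py = start
    t = 0.0
    xs, ys, ts = [px], [py], [0.0]
    lo, hi = config.dt_ms - config.dt_jitter_ms, config.dt_ms + config.dt_jitter_ms
    while True:
        dt = float(rng.integers(lo, hi + 1))
        t += dt
        if t > config.max_trial_ms:
            raise GenerationError(
                f"trial did not terminate within {config.max_trial_ms} ms; "
                "check speed/noise/commit settings"
            )
        if t >= latency:
            if not committed:
                if t >= commit_t:
                    committed = True
                    chosen = attractor
                elif rng.random() < 1.0 - math.exp(-config.switch_hazard_per_ms * dt):
                    attractor = "left" if attractor == "right" else "right"
                    n_switches += 1
                    boost_until = t + config.boost_duration_ms
            speed = config.speed_px_per_ms * (
                config.switch_speed_boost if t < boost_until else 1.0)
            tx, ty = targets[attractor]
            dx, dy = tx - px, ty - py
            dist = math.hypot(dx, dy)
            # movement noise only while actually travelling; a cursor
            # resting on a button pre-commit holds still (hand tremor at
            # rest is far below movement noise)
            if dist > config.click_radius_px or committed:
                step = speed * dt
                if dist > 0:
                    frac = min(1.0, step / dist)
                    px += dx * frac
                    py += dy * frac
                if config.noise_sd_px > 0:
                    px += rng.normal(0.0, config.noise_sd_px)
                    py += rng.normal(0.0, config.noise_sd_px)
        xs.append(px)
        ys.append(py)
        ts.append(t)
        if committed:
            cx, cy = targets[chosen]
            if math.hypot(px - cx, py - cy) <= config.click_radius_px:
                break

    xi = [int(round(x * zoom)) for x in xs]
    yi = [int(round(y * zoom)) for y in ys]
    ti = [int(round(v)) for v in ts]
    first_move = next(
        (ti[i] for i in range(len(xi)) if (xi[i], yi[i]) != (xi[0], yi[0])),
        None,
    )
    return {
        "xs": xi,
        "ys": yi,
        "ts_rel": ti,
        "chosen": chosen,
        "first_move_ms": first_move,
        "duration_ms": ti[-1],
        "n_switches": n_switches,
    }


def _choice(rng: np.random.Generator, table) -> str:
    names = [n for n, _ in table]
    probs = np.array([p for _, p in table])
    return str(rng.choice(names, p=probs / probs.sum()))


def simulate_dataset(
    config: SimConfig, dialect: ExportDialect | None = None
) -> tuple[list[RawSubjectRecord], GroundTruth]:
    """Generate a full cohort serialized into the raw export dialect.

    Stimulus presentation order is randomized per subject (and the
    permutation recorded), coordinate streams are concatenated across
    trials and joined with the dialect separator, alert codes are
    derived from the generated timings, and idiosyncrasies (zoom,
    small windows, data loss) are injected per subject at the
    configured rates.
    """
    dialect = dialect or ExportDialect(n_trials_expected=config.n_trials)
    rng = np.random.default_rng(config.seed)
    amb_map = config.ambiguity_map()
    ids = config.stimulus_ids()

    records: list[RawSubjectRecord] = []
    truth_rows: list[dict] = []
    for s in range(config.n_subjects):
        sid = f"S{s + 1:04d}"
        browser = _choice(rng, _BROWSERS)
        system = _choice(rng, _SYSTEMS)
        zoom = 1.0
        if rng.random() < config.p_weird_zoom:
            zoom = float(rng.choice(config.zoom_choices))
        small_window = rng.random() < config.p_small_window
        data_loss = rng.random() < config.p_data_loss
        win_w = int(rng.normal(1530, 250))
        win_h = int(rng.normal(780, 120))
        win_w = max(win_w, int(config.geometry.min_window_width) + 100)
        win_h = max(win_h, int(config.geometry.min_window_height) + 50)
        if small_window:
            n_small = int(rng.integers(1, config.n_trials + 1))
            small_trials = set(
                rng.choice(config.n_trials, size=n_small, replace=False))
        else:
            small_trials = set()

        order = [ids[i] for i in rng.permutation(config.n_trials)]
        t_cursor = config.epoch_origin_ms + int(rng.integers(0, 86_400_000))
        all_x: list[float] = []
        all_y: list[float] = []
        all_t: list[float] = []
        on_load, on_ready, button_click, page_submit = [], [], [], []
        widths, heights, alert_toks, latencies, categories = [], [], [], [], []
        for j, stim in enumerate(order):
            gap = rng.uniform(*config.intertrial_gap_ms)
            ready = t_cursor + int(round(gap))
            traj = simulate_trajectory(
                config, rng, ambiguous=bool(amb_map[stim]), zoom=zoom)
            click = ready + traj["duration_ms"]
            all_x.extend(traj["xs"])
            all_y.extend(traj["ys"])
            all_t.extend(ready + t for t in traj["ts_rel"])
            on_load.append(ready - int(rng.integers(100, 400)))
            on_ready.append(ready)
            button_click.append(click)
            page_submit.append(click + int(rng.integers(300, 1200)))
            small = j in small_trials
            widths.append(640 if small else win_w)
            heights.append(480 if small else win_h)
            lat = traj["first_move_ms"]
            latencies.append(lat if lat is not None else traj["duration_ms"])
            codes = set()
            if rng.random() < config.p_started_too_early:
                codes.add(1)
            if lat is not None and lat > config.max_latency_alert_ms:
                codes.add(2)
            if traj["duration_ms"] > config.max_answer_time_ms:
                codes.add(3)
            if small:
                codes.add(4)
            alert_toks.append(encode_alert_codes(codes))
            categories.append(traj["chosen"])
            t_cursor = page_submit[-1]
            truth_rows.append({
                "subject_id": sid,
                "presented_index": j + 1,
                "stimulus_id": stim,
                "ambiguous": amb_map[stim],
                "first_move_ms": lat,
                "duration_ms": traj["duration_ms"],
                "n_switches": traj["n_switches"],
                "n_samples": len(traj["ts_rel"]),
                "chosen": traj["chosen"],
                "zoom": zoom,
                "small_window": small,
                "data_loss": data_loss,
                "alert_code": alert_toks[-1],
            })

        if data_loss:
            all_x, all_y, all_t = [], [], []
        records.append(RawSubjectRecord(
            subject_id=sid,
            x_stream=join_stream(all_x, dialect),
            y_stream=join_stream(all_y, dialect),
            t_stream=join_stream(all_t, dialect),
            on_load_times=join_stream(on_load, dialect),
            on_ready_times=join_stream(on_ready, dialect),
            button_click_times=join_stream(button_click, dialect),
            page_submit_times=join_stream(page_submit, dialect),
            window_widths=join_stream(widths, dialect),
            window_heights=join_stream(heights, dialect),
            alerts_stream=join_stream(alert_toks, dialect),
            latency_stream=join_stream(latencies, dialect),
            stimulus_order=join_text_stream(order, dialect),
            chosen_categories=join_text_stream(categories, dialect),
            browser=browser,
            browser_version=f"{rng.integers(70, 120)}.0",
            operating_system=system,
            resolution=f"{win_w + 300}x{win_h + 200}",
        ))

    truth = GroundTruth(
        trials=pd.DataFrame(truth_rows), ambiguity_map=dict(amb_map))
    return records, truth


def simulate_measures_table(
    n_subjects: int,
    n_trials: int = 10,
    effects: Mapping[str, float] | None = None,
    icc: float = 0.3,
    ambiguous_fraction: float = 0.5,
    xflips_base_rate: float = 3.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a long-format measures table with planted effects.

    This outcome-level generator bypasses trajectory dynamics: each
    continuous outcome follows an exchangeable Gaussian model
    ``y = beta * ambiguous + b_subject + e`` with ``Var(b) = icc`` and
    ``Var(e) = 1 - icc`` (unit residual scale, so ``beta`` is the
    planted standardized ambiguity effect), while x-flips are Poisson
    with a log-normal subject frailty.  It is the harness for checking
    the model-fitting machinery: type-I error, bias and interval
    coverage under known truth.
    """
    if not 0.0 <= icc < 1.0:
        raise ValueError("icc must be in [0, 1)")
    effects = dict(effects or {})
    rng = np.random.default_rng(seed)
    n_amb = round(n_trials * ambiguous_fraction)
    amb_per_subject = np.array([1] * n_amb + [0] * (n_trials - n_amb))

    rows = []
    for s in range(n_subjects):
        sid = f"S{s + 1:04d}"
        b = {o: rng.normal(0.0, math.sqrt(icc)) for o in
             ("xdev", "area", "maxspeed", "rt")}
        frailty = rng.normal(0.0, 0.3)
        for j in range(n_trials):
            amb = int(amb_per_subject[j])
            row = {
                "subject_id": sid,
                "stimulus_id": f"stim{j + 1:02d}",
                "presented_index": j + 1,
                "ambiguous": amb,
                "weird_scaling": 0,
                "wts": 0,
                "alerts": 0,
                "latency": np.nan,
            }
            for o in ("xdev", "area", "maxspeed", "rt"):
                beta = effects.get(o, 0.0)
                row[o] = (beta * amb + b[o]
                          + rng.normal(0.0, math.sqrt(1.0 - icc)))
            mu = xflips_base_rate * math.exp(
                effects.get("xflips", 0.0) * amb + frailty)
            row["xflips"] = int(rng.poisson(mu))
            rows.append(row)
    table = pd.DataFrame(rows)
    amb_map = {f"stim{j + 1:02d}": int(amb_per_subject[j])
               for j in range(n_trials)}
    truth = GroundTruth(
        trials=table[["subject_id", "stimulus_id", "ambiguous"]].copy(),
        ambiguity_map=amb_map,
        planted_effects=effects,
    )
    return table, truth
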