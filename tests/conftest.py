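import numpy as np
import pytest

from mtpipe.raw_io import ExportDialect
from mtpipe.simulate import SimConfig, simulate_dataset
from mtpipe.trial_builder import TrialTrajectory


@pytest.fixture
def dialect():
    return ExportDialect()


@pytest.fixture(scope="session")
def clean_cohort():
    """Small clean cohort (no injected idiosyncrasies) with ground truth."""
    cfg = SimConfig(n_subjects=8, seed=11).clean()
    records, truth = simulate_dataset(cfg)
    return cfg, records, truth


def make_trial(xs, ys, ts, on_ready=None, button_click=None, **kw):
    """Build a TrialTrajectory directly from coordinate lists."""
    ts = list(ts)
    defaults = dict(subject_id="S0001", presented_index=1, stimulus_id="stim01")
    defaults.update(kw)
    return TrialTrajectory(
        xs=np.asarray(xs, dtype=float),
        ys=np.asarray(ys, dtype=float),
        ts=np.asarray(ts, dtype=float),
        on_ready=ts[0] if on_ready is None else on_ready,
        button_click=ts[-1] if button_click is None else button_click,
        **defaults,
    )


def random_trajectory(rng, n_min=3, n_max=60):
    """A random trajectory with distinct start/end y, for oracle checks."""
    while True:
        n = int(rng.integers(n_min, n_max + 1))
        xs = rng.normal(500, 200, n)
        ys = rng.normal(400, 150, n)
        dts = rng.integers(1, 30, n - 1)
        ts = 1_000_000 + np.concatenate([[0], np.cumsum(dts)]).astype(float)
        if ys[0] != ys[-1] and xs.min() != xs.max() and ys.min() != ys.max():
            return make_trial(xs, ys, ts)


# ---- independent brute-force references (plain loops, no numpy tricks) ----

def brute_xflips(xs, jitter=0.0):
    deltas = []
    for a, b in zip(xs[:-1], xs[1:]):
        d = b - a
        if abs(d) > jitter:
            deltas.append(d)
    flips = 0
    for d1, d2 in zip(deltas[:-1], deltas[1:]):
        if (d1 > 0) != (d2 > 0):
            flips += 1
    return flips


def _line_x(x0, y0, x1, y1, y):
    return x0 + (x1 - x0) * (y - y0) / (y1 - y0)


def brute_xdev(xs, ys):
    x0, y0, x1, y1 = xs[0], ys[0], xs[-1], ys[-1]
    return max(abs(x - _line_x(x0, y0, x1, y1, y)) for x, y in zip(xs, ys))


def brute_area(xs, ys, method="trapezoid"):
    x0, y0, x1, y1 = xs[0], ys[0], xs[-1], ys[-1]
    d = [abs(x - _line_x(x0, y0, x1, y1, y)) for x, y in zip(xs, ys)]
    total = 0.0
    for i in range(len(xs) - 1):
        dy = abs(ys[i + 1] - ys[i])
        if method == "trapezoid":
            total += (d[i] + d[i + 1]) / 2.0 * dy
        else:
            total += d[i] * dy
    return total


def brute_maxspeed(xs, ys, ts):
    best = None
    for i in range(len(ts) - 1):
        dt = ts[i + 1] - ts[i]
        if dt <= 0:
            continue
        disp = ((xs[i + 1] - xs[i]) ** 2 + (ys[i + 1] - ys[i]) ** 2) ** 0.5
        v = disp / dt
        best = v if best is None else max(best, v)
    return best
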