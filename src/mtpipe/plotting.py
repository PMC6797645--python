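"""Minimal trajectory plotting: unit-scaled paths, one panel per stimulus."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .errors import DataError
from .metrics import rescale_space
from .trial_builder import SegmentedSubject

__all__ = ["plot_trajectories"]


def plot_trajectories(
    subjects: Sequence[SegmentedSubject],
    out_dir: str | Path,
    stimuli: Sequence[str] | None = None,
) -> list[Path]:
    """Write one PNG per stimulus with all subjects' unit-scaled paths.

    Browser coordinates grow downward, so the y-axis is inverted for
    display: trials start at the bottom (the Next button) and end at a
    category button at the top.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_stim: dict[str, list] = {}
    for seg in subjects:
        for trial in seg.trials:
            if trial.n_samples >= 2:
                by_stim.setdefault(trial.stimulus_id, []).append(trial)
    if stimuli is None:
        stimuli = sorted(by_stim)
    if not by_stim:
        raise DataError("no plottable trials")

    written: list[Path] = []
    for stim in stimuli:
        fig, ax = plt.subplots(figsize=(4, 4))
        for trial in by_stim.get(stim, []):
            norm = rescale_space(trial)
            ax.plot(norm.xs, norm.ys, lw=0.6, alpha=0.5, color="tab:blue")
        ax.set_xlim(-0.05, 1.05)
        ax.set_ylim(-0.05, 1.05)
        ax.invert_yaxis()
        ax.set_title(stim)
        ax.set_xlabel("x (unit-scaled)")
        ax.set_ylabel("y (unit-scaled)")
        path = out_dir / f"trajectories_{stim}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)
    return written
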