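"""End-to-end glue: raw records -> QC -> exclusions -> measures table."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .metrics import measures_long_table
from .raw_io import ExportDialect, RawSubjectRecord
from .trial_builder import (
    ExclusionReport,
    Geometry,
    QCFlags,
    SegmentedSubject,
    apply_exclusions,
    flag_subject,
    reorder_by_stimulus,
    segment_trials,
)

__all__ = ["ProcessResult", "process_records", "alert_summary"]

log = logging.getLogger("mtpipe")


@dataclass
class ProcessResult:
    segmented: list[SegmentedSubject]
    flags: list[QCFlags]
    report: ExclusionReport
    measures: pd.DataFrame
    kept: list[SegmentedSubject] = field(default_factory=list)

    def qc_json(self) -> dict:
        return {
            "subjects": [f.to_dict() for f in self.flags],
            "exclusions": self.report.to_dict(),
            "alerts": alert_summary(self.flags),
        }


def alert_summary(flags: Sequence[QCFlags]) -> dict:
    """Cohort alert frequencies: per-code counts and the share of
    trials that triggered no alert at all."""
    code_counts: dict[int, int] = {1: 0, 2: 0, 3: 0, 4: 0}
    n_trials = 0
    n_with_alert = 0
    for f in flags:
        for code, c in f.per_trial_alert_counts.items():
            code_counts[code] = code_counts.get(code, 0) + c
        n_trials += f.n_trials
        n_with_alert += f.n_trials_with_alerts
    return {
        "alert_counts": {str(k): v for k, v in sorted(code_counts.items())},
        "n_alerts_total": sum(code_counts.values()),
        "n_trials": n_trials,
        "pct_trials_no_alerts": (
            100.0 * (n_trials - n_with_alert) / n_trials if n_trials else None
        ),
    }


def process_records(
    records: Sequence[RawSubjectRecord],
    dialect: ExportDialect | None = None,
    geometry: Geometry | None = None,
    canonical_order: Sequence[str] | None = None,
    ambiguity_map: Mapping[str, int] | None = None,
    policy: str = "conservative",
    jitter_threshold: float = 0.0,
    riemann_method: str = "trapezoid",
) -> ProcessResult:
    """Run segmentation, reordering, QC, exclusion, and measures.

    ``canonical_order`` is the stimulus set in canonical order; when
    omitted it defaults to the sorted union of presented stimuli.
    Subjects excluded by the policy are absent from the measures table
    but present in the QC report.
    """
    dialect = dialect or ExportDialect()
    geometry = geometry or Geometry()
    segmented = [segment_trials(r, dialect) for r in records]
    flags = [flag_subject(s, geometry, dialect) for s in segmented]
    report = apply_exclusions(flags, policy)
    kept_ids = set(report.kept_ids)

    if canonical_order is None:
        stimuli = sorted({t.stimulus_id for s in segmented for t in s.trials})
    else:
        stimuli = list(canonical_order)

    kept: list[SegmentedSubject] = []
    kept_flags: list[QCFlags] = []
    for seg, f in zip(segmented, flags):
        if seg.subject_id not in kept_ids:
            continue
        seg.trials = reorder_by_stimulus(seg.trials, stimuli)
        kept.append(seg)
        kept_flags.append(f)

    measures = measures_long_table(
        list(zip(kept, kept_flags)),
        ambiguity_map=ambiguity_map,
        geometry=geometry,
        jitter_threshold=jitter_threshold,
        riemann_method=riemann_method,
    )
    n_excl = len(report.excluded)
    log.info("processed %d subjects: kept %d, excluded %d",
             len(records), len(kept), n_excl)
    return ProcessResult(segmented=segmented, flags=flags, report=report,
                         measures=measures, kept=kept)
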