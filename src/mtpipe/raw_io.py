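"""Reading and writing the wide-format raw export of a mouse-tracking survey.

One CSV row per subject.  Cursor samples (x, y, t) are stored as long
character-separated strings — by convention the separator is the letter
``"a"`` — while per-trial quantities (trial onset, button click, window
size, alerts, latency) are shorter streams with one token per trial.
Stimulus identifiers and category responses are text, so they use a
separate separator that cannot collide with URL characters.

Parsing of the numeric streams is strict: tokens are plain decimals with
an optional sign and fraction (no scientific notation, no thousands
separators, no locale dependence), and any residue raises
:class:`~mtpipe.errors.StreamParseError` naming the subject, column and
token position.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import ConfigError, StreamParseError

__all__ = [
    "ExportDialect",
    "RawSubjectRecord",
    "parse_separated_stream",
    "join_stream",
    "split_text_stream",
    "join_text_stream",
    "read_raw_export",
    "write_raw_export",
]

#: codebook roles -> default CSV header names
DEFAULT_COLUMNS: dict[str, str] = {
    "subject_id": "ResponseId",
    "x": "xPos",
    "y": "yPos",
    "t": "time",
    "on_load": "onLoadTime",
    "on_ready": "onReadyTime",
    "button_click": "buttonClickTime",
    "page_submit": "pageSubmitTime",
    "window_width": "windowWidth",
    "window_height": "windowHeight",
    "alerts": "alerts",
    "latency": "latency",
    "stimulus_order": "stimulusOrder",
    "chosen_category": "chosenCategory",
    "browser": "browser_Browser",
    "browser_version": "browser_Version",
    "operating_system": "browser_Operating.System",
    "resolution": "browser_Resolution",
}

#: roles that must be present in the header for the pipeline to run
REQUIRED_ROLES = (
    "subject_id",
    "x",
    "y",
    "t",
    "on_ready",
    "button_click",
    "window_width",
    "window_height",
    "alerts",
    "latency",
    "stimulus_order",
)

_NUMBER_RE = re.compile(r"^[+-]?(?:\d+(?:\.\d*)?|\.\d+)$")


@dataclass(frozen=True)
class ExportDialect:
    """Parameters of the raw-export format.

    Parameters
    ----------
    separator
        Single character separating numeric recordings within a stream.
        Must not be a digit, sign, or decimal point.
    stimulus_separator
        Separator for textual streams (stimulus URLs/IDs, category
        labels), which may themselves contain letters.
    column_names
        Mapping from codebook roles to CSV header names; unspecified
        roles fall back to the standard names (``xPos``, ``yPos``,
        ``time``, ``onReadyTime`` ...).
    n_trials_expected
        Number of recorded experimental trials per subject.
    n_practice_expected
        Number of practice trials (not recorded; kept for bookkeeping).
    skip_rows
        Extra header rows to skip after the first (survey platforms
        often emit one or two label rows below the header).
    """

    separator: str = "a"
    stimulus_separator: str = ";"
    column_names: Mapping[str, str] = field(default_factory=dict)
    n_trials_expected: int = 10
    n_practice_expected: int = 6
    skip_rows: int = 0

    def __post_init__(self):
        if len(self.separator) != 1 or self.separator in "+-.0123456789":
            raise ConfigError(
                f"stream separator must be a single non-numeric character, "
                f"got {self.separator!r}"
            )
        if self.n_trials_expected < 1:
            raise ConfigError("n_trials_expected must be >= 1")
        unknown = set(self.column_names) - set(DEFAULT_COLUMNS)
        if unknown:
            raise ConfigError(f"unknown codebook roles: {sorted(unknown)}")

    def column(self, role: str) -> str:
        return self.column_names.get(role, DEFAULT_COLUMNS[role])

    def with_columns(self, **roles: str) -> "ExportDialect":
        merged = {**self.column_names, **roles}
        return replace(self, column_names=merged)


@dataclass
class RawSubjectRecord:
    """One wide-export row: unparsed streams plus system metadata.

    Stream fields hold the literal cell text; parsing is deferred so
    that malformed streams can be flagged per subject instead of
    aborting the whole read.
    """

    subject_id: str
    x_stream: str = ""
    y_stream: str = ""
    t_stream: str = ""
    on_load_times: str = ""
    on_ready_times: str = ""
    button_click_times: str = ""
    page_submit_times: str = ""
    window_widths: str = ""
    window_heights: str = ""
    alerts_stream: str = ""
    latency_stream: str = ""
    stimulus_order: str = ""
    chosen_categories: str = ""
    browser: str = ""
    browser_version: str = ""
    operating_system: str = ""
    resolution: str = ""
    extra_columns: dict[str, str] = field(default_factory=dict)


#: record attribute -> codebook role, for the stream and metadata fields
_FIELD_ROLES: dict[str, str] = {
    "x_stream": "x",
    "y_stream": "y",
    "t_stream": "t",
    "on_load_times": "on_load",
    "on_ready_times": "on_ready",
    "button_click_times": "button_click",
    "page_submit_times": "page_submit",
    "window_widths": "window_width",
    "window_heights": "window_height",
    "alerts_stream": "alerts",
    "latency_stream": "latency",
    "stimulus_order": "stimulus_order",
    "chosen_categories": "chosen_category",
    "browser": "browser",
    "browser_version": "browser_version",
    "operating_system": "operating_system",
    "resolution": "resolution",
}


def parse_separated_stream(
    raw: str,
    dialect: ExportDialect | None = None,
    *,
    subject_id: str | None = None,
    column: str | None = None,
) -> list[float]:
    """Split a character-separated stream into an ordered list of numbers.

    An empty string yields an empty list.  Integer-valued tokens come
    back as exact floats; parsing accepts an optional sign and decimal
    fraction but nothing else.
    """
    dialect = dialect or ExportDialect()
    if raw == "":
        return []
    out: list[float] = []
    for i, tok in enumerate(raw.split(dialect.separator)):
        if not _NUMBER_RE.match(tok):
            raise StreamParseError(
                f"non-numeric token {tok!r} at position {i}"
                + (f" in column {column!r}" if column else "")
                + (f" for subject {subject_id!r}" if subject_id else ""),
                subject_id=subject_id,
                column=column,
                position=i,
            )
        out.append(float(tok))
    return out


def _format_number(v: float) -> str:
    # integers render without a trailing ".0" so written streams look
    # like the raw px/ms integers the collector emits
    if float(v) == int(v):
        return str(int(v))
    return repr(float(v))


def join_stream(values: Sequence[float], dialect: ExportDialect | None = None) -> str:
    """Inverse of :func:`parse_separated_stream` (up to float formatting)."""
    dialect = dialect or ExportDialect()
    return dialect.separator.join(_format_number(v) for v in values)


def split_text_stream(raw: str, dialect: ExportDialect | None = None) -> list[str]:
    """Split a textual stream (stimulus IDs, category labels)."""
    dialect = dialect or ExportDialect()
    if raw == "":
        return []
    return raw.split(dialect.stimulus_separator)


def join_text_stream(items: Sequence[str], dialect: ExportDialect | None = None) -> str:
    dialect = dialect or ExportDialect()
    sep = dialect.stimulus_separator
    for it in items:
        if sep in it:
            raise ConfigError(
                f"text token {it!r} contains the stimulus separator {sep!r}"
            )
    return sep.join(items)


def read_raw_export(
    path: str | Path, dialect: ExportDialect | None = None
) -> list[RawSubjectRecord]:
    """Read a wide-format raw export into one record per subject row.

    Streams are kept as raw strings (lazy parse); unknown columns are
    preserved verbatim in ``extra_columns``.
    """
    dialect = dialect or ExportDialect()
    df = pd.read_csv(
        path,
        dtype=str,
        keep_default_na=False,
        skiprows=lambda i: 1 <= i <= dialect.skip_rows,
    )
    missing = [
        dialect.column(role)
        for role in REQUIRED_ROLES
        if dialect.column(role) not in df.columns
    ]
    if missing:
        raise ConfigError(
            f"raw export {path} is missing mandatory columns: {missing}"
        )
    known = {dialect.column(role) for role in DEFAULT_COLUMNS}
    records: list[RawSubjectRecord] = []
    for _, row in df.iterrows():
        kwargs = {"subject_id": row[dialect.column("subject_id")]}
        for attr, role in _FIELD_ROLES.items():
            col = dialect.column(role)
            if col in df.columns:
                kwargs[attr] = row[col]
        extra = {c: row[c] for c in df.columns if c not in known}
        records.append(RawSubjectRecord(**kwargs, extra_columns=extra))
    return records


def write_raw_export(
    records: Sequence[RawSubjectRecord],
    path: str | Path,
    dialect: ExportDialect | None = None,
) -> None:
    """Write records as a wide CSV such that reading it back is lossless."""
    dialect = dialect or ExportDialect()
    columns = [dialect.column("subject_id")] + [
        dialect.column(role) for role in _FIELD_ROLES.values()
    ]
    extra_cols: list[str] = []
    for rec in records:
        for c in rec.extra_columns:
            if c not in extra_cols:
                extra_cols.append(c)
    rows = []
    for rec in records:
        row = {dialect.column("subject_id"): rec.subject_id}
        for attr, role in _FIELD_ROLES.items():
            row[dialect.column(role)] = getattr(rec, attr)
        for c in extra_cols:
            row[c] = rec.extra_columns.get(c, "")
        rows.append(row)
    df = pd.DataFrame(rows, columns=columns + extra_cols, dtype=str)
    df.to_csv(path, index=False)
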