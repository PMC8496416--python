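"""Readers/writers for gaze recordings.

Two dialects are supported:

* a delimited text format with header
  ``t,x_left,y_left,pupil_left,x_right,y_right,pupil_right`` and one sample
  per row, and
* a minimal EyeLink-ASC-style sample dialect where every line whose first
  token is numeric is a sample line ``t xL yL pL xR yR pR`` and all other
  lines (messages, events) are ignored.  Missing-data tokens (``.`` or an
  empty field) become blink-flagged samples.
"""

from __future__ import annotations

import io
import os
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from .errors import DataError, FormatError
from .gaze import GazeTrace

__all__ = [
    "CSV_COLUMNS",
    "read_gaze_csv",
    "write_gaze_csv",
    "read_asc_samples",
    "write_asc_samples",
]

#: canonical column order of the delimited sample format
CSV_COLUMNS = (
    "t",
    "x_left",
    "y_left",
    "pupil_left",
    "x_right",
    "y_right",
    "pupil_right",
)

PathLike = Union[str, os.PathLike]


def _monotone_check(t: np.ndarray) -> None:
    dt = np.diff(t)
    bad = np.flatnonzero(dt <= 0)
    if bad.size:
        # 1-based data row index of the first offending sample
        raise DataError(
            f"non-monotone timestamp at data row {bad[0] + 2}: "
            f"t={t[bad[0] + 1]!r} follows t={t[bad[0]]!r}"
        )


def read_gaze_csv(
    path: PathLike,
    dialect: Optional[Mapping[str, str]] = None,
    rate_hz: Optional[float] = None,
) -> GazeTrace:
    """Read a delimited gaze-sample file.

    ``dialect`` optionally maps the seven canonical field names to the
    column names used in the file.  Blink samples (pupil 0/NaN) are retained
    and flagged through :attr:`GazeTrace.track_lost`.  The sampling rate is
    taken from ``rate_hz`` or inferred from the median timestamp spacing.
    """
    df = pd.read_csv(path)
    colmap = {k: k for k in CSV_COLUMNS}
    if dialect:
        colmap.update(dialect)
    for field_name, col in colmap.items():
        if col not in df.columns:
            raise FormatError(
                f"missing column {col!r} (for field {field_name!r}) in {path}"
            )
    arrays = {f: df[colmap[f]].to_numpy(dtype=float) for f in CSV_COLUMNS}
    _monotone_check(arrays["t"])
    if rate_hz is None:
        spacing = np.median(np.diff(arrays["t"])) if arrays["t"].size > 1 else 1.0
        rate_hz = 1000.0 / float(spacing)
    return GazeTrace(
        t=arrays["t"],
        x_left=arrays["x_left"],
        y_left=arrays["y_left"],
        x_right=arrays["x_right"],
        y_right=arrays["y_right"],
        pupil_left=arrays["pupil_left"],
        pupil_right=arrays["pupil_right"],
        rate_hz=float(rate_hz),
        meta={"source": str(path)},
    )


def write_gaze_csv(trace: GazeTrace, path: PathLike) -> None:
    """Write a trace in the canonical delimited format.

    Values are printed with ``%.9g`` so that a read-write-read cycle is the
    identity at that precision (the round-trip contract used by the tests).
    """
    df = pd.DataFrame({c: getattr(trace, c) for c in CSV_COLUMNS})
    df.to_csv(path, index=False, float_format="%.9g")


def _asc_token(value: float) -> str:
    return "." if not np.isfinite(value) else f"{value:.9g}"


def write_asc_samples(trace: GazeTrace, path: PathLike) -> None:
    """Emit the minimal ASC sample dialect (``t xL yL pL xR yR pR``)."""
    with open(path, "w") as fh:
        fh.write("MSG 0 RECORDING START\n")
        for s in trace.samples():
            fields = [
                f"{s.t:.9g}",
                _asc_token(s.x_left),
                _asc_token(s.y_left),
                _asc_token(s.pupil_left),
                _asc_token(s.x_right),
                _asc_token(s.y_right),
                _asc_token(s.pupil_right),
            ]
            fh.write("\t".join(fields) + "\n")
        fh.write("MSG 1 RECORDING END\n")


def _is_numeric(token: str) -> bool:
    try:
        float(token)
    except ValueError:
        return False
    return True


def read_asc_samples(path: PathLike, rate_hz: Optional[float] = None) -> GazeTrace:
    """Parse sample lines from a minimal EyeLink-ASC-style file.

    Lines whose first whitespace-separated token is numeric are samples in
    the order ``t xL yL pL xR yR pR``; everything else is skipped.  ``.`` or
    empty tokens become NaN (pupil 0), i.e. blink-flagged samples.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            tokens = line.strip().split()
            if not tokens or not _is_numeric(tokens[0]):
                continue
            # pad truncated lines with missing markers
            tokens = (tokens + ["."] * 7)[:7]
            vals = [
                float(tok) if _is_numeric(tok) else np.nan for tok in tokens
            ]
            rows.append(vals)
    if not rows:
        raise DataError(f"no sample lines found in {path}")
    arr = np.asarray(rows, dtype=float)
    t, xl, yl, pl, xr, yr, pr = arr.T
    _monotone_check(t)
    # a missing pupil marker means track loss: encode as pupil 0
    pl = np.where(np.isnan(pl), 0.0, pl)
    pr = np.where(np.isnan(pr), 0.0, pr)
    if rate_hz is None:
        spacing = np.median(np.diff(t)) if t.size > 1 else 1.0
        rate_hz = 1000.0 / float(spacing)
    return GazeTrace(
        t=t,
        x_left=xl,
        y_left=yl,
        x_right=xr,
        y_right=yr,
        pupil_left=pl,
        pupil_right=pr,
        rate_hz=float(rate_hz),
        meta={"source": str(path)},
    )
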