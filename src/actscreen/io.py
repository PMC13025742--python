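"""Reading and writing GazePoint-style gaze logs.

The dialect is a seven-column delimited text table — Timestamp, LPCX, LPCY,
RPCX, RPCY, LPV, RPV — one row per 60 Hz frame.  Readers accept comma, tab or
whitespace delimiters and match headers case-insensitively (vendor exports
vary); extra vendor columns are ignored with a warning.  Writers always emit
comma-separated UTF-8 with coordinates at fixed 5-decimal precision.
"""

from __future__ import annotations

import io as _io
import logging
from os import PathLike
from pathlib import Path
from typing import IO, Union

import numpy as np
import pandas as pd

from .exceptions import ParseError, SchemaError
from .simulate import GAZE_COLUMNS, GazeRecording

__all__ = ["read_recording", "write_recording"]

logger = logging.getLogger(__name__)

Source = Union[str, PathLike, IO[str]]


def _load_table(source: Source) -> pd.DataFrame:
    import csv

    try:
        return pd.read_csv(source, sep=None, engine="python", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError("empty gaze log: no header row") from exc
    except csv.Error as exc:
        raise SchemaError(f"cannot determine gaze-log dialect: {exc}") from exc


def read_recording(
    source: Source,
    participant_id: str = "P000",
    sample_index: int = 0,
) -> GazeRecording:
    """Parse a gaze log into a :class:`GazeRecording`.

    Header matching is case- and order-insensitive; unknown extra columns are
    dropped with a logged warning.  Invalid frames (LPV/RPV = 0) are retained
    — deciding how to treat them is the preprocessing pipeline's job.

    Raises
    ------
    SchemaError
        If a required column is missing or the file is empty.
    ParseError
        If a cell cannot be parsed, reporting the 1-based data row.
    """
    raw = _load_table(source)
    lower_map = {str(c).strip().lower(): c for c in raw.columns}
    missing = [c for c in GAZE_COLUMNS if c.lower() not in lower_map]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    extra = [c for c in raw.columns if str(c).strip().lower() not in
             {c.lower() for c in GAZE_COLUMNS}]
    if extra:
        logger.warning("ignoring extra column(s) in gaze log: %s", extra)

    data = {}
    for canon in GAZE_COLUMNS:
        col = raw[lower_map[canon.lower()]]
        numeric = pd.to_numeric(col, errors="coerce")
        bad = numeric.isna() & col.notna() & (col.str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 1
            raise ParseError(
                f"non-numeric value {col[bad].iloc[0]!r} in column {canon} "
                f"at data row {row}"
            )
        if numeric.isna().any():
            row = int(np.flatnonzero(numeric.isna().to_numpy())[0]) + 1
            raise ParseError(f"empty cell in column {canon} at data row {row}")
        data[canon] = numeric.to_numpy(dtype=float)
    if len(data["Timestamp"]) == 0:
        raise SchemaError("gaze log contains a header but no data rows")

    for flag in ("LPV", "RPV"):
        vals = data[flag]
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ParseError(f"{flag} values must be 0 or 1")
        data[flag] = vals.astype(int)

    frames = pd.DataFrame(data, columns=list(GAZE_COLUMNS))
    return GazeRecording(
        frames=frames, participant_id=participant_id, sample_index=sample_index
    )


def write_recording(recording: GazeRecording, sink: Source) -> None:
    """Write a recording as a comma-separated gaze log (5-decimal coordinates)."""
    if recording.n_frames == 0:
        raise ValueError("cannot write an empty recording")
    frames = recording.frames
    lines = [",".join(GAZE_COLUMNS)]
    for row in frames.itertuples(index=False):
        lines.append(
            f"{row.Timestamp:.5f},{row.LPCX:.5f},{row.LPCY:.5f},"
            f"{row.RPCX:.5f},{row.RPCY:.5f},{int(row.LPV)},{int(row.RPV)}"
        )
    text = "\n".join(lines) + "\n"
    if isinstance(sink, (str, PathLike)):
        Path(sink).write_text(text, encoding="utf-8")
    else:
        sink.write(text)
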