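"""Reading and writing per-frame position files, reports, and configs.

Canonical position-file layout
------------------------------
Delimited ASCII text with header ``frame,time,x,y`` and one organism per
line; comma or whitespace delimited (sniffed under ``dialect='auto'``).
``x`` is the cross-axis coordinate (across the three fluid bands), ``y`` the
long-axis coordinate (along the channel).  A frame with no organisms is
preserved as a single line with empty ``x`` and ``y`` fields.  Headerless
files are accepted with a user-supplied ``column_map``; when the time column
is absent, timestamps fall back to ``frame / fps``.

Positions are passed through :func:`chemofield.point_field.normalize_points`
with the configured physical channel bounds, so files may hold raw pixel or
micrometer coordinates.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .point_field import FrameSeries, PointField, RegionBounds, normalize_points

__all__ = [
    "read_frame_series",
    "write_frame_series",
    "write_report",
    "read_report",
    "load_config",
    "REPORT_COLUMNS",
]

CANONICAL_COLUMNS = ("frame", "time", "x", "y")
REPORT_COLUMNS = (
    "time",
    "axis",
    "k",
    "statistic",
    "lower",
    "upper",
    "verdict",
    "n",
    "chemotactic_index",
)


def _sniff_sep(first_line: str) -> str | None:
    """Comma-separated if a comma appears, otherwise whitespace."""
    return "," if "," in first_line else r"\s+"


def read_frame_series(
    path,
    bounds: RegionBounds = RegionBounds(),
    dialect: str = "auto",
    fps: float | None = None,
    column_map: Sequence[str] | None = None,
) -> FrameSeries:
    """Read a per-frame position file into a :class:`FrameSeries`.

    Parameters
    ----------
    path : path-like
        Delimited text file in the canonical layout (or a headerless variant
        with ``column_map`` naming its columns in order).
    bounds
        Physical channel extents; raw positions are normalized onto [0,1]^2.
    dialect
        ``'auto'`` (sniff comma vs whitespace), ``'csv'`` or ``'whitespace'``.
    fps
        Frames per second, used for timestamps when the file has no time
        column.
    column_map
        Column names, in file order, for headerless files.  Must include
        ``frame``, ``x`` and ``y``; ``time`` is optional.

    Raises
    ------
    ValueError
        On an empty file, an unparseable line (reported with its line
        number), non-monotone frame times, or out-of-bounds coordinates
        (reported with their line numbers).
    """
    path = Path(path)
    text = path.read_text()
    lines = text.splitlines()
    if not lines or not text.strip():
        raise ValueError(f"{path}: empty position file")

    if dialect == "auto":
        sep = _sniff_sep(lines[0])
    elif dialect == "csv":
        sep = ","
    elif dialect == "whitespace":
        sep = r"\s+"
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    first_tokens = [t.strip().lower() for t in
                    (lines[0].split(",") if sep == "," else lines[0].split())]
    has_header = "frame" in first_tokens
    if has_header:
        names = first_tokens
        skip = 1
    elif column_map is not None:
        names = [c.strip().lower() for c in column_map]
        skip = 0
    else:
        # headerless default: canonical column order
        names = list(CANONICAL_COLUMNS)
        skip = 0
    for required in ("frame", "x", "y"):
        if required not in names:
            raise ValueError(f"{path}: no {required!r} column (have {names})")

    df = pd.read_csv(
        _io.StringIO(text),
        sep=sep,
        names=names,
        header=None,
        skiprows=skip,
        skip_blank_lines=False,
        dtype=str,
        engine="python",
    )
    if len(df.columns) != len(names):
        raise ValueError(f"{path}: expected {len(names)} columns, found {len(df.columns)}")
    # line numbers in the original file (1-based)
    df.index = np.arange(skip + 1, skip + 1 + len(df))

    def _numeric(col: str, required: bool) -> pd.Series:
        # python float() keeps full precision (pandas' fast parser can be
        # one ulp off, breaking the lossless round-trip contract)
        raw = df[col]
        out = np.empty(len(raw))
        for pos, (line_no, v) in enumerate(raw.items()):
            text_v = "" if v is None or (isinstance(v, float) and np.isnan(v)) \
                else str(v).strip()
            if not text_v:
                if required:
                    raise ValueError(f"{path}: line {line_no}: missing {col!r} value")
                out[pos] = np.nan
                continue
            try:
                out[pos] = float(text_v)
            except ValueError:
                raise ValueError(
                    f"{path}: line {line_no}: cannot parse {col!r} value {v!r}"
                ) from None
        return pd.Series(out, index=raw.index)

    frame_ids = _numeric("frame", required=True)
    x = _numeric("x", required=False)
    y = _numeric("y", required=False)
    # a row is an empty-frame marker iff both coordinates are blank
    empty_marker = x.isna() & y.isna()
    half = x.isna() ^ y.isna()
    if half.any():
        line = int(half.idxmax())
        raise ValueError(f"{path}: line {line}: one of x/y present without the other")

    if "time" in names:
        times_col = _numeric("time", required=True)
    else:
        if fps is None:
            raise ValueError(
                f"{path}: file has no time column and no fps was configured"
            )
        times_col = frame_ids / float(fps)

    order = frame_ids.drop_duplicates().to_numpy()
    times, fields = [], []
    for fid in order:
        mask = (frame_ids == fid).to_numpy()
        times.append(float(times_col.to_numpy()[mask][0]))
        rows = mask & ~empty_marker.to_numpy()
        raw_xy = np.column_stack([x.to_numpy()[rows], y.to_numpy()[rows]])
        try:
            fields.append(normalize_points(raw_xy, bounds))
        except ValueError as exc:
            first_line = int(np.flatnonzero(rows)[0]) + skip + 1
            raise ValueError(
                f"{path}: frame {fid} (starting line {first_line}): {exc}"
            ) from exc
    t = np.asarray(times)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        i = int(np.argmax(np.diff(t) <= 0))
        raise ValueError(
            f"{path}: frame times not strictly increasing "
            f"(t={t[i]} followed by t={t[i + 1]})"
        )
    return FrameSeries(t, fields)


def write_frame_series(series: FrameSeries, path) -> Path:
    """Write a series in the canonical layout.

    Positions are written as normalized unit-square coordinates at full
    float precision, so ``read_frame_series`` with unit bounds round-trips
    losslessly.  Output bytes are deterministic for a fixed input.  Empty
    frames are written as a marker line with blank ``x`` and ``y``.
    """
    path = Path(path)
    out = ["frame,time,x,y"]
    for fid, (t, fld) in enumerate(series):
        ts = np.format_float_positional(t, trim="0", unique=True)
        if fld.n == 0:
            out.append(f"{fid},{ts},,")
            continue
        coords = fld.coords if fld.dim == 2 else np.column_stack(
            [fld.coords[:, 0], np.zeros(fld.n)]
        )
        for cx, cy in coords:
            xs = np.format_float_positional(cx, trim="0", unique=True)
            ys = np.format_float_positional(cy, trim="0", unique=True)
            out.append(f"{fid},{ts},{xs},{ys}")
    path.write_text("\n".join(out) + "\n")
    return path


def write_report(table: pd.DataFrame, path) -> Path:
    """Write a long-format report table as CSV with the canonical header."""
    path = Path(path)
    cols = [c for c in REPORT_COLUMNS if c in table.columns]
    table.to_csv(path, index=False, columns=cols, float_format="%.12g")
    return path


def read_report(path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path) -> dict:
    """Load a YAML key-value config file (empty file -> empty dict)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: config must be a key-value mapping")
    return dict(data)


def write_manifest(path, payload: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
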