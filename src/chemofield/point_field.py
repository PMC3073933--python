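"""Point fields on the unit interval/square and their geometric operations.

A *point field* is one observation frame: the positions of all tracked
organisms at a single instant, normalized to the unit interval (1-D) or the
unit square (2-D).  Everything downstream — quadrat counting, the dispersion
test, the chemotactic index — consumes these types.

Axis naming convention
----------------------
The microfluidic channel holds three side-by-side fluid bands.  We call the
direction *across* the bands the ``cross`` axis (the axis on which chemical
structure, and hence chemotaxis, exists) and the direction *along* the
channel the ``long`` axis (the control direction).  In a 2-D field the
``cross`` coordinate is stored first, the ``long`` coordinate second; in the
canonical file layout the ``x`` column is the cross axis and ``y`` the long
axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np

__all__ = [
    "Axis",
    "AXES",
    "PointField",
    "RegionBounds",
    "CountVector",
    "FrameSeries",
    "normalize_points",
    "marginal",
    "partition_counts",
    "count_in_interval",
]

Axis = Literal["cross", "long"]
AXES: tuple[Axis, Axis] = ("cross", "long")

# column index of each axis in a 2-D coordinate array
_AXIS_COLUMN = {"cross": 0, "long": 1}


@dataclass(frozen=True)
class PointField:
    """A finite set of positions in [0,1] (dim 1) or [0,1]^2 (dim 2).

    Parameters
    ----------
    coords : array_like
        Shape ``(n,)`` or ``(n, 1)`` for a 1-D field, ``(n, 2)`` for 2-D.
        Point order is preserved; points carry no identity.
    """

    coords: np.ndarray

    def __init__(self, coords) -> None:
        arr = np.asarray(coords, dtype=float)
        if arr.size == 0:
            # empty fields default to 1-D unless an explicit 2-column shape given
            if arr.ndim == 2 and arr.shape[1] == 2:
                arr = arr.reshape(0, 2)
            else:
                arr = arr.reshape(0, 1)
        elif arr.ndim == 1:
            arr = arr.reshape(-1, 1)
        elif arr.ndim != 2 or arr.shape[1] not in (1, 2):
            raise ValueError(
                f"coords must have shape (n,), (n,1) or (n,2); got {arr.shape}"
            )
        if arr.size and (np.min(arr) < 0.0 or np.max(arr) > 1.0):
            bad = np.argwhere((arr < 0.0) | (arr > 1.0))[0]
            raise ValueError(
                f"coordinate out of [0,1]: point {bad[0]}, axis {bad[1]}, "
                f"value {arr[bad[0], bad[1]]!r}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("coordinates must be finite")
        arr.setflags(write=False)
        object.__setattr__(self, "coords", arr)

    @property
    def n(self) -> int:
        """Number of points."""
        return self.coords.shape[0]

    @property
    def dim(self) -> int:
        return self.coords.shape[1]

    @property
    def values(self) -> np.ndarray:
        """1-D positions as a flat array (1-D fields only)."""
        if self.dim != 1:
            raise ValueError("values is defined for 1-D fields only")
        return self.coords[:, 0]

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n


@dataclass(frozen=True)
class RegionBounds:
    """Physical extents of the channel, one ``(low, high)`` pair per raw axis.

    ``x`` is the raw coordinate mapped onto the cross axis, ``y`` the one
    mapped onto the long axis.  Normalization always uses these configured
    extents, never per-frame minima/maxima, so the time evolution of the
    dispersion index is not distorted by frame-wise rescaling.
    """

    x: tuple[float, float] = (0.0, 1.0)
    y: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        for name, (lo, hi) in (("x", self.x), ("y", self.y)):
            if not hi > lo:
                raise ValueError(f"degenerate bounds on axis {name}: ({lo}, {hi})")

    @property
    def unit(self) -> bool:
        return self.x == (0.0, 1.0) and self.y == (0.0, 1.0)


@dataclass(frozen=True)
class CountVector:
    """Quadrat counts of a 1-D field over ``k`` equal subintervals."""

    k: int
    counts: np.ndarray

    def __init__(self, k: int, counts) -> None:
        arr = np.asarray(counts, dtype=np.int64)
        if int(k) < 2:
            raise ValueError(f"k must be >= 2, got {k}")
        if arr.ndim != 1 or arr.shape[0] != int(k):
            raise ValueError(f"counts must have length k={k}, got shape {arr.shape}")
        if np.any(arr < 0):
            raise ValueError("counts must be nonnegative")
        arr.setflags(write=False)
        object.__setattr__(self, "k", int(k))
        object.__setattr__(self, "counts", arr)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class FrameSeries:
    """Time-ordered per-frame point fields from one experiment or simulation."""

    times: np.ndarray
    fields: tuple[PointField, ...]

    def __init__(self, times, fields: Iterable[PointField]) -> None:
        t = np.asarray(times, dtype=float)
        flds = tuple(fields)
        if t.ndim != 1 or t.shape[0] != len(flds):
            raise ValueError("times and fields must have equal length")
        if t.shape[0] and np.any(np.diff(t) <= 0):
            raise ValueError("frame times must be strictly increasing")
        dims = {f.dim for f in flds if f.n > 0}
        if len(dims) > 1:
            raise ValueError(f"all frames must share dim; found {sorted(dims)}")
        t.setflags(write=False)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "fields", flds)

    @property
    def n_frames(self) -> int:
        return len(self.fields)

    def __iter__(self):
        return iter(zip(self.times, self.fields))

    def __len__(self) -> int:
        return self.n_frames


def normalize_points(
    raw: Sequence[tuple[float, float]] | np.ndarray, bounds: RegionBounds
) -> PointField:
    """Affinely map raw ``(x, y)`` positions onto the unit square.

    Every raw coordinate must lie within its axis bounds (zero tolerance);
    an out-of-range coordinate raises ``ValueError`` naming the offending
    point and axis.  Point order and count are preserved.
    """
    arr = np.asarray(raw, dtype=float).reshape(-1, 2)
    out = np.empty_like(arr)
    for j, (name, (lo, hi)) in enumerate((("x", bounds.x), ("y", bounds.y))):
        col = arr[:, j]
        bad = np.nonzero((col < lo) | (col > hi))[0]
        if bad.size:
            i = int(bad[0])
            raise ValueError(
                f"point {i} has {name}={col[i]:g} outside bounds ({lo}, {hi})"
            )
        out[:, j] = (col - lo) / (hi - lo)
    # guard round-off: (hi-lo)/(hi-lo) may exceed 1 by one ulp
    np.clip(out, 0.0, 1.0, out=out)
    return PointField(out)


def marginal(fld: PointField, axis: Axis) -> PointField:
    """Project a 2-D field onto one coordinate, preserving order and count."""
    if fld.dim != 2:
        raise ValueError(f"marginal requires a 2-D field, got dim={fld.dim}")
    if axis not in _AXIS_COLUMN:
        raise ValueError(f"axis must be one of {AXES}, got {axis!r}")
    return PointField(fld.coords[:, _AXIS_COLUMN[axis]])


def partition_counts(fld: PointField, k: int) -> CountVector:
    """Quadrat counts of a 1-D field over ``k`` equal subintervals.

    Cell ``i`` (0-based) is the half-open interval ``[i/k, (i+1)/k)``; the
    last cell is closed at 1 so boundary points are never lost.  Counts sum
    to ``n`` exactly.
    """
    if fld.dim != 1:
        raise ValueError("partition_counts requires a 1-D field")
    if int(k) < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    k = int(k)
    idx = np.floor(fld.values * k).astype(np.int64)
    np.clip(idx, 0, k - 1, out=idx)  # x == 1.0 goes to the last cell
    return CountVector(k, np.bincount(idx, minlength=k))


def count_in_interval(fld: PointField, interval: tuple[float, float]) -> int:
    """Number of points in ``[a, b)`` (closed at ``b`` only when ``b == 1``)."""
    a, b = float(interval[0]), float(interval[1])
    if not (0.0 <= a < b <= 1.0):
        raise ValueError(f"need 0 <= a < b <= 1, got ({a}, {b})")
    if fld.dim != 1:
        raise ValueError("count_in_interval requires a 1-D field")
    x = fld.values
    if b == 1.0:
        return int(np.count_nonzero((x >= a) & (x <= b)))
    return int(np.count_nonzero((x >= a) & (x < b)))
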