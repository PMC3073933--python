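"""Model/Results interface for the frame-wise homogeneity analysis.

:class:`HomogeneityModel` holds a time series of point fields together with
the analysis configuration (partition sweep, test level, axes, band
geometry); :meth:`HomogeneityModel.fit` runs the dispersion test of every
frame's coordinate marginals at every partition scale and returns a
:class:`HomogeneityResults` carrying the long-format report table, rejection
summaries, a text ``summary()`` and plotting helpers.

The null model being tested is the homogeneous Poisson point field: for each
frame and axis, quadrat counts over ``k`` equal subintervals yield the
dispersion index ``(k-1) S^2 / Nbar``, compared against two-sided
chi-squared(k-1) bounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import io as cio
from .point_field import AXES, Axis, FrameSeries, PointField, RegionBounds, marginal
from .stats import (
    DEFAULT_ALPHA,
    DEFAULT_K_RANGE,
    BandGeometry,
    chemotactic_index,
    multiscale_dispersion,
)

__all__ = ["HomogeneityModel", "HomogeneityResults"]

logger = logging.getLogger(__name__)


class HomogeneityModel:
    """Frame-wise test of complete spatial randomness for tracked positions.

    Parameters
    ----------
    series
        Time-ordered 2-D point fields (or 1-D fields, in which case only the
        ``cross`` axis is analyzed).
    k_range
        Strictly increasing partition scales for the multiscale sweep.
    alpha
        Per-test type-I error probability.  No multiple-testing correction
        is applied across scales or frames; ``alpha`` is reported per row.
    axes
        Coordinate marginals to analyze.
    band
        Geometry of the chemically loaded central band (cross axis), used
        for the chemotactic index.
    compute_chemotactic_index
        Attach the in-band/out-of-band density ratio to cross-axis rows.

    Examples
    --------
    >>> from chemofield import scenario, simulate_chemotaxis_frames
    >>> series = simulate_chemotaxis_frames(scenario("control", seed=1))
    >>> res = HomogeneityModel(series, k_range=[10]).fit()
    >>> res.table.columns.tolist()[:4]
    ['time', 'axis', 'k', 'statistic']
    """

    def __init__(
        self,
        series: FrameSeries,
        k_range: Sequence[int] = DEFAULT_K_RANGE,
        alpha: float = DEFAULT_ALPHA,
        axes: Sequence[Axis] = AXES,
        band: BandGeometry = BandGeometry(),
        compute_chemotactic_index: bool = True,
    ) -> None:
        if series.n_frames == 0:
            raise ValueError("series has no frames")
        ks = [int(k) for k in k_range]
        if not ks or any(k < 2 for k in ks):
            raise ValueError("k_range must be nonempty with every k >= 2")
        if any(b <= a for a, b in zip(ks, ks[1:])):
            raise ValueError("k_range must be strictly increasing")
        if not 0 < alpha < 1:
            raise ValueError("alpha must lie in (0,1)")
        axes = tuple(axes)
        if not axes or any(a not in AXES for a in axes):
            raise ValueError(f"axes must be a nonempty subset of {AXES}")
        self.series = series
        self.k_range = ks
        self.alpha = float(alpha)
        self.axes = axes
        self.band = band
        self.compute_chemotactic_index = bool(compute_chemotactic_index)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        bounds: RegionBounds = RegionBounds(),
        fps: float | None = None,
        **kwargs,
    ) -> "HomogeneityModel":
        """Build from a tidy frame/time/x/y DataFrame (raw coordinates)."""
        from .point_field import normalize_points

        if "frame" not in df.columns or "x" not in df.columns or "y" not in df.columns:
            raise ValueError("DataFrame needs 'frame', 'x' and 'y' columns")
        times, fields = [], []
        for fid, grp in df.groupby("frame", sort=True):
            if "time" in df.columns:
                times.append(float(grp["time"].iloc[0]))
            elif fps is not None:
                times.append(float(fid) / fps)
            else:
                raise ValueError("DataFrame has no 'time' column and no fps given")
            xy = grp[["x", "y"]].to_numpy(dtype=float)
            xy = xy[~np.isnan(xy).all(axis=1)]
            fields.append(normalize_points(xy, bounds))
        return cls(FrameSeries(times, fields), **kwargs)

    @classmethod
    def from_file(
        cls,
        path,
        bounds: RegionBounds = RegionBounds(),
        fps: float | None = None,
        dialect: str = "auto",
        column_map: Sequence[str] | None = None,
        **kwargs,
    ) -> "HomogeneityModel":
        """Build from a canonical (or mapped headerless) position file."""
        series = cio.read_frame_series(
            path, bounds=bounds, dialect=dialect, fps=fps, column_map=column_map
        )
        return cls(series, **kwargs)

    def _axis_field(self, fld: PointField, axis: Axis) -> PointField:
        if fld.dim == 2:
            return marginal(fld, axis)
        if axis != "cross":
            raise ValueError("1-D fields expose only the cross axis")
        return fld

    def fit(self) -> "HomogeneityResults":
        """Run the multiscale dispersion test on every frame and axis."""
        kmax = max(self.k_range)
        rows = []
        for t, fld in self.series:
            if 0 < fld.n < 2 * kmax:
                logger.warning(
                    "frame at t=%.6g has only n=%d points for k up to %d; "
                    "chi-squared approximation may be unreliable", t, fld.n, kmax
                )
            for axis in self.axes:
                if fld.n == 0:
                    # undefined-marked rows, never silent omission
                    for k in self.k_range:
                        rows.append((t, axis, k, np.nan, np.nan, np.nan,
                                     "undefined", 0, np.nan))
                    continue
                axis_field = self._axis_field(fld, axis)
                ci = np.nan
                if axis == "cross" and self.compute_chemotactic_index:
                    ci = chemotactic_index(axis_field, self.band)
                ms = multiscale_dispersion(axis_field, self.k_range, self.alpha)
                for r in ms:
                    rows.append((t, axis, r.k, r.statistic, r.lower, r.upper,
                                 r.verdict, axis_field.n, ci))
        table = pd.DataFrame(rows, columns=list(cio.REPORT_COLUMNS))
        table.sort_values(["time", "axis", "k"], inplace=True, kind="stable")
        table.reset_index(drop=True, inplace=True)
        return HomogeneityResults(self, table)


@dataclass
class HomogeneityResults:
    """Fitted results: one report row per (frame, axis, partition scale)."""

    model: HomogeneityModel
    table: pd.DataFrame

    @property
    def alpha(self) -> float:
        return self.model.alpha

    @property
    def k_range(self) -> list[int]:
        return self.model.k_range

    def rejection_rate(self, axis: Axis | None = None, k: int | None = None) -> float:
        """Fraction of defined test rows whose verdict rejects the null."""
        t = self.table[self.table["verdict"] != "undefined"]
        if axis is not None:
            t = t[t["axis"] == axis]
        if k is not None:
            t = t[t["k"] == k]
        if len(t) == 0:
            raise ValueError("no defined rows match the selection")
        return float((t["verdict"] != "consistent").mean())

    def statistic_series(self, axis: Axis, k: int) -> pd.DataFrame:
        """time/statistic/bounds/verdict rows for one axis and scale."""
        t = self.table[(self.table["axis"] == axis) & (self.table["k"] == k)]
        if len(t) == 0:
            raise ValueError(f"no rows for axis={axis!r}, k={k}")
        return t.reset_index(drop=True)

    def to_csv(self, path) -> None:
        cio.write_report(self.table, path)

    def summary(self, k: int | None = None) -> str:
        """Human-readable per-axis summary of the homogeneity analysis."""
        k = k if k is not None else self.k_range[len(self.k_range) // 2]
        lines = [
            "Frame-wise homogeneity analysis (dispersion index vs chi-squared bounds)",
            f"  frames: {self.model.series.n_frames}   "
            f"k range: {self.k_range[0]}..{self.k_range[-1]}   "
            f"alpha: {self.alpha:g} (per test, uncorrected)",
            "",
            f"{'axis':<6} {'rej. rate':>9} {'median I(k=%d)' % k:>15} "
            f"{'first I':>9} {'last I':>9}",
        ]
        for axis in self.model.axes:
            sub = self.statistic_series(axis, k)
            stats = sub["statistic"].dropna()
            lines.append(
                f"{axis:<6} {self.rejection_rate(axis=axis):>9.3f} "
                f"{stats.median():>15.2f} {stats.iloc[0]:>9.2f} {stats.iloc[-1]:>9.2f}"
            )
        lo = self.table["lower"].dropna()
        hi = self.table["upper"].dropna()
        if len(lo):
            sub = self.table[self.table["k"] == k].dropna(subset=["lower"])
            if len(sub):
                lines.append(
                    f"\nrejection band at k={k}: "
                    f"({sub['lower'].iloc[0]:.3f}, {sub['upper'].iloc[0]:.3f})"
                )
        if self.model.compute_chemotactic_index and "cross" in self.model.axes:
            ci = self.table[self.table["axis"] == "cross"].drop_duplicates("time")[
                "chemotactic_index"
            ].dropna()
            if len(ci):
                lines.append(
                    f"chemotactic index (cross axis): first {ci.iloc[0]:.3f}, "
                    f"last {ci.iloc[-1]:.3f}"
                )
        return "\n".join(lines)

    def plot_dispersion(self, axis: Axis = "cross", k: int | None = None, ax=None):
        """Dispersion index vs time with the chi-squared rejection band."""
        from .plotting import plot_dispersion_time

        k = k if k is not None else self.k_range[len(self.k_range) // 2]
        return plot_dispersion_time(self.table, axis=axis, k=k, ax=ax)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<HomogeneityResults: {self.model.series.n_frames} frames, "
            f"axes={self.model.axes}, k={self.k_range[0]}..{self.k_range[-1]}, "
            f"alpha={self.alpha:g}>"
        )
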