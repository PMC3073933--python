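"""Plots derived from the long-format report table and point fields."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .point_field import PointField
from .stats import BandGeometry

__all__ = ["plot_dispersion_time", "plot_field_snapshot"]


def plot_dispersion_time(table: pd.DataFrame, axis: str = "cross", k: int = 10, ax=None):
    """Dispersion index vs time for one axis and scale, with the two-sided
    chi-squared rejection band shaded."""
    import matplotlib.pyplot as plt

    sub = table[(table["axis"] == axis) & (table["k"] == k)].dropna(subset=["statistic"])
    if len(sub) == 0:
        raise ValueError(f"no defined rows for axis={axis!r}, k={k}")
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    t = sub["time"].to_numpy()
    ax.fill_between(t, sub["lower"], sub["upper"], color="0.85",
                    label="consistent with homogeneous Poisson")
    ax.plot(t, sub["statistic"], "o-", ms=3, label=f"dispersion index (k={k})")
    ax.set_xlabel("time [s]")
    ax.set_ylabel("dispersion index")
    ax.set_title(f"{axis} axis")
    ax.legend(frameon=False, fontsize="small")
    return ax


def plot_field_snapshot(field: PointField, time: float | None = None,
                        band: BandGeometry | None = None, ax=None):
    """Scatter of one 2-D frame; optionally shade the loaded central band."""
    import matplotlib.pyplot as plt

    if field.dim != 2:
        raise ValueError("snapshot requires a 2-D field")
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    if band is not None:
        ax.axvspan(band.low, band.high, color="tab:orange", alpha=0.15)
    ax.plot(field.coords[:, 0], field.coords[:, 1], "k.", ms=3)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("cross axis")
    ax.set_ylabel("long axis")
    if time is not None:
        ax.set_title(f"t = {time:g} s  (n = {field.n})")
    return ax
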