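"""Cooling-footprint products from paired control/injection runs.

The attributed effect of an injection is the per-cell time-mean of
(control - injected) temperature over a spring-neap cycle; positive values
are cooling.  The footprint is summarised as a histogram of reef area
(cells with depth < 20 m) against that mean reduction in 0.05 degC bins,
from which threshold areas ("ha cooled by at least 0.15 degC") and the
Degree-Heating-Week reduction of a sustained cooling are derived:

    DHW reduction = dT [degC] * days / 7.

Bins are half-open [lo, hi); warming cells (negative reduction) are lumped
into a single below-zero bin and never counted toward threshold areas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .synthetic_reef import ReefGrid
from .tracer_engine import TracerState

__all__ = [
    "CoolingFootprint",
    "DhwReduction",
    "mean_reduction_field",
    "footprint_histogram",
    "area_at_threshold",
    "dhw_reduction",
    "footprint_to_csv",
    "field_to_netcdf",
]

M2_PER_HA = 1e4


@dataclass(frozen=True)
class CoolingFootprint:
    """Area-vs-cooling histogram over the depth < 20 m footprint.

    ``bin_edges`` has length nbins+1 (degC, width 0.05 by default);
    ``area_ha[k]`` is the footprint area with mean reduction in
    [edges[k], edges[k+1]).  Bins with area <= ``cutoff_ha`` are flagged as
    not displayed but always retained, so area totals are conserved.
    """

    bin_edges: np.ndarray  # degC
    area_ha: np.ndarray  # ha, per bin
    negative_area_ha: float  # warming cells, single bin
    total_footprint_ha: float
    cutoff_ha: float = 1.0

    def __post_init__(self) -> None:
        if np.any(self.area_ha < 0) or self.negative_area_ha < 0:
            raise ValueError("bin areas must be >= 0")
        binned = float(self.area_ha.sum()) + self.negative_area_ha
        if binned > self.total_footprint_ha * (1 + 1e-9) + 1e-9:
            raise ValueError("binned area exceeds the total footprint area")

    @property
    def displayed(self) -> np.ndarray:
        """Bins large enough to show (area > cutoff)."""
        return self.area_ha > self.cutoff_ha

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_lo_degC": self.bin_edges[:-1],
            "bin_hi_degC": self.bin_edges[1:],
            "area_ha": self.area_ha,
            "displayed": self.displayed,
        })


@dataclass(frozen=True)
class DhwReduction:
    """Thermal-stress relief of a sustained cooling, in degC-weeks."""

    delta_t: float  # degC
    days: float
    reduction: float  # DHW

    def __post_init__(self) -> None:
        if self.reduction < 0:
            raise ValueError("DHW reduction must be >= 0")


def mean_reduction_field(
    control: list[TracerState],
    injected: list[TracerState],
    window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Per-cell time-mean of (control - injected) temperature over ``window``.

    The two trajectories must share time stamps; ``window`` defaults to the
    full common record and should span one spring-neap cycle for footprint
    use.  Positive values are cooling.
    """
    if len(control) != len(injected):
        raise ValueError("control and injected trajectories differ in length")
    tc = np.array([s.time for s in control])
    ti = np.array([s.time for s in injected])
    if not np.allclose(tc, ti, rtol=0, atol=1e-6):
        raise ValueError("control and injected time axes are misaligned")
    if window is None:
        sel = np.ones(tc.size, dtype=bool)
    else:
        t0, t1 = window
        sel = (tc >= t0 - 1e-6) & (tc <= t1 + 1e-6)
        if not sel.any():
            raise ValueError("window contains no samples")
    diffs = [control[k].values - injected[k].values
             for k in np.nonzero(sel)[0]]
    return np.mean(diffs, axis=0)


def footprint_histogram(
    delta_t: np.ndarray,
    grid: ReefGrid,
    bin_width: float = 0.05,
    cutoff_ha: float = 1.0,
) -> CoolingFootprint:
    """Bin footprint-cell areas by their mean temperature reduction."""
    mask = grid.footprint_mask
    vals = np.asarray(delta_t, dtype=float)[mask]
    cell_ha = grid.cell_area / M2_PER_HA
    total_ha = mask.sum() * cell_ha

    pos = vals[vals >= 0.0]
    neg_area = float((vals < 0.0).sum() * cell_ha)
    vmax = pos.max() if pos.size else 0.0
    nbins = max(1, int(np.floor(vmax / bin_width + 1e-9)) + 1)
    edges = np.arange(nbins + 1) * bin_width
    idx = np.minimum((pos / bin_width + 1e-9).astype(int), nbins - 1)
    area = np.bincount(idx, minlength=nbins).astype(float) * cell_ha

    return CoolingFootprint(bin_edges=edges, area_ha=area,
                            negative_area_ha=neg_area,
                            total_footprint_ha=float(total_ha),
                            cutoff_ha=cutoff_ha)


def area_at_threshold(footprint: CoolingFootprint, threshold: float) -> float:
    """Total area [ha] with mean reduction at or above ``threshold``.

    ``threshold`` must align with a bin edge (no interpolation across bins).
    """
    width = footprint.bin_edges[1] - footprint.bin_edges[0]
    if abs(threshold / width - round(threshold / width)) > 1e-6:
        raise ValueError(
            f"threshold {threshold} does not align with the {width} degC bin edges")
    lo = footprint.bin_edges[:-1]
    return float(footprint.area_ha[lo >= threshold - 1e-9].sum())


def dhw_reduction(delta_t: float, days: float) -> DhwReduction:
    """Degree-Heating-Week relief of cooling by ``delta_t`` for ``days``."""
    if delta_t < 0 or days < 0:
        raise ValueError("delta_t and days must be >= 0")
    return DhwReduction(delta_t=float(delta_t), days=float(days),
                        reduction=float(delta_t) * float(days) / 7.0)


def footprint_to_csv(footprint: CoolingFootprint, path) -> None:
    footprint.as_frame().to_csv(path, index=False)


def field_to_netcdf(delta_t: np.ndarray, grid: ReefGrid, path, **attrs) -> None:
    """Write a mean temperature-reduction field as NetCDF."""
    ds = xr.Dataset(
        {"delta_t": (("y", "x"), np.asarray(delta_t, dtype=float),
                     {"units": "degC", "positive": "cooling"})},
        coords={"x": ("x", grid.x, {"units": "m"}),
                "y": ("y", grid.y, {"units": "m"})},
        attrs=attrs,
    )
    ds.to_netcdf(path, engine="scipy")
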