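"""Applying a trained retrieval model: maps, profiles, validation.

Inverts multiband reflectance rasters pixel-by-pixel into LAI and
uncertainty maps, aggregates dated LAI maps over plot polygons into
per-plot phenology profiles on a days-after-sowing axis, and scores
predicted against observed LAI.

Growth phases follow the rice calendar: vegetative through 57 DAS,
reproductive (panicle initiation to heading) 58-72 DAS, ripening
beyond.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as _shapely_shape

from .gpr import GPRModel, ValidationReport, predict, regression_metrics
from .raster import Raster

__all__ = [
    "PhaseCalendar",
    "PhenologyProfile",
    "invert_raster",
    "extract_profiles",
    "validate",
    "load_plots_geojson",
]

#: Reflectance sanity window: pixels with any band outside are masked
#: (atmospheric correction can push surface reflectance slightly over 1).
REFLECTANCE_VALID = (0.0, 1.2)


@dataclass(frozen=True)
class PhaseCalendar:
    """Sowing date and DAS thresholds delimiting the growth phases."""

    sowing_date: _dt.date
    vegetative_end: int = 57
    reproductive_end: int = 72

    def das(self, date: _dt.date) -> int:
        return (date - self.sowing_date).days

    def phase(self, das: int) -> str:
        if das <= self.vegetative_end:
            return "vegetative"
        if das <= self.reproductive_end:
            return "reproductive"
        return "ripening"


@dataclass(frozen=True)
class PhenologyProfile:
    """Per-plot LAI time series with phase labels."""

    plot_id: str
    observations: pd.DataFrame  # date, das, lai_mean, lai_sd, phase

    def __post_init__(self) -> None:
        das = self.observations["das"].to_numpy()
        if np.any(np.diff(das) <= 0):
            raise ValueError("days_after_sowing must be strictly increasing")


def invert_raster(model: GPRModel, raster: Raster) -> tuple[Raster, Raster]:
    """Per-pixel LAI mean and standard-deviation maps.

    Nodata pixels and pixels with any band outside the plausible
    reflectance window are propagated as nodata; georeferencing is
    preserved.
    """
    if raster.n_bands != model.n_bands:
        raise ValueError(
            f"raster has {raster.n_bands} bands, model expects {model.n_bands}"
        )
    bad = raster.mask()
    lo, hi = REFLECTANCE_VALID
    with np.errstate(invalid="ignore"):
        bad |= ((raster.data < lo) | (raster.data > hi)).any(axis=0)

    rows, cols = raster.shape
    X = raster.data.reshape(raster.n_bands, -1).T
    valid = ~bad.ravel()
    lai = np.full(rows * cols, np.nan)
    sd = np.full(rows * cols, np.nan)
    if valid.any():
        pred = predict(model, X[valid])
        lai[valid] = pred.mean
        sd[valid] = np.sqrt(pred.variance)

    nodata = raster.nodata if raster.nodata is not None else -9999.0
    lai = np.where(np.isnan(lai), nodata, lai).reshape(rows, cols)
    sd = np.where(np.isnan(sd), nodata, sd).reshape(rows, cols)
    out_lai = Raster(
        lai[None], raster.transform, nodata=nodata, epsg=raster.epsg,
        band_names=("lai",),
    )
    out_sd = Raster(
        sd[None], raster.transform, nodata=nodata, epsg=raster.epsg,
        band_names=("lai_sd",),
    )
    return out_lai, out_sd


def load_plots_geojson(source) -> dict[str, shapely.Geometry]:
    """plot_id -> polygon from a GeoJSON FeatureCollection (path or dict)."""
    if isinstance(source, (str, bytes)) or hasattr(source, "read"):
        with open(source) as fh:
            gj = json.load(fh)
    elif isinstance(source, dict):
        gj = source
    else:
        raise TypeError("expected a path or GeoJSON dict")
    plots = {}
    for feat in gj["features"]:
        pid = str(feat["properties"]["plot_id"])
        plots[pid] = _shapely_shape(feat["geometry"])
    if not plots:
        raise ValueError("no features with a plot_id property found")
    return plots


def _plot_pixels(raster: Raster, geom: shapely.Geometry) -> np.ndarray:
    """Values of band 0 at valid pixel centres inside the polygon."""
    x, y = raster.pixel_centers()
    inside = shapely.contains_xy(geom, x.ravel(), y.ravel()).reshape(x.shape)
    if not inside.any():
        raise ValueError("plot polygon does not intersect the raster")
    good = inside & ~raster.mask()
    return raster.data[0][good]


def extract_profiles(
    lai_maps: list[tuple[_dt.date, Raster]],
    plots: dict[str, shapely.Geometry],
    calendar: PhaseCalendar,
) -> list[PhenologyProfile]:
    """Aggregate dated LAI maps into per-plot phenology profiles.

    For every plot polygon and map date: mean and standard deviation of
    the valid pixels whose centres fall inside the polygon, the DAS from
    the sowing date, and the growth-phase label.  Observations are
    sorted by DAS regardless of input order.
    """
    profiles = []
    for pid, geom in plots.items():
        rows = []
        for date, raster in sorted(lai_maps, key=lambda dr: dr[0]):
            vals = _plot_pixels(raster, geom)
            das = calendar.das(date)
            rows.append(
                {
                    "date": date,
                    "das": das,
                    "lai_mean": float(vals.mean()) if vals.size else np.nan,
                    "lai_sd": float(vals.std()) if vals.size else np.nan,
                    "phase": calendar.phase(das),
                }
            )
        profiles.append(PhenologyProfile(pid, pd.DataFrame(rows)))
    return profiles


def validate(
    predicted: np.ndarray,
    observed: np.ndarray,
    phases: np.ndarray | None = None,
    subset: str = "all",
) -> ValidationReport:
    """Score predicted against observed LAI.

    ``subset`` may name a growth phase (with ``phases`` labels supplied)
    or "all".  Reports the least-squares fit R², slope and intercept of
    predicted on observed (for 1:1-line deviation reporting), the RMSE,
    and a secondary 1:1-agreement R².
    """
    p = np.asarray(predicted, dtype=float)
    o = np.asarray(observed, dtype=float)
    if p.shape != o.shape:
        raise ValueError("predicted and observed must have equal length")
    if subset != "all":
        if phases is None:
            raise ValueError("phase labels required for a phase subset")
        keep = np.asarray(phases) == subset
        p, o = p[keep], o[keep]
    if p.size < 2:
        raise ValueError("need at least 2 samples after subsetting")
    return regression_metrics(p, o)
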