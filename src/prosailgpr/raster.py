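"""Lightweight multiband GeoTIFF raster I/O.

A raster is a (bands, rows, cols) array with a north-up affine
geotransform (GDAL order: x0, dx, 0, y0, 0, -dy), an optional nodata
value and an optional EPSG code.  Files are written as tiled-free
striped GeoTIFFs via tifffile with the standard georeferencing tags
(ModelPixelScale, ModelTiepoint, GDAL_NODATA and a minimal
GeoKeyDirectory carrying the EPSG code), so they round-trip through
this module and open in GIS software.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import tifffile

__all__ = ["Raster", "read_geotiff", "write_geotiff"]

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEYS = 34735
_TAG_GDAL_NODATA = 42113


@dataclass
class Raster:
    """Multiband pixel grid with spatial referencing."""

    data: np.ndarray  # (bands, rows, cols)
    transform: tuple[float, float, float, float, float, float] = (
        0.0,
        1.0,
        0.0,
        0.0,
        0.0,
        -1.0,
    )
    nodata: float | None = None
    epsg: int | None = None
    band_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        a = np.asarray(self.data)
        if a.ndim == 2:
            a = a[None]
        if a.ndim != 3:
            raise ValueError("raster data must be (bands, rows, cols)")
        self.data = a
        if self.band_names and len(self.band_names) != a.shape[0]:
            raise ValueError("one band name per band required")

    @property
    def n_bands(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    def mask(self) -> np.ndarray:
        """Boolean (rows, cols) array: True where any band is nodata/NaN."""
        bad = ~np.isfinite(self.data).all(axis=0)
        if self.nodata is not None:
            bad |= (self.data == self.nodata).any(axis=0)
        return bad

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) world coordinates of every pixel centre, as 2-D arrays."""
        x0, dx, _, y0, _, dy = self.transform
        rows, cols = self.shape
        cc, rr = np.meshgrid(np.arange(cols), np.arange(rows))
        return x0 + (cc + 0.5) * dx, y0 + (rr + 0.5) * dy

    def like(self, data: np.ndarray, band_names: tuple[str, ...] = ()) -> "Raster":
        """A new raster sharing this one's georeferencing."""
        return replace(self, data=data, band_names=band_names)


def write_geotiff(path, raster: Raster) -> None:
    x0, dx, _, y0, _, dy = raster.transform
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (abs(dx), abs(dy), 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, x0, y0, 0.0)),
    ]
    if raster.epsg is not None:
        # minimal GeoKeyDirectory: version 1.1.0, one key (ProjectedCSType)
        keys = (1, 1, 0, 1, 3072, 0, 1, int(raster.epsg))
        extratags.append((_TAG_GEO_KEYS, "H", len(keys), keys))
    if raster.nodata is not None:
        nd = str(raster.nodata)
        extratags.append((_TAG_GDAL_NODATA, "s", len(nd) + 1, nd))
    if raster.n_bands == 1:
        tifffile.imwrite(
            path, raster.data[0], photometric="minisblack", extratags=extratags
        )
    else:
        tifffile.imwrite(
            path,
            raster.data,
            planarconfig="separate",
            photometric="minisblack",
            extratags=extratags,
        )


def read_geotiff(path) -> Raster:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = tif.asarray()
        if data.ndim == 2:
            data = data[None]
        tags = page.tags
        transform = (0.0, 1.0, 0.0, 0.0, 0.0, -1.0)
        if _TAG_MODEL_PIXEL_SCALE in tags and _TAG_MODEL_TIEPOINT in tags:
            sx, sy, _ = tags[_TAG_MODEL_PIXEL_SCALE].value
            _, _, _, x0, y0, _ = tags[_TAG_MODEL_TIEPOINT].value
            transform = (float(x0), float(sx), 0.0, float(y0), 0.0, -float(sy))
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
        epsg = None
        if _TAG_GEO_KEYS in tags:
            v = tags[_TAG_GEO_KEYS].value
            for i in range(4, len(v), 4):
                if v[i] == 3072:
                    epsg = int(v[i + 3])
    return Raster(data, transform=transform, nodata=nodata, epsg=epsg)
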