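"""Sentinel-2 MSI band definitions and spectral resampling.

The ten surface-reflectance bands retained after Level-2A processing at
20 m (B2-B8A, B11, B12).  Full-resolution (1 nm) spectra are convolved
with per-band spectral response functions; by default each response is a
Gaussian whose FWHM equals the nominal bandwidth, truncated at twice the
FWHM either side of the centre.  Tabulated official response functions
can be supplied per band to override the Gaussian shape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["Band", "BandSet", "sentinel2_bands", "resample_to_bands"]


@dataclass(frozen=True)
class Band:
    """One spectral band: centre in µm, bandwidth (FWHM) in nm."""

    name: str
    center_um: float
    bandwidth_nm: float
    resolution_m: float = 20.0
    #: optional tabulated response: (wavelengths_nm, weights)
    srf: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def center_nm(self) -> float:
        return self.center_um * 1000.0

    def response(self, wavelengths: np.ndarray) -> np.ndarray:
        """Response weights on the given 1 nm wavelength grid."""
        wl = np.asarray(wavelengths, dtype=float)
        if self.srf is not None:
            swl, sw = self.srf
            return np.interp(wl, swl, sw, left=0.0, right=0.0)
        c = self.center_nm
        fwhm = self.bandwidth_nm
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        w = np.exp(-0.5 * ((wl - c) / sigma) ** 2)
        w[np.abs(wl - c) > 2.0 * fwhm] = 0.0
        return w


@dataclass(frozen=True)
class BandSet:
    """Ordered collection of bands with strictly increasing centres."""

    bands: tuple[Band, ...]

    def __post_init__(self) -> None:
        centers = [b.center_um for b in self.bands]
        if any(c2 <= c1 for c1, c2 in zip(centers, centers[1:])):
            raise ValueError("band centres must be strictly increasing")
        if any(b.bandwidth_nm <= 0 for b in self.bands):
            raise ValueError("bandwidths must be positive")

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.bands]

    def weight_matrix(self, wavelengths: np.ndarray) -> np.ndarray:
        """(n_bands, n_wavelengths) normalized response weights.

        Each band's nominal interval (centre ± bandwidth/2) must be
        covered by the wavelength grid; Gaussian tails beyond the grid
        are clipped.
        """
        wl = np.asarray(wavelengths, dtype=float)
        W = np.empty((len(self.bands), wl.size))
        for i, b in enumerate(self.bands):
            half = b.bandwidth_nm / 2.0
            if b.center_nm - half < wl[0] or b.center_nm + half > wl[-1]:
                raise ValueError(
                    f"band {b.name} nominal support "
                    f"[{b.center_nm - half:.0f}, {b.center_nm + half:.0f}] nm "
                    f"outside spectrum grid [{wl[0]:.0f}, {wl[-1]:.0f}] nm"
                )
            w = b.response(wl)
            s = w.sum()
            if s <= 0:
                raise ValueError(f"band {b.name} response is zero on the grid")
            W[i] = w / s
        return W

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": self.names,
                "center_um": [b.center_um for b in self.bands],
                "bandwidth_nm": [b.bandwidth_nm for b in self.bands],
                "resolution_m": [b.resolution_m for b in self.bands],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BandSet":
        return cls(
            tuple(
                Band(r["name"], r["center_um"], r["bandwidth_nm"], r["resolution_m"])
                for _, r in df.iterrows()
            )
        )


#: Table of the ten retained MSI bands: name, centre (µm), FWHM (nm), res (m).
_S2 = [
    ("B2", 0.49, 65.0, 10.0),
    ("B3", 0.56, 35.0, 10.0),
    ("B4", 0.67, 30.0, 10.0),
    ("B5", 0.71, 15.0, 20.0),
    ("B6", 0.74, 15.0, 20.0),
    ("B7", 0.783, 20.0, 20.0),
    ("B8", 0.84, 115.0, 10.0),
    ("B8A", 0.87, 20.0, 20.0),
    ("B11", 1.61, 90.0, 20.0),
    ("B12", 2.19, 180.0, 20.0),
]


def sentinel2_bands() -> BandSet:
    """The default ten-band Sentinel-2 MSI set (B2-B8A, B11, B12)."""
    return BandSet(tuple(Band(n, c, bw, r) for n, c, bw, r in _S2))


def resample_to_bands(
    spectrum_values: np.ndarray,
    band_set: BandSet,
    wavelengths: np.ndarray,
) -> np.ndarray:
    """Convolve spectra with band responses.

    ``spectrum_values`` may be 1-D (n_wl,) or 2-D (n_spectra, n_wl);
    returns (n_bands,) or (n_spectra, n_bands) accordingly.  Linear in
    the spectra; a flat spectrum is a fixed point.
    """
    W = band_set.weight_matrix(wavelengths)
    v = np.asarray(spectrum_values, dtype=float)
    if v.ndim == 1:
        return W @ v
    return v @ W.T
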