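"""Look-up-table generation: parameter sampling -> coupled RTM -> bands.

The training database for the retrieval model: sampled parameter
vectors are pushed through the leaf and canopy radiative-transfer
models against seeded soil backgrounds, the resulting 1 nm spectra are
resampled to the sensor bands, and (separately, so that the clean table
is preserved) Gaussian noise is applied for training.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import BandSet, sentinel2_bands
from .canopy import CanopyParams, ViewGeometry, sail_reflectance
from .leaf import AbsorptionTable, LeafParams, default_absorption_table, leaf_rt
from .noise import NoiseModel, add_noise
from .sampling import SamplingConfig, default_sampling_config, sample_parameters
from .synthetic import SoilLibrary, generate_soil_library

__all__ = ["LUT", "simulate_lut", "build_training_lut"]

_LEAF_COLS = ("N", "Cab", "Cw", "Cm")


@dataclass
class LUT:
    """Sampled parameters paired with simulated band reflectance."""

    params: pd.DataFrame  # (n, p)
    spectra: np.ndarray  # (n, n_bands)
    band_set: BandSet
    noisy: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.params) != self.spectra.shape[0]:
            raise ValueError("params and spectra row counts differ")
        if not np.all(np.isfinite(self.spectra)):
            raise ValueError("spectra must be finite")
        if not self.noisy and (
            self.spectra.min() < 0 or self.spectra.max() > 1
        ):
            raise ValueError("pre-noise spectra must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.params)

    @property
    def lai(self) -> np.ndarray:
        return self.params["LAI"].to_numpy()

    def with_noise(self, noise: NoiseModel, seed: int | None = None) -> "LUT":
        """A noisy copy of this LUT (clean table left untouched)."""
        rng = np.random.default_rng(noise.seed if seed is None else seed)
        noisy = add_noise(self.spectra, noise, rng)
        prov = dict(self.provenance)
        prov["noise"] = asdict(noise)
        if seed is not None:
            prov["noise"]["seed"] = seed
        return LUT(self.params, noisy, self.band_set, noisy=True, provenance=prov)

    def save(self, directory) -> None:
        """Persist as params CSV + spectra CSV + JSON sidecar (bit-exact)."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.params.to_csv(d / "lut_params.csv", index=False, float_format="%.17g")
        pd.DataFrame(self.spectra, columns=self.band_set.names).to_csv(
            d / "lut_spectra.csv", index=False, float_format="%.17g"
        )
        sidecar = {
            "noisy": self.noisy,
            "provenance": self.provenance,
            "bands": self.band_set.to_frame().to_dict(orient="records"),
        }
        (d / "lut_meta.json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, directory) -> "LUT":
        d = Path(directory)
        params = pd.read_csv(d / "lut_params.csv", float_precision="round_trip")
        spectra_df = pd.read_csv(d / "lut_spectra.csv", float_precision="round_trip")
        meta = json.loads((d / "lut_meta.json").read_text())
        band_set = BandSet.from_frame(pd.DataFrame(meta["bands"]))
        return cls(
            params,
            spectra_df.to_numpy(),
            band_set,
            noisy=meta["noisy"],
            provenance=meta["provenance"],
        )


def simulate_lut(
    params: pd.DataFrame,
    soil_library: SoilLibrary,
    band_set: BandSet | None = None,
    table: AbsorptionTable | None = None,
    geometry: ViewGeometry | None = None,
    skyl: float = 0.1,
    soil_seed: int = 0,
) -> LUT:
    """Simulate one clean band spectrum per parameter row.

    Every row needs the leaf columns (N, Cab, Cw, Cm), LAI, ALA and a
    ``soil`` scaling factor; ``psi`` (relative azimuth, deg) and
    ``hotspot`` are optional.  Each row's soil background is a seeded
    draw of a wet/dry endmember pair from the library mixed by the row's
    scaling factor.  Full 1 nm spectra are resampled to the band set
    before storage.
    """
    band_set = band_set or sentinel2_bands()
    table = table or default_absorption_table()
    geometry = geometry or ViewGeometry()
    required = set(_LEAF_COLS) | {"LAI", "ALA", "soil"}
    missing = required - set(params.columns)
    if missing:
        raise ValueError(f"parameter matrix missing columns {sorted(missing)}")
    if len(soil_library) == 0:
        raise ValueError("soil library is empty")

    rng = np.random.default_rng(soil_seed)
    W = band_set.weight_matrix(table.wavelengths)
    spectra = np.empty((len(params), len(band_set)))

    cols = {c: params[c].to_numpy() for c in params.columns}
    for i in range(len(params)):
        leaf = LeafParams(
            cols["N"][i], cols["Cab"][i], cols["Cw"][i], cols["Cm"][i]
        )
        lr, lt = leaf_rt(leaf, table)
        soil = soil_library.background(float(cols["soil"][i]), rng)
        canopy = CanopyParams(
            LAI=float(cols["LAI"][i]),
            ALA=float(cols["ALA"][i]),
            hotspot=float(cols["hotspot"][i]) if "hotspot" in cols else 0.01,
            skyl=skyl,
        )
        geom = ViewGeometry(
            geometry.sun_zenith,
            geometry.view_zenith,
            float(cols["psi"][i]) if "psi" in cols else geometry.relative_azimuth,
        )
        toc = sail_reflectance(lr, lt, canopy, soil, geom)
        spectra[i] = W @ toc.values

    provenance = {
        "soil_seed": soil_seed,
        "n_soil_samples": len(soil_library),
        "geometry": {
            "sun_zenith": geometry.sun_zenith,
            "view_zenith": geometry.view_zenith,
        },
        "skyl": skyl,
        "rtm": "prospect4+4sail",
    }
    return LUT(params.reset_index(drop=True), spectra, band_set, provenance=provenance)


def build_training_lut(
    n_samples: int = 2000,
    seed: int = 0,
    noise: NoiseModel | None = None,
    sampling: SamplingConfig | None = None,
    soil_library: SoilLibrary | None = None,
    band_set: BandSet | None = None,
    table: AbsorptionTable | None = None,
    geometry: ViewGeometry | None = None,
) -> tuple[LUT, LUT]:
    """One-call study pipeline: sample, simulate, perturb.

    Returns ``(clean, noisy)`` LUTs.  Defaults reproduce the standard
    training database: 2000 samples, the Table-style parameter
    distributions, a 69-sample synthetic wet/dry soil library and the
    four-component noise model at AD=AI=0.01, MD=MI=2 %.  All randomness
    derives from ``seed``.
    """
    rng = np.random.default_rng(seed)
    s_sample, s_soil, s_soilgen, s_noise = rng.integers(2**31, size=4)
    sampling = sampling or default_sampling_config(n_samples=n_samples)
    sampling = sampling.with_overrides(n_samples=n_samples, seed=int(s_sample))
    params = sample_parameters(sampling)
    soil_library = (
        soil_library
        if soil_library is not None
        else generate_soil_library(69, seed=int(s_soilgen))
    )
    clean = simulate_lut(
        params,
        soil_library,
        band_set=band_set,
        table=table,
        geometry=geometry,
        soil_seed=int(s_soil),
    )
    clean.provenance["seed"] = seed
    noise = noise if noise is not None else NoiseModel()
    noisy = clean.with_noise(noise, seed=int(s_noise))
    return clean, noisy
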