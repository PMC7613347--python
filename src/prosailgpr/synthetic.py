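"""Synthetic stand-ins for the field data of an irrigated-rice campaign.

The retrieval pipeline needs three things no public archive provides for
the target system: a library of wet/dry soil background spectra, true
per-plot LAI trajectories under crossed nitrogen x irrigation
treatments, and plot-level reflectance with matching noisy LAI
observations.  Everything here is generated deterministically from a
seed so end-to-end tests are reproducible.

The experiment layout emulated is a split-plot factorial: 3 blocks x 3
plots x 3 subplots = 27 sampling units; irrigation regime (continuously
flooded CF, alternate wetting with moderate AWMD or severe AWSD drying)
varies between plots and nitrogen rate (55/110/165 kg/ha) between
subplots.  Trajectories follow a double-logistic curve in days after
sowing (DAS): LAI rises through the vegetative phase, peaks in the
reproductive or ripening phase, then declines; water-limited regimes
show a transient dip late in the vegetative phase and peak LAI grows
with nitrogen rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bands import BandSet, resample_to_bands, sentinel2_bands
from .canopy import CanopyParams, SoilSpectrum, ViewGeometry, mix_soil, sail_reflectance
from .leaf import AbsorptionTable, LeafParams, Spectrum, WAVELENGTHS, leaf_rt
from .noise import NoiseModel, add_noise
from .sampling import SamplingConfig, default_sampling_config

__all__ = [
    "TreatmentConfig",
    "SoilLibrary",
    "SyntheticCampaign",
    "generate_soil_library",
    "generate_phenology_truth",
    "render_campaign",
    "coefficient_fixture",
    "DEFAULT_DAS",
]

#: Default observation days-after-sowing (seven field/satellite dates).
DEFAULT_DAS = (37, 42, 52, 57, 62, 72, 92)

NITROGEN_RATES = {"low": 55.0, "normal": 110.0, "high": 165.0}
IRRIGATION_REGIMES = ("CF", "AWMD", "AWSD")


@dataclass(frozen=True)
class TreatmentConfig:
    """Factorial layout of the synthetic experiment."""

    blocks: int = 3
    plots: int = 3
    subplots: int = 3

    def units(self) -> pd.DataFrame:
        """One row per sampling unit with its treatment assignment.

        Irrigation varies between plots, nitrogen between subplots.
        """
        rows = []
        nitro = list(NITROGEN_RATES)
        for b in range(self.blocks):
            for p in range(self.plots):
                irr = IRRIGATION_REGIMES[p % len(IRRIGATION_REGIMES)]
                for s in range(self.subplots):
                    nl = nitro[s % len(nitro)]
                    rows.append(
                        {
                            "plot_id": f"B{b + 1}P{p + 1}SP{s + 1}",
                            "block": b + 1,
                            "plot": p + 1,
                            "subplot": s + 1,
                            "irrigation": irr,
                            "nitrogen": nl,
                            "nitrogen_kg_ha": NITROGEN_RATES[nl],
                        }
                    )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class SoilLibrary:
    """Paired wet/dry soil reflectance spectra on a common grid."""

    wavelengths: np.ndarray
    spectra: np.ndarray  # (n_samples, n_wl)
    labels: tuple[str, ...]  # "wet" | "dry" per sample

    def __post_init__(self) -> None:
        if self.spectra.shape[0] != len(self.labels):
            raise ValueError("one label per spectrum required")

    def __len__(self) -> int:
        return self.spectra.shape[0]

    @property
    def dry(self) -> np.ndarray:
        return self.spectra[[l == "dry" for l in self.labels]]

    @property
    def wet(self) -> np.ndarray:
        return self.spectra[[l == "wet" for l in self.labels]]

    def draw_pair(self, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        """A random (dry, wet) endmember pair."""
        d, w = self.dry, self.wet
        k = int(rng.integers(0, min(len(d), len(w))))
        return d[k], w[k]

    def background(self, scaling: float, rng: np.random.Generator) -> SoilSpectrum:
        """Seeded soil background: scaling-weighted dry/wet mixture."""
        d, w = self.draw_pair(rng)
        return mix_soil(
            Spectrum(self.wavelengths, d), Spectrum(self.wavelengths, w), scaling
        )

    def to_csv(self, path, metadata_path) -> None:
        df = pd.DataFrame(
            self.spectra.T, columns=[f"s{i:03d}" for i in range(len(self))]
        )
        df.insert(0, "wavelength_nm", self.wavelengths)
        df.to_csv(path, index=False)
        pd.DataFrame(
            {"sample_id": [f"s{i:03d}" for i in range(len(self))], "moisture_label": self.labels}
        ).to_csv(metadata_path, index=False)

    @classmethod
    def from_csv(cls, path, metadata_path) -> "SoilLibrary":
        df = pd.read_csv(path)
        meta = pd.read_csv(metadata_path)
        wl = df["wavelength_nm"].to_numpy()
        ids = meta["sample_id"].tolist()
        spectra = df[ids].to_numpy().T
        return cls(wl, spectra, tuple(meta["moisture_label"]))


def _soil_template(wl: np.ndarray) -> np.ndarray:
    """Smooth dry-soil reflectance shape rising into the SWIR."""
    base = 0.10 + 0.16 * (1.0 - np.exp(-(wl - 400.0) / 900.0))
    # weak clay/carbonate features
    base -= 0.015 * np.exp(-0.5 * ((wl - 2200.0) / 80.0) ** 2)
    return base


def _water_darkening(wl: np.ndarray) -> np.ndarray:
    """Multiplicative darkening of a wetted soil (deepest at water bands)."""
    absorb = (
        0.25 * np.exp(-0.5 * ((wl - 1450.0) / 90.0) ** 2)
        + 0.35 * np.exp(-0.5 * ((wl - 1940.0) / 110.0) ** 2)
        + 0.10 * np.exp(-0.5 * ((wl - 2400.0) / 150.0) ** 2)
        + 0.05 * np.exp(-0.5 * ((wl - 970.0) / 60.0) ** 2)
    )
    return (1.0 - absorb) * 0.62


def generate_soil_library(n_samples: int = 69, seed: int = 0) -> SoilLibrary:
    """Synthetic wet/dry soil spectral library.

    Each sample is the smooth dry-soil template scaled by a per-sample
    brightness factor in [0.5, 1.5] with mild spectral slope variation;
    wet samples are darkened counterparts with deepened water-absorption
    bands.  Labels split half/half (dry gets the extra sample when n is
    odd).  Deterministic given the seed.
    """
    if n_samples < 2:
        raise ValueError("soil library needs at least 2 samples")
    rng = np.random.default_rng(seed)
    wl = WAVELENGTHS
    template = _soil_template(wl)
    darken = _water_darkening(wl)

    n_dry = (n_samples + 1) // 2
    n_wet = n_samples - n_dry
    spectra = []
    labels = []
    dry_bank = []
    for i in range(n_dry):
        brightness = rng.uniform(0.5, 1.5)
        slope = 1.0 + rng.uniform(-0.1, 0.1) * (wl - 1450.0) / 1050.0
        s = np.clip(template * brightness * slope, 0.0, 1.0)
        dry_bank.append(s)
        spectra.append(s)
        labels.append("dry")
    for i in range(n_wet):
        wet = np.clip(dry_bank[i % n_dry] * darken, 0.0, 1.0)
        spectra.append(wet)
        labels.append("wet")
    return SoilLibrary(wl, np.asarray(spectra), tuple(labels))


def _double_logistic(
    das: np.ndarray,
    base: float,
    amplitude: float,
    t_rise: float,
    k_rise: float,
    t_fall: float,
    k_fall: float,
) -> np.ndarray:
    rise = 1.0 / (1.0 + np.exp(-k_rise * (das - t_rise)))
    fall = 1.0 / (1.0 + np.exp(-k_fall * (das - t_fall)))
    return base + amplitude * (rise - fall)


#: Peak LAI by nitrogen rate for a continuously flooded plot, before
#: block/plot effects; spacing exceeds the random-effect range so the
#: nitrogen ordering of peaks is preserved in every replicate.
_PEAK_BY_NITROGEN = {"low": 4.6, "normal": 6.0, "high": 7.4}
#: Transient vegetative-phase dip depth (fraction) by irrigation regime.
_DIP_BY_IRRIGATION = {"CF": 0.0, "AWMD": 0.12, "AWSD": 0.22}


def generate_phenology_truth(
    treatments: TreatmentConfig | None = None,
    dates: tuple[int, ...] = DEFAULT_DAS,
    seed: int = 0,
) -> pd.DataFrame:
    """True LAI trajectories for every sampling unit.

    Returns a long DataFrame (plot_id, block, irrigation, nitrogen, das,
    lai_true).  Trajectories are double-logistic in DAS: amplitude set
    by the nitrogen rate (plus seeded block and plot effects smaller
    than the between-rate gaps), a transient dip late in the vegetative
    phase for the alternate-wetting regimes, and peak timing in the
    reproductive/ripening window.  All values lie in [0.2, 9].
    """
    if len(dates) == 0:
        raise ValueError("at least one observation date is required")
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise ValueError("dates must be strictly increasing")
    treatments = treatments or TreatmentConfig()
    rng = np.random.default_rng(seed)
    das = np.asarray(dates, dtype=float)

    units = treatments.units()
    block_eff = {
        b: rng.uniform(-0.25, 0.25) for b in sorted(units["block"].unique())
    }
    rows = []
    for _, u in units.iterrows():
        peak = _PEAK_BY_NITROGEN[u["nitrogen"]] + block_eff[u["block"]]
        peak += rng.uniform(-0.2, 0.2)  # plot effect, smaller than rate gaps
        base = 1.35 + rng.uniform(-0.15, 0.15)
        t_rise = 50.0 + rng.uniform(-2.0, 2.0)
        t_fall = 88.0 + rng.uniform(-2.0, 2.0)
        lai = _double_logistic(das, base, peak - base, t_rise, 0.16, t_fall, 0.25)
        dip = _DIP_BY_IRRIGATION[u["irrigation"]]
        if dip > 0:
            # water-stress dip centred on the late vegetative phase
            lai = lai * (1.0 - dip * np.exp(-0.5 * ((das - 56.0) / 5.0) ** 2))
        lai = np.clip(lai, 0.2, 9.0)
        for d, v in zip(das, lai):
            rows.append(
                {
                    "plot_id": u["plot_id"],
                    "block": u["block"],
                    "irrigation": u["irrigation"],
                    "nitrogen": u["nitrogen"],
                    "das": d,
                    "lai_true": v,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SyntheticCampaign:
    """Rendered field campaign: truth, band reflectance, noisy LAI."""

    truth: pd.DataFrame  # plot_id, block, irrigation, nitrogen, das, lai_true
    reflectance: np.ndarray  # (n_obs, n_bands) aligned with truth rows
    observed_lai: np.ndarray  # (n_obs,) truth + observation noise
    band_names: tuple[str, ...]
    seed: int = 0

    def __len__(self) -> int:
        return len(self.truth)

    def save(self, directory) -> None:
        import json
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        t = self.truth.copy()
        t["observed_lai"] = self.observed_lai
        t.to_csv(d / "campaign_truth.csv", index=False)
        pd.DataFrame(self.reflectance, columns=list(self.band_names)).to_csv(
            d / "campaign_reflectance.csv", index=False
        )
        (d / "campaign_meta.json").write_text(
            json.dumps({"seed": self.seed, "bands": list(self.band_names)}, indent=2)
        )


def render_campaign(
    truth: pd.DataFrame,
    table: AbsorptionTable | None = None,
    soil_library: SoilLibrary | None = None,
    band_set: BandSet | None = None,
    noise: NoiseModel | None = None,
    obs_noise_sd: float = 0.3,
    geometry: ViewGeometry | None = None,
    sampling: SamplingConfig | None = None,
    skyl: float = 0.1,
    seed: int = 0,
) -> SyntheticCampaign:
    """Render band reflectance and noisy LAI for each truth row.

    Per plot-date, leaf and soil nuisance parameters are drawn from the
    LUT sampling distributions, reflectance is rendered at the true LAI
    with the coupled leaf/canopy model, band noise is applied per the
    noise model, and observed LAI = truth + N(0, obs_noise_sd^2).
    """
    from .leaf import default_absorption_table

    table = table or default_absorption_table()
    band_set = band_set or sentinel2_bands()
    noise = noise if noise is not None else NoiseModel(0, 0, 0, 0)
    rng = np.random.default_rng(seed)
    soil_library = (
        soil_library
        if soil_library is not None
        else generate_soil_library(69, seed=int(rng.integers(2**31)))
    )
    sampling = sampling or default_sampling_config()
    geometry = geometry or ViewGeometry()

    spectra = np.empty((len(truth), len(band_set)))
    for i, (_, row) in enumerate(truth.iterrows()):
        u = rng.random(len(sampling.parameters))
        draw = {
            p.name: float(p.draw(np.array([u[j]]))[0])
            for j, p in enumerate(sampling.parameters)
        }
        leaf = LeafParams(draw["N"], draw["Cab"], draw["Cw"], draw["Cm"])
        lr, lt = leaf_rt(leaf, table)
        soil = soil_library.background(draw["soil"], rng)
        canopy = CanopyParams(
            LAI=float(row["lai_true"]),
            ALA=draw["ALA"],
            hotspot=draw.get("hotspot", 0.01),
            skyl=skyl,
        )
        geom = ViewGeometry(
            geometry.sun_zenith, geometry.view_zenith, draw.get("psi", 0.0)
        )
        toc = sail_reflectance(lr, lt, canopy, soil, geom)
        spectra[i] = resample_to_bands(toc.values, band_set, toc.wavelengths)

    spectra = add_noise(spectra, noise, rng)
    observed = truth["lai_true"].to_numpy() + rng.normal(
        0.0, obs_noise_sd, size=len(truth)
    )
    return SyntheticCampaign(
        truth.reset_index(drop=True),
        spectra,
        observed,
        tuple(band_set.names),
        seed=seed,
    )


def coefficient_fixture() -> AbsorptionTable:
    """Minimal synthetic absorption/refraction table for tests.

    Independent of the package default coefficients: simple Gaussian
    bands with a chlorophyll-like feature near 670 nm and water-like
    features near 1450/1940 nm on a flat refractive index.
    """
    wl = WAVELENGTHS
    nr = np.full_like(wl, 1.45)
    k_cab = 0.06 * np.exp(-0.5 * ((wl - 670.0) / 25.0) ** 2)
    k_cw = 40.0 * np.exp(-0.5 * ((wl - 1450.0) / 40.0) ** 2) + 90.0 * np.exp(
        -0.5 * ((wl - 1940.0) / 50.0) ** 2
    )
    k_cm = 10.0 * np.exp(-0.5 * ((wl - 2100.0) / 80.0) ** 2)
    return AbsorptionTable(wl, nr, k_cab, k_cw, k_cm)
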