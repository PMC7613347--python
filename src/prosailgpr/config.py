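"""YAML/JSON run-configuration: sampling, bands, noise, geometry, soil."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .bands import Band, BandSet, sentinel2_bands
from .canopy import ViewGeometry
from .noise import NoiseModel
from .sampling import ParameterSpec, SamplingConfig, default_sampling_config

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    sampling: SamplingConfig
    bands: BandSet
    noise: NoiseModel
    geometry: ViewGeometry
    skyl: float = 0.1
    soil_samples: int = 69


def _parse_sampling(section: dict | None) -> SamplingConfig:
    if not section:
        return default_sampling_config()
    base = default_sampling_config(
        n_samples=section.get("n_samples", 2000), seed=section.get("seed", 0)
    )
    if "parameters" not in section:
        return base
    params = []
    for entry in section["parameters"]:
        params.append(
            ParameterSpec(
                name=entry["name"],
                lo=float(entry["range"][0]),
                hi=float(entry["range"][1]),
                distribution=entry.get("distribution", "uniform"),
                mean=entry.get("mean"),
                sd=entry.get("sd"),
            )
        )
    return SamplingConfig(
        tuple(params),
        n_samples=section.get("n_samples", 2000),
        seed=section.get("seed", 0),
    )


def _parse_bands(section: list | None) -> BandSet:
    if not section:
        return sentinel2_bands()
    return BandSet(
        tuple(
            Band(
                b["name"],
                float(b["center_um"]),
                float(b["bandwidth_nm"]),
                float(b.get("resolution_m", 20.0)),
            )
            for b in section
        )
    )


def load_config(path) -> RunConfig:
    """Read a config file; omitted sections fall back to study defaults."""
    text = Path(path).read_text()
    raw = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    raw = raw or {}
    noise_sec = raw.get("noise") or {}
    geom_sec = raw.get("geometry") or {}
    soil_sec = raw.get("soil") or {}
    return RunConfig(
        sampling=_parse_sampling(raw.get("sampling")),
        bands=_parse_bands(raw.get("bands")),
        noise=NoiseModel(
            AD=noise_sec.get("AD", 0.01),
            AI=noise_sec.get("AI", 0.01),
            MD=noise_sec.get("MD", 2.0),
            MI=noise_sec.get("MI", 2.0),
            seed=noise_sec.get("seed", 0),
        ),
        geometry=ViewGeometry(
            sun_zenith=geom_sec.get("sun_zenith", 30.0),
            view_zenith=geom_sec.get("view_zenith", 0.0),
            relative_azimuth=geom_sec.get("relative_azimuth", 0.0),
        ),
        skyl=(raw.get("geometry") or {}).get("skyl", 0.1),
        soil_samples=soil_sec.get("n_samples", 69),
    )
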