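"""Random sampling of leaf/canopy parameter vectors for LUT generation.

Each parameter carries a range and a distribution: uniform, a Gaussian
truncated to the range (sampled by inverse-CDF so that draws are
deterministic given the seed), or a fixed constant.  The default
configuration reproduces the simulation conditions of the retrieval
study: LAI and chlorophyll from truncated Gaussians (the only
parameters with stated moments), everything else uniform, 2000 samples.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ParameterSpec", "SamplingConfig", "sample_parameters", "default_sampling_config"]


@dataclass(frozen=True)
class ParameterSpec:
    """One sampled parameter: name, range and distribution."""

    name: str
    lo: float
    hi: float
    distribution: str = "uniform"  # uniform | truncated-gaussian | fixed
    mean: float | None = None
    sd: float | None = None

    def __post_init__(self) -> None:
        if self.distribution == "fixed":
            if self.lo != self.hi:
                raise ValueError(f"{self.name}: fixed parameter needs lo == hi")
            return
        if not self.lo < self.hi:
            raise ValueError(f"{self.name}: require lo < hi")
        if self.distribution == "truncated-gaussian":
            if self.mean is None or self.sd is None or not np.isfinite(
                [self.mean, self.sd]
            ).all():
                raise ValueError(
                    f"{self.name}: truncated-gaussian needs finite mean and sd"
                )
        elif self.distribution != "uniform":
            raise ValueError(f"{self.name}: unknown distribution {self.distribution!r}")

    def draw(self, u: np.ndarray) -> np.ndarray:
        """Map uniform(0,1) variates to this parameter's distribution."""
        if self.distribution == "fixed":
            return np.full_like(u, self.lo)
        if self.distribution == "uniform":
            return self.lo + (self.hi - self.lo) * u
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return stats.truncnorm.ppf(u, a, b, loc=self.mean, scale=self.sd)


@dataclass(frozen=True)
class SamplingConfig:
    parameters: tuple[ParameterSpec, ...]
    n_samples: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.parameters:
            raise ValueError("sampling config has no parameters")
        if self.n_samples < 0:
            raise ValueError("n_samples must be non-negative")

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.parameters]

    def get(self, name: str) -> ParameterSpec:
        for p in self.parameters:
            if p.name == name:
                return p
        raise KeyError(name)

    def with_overrides(self, **kw) -> "SamplingConfig":
        return replace(self, **kw)


def default_sampling_config(n_samples: int = 2000, seed: int = 0) -> SamplingConfig:
    """The standard rice-canopy LUT sampling scheme.

    LAI ~ TG(5.5, 4) on [0.2, 9] and Cab ~ TG(35, 20) on [10, 55];
    leaf structure N, dry matter Cm, water Cw, mean leaf angle ALA, the
    soil brightness/moisture scaling and the sun-sensor relative azimuth
    are uniform on their ranges; the hot-spot parameter is held at a
    small fixed value.
    """
    tg = "truncated-gaussian"
    params = (
        ParameterSpec("N", 1.2, 2.5, "uniform"),
        ParameterSpec("Cab", 10.0, 55.0, tg, mean=35.0, sd=20.0),
        ParameterSpec("Cw", 0.0, 0.05, "uniform"),
        ParameterSpec("Cm", 0.0, 0.03, "uniform"),
        ParameterSpec("LAI", 0.2, 9.0, tg, mean=5.5, sd=4.0),
        ParameterSpec("ALA", 40.0, 80.0, "uniform"),
        ParameterSpec("soil", 0.0, 1.0, "uniform"),
        ParameterSpec("psi", 0.0, 180.0, "uniform"),
        ParameterSpec("hotspot", 0.01, 0.01, "fixed"),
    )
    return SamplingConfig(params, n_samples=n_samples, seed=seed)


def sample_parameters(config: SamplingConfig) -> pd.DataFrame:
    """Draw the configured number of parameter vectors.

    Deterministic given ``config.seed``; every value lies inside its
    configured range.  Returns a DataFrame with one column per parameter
    in configuration order.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    data = {}
    for p in config.parameters:
        u = rng.random(n)
        data[p.name] = p.draw(u)
    return pd.DataFrame(data, columns=config.names)
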