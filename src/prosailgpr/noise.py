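"""Gaussian noise model for simulated band reflectance.

Training a regressor on perfectly clean simulations overfits features
that real imagery cannot deliver, so the LUT spectra are perturbed with
four white-Gaussian components before training:

    R*(b) = R(b) * (1 + md(b) + mi) + ad(b) + ai

md(b) ~ N(0, (MD/100)^2) drawn independently per band (multiplicative,
wavelength-dependent), mi ~ N(0, (MI/100)^2) drawn once per sample
(multiplicative, wavelength-independent), ad(b) ~ N(0, AD^2) per band
and ai ~ N(0, AI^2) per sample (additive counterparts).  Defaults:
AD = AI = 0.01 reflectance units, MD = MI = 2 %.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["NoiseModel", "add_noise"]


@dataclass(frozen=True)
class NoiseModel:
    """Noise magnitudes: AD/AI in reflectance units, MD/MI in percent."""

    AD: float = 0.01
    AI: float = 0.01
    MD: float = 2.0
    MI: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("AD", "AI", "MD", "MI"):
            if getattr(self, name) < 0:
                raise ValueError(f"noise magnitude {name} must be non-negative")

    @property
    def is_zero(self) -> bool:
        return self.AD == self.AI == self.MD == self.MI == 0


def add_noise(
    band_vectors: np.ndarray,
    noise: NoiseModel,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Apply the four-component Gaussian noise model.

    ``band_vectors`` is (n_bands,) or (n_samples, n_bands).  Per-band
    components are drawn independently for every (sample, band) cell;
    per-sample components once per row and shared across its bands.
    Deterministic given the generator (or ``noise.seed`` if none given).
    """
    if rng is None:
        rng = np.random.default_rng(noise.seed)
    R = np.asarray(band_vectors, dtype=float)
    squeeze = R.ndim == 1
    R = np.atleast_2d(R)
    n, B = R.shape

    if noise.is_zero:
        out = R.copy()
    else:
        md = rng.normal(0.0, noise.MD / 100.0, size=(n, B))
        mi = rng.normal(0.0, noise.MI / 100.0, size=(n, 1))
        ad = rng.normal(0.0, noise.AD, size=(n, B))
        ai = rng.normal(0.0, noise.AI, size=(n, 1))
        out = R * (1.0 + md + mi) + ad + ai
    return out[0] if squeeze else out
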