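"""PROSPECT-4 leaf optical properties model.

Directional-hemispherical reflectance and transmittance of a leaf over
400-2500 nm (1 nm grid) as a function of four parameters: a structure
index ``N`` (effective number of elementary plates), chlorophyll a+b
content ``Cab`` (µg/cm²), equivalent water thickness ``Cw`` (cm) and dry
matter content ``Cm`` (g/cm²).

The model stacks N compact "plates" (absorbing slabs bounded by rough
dielectric interfaces).  A single plate's reflectance/transmittance
follows from Fresnel interface transmissivities averaged over the
incidence cone (the Stern/Allen ``tav`` formula) and the isotropic slab
transmissivity expressed through the exponential integral; the extension
to a real-valued number of plates uses the Stokes system of equations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WAVELENGTHS",
    "LeafParams",
    "AbsorptionTable",
    "Spectrum",
    "layer_absorption",
    "elementary_transmissivity",
    "leaf_rt",
    "exp_integral_e1",
    "tav",
    "synthetic_absorption_table",
    "default_absorption_table",
    "load_absorption_table",
]

#: Standard wavelength grid, nm (2101 samples).
WAVELENGTHS = np.arange(400, 2501, dtype=float)

#: Maximum incidence angle (degrees) of the cone illuminating the top
#: leaf surface; the published PROSPECT value for a rough epidermis.
DEFAULT_INCIDENCE_DEG = 40.0

_EULER_GAMMA = 0.5772156649015328606


@dataclass(frozen=True)
class LeafParams:
    """PROSPECT-4 inputs.

    N is dimensionless (>= 1), Cab in µg/cm², Cw in cm, Cm in g/cm².
    """

    N: float
    Cab: float
    Cw: float
    Cm: float

    def __post_init__(self) -> None:
        if self.N < 1:
            raise ValueError(f"leaf structure index N must be >= 1, got {self.N}")
        for name in ("Cab", "Cw", "Cm"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class Spectrum:
    """Wavelengths (nm, strictly increasing) paired with unitless values."""

    wavelengths: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if wl.shape != v.shape:
            raise ValueError("wavelengths and values must have the same shape")
        if wl.size > 1 and not np.all(np.diff(wl) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", v)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"wavelength_nm": self.wavelengths, "value": self.values}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Spectrum":
        df = pd.read_csv(path)
        return cls(df["wavelength_nm"].to_numpy(), df["value"].to_numpy())


@dataclass(frozen=True)
class AbsorptionTable:
    """Per-wavelength leaf optical constants.

    ``refractive_index`` is the real refractive index of leaf material;
    ``k_cab``, ``k_cw``, ``k_cm`` are specific absorption coefficients per
    unit of Cab (cm²/µg), Cw (1/cm) and Cm (cm²/g) respectively.
    """

    wavelengths: np.ndarray
    refractive_index: np.ndarray
    k_cab: np.ndarray
    k_cw: np.ndarray
    k_cm: np.ndarray

    def __post_init__(self) -> None:
        arrs = {}
        n = None
        for name in ("wavelengths", "refractive_index", "k_cab", "k_cw", "k_cm"):
            a = np.asarray(getattr(self, name), dtype=float)
            if n is None:
                n = a.size
            elif a.size != n:
                raise ValueError(
                    f"column {name!r} has length {a.size}, expected {n}"
                )
            arrs[name] = a
        if np.any(arrs["refractive_index"] <= 1):
            raise ValueError("refractive index must exceed 1 everywhere")
        for name in ("k_cab", "k_cw", "k_cm"):
            if np.any(arrs[name] < 0):
                raise ValueError(f"{name} must be non-negative")
        for name, a in arrs.items():
            object.__setattr__(self, name, a)

    def to_file(self, path, delimiter: str = ",") -> None:
        header = "wavelength_nm,refractive_index,k_cab,k_cw,k_cm".replace(
            ",", delimiter
        )
        data = np.column_stack(
            [self.wavelengths, self.refractive_index, self.k_cab, self.k_cw, self.k_cm]
        )
        np.savetxt(path, data, delimiter=delimiter, header=header, comments="")


def load_absorption_table(path) -> AbsorptionTable:
    """Read a whitespace- or comma-delimited coefficient table.

    Columns: wavelength_nm, refractive_index, k_cab, k_cw, k_cm.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols = ["wavelength_nm", "refractive_index", "k_cab", "k_cw", "k_cm"]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"absorption table missing columns {missing}")
    return AbsorptionTable(
        df["wavelength_nm"].to_numpy(),
        df["refractive_index"].to_numpy(),
        df["k_cab"].to_numpy(),
        df["k_cw"].to_numpy(),
        df["k_cm"].to_numpy(),
    )


def _gauss(wl: np.ndarray, center: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / sigma) ** 2)


def synthetic_absorption_table(wavelengths: np.ndarray | None = None) -> AbsorptionTable:
    """Deterministic *synthetic* leaf optical constants.

    This is a stand-in for the published PROSPECT-4 calibration data,
    which is not redistributed with this package.  The table reproduces
    the qualitative structure of real leaf optical constants — a
    refractive index near 1.5 falling gently with wavelength, chlorophyll
    absorption peaking in the blue (~430 nm) and red (~670 nm) and absent
    in the near infrared, liquid-water absorption bands near 970, 1200,
    1450, 1940 and 2400 nm, and broad dry-matter absorption growing into
    the shortwave infrared.  Magnitudes are chosen so that a mid-range
    leaf shows realistic reflectance levels (low red, ~0.45 NIR plateau,
    water-dominated SWIR).  Users with the published calibration can load
    it via :func:`load_absorption_table` instead.
    """
    wl = WAVELENGTHS if wavelengths is None else np.asarray(wavelengths, dtype=float)

    nr = 1.35 + 0.17 * np.exp(-(wl - 400.0) / 800.0)

    # chlorophyll a+b, cm²/µg: blue and red peaks, green gap, red edge cutoff
    k_cab = (
        0.110 * _gauss(wl, 430.0, 35.0)
        + 0.080 * _gauss(wl, 670.0, 28.0)
        + 0.035 * _gauss(wl, 620.0, 40.0)
        + 0.020 * _gauss(wl, 540.0, 60.0)
    )
    k_cab[wl > 780.0] = 0.0

    # liquid water, 1/cm: overtone bands growing toward the SWIR
    k_cw = (
        3.0 * _gauss(wl, 970.0, 35.0)
        + 9.0 * _gauss(wl, 1190.0, 45.0)
        + 55.0 * _gauss(wl, 1450.0, 50.0)
        + 120.0 * _gauss(wl, 1940.0, 60.0)
        + 60.0 * _gauss(wl, 2400.0, 120.0)
        + np.clip((wl - 1300.0) / 1200.0, 0.0, None) * 12.0
    )
    k_cw[wl < 850.0] = 0.0

    # dry matter, cm²/g: weak NIR features, broad SWIR rise
    k_cm = (
        np.clip((wl - 800.0) / 1700.0, 0.0, None) ** 2 * 60.0
        + 14.0 * _gauss(wl, 1720.0, 50.0)
        + 18.0 * _gauss(wl, 2100.0, 60.0)
        + 16.0 * _gauss(wl, 2300.0, 60.0)
    )
    k_cm[wl < 800.0] = 0.0

    return AbsorptionTable(wl, nr, k_cab, k_cw, k_cm)


_DEFAULT_TABLE: AbsorptionTable | None = None


def default_absorption_table() -> AbsorptionTable:
    """The package default coefficient table (synthetic; cached)."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = synthetic_absorption_table()
    return _DEFAULT_TABLE


def layer_absorption(leaf: LeafParams, table: AbsorptionTable) -> np.ndarray:
    """Specific absorption of one elementary plate.

    k(λ) = (Cab·k_cab + Cw·k_cw + Cm·k_cm) / N — the leaf's absorbers
    distributed evenly over its N elementary layers.
    """
    return (
        leaf.Cab * table.k_cab + leaf.Cw * table.k_cw + leaf.Cm * table.k_cm
    ) / leaf.N


def exp_integral_e1(x: np.ndarray | float) -> np.ndarray:
    """Exponential integral E1(x) for x > 0.

    Power series for x <= 1, modified-Lentz continued fraction for x > 1.
    Agrees with quadrature of ∫_x^∞ e^(-t)/t dt to ~1e-14 relative.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise ValueError("E1 requires x >= 0")
    out = np.full(x.shape, np.inf)

    small = (x > 0) & (x <= 1.0)
    if np.any(small):
        xs = x[small]
        term = np.ones_like(xs)
        total = np.zeros_like(xs)
        for n in range(1, 30):
            term = term * (-xs) / n
            contrib = -term / n
            total += contrib
            if np.all(np.abs(contrib) < 1e-17):
                break
        out[small] = -_EULER_GAMMA - np.log(xs) + total

    large = x > 1.0
    if np.any(large):
        xl = x[large]
        # modified-Lentz evaluation of the continued fraction
        # E1(x) = e^{-x} / (x+1 - 1/(x+3 - 4/(x+5 - 9/(...))))
        b = xl + 1.0
        c = np.full_like(xl, 1e300)
        d = 1.0 / b
        h = d.copy()
        for i in range(1, 120):
            a = -i * i * 1.0
            b = b + 2.0
            d = 1.0 / (a * d + b)
            c = b + a / c
            dl = c * d
            h = h * dl
            if np.all(np.abs(dl - 1.0) < 1e-15):
                break
        out[large] = h * np.exp(-xl)

    return out


def elementary_transmissivity(k: np.ndarray | float) -> np.ndarray:
    """Isotropic transmissivity θ(k) of one elementary absorbing plate.

    θ(k) = ∫ exp(-k/cos α)·2 cos α sin α dα over the incidence hemisphere,
    which integrates in closed form to (1-k)e^(-k) + k²E1(k); θ(0)=1 and θ
    decreases monotonically to 0.
    """
    k = np.asarray(k, dtype=float)
    if np.any(k < 0):
        raise ValueError("absorption coefficient must be non-negative")
    out = np.ones_like(k)
    pos = k > 0
    if np.any(pos):
        kp = k[pos]
        with np.errstate(over="ignore", under="ignore"):
            e1 = exp_integral_e1(kp)
            val = (1.0 - kp) * np.exp(-kp) + kp * kp * e1
        out[pos] = np.clip(val, 0.0, 1.0)
    return out


def tav(theta_deg: float, nr: np.ndarray) -> np.ndarray:
    """Average transmissivity of a dielectric interface (Stern/Allen).

    ``theta_deg`` is the half-angle of the incidence cone; ``nr`` the
    refractive index.  Vectorized over ``nr``.
    """
    nr = np.asarray(nr, dtype=float)
    n2 = nr * nr
    npl = n2 + 1.0
    nmi = n2 - 1.0
    a = (nr + 1.0) ** 2 / 2.0
    k = -(nmi**2) / 4.0

    if theta_deg == 0.0:
        return 4.0 * nr / (nr + 1.0) ** 2

    sa2 = np.sin(np.radians(theta_deg)) ** 2
    if theta_deg == 90.0:
        b1 = np.zeros_like(nr)
    else:
        b1 = np.sqrt((sa2 - npl / 2.0) ** 2 + k)
    b2 = sa2 - npl / 2.0
    b = b1 - b2

    ts = (k**2 / (6.0 * b**3) + k / b - b / 2.0) - (
        k**2 / (6.0 * a**3) + k / a - a / 2.0
    )
    tp1 = -2.0 * n2 * (b - a) / npl**2
    tp2 = -2.0 * n2 * npl * np.log(b / a) / nmi**2
    tp3 = n2 * (1.0 / b - 1.0 / a) / 2.0
    tp4 = (
        16.0
        * n2**2
        * (n2**2 + 1.0)
        * np.log((2.0 * npl * b - nmi**2) / (2.0 * npl * a - nmi**2))
        / (npl**3 * nmi**2)
    )
    tp5 = (
        16.0
        * n2**3
        * (1.0 / (2.0 * npl * b - nmi**2) - 1.0 / (2.0 * npl * a - nmi**2))
        / npl**3
    )
    tp = tp1 + tp2 + tp3 + tp4 + tp5
    return (ts + tp) / (2.0 * sa2)


def _stokes_stack(r: np.ndarray, t: np.ndarray, n_layers: float):
    """Reflectance/transmittance of ``n_layers`` identical symmetric plates.

    Stokes' solution of the pile-of-plates system; valid for real-valued
    layer counts >= 0 (0 plates -> perfect transmission).
    """
    r = np.asarray(r, dtype=float)
    t = np.asarray(t, dtype=float)
    if n_layers == 0:
        return np.zeros_like(r), np.ones_like(t)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        d2 = (1.0 + r + t) * (1.0 + r - t) * (1.0 - r + t) * (1.0 - r - t)
        D = np.sqrt(np.clip(d2, 0.0, None))
        rq = r * r
        tq = t * t
        a = (1.0 + rq - tq + D) / (2.0 * r)
        b = (1.0 - rq + tq + D) / (2.0 * t)
        bN = b**n_layers
        bN2 = bN * bN
        a2 = a * a
        denom = a2 * bN2 - 1.0
        Rsub = a * (bN2 - 1.0) / denom
        Tsub = bN * (a2 - 1.0) / denom

    # conservative limit r+t -> 1 (D -> 0): Stokes form is singular
    cons = 1.0 - r - t < 1e-9
    if np.any(cons):
        Tc = t / (t + (1.0 - t) * n_layers)
        Tsub = np.where(cons, Tc, Tsub)
        Rsub = np.where(cons, 1.0 - Tc, Rsub)
    # opaque limit r -> 0: no interlayer scattering
    dark = r < 1e-12
    if np.any(dark):
        Tsub = np.where(dark, t**n_layers, Tsub)
        Rsub = np.where(dark, 0.0, Rsub)
    # opaque limit t -> 0: only the first plate's face is visible
    opaque = t < 1e-30
    if np.any(opaque):
        Tsub = np.where(opaque, 0.0, Tsub)
        Rsub = np.where(opaque, r, Rsub)
    return np.clip(Rsub, 0.0, 1.0), np.clip(Tsub, 0.0, 1.0)


def leaf_rt(
    leaf: LeafParams,
    table: AbsorptionTable | None = None,
    incidence_deg: float = DEFAULT_INCIDENCE_DEG,
) -> tuple[Spectrum, Spectrum]:
    """Leaf directional-hemispherical reflectance and transmittance.

    The top plate is lit through a cone of half-angle ``incidence_deg``;
    interior plates exchange isotropic flux.  Returns (R, T) spectra on
    the table's wavelength grid with R+T <= 1 everywhere.
    """
    if table is None:
        table = default_absorption_table()

    k = layer_absorption(leaf, table)
    theta = elementary_transmissivity(k)
    nr = table.refractive_index

    talf = tav(incidence_deg, nr)
    ralf = 1.0 - talf
    t12 = tav(90.0, nr)
    r12 = 1.0 - t12
    t21 = t12 / (nr * nr)
    r21 = 1.0 - t21

    denom = 1.0 - r21 * r21 * theta * theta
    Ta = talf * theta * t21 / denom
    Ra = ralf + r21 * theta * Ta
    t = t12 * theta * t21 / denom
    r = r12 + r21 * theta * t

    Rsub, Tsub = _stokes_stack(r, t, leaf.N - 1.0)

    denom2 = 1.0 - Rsub * r
    tran = Ta * Tsub / denom2
    refl = Ra + Ta * Rsub * t / denom2

    refl = np.clip(refl, 0.0, 1.0)
    # guard against R+T creeping above 1 by last-digit round-off
    tran = np.clip(tran, 0.0, 1.0 - refl)
    return Spectrum(table.wavelengths, refl), Spectrum(table.wavelengths, tran)
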