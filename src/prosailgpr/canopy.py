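"""4SAIL turbid-medium canopy bidirectional reflectance model.

Couples leaf reflectance/transmittance spectra with canopy structure
(LAI, leaf inclination distribution, hot-spot size), a Lambertian soil
background and the sun-target-sensor geometry into top-of-canopy
bidirectional reflectance.  The canopy is a horizontally homogeneous
turbid medium: the four-stream system (direct solar flux, downward and
upward diffuse flux, flux-equivalent radiance toward the observer) is
solved analytically per wavelength, with the Kuusk hot-spot correction
applied to the single-scattering term.

Leaf inclination is parameterized by its mean angle (ALA, degrees from
horizontal) through the ellipsoidal (Campbell) distribution, discretized
into inclination classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .leaf import Spectrum

__all__ = [
    "CanopyParams",
    "ViewGeometry",
    "SoilSpectrum",
    "lidf_from_ala",
    "mix_soil",
    "sail_reflectance",
    "sail_components",
]

#: Class centre angles (deg) of the classic 13-class SAIL discretization:
#: eight 10-degree classes plus five 2-degree classes near vertical.
SAIL13_CENTRES = np.array(
    [5.0, 15.0, 25.0, 35.0, 45.0, 55.0, 65.0, 75.0, 81.0, 83.0, 85.0, 87.0, 89.0]
)
SAIL13_EDGES = np.array(
    [0.0, 10, 20, 30, 40, 50, 60, 70, 80, 82, 84, 86, 88, 90.0]
)


@dataclass(frozen=True)
class CanopyParams:
    """4SAIL structural inputs.

    LAI in m²/m²; ALA = mean leaf inclination (deg from horizontal);
    hotspot = leaf width / canopy height; skyl = diffuse irradiance
    fraction.
    """

    LAI: float
    ALA: float = 57.3
    hotspot: float = 0.01
    skyl: float = 0.1

    def __post_init__(self) -> None:
        if self.LAI < 0:
            raise ValueError("LAI must be non-negative")
        if not 0 < self.ALA < 90:
            raise ValueError("ALA must lie strictly between 0 and 90 degrees")
        if self.hotspot < 0:
            raise ValueError("hotspot parameter must be non-negative")
        if not 0 <= self.skyl <= 1:
            raise ValueError("skyl must lie in [0, 1]")


@dataclass(frozen=True)
class ViewGeometry:
    """Sun and view zenith angles plus their azimuth difference (deg)."""

    sun_zenith: float = 30.0
    view_zenith: float = 0.0
    relative_azimuth: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.sun_zenith <= 89 or not 0 <= self.view_zenith <= 89:
            raise ValueError("zenith angles must lie in [0, 89] degrees")
        psi = abs(self.relative_azimuth) % 360.0
        if psi > 180.0:
            psi = 360.0 - psi
        object.__setattr__(self, "relative_azimuth", psi)


@dataclass(frozen=True)
class SoilSpectrum:
    """Soil background reflectance with moisture provenance."""

    spectrum: Spectrum
    moisture_label: str = "dry"
    scaling: float = 1.0

    def __post_init__(self) -> None:
        v = self.spectrum.values
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("soil reflectance must lie in [0, 1]")
        if self.moisture_label not in ("wet", "dry", "mixed"):
            raise ValueError("moisture_label must be wet, dry or mixed")
        if not 0 <= self.scaling <= 1:
            raise ValueError("soil scaling must lie in [0, 1]")


def mix_soil(dry: Spectrum, wet: Spectrum, scaling: float) -> SoilSpectrum:
    """Linear wet/dry soil mixture: scaling·dry + (1-scaling)·wet."""
    if not 0 <= scaling <= 1:
        raise ValueError("soil scaling factor must lie in [0, 1]")
    if dry.wavelengths.shape != wet.wavelengths.shape or np.any(
        dry.wavelengths != wet.wavelengths
    ):
        raise ValueError("dry and wet soil spectra must share a wavelength grid")
    mixed = scaling * dry.values + (1.0 - scaling) * wet.values
    return SoilSpectrum(
        Spectrum(dry.wavelengths, mixed), moisture_label="mixed", scaling=scaling
    )


def _ellipsoidal_pdf(theta: np.ndarray, chi: float) -> np.ndarray:
    # unnormalized ellipsoidal leaf-inclination density, theta in radians
    s, c = np.sin(theta), np.cos(theta)
    return chi**3 * s / (c * c + chi * chi * s * s) ** 2


def _ellipsoidal_mean_deg(chi: float, grid: np.ndarray) -> float:
    g = _ellipsoidal_pdf(grid, chi)
    return float(np.degrees(np.trapezoid(grid * g, grid) / np.trapezoid(g, grid)))


_CHI_TABLE: tuple[np.ndarray, np.ndarray] | None = None
_LIDF_CACHE: dict[tuple[float, int], np.ndarray] = {}


def _chi_from_ala(ala: float) -> float:
    """Ellipsoid axis ratio whose continuous mean inclination equals ala."""
    global _CHI_TABLE
    grid = np.linspace(1e-6, np.pi / 2 - 1e-6, 2001)
    if _CHI_TABLE is None:
        logchi = np.linspace(-3.0, 3.0, 601)
        means = np.array([_ellipsoidal_mean_deg(10.0**lc, grid) for lc in logchi])
        # mean angle decreases monotonically with log-chi
        _CHI_TABLE = (means[::-1], logchi[::-1])
    means_inc, logchi_inc = _CHI_TABLE
    return float(10.0 ** np.interp(ala, means_inc, logchi_inc))


def lidf_from_ala(ala: float, n_classes: int = 13) -> np.ndarray:
    """Leaf inclination distribution fractions for a given mean angle.

    Uses the ellipsoidal distribution whose axis ratio is solved
    numerically so that the continuous mean inclination equals ``ala``.
    With the default 13 classes the classic SAIL discretization (eight
    10-degree + five 2-degree classes) is used; otherwise classes are
    uniform in inclination.
    """
    if not 0 < ala < 90:
        raise ValueError("ALA must lie strictly between 0 and 90 degrees")
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")

    key = (round(float(ala), 6), n_classes)
    cached = _LIDF_CACHE.get(key)
    if cached is not None:
        return cached.copy()

    chi = _chi_from_ala(ala)

    if n_classes == 13:
        edges = np.radians(SAIL13_EDGES)
    else:
        edges = np.radians(np.linspace(0.0, 90.0, n_classes + 1))
    fracs = np.empty(n_classes)
    for i in range(n_classes):
        seg = np.linspace(edges[i] + 1e-9, edges[i + 1] - 1e-9, 200)
        fracs[i] = np.trapezoid(_ellipsoidal_pdf(seg, chi), seg)
    fracs = np.clip(fracs, 0.0, None)
    fracs /= fracs.sum()
    if len(_LIDF_CACHE) < 4096:
        _LIDF_CACHE[key] = fracs.copy()
    return fracs


def _class_centres(n_classes: int) -> np.ndarray:
    if n_classes == 13:
        return SAIL13_CENTRES
    edges = np.linspace(0.0, 90.0, n_classes + 1)
    return 0.5 * (edges[:-1] + edges[1:])


def _volscatt(tts: float, tto: float, psi: float, ttl: float):
    """Geometric factors of one leaf-inclination class.

    Returns (chi_s, chi_o, frho, ftau): fractions of leaf area projected
    toward sun and observer, and the bidirectional scattering kernels for
    leaf reflectance and transmittance.  Angles in degrees.
    """
    rd = np.pi / 180.0
    cts, cto = np.cos(rd * tts), np.cos(rd * tto)
    sts, sto = np.sin(rd * tts), np.sin(rd * tto)
    cospsi = np.cos(rd * psi)
    psir = rd * psi
    cttl, sttl = np.cos(rd * ttl), np.sin(rd * ttl)
    cs = cttl * cts
    co = cttl * cto
    ss = sttl * sts
    so = sttl * sto

    cosbts = 5.0
    if abs(ss) > 1e-6:
        cosbts = -cs / ss
    cosbto = 5.0
    if abs(so) > 1e-6:
        cosbto = -co / so

    if abs(cosbts) < 1.0:
        bts = np.arccos(cosbts)
        ds = ss
    else:
        bts = np.pi
        ds = cs
    chi_s = 2.0 / np.pi * ((bts - np.pi * 0.5) * cs + np.sin(bts) * ss)

    if abs(cosbto) < 1.0:
        bto = np.arccos(cosbto)
        do_ = so
    else:
        bto = np.pi if tto < 90.0 else 0.0
        do_ = co
    chi_o = 2.0 / np.pi * ((bto - np.pi * 0.5) * co + np.sin(bto) * so)

    btran1 = abs(bts - bto)
    btran2 = np.pi - abs(bts + bto - np.pi)
    if psir <= btran1:
        bt1, bt2, bt3 = psir, btran1, btran2
    elif psir <= btran2:
        bt1, bt2, bt3 = btran1, psir, btran2
    else:
        bt1, bt2, bt3 = btran1, btran2, psir

    t1 = 2.0 * cs * co + ss * so * cospsi
    t2 = 0.0
    if bt2 > 0.0:
        t2 = np.sin(bt2) * (2.0 * ds * do_ + ss * so * np.cos(bt1) * np.cos(bt3))
    denom = 2.0 * np.pi**2
    frho = max(((np.pi - bt2) * t1 + t2) / denom, 0.0)
    ftau = max((-bt2 * t1 + t2) / denom, 0.0)
    return chi_s, chi_o, frho, ftau


def suits_coefficients(lidf: np.ndarray, geom: ViewGeometry):
    """LIDF-weighted SAIL scattering coefficients (ks, ko, bf, sob, sof)."""
    centres = _class_centres(lidf.size)
    rd = np.pi / 180.0
    cts = np.cos(rd * geom.sun_zenith)
    cto = np.cos(rd * geom.view_zenith)
    ks = ko = bf = sob = sof = 0.0
    for frac, ttl in zip(lidf, centres):
        chi_s, chi_o, frho, ftau = _volscatt(
            geom.sun_zenith, geom.view_zenith, geom.relative_azimuth, ttl
        )
        ks += frac * chi_s / cts
        ko += frac * chi_o / cto
        bf += frac * np.cos(rd * ttl) ** 2
        sob += frac * frho * np.pi / (cts * cto)
        sof += frac * ftau * np.pi / (cts * cto)
    return ks, ko, bf, sob, sof


def _jfunc1(k: float, m: np.ndarray, t: float) -> np.ndarray:
    # J1(k, m, t) = (e^{-mt} - e^{-kt}) / (k - m), stable near k == m
    dl = (k - m) * t
    out = np.empty_like(m)
    near = np.abs(dl) < 1e-3
    far = ~near
    out[far] = (np.exp(-m[far] * t) - np.exp(-k * t)) / (k - m[far])
    out[near] = (
        0.5
        * t
        * (np.exp(-k * t) + np.exp(-m[near] * t))
        * (1.0 - dl[near] * dl[near] / 12.0)
    )
    return out


def _jfunc2(k: float, m: np.ndarray, t: float) -> np.ndarray:
    return (1.0 - np.exp(-(k + m) * t)) / (k + m)


def _hotspot_sumint(
    ks: float, ko: float, lai: float, hotspot: float, tts: float, tto: float, psi: float
):
    """Kuusk hot-spot bidirectional gap integral.

    Returns (tsstoo, sumint): joint sun-view gap probability and the
    integral weighting the single-scattering source.
    """
    rd = np.pi / 180.0
    tants = np.tan(rd * tts)
    tanto = np.tan(rd * tto)
    dso = np.sqrt(tants**2 + tanto**2 - 2.0 * tants * tanto * np.cos(rd * psi))

    tss = np.exp(-ks * lai)
    too = np.exp(-ko * lai)
    if hotspot <= 0.0:
        # no hot-spot correction: independent sun and view gaps
        tsstoo = tss * too
        sumint = (1.0 - np.exp(-(ks + ko) * lai)) / ((ks + ko) * lai)
        return tsstoo, sumint

    alf = 1e36
    if hotspot > 0.0:
        alf = (dso / hotspot) * 2.0 / (ks + ko)
    if alf == 0.0:
        # exact backscatter: full correlation of sun and view paths
        tsstoo = tss
        sumint = (1.0 - tss) / (ks * lai)
        return tsstoo, sumint

    alf = min(alf, 200.0)
    fhot = lai * np.sqrt(ko * ks)
    x1 = y1 = 0.0
    f1 = 1.0
    fint = (1.0 - np.exp(-alf)) * 0.05
    sumint = 0.0
    for istep in range(1, 21):
        if istep < 20:
            x2 = -np.log(1.0 - istep * fint) / alf
        else:
            x2 = 1.0
        y2 = -(ko + ks) * lai * x2 + fhot * (1.0 - np.exp(-alf * x2)) / alf
        f2 = np.exp(y2)
        sumint += (f2 - f1) * (x2 - x1) / (y2 - y1)
        x1, y1, f1 = x2, y2, f2
    tsstoo = f1
    return tsstoo, sumint


def sail_components(
    leaf_r: np.ndarray,
    leaf_t: np.ndarray,
    lai: float,
    lidf: np.ndarray,
    hotspot: float,
    geom: ViewGeometry,
) -> dict[str, np.ndarray]:
    """Four-stream reflectance/transmittance factors of the canopy layer.

    Returns the standard SAIL operator set (vectorized over wavelength):
    rdd/tdd (diffuse-diffuse), rsd/tsd (direct-diffuse), rdo/tdo
    (diffuse-directional), rso (direct-directional), plus the direct
    beam (tss), view-path (too) and joint (tsstoo) gap transmittances.
    """
    rho = np.asarray(leaf_r, dtype=float)
    tau = np.asarray(leaf_t, dtype=float)
    geom = ViewGeometry(geom.sun_zenith, geom.view_zenith, geom.relative_azimuth)
    ks, ko, bf, sob, sof = suits_coefficients(lidf, geom)

    sdb = 0.5 * (ks + bf)
    sdf = 0.5 * (ks - bf)
    dob = 0.5 * (ko + bf)
    dof = 0.5 * (ko - bf)
    ddb = 0.5 * (1.0 + bf)
    ddf = 0.5 * (1.0 - bf)

    sigb = ddb * rho + ddf * tau
    sigf = ddf * rho + ddb * tau
    att = 1.0 - sigf
    # the analytic solution is singular for perfectly conservative
    # scattering (rho + tau = 1, i.e. att == sigb); nudge sigb down by an
    # epsilon there, equivalent to adding ~1e-6 of absorption, keeping the
    # coefficient set {att, sigb, m} internally consistent
    sigb = np.minimum(sigb, att - 1e-6)
    m = np.sqrt((att + sigb) * (att - sigb))
    sb = sdb * rho + sdf * tau
    sf = sdf * rho + sdb * tau
    vb = dob * rho + dof * tau
    vf = dof * rho + dob * tau
    w = sob * rho + sof * tau

    tss = np.exp(-ks * lai)
    too = np.exp(-ko * lai)

    e1 = np.exp(-m * lai)
    e2 = e1 * e1
    rinf = sigb / (att + m)
    rinf2 = rinf * rinf
    re = rinf * e1
    denom = 1.0 - rinf2 * e2

    J1ks = _jfunc1(ks, m, lai)
    J2ks = _jfunc2(ks, m, lai)
    J1ko = _jfunc1(ko, m, lai)
    J2ko = _jfunc2(ko, m, lai)

    Ps = (sf + sb * rinf) * J1ks
    Qs = (sf * rinf + sb) * J2ks
    Pv = (vf + vb * rinf) * J1ko
    Qv = (vf * rinf + vb) * J2ko

    tdd = (1.0 - rinf2) * e1 / denom
    rdd = rinf * (1.0 - e2) / denom
    tsd = (Ps - re * Qs) / denom
    rsd = (Qs - re * Ps) / denom
    tdo = (Pv - re * Qv) / denom
    rdo = (Qv - re * Pv) / denom

    # multiple-scattering contribution to the bidirectional term: exact
    # solution of the two-stream system driven by the attenuated direct
    # beam over a black background, integrated along the view path.
    #   E-(x) = P e^{-ks x} + A e^{-m x} + B e^{+m x}
    #   E+(x) = Q e^{-ks x} + rinf A e^{-m x} + (B/rinf) e^{+m x}
    # with E-(0) = 0 and E+(L) = 0.
    ks_eff = np.where(np.abs(ks - m) < 1e-5, m + 1e-5, ks)
    det_p = m * m - ks_eff * ks_eff
    P = (sf * (att + ks_eff) + sb * sigb) / det_p
    Q = (sb * (att - ks_eff) + sf * sigb) / det_p
    tss_eff = np.exp(-ks_eff * lai)
    eLp = np.exp(m * lai)
    det_h = eLp - rinf2 * e1
    A = (-P * eLp + rinf * Q * tss_eff) / det_h
    Bp = (-Q * tss_eff + P * rinf * e1) / det_h  # Bp = B / rinf

    def _jview(kk):
        # integral of e^{-(ko+kk) x} over [0, lai], stable for ko+kk -> 0
        s = ko + kk
        out = np.where(
            np.abs(s) > 1e-12, -np.expm1(-s * lai) / np.where(s == 0, 1.0, s), lai
        )
        return out

    Jks = _jview(ks_eff)
    Jm = _jview(m)
    Jmn = _jview(-m)
    rsod = vb * (P * Jks + A * Jm + rinf * Bp * Jmn) + vf * (
        Q * Jks + rinf * A * Jm + Bp * Jmn
    )

    tsstoo, sumint = _hotspot_sumint(
        ks, ko, lai, hotspot, geom.sun_zenith, geom.view_zenith, geom.relative_azimuth
    )
    rsos = w * lai * sumint
    rso = rsos + rsod

    return {
        "rdd": rdd,
        "tdd": tdd,
        "rsd": rsd,
        "tsd": tsd,
        "rdo": rdo,
        "tdo": tdo,
        "rso": rso,
        "tss": np.full_like(rho, tss),
        "too": np.full_like(rho, too),
        "tsstoo": np.full_like(rho, tsstoo),
    }


def sail_reflectance(
    leaf_r: Spectrum,
    leaf_t: Spectrum,
    canopy: CanopyParams,
    soil: SoilSpectrum,
    geom: ViewGeometry | None = None,
) -> Spectrum:
    """Top-of-canopy bidirectional reflectance factor.

    Combines the canopy-layer four-stream operators with the Lambertian
    soil boundary and mixes the direct/diffuse illumination streams with
    the canopy's ``skyl`` fraction.  Reduces to the soil spectrum at
    LAI = 0.
    """
    if geom is None:
        geom = ViewGeometry()
    wl = leaf_r.wavelengths
    for other in (leaf_t, soil.spectrum):
        if other.wavelengths.shape != wl.shape or np.any(other.wavelengths != wl):
            raise ValueError("leaf and soil spectra must share a wavelength grid")
    if canopy.LAI < 0:
        raise ValueError("LAI must be non-negative")

    rsoil = soil.spectrum.values
    if canopy.LAI == 0:
        return Spectrum(wl, rsoil.copy())

    lidf = lidf_from_ala(canopy.ALA)
    c = sail_components(
        leaf_r.values, leaf_t.values, canopy.LAI, lidf, canopy.hotspot, geom
    )
    rdd, tdd = c["rdd"], c["tdd"]
    rsd, tsd = c["rsd"], c["tsd"]
    rdo, tdo = c["rdo"], c["tdo"]
    rso = c["rso"]
    tss, too, tsstoo = c["tss"], c["too"], c["tsstoo"]

    dn = 1.0 - rsoil * rdd
    # observer-direction reflectance factors for direct and diffuse incidence
    rdot = rdo + tdd * rsoil * (tdo + too) / dn
    rsodt = rso + ((tss + tsd) * tdo + (tsd + tss * rsoil * rdd) * too) * rsoil / dn
    rsost = tsstoo * rsoil
    rsot = rsodt + rsost

    out = (1.0 - canopy.skyl) * rsot + canopy.skyl * rdot
    return Spectrum(wl, np.clip(out, 0.0, 1.0))
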