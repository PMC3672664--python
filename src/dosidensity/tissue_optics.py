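"""Forward models of near-infrared light transport in breast tissue.

This module maps tissue composition (hemoglobin, water, lipid) to optical
measurements:

* :func:`mua_from_composition` — Beer–Lambert superposition of chromophore
  extinction spectra, giving the tissue absorption coefficient ``mua(λ)``.
* :func:`musp_power_law` — the standard Mie-type spectral model of reduced
  scattering, ``musp(λ) = A (λ/λ0)^(-b)``.
* :func:`fd_reflectance` — frequency-domain photon-density-wave reflectance
  (amplitude and phase) of a semi-infinite homogeneous medium in the diffusion
  approximation with an extrapolated boundary.
* :func:`steady_state_reflectance` — the zero-frequency (continuous-wave)
  limit, used for broadband reflectance up to an unknown positive gain.

Units follow tissue-optics convention: wavelengths in nm, coefficients in
mm⁻¹, hemoglobin concentrations in µM, water and lipid as percent of the
pure substance's absorption (volume-fraction convention), source–detector
separations in mm, modulation frequencies in MHz, phases in radians.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

import numpy as np

__all__ = [
    "SPEED_OF_LIGHT_MM_S",
    "TissueComposition",
    "ExtinctionTable",
    "OpticalProperties",
    "ScatterPowerFit",
    "FDGeometry",
    "FDMeasurement",
    "BroadbandReflectance",
    "DiffusionRegimeWarning",
    "mua_from_composition",
    "musp_power_law",
    "complex_reflectance",
    "fd_reflectance",
    "steady_state_reflectance",
]

#: vacuum speed of light in mm/s
SPEED_OF_LIGHT_MM_S = 2.99792458e11

_DEFAULT_LASERS = (660.0, 680.0, 780.0, 810.0, 830.0, 850.0)


class DiffusionRegimeWarning(UserWarning):
    """Raised when musp < 10 * mua, where the diffusion approximation degrades."""


@dataclass(frozen=True)
class TissueComposition:
    """Chromophore content of breast tissue at a point or subject average.

    Attributes
    ----------
    ct_hhb : float
        Deoxyhemoglobin concentration, µM.
    ct_o2hb : float
        Oxyhemoglobin concentration, µM.
    water, lipid : float
        Percent of pure-substance absorption (0–100); a tissue fraction
        ``f`` contributes ``f/100`` of the pure chromophore's absorption.
    """

    ct_hhb: float
    ct_o2hb: float
    water: float
    lipid: float

    def __post_init__(self) -> None:
        for name in ("ct_hhb", "ct_o2hb", "water", "lipid"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_array(self) -> np.ndarray:
        """Return ``[ct_hhb, ct_o2hb, water, lipid]`` as a float array."""
        return np.array([self.ct_hhb, self.ct_o2hb, self.water, self.lipid])

    @classmethod
    def from_array(cls, values) -> "TissueComposition":
        a = np.asarray(values, dtype=float)
        return cls(ct_hhb=a[0], ct_o2hb=a[1], water=a[2], lipid=a[3])


@dataclass(frozen=True)
class ExtinctionTable:
    """Chromophore basis spectra on a common wavelength grid.

    ``eps_hhb`` and ``eps_o2hb`` are molar extinction in mm⁻¹·µM⁻¹ (natural,
    i.e. multiplying a µM concentration gives mm⁻¹ absorption directly);
    ``mua_water`` and ``mua_lipid`` are the absorption of the pure substance
    in mm⁻¹, so a tissue fraction of f % contributes f/100 of them.

    The bundled default table (``data/extinction_synthetic.csv``) is a
    synthetic literature-style compilation on a 1-nm grid from 650 to
    1000 nm: physically plausible (hemoglobin isosbestic point near 800 nm,
    water peak near 975 nm, lipid peak near 930 nm) and internally
    consistent with every forward/inverse operation in this package, but not
    a verbatim copy of any published tabulation.  User-supplied tables in
    the same CSV format are accepted everywhere.
    """

    wavelengths: np.ndarray
    eps_hhb: np.ndarray
    eps_o2hb: np.ndarray
    mua_water: np.ndarray
    mua_lipid: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        if wl.ndim != 1 or wl.size < 2 or not np.all(np.diff(wl) > 0):
            raise ValueError("wavelength grid must be 1-D and strictly increasing")
        if wl[0] > 650 or wl[-1] < 1000:
            raise ValueError("extinction table must cover 650-1000 nm")
        for name in ("eps_hhb", "eps_o2hb", "mua_water", "mua_lipid"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != wl.shape:
                raise ValueError(f"{name} shape does not match wavelength grid")
            if np.any(v < 0):
                raise ValueError(f"{name} must be non-negative")
            object.__setattr__(self, name, v)
        object.__setattr__(self, "wavelengths", wl)

    def _check_range(self, wavelengths: np.ndarray) -> None:
        lo, hi = self.wavelengths[0], self.wavelengths[-1]
        if np.any(wavelengths < lo) or np.any(wavelengths > hi):
            raise ValueError(
                f"requested wavelength outside table range [{lo}, {hi}] nm"
            )

    def basis(self, wavelengths) -> np.ndarray:
        """Interpolated (n, 4) design matrix at the given wavelengths.

        Columns are ordered (eps_hhb, eps_o2hb, mua_water/100, mua_lipid/100)
        so that ``basis @ comp.as_array()`` is the Beer–Lambert absorption.
        Interpolation is linear and restricted to the table's range.
        """
        wl = np.atleast_1d(np.asarray(wavelengths, dtype=float))
        self._check_range(wl)
        cols = [
            np.interp(wl, self.wavelengths, self.eps_hhb),
            np.interp(wl, self.wavelengths, self.eps_o2hb),
            np.interp(wl, self.wavelengths, self.mua_water) / 100.0,
            np.interp(wl, self.wavelengths, self.mua_lipid) / 100.0,
        ]
        return np.stack(cols, axis=1)

    @classmethod
    def from_csv(cls, path) -> "ExtinctionTable":
        """Load a table from CSV with columns
        wavelength_nm, eps_hhb, eps_o2hb, mua_water, mua_lipid."""
        data = np.genfromtxt(path, delimiter=",", names=True)
        return cls(
            wavelengths=data["wavelength_nm"],
            eps_hhb=data["eps_hhb"],
            eps_o2hb=data["eps_o2hb"],
            mua_water=data["mua_water"],
            mua_lipid=data["mua_lipid"],
        )

    @classmethod
    def default(cls) -> "ExtinctionTable":
        """The bundled synthetic compilation (cached)."""
        return _load_default_table()


@lru_cache(maxsize=1)
def _load_default_table() -> ExtinctionTable:
    ref = resources.files("dosidensity.data") / "extinction_synthetic.csv"
    with resources.as_file(ref) as path:
        return ExtinctionTable.from_csv(path)


@dataclass(frozen=True)
class OpticalProperties:
    """Absorption and reduced-scattering spectra on a wavelength grid."""

    wavelengths: np.ndarray
    mua: np.ndarray
    musp: np.ndarray

    def __post_init__(self) -> None:
        wl = np.atleast_1d(np.asarray(self.wavelengths, dtype=float))
        mua = np.atleast_1d(np.asarray(self.mua, dtype=float))
        musp = np.atleast_1d(np.asarray(self.musp, dtype=float))
        if not (wl.shape == mua.shape == musp.shape):
            raise ValueError("wavelengths, mua, musp must share a shape")
        if np.any(mua <= 0) or np.any(musp <= 0):
            raise ValueError("optical properties must be strictly positive")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "mua", mua)
        object.__setattr__(self, "musp", musp)

    @property
    def diffusion_valid(self) -> np.ndarray:
        """Boolean mask where musp >= 10 * mua (diffusion regime)."""
        return self.musp >= 10.0 * self.mua


@dataclass(frozen=True)
class ScatterPowerFit:
    """Power-law description of reduced scattering.

    ``musp(λ) = amplitude * (λ / lambda0) ** (-power)`` with the scattering
    amplitude given at the reference wavelength ``lambda0`` (650 nm by
    default, the short edge of the broadband window).
    """

    amplitude: float
    power: float
    lambda0: float = 650.0

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise ValueError("scattering amplitude must be positive")
        if not np.isfinite(self.power):
            raise ValueError("scattering power must be finite")

    def __call__(self, wavelengths) -> np.ndarray:
        return musp_power_law(self, wavelengths)


@dataclass(frozen=True)
class FDGeometry:
    """Frequency-domain measurement geometry.

    ``sd_separation`` is the source–detector distance on the hand-held probe
    (mm); ``modulation_frequencies`` is the sweep in MHz (default 20 points
    across 50–500 MHz); ``n_tissue`` the tissue refractive index used for
    the boundary condition; ``laser_wavelengths`` the diode wavelengths.
    """

    sd_separation: float = 22.0
    modulation_frequencies: tuple = tuple(np.linspace(50.0, 500.0, 20))
    n_tissue: float = 1.4
    laser_wavelengths: tuple = _DEFAULT_LASERS

    def __post_init__(self) -> None:
        if not self.sd_separation > 0:
            raise ValueError("source-detector separation must be positive")
        freqs = tuple(float(f) for f in self.modulation_frequencies)
        if len(freqs) == 0 or any(f <= 0 or f > 1000 for f in freqs):
            raise ValueError("modulation frequencies must lie in (0, 1000] MHz")
        object.__setattr__(self, "modulation_frequencies", freqs)
        object.__setattr__(
            self, "laser_wavelengths", tuple(float(w) for w in self.laser_wavelengths)
        )


@dataclass
class FDMeasurement:
    """Relative amplitude and phase per (wavelength, frequency).

    ``amplitude`` and ``phase`` are 2-D arrays of shape
    ``(len(wavelengths), len(frequencies))``.  Amplitudes carry an arbitrary
    per-wavelength gain; phases are in radians in (−π, π].
    """

    geometry: FDGeometry
    wavelengths: np.ndarray
    frequencies: np.ndarray
    amplitude: np.ndarray
    phase: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.atleast_1d(np.asarray(self.wavelengths, float))
        self.frequencies = np.atleast_1d(np.asarray(self.frequencies, float))
        self.amplitude = np.asarray(self.amplitude, float)
        self.phase = np.asarray(self.phase, float)
        shape = (self.wavelengths.size, self.frequencies.size)
        if self.amplitude.shape != shape or self.phase.shape != shape:
            raise ValueError("amplitude/phase must be (n_wavelengths, n_frequencies)")
        if np.any(self.amplitude <= 0):
            raise ValueError("amplitudes must be positive")

    def at_wavelength(self, wavelength: float):
        """Return (frequencies, amplitude, phase) rows for one laser line."""
        idx = np.flatnonzero(np.isclose(self.wavelengths, wavelength))
        if idx.size == 0:
            raise ValueError(f"wavelength {wavelength} nm not in measurement")
        i = int(idx[0])
        return self.frequencies, self.amplitude[i], self.phase[i]


@dataclass
class BroadbandReflectance:
    """Relative CW reflectance spectrum with an unidentifiable global gain."""

    wavelengths: np.ndarray
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        self.wavelengths = np.atleast_1d(np.asarray(self.wavelengths, float))
        self.reflectance = np.atleast_1d(np.asarray(self.reflectance, float))
        if self.wavelengths.shape != self.reflectance.shape:
            raise ValueError("wavelength and reflectance grids differ")
        if np.any(self.reflectance <= 0):
            raise ValueError("reflectance must be positive")


def mua_from_composition(
    comp: TissueComposition, table: ExtinctionTable, wavelengths
) -> np.ndarray:
    """Beer–Lambert absorption spectrum of a tissue composition (mm⁻¹).

    μa(λ) = ε_HHb(λ)·ctHHb + ε_O2Hb(λ)·ctO2Hb
            + (water/100)·μa_water(λ) + (lipid/100)·μa_lipid(λ)

    Exactly linear in the composition.  Raises ``ValueError`` for
    wavelengths outside the table's range.
    """
    return table.basis(wavelengths) @ comp.as_array()


def musp_power_law(fit: ScatterPowerFit, wavelengths) -> np.ndarray:
    """Evaluate musp(λ) = A (λ/λ0)^(-b) on the given wavelengths (mm⁻¹)."""
    wl = np.atleast_1d(np.asarray(wavelengths, dtype=float))
    return fit.amplitude * (wl / fit.lambda0) ** (-fit.power)


def _effective_reflection_coefficient(n: float) -> float:
    # Groenhuis polynomial approximation of the internal reflection parameter
    return -1.440 / n**2 + 0.710 / n + 0.668 + 0.0636 * n


def complex_reflectance(mua, musp, rho_mm, frequency_mhz, n_tissue: float = 1.4):
    """Complex photon-density-wave reflectance of a semi-infinite medium.

    Diffusion approximation with an extrapolated boundary: an isotropic
    point source is placed one transport mean free path below the surface
    and its negative image above the extrapolated boundary
    ``z_b = 2 A D`` with ``A = (1 + R_eff)/(1 - R_eff)``.  The detected
    quantity is modeled as the complex fluence difference of the two
    sources at lateral distance ``rho``:

        R ∝ exp(-k r1)/r1 − exp(-k r2)/r2,
        k = sqrt((μa + iω/c_n) / D),  D = 1/(3 (μa + μs')).

    Broadcasts over array inputs; frequency 0 gives the CW limit.
    """
    mua = np.asarray(mua, dtype=float)
    musp = np.asarray(musp, dtype=float)
    if np.any(mua <= 0) or np.any(musp <= 0):
        raise ValueError("mua and musp must be strictly positive")
    if np.any(musp < 10.0 * mua):
        warnings.warn(
            "musp < 10*mua: diffusion approximation may be inaccurate",
            DiffusionRegimeWarning,
            stacklevel=2,
        )
    omega = 2.0 * np.pi * np.asarray(frequency_mhz, dtype=float) * 1e6
    c_n = SPEED_OF_LIGHT_MM_S / n_tissue
    mut = mua + musp
    diff = 1.0 / (3.0 * mut)
    k = np.sqrt((mua + 1j * omega / c_n) / diff)
    z0 = 1.0 / mut
    reff = _effective_reflection_coefficient(n_tissue)
    zb = 2.0 * diff * (1.0 + reff) / (1.0 - reff)
    r1 = np.sqrt(rho_mm**2 + z0**2)
    r2 = np.sqrt(rho_mm**2 + (z0 + 2.0 * zb) ** 2)
    return (np.exp(-k * r1) / r1 - np.exp(-k * r2) / r2) / (4.0 * np.pi * diff)


def fd_reflectance(mua, musp, geometry: FDGeometry, frequency_mhz):
    """Frequency-domain amplitude (relative) and phase lag (radians).

    Phase is reported as a positive lag that vanishes in the DC limit and
    grows with modulation frequency; amplitude decreases with both
    source–detector separation and absorption.
    """
    r = complex_reflectance(
        mua, musp, geometry.sd_separation, frequency_mhz, geometry.n_tissue
    )
    amplitude = np.abs(r)
    phase = np.mod(-np.angle(r) + np.pi, 2.0 * np.pi) - np.pi
    # map the wrap point so phase lies in (-pi, pi]
    phase = np.where(phase == -np.pi, np.pi, phase)
    return amplitude, phase


def steady_state_reflectance(
    props: OpticalProperties, geometry: FDGeometry
) -> BroadbandReflectance:
    """Relative CW diffuse reflectance spectrum (arbitrary positive gain).

    Deterministic given the inputs; every downstream consumer treats the
    result as known only up to a global positive scale factor.
    """
    r = complex_reflectance(
        props.mua, props.musp, geometry.sd_separation, 0.0, geometry.n_tissue
    )
    return BroadbandReflectance(props.wavelengths, np.real(r))
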