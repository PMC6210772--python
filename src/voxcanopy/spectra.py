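"""Spectral data carrier and synthetic material/illumination templates.

The material spectra shipped here are *synthetic* analytic templates that
stand in for field-measured leaf, bark and soil spectra: smooth curves with
the qualitative features a spectroradiometer records on a broad-leaved
canopy (green peak, red edge, NIR plateau, liquid-water absorption near
1450/1940 nm). They are not a leaf optical-properties model; use measured
CSV spectra via :meth:`Spectrum.from_csv` when available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "generate_material_spectra",
    "leaf_optics",
    "default_wavelengths",
    "MATERIAL_KINDS",
]

#: wavelength grid used by all templates: 350-2500 nm at 10 nm (216 samples)
WL_MIN, WL_MAX, WL_STEP = 350.0, 2500.0, 10.0

MATERIAL_KINDS = (
    "leaf",
    "leaf_reflectance",
    "leaf_transmittance",
    "trunk",
    "soil",
    "sun_direct",
    "sky_diffuse",
)


def default_wavelengths() -> np.ndarray:
    """Template wavelength grid in nm: 350-2500 at 10 nm, inclusive."""
    n = int(round((WL_MAX - WL_MIN) / WL_STEP)) + 1
    return WL_MIN + WL_STEP * np.arange(n)


@dataclass
class Spectrum:
    """A sampled spectral quantity on a strictly increasing wavelength grid.

    Parameters
    ----------
    wavelengths:
        Band centers in nm, strictly increasing.
    values:
        One value per band.  Dimensionless for reflectance/transmittance,
        W m^-2 nm^-1 for irradiance, W m^-2 sr^-1 nm^-1 for radiance.
    kind:
        Free-form tag ("leaf_reflectance", "sun_direct", ...).
    """

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str = ""

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.ndim != 1 or self.wavelengths.shape != self.values.shape:
            raise ValueError("wavelengths and values must be 1-D and equal length")
        if self.wavelengths.size >= 2 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return self.wavelengths.size

    def value_at(self, lam: float) -> float:
        """Value at the band center nearest to ``lam`` (ties toward lower λ)."""
        return self.values[self.band_index(lam)]

    def band_index(self, lam: float) -> int:
        wl = self.wavelengths
        if lam < wl[0] or lam > wl[-1]:
            raise ValueError(
                f"wavelength {lam} nm outside spectrum range "
                f"[{wl[0]}, {wl[-1]}] nm"
            )
        d = np.abs(wl - lam)
        # ties toward the lower wavelength: argmin returns the first minimum
        return int(np.argmin(d))

    def resample(self, wavelengths: np.ndarray) -> "Spectrum":
        """Linear interpolation onto a new grid (must lie inside the range)."""
        wavelengths = np.asarray(wavelengths, dtype=float)
        if wavelengths.min() < self.wavelengths[0] or wavelengths.max() > self.wavelengths[-1]:
            raise ValueError("target grid extends outside the spectrum range")
        vals = np.interp(wavelengths, self.wavelengths, self.values)
        return Spectrum(wavelengths, vals, kind=self.kind)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"wavelength_nm": self.wavelengths, "value": self.values}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, kind: str = "") -> "Spectrum":
        df = pd.read_csv(path)
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy(), kind=kind)


def _gauss(wl: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - center) / width) ** 2)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _leaf_reflectance(wl: np.ndarray) -> np.ndarray:
    # visible: chlorophyll absorption with a green bump at 550 nm
    vis = 0.04 + 0.065 * _gauss(wl, 550.0, 45.0)
    # red edge into the NIR plateau, damped by liquid-water absorption
    edge = _sigmoid((wl - 715.0) / 10.0)
    absorb = (
        0.06 * _gauss(wl, 970.0, 40.0)
        + 0.10 * _gauss(wl, 1200.0, 50.0)
        + 0.65 * _gauss(wl, 1450.0, 60.0)
        + 1.50 * _gauss(wl, 1940.0, 90.0)
        + 0.70 * _gauss(wl, 2500.0, 200.0)
        + 0.35 * _sigmoid((wl - 1350.0) / 100.0)
    )
    return vis + 0.42 * edge * np.exp(-absorb)


def _leaf_transmittance(wl: np.ndarray, refl: np.ndarray) -> np.ndarray:
    vis = 0.012 + 0.055 * _gauss(wl, 550.0, 45.0)
    edge = _sigmoid((wl - 720.0) / 11.0)
    absorb = (
        0.07 * _gauss(wl, 970.0, 40.0)
        + 0.12 * _gauss(wl, 1200.0, 50.0)
        + 0.75 * _gauss(wl, 1450.0, 60.0)
        + 1.70 * _gauss(wl, 1940.0, 90.0)
        + 0.80 * _gauss(wl, 2500.0, 200.0)
        + 0.40 * _sigmoid((wl - 1350.0) / 100.0)
    )
    trans = vis + 0.43 * edge * np.exp(-absorb)
    # single-scattering albedo of a real leaf never reaches 1
    return np.minimum(trans, 0.97 - refl)


def _trunk_reflectance(wl: np.ndarray) -> np.ndarray:
    base = 0.06 + 0.26 * _sigmoid((wl - 700.0) / 160.0)
    dips = 0.25 * _gauss(wl, 1450.0, 60.0) + 0.55 * _gauss(wl, 1940.0, 90.0)
    return base * np.exp(-dips)


def _soil_reflectance(wl: np.ndarray) -> np.ndarray:
    # brightening from the visible into the SWIR, gentle water features
    # beyond 1350 nm; monotone non-decreasing over 400-1300 nm
    base = 0.045 + 0.27 * (1.0 - np.exp(-(wl - 350.0) / 950.0))
    dips = _sigmoid((wl - 1370.0) / 15.0) * (
        0.10 * _gauss(wl, 1450.0, 50.0) + 0.25 * _gauss(wl, 1940.0, 80.0)
    )
    return base * np.exp(-dips)


_H = 6.62607015e-34
_C = 2.99792458e8
_KB = 1.380649e-23


def _planck(wl_nm: np.ndarray, temp_k: float) -> np.ndarray:
    lam = wl_nm * 1e-9
    x = _H * _C / (lam * _KB * temp_k)
    return 1.0 / (lam**5 * (np.exp(x) - 1.0))


def _sun_direct(wl: np.ndarray) -> np.ndarray:
    # smooth 5800 K continuum, scaled to ~1.5 W m^-2 nm^-1 at 500 nm
    e = _planck(wl, 5800.0)
    return 1.5 * e / _planck(np.array([500.0]), 5800.0)[0]


def _sky_diffuse(wl: np.ndarray) -> np.ndarray:
    # Rayleigh-weighted continuum; isotropic radiance such that the diffuse
    # horizontal irradiance pi*L is ~15% of the direct beam at 500 nm
    e = _planck(wl, 5800.0) * (500.0 / wl) ** 4
    lam500 = _planck(np.array([500.0]), 5800.0)[0]
    return 0.15 * 1.5 / np.pi * e / lam500


def generate_material_spectra(kind: str) -> Spectrum:
    """Return the synthetic template spectrum for ``kind``.

    Recognized kinds: ``leaf`` (alias ``leaf_reflectance``),
    ``leaf_transmittance``, ``trunk``, ``soil``, ``sun_direct``,
    ``sky_diffuse``.  Reflectance/transmittance values are dimensionless and
    satisfy leaf ρ(λ)+τ(λ) ≤ 1 at every band.
    """
    wl = default_wavelengths()
    if kind in ("leaf", "leaf_reflectance"):
        return Spectrum(wl, _leaf_reflectance(wl), kind="leaf_reflectance")
    if kind == "leaf_transmittance":
        refl = _leaf_reflectance(wl)
        return Spectrum(wl, _leaf_transmittance(wl, refl), kind="leaf_transmittance")
    if kind == "trunk":
        return Spectrum(wl, _trunk_reflectance(wl), kind="trunk_reflectance")
    if kind == "soil":
        return Spectrum(wl, _soil_reflectance(wl), kind="soil_reflectance")
    if kind == "sun_direct":
        return Spectrum(wl, _sun_direct(wl), kind="sun_direct")
    if kind == "sky_diffuse":
        return Spectrum(wl, _sky_diffuse(wl), kind="sky_diffuse")
    raise ValueError(f"unknown material kind: {kind!r}; expected one of {MATERIAL_KINDS}")


def leaf_optics() -> tuple[Spectrum, Spectrum]:
    """Convenience: (reflectance, transmittance) leaf template pair."""
    return (
        generate_material_spectra("leaf_reflectance"),
        generate_material_spectra("leaf_transmittance"),
    )
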