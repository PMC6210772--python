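"""Vegetation indices from reflectance spectra and configuration reports.

Six indices are computed: NDVI, the Zarco-Tejada & Miller red-edge ratio
(ZM), the Carter & Miller ratio (CM), the renormalized difference index
(RDVI), the triangular vegetation index (TVI) and the normalized
difference infrared index (NDII).  Band requests resolve to the nearest
band center, ties toward the lower wavelength, and the matching is
recorded.

The TVI is offered in two variants: the ``printed`` default evaluates
``0.5·(120·(R750 − R550) − 200·(R670 + R550))`` exactly as configured,
while ``canonical`` uses the Broge–Leblanc form with ``(R670 − R550)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import Spectrum

__all__ = ["band_value", "compute_indices", "percent_difference", "VIReport",
           "INDEX_NAMES"]

INDEX_NAMES = ("NDVI", "ZM", "CM", "RDVI", "TVI", "NDII")

#: wavelengths (nm) each index reads
INDEX_BANDS = {
    "NDVI": (800, 670),
    "ZM": (750, 710),
    "CM": (695, 760),
    "RDVI": (800, 670),
    "TVI": (750, 550, 670),
    "NDII": (850, 1650),
}


def band_value(spectrum: Spectrum, wavelength_nm: float) -> tuple[float, float]:
    """(reflectance, matched band center) at the nearest band.

    Ties between two equally distant band centers resolve to the lower
    wavelength.  Raises when the request falls outside the spectrum range.
    """
    i = spectrum.band_index(wavelength_nm)
    return float(spectrum.values[i]), float(spectrum.wavelengths[i])


def _safe_ratio(num: float, den: float, flags: list, name: str) -> float:
    if den == 0.0:
        flags.append(name)
        return math.nan
    return num / den


def compute_indices(
    spectrum: Spectrum,
    tvi_variant: str = "printed",
) -> tuple[dict[str, float], dict[float, float], list[str]]:
    """Evaluate the six indices on one spectrum.

    Returns ``(values, band_matching, undefined)`` where ``band_matching``
    maps requested → used wavelength and ``undefined`` lists indices whose
    denominator vanished (their value is NaN, never silently 0).
    """
    if tvi_variant not in ("printed", "canonical"):
        raise ValueError("tvi_variant must be 'printed' or 'canonical'")
    matching: dict[float, float] = {}

    def r(lam: float) -> float:
        val, used = band_value(spectrum, lam)
        matching[lam] = used
        return val

    r550, r670, r695, r710 = r(550), r(670), r(695), r(710)
    r750, r760, r800, r850, r1650 = r(750), r(760), r(800), r(850), r(1650)
    flags: list[str] = []
    values = {
        "NDVI": _safe_ratio(r800 - r670, r800 + r670, flags, "NDVI"),
        "ZM": _safe_ratio(r750, r710, flags, "ZM"),
        "CM": _safe_ratio(r695, r760, flags, "CM"),
    }
    s = r800 + r670
    if s <= 0:
        flags.append("RDVI")
        values["RDVI"] = math.nan
    else:
        values["RDVI"] = (r800 - r670) / math.sqrt(s)
    if tvi_variant == "printed":
        values["TVI"] = 0.5 * (120.0 * (r750 - r550) - 200.0 * (r670 + r550))
    else:
        values["TVI"] = 0.5 * (120.0 * (r750 - r550) - 200.0 * (r670 - r550))
    values["NDII"] = _safe_ratio(r850 - r1650, r850 + r1650, flags, "NDII")
    return values, matching, flags


def percent_difference(
    values: dict[str, float],
    reference: dict[str, float],
) -> tuple[dict[str, float], dict[str, float], list[str]]:
    """Per-index percent difference vs a reference configuration.

    Returns ``(magnitude %, signed %, undefined)``; the magnitude is
    ``100·|VI − VI_ref| / |VI_ref|``, flagged undefined when the reference
    is zero.
    """
    mag: dict[str, float] = {}
    signed: dict[str, float] = {}
    flags: list[str] = []
    for name, ref in reference.items():
        v = values[name]
        if ref == 0.0 or math.isnan(ref):
            flags.append(name)
            mag[name] = math.nan
            signed[name] = math.nan
        else:
            signed[name] = 100.0 * (v - ref) / abs(ref)
            mag[name] = abs(signed[name])
    return mag, signed, flags


@dataclass
class VIReport:
    """Per-configuration index values and percent differences vs a reference."""

    reference: str
    values: dict[str, dict[str, float]]  # config -> index -> value
    pct_diff: dict[str, dict[str, float]]  # magnitudes; reference row is 0
    signed_diff: dict[str, dict[str, float]]
    band_matching: dict[float, float]
    undefined: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def from_spectra(
        cls,
        spectra: dict[str, Spectrum],
        reference: str = "LR",
        tvi_variant: str = "printed",
    ) -> "VIReport":
        if reference not in spectra:
            raise ValueError(f"reference configuration {reference!r} missing")
        values: dict[str, dict[str, float]] = {}
        undefined: dict[str, list[str]] = {}
        matching: dict[float, float] = {}
        for cfg, spec in spectra.items():
            vals, match, flags = compute_indices(spec, tvi_variant)
            values[cfg] = vals
            matching.update(match)
            if flags:
                undefined[cfg] = flags
        pct: dict[str, dict[str, float]] = {}
        signed: dict[str, dict[str, float]] = {}
        for cfg, vals in values.items():
            mag, sgn, flags = percent_difference(vals, values[reference])
            pct[cfg] = mag
            signed[cfg] = sgn
            if flags:
                undefined.setdefault(cfg, []).extend(
                    f for f in flags if f not in undefined.get(cfg, [])
                )
        return cls(reference, values, pct, signed, matching, undefined)

    def table(self) -> pd.DataFrame:
        rows = []
        for cfg, vals in self.values.items():
            for name in INDEX_NAMES:
                rows.append(
                    {
                        "config": cfg,
                        "index": name,
                        "value": vals[name],
                        "pct_diff_vs_ref": self.pct_diff[cfg][name],
                        "signed_pct_diff": self.signed_diff[cfg][name],
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.table().to_csv(path, index=False)

    def to_json(self, path) -> None:
        import json

        payload = {
            "reference": self.reference,
            "values": self.values,
            "pct_diff_vs_ref": self.pct_diff,
            "signed_pct_diff": self.signed_diff,
            "band_matching": {str(k): v for k, v in self.band_matching.items()},
            "undefined": self.undefined,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
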