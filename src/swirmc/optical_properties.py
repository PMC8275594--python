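"""Chromophore optical properties of finger tissue in the short-wave infrared.

The package carries a default table of absorption coefficients (water,
lactate, lipid, melanin) and scattering coefficients (skin collagen,
hypodermal fat) at ten characterising SWIR wavelengths between 1310 and
2299 nm, all in mm^-1.  The lactate column is the absorption of a
100 mmol/L aqueous reference solution, so a blood lactate concentration
``c`` mmol/L maps to a volume fraction ``c / 100`` of that reference.

Per-layer absorption is a volume-fraction mixture: blood (itself a
lactate + lipid mixture), water, optionally epidermal melanin, and a
weak scattering-tissue baseline ``7.84e8 * lambda**-3.255`` filling the
residual volume.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "OpticalPropertyRecord",
    "OpticalPropertyTable",
    "ChromophoreFractions",
    "MissingWavelengthError",
    "baseline_absorption",
    "blood_absorption",
    "layer_absorption",
    "lactate_volume_fraction",
    "default_table",
    "BASELINE_CONSTANT",
    "BASELINE_EXPONENT",
    "C_REF_MMOL_L",
]

#: Power-law baseline absorption of absorber-free tissue, lambda in nm,
#: result in mm^-1 (the constant may be overridden if a per-cm
#: convention is preferred; the default follows the tabulated mm^-1 units).
BASELINE_CONSTANT = 7.84e8
BASELINE_EXPONENT = -3.255

#: Concentration of the in-vitro lactate reference solution whose
#: absorption the table's lactate column reports.
C_REF_MMOL_L = 100.0

_CSV_COLUMNS = [
    "wavelength_nm",
    "mua_water",
    "mua_lactate",
    "mua_lipid",
    "mua_melanin",
    "mus_skin",
    "mus_fat",
]


class MissingWavelengthError(KeyError):
    """Raised when a wavelength is not present in a property table."""

    def __init__(self, wavelength: float, available: Sequence[float]):
        avail = np.asarray(available, dtype=float)
        order = np.argsort(np.abs(avail - wavelength))
        nearest = avail[order[: min(2, avail.size)]]
        self.wavelength = wavelength
        self.nearest = tuple(float(w) for w in nearest)
        super().__init__(
            f"wavelength {wavelength} nm not in table; nearest available rows: "
            + ", ".join(f"{w:g} nm" for w in self.nearest)
        )


@dataclass(frozen=True)
class OpticalPropertyRecord:
    """One wavelength row of the optical-property table (all mm^-1)."""

    wavelength_nm: float
    mu_a_water: float
    mu_a_lactate: float
    mu_a_lipid: float
    mu_a_melanin: float
    mu_s_skin: float
    mu_s_fat: float

    def __post_init__(self) -> None:
        for name in (
            "mu_a_water",
            "mu_a_lactate",
            "mu_a_lipid",
            "mu_a_melanin",
            "mu_s_skin",
            "mu_s_fat",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")


@dataclass(frozen=True)
class ChromophoreFractions:
    """Volume fractions of the absorbers within one tissue layer.

    ``v_lipid_blood`` and ``v_lactate`` are fractions *of blood*, the
    others fractions of the whole layer volume.  The blood + water
    (+ melanin) budget may not exceed unity; the remainder is assigned
    the baseline absorber-free tissue absorption.
    """

    v_blood: float = 0.0
    v_water: float = 0.0
    v_melanin: float = 0.0
    v_lipid_blood: float = 0.01
    v_lactate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("v_blood", "v_water", "v_melanin", "v_lipid_blood", "v_lactate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.v_blood + self.v_water + self.v_melanin > 1.0 + 1e-12:
            raise ValueError(
                "v_blood + v_water + v_melanin exceeds 1; no residual volume left"
            )


class OpticalPropertyTable:
    """Wavelength-indexed collection of :class:`OpticalPropertyRecord`.

    Wavelengths must be strictly increasing and unique.  Lookup is exact
    by default; linear interpolation between neighbouring rows can be
    requested explicitly (useful for synthetic tables, not part of the
    ten-wavelength study grid).
    """

    def __init__(self, records: Iterable[OpticalPropertyRecord]):
        records = list(records)
        if not records:
            raise ValueError("property table needs at least one record")
        wl = np.array([r.wavelength_nm for r in records], dtype=float)
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing (no duplicates)")
        self._records = tuple(records)
        self._wavelengths = wl
        self._by_wavelength = {r.wavelength_nm: r for r in records}

    @property
    def records(self) -> tuple[OpticalPropertyRecord, ...]:
        return self._records

    @property
    def wavelengths(self) -> np.ndarray:
        return self._wavelengths.copy()

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, wavelength: float) -> bool:
        return float(wavelength) in self._by_wavelength

    def lookup(self, wavelength: float, interpolate: bool = False) -> OpticalPropertyRecord:
        """Return the record at ``wavelength`` (exact match by default)."""
        wavelength = float(wavelength)
        rec = self._by_wavelength.get(wavelength)
        if rec is not None:
            return rec
        if not interpolate:
            raise MissingWavelengthError(wavelength, self._wavelengths)
        wl = self._wavelengths
        if wavelength < wl[0] or wavelength > wl[-1]:
            raise MissingWavelengthError(wavelength, wl)
        hi = int(np.searchsorted(wl, wavelength))
        lo = hi - 1
        t = (wavelength - wl[lo]) / (wl[hi] - wl[lo])
        a, b = self._records[lo], self._records[hi]

        def mix(x: float, y: float) -> float:
            return (1.0 - t) * x + t * y

        return OpticalPropertyRecord(
            wavelength_nm=wavelength,
            mu_a_water=mix(a.mu_a_water, b.mu_a_water),
            mu_a_lactate=mix(a.mu_a_lactate, b.mu_a_lactate),
            mu_a_lipid=mix(a.mu_a_lipid, b.mu_a_lipid),
            mu_a_melanin=mix(a.mu_a_melanin, b.mu_a_melanin),
            mu_s_skin=mix(a.mu_s_skin, b.mu_s_skin),
            mu_s_fat=mix(a.mu_s_fat, b.mu_s_fat),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "wavelength_nm": [r.wavelength_nm for r in self._records],
                "mua_water": [r.mu_a_water for r in self._records],
                "mua_lactate": [r.mu_a_lactate for r in self._records],
                "mua_lipid": [r.mu_a_lipid for r in self._records],
                "mua_melanin": [r.mu_a_melanin for r in self._records],
                "mus_skin": [r.mu_s_skin for r in self._records],
                "mus_fat": [r.mu_s_fat for r in self._records],
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "OpticalPropertyTable":
        missing = set(_CSV_COLUMNS) - set(frame.columns)
        if missing:
            raise ValueError(f"property table missing columns: {sorted(missing)}")
        frame = frame.sort_values("wavelength_nm")
        return cls(
            OpticalPropertyRecord(
                wavelength_nm=float(row.wavelength_nm),
                mu_a_water=float(row.mua_water),
                mu_a_lactate=float(row.mua_lactate),
                mu_a_lipid=float(row.mua_lipid),
                mu_a_melanin=float(row.mua_melanin),
                mu_s_skin=float(row.mus_skin),
                mu_s_fat=float(row.mus_fat),
            )
            for row in frame.itertuples()
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "OpticalPropertyTable":
        return cls.from_frame(pd.read_csv(path))

    @classmethod
    def default(cls) -> "OpticalPropertyTable":
        """The packaged ten-wavelength SWIR table."""
        ref = importlib.resources.files("swirmc.data") / "swir_optical_properties.csv"
        with importlib.resources.as_file(ref) as path:
            return cls.from_csv(path)


def default_table() -> OpticalPropertyTable:
    return OpticalPropertyTable.default()


def baseline_absorption(
    wavelength_nm: float,
    constant: float = BASELINE_CONSTANT,
    exponent: float = BASELINE_EXPONENT,
) -> float:
    """Absorption (mm^-1) of tissue stripped of water, blood and melanin."""
    wavelength_nm = np.asarray(wavelength_nm, dtype=float)
    if np.any(wavelength_nm <= 0):
        raise ValueError("wavelength must be positive")
    out = constant * wavelength_nm ** exponent
    return float(out) if out.ndim == 0 else out


def blood_absorption(
    v_lactate: float, v_lipid: float, record: OpticalPropertyRecord
) -> float:
    """Cumulative blood absorption (mm^-1) from its lactate and lipid content."""
    for name, v in (("v_lactate", v_lactate), ("v_lipid", v_lipid)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    return v_lactate * record.mu_a_lactate + v_lipid * record.mu_a_lipid


def layer_absorption(
    fractions: ChromophoreFractions,
    record: OpticalPropertyRecord,
    baseline_constant: float = BASELINE_CONSTANT,
    baseline_exponent: float = BASELINE_EXPONENT,
) -> float:
    """Cumulative absorption coefficient (mm^-1) of one tissue layer.

    Mixture of blood, water and (for the epidermis) melanin by volume,
    with the residual volume absorbing at the baseline tissue rate.
    """
    f = fractions
    mu_a_b = blood_absorption(f.v_lactate, f.v_lipid_blood, record)
    residual = 1.0 - (f.v_blood + f.v_water + f.v_melanin)
    if residual < -1e-12:
        raise ValueError("volume fractions exceed 1")
    mu_a_t = baseline_absorption(
        record.wavelength_nm, baseline_constant, baseline_exponent
    )
    return (
        f.v_blood * mu_a_b
        + f.v_water * record.mu_a_water
        + f.v_melanin * record.mu_a_melanin
        + residual * mu_a_t
    )


def lactate_volume_fraction(
    c_lactate_mmol_l: float, c_ref_mmol_l: float = C_REF_MMOL_L
) -> float:
    """Map a blood lactate concentration to the volume fraction of the
    100 mmol/L reference solution with the tabulated lactate absorption."""
    if c_lactate_mmol_l < 0:
        raise ValueError("lactate concentration must be non-negative")
    if c_ref_mmol_l <= 0:
        raise ValueError("reference concentration must be positive")
    return c_lactate_mmol_l / c_ref_mmol_l
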