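"""Layered finger-tissue model and reflectance sensor geometry.

The default stack is a semi-infinite slab sandwich, 13 mm deep and
13 mm wide, of eight layers: stratum corneum and epidermis (bloodless),
four dermal sublayers with increasing blood content, and hypodermal fat
down to the bottom of the volume.  Scattering is either the skin
(collagen) or fat (lipid droplet) coefficient of the property table;
the anisotropy ``g = 0.9`` and refractive index ``n = 1.4`` are uniform
across layers, so only the external air-tissue interface refracts.

Coordinates: ``z = 0`` at the air-tissue surface, +z downward; the
source is centred at the origin and the detector centre sits at
``(d, 0, 0)``.  Layer intervals are half-open ``[top, bottom)``.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .optical_properties import (
    ChromophoreFractions,
    OpticalPropertyTable,
    layer_absorption,
    lactate_volume_fraction,
)

__all__ = [
    "TissueLayer",
    "LayeredTissueModel",
    "SensorGeometry",
    "build_finger_model",
    "layer_at_depth",
    "load_model_config",
    "default_model_config",
    "STUDY_SEPARATIONS_MM",
]

#: Source-detector separations of the study grid (mm).
STUDY_SEPARATIONS_MM = (0.7, 1.0, 1.5)


@dataclass(frozen=True)
class TissueLayer:
    """One homogeneous slab with resolved optical coefficients.

    ``mu_s`` is the coefficient the engine transports with; under the
    default reduced-scattering convention it equals the tabulated
    (transport-equivalent) value divided by ``1 - g``, and
    ``mu_s_tabulated`` keeps the table's value for reference.
    """

    name: str
    thickness_mm: float
    fractions: ChromophoreFractions
    scatter_class: str  # "skin" or "fat"
    mu_a: float  # mm^-1
    mu_s: float  # mm^-1
    g: float
    n: float
    mu_s_tabulated: float = None  # mm^-1, as read from the property table

    def __post_init__(self) -> None:
        if self.mu_s_tabulated is None:
            object.__setattr__(self, "mu_s_tabulated", self.mu_s)
        if self.thickness_mm <= 0:
            raise ValueError(f"layer {self.name}: thickness must be positive")
        if self.mu_a < 0 or self.mu_s < 0:
            raise ValueError(f"layer {self.name}: coefficients must be non-negative")
        if not -1.0 < self.g < 1.0:
            raise ValueError(f"layer {self.name}: g must lie in (-1, 1)")
        if self.n < 1.0:
            raise ValueError(f"layer {self.name}: refractive index must be >= 1")
        if self.scatter_class not in ("skin", "fat"):
            raise ValueError(f"layer {self.name}: unknown scatter class")


@dataclass(frozen=True)
class LayeredTissueModel:
    """Ordered top-to-bottom layer stack with its bounding box."""

    layers: tuple[TissueLayer, ...]
    wavelength_nm: float
    c_lactate_mmol_l: float
    lateral_mm: float = 13.0
    total_depth_mm: float = 13.0
    n_external: float = 1.0

    def __post_init__(self) -> None:
        total = sum(l.thickness_mm for l in self.layers)
        if abs(total - self.total_depth_mm) > 1e-9:
            raise ValueError(
                f"layer thicknesses sum to {total} mm, expected {self.total_depth_mm} mm"
            )

    @property
    def z_edges(self) -> np.ndarray:
        """Depth of each layer interface, length ``len(layers) + 1``."""
        t = np.array([l.thickness_mm for l in self.layers])
        return np.concatenate([[0.0], np.cumsum(t)])

    @property
    def mu_a(self) -> np.ndarray:
        return np.array([l.mu_a for l in self.layers])

    @property
    def mu_s(self) -> np.ndarray:
        return np.array([l.mu_s for l in self.layers])

    @property
    def g(self) -> float:
        return self.layers[0].g

    @property
    def n_tissue(self) -> float:
        return self.layers[0].n

    def layer_named(self, name: str) -> TissueLayer:
        for l in self.layers:
            if l.name == name:
                return l
        raise KeyError(name)

    def summary(self) -> dict:
        return {
            "wavelength_nm": self.wavelength_nm,
            "c_lactate_mmol_l": self.c_lactate_mmol_l,
            "lateral_mm": self.lateral_mm,
            "total_depth_mm": self.total_depth_mm,
            "n_external": self.n_external,
            "layers": [
                {
                    "name": l.name,
                    "thickness_mm": l.thickness_mm,
                    "mu_a": l.mu_a,
                    "mu_s": l.mu_s,
                    "g": l.g,
                    "n": l.n,
                }
                for l in self.layers
            ],
        }


@dataclass(frozen=True)
class SensorGeometry:
    """Gaussian source beam and circular detector on the tissue surface."""

    separation_mm: float
    source_radius_mm: float = 0.1
    detector_radius_mm: float = 0.2
    beam_profile: str = "gaussian"  # or "flat"
    beam_center_x_mm: float = 0.0  # off-axis source, for symmetry checks

    def __post_init__(self) -> None:
        if self.separation_mm <= 0 or self.source_radius_mm <= 0 or self.detector_radius_mm <= 0:
            raise ValueError("sensor dimensions must be positive")
        if self.beam_profile not in ("gaussian", "flat"):
            raise ValueError("beam_profile must be 'gaussian' or 'flat'")


# Default anatomy.  Dermal sublayer thicknesses and blood/water contents
# follow the multilayer finger model; stratum corneum (0.02 mm) and
# epidermis (0.25 mm) are chosen so the papillary dermis spans
# 0.27-0.37 mm, and the hypodermis (5% blood, 70% water) fills the
# remaining volume down to 13 mm.
_DEFAULT_LAYER_SPECS = (
    # (name, thickness_mm [None = fill], v_blood, v_water, v_melanin, scatter_class)
    ("stratum_corneum", 0.02, 0.0, 0.05, 0.0, "skin"),
    ("epidermis", 0.25, 0.0, 0.20, 0.02, "skin"),
    ("papillary_dermis", 0.10, 0.04, 0.50, 0.0, "skin"),
    ("upper_blood_net_dermis", 0.08, 0.30, 0.60, 0.0, "skin"),
    ("reticular_dermis", 0.20, 0.04, 0.70, 0.0, "skin"),
    ("deep_blood_net_dermis", 0.30, 0.10, 0.70, 0.0, "skin"),
    ("hypodermis", None, 0.05, 0.70, 0.0, "fat"),
)


def _default_layer_dicts() -> list[dict]:
    return [
        {
            "name": name,
            "thickness_mm": th,
            "v_blood": vb,
            "v_water": vw,
            "v_melanin": vm,
            "scatter_class": sc,
        }
        for name, th, vb, vw, vm, sc in _DEFAULT_LAYER_SPECS
    ]


def default_model_config() -> dict:
    """The packaged finger-model configuration as a plain dict."""
    ref = importlib.resources.files("swirmc.data") / "finger_model.yaml"
    with importlib.resources.as_file(ref) as path:
        return load_model_config(path)


def load_model_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, Mapping) or "layers" not in cfg:
        raise ValueError("model config must be a mapping with a 'layers' block")
    return dict(cfg)


def build_finger_model(
    table: OpticalPropertyTable,
    wavelength_nm: float,
    c_lactate_mmol_l: float,
    overrides: Mapping | None = None,
    *,
    layers: Sequence[Mapping] | None = None,
    v_lipid_blood: float = 0.01,
    c_ref_mmol_l: float = 100.0,
    g: float = 0.9,
    n_tissue: float = 1.4,
    n_external: float = 1.0,
    total_depth_mm: float = 13.0,
    lateral_mm: float = 13.0,
    scatter_convention: str = "reduced",
) -> LayeredTissueModel:
    """Resolve the layered finger model at one wavelength and lactate level.

    ``overrides`` may carry any of the keyword parameters above (as from a
    YAML config) plus a ``layers`` list replacing the default stack; a
    layer entry with ``thickness_mm: null`` fills the remaining depth.

    ``scatter_convention`` controls how the table's scattering columns
    are fed to the anisotropic engine: ``"reduced"`` (default) treats
    them as transport-equivalent coefficients and transports with
    ``mu_s' / (1 - g)``; ``"as_tabulated"`` uses them unscaled.  The
    default reproduces the study's penetration-depth and detected-power
    regime; the face-value reading under-scatters by an order of
    magnitude.
    """
    if c_lactate_mmol_l < 0:
        raise ValueError("lactate concentration must be non-negative")
    if overrides:
        overrides = dict(overrides)
        layers = overrides.pop("layers", layers)
        v_lipid_blood = overrides.pop("v_lipid_blood", v_lipid_blood)
        c_ref_mmol_l = overrides.pop("c_ref_mmol_l", c_ref_mmol_l)
        g = overrides.pop("g", g)
        n_tissue = overrides.pop("n_tissue", n_tissue)
        n_external = overrides.pop("n_external", n_external)
        total_depth_mm = overrides.pop("total_depth_mm", total_depth_mm)
        lateral_mm = overrides.pop("lateral_mm", lateral_mm)
        scatter_convention = overrides.pop("scatter_convention", scatter_convention)
        if overrides:
            raise ValueError(f"unknown model overrides: {sorted(overrides)}")
    layer_specs = [dict(l) for l in (layers if layers is not None else _default_layer_dicts())]

    fixed = sum(l["thickness_mm"] or 0.0 for l in layer_specs)
    n_fill = sum(1 for l in layer_specs if l["thickness_mm"] is None)
    if n_fill > 1:
        raise ValueError("at most one layer may fill the remaining depth")
    if n_fill == 1:
        remainder = total_depth_mm - fixed
        if remainder <= 0:
            raise ValueError("fixed layer thicknesses exceed the total depth")
        for l in layer_specs:
            if l["thickness_mm"] is None:
                l["thickness_mm"] = remainder
    elif abs(fixed - total_depth_mm) > 1e-9:
        raise ValueError(
            f"layer thicknesses sum to {fixed} mm but total depth is {total_depth_mm} mm"
        )

    if scatter_convention not in ("reduced", "as_tabulated"):
        raise ValueError("scatter_convention must be 'reduced' or 'as_tabulated'")
    scatter_scale = 1.0 / (1.0 - g) if scatter_convention == "reduced" else 1.0
    v_lact = lactate_volume_fraction(c_lactate_mmol_l, c_ref_mmol_l)
    record = table.lookup(wavelength_nm)
    resolved = []
    for spec in layer_specs:
        fractions = ChromophoreFractions(
            v_blood=spec.get("v_blood", 0.0),
            v_water=spec.get("v_water", 0.0),
            v_melanin=spec.get("v_melanin", 0.0),
            v_lipid_blood=v_lipid_blood,
            v_lactate=v_lact,
        )
        mu_s = record.mu_s_skin if spec["scatter_class"] == "skin" else record.mu_s_fat
        resolved.append(
            TissueLayer(
                name=spec["name"],
                thickness_mm=float(spec["thickness_mm"]),
                fractions=fractions,
                scatter_class=spec["scatter_class"],
                mu_a=layer_absorption(fractions, record),
                mu_s=mu_s * scatter_scale,
                g=g,
                n=n_tissue,
                mu_s_tabulated=mu_s,
            )
        )
    return LayeredTissueModel(
        layers=tuple(resolved),
        wavelength_nm=wavelength_nm,
        c_lactate_mmol_l=c_lactate_mmol_l,
        lateral_mm=lateral_mm,
        total_depth_mm=total_depth_mm,
        n_external=n_external,
    )


def layer_at_depth(model: LayeredTissueModel, z_mm: float) -> int:
    """Index of the layer whose half-open interval [top, bottom) holds ``z``.

    The bottom of the terminal layer is included so every depth of the
    slab maps to a layer.
    """
    if z_mm < 0 or z_mm > model.total_depth_mm:
        raise ValueError(f"depth {z_mm} mm outside [0, {model.total_depth_mm}] mm")
    edges = model.z_edges
    if z_mm >= edges[-1]:
        return len(model.layers) - 1
    return int(np.searchsorted(edges, z_mm, side="right") - 1)
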