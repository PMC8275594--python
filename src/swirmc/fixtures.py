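"""Degenerate media and perturbed tables with independently known answers.

Every transport stage is checked against an oracle that does not share
code with the engine: closed-form ballistic transmittance for a pure
absorber, an unweighted brute-force Monte Carlo (and, for the matched
isotropic case, the exact Chandrasekhar H-function solution) for
semi-infinite diffuse reflectance, and the cylindrical symmetry of the
geometry itself.  The frozen oracle constants below were produced by
the brute-force simulator in this module before the weighted engine
existed and are not regenerated at test time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .optical_properties import (
    ChromophoreFractions,
    OpticalPropertyRecord,
    OpticalPropertyTable,
)
from .tissue_model import LayeredTissueModel, SensorGeometry, TissueLayer

__all__ = [
    "AnalyticFixture",
    "make_pure_absorber_slab",
    "make_semiinfinite_medium",
    "perturb_property_table",
    "symmetry_fixture",
    "azimuthal_uniformity",
    "brute_force_semiinfinite_reflectance",
    "FROZEN_SEMIINF_MATCHED",
    "FROZEN_SEMIINF_MATCHED_SE",
    "EXACT_SEMIINF_MATCHED",
    "FROZEN_SEMIINF_TISSUE_BOUNDARY",
    "FROZEN_SEMIINF_TISSUE_BOUNDARY_SE",
]

# Frozen outputs of brute_force_semiinfinite_reflectance
# (albedo 0.9, g = 0, 10^6 photons, seed 20210712):
#: matched boundary (n_in = n_out)
FROZEN_SEMIINF_MATCHED = 0.41392
FROZEN_SEMIINF_MATCHED_SE = 0.00049
#: exact H-function value for the same matched configuration
EXACT_SEMIINF_MATCHED = 0.414947
#: air-tissue Fresnel boundary, n = 1.4 into 1.0 (the classic
#: mismatched-boundary benchmark, approximately 0.26)
FROZEN_SEMIINF_TISSUE_BOUNDARY = 0.25825
FROZEN_SEMIINF_TISSUE_BOUNDARY_SE = 0.00044


@dataclass(frozen=True)
class AnalyticFixture:
    """A degenerate medium bundled with its independent oracle."""

    model: LayeredTissueModel
    geometry: SensorGeometry
    oracle_kind: str  # beer_lambert | semi_infinite_albedo | symmetry
    oracle_value: Optional[float]
    oracle_se: float = 0.0
    tolerance_policy: str = "3 sigma combined MC standard error"
    notes: str = ""


def _uniform_layer(
    name: str,
    thickness: float,
    mu_a: float,
    mu_s: float,
    g: float,
    n: float,
) -> TissueLayer:
    return TissueLayer(
        name=name,
        thickness_mm=thickness,
        fractions=ChromophoreFractions(),
        scatter_class="skin",
        mu_a=mu_a,
        mu_s=mu_s,
        g=g,
        n=n,
    )


def make_pure_absorber_slab(
    mu_a: float, thickness_mm: float, wavelength_nm: float = 1684.0
) -> AnalyticFixture:
    """Single matched-boundary purely absorbing slab.

    With no scattering the transport is ballistic along +z and the
    transmitted (bottom-escaping) fraction is exp(-mu_a * L) exactly.
    """
    if mu_a <= 0:
        raise ValueError("mu_a must be positive")
    model = LayeredTissueModel(
        layers=(_uniform_layer("absorber", thickness_mm, mu_a, 0.0, 0.0, 1.0),),
        wavelength_nm=wavelength_nm,
        c_lactate_mmol_l=0.0,
        lateral_mm=1000.0,
        total_depth_mm=thickness_mm,
        n_external=1.0,
    )
    geometry = SensorGeometry(separation_mm=1.0)
    return AnalyticFixture(
        model=model,
        geometry=geometry,
        oracle_kind="beer_lambert",
        oracle_value=float(np.exp(-mu_a * thickness_mm)),
        oracle_se=0.0,
        tolerance_policy="3 MC standard errors of the engine run",
        notes="transmitted = escaped_other (all bottom escapes; no top exits)",
    )


def make_semiinfinite_medium(
    albedo: float,
    g: float,
    boundary: str = "matched",
    mu_t: float = 1.0,
    depth_mm: float = 2000.0,
) -> AnalyticFixture:
    """Effectively semi-infinite homogeneous medium.

    ``boundary='matched'`` has no index step (oracle: exact H-function /
    frozen brute-force MC); ``boundary='tissue'`` applies the n=1.4
    air-tissue Fresnel interface, the classic mismatched benchmark with
    diffuse reflectance near 0.26 at albedo 0.9, g = 0.  Reflectance is
    measured as total top-surface escape relative to the weight entering
    the medium.
    """
    if not 0.0 < albedo < 1.0:
        raise ValueError("albedo must lie in (0, 1)")
    if boundary not in ("matched", "tissue"):
        raise ValueError("boundary must be 'matched' or 'tissue'")
    n_tissue = 1.0 if boundary == "matched" else 1.4
    mu_s = albedo * mu_t
    mu_a = mu_t - mu_s
    model = LayeredTissueModel(
        layers=(_uniform_layer("bulk", depth_mm, mu_a, mu_s, g, n_tissue),),
        wavelength_nm=1684.0,
        c_lactate_mmol_l=0.0,
        lateral_mm=4.0 * depth_mm,
        total_depth_mm=depth_mm,
        n_external=1.0,
    )
    # a detector disk covering the whole surface: every top escape detected
    geometry = SensorGeometry(
        separation_mm=1e-6, detector_radius_mm=4.0 * depth_mm
    )
    if albedo == 0.9 and g == 0.0:
        if boundary == "matched":
            value, se = FROZEN_SEMIINF_MATCHED, FROZEN_SEMIINF_MATCHED_SE
        else:
            value, se = (
                FROZEN_SEMIINF_TISSUE_BOUNDARY,
                FROZEN_SEMIINF_TISSUE_BOUNDARY_SE,
            )
    else:
        value, se = None, 0.0
    return AnalyticFixture(
        model=model,
        geometry=geometry,
        oracle_kind="semi_infinite_albedo",
        oracle_value=value,
        oracle_se=se,
        tolerance_policy="combined 3 sigma of engine and frozen oracle",
        notes="reflectance = detected_weight / launched_weight (post-specular)",
    )


def brute_force_semiinfinite_reflectance(
    albedo: float,
    g: float,
    n_photons: int,
    seed: int,
    n_in: float = 1.0,
    n_out: float = 1.0,
) -> float:
    """Unweighted (analog) MC for semi-infinite diffuse reflectance.

    Photons are absorbed outright with probability ``1 - albedo`` at
    each interaction; the top boundary applies unpolarised Fresnel
    statistics when ``n_in != n_out``.  Independent of the weighted
    engine; source of the frozen oracle constants above.
    """
    rng = np.random.default_rng(seed)
    z = np.zeros(n_photons)
    ux = np.zeros(n_photons)
    uy = np.zeros(n_photons)
    uz = np.ones(n_photons)
    alive = np.ones(n_photons, bool)
    reflected = 0
    while alive.any():
        idx = np.flatnonzero(alive)
        s = -np.log(rng.random(idx.size))
        z[idx] += s * uz[idx]
        up = idx[z[idx] < 0]
        if up.size:
            if n_in == n_out:
                reflected += up.size
                alive[up] = False
            else:
                ci = -uz[up]
                sin_t2 = (n_in / n_out) ** 2 * (1 - ci**2)
                R = np.ones(up.size)
                ok = sin_t2 < 1
                ct = np.sqrt(np.maximum(0.0, 1 - sin_t2[ok]))
                cio = ci[ok]
                rs = ((n_in * cio - n_out * ct) / (n_in * cio + n_out * ct)) ** 2
                rp = ((n_in * ct - n_out * cio) / (n_in * ct + n_out * cio)) ** 2
                R[ok] = 0.5 * (rs + rp)
                esc = rng.random(up.size) >= R
                reflected += int(esc.sum())
                alive[up[esc]] = False
                back = up[~esc]
                z[back] = -z[back]
                uz[back] = -uz[back]
        idx = np.flatnonzero(alive)
        kill = rng.random(idx.size) >= albedo
        alive[idx[kill]] = False
        idx = idx[~kill]
        if g == 0.0:
            ct = 2 * rng.random(idx.size) - 1
        else:
            xi = rng.random(idx.size)
            t = (1 - g * g) / (1 - g + 2 * g * xi)
            ct = (1 + g * g - t * t) / (2 * g)
        st = np.sqrt(np.maximum(0.0, 1 - ct**2))
        phi = 2 * np.pi * rng.random(idx.size)
        cp, sp = np.cos(phi), np.sin(phi)
        uxo, uyo, uzo = ux[idx], uy[idx], uz[idx]
        nv = np.abs(uzo) > 0.99999
        den = np.sqrt(np.maximum(1e-300, 1 - uzo**2))
        nux = st * (uxo * uzo * cp - uyo * sp) / den + uxo * ct
        nuy = st * (uyo * uzo * cp + uxo * sp) / den + uyo * ct
        nuz = -st * cp * den + uzo * ct
        nux = np.where(nv, st * cp, nux)
        nuy = np.where(nv, st * sp, nuy)
        nuz = np.where(nv, np.sign(uzo) * ct, nuz)
        nrm = np.sqrt(nux**2 + nuy**2 + nuz**2)
        ux[idx], uy[idx], uz[idx] = nux / nrm, nuy / nrm, nuz / nrm
    return reflected / n_photons


def perturb_property_table(
    table: OpticalPropertyTable, relative_noise: float, seed: int
) -> OpticalPropertyTable:
    """Multiply every coefficient by an independent log-normal factor
    with the given coefficient of variation (mean-preserving).

    Positivity and wavelength ordering are preserved by construction.
    """
    if not 0.0 <= relative_noise <= 0.5:
        raise ValueError("relative_noise must lie in [0, 0.5]")
    if relative_noise == 0.0:
        return table
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(relative_noise**2))
    mu = -0.5 * sigma**2

    def jitter(v: float) -> float:
        return float(v * np.exp(mu + sigma * rng.standard_normal()))

    records = [
        OpticalPropertyRecord(
            wavelength_nm=r.wavelength_nm,
            mu_a_water=jitter(r.mu_a_water),
            mu_a_lactate=jitter(r.mu_a_lactate),
            mu_a_lipid=jitter(r.mu_a_lipid),
            mu_a_melanin=jitter(r.mu_a_melanin),
            mu_s_skin=jitter(r.mu_s_skin),
            mu_s_fat=jitter(r.mu_s_fat),
        )
        for r in table.records
    ]
    return OpticalPropertyTable(records)


def symmetry_fixture(
    table: OpticalPropertyTable | None = None,
    wavelength_nm: float = 1684.0,
    ring_radius_mm: float = 1.0,
    beam_center_x_mm: float = 0.0,
) -> AnalyticFixture:
    """Finger model with a ring detector at ``ring_radius``.

    A centred normal-incidence beam in laterally homogeneous slabs has
    azimuthally uniform exit statistics; an off-centre beam breaks the
    symmetry (negative control).
    """
    from .tissue_model import build_finger_model

    table = table or OpticalPropertyTable.default()
    model = build_finger_model(table, wavelength_nm, 2.0)
    geometry = SensorGeometry(
        separation_mm=ring_radius_mm,
        detector_radius_mm=0.2,
        beam_center_x_mm=beam_center_x_mm,
    )
    return AnalyticFixture(
        model=model,
        geometry=geometry,
        oracle_kind="symmetry",
        oracle_value=None,
        tolerance_policy="chi-square over 12 azimuthal sectors, alpha = 0.01",
        notes="run with TransportConfig(ring_detector=True)",
    )


def azimuthal_uniformity(exit_x, exit_y, n_sectors: int = 12) -> float:
    """p-value of a chi-square test of uniform azimuthal sector counts."""
    phi = np.arctan2(np.asarray(exit_y), np.asarray(exit_x))
    sector = np.floor((phi + np.pi) / (2 * np.pi) * n_sectors).astype(int)
    sector = np.clip(sector, 0, n_sectors - 1)
    counts = np.bincount(sector, minlength=n_sectors)
    return float(stats.chisquare(counts).pvalue)
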