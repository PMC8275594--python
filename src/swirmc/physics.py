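"""Elementary photon-transport operations.

Vectorised numpy reference implementations of the steps the compiled
engine performs per packet: beam launch, exponential free paths,
implicit-capture weight deposit, Henyey-Greenstein scattering, Fresnel
boundary physics, detection, and Russian roulette.  The compiled kernel
in :mod:`swirmc._kernel` inlines the same formulas; these functions are
the testable statement of the physics.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "specular_reflectance",
    "fresnel_unpolarized",
    "sample_launch",
    "free_path",
    "deposit",
    "sample_hg_cosine",
    "scatter_hg",
    "surface_escape",
    "detect",
    "roulette",
    "BEAM_TRUNCATION_RADII",
]

#: The Gaussian beam is truncated at this multiple of its 1/e^2 radius.
BEAM_TRUNCATION_RADII = 2.0


def specular_reflectance(n_tissue: float, n_external: float = 1.0) -> float:
    """Normal-incidence Fresnel reflectance of the external interface."""
    return ((n_tissue - n_external) / (n_tissue + n_external)) ** 2


def fresnel_unpolarized(cos_incident, n_from: float, n_to: float):
    """Unpolarised Fresnel reflectance for |cos| of the incident angle.

    Returns 1 beyond the critical angle (total internal reflection).
    """
    ci = np.abs(np.asarray(cos_incident, dtype=float))
    sin_t2 = (n_from / n_to) ** 2 * (1.0 - ci**2)
    R = np.ones_like(ci)
    ok = sin_t2 < 1.0
    ct = np.sqrt(1.0 - sin_t2[ok])
    cio = ci[ok]
    rs = ((n_from * cio - n_to * ct) / (n_from * cio + n_to * ct)) ** 2
    rp = ((n_from * ct - n_to * cio) / (n_from * ct + n_to * cio)) ** 2
    R[ok] = 0.5 * (rs + rp)
    return float(R) if R.ndim == 0 else R


def sample_launch(
    rng: np.random.Generator,
    n: int,
    beam_radius_mm: float = 0.1,
    n_tissue: float = 1.4,
    n_external: float = 1.0,
    beam_profile: str = "gaussian",
    beam_center_x_mm: float = 0.0,
    truncation_radii: float = BEAM_TRUNCATION_RADII,
):
    """Launch positions and initial weights of ``n`` packets.

    Radial positions follow the 1/e^2-radius Gaussian intensity profile
    truncated at ``truncation_radii`` beam radii (or a uniform disk of
    that radius for a flat-top beam); incidence is normal, and the
    initial weight is reduced by the specular reflectance.
    """
    xi = rng.random(n)
    r_max = truncation_radii * beam_radius_mm
    if beam_profile == "flat":
        r = r_max * np.sqrt(xi)
    elif beam_profile == "gaussian":
        norm = 1.0 - np.exp(-2.0 * truncation_radii**2)
        r = beam_radius_mm * np.sqrt(-0.5 * np.log(1.0 - xi * norm))
    else:
        raise ValueError("beam_profile must be 'gaussian' or 'flat'")
    phi = 2.0 * np.pi * rng.random(n)
    x = beam_center_x_mm + r * np.cos(phi)
    y = r * np.sin(phi)
    w = np.full(n, 1.0 - specular_reflectance(n_tissue, n_external))
    return x, y, w


def free_path(rng: np.random.Generator, mu_t: float, size=None):
    """Exponential free path ``-ln(xi)/mu_t`` (mm)."""
    if mu_t <= 0:
        raise ValueError("mu_t must be positive (degenerate medium)")
    xi = rng.random(size)
    return -np.log1p(-xi) / mu_t  # xi uniform on [0,1) -> 1-xi on (0,1]


def deposit(weight, mu_a: float, mu_s: float):
    """Implicit-capture deposit: returns (new_weight, deposited)."""
    mu_t = mu_a + mu_s
    if mu_t <= 0:
        raise ValueError("mu_a + mu_s must be positive")
    deposited = np.asarray(weight, dtype=float) * (mu_a / mu_t)
    return weight - deposited, deposited


def sample_hg_cosine(rng: np.random.Generator, g: float, size=None):
    """Deflection cosine from the Henyey-Greenstein inverse CDF."""
    xi = rng.random(size)
    if g == 0.0:
        return 2.0 * xi - 1.0
    t = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
    return (1.0 + g * g - t * t) / (2.0 * g)


def scatter_hg(rng: np.random.Generator, g: float, directions: np.ndarray) -> np.ndarray:
    """Scatter unit direction vectors (n, 3) through an HG deflection."""
    directions = np.atleast_2d(np.asarray(directions, dtype=float))
    n = directions.shape[0]
    ct = np.asarray(sample_hg_cosine(rng, g, n))
    st = np.sqrt(np.maximum(0.0, 1.0 - ct**2))
    phi = 2.0 * np.pi * rng.random(n)
    cp, sp = np.cos(phi), np.sin(phi)
    ux, uy, uz = directions.T
    near_vertical = np.abs(uz) > 0.99999
    den = np.sqrt(np.maximum(1e-300, 1.0 - uz**2))
    nux = st * (ux * uz * cp - uy * sp) / den + ux * ct
    nuy = st * (uy * uz * cp + ux * sp) / den + uy * ct
    nuz = -st * cp * den + uz * ct
    nux = np.where(near_vertical, st * cp, nux)
    nuy = np.where(near_vertical, st * sp, nuy)
    nuz = np.where(near_vertical, np.sign(uz) * ct, nuz)
    out = np.stack([nux, nuy, nuz], axis=1)
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    return out


def surface_escape(
    rng: np.random.Generator,
    uz,
    n_tissue: float = 1.4,
    n_external: float = 1.0,
):
    """Sample transmission of upward-moving packets at the top surface.

    Returns a boolean array: True where the packet leaves the tissue,
    False where it is internally reflected (always False beyond the
    critical angle).
    """
    uz = np.asarray(uz, dtype=float)
    if np.any(uz >= 0):
        raise ValueError("surface escape requires an upward (uz < 0) direction")
    R = fresnel_unpolarized(np.abs(uz), n_tissue, n_external)
    return rng.random(np.shape(uz)) >= R


def detect(x, y, separation_mm: float, detector_radius_mm: float = 0.2):
    """True where the surface exit position lies on the detector disk
    centred at ``(separation, 0)`` (boundary inclusive)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    hit = (x - separation_mm) ** 2 + y**2 <= detector_radius_mm**2
    return bool(hit) if hit.ndim == 0 else hit


def roulette(rng: np.random.Generator, weight, survival: float):
    """Russian roulette: survivors keep ``weight / survival``, the rest
    are terminated (weight 0).  Unbiased in expectation."""
    if not 0.0 < survival <= 1.0:
        raise ValueError("survival probability must lie in (0, 1]")
    weight = np.asarray(weight, dtype=float)
    survive = rng.random(weight.shape) < survival
    out = np.where(survive, weight / survival, 0.0)
    return float(out) if out.ndim == 0 else out
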