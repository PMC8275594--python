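"""Weighted-photon Monte Carlo runs over a layered tissue model.

`run_simulation` drives the compiled kernel and returns a
:class:`SimulationResult` with the energy tallies (detected, absorbed,
escaped, specular), per-detected-packet records (exit position and
weight, maximum depth reached, interaction count) and, optionally, a
voxelised interaction-event map restricted to detected-photon paths —
the source-to-detector "banana" sampling volume.

Energy bookkeeping: with roulette disabled every launched unit of
weight ends in exactly one of the detected / absorbed / escaped pools,
so ``launched = detected + absorbed + escaped_other`` holds to floating
precision; with roulette enabled the identity holds in expectation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import h5py

from ._kernel import transport_kernel
from .tissue_model import LayeredTissueModel, SensorGeometry
from .physics import BEAM_TRUNCATION_RADII

__all__ = [
    "TransportConfig",
    "SimulationResult",
    "run_simulation",
    "save_result",
    "load_result_summary",
    "DegenerateMediumError",
]

#: Default voxel grid for interaction-event maps: a window around the
#: source-detector axis, (x, y, z) bounds in mm.
DEFAULT_MAP_BOUNDS = ((-2.0, 4.0), (-2.0, 2.0), (0.0, 3.0))


class DegenerateMediumError(ValueError):
    """A layer with mu_a + mu_s = 0 cannot transport photons."""


@dataclass(frozen=True)
class TransportConfig:
    """Engine parameters independent of the tissue and sensor."""

    n_photons: int
    seed: int = 0
    weight_threshold: float = 1e-4
    roulette_survival: float = 0.1
    max_events: int = 100_000
    record_map: bool = False
    map_voxel_mm: float = 0.02
    map_bounds: tuple = DEFAULT_MAP_BOUNDS
    map_all_paths: bool = False
    ring_detector: bool = False
    n_workers: int = 1

    def __post_init__(self) -> None:
        if self.n_photons < 1:
            raise ValueError("n_photons must be >= 1")
        if not 0.0 < self.roulette_survival <= 1.0:
            raise ValueError("roulette_survival must lie in (0, 1]")
        if not 0.0 <= self.weight_threshold < 1.0:
            raise ValueError("weight_threshold must lie in [0, 1)")
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")


@dataclass
class SimulationResult:
    """Tallies and per-detected-packet records of one run."""

    n_photons: int
    incident_weight: float        # pre-specular: one unit per packet
    launched_weight: float        # post-specular weight entering the tissue
    detected_weight: float
    detected_weight_sq: float     # sum of squared detected packet weights
    absorbed_weight: float
    escaped_other_weight: float   # surface outside detector + lateral + bottom
    specular_weight: float
    n_detected: int
    exit_x: np.ndarray
    exit_y: np.ndarray
    exit_weight: np.ndarray
    max_depth: np.ndarray
    n_events: np.ndarray
    #: (n_detected, n_layers) path length travelled in each layer; the
    #: sufficient statistic for exact absorption-perturbation reweighting
    layer_path_lengths: np.ndarray
    n_cap_exceeded: int
    event_map: Optional[np.ndarray]
    map_origin: Optional[np.ndarray]
    map_voxel_mm: Optional[float]
    config: TransportConfig = None
    geometry: SensorGeometry = None
    model_summary: dict = field(default_factory=dict)

    @property
    def detected_fraction(self) -> float:
        """Detected weight as a fraction of the incident (pre-specular) power."""
        return self.detected_weight / self.incident_weight

    def conservation_defect(self) -> float:
        """Relative gap in launched = detected + absorbed + escaped_other."""
        total = self.detected_weight + self.absorbed_weight + self.escaped_other_weight
        return abs(total - self.launched_weight) / self.launched_weight


def _derive_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def run_simulation(
    model: LayeredTissueModel,
    geometry: SensorGeometry,
    config: TransportConfig,
) -> SimulationResult:
    """Propagate ``config.n_photons`` weighted packets through ``model``.

    Deterministic for a fixed ``(seed, n_workers)``; the photon budget is
    split evenly over workers with seeds derived from ``config.seed``, and
    worker tallies are summed in worker order.
    """
    mu_a = model.mu_a
    mu_s = model.mu_s
    if np.any(mu_a + mu_s <= 0):
        bad = [l.name for l in model.layers if l.mu_a + l.mu_s <= 0]
        raise DegenerateMediumError(f"layers with mu_a + mu_s = 0: {bad}")

    z_edges = model.z_edges
    if config.record_map:
        (x0, x1), (y0, y1), (z0, z1) = config.map_bounds
        vox = config.map_voxel_mm
        shape = (
            max(1, int(round((x1 - x0) / vox))),
            max(1, int(round((y1 - y0) / vox))),
            max(1, int(round((z1 - z0) / vox))),
        )
        event_map = np.zeros(shape, dtype=np.int64)
        map_origin = np.array([x0, y0, z0])
    else:
        event_map = np.zeros((1, 1, 1), dtype=np.int64)
        map_origin = np.zeros(3)
    event_buf = np.zeros((config.max_events, 3), dtype=np.int32)

    seeds = _derive_seeds(config.seed, config.n_workers)
    counts = np.full(config.n_workers, config.n_photons // config.n_workers)
    counts[: config.n_photons % config.n_workers] += 1

    n_detected = 0
    detected_w = detected_w2 = absorbed_w = escaped_w = specular_w = 0.0
    n_cap = 0
    n_layers = len(model.layers)
    chunks_x, chunks_y, chunks_w, chunks_z, chunks_ev, chunks_lp = [], [], [], [], [], []
    for wseed, n_chunk in zip(seeds, counts):
        if n_chunk == 0:
            continue
        ex = np.empty(n_chunk)
        ey = np.empty(n_chunk)
        ew = np.empty(n_chunk)
        mz = np.empty(n_chunk)
        ne = np.empty(n_chunk, dtype=np.int64)
        lp = np.empty((n_chunk, n_layers))
        (nd, dw, dw2, aw, ow, sw, nc) = transport_kernel(
            int(wseed),
            int(n_chunk),
            z_edges,
            mu_a,
            mu_s,
            float(model.g),
            float(model.n_tissue),
            float(model.n_external),
            float(model.lateral_mm / 2.0),
            float(geometry.source_radius_mm),
            float(BEAM_TRUNCATION_RADII),
            geometry.beam_profile == "flat",
            float(geometry.beam_center_x_mm),
            float(geometry.separation_mm),
            float(geometry.detector_radius_mm),
            bool(config.ring_detector),
            float(config.weight_threshold),
            float(config.roulette_survival),
            int(config.max_events),
            bool(config.record_map),
            bool(config.map_all_paths),
            map_origin,
            float(config.map_voxel_mm),
            event_map,
            event_buf,
            ex,
            ey,
            ew,
            mz,
            ne,
            lp,
        )
        n_detected += nd
        detected_w += dw
        detected_w2 += dw2
        absorbed_w += aw
        escaped_w += ow
        specular_w += sw
        n_cap += nc
        chunks_x.append(ex[:nd])
        chunks_y.append(ey[:nd])
        chunks_w.append(ew[:nd])
        chunks_z.append(mz[:nd])
        chunks_ev.append(ne[:nd])
        chunks_lp.append(lp[:nd])

    if n_cap > 0.001 * config.n_photons:
        warnings.warn(
            f"event cap ({config.max_events}) hit by {n_cap} of "
            f"{config.n_photons} packets; residual weight pooled with escapes",
            RuntimeWarning,
        )

    r_spec_total = specular_w
    return SimulationResult(
        n_photons=config.n_photons,
        incident_weight=float(config.n_photons),
        launched_weight=float(config.n_photons) - r_spec_total,
        detected_weight=detected_w,
        detected_weight_sq=detected_w2,
        absorbed_weight=absorbed_w,
        escaped_other_weight=escaped_w,
        specular_weight=r_spec_total,
        n_detected=n_detected,
        exit_x=np.concatenate(chunks_x) if chunks_x else np.empty(0),
        exit_y=np.concatenate(chunks_y) if chunks_y else np.empty(0),
        exit_weight=np.concatenate(chunks_w) if chunks_w else np.empty(0),
        max_depth=np.concatenate(chunks_z) if chunks_z else np.empty(0),
        n_events=np.concatenate(chunks_ev) if chunks_ev else np.empty(0, dtype=np.int64),
        layer_path_lengths=(
            np.concatenate(chunks_lp) if chunks_lp else np.empty((0, n_layers))
        ),
        n_cap_exceeded=n_cap,
        event_map=event_map if config.record_map else None,
        map_origin=map_origin if config.record_map else None,
        map_voxel_mm=config.map_voxel_mm if config.record_map else None,
        config=config,
        geometry=geometry,
        model_summary=model.summary(),
    )


def save_result(result: SimulationResult, path: str | Path) -> None:
    """Write a result to an HDF5 container (datasets ``event_map``,
    ``max_depths``, ``exit_weights``, ... with the config echoed as
    a JSON attribute)."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("max_depths", data=result.max_depth)
        fh.create_dataset("exit_weights", data=result.exit_weight)
        fh.create_dataset("exit_x", data=result.exit_x)
        fh.create_dataset("exit_y", data=result.exit_y)
        fh.create_dataset("n_events", data=result.n_events)
        fh.create_dataset("layer_path_lengths", data=result.layer_path_lengths)
        if result.event_map is not None:
            fh.create_dataset("event_map", data=result.event_map, compression="gzip")
            fh["event_map"].attrs["voxel_mm"] = result.map_voxel_mm
            fh["event_map"].attrs["origin_mm"] = result.map_origin
        fh.attrs["config"] = json.dumps(
            {
                "transport": asdict(result.config),
                "geometry": asdict(result.geometry),
                "model": result.model_summary,
            },
            default=str,
        )
        for name in (
            "n_photons",
            "incident_weight",
            "launched_weight",
            "detected_weight",
            "absorbed_weight",
            "escaped_other_weight",
            "specular_weight",
            "n_detected",
        ):
            fh.attrs[name] = getattr(result, name)


def load_result_summary(path: str | Path) -> dict:
    """Read back the scalar tallies and config echo of a saved result."""
    with h5py.File(path, "r") as fh:
        out = {k: fh.attrs[k] for k in fh.attrs if k != "config"}
        out["config"] = json.loads(fh.attrs["config"])
    return out
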