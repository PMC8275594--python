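"""The weighted-photon engine against analytic and frozen MC oracles."""

import dataclasses

import numpy as np
import pytest

from swirmc.fixtures import (
    EXACT_SEMIINF_MATCHED,
    FROZEN_SEMIINF_MATCHED,
    FROZEN_SEMIINF_MATCHED_SE,
    make_pure_absorber_slab,
    make_semiinfinite_medium,
)
from swirmc.tissue_model import SensorGeometry, build_finger_model
from swirmc.transport import (
    DegenerateMediumError,
    TransportConfig,
    run_simulation,
)


def binomial_se(p, n):
    return np.sqrt(max(p * (1 - p), 1e-12) / n)


class TestBeerLambert:
    def test_pure_absorber_slab_transmittance(self):
        """Ballistic transmission through mu_a = 1/mm, L = 1 mm is e^-1."""
        fx = make_pure_absorber_slab(1.0, 1.0)
        res = run_simulation(fx.model, fx.geometry, TransportConfig(n_photons=100_000, seed=3))
        trans = res.escaped_other_weight / res.launched_weight
        assert trans == pytest.approx(
            fx.oracle_value, abs=3 * binomial_se(fx.oracle_value, 100_000)
        )
        # no scattering: nothing comes back out of the top
        assert res.detected_weight == 0.0

    def test_water_only_slab_at_1684(self):
        fx = make_pure_absorber_slab(0.45, 1.0)
        assert fx.oracle_value == pytest.approx(0.6376, abs=2e-4)
        res = run_simulation(fx.model, fx.geometry, TransportConfig(n_photons=50_000, seed=9))
        trans = res.escaped_other_weight / res.launched_weight
        assert trans == pytest.approx(fx.oracle_value, abs=3 * binomial_se(fx.oracle_value, 50_000))


class TestSemiInfinite:
    def test_matched_boundary_reflectance_vs_frozen_oracle(self):
        """Albedo-0.9 isotropic diffuse reflectance against the
        unweighted brute-force MC (frozen) and the exact H-function
        value 0.414947."""
        fx = make_semiinfinite_medium(0.9, 0.0, boundary="matched")
        n = 150_000
        res = run_simulation(fx.model, fx.geometry, TransportConfig(n_photons=n, seed=4))
        refl = res.detected_weight / res.launched_weight
        combined = np.hypot(fx.oracle_se, binomial_se(FROZEN_SEMIINF_MATCHED, n))
        assert refl == pytest.approx(FROZEN_SEMIINF_MATCHED, abs=3 * combined)
        assert refl == pytest.approx(EXACT_SEMIINF_MATCHED, abs=3 * combined)

    def test_forward_peaked_reflects_less_than_isotropic(self):
        iso = make_semiinfinite_medium(0.9, 0.0, boundary="matched")
        fwd = make_semiinfinite_medium(0.9, 0.9, boundary="matched")
        cfg = TransportConfig(n_photons=40_000, seed=6)
        r_iso = run_simulation(iso.model, iso.geometry, cfg)
        r_fwd = run_simulation(fwd.model, fwd.geometry, cfg)
        assert (
            r_fwd.detected_weight / r_fwd.launched_weight
            < r_iso.detected_weight / r_iso.launched_weight
        )


class TestConservationAndDeterminism:
    def test_energy_conservation_with_roulette_disabled(self, table):
        """launched = detected + absorbed + escaped_other to 1e-9
        relative when no packet is stochastically terminated."""
        model = build_finger_model(table, 1920, 2.0)
        cfg = TransportConfig(
            n_photons=5_000, seed=5, weight_threshold=0.0, max_events=10_000_000
        )
        res = run_simulation(model, SensorGeometry(separation_mm=1.0), cfg)
        assert res.n_cap_exceeded == 0
        assert res.conservation_defect() < 1e-9
        # specular + launched = incident, by construction of the launch
        assert res.specular_weight + res.launched_weight == pytest.approx(
            res.incident_weight, rel=1e-12
        )

    def test_seed_determinism_is_bit_exact(self, table):
        model = build_finger_model(table, 1684, 2.0)
        geo = SensorGeometry(separation_mm=1.0)
        cfg = TransportConfig(n_photons=20_000, seed=42)
        a = run_simulation(model, geo, cfg)
        b = run_simulation(model, geo, cfg)
        assert a.detected_weight == b.detected_weight
        assert a.absorbed_weight == b.absorbed_weight
        assert np.array_equal(a.max_depth, b.max_depth)
        assert np.array_equal(a.exit_x, b.exit_x)

    def test_different_seeds_differ(self, table):
        model = build_finger_model(table, 1684, 2.0)
        geo = SensorGeometry(separation_mm=1.0)
        a = run_simulation(model, geo, TransportConfig(n_photons=20_000, seed=1))
        b = run_simulation(model, geo, TransportConfig(n_photons=20_000, seed=2))
        assert a.detected_weight != b.detected_weight

    def test_worker_split_conserves_and_is_reproducible(self, table):
        model = build_finger_model(table, 1920, 2.0)
        geo = SensorGeometry(separation_mm=1.0)
        cfg = TransportConfig(
            n_photons=6_000, seed=11, n_workers=3, weight_threshold=0.0,
            max_events=10_000_000,
        )
        a = run_simulation(model, geo, cfg)
        b = run_simulation(model, geo, cfg)
        assert a.conservation_defect() < 1e-9
        assert a.detected_weight == b.detected_weight
        assert a.n_detected == b.n_detected


class TestPhysicalMonotonicity:
    def test_doubling_absorption_reduces_detection(self, table):
        model = build_finger_model(table, 1650, 2.0)
        doubled = dataclasses.replace(
            model,
            layers=tuple(
                dataclasses.replace(l, mu_a=2 * l.mu_a) for l in model.layers
            ),
        )
        geo = SensorGeometry(separation_mm=0.7)
        cfg = TransportConfig(n_photons=60_000, seed=13)
        base = run_simulation(model, geo, cfg)
        more = run_simulation(doubled, geo, cfg)
        assert more.detected_weight < base.detected_weight

    def test_detection_decreases_with_separation(self, table):
        model = build_finger_model(table, 1684, 2.0)
        cfg = TransportConfig(n_photons=60_000, seed=17)
        powers = [
            run_simulation(model, SensorGeometry(separation_mm=d), cfg).detected_weight
            for d in (0.7, 1.0, 1.5)
        ]
        assert powers[0] > powers[1] > powers[2]


class TestEventMap:
    def test_map_accumulates_only_detected_paths_by_default(self, table):
        model = build_finger_model(table, 1684, 2.0)
        geo = SensorGeometry(separation_mm=0.7)
        cfg = TransportConfig(n_photons=30_000, seed=23, record_map=True)
        res = run_simulation(model, geo, cfg)
        assert res.event_map is not None and res.event_map.sum() > 0
        all_cfg = dataclasses.replace(cfg, map_all_paths=True)
        res_all = run_simulation(model, geo, all_cfg)
        assert res_all.event_map.sum() > res.event_map.sum()

    def test_detected_map_events_bounded_by_detected_interactions(self, table):
        model = build_finger_model(table, 1684, 2.0)
        cfg = TransportConfig(n_photons=30_000, seed=23, record_map=True)
        res = run_simulation(model, SensorGeometry(separation_mm=0.7), cfg)
        assert res.event_map.sum() <= res.n_events.sum()

    def test_banana_shape_peaks_between_source_and_detector(self, table):
        """The detected-path event cloud is confined near the
        source-detector axis and shallower than the full slab."""
        model = build_finger_model(table, 1684, 2.0)
        cfg = TransportConfig(n_photons=60_000, seed=29, record_map=True)
        res = run_simulation(model, SensorGeometry(separation_mm=1.0), cfg)
        nx, ny, nz = res.event_map.shape
        x_profile = res.event_map.sum(axis=(1, 2))
        x_centres = res.map_origin[0] + (np.arange(nx) + 0.5) * res.map_voxel_mm
        x_peak = x_centres[np.argmax(x_profile)]
        assert -0.5 < x_peak < 1.5  # between source (0) and detector (1 mm)


class TestResultContainer:
    def test_degenerate_medium_rejected(self, table):
        fx_model = build_finger_model(table, 1684, 2.0)
        dead = dataclasses.replace(
            fx_model,
            layers=tuple(
                dataclasses.replace(l, mu_a=0.0, mu_s=0.0) for l in fx_model.layers
            ),
        )
        with pytest.raises(DegenerateMediumError):
            run_simulation(dead, SensorGeometry(separation_mm=1.0), TransportConfig(n_photons=10))

    def test_hdf5_round_trip(self, table, tmp_path):
        from swirmc.transport import load_result_summary, save_result

        model = build_finger_model(table, 1684, 2.0)
        cfg = TransportConfig(n_photons=5_000, seed=31, record_map=True)
        res = run_simulation(model, SensorGeometry(separation_mm=1.0), cfg)
        path = tmp_path / "run.h5"
        save_result(res, path)
        summary = load_result_summary(path)
        assert summary["detected_weight"] == pytest.approx(res.detected_weight)
        assert summary["config"]["transport"]["seed"] == 31
        assert summary["config"]["model"]["wavelength_nm"] == 1684
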