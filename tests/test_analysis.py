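"""Summary statistics: penetration depth, relative power, absorbance."""

import math

import numpy as np
import pandas as pd
import pytest

from swirmc.analysis import (
    InsufficientStatisticsError,
    absorbance,
    concentration_sweep,
    mean_penetration_depth,
    normalize_absorbance,
    power_standard_error,
    relative_power,
)
from swirmc.tissue_model import SensorGeometry
from swirmc.transport import SimulationResult, TransportConfig


def fake_result(detected_weight, n_photons=100, max_depths=(), weights=None):
    max_depths = np.asarray(max_depths, dtype=float)
    n_det = max_depths.size
    weights = (
        np.asarray(weights, dtype=float) if weights is not None else np.ones(n_det)
    )
    return SimulationResult(
        n_photons=n_photons,
        incident_weight=float(n_photons),
        launched_weight=float(n_photons),
        detected_weight=detected_weight,
        detected_weight_sq=float(np.sum(weights**2)),
        absorbed_weight=0.0,
        escaped_other_weight=float(n_photons) - detected_weight,
        specular_weight=0.0,
        n_detected=n_det,
        exit_x=np.zeros(n_det),
        exit_y=np.zeros(n_det),
        exit_weight=weights,
        max_depth=max_depths,
        n_events=np.ones(n_det, dtype=np.int64),
        layer_path_lengths=np.zeros((n_det, 7)),
        n_cap_exceeded=0,
        event_map=None,
        map_origin=None,
        map_voxel_mm=None,
        config=TransportConfig(n_photons=n_photons),
        geometry=SensorGeometry(separation_mm=1.0),
    )


class TestMeanPenetrationDepth:
    def test_single_photon(self):
        assert mean_penetration_depth(fake_result(1.0, max_depths=[0.5])) == 0.5

    def test_arithmetic_mean_is_unweighted(self):
        res = fake_result(1.0, max_depths=[0.2, 0.4, 0.6], weights=[1.0, 1.0, 0.01])
        assert mean_penetration_depth(res) == pytest.approx(0.4)
        assert mean_penetration_depth(res, weighted=True) < 0.4

    def test_zero_detected_raises_with_count(self):
        with pytest.raises(InsufficientStatisticsError) as err:
            mean_penetration_depth(fake_result(0.0))
        assert err.value.n_detected == 0


class TestRelativePower:
    def test_full_detection_is_100_percent(self):
        assert relative_power(fake_result(100.0, n_photons=100)) == pytest.approx(100.0)

    def test_fraction_maps_to_percent(self):
        assert relative_power(fake_result(2.51, n_photons=100)) == pytest.approx(2.51)

    def test_standard_error_scales_with_sqrt_n(self):
        lo = power_standard_error(fake_result(1.0, n_photons=100, max_depths=[0.1]))
        hi = power_standard_error(fake_result(1.0, n_photons=10_000, max_depths=[0.1]))
        assert lo > hi


class TestAbsorbance:
    def test_log_identities(self):
        assert absorbance(fake_result(1.0, n_photons=100)) == pytest.approx(2.0)
        assert absorbance(fake_result(100.0, n_photons=100)) == pytest.approx(0.0)

    def test_round_trip_with_relative_power(self):
        res = fake_result(0.81, n_photons=100)
        assert absorbance(res) == pytest.approx(
            2.0 - math.log10(relative_power(res)), rel=1e-12
        )

    def test_zero_detection_returns_inf_sentinel(self):
        with pytest.warns(RuntimeWarning, match="zero detected"):
            assert absorbance(fake_result(0.0)) == math.inf


class TestNormalizeAbsorbance:
    def test_min_max(self):
        assert np.allclose(normalize_absorbance([1, 2, 3]), [0, 0.5, 1])

    def test_flat_curve_sentinel(self):
        assert np.allclose(normalize_absorbance([5, 5, 5]), 0.0)

    def test_preserves_order(self, rng):
        a = np.sort(rng.random(10))
        assert np.all(np.diff(normalize_absorbance(a)) >= 0)

    def test_needs_two_points(self):
        with pytest.raises(ValueError):
            normalize_absorbance([1.0])


class TestConcentrationSweep:
    def test_single_concentration_yields_one_row(self, table):
        frame = concentration_sweep(
            table, 1920, 1.0, [2.0], TransportConfig(n_photons=20_000, seed=3)
        )
        assert len(frame) == 1
        row = frame.iloc[0]
        assert row.wavelength_nm == 1920
        assert 0 <= row.relative_power_pct <= 100
        assert row.absorbance_au >= 0

    def test_empty_concentration_list_rejected(self, table):
        with pytest.raises(ValueError):
            concentration_sweep(table, 1920, 1.0, [], TransportConfig(n_photons=10))

    def test_reweight_is_identity_at_the_reference_concentration(self, table):
        from swirmc.analysis import reweight_detected_weights
        from swirmc.tissue_model import build_finger_model
        from swirmc.transport import run_simulation

        model = build_finger_model(table, 1684, 2.0)
        res = run_simulation(
            model, SensorGeometry(separation_mm=0.7), TransportConfig(n_photons=30_000, seed=3)
        )
        w = reweight_detected_weights(res, model.mu_a, model.mu_a)
        assert np.array_equal(w, res.exit_weight)

    def test_reweighted_power_matches_an_independent_simulation(self, table):
        """Scoring C=6 mmol/L on C=2 paths via the exact perturbation
        factor agrees with simulating C=6 outright."""
        cfg = TransportConfig(n_photons=60_000, seed=7)
        frame = concentration_sweep(table, 1684, 0.7, [2.0, 6.0], cfg, method="reweight")
        rerun = concentration_sweep(
            table, 1684, 0.7, [6.0], TransportConfig(n_photons=60_000, seed=99),
            method="rerun",
        )
        a, b = frame.iloc[1], rerun.iloc[0]
        combined = np.hypot(a.se_power_pct, b.se_power_pct)
        assert a.relative_power_pct == pytest.approx(
            b.relative_power_pct, abs=3 * combined
        )

    def test_reweighted_absorbance_strictly_increases_with_lactate(self, table):
        """Adding lactate adds absorption in every blood-bearing layer,
        so on shared paths the absorbance curve is exactly monotone."""
        cfg = TransportConfig(n_photons=30_000, seed=11)
        frame = concentration_sweep(table, 1650, 1.0, [1, 2, 3, 4, 5, 6], cfg)
        assert np.all(np.diff(frame.absorbance_au.to_numpy()) > 0)
        assert frame.mean_penetration_depth_mm.nunique() == 1

    def test_common_random_numbers_suppress_noise(self, table):
        """With shared seeds the absorbance difference between nearby
        concentrations is far smaller than the run-to-run MC scatter."""
        cfg = TransportConfig(n_photons=30_000, seed=101)
        frame = concentration_sweep(table, 1650, 0.7, [1.0, 6.0], cfg)
        paired_delta = abs(frame.absorbance_au.iloc[1] - frame.absorbance_au.iloc[0])
        other = concentration_sweep(
            table, 1650, 0.7, [1.0], TransportConfig(n_photons=30_000, seed=202)
        )
        independent_delta = abs(
            other.absorbance_au.iloc[0] - frame.absorbance_au.iloc[0]
        )
        assert paired_delta < independent_delta
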