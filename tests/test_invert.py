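"""Inverse Monte Carlo solver: lookup table contracts, validation,
determinism, and parameter recovery on synthetic forward data."""

import math

import numpy as np
import pandas as pd
import pytest

from tissuelight import invert, mc
from tissuelight.invert import (
    DoubleSphereInversion,
    MeasurementRecord,
    NonPhysicalMeasurementError,
    SolverConfig,
    average_replicates,
    build_lookup,
)


class TestLookupTable:
    def test_node_fractions_and_monotone_transmittance(self, lut_d12):
        assert lut_d12.Rd.shape == (6, 6)
        assert ((lut_d12.Rd >= 0) & (lut_d12.Rd <= 1)).all()
        assert ((lut_d12.Tt >= 0) & (lut_d12.Tt <= 1)).all()
        # Tt decreases with mu_a along each mu_sp column (3-SE separation
        # guaranteed here by the wide log-spaced grid)
        assert (np.diff(lut_d12.Tt, axis=0) < 0).all()

    def test_node_equals_direct_simulation(self, lut_d12, small_cfg):
        i, j = 2, 3
        stack = mc.build_slab(
            lut_d12.mu_a_grid[i], lut_d12.mu_sp_grid[j], 1.2
        )
        res = mc.simulate_rt(stack, n_photons=small_cfg.lut_n_photons,
                             seed=small_cfg.seed)
        assert lut_d12.Rd[i, j] == res.Rd
        assert lut_d12.Tt[i, j] == res.Tt

    def test_interpolation_identity_at_nodes(self, lut_d12):
        f_rd, f_tt = lut_d12.interpolators()
        i, j = 1, 4
        x = [math.log(lut_d12.mu_a_grid[i]), math.log(lut_d12.mu_sp_grid[j])]
        assert f_rd(x).item() == pytest.approx(lut_d12.Rd[i, j], rel=1e-12)
        assert f_tt(x).item() == pytest.approx(lut_d12.Tt[i, j], rel=1e-12)

    def test_degenerate_grid_rejected(self):
        with pytest.raises(ValueError):
            build_lookup(1.0, cfg=SolverConfig(lut_shape=(1, 5)))


class TestValidation:
    def test_non_physical_measurement_rejected(self):
        with pytest.raises(NonPhysicalMeasurementError):
            MeasurementRecord(635.0, 0.6, 0.5, 1.2)

    def test_negative_fractions_rejected(self):
        with pytest.raises(ValueError):
            MeasurementRecord(635.0, -0.1, 0.2, 1.2)

    def test_fit_requires_measurement_columns(self):
        with pytest.raises(ValueError, match="lacks columns"):
            DoubleSphereInversion().fit(pd.DataFrame({"wavelength_nm": [500]}))


class TestInversion:
    def test_round_trip_recovers_truth(self, lut_d12, small_cfg,
                                       ureter_635_measurement):
        meas = ureter_635_measurement
        rec = MeasurementRecord(635.0, meas.Rd, meas.Tt, 1.2)
        res = invert.invert_single(rec, lut=lut_d12, cfg=small_cfg)
        assert res.converged
        assert res.props.mu_a == pytest.approx(0.25, rel=0.10)
        assert res.props.mu_sp == pytest.approx(1.71, rel=0.10)

    def test_deterministic_given_identical_inputs(self, lut_d12, small_cfg,
                                                  ureter_635_measurement):
        meas = ureter_635_measurement
        rec = MeasurementRecord(635.0, meas.Rd, meas.Tt, 1.2)
        a = invert.invert_single(rec, lut=lut_d12, cfg=small_cfg)
        b = invert.invert_single(rec, lut=lut_d12, cfg=small_cfg)
        assert a == b

    def test_self_consistency_of_solution(self, lut_d12, small_cfg,
                                          ureter_635_measurement):
        """Re-simulating at the recovered properties reproduces the
        measured Rd/Tt within tolerance plus 3 forward SEs."""
        meas = ureter_635_measurement
        rec = MeasurementRecord(635.0, meas.Rd, meas.Tt, 1.2)
        res = invert.invert_single(rec, lut=lut_d12, cfg=small_cfg)
        stack = mc.build_slab(res.props.mu_a, res.props.mu_sp, 1.2)
        resim = mc.simulate_rt(stack, n_photons=small_cfg.n_photons_final,
                               seed=99)
        assert abs(resim.Rd - meas.Rd) <= small_cfg.tol * meas.Rd + 3 * resim.se_Rd
        assert abs(resim.Tt - meas.Tt) <= small_cfg.tol * meas.Tt + 3 * resim.se_Tt

    def test_truth_outside_grid_flagged_not_clipped(self, small_cfg):
        # truth mu_a = 8 mm^-1 lies beyond the 5 mm^-1 search bound
        stack = mc.build_slab(8.0, 2.0, 1.2)
        meas = mc.simulate_rt(stack, n_photons=100_000, seed=21)
        rec = MeasurementRecord(635.0, meas.Rd, meas.Tt, 1.2)
        cfg = SolverConfig(
            lut_shape=(6, 6), lut_n_photons=10_000, n_photons_iter=10_000,
            n_photons_final=10_000, max_iter=25,
        )
        res = invert.invert_single(rec, cfg=cfg)
        assert not res.converged  # flagged, never a silent in-range estimate
        assert res.residual > cfg.tol

    def test_boundary_recovery_pure_scatterer(self, lut_d12, small_cfg):
        """A non-absorbing sample inverts to the mu_a search floor, flagged
        as a bound solution, with mu_a at most 0.02 mm^-1."""
        stack = mc.build_slab(0.0, 2.0, 1.2)
        meas = mc.simulate_rt(stack, n_photons=200_000, seed=31)
        rec = MeasurementRecord(635.0, meas.Rd, meas.Tt, 1.2)
        res = invert.invert_single(rec, lut=lut_d12, cfg=small_cfg)
        assert res.props.mu_a <= 0.02


class TestSpectrumAggregation:
    @staticmethod
    def _fit(records, cfg):
        est = DoubleSphereInversion(
            tol=cfg.tol, max_iter=cfg.max_iter,
            n_photons_iter=cfg.n_photons_iter,
            n_photons_final=cfg.n_photons_final, lut_shape=cfg.lut_shape,
            lut_n_photons=cfg.lut_n_photons, seed=cfg.seed,
        )
        return est.fit(records)

    def test_duplicate_records_give_zero_sd(self, small_cfg,
                                            ureter_635_measurement):
        meas = ureter_635_measurement
        row = {"wavelength_nm": 635.0, "Rd": meas.Rd, "Tt": meas.Tt,
               "thickness_mm": 1.2}
        records = pd.DataFrame([row, row])
        est = self._fit(records, small_cfg)
        assert est.spectrum_["mu_a_sd"].iloc[0] == 0.0
        assert est.spectrum_["mu_sp_sd"].iloc[0] == 0.0

    def test_single_record_sd_absent(self, small_cfg, ureter_635_measurement):
        meas = ureter_635_measurement
        records = pd.DataFrame(
            [{"wavelength_nm": 635.0, "Rd": meas.Rd, "Tt": meas.Tt,
              "thickness_mm": 1.2}]
        )
        est = self._fit(records, small_cfg)
        assert len(est.results_) == 1
        assert np.isnan(est.spectrum_["mu_a_sd"].iloc[0])

    def test_sklearn_params_round_trip(self):
        est = DoubleSphereInversion(g=0.8, n=1.5)
        params = est.get_params()
        assert params["g"] == 0.8
        clone = DoubleSphereInversion(**params)
        assert clone.get_params() == params

    def test_average_replicates(self):
        df = pd.DataFrame(
            {
                "sample_id": ["a"] * 4,
                "wavelength_nm": [500.0, 500.0, 600.0, 600.0],
                "thickness_mm": [1.0] * 4,
                "replicate": [0, 1, 0, 1],
                "Rd": [0.10, 0.12, 0.20, 0.22],
                "Tt": [0.30, 0.32, 0.40, 0.42],
            }
        )
        out = average_replicates(df)
        assert len(out) == 2
        assert out.loc[out.wavelength_nm == 500.0, "Rd"].iloc[0] == pytest.approx(0.11)
        assert out.loc[out.wavelength_nm == 600.0, "Tt"].iloc[0] == pytest.approx(0.41)
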