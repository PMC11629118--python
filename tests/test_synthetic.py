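"""Chromophore basis, tissue presets, cohort generation, and the
measurement noise model."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from hypothesis import given, settings
from hypothesis import strategies as st

from tissuelight import io, mc, synthetic
from tissuelight.synthetic import (
    InstrumentConfig,
    SyntheticTissueModel,
    chromophore_basis,
    generate_cohort,
    mua_spectrum,
    musp_spectrum,
    preset,
    wavelength_grid,
)


def _local_maxima(grid, values):
    inner = (values[1:-1] > values[:-2]) & (values[1:-1] > values[2:])
    return set(grid[np.r_[False, inner, False]])


class TestChromophoreBasis:
    def test_nonnegative_and_red_tail_ordering(self):
        grid = wavelength_grid()
        basis = chromophore_basis(grid)
        assert (basis[["eps_oxy", "eps_deoxy", "eps_bilirubin"]] >= 0).all().all()
        red = basis[(basis.wavelength_nm >= 600) & (basis.wavelength_nm <= 700)]
        assert (red["eps_deoxy"] > red["eps_oxy"]).all()

    def test_support_is_enforced(self):
        with pytest.raises(ValueError):
            chromophore_basis([350.0])
        with pytest.raises(ValueError):
            mua_spectrum(preset("human_ureter"), [720.0])

    def test_grid_contains_reference_wavelengths(self):
        grid = wavelength_grid()
        for wl in synthetic.REFERENCE_WAVELENGTHS:
            assert float(wl) in grid


class TestAbsorptionModel:
    def test_zero_weights_give_flat_baseline(self):
        m = SyntheticTissueModel(0.0, 0.5, 0.0, 0.1, 1.0, 0.0, 1.0)
        mu_a = mua_spectrum(m, wavelength_grid())
        assert np.allclose(mu_a, 0.1)

    def test_linearity_in_blood_volume(self):
        grid = wavelength_grid()
        base = SyntheticTissueModel(0.01, 0.3, 0.0, 0.0, 1.0, 0.0, 1.0)
        doubled = replace(base, blood_volume_fraction=0.02)
        assert np.allclose(mua_spectrum(doubled, grid),
                           2 * mua_spectrum(base, grid))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        bvf=st.floats(0.0, 0.1),
        s=st.floats(0.0, 1.0),
        cbil=st.floats(0.0, 0.2),
        base=st.floats(0.0, 0.5),
    )
    def test_nonnegative_everywhere(self, bvf, s, cbil, base):
        m = SyntheticTissueModel(bvf, s, cbil, base, 1.0, 0.0, 1.0)
        assert (mua_spectrum(m, wavelength_grid()) >= 0).all()


class TestScatteringModel:
    def test_normalization_at_500nm(self):
        m = SyntheticTissueModel(0.0, 0.0, 0.0, 0.0, 2.6, 0.4, 1.2)
        assert musp_spectrum(m, [500.0])[0] == pytest.approx(2.6)

    def test_pure_rayleigh_limit(self):
        m = SyntheticTissueModel(0.0, 0.0, 0.0, 0.0, 1.0, 1.0, 1.0)
        v400, v500 = musp_spectrum(m, [400.0, 500.0])
        assert v400 / v500 == pytest.approx((500 / 400) ** 4, rel=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        a=st.floats(0.1, 10.0),
        f=st.floats(0.0, 1.0),
        b=st.floats(0.05, 4.0),
    )
    def test_strictly_decreasing(self, a, f, b):
        m = SyntheticTissueModel(0.0, 0.0, 0.0, 0.0, a, f, b)
        mu_sp = musp_spectrum(m, wavelength_grid())
        assert np.all(np.diff(mu_sp) < 0)


class TestPresets:
    @pytest.mark.parametrize("tissue", io.REFERENCE_TISSUES)
    def test_fidelity_within_one_sd(self, tissue, reference_table):
        """Preset spectra stay within 1 reference SD at >= 9 of the 11
        tabulated wavelengths for both coefficients."""
        t = reference_table[reference_table.tissue == tissue]
        lam = t.wavelength_nm.to_numpy(float)
        m = preset(tissue)
        ok_a = (np.abs(mua_spectrum(m, lam) - t.mu_a) <= t.mu_a_sd).sum()
        ok_s = (np.abs(musp_spectrum(m, lam) - t.mu_sp) <= t.mu_sp_sd).sum()
        assert ok_a >= 9
        assert ok_s >= 9

    @pytest.mark.parametrize(
        "tissue,expected_peaks",
        [
            ("human_ureter", {425.0, 550.0}),
            ("ureteral_carcinoma", {425.0, 550.0}),
            ("renal_pelvic_carcinoma", {425.0, 550.0}),
            ("porcine_ureter", {425.0, 550.0}),
            ("human_fat", {415.0, 540.0, 575.0}),
            ("porcine_fat", {415.0, 540.0, 575.0}),
        ],
    )
    def test_absorption_peak_locations(self, tissue, expected_peaks):
        """Deoxy-dominant tissues peak at the grid points nearest 427 and
        550 nm; oxy-dominant fat at those nearest 416, 540, and 575 nm."""
        grid = wavelength_grid()
        mu_a = mua_spectrum(preset(tissue), grid)
        assert expected_peaks <= _local_maxima(grid, mu_a)

    @pytest.mark.parametrize("tissue", io.REFERENCE_TISSUES)
    def test_preset_musp_strictly_decreasing(self, tissue):
        mu_sp = musp_spectrum(preset(tissue), wavelength_grid())
        assert np.all(np.diff(mu_sp) < 0)

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError):
            preset("liver")


class TestCohorts:
    def test_seeded_reproducibility(self):
        a = generate_cohort("human_ureter", 4, seed=11)
        b = generate_cohort("human_ureter", 4, seed=11)
        for sa, sb in zip(a, b):
            assert sa.thickness_mm == sb.thickness_mm
            pd.testing.assert_frame_equal(sa.props, sb.props)

    def test_single_sample_deterministic(self):
        a = generate_cohort("porcine_fat", 1, seed=2)[0]
        b = generate_cohort("porcine_fat", 1, seed=2)[0]
        pd.testing.assert_frame_equal(a.props, b.props)

    def test_cohort_cv_matches_reference_order(self):
        """CV of mu_sp at 635 nm across a 20-sample ureter cohort is within
        a factor of 2 of the reference 0.35/1.71 ~ 20%."""
        cohort = generate_cohort("human_ureter", 20, seed=13)
        vals = np.array(
            [
                s.props.loc[s.props.wavelength_nm == 635.0, "mu_sp"].iloc[0]
                for s in cohort
            ]
        )
        cv = vals.std(ddof=1) / vals.mean()
        target = 0.35 / 1.71
        assert target / 2 <= cv <= target * 2

    def test_every_sample_monotone_and_nonnegative(self):
        for s in generate_cohort("renal_pelvic_carcinoma", 6, seed=5):
            assert (s.props["mu_a"] >= 0).all()
            assert np.all(np.diff(s.props["mu_sp"]) < 0)
            assert s.thickness_mm >= 0.1

    def test_sample_count_validated(self):
        with pytest.raises(ValueError):
            generate_cohort("human_ureter", 0, seed=1)


class TestMeasurementNoise:
    def test_noise_disabled_returns_exact_tallies(self):
        props = pd.DataFrame(
            {"wavelength_nm": [635.0], "mu_a": [0.25], "mu_sp": [1.71]}
        )
        inst = InstrumentConfig(n_photons=20_000, n_replicates=2, noise=False)
        rec = synthetic.simulate_measurement(props, 1.2, inst, seed=4)
        assert rec["Rd"].nunique() == 1
        stack = mc.build_slab(0.25, 1.71, 1.2)
        rng = np.random.default_rng(4)
        rt = mc.simulate_rt(stack, n_photons=20_000,
                            seed=int(rng.integers(0, 2**31 - 1)))
        assert rec["Rd"].iloc[0] == rt.Rd
        assert rec["Tt"].iloc[0] == rt.Tt

    def test_calibration_error_bounded(self):
        """Replicate perturbations stay within the 0.8% calibration bound."""
        props = pd.DataFrame(
            {"wavelength_nm": [635.0], "mu_a": [0.25], "mu_sp": [1.71]}
        )
        inst = InstrumentConfig(n_photons=20_000, n_replicates=100, noise=True)
        noisy = synthetic.simulate_measurement(props, 1.2, inst, seed=4)
        clean = synthetic.simulate_measurement(
            props, 1.2, replace(inst, noise=False, n_replicates=1), seed=4
        )
        for col in ("Rd", "Tt"):
            rel = noisy[col] / clean[col].iloc[0] - 1.0
            assert (rel.abs() <= 0.008 + 1e-12).all()
            assert rel.abs().max() > 0.001  # noise actually applied
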