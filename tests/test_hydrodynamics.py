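"""SEC calibration, Siegel-Monte mass, scaling laws, Q-factor, sedimentation."""

import math

import numpy as np
import pandas as pd
import pytest

import foldstate as fs
from foldstate.hydrodynamics import ExtrapolationWarning
from foldstate.synthetic import SimulationSpec, NoiseModel, make_sec_run


class TestPartitionCoefficient:
    def test_void_and_total_limits(self):
        assert fs.partition_coefficient(8.0, 8.0, 24.0) == 0.0
        assert fs.partition_coefficient(24.0, 8.0, 24.0) == 1.0

    def test_interior_value(self):
        ve = 8.0 + 0.422 * 16.0
        assert fs.partition_coefficient(ve, 8.0, 24.0) == pytest.approx(0.422)

    def test_outside_column_warns_but_returns(self):
        with pytest.warns(ExtrapolationWarning):
            kav = fs.partition_coefficient(25.0, 8.0, 24.0)
        assert kav > 1.0

    def test_bad_volumes(self):
        with pytest.raises(ValueError):
            fs.partition_coefficient(10.0, 24.0, 8.0)


def synthetic_standards(slope=-0.8, intercept=0.9, rh=(2.0, 3.0, 4.3, 5.5, 8.5)):
    rows = []
    for i, r in enumerate(rh):
        kav = slope * math.log10(r) + intercept
        rows.append({"name": f"s{i}", "Ve_mL": 8.0 + kav * 16.0, "Rh_nm": r,
                     "mass_Da": 10 ** (3 + 0.5 * i)})
    return pd.DataFrame(rows)


class TestSECCalibration:
    def test_two_point_fit_exact(self):
        df = synthetic_standards(rh=(2.0, 8.0))
        cal = fs.calibrate_sec(df, 8.0, 24.0)
        for _, row in df.iterrows():
            kav = fs.partition_coefficient(row.Ve_mL, 8.0, 24.0)
            assert cal.fit_rh.predict(math.log10(row.Rh_nm)) == pytest.approx(kav, abs=1e-12)

    def test_zero_noise_recovers_generating_line(self):
        cal = fs.calibrate_sec(synthetic_standards(), 8.0, 24.0)
        assert cal.fit_rh.slope == pytest.approx(-0.8, abs=1e-12)
        assert cal.fit_rh.intercept == pytest.approx(0.9, abs=1e-12)
        assert cal.fit_rh.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_recovery_over_seeds(self):
        # with sigma = 0.05 mL on Ve the OLS slope stays unbiased
        slopes = []
        for seed in range(100):
            spec = SimulationSpec(seed=seed, noise=NoiseModel("gaussian_absolute", 0.05))
            df, _ = make_sec_run(
                [(f"s{i}", r, 10 ** (4 + 0.3 * i))
                 for i, r in enumerate((2.0, 3.0, 4.3, 5.5, 8.5))],
                3.4, 8.0, 24.0, (-0.8, 0.9), spec)
            cal = fs.calibrate_sec(df, 8.0, 24.0)
            slopes.append(cal.fit_rh.slope)
        assert np.mean(slopes) == pytest.approx(-0.8, abs=0.01)

    def test_too_few_standards(self):
        with pytest.raises(ValueError):
            fs.calibrate_sec(synthetic_standards(rh=(3.0,)), 8.0, 24.0)

    def test_degenerate_equal_kav(self):
        df = synthetic_standards(rh=(3.0, 3.0, 3.0))
        with pytest.raises(ValueError, match="degenerate"):
            fs.calibrate_sec(df, 8.0, 24.0)


class TestSECEstimate:
    def test_standard_kav_returns_standard_rh(self):
        df = synthetic_standards(rh=(2.0, 8.0))
        cal = fs.calibrate_sec(df, 8.0, 24.0)
        kav = fs.partition_coefficient(df.Ve_mL[0], 8.0, 24.0)
        rh, _ = fs.sec_estimate(kav, cal)
        assert rh == pytest.approx(2.0, abs=1e-9)

    def test_known_line_inversion(self):
        cal = fs.calibrate_sec(synthetic_standards(), 8.0, 24.0)
        kav = -0.8 * 0.5 + 0.9          # so log10(Rh) = 0.5
        rh, _ = fs.sec_estimate(kav, cal)
        assert rh == pytest.approx(10**0.5, rel=1e-9)

    def test_noiseless_round_trip(self):
        spec = SimulationSpec(seed=0)
        truth = [(f"s{i}", r, 10 ** (4 + 0.3 * i))
                 for i, r in enumerate((2.0, 3.0, 4.3, 5.5, 8.5))]
        df, ve = make_sec_run(truth, 3.4, 8.0, 24.0, (-0.8, 0.9), spec)
        cal = fs.calibrate_sec(df, 8.0, 24.0)
        rh, _ = fs.sec_estimate(fs.partition_coefficient(ve, 8.0, 24.0), cal)
        assert rh == pytest.approx(3.4, rel=1e-9)

    def test_extrapolation_warns(self):
        cal = fs.calibrate_sec(synthetic_standards(), 8.0, 24.0)
        with pytest.warns(ExtrapolationWarning):
            fs.sec_estimate(0.99, cal)


class TestSiegelMonte:
    def test_hand_tracked_units(self):
        # 4.2e-13 s * 6.02214e23 /mol * 6*pi*1e-3 Pa.s * 3.4e-9 m / 0.27
        # = 60.04 kg/mol = 60,037 Da
        mass = fs.siegel_monte_mass(4.2, 3.4)
        assert mass == pytest.approx(60037, rel=1e-4)

    def test_linear_in_s_and_rh(self):
        base = fs.siegel_monte_mass(4.2, 3.4)
        assert fs.siegel_monte_mass(8.4, 3.4) == pytest.approx(2 * base)
        assert fs.siegel_monte_mass(4.2, 6.8) == pytest.approx(2 * base)

    def test_halving_buoyancy_complement_doubles_mass(self):
        base = fs.siegel_monte_mass(4.2, 3.4, fs.SolventModel(buoyancy_product=0.73))
        double = fs.siegel_monte_mass(4.2, 3.4, fs.SolventModel(buoyancy_product=1 - 0.27 / 2))
        assert double == pytest.approx(2 * base)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            fs.siegel_monte_mass(-1.0, 3.4)
        with pytest.raises(ValueError):
            fs.SolventModel(buoyancy_product=1.0)


class TestConformerRh:
    def test_native_dimer_near_3nm(self):
        assert fs.conformer_rh(2 * 27551.7, "native") == pytest.approx(3.13, abs=0.02)

    def test_molten_globule_dimer_matches_observed(self):
        # the MG law at the dimer mass lands inside the measured 3.4 +/- 0.2 nm
        rh = fs.conformer_rh(2 * 27551.7, "molten_globule")
        assert 3.2 <= rh <= 3.6

    @pytest.mark.parametrize("state", fs.hydrodynamics.STATES)
    def test_power_law_doubling(self, state):
        a = fs.default_config()["scaling_laws"][state]["a"]
        ratio = fs.conformer_rh(2e5, state) / fs.conformer_rh(1e5, state)
        assert ratio == pytest.approx(2**a, rel=1e-12)

    @pytest.mark.parametrize("state", fs.hydrodynamics.STATES)
    def test_strictly_increasing_in_mass(self, state):
        masses = np.logspace(3, 6, 20)
        rh = [fs.conformer_rh(m, state) for m in masses]
        assert all(b > a for a, b in zip(rh, rh[1:]))

    def test_expanded_states_grow_faster(self):
        laws = fs.default_config()["scaling_laws"]
        assert laws["urea_unfolded"]["a"] > laws["native"]["a"]

    def test_unknown_state(self):
        with pytest.raises(ValueError, match="unknown state"):
            fs.conformer_rh(1e4, "liquid_crystal")


class TestQFactor:
    def test_paper_like_ratio(self):
        q, _ = fs.q_factor(3.5, 3.4)
        assert q == pytest.approx(1.03, abs=0.005)

    def test_equal_radii(self):
        assert fs.q_factor(3.4, 3.4)[0] == 1.0

    def test_solid_sphere_analytic(self):
        r = 7.0
        q, _ = fs.q_factor(math.sqrt(3 / 5) * r, r)
        assert q == pytest.approx(math.sqrt(0.6), abs=1e-12)
        assert fs.sphere_q_factor() == pytest.approx(0.7746, abs=1e-4)

    def test_uncertainty_quadrature(self):
        q, err = fs.q_factor(3.5, 3.4, rg_err=0.1, rh_err=0.2)
        assert err == pytest.approx(q * math.hypot(0.1 / 3.5, 0.2 / 3.4), rel=1e-12)


class TestQClassify:
    def test_pre_mg_with_mg_adjacent(self):
        members, adjacent = fs.q_classify(1.03)
        assert members == ["pre_molten_globule"]
        assert "molten_globule" in adjacent

    def test_overlapping_bands_all_returned(self):
        members, _ = fs.q_classify(0.775)
        assert set(members) == {"sphere", "globular", "molten_globule"}

    def test_random_coil(self):
        members, _ = fs.q_classify(1.51)
        assert members == ["random_coil"]

    def test_nonpositive_errors(self):
        with pytest.raises(ValueError):
            fs.q_classify(0.0)


class TestSedimentationGradient:
    STANDARDS = [(6.6, 2.8), (9.6, 4.3), (11.2, 5.1)]

    def test_standard_position_two_point(self):
        assert fs.sedimentation_from_gradient(6.6, self.STANDARDS[:2]) == pytest.approx(2.8)

    def test_midway_is_mean(self):
        mid = (6.6 + 9.6) / 2
        assert fs.sedimentation_from_gradient(mid, self.STANDARDS[:2]) == pytest.approx(
            (2.8 + 4.3) / 2)

    def test_noisy_recovery_over_seeds(self):
        from foldstate.synthetic import make_gradient_run
        estimates = []
        for seed in range(50):
            spec = SimulationSpec(seed=seed, noise=NoiseModel("gaussian_absolute", 0.1))
            table = make_gradient_run(
                [("ca", 2.8), ("bsa", 4.3), ("conalb", 5.1)], (2.0, 1.0), spec)
            estimates.append(fs.sedimentation_from_gradient(2.0 * 4.2 + 1.0, table))
        assert np.mean(estimates) == pytest.approx(4.2, abs=0.05)

    def test_non_monotone_errors(self):
        with pytest.raises(ValueError, match="monotone"):
            fs.sedimentation_from_gradient(7.0, [(6.6, 2.8), (5.0, 4.3), (11.2, 5.1)])

    def test_outside_span_warns(self):
        with pytest.warns(ExtrapolationWarning):
            fs.sedimentation_from_gradient(20.0, self.STANDARDS)


class TestCoilQFactor:
    def test_approaches_kirkwood_asymptote(self):
        # 8/(3*sqrt(pi)) = 1.5045 for an infinite Gaussian chain
        asym = 8.0 / (3.0 * math.sqrt(math.pi))
        q5 = fs.coil_q_factor(100_000)
        assert q5 == pytest.approx(asym, rel=0.005)
        assert fs.coil_q_factor(10_000) < q5 < asym
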