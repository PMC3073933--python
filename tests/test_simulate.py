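"""Poisson field generators and the biased-random-walk chemotaxis simulator."""

import math

import numpy as np
import pytest

from chemofield import (
    AgentSimConfig,
    ChemicalProfile,
    IntensityFunction,
    PointField,
    chemical_profile_value,
    count_in_interval,
    dispersion_index,
    marginal,
    partition_counts,
    rejection_bounds,
    scenario,
    simulate_chemotaxis_frames,
    simulate_homogeneous_poisson,
    simulate_inhomogeneous_poisson,
)

BAND = (1 / 3, 2 / 3)


class TestHomogeneousPoisson:
    def test_zero_intensity_gives_empty_field(self):
        assert simulate_homogeneous_poisson(0.0, seed=1).n == 0

    def test_negative_intensity_rejected(self):
        with pytest.raises(ValueError):
            simulate_homogeneous_poisson(-1.0, seed=1)

    def test_seed_reproducibility(self):
        a = simulate_homogeneous_poisson(200, seed=42)
        b = simulate_homogeneous_poisson(200, seed=42)
        np.testing.assert_array_equal(a.coords, b.coords)

    def test_count_moments_match_poisson(self):
        rng = np.random.default_rng(7)
        counts = [simulate_homogeneous_poisson(200, rng).n for _ in range(1000)]
        mean = np.mean(counts)
        # Poisson(200): mean 200, var 200 -> SE of the MC mean is sqrt(0.2)
        assert abs(mean - 200) < 3 * math.sqrt(0.2)


class TestInhomogeneousPoisson:
    def test_zero_intensity_gives_empty_field(self):
        fn = IntensityFunction(lambda x: np.zeros_like(x), lambda_max=0.0)
        assert simulate_inhomogeneous_poisson(fn, seed=1).n == 0

    def test_constant_intensity_matches_homogeneous_generator(self):
        fn = IntensityFunction(lambda x: np.full_like(x, 200.0), lambda_max=200.0)
        rng = np.random.default_rng(11)
        inhom = [simulate_inhomogeneous_poisson(fn, rng).n for _ in range(1000)]
        rng2 = np.random.default_rng(12)
        hom = [simulate_homogeneous_poisson(200, rng2).n for _ in range(1000)]
        se = math.sqrt(np.var(inhom) / 1000 + np.var(hom) / 1000)
        assert abs(np.mean(inhom) - np.mean(hom)) < 3 * se

    def test_central_third_support_concentrates_mass(self):
        # fn = 600 on the central third integrates to 200
        fn = IntensityFunction(
            lambda x: np.where((x >= BAND[0]) & (x < BAND[1]), 600.0, 0.0),
            lambda_max=600.0,
        )
        rng = np.random.default_rng(21)
        in_counts, out_counts = [], []
        for _ in range(300):
            fld = simulate_inhomogeneous_poisson(fn, rng)
            n_in = count_in_interval(fld, BAND)
            in_counts.append(n_in)
            out_counts.append(fld.n - n_in)
        assert abs(np.mean(in_counts) - 200) < 3 * math.sqrt(200 / 300)
        assert np.mean(out_counts) < 1

    def test_misdeclared_bound_rejected(self):
        fn = IntensityFunction(lambda x: np.full_like(x, 10.0), lambda_max=5.0)
        with pytest.raises(ValueError, match="exceeds lambda_max"):
            simulate_inhomogeneous_poisson(fn, seed=1)
        neg = IntensityFunction(lambda x: -np.ones_like(x), lambda_max=5.0)
        with pytest.raises(ValueError, match="negative"):
            simulate_inhomogeneous_poisson(neg, seed=1)


class TestChemicalProfile:
    def test_band_center_has_full_amplitude_and_zero_gradient(self):
        for sigma in (0.0, 0.02, 0.1, 0.3):
            p = ChemicalProfile(sigma=sigma, amplitude=2.5)
            c, g = chemical_profile_value(p, 0.5)
            assert c == pytest.approx(2.5, rel=1e-12)
            assert g == pytest.approx(0.0, abs=1e-9)

    def test_far_outside_band_is_nearly_zero(self):
        p = ChemicalProfile(sigma=0.02)
        c, _ = chemical_profile_value(p, 0.0)
        assert c < 1e-6

    def test_gradient_antisymmetric_about_center(self):
        p = ChemicalProfile(sigma=0.08)
        for d in (0.05, 0.15, 0.3):
            _, g_plus = chemical_profile_value(p, 0.5 + d)
            _, g_minus = chemical_profile_value(p, 0.5 - d)
            assert g_plus == pytest.approx(-g_minus, rel=1e-10)

    def test_sharp_indicator_when_sigma_zero(self):
        p = ChemicalProfile(sigma=0.0)
        assert chemical_profile_value(p, 0.4) == (1.0, 0.0)
        assert chemical_profile_value(p, 0.1) == (0.0, 0.0)

    def test_position_outside_domain_rejected(self):
        with pytest.raises(ValueError):
            ChemicalProfile().value(1.2)


class TestSimulatorContracts:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            AgentSimConfig(dt=0.0)
        with pytest.raises(ValueError):
            AgentSimConfig(n_steps=0)
        with pytest.raises(ValueError):
            AgentSimConfig(n_steps=10, frame_stride=11)

    def test_determinism_and_conservation(self):
        cfg = scenario("attractant", seed=5, n_steps=100)
        a = simulate_chemotaxis_frames(cfg)
        b = simulate_chemotaxis_frames(cfg)
        assert a.n_frames == b.n_frames == 6
        for (ta, fa), (tb, fb) in zip(a, b):
            assert ta == tb
            np.testing.assert_array_equal(fa.coords, fb.coords)
            assert fa.n == cfg.n_agents  # agent count conserved
            assert fa.coords.min() >= 0.0 and fa.coords.max() <= 1.0

    def test_frozen_dynamics_without_noise_or_drift(self):
        # diffusion must be positive; emulate "frozen" by making both the
        # drift and the noise negligible at double precision
        cfg = AgentSimConfig(n_agents=50, diffusion=1e-30, sensitivity=0.0,
                             dt=0.1, n_steps=50, frame_stride=10, seed=3)
        series = simulate_chemotaxis_frames(cfg)
        first = series.fields[0].coords
        for _, fld in series:
            np.testing.assert_allclose(fld.coords, first, atol=1e-12)

    def test_positions_stay_in_unit_square_under_strong_drift(self):
        cfg = AgentSimConfig(n_agents=100, diffusion=0.05, sensitivity=0.3,
                             dt=0.1, n_steps=200, frame_stride=50, seed=9)
        for _, fld in simulate_chemotaxis_frames(cfg):
            assert fld.coords.min() >= 0.0
            assert fld.coords.max() <= 1.0

    def test_msd_grows_like_2dt_before_boundaries(self):
        """Cross-axis MSD of drift-free agents matches 2*D*t within 10%
        while sqrt(2Dt) < 0.2 (middle-third start keeps walls far)."""
        D = 5e-3
        cfg = AgentSimConfig(n_agents=2000, diffusion=D, sensitivity=0.0,
                             dt=0.01, n_steps=300, frame_stride=100,
                             init="middle_third", seed=17)
        series = simulate_chemotaxis_frames(cfg)
        x0 = series.fields[0].coords[:, 0]
        for t, fld in list(series)[1:]:
            assert math.sqrt(2 * D * t) < 0.2
            msd = float(np.mean((fld.coords[:, 0] - x0) ** 2))
            assert msd == pytest.approx(2 * D * t, rel=0.10)


class TestSimulatorStatisticalStructure:
    def test_null_rejection_rate_matches_alpha(self):
        """chi=0 + uniform init: the simulator's frames are themselves
        homogeneous, so the dispersion test rejects at ~alpha.  Measured on
        the final frames of 1000 independent short runs (frames within one
        run are autocorrelated)."""
        rejections = 0
        for seed in range(1000):
            cfg = AgentSimConfig(n_agents=200, sensitivity=0.0, init="uniform",
                                 dt=0.05, n_steps=40, frame_stride=40, seed=seed)
            fld = simulate_chemotaxis_frames(cfg).fields[-1]
            stat = dispersion_index(partition_counts(marginal(fld, "cross"), 10))
            lo, hi = rejection_bounds(0.05, 10)
            rejections += not (lo <= stat <= hi)
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_attractant_and_repellent_are_mirror_experiments(self):
        """Equal |chi|: the attractant's in-band fraction rises and the
        repellent's falls, monotonically in MC mean over the transient."""
        checkpoints = [0, 4, 8, 12]  # frames at t = 0, 4, 8, 12 s
        fracs = {name: [] for name in ("attractant", "repellent")}
        for name in fracs:
            for seed in range(40):
                cfg = scenario(name, seed=seed, n_steps=240, frame_stride=20)
                series = simulate_chemotaxis_frames(cfg)
                fracs[name].append([
                    count_in_interval(marginal(series.fields[i], "cross"), BAND)
                    / cfg.n_agents
                    for i in checkpoints
                ])
        att = np.mean(fracs["attractant"], axis=0)
        rep = np.mean(fracs["repellent"], axis=0)
        assert np.all(np.diff(att) > 0)
        assert np.all(np.diff(rep) < 0)
        assert abs(scenario("attractant").sensitivity) == abs(
            scenario("repellent").sensitivity
        )


class TestScenarioPresets:
    def test_control_has_zero_sensitivity_and_central_release(self):
        cfg = scenario("control")
        assert cfg.sensitivity == 0.0
        assert cfg.init == "middle_third"

    def test_attractant_positive_repellent_negative(self):
        assert scenario("attractant").sensitivity > 0
        assert scenario("repellent").sensitivity < 0
        assert scenario("attractant").init == "uniform"

    def test_defaults_describe_the_assay(self):
        cfg = scenario("control")
        assert cfg.n_agents == 200
        assert cfg.total_time == pytest.approx(120.0)  # two-minute horizon

    def test_overrides_merge_on_top(self):
        cfg = scenario("control", n_agents=500)
        assert cfg.n_agents == 500
        assert cfg.sensitivity == 0.0  # preset untouched

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            scenario("mystery")
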