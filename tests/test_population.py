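"""Population sampler, oscillation model, Brownian motion and read synthesis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from liposort import (
    ConfigurationError,
    GenotypeSpec,
    InputError,
    OscillationState,
    PlacementError,
    PopulationConfig,
    assign_oscillation,
    brownian_step,
    generate_reads,
    make_mts_library,
    membrane_fraction,
    sample_population,
)
from liposort.population import DEFAULT_DIFFUSION_SCALE, OSCILLATORY_MODES


class TestSamplePopulation:
    def test_degenerate_mixture_all_express_single_genotype(self):
        g = GenotypeSpec(name="only", phenotype="lumen")
        cfg = PopulationConfig(components=[(g, 1.0)], p_expression=1.0,
                               liposomes_per_fov=(60, 60), n_fov=2, seed=0)
        for fov in sample_population(cfg):
            assert all(lp.genotype.name == "only" and lp.expressing for lp in fov)

    def test_bad_fractions_rejected(self):
        g = GenotypeSpec(name="a")
        with pytest.raises(ConfigurationError):
            PopulationConfig(components=[(g, 0.6), (g, 0.3)]).volume_fractions()

    def test_overcrowded_fov_raises_placement_error(self):
        g = GenotypeSpec(name="a")
        cfg = PopulationConfig(components=[(g, 1.0)], liposomes_per_fov=(200, 200),
                               n_fov=1, seed=0)
        with pytest.raises(PlacementError):
            sample_population(cfg)

    def test_mixture_fraction_within_exact_binomial_ci(self, big_mock_sample):
        """Reporter-genotype share of a 1:39 mix sits in the exact binomial 99% CI."""
        n = len(big_mock_sample)
        k = sum(lp.genotype.name == "YFP" for lp in big_mock_sample)
        lo, hi = stats.binom.ppf([0.005, 0.995], n, 1 / 40)
        assert lo <= k <= hi

    def test_expressing_reporter_share_in_one_to_two_percent_band(self, big_mock_sample):
        """With p=0.6 expression, ~1.5% of vesicles show the reporter."""
        n = len(big_mock_sample)
        k = sum(lp.expressing and lp.genotype.name == "YFP" for lp in big_mock_sample)
        assert 0.01 <= k / n <= 0.02

    def test_geometry_invariants(self, big_mock_sample):
        for lp in big_mock_sample[:5000]:
            assert 2.0 <= lp.diameter_um <= 20.0
            x, y = lp.center_um
            r = lp.radius_um
            assert r <= x <= 128.0 - r and r <= y <= 128.0 - r

    def test_minimum_spacing_respected(self):
        g = GenotypeSpec(name="a")
        cfg = PopulationConfig(components=[(g, 1.0)], liposomes_per_fov=(80, 80),
                               n_fov=1, seed=7)
        pop = sample_population(cfg)[0]
        centers = np.array([lp.center_um for lp in pop])
        radii = np.array([lp.radius_um for lp in pop])
        d = np.linalg.norm(centers[:, None] - centers[None], axis=-1)
        required = radii[:, None] + radii[None] + 1.0
        np.fill_diagonal(d, np.inf)
        assert (d >= required - 1e-9).all()


class TestOscillation:
    def test_concentrated_weights_give_static_lumen_without_period(self, rng):
        for _ in range(20):
            osc = assign_oscillation(None, {"static_lumen": 1.0}, rng)
            assert osc.mode == "static_lumen" and osc.period_s is None

    def test_mode_frequencies_within_multinomial_ci(self, rng):
        weights = {m: 1.0 for m in OSCILLATORY_MODES}
        n = 10_000
        draws = [assign_oscillation(None, weights, rng).mode for _ in range(n)]
        # simultaneous 99% CI: Bonferroni over the three binomial margins
        lo, hi = stats.binom.ppf([0.005 / 3, 1 - 0.005 / 3], n, 1 / 3)
        for m in OSCILLATORY_MODES:
            assert lo <= draws.count(m) <= hi

    def test_periods_within_stated_range(self, rng):
        for _ in range(200):
            osc = assign_oscillation(None, {"pulsing": 1, "circling": 1}, rng)
            assert 15.0 <= osc.period_s <= 45.0
            assert 0.0 <= osc.phase < 2 * math.pi

    def test_negative_weight_rejected(self, rng):
        with pytest.raises(ConfigurationError):
            assign_oscillation(None, {"pulsing": -0.1, "circling": 1.1}, rng)

    def test_period_presence_matches_mode(self):
        with pytest.raises(ConfigurationError):
            OscillationState(mode="pulsing")  # oscillatory without period
        with pytest.raises(ConfigurationError):
            OscillationState(mode="static_lumen", period_s=20.0)


class TestMembraneFraction:
    def test_static_lumen_constant(self):
        osc = OscillationState(mode="static_lumen")
        for t in (0.0, 3.0, 1e4):
            m, _ = membrane_fraction(osc, t)
            assert m == 0.05

    def test_pulsing_square_wave_closed_form(self):
        osc = OscillationState(mode="pulsing", period_s=24.0, phase=0.0)
        values = [membrane_fraction(osc, t)[0] for t in (0, 12, 24, 36, 48)]
        assert values == [0.9, 0.1, 0.9, 0.1, 0.9]

    def test_pole_to_pole_cap_flips_by_pi_each_half_period(self):
        osc = OscillationState(mode="pole_to_pole", period_s=30.0, phase=0.0,
                               axis_angle=1.0)
        theta = np.linspace(0, 2 * math.pi, 720, endpoint=False)
        _, prof_a = membrane_fraction(osc, 3.0)
        _, prof_b = membrane_fraction(osc, 3.0 + 15.0)
        peak_a = theta[np.argmax(prof_a(theta))]
        peak_b = theta[np.argmax(prof_b(theta))]
        diff = abs(peak_a - peak_b) % (2 * math.pi)
        assert diff == pytest.approx(math.pi, abs=0.02)

    @pytest.mark.parametrize("mode", OSCILLATORY_MODES)
    def test_periodicity(self, mode, rng):
        for _ in range(20):
            osc = OscillationState(mode=mode, period_s=float(rng.uniform(15, 45)),
                                   phase=float(rng.uniform(0, 2 * math.pi)),
                                   axis_angle=float(rng.uniform(0, 2 * math.pi)))
            t = float(rng.uniform(0, 100))
            m1, p1 = membrane_fraction(osc, t)
            m2, p2 = membrane_fraction(osc, t + osc.period_s)
            assert abs(m1 - m2) < 1e-9
            theta = np.linspace(0, 2 * math.pi, 32, endpoint=False)
            assert np.allclose(p1(theta), p2(theta), atol=1e-9)

    def test_angular_profile_mean_is_one(self):
        osc = OscillationState(mode="circling", period_s=20.0, phase=0.5, axis_angle=2.0)
        _, prof = membrane_fraction(osc, 7.0)
        theta = np.linspace(0, 2 * math.pi, 100_000, endpoint=False)
        assert prof(theta).mean() == pytest.approx(1.0, abs=1e-4)


class TestBrownian:
    def test_zero_scale_keeps_center(self, rng):
        assert brownian_step((10.0, 20.0), 10.0, 0.0, rng) == (10.0, 20.0)

    def test_mean_displacement_matches_rayleigh_closed_form(self, rng):
        """Default scale gives 0.5 um mean planar displacement over 10 s."""
        n = 10_000
        start = np.array([64.0, 64.0])
        disp = np.array([
            np.hypot(*(np.array(brownian_step((64.0, 64.0), 10.0,
                                              DEFAULT_DIFFUSION_SCALE, rng)) - start))
            for _ in range(n)
        ])
        s = DEFAULT_DIFFUSION_SCALE * math.sqrt(10.0)
        expected = s * math.sqrt(math.pi / 2.0)
        assert expected == pytest.approx(0.5, abs=1e-12)
        se = math.sqrt((2 - math.pi / 2) * s**2 / n)
        assert abs(disp.mean() - 0.5) < 3 * se
        # full distributional check, far from the reflecting boundary
        ks = stats.kstest(disp, stats.rayleigh(scale=s).cdf)
        assert ks.pvalue > 0.01

    def test_reflection_keeps_centers_inside(self, rng):
        c = (0.3, 127.8)
        for _ in range(500):
            c = brownian_step(c, 10.0, 1.0, rng)
            assert 0.0 <= c[0] <= 128.0 and 0.0 <= c[1] <= 128.0

    def test_nonpositive_dt_rejected(self, rng):
        with pytest.raises(InputError):
            brownian_step((1.0, 1.0), 0.0, 0.1, rng)


class TestGenerateReads:
    def test_zero_reads_empty(self, rng):
        assert generate_reads({"Var1": 1.0}, 0, rng=rng) == []

    def test_unknown_variant_rejected(self, rng):
        with pytest.raises(InputError):
            generate_reads({"nope": 1.0}, 10, rng=rng)

    def test_even_pool_recovered_within_binomial_ci(self, rng):
        from liposort.quantify import MtsExtractor, count_variants

        lib = make_mts_library()
        reads = generate_reads({"Var1": 0.5, "Var7": 0.5}, 1000, error_rate=0.0,
                               length_model={"sd_bp": 0.0}, rng=rng, library=lib)
        ex = MtsExtractor(left_flank=lib.left_flank, right_flank=lib.right_flank)
        counts, qc = count_variants(reads, ex)
        assert qc["extracted"] == 1000
        lo, hi = stats.binom.ppf([0.005, 0.995], 1000, 0.5)
        assert lo <= counts[lib.variants["Var1"]] <= hi

    def test_junk_reads_removed_by_length_filter(self, rng):
        from liposort.quantify import filter_reads

        reads = generate_reads({"Var1": 1.0}, 1000, rng=rng, junk_fraction=0.2)
        kept = filter_reads(reads, (1100, 1400))
        removed = 1000 - len(kept)
        lo, hi = stats.binom.ppf([0.005, 0.995], 1000, 0.2)
        assert lo <= removed <= hi

    def test_fastq_round_trip(self, rng, tmp_path):
        from liposort.population import write_fastq
        from liposort.quantify import read_fastq

        reads = generate_reads({"Var1": 1.0}, 5, rng=rng)
        path = tmp_path / "r.fastq"
        assert write_fastq(reads, path) == 5
        back = read_fastq(path)
        assert [str(r.seq) for r in back] == [str(r.seq) for r in reads]


@given(phase=st.floats(0, 2 * math.pi), t=st.floats(0, 500),
       period=st.floats(15, 45))
@settings(max_examples=50, deadline=None)
def test_membrane_fraction_bounds_property(phase, t, period):
    """m always lies in [0, 1] for every mode, phase and time."""
    for mode in ("pulsing", "pole_to_pole", "circling"):
        osc = OscillationState(mode=mode, period_s=period, phase=phase)
        m, _ = membrane_fraction(osc, t)
        assert 0.0 <= m <= 1.0
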