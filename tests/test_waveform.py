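import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from opwf.errors import (
    DegeneratePhaseError,
    DomainError,
    SynchronizationError,
    UnderdeterminedFitError,
)
from opwf.synthetic import PulseTemplateSpec, make_pulse_template, triangular_closed_form
from opwf.waveform import (
    CardiacCycleWaveform,
    Extrema,
    acceleration_time_index,
    blowout_score,
    blowout_time,
    compute_pwf,
    falling_rate,
    fit_quadratic,
    flow_acceleration_index,
    resistivity_index,
    rising_rate,
    s1_area,
    s2_area,
    subdivide_waveform,
    synchronize_cycles,
    waveform_extrema,
)

from conftest import make_cycle


def cycle_from(values, f=1.0):
    return CardiacCycleWaveform(samples=np.asarray(values, dtype=float), f=f)


# ---------------------------------------------------------------------------
# synchronize_cycles
# ---------------------------------------------------------------------------

class TestSynchronizeCycles:
    def test_offset_sinusoid_recovers_period_and_extrema(self):
        fs, period = 30.0, 0.3
        t = np.arange(int(4 * fs)) / fs
        series = 35.0 + 5.0 * np.sin(2 * np.pi * t / period)
        cycle = synchronize_cycles(series, fs, n_out=30)
        assert cycle.f == pytest.approx(period, abs=0.02)
        assert cycle.samples.max() == pytest.approx(40.0, abs=0.3)
        assert cycle.samples.min() == pytest.approx(30.0, abs=0.3)

    def test_identical_triangular_cycles_average_to_template(self):
        spec = PulseTemplateSpec(dc=35, ac=10, rise_fraction=0.5, n_frames=30)
        template = make_pulse_template(spec)
        series = np.tile(template, 3)
        cycle = synchronize_cycles(series, frame_rate_hz=30.0, n_out=30, smooth_sigma=0.0)
        # one complete onset-to-onset segment reproduces the template
        np.testing.assert_allclose(cycle.samples, template, atol=1e-6)
        assert cycle.f == pytest.approx(1.0, abs=1e-9)

    def test_constant_series_raises(self):
        with pytest.raises(SynchronizationError):
            synchronize_cycles(np.full(120, 35.0), 30.0)

    def test_single_cycle_raises(self):
        t = np.arange(40) / 40
        with pytest.raises(SynchronizationError):
            synchronize_cycles(35 + 5 * np.sin(2 * np.pi * t), 40.0)


# ---------------------------------------------------------------------------
# extrema and scalar indices
# ---------------------------------------------------------------------------

class TestExtrema:
    def test_direct_scan(self):
        ex = waveform_extrema(cycle_from([30, 35, 40, 35, 30]))
        assert ex.mbr_max == 40
        assert ex.mbr_min == 30
        assert ex.ac == 10
        assert ex.dc == pytest.approx(34.0)  # 170 / 5

    def test_constant(self):
        ex = waveform_extrema(cycle_from([35] * 10))
        assert ex.ac == 0
        assert ex.dc == 35

    def test_template_amplitude(self):
        spec = PulseTemplateSpec(dc=35, ac=10, rise_fraction=0.5, n_frames=100)
        ex = waveform_extrema(make_cycle(spec))
        assert ex.ac == pytest.approx(10.0, abs=1e-9)

    def test_t_peak_is_first_max_on_plateau(self):
        ex = waveform_extrema(cycle_from([30, 40, 40, 40, 30, 30, 30, 30], f=8.0))
        assert ex.t_peak == pytest.approx(1.0)


class TestBlowoutScore:
    def test_zero_amplitude_limit(self):
        assert blowout_score(Extrema(35, 35, 0, 35, 0.0)) == pytest.approx(200.0)

    def test_ac_equals_dc(self):
        assert blowout_score(Extrema(40, 0, 35, 35, 0.2)) == pytest.approx(100.0)

    def test_direct_arithmetic(self):
        assert blowout_score(Extrema(45, 35, 10, 40, 0.2)) == pytest.approx(175.0)

    def test_nonpositive_dc_raises(self):
        with pytest.raises(DomainError):
            blowout_score(Extrema(1, 0, 1, 0.0, 0.1))


class TestBlowoutTime:
    def test_symmetric_triangle_half_width(self, tri_cycle_1000):
        ex = waveform_extrema(tri_cycle_1000)
        w, bot = blowout_time(tri_cycle_1000, ex)
        assert bot == pytest.approx(50.0, abs=0.2)
        assert w == pytest.approx(0.5, abs=0.002)

    def test_constant_cycle_convention(self):
        cycle = cycle_from([35] * 20, f=2.0)
        w, bot = blowout_time(cycle, waveform_extrema(cycle))
        assert (w, bot) == (2.0, 100.0)

    def test_rectangular_pulse_crossings(self):
        # oracle: analytic crossing times of the piecewise-linear pulse;
        # high plateau of 60/200 samples plus two half-sample crossing legs
        n = 200
        samples = np.full(n, 30.0)
        samples[70:130] = 40.0
        cycle = cycle_from(samples, f=1.0)
        _, bot = blowout_time(cycle, waveform_extrema(cycle))
        assert bot == pytest.approx(30.0, abs=100.0 / n)


class TestSubdivision:
    def test_triangular_areas(self, tri_cycle_1000):
        areas = subdivide_waveform(tri_cycle_1000, waveform_extrema(tri_cycle_1000))
        assert areas.s1_under == pytest.approx(17.5, rel=1e-3)
        assert areas.rise_above == pytest.approx(2.5, rel=1e-2)
        assert areas.fall_under == pytest.approx(17.5, rel=1e-3)
        assert areas.fall_above == pytest.approx(2.5, rel=1e-2)

    def test_constant_cycle_degenerate(self):
        cycle = cycle_from([35] * 10)
        with pytest.raises(DegeneratePhaseError):
            subdivide_waveform(cycle, waveform_extrema(cycle))

    def test_partition_identity_gamma(self):
        spec = PulseTemplateSpec(dc=35, ac=10, rise_fraction=0.3, shape="gamma_like", n_frames=200)
        cycle = make_cycle(spec)
        ex = waveform_extrema(cycle)
        areas = subdivide_waveform(cycle, ex)
        assert areas.s1_under + areas.rise_above == pytest.approx(
            areas.t_peak * ex.mbr_max, rel=1e-12
        )
        assert areas.fall_under + areas.fall_above == pytest.approx(
            (cycle.f - areas.t_peak) * ex.mbr_max, rel=1e-12
        )


class TestRates:
    def test_rising_rate_triangular(self, tri_cycle_1000):
        areas = subdivide_waveform(tri_cycle_1000, waveform_extrema(tri_cycle_1000))
        assert rising_rate(areas) == pytest.approx(25 * 17.5 / 2.5, rel=0.01)

    def test_balance_point(self):
        areas_kwargs = dict(t_peak=0.5, f=1.0, mbr_max=40.0, fall_under=1.0, fall_above=1.0, w=0.5)
        from opwf.waveform import WaveformAreas

        areas = WaveformAreas(s1_under=2.0, rise_above=2.0, **areas_kwargs)
        assert rising_rate(areas) == pytest.approx(25.0)
        assert falling_rate(areas) == pytest.approx(25.0)

    def test_falling_rate_triangular(self, tri_cycle_1000):
        areas = subdivide_waveform(tri_cycle_1000, waveform_extrema(tri_cycle_1000))
        assert falling_rate(areas) == pytest.approx(25 * 2.5 / 17.5, rel=0.01)

    def test_steeper_rise_increases_rr(self):
        # oracle: numeric areas on two templates differing only in rise time
        def rr_of(rise):
            spec = PulseTemplateSpec(dc=35, ac=10, rise_fraction=rise, shape="gamma_like", n_frames=400)
            cycle = make_cycle(spec)
            return rising_rate(subdivide_waveform(cycle, waveform_extrema(cycle)))

        assert rr_of(0.2) > rr_of(0.4)

    def test_sharper_fall_increases_fr(self):
        def fr_of(rise):
            spec = PulseTemplateSpec(dc=35, ac=10, rise_fraction=rise, n_frames=400)
            cycle = make_cycle(spec)
            return falling_rate(subdivide_waveform(cycle, waveform_extrema(cycle)))

        # later peak -> shorter fall; FR is scale-free in fall duration for
        # triangles, so compare gamma templates instead
        def fr_gamma(rise):
            spec = PulseTemplateSpec(dc=35, ac=10, rise_fraction=rise, shape="gamma_like", n_frames=400)
            cycle = make_cycle(spec)
            return falling_rate(subdivide_waveform(cycle, waveform_extrema(cycle)))

        assert fr_gamma(0.6) > fr_gamma(0.2)


class TestScalarIndices:
    def test_fai_direct(self):
        assert flow_acceleration_index(cycle_from([30, 34, 40, 38, 33, 30])) == 6.0

    def test_fai_constant(self):
        assert flow_acceleration_index(cycle_from([35] * 10)) == 0.0

    def test_fai_affine_equivariance(self):
        base = np.array([30, 34, 40, 38, 33, 30], dtype=float)
        scaled = flow_acceleration_index(cycle_from(2.0 * base + 5.0))
        assert scaled == pytest.approx(2.0 * 6.0)

    def test_ati_symmetric(self, tri_cycle_1000):
        ex = waveform_extrema(tri_cycle_1000)
        assert acceleration_time_index(tri_cycle_1000, ex) == pytest.approx(50.0, abs=0.2)

    def test_ati_rise_fraction(self):
        n = 200
        spec = PulseTemplateSpec(dc=35, ac=10, rise_fraction=0.3, n_frames=n)
        cycle = make_cycle(spec)
        ex = waveform_extrema(cycle)
        assert acceleration_time_index(cycle, ex) == pytest.approx(30.0, abs=100.0 / n)

    def test_ati_first_interior_peak(self):
        n = 10
        cycle = cycle_from([30, 40, 35, 34, 33, 32, 31, 30, 30, 30])
        ex = waveform_extrema(cycle)
        assert acceleration_time_index(cycle, ex) == pytest.approx(100.0 / n)

    @pytest.mark.parametrize(
        "mx, mn, expected", [(40, 30, 0.25), (40, 40, 0.0), (40, 0, 1.0)]
    )
    def test_ri(self, mx, mn, expected):
        ex = Extrema(mbr_max=mx, mbr_min=mn, ac=mx - mn, dc=(mx + mn) / 2, t_peak=0.5)
        assert resistivity_index(ex) == pytest.approx(expected)

    def test_ri_domain_error(self):
        with pytest.raises(DomainError):
            resistivity_index(Extrema(0, 0, 0, 0, 0.0))


# ---------------------------------------------------------------------------
# quadratic fit and S1/S2
# ---------------------------------------------------------------------------

class TestQuadraticFit:
    def test_exact_quadratic(self):
        t = np.linspace(0, 1, 50)
        fit = fit_quadratic(t, t**2)
        assert fit.a == pytest.approx(1.0, abs=1e-9)
        assert fit.b == pytest.approx(0.0, abs=1e-9)
        assert fit.c == pytest.approx(0.0, abs=1e-9)
        assert fit.rmse == pytest.approx(0.0, abs=1e-9)

    def test_exact_linear(self):
        t = np.linspace(0, 1, 20)
        fit = fit_quadratic(t, 30 + 20 * t)
        assert fit.a == pytest.approx(0.0, abs=1e-8)
        assert fit.b == pytest.approx(20.0, abs=1e-8)
        assert fit.c == pytest.approx(30.0, abs=1e-8)

    def test_noisy_quadratic_within_3_se(self):
        # oracle: normal-equations solve plus classical coefficient SEs
        rng = np.random.default_rng(42)
        t = np.linspace(0, 1, 50)
        y = 2.0 * t**2 - 1.0 * t + 3.0 + rng.normal(0, 0.1, t.size)
        design = np.column_stack([t**2, t, np.ones_like(t)])
        coef = np.linalg.solve(design.T @ design, design.T @ y)
        resid = y - design @ coef
        sigma2 = resid @ resid / (t.size - 3)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(design.T @ design)))
        fit = fit_quadratic(t, y)
        np.testing.assert_allclose([fit.a, fit.b, fit.c], coef, rtol=1e-9)
        for got, truth, s in zip((fit.a, fit.b, fit.c), (2.0, -1.0, 3.0), se):
            assert abs(got - truth) < 3 * s

    def test_underdetermined(self):
        with pytest.raises(UnderdeterminedFitError):
            fit_quadratic([0.0, 1.0], [1.0, 2.0])
        with pytest.raises(UnderdeterminedFitError):
            fit_quadratic([0.0, 0.0, 0.0], [1.0, 2.0, 3.0])

    def test_polynomial_integrals(self):
        t = np.linspace(0, 0.5, 20)
        fit = fit_quadratic(t, 30 + 20 * t)
        assert fit.integral(0.0, 0.5) == pytest.approx(17.5, rel=1e-9)
        t = np.linspace(0, 1, 20)
        assert fit_quadratic(t, t**2).integral(0.0, 1.0) == pytest.approx(1 / 3, rel=1e-9)


class TestLimbAreas:
    def test_s1_triangular(self, tri_cycle_1000):
        ex = waveform_extrema(tri_cycle_1000)
        assert s1_area(tri_cycle_1000, ex) == pytest.approx(17.5, rel=0.01)

    def test_s2_triangular(self, tri_cycle_1000):
        ex = waveform_extrema(tri_cycle_1000)
        areas = subdivide_waveform(tri_cycle_1000, ex)
        fr = falling_rate(areas)
        assert fr == pytest.approx(25 / 7, rel=0.01)
        assert s2_area(tri_cycle_1000, ex, fr) == pytest.approx(2.5, rel=0.01)

    def test_s2_equals_fall_under_when_fr_is_c(self, tri_cycle_1000):
        ex = waveform_extrema(tri_cycle_1000)
        areas = subdivide_waveform(tri_cycle_1000, ex)
        s2 = s2_area(tri_cycle_1000, ex, fr=25.0)
        assert s2 == pytest.approx(areas.fall_under, rel=1e-3)

    def test_s1_gamma_matches_trapezoid_within_5pc(self):
        spec = PulseTemplateSpec(dc=35, ac=10, rise_fraction=0.3, shape="gamma_like", n_frames=150)
        cycle = make_cycle(spec)
        ex = waveform_extrema(cycle)
        areas = subdivide_waveform(cycle, ex)
        assert s1_area(cycle, ex) == pytest.approx(areas.s1_under, rel=0.05)

    def test_s2_decreases_with_more_gradual_fall(self):
        # oracle: numeric areas on two cycles identical except for the
        # exponential decay constant of the falling limb
        def s2_of(tau):
            n, t_peak = 300, 0.3
            t = np.arange(n) / n
            y = np.where(
                t <= t_peak,
                30.0 + 10.0 * t / t_peak,
                30.0 + 10.0 * np.exp(-(t - t_peak) / tau),
            )
            cycle = cycle_from(y)
            ex = waveform_extrema(cycle)
            areas = subdivide_waveform(cycle, ex)
            return s2_area(cycle, ex, falling_rate(areas))

        sharp, gradual = s2_of(0.05), s2_of(0.5)
        assert gradual >= 0
        assert gradual < sharp


# ---------------------------------------------------------------------------
# compute_pwf
# ---------------------------------------------------------------------------

class TestComputePWF:
    def test_triangular_closed_forms(self, tri_spec_1000, tri_cycle_1000):
        params = compute_pwf(tri_cycle_1000)
        truth = triangular_closed_form(tri_spec_1000, f=1.0)
        for key, expected in truth.items():
            assert getattr(params, key if key != "mbr" else "mbr") == pytest.approx(
                expected, rel=0.01
            ), key

    def test_constant_cycle_names_degeneracy(self):
        with pytest.raises(DegeneratePhaseError, match="subdivision|peak"):
            compute_pwf(cycle_from([35] * 20))

    def test_homogeneity_under_amplitude_scaling(self, tri_cycle_1000):
        p1 = compute_pwf(tri_cycle_1000)
        p2 = compute_pwf(
            CardiacCycleWaveform(samples=2.0 * tri_cycle_1000.samples, f=tri_cycle_1000.f)
        )
        for name in ("mbr", "mbr_max", "mbr_min", "ac", "fai", "s1_area", "s2_area"):
            assert getattr(p2, name) == pytest.approx(2.0 * getattr(p1, name), rel=1e-9)
        for name in ("bos", "bot", "ri", "rr", "fr", "ati", "w"):
            assert getattr(p2, name) == pytest.approx(getattr(p1, name), rel=1e-9)

    def test_internal_identities(self, tri_cycle_1000):
        p = compute_pwf(tri_cycle_1000)
        assert p.ri == pytest.approx(p.ac / p.mbr_max, rel=1e-12)
        assert p.bos == pytest.approx(200 - 100 * p.ac / p.mbr, rel=1e-12)
        assert p.bot == pytest.approx(100 * p.w / p.f, rel=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(
        ac=hst.floats(min_value=1.0, max_value=18.0),
        dc=hst.floats(min_value=20.0, max_value=60.0),
    )
    def test_monotonicity_bos_ri_in_ac(self, ac, dc):
        spec_hi = PulseTemplateSpec(dc=dc, ac=ac, rise_fraction=0.5, n_frames=64)
        spec_lo = PulseTemplateSpec(dc=dc, ac=ac * 0.5, rise_fraction=0.5, n_frames=64)
        p_hi = compute_pwf(make_cycle(spec_hi))
        p_lo = compute_pwf(make_cycle(spec_lo))
        assert p_lo.bos > p_hi.bos
        assert p_lo.ri < p_hi.ri
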