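"""Two-site exchange lineshape simulation and peak measurement."""

import math

import numpy as np
import pytest

from mbdex.errors import InvalidInputError
from mbdex.lineshape import (
    SpinSystem,
    Spectrum,
    classify_regime,
    default_grid,
    measure_peaks,
    min_fast_exchange_rate,
    population_from_shift,
    simulate_lineshape,
)


def make_sys(**kw):
    base = dict(nu_a=-50.0, nu_b=50.0, r2_a=50.0, r2_b=50.0, p_a=0.5, k_ex=0.0)
    base.update(kw)
    return SpinSystem(**base)


class TestSimulate:
    def test_exchange_free_limit_is_lorentzian(self):
        sys_ = make_sys(p_a=1.0, k_ex=0.0)
        peaks = measure_peaks(simulate_lineshape(sys_))
        assert len(peaks) == 1
        assert peaks[0].position == pytest.approx(-50.0, abs=0.05)
        assert peaks[0].fwhm == pytest.approx(50.0 / math.pi, rel=0.01)

    def test_fast_limit_single_averaged_peak(self):
        sys_ = make_sys(k_ex=1e6)
        spec = simulate_lineshape(sys_)
        peaks = measure_peaks(spec)
        assert peaks[0].n_maxima == 1
        step = spec.freqs[1] - spec.freqs[0]
        assert abs(peaks[0].position - 0.0) < step
        assert peaks[0].fwhm == pytest.approx(50.0 / math.pi, rel=0.05)

    def test_fast_limit_asymmetric_population_position(self):
        sys_ = make_sys(p_a=0.38, k_ex=1e6)
        spec = simulate_lineshape(sys_)
        peaks = measure_peaks(spec)
        expected = 0.38 * -50.0 + 0.62 * 50.0
        step = spec.freqs[1] - spec.freqs[0]
        assert abs(peaks[0].position - expected) < step

    def test_slow_limit_two_peaks_at_site_frequencies(self):
        sys_ = make_sys(r2_a=20.0, r2_b=20.0, k_ex=0.1 * 2 * math.pi * 100.0)
        spec = simulate_lineshape(sys_)
        peaks = measure_peaks(spec)
        assert peaks[0].n_maxima == 2
        step = spec.freqs[1] - spec.freqs[0]
        pos = sorted(p.position for p in peaks)
        # exchange pulls the two maxima slightly toward each other
        assert abs(pos[0] - -50.0) < 5 * step and abs(pos[1] - 50.0) < 5 * step

    def test_slow_limit_width_is_r2_plus_kout(self):
        k_ex = 10.0  # very slow vs delta_omega = 2*pi*100
        sys_ = make_sys(r2_a=30.0, r2_b=30.0, k_ex=k_ex)
        peaks = measure_peaks(simulate_lineshape(sys_, default_grid(sys_, n=16384)))
        expected = (30.0 + 0.5 * k_ex) / math.pi  # k_out = k_ex * p = 5 s^-1
        for p in peaks:
            assert p.fwhm == pytest.approx(expected, rel=0.02)

    def test_area_conserved_across_kex_sweep(self):
        areas = []
        for k_ex in [0.0, 10.0, 100.0, 628.0, 5000.0, 1e6]:
            sys_ = make_sys(k_ex=k_ex)
            grid = default_grid(sys_, n=8192, pad=60.0)
            areas.append(simulate_lineshape(sys_, grid).area)
        assert np.allclose(areas, 1.0, atol=0.01)

    def test_fwhm_monotone_decreasing_in_fast_regime(self):
        widths = []
        for k_ex in [5e3, 1e4, 3e4, 1e5, 1e6]:
            sys_ = make_sys(k_ex=k_ex)
            widths.append(measure_peaks(simulate_lineshape(sys_))[0].fwhm)
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_grid_must_cover_resonances(self):
        with pytest.raises(InvalidInputError):
            simulate_lineshape(make_sys(), np.linspace(-20.0, 20.0, 256))


class TestMeasure:
    def test_scale_invariance(self):
        spec = simulate_lineshape(make_sys(k_ex=1e6))
        scaled = Spectrum(freqs=spec.freqs, intensity=spec.intensity * 123.4)
        for p, q in zip(measure_peaks(spec), measure_peaks(scaled)):
            assert p.position == pytest.approx(q.position, abs=1e-9)
            assert p.fwhm == pytest.approx(q.fwhm, abs=1e-9)
            assert p.n_maxima == q.n_maxima

    def test_symmetric_doublet_positions_mirror(self):
        spec = simulate_lineshape(make_sys(r2_a=20.0, r2_b=20.0, k_ex=30.0))
        pos = sorted(p.position for p in measure_peaks(spec))
        assert pos[0] == pytest.approx(-pos[1], abs=0.1)

    def test_flat_spectrum_rejected(self):
        grid = np.linspace(-100, 100, 64)
        with pytest.raises(InvalidInputError):
            measure_peaks(Spectrum(freqs=grid, intensity=np.ones_like(grid)))


class TestPopulation:
    def test_reported_occupancy_readoff(self):
        # a peak 62% of the way from site A to site B means 62% occupancy of B
        est = population_from_shift(0.62, 0.0, 1.0)
        assert est.fraction == pytest.approx(0.62)
        assert est.in_range

    @pytest.mark.parametrize("obs,expected", [(10.0, 0.0), (15.0, 0.5)])
    def test_endpoints_and_midpoint(self, obs, expected):
        assert population_from_shift(obs, 10.0, 20.0).fraction == pytest.approx(expected)

    def test_out_of_range_flagged(self):
        est = population_from_shift(25.0, 10.0, 20.0)
        assert est.fraction == pytest.approx(1.5)
        assert not est.in_range

    def test_degenerate_references_rejected(self):
        with pytest.raises(InvalidInputError):
            population_from_shift(1.0, 5.0, 5.0)

    def test_round_trip_through_fast_limit_simulation(self):
        sys_ = make_sys(p_a=0.38, k_ex=1e6)
        spec = simulate_lineshape(sys_)
        pos = measure_peaks(spec)[0].position
        est = population_from_shift(pos, sys_.nu_a, sys_.nu_b)
        step = (spec.freqs[1] - spec.freqs[0]) / (sys_.nu_b - sys_.nu_a)
        assert est.fraction == pytest.approx(0.62, abs=step)


class TestRegime:
    def test_slow_fast_labels(self):
        assert classify_regime(make_sys(nu_a=0, nu_b=80, k_ex=25.0)) == "slow"
        assert classify_regime(make_sys(nu_a=0, nu_b=80, k_ex=1e4)) == "fast"

    def test_coalescence_is_intermediate(self):
        sys_ = make_sys(nu_a=0, nu_b=80)
        k_c = sys_.delta_omega / math.sqrt(2)
        assert classify_regime(make_sys(nu_a=0, nu_b=80, k_ex=k_c)) == "intermediate"

    def test_degenerate_frequencies_warn_fast(self):
        with pytest.warns(UserWarning):
            assert classify_regime(make_sys(nu_b=-50.0, k_ex=1.0)) == "fast"

    def test_min_fast_exchange_rate(self):
        k_min = min_fast_exchange_rate(80.0, ratio=5.0)
        assert k_min == pytest.approx(2513.0, rel=1e-3)
        assert 1.0 / k_min == pytest.approx(0.000398, rel=1e-2)
        assert min_fast_exchange_rate(80.0, ratio=1.0) == pytest.approx(
            2 * math.pi * 80.0
        )
        assert min_fast_exchange_rate(160.0) == pytest.approx(2 * k_min)
        with pytest.raises(InvalidInputError):
            min_fast_exchange_rate(0.0)
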