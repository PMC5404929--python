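import numpy as np
import pytest

from snarepore import (
    CurrentTrace,
    averaged_pdf,
    conductance_from_radius,
    detect_bursts,
    detect_flickers,
    energy_from_pdf,
    fit_burst_exponential,
    fit_flicker_geometric,
    geometric_mean_flickers,
    nucleation_rate,
    pore_record,
    preprocess,
    radius_from_conductance,
)
from snarepore.traces import ProcessedTrace

RATE = 20000.0
DT125 = 1 / 125.0


def make_processed(samples):
    return ProcessedTrace(
        samples=np.asarray(samples, dtype=float),
        rate=125.0,
        driving_mv=16.0,
        resistivity=0.60,
    )


def square_pulse_trace(level_pa, start_s, dur_s, total_s=10.0, rate=RATE):
    x = np.zeros(int(total_s * rate))
    i0, i1 = int(start_s * rate), int((start_s + dur_s) * rate)
    x[i0:i1] = level_pa
    return CurrentTrace(samples=x, rate=rate)


class TestPreprocess:
    def test_dc_preserved(self):
        trace = CurrentTrace(samples=np.full(40000, -3.7), rate=RATE)
        p = preprocess(trace)
        assert p.rate == pytest.approx(RATE / 80)
        assert np.allclose(p.samples, -3.7, atol=1e-9)

    def test_line_noise_notch_attenuation(self):
        t = np.arange(int(4 * RATE)) / RATE
        hum = 2.0 * np.sin(2 * np.pi * 60.0 * t)
        p_without = preprocess(CurrentTrace(samples=hum, rate=RATE))
        p_with = preprocess(CurrentTrace(samples=hum, rate=RATE), notch_hz=(60.0,))
        # > 20 dB amplitude attenuation relative to the un-notched chain
        mid = slice(50, -50)  # avoid filter edge transients
        assert (
            np.std(p_with.samples[mid]) < 0.1 * np.std(p_without.samples[mid])
        )

    def test_noise_rms_after_chain(self, rng):
        # 2 pA white noise at 20 kHz must land at <= 0.25 pA rms after
        # 280 Hz zero-phase filtering and 80-point block averaging
        noise = rng.normal(0, 2.0, size=int(60 * RATE))
        p = preprocess(CurrentTrace(samples=noise, rate=RATE))
        rms = np.std(p.samples)
        assert 0.1 < rms < 0.25

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            preprocess(CurrentTrace(samples=np.zeros(40), rate=RATE))


class TestBurstDetection:
    def test_flat_trace_has_no_bursts(self):
        assert detect_bursts(make_processed(np.zeros(1000))) == []

    def test_square_pulse_detected_with_exact_lifetime(self):
        p = preprocess(square_pulse_trace(-7.2, start_s=2.0, dur_s=0.4))
        bursts = detect_bursts(p)
        assert len(bursts) == 1
        start, end = bursts[0]
        assert end - start == pytest.approx(0.4, abs=2 * DT125)
        assert start == pytest.approx(2.0, abs=2 * DT125)

    def test_short_pulse_rejected(self):
        p = preprocess(square_pulse_trace(-7.2, start_s=2.0, dur_s=0.1))
        assert detect_bursts(p) == []

    def test_amplitude_criterion_uses_absolute_value(self):
        p = preprocess(square_pulse_trace(+7.2, start_s=2.0, dur_s=0.4))
        assert len(detect_bursts(p)) == 1

    def test_flickering_burst_stays_one_burst(self):
        # two open periods separated by a 200 ms closure: one burst whose
        # lifetime spans the closure
        x = np.zeros(int(10 * RATE))
        x[int(2.0 * RATE):int(2.5 * RATE)] = -7.2
        x[int(2.7 * RATE):int(3.2 * RATE)] = -7.2
        p = preprocess(CurrentTrace(samples=x, rate=RATE))
        bursts = detect_bursts(p)
        assert len(bursts) == 1
        assert bursts[0][1] - bursts[0][0] == pytest.approx(1.2, abs=3 * DT125)

    def test_distant_bursts_stay_separate(self):
        x = np.zeros(int(20 * RATE))
        x[int(2.0 * RATE):int(2.4 * RATE)] = -7.2
        x[int(10.0 * RATE):int(10.4 * RATE)] = -7.2
        p = preprocess(CurrentTrace(samples=x, rate=RATE))
        assert len(detect_bursts(p)) == 2


class TestFlickerDetection:
    def test_burst_without_openings(self):
        # positive-going current exceeds the burst amplitude criterion but
        # never the (negative) open-pore threshold
        samples = np.zeros(500)
        samples[100:200] = +7.2
        p = make_processed(samples)
        assert detect_flickers(p, (100 * DT125, 200 * DT125)) == []

    def test_five_separated_open_periods(self):
        samples = np.zeros(500)
        for k in range(5):
            start = 100 + k * 40
            samples[start:start + 20] = -7.2  # 160 ms each
        p = make_processed(samples)
        opens = detect_flickers(p, (100 * DT125, 300 * DT125))
        assert len(opens) == 5

    def test_minimum_duration_boundary(self):
        # exactly 15 points (60 ms) counts, 14 points does not
        for n_pts, expected in [(14, 0), (15, 1)]:
            samples = np.zeros(300)
            samples[100:100 + n_pts] = -0.9
            p = make_processed(samples)
            opens = detect_flickers(p, (0.0, 300 * DT125))
            assert len(opens) == expected

    def test_bounds_validation(self):
        p = make_processed(np.zeros(100))
        with pytest.raises(ValueError):
            detect_flickers(p, (0.0, 200 * DT125))


class TestPoreRecord:
    def test_conductance_from_constant_open_current(self):
        # -7.2 pA at 16 mV driving force -> 450 pS
        samples = np.zeros(500)
        samples[100:200] = -7.2
        p = make_processed(samples)
        rec = pore_record(p, (100 * DT125, 200 * DT125))
        assert rec.g_po_ps == pytest.approx(450.0, rel=1e-12)
        assert rec.n_flickers == 1

    def test_fully_open_burst_has_unit_open_probability(self):
        samples = np.zeros(500)
        samples[100:200] = -7.2
        p = make_processed(samples)
        rec = pore_record(p, (100 * DT125, 200 * DT125))
        assert rec.p_open == pytest.approx(1.0)

    def test_half_open_burst(self):
        samples = np.zeros(800)
        samples[100:200] = -7.2
        samples[300:400] = -7.2
        p = make_processed(samples)
        rec = pore_record(p, (100 * DT125, 500 * DT125))
        assert rec.p_open == pytest.approx(0.5)
        assert rec.n_flickers == 2

    def test_never_open_burst_flagged(self):
        samples = np.zeros(500)
        samples[100:200] = +7.2
        p = make_processed(samples)
        rec = pore_record(p, (100 * DT125, 200 * DT125))
        assert rec.p_open == 0.0
        assert np.isnan(rec.g_po_ps)


class TestRadiusConversion:
    def test_zero_maps_to_zero(self):
        assert radius_from_conductance(0.0) == 0.0

    def test_one_nanosiemens_is_about_1_7_nm(self):
        assert radius_from_conductance(1000.0, 0.60) == pytest.approx(1.7, abs=0.05)

    def test_hand_evaluated_value(self):
        # sqrt(0.60 * 15e-9 * 450e-12 / pi) = 1.135 nm
        assert radius_from_conductance(450.0, 0.60) == pytest.approx(
            1.1354, abs=2e-4
        )

    def test_round_trip_identity(self, rng):
        g = rng.uniform(10.0, 8000.0, size=50)
        back = conductance_from_radius(radius_from_conductance(g))
        assert np.allclose(back, g, rtol=1e-12)

    def test_negative_conductance_rejected(self):
        with pytest.raises(ValueError):
            radius_from_conductance(-5.0)


class TestAveragedPdf:
    def test_single_pore_is_its_own_histogram(self, rng):
        s = rng.normal(5.0, 1.0, size=400)
        edges, dens = averaged_pdf([s], bin_width=0.2)
        ref = np.histogram(s, bins=edges, density=True)[0]
        assert np.allclose(dens, ref)

    def test_integrates_to_one(self, rng):
        pools = [rng.normal(3, 0.5, 200), rng.normal(8, 1.0, 50)]
        edges, dens = averaged_pdf(pools, bin_width=0.25)
        assert np.sum(dens) * 0.25 == pytest.approx(1.0, abs=1e-9)

    def test_pores_weighted_equally(self):
        # two delta-like pores of very different open durations still get
        # half the mass each
        a = np.full(1000, 2.0)
        b = np.full(10, 8.0)
        edges, dens = averaged_pdf([a, b], bin_width=1.0, lo=0.0, hi=10.0)
        mass = dens * 1.0
        assert mass[2] == pytest.approx(0.5)
        assert mass[8] == pytest.approx(0.5)
        # a pooled histogram would put ~99% of the mass on the long pore
        pooled = np.histogram(np.concatenate([a, b]), bins=edges, density=True)[0]
        assert pooled[2] > 0.9

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            averaged_pdf([], bin_width=0.1)


class TestEnergyFromPdf:
    def test_uniform_density_is_flat_zero(self):
        U = energy_from_pdf(np.full(8, 0.125), bin_width=1.0)
        assert np.allclose(U, 0.0)

    def test_two_bin_ratio(self):
        U = energy_from_pdf(np.array([0.9, 0.1]), bin_width=1.0)
        assert U[0] == 0.0
        assert U[1] == pytest.approx(np.log(9.0), rel=1e-12)

    def test_unvisited_bins_masked_not_infinite(self):
        U = energy_from_pdf(np.array([0.5, 0.0, 0.5]), bin_width=1.0)
        assert np.isnan(U[1])
        assert np.nanmin(U) == 0.0

    def test_boltzmann_inversion_round_trip(self, rng):
        # sample radii from exp(-U0) for a known double-well-free U0 and
        # rebuild the energy from the histogram: agreement within 0.3 kT
        grid = np.linspace(0.3, 3.0, 271)
        U0 = 4.0 * (grid - 1.0) ** 2
        p = np.exp(-U0)
        samples = rng.choice(grid, size=10000, p=p / p.sum())
        bw = 0.1
        edges, dens = averaged_pdf([samples], bin_width=bw, lo=0.3, hi=3.0)
        U = energy_from_pdf(dens, bw)
        centers = edges[:-1] + bw / 2
        visited = ~np.isnan(U)
        U0_c = 4.0 * (centers - 1.0) ** 2
        U0_c -= U0_c[visited].min()
        # compare where sampling is meaningful (U0 below ~4 kT)
        m = visited & (U0_c < 4.0)
        assert np.max(np.abs(U[m] - U0_c[m])) < 0.3

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            energy_from_pdf(np.zeros(5), 0.1)


class TestDwellStatistics:
    def test_geometric_mean_at_reference_p(self):
        assert geometric_mean_flickers(0.0573) == pytest.approx(16.45, abs=0.01)

    def test_mle_closed_form(self):
        p, _ = fit_flicker_geometric(np.full(64, 16.0))
        assert p == pytest.approx(1 / 17, rel=1e-12)

    def test_all_zero_counts_edge_case(self):
        p, ci = fit_flicker_geometric(np.zeros(10))
        assert p == 1.0

    def test_geometric_sampling_consistency(self, rng):
        p_true = 0.0573
        counts = rng.geometric(p_true, size=500) - 1
        p_hat, (lo, hi) = fit_flicker_geometric(counts)
        assert lo < p_true < hi
        assert p_hat == pytest.approx(p_true, rel=0.15)

    def test_exponential_mle(self):
        mean, se = fit_burst_exponential(np.full(16, 10.3))
        assert mean == pytest.approx(10.3)
        assert se == pytest.approx(10.3 / 4)

    def test_exponential_sampling(self, rng):
        t = rng.exponential(10.3, size=64)
        mean, se = fit_burst_exponential(t)
        assert abs(mean - 10.3) < 2 * 10.3 / np.sqrt(64)

    def test_single_observation_se(self):
        mean, se = fit_burst_exponential([4.2])
        assert se == pytest.approx(4.2)

    def test_nonpositive_lifetime_rejected(self):
        with pytest.raises(ValueError):
            fit_burst_exponential([3.0, 0.0])


class TestNucleationRate:
    def test_basic_rate(self):
        rate, per = nucleation_rate([2], [10.0])
        assert rate == pytest.approx(0.2)

    def test_exclusions_shrink_denominator(self):
        rate, _ = nucleation_rate([2], [12.0], excluded_min=[2.0])
        assert rate == pytest.approx(0.2)

    def test_mean_of_rates_differs_from_pooled(self):
        # 1 burst / 1 min and 1 burst / 10 min: mean of rates is 0.55/min,
        # pooled would be 2/11
        rate, per = nucleation_rate([1, 1], [1.0, 10.0])
        assert rate == pytest.approx(0.55)
        assert rate != pytest.approx(2 / 11)

    def test_zero_duration_recording_dropped(self):
        with pytest.warns(RuntimeWarning):
            rate, per = nucleation_rate([1, 3], [10.0, 5.0], excluded_min=[0.0, 5.0])
        assert rate == pytest.approx(0.1)
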