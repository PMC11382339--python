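import numpy as np
import pytest

from oligoms.twodms import (
    Acq2DParams,
    DEFAULT_CALIBRATION_A as A,
    DenoiseParams,
    EddGeometry,
    Map2D,
    SpeciesModel,
    average_scans,
    closest_approach,
    denoise_low_rank,
    extract_autocorrelation,
    extract_fragment_line,
    extract_precursor_line,
    gaussian_profile,
    harmonic_mz,
    photon_energy,
    plateau_profile,
    process_2d,
    simulate_2d,
    snr,
)

F1 = np.fft.rfftfreq(64, d=2e-6)
F2 = np.fft.rfftfreq(256, d=1e-6)
PREC_MZ = A / F1[8]
FRAG_MZ = A / F2[40]


def params(m=1, seed=0, n_t1=64, n_t2=256):
    return Acq2DParams(
        n_t1=n_t1, m_scans=m, t1_step=2e-6, n_t2=n_t2,
        sample_rate=1e6, seed=seed,
    )


def model(noise=0.0, frags=((FRAG_MZ, 1.0),), **kw):
    return SpeciesModel(
        precursor_mz=PREC_MZ, precursor_charge=8,
        fragments=list(frags), noise_sigma=noise, **kw
    )


class TestSimulate:
    def test_reproducible(self):
        m1 = simulate_2d(params(seed=42), model(noise=0.5))
        m2 = simulate_2d(params(seed=42), model(noise=0.5))
        assert np.array_equal(m1.matrix, m2.matrix)

    def test_flat_profile_rows_identical(self):
        flat = model()
        flat.profile = lambda c: 1.0
        m = simulate_2d(params(), flat)
        assert np.allclose(m.matrix, m.matrix[0])

    def test_cosine_modulation_periodic_at_precursor_freq(self):
        m = simulate_2d(params(), model())
        interferogram = m.matrix[:, 0]  # t2=0 sample carries the full amplitude
        spec = np.abs(np.fft.rfft(interferogram - interferogram.mean()))
        assert np.argmax(spec) == 8  # precursor frequency bin

    def test_shape_and_log(self):
        m = simulate_2d(params(), model())
        assert m.matrix.shape == (64, 256)
        assert m.domain == "time"
        assert m.log


class TestAverageScans:
    def test_identity_on_identical_rows(self):
        row = np.arange(8.0)
        assert np.array_equal(average_scans([row] * 5), row)

    def test_noise_reduction_sqrt8(self):
        rng = np.random.default_rng(0)
        stds = []
        for _ in range(200):
            rows = [rng.normal(0, 1, 64) for _ in range(8)]
            stds.append(average_scans(rows).std())
        assert np.mean(stds) == pytest.approx(1 / np.sqrt(8), rel=0.05)

    def test_passthrough_m1(self):
        row = np.arange(4.0)
        assert np.array_equal(average_scans([row]), row)

    def test_empty_and_ragged(self):
        with pytest.raises(ValueError):
            average_scans([])
        with pytest.raises(ValueError):
            average_scans([np.zeros(3), np.zeros(4)])


class TestDenoise:
    def test_exact_on_low_rank(self):
        rng = np.random.default_rng(1)
        m = rng.normal(size=(64, 3)) @ rng.normal(size=(3, 256))
        map2d = Map2D(m, params())
        out = denoise_low_rank(map2d, DenoiseParams(rank=3))
        assert np.abs(out.matrix - m).max() < 1e-9

    def test_improves_snr_on_noisy_low_rank(self):
        rng = np.random.default_rng(2)
        signal = rng.normal(size=(64, 3)) @ rng.normal(size=(3, 256))
        noisy = signal + rng.normal(0, 0.5, signal.shape)
        out = denoise_low_rank(Map2D(noisy, params()), DenoiseParams(rank=10))
        err_before = np.linalg.norm(noisy - signal)
        err_after = np.linalg.norm(out.matrix - signal)
        assert err_after < err_before

    def test_randomized_matches_truncated_on_exact_rank(self):
        rng = np.random.default_rng(3)
        m = rng.normal(size=(64, 4)) @ rng.normal(size=(4, 128))
        t = denoise_low_rank(Map2D(m, params()), DenoiseParams(rank=4))
        r = denoise_low_rank(
            Map2D(m, params()),
            DenoiseParams(rank=4, algorithm="randomized-rank", seed=0),
        )
        assert np.abs(t.matrix - r.matrix).max() < 1e-6

    def test_default_rank_is_10(self):
        assert DenoiseParams().rank == 10

    def test_rank_bounds(self):
        with pytest.raises(ValueError):
            denoise_low_rank(Map2D(np.zeros((8, 16)), params()), DenoiseParams(rank=8))

    def test_does_not_shift_top_peaks(self):
        sim = simulate_2d(params(seed=5), model(noise=0.2))
        den = denoise_low_rank(sim, DenoiseParams(rank=10))
        p_ref = process_2d(sim)
        p_den = process_2d(den)
        ref_idx = np.unravel_index(np.argmax(p_ref.matrix[1:, 1:]), p_ref.matrix[1:, 1:].shape)
        den_idx = np.unravel_index(np.argmax(p_den.matrix[1:, 1:]), p_den.matrix[1:, 1:].shape)
        assert abs(ref_idx[0] - den_idx[0]) <= 1
        assert abs(ref_idx[1] - den_idx[1]) <= 1


class TestProcess2D:
    def test_single_fragment_localizes(self):
        p = process_2d(simulate_2d(params(), model()))
        sub = p.matrix[1:, 1:]
        row, col = np.unravel_index(np.argmax(sub), sub.shape)
        assert p.mz_axis_precursor[row + 1] == pytest.approx(PREC_MZ)
        assert p.mz_axis_fragment[col + 1] == pytest.approx(FRAG_MZ)

    def test_unmodulated_signal_confined_to_dc_row(self):
        flat = model()
        flat.profile = lambda c: 1.0
        p = process_2d(simulate_2d(params(), flat))
        off_dc = p.matrix[1:].sum()
        assert p.matrix[0].sum() > 1e3 * max(off_dc, 1e-12)

    def test_parseval_t2_stage(self):
        sim = simulate_2d(params(seed=9), model(noise=0.3))
        x = sim.matrix[5]
        spec = np.fft.fft(x)
        assert np.sum(np.abs(spec) ** 2) / len(x) == pytest.approx(
            np.sum(x**2), rel=1e-6
        )

    def test_zero_fill_non_pow2(self):
        p = Acq2DParams(n_t1=60, m_scans=1, t1_step=2e-6, n_t2=250,
                        sample_rate=1e6, seed=0)
        out = process_2d(simulate_2d(p, model()))
        assert out.matrix.shape == (64 // 2 + 1, 256 // 2 + 1)

    def test_requires_time_domain(self):
        p = process_2d(simulate_2d(params(), model()))
        with pytest.raises(ValueError):
            process_2d(p)


class TestExtraction:
    def _three_precursor_map(self):
        prec_mzs = [A / F1[6], A / F1[10], A / F1[14]]
        frag_sets = [
            [(A / F2[30], 1.0), (A / F2[70], 0.8)],
            [(A / F2[44], 1.0), (A / F2[70], 0.6)],  # shares F2[70]
            [(A / F2[90], 1.0)],
        ]
        total = None
        for pmz, frags in zip(prec_mzs, frag_sets):
            sim = simulate_2d(
                params(seed=0),
                SpeciesModel(pmz, 8, frags, precursor_amplitude=1.0),
            )
            total = sim.matrix if total is None else total + sim.matrix
        combined = Map2D(total, params())
        return process_2d(combined), prec_mzs

    def test_autocorrelation_shows_precursors(self):
        p, prec_mzs = self._three_precursor_map()
        axis, line = extract_autocorrelation(p)
        finite = np.isfinite(axis)
        threshold = line[finite].max() * 0.2
        peak_rows = {i for i in np.nonzero(line > threshold)[0] if finite[i]}
        for pmz in prec_mzs:
            i = np.argmin(np.where(finite, np.abs(axis - pmz), np.inf))
            assert i in peak_rows

    def test_fragment_line_contains_own_fragments(self):
        p, prec_mzs = self._three_precursor_map()
        axis, line = extract_fragment_line(p, prec_mzs[0])
        assert line[30] > 10 * line[90]  # own fragment vs other precursor's

    def test_shared_fragment_on_precursor_line(self):
        p, prec_mzs = self._three_precursor_map()
        axis, line = extract_precursor_line(p, A / F2[70])
        assert line[6] > 5 * line[14]
        assert line[10] > 5 * line[14]

    def test_out_of_range_request(self):
        p, _ = self._three_precursor_map()
        with pytest.raises(ValueError):
            extract_fragment_line(p, 1e9)


class TestSnr:
    def test_pure_noise_is_order_one(self):
        rng = np.random.default_rng(0)
        axis = np.linspace(100, 1000, 512)
        spec = np.abs(rng.normal(0, 1, 512))
        values = [
            snr(spec, axis, float(rng.uniform(150, 450)), (500, 900))
            for _ in range(50)
        ]
        assert np.median(values) < 5

    def test_linear_in_amplitude(self):
        axis = np.linspace(100, 1000, 512)
        spec = np.ones(512) * 0.1
        spec[100] = 5.0
        s1 = snr(spec, axis, axis[100], (500, 900))
        spec2 = spec.copy()
        spec2[100] = 10.0
        assert snr(spec2, axis, axis[100], (500, 900)) == pytest.approx(2 * s1)

    def test_empty_noise_region(self):
        axis = np.linspace(100, 1000, 64)
        with pytest.raises(ValueError):
            snr(np.ones(64), axis, 500, (2000, 3000))


class TestAccumulationGain:
    def _gain(self, m, n_rep=40):
        ratios = []
        for s in range(n_rep):
            out = []
            for mm, seed in ((1, s), (m, s + 10_000)):
                sim = simulate_2d(params(m=mm, seed=seed), model(noise=0.4))
                proc = process_2d(sim)
                ax, line = extract_fragment_line(proc, PREC_MZ)
                out.append(
                    snr(line, ax, FRAG_MZ, (A / F2[120], A / F2[60]))
                )
            ratios.append(out[1] / out[0])
        return float(np.median(ratios))

    def test_sqrt_m_exponent(self):
        ms = [1, 2, 4, 8, 16]
        gains = [self._gain(m, n_rep=30) for m in ms]
        slope = np.polyfit(np.log(ms), np.log(gains), 1)[0]
        assert 0.4 <= slope <= 0.6

    def test_m8_gain_in_observed_band(self):
        gain = self._gain(8, n_rep=60)
        assert 1.7 <= gain <= 3.0

    def test_same_peak_positions_m1_vs_m8(self):
        for m in (1, 8):
            proc = process_2d(simulate_2d(params(m=m, seed=1), model(noise=0.2)))
            sub = proc.matrix[1:, 1:]
            row, col = np.unravel_index(np.argmax(sub), sub.shape)
            assert (row + 1, col + 1) == (8, 40)


class TestPhysics:
    def test_harmonics_of_cutoff(self):
        assert harmonic_mz(2000, 2) == pytest.approx(1000.0)
        assert harmonic_mz(2000, 3) == pytest.approx(666.7, abs=0.1)
        assert harmonic_mz(1234.5, 1) == 1234.5
        with pytest.raises(ValueError):
            harmonic_mz(2000, 0)

    def test_closest_approach_printed_values(self):
        assert closest_approach(5, 22.8) == pytest.approx(3.16, abs=0.01)
        assert closest_approach(9, 22.8) == pytest.approx(5.68, abs=0.01)
        assert closest_approach(1, 14.39964) == pytest.approx(1.0)

    def test_closest_approach_scaling(self):
        d1 = closest_approach(3, 20.0)
        assert closest_approach(6, 20.0) == pytest.approx(2 * d1)
        assert closest_approach(3, 40.0) == pytest.approx(d1 / 2)
        with pytest.raises(ValueError):
            closest_approach(3, 0.0)

    def test_edd_geometry(self):
        g = EddGeometry(z=5, v_bias=22.8)
        assert g.distance == pytest.approx(3.158, abs=1e-3)

    def test_photon_energy(self):
        assert photon_energy(193) == pytest.approx(6.42, abs=0.01)
        assert photon_energy(1239.841) == pytest.approx(1.0, abs=1e-4)
        assert photon_energy(10600) == pytest.approx(0.117, abs=0.001)
        with pytest.raises(ValueError):
            photon_energy(0)


class TestHdf5RoundTrip:
    def test_save_load(self, tmp_path):
        sim = simulate_2d(params(seed=3), model(noise=0.1))
        proc = process_2d(sim)
        path = tmp_path / "map.h5"
        proc.save_hdf5(path)
        back = Map2D.load_hdf5(path)
        assert np.array_equal(back.matrix, proc.matrix)
        assert back.domain == "spectrum"
        assert np.array_equal(back.mz_axis_fragment, proc.mz_axis_fragment)
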