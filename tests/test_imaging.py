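"""Focusing, beamforming, envelope detection and band splitting."""

import numpy as np
import pytest

from skullwave import imaging
from skullwave.imaging import (FocusSequence, ImageGrid, RFImage,
                               bandpass_component, blank_transmit,
                               das_beamform, envelope_bmode, tx_focus_delays)
from skullwave.solver import ChannelData, Pulse, TransducerArray


class TestTxFocusDelays:
    def test_symmetric_array_on_axis_focus(self):
        arr = TransducerArray(n_elements=32, pitch=0.3e-3)
        d = tx_focus_delays(arr, (0.0, 0.03))
        assert np.allclose(d, d[::-1])
        assert d.argmax() in (15, 16)
        assert d.min() == 0.0

    def test_plane_wave_limit_at_infinite_focus(self):
        arr = TransducerArray(n_elements=32, pitch=0.3e-3)
        d = tx_focus_delays(arr, (0.0, 1e3))
        assert d.max() < 1e-11

    def test_geometric_oracle(self):
        # single element at lateral 0, edge element at 16 mm, focus 40 mm
        arr = TransducerArray(n_elements=2, pitch=16e-3)
        d = tx_focus_delays(arr, (-8e-3, 0.04), c0=1540.0)
        expected = (np.hypot(0.016, 0.04) - 0.04) / 1540.0
        assert d[1] == 0.0  # the far element fires first
        assert d[0] == pytest.approx(expected, rel=1e-6)
        assert expected == pytest.approx(2.0e-6, rel=2e-3)

    def test_focus_behind_array_rejected(self):
        with pytest.raises(ValueError):
            tx_focus_delays(TransducerArray(), (0.0, -0.01))


def synthetic_point_echo(arr, target, c0=1540.0, dt=1e-8, n_t=6000,
                         t_tx=None):
    """Forward-model traces of an ideal point echo (no solver)."""
    pulse = Pulse(f0=2.5e6, cycles=2, amplitude=1.0)
    tx_x, tz = target
    t_tx = t_tx if t_tx is not None else tz / c0
    traces = np.zeros((arr.n_elements, n_t))
    t = dt * np.arange(n_t)
    for e, xe in enumerate(arr.positions):
        arrival = t_tx + np.hypot(tz, tx_x - xe) / c0
        traces[e] = pulse.waveform(t - arrival + pulse.t_center)
    return ChannelData(traces, dt=dt, element_x=arr.positions, f0=2.5e6,
                       t_pulse_center=0.0)


class TestDasBeamform:
    def _grid(self):
        return ImageGrid.regular((0.02, 0.04), (-0.005, 0.005), 1e-4)

    def test_zero_traces_give_zero_image(self):
        arr = TransducerArray(n_elements=16)
        cd = ChannelData(np.zeros((16, 1000)), dt=1e-8,
                         element_x=arr.positions, t_pulse_center=0.0)
        rf = das_beamform(cd, arr, self._grid())
        assert np.all(rf.data == 0.0)

    def test_point_echo_peak_at_target(self):
        arr = TransducerArray(n_elements=48, pitch=0.3e-3)
        target = (0.001, 0.03)
        cd = synthetic_point_echo(arr, target)
        rf = das_beamform(cd, arr, self._grid())
        bm = envelope_bmode(rf)
        iz, ix = np.unravel_index(np.argmax(bm.envelope), bm.envelope.shape)
        g = self._grid()
        assert abs(g.z[iz] - target[1]) <= 1.5e-4
        assert abs(g.x[ix] - target[0]) <= 1.5e-4

    def test_lateral_shift_consistency(self):
        arr = TransducerArray(n_elements=48, pitch=0.3e-3)
        g = self._grid()
        peaks = []
        for xt in (0.0, 0.002):
            cd = synthetic_point_echo(arr, (xt, 0.03))
            bm = envelope_bmode(das_beamform(cd, arr, g))
            peaks.append(np.unravel_index(np.argmax(bm.envelope),
                                          bm.envelope.shape)[1])
        assert peaks[1] - peaks[0] == pytest.approx(0.002 / 1e-4, abs=1)

    def test_linearity(self):
        arr = TransducerArray(n_elements=16, pitch=0.3e-3)
        rng = np.random.default_rng(0)
        mk = lambda tr: ChannelData(tr, dt=1e-8, element_x=arr.positions,
                                    t_pulse_center=0.0)
        a = rng.normal(size=(16, 4000))
        b = rng.normal(size=(16, 4000))
        g = self._grid()
        img_sum = das_beamform(mk(a + b), arr, g).data
        img_a = das_beamform(mk(a), arr, g).data
        img_b = das_beamform(mk(b), arr, g).data
        np.testing.assert_allclose(img_sum, img_a + img_b, atol=1e-6)

    def test_requests_beyond_trace_length_zero_filled(self):
        arr = TransducerArray(n_elements=8)
        cd = ChannelData(np.ones((8, 10)), dt=1e-8,
                         element_x=arr.positions, t_pulse_center=0.0)
        rf = das_beamform(cd, arr, self._grid())  # all times out of range
        assert np.all(rf.data == 0.0)


class TestPsfGeometry:
    def test_focused_psf_peak_and_width(self, homogeneous_point_psf):
        cd, arr, grid, m, pulse = homogeneous_point_psf
        bm = envelope_bmode(das_beamform(cd, arr, grid))
        iz, ix = np.unravel_index(np.argmax(bm.envelope), bm.envelope.shape)
        assert abs(grid.z[iz] - 0.035) < 4e-4
        assert abs(grid.x[ix] - 0.0) < 3e-4
        # two-way lateral width: FWHM(sinc^2) = 0.64 lambda z / D
        row = bm.envelope[iz]
        above = np.where(row >= row.max() / 2)[0]
        fwhm = grid.x[above[-1]] - grid.x[above[0]]
        lam = 1540.0 / pulse.f0
        expected = 0.64 * lam * 0.035 / arr.aperture
        assert fwhm == pytest.approx(expected, rel=0.20)


class TestGridConvergence:
    def test_psf_peak_position_stable_between_15_and_20_ppw(self):
        from skullwave import media, solver

        f0 = 1.25e6
        grid = ImageGrid.regular((0.022, 0.034), (-0.004, 0.004), 2e-4)
        peaks = {}
        for ppw in (15, 20):
            dx = (1540.0 / f0) / ppw
            m = media.uniform_map((int(0.035 / dx), int(0.018 / dx)), dx,
                                  attenuation=0.0)
            m = media.insert_point_target(m, depth=0.028)
            arr = TransducerArray(n_elements=48, pitch=0.295e-3)
            pulse = Pulse(f0=f0, cycles=2, amplitude=1e5)
            cfg = solver.SolverConfig(points_per_wavelength=ppw,
                                      duration=2 * 0.032 / 1540 + 8e-6)
            res = solver.run_simulation(
                m, arr, pulse, cfg,
                tx_delays=tx_focus_delays(arr, (0.0, 0.028)),
                focus=(0.0, 0.028))
            bm = envelope_bmode(das_beamform(res.channel_data, arr, grid))
            peaks[ppw] = np.unravel_index(np.argmax(bm.envelope),
                                          bm.envelope.shape)
        assert abs(peaks[15][0] - peaks[20][0]) <= 1
        assert abs(peaks[15][1] - peaks[20][1]) <= 1


class TestEnvelopeBmode:
    def test_self_normalized_max_is_zero_db(self, rng):
        rf = RFImage(rng.normal(size=(64, 32)), ImageGrid(
            np.linspace(0, 1e-2, 64), np.linspace(-1e-3, 1e-3, 32)))
        bm = envelope_bmode(rf)
        assert np.nanmax(bm.db) == pytest.approx(0.0, abs=1e-12)
        assert bm.self_normalized

    def test_sinusoid_envelope_amplitude(self):
        z = np.linspace(0, 2e-2, 512)
        data = 3.0 * np.sin(2 * np.pi * z / 1e-3)[:, None] * np.ones((1, 8))
        rf = RFImage(data, ImageGrid(z, np.arange(8.0)))
        bm = envelope_bmode(rf)
        core = bm.envelope[100:-100]
        assert np.allclose(core, 3.0, rtol=0.01)

    def test_scale_invariance_of_self_normalized_image(self, rng):
        data = rng.normal(size=(64, 16))
        g = ImageGrid(np.linspace(0, 1e-2, 64), np.arange(16.0))
        a = envelope_bmode(RFImage(data, g)).db
        b = envelope_bmode(RFImage(2 * data, g)).db
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_all_zero_rf_rejected(self):
        rf = RFImage(np.zeros((16, 8)), ImageGrid(np.linspace(0, 1e-3, 16),
                                                  np.arange(8.0)))
        with pytest.raises(ValueError, match="zero"):
            envelope_bmode(rf)

    def test_display_clips_but_db_does_not(self, rng):
        data = rng.normal(size=(64, 16))
        data[0, 0] *= 1e6
        g = ImageGrid(np.linspace(0, 1e-2, 64), np.arange(16.0))
        bm = envelope_bmode(RFImage(data, g), dynamic_range=60.0)
        assert bm.db.min() < -60.0
        assert bm.display().min() == -60.0


class TestBandpass:
    def _tone(self, freqs_amps, dt=2e-9, n=8192):
        t = dt * np.arange(n)
        tr = sum(a * np.sin(2 * np.pi * f * t) for f, a in freqs_amps)
        win = np.hanning(n)
        return ChannelData((tr * win)[None, :], dt=dt)

    def test_stop_band_suppression(self):
        cd = self._tone([(1.25e6, 1.0)])
        out = bandpass_component(cd, 2.5e6)
        assert 20 * np.log10(np.abs(out.traces).max()
                             / np.abs(cd.traces).max()) < -60.0

    def test_pass_band_preserved(self):
        cd = self._tone([(1.25e6, 1.0)])
        out = bandpass_component(cd, 1.25e6)
        assert np.abs(out.traces).max() == pytest.approx(
            np.abs(cd.traces).max(), rel=0.01)

    def test_two_tone_split(self):
        cd = self._tone([(1.25e6, 1.0), (2.5e6, 0.5)])
        fund = bandpass_component(cd, 1.25e6)
        harm = bandpass_component(cd, 2.5e6)
        assert np.abs(fund.traces).max() == pytest.approx(1.0, rel=0.02)
        assert np.abs(harm.traces).max() == pytest.approx(0.5, rel=0.02)

    def test_band_beyond_nyquist_rejected(self):
        cd = self._tone([(1.25e6, 1.0)], dt=4e-7)
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass_component(cd, 2.0e6)


class TestFocusSequence:
    def test_strips_tile_without_gaps(self):
        seq = FocusSequence.lateral_sweep(12, 0.4e-3, 0.03)
        x = np.linspace(-0.01, 0.01, 201)
        edges = seq.strip_edges(x)
        covered = np.zeros_like(x, dtype=int)
        for lo, hi in edges:
            covered += ((x > lo) & (x <= hi)).astype(int)
        assert np.all(covered == 1)

    def test_unsorted_foci_rejected(self):
        with pytest.raises(ValueError):
            FocusSequence([(0.001, 0.03), (0.0, 0.03)])


class TestBlanking:
    def test_blank_zeroes_only_early_samples(self):
        cd = ChannelData(np.ones((4, 100)), dt=1e-8)
        out = blank_transmit(cd, 50e-8)
        assert np.all(out.traces[:, :49] == 0.0)
        assert np.all(out.traces[:, 51:] == 1.0)
        assert np.all(cd.traces == 1.0)  # input untouched
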