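"""Beating-LV phantom and gated-acquisition simulator."""

import numpy as np
import pytest

from gatedspect.gating import GateConfig, accept_beats
from gatedspect.phantom import (
    LVPhantomSpec,
    generate_rr_series,
    phantom_frame,
    simulate_gated_sinogram,
)
from gatedspect.projector import Projector


class TestRRSeries:
    def test_zero_variance_gives_exact_beats(self):
        beats = generate_rr_series(1.0, 0.0, 10.0, seed=42)
        assert len(beats.rr_intervals) == 10
        assert np.allclose(beats.rr_intervals, 1.0)

    def test_sample_moments_match_at_large_n(self):
        beats = generate_rr_series(1.0, 0.1, 1000.0, seed=7)
        assert beats.rr_intervals.mean() == pytest.approx(1.0, abs=0.01)
        assert beats.rr_intervals.std(ddof=1) == pytest.approx(0.1, abs=0.01)

    def test_invalid_parameters_raise(self):
        with pytest.raises(ValueError):
            generate_rr_series(0.0, 0.1, 10.0, seed=0)
        with pytest.raises(ValueError):
            generate_rr_series(1.0, 0.1, 0.5, seed=0)
        with pytest.raises(ValueError):
            generate_rr_series(1.0, -0.1, 10.0, seed=0)

    def test_seed_reproducibility(self):
        a = generate_rr_series(0.9, 0.08, 100.0, seed=3)
        b = generate_rr_series(0.9, 0.08, 100.0, seed=3)
        assert np.array_equal(a.rr_intervals, b.rr_intervals)

    def test_truncation_floor(self):
        beats = generate_rr_series(1.0, 0.6, 500.0, seed=5)
        assert beats.rr_intervals.min() >= 0.3

    def test_trigger_invariant(self):
        beats = generate_rr_series(0.8, 0.05, 50.0, seed=9)
        assert np.allclose(np.diff(beats.trigger_times), beats.rr_intervals)


class TestPhantomFrame:
    def test_total_activity_conserved_over_cycle(self, small_phantom):
        totals = [phantom_frame(small_phantom, p).data.sum() for p in range(0, 360, 30)]
        assert np.ptp(totals) / np.mean(totals) < 0.01

    def test_wall_thickens_and_moves_inward_at_end_systole(self):
        """With zero delay the thickening term vanishes at phase 0 (R wave)
        and peaks at 180°; the incompressible wall is then radially thicker
        and its mid-wall radius smaller."""
        spec = LVPhantomSpec()
        from gatedspect.phantom import _phantom_maps

        r, _ = _phantom_maps(spec)
        thr = 0.5 * spec.wall_activity

        def radial_stats(phase):
            plane = phantom_frame(spec, phase).data[:, :, spec.z_extent[0]]
            wall_r = r[plane > thr]
            return wall_r.max() - wall_r.min(), wall_r.mean()

        extent0, mid0 = radial_stats(0.0)
        extent180, mid180 = radial_stats(180.0)
        assert extent180 > extent0
        assert mid180 < mid0

    def test_delayed_sector_curve_is_shifted_copy(self, small_phantom):
        from dataclasses import replace

        delays = [0.0] * small_phantom.n_sectors
        delays[1] = 45.0
        spec = replace(small_phantom, sector_phase_delays=tuple(delays))
        _, sector = _maps(spec)
        phases = np.arange(0, 360, 45)
        ref, dly = [], []
        for p in phases:
            f = phantom_frame(spec, float(p)).data[:, :, spec.z_extent[0]]
            ref.append(f[sector == 0].sum())
            dly.append(f[sector == 1].sum())
        # the delayed sector's count-phase curve equals the reference's
        # shifted by one 45° step
        assert np.allclose(np.roll(ref, 1), dly, rtol=1e-6)

    def test_spec_validation(self):
        with pytest.raises(ValueError):
            LVPhantomSpec(endocardial_radius_mm=40.0)  # endo >= epi
        with pytest.raises(ValueError):
            LVPhantomSpec(contraction_fraction=1.5)
        with pytest.raises(ValueError):
            LVPhantomSpec(sector_phase_delays=(0.0,))


def _maps(spec):
    from gatedspect.phantom import _phantom_maps

    return _phantom_maps(spec)


class TestSimulator:
    def test_static_no_hrv_bins_exchangeable(
        self, small_phantom, small_geometry, small_projector, gate_config
    ):
        """No HRV and no motion: equal expected counts, τ = dwell/8."""
        from dataclasses import replace

        static = replace(small_phantom, contraction_fraction=0.0)
        dwell = 10.0
        beats = generate_rr_series(1.0, 0.0, 8 * dwell + 1, seed=0)
        _, tau, _, lam = simulate_gated_sinogram(
            static, beats, small_geometry, gate_config, seed=1,
            dwell_time=dwell, projector=small_projector, return_expected=True,
        )
        bin_sums = lam.sum(axis=(0, 2, 3))
        assert np.ptp(bin_sums) / bin_sums.mean() < 1e-9
        assert np.allclose(tau.tau, dwell / 8)  # 10 beats x 0.125 s per bin
        assert np.allclose(tau.tau.sum(axis=1), dwell)

    def test_expected_counts_match_beat_by_beat_oracle(
        self, small_phantom, small_geometry, small_projector, gate_config
    ):
        """Brute-force oracle: loop every accepted beat and sub-interval,
        forward-project its frame, and integrate."""
        dwell = 5.0
        beats = generate_rr_series(0.9, 0.08 * 0.9, 8 * dwell + 1, seed=21)
        _, tau, _, lam = simulate_gated_sinogram(
            small_phantom, beats, small_geometry, gate_config, seed=2,
            dwell_time=dwell, projector=small_projector, return_expected=True,
        )
        acc = accept_beats(beats, gate_config)
        delta = acc.bin_length
        oracle = np.zeros_like(lam)
        tau_oracle = np.zeros_like(tau.tau)
        for i, rr in enumerate(beats.rr_intervals):
            l = int(beats.trigger_times[i] // dwell)
            if l >= small_geometry.n_angles or not acc.accepted[i]:
                continue
            for b in range(8):
                lo = min(rr, b * delta)
                hi = min(rr, (b + 1) * delta)
                if hi <= lo:
                    continue
                mid_phase = 0.5 * (lo + hi) / rr * 360.0
                frame = phantom_frame(small_phantom, mid_phase).data
                oracle[l, b] += (hi - lo) * small_projector.forward(frame, l)
                tau_oracle[l, b] += hi - lo
        assert np.allclose(lam, oracle, rtol=1e-6, atol=1e-9)
        assert np.allclose(tau.tau, tau_oracle, rtol=1e-9)

    def test_hrv_starves_only_last_bin(
        self, small_phantom, small_geometry, small_projector, gate_config
    ):
        beats = generate_rr_series(0.9, 0.09, 8 * 10.0 + 1, seed=6)
        _, tau, _ = simulate_gated_sinogram(
            small_phantom, beats, small_geometry, gate_config, seed=7,
            dwell_time=10.0, projector=small_projector,
        )
        col = tau.tau.sum(axis=0)
        assert col[7] < col[0]
        # earlier bins are nearly untouched by moderate HRV
        assert np.ptp(col[:6]) / col[0] < 0.02

    def test_seed_fixes_outputs_bitwise(
        self, small_phantom, small_geometry, small_projector, gate_config
    ):
        beats = generate_rr_series(0.9, 0.05, 8 * 5.0 + 1, seed=13)
        out1 = simulate_gated_sinogram(
            small_phantom, beats, small_geometry, gate_config, seed=14,
            dwell_time=5.0, projector=small_projector,
        )
        out2 = simulate_gated_sinogram(
            small_phantom, beats, small_geometry, gate_config, seed=14,
            dwell_time=5.0, projector=small_projector,
        )
        assert np.array_equal(out1[0].counts, out2[0].counts)
        assert np.array_equal(out1[1].tau, out2[1].tau)

    def test_phase_cache_close_to_exact(
        self, small_phantom, small_geometry, small_projector, gate_config
    ):
        beats = generate_rr_series(0.9, 0.05, 8 * 5.0 + 1, seed=30)
        _, _, _, lam_exact = simulate_gated_sinogram(
            small_phantom, beats, small_geometry, gate_config, seed=0,
            dwell_time=5.0, projector=small_projector, return_expected=True,
        )
        _, _, _, lam_cached = simulate_gated_sinogram(
            small_phantom, beats, small_geometry, gate_config, seed=0,
            dwell_time=5.0, projector=small_projector, phase_cache=256,
            return_expected=True,
        )
        rel = np.abs(lam_cached - lam_exact).sum() / lam_exact.sum()
        assert rel < 0.01

    def test_short_dwell_raises(
        self, small_phantom, small_geometry, small_projector, gate_config
    ):
        beats = generate_rr_series(1.0, 0.0, 10.0, seed=0)
        with pytest.raises(ValueError):
            simulate_gated_sinogram(
                small_phantom, beats, small_geometry, gate_config, seed=0,
                dwell_time=0.5, projector=small_projector,
            )
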