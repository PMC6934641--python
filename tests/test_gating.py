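"""Fixed forward gating: beat acceptance, acquisition-time maps, event
binning and last-bin thinning."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gatedspect.gating import (
    AcquisitionTimeMap,
    EventStream,
    GateConfig,
    GatedSinogram,
    GatingError,
    accept_beats,
    bin_events,
    compute_tau,
    count_activity_ratio,
    thin_last_bin,
)
from gatedspect.phantom import BeatSeries


def _beats(rrs):
    rrs = np.asarray(rrs, dtype=float)
    return BeatSeries(rr_intervals=rrs, trigger_times=np.concatenate([[0], np.cumsum(rrs)]))


class TestAcceptBeats:
    def test_hand_worked_example(self, gate_config):
        """Mean of [1,1,1,.7] is .925; the ±20% window rejects the 0.7 beat."""
        res = accept_beats(_beats([1.0, 1.0, 1.0, 0.7]), gate_config)
        assert res.accepted.tolist() == [True, True, True, False]
        assert res.mean_accepted_rr == pytest.approx(1.0)
        assert res.bin_length == pytest.approx(0.125)

    def test_identical_beats_all_accepted(self, gate_config):
        res = accept_beats(_beats([0.8] * 10), gate_config)
        assert res.accepted.all()
        assert res.sd_rr_normalized == 0.0

    def test_reported_pair_ratio_identity(self, gate_config):
        """SD_R-R 0.011 with SD 9.1 ms implies a mean near 827 ms; the two
        outputs must satisfy sd_norm = sd/mean on any input."""
        rng = np.random.default_rng(0)
        rr = rng.normal(0.827, 0.0091, size=400)
        res = accept_beats(_beats(rr), gate_config)
        assert res.sd_rr_normalized == pytest.approx(
            res.sd_accepted_rr / res.mean_accepted_rr, rel=1e-12
        )
        assert res.sd_rr_normalized == pytest.approx(0.011, abs=0.002)
        assert res.mean_accepted_rr == pytest.approx(0.827, abs=0.005)

    @given(
        st.lists(st.floats(min_value=0.4, max_value=1.6), min_size=2, max_size=60),
    )
    @settings(max_examples=50, deadline=None)
    def test_ratio_identity_property(self, rrs):
        try:
            res = accept_beats(_beats(rrs), GateConfig())
        except GatingError:
            return
        assert res.sd_rr_normalized * res.mean_accepted_rr == pytest.approx(
            res.sd_accepted_rr, abs=1e-12
        )
        assert res.bin_length == pytest.approx(res.mean_accepted_rr / 8)

    def test_no_acceptance_raises(self):
        with pytest.raises(GatingError):
            accept_beats(_beats([0.4, 1.6]), GateConfig(acceptance_window=0.05))

    def test_too_few_beats(self, gate_config):
        with pytest.raises(GatingError):
            accept_beats(_beats([1.0]), gate_config)


class TestComputeTau:
    def test_exact_fit_beat(self):
        tau = compute_tau([np.array([1.0])], bin_length=0.125, n_bins=8)
        assert np.allclose(tau.tau, 0.125)

    def test_short_beat_truncates_last_bin(self):
        tau = compute_tau([np.array([0.95])], bin_length=0.125, n_bins=8)
        assert np.allclose(tau.tau[0, :7], 0.125)
        assert tau.tau[0, 7] == pytest.approx(0.075)

    def test_long_beat_tail_discarded(self):
        tau = compute_tau([np.array([1.1])], bin_length=0.125, n_bins=8)
        assert np.allclose(tau.tau[0], 0.125)

    @given(
        st.lists(st.floats(min_value=0.3, max_value=1.8), min_size=1, max_size=20),
    )
    @settings(max_examples=50, deadline=None)
    def test_total_time_conservation(self, rrs):
        """Σ_b τ[l,b] = Σ_i min(RR_i, n_bins·Δ)."""
        rrs = np.asarray(rrs)
        delta = 0.125
        tau = compute_tau([rrs], delta, 8)
        assert tau.tau.sum() == pytest.approx(np.minimum(rrs, 8 * delta).sum(), rel=1e-9)

    def test_tau_nonincreasing_in_bin(self):
        rng = np.random.default_rng(4)
        rrs = rng.normal(0.9, 0.1, 50)
        tau = compute_tau([rrs], 0.9 / 8, 8)
        assert np.all(np.diff(tau.tau[0]) <= 1e-12)


class TestBinEvents:
    def _setup(self):
        beats = _beats([1.0, 1.0, 0.7, 1.0])
        cfg = GateConfig()
        acc = accept_beats(beats, cfg)
        return beats, cfg, acc

    def _sino(self, times, beats, acc, cfg):
        ev = EventStream(
            times=np.asarray(times, dtype=float),
            angle_index=np.zeros(len(times), dtype=np.int64),
            u=np.zeros(len(times), dtype=np.int64),
            v=np.zeros(len(times), dtype=np.int64),
        )
        return bin_events(ev, beats, acc, cfg, detector_shape=(1, 1), angles_deg=(0.0,))

    def test_left_edge_goes_to_first_bin(self):
        beats, cfg, acc = self._setup()
        sino = self._sino([0.0], beats, acc, cfg)
        assert sino.counts[0, 0, 0, 0] == 1

    def test_late_event_goes_to_last_bin(self):
        beats, cfg, acc = self._setup()
        delta = acc.bin_length
        sino = self._sino([7.5 * delta], beats, acc, cfg)
        assert sino.counts[0, 7, 0, 0] == 1

    def test_event_beyond_last_bin_of_long_beat_discarded(self):
        beats = _beats([1.1, 1.0, 1.0])  # all within the ±20% window
        cfg = GateConfig()
        acc = accept_beats(beats, cfg)
        assert acc.accepted.all()
        t = 8.05 * acc.bin_length  # still inside beat 0, past the last bin
        assert t < 1.1
        sino = self._sino([t], beats, acc, cfg)
        assert sino.counts.sum() == 0

    def test_event_in_rejected_beat_discarded(self):
        beats, cfg, acc = self._setup()
        assert not acc.accepted[2]  # the 0.7 s beat
        sino = self._sino([2.1], beats, acc, cfg)  # inside beat 2
        assert sino.counts.sum() == 0

    def test_event_before_first_trigger_discarded(self):
        beats, cfg, acc = self._setup()
        sino = self._sino([-0.5, 0.01], beats, acc, cfg)
        assert sino.counts.sum() == 1


class TestThinLastBin:
    def _fixture(self, last_total=1000, seed=0):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(125, size=(2, 8, 4, 1))
        counts[:, 7] = rng.poisson(last_total / 8, size=(2, 4, 1))
        sino = GatedSinogram(counts=counts, angles_deg=(0.0, 90.0), det_bin_mm=4.0)
        tau = AcquisitionTimeMap(tau=np.full((2, 8), 0.2))
        return sino, tau

    def test_target_equal_to_current_is_identity(self):
        sino, tau = self._fixture()
        current = count_activity_ratio(sino)
        out, out_tau = thin_last_bin(sino, tau, current, seed=1)
        assert np.array_equal(out.counts, sino.counts)
        assert np.allclose(out_tau.tau, tau.tau)

    def test_binomial_thinning_within_3_sigma(self):
        sino, tau = self._fixture()
        current = count_activity_ratio(sino)
        target = 0.5 * current
        total = sino.counts[:, 7].sum()
        out, _ = thin_last_bin(sino, tau, target, seed=2)
        kept = out.counts[:, 7].sum()
        sigma = np.sqrt(total * 0.5 * 0.5)
        assert abs(kept - 0.5 * total) < 3 * sigma

    def test_tau_scaling_contract(self):
        sino, tau = self._fixture()
        current = count_activity_ratio(sino)
        out, out_tau = thin_last_bin(sino, tau, 0.5 * current, seed=3)
        assert np.allclose(out_tau.tau[:, 7], 0.1)
        assert np.allclose(out_tau.tau[:, :7], 0.2)

    def test_other_bins_bit_identical(self):
        sino, tau = self._fixture()
        out, _ = thin_last_bin(sino, tau, 0.3 * count_activity_ratio(sino), seed=4)
        assert np.array_equal(out.counts[:, :7], sino.counts[:, :7])

    def test_target_above_current_raises_unless_clamped(self):
        sino, tau = self._fixture()
        current = count_activity_ratio(sino)
        with pytest.raises(ValueError):
            thin_last_bin(sino, tau, 1.5 * current, seed=5)
        out, _ = thin_last_bin(sino, tau, 1.5 * current, seed=5, clamp=True)
        assert np.array_equal(out.counts, sino.counts)


class TestEventStreamConsistency:
    def test_binned_events_match_expected_counts(
        self, small_phantom, small_geometry, small_projector, gate_config
    ):
        """Re-binning the list-mode stream reproduces the bin-level expected
        counts within Poisson tolerance (χ² test at α = 0.001)."""
        from scipy.stats import chi2

        from gatedspect.phantom import (
            generate_rr_series,
            simulate_event_stream,
            simulate_gated_sinogram,
        )

        beats = generate_rr_series(0.9, 0.05 * 0.9, 8 * 10.0 + 1, seed=8)
        _, _, _, lam = simulate_gated_sinogram(
            small_phantom, beats, small_geometry, gate_config,
            seed=9, dwell_time=10.0, projector=small_projector,
            return_expected=True,
        )
        events = simulate_event_stream(
            small_phantom, beats, small_geometry, gate_config,
            seed=10, dwell_time=10.0, projector=small_projector,
        )
        acc = accept_beats(beats, gate_config)
        sino = bin_events(
            events, beats, acc, gate_config,
            detector_shape=small_geometry.detector_shape,
            angles_deg=small_geometry.angles_deg,
        )
        big = lam > 20
        assert big.sum() > 100
        stat = np.sum((sino.counts[big] - lam[big]) ** 2 / lam[big])
        assert stat < chi2.ppf(0.999, df=int(big.sum()))
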