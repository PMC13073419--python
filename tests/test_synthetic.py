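"""Generators: determinism, distributional behavior, and pipeline recovery."""

from dataclasses import replace

import numpy as np
import pytest

from remact.concordance import cohens_kappa, contingency_table
from remact.counts import compute_activity_counts, enmo, epoch_activity
from remact.grid import Hypnogram, mini_epoch_grid, rem_periods, score_emg_mini_epochs
from remact.synthetic import (
    MotorEvent,
    SimulationConfig,
    TransitionSpec,
    event_occupancy,
    generate_hypnogram,
    generate_latent_events,
    render_accelerometry,
    render_emg_envelope,
    render_modality_annotations,
)


def rem_only(n):
    return Hypnogram(tuple(["R"] * n))


class TestGenerateHypnogram:
    def test_absorbing_state(self):
        spec = TransitionSpec(np.eye(5), np.array([0, 0, 1, 0, 0]))
        hyp = generate_hypnogram(10, spec, seed=0)
        assert hyp.stages == ("N2",) * 10

    def test_same_seed_identical(self):
        a = generate_hypnogram(200, seed=5)
        b = generate_hypnogram(200, seed=5)
        assert a.stages == b.stages
        assert a.stages != generate_hypnogram(200, seed=6).stages

    def test_forced_rem_entry_survives_period_filter(self):
        # W -> R, R absorbing: one REM run of length >= 10 epochs (5 min)
        m = np.eye(5)
        m[0] = [0, 0, 0, 0, 1]
        m[4] = [0, 0, 0, 0, 1]
        hyp = generate_hypnogram(20, TransitionSpec(m, np.array([1, 0, 0, 0, 0])), seed=0)
        periods = rem_periods(hyp)
        assert len(periods) == 1
        assert periods[0].duration >= 300.0

    def test_non_stochastic_matrix_rejected(self):
        m = np.eye(5)
        m[2, 2] = 0.7
        with pytest.raises(ValueError, match="stochastic"):
            TransitionSpec(m, np.array([1, 0, 0, 0, 0]))


class TestGenerateLatentEvents:
    def test_zero_rates_empty(self):
        cfg = SimulationConfig(
            stage_event_rates={s: 0.0 for s in ("W", "N1", "N2", "N3", "R")}
        )
        assert generate_latent_events(rem_only(20), cfg) == []

    def test_poisson_mean_recovered_over_seeds(self):
        hyp = rem_only(120)  # 60 min of REM
        rates = {"W": 0, "N1": 0, "N2": 0, "N3": 0, "R": 2.0}
        counts = [
            len(generate_latent_events(hyp, SimulationConfig(stage_event_rates=rates, seed=s)))
            for s in range(20)
        ]
        # mean of 20 Poisson(120) draws within 3 sigma of its expectation
        assert np.mean(counts) == pytest.approx(120, abs=3 * np.sqrt(120 / 20))

    def test_events_sorted_inside_span_and_within_stage_bouts(self):
        hyp = generate_hypnogram(240, seed=2)
        cfg = SimulationConfig(seed=2)
        events = generate_latent_events(hyp, cfg)
        onsets = [ev.onset for ev in events]
        assert onsets == sorted(onsets)
        for ev in events:
            assert 0 <= ev.onset and ev.offset <= hyp.duration + 1e-9
            assert ev.duration > 0
            # never straddles a stage boundary: the stage is constant over the event
            first = hyp.stages[int(ev.onset // 30)]
            last = hyp.stages[int(min(ev.offset - 1e-6, hyp.duration - 1e-6) // 30)]
            assert first == last == ev.stage

    def test_rem_dominant_rates_give_rem_dominant_occupancy(self):
        stages = tuple(["R"] * 20 + ["N3"] * 20)
        hyp = Hypnogram(stages)
        cfg = SimulationConfig(
            stage_event_rates={"W": 0, "N1": 0, "N2": 0, "N3": 0.2, "R": 4.0}, seed=0
        )
        events = generate_latent_events(hyp, cfg)
        n_rem = sum(ev.stage == "R" for ev in events)
        n_n3 = sum(ev.stage == "N3" for ev in events)
        assert n_rem > n_n3


class TestRenderAccelerometry:
    def test_no_events_no_noise_unit_gravity_and_zero_counts(self):
        cfg = SimulationConfig(noise_sd=0.0)
        rec = render_accelerometry([], rem_only(20), cfg, "L")
        assert np.allclose(rec.magnitude(), 1.0)
        counts = compute_activity_counts(rec)
        assert np.all(counts.values == 0)

    def test_single_event_max_enmo_exceeds_rounding_threshold(self):
        cfg = SimulationConfig(noise_sd=0.0)
        ev = MotorEvent(onset=100.0, duration=2.0, amplitude=0.5, side="L", stage="R")
        rec = render_accelerometry([ev], rem_only(20), cfg, "L")
        window = enmo(rec)[int(100 * cfg.device_rate) : int(102 * cfg.device_rate)]
        assert window.max() > 0.1

    def test_bit_identical_per_seed(self):
        cfg = SimulationConfig(seed=9)
        hyp = generate_hypnogram(60, seed=9)
        events = generate_latent_events(hyp, cfg)
        a = render_accelerometry(events, hyp, cfg, "L")
        b = render_accelerometry(events, hyp, cfg, "L")
        assert np.array_equal(a.z, b.z)

    def test_burst_conservation_and_bilateral_symmetry(self):
        cfg = SimulationConfig(noise_sd=0.0)
        events = [
            MotorEvent(10.0, 1.0, 0.8, "L", "R"),
            MotorEvent(50.0, 1.0, 0.8, "R", "R"),
            MotorEvent(100.0, 1.0, 0.8, "both", "R"),
        ]
        hyp = rem_only(20)
        left = render_accelerometry(events, hyp, cfg, "L")
        right = render_accelerometry(events, hyp, cfg, "R")

        def burst_present(rec, onset, dur):
            i0, i1 = int(onset * 50), int((onset + dur) * 50)
            return np.max(np.abs(rec.z[i0:i1] - 1.0)) > 0.1

        assert burst_present(left, 10, 1) and not burst_present(right, 10, 1)
        assert burst_present(right, 50, 1) and not burst_present(left, 50, 1)
        # bilateral event renders identically on both wrists
        i0, i1 = 100 * 50, 101 * 50
        assert np.array_equal(left.z[i0:i1], right.z[i0:i1])

    def test_event_outside_span_rejected(self):
        cfg = SimulationConfig()
        ev = MotorEvent(onset=590.0, duration=20.0, amplitude=0.5, side="L", stage="R")
        with pytest.raises(ValueError, match="span"):
            render_accelerometry([ev], rem_only(20), cfg, "L")


class TestRenderEmgEnvelope:
    def test_no_events_constant_atonia_nothing_scored(self):
        cfg = SimulationConfig()
        env = render_emg_envelope([], cfg, "L", total_s=600.0)
        assert np.all(env.values == cfg.emg_atonia)
        grid = mini_epoch_grid(rem_periods(rem_only(20)))
        assert score_emg_mini_epochs(env, grid).labels.sum() == 0

    def test_certain_detection_burst_scored_by_rule(self):
        cfg = SimulationConfig(detect_probs={"emg": 1.0, "acti": 1.0, "video": 1.0})
        ev = MotorEvent(onset=100.2, duration=0.5, amplitude=0.5, side="L", stage="R")
        env = render_emg_envelope([ev], cfg, "L", total_s=600.0)
        grid = mini_epoch_grid(rem_periods(rem_only(20)))
        labels = score_emg_mini_epochs(env, grid)
        assert labels.labels.sum() >= 1
        # activity confined to the epochs overlapping the event
        active = np.flatnonzero(labels.labels)
        assert set(active) <= {33, 34}

    def test_subthreshold_burst_multiple_not_scored(self):
        cfg = SimulationConfig(
            detect_probs={"emg": 1.0, "acti": 1.0, "video": 1.0}, emg_burst_multiple=1.5
        )
        ev = MotorEvent(onset=100.2, duration=0.5, amplitude=0.5, side="L", stage="R")
        env = render_emg_envelope([ev], cfg, "L", total_s=600.0)
        grid = mini_epoch_grid(rem_periods(rem_only(20)))
        assert score_emg_mini_epochs(env, grid).labels.sum() == 0


class TestAnnotations:
    def make_events(self, n, spacing=9.0, dur=2.0):
        return [MotorEvent(3.0 + i * spacing, dur, 0.5, "both", "R") for i in range(n)]

    def grid_for(self, n_epochs):
        return mini_epoch_grid(rem_periods(rem_only(n_epochs)))

    def test_certain_detection_equals_occupancy(self):
        cfg = SimulationConfig(
            detect_probs={"emg": 1.0, "acti": 1.0, "video": 1.0},
            fp_rates={"emg": 0.0, "acti": 0.0, "video": 0.0},
        )
        grid = self.grid_for(40)
        events = self.make_events(30)
        labels = render_modality_annotations(events, grid, cfg, "video")
        assert np.array_equal(labels.labels, event_occupancy(events, grid))

    def test_zero_detection_all_zero(self):
        cfg = SimulationConfig(
            detect_probs={"emg": 0.0, "acti": 0.0, "video": 0.0},
            fp_rates={"emg": 0.0, "acti": 0.0, "video": 0.0},
        )
        grid = self.grid_for(40)
        labels = render_modality_annotations(self.make_events(30), grid, cfg, "video")
        assert labels.labels.sum() == 0

    def test_binomial_detection_fraction_over_seeds(self):
        grid = self.grid_for(300)  # 150 min of REM
        events = self.make_events(500, spacing=17.9)
        fracs = []
        for seed in range(20):
            cfg = SimulationConfig(
                detect_probs={"emg": 0.7, "acti": 0.7, "video": 0.7},
                fp_rates={"emg": 0.0, "acti": 0.0, "video": 0.0},
                seed=seed,
            )
            labels = render_modality_annotations(events, grid, cfg, "video")
            detected = [
                labels.labels[(grid.starts < ev.offset) & (grid.ends > ev.onset)].any()
                for ev in events
            ]
            fracs.append(np.mean(detected))
        sigma = np.sqrt(0.7 * 0.3 / 500) / np.sqrt(20)
        assert np.mean(fracs) == pytest.approx(0.7, abs=3 * sigma + 0.01)


class TestStratifiedMagnitude:
    def test_multimodal_events_with_larger_bursts_rank_highest(self):
        """When the events seen by all three modalities carry 5x the burst
        amplitude, the mean actigraphy count is higher for all-three epochs
        than for actigraphy-only epochs."""
        from remact.concordance import stratified_activity_counts

        cfg = SimulationConfig(noise_sd=0.0, seed=0)
        hyp = rem_only(40)
        big = [MotorEvent(60.0 * i + 9.0, 3.0, 2.5, "both", "R") for i in range(1, 10)]
        small = [MotorEvent(60.0 * i + 39.0, 3.0, 0.5, "both", "R") for i in range(1, 10)]
        events = sorted(big + small, key=lambda e: e.onset)
        grid = mini_epoch_grid(rem_periods(hyp))
        counts = compute_activity_counts(render_accelerometry(events, hyp, cfg, "L"))
        acti = epoch_activity(counts, grid)
        multimodal = event_occupancy(big, grid)  # only big events seen by EMG+video
        out = stratified_activity_counts(counts, multimodal, acti, multimodal, grid)
        assert out["all_three"] > out["acti_only"]


class TestPipelineRecovery:
    def test_perfect_detection_large_bursts_kappa_one(self):
        """With certain detection, no false positives and epoch-aligned large
        bursts, actigraphy (through the full count pipeline) and video agree
        perfectly on the REM grid."""
        cfg = SimulationConfig(
            detect_probs={"emg": 1.0, "acti": 1.0, "video": 1.0},
            fp_rates={"emg": 0.0, "acti": 0.0, "video": 0.0},
            seed=1,
        )
        hyp = rem_only(40)
        # epoch-aligned 3 s bursts, well separated, 2 g peak
        events = [MotorEvent(30.0 * i + 9.0, 3.0, 2.0, "both", "R") for i in range(1, 20)]
        rec = render_accelerometry(events, hyp, cfg, "L")
        grid = mini_epoch_grid(rem_periods(hyp))
        acti = epoch_activity(compute_activity_counts(rec), grid)
        video = render_modality_annotations(events, grid, cfg, "video").labels
        assert np.array_equal(acti, video)
        assert cohens_kappa(contingency_table(acti, video)) == pytest.approx(1.0)
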