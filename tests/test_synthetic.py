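"""Generator ground truth: determinism, process statistics, design shapes."""

import numpy as np
import pandas as pd
import pytest

from dyadwarp.errors import DyadwarpError
from dyadwarp.preprocess import remove_impossible_values
from dyadwarp.synthetic_dyads import (
    CouplingSpec,
    inject_artifacts,
    simulate_follower,
    simulate_leader,
    simulate_study,
)

ALL_TASKS = ("truth", "easy_lie", "difficult_lie", "very_difficult_lie")


class TestLeader:
    def test_same_seed_is_identical(self):
        a = simulate_leader(5.0, 120.0, seed=4)
        b = simulate_leader(5.0, 120.0, seed=4)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a = simulate_leader(5.0, 120.0, seed=4)
        b = simulate_leader(5.0, 120.0, seed=5)
        assert not np.allclose(a["gx"], b["gx"])

    def test_stationary_sd_near_target(self):
        lead = simulate_leader(300.0, 120.0, seed=6)
        sds = lead[["gx", "gy", "gz"]].std(ddof=1)
        assert np.all(np.abs(sds - 1.0) < 0.05)

    def test_zero_sigma_gives_constant_stream(self):
        lead = simulate_leader(5.0, 120.0, seed=7, stationary_sd=0.0)
        assert np.all(lead[["gx", "gy", "gz"]].to_numpy() == 0.0)

    def test_invalid_duration_fatal(self):
        with pytest.raises(DyadwarpError):
            simulate_leader(-1.0, 120.0, seed=0)


class TestFollower:
    def test_full_coupling_no_lag_reproduces_leader(self):
        lead = simulate_leader(10.0, 120.0, seed=8)
        spec = CouplingSpec(kappa=1.0, tau0=0.0, lag_drift=0.0, noise_sd=0.0)
        follow = simulate_follower(lead, spec, seed=9)
        assert np.allclose(
            follow[["gx", "gy", "gz"]].to_numpy(), lead[["gx", "gy", "gz"]].to_numpy()
        )

    def test_zero_coupling_is_independent(self):
        lead = simulate_leader(300.0, 120.0, seed=10)
        spec = CouplingSpec(kappa=0.0, tau0=0.0, lag_drift=0.0, noise_sd=0.0)
        follow = simulate_follower(lead, spec, seed=11)
        r = np.corrcoef(lead["gx"], follow["gx"])[0, 1]
        assert abs(r) < 0.1

    @pytest.mark.parametrize("kappa", [0.0, 0.5, 1.0])
    def test_variance_preserved_across_coupling(self, kappa):
        lead = simulate_leader(300.0, 120.0, seed=12, start_s=-2.0)
        spec = CouplingSpec(kappa=kappa, tau0=0.5, lag_drift=0.2, noise_sd=0.0)
        follow = simulate_follower(lead, spec, seed=13)
        lead_sd = lead[["gx", "gy", "gz"]].std(ddof=1).mean()
        follow_sd = follow[["gx", "gy", "gz"]].std(ddof=1).mean()
        assert abs(follow_sd / lead_sd - 1.0) < 0.05

    def test_lag_exceeding_duration_fatal(self):
        lead = simulate_leader(2.0, 120.0, seed=14)
        with pytest.raises(DyadwarpError, match="lag"):
            simulate_follower(lead, CouplingSpec(tau0=5.0), seed=15)


class TestArtifacts:
    def _device_stream(self, seed, duration=300.0):
        lead = simulate_leader(duration, 120.0, seed=seed)
        out = lead.copy()
        for c in ("gx", "gy", "gz"):
            out[c] = np.round(out[c] * 100).astype(np.int64)
        return out

    def test_zero_rate_identity_apart_from_offset(self):
        dev = self._device_stream(16, duration=10.0)
        spec = CouplingSpec(artifact_rate=0.0, clock_offset_ms=500)
        out, spikes = inject_artifacts(dev, spec, seed=17)
        assert spikes.size == 0
        expected = dev[dev["t_ms"] >= 500].reset_index(drop=True)
        pd.testing.assert_frame_equal(out, expected)

    def test_spike_count_within_binomial_bounds(self):
        dev = self._device_stream(18)  # 36 000 samples
        out, spikes = inject_artifacts(dev, CouplingSpec(artifact_rate=0.005), seed=19)
        assert 126 <= spikes.size <= 234  # 180 +/- 3 sd

    def test_screening_removes_exactly_the_injected_spikes(self):
        dev = self._device_stream(20)
        out, spikes = inject_artifacts(dev, CouplingSpec(artifact_rate=0.005), seed=21)
        cleaned, removed = remove_impossible_values(out, (-500, 500))
        assert removed == spikes.size
        kept_t = set(cleaned["t_ms"])
        spike_t = set(out["t_ms"].to_numpy()[spikes])
        assert kept_t.isdisjoint(spike_t)


class TestStudy:
    def test_exp1_design_counts(self):
        sessions, judgements, truth = simulate_study(n_dyads=43, design="exp1", seed=22, sites=())
        assert len(sessions) == 43
        counts = truth.kappa["task"].value_counts()
        assert counts["truth"] == 43
        assert counts["easy_lie"] == 43
        assert counts["difficult_lie"] == 22
        assert counts["very_difficult_lie"] == 21
        assert len(judgements) == 43 * 3

    def test_exp2_design_counts_and_instructions(self):
        sessions, judgements, truth = simulate_study(n_dyads=42, design="exp2", seed=23, sites=())
        instr = pd.Series([s.conditions["attention_instruction"] for s in sessions]).value_counts()
        assert instr["nonverbal"] == 12 and instr["verbal"] == 14 and instr["none"] == 16
        assert set(truth.kappa["task"]) == {"truth", "easy_lie", "very_difficult_lie"}

    def test_determinism_and_counter_based_substreams(self):
        # exp2: every dyad has the same task set, so the per-dyad streams
        # must be invariant to the total number of dyads generated
        s1, j1, t1 = simulate_study(n_dyads=3, design="exp2", seed=24, sites=("head",))
        s2, j2, t2 = simulate_study(n_dyads=3, design="exp2", seed=24, sites=("head",))
        for a, b in zip(s1, s2):
            for k in a.streams:
                pd.testing.assert_frame_equal(a.streams[k], b.streams[k])
        pd.testing.assert_frame_equal(j1, j2)
        s3, j3, _ = simulate_study(n_dyads=5, design="exp2", seed=24, sites=("head",))
        for a, b in zip(s1, s3):
            for k in a.streams:
                pd.testing.assert_frame_equal(a.streams[k], b.streams[k])

    def test_judgement_accuracy_matches_targets(self):
        from dyadwarp.stats import code_judgements

        acc = {"easy_lie": 0.16, "difficult_lie": 0.32, "very_difficult_lie": 0.57, "truth": 0.63}
        _, judgements, _ = simulate_study(
            n_dyads=2000, design="exp1", judgement_accuracy_by_task=acc, seed=25, sites=()
        )
        judgements["coded"] = code_judgements(judgements)
        got = (
            judgements.assign(ok=judgements["coded"] == "correct")
            .groupby("task")["ok"]
            .mean()
        )
        for task, p in acc.items():
            assert abs(got[task] - p) < 0.03

    def test_kappa_reflects_dyad_effect(self):
        _, _, truth = simulate_study(n_dyads=20, design="exp1", seed=26, sites=())
        merged = truth.kappa.copy()
        merged["b"] = merged["dyad_id"].map(truth.dyad_effect)
        base = {"easy_lie": 0.20, "truth": 0.30, "difficult_lie": 0.45, "very_difficult_lie": 0.60}
        expect = np.clip(merged["task"].map(base) + merged["b"], 0.0, 1.0)
        assert np.allclose(merged["kappa"], expect)

    def test_unknown_design_fatal(self):
        with pytest.raises(DyadwarpError, match="design"):
            simulate_study(n_dyads=2, design="exp3", seed=0)


class TestKernelIndependence:
    def test_coupling_detectable_for_either_movement_kernel(self):
        # The pipeline must not depend on the OU kernel choice: a smoothed
        # white-noise kernel with the same coupling structure must order
        # scores the same way.
        from dyadwarp.coordination import score_part
        from dyadwarp.preprocess import CleanSegment, downsample_5hz, standardize_z1000

        def score_for(leader_vals, kappa, rng):
            lag = 60  # 0.5 s at 120 Hz
            indep = rng.normal(size=leader_vals.shape)
            follow = kappa * np.roll(leader_vals, lag, axis=0) + np.sqrt(1 - kappa**2) * indep
            t = (np.round(np.arange(len(leader_vals)) * 1000.0 / 120.0)).astype(np.int64)
            mk = lambda v: pd.DataFrame({"t_ms": t, "gx": v[:, 0], "gy": v[:, 1], "gz": v[:, 2]})
            fa = standardize_z1000(downsample_5hz(mk(leader_vals)))
            fb = standardize_z1000(downsample_5hz(mk(follow)))
            n = min(len(fa), len(fb))
            a = CleanSegment(site="head", role="interviewer", task="truth", frames=fa[:n])
            b = CleanSegment(site="head", role="interviewee", task="truth", frames=fb[:n])
            return score_part((a, b))

        n = 120 * 30
        rng = np.random.default_rng(27)
        # kernel 1: OU; kernel 2: Gaussian-smoothed white noise
        ou = simulate_leader(30.0, 120.0, seed=28)[["gx", "gy", "gz"]].to_numpy()
        from scipy.ndimage import gaussian_filter1d

        wn = gaussian_filter1d(rng.normal(size=(n, 3)), sigma=40, axis=0)
        wn /= wn.std(axis=0, ddof=1)
        for kernel in (ou, wn):
            hi = score_for(kernel, 0.8, np.random.default_rng(29))
            lo = score_for(kernel, 0.1, np.random.default_rng(29))
            assert hi > lo
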