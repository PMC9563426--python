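"""Automated vigilance-state scoring: features, threshold cascade,
smoothing rules, hypnogram I/O."""

import numpy as np
import pytest

import somnospec as sp
from somnospec.staging import (
    EpochFeatures,
    Hypnogram,
    _absorb_short_runs,
    _forbid_wake_to_rem,
)


def make_features(swa, theta_ratio, movement):
    return EpochFeatures(
        swa=np.asarray(swa, dtype=float),
        theta_ratio=np.asarray(theta_ratio, dtype=float),
        movement=np.asarray(movement, dtype=float),
    )


def clustered_features(labels, swa_levels, theta_levels, mov_levels):
    labels = np.asarray(labels)
    idx = {"WAKE": 0, "NREM": 1, "REM": 2}
    pick = np.array([idx[s] for s in labels])
    return make_features(
        np.asarray(swa_levels)[pick],
        np.asarray(theta_levels)[pick],
        np.asarray(mov_levels)[pick],
    )


class TestExtractFeatures:
    def test_synthetic_extremes(self):
        """Pure delta content with a still accelerometer gives high SWA,
        low theta ratio and near-zero movement; pure theta flips the ratio."""
        fs = 400.0
        t = np.arange(int(30 * fs)) / fs
        rng = np.random.default_rng(0)

        def build(freq):
            wave = np.sin(2 * np.pi * freq * t) + 0.01 * rng.standard_normal(len(t))
            data = np.vstack([wave, wave, wave, wave,
                              1e-4 * rng.standard_normal((3, len(t)))])
            return sp.Recording(
                data=data, sample_rate=fs,
                channel_names=["EEG FrontL", "EEG FrontR", "EEG ParL",
                               "EEG ParR", "ACC X", "ACC Y", "ACC Z"],
                channel_roles=["frontal", "frontal", "parietal", "parietal",
                               "accelerometer", "accelerometer", "accelerometer"],
            )

        delta_rec = build(2.0)
        feats = sp.extract_features(sp.compute_epoch_spectra(delta_rec), delta_rec)
        assert feats.theta_ratio.mean() < 0.5
        assert feats.movement.mean() < 1e-4

        theta_rec = build(7.0)
        feats = sp.extract_features(sp.compute_epoch_spectra(theta_rec), theta_rec)
        assert feats.theta_ratio.mean() > 0.5

    def test_missing_accelerometer_is_an_error(self):
        rec = sp.Recording(
            data=np.zeros((2, 4000)), sample_rate=400.0,
            channel_names=["EEG FrontL", "EEG ParL"],
            channel_roles=["frontal", "parietal"],
        )
        spectra = sp.compute_epoch_spectra(rec)
        with pytest.raises(ValueError, match="accelerometer"):
            sp.extract_features(spectra, rec)

    def test_swa_tracks_nrem(self, short_recording, short_spectra):
        rec, truth = short_recording
        feats = sp.extract_features(short_spectra, rec)
        nrem = (truth.hypnogram == "NREM").astype(float)
        r = np.corrcoef(feats.swa, nrem)[0, 1]
        assert r > 0.5


class TestScoreStates:
    def test_perfectly_separated_clusters_are_exact(self):
        rng = np.random.default_rng(1)
        labels = rng.choice(["WAKE", "NREM", "REM"], size=300)
        feats = clustered_features(
            labels, swa_levels=[1.0, 100.0, 1.0],
            theta_levels=[0.1, 0.1, 0.9], mov_levels=[100.0, 0.01, 0.01],
        )
        h = sp.score_states(feats, min_bout_s=1, forbid_wake_to_rem=False)
        assert (h.labels == labels).mean() == 1.0

    def test_scoring_is_deterministic(self, short_recording, short_spectra):
        rec, _ = short_recording
        feats = sp.extract_features(short_spectra, rec)
        a = sp.score_states(feats)
        b = sp.score_states(feats)
        assert np.array_equal(a.labels, b.labels)

    def test_degenerate_features_warn_and_yield_single_state(self):
        feats = make_features(np.ones(100), np.ones(100) * 0.5, np.zeros(100))
        with pytest.warns(UserWarning, match="degenerate"):
            h = sp.score_states(feats)
        assert len(set(h.labels)) == 1

    def test_too_short_input_rejected(self):
        feats = make_features(np.ones(10), np.ones(10), np.ones(10))
        with pytest.raises(ValueError, match="60"):
            sp.score_states(feats)

    def test_thresholds_are_logged_for_audit(self, short_recording, short_spectra):
        rec, _ = short_recording
        feats = sp.extract_features(short_spectra, rec)
        h = sp.score_states(feats)
        assert set(h.meta["thresholds"]) == {"log_movement", "log_swa",
                                             "theta_ratio"}

    def test_signature_swap_swaps_labels(self, short_config):
        """Swapping the NREM/REM spectral signatures in the generator swaps
        the recovered labels (movement variances swapped as well)."""
        import copy

        cfg = copy.deepcopy(short_config)
        comps = cfg.spectral_components
        comps["NREM"], comps["REM"] = comps["REM"], comps["NREM"]
        mv = cfg.movement_variance
        mv["NREM"], mv["REM"] = mv["REM"], mv["NREM"]
        truth = sp.sample_hypnogram(cfg, 11)
        rec = sp.synthesize_signals(truth, cfg, 12)
        feats = sp.extract_features(sp.compute_epoch_spectra(rec), rec)
        h = sp.score_states(feats, forbid_wake_to_rem=False)
        swapped = {"WAKE": "WAKE", "NREM": "REM", "REM": "NREM"}
        target = np.array([swapped[s] for s in truth.hypnogram])
        assert (h.labels == target).mean() > 0.8

    def test_accuracy_degrades_with_state_separation(self):
        """Shrinking the oscillatory contrast between states degrades
        scoring accuracy monotonically across three levels."""
        import copy

        from somnospec.experiments import scaled_config

        accs = []
        for contrast in (1.0, 0.35, 0.1):
            cfg = copy.deepcopy(scaled_config(900, 400.0, 0.25))
            for state in cfg.spectral_components:
                for role, comps in cfg.spectral_components[state].items():
                    cfg.spectral_components[state][role] = [
                        sp.SpectralComponent(
                            c.center_hz, c.bandwidth_hz,
                            1.0 + (c.amplitude - 1.0) * contrast,
                        )
                        for c in comps
                    ]
            acc = []
            for seed in (21, 22, 23):
                truth = sp.sample_hypnogram(cfg, seed)
                rec = sp.synthesize_signals(truth, cfg, seed + 100)
                feats = sp.extract_features(sp.compute_epoch_spectra(rec), rec)
                h = sp.score_states(feats)
                acc.append((h.labels == truth.hypnogram).mean())
            accs.append(np.mean(acc))
        assert accs[0] > accs[1] > accs[2]


class TestSmoothingRules:
    def test_short_run_absorbed_into_longer_flank(self):
        labels = np.array(["NREM"] * 5 + ["REM"] * 2 + ["NREM"] * 5)
        out = _absorb_short_runs(labels, 3)
        assert (out == "NREM").all()

    def test_tie_goes_to_preceding_state(self):
        labels = np.array(["WAKE"] * 3 + ["REM"] * 2 + ["NREM"] * 3)
        out = _absorb_short_runs(labels, 3)
        assert list(out[3:5]) == ["WAKE", "WAKE"]

    def test_edge_runs_keep_their_length(self):
        labels = np.array(["REM"] * 2 + ["NREM"] * 10 + ["WAKE"] * 1)
        out = _absorb_short_runs(labels, 3)
        assert list(out[:2]) == ["REM", "REM"] and out[-1] == "WAKE"

    def test_no_interior_run_below_minimum_after_smoothing(self):
        rng = np.random.default_rng(6)
        labels = rng.choice(["WAKE", "NREM", "REM"], size=500)
        out = _absorb_short_runs(labels, 3)
        runs, start = [], 0
        for i in range(1, len(out) + 1):
            if i == len(out) or out[i] != out[start]:
                runs.append(i - start)
                start = i
        assert all(r >= 3 for r in runs[1:-1])

    def test_rem_after_wake_is_relabelled(self):
        labels = np.array(["WAKE"] * 20 + ["REM"] * 5 + ["WAKE"] * 5)
        out = _forbid_wake_to_rem(labels)
        assert "REM" not in out

    def test_rem_after_nrem_is_kept(self):
        labels = np.array(["NREM"] * 20 + ["REM"] * 5 + ["WAKE"] * 5)
        out = _forbid_wake_to_rem(labels)
        assert (out[20:25] == "REM").all()


class TestHypnogramIO:
    def test_round_trip(self, tmp_path):
        h = Hypnogram(np.array(["WAKE", "NREM", "NREM", "REM"]))
        path = tmp_path / "h.csv"
        sp.save_hypnogram(h, path)
        assert sp.load_hypnogram(path) == h

    def test_unknown_token_reports_line(self, tmp_path):
        path = tmp_path / "h.csv"
        path.write_text("epoch_start_s,state\n0,WAKE\n1,N1\n")
        with pytest.raises(ValueError, match="line 3.*N1"):
            sp.load_hypnogram(path)

    def test_non_contiguous_epochs_rejected(self, tmp_path):
        path = tmp_path / "h.csv"
        path.write_text("epoch_start_s,state\n0,WAKE\n1,WAKE\n5,NREM\n")
        with pytest.raises(ValueError, match="non-contiguous"):
            sp.load_hypnogram(path)

    def test_ground_truth_provenance(self, tmp_path):
        h = Hypnogram(np.array(["WAKE"] * 3), provenance="ground-truth")
        path = tmp_path / "truth.csv"
        sp.save_hypnogram(h, path)
        loaded = sp.load_hypnogram(path, provenance="ground-truth")
        assert loaded.provenance == "ground-truth"
        assert loaded == h
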