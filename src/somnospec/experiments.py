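"""Cohort-level recovery and calibration experiments.

These functions run the full pipeline on synthetic cohorts and measure how
well it recovers the configured architecture and spectral phenotypes, and
how the statistical layer behaves under the null. They are shared by the
analysis drivers, the test suite and the results-reproduction script.

Problem sizes: the full study conditions are 12-h recordings at 1 kHz, but
staging and spectral recovery are measured on shorter sessions (1 h and
20 min respectively) at 400 Hz — still Nyquist-safe for the ripple band —
so a complete reproduction runs on a laptop in minutes. Architecture
experiments need only hypnograms and use the full 12-h duration.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .group_stats import gated_two_group_test, run_comparison_suite, sex_ratio_test
from .hypno_metrics import compute_architecture, cohort_table
from .pipeline import process_recording
from .spectral import compute_epoch_spectra
from .staging import Hypnogram, extract_features, score_states
from .synth import (
    GenotypeEffects,
    SimConfig,
    default_mutant_effects,
    sample_hypnogram,
    simulate_cohort,
    synthesize_signals,
)

#: EEG cohort shape of the study this pipeline models (mutant n=5, WT n=9)
COHORT_N_WT = 9
COHORT_N_MUT = 5

#: sex counts (females, males) per genotype for the two cohorts
SEX_TABLE_MOTOR = [[5, 6], [5, 7]]
SEX_TABLE_EEG = [[3, 2], [5, 4]]


def _seeds(master_seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(master_seed).generate_state(n) >> 1]


def scaled_config(duration_s: int, sample_rate: float = 400.0,
                  dwell_scale: float = 0.15) -> SimConfig:
    """Time-compressed study conditions for signal-bearing experiments.

    Shortening a 12-h session without touching bout durations would leave
    only a handful of sleep-wake cycles per recording, making the state
    composition — and with it the normalization medians — wildly variable
    between animals. Scaling dwell means by ``dwell_scale`` keeps the
    number of cycles per recording close to a full-length session.
    """
    cfg = SimConfig(duration_s=duration_s, sample_rate=sample_rate)
    cfg.dwell = {
        s: type(d)(max(d.mean_s * dwell_scale, 2.0), d.cv)
        for s, d in cfg.dwell.items()
    }
    return cfg


def _f1(truth: np.ndarray, pred: np.ndarray, state: str) -> float:
    tp = np.sum((truth == state) & (pred == state))
    fp = np.sum((truth != state) & (pred == state))
    fn = np.sum((truth == state) & (pred != state))
    denom = 2 * tp + fp + fn
    return 2 * tp / denom if denom else float("nan")


def staging_recovery(
    master_seed: int,
    n_seeds: int = 10,
    duration_s: int = 3600,
    sample_rate: float = 400.0,
) -> pd.DataFrame:
    """Score synthetic recordings and compare against the true hypnogram.

    One wild-type animal per seed. Returns per-seed epoch accuracy and
    per-state F1.
    """
    rows = []
    for seed in _seeds(master_seed, n_seeds):
        cfg = SimConfig(duration_s=duration_s, sample_rate=sample_rate)
        truth = sample_hypnogram(cfg, seed)
        rec = synthesize_signals(truth, cfg, seed + 1)
        spectra = compute_epoch_spectra(rec)
        feats = extract_features(spectra, rec)
        h = score_states(feats)
        t = truth.hypnogram[: len(h.labels)]
        rows.append(
            {
                "seed": seed,
                "accuracy": float(np.mean(h.labels == t)),
                "f1_WAKE": _f1(t, h.labels, "WAKE"),
                "f1_NREM": _f1(t, h.labels, "NREM"),
                "f1_REM": _f1(t, h.labels, "REM"),
            }
        )
    return pd.DataFrame(rows)


def architecture_recovery(
    master_seed: int,
    n_seeds: int = 20,
    n_wt: int = COHORT_N_WT,
    n_mut: int = COHORT_N_MUT,
    duration_s: int = 43_200,
    effects: GenotypeEffects | None = None,
) -> pd.DataFrame:
    """Fragmentation-phenotype recovery from ground-truth hypnograms.

    For each master seed, simulates a cohort (hypnograms only), runs the
    architecture metrics and the comparison suite, and records per state
    whether mutants show more bouts and shorter bouts (direction) and
    whether those contrasts are significant after Bonferroni correction.
    """
    if effects is None:
        effects = default_mutant_effects()
    rows = []
    for seed in _seeds(master_seed, n_seeds):
        cfg = SimConfig(duration_s=duration_s)
        cohort = simulate_cohort(n_wt, n_mut, cfg, seed,
                                 mutant_effects=effects, signals=False)
        archs = [
            compute_architecture(Hypnogram(a.truth.hypnogram), a.animal_id,
                                 a.genotype)
            for a in cohort
        ]
        report = run_comparison_suite(cohort_table(archs))
        row: dict = {"seed": seed}
        for state in ("WAKE", "NREM", "REM"):
            nb = report.query("metric == 'n_bouts' and state == @state").iloc[0]
            mb = report.query("metric == 'mean_bout_s' and state == @state").iloc[0]
            row[f"n_bouts_up_{state}"] = nb["mean_mut"] > nb["mean_wt"]
            row[f"mean_bout_down_{state}"] = mb["mean_mut"] < mb["mean_wt"]
            row[f"n_bouts_sig_{state}"] = bool(nb["significant"])
            row[f"mean_bout_sig_{state}"] = bool(mb["significant"])
        rem_total = report.query("metric == 'total_s' and state == 'REM'").iloc[0]
        row["rem_total_up"] = rem_total["mean_mut"] > rem_total["mean_wt"]
        rows.append(row)
    df = pd.DataFrame(rows)
    flags = [c for c in df.columns
             if c.startswith(("n_bouts_up", "mean_bout_down"))]
    df["fragmentation_recovered"] = df[flags].all(axis=1)
    return df


#: the spectral phenotype contrasts the suite is expected to recover,
#: as (state, role, band, direction) with direction +1 = higher in mutants
SPECTRAL_CONTRASTS = (
    ("REM", "frontal", "beta", +1),
    ("REM", "parietal", "beta", +1),
    ("NREM", "parietal", "beta", +1),
    ("WAKE", "parietal", "delta", +1),
    ("WAKE", "parietal", "gamma", -1),
)


def cohort_spectral_tables(cohort, use_truth: bool = True):
    """Per-animal band summaries and theta peaks for a simulated cohort."""
    summaries, theta_rows = [], []
    for a in cohort:
        h = Hypnogram(a.truth.hypnogram, provenance="ground-truth")
        if not use_truth:
            spectra = compute_epoch_spectra(a.recording)
            h = score_states(extract_features(spectra, a.recording))
        table, summary, peaks = process_recording(a.recording, h)
        summary.insert(0, "animal", a.animal_id)
        summary.insert(1, "genotype", a.genotype)
        summaries.append(summary)
        for role, hz in peaks.items():
            theta_rows.append({"animal": a.animal_id, "genotype": a.genotype,
                               "role": role, "theta_peak_hz": hz})
    return pd.concat(summaries, ignore_index=True), pd.DataFrame(theta_rows)


def spectral_recovery(
    master_seed: int,
    n_seeds: int = 20,
    n_wt: int = COHORT_N_WT,
    n_mut: int = COHORT_N_MUT,
    duration_s: int = 3600,
    sample_rate: float = 400.0,
    dwell_scale: float = 0.15,
    effects: GenotypeEffects | None = None,
) -> pd.DataFrame:
    """Spectral-phenotype recovery on ground-truth hypnograms.

    Per master seed: simulate a cohort with signals, quantify band power,
    run the comparison suite, and record for each configured contrast
    whether it is recovered (correct direction and adjusted p < 0.05), plus
    the recovered mutant-minus-wild-type REM theta peak shift in Hz
    (averaged over roles).
    """
    if effects is None:
        effects = default_mutant_effects()
    rows = []
    for seed in _seeds(master_seed, n_seeds):
        cfg = scaled_config(duration_s, sample_rate, dwell_scale)
        cohort = simulate_cohort(n_wt, n_mut, cfg, seed, mutant_effects=effects)
        band_summary, theta_df = cohort_spectral_tables(cohort)
        report = run_comparison_suite(
            band_summary=band_summary, theta_peaks=theta_df,
            on_insufficient="skip",
        )
        row: dict = {"seed": seed}
        for state, role, band, direction in SPECTRAL_CONTRASTS:
            sub = report.query(
                "state == @state and role == @role and band == @band"
            )
            if len(sub) == 0:
                row[f"{state}_{role}_{band}"] = False
                continue
            r = sub.iloc[0]
            right_dir = (r["mean_mut"] - r["mean_wt"]) * direction > 0
            row[f"{state}_{role}_{band}"] = bool(right_dir and r["significant"])
        shifts = []
        for role in ("frontal", "parietal"):
            sub = theta_df[theta_df["role"] == role].dropna()
            wt = sub.loc[sub["genotype"] == "WT", "theta_peak_hz"]
            mut = sub.loc[sub["genotype"] == "MUT", "theta_peak_hz"]
            if len(wt) and len(mut):
                shifts.append(mut.mean() - wt.mean())
        row["theta_shift_hz"] = float(np.mean(shifts)) if shifts else np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    names = [f"{s}_{r}_{b}" for s, r, b, _ in SPECTRAL_CONTRASTS]
    df["all_contrasts_recovered"] = df[names].all(axis=1)
    return df


def null_calibration(
    master_seed: int,
    n_seeds: int = 100,
    n_wt: int = COHORT_N_WT,
    n_mut: int = COHORT_N_MUT,
    arch_duration_s: int = 43_200,
    spectral_duration_s: int = 600,
    sample_rate: float = 400.0,
) -> pd.DataFrame:
    """Family-wise false-positive rate with no genotype effects.

    Architecture families use full 12-h hypnograms (cheap); spectral
    families use short signal-bearing recordings. Returns one row per
    Bonferroni family with the fraction of seeds flagging any comparison
    in that family as significant.
    """
    null = GenotypeEffects()
    fam_hits: dict[str, int] = {}
    fam_seen: dict[str, int] = {}
    for seed in _seeds(master_seed, n_seeds):
        cfg = SimConfig(duration_s=arch_duration_s)
        cohort = simulate_cohort(n_wt, n_mut, cfg, seed,
                                 mutant_effects=null, signals=False)
        archs = [
            compute_architecture(Hypnogram(a.truth.hypnogram), a.animal_id,
                                 a.genotype)
            for a in cohort
        ]
        scfg = scaled_config(spectral_duration_s, sample_rate)
        scohort = simulate_cohort(n_wt, n_mut, scfg, seed + 1,
                                  mutant_effects=null)
        band_summary, theta_df = cohort_spectral_tables(scohort)
        report = run_comparison_suite(
            cohort_table(archs), band_summary, theta_df, on_insufficient="skip"
        )
        for fam, sub in report.groupby("family"):
            fam_seen[fam] = fam_seen.get(fam, 0) + 1
            fam_hits[fam] = fam_hits.get(fam, 0) + int(sub["significant"].any())
    rows = [
        {"family": fam, "n_seeds": fam_seen[fam],
         "false_positive_rate": fam_hits[fam] / fam_seen[fam]}
        for fam in sorted(fam_seen)
    ]
    return pd.DataFrame(rows)


def gate_type_i_error(
    master_seed: int,
    n_reps: int = 2000,
    n_a: int = COHORT_N_MUT,
    n_b: int = COHORT_N_WT,
    dist: str = "normal",
    alpha: float = 0.05,
) -> float:
    """Rejection rate of the gated two-group test under an exchangeable null."""
    rng = np.random.default_rng(master_seed)
    hits = 0
    for _ in range(n_reps):
        if dist == "normal":
            x, y = rng.standard_normal(n_a), rng.standard_normal(n_b)
        elif dist == "lognormal":
            x, y = rng.lognormal(size=n_a), rng.lognormal(size=n_b)
        else:
            raise ValueError(f"unknown dist {dist!r}")
        hits += gated_two_group_test(x, y).p < alpha
    return hits / n_reps


def sex_ratio_pvalues() -> dict[str, float]:
    """Chi-square p-values for the printed genotype-by-sex count tables."""
    return {
        "motor_cohort": sex_ratio_test(np.asarray(SEX_TABLE_MOTOR)).p,
        "eeg_cohort": sex_ratio_test(np.asarray(SEX_TABLE_EEG)).p,
    }
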