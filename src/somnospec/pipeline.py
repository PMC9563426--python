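"""End-to-end pipeline driver: simulate -> score -> spectra -> metrics -> compare.

Every stage writes CSV outputs under the run directory and is recorded in a
JSON run manifest (config snapshot, seeds, per-stage output paths, SHA-256
hashes, software version, timestamps). A fixed master seed yields
byte-identical CSV outputs on rerun.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .edf import read_recording, write_edf
from .group_stats import run_comparison_suite
from .hypno_metrics import compute_architecture, cohort_table
from .spectral import (
    band_table_to_frame,
    compute_epoch_spectra,
    flag_outliers,
    integrate_bands,
    normalize_power,
    state_band_summary,
    theta_peak_frequency,
)
from .staging import Hypnogram, extract_features, load_hypnogram, save_hypnogram, score_states
from .synth import SimConfig, default_mutant_effects, simulate_cohort


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def process_recording(recording, hypnogram, outlier_k: float = 15.0):
    """Spectral quantification for one animal.

    Returns (band_table, state summary DataFrame, theta peak dict).
    """
    spectra = compute_epoch_spectra(recording)
    table = integrate_bands(spectra)
    table = flag_outliers(table, k=outlier_k)
    table = normalize_power(table)
    labels = hypnogram.labels[: table.raw.shape[0]]
    summary = state_band_summary(table, labels)
    peaks = theta_peak_frequency(spectra, labels, outlier=table.outlier)
    return table, summary, peaks


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


DEFAULT_CONFIG = {
    "n_wt": 9,
    "n_mut": 5,
    "duration_s": 1200,
    "sample_rate": 400.0,
    "use_ground_truth_hypnograms": False,
    "min_bout_s": 3,
    "outlier_k": 15.0,
    "mutant_effects": True,
    "write_edf": True,
}


def run_pipeline(config: dict, out_dir, seed: int) -> dict:
    """Run the full synthetic-cohort analysis; returns the manifest dict."""
    cfg = {**DEFAULT_CONFIG, **(config or {})}
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": seed,
        "config": cfg,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }
    manifest_path = out / "manifest.json"

    def record_stage(name: str, outputs: list[Path]) -> None:
        manifest["stages"][name] = {
            "outputs": [
                {"path": str(p.relative_to(out)), "sha256": _sha256(p)}
                for p in outputs
            ]
        }
        manifest_path.write_text(json.dumps(manifest, indent=1))

    def fail(stage: str, exc: Exception) -> None:
        manifest["failed_stage"] = stage
        manifest_path.write_text(json.dumps(manifest, indent=1))
        raise PipelineError(stage, exc) from exc

    # --- simulate -----------------------------------------------------------
    try:
        sim = SimConfig(duration_s=int(cfg["duration_s"]),
                        sample_rate=float(cfg["sample_rate"]))
        effects = default_mutant_effects() if cfg["mutant_effects"] else None
        cohort = simulate_cohort(cfg["n_wt"], cfg["n_mut"], sim, seed,
                                 mutant_effects=effects)
        outputs = []
        edf_dir = out / "recordings"
        edf_dir.mkdir(exist_ok=True)
        for a in cohort:
            truth_csv = edf_dir / f"{a.animal_id}_truth.csv"
            save_hypnogram(Hypnogram(a.truth.hypnogram, provenance="ground-truth"),
                           truth_csv)
            outputs.append(truth_csv)
            if cfg["write_edf"]:
                p = write_edf(a.recording, edf_dir / f"{a.animal_id}.edf")
                outputs.extend([p, Path(f"{p}.json")])
        record_stage("simulate", outputs)
    except Exception as e:  # noqa: BLE001 - abort with stage name
        fail("simulate", e)

    # --- score --------------------------------------------------------------
    hypnograms: dict[str, Hypnogram] = {}
    try:
        outputs = []
        for a in cohort:
            rec = (read_recording(out / "recordings" / f"{a.animal_id}.edf")
                   if cfg["write_edf"] else a.recording)
            if cfg["use_ground_truth_hypnograms"]:
                h = Hypnogram(a.truth.hypnogram, provenance="ground-truth")
            else:
                spectra = compute_epoch_spectra(rec)
                feats = extract_features(spectra, rec)
                h = score_states(feats, min_bout_s=int(cfg["min_bout_s"]))
            hypnograms[a.animal_id] = h
            p = out / f"{a.animal_id}_hypnogram.csv"
            save_hypnogram(h, p)
            outputs.append(p)
        record_stage("score", outputs)
    except Exception as e:  # noqa: BLE001
        fail("score", e)

    # --- spectra ------------------------------------------------------------
    try:
        summaries, theta_rows = [], []
        for a in cohort:
            rec = (read_recording(out / "recordings" / f"{a.animal_id}.edf")
                   if cfg["write_edf"] else a.recording)
            table, summary, peaks = process_recording(
                rec, hypnograms[a.animal_id], outlier_k=float(cfg["outlier_k"])
            )
            summary.insert(0, "animal", a.animal_id)
            summary.insert(1, "genotype", a.genotype)
            summaries.append(summary)
            for role, hz in peaks.items():
                theta_rows.append({"animal": a.animal_id, "genotype": a.genotype,
                                   "role": role, "theta_peak_hz": hz})
        band_summary = pd.concat(summaries, ignore_index=True)
        theta_df = pd.DataFrame(theta_rows)
        p1 = out / "band_summary.csv"
        p2 = out / "theta_peaks.csv"
        band_summary.to_csv(p1, index=False)
        theta_df.to_csv(p2, index=False)
        record_stage("spectra", [p1, p2])
    except Exception as e:  # noqa: BLE001
        fail("spectra", e)

    # --- metrics ------------------------------------------------------------
    try:
        archs = [
            compute_architecture(hypnograms[a.animal_id], a.animal_id, a.genotype)
            for a in cohort
        ]
        arch_df = cohort_table(archs)
        p = out / "architecture.csv"
        arch_df.to_csv(p, index=False)
        record_stage("metrics", [p])
    except Exception as e:  # noqa: BLE001
        fail("metrics", e)

    # --- compare ------------------------------------------------------------
    try:
        report = run_comparison_suite(arch_df, band_summary, theta_df,
                                      on_insufficient="skip")
        p = out / "comparisons.csv"
        report.to_csv(p, index=False)
        record_stage("compare", [p])
    except Exception as e:  # noqa: BLE001
        fail("compare", e)

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest
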