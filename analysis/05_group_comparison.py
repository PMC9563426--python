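#!/usr/bin/env python
"""Two-group genotype statistics over the architecture and spectral tables:
Shapiro/Levene-gated t-test vs Mann-Whitney per metric, Bonferroni within
per-panel families.

Reads results/architecture.csv, band_summary.csv, theta_peaks.csv (run
scripts 01-04 first); writes results/comparisons.csv.
"""
import warnings
from pathlib import Path

import pandas as pd

from somnospec.group_stats import run_comparison_suite

warnings.filterwarnings("ignore")
ROOT = Path(__file__).resolve().parents[1] / "results"

arch = pd.read_csv(ROOT / "architecture.csv")
bands = pd.read_csv(ROOT / "band_summary.csv")
theta = pd.read_csv(ROOT / "theta_peaks.csv")

report = run_comparison_suite(arch, bands, theta, on_insufficient="skip")
report.to_csv(ROOT / "comparisons.csv", index=False)

sig = report[report.significant]
print(f"{len(report)} comparisons, {len(sig)} significant after Bonferroni:")
cols = ["metric", "state", "role", "band", "test", "p_adj",
        "mean_wt", "mean_mut"]
print(sig[cols].round(4).to_string(index=False))
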