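#!/usr/bin/env python
"""Simulate the demo cohort: 9 wild-type and 5 mutant animals.

Writes EDF recordings, JSON sidecars and ground-truth hypnograms under
results/cohort/. The session is a time-compressed stand-in for the study's
12-h lights-on recording (60 min at 400 Hz, bout durations scaled to keep
the number of sleep-wake cycles realistic); the mutant phenotype carries
all default genotype effects.
"""
import warnings
from pathlib import Path

import somnospec as sp
from somnospec.experiments import scaled_config
from somnospec.staging import Hypnogram

warnings.filterwarnings("ignore")
OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 1

cfg = scaled_config(duration_s=3600, sample_rate=400.0)
cohort = sp.simulate_cohort(9, 5, cfg, seed=SEED)
for a in cohort:
    sp.write_edf(a.recording, OUT / f"{a.animal_id}.edf")
    sp.save_hypnogram(Hypnogram(a.truth.hypnogram, provenance="ground-truth"),
                      OUT / f"{a.animal_id}_truth.csv")
    rem_s = (a.truth.hypnogram == "REM").sum()
    print(f"{a.animal_id} ({a.genotype}): {len(a.truth.bouts)} bouts, "
          f"{rem_s} s REM")
print(f"wrote {len(cohort)} recordings to {OUT}")
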