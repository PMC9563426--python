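"""Sleep-architecture metrics from a hypnogram.

For each state: total time, percentage of total sleep time (TST = REM +
NREM seconds; REM and NREM only), bout count, and mean bout duration. A
bout is a maximal run of identical labels; edge runs count. No minimum bout
length is imposed here — smoothing belongs to the scorer — so the module
measures exactly what it is given (1-s singleton runs count as bouts).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .recording import STATES
from .staging import Hypnogram

MISSING = float("nan")


@dataclass
class StateMetrics:
    total_s: float
    n_bouts: int
    mean_bout_s: float  # NaN when the state is absent
    pct_tst: float      # NaN for WAKE or when TST == 0


@dataclass
class StateArchitecture:
    animal_id: str
    genotype: str
    duration_s: float
    per_state: dict[str, StateMetrics]


def _run_lengths(labels: np.ndarray) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            out.append((str(labels[start]), i - start))
            start = i
    return out


def compute_architecture(
    h: Hypnogram, animal_id: str = "animal", genotype: str = "NA"
) -> StateArchitecture:
    """Total time, %TST, bout count and mean bout duration per state."""
    if len(h) == 0:
        raise ValueError("empty hypnogram")
    runs = _run_lengths(h.labels)
    epoch = h.epoch_s
    totals = {s: 0.0 for s in STATES}
    counts = {s: 0 for s in STATES}
    for state, length in runs:
        totals[state] += length * epoch
        counts[state] += 1
    tst = totals["REM"] + totals["NREM"]
    per_state = {}
    for s in STATES:
        mean_bout = totals[s] / counts[s] if counts[s] else MISSING
        if s == "WAKE" or tst == 0:
            pct = MISSING
        else:
            pct = 100.0 * totals[s] / tst
        per_state[s] = StateMetrics(totals[s], counts[s], mean_bout, pct)
    return StateArchitecture(animal_id, genotype, len(h) * epoch, per_state)


METRIC_NAMES = ("total_s", "pct_TST", "n_bouts", "mean_bout_s")


def cohort_table(architectures: list[StateArchitecture]) -> pd.DataFrame:
    """Long-format per-animal table: animal, genotype, state, metric, value.

    Missing values (absent states, undefined %TST) are dropped.
    """
    if not architectures:
        raise ValueError("need at least one animal")
    ids = [a.animal_id for a in architectures]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate animal ids: {dupes}")
    rows = []
    for a in architectures:
        for s in STATES:
            m = a.per_state[s]
            values = {
                "total_s": m.total_s,
                "pct_TST": m.pct_tst,
                "n_bouts": float(m.n_bouts),
                "mean_bout_s": m.mean_bout_s,
            }
            for metric in METRIC_NAMES:
                v = values[metric]
                if metric == "pct_TST" and s == "WAKE":
                    continue
                if np.isnan(v):
                    continue
                rows.append(
                    {"animal": a.animal_id, "genotype": a.genotype,
                     "state": s, "metric": metric, "value": v}
                )
    return pd.DataFrame(rows)
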