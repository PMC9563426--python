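"""Two-group genotype statistics.

Each metric is compared between genotypes with a distribution-gated test:
Shapiro-Wilk normality per group and median-centred Levene variance
equality decide between the pooled-variance independent t-test (all gate
p-values above ``alpha_gate``) and the Mann-Whitney U test (otherwise;
exact null distribution when the combined sample is small). Sex ratios use
Pearson's chi-square without continuity correction. Post hoc families are
Bonferroni corrected; family membership defaults to per-state panels for
spectral metrics and per-metric panels for architecture metrics.

All tests are two-sided; significance is reported at p < 0.05 on the
adjusted values. The gate instruments and their p-values are kept on every
comparison so the decision trail is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05


@dataclass
class GroupComparison:
    metric: str
    test_used: str  # "t-test" | "mann-whitney" | "chi-square" | "kruskal"
    statistic: float
    p: float
    n_a: int
    n_b: int
    p_adjusted: float | None = None
    mean_a: float = float("nan")
    mean_b: float = float("nan")
    gate: dict = field(default_factory=dict)  # normality/variance p-values


def _shapiro_p(x: np.ndarray) -> float:
    # constant samples are maximally non-normal for gating purposes
    if np.ptp(x) == 0:
        return 0.0
    return float(stats.shapiro(x).pvalue)


def gated_two_group_test(
    x, y, alpha_gate: float = ALPHA, metric: str = "metric",
    alternative_test: str | None = None,
) -> GroupComparison:
    """Independent t-test or Mann-Whitney, chosen by a normality/variance gate.

    ``alternative_test`` bypasses the gate: "kruskal" runs a Kruskal-Wallis
    test (equivalent to Mann-Whitney for two groups up to the statistic),
    "mannwhitney" forces the rank test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError(
            f"{metric}: need n >= 3 per group (got {len(x)}, {len(y)}); "
            "the normality gate is undefined below that"
        )

    if alternative_test == "kruskal":
        res = stats.kruskal(x, y)
        return GroupComparison(metric, "kruskal", float(res.statistic),
                               float(res.pvalue), len(x), len(y),
                               mean_a=float(x.mean()), mean_b=float(y.mean()))
    if alternative_test == "mannwhitney":
        c = _mannwhitney(x, y, metric)
        return c

    p_norm_x = _shapiro_p(x)
    p_norm_y = _shapiro_p(y)
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        p_var = 1.0
    else:
        p_var = float(stats.levene(x, y, center="median").pvalue)
    gate = {"normality_p_a": p_norm_x, "normality_p_b": p_norm_y,
            "variance_p": p_var, "alpha_gate": alpha_gate}

    if min(p_norm_x, p_norm_y, p_var) > alpha_gate:
        res = stats.ttest_ind(x, y, equal_var=True)
        p = float(res.pvalue)
        if np.isnan(p):  # degenerate (identical constants): no evidence
            p = 1.0
        return GroupComparison(metric, "t-test", float(res.statistic), p,
                               len(x), len(y), mean_a=float(x.mean()),
                               mean_b=float(y.mean()), gate=gate)
    c = _mannwhitney(x, y, metric)
    c.gate = gate
    return c


def _mannwhitney(x: np.ndarray, y: np.ndarray, metric: str) -> GroupComparison:
    """Two-sided Mann-Whitney with mid-rank ties; exact null distribution
    for combined n <= 20 (when tie-free)."""
    combined = np.concatenate([x, y])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if np.isnan(p):
        p = 1.0
    return GroupComparison(metric, "mann-whitney", float(res.statistic), p,
                           len(x), len(y), mean_a=float(x.mean()),
                           mean_b=float(y.mean()))


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """p_adj = min(1, m * p) for a family of ``m`` tests."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError(f"family size m={m} smaller than {len(p)} p-values")
    return np.minimum(1.0, m * p)


def sex_ratio_test(counts) -> GroupComparison:
    """Pearson chi-square (no continuity correction, 1 df) on a 2x2
    genotype-by-sex table."""
    table = np.asarray(counts)
    if table.shape != (2, 2):
        raise ValueError(f"need a 2x2 table, got shape {table.shape}")
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        if np.any(table != np.floor(table)) or np.any(table < 0):
            raise ValueError("counts must be nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    res = stats.chi2_contingency(table, correction=False)
    return GroupComparison(
        "sex_ratio", "chi-square", float(res.statistic), float(res.pvalue),
        int(table[0].sum()), int(table[1].sum()),
    )


# ---------------------------------------------------------------------------
# comparison suite over cohort tables


def _suite_rows(arch: pd.DataFrame | None, bands: pd.DataFrame | None,
                theta: pd.DataFrame | None):
    """Yield (family, metric_id, state, role, band, values_by_genotype)."""
    if arch is not None and len(arch):
        for (metric, state), sub in arch.groupby(["metric", "state"], sort=True):
            yield (f"arch_{metric}", f"{metric}", state, "", "", sub)
    if bands is not None and len(bands):
        for (state, role, band), sub in bands.groupby(
            ["state", "role", "band"], sort=True
        ):
            sub = sub.rename(columns={"mean_norm_power": "value"})
            yield (f"power_{state}", "mean_norm_power", state, role, band, sub)
    if theta is not None and len(theta):
        for role, sub in theta.groupby("role", sort=True):
            sub = sub.rename(columns={"theta_peak_hz": "value"})
            yield ("theta_peak_REM", "theta_peak_hz", "REM", role, "", sub)


def run_comparison_suite(
    architecture: pd.DataFrame | None = None,
    band_summary: pd.DataFrame | None = None,
    theta_peaks: pd.DataFrame | None = None,
    group_col: str = "genotype",
    groups: tuple[str, str] = ("WT", "MUT"),
    alpha: float = ALPHA,
    alternative_test: str | None = None,
    on_insufficient: str = "error",
) -> pd.DataFrame:
    """Gated two-group test per metric with per-family Bonferroni correction.

    Inputs are tidy per-animal tables: ``architecture`` with columns
    (animal, genotype, state, metric, value); ``band_summary`` with
    (animal, genotype, state, role, band, mean_norm_power); ``theta_peaks``
    with (animal, genotype, role, theta_peak_hz). Returns one row per
    comparison with the family id, gate diagnostics, raw and adjusted p.

    ``on_insufficient`` controls what happens when a metric has fewer than
    3 non-missing animals in a group (e.g. a state absent from a short
    recording): "error" raises, "skip" drops that comparison from the
    report (and from its Bonferroni family).
    """
    if on_insufficient not in ("error", "skip"):
        raise ValueError(f"on_insufficient must be 'error' or 'skip'")
    rows = []
    for family, metric, state, role, band, sub in _suite_rows(
        architecture, band_summary, theta_peaks
    ):
        missing = {"value", group_col} - set(sub.columns)
        if missing:
            raise ValueError(f"missing column(s) {sorted(missing)} for {metric}")
        a = sub.loc[sub[group_col] == groups[0], "value"].to_numpy(float)
        b = sub.loc[sub[group_col] == groups[1], "value"].to_numpy(float)
        a, b = a[~np.isnan(a)], b[~np.isnan(b)]
        if (len(a) < 3 or len(b) < 3) and on_insufficient == "skip":
            continue
        cmp_id = "/".join(filter(None, [metric, state, role, band]))
        c = gated_two_group_test(a, b, metric=cmp_id,
                                 alternative_test=alternative_test)
        rows.append(
            {"metric": metric, "state": state, "role": role, "band": band,
             "family": family, "test": c.test_used, "statistic": c.statistic,
             "p": c.p, "n_wt": c.n_a, "n_mut": c.n_b,
             "mean_wt": c.mean_a, "mean_mut": c.mean_b,
             "normality_p_wt": c.gate.get("normality_p_a", np.nan),
             "normality_p_mut": c.gate.get("normality_p_b", np.nan),
             "variance_p": c.gate.get("variance_p", np.nan)}
        )
    report = pd.DataFrame(rows)
    if len(report):
        report["p_adj"] = np.nan
        for fam, idx in report.groupby("family").groups.items():
            report.loc[idx, "p_adj"] = bonferroni(report.loc[idx, "p"].to_numpy())
        report["significant"] = report["p_adj"] < alpha
    return report
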