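"""Statistical comparison of stain-translation configurations.

For each metric, trials form a complete configs x trials matrix (the same
test tiles are scored under every configuration, so measures are
repeated).  The harness runs:

- one-way repeated-measures ANOVA (error df = (k-1)(n-1));
- Tukey HSD pairwise comparisons with Bonferroni-adjusted paired
  confidence intervals for fused-vs-individual differences;
- paired Wilcoxon signed-rank tests of the fused output against each
  configuration (Bonferroni-corrected across all comparisons);
- paired Cohen's d effect sizes;
- Shapiro-Wilk and Anderson-Darling normality screens per configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = ["RmAnovaResult", "StatsReport", "rm_anova_error_df", "cohens_d_paired",
           "stats_harness", "aggregate_trials"]


def rm_anova_error_df(k: int, n: int) -> int:
    """Error degrees of freedom of a one-way RM-ANOVA: (k-1)(n-1)."""
    return (k - 1) * (n - 1)


def cohens_d_paired(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d for paired samples: mean difference over SD of differences."""
    d = np.asarray(a, float) - np.asarray(b, float)
    sd = d.std(ddof=1)
    if sd == 0:
        return 0.0
    return float(d.mean() / sd)


@dataclass
class RmAnovaResult:
    F: float
    ddof1: int
    ddof2: int
    p: float


@dataclass
class StatsReport:
    anova: RmAnovaResult
    tukey: pd.DataFrame
    wilcoxon: pd.DataFrame
    normality: pd.DataFrame
    notes: list[str] = field(default_factory=list)


def _long_format(matrix: pd.DataFrame) -> pd.DataFrame:
    df = matrix.reset_index(names="trial").melt(
        id_vars="trial", var_name="config", value_name="value")
    return df


def stats_harness(matrix: pd.DataFrame, fused_label: str = "Fused",
                  alternative: str = "two-sided",
                  n_comparisons: int | None = None) -> StatsReport:
    """Run the full statistical battery on one metric's trial matrix.

    ``matrix`` has one row per trial and one column per configuration
    (including the fused output).  ``n_comparisons`` is the Bonferroni
    family size; by default the number of fused-vs-config comparisons in
    this matrix (pass 20 when correcting across five metrics as a family).
    """
    if matrix.isna().any().any():
        raise ValueError("trial matrix has missing cells")
    configs = list(matrix.columns)
    k, n = len(configs), len(matrix)

    try:
        aov = pg.rm_anova(data=_long_format(matrix), dv="value", within="config",
                          subject="trial", detailed=False)
        anova = RmAnovaResult(F=float(aov["F"].iloc[0]),
                              ddof1=int(aov["ddof1"].iloc[0]),
                              ddof2=int(aov["ddof2"].iloc[0]),
                              p=float(aov["p_unc"].iloc[0]))
    except (KeyError, ValueError, ZeroDivisionError):
        # degenerate input (e.g. identical configs): fall back to the plain
        # sums-of-squares formula with the 0/0 -> 0 convention
        x = matrix.to_numpy(float)
        grand = x.mean()
        ss_config = n * ((x.mean(axis=0) - grand)**2).sum()
        resid = x - x.mean(axis=0) - x.mean(axis=1, keepdims=True) + grand
        ss_err = (resid**2).sum()
        df1, df2 = k - 1, (k - 1) * (n - 1)
        f = 0.0 if ss_config == 0 else (ss_config / df1) / (ss_err / df2)
        p = 1.0 if ss_config == 0 else float(sps.f.sf(f, df1, df2))
        anova = RmAnovaResult(F=f, ddof1=df1, ddof2=df2, p=p)

    long = _long_format(matrix)
    tk = pairwise_tukeyhsd(long["value"].to_numpy(), long["config"].to_numpy())
    tukey = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])

    others = [c for c in configs if c != fused_label]
    m = n_comparisons or len(others)
    rows = []
    notes = []
    for c in others:
        a = matrix[fused_label].to_numpy()
        b = matrix[c].to_numpy()
        diff = a - b
        if np.all(diff == 0):
            notes.append(f"degenerate Wilcoxon (all-zero differences) for {c}")
            p = 1.0
            stat = np.nan
        else:
            res = sps.wilcoxon(a, b, alternative=alternative)
            stat, p = float(res.statistic), float(res.pvalue)
        # Bonferroni-adjusted paired CI for the mean difference
        alpha = 0.05 / m
        se = diff.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        tcrit = sps.t.ppf(1 - alpha / 2, n - 1) if n > 1 else np.nan
        rows.append({"comparison": f"{fused_label} vs {c}",
                     "mean_diff": float(diff.mean()),
                     "ci_low": float(diff.mean() - tcrit * se),
                     "ci_high": float(diff.mean() + tcrit * se),
                     "W": stat, "p": p,
                     "p_bonf": min(1.0, p * m),
                     "cohens_d": cohens_d_paired(a, b)})
    wilcoxon = pd.DataFrame(rows)

    norm_rows = []
    for c in configs:
        v = matrix[c].to_numpy()
        sw = sps.shapiro(v)
        ad = sps.anderson(v, dist="norm", method="interpolate")
        norm_rows.append({"config": c, "shapiro_W": float(sw.statistic),
                          "shapiro_p": float(sw.pvalue),
                          "anderson_A2": float(ad.statistic),
                          "anderson_p": float(ad.pvalue)})
    normality = pd.DataFrame(norm_rows)
    return StatsReport(anova=anova, tukey=tukey, wilcoxon=wilcoxon,
                       normality=normality, notes=notes)


def aggregate_trials(reports: list[dict[str, float]],
                     trial_labels: list | None = None) -> pd.DataFrame:
    """Aggregate per-trial metric dicts into a mean +/- std summary table.

    Sample standard deviation (ddof=1) is reported for 2+ trials and 0 for
    a single trial.  The direction column mirrors the higher/lower-is-
    better annotation of each metric.
    """
    from .metrics import METRIC_DIRECTIONS

    if not reports:
        raise ValueError("need at least one report")
    keys = set(reports[0])
    if any(set(r) != keys for r in reports):
        raise ValueError("inconsistent metric sets across trials")
    df = pd.DataFrame(reports, index=trial_labels)
    out = pd.DataFrame({
        "mean": df.mean(),
        "std": df.std(ddof=1).fillna(0.0) if len(df) > 1
               else pd.Series(0.0, index=df.columns),
        "n_trials": len(df),
    })
    out["direction"] = [METRIC_DIRECTIONS.get(mname, "?") for mname in out.index]
    return out
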