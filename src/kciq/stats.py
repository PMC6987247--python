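"""Group summaries, non-parametric tests and correlations for the study table.

The analysis variables are the three through-focus parameters (peak IQ, best
focus, DOF) and HORMS, one row per eye-condition. Following standard practice
for small non-normal ophthalmic samples, comparisons are non-parametric:
Wilcoxon signed-rank within eyes (unaided vs RGP), Mann-Whitney U between
groups, Kruskal-Wallis across three groups, Spearman rank correlations, with
two-sided p-values at α = 0.05 and no multiplicity correction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StatsReport",
    "validate_study_table",
    "summarize_groups",
    "run_comparisons",
    "correlation_analysis",
    "quantile_envelope",
]

VARIABLES = ("peak_iq", "best_focus_D", "dof_D")
REQUIRED_COLUMNS = ("subject_id", "eye", "cohort", "condition") + VARIABLES


class PairingError(ValueError):
    """A paired contrast was requested but some rows lack their partner."""


def validate_study_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"study table is missing columns: {missing}")
    if len(table) == 0:
        raise ValueError("study table is empty")
    dup = table.duplicated(subset=["subject_id", "eye", "condition"])
    if dup.any():
        raise ValueError(
            f"duplicated (subject_id, eye, condition) rows: "
            f"{table.loc[dup, ['subject_id', 'eye', 'condition']].values.tolist()}")
    return table


def _group_key(table: pd.DataFrame) -> pd.Series:
    return table["cohort"] + "/" + table["condition"]


def summarize_groups(table: pd.DataFrame,
                     variables: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Median and 25th–75th IQR per cohort × condition × variable."""
    validate_study_table(table)
    if variables is None:
        variables = tuple(v for v in VARIABLES + ("horms_um",)
                          if v in table.columns)
    rows = []
    for (cohort, condition), g in table.groupby(["cohort", "condition"]):
        for var in variables:
            vals = g[var].dropna().to_numpy()
            if vals.size == 0:
                continue
            rows.append({
                "cohort": cohort, "condition": condition, "variable": var,
                "n": int(vals.size),
                "median": float(np.median(vals)),
                "q25": float(np.percentile(vals, 25)),
                "q75": float(np.percentile(vals, 75)),
            })
    return pd.DataFrame(rows)


def _paired(table: pd.DataFrame, cohorts: tuple[str, ...],
            cond_a: str, cond_b: str, var: str,
            keys: list[str] = ["subject_id", "eye"]):
    sub = table[table["cohort"].isin(cohorts)]
    a = sub[sub["condition"] == cond_a].set_index(keys)[var]
    b = sub[sub["condition"] == cond_b].set_index(keys)[var]
    common = a.index.intersection(b.index)
    orphans = sorted(set(a.index.symmetric_difference(b.index)))
    if orphans:
        raise PairingError(
            f"unmatched rows for paired contrast {cond_a} vs {cond_b} "
            f"({var}): {orphans}")
    return a.loc[common].to_numpy(), b.loc[common].to_numpy()


def _paired_across_eyes(table: pd.DataFrame, cohort_a: str, cohort_b: str,
                        condition: str, var: str):
    sub = table[table["condition"] == condition]
    a = sub[sub["cohort"] == cohort_a].set_index("subject_id")[var]
    b = sub[sub["cohort"] == cohort_b].set_index("subject_id")[var]
    common = a.index.intersection(b.index)
    orphans = sorted(set(a.index.symmetric_difference(b.index)))
    if orphans:
        raise PairingError(
            f"unmatched subjects for paired contrast {cohort_a} vs {cohort_b} "
            f"({var}): {orphans}")
    return a.loc[common].to_numpy(), b.loc[common].to_numpy()


def _wilcoxon(a, b):
    d = np.asarray(a, float) - np.asarray(b, float)
    if np.allclose(d, 0):
        return np.nan, 1.0, len(d)
    res = sps.wilcoxon(a, b, zero_method="wilcox", alternative="two-sided",
                       method="auto")
    return float(res.statistic), float(res.pvalue), len(d)


@dataclass
class StatsReport:
    """Full statistical report: summaries, tests, correlations, envelope."""

    summaries: pd.DataFrame
    tests: pd.DataFrame
    correlations: pd.DataFrame
    envelope: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)
    alpha: float = 0.05

    def to_json(self, path=None) -> str:
        payload = {
            "alpha": self.alpha,
            "summaries": self.summaries.to_dict("records"),
            "tests": self.tests.to_dict("records"),
            "correlations": self.correlations.to_dict("records"),
            "envelope": (self.envelope.to_dict("records")
                         if self.envelope is not None else None),
            "warnings": self.warnings,
        }
        text = json.dumps(payload, indent=2, default=float)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_text(self) -> str:
        lines = ["Group summaries [median (q25-q75)]", "=" * 40]
        for _, r in self.summaries.iterrows():
            lines.append(f"{r.cohort}/{r.condition:8s} {r.variable:14s} "
                         f"{r['median']:+7.3f} ({r.q25:+.3f} - {r.q75:+.3f})  n={r.n}")
        lines += ["", "Hypothesis tests (two-sided)", "=" * 40]
        for _, r in self.tests.iterrows():
            star = "*" if r.p_value < self.alpha else " "
            lines.append(f"{r.test:16s} {r.contrast:48s} {r.variable:14s} "
                         f"stat={r.statistic:9.3f} n={int(r.n):3d} p={r.p_value:.4f}{star}")
        lines += ["", "Spearman rank correlations", "=" * 40]
        for _, r in self.correlations.iterrows():
            lines.append(f"{r.subset:28s} {r.x} vs {r.y}: "
                         f"r={r.r:+.3f} p={r.p_value:.4f} n={int(r.n)}")
        for w in self.warnings:
            lines.append(f"WARNING: {w}")
        return "\n".join(lines)


def run_comparisons(table: pd.DataFrame,
                    variables: tuple[str, ...] = VARIABLES) -> StatsReport:
    """Run the planned normality screen, paired, unpaired and 3-group tests."""
    validate_study_table(table)
    warnings: list[str] = []
    rows = []

    def have(cohort, condition):
        return ((table["cohort"] == cohort)
                & (table["condition"] == condition)).any()

    # Shapiro-Wilk normality screen per group x variable
    for (cohort, condition), g in table.groupby(["cohort", "condition"]):
        for var in variables:
            vals = g[var].dropna().to_numpy()
            if vals.size < 3 or np.ptp(vals) == 0:
                continue
            stat, p = sps.shapiro(vals)
            rows.append({"test": "shapiro", "contrast": f"{cohort}/{condition}",
                         "variable": var, "statistic": float(stat),
                         "n": vals.size, "p_value": float(p)})

    for var in variables:
        # paired: unaided vs RGP within eyes; the ectatic VAE eye is unique
        # per subject, so that contrast pairs on subject alone
        for cohorts, label, keys in (
                (("KCE",), "KCE unaided vs RGP", ["subject_id", "eye"]),
                (("VAE_ectatic",), "VAE ectatic unaided vs RGP",
                 ["subject_id"])):
            if all(have(c, "unaided") and have(c, "RGP") for c in cohorts):
                a, b = _paired(table, cohorts, "unaided", "RGP", var, keys)
                stat, p, n = _wilcoxon(a, b)
                rows.append({"test": "wilcoxon", "contrast": label,
                             "variable": var, "statistic": stat,
                             "n": n, "p_value": p})
        # paired across eyes within VAE subjects
        for cond in ("unaided",):
            if have("VAE_ectatic", cond) and have("VAE_nonectatic", cond):
                a, b = _paired_across_eyes(table, "VAE_ectatic",
                                           "VAE_nonectatic", cond, var)
                stat, p, n = _wilcoxon(a, b)
                rows.append({"test": "wilcoxon",
                             "contrast": f"VAE ectatic vs non-ectatic ({cond})",
                             "variable": var, "statistic": stat,
                             "n": n, "p_value": p})
        # unpaired vs controls
        for cohort, cond in (("KCE", "unaided"), ("KCE", "RGP"),
                             ("VAE_ectatic", "unaided"), ("VAE_ectatic", "RGP"),
                             ("VAE_nonectatic", "unaided")):
            if have(cohort, cond) and have("control", "unaided"):
                a = table.query("cohort == @cohort and condition == @cond")[var]
                b = table.query("cohort == 'control'")[var]
                res = sps.mannwhitneyu(a, b, alternative="two-sided")
                rows.append({"test": "mannwhitneyu",
                             "contrast": f"{cohort}/{cond} vs control",
                             "variable": var, "statistic": float(res.statistic),
                             "n": len(a) + len(b), "p_value": float(res.pvalue)})
        # 3-group Kruskal-Wallis: control vs KCE unaided vs KCE RGP
        if have("control", "unaided") and have("KCE", "unaided") and have("KCE", "RGP"):
            groups = [table.query("cohort == 'control'")[var],
                      table.query("cohort == 'KCE' and condition == 'unaided'")[var],
                      table.query("cohort == 'KCE' and condition == 'RGP'")[var]]
            res = sps.kruskal(*groups)
            rows.append({"test": "kruskal",
                         "contrast": "control vs KCE-unaided vs KCE-RGP",
                         "variable": var, "statistic": float(res.statistic),
                         "n": sum(len(g) for g in groups),
                         "p_value": float(res.pvalue)})

    if not any(r["test"] != "shapiro" for r in rows):
        warnings.append("no planned contrast had the required groups; "
                        "comparisons skipped")
    summaries = summarize_groups(table)
    correlations = correlation_analysis(table) if len(table) >= 5 else pd.DataFrame(
        columns=["subset", "x", "y", "r", "p_value", "n"])
    if len(table) < 5:
        warnings.append("fewer than 5 rows; correlations skipped")
    env = None
    if len(table) >= 10:
        env = quantile_envelope(table["peak_iq"].to_numpy(),
                                table["best_focus_D"].to_numpy())
    return StatsReport(summaries=summaries,
                       tests=pd.DataFrame(rows),
                       correlations=correlations,
                       envelope=env,
                       warnings=warnings)


def correlation_analysis(table: pd.DataFrame) -> pd.DataFrame:
    """Spearman correlations of best focus and DOF against peak IQ.

    Reported pooled over all eye-conditions and per cohort-condition subgroup.
    Constant inputs yield an undefined correlation, reported as NaN.
    """
    validate_study_table(table)
    if len(table) < 5:
        raise ValueError("correlation analysis needs at least 5 rows")
    pairs = (("peak_iq", "best_focus_D"), ("peak_iq", "dof_D"))
    rows = []

    def one(subset_name, df):
        for x, y in pairs:
            xv, yv = df[x].to_numpy(), df[y].to_numpy()
            if np.ptp(xv) == 0 or np.ptp(yv) == 0 or len(xv) < 3:
                r, p = np.nan, np.nan
            else:
                r, p = sps.spearmanr(xv, yv)
            rows.append({"subset": subset_name, "x": x, "y": y,
                         "r": float(r) if r == r else np.nan,
                         "p_value": float(p) if p == p else np.nan,
                         "n": len(xv)})

    one("pooled", table)
    for (cohort, condition), g in table.groupby(["cohort", "condition"]):
        one(f"{cohort}/{condition}", g)
    return pd.DataFrame(rows)


def quantile_envelope(x: np.ndarray, y: np.ndarray,
                      q_low: float = 0.10, q_high: float = 0.90,
                      window: int | None = None) -> pd.DataFrame:
    """Moving-window quantile envelope of y across sorted x.

    Windows of ``max(9, n // 5)`` consecutive points (step 1) slide over the
    x-sorted data; each yields the window-center x and the two y quantiles.
    A shrinking envelope width with increasing x indicates decreasing
    inter-subject variability.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 10:
        raise ValueError("quantile envelope needs at least 10 points")
    if window is None:
        window = max(9, n // 5)
    window = min(window, n)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    rows = []
    for i in range(n - window + 1):
        xw = xs[i:i + window]
        yw = ys[i:i + window]
        lo = float(np.quantile(yw, q_low))
        hi = float(np.quantile(yw, q_high))
        rows.append({"x_center": float(xw.mean()), "q_low": lo, "q_high": hi,
                     "width": hi - lo})
    return pd.DataFrame(rows)
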