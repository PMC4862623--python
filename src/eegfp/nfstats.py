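"""Neurofeedback success statistics.

Three analyses evaluate a logged cEFP series study: a per-subject
one-sided Welch t-test of feedback-period vs baseline values (success:
p(NF < BL) < alpha), a 2 (group: test vs sham) x 2 (condition: BL vs NF)
mixed-design ANOVA on per-subject condition means, and a two-sided Fisher
exact test comparing group success counts.

The per-subject test treats 3-s samples as independent; cEFP series are
autocorrelated, so its effective sample size is optimistic.  No correction
is applied (none is standard for this design) — treat per-subject p-values
as descriptive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

BASELINE_LABEL = "BL"


@dataclass
class NFSessionRecord:
    """One subject's logged cEFP series with period labels (BL, NF1..NFk)."""

    subject_id: str
    group: str  # "test" or "sham"
    values: np.ndarray
    period_labels: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(self.period_labels):
            raise ValueError("one label per value required")
        labels = set(self.period_labels)
        if BASELINE_LABEL not in labels:
            raise ValueError("a baseline (BL) period is required")
        if not any(lbl.startswith("NF") for lbl in labels):
            raise ValueError("at least one NF period is required")
        if self.group not in {"test", "sham"}:
            raise ValueError("group must be 'test' or 'sham'")

    def condition_values(self, condition: str) -> np.ndarray:
        mask = [
            (lbl == BASELINE_LABEL) if condition == "BL" else lbl.startswith("NF")
            for lbl in self.period_labels
        ]
        return self.values[np.asarray(mask)]


def subject_success(
    rec: NFSessionRecord, alpha: float = 0.05
) -> tuple[float, float, bool, dict]:
    """One-sided Welch t-test of NF vs BL values for a single subject.

    Returns (t, p, success, means) with p = p(NF < BL) and success iff
    p < alpha.
    """
    bl = rec.condition_values("BL")
    nf = rec.condition_values("NF")
    if bl.size < 2 or nf.size < 2:
        raise ValueError("need at least two values per condition")
    if bl.std(ddof=1) == 0 and nf.std(ddof=1) == 0:
        raise ValueError("degenerate variance in both conditions")
    t, p = stats.ttest_ind(nf, bl, equal_var=False, alternative="less")
    means = {"BL": float(bl.mean()), "NF": float(nf.mean())}
    return float(t), float(p), bool(p < alpha), means


def _condition_means(records: list[NFSessionRecord]) -> pd.DataFrame:
    rows = [{
        "subject_id": r.subject_id,
        "group": r.group,
        "BL": float(r.condition_values("BL").mean()),
        "NF": float(r.condition_values("NF").mean()),
    } for r in records]
    return pd.DataFrame(rows)


def mixed_anova_2x2(records: list[NFSessionRecord]) -> pd.DataFrame:
    """Mixed-design ANOVA on per-subject (BL, NF) means.

    Between factor: group (test/sham); within factor: condition (BL/NF).
    With two within levels the analysis reduces exactly to independent
    comparisons of per-subject sums (group effect) and differences
    (condition and interaction); every F has df (1, n_subjects - 2).
    Simple (within-group) condition effects against the pooled difference
    error are appended as planned comparisons.
    """
    means = _condition_means(records)
    groups = sorted(means["group"].unique())
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    ns = means.groupby("group").size()
    if (ns < 2).any():
        raise ValueError("each group needs at least two subjects")
    n = len(means)
    df_err = n - 2
    d = (means["NF"] - means["BL"]).to_numpy()
    s = ((means["NF"] + means["BL"]) / 2).to_numpy()
    g = means["group"].to_numpy()
    inv_n = sum(1.0 / ns[gr] for gr in groups)

    def pooled_var(x: np.ndarray) -> float:
        return float(sum(
            ((x[g == gr] - x[g == gr].mean()) ** 2).sum() for gr in groups
        ) / df_err)

    ms_s = pooled_var(s)       # between-subject error on subject means
    ms_d = pooled_var(d)       # subject-by-condition error on differences
    d_bar = {gr: float(d[g == gr].mean()) for gr in groups}
    s_bar = {gr: float(s[g == gr].mean()) for gr in groups}

    rows = []

    def add(effect: str, contrast: float, ms: float, c_var: float) -> None:
        ss = contrast**2 / c_var
        f = ss / ms if ms > 0 else 0.0
        p = float(stats.f.sf(f, 1, df_err)) if ms > 0 else 1.0
        rows.append({"effect": effect, "SS": ss, "df1": 1, "df2": df_err,
                     "F": f, "p": p})

    add("group", s_bar[groups[0]] - s_bar[groups[1]], ms_s, inv_n)
    # condition main effect on the subject-weighted mean difference
    # (the textbook sums-of-squares convention for unbalanced groups)
    add("condition", float(d.mean()), ms_d, 1.0 / n)
    add("interaction", d_bar[groups[0]] - d_bar[groups[1]], ms_d, inv_n)
    for gr in groups:
        add(f"condition within {gr}", d_bar[gr], ms_d, 1.0 / ns[gr])
    table = pd.DataFrame(rows).set_index("effect")
    table.attrs["cell_means"] = {
        gr: {"BL": float(means.loc[means.group == gr, "BL"].mean()),
             "NF": float(means.loc[means.group == gr, "NF"].mean())}
        for gr in groups}
    return table


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration.

    The table is ((a, b), (c, d)) with fixed margins; the p-value sums the
    probabilities of every table whose probability does not exceed the
    observed table's (with a small relative tolerance for ties).
    """
    counts = (a, b, c, d)
    if any(x < 0 or x != int(x) for x in counts):
        raise ValueError("counts must be nonnegative integers")
    if sum(counts) == 0:
        raise ValueError("empty table")
    a, b, c, d = (int(x) for x in counts)
    row1, col1, total = a + b, a + c, a + b + c + d
    if row1 == 0 or row1 == total or col1 == 0 or col1 == total:
        raise ValueError("margins must be positive")

    def log_prob(k: int) -> float:
        # P(k) for the (1,1) cell under the hypergeometric null
        return (math.lgamma(row1 + 1) - math.lgamma(k + 1)
                - math.lgamma(row1 - k + 1)
                + math.lgamma(total - row1 + 1) - math.lgamma(col1 - k + 1)
                - math.lgamma(total - row1 - col1 + k + 1)
                + math.lgamma(col1 + 1) + math.lgamma(total - col1 + 1)
                - math.lgamma(total + 1))

    k_min = max(0, col1 - (total - row1))
    k_max = min(row1, col1)
    obs = log_prob(a)
    p = 0.0
    for k in range(k_min, k_max + 1):
        lp = log_prob(k)
        if lp <= obs + 1e-7:  # relative tie tolerance for float noise
            p += math.exp(lp)
    return min(p, 1.0)


def evaluate_study(
    records: list[NFSessionRecord], alpha: float = 0.05
) -> dict:
    """Full study report: per-subject tests, ANOVA table, Fisher p."""
    per_subject = []
    success = {"test": 0, "sham": 0}
    totals = {"test": 0, "sham": 0}
    for rec in records:
        t, p, ok, cond_means = subject_success(rec, alpha)
        per_subject.append({"subject_id": rec.subject_id, "group": rec.group,
                            "t": t, "p": p, "success": ok, **cond_means})
        totals[rec.group] += 1
        success[rec.group] += int(ok)
    anova = mixed_anova_2x2(records)
    fisher_p = fisher_exact_2x2(
        success["test"], totals["test"] - success["test"],
        success["sham"], totals["sham"] - success["sham"])
    return {
        "per_subject": pd.DataFrame(per_subject),
        "anova": anova,
        "success_counts": {g: (success[g], totals[g]) for g in totals},
        "fisher_p": fisher_p,
    }
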