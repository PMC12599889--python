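"""Repeated-measures statistical comparison of detector conditions.

Implements the reporting pipeline used on the per-split F1 scores:
Shapiro-Wilk normality screening, one-way repeated-measures ANOVA with
Mauchly sphericity testing and Huynh-Feldt correction, a Friedman test
for the non-normal branch, a two-way repeated-measures ANOVA for the
sensor-type x position factorial, and Bonferroni-adjusted pairwise post
hoc tests.  The repeated-measures subject is the split index.

ANOVA sums of squares and partial eta squared are computed here directly;
sphericity statistics (Mauchly W, Huynh-Feldt epsilon) are delegated to
pingouin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

__all__ = [
    "ConditionMatrix",
    "StatsReport",
    "shapiro_wilk",
    "rm_anova_oneway",
    "rm_anova_twoway",
    "friedman",
    "bonferroni_posthoc",
    "ALPHA",
]

ALPHA = 0.05  # significance level; sphericity correction trigger


@dataclass
class ConditionMatrix:
    """Paired F1 scores: one row per split, one column per condition."""

    values: np.ndarray  # (n_splits, n_conditions)
    conditions: Tuple[str, ...]
    split_ids: Tuple[int, ...] = ()

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a splits x conditions matrix")
        n, k = self.values.shape
        if n < 3 or k < 2:
            raise ValueError("need >= 3 splits and >= 2 conditions")
        if len(self.conditions) != k:
            raise ValueError("condition names do not match matrix width")
        if np.isnan(self.values).any():
            raise ValueError("missing cells are not allowed (paired design)")
        if not self.split_ids:
            self.split_ids = tuple(range(n))

    @classmethod
    def from_results(cls, df: pd.DataFrame, metric: str = "f1",
                     conditions: Optional[Sequence[str]] = None) -> "ConditionMatrix":
        """Pivot a tidy (condition, split_id, metric) results frame."""
        wide = df.pivot(index="split_id", columns="condition", values=metric)
        if conditions is not None:
            wide = wide[list(conditions)]
        return cls(
            values=wide.to_numpy(),
            conditions=tuple(wide.columns),
            split_ids=tuple(int(i) for i in wide.index),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, columns=list(self.conditions), index=list(self.split_ids)
        )


@dataclass
class StatsReport:
    """One test's outcome in a publication-style reporting layout."""

    test: str
    statistic: float
    df: Tuple[float, ...]
    p: float
    effect_size: Optional[float] = None  # partial eta squared
    correction: Optional[str] = None
    sphericity_w: Optional[float] = None
    sphericity_p: Optional[float] = None
    epsilon: Optional[float] = None
    posthoc: Optional[pd.DataFrame] = None
    extra: Dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return self.p <= ALPHA

    def to_text(self) -> str:
        dfs = ", ".join(f"{d:g}" for d in self.df)
        lines = [f"{self.test}: statistic={self.statistic:.4f}, df=({dfs}), p={self.p:.4g}"]
        if self.effect_size is not None:
            lines.append(f"  partial eta^2 = {self.effect_size:.3f}")
        if self.sphericity_w is not None:
            lines.append(
                f"  Mauchly W = {self.sphericity_w:.4f} (p = {self.sphericity_p:.4g}); "
                + (
                    f"Huynh-Feldt epsilon = {self.epsilon:.4f} applied"
                    if self.correction
                    else "sphericity assumed"
                )
            )
        if self.posthoc is not None:
            lines.append("  post hoc (Bonferroni):")
            for _, row in self.posthoc.iterrows():
                flag = " *" if row["p_adjusted"] <= ALPHA else ""
                lines.append(
                    f"    {row['a']} vs {row['b']}: t={row['statistic']:.3f}, "
                    f"p_adj={row['p_adjusted']:.4g}{flag}"
                )
        return "\n".join(lines)


def shapiro_wilk(sample: Sequence[float]) -> StatsReport:
    """Shapiro-Wilk normality test for one condition's per-split scores."""
    x = np.asarray(sample, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk is undefined for a constant sample")
    w, p = stats.shapiro(x)
    return StatsReport(test="shapiro_wilk", statistic=float(w), df=(x.size,), p=float(p))


def _oneway_ss(y: np.ndarray) -> Tuple[float, float, float]:
    """Within-subjects decomposition: (SS_condition, SS_subject, SS_error)."""
    grand = y.mean()
    ss_cond = y.shape[0] * float(np.sum((y.mean(axis=0) - grand) ** 2))
    ss_subj = y.shape[1] * float(np.sum((y.mean(axis=1) - grand) ** 2))
    ss_tot = float(np.sum((y - grand) ** 2))
    return ss_cond, ss_subj, ss_tot - ss_cond - ss_subj


def _sphericity(wide: pd.DataFrame) -> Tuple[float, float, float]:
    """Mauchly W, its p-value, and the Huynh-Feldt epsilon."""
    spher = pg.sphericity(wide)
    eps = float(pg.epsilon(wide, correction="hf"))
    return float(spher.W), float(spher.pval), eps


def rm_anova_oneway(matrix: ConditionMatrix) -> StatsReport:
    """One-way repeated-measures ANOVA over conditions, paired on split.

    Sphericity is screened with Mauchly's test; when violated (p <= 0.05)
    the Huynh-Feldt epsilon rescales both degrees of freedom.
    """
    y = matrix.values
    n, k = y.shape
    ss_cond, _ss_subj, ss_err = _oneway_ss(y)
    df1, df2 = k - 1, (n - 1) * (k - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err > 0:
        f_stat = ms_cond / ms_err
    else:
        f_stat = 0.0 if np.isclose(ms_cond, 0.0) else np.inf
    eta_p = ss_cond / (ss_cond + ss_err) if ss_cond + ss_err > 0 else 0.0
    w = w_p = eps = None
    correction = None
    if k > 2 and not np.allclose(y, y[:, [0]]):
        w, w_p, eps = _sphericity(matrix.to_frame())
        if w_p <= ALPHA:
            correction = "huynh-feldt"
            df1, df2 = eps * df1, eps * df2
    p = float(stats.f.sf(f_stat, df1, df2)) if np.isfinite(f_stat) else 0.0
    return StatsReport(
        test="rm_anova_oneway",
        statistic=float(f_stat),
        df=(df1, df2),
        p=p,
        effect_size=float(eta_p),
        correction=correction,
        sphericity_w=w,
        sphericity_p=w_p,
        epsilon=eps,
    )


def rm_anova_twoway(
    cells: np.ndarray,
    factor_a: Tuple[str, Sequence[str]],
    factor_b: Tuple[str, Sequence[str]],
) -> Dict[str, StatsReport]:
    """Two-way fully-within RM-ANOVA on a (subjects, a, b) cell array.

    Returns a report per effect (factor A, factor B, interaction), each
    with F, df, p and partial eta squared; each effect's error term is its
    own subject-interaction.  Sphericity handling matches the one-way
    variant and applies to effects with more than 1 numerator df.
    """
    y = np.asarray(cells, dtype=float)
    if y.ndim != 3:
        raise ValueError("cells must be (subjects, levels_a, levels_b)")
    n, a, b = y.shape
    name_a, levels_a = factor_a
    name_b, levels_b = factor_b
    if len(levels_a) != a or len(levels_b) != b:
        raise ValueError("factor level names do not match cell array shape")
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if np.isnan(y).any():
        raise ValueError("incomplete factorial (missing cells)")

    grand = y.mean()
    m_s = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)
    m_ab = y.mean(axis=0)

    ss_a = n * b * float(np.sum((m_a - grand) ** 2))
    ss_b = n * a * float(np.sum((m_b - grand) ** 2))
    ss_ab = n * float(
        np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    )
    ss_err_a = b * float(
        np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    )
    ss_err_b = a * float(
        np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    )
    resid = (
        y
        - m_sa[:, :, None]
        - m_sb[:, None, :]
        - m_ab[None, :, :]
        + m_s[:, None, None]
        + m_a[None, :, None]
        + m_b[None, None, :]
        - grand
    )
    ss_err_ab = float(np.sum(resid**2))

    # long frame for pingouin's sphericity machinery
    rows = []
    for s in range(n):
        for i, la in enumerate(levels_a):
            for j, lb in enumerate(levels_b):
                rows.append((s, la, lb, y[s, i, j]))
    long = pd.DataFrame(rows, columns=["subject", name_a, name_b, "y"])

    def effect(name, ss_eff, ss_err, df1, df2, wide=None, within=None):
        ms_eff = ss_eff / df1
        ms_err = ss_err / df2
        if ms_err > 0:
            f_stat = ms_eff / ms_err
        else:
            f_stat = 0.0 if np.isclose(ms_eff, 0.0) else np.inf
        eta_p = ss_eff / (ss_eff + ss_err) if ss_eff + ss_err > 0 else 0.0
        w = w_p = eps = None
        correction = None
        if df1 > 1 and ss_eff + ss_err > 1e-12:
            if wide is not None:
                w, w_p, eps = _sphericity(wide)
            else:
                spher = pg.sphericity(
                    long, dv="y", within=within, subject="subject"
                )
                w, w_p = float(spher.W), float(spher.pval)
                eps = float(
                    pg.epsilon(long, dv="y", within=within, subject="subject",
                               correction="hf")
                )
            if w_p <= ALPHA:
                correction = "huynh-feldt"
                df1, df2 = eps * df1, eps * df2
        p = float(stats.f.sf(f_stat, df1, df2)) if np.isfinite(f_stat) else 0.0
        if not np.isfinite(f_stat):
            correction = (correction or "") + " [degenerate zero error variance]"
        return StatsReport(
            test=f"rm_anova_twoway:{name}",
            statistic=float(f_stat),
            df=(df1, df2),
            p=p,
            effect_size=float(eta_p),
            correction=correction,
            sphericity_w=w,
            sphericity_p=w_p,
            epsilon=eps,
        )

    wide_a = pd.DataFrame(m_sa, columns=list(levels_a))
    wide_b = pd.DataFrame(m_sb, columns=list(levels_b))
    return {
        name_a: effect(name_a, ss_a, ss_err_a, a - 1, (n - 1) * (a - 1), wide=wide_a),
        name_b: effect(name_b, ss_b, ss_err_b, b - 1, (n - 1) * (b - 1), wide=wide_b),
        f"{name_a} * {name_b}": effect(
            f"{name_a} * {name_b}",
            ss_ab,
            ss_err_ab,
            (a - 1) * (b - 1),
            (n - 1) * (a - 1) * (b - 1),
            within=[name_a, name_b],
        ),
    }


def friedman(matrix: ConditionMatrix) -> StatsReport:
    """Friedman rank test across conditions, blocked on split."""
    y = matrix.values
    if np.all(y == y[:, [0]]):
        # all conditions identical in every block: no rank information
        chi2, p = 0.0, 1.0
    else:
        chi2, p = stats.friedmanchisquare(*[y[:, j] for j in range(y.shape[1])])
    return StatsReport(
        test="friedman",
        statistic=float(chi2),
        df=(y.shape[1] - 1,),
        p=float(p),
    )


def bonferroni_posthoc(
    matrix: ConditionMatrix,
    pairs: Optional[Sequence[Tuple[str, str]]] = None,
    method: str = "ttest",
) -> pd.DataFrame:
    """Bonferroni-adjusted pairwise paired comparisons.

    ``method`` is the base test: "ttest" (paired t, ANOVA follow-up) or
    "wilcoxon" (signed-rank, Friedman follow-up).  Adjusted p is
    min(1, raw p x number of comparisons).  Zero-variance difference
    vectors are flagged with p = NaN.
    """
    if pairs is None:
        pairs = list(combinations(matrix.conditions, 2))
    if method not in ("ttest", "wilcoxon"):
        raise ValueError(f"unknown post hoc method {method!r}")
    m = len(pairs)
    idx = {c: j for j, c in enumerate(matrix.conditions)}
    rows = []
    for a, b in pairs:
        xa = matrix.values[:, idx[a]]
        xb = matrix.values[:, idx[b]]
        diff = xa - xb
        if np.ptp(diff) == 0:
            rows.append((a, b, np.nan, np.nan, np.nan, True))
            continue
        if method == "ttest":
            t_stat, p_raw = stats.ttest_rel(xa, xb)
        else:
            t_stat, p_raw = stats.wilcoxon(xa, xb)
        rows.append((a, b, float(t_stat), float(p_raw),
                     min(1.0, float(p_raw) * m), False))
    return pd.DataFrame(
        rows,
        columns=["a", "b", "statistic", "p_raw", "p_adjusted", "degenerate"],
    )


def full_report(
    matrix: ConditionMatrix,
    header: str = "",
    posthoc_method: str = "ttest",
) -> Tuple[List[StatsReport], str]:
    """Standard reporting pipeline for one condition family.

    Shapiro-Wilk per condition; if every condition passes normality the
    family is compared with the one-way RM-ANOVA (plus Bonferroni paired
    t post hocs when significant), otherwise with the Friedman test (plus
    Bonferroni Wilcoxon post hocs when significant).
    """
    reports: List[StatsReport] = []
    normal = True
    for j, cond in enumerate(matrix.conditions):
        col = matrix.values[:, j]
        try:
            rep = shapiro_wilk(col)
        except ValueError:
            normal = False
            continue
        rep.extra["condition"] = cond
        reports.append(rep)
        if rep.p <= ALPHA:
            normal = False
    if normal:
        main = rm_anova_oneway(matrix)
        follow = "ttest"
    else:
        main = friedman(matrix)
        follow = "wilcoxon" if posthoc_method == "ttest" else posthoc_method
    if main.significant:
        main.posthoc = bonferroni_posthoc(matrix, method=follow)
    reports.append(main)
    lines = [header, "repeated-measures subject: split index", ""]
    for rep in reports:
        tag = rep.extra.get("condition")
        prefix = f"[{tag}] " if tag else ""
        lines.append(prefix + rep.to_text())
    return reports, "\n".join(lines)
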