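"""Mixed-design repeated-measures ANOVA and nonparametric test battery.

The mixed ANOVA has one between-subjects factor (group) and one
within-subjects factor (timepoint), with the classical sum-of-squares
decomposition: the between-subjects variation splits into the group effect
and subject-within-group error, the within-subjects variation into the
time effect, the group x time interaction and the time x subject-within-
group error; each F ratio uses its matching error term.  Because every
subject is observed at every timepoint, the decomposition is exactly
orthogonal even when group sizes differ.

Pairwise comparisons use the Mann-Whitney U test (independent samples) and
the Wilcoxon signed-rank test (paired samples), exact for small samples and
tie-corrected normal approximations otherwise; all p-values are two-tailed.
Post hoc per-electrode-pair tables report uncorrected p-values (thresholded
at alpha) alongside a Bonferroni-adjusted column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .exceptions import (
    DegenerateInputError,
    UnbalancedDesignError,
    UndefinedTestError,
)
from .network import FeatureTable


# --------------------------------------------------------------------------
# mixed-design repeated-measures ANOVA

@dataclass
class MixedAnovaResults:
    """ANOVA table plus convenience accessors for the three tested effects."""

    table: pd.DataFrame  # index: term; columns: sum_sq, df, ms, F, p
    group_labels: tuple[str, ...]
    timepoint_labels: tuple[str, ...]
    n_subjects: int

    def _row(self, term: str) -> pd.Series:
        return self.table.loc[term]

    @property
    def f_group(self) -> float:
        return float(self._row("group")["F"])

    @property
    def p_group(self) -> float:
        return float(self._row("group")["p"])

    @property
    def f_time(self) -> float:
        return float(self._row("time")["F"])

    @property
    def p_time(self) -> float:
        return float(self._row("time")["p"])

    @property
    def f_interaction(self) -> float:
        return float(self._row("group:time")["F"])

    @property
    def p_interaction(self) -> float:
        return float(self._row("group:time")["p"])

    def summary(self) -> str:
        lines = [
            "Mixed-design repeated-measures ANOVA",
            "=" * 37,
            f"groups: {', '.join(map(str, self.group_labels))}   "
            f"timepoints: {', '.join(map(str, self.timepoint_labels))}   "
            f"subjects: {self.n_subjects}",
            "",
            self.table.to_string(float_format=lambda v: f"{v:.6g}"),
        ]
        return "\n".join(lines)


class MixedAnova:
    """Two-way mixed ANOVA model: ``MixedAnova(values, groups).fit()``.

    values: (n_subjects, n_timepoints) array, one row per subject with a
        complete set of timepoint observations (missing values raise —
        listwise deletion is never applied silently).
    groups: per-subject group label.
    """

    def __init__(self, values: np.ndarray, groups,
                 timepoint_labels: tuple[str, ...] | None = None) -> None:
        values = np.asarray(values, dtype=float)
        if values.ndim != 2 or values.shape[1] < 2:
            raise DegenerateInputError(
                "values must be (n_subjects, n_timepoints>=2)")
        if np.isnan(values).any():
            raise UnbalancedDesignError(
                "missing timepoint observations; complete cases are required")
        groups = np.asarray(groups)
        if groups.shape[0] != values.shape[0]:
            raise DegenerateInputError("one group label per subject required")
        labels, counts = np.unique(groups, return_counts=True)
        if labels.size < 2:
            raise DegenerateInputError("need >= 2 groups")
        if counts.min() < 2:
            raise DegenerateInputError("need >= 2 subjects per group")
        self.values = values
        self.groups = groups
        self.group_labels = tuple(labels)
        self.timepoint_labels = timepoint_labels or tuple(
            f"T{t + 1}" for t in range(values.shape[1]))

    @classmethod
    def from_long(cls, df: pd.DataFrame, dv: str, subject: str,
                  within: str, between: str) -> "MixedAnova":
        """Build from a long-format DataFrame (one row per observation)."""
        wide = df.pivot_table(index=subject, columns=within, values=dv,
                              aggfunc="mean")
        if wide.isna().any().any():
            raise UnbalancedDesignError(
                "some subjects lack observations at some timepoints")
        grp = df.groupby(subject)[between].agg(
            lambda s: s.iloc[0]).reindex(wide.index)
        return cls(wide.to_numpy(), grp.to_numpy(),
                   timepoint_labels=tuple(map(str, wide.columns)))

    def fit(self) -> MixedAnovaResults:
        y = self.values
        groups = self.groups
        n, t = y.shape
        labels = self.group_labels
        g = len(labels)

        grand = y.mean()
        subj_mean = y.mean(axis=1)
        time_mean = y.mean(axis=0)
        group_mean = {lbl: y[groups == lbl].mean() for lbl in labels}
        n_g = {lbl: int((groups == lbl).sum()) for lbl in labels}
        cell_mean = {(lbl, j): y[groups == lbl, j].mean()
                     for lbl in labels for j in range(t)}

        ss_total = float(((y - grand) ** 2).sum())
        ss_subjects = float(t * ((subj_mean - grand) ** 2).sum())
        ss_group = float(t * sum(n_g[lbl] * (group_mean[lbl] - grand) ** 2
                                 for lbl in labels))
        ss_subj_within = ss_subjects - ss_group
        ss_time = float(n * ((time_mean - grand) ** 2).sum())
        ss_inter = float(sum(
            n_g[lbl] * (cell_mean[(lbl, j)] - group_mean[lbl]
                        - time_mean[j] + grand) ** 2
            for lbl in labels for j in range(t)))
        ss_err_within = ss_total - ss_subjects - ss_time - ss_inter
        ss_err_within = max(ss_err_within, 0.0)

        df_group, df_sw = g - 1, n - g
        df_time = t - 1
        df_inter = (g - 1) * (t - 1)
        df_err = (n - g) * (t - 1)

        def f_and_p(ss_eff, df_eff, ss_err, df_err):
            ms_eff = ss_eff / df_eff if df_eff else np.nan
            ms_err = ss_err / df_err if df_err else np.nan
            if not np.isfinite(ms_err) or ms_err <= 0:
                if ms_eff <= 1e-300 or not np.isfinite(ms_eff):
                    return 0.0, 1.0
                return np.inf, 0.0
            f = ms_eff / ms_err
            return float(f), float(sps.f.sf(f, df_eff, df_err))

        f_g, p_g = f_and_p(ss_group, df_group, ss_subj_within, df_sw)
        f_t, p_t = f_and_p(ss_time, df_time, ss_err_within, df_err)
        f_i, p_i = f_and_p(ss_inter, df_inter, ss_err_within, df_err)

        rows = {
            "group": (ss_group, df_group, f_g, p_g),
            "subject(group)": (ss_subj_within, df_sw, np.nan, np.nan),
            "time": (ss_time, df_time, f_t, p_t),
            "group:time": (ss_inter, df_inter, f_i, p_i),
            "time:subject(group)": (ss_err_within, df_err, np.nan, np.nan),
        }
        table = pd.DataFrame(
            {"sum_sq": {k: v[0] for k, v in rows.items()},
             "df": {k: v[1] for k, v in rows.items()},
             "F": {k: v[2] for k, v in rows.items()},
             "p": {k: v[3] for k, v in rows.items()}},
        )
        table["ms"] = table["sum_sq"] / table["df"].replace(0, np.nan)
        table = table[["sum_sq", "df", "ms", "F", "p"]]
        return MixedAnovaResults(table=table, group_labels=labels,
                                 timepoint_labels=self.timepoint_labels,
                                 n_subjects=n)


def mixed_anova(values: np.ndarray, groups,
                timepoint_labels=None) -> MixedAnovaResults:
    """Functional shorthand for ``MixedAnova(values, groups).fit()``."""
    return MixedAnova(values, groups, timepoint_labels).fit()


# --------------------------------------------------------------------------
# rank tests

def _has_ties(pooled: np.ndarray) -> bool:
    return np.unique(pooled).size < pooled.size


def mann_whitney(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-tailed Mann-Whitney U test; returns (U, p) with U the statistic
    of the first sample.

    mode "exact" enumerates the null distribution (valid without ties);
    "normal" uses the tie-corrected normal approximation with continuity
    correction; "auto" picks exact when n1+n2 <= 12 and there are no ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise DegenerateInputError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if mode == "auto":
        mode = ("exact" if x.size + y.size <= 12 and not _has_ties(pooled)
                else "normal")
    if mode == "exact" and _has_ties(pooled):
        mode = "normal"  # the exact null distribution assumes no ties
    method = "exact" if mode == "exact" else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method,
                           use_continuity=True)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def wilcoxon_signed_rank(x, y, mode: str = "auto") -> tuple[float, float]:
    """Two-tailed Wilcoxon signed-rank test for paired samples; zero
    differences are dropped.  Returns (W, p) with W the smaller signed-rank
    sum.  mode "exact" (valid for untied ranks) is chosen automatically for
    n <= 15 effective pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DegenerateInputError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise UndefinedTestError("all paired differences are zero")
    if d.size < 2:
        raise DegenerateInputError(
            "need >= 2 nonzero differences for the signed-rank test")
    if mode == "auto":
        # scipy's exact method enumerates sign assignments and handles
        # tied midranks correctly
        mode = "exact" if d.size <= 15 else "normal"
    method = "exact" if mode == "exact" else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                           method=method, correction=False)
    return float(res.statistic), float(min(res.pvalue, 1.0))


# --------------------------------------------------------------------------
# post hoc per-pair comparisons

@dataclass
class PosthocTable:
    """Per-electrode-pair comparison table for one contrast."""

    table: pd.DataFrame  # pair, statistic, p, p_bonferroni, significant, ...
    contrast: str
    test: str
    alpha: float

    def significant_pairs(self) -> list[str]:
        return list(self.table.loc[self.table["significant"], "pair"])

    def summary(self) -> str:
        head = (f"Post hoc {self.test} tests, {self.contrast} "
                f"(alpha={self.alpha}; uncorrected threshold, Bonferroni "
                f"column reported alongside)")
        return head + "\n" + self.table.to_string(
            index=False, float_format=lambda v: f"{v:.4g}")


def posthoc_pairs(table: FeatureTable, alpha: float = 0.05,
                  between: tuple[str, str] | None = None,
                  group_column: str = "group",
                  timepoint: str | None = None,
                  within_group: str | None = None,
                  timepoints: tuple[str, str] | None = None,
                  mode: str = "auto") -> PosthocTable:
    """Per-pair comparisons for a between-group or within-group contrast.

    Between-group: ``posthoc_pairs(ft, between=("responder",
    "nonresponder"), group_column="responder", timepoint="baseline")`` runs
    a Mann-Whitney U test per electrode pair.  Within-group:
    ``posthoc_pairs(ft, within_group="treated", timepoints=("baseline",
    "month12"))`` runs a Wilcoxon signed-rank test per pair, paired by
    subject.  Reports the uncorrected p (flagged at ``alpha``, as in
    exploratory post hoc practice) and a Bonferroni-adjusted column.
    """
    if (between is None) == (within_group is None):
        raise DegenerateInputError(
            "specify exactly one of `between` or `within_group`")
    rows = []
    if between is not None:
        a, b = between
        sub = table.rows(timepoint=timepoint)
        xa = sub.df[sub.df[group_column] == a]
        xb = sub.df[sub.df[group_column] == b]
        if len(xa) < 2 or len(xb) < 2:
            raise DegenerateInputError(
                f"contrast {a} vs {b} needs >= 2 rows per side "
                f"(got {len(xa)}, {len(xb)})")
        contrast = f"{a} vs {b}" + (f" at {timepoint}" if timepoint else "")
        test = "Mann-Whitney U"
        for feat in table.feature_columns:
            va, vb = xa[feat].to_numpy(), xb[feat].to_numpy()
            stat, p = mann_whitney(va, vb, mode=mode)
            rows.append({"pair": feat, "statistic": stat, "p": p,
                         "median_diff": float(np.median(va) - np.median(vb)),
                         "n1": len(va), "n2": len(vb)})
    else:
        t1, t2 = timepoints or ("baseline", "month12")
        sub = table.rows(group=within_group) if within_group != "all" \
            else table
        w1 = sub.df[sub.df["timepoint"] == t1].set_index("subject_id")
        w2 = sub.df[sub.df["timepoint"] == t2].set_index("subject_id")
        common = w1.index.intersection(w2.index)
        if len(common) < 2:
            raise DegenerateInputError(
                f"paired contrast needs >= 2 subjects with both timepoints")
        contrast = f"{within_group}: {t1} vs {t2}"
        test = "Wilcoxon signed-rank"
        for feat in table.feature_columns:
            va = w1.loc[common, feat].to_numpy()
            vb = w2.loc[common, feat].to_numpy()
            try:
                stat, p = wilcoxon_signed_rank(va, vb, mode=mode)
            except UndefinedTestError:
                stat, p = np.nan, 1.0  # identical paired values: no evidence
            rows.append({"pair": feat, "statistic": stat, "p": p,
                         "median_diff": float(np.median(va - vb)),
                         "n1": len(common), "n2": len(common)})
    out = pd.DataFrame(rows)
    m = len(out)
    out["p_bonferroni"] = np.minimum(out["p"] * m, 1.0)
    out["significant"] = out["p"] < alpha
    return PosthocTable(table=out, contrast=contrast, test=test, alpha=alpha)
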