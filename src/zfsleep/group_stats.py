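"""Group-level statistics: mean ± SEM, ANOVA + Tukey HSD, t-test, MANOVA.

Classical equal-variance tests are the default (a Welch switch is provided
for the two-sample t and one-way ANOVA); the multivariate comparison uses
Wilks' lambda with per-metric ANOVA follow-ups under Bonferroni correction.
Alpha defaults to 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import StatisticsError

DEFAULT_ALPHA = 0.05


@dataclass
class GroupSummary:
    group_label: str
    n: int
    mean: float
    sem: float  # NaN for n == 1

    def to_dict(self) -> dict:
        return {"group_label": self.group_label, "n": self.n,
                "mean": self.mean, "sem": self.sem}


@dataclass
class ComparisonResult:
    """An omnibus statistic with optional pairwise follow-ups.

    ``pairwise`` rows are (group_a, group_b, estimate, adjusted_p,
    significant); estimates are mean(a) - mean(b).
    """

    test: str
    statistic: float
    p_value: float
    df: tuple
    alpha: float = DEFAULT_ALPHA
    pairwise: list = field(default_factory=list)
    per_metric: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)


def _as_groups(values_by_group: dict, min_n: int = 1) -> dict:
    if len(values_by_group) < 1:
        raise StatisticsError("no groups supplied")
    out = {}
    for label, vals in values_by_group.items():
        arr = np.asarray(vals, dtype=float)
        arr = arr[np.isfinite(arr)]
        if arr.size < min_n:
            raise StatisticsError(
                f"group {label!r} has {arr.size} finite values; need >= {min_n}"
            )
        out[label] = arr
    return out


def summarize_groups(values_by_group: dict) -> list:
    """Per-group mean and SEM (sample sd over sqrt n); SEM is NaN for n = 1."""
    groups = _as_groups(values_by_group, min_n=1)
    out = []
    for label, arr in groups.items():
        sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else float("nan")
        out.append(GroupSummary(label, int(arr.size), float(arr.mean()), sem))
    return out


def two_sample_t(
    a, b, alpha: float = DEFAULT_ALPHA, welch: bool = False
) -> ComparisonResult:
    """Two-sided Student's t (pooled variance by default; Welch optional)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise StatisticsError("each sample needs n >= 2")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df = res.df if hasattr(res, "df") else a.size + b.size - 2
    return ComparisonResult(
        test="welch_t" if welch else "student_t",
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        df=(float(df),),
        alpha=alpha,
    )


def one_way_anova(
    values_by_group: dict, alpha: float = DEFAULT_ALPHA, welch: bool = False
) -> ComparisonResult:
    """One-way fixed-effects ANOVA across k groups; df = (k-1, N-k)."""
    groups = _as_groups(values_by_group, min_n=2)
    if len(groups) < 2:
        raise StatisticsError("ANOVA needs >= 2 groups")
    arrays = list(groups.values())
    allv = np.concatenate(arrays)
    if np.ptp(allv) == 0:
        raise StatisticsError("degenerate data: all values identical")
    k = len(arrays)
    n = allv.size
    if welch:
        ni = np.array([a.size for a in arrays], float)
        mi = np.array([a.mean() for a in arrays])
        vi = np.array([a.var(ddof=1) for a in arrays])
        if np.any(vi == 0):
            raise StatisticsError("Welch ANOVA needs nonzero within-group variance")
        wi = ni / vi
        W = wi.sum()
        mw = (wi * mi).sum() / W
        a_term = (wi * (mi - mw) ** 2).sum() / (k - 1)
        lam = 3.0 * ((1 - wi / W) ** 2 / (ni - 1)).sum() / (k**2 - 1)
        stat = float(a_term / (1 + 2 * lam * (k - 2) / 3))
        df2 = 1.0 / lam
        p = float(sps.f.sf(stat, k - 1, df2))
        return ComparisonResult(
            test="welch_anova", statistic=stat, p_value=p,
            df=(k - 1, float(df2)), alpha=alpha,
        )
    res = sps.f_oneway(*arrays)
    stat, p = float(res.statistic), float(res.pvalue)
    # identical groups give SSbetween = 0 -> F = 0, p = 1
    if np.isnan(stat):
        stat, p = 0.0, 1.0
    return ComparisonResult(
        test="one_way_anova", statistic=stat, p_value=p, df=(k - 1, n - k),
        alpha=alpha,
    )


def tukey_hsd(values_by_group: dict, alpha: float = DEFAULT_ALPHA) -> ComparisonResult:
    """Tukey honest-significant-difference pairwise comparisons.

    Adjusted p-values come from the studentized-range distribution; the
    omnibus fields carry the parent ANOVA.
    """
    groups = _as_groups(values_by_group, min_n=2)
    if len(groups) < 2:
        raise StatisticsError("Tukey HSD needs >= 2 groups")
    labels = list(groups)
    arrays = [groups[g] for g in labels]
    allv = np.concatenate(arrays)
    if np.ptp(allv) == 0:
        raise StatisticsError("degenerate data: all values identical")
    omni = one_way_anova(values_by_group, alpha=alpha)
    res = sps.tukey_hsd(*arrays)
    pairwise = []
    for i, j in combinations(range(len(labels)), 2):
        est = float(arrays[i].mean() - arrays[j].mean())
        p = float(res.pvalue[i, j])
        pairwise.append((labels[i], labels[j], est, p, p < alpha))
    return ComparisonResult(
        test="tukey_hsd",
        statistic=omni.statistic,
        p_value=omni.p_value,
        df=omni.df,
        alpha=alpha,
        pairwise=pairwise,
    )


def bonferroni(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: multiply by the number of tests, cap at 1."""
    p = np.asarray(p_values, dtype=float)
    m = int(m if m is not None else p.size)
    return np.minimum(p * m, 1.0)


def multivariate_comparison(
    metrics_by_group: dict,
    alpha: float = DEFAULT_ALPHA,
    metric_names: list | None = None,
) -> ComparisonResult:
    """Wilks'-lambda MANOVA across groups, Bonferroni-corrected follow-ups.

    ``metrics_by_group`` maps group label -> (n_subjects, n_metrics) array.
    When the omnibus test is significant, each metric gets a one-way ANOVA
    whose p-value is multiplied by the number of metrics (capped at 1).
    """
    from statsmodels.multivariate.manova import MANOVA

    labels = list(metrics_by_group)
    if len(labels) < 2:
        raise StatisticsError("MANOVA needs >= 2 groups")
    mats = {}
    for g in labels:
        m = np.atleast_2d(np.asarray(metrics_by_group[g], dtype=float))
        if m.ndim != 2:
            raise StatisticsError(f"group {g!r}: metric matrix must be 2-D")
        mats[g] = m
    n_metrics = mats[labels[0]].shape[1]
    if metric_names is None:
        metric_names = [f"metric_{i}" for i in range(n_metrics)]
    if len(metric_names) != n_metrics:
        raise StatisticsError("metric_names length mismatch")
    for g, m in mats.items():
        if m.shape[1] != n_metrics:
            raise StatisticsError("groups disagree on number of metrics")
        if m.shape[0] <= n_metrics:
            raise StatisticsError(
                f"group {g!r}: n = {m.shape[0]} must exceed {n_metrics} metrics"
            )
        if not np.all(np.isfinite(m)):
            raise StatisticsError(f"group {g!r}: non-finite metric values")

    endog = np.vstack([mats[g] for g in labels])
    # dummy-coded design with intercept
    sizes = [mats[g].shape[0] for g in labels]
    gidx = np.repeat(np.arange(len(labels)), sizes)
    exog = np.column_stack(
        [np.ones(endog.shape[0])]
        + [(gidx == k).astype(float) for k in range(1, len(labels))]
    )

    if n_metrics == 1:
        # a single metric reduces exactly to the one-way ANOVA
        uni = one_way_anova({g: mats[g][:, 0] for g in labels}, alpha=alpha)
        return ComparisonResult(
            test="manova_wilks", statistic=uni.statistic, p_value=uni.p_value,
            df=uni.df, alpha=alpha,
            per_metric={metric_names[0]: {"F": uni.statistic, "p": uni.p_value,
                                          "p_adjusted": uni.p_value}},
        )

    try:
        mv = MANOVA(endog, exog)
        table = mv.mv_test(
            hypotheses=[("group", np.eye(exog.shape[1])[1:], None)]
        ).results["group"]["stat"]
    except Exception as exc:  # singular pooled covariance and friends
        raise StatisticsError(
            "MANOVA failed (singular covariance? try a metric subset): "
            f"{exc}"
        ) from exc
    row = table.loc["Wilks' lambda"]
    stat = float(row["Value"])
    p = float(row["Pr > F"])
    df = (float(row["Num DF"]), float(row["Den DF"]))

    per_metric: dict = {}
    raw = []
    for j, name in enumerate(metric_names):
        uni = one_way_anova({g: mats[g][:, j] for g in labels}, alpha=alpha)
        raw.append(uni.p_value)
        per_metric[name] = {"F": uni.statistic, "p": uni.p_value}
    adj = bonferroni(raw, m=n_metrics)
    for name, pa in zip(metric_names, adj):
        per_metric[name]["p_adjusted"] = float(pa)

    return ComparisonResult(
        test="manova_wilks", statistic=stat, p_value=p, df=df, alpha=alpha,
        per_metric=per_metric,
    )


def summaries_frame(summaries: list) -> pd.DataFrame:
    return pd.DataFrame([s.to_dict() for s in summaries])
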