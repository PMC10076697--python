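"""Reliability and validity statistics for score tables.

The validation layer mirrors how automated scoring of an open-ended scale is
conventionally evaluated: internal consistency of each method's 20 item
scores (Cronbach's alpha with a Feldt F-based 95% CI), agreement of each
method with a reference (hand) scoring via Pearson correlation and the mean
absolute per-protocol difference, covariate-adjusted correlations (partial
correlations controlling for word count + vocabulary jointly, or for
completion time with the one-hour exclusion), and a Welch two-sample t-test
for group comparisons.

All results are returned as :class:`StatResult` records (estimate, 95% CI,
p-value, n, df) that serialize to plain JSON.  Missing covariates are
handled by listwise deletion with the effective n reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats as sps

from .errors import DegenerateDesignError, UndefinedStatisticError, UsageError
from .scoring import LEVEL_METHODS, TIME_EXCLUSION_MINUTES

__all__ = [
    "StatResult",
    "cronbach_alpha",
    "pearson_r",
    "partial_r",
    "independent_t_test",
    "mean_protocol_difference",
    "agreement_report",
    "analyze",
]


@dataclass
class StatResult:
    """An estimate with its 95% CI, p-value, effective n and df."""

    estimate: float
    ci95: tuple[float, float] | None = None
    p_value: float | None = None
    n: int | None = None
    df: float | None = None
    statistic: float | None = None  # test statistic where distinct from estimate

    def to_dict(self) -> dict:
        d: dict = {"estimate": _f(self.estimate)}
        d["ci95"] = [_f(self.ci95[0]), _f(self.ci95[1])] if self.ci95 else None
        d["p_value"] = _f(self.p_value)
        d["n"] = int(self.n) if self.n is not None else None
        d["df"] = _f(self.df)
        if self.statistic is not None:
            d["statistic"] = _f(self.statistic)
        return d


def _f(x) -> float | None:
    return None if x is None else float(x)


def _asarray(x) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise UsageError("expected a 1-d numeric vector")
    return a


def cronbach_alpha(matrix, ci: float = 0.95) -> StatResult:
    """Cronbach's alpha over an items matrix (rows = respondents).

    alpha = k/(k-1) * (1 - sum(item variances) / variance(total)), with
    sample (n-1) variances.  The CI is Feldt's F interval: 1 - alpha is
    proportional to an F ratio with (n-1) and (n-1)(k-1) degrees of freedom.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2:
        raise UsageError("items matrix must be 2-dimensional")
    n, k = M.shape
    if k < 2:
        raise UsageError("alpha needs at least 2 items")
    if n < 3:
        raise UsageError("alpha needs at least 3 respondents")
    item_vars = M.var(axis=0, ddof=1)  # per-item (column) variances
    total_var = M.sum(axis=1).var(ddof=1)
    if total_var <= 0:
        raise UndefinedStatisticError("total-score variance is zero")
    alpha = k / (k - 1) * (1.0 - item_vars.sum() / total_var)
    q = (1.0 - ci) / 2.0
    df1, df2 = n - 1, (n - 1) * (k - 1)
    lower = 1.0 - (1.0 - alpha) * sps.f.isf(q, df1, df2)
    upper = 1.0 - (1.0 - alpha) * sps.f.ppf(q, df1, df2)
    return StatResult(estimate=alpha, ci95=(lower, upper), p_value=None, n=n, df=df1)


def pearson_r(x, y, ci: float = 0.95) -> StatResult:
    """Pearson product-moment correlation with Fisher-z CI.

    Two-sided p from the t distribution with n-2 df.  Zero variance in either
    vector is an undefined statistic, not a silent NaN.
    """
    x, y = _asarray(x), _asarray(y)
    if len(x) != len(y):
        raise UsageError(f"length mismatch: {len(x)} vs {len(y)}")
    n = len(x)
    if n < 3:
        raise UsageError("correlation needs n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise UndefinedStatisticError("zero variance in input vector")
    res = sps.pearsonr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    if abs(r) >= 1.0 - 1e-15:
        ci95 = (r, r)
    elif n > 3:
        iv = res.confidence_interval(confidence_level=ci)
        ci95 = (float(iv.low), float(iv.high))
    else:
        ci95 = None  # Fisher z interval needs n > 3
    return StatResult(estimate=r, ci95=ci95, p_value=p, n=n, df=n - 2)


def partial_r(x, y, covariates: Sequence | None = None, ci: float = 0.95) -> StatResult:
    """Partial correlation of x and y given covariates.

    Computed as the correlation of the residuals of x and y after linear
    regression on the covariates (pingouin's residual method, identical to
    the recursive partial-correlation formula); two-sided p from t with
    n - 2 - q df.  An empty covariate set reduces to :func:`pearson_r`.
    """
    x, y = _asarray(x), _asarray(y)
    covs = [_asarray(c) for c in (covariates or [])]
    if not covs:
        return pearson_r(x, y, ci=ci)
    for c in covs:
        if len(c) != len(x):
            raise UsageError("covariate length mismatch")
    if len(x) != len(y):
        raise UsageError(f"length mismatch: {len(x)} vs {len(y)}")
    q = len(covs)
    design = np.column_stack([np.ones_like(x)] + covs)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise DegenerateDesignError("covariate design matrix is rank deficient")
    if np.var(x) == 0 or np.var(y) == 0:
        raise UndefinedStatisticError("zero variance in input vector")
    import pingouin as pg

    df = pd.DataFrame({"x": x, "y": y})
    covar_names = []
    for i, c in enumerate(covs):
        name = f"c{i}"
        df[name] = c
        covar_names.append(name)
    out = pg.partial_corr(data=df, x="x", y="y", covar=covar_names, method="pearson")
    r = float(out["r"].iloc[0])
    p_col = "p_val" if "p_val" in out.columns else "p-val"
    p = float(out[p_col].iloc[0])
    n = int(out["n"].iloc[0])
    # Fisher z interval with the covariate-adjusted standard error
    if abs(r) >= 1.0 - 1e-15 or n - q - 3 <= 0:
        ci95 = (r, r) if abs(r) >= 1.0 - 1e-15 else None
    else:
        z = math.atanh(r)
        half = sps.norm.ppf(1 - (1 - ci) / 2) / math.sqrt(n - q - 3)
        ci95 = (math.tanh(z - half), math.tanh(z + half))
    return StatResult(estimate=r, ci95=ci95, p_value=p, n=n, df=n - 2 - q)


def independent_t_test(a, b) -> StatResult:
    """Welch's two-sided independent-samples t-test.

    Unequal-variance t with Welch-Satterthwaite df.  The estimate is the
    mean difference (a - b) with its Welch CI; the t statistic is reported
    alongside.
    """
    a, b = _asarray(a), _asarray(b)
    if len(a) < 2 or len(b) < 2:
        raise UsageError("each group needs at least 2 observations")
    res = sps.ttest_ind(a, b, equal_var=False)
    iv = res.confidence_interval(confidence_level=0.95)
    return StatResult(
        estimate=float(a.mean() - b.mean()),
        ci95=(float(iv.low), float(iv.high)),
        p_value=float(res.pvalue),
        n=len(a) + len(b),
        df=float(res.df),
        statistic=float(res.statistic),
    )


def mean_protocol_difference(method_scores, reference_scores) -> float:
    """Mean absolute per-respondent difference between paired protocol scores."""
    m, r = _asarray(method_scores), _asarray(reference_scores)
    if len(m) != len(r):
        raise UsageError(f"length mismatch: {len(m)} vs {len(r)}")
    if len(m) == 0:
        raise UsageError("empty score vectors")
    return float(np.mean(np.abs(m - r)))


def _item_cols(score_table: pd.DataFrame, method: str) -> list[str]:
    return [c for c in score_table.columns if c.startswith(f"{method}_item")]


def _methods_in(score_table: pd.DataFrame) -> list[str]:
    return [m for m in LEVEL_METHODS if f"{m}_protocol" in score_table.columns]


def agreement_report(
    score_table: pd.DataFrame,
    reference: pd.Series,
    methods: Iterable[str] | None = None,
) -> dict:
    """Agreement of each method with a reference scoring.

    For each method on the respondents shared with the reference: Pearson r
    of protocol scores vs the reference, the mean absolute per-protocol
    difference, and the method's internal consistency (alpha over its item
    columns).  An undefined statistic for one method (e.g. constant scores)
    is surfaced as an error entry without affecting the others.
    """
    methods = list(methods) if methods is not None else _methods_in(score_table)
    common = score_table.index.intersection(reference.dropna().index)
    if len(common) == 0:
        raise UsageError("no respondents shared between scores and reference")
    ref = reference.loc[common].astype(float)
    report: dict = {"n": int(len(common)), "methods": {}}
    for m in methods:
        entry: dict = {}
        proto = score_table.loc[common, f"{m}_protocol"].astype(float)
        try:
            entry["r"] = pearson_r(proto, ref).to_dict()
        except UndefinedStatisticError as e:
            entry["r"] = {"error": str(e)}
        entry["mean_difference"] = mean_protocol_difference(proto, ref)
        cols = _item_cols(score_table, m)
        if cols:
            try:
                entry["alpha"] = cronbach_alpha(score_table.loc[common, cols]).to_dict()
            except UndefinedStatisticError as e:
                entry["alpha"] = {"error": str(e)}
        report["methods"][m] = entry
    return report


def _binary_code(series: pd.Series) -> tuple[pd.Series, dict | None]:
    """Code a two-level categorical column as 0/1 (levels sorted, first = 0)."""
    s = series.dropna()
    if s.empty:
        return series.astype(float), None
    try:
        return series.astype(float), None
    except (TypeError, ValueError):
        pass
    levels = sorted(s.astype(str).unique())
    if len(levels) > 2:
        raise UsageError(
            f"cannot 0/1-code column with {len(levels)} levels: {levels}"
        )
    coding = {lvl: i for i, lvl in enumerate(levels)}
    return series.astype(str).map(coding).astype(float), coding


_SOCIODEMOGRAPHIC = ("age", "gender", "education", "children")
_EXTERNAL_SCALES = ("pat", "mss", "tas20", "bdi", "dass", "pat_like")


def _pairwise(x: pd.Series, y: pd.Series, covs: list[pd.Series] | None = None):
    """Listwise-deleted correlation helper returning a dict or error entry."""
    frame = pd.concat([x, y] + (covs or []), axis=1).dropna()
    if len(frame) < 4:
        return {"error": f"insufficient complete cases (n={len(frame)})"}
    cols = frame.columns
    try:
        if covs:
            res = partial_r(
                frame.iloc[:, 0], frame.iloc[:, 1],
                [frame.iloc[:, i] for i in range(2, len(cols))],
            )
        else:
            res = pearson_r(frame.iloc[:, 0], frame.iloc[:, 1])
        return res.to_dict()
    except (UndefinedStatisticError, DegenerateDesignError) as e:
        return {"error": str(e)}


def analyze(
    scores: pd.DataFrame,
    reference: pd.Series | None = None,
    methods: Iterable[str] | None = None,
) -> dict:
    """Full psychometric report for a score table.

    ``scores`` is the score table produced by ``score_survey`` /
    ``write_scores`` (item and protocol columns per method, plus any
    auxiliary covariate columns).  Sections:

    - ``alpha``: internal consistency per method.
    - ``agreement``: vs the reference scoring, when given.
    - ``sociodemographic``: protocol correlations with age, gender (0/1),
      education and children (0/1); the coding used is recorded.
    - ``covariate_adjusted``: protocol correlations with external scale
      totals, first-order and adjusted for word count + vocabulary and for
      completion time (respondents over one hour excluded from the
      time-adjusted column only).
    - ``group_tests``: Welch t comparing the two gender groups per method.
    """
    methods = list(methods) if methods is not None else _methods_in(scores)
    report: dict = {"n": int(len(scores)), "codings": {}}

    alpha: dict = {}
    for m in methods:
        cols = _item_cols(scores, m)
        if not cols:
            continue
        try:
            alpha[m] = cronbach_alpha(scores[cols]).to_dict()
        except UndefinedStatisticError as e:
            alpha[m] = {"error": str(e)}
    report["alpha"] = alpha

    if reference is not None:
        report["agreement"] = agreement_report(scores, reference, methods)

    coded: dict[str, pd.Series] = {}
    for col in _SOCIODEMOGRAPHIC:
        if col in scores.columns:
            series, coding = _binary_code(scores[col])
            coded[col] = series
            if coding:
                report["codings"][col] = coding
    socio: dict = {}
    for m in methods:
        proto = scores[f"{m}_protocol"].astype(float)
        socio[m] = {
            col: _pairwise(proto, coded[col]) for col in coded
        }
    report["sociodemographic"] = socio

    has_wc = {"wordcount_protocol", "vocabulary_protocol"} <= set(scores.columns)
    time_col = scores["time_minutes"] if "time_minutes" in scores.columns else None
    adjusted: dict = {}
    for m in methods:
        proto = scores[f"{m}_protocol"].astype(float)
        per_scale: dict = {}
        for scale in _EXTERNAL_SCALES:
            if scale not in scores.columns:
                continue
            target = scores[scale].astype(float)
            cell: dict = {"first_order": _pairwise(proto, target)}
            if has_wc:
                cell["adjusted_wordcount_vocabulary"] = _pairwise(
                    proto, target,
                    [scores["wordcount_protocol"].astype(float),
                     scores["vocabulary_protocol"].astype(float)],
                )
            if time_col is not None:
                keep = time_col.astype(float) <= TIME_EXCLUSION_MINUTES
                cell["adjusted_time"] = _pairwise(
                    proto[keep], target[keep], [time_col[keep].astype(float)]
                )
            per_scale[scale] = cell
        if per_scale:
            adjusted[m] = per_scale
    report["covariate_adjusted"] = adjusted

    group: dict = {}
    if "gender" in coded:
        g = coded["gender"]
        for m in methods:
            proto = scores[f"{m}_protocol"].astype(float)
            frame = pd.concat([proto, g], axis=1).dropna()
            levels = sorted(frame.iloc[:, 1].unique())
            if len(levels) == 2:
                a = frame[frame.iloc[:, 1] == levels[0]].iloc[:, 0]
                b = frame[frame.iloc[:, 1] == levels[1]].iloc[:, 0]
                if len(a) >= 2 and len(b) >= 2:
                    group[m] = independent_t_test(a, b).to_dict()
    report["group_tests"] = group
    return report
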