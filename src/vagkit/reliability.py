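"""ICC(A,1) test-retest reliability from subject-by-session matrices.

The estimator is the single-measurement, absolute-agreement intraclass
correlation of McGraw & Wong for a two-way crossed design without
replication (n subjects by k sessions):

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n) (MSC - MSE))

where MSR, MSC, MSE are the between-subjects, between-sessions and residual
mean squares of the two-way ANOVA. Confidence bounds use the McGraw-Wong
F-interval with Satterthwaite degrees of freedom for the denominator.

Point estimates are categorized with the Koo-Li bands: poor (< 0.5),
moderate [0.5, 0.75), good [0.75, 0.9), excellent [0.9, 1.0] — left-closed
at the cutpoints, and anything negative is poor.

ICC(A,k) — the reliability of the mean of the k sessions — is available via
``icc_a1(..., average=True)`` for completeness; the headline statistic is
the single-measurement form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from vagkit.features import FEATURE_NAMES

KOO_LI_BANDS = ((0.5, "poor"), (0.75, "moderate"), (0.9, "good"), (np.inf, "excellent"))


@dataclass(frozen=True)
class MeasurementMatrix:
    """n x k matrix of one feature: rows are subjects, columns sessions."""

    values: np.ndarray
    feature_name: str = ""
    group: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] < 2 or v.shape[1] < 2:
            raise ValueError("need an n x k matrix with n >= 2 subjects and k >= 2 sessions")
        if not np.all(np.isfinite(v)):
            raise ValueError("matrix contains missing or non-finite cells")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ReliabilityResult:
    """ICC point estimate with its confidence interval and ANOVA mean squares."""

    icc: float
    lci: float
    uci: float
    confidence: float
    msr: float
    msc: float
    mse: float
    n: int
    k: int
    category: str
    flags: tuple[str, ...] = ()


def anova_mean_squares(matrix: MeasurementMatrix | np.ndarray) -> tuple[float, float, float]:
    """Mean squares (MSR, MSC, MSE) of the two-way ANOVA without replication.

    SSR = k * sum_i (row_mean_i - grand)^2 on n-1 df;
    SSC = n * sum_j (col_mean_j - grand)^2 on k-1 df;
    SSE = SST - SSR - SSC on (n-1)(k-1) df.
    """
    if not isinstance(matrix, MeasurementMatrix):
        matrix = MeasurementMatrix(values=matrix)
    x = matrix.values
    n, k = matrix.n, matrix.k
    grand = x.mean()
    ssr = k * float(np.sum((x.mean(axis=1) - grand) ** 2))
    ssc = n * float(np.sum((x.mean(axis=0) - grand) ** 2))
    sst = float(np.sum((x - grand) ** 2))
    sse = max(sst - ssr - ssc, 0.0)
    return ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))


def interpret_icc(icc: float) -> str:
    """Koo-Li reliability category for an ICC point estimate (left-closed bands)."""
    if icc > 1:
        raise ValueError("ICC cannot exceed 1")
    for upper, label in KOO_LI_BANDS:
        if icc < upper:
            return label
    return "excellent"


def icc_a1(
    matrix: MeasurementMatrix | np.ndarray,
    confidence: float = 0.95,
    average: bool = False,
) -> ReliabilityResult:
    """ICC(A,1) with a McGraw-Wong confidence interval.

    Parameters
    ----------
    matrix : MeasurementMatrix or array
        n subjects x k sessions of one feature.
    confidence : float
        Two-sided confidence level of the interval.
    average : bool
        If True return ICC(A,k), the absolute agreement of the k-session
        mean, instead of the single-measurement form.
    """
    if not isinstance(matrix, MeasurementMatrix):
        matrix = MeasurementMatrix(values=matrix)
    if not 0 < confidence < 1:
        raise ValueError("confidence must be in (0, 1)")
    n, k = matrix.n, matrix.k
    msr, msc, mse = anova_mean_squares(matrix)
    flags: list[str] = []

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0:
        flags.append("undefined")
        icc = float("nan")
    else:
        icc = (msr - mse) / denom
        if average:
            denom_k = msr + (msc - mse) / n
            icc = (msr - mse) / denom_k if denom_k > 0 else float("nan")

    alpha = 1.0 - confidence
    if np.isnan(icc):
        lci = uci = float("nan")
    elif mse == 0 and msc <= mse:
        # Degenerate: no within-subject variability at all; interval collapses.
        lci = uci = icc
    else:
        a = k * icc / (n * (1.0 - icc)) if icc < 1 else np.inf
        b = 1.0 + k * icc * (n - 1.0) / (n * (1.0 - icc)) if icc < 1 else np.inf
        with np.errstate(invalid="ignore", divide="ignore"):
            v = (a * msc + b * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
        if not np.isfinite(v):
            v = (n - 1) * (k - 1)
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
        c = k * msc + (k * n - k - n) * mse
        with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
            lci = n * (msr - f_l * mse) / (f_l * c + n * msr)
            uci = n * (f_u * msr - mse) / (c + n * f_u * msr)
        # Satterthwaite df can collapse to ~0, sending the F-quantile to
        # infinity; take the analytic limits of the bounds there.
        if not np.isfinite(lci):
            lci = -n * mse / c if c > 0 else icc
        if not np.isfinite(uci):
            uci = 1.0 if msr > 0 else icc
        if average:
            # Spearman-Brown step-up of the single-measurement bounds.
            lci = k * lci / (1 + (k - 1) * lci)
            uci = k * uci / (1 + (k - 1) * uci)
        lci, uci = min(lci, icc), max(uci, min(icc, 1.0))
        uci = min(uci, 1.0)

    category = interpret_icc(min(icc, 1.0)) if np.isfinite(icc) else "undefined"
    return ReliabilityResult(icc=float(icc), lci=float(lci), uci=float(uci),
                             confidence=confidence, msr=msr, msc=msc, mse=mse,
                             n=n, k=k, category=category, flags=tuple(flags))


def _matrix_from_table(table: pd.DataFrame, feature: str) -> np.ndarray | None:
    """Pivot one feature into a subjects x sessions matrix, dropping unpaired rows."""
    wide = table.pivot_table(index="subject_id", columns="session",
                             values=feature, aggfunc="mean")
    complete = wide.dropna()
    dropped = len(wide) - len(complete)
    if dropped:
        warnings.warn(f"{dropped} subject(s) without complete sessions excluded "
                      f"for feature {feature!r}", stacklevel=3)
    if len(complete) < 2:
        return None
    return complete.to_numpy()


def reliability_report(
    feature_table: pd.DataFrame,
    features: list[str] | None = None,
    confidence: float = 0.95,
    groups: tuple[str, ...] = ("symptomatic", "asymptomatic", "combined"),
) -> pd.DataFrame:
    """ICC(A,1) per feature for the study group, control group and both combined.

    Expects a long-format feature table with columns
    ``subject_id, group, session`` plus one column per feature. Emits one row
    per (feature, group) with columns ``feature, group, lci, icc, uci,
    category`` — the layout of a per-group reliability table.
    """
    features = features or FEATURE_NAMES
    rows = []
    for feature in features:
        for group in groups:
            sub = feature_table if group == "combined" else \
                feature_table[feature_table["group"] == group]
            mat = _matrix_from_table(sub, feature)
            if mat is None:
                res = dict(lci=np.nan, icc=np.nan, uci=np.nan, category="undefined")
            else:
                r = icc_a1(MeasurementMatrix(mat, feature_name=feature, group=group),
                           confidence=confidence)
                res = dict(lci=r.lci, icc=r.icc, uci=r.uci, category=r.category)
            rows.append({"feature": feature, "group": group, **res})
    return pd.DataFrame(rows, columns=["feature", "group", "lci", "icc", "uci", "category"])
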