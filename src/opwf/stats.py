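"""Baseline normalization, statistical battery and VRP/VEP phase classification.

Documented defaults for choices the statistical protocol leaves open:
Shapiro-Wilk at alpha = 0.05 gates parametric vs. rank-based tests;
Greenhouse-Geisser correction is applied when Mauchly's test rejects;
outliers use Tukey fences with linearly interpolated quartiles; no
multiple-testing correction by default (a Holm helper is provided).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from .errors import (
    CollinearityError,
    DegenerateTestError,
    MissingTrendError,
    NormalizationError,
    UndefinedCorrelationError,
)

__all__ = [
    "PhaseLabel",
    "TrendSummary",
    "OutlierResult",
    "RMTestResult",
    "CorrelationResult",
    "MultivariateFitResult",
    "normalize_to_baseline",
    "remove_outliers",
    "rm_test",
    "correlate",
    "multivariate_fit",
    "compute_trend",
    "trend_summaries",
    "classify_phase",
    "holm_correction",
]

ALPHA_NORMALITY = 0.05
PHASE_PARAMS = ("bos", "bot", "fr", "fai", "ri", "ac")


class PhaseLabel(str, enum.Enum):
    NORMAL = "NORMAL"
    VRP = "VRP"
    VEP = "VEP"
    INDETERMINATE = "INDETERMINATE"


@dataclass(frozen=True)
class TrendSummary:
    """OLS slope of baseline-normalized values against the day index."""

    parameter: str
    slope: float
    stderr: float
    p_value: float
    window: tuple[int, int]
    n: int


@dataclass(frozen=True)
class OutlierResult:
    kept: np.ndarray
    removed_indices: np.ndarray
    skipped: bool


@dataclass(frozen=True)
class RMTestResult:
    statistic: float
    p_value: float
    method: str  # "rm_anova" | "friedman"
    sphericity_corrected: bool = False


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    method: str  # "pearson" | "spearman"


@dataclass(frozen=True)
class MultivariateFitResult:
    predictors: tuple[str, ...]
    coef: np.ndarray  # unstandardized B (per predictor, no intercept)
    se: np.ndarray  # SE_B
    beta: np.ndarray  # standardized coefficients
    intercept: float
    r: float  # multiple correlation coefficient
    f_statistic: float
    f_pvalue: float
    df_model: int
    df_resid: int

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"B": self.coef, "SE_B": self.se, "beta": self.beta},
            index=list(self.predictors),
        )


# ---------------------------------------------------------------------------
# normalization & outliers
# ---------------------------------------------------------------------------

def normalize_to_baseline(data: pd.DataFrame, parameter: str) -> pd.DataFrame:
    """Divide each value by its rabbit/region baseline-session mean.

    Returns a copy of ``data`` with ``baseline_mean`` and ``normalized``
    columns added for ``parameter``.
    """
    if parameter not in data.columns:
        raise NormalizationError(f"parameter column {parameter!r} missing")
    out = data.copy()
    out["baseline_mean"] = np.nan
    for (rabbit, region), group in data.groupby(["rabbit_id", "region"]):
        baseline = group.loc[group["is_baseline"], parameter]
        if baseline.empty:
            raise NormalizationError(f"no baseline sessions for {rabbit}/{region}")
        mean = float(baseline.mean())
        if not np.isfinite(mean) or mean <= 0:
            raise NormalizationError(
                f"non-positive baseline mean for {rabbit}/{region}: {mean}"
            )
        out.loc[group.index, "baseline_mean"] = mean
    out["normalized"] = out[parameter] / out["baseline_mean"]
    return out


def remove_outliers(values: Sequence[float]) -> OutlierResult:
    """Tukey-fence outlier removal (quartiles by linear interpolation).

    With fewer than 4 values the rule is skipped and everything is kept.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 4:
        return OutlierResult(kept=values, removed_indices=np.array([], dtype=int), skipped=True)
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    low, high = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    outside = (values < low) | (values > high)
    return OutlierResult(
        kept=values[~outside],
        removed_indices=np.flatnonzero(outside),
        skipped=False,
    )


# ---------------------------------------------------------------------------
# hypothesis tests
# ---------------------------------------------------------------------------

def _residual_normality_ok(matrix: np.ndarray) -> bool:
    """Shapiro-Wilk on two-way additive-model residuals at alpha = 0.05."""
    grand = matrix.mean()
    resid = matrix - matrix.mean(axis=1, keepdims=True) - matrix.mean(axis=0) + grand
    flat = resid.ravel()
    if np.ptp(flat) < 1e-12:  # perfectly additive data: nothing to test
        return True
    return sps.shapiro(flat).pvalue >= ALPHA_NORMALITY


def rm_test(matrix: np.ndarray) -> RMTestResult:
    """One-way repeated-measures test on a subjects x timepoints matrix.

    RM-ANOVA (Greenhouse-Geisser corrected when Mauchly's test rejects)
    when the additive-model residuals pass Shapiro-Wilk, else Friedman.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 3 or matrix.shape[1] < 3:
        raise ValueError("need >= 3 subjects and >= 3 timepoints")
    if np.any(~np.isfinite(matrix)):
        raise ValueError("matrix must be complete (no missing values)")
    if np.all(np.ptp(matrix, axis=1) < 1e-12):
        raise DegenerateTestError("zero within-subject variance everywhere")

    if not _residual_normality_ok(matrix):
        stat, p = sps.friedmanchisquare(*[matrix[:, j] for j in range(matrix.shape[1])])
        return RMTestResult(statistic=float(stat), p_value=float(p), method="friedman")

    n_subj, n_time = matrix.shape
    long = pd.DataFrame(
        {
            "subject": np.repeat(np.arange(n_subj), n_time),
            "time": np.tile(np.arange(n_time), n_subj),
            "value": matrix.ravel(),
        }
    )
    aov = pg.rm_anova(
        data=long, dv="value", within="time", subject="subject", correction="auto"
    )
    row = aov.iloc[0]
    corrected = False
    p = float(row["p_unc"])
    # correction="auto" emits GG columns only when Mauchly's test rejects
    if "p_GG_corr" in aov.columns and np.isfinite(row.get("p_GG_corr", np.nan)):
        sphericity_ok = bool(row["sphericity"]) if "sphericity" in aov.columns else False
        if not sphericity_ok:
            p = float(row["p_GG_corr"])
            corrected = True
    return RMTestResult(
        statistic=float(row["F"]), p_value=p, method="rm_anova",
        sphericity_corrected=corrected,
    )


def correlate(
    x: Sequence[float], y: Sequence[float], force_method: Optional[str] = None
) -> CorrelationResult:
    """Pearson correlation, or Spearman when either margin fails normality.

    ``force_method`` overrides the normality gate.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("need >= 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("correlation undefined for a constant margin")
    if force_method is not None:
        method = force_method
        if method not in ("pearson", "spearman"):
            raise ValueError(f"unknown method {method!r}")
    else:
        normal = (
            sps.shapiro(x).pvalue >= ALPHA_NORMALITY
            and sps.shapiro(y).pvalue >= ALPHA_NORMALITY
        )
        method = "pearson" if normal else "spearman"
    if method == "pearson":
        res = sps.pearsonr(x, y)
    else:
        res = sps.spearmanr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue), method=method)


def multivariate_fit(
    predictors: pd.DataFrame, response: Sequence[float]
) -> MultivariateFitResult:
    """OLS of the NBA response on a PWF predictor set.

    Reports unstandardized B with standard errors, standardized beta (from
    z-scored predictors and response), the multiple correlation R, and the
    overall F test.
    """
    if not isinstance(predictors, pd.DataFrame):
        predictors = pd.DataFrame(np.asarray(predictors, dtype=float))
        predictors.columns = [f"x{i}" for i in range(predictors.shape[1])]
    names = tuple(str(c) for c in predictors.columns)
    x = predictors.to_numpy(dtype=float)
    y = np.asarray(response, dtype=float)
    n, p = x.shape
    if y.size != n:
        raise ValueError("response length must match predictor rows")
    if n <= p + 1:
        raise ValueError("need n > p + 1 observations")

    constant = [names[j] for j in range(p) if np.ptp(x[:, j]) == 0]
    if constant:
        raise CollinearityError(constant, f"constant predictor columns: {constant}")
    design = np.column_stack([np.ones(n), x])
    rank = np.linalg.matrix_rank(design)
    if rank < p + 1:
        # pivoted QR: columns pivoted past the numerical rank are dependent
        from scipy.linalg import qr

        _, r_mat, piv = qr(design, mode="economic", pivoting=True)
        tol = np.abs(r_mat[0, 0]) * max(design.shape) * np.finfo(float).eps
        bad = [int(j) for j in piv[rank:] if j > 0]
        offenders = [names[j - 1] for j in sorted(bad)]
        raise CollinearityError(offenders)

    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    fitted = design @ coef
    resid = y - fitted
    df_resid = n - p - 1
    ssr = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        raise UndefinedCorrelationError("constant response")
    sigma2 = ssr / df_resid
    cov = sigma2 * np.linalg.inv(design.T @ design)
    se = np.sqrt(np.diag(cov))[1:]
    r_squared = 1.0 - ssr / sst
    sd_x = x.std(axis=0, ddof=1)
    sd_y = y.std(ddof=1)
    beta = coef[1:] * sd_x / sd_y
    if r_squared >= 1.0:
        f_stat, f_p = np.inf, 0.0
    else:
        f_stat = (r_squared / p) / ((1.0 - r_squared) / df_resid)
        f_p = float(sps.f.sf(f_stat, p, df_resid))
    return MultivariateFitResult(
        predictors=names,
        coef=coef[1:],
        se=se,
        beta=beta,
        intercept=float(coef[0]),
        r=float(np.sqrt(max(r_squared, 0.0))),
        f_statistic=float(f_stat),
        f_pvalue=f_p,
        df_model=p,
        df_resid=df_resid,
    )


# ---------------------------------------------------------------------------
# trends & phase classification
# ---------------------------------------------------------------------------

def compute_trend(
    days: Sequence[float],
    values: Sequence[float],
    parameter: str,
    window: tuple[int, int],
) -> TrendSummary:
    """OLS slope (with SE and two-sided t p-value) of value vs. day."""
    days = np.asarray(days, dtype=float)
    values = np.asarray(values, dtype=float)
    if np.unique(days).size < 3:
        raise ValueError("trend window must contain >= 3 timepoints")
    res = sps.linregress(days, values)
    return TrendSummary(
        parameter=parameter,
        slope=float(res.slope),
        stderr=float(res.stderr),
        p_value=float(res.pvalue),
        window=(int(window[0]), int(window[1])),
        n=int(days.size),
    )


def trend_summaries(
    data: pd.DataFrame,
    region: str,
    window: tuple[int, int],
    parameters: Sequence[str] = PHASE_PARAMS,
) -> dict[str, TrendSummary]:
    """Baseline-normalize each parameter and fit its trend inside ``window``.

    Pools post-surgery records of all rabbits for ``region`` with
    ``window[0] <= day <= window[1]``.
    """
    out: dict[str, TrendSummary] = {}
    for parameter in parameters:
        norm = normalize_to_baseline(data, parameter)
        sel = norm[
            (~norm["is_baseline"])
            & (norm["region"] == region)
            & (norm["day"] >= window[0])
            & (norm["day"] <= window[1])
        ]
        out[parameter] = compute_trend(
            sel["day"], sel["normalized"], parameter, window
        )
    return out


def _direction(trend: TrendSummary, alpha: float) -> str:
    if trend.p_value < alpha:
        return "up" if trend.slope > 0 else "down"
    return "flat"


def classify_phase(
    trends: Mapping[str, TrendSummary], alpha: float = 0.05
) -> PhaseLabel:
    """Classify the vessel state from the six-parameter trend pattern.

    VRP: BOS up; FAI, RI, AC down; BOT and FR not down.
    VEP: all six down.  NORMAL: all six flat.  Otherwise INDETERMINATE.
    """
    missing = [p for p in PHASE_PARAMS if p not in trends]
    if missing:
        raise MissingTrendError(f"missing parameter trends: {missing}")
    d = {p: _direction(trends[p], alpha) for p in PHASE_PARAMS}
    if all(v == "down" for v in d.values()):
        return PhaseLabel.VEP
    if (
        d["bos"] == "up"
        and d["fai"] == "down"
        and d["ri"] == "down"
        and d["ac"] == "down"
        and d["bot"] != "down"
        and d["fr"] != "down"
    ):
        return PhaseLabel.VRP
    if all(v == "flat" for v in d.values()):
        return PhaseLabel.NORMAL
    return PhaseLabel.INDETERMINATE


def holm_correction(p_values: Sequence[float]) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; off by default everywhere)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adjusted = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adjusted[idx] = min(running, 1.0)
    return adjusted
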