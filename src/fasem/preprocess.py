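"""Data preparation: transforms, standardization, normality and MSA screening.

The preparation sequence mirrors common practice for latent-variable analysis
of compositional biomarker panels: univariate skewness/kurtosis decide
log-transforms, variables are z-scored so low-abundance acids are not swamped
by the 20%-scale ones, multivariate normality is screened through squared
Mahalanobis distances (rejection switches the downstream fits to robust
scaling), and Kaiser's measure of sampling adequacy iteratively drops
variables unrelated to the common correlation structure.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model_core import IDENTITY, NATURAL_LOG, StandardizationConstants

logger = logging.getLogger(__name__)

__all__ = [
    "ScreeningReport",
    "sample_moments",
    "choose_transforms",
    "detection_limit_filter",
    "standardize",
    "multivariate_normality_test",
    "msa",
    "msa_filter",
]


@dataclass
class ScreeningReport:
    """What the screening stage decided, and why."""

    skewness: dict[str, float] = field(default_factory=dict)
    kurtosis: dict[str, float] = field(default_factory=dict)
    transforms: dict[str, str] = field(default_factory=dict)
    detection_limit_dropped: list[str] = field(default_factory=list)
    msa_trace: list[tuple[str, float, float]] = field(default_factory=list)
    final_overall_msa: float = float("nan")
    mvn_statistic: float = float("nan")
    mvn_pvalue: float = float("nan")
    n_missing_dropped: int = 0

    def to_dict(self) -> dict:
        return {
            "skewness": self.skewness,
            "kurtosis": self.kurtosis,
            "transforms": self.transforms,
            "detection_limit_dropped": self.detection_limit_dropped,
            "msa_trace": [list(t) for t in self.msa_trace],
            "final_overall_msa": self.final_overall_msa,
            "mvn_statistic": self.mvn_statistic,
            "mvn_pvalue": self.mvn_pvalue,
            "n_missing_dropped": self.n_missing_dropped,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScreeningReport":
        out = cls()
        out.skewness = dict(d["skewness"])
        out.kurtosis = dict(d["kurtosis"])
        out.transforms = dict(d["transforms"])
        out.detection_limit_dropped = list(d["detection_limit_dropped"])
        out.msa_trace = [tuple(t) for t in d["msa_trace"]]
        out.final_overall_msa = d["final_overall_msa"]
        out.mvn_statistic = d["mvn_statistic"]
        out.mvn_pvalue = d["mvn_pvalue"]
        out.n_missing_dropped = d.get("n_missing_dropped", 0)
        return out


def sample_moments(values) -> tuple[float, float]:
    """Skewness and the (non-excess) kurtosis index of a sample.

    Returns the bias-adjusted standardized third moment and the fourth-moment
    index whose Gaussian reference value is 3 — the scale on which the
    "|kurtosis| > 10 or skewness > 3" transform rules operate.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    if np.ptp(x) == 0:
        raise ValueError("constant vector has undefined skewness/kurtosis")
    skew = float(stats.skew(x, bias=False))
    kurt = float(stats.kurtosis(x, fisher=False, bias=False))
    return skew, kurt


def choose_transforms(
    data: pd.DataFrame,
    kurtosis_limit: float = 10.0,
    skew_limit: float = 3.0,
) -> dict[str, str]:
    """Flag a natural-log transform where a variable is grossly non-Gaussian.

    The rule: ``|kurtosis index| > kurtosis_limit`` (Gaussian reference 3) or
    ``skewness > skew_limit``.  Log-flagged variables must be strictly
    positive.
    """
    flags: dict[str, str] = {}
    for col in data.columns:
        skew, kurt = sample_moments(data[col].to_numpy())
        if abs(kurt) > kurtosis_limit or skew > skew_limit:
            if np.any(data[col].to_numpy() <= 0):
                raise ValueError(f"variable {col!r} selected for log transform has nonpositive values")
            flags[col] = NATURAL_LOG
        else:
            flags[col] = IDENTITY
    return flags


def detection_limit_filter(
    data: pd.DataFrame,
    limit: float = 0.1,
    max_fraction: float = 0.5,
) -> list[str]:
    """Variables whose share of values below the assay detection limit is too
    large to carry signal (log-transforming such a variable only normalizes
    noise).  Returns the variables to drop."""
    dropped = []
    for col in data.columns:
        frac = float(np.mean(data[col].to_numpy() < limit))
        if frac > max_fraction:
            logger.info("dropping %s: %.0f%% of values below detection limit %g", col, 100 * frac, limit)
            dropped.append(col)
    return dropped


def standardize(
    data: pd.DataFrame,
    constants: StandardizationConstants | None = None,
    transforms: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Z-score each variable, after its transform, column by column.

    With ``constants`` the stored (e.g. published) means/SDs are used — the
    scoring-algorithm convention.  Without, the pooled sample mean/SD of the
    transformed data are used (``transforms`` then says which columns to log;
    the sample constants are computed on the log scale).
    """
    out = {}
    if constants is not None:
        for col in data.columns:
            out[col] = constants.zscore(col, data[col].to_numpy())
        return pd.DataFrame(out, index=data.index)
    transforms = transforms or {}
    for col in data.columns:
        x = data[col].to_numpy(dtype=float)
        if transforms.get(col, IDENTITY) == NATURAL_LOG:
            if np.any(x <= 0):
                raise ValueError(f"nonpositive value in log-transformed variable {col!r}")
            x = np.log(x)
        sd = x.std(ddof=1)
        if sd <= 0:
            raise ValueError(f"variable {col!r} has zero variance")
        out[col] = (x - x.mean()) / sd
    return pd.DataFrame(out, index=data.index)


def multivariate_normality_test(data: pd.DataFrame | np.ndarray) -> tuple[float, float]:
    """Screen multivariate normality through squared Mahalanobis distances.

    Under multivariate normality the squared distances D2_i of the n subjects
    from the sample mean (metric: sample covariance) are, for large n,
    chi-square distributed with p degrees of freedom.  Because the D2_i are
    computed with estimated moments they are dependent (their sum is fixed),
    so empirical-CDF tests of that reference are severely conservative; the
    calibrated form of the comparison is Mardia's multivariate kurtosis —
    the second moment of the D2_i against its chi-square reference value
    p(p+2), standardized by its exact-normal mean and asymptotic variance.
    Returns (z-statistic, two-sided p-value); rejection signals that
    downstream fitting should use robust scaling.
    """
    X = np.asarray(data, dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more subjects than variables (n={n}, p={p})")
    S = np.cov(X, rowvar=False, ddof=0)  # ML covariance, Mardia's convention
    try:
        Sinv = np.linalg.inv(S)
    except np.linalg.LinAlgError:
        raise ValueError("singular covariance matrix") from None
    d = X - X.mean(axis=0)
    d2 = np.einsum("ij,jk,ik->i", d, Sinv, d)
    b2p = float(np.mean(d2**2))
    mean = p * (p + 2) * (n - 1) / (n + 1)  # exact under normality
    var = 8.0 * p * (p + 2) / n
    z = (b2p - mean) / np.sqrt(var)
    pvalue = 2.0 * float(stats.norm.sf(abs(z)))
    return float(z), pvalue


def msa(corr: np.ndarray | pd.DataFrame) -> tuple[np.ndarray, float]:
    """Kaiser's measure of sampling adequacy, per variable and overall.

    MSA = sum(simple r^2) / [sum(simple r^2) + sum(partial r^2)], where the
    partials are the anti-image (full conditional) correlations obtained from
    the inverse correlation matrix.  A diagonal correlation matrix yields the
    0/0 form; by convention 0 is reported (no shared variance) with a warning.
    """
    R = np.asarray(corr, dtype=float)
    p = R.shape[0]
    if R.shape != (p, p) or not np.allclose(R, R.T, atol=1e-8):
        raise ValueError("correlation matrix must be square symmetric")
    if not np.allclose(np.diag(R), 1.0, atol=1e-6):
        raise ValueError("correlation matrix must have a unit diagonal")
    try:
        Rinv = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        raise ValueError("singular correlation matrix") from None
    dinv = np.sqrt(np.diag(Rinv))
    partial = -Rinv / np.outer(dinv, dinv)
    off = ~np.eye(p, dtype=bool)
    r2 = np.where(off, R**2, 0.0)
    q2 = np.where(off, partial**2, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_var = r2.sum(axis=1) / (r2.sum(axis=1) + q2.sum(axis=1))
        overall = r2.sum() / (r2.sum() + q2.sum())
    if not np.isfinite(overall):
        warnings.warn("all off-diagonal correlations are zero; MSA reported as 0", stacklevel=2)
        overall = 0.0
    per_var = np.nan_to_num(per_var, nan=0.0)
    return per_var, float(overall)


def msa_filter(
    corr: pd.DataFrame,
    threshold: float = 0.60,
    report: ScreeningReport | None = None,
) -> tuple[list[str], ScreeningReport]:
    """Iteratively drop the single worst-MSA variable until all pass.

    Each round recomputes MSA on the reduced matrix and removes the variable
    with the lowest per-variable MSA if it falls below ``threshold`` (ties
    break to the earlier panel position).  The drop trace records
    (variable, its MSA, overall MSA after the drop).
    """
    if report is None:
        report = ScreeningReport()
    if not isinstance(corr, pd.DataFrame):
        raise TypeError("msa_filter needs a labeled correlation matrix (pandas DataFrame)")
    current = corr.copy()
    while True:
        names = list(current.columns)
        if len(names) < 2:
            raise ValueError("MSA filter eliminated all but one variable")
        per_var, overall = msa(current.to_numpy())
        worst = int(np.argmin(per_var))  # argmin takes the first minimum: panel-order tie-break
        if per_var[worst] >= threshold:
            report.final_overall_msa = overall
            return names, report
        dropped = names[worst]
        current = current.drop(index=dropped, columns=dropped)
        _, overall_after = msa(current.to_numpy())
        report.msa_trace.append((dropped, float(per_var[worst]), float(overall_after)))
        logger.info("MSA filter dropped %s (MSA %.3f); overall MSA now %.3f", dropped, per_var[worst], overall_after)


def listwise_complete(data: pd.DataFrame, report: ScreeningReport | None = None) -> pd.DataFrame:
    """Drop subjects with any missing value, logging the count."""
    complete = data.dropna(axis=0)
    n_dropped = len(data) - len(complete)
    if n_dropped:
        logger.info("listwise deletion removed %d of %d subjects", n_dropped, len(data))
    if report is not None:
        report.n_missing_dropped = n_dropped
    return complete
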