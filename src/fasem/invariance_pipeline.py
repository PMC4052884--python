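"""End-to-end orchestration: screen, choose dimensions, test invariance, reduce.

The pipeline runs the full analysis on a subject-by-variable table with a
gender label: univariate transform selection, pooled standardization, the
Mahalanobis multivariate-normality screen (rejection switches every model to
robust scaling), the iterative MSA variable filter, per-gender eigenvalue
retention, the M0-M5 gender-invariance ladder with the H1-H5 scaled
difference tests, construction of the knowledge-constrained SEM (M6) from
thresholded rotated loadings plus dietary and biosynthesis residual
covariances, and reduction to the parsimonious final model (M7).  Everything
is deterministic given the data and configuration.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import bundled
from .factor_engine import (
    FitResult,
    GroupMoments,
    ScaledDifference,
    baseline_fit,
    compute_fit_indices,
    eigen_retention,
    fit_model,
    quartimin_rotate,
    robust_scaling,
    scaled_chi2_difference,
    split_by_group,
)
from .model_core import (
    NATURAL_LOG,
    ModelSpec,
    PanelDefinition,
    build_invariance_ladder,
    build_sem_spec,
    reduce_spec,
)
from .preprocess import (
    ScreeningReport,
    choose_transforms,
    detection_limit_filter,
    listwise_complete,
    msa_filter,
    multivariate_normality_test,
    sample_moments,
    standardize,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "InvarianceTest", "InvarianceReport", "run_pipeline"]

#: Hypothesis -> (nested model, parent model).  H4 tests the factor
#: covariances on top of the equal-loadings model; the others nest in the
#: configural model.
DEFAULT_PAIRINGS = (
    ("H1", "M1", "M0"),
    ("H2", "M2", "M0"),
    ("H3", "M3", "M0"),
    ("H4", "M4", "M2"),
    ("H5", "M5", "M0"),
)


@dataclass
class PipelineConfig:
    """Thresholds and conventions for a pipeline run."""

    gender_column: str = "gender"
    groups: tuple[str, ...] = ("male", "female")
    msa_threshold: float = 0.60
    loading_threshold: float = 0.15
    diet_threshold: float = 0.80
    diet_cap: float = 0.95
    reduce_epsilon: float = 0.05
    kurtosis_limit: float = 10.0
    skew_limit: float = 3.0
    alpha: float = 0.05
    bonferroni: bool = False
    detection_limit: float | None = 0.1
    detection_max_fraction: float = 0.5
    n_factors: int | None = None  # None: eigenvalue-over-one retention
    robust: str = "auto"  # auto | always | never
    mvn_alpha: float = 0.05
    rmsea_convention: str = "single"
    transforms: str = "auto"  # auto (moment rules) | panel (known log flags)
    diet_corr: pd.DataFrame | None = None
    biosynthesis_pairs: tuple[tuple[str, str], ...] = bundled.BIOSYNTHESIS_PAIRS
    convergence_exclusions: tuple[tuple[str, str], ...] = ()
    zero_mean_variables: tuple[str, ...] = bundled.ZERO_MEAN_VARIABLES
    pairings: tuple[tuple[str, str, str], ...] = DEFAULT_PAIRINGS
    already_standardized: bool = False
    family_overrides: Mapping[str, str] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        for name in ("msa_threshold", "loading_threshold", "diet_threshold", "reduce_epsilon"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not (0 <= self.alpha <= 1):
            raise ValueError("alpha must be in [0, 1]")
        if self.robust not in ("auto", "always", "never"):
            raise ValueError("robust must be auto, always or never")
        if self.transforms not in ("auto", "panel"):
            raise ValueError("transforms must be 'auto' or 'panel'")


@dataclass
class InvarianceTest:
    label: str  # hypothesis (H1..H5) or reduction comparison
    nested: str
    parent: str
    delta_chi2: float
    delta_df: int
    c_d: float
    pvalue: float
    alpha: float
    rejected: bool

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class InvarianceReport:
    """Ledger of fitted models, the decision table, and the screening trail."""

    ledger: dict[str, FitResult]
    tests: list[InvarianceTest]
    screening: ScreeningReport
    n_factors: int
    robust_used: bool
    variables: list[str]

    def ledger_frame(self) -> pd.DataFrame:
        """The goodness-of-fit table, one row per model."""
        rows = []
        for label, fit in self.ledger.items():
            row = {
                "model": label,
                "chi2": fit.chi2,
                "df": fit.df,
                "scaling": fit.scaling,
            }
            if fit.indices is not None:
                row.update(fit.indices.to_dict())
            rows.append(row)
        return pd.DataFrame(rows).set_index("model")

    def to_dict(self) -> dict:
        return {
            "ledger": {k: v.to_dict() for k, v in self.ledger.items()},
            "tests": [t.to_dict() for t in self.tests],
            "screening": self.screening.to_dict(),
            "n_factors": self.n_factors,
            "robust_used": self.robust_used,
            "variables": list(self.variables),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "InvarianceReport":
        return cls(
            ledger={k: FitResult.from_dict(v) for k, v in d["ledger"].items()},
            tests=[InvarianceTest(**t) for t in d["tests"]],
            screening=ScreeningReport.from_dict(d["screening"]),
            n_factors=d["n_factors"],
            robust_used=d["robust_used"],
            variables=list(d["variables"]),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "InvarianceReport":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _panel_for(variables: Sequence[str], transforms: Mapping[str, str], overrides: Mapping[str, str]) -> PanelDefinition:
    tab = bundled.standardization_table().set_index("variable")
    family = []
    for v in variables:
        if v in overrides:
            family.append(overrides[v])
        elif v in tab.index:
            family.append(tab.loc[v, "family"])
        else:
            raise KeyError(
                f"no family label known for variable {v!r}; supply it via family_overrides"
            )
    return PanelDefinition(
        variables=tuple(variables),
        family=tuple(family),
        transform=tuple(transforms.get(v, "identity") for v in variables),
    )


def run_pipeline(data: pd.DataFrame, config: PipelineConfig | None = None) -> InvarianceReport:
    """Run the full invariance analysis on a raw (or standardized) panel table.

    ``data`` must contain the gender column plus one numeric column per fatty
    acid.  Returns the report with the M0-M7 ledger, the H1-H5 and reduction
    tests, and the screening trail.  Fitting errors are re-raised with the
    model label attached.
    """
    if config is None:
        config = PipelineConfig()
    report = ScreeningReport()
    if config.gender_column not in data.columns:
        raise KeyError(f"missing gender column {config.gender_column!r}")
    data = listwise_complete(data, report)
    gender = data[config.gender_column]
    unknown = sorted(set(gender) - set(config.groups))
    if unknown:
        raise ValueError(f"unknown gender labels {unknown}")
    values = data.drop(columns=[config.gender_column])
    p0 = values.shape[1]
    for g in config.groups:
        if (gender == g).sum() < p0 + 2:
            raise ValueError(f"group {g!r} needs at least p + 2 subjects")

    # --- univariate screening and transforms -----------------------------
    if config.already_standardized:
        transforms = {c: "identity" for c in values.columns}
        for col in values.columns:
            report.skewness[col], report.kurtosis[col] = sample_moments(values[col].to_numpy())
        z = values
    else:
        for col in values.columns:
            report.skewness[col], report.kurtosis[col] = sample_moments(values[col].to_numpy())
        if config.detection_limit is not None:
            dropped = detection_limit_filter(values, config.detection_limit, config.detection_max_fraction)
            report.detection_limit_dropped = dropped
            values = values.drop(columns=dropped)
        if config.transforms == "panel":
            # known log-scale acids from the nomenclature table; moment rules
            # only for variables outside it
            tab = bundled.standardization_table().set_index("variable")
            auto = choose_transforms(values, config.kurtosis_limit, config.skew_limit)
            transforms = {
                c: (tab.loc[c, "transform"] if c in tab.index else auto[c]) for c in values.columns
            }
        else:
            transforms = choose_transforms(values, config.kurtosis_limit, config.skew_limit)
        z = standardize(values, transforms=transforms)
    report.transforms = dict(transforms)

    # --- multivariate normality ------------------------------------------
    stat, pval = multivariate_normality_test(z)
    report.mvn_statistic, report.mvn_pvalue = stat, pval
    if config.robust == "auto":
        robust = pval < config.mvn_alpha
    else:
        robust = config.robust == "always"

    # --- MSA filter -------------------------------------------------------
    corr = z.corr()
    survivors, report = msa_filter(corr, config.msa_threshold, report)
    z = z[survivors]
    panel = _panel_for(survivors, transforms, config.family_overrides)
    p = panel.n_variables

    # --- dimension choice -------------------------------------------------
    by_group = split_by_group(z, gender, config.groups)
    if config.n_factors is not None:
        m = config.n_factors
    else:
        ms = {g: eigen_retention(np.corrcoef(np.asarray(df), rowvar=False)) for g, df in by_group.items()}
        vals = set(ms.values())
        m = max(vals)
        if len(vals) > 1:
            warnings.warn(f"groups disagree on dimensionality {ms}; taking the larger m = {m}", stacklevel=2)
    moments = GroupMoments.from_data(by_group)

    # --- ladder fits and hypothesis tests --------------------------------
    ladder_specs = build_invariance_ladder(panel, m, config.groups)
    ledger: dict[str, FitResult] = {}
    for label, spec in ladder_specs.items():
        ledger[label] = _fit_labeled(label, moments, spec, by_group, robust, config)

    alpha = config.alpha / len(config.pairings) if config.bonferroni else config.alpha
    tests: list[InvarianceTest] = []
    for hyp, nested, parent in config.pairings:
        sd = scaled_chi2_difference(ledger[nested], ledger[parent])
        tests.append(_decision(hyp, nested, parent, sd, alpha))

    # --- constrained SEM (M6) and reduction (M7) -------------------------
    m0 = ledger["M0"]
    efa_loadings = {}
    for g in config.groups:
        L = m0.estimates.loadings[g]
        if m >= 2:
            L, _phi, _f, _c = quartimin_rotate(L)
        efa_loadings[g] = L
    diet = config.diet_corr
    if diet is not None:
        keep = [v for v in diet.columns if v in set(survivors)]
        diet = diet.loc[keep, keep]
    else:
        logger.info("no dietary correlation table supplied; M6 uses biosynthesis pairs only")
    bio = [pr for pr in config.biosynthesis_pairs if pr[0] in set(survivors) and pr[1] in set(survivors)]
    zero_means = [v for v in config.zero_mean_variables if v in set(survivors)]
    m6_spec = build_sem_spec(
        efa_loadings,
        config.loading_threshold,
        diet,
        config.diet_threshold,
        bio,
        config.convergence_exclusions,
        panel=panel,
        groups=config.groups,
        zero_mean_variables=zero_means,
        diet_cap=config.diet_cap,
    )
    ledger["M6"] = _fit_labeled("M6", moments, m6_spec, by_group, robust, config)
    sd = scaled_chi2_difference(ledger["M6"], ledger["M0"])
    tests.append(_decision("M6-vs-M0", "M6", "M0", sd, alpha))

    m7_spec = reduce_spec(m6_spec, ledger["M6"].estimates, config.reduce_epsilon)
    ledger["M7"] = _fit_labeled("M7", moments, m7_spec, by_group, robust, config)
    sd = scaled_chi2_difference(ledger["M7"], ledger["M6"])
    tests.append(_decision("M7-vs-M6", "M7", "M6", sd, alpha))

    return InvarianceReport(
        ledger=ledger,
        tests=tests,
        screening=report,
        n_factors=m,
        robust_used=bool(robust),
        variables=list(survivors),
    )


def _fit_labeled(label, moments, spec, by_group, robust, config) -> FitResult:
    try:
        fit = fit_model(moments, spec, seed=config.seed)
        if robust:
            c = robust_scaling(by_group, fit)
            fit = fit.with_scaling(c)
        fit.indices = compute_fit_indices(fit, moments, config.rmsea_convention)
        return fit
    except Exception as exc:
        raise type(exc)(f"[{label}] {exc}") from exc


def _decision(label, nested, parent, sd: ScaledDifference, alpha: float) -> InvarianceTest:
    return InvarianceTest(
        label=label,
        nested=nested,
        parent=parent,
        delta_chi2=sd.delta_chi2,
        delta_df=sd.delta_df,
        c_d=sd.c_d,
        pvalue=sd.pvalue,
        alpha=alpha,
        rejected=bool(sd.pvalue < alpha or alpha >= 1.0),
    )
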