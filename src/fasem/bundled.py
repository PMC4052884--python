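"""Loaders for the bundled published parameter tables and panel metadata.

The package ships, as versioned CSV resources: the overall standardization
constants (weight% means/SDs, log-scale constants for the two log-normal
acids), the final reduced model's loadings, standardized means and factor
correlations per gender, the gender-invariant residual matrix Theta, the
structured residual-covariance pair list (dietary / desaturase-biosynthesis),
and the goodness-of-fit ledger of the eight models M0-M7.

The dietary-intake correlation matrix is a *synthetic* stand-in (see
``dietary_correlations_synthetic.csv``): the real food-frequency-questionnaire
table is not redistributable, so a matrix was constructed in which exactly the
known 14 pairs exceed r = 0.80, including the near-collinear C18:1t-C18:2t
pair at r = 0.98.
"""

from __future__ import annotations

from functools import lru_cache
from importlib import resources

import numpy as np
import pandas as pd

from .model_core import (
    EQUAL,
    FREE,
    ZERO,
    ModelSpec,
    PanelDefinition,
    ParameterSet,
    ResidualCovariance,
    StandardizationConstants,
    normalize_pair,
)

FACTORS = ("PUFA", "SAT", "TRANS")
GROUPS = ("male", "female")

#: Standardized gender mean contrasts not distinguishable from zero; their
#: nu entries are fixed at 0 in the constrained models.
ZERO_MEAN_VARIABLES = ("C22:6n3", "C20:4n6", "C16:0", "C18:1t")

#: Desaturase-pathway residual covariances: shared D5D/D6D steps and the
#: n3/n6 competition for those enzymes.
BIOSYNTHESIS_PAIRS = (
    ("C18:3n3", "C20:5n3"),
    ("C18:3n3", "C22:6n3"),
    ("C22:4n6", "C22:5n6"),
    ("C20:5n3", "C20:4n6"),
    ("C22:6n3", "C22:5n6"),
)


def _read(name: str, **kw) -> pd.DataFrame:
    with resources.files("fasem.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, **kw)


@lru_cache(maxsize=None)
def standardization_table() -> pd.DataFrame:
    """Full 22-variable screening table: family, transform, mean (SD)."""
    return _read("standardization.csv")


def bundled_panel() -> PanelDefinition:
    """The 13-variable modeled panel, in the published matrix row order."""
    lm = _read("m7_loadings_means.csv")
    order = list(lm[lm["group"] == "male"]["variable"])
    tab = standardization_table().set_index("variable").loc[order]
    return PanelDefinition(
        variables=tuple(order),
        family=tuple(tab["family"]),
        transform=tuple(tab["transform"]),
    )


def screening_panel() -> PanelDefinition:
    """All 22 measured fatty acids (for end-to-end screening exercises)."""
    tab = standardization_table()
    return PanelDefinition(
        variables=tuple(tab["variable"]),
        family=tuple(tab["family"]),
        transform=tuple(tab["transform"]),
    )


def bundled_constants(log_scale: str = "fraction", variables=None) -> StandardizationConstants:
    """Standardization constants for the modeled panel.

    Log-flagged variables carry the published log-scale mean/SD, which are on
    the weight-fraction (percent/100) scale by default.
    """
    tab = standardization_table().set_index("variable")
    if variables is None:
        variables = bundled_panel().variables
    means, sds, transforms = [], [], []
    for v in variables:
        row = tab.loc[v]
        if row["transform"] == "natural_log":
            if pd.isna(row["log_mean"]):
                raise KeyError(f"no published log-scale constants for {v!r}")
            mu, sd = float(row["log_mean"]), float(row["log_sd"])
            if log_scale == "percent":
                mu = mu + np.log(100.0)  # ln(x) = ln(x/100) + ln(100)
        else:
            mu, sd = float(row["mean"]), float(row["sd"])
        means.append(mu)
        sds.append(sd)
        transforms.append(row["transform"])
    return StandardizationConstants(
        variables=tuple(variables),
        mean=tuple(means),
        sd=tuple(sds),
        transform=tuple(transforms),
        log_scale=log_scale,
    )


@lru_cache(maxsize=None)
def bundled_m7_parameters() -> ParameterSet:
    """The published reduced-model estimates (printed 3-decimal precision).

    PUFA signs follow the printed convention (n3 acids positive).  Theta is
    gender-invariant: both groups carry the same residual matrix.
    """
    panel = bundled_panel()
    lm = _read("m7_loadings_means.csv")
    psi_tab = _read("m7_factor_correlations.csv")
    theta = _read("m7_residual_covariance.csv", index_col=0)
    theta = theta.loc[list(panel.variables), list(panel.variables)].to_numpy(dtype=float)
    loadings, factor_cov, means = {}, {}, {}
    for g in GROUPS:
        sub = lm[lm["group"] == g].set_index("variable").loc[list(panel.variables)]
        loadings[g] = sub[list(FACTORS)].to_numpy(dtype=float)
        means[g] = sub["mean"].to_numpy(dtype=float)
        psub = psi_tab[psi_tab["group"] == g].set_index("factor").loc[list(FACTORS), list(FACTORS)]
        factor_cov[g] = psub.to_numpy(dtype=float)
    return ParameterSet(
        panel=panel,
        groups=GROUPS,
        factor_names=FACTORS,
        loadings=loadings,
        factor_cov=factor_cov,
        residual_cov={g: theta for g in GROUPS},
        std_means=means,
    )


@lru_cache(maxsize=None)
def residual_pair_table() -> pd.DataFrame:
    return _read("residual_covariance_pairs.csv")


def _pattern_from_parameters(params: ParameterSet, pairs: pd.DataFrame) -> ModelSpec:
    panel = params.panel
    p, m = panel.n_variables, len(FACTORS)
    loading_pattern = {
        g: np.where(params.loadings[g] != 0, FREE, ZERO).astype(object) for g in GROUPS
    }
    mean_pattern = {
        g: np.where(params.std_means[g] != 0, FREE, ZERO).astype(object) for g in GROUPS
    }
    rcs = tuple(
        ResidualCovariance(*normalize_pair(r.var1, r.var2), r.kind, EQUAL)
        for r in pairs.itertuples()
    )
    return ModelSpec(
        panel=panel,
        groups=GROUPS,
        n_factors=m,
        factor_names=FACTORS,
        loading_pattern=loading_pattern,
        mean_pattern=mean_pattern,
        residual_variance_pattern=np.full(p, EQUAL, dtype=object),
        residual_covariance_pattern=rcs,
        factor_cov_pattern=np.full((m, m), FREE, dtype=object),
        rotation="none",
    )


def bundled_m7_spec() -> ModelSpec:
    """The reduced-model pattern: 45 loadings, 18 means, 6 factor
    covariances gender-specific; 13 variances + 15 covariances invariant."""
    pairs = residual_pair_table()
    return _pattern_from_parameters(bundled_m7_parameters(), pairs[pairs["in_m7"] == 1])


def bundled_m6_spec() -> ModelSpec:
    """The pre-reduction constrained SEM pattern (one extra loading, all 18
    structured residual covariances).

    Which single loading the reduction removed is not identified in print;
    the bundled pattern places it symmetrically with the women's solution
    (men's C18:0 x TRANS cell).  Parameter counts do not depend on the
    placement.
    """
    spec = _pattern_from_parameters(bundled_m7_parameters(), residual_pair_table())
    spec.loading_pattern["male"][spec.panel.index("C18:0"), FACTORS.index("TRANS")] = FREE
    return spec


def bundled_fit_ledger() -> pd.DataFrame:
    """Published goodness-of-fit ledger for models M0-M7 (chi2 is the
    robust/scaled statistic; `scaling` the robust correction factor)."""
    return _read("fit_ledger.csv").set_index("model")


def synthetic_dietary_correlations() -> pd.DataFrame:
    """Synthetic dietary-intake correlation matrix (see module docstring)."""
    df = _read("dietary_correlations_synthetic.csv", index_col=0)
    df.index.name = None
    return df
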