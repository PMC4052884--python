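"""Regression-method latent-variable scores from raw fatty-acid profiles.

The score for subject i is the best linear predictor of the factors given the
observed standardized profile:

    eta_i = (Z_i - nu') [ Psi Lambda' (Lambda Psi Lambda' + Theta)^-1 ]'

computed with the gender-matched parameter matrices.  With the bundled
published parameters this yields the PUFA / SATURATED / TRANS factor scores:
log-transform C18:3n3 and C20:5n3 (weight-fraction scale), z-score every
variable with the published overall means/SDs, center at the gender's
standardized mean profile, and apply the weight matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import bundled
from .model_core import ParameterSet, StandardizationConstants

__all__ = ["LatentScores", "scoring_weights", "score_subjects"]


@dataclass
class LatentScores:
    """Per-subject factor scores on the standardized factor metric."""

    scores: pd.DataFrame  # one column per factor
    gender: pd.Series
    parameter_id: str

    def __len__(self) -> int:
        return len(self.scores)


def scoring_weights(params: ParameterSet, gender: str) -> np.ndarray:
    """The m x p regression-score weight matrix W = Psi Lambda' Sigma^-1.

    Applied to centered standardized profiles; requires the implied
    covariance to be invertible.
    """
    if gender not in params.groups:
        raise KeyError(f"unknown gender {gender!r}; expected one of {params.groups}")
    L = params.loadings[gender]
    psi = params.factor_cov[gender]
    th = params.residual_cov[gender]
    sigma = L @ psi @ L.T + th
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        raise ValueError("implied covariance matrix is singular or not positive definite") from None
    # W' solves Sigma W' = Lambda Psi
    rhs = L @ psi
    wt = np.linalg.solve(sigma, rhs)
    return wt.T


def score_subjects(
    profiles: pd.DataFrame,
    gender: Sequence,
    constants: StandardizationConstants | None = None,
    params: ParameterSet | None = None,
    parameter_id: str = "bundled-M7",
    already_standardized: bool = False,
) -> LatentScores:
    """Score raw weight% profiles with gender-matched matrices.

    All panel variables must be present; log-flagged variables must be
    strictly positive.  Subjects with a gender label outside the parameter
    set's groups are refused.  Set ``already_standardized`` when the profiles
    are on the model (z-score) scale.
    """
    if params is None:
        params = bundled.bundled_m7_parameters()
    if constants is None and not already_standardized:
        constants = bundled.bundled_constants()
    panel = params.panel
    missing = [v for v in panel.variables if v not in profiles.columns]
    if missing:
        raise KeyError(f"profiles are missing panel variables: {missing}")
    gender = pd.Series(list(gender), index=profiles.index, name="gender")
    unknown = sorted(set(gender) - set(params.groups))
    if unknown:
        raise ValueError(f"unknown gender labels {unknown}; expected {params.groups}")

    if already_standardized:
        Z = profiles[list(panel.variables)].to_numpy(dtype=float)
    else:
        cols = []
        for v in panel.variables:
            cols.append(constants.zscore(v, profiles[v].to_numpy(dtype=float)))
        Z = np.column_stack(cols)

    out = np.empty((len(profiles), len(params.factor_names)))
    for g in params.groups:
        mask = (gender == g).to_numpy()
        if not mask.any():
            continue
        W = scoring_weights(params, g)
        nu = params.std_means[g]
        out[mask] = (Z[mask] - nu) @ W.T
    if not np.all(np.isfinite(out)):
        raise ValueError("non-finite factor scores; check the input profiles")
    scores = pd.DataFrame(out, columns=list(params.factor_names), index=profiles.index)
    return LatentScores(scores=scores, gender=gender, parameter_id=parameter_id)
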