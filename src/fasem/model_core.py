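"""Domain types and parameter accounting for multi-group fatty-acid factor models.

The measurement model is ``y = nu + Lambda.eta + eps`` per group (gender), with
``Sigma_g = Lambda_g Psi_g Lambda_g' + Theta`` on the standardized scale.  A
:class:`ModelSpec` records, cell by cell, which parameters are free per group,
fixed to zero, or constrained equal across groups; everything downstream
(degrees of freedom, the gender-invariance ladder, constraint construction,
model reduction) is a transformation of that symbolic pattern.

Parameter accounting follows the multi-group ESEM convention: factor variances
are fixed at one (factors are standardized, so ``Psi`` is a correlation
matrix), an obliquely rotated loading matrix carries ``m(m-1)`` rotational
identification constraints per *distinct* loading matrix, and when loadings
are constrained equal across groups while factor covariances are not, the
non-reference groups recover ``m`` free factor variances.  This reproduces the
standard degrees-of-freedom ledger for configural/metric/scalar invariance
testing exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

FREE = "free"
ZERO = "zero"
EQUAL = "equal"

IDENTITY = "identity"
NATURAL_LOG = "natural_log"

FAMILIES = ("n3", "n6", "saturated", "monounsaturated", "trans")

__all__ = [
    "FREE",
    "ZERO",
    "EQUAL",
    "IDENTITY",
    "NATURAL_LOG",
    "PanelDefinition",
    "StandardizationConstants",
    "ResidualCovariance",
    "ModelSpec",
    "ParameterSet",
    "count_free_parameters",
    "model_df",
    "build_invariance_ladder",
    "build_sem_spec",
    "reduce_spec",
    "saturated_spec",
    "align_factor_signs",
    "align_signs_to",
    "flip_factor_signs",
    "normalize_pair",
]


def normalize_pair(a: str, b: str) -> tuple[str, str]:
    """Canonical (sorted) form of an unordered variable pair."""
    if a == b:
        raise ValueError(f"residual covariance pair must involve two distinct variables, got {a!r} twice")
    return (a, b) if a <= b else (b, a)


@dataclass(frozen=True)
class PanelDefinition:
    """An ordered panel of fatty-acid variables.

    The order is load-bearing: every matrix in the package uses it, and the
    bundled 13-variable panel follows the published row order
    (C18:3n3 ... C18:2t, with the two log-scale acids first).
    """

    variables: tuple[str, ...]
    family: tuple[str, ...]
    transform: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("panel variables must be unique")
        if not (len(self.variables) == len(self.family) == len(self.transform)):
            raise ValueError("variables, family and transform must have equal length")
        for fam in self.family:
            if fam not in FAMILIES:
                raise ValueError(f"unknown family label {fam!r}")
        for tr in self.transform:
            if tr not in (IDENTITY, NATURAL_LOG):
                raise ValueError(f"unknown transform flag {tr!r}")

    @property
    def n_variables(self) -> int:
        return len(self.variables)

    def index(self, variable: str) -> int:
        try:
            return self.variables.index(variable)
        except ValueError:
            raise KeyError(f"variable {variable!r} is not in the panel") from None

    def subset(self, variables: Sequence[str]) -> "PanelDefinition":
        """Sub-panel in the original order restricted to ``variables``."""
        keep = [v for v in self.variables if v in set(variables)]
        missing = set(variables) - set(self.variables)
        if missing:
            raise KeyError(f"variables not in panel: {sorted(missing)}")
        idx = [self.index(v) for v in keep]
        return PanelDefinition(
            variables=tuple(self.variables[i] for i in idx),
            family=tuple(self.family[i] for i in idx),
            transform=tuple(self.transform[i] for i in idx),
        )


@dataclass(frozen=True)
class StandardizationConstants:
    """Per-variable location/scale used for z-scoring, on the transform scale.

    For log-flagged variables the mean/sd are on the natural-log scale.  The
    ``log_scale`` convention states what is logged: the weight *fraction*
    (percent / 100, the default, which matches the published log-scale
    constants) or the weight percent itself.
    """

    variables: tuple[str, ...]
    mean: tuple[float, ...]
    sd: tuple[float, ...]
    transform: tuple[str, ...]
    log_scale: str = "fraction"

    def __post_init__(self):
        if not (len(self.variables) == len(self.mean) == len(self.sd) == len(self.transform)):
            raise ValueError("constants fields must have equal length")
        if any(s <= 0 for s in self.sd):
            raise ValueError("standard deviations must be positive")
        if self.log_scale not in ("fraction", "percent"):
            raise ValueError("log_scale must be 'fraction' or 'percent'")

    def index(self, variable: str) -> int:
        try:
            return self.variables.index(variable)
        except ValueError:
            raise KeyError(f"no standardization constants for variable {variable!r}") from None

    def transform_values(self, variable: str, x: np.ndarray) -> np.ndarray:
        """Apply the variable's transform to raw weight-percent values."""
        i = self.index(variable)
        x = np.asarray(x, dtype=float)
        if self.transform[i] == NATURAL_LOG:
            if np.any(x <= 0):
                raise ValueError(f"nonpositive value for log-transformed variable {variable!r}")
            return np.log(x / 100.0) if self.log_scale == "fraction" else np.log(x)
        return x

    def zscore(self, variable: str, x: np.ndarray) -> np.ndarray:
        i = self.index(variable)
        return (self.transform_values(variable, x) - self.mean[i]) / self.sd[i]

    def inverse(self, variable: str, z: np.ndarray) -> np.ndarray:
        """Map standardized values back to raw weight percent."""
        i = self.index(variable)
        t = self.mean[i] + self.sd[i] * np.asarray(z, dtype=float)
        if self.transform[i] == NATURAL_LOG:
            frac = np.exp(t)
            return frac * 100.0 if self.log_scale == "fraction" else frac
        return t


class ResidualCovariance(NamedTuple):
    """A structured off-diagonal entry of the residual matrix Theta."""

    var1: str
    var2: str
    kind: str  # "dietary" | "biosynthesis"
    code: str = EQUAL  # EQUAL (shared across groups) | FREE (per group)

    @property
    def pair(self) -> tuple[str, str]:
        return normalize_pair(self.var1, self.var2)


_PATTERN_CODES = {FREE, ZERO, EQUAL}


@dataclass
class ModelSpec:
    """Symbolic pattern of free / zero / cross-group-equal parameters.

    ``loading_pattern`` and ``mean_pattern`` map each group label to a grid of
    codes; a cell coded ``equal`` must be coded ``equal`` in every group (it is
    a single shared parameter).  Factor variances are fixed at one except where
    ``factor_variance_pattern`` frees them (metric-invariant rotated models
    free them in non-reference groups).
    """

    panel: PanelDefinition
    groups: tuple[str, ...]
    n_factors: int
    factor_names: tuple[str, ...]
    loading_pattern: dict[str, np.ndarray]
    mean_pattern: dict[str, np.ndarray]
    residual_variance_pattern: np.ndarray
    residual_covariance_pattern: tuple[ResidualCovariance, ...]
    factor_cov_pattern: np.ndarray
    factor_variance_pattern: dict[str, str] = field(default_factory=dict)
    rotation: str = "none"

    def __post_init__(self):
        p, m = self.panel.n_variables, self.n_factors
        if m < 0:
            raise ValueError("n_factors must be nonnegative")
        if len(self.factor_names) != m:
            raise ValueError("factor_names must have length n_factors")
        if self.rotation not in ("none", "quartimin"):
            raise ValueError(f"unknown rotation {self.rotation!r}")
        if not self.factor_variance_pattern:
            self.factor_variance_pattern = {g: "fixed" for g in self.groups}
        for g in self.groups:
            L = np.asarray(self.loading_pattern[g], dtype=object)
            if L.shape != (p, m):
                raise ValueError(f"loading pattern for group {g!r} must be {p}x{m}")
            mu = np.asarray(self.mean_pattern[g], dtype=object)
            if mu.shape != (p,):
                raise ValueError(f"mean pattern for group {g!r} must have length {p}")
            for grid in (L.ravel(), mu):
                bad = set(grid) - _PATTERN_CODES
                if bad:
                    raise ValueError(f"unknown pattern codes {bad} in group {g!r}")
            self.loading_pattern[g] = L
            self.mean_pattern[g] = mu
        rv = np.asarray(self.residual_variance_pattern, dtype=object)
        if rv.shape != (p,) or set(rv) - {FREE, EQUAL}:
            raise ValueError("residual_variance_pattern must be length-p with codes free/equal")
        self.residual_variance_pattern = rv
        fc = np.asarray(self.factor_cov_pattern, dtype=object)
        if m and (fc.shape != (m, m) or set(fc[~np.eye(m, dtype=bool)]) - {FREE, EQUAL, ZERO}):
            raise ValueError("factor_cov_pattern must be m x m with off-diagonal codes free/equal/zero")
        self.factor_cov_pattern = fc
        # equal cells must agree across groups
        for g in self.groups[1:]:
            ref_eq = self.loading_pattern[self.groups[0]] == EQUAL
            if not np.array_equal(self.loading_pattern[g] == EQUAL, ref_eq):
                raise ValueError("loading cells coded 'equal' must match across groups")
            ref_eq = self.mean_pattern[self.groups[0]] == EQUAL
            if not np.array_equal(self.mean_pattern[g] == EQUAL, ref_eq):
                raise ValueError("mean cells coded 'equal' must match across groups")
        if self.rotation == "quartimin":
            for g in self.groups:
                if np.any(self.loading_pattern[g] == ZERO):
                    raise ValueError("a quartimin (rotated) spec must have a fully free loading pattern")
        pairs = [rc.pair for rc in self.residual_covariance_pattern]
        if len(set(pairs)) != len(pairs):
            raise ValueError("residual covariance pairs must be distinct")
        for rc in self.residual_covariance_pattern:
            self.panel.index(rc.var1)
            self.panel.index(rc.var2)
            if rc.kind not in ("dietary", "biosynthesis"):
                raise ValueError(f"unknown residual covariance kind {rc.kind!r}")

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def to_dict(self) -> dict:
        return {
            "panel": {
                "variables": list(self.panel.variables),
                "family": list(self.panel.family),
                "transform": list(self.panel.transform),
            },
            "groups": list(self.groups),
            "n_factors": self.n_factors,
            "factor_names": list(self.factor_names),
            "loading_pattern": {g: self.loading_pattern[g].tolist() for g in self.groups},
            "mean_pattern": {g: self.mean_pattern[g].tolist() for g in self.groups},
            "residual_variance_pattern": self.residual_variance_pattern.tolist(),
            "residual_covariance_pattern": [list(rc) for rc in self.residual_covariance_pattern],
            "factor_cov_pattern": self.factor_cov_pattern.tolist(),
            "factor_variance_pattern": dict(self.factor_variance_pattern),
            "rotation": self.rotation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        panel = PanelDefinition(
            variables=tuple(d["panel"]["variables"]),
            family=tuple(d["panel"]["family"]),
            transform=tuple(d["panel"]["transform"]),
        )
        groups = tuple(d["groups"])
        return cls(
            panel=panel,
            groups=groups,
            n_factors=d["n_factors"],
            factor_names=tuple(d["factor_names"]),
            loading_pattern={g: np.array(d["loading_pattern"][g], dtype=object) for g in groups},
            mean_pattern={g: np.array(d["mean_pattern"][g], dtype=object) for g in groups},
            residual_variance_pattern=np.array(d["residual_variance_pattern"], dtype=object),
            residual_covariance_pattern=tuple(ResidualCovariance(*rc) for rc in d["residual_covariance_pattern"]),
            factor_cov_pattern=np.array(d["factor_cov_pattern"], dtype=object).reshape(d["n_factors"], d["n_factors"]),
            factor_variance_pattern=dict(d["factor_variance_pattern"]),
            rotation=d["rotation"],
        )

    def shares_loading_matrix(self) -> bool:
        """True when all estimated loading cells are cross-group equal."""
        ref = self.loading_pattern[self.groups[0]]
        return bool(np.all((ref == EQUAL) | (ref == ZERO))) and any(
            np.any(self.loading_pattern[g] == EQUAL) for g in self.groups
        )

    def copy(self) -> "ModelSpec":
        return replace(
            self,
            loading_pattern={g: a.copy() for g, a in self.loading_pattern.items()},
            mean_pattern={g: a.copy() for g, a in self.mean_pattern.items()},
            residual_variance_pattern=self.residual_variance_pattern.copy(),
            residual_covariance_pattern=tuple(self.residual_covariance_pattern),
            factor_cov_pattern=self.factor_cov_pattern.copy(),
            factor_variance_pattern=dict(self.factor_variance_pattern),
        )


@dataclass
class ParameterSet:
    """Numeric parameter values conforming to a spec's shapes.

    ``factor_cov`` holds per-group factor correlation matrices Psi (unit
    diagonal unless factor variances were freed); ``residual_cov`` is the full
    symmetric residual matrix Theta per group (identical objects across groups
    when Theta is constrained gender-invariant); ``std_means`` are the
    standardized mean profiles nu.
    """

    panel: PanelDefinition
    groups: tuple[str, ...]
    factor_names: tuple[str, ...]
    loadings: dict[str, np.ndarray]
    factor_cov: dict[str, np.ndarray]
    residual_cov: dict[str, np.ndarray]
    std_means: dict[str, np.ndarray]

    def __post_init__(self):
        p, m = self.panel.n_variables, len(self.factor_names)
        for g in self.groups:
            self.loadings[g] = np.asarray(self.loadings[g], dtype=float).reshape(p, m)
            self.factor_cov[g] = np.asarray(self.factor_cov[g], dtype=float).reshape(m, m)
            self.residual_cov[g] = np.asarray(self.residual_cov[g], dtype=float).reshape(p, p)
            self.std_means[g] = np.asarray(self.std_means[g], dtype=float).reshape(p)

    def validate(self, atol: float = 1e-8) -> None:
        for g in self.groups:
            psi = self.factor_cov[g]
            if not np.allclose(psi, psi.T, atol=atol):
                raise ValueError(f"factor covariance for {g!r} is not symmetric")
            if psi.size and np.linalg.eigvalsh(psi).min() <= 0:
                raise ValueError(f"factor covariance for {g!r} is not positive definite")
            th = self.residual_cov[g]
            if not np.allclose(th, th.T, atol=atol):
                raise ValueError(f"residual matrix for {g!r} is not symmetric")

    def to_dict(self) -> dict:
        return {
            "panel": {
                "variables": list(self.panel.variables),
                "family": list(self.panel.family),
                "transform": list(self.panel.transform),
            },
            "groups": list(self.groups),
            "factor_names": list(self.factor_names),
            "loadings": {g: self.loadings[g].tolist() for g in self.groups},
            "factor_cov": {g: self.factor_cov[g].tolist() for g in self.groups},
            "residual_cov": {g: self.residual_cov[g].tolist() for g in self.groups},
            "std_means": {g: self.std_means[g].tolist() for g in self.groups},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        panel = PanelDefinition(
            variables=tuple(d["panel"]["variables"]),
            family=tuple(d["panel"]["family"]),
            transform=tuple(d["panel"]["transform"]),
        )
        groups = tuple(d["groups"])
        return cls(
            panel=panel,
            groups=groups,
            factor_names=tuple(d["factor_names"]),
            loadings={g: np.array(d["loadings"][g], dtype=float) for g in groups},
            factor_cov={g: np.array(d["factor_cov"][g], dtype=float) for g in groups},
            residual_cov={g: np.array(d["residual_cov"][g], dtype=float) for g in groups},
            std_means={g: np.array(d["std_means"][g], dtype=float) for g in groups},
        )

    def conforms_to(self, spec: ModelSpec, atol: float = 1e-10) -> bool:
        """Zero cells of the spec must be exactly (numerically) zero here."""
        for g in spec.groups:
            if np.any(np.abs(self.loadings[g][spec.loading_pattern[g] == ZERO]) > atol):
                return False
            if np.any(np.abs(self.std_means[g][spec.mean_pattern[g] == ZERO]) > atol):
                return False
            allowed = np.eye(spec.panel.n_variables, dtype=bool)
            for rc in spec.residual_covariance_pattern:
                i, j = spec.panel.index(rc.var1), spec.panel.index(rc.var2)
                allowed[i, j] = allowed[j, i] = True
            if np.any(np.abs(self.residual_cov[g][~allowed]) > atol):
                return False
        return True


# ---------------------------------------------------------------------------
# parameter / degrees-of-freedom accounting
# ---------------------------------------------------------------------------

def count_free_parameters(spec: ModelSpec) -> int:
    """Count distinct estimated parameters of a multi-group spec.

    Cross-group-equal cells count once, free cells once per group.  A rotated
    (quartimin) loading matrix loses ``m(m-1)`` rotational-identification
    constraints per distinct loading matrix; freed factor variances (metric
    invariance with group-specific factor scale) count per group.
    """
    G, m = spec.n_groups, spec.n_factors
    count = 0
    ref = spec.groups[0]
    # loadings and means: cell-wise over the per-group grids
    for pattern in (spec.loading_pattern, spec.mean_pattern):
        grid_ref = pattern[ref]
        eq = grid_ref == EQUAL
        count += int(eq.sum())
        for g in spec.groups:
            count += int((pattern[g] == FREE).sum())
    if spec.rotation == "quartimin" and m >= 2:
        n_distinct = 1 if spec.shares_loading_matrix() else G
        count -= n_distinct * m * (m - 1)
    # factor covariance off-diagonals
    if m:
        iu = np.triu_indices(m, 1)
        off = spec.factor_cov_pattern[iu]
        count += int((off == EQUAL).sum()) + G * int((off == FREE).sum())
    # factor variances freed per group (one per factor)
    count += m * sum(1 for g in spec.groups if spec.factor_variance_pattern.get(g) == FREE)
    # residual variances / covariances
    rv = spec.residual_variance_pattern
    count += int((rv == EQUAL).sum()) + G * int((rv == FREE).sum())
    for rc in spec.residual_covariance_pattern:
        count += 1 if rc.code == EQUAL else G
    return count


def model_df(spec: ModelSpec, n_variables: int | None = None, n_groups: int | None = None) -> int:
    """Degrees of freedom: total sample moments minus free parameters.

    Each group contributes ``p`` means plus ``p(p+1)/2`` variances/covariances
    (13 variables, two groups: 2*(13 + 91) = 208 moments).
    """
    p = spec.panel.n_variables if n_variables is None else n_variables
    G = spec.n_groups if n_groups is None else n_groups
    df = G * (p + p * (p + 1) // 2) - count_free_parameters(spec)
    if df < 0:
        raise ValueError(f"over-parameterized spec: df = {df} < 0")
    return df


# ---------------------------------------------------------------------------
# spec builders
# ---------------------------------------------------------------------------

def _full(p_or_shape, code):
    return np.full(p_or_shape, code, dtype=object)


def _base_rotated_spec(panel: PanelDefinition, n_factors: int, groups: tuple[str, ...]) -> ModelSpec:
    p, m = panel.n_variables, n_factors
    return ModelSpec(
        panel=panel,
        groups=groups,
        n_factors=m,
        factor_names=tuple(f"F{k + 1}" for k in range(m)),
        loading_pattern={g: _full((p, m), FREE) for g in groups},
        mean_pattern={g: _full(p, FREE) for g in groups},
        residual_variance_pattern=_full(p, FREE),
        residual_covariance_pattern=(),
        factor_cov_pattern=_full((m, m), FREE),
        factor_variance_pattern={g: "fixed" for g in groups},
        rotation="quartimin",
    )


def build_invariance_ladder(
    panel: PanelDefinition,
    n_factors: int,
    groups: tuple[str, ...] = ("male", "female"),
) -> dict[str, ModelSpec]:
    """The six-rung gender-invariance ladder M0..M5.

    M0 configural (all free); M1 equal means (H1); M2 equal loadings (H2);
    M3 equal residual variances (H3); M4 equal loadings and factor
    covariances (H4, built on M2); M5 equal loadings, factor covariances and
    residual variances (H5) — i.e. equal implied covariance matrices.
    """
    if n_factors < 1:
        raise ValueError("n_factors must be >= 1")

    def equal_loadings(spec: ModelSpec) -> None:
        for g in spec.groups:
            spec.loading_pattern[g][:] = EQUAL
        # metric invariance with rotation: non-reference groups keep their own
        # factor scale unless Psi is also constrained
        spec.factor_variance_pattern = {g: ("fixed" if g == spec.groups[0] else FREE) for g in spec.groups}

    m0 = _base_rotated_spec(panel, n_factors, groups)

    m1 = m0.copy()
    for g in groups:
        m1.mean_pattern[g][:] = EQUAL

    m2 = m0.copy()
    equal_loadings(m2)

    m3 = m0.copy()
    m3.residual_variance_pattern[:] = EQUAL

    m4 = m2.copy()
    m4.factor_cov_pattern[:] = EQUAL
    m4.factor_variance_pattern = {g: "fixed" for g in groups}

    m5 = m4.copy()
    m5.residual_variance_pattern[:] = EQUAL

    return {"M0": m0, "M1": m1, "M2": m2, "M3": m3, "M4": m4, "M5": m5}


def build_sem_spec(
    efa_loadings: Mapping[str, np.ndarray],
    loading_threshold: float,
    diet_corr=None,
    diet_threshold: float = 0.80,
    biosynthesis_pairs: Iterable[tuple[str, str]] = (),
    convergence_exclusions: Iterable[tuple[str, str]] = (),
    *,
    panel: PanelDefinition,
    groups: tuple[str, ...] = ("male", "female"),
    factor_names: tuple[str, ...] | None = None,
    zero_mean_variables: Iterable[str] = (),
    diet_cap: float = 0.95,
) -> ModelSpec:
    """Build the knowledge-constrained SEM spec (M6 style).

    Loading cells are fixed to zero where the reference (rotated) solution has
    ``|loading| < loading_threshold`` in that group; residual covariances are
    added for every dietary pair with ``|r| > diet_threshold`` (pairs above
    ``diet_cap`` are auto-excluded as collinearity hazards, as are any listed
    ``convergence_exclusions``) plus the stated biosynthesis pairs; residual
    variances and covariances are gender-invariant, loadings/means/factor
    covariances gender-specific.  ``diet_corr`` is a labeled square pandas
    DataFrame of dietary-intake correlations, or None.
    """
    if not (0 < loading_threshold < 1):
        raise ValueError("loading_threshold must be in (0, 1)")
    if not (0 < diet_threshold < 1):
        raise ValueError("diet_threshold must be in (0, 1)")
    p = panel.n_variables
    first = next(iter(efa_loadings.values()))
    m = np.asarray(first).shape[1]
    if factor_names is None:
        factor_names = tuple(f"F{k + 1}" for k in range(m))

    loading_pattern = {}
    for g in groups:
        L = np.asarray(efa_loadings[g], dtype=float)
        if L.shape != (p, m):
            raise ValueError(f"EFA loadings for group {g!r} must be {p}x{m}")
        loading_pattern[g] = np.where(np.abs(L) < loading_threshold, ZERO, FREE).astype(object)

    excl = {normalize_pair(*pr) for pr in convergence_exclusions}
    pairs: list[ResidualCovariance] = []
    seen: set[tuple[str, str]] = set()
    for a, b in biosynthesis_pairs:
        key = normalize_pair(a, b)
        panel.index(key[0]), panel.index(key[1])
        if key not in seen:
            pairs.append(ResidualCovariance(key[0], key[1], "biosynthesis", EQUAL))
            seen.add(key)
    if diet_corr is not None:
        cols = list(diet_corr.columns)
        for i, a in enumerate(cols):
            for b in cols[i + 1:]:
                r = float(diet_corr.loc[a, b])
                if abs(r) <= diet_threshold:
                    continue
                key = normalize_pair(a, b)
                panel.index(key[0]), panel.index(key[1])
                if abs(r) > diet_cap:
                    warnings.warn(
                        f"dietary pair {key} auto-excluded: |r| = {abs(r):.2f} exceeds the {diet_cap} cap",
                        stacklevel=2,
                    )
                    continue
                if key in excl or key in seen:
                    continue
                pairs.append(ResidualCovariance(key[0], key[1], "dietary", EQUAL))
                seen.add(key)

    zero_means = set(zero_mean_variables)
    mean_pattern = {}
    for g in groups:
        mu = _full(p, FREE)
        for v in zero_means:
            mu[panel.index(v)] = ZERO
        mean_pattern[g] = mu

    return ModelSpec(
        panel=panel,
        groups=groups,
        n_factors=m,
        factor_names=factor_names,
        loading_pattern=loading_pattern,
        mean_pattern=mean_pattern,
        residual_variance_pattern=_full(p, EQUAL),
        residual_covariance_pattern=tuple(pairs),
        factor_cov_pattern=_full((m, m), FREE),
        factor_variance_pattern={g: "fixed" for g in groups},
        rotation="none",
    )


def reduce_spec(spec: ModelSpec, fitted: ParameterSet, epsilon: float) -> ModelSpec:
    """Zero out free loadings and residual covariances smaller than ``epsilon``.

    Residual variances and factor covariances are never removed.  Applying the
    reduction twice with the same epsilon is a no-op the second time.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    out = spec.copy()
    for g in spec.groups:
        L = fitted.loadings[g]
        pat = out.loading_pattern[g]
        pat[(pat == FREE) & (np.abs(L) < epsilon)] = ZERO
    # equal loading cells: judged on the reference group's value
    ref = spec.groups[0]
    pat_ref = out.loading_pattern[ref]
    eq_small = (pat_ref == EQUAL) & (np.abs(fitted.loadings[ref]) < epsilon)
    if np.any(eq_small):
        for g in spec.groups:
            out.loading_pattern[g][eq_small] = ZERO
    kept = []
    for rc in spec.residual_covariance_pattern:
        i, j = spec.panel.index(rc.var1), spec.panel.index(rc.var2)
        vals = [abs(fitted.residual_cov[g][i, j]) for g in spec.groups]
        value = vals[0] if rc.code == EQUAL else max(vals)
        if value >= epsilon:
            kept.append(rc)
    out.residual_covariance_pattern = tuple(kept)
    return out


def saturated_spec(panel: PanelDefinition, groups: tuple[str, ...] = ("all",)) -> ModelSpec:
    """A zero-factor spec with all means, variances and covariances free."""
    p = panel.n_variables
    pairs = tuple(
        ResidualCovariance(*normalize_pair(panel.variables[i], panel.variables[j]), "dietary", FREE)
        for i in range(p)
        for j in range(i + 1, p)
    )
    return ModelSpec(
        panel=panel,
        groups=groups,
        n_factors=0,
        factor_names=(),
        loading_pattern={g: _full((p, 0), FREE) for g in groups},
        mean_pattern={g: _full(p, FREE) for g in groups},
        residual_variance_pattern=_full(p, FREE),
        residual_covariance_pattern=pairs,
        factor_cov_pattern=_full((0, 0), FREE),
        factor_variance_pattern={g: "fixed" for g in groups},
        rotation="none",
    )


# ---------------------------------------------------------------------------
# sign conventions
# ---------------------------------------------------------------------------

def align_factor_signs(loadings: np.ndarray, factor_cov: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flip factor columns so the largest-magnitude loading of each is positive.

    Loading signs are arbitrary up to a joint column/psi flip; this fixes a
    deterministic convention.  Returns (loadings, factor_cov, signs).
    """
    L = np.asarray(loadings, dtype=float).copy()
    psi = np.asarray(factor_cov, dtype=float).copy()
    m = L.shape[1]
    signs = np.ones(m)
    for k in range(m):
        j = int(np.argmax(np.abs(L[:, k])))
        if L[j, k] < 0:
            signs[k] = -1.0
    L *= signs
    psi = psi * np.outer(signs, signs)
    return L, psi, signs


def align_signs_to(params: ParameterSet, reference: ParameterSet) -> ParameterSet:
    """Resolve the factor-sign indeterminacy against a reference solution.

    Per group, each factor column is flipped when its inner product with the
    reference column is negative (Psi flipped jointly).  Useful for comparing
    fitted solutions with published or generating values, whose sign
    convention is arbitrary.
    """
    out = ParameterSet(
        panel=params.panel,
        groups=params.groups,
        factor_names=params.factor_names,
        loadings={g: params.loadings[g].copy() for g in params.groups},
        factor_cov={g: params.factor_cov[g].copy() for g in params.groups},
        residual_cov={g: params.residual_cov[g].copy() for g in params.groups},
        std_means={g: params.std_means[g].copy() for g in params.groups},
    )
    for g in params.groups:
        dots = np.einsum("jk,jk->k", params.loadings[g], reference.loadings[g])
        signs = np.where(dots < 0, -1.0, 1.0)
        out.loadings[g] *= signs
        out.factor_cov[g] = out.factor_cov[g] * np.outer(signs, signs)
    return out


def flip_factor_signs(params: ParameterSet, factors: Sequence[str]) -> ParameterSet:
    """Reverse the sign of the named factors in every group (published-table
    convention: e.g. the PUFA column flipped so n3 acids load positively)."""
    signs = np.array([-1.0 if f in set(factors) else 1.0 for f in params.factor_names])
    return ParameterSet(
        panel=params.panel,
        groups=params.groups,
        factor_names=params.factor_names,
        loadings={g: params.loadings[g] * signs for g in params.groups},
        factor_cov={g: params.factor_cov[g] * np.outer(signs, signs) for g in params.groups},
        residual_cov={g: params.residual_cov[g].copy() for g in params.groups},
        std_means={g: params.std_means[g].copy() for g in params.groups},
    )
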