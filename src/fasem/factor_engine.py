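"""Factor extraction, multi-group constrained ML fitting, and fit assessment.

The engine fits the multi-group measurement model by minimizing the ML
discrepancy

    F = sum_g (n_g/N) [ log|Sigma_g| + tr(S_g Sigma_g^-1) - log|S_g| - p
                        + (m_g - mu_g)' Sigma_g^-1 (m_g - mu_g) ]

with Sigma_g = Lambda_g Psi_g Lambda_g' + Theta_g, under arbitrary
free / zero / cross-group-equal constraints from a :class:`~fasem.model_core.ModelSpec`.
The test statistic convention is chi2 = (N - G) * F_min.  Non-normality is
handled by a Satorra-Bentler-type mean-adjusting correction computed from the
empirical fourth-order moment matrix; nested models are compared with the
scaled chi-square difference test, combining the two models' scaling factors
through the df-weighted factor c_d.

Rotation-based specs (the invariance ladder) are fitted with their loading
matrices unconstrained beyond the symbolic pattern: the ML discrepancy is
rotation-invariant, so chi-square and degrees of freedom are exact, and the
direct-quartimin rotation is applied to the fitted solution for reporting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .model_core import (
    EQUAL,
    FREE,
    ZERO,
    ModelSpec,
    ParameterSet,
    align_factor_signs,
    count_free_parameters,
    model_df,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ConvergenceError",
    "UnderIdentifiedError",
    "InvalidComparisonError",
    "GroupMoments",
    "EfaResult",
    "FitIndices",
    "FitResult",
    "eigen_retention",
    "efa_ml",
    "quartimin_rotate",
    "implied_moments",
    "fit_model",
    "robust_scaling",
    "baseline_fit",
    "fit_indices",
    "compute_fit_indices",
    "scaled_chi2_difference",
    "communalities",
    "first_dimension_share",
]


class ConvergenceError(RuntimeError):
    """Optimization failed to converge after multi-start."""


class UnderIdentifiedError(RuntimeError):
    """The model's moment Jacobian is rank-deficient at the solution."""


class InvalidComparisonError(ValueError):
    """A scaled difference test with a nonpositive c_d or equal df."""


# ---------------------------------------------------------------------------
# sample moments container
# ---------------------------------------------------------------------------

@dataclass
class GroupMoments:
    """Per-group sample mean vector, covariance matrix and size.

    Covariances use the ML (divide-by-n) convention, matching the
    (N - G) * F chi-square convention used throughout.
    """

    groups: tuple[str, ...]
    means: dict[str, np.ndarray]
    covs: dict[str, np.ndarray]
    ns: dict[str, int]

    @property
    def n_total(self) -> int:
        return sum(self.ns.values())

    @property
    def n_variables(self) -> int:
        return len(next(iter(self.means.values())))

    def weight(self, g: str) -> float:
        return self.ns[g] / self.n_total

    @classmethod
    def from_data(cls, data_by_group: Mapping[str, pd.DataFrame | np.ndarray]) -> "GroupMoments":
        groups = tuple(data_by_group)
        means, covs, ns = {}, {}, {}
        for g, df in data_by_group.items():
            X = np.asarray(df, dtype=float)
            ns[g] = X.shape[0]
            means[g] = X.mean(axis=0)
            covs[g] = np.cov(X, rowvar=False, ddof=0)
        return cls(groups, means, covs, ns)

    @classmethod
    def from_parameters(cls, params: ParameterSet, ns: Mapping[str, int]) -> "GroupMoments":
        """Population moments implied by a parameter set (self-consistency runs)."""
        mom = implied_moments(params)
        return cls(
            groups=params.groups,
            means={g: mom[g][1].copy() for g in params.groups},
            covs={g: mom[g][0].copy() for g in params.groups},
            ns=dict(ns),
        )


def split_by_group(data: pd.DataFrame, gender: Sequence, groups: tuple[str, ...]) -> dict[str, pd.DataFrame]:
    gender = np.asarray(gender)
    out = {}
    for g in groups:
        mask = gender == g
        if mask.sum() == 0:
            raise ValueError(f"no subjects in group {g!r}")
        out[g] = data.loc[mask] if isinstance(data, pd.DataFrame) else data[mask]
    return out


# ---------------------------------------------------------------------------
# exploratory factor analysis
# ---------------------------------------------------------------------------

def eigen_retention(corr: np.ndarray | pd.DataFrame, tol: float = 1e-8) -> int:
    """Number of eigenvalues of the correlation matrix strictly above one."""
    R = np.asarray(corr, dtype=float)
    return int(np.sum(np.linalg.eigvalsh(R) > 1.0 + tol))


@dataclass
class EfaResult:
    loadings: np.ndarray  # p x m, unrotated
    uniquenesses: np.ndarray
    criterion: float
    converged: bool
    heywood: bool


def _efa_objective(u: np.ndarray, R: np.ndarray, m: int) -> float:
    sc = 1.0 / np.sqrt(u)
    lam = np.linalg.eigvalsh(sc[:, None] * R * sc[None, :])[::-1]
    tail = lam[m:]
    return float(np.sum(tail - np.log(tail) - 1.0))


def _efa_loadings(u: np.ndarray, R: np.ndarray, m: int) -> np.ndarray:
    sc = 1.0 / np.sqrt(u)
    vals, vecs = np.linalg.eigh(sc[:, None] * R * sc[None, :])
    vals, vecs = vals[::-1], vecs[:, ::-1]
    L = vecs[:, :m] * np.sqrt(np.maximum(vals[:m] - 1.0, 0.0))
    return np.sqrt(u)[:, None] * L


def _efa_gradient(u: np.ndarray, R: np.ndarray, m: int) -> np.ndarray:
    L = _efa_loadings(u, R, m)
    g = L @ L.T + np.diag(u) - R
    return np.diag(g) / u**2


def efa_ml(
    corr: np.ndarray | pd.DataFrame,
    n_factors: int,
    lower: float = 0.005,
) -> EfaResult:
    """Maximum-likelihood exploratory factor analysis of a correlation matrix.

    Profiles the Wishart likelihood over the uniquenesses (the classical
    Lawley eigenvalue reduction); a uniqueness pinned to the lower bound is a
    Heywood case — flagged, never silently truncated away.
    """
    R = np.asarray(corr, dtype=float)
    p = R.shape[0]
    if not (0 < n_factors < p):
        raise ValueError("need 0 < n_factors < p")
    if np.linalg.eigvalsh(R).min() <= 0:
        raise ValueError("correlation matrix must be positive definite")
    # squared-multiple-correlation start
    smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    u0 = np.clip(1.0 - smc, lower * 2, 1.0)
    res = optimize.minimize(
        _efa_objective,
        u0,
        args=(R, n_factors),
        jac=_efa_gradient,
        method="L-BFGS-B",
        bounds=[(lower, 1.0)] * p,
        options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-8},
    )
    u = res.x
    heywood = bool(np.any(u <= lower * 1.001))
    if heywood:
        warnings.warn("Heywood case: at least one uniqueness at its lower bound", stacklevel=2)
    return EfaResult(
        loadings=_efa_loadings(u, R, n_factors),
        uniquenesses=u,
        criterion=float(res.fun),
        converged=bool(res.success),
        heywood=heywood,
    )


# ---------------------------------------------------------------------------
# direct quartimin rotation (gradient-projection algorithm, oblique)
# ---------------------------------------------------------------------------

def _quartimin_criterion(L: np.ndarray, N: np.ndarray) -> tuple[float, np.ndarray]:
    L2 = L * L
    X = L2 @ N
    return float(np.sum(L2 * X) / 4.0), L * X


def quartimin_rotate(
    loadings: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-7,
    n_starts: int = 4,
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    """Direct-quartimin oblique rotation via gradient projection.

    Minimizes the quartimin criterion over oblique transformations
    ``L = A (T^-1)'`` with unit-length columns of T; the common covariance
    ``L Phi L'`` (Phi = T'T) equals ``A A'`` exactly for every iterate.
    Several deterministic starts guard against local minima; factor signs are
    aligned so each factor's largest loading is positive.  Returns
    (rotated loadings, factor correlation matrix, criterion, converged).
    """
    A = np.asarray(loadings, dtype=float)
    m = A.shape[1]
    if m < 2:
        raise ValueError("rotation needs at least 2 factors")
    rng = np.random.default_rng(20140415)  # fixed: rotation is deterministic
    starts = [np.eye(m)]
    for _ in range(n_starts - 1):
        Q, _r = np.linalg.qr(rng.standard_normal((m, m)))
        starts.append(Q)
    best = None
    for T0 in starts:
        out = _gpa_oblique(A, T0, max_iter, tol)
        if best is None or out[2] < best[2] - 1e-12:
            best = out
    L, Phi, f, converged = best
    L, Phi, _signs = align_factor_signs(L, Phi)
    return L, Phi, f, converged


def _gpa_oblique(A, T0, max_iter, tol):
    m = A.shape[1]
    N = np.ones((m, m)) - np.eye(m)
    T = T0.copy()
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _quartimin_criterion(L, N)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    converged = False
    for _ in range(max_iter):
        Gp = G - T * np.sum(T * G, axis=0, keepdims=True)
        s = np.sqrt(np.sum(Gp * Gp))
        if s < tol:
            converged = True
            break
        al *= 2.0
        for _ls in range(16):
            X = T - al * Gp
            X /= np.sqrt(np.sum(X * X, axis=0, keepdims=True))
            Xi = np.linalg.inv(X)
            Lt = A @ Xi.T
            ft, Gq = _quartimin_criterion(Lt, N)
            if ft < f - 0.5 * s * s * al:
                break
            al /= 2.0
        T, Ti, L, f = X, Xi, Lt, ft
        G = -(L.T @ Gq @ Ti).T
    Phi = T.T @ T
    return L, Phi, f, converged


# ---------------------------------------------------------------------------
# implied moments
# ---------------------------------------------------------------------------

def implied_moments(params: ParameterSet, check_pd: bool = True) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Model-implied (Sigma_g, mu_g) per group."""
    out = {}
    for g in params.groups:
        L, psi, th = params.loadings[g], params.factor_cov[g], params.residual_cov[g]
        sigma = L @ psi @ L.T + th
        if check_pd and np.linalg.eigvalsh(sigma).min() <= 0:
            warnings.warn(f"implied covariance for group {g!r} is not positive definite", stacklevel=2)
        out[g] = (sigma, params.std_means[g].copy())
    return out


# ---------------------------------------------------------------------------
# parameter indexing for the constrained fit
# ---------------------------------------------------------------------------

class _ParamMap:
    """Maps a flat parameter vector onto the structured per-group matrices.

    Equality constraints are shared indices, so degrees-of-freedom accounting
    and the information matrix see one parameter per constrained set.
    Factor-variance cells hold -2 when fixed at one.
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        p, m, groups = spec.panel.n_variables, spec.n_factors, spec.groups
        self.p, self.m, self.groups = p, m, groups
        self.Lid = {g: -np.ones((p, m), dtype=int) for g in groups}
        self.Mid = {g: -np.ones(p, dtype=int) for g in groups}
        self.PsiId = {g: -np.ones((m, m), dtype=int) for g in groups}
        self.ThId = {g: -np.ones((p, p), dtype=int) for g in groups}
        n = 0

        def new():
            nonlocal n
            n += 1
            return n - 1

        ref = groups[0]
        for i in range(p):
            for k in range(m):
                if spec.loading_pattern[ref][i, k] == EQUAL:
                    j = new()
                    for g in groups:
                        self.Lid[g][i, k] = j
                else:
                    for g in groups:
                        if spec.loading_pattern[g][i, k] == FREE:
                            self.Lid[g][i, k] = new()
        for i in range(p):
            if spec.mean_pattern[ref][i] == EQUAL:
                j = new()
                for g in groups:
                    self.Mid[g][i] = j
            else:
                for g in groups:
                    if spec.mean_pattern[g][i] == FREE:
                        self.Mid[g][i] = new()
        for k in range(m):
            for l in range(k + 1, m):
                code = spec.factor_cov_pattern[k, l]
                if code == EQUAL:
                    j = new()
                    for g in groups:
                        self.PsiId[g][k, l] = self.PsiId[g][l, k] = j
                elif code == FREE:
                    for g in groups:
                        j = new()
                        self.PsiId[g][k, l] = self.PsiId[g][l, k] = j
        for g in groups:
            for k in range(m):
                if spec.factor_variance_pattern.get(g) == FREE:
                    self.PsiId[g][k, k] = new()
                else:
                    self.PsiId[g][k, k] = -2
        for i in range(p):
            if spec.residual_variance_pattern[i] == EQUAL:
                j = new()
                for g in groups:
                    self.ThId[g][i, i] = j
            else:
                for g in groups:
                    self.ThId[g][i, i] = new()
        for rc in spec.residual_covariance_pattern:
            i, jv = spec.panel.index(rc.var1), spec.panel.index(rc.var2)
            if rc.code == EQUAL:
                j = new()
                for g in groups:
                    self.ThId[g][i, jv] = self.ThId[g][jv, i] = j
            else:
                for g in groups:
                    j = new()
                    self.ThId[g][i, jv] = self.ThId[g][jv, i] = j
        self.n_params = n
        # vectorized gradient scatter: upper-triangular ids and multipliers
        self._scatter = {}
        iu_p = np.triu_indices(p)
        iu_m = np.triu_indices(m)
        for g in groups:
            th_ids = self.ThId[g][iu_p]
            th_keep = th_ids >= 0
            th_mult = np.where(iu_p[0] == iu_p[1], 1.0, 2.0)[th_keep]
            psi_ids = self.PsiId[g][iu_m] if m else np.empty(0, dtype=int)
            psi_keep = psi_ids >= 0
            psi_mult = (np.where(iu_m[0] == iu_m[1], 1.0, 2.0)[psi_keep] if m else np.empty(0))
            l_ids = self.Lid[g]
            l_keep = l_ids >= 0
            m_ids = self.Mid[g]
            m_keep = m_ids >= 0
            self._scatter[g] = (
                (iu_p[0][th_keep], iu_p[1][th_keep], th_ids[th_keep], th_mult),
                ((iu_m[0][psi_keep], iu_m[1][psi_keep], psi_ids[psi_keep], psi_mult) if m else None),
                (l_keep, l_ids[l_keep]),
                (m_keep, m_ids[m_keep]),
            )

    def unpack(self, x: np.ndarray, g: str):
        L = np.where(self.Lid[g] >= 0, x[np.maximum(self.Lid[g], 0)], 0.0)
        nu = np.where(self.Mid[g] >= 0, x[np.maximum(self.Mid[g], 0)], 0.0)
        psi = np.where(self.PsiId[g] >= 0, x[np.maximum(self.PsiId[g], 0)], 0.0)
        psi[self.PsiId[g] == -2] = 1.0
        th = np.where(self.ThId[g] >= 0, x[np.maximum(self.ThId[g], 0)], 0.0)
        return nu, L, psi, th

    def to_parameter_set(self, x: np.ndarray) -> ParameterSet:
        loadings, psis, thetas, means = {}, {}, {}, {}
        for g in self.groups:
            nu, L, psi, th = self.unpack(x, g)
            loadings[g], psis[g], thetas[g], means[g] = L, psi, th, nu
        return ParameterSet(
            panel=self.spec.panel,
            groups=self.groups,
            factor_names=self.spec.factor_names,
            loadings=loadings,
            factor_cov=psis,
            residual_cov=thetas,
            std_means=means,
        )


# ---------------------------------------------------------------------------
# fit results
# ---------------------------------------------------------------------------

@dataclass
class FitIndices:
    rmsea_point: float
    rmsea_upper90: float
    cfi: float
    tli: float
    srmsr: float
    sbc: float
    aic: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class FitResult:
    """One fitted model: the chi-square ledger row plus estimates.

    ``chi2`` is the reported statistic — the raw ML value when ``scaling`` is
    one, the robust (scaled) value otherwise, so that ``chi2 * scaling``
    always recovers the unscaled ML statistic.
    """

    spec: ModelSpec
    estimates: ParameterSet
    chi2: float
    df: int
    scaling: float
    loglik: float
    n_per_group: dict[str, int]
    converged: bool
    fmin: float
    grad_norm: float
    indices: FitIndices | None = None
    warnings: list[str] = field(default_factory=list)
    param_vector: np.ndarray | None = None
    _param_map: "_ParamMap | None" = None

    @property
    def chi2_ml(self) -> float:
        return self.chi2 * self.scaling

    @property
    def n_total(self) -> int:
        return sum(self.n_per_group.values())

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "estimates": self.estimates.to_dict(),
            "chi2": float(self.chi2),
            "df": int(self.df),
            "scaling": float(self.scaling),
            "loglik": float(self.loglik),
            "n_per_group": {k: int(v) for k, v in self.n_per_group.items()},
            "converged": bool(self.converged),
            "fmin": float(self.fmin),
            "grad_norm": float(self.grad_norm),
            "indices": self.indices.to_dict() if self.indices is not None else None,
            "warnings": list(self.warnings),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(
            spec=ModelSpec.from_dict(d["spec"]),
            estimates=ParameterSet.from_dict(d["estimates"]),
            chi2=d["chi2"],
            df=d["df"],
            scaling=d["scaling"],
            loglik=d["loglik"],
            n_per_group=dict(d["n_per_group"]),
            converged=d["converged"],
            fmin=d["fmin"],
            grad_norm=d["grad_norm"],
            indices=FitIndices(**d["indices"]) if d["indices"] is not None else None,
            warnings=list(d["warnings"]),
        )

    def with_scaling(self, scaling: float) -> "FitResult":
        """Re-express the statistic under a robust scaling correction."""
        if scaling <= 0:
            raise ValueError("scaling factor must be positive")
        out = FitResult(**{**self.__dict__})
        out.chi2 = self.chi2_ml / scaling
        out.scaling = scaling
        return out


# ---------------------------------------------------------------------------
# multi-group constrained ML fit
# ---------------------------------------------------------------------------

def _discrepancy_and_grad(x, pmap: _ParamMap, moments: GroupMoments):
    F = 0.0
    grad = np.zeros(pmap.n_params)
    p = pmap.p
    for g in pmap.groups:
        w = moments.weight(g)
        nu, L, psi, th = pmap.unpack(x, g)
        sigma = L @ psi @ L.T + th
        try:
            c = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return 1e10, grad
        if pmap.m and np.linalg.eigvalsh(psi).min() <= 0:
            return 1e10, grad
        S = moments.covs[g]
        d = moments.means[g] - nu
        cinv = np.linalg.inv(c)
        sinv = cinv.T @ cinv
        sign, logdet = np.linalg.slogdet(S)
        F += w * (
            2.0 * np.sum(np.log(np.diag(c)))
            - logdet
            + float(np.sum(sinv * S))
            - p
            + float(d @ sinv @ d)
        )
        omega = sinv - sinv @ (S + np.outer(d, d)) @ sinv
        dL = 2.0 * w * (omega @ L @ psi)
        dPsi = w * (L.T @ omega @ L)
        dnu = -2.0 * w * (sinv @ d)
        dTh = w * omega
        th_sc, psi_sc, l_sc, m_sc = pmap._scatter[g]
        np.add.at(grad, l_sc[1], dL[l_sc[0]])
        np.add.at(grad, m_sc[1], dnu[m_sc[0]])
        if psi_sc is not None:
            np.add.at(grad, psi_sc[2], psi_sc[3] * dPsi[psi_sc[0], psi_sc[1]])
        np.add.at(grad, th_sc[2], th_sc[3] * dTh[th_sc[0], th_sc[1]])
    return F, grad


def _start_vector(pmap: _ParamMap, moments: GroupMoments, rng: np.random.Generator | None = None):
    """Eigen-based start: per-group principal-factor loadings, quartimin
    rotated and greedily matched to the spec's free-cell pattern."""
    spec = pmap.spec
    p, m = pmap.p, pmap.m
    x = np.zeros(pmap.n_params)
    counts = np.zeros(pmap.n_params)

    def add(j, v):
        if j >= 0:
            x[j] += v
            counts[j] += 1

    for g in pmap.groups:
        S = moments.covs[g]
        sd = np.sqrt(np.diag(S))
        R = S / np.outer(sd, sd)
        if m:
            vals, vecs = np.linalg.eigh(R)
            vals, vecs = vals[::-1][:m], vecs[:, ::-1][:, :m]
            L0 = vecs * np.sqrt(np.maximum(vals, 0.1))
            if m >= 2:
                L0, _phi, _f, _c = quartimin_rotate(L0, max_iter=200, tol=1e-5, n_starts=1)
            pattern_free = np.array(
                [[spec.loading_pattern[g][i, k] != ZERO for k in range(m)] for i in range(p)]
            )
            # greedy column assignment: rotated column -> pattern column
            remaining = list(range(m))
            order = []
            for k in range(m):
                best_j, best_v = remaining[0], -1.0
                for j in remaining:
                    v = float(np.sum(np.abs(L0[pattern_free[:, k], j])))
                    if v > best_v:
                        best_j, best_v = j, v
                order.append(best_j)
                remaining.remove(best_j)
            L0 = L0[:, order]
            L0 = L0 * sd[:, None]
            h2 = np.sum(L0 * L0, axis=1)
        else:
            h2 = np.zeros(p)
        for i in range(p):
            for k in range(m):
                add(pmap.Lid[g][i, k], L0[i, k])
        for i in range(p):
            add(pmap.Mid[g][i], moments.means[g][i])
            add(pmap.ThId[g][i, i], max(S[i, i] - h2[i], 0.2 * S[i, i]))
        for k in range(m):
            if pmap.PsiId[g][k, k] >= 0:
                add(pmap.PsiId[g][k, k], 1.0)
        # psi off-diagonals and theta off-diagonals start at zero
    counts[counts == 0] = 1.0
    x = x / counts
    if rng is not None:
        x = x + rng.normal(0.0, 0.05, size=x.shape)
    return x


def _moment_vector(pmap: _ParamMap, x: np.ndarray) -> np.ndarray:
    """Stacked implied moments [vech(Sigma_g); mu_g] over groups."""
    p = pmap.p
    iu = np.triu_indices(p)
    parts = []
    for g in pmap.groups:
        nu, L, psi, th = pmap.unpack(x, g)
        sigma = L @ psi @ L.T + th
        parts.append(sigma[iu])
        parts.append(nu)
    return np.concatenate(parts)


def _moment_jacobian(pmap: _ParamMap, x: np.ndarray) -> np.ndarray:
    base = _moment_vector(pmap, x)
    J = np.empty((base.size, x.size))
    for j in range(x.size):
        h = 1e-6 * max(1.0, abs(x[j]))
        xp = x.copy()
        xp[j] += h
        J[:, j] = (_moment_vector(pmap, xp) - base) / h
    return J


def fit_model(
    moments: GroupMoments | Mapping[str, pd.DataFrame | np.ndarray],
    spec: ModelSpec,
    n_starts: int = 5,
    seed: int = 0,
    gtol: float = 1e-5,
    check_identification: bool | None = None,
) -> FitResult:
    """Fit a spec to per-group sample moments by constrained ML.

    Quasi-Newton (L-BFGS) minimization with analytic gradients from an
    eigen-based start; up to ``n_starts`` jittered restarts before declaring
    non-convergence.  Negative fitted residual variances are reported as
    Heywood warnings, not silently bounded.  For unrotated (CFA-style) specs
    a rank check of the moment Jacobian at the solution guards against
    under-identified patterns.
    """
    if not isinstance(moments, GroupMoments):
        moments = GroupMoments.from_data(moments)
    p = spec.panel.n_variables
    if moments.n_variables != p:
        raise ValueError("moments and spec disagree on the number of variables")
    for g in spec.groups:
        if np.linalg.eigvalsh(moments.covs[g]).min() <= 0:
            raise ValueError(f"sample covariance for group {g!r} is not positive definite")
    for g in spec.groups:
        for k in range(spec.n_factors):
            if np.all(spec.loading_pattern[g][:, k] == ZERO):
                raise UnderIdentifiedError(
                    f"factor {spec.factor_names[k]!r} has no free loading in group {g!r}"
                )
    df = model_df(spec)
    pmap = _ParamMap(spec)
    rng = np.random.default_rng(seed)
    best = None
    for attempt in range(n_starts):
        x0 = _start_vector(pmap, moments, rng if attempt else None)
        res = None
        for _round in range(3):  # restarting L-BFGS resets its curvature memory
            res = optimize.minimize(
                _discrepancy_and_grad,
                x0 if res is None else res.x,
                args=(pmap, moments),
                jac=True,
                method="L-BFGS-B",
                options={"maxiter": 5000, "maxfun": 100000, "ftol": 1e-13, "gtol": 1e-8},
            )
            gn = float(np.max(np.abs(res.jac)))
            if gn < gtol:
                break
        if best is None or res.fun < best[0].fun - 1e-12:
            best = (res, gn)
        if gn < gtol and res.fun < 1e9:
            best = (res, gn)
            break
    res, gn = best
    converged = bool(gn < gtol and res.fun < 1e9)
    if not converged:
        raise ConvergenceError(
            f"fit did not converge after {n_starts} starts (grad norm {gn:.2e}, F {res.fun:.3e})"
        )
    x = res.x
    fit_warnings: list[str] = []
    params = pmap.to_parameter_set(x)
    _align_estimate_signs(spec, params)
    for g in spec.groups:
        tv = np.diag(params.residual_cov[g])
        if np.any(tv <= 0):
            bad = [spec.panel.variables[i] for i in np.flatnonzero(tv <= 0)]
            fit_warnings.append(f"Heywood condition in group {g!r}: nonpositive residual variance for {bad}")
    if check_identification is None:
        check_identification = spec.rotation == "none"
    if check_identification:
        J = _moment_jacobian(pmap, x)
        rank = np.linalg.matrix_rank(J, tol=1e-8 * max(1.0, float(np.abs(J).max())))
        if rank < pmap.n_params:
            raise UnderIdentifiedError(
                f"moment Jacobian rank {rank} < {pmap.n_params} free parameters"
            )
    N, G = moments.n_total, len(spec.groups)
    chi2 = (N - G) * res.fun
    loglik = _loglik(params, moments)
    for w in fit_warnings:
        logger.warning(w)
    return FitResult(
        spec=spec,
        estimates=params,
        chi2=float(chi2),
        df=int(df),
        scaling=1.0,
        loglik=float(loglik),
        n_per_group=dict(moments.ns),
        converged=converged,
        fmin=float(res.fun),
        grad_norm=gn,
        warnings=fit_warnings,
        param_vector=x,
        _param_map=pmap,
    )


def _align_estimate_signs(spec: ModelSpec, params: ParameterSet) -> None:
    """Fix the factor-sign indeterminacy of a fitted solution in place.

    Each factor column is flipped so its largest-magnitude loading is
    positive (jointly with Psi).  When loadings or factor covariances are
    shared across groups the reference group's flips apply everywhere, so
    equality constraints stay intact.
    """
    m = spec.n_factors
    if m == 0:
        return
    iu = np.triu_indices(m, 1)
    shared = spec.shares_loading_matrix() or (m > 1 and np.any(spec.factor_cov_pattern[iu] == EQUAL))
    ref_signs = None
    for g in spec.groups:
        L, psi, signs = align_factor_signs(params.loadings[g], params.factor_cov[g])
        if shared:
            if ref_signs is None:
                ref_signs = signs
            else:
                L = params.loadings[g] * ref_signs
                psi = params.factor_cov[g] * np.outer(ref_signs, ref_signs)
        params.loadings[g] = L
        params.factor_cov[g] = psi


def _loglik(params: ParameterSet, moments: GroupMoments) -> float:
    """Gaussian log-likelihood at the fitted parameters (full constants)."""
    ll = 0.0
    p = moments.n_variables
    for g in params.groups:
        sigma, mu = implied_moments(params, check_pd=False)[g]
        n = moments.ns[g]
        S, mbar = moments.covs[g], moments.means[g]
        sign, logdet = np.linalg.slogdet(sigma)
        sinv = np.linalg.inv(sigma)
        d = mbar - mu
        ll -= 0.5 * n * (p * np.log(2 * np.pi) + logdet + float(np.sum(sinv * S)) + float(d @ sinv @ d))
    return ll


# ---------------------------------------------------------------------------
# robust (Satorra-Bentler-type) scaling
# ---------------------------------------------------------------------------

def _duplication(p: int) -> np.ndarray:
    """Duplication matrix mapping vech to vec for symmetric p x p matrices."""
    ns = p * (p + 1) // 2
    D = np.zeros((p * p, ns))
    col = 0
    for i in range(p):
        for j in range(i, p):
            D[i * p + j, col] = 1.0
            D[j * p + i, col] = 1.0
            col += 1
    return D


def _vech_indices(p: int):
    return np.triu_indices(p)


def robust_scaling(
    data_by_group: Mapping[str, pd.DataFrame | np.ndarray],
    fit: FitResult,
) -> float:
    """Mean-adjusting robust correction factor for the chi-square statistic.

    c = tr(U Gamma) / df with U the normal-theory residual weight matrix at
    the estimates and Gamma the empirical asymptotic covariance of the sample
    means and covariances (fourth-order moments).  The scaled statistic is
    chi2 / c; under exact multivariate normality c tends to one.
    """
    if fit.param_vector is None or fit._param_map is None:
        raise ValueError("fit carries no parameter vector; robust scaling needs a fitted model")
    pmap = fit._param_map
    spec = fit.spec
    p = pmap.p
    ns_cov = p * (p + 1) // 2
    mdim = ns_cov + p
    iu = _vech_indices(p)
    D = _duplication(p)
    N = sum(len(np.asarray(v)) for v in data_by_group.values())
    G = len(spec.groups)
    mom = implied_moments(fit.estimates, check_pd=False)

    V_blocks, Gamma_blocks = [], []
    for g in spec.groups:
        X = np.asarray(data_by_group[g], dtype=float)
        n_g = X.shape[0]
        w = n_g / N
        if n_g < ns_cov:
            warnings.warn(
                f"group {g!r}: n = {n_g} < p(p+1)/2 = {ns_cov}; fourth-moment estimates unstable",
                stacklevel=2,
            )
        c = X - X.mean(axis=0)
        # z_i = [vech(c_i c_i'), y_i]
        outer = np.einsum("ni,nj->nij", c, c)
        Z = np.concatenate([outer[:, iu[0], iu[1]], X], axis=1)
        Gamma = np.cov(Z, rowvar=False, ddof=0)
        sigma, _mu = mom[g]
        sinv = np.linalg.inv(sigma)
        Vcov = 0.5 * D.T @ np.kron(sinv, sinv) @ D
        V = np.zeros((mdim, mdim))
        V[:ns_cov, :ns_cov] = Vcov
        V[ns_cov:, ns_cov:] = sinv
        V_blocks.append(w * V)
        Gamma_blocks.append(Gamma / w)

    from scipy.linalg import block_diag

    V = block_diag(*V_blocks)
    Gamma = block_diag(*Gamma_blocks)
    Delta = _moment_jacobian(pmap, fit.param_vector)
    VD = V @ Delta
    middle = Delta.T @ VD
    U = V - VD @ np.linalg.pinv(middle, rcond=1e-10) @ VD.T
    c = float(np.trace(U @ Gamma)) / fit.df
    if c <= 0:
        raise ValueError(f"nonpositive scaling factor {c:.3e}")
    return c


# ---------------------------------------------------------------------------
# fit indices
# ---------------------------------------------------------------------------

def baseline_fit(moments: GroupMoments) -> tuple[float, int, float]:
    """Closed-form fit of the zero-correlation baseline model.

    Per group: diagonal covariance with free variances and free means.
    Returns (chi2, df, loglik).
    """
    F = 0.0
    ll = 0.0
    p = moments.n_variables
    G = len(moments.groups)
    N = moments.n_total
    for g in moments.groups:
        S = moments.covs[g]
        n = moments.ns[g]
        w = moments.weight(g)
        sign, logdetS = np.linalg.slogdet(S)
        logdetD = float(np.sum(np.log(np.diag(S))))
        F += w * (logdetD - logdetS)
        ll -= 0.5 * n * (p * np.log(2 * np.pi) + logdetD + p)
    chi2 = (N - G) * F
    df = G * (p + p * (p + 1) // 2) - G * 2 * p
    return float(chi2), int(df), float(ll)


def _rmsea_upper(chi2: float, df: int, n_minus_1: float, level: float = 0.90) -> float:
    """Upper confidence limit by inverting the noncentral chi-square at the
    (1-level)/2 ... here the conventional one-sided 5th percentile."""
    alpha = (1.0 - level) / 2.0  # 0.05 for the 90% limit
    if stats.chi2.cdf(chi2, df) < alpha:
        return 0.0

    def f(lam):
        return stats.ncx2.cdf(chi2, df, lam) - alpha

    hi = max(chi2 * 2.0, 10.0)
    while f(hi) > 0 and hi < 1e8:
        hi *= 2.0
    lam_u = optimize.brentq(f, 0.0, hi, xtol=1e-8)
    return float(np.sqrt(lam_u / (df * n_minus_1)))


def fit_indices(
    chi2: float,
    df: int,
    scaling: float,
    n: int,
    n_groups: int,
    baseline_chi2: float,
    baseline_df: int,
    loglik: float,
    k_params: int,
    residuals: Sequence[np.ndarray] = (),
    weights: Sequence[float] | None = None,
    rmsea_convention: str = "single",
) -> FitIndices:
    """Assemble the fit-index suite from a model's summary numbers.

    RMSEA uses the per-degree-of-freedom discrepancy
    ``sqrt((chi2 - df) / (df (N-1)))`` (zero when chi2 < df), with the 90%
    upper limit from the noncentral chi-square; the optional ``inflated``
    convention multiplies by sqrt(G).  ``residuals`` are per-group
    standardized (observed - implied) moment residual matrices, including the
    diagonal, pooled into SRMSR by group weight.
    """
    if df <= 0:
        raise ValueError("fit indices other than SRMSR are undefined at df = 0")
    n1 = n - 1
    excess = max(chi2 - df, 0.0)
    rmsea = float(np.sqrt(excess / (df * n1)))
    upper = _rmsea_upper(chi2, df, n1)
    if rmsea_convention == "inflated":
        rmsea *= np.sqrt(n_groups)
        upper *= np.sqrt(n_groups)
    elif rmsea_convention != "single":
        raise ValueError("rmsea_convention must be 'single' or 'inflated'")
    denom = max(baseline_chi2 - baseline_df, excess, 0.0)
    cfi = 1.0 if denom == 0 else 1.0 - excess / denom
    cfi = float(np.clip(cfi, 0.0, 1.0))
    base_ratio = baseline_chi2 / baseline_df
    tli = float((base_ratio - chi2 / df) / (base_ratio - 1.0))
    if residuals:
        w = np.asarray(weights if weights is not None else [1.0 / len(residuals)] * len(residuals))
        w = w / w.sum()
        ms = 0.0
        for wi, res in zip(w, residuals):
            iu = np.triu_indices(res.shape[0])
            ms += wi * float(np.mean(res[iu] ** 2))
        srmsr = float(np.sqrt(ms))
    else:
        srmsr = float("nan")
    sbc = -2.0 * loglik + k_params * np.log(n)
    aic = -2.0 * loglik + 2.0 * k_params
    return FitIndices(
        rmsea_point=rmsea,
        rmsea_upper90=float(upper),
        cfi=cfi,
        tli=tli,
        srmsr=srmsr,
        sbc=float(sbc),
        aic=float(aic),
    )


def compute_fit_indices(
    fit: FitResult,
    moments: GroupMoments,
    rmsea_convention: str = "single",
) -> FitIndices:
    """Convenience wrapper: baseline, residual correlations and index suite."""
    b_chi2, b_df, _bll = baseline_fit(moments)
    mom = implied_moments(fit.estimates, check_pd=False)
    residuals, wts = [], []
    for g in fit.spec.groups:
        S = moments.covs[g]
        sigma, mu = mom[g]
        sd = np.sqrt(np.diag(S))
        res = (S - sigma) / np.outer(sd, sd)
        residuals.append(res)
        wts.append(moments.weight(g))
    k = count_free_parameters(fit.spec)
    return fit_indices(
        chi2=fit.chi2,
        df=fit.df,
        scaling=fit.scaling,
        n=fit.n_total,
        n_groups=len(fit.spec.groups),
        baseline_chi2=b_chi2,
        baseline_df=b_df,
        loglik=fit.loglik,
        k_params=k,
        residuals=residuals,
        weights=wts,
        rmsea_convention=rmsea_convention,
    )


# ---------------------------------------------------------------------------
# scaled chi-square difference test
# ---------------------------------------------------------------------------

class ScaledDifference(NamedTuple):
    delta_chi2: float
    delta_df: int
    c_d: float
    pvalue: float


def _as_summary(fit) -> tuple[float, int, float]:
    if hasattr(fit, "chi2"):
        return float(fit.chi2), int(fit.df), float(getattr(fit, "scaling", 1.0))
    chi2, df, scaling = fit
    return float(chi2), int(df), float(scaling)


def scaled_chi2_difference(nested, parent) -> ScaledDifference:
    """Scaled likelihood-ratio test between nested models.

    c_d = (df_n * c_n - df_p * c_p) / (df_n - df_p); the difference statistic
    is |chi2_n * c_n - chi2_p * c_p| / c_d on df_n - df_p degrees of freedom
    (chi2 here being each model's reported scaled statistic, so multiplying
    by its scaling recovers the raw ML value).  The absolute value covers the
    occasional direction reversal when a constrained model fits *better*.
    Inputs may be :class:`FitResult` objects or (chi2, df, scaling) triples.
    """
    chi2_n, df_n, c_n = _as_summary(nested)
    chi2_p, df_p, c_p = _as_summary(parent)
    delta_df = df_n - df_p
    if delta_df <= 0:
        raise InvalidComparisonError("nested model must have more degrees of freedom than its parent")
    c_d = (df_n * c_n - df_p * c_p) / delta_df
    if c_d <= 0:
        raise InvalidComparisonError(f"nonpositive difference scaling c_d = {c_d:.4f}")
    delta = abs(chi2_n * c_n - chi2_p * c_p) / c_d
    pvalue = float(stats.chi2.sf(delta, delta_df))
    return ScaledDifference(float(delta), int(delta_df), float(c_d), pvalue)


# ---------------------------------------------------------------------------
# communalities and explained variance
# ---------------------------------------------------------------------------

def communalities(params: ParameterSet) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Per-variable communalities and per-factor explained-variance shares.

    The communality of variable j is lambda_j' Psi lambda_j (factor
    correlations included).  The per-factor share attributes
    [Lambda' Lambda Psi]_kk / p to factor k — the standardized variance it
    explains, cross-factor covariance split symmetrically.
    """
    h, shares = {}, {}
    p = params.panel.n_variables
    for g in params.groups:
        L, psi = params.loadings[g], params.factor_cov[g]
        h[g] = np.einsum("jk,kl,jl->j", L, psi, L)
        shares[g] = np.diag(L.T @ L @ psi) / p
    return h, shares


def first_dimension_share(params: ParameterSet, group: str) -> float:
    """Share of total standardized variance carried by the first extracted
    dimension: the leading eigenvalue of the implied correlation matrix
    over p."""
    sigma, _mu = implied_moments(params, check_pd=False)[group]
    sd = np.sqrt(np.diag(sigma))
    R = sigma / np.outer(sd, sd)
    return float(np.linalg.eigvalsh(R).max() / params.panel.n_variables)
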