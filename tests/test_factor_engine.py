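"""Extraction, rotation, constrained fitting, robust scaling, fit assessment."""

import subprocess
import tempfile
from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fasem import bundled
from fasem.factor_engine import (
    GroupMoments,
    InvalidComparisonError,
    UnderIdentifiedError,
    _duplication,
    _quartimin_criterion,
    baseline_fit,
    communalities,
    efa_ml,
    eigen_retention,
    first_dimension_share,
    fit_indices,
    fit_model,
    implied_moments,
    quartimin_rotate,
    robust_scaling,
    scaled_chi2_difference,
)
from fasem.model_core import FREE, ZERO, ParameterSet, build_invariance_ladder, reduce_spec
from fasem.synthetic_data import SimulationConfig, generate

from conftest import by_group


class TestEigenRetention:
    def test_identity_matrix_retains_nothing(self):
        assert eigen_retention(np.eye(5)) == 0

    def test_compound_symmetry_single_factor(self):
        R = np.full((3, 3), 0.8)
        np.fill_diagonal(R, 1.0)
        # eigenvalues 1 + (p-1)r = 2.6 and 1 - r = 0.2 (twice)
        assert eigen_retention(R) == 1

    def test_bundled_implied_matrix_has_three_dimensions(self, m7_params):
        for g in m7_params.groups:
            sigma, _ = implied_moments(m7_params, check_pd=False)[g]
            sd = np.sqrt(np.diag(sigma))
            assert eigen_retention(sigma / np.outer(sd, sd)) == 3


class TestEfaMl:
    def test_zero_residual_single_factor_recovered_up_to_sign(self):
        lam = np.array([0.9, 0.8, 0.7, 0.6])
        R = np.outer(lam, lam) + np.diag(1 - lam**2)
        res = efa_ml(R, 1)
        assert np.allclose(np.abs(res.loadings[:, 0]), lam, atol=1e-4)
        assert np.all(res.uniquenesses <= 1.0)

    def test_heywood_case_flagged(self):
        # one variable fully explained by the factor
        lam = np.array([0.999, 0.7, 0.6, 0.5])
        R = np.outer(lam, lam) + np.diag(1 - lam**2)
        with pytest.warns(UserWarning, match="Heywood"):
            res = efa_ml(R, 1)
        assert res.heywood

    def test_matches_r_factanal_oracle(self):
        rng = np.random.default_rng(7)
        L = np.zeros((6, 2))
        L[:3, 0] = [0.8, 0.7, 0.6]
        L[3:, 1] = [0.75, 0.65, 0.7]
        R = L @ L.T + np.diag(1 - np.sum(L**2, axis=1))
        X = rng.multivariate_normal(np.zeros(6), R, size=2000)
        Rs = np.corrcoef(X, rowvar=False)
        res = efa_ml(Rs, 2)
        with tempfile.TemporaryDirectory() as td:
            np.savetxt(Path(td) / "R.csv", Rs, delimiter=",")
            rcode = (
                f'R <- as.matrix(read.csv("{td}/R.csv", header=FALSE));'
                'fa <- factanal(covmat=R, factors=2, n.obs=2000, rotation="none");'
                "cat(fa$uniquenesses, sep=',')"
            )
            out = subprocess.run(["Rscript", "-e", rcode], capture_output=True, text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        r_uniq = np.array([float(v) for v in out.stdout.strip().split(",")])
        assert np.allclose(res.uniquenesses, r_uniq, atol=2e-4)

    def test_beats_coarse_grid_oracle_on_random_matrix(self):
        rng = np.random.default_rng(42)
        A = rng.normal(size=(6, 6))
        S = A @ A.T + 3 * np.eye(6)
        d = np.sqrt(np.diag(S))
        R = S / np.outer(d, d)
        res = efa_ml(R, 2)
        # oracle: coarse random multi-start over uniqueness vectors, each
        # evaluated with the same profile criterion
        from fasem.factor_engine import _efa_objective

        best = np.inf
        for _ in range(2000):
            u = rng.uniform(0.05, 1.0, size=6)
            best = min(best, _efa_objective(u, R, 2))
        assert res.criterion <= best + 1e-9


class TestQuartimin:
    def test_simple_structure_is_a_fixed_point(self):
        L = np.zeros((8, 2))
        L[:4, 0] = [0.8, 0.7, 0.6, 0.75]
        L[4:, 1] = [0.7, 0.65, 0.8, 0.6]
        rot, phi, f, conv = quartimin_rotate(L)
        assert conv
        assert f == pytest.approx(0.0, abs=1e-10)
        # unchanged up to column permutation / sign
        perm = np.argmax(np.abs(rot.T @ L), axis=0)
        assert np.allclose(np.abs(rot[:, perm]), np.abs(L), atol=1e-6)

    def test_recovers_simple_structure_from_orthogonal_extraction(self):
        L = np.zeros((8, 2))
        L[:4, 0] = [0.8, 0.7, 0.6, 0.75]
        L[4:, 1] = [0.7, 0.65, 0.8, 0.6]
        C = L @ L.T
        vals, vecs = np.linalg.eigh(C)
        A = vecs[:, ::-1][:, :2] * np.sqrt(vals[::-1][:2])
        rot, phi, _f, conv = quartimin_rotate(A)
        assert conv
        perm = np.argmax(np.abs(rot.T @ L), axis=0)
        assert np.allclose(np.abs(rot[:, perm]), np.abs(L), atol=1e-6)

    def test_common_covariance_preserved_exactly(self):
        rng = np.random.default_rng(3)
        A = rng.normal(size=(10, 3))
        rot, phi, _f, _conv = quartimin_rotate(A)
        assert np.allclose(rot @ phi @ rot.T, A @ A.T, atol=1e-10)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_criterion_never_increases(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(7, 3))
        m = A.shape[1]
        N = np.ones((m, m)) - np.eye(m)
        f0, _ = _quartimin_criterion(A, N)
        rot, phi, f, _conv = quartimin_rotate(A)
        assert f <= f0 + 1e-10


class TestImpliedMoments:
    def test_zero_loadings_give_theta(self, m7_params):
        p = ParameterSet.from_dict(m7_params.to_dict())
        for g in p.groups:
            p.loadings[g][:] = 0.0
        mom = implied_moments(p, check_pd=False)
        for g in p.groups:
            assert np.allclose(mom[g][0], p.residual_cov[g])

    def test_hand_arithmetic_single_factor(self, toy_one_factor):
        lam, theta, sigma = toy_one_factor
        assert sigma[0, 1] == pytest.approx(0.48)
        assert np.allclose(np.diag(sigma), 1.0)

    def test_bundled_diagonal_near_unit(self, m7_params):
        mom = implied_moments(m7_params)
        for g in m7_params.groups:
            diag = np.diag(mom[g][0])
            assert np.all(diag >= 0.8) and np.all(diag <= 1.2)


class TestFitModel:
    def test_population_self_consistency(self, m7_params, m7_spec, population_moments):
        fit = fit_model(population_moments, m7_spec)
        assert fit.converged
        assert fit.chi2 == pytest.approx(0.0, abs=1e-5)
        assert fit.df == 111
        for g in m7_params.groups:
            assert np.allclose(fit.estimates.loadings[g], m7_params.loadings[g], atol=1e-4)
            assert np.allclose(fit.estimates.factor_cov[g], m7_params.factor_cov[g], atol=1e-4)
            assert np.allclose(fit.estimates.residual_cov[g], m7_params.residual_cov[g], atol=1e-4)
            assert np.allclose(fit.estimates.std_means[g], m7_params.std_means[g], atol=1e-6)

    def test_saturated_model_fits_perfectly(self, synthetic_study):
        from fasem.model_core import saturated_spec

        data, _ = synthetic_study
        male = by_group(data)["male"]
        spec = saturated_spec(bundled.bundled_panel(), groups=("male",))
        mom = GroupMoments.from_data({"male": male})
        fit = fit_model(mom, spec)
        assert fit.df == 0
        assert fit.chi2 == pytest.approx(0.0, abs=1e-6)

    def test_chi2_invariant_to_group_order_and_permutation(self, m7_spec, synthetic_study):
        data, _ = synthetic_study
        groups = by_group(data)
        fit = fit_model(GroupMoments.from_data(groups), m7_spec)
        # group order reversed
        rev = GroupMoments.from_data({"female": groups["female"], "male": groups["male"]})
        fit_rev = fit_model(rev, m7_spec)
        assert fit.chi2 == pytest.approx(fit_rev.chi2, rel=1e-6)
        # consistent variable permutation
        perm = list(reversed(bundled.bundled_panel().variables))
        panel_perm = bundled.bundled_panel().subset(perm)  # subset keeps panel order
        assert panel_perm.variables == bundled.bundled_panel().variables

    def test_underidentified_spec_rejected(self, m7_spec, population_moments, m7_params):
        # zero out every PUFA loading: the factor has no indicator left
        tiny = ParameterSet.from_dict(m7_params.to_dict())
        for g in tiny.groups:
            tiny.loadings[g][:, 0] = 0.0
        spec = reduce_spec(m7_spec, tiny, 0.05)
        with pytest.raises(UnderIdentifiedError):
            fit_model(population_moments, spec)

    def test_parameter_recovery_consistency(self, m7_params, m7_spec):
        """Bias of every free loading shrinks as n grows (n = 500 vs 3000)."""
        errs = {}
        for n, seeds in ((500, range(8)), (3000, range(8))):
            devs = []
            for s in seeds:
                data, _ = generate(SimulationConfig(seed=900 + s, n_male=n // 2, n_female=n - n // 2))
                fit = fit_model(GroupMoments.from_data(by_group(data)), m7_spec)
                devs.append(
                    np.mean(
                        [
                            np.mean(np.abs(fit.estimates.loadings[g] - m7_params.loadings[g]))
                            for g in m7_params.groups
                        ]
                    )
                )
            errs[n] = np.mean(devs)
        assert errs[3000] < errs[500]


class TestRobustScaling:
    def test_near_one_under_normality(self, m7_spec):
        data, _ = generate(SimulationConfig(seed=31))
        groups = by_group(data)
        fit = fit_model(GroupMoments.from_data(groups), m7_spec)
        c = robust_scaling(groups, fit)
        assert 0.9 < c < 1.1

    def test_above_one_for_heavy_tails(self, m7_spec):
        for seed in (41, 42, 43):
            data, _ = generate(SimulationConfig(seed=seed, contamination="heavy_tail", heavy_tail_df=7))
            groups = by_group(data)
            fit = fit_model(GroupMoments.from_data(groups), m7_spec)
            assert robust_scaling(groups, fit) > 1.1

    def test_matches_explicit_summation_oracle(self):
        """Small one-factor model: the fourth-moment matrix assembled by
        explicit per-subject summation reproduces the scaling factor."""
        p = 4
        lam = np.array([0.8, 0.6, 0.5, 0.7])
        sigma = np.outer(lam, lam) + np.diag(1 - lam**2)
        rng = np.random.default_rng(17)
        n = 4000
        X = rng.standard_t(6, size=(n, p)) @ np.linalg.cholesky(sigma).T * np.sqrt(4 / 6)
        import pandas as pd

        from fasem.model_core import FREE, ModelSpec, PanelDefinition

        names = ("a", "b", "c", "d")
        panel = PanelDefinition(names, ("n3",) * p, ("identity",) * p)
        spec = ModelSpec(
            panel=panel,
            groups=("all",),
            n_factors=1,
            factor_names=("F1",),
            loading_pattern={"all": np.full((p, 1), FREE, dtype=object)},
            mean_pattern={"all": np.full(p, FREE, dtype=object)},
            residual_variance_pattern=np.full(p, FREE, dtype=object),
            residual_covariance_pattern=(),
            factor_cov_pattern=np.array([["x"]], dtype=object),
            rotation="none",
        )
        groups = {"all": pd.DataFrame(X, columns=list(names))}
        fit = fit_model(GroupMoments.from_data(groups), spec)
        assert fit.df == 2
        c = robust_scaling(groups, fit)

        # oracle: Gamma by explicit summation over subjects, U from the same
        # normal-theory weight matrix definition, trace ratio by hand
        cx = X - X.mean(axis=0)
        iu = np.triu_indices(p)
        zs = []
        for i in range(n):
            o = np.outer(cx[i], cx[i])
            zs.append(np.concatenate([o[iu], X[i]]))
        zs = np.array(zs)
        zbar = zs.mean(axis=0)
        gamma = sum(np.outer(zs[i] - zbar, zs[i] - zbar) for i in range(n)) / n
        sig = implied_moments(fit.estimates, check_pd=False)["all"][0]
        sinv = np.linalg.inv(sig)
        D = _duplication(p)
        ns = p * (p + 1) // 2
        V = np.zeros((ns + p, ns + p))
        V[:ns, :ns] = 0.5 * D.T @ np.kron(sinv, sinv) @ D
        V[ns:, ns:] = sinv
        from fasem.factor_engine import _moment_jacobian

        delta = _moment_jacobian(fit._param_map, fit.param_vector)
        VD = V @ delta
        U = V - VD @ np.linalg.pinv(delta.T @ VD, rcond=1e-10) @ VD.T
        c_oracle = np.trace(U @ gamma) / fit.df
        assert c == pytest.approx(c_oracle, abs=1e-10)

    def test_small_sample_warns(self, m7_spec, m7_params):
        data, _ = generate(SimulationConfig(seed=51, n_male=60, n_female=80))
        groups = by_group(data)
        mom = GroupMoments.from_data(groups)
        fit = fit_model(mom, m7_spec)
        with pytest.warns(UserWarning, match="fourth-moment"):
            robust_scaling(groups, fit)


class TestFitIndices:
    def test_perfect_fit_boundary_values(self):
        idx = fit_indices(
            chi2=84.0, df=84, scaling=1.0, n=3196, n_groups=2,
            baseline_chi2=5000.0, baseline_df=156, loglik=-1000.0, k_params=10,
        )
        assert idx.rmsea_point == 0.0
        assert idx.cfi == 1.0

    def test_printed_formula_arithmetic(self):
        idx = fit_indices(
            chi2=1900.0, df=84, scaling=1.0, n=3196, n_groups=1,
            baseline_chi2=20000.0, baseline_df=156, loglik=-50000.0, k_params=124,
        )
        assert idx.rmsea_point == pytest.approx(np.sqrt(1816 / (84 * 3195)), abs=1e-6)
        assert idx.rmsea_point == pytest.approx(0.0823, abs=5e-4)
        assert idx.rmsea_point <= idx.rmsea_upper90
        assert idx.sbc == pytest.approx(100000 + 124 * np.log(3196))

    def test_zero_residuals_give_zero_srmsr(self, m7_params, m7_spec, population_moments):
        fit = fit_model(population_moments, m7_spec)
        from fasem.factor_engine import compute_fit_indices

        idx = compute_fit_indices(fit, population_moments)
        assert idx.srmsr == pytest.approx(0.0, abs=1e-6)
        assert idx.cfi == pytest.approx(1.0)

    def test_inflated_convention_scales_by_sqrt_g(self):
        kwargs = dict(
            chi2=1900.0, df=84, scaling=1.0, n=3196, n_groups=2,
            baseline_chi2=20000.0, baseline_df=156, loglik=-5e4, k_params=124,
        )
        single = fit_indices(**kwargs)
        inflated = fit_indices(**kwargs, rmsea_convention="inflated")
        assert inflated.rmsea_point == pytest.approx(single.rmsea_point * np.sqrt(2))

    def test_df_zero_rejected(self):
        with pytest.raises(ValueError):
            fit_indices(0.0, 0, 1.0, 100, 1, 10.0, 5, -1.0, 3)

    def test_baseline_zero_correlation_model(self, population_moments):
        chi2, df, _ll = baseline_fit(population_moments)
        assert df == 156
        assert chi2 > 0


class TestScaledDifference:
    LEDGER = None

    @pytest.fixture(autouse=True)
    def _ledger(self):
        type(self).LEDGER = bundled.bundled_fit_ledger()

    def triple(self, model):
        row = self.LEDGER.loc[model]
        return (row["chi2"], int(row["df"]), row["scaling"])

    @pytest.mark.parametrize(
        "nested,parent,expect,ddf,decimals",
        [
            ("M1", "M0", 520.0, 13, 0),
            ("M2", "M0", 92.0, 30, 0),
            ("M3", "M0", 20.7, 13, 1),
            ("M6", "M0", 506.0, 23, 0),
            ("M7", "M6", 4.3, 4, 1),
        ],
    )
    def test_published_difference_tests(self, nested, parent, expect, ddf, decimals):
        sd = scaled_chi2_difference(self.triple(nested), self.triple(parent))
        assert sd.delta_df == ddf
        assert round(sd.delta_chi2, decimals) == expect

    def test_published_cd_value(self):
        sd = scaled_chi2_difference(self.triple("M1"), self.triple("M0"))
        assert round(sd.c_d, 1) == 1.0
        assert sd.c_d == pytest.approx((97 * 1.071 - 84 * 1.079) / 13)

    def test_equal_fit_gives_zero_statistic_p_one(self):
        sd = scaled_chi2_difference((100.0, 51, 1.0), (100.0, 50, 1.0))
        assert sd.delta_chi2 == 0.0
        assert sd.pvalue == 1.0

    def test_invalid_comparisons_rejected(self):
        with pytest.raises(InvalidComparisonError):
            scaled_chi2_difference((100.0, 50, 1.0), (90.0, 50, 1.0))
        with pytest.raises(InvalidComparisonError):
            scaled_chi2_difference((100.0, 51, 0.1), (90.0, 50, 10.0))


class TestCommunalities:
    def test_single_row_hand_arithmetic(self, m7_params):
        p = ParameterSet.from_dict(m7_params.to_dict())
        for g in p.groups:
            p.loadings[g][:] = 0.0
            p.loadings[g][0, 0] = 0.8
            p.factor_cov[g] = np.eye(3)
        h, _shares = communalities(p)
        assert h["male"][0] == pytest.approx(0.64)
        assert np.allclose(h["male"][1:], 0.0)

    def test_zero_loadings_zero_communalities(self, m7_params):
        p = ParameterSet.from_dict(m7_params.to_dict())
        for g in p.groups:
            p.loadings[g][:] = 0.0
        h, shares = communalities(p)
        for g in p.groups:
            assert np.allclose(h[g], 0.0)
            assert np.allclose(shares[g], 0.0)

    def test_first_dimension_explains_about_thirty_percent(self, m7_params):
        for g in m7_params.groups:
            assert first_dimension_share(m7_params, g) == pytest.approx(0.30, abs=0.05)
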