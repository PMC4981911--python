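import math

import numpy as np
import pytest
from scipy.stats import multivariate_normal, spearmanr, ttest_ind

from crtmi.core_data import TrialDataset
from crtmi.dgp import ModelConstants, ScenarioConfig, fixed_sizes, generate_trial
from crtmi.harness import make_mechanism
from crtmi.imputers import (
    CollinearDesignError,
    GibbsControl,
    InsufficientDataError,
    choose_reference_cluster,
    draw_regression_posterior,
    impute_fmi,
    impute_mmi,
    impute_mmi_many,
    impute_smi,
    _gibbs_arm,
)
from crtmi.missingness import apply_missingness

from conftest import make_trial


class TestConjugateDraw:
    def test_degenerate_likelihood_limit(self, rng):
        # zero residual variance: coefficient draws concentrate on truth
        n = 4000
        X = np.column_stack([np.ones(n), rng.standard_normal(n)])
        B = np.array([[2.0, -1.0], [0.5, 3.0]])
        y = X @ B + 1e-6 * rng.standard_normal((n, 2))
        draws = np.array(
            [draw_regression_posterior(y, X, rng).coef for _ in range(50)]
        )
        assert np.allclose(draws.mean(axis=0), B, atol=1e-4)
        assert draws.std(axis=0).max() < 1e-4

    def test_posterior_moments_match_closed_form(self, rng):
        # intercept-only: Sigma | y ~ IW(n - 1, S); E = S / (n - 1 - 3)
        n = 60
        y = rng.standard_normal((n, 2)) @ np.array([[2.0, 0.3], [0.0, 1.0]])
        X = np.ones((n, 1))
        resid = y - y.mean(axis=0)
        S = resid.T @ resid
        expected = S / (n - 1 - 3)
        draws = np.array(
            [draw_regression_posterior(y, X, rng).resid_cov
             for _ in range(4000)]
        )
        got = draws.mean(axis=0)
        mc_se = draws.std(axis=0) / math.sqrt(4000)
        assert np.all(np.abs(got - expected) < 4 * mc_se)

    def test_collinear_design_rejected(self, rng):
        n = 30
        x = rng.standard_normal(n)
        X = np.column_stack([np.ones(n), x, x])
        with pytest.raises(CollinearDesignError):
            draw_regression_posterior(rng.standard_normal((n, 2)), X, rng)

    def test_insufficient_rows_rejected(self, rng):
        X = np.ones((4, 2))
        with pytest.raises(InsufficientDataError):
            draw_regression_posterior(np.zeros((4, 2)), X, rng)


class TestReferenceCluster:
    def test_nearest_to_arm_mean(self):
        d = make_trial(
            arms=[0] * 6,
            clusters=["a", "a", "b", "b", "c", "c"],
            y1=[10, 10, 20, 20, 30, 30],
            y2=[10, 10, 20, 20, 30, 30],
        )
        # arm mean = 20; widen slightly so 'b' mean 20 is nearest
        d.y1[5] = 33.0  # arm mean 20.5, cluster means 10, 20, 31.5
        assert choose_reference_cluster(d, outcome=1) == "b"

    def test_single_cluster(self):
        d = make_trial(arms=[0, 0], clusters=["z", "z"], y1=[1, 2], y2=[3, 4])
        assert choose_reference_cluster(d) == "z"

    def test_tie_goes_to_first_appearing(self):
        d = make_trial(
            arms=[0] * 4,
            clusters=["p", "p", "q", "q"],
            y1=[18, 18, 24, 24],
            y2=[0, 0, 0, 0],
        )
        # arm mean 21, both clusters distance 3 on y1
        assert choose_reference_cluster(d, outcome=1) == "p"

    def test_no_observed_outcome_error(self):
        d = make_trial(
            arms=[0, 0], clusters=["a", "b"],
            y1=[np.nan, np.nan], y2=[1.0, 2.0],
        )
        with pytest.raises(InsufficientDataError):
            choose_reference_cluster(d, outcome=1)


def _masked_scenario(seed=0, J=25, nj=10, icc1=0.05, icc2=0.05):
    mech = make_mechanism("both", "low", (0.25, 0.25))
    scn = ScenarioConfig(
        J=J, cluster_size_spec=fixed_sizes(nj), icc1=icc1, icc2=icc2,
        mechanism=mech, seed=seed,
    )
    rng = scn.replicate_rng(0)
    data = generate_trial(scn, rng)
    return data, apply_missingness(data, mech, rng)


@pytest.mark.parametrize("engine,kwargs", [
    (impute_smi, {}),
    (impute_fmi, {}),
    (impute_mmi, {"control": GibbsControl(burn_in=50, thin=20)}),
])
class TestEngineContracts:
    def test_no_missing_gives_identical_copies(self, engine, kwargs, rng):
        data, _ = _masked_scenario()
        stack = engine(data, 3, rng=rng, **kwargs)
        stack.validate()
        for d in stack.m_copies:
            assert np.array_equal(d.y1, data.y1)
            assert np.array_equal(d.y2, data.y2)

    def test_observed_preserved_and_proper(self, engine, kwargs, rng):
        _, masked = _masked_scenario(seed=1)
        stack = engine(masked, 6, rng=rng, **kwargs)
        stack.validate()  # observed-value preservation
        mis = np.nonzero(masked.r1 == 1)[0]
        vals = np.array([d.y1[mis] for d in stack.m_copies])
        # properness: imputations differ across copies for every cell
        assert (vals.std(axis=0) > 0).all()

    def test_per_arm_independence(self, engine, kwargs, rng):
        _, masked = _masked_scenario(seed=2)
        other = TrialDataset(
            individual_id=masked.individual_id,
            cluster_id=masked.cluster_id,
            arm=masked.arm,
            x=masked.x,
            w=masked.w,
            y1=masked.y1.copy(),
            y2=masked.y2.copy(),
            r1=masked.r1,
            r2=masked.r2,
        )
        # perturb arm-1 outcomes only; arm-0 imputations must not change
        sel = (other.arm == 1) & (other.r1 == 0)
        other.y1[sel] += 37.0
        s1 = engine(masked, 3, rng=np.random.default_rng(9), **kwargs)
        s2 = engine(other, 3, rng=np.random.default_rng(9), **kwargs)
        arm0 = masked.arm == 0
        for d1, d2 in zip(s1.m_copies, s2.m_copies):
            assert np.array_equal(d1.y1[arm0], d2.y1[arm0])
            assert np.array_equal(d1.y2[arm0], d2.y2[arm0])


class TestSMI:
    def test_mcar_preserves_means(self, rng):
        mc = ModelConstants(beta_x1=0, beta_x2=0, beta_w1=0, beta_w2=0)
        scn = ScenarioConfig(
            J=10, cluster_size_spec=fixed_sizes(500), icc1=0.0, icc2=0.0,
            model_constants=mc, seed=3,
        )
        data = generate_trial(scn, scn.replicate_rng(0))
        mask = rng.random(data.n) < 0.3
        y1 = data.y1.copy()
        y1[mask] = np.nan
        masked = TrialDataset(
            data.individual_id, data.cluster_id, data.arm, data.x, data.w,
            y1, data.y2, mask.astype(np.int8), np.zeros(data.n, np.int8),
        )
        stack = impute_smi(masked, 5, rng=rng)
        obs_mean = y1[~mask].mean()
        imp_mean = np.mean([d.y1[mask].mean() for d in stack.m_copies])
        pooled_sd = data.y1.std()
        assert abs(imp_mean - obs_mean) < 4 * pooled_sd / math.sqrt(mask.sum())

    def test_conditional_structure_tracks_coobserved_outcome(self, rng):
        # strongly correlated outcomes: imputed y1 must track observed y2
        n = 400
        z = rng.standard_normal(n)
        y1 = z + 0.05 * rng.standard_normal(n)
        y2 = z + 0.05 * rng.standard_normal(n)
        mask = rng.random(n) < 0.4
        y1m = y1.copy()
        y1m[mask] = np.nan
        d = make_trial(
            arms=[0] * (n // 2) + [1] * (n // 2),
            clusters=["a"] * (n // 2) + ["b"] * (n // 2),
            y1=y1m, y2=y2,
        )
        stack = impute_smi(d, 4, aux=(), rng=rng)
        for dd in stack.m_copies:
            r, _ = spearmanr(dd.y1[mask], y2[mask])
            assert r > 0.9


class TestFMI:
    def test_imputations_track_cluster_means(self, rng):
        # two distant clusters per arm with small residual spread
        arms, clusters, y1 = [], [], []
        for k, (lo, hi) in enumerate((("lo", "hi"), ("lo2", "hi2"))):
            for cl, mean in ((lo, 0.0), (hi, 100.0)):
                vals = mean + 0.1 * rng.standard_normal(3)
                for v in vals:
                    arms.append(k)
                    clusters.append(cl)
                    y1.append(v)
                arms.append(k)
                clusters.append(cl)
                y1.append(np.nan)
        y1 = np.array(y1)
        y2 = 0.5 * y1 + 0.1 * rng.standard_normal(y1.size)
        y2[np.isnan(y1)] = np.nan  # both outcomes missing on those rows
        d = make_trial(
            arms=arms, clusters=clusters, y1=y1, y2=y2,
            x=list(rng.standard_normal(len(arms))),
        )
        stack = impute_fmi(d, 8, rng=rng)
        lo_mis = np.nonzero(np.isnan(y1) & (np.array(clusters) == "lo"))[0][0]
        hi_mis = np.nonzero(np.isnan(y1) & (np.array(clusters) == "hi"))[0][0]
        lo_imputed = np.array([c.y1[lo_mis] for c in stack.m_copies])
        hi_imputed = np.array([c.y1[hi_mis] for c in stack.m_copies])
        assert lo_imputed.mean() < 40.0
        assert hi_imputed.mean() > 60.0

    def test_empty_cluster_imputed_from_reference(self, rng):
        # cluster "e" has no observed outcomes; its imputations should
        # match the reference cluster's predictive distribution
        arms, clusters, y1 = [], [], []
        for cl, mean in (("a", 0.0), ("b", 10.0), ("c", 20.0)):
            for v in mean + 0.5 * rng.standard_normal(30):
                arms.append(0)
                clusters.append(cl)
                y1.append(v)
        for _ in range(30):
            arms.append(0)
            clusters.append("e")
            y1.append(np.nan)
        for cl in ("f", "g"):
            for v in 5.0 + 0.5 * rng.standard_normal(10):
                arms.append(1)
                clusters.append(cl)
                y1.append(v)
        y1 = np.array(y1)
        y2 = 0.5 * y1 + 0.2 * rng.standard_normal(y1.size)
        y2[np.isnan(y1)] = np.nan
        d = make_trial(arms=arms, clusters=clusters, y1=y1, y2=y2,
                       x=list(rng.standard_normal(len(arms))))
        arm0 = np.array(arms) == 0
        ref = choose_reference_cluster(
            make_trial(
                arms=[0] * int(arm0.sum()),
                clusters=list(np.array(clusters)[arm0]),
                y1=y1[arm0], y2=y2[arm0],
            ),
            candidates=["a", "b", "c"],
        )
        assert ref == "b"  # arm mean ~10 -> middle cluster
        stack = impute_fmi(d, 40, rng=rng)
        e_idx = np.array([c == "e" for c in clusters])
        imputed = np.concatenate([c.y1[e_idx] for c in stack.m_copies])
        assert abs(imputed.mean() - 10.0) < 1.0

    def test_rejects_cluster_level_covariate(self, rng):
        _, masked = _masked_scenario(seed=4)
        with pytest.raises(ValueError, match="cluster-level"):
            impute_fmi(masked, 2, aux=("x", "w"), rng=rng)


class TestMMI:
    def test_parameter_recovery(self, rng):
        # generation per the imputation model itself: tau=(20,10), phi=0.3,
        # sigma=(40,20), rho=0.1; J=200 clusters of 20, 20% MCAR
        mc = ModelConstants(
            beta_x1=0, beta_x2=0, beta_w1=0, beta_w2=0, phi=0.3, rho=0.1
        )
        scn = ScenarioConfig(
            J=200, cluster_size_spec=fixed_sizes(20),
            icc1=0.2, icc2=0.2,  # tau1=20, tau2=10
            model_constants=mc, seed=12,
        )
        sigs, phis = [], []
        for rep in range(3):
            data = generate_trial(scn, scn.replicate_rng(rep))
            y1 = data.y1.copy()
            y2 = data.y2.copy()
            y1[rng.random(data.n) < 0.2] = np.nan
            y2[rng.random(data.n) < 0.2] = np.nan
            masked = TrialDataset(
                data.individual_id, data.cluster_id, data.arm, data.x,
                data.w, y1, y2, np.isnan(y1).astype(np.int8),
                np.isnan(y2).astype(np.int8),
            )
            _, draws = impute_mmi(
                masked, 25, control=GibbsControl(burn_in=200, thin=25),
                rng=rng, return_draws=True,
            )
            sigs.append(
                np.mean([d.resid_cov for a in draws for d in a], axis=0))
            phis.append(
                np.mean([d.raneff_cov for a in draws for d in a], axis=0))
        sig = np.mean(sigs, axis=0)
        phi_mat = np.mean(phis, axis=0)
        assert sig[0, 0] == pytest.approx(1600.0, rel=0.10)
        assert sig[1, 1] == pytest.approx(400.0, rel=0.10)
        assert phi_mat[0, 0] == pytest.approx(400.0, rel=0.10)
        assert phi_mat[1, 1] == pytest.approx(100.0, rel=0.10)
        assert phi_mat[0, 1] == pytest.approx(0.3 * 20 * 10, rel=0.35)

    def test_collapse_to_single_level_when_no_clustering(self):
        # tau ~ 0: MMI imputations should be distributionally
        # indistinguishable from SMI imputations of the same data
        mc = ModelConstants(beta_x1=0, beta_x2=0, beta_w1=0, beta_w2=0)
        scn = ScenarioConfig(
            J=20, cluster_size_spec=fixed_sizes(25), icc1=0.0, icc2=0.0,
            model_constants=mc, seed=13,
        )
        rng = np.random.default_rng(77)
        data = generate_trial(scn, scn.replicate_rng(0))
        y1 = data.y1.copy()
        y1[rng.random(data.n) < 0.3] = np.nan
        masked = TrialDataset(
            data.individual_id, data.cluster_id, data.arm, data.x, data.w,
            y1, data.y2, np.isnan(y1).astype(np.int8),
            np.zeros(data.n, np.int8),
        )
        mis = np.isnan(y1)
        s_smi = impute_smi(masked, 10, rng=np.random.default_rng(1))
        s_mmi = impute_mmi(
            masked, 10, control=GibbsControl(burn_in=100, thin=30),
            rng=np.random.default_rng(2),
        )
        # compare per-imputation means (imputations are the independent
        # units; cells within an imputation share parameter draws)
        a = np.array([c.y1[mis].mean() for c in s_smi.m_copies])
        b = np.array([c.y1[mis].mean() for c in s_mmi.m_copies])
        _, p = ttest_ind(a, b)
        assert p > 0.01

    def test_batched_engine_matches_sequential_distribution(self):
        # same data, sequential vs batched chains: pooled means and SDs of
        # the imputed cells must agree statistically
        _, masked = _masked_scenario(seed=5, J=8, nj=12)
        ctrl = GibbsControl(burn_in=100, thin=25)
        seq = impute_mmi(masked, 20, control=ctrl, rng=np.random.default_rng(3))
        (bat,) = impute_mmi_many(
            [masked], 20, control=ctrl, rng=np.random.default_rng(4)
        )
        bat.validate()
        mis = np.nonzero(masked.r1 == 1)[0]
        a = np.array([c.y1[mis] for c in seq.m_copies])
        b = np.array([c.y1[mis] for c in bat.m_copies])
        # cellwise means across imputations, compared in aggregate
        diff = a.mean(axis=0) - b.mean(axis=0)
        spread = np.sqrt(a.var(axis=0) / 20 + b.var(axis=0) / 20)
        frac_off = np.mean(np.abs(diff) > 3 * spread)
        assert frac_off < 0.05

    def test_gibbs_mean_matches_quadrature_oracle(self):
        """2 clusters, 6 observations, one missing value: the sampler's
        stationary mean must match direct numerical integration of the
        posterior predictive mean over the residual-covariance posterior
        (coefficients and cluster-effect covariance held fixed)."""
        y = np.array([
            [10.0, 5.0],
            [11.0, 5.5],
            [np.nan, 4.5],
            [14.0, 7.0],
            [13.0, 6.5],
            [12.5, 6.8],
        ])
        codes = np.array([0, 0, 0, 1, 1, 1])
        X = np.ones((6, 1))
        B_fix = np.array([[12.0, 6.0]])
        Phi_fix = np.array([[4.0, 1.0], [1.0, 2.25]])

        # --- oracle: integrate over Sigma = (s1, s2, r) on a grid
        prior_df, prior_scale = 2.0, np.eye(2)
        obs_idx = [0, 1, 3, 4, 5]  # rows fully observed
        # observed coordinates: all y-cells except y1 of row 2
        def post_parts(s1, s2, r):
            Sig = np.array([[s1 * s1, r * s1 * s2], [r * s1 * s2, s2 * s2]])
            # joint covariance of the 12-vector (row-major y11,y12,...)
            cov = np.zeros((12, 12))
            for i in range(6):
                for j in range(6):
                    if i == j:
                        cov[2 * i: 2 * i + 2, 2 * j: 2 * j + 2] = Sig + Phi_fix
                    elif codes[i] == codes[j]:
                        cov[2 * i: 2 * i + 2, 2 * j: 2 * j + 2] = Phi_fix
            mean = np.tile(B_fix[0], 6)
            keep = [k for k in range(12) if k != 4]  # drop missing y1 of row 2
            sub = cov[np.ix_(keep, keep)]
            yobs = np.delete(y.reshape(-1), 4)
            mobs = np.delete(mean, 4)
            loglik = multivariate_normal.logpdf(yobs, mobs, sub)
            # conditional mean of the missing coordinate
            c12 = cov[4, keep]
            cond_mean = mean[4] + c12 @ np.linalg.solve(sub, yobs - mobs)
            # inverse-Wishart(2, I) log-density (up to constant)
            sign, logdet = np.linalg.slogdet(Sig)
            lp = -0.5 * (prior_df + 3) * logdet - 0.5 * np.trace(
                np.linalg.solve(Sig, prior_scale)
            )
            # Jacobian of (s1, s2, r) -> (sig11, sig22, sig12): 4 s1^2 s2^2
            jac = math.log(4.0 * s1 * s1 * s2 * s2)
            return loglik + lp + jac, cond_mean

        s1g = np.linspace(0.4, 6.0, 48)
        s2g = np.linspace(0.3, 5.0, 48)
        rg = np.linspace(-0.92, 0.92, 24)
        logw, cm = [], []
        for s1 in s1g:
            for s2 in s2g:
                for r in rg:
                    lw, m = post_parts(s1, s2, r)
                    logw.append(lw)
                    cm.append(m)
        logw = np.array(logw)
        w = np.exp(logw - logw.max())
        oracle = float(np.average(np.array(cm), weights=w))

        # --- sampler with the same pieces fixed
        ctrl = GibbsControl(burn_in=300, thin=3, prior_df=2.0)
        completed, _, _ = _gibbs_arm(
            y.copy(), X, codes, 3000, ctrl, np.random.default_rng(42),
            fix_coef=B_fix, fix_raneff_cov=Phi_fix,
        )
        sampled = float(np.mean([c[2, 0] for c in completed]))
        assert sampled == pytest.approx(oracle, rel=0.02)
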