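"""Substantive-model estimation, Rubin's-rules pooling and net benefit.

The substantive model is the bivariate linear mixed model with treatment
as the only fixed effect,

    Y1_ijk = b10 + b1*k + u1_jk + e1_ijk
    Y2_ijk = b20 + b2*k + u2_jk + e2_ijk,

with common covariance structure across arms: individual-level residual
covariance Sigma (SDs sigma1, sigma2, correlation rho) and cluster-level
random-intercept covariance Phi (SDs tau1, tau2, correlation phi).

Because the fixed part is saturated in arm, the per-cluster marginal
covariance I (x) Sigma + J (x) Phi admits an exact spectral split into
the cluster-mean direction (covariance Sigma + n_j * Phi) and the n_j-1
within-cluster contrasts (covariance Sigma).  The log-likelihood is then
a function of cluster-level sufficient statistics only (sizes, cluster
means, pooled within-cluster cross-products), the fixed effects profile
out by generalised least squares, and the variance components are
optimised over (log-SD, arctanh-correlation) coordinates.  A restricted
(REML) correction is applied by default.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np
from scipy.optimize import minimize
from scipy.stats import norm

from .core_data import (
    DegenerateDataError,
    FitResult,
    PooledResult,
    TrialDataset,
)

__all__ = [
    "INBResult",
    "fit_bivariate_mixed",
    "loglikelihood",
    "rubin_pool",
    "make_ci",
    "inb",
]

_LOG2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# sufficient statistics


class _SuffStats:
    """Cluster-level sufficient statistics grouped by (arm, size)."""

    __slots__ = (
        "groups", "w_tot", "n", "n_clusters", "ybar_mean", "clusters_per_arm",
        "g_arm", "g_n", "g_cnt", "g_sy0", "g_sy1", "g_q00", "g_q01", "g_q11",
    )

    def __init__(self, data: TrialDataset):
        y = np.column_stack([data.y1, data.y2])
        if np.isnan(y).any():
            raise ValueError("the substantive model requires complete outcomes")
        # cluster codes by first appearance
        order_map: dict = {}
        for c in data.cluster_id:
            if c not in order_map:
                order_map[c] = len(order_map)
        codes = np.array([order_map[c] for c in data.cluster_id])
        J = len(order_map)
        srt = np.argsort(codes, kind="stable")
        ys, cs = y[srt], codes[srt]
        sizes = np.bincount(cs, minlength=J)
        starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
        sums = np.add.reduceat(ys, starts, axis=0)
        ybar = sums / sizes[:, None]
        arm_cl = np.zeros(J, dtype=int)
        arm_cl[codes] = data.arm
        self.clusters_per_arm = (
            int((arm_cl == 0).sum()), int((arm_cl == 1).sum())
        )
        # pooled within-cluster cross products
        dev = ys - ybar[cs]
        w_tot = dev.T @ dev
        # scalar sufficient statistics per (arm, size) group:
        # (count, sum ybar0, sum ybar1, sum y0y0, sum y0y1, sum y1y1)
        groups: dict = defaultdict(lambda: [0, 0.0, 0.0, 0.0, 0.0, 0.0])
        b0, b1 = ybar[:, 0], ybar[:, 1]
        for key in {(int(a), int(s)) for a, s in zip(arm_cl, sizes)}:
            sel = (arm_cl == key[0]) & (sizes == key[1])
            g0, g1 = b0[sel], b1[sel]
            groups[key] = (
                int(sel.sum()),
                float(g0.sum()),
                float(g1.sum()),
                float(g0 @ g0),
                float(g0 @ g1),
                float(g1 @ g1),
            )
        self.groups = dict(groups)
        # array form of the group statistics (for vectorised evaluation)
        keys = sorted(self.groups)
        self.g_arm = np.array([k for k, _ in keys], dtype=np.int64)
        self.g_n = np.array([s for _, s in keys], dtype=float)
        arr = np.array([self.groups[key] for key in keys], dtype=float)
        self.g_cnt = arr[:, 0]
        self.g_sy0 = arr[:, 1]
        self.g_sy1 = arr[:, 2]
        self.g_q00 = arr[:, 3]
        self.g_q01 = arr[:, 4]
        self.g_q11 = arr[:, 5]
        self.w_tot = w_tot
        self.n = int(sizes.sum())
        self.n_clusters = J
        self.ybar_mean = ybar.mean(axis=0)


def _nll(theta, st: _SuffStats, reml: bool, full: bool = True):
    """Negative log-likelihood (exact, with constants) profiled over the
    per-arm fixed-effect means; returns (nll, mu, F) where mu[k] is the
    GLS mean and F[k] the 2x2 information for arm k.  Pure scalar
    arithmetic: this sits in the optimizer's innermost loop."""
    ls1, ls2, zr, lt1, lt2, zp = theta
    s1, s2 = math.exp(ls1), math.exp(ls2)
    t1, t2 = math.exp(lt1), math.exp(lt2)
    rho, phi = math.tanh(zr), math.tanh(zp)
    sa, sb, sc = s1 * s1, rho * s1 * s2, s2 * s2
    pa, pb, pc = t1 * t1, phi * t1 * t2, t2 * t2
    det_s = sa * sc - sb * sb
    if det_s <= 0:
        return math.inf, None, None
    log_det_s = math.log(det_s)
    si_a, si_b, si_c = sc / det_s, -sb / det_s, sa / det_s

    # per (arm, n): G_n = Sigma + n Phi, A_n = n * G_n^{-1}; vectorised
    # over the (arm, size) groups of clusters
    nsz, cnt, arm = st.g_n, st.g_cnt, st.g_arm
    ga = sa + nsz * pa
    gb = sb + nsz * pb
    gc = sc + nsz * pc
    det_g = ga * gc - gb * gb
    if np.any(det_g <= 0):
        return math.inf, None, None
    r = nsz / det_g
    a00, a01, a11 = gc * r, -gb * r, ga * r
    f00 = np.bincount(arm, weights=cnt * a00, minlength=2)
    f01 = np.bincount(arm, weights=cnt * a01, minlength=2)
    f11 = np.bincount(arm, weights=cnt * a11, minlength=2)
    bv0 = np.bincount(arm, weights=a00 * st.g_sy0 + a01 * st.g_sy1, minlength=2)
    bv1 = np.bincount(arm, weights=a01 * st.g_sy0 + a11 * st.g_sy1, minlength=2)
    const = float(cnt @ ((nsz - 1.0) * log_det_s + np.log(det_g)))
    det_f = f00 * f11 - f01 * f01
    if np.any(det_f <= 0):
        return math.inf, None, None
    mu0 = (f11 * bv0 - f01 * bv1) / det_f  # per-arm GLS means, outcome 1
    mu1 = (f00 * bv1 - f01 * bv0) / det_f  # per-arm GLS means, outcome 2
    # quadratic forms
    m0, m1 = mu0[arm], mu1[arm]
    quad = (
        si_a * st.w_tot[0, 0] + 2.0 * si_b * st.w_tot[0, 1] + si_c * st.w_tot[1, 1]
    )
    quad += float(np.sum(
        a00 * st.g_q00 + 2.0 * a01 * st.g_q01 + a11 * st.g_q11
        - 2.0 * (m0 * (a00 * st.g_sy0 + a01 * st.g_sy1)
                 + m1 * (a01 * st.g_sy0 + a11 * st.g_sy1))
        + cnt * (a00 * m0 * m0 + 2.0 * a01 * m0 * m1 + a11 * m1 * m1)
    ))
    nll = 0.5 * (2.0 * st.n * _LOG2PI + const + quad)
    if reml:
        nll += 0.5 * float(np.sum(np.log(det_f))) - 2.0 * _LOG2PI
    if not full:
        return nll, None, None
    F = [
        np.array([[f00[0], f01[0]], [f01[0], f11[0]]]),
        np.array([[f00[1], f01[1]], [f01[1], f11[1]]]),
    ]
    return nll, [np.array([mu0[k], mu1[k]]) for k in (0, 1)], F


def _sym_sandwich(x00, x01, x11, y00, y01, y11):
    """Components of X Y X for symmetric 2x2 X, Y (result is symmetric)."""
    t00 = x00 * y00 + x01 * y01
    t01 = x00 * y01 + x01 * y11
    t10 = x01 * y00 + x11 * y01
    t11 = x01 * y01 + x11 * y11
    return (
        t00 * x00 + t01 * x01,
        t00 * x01 + t01 * x11,
        t10 * x01 + t11 * x11,
    )


def _tr2(x00, x01, x11, y00, y01, y11):
    """tr(X Y) for symmetric 2x2 matrices given componentwise."""
    return x00 * y00 + 2.0 * x01 * y01 + x11 * y11


def _nll_grad(theta, st: _SuffStats, reml: bool):
    """(nll, analytic gradient) of :func:`_nll` in the transformed
    coordinates, computed in one pass.  The fixed effects are profiled
    out, so by the envelope theorem their dependence on theta contributes
    nothing to the gradient."""
    ls1, ls2, zr, lt1, lt2, zp = theta
    s1, s2 = math.exp(ls1), math.exp(ls2)
    t1, t2 = math.exp(lt1), math.exp(lt2)
    rho, phi = math.tanh(zr), math.tanh(zp)
    sa, sb, sc = s1 * s1, rho * s1 * s2, s2 * s2
    pa, pb, pc = t1 * t1, phi * t1 * t2, t2 * t2
    det_s = sa * sc - sb * sb
    if det_s <= 0:
        return math.inf, np.zeros(6)
    si = (sc / det_s, -sb / det_s, sa / det_s)

    nsz, cnt, arm = st.g_n, st.g_cnt, st.g_arm
    ga = sa + nsz * pa
    gb = sb + nsz * pb
    gc = sc + nsz * pc
    det_g = ga * gc - gb * gb
    if np.any(det_g <= 0):
        return math.inf, np.zeros(6)
    gi00, gi01, gi11 = gc / det_g, -gb / det_g, ga / det_g
    a00, a01, a11 = nsz * gi00, nsz * gi01, nsz * gi11
    f00 = np.bincount(arm, weights=cnt * a00, minlength=2)
    f01 = np.bincount(arm, weights=cnt * a01, minlength=2)
    f11 = np.bincount(arm, weights=cnt * a11, minlength=2)
    bv0 = np.bincount(arm, weights=a00 * st.g_sy0 + a01 * st.g_sy1, minlength=2)
    bv1 = np.bincount(arm, weights=a01 * st.g_sy0 + a11 * st.g_sy1, minlength=2)
    f_det = f00 * f11 - f01 * f01
    if np.any(f_det <= 0):
        return math.inf, np.zeros(6)
    mu0 = (f11 * bv0 - f01 * bv1) / f_det
    mu1 = (f00 * bv1 - f01 * bv0) / f_det
    m0, m1 = mu0[arm], mu1[arm]
    mm00 = st.g_q00 - 2.0 * st.g_sy0 * m0 + cnt * m0 * m0
    mm01 = st.g_q01 - st.g_sy0 * m1 - st.g_sy1 * m0 + cnt * m0 * m1
    mm11 = st.g_q11 - 2.0 * st.g_sy1 * m1 + cnt * m1 * m1

    # nll itself
    log_det_s = math.log(det_s)
    const = float(cnt @ ((nsz - 1.0) * log_det_s + np.log(det_g)))
    quad = (
        si[0] * st.w_tot[0, 0] + 2.0 * si[1] * st.w_tot[0, 1]
        + si[2] * st.w_tot[1, 1]
    )
    quad += float(np.sum(a00 * mm00 + 2.0 * a01 * mm01 + a11 * mm11))
    nll = 0.5 * (2.0 * st.n * _LOG2PI + const + quad)
    if reml:
        nll += 0.5 * float(np.sum(np.log(f_det))) - 2.0 * _LOG2PI

    # dSigma/dtheta_i and dPhi/dtheta_i, componentwise (00, 01, 11)
    d_sig = [
        (2.0 * sa, sb, 0.0),
        (0.0, sb, 2.0 * sc),
        (0.0, (1.0 - rho * rho) * s1 * s2, 0.0),
    ]
    d_phi = [
        (2.0 * pa, pb, 0.0),
        (0.0, pb, 2.0 * pc),
        (0.0, (1.0 - phi * phi) * t1 * t2, 0.0),
    ]

    w00, w01, w11 = st.w_tot[0, 0], st.w_tot[0, 1], st.w_tot[1, 1]
    n_minus_j = st.n - st.n_clusters
    grad = [0.0] * 6
    # Sigma-only block: (n - J) log|Sigma| + tr(Sigma^-1 W)
    for i, ds in enumerate(d_sig):
        csig = _sym_sandwich(*si, *ds)
        grad[i] += 0.5 * (
            n_minus_j * _tr2(*si, *ds) - _tr2(*csig, w00, w01, w11)
        )

    fi00 = f11 / f_det
    fi01 = -f01 / f_det
    fi11 = f00 / f_det
    kf00, kf01, kf11 = fi00[arm], fi01[arm], fi11[arm]
    # all six parameter directions at once: dG is (6, G)
    ones = np.ones_like(nsz)
    dg00 = np.stack([d_sig[0][0] * ones, d_sig[1][0] * ones, d_sig[2][0] * ones,
                     d_phi[0][0] * nsz, d_phi[1][0] * nsz, d_phi[2][0] * nsz])
    dg01 = np.stack([d_sig[0][1] * ones, d_sig[1][1] * ones, d_sig[2][1] * ones,
                     d_phi[0][1] * nsz, d_phi[1][1] * nsz, d_phi[2][1] * nsz])
    dg11 = np.stack([d_sig[0][2] * ones, d_sig[1][2] * ones, d_sig[2][2] * ones,
                     d_phi[0][2] * nsz, d_phi[1][2] * nsz, d_phi[2][2] * nsz])
    c00, c01, c11 = _sym_sandwich(gi00, gi01, gi11, dg00, dg01, dg11)
    term = (
        cnt * _tr2(gi00, gi01, gi11, dg00, dg01, dg11)
        - nsz * _tr2(c00, c01, c11, mm00, mm01, mm11)
    )
    if reml:
        term = term - cnt * nsz * _tr2(kf00, kf01, kf11, c00, c01, c11)
    return nll, np.asarray(grad) + 0.5 * term.sum(axis=1)


def loglikelihood(
    data: TrialDataset,
    intercepts: tuple,
    effects: tuple,
    varcomp: tuple,
) -> float:
    """Exact Gaussian log-likelihood of the substantive model at given
    parameters (no profiling; used for validation against direct
    multivariate-normal evaluation).

    ``varcomp`` is (sigma1, sigma2, rho, tau1, tau2, phi).
    """
    s1, s2, rho, t1, t2, phi = varcomp
    st = _SuffStats(data)
    sa, sb, sc = s1 * s1, rho * s1 * s2, s2 * s2
    pa, pb, pc = t1 * t1, phi * t1 * t2, t2 * t2
    det_s = sa * sc - sb * sb
    si = np.array([[sc, -sb], [-sb, sa]]) / det_s
    total = -st.n * _LOG2PI
    quad = float(np.einsum("ij,ij->", si, st.w_tot))
    const = 0.0
    mu_arm = {
        k: np.array([intercepts[0] + effects[0] * k, intercepts[1] + effects[1] * k])
        for k in (0, 1)
    }
    for (k, nsz), (cnt, sy0, sy1, q00, q01, q11) in st.groups.items():
        ga, gb, gc = sa + nsz * pa, sb + nsz * pb, sc + nsz * pc
        det_g = ga * gc - gb * gb
        r = nsz / det_g
        a00, a01, a11 = gc * r, -gb * r, ga * r
        m0, m1 = mu_arm[k]
        const += cnt * ((nsz - 1) * math.log(det_s) + math.log(det_g))
        quad += (
            a00 * q00 + 2.0 * a01 * q01 + a11 * q11
            - 2.0 * (m0 * (a00 * sy0 + a01 * sy1) + m1 * (a01 * sy0 + a11 * sy1))
            + cnt * (a00 * m0 * m0 + 2.0 * a01 * m0 * m1 + a11 * m1 * m1)
        )
    return total - 0.5 * (const + quad)


def _start_values(st: _SuffStats) -> np.ndarray:
    """Moment-based starting point for the variance-component search."""
    n, J = st.n, st.n_clusters
    w_var = np.diag(st.w_tot) / max(n - J, 1)
    w_cov = st.w_tot[0, 1] / max(n - J, 1)
    # between-cluster moments of the cluster means around group means
    bvar = np.zeros(2)
    bcov = 0.0
    nbar = n / J
    cnt_tot = 0
    for (_k, _nsz), (cnt, sy0, sy1, q00, q01, q11) in st.groups.items():
        bvar[0] += q00 - sy0 * sy0 / cnt
        bvar[1] += q11 - sy1 * sy1 / cnt
        bcov += q01 - sy0 * sy1 / cnt
        cnt_tot += cnt
    bvar /= max(cnt_tot - 2, 1)
    bcov /= max(cnt_tot - 2, 1)
    # degenerate data (zero within- or between-cluster spread) still needs
    # a finite interior starting point
    scale = max(float(bvar.max()), float(w_var.max()), 1e-6)
    w_var = np.maximum(w_var, 1e-4 * scale)
    tau_sq = np.maximum(bvar - w_var / nbar, 1e-4 * scale)
    s1, s2 = math.sqrt(w_var[0]), math.sqrt(w_var[1])
    rho = min(max(w_cov / (s1 * s2), -0.95), 0.95)
    t1, t2 = math.sqrt(tau_sq[0]), math.sqrt(tau_sq[1])
    phi = min(max(bcov / max(t1 * t2, 1e-12), -0.9), 0.9)
    return np.array(
        [
            math.log(s1),
            math.log(s2),
            math.atanh(rho),
            math.log(t1),
            math.log(t2),
            math.atanh(phi),
        ]
    )


def fit_bivariate_mixed(
    data: TrialDataset,
    reml: bool = True,
    max_restarts: int = 3,
    start: tuple | None = None,
) -> FitResult:
    """Fit the bivariate random-intercept model to complete data.

    Treatment effects and intercepts are profiled out by GLS at every
    variance-parameter value; the variance components are estimated by
    (restricted) maximum likelihood over log-SD / arctanh-correlation
    coordinates with L-BFGS-B and jittered restarts on failure.
    ``vcov_treat`` is the GLS covariance of the two treatment effects at
    the optimum.  ``start`` optionally warm-starts the search from a
    previous fit's ``varcomp`` (useful across imputed copies of the same
    dataset); moment-based starting values are used otherwise.
    """
    st = _SuffStats(data)
    for k in (0, 1):
        if st.clusters_per_arm[k] < 2:
            raise DegenerateDataError(f"arm {k} has fewer than 2 clusters")
    # correlations bounded at tanh(4.5) ~ 0.99975: close enough to the
    # boundary for degenerate data while keeping the objective well
    # conditioned near |corr| -> 1
    bounds = [
        (-20.0, 30.0),
        (-20.0, 30.0),
        (-4.5, 4.5),
        (-20.0, 30.0),
        (-20.0, 30.0),
        (-4.5, 4.5),
    ]

    def objective(theta):
        return _nll_grad(theta, st, reml)

    if start is not None:
        s1, s2, rho, t1, t2, phi = start
        # correlations clamped well inside the boundary: atanh explodes
        # near +/-1 and leaves the optimizer in a flat region
        x0 = np.array([
            math.log(max(s1, 1e-8)),
            math.log(max(s2, 1e-8)),
            math.atanh(min(max(rho, -0.99), 0.99)),
            math.log(max(t1, 1e-8)),
            math.log(max(t2, 1e-8)),
            math.atanh(min(max(phi, -0.99), 0.99)),
        ])
    else:
        x0 = _start_values(st)
    best = None
    rng = np.random.default_rng(0)  # jitter only; fit is deterministic in data
    for attempt in range(max_restarts + 1):
        start = x0 if attempt == 0 else x0 + rng.normal(scale=0.3, size=6)
        start = np.clip(start, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(
            objective,
            start,
            method="L-BFGS-B",
            jac=True,
            bounds=bounds,
            options={"maxiter": 500, "ftol": 1e-9, "gtol": 1e-6},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if best is not None and np.isfinite(best.fun) and best.success:
            break
    converged = bool(best.success and np.isfinite(best.fun))
    nll, mu, F = _nll(best.x, st, reml)
    if mu is None:
        return FitResult(
            beta1_hat=math.nan,
            beta2_hat=math.nan,
            intercept1=math.nan,
            intercept2=math.nan,
            vcov_treat=np.full((2, 2), math.nan),
            varcomp=(math.nan,) * 6,
            n_used=st.n,
            converged=False,
        )
    ls1, ls2, zr, lt1, lt2, zp = best.x
    varcomp = (
        math.exp(ls1),
        math.exp(ls2),
        math.tanh(zr),
        math.exp(lt1),
        math.exp(lt2),
        math.tanh(zp),
    )
    F0_inv = np.linalg.inv(F[0])
    F1_inv = np.linalg.inv(F[1])
    vcov_treat = F0_inv + F1_inv
    return FitResult(
        beta1_hat=float(mu[1][0] - mu[0][0]),
        beta2_hat=float(mu[1][1] - mu[0][1]),
        intercept1=float(mu[0][0]),
        intercept2=float(mu[0][1]),
        vcov_treat=vcov_treat,
        varcomp=varcomp,
        n_used=st.n,
        converged=converged,
        loglik=-nll,
    )


# ---------------------------------------------------------------------------
# pooling and net benefit


def rubin_pool(fits, estimand: str, level: float = 0.95) -> PooledResult:
    """Combine M completed-data fits by Rubin's rules.

    Pooled point estimate is the mean of the per-imputation estimates;
    total variance T = W + (1 + 1/M) B with W the mean within-imputation
    variance and B the between-imputation sample variance (denominator
    M - 1).  The CI is normal-based.
    """
    fits = [f for f in fits]
    M = len(fits)
    if M < 2:
        raise ValueError("Rubin pooling needs at least M = 2 fits")
    est = np.array([f.estimate(estimand) for f in fits])
    var = np.array([f.se(estimand) ** 2 for f in fits])
    q_bar = float(est.mean())
    w_within = float(var.mean())
    b_between = float(est.var(ddof=1))
    t_total = w_within + (1.0 + 1.0 / M) * b_between
    pooled = PooledResult(
        q_bar=q_bar,
        w_within=w_within,
        b_between=b_between,
        t_total=t_total,
        ci_low=math.nan,
        ci_high=math.nan,
        level=level,
        M=M,
    )
    return make_ci(pooled, level)


def make_ci(pooled: PooledResult, level: float = 0.95) -> PooledResult:
    """Normal-based interval Q_bar +/- z * sqrt(T) at the given level."""
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie strictly in (0, 1)")
    z = norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(pooled.t_total)
    pooled.ci_low = pooled.q_bar - half
    pooled.ci_high = pooled.q_bar + half
    pooled.level = level
    return pooled


class INBResult:
    """Incremental net monetary benefit at one willingness-to-pay."""

    def __init__(self, lam: float, inb_hat: float, inb_se: float, level: float):
        self.lam = lam
        self.inb_hat = inb_hat
        self.inb_se = inb_se
        self.level = level
        z = norm.ppf(0.5 + level / 2.0)
        self.ci = (inb_hat - z * inb_se, inb_hat + z * inb_se)

    def __repr__(self):
        return (
            f"INBResult(lambda={self.lam:g}, inb={self.inb_hat:.2f}, "
            f"se={self.inb_se:.2f}, ci={self.ci[0]:.2f}..{self.ci[1]:.2f})"
        )


def inb(
    delta_q: float,
    delta_c: float,
    vcov: np.ndarray,
    lam: float,
    level: float = 0.95,
) -> INBResult:
    """Incremental net benefit INB(lambda) = lambda*delta_Q - delta_C.

    ``vcov`` is the 2x2 covariance of (delta_C, delta_Q); the variance is
    lambda^2 var(dQ) + var(dC) - 2 lambda cov(dC, dQ).
    """
    if lam < 0:
        raise ValueError("willingness-to-pay must be non-negative")
    vcov = np.asarray(vcov, dtype=float)
    variance = (
        lam * lam * vcov[1, 1] + vcov[0, 0] - 2.0 * lam * vcov[0, 1]
    )
    if variance < 0:
        raise ValueError("inconsistent covariance matrix yields negative variance")
    return INBResult(lam, lam * delta_q - delta_c, math.sqrt(variance), level)
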