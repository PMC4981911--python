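"""Multiple-imputation engines for bivariate outcomes in clustered trials.

Three engines, all fitted separately within each treatment arm and all
*proper* (parameters are drawn from their posterior before outcomes are
drawn from the predictive):

* :func:`impute_smi` — single-level bivariate normal regression on the
  auxiliary covariates, ignoring the cluster structure;
* :func:`impute_fmi` — as SMI but with a fixed (dummy-coded) effect for
  every cluster except a reference cluster chosen nearest the arm mean;
  cluster-level covariates are inadmissible in this design;
* :func:`impute_mmi` — a bivariate random-intercept joint model sampled
  with a Gibbs chain (data augmentation over the missing outcomes,
  inverse-Wishart full conditionals for both covariance matrices).

Because both outcomes are Gaussian, chained-equations cycling and joint
multivariate-normal sampling coincide; SMI/FMI therefore use the exact
conjugate matrix-normal/inverse-Wishart draw directly (the ``cycles``
argument is accepted for interface compatibility and has no effect on
the sampled distribution).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import qr as _qr

from ._bivariate import (
    chol2,
    chol2s,
    chol2s_vec,
    conditional_impute,
    draw_invwishart2,
    draw_invwishart2s,
    draw_invwishart2s_vec,
    inv2s,
    inv2s_vec,
)
from .core_data import ImputedStack, TrialDataset

__all__ = [
    "PosteriorDraw",
    "GibbsControl",
    "InsufficientDataError",
    "CollinearDesignError",
    "SamplerError",
    "draw_regression_posterior",
    "choose_reference_cluster",
    "impute_smi",
    "impute_fmi",
    "impute_mmi",
]


class InsufficientDataError(ValueError):
    """Too few complete rows to form a proper posterior."""


class CollinearDesignError(ValueError):
    """The design matrix is rank deficient."""


class SamplerError(RuntimeError):
    """The Gibbs chain produced a non-finite draw."""


@dataclass
class PosteriorDraw:
    """One draw from a multivariate-regression posterior."""

    coef: np.ndarray  # (p, 2)
    resid_cov: np.ndarray  # 2x2
    raneff_cov: np.ndarray | None = None  # 2x2, multilevel engine only
    cluster_effects: np.ndarray | None = None  # (J, 2), multilevel engine only


@dataclass(frozen=True)
class GibbsControl:
    """Chain settings for the multilevel engine.

    Defaults follow common practice for this model class: a 1000-iteration
    burn-in with imputations retained every 1000 iterations, and diffuse
    inverse-Wishart(df=2, identity) priors on both covariance matrices.
    With very few clusters per arm (<= 5) a burn-in of 5000 is
    recommended, as the chain mixes slowly when the cluster effects are
    weakly identified.
    """

    burn_in: int = 1000
    thin: int = 1000
    prior_df: float = 2.0
    prior_scale: np.ndarray | None = None  # default: identity

    def __post_init__(self):
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.prior_df < 2:
            raise ValueError("prior_df must be >= dimension (2)")

    def scale(self) -> np.ndarray:
        return np.eye(2) if self.prior_scale is None else np.asarray(self.prior_scale)


def draw_regression_posterior(
    y_obs: np.ndarray,
    design: np.ndarray,
    rng: np.random.Generator,
) -> PosteriorDraw:
    """Exact conjugate draw for the bivariate normal regression.

    Under the Jeffreys-style prior (flat on the coefficient matrix,
    |Sigma|^{-3/2}), the posterior is Sigma ~ IW(n - p, S) with S the
    residual cross-product matrix, and coef | Sigma matrix-normal around
    the least-squares solution with row covariance (X'X)^{-1}.
    """
    y_obs = np.asarray(y_obs, dtype=float)
    X = np.asarray(design, dtype=float)
    n, p = X.shape
    if y_obs.shape != (n, 2):
        raise ValueError("y_obs must be n x 2 and aligned with the design")
    if n <= p + 2:
        raise InsufficientDataError(
            f"need more than p + 2 = {p + 2} complete rows, got {n}"
        )
    R = _qr(X, mode="r")[0][:p, :p]
    r_diag = np.abs(np.diag(R))
    tol = 1e-8 * max(float(r_diag.max()), 1.0)
    if (r_diag < tol).any():
        bad = np.nonzero(r_diag < tol)[0].tolist()
        raise CollinearDesignError(f"design is rank deficient near columns {bad}")
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    bhat = xtx_inv @ (X.T @ y_obs)
    resid = y_obs - X @ bhat
    S = resid.T @ resid
    sigma = draw_invwishart2(n - p, S, rng)
    Lx = np.linalg.cholesky(xtx_inv)
    coef = bhat + Lx @ rng.standard_normal((p, 2)) @ chol2(sigma).T
    return PosteriorDraw(coef=coef, resid_cov=sigma)


# ---------------------------------------------------------------------------
# shared per-arm plumbing


def _arm_view(data: TrialDataset, k: int) -> np.ndarray:
    return np.nonzero(data.arm == k)[0]


def _cluster_codes(cluster_id: np.ndarray):
    """Integer codes by first appearance, plus ordered labels."""
    order: dict = {}
    for c in cluster_id:
        if c not in order:
            order[c] = len(order)
    codes = np.array([order[c] for c in cluster_id], dtype=np.int64)
    return codes, list(order)


def _pattern_indices(y: np.ndarray):
    m1 = np.isnan(y[:, 0])
    m2 = np.isnan(y[:, 1])
    return (
        np.nonzero(m1 & m2)[0],
        np.nonzero(m1 & ~m2)[0],
        np.nonzero(~m1 & m2)[0],
        np.nonzero(~m1 & ~m2)[0],
    )


def choose_reference_cluster(
    data_arm: TrialDataset,
    outcome: int | None = None,
    candidates: Sequence | None = None,
):
    """Cluster whose observed-outcome mean is nearest the arm mean.

    With ``outcome`` in {1, 2} the distance is |cluster mean - arm mean|
    for that outcome; with ``outcome=None`` the two distances are
    standardised by the arm-level observed SDs and summed.  Ties go to
    the first-appearing cluster.  ``candidates`` optionally restricts the
    clusters considered (labels).
    """
    codes, labels = _cluster_codes(data_arm.cluster_id)
    outcomes = (1, 2) if outcome is None else (outcome,)
    dist = np.zeros(len(labels))
    any_obs = np.zeros(len(labels), dtype=bool)
    for ell in outcomes:
        y = data_arm.y1 if ell == 1 else data_arm.y2
        obs = ~np.isnan(y)
        if not obs.any():
            raise InsufficientDataError(f"no observed values of y{ell} in this arm")
        arm_mean = float(y[obs].mean())
        sd = float(y[obs].std()) or 1.0
        for j, lab in enumerate(labels):
            sel = obs & (codes == j)
            if sel.any():
                any_obs[j] = True
                dist[j] += abs(float(y[sel].mean()) - arm_mean) / sd
            else:
                dist[j] += np.inf
    if candidates is not None:
        allowed = np.array([lab in set(candidates) for lab in labels])
    else:
        allowed = np.ones(len(labels), dtype=bool)
    allowed &= any_obs
    if not allowed.any():
        raise InsufficientDataError("no cluster with observed outcomes to reference")
    dist = np.where(allowed, dist, np.inf)
    return labels[int(np.argmin(dist))]  # argmin takes first minimum: tie rule


def _impute_single_level(
    data: TrialDataset,
    M: int,
    rng: np.random.Generator,
    method_tag: str,
    design_builder,
) -> ImputedStack:
    """Common SMI/FMI loop: per-arm conjugate draws + predictive fills."""
    y_full = np.column_stack([data.y1, data.y2])
    copies = [y_full.copy() for _ in range(M)]
    arm_streams = rng.spawn(2)
    for k in (0, 1):
        idx = _arm_view(data, k)
        y = y_full[idx]
        X = design_builder(data, idx)
        both, only1, only2, complete = _pattern_indices(y)
        n_missing = both.size + only1.size + only2.size
        if n_missing == 0:
            continue
        Xc, yc = X[complete], y[complete]
        imp_streams = arm_streams[k].spawn(M)
        for m in range(M):
            draw = draw_regression_posterior(yc, Xc, imp_streams[m])
            mu = X @ draw.coef
            ym = y.copy()
            conditional_impute(
                ym, mu, draw.resid_cov, both, only1, only2, imp_streams[m]
            )
            copies[m][idx] = ym
    stack = ImputedStack(
        m_copies=[data.copy_with_outcomes(c[:, 0], c[:, 1]) for c in copies],
        source=data,
        method_tag=method_tag,
        M=M,
    )
    return stack


def _smi_design(aux: Sequence[str]):
    def build(data: TrialDataset, idx: np.ndarray) -> np.ndarray:
        cols = [np.ones(idx.size)]
        for name in aux:
            cols.append(getattr(data, name)[idx])
        return np.column_stack(cols)

    return build


def impute_smi(
    data: TrialDataset,
    M: int,
    aux: Sequence[str] = ("x", "w"),
    rng: np.random.Generator | None = None,
    cycles: int = 10,
) -> ImputedStack:
    """Single-level multiple imputation ignoring the cluster structure."""
    if rng is None:
        rng = np.random.default_rng()
    return _impute_single_level(data, M, rng, "SMI", _smi_design(aux))


def _fmi_design(aux: Sequence[str]):
    if "w" in aux:
        raise ValueError(
            "cluster-level covariates cannot enter a fixed-cluster-effects design"
        )

    def build(data: TrialDataset, idx: np.ndarray) -> np.ndarray:
        sub_ids = data.cluster_id[idx]
        codes, labels = _cluster_codes(sub_ids)
        y = np.column_stack([data.y1[idx], data.y2[idx]])
        complete = ~np.isnan(y).any(axis=1)
        with_complete = [lab for j, lab in enumerate(labels)
                         if complete[codes == j].any()]
        if len(with_complete) == 0:
            raise InsufficientDataError("no cluster has complete rows in this arm")
        arm_ds = TrialDataset(
            individual_id=data.individual_id[idx],
            cluster_id=sub_ids,
            arm=data.arm[idx],
            x=data.x[idx],
            w=data.w[idx],
            y1=data.y1[idx],
            y2=data.y2[idx],
            r1=data.r1[idx],
            r2=data.r2[idx],
        )
        ref = choose_reference_cluster(arm_ds, candidates=with_complete)
        cols = [np.ones(idx.size)]
        for name in aux:
            cols.append(getattr(data, name)[idx])
        # indicator per non-reference cluster having complete rows; empty
        # clusters get no indicator and inherit the reference distribution
        for lab in with_complete:
            if lab == ref:
                continue
            cols.append((sub_ids == lab).astype(float))
        return np.column_stack(cols)

    return build


def impute_fmi(
    data: TrialDataset,
    M: int,
    aux: Sequence[str] = ("x",),
    rng: np.random.Generator | None = None,
    cycles: int = 10,
) -> ImputedStack:
    """Fixed-cluster-effects multiple imputation.

    The per-arm design adds an indicator column for every cluster with
    observed (complete) rows except the reference cluster, which is the
    one whose observed mean lies nearest the arm mean; clusters with no
    observed rows are imputed from the reference cluster's distribution.
    Only individual-level auxiliaries are admissible.
    """
    if rng is None:
        rng = np.random.default_rng()
    for k in (0, 1):
        if len(set(data.cluster_id[data.arm == k])) < 2:
            raise InsufficientDataError("fixed-effects MI needs >= 2 clusters per arm")
    return _impute_single_level(data, M, rng, "FMI", _fmi_design(aux))


# ---------------------------------------------------------------------------
# multilevel engine


def _gibbs_arm(
    y: np.ndarray,
    X: np.ndarray,
    codes: np.ndarray,
    M: int,
    control: GibbsControl,
    rng: np.random.Generator,
    fix_coef: np.ndarray | None = None,
    fix_raneff_cov: np.ndarray | None = None,
    collect_params: bool = False,
):
    """Gibbs chain for one arm's bivariate random-intercept model.

    ``y`` is n x 2 with NaN for missing cells; ``codes`` are contiguous
    cluster codes 0..J-1.  Returns (list of M completed y matrices,
    list of retained PosteriorDraw if requested, diagnostic trace).
    ``fix_coef``/``fix_raneff_cov`` pin the coefficient matrix or the
    cluster-effect covariance (validation and diagnostics only).
    """
    n, p = X.shape
    J = int(codes.max()) + 1
    order = np.argsort(codes, kind="stable")
    inv_order = np.empty_like(order)
    inv_order[order] = np.arange(n)
    yo = y[order].copy()
    Xo = X[order]
    co = codes[order]
    sizes = np.bincount(co, minlength=J)
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]])
    both, only1, only2, _complete = _pattern_indices(yo)
    n_both, n_only1, n_only2 = both.size, only1.size, only2.size

    # --- initial values: column-mean fill, OLS, moment covariances
    col_mean = np.nanmean(yo, axis=0)
    yw = yo.copy()
    for ell in (0, 1):
        col = yw[:, ell]
        col[np.isnan(col)] = col_mean[ell]
    xtx_inv = np.linalg.inv(Xo.T @ Xo)
    Lx = np.linalg.cholesky(xtx_inv)
    B = fix_coef.copy() if fix_coef is not None else xtx_inv @ (Xo.T @ yw)
    resid = yw - Xo @ B
    s_init = np.cov(resid.T) + 1e-6 * np.eye(2)
    sa, sb, sc = s_init[0, 0], s_init[0, 1], s_init[1, 1]
    cl_means = np.add.reduceat(resid, starts, axis=0) / sizes[:, None]
    if fix_raneff_cov is not None:
        pa, pb, pc = (fix_raneff_cov[0, 0], fix_raneff_cov[0, 1],
                      fix_raneff_cov[1, 1])
    else:
        p_init = np.atleast_2d(np.cov(cl_means.T)) + 1e-3 * np.eye(2)
        pa, pb, pc = p_init[0, 0], p_init[0, 1], p_init[1, 1]
    u = np.zeros((J, 2))

    nu0 = control.prior_df
    S0 = control.scale()
    q0a, q0b, q0c = S0[0, 0], S0[0, 1], S0[1, 1]
    size_groups = [
        (int(nsz), np.nonzero(sizes == nsz)[0]) for nsz in np.unique(sizes)
    ]
    completed: list = []
    retained_draws: list = []
    trace: list = []
    XB = Xo @ B

    total_iter = control.burn_in + (M - 1) * control.thin + 1
    retain_at = {control.burn_in + m * control.thin for m in range(M)}
    for it in range(total_iter):
        # (a) cluster effects from their MVN full conditionals
        si_a, si_b, si_c = inv2s(sa, sb, sc)
        pi_a, pi_b, pi_c = inv2s(pa, pb, pc)
        resid = yw - XB
        s_j = np.add.reduceat(resid, starts, axis=0)
        s0, s1 = s_j[:, 0], s_j[:, 1]
        for nsz, grp in size_groups:
            va, vb, vc = inv2s(
                nsz * si_a + pi_a, nsz * si_b + pi_b, nsz * si_c + pi_c
            )
            # M = V @ Sigma^{-1}
            m00 = va * si_a + vb * si_b
            m01 = va * si_b + vb * si_c
            m10 = vb * si_a + vc * si_b
            m11 = vb * si_b + vc * si_c
            l11, l21, l22 = chol2s(va, vb, vc)
            z = rng.standard_normal((grp.size, 2))
            g0, g1 = s0[grp], s1[grp]
            u[grp, 0] = m00 * g0 + m01 * g1 + l11 * z[:, 0]
            u[grp, 1] = m10 * g0 + m11 * g1 + l21 * z[:, 0] + l22 * z[:, 1]
        # (b) cluster-effect covariance from its inverse-Wishart conditional
        u0, u1 = u[:, 0], u[:, 1]
        if fix_raneff_cov is None:
            pa, pb, pc = draw_invwishart2s(
                nu0 + J,
                q0a + u0 @ u0,
                q0b + u0 @ u1,
                q0c + u1 @ u1,
                rng,
            )
        # (c) residual covariance from its inverse-Wishart conditional
        e = resid - u[co]
        e0, e1 = e[:, 0], e[:, 1]
        sa, sb, sc = draw_invwishart2s(
            nu0 + n, q0a + e0 @ e0, q0b + e0 @ e1, q0c + e1 @ e1, rng
        )
        if not (
            math.isfinite(sa) and math.isfinite(sc) and math.isfinite(pa)
            and math.isfinite(pc)
        ):
            raise SamplerError(f"non-finite covariance draw at iteration {it}")
        cl11, cl21, cl22 = chol2s(sa, sb, sc)
        # (d) coefficients from their matrix-normal conditional
        if fix_coef is None:
            ydag = yw - u[co]
            bhat = xtx_inv @ (Xo.T @ ydag)
            z = Lx @ rng.standard_normal((p, 2))
            B = bhat + np.column_stack(
                [cl11 * z[:, 0], cl21 * z[:, 0] + cl22 * z[:, 1]]
            )
            XB = Xo @ B
        # (e) missing outcomes from their conditional normals
        mu = XB + u[co]
        if n_both:
            z = rng.standard_normal((n_both, 2))
            yw[both, 0] = mu[both, 0] + cl11 * z[:, 0]
            yw[both, 1] = mu[both, 1] + cl21 * z[:, 0] + cl22 * z[:, 1]
        if n_only1:
            slope = sb / sc
            sd = math.sqrt(max(sa - sb * sb / sc, 0.0))
            yw[only1, 0] = (
                mu[only1, 0]
                + slope * (yw[only1, 1] - mu[only1, 1])
                + sd * rng.standard_normal(n_only1)
            )
        if n_only2:
            slope = sb / sa
            sd = math.sqrt(max(sc - sb * sb / sa, 0.0))
            yw[only2, 1] = (
                mu[only2, 1]
                + slope * (yw[only2, 0] - mu[only2, 0])
                + sd * rng.standard_normal(n_only2)
            )
        if collect_params:
            trace.append((sa, sc, sb, pa, pc, pb))
        if it in retain_at:
            completed.append(yw[inv_order].copy())
            retained_draws.append(
                PosteriorDraw(
                    coef=B.copy(),
                    resid_cov=np.array([[sa, sb], [sb, sc]]),
                    raneff_cov=np.array([[pa, pb], [pb, pc]]),
                    cluster_effects=u.copy(),
                )
            )
    return completed, retained_draws, np.asarray(trace)


def impute_mmi(
    data: TrialDataset,
    M: int,
    aux: Sequence[str] = ("x", "w"),
    control: GibbsControl | None = None,
    rng: np.random.Generator | None = None,
    fix_coef=None,
    fix_raneff_cov=None,
    return_draws: bool = False,
):
    """Multilevel multiple imputation via a bivariate random-intercept
    joint model, one Gibbs chain per treatment arm.

    The chain cycles: cluster effects -> cluster-effect covariance (IW)
    -> residual covariance (IW) -> coefficients (matrix normal) ->
    missing outcomes (conditional normals), retaining a completed
    dataset after ``burn_in`` iterations and every ``thin`` thereafter.
    """
    if rng is None:
        rng = np.random.default_rng()
    if control is None:
        control = GibbsControl()
    if M >= 1 and control.burn_in + (M - 1) * control.thin > 50_000_000:
        raise ValueError("requested chain length is unreasonably large")
    y_full = np.column_stack([data.y1, data.y2])
    copies = [y_full.copy() for _ in range(M)]
    draws: list = []
    arm_streams = rng.spawn(2)
    for k in (0, 1):
        idx = _arm_view(data, k)
        codes, _ = _cluster_codes(data.cluster_id[idx])
        if codes.max() + 1 < 2:
            raise InsufficientDataError("multilevel MI needs >= 2 clusters per arm")
        cols = [np.ones(idx.size)]
        for name in aux:
            cols.append(getattr(data, name)[idx])
        X = np.column_stack(cols)
        completed, arm_draws, _ = _gibbs_arm(
            y_full[idx],
            X,
            codes,
            M,
            control,
            arm_streams[k],
            fix_coef=fix_coef,
            fix_raneff_cov=fix_raneff_cov,
        )
        for m in range(M):
            copies[m][idx] = completed[m]
        draws.append(arm_draws)
    stack = ImputedStack(
        m_copies=[data.copy_with_outcomes(c[:, 0], c[:, 1]) for c in copies],
        source=data,
        method_tag="MMI",
        M=M,
    )
    if return_draws:
        return stack, draws
    return stack


# ---------------------------------------------------------------------------
# batched multilevel engine (many replicate datasets at once)


def _gibbs_arm_batched(
    Y: np.ndarray,
    Xf: np.ndarray,
    valid: np.ndarray,
    sizes: np.ndarray,
    n_max: int,
    M: int,
    control: GibbsControl,
    rng: np.random.Generator,
):
    """Batched version of :func:`_gibbs_arm` over a leading replicate axis.

    ``Y`` is (N, R, 2) with NaN for missing cells and 0 at padding rows,
    ``Xf`` (N, R, p) with zero rows at padding, ``valid`` (N, R) boolean,
    ``sizes`` (N, J) cluster sizes, with R = J * n_max and rows grouped
    in n_max-blocks per cluster.  The update equations are identical to
    the sequential sampler; every replicate runs an independent chain
    (they share nothing but the vectorised arithmetic).  Returns a list
    of M arrays (N, R, 2) of completed outcomes.
    """
    N, R, p = Xf.shape
    J = sizes.shape[1]
    validf = valid.astype(float)[:, :, None]
    m1 = np.isnan(Y[:, :, 0])
    m2 = np.isnan(Y[:, :, 1])
    both = m1 & m2
    only1 = m1 & ~m2
    only2 = m2 & ~m1
    n_valid = valid.sum(axis=1)

    xtx = Xf.transpose(0, 2, 1) @ Xf
    xtx_inv = np.linalg.inv(xtx)
    Lx = np.linalg.cholesky(xtx_inv)

    # initial fill: per-replicate observed column means
    Yw = Y.copy()
    for ell in (0, 1):
        col = Yw[:, :, ell]
        obs = ~np.isnan(col) & valid
        means = np.where(obs, col, 0.0).sum(1) / np.maximum(obs.sum(1), 1)
        col[np.isnan(col)] = np.broadcast_to(means[:, None], col.shape)[
            np.isnan(col)
        ]
    B = xtx_inv @ (Xf.transpose(0, 2, 1) @ Yw)
    XB = Xf @ B
    resid = (Yw - XB) * validf
    denom = np.maximum(n_valid - 1.0, 1.0)
    sa = np.einsum("nr,nr->n", resid[:, :, 0], resid[:, :, 0]) / denom + 1e-6
    sb = np.einsum("nr,nr->n", resid[:, :, 0], resid[:, :, 1]) / denom
    sc = np.einsum("nr,nr->n", resid[:, :, 1], resid[:, :, 1]) / denom + 1e-6
    cl_means = resid.reshape(N, J, n_max, 2).sum(2) / sizes[:, :, None]
    dev = cl_means - cl_means.mean(1, keepdims=True)
    pa = np.einsum("nj,nj->n", dev[:, :, 0], dev[:, :, 0]) / (J - 1) + 1e-3
    pb = np.einsum("nj,nj->n", dev[:, :, 0], dev[:, :, 1]) / (J - 1)
    pc = np.einsum("nj,nj->n", dev[:, :, 1], dev[:, :, 1]) / (J - 1) + 1e-3
    u = np.zeros((N, J, 2))

    nu0 = control.prior_df
    S0 = control.scale()
    q0a, q0b, q0c = S0[0, 0], S0[0, 1], S0[1, 1]
    completed: list = []

    total_iter = control.burn_in + (M - 1) * control.thin + 1
    retain_at = {control.burn_in + m * control.thin for m in range(M)}
    for it in range(total_iter):
        si_a, si_b, si_c = inv2s_vec(sa, sb, sc)
        pi_a, pi_b, pi_c = inv2s_vec(pa, pb, pc)
        resid = Yw - XB
        s_j = (resid * validf).reshape(N, J, n_max, 2).sum(2)
        # (a) cluster effects
        va, vb, vc = inv2s_vec(
            sizes * si_a[:, None] + pi_a[:, None],
            sizes * si_b[:, None] + pi_b[:, None],
            sizes * si_c[:, None] + pi_c[:, None],
        )
        m00 = va * si_a[:, None] + vb * si_b[:, None]
        m01 = va * si_b[:, None] + vb * si_c[:, None]
        m10 = vb * si_a[:, None] + vc * si_b[:, None]
        m11 = vb * si_b[:, None] + vc * si_c[:, None]
        l11, l21, l22 = chol2s_vec(va, vb, vc)
        z = rng.standard_normal((N, J, 2))
        s0, s1 = s_j[:, :, 0], s_j[:, :, 1]
        u[:, :, 0] = m00 * s0 + m01 * s1 + l11 * z[:, :, 0]
        u[:, :, 1] = m10 * s0 + m11 * s1 + l21 * z[:, :, 0] + l22 * z[:, :, 1]
        # (b) cluster-effect covariance
        u0, u1 = u[:, :, 0], u[:, :, 1]
        pa, pb, pc = draw_invwishart2s_vec(
            nu0 + J,
            q0a + np.einsum("nj,nj->n", u0, u0),
            q0b + np.einsum("nj,nj->n", u0, u1),
            q0c + np.einsum("nj,nj->n", u1, u1),
            rng,
        )
        # (c) residual covariance
        ucol = np.repeat(u, n_max, axis=1)
        e = (resid - ucol) * validf
        e0, e1 = e[:, :, 0], e[:, :, 1]
        sa, sb, sc = draw_invwishart2s_vec(
            nu0 + n_valid,
            q0a + np.einsum("nr,nr->n", e0, e0),
            q0b + np.einsum("nr,nr->n", e0, e1),
            q0c + np.einsum("nr,nr->n", e1, e1),
            rng,
        )
        if not np.all(np.isfinite(sa + sc + pa + pc)):
            raise SamplerError(f"non-finite covariance draw at iteration {it}")
        cl11, cl21, cl22 = chol2s_vec(sa, sb, sc)
        # (d) coefficients
        ydag = Yw - ucol
        bhat = xtx_inv @ (Xf.transpose(0, 2, 1) @ ydag)
        zb = Lx @ rng.standard_normal((N, p, 2))
        B = np.empty_like(bhat)
        B[:, :, 0] = bhat[:, :, 0] + cl11[:, None] * zb[:, :, 0]
        B[:, :, 1] = (
            bhat[:, :, 1]
            + cl21[:, None] * zb[:, :, 0]
            + cl22[:, None] * zb[:, :, 1]
        )
        XB = Xf @ B
        # (e) missing outcomes
        mu = XB + ucol
        z1 = rng.standard_normal((N, R))
        z2 = rng.standard_normal((N, R))
        mu0, mu1 = mu[:, :, 0], mu[:, :, 1]
        slope12 = (sb / sc)[:, None]
        sd1 = np.sqrt(np.maximum(sa - sb * sb / sc, 0.0))[:, None]
        slope21 = (sb / sa)[:, None]
        sd2 = np.sqrt(np.maximum(sc - sb * sb / sa, 0.0))[:, None]
        y0, y1col = Yw[:, :, 0], Yw[:, :, 1]
        joint0 = mu0 + cl11[:, None] * z1
        joint1 = mu1 + cl21[:, None] * z1 + cl22[:, None] * z2
        cond0 = mu0 + slope12 * (y1col - mu1) + sd1 * z1
        cond1 = mu1 + slope21 * (y0 - mu0) + sd2 * z2
        Yw[:, :, 0] = np.where(both, joint0, np.where(only1, cond0, y0))
        Yw[:, :, 1] = np.where(both, joint1, np.where(only2, cond1, y1col))
        if it in retain_at:
            completed.append(Yw.copy())
    return completed


def impute_mmi_many(
    datasets: Sequence[TrialDataset],
    M: int,
    aux: Sequence[str] = ("x", "w"),
    control: GibbsControl | None = None,
    rng: np.random.Generator | None = None,
) -> list:
    """Run :func:`impute_mmi` for a batch of same-design datasets at once.

    All datasets must have the same number of clusters per arm (cluster
    sizes may differ).  Each dataset gets its own independent chain; the
    batch exists purely so the chains advance in lockstep through
    vectorised arithmetic, which is much faster than sequential calls
    when many replicates of one scenario are imputed.  Returns a list of
    :class:`ImputedStack`, one per dataset.
    """
    if rng is None:
        rng = np.random.default_rng()
    if control is None:
        control = GibbsControl()
    datasets = list(datasets)
    N = len(datasets)
    if N == 0:
        return []
    out_y = [
        [np.column_stack([d.y1, d.y2]).copy() for d in datasets]
        for _ in range(M)
    ]
    arm_streams = rng.spawn(2)
    for k in (0, 1):
        per_ds = []
        J_ref = None
        for d in datasets:
            idx = _arm_view(d, k)
            codes, _ = _cluster_codes(d.cluster_id[idx])
            J = int(codes.max()) + 1
            if J < 2:
                raise InsufficientDataError(
                    "multilevel MI needs >= 2 clusters per arm"
                )
            if J_ref is None:
                J_ref = J
            elif J != J_ref:
                raise ValueError(
                    "batched imputation requires equal cluster counts per arm"
                )
            order = np.argsort(codes, kind="stable")
            sizes = np.bincount(codes, minlength=J)
            per_ds.append((idx, codes, order, sizes))
        n_max = max(int(s.max()) for (_, _, _, s) in per_ds)
        R = J_ref * n_max
        p = 1 + len(aux)
        Y = np.zeros((N, R, 2))
        Xf = np.zeros((N, R, p))
        valid = np.zeros((N, R), dtype=bool)
        size_mat = np.zeros((N, J_ref), dtype=float)
        positions = []
        for i, (d, (idx, codes, order, sizes)) in enumerate(
            zip(datasets, per_ds)
        ):
            # flat position: cluster block * n_max + within-cluster rank
            rank = np.empty(idx.size, dtype=np.int64)
            offs = np.concatenate([[0], np.cumsum(sizes)[:-1]])
            for j in range(J_ref):
                blk = order[offs[j]: offs[j] + sizes[j]]
                rank[blk] = np.arange(sizes[j])
            pos = codes * n_max + rank
            positions.append((idx, pos))
            Y[i, pos, 0] = d.y1[idx]
            Y[i, pos, 1] = d.y2[idx]
            Xf[i, pos, 0] = 1.0
            for a, name in enumerate(aux, start=1):
                Xf[i, pos, a] = getattr(d, name)[idx]
            valid[i, pos] = True
            size_mat[i] = sizes
        completed = _gibbs_arm_batched(
            Y, Xf, valid, size_mat, n_max, M, control, arm_streams[k]
        )
        for m in range(M):
            for i, (idx, pos) in enumerate(positions):
                out_y[m][i][idx, 0] = completed[m][i, pos, 0]
                out_y[m][i][idx, 1] = completed[m][i, pos, 1]
    stacks = []
    for i, d in enumerate(datasets):
        stacks.append(
            ImputedStack(
                m_copies=[
                    d.copy_with_outcomes(out_y[m][i][:, 0], out_y[m][i][:, 1])
                    for m in range(M)
                ],
                source=d,
                method_tag="MMI",
                M=M,
            )
        )
    return stacks
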