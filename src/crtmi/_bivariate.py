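"""Closed-form 2x2 matrix utilities and Wishart-family draws.

The imputation engines and the mixed-model likelihood spend all their
time on 2x2 symmetric matrices; doing these operations with explicit
formulas (rather than generic linalg calls) keeps the per-iteration cost
of the Gibbs sampler and the per-evaluation cost of the REML objective
small.
"""

from __future__ import annotations

import math

import numpy as np


def inv2(m: np.ndarray) -> np.ndarray:
    """Inverse of a symmetric positive-definite 2x2 matrix."""
    a, b, c = m[0, 0], m[0, 1], m[1, 1]
    det = a * c - b * b
    if det <= 0 or a <= 0:
        raise np.linalg.LinAlgError("matrix not positive definite")
    return np.array([[c, -b], [-b, a]]) / det


def chol2(m: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor of a symmetric positive-definite 2x2 matrix."""
    a, b, c = m[0, 0], m[0, 1], m[1, 1]
    l11 = math.sqrt(a)
    l21 = b / l11
    l22sq = c - l21 * l21
    if l22sq <= 0:
        raise np.linalg.LinAlgError("matrix not positive definite")
    return np.array([[l11, 0.0], [l21, math.sqrt(l22sq)]])


def logdet2(m: np.ndarray) -> float:
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    if det <= 0:
        raise np.linalg.LinAlgError("matrix not positive definite")
    return math.log(det)


def draw_wishart2(df: float, scale: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One Wishart(df, scale) draw in dimension 2 via the Bartlett factor."""
    if df <= 1.0:
        raise ValueError("Wishart df must exceed dimension - 1 = 1")
    L = chol2(scale)
    a11 = math.sqrt(rng.chisquare(df))
    a22 = math.sqrt(rng.chisquare(df - 1.0))
    a21 = rng.standard_normal()
    B = L @ np.array([[a11, 0.0], [a21, a22]])
    return B @ B.T


def draw_invwishart2(
    df: float, scale: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One inverse-Wishart(df, scale) draw in dimension 2.

    Parameterised so that E[draw] = scale / (df - 3) for df > 3.
    """
    W = draw_wishart2(df, inv2(scale), rng)
    return inv2(W)


def inv2s(a: float, b: float, c: float):
    """Scalar inverse of the symmetric 2x2 [[a, b], [b, c]]."""
    det = a * c - b * b
    if det <= 0.0 or a <= 0.0:
        raise np.linalg.LinAlgError("matrix not positive definite")
    return c / det, -b / det, a / det


def chol2s(a: float, b: float, c: float):
    """Scalar lower-Cholesky components (l11, l21, l22) of [[a, b], [b, c]]."""
    l11 = math.sqrt(a)
    l21 = b / l11
    l22sq = c - l21 * l21
    if l22sq <= 0.0:
        raise np.linalg.LinAlgError("matrix not positive definite")
    return l11, l21, math.sqrt(l22sq)


def draw_invwishart2s(
    df: float, a: float, b: float, c: float, rng: np.random.Generator
):
    """Scalar-path inverse-Wishart(df, [[a, b], [b, c]]) draw, returning
    the components (s11, s12, s22).  Same distribution as
    :func:`draw_invwishart2`, avoiding small-array allocation."""
    ia, ib, ic = inv2s(a, b, c)
    l11, l21, l22 = chol2s(ia, ib, ic)
    a11 = math.sqrt(rng.chisquare(df))
    a22 = math.sqrt(rng.chisquare(df - 1.0))
    a21 = rng.standard_normal()
    # B = L @ A (lower triangular)
    b11 = l11 * a11
    b21 = l21 * a11 + l22 * a21
    b22 = l22 * a22
    # W = B B'
    w11 = b11 * b11
    w12 = b11 * b21
    w22 = b21 * b21 + b22 * b22
    wdet = w11 * w22 - w12 * w12
    if wdet <= 0.0:
        raise np.linalg.LinAlgError("degenerate Wishart draw")
    return w22 / wdet, -w12 / wdet, w11 / wdet


def inv2s_vec(a, b, c):
    """Vectorised :func:`inv2s` on component arrays."""
    det = a * c - b * b
    if np.any(det <= 0.0):
        raise np.linalg.LinAlgError("matrix not positive definite")
    return c / det, -b / det, a / det


def chol2s_vec(a, b, c):
    """Vectorised :func:`chol2s` on component arrays."""
    l11 = np.sqrt(a)
    l21 = b / l11
    l22sq = c - l21 * l21
    if np.any(l22sq <= 0.0):
        raise np.linalg.LinAlgError("matrix not positive definite")
    return l11, l21, np.sqrt(l22sq)


def draw_invwishart2s_vec(df, a, b, c, rng: np.random.Generator):
    """Vectorised :func:`draw_invwishart2s`: independent inverse-Wishart
    draws for a batch of scale matrices given componentwise."""
    ia, ib, ic = inv2s_vec(a, b, c)
    l11, l21, l22 = chol2s_vec(ia, ib, ic)
    shape = np.shape(a)
    a11 = np.sqrt(rng.chisquare(df, size=shape))
    a22 = np.sqrt(rng.chisquare(np.asarray(df) - 1.0, size=shape))
    a21 = rng.standard_normal(shape)
    b11 = l11 * a11
    b21 = l21 * a11 + l22 * a21
    b22 = l22 * a22
    w11 = b11 * b11
    w12 = b11 * b21
    w22 = b21 * b21 + b22 * b22
    wdet = w11 * w22 - w12 * w12
    if np.any(wdet <= 0.0):
        raise np.linalg.LinAlgError("degenerate Wishart draw")
    return w22 / wdet, -w12 / wdet, w11 / wdet


def conditional_impute(
    y: np.ndarray,
    mu: np.ndarray,
    sigma: np.ndarray,
    both_idx: np.ndarray,
    only1_idx: np.ndarray,
    only2_idx: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Fill missing outcome cells of ``y`` (n x 2, modified in place).

    ``mu`` is the n x 2 conditional mean surface, ``sigma`` the 2x2
    residual covariance.  ``both_idx`` are rows with both outcomes
    missing (joint bivariate draw); ``only1_idx``/``only2_idx`` rows with
    only y1/y2 missing (univariate conditional normal given the observed
    co-outcome).
    """
    s11, s12, s22 = sigma[0, 0], sigma[0, 1], sigma[1, 1]
    if both_idx.size:
        L = chol2(sigma)
        z = rng.standard_normal((both_idx.size, 2))
        y[both_idx, :] = mu[both_idx, :] + z @ L.T
    if only1_idx.size:
        slope = s12 / s22
        sd = math.sqrt(max(s11 - s12 * s12 / s22, 0.0))
        resid2 = y[only1_idx, 1] - mu[only1_idx, 1]
        y[only1_idx, 0] = (
            mu[only1_idx, 0] + slope * resid2
            + sd * rng.standard_normal(only1_idx.size)
        )
    if only2_idx.size:
        slope = s12 / s11
        sd = math.sqrt(max(s22 - s12 * s12 / s11, 0.0))
        resid1 = y[only2_idx, 0] - mu[only2_idx, 0]
        y[only2_idx, 1] = (
            mu[only2_idx, 1] + slope * resid1
            + sd * rng.standard_normal(only2_idx.size)
        )
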