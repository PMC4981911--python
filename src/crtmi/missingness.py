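"""MAR non-response mechanisms for the bivariate outcomes.

Each outcome l gets an independent Bernoulli non-response indicator with

    logit pi_l = alpha0_l + eta_X * X_i + eta_W * W_j

where the covariates entering depend on the mechanism kind:

* ``individual`` — X only;
* ``cluster``    — W only;
* ``both``       — X and W with a shared association strength;
* ``differential`` — X and W with arm-specific strengths eta_{.,k},
  emulating a treatment-covariate interaction in the dropout process.

Missingness depends only on the fully observed covariates (never on the
outcomes or the cluster effects), so every mechanism is MAR by
construction.  The intercept alpha0 is calibrated so the marginal
non-response rate over standard-normal covariates hits a target
proportion; for the differential kind the default calibrates in the
control arm and lets the intervention-arm rate emerge from the stronger
association.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, logit, roots_hermitenorm

from .core_data import TrialDataset

__all__ = [
    "MissingnessMechanism",
    "UncalibratedError",
    "linear_predictor",
    "calibrate_alpha0",
    "calibrate",
    "apply_missingness",
]

_KINDS = ("individual", "cluster", "both", "differential")


class UncalibratedError(RuntimeError):
    """The mechanism's alpha0 has not been calibrated yet."""


@dataclass(frozen=True)
class MissingnessMechanism:
    """A MAR non-response specification for both outcomes.

    ``eta_x``/``eta_w`` map arm -> association strength (identical across
    arms except for ``kind='differential'``).  ``target_rates`` gives the
    expected non-response proportion per outcome; for the differential
    kind it refers to the calibration arm (control by default).
    ``alpha0`` maps (outcome, arm) -> calibrated intercept and is filled
    by :func:`calibrate`.
    """

    kind: str
    eta_x: Mapping[int, float]
    eta_w: Mapping[int, float]
    target_rates: tuple  # (rate_y1, rate_y2)
    per_arm_targets: bool = False
    alpha0: Mapping[tuple, float] | None = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown mechanism kind {self.kind!r}")
        for rate in self.target_rates:
            if not (0.0 < rate < 1.0):
                raise ValueError("target rates must lie strictly in (0, 1)")
        if self.kind != "differential":
            if (self.eta_x[0] != self.eta_x[1]) or (self.eta_w[0] != self.eta_w[1]):
                raise ValueError(
                    "eta must be identical across arms unless kind='differential'"
                )

    @classmethod
    def make(
        cls,
        kind: str,
        eta: float | tuple = 1.0,
        target_rates: tuple = (0.2, 0.2),
        per_arm_targets: bool = False,
    ) -> "MissingnessMechanism":
        """Convenience constructor.

        ``eta`` is a scalar for non-differential kinds, or a pair
        (control, intervention) for ``kind='differential'``.
        """
        if kind == "differential":
            e0, e1 = eta  # type: ignore[misc]
            ex = ew = {0: float(e0), 1: float(e1)}
        else:
            e = float(eta)  # type: ignore[arg-type]
            ex = {0: e, 1: e} if kind in ("individual", "both") else {0: 0.0, 1: 0.0}
            ew = {0: e, 1: e} if kind in ("cluster", "both") else {0: 0.0, 1: 0.0}
            if kind == "individual":
                ew = {0: 0.0, 1: 0.0}
            if kind == "cluster":
                ex = {0: 0.0, 1: 0.0}
        return cls(
            kind=kind,
            eta_x=ex,
            eta_w=ew,
            target_rates=(float(target_rates[0]), float(target_rates[1])),
            per_arm_targets=per_arm_targets,
        )

    def uses_x(self) -> bool:
        return self.kind in ("individual", "both", "differential")

    def uses_w(self) -> bool:
        return self.kind in ("cluster", "both", "differential")

    def is_calibrated(self) -> bool:
        return self.alpha0 is not None


def linear_predictor(
    mech: MissingnessMechanism,
    x,
    w,
    arm: int,
    outcome: int,
) -> np.ndarray:
    """Logit non-response probability for outcome ``outcome`` (1 or 2)."""
    if not mech.is_calibrated():
        raise UncalibratedError("calibrate the mechanism before use")
    a0 = mech.alpha0[(outcome, arm)]
    lp = a0 + np.zeros_like(np.asarray(x, dtype=float))
    if mech.uses_x():
        lp = lp + mech.eta_x[arm] * np.asarray(x, dtype=float)
    if mech.uses_w():
        lp = lp + mech.eta_w[arm] * np.asarray(w, dtype=float)
    return lp


def _marginal_rate(alpha0: float, s: float, nodes, weights) -> float:
    """E[expit(alpha0 + s*Z)], Z standard normal, by Gauss-Hermite."""
    if s == 0.0:
        return float(expit(alpha0))
    return float(weights @ expit(alpha0 + s * nodes))


def calibrate_alpha0(
    mech: MissingnessMechanism, outcome: int, target: float, arm: int = 0
) -> float:
    """Intercept achieving E[pi_l] = target over standard-normal covariates.

    The expectation is a one-dimensional Gaussian integral because the
    covariate combination eta_X*X + eta_W*W is normal with SD
    s = sqrt(eta_X^2 + eta_W^2); it is evaluated with 96-node
    Gauss-Hermite quadrature and solved for alpha0 by Brent root-finding
    to |E - target| < 1e-10.
    """
    if not (0.0 < target < 1.0):
        raise ValueError("target must lie strictly in (0, 1)")
    sx = mech.eta_x[arm] if mech.uses_x() else 0.0
    sw = mech.eta_w[arm] if mech.uses_w() else 0.0
    s = math.hypot(sx, sw)
    if s == 0.0:
        return float(logit(target))
    nodes, weights = roots_hermitenorm(96)
    weights = weights / math.sqrt(2.0 * math.pi)
    lo = float(logit(target)) - 6.0 * s - 10.0
    hi = float(logit(target)) + 6.0 * s + 10.0
    return float(
        brentq(
            lambda a: _marginal_rate(a, s, nodes, weights) - target,
            lo,
            hi,
            xtol=1e-12,
            rtol=8.9e-16,
        )
    )


def calibrate(mech: MissingnessMechanism) -> MissingnessMechanism:
    """Return a copy with alpha0 filled for every (outcome, arm).

    Default mode shares one alpha0 per outcome across arms, calibrated in
    the control arm; with ``per_arm_targets=True`` each arm is calibrated
    to the target separately (only meaningful for the differential kind).
    """
    alpha0: dict = {}
    for ell, target in zip((1, 2), mech.target_rates):
        if mech.per_arm_targets:
            for k in (0, 1):
                alpha0[(ell, k)] = calibrate_alpha0(mech, ell, target, arm=k)
        else:
            a0 = calibrate_alpha0(mech, ell, target, arm=0)
            alpha0[(ell, 0)] = a0
            alpha0[(ell, 1)] = a0
    return replace(mech, alpha0=alpha0)


def apply_missingness(
    data: TrialDataset,
    mech: MissingnessMechanism,
    rng: np.random.Generator,
) -> TrialDataset:
    """Mask outcomes by independent Bernoulli draws of the non-response
    indicators; covariates and arm are never masked."""
    if (data.r1 != 0).any() or (data.r2 != 0).any():
        raise ValueError("dataset already has missing outcomes")
    if not mech.is_calibrated():
        raise UncalibratedError("calibrate the mechanism before use")

    y1 = data.y1.copy()
    y2 = data.y2.copy()
    r1 = np.zeros(data.n, dtype=np.int8)
    r2 = np.zeros(data.n, dtype=np.int8)
    for ell, (y, r) in zip((1, 2), ((y1, r1), (y2, r2))):
        pi = np.empty(data.n)
        for k in (0, 1):
            sel = data.arm == k
            pi[sel] = expit(linear_predictor(mech, data.x[sel], data.w[sel], k, ell))
        mask = rng.random(data.n) < pi
        y[mask] = np.nan
        r[mask] = 1
    return TrialDataset(
        individual_id=data.individual_id,
        cluster_id=data.cluster_id,
        arm=data.arm,
        x=data.x,
        w=data.w,
        y1=y1,
        y2=y2,
        r1=r1,
        r2=r2,
    )
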