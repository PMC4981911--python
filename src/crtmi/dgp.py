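"""Synthetic clustered bivariate-outcome trials.

Generates two-arm cluster randomised trials in which each individual i in
cluster j of arm k has outcomes

    Y1_ijk = b10 + b1*k + bw1*W_j + bx1*X_i + u1_jk + e1_ijk
    Y2_ijk = b20 + b2*k + bw2*W_j + bx2*X_i + u2_jk + e2_ijk

with (e1, e2) bivariate normal (SDs sigma1, sigma2, correlation rho) at the
individual level and (u1, u2) bivariate normal (SDs tau1, tau2, correlation
phi) at the cluster level.  Covariates X (individual) and W (cluster) are
i.i.d. standard normal and independent of treatment — pre-randomisation
auxiliary variables.  The cluster-effect SDs are parameterised through the
intra-cluster correlation coefficient ICC_l = tau_l^2/(tau_l^2+sigma_l^2),
defined on the model scale (excluding the covariate contribution).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .core_data import TrialDataset

__all__ = [
    "ModelConstants",
    "ClusterSizeSpec",
    "fixed_sizes",
    "gamma_sizes",
    "ClusterDesign",
    "ScenarioConfig",
    "tau_from_icc",
    "draw_cluster_sizes",
    "generate_trial",
]


@dataclass(frozen=True)
class ModelConstants:
    """Fixed-effect and variance constants of the outcome model.

    Defaults are the trial-emulation values used throughout the package:
    a "cost-like" outcome Y1 (intercept 100, treatment effect 120,
    sigma 40) and a "QALY-like" outcome Y2 (intercept 50, effect 10,
    sigma 20), residual correlation 0.1.  Covariate effects default to a
    quarter of each outcome's residual SD: large enough that the
    auxiliaries are materially prognostic (and selective non-response on
    them biases complete-case analysis), while keeping the
    treatment-effect estimator's sampling variance — and hence CI widths
    in the low-ICC design — at the scale typical of trials of this size.
    The cluster-effect correlation defaults to the residual correlation.
    """

    intercept1: float = 100.0
    intercept2: float = 50.0
    effect1: float = 120.0
    effect2: float = 10.0
    sigma1: float = 40.0
    sigma2: float = 20.0
    rho: float = 0.1
    beta_x1: float = 10.0
    beta_x2: float = 5.0
    beta_w1: float = 10.0
    beta_w2: float = 5.0
    phi: float = 0.1

    def validate(self) -> None:
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ValueError("residual SDs must be positive")
        if not (abs(self.rho) < 1 and abs(self.phi) < 1):
            raise ValueError("correlations must lie strictly in (-1, 1)")


@dataclass(frozen=True)
class ClusterSizeSpec:
    """Fixed or rounded-Gamma cluster sizes.

    ``kind='fixed'`` uses ``size`` for every cluster.  ``kind='gamma'``
    draws sizes by rounding a Gamma variate with the given mean and
    coefficient of variation (shape 1/cv^2, scale mean*cv^2), flooring at
    ``min_size``.
    """

    kind: str  # 'fixed' | 'gamma'
    size: int = 0
    mean: float = 0.0
    cv: float = 0.0
    min_size: int = 2

    def validate(self) -> None:
        if self.kind == "fixed":
            if self.size < 1:
                raise ValueError("fixed cluster size must be >= 1")
        elif self.kind == "gamma":
            if self.cv <= 0:
                raise ValueError("coefficient of variation must be > 0")
            if self.mean < 1:
                raise ValueError("mean cluster size must be >= 1")
            if self.min_size < 1:
                raise ValueError("min_size must be >= 1")
        else:
            raise ValueError(f"unknown cluster size spec kind {self.kind!r}")


def fixed_sizes(size: int) -> ClusterSizeSpec:
    return ClusterSizeSpec(kind="fixed", size=size)


def gamma_sizes(mean: float, cv: float, min_size: int = 2) -> ClusterSizeSpec:
    return ClusterSizeSpec(kind="gamma", mean=mean, cv=cv, min_size=min_size)


@dataclass(frozen=True)
class ClusterDesign:
    """Realised cluster sizes per arm."""

    sizes_control: tuple
    sizes_intervention: tuple

    def __post_init__(self):
        if min(self.sizes_control + self.sizes_intervention) < 1:
            raise ValueError("all cluster sizes must be >= 1")


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the factorial design.

    ``mechanism`` is a :class:`crtmi.missingness.MissingnessMechanism` (or
    None for complete-data scenarios).  ``seed`` is the scenario's master
    seed; per-replicate streams are derived from it by counter-based
    spawning so replicates are reproducible independently of order.
    """

    J: int
    cluster_size_spec: ClusterSizeSpec
    icc1: float
    icc2: float
    mechanism: Optional[object] = None
    model_constants: ModelConstants = field(default_factory=ModelConstants)
    M: int = 10
    seed: int = 0
    label: str = ""

    def validate(self) -> None:
        if self.J < 1:
            raise ValueError("J must be >= 1")
        for icc in (self.icc1, self.icc2):
            if not (0.0 <= icc < 1.0):
                raise ValueError("ICC must lie in [0, 1)")
        self.cluster_size_spec.validate()
        self.model_constants.validate()

    def replicate_rng(self, replicate: int) -> np.random.Generator:
        """Independent, order-insensitive stream for one replicate."""
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(replicate,))
        return np.random.default_rng(ss)


def tau_from_icc(icc: float, sigma: float) -> float:
    """Cluster random-effect SD giving the requested ICC.

    Solves tau^2/(tau^2 + sigma^2) = icc, i.e. tau = sigma*sqrt(icc/(1-icc)).
    """
    if not (0.0 <= icc < 1.0):
        raise ValueError("icc must lie in [0, 1)")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return sigma * math.sqrt(icc / (1.0 - icc))


def draw_cluster_sizes(
    J: int, spec: ClusterSizeSpec, rng: np.random.Generator
) -> ClusterDesign:
    """Draw the 2*J cluster sizes (J per arm) for one trial replicate."""
    if J < 1:
        raise ValueError("J must be >= 1")
    spec.validate()
    if spec.kind == "fixed":
        sizes = np.full(2 * J, spec.size, dtype=np.int64)
    else:
        shape = 1.0 / spec.cv**2
        scale = spec.mean * spec.cv**2
        raw = rng.gamma(shape=shape, scale=scale, size=2 * J)
        # round half to even, then floor at min_size
        sizes = np.maximum(np.rint(raw).astype(np.int64), spec.min_size)
    return ClusterDesign(
        sizes_control=tuple(int(s) for s in sizes[:J]),
        sizes_intervention=tuple(int(s) for s in sizes[J:]),
    )


def generate_trial(
    scenario: ScenarioConfig,
    rng: np.random.Generator,
    design: ClusterDesign | None = None,
) -> TrialDataset:
    """Generate one complete trial dataset (no missingness) for a scenario."""
    scenario.validate()
    mc = scenario.model_constants
    if design is None:
        design = draw_cluster_sizes(scenario.J, scenario.cluster_size_spec, rng)
    sizes = np.asarray(design.sizes_control + design.sizes_intervention)
    J2 = sizes.size
    arms_cl = np.repeat((0, 1), (len(design.sizes_control),
                                 len(design.sizes_intervention)))
    n = int(sizes.sum())

    cluster_idx = np.repeat(np.arange(J2), sizes)
    arm = arms_cl[cluster_idx]
    x = rng.standard_normal(n)
    w_cl = rng.standard_normal(J2)
    w = w_cl[cluster_idx]

    tau1 = tau_from_icc(scenario.icc1, mc.sigma1)
    tau2 = tau_from_icc(scenario.icc2, mc.sigma2)
    zu = rng.standard_normal((J2, 2))
    u1 = tau1 * zu[:, 0]
    u2 = tau2 * (mc.phi * zu[:, 0] + math.sqrt(1.0 - mc.phi**2) * zu[:, 1])
    ze = rng.standard_normal((n, 2))
    e1 = mc.sigma1 * ze[:, 0]
    e2 = mc.sigma2 * (mc.rho * ze[:, 0] + math.sqrt(1.0 - mc.rho**2) * ze[:, 1])

    y1 = (mc.intercept1 + mc.effect1 * arm + mc.beta_w1 * w + mc.beta_x1 * x
          + u1[cluster_idx] + e1)
    y2 = (mc.intercept2 + mc.effect2 * arm + mc.beta_w2 * w + mc.beta_x2 * x
          + u2[cluster_idx] + e2)

    cluster_id = np.array([f"c{j:03d}" for j in cluster_idx], dtype=object)
    individual_id = np.array([f"i{t:06d}" for t in range(n)], dtype=object)
    return TrialDataset(
        individual_id=individual_id,
        cluster_id=cluster_id,
        arm=arm,
        x=x,
        w=w,
        y1=y1,
        y2=y2,
        r1=np.zeros(n, dtype=np.int8),
        r2=np.zeros(n, dtype=np.int8),
    )
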