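"""Full-factorial simulation harness.

Each replicate runs the five-stage pipeline generate -> mask -> handle
(CCA or one of the MI engines) -> fit the bivariate mixed model -> pool,
and scenarios summarise coverage, bias, RMSE and average CI width over
replicates.  Methods are *paired*: within a replicate every method
consumes the identical masked dataset, which sharpens between-method
comparisons without biasing per-method summaries.
"""

from __future__ import annotations

import itertools
import logging
import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .core_data import TrialDataset, complete_cases
from .dgp import (
    ModelConstants,
    ScenarioConfig,
    fixed_sizes,
    gamma_sizes,
    generate_trial,
)
from .estimation import fit_bivariate_mixed, make_ci, rubin_pool
from .imputers import (
    GibbsControl,
    impute_fmi,
    impute_mmi,
    impute_mmi_many,
    impute_smi,
)
from .missingness import MissingnessMechanism, apply_missingness, calibrate

logger = logging.getLogger("crtmi.harness")

__all__ = [
    "MethodSpec",
    "PerformanceSummary",
    "expand_grid",
    "default_factors",
    "run_replicate",
    "run_scenario",
    "coverage",
    "bias_metrics",
    "avg_ci_width",
    "TRUE_EFFECTS",
]

#: true treatment effects of the generating model, per estimand
TRUE_EFFECTS = {"beta1": 120.0, "beta2": 10.0}

ESTIMANDS = ("beta1", "beta2")


@dataclass(frozen=True)
class MethodSpec:
    """One missing-data handling strategy in the comparison.

    Kind ``full`` is the complete-data benchmark: it fits the substantive
    model to the replicate's pre-masking dataset.  Its paired difference
    with any other method is an exactly unbiased, low-variance estimate of
    that method's bias (the complete-data GLS estimator is unbiased, and
    the shared data cancel the generation noise).
    """

    kind: str  # 'cca' | 'smi' | 'fmi' | 'mmi' | 'full'
    name: str = ""
    control: GibbsControl = field(default_factory=GibbsControl)

    def __post_init__(self):
        if self.kind not in ("cca", "smi", "fmi", "mmi", "full"):
            raise ValueError(f"unknown method kind {self.kind!r}")
        if not self.name:
            object.__setattr__(self, "name", self.kind.upper())

    def stream_key(self) -> int:
        return zlib.crc32(self.name.encode()) & 0x7FFFFFFF


@dataclass
class PerformanceSummary:
    """Per-scenario, per-(method, estimand) performance metrics."""

    scenario_label: str
    n_replicates: int
    truth: dict
    table: dict  # (method_name, estimand) -> metrics dict
    flagged: list  # method names with >10% exclusions

    def metric(self, method: str, estimand: str, key: str):
        return self.table[(method, estimand)][key]


# ---------------------------------------------------------------------------
# grid expansion

#: Table-of-levels used by :func:`default_factors` (the full design:
#: 3 designs x 4 ICC pairs x 4 mechanisms x 2 association strengths x
#: 2 non-response patterns = 192 scenarios).
_DESIGNS = (
    ("many_small", 25, fixed_sizes(10)),
    ("few_large", 5, fixed_sizes(50)),
    ("unbalanced", 15, gamma_sizes(20.0, 0.5, 2)),
)
_ICCS = ((0.01, 0.01), (0.20, 0.05), (0.20, 0.20), (0.60, 0.01))
_MECHANISMS = ("individual", "cluster", "both", "differential")
_ASSOCIATIONS = ("low", "high")
_NONRESPONSE = ((0.20, 0.20), (0.30, 0.10))

_ETA = {
    # non-differential kinds share eta across arms
    ("individual", "low"): 1.0,
    ("individual", "high"): 2.0,
    ("cluster", "low"): 1.0,
    ("cluster", "high"): 2.0,
    ("both", "low"): 1.0,
    ("both", "high"): 2.0,
    # differential: (control, intervention)
    ("differential", "low"): (1.0, 2.0),
    ("differential", "high"): (1.5, 3.0),
}


def default_factors() -> dict:
    return {
        "designs": _DESIGNS,
        "iccs": _ICCS,
        "mechanisms": _MECHANISMS,
        "associations": _ASSOCIATIONS,
        "nonresponse": _NONRESPONSE,
    }


def make_mechanism(
    kind: str, association: str, targets: tuple
) -> MissingnessMechanism:
    """Calibrated mechanism for one factorial cell."""
    return calibrate(
        MissingnessMechanism.make(kind, _ETA[(kind, association)], targets)
    )


def expand_grid(
    factors: dict | None = None,
    model_constants: ModelConstants | None = None,
    M: int = 10,
    master_seed: int = 0,
) -> list:
    """Cartesian product of the factor levels, deterministic ordering,
    per-scenario derived seeds."""
    factors = default_factors() if factors is None else factors
    for key in ("designs", "iccs", "mechanisms", "associations", "nonresponse"):
        if not factors.get(key):
            raise ValueError(f"factor {key!r} has no levels")
    mc = model_constants or ModelConstants()
    scenarios = []
    combos = itertools.product(
        factors["designs"],
        factors["iccs"],
        factors["mechanisms"],
        factors["associations"],
        factors["nonresponse"],
    )
    for i, ((dlabel, J, spec), (icc1, icc2), kind, assoc, targets) in enumerate(
        combos
    ):
        label = (
            f"{dlabel}|icc{icc1:g},{icc2:g}|{kind}|{assoc}"
            f"|nr{targets[0]:g},{targets[1]:g}"
        )
        seed = int(
            np.random.SeedSequence(
                entropy=master_seed, spawn_key=(i,)
            ).generate_state(1)[0]
            & 0x7FFFFFFF
        )
        scenarios.append(
            ScenarioConfig(
                J=J,
                cluster_size_spec=spec,
                icc1=icc1,
                icc2=icc2,
                mechanism=make_mechanism(kind, assoc, targets),
                model_constants=mc,
                M=M,
                seed=seed,
                label=label,
            )
        )
    return scenarios


# ---------------------------------------------------------------------------
# replicate pipeline


def _handle_and_fit(masked: TrialDataset, scenario, method, rng, full=None):
    """Stage 3-5 of the pipeline for one method; returns per-estimand dict."""
    if method.kind in ("cca", "full"):
        if method.kind == "full":
            if full is None:
                raise ValueError("complete-data benchmark needs the full data")
            fit = fit_bivariate_mixed(full)
        else:
            fit = fit_bivariate_mixed(complete_cases(masked))
        if not fit.converged:
            raise RuntimeError("complete-case fit did not converge")
        out = {}
        z = norm.ppf(0.975)
        for est in ESTIMANDS:
            q, se = fit.estimate(est), fit.se(est)
            out[est] = {"estimate": q, "se": se, "ci": (q - z * se, q + z * se)}
        return out
    if method.kind == "smi":
        stack = impute_smi(masked, scenario.M, aux=("x", "w"), rng=rng)
    elif method.kind == "fmi":
        stack = impute_fmi(masked, scenario.M, aux=("x",), rng=rng)
    elif method.kind == "mmi":
        stack = impute_mmi(
            masked, scenario.M, aux=("x", "w"), control=method.control, rng=rng
        )
    return _fit_and_pool(stack.m_copies)


def _fit_and_pool(copies) -> dict:
    """Fit every completed copy (warm-starting after the first) and pool."""
    fits = []
    start = None
    for d in copies:
        f = fit_bivariate_mixed(d, start=start)
        if f.converged:
            start = f.varcomp
        fits.append(f)
    good = [f for f in fits if f.converged]
    if len(good) < len(fits):
        raise RuntimeError(
            f"{len(fits) - len(good)} of {len(fits)} imputed-data fits failed"
        )
    out = {}
    for est in ESTIMANDS:
        pooled = make_ci(rubin_pool(good, est), 0.95)
        out[est] = {
            "estimate": pooled.q_bar,
            "se": math.sqrt(pooled.t_total),
            "ci": (pooled.ci_low, pooled.ci_high),
        }
    return out


def run_replicate(
    scenario: ScenarioConfig,
    method: MethodSpec,
    rng: np.random.Generator,
) -> dict:
    """Run the five-stage pipeline once for one method.

    ``rng`` drives data generation, masking and the engine; identical
    (scenario, method, seed) triples give identical output.
    """
    full = generate_trial(scenario, rng)
    masked = (
        apply_missingness(full, scenario.mechanism, rng)
        if scenario.mechanism is not None
        else full
    )
    return _handle_and_fit(masked, scenario, method, rng, full=full)


def _normalise_methods(methods) -> list:
    out = []
    for m in methods:
        if isinstance(m, MethodSpec):
            out.append(m)
        else:
            out.append(MethodSpec(kind=str(m).lower()))
    return out


def run_scenario(
    scenario: ScenarioConfig,
    N: int,
    methods: Sequence,
    master_seed: int | None = None,
    collect: dict | None = None,
) -> PerformanceSummary:
    """N paired replicates of every method, summarised per estimand.

    All methods consume byte-identical masked datasets within a
    replicate.  Replicates whose handling or fitting fails are excluded
    for that method and logged; a method losing more than 10% of its
    replicates is flagged in the summary.  ``collect`` (optional dict)
    receives the raw per-method estimate/CI arrays.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    methods = _normalise_methods(methods)
    scn = scenario if master_seed is None else replace(scenario, seed=master_seed)
    results = {
        (m.name, est): {"estimates": [], "cis": [], "rep_ids": []}
        for m in methods
        for est in ESTIMANDS
    }
    excluded = {m.name: 0 for m in methods}
    # stage 1+2 once per replicate; every method sees the same masked data
    full_data = []
    masked_data = []
    for rep in range(N):
        gen_rng = scn.replicate_rng(rep)
        data = generate_trial(scn, gen_rng)
        full_data.append(data)
        masked_data.append(
            apply_missingness(data, scn.mechanism, gen_rng)
            if scn.mechanism is not None
            else data
        )
    for m in methods:
        if m.kind == "mmi":
            # all replicate chains advance in lockstep (vectorised batch)
            m_rng = np.random.default_rng(
                np.random.SeedSequence(entropy=scn.seed,
                                       spawn_key=(m.stream_key(),))
            )
            stacks = impute_mmi_many(
                masked_data, scn.M, aux=("x", "w"), control=m.control, rng=m_rng
            )
            for rep, stack in enumerate(stacks):
                try:
                    out = _fit_and_pool(stack.m_copies)
                except Exception as exc:  # noqa: BLE001 - excluded with logging
                    excluded[m.name] += 1
                    logger.warning(
                        "scenario %s method %s replicate %d excluded: %s",
                        scn.label, m.name, rep, exc,
                    )
                    continue
                for est in ESTIMANDS:
                    cell = results[(m.name, est)]
                    cell["estimates"].append(out[est]["estimate"])
                    cell["cis"].append(out[est]["ci"])
                    cell["rep_ids"].append(rep)
            continue
        for rep, masked in enumerate(masked_data):
            m_rng = np.random.default_rng(
                np.random.SeedSequence(
                    entropy=scn.seed, spawn_key=(rep, m.stream_key())
                )
            )
            try:
                out = _handle_and_fit(masked, scn, m, m_rng,
                                      full=full_data[rep])
            except Exception as exc:  # noqa: BLE001 - excluded with logging
                excluded[m.name] += 1
                logger.warning(
                    "scenario %s method %s replicate %d excluded: %s",
                    scn.label, m.name, rep, exc,
                )
                continue
            for est in ESTIMANDS:
                cell = results[(m.name, est)]
                cell["estimates"].append(out[est]["estimate"])
                cell["cis"].append(out[est]["ci"])
                cell["rep_ids"].append(rep)

    truth = TRUE_EFFECTS
    table = {}
    flagged = []
    for m in methods:
        if excluded[m.name] > 0.10 * N and m.name not in flagged:
            flagged.append(m.name)
        for est in ESTIMANDS:
            cell = results[(m.name, est)]
            ests, cis = cell["estimates"], cell["cis"]
            n_ok = len(ests)
            if n_ok == 0:
                table[(m.name, est)] = {"n_replicates": 0,
                                        "n_excluded": excluded[m.name]}
                continue
            cov = coverage(cis, truth[est])
            b, pbias, rmse = bias_metrics(ests, truth[est])
            p = cov / 100.0
            table[(m.name, est)] = {
                "coverage_pct": cov,
                "bias": b,
                "percent_bias": pbias,
                "rmse": rmse,
                "avg_ci_width": avg_ci_width(cis),
                "n_replicates": n_ok,
                "n_excluded": excluded[m.name],
                "mc_se_coverage": 100.0 * math.sqrt(p * (1.0 - p) / n_ok),
            }
    if collect is not None:
        collect.update(results)
    return PerformanceSummary(
        scenario_label=scn.label,
        n_replicates=N,
        truth=dict(truth),
        table=table,
        flagged=flagged,
    )


# ---------------------------------------------------------------------------
# performance criteria


def coverage(cis: Sequence, truth: float) -> float:
    """Percent of closed intervals containing the truth."""
    if len(cis) == 0:
        raise ValueError("need at least one interval")
    hits = sum(1 for lo, hi in cis if lo <= truth <= hi)
    return 100.0 * hits / len(cis)


def bias_metrics(estimates: Sequence, truth: float):
    """(empirical bias, percent bias, RMSE) of the estimates."""
    est = np.asarray(estimates, dtype=float)
    if est.size == 0:
        raise ValueError("need at least one estimate")
    b = float(est.mean() - truth)
    pbias = 100.0 * b / truth if truth != 0 else math.nan
    rmse = float(np.sqrt(np.mean((est - truth) ** 2)))
    return b, pbias, rmse


def avg_ci_width(cis: Sequence) -> float:
    """Mean upper limit minus mean lower limit."""
    if len(cis) == 0:
        raise ValueError("need at least one interval")
    arr = np.asarray(cis, dtype=float)
    return float(arr[:, 1].mean() - arr[:, 0].mean())
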