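"""Domain containers for two-arm clustered trials with partially observed
bivariate outcomes, plus long-format CSV ingestion.

The central object is :class:`TrialDataset`: one record per individual,
holding the cluster label, treatment arm (0 = control, 1 = intervention),
an individual-level covariate ``x``, a cluster-level covariate ``w``
(constant within cluster) and two continuous outcomes ``y1``/``y2`` that
may each be missing.  Missingness is tracked by indicators ``r1``/``r2``
(1 = missing), mirroring the non-response indicators of the underlying
trial model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TrialDataset",
    "ImputedStack",
    "FitResult",
    "PooledResult",
    "SchemaError",
    "ValidationError",
    "DegenerateDataError",
    "read_trial_csv",
    "write_trial_csv",
    "complete_cases",
    "DEFAULT_SCHEMA",
]


class SchemaError(ValueError):
    """A required column is absent or uninterpretable."""


class ValidationError(ValueError):
    """The data violate a structural invariant of a clustered trial."""


class DegenerateDataError(ValueError):
    """An operation left too little data to support the analysis."""


DEFAULT_SCHEMA: Mapping[str, str] = {
    "individual_id": "individual_id",
    "cluster_id": "cluster_id",
    "arm": "arm",
    "x": "x",
    "w": "w",
    "y1": "y1",
    "y2": "y2",
}

#: strings treated as missing outcome cells on read, besides empty fields
DEFAULT_NA_SENTINELS: Sequence[str] = ("", "NA", "NaN", "nan")


@dataclass
class TrialDataset:
    """Per-individual records of a two-arm clustered trial.

    Arrays are aligned; ``y1``/``y2`` hold ``nan`` exactly where the
    corresponding indicator ``r1``/``r2`` is 1.  Cluster and individual
    ids are opaque; ordering is by first appearance.
    """

    individual_id: np.ndarray
    cluster_id: np.ndarray
    arm: np.ndarray
    x: np.ndarray
    w: np.ndarray
    y1: np.ndarray
    y2: np.ndarray
    r1: np.ndarray
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.individual_id = np.asarray(self.individual_id, dtype=object)
        self.cluster_id = np.asarray(self.cluster_id, dtype=object)
        self.arm = np.asarray(self.arm, dtype=np.int64)
        for name in ("x", "w", "y1", "y2"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.r1 = np.asarray(self.r1, dtype=np.int8)
        self.r2 = np.asarray(self.r2, dtype=np.int8)

    # -- basic accessors -------------------------------------------------
    @property
    def n(self) -> int:
        return self.individual_id.shape[0]

    @property
    def clusters(self) -> list:
        """Cluster labels in order of first appearance."""
        seen: dict = {}
        for c in self.cluster_id:
            seen.setdefault(c, None)
        return list(seen)

    def validate(self) -> None:
        """Check the structural invariants; raise ValidationError on failure."""
        n = self.n
        for name in ("cluster_id", "arm", "x", "w", "y1", "y2", "r1", "r2"):
            if getattr(self, name).shape[0] != n:
                raise ValidationError(f"field {name!r} has mismatched length")
        if n == 0:
            raise ValidationError("dataset has no records")
        if not np.isin(self.arm, (0, 1)).all():
            raise ValidationError("arm codes must be 0 or 1")
        if not ((np.isnan(self.y1) == (self.r1 == 1)).all()
                and (np.isnan(self.y2) == (self.r2 == 1)).all()):
            raise ValidationError("y_l must be absent exactly when r_l = 1")
        if np.isnan(self.x).any() or np.isnan(self.w).any():
            raise ValidationError("covariates x and w must be fully observed")
        for cl in self.clusters:
            sel = self.cluster_id == cl
            if np.unique(self.arm[sel]).size != 1:
                raise ValidationError(f"arm varies within cluster {cl!r}")
            if np.unique(self.w[sel]).size != 1:
                raise ValidationError(f"w varies within cluster {cl!r}")
        for k in (0, 1):
            if not (self.arm == k).any():
                raise ValidationError(f"arm {k} has no clusters")

    # -- conversion ------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "individual_id": self.individual_id,
                "cluster_id": self.cluster_id,
                "arm": self.arm,
                "x": self.x,
                "w": self.w,
                "y1": self.y1,
                "y2": self.y2,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, validate: bool = True) -> "TrialDataset":
        y1 = df["y1"].to_numpy(dtype=float)
        y2 = df["y2"].to_numpy(dtype=float)
        ds = cls(
            individual_id=df["individual_id"].to_numpy(dtype=object),
            cluster_id=df["cluster_id"].to_numpy(dtype=object),
            arm=df["arm"].to_numpy(),
            x=df["x"].to_numpy(dtype=float),
            w=df["w"].to_numpy(dtype=float),
            y1=y1,
            y2=y2,
            r1=np.isnan(y1).astype(np.int8),
            r2=np.isnan(y2).astype(np.int8),
        )
        if validate:
            ds.validate()
        return ds

    def copy_with_outcomes(self, y1: np.ndarray, y2: np.ndarray) -> "TrialDataset":
        """A completed copy sharing id/covariate arrays (used by imputers)."""
        return TrialDataset(
            individual_id=self.individual_id,
            cluster_id=self.cluster_id,
            arm=self.arm,
            x=self.x,
            w=self.w,
            y1=np.asarray(y1, dtype=float).copy(),
            y2=np.asarray(y2, dtype=float).copy(),
            r1=np.zeros(self.n, dtype=np.int8),
            r2=np.zeros(self.n, dtype=np.int8),
        )

    def equals(self, other: "TrialDataset") -> bool:
        return (
            (self.individual_id == other.individual_id).all()
            and (self.cluster_id == other.cluster_id).all()
            and (self.arm == other.arm).all()
            and np.allclose(self.x, other.x)
            and np.allclose(self.w, other.w)
            and np.allclose(self.y1, other.y1, equal_nan=True)
            and np.allclose(self.y2, other.y2, equal_nan=True)
            and (self.r1 == other.r1).all()
            and (self.r2 == other.r2).all()
        )


@dataclass
class ImputedStack:
    """M completed copies of a :class:`TrialDataset` from one MI engine."""

    m_copies: list
    source: TrialDataset
    method_tag: str  # one of {"SMI", "FMI", "MMI"}
    M: int

    def validate(self) -> None:
        if len(self.m_copies) != self.M:
            raise ValidationError("stack length differs from M")
        src = self.source
        obs1, obs2 = src.r1 == 0, src.r2 == 0
        for d in self.m_copies:
            if np.isnan(d.y1).any() or np.isnan(d.y2).any():
                raise ValidationError("completed copy still has absent outcomes")
            if not (np.array_equal(d.y1[obs1], src.y1[obs1])
                    and np.array_equal(d.y2[obs2], src.y2[obs2])):
                raise ValidationError("completed copy altered observed values")


@dataclass
class FitResult:
    """Treatment-effect estimates from one bivariate mixed-model fit."""

    beta1_hat: float
    beta2_hat: float
    intercept1: float
    intercept2: float
    vcov_treat: np.ndarray  # 2x2 covariance of (beta1_hat, beta2_hat)
    varcomp: tuple  # (sigma1, sigma2, rho, tau1, tau2, phi)
    n_used: int
    converged: bool
    loglik: float = float("nan")

    def se(self, estimand: str) -> float:
        i = {"beta1": 0, "beta2": 1}[estimand]
        return float(np.sqrt(self.vcov_treat[i, i]))

    def estimate(self, estimand: str) -> float:
        return {"beta1": self.beta1_hat, "beta2": self.beta2_hat}[estimand]


@dataclass
class PooledResult:
    """Rubin-pooled estimate with within/between/total variance and CI."""

    q_bar: float
    w_within: float
    b_between: float
    t_total: float
    ci_low: float
    ci_high: float
    level: float
    M: int


def read_trial_csv(
    path,
    schema: Mapping[str, str] | None = None,
    na_sentinels: Sequence[str] = DEFAULT_NA_SENTINELS,
    validate: bool = True,
) -> TrialDataset:
    """Read a long-format trial table.

    ``schema`` maps canonical field names (keys of :data:`DEFAULT_SCHEMA`)
    to the column names present in the file.  Empty outcome cells (or any
    cell in ``na_sentinels``) become absent values with the corresponding
    non-response indicator set.
    """
    schema = dict(DEFAULT_SCHEMA) if schema is None else dict(schema)
    missing_keys = set(DEFAULT_SCHEMA) - set(schema)
    if missing_keys:
        raise SchemaError(f"schema lacks mappings for {sorted(missing_keys)}")
    df = pd.read_csv(
        path,
        na_values=list(na_sentinels),
        keep_default_na=False,
        dtype={schema["individual_id"]: str, schema["cluster_id"]: str},
    )
    absent = [schema[k] for k in DEFAULT_SCHEMA if schema[k] not in df.columns]
    if absent:
        raise SchemaError(f"missing required columns: {absent}")
    renamed = df.rename(columns={v: k for k, v in schema.items()})
    try:
        renamed["arm"] = renamed["arm"].astype(int)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"arm codes not coercible to integers: {exc}") from exc
    for col in ("x", "w"):
        if renamed[col].isna().any():
            raise ValidationError(f"covariate column {col!r} has missing cells")
    return TrialDataset.from_frame(renamed, validate=validate)


def write_trial_csv(data: TrialDataset, path) -> None:
    """Write a :class:`TrialDataset` so that a read round-trips it exactly.

    Absent outcome cells are written as empty fields; numeric fields use
    repr-precision so values survive the round trip bit-for-bit.
    """
    data.validate()
    df = data.to_frame()
    df.to_csv(path, index=False, na_rep="")


def complete_cases(data: TrialDataset) -> TrialDataset:
    """Records with BOTH outcomes observed (the bivariate model's complete
    cases); clusters left empty are dropped.

    Raises :class:`DegenerateDataError` if an arm is left without clusters.
    """
    keep = (data.r1 == 0) & (data.r2 == 0)
    for k in (0, 1):
        if not keep[data.arm == k].any():
            raise DegenerateDataError(
                f"complete-case restriction removed every record in arm {k}"
            )
    return TrialDataset(
        individual_id=data.individual_id[keep],
        cluster_id=data.cluster_id[keep],
        arm=data.arm[keep],
        x=data.x[keep],
        w=data.w[keep],
        y1=data.y1[keep],
        y2=data.y2[keep],
        r1=data.r1[keep],
        r2=data.r2[keep],
    )
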