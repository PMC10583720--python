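"""Observed-data containers for the binary two-mediator setting.

The sufficient statistic for all bound computations is the table of 16
conditional probabilities

    p_{y m1 m2 . x} = P(Y=y, M1=m1, M2=m2 | X=x),

two 8-cell simplexes, one per treatment arm.  The marginal distribution of X
carries no information about the bounds (X is treated as randomized) and is
retained only as per-arm record counts.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ArmAbsentError, CodingError

__all__ = [
    "BinaryDataset",
    "ObservedDistribution",
    "DistributionDiagnostics",
    "estimate_observed_distribution",
    "validate_distribution",
    "dichotomize",
]

_NORM_TOL = 1e-12


def _binary_array(values, name: str) -> np.ndarray:
    arr = np.asarray(values)
    if arr.size and not np.isin(arr, (0, 1)).all():
        bad = arr[~np.isin(arr, (0, 1))][:5]
        raise CodingError(f"column {name} must be binary 0/1; found {bad.tolist()}")
    return arr.astype(np.int8)


@dataclass
class BinaryDataset:
    """Individual-level records (X, M1, M2, Y) with optional covariates C.

    All four analysis variables must be coded 0/1; covariates are free-form
    and stored as a DataFrame aligned with the records.
    """

    x: np.ndarray
    m1: np.ndarray
    m2: np.ndarray
    y: np.ndarray
    covariates: Optional[pd.DataFrame] = None

    def __post_init__(self):
        self.x = _binary_array(self.x, "X")
        self.m1 = _binary_array(self.m1, "M1")
        self.m2 = _binary_array(self.m2, "M2")
        self.y = _binary_array(self.y, "Y")
        n = len(self.x)
        for name, col in (("M1", self.m1), ("M2", self.m2), ("Y", self.y)):
            if len(col) != n:
                raise CodingError(f"column {name} has length {len(col)}, expected {n}")
        if self.covariates is not None:
            if len(self.covariates) != n:
                raise CodingError(
                    f"covariate frame has {len(self.covariates)} rows, expected {n}"
                )
            self.covariates = self.covariates.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.x)

    @property
    def covariate_names(self) -> list:
        return [] if self.covariates is None else list(self.covariates.columns)

    def subset(self, idx) -> "BinaryDataset":
        cov = None if self.covariates is None else self.covariates.iloc[idx]
        return BinaryDataset(self.x[idx], self.m1[idx], self.m2[idx], self.y[idx], cov)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"X": self.x, "M1": self.m1, "M2": self.m2, "Y": self.y})
        if self.covariates is not None:
            df = pd.concat([df, self.covariates], axis=1)
        return df

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, covariate_columns: Optional[Sequence[str]] = None
    ) -> "BinaryDataset":
        cols = {c.lower(): c for c in df.columns}
        missing = [k for k in ("x", "m1", "m2", "y") if k not in cols]
        if missing:
            raise CodingError(f"missing required columns {missing} (case-insensitive)")
        core = [cols["x"], cols["m1"], cols["m2"], cols["y"]]
        if covariate_columns is None:
            covariate_columns = [c for c in df.columns if c not in core]
        cov = df[list(covariate_columns)].copy() if covariate_columns else None
        return cls(
            df[cols["x"]].to_numpy(),
            df[cols["m1"]].to_numpy(),
            df[cols["m2"]].to_numpy(),
            df[cols["y"]].to_numpy(),
            cov,
        )

    @classmethod
    def from_csv(cls, path, covariate_columns: Optional[Sequence[str]] = None):
        return cls.from_dataframe(pd.read_csv(path), covariate_columns)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def cell_counts(self) -> np.ndarray:
        """Joint counts indexed ``[y, m1, m2, x]`` (shape (2,2,2,2))."""
        code = (
            self.y.astype(np.int64) * 8
            + self.m1.astype(np.int64) * 4
            + self.m2.astype(np.int64) * 2
            + self.x.astype(np.int64)
        )
        return np.bincount(code, minlength=16).reshape(2, 2, 2, 2)


@dataclass
class ObservedDistribution:
    """The 16 probabilities p_{y m1 m2 . x}, indexed ``p[y, m1, m2, x]``."""

    p: np.ndarray
    n_by_arm: Optional[np.ndarray] = None

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (2, 2, 2, 2):
            raise CodingError(f"probability table must have shape (2,2,2,2), got {self.p.shape}")
        if self.n_by_arm is not None:
            self.n_by_arm = np.asarray(self.n_by_arm, dtype=np.int64)

    def prob(self, y: int, m1: int, m2: int, x: int) -> float:
        return float(self.p[y, m1, m2, x])

    def arm(self, x: int) -> np.ndarray:
        """The 8-vector over (y, m1, m2) lexicographic for arm ``x``."""
        return self.p[:, :, :, x].reshape(8)

    def swap_mediators(self) -> "ObservedDistribution":
        """The distribution with the M1 and M2 labels exchanged."""
        return ObservedDistribution(self.p.transpose(0, 2, 1, 3).copy(), self.n_by_arm)

    # -- JSON round trip ----------------------------------------------------
    def to_dict(self) -> dict:
        out = {
            f"p_y{y}m1{a}m2{b}.x{x}": float(self.p[y, a, b, x])
            for y, a, b, x in itertools.product((0, 1), repeat=4)
        }
        if self.n_by_arm is not None:
            out["n_by_arm"] = self.n_by_arm.tolist()
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "ObservedDistribution":
        p = np.zeros((2, 2, 2, 2))
        for y, a, b, x in itertools.product((0, 1), repeat=4):
            p[y, a, b, x] = d[f"p_y{y}m1{a}m2{b}.x{x}"]
        n = d.get("n_by_arm")
        return cls(p, None if n is None else np.asarray(n))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "ObservedDistribution":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def estimate_observed_distribution(data: BinaryDataset) -> ObservedDistribution:
    """Empirical conditional frequencies p_{y m1 m2 . x} from records.

    Both arms must be present; counts are retained in ``n_by_arm``.
    """
    counts = data.cell_counts().astype(float)
    n_by_arm = counts.sum(axis=(0, 1, 2))
    if (n_by_arm == 0).any():
        missing = int(np.where(n_by_arm == 0)[0][0])
        raise ArmAbsentError(f"no records in arm X={missing}")
    p = counts / n_by_arm[None, None, None, :]
    return ObservedDistribution(p, n_by_arm.astype(np.int64))


@dataclass
class DistributionDiagnostics:
    """Validation report for an :class:`ObservedDistribution`."""

    nonnegative: bool
    normalized: bool
    arm_sums: np.ndarray
    zero_cells: list = field(default_factory=list)

    @property
    def valid(self) -> bool:
        return self.nonnegative and self.normalized

    def summary(self) -> str:
        if not self.nonnegative:
            return "negative cells present"
        if not self.normalized:
            return (
                "normalization violated: per-arm sums "
                f"{self.arm_sums[0]:.6g}, {self.arm_sums[1]:.6g}"
            )
        if self.zero_cells:
            return f"valid, {len(self.zero_cells)} zero cells"
        return "valid, no zero cells"


def validate_distribution(dist: ObservedDistribution, tol: float = 1e-9) -> DistributionDiagnostics:
    """Report nonnegativity, per-arm normalization, and empty cells.

    Zero cells are reported (not rejected): they are legal probabilities but
    make plug-in estimators that condition on the corresponding stratum
    undefined.
    """
    arm_sums = dist.p.sum(axis=(0, 1, 2))
    zero = [
        (y, a, b, x)
        for y, a, b, x in itertools.product((0, 1), repeat=4)
        if dist.p[y, a, b, x] == 0.0
    ]
    return DistributionDiagnostics(
        nonnegative=bool((dist.p >= 0).all()),
        normalized=bool(np.allclose(arm_sums, 1.0, rtol=0, atol=max(tol, _NORM_TOL))),
        arm_sums=arm_sums,
        zero_cells=zero,
    )


def dichotomize(values: Iterable[float], threshold: float, direction: str = ">=") -> np.ndarray:
    """Cut a numeric sequence at ``threshold`` into 0/1.

    ``direction`` controls the tie side: ``">="`` (default) maps the
    threshold itself to 1, ``">"`` maps it to 0.
    """
    if direction not in (">=", ">"):
        raise CodingError(f"direction must be '>=' or '>', got {direction!r}")
    if not np.isfinite(threshold):
        raise CodingError("threshold must be finite")
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float)
    if arr.size and not np.isfinite(arr).all():
        raise CodingError("non-finite value in input to dichotomize")
    if direction == ">=":
        return (arr >= threshold).astype(np.int8)
    return (arr > threshold).astype(np.int8)
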