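"""Domain types and table I/O for covariate-aware multiple testing.

A hypothesis test is a (p-value, covariate) pair.  The raw covariate (basepair
distance, read depth, ...) is mapped to the informative variable ``z`` on the
uniform scale by rank-based quantile normalization, so every downstream
estimator can assume Z ~ Uniform(0,1).

The canonical in-memory container is :class:`Dataset`, a thin frozen wrapper
around numpy arrays aligned by test index; :meth:`Dataset.to_frame` exposes the
same data as a pandas DataFrame.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import (
    AlignmentError,
    InvalidInputError,
    SchemaError,
    ValidationError,
)

#: clamping width for p-values at the boundary, keeps probit transforms finite
EPS_P = 1e-15

#: tolerance within which out-of-range p-values are clamped rather than rejected
P_CLAMP_TOL = 1e-6

DEFAULT_COLUMNS = {"id": "id", "p": "pvalue", "covariate": "covariate"}


def quantile_normalize(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Map raw covariate values to the Uniform(0,1) scale by average ranks.

    Returns ``(rank_i - 0.5) / m`` with average ranks under ties, so the output
    lies strictly inside (0,1), is order-preserving on distinct values, and is
    invariant to any strictly monotone transform of the input.

    Parameters
    ----------
    values
        At least two finite real numbers.

    Raises
    ------
    InvalidInputError
        If fewer than two values are given or any value is non-finite.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size < 2:
        raise InvalidInputError(
            f"quantile normalization needs at least 2 values, got {arr.size}"
        )
    if not np.all(np.isfinite(arr)):
        raise InvalidInputError("covariate values must be finite")
    ranks = rankdata(arr, method="average")
    return (ranks - 0.5) / arr.size


@dataclass(frozen=True)
class TestRecord:
    """One hypothesis test.

    ``h`` is the true status (0 null, 1 alternative) and is populated only by
    the simulator.
    """

    id: str
    p: float
    z_raw: float
    z: float
    h: int | None = None


@dataclass(frozen=True)
class Dataset:
    """An ordered collection of hypothesis tests with aligned per-test arrays."""

    ids: np.ndarray
    p: np.ndarray
    z_raw: np.ndarray
    z: np.ndarray
    h: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = len(self.ids)
        for name in ("p", "z_raw", "z"):
            if len(getattr(self, name)) != m:
                raise AlignmentError(f"column '{name}' has length != {m}")
        if self.h is not None and len(self.h) != m:
            raise AlignmentError(f"column 'h' has length != {m}")
        if len(np.unique(self.ids)) != m:
            raise ValidationError("test ids must be unique")

    @property
    def m(self) -> int:
        return len(self.ids)

    def __len__(self) -> int:
        return self.m

    def record(self, i: int) -> TestRecord:
        return TestRecord(
            id=str(self.ids[i]),
            p=float(self.p[i]),
            z_raw=float(self.z_raw[i]),
            z=float(self.z[i]),
            h=None if self.h is None else int(self.h[i]),
        )

    def to_frame(self) -> pd.DataFrame:
        data = {"id": self.ids, "pvalue": self.p, "covariate": self.z_raw, "z": self.z}
        if self.h is not None:
            data["truth"] = self.h
        return pd.DataFrame(data)

    @classmethod
    def from_arrays(
        cls,
        p: np.ndarray,
        z_raw: np.ndarray,
        ids: Sequence[str] | None = None,
        h: np.ndarray | None = None,
    ) -> "Dataset":
        """Build a dataset from p-values and a raw covariate.

        The covariate is quantile normalized to produce ``z``; p-values are
        validated and boundary values clamped to ``[EPS_P, 1 - EPS_P]``.
        """
        p = np.asarray(p, dtype=float)
        z_raw = np.asarray(z_raw, dtype=float)
        p = _validate_pvalues(p)
        z = quantile_normalize(z_raw)
        if ids is None:
            ids = np.array([f"t{i}" for i in range(len(p))])
        else:
            ids = np.asarray(ids)
        if h is not None:
            h = np.asarray(h, dtype=int)
        return cls(ids=ids, p=p, z_raw=z_raw, z=z, h=h)


def _validate_pvalues(p: np.ndarray) -> np.ndarray:
    """Clamp p into [EPS_P, 1-EPS_P]; reject values outside [0,1] beyond tolerance."""
    if not np.all(np.isfinite(p)):
        bad = int(np.flatnonzero(~np.isfinite(p))[0])
        raise ValidationError(f"non-finite p-value at row {bad}")
    out_of_range = (p < -P_CLAMP_TOL) | (p > 1 + P_CLAMP_TOL)
    if np.any(out_of_range):
        bad = int(np.flatnonzero(out_of_range)[0])
        raise ValidationError(
            f"p-value {p[bad]!r} at row {bad} outside [0,1] beyond tolerance "
            f"{P_CLAMP_TOL}"
        )
    return np.clip(p, EPS_P, 1.0 - EPS_P)


def read_tests(
    path,
    id_col: str = "id",
    p_col: str = "pvalue",
    covariate_col: str = "covariate",
    truth_col: str = "truth",
) -> Dataset:
    """Read a tab-separated table of tests and quantile-normalize the covariate.

    The file must have a header naming at least the id, p-value and covariate
    columns; an optional 0/1 ``truth`` column is carried through (useful for
    simulation round-trips).  Rows keep file order.
    """
    df = pd.read_csv(path, sep="\t")
    for col in (id_col, p_col, covariate_col):
        if col not in df.columns:
            raise SchemaError(f"input table {path} is missing column '{col}'")
    if len(df) == 0:
        raise InvalidInputError(f"input table {path} has a header but no rows")
    h = None
    if truth_col in df.columns:
        h = df[truth_col].to_numpy(dtype=int)
    return Dataset.from_arrays(
        p=df[p_col].to_numpy(dtype=float),
        z_raw=df[covariate_col].to_numpy(dtype=float),
        ids=df[id_col].astype(str).to_numpy(),
        h=h,
    )


def write_results(path, dataset: Dataset, result) -> None:
    """Write per-test results as a TSV.

    Columns: ``id, pvalue, z, pi0, lfdr, qvalue, significant``.  Numeric values
    are written with 12 significant digits so a read/write cycle is lossless at
    that precision.

    Parameters
    ----------
    path
        Output file path.
    dataset
        The tests, aligned by index with ``result``.
    result
        An :class:`~funcfdr.core.FfdrResult`.
    """
    if len(result.r) != dataset.m:
        raise AlignmentError(
            f"result has {len(result.r)} tests but dataset has {dataset.m}"
        )
    df = pd.DataFrame(
        {
            "id": dataset.ids,
            "pvalue": dataset.p,
            "z": dataset.z,
            "pi0": result.pi0_at_z,
            "lfdr": result.r,
            "qvalue": result.q,
            "significant": result.significant.astype(int),
        }
    )
    try:
        df.to_csv(path, sep="\t", index=False, float_format="%.12g")
    except OSError as exc:
        raise OSError(f"cannot write results to {path}: {exc}") from exc
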