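"""Min-max normalization and train/test splitting.

Features are rescaled column-wise to [0, 1] using the training-set extrema:

    y_norm = (y - min) / (max - min)

Constant columns map to 0 (the formula is 0/0 there) and values outside the
training extrema are clipped, so the [0, 1] contract holds at predict time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "NormalizationParams",
    "fit_minmax",
    "apply_minmax",
    "invert_minmax",
    "split_train_test",
]


@dataclass(frozen=True)
class NormalizationParams:
    """Per-column extrema of the training data."""

    minimum: np.ndarray
    maximum: np.ndarray
    column_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        mn = np.asarray(self.minimum, dtype=float)
        mx = np.asarray(self.maximum, dtype=float)
        if mn.shape != mx.shape or mn.ndim != 1:
            raise ValueError("minimum and maximum must be 1-D vectors of equal length")
        if np.any(mx < mn):
            raise ValueError("maximum must be >= minimum element-wise")
        object.__setattr__(self, "minimum", mn)
        object.__setattr__(self, "maximum", mx)

    def to_dict(self) -> dict:
        return {
            "minimum": self.minimum.tolist(),
            "maximum": self.maximum.tolist(),
            "column_names": list(self.column_names) if self.column_names else None,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        cols = tuple(d["column_names"]) if d.get("column_names") else None
        return cls(np.asarray(d["minimum"], float), np.asarray(d["maximum"], float), cols)


def _as_matrix(data) -> tuple[np.ndarray, tuple[str, ...] | None]:
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(dtype=float), tuple(map(str, data.columns))
    arr = np.asarray(data, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    return arr, None


def fit_minmax(data) -> NormalizationParams:
    """Record column-wise extrema of the training data.

    Raises ``ValueError`` on any non-finite value.
    """
    arr, cols = _as_matrix(data)
    if arr.size == 0:
        raise ValueError("cannot fit normalization on empty data")
    if not np.all(np.isfinite(arr)):
        raise ValueError("non-finite values in data; impute or drop before normalizing")
    return NormalizationParams(arr.min(axis=0), arr.max(axis=0), cols)


def apply_minmax(data, params: NormalizationParams):
    """Rescale each column to [0, 1] with the fitted extrema.

    Constant columns map to 0; out-of-range values are clipped.
    Returns the same container type as ``data`` (DataFrame in, DataFrame out).
    """
    arr, cols = _as_matrix(data)
    if arr.shape[1] != params.minimum.shape[0]:
        raise ValueError(
            f"column count {arr.shape[1]} does not match fitted params "
            f"({params.minimum.shape[0]} columns)"
        )
    span = params.maximum - params.minimum
    out = np.zeros_like(arr)
    nz = span > 0
    out[:, nz] = (arr[:, nz] - params.minimum[nz]) / span[nz]
    np.clip(out, 0.0, 1.0, out=out)
    if isinstance(data, pd.DataFrame):
        return pd.DataFrame(out, columns=data.columns, index=data.index)
    return out


def invert_minmax(normalized, params: NormalizationParams):
    """Map [0, 1] values back to the original scale (inverse of apply_minmax)."""
    arr, _ = _as_matrix(normalized)
    out = params.minimum + arr * (params.maximum - params.minimum)
    if isinstance(normalized, pd.DataFrame):
        return pd.DataFrame(out, columns=normalized.columns, index=normalized.index)
    return out


def split_train_test(
    n: int,
    test_fraction: float,
    seed: int,
    labels=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test index partition.

    Parameters
    ----------
    n : number of rows.
    test_fraction : fraction held out, in (0, 1); test size is round(n * f).
    seed : RNG seed; identical seeds give identical partitions.
    labels : optional label vector; when given the split is stratified, with
        class proportions preserved within one record per class.

    Returns (train_idx, test_idx), both sorted.
    """
    if n < 2:
        raise ValueError("need at least 2 rows to split")
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    if labels is None:
        n_test = int(round(n * test_fraction))
        n_test = min(max(n_test, 1), n - 1)
        perm = rng.permutation(n)
        test = np.sort(perm[:n_test])
        train = np.sort(perm[n_test:])
        return train, test

    labels = np.asarray(labels)
    if labels.shape[0] != n:
        raise ValueError("labels length must equal n")
    test_parts: list[np.ndarray] = []
    # fractional test counts are apportioned largest-remainder so that the
    # total matches round(n * f) while every class stays within +/-1 record
    classes, inv = np.unique(labels, return_inverse=True)
    counts = np.bincount(inv)
    if np.any(counts < 2):
        bad = classes[counts < 2]
        raise ValueError(f"stratified split requires >= 2 members per class; offending: {bad}")
    ideal = counts * test_fraction
    base = np.floor(ideal).astype(int)
    short = int(round(n * test_fraction)) - base.sum()
    order = np.argsort(-(ideal - base), kind="stable")
    for k in order[: max(short, 0)]:
        base[k] += 1
    base = np.clip(base, 1, counts - 1)
    for ci in range(classes.size):
        members = np.flatnonzero(inv == ci)
        perm = rng.permutation(members.size)
        test_parts.append(members[perm[: base[ci]]])
    test = np.sort(np.concatenate(test_parts))
    mask = np.ones(n, dtype=bool)
    mask[test] = False
    return np.flatnonzero(mask), test
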