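"""Triangular low/medium/high fuzzification and fuzzy-entropy split gains.

Each feature gets three triangular membership functions anchored at the
training minimum, median and maximum:

    low    = (min, min, median)    — 1 at the minimum, 0 at the median
    medium = (min, median, max)    — peak at the median
    high   = (median, max, max)    — 0 at the median, 1 at the maximum

which form a partition of unity on [min, max]. Fuzzy entropy replaces
crisp class counts with summed membership degrees, and the fuzzy gain of a
feature is the entropy drop across its membership-weighted partition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FeatureTerms", "FuzzyTermSet", "fit_fuzzy_terms", "fuzzy_entropy", "fuzzy_gain"]

TERM_NAMES = ("low", "medium", "high")


def _triangle(x: np.ndarray, left: float, peak: float, right: float) -> np.ndarray:
    """Triangular membership with degenerate shoulders handled as steps."""
    y = np.zeros_like(x, dtype=float)
    if peak > left:
        rising = (x > left) & (x <= peak)
        y[rising] = (x[rising] - left) / (peak - left)
    else:
        y[x <= peak] = 1.0
    if right > peak:
        falling = (x > peak) & (x < right)
        y[falling] = (right - x[falling]) / (right - peak)
    else:
        y[x >= peak] = 1.0
    y[x == peak] = 1.0
    return y


@dataclass(frozen=True)
class FeatureTerms:
    """Fuzzified description of one feature.

    kind is "three" (low/medium/high), "two" (low/high fallback for
    features with only two distinct values) or "constant" (one always-on
    medium term; produces no split candidates).
    """

    minimum: float
    peak: float
    maximum: float
    kind: str = "three"

    @property
    def term_names(self) -> tuple[str, ...]:
        return {"three": TERM_NAMES, "two": ("low", "high"), "constant": ("medium",)}[self.kind]

    def membership(self, x: np.ndarray) -> np.ndarray:
        """n x n_terms membership matrix; rows sum to 1 on [min, max]."""
        x = np.clip(np.asarray(x, float), self.minimum, self.maximum)
        if self.kind == "constant":
            return np.ones((x.shape[0], 1))
        if self.kind == "two":
            hi = np.zeros_like(x) if self.maximum == self.minimum else (
                (x - self.minimum) / (self.maximum - self.minimum))
            return np.column_stack([1.0 - hi, hi])
        lo = _triangle(x, self.minimum, self.minimum, self.peak)
        md = _triangle(x, self.minimum, self.peak, self.maximum)
        hi = _triangle(x, self.peak, self.maximum, self.maximum)
        # at the anchors two triangles can both report 1; renormalize
        total = lo + md + hi
        return np.column_stack([lo, md, hi]) / total[:, None]

    def thresholds(self) -> list[tuple[str, float]]:
        """Crisp 0.5-membership crossings usable as split thresholds.

        low crosses 0.5 halfway up its slope at (min+peak)/2; high at
        (peak+max)/2; medium's falling crossing coincides with high's.
        """
        if self.kind == "constant":
            return []
        if self.kind == "two":
            t = 0.5 * (self.minimum + self.maximum)
            return [("low", t), ("high", t)]
        return [
            ("low", 0.5 * (self.minimum + self.peak)),
            ("medium", 0.5 * (self.peak + self.maximum)),
            ("high", 0.5 * (self.peak + self.maximum)),
        ]

    def to_dict(self) -> dict:
        return {"minimum": self.minimum, "peak": self.peak,
                "maximum": self.maximum, "kind": self.kind}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureTerms":
        return cls(float(d["minimum"]), float(d["peak"]), float(d["maximum"]), d["kind"])


@dataclass(frozen=True)
class FuzzyTermSet:
    """Per-feature fuzzification of a training matrix."""

    features: tuple[FeatureTerms, ...]

    def membership(self, X: np.ndarray, feature: int) -> np.ndarray:
        return self.features[feature].membership(np.asarray(X, float)[:, feature])

    def to_dict(self) -> dict:
        return {"features": [f.to_dict() for f in self.features]}

    @classmethod
    def from_dict(cls, d: dict) -> "FuzzyTermSet":
        return cls(tuple(FeatureTerms.from_dict(f) for f in d["features"]))


def fit_fuzzy_terms(X: np.ndarray) -> FuzzyTermSet:
    """Anchor low/medium/high triangles at each column's min/median/max.

    Columns with two distinct values fall back to a two-term low/high ramp;
    constant columns get a single always-on term. A median equal to an
    extremum (heavily skewed data) is nudged to the range midpoint so the
    triangles stay non-degenerate.
    """
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("X must be a non-empty 2-D matrix")
    feats = []
    for j in range(X.shape[1]):
        col = X[:, j]
        lo, hi = float(col.min()), float(col.max())
        n_distinct = np.unique(col).size
        if n_distinct == 1:
            feats.append(FeatureTerms(lo, lo, hi, "constant"))
            continue
        if n_distinct == 2:
            feats.append(FeatureTerms(lo, 0.5 * (lo + hi), hi, "two"))
            continue
        med = float(np.median(col))
        if not lo < med < hi:
            med = 0.5 * (lo + hi)
        feats.append(FeatureTerms(lo, med, hi, "three"))
    return FuzzyTermSet(tuple(feats))


def fuzzy_entropy(masses, sign: str = "conventional") -> float:
    """Entropy of per-class membership masses, in bits.

    q_s = mass_s / total; conventional returns -sum q log2 q, as_printed
    returns +sum q log2 q (the sign-flipped variant kept for fidelity
    experiments). 0 log 0 = 0.
    """
    m = np.asarray(masses, float)
    if np.any(m < 0):
        raise ValueError("membership masses must be non-negative")
    total = m.sum()
    if total <= 0:
        raise ValueError("total membership mass must be positive")
    q = m[m > 0] / total
    h = float(-(q * np.log2(q)).sum())
    if sign == "conventional":
        return h
    if sign == "as_printed":
        return -h
    raise ValueError(f"unknown entropy sign mode: {sign!r}")


def fuzzy_gain(parent_masses, branch_masses, sign: str = "conventional") -> float:
    """Entropy drop of a fuzzy partition: M = G(parent) - sum_k q_k G(branch_k).

    q_k weighs each branch by its share of the total branch mass. Branch
    masses must add back to the parent masses (partition of unity makes
    fuzzy masses additive).
    """
    parent = np.asarray(parent_masses, float)
    branches = [np.asarray(b, float) for b in branch_masses]
    total = sum(b.sum() for b in branches)
    if total <= 0:
        raise ValueError("zero total branch mass")
    recon = np.sum(branches, axis=0)
    if np.max(np.abs(recon - parent)) > 1e-9 * max(1.0, parent.sum()):
        raise ValueError("branch masses do not add up to the parent masses")
    g = fuzzy_entropy(parent, sign)
    for b in branches:
        bs = b.sum()
        if bs > 0:
            g -= (bs / total) * fuzzy_entropy(b, sign)
    return g
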