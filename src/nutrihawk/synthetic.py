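"""Synthetic anthropometric data with known ground truth.

Two generators cover the two table shapes the pipeline consumes:

* child-level cohorts — one row per child (age, sex, height, weight, MUAC,
  residence, income) with weight-for-height, height-for-age and
  weight-for-age z-scores and a nutritional-status label derived from the
  WHO-convention z-score thresholds;
* country-level prevalence tables — one row per country (income index plus
  wasting / severe wasting / overweight / stunting / underweight
  prevalences) drawn from separated Gaussian blobs with a retained
  ground-truth cluster id, for clustering-recovery experiments.

Labels follow a fixed severity-first priority so each child gets exactly one
class even when several thresholds fire at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LABELS",
    "MALNUTRITION_LABELS",
    "CohortSpec",
    "assign_nutrition_label",
    "generate_child_cohort",
    "generate_prevalence_table",
]

#: Label universe in priority order (most severe first); ``adequate`` is the
#: residual class for children clearing every threshold.
MALNUTRITION_LABELS = ("severe_wasting", "wasting", "underweight", "stunting", "overweight")
LABELS = MALNUTRITION_LABELS + ("adequate",)

COHORT_COLUMNS = (
    "age_months", "sex", "height_cm", "weight_kg", "muac_cm", "residence",
    "income_index", "z_wfh", "z_hfa", "z_wfa", "label",
)

PREVALENCE_COLUMNS = (
    "country_id", "income_level", "wasting_pct", "severe_wasting_pct",
    "overweight_pct", "stunting_pct", "underweight_pct",
)


def assign_nutrition_label(z_wfh: float, z_hfa: float, z_wfa: float) -> str:
    """Classify one child from three growth-standard z-scores.

    Thresholds (WHO convention): severe wasting z_wfh < -3, wasting
    z_wfh < -2, underweight z_wfa < -2, stunting z_hfa < -2, overweight
    z_wfh > +2; otherwise adequate. When several conditions hold the most
    severe wins, in the order severe_wasting > wasting > underweight >
    stunting > overweight.
    """
    zs = (z_wfh, z_hfa, z_wfa)
    if not all(np.isfinite(z) for z in zs):
        raise ValueError(f"z-scores must be finite, got {zs}")
    if z_wfh < -3:
        return "severe_wasting"
    if z_wfh < -2:
        return "wasting"
    if z_wfa < -2:
        return "underweight"
    if z_hfa < -2:
        return "stunting"
    if z_wfh > 2:
        return "overweight"
    return "adequate"


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for a synthetic child cohort.

    class_mixture maps each label to its sampling probability (must sum
    to 1); noise_sd is the within-class spread of the z-scores.
    """

    n_records: int
    class_mixture: dict[str, float] = field(
        default_factory=lambda: {lab: 1.0 / len(LABELS) for lab in LABELS}
    )
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_records <= 0:
            raise ValueError("n_records must be positive")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        unknown = set(self.class_mixture) - set(LABELS)
        if unknown:
            raise ValueError(f"unknown labels in mixture: {sorted(unknown)}")
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"class_mixture must sum to 1, got {total}")


def _truncated_normal(rng, mean, sd, low, high, size):
    """Rejection-sampled N(mean, sd) restricted to (low, high)."""
    out = np.empty(size)
    pending = np.arange(size)
    for _ in range(1000):
        draw = rng.normal(mean, sd, size=pending.size)
        ok = (draw > low) & (draw < high)
        out[pending[ok]] = draw[ok]
        pending = pending[~ok]
        if pending.size == 0:
            return out
    # pathological mean/sd vs bounds: pin stragglers just inside the interval
    eps = 1e-6 * max(1.0, abs(high - low) if np.isfinite(high - low) else 1.0)
    out[pending] = np.clip(rng.normal(mean, sd, pending.size),
                           low + eps if np.isfinite(low) else -np.inf,
                           high - eps if np.isfinite(high) else np.inf)
    return out


# class-conditional z-score recipes: (mean, (low, high)) per z dimension,
# chosen so the sampled scores satisfy the label's own threshold and never
# trip a higher-priority one
_Z_RECIPES = {
    "severe_wasting": {"z_wfh": (-3.6, (-np.inf, -3.0)), "z_hfa": (0.0, None), "z_wfa": (-1.0, None)},
    "wasting": {"z_wfh": (-2.5, (-3.0, -2.0)), "z_hfa": (0.0, None), "z_wfa": (-1.0, None)},
    "underweight": {"z_wfh": (0.0, (-2.0, 2.0)), "z_hfa": (-1.0, None), "z_wfa": (-2.6, (-np.inf, -2.0))},
    "stunting": {"z_wfh": (0.0, (-2.0, 2.0)), "z_hfa": (-2.6, (-np.inf, -2.0)), "z_wfa": (0.0, (-2.0, np.inf))},
    "overweight": {"z_wfh": (2.6, (2.0, np.inf)), "z_hfa": (0.5, (-2.0, np.inf)), "z_wfa": (0.5, (-2.0, np.inf))},
    "adequate": {"z_wfh": (0.0, (-2.0, 2.0)), "z_hfa": (0.0, (-2.0, np.inf)), "z_wfa": (0.0, (-2.0, np.inf))},
}


def _reference_growth(age_months: np.ndarray, is_male: np.ndarray):
    """Internal growth reference: medians/SDs of height and weight by age/sex.

    Monotone in age by construction; a stand-in curve, not the WHO tables.
    """
    a = age_months.astype(float)
    h_med = 50.0 + 0.95 * a - 0.004 * a ** 2 + np.where(is_male, 0.7, 0.0)
    h_sd = 2.0 + 0.02 * a
    w_med = 3.3 + 0.28 * a - 0.0018 * a ** 2 + np.where(is_male, 0.15, 0.0)
    w_sd = 0.45 + 0.016 * a
    return h_med, h_sd, w_med, w_sd


def generate_child_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Sample a labelled child cohort following the given class mixture.

    z-scores come from class-conditional truncated Gaussians whose means sit
    beyond the label's threshold; height and weight are back-computed from
    z_hfa / z_wfa against the internal growth reference, and MUAC tracks
    z_wfh around a 13.5 cm centre. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    labels = np.array(LABELS)
    probs = np.array([spec.class_mixture.get(lab, 0.0) for lab in LABELS])
    label_idx = rng.choice(len(LABELS), size=spec.n_records, p=probs)

    n = spec.n_records
    z = {k: np.empty(n) for k in ("z_wfh", "z_hfa", "z_wfa")}
    for li, lab in enumerate(LABELS):
        rows = np.flatnonzero(label_idx == li)
        if rows.size == 0:
            continue
        for zname, (mean, bounds) in _Z_RECIPES[lab].items():
            lo, hi = bounds if bounds is not None else (-np.inf, np.inf)
            z[zname][rows] = _truncated_normal(rng, mean, spec.noise_sd, lo, hi, rows.size)

    age = rng.integers(0, 60, size=n)
    is_male = rng.random(n) < 0.5
    h_med, h_sd, w_med, w_sd = _reference_growth(age, is_male)
    height = np.maximum(h_med + z["z_hfa"] * h_sd, 35.0)
    weight = np.maximum(w_med + z["z_wfa"] * w_sd, 1.2)
    muac = np.maximum(13.5 + 1.1 * z["z_wfh"] + rng.normal(0, 0.2, n), 6.0)

    df = pd.DataFrame({
        "age_months": age,
        "sex": np.where(is_male, "male", "female"),
        "height_cm": height,
        "weight_kg": weight,
        "muac_cm": muac,
        "residence": np.where(rng.random(n) < 0.5, "rural", "urban"),
        "income_index": rng.random(n),
        "z_wfh": z["z_wfh"],
        "z_hfa": z["z_hfa"],
        "z_wfa": z["z_wfa"],
        "label": labels[label_idx],
    })
    # the sampled scores must reproduce their own label; guards recipe drift
    check = [assign_nutrition_label(a, b, c) for a, b, c in zip(df.z_wfh, df.z_hfa, df.z_wfa)]
    assert (df.label == check).all()
    return df


def generate_prevalence_table(
    n_countries: int,
    n_clusters: int,
    separation: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Country-level prevalence table drawn from separated Gaussian blobs.

    Blobs live in the 6-D (income, wasting, severe wasting, overweight,
    stunting, underweight) space; centers are at least ``separation`` times
    the within-blob standard deviation apart. The true blob id is kept in a
    ``true_cluster`` column and the centers (output units) in
    ``df.attrs["centers"]``.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_countries < n_clusters:
        raise ValueError("need at least one country per cluster")
    if separation <= 0:
        raise ValueError("separation must be positive")

    rng = np.random.default_rng(seed)
    # standardized space: unit within-blob sd per dim; margin keeps blobs
    # 4 sd clear of the physical bounds so clipping is negligible
    sds = np.array([0.03, 1.5, 1.5, 1.5, 1.5, 1.5])  # income, then 5 pcts
    upper = np.array([1.0, 100.0, 100.0, 100.0, 100.0, 100.0]) / sds
    margin = 4.0
    box_lo, box_hi = margin, upper - margin

    centers = np.empty((n_clusters, 6))
    k = 0
    for _ in range(20000):
        cand = rng.uniform(box_lo, box_hi)
        if cand[2] > cand[1] - 6.0:  # severe-wasting center well below wasting
            continue
        if k and np.min(np.linalg.norm(centers[:k] - cand, axis=1)) < separation:
            continue
        centers[k] = cand
        k += 1
        if k == n_clusters:
            break
    if k < n_clusters:
        raise RuntimeError(
            f"could not place {n_clusters} centers {separation} sd apart; "
            "reduce separation or n_clusters"
        )

    # round-robin so every cluster is populated, then random remainder
    assign = np.concatenate([
        np.tile(np.arange(n_clusters), n_countries // n_clusters),
        rng.choice(n_clusters, size=n_countries % n_clusters, replace=False)
        if n_countries % n_clusters else np.empty(0, int),
    ])
    rng.shuffle(assign)
    pts = centers[assign] + rng.normal(size=(n_countries, 6))
    pts = np.clip(pts * sds, 0.0, [1.0, 100, 100, 100, 100, 100])
    pts[:, 2] = np.minimum(pts[:, 2], pts[:, 1])  # severe_wasting <= wasting

    df = pd.DataFrame({
        "country_id": [f"C{i + 1:03d}" for i in range(n_countries)],
        "income_level": pts[:, 0],
        "wasting_pct": pts[:, 1],
        "severe_wasting_pct": pts[:, 2],
        "overweight_pct": pts[:, 3],
        "stunting_pct": pts[:, 4],
        "underweight_pct": pts[:, 5],
        "true_cluster": assign,
    })
    df.attrs["centers"] = centers * sds
    return df
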