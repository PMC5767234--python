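"""Induced-feature detection by co-culture vs mono-culture comparison.

A feature is *newly synthesized* when it is detected (above the instrument
detection floor in at least 2 of 3 biological replicates) in the co-culture
but stays below the floor in both control mono-cultures, and *fold increased*
when its co-culture group mean is at least ``fold_threshold`` times the
larger of the two mono-culture group means.  The two classes are disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "InducedFeature",
    "fold_change",
    "detect_induced",
    "DETECTION_FLOOR",
    "FOLD_THRESHOLD",
]

#: MS signal-intensity detection threshold (counts)
DETECTION_FLOOR = 1.0e3
#: default fold-increase threshold (ratio of group means)
FOLD_THRESHOLD = 5.0

GROUPS = ("co", "monoA", "monoB")


@dataclass
class FeatureMatrix:
    """Features x samples intensity matrix with sample and feature metadata.

    ``intensities`` is indexed by feature id with one column per sample;
    ``samples`` carries per-sample ``group`` (co / monoA / monoB),
    ``bio_rep`` and ``ana_rep``; ``features`` carries per-feature m/z, RT,
    polarity and optionally a formula string.
    """

    intensities: pd.DataFrame
    samples: pd.DataFrame
    features: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.intensities.to_numpy() < 0).any():
            raise ValueError("intensities must be non-negative")
        if "group" not in self.samples.columns:
            raise ValueError("sample metadata must include a 'group' column")
        missing = set(self.intensities.columns) - set(self.samples.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")

    def group_columns(self, group: str) -> list[str]:
        return list(self.samples.index[self.samples["group"] == group])

    def bio_replicate_means(self, feature_id: str, group: str) -> np.ndarray:
        """Mean intensity per biological replicate (analytical reps averaged)."""
        cols = self.group_columns(group)
        sub = self.samples.loc[cols]
        vals = self.intensities.loc[feature_id, cols]
        return (
            pd.Series(vals.to_numpy(), index=sub["bio_rep"].to_numpy())
            .groupby(level=0)
            .mean()
            .to_numpy()
        )


@dataclass
class InducedFeature:
    """A feature induced by the co-culture, with class and fold statistics."""

    feature_id: str
    induction_class: str  # "newly_synthesized" | "fold_increased"
    fold: float | None
    fold_sd: float | None
    co_mean: float


def fold_change(
    co: np.ndarray, mono: np.ndarray, detection_floor: float = DETECTION_FLOOR
) -> tuple[float, float]:
    """Fold change of co-culture over mono-culture replicate intensities.

    Returns the ratio of group means and the standard deviation across
    per-biological-replicate ratios.  If the mono-culture mean is below the
    detection floor the ratio is undefined (the feature belongs on the
    newly-synthesized path) and a ValueError is raised.
    """
    co = np.asarray(co, dtype=float)
    mono = np.asarray(mono, dtype=float)
    if mono.mean() <= detection_floor:
        raise ValueError(
            "mono-culture mean below detection floor; feature is newly synthesized"
        )
    ratio = co.mean() / mono.mean()
    k = min(len(co), len(mono))
    per_rep = co[:k] / mono[:k]
    sd = float(np.std(per_rep, ddof=1)) if k > 1 else 0.0
    return float(ratio), sd


def detect_induced(
    fm: FeatureMatrix,
    fold_threshold: float = FOLD_THRESHOLD,
    detection_floor: float = DETECTION_FLOOR,
    min_detected_reps: int = 2,
) -> list[InducedFeature]:
    """Detect co-culture-induced features in a three-group feature matrix."""
    for g in GROUPS:
        if not fm.group_columns(g):
            raise ValueError(f"feature matrix is missing group {g!r}")
    # per-group biological-replicate means, all features at once
    rep_means: dict[str, np.ndarray] = {}
    for g in GROUPS:
        cols = fm.group_columns(g)
        bio = fm.samples.loc[cols, "bio_rep"].to_numpy()
        vals = fm.intensities[cols].to_numpy()
        rep_means[g] = np.column_stack(
            [vals[:, bio == b].mean(axis=1) for b in np.unique(bio)]
        )
    induced: list[InducedFeature] = []
    for k, fid in enumerate(fm.intensities.index):
        co_reps = rep_means["co"][k]
        a_reps = rep_means["monoA"][k]
        b_reps = rep_means["monoB"][k]
        detected_co = int((co_reps > detection_floor).sum()) >= min_detected_reps
        if not detected_co:
            continue
        a_mean, b_mean = a_reps.mean(), b_reps.mean()
        if a_mean <= detection_floor and b_mean <= detection_floor:
            induced.append(
                InducedFeature(
                    feature_id=fid,
                    induction_class="newly_synthesized",
                    fold=None,
                    fold_sd=None,
                    co_mean=float(co_reps.mean()),
                )
            )
            continue
        # fold rule against the larger (conservative) mono-culture mean
        mono_reps = a_reps if a_mean >= b_mean else b_reps
        ratio, sd = fold_change(co_reps, mono_reps, detection_floor=0.0)
        if ratio >= fold_threshold:
            induced.append(
                InducedFeature(
                    feature_id=fid,
                    induction_class="fold_increased",
                    fold=ratio,
                    fold_sd=sd,
                    co_mean=float(co_reps.mean()),
                )
            )
    return induced
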