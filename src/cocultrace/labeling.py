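"""Natural-abundance correction and total 13C-incorporation metrics.

The relative isotopic abundance of isotopologue i is M_i = m_i / sum_j m_j
(the mass isotopomer distribution, MID).  Measured ladders are corrected for
natural heavy isotopes by solving ``C x = raw`` against the theoretical
correction matrix under a non-negativity constraint; the total
13C-incorporation of an N-carbon feature is then

    total incorporation (%) = 100 * sum_i i * M_i / N,

the carbon-number-normalized mean label content.  For a binomial labeling
model with per-carbon enrichment p this equals 100 p.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .chem import CorrectionMatrix

__all__ = [
    "MID",
    "LabelingResult",
    "relative_isotopic_abundance",
    "correct_natural_abundance",
    "total_incorporation",
    "labeling_significance",
    "steady_state_assessment",
    "abts_scavenging",
]

#: default minimum mean incorporation (%) for a feature to be called labeled;
#: guards against residual correction error being declared significant.
DEFAULT_ENRICHMENT_FLOOR = 1.0

#: relative residual above which the non-negative solve emits a warning
#: (a fit this poor suggests a wrong formula or corrupted ladder); the
#: residual itself is always recorded on the returned MID
RESIDUAL_TOL = 0.1


@dataclass
class MID:
    """Mass isotopomer distribution M0..MN of an N-carbon feature."""

    fractions: np.ndarray
    residual: float = 0.0

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if np.any(self.fractions < 0):
            raise ValueError("MID fractions must be non-negative")
        total = self.fractions.sum()
        if total <= 0:
            raise ValueError("MID undefined for an all-zero vector")
        self.fractions = self.fractions / total

    @property
    def n(self) -> int:
        return len(self.fractions) - 1


@dataclass
class LabelingResult:
    """Per-feature labeling summary for one organism/timepoint/condition."""

    feature_id: str
    group: str
    timepoint: int
    condition: str
    replicate_incorporations: list[float]
    baseline_incorporations: list[float] = field(default_factory=list)
    mids: list[MID] = field(default_factory=list)
    p_value: float | None = None
    labeled: bool = False

    @property
    def mean_incorporation(self) -> float:
        return float(np.mean(self.replicate_incorporations))

    @property
    def sd_incorporation(self) -> float:
        return float(np.std(self.replicate_incorporations, ddof=1))

    @property
    def n_replicates(self) -> int:
        return len(self.replicate_incorporations)


def relative_isotopic_abundance(raw: np.ndarray) -> MID:
    """Normalize a raw isotopologue intensity ladder to a MID."""
    return MID(np.asarray(raw, dtype=float))


def correct_natural_abundance(raw: np.ndarray, cm: CorrectionMatrix) -> MID:
    """Remove natural-isotope contributions from a measured ladder.

    Solves ``cm.matrix @ x = raw`` for x >= 0 by non-negative least squares
    (preventing the negative fractions a direct inversion produces on noisy
    data) and normalizes x to a MID.  Noiseless forward-convolved inputs are
    recovered exactly; a solve residual above tolerance is recorded on the
    returned MID and emitted as a warning.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 1 or len(raw) != cm.matrix.shape[0]:
        raise ValueError(
            f"ladder length {len(raw)} does not match correction matrix "
            f"dimension {cm.matrix.shape[0]}"
        )
    x, rnorm = optimize.nnls(cm.matrix, raw)
    scale = np.linalg.norm(raw)
    residual = rnorm / scale if scale > 0 else 0.0
    if residual > RESIDUAL_TOL:
        warnings.warn(
            f"natural-abundance correction residual {residual:.2e} above "
            f"{RESIDUAL_TOL:.0e}",
            stacklevel=2,
        )
    mid = MID(x)
    mid.residual = residual
    return mid


def total_incorporation(mid: MID) -> float:
    """Total 13C-incorporation (%) of a MID: 100 * sum(i * M_i) / N."""
    n = mid.n
    if n < 1:
        raise ValueError("total incorporation requires >= 1 carbon")
    return float(100.0 * np.dot(np.arange(n + 1), mid.fractions) / n)


def labeling_significance(
    replicate_incorporations: list[float],
    baseline_incorporations: list[float],
    alpha: float = 0.05,
    enrichment_floor: float = DEFAULT_ENRICHMENT_FLOOR,
) -> tuple[float, bool]:
    """Two-sample t-test of incorporation against an unlabeled baseline.

    Returns ``(p_value, labeled)`` where ``labeled`` requires both p < alpha
    and a mean enrichment above the baseline of at least the enrichment
    floor (%).  The floor is applied to the excess over the baseline rather
    than the absolute mean so that static interference (e.g. a co-eluting
    isobaric ladder inflating the apparent incorporation of both arms
    equally) cannot be declared labeling.  The test is two-sided with pooled
    variance.
    """
    a = np.asarray(replicate_incorporations, dtype=float)
    b = np.asarray(baseline_incorporations, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("labeling significance requires >= 2 replicates per arm")
    p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    if np.isnan(p):  # zero variance in both arms -> indistinguishable
        p = 1.0
    labeled = (p < alpha) and (a.mean() - b.mean() >= enrichment_floor)
    return p, labeled


def steady_state_assessment(
    day_early: LabelingResult, day_late: LabelingResult, alpha: float = 0.05
) -> str:
    """Classify a labeled feature's time course as steady or increasing.

    Runs a two-sample t-test between the replicate incorporations at the two
    timepoints: no significant difference means the feature has reached
    isotopic steady state by the early timepoint; a significant increase
    means labeling was still rising.  A significant decrease is physically
    anomalous and reported as such.  Unlabeled features are not applicable.
    """
    if not (day_early.labeled and day_late.labeled):
        return "not_applicable"
    a = np.asarray(day_early.replicate_incorporations, dtype=float)
    b = np.asarray(day_late.replicate_incorporations, dtype=float)
    res = stats.ttest_ind(a, b, equal_var=True)
    p = float(res.pvalue)
    if np.isnan(p) or p >= alpha:
        return "steady"
    return "increasing" if b.mean() > a.mean() else "anomalous"


def abts_scavenging(abs_sample: float, abs_blank: float) -> float:
    """ABTS radical scavenging effect (%): (1 - Abs_sample/Abs_blank) * 100."""
    if abs_blank <= 0:
        raise ValueError("blank absorbance must be positive")
    return (1.0 - abs_sample / abs_blank) * 100.0
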