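"""Equal-sensitivity/specificity cutoffs and diagnostic validity indices.

A thickness cutoff classifies an eye as glaucomatous when its (mean-index)
thickness falls *below* the cutoff, healthy when above; a value exactly at
the cutoff counts as healthy, a convention that never bites in practice
because candidate cutoffs are midpoints between distinct observed values.

The cutoff is chosen so that sensitivity and specificity are as equal and
as high as possible: among the candidate cutoffs (midpoints of consecutive
distinct pooled values, plus one candidate below the minimum and one above
the maximum), minimise |Se - Sp|, break ties by maximal Se + Sp, then by
the smallest cutoff.  Sensitivity, specificity, PPV and NPV are reported
as percentages with Wald 95% confidence intervals truncated to [0, 100].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grid import Group, Segmentation

__all__ = [
    "ConfusionCounts",
    "ProportionCI",
    "DiagnosticIndices",
    "CutoffResult",
    "classify",
    "counts_at_cutoff",
    "diagnostic_indices",
    "candidate_cutoffs",
    "choose_cutoff",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """2x2 classification counts; positives are glaucoma calls."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def n_glaucoma(self) -> int:
        return self.tp + self.fn

    @property
    def n_control(self) -> int:
        return self.tn + self.fp


@dataclass(frozen=True)
class ProportionCI:
    """A percentage with its Wald CI; ``defined`` is False on a 0 denominator."""

    value: float
    ci_low: float
    ci_high: float
    defined: bool = True


@dataclass(frozen=True)
class DiagnosticIndices:
    sensitivity: ProportionCI
    specificity: ProportionCI
    ppv: ProportionCI
    npv: ProportionCI


@dataclass(frozen=True)
class CutoffResult:
    """Chosen cutoff (um) with its confusion counts and validity indices."""

    cutoff: float
    counts: ConfusionCounts
    indices: DiagnosticIndices
    degenerate: bool = False
    segmentation: Segmentation | None = None


def classify(index_value: float, cutoff: float) -> Group:
    """Below the cutoff -> glaucoma; at or above the cutoff -> healthy."""
    return Group.GLAUCOMA if index_value < cutoff else Group.CONTROL


def counts_at_cutoff(
    control_values: np.ndarray, glaucoma_values: np.ndarray, cutoff: float
) -> ConfusionCounts:
    control = np.asarray(control_values, dtype=float)
    glaucoma = np.asarray(glaucoma_values, dtype=float)
    tp = int(np.sum(glaucoma < cutoff))
    fp = int(np.sum(control < cutoff))
    return ConfusionCounts(
        tp=tp, fp=fp, tn=len(control) - fp, fn=len(glaucoma) - tp
    )


def _wald_pct(k: int, n: int, ci_level: float) -> ProportionCI:
    if n == 0:
        return ProportionCI(float("nan"), float("nan"), float("nan"), defined=False)
    p = k / n
    z = float(stats.norm.ppf(0.5 + ci_level / 2.0))
    half = z * np.sqrt(p * (1.0 - p) / n)
    return ProportionCI(
        value=100.0 * p,
        ci_low=float(np.clip(100.0 * (p - half), 0.0, 100.0)),
        ci_high=float(np.clip(100.0 * (p + half), 0.0, 100.0)),
    )


def diagnostic_indices(
    counts: ConfusionCounts, ci_level: float = 0.95
) -> DiagnosticIndices:
    """Se, Sp, PPV, NPV (%) with Wald CIs.

    Denominators: Se over all glaucoma eyes, Sp over all control eyes,
    PPV over positive calls (tp + fp), NPV over negative calls (tn + fn).
    A zero PPV/NPV denominator yields an undefined (flagged) value.
    """
    if counts.n_glaucoma == 0 or counts.n_control == 0:
        raise ValueError("both groups must be non-empty")
    return DiagnosticIndices(
        sensitivity=_wald_pct(counts.tp, counts.n_glaucoma, ci_level),
        specificity=_wald_pct(counts.tn, counts.n_control, ci_level),
        ppv=_wald_pct(counts.tp, counts.tp + counts.fp, ci_level),
        npv=_wald_pct(counts.tn, counts.tn + counts.fn, ci_level),
    )


def candidate_cutoffs(
    control_values: np.ndarray, glaucoma_values: np.ndarray
) -> np.ndarray:
    """Midpoints between consecutive distinct pooled values, extended by one
    candidate below the minimum and one above the maximum."""
    pooled = np.unique(
        np.concatenate(
            [np.asarray(control_values, float), np.asarray(glaucoma_values, float)]
        )
    )
    mids = (pooled[:-1] + pooled[1:]) / 2.0
    return np.concatenate([[pooled[0] - 1.0], mids, [pooled[-1] + 1.0]])


def choose_cutoff(
    control_values,
    glaucoma_values,
    ci_level: float = 0.95,
    segmentation: Segmentation | None = None,
) -> CutoffResult:
    """Equal-and-high sensitivity/specificity cutoff over midpoint candidates.

    Deterministic selection: minimise |Se - Sp|; among ties maximise
    Se + Sp; among remaining ties take the smallest cutoff.  Degenerate
    (flagged) when the pooled values are all identical, leaving no interior
    candidate.
    """
    control = np.asarray(control_values, dtype=float).ravel()
    glaucoma = np.asarray(glaucoma_values, dtype=float).ravel()
    if control.size == 0 or glaucoma.size == 0:
        raise ValueError("both groups must be non-empty")
    cands = candidate_cutoffs(control, glaucoma)
    degenerate = np.unique(np.concatenate([control, glaucoma])).size == 1

    best = None
    best_key = None
    for cut in cands:
        counts = counts_at_cutoff(control, glaucoma, cut)
        se = counts.tp / counts.n_glaucoma
        sp = counts.tn / counts.n_control
        key = (abs(se - sp), -(se + sp), cut)
        if best_key is None or key < best_key:
            best_key = key
            best = (cut, counts)
    cut, counts = best
    return CutoffResult(
        cutoff=float(cut),
        counts=counts,
        indices=diagnostic_indices(counts, ci_level),
        degenerate=degenerate,
        segmentation=segmentation,
    )


def cutoff_table(results: list[CutoffResult]) -> pd.DataFrame:
    """Cutoff report: one row per segmentation with Se/Sp/PPV/NPV and CIs."""
    rows = []
    for res in results:
        ind = res.indices
        rows.append(
            {
                "segmentation": res.segmentation.value if res.segmentation else "",
                "cutoff_microns": res.cutoff,
                "specificity_pct": ind.specificity.value,
                "specificity_ci_low": ind.specificity.ci_low,
                "specificity_ci_high": ind.specificity.ci_high,
                "sensitivity_pct": ind.sensitivity.value,
                "sensitivity_ci_low": ind.sensitivity.ci_low,
                "sensitivity_ci_high": ind.sensitivity.ci_high,
                "ppv_pct": ind.ppv.value,
                "ppv_ci_low": ind.ppv.ci_low,
                "ppv_ci_high": ind.ppv.ci_high,
                "npv_pct": ind.npv.value,
                "npv_ci_low": ind.npv.ci_low,
                "npv_ci_high": ind.npv.ci_high,
                "degenerate": res.degenerate,
            }
        )
    return pd.DataFrame(rows)
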