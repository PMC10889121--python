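"""AUROC with DeLong variance and the paired DeLong test.

The AUROC here is oriented as the probability that a randomly chosen
control eye is *thicker* than a randomly chosen glaucoma eye, with ties
counted one half (the Mann-Whitney estimator with midranks).  Under this
convention glaucomatous thinning produces AUROC > 0.5, so "AUROC >= 0.70
means discriminative thinning" holds without per-cell sign flips.

Variances use DeLong's structural components (placement values): writing
``psi(x, y) = 1`` if ``x > y``, ``1/2`` if ``x == y`` and ``0`` otherwise,
the placement of control eye i is ``V_X(i) = mean_j psi(x_i, y_j)`` and of
glaucoma eye j is ``V_Y(j) = mean_i psi(x_i, y_j)``; then

    Var(AUC) = S_X / m + S_Y / n

with ``S_X``, ``S_Y`` the sample variances of the placements.  For two
markers measured on the same eyes, the difference of AUCs is tested with
the covariance of the paired placement vectors (DeLong, DeLong &
Clarke-Pearson, 1988).  Confidence intervals are Wald on the AUC scale,
truncated to [0, 1]; p-values use the standard normal reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["AurocResult", "DeLongComparison", "auroc", "delong_paired"]

_DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class AurocResult:
    """AUROC point estimate with DeLong standard error, CI and p-value.

    ``p_value`` tests H0: AUC = 0.5 (two-sided normal).  ``degenerate`` is
    set when the placement variance vanishes (e.g. all values tied), in
    which case se = 0 and p = 1.
    """

    auc: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n_neg: int  # controls
    n_pos: int  # glaucoma
    degenerate: bool = False


@dataclass(frozen=True)
class DeLongComparison:
    """Paired DeLong comparison of two markers on the same eyes."""

    auc_a: float
    auc_b: float
    z: float
    p_value: float
    degenerate: bool = False


def _placements(control: np.ndarray, glaucoma: np.ndarray):
    """Midrank placement values for AUC = P(control > glaucoma).

    Returns ``(auc, v_control, v_glaucoma)`` where ``v_control[i]`` is the
    fraction of glaucoma values below control value i (ties half) and
    ``v_glaucoma[j]`` the fraction of control values above glaucoma value j.
    """
    m, n = len(control), len(glaucoma)
    combined = np.concatenate([control, glaucoma])
    r_all = stats.rankdata(combined)  # midranks
    r_x = stats.rankdata(control)
    r_y = stats.rankdata(glaucoma)
    v_x = (r_all[:m] - r_x) / n
    v_y = 1.0 - (r_all[m:] - r_y) / m
    auc = float(np.mean(v_x))
    return auc, v_x, v_y


def _as_group(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} group is empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} group contains non-finite values")
    return arr


def auroc(control_values, glaucoma_values, ci_level: float = 0.95) -> AurocResult:
    """AUROC of thickness for control vs glaucoma eyes, with DeLong inference.

    Parameters
    ----------
    control_values, glaucoma_values
        Thickness (or index) values for the two groups; need not be equal
        length.  Orientation: AUC = P(control > glaucoma), ties half.
    ci_level
        Two-sided Wald confidence level (default 95%).
    """
    x = _as_group(control_values, "control")
    y = _as_group(glaucoma_values, "glaucoma")
    m, n = len(x), len(y)
    auc, v_x, v_y = _placements(x, y)
    s_x = float(np.var(v_x, ddof=1)) if m > 1 else 0.0
    s_y = float(np.var(v_y, ddof=1)) if n > 1 else 0.0
    var = s_x / m + s_y / n
    se = float(np.sqrt(max(var, 0.0)))
    zcrit = float(stats.norm.ppf(0.5 + ci_level / 2.0))
    if se <= _DEGENERATE_TOL:
        return AurocResult(
            auc=auc, se=0.0, ci_low=auc, ci_high=auc, p_value=1.0,
            n_neg=m, n_pos=n, degenerate=True,
        )
    z = (auc - 0.5) / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return AurocResult(
        auc=auc,
        se=se,
        ci_low=float(np.clip(auc - zcrit * se, 0.0, 1.0)),
        ci_high=float(np.clip(auc + zcrit * se, 0.0, 1.0)),
        p_value=p,
        n_neg=m,
        n_pos=n,
        degenerate=False,
    )


def delong_paired(
    control_a, glaucoma_a, control_b, glaucoma_b
) -> DeLongComparison:
    """Paired DeLong test for two markers measured on the same eyes.

    Marker A and marker B must be given in the same eye order within each
    group.  The statistic is

        z = (AUC_A - AUC_B) / sqrt(var_A + var_B - 2 cov_AB)

    with variances and covariance from the placement values.  When the
    variance of the difference vanishes (e.g. marker B is a strictly
    increasing transform of marker A), the comparison is degenerate:
    z = 0, p = 1, flag set.
    """
    xa = _as_group(control_a, "control (marker A)")
    ya = _as_group(glaucoma_a, "glaucoma (marker A)")
    xb = _as_group(control_b, "control (marker B)")
    yb = _as_group(glaucoma_b, "glaucoma (marker B)")
    if len(xa) != len(xb) or len(ya) != len(yb):
        raise ValueError(
            "paired design requires equal group lengths across markers: "
            f"controls {len(xa)} vs {len(xb)}, glaucoma {len(ya)} vs {len(yb)}"
        )
    m, n = len(xa), len(ya)
    auc_a, vxa, vya = _placements(xa, ya)
    auc_b, vxb, vyb = _placements(xb, yb)
    dvx = vxa - vxb
    dvy = vya - vyb
    var_diff = 0.0
    if m > 1:
        var_diff += float(np.var(dvx, ddof=1)) / m
    if n > 1:
        var_diff += float(np.var(dvy, ddof=1)) / n
    if var_diff <= _DEGENERATE_TOL:
        if abs(auc_a - auc_b) <= _DEGENERATE_TOL:
            # identical placements (e.g. monotone transform): no evidence
            return DeLongComparison(
                auc_a=auc_a, auc_b=auc_b, z=0.0, p_value=1.0, degenerate=True
            )
        # zero-variance difference with unequal AUCs (perfect separation in
        # opposite directions): the difference is deterministic
        z = math.inf if auc_a > auc_b else -math.inf
        return DeLongComparison(
            auc_a=auc_a, auc_b=auc_b, z=z, p_value=0.0, degenerate=False
        )
    z = (auc_a - auc_b) / float(np.sqrt(var_diff))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return DeLongComparison(auc_a=auc_a, auc_b=auc_b, z=z, p_value=p, degenerate=False)
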