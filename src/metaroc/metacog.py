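"""Response-conditional type-2 ROC curves and auROC2.

Metacognitive sensitivity is quantified by the area under the
response-conditional type-2 ROC (rc-ROC): for the trials sharing one
response, the cumulative distribution of confidence ratings (high to low)
on correct trials is plotted against the same cumulative distribution on
incorrect trials.  An area of 0.5 means confidence carries no information
about accuracy; 1.0 means perfect separation.  The difference between the
areas for the two responses (Delta AUC = auROC2 for S1 responses minus
auROC2 for S2 responses) is the metacognitive-asymmetry statistic.

auROC2 is always computed on the raw continuous ratings; the equal-width
20-bin assignment is provided for visualization only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "RcRocCurve",
    "AsymmetrySummary",
    "InclusionError",
    "rcroc_curve",
    "auroc2",
    "subject_asymmetry",
    "bin_confidence",
]


class InclusionError(ValueError):
    """A subject violates a precondition of the metacognitive analysis."""


@dataclass
class RcRocCurve:
    """An rc-ROC as ordered (FPR, TPR) points from (0,0) to (1,1).

    ``points[:, 0]`` is the cumulative proportion of incorrect trials at or
    above each confidence level (descending levels), ``points[:, 1]`` the
    same for correct trials; ``auc`` is the trapezoidal area.
    """

    points: np.ndarray
    auc: float
    response: str | None = None


@dataclass
class AsymmetrySummary:
    auc_s1: float
    auc_s2: float
    delta_auc: float  # auc_s1 - auc_s2


def rcroc_curve(
    confidences,
    corrects,
    response: str | None = None,
) -> RcRocCurve:
    """Build the rc-ROC from confidence ratings and per-trial correctness.

    Thresholds are the distinct confidence values in descending order;
    each point is (proportion of incorrect trials at or above the
    threshold, proportion of correct trials at or above it), with tied
    ratings sharing a single point and (0,0)/(1,1) as endpoints.

    Raises
    ------
    InclusionError
        If all trials are correct or all incorrect — the curve is
        undefined, which is exactly why the >=2-errors exclusion exists.
    """
    conf = np.asarray(confidences, dtype=float)
    corr = np.asarray(corrects, dtype=bool)
    if conf.shape != corr.shape or conf.ndim != 1:
        raise ValueError("confidences and corrects must be equal-length 1-D")
    n_corr = int(corr.sum())
    n_inc = int((~corr).sum())
    if n_corr == 0 or n_inc == 0:
        raise InclusionError(
            "rc-ROC undefined: need at least one correct and one incorrect trial"
        )
    # descending sort; cumulative at-or-above counts at each distinct level
    order = np.argsort(-conf, kind="mergesort")
    c_sorted = conf[order]
    corr_sorted = corr[order]
    cum_corr = np.cumsum(corr_sorted)
    cum_inc = np.cumsum(~corr_sorted)
    last = np.nonzero(np.diff(c_sorted, append=-1.0) != 0)[0]  # run ends (ties share a point)
    fpr = cum_inc[last] / n_inc
    tpr = cum_corr[last] / n_corr
    pts = np.column_stack([np.concatenate([[0.0], fpr]), np.concatenate([[0.0], tpr])])
    if pts[-1, 0] != 1.0 or pts[-1, 1] != 1.0:
        pts = np.vstack([pts, [1.0, 1.0]])
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return RcRocCurve(points=pts, auc=auc, response=response)


def auroc2(curve: RcRocCurve) -> float:
    """Trapezoidal area under an rc-ROC.

    Equals the concordance statistic
    P(conf_correct > conf_incorrect) + 0.5 P(tie) over all correct x
    incorrect trial pairs — an identity property-tested in the suite.
    """
    pts = curve.points
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def subject_asymmetry(table: pd.DataFrame) -> AsymmetrySummary:
    """Delta AUC for one subject: auROC2(S1 responses) - auROC2(S2 responses).

    The subject must satisfy the inclusion rules this statistic relies on:
    at least two errors within each response category (so both curves
    exist) and at least two distinct confidence levels per response.
    """
    out = {}
    for resp in ("S1", "S2"):
        sub = table[table["response"] == resp]
        if sub["confidence"].nunique() < 2:
            raise InclusionError(
                f"too_few_confidence_levels: response {resp} has <2 distinct ratings"
            )
        n_err = int((~sub["correct"].astype(bool)).sum())
        if n_err < 2:
            raise InclusionError(
                f"too_few_errors_per_type: response {resp} has {n_err} errors"
            )
        curve = rcroc_curve(
            sub["confidence"].to_numpy(),
            sub["correct"].to_numpy(dtype=bool),
            response=resp,
        )
        out[resp] = curve.auc
    return AsymmetrySummary(
        auc_s1=out["S1"], auc_s2=out["S2"], delta_auc=out["S1"] - out["S2"]
    )


def bin_confidence(confidences, n_bins: int = 20) -> np.ndarray:
    """Assign ratings to equal-width bins spanning the subject's own range.

    Used for plotting confidence distributions only; auROC2 never touches
    the binned values.  A zero-range input collapses to a single bin with
    a warning.
    """
    conf = np.asarray(confidences, dtype=float)
    if conf.size == 0:
        raise ValueError("bin_confidence requires a non-empty list")
    lo, hi = conf.min(), conf.max()
    if hi == lo:
        warnings.warn("zero confidence range: all ratings in one bin", stacklevel=2)
        return np.zeros(conf.shape, dtype=int)
    idx = np.floor((conf - lo) / (hi - lo) * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def curve_frame(curves: list[RcRocCurve]) -> pd.DataFrame:
    """Stack curves into a (response, fpr, tpr) table for text export."""
    parts = []
    for c in curves:
        parts.append(
            pd.DataFrame(
                {
                    "response": c.response or "",
                    "fpr": c.points[:, 0],
                    "tpr": c.points[:, 1],
                }
            )
        )
    return pd.concat(parts, ignore_index=True)
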