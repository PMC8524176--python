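"""Equal-variance SDT fitting, the SDT-matched rc-ROC null, and zROC slopes.

Evidence-axis convention throughout: S2 ~ Normal(0, 1), S1 ~ Normal(d', 1),
respond S1 iff evidence exceeds the threshold k = -z(FA rate).  The
``expected_rcroc`` construction answers the bias-control question: what
rc-ROC *would* an equal-variance observer with this subject's sensitivity,
response bias and incorrect-trial confidence distribution produce?  The
difference between the observed and expected asymmetry (``h3_statistic``)
is therefore a measure of metacognitive asymmetry that a response bias
alone cannot create or mask.

The zROC analysis transforms hit and false-alarm rates at successive
confidence thresholds through the inverse normal CDF; under the
unequal-variance normal model the points are exactly collinear with slope
sigma_noise / sigma_signal (1 under equal variance), so the fitted slope
is a variance-ratio proxy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .metacog import RcRocCurve, subject_asymmetry

__all__ = [
    "SdtFit",
    "ZRocFit",
    "fit_sdt",
    "fit_sdt_from_table",
    "expected_rcroc",
    "expected_asymmetry",
    "h3_statistic",
    "zroc_points",
    "zroc_slope",
]


@dataclass
class SdtFit:
    """Equal-variance SDT parameters recovered from response counts.

    ``threshold_k`` is the decision cut on the evidence axis
    (S2 ~ N(0,1), S1 ~ N(d',1)): k = -z(fa_rate), so that
    P(evidence > k | S2) reproduces the false-alarm rate.
    """

    hit_rate: float
    fa_rate: float
    dprime: float
    criterion_c: float
    threshold_k: float
    correction_applied: bool


@dataclass
class ZRocFit:
    slope: float
    intercept: float
    n_points: int
    log_slope: float


def fit_sdt(n_hit: int, n_miss: int, n_fa: int, n_cr: int) -> SdtFit:
    """Fit equal-variance SDT from the 2x2 response counts.

    A hit is an S1 response to S1; a false alarm an S1 response to S2.
    When any cell is zero the log-linear correction (add 0.5 to every
    cell, 1 to every denominator) is applied so that z-transforms stay
    finite; ``correction_applied`` records this.
    """
    if min(n_hit, n_miss, n_fa, n_cr) < 0:
        raise ValueError("counts must be non-negative")
    n_s1 = n_hit + n_miss
    n_s2 = n_fa + n_cr
    if n_s1 == 0 or n_s2 == 0:
        raise ValueError("each stimulus class needs at least one trial")
    correction = min(n_hit, n_miss, n_fa, n_cr) == 0
    if correction:
        hit = (n_hit + 0.5) / (n_s1 + 1)
        fa = (n_fa + 0.5) / (n_s2 + 1)
    else:
        hit = n_hit / n_s1
        fa = n_fa / n_s2
    z_hit = norm.ppf(hit)
    z_fa = norm.ppf(fa)
    return SdtFit(
        hit_rate=float(hit),
        fa_rate=float(fa),
        dprime=float(z_hit - z_fa),
        criterion_c=float(-(z_hit + z_fa) / 2),
        threshold_k=float(-z_fa),
        correction_applied=correction,
    )


def fit_sdt_from_table(table: pd.DataFrame) -> SdtFit:
    """Fit equal-variance SDT from one subject's trial table."""
    s1 = table["stimulus"] == "S1"
    r1 = table["response"] == "S1"
    return fit_sdt(
        n_hit=int((s1 & r1).sum()),
        n_miss=int((s1 & ~r1).sum()),
        n_fa=int((~s1 & r1).sum()),
        n_cr=int((~s1 & ~r1).sum()),
    )


def _incorrect_cumfracs(incorrect_confidences) -> np.ndarray:
    """At-or-above cumulative fractions of incorrect confidences, descending levels."""
    conf = np.sort(np.asarray(incorrect_confidences, dtype=float))[::-1]
    last = np.nonzero(np.diff(conf, append=-np.inf) != 0)[0]
    return (last + 1) / conf.size


def expected_rcroc(
    fit: SdtFit, incorrect_confidences, response: str
) -> RcRocCurve:
    """rc-ROC expected under the matched equal-variance SDT model.

    For each cumulative proportion ``p`` of the subject's own
    incorrect-trial confidences (at or above each descending level), the
    equal-variance model with the fitted d' and threshold k is inverted to
    the evidence threshold that produces ``p`` on the incorrect side of
    the given response, and the correct-trial cumulative ``q`` the model
    implies at that threshold is computed analytically from the truncated
    normal on the correct side.  The curve {(p, q)} has the same false-
    positive coordinates as the empirical curve but model-derived
    true-positive coordinates.
    """
    d, k = fit.dprime, fit.threshold_k
    p = _incorrect_cumfracs(incorrect_confidences)
    if p.size < 2:
        # single confidence level: degenerate two-point curve
        pts = np.array([[0.0, 0.0], [1.0, 1.0]])
        return RcRocCurve(points=pts, auc=0.5, response=response)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("cumulative proportions must lie in (0, 1]")
    if response == "S1":
        # incorrect trials are S2 stimuli with evidence above k
        tail_inc = norm.sf(k)            # P(x > k | S2)
        tail_cor = norm.sf(k - d)        # P(x > k | S1)
        theta = norm.isf(p * tail_inc)   # evidence threshold achieving p
        q = norm.sf(theta - d) / tail_cor
    elif response == "S2":
        # incorrect trials are S1 stimuli with evidence at or below k;
        # confidence increases as evidence decreases
        tail_inc = norm.cdf(k - d)       # P(x <= k | S1)
        tail_cor = norm.cdf(k)           # P(x <= k | S2)
        theta = norm.ppf(p * tail_inc) + d
        q = norm.cdf(theta) / tail_cor
    else:
        raise ValueError("response must be 'S1' or 'S2'")
    if tail_inc <= 0 or tail_cor <= 0:
        raise ValueError("degenerate fit: zero mass on one side of the threshold")
    q = np.clip(q, 0.0, 1.0)
    pts = np.column_stack([[0.0, *p], [0.0, *q]])
    if pts[-1, 0] != 1.0 or pts[-1, 1] != 1.0:
        pts = np.vstack([pts, [1.0, 1.0]])
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return RcRocCurve(points=pts, auc=auc, response=response)


def expected_asymmetry(table: pd.DataFrame) -> float:
    """Expected Delta AUC under the matched equal-variance SDT null."""
    fit = fit_sdt_from_table(table)
    aucs = {}
    for resp in ("S1", "S2"):
        sub = table[table["response"] == resp]
        inc = sub.loc[~sub["correct"].astype(bool), "confidence"].to_numpy()
        if inc.size < 1:
            raise ValueError(f"response {resp} has no incorrect trials")
        aucs[resp] = expected_rcroc(fit, inc, resp).auc
    return aucs["S1"] - aucs["S2"]


def h3_statistic(table: pd.DataFrame) -> float:
    """Observed minus SDT-expected metacognitive asymmetry for one subject.

    Positive values mean the confidence data are more asymmetric than an
    equal-variance observer with the same sensitivity, response bias and
    incorrect-confidence distributions could be.
    """
    observed = subject_asymmetry(table).delta_auc
    return observed - expected_asymmetry(table)


def zroc_points(table: pd.DataFrame) -> np.ndarray:
    """(z_fa, z_hit) pairs at successive signed-confidence thresholds.

    A signed-confidence axis orders trials by graded evidence for S1:
    S1 responses map to +confidence, S2 responses to -confidence.  Each
    distinct signed value serves as a threshold; the hit rate is the
    fraction of S1-stimulus trials at or above it and the false-alarm rate
    the same fraction among S2-stimulus trials.  Degenerate rates (0 or 1)
    are dropped before the inverse-normal transform.
    """
    signed = np.where(
        table["response"] == "S1", table["confidence"], -table["confidence"]
    ).astype(float)
    is_s1 = (table["stimulus"] == "S1").to_numpy()
    n_s1 = int(is_s1.sum())
    n_s2 = int((~is_s1).sum())
    if n_s1 == 0 or n_s2 == 0:
        raise ValueError("both stimulus classes required")
    order = np.argsort(-signed, kind="mergesort")
    sorted_vals = signed[order]
    sorted_s1 = is_s1[order]
    # cumulative counts at-or-above each descending distinct value
    cum_s1 = np.cumsum(sorted_s1)
    cum_s2 = np.cumsum(~sorted_s1)
    # last index of each run of equal values
    last = np.nonzero(np.diff(sorted_vals, append=-np.inf) != 0)[0]
    hit = cum_s1[last] / n_s1
    fa = cum_s2[last] / n_s2
    keep = (hit > 0) & (hit < 1) & (fa > 0) & (fa < 1)
    pts = np.column_stack([norm.ppf(fa[keep]), norm.ppf(hit[keep])])
    if len(pts) < 3:
        raise ValueError("fewer than 3 usable zROC points")
    return pts


def zroc_slope(points: np.ndarray) -> ZRocFit:
    """Ordinary least squares of z(hit) on z(FA)."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 3:
        raise ValueError("need at least 3 points")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("zero variance in z(FA)")
    slope, intercept = np.polyfit(x, y, 1)
    if slope <= 0:
        raise ValueError("non-positive zROC slope; log-slope undefined")
    return ZRocFit(
        slope=float(slope),
        intercept=float(intercept),
        n_points=len(pts),
        log_slope=float(np.log(slope)),
    )
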