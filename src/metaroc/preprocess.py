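"""Trial- and participant-level exclusion rules and descriptive summaries.

The exclusion logic mirrors a pre-registered analysis plan for a masked
discrimination task with confidence ratings: the first (practice-like)
block is discarded, trials with implausible response times are dropped,
and participants are excluded for low accuracy, an excessive fraction of
extreme-RT trials, a failed comprehension check, too few errors of either
type for a type-2 ROC to exist, or too little confidence variability for
one to be informative.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SchemaError

logger = logging.getLogger(__name__)

__all__ = [
    "ExclusionReport",
    "SubjectDescriptives",
    "RT_MIN_MS",
    "RT_MAX_MS",
    "filter_blocks",
    "filter_trials",
    "assess_subject",
    "apply_exclusions",
    "describe_subject",
]

RT_MIN_MS = 250.0
RT_MAX_MS = 5000.0

#: Exclusion reason codes.
LOW_ACCURACY = "low_accuracy"
EXTREME_RT = "extreme_rt_fraction"
FAILED_COMPREHENSION = "failed_comprehension"
TOO_FEW_ERRORS = "too_few_errors_per_type"
TOO_FEW_CONF_LEVELS = "too_few_confidence_levels"


@dataclass
class ExclusionReport:
    subject_id: str
    included: bool
    reasons: set[str] = field(default_factory=set)
    n_trials_before: int = 0
    n_trials_after: int = 0


@dataclass
class SubjectDescriptives:
    """Per-subject descriptive statistics on clean (analyzed) trials."""

    accuracy: float
    p_s1_response: float
    response_bias: float  # p_s1_response - 0.5
    mean_confidence: float
    conf_correct_minus_incorrect: float  # NaN when either category is empty
    last_trial_soa_ms: float


def filter_blocks(table: pd.DataFrame) -> pd.DataFrame:
    """Drop the first block; only the remaining blocks are analyzed."""
    if "block" not in table.columns:
        raise SchemaError("trial table missing 'block' column")
    return table[table["block"] != 1]


def filter_trials(table: pd.DataFrame) -> pd.DataFrame:
    """Drop trials with RT below 250 ms or above 5 s (boundaries retained)."""
    if "rt_ms" not in table.columns:
        raise SchemaError("trial table missing 'rt_ms' column")
    keep = (table["rt_ms"] >= RT_MIN_MS) & (table["rt_ms"] <= RT_MAX_MS)
    return table[keep]


def _drop_nan_confidence(table: pd.DataFrame) -> pd.DataFrame:
    nan = table["confidence"].isna()
    if nan.any():
        warnings.warn(
            f"dropping {int(nan.sum())} trials with missing confidence",
            stacklevel=3,
        )
        table = table[~nan]
    return table


def assess_subject(
    table: pd.DataFrame, accuracy_on_all_blocks: bool = False
) -> ExclusionReport:
    """Evaluate the five participant-level exclusion rules for one subject.

    Expects the subject's full (unfiltered) table.  The extreme-RT fraction
    is judged on all trials; accuracy, error counts and confidence-level
    counts on the analyzed blocks (all blocks if ``accuracy_on_all_blocks``
    for the accuracy rule), before RT filtering so that trial filtering
    cannot itself create an exclusion.
    """
    sid = str(table["subject_id"].iloc[0]) if len(table) else "<empty>"
    if table.empty:
        return ExclusionReport(
            subject_id=sid,
            included=False,
            reasons={LOW_ACCURACY, TOO_FEW_ERRORS, TOO_FEW_CONF_LEVELS},
        )
    table = _drop_nan_confidence(table)
    analyzed = filter_blocks(table)
    reasons: set[str] = set()

    acc_basis = table if accuracy_on_all_blocks else analyzed
    if len(acc_basis) == 0 or acc_basis["correct"].mean() < 0.60:
        reasons.add(LOW_ACCURACY)

    extreme = (table["rt_ms"] < RT_MIN_MS) | (table["rt_ms"] > RT_MAX_MS)
    if extreme.mean() > 0.25:
        reasons.add(EXTREME_RT)

    if not bool(table["comprehension_passed"].iloc[0]):
        reasons.add(FAILED_COMPREHENSION)

    # error types: S1 stimulus called S2 (miss) and S2 stimulus called S1 (FA)
    miss = ((analyzed["stimulus"] == "S1") & (analyzed["response"] == "S2")).sum()
    fa = ((analyzed["stimulus"] == "S2") & (analyzed["response"] == "S1")).sum()
    if miss < 2 or fa < 2:
        reasons.add(TOO_FEW_ERRORS)

    for resp in ("S1", "S2"):
        conf = analyzed.loc[analyzed["response"] == resp, "confidence"]
        if conf.nunique() < 2:
            reasons.add(TOO_FEW_CONF_LEVELS)

    n_after = len(filter_trials(analyzed)) if not reasons else 0
    return ExclusionReport(
        subject_id=sid,
        included=not reasons,
        reasons=reasons,
        n_trials_before=len(table),
        n_trials_after=n_after,
    )


def apply_exclusions(
    table: pd.DataFrame, accuracy_on_all_blocks: bool = False
) -> tuple[pd.DataFrame, list[ExclusionReport]]:
    """Apply all exclusion rules to a multi-subject trial table.

    Returns the clean table (included subjects only, block- and
    trial-filtered) and one :class:`ExclusionReport` per input subject, in
    input order.
    """
    reports: list[ExclusionReport] = []
    clean_parts: list[pd.DataFrame] = []
    for sid, sub in table.groupby("subject_id", sort=False):
        report = assess_subject(sub, accuracy_on_all_blocks=accuracy_on_all_blocks)
        reports.append(report)
        if report.included:
            clean_parts.append(filter_trials(filter_blocks(_drop_nan_confidence(sub))))
        else:
            logger.info(
                "excluding subject %s: %s", sid, ", ".join(sorted(report.reasons))
            )
    clean = (
        pd.concat(clean_parts, ignore_index=True)
        if clean_parts
        else table.iloc[0:0].copy()
    )
    return clean, reports


def describe_subject(table: pd.DataFrame) -> SubjectDescriptives:
    """Descriptive statistics for one subject's clean table."""
    if table.empty:
        raise ValueError("describe_subject requires a non-empty table")
    correct = table["correct"].astype(bool)
    p_s1 = float((table["response"] == "S1").mean())
    if correct.all() or not correct.any():
        diff = np.nan
    else:
        diff = float(
            table.loc[correct, "confidence"].mean()
            - table.loc[~correct, "confidence"].mean()
        )
    last = table.sort_values("trial_idx").iloc[-1]
    return SubjectDescriptives(
        accuracy=float(correct.mean()),
        p_s1_response=p_s1,
        response_bias=p_s1 - 0.5,
        mean_confidence=float(table["confidence"].mean()),
        conf_correct_minus_incorrect=diff,
        last_trial_soa_ms=float(last["soa_ms"]),
    )


def exclusion_report_frame(reports: list[ExclusionReport]) -> pd.DataFrame:
    """Tabular form of exclusion reports for export as delimited text."""
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in reports],
            "included": [r.included for r in reports],
            "reasons": [";".join(sorted(r.reasons)) for r in reports],
            "n_trials_before": [r.n_trials_before for r in reports],
            "n_trials_after": [r.n_trials_after for r in reports],
        }
    )
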