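"""Clinical blood-pressure arm: categorization, paired tests, transitions.

Blood pressure is categorized by the 2023 European cutpoints — normal
(<130/85 mmHg), high-normal (130-139/85-89 mmHg), hypertension (>=140/90
mmHg) — with a patient's category the maximum of the systolic- and
diastolic-implied categories.  Pre/post paired shifts are tested with the
Wilcoxon signed-rank test (paired t-test behind a flag) and category changes
are tallied into a 3x3 transition matrix ready for Sankey rendering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

CATEGORIES = ("normal", "high_normal", "hypertension")

#: Category thresholds: hypertension iff sbp >= 140 or dbp >= 90;
#: high_normal iff sbp >= 130 or dbp >= 85 (and not hypertension).
SBP_HIGH_NORMAL, DBP_HIGH_NORMAL = 130.0, 85.0
SBP_HYPERTENSION, DBP_HYPERTENSION = 140.0, 90.0

PLAUSIBLE_LOW, PLAUSIBLE_HIGH = 30.0, 300.0

BP_COLUMNS = ["patient_id", "drug_class", "sbp_pre", "dbp_pre", "sbp_post", "dbp_post"]


def _check_window(values: np.ndarray, name: str) -> None:
    bad = (values <= PLAUSIBLE_LOW) | (values >= PLAUSIBLE_HIGH)
    if np.any(bad):
        raise ValueError(
            f"{name}: {int(bad.sum())} values outside the plausibility window "
            f"({PLAUSIBLE_LOW}, {PLAUSIBLE_HIGH}) mmHg"
        )


def categorize_arrays(sbp, dbp) -> np.ndarray:
    """Vectorized categorization; returns integer codes 0/1/2 into CATEGORIES."""
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    _check_window(sbp, "sbp")
    _check_window(dbp, "dbp")
    code = np.zeros(sbp.shape, dtype=int)
    code[(sbp >= SBP_HIGH_NORMAL) | (dbp >= DBP_HIGH_NORMAL)] = 1
    code[(sbp >= SBP_HYPERTENSION) | (dbp >= DBP_HYPERTENSION)] = 2
    return code


def categorize(sbp: float, dbp: float) -> str:
    """Category of one (systolic, diastolic) pair; the worse component governs."""
    return CATEGORIES[int(categorize_arrays(np.array([sbp]), np.array([dbp]))[0])]


@dataclass(frozen=True)
class TransitionMatrix:
    """3x3 pre-category x post-category patient counts for one cohort."""

    counts: np.ndarray
    cohort: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (3, 3) or (counts < 0).any():
            raise ValueError("counts must be a nonnegative 3x3 integer matrix")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def count(self, pre: str, post: str) -> int:
        return int(self.counts[CATEGORIES.index(pre), CATEGORIES.index(post)])

    def to_long(self) -> pd.DataFrame:
        """Long (pre_cat, post_cat, count) table for Sankey rendering."""
        rows = [
            {"pre_cat": p, "post_cat": q, "count": int(self.counts[i, j])}
            for i, p in enumerate(CATEGORIES)
            for j, q in enumerate(CATEGORIES)
        ]
        return pd.DataFrame(rows)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TransitionMatrix):
            return NotImplemented
        return bool(np.array_equal(self.counts, other.counts))


def read_bp_csv(path: str | Path) -> pd.DataFrame:
    """Read a clinical BP cohort CSV and validate its invariants."""
    frame = pd.read_csv(path)
    missing = [c for c in BP_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"BP CSV missing columns: {missing}")
    frame = frame[BP_COLUMNS].copy()
    validate_bp_frame(frame)
    return frame


def write_bp_csv(frame: pd.DataFrame, path: str | Path) -> None:
    frame[BP_COLUMNS].to_csv(path, index=False)


def validate_bp_frame(frame: pd.DataFrame) -> None:
    for col in ("sbp_pre", "dbp_pre", "sbp_post", "dbp_post"):
        _check_window(frame[col].to_numpy(dtype=float), col)
    for when in ("pre", "post"):
        inverted = frame[f"sbp_{when}"] <= frame[f"dbp_{when}"]
        if inverted.any():
            raise ValueError(
                f"{int(inverted.sum())} records with sbp_{when} <= dbp_{when}"
            )


def paired_pre_post_test(
    cohort: pd.DataFrame, component: str = "sbp", method: str = "wilcoxon"
) -> dict:
    """Paired pre/post comparison of one BP component over a cohort.

    Returns a dict with the test statistic and p-value, pre/post medians and
    IQRs, and the median shift.  ``method`` is "wilcoxon" (signed-rank,
    default) or "ttest" (paired t).  A cohort with no change at all has
    p = 1 by convention.
    """
    if component not in ("sbp", "dbp"):
        raise ValueError("component must be 'sbp' or 'dbp'")
    if len(cohort) < 2:
        raise ValueError("paired test requires at least 2 patients")
    pre = cohort[f"{component}_pre"].to_numpy(dtype=float)
    post = cohort[f"{component}_post"].to_numpy(dtype=float)
    diff = post - pre
    if np.all(diff == 0):
        statistic, p = 0.0, 1.0
    elif method == "wilcoxon":
        res = stats.wilcoxon(post, pre, zero_method="wilcox", alternative="two-sided")
        statistic, p = float(res.statistic), float(res.pvalue)
    elif method == "ttest":
        res = stats.ttest_rel(post, pre)
        statistic, p = float(res.statistic), float(res.pvalue)
    else:
        raise ValueError("method must be 'wilcoxon' or 'ttest'")

    def q(v):
        lo, med, hi = np.quantile(v, [0.25, 0.5, 0.75])
        return float(med), float(lo), float(hi)

    med_pre, q1_pre, q3_pre = q(pre)
    med_post, q1_post, q3_post = q(post)
    return {
        "component": component,
        "n": int(len(cohort)),
        "method": method,
        "statistic": statistic,
        "p_value": p,
        "median_pre": med_pre,
        "iqr_pre": (q1_pre, q3_pre),
        "median_post": med_post,
        "iqr_post": (q1_post, q3_post),
        "median_shift": float(np.median(diff)),
    }


def transition_matrix(cohort: pd.DataFrame, label: str = "") -> TransitionMatrix:
    """Count per-(pre, post)-category patients; the total equals cohort size."""
    pre = categorize_arrays(cohort["sbp_pre"], cohort["dbp_pre"])
    post = categorize_arrays(cohort["sbp_post"], cohort["dbp_post"])
    counts = np.zeros((3, 3), dtype=int)
    np.add.at(counts, (pre, post), 1)
    return TransitionMatrix(counts=counts, cohort=label)


def combine_matrices(matrices) -> TransitionMatrix:
    """Elementwise sum of transition matrices (e.g. VEGFi + VEGFRi cohorts)."""
    matrices = list(matrices)
    if not matrices:
        raise ValueError("need at least one matrix")
    total = np.zeros((3, 3), dtype=int)
    labels = []
    for m in matrices:
        total = total + m.counts
        if m.cohort:
            labels.append(m.cohort)
    return TransitionMatrix(counts=total, cohort="+".join(labels))
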