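"""Time-to-onset (TTO) analysis: extraction, summaries, ECDF, rank tests.

TTO is the whole-day difference between therapy start and event onset.
Groups (drugs or classes) are summarized by median and IQR under the
linear-interpolation quantile convention; distributions are compared with
the two-sided Mann-Whitney U test — tie-corrected normal approximation for
groups of 8 or more, exact permutation enumeration below that.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from vegfpv.report_store import ReportSet, split_reactions

logger = logging.getLogger(__name__)

EXACT_MAX_N = 7  # largest per-group size for the exact enumeration path


@dataclass(frozen=True)
class OnsetSummary:
    group: str
    n: int
    median_days: float
    iqr_low: float
    iqr_high: float


def extract_tto(rs: ReportSet, pts: frozenset[str] | set[str]) -> pd.DataFrame:
    """One onset record per report x matching PT, for reports with both dates.

    Records with a missing date or a negative start-to-event difference are
    excluded and counted in the log.  Same-day onsets (0 days) are retained.
    Returns columns: report_id, drug_name, drug_class, pt, tto_days.
    """
    pts = frozenset(pts)
    frame = rs.frame
    has_dates = frame["event_date"].notna() & frame["therapy_start_date"].notna()
    n_missing = int((~has_dates).sum())
    sub = frame[has_dates]
    delta = (sub["event_date"] - sub["therapy_start_date"]).dt.days
    negative = delta < 0
    if negative.any():
        logger.info("extract_tto: excluded %d reports with event before start", int(negative.sum()))
    if n_missing:
        logger.info("extract_tto: excluded %d reports with missing dates", n_missing)
    sub = sub[~negative]
    delta = delta[~negative]

    rows = []
    classes = sub["drug_class"] if "drug_class" in sub.columns else pd.Series("other", index=sub.index)
    for idx, reactions in sub["reactions"].items():
        matched = pts & split_reactions(reactions)
        for pt in sorted(matched):
            rows.append(
                {
                    "report_id": sub.at[idx, "report_id"],
                    "drug_name": sub.at[idx, "drug_name"],
                    "drug_class": classes.at[idx] if idx in classes.index else "other",
                    "pt": pt,
                    "tto_days": float(delta.at[idx]),
                }
            )
    return pd.DataFrame(rows, columns=["report_id", "drug_name", "drug_class", "pt", "tto_days"])


def summarize(records: pd.DataFrame, group_by: str = "drug_class") -> pd.DataFrame:
    """Median and IQR of tto_days per group (linear-interpolation quantiles).

    ``group_by`` is "drug_name" (per drug) or "drug_class" (per class).
    Empty groups are simply absent (there is no row to aggregate).
    Returns columns: group, n, median_days, iqr_low, iqr_high.
    """
    if group_by not in ("drug_name", "drug_class"):
        raise ValueError("group_by must be 'drug_name' or 'drug_class'")
    rows = []
    for group, sub in records.groupby(group_by, sort=True):
        values = sub["tto_days"].to_numpy(dtype=float)
        q1, med, q3 = np.quantile(values, [0.25, 0.5, 0.75])
        rows.append(
            {
                "group": group,
                "n": len(values),
                "median_days": float(med),
                "iqr_low": float(q1),
                "iqr_high": float(q3),
            }
        )
    return pd.DataFrame(rows, columns=["group", "n", "median_days", "iqr_low", "iqr_high"])


def ecdf_curve(values) -> pd.DataFrame:
    """Right-continuous empirical CDF as a (t, F) step table.

    Tied values contribute their full mass at the tie point; F at the largest
    observation is exactly 1.
    """
    values = np.sort(np.asarray(values, dtype=float))
    if values.size == 0:
        raise ValueError("ecdf_curve requires a non-empty group")
    t, counts = np.unique(values, return_counts=True)
    f = np.cumsum(counts) / values.size
    return pd.DataFrame({"t": t, "F": f})


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney U for x (count of (x_i > y_j) pairs, ties as 1/2)."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def _exact_mannwhitney_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Two-sided exact p by full enumeration of group assignments.

    Enumerates every way of splitting the pooled sample into groups of the
    observed sizes (handles ties naturally) and computes the permutation
    probability that |U − nm/2| is at least as large as observed.
    """
    pooled = np.concatenate([x, y])
    n, m = len(x), len(y)
    center = n * m / 2.0
    obs_dev = abs(u_obs - center) - 1e-12
    count = 0
    total = 0
    indices = range(n + m)
    for combo in itertools.combinations(indices, n):
        mask = np.zeros(n + m, dtype=bool)
        mask[list(combo)] = True
        u = _u_statistic(pooled[mask], pooled[~mask])
        if abs(u - center) >= obs_dev:
            count += 1
        total += 1
    return count / total


def compare_groups(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test between two samples.

    Returns (U, p) where U counts (x > y) pairs with ties at 1/2.  For group
    sizes of 8 or more the tie-corrected normal approximation is used; below
    that the p-value is the exact permutation probability.  Two samples with
    no variation at all compare at p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    u_obs = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return u_obs, 1.0
    if min(x.size, y.size) <= EXACT_MAX_N:
        return u_obs, _exact_mannwhitney_p(x, y, u_obs)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def pairwise_drug_comparison(
    records: pd.DataFrame, drugs: list[str] | None = None, holm: bool = False
) -> pd.DataFrame:
    """Symmetric matrix of pairwise Mann-Whitney p-values between drugs.

    ``drugs`` defaults to every drug present in ``records``; drugs without
    onset records are skipped with a warning.  Raw p-values by default; the
    Holm step-down adjustment (applied to the upper triangle) is available
    behind ``holm``.  The diagonal is 1 by construction.
    """
    groups = {}
    for drug in drugs if drugs is not None else sorted(records["drug_name"].unique()):
        vals = records.loc[records["drug_name"] == drug, "tto_days"].to_numpy(dtype=float)
        if vals.size == 0:
            logger.warning("pairwise_drug_comparison: no records for %s; skipped", drug)
            continue
        groups[drug] = vals
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 drugs with onset records")
    mat = pd.DataFrame(np.ones((len(names), len(names))), index=names, columns=names)
    pairs = list(itertools.combinations(names, 2))
    pvals = []
    for d1, d2 in pairs:
        _, p = compare_groups(groups[d1], groups[d2])
        pvals.append(p)
    if holm:
        order = np.argsort(pvals)
        m = len(pvals)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, min(1.0, (m - rank) * pvals[idx]))
            adj[idx] = running
        pvals = adj.tolist()
    for (d1, d2), p in zip(pairs, pvals):
        mat.at[d1, d2] = p
        mat.at[d2, d1] = p
    return mat
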