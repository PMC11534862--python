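"""Disproportionality statistics: ROR, IC, and the three-part signal rule.

The reporting odds ratio for a drug x event 2x2 table

    ==============  ============  ============
                    target event  other events
    target drug     a             b
    other drugs     c             d
    ==============  ============  ============

is ROR = ad/(bc), with the Woolf log-scale 95% CI
``exp(ln ROR ± 1.96·sqrt(1/a + 1/b + 1/c + 1/d))``.  The information
component is the log2 observed/expected co-reporting ratio
``IC = log2(a·N / ((a+b)(a+c)))`` with ``N = a+b+c+d``; its lower bound is
``IC025 = IC − 1.96·sqrt(1/a + 1/b + 1/c + 1/d)`` on the log2 scale.  A pair
is a signal when a ≥ 3, the ROR CI lower bound exceeds 1, and IC025 exceeds
0 (all strict).

Zero cells: the point ROR for a = 0 is reported as 0 (a drug with no
target-event reports has no observed excess), while CI, IC and IC025 are
computed on a Haldane–Anscombe +0.5-corrected table so interval bounds stay
finite.  The policy actually used is recorded on every result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from vegfpv.report_store import ReportSet, normalize_drug_name, split_reactions

logger = logging.getLogger(__name__)

Z95 = 1.96  # normal quantile constant used throughout


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 drug x event table; cells are nonnegative integers."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(int(x) != x or x < 0 for x in cells):
            raise ValueError(f"cells must be nonnegative integers, got {cells}")
        if self.N == 0:
            raise ValueError("all-zero contingency table")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    def corrected(self) -> tuple[float, float, float, float]:
        """Haldane–Anscombe +0.5-corrected cells (applied when any cell is 0)."""
        return (self.a + 0.5, self.b + 0.5, self.c + 0.5, self.d + 0.5)

    @property
    def has_zero_cell(self) -> bool:
        return min(self.a, self.b, self.c, self.d) == 0


@dataclass(frozen=True)
class SignalResult:
    """ROR/CI/IC/IC025 and the signal flag for one drug(-class) x event pair."""

    table: ContingencyTable
    ror: float
    ror_ci_low: float
    ror_ci_high: float
    ic: float
    ic025: float
    is_signal: bool
    zero_cell_policy_used: str  # "none" | "haldane"
    z: float = Z95


# ---------------------------------------------------------------------------
# Vectorized kernels (operate on float arrays; scalar API wraps them)


def _ror_ci_arrays(a, b, c, d):
    """ROR and Woolf 95% CI on (possibly corrected) cell arrays."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    ror = (a * d) / (b * c)
    se = np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    lo = np.exp(np.log(ror) - Z95 * se)
    hi = np.exp(np.log(ror) + Z95 * se)
    return ror, lo, hi


def _ic_arrays(a, b, c, d, literal_ic=False):
    """IC and IC025 on (possibly corrected) cell arrays.

    Default: expected-count form log2(a·N/((a+b)(a+c))), which is 0 when the
    drug and event are reported independently.  ``literal_ic`` switches the
    denominator to (a+b)(c+d) for auditing the alternative reading.
    """
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    denom = (a + b) * ((c + d) if literal_ic else (a + c))
    ic = np.log2(a * n / denom)
    se = np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    return ic, ic - Z95 * se


def ror_with_ci(t: ContingencyTable) -> tuple[float, float, float]:
    """ROR point estimate and 95% CI for one table.

    With a = 0 the point estimate is 0; with any zero cell the CI comes from
    the +0.5-corrected table.
    """
    if t.has_zero_cell:
        ca, cb, cc, cd = t.corrected()
        ror_c, lo, hi = _ror_ci_arrays(ca, cb, cc, cd)
        point = 0.0 if t.a == 0 else float(ror_c)
        return point, float(lo), float(hi)
    ror, lo, hi = _ror_ci_arrays(t.a, t.b, t.c, t.d)
    return float(ror), float(lo), float(hi)


def ic_with_ic025(t: ContingencyTable, literal_ic: bool = False) -> tuple[float, float]:
    """Information component and its lower bound for one table."""
    cells = t.corrected() if t.has_zero_cell else (t.a, t.b, t.c, t.d)
    ic, ic025 = _ic_arrays(*cells, literal_ic=literal_ic)
    return float(ic), float(ic025)


def flag_signal(a: int, ror_ci_low: float, ic025: float) -> bool:
    """Three-part signal rule: a ≥ 3 AND ROR CI low > 1 AND IC025 > 0."""
    return (a >= 3) and (ror_ci_low > 1.0) and (ic025 > 0.0)


def evaluate_pair(t: ContingencyTable, literal_ic: bool = False) -> SignalResult:
    """Full scalar pipeline for one table: ROR, CI, IC, IC025, signal flag."""
    ror, lo, hi = ror_with_ci(t)
    ic, ic025 = ic_with_ic025(t, literal_ic=literal_ic)
    return SignalResult(
        table=t,
        ror=ror,
        ror_ci_low=lo,
        ror_ci_high=hi,
        ic=ic,
        ic025=ic025,
        is_signal=flag_signal(t.a, lo, ic025),
        zero_cell_policy_used="haldane" if t.has_zero_cell else "none",
    )


# ---------------------------------------------------------------------------
# Contingency construction from report sets


def _target_masks(
    rs: ReportSet, target_drugs: Sequence[str], target_pts: Sequence[str]
) -> tuple[pd.Series, pd.Series]:
    drugs = {normalize_drug_name(d) for d in target_drugs}
    pts = frozenset(target_pts)
    has_drug = rs.frame["drug_name"].isin(drugs)
    has_pt = rs.frame["reactions"].map(lambda cell: not pts.isdisjoint(split_reactions(cell)))
    return has_drug, has_pt


def build_contingency(
    rs: ReportSet, target_drugs: Sequence[str], target_pts: Sequence[str]
) -> ContingencyTable:
    """Count the 2x2 cells over a preprocessed report set.

    a = target drug & target PT; b = target drug only; c = target PT only;
    d = neither.  The comparator is everything else in the same report set.
    """
    if len(rs) == 0:
        raise ValueError("cannot build a contingency table from an empty ReportSet")
    has_drug, has_pt = _target_masks(rs, target_drugs, target_pts)
    a = int((has_drug & has_pt).sum())
    b = int((has_drug & ~has_pt).sum())
    c = int((~has_drug & has_pt).sum())
    d = int((~has_drug & ~has_pt).sum())
    return ContingencyTable(a, b, c, d)


def signal_table(
    rs: ReportSet,
    drugs: Sequence[str] | Mapping[str, Sequence[str]],
    pt_groups: Mapping[str, Sequence[str]],
    literal_ic: bool = False,
) -> pd.DataFrame:
    """Long-format signal table, one row per (drug, PT group) pair.

    ``drugs`` is either a list of drug names (each its own row label) or a
    mapping label -> drug-name list (class-level rows).  Rows are ordered
    lexicographically by (drug, pt_group).
    """
    if not drugs or not pt_groups:
        raise ValueError("drugs and pt_groups must be non-empty")
    if not isinstance(drugs, Mapping):
        drugs = {d: [d] for d in drugs}
    rows = []
    for label in sorted(drugs):
        for group in sorted(pt_groups):
            t = build_contingency(rs, drugs[label], pt_groups[group])
            r = evaluate_pair(t, literal_ic=literal_ic)
            rows.append(
                {
                    "drug": label,
                    "pt_group": group,
                    "a": t.a,
                    "b": t.b,
                    "c": t.c,
                    "d": t.d,
                    "ror": r.ror,
                    "ci_low": r.ror_ci_low,
                    "ci_high": r.ror_ci_high,
                    "ic": r.ic,
                    "ic025": r.ic025,
                    "is_signal": r.is_signal,
                    "zero_cell_policy": r.zero_cell_policy_used,
                }
            )
    return pd.DataFrame(rows)


def per_cancer_ror(
    rs: ReportSet,
    cancer_label: Mapping[str, str],
    target_drugs: Sequence[str],
    target_pts: Sequence[str],
    min_cases: int = 5,
    literal_ic: bool = False,
) -> pd.DataFrame:
    """One ROR per cancer type; types with a < ``min_cases`` are omitted.

    ``cancer_label`` maps (normalized, lowercase) indication strings to
    cancer-type codes; reports with unmapped indications are ignored.  Within
    each cancer type the 2x2 table contrasts the target drugs against all
    other drugs reported for that cancer.  The exclusion is strict: a type
    with exactly ``min_cases`` exposed cases is included.
    """
    if min_cases < 1:
        raise ValueError("min_cases must be >= 1")
    labels = {str(k).strip().lower(): v for k, v in cancer_label.items()}
    cancer = rs.frame["indication"].astype(str).str.strip().str.lower().map(labels)
    rows = []
    for cancer_type in sorted(c for c in cancer.dropna().unique()):
        sub = rs.with_frame(rs.frame[cancer == cancer_type])
        t = build_contingency(sub, target_drugs, target_pts)
        if t.a < min_cases:
            logger.info(
                "per_cancer_ror: omitting %s (a=%d < min_cases=%d)",
                cancer_type, t.a, min_cases,
            )
            continue
        r = evaluate_pair(t, literal_ic=literal_ic)
        rows.append(
            {
                "cancer_type": cancer_type,
                "a": t.a,
                "b": t.b,
                "c": t.c,
                "d": t.d,
                "ror": r.ror,
                "ci_low": r.ror_ci_low,
                "ci_high": r.ror_ci_high,
                "ic": r.ic,
                "ic025": r.ic025,
                "is_signal": r.is_signal,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cancer_type", "a", "b", "c", "d",
            "ror", "ci_low", "ci_high", "ic", "ic025", "is_signal",
        ],
    )


def pivot_heatmap(table: pd.DataFrame, value: str = "ror") -> pd.DataFrame:
    """Heatmap-ready wide pivot (drug rows x PT-group columns) of one column."""
    return table.pivot(index="drug", columns="pt_group", values=value)
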