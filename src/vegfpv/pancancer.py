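"""Pan-cancer arm: FPKM→TPM, ssGSEA scoring, and ROR correlation.

Per-sample pathway activity is scored with single-sample gene-set enrichment
(ssGSEA): genes are ranked by expression within the sample, in-set genes are
weighted by rank^alpha, and the enrichment score is the running-sum
difference between the weighted in-set ECDF and the uniform out-of-set ECDF,
integrated over the ranked list.  Per-cancer mean scores are then correlated
(Spearman) with the per-cancer hypertension reporting odds ratio.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.25
EXACT_SPEARMAN_MAX_N = 9  # permutation p below this many pairs; t-approx at >= 10
TPM_TOTAL = 1e6


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix with cancer-type labels.

    ``values`` is a DataFrame (index = gene identifiers, columns = sample
    identifiers); ``sample_types`` maps each sample to its cancer-type code;
    ``scale`` is "FPKM" or "TPM".
    """

    values: pd.DataFrame
    sample_types: pd.Series
    scale: str = "FPKM"

    def __post_init__(self) -> None:
        if self.scale not in ("FPKM", "TPM"):
            raise ValueError("scale must be 'FPKM' or 'TPM'")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")
        self.sample_types = self.sample_types.reindex(self.values.columns)
        if self.sample_types.isna().any():
            missing = self.sample_types.index[self.sample_types.isna()].tolist()[:3]
            raise ValueError(f"samples without a cancer-type label (e.g. {missing})")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns


def fpkm_to_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale each sample so abundances sum to 1e6 (FPKM → TPM).

    TPM_g = FPKM_g / sum_g FPKM_g * 1e6, per sample.  A sample whose column
    is all zero cannot be rescaled and raises with the sample named.
    """
    if m.scale != "FPKM":
        raise ValueError("fpkm_to_tpm expects an FPKM-scale matrix")
    totals = m.values.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero expression column(s): {zero.index.tolist()[:5]}")
    values = m.values.div(totals, axis=1) * TPM_TOTAL
    return ExpressionMatrix(values=values, sample_types=m.sample_types.copy(), scale="TPM")


def _ssgsea_single(
    expr: np.ndarray,
    order_key: np.ndarray,
    in_set: np.ndarray,
    alpha: float,
    statistic: str,
) -> float:
    """ES for one sample.

    ``expr`` are the per-gene values, ``in_set`` the membership mask.  Genes
    are ranked ascending (average ranks for ties, so the top gene carries the
    largest rank value), walked in descending-rank order with ``order_key``
    breaking ties deterministically, and the weighted in-set ECDF minus the
    uniform out-of-set ECDF is accumulated.
    """
    g = expr.size
    ranks = stats.rankdata(expr)  # ties -> average ranks
    # Walk from highest to lowest rank; order_key gives a stable tie-break.
    order = np.lexsort((order_key, -ranks))
    in_ordered = in_set[order]
    w = ranks[order] ** alpha
    w[~in_ordered] = 0.0
    w_total = w.sum()
    if w_total == 0:
        raise ValueError("gene set has no members in the matrix")
    p_in = np.cumsum(w) / w_total
    n_out = g - int(in_set.sum())
    if n_out == 0:
        raise ValueError("gene set covers every gene; the complement is empty")
    p_out = np.cumsum(~in_ordered) / n_out
    diff = p_in - p_out
    if statistic == "integrated":
        return float(diff.sum())
    if statistic == "max":
        k = int(np.argmax(np.abs(diff)))
        return float(diff[k])
    raise ValueError("statistic must be 'integrated' or 'max'")


def ssgsea_score(
    m: ExpressionMatrix,
    gene_sets: Mapping[str, Sequence[str]],
    alpha: float = DEFAULT_ALPHA,
    statistic: str = "integrated",
    minmax_normalize: bool = False,
) -> pd.DataFrame:
    """Per-sample enrichment scores, one column per gene set.

    Scores are rank-based and therefore invariant under strictly monotone
    transforms of each sample's expression values.  ``minmax_normalize``
    optionally rescales each gene set's scores to [0, 1] across samples
    (off by default; the single-sample contract needs no cross-sample step).
    """
    genes = m.genes
    expr = m.values.to_numpy(dtype=float)
    order_key = np.arange(len(genes))  # stable positional tie-break
    out = {}
    for name in gene_sets:
        members = frozenset(gene_sets[name])
        in_set = np.asarray(genes.isin(members))
        n_in = int(in_set.sum())
        if n_in == 0:
            raise ValueError(f"gene set {name!r} has no members in the matrix")
        if n_in == len(genes):
            raise ValueError(f"gene set {name!r} covers every gene")
        out[name] = [
            _ssgsea_single(expr[:, j], order_key, in_set, alpha, statistic)
            for j in range(expr.shape[1])
        ]
    scores = pd.DataFrame(out, index=m.samples)
    if minmax_normalize:
        rng = scores.max() - scores.min()
        rng = rng.replace(0, 1.0)
        scores = (scores - scores.min()) / rng
    return scores


def per_cancer_pathway_score(scores: pd.DataFrame, sample_types: pd.Series) -> pd.DataFrame:
    """Arithmetic mean enrichment score per cancer type (rows) per pathway."""
    labels = sample_types.reindex(scores.index)
    if labels.isna().any():
        raise ValueError("every scored sample needs a cancer-type label")
    return scores.groupby(labels).mean().sort_index()


def _exact_spearman_p(xr: np.ndarray, yr: np.ndarray, rho_obs: float) -> float:
    """Two-sided permutation p for Spearman rho by full enumeration."""
    n = xr.size
    xc = xr - xr.mean()
    denom_x = math.sqrt(float(xc @ xc))
    perms = np.array(list(itertools.permutations(range(n))))
    y_perm = yr[perms]  # (n!, n)
    yc = y_perm - y_perm.mean(axis=1, keepdims=True)
    denom_y = np.sqrt((yc * yc).sum(axis=1))
    rhos = (yc @ xc) / (denom_x * denom_y)
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


def correlate_with_ror(
    scores: pd.DataFrame | pd.Series, rors: pd.Series
) -> pd.DataFrame:
    """Spearman correlation of per-cancer pathway scores with per-cancer ROR.

    ``scores`` has cancer types as index (columns = pathways; a Series is one
    pathway); ``rors`` maps cancer type to ROR.  Types are inner-joined; at
    least 4 shared types are required.  The p-value uses the t-approximation
    for n >= 10 and exact permutation enumeration below that.  Returns a
    table with columns pathway, rho, p_value, n_cancers.
    """
    if isinstance(scores, pd.Series):
        scores = scores.to_frame(name=scores.name or "pathway")
    shared = scores.index.intersection(rors.index)
    if len(shared) < 4:
        raise ValueError(f"only {len(shared)} shared cancer types; need >= 4")
    ror_vals = rors.loc[shared].to_numpy(dtype=float)
    yr = stats.rankdata(ror_vals)
    rows = []
    for pathway in scores.columns:
        x = scores.loc[shared, pathway].to_numpy(dtype=float)
        xr = stats.rankdata(x)
        rho = float(stats.spearmanr(x, ror_vals).statistic)
        if len(shared) <= EXACT_SPEARMAN_MAX_N:
            p = _exact_spearman_p(xr, yr, rho)
        else:
            p = float(stats.spearmanr(x, ror_vals).pvalue)
        rows.append(
            {"pathway": pathway, "rho": rho, "p_value": p, "n_cancers": int(len(shared))}
        )
    return pd.DataFrame(rows, columns=["pathway", "rho", "p_value", "n_cancers"])


# ---------------------------------------------------------------------------
# File formats


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets from GMT (name, description, members...; tab-separated)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: Mapping[str, Sequence[str]], path: str | Path) -> None:
    lines = [
        "\t".join([name, "na", *gene_sets[name]]) for name in gene_sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_expression(
    matrix_path: str | Path, sidecar_path: str | Path, scale: str = "FPKM"
) -> ExpressionMatrix:
    """Read a delimited genes x samples matrix plus a sample→type sidecar CSV."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    sidecar = pd.read_csv(sidecar_path)
    if not {"sample", "cancer_type"} <= set(sidecar.columns):
        raise ValueError("sidecar needs 'sample' and 'cancer_type' columns")
    types = sidecar.set_index("sample")["cancer_type"]
    return ExpressionMatrix(values=values, sample_types=types, scale=scale)


def write_expression(m: ExpressionMatrix, matrix_path: str | Path, sidecar_path: str | Path) -> None:
    m.values.to_csv(matrix_path, sep="\t")
    pd.DataFrame(
        {"sample": m.samples, "cancer_type": m.sample_types.reindex(m.samples).to_numpy()}
    ).to_csv(sidecar_path, index=False)
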