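"""Seeded generators emulating every input the pipeline consumes.

Three generators cover the three data arms:

* :func:`simulate_reports` — spontaneous adverse-event reports with planted
  per-(drug, PT-group) reporting odds ratios, malignancy fractions, injected
  duplicates, missing dates, and per-class log-normal onset delays;
* :func:`simulate_clinical` — paired pre/post blood pressures from a
  truncated bivariate normal with planted per-class additive shifts;
* :func:`simulate_expression` — FPKM matrices with planted per-cancer
  pathway-activity gradients tied to a per-cancer ROR vector through a
  Gaussian copula at a chosen Spearman correlation.

Every generator is a pure function of its config (seed included) and returns
a truth record carrying the planted parameters and realized bookkeeping
needed to compute expected values of every downstream statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from vegfpv.bp_clinical import BP_COLUMNS, CATEGORIES
from vegfpv.pancancer import ExpressionMatrix
from vegfpv.report_store import REPORT_COLUMNS, ReportSet, join_reactions

logger = logging.getLogger(__name__)

# Cancer-type codes used for synthetic indications (TCGA-style abbreviations).
CANCER_TYPES = [
    "PRAD", "OV", "COAD", "THCA", "CHOL", "KIRP", "LUAD", "LIHC", "LAML",
    "PAAD", "STAD", "MESO", "READ", "ESCA", "BRCA", "KIRC", "BLCA", "UCS",
    "SARC", "CRC", "DLBC", "LUSC", "ACC", "GBM", "CESC", "NSCLC", "SKCM",
    "UCEC", "HNSC",
]

#: Synthetic malignant indication strings and their cancer-type codes.
MALIGNANT_INDICATIONS = {
    "Prostate carcinoma": "PRAD",
    "Ovarian cancer": "OV",
    "Colon adenocarcinoma": "COAD",
    "Thyroid cancer": "THCA",
    "Cholangiocarcinoma": "CHOL",
    "Renal pelvis adenocarcinoma": "KIRP",
    "Lung adenocarcinoma": "LUAD",
    "Hepatocellular carcinoma": "LIHC",
    "Acute myeloid leukemia": "LAML",
    "Pancreatic adenocarcinoma": "PAAD",
    "Gastric adenocarcinoma": "STAD",
    "Mesothelioma malignant": "MESO",
    "Rectal adenocarcinoma": "READ",
    "Oesophageal cancer": "ESCA",
    "Breast cancer": "BRCA",
    "Renal cell carcinoma": "KIRC",
    "Bladder cancer": "BLCA",
    "Uterine sarcoma": "UCS",
    "Soft tissue sarcoma": "SARC",
    "Colorectal cancer": "CRC",
    "Diffuse large B-cell lymphoma": "DLBC",
    "Lung squamous cell carcinoma": "LUSC",
    "Adrenocortical carcinoma": "ACC",
    "Glioblastoma": "GBM",
    "Cervical carcinoma": "CESC",
    "Non-small cell lung cancer": "NSCLC",
    "Malignant melanoma": "SKCM",
    "Endometrial carcinoma": "UCEC",
    "Head and neck squamous cell carcinoma": "HNSC",
}

NON_MALIGNANT_INDICATIONS = [
    "Macular degeneration",
    "Diabetic retinopathy",
    "Retinal vein occlusion",
    "Idiopathic pulmonary fibrosis",
    "Rheumatoid arthritis",
]

BACKGROUND_PTS = [
    "Nausea", "Fatigue", "Diarrhoea", "Decreased appetite", "Rash",
    "Vomiting", "Headache", "Pyrexia", "Arthralgia", "Dizziness",
    "Proteinuria", "Epistaxis",
]

COUNTRIES = ["US", "JP", "FR", "DE", "GB", "CN", "IT", "CA", "ES", "BR"]

#: Default PT groups mirroring the blood-pressure screen structure.
DEFAULT_PT_GROUPS: dict[str, list[str]] = {
    "hypertension": [
        "Hypertension", "Hypertensive crisis", "Systolic hypertension",
        "Diastolic hypertension", "Secondary hypertension",
        "Malignant hypertension",
    ],
    "bp_increased": [
        "Blood pressure increased", "Blood pressure systolic increased",
        "Blood pressure diastolic increased",
    ],
}

#: Default drug marginal reporting probabilities (rest = non-target drugs).
DEFAULT_DRUG_PROBS: dict[str, float] = {
    "bevacizumab": 0.10,
    "ranibizumab": 0.02,
    "aflibercept": 0.02,
    "lenvatinib": 0.05,
    "cabozantinib": 0.05,
    "sunitinib": 0.06,
    "pazopanib": 0.05,
    "axitinib": 0.04,
    "regorafenib": 0.04,
    "sorafenib": 0.06,
    "ramucirumab": 0.03,
    "aspirin": 0.16,
    "metformin": 0.11,
    "atezolizumab": 0.11,
    "paclitaxel": 0.10,
}

VEGFI = {"bevacizumab", "ranibizumab", "brolucizumab", "aflibercept", "conbercept",
         "pegaptanib"}
VEGFRI = {"ramucirumab", "nintedanib", "apatinib", "axitinib", "sunitinib", "sorafenib",
          "regorafenib", "vandetanib", "cabozantinib", "pazopanib", "lenvatinib",
          "anlotinib", "fruquintinib", "tivozanib", "cediranib", "brivanib"}


def _drug_class(name: str) -> str:
    if name in VEGFI:
        return "VEGFi"
    if name in VEGFRI:
        return "VEGFRi"
    return "other"


@dataclass(frozen=True)
class FaersSimConfig:
    """Configuration for the spontaneous-report generator.

    ``planted_ror`` maps (drug_or_class, pt_group) to an odds multiplier: a
    report carrying that drug has group-event odds equal to the multiplier
    times the background odds, so the planted value IS the true reporting
    odds ratio for the pair.  Onset delays are log-normal per class,
    parameterized by median days and log-sd (right-skewed, as observed
    onset-time distributions are).
    """

    n_reports: int = 20_000
    seed: int = 0
    drug_probs: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DRUG_PROBS)
    )
    pt_groups: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_PT_GROUPS.items()}
    )
    base_rates: Mapping[str, float] = field(
        default_factory=lambda: {"hypertension": 0.05, "bp_increased": 0.03}
    )
    planted_ror: Mapping[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("VEGFi", "hypertension"): 4.0,
            ("VEGFRi", "hypertension"): 8.0,
            ("VEGFRi", "bp_increased"): 3.0,
        }
    )
    malignant_fraction: float = 0.8
    duplicate_rate: float = 0.0
    missing_date_rate: float = 0.0
    tto_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "VEGFi": (59.0, 1.55),
            "VEGFRi": (21.0, 1.65),
            "other": (45.0, 1.5),
        }
    )
    indication_probs: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be >= 1")
        probs = np.array(list(self.drug_probs.values()), dtype=float)
        if (probs < 0).any() or not np.isclose(probs.sum(), 1.0):
            raise ValueError("drug_probs must be nonnegative and sum to 1")
        if not 0 <= self.malignant_fraction <= 1:
            raise ValueError("malignant_fraction must be in [0, 1]")
        if not 0 <= self.duplicate_rate <= 1 or not 0 <= self.missing_date_rate <= 1:
            raise ValueError("rates must be in [0, 1]")
        for pair, r in self.planted_ror.items():
            if r <= 0:
                raise ValueError(f"planted ROR for {pair} must be > 0")
        for cls, (med, sd) in self.tto_params.items():
            if med <= 0 or sd <= 0:
                raise ValueError(f"tto_params for {cls} must be positive")


def _pair_rate(cfg: FaersSimConfig, drug: str, group: str) -> float:
    """Group-event probability for one drug: planted odds x background odds."""
    base = cfg.base_rates.get(group, 0.0)
    mult = cfg.planted_ror.get((drug, group))
    if mult is None:
        mult = cfg.planted_ror.get((_drug_class(drug), group), 1.0)
    odds = mult * base / (1.0 - base)
    return odds / (1.0 + odds)


def simulate_reports(cfg: FaersSimConfig) -> tuple[ReportSet, dict]:
    """Draw a synthetic report set and its truth record.

    The truth record stores, per planted pair and per class-level pair, the
    realized 2x2 cells counted on the malignancy-filtered base set (what the
    pipeline sees after deduplication removes the injected copies), plus the
    injected duplicate count, missing-date count, and per-class onset
    parameters.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_reports
    drug_names = list(cfg.drug_probs)
    drug_p = np.array([cfg.drug_probs[d] for d in drug_names], dtype=float)
    drugs = rng.choice(drug_names, size=n, p=drug_p)
    classes = np.array([_drug_class(d) for d in drugs])

    malignant = rng.random(n) < cfg.malignant_fraction
    mal_names = list(MALIGNANT_INDICATIONS)
    if cfg.indication_probs is not None:
        mal_names = list(cfg.indication_probs)
        mal_p = np.array([cfg.indication_probs[i] for i in mal_names], dtype=float)
        mal_p = mal_p / mal_p.sum()
    else:
        mal_p = np.full(len(mal_names), 1.0 / len(mal_names))
    indication = np.where(
        malignant,
        rng.choice(mal_names, size=n, p=mal_p),
        rng.choice(NON_MALIGNANT_INDICATIONS, size=n),
    )

    # Reaction assembly: two distinct background PTs always (non-empty
    # invariant, large dedup keyspace) plus each PT group at its per-drug rate.
    bg_idx = np.array([rng.choice(len(BACKGROUND_PTS), size=2, replace=False) for _ in range(n)])
    group_occurs: dict[str, np.ndarray] = {}
    group_pt_choice: dict[str, np.ndarray] = {}
    for group, pts in cfg.pt_groups.items():
        p = np.array([_pair_rate(cfg, d, group) for d in drugs])
        group_occurs[group] = rng.random(n) < p
        group_pt_choice[group] = rng.integers(0, len(pts), size=n)

    reactions = []
    bg = np.asarray(BACKGROUND_PTS)
    for i in range(n):
        pts = [bg[bg_idx[i, 0]], bg[bg_idx[i, 1]]]
        for group, occ in group_occurs.items():
            if occ[i]:
                pts.append(list(cfg.pt_groups[group])[group_pt_choice[group][i]])
        reactions.append(join_reactions(pts))
    reactions = np.asarray(reactions, dtype=object)

    # Dates: therapy start uniform over the study decade; onset log-normal.
    start_origin = np.datetime64("2013-01-01")
    start_offset = rng.integers(0, 3650, size=n)
    start = start_origin + start_offset.astype("timedelta64[D]")
    tto = np.empty(n)
    for cls, (median, log_sd) in cfg.tto_params.items():
        mask = classes == cls
        tto[mask] = np.round(rng.lognormal(np.log(median), log_sd, size=int(mask.sum())))
    event = start + tto.astype(int).astype("timedelta64[D]")
    missing = rng.random(n) < cfg.missing_date_rate
    event_date = pd.Series(pd.to_datetime(event)).mask(missing, pd.NaT)

    frame = pd.DataFrame(
        {
            "report_id": [f"R{i:07d}" for i in range(n)],
            "sex": rng.choice(["male", "female"], size=n),
            "age": rng.integers(18, 91, size=n).astype(float),
            "age_unit": "years",
            "country": rng.choice(COUNTRIES, size=n),
            "event_date": event_date.to_numpy(),
            "therapy_start_date": pd.to_datetime(start),
            "drug_name": drugs,
            "drug_role": "primary_suspect",
            "indication": indication,
            "reactions": reactions,
        },
        columns=REPORT_COLUMNS,
    )

    # Truth cells on the malignancy-filtered base set.
    def cells(drug_mask: np.ndarray, group: str) -> tuple[int, int, int, int]:
        occ = group_occurs[group]
        m = malignant
        a = int((drug_mask & occ & m).sum())
        b = int((drug_mask & ~occ & m).sum())
        c = int((~drug_mask & occ & m).sum())
        d = int((~drug_mask & ~occ & m).sum())
        return a, b, c, d

    truth_cells: dict[str, tuple[int, int, int, int]] = {}
    for target, group in cfg.planted_ror:
        if target in ("VEGFi", "VEGFRi", "other"):
            mask = classes == target
        else:
            mask = drugs == target
        truth_cells[f"{target}|{group}"] = cells(mask, group)
    for cls in ("VEGFi", "VEGFRi"):
        for group in cfg.pt_groups:
            truth_cells.setdefault(f"{cls}|{group}", cells(classes == cls, group))

    # Duplicate injection: copy the full dedup key under fresh report ids.
    n_dup = int(round(cfg.duplicate_rate * n))
    if n_dup:
        picks = rng.choice(n, size=n_dup, replace=False)
        copies = frame.iloc[picks].copy()
        copies["report_id"] = [f"D{i:07d}" for i in range(n_dup)]
        frame = pd.concat([frame, copies], ignore_index=True)

    truth = {
        "n_base": n,
        "n_duplicates": n_dup,
        "n_missing_event_date": int(missing.sum()),
        "n_malignant": int(malignant.sum()),
        "planted_ror": {f"{d}|{g}": r for (d, g), r in cfg.planted_ror.items()},
        "cells": truth_cells,
        "tto_params": {c: list(v) for c, v in cfg.tto_params.items()},
        "cancer_label": {k.lower(): v for k, v in MALIGNANT_INDICATIONS.items()},
    }
    return ReportSet(frame, provenance=f"synthetic(seed={cfg.seed})"), truth


# ---------------------------------------------------------------------------
# Clinical blood-pressure cohorts


@dataclass(frozen=True)
class ClinicalSimConfig:
    """Paired pre/post blood-pressure cohort generator settings.

    Pre-treatment (sbp, dbp) is bivariate normal per class; post = pre +
    planted additive shift + independent noise.  Defaults emulate observed
    oncology cohorts: pre medians near 125-128/77-78 mmHg with post shifts
    of +12/+2 (ligand inhibitors) and +7/+4 (receptor inhibitors).
    """

    n_per_class: Mapping[str, int] = field(
        default_factory=lambda: {"VEGFi": 1087, "VEGFRi": 529}
    )
    pre_params: Mapping[str, tuple[float, float, float, float, float]] = field(
        # (sbp_mean, sbp_sd, dbp_mean, dbp_sd, correlation)
        default_factory=lambda: {
            "VEGFi": (128.0, 19.0, 78.0, 11.0, 0.6),
            "VEGFRi": (125.0, 17.0, 77.0, 12.0, 0.6),
        }
    )
    shifts: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"VEGFi": (12.0, 2.0), "VEGFRi": (7.0, 4.0)}
    )
    noise_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        for cls, (_, ssd, _, dsd, rho) in self.pre_params.items():
            if ssd <= 0 or dsd <= 0:
                raise ValueError(f"{cls}: sds must be > 0")
            if not -1 < rho < 1:
                raise ValueError(f"{cls}: |correlation| must be < 1")


def _class_cov(params: tuple[float, float, float, float, float], noise_sd: float) -> np.ndarray:
    """4x4 covariance of (sbp_pre, dbp_pre, sbp_post, dbp_post)."""
    _, ssd, _, dsd, rho = params
    pre = np.array([[ssd**2, rho * ssd * dsd], [rho * ssd * dsd, dsd**2]])
    cov = np.zeros((4, 4))
    cov[:2, :2] = pre
    cov[2:, :2] = pre
    cov[:2, 2:] = pre
    cov[2:, 2:] = pre + np.eye(2) * noise_sd**2
    return cov


def expected_transition_probs(cfg: ClinicalSimConfig, drug_class: str) -> np.ndarray:
    """Analytic 3x3 pre/post category transition probabilities for one class.

    Each category region is a difference of quadrant rectangles, so every
    cell probability expands into a signed sum of 4-dimensional normal CDF
    evaluations on (sbp_pre, dbp_pre, sbp_post, dbp_post).  Truncation to
    the plausibility window is ignored (its mass is negligible at the
    default parameters).
    """
    params = cfg.pre_params[drug_class]
    s_shift, d_shift = cfg.shifts[drug_class]
    mean = np.array([params[0], params[2], params[0] + s_shift, params[2] + d_shift])
    cov = _class_cov(params, cfg.noise_sd)
    mvn = stats.multivariate_normal(mean=mean, cov=cov, allow_singular=True)

    inf = np.inf
    # Category = signed combination of rectangles {sbp < s, dbp < d}.
    rect_terms = {
        0: [(1.0, (130.0, 85.0))],
        1: [(1.0, (140.0, 90.0)), (-1.0, (130.0, 85.0))],
        2: [(1.0, (inf, inf)), (-1.0, (140.0, 90.0))],
    }
    probs = np.zeros((3, 3))
    for i, pre_terms in rect_terms.items():
        for j, post_terms in rect_terms.items():
            total = 0.0
            for ci, (s1, d1) in pre_terms:
                for cj, (s2, d2) in post_terms:
                    total += ci * cj * float(mvn.cdf([s1, d1, s2, d2]))
            probs[i, j] = total
    return np.clip(probs, 0.0, 1.0)


def simulate_clinical(cfg: ClinicalSimConfig) -> tuple[pd.DataFrame, dict]:
    """Draw paired pre/post BP cohorts and the truth record.

    Rows violating the plausibility window or sbp <= dbp are redrawn, so the
    emitted frame always satisfies the clinical-record invariants.  The truth
    record stores the planted shifts and the analytic transition-probability
    matrices per class.
    """
    rng = np.random.default_rng(cfg.seed)
    frames = []
    for cls in sorted(cfg.n_per_class):
        n = cfg.n_per_class[cls]
        params = cfg.pre_params[cls]
        s_shift, d_shift = cfg.shifts[cls]
        s_mean, ssd, d_mean, dsd, rho = params
        pre_chol = np.linalg.cholesky(
            np.array([[ssd**2, rho * ssd * dsd], [rho * ssd * dsd, dsd**2]])
        )

        out = np.empty((n, 4))
        remaining = np.arange(n)
        while remaining.size:
            pre = np.array([s_mean, d_mean]) + rng.standard_normal(
                (remaining.size, 2)
            ) @ pre_chol.T
            post = pre + np.array([s_shift, d_shift]) + rng.normal(
                0.0, cfg.noise_sd, size=(remaining.size, 2)
            )
            draw = np.hstack([pre, post])
            # margins keep the 0.1-mmHg rounding below from breaching the
            # plausibility window or collapsing sbp onto dbp
            ok = (
                (draw > 30.1).all(axis=1)
                & (draw < 299.9).all(axis=1)
                & (draw[:, 0] > draw[:, 1] + 0.11)
                & (draw[:, 2] > draw[:, 3] + 0.11)
            )
            out[remaining[ok]] = draw[ok]
            remaining = remaining[~ok]
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": [f"{cls}-{i:05d}" for i in range(n)],
                    "drug_class": cls,
                    "sbp_pre": np.round(out[:, 0], 1),
                    "dbp_pre": np.round(out[:, 1], 1),
                    "sbp_post": np.round(out[:, 2], 1),
                    "dbp_post": np.round(out[:, 3], 1),
                },
                columns=BP_COLUMNS,
            )
        )
    cohort = pd.concat(frames, ignore_index=True)
    truth = {
        "shifts": {c: list(v) for c, v in cfg.shifts.items()},
        "noise_sd": cfg.noise_sd,
        "transition_probs": {
            c: expected_transition_probs(cfg, c).tolist() for c in cfg.n_per_class
        },
        "categories": list(CATEGORIES),
    }
    return cohort, truth


# ---------------------------------------------------------------------------
# Pan-cancer expression with planted pathway-ROR correlation


@dataclass(frozen=True)
class ExpressionSimConfig:
    """Expression-matrix generator with planted pathway–ROR correlations.

    Per cancer type a latent severity drives the ROR vector; each pathway's
    per-type activity is coupled to that latent through a Gaussian copula
    whose Pearson parameter is chosen (r = 2 sin(pi * rho / 6)) so the
    type-level Spearman correlation equals the planted rho.  Member genes of
    a pathway are shifted on the log scale by the type's activity.
    """

    n_genes: int = 1000
    n_cancer_types: int = 24
    samples_per_type: int = 3
    set_size: int = 40
    planted_rho: Mapping[str, float] = field(
        default_factory=lambda: {
            "mapk_negative_feedback": -0.379,
            "triglyceride_metabolism_negative_regulation": -0.664,
            "ip3_calcium_release_channel_activity": 0.389,
            "enos_no_metabolism": -0.439,
        }
    )
    effect_size: float = 1.0
    noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        for name, rho in self.planted_rho.items():
            if not -1 <= rho <= 1:
                raise ValueError(f"{name}: |rho| must be <= 1")
        if self.set_size * len(self.planted_rho) > self.n_genes:
            raise ValueError("gene sets exceed the gene universe")
        if self.n_cancer_types > len(CANCER_TYPES):
            raise ValueError(f"at most {len(CANCER_TYPES)} cancer types supported")


def simulate_expression(
    cfg: ExpressionSimConfig,
) -> tuple[ExpressionMatrix, dict[str, list[str]], pd.Series, dict]:
    """Draw the FPKM matrix, gene sets, per-cancer ROR vector and truth.

    Returns ``(matrix, gene_sets, rors, truth)`` where ``rors`` is indexed by
    cancer type and the truth record stores the planted rho per pathway and
    the latent per-type activities.
    """
    rng = np.random.default_rng(cfg.seed)
    types = CANCER_TYPES[: cfg.n_cancer_types]
    genes = [f"G{i:05d}" for i in range(cfg.n_genes)]

    pathways = list(cfg.planted_rho)
    gene_sets = {
        p: genes[i * cfg.set_size : (i + 1) * cfg.set_size] for i, p in enumerate(pathways)
    }

    latent = rng.standard_normal(cfg.n_cancer_types)  # shared ROR severity
    rors = pd.Series(np.exp(np.log(6.0) + 0.55 * latent), index=types, name="ror")

    activities = {}
    for p in pathways:
        r_pearson = 2.0 * np.sin(np.pi * cfg.planted_rho[p] / 6.0)
        eps = rng.standard_normal(cfg.n_cancer_types)
        activities[p] = r_pearson * latent + np.sqrt(1.0 - r_pearson**2) * eps

    base_log = rng.normal(3.0, 1.0, size=cfg.n_genes)
    n_samples = cfg.n_cancer_types * cfg.samples_per_type
    sample_ids = []
    sample_types = []
    log_expr = np.empty((cfg.n_genes, n_samples))
    col = 0
    for t_idx, t in enumerate(types):
        shift = np.zeros(cfg.n_genes)
        for p in pathways:
            members = slice(pathways.index(p) * cfg.set_size, (pathways.index(p) + 1) * cfg.set_size)
            shift[members] = cfg.effect_size * activities[p][t_idx]
        for s in range(cfg.samples_per_type):
            noise = rng.normal(0.0, cfg.noise_sd, size=cfg.n_genes)
            log_expr[:, col] = base_log + shift + noise
            sample_ids.append(f"{t}-S{s:02d}")
            sample_types.append(t)
            col += 1

    values = pd.DataFrame(np.exp(log_expr), index=genes, columns=sample_ids)
    matrix = ExpressionMatrix(
        values=values,
        sample_types=pd.Series(sample_types, index=sample_ids, name="cancer_type"),
        scale="FPKM",
    )
    truth = {
        "planted_rho": dict(cfg.planted_rho),
        "latent": latent.tolist(),
        "activities": {p: a.tolist() for p, a in activities.items()},
        "rors": rors.to_dict(),
        "types": types,
    }
    return matrix, gene_sets, rors, truth
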