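# Methods

This note documents the models, conventions and design choices behind
`vegfpv`, in the order the pipeline runs.

## Report screening

A case report carries demographics (sex, age with unit, country), the
suspect drug and its role, one indication, a non-empty set of MedDRA-style
preferred terms (PTs), and optional therapy-start/event dates. The
screening chain is:

1. **Deduplication.** Reports are duplicates when *all* of sex, age
   (value+unit compared verbatim, no unit conversion), country, event date,
   the reaction set as a whole (canonical sorted form), drug and indication
   coincide; the first occurrence in input order is retained. This is a
   field-identity rule, deterministic and order-stable; it does not attempt
   probabilistic record linkage.
2. **Malignancy filter.** Case-insensitive substring match of the
   indication against an editable keyword list (carcinoma, cancer,
   sarcoma, lymphoma, leukemia, melanoma, ...). A licensed MedDRA
   SOC mapping would be preferable; the keyword list is the portable
   approximation and is fully configurable. Reports without an indication
   cannot be confirmed malignant and are excluded (counted separately).
3. **Class assignment.** Drug names are normalized (lowercase, trimmed,
   trade-name parentheticals stripped) and looked up in a catalog mapping
   to VEGFi / VEGFRi / other. A flag restricts the set to primary-suspect
   reports.

The FAERS quarterly ASCII reader joins DEMO/DRUG/REAC/INDI/THER on
primaryid, emits one report per (primaryid, suspect drug), keeps
unparseable dates as absent, and drops reports with an empty reaction join
(logged). The flat CSV dialect (ISO dates, `;`-joined PTs) round-trips
losslessly and is what the synthetic generator emits.

## Disproportionality

ROR = ad/(bc) with the Woolf log-scale 95% CI; IC = log₂(a·N/((a+b)(a+c)))
with IC025 = IC − 1.96·√(1/a+1/b+1/c+1/d) on the log₂ scale. The IC
denominator is the expected-count form, which is exactly 0 under
independence; the alternative denominator (a+b)(c+d) is available as
`literal_ic` for auditing, and is the only one of the two that is strictly
monotone in `a` on very small tables (in the expected-count form `a` also
enters N and both margins, so an integer step can leave IC unchanged or
slightly lower it — e.g. (1,1,1,6)→(2,1,1,6)).

Zero cells: the point ROR with a = 0 is reported as 0 — a drug with no
observed target-event reports has no measurable excess — while CI, IC and
IC025 come from the +0.5 Haldane–Anscombe-corrected table so bounds stay
finite. The policy actually applied is recorded on every result.

The signal rule (a ≥ 3, ROR CI low > 1, IC025 > 0, all strict) is the error
control; no multiplicity adjustment is applied to signal tables. The
comparator for every table is "everything else in the analyzed report set":
class-level RORs are therefore within-database contrasts, and a strongly
over-reporting class sitting in the comparator masks weaker classes (the
README example shows this). Per-cancer RORs stratify the report set by an
indication→cancer-type mapping and omit strata with fewer than `min_cases`
exposed cases (default 5, strict: exactly 5 is kept).

## Time to onset

TTO is the whole-day difference event − therapy start; reports with a
missing date or a negative difference are excluded and counted, same-day
onsets are retained, and the first therapy start is used. Summaries use
linear-interpolation quantiles (the numpy/R type-7 default). Group
comparisons use the two-sided Mann–Whitney U test: tie-corrected normal
approximation when both groups have ≥ 8 observations, full permutation
enumeration below that (the enumeration handles ties, which textbook exact
tables do not). Two samples with no variation at all compare at p = 1 by
convention. Pairwise drug matrices report raw p-values; Holm step-down is
available behind a flag.

## Blood-pressure arm

Categories follow the 2023 European cutpoints with the printed gap between
139 and 140 (and 89/90) resolved as: hypertension iff sbp ≥ 140 or
dbp ≥ 90; high-normal iff sbp ∈ [130, 140) or dbp ∈ [85, 90); else normal.
A patient's category is the maximum of the systolic- and diastolic-implied
categories. Pressures outside (30, 300) mmHg are rejected as implausible.
The paired pre/post test is the Wilcoxon signed-rank (robust, consistent
with median/IQR reporting); a paired t-test is available behind a flag. An
all-zero difference vector yields p = 1 rather than an error. Transition
matrices are plain 3×3 counts (pre × post category) whose total equals the
cohort size; combining cohorts is elementwise addition.

## Pan-cancer arm

FPKM→TPM divides each sample column by its sum and scales to 10⁶. ssGSEA
scores one sample at a time: genes are ranked by expression (average ranks
for ties; tie order fixed positionally for determinism), in-set genes are
weighted by rank^α with α = 0.25 (the conventional exponent; configurable),
and the enrichment score is the sum over the ranked list of the weighted
in-set ECDF minus the uniform out-of-set ECDF. The integrated statistic is
the default; the maximum-deviation variant is switchable. No cross-sample
normalization is applied by default (single-sample contract); min–max
rescaling across samples is available behind a flag. Per-cancer activity is
the arithmetic mean score over that type's samples — the aggregation
statistic was an open choice; the mean is simple and matches the
per-cancer-mean framing of the correlation step. Spearman correlation with
per-cancer ROR uses the t-approximation at n ≥ 10 shared types and exact
permutation enumeration below; fewer than 4 shared types is an error.

## Synthetic data: what it emulates and what it does not

`simulate_reports` draws drugs from a marginal catalog, plants
per-(drug-or-class, PT-group) reporting odds ratios as *odds multipliers*
(so the planted value is exactly the true conditional odds ratio of the
pair against background), assigns a malignant indication with probability
0.8 by default, injects field-identical duplicates and missing event dates
at configurable rates, and draws onset delays from per-class log-normals —
medians 59 d (VEGFi), 21 d (VEGFRi) with log-sd ≈ 1.55/1.65 chosen so the
quartile ratios match the right-skew of observed onset distributions. Every
report carries two distinct background reactions so the deduplication
keyspace is large and accidental key collisions are negligible at test
sizes. Truth records store realized 2×2 cells on the malignancy-filtered
base set, so expected values of downstream statistics need no re-reading of
the data.

`simulate_clinical` draws pre-treatment (sbp, dbp) from a bivariate normal
(defaults 128/78 and 125/77 mmHg means, correlation 0.6) and adds planted
post shifts (+12/+2 VEGFi, +7/+4 VEGFRi) plus independent noise
(sd 10 mmHg, so post spreads widen as observed cohorts do); draws breaching
the plausibility window or sbp ≤ dbp are redrawn, and values are rounded to
0.1 mmHg. The truth record carries *analytic* transition probabilities
computed by inclusion–exclusion of 4-dimensional normal CDFs over the
category rectangles (truncation ignored; its mass is ~10⁻⁴ at the
defaults), validated against empirical frequencies to < 0.5%.

`simulate_expression` couples per-type pathway activities to a latent
per-cancer severity through a Gaussian copula with Pearson parameter
2·sin(π·ρ/6), so the type-level Spearman correlation with the derived ROR
vector equals the planted ρ (defaults −0.379, −0.664, +0.389, −0.439 across
four disjoint 40-gene sets in a 1000-gene universe, 24 cancer types, 3
samples per type, log-scale effect 1.0 and noise sd 0.3).

What the generators do **not** emulate: MedDRA vocabulary structure and PT
co-occurrence patterns, FAERS case versioning across quarters, reporting
heterogeneity over time and country, antihypertensive co-medication,
repeated blood-pressure trajectories, and gene–gene correlation beyond the
planted set-level shifts. Passing recovery tests therefore demonstrates
that the estimators are correct under the stated models, not that real
FAERS/TCGA extracts would reproduce any particular published value.

## Problem sizes and numerical conventions

Recovery tests run at 10⁴–5×10⁴ reports, 10³–5×10³ patients per cohort, and
24 cancer types × 3 samples — sizes at which the planted effects are
comfortably identified while the full suite stays fast. Formula agreement
is required to 1e-12 relative error; CI calibration is checked over 2500
multinomial draws; sign-recovery claims are evaluated over 100 fixed seeds.
All randomness flows through `numpy.random.default_rng(seed)`; identical
configs (seed included) give byte-identical outputs, which the tests check
on the emitted CSVs.

## Known limitations

- Keyword-based malignancy filtering is a stand-in for dictionary-based
  indication coding and is sensitive to the shipped term list.
- The Woolf CI and normal-approximation IC bound are asymptotic; at very
  small cells the +0.5 correction biases point estimates toward the null.
- Masking is inherent to within-database RORs; no restriction/active
  comparator designs are implemented.
- Transition matrices describe one pre/post pair per patient; dose,
  duration and antihypertensive treatment are out of scope.
- ssGSEA scores are comparable across samples only through their common
  rank construction; no batch/purity adjustment is attempted.
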