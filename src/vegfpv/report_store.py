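"""Case-report store: data model, readers and the preprocessing chain.

Spontaneous adverse-event reports are held column-wise in a
:class:`pandas.DataFrame` wrapped by :class:`ReportSet`; the per-report view
(:class:`CaseReport`) is materialized on demand.  The preprocessing chain —
:func:`deduplicate`, :func:`filter_malignancy`, :func:`assign_class` — mirrors
the screening flow of a FAERS disproportionality study: remove field-identical
duplicate reports, keep malignancy indications only, and label every suspect
drug with its class (VEGF-ligand inhibitor, VEGFR tyrosine-kinase inhibitor,
or other).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

PT_SEPARATOR = ";"

#: Columns every ReportSet frame carries, in canonical order.
REPORT_COLUMNS = [
    "report_id",
    "sex",
    "age",
    "age_unit",
    "country",
    "event_date",
    "therapy_start_date",
    "drug_name",
    "drug_role",
    "indication",
    "reactions",
]

SEXES = ("male", "female", "unknown")
AGE_UNITS = ("years", "months", "unknown")
DRUG_ROLES = ("primary_suspect", "other")
DRUG_CLASSES = ("VEGFi", "VEGFRi", "other")

#: Fields whose joint identity defines a duplicate report.
DEDUP_KEY = [
    "sex",
    "age",
    "age_unit",
    "country",
    "event_date",
    "reactions",
    "drug_name",
    "indication",
]

_PAREN_RE = re.compile(r"\s*\([^)]*\)")


def normalize_drug_name(name: str) -> str:
    """Lowercase, trim, and strip trade-name parentheticals.

    ``"Avastin (Bevacizumab)"`` and ``"BEVACIZUMAB"`` both normalize to a
    bare lowercase token so catalog lookup is spelling-insensitive.
    """
    return _PAREN_RE.sub("", str(name)).strip().lower()


def join_reactions(reactions: Iterable[str]) -> str:
    """Canonical string form of a reaction set: sorted, ';'-joined PTs."""
    pts = sorted({str(r).strip() for r in reactions if str(r).strip()})
    return PT_SEPARATOR.join(pts)


def split_reactions(cell: str) -> frozenset[str]:
    if not cell:
        return frozenset()
    return frozenset(p.strip() for p in str(cell).split(PT_SEPARATOR) if p.strip())


@dataclass(frozen=True)
class CaseReport:
    """One spontaneous adverse-event report."""

    report_id: str
    sex: str = "unknown"
    age: float | None = None
    age_unit: str = "unknown"
    country: str = ""
    event_date: date | None = None
    therapy_start_date: date | None = None
    drug_name: str = ""
    drug_role: str = "primary_suspect"
    indication: str = ""
    reactions: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.reactions:
            raise ValueError(f"report {self.report_id!r}: reactions must be non-empty")
        if self.sex not in SEXES:
            raise ValueError(f"report {self.report_id!r}: invalid sex {self.sex!r}")
        if self.age_unit not in AGE_UNITS:
            raise ValueError(f"report {self.report_id!r}: invalid age unit {self.age_unit!r}")
        if self.drug_role not in DRUG_ROLES:
            raise ValueError(f"report {self.report_id!r}: invalid drug role {self.drug_role!r}")


class ReportSet:
    """An ordered collection of case reports with filter provenance.

    Parameters
    ----------
    frame
        DataFrame with the :data:`REPORT_COLUMNS` layout.  ``reactions`` is
        the canonical sorted ';'-joined string; dates are ``datetime64``.
    provenance
        Free-text label of where the reports came from.
    filters_applied
        Ordered names of preprocessing steps already applied; grows
        monotonically as the chain runs.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        provenance: str = "",
        filters_applied: Sequence[str] = (),
    ) -> None:
        missing = [c for c in REPORT_COLUMNS if c not in frame.columns]
        if missing:
            raise ValueError(f"ReportSet frame missing columns: {missing}")
        frame = frame.reset_index(drop=True)
        if frame["report_id"].duplicated().any():
            dupes = frame.loc[frame["report_id"].duplicated(), "report_id"].head(3).tolist()
            raise ValueError(f"duplicate report_id values (e.g. {dupes})")
        empty = frame["reactions"].astype(str).str.len() == 0
        if empty.any():
            raise ValueError(f"{int(empty.sum())} reports have an empty reaction set")
        self.frame = frame
        self.provenance = provenance
        self.filters_applied = list(filters_applied)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ReportSet):
            return NotImplemented
        a = self.frame[REPORT_COLUMNS].reset_index(drop=True)
        b = other.frame[REPORT_COLUMNS].reset_index(drop=True)
        return a.equals(b)

    def __repr__(self) -> str:
        return (
            f"ReportSet(n={len(self)}, provenance={self.provenance!r}, "
            f"filters={self.filters_applied})"
        )

    @property
    def reports(self) -> Iterator[CaseReport]:
        """Yield per-report :class:`CaseReport` views (row order)."""
        for row in self.frame.itertuples(index=False):
            yield CaseReport(
                report_id=row.report_id,
                sex=row.sex,
                age=None if pd.isna(row.age) else float(row.age),
                age_unit=row.age_unit,
                country=row.country,
                event_date=None if pd.isna(row.event_date) else row.event_date.date(),
                therapy_start_date=(
                    None if pd.isna(row.therapy_start_date) else row.therapy_start_date.date()
                ),
                drug_name=row.drug_name,
                drug_role=row.drug_role,
                indication=row.indication,
                reactions=split_reactions(row.reactions),
            )

    def with_frame(self, frame: pd.DataFrame, extra_filter: str | None = None) -> "ReportSet":
        filters = self.filters_applied + ([extra_filter] if extra_filter else [])
        out = ReportSet.__new__(ReportSet)
        out.frame = frame.reset_index(drop=True)
        out.provenance = self.provenance
        out.filters_applied = filters
        return out

    @classmethod
    def from_reports(cls, reports: Iterable[CaseReport], provenance: str = "") -> "ReportSet":
        rows = []
        for r in reports:
            rows.append(
                {
                    "report_id": r.report_id,
                    "sex": r.sex,
                    "age": float("nan") if r.age is None else float(r.age),
                    "age_unit": r.age_unit,
                    "country": r.country,
                    "event_date": pd.Timestamp(r.event_date) if r.event_date else pd.NaT,
                    "therapy_start_date": (
                        pd.Timestamp(r.therapy_start_date) if r.therapy_start_date else pd.NaT
                    ),
                    "drug_name": normalize_drug_name(r.drug_name),
                    "drug_role": r.drug_role,
                    "indication": str(r.indication).strip(),
                    "reactions": join_reactions(r.reactions),
                }
            )
        frame = pd.DataFrame(rows, columns=REPORT_COLUMNS)
        frame["event_date"] = pd.to_datetime(frame["event_date"])
        frame["therapy_start_date"] = pd.to_datetime(frame["therapy_start_date"])
        return cls(frame, provenance=provenance)


@dataclass(frozen=True)
class DrugCatalog:
    """Mapping of normalized drug name to inhibitor class."""

    entries: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {v for v in self.entries.values()} - set(DRUG_CLASSES)
        if bad:
            raise ValueError(f"unknown drug classes: {sorted(bad)}")

    def classify(self, drug_name: str) -> str:
        return self.entries.get(normalize_drug_name(drug_name), "other")

    def names_in_class(self, drug_class: str) -> frozenset[str]:
        return frozenset(n for n, c in self.entries.items() if c == drug_class)

    @classmethod
    def default(cls) -> "DrugCatalog":
        """Catalog of the VEGF-ligand and VEGFR inhibitors under study."""
        vegfi = [
            "bevacizumab",
            "ranibizumab",
            "brolucizumab",
            "aflibercept",
            "conbercept",
            "pegaptanib",
        ]
        vegfri = [
            "ramucirumab",
            "nintedanib",
            "apatinib",
            "axitinib",
            "sunitinib",
            "sorafenib",
            "regorafenib",
            "vandetanib",
            "cabozantinib",
            "pazopanib",
            "lenvatinib",
            "anlotinib",
            "fruquintinib",
            "tivozanib",
            "cediranib",
            "brivanib",
        ]
        entries = {n: "VEGFi" for n in vegfi}
        entries.update({n: "VEGFRi" for n in vegfri})
        return cls(entries=entries)


@dataclass(frozen=True)
class PTCatalog:
    """Configurable preferred-term (PT) catalog for the blood-pressure arm.

    ``bp_related`` is the full screening list; ``hypertension_directly_related``
    is the subset used for the hypertension-focused analyses.  The default is
    a stand-in list with the structure of the study's screen (18 BP-related
    terms, 11 of them hypertension-direct); real analyses supply their own
    licensed terminology.
    """

    bp_related: frozenset[str]
    hypertension_directly_related: frozenset[str]

    def __post_init__(self) -> None:
        if not self.hypertension_directly_related <= self.bp_related:
            extra = self.hypertension_directly_related - self.bp_related
            raise ValueError(f"hypertension PTs not in bp_related: {sorted(extra)}")

    @classmethod
    def default(cls) -> "PTCatalog":
        hypertension = frozenset(
            {
                "Hypertension",
                "Hypertensive crisis",
                "Hypertensive emergency",
                "Hypertensive urgency",
                "Systolic hypertension",
                "Diastolic hypertension",
                "Secondary hypertension",
                "Malignant hypertension",
                "Labile hypertension",
                "Accelerated hypertension",
                "Hypertensive encephalopathy",
            }
        )
        bp_related = hypertension | frozenset(
            {
                "Blood pressure increased",
                "Blood pressure systolic increased",
                "Blood pressure diastolic increased",
                "Blood pressure abnormal",
                "Blood pressure fluctuation",
                "Blood pressure inadequately controlled",
                "Blood pressure ambulatory increased",
            }
        )
        return cls(bp_related=bp_related, hypertension_directly_related=hypertension)


#: Default malignancy keyword list (case-insensitive substring match).
DEFAULT_MALIGNANCY_TERMS = (
    "carcinoma",
    "cancer",
    "neoplasm malignant",
    "malignant neoplasm",
    "malignant melanoma",
    "sarcoma",
    "lymphoma",
    "leukemia",
    "leukaemia",
    "melanoma",
    "myeloma",
    "glioblastoma",
    "glioma",
    "mesothelioma",
    "blastoma",
    "adenocarcinoma",
    "tumour malignant",
    "tumor malignant",
)


# ---------------------------------------------------------------------------
# Readers / writers


def write_simple_csv(rs: ReportSet, path: str | Path) -> None:
    """Write the flat CSV dialect (ISO dates, ';'-joined reactions)."""
    out = rs.frame.copy()
    out["event_date"] = out["event_date"].dt.strftime("%Y-%m-%d")
    out["therapy_start_date"] = out["therapy_start_date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_simple_csv(path: str | Path, provenance: str | None = None) -> ReportSet:
    """Read the flat CSV dialect into a :class:`ReportSet`.

    Raises
    ------
    ValueError
        If a mandatory column is missing (named in the message) or a
        ``report_id`` occurs twice.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in REPORT_COLUMNS:
        if col not in frame.columns:
            raise ValueError(f"missing mandatory column: {col!r}")
    frame = frame[REPORT_COLUMNS].copy()
    frame["age"] = pd.to_numeric(frame["age"].replace("", None), errors="coerce")
    frame["event_date"] = pd.to_datetime(frame["event_date"], errors="coerce")
    frame["therapy_start_date"] = pd.to_datetime(frame["therapy_start_date"], errors="coerce")
    frame["drug_name"] = frame["drug_name"].map(normalize_drug_name)
    frame["reactions"] = frame["reactions"].map(lambda c: join_reactions(split_reactions(c)))
    return ReportSet(frame, provenance=provenance or str(path))


def _read_faers_table(path: str | Path) -> pd.DataFrame:
    """Read one $-delimited FAERS quarterly ASCII table, skipping bad rows."""
    frame = pd.read_csv(
        path,
        sep="$",
        dtype=str,
        keep_default_na=False,
        engine="python",
        on_bad_lines="warn",
    )
    frame.columns = [c.strip().lower() for c in frame.columns]
    return frame


def _parse_faers_date(series: pd.Series) -> pd.Series:
    """FAERS dates are YYYYMMDD (sometimes truncated); unparseable -> NaT."""
    return pd.to_datetime(series.str.strip(), format="%Y%m%d", errors="coerce")


def read_faers_ascii(paths: Mapping[str, str | Path], provenance: str = "faers") -> ReportSet:
    """Ingest FAERS quarterly ASCII tables into a :class:`ReportSet`.

    ``paths`` maps table names (``DEMO`` required; ``DRUG``, ``REAC``,
    ``INDI``, ``THER`` optional, case-insensitive) to file paths.  One report
    is produced per (primaryid, suspect drug); reports with no reactions are
    dropped and counted in the log.
    """
    keyed = {k.upper(): v for k, v in paths.items()}
    if "DEMO" not in keyed:
        raise ValueError("FAERS ingestion requires a DEMO table path")

    demo = _read_faers_table(keyed["DEMO"])
    if "primaryid" not in demo.columns:
        raise ValueError("DEMO table lacks a 'primaryid' column")
    n_raw = len(demo)
    demo = demo[demo["primaryid"].str.strip() != ""].copy()
    if len(demo) < n_raw:
        logger.warning("DEMO: skipped %d rows without primaryid", n_raw - len(demo))
    demo["primaryid"] = demo["primaryid"].str.strip()

    sex_map = {"M": "male", "F": "female"}
    demo["_sex"] = demo.get("sex", pd.Series("", index=demo.index)).str.strip().str.upper()
    demo["_sex"] = demo["_sex"].map(sex_map).fillna("unknown")
    demo["_age"] = pd.to_numeric(demo.get("age", pd.Series("", index=demo.index)), errors="coerce")
    unit_map = {"YR": "years", "MON": "months"}
    demo["_age_unit"] = (
        demo.get("age_cod", pd.Series("", index=demo.index)).str.strip().str.upper()
    )
    demo["_age_unit"] = demo["_age_unit"].map(unit_map).fillna("unknown")
    demo.loc[demo["_age"].isna(), "_age_unit"] = "unknown"
    demo["_country"] = demo.get("occr_country", pd.Series("", index=demo.index)).str.strip()
    demo["_event_date"] = _parse_faers_date(
        demo.get("event_dt", pd.Series("", index=demo.index))
    )
    n_bad_dates = int((demo.get("event_dt", pd.Series("", index=demo.index)).str.strip() != "").sum()
                      - demo["_event_date"].notna().sum())
    if n_bad_dates:
        logger.warning("DEMO: %d unparseable event dates kept as absent", n_bad_dates)
    demo = demo.drop_duplicates("primaryid", keep="first")

    if "DRUG" in keyed:
        drug = _read_faers_table(keyed["DRUG"])
        drug = drug[drug.get("drugname", pd.Series("", index=drug.index)).str.strip() != ""]
        drug = drug.assign(
            _drug=drug["drugname"].map(normalize_drug_name),
            _role=drug.get("role_cod", pd.Series("", index=drug.index))
            .str.strip()
            .str.upper()
            .map(lambda r: "primary_suspect" if r == "PS" else "other"),
            _seq=drug.get("drug_seq", pd.Series("", index=drug.index)).str.strip(),
        )[["primaryid", "_drug", "_role", "_seq"]]
        drug["primaryid"] = drug["primaryid"].str.strip()
        drug = drug.drop_duplicates(["primaryid", "_drug"], keep="first")
    else:
        drug = pd.DataFrame({"primaryid": demo["primaryid"], "_drug": "", "_role": "other",
                             "_seq": ""})

    if "REAC" in keyed:
        reac = _read_faers_table(keyed["REAC"])
        reac["primaryid"] = reac["primaryid"].str.strip()
        reac = reac[reac.get("pt", pd.Series("", index=reac.index)).str.strip() != ""]
        reactions = (
            reac.groupby("primaryid")["pt"].apply(lambda s: join_reactions(s)).rename("_reactions")
        )
    else:
        reactions = pd.Series(dtype=str, name="_reactions")

    if "INDI" in keyed:
        indi = _read_faers_table(keyed["INDI"])
        indi["primaryid"] = indi["primaryid"].str.strip()
        indi = indi[indi.get("indi_pt", pd.Series("", index=indi.index)).str.strip() != ""]
        indications = indi.groupby("primaryid")["indi_pt"].first().str.strip().rename("_indication")
    else:
        indications = pd.Series(dtype=str, name="_indication")

    if "THER" in keyed:
        ther = _read_faers_table(keyed["THER"])
        ther["primaryid"] = ther["primaryid"].str.strip()
        ther["_start"] = _parse_faers_date(ther.get("start_dt", pd.Series("", index=ther.index)))
        starts = ther.groupby("primaryid")["_start"].min().rename("_start")
    else:
        starts = pd.Series(dtype="datetime64[ns]", name="_start")

    merged = drug.merge(demo, on="primaryid", how="inner")
    for side in (reactions, indications, starts):
        merged = merged.merge(
            side.rename_axis("primaryid").reset_index(), on="primaryid", how="left"
        )

    no_reac = merged["_reactions"].isna() | (merged["_reactions"].astype(str).str.len() == 0)
    if no_reac.any():
        logger.warning("dropped %d (primaryid, drug) rows with no reactions", int(no_reac.sum()))
    merged = merged[~no_reac].copy()

    frame = pd.DataFrame(
        {
            "report_id": merged["primaryid"] + "-" + merged["_seq"].replace("", "1"),
            "sex": merged["_sex"],
            "age": merged["_age"],
            "age_unit": merged["_age_unit"],
            "country": merged["_country"],
            "event_date": merged["_event_date"],
            "therapy_start_date": merged.get("_start", pd.NaT),
            "drug_name": merged["_drug"],
            "drug_role": merged["_role"],
            "indication": merged["_indication"].fillna(""),
            "reactions": merged["_reactions"],
        },
        columns=REPORT_COLUMNS,
    )
    frame["therapy_start_date"] = pd.to_datetime(frame["therapy_start_date"])
    # Disambiguate any residual id collisions deterministically.
    dup = frame["report_id"].duplicated(keep=False)
    if dup.any():
        frame.loc[dup, "report_id"] = (
            frame.loc[dup, "report_id"] + "-" + frame.loc[dup].groupby("report_id").cumcount().astype(str)
        )
    logger.info("FAERS ingestion: %d reports from %d DEMO rows", len(frame), n_raw)
    return ReportSet(frame, provenance=provenance)


# ---------------------------------------------------------------------------
# Preprocessing chain


def deduplicate(rs: ReportSet) -> ReportSet:
    """Drop reports whose dedup key fields are all identical, keeping the first.

    The key is (sex, age+unit, country, event date, reaction set, drug,
    indication); the reaction set is compared as a whole via its canonical
    sorted string.  Age is compared as the (value, unit) pair verbatim — no
    unit conversion.
    """
    keep = ~rs.frame.duplicated(subset=DEDUP_KEY, keep="first")
    removed = int((~keep).sum())
    if removed:
        logger.info("deduplicate: removed %d of %d reports", removed, len(rs))
    return rs.with_frame(rs.frame[keep], extra_filter="deduplicate")


def filter_malignancy(
    rs: ReportSet, terms: Sequence[str] = DEFAULT_MALIGNANCY_TERMS
) -> ReportSet:
    """Keep reports whose indication matches a malignancy keyword.

    Matching is case-insensitive substring against ``terms``.  Reports with a
    blank indication cannot be confirmed malignant and are excluded (counted
    separately in the log).
    """
    if not terms:
        raise ValueError("malignancy term list must be non-empty")
    indication = rs.frame["indication"].astype(str).str.lower()
    pattern = "|".join(re.escape(t.lower()) for t in terms)
    matched = indication.str.contains(pattern, regex=True)
    blank = indication.str.strip() == ""
    keep = matched & ~blank
    logger.info(
        "filter_malignancy: kept %d of %d (%d blank-indication excluded)",
        int(keep.sum()),
        len(rs),
        int(blank.sum()),
    )
    return rs.with_frame(rs.frame[keep], extra_filter="filter_malignancy")


def assign_class(
    rs: ReportSet,
    cat: DrugCatalog | None = None,
    primary_suspect_only: bool = False,
) -> ReportSet:
    """Annotate each report with its drug class; optionally keep primary suspects.

    Adds a ``drug_class`` column (VEGFi / VEGFRi / other).  With
    ``primary_suspect_only`` the set is restricted to reports where the drug
    was the primary suspect, mirroring the primary-suspicion screen.
    """
    cat = cat or DrugCatalog.default()
    frame = rs.frame.copy()
    frame["drug_class"] = frame["drug_name"].map(cat.classify)
    filters = ["assign_class"]
    if primary_suspect_only:
        before = len(frame)
        frame = frame[frame["drug_role"] == "primary_suspect"]
        logger.info("primary-suspect screen: kept %d of %d", len(frame), before)
        filters.append("primary_suspect_only")
    out = rs.with_frame(frame)
    out.filters_applied += filters
    return out
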