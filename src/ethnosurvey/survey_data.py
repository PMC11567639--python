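"""Data model, ingestion and validation for long-format use-report tables.

A use-report table has one row per (informant, species, use category)
mention.  Loading normalizes identifiers, collapses duplicate triples
(a use report is a *distinct* triple: repeated mentions by the same
informant of the same species for the same purpose carry no extra
information), and attaches the study design — the total number of
respondents surveyed (N) and the fixed, ordered set of use categories
(NC of them).  N and NC are survey-frame quantities: they are the
denominators of the relative indices and must not silently shrink to
whatever happens to appear in a particular data file.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "SurveyError",
    "SchemaError",
    "EmptyInputError",
    "DesignError",
    "UseRecord",
    "StudyDesign",
    "UseReportTable",
    "Finding",
    "normalize_label",
    "load_use_reports",
    "load_use_reports_xlsx",
    "table_from_records",
    "validate",
    "write_use_reports",
]

#: Default CSV column names for the three identifier columns.
DEFAULT_COLUMNS = {
    "informant": "informant",
    "species": "species",
    "category": "use_category",
}

_WS = re.compile(r"\s+")


class SurveyError(Exception):
    """Base class for use-report table errors."""


class SchemaError(SurveyError):
    """A required column is missing from the input."""


class EmptyInputError(SurveyError):
    """The input contains no use reports."""


class DesignError(SurveyError):
    """Records are inconsistent with an explicitly supplied study design."""


def normalize_label(value: str, *, casefold: bool = True) -> str:
    """Normalize a hand-entered identifier.

    Trims leading/trailing whitespace and collapses internal runs of
    whitespace to a single space; species and use-category names are
    additionally case-folded.  Informant codes keep their case (set
    ``casefold=False``) because survey codes such as ``"a1"``/``"A1"``
    may be distinct respondents.
    """
    out = _WS.sub(" ", str(value).strip())
    return out.casefold() if casefold else out


@dataclass(frozen=True, order=True)
class UseRecord:
    """One use report: an informant citing a species for a use category."""

    informant_id: str
    species_id: str
    category_id: str

    def __post_init__(self) -> None:
        for f in ("informant_id", "species_id", "category_id"):
            if not getattr(self, f):
                raise ValueError(f"UseRecord.{f} must be non-empty")


@dataclass(frozen=True)
class StudyDesign:
    """The survey frame: total respondents N and the designed category set.

    ``n_informants`` is the number of people interviewed, which may exceed
    the number of informants contributing records; ``categories`` is the
    ordered tuple of designed use categories (its length is NC).
    """

    n_informants: int
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_informants < 1:
            raise ValueError("n_informants must be a positive integer")
        if len(self.categories) < 1:
            raise ValueError("at least one use category is required")
        if len(set(self.categories)) != len(self.categories):
            raise ValueError("use categories must be unique")
        object.__setattr__(self, "categories", tuple(self.categories))

    @property
    def n_categories(self) -> int:
        return len(self.categories)


@dataclass(frozen=True)
class UseReportTable:
    """A deduplicated use-report table plus its study design.

    ``records`` is a DataFrame with columns ``informant``, ``species``,
    ``category`` — one row per distinct triple, sorted lexicographically
    so that equal record sets compare equal regardless of input order.
    ``species_meta`` optionally carries passthrough strings per species
    (family, local name, voucher id, conservation status).
    """

    records: pd.DataFrame
    design: StudyDesign
    species_meta: Mapping[str, Mapping[str, str]] | None = field(default=None)

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def species(self) -> list[str]:
        return sorted(self.records["species"].unique())

    @property
    def informants(self) -> list[str]:
        return sorted(self.records["informant"].unique())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, UseReportTable):
            return NotImplemented
        return (
            self.design == other.design
            and self.records.reset_index(drop=True).equals(
                other.records.reset_index(drop=True)
            )
        )


def _canonical_frame(rows: pd.DataFrame) -> pd.DataFrame:
    """Deduplicate triples and impose the canonical sort order."""
    out = rows.drop_duplicates().sort_values(
        ["informant", "species", "category"], kind="mergesort"
    )
    return out.reset_index(drop=True)


def table_from_records(
    records: Iterable[UseRecord | tuple[str, str, str]],
    design: StudyDesign | None = None,
    species_meta: Mapping[str, Mapping[str, str]] | None = None,
) -> UseReportTable:
    """Build a table from in-memory records (already-normalized ids)."""
    triples = [
        (r.informant_id, r.species_id, r.category_id)
        if isinstance(r, UseRecord)
        else tuple(r)
        for r in records
    ]
    if not triples:
        raise EmptyInputError("no use reports supplied")
    frame = _canonical_frame(
        pd.DataFrame(triples, columns=["informant", "species", "category"]).astype(str)
    )
    design = _resolve_design(frame, design)
    return UseReportTable(records=frame, design=design, species_meta=species_meta)


def _resolve_design(frame: pd.DataFrame, design: StudyDesign | None) -> StudyDesign:
    observed_informants = frame["informant"].nunique()
    observed_categories = sorted(frame["category"].unique())
    if design is None:
        return StudyDesign(observed_informants, tuple(observed_categories))
    offenders = sorted(set(observed_categories) - set(design.categories))
    if offenders:
        raise DesignError(
            "categories in records absent from study design: " + ", ".join(offenders)
        )
    if design.n_informants < observed_informants:
        raise DesignError(
            f"design declares {design.n_informants} informants but records "
            f"contain {observed_informants} distinct informant ids"
        )
    return design


def load_use_reports(
    source: str | Path | IO[str],
    column_map: Mapping[str, str] | None = None,
    design: StudyDesign | None = None,
    *,
    delimiter: str = ",",
    normalize: bool = True,
    species_meta: Mapping[str, Mapping[str, str]] | None = None,
) -> UseReportTable:
    """Read a use-report table from a CSV stream or path.

    Parameters
    ----------
    source
        Path or text stream of a delimited file with a header row.
    column_map
        Maps the roles ``informant``, ``species``, ``category`` to column
        names in the file; defaults to ``informant,species,use_category``.
    design
        Explicit study design.  When absent, N defaults to the number of
        distinct informant ids observed and the categories to the distinct
        category labels observed (sorted).
    normalize
        Apply identifier normalization (whitespace; case-fold species and
        category labels).  Informant ids are never case-folded.

    Loading is order-independent: the same set of rows in any order yields
    an identical table.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    try:
        raw = pd.read_csv(source, sep=delimiter, dtype=str, skipinitialspace=False)
    except pd.errors.EmptyDataError:
        raise EmptyInputError("input file has no header row or content") from None
    missing = [cols[k] for k in ("informant", "species", "category") if cols[k] not in raw.columns]
    if missing:
        raise SchemaError(
            "missing required column(s): " + ", ".join(missing)
            + f" (found: {', '.join(raw.columns)})"
        )
    if raw.empty:
        raise EmptyInputError("input file contains a header but no use reports")
    frame = pd.DataFrame(
        {
            "informant": raw[cols["informant"]],
            "species": raw[cols["species"]],
            "category": raw[cols["category"]],
        }
    ).dropna()
    if normalize:
        frame["informant"] = frame["informant"].map(
            lambda v: normalize_label(v, casefold=False)
        )
        frame["species"] = frame["species"].map(normalize_label)
        frame["category"] = frame["category"].map(normalize_label)
    for col in ("informant", "species", "category"):
        if (frame[col] == "").any():
            raise SchemaError(f"empty {col} identifier after normalization")
    frame = _canonical_frame(frame)
    return UseReportTable(
        records=frame,
        design=_resolve_design(frame, design),
        species_meta=species_meta,
    )


def load_use_reports_xlsx(
    source: str | Path | IO[bytes],
    column_map: Mapping[str, str] | None = None,
    design: StudyDesign | None = None,
    *,
    sheet: str | int = 0,
    normalize: bool = True,
) -> UseReportTable:
    """Convenience reader for an XLSX sheet with the same columns as the CSV.

    Converts the sheet to CSV text and delegates to :func:`load_use_reports`,
    so both paths share one record model.  Requires ``openpyxl``.
    """
    raw = pd.read_excel(source, sheet_name=sheet, dtype=str)
    buf = io.StringIO()
    raw.to_csv(buf, index=False)
    buf.seek(0)
    return load_use_reports(buf, column_map, design, normalize=normalize)


@dataclass(frozen=True)
class Finding:
    """One validation diagnostic (informational; never an error)."""

    code: str
    message: str
    subjects: tuple[str, ...] = ()


def validate(table: UseReportTable) -> list[Finding]:
    """Report data-quality diagnostics without mutating the table.

    Flags informants declared in the design but contributing no records,
    designed categories with zero records, and species cited by a single
    informant (which make index estimates fragile).  An empty list means
    the table is fully populated.
    """
    findings: list[Finding] = []
    n_observed = table.records["informant"].nunique()
    silent = table.design.n_informants - n_observed
    if silent > 0:
        findings.append(
            Finding(
                "silent-informants",
                f"{silent} informant{'s' if silent != 1 else ''} contribute no records "
                f"(design N={table.design.n_informants}, observed {n_observed})",
            )
        )
    seen_categories = set(table.records["category"])
    empty = tuple(c for c in table.design.categories if c not in seen_categories)
    if empty:
        findings.append(
            Finding(
                "empty-categories",
                "designed use categories with zero records: " + ", ".join(empty),
                empty,
            )
        )
    fc = table.records.groupby("species")["informant"].nunique()
    singletons = tuple(fc.index[fc == 1])
    if singletons:
        findings.append(
            Finding(
                "single-informant-species",
                f"{len(singletons)} species cited by a single informant",
                singletons,
            )
        )
    return findings


def write_use_reports(table: UseReportTable, dest: str | Path | IO[str]) -> None:
    """Write the canonical deduplicated CSV (sorted, default column names)."""
    out = table.records.rename(
        columns={"informant": "informant", "species": "species", "category": "use_category"}
    )
    out.to_csv(dest, index=False, lineterminator="\n")
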