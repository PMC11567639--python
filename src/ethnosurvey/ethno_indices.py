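"""Per-species ethnobotanical indices and the ranked species index table.

Definitions (N = total respondents surveyed, NC = number of designed use
categories, maxima taken over the species in the analyzed table):

====  =========================================================
UR    use reports: distinct (informant, category) mentions of the species,
      summed over categories
FC    frequency of citation: distinct informants citing the species
NU    number of uses: distinct categories in which the species is cited
CI    cultural importance, UR / N (can exceed 1 for multi-use species)
RFC   relative frequency of citation, FC / N
RI    relative importance, (RFC/max RFC + NU/max NU) / 2
CVe   cultural value, (NU/NC) * RFC * CI
====  =========================================================

All arithmetic is full precision; rounding happens only at render time.
"""

from __future__ import annotations

import pandas as pd

from ethnosurvey.survey_data import EmptyInputError, UseReportTable

__all__ = [
    "use_report_count",
    "frequency_of_citation",
    "number_of_uses",
    "cultural_importance",
    "relative_frequency_of_citation",
    "relative_importance",
    "cultural_value",
    "species_index_table",
]


def _species_records(table: UseReportTable, species: str) -> pd.DataFrame:
    sub = table.records[table.records["species"] == species]
    if sub.empty:
        raise KeyError(f"species not present in table: {species!r}")
    return sub


def use_report_count(table: UseReportTable, species: str) -> int:
    """UR: number of distinct (informant, category) mentions of the species."""
    return len(_species_records(table, species))


def frequency_of_citation(table: UseReportTable, species: str) -> int:
    """FC: number of distinct informants citing the species for any use."""
    return int(_species_records(table, species)["informant"].nunique())


def number_of_uses(table: UseReportTable, species: str) -> int:
    """NU: number of distinct use categories in which the species is cited."""
    return int(_species_records(table, species)["category"].nunique())


def cultural_importance(ur: int, n: int) -> float:
    """CI = UR / N."""
    if n < 1:
        raise ValueError("informant total N must be >= 1")
    if ur < 0:
        raise ValueError("use-report count must be non-negative")
    return ur / n


def relative_frequency_of_citation(fc: int, n: int) -> float:
    """RFC = FC / N, a proportion in [0, 1]."""
    if n < 1:
        raise ValueError("informant total N must be >= 1")
    if not 0 <= fc <= n:
        raise ValueError(f"citation count {fc} outside [0, N={n}]")
    return fc / n


def relative_importance(fc_or_rfc: float, nu: int, max_rfc: float, max_nu: int) -> float:
    """RI = ((RFC / max RFC) + (NU / max NU)) / 2.

    ``fc_or_rfc`` and ``max_rfc`` must be on the same scale (both RFC
    proportions or both raw FC counts — the N denominator cancels).  The
    maxima are taken over the analyzed table, so RI is 1 only for a
    species attaining both the highest citation frequency and the highest
    number of uses.
    """
    if max_rfc <= 0:
        raise ValueError("max RFC must be positive (empty table?)")
    if max_nu < 1:
        raise ValueError("max NU must be >= 1")
    if fc_or_rfc > max_rfc or nu > max_nu:
        raise ValueError("species value exceeds the stated table maximum")
    return (fc_or_rfc / max_rfc + nu / max_nu) / 2


def cultural_value(nu: int, nc: int, fc: int, ur: int, n: int) -> float:
    """CVe = (NU / NC) * (FC / N) * (UR / N)."""
    if nc < 1 or n < 1:
        raise ValueError("NC and N must be >= 1")
    return (nu / nc) * (fc / n) * (ur / n)


def species_index_table(table: UseReportTable) -> pd.DataFrame:
    """All per-species indices, ranked by UR descending.

    Returns one row per species with columns ``species, ur, fc, nu, ci,
    rfc, ri, cve`` (plus any ``species_meta`` passthrough columns), sorted
    by UR descending with ties broken by species id ascending.  Values are
    full precision; apply display rounding at render time.
    """
    if table.n_records == 0:
        raise EmptyInputError("cannot build an index table from an empty table")
    n = table.design.n_informants
    nc = table.design.n_categories
    grouped = table.records.groupby("species")
    stats = pd.DataFrame(
        {
            "ur": grouped.size(),
            "fc": grouped["informant"].nunique(),
            "nu": grouped["category"].nunique(),
        }
    )
    stats["ci"] = stats["ur"] / n
    stats["rfc"] = stats["fc"] / n
    max_rfc = stats["rfc"].max()
    max_nu = stats["nu"].max()
    stats["ri"] = (stats["rfc"] / max_rfc + stats["nu"] / max_nu) / 2
    stats["cve"] = (stats["nu"] / nc) * stats["rfc"] * stats["ci"]
    stats = (
        stats.rename_axis("species")
        .reset_index()
        .sort_values(["ur", "species"], ascending=[False, True], kind="mergesort")
        .reset_index(drop=True)
    )
    if table.species_meta:
        meta = pd.DataFrame.from_dict(table.species_meta, orient="index").rename_axis(
            "species"
        )
        stats = stats.merge(meta.reset_index(), on="species", how="left")
        # keep meta columns in front of the numeric block, after the key
        meta_cols = [c for c in meta.columns]
        stats = stats[["species", *meta_cols, "ur", "fc", "nu", "ci", "rfc", "ri", "cve"]]
    return stats
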