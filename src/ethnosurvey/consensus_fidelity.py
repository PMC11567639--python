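"""Per-category consensus (IAR) and species-by-category fidelity levels (FL).

The informant agreement ratio of Trotter & Logan measures, for one use
category, how concentrated its use reports are on few species::

    IAR = (Nur - Ns) / (Nur - 1)

where Nur is the category's total use reports and Ns the number of species
cited for it.  IAR is 1 when all reports name a single species, 0 when
every report names a different one, and undefined for Nur <= 1 (a single
report carries no information about agreement).

The fidelity level of a species s for category u is the percentage of the
informants citing s at all who cite it for u::

    FL = 100 * UR_su / FC_s

The denominator is FC (distinct informants citing the species for any
use), so a species' FL values across categories sum to 100 * UR_s / FC_s,
which exceeds 100 whenever informants cite the species for several
purposes.
"""

from __future__ import annotations

import logging
import math

import pandas as pd

from ethnosurvey.survey_data import EmptyInputError, UseReportTable

__all__ = [
    "informant_agreement_ratio",
    "consensus_table",
    "fidelity_level",
    "fidelity_table",
]

logger = logging.getLogger(__name__)


def informant_agreement_ratio(nur: int, ns: int) -> float:
    """IAR = (Nur - Ns)/(Nur - 1); NaN (with a warning) for Nur <= 1."""
    if nur < 0 or ns < 0:
        raise ValueError("counts must be non-negative")
    if ns > nur:
        raise ValueError(f"species count Ns={ns} exceeds use reports Nur={nur}")
    if nur <= 1:
        logger.warning(
            "IAR undefined for Nur=%d (need at least 2 use reports)", nur
        )
        return math.nan
    return (nur - ns) / (nur - 1)


def consensus_table(table: UseReportTable) -> pd.DataFrame:
    """Per-category Nur, Ns and IAR, one row per designed category.

    Rows follow the study-design category order.  Designed categories with
    zero records appear with nur=0, ns=0 and an undefined (NaN) IAR.
    Columns ``nur_minus_ns`` and ``nur_minus_1`` expose the ratio's parts.
    """
    if table.n_records == 0:
        raise EmptyInputError("cannot build a consensus table from an empty table")
    grouped = table.records.groupby("category")
    nur = grouped.size()
    ns = grouped["species"].nunique()
    rows = []
    for cat in table.design.categories:
        c_nur = int(nur.get(cat, 0))
        c_ns = int(ns.get(cat, 0))
        rows.append(
            {
                "category": cat,
                "nur": c_nur,
                "ns": c_ns,
                "nur_minus_ns": c_nur - c_ns,
                "nur_minus_1": max(c_nur - 1, 0),
                "iar": informant_agreement_ratio(c_nur, c_ns),
            }
        )
    return pd.DataFrame(rows)


def fidelity_level(ur_su: int, fc_s: int) -> float:
    """FL = 100 * UR_su / FC_s, a percentage (full precision)."""
    if fc_s < 1:
        raise ValueError("citation frequency FC must be >= 1")
    if not 0 <= ur_su <= fc_s:
        raise ValueError(f"category count {ur_su} outside [0, FC={fc_s}]")
    return 100.0 * ur_su / fc_s


def fidelity_table(table: UseReportTable) -> pd.DataFrame:
    """FL for every populated (species, category) pair, grouped by category.

    One row per pair with ur_su >= 1, with columns ``category, species,
    ur_su, fl``.  Categories follow the study-design order; within a
    category rows sort by FL descending, species ascending.
    """
    if table.n_records == 0:
        raise EmptyInputError("cannot build a fidelity table from an empty table")
    fc = table.records.groupby("species")["informant"].nunique()
    pairs = (
        table.records.groupby(["category", "species"])
        .size()
        .rename("ur_su")
        .reset_index()
    )
    pairs["fl"] = 100.0 * pairs["ur_su"] / pairs["species"].map(fc)
    order = {c: i for i, c in enumerate(table.design.categories)}
    pairs["_rank"] = pairs["category"].map(order)
    pairs = (
        pairs.sort_values(
            ["_rank", "fl", "species"],
            ascending=[True, False, True],
            kind="mergesort",
        )
        .drop(columns="_rank")
        .reset_index(drop=True)
    )
    return pairs[["category", "species", "ur_su", "fl"]]
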