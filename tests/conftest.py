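"""Shared fixtures: the Ghana reference survey, published expected values,
small hand-built tables, and a brute-force index oracle.

The published_* CSVs freeze the index/consensus/fidelity values of the
Ghana vernacular-building survey as printed (3-decimal indices, 2-decimal
FL).  Two fidelity rows absent from the printed table (Bambusa vulgaris,
thatch material; and the thatch row completing Ns=8) are recovered from
exact marginal closure and included.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pytest
from hypothesis import settings

from ethnosurvey.reference import reference_table
from ethnosurvey.survey_data import UseReportTable, table_from_records

settings.register_profile("ci", derandomize=True, max_examples=60)
settings.load_profile("ci")

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def ghana_table() -> UseReportTable:
    return reference_table()


@pytest.fixture(scope="session")
def published_indices() -> pd.DataFrame:
    return pd.read_csv(DATA / "published_species_indices.csv", dtype=str)


@pytest.fixture(scope="session")
def published_consensus() -> pd.DataFrame:
    return pd.read_csv(DATA / "published_consensus.csv", dtype=str)


@pytest.fixture(scope="session")
def published_fidelity() -> pd.DataFrame:
    return pd.read_csv(DATA / "published_fidelity.csv", dtype=str)


@pytest.fixture
def tiny_table() -> UseReportTable:
    """3 informants, 2 species, 2 categories; hand-enumerable."""
    return table_from_records(
        [
            ("i1", "sp a", "cat1"),
            ("i1", "sp a", "cat2"),
            ("i2", "sp a", "cat1"),
            ("i3", "sp a", "cat1"),
            ("i3", "sp b", "cat2"),
        ]
    )


# ---------------------------------------------------------------- oracle


def brute_force_indices(
    triples: set[tuple[str, str, str]], n: int, nc: int
) -> dict[str, dict[str, float]]:
    """Direct enumeration of every per-species index from a triple set.

    Independent of the pandas implementation: pure python sets and loops.
    """
    species = {s for _, s, _ in triples}
    out: dict[str, dict[str, float]] = {}
    for s in species:
        mine = {(i, c) for i, s2, c in triples if s2 == s}
        ur = len(mine)
        fc = len({i for i, _ in mine})
        nu = len({c for _, c in mine})
        out[s] = {
            "ur": ur,
            "fc": fc,
            "nu": nu,
            "ci": ur / n,
            "rfc": fc / n,
            "cve": (nu / nc) * (fc / n) * (ur / n),
        }
    max_rfc = max(v["rfc"] for v in out.values())
    max_nu = max(v["nu"] for v in out.values())
    for v in out.values():
        v["ri"] = (v["rfc"] / max_rfc + v["nu"] / max_nu) / 2
    return out


def brute_force_consensus(
    triples: set[tuple[str, str, str]], categories: tuple[str, ...]
) -> dict[str, tuple[int, int]]:
    """Per-category (Nur, Ns) by direct enumeration."""
    return {
        cat: (
            sum(1 for _, _, c in triples if c == cat),
            len({s for _, s, c in triples if c == cat}),
        )
        for cat in categories
    }


def brute_force_fidelity(
    triples: set[tuple[str, str, str]]
) -> dict[tuple[str, str], float]:
    """FL per populated (species, category) pair by direct enumeration."""
    out = {}
    species = {s for _, s, _ in triples}
    for s in species:
        fc = len({i for i, s2, _ in triples if s2 == s})
        for cat in {c for _, s2, c in triples if s2 == s}:
            ur_su = len({i for i, s2, c in triples if s2 == s and c == cat})
            out[(s, cat)] = 100.0 * ur_su / fc
    return out
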