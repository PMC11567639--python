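"""Per-species index arithmetic, ranking, and oracle equivalence."""

from __future__ import annotations

import pytest
from hypothesis import given
from hypothesis import strategies as st

from ethnosurvey.ethno_indices import (
    cultural_importance,
    cultural_value,
    frequency_of_citation,
    number_of_uses,
    relative_frequency_of_citation,
    relative_importance,
    species_index_table,
    use_report_count,
)
from ethnosurvey.survey_data import EmptyInputError, table_from_records

from conftest import brute_force_indices


class TestScalarFormulas:
    @pytest.mark.parametrize(
        "ur,n,expected",
        [(440, 258, 1.705), (406, 258, 1.574), (0, 258, 0.0)],
    )
    def test_cultural_importance(self, ur, n, expected):
        assert cultural_importance(ur, n) == pytest.approx(expected, abs=5e-4)

    @pytest.mark.parametrize(
        "fc,n,expected",
        [(251, 258, 0.973), (258, 258, 1.0), (211, 258, 0.818)],
    )
    def test_relative_frequency_of_citation(self, fc, n, expected):
        assert relative_frequency_of_citation(fc, n) == pytest.approx(
            expected, abs=5e-4
        )

    @pytest.mark.parametrize(
        "rfc,nu,max_rfc,max_nu,expected",
        [
            (162 / 258, 4, 251 / 258, 4, 0.823),  # top-RI species
            (251 / 258, 2, 251 / 258, 4, 0.750),  # top-RFC species, NU=2
            (61 / 258, 1, 251 / 258, 4, 0.247),  # ((61/251)+(1/4))/2
            (0.5, 3, 0.5, 3, 1.0),  # attains both maxima
        ],
    )
    def test_relative_importance(self, rfc, nu, max_rfc, max_nu, expected):
        assert relative_importance(rfc, nu, max_rfc, max_nu) == pytest.approx(
            expected, abs=5e-4
        )

    @pytest.mark.parametrize(
        "nu,nc,fc,ur,n,expected",
        [
            (4, 6, 162, 440, 258, 0.714),
            (1, 6, 187, 187, 258, 0.088),  # (1/6)*(187/258)^2
            (3, 6, 107, 288, 258, 0.231),
            (2, 6, 10, 0, 258, 0.0),
        ],
    )
    def test_cultural_value(self, nu, nc, fc, ur, n, expected):
        assert cultural_value(nu, nc, fc, ur, n) == pytest.approx(expected, abs=5e-4)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            cultural_importance(10, 0)
        with pytest.raises(ValueError):
            relative_frequency_of_citation(5, 4)
        with pytest.raises(ValueError):
            relative_importance(0.5, 1, 0.0, 4)
        with pytest.raises(ValueError):
            cultural_value(1, 0, 1, 1, 10)


class TestTableCounts:
    def test_hand_enumerated_counts(self, tiny_table):
        # sp a: i1 x {cat1,cat2}, i2 x cat1, i3 x cat1 -> UR=4, FC=3, NU=2
        assert use_report_count(tiny_table, "sp a") == 4
        assert frequency_of_citation(tiny_table, "sp a") == 3
        assert number_of_uses(tiny_table, "sp a") == 2
        assert use_report_count(tiny_table, "sp b") == 1

    def test_three_informants_two_categories_each(self):
        t = table_from_records(
            [(f"i{k}", "x", c) for k in range(3) for c in ("u1", "u2")]
        )
        assert use_report_count(t, "x") == 6
        assert frequency_of_citation(t, "x") == 3

    def test_informant_counted_once_across_categories(self):
        t = table_from_records([("i1", "x", c) for c in "abcd"])
        assert frequency_of_citation(t, "x") == 1
        assert use_report_count(t, "x") == 4

    def test_unknown_species_raises_lookup_error(self, tiny_table):
        with pytest.raises(KeyError):
            use_report_count(tiny_table, "nope")


class TestIndexTable:
    def test_sorted_by_ur_then_species(self):
        t = table_from_records(
            [("i1", "b", "c1"), ("i1", "a", "c1"), ("i2", "a", "c1"), ("i2", "b", "c2")]
        )
        idx = species_index_table(t)
        assert list(idx["species"]) == ["a", "b"]  # UR tie at 2 -> id ascending

    def test_single_record_table(self):
        idx = species_index_table(table_from_records([("i", "s", "c")]))
        row = idx.iloc[0]
        assert (row.ur, row.fc, row.nu) == (1, 1, 1)
        assert row.ri == 1.0

    def test_empty_table_rejected_at_construction(self):
        with pytest.raises(EmptyInputError):
            table_from_records([])

    def test_internal_consistency_invariants(self, ghana_table):
        idx = species_index_table(ghana_table)
        n = ghana_table.design.n_informants
        nc = ghana_table.design.n_categories
        assert (idx.fc <= idx.ur).all()
        assert (idx.ur <= idx.fc * idx.nu).all()
        assert (idx.rfc <= idx.ci + 1e-12).all()
        assert (idx.ci == idx.ur / n).all()
        expected_cve = (idx.nu / nc) * idx.rfc * idx.ci
        assert (idx.cve - expected_cve).abs().max() < 1e-12

    def test_meta_columns_passthrough(self, ghana_table):
        idx = species_index_table(ghana_table)
        assert {"family", "local_name", "status"} <= set(idx.columns)
        top = idx.iloc[0]
        assert (top.species, top.family) == ("bambusa vulgaris", "Poaceae")


triples_strategy = st.sets(
    st.tuples(
        st.sampled_from([f"i{k}" for k in range(10)]),
        st.sampled_from([f"s{k}" for k in range(5)]),
        st.sampled_from([f"c{k}" for k in range(4)]),
    ),
    min_size=1,
    max_size=60,
)


@given(triples=triples_strategy)
def test_indices_match_brute_force_enumeration(triples):
    """Grouped pandas implementation equals direct set enumeration."""
    t = table_from_records(sorted(triples))
    n, nc = t.design.n_informants, t.design.n_categories
    oracle = brute_force_indices(triples, n, nc)
    idx = species_index_table(t).set_index("species")
    assert set(idx.index) == set(oracle)
    for s, exp in oracle.items():
        for col in ("ur", "fc", "nu", "ci", "rfc", "ri", "cve"):
            assert idx.loc[s, col] == pytest.approx(exp[col], rel=1e-12), (s, col)


@given(triples=triples_strategy, extra=st.tuples(
    st.sampled_from([f"i{k}" for k in range(10)]),
    st.sampled_from([f"s{k}" for k in range(5)]),
    st.sampled_from([f"c{k}" for k in range(4)]),
))
def test_adding_a_record_never_decreases_per_species_counts(triples, extra):
    base = table_from_records(sorted(triples))
    grown = table_from_records(sorted(triples | {extra}))
    sp = extra[1]
    n = max(base.design.n_informants, grown.design.n_informants)
    before = (
        (0, 0, 0)
        if sp not in base.species
        else (
            use_report_count(base, sp),
            frequency_of_citation(base, sp),
            number_of_uses(base, sp),
        )
    )
    after = (
        use_report_count(grown, sp),
        frequency_of_citation(grown, sp),
        number_of_uses(grown, sp),
    )
    assert all(a >= b for a, b in zip(after, before))


@given(triples=triples_strategy)
def test_ri_invariant_under_informant_pool_duplication(triples):
    """Duplicating every informant's records under fresh ids leaves RI fixed."""
    doubled = set(triples) | {(i + "_copy", s, c) for i, s, c in triples}
    ri1 = species_index_table(table_from_records(sorted(triples))).set_index("species")["ri"]
    ri2 = species_index_table(table_from_records(sorted(doubled))).set_index("species")["ri"]
    for s in ri1.index:
        assert ri2[s] == pytest.approx(ri1[s], rel=1e-12)
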