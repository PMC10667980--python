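"""Binning, bucket tables, aggregation, expansion: the integration algebra."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from fedpipe.integration import (
    EMPTY_LABEL,
    BucketTable,
    IntegrationError,
    aggregate,
    bucketize,
    categorize,
    categorize_with_notes,
    default_scheme,
    expand,
    suppress_small_cells,
)

from conftest import make_record


# -- independent categorization oracle (plain if/elif, no BinSpec logic) -----

def oracle_tuple(values):
    def age_label(a):
        if a is None:
            return EMPTY_LABEL
        if 18 <= a < 50:
            return "18-50"
        if 50 <= a < 70:
            return "50-70"
        if a >= 70:
            return ">70"
        return EMPTY_LABEL

    def edss_label(e):
        if e is None:
            return EMPTY_LABEL
        if 0 <= e < 6:
            return "0-6"
        if 6 <= e <= 10:
            return "6-10"
        return EMPTY_LABEL

    def choice(v):
        return EMPTY_LABEL if v is None else v

    return (
        age_label(values.get("age_years")),
        choice(values.get("sex")),
        choice(values.get("ms_type")),
        edss_label(values.get("edss_value")),
        choice(values.get("type_dmt")),
        choice(values.get("covid19_admission_hospital")),
        choice(values.get("covid19_icu_admission")),
        choice(values.get("covid19_ventilation")),
        choice(values.get("covid19_death")),
    )


class TestScheme:
    def test_age_has_three_bins(self, scheme):
        assert scheme.labels("age_years") == ("18-50", "50-70", ">70")

    def test_dmt_has_twelve_categories(self, scheme):
        assert len(scheme.labels("type_dmt")) == 12

    def test_all_labels_unique_within_variable(self, scheme):
        for var in scheme.variables:
            labels = scheme.labels(var)
            assert len(labels) == len(set(labels))

    def test_severity_outcomes_are_binary_indicators(self, scheme):
        for var in ("covid19_admission_hospital", "covid19_icu_admission",
                    "covid19_ventilation", "covid19_death"):
            assert scheme.labels(var) == ("yes", "no")


class TestCategorize:
    @pytest.mark.parametrize(
        "age,label",
        [(49, "18-50"), (50, "50-70"), (69, "50-70"), (70, ">70"), (95, ">70"),
         (18, "18-50")],
    )
    def test_age_interval_closure_lower_inclusive(self, scheme, age, label):
        tup = categorize(make_record(age_years=age), scheme)
        assert tup[0] == label

    @pytest.mark.parametrize("edss,label", [(5.5, "0-6"), (6.0, "6-10"), (10.0, "6-10")])
    def test_edss_dichotomized_at_six(self, scheme, edss, label):
        tup = categorize(make_record(edss_value=edss), scheme)
        assert tup[3] == label

    def test_missing_value_maps_to_empty(self, scheme):
        tup = categorize(make_record(edss_value=None), scheme)
        assert tup[3] == EMPTY_LABEL

    def test_under_age_domain_maps_to_empty_with_note(self, scheme):
        tup, notes = categorize_with_notes(make_record(age_years=15), scheme)
        assert tup[0] == EMPTY_LABEL
        assert any("age_years" in n for n in notes)

    @given(
        age=st.one_of(st.none(), st.integers(0, 110)),
        edss=st.one_of(st.none(),
                       st.integers(0, 20).map(lambda i: i / 2.0)),
    )
    @settings(max_examples=200, derandomize=True, deadline=None)
    def test_every_in_domain_value_falls_in_exactly_one_bin(self, scheme, age, edss):
        """Partition property: bins are disjoint and cover the domain."""
        for var, value in (("age_years", age), ("edss_value", edss)):
            if value is None:
                continue
            hits = [b.label for b in scheme.bin_specs(var) if b.contains(value)]
            assert len(hits) <= 1
            if var == "edss_value" or value >= 18:
                assert len(hits) == 1  # in-domain -> exactly one

    def test_matches_independent_oracle_on_synthetic_records(self, scheme,
                                                             cleaned_records):
        _, pooled = cleaned_records
        for rec in pooled[:200]:
            assert categorize(rec, scheme) == oracle_tuple(rec.values)


class TestBucketize:
    def test_identical_records_share_one_row(self, scheme):
        records = [make_record(record_id=str(i)) for i in range(3)]
        table = bucketize(records, scheme)
        assert len(table.counts) == 1
        assert table.n == 3

    def test_zero_records_give_empty_table(self, scheme):
        table = bucketize([], scheme)
        assert table.counts == {}
        assert table.n == 0

    def test_counts_match_brute_force_tally(self, scheme, cleaned_records):
        _, pooled = cleaned_records
        records = pooled[:200]
        tally = {}
        for rec in records:
            tup = oracle_tuple(rec.values)
            tally[tup] = tally.get(tup, 0) + 1
        assert bucketize(records, scheme).counts == tally

    def test_counts_strictly_positive(self, scheme):
        with pytest.raises(IntegrationError):
            BucketTable(scheme=scheme, counts={("18-50",) + (EMPTY_LABEL,) * 8: 0})


class TestAggregate:
    def test_counts_add_tuple_wise(self, scheme, cleaned_records):
        per_source, pooled = cleaned_records
        tables = [bucketize(recs, scheme, sid) for sid, recs in per_source.items()]
        combined = aggregate(tables)
        assert combined == bucketize(pooled, scheme)
        assert combined.n == len(pooled)

    def test_disjoint_and_overlapping_tuples(self, scheme):
        a_tup = ("18-50", "female", "relapsing_remitting", "0-6", "untreated",
                 "no", "no", "no", "no")
        b_tup = ("50-70",) + a_tup[1:]
        t1 = BucketTable(scheme=scheme, counts={a_tup: 2}, source_id="a")
        t2 = BucketTable(scheme=scheme, counts={a_tup: 3, b_tup: 1}, source_id="b")
        combined = aggregate([t1, t2])
        assert combined.counts == {a_tup: 5, b_tup: 1}
        assert combined.sources == ("a", "b")

    def test_commutative_and_associative(self, scheme, cleaned_records):
        per_source, _ = cleaned_records
        t = [bucketize(recs, scheme, sid) for sid, recs in per_source.items()]
        assert aggregate(t) == aggregate(t[::-1])
        assert aggregate([aggregate(t[:2]), t[2]]) == aggregate([t[0], aggregate(t[1:])])

    def test_scheme_mismatch_names_first_differing_bin(self, scheme, cleaned_records):
        from fedpipe.integration import BinSpec, BinningScheme

        _, pooled = cleaned_records
        other = BinningScheme(
            bins=tuple(
                (var, specs) if var != "edss_value"
                else (var, (BinSpec("edss_value", "0-4", lo=0, hi=4),
                            BinSpec("edss_value", "4-10", lo=4, hi=10, hi_incl=True)))
                for var, specs in scheme.bins
            )
        )
        t1 = bucketize(pooled[:10], scheme, "a")
        t2 = bucketize(pooled[:10], other, "b")
        with pytest.raises(IntegrationError, match="edss_value"):
            aggregate([t1, t2])

    def test_federated_equivalence_over_random_partitions(self, scheme,
                                                          cleaned_records):
        """Core property: aggregating per-source tables equals bucketizing
        the pooled records, for arbitrary partitions of the record set."""
        _, pooled = cleaned_records
        pooled_table = bucketize(pooled, scheme)
        rng = random.Random(2024)
        for trial in range(30):
            k = rng.randint(1, 6)
            parts = [[] for _ in range(k)]
            for rec in pooled:
                parts[rng.randrange(k)].append(rec)
            tables = [bucketize(p, scheme, f"part{j}") for j, p in enumerate(parts) if p]
            assert aggregate(tables) == pooled_table


class TestExpand:
    def test_single_tuple_repeats_count_times(self, scheme):
        tup = ("18-50", "female", "relapsing_remitting", "0-6", "untreated",
               "no", "no", "no", "no")
        table = BucketTable(scheme=scheme, counts={tup: 3}, source_id="a")
        expanded = expand(table)
        assert expanded.rows == (tup, tup, tup)
        assert expanded.sources == ("a", "a", "a")

    def test_empty_table_expands_to_zero_rows(self, scheme):
        assert expand(BucketTable(scheme=scheme, counts={})).n == 0

    def test_expansion_order_is_deterministic(self, scheme, cleaned_records):
        per_source, _ = cleaned_records
        tables = [bucketize(recs, scheme, sid) for sid, recs in per_source.items()]
        a = expand(aggregate(tables))
        b = expand(aggregate(tables[::-1]))
        assert a.rows == b.rows
        assert a.sources == b.sources

    def test_round_trip_on_random_bucket_tables(self, scheme):
        """bucketize(expand(S)) == S for arbitrary canonical tables."""
        rng = random.Random(7)
        label_sets = [list(scheme.labels(v)) + [EMPTY_LABEL] for v in scheme.variables]
        for trial in range(50):
            counts = {}
            for _ in range(rng.randint(0, 40)):
                tup = tuple(rng.choice(ls) for ls in label_sets)
                counts[tup] = rng.randint(1, 9)
            table = BucketTable(scheme=scheme, counts=counts,
                                source_id=f"t{trial}")
            expanded = expand(table)
            assert expanded.n == table.n
            assert expanded.to_bucket_table() == table

    def test_expanded_table_contains_only_bin_labels(self, scheme, cleaned_records):
        """Privacy surface: no raw age, date or score survives expansion."""
        _, pooled = cleaned_records
        expanded = expand(bucketize(pooled, scheme))
        allowed = {v: set(scheme.labels(v)) | {EMPTY_LABEL} for v in scheme.variables}
        for row in expanded.rows:
            for var, label in zip(scheme.variables, row):
                assert label in allowed[var]


class TestSuppression:
    def test_threshold_zero_is_identity(self, scheme, cleaned_records):
        _, pooled = cleaned_records
        table = bucketize(pooled, scheme)
        out, suppressed = suppress_small_cells(table, 0)
        assert out == table
        assert suppressed == 0

    def test_small_cells_removed_and_total_reported(self, scheme):
        a = ("18-50", "female", "relapsing_remitting", "0-6", "untreated",
             "no", "no", "no", "no")
        b = ("50-70",) + a[1:]
        table = BucketTable(scheme=scheme, counts={a: 1, b: 5})
        out, suppressed = suppress_small_cells(table, 2)
        assert out.counts == {b: 5}
        assert suppressed == 1

    def test_suppression_never_increases_counts(self, scheme, cleaned_records):
        _, pooled = cleaned_records
        table = bucketize(pooled, scheme)
        out, suppressed = suppress_small_cells(table, 3)
        for tup, c in out.counts.items():
            assert c == table.counts[tup]
        assert out.n + suppressed == table.n
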