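import itertools
import random

import pytest
from hypothesis import given, strategies as st

from phycodelim.cbc_barcode import (AnalysisConfig, Barcode, BarcodeColumn,
                                    ChangeClass, Lineage, PAIR_CODES,
                                    classify_change, compare_barcodes,
                                    count_variable_positions,
                                    delimit_species, encode_pair)
from phycodelim.io_formats import FormatError

SIX = list(PAIR_CODES)


class TestEncodePair:
    @pytest.mark.parametrize("b5,b3,code", [
        ("A", "U", 1), ("U", "A", 2), ("G", "C", 3),
        ("C", "G", 4), ("G", "U", 5), ("U", "G", 6),
        ("C", "C", 7), ("A", "G", 7),
        ("A", "-", 8), ("-", "-", 8),
    ])
    def test_code_table(self, b5, b3, code):
        assert encode_pair(b5, b3).code == code

    def test_unpaired_flag_forces_deletion_code(self):
        assert encode_pair("A", "U", paired=False).code == 8

    def test_dna_input_normalized(self):
        assert encode_pair("a", "t").code == 1

    def test_non_iupac_rejected(self):
        with pytest.raises(FormatError):
            encode_pair("A", "Z")


def brute_force_class(a: BarcodeColumn, b: BarcodeColumn) -> ChangeClass:
    """Independent nucleotide-level classification (no code arithmetic)."""
    unamb = set("ACGU")
    if (a.base5, a.base3) == (b.base5, b.base3):
        return ChangeClass.IDENTICAL
    if {a.base5, a.base3, b.base5, b.base3} - (unamb | {"-"}):
        return ChangeClass.AMBIGUOUS
    gap_a = "-" in (a.base5, a.base3) or a.code == 8
    gap_b = "-" in (b.base5, b.base3) or b.code == 8
    if gap_a or gap_b:
        return ChangeClass.INDEL_CHANGE
    pairing = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"),
               ("G", "U"), ("U", "G")}
    if (a.base5, a.base3) not in pairing or (b.base5, b.base3) not in pairing:
        return ChangeClass.MISMATCH_CHANGE
    changed = (a.base5 != b.base5) + (a.base3 != b.base3)
    return ChangeClass.CBC if changed == 2 else ChangeClass.HCBC


class TestClassifyChange:
    @pytest.mark.parametrize("pa,pb,expected", [
        (("A", "U"), ("G", "C"), ChangeClass.CBC),
        (("A", "U"), ("G", "U"), ChangeClass.HCBC),
        (("G", "C"), ("G", "U"), ChangeClass.HCBC),
        (("A", "U"), ("A", "U"), ChangeClass.IDENTICAL),
        (("-", "-"), ("-", "-"), ChangeClass.IDENTICAL),
        (("C", "C"), ("G", "C"), ChangeClass.MISMATCH_CHANGE),
        (("A", "N"), ("G", "C"), ChangeClass.AMBIGUOUS),
    ])
    def test_examples(self, pa, pb, expected):
        assert classify_change(encode_pair(*pa), encode_pair(*pb)) == expected

    def test_deletion_vs_pair_is_indel(self):
        a = encode_pair("A", "-")
        b = encode_pair("G", "C")
        assert a.code == 8 and b.code == 3
        assert classify_change(a, b) is ChangeClass.INDEL_CHANGE

    def test_exhaustive_pair_type_grid(self):
        """All 36 ordered combinations of the six pairing-retaining types:
        CBC iff both strands differ, HCBC iff exactly one, else identical."""
        for pa, pb in itertools.product(SIX, repeat=2):
            a, b = encode_pair(*pa), encode_pair(*pb)
            got = classify_change(a, b)
            changed = (pa[0] != pb[0]) + (pa[1] != pb[1])
            want = {0: ChangeClass.IDENTICAL, 1: ChangeClass.HCBC,
                    2: ChangeClass.CBC}[changed]
            assert got is want, (pa, pb)

    @given(st.sampled_from("ACGU-N"), st.sampled_from("ACGU-N"),
           st.sampled_from("ACGU-N"), st.sampled_from("ACGU-N"))
    def test_symmetric(self, a5, a3, b5, b3):
        a, b = encode_pair(a5, a3), encode_pair(b5, b3)
        assert classify_change(a, b) is classify_change(b, a)


def _random_barcode(rng, strain, n):
    cols = []
    for _ in range(n):
        kind = rng.random()
        if kind < 0.7:
            cols.append(encode_pair(*SIX[rng.randrange(6)]))
        elif kind < 0.85:
            b5, b3 = rng.choice("ACGU"), rng.choice("ACGU")
            cols.append(encode_pair(b5, b3))
        else:
            cols.append(encode_pair(rng.choice("ACGU-"), "-"))
    return Barcode(strain, tuple(cols))


class TestCompareBarcodes:
    def test_identical_barcodes(self):
        b = Barcode("x", tuple(encode_pair(*p) for p in SIX))
        c = compare_barcodes(b, b)
        assert (c.n_cbc, c.n_hcbc, c.n_other) == (0, 0, 0)

    def test_length_mismatch(self):
        a = Barcode("a", (encode_pair("A", "U"),))
        b = Barcode("b", tuple(encode_pair(*p) for p in SIX))
        with pytest.raises(ValueError, match="length"):
            compare_barcodes(a, b)

    def test_planted_counts_recovered(self, its2_barcodes):
        barcodes, _, truth = its2_barcodes
        by_strain = {b.strain: b for b in barcodes}
        for (spa, spb), (k_cbc, k_hcbc) in truth.pair_changes.items():
            a = by_strain[f"{spa}_s1"]
            b = by_strain[f"{spb}_s1"]
            cmp_ = compare_barcodes(a, b)
            assert (cmp_.n_cbc, cmp_.n_hcbc) == (k_cbc, k_hcbc)

    def test_counts_match_brute_force_on_random_pairs(self):
        rng = random.Random(42)
        for _ in range(100):
            a = _random_barcode(rng, "a", 20)
            b = _random_barcode(rng, "b", 20)
            cmp_ = compare_barcodes(a, b)
            tally = [brute_force_class(x, y)
                     for x, y in zip(a.columns, b.columns)]
            assert cmp_.n_cbc == tally.count(ChangeClass.CBC)
            assert cmp_.n_hcbc == tally.count(ChangeClass.HCBC)
            assert cmp_.n_other == tally.count(ChangeClass.MISMATCH_CHANGE) \
                + tally.count(ChangeClass.INDEL_CHANGE)

    def test_counts_sum_to_non_identical_non_ambiguous(self):
        rng = random.Random(1)
        a = _random_barcode(rng, "a", 30)
        b = _random_barcode(rng, "b", 30)
        c = compare_barcodes(a, b)
        n_ident = sum(cls is ChangeClass.IDENTICAL for cls in c.per_column)
        n_amb = sum(cls is ChangeClass.AMBIGUOUS for cls in c.per_column)
        assert c.n_cbc + c.n_hcbc + c.n_other == 30 - n_ident - n_amb


class TestVariablePositions:
    def test_all_identical_is_zero(self):
        b = Barcode("x", tuple(encode_pair(*p) for p in SIX))
        assert count_variable_positions([b, Barcode("y", b.columns)]) == 0

    def test_planted_count(self, its2_barcodes):
        barcodes, _, truth = its2_barcodes
        assert count_variable_positions(barcodes) == truth.n_variable_pairs

    def test_fewer_than_two_is_error(self):
        b = Barcode("x", (encode_pair("A", "U"),))
        with pytest.raises(ValueError):
            count_variable_positions([b])

    def test_monotone_in_added_barcodes(self):
        rng = random.Random(3)
        barcodes = [_random_barcode(rng, f"s{i}", 15) for i in range(6)]
        counts = [count_variable_positions(barcodes[:k])
                  for k in range(2, 7)]
        assert counts == sorted(counts)

    def test_two_distinct_mismatches_count_as_variable(self):
        # both columns code 7, but the bases differ -> variable
        a = Barcode("a", (encode_pair("C", "C"),))
        b = Barcode("b", (encode_pair("A", "A"),))
        assert count_variable_positions([a, b]) == 1


def _mk(strain, pairs):
    return Barcode(strain, tuple(encode_pair(*p) for p in pairs))


class TestDelimitSpecies:
    def test_single_lineage_single_strain(self):
        b = _mk("s1", SIX)
        part = delimit_species([Lineage("L1", frozenset(["s1"]))], [b])
        assert part.groups == (("s1",),)

    def test_cbc_separates_despite_low_support(self):
        a = _mk("a", [("A", "U")])
        b = _mk("b", [("G", "C")])
        part = delimit_species(
            [Lineage("A", frozenset(["a"]), bootstrap=10.0),
             Lineage("B", frozenset(["b"]), bootstrap=10.0)], [a, b])
        assert part.n_species == 2
        assert next(iter(part.evidence.values()))["kind"] == "CBC"

    def test_hcbc_with_low_support_merges(self):
        a = _mk("a", [("A", "U")])
        b = _mk("b", [("G", "U")])
        part = delimit_species(
            [Lineage("A", frozenset(["a"]), bootstrap=60.0),
             Lineage("B", frozenset(["b"]), bootstrap=60.0)], [a, b])
        assert part.groups == (("a", "b"),)

    def test_hcbc_with_high_support_separates(self):
        a = _mk("a", [("A", "U")])
        b = _mk("b", [("G", "U")])
        part = delimit_species(
            [Lineage("A", frozenset(["a"]), bootstrap=95.0),
             Lineage("B", frozenset(["b"]), bootstrap=95.0)], [a, b])
        assert part.n_species == 2
        assert next(iter(part.evidence.values()))["kind"] == "HCBC+support"

    def test_posterior_can_supply_support(self):
        a = _mk("a", [("A", "U")])
        b = _mk("b", [("G", "U")])
        part = delimit_species(
            [Lineage("A", frozenset(["a"]), posterior=0.99),
             Lineage("B", frozenset(["b"]), posterior=0.99)], [a, b])
        assert part.n_species == 2

    def test_planted_partition_recovered(self, its2_barcodes):
        barcodes, _, truth = its2_barcodes
        part = delimit_species(truth.lineages, barcodes)
        assert part.groups == truth.partition

    def test_invariant_to_ordering(self, its2_barcodes):
        barcodes, _, truth = its2_barcodes
        part1 = delimit_species(truth.lineages, barcodes)
        part2 = delimit_species(list(reversed(truth.lineages)),
                                list(reversed(barcodes)))
        assert part1.groups == part2.groups

    def test_strain_without_barcode_is_error(self):
        b = _mk("a", [("A", "U")])
        with pytest.raises(ValueError, match="barcode"):
            delimit_species([Lineage("A", frozenset(["a", "ghost"]))], [b])

    def test_config_validation(self):
        with pytest.raises(ValueError):
            AnalysisConfig(bootstrap_support_min=150)


def test_code_string_rendering():
    b = _mk("x", [("G", "C"), ("C", "G"), ("A", "U"), ("U", "A")])
    assert b.code_string() == "3412"
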