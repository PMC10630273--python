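"""Cassette mining, size groups, combination tables, histogram."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lyticmine import (
    CdsFeature,
    GenomeRecord,
    LyticRole,
    ProteinArchitecture,
    assign_size_group,
    build_cassette,
    find_cassettes,
    group_census,
    size_histogram,
    tabulate,
    type_cassette,
)
from lyticmine.annotation import Category, DomainSpan
from lyticmine.mining import primary_cassette, round_percent


class TestSizeGroups:
    @pytest.mark.parametrize("length,label", [
        (15_000, 1), (19_999, 1),
        (20_000, 2), (49_999, 2),   # boundary goes to the upper group
        (50_000, 3), (65_000, 4), (99_999, 4),
        (100_000, 5), (120_000, 5),
    ])
    def test_assignment(self, length, label):
        assert assign_size_group(length).label == label

    @pytest.mark.parametrize("bad", [0, -5])
    def test_non_positive_length_rejected(self, bad):
        with pytest.raises(ValueError):
            assign_size_group(bad)

    def test_partition_of_random_lengths(self):
        rng = np.random.default_rng(0)
        lengths = rng.integers(1, 200_000, size=2_000)
        genomes = [
            GenomeRecord(f"g{i}", f"g{i}", int(n)) for i, n in enumerate(lengths)
        ]
        census = group_census(genomes)
        assert sum(census.values()) == 2_000
        for g in genomes:  # exactly one group: bounds are exclusive above
            sg = assign_size_group(g.length_bp)
            assert sg.lower_bp <= g.length_bp < sg.upper_bp


def _genome_with_roles(roles, length=10_000):
    cds, archs = [], []
    for i, role in enumerate(roles):
        pid = f"p{i}"
        cds.append(CdsFeature(pid, i * 400, i * 400 + 300, "+",
                              translation="M" * 99))
        domains = ()
        if role is LyticRole.HOLIN:
            domains = (DomainSpan("Phage_holin_1", Category.HOLIN, 1, 80),)
        elif role is LyticRole.ENDOLYSIN:
            domains = (DomainSpan("Amidase_2", Category.CATALYTIC, 1, 90),)
        elif role is LyticRole.HOLIN_LIKE:
            domains = (DomainSpan("XhlA", Category.HOLIN_LIKE, 1, 80),)
        archs.append(ProteinArchitecture(pid, role, domains))
    genome = GenomeRecord("g", "g", length, cds=tuple(cds))
    return genome, archs


U, H, E, X = (LyticRole.UNKNOWN, LyticRole.HOLIN, LyticRole.ENDOLYSIN,
              LyticRole.HOLIN_LIKE)


class TestFindCassettes:
    def test_unknown_ends_trimmed(self):
        genome, archs = _genome_with_roles([U, H, E, U])
        (c,) = find_cassettes(genome, archs)
        assert c.member_ids == ("p1", "p2")

    def test_gap_over_limit_splits_cassettes(self):
        genome, archs = _genome_with_roles([H, U, U, U, E])
        cassettes = find_cassettes(genome, archs, max_gap_genes=2)
        assert [c.member_ids for c in cassettes] == [("p0",), ("p4",)]

    def test_gap_within_limit_bridges(self):
        genome, archs = _genome_with_roles([H, U, U, E])
        (c,) = find_cassettes(genome, archs, max_gap_genes=2)
        assert c.member_ids == ("p0", "p1", "p2", "p3")

    def test_holin_like_neighbor_joins_and_sets_xhla(self):
        genome, archs = _genome_with_roles([X, H, E])
        (c,) = find_cassettes(genome, archs)
        assert c.member_ids == ("p0", "p1", "p2")
        assert c.has_xhla

    def test_no_seed_no_cassette(self):
        genome, archs = _genome_with_roles([U, X, U])
        assert find_cassettes(genome, archs) == []

    def test_mining_is_idempotent(self):
        genome, archs = _genome_with_roles([U, H, E, U, U, U, H, E])
        first = find_cassettes(genome, archs)
        second = find_cassettes(genome, archs)
        assert first == second
        assert len(first) == 2

    def test_architectures_must_cover_all_cds(self):
        genome, archs = _genome_with_roles([H, E])
        with pytest.raises(ValueError):
            find_cassettes(genome, archs[:1])

    def test_primary_cassette_largest_then_leftmost(self):
        genome, archs = _genome_with_roles([H, U, U, U, H, E])
        cassettes = find_cassettes(genome, archs)
        assert primary_cassette(cassettes).member_ids == ("p4", "p5")


def _cassette(holin=None, endolysins=(), xhla=False, accession="g"):
    members = []
    i = 0
    if xhla:
        members.append(ProteinArchitecture(
            f"{accession}_x{i}", LyticRole.HOLIN_LIKE,
            (DomainSpan("XhlA", Category.HOLIN_LIKE, 1, 80),)))
    if holin:
        members.append(ProteinArchitecture(
            f"{accession}_h", LyticRole.HOLIN,
            (DomainSpan(holin, Category.HOLIN, 1, 80),)))
    for j, (cat, cwbs) in enumerate(endolysins):
        domains = [DomainSpan(cat, Category.CATALYTIC, 1, 150)]
        pos = 170
        for cwb in cwbs:
            domains.append(DomainSpan(cwb, Category.CWB, pos, pos + 55))
            pos += 60
        members.append(ProteinArchitecture(
            f"{accession}_e{j}", LyticRole.ENDOLYSIN, tuple(domains)))
    return build_cassette(accession, tuple(members))


class TestTypeCassette:
    def test_known_pair_key(self):
        c = _cassette("Phage_holin_1", [("Amidase_2", ["SH3_5"])])
        assert type_cassette(c).key == "PH_1|Amidase_2+SH3_5|xhla=0"

    def test_no_cwb_is_unknown(self):
        c = _cassette("Phage_holin_4_1", [("Amidase_2", [])])
        assert "Amidase_2+Unknown" in type_cassette(c).key

    def test_two_cwb_domains_joined_n_to_c(self):
        c = _cassette("Phage_holin_5_2", [("Amidase_2", ["SH3_5", "SH3_3"])])
        assert "Amidase_2+SH3_5 + SH3_3" in type_cassette(c).key

    def test_identical_content_same_key(self):
        a = _cassette("Phage_holin_1", [("Amidase_2", ["SH3_5"])], accession="a")
        b = _cassette("Phage_holin_1", [("Amidase_2", ["SH3_5"])], accession="b")
        assert type_cassette(a) == type_cassette(b)

    def test_empty_cassette_rejected(self):
        arch = ProteinArchitecture("p", LyticRole.UNKNOWN)
        with pytest.raises(ValueError):
            type_cassette(build_cassette("g", (arch,)))


class TestTabulate:
    def test_dominant_category_percent(self):
        cassettes = (
            [_cassette("Phage_holin_1", [("Amidase_2", [])], accession=f"a{i}")
             for i in range(56)]
            + [_cassette("Phage_holin_1", [("CHAP", [])], accession=f"b{i}")
               for i in range(115)]
        )
        table = tabulate(cassettes)
        assert table.total == 171
        row = next(r for r in table.rows if r[0] == ("Amidase_2", "Unknown"))
        assert (row[1], row[2]) == (56, 32.75)

    def test_single_category_is_100(self):
        cassettes = [_cassette("Holin_SPP1", [("Amidase_5", ["SH3_5"])],
                               accession=f"g{i}") for i in range(7)]
        table = tabulate(cassettes)
        assert table.rows[0][2] == 100.00

    def test_19_of_171_is_11_11(self):
        assert round_percent(100 * 19 / 171) == 11.11

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            tabulate([])

    def test_holin_axis(self):
        cassettes = [_cassette("Phage_holin_1", [("Amidase_2", ["SH3_5"])],
                               accession=f"g{i}") for i in range(3)]
        table = tabulate(cassettes, "holin_catalytic_cwb")
        assert table.rows[0][0] == ("PH_1", "Amidase_2", "SH3_5")

    @given(st.lists(st.integers(min_value=1, max_value=50), min_size=1,
                    max_size=8))
    def test_conservation(self, counts):
        """Counts sum to total and percents to 100 within rounding slack."""
        cassettes = []
        for k, n in enumerate(counts):
            cat = f"Cat{k}"
            cassettes += [_cassette("Phage_holin_1", [(cat, [])],
                                    accession=f"g{k}_{i}") for i in range(n)]
        table = tabulate(cassettes)
        assert sum(r[1] for r in table.rows) == table.total == sum(counts)
        assert abs(sum(r[2] for r in table.rows) - 100.0) \
            <= 0.01 * len(table.rows)


class TestHistogram:
    def test_example_bins(self):
        genomes = [GenomeRecord(f"g{i}", f"g{i}", n)
                   for i, n in enumerate([15_000, 35_000, 36_000])]
        assert size_histogram(genomes, 10_000) == [(10_000, 1), (30_000, 2)]

    def test_empty(self):
        assert size_histogram([], 10_000) == []

    def test_counts_sum_to_input_size(self):
        rng = np.random.default_rng(1)
        genomes = [GenomeRecord(f"g{i}", f"g{i}", int(n))
                   for i, n in enumerate(rng.integers(1, 150_000, size=500))]
        hist = size_histogram(genomes, 7_000)
        assert sum(c for _, c in hist) == 500

    def test_bad_width_rejected(self):
        with pytest.raises(ValueError):
            size_histogram([], 0)
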