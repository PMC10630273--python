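"""Lytic-cassette mining and tabulation.

Finds lytic cassettes as gene neighborhoods seeded on holins/endolysins,
stratifies genomes into the five genome-size groups, abstracts cassettes
into canonical type keys, and builds the catalytic×CWB and
holin×catalytic×CWB combination tables plus the genome-size histogram.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from .annotation import Category, LyticRole, ProteinArchitecture
from .genome_io import GenomeRecord

#: (label, lower inclusive, upper exclusive); the five groups partition (0, inf)
SIZE_GROUP_BOUNDS: tuple[tuple[int, int, float], ...] = (
    (1, 0, 20_000),
    (2, 20_000, 50_000),
    (3, 50_000, 65_000),
    (4, 65_000, 100_000),
    (5, 100_000, float("inf")),
)

#: display abbreviations for holin family names in combination tables
HOLIN_ALIASES = {
    "Phage_holin_1": "PH_1",
    "Phage_holin_Dp1": "PH_Dp1",
    "Phage_holin_4_1": "PH_4_1",
    "Phage_holin_5_2": "PH_5_2",
    "Phage_holin_2_2": "PH_2_2",
    "Holin_SPP1": "Holin_SPP1",
    "Holin_BhlA": "HolinBhlA",
}

UNKNOWN_CWB = "Unknown"


@dataclass(frozen=True)
class SizeGroup:
    label: int
    lower_bp: int
    upper_bp: float


def assign_size_group(length_bp: int) -> SizeGroup:
    """Place a genome in its unique size group (half-open, lower-inclusive:
    a genome of exactly 20,000 bp belongs to Group 2)."""
    if length_bp <= 0:
        raise ValueError(f"genome length must be positive, got {length_bp}")
    for label, lo, hi in SIZE_GROUP_BOUNDS:
        if lo <= length_bp < hi:
            return SizeGroup(label, lo, hi)
    raise AssertionError("size groups do not partition (0, inf)")  # pragma: no cover


@dataclass(frozen=True)
class Endolysin:
    """The abstracted composition of one endolysin in a cassette."""

    protein_id: str
    catalytic: str | None
    cwb: tuple[str, ...]  # N->C order; empty means no known CWB domain

    @property
    def cwb_label(self) -> str:
        return " + ".join(self.cwb) if self.cwb else UNKNOWN_CWB


@dataclass(frozen=True)
class LyticCassette:
    genome_accession: str
    members: tuple[ProteinArchitecture, ...]
    holin_domains: frozenset[str]
    endolysins: tuple[Endolysin, ...]
    has_xhla: bool

    @property
    def member_ids(self) -> tuple[str, ...]:
        return tuple(m.protein_id for m in self.members)


SEED_ROLES = (LyticRole.HOLIN, LyticRole.ENDOLYSIN)


def find_cassettes(
    genome: GenomeRecord,
    architectures: Sequence[ProteinArchitecture],
    max_gap_genes: int = 2,
) -> list[LyticCassette]:
    """Mine lytic cassettes from one genome.

    Every holin or endolysin seeds a cassette; neighbors on either strand
    with a lytic role (anything but ``unknown``) extend it, tolerating up to
    ``max_gap_genes`` consecutive unknown-role genes inside, trimming
    unknown-role genes from the ends.  Overlapping seeds merge.
    """
    if len(architectures) != len(genome.cds):
        raise ValueError(
            f"{genome.accession}: {len(architectures)} architectures for "
            f"{len(genome.cds)} CDS; architectures must cover every CDS")
    roles = [a.role for a in architectures]
    n = len(roles)
    clusters: list[tuple[int, int]] = []  # inclusive index ranges
    i = 0
    while i < n:
        if roles[i] in SEED_ROLES:
            start = i
            # extend left over lytic-role genes with gaps <= max_gap_genes
            j = i - 1
            gap = 0
            while j >= 0:
                if roles[j] == LyticRole.UNKNOWN:
                    gap += 1
                    if gap > max_gap_genes:
                        break
                else:
                    start = j
                    gap = 0
                j -= 1
            # extend right the same way
            end = i
            j = i + 1
            gap = 0
            while j < n:
                if roles[j] == LyticRole.UNKNOWN:
                    gap += 1
                    if gap > max_gap_genes:
                        break
                else:
                    end = j
                    gap = 0
                j += 1
            if clusters and start <= clusters[-1][1]:
                clusters[-1] = (clusters[-1][0], max(clusters[-1][1], end))
            else:
                clusters.append((start, end))
            i = end + 1
        else:
            i += 1
    cassettes = []
    for start, end in clusters:
        members = tuple(architectures[start:end + 1])
        if not any(m.role in SEED_ROLES for m in members):
            continue
        cassettes.append(build_cassette(genome.accession, members))
    return cassettes


def build_cassette(accession: str,
                   members: tuple[ProteinArchitecture, ...]) -> LyticCassette:
    """Assemble a cassette from ordered member architectures."""
    holins = frozenset(
        d.name for m in members if m.role == LyticRole.HOLIN
        for d in m.domains_in(Category.HOLIN)
    )
    endolysins = []
    for m in members:
        if m.role != LyticRole.ENDOLYSIN:
            continue
        cats = m.domains_in(Category.CATALYTIC)
        cwbs = m.domains_in(Category.CWB)
        endolysins.append(Endolysin(
            protein_id=m.protein_id,
            catalytic=cats[0].name if cats else None,
            cwb=tuple(d.name for d in cwbs),
        ))
    return LyticCassette(
        genome_accession=accession,
        members=members,
        holin_domains=holins,
        endolysins=tuple(endolysins),
        has_xhla=any(m.has_xhla for m in members),
    )


def primary_cassette(cassettes: Sequence[LyticCassette]) -> LyticCassette | None:
    """The genome's primary cassette: most members, ties to the leftmost."""
    if not cassettes:
        return None
    return max(enumerate(cassettes), key=lambda t: (len(t[1].members), -t[0]))[1]


def holin_alias(name: str) -> str:
    return HOLIN_ALIASES.get(name, name)


@dataclass(frozen=True)
class CassetteType:
    """Deterministic canonical key for a cassette's abstracted content."""

    key: str


def type_cassette(c: LyticCassette) -> CassetteType:
    """Canonical type key: sorted holin aliases, per-endolysin
    "catalytic+CWB" strings (multiple CWB domains joined N→C with " + "),
    and the XhlA flag."""
    if not c.holin_domains and not c.endolysins:
        raise ValueError(
            f"{c.genome_accession}: cassette has neither holin nor endolysin")
    holin_part = "+".join(sorted(holin_alias(h) for h in c.holin_domains)) or "NoHolin"
    endo_parts = [
        f"{e.catalytic or 'Unknown'}+{e.cwb_label}" for e in c.endolysins
    ]
    endo_part = ";".join(endo_parts) or "NoEndolysin"
    return CassetteType(f"{holin_part}|{endo_part}|xhla={int(c.has_xhla)}")


# ---------------------------------------------------------------------------
# Tabulation
# ---------------------------------------------------------------------------

def round_percent(value: float) -> float:
    """Round to two decimals, half away from zero (matches the printed
    combination-table percentages, e.g. 56/171 -> 32.75)."""
    return float(Decimal(repr(value)).quantize(Decimal("0.01"),
                                               rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CombinationTable:
    axes: tuple[str, ...]
    rows: tuple[tuple[tuple[str, ...], int, float], ...]  # (key, count, percent)
    total: int

    def as_records(self) -> list[dict[str, object]]:
        recs = []
        for key, count, pct in self.rows:
            rec: dict[str, object] = dict(zip(self.axes, key))
            rec["n_cassettes"] = count
            rec["percent"] = pct
            recs.append(rec)
        return recs


def _endolysin_units(cassettes: Iterable[LyticCassette], with_holin: bool
                     ) -> list[tuple[str, ...]]:
    units = []
    for c in cassettes:
        for e in c.endolysins:
            cat = e.catalytic or "Unknown"
            if with_holin:
                holin = "+".join(sorted(holin_alias(h) for h in c.holin_domains)) \
                    or "NoHolin"
                units.append((holin, cat, e.cwb_label))
            else:
                units.append((cat, e.cwb_label))
    return units


def tabulate(cassettes: Sequence[LyticCassette],
             axes: str = "catalytic_cwb") -> CombinationTable:
    """Count catalytic×CWB (``axes="catalytic_cwb"``) or
    holin×catalytic×CWB (``axes="holin_catalytic_cwb"``) combinations.

    One unit per endolysin per cassette; percent = 100·count/total rounded
    half-away-from-zero to two decimals; rows sorted by count descending,
    then key.
    """
    if not cassettes:
        raise ValueError("tabulate: empty cassette list")
    if axes == "catalytic_cwb":
        axis_names = ("catalytic_domain", "cwb_domain")
        units = _endolysin_units(cassettes, with_holin=False)
    elif axes == "holin_catalytic_cwb":
        axis_names = ("holin", "catalytic_domain", "cwb_domain")
        units = _endolysin_units(cassettes, with_holin=True)
    else:
        raise ValueError(f"unknown axes spec {axes!r}")
    counts: dict[tuple[str, ...], int] = {}
    for u in units:
        counts[u] = counts.get(u, 0) + 1
    total = len(units)
    rows = tuple(
        (key, count, round_percent(100.0 * count / total))
        for key, count in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    )
    return CombinationTable(axes=axis_names, rows=rows, total=total)


def tabulate_counts(counts: Sequence[tuple[tuple[str, ...], int]],
                    axis_names: tuple[str, ...]) -> CombinationTable:
    """Build a combination table directly from (key, count) pairs — the same
    percent arithmetic as :func:`tabulate` for externally counted tables."""
    total = sum(c for _, c in counts)
    if total <= 0:
        raise ValueError("tabulate_counts: counts must sum to a positive total")
    rows = tuple(
        (tuple(key), count, round_percent(100.0 * count / total))
        for key, count in sorted(counts, key=lambda kv: (-kv[1], tuple(kv[0])))
    )
    return CombinationTable(axes=axis_names, rows=rows, total=total)


def size_histogram(genomes: Sequence[GenomeRecord],
                   bin_width_bp: int = 5_000) -> list[tuple[int, int]]:
    """Genome-size histogram with left-closed bins from zero; returns
    (bin lower bound, count) for non-empty bins, ascending."""
    if bin_width_bp <= 0:
        raise ValueError("bin_width_bp must be positive")
    counts: dict[int, int] = {}
    for g in genomes:
        b = (g.length_bp // bin_width_bp) * bin_width_bp
        counts[b] = counts.get(b, 0) + 1
    return sorted(counts.items())


def group_census(genomes: Sequence[GenomeRecord]) -> dict[int, int]:
    """Number of genomes per size group (labels 1–5, zero included)."""
    census = {label: 0 for label, _, _ in SIZE_GROUP_BOUNDS}
    for g in genomes:
        census[assign_size_group(g.length_bp).label] += 1
    return census
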