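"""Genome and domain-scan I/O.

Reads GenBank flat files into a minimal coordinate model (0-based,
half-open, strand as ``'+'``/``'-'``), reads InterProScan-style TSV domain
scans, and writes the pipeline's tab-separated report tables.  All other
modules work exclusively on the types defined here.

Coordinate conventions
----------------------
GenBank positions are 1-based inclusive; they are converted to 0-based
half-open intervals at the parse boundary and never appear internally.
Protein (amino-acid) coordinates in domain hits stay 1-based inclusive,
matching the InterProScan output they come from.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq, UndefinedSequenceError
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("lyticmine")

#: translation table used when a CDS lacks a /translation qualifier
BACTERIAL_TABLE = 11

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


class FormatError(ValueError):
    """Input file cannot be parsed as the expected format."""


class IntegrityError(ValueError):
    """Parsed data violates an internal consistency requirement."""


@dataclass(frozen=True)
class CdsFeature:
    """One protein-coding feature of a genome.

    ``start``/``end`` are 0-based half-open nucleotide coordinates on the
    forward strand regardless of ``strand``.  ``translation`` is the amino
    acid sequence without the trailing stop; it may be empty only when the
    source record carried no translation and no nucleotide sequence, in
    which case ``translation_missing`` is set.
    """

    protein_id: str
    start: int
    end: int
    strand: str
    product: str = ""
    translation: str = ""
    translation_missing: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise IntegrityError(
                f"CDS {self.protein_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise IntegrityError(f"CDS {self.protein_id!r}: strand must be '+' or '-'")
        bad = set(self.translation) - AA_ALPHABET
        if bad:
            raise IntegrityError(
                f"CDS {self.protein_id!r}: non-standard residues {sorted(bad)}"
            )


@dataclass(frozen=True)
class GenomeRecord:
    """A phage genome: accession, length, optional sequence, CDS features.

    ``sequence`` is ``None`` for feature-table-only records; operations that
    need nucleotides must check and fail per record.  ``cds`` is sorted by
    start coordinate (stable for ties).
    """

    accession: str
    name: str
    length_bp: int
    sequence: str | None = None
    cds: tuple[CdsFeature, ...] = ()

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise IntegrityError(f"{self.accession}: length_bp must be positive")
        if self.sequence is not None and len(self.sequence) != self.length_bp:
            raise IntegrityError(
                f"{self.accession}: LOCUS length {self.length_bp} != sequence "
                f"length {len(self.sequence)}"
            )
        for f in self.cds:
            if f.end > self.length_bp:
                raise IntegrityError(
                    f"{self.accession}: CDS {f.protein_id!r} ends at {f.end} beyond "
                    f"genome length {self.length_bp}"
                )
        object.__setattr__(
            self, "cds", tuple(sorted(self.cds, key=lambda f: f.start))
        )


@dataclass(frozen=True)
class ProteinDomainHit:
    """A signature match on a protein, 1-based inclusive aa coordinates."""

    protein_id: str
    signature_accession: str
    signature_name: str
    start_aa: int
    end_aa: int
    score: float | None = None

    def __post_init__(self) -> None:
        if not (1 <= self.start_aa <= self.end_aa):
            raise IntegrityError(
                f"hit {self.signature_accession} on {self.protein_id!r}: "
                f"invalid span [{self.start_aa}, {self.end_aa}]"
            )


# ---------------------------------------------------------------------------
# GenBank reading
# ---------------------------------------------------------------------------

def _clean_translation(raw: str) -> str:
    aa = raw.upper().replace("*", "")
    return "".join(c if c in AA_ALPHABET else "X" for c in aa)


def _feature_to_cds(feat: SeqFeature, rec: SeqRecord, seq_defined: bool,
                    index: int) -> CdsFeature:
    loc = feat.location
    strand = "-" if loc.strand == -1 else "+"
    protein_id = (
        feat.qualifiers.get("protein_id", [None])[0]
        or feat.qualifiers.get("locus_tag", [None])[0]
        or f"{rec.id}_cds{index}"
    )
    product = feat.qualifiers.get("product", [""])[0]
    translation = feat.qualifiers.get("translation", [""])[0]
    missing = False
    if not translation:
        if seq_defined:
            nt = feat.extract(rec.seq)
            translation = str(Seq(nt).translate(table=BACTERIAL_TABLE))
            translation = translation[:-1] if translation.endswith("*") else translation
        else:
            missing = True
            logger.warning(
                "%s: CDS %s has no translation and the record has no sequence; "
                "kept with empty translation", rec.id, protein_id,
            )
    # simple CDS with in-frame translation should be a multiple of 3; flag only
    parts = getattr(loc, "parts", [loc])
    if len(parts) == 1 and (int(loc.end) - int(loc.start)) % 3 != 0:
        logger.warning(
            "%s: CDS %s length %d not a multiple of 3",
            rec.id, protein_id, int(loc.end) - int(loc.start),
        )
    return CdsFeature(
        protein_id=protein_id,
        start=int(loc.start),
        end=int(loc.end),
        strand=strand,
        product=product,
        translation=_clean_translation(translation),
        translation_missing=missing,
    )


def read_genbank(path: str | Path) -> list[GenomeRecord]:
    """Parse a (possibly multi-record) GenBank flat file.

    Coordinates are converted to 0-based half-open; ``complement`` features
    get strand ``'-'``.  CDS lacking a translation qualifier are translated
    from the nucleotide sequence (table 11) when one is present, otherwise
    kept with an empty translation and flagged.
    """
    path = Path(path)
    records: list[GenomeRecord] = []
    try:
        parsed = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise FormatError(f"{path}: not parseable as GenBank: {exc}") from exc
    if not parsed:
        raise FormatError(f"{path}: no GenBank records found")
    for rec in parsed:
        try:
            sequence: str | None = str(rec.seq)
            seq_defined = True
        except UndefinedSequenceError:
            sequence = None
            seq_defined = False
        cds = [
            _feature_to_cds(f, rec, seq_defined, i)
            for i, f in enumerate(rec.features)
            if f.type == "CDS"
        ]
        records.append(
            GenomeRecord(
                accession=rec.id,
                name=rec.name,
                length_bp=len(rec.seq),
                sequence=sequence,
                cds=tuple(cds),
            )
        )
    return records


# ---------------------------------------------------------------------------
# Minimal GenBank writing (fixtures / synthetic output)
# ---------------------------------------------------------------------------

def write_genbank(records: Iterable[GenomeRecord], path: str | Path) -> None:
    """Write records as GenBank.  Round-trips accession, length and the CDS
    (start, end, strand, translation) tuples through :func:`read_genbank`."""
    seq_records = []
    for g in records:
        if g.sequence is None:
            seq = Seq(None, length=g.length_bp)
        else:
            seq = Seq(g.sequence)
        rec = SeqRecord(seq, id=g.accession, name=g.name or g.accession,
                        description="")
        rec.annotations["molecule_type"] = "DNA"
        for f in g.cds:
            loc = SimpleLocation(f.start, f.end, strand=(-1 if f.strand == "-" else 1))
            quals = {
                "protein_id": [f.protein_id],
                "product": [f.product],
            }
            if f.translation:
                quals["translation"] = [f.translation]
            rec.features.append(SeqFeature(loc, type="CDS", qualifiers=quals))
        seq_records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(seq_records, fh, "genbank")


# ---------------------------------------------------------------------------
# InterProScan-style domain scans
# ---------------------------------------------------------------------------

def read_domain_scan(
    path: str | Path,
    accepted_dbs: frozenset[str] | set[str] = frozenset({"Pfam"}),
) -> list[ProteinDomainHit]:
    """Read a tab-separated domain scan.

    Accepts the full InterProScan TSV dialect (protein id, md5, length,
    database, accession, description, start, stop, score, ...) as well as a
    compact six-column form (protein id, database, accession, description,
    start, stop).  Rows whose signature database is not in ``accepted_dbs``
    are dropped; the skip count is logged.
    """
    path = Path(path)
    hits: list[ProteinDomainHit] = []
    skipped: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) >= 8 and _is_int(cols[6]) and _is_int(cols[7]):
                pid, db, acc, desc = cols[0], cols[3], cols[4], cols[5]
                start_s, stop_s = cols[6], cols[7]
                score = _maybe_float(cols[8]) if len(cols) > 8 else None
            elif len(cols) >= 6:
                pid, db, acc, desc = cols[0], cols[1], cols[2], cols[3]
                start_s, stop_s = cols[4], cols[5]
                score = _maybe_float(cols[6]) if len(cols) > 6 else None
            else:
                raise FormatError(f"{path}:{lineno}: expected >= 6 tab-separated columns")
            if db not in accepted_dbs:
                skipped[db] = skipped.get(db, 0) + 1
                continue
            if not (_is_int(start_s) and _is_int(stop_s)):
                raise FormatError(f"{path}:{lineno}: non-integer start/stop "
                                  f"({start_s!r}, {stop_s!r})")
            start, stop = int(start_s), int(stop_s)
            if start > stop:
                raise FormatError(f"{path}:{lineno}: start {start} > stop {stop}")
            hits.append(ProteinDomainHit(pid, acc, desc, start, stop, score))
    if skipped:
        logger.info("read_domain_scan(%s): skipped rows by database: %s", path, skipped)
    return hits


def _is_int(s: str) -> bool:
    try:
        int(s)
    except ValueError:
        return False
    return True


def _maybe_float(s: str) -> float | None:
    try:
        return float(s)
    except ValueError:
        return None


def cross_link(
    genomes: Sequence[GenomeRecord], hits: Sequence[ProteinDomainHit]
) -> tuple[dict[str, list[ProteinDomainHit]], list[ProteinDomainHit]]:
    """Group hits per protein id and report (not drop) orphan hits whose
    protein id occurs in no genome."""
    known = {f.protein_id for g in genomes for f in g.cds}
    by_protein: dict[str, list[ProteinDomainHit]] = {}
    orphans: list[ProteinDomainHit] = []
    for h in hits:
        if h.protein_id in known:
            by_protein.setdefault(h.protein_id, []).append(h)
        else:
            orphans.append(h)
    if orphans:
        logger.warning("%d domain hits refer to unknown protein ids "
                       "(e.g. %s)", len(orphans), orphans[0].protein_id)
    return by_protein, orphans


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def write_table(
    rows: Sequence[Mapping[str, object]],
    path: str | Path,
    key_columns: Sequence[str] = (),
    percent_columns: Sequence[str] = (),
    columns: Sequence[str] | None = None,
) -> None:
    """Write uniform records as TSV with a header line.

    Rows are stably sorted by ``key_columns``; every column in
    ``percent_columns`` is printed with exactly two decimals.  An empty row
    list still produces the header (``columns`` must then be given).
    """
    rows = list(rows)
    if rows:
        names = list(rows[0].keys())
        for r in rows:
            if list(r.keys()) != names:
                raise ValueError("write_table: rows do not share field names")
        df = pd.DataFrame(rows, columns=names)
    else:
        if columns is None:
            raise ValueError("write_table: empty row list needs explicit columns")
        df = pd.DataFrame(columns=list(columns))
    if key_columns and len(df):
        df = df.sort_values(list(key_columns), kind="stable")
    for col in percent_columns:
        if col in df.columns:
            df[col] = df[col].map(lambda v: f"{float(v):.2f}")
    df.to_csv(path, sep="\t", index=False)
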