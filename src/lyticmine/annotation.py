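"""Lytic-role annotation.

Classifies phage proteins into lytic roles (endolysin / holin / holin-like /
other lytic / unknown) from two evidence streams: keyword matches against
the GenBank ``product`` string, and Pfam signature hits mapped through a
controlled domain vocabulary.  Domain evidence outranks keyword evidence —
a "tail fiber protein" carrying an XhlA hemolysin signature is a holin-like
protein, and a "holin" carrying an amidase signature is an endolysin.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .genome_io import CdsFeature, IntegrityError, ProteinDomainHit


class Category(str, enum.Enum):
    CATALYTIC = "catalytic"
    CWB = "cwb"
    HOLIN = "holin"
    HOLIN_LIKE = "holin_like"
    OTHER_LYTIC = "other_lytic"


class LyticRole(str, enum.Enum):
    ENDOLYSIN = "endolysin"
    HOLIN = "holin"
    HOLIN_LIKE = "holin_like"
    OTHER_LYTIC = "other_lytic"
    UNKNOWN = "unknown"


#: Pfam accession -> (canonical name, category); the holin, catalytic and
#: cell-wall-binding domain families observed in enterococcal phage lytic
#: cassettes, extensible via vocabulary files.
DEFAULT_VOCABULARY_ENTRIES: dict[str, tuple[str, Category]] = {
    # holin families
    "PF05105": ("Phage_holin_4_1", Category.HOLIN),
    "PF10960": ("Holin_BhlA", Category.HOLIN),
    "PF04531": ("Phage_holin_1", Category.HOLIN),
    "PF16938": ("Phage_holin_Dp1", Category.HOLIN),
    "PF10746": ("Phage_holin_2_2", Category.HOLIN),
    "PF16079": ("Phage_holin_5_2", Category.HOLIN),
    "PF04688": ("Holin_SPP1", Category.HOLIN),
    # hemolysin-like holin companion
    "PF10779": ("XhlA", Category.HOLIN_LIKE),
    # endolysin catalytic domains
    "PF01510": ("Amidase_2", Category.CATALYTIC),
    "PF05257": ("CHAP", Category.CATALYTIC),
    "PF01183": ("Glyco_hydro_25", Category.CATALYTIC),
    "PF05382": ("Amidase_5", Category.CATALYTIC),
    "PF01551": ("Peptidase_M23", Category.CATALYTIC),
    "PF01832": ("Glucosaminidase", Category.CATALYTIC),
    # cell-wall-binding domains
    "PF16775": ("ZoocinA", Category.CWB),
    "PF08239": ("SH3_3", Category.CWB),
    "PF08460": ("SH3_5", Category.CWB),
    "PF01476": ("LysM", Category.CWB),
}

ENDOLYSIN_KEYWORDS = (
    "n-acetylmuramoyl-l-alanine amidase",
    "endolysin",
    "phage lysin",
    "lysin",
)
HOLIN_KEYWORD = "holin"


class DomainVocabulary:
    """Mapping from signature accessions to canonical domain names and
    categories; version suffixes (``PF01510.28``) are stripped on lookup."""

    def __init__(self, entries: Mapping[str, tuple[str, Category]] | None = None):
        self._entries = dict(DEFAULT_VOCABULARY_ENTRIES if entries is None else entries)

    @classmethod
    def default(cls) -> "DomainVocabulary":
        return cls()

    def extended(self, extra: Mapping[str, tuple[str, Category]]) -> "DomainVocabulary":
        merged = dict(self._entries)
        merged.update(extra)
        return DomainVocabulary(merged)

    @classmethod
    def from_file(cls, path: str | Path, base: "DomainVocabulary | None" = None
                  ) -> "DomainVocabulary":
        """Load a two-column override file: ``accession<TAB>name:category``."""
        extra: dict[str, tuple[str, Category]] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                try:
                    acc, spec = line.split(None, 1)
                    name, category = spec.rsplit(":", 1)
                    extra[acc] = (name, Category(category))
                except ValueError as exc:
                    raise ValueError(f"{path}:{lineno}: expected "
                                     f"'accession name:category'") from exc
        vocab = base if base is not None else cls.default()
        return vocab.extended(extra)

    def lookup(self, accession: str) -> tuple[str, Category] | None:
        return self._entries.get(accession.split(".", 1)[0])

    def accession_of(self, canonical_name: str) -> str | None:
        for acc, (name, _) in self._entries.items():
            if name == canonical_name:
                return acc
        return None

    @property
    def canonical_names(self) -> frozenset[str]:
        return frozenset(name for name, _ in self._entries.values())

    def __contains__(self, accession: str) -> bool:
        return self.lookup(accession) is not None

    def __len__(self) -> int:
        return len(self._entries)


@dataclass(frozen=True)
class DomainSpan:
    """One domain occurrence on a protein, 1-based inclusive aa span."""

    name: str
    category: Category
    start_aa: int
    end_aa: int


@dataclass(frozen=True)
class ProteinArchitecture:
    """A protein's lytic role and its N→C ordered domain composition."""

    protein_id: str
    role: LyticRole
    domains: tuple[DomainSpan, ...] = ()
    evidence: str = "keyword"  # keyword | domain | both
    product: str = ""

    def domains_in(self, category: Category) -> tuple[DomainSpan, ...]:
        return tuple(d for d in self.domains if d.category == category)

    @property
    def has_xhla(self) -> bool:
        return any(d.name == "XhlA" for d in self.domains)


def classify_by_keyword(product: str) -> LyticRole:
    """Case-insensitive substring classification of a product string.

    Endolysin keywords are checked before the holin keyword, so a product
    like "endolysin/holin fusion" resolves to endolysin; no match is
    ``unknown``.  Total: never raises.
    """
    p = (product or "").lower()
    if any(k in p for k in ENDOLYSIN_KEYWORDS):
        return LyticRole.ENDOLYSIN
    if HOLIN_KEYWORD in p:
        return LyticRole.HOLIN
    return LyticRole.UNKNOWN


def map_signature(accession: str, vocab: DomainVocabulary
                  ) -> tuple[str, Category] | None:
    """Exact accession lookup in the vocabulary (version suffix stripped)."""
    return vocab.lookup(accession)


def _merge_spans(spans: list[DomainSpan]) -> list[DomainSpan]:
    """Merge overlapping same-name spans to their envelope; keep distinct
    names (and non-overlapping repeats such as tandem LysM copies) separate."""
    spans = sorted(spans, key=lambda d: (d.start_aa, d.end_aa, d.name))
    merged: list[DomainSpan] = []
    for s in spans:
        if merged and merged[-1].name == s.name and s.start_aa <= merged[-1].end_aa:
            prev = merged[-1]
            merged[-1] = DomainSpan(prev.name, prev.category, prev.start_aa,
                                    max(prev.end_aa, s.end_aa))
        else:
            merged.append(s)
    return merged


def annotate_protein(
    feature: CdsFeature,
    hits: Iterable[ProteinDomainHit],
    vocab: DomainVocabulary | None = None,
) -> ProteinArchitecture:
    """Resolve one protein's lytic role from domain and keyword evidence.

    Precedence: holin-family domain > XhlA > catalytic domain > CWB-only >
    keyword > unknown.  The result is independent of the input order of
    ``hits``.
    """
    vocab = vocab or DomainVocabulary.default()
    spans: list[DomainSpan] = []
    for h in hits:
        if h.protein_id != feature.protein_id:
            raise IntegrityError(
                f"hit for {h.protein_id!r} passed to protein {feature.protein_id!r}")
        if feature.translation and h.end_aa > len(feature.translation):
            raise IntegrityError(
                f"{feature.protein_id}: hit {h.signature_accession} ends at aa "
                f"{h.end_aa} beyond translation length {len(feature.translation)}")
        mapped = vocab.lookup(h.signature_accession)
        if mapped is None:
            continue
        name, category = mapped
        spans.append(DomainSpan(name, category, h.start_aa, h.end_aa))
    spans = _merge_spans(spans)
    categories = {d.category for d in spans}

    keyword_role = classify_by_keyword(feature.product)
    if Category.HOLIN in categories:
        domain_role = LyticRole.HOLIN
    elif Category.HOLIN_LIKE in categories:
        domain_role = LyticRole.HOLIN_LIKE
    elif Category.CATALYTIC in categories:
        domain_role = LyticRole.ENDOLYSIN
    elif Category.CWB in categories:
        domain_role = LyticRole.OTHER_LYTIC
    elif Category.OTHER_LYTIC in categories:
        domain_role = LyticRole.OTHER_LYTIC
    else:
        domain_role = None

    if domain_role is not None:
        evidence = "both" if keyword_role == domain_role else "domain"
        role = domain_role
    else:
        role = keyword_role
        evidence = "keyword"
    return ProteinArchitecture(
        protein_id=feature.protein_id,
        role=role,
        domains=tuple(spans),
        evidence=evidence,
        product=feature.product,
    )


def annotate_genome(
    cds: Sequence[CdsFeature],
    hits_by_protein: Mapping[str, Sequence[ProteinDomainHit]],
    vocab: DomainVocabulary | None = None,
) -> list[ProteinArchitecture]:
    """Annotate every CDS of one genome, preserving genomic order."""
    return [
        annotate_protein(f, hits_by_protein.get(f.protein_id, ()), vocab)
        for f in cds
    ]
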