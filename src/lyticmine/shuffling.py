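"""Gene- and domain-shuffling detection.

Formalises the comparative-alignment evidence for mosaicism in lytic
cassettes: endolysins are segmented into catalytic region, proline/lysine
rich interdomain linker (consensus KPTKPPSKPPPKP) and cell-wall-binding
(CWB) region; unannotated C-terminal regions become putative unknown CWB
(UCWB) domains and are clustered by global-alignment identity; shuffling
events are called from region-wise pairwise identities:

* near-identical catalytic regions with unrelated CWB regions -> a CWB
  domain swap;
* unrelated catalytic regions with near-identical CWB regions -> a
  catalytic domain swap;
* within a cluster of near-identical endolysins, a cassette whose holin
  family differs from the cluster's modal holin -> a holin gene swap.

All identities are global (Needleman-Wunsch, BLOSUM62, affine gaps) with
gaps counting against identity, so length differences are themselves
evidence.  No randomness is used anywhere in this module.
"""

from __future__ import annotations

import enum
import functools
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .annotation import Category, ProteinArchitecture
from .mining import LyticCassette

LINKER_CONSENSUS = "KPTKPPSKPPPKP"

_BLOSUM_ALPHABET = set("ARNDCQEGHILKMFPSTWYVBZX")


@functools.lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aligner.mode = "global"
    return aligner


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment; ``identity`` uses the full alignment length as
    denominator (gap columns count as mismatches)."""

    aligned_a: str
    aligned_b: str
    score: float

    @property
    def identity(self) -> float:
        matches = sum(
            1 for x, y in zip(self.aligned_a, self.aligned_b)
            if x == y and x != "-"
        )
        return matches / len(self.aligned_a)


def _sanitize(seq: str) -> str:
    s = seq.upper()
    return "".join(c if c in _BLOSUM_ALPHABET else "X" for c in s)


@functools.lru_cache(maxsize=65536)
def _align_ordered(a: str, b: str) -> tuple[str, str, float]:
    aln = _aligner().align(a, b)[0]
    return aln[0], aln[1], float(aln.score)


def global_align(a: str, b: str) -> PairwiseAlignment:
    """Optimal global alignment of two amino-acid strings.

    Non-standard residues score as X.  The pair is aligned in a canonical
    order internally, so ``identity(a, b) == identity(b, a)`` exactly.
    """
    if not a or not b:
        raise ValueError("global_align: sequences must be non-empty")
    sa, sb = _sanitize(a), _sanitize(b)
    swapped = (sb, b) < (sa, a)
    ga, gb, score = _align_ordered(*((sb, sa) if swapped else (sa, sb)))
    if swapped:
        ga, gb = gb, ga
    # restore the caller's original residues under the sanitised alignment
    ga = _restore(ga, a)
    gb = _restore(gb, b)
    return PairwiseAlignment(aligned_a=ga, aligned_b=gb, score=score)


def _restore(gapped: str, original: str) -> str:
    out, i = [], 0
    for c in gapped:
        if c == "-":
            out.append("-")
        else:
            out.append(original[i])
            i += 1
    return "".join(out)


def identity(a: str, b: str) -> float:
    return global_align(a, b).identity


# ---------------------------------------------------------------------------
# Interdomain linker detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LinkerCall:
    """A called interdomain linker: 1-based inclusive span, fraction of
    proline+lysine residues, and edit distance to the consensus motif."""

    protein_id: str
    start_aa: int
    end_aa: int
    pk_fraction: float
    motif_distance: int

    @property
    def length(self) -> int:
        return self.end_aa - self.start_aa + 1


def _edit_distance(a: str, b: str) -> int:
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _best_infix_match(pattern: str, text: str) -> tuple[int, int, int] | None:
    """Best approximate occurrence of ``pattern`` inside ``text``.

    Returns (start, end, distance) with 0-based half-open coordinates in
    ``text``; ties broken toward the leftmost start, then shortest match.
    Free start/end: a standard semi-global edit-distance DP.
    """
    m, n = len(pattern), len(text)
    if n == 0:
        return None
    INF = 10 ** 9
    # dp[j] = (cost, start) best alignment of full-so-far pattern prefix
    dp = [(0, j) for j in range(n + 1)]
    for i in range(1, m + 1):
        ndp = [(INF, 0)] * (n + 1)
        ndp[0] = (dp[0][0] + 1, 0)
        for j in range(1, n + 1):
            cand = (
                (dp[j - 1][0] + (pattern[i - 1] != text[j - 1]), dp[j - 1][1]),
                (dp[j][0] + 1, dp[j][1]),          # deletion in text
                (ndp[j - 1][0] + 1, ndp[j - 1][1]),  # insertion in text
            )
            ndp[j] = min(cand)
        dp = ndp
    best_j, (best_cost, best_start) = min(
        enumerate(dp), key=lambda t: (t[1][0], t[1][1], t[0])
    )
    return best_start, best_j, best_cost


def _pk_fraction(window: str) -> float:
    return sum(1 for c in window if c in "PK") / len(window)


def detect_linker(
    seq: str,
    search_start: int = 1,
    *,
    protein_id: str = "",
    min_len: int = 12,
    max_len: int = 16,
    search_span: int = 80,
    pk_threshold: float = 0.5,
    motif_tolerance: int = 3,
    consensus: str = LINKER_CONSENSUS,
) -> LinkerCall | None:
    """Find the interdomain linker downstream of ``search_start``.

    Two criteria are scanned over windows within ``search_span`` residues of
    ``search_start``: (a) composition — the best window of length
    ``min_len``..``max_len`` with P+K fraction >= ``pk_threshold``, extended
    maximally while the fraction holds; (b) motif — the best substring
    within edit distance ``motif_tolerance`` of the consensus.  The higher
    scoring criterion wins (motif score = 1 - distance/len(consensus);
    composition score = P+K fraction; ties favour the motif).  Returns
    ``None`` when neither criterion fires.
    """
    if not (1 <= search_start <= len(seq)):
        raise ValueError(f"search_start {search_start} outside sequence "
                         f"of length {len(seq)}")
    lo = search_start - 1  # 0-based
    hi = min(len(seq), lo + search_span + max_len)

    # --- composition criterion ---
    comp: tuple[float, int, int] | None = None  # (fraction, start0, end0)
    for s in range(lo, min(lo + search_span + 1, len(seq))):
        for L in range(min_len, max_len + 1):
            if s + L > len(seq):
                break
            frac = _pk_fraction(seq[s:s + L])
            if frac >= pk_threshold and (comp is None or frac > comp[0]):
                comp = (frac, s, s + L)
    if comp is not None:
        _, s, e = comp
        # extend maximally over P/K residues: any such extension keeps the
        # fraction at or above its current value (hence above threshold),
        # while a non-P/K extension would only dilute the window
        while e < len(seq) and seq[e] in "PK":
            e += 1
        while s > 0 and seq[s - 1] in "PK":
            s -= 1
        comp = (_pk_fraction(seq[s:e]), s, e)

    # --- motif criterion ---
    motif: tuple[int, int, int] | None = None  # (start0, end0, distance)
    region = seq[lo:hi]
    m = _best_infix_match(consensus, region)
    if m is not None and m[2] <= motif_tolerance:
        motif = (lo + m[0], lo + m[1], m[2])

    comp_score = comp[0] if comp is not None else -1.0
    motif_score = (1.0 - motif[2] / len(consensus)) if motif is not None else -1.0
    if comp is None and motif is None:
        return None
    if motif is not None and motif_score >= comp_score:
        s, e, dist = motif
        window = seq[s:e]
        return LinkerCall(protein_id, s + 1, e, _pk_fraction(window), dist)
    frac, s, e = comp  # type: ignore[misc]
    return LinkerCall(protein_id, s + 1, e, frac,
                      _edit_distance(seq[s:e], consensus))


# ---------------------------------------------------------------------------
# Endolysin segmentation
# ---------------------------------------------------------------------------

UCWB_CANDIDATE = "UCWB?"


@dataclass(frozen=True)
class Region:
    start_aa: int  # 1-based inclusive
    end_aa: int
    label: str

    @property
    def length(self) -> int:
        return self.end_aa - self.start_aa + 1


@dataclass(frozen=True)
class EndolysinSegmentation:
    """Catalytic / linker / CWB decomposition of one endolysin.

    ``cwb_region`` holds the known CWB span when one is annotated, else the
    putative UCWB candidate; ``pre_cwb_ucwb`` is an additional candidate
    region between the linker and a known CWB domain.  UCWB labels start as
    ``"UCWB?"`` and become ``"UCWB-k"`` after clustering.  ``failed`` marks
    endolysins with neither a catalytic domain nor a detectable linker.
    """

    protein_id: str
    sequence: str
    catalytic_region: Region | None = None
    linker: LinkerCall | None = None
    cwb_region: Region | None = None
    pre_cwb_ucwb: Region | None = None
    failed: bool = False

    def region_seq(self, r: Region | None) -> str:
        return "" if r is None else self.sequence[r.start_aa - 1:r.end_aa]

    @property
    def catalytic_seq(self) -> str:
        return self.region_seq(self.catalytic_region)

    @property
    def cwb_comparison_seq(self) -> str:
        """Everything C-terminal of the linker end (or of the catalytic
        domain end when no linker was found) — the region the shuffling
        comparison uses."""
        if self.linker is not None:
            return self.sequence[self.linker.end_aa:]
        if self.catalytic_region is not None:
            return self.sequence[self.catalytic_region.end_aa:]
        return ""


def segment_endolysin(
    arch: ProteinArchitecture,
    seq: str,
    min_ucwb_len: int = 40,
    **linker_kwargs,
) -> EndolysinSegmentation:
    """Segment one endolysin into catalytic region, linker and CWB region.

    The catalytic region is the first catalytic-domain span; the linker is
    searched from its end.  When no CWB domain is annotated, the stretch
    from the linker end to the C terminus becomes a putative UCWB candidate
    if it is at least ``min_ucwb_len`` residues; when a known CWB domain
    starts at least ``min_ucwb_len`` residues after the linker, the gap is
    emitted as an additional candidate before it.
    """
    cats = arch.domains_in(Category.CATALYTIC)
    cat_region = None
    if cats:
        d = cats[0]
        cat_region = Region(d.start_aa, min(d.end_aa, len(seq)), d.name)
    search_from = cat_region.end_aa + 1 if cat_region else 1
    linker = None
    if search_from <= len(seq):
        linker = detect_linker(seq, search_from, protein_id=arch.protein_id,
                               **linker_kwargs)
    if cat_region is None and linker is None:
        return EndolysinSegmentation(arch.protein_id, seq, failed=True)

    after = (linker.end_aa if linker else cat_region.end_aa) + 1  # type: ignore[union-attr]
    cwbs = arch.domains_in(Category.CWB)
    cwb_region = None
    pre_ucwb = None
    if cwbs:
        label = " + ".join(d.name for d in cwbs)
        cwb_region = Region(cwbs[0].start_aa, min(cwbs[-1].end_aa, len(seq)), label)
        gap = cwbs[0].start_aa - after
        if gap >= min_ucwb_len:
            pre_ucwb = Region(after, cwbs[0].start_aa - 1, UCWB_CANDIDATE)
    else:
        if len(seq) - after + 1 >= min_ucwb_len:
            cwb_region = Region(after, len(seq), UCWB_CANDIDATE)
    return EndolysinSegmentation(
        protein_id=arch.protein_id,
        sequence=seq,
        catalytic_region=cat_region,
        linker=linker,
        cwb_region=cwb_region,
        pre_cwb_ucwb=pre_ucwb,
    )


# ---------------------------------------------------------------------------
# UCWB clustering
# ---------------------------------------------------------------------------

class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def cluster_regions(
    regions: Sequence[tuple[str, str]],
    identity_threshold: float = 0.8,
    label_prefix: str = "UCWB",
) -> dict[str, str]:
    """Single-linkage clustering of (id, sequence) pairs on global-alignment
    identity; labels ``UCWB-1``, ``UCWB-2``, ... assigned by descending
    cluster size, then lexicographically smallest member id.  Deterministic
    and stable under input permutation."""
    if any(not s for _, s in regions):
        raise ValueError("cluster_regions: empty sequence")
    regions = sorted(regions)
    ids = [i for i, _ in regions]
    if len(set(ids)) != len(ids):
        raise ValueError("cluster_regions: duplicate region ids")
    seqs = dict(regions)
    uf = _UnionFind(ids)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if identity(seqs[ids[i]], seqs[ids[j]]) >= identity_threshold:
                uf.union(ids[i], ids[j])
    clusters: dict[str, list[str]] = {}
    for x in ids:
        clusters.setdefault(uf.find(x), []).append(x)
    ordered = sorted(clusters.values(), key=lambda c: (-len(c), min(c)))
    labels: dict[str, str] = {}
    for k, members in enumerate(ordered, start=1):
        for m in members:
            labels[m] = f"{label_prefix}-{k}"
    return labels


def assign_ucwb_labels(
    segmented: Sequence[EndolysinSegmentation],
    identity_threshold: float = 0.8,
) -> list[EndolysinSegmentation]:
    """Replace ``UCWB?`` candidate labels by clustered ``UCWB-k`` labels."""
    candidates: list[tuple[str, str]] = []
    for s in segmented:
        for attr in ("cwb_region", "pre_cwb_ucwb"):
            r: Region | None = getattr(s, attr)
            if r is not None and r.label == UCWB_CANDIDATE and s.region_seq(r):
                candidates.append((f"{s.protein_id}:{attr}", s.region_seq(r)))
    if not candidates:
        return list(segmented)
    labels = cluster_regions(candidates, identity_threshold)
    out = []
    for s in segmented:
        upd: dict[str, Region] = {}
        for attr in ("cwb_region", "pre_cwb_ucwb"):
            r = getattr(s, attr)
            key = f"{s.protein_id}:{attr}"
            if r is not None and key in labels:
                upd[attr] = Region(r.start_aa, r.end_aa, labels[key])
        out.append(replace(s, **upd) if upd else s)
    return out


# ---------------------------------------------------------------------------
# Shuffling events
# ---------------------------------------------------------------------------

class EventClass(str, enum.Enum):
    GENE_HOLIN_SWAP = "gene_holin_swap"
    DOMAIN_CWB_SWAP = "domain_cwb_swap"
    DOMAIN_CATALYTIC_SWAP = "domain_catalytic_swap"


@dataclass(frozen=True)
class ShufflingEvent:
    event_class: EventClass
    participants: frozenset[str]
    evidence: tuple[tuple[str, object], ...] = ()
    context: str = ""

    def to_dict(self) -> dict[str, object]:
        return {
            "event_class": self.event_class.value,
            "participants": sorted(self.participants),
            "evidence": dict(self.evidence),
            "context": self.context,
        }


def detect_domain_shuffling(
    segmented: Sequence[EndolysinSegmentation],
    high_id: float = 0.9,
    low_id: float = 0.5,
) -> list[ShufflingEvent]:
    """Call CWB- and catalytic-domain swaps from all-pairs region identities.

    A pair with catalytic identity >= ``high_id`` and CWB-region identity
    <= ``low_id`` is a CWB swap; the mirrored condition is a catalytic
    swap.  Pairs missing either region are skipped.  Both identities are
    carried as evidence.
    """
    usable = [
        s for s in segmented
        if not s.failed and s.catalytic_seq and s.cwb_comparison_seq
    ]
    usable.sort(key=lambda s: s.protein_id)
    events: list[ShufflingEvent] = []
    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            a, b = usable[i], usable[j]
            cat_id = identity(a.catalytic_seq, b.catalytic_seq)
            cwb_id = identity(a.cwb_comparison_seq, b.cwb_comparison_seq)
            cls = None
            if cat_id >= high_id and cwb_id <= low_id:
                cls = EventClass.DOMAIN_CWB_SWAP
            elif cat_id <= low_id and cwb_id >= high_id:
                cls = EventClass.DOMAIN_CATALYTIC_SWAP
            if cls is not None:
                events.append(ShufflingEvent(
                    event_class=cls,
                    participants=frozenset({a.protein_id, b.protein_id}),
                    evidence=(("catalytic_identity", round(cat_id, 4)),
                              ("cwb_identity", round(cwb_id, 4))),
                ))
    return events


def detect_gene_shuffling(
    cassettes: Sequence[LyticCassette],
    sequences: Mapping[str, str],
    endolysin_cluster_id: float = 0.9,
    min_cluster_size: int = 3,
) -> list[ShufflingEvent]:
    """Call holin gene swaps.

    Cassettes are clustered by full-length identity of their (first)
    endolysin (single linkage, identity >= ``endolysin_cluster_id``); in
    every cluster of at least ``min_cluster_size`` cassettes with a unique
    modal holin, each cassette whose holin differs from the mode yields a
    ``gene_holin_swap`` event naming the minority and modal holins.
    """
    usable: list[tuple[str, str, str]] = []  # (accession, endolysin seq, holin sig)
    for c in cassettes:
        endos = [e for e in c.endolysins if sequences.get(e.protein_id)]
        if not endos or not c.holin_domains:
            continue
        from .mining import holin_alias
        holin_sig = "+".join(sorted(holin_alias(h) for h in c.holin_domains))
        usable.append((c.genome_accession, sequences[endos[0].protein_id],
                       holin_sig))
    usable.sort(key=lambda t: t[0])
    n = len(usable)
    uf = _UnionFind(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if identity(usable[i][1], usable[j][1]) >= endolysin_cluster_id:
                uf.union(i, j)
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(uf.find(i), []).append(i)
    events: list[ShufflingEvent] = []
    ordered = sorted(clusters.values(), key=lambda c: (-len(c), usable[c[0]][0]))
    for cluster_no, members in enumerate(ordered, start=1):
        if len(members) < min_cluster_size:
            continue
        tally: dict[str, int] = {}
        for i in members:
            tally[usable[i][2]] = tally.get(usable[i][2], 0) + 1
        top = max(tally.values())
        modes = [h for h, c in tally.items() if c == top]
        if len(modes) != 1:
            continue  # no unique modal holin: conservative skip
        modal = modes[0]
        for i in members:
            if usable[i][2] != modal:
                events.append(ShufflingEvent(
                    event_class=EventClass.GENE_HOLIN_SWAP,
                    participants=frozenset({usable[i][0]}),
                    evidence=(("minority_holin", usable[i][2]),
                              ("modal_holin", modal)),
                    context=f"endolysin-cluster-{cluster_no}",
                ))
    return events
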