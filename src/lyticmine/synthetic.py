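"""Synthetic genome populations with planted lytic cassettes.

Generates phage-like genome records for the five genome-size groups, each
carrying filler CDS plus one planted lytic cassette (optional XhlA
holin-like gene, holin gene, endolysin assembled as catalytic block +
interdomain linker + CWB block), together with a matching InterProScan-style
domain-scan table and a ground-truth ledger of every planted block, linker
coordinate and shuffling event.  This makes every pipeline stage testable
with no downloads.

Mutation model: each block copy receives exactly ``round(rate × length)``
substitutions at distinct sites (never touching the linker, mirroring the
observed conservation of interdomain linkers).  Deterministic substitution
counts make within-family and between-family identities structurally
bounded, so planted events are recoverable by construction rather than with
high probability.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Data import CodonTable

from .annotation import DomainVocabulary
from .genome_io import CdsFeature, GenomeRecord
from .shuffling import (
    LINKER_CONSENSUS,
    EventClass,
    ShufflingEvent,
    identity,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: known CWB family names (have Pfam rows); UCWB-* blocks have none
KNOWN_CWB = ("SH3_5", "SH3_3", "ZoocinA", "LysM")


class GenerationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Block library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlockLibrary:
    """Named amino-acid building blocks, one archetype per family."""

    catalytic_blocks: dict[str, str]
    cwb_blocks: dict[str, str]
    linker_blocks: tuple[str, ...]
    holin_genes: dict[str, str]
    xhla_block: str


def _random_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(AA20), size=length))


def _draw_block_set(
    rng: np.random.Generator,
    names: Sequence[str],
    length_range: tuple[int, int],
    max_identity: float,
    max_retries: int = 30,
) -> dict[str, str]:
    """Draw one random block per family, re-drawing any block whose global
    identity to an already-accepted block exceeds ``max_identity``."""
    blocks: dict[str, str] = {}
    for name in names:
        for _ in range(max_retries):
            cand = _random_protein(rng, int(rng.integers(*length_range)))
            if all(identity(cand, other) <= max_identity
                   for other in blocks.values()):
                blocks[name] = cand
                break
        else:
            raise GenerationError(
                f"could not draw block {name!r} under identity <= {max_identity}")
    return blocks


def build_library(seed: int, max_cross_identity: float = 0.3) -> BlockLibrary:
    """Deterministic block library for a seed; between-family identity is
    bounded by ``max_cross_identity`` by construction (checked with the
    same global alignment the analysis uses)."""
    rng = np.random.default_rng(seed)
    catalytic = _draw_block_set(
        rng,
        ["Amidase_2", "Glyco_hydro_25", "CHAP", "Amidase_5",
         "Peptidase_M23", "Glucosaminidase"],
        (120, 161), max_cross_identity,
    )
    cwb = _draw_block_set(
        rng,
        ["SH3_5", "SH3_3", "ZoocinA", "LysM", "UCWB-1", "UCWB-2", "UCWB-3"],
        (60, 101), max_cross_identity,
    )
    holins = _draw_block_set(
        rng,
        ["Phage_holin_4_1", "Holin_BhlA", "Phage_holin_1", "Phage_holin_Dp1",
         "Phage_holin_2_2", "Phage_holin_5_2", "Holin_SPP1"],
        (70, 101), max_cross_identity,
    )
    xhla = _random_protein(rng, int(rng.integers(80, 101)))
    # consensus first; variants stay within the motif tolerance of the scanner
    linkers = (LINKER_CONSENSUS, "KPTKPPSKPAPKP", "KPTKPPSKPPPKPK")
    return BlockLibrary(
        catalytic_blocks=catalytic,
        cwb_blocks=cwb,
        linker_blocks=linkers,
        holin_genes=holins,
        xhla_block=xhla,
    )


# ---------------------------------------------------------------------------
# Simulation spec
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CassetteTemplate:
    group: int
    holin_family: str
    catalytic: str
    cwb: str  # known CWB name or UCWB-k
    xhla: bool


#: one template per size group; catalytic families deliberately distinct so
#: that cross-group endolysin pairs share no region at default thresholds
DEFAULT_TEMPLATES: tuple[CassetteTemplate, ...] = (
    CassetteTemplate(1, "Phage_holin_4_1", "Amidase_2", "UCWB-1", False),
    CassetteTemplate(2, "Phage_holin_Dp1", "Glyco_hydro_25", "LysM", True),
    CassetteTemplate(3, "Phage_holin_5_2", "CHAP", "UCWB-2", False),
    CassetteTemplate(4, "Phage_holin_1", "Amidase_5", "SH3_5", False),
    CassetteTemplate(5, "Holin_SPP1", "Peptidase_M23", "ZoocinA", False),
)

#: sampling ranges for genome length per group (bp, half-open); sub-ranges
#: of the group bounds leaving room for the planted genes
GROUP_LENGTH_RANGES = {
    1: (10_000, 20_000),
    2: (20_000, 50_000),
    3: (50_000, 65_000),
    4: (65_000, 100_000),
    5: (100_000, 140_000),
}

#: donor pools for planted swaps (never used by any template)
CWB_DONORS = ("SH3_3", "UCWB-3")
CATALYTIC_DONORS = ("Glucosaminidase",)

FILLER_PRODUCTS = (
    "hypothetical protein", "terminase large subunit", "portal protein",
    "major capsid protein", "tail fiber protein", "DNA polymerase",
)
ENDOLYSIN_PRODUCTS = ("endolysin", "N-acetylmuramoyl-L-alanine amidase",
                      "putative endolysin", "hypothetical protein")
HOLIN_PRODUCTS = ("holin", "putative holin", "hypothetical protein")
XHLA_PRODUCT = "tail fiber protein"  # rescued by its XhlA domain hit


@dataclass(frozen=True)
class SimulationSpec:
    """Study conditions for one synthetic population."""

    seed: int
    n_genomes: Mapping[int, int] = field(
        default_factory=lambda: {1: 6, 2: 6, 3: 6, 4: 6, 5: 6})
    divergence: float = 0.03
    n_gene_swaps: int = 3
    n_cwb_swaps: int = 3
    n_catalytic_swaps: int = 3
    templates: tuple[CassetteTemplate, ...] = DEFAULT_TEMPLATES

    def __post_init__(self) -> None:
        if not (0.0 <= self.divergence <= 0.1):
            raise ValueError("divergence must be in [0, 0.1]")
        for name in ("n_gene_swaps", "n_cwb_swaps", "n_catalytic_swaps"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if any(n < 0 for n in self.n_genomes.values()):
            raise ValueError("n_genomes counts must be >= 0")


@dataclass
class TruthLedger:
    """Ground truth for one generated population."""

    events: list[ShufflingEvent] = field(default_factory=list)
    cassettes: dict[str, list[str]] = field(default_factory=dict)  # acc -> protein ids
    linkers: dict[str, tuple[int, int]] = field(default_factory=dict)  # pid -> span
    blocks: dict[str, dict[str, str]] = field(default_factory=dict)  # pid -> labels

    def to_json(self) -> str:
        return json.dumps({
            "events": [e.to_dict() for e in self.events],
            "cassettes": self.cassettes,
            "linkers": {k: list(v) for k, v in self.linkers.items()},
            "blocks": self.blocks,
        }, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthLedger":
        d = json.loads(text)
        events = [
            ShufflingEvent(
                event_class=EventClass(e["event_class"]),
                participants=frozenset(e["participants"]),
                evidence=tuple(sorted(e["evidence"].items())),
                context=e.get("context", ""),
            )
            for e in d["events"]
        ]
        return cls(
            events=events,
            cassettes=d["cassettes"],
            linkers={k: (v[0], v[1]) for k, v in d["linkers"].items()},
            blocks=d["blocks"],
        )


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _mutated_copy(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Exactly round(rate·len) substitutions at distinct sites, each to a
    different residue."""
    n = int(round(rate * len(seq)))
    if n == 0:
        return seq
    sites = rng.choice(len(seq), size=n, replace=False)
    chars = list(seq)
    for i in sites:
        choices = [c for c in AA20 if c != chars[i]]
        chars[i] = choices[int(rng.integers(len(choices)))]
    return "".join(chars)


@dataclass
class _PlannedGene:
    protein_id: str
    product: str
    protein: str
    strand: str
    domain_rows: list[tuple[str, str, int, int]]  # (accession, name, start, stop)


_BACK_TABLE: dict[str, list[str]] | None = None


def _back_table() -> dict[str, list[str]]:
    global _BACK_TABLE
    if _BACK_TABLE is None:
        table = CodonTable.unambiguous_dna_by_id[11]
        back: dict[str, list[str]] = {}
        for codon, aa in table.forward_table.items():
            back.setdefault(aa, []).append(codon)
        for aa in back:
            back[aa].sort()
        _BACK_TABLE = back
    return _BACK_TABLE


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    back = _back_table()
    codons = [back[aa][int(rng.integers(len(back[aa])))] for aa in protein]
    stops = sorted(CodonTable.unambiguous_dna_by_id[11].stop_codons)
    codons.append(stops[int(rng.integers(len(stops)))])
    return "".join(codons)


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _revcomp(nt: str) -> str:
    return nt.translate(_COMPLEMENT)[::-1]


def _swap_assignments(spec: SimulationSpec, groups: list[int]
                      ) -> dict[str, list[int]]:
    """Round-robin group assignment per swap class, offset so that swaps of
    different classes land in different groups first."""
    def cycle(offset: int, n: int) -> list[int]:
        if not groups:
            if n:
                raise GenerationError("swaps requested but no groups populated")
            return []
        return [groups[(offset + k) % len(groups)] for k in range(n)]

    return {
        "cwb": cycle(0, spec.n_cwb_swaps),
        "catalytic": cycle(3, spec.n_catalytic_swaps),
        "gene": cycle(1, spec.n_gene_swaps),
    }


def generate_population(
    spec: SimulationSpec,
    lib: BlockLibrary | None = None,
    vocab: DomainVocabulary | None = None,
) -> tuple[list[GenomeRecord], list[tuple[str, ...]], TruthLedger]:
    """Generate genomes, InterProScan-style rows and the truth ledger.

    Deterministic for a given spec: two runs produce byte-identical
    records, rows and ledger JSON.
    """
    lib = lib or build_library(spec.seed)
    vocab = vocab or DomainVocabulary.default()
    rng = np.random.default_rng(spec.seed + 1)
    templates = {t.group: t for t in spec.templates}

    populated = [g for g in sorted(spec.n_genomes) if spec.n_genomes[g] > 0]
    assignments = _swap_assignments(spec, populated)

    # per-genome plan: which swap (if any) applies
    plans: list[tuple[int, int, str | None]] = []  # (group, index, swap class)
    per_group_counts: dict[int, int] = {}
    swap_slots: dict[int, list[str]] = {g: [] for g in populated}
    for cls in ("cwb", "catalytic", "gene"):
        for g in assignments[cls]:
            swap_slots[g].append(cls)
    for g in populated:
        n = spec.n_genomes[g]
        if len(swap_slots[g]) > n:
            raise GenerationError(
                f"group {g}: {len(swap_slots[g])} swaps requested for {n} genomes")
        domain_swaps = sum(1 for c in swap_slots[g] if c != "gene")
        if "gene" in swap_slots[g] and n - domain_swaps < 3:
            raise GenerationError(
                f"group {g}: too few genomes for a detectable gene swap")
        for i in range(n):
            swap = swap_slots[g][i] if i < len(swap_slots[g]) else None
            plans.append((g, i, swap))
        per_group_counts[g] = n

    genomes: list[GenomeRecord] = []
    rows: list[tuple[str, ...]] = []
    truth = TruthLedger()
    #: per endolysin: (catalytic family, cwb family) labels for truth calls
    endolysin_labels: dict[str, tuple[str, str]] = {}
    #: per genome: (group, holin family, endolysin pid, has domain swap)
    genome_info: dict[str, tuple[int, str, str, bool]] = {}

    cwb_donor_i = 0
    cat_donor_i = 0
    for group, idx, swap in plans:
        t = templates.get(group)
        if t is None:
            raise GenerationError(f"no cassette template for group {group}")
        accession = f"SYN_G{group}_{idx:02d}"
        holin_family = t.holin_family
        catalytic = t.catalytic
        cwb = t.cwb
        if swap == "gene":
            others = sorted(f for f in lib.holin_genes if f != t.holin_family)
            holin_family = others[int(rng.integers(len(others)))]
        elif swap == "cwb":
            cwb = CWB_DONORS[cwb_donor_i % len(CWB_DONORS)]
            cwb_donor_i += 1
        elif swap == "catalytic":
            catalytic = CATALYTIC_DONORS[cat_donor_i % len(CATALYTIC_DONORS)]
            cat_donor_i += 1

        genome, genome_rows, endo_pid, cassette_pids, linker_span = _build_genome(
            rng, spec, lib, vocab, accession, group,
            holin_family, catalytic, cwb, t.xhla,
        )
        genomes.append(genome)
        rows.extend(genome_rows)
        truth.cassettes[accession] = cassette_pids
        truth.linkers[endo_pid] = linker_span
        truth.blocks[endo_pid] = {"catalytic": catalytic, "cwb": cwb}
        for pid in cassette_pids:
            truth.blocks.setdefault(pid, {})
        truth.blocks[cassette_pids[-2]]["holin"] = holin_family  # holin precedes endolysin
        endolysin_labels[endo_pid] = (catalytic, cwb)
        genome_info[accession] = (group, holin_family, endo_pid,
                                  swap in ("cwb", "catalytic"))

    _enumerate_truth_events(truth, endolysin_labels, genome_info)
    return genomes, rows, truth


def _build_genome(
    rng: np.random.Generator,
    spec: SimulationSpec,
    lib: BlockLibrary,
    vocab: DomainVocabulary,
    accession: str,
    group: int,
    holin_family: str,
    catalytic: str,
    cwb: str,
    xhla: bool,
) -> tuple[GenomeRecord, list[tuple[str, ...]], str, list[str], tuple[int, int]]:
    lo, hi = GROUP_LENGTH_RANGES[group]
    length = int(rng.integers(lo, hi))
    n_filler = max(4, min(40, length // 2500))
    cassette_at = int(rng.integers(1, n_filler))  # gene index of cassette start

    # --- assemble proteins ---
    rate = spec.divergence
    cat_copy = _mutated_copy(rng, lib.catalytic_blocks[catalytic], rate)
    cwb_copy = _mutated_copy(rng, lib.cwb_blocks[cwb], rate)
    linker = lib.linker_blocks[0]  # exact consensus; never mutated
    endolysin = cat_copy + linker + cwb_copy
    holin = _mutated_copy(rng, lib.holin_genes[holin_family], rate)
    xhla_prot = _mutated_copy(rng, lib.xhla_block, rate) if xhla else None
    linker_span = (len(cat_copy) + 1, len(cat_copy) + len(linker))

    genes: list[_PlannedGene] = []
    pid_no = 0

    def next_pid() -> str:
        nonlocal pid_no
        pid_no += 1
        return f"{accession}_p{pid_no:02d}"

    def filler() -> _PlannedGene:
        plen = int(rng.integers(80, 301))
        return _PlannedGene(
            protein_id=next_pid(),
            product=FILLER_PRODUCTS[int(rng.integers(len(FILLER_PRODUCTS)))],
            protein=_random_protein(rng, plen),
            strand="+" if rng.random() < 0.7 else "-",
            domain_rows=[],
        )

    cassette_pids: list[str] = []
    endo_pid = ""
    for gi in range(n_filler + 1):
        if gi == cassette_at:
            if xhla_prot is not None:
                pid = next_pid()
                genes.append(_PlannedGene(
                    pid, XHLA_PRODUCT, xhla_prot, "+",
                    [(_acc(vocab, "XhlA"), "XhlA", 1, len(xhla_prot))]))
                cassette_pids.append(pid)
            pid = next_pid()
            genes.append(_PlannedGene(
                pid, HOLIN_PRODUCTS[int(rng.integers(len(HOLIN_PRODUCTS)))],
                holin, "+",
                [(_acc(vocab, holin_family), holin_family, 1, len(holin))]))
            cassette_pids.append(pid)
            pid = next_pid()
            endo_pid = pid
            endo_rows = [(_acc(vocab, catalytic), catalytic, 1, len(cat_copy))]
            if cwb in KNOWN_CWB:
                endo_rows.append((_acc(vocab, cwb), cwb,
                                  linker_span[1] + 1, len(endolysin)))
            genes.append(_PlannedGene(
                pid,
                ENDOLYSIN_PRODUCTS[int(rng.integers(len(ENDOLYSIN_PRODUCTS)))],
                endolysin, "+", endo_rows))
            cassette_pids.append(pid)
        else:
            genes.append(filler())

    # --- lay genes out on the genome ---
    nt_parts: list[str] = []
    cds: list[CdsFeature] = []
    cursor = int(rng.integers(100, 400))
    nt_parts.append(_random_nt(rng, cursor))
    for g in genes:
        gene_nt = _reverse_translate(rng, g.protein)
        if g.strand == "-":
            gene_nt = _revcomp(gene_nt)
        start, end = cursor, cursor + len(gene_nt)
        if end > length - 100:
            raise GenerationError(
                f"{accession}: group {group} length {length} too small for "
                f"{len(genes)} genes")
        cds.append(CdsFeature(
            protein_id=g.protein_id, start=start, end=end, strand=g.strand,
            product=g.product, translation=g.protein))
        nt_parts.append(gene_nt)
        gap = int(rng.integers(50, 300))
        nt_parts.append(_random_nt(rng, gap))
        cursor = end + gap
    nt_parts.append(_random_nt(rng, length - cursor))
    sequence = "".join(nt_parts)

    rows = []
    for g in genes:
        for acc, name, start, stop in g.domain_rows:
            rows.append(_ips_row(g.protein_id, len(g.protein), acc, name,
                                 start, stop))
        # a non-Pfam decoy row the reader must skip
        if g.domain_rows and rng.random() < 0.3:
            rows.append((g.protein_id, "-", str(len(g.protein)), "Gene3D",
                         "G3DSA:3.40.630.40", "-", "1", str(len(g.protein)),
                         "1.0e-10", "T", "-"))

    record = GenomeRecord(
        accession=accession, name=accession, length_bp=length,
        sequence=sequence, cds=tuple(cds))
    return record, rows, endo_pid, cassette_pids, linker_span


def _acc(vocab: DomainVocabulary, name: str) -> str:
    acc = vocab.accession_of(name)
    if acc is None:
        raise GenerationError(f"no accession for domain {name!r} in vocabulary")
    return acc


def _ips_row(pid: str, plen: int, acc: str, name: str, start: int, stop: int
             ) -> tuple[str, ...]:
    return (pid, "-", str(plen), "Pfam", acc, name, str(start), str(stop),
            "1.0e-30", "T", "-")


def _random_nt(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return "".join(np.array(["A", "C", "G", "T"])[rng.integers(0, 4, size=n)])


def _enumerate_truth_events(
    truth: TruthLedger,
    endolysin_labels: dict[str, tuple[str, str]],
    genome_info: dict[str, tuple[int, str, str, bool]],
) -> None:
    """Derive the ledger's events from the planted block labels.

    Domain events are label-level pairs: equal catalytic family with
    different CWB families is a CWB swap (and symmetrically); this is
    exactly the pair set a threshold detector should call.  Gene events are
    minority holins within each group's endolysin-pure cassettes.
    """
    pids = sorted(endolysin_labels)
    for i in range(len(pids)):
        for j in range(i + 1, len(pids)):
            (cat_a, cwb_a), (cat_b, cwb_b) = (endolysin_labels[pids[i]],
                                              endolysin_labels[pids[j]])
            cls = None
            if cat_a == cat_b and cwb_a != cwb_b:
                cls = EventClass.DOMAIN_CWB_SWAP
            elif cat_a != cat_b and cwb_a == cwb_b:
                cls = EventClass.DOMAIN_CATALYTIC_SWAP
            if cls is not None:
                truth.events.append(ShufflingEvent(
                    event_class=cls,
                    participants=frozenset({pids[i], pids[j]}),
                ))
    # gene swaps: per group, among genomes whose endolysin is the template one
    by_group: dict[int, list[str]] = {}
    for acc, (group, _, _, domain_swapped) in genome_info.items():
        if not domain_swapped:
            by_group.setdefault(group, []).append(acc)
    for group, accs in sorted(by_group.items()):
        if len(accs) < 3:
            continue
        tally: dict[str, int] = {}
        for acc in accs:
            tally[genome_info[acc][1]] = tally.get(genome_info[acc][1], 0) + 1
        top = max(tally.values())
        modes = [h for h, c in tally.items() if c == top]
        if len(modes) != 1:
            continue
        for acc in sorted(accs):
            if genome_info[acc][1] != modes[0]:
                truth.events.append(ShufflingEvent(
                    event_class=EventClass.GENE_HOLIN_SWAP,
                    participants=frozenset({acc}),
                ))


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------

def _event_key(e: ShufflingEvent) -> tuple[str, frozenset[str]]:
    return (e.event_class.value, e.participants)


def score_recovery(
    truth: TruthLedger | Sequence[ShufflingEvent],
    called: Sequence[ShufflingEvent],
) -> tuple[float, float, dict[str, dict[str, float]]]:
    """Precision/recall of called events against planted truth.

    An event matches when its class and unordered participant set agree.
    Both lists empty gives precision = recall = 1.0 by convention; the
    per-class table follows the same convention class-wise.
    """
    truth_events = truth.events if isinstance(truth, TruthLedger) else list(truth)
    truth_keys = {_event_key(e) for e in truth_events}
    called_keys = {_event_key(e) for e in called}
    classes = sorted({k[0] for k in truth_keys | called_keys}
                     | {c.value for c in EventClass})
    table: dict[str, dict[str, float]] = {}
    for cls in classes:
        t = {k for k in truth_keys if k[0] == cls}
        c = {k for k in called_keys if k[0] == cls}
        tp = len(t & c)
        table[cls] = {
            "n_truth": len(t),
            "n_called": len(c),
            "tp": tp,
            "precision": tp / len(c) if c else 1.0,
            "recall": tp / len(t) if t else 1.0,
        }
    tp_all = len(truth_keys & called_keys)
    precision = tp_all / len(called_keys) if called_keys else 1.0
    recall = tp_all / len(truth_keys) if truth_keys else 1.0
    return precision, recall, table


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------

def write_domain_rows(rows: Sequence[tuple[str, ...]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in rows:
            fh.write("\t".join(r) + "\n")


def write_protein_fasta(genomes: Sequence[GenomeRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            for f in g.cds:
                if f.translation:
                    fh.write(f">{f.protein_id} {f.product}\n{f.translation}\n")
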