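"""End-to-end pipeline: annotate -> mine cassettes -> segment endolysins ->
call shuffling events.  The CLI is a thin wrapper over this module."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .annotation import DomainVocabulary, LyticRole, ProteinArchitecture, annotate_genome
from .config import RunConfig
from .genome_io import GenomeRecord, ProteinDomainHit, cross_link
from .mining import (
    CombinationTable,
    LyticCassette,
    assign_size_group,
    find_cassettes,
    group_census,
    primary_cassette,
    size_histogram,
    tabulate,
    type_cassette,
)
from .shuffling import (
    EndolysinSegmentation,
    ShufflingEvent,
    assign_ucwb_labels,
    detect_domain_shuffling,
    detect_gene_shuffling,
    segment_endolysin,
)


@dataclass
class PipelineResult:
    genomes: list[GenomeRecord]
    architectures: dict[str, list[ProteinArchitecture]]  # accession -> per-CDS
    cassettes: list[LyticCassette]  # one primary per genome unless all_cassettes
    segmentations: list[EndolysinSegmentation]
    events: list[ShufflingEvent]
    table1: CombinationTable | None = None
    table2: CombinationTable | None = None
    histogram: list[tuple[int, int]] = field(default_factory=list)
    census: dict[int, int] = field(default_factory=dict)

    def sequences(self) -> dict[str, str]:
        return {
            f.protein_id: f.translation
            for g in self.genomes for f in g.cds if f.translation
        }


def run_pipeline(
    genomes: Sequence[GenomeRecord],
    hits: Sequence[ProteinDomainHit],
    config: RunConfig | None = None,
    vocab: DomainVocabulary | None = None,
) -> PipelineResult:
    """Run the full comparative analysis on a genome set."""
    config = config or RunConfig()
    if vocab is None:
        vocab = (DomainVocabulary.from_file(config.vocab_path)
                 if config.vocab_path else DomainVocabulary.default())
    hits_by_protein, _orphans = cross_link(genomes, hits)

    architectures: dict[str, list[ProteinArchitecture]] = {}
    cassettes: list[LyticCassette] = []
    for g in genomes:
        archs = annotate_genome(g.cds, hits_by_protein, vocab)
        architectures[g.accession] = archs
        found = find_cassettes(g, archs, max_gap_genes=config.max_gap_genes)
        if config.all_cassettes:
            cassettes.extend(found)
        else:
            primary = primary_cassette(found)
            if primary is not None:
                cassettes.append(primary)

    sequences = {
        f.protein_id: f.translation
        for g in genomes for f in g.cds if f.translation
    }
    segmentations = []
    for c in cassettes:
        for m in c.members:
            if m.role == LyticRole.ENDOLYSIN and sequences.get(m.protein_id):
                segmentations.append(segment_endolysin(
                    m, sequences[m.protein_id],
                    min_ucwb_len=config.min_ucwb_len,
                    **config.linker_kwargs()))
    segmentations = assign_ucwb_labels(segmentations, config.ucwb_cluster_id)

    events = detect_domain_shuffling(segmentations, config.high_id, config.low_id)
    events += detect_gene_shuffling(cassettes, sequences,
                                    config.endolysin_cluster_id)

    result = PipelineResult(
        genomes=list(genomes),
        architectures=architectures,
        cassettes=cassettes,
        segmentations=segmentations,
        events=events,
        histogram=size_histogram(genomes, config.histogram_bin_bp),
        census=group_census(genomes),
    )
    if cassettes:
        result.table1 = tabulate(cassettes, "catalytic_cwb")
        result.table2 = tabulate(cassettes, "holin_catalytic_cwb")
    return result


def cassette_records(result: PipelineResult) -> list[dict[str, object]]:
    """Flatten cassettes to uniform rows for the cassettes.tsv report."""
    rows: list[dict[str, object]] = []
    for i, c in enumerate(result.cassettes):
        genome = next(g for g in result.genomes if g.accession == c.genome_accession)
        for m in c.members:
            rows.append({
                "cassette_id": f"{c.genome_accession}:cas{i}",
                "genome_accession": c.genome_accession,
                "size_group": assign_size_group(genome.length_bp).label,
                "cassette_type": type_cassette(c).key,
                "protein_id": m.protein_id,
                "role": m.role.value,
                "product": m.product,
                "domains": ";".join(
                    f"{d.name}:{d.category.value}:{d.start_aa}-{d.end_aa}"
                    for d in m.domains),
                "evidence": m.evidence,
            })
    return rows
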