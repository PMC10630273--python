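"""Shared fixtures: a frozen minus-strand CDS oracle, an exhaustive
alignment-score oracle, and a cached default synthetic run."""

from __future__ import annotations

import functools

import pytest
from hypothesis import settings

from lyticmine import (
    ProteinDomainHit,
    SimulationSpec,
    build_library,
    generate_population,
    run_pipeline,
)

settings.register_profile("suite", derandomize=True, max_examples=25,
                          deadline=None)
settings.load_profile("suite")


# --- frozen fixture: a 99-aa protein whose gene sits on the minus strand of
# a 1200 bp genome at positions 100..399 (1-based inclusive).  Both strings
# were derived with a hand-written table-11 codon map, so the expected
# translation is independent of any library translation code.
MINUS_STRAND_PROTEIN = (
    "MDAHGGCDWNYFRANEGTVAWEWFGPYHAQFLHCELDNMDKKVHRPWDMNWIVKYENRGINGDMHPKQKK"
    "EHNVQWGQPMHWGLRGRLMHNEYLESMPC"
)
MINUS_STRAND_GENOME = (
    "GCCGTTGCCTAAACCTATTTGAAGGAGTCTAGCAGCCGCAGTAAGGCACAATACCTCGTCCGTGTTACCAGACCAAACAAGACGTCCTCTTCAATGTTT"
    "TTAACAAGGCATAGATTCAAGATATTCATTATGCATAAGACGACCACGAAGACCCCAATGCATAGGTTGACCCCATTGAACATTATGTTCTTTTTTTTG"
    "TTTAGGATGCATATCACCATTAATACCACGATTTTCATATTTAACAATCCAATTCATATCCCAAGGACGATGAACTTTTTTATCCATATTATCAAGTTC"
    "ACAATGAAGAAATTGAGCATGATAAGGACCAAACCATTCCCAAGCAACAGTACCTTCATTAGCACGAAAATAATTCCAATCACAACCACCATGAGCATC"
    "CATCGTTATGTCTCATAATCTCAGTGCTGGTGTGATAAGCAAACCACCCTACTGGCACGAAGTTCACAGAAGTGAGATTATGTCTCGTTTGGCAGTCTT"
    "GATGCTCGGGGGACACTTCTTTAAGCTCGGTGTGGTGGGCACGACCCTGGACGCGCGACGAAGCTAAGTTTGCAGTAATTAACCGACATCTTTGTGAAC"
    "CGACCCACATTTGACGGTACGCTACCGCAACGGTATGTGTTAATGGAACAGACTTGCTTATGTGGACGTTGTATAGGGATATTACGTTACGCGTTAACC"
    "GATACATACTGGTTTCTCTCCAGTGGAGGTCTTGGTTGCCTCTAGTTTCTACGATATACTCATGGTAGTGTAACGCATAATCGAAGAGGGTCCTCCCAT"
    "CTCCTGTGATGCATGGTGTGCTTACTGGGATGAATGCGCCGCAAGTAGCAGGTCCCGGCGTGGATACCTGATAGATGGTGACTAGCATGTACAAGTAAC"
    "CTTGTCTATTGAGCTTCGAGGATGCATACAAGCCCACCCGCAGCCGCAACAGCGACGACTAATTGATCAGTAATTTATTAAGCACGGTGTTAACTTCTG"
    "TTTAGTGGGCTAAAATAGCAGATGTAGGGACCTCAGGAGCTAGACGGGGACCTACAACTTTGCGGGAACCAAGTTTTTGCAGTAGTGACTAACGCCGGG"
    "AATTCCTCGATATATAGTTTGATAGCTGATACTTATGGCGCAACGGCCACGCCCACTTTGGCTATTGGAGAGTTAAGGAATTATCGTCATAGACACTTC"
    "GGGTTGAGAGAT"
)


@pytest.fixture(scope="session")
def minus_strand_fixture() -> tuple[str, str]:
    assert len(MINUS_STRAND_GENOME) == 1200
    return MINUS_STRAND_PROTEIN, MINUS_STRAND_GENOME


# ---------------------------------------------------------------------------
# Exhaustive alignment-score oracle
# ---------------------------------------------------------------------------

def bruteforce_nw_score(a: str, b: str, open_gap: float = 10.0,
                        extend_gap: float = 0.5) -> float:
    """Maximum score over all global gapped alignments of ``a`` and ``b``
    under BLOSUM62 with affine gaps (first gap residue costs ``open_gap``,
    each further one ``extend_gap``).  Memoised recursion over
    (i, j, previous move) — exhaustive maximisation, independent of any
    dynamic-programming aligner implementation."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")

    @functools.lru_cache(maxsize=None)
    def best(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            options.append(mat[a[i], b[j]] + best(i + 1, j + 1, "d"))
        if i < len(a):
            cost = extend_gap if prev == "u" else open_gap
            options.append(-cost + best(i + 1, j, "u"))
        if j < len(b):
            cost = extend_gap if prev == "l" else open_gap
            options.append(-cost + best(i, j + 1, "l"))
        return max(options)

    return best(0, 0, "d")


@pytest.fixture(scope="session")
def nw_oracle():
    return bruteforce_nw_score


# ---------------------------------------------------------------------------
# Cached default synthetic run (seed 1, default study conditions)
# ---------------------------------------------------------------------------

def hits_from_rows(rows) -> list[ProteinDomainHit]:
    return [
        ProteinDomainHit(r[0], r[4], r[5], int(r[6]), int(r[7]))
        for r in rows if r[3] == "Pfam"
    ]


@pytest.fixture(scope="session")
def default_run():
    """(spec, library, genomes, rows, truth, pipeline result) for seed 1."""
    spec = SimulationSpec(seed=1)
    lib = build_library(spec.seed)
    genomes, rows, truth = generate_population(spec, lib)
    result = run_pipeline(genomes, hits_from_rows(rows))
    return spec, lib, genomes, rows, truth, result
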