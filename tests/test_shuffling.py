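"""Alignment, linker detection, segmentation, UCWB clustering and
shuffling-event calling."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lyticmine import (
    LINKER_CONSENSUS,
    EventClass,
    LyticRole,
    ProteinArchitecture,
    build_cassette,
    cluster_regions,
    detect_domain_shuffling,
    detect_gene_shuffling,
    detect_linker,
    global_align,
    identity,
    segment_endolysin,
)
from lyticmine.annotation import Category, DomainSpan

AA = "ACDEFGHIKLMNPQRSTVWY"


def rand_prot(rng, n, alphabet=AA):
    return "".join(rng.choice(list(alphabet), size=n))


aa_text = st.text(alphabet=AA, min_size=1, max_size=12)


class TestGlobalAlign:
    def test_self_identity_one(self):
        assert global_align("PELIG", "PELIG").identity == 1.0

    def test_unrelated_identity_zero(self):
        assert identity("AAAA", "WWWW") == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            global_align("", "PELIG")

    def test_degapping_recovers_inputs(self):
        aln = global_align("MKVLINGKT", "MKVGKT")
        assert aln.aligned_a.replace("-", "") == "MKVLINGKT"
        assert aln.aligned_b.replace("-", "") == "MKVGKT"

    def test_nonstandard_residue_scored_as_x(self):
        # U is not in BLOSUM62; it must align without error, like X
        assert global_align("MUV", "MXV").score == global_align("MXV", "MXV").score

    @given(aa_text, aa_text)
    def test_identity_symmetric_and_bounded(self, a, b):
        ab, ba = identity(a, b), identity(b, a)
        assert ab == ba
        assert 0.0 <= ab <= 1.0

    @given(aa_text)
    def test_self_identity(self, a):
        assert identity(a, a) == 1.0

    def test_scores_match_exhaustive_enumeration(self, nw_oracle):
        rng = np.random.default_rng(11)
        for _ in range(40):
            a = rand_prot(rng, int(rng.integers(1, 9)))
            b = rand_prot(rng, int(rng.integers(1, 9)))
            assert global_align(a, b).score == pytest.approx(nw_oracle(a, b))


class TestDetectLinker:
    def test_exact_consensus_found_at_coordinates(self):
        rng = np.random.default_rng(2)
        seq = rand_prot(rng, 150) + LINKER_CONSENSUS + rand_prot(rng, 100)
        call = detect_linker(seq, search_start=141)
        assert call is not None
        assert (call.start_aa, call.end_aa) == (151, 163)
        assert call.motif_distance == 0

    def test_poly_alanine_has_no_linker(self):
        assert detect_linker("A" * 200, search_start=1) is None

    def test_pure_pk_window_called_by_composition(self):
        rng = np.random.default_rng(3)
        seq = rand_prot(rng, 50, alphabet="ACDEFGHILMNQRSTVWY") \
            + "KPKPKPKPKPKP" \
            + rand_prot(rng, 40, alphabet="ACDEFGHILMNQRSTVWY")
        call = detect_linker(seq, search_start=30)
        assert call is not None
        assert call.pk_fraction == 1.0
        assert (call.start_aa, call.end_aa) == (51, 62)

    def test_near_consensus_within_tolerance(self):
        rng = np.random.default_rng(4)
        variant = "KPTKPPSKPAPKP"  # one substitution
        seq = rand_prot(rng, 100, alphabet="ACDEFGHILMNQRSTVWY") + variant \
            + rand_prot(rng, 60, alphabet="ACDEFGHILMNQRSTVWY")
        call = detect_linker(seq, search_start=90)
        assert call is not None and call.motif_distance == 1

    def test_bad_search_start_rejected(self):
        with pytest.raises(ValueError):
            detect_linker("MKV", search_start=10)


def endolysin_arch(pid, domains):
    return ProteinArchitecture(pid, LyticRole.ENDOLYSIN, tuple(domains))


@pytest.fixture(scope="module")
def blocks():
    rng = np.random.default_rng(7)
    no_pk = "ACDEFGHILMNQRSTVWY"
    return {
        "cat": rand_prot(rng, 150, no_pk),
        "cat2": rand_prot(rng, 150, no_pk),
        "cwb_sh3": rand_prot(rng, 61, no_pk),
        "cwb_zoo": rand_prot(rng, 67, no_pk),
        "ucwb": rand_prot(rng, 90, no_pk),
        "spacer": rand_prot(rng, 4, no_pk),
        "gap62": rand_prot(rng, 62, no_pk),
    }


class TestSegmentEndolysin:
    def test_unannotated_tail_becomes_ucwb_candidate(self, blocks):
        seq = blocks["cat"] + blocks["spacer"] + LINKER_CONSENSUS + \
            blocks["ucwb"] + blocks["ucwb"][:23]
        assert len(seq) == 280
        arch = endolysin_arch("e1", [
            DomainSpan("Amidase_2", Category.CATALYTIC, 1, 150)])
        seg = segment_endolysin(arch, seq)
        assert seg.linker is not None
        assert (seg.linker.start_aa, seg.linker.end_aa) == (155, 167)
        assert seg.cwb_region is not None
        assert (seg.cwb_region.start_aa, seg.cwb_region.end_aa) == (168, 280)
        assert seg.cwb_region.label.startswith("UCWB")

    def test_gap_before_known_cwb_emits_extra_ucwb(self, blocks):
        seq = blocks["cat"] + blocks["spacer"] + LINKER_CONSENSUS + \
            blocks["gap62"] + blocks["cwb_sh3"]
        assert len(seq) == 290
        arch = endolysin_arch("e2", [
            DomainSpan("Amidase_2", Category.CATALYTIC, 1, 150),
            DomainSpan("SH3_5", Category.CWB, 230, 290)])
        seg = segment_endolysin(arch, seq)
        assert seg.cwb_region.label == "SH3_5"
        assert seg.pre_cwb_ucwb is not None
        assert (seg.pre_cwb_ucwb.start_aa, seg.pre_cwb_ucwb.end_aa) == (168, 229)

    def test_cwb_right_after_linker_no_ucwb(self, blocks):
        seq = blocks["cat"] + LINKER_CONSENSUS + blocks["cwb_zoo"]
        arch = endolysin_arch("e3", [
            DomainSpan("Amidase_2", Category.CATALYTIC, 1, 150),
            DomainSpan("ZoocinA", Category.CWB, 164, 230)])
        seg = segment_endolysin(arch, seq)
        assert (seg.linker.start_aa, seg.linker.end_aa) == (151, 163)
        assert seg.cwb_region.label == "ZoocinA"
        assert seg.pre_cwb_ucwb is None

    def test_no_catalytic_no_linker_is_failed_marker(self):
        arch = endolysin_arch("e4", [])
        seg = segment_endolysin(arch, "A" * 120)
        assert seg.failed


class TestClusterRegions:
    def test_identical_strings_one_cluster(self, blocks):
        s = blocks["ucwb"]
        labels = cluster_regions([("a", s), ("b", s), ("c", s)])
        assert set(labels.values()) == {"UCWB-1"}

    def test_two_plus_one(self, blocks):
        rng = np.random.default_rng(9)
        s = blocks["ucwb"]
        close = list(s)
        for i in rng.choice(len(s), size=4, replace=False):
            close[i] = "A" if s[i] != "A" else "C"
        far = rand_prot(rng, 90)
        labels = cluster_regions([("a", s), ("b", "".join(close)), ("c", far)])
        assert labels["a"] == labels["b"] == "UCWB-1"
        assert labels["c"] == "UCWB-2"

    def test_labels_stable_under_permutation(self, blocks):
        items = [("a", blocks["ucwb"]), ("b", blocks["cwb_sh3"]),
                 ("c", blocks["ucwb"])]
        ref = cluster_regions(items)
        assert cluster_regions(items[::-1]) == ref

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            cluster_regions([("a", "")])


def _segmented(pid, cat_seq, cwb_seq):
    seq = cat_seq + LINKER_CONSENSUS + cwb_seq
    arch = endolysin_arch(pid, [
        DomainSpan("Amidase_2", Category.CATALYTIC, 1, len(cat_seq))])
    return segment_endolysin(arch, seq)


class TestDetectDomainShuffling:
    def test_shared_catalytic_unrelated_cwb_is_cwb_swap(self, blocks):
        segs = [_segmented("a", blocks["cat"], blocks["ucwb"]),
                _segmented("b", blocks["cat"], blocks["cwb_zoo"])]
        (event,) = detect_domain_shuffling(segs)
        assert event.event_class is EventClass.DOMAIN_CWB_SWAP
        assert event.participants == frozenset({"a", "b"})
        evidence = dict(event.evidence)
        assert evidence["catalytic_identity"] >= 0.9
        assert evidence["cwb_identity"] <= 0.5

    def test_identical_endolysins_no_event(self, blocks):
        segs = [_segmented("a", blocks["cat"], blocks["ucwb"]),
                _segmented("b", blocks["cat"], blocks["ucwb"])]
        assert detect_domain_shuffling(segs) == []

    def test_different_catalytic_same_cwb_is_catalytic_swap(self, blocks):
        segs = [_segmented("a", blocks["cat"], blocks["ucwb"]),
                _segmented("b", blocks["cat2"], blocks["ucwb"])]
        (event,) = detect_domain_shuffling(segs)
        assert event.event_class is EventClass.DOMAIN_CATALYTIC_SWAP

    def test_homogeneous_population_yields_no_events(self, blocks):
        """Mutated copies (<= 5% divergence) of one archetype never trigger
        domain-swap calls at default thresholds."""
        rng = np.random.default_rng(12)
        archetype = blocks["cat"] + LINKER_CONSENSUS + blocks["ucwb"]
        segs = []
        for k in range(6):
            chars = list(archetype)
            n_sub = int(0.05 * len(chars))
            for i in rng.choice(len(chars), size=n_sub, replace=False):
                chars[i] = AA[(AA.index(chars[i]) + 1) % len(AA)]
            arch = endolysin_arch(f"c{k}", [
                DomainSpan("Amidase_2", Category.CATALYTIC, 1, 150)])
            segs.append(segment_endolysin(arch, "".join(chars)))
        assert detect_domain_shuffling(segs) == []

    def test_threshold_monotonicity(self, blocks):
        segs = [_segmented("a", blocks["cat"], blocks["ucwb"]),
                _segmented("b", blocks["cat"], blocks["cwb_zoo"]),
                _segmented("c", blocks["cat2"], blocks["ucwb"])]
        base = len(detect_domain_shuffling(segs, 0.9, 0.5))
        assert len(detect_domain_shuffling(segs, 0.95, 0.5)) <= base
        assert len(detect_domain_shuffling(segs, 0.9, 0.4)) <= base
        assert len(detect_domain_shuffling(segs, 0.99, 0.01)) <= base


def _holin_cassette(accession, holin, endo_seq, sequences):
    pid_h, pid_e = f"{accession}_h", f"{accession}_e"
    members = (
        ProteinArchitecture(pid_h, LyticRole.HOLIN,
                            (DomainSpan(holin, Category.HOLIN, 1, 80),)),
        ProteinArchitecture(pid_e, LyticRole.ENDOLYSIN,
                            (DomainSpan("Glyco_hydro_25", Category.CATALYTIC,
                                        1, 40),)),
    )
    sequences[pid_e] = endo_seq
    return build_cassette(accession, members)


class TestDetectGeneShuffling:
    def test_minority_holins_in_cluster_of_13(self):
        """Eleven cassettes with the cluster-typical holin plus two using a
        different family yield exactly two holin-swap events."""
        rng = np.random.default_rng(5)
        endo = rand_prot(rng, 60)
        sequences = {}
        cassettes = [
            _holin_cassette(f"g{i:02d}", "Phage_holin_Dp1", endo, sequences)
            for i in range(11)
        ] + [
            _holin_cassette(f"m{i}", "Phage_holin_1", endo, sequences)
            for i in range(2)
        ]
        events = detect_gene_shuffling(cassettes, sequences)
        assert len(events) == 2
        assert {min(e.participants) for e in events} == {"m0", "m1"}
        for e in events:
            assert dict(e.evidence) == {"minority_holin": "PH_1",
                                        "modal_holin": "PH_Dp1"}

    def test_single_holin_family_no_events(self):
        rng = np.random.default_rng(6)
        endo = rand_prot(rng, 60)
        sequences = {}
        cassettes = [
            _holin_cassette(f"g{i}", "Holin_SPP1", endo, sequences)
            for i in range(5)
        ]
        assert detect_gene_shuffling(cassettes, sequences) == []

    def test_one_outlier_in_cluster_of_41(self):
        rng = np.random.default_rng(8)
        endo = rand_prot(rng, 60)
        sequences = {}
        cassettes = [
            _holin_cassette(f"g{i:02d}", "Holin_SPP1", endo, sequences)
            for i in range(40)
        ] + [_holin_cassette("odd", "Phage_holin_4_1", endo, sequences)]
        events = detect_gene_shuffling(cassettes, sequences)
        assert len(events) == 1
        assert events[0].participants == frozenset({"odd"})

    def test_small_clusters_ignored(self):
        rng = np.random.default_rng(10)
        sequences = {}
        cassettes = [
            _holin_cassette("a", "Holin_SPP1", rand_prot(rng, 60), sequences),
            _holin_cassette("b", "Phage_holin_1", rand_prot(rng, 60), sequences),
        ]
        assert detect_gene_shuffling(cassettes, sequences) == []
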