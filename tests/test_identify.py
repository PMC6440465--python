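"""Zinc-finger scanning, domain assembly and family identification."""

import pytest

from famscan.identify import (
    FamilyMember,
    ZincFinger,
    annotate_member,
    assemble_id_domain,
    find_cterm_motifs,
    find_nls,
    identify_family,
    locus_of,
    scan_zinc_fingers,
)
from famscan.genome_io import SeqRecord

# exact-consensus fingers used to build deterministic test proteins
C2H2 = "FACDDCDDDYDDDDDLDDHDDDH"
C2HC = "FACDDCDDDYDDDDDLDDHDDDC"


def _zf(kind, start):
    return ZincFinger(kind, start, start + 23, (start + 2, start + 5, start + 18, start + 22))


class TestScanZincFingers:
    def test_no_fingers(self):
        assert scan_zinc_fingers("MAAA") == []

    def test_planted_c2h2_found_at_offset(self):
        seq = "A" * 17 + C2H2 + "A" * 9
        hits = scan_zinc_fingers(seq)
        assert len(hits) == 1
        assert hits[0].kind == "C2H2"
        assert hits[0].start == 17

    def test_planted_c2hc(self):
        hits = scan_zinc_fingers("A" * 5 + C2HC + "A" * 5)
        assert [h.kind for h in hits] == ["C2HC"]

    def test_broken_finger_not_matched(self):
        broken = C2H2.replace("FAC", "FAS", 1)  # first coordinating C -> S
        assert scan_zinc_fingers("A" * 10 + broken + "A" * 10) == []

    def test_coordinating_positions(self):
        hits = scan_zinc_fingers(C2H2)
        (zf,) = hits
        c1, c2, h1, h2 = zf.coordinating
        assert C2H2[c1] == C2H2[c2] == "C"
        assert C2H2[h1] == C2H2[h2] == "H"
        assert c1 < c2 < h1 < h2

    def test_multiple_nonoverlapping_leftmost(self):
        seq = C2H2 + "DDD" + C2HC + "DDD" + C2HC
        hits = scan_zinc_fingers(seq)
        assert [h.kind for h in hits] == ["C2H2", "C2HC", "C2HC"]
        assert all(a.end <= b.start for a, b in zip(hits, hits[1:]))


class TestAssembleDomain:
    def test_canonical_quartet(self):
        zfs = [_zf("C2H2", 0), _zf("C2H2", 40), _zf("C2HC", 80), _zf("C2HC", 120)]
        dom = assemble_id_domain(zfs)
        assert dom is not None
        assert dom.start == 0 and dom.end == 143

    def test_order_violation_returns_none(self):
        zfs = [_zf("C2H2", 0), _zf("C2HC", 40), _zf("C2H2", 80), _zf("C2HC", 120)]
        assert assemble_id_domain(zfs) is None

    def test_span_limit(self):
        zfs = [_zf("C2H2", 0), _zf("C2H2", 80), _zf("C2HC", 160), _zf("C2HC", 240)]
        assert assemble_id_domain(zfs) is None  # span 263 > 220
        assert assemble_id_domain(zfs, max_domain_span=300) is not None

    def test_sliding_window_over_quartets(self):
        """With five fingers where only positions 2..5 form a valid quartet,
        the assembled domain starts at the second finger — matching an
        exhaustive check over all quartet windows."""
        zfs = [
            _zf("C2HC", 0),
            _zf("C2H2", 30),
            _zf("C2H2", 60),
            _zf("C2HC", 90),
            _zf("C2HC", 120),
        ]
        dom = assemble_id_domain(zfs)
        want = ("C2H2", "C2H2", "C2HC", "C2HC")
        valid_starts = [
            i for i in range(len(zfs) - 3)
            if tuple(z.kind for z in zfs[i:i + 4]) == want
            and zfs[i + 3].end - zfs[i].start <= 220
        ]
        assert dom is not None
        assert dom.zfs[0] is zfs[valid_starts[0]]


def _member_seq(nls="KKKR", tail="DD" + "MSATALLQKAA" + "DDDD" + "TRDFLG" + "DD"):
    dom = C2H2 + "DDDDD" + C2H2 + "DDDDD" + C2HC + "DDDDD" + C2HC
    return "M" + "DDD" + nls + "DDDDD" + dom + tail


class TestMotifs:
    def test_nls_found_before_domain(self):
        seq = "M" + "KKKR" + "DDDD" + C2H2 + "DD" + C2H2 + "DD" + C2HC + "DD" + C2HC
        dom = assemble_id_domain(scan_zinc_fingers(seq))
        hit = find_nls(seq, dom)
        assert hit is not None and hit.position == 1

    def test_nls_after_domain_rejected(self):
        seq = "M" + "DDDD" + C2H2 + "DD" + C2H2 + "DD" + C2HC + "DD" + C2HC + "KKKR"
        dom = assemble_id_domain(scan_zinc_fingers(seq))
        assert find_nls(seq, dom) is None

    def test_cterm_exact_and_mismatch(self):
        seq = _member_seq()
        dom = assemble_id_domain(scan_zinc_fingers(seq))
        hits = {h.motif: h for h in find_cterm_motifs(seq, dom)}
        assert hits["MSATALLQKAA"].mismatches == 0
        assert hits["TRDFLG"].mismatches == 0
        seq1 = _member_seq(tail="DD" + "MSATALLQKAV" + "DDDDDDDDDD")
        dom1 = assemble_id_domain(scan_zinc_fingers(seq1))
        hits1 = {h.motif: h.mismatches for h in find_cterm_motifs(seq1, dom1)}
        assert hits1 == {"MSATALLQKAA": 1}

    def test_mismatch_budget_exceeded(self):
        seq = _member_seq(tail="DD" + "MSATADDQKDA" + "DDDDDDDDDD")  # 3 mismatches
        dom = assemble_id_domain(scan_zinc_fingers(seq))
        assert find_cterm_motifs(seq, dom) == []


def test_locus_of():
    assert locus_of("Pbr029706.1") == "Pbr029706"
    assert locus_of("gene42") == "gene42"
    assert locus_of("x.y") == "x.y"


class TestIdentifyFamily:
    def test_proteome_equals_queries_all_retained(self):
        seqs = [SeqRecord("q1", _member_seq()), SeqRecord("q2", _member_seq("KRKR"))]
        members = identify_family(seqs, seqs)
        assert {m.protein.id for m in members} == {"q1", "q2"}

    def test_decoy_only_proteome_empty(self, bundle):
        decoys = [p for p in bundle.proteome if p.id in set(bundle.truth.decoys)]
        assert identify_family(decoys, bundle.queries) == []

    def test_perfect_precision_recall_on_bundle(self, bundle):
        members = identify_family(bundle.proteome, bundle.queries)
        assert {m.protein.id for m in members} == set(bundle.truth.members)

    def test_all_members_have_canonical_finger_order(self, bundle):
        for m in identify_family(bundle.proteome, bundle.queries):
            assert [z.kind for z in m.domain.zfs] == ["C2H2", "C2H2", "C2HC", "C2HC"]

    def test_idempotent(self, bundle):
        members = identify_family(bundle.proteome, bundle.queries)
        again = identify_family([m.protein for m in members], bundle.queries)
        assert {m.protein.id for m in again} == {m.protein.id for m in members}

    def test_nls_detection_matches_planted_fraction(self, bundle):
        members = identify_family(bundle.proteome, bundle.queries)
        detected = {m.protein.id: m.nls is not None for m in members}
        assert detected == bundle.truth.has_nls

    def test_group4_lacks_cterm_motifs(self, bundle):
        members = {m.protein.id: m for m in identify_family(bundle.proteome, bundle.queries)}
        for gid, group in bundle.truth.groups.items():
            motifs = {h.motif for h in members[gid].cterm_motifs}
            if group == 4:
                assert motifs == set(), gid
            else:
                assert motifs == {"MSATALLQKAA", "TRDFLG"}, gid

    def test_longest_isoform_kept(self):
        long = _member_seq()
        short = long[:-6]
        proteome = [SeqRecord("g1.1", short), SeqRecord("g1.2", long)]
        members = identify_family(proteome, [SeqRecord("q", long)])
        assert len(members) == 1
        assert members[0].protein.id == "g1.2"
        assert members[0].gene_id == "g1"

    def test_empty_queries_rejected(self):
        with pytest.raises(ValueError):
            identify_family([SeqRecord("a", "MDD")], [])


def test_annotate_member_none_without_domain():
    assert annotate_member(SeqRecord("x", "M" + "D" * 50)) is None
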