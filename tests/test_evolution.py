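"""NG86 Ka/Ks correctness, duplication rules and sliding windows."""

import itertools
import math

import pytest

from famscan.align import SENSE_CODONS, align_cds_pair
from famscan.evolution import (
    DupPair,
    KaKsError,
    classify_duplicates,
    jukes_cantor,
    kaks_for_cds_pair,
    ng86_pair,
    ng86_site_counts,
    sliding_window,
)
from famscan.evolution import _pathway_counts
from famscan.genome_io import GeneModel
from oracles import ng86_pathways_oracle, ng86_sites_oracle


class TestSiteCounts:
    def test_phe_ttt(self):
        # only TTC (third position) is synonymous
        s, n = ng86_site_counts("TTT")
        assert s == pytest.approx(1 / 3)
        assert n == pytest.approx(8 / 3)

    def test_trp_tgg_no_synonymous(self):
        s, n = ng86_site_counts("TGG")
        assert s == 0.0
        assert n == 3.0

    def test_sites_sum_to_three_all_codons(self):
        for codon in SENSE_CODONS:
            s, n = ng86_site_counts(codon)
            assert s + n == pytest.approx(3.0, abs=1e-12)

    def test_matches_oracle_all_codons(self):
        for codon in SENSE_CODONS:
            assert ng86_site_counts(codon) == pytest.approx(
                ng86_sites_oracle(codon), abs=1e-12
            )

    def test_stop_codon_rejected(self):
        with pytest.raises(KaKsError):
            ng86_site_counts("TAA")


class TestPathways:
    def test_all_sense_codon_pairs_match_oracle(self):
        """Pathway-averaged Sd/Nd equals explicit enumeration for every
        one of the 61 x 61 sense-codon pairs."""
        for ca, cb in itertools.product(SENSE_CODONS, repeat=2):
            got = _pathway_counts(ca, cb)
            want = ng86_pathways_oracle(ca, cb)
            assert got == pytest.approx(want, abs=1e-12), (ca, cb)

    def test_lys_third_position_transition(self):
        r = ng86_pair("AAA", "AAG")
        assert r.sd == pytest.approx(1.0)
        assert r.nd == pytest.approx(0.0)

    def test_symmetry(self):
        for ca, cb in [("AAA", "CGT"), ("TTT", "GGG"), ("ATG", "TGG")]:
            a = ng86_pair(ca, cb)
            b = ng86_pair(cb, ca)
            assert (a.sd, a.nd, a.s_sites, a.n_sites) == (b.sd, b.nd, b.s_sites, b.n_sites)


class TestNg86Pair:
    def test_identical_sequences(self):
        r = ng86_pair("ATGAAACCC", "ATGAAACCC")
        assert r.ka == 0.0 and r.ks == 0.0
        assert r.ratio is None  # 0/0
        assert r.selection == "n/a"

    def test_gap_columns_skipped(self):
        r = ng86_pair("ATG---AAA", "ATGCCCAAA")
        assert r.codons == 2
        assert r.s_sites + r.n_sites == pytest.approx(6.0)

    def test_difference_conservation(self):
        """Pathway-averaged Sd+Nd equals the plain nucleotide difference
        count over compared codons."""
        pairs = [("ATGAAA", "ATGAAG"), ("AAACCC", "AGACGC"), ("TTTGGG", "GTTGGC")]
        for a, b in pairs:
            r = ng86_pair(a, b)
            raw = sum(x != y for x, y in zip(a, b))
            assert r.sd + r.nd == pytest.approx(raw, abs=1e-12)

    def test_jukes_cantor_saturation(self):
        assert jukes_cantor(0.8) is None
        assert jukes_cantor(0.0) == 0.0
        assert jukes_cantor(0.3) == pytest.approx(-0.75 * math.log(1 - 0.4))


class TestSlidingWindow:
    @staticmethod
    def _pair(n_codons):
        a = "ATG" + "AAA" * (n_codons - 1)
        return a, a

    def test_window_counts(self):
        for L in range(150, 601, 3):
            a = "AAA" * (L // 3)
            profile = sliding_window(a, a)
            assert len(profile.window_starts) == (L - 150) // 9 + 1, L
            assert profile.window_starts == tuple(range(0, L - 150 + 1, 9))

    def test_single_window(self):
        a = "AAA" * 50
        profile = sliding_window(a, a)
        assert profile.window_starts == (0,)

    def test_short_alignment_warns_empty(self):
        a = "AAA" * 10
        with pytest.warns(UserWarning, match="shorter"):
            profile = sliding_window(a, a)
        assert profile.window_starts == ()

    def test_window_step_must_be_codon_aligned(self):
        with pytest.raises(KaKsError):
            sliding_window("AAA" * 60, "AAA" * 60, window=100, step=9)


def _model(gid, chrom, start, end):
    return GeneModel(gid, chrom, "+", start, end, exons=[(start, end)])


class TestClassifyDuplicates:
    def test_planted_pairs_recovered(self, bundle):
        members = {m.gene_id: m for m in bundle.models
                   if m.gene_id in set(bundle.truth.members)}
        pairs = classify_duplicates(members, bundle.cds)
        got = {frozenset((p.gene_a, p.gene_b)): p.dup_class for p in pairs}
        want = {frozenset((d.gene_a, d.gene_b)): d.dup_type
                for d in bundle.truth.dup_pairs}
        assert got == want

    def test_identity_threshold(self, bundle):
        members = {m.gene_id: m for m in bundle.models
                   if m.gene_id in set(bundle.truth.members)}
        for p in classify_duplicates(members, bundle.cds):
            assert p.identity > 0.8

    def test_segmental_requires_different_chromosomes(self, bundle):
        members = {m.gene_id: m for m in bundle.models
                   if m.gene_id in set(bundle.truth.members)}
        for p in classify_duplicates(members, bundle.cds):
            if p.dup_class == "segmental":
                assert p.chrom_a != p.chrom_b

    def test_tandem_rule_switch(self):
        cds = "ATGAAACCCGGGTTTTAA"
        models = {
            "a": _model("a", "chr1", 1_000, 2_000),
            "b": _model("b", "chr1", 500_000, 501_000),
            "c": _model("c", "chr1", 3_000, 4_000),
        }
        cds_map = {g: cds for g in models}
        as_printed = {(p.gene_a, p.gene_b): p.dup_class
                      for p in classify_duplicates(models, cds_map)}
        assert as_printed[("a", "b")] == "tandem"  # >= 200 kb apart
        assert as_printed[("a", "c")] == "unclassified"
        conventional = {(p.gene_a, p.gene_b): p.dup_class
                        for p in classify_duplicates(models, cds_map,
                                                     tandem_rule="conventional")}
        assert conventional[("a", "c")] == "tandem"  # < 200 kb apart
        assert conventional[("a", "b")] == "unclassified"

    def test_missing_cds_is_error(self):
        models = {"a": _model("a", "chr1", 0, 10), "b": _model("b", "chr2", 0, 10)}
        with pytest.raises(KaKsError):
            classify_duplicates(models, {"a": "ATG"})


def test_kaks_identical_genes_zero(bundle):
    gid = bundle.truth.members[0]
    r = kaks_for_cds_pair(bundle.cds[gid], bundle.cds[gid])
    assert r.ka == 0.0 and r.ks == 0.0


def test_kaks_planted_pair_recovery(bundle):
    """NG86 on one planted duplicate pair lands near the generator's
    targets (the full 20-seed recovery experiment lives in acceptance)."""
    d = bundle.truth.dup_pairs[0]
    r = kaks_for_cds_pair(bundle.cds[d.gene_a], bundle.cds[d.gene_b])
    assert r.ka == pytest.approx(d.target_ka, abs=0.05)
    assert r.ks == pytest.approx(d.target_ks, abs=0.05)
    assert r.selection == "purifying"
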