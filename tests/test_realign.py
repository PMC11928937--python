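"""Synteny candidates, edit-distance realignment, filtering, merging."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from splicecons.alignment import read_maf
from splicecons.catalogs import ExonInterval, unique_exons
from splicecons.genomes import GenomeSet
from splicecons.realign import (
    AlignmentPatch,
    RealignmentCandidate,
    RealignmentScores,
    accept_patch,
    compute_scores,
    find_candidates,
    merge_alignments,
    realign_exon,
    realign_missing_exons,
)


def _gs(ref, target=None, target_id="g2"):
    genomes = {"hg": {"chr1": ref}}
    if target is not None:
        genomes[target_id] = {"chr1": target}
    return GenomeSet(genomes=genomes, reference_id="hg")


def _edit_distance_oracle(query, target_infix):
    """Brute-force semi-global DP: query global, target infix (free leading
    and trailing target gaps).  Independent of edlib."""
    n, m = len(query), len(target_infix)
    prev = np.zeros(m + 1, dtype=int)  # free start gap in target
    for i in range(1, n + 1):
        cur = np.empty(m + 1, dtype=int)
        cur[0] = i
        for j in range(1, m + 1):
            sub = prev[j - 1] + (query[i - 1] != target_infix[j - 1])
            cur[j] = min(sub, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return int(prev.min())  # free end gap


# ---------------------------------------------------------------------------
# candidates


MAF_ANCHORS = """##maf version=1
a score=0
s hg.chr1 0 100 + 400 {a}
s g2.chr1 1000 100 + 5000 {a}

a score=0
s hg.chr1 300 100 + 400 {b}
s g2.chr1 1200 100 + 5000 {b}
"""


def _anchor_map(ref):
    text = MAF_ANCHORS.format(a=ref[:100], b=ref[300:400])
    return read_maf(io.StringIO(text), "hg")


def test_target_segment_from_anchor_images():
    ref = "ACGT" * 100
    amap = _anchor_map(ref)
    exons = [
        ExonInterval("chr1", 0, 100, "+", "coding"),
        ExonInterval("chr1", 150, 250, "+", "coding"),
        ExonInterval("chr1", 300, 400, "+", "coding"),
    ]
    cands, rejected = find_candidates(exons, "g2", amap)
    assert len(cands) == 1 and not rejected
    c = cands[0]
    assert (c.u_start, c.u_end) == (1100, 1199)
    assert c.left_anchor.start == 0 and c.right_anchor.start == 300


def test_first_exon_has_no_candidate():
    ref = "ACGT" * 100
    amap = _anchor_map(ref)
    exons = [
        ExonInterval("chr1", 0, 50, "+", "coding"),  # region never aligned
        ExonInterval("chr1", 300, 400, "+", "coding"),
    ]
    # make the first exon unaligned by placing it outside the blocks
    exons[0] = ExonInterval("chr1", 110, 150, "+", "coding")
    cands, rejected = find_candidates(exons, "g2", amap)
    assert cands == []
    assert rejected["no_flanking_anchor"] == 1


def test_segment_cap_drops_long_candidates():
    ref = "ACGT" * 100
    amap = _anchor_map(ref)
    exons = [
        ExonInterval("chr1", 0, 100, "+", "coding"),
        ExonInterval("chr1", 150, 250, "+", "coding"),
        ExonInterval("chr1", 300, 400, "+", "coding"),
    ]
    cands, rejected = find_candidates(exons, "g2", amap, max_segment=50)
    assert cands == [] and rejected["segment_too_long"] == 1


def test_planted_erasures_yield_candidates_containing_truth(small_study, small_map):
    """Every planted erasure of a syntenic exon produces exactly one
    candidate whose segment contains the true interval."""
    exons = unique_exons([small_study.mane, small_study.extra])
    by_target = {}
    for e in small_study.erasures:
        by_target.setdefault(e.target, []).append(e)
    checked = 0
    for target, erasures in by_target.items():
        cands, _ = find_candidates(exons, target, small_map)
        by_exon = {(c.exon.start, c.exon.end): c for c in cands}
        for er in erasures:
            key = (er.exon_key[1], er.exon_key[2])
            if key not in by_exon:  # not syntenic (no disjoint anchors)
                continue
            c = by_exon[key]
            assert c.u_start <= er.true_start and er.true_end - 1 <= c.u_end
            checked += 1
    assert checked >= 10


# ---------------------------------------------------------------------------
# realignment of one exon


def test_exact_infix_match_maps_everything():
    ref = "TTTTTTTTTT" + "ACGTACGT" + "TTTT"
    target = "CCCCC" + "TTACGTACGTTT" + "CCCC"
    gs = _gs(ref, target)
    cand = RealignmentCandidate(
        exon=ExonInterval("chr1", 10, 18, "+", "coding"),
        target_genome="g2",
        left_anchor=None,
        right_anchor=None,
        target_contig="chr1",
        u_start=5,
        u_end=16,
    )
    patch = realign_exon(cand, gs)
    assert patch.r_prime == 1.0 and patch.edit_distance == 0
    assert patch.ref_positions.tolist() == list(range(10, 18))
    assert patch.target_positions.tolist() == list(range(7, 15))


def test_single_mismatch_still_maps_all_positions():
    ref = "AAAA" + "ACGT" + "AAAA"
    gs = _gs(ref, "AGGT")
    cand = RealignmentCandidate(
        exon=ExonInterval("chr1", 4, 8, "+", "coding"),
        target_genome="g2",
        left_anchor=None,
        right_anchor=None,
        target_contig="chr1",
        u_start=0,
        u_end=3,
    )
    patch = realign_exon(cand, gs)
    assert patch.edit_distance == 1
    assert patch.n_mapped == 4 and patch.r_prime == 1.0


def test_two_base_deletion_in_target():
    exon_seq = "AACCGGTTAA"
    ref = "T" * 5 + exon_seq + "T" * 5
    target = "TTAACCTTAAGG"  # GG of the exon absent
    gs = _gs(ref, target)
    cand = RealignmentCandidate(
        exon=ExonInterval("chr1", 5, 15, "+", "coding"),
        target_genome="g2",
        left_anchor=None,
        right_anchor=None,
        target_contig="chr1",
        u_start=0,
        u_end=11,
    )
    patch = realign_exon(cand, gs)
    assert patch.r_prime == (len(exon_seq) - 2) / len(exon_seq)
    # strictly increasing in both coordinates
    assert np.all(np.diff(patch.ref_positions) > 0)
    assert np.all(np.diff(patch.target_positions) > 0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    query=st.text(alphabet="ACGT", min_size=3, max_size=12),
    left=st.text(alphabet="ACGT", min_size=0, max_size=8),
    mid=st.text(alphabet="ACGT", min_size=1, max_size=12),
    right=st.text(alphabet="ACGT", min_size=0, max_size=8),
)
def test_realignment_edit_distance_matches_dp_oracle(query, left, mid, right):
    """edlib's semi-global score equals a brute-force DP on random strings."""
    segment = left + mid + right
    ref = "T" * 4 + query + "T" * 4
    gs = _gs(ref, segment)
    cand = RealignmentCandidate(
        exon=ExonInterval("chr1", 4, 4 + len(query), "+", "coding"),
        target_genome="g2",
        left_anchor=None,
        right_anchor=None,
        target_contig="chr1",
        u_start=0,
        u_end=len(segment) - 1,
    )
    patch = realign_exon(cand, gs)
    assert patch.edit_distance == _edit_distance_oracle(query, segment)


def test_minus_strand_candidate_realigned_via_revcomp():
    from splicecons.genomes import revcomp

    exon_seq = "ACGTTGCAAC"
    ref = "G" * 6 + exon_seq + "G" * 6
    target = "AAAA" + revcomp(exon_seq) + "CCCC"
    gs = _gs(ref, target)
    cand = RealignmentCandidate(
        exon=ExonInterval("chr1", 6, 16, "+", "coding"),
        target_genome="g2",
        left_anchor=None,
        right_anchor=None,
        target_contig="chr1",
        u_start=0,
        u_end=len(target) - 1,
        strand=-1,
    )
    patch = realign_exon(cand, gs)
    assert patch.r_prime == 1.0
    # mapping decreases in target coordinates on the minus strand
    assert np.all(np.diff(patch.target_positions) < 0)
    # first exon base maps to the last base of the reverse-complement image
    assert patch.target_positions[0] == 4 + len(exon_seq) - 1


# ---------------------------------------------------------------------------
# acceptance filter


def test_accept_threshold_hand_computed():
    scores = RealignmentScores("g2", np.array([1.0, 0.8, 0.6]))
    assert scores.mu == pytest.approx(0.8)
    assert scores.sigma == pytest.approx(0.16329931, abs=1e-6)
    patch = AlignmentPatch(
        exon=ExonInterval("chr1", 0, 10, "+", "coding"),
        target_genome="g2",
        target_contig="chr1",
        strand=1,
        ref_positions=np.arange(7),
        target_positions=np.arange(7),
        r_prime=0.7,
    )
    assert accept_patch(patch, scores).accepted  # 0.7 > 0.6367


def test_accept_is_strict_at_boundary():
    scores = RealignmentScores("g2", np.array([0.9, 0.9]))  # mu=0.9, sigma=0
    patch = AlignmentPatch(
        exon=ExonInterval("chr1", 0, 10, "+", "coding"),
        target_genome="g2",
        target_contig="chr1",
        strand=1,
        ref_positions=np.arange(9),
        target_positions=np.arange(9),
        r_prime=0.9,
    )
    assert not accept_patch(patch, scores).accepted
    patch.r_prime = 1.0
    assert accept_patch(patch, scores).accepted


def test_empty_score_set_rejects():
    patch = AlignmentPatch(
        exon=ExonInterval("chr1", 0, 10, "+", "coding"),
        target_genome="g2",
        target_contig="chr1",
        strand=1,
        ref_positions=np.arange(10),
        target_positions=np.arange(10),
        r_prime=1.0,
    )
    assert not accept_patch(patch, RealignmentScores("g2", np.array([]))).accepted


# ---------------------------------------------------------------------------
# merging


def test_merge_identity_without_patches(fig1, fig1_map):
    merged = merge_alignments(fig1_map, [])
    for pos in range(0, 260):
        assert merged.w("chr1", pos, "g2") == fig1_map.w("chr1", pos, "g2")


def test_merge_is_conservative_and_counts_recovery(small_study, small_map):
    """w' equals w at every originally aligned position; patches only fill
    gaps; patched positions stay inside their segment."""
    genomes = small_study.genomes
    exons = unique_exons([small_study.mane, small_study.extra])
    res = realign_missing_exons(exons, small_map, genomes)
    contig = "chr1"
    n = small_map.ref_lengths[contig]
    for target in small_map.targets:
        orig = small_map.tpos_slice(target, contig, 0, n)
        new = res.merged.tpos_slice(target, contig, 0, n)
        was_aligned = orig != -1
        assert np.array_equal(orig[was_aligned], new[was_aligned])
    for p in res.patches:
        if p.accepted and len(p.target_positions):
            assert np.all(np.diff(p.ref_positions) > 0)


def test_overlapping_patches_higher_r_prime_wins():
    import splicecons.alignment as al

    amap = al.AlignmentMap("hg")
    amap.ref_lengths["chr1"] = 100
    common = dict(
        target_genome="g2", target_contig="c1", strand=1
    )
    lo = AlignmentPatch(
        exon=ExonInterval("chr1", 10, 20, "+", "coding"),
        ref_positions=np.arange(10, 18),
        target_positions=np.arange(50, 58),
        r_prime=0.8,
        accepted=True,
        **common,
    )
    hi = AlignmentPatch(
        exon=ExonInterval("chr1", 12, 22, "+", "coding"),
        ref_positions=np.arange(12, 22),
        target_positions=np.arange(70, 80),
        r_prime=1.0,
        accepted=True,
        **common,
    )
    merged = merge_alignments(amap, [lo, hi])
    assert merged.w("chr1", 15, "g2") == 73  # from the higher-r' patch
    assert merged.w("chr1", 10, "g2") == 50  # non-overlapping part kept
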