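"""Synteny-anchored recovery of missing exon alignments.

An exon that is unaligned in a target genome but whose flanking exons are both
aligned to the same target contig ("syntenic") is realigned with a semi-global
edit-distance alignment (edlib, exon global / segment infix) into the target
segment u spanned between the images of its anchors.  A realignment is
accepted when its coverage score r'(e) exceeds mu(R_t) - sigma(R_t), where R_t
holds the coverage scores r(e) of the originally aligned exons of the same
target genome (strict inequality; sigma is the population standard
deviation).  Accepted patches are merged into the original map to give w',
which never overrides an originally aligned position.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import edlib
import numpy as np

from .alignment import AlignmentMap, aligned_positions
from .catalogs import ExonInterval
from .genomes import GenomeSet, revcomp

log = logging.getLogger(__name__)

#: target segments longer than this are not realigned
MAX_SEGMENT = 100_000

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass
class RealignmentCandidate:
    """An unaligned-but-syntenic exon with its inter-anchor target segment.

    ``u_start``/``u_end`` are inclusive forward-strand target coordinates of
    the segment u; ``strand`` is the shared strand of the anchor images.
    """

    exon: ExonInterval
    target_genome: str
    left_anchor: ExonInterval
    right_anchor: ExonInterval
    target_contig: str
    u_start: int
    u_end: int
    strand: int = 1


@dataclass
class RealignmentScores:
    """Coverage scores r(e) of originally aligned exons in one target."""

    target_genome: str
    scores: np.ndarray

    @property
    def mu(self) -> float:
        return float(np.mean(self.scores)) if len(self.scores) else float("nan")

    @property
    def sigma(self) -> float:
        # population standard deviation (ddof=0), fixed for determinism
        return float(np.std(self.scores)) if len(self.scores) else float("nan")


@dataclass
class AlignmentPatch:
    """The per-exon alignment function w_e produced by realignment."""

    exon: ExonInterval
    target_genome: str
    target_contig: str
    strand: int
    ref_positions: np.ndarray
    target_positions: np.ndarray
    r_prime: float
    edit_distance: int = -1
    accepted: bool = False

    @property
    def n_mapped(self) -> int:
        return len(self.ref_positions)


# ---------------------------------------------------------------------------


def compute_scores(
    exons: Sequence[ExonInterval], target: str, amap: AlignmentMap
) -> RealignmentScores:
    """R_t: r(e) = (aligned positions of e) / len(e) over aligned exons."""
    scores = []
    for e in exons:
        tpos = amap.tpos_slice(target, e.contig, e.start, e.end)
        n = int(np.count_nonzero(tpos != -1))
        if n > 0:
            scores.append(n / len(e))
    return RealignmentScores(target_genome=target, scores=np.asarray(scores))


def find_candidates(
    exons: Sequence[ExonInterval],
    target: str,
    amap: AlignmentMap,
    max_segment: int = MAX_SEGMENT,
) -> tuple[list[RealignmentCandidate], Counter]:
    """One candidate per unaligned exon flanked by aligned exons whose images
    lie on one target contig and strand.  Returns (candidates, reject counts).

    Anchors are the nearest aligned exons on each side, per reference contig
    over the deduplicated, sorted exon set.
    """
    rejected: Counter = Counter()
    candidates: list[RealignmentCandidate] = []

    by_contig: Dict[str, list[ExonInterval]] = {}
    for e in sorted(exons, key=lambda e: (e.contig, e.start, e.end)):
        by_contig.setdefault(e.contig, []).append(e)

    for contig, contig_exons in by_contig.items():
        aligned = np.array(
            [
                bool(
                    (amap.tpos_slice(target, contig, e.start, e.end) != -1).any()
                )
                for e in contig_exons
            ]
        )
        n = len(contig_exons)
        for i, e in enumerate(contig_exons):
            if aligned[i]:
                continue
            # nearest aligned exons strictly flanking e (disjoint on the
            # reference); overlapping exon variants are skipped over
            li = i - 1
            while li >= 0 and not (
                aligned[li] and contig_exons[li].end <= e.start
            ):
                li -= 1
            ri = i + 1
            while ri < n and not (
                aligned[ri] and contig_exons[ri].start >= e.end
            ):
                ri += 1
            if li < 0 or ri >= n:
                rejected["no_flanking_anchor"] += 1
                continue
            ea, eb = contig_exons[li], contig_exons[ri]
            info_a = _anchor_image(ea, target, amap)
            info_b = _anchor_image(eb, target, amap)
            if info_a is None or info_b is None:
                rejected["anchor_multi_contig_or_strand"] += 1
                continue
            (ca, lo_a, hi_a, st_a) = info_a
            (cb, lo_b, hi_b, st_b) = info_b
            if ca != cb:
                rejected["anchors_different_contigs"] += 1
                continue
            if st_a != st_b:
                rejected["anchors_mixed_strand"] += 1
                continue
            if st_a == 1:
                u_start, u_end = hi_a + 1, lo_b - 1
            else:
                u_start, u_end = hi_b + 1, lo_a - 1
            if u_start > u_end:
                rejected["inverted_or_empty_segment"] += 1
                continue
            if u_end - u_start + 1 > max_segment:
                rejected["segment_too_long"] += 1
                continue
            candidates.append(
                RealignmentCandidate(
                    exon=e,
                    target_genome=target,
                    left_anchor=ea,
                    right_anchor=eb,
                    target_contig=ca,
                    u_start=u_start,
                    u_end=u_end,
                    strand=st_a,
                )
            )
    return candidates, rejected


def _anchor_image(
    e: ExonInterval, target: str, amap: AlignmentMap
) -> Optional[tuple[str, int, int, int]]:
    """(contig, min(A), max(A), strand) of an anchor exon's image, or None
    when its aligned positions straddle contigs or strands."""
    arrs = amap.arrays(target, e.contig)
    if arrs is None:
        return None
    sl = slice(e.start, e.end)
    tpos = arrs["tpos"][sl]
    mask = tpos != -1
    if not mask.any():
        return None
    contigs = np.unique(arrs["tcontig"][sl][mask])
    strands = np.unique(arrs["tstrand"][sl][mask])
    if len(contigs) != 1 or len(strands) != 1:
        return None
    positions = tpos[mask]
    return (
        amap.contig_name(target, int(contigs[0])),
        int(positions.min()),
        int(positions.max()),
        int(strands[0]),
    )


def realign_exon(
    cand: RealignmentCandidate, genomes: GenomeSet
) -> AlignmentPatch:
    """Semi-global (exon global, segment infix) edit-distance alignment of
    the exon into the target segment; match/mismatch columns map positions,
    indel columns map nothing.  edlib reports the leftmost co-optimal
    placement, which fixes the tie-break deterministically."""
    e = cand.exon
    exon_seq = genomes.seq(genomes.reference_id, e.contig, e.start, e.end)
    segment = genomes.seq(
        cand.target_genome, cand.target_contig, cand.u_start, cand.u_end + 1
    )
    if cand.strand == -1:
        segment = revcomp(segment)
    if not segment:
        return AlignmentPatch(
            exon=e,
            target_genome=cand.target_genome,
            target_contig=cand.target_contig,
            strand=cand.strand,
            ref_positions=np.empty(0, dtype=np.int64),
            target_positions=np.empty(0, dtype=np.int64),
            r_prime=0.0,
        )
    res = edlib.align(exon_seq, segment, mode="HW", task="path")
    seg_start = res["locations"][0][0]
    qpos, tpos = 0, seg_start
    ref_hits: list[int] = []
    seg_hits: list[int] = []
    for count, op in _CIGAR_RE.findall(res["cigar"]):
        count = int(count)
        if op in "=XM":
            ref_hits.extend(range(qpos, qpos + count))
            seg_hits.extend(range(tpos, tpos + count))
            qpos += count
            tpos += count
        elif op == "I":  # exon base absent from segment
            qpos += count
        else:  # "D": segment base absent from exon
            tpos += count
    ref_positions = e.start + np.asarray(ref_hits, dtype=np.int64)
    seg_arr = np.asarray(seg_hits, dtype=np.int64)
    if cand.strand == 1:
        target_positions = cand.u_start + seg_arr
    else:
        target_positions = cand.u_end - seg_arr
    return AlignmentPatch(
        exon=e,
        target_genome=cand.target_genome,
        target_contig=cand.target_contig,
        strand=cand.strand,
        ref_positions=ref_positions,
        target_positions=target_positions,
        r_prime=len(ref_positions) / len(e),
        edit_distance=res["editDistance"],
    )


def accept_patch(
    patch: AlignmentPatch, scores: RealignmentScores
) -> AlignmentPatch:
    """Accept iff r'(e) > mu(R_t) - sigma(R_t), strictly."""
    if len(scores.scores) == 0:
        log.warning(
            "no aligned exons in %s; patch rejected", patch.target_genome
        )
        patch.accepted = False
        return patch
    patch.accepted = bool(patch.r_prime > scores.mu - scores.sigma)
    return patch


def merge_alignments(
    amap: AlignmentMap, patches: Sequence[AlignmentPatch]
) -> AlignmentMap:
    """w': the original map with accepted patch mappings filled in wherever
    w = -1.  The original always wins; among overlapping patches the one with
    the higher r' wins."""
    merged = amap.copy(source="merged")
    ordered = sorted(
        (p for p in patches if p.accepted), key=lambda p: -p.r_prime
    )
    for p in ordered:
        merged.add_mappings(
            p.target_genome,
            p.exon.contig,
            p.ref_positions,
            p.target_contig,
            p.target_positions,
            p.strand,
        )
    return merged


@dataclass
class RealignmentResult:
    merged: AlignmentMap
    patches: list[AlignmentPatch]
    scores: Dict[str, RealignmentScores]
    rejected: Counter = field(default_factory=Counter)


def realign_missing_exons(
    exons: Sequence[ExonInterval],
    amap: AlignmentMap,
    genomes: GenomeSet,
    max_segment: int = MAX_SEGMENT,
) -> RealignmentResult:
    """Full realignment pass over every target genome: score, find syntenic
    candidates, realign, filter, merge."""
    patches: list[AlignmentPatch] = []
    scores: Dict[str, RealignmentScores] = {}
    rejected: Counter = Counter()
    for target in amap.targets:
        sc = compute_scores(exons, target, amap)
        scores[target] = sc
        cands, rej = find_candidates(exons, target, amap, max_segment)
        rejected.update(rej)
        for cand in cands:
            patch = realign_exon(cand, genomes)
            accept_patch(patch, sc)
            patches.append(patch)
    merged = merge_alignments(amap, patches)
    return RealignmentResult(
        merged=merged, patches=patches, scores=scores, rejected=rejected
    )
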