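"""The "Random" negative dataset: synthetic two-exon transcripts placed
inside MANE-like introns, away from real splicing motifs.

Each generated transcript contributes exactly one donor and one acceptor
site.  Donor origins are placed on reference GT dinucleotides and acceptor
origins on AG (neutrally evolving canonical-motif positions), at least
``motif_margin`` bases away from every annotated splice-site origin, with the
whole transcript contained in a single host intron.  Placement is rejection
sampling over candidate motif positions (which weights host introns by their
motif content, i.e. roughly by length); the generator is deterministic per
seed.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np

from .catalogs import Catalog, ExonInterval, TranscriptRecord
from .genomes import GenomeSet

log = logging.getLogger(__name__)

DEFAULT_N = 180_000
MOTIF_MARGIN = 31
EXON_LEN = (50, 150)
INTRON_LEN = (200, 2000)


def _allowed_origin_mask(
    length: int, annotated_origins: np.ndarray, margin: int
) -> np.ndarray:
    """False within ``margin`` bases of any annotated site origin."""
    allowed = np.ones(length, dtype=bool)
    for o in annotated_origins:
        allowed[max(0, o - margin) : min(length, o + margin + 1)] = False
    return allowed


def _dinucleotide_positions(seq: np.ndarray, first: int, second: int) -> np.ndarray:
    return np.flatnonzero((seq[:-1] == first) & (seq[1:] == second))


def generate_random_transcripts(
    mane: Catalog,
    reference: GenomeSet,
    n: int = DEFAULT_N,
    seed: int = 0,
    exon_len: tuple[int, int] = EXON_LEN,
    intron_len: tuple[int, int] = INTRON_LEN,
    motif_margin: int = MOTIF_MARGIN,
    exclude_catalogs: Sequence[Catalog] = (),
    require_motif: bool = True,
) -> Catalog:
    """Generate ``n`` two-exon transcripts inside MANE introns.

    ``exclude_catalogs`` adds further catalogs whose annotated site origins
    must be avoided (the margin applies to the union of all catalogs).  With
    ``require_motif=False`` placements ignore the underlying sequence and the
    generated sites are not guaranteed canonical.

    Raises ``RuntimeError`` when the constraint space is exhausted before
    ``n`` placements, reporting the achieved count.
    """
    rng = np.random.default_rng(seed)
    emin, emax = exon_len
    imin, imax = intron_len
    if emin < 1 or imin < 4 or emin > emax or imin > imax:
        raise ValueError("infeasible exon/intron length ranges")

    catalogs = [mane, *exclude_catalogs]
    origins: dict[str, list[int]] = {}
    for cat in catalogs:
        for site in cat.site_index.values():
            origins.setdefault(site.contig, []).append(site.origin)

    # per-contig candidate tables
    per_contig = []
    for contig, seq_str in reference.reference.items():
        introns: dict[tuple[int, int], None] = {}
        for tr in mane.transcripts.values():
            if tr.contig != contig:
                continue
            for s, e in tr.introns():
                introns.setdefault((s, e), None)
        if not introns:
            continue
        istart, iend = map(
            np.asarray, zip(*sorted(introns))
        )
        seq = reference.contig_bytes(reference.reference_id, contig)
        allowed = _allowed_origin_mask(
            len(seq), np.asarray(origins.get(contig, []), dtype=int), motif_margin
        )
        if require_motif:
            gt = _dinucleotide_positions(seq, ord("G"), ord("T"))
            ag = _dinucleotide_positions(seq, ord("A"), ord("G"))
        else:
            gt = ag = np.arange(len(seq) - 1)
        gt = gt[allowed[gt]]
        ag = ag[allowed[ag]]

        # donor candidates: inside an intron with room for the upstream exon
        idx = np.searchsorted(istart, gt, side="right") - 1
        ok = idx >= 0
        ok &= gt - istart[np.clip(idx, 0, None)] >= emin
        ok &= gt + imin + emin <= iend[np.clip(idx, 0, None)]
        gt, gt_intron = gt[ok], idx[ok]

        aidx = np.searchsorted(istart, ag, side="right") - 1
        aok = (aidx >= 0) & (ag + 2 + emin <= iend[np.clip(aidx, 0, None)])
        ag = ag[aok]
        if len(gt) == 0 or len(ag) == 0:
            continue
        per_contig.append(
            {
                "contig": contig,
                "istart": istart,
                "iend": iend,
                "gt": gt,
                "gt_intron": gt_intron,
                "ag": ag,
            }
        )
    if not per_contig:
        raise RuntimeError(
            "no feasible placement positions (achieved 0 of "
            f"{n}); limiting constraint: candidate motif positions"
        )

    capacities = np.array([len(c["gt"]) for c in per_contig], dtype=float)
    quota = np.floor(capacities / capacities.sum() * n).astype(int)
    # largest-remainder top-up
    for i in np.argsort(-(capacities / capacities.sum() * n - quota)):
        if quota.sum() >= n:
            break
        quota[i] += 1

    transcripts: dict[str, TranscriptRecord] = {}
    counter = 0
    for c, n_c in zip(per_contig, quota):
        if n_c == 0:
            continue
        placements = _sample_contig(c, int(n_c), rng, emin, emax, imin, imax, n)
        for p, q, l1, l2 in placements:
            counter += 1
            tid = f"RAND{counter:07d}"
            exons = [
                ExonInterval(c["contig"], int(p - l1), int(p), "+", "random"),
                ExonInterval(c["contig"], int(q + 2), int(q + 2 + l2), "+", "random"),
            ]
            transcripts[tid] = TranscriptRecord(
                transcript_id=tid,
                gene_id=tid,
                gene_type="random",
                contig=c["contig"],
                strand="+",
                exons=exons,
            )
    catalog = Catalog(name="Random", transcripts=transcripts)
    catalog.build_site_index(reference)
    return catalog


def _sample_contig(
    c: dict,
    n_c: int,
    rng: np.random.Generator,
    emin: int,
    emax: int,
    imin: int,
    imax: int,
    n_total: int,
) -> list[tuple[int, int, int, int]]:
    """Rejection-sample ``n_c`` placements (p=donor origin, q=acceptor
    origin, exon lengths) on one contig."""
    gt, gt_intron = c["gt"], c["gt_intron"]
    ag = c["ag"]
    istart, iend = c["istart"], c["iend"]
    used_donor: set[int] = set()
    used_acceptor: set[int] = set()
    out: list[tuple[int, int, int, int]] = []
    stale_rounds = 0
    while len(out) < n_c:
        batch = max(1024, int((n_c - len(out)) * 1.5))
        pick = rng.integers(0, len(gt), size=batch)
        p = gt[pick]
        it = gt_intron[pick]
        lo = np.searchsorted(ag, p + imin - 2, side="left")
        hi_bound = np.minimum(p + imax - 2, iend[it] - 2 - emin)
        hi = np.searchsorted(ag, hi_bound, side="right")
        count = hi - lo
        ok = count > 0
        if not ok.any():
            stale_rounds += 1
            if stale_rounds > 50:
                break
            continue
        p, it, lo, count = p[ok], it[ok], lo[ok], count[ok]
        j = lo + (rng.random(len(p)) * count).astype(np.int64)
        q = ag[j]
        room1 = np.minimum(p - istart[it], emax)
        room2 = np.minimum(iend[it] - (q + 2), emax)
        l1 = emin + (rng.random(len(p)) * (room1 - emin + 1)).astype(np.int64)
        l2 = emin + (rng.random(len(p)) * (room2 - emin + 1)).astype(np.int64)
        progressed = False
        for pi, qi, a, b in zip(p, q, l1, l2):
            if len(out) >= n_c:
                break
            if pi in used_donor or qi in used_acceptor:
                continue
            used_donor.add(int(pi))
            used_acceptor.add(int(qi))
            out.append((int(pi), int(qi), int(a), int(b)))
            progressed = True
        stale_rounds = 0 if progressed else stale_rounds + 1
        if stale_rounds > 50:
            break
    if len(out) < n_c:
        raise RuntimeError(
            f"constraint space exhausted on {c['contig']}: achieved "
            f"{len(out)} of {n_c} placements (of {n_total} requested); "
            "limiting constraint: distinct unoccupied GT/AG origins"
        )
    return out
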