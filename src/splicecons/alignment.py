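"""Materialising the alignment function w(k, g_t) from a MAF file.

For each target genome the map stores, per reference contig, a dense array of
target coordinates (-1 where unaligned) plus the target contig and strand.
MAF blocks are parsed with ``Bio.AlignIO`` and expanded column-wise; target
coordinates on minus-strand rows are converted to forward-strand coordinates
(``srcSize - (start + offset) - 1``).

Duplicate coverage of the same reference position by overlapping blocks is
resolved first-block-wins; conflicting duplicates are counted in
``AlignmentMap.conflicts``.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO

from .catalogs import ExonInterval

log = logging.getLogger(__name__)


class AlignmentMap:
    """w(k, g_t): reference position -> target (contig, position, strand).

    Positions absent from the map have w = -1 (unaligned).
    """

    def __init__(self, reference_id: str, source: str = "original") -> None:
        self.reference_id = reference_id
        self.source = source
        self.ref_lengths: Dict[str, int] = {}
        # (target, ref_contig) -> {tpos, tcontig, tstrand} arrays
        self._arrays: Dict[tuple, dict] = {}
        # per target: contig-name interning table
        self._contig_names: Dict[str, list] = {}
        self.conflicts = 0

    # -- construction -----------------------------------------------------

    def _contig_index(self, target: str, contig: str) -> int:
        names = self._contig_names.setdefault(target, [])
        try:
            return names.index(contig)
        except ValueError:
            names.append(contig)
            return len(names) - 1

    def _ensure(self, target: str, ref_contig: str) -> dict:
        key = (target, ref_contig)
        arrs = self._arrays.get(key)
        if arrs is None:
            n = self.ref_lengths[ref_contig]
            arrs = {
                "tpos": np.full(n, -1, dtype=np.int64),
                "tcontig": np.full(n, -1, dtype=np.int32),
                "tstrand": np.zeros(n, dtype=np.int8),
            }
            self._arrays[key] = arrs
        return arrs

    def add_mappings(
        self,
        target: str,
        ref_contig: str,
        ref_positions: np.ndarray,
        target_contig: str,
        target_positions: np.ndarray,
        target_strand: int,
        first_wins: bool = True,
    ) -> None:
        """Bulk-insert column mappings; earlier entries win on overlap."""
        arrs = self._ensure(target, ref_contig)
        tpos = arrs["tpos"]
        existing = tpos[ref_positions]
        fresh = existing == -1
        self.conflicts += int(
            np.count_nonzero(~fresh & (existing != target_positions))
        )
        if not first_wins:
            fresh = np.ones_like(fresh)
        idx = ref_positions[fresh]
        tpos[idx] = target_positions[fresh]
        arrs["tcontig"][idx] = self._contig_index(target, target_contig)
        arrs["tstrand"][idx] = target_strand

    # -- queries -----------------------------------------------------------

    @property
    def targets(self) -> list[str]:
        return sorted({t for t, _ in self._arrays} | set(self._contig_names))

    def has_contig(self, ref_contig: str) -> bool:
        return ref_contig in self.ref_lengths

    def w(self, ref_contig: str, pos: int, target: str) -> int:
        """Target coordinate of a reference position, or -1."""
        arrs = self._arrays.get((target, ref_contig))
        if arrs is None or not (0 <= pos < len(arrs["tpos"])):
            return -1
        return int(arrs["tpos"][pos])

    def lookup(
        self, ref_contig: str, pos: int, target: str
    ) -> Optional[tuple[str, int, int]]:
        """(target_contig, target_position, strand) or None if unaligned."""
        arrs = self._arrays.get((target, ref_contig))
        if arrs is None or not (0 <= pos < len(arrs["tpos"])):
            return None
        tp = int(arrs["tpos"][pos])
        if tp == -1:
            return None
        ci = int(arrs["tcontig"][pos])
        return (
            self._contig_names[target][ci],
            tp,
            int(arrs["tstrand"][pos]),
        )

    def tpos_slice(
        self, target: str, ref_contig: str, start: int, end: int
    ) -> np.ndarray:
        """Dense w(k) over [start, end); -1 where unaligned/uncovered."""
        arrs = self._arrays.get((target, ref_contig))
        if arrs is None:
            return np.full(end - start, -1, dtype=np.int64)
        return arrs["tpos"][start:end]

    def arrays(self, target: str, ref_contig: str) -> Optional[dict]:
        return self._arrays.get((target, ref_contig))

    def contig_name(self, target: str, index: int) -> str:
        return self._contig_names[target][index]

    def copy(self, source: str = "merged") -> "AlignmentMap":
        out = AlignmentMap(self.reference_id, source=source)
        out.ref_lengths = dict(self.ref_lengths)
        out._contig_names = {t: list(v) for t, v in self._contig_names.items()}
        out._arrays = {
            k: {n: a.copy() for n, a in v.items()} for k, v in self._arrays.items()
        }
        return out


def _split_src(src: str) -> tuple[str, str]:
    """MAF 'src' fields are 'genome.contig'."""
    genome, _, contig = src.partition(".")
    return genome, contig or src


def read_maf(
    maf_path: str | os.PathLike,
    reference_id: str,
    genome_subset: Optional[Iterable[str]] = None,
) -> AlignmentMap:
    """Build an :class:`AlignmentMap` from a MAF file.

    Only columns where both the reference and the target carry a non-gap base
    produce an entry.  Blocks without a reference row are skipped with a
    warning; ``genome_subset`` restricts the targets that are retained.
    """
    subset = set(genome_subset) if genome_subset is not None else None
    amap = AlignmentMap(reference_id)
    source = maf_path if hasattr(maf_path, "read") else str(maf_path)
    for block in AlignIO.parse(source, "maf"):
        ref_rec = None
        for rec in block:
            genome, _ = _split_src(rec.id)
            if genome == reference_id:
                ref_rec = rec
                break
        if ref_rec is None:
            log.warning("MAF block without reference row skipped")
            continue
        if ref_rec.annotations["strand"] != 1:
            log.warning("MAF block with minus-strand reference row skipped")
            continue
        _, ref_contig = _split_src(ref_rec.id)
        amap.ref_lengths.setdefault(ref_contig, ref_rec.annotations["srcSize"])

        ref_arr = np.frombuffer(str(ref_rec.seq).encode("ascii"), dtype=np.uint8)
        ref_nongap = ref_arr != ord("-")
        ref_pos = ref_rec.annotations["start"] + np.cumsum(ref_nongap) - 1

        for rec in block:
            genome, tcontig = _split_src(rec.id)
            if genome == reference_id:
                continue
            if subset is not None and genome not in subset:
                continue
            t_arr = np.frombuffer(str(rec.seq).encode("ascii"), dtype=np.uint8)
            t_nongap = t_arr != ord("-")
            offset = np.cumsum(t_nongap) - 1
            t_start = rec.annotations["start"]
            strand = rec.annotations["strand"]
            if strand == 1:
                t_pos = t_start + offset
            else:
                t_pos = rec.annotations["srcSize"] - (t_start + offset) - 1
            mask = ref_nongap & t_nongap
            amap.add_mappings(
                genome,
                ref_contig,
                ref_pos[mask],
                tcontig,
                t_pos[mask],
                int(strand),
            )
    return amap


# ---------------------------------------------------------------------------
# exon alignment status


def aligned_positions(
    e: ExonInterval, target: str, amap: AlignmentMap
) -> np.ndarray:
    """A(e): sorted array of target positions of e's aligned positions.

    Empty iff the exon is unaligned in the target genome.
    """
    tpos = amap.tpos_slice(target, e.contig, e.start, e.end)
    return np.sort(tpos[tpos != -1])


def exon_aligned(e: ExonInterval, target: str, amap: AlignmentMap) -> bool:
    """W(e, g_t): at least one exon position is aligned."""
    tpos = amap.tpos_slice(target, e.contig, e.start, e.end)
    return bool((tpos != -1).any())


@dataclass
class CompletenessSummary:
    """s_a / s_m / s_r per (chromosome, gene_type) stratum."""

    counts: Dict[tuple, Dict[str, int]] = field(default_factory=dict)
    n_targets: int = 0

    def _stratum(self, key: tuple) -> Dict[str, int]:
        return self.counts.setdefault(
            key, {"aligned": 0, "missing": 0, "recovered": 0}
        )

    def totals(self) -> Dict[str, int]:
        out = {"aligned": 0, "missing": 0, "recovered": 0}
        for c in self.counts.values():
            for k in out:
                out[k] += c[k]
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "contig": contig,
                "gene_type": gt,
                "aligned": c["aligned"],
                "missing": c["missing"],
                "recovered": c["recovered"],
            }
            for (contig, gt), c in sorted(self.counts.items())
        ]
        return pd.DataFrame(
            rows, columns=["contig", "gene_type", "aligned", "missing", "recovered"]
        )


def completeness_summary(
    exons: Sequence[ExonInterval],
    amap: AlignmentMap,
    merged: Optional[AlignmentMap] = None,
) -> CompletenessSummary:
    """Count aligned / missing (and, given the merged map, recovered)
    exon/genome pairs per (contig, gene_type) stratum.

    ``exons`` must be the deduplicated exon set.  W(e, g_t) = 1 when at least
    one exon position is aligned; W_r counts pairs missing in the original map
    but aligned under the merged one.
    """
    targets = amap.targets
    summary = CompletenessSummary(n_targets=len(targets))
    if not exons:
        return summary

    starts = np.array([e.start for e in exons])
    ends = np.array([e.end for e in exons])
    contigs = np.array([e.contig for e in exons])
    keys = [(e.contig, e.gene_type) for e in exons]

    for target in targets:
        for contig in np.unique(contigs):
            sel = np.flatnonzero(contigs == contig)
            n_ref = amap.ref_lengths.get(contig)

            def any_aligned(m: AlignmentMap) -> np.ndarray:
                arrs = m.arrays(target, contig)
                if arrs is None or n_ref is None:
                    return np.zeros(len(sel), dtype=bool)
                prefix = np.concatenate(
                    ([0], np.cumsum(arrs["tpos"] != -1))
                )
                return (prefix[ends[sel]] - prefix[starts[sel]]) > 0

            w = any_aligned(amap)
            wr = any_aligned(merged) if merged is not None else None
            for j, i in enumerate(sel):
                c = summary._stratum(keys[i])
                if w[j]:
                    c["aligned"] += 1
                else:
                    c["missing"] += 1
                    if wr is not None and wr[j]:
                        c["recovered"] += 1
    return summary
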