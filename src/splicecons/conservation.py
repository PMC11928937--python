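"""The conservation function C and per-site feature vectors.

``C(s, l, t)`` indicates whether the reference base at shift ``l`` from the
origin of splice site ``s`` (moving 5'->3' along the transcript) equals its
aligned base in target genome ``t``.  Unaligned positions (w = -1) and N
bases never match.  Comparisons are done against the base in alignment
orientation: when the reference maps to the target minus strand, the target
base is complemented first, so the indicator equals column identity in the
alignment and is invariant under the strand convention of the site.

A site's feature vector consists of the joint dinucleotide conservation count
(both canonical bases intact in the same genome) plus one positional count
per shift in [-30, 31] excluding {0, 1} -- 60 positional features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .alignment import AlignmentMap
from .catalogs import SpliceSite
from .genomes import GenomeSet

log = logging.getLogger(__name__)

#: feature window: 30 exonic-side and 30 intronic-side shifts around the
#: dinucleotide (shifts 0 and 1 are the dinucleotide itself)
SHIFTS: tuple[int, ...] = tuple(range(-30, 0)) + tuple(range(2, 32))
#: all shifts tracked internally, dinucleotide positions included
ALL_SHIFTS: tuple[int, ...] = tuple(range(-30, 32))
WINDOW = (-30, 31)

_COMP_LUT = np.arange(256, dtype=np.uint8)
for a, b in zip(b"ACGTacgt", b"TGCAtgca"):
    _COMP_LUT[a] = b
_UPPER_LUT = np.arange(256, dtype=np.uint8)
for a, b in zip(b"acgtn", b"ACGTN"):
    _UPPER_LUT[a] = b


@dataclass
class ConservationProfile:
    """Feature vector of one splice site.

    ``positional_counts`` covers every shift in [-30, 31]; the entries at
    shifts 0 and 1 are the per-position dinucleotide counts (kept for the
    descriptive summaries) and are excluded from the model feature vector,
    which uses the joint count instead.
    """

    site: SpliceSite
    joint_count: int
    positional_counts: Dict[int, int]
    m_effective: int

    def vector(self) -> np.ndarray:
        """[joint_count, counts at SHIFTS...] in fixed shift order."""
        return np.array(
            [self.joint_count] + [self.positional_counts[l] for l in SHIFTS],
            dtype=np.float64,
        )


def conservation(
    site: SpliceSite,
    shift: int,
    target: str,
    amap: AlignmentMap,
    genomes: GenomeSet,
) -> int:
    """C(s, l, t) for a single site/shift/genome, by direct lookup."""
    sign = 1 if site.strand == "+" else -1
    pos = site.origin + sign * shift
    ref_seq = genomes.reference[site.contig]
    if not (0 <= pos < len(ref_seq)):
        log.warning("shift %d walks off contig %s at site %s", shift, site.contig, site.identity)
        return 0
    hit = amap.lookup(site.contig, pos, target)
    if hit is None:
        return 0
    tcontig, tpos, tstrand = hit
    ref_base = ref_seq[pos].upper()
    t_base = genomes.base(target, tcontig, tpos).upper()
    if tstrand == -1:
        t_base = {"A": "T", "C": "G", "G": "C", "T": "A"}.get(t_base, "N")
    if ref_base == "N" or t_base == "N":
        return 0
    return int(ref_base == t_base)


class ConservationIndex:
    """Vectorised per-position conservation over all targets of a map.

    For each reference contig, lazily builds a (n_targets x contig_length)
    0/1 matrix whose entry is C at that position, enabling bulk feature
    extraction for many sites.
    """

    def __init__(
        self,
        amap: AlignmentMap,
        genomes: GenomeSet,
        targets: Optional[Sequence[str]] = None,
    ) -> None:
        self.amap = amap
        self.genomes = genomes
        self.targets = list(targets) if targets is not None else amap.targets
        self._match: Dict[str, np.ndarray] = {}

    @property
    def m_effective(self) -> int:
        return len(self.targets)

    def match_matrix(self, contig: str) -> np.ndarray:
        mat = self._match.get(contig)
        if mat is None:
            mat = self._build(contig)
            self._match[contig] = mat
        return mat

    def _build(self, contig: str) -> np.ndarray:
        ref = _UPPER_LUT[self.genomes.contig_bytes(self.genomes.reference_id, contig)]
        n = len(ref)
        mat = np.zeros((len(self.targets), n), dtype=np.uint8)
        valid_ref = ref != ord("N")
        for ti, target in enumerate(self.targets):
            arrs = self.amap.arrays(target, contig)
            if arrs is None:
                continue
            tpos = arrs["tpos"]
            aligned = tpos != -1
            if not aligned.any():
                continue
            for ci in np.unique(arrs["tcontig"][aligned]):
                sel = aligned & (arrs["tcontig"] == ci)
                tseq = _UPPER_LUT[
                    self.genomes.contig_bytes(
                        target, self.amap.contig_name(target, int(ci))
                    )
                ]
                gathered = tseq[tpos[sel]]
                minus = arrs["tstrand"][sel] == -1
                if minus.any():
                    gathered = np.where(
                        minus, _COMP_LUT[gathered], gathered
                    )
                ok = (
                    (gathered == ref[sel])
                    & (gathered != ord("N"))
                    & valid_ref[sel]
                )
                mat[ti, sel] = ok.astype(np.uint8)
        return mat


def site_features(
    site: SpliceSite,
    amap: AlignmentMap,
    genomes: GenomeSet,
    index: Optional[ConservationIndex] = None,
) -> ConservationProfile:
    """Feature vector of one site; see :func:`profiles_for_sites` for bulk."""
    if index is None:
        index = ConservationIndex(amap, genomes)
    return profiles_for_sites([site], amap, genomes, index)[0]


def profiles_for_sites(
    sites: Sequence[SpliceSite],
    amap: AlignmentMap,
    genomes: GenomeSet,
    index: Optional[ConservationIndex] = None,
) -> list[ConservationProfile]:
    """Bulk feature extraction via the vectorised conservation index.

    Positions that fall outside the contig contribute 0, as do sites on
    contigs absent from the alignment (all-zero profile, logged).
    """
    if index is None:
        index = ConservationIndex(amap, genomes)
    out: list[ConservationProfile] = []
    shifts_arr = np.array(ALL_SHIFTS)
    for contig in sorted({s.contig for s in sites}):
        contig_sites = [s for s in sites if s.contig == contig]
        if not amap.has_contig(contig):
            log.warning("contig %s absent from alignment; zero profiles", contig)
            for s in contig_sites:
                out.append(
                    ConservationProfile(
                        site=s,
                        joint_count=0,
                        positional_counts={l: 0 for l in ALL_SHIFTS},
                        m_effective=index.m_effective,
                    )
                )
            continue
        mat = index.match_matrix(contig)
        n = mat.shape[1]
        for s in contig_sites:
            sign = 1 if s.strand == "+" else -1
            pos = s.origin + sign * shifts_arr
            inside = (pos >= 0) & (pos < n)
            counts = np.zeros(len(ALL_SHIFTS), dtype=np.int64)
            counts[inside] = mat[:, pos[inside]].sum(axis=0)
            o0, o1 = s.origin, s.origin + sign
            if 0 <= o0 < n and 0 <= o1 < n:
                joint = int((mat[:, o0] & mat[:, o1]).sum())
            else:
                joint = 0
            out.append(
                ConservationProfile(
                    site=s,
                    joint_count=joint,
                    positional_counts=dict(zip(ALL_SHIFTS, counts.tolist())),
                    m_effective=index.m_effective,
                )
            )
    # restore input order
    order = {id(s): i for i, s in enumerate(sites)}
    out.sort(key=lambda p: order[id(p.site)])
    return out


def features_matrix(profiles: Sequence[ConservationProfile]) -> np.ndarray:
    """(n_sites, 61) matrix: joint count then the 60 positional counts."""
    return np.vstack([p.vector() for p in profiles])


def joint_count_distribution(
    profiles: Sequence[ConservationProfile], normalize: bool = True
) -> pd.DataFrame:
    """Histogram of joint dinucleotide conservation counts per site kind."""
    df = pd.DataFrame(
        {
            "kind": [p.site.kind for p in profiles],
            "joint_count": [p.joint_count for p in profiles],
        }
    )
    out = (
        df.groupby(["kind", "joint_count"]).size().rename("n_sites").reset_index()
    )
    if normalize:
        totals = out.groupby("kind")["n_sites"].transform("sum")
        out["fraction"] = out["n_sites"] / totals
    return out


def positional_conservation_summary(
    profiles: Sequence[ConservationProfile],
) -> pd.DataFrame:
    """Mean fraction of genomes conserved at each shift, per site kind."""
    rows = []
    for kind in sorted({p.site.kind for p in profiles}):
        ps = [p for p in profiles if p.site.kind == kind]
        m = ps[0].m_effective or 1
        for l in ALL_SHIFTS:
            rows.append(
                {
                    "kind": kind,
                    "shift": l,
                    "mean_fraction": float(
                        np.mean([p.positional_counts[l] for p in ps]) / m
                    ),
                }
            )
    return pd.DataFrame(rows).sort_values(["kind", "shift"]).reset_index(drop=True)
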