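"""Population-variant, clinical and transcriptomic corroboration layers.

These statistics cross-check the conservation-based labels against
independent evidence: SNP rates around splice sites (sites under selection
should rarely carry homozygous SNPs at their dinucleotides), clinically
pathogenic variants (functional sites disrupted by a SNP are more likely to
be flagged pathogenic), splice-junction read coverage (functional introns are
expressed), and isoform sharing.

Variants come from a VCF whose INFO keys carry the homozygote count, allele
frequency and clinical significance; the key names are configurable since
they vary by release.  Junction coverage comes from a TSV with columns
``contig  start  end  strand  tissue  reads`` (0-based half-open intron
coordinates; a flag converts 1-based dialects).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .catalogs import Catalog, SpliceSite

log = logging.getLogger(__name__)

PATHOGENIC = {"pathogenic", "likely pathogenic", "likely_pathogenic"}


@dataclass(frozen=True)
class VariantRecord:
    """A single-nucleotide variant (internal 0-based position)."""

    contig: str
    position: int
    ref: str
    alt: str
    n_homozygous: int
    frequency: Optional[float] = None
    clinical_significance: frozenset = frozenset()

    @property
    def is_pathogenic(self) -> bool:
        return bool(
            {c.lower().replace("_", " ") for c in self.clinical_significance}
            & {"pathogenic", "likely pathogenic"}
        )


@dataclass
class JunctionRecord:
    """Read support of one intron's donor-acceptor junction."""

    contig: str
    start: int
    end: int
    strand: str
    counts: Dict[str, int] = field(default_factory=dict)

    @property
    def max_coverage(self) -> int:
        return max(self.counts.values()) if self.counts else 0

    @property
    def key(self) -> tuple:
        return (self.contig, self.start, self.end, self.strand)


def read_vcf(
    path: str | os.PathLike,
    nhom_key: str = "nhomalt",
    af_key: str = "AF",
    clnsig_key: str = "CLNSIG",
) -> list[VariantRecord]:
    """Read SNVs from a VCF; indels are skipped (SNPs only)."""
    out: list[VariantRecord] = []
    for v in VCF(str(path)):
        for alt in v.ALT:
            if len(v.REF) != 1 or len(alt) != 1:
                continue
            clnsig = v.INFO.get(clnsig_key)
            sig = (
                frozenset(s.strip() for s in str(clnsig).split("|") if s.strip())
                if clnsig is not None
                else frozenset()
            )
            nhom = v.INFO.get(nhom_key)
            af = v.INFO.get(af_key)
            out.append(
                VariantRecord(
                    contig=v.CHROM,
                    position=v.POS - 1,
                    ref=v.REF,
                    alt=alt,
                    n_homozygous=int(nhom) if nhom is not None else 0,
                    frequency=float(af) if af is not None else None,
                    clinical_significance=sig,
                )
            )
    return out


def read_junctions(
    path: str | os.PathLike, one_based: bool = False
) -> Dict[tuple, JunctionRecord]:
    """Load a junction coverage TSV into ``{(contig,start,end,strand): rec}``."""
    df = pd.read_csv(path, sep="\t")
    offset = 1 if one_based else 0
    juncs: Dict[tuple, JunctionRecord] = {}
    for row in df.itertuples(index=False):
        key = (row.contig, int(row.start) - offset, int(row.end), row.strand)
        rec = juncs.get(key)
        if rec is None:
            rec = JunctionRecord(key[0], key[1], key[2], key[3])
            juncs[key] = rec
        rec.counts[row.tissue] = max(
            rec.counts.get(row.tissue, 0), int(row.reads)
        )
    return juncs


# ---------------------------------------------------------------------------
# SNP statistics


def _site_pos(site: SpliceSite, shift: int) -> int:
    return site.origin + (shift if site.strand == "+" else -shift)


def _qualifying_positions(
    variants: Iterable[VariantRecord], require_homozygous: bool
) -> Dict[str, set]:
    by_contig: Dict[str, set] = {}
    for v in variants:
        if require_homozygous and v.n_homozygous < 1:
            continue
        by_contig.setdefault(v.contig, set()).add(v.position)
    return by_contig


def snp_rate_profile(
    sites: Sequence[SpliceSite],
    variants: Sequence[VariantRecord],
    shifts: Iterable[int] = range(-30, 32),
    require_homozygous: bool = True,
    labels: Optional[Dict[tuple, str]] = None,
) -> pd.DataFrame:
    """Fraction of sites with >=1 qualifying SNP at each transcript-oriented
    shift, per site kind (and per label class when ``labels`` is given)."""
    positions = _qualifying_positions(variants, require_homozygous)
    shifts = list(shifts)
    rows = []
    groups: Dict[tuple, list[SpliceSite]] = {}
    for s in sites:
        lab = labels.get(s.identity, "all") if labels else "all"
        groups.setdefault((s.kind, lab), []).append(s)
    for (kind, lab), grp in sorted(groups.items()):
        cpos = [positions.get(s.contig, frozenset()) for s in grp]
        for l in shifts:
            hit = sum(
                1 for s, ps in zip(grp, cpos) if _site_pos(s, l) in ps
            )
            rows.append(
                {
                    "kind": kind,
                    "label": lab,
                    "shift": l,
                    "n_sites": len(grp),
                    "rate": hit / len(grp),
                }
            )
    return pd.DataFrame(rows)


def pathogenic_site_counts(
    sites: Sequence[SpliceSite],
    variants: Sequence[VariantRecord],
    labels: Optional[Dict[tuple, str]] = None,
) -> pd.DataFrame:
    """Sites with >=1 pathogenic / likely-pathogenic SNP overlapping the
    canonical dinucleotide (positions o and o+1 in transcript orientation)."""
    patho: Dict[str, set] = {}
    for v in variants:
        if v.is_pathogenic:
            patho.setdefault(v.contig, set()).add(v.position)
    rows = []
    groups: Dict[tuple, list[SpliceSite]] = {}
    for s in sites:
        lab = labels.get(s.identity, "all") if labels else "all"
        groups.setdefault((s.kind, lab), []).append(s)
    for (kind, lab), grp in sorted(groups.items()):
        n = sum(
            1
            for s in grp
            if {_site_pos(s, 0), _site_pos(s, 1)} & patho.get(s.contig, set())
        )
        rows.append(
            {
                "kind": kind,
                "label": lab,
                "n_sites": len(grp),
                "n_pathogenic": n,
                "percent": 100.0 * n / len(grp),
            }
        )
    return pd.DataFrame(rows)


def allele_frequency_distributions(
    sites: Sequence[SpliceSite],
    variants: Sequence[VariantRecord],
    labels: Optional[Dict[tuple, str]] = None,
) -> pd.DataFrame:
    """Median and IQR of homozygous-SNP frequencies overlapping the
    dinucleotides, per kind and label class."""
    freq: Dict[tuple, list[float]] = {}
    for v in variants:
        if v.n_homozygous >= 1 and v.frequency is not None:
            freq.setdefault((v.contig, v.position), []).append(v.frequency)
    rows = []
    groups: Dict[tuple, list[float]] = {}
    for s in sites:
        lab = labels.get(s.identity, "all") if labels else "all"
        for pos in (_site_pos(s, 0), _site_pos(s, 1)):
            for f in freq.get((s.contig, pos), ()):
                groups.setdefault((s.kind, lab), []).append(f)
    for (kind, lab), fs in sorted(groups.items()):
        arr = np.asarray(fs)
        q1, med, q3 = np.percentile(arr, [25, 50, 75])
        rows.append(
            {
                "kind": kind,
                "label": lab,
                "n_snps": len(arr),
                "median": med,
                "q1": q1,
                "q3": q3,
                "iqr": q3 - q1,
            }
        )
    return pd.DataFrame(
        rows, columns=["kind", "label", "n_snps", "median", "q1", "q3", "iqr"]
    )


# ---------------------------------------------------------------------------
# junction support


def intron_support_categories(
    catalog: Catalog,
    labels: Dict[tuple, bool],
    junctions: Dict[tuple, JunctionRecord],
    mane: Optional[Catalog] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-intron support category and junction-coverage summaries.

    Each intron is categorised by which of its two sites are well-supported
    (``neither`` / ``donor_only`` / ``acceptor_only`` / ``both``); MANE
    membership counts as well-supported.  Introns without a junction record
    get coverage 0 and are flagged.  Returns (per-intron table, per-category
    summary with median and IQR of max coverage).
    """

    def supported(ident: tuple) -> bool:
        if mane is not None and ident in mane.site_index:
            return True
        if ident not in labels:
            raise ValueError(f"unlabelled site {ident}")
        return labels[ident]

    rows = []
    seen: set = set()
    for tid, tr in catalog.transcripts.items():
        idents = catalog.transcript_sites.get(tid, [])
        donors = [i for i in idents if i[2] == "donor"]
        acceptors = [i for i in idents if i[2] == "acceptor"]
        introns = tr.introns()
        if tr.strand == "-":
            introns = introns[::-1]
        for (s, e), d_id, a_id in zip(introns, donors, acceptors):
            key = (tr.contig, s, e, tr.strand)
            if key in seen:
                continue
            seen.add(key)
            d_ok, a_ok = supported(d_id), supported(a_id)
            category = {
                (True, True): "both",
                (True, False): "donor_only",
                (False, True): "acceptor_only",
                (False, False): "neither",
            }[(d_ok, a_ok)]
            rec = junctions.get(key)
            rows.append(
                {
                    "contig": tr.contig,
                    "start": s,
                    "end": e,
                    "strand": tr.strand,
                    "category": category,
                    "max_coverage": rec.max_coverage if rec else 0,
                    "has_junction": rec is not None,
                }
            )
    introns_df = pd.DataFrame(rows)
    if introns_df.empty:
        return introns_df, pd.DataFrame()
    summary = (
        introns_df.groupby("category")["max_coverage"]
        .agg(
            n="size",
            median="median",
            q1=lambda x: float(np.percentile(x, 25)),
            q3=lambda x: float(np.percentile(x, 75)),
        )
        .reset_index()
    )
    summary["iqr"] = summary["q3"] - summary["q1"]
    return introns_df, summary


def isoform_sharing_counts(
    catalog: Catalog, labels: Optional[Dict[tuple, str]] = None
) -> pd.DataFrame:
    """Per-site count of transcripts (isoforms) using the site."""
    counts: Dict[tuple, int] = {}
    for tid in catalog.transcripts:
        for ident in set(catalog.transcript_sites.get(tid, [])):
            counts[ident] = counts.get(ident, 0) + 1
    rows = [
        {
            "contig": ident[0],
            "origin": ident[1],
            "kind": ident[2],
            "strand": ident[3],
            "label": labels.get(ident, "all") if labels else "all",
            "n_isoforms": c,
            "in_index": ident in catalog.site_index,
        }
        for ident, c in sorted(counts.items())
    ]
    return pd.DataFrame(rows)
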