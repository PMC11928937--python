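"""Gene catalogs: GFF3/GTF reading, biotype filtering, splice-site extraction.

The analysis consumes four kinds of catalog: a MANE-like consensus set (one
transcript per coding gene), larger catalogs in the style of GENCODE / RefSeq /
CHESS, their "reduced" variants with MANE-shared splice sites removed, and a
synthetic "Random" negative catalog.  Only protein-coding and lncRNA
transcripts are retained; the attribute conventions that encode the biotype
differ per catalog and are captured by :class:`BiotypeRules`.

All internal coordinates are 0-based half-open; GFF/GTF coordinates (1-based
inclusive) are converted at the I/O boundary.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence

import gffutils

from .genomes import GenomeSet, revcomp

log = logging.getLogger(__name__)

#: gene types retained by every analysis
GENE_TYPES = ("coding", "lncRNA")

#: minimum intron length below which donor/acceptor dinucleotides overlap
MIN_INTRON = 4


@dataclass(frozen=True)
class ExonInterval:
    """A reference exon segment, 0-based half-open."""

    contig: str
    start: int
    end: int
    strand: str
    gene_type: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty exon {self.contig}:{self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> tuple:
        """Deduplication key: exons are a set over these fields."""
        return (self.contig, self.start, self.end, self.gene_type)


@dataclass(frozen=True)
class SpliceSite:
    """A donor or acceptor splice site.

    ``origin`` is the genomic (forward-strand) coordinate of the first base of
    the canonical dinucleotide *in transcript orientation*: for a plus-strand
    intron [s, e) the donor origin is ``s`` and the acceptor origin ``e - 2``;
    on the minus strand the donor origin is ``e - 1`` and the acceptor origin
    ``s + 1``.  Site identity is ``(contig, origin, kind, strand)``.
    """

    kind: str  # "donor" | "acceptor"
    contig: str
    origin: int
    strand: str
    ref_dinucleotide: str
    canonical: bool
    gene_type: str

    @property
    def identity(self) -> tuple:
        return (self.contig, self.origin, self.kind, self.strand)


@dataclass
class TranscriptRecord:
    transcript_id: str
    gene_id: str
    gene_type: str
    contig: str
    strand: str
    exons: list[ExonInterval]

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping exons in transcript {self.transcript_id}"
                )

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    def introns(self) -> list[tuple[int, int]]:
        """Intron intervals [end_i, start_{i+1}) in genomic order."""
        return [
            (a.end, b.start) for a, b in zip(self.exons, self.exons[1:])
        ]


@dataclass
class Catalog:
    """A named transcript collection with a derived splice-site index."""

    name: str
    transcripts: Dict[str, TranscriptRecord]
    site_index: Dict[tuple, SpliceSite] = field(default_factory=dict)
    #: transcript_id -> list of site identities, in transcript order
    transcript_sites: Dict[str, list[tuple]] = field(default_factory=dict)

    def build_site_index(self, reference: GenomeSet) -> "Catalog":
        """(Re)derive ``site_index`` and per-transcript site lists."""
        self.site_index = {}
        self.transcript_sites = {}
        for tid, tr in self.transcripts.items():
            sites = extract_splice_sites(tr, reference)
            self.transcript_sites[tid] = [s.identity for s in sites]
            for s in sites:
                self.site_index.setdefault(s.identity, s)
        return self

    @property
    def sites(self) -> list[SpliceSite]:
        return list(self.site_index.values())

    def exon_set(self) -> list[ExonInterval]:
        """Deduplicated exons over all transcripts (E is a set)."""
        seen: Dict[tuple, ExonInterval] = {}
        for tr in self.transcripts.values():
            for e in tr.exons:
                seen.setdefault(e.key, e)
        return sorted(seen.values(), key=lambda e: (e.contig, e.start, e.end))


# ---------------------------------------------------------------------------
# biotype rules


@dataclass(frozen=True)
class BiotypeRules:
    """How a catalog encodes coding/lncRNA status in GFF attributes.

    ``style`` selects the attribute test:

    - ``transcript_type`` (GENCODE, MANE): transcript attribute
      ``transcript_type`` equal to ``protein_coding`` / ``lncRNA``;
    - ``gene_type`` (CHESS): transcript attribute ``gene_type``;
    - ``refseq``: gene ``gene_biotype=protein_coding`` and transcript
      ``transcript_biotype=mRNA`` for coding, gene ``gene_biotype=lncRNA``
      and transcript ``transcript_biotype=lnc_RNA`` for lncRNA.
    """

    style: str

    def classify(self, tx_attrs: dict, gene_attrs: dict) -> Optional[str]:
        def first(attrs, key):
            v = attrs.get(key)
            return v[0] if v else None

        if self.style == "transcript_type":
            t = first(tx_attrs, "transcript_type")
            if t == "protein_coding":
                return "coding"
            if t == "lncRNA":
                return "lncRNA"
            if t == "random":  # the synthetic neutral dataset round-trips
                return "random"
        elif self.style == "gene_type":
            t = first(tx_attrs, "gene_type")
            if t == "protein_coding":
                return "coding"
            if t == "lncRNA":
                return "lncRNA"
            if t == "random":
                return "random"
        elif self.style == "refseq":
            g = first(gene_attrs, "gene_biotype")
            t = first(tx_attrs, "transcript_biotype")
            if g == "protein_coding" and t == "mRNA":
                return "coding"
            if g == "lncRNA" and t == "lnc_RNA":
                return "lncRNA"
        else:
            raise ValueError(f"unknown biotype rule style {self.style!r}")
        return None


RULES = {
    "gencode": BiotypeRules("transcript_type"),
    "mane": BiotypeRules("transcript_type"),
    "chess": BiotypeRules("gene_type"),
    "refseq": BiotypeRules("refseq"),
}


# ---------------------------------------------------------------------------
# GFF reading / writing


def read_catalog(
    gff_path: str | os.PathLike,
    catalog_name: str,
    rules: BiotypeRules | str = "gencode",
    reference: Optional[GenomeSet] = None,
) -> Catalog:
    """Read a GFF3/GTF file into a :class:`Catalog`, keeping only coding and
    lncRNA transcripts per the catalog's biotype rules.

    If ``reference`` is given the splice-site index is built immediately.
    """
    if isinstance(rules, str):
        rules = RULES[rules]
    try:
        db = gffutils.create_db(
            str(gff_path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except Exception as exc:  # gffutils reports the offending line
        raise ValueError(f"malformed annotation file {gff_path}: {exc}") from exc

    # group exons under their parent transcript; robust to feature-type
    # dialects (transcript vs mRNA vs lnc_RNA ...)
    exons_by_parent: Dict[str, list] = {}
    for ex in db.features_of_type("exon"):
        for parent in ex.attributes.get("Parent", []):
            exons_by_parent.setdefault(parent, []).append(ex)

    transcripts: Dict[str, TranscriptRecord] = {}
    for tid, exs in exons_by_parent.items():
        try:
            tx = db[tid]
        except gffutils.FeatureNotFoundError:
            log.warning("exon parent %s has no feature record; skipped", tid)
            continue
        gene_attrs: dict = {}
        gene_id = tid
        for gid in tx.attributes.get("Parent", []):
            try:
                gene = db[gid]
            except gffutils.FeatureNotFoundError:
                continue
            gene_attrs = dict(gene.attributes)
            gene_id = gid
            break
        gene_type = rules.classify(dict(tx.attributes), gene_attrs)
        if gene_type is None:
            continue
        exon_ivs = [
            ExonInterval(ex.seqid, ex.start - 1, ex.end, ex.strand, gene_type)
            for ex in exs
        ]
        transcripts[tid] = TranscriptRecord(
            transcript_id=tid,
            gene_id=gene_id,
            gene_type=gene_type,
            contig=exs[0].seqid,
            strand=exs[0].strand,
            exons=exon_ivs,
        )

    cat = Catalog(name=catalog_name, transcripts=transcripts)
    if reference is not None:
        cat.build_site_index(reference)
    return cat


def write_catalog_gff3(catalog: Catalog, path: str | os.PathLike) -> None:
    """Write a catalog as GFF3 using GENCODE-style ``transcript_type``
    attributes, so that re-reading with the ``gencode`` rules round-trips."""
    biotype = {"coding": "protein_coding", "lncRNA": "lncRNA", "random": "random"}
    genes: Dict[str, list[TranscriptRecord]] = {}
    for tr in catalog.transcripts.values():
        genes.setdefault(tr.gene_id, []).append(tr)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gid in sorted(genes):
            trs = sorted(genes[gid], key=lambda t: t.transcript_id)
            g_start = min(t.exons[0].start for t in trs)
            g_end = max(t.exons[-1].end for t in trs)
            tr0 = trs[0]
            # a gene feature must not share its ID with a transcript
            gene_fid = (
                gid if all(t.transcript_id != gid for t in trs) else gid + ".gene"
            )
            fh.write(
                f"{tr0.contig}\tsplicecons\tgene\t{g_start + 1}\t{g_end}\t.\t"
                f"{tr0.strand}\t.\tID={gene_fid}\n"
            )
            for tr in trs:
                bt = biotype[tr.gene_type]
                fh.write(
                    f"{tr.contig}\tsplicecons\ttranscript\t"
                    f"{tr.exons[0].start + 1}\t{tr.exons[-1].end}\t.\t"
                    f"{tr.strand}\t.\tID={tr.transcript_id};Parent={gene_fid};"
                    f"transcript_type={bt}\n"
                )
                for i, e in enumerate(tr.exons, 1):
                    fh.write(
                        f"{e.contig}\tsplicecons\texon\t{e.start + 1}\t{e.end}"
                        f"\t.\t{e.strand}\t.\tID={tr.transcript_id}.exon{i};"
                        f"Parent={tr.transcript_id}\n"
                    )


def write_catalog_bed12(catalog: Catalog, path: str | os.PathLike) -> None:
    """BED12 dump of transcript structures, for genome-browser inspection."""
    with open(path, "w") as fh:
        for tr in sorted(catalog.transcripts.values(), key=lambda t: t.transcript_id):
            start = tr.exons[0].start
            end = tr.exons[-1].end
            sizes = ",".join(str(len(e)) for e in tr.exons)
            starts = ",".join(str(e.start - start) for e in tr.exons)
            fh.write(
                f"{tr.contig}\t{start}\t{end}\t{tr.transcript_id}\t0\t"
                f"{tr.strand}\t{start}\t{end}\t0\t{len(tr.exons)}\t"
                f"{sizes},\t{starts},\n"
            )


# ---------------------------------------------------------------------------
# operations


def apply_exclusions(
    catalog: Catalog,
    excluded_contigs: Iterable[str] = ("chrY",),
    alignment_contigs: Optional[Iterable[str]] = None,
    reference: Optional[GenomeSet] = None,
) -> Catalog:
    """Drop transcripts on excluded contigs (chrY by default), on contigs
    absent from the alignment (alternative sequences), and single-exon
    transcripts."""
    excluded = set(excluded_contigs)
    allowed = set(alignment_contigs) if alignment_contigs is not None else None
    kept = {
        tid: tr
        for tid, tr in catalog.transcripts.items()
        if tr.contig not in excluded
        and (allowed is None or tr.contig in allowed)
        and tr.n_introns >= 1
    }
    out = Catalog(name=catalog.name, transcripts=kept)
    if reference is not None:
        out.build_site_index(reference)
    return out


def extract_splice_sites(
    transcript: TranscriptRecord, reference: GenomeSet
) -> list[SpliceSite]:
    """One donor and one acceptor per intron, in transcript orientation.

    Introns shorter than 4 bases are degenerate (the two dinucleotides would
    overlap) and yield no sites.
    """
    seqs = reference.reference
    contig_seq = seqs[transcript.contig]
    sites: list[SpliceSite] = []
    introns = transcript.introns()
    if transcript.strand == "-":
        introns = introns[::-1]  # transcript order
    for s, e in introns:
        if e - s < MIN_INTRON:
            log.warning(
                "degenerate intron %s:%d-%d in %s; sites excluded",
                transcript.contig, s, e, transcript.transcript_id,
            )
            continue
        if transcript.strand == "+":
            donor_origin, acceptor_origin = s, e - 2
            donor_din = contig_seq[s : s + 2]
            acceptor_din = contig_seq[e - 2 : e]
        else:
            donor_origin, acceptor_origin = e - 1, s + 1
            donor_din = revcomp(contig_seq[e - 2 : e])
            acceptor_din = revcomp(contig_seq[s : s + 2])
        sites.append(
            SpliceSite(
                kind="donor",
                contig=transcript.contig,
                origin=donor_origin,
                strand=transcript.strand,
                ref_dinucleotide=donor_din,
                canonical=donor_din == "GT",
                gene_type=transcript.gene_type,
            )
        )
        sites.append(
            SpliceSite(
                kind="acceptor",
                contig=transcript.contig,
                origin=acceptor_origin,
                strand=transcript.strand,
                ref_dinucleotide=acceptor_din,
                canonical=acceptor_din == "AG",
                gene_type=transcript.gene_type,
            )
        )
    return sites


def build_reduced_catalog(catalog: Catalog, mane: Catalog) -> Catalog:
    """The starred catalog variant: same transcripts, but the site index
    excludes every (coding-gene) site identity present in MANE."""
    reduced = Catalog(
        name=catalog.name + "*",
        transcripts=dict(catalog.transcripts),
        transcript_sites=dict(catalog.transcript_sites),
    )
    reduced.site_index = {
        ident: site
        for ident, site in catalog.site_index.items()
        if not (site.gene_type == "coding" and ident in mane.site_index)
    }
    return reduced


def unique_exons(catalogs: Sequence[Catalog]) -> list[ExonInterval]:
    """Union of the catalogs' exon sets, deduplicated by (contig, start,
    end, gene_type)."""
    seen: Dict[tuple, ExonInterval] = {}
    for cat in catalogs:
        for e in cat.exon_set():
            seen.setdefault(e.key, e)
    return sorted(seen.values(), key=lambda e: (e.contig, e.start, e.end))
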