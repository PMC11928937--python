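"""Synthetic study inputs: reference, catalogs, alignment, variants, coverage.

The generator emulates the statistical structure the analysis assumes, so the
whole pipeline runs end-to-end without any download:

- a reference genome with multi-exon genes on both strands and canonical
  GT/AG introns; a MANE-like catalog (one transcript per gene) and a larger
  catalog that adds one alternative transcript per gene whose single novel
  splice site is functional (constrained) or neutral with a planted
  probability;
- per-species target genomes derived from the reference by i.i.d.
  substitutions: neutral positions mismatch with the per-species divergence,
  constrained positions (functional dinucleotides, their motif flanks, and
  MANE exon bodies) match with elevated retention probabilities.  Species are
  i.i.d. given the reference (star topology) -- the analysis consumes only
  per-species match counts;
- a MAF alignment in which randomly chosen (exon, species) pairs are erased
  (alignment dropout) while the underlying target sequence stays intact, so
  synteny realignment can recover them, plus partially covered exons so the
  acceptance statistic R_t has spread;
- homozygous SNPs at splice-site dinucleotides with class-dependent rates,
  clinical-significance tags, and junction read counts with class-dependent
  negative-binomial means.

Every operation is deterministic given the seed.  No indels are simulated;
realignment is exercised through dropout.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .catalogs import Catalog, ExonInterval, TranscriptRecord, write_catalog_gff3
from .genomes import GenomeSet, write_fasta

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CODE = {b: i for i, b in enumerate(b"ACGT")}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the standard conditions."""

    seed: int = 0
    m: int = 40                       # genomes, reference included
    divergence: float = 0.3           # neutral per-site mismatch probability
    retention: float = 0.99           # match prob at functional dinucleotides
    flank_retention: float = 0.95     # match prob at motif flank positions
    exon_retention: float = 0.92      # match prob in MANE exon bodies
    motif_flank: int = 5
    n_genes: int = 250
    exons_per_gene: int = 5
    exon_len: tuple = (80, 160)
    intron_len: tuple = (300, 600)
    intergenic_len: int = 300
    minus_fraction: float = 0.5
    fraction_functional_sites: float = 0.5
    n_random_transcripts: int = 1000
    random_exon_len: tuple = (20, 40)     # sized to fit inside host introns
    random_intron_len: tuple = (100, 200)
    alignment_dropout: float = 0.1
    partial_prob: float = 0.25        # aligned exon covered only partially
    exon_chunks: int = 3
    snp_rate_functional: float = 0.002
    snp_rate_neutral: float = 0.012
    snp_rate_nonhom: float = 0.002    # zero-homozygote variants (filtered out)
    pathogenic_fraction: float = 0.5
    pathogenic_fraction_neutral: float = 0.05
    coverage_mean_supported: float = 250.0
    coverage_mean_unsupported: float = 100.0
    coverage_dispersion: float = 10.0
    n_tissues: int = 5
    contig: str = "chr1"
    reference_id: str = "hg"

    def __post_init__(self) -> None:
        for name in (
            "divergence", "retention", "flank_retention", "exon_retention",
            "minus_fraction", "fraction_functional_sites",
            "alignment_dropout", "partial_prob",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.m < 2:
            raise ValueError("need at least two genomes")

    def with_(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class Erasure:
    """A planted alignment dropout and where the exon truly lies."""

    exon_key: tuple
    target: str
    true_start: int
    true_end: int


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    genomes: GenomeSet
    mane: Catalog
    extra: Catalog
    random: Optional[Catalog]
    truth_sites: Dict[tuple, bool]          # identity -> functional?
    novel_site_of: Dict[str, tuple]         # alt transcript -> novel identity
    maf_path: Optional[Path]
    erasures: list[Erasure]
    variants_path: Optional[Path] = None
    junctions_path: Optional[Path] = None


# ---------------------------------------------------------------------------
# reference and catalogs


def simulate_reference_and_catalogs(
    cfg: SimulationConfig,
) -> tuple[GenomeSet, Catalog, Catalog, Dict[tuple, bool], Dict[str, tuple]]:
    """Build the reference genome, the MANE-like catalog, the extended
    catalog with one alternative transcript per gene, the per-site truth
    (functional or neutral), and the alt-transcript -> novel-site map."""
    rng = np.random.default_rng(cfg.seed)
    emin, emax = cfg.exon_len
    imin, imax = cfg.intron_len
    if emin < 10 or imin < 100:
        raise ValueError("exon/intron length ranges too small for the layout")

    genes = []
    cursor = cfg.intergenic_len
    for gi in range(cfg.n_genes):
        exon_lens = rng.integers(emin, emax + 1, size=cfg.exons_per_gene)
        intron_lens = rng.integers(imin, imax + 1, size=cfg.exons_per_gene - 1)
        strand = "-" if rng.random() < cfg.minus_fraction else "+"
        exons = []
        pos = cursor
        for k, el in enumerate(exon_lens):
            exons.append((pos, pos + int(el)))
            pos += int(el)
            if k < len(intron_lens):
                pos += int(intron_lens[k])
        cursor = pos + cfg.intergenic_len
        # alternative transcript: shrink one intron from one side
        j = int(rng.integers(0, len(intron_lens)))
        side = "left" if rng.random() < 0.5 else "right"
        delta = int(rng.integers(8, 41))
        functional = bool(rng.random() < cfg.fraction_functional_sites)
        genes.append(
            {
                "id": f"G{gi:05d}",
                "strand": strand,
                "exons": exons,
                "alt": (j, side, delta, functional),
            }
        )
    total = cursor

    ref = rng.integers(0, 4, size=total, dtype=np.uint8)

    def plant(pos: int, dinuc: bytes) -> None:
        ref[pos] = _CODE[dinuc[0]]
        ref[pos + 1] = _CODE[dinuc[1]]

    mane_tx: Dict[str, TranscriptRecord] = {}
    extra_tx: Dict[str, TranscriptRecord] = {}
    alt_novel: Dict[str, tuple] = {}

    for g in genes:
        strand = g["strand"]
        exons = g["exons"]
        introns = [(a[1], b[0]) for a, b in zip(exons, exons[1:])]
        for s, e in introns:
            if strand == "+":
                plant(s, b"GT")
                plant(e - 2, b"AG")
            else:
                plant(s, b"CT")   # acceptor AG on the minus strand
                plant(e - 2, b"AC")  # donor GT on the minus strand

        j, side, delta, functional = g["alt"]
        s, e = introns[j]
        alt_exons = [list(x) for x in exons]
        if side == "left":
            alt_exons[j][1] = s + delta
            if strand == "+":
                plant(s + delta, b"GT")
                novel = (cfg.contig, s + delta, "donor", "+")
            else:
                plant(s + delta, b"CT")
                novel = (cfg.contig, s + delta + 1, "acceptor", "-")
        else:
            alt_exons[j + 1][0] = e - delta
            if strand == "+":
                plant(e - delta - 2, b"AG")
                novel = (cfg.contig, e - delta - 2, "acceptor", "+")
            else:
                plant(e - delta - 2, b"AC")
                novel = (cfg.contig, e - delta - 1, "donor", "-")

        def record(tid, ex_list, store):
            store[tid] = TranscriptRecord(
                transcript_id=tid,
                gene_id=g["id"],
                gene_type="coding",
                contig=cfg.contig,
                strand=strand,
                exons=[
                    ExonInterval(cfg.contig, int(a), int(b), strand, "coding")
                    for a, b in ex_list
                ],
            )

        record(g["id"] + ".mane", exons, mane_tx)
        record(g["id"] + ".mane", exons, extra_tx)
        record(g["id"] + ".alt", alt_exons, extra_tx)
        alt_novel[g["id"] + ".alt"] = novel

    seq = _BASES[ref].tobytes().decode("ascii")
    genomes = GenomeSet(
        genomes={cfg.reference_id: {cfg.contig: seq}},
        reference_id=cfg.reference_id,
    )
    mane = Catalog("MANE", mane_tx).build_site_index(genomes)
    extra = Catalog("EXTRA", extra_tx).build_site_index(genomes)

    truth: Dict[tuple, bool] = {ident: True for ident in mane.site_index}
    for g in genes:
        tid = g["id"] + ".alt"
        novel = alt_novel[tid]
        if novel not in extra.site_index:
            raise AssertionError(f"planted novel site {novel} not derived")
        truth[novel] = g["alt"][3]
    return genomes, mane, extra, truth, alt_novel


# ---------------------------------------------------------------------------
# alignment


def _match_probability(
    cfg: SimulationConfig,
    length: int,
    mane: Catalog,
    truth: Dict[tuple, bool],
    extra: Catalog,
) -> np.ndarray:
    """Per-position probability that a target base matches the reference."""
    p = np.full(length, 1.0 - cfg.divergence)
    for tr in mane.transcripts.values():
        for e in tr.exons:
            p[e.start : e.end] = cfg.exon_retention
    fl = cfg.motif_flank
    for ident, functional in truth.items():
        if not functional:
            continue
        _, origin, _, strand = ident
        sign = 1 if strand == "+" else -1
        d0, d1 = origin, origin + sign
        lo, hi = min(d0, d1), max(d0, d1)
        p[max(0, lo - fl) : min(length, hi + fl + 1)] = cfg.flank_retention
    for ident, functional in truth.items():
        if not functional:
            continue
        _, origin, _, strand = ident
        sign = 1 if strand == "+" else -1
        for pos in (origin, origin + sign):
            if 0 <= pos < length:
                p[pos] = cfg.retention
    return p


def simulate_alignment(
    cfg: SimulationConfig,
    genomes: GenomeSet,
    mane: Catalog,
    extra: Catalog,
    truth: Dict[tuple, bool],
    maf_path: str | os.PathLike,
) -> tuple[GenomeSet, list[Erasure]]:
    """Derive the target genomes, apply exon-level alignment dropout and
    partial coverage, and write the MAF.  Returns the extended
    :class:`GenomeSet` (reference + targets) and the erasure ledger.

    Each target contig is the mutated reference preceded by a per-species
    pad, so target coordinates differ from reference coordinates.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    contig = cfg.contig
    ref_seq = genomes.reference[contig]
    n = len(ref_seq)
    ref_codes = np.frombuffer(ref_seq.encode(), dtype=np.uint8)
    ref04 = np.zeros(n, dtype=np.uint8)
    for b, i in _CODE.items():
        ref04[ref_codes == b] = i

    pmatch = _match_probability(cfg, n, mane, truth, extra)
    targets = [f"sp{t:03d}" for t in range(1, cfg.m)]
    pads = rng.integers(10, 200, size=len(targets))

    all_genomes = {cfg.reference_id: {contig: ref_seq}}
    target_codes: Dict[str, np.ndarray] = {}
    for t, target in enumerate(targets):
        mutate = rng.random(n) > pmatch
        codes = ref04.copy()
        k = int(mutate.sum())
        codes[mutate] = (codes[mutate] + rng.integers(1, 4, size=k)) % 4
        target_codes[target] = codes
        pad = _BASES[rng.integers(0, 4, size=int(pads[t]))].tobytes().decode()
        all_genomes[target] = {contig: pad + _BASES[codes].tobytes().decode()}

    # atomic segments: exon boundaries plus chunk splits inside each exon
    exons = {}
    for cat in (mane, extra):
        for e in cat.exon_set():
            exons.setdefault((e.start, e.end), e)
    bounds = {0, n}
    for (s, e) in exons:
        bounds.add(s)
        bounds.add(e)
        for c in range(1, cfg.exon_chunks):
            cut = s + (e - s) * c // cfg.exon_chunks
            if s < cut < e:
                bounds.add(cut)
    bounds = np.array(sorted(bounds))
    seg_start, seg_end = bounds[:-1], bounds[1:]
    n_seg = len(seg_start)

    member = np.ones((len(targets), n_seg), dtype=bool)
    erasures: list[Erasure] = []
    for (s, e), exon in sorted(exons.items()):
        segs = np.flatnonzero((seg_start >= s) & (seg_end <= e))
        u = rng.random(len(targets))
        for t, target in enumerate(targets):
            if u[t] < cfg.alignment_dropout:
                member[t, segs] = False
                erasures.append(
                    Erasure(exon.key, target, int(s + pads[t]), int(e + pads[t]))
                )
            elif u[t] < cfg.alignment_dropout + cfg.partial_prob and len(segs) > 1:
                n_drop = int(rng.integers(1, len(segs)))
                drop = rng.choice(segs, size=n_drop, replace=False)
                member[t, drop] = False

    with open(maf_path, "w") as fh:
        fh.write("##maf version=1 program=splicecons-simulate\n")
        for si in range(n_seg):
            a, b = int(seg_start[si]), int(seg_end[si])
            rows = [
                f"s {cfg.reference_id}.{contig} {a} {b - a} + {n} {ref_seq[a:b]}"
            ]
            for t, target in enumerate(targets):
                if not member[t, si]:
                    continue
                tseq = _BASES[target_codes[target][a:b]].tobytes().decode()
                tstart = a + int(pads[t])
                tsize = n + int(pads[t])
                rows.append(
                    f"s {target}.{contig} {tstart} {b - a} + {tsize} {tseq}"
                )
            fh.write("a score=0\n" + "\n".join(rows) + "\n\n")

    return (
        GenomeSet(genomes=all_genomes, reference_id=cfg.reference_id),
        erasures,
    )


# ---------------------------------------------------------------------------
# variants and junction coverage


def simulate_variants_and_coverage(
    cfg: SimulationConfig,
    genomes: GenomeSet,
    catalogs: Sequence[Catalog],
    truth: Dict[tuple, bool],
    vcf_path: str | os.PathLike,
    junctions_path: str | os.PathLike,
) -> None:
    """Plant homozygous SNPs at splice-site dinucleotides with
    class-dependent rates (plus zero-homozygote decoys), tag a fraction of
    functional-site SNPs as pathogenic, and emit junction read counts whose
    negative-binomial mean depends on whether both intron ends are
    functional."""
    rng = np.random.default_rng(cfg.seed + 2)
    contig = cfg.contig
    ref = genomes.reference[contig]

    sites = {}
    for cat in catalogs:
        for ident, s in cat.site_index.items():
            sites.setdefault(ident, s)

    records = {}
    for ident, site in sorted(sites.items()):
        functional = truth.get(ident, False)
        rate = cfg.snp_rate_functional if functional else cfg.snp_rate_neutral
        p_path = (
            cfg.pathogenic_fraction
            if functional
            else cfg.pathogenic_fraction_neutral
        )
        sign = 1 if site.strand == "+" else -1
        for pos in (site.origin, site.origin + sign):
            if pos in records or not (0 <= pos < len(ref)):
                continue
            u = rng.random()
            if u < rate:
                nhom = 1 + int(rng.poisson(2.0))
                expo = rng.uniform(-5.0, -4.0) if functional else rng.uniform(-4.5, -3.5)
                clnsig = "Pathogenic" if rng.random() < p_path else "Benign"
                records[pos] = (nhom, 10.0 ** expo, clnsig)
            elif u < rate + cfg.snp_rate_nonhom:
                records[pos] = (0, 10.0 ** rng.uniform(-6.0, -5.0), ".")

    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={len(ref)}>\n")
        fh.write(
            '##INFO=<ID=nhomalt,Number=1,Type=Integer,'
            'Description="Homozygous sample count">\n'
        )
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">\n')
        fh.write(
            '##INFO=<ID=CLNSIG,Number=1,Type=String,'
            'Description="Clinical significance">\n'
        )
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        others = {"A": "G", "C": "T", "G": "A", "T": "C"}
        for pos in sorted(records):
            nhom, af, clnsig = records[pos]
            refb = ref[pos]
            alt = others.get(refb, "A")
            info = f"nhomalt={nhom};AF={af:.3e}"
            if clnsig != ".":
                info += f";CLNSIG={clnsig}"
            fh.write(
                f"{contig}\t{pos + 1}\t.\t{refb}\t{alt}\t.\tPASS\t{info}\n"
            )

    # junction coverage: one row per intron x tissue
    introns = {}
    for cat in catalogs:
        for tid, tr in cat.transcripts.items():
            idents = cat.transcript_sites.get(tid, [])
            donors = [i for i in idents if i[2] == "donor"]
            acceptors = [i for i in idents if i[2] == "acceptor"]
            ivs = tr.introns()
            if tr.strand == "-":
                ivs = ivs[::-1]
            for (s, e), d, a in zip(ivs, donors, acceptors):
                both = truth.get(d, False) and truth.get(a, False)
                introns.setdefault((tr.contig, s, e, tr.strand), both)

    disp = cfg.coverage_dispersion
    rows = []
    for (c, s, e, strand), both in sorted(introns.items()):
        mean = cfg.coverage_mean_supported if both else cfg.coverage_mean_unsupported
        p = disp / (disp + mean)
        for ti in range(cfg.n_tissues):
            reads = int(rng.negative_binomial(disp, p))
            rows.append((c, s, e, strand, f"tissue{ti + 1}", reads))
    pd.DataFrame(
        rows, columns=["contig", "start", "end", "strand", "tissue", "reads"]
    ).to_csv(junctions_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# orchestration


def simulate_study(
    cfg: SimulationConfig,
    out_dir: str | os.PathLike,
    with_random: bool = True,
    with_evidence: bool = True,
    write_fastas: bool = False,
) -> SimulatedStudy:
    """Run the whole generator, writing the MAF (and optionally VCF,
    junction TSV, GFF3s and FASTAs) under ``out_dir``."""
    from .random_sites import generate_random_transcripts

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genomes_ref, mane, extra, truth, novel = simulate_reference_and_catalogs(cfg)
    maf_path = out / "alignment.maf"
    genomes, erasures = simulate_alignment(
        cfg, genomes_ref, mane, extra, truth, maf_path
    )
    random_cat = None
    if with_random:
        random_cat = generate_random_transcripts(
            mane,
            genomes,
            n=cfg.n_random_transcripts,
            seed=cfg.seed + 3,
            exon_len=cfg.random_exon_len,
            intron_len=cfg.random_intron_len,
            exclude_catalogs=[extra],
        )
        for ident in random_cat.site_index:
            truth.setdefault(ident, False)

    study = SimulatedStudy(
        config=cfg,
        genomes=genomes,
        mane=mane,
        extra=extra,
        random=random_cat,
        truth_sites=truth,
        novel_site_of=novel,
        maf_path=maf_path,
        erasures=erasures,
    )
    if with_evidence:
        catalogs = [extra] + ([random_cat] if random_cat else [])
        study.variants_path = out / "variants.vcf"
        study.junctions_path = out / "junctions.tsv"
        simulate_variants_and_coverage(
            cfg, genomes, catalogs, truth,
            study.variants_path, study.junctions_path,
        )
    cat_dir = out / "catalogs"
    cat_dir.mkdir(exist_ok=True)
    write_catalog_gff3(mane, cat_dir / "mane.gff3")
    write_catalog_gff3(extra, cat_dir / "extra.gff3")
    if random_cat is not None:
        write_catalog_gff3(random_cat, cat_dir / "random.gff3")
    pd.DataFrame(
        [
            {"contig": c, "origin": o, "kind": k, "strand": st, "functional": f}
            for (c, o, k, st), f in sorted(truth.items())
        ]
    ).to_csv(out / "truth_sites.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "contig": e.exon_key[0],
                "start": e.exon_key[1],
                "end": e.exon_key[2],
                "target": e.target,
                "true_start": e.true_start,
                "true_end": e.true_end,
            }
            for e in erasures
        ]
    ).to_csv(out / "truth_erasures.tsv", sep="\t", index=False)
    if write_fastas:
        fa_dir = out / "fasta"
        fa_dir.mkdir(exist_ok=True)
        for gid, contigs in genomes.genomes.items():
            write_fasta(contigs, fa_dir / f"{gid}.fa")
    return study


# ---------------------------------------------------------------------------
# the two-genome worked example


@dataclass
class Figure1Fixture:
    """The toy two-genome alignment used as a worked example.

    Three exons; the middle one is unaligned but syntenic (its alignment rows
    are absent from the MAF while the sequence is present in the target).
    The donor of the first intron (``d1``) has both canonical bases intact in
    the target; the acceptor of the second intron (``a1``) has its first base
    substituted and its second intact.
    """

    genomes: GenomeSet
    catalog: Catalog
    maf_text: str
    d1: object
    a1: object
    middle_exon: ExonInterval

    def write_maf(self, path: str | os.PathLike) -> Path:
        p = Path(path)
        p.write_text(self.maf_text)
        return p


def figure1_fixture() -> Figure1Fixture:
    rng = np.random.default_rng(20240101)
    n = 260
    ref = rng.integers(0, 4, size=n, dtype=np.uint8)
    # exons [20,50) [110,140) [200,230); introns [50,110) and [140,200)
    for pos, dinuc in ((50, b"GT"), (108, b"AG"), (140, b"GT"), (198, b"AG")):
        ref[pos] = _CODE[dinuc[0]]
        ref[pos + 1] = _CODE[dinuc[1]]
    ref_seq = _BASES[ref].tobytes().decode()

    pad = 30
    g2 = ref.copy()
    sub = {0: 1, 1: 2, 2: 3, 3: 0}
    g2[198] = sub[g2[198]]  # acceptor first base mutated in the target
    g2_seq = _BASES[rng.integers(0, 4, size=pad, dtype=np.uint8)].tobytes().decode()
    g2_seq += _BASES[g2].tobytes().decode()

    genomes = GenomeSet(
        genomes={"hg": {"chr1": ref_seq}, "g2": {"chr1": g2_seq}},
        reference_id="hg",
    )
    tr = TranscriptRecord(
        transcript_id="T1",
        gene_id="GENE1",
        gene_type="coding",
        contig="chr1",
        strand="+",
        exons=[
            ExonInterval("chr1", 20, 50, "+", "coding"),
            ExonInterval("chr1", 110, 140, "+", "coding"),
            ExonInterval("chr1", 200, 230, "+", "coding"),
        ],
    )
    catalog = Catalog("toy", {"T1": tr}).build_site_index(genomes)

    def block(a: int, b: int) -> str:
        return (
            "a score=0\n"
            f"s hg.chr1 {a} {b - a} + {n} {ref_seq[a:b]}\n"
            f"s g2.chr1 {a + pad} {b - a} + {n + pad} {g2_seq[a + pad:b + pad]}\n\n"
        )

    # the left anchor exon is only partially covered (ref 45..47 uncovered),
    # so the originally-aligned scores R_t have nonzero spread
    maf = "##maf version=1\n" + block(0, 45) + block(48, 110) + block(140, 260)

    d1 = catalog.site_index[("chr1", 50, "donor", "+")]
    a1 = catalog.site_index[("chr1", 198, "acceptor", "+")]
    return Figure1Fixture(
        genomes=genomes,
        catalog=catalog,
        maf_text=maf,
        d1=d1,
        a1=a1,
        middle_exon=tr.exons[1],
    )
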