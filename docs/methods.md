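# Methods

This note documents the models and procedures implemented in `splicecons`,
the assumptions behind them, the tunable parameters, and the design choices
made where the problem was genuinely open. Nothing here states an empirical
result beyond what the test suite and `scripts/acceptance.py` compute.

## Coordinates and site definitions

All internal coordinates are 0-based half-open. GFF/GTF (1-based inclusive),
MAF (0-based, strand-relative) and VCF (1-based) are converted at the I/O
boundary; a single internal convention eliminates off-by-one drift.

A splice site's *origin* is the genomic (forward-strand) coordinate of the
first base of its canonical dinucleotide in transcript orientation: for a
plus-strand intron [s, e) the donor origin is s and the acceptor origin
e − 2; on the minus strand the donor origin is e − 1 and the acceptor origin
s + 1. Site identity is (contig, origin, kind, strand). Shift ℓ moves 5′→3′
along the transcript, i.e. genomically leftward on the minus strand. Introns
shorter than 4 bp are degenerate (the dinucleotides would overlap) and yield
no sites. For coding genes all introns are kept, including those in
untranslated regions; single-exon transcripts are excluded everywhere, as is
chromosome Y by default and any contig absent from the alignment.

Catalog biotype filtering keeps protein-coding and lncRNA transcripts.
The attribute conventions differ by catalog and are encoded as rule presets:
`transcript_type` on the transcript (GENCODE/MANE style), `gene_type` on the
transcript (CHESS style), or the gene's `gene_biotype` combined with the
transcript's `transcript_biotype` (RefSeq style). Reduced ("starred")
catalog variants remove every coding-gene site identity shared with the
consensus (MANE-like) catalog; removal is keyed on the full identity tuple
including strand, and only coding sites are affected since the consensus set
has no lncRNA.

## Alignment function and completeness

`read_maf` expands each MAF block column-wise: a column contributes an entry
w(k, g_t) only when both the reference and the target carry a non-gap base.
Minus-strand target coordinates are converted to forward-strand positions as
srcSize − (start + offset) − 1. Overlapping blocks that cover the same
reference position are resolved first-block-wins, with conflicting
duplicates counted and reported — the choice is arbitrary but deterministic.
The map is stored densely per (target, reference contig) as int64
target-position arrays plus interned contig ids and strands, which makes the
per-exon and per-window queries vectorisable at the scales this package
targets (tens of megabase-genomes × tens of species in memory).

An exon is *aligned* in a target (W(e, g_t) = 1) when at least one of its
positions maps — not full coverage; this matches the definition of the
completeness statistics s_a = ΣW and s_m = Σ(1 − W), reported per
(chromosome × gene type) stratum over the deduplicated exon set (exons form
a set keyed by contig, start, end and gene type, since the same exon is
shared by many transcripts). s_r counts pairs missing under w but aligned
under the merged w′.

## Synteny realignment

For each target genome, every unaligned exon flanked on both sides by
aligned exons is a realignment candidate. Anchors are the *nearest* aligned
exons that are disjoint from the candidate on the reference (overlapping
exon variants are skipped over, since the formal synteny relation requires
y_a < x < y < x_b). Both anchors must map to the same target contig and
strand; mixed-strand or cross-contig anchor pairs are rejected and counted.
The target segment is u = (max A(e_a) + 1, min A(e_b) − 1) on the forward
strand (roles swap for minus-strand anchor images, and the segment is
reverse-complemented before alignment). Segments longer than 100 000 bp are
not attempted.

The exon is aligned to the segment with edlib in semi-global mode (exon
global, segment infix — free gaps at the segment ends), which is the natural
reading of "best alignment of the exon to the range u". Match and mismatch
columns map positions; indel columns map nothing; edlib reports the leftmost
co-optimal placement, fixing tie-breaks deterministically.

A patch is accepted iff its coverage score r′(e) — mapped positions divided
by exon length — strictly exceeds μ(R_t) − σ(R_t), where R_t holds the
coverage scores r(e) of the originally aligned exons of the same target.
Two open points are fixed as follows: σ is the *population* standard
deviation (ddof = 0), and the denominator of r is the exon length under the
half-open convention (with inclusive coordinates the literal expression
would be length − 1; using the length is the consistent reading here).
Merging is conservative: w′ equals w wherever w is defined; accepted patches
only fill gaps, and where accepted patches overlap, the higher-r′ patch
wins. Both the real catalogs' exons and the Random dataset's exons are
eligible for realignment.

## Conservation features

C(s, ℓ, t) is 1 iff the reference base at shift ℓ equals its aligned target
base. Three conventions: (i) unaligned positions give 0 — the indicator is
undefined at w = −1 and treating a missing species as non-conserving is the
conservative choice; (ii) N never matches and comparison is
case-insensitive; (iii) when the reference maps to the target minus strand
the target base is complemented before comparison, so the indicator equals
column identity in the alignment and the whole computation is invariant
under reverse-complementing the fixture (verified by a property test).
Conservation always compares against the site's actual reference bases, so
noncanonical (GC–AG, AT–AC) sites are handled identically.

A site's feature vector is the joint dinucleotide count
Σ_t I[C(s,0,t) ∧ C(s,1,t)] plus one positional count Σ_t C(s, ℓ, t) for each
of the 60 shifts in [−30, 31] \ {0, 1} (the asymmetric window follows the
summation limits of the log-odds model: 30 positions on the exonic side and
30 on the intronic side of the dinucleotide). Per-position counts at shifts
0 and 1 are kept internally for the descriptive summaries but excluded from
the model features. Features are always computed on w′; for sites whose
surroundings were never realigned this is identical to w. Bulk extraction
uses a per-contig (targets × positions) 0/1 match matrix; a scalar
per-site/per-shift/per-genome implementation serves as the oracle in tests.

## Random (neutral) sites

The negative dataset consists of two-exon transcripts placed inside
consensus-catalog introns, each contributing exactly one donor and one
acceptor. Donor origins sit on reference `GT` and acceptor origins on `AG`
— neutral canonical-motif positions, which is the appropriate null for
"how conserved is a GT/AG that splicing does not use" (placement ignoring
sequence is available behind `require_motif=False`). "Outside splicing
motifs" is operationalised as keeping every generated origin more than 31 bp
from any annotated site origin of any input catalog, which guarantees that
feature windows of real and generated sites never share a dinucleotide.
Exon lengths default to 50–150 bp and generated intron lengths to
200–2000 bp ("two short exons" is otherwise unquantified); both are
configurable, and the simulator uses smaller values scaled to its host
introns. Placement is rejection sampling over candidate motif positions
(weighting host introns roughly by length); site identities are unique, the
generator is byte-deterministic per seed, and exhaustion of the constraint
space fails loudly with the achieved count.

## Classifier

`SpliceSiteClassifier` is a scikit-learn estimator wrapping an L2-penalised
logistic regression (lbfgs) over the 61-feature vector (full variant) or the
joint count alone (dinucleotide-only variant). Donor and acceptor models are
fitted separately. Defaults: C = 1.0 (mild regularisation — the exact
strength used with real data is not critical and coefficients are reported),
no feature scaling (counts used raw, so coefficients read as per-genome
log-odds increments), no class weighting (classes are near-balanced by
construction), 20% stratified hold-out, threshold 0.5 with ties labelled
well-supported. Non-convergence raises with the iteration budget rather
than warning. Evaluation reports ROC/AUC by threshold sweep and the F-score
at the threshold; tests check AUC against an exhaustive concordant-pair
oracle and the coefficients against a plain gradient-descent fit of the same
objective. A transcript is "well-supported" when every one of its sites is
either shared with the consensus catalog or labelled well-supported.

## Evidence layers

SNP rates are the fraction of sites with at least one qualifying SNP at a
given transcript-oriented shift; by default a variant qualifies only with at
least one homozygous carrier (a homozygous splice-site SNP is very likely to
disrupt splicing). Only SNVs are considered; indels are out of scope.
Homozygote counts, allele frequencies and clinical significance are read
from configurable VCF INFO keys (`nhomalt`, `AF`, `CLNSIG` by default) since
key names vary by release; clinical matching is case-insensitive on
{pathogenic, likely pathogenic}. "Overlapping the canonical dinucleotides"
means positions o and o + 1 in transcript orientation. Junction records
match introns exactly on (contig, start, end, strand), with a flag for
1-based junction dialects; introns without a record count as coverage 0 and
are flagged. Each intron falls in one of four categories (neither /
donor-only / acceptor-only / both well-supported) and coverage is summarised
as the median and IQR of the per-intron maximum across tissues.

## Synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not mammalian genome evolution:

- **Reference and catalogs.** Multi-exon genes on both strands with planted
  canonical dinucleotides; one consensus transcript per gene, plus one
  alternative transcript per gene that shrinks one intron from one side,
  creating exactly one novel splice site whose planted truth (functional
  vs neutral) is Bernoulli(`fraction_functional_sites`).
- **Species.** Targets are i.i.d. given the reference (star topology, no
  tree): the analysis consumes only per-species match counts, so rate
  heterogeneity and shared branches would change nothing the code paths
  exercise; this is stated as a deliberate simplification. Each target
  position matches the reference with probability 1 − divergence (default
  0.3), raised to `retention` (0.99) at functional dinucleotides,
  `flank_retention` (0.95) within ±5 bp of them, and `exon_retention`
  (0.92) in consensus exon bodies — the last produces the exonic/intronic
  conservation asymmetry around sites. Substitutions are uniform over the
  three other bases; no indels (realignment is exercised through dropout).
  Target contigs carry a random leading pad so target coordinates are
  genuinely shifted relative to the reference.
- **Alignment.** The MAF is emitted as atomic segments split at exon
  boundaries (each exon further split into 3 chunks). Per (exon, species):
  with probability `alignment_dropout` (0.1) all its segments are erased for
  that species — the planted erasure, recorded in a truth ledger with the
  true target interval — and with probability `partial_prob` (0.25) a proper
  subset of chunks is erased, giving the originally-aligned score set R_t a
  realistic spread (without it μ − σ would equal 1 and the strict acceptance
  filter could never pass). An erased alternative exon that contains a
  consensus exon erases it too; conversely a dinucleotide lying inside an
  erased overlapping exon can lose alignment until realignment restores it.
  Random-dataset exons lie inside always-aligned intron segments and are
  therefore never dropped.
- **Variants and coverage.** Homozygous SNPs are planted per dinucleotide
  position at `snp_rate_functional` = 0.002 vs `snp_rate_neutral` = 0.012 —
  the magnitudes of the constrained/neutral contrast the analysis is meant
  to detect — alongside zero-homozygote decoys that the default filter must
  remove. Allele frequencies are log-uniform with a lower decade for
  functional sites; a fraction of functional-site SNPs is tagged pathogenic.
  Junction read counts are negative-binomial (dispersion 10) with mean 250
  for introns whose both sites are functional and 100 otherwise (≈2.5×
  contrast in medians of the per-intron maximum across 5 tissues).

The standard configuration — 40 genomes, 250 five-exon genes
(1000 consensus introns, i.e. ~2000 positive sites), 1000 random
transcripts (~2000 negative sites), divergence 0.3, retention 0.99 —
is the condition under which held-out AUC and transcript recovery are
asserted; the realignment-recovery check uses 10 genomes at 10% divergence
and 15% dropout. These sizes keep the full pipeline to roughly a minute on
one CPU while leaving thousands of exon/genome events per assertion.

What the simulation does *not* capture — phylogenetic correlation between
species, indel evolution, paralogy and repeat-driven misalignment, biased
gene conversion, catalog-specific error modes — bounds what passing tests
show: they validate the machinery (definitions, bookkeeping, estimators,
recovery logic) under the planted model, not the biological conclusions on
real data.

## Worked-example fixture

A hand-constructed two-genome toy encodes the package's canonical worked
example: three exons, the middle one unaligned but syntenic (its sequence is
intact in the target; only its alignment rows are missing), the left anchor
only partially covered so the acceptance statistic has spread, a donor whose
dinucleotide is intact in the target, and an acceptor whose first base is
substituted with the second intact. On this fixture C(d1, 0, 2) =
C(d1, 1, 2) = 1, C(a1, 0, 2) = 0, C(a1, 1, 2) = 1, and realignment places
the middle exon strictly between its anchors' images;
`scripts/acceptance.py` recomputes these from scratch.

## Known limitations

- Realignment never revisits exons that are aligned but poorly, and does not
  project through a third genome.
- The dense per-contig map representation trades memory for speed; it is
  sized for desk-scale genomes, not for hundreds of full mammalian
  chromosomes.
- The classifier is a plain logistic link; no calibration beyond it, and no
  cross-validation beyond the single stratified split.
- Junction matching is exact-coordinate; fuzzy junction dialects must be
  normalised upstream (a 1-based conversion flag is provided).
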