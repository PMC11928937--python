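# splicecons

Conservation-based assessment of splice-site annotations from multi-species
whole-genome alignments.

Gene catalogs for well-studied genomes disagree about which transcripts — and
hence which splice sites — are real. Deep multiple whole-genome alignments
offer a way to triage them: splice sites under purifying selection keep their
canonical `GT`/`AG` dinucleotides across hundreds of species, while
misannotated or non-functional sites drift like neutral sequence. This
package implements that analysis end to end for annotation curators and
comparative genomicists: alignment completeness accounting, synteny-based
recovery of missing exon alignments, per-site conservation features, a
logistic well-supported/less-supported classifier, and corroboration against
population variants and splice-junction read coverage. A synthetic-data
module generates every input with the statistical structure the analysis
assumes, so the whole pipeline runs and is tested at desk scale without any
download.

## The model

A whole-genome alignment of genomes *g₁* (reference), …, *g_m* is
materialised as an alignment function *w(k, g_t)* mapping reference position
*k* to its homologous position in target *g_t* (−1 when unaligned). An exon
that is unaligned in *g_t* but flanked by exons aligned to the same target
contig is *syntenic*; it is realigned with a semi-global edit-distance
alignment (edlib) into the target segment *u* between its anchors' images,
and the patch is accepted when its coverage score exceeds
*μ(R_t) − σ(R_t)*, where *R_t* are the coverage scores of the originally
aligned exons. Merging accepted patches yields the extended function *w′*.

For a splice site *s* with origin *o(s)* (the first canonical-dinucleotide
base, in transcript orientation), the conservation function is the indicator

> *C(s, ℓ, t) = I[ b₁,ₒ₍ₛ₎₊ℓ = b_t,w′(o(s)+ℓ, t) ]*,

i.e. whether the base at shift ℓ matches its aligned base in genome *t*.
The classifier models the log odds of a site being "well-supported" as

> log *p*/(1−*p*) = α₀ + α₁ Σ_t I[C(s,0,t)=1 ∧ C(s,1,t)=1] +
> Σ_{−30 ≤ ℓ ≤ 31, ℓ∉{0,1}} α_ℓ Σ_t C(s, ℓ, t),

fitted separately for donors and acceptors on consensus-catalog (MANE-like)
sites as positives and random intronic `GT`/`AG` sites as negatives, with a
20% hold-out and a 0.5 probability threshold. A dinucleotide-only variant
(α₀, α₁ only) isolates the contribution of the flanking motif positions.
Transcripts whose every site is either shared with the consensus catalog or
classified well-supported form a high-confidence subset.

## Worked example

```python
import io
from splicecons import (
    SimulationConfig, simulate_study, read_maf, unique_exons,
    realign_missing_exons, completeness_summary, ConservationIndex,
    profiles_for_sites, assemble_training_set, fit_model, evaluate,
)

cfg = SimulationConfig(seed=1)          # 40 genomes, 250 genes, 10% dropout
study = simulate_study(cfg, "study")
w = read_maf(study.maf_path, cfg.reference_id)

exons = unique_exons([study.mane, study.extra, study.random])
res = realign_missing_exons(exons, w, study.genomes)
tot = completeness_summary(unique_exons([study.mane, study.extra]), w, res.merged).totals()
print(f"exon/genome pairs: {tot['aligned']} aligned, "
      f"{tot['missing']} missing, {tot['recovered']} recovered")

index = ConservationIndex(res.merged, study.genomes)
pos = profiles_for_sites(study.mane.sites, res.merged, study.genomes, index)
neg = profiles_for_sites(study.random.sites, res.merged, study.genomes, index)
for kind in ("donor", "acceptor"):
    split = assemble_training_set(pos, neg, kind, split=0.2, seed=1)
    model = fit_model(split, variant="full")
    m = evaluate(model, split.X_test, split.y_test)
    print(f"{kind}: AUC={m.auc:.3f}  F-score={m.f_score:.3f}  "
          f"alpha1={model.alpha1_:.2f}")
```

prints

```
exon/genome pairs: 51413 aligned, 7087 missing, 7079 recovered
donor: AUC=1.000  F-score=0.997  alpha1=1.28
acceptor: AUC=1.000  F-score=1.000  alpha1=1.25
```

Of the 7087 exon/genome pairs whose alignment was erased by the simulated
dropout, 7079 are recovered by synteny realignment (the rest lack a flanking
anchor). Held-out AUC near 1 reflects the planted separation between
constrained sites (per-species dinucleotide retention 0.99) and neutral ones
(30% per-site divergence); the positive α₁ means each additional genome with
an intact dinucleotide raises the log odds of being well-supported by ~1.3.

The same pipeline is scriptable from the shell via the `splicecons` CLI
(`simulate`, `catalog`, `completeness`, `realign`, `features`,
`random-sites`, `train`, `classify`, `evidence`).

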