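"""The conservation function C, feature vectors, and descriptive summaries."""

import io

import numpy as np
import pytest

from splicecons.alignment import read_maf
from splicecons.catalogs import Catalog, ExonInterval, TranscriptRecord
from splicecons.conservation import (
    ALL_SHIFTS,
    SHIFTS,
    ConservationIndex,
    conservation,
    features_matrix,
    joint_count_distribution,
    positional_conservation_summary,
    profiles_for_sites,
    site_features,
)
from splicecons.genomes import GenomeSet, revcomp


def test_worked_example_conservation_values(fig1, fig1_map):
    """The donor has both canonical bases intact in the target; the acceptor
    has its first base substituted and its second intact."""
    assert conservation(fig1.d1, 0, "g2", fig1_map, fig1.genomes) == 1
    assert conservation(fig1.d1, 1, "g2", fig1_map, fig1.genomes) == 1
    assert conservation(fig1.a1, 0, "g2", fig1_map, fig1.genomes) == 0
    assert conservation(fig1.a1, 1, "g2", fig1_map, fig1.genomes) == 1


def test_unaligned_position_gives_zero(fig1, fig1_map):
    # shift that lands inside the unaligned middle exon
    d1 = fig1.d1  # origin 50; middle exon starts at 110
    assert fig1_map.w("chr1", 112, "g2") == -1
    # construct a shift hitting 112 from the acceptor a1 (origin 198, '+')
    assert conservation(fig1.a1, 112 - 198, "g2", fig1_map, fig1.genomes) == 0


def test_profiles_match_scalar_oracle(small_study, small_map):
    """Vectorised feature extraction equals the naive per-site, per-shift,
    per-genome double loop, exactly."""
    genomes = small_study.genomes
    sites = (small_study.mane.sites + small_study.random.sites)[:30]
    index = ConservationIndex(small_map, genomes)
    profiles = profiles_for_sites(sites, small_map, genomes, index)
    targets = small_map.targets
    for p in profiles:
        s = p.site
        for l in ALL_SHIFTS:
            naive = sum(
                conservation(s, l, t, small_map, genomes) for t in targets
            )
            assert p.positional_counts[l] == naive, (s.identity, l)
        naive_joint = sum(
            conservation(s, 0, t, small_map, genomes)
            * conservation(s, 1, t, small_map, genomes)
            for t in targets
        )
        assert p.joint_count == naive_joint


def test_joint_count_bounded_by_dinucleotide_positions(std_study, std_map):
    genomes = std_study.genomes
    index = ConservationIndex(std_map, genomes)
    profiles = profiles_for_sites(
        std_study.mane.sites[:200], std_map, genomes, index
    )
    for p in profiles:
        assert p.joint_count <= min(
            p.positional_counts[0], p.positional_counts[1]
        )
        assert all(0 <= c <= p.m_effective for c in p.positional_counts.values())


def _mirror_fixture():
    """A 2-genome fixture and its reverse-complemented mirror image.

    The mirrored transcript sits on the minus strand, so its sites read the
    same in transcript orientation; profiles must be identical.
    """
    rng = np.random.default_rng(99)
    n = 400
    bases = np.array(list("ACGT"))
    ref = list("".join(bases[rng.integers(0, 4, n)]))
    # exons [50,120) and [200,280); intron [120,200) with GT..AG
    ref[120:122] = "GT"
    ref[198:200] = "AG"
    ref = "".join(ref)
    g2 = list(ref)
    for pos in rng.integers(0, n, 40):  # scatter substitutions
        g2[pos] = bases[(bases.tolist().index(g2[pos]) + 1) % 4]
    g2 = "".join(g2)

    def build(seq_r, seq_t, strand):
        gs = GenomeSet(
            genomes={"hg": {"chr1": seq_r}, "g2": {"chr1": seq_t}},
            reference_id="hg",
        )
        if strand == "+":
            exons = [(50, 120), (200, 280)]
        else:
            exons = [(n - 280, n - 200), (n - 120, n - 50)]
        tr = TranscriptRecord(
            transcript_id="T1",
            gene_id="G1",
            gene_type="coding",
            contig="chr1",
            strand=strand,
            exons=[ExonInterval("chr1", a, b, strand, "coding") for a, b in exons],
        )
        cat = Catalog("toy", {"T1": tr}).build_site_index(gs)
        maf = (
            "##maf version=1\n"
            f"a score=0\ns hg.chr1 0 {n} + {n} {seq_r}\n"
            f"s g2.chr1 0 {n} + {n} {seq_t}\n\n"
        )
        return gs, cat, read_maf(io.StringIO(maf), "hg")

    fwd = build(ref, g2, "+")
    rev = build(revcomp(ref), revcomp(g2), "-")
    return fwd, rev


def test_strand_symmetry_of_profiles():
    """Recomputing on the reverse-complemented fixture yields identical
    conservation profiles."""
    (gs_f, cat_f, map_f), (gs_r, cat_r, map_r) = _mirror_fixture()
    for kind in ("donor", "acceptor"):
        s_f = next(s for s in cat_f.sites if s.kind == kind)
        s_r = next(s for s in cat_r.sites if s.kind == kind)
        assert s_f.ref_dinucleotide == s_r.ref_dinucleotide
        p_f = site_features(s_f, map_f, gs_f)
        p_r = site_features(s_r, map_r, gs_r)
        assert p_f.joint_count == p_r.joint_count
        assert p_f.positional_counts == p_r.positional_counts


def test_fully_conserved_fixture_has_unit_mass_at_m_minus_1():
    n = 400
    rng = np.random.default_rng(1)
    ref = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
    ref = ref[:120] + "GT" + ref[122:198] + "AG" + ref[200:]
    genomes = {"hg": {"chr1": ref}}
    maf = "##maf version=1\n"
    for t in range(1, 5):
        genomes[f"g{t}"] = {"chr1": ref}
    maf += (
        "a score=0\n"
        + f"s hg.chr1 0 {n} + {n} {ref}\n"
        + "\n".join(f"s g{t}.chr1 0 {n} + {n} {ref}" for t in range(1, 5))
        + "\n\n"
    )
    gs = GenomeSet(genomes=genomes, reference_id="hg")
    tr = TranscriptRecord(
        transcript_id="T1",
        gene_id="G1",
        gene_type="coding",
        contig="chr1",
        strand="+",
        exons=[
            ExonInterval("chr1", 50, 120, "+", "coding"),
            ExonInterval("chr1", 200, 280, "+", "coding"),
        ],
    )
    cat = Catalog("toy", {"T1": tr}).build_site_index(gs)
    amap = read_maf(io.StringIO(maf), "hg")
    profiles = profiles_for_sites(cat.sites, amap, gs)
    assert all(p.joint_count == 4 for p in profiles)
    assert all(
        c == 4 for p in profiles for c in p.positional_counts.values()
    )
    dist = joint_count_distribution(profiles)
    assert set(dist["joint_count"]) == {4}
    assert np.allclose(dist["fraction"], 1.0)


def test_class_separation_of_joint_counts(std_study, std_map):
    """MANE-like sites concentrate near m-1 genomes; neutral sites track the
    neutral identity level of the generator."""
    genomes = std_study.genomes
    cfg = std_study.config
    index = ConservationIndex(std_map, genomes)
    mane_p = profiles_for_sites(std_study.mane.sites, std_map, genomes, index)
    rand_p = profiles_for_sites(std_study.random.sites, std_map, genomes, index)
    m1 = cfg.m - 1
    mane_counts = np.array([p.joint_count for p in mane_p])
    mode = np.bincount(mane_counts).argmax()
    assert mode > 0.85 * m1
    neutral_expect = m1 * (1 - cfg.divergence) ** 2
    rand_mean = np.mean([p.joint_count for p in rand_p])
    assert abs(rand_mean - neutral_expect) < 1.5


def test_positional_summary_dinucleotide_maxima_and_neutral_flatness(
    std_study, std_map
):
    genomes = std_study.genomes
    index = ConservationIndex(std_map, genomes)
    mane_p = profiles_for_sites(std_study.mane.sites, std_map, genomes, index)
    rand_p = profiles_for_sites(std_study.random.sites, std_map, genomes, index)
    summ = positional_conservation_summary(mane_p)
    for kind in ("donor", "acceptor"):
        sk = summ[summ["kind"] == kind].set_index("shift")["mean_fraction"]
        top2 = set(sk.sort_values(ascending=False).index[:2])
        assert top2 == {0, 1}
    rand_summ = positional_conservation_summary(rand_p)
    spread = rand_summ.groupby("kind")["mean_fraction"].agg(lambda x: x.max() - x.min())
    assert (spread < 0.15).all()


def test_exonic_side_more_conserved_than_intronic_for_donors(
    std_study, std_realign
):
    """The generator constrains exon bodies, so donor upstream (exonic)
    shifts are more conserved than downstream (intronic) ones on the merged
    alignment w'."""
    genomes = std_study.genomes
    amap = std_realign.merged
    index = ConservationIndex(amap, genomes)
    mane_p = profiles_for_sites(std_study.mane.sites, amap, genomes, index)
    summ = positional_conservation_summary(
        [p for p in mane_p if p.site.kind == "donor"]
    )
    sk = summ.set_index("shift")["mean_fraction"]
    exonic = np.mean([sk[l] for l in range(-25, -5)])
    intronic = np.mean([sk[l] for l in range(12, 32)])
    assert exonic > intronic + 0.05


def test_features_matrix_layout(small_study, small_map):
    sites = small_study.mane.sites[:3]
    profiles = profiles_for_sites(sites, small_map, small_study.genomes)
    X = features_matrix(profiles)
    assert X.shape == (3, 1 + len(SHIFTS))
    assert X[0, 0] == profiles[0].joint_count
    assert X[1, 1] == profiles[1].positional_counts[SHIFTS[0]]
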