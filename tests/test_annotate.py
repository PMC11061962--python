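"""Location categories, coding effects, interval overlap, group-specific SNPs."""

import numpy as np
import pytest

from sweepscan.annotate import (category_enrichment, classify_location,
                                coding_effect, group_specific_snps,
                                interval_overlap)
from sweepscan.variants import site_table_from_counts


@pytest.mark.parametrize("pos1, expected", [
    (8005, "coding"),          # inside geneB CDS
    (2100, "UTR5"),            # geneA 5' UTR
    (5800, "UTR3"),            # geneA 3' UTR
    (4000, "intronic"),        # middle of geneA intron
    (3001, "splicing"),        # first base of geneA intron (donor side)
    (3002, "splicing"),        # second base of the intron
    (3003, "intronic"),        # third base: past the 2 bp splice margin
    (1500, "updownstream"),    # 500 bp upstream of geneA start
    (12_500, "ncRNA"),
    (500, "intergenic"),
    (19_999, "intergenic"),
])
def test_location_categories(toy_annotation, pos1, expected):
    assert classify_location("chr1", pos1, toy_annotation) == expected


def test_intronic_beats_updownstream(toy_annotation):
    """A SNP in geneA's intron that is also near another feature stays intronic."""
    # position 5999 (1-based 6000) is inside geneA's last exon (UTR3);
    # instead test the precedence list directly on an intron position that
    # also lies within 1 kb downstream of nothing else: use 4800, which is
    # intronic for geneA and within 1 kb of geneA's exon only.
    assert classify_location("chr1", 4500, toy_annotation) == "intronic"


def test_updownstream_window_is_1kb(toy_annotation):
    # geneA starts at 0-based 2000 -> upstream covers 0-based [1000, 2000)
    assert classify_location("chr1", 1001, toy_annotation) == "updownstream"
    assert classify_location("chr1", 1000, toy_annotation) == "intergenic"


def test_unannotated_chromosome_is_intergenic(toy_annotation):
    assert classify_location("chrUn", 100, toy_annotation) == "intergenic"


def test_coding_effects_plus_strand(toy_annotation):
    # geneB codon 2 is CGG (0-based 8003..8005); CGG->TGG is R->W
    assert coding_effect("chr1", 8004, "C", "T", toy_annotation) == "nonsynonymous"
    # codon 3 GGA->GGG: third-position wobble
    assert coding_effect("chr1", 8009, "A", "G", toy_annotation) == "synonymous"
    # codon 4 TGG->TAG: stop gain
    assert coding_effect("chr1", 8011, "G", "A", toy_annotation) == "stop-gain"


def test_coding_effect_minus_strand(toy_annotation):
    # geneC codon at plus-strand 15291-15293 (CCA) reads TGG on minus strand;
    # plus-strand A->G at 1-based 15294 makes it CGG: W->R nonsynonymous
    assert coding_effect("chr1", 15_294, "A", "G",
                         toy_annotation) == "nonsynonymous"


def test_coding_effect_outside_cds_is_none(toy_annotation):
    assert coding_effect("chr1", 500, "A", "G", toy_annotation) is None


def test_interval_overlap_toy_fractions():
    dss = [("chr1", 0, 60_000)]
    qtl = [("chr1", 50_000, 70_000, "q1"), ("chr1", 200_000, 300_000, "q2")]
    q_frac, f_frac, per = interval_overlap(dss, qtl)
    assert q_frac == 1.0
    assert f_frac == 0.5
    assert per == [["q1"]]


def test_interval_overlap_halfopen_abutting():
    q_frac, f_frac, per = interval_overlap(
        [("chr1", 0, 60_000)], [("chr1", 60_000, 70_000, "q")])
    assert q_frac == 0.0 and f_frac == 0.0 and per == [[]]


def test_interval_overlap_empty_inputs():
    q_frac, f_frac, per = interval_overlap([], [("chr1", 0, 10, "q")])
    assert q_frac == 0.0 and f_frac == 0.0 and per == []


def test_interval_overlap_directional_symmetry():
    a = [("chr1", 0, 100), ("chr1", 500, 600)]
    b = [("chr1", 50, 80, 0), ("chr1", 900, 950, 1)]
    qa, fa, _ = interval_overlap(a, b)
    qb, fb, _ = interval_overlap([(c, s, e) for c, s, e, _ in b],
                                 [(c, s, e, i) for i, (c, s, e) in enumerate(a)])
    assert (qa, fa) == (fb, qb)


def _freq_table():
    return site_table_from_counts(
        {"chrom": ["chr1"] * 4, "pos": [1, 2, 3, 4]},
        {"A": {"n": [10] * 4, "ac": [19, 8, 0, 4], "het": [1, 4, 0, 2]},
         "B": {"n": [10] * 4, "ac": [0, 0, 5, 3], "het": [0, 0, 3, 3]}},
    )


def test_group_specific_and_nearly_fixed():
    spec, fixed = group_specific_snps(_freq_table(), "A")
    assert list(spec["pos"]) == [1, 2]      # alt absent in B
    assert list(fixed["pos"]) == [1]        # p = 0.95 > 0.9
    spec_b, _ = group_specific_snps(_freq_table(), "B")
    assert list(spec_b["pos"]) == [3]       # pos 4 is shared
    with pytest.raises(ValueError):
        group_specific_snps(_freq_table(), "Z")


def test_nearly_fixed_threshold_strict():
    t = site_table_from_counts(
        {"chrom": ["chr1"], "pos": [1]},
        {"A": {"n": [10], "ac": [18], "het": [2]},
         "B": {"n": [10], "ac": [0], "het": [0]}},
    )
    spec, fixed = group_specific_snps(t, "A", fixation_threshold=0.9)
    assert len(spec) == 1 and len(fixed) == 0   # p = 0.9 exactly, strict >


def test_category_enrichment_ratios():
    obs = {"noncoding": 0.9820, "coding": 0.0180}
    genome = {"noncoding": 0.9692, "coding": 1 - 0.9692}
    ratios = category_enrichment(obs, genome)
    assert ratios["noncoding"] == pytest.approx(1.0132, abs=1e-4)
    assert ratios["coding"] == pytest.approx(0.584, abs=1e-3)
    same = category_enrichment(genome, genome)
    assert all(v == pytest.approx(1.0) for v in same.values())
    flagged = category_enrichment({"x": 0.5}, {"x": 0.0})
    assert np.isnan(flagged["x"])


def test_gff3_loading_roundtrip(tmp_path):
    """GFF3-loaded models classify like directly constructed ones."""
    from sweepscan.annotate import GenomeAnnotation

    gff = tmp_path / "toy.gff3"
    gff.write_text("\n".join([
        "##gff-version 3",
        "chr1\t.\tgene\t2001\t6000\t.\t+\t.\tID=geneA",
        "chr1\t.\tmRNA\t2001\t6000\t.\t+\t.\tID=geneA.t1;Parent=geneA",
        "chr1\t.\texon\t2001\t3000\t.\t+\t.\tParent=geneA.t1",
        "chr1\t.\texon\t5001\t6000\t.\t+\t.\tParent=geneA.t1",
        "chr1\t.\tfive_prime_UTR\t2001\t2300\t.\t+\t.\tParent=geneA.t1",
        "chr1\t.\tCDS\t2301\t3000\t.\t+\t0\tParent=geneA.t1",
        "chr1\t.\tCDS\t5001\t5700\t.\t+\t2\tParent=geneA.t1",
        "chr1\t.\tthree_prime_UTR\t5701\t6000\t.\t+\t.\tParent=geneA.t1",
        "chr1\t.\tncRNA\t12001\t13000\t.\t+\t.\tID=geneN.t1",
        "",
    ]))
    ann = GenomeAnnotation.from_gff3(str(gff))
    assert classify_location("chr1", 2500, ann) == "coding"
    assert classify_location("chr1", 2100, ann) == "UTR5"
    assert classify_location("chr1", 4000, ann) == "intronic"
    assert classify_location("chr1", 12_500, ann) == "ncRNA"
    assert classify_location("chr1", 1500, ann) == "updownstream"
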