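"""SNP location categories, coding effects, and interval-overlap reports.

SNPs are classified into seven mutually exclusive location categories —
intergenic, intronic, coding (with synonymous / nonsynonymous /
stop-gain / stop-loss subtypes), up/downstream (within 1 kb of a
transcript start or end), splicing (within 2 bp of an intron boundary),
5'/3' UTR, and ncRNA — resolving multi-annotation sites by a fixed
precedence:

    coding > splicing > ncRNA > UTR5 > UTR3 > intronic > up/downstream
           > intergenic

Splicing is defined on intronic positions only (the first/last 2 bp of
an intron), so it never competes with coding.  Coding effects are
computed strand-aware by substituting the alternate base into the
reference codon and translating both with the standard genetic code.

The module also provides DSS-by-feature interval overlap (e.g. against
QTL intervals), group-specific SNP extraction with a near-fixation
threshold, and observed/expected category enrichment against genome
composition fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = ["Transcript", "GenomeAnnotation", "classify_location",
           "coding_effect", "interval_overlap", "group_specific_snps",
           "category_enrichment", "CATEGORY_PRECEDENCE"]

CATEGORY_PRECEDENCE = ["coding", "splicing", "ncRNA", "UTR5", "UTR3",
                       "intronic", "updownstream", "intergenic"]

UPDOWNSTREAM_BP = 1_000
SPLICE_BP = 2


@dataclass
class Transcript:
    """One transcript's structure (all intervals 0-based half-open)."""

    tx_id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)
    coding: bool = True

    def introns(self) -> list[tuple[int, int]]:
        ex = sorted(self.exons)
        return [(a_end, b_start) for (_, a_end), (b_start, _)
                in zip(ex, ex[1:]) if b_start > a_end]


class GenomeAnnotation:
    """Gene models + optional reference sequence, indexed for lookup."""

    def __init__(self, transcripts: list[Transcript],
                 reference: "object | None" = None):
        self.transcripts = transcripts
        self.reference = reference
        self._trees: dict[str, IntervalTree] = {}
        self._build_trees()

    @classmethod
    def from_gff3(cls, gff_path: str, fasta_path: str | None = None
                  ) -> "GenomeAnnotation":
        """Load transcript models from GFF3 (and codons from FASTA)."""
        import gffutils

        db = gffutils.create_db(gff_path, dbfn=":memory:", force=True,
                                keep_order=True,
                                merge_strategy="create_unique")
        transcripts = []
        tx_types = {"mRNA", "transcript", "ncRNA", "lnc_RNA", "miRNA",
                    "snoRNA", "rRNA", "tRNA"}
        for feat in db.all_features():
            if feat.featuretype not in tx_types:
                continue
            tx = Transcript(
                tx_id=feat.id, chrom=feat.seqid, strand=feat.strand,
                start=feat.start - 1, end=feat.end,
            )
            for child in db.children(feat):
                iv = (child.start - 1, child.end)
                if child.featuretype == "exon":
                    tx.exons.append(iv)
                elif child.featuretype == "CDS":
                    tx.cds.append(iv)
                elif child.featuretype == "five_prime_UTR":
                    tx.utr5.append(iv)
                elif child.featuretype == "three_prime_UTR":
                    tx.utr3.append(iv)
            tx.coding = bool(tx.cds) and feat.featuretype == "mRNA"
            if not tx.exons:
                tx.exons = sorted(tx.cds) or [(tx.start, tx.end)]
            transcripts.append(tx)

        reference = None
        if fasta_path is not None:
            from pyfaidx import Fasta
            reference = Fasta(fasta_path)
        return cls(transcripts, reference)

    def _add(self, chrom: str, start: int, end: int, category: str,
             tx: Transcript) -> None:
        if end > start:
            self._trees.setdefault(chrom, IntervalTree()).addi(
                start, end, (category, tx))

    def _build_trees(self) -> None:
        for tx in self.transcripts:
            c = tx.chrom
            if tx.coding:
                for s, e in tx.cds:
                    self._add(c, s, e, "coding", tx)
                for s, e in tx.utr5:
                    self._add(c, s, e, "UTR5", tx)
                for s, e in tx.utr3:
                    self._add(c, s, e, "UTR3", tx)
                for s, e in tx.introns():
                    self._add(c, s, min(s + SPLICE_BP, e), "splicing", tx)
                    self._add(c, max(e - SPLICE_BP, s), e, "splicing", tx)
                    self._add(c, s, e, "intronic", tx)
            else:
                self._add(c, tx.start, tx.end, "ncRNA", tx)
            self._add(c, max(tx.start - UPDOWNSTREAM_BP, 0), tx.start,
                      "updownstream", tx)
            self._add(c, tx.end, tx.end + UPDOWNSTREAM_BP, "updownstream", tx)

    def hits(self, chrom: str, pos: int) -> list[tuple[str, Transcript]]:
        """Annotation features covering a 1-based position."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [iv.data for iv in tree.at(pos - 1)]


def classify_location(chrom: str, pos: int, annotation: GenomeAnnotation
                      ) -> str:
    """Single location category for a SNP at 1-based ``pos``."""
    cats = {cat for cat, _ in annotation.hits(chrom, pos)}
    if not cats:
        return "intergenic"
    for cat in CATEGORY_PRECEDENCE:
        if cat in cats:
            return cat
    return "intergenic"


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def coding_effect(chrom: str, pos: int, ref: str, alt: str,
                  annotation: GenomeAnnotation) -> str | None:
    """Effect of a coding SNP: synonymous / nonsynonymous / stop-gain / -loss.

    Uses the first coding transcript whose CDS covers the position and
    whose CDS length is a multiple of 3 (others are skipped with a
    warning).  Returns None when no usable transcript covers the SNP.
    """
    from Bio.Seq import Seq

    if annotation.reference is None:
        raise ValueError("coding_effect requires a reference sequence")

    pos0 = pos - 1
    for cat, tx in annotation.hits(chrom, pos):
        if cat != "coding":
            continue
        segs = sorted(tx.cds)
        total = sum(e - s for s, e in segs)
        if total % 3 != 0:
            logger.warning("CDS length of %s not a multiple of 3; skipped",
                           tx.tx_id)
            continue
        # offset of the site in the spliced CDS, in genomic (+) order
        off = 0
        for s, e in segs:
            if s <= pos0 < e:
                off += pos0 - s
                break
            off += e - s
        else:
            continue
        if tx.strand == "-":
            off = total - 1 - off
        codon_idx = off // 3
        within = off % 3

        # genomic coordinates of the codon's three bases, in CDS order
        flat: list[int] = []
        for s, e in segs:
            flat.extend(range(s, e))
        if tx.strand == "-":
            flat = flat[::-1]
        codon_pos = flat[codon_idx * 3: codon_idx * 3 + 3]

        seq = annotation.reference[chrom]
        bases = [str(seq[g]) for g in codon_pos]
        if tx.strand == "-":
            bases = [b.translate(_COMPLEMENT) for b in bases]
        ref_base = ref if tx.strand == "+" else ref.translate(_COMPLEMENT)
        alt_base = alt if tx.strand == "+" else alt.translate(_COMPLEMENT)
        if bases[within].upper() != ref_base.upper():
            logger.warning("reference mismatch at %s:%d (have %s, VCF ref %s)",
                           chrom, pos, bases[within], ref)
        ref_codon = "".join(bases).upper()
        alt_codon = (ref_codon[:within] + alt_base.upper()
                     + ref_codon[within + 1:])
        aa_ref = str(Seq(ref_codon).translate())
        aa_alt = str(Seq(alt_codon).translate())
        if aa_ref == aa_alt:
            return "synonymous"
        if aa_alt == "*":
            return "stop-gain"
        if aa_ref == "*":
            return "stop-loss"
        return "nonsynonymous"
    return None


def interval_overlap(queries: list[tuple[str, int, int]],
                     features: list[tuple[str, int, int, object]]
                     ) -> tuple[float, float, list[list[object]]]:
    """Overlap (≥1 shared bp, half-open) between two interval sets.

    Returns (fraction of queries touched by ≥1 feature, fraction of
    features touched by ≥1 query, per-query feature-label lists).
    """
    trees: dict[str, IntervalTree] = {}
    for i, (chrom, start, end, label) in enumerate(features):
        if end > start:
            trees.setdefault(chrom, IntervalTree()).addi(start, end, (i, label))

    per_query: list[list[object]] = []
    hit_features: set[int] = set()
    n_hit_queries = 0
    for chrom, start, end in queries:
        tree = trees.get(chrom)
        found = sorted(tree.overlap(start, end)) if tree is not None else []
        labels = [iv.data[1] for iv in found]
        per_query.append(labels)
        if labels:
            n_hit_queries += 1
            hit_features.update(iv.data[0] for iv in found)

    q_frac = n_hit_queries / len(queries) if queries else 0.0
    f_frac = len(hit_features) / len(features) if features else 0.0
    return q_frac, f_frac, per_query


def group_specific_snps(table: pd.DataFrame, focal_group: str,
                        fixation_threshold: float = 0.9
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SNPs whose alternate allele occurs only in the focal group.

    Specific: p > 0 in the focal group and p = 0 (among called alleles)
    in every other group.  The nearly-fixed subset additionally has
    p > ``fixation_threshold`` (strict) in the focal group.  Frequencies
    are taken among called alleles; missing genotypes are ignored.
    """
    from .variants import group_names

    groups = group_names(table)
    if focal_group not in groups:
        raise ValueError(f"unknown group {focal_group!r}")
    p_focal = table[f"p_{focal_group}"].to_numpy(dtype=float)
    specific = p_focal > 0
    for g in groups:
        if g == focal_group:
            continue
        p_other = table[f"p_{g}"].to_numpy(dtype=float)
        specific &= np.where(np.isnan(p_other), True, p_other == 0)
    specific &= ~np.isnan(p_focal)
    spec_t = table.loc[specific].reset_index(drop=True)
    fixed_t = spec_t.loc[
        spec_t[f"p_{focal_group}"] > fixation_threshold].reset_index(drop=True)
    return spec_t, fixed_t


def category_enrichment(observed: dict[str, float],
                        genome: dict[str, float]) -> dict[str, float]:
    """Observed/expected ratio per category; NaN where genome mass is 0."""
    out = {}
    for cat, obs in observed.items():
        g = genome.get(cat, 0.0)
        if g == 0.0:
            logger.warning("category %s has zero genome fraction", cat)
            out[cat] = float("nan")
        else:
            out[cat] = obs / g
    return out
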