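"""Shared fixtures: tiny VCF cohorts and a toy genome annotation."""

import textwrap

import numpy as np
import pytest

from sweepscan import simdata
from sweepscan.annotate import GenomeAnnotation, Transcript


def wc_fst_oracle(n1, p1, h1, n2, p2, h2):
    """Straight-line two-population Weir–Cockerham components.

    Independent of the vectorized implementation: scalar arithmetic
    transcribed directly from the estimator's definition, used as the
    oracle in equivalence tests.
    """
    r = 2
    n_bar = (n1 + n2) / r
    n_c = (r * n_bar - (n1 * n1 + n2 * n2) / (r * n_bar)) / (r - 1)
    p_bar = (n1 * p1 + n2 * p2) / (r * n_bar)
    s2 = (n1 * (p1 - p_bar) ** 2 + n2 * (p2 - p_bar) ** 2) / ((r - 1) * n_bar)
    h_bar = (n1 * h1 + n2 * h2) / (r * n_bar)
    a = (n_bar / n_c) * (
        s2 - (p_bar * (1 - p_bar) - s2 * (r - 1) / r - h_bar / 4) / (n_bar - 1)
    )
    b = (n_bar / (n_bar - 1)) * (
        p_bar * (1 - p_bar) - s2 * (r - 1) / r
        - h_bar * (2 * n_bar - 1) / (4 * n_bar)
    )
    c = h_bar / 2
    return a, b, c


@pytest.fixture(scope="session")
def tiny_cohort(tmp_path_factory):
    """A small simulated two-group cohort written to disk (VCF + map + truth)."""
    out = tmp_path_factory.mktemp("tiny_cohort")
    cfg = simdata.SimulationConfig(
        chrom_lengths={"chr1": 400_000, "chr2": 200_000},
        snp_density=0.002,
        sweeps=(simdata.SweepSpec("chr1", 100_000, 200_000, 1),),
        info_failure_rate=0.05,
        seed=11,
    )
    paths = simdata.emit_dataset(cfg, str(out))
    return cfg, paths


@pytest.fixture(scope="session")
def handmade_vcf(tmp_path_factory):
    """A hand-written VCF covering counting, filtering and class edge cases."""
    out = tmp_path_factory.mktemp("handmade")
    body = textwrap.dedent("""\
        ##fileformat=VCFv4.2
        ##contig=<ID=chr1,length=100000>
        ##INFO=<ID=QD,Number=1,Type=Float,Description="QD">
        ##INFO=<ID=FS,Number=1,Type=Float,Description="FS">
        ##INFO=<ID=MQ,Number=1,Type=Float,Description="MQ">
        ##INFO=<ID=SOR,Number=1,Type=Float,Description="SOR">
        ##INFO=<ID=MQRankSum,Number=1,Type=Float,Description="MQRankSum">
        ##INFO=<ID=ReadPosRankSum,Number=1,Type=Float,Description="ReadPosRankSum">
        ##INFO=<ID=InbreedingCoeff,Number=1,Type=Float,Description="InbreedingCoeff">
        ##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
        #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ta1\ta2\ta3\tb1\tb2\tb3
        chr1\t100\t.\tA\tG\t50\t.\tQD=25;FS=1;MQ=60;SOR=1\tGT\t0/0\t0/1\t1/1\t0/0\t0/0\t0/0
        chr1\t200\t.\tA\tG\t50\t.\tQD=1.5;FS=1;MQ=60;SOR=1\tGT\t0/1\t0/1\t0/1\t0/1\t0/1\t0/1
        chr1\t300\t.\tA\tG\t50\t.\tQD=2.0;FS=60.0;MQ=40.0;SOR=3.0;MQRankSum=-12.5;ReadPosRankSum=-8.0\tGT\t0/1\t0/0\t0/0\t1/1\t1/1\t1/1
        chr1\t400\t.\tA\tAT\t50\t.\tQD=25;FS=150\tGT\t0/1\t0/1\t0/1\t0/0\t0/0\t0/0
        chr1\t500\t.\tA\tAT\t50\t.\tQD=25;FS=250\tGT\t0/1\t0/1\t0/1\t0/0\t0/0\t0/0
        chr1\t600\t.\tA\tG,T\t50\t.\tQD=25\tGT\t0/1\t0/2\t0/0\t0/0\t0/0\t0/0
        chr1\t700\t.\tA\tG\t50\t.\tQD=25\tGT\t0/0\t0/0\t0/0\t0/0\t0/0\t0/0
        chr1\t800\t.\tA\tG\t50\t.\tQD=25\tGT\t./.\t./.\t./.\t0/1\t0/1\t0/0
        chr1\t900\t.\tA\tG\t50\t.\tQD=25\tGT\t0/1\t1/1\t0/0\t0/0\t0/1\t0/0
        """)
    vcf = out / "hand.vcf"
    vcf.write_text(body)
    pop_map = out / "popmap.tsv"
    pop_map.write_text("a1\tA\na2\tA\na3\tA\nb1\tB\nb2\tB\nb3\tB\n")
    return str(vcf), str(pop_map)


@pytest.fixture(scope="session")
def toy_annotation(tmp_path_factory):
    """Two genes on a 20 kb toy chromosome, plus a minus-strand gene.

    geneA (+, coding): tx 2000-6000; exons 2000-3000 and 5000-6000,
    CDS 2300-3000 + 5000-5700, UTR5 2000-2300, UTR3 5700-6000.
    geneB (+, coding): tx 8000-9000, single-exon CDS.
    geneN (ncRNA): 12000-13000.
    geneC (-, coding): tx 15000-15300, single-exon CDS on the minus strand.
    """
    out = tmp_path_factory.mktemp("toy_genome")
    rng = np.random.default_rng(5)
    seq = list(rng.choice(list("ACGT"), size=20_000))
    # plant codons at known positions (0-based): geneB CDS starts at 8000
    seq[8000:8009] = list("ATGCGGGGA")  # M, R(CGG), G(GGA)
    seq[8009:8012] = list("TGG")        # W (stop-gain target TGG->TAG)
    # geneC (minus strand) CDS 15000-15300; plus-strand CCA at 15291-15294
    # reads TGG (W) on the minus strand
    seq[15291:15294] = list("CCA")
    fasta = out / "toy.fa"
    fasta.write_text(">chr1\n" + "".join(seq) + "\n")

    transcripts = [
        Transcript("geneA.t1", "chr1", "+", 2000, 6000,
                   exons=[(2000, 3000), (5000, 6000)],
                   cds=[(2300, 3000), (5000, 5700)],
                   utr5=[(2000, 2300)], utr3=[(5700, 6000)]),
        Transcript("geneB.t1", "chr1", "+", 8000, 9000,
                   exons=[(8000, 9000)], cds=[(8000, 8999 - (999 % 3))]),
        Transcript("geneN.t1", "chr1", "+", 12_000, 13_000,
                   exons=[(12_000, 13_000)], coding=False),
        Transcript("geneC.t1", "chr1", "-", 15_000, 15_300,
                   exons=[(15_000, 15_300)], cds=[(15_000, 15_300)]),
    ]
    from pyfaidx import Fasta
    return GenomeAnnotation(transcripts, Fasta(str(fasta)))
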