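"""Shared fixtures: plain-text SAM/VCF builders around the KRAS G12 locus
and small reproducible cohorts."""

from __future__ import annotations

import textwrap
from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from krasdose.dosage import G12_HG19
from krasdose.simulate import SimulationConfig, generate_cohort

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

# G12 codon occupies 1-based 25,398,283-25,398,285 (plus-strand ACC).
CODON_START1 = G12_HG19.codon_positions[0]
READ_START1 = CODON_START1 - 20  # codon at read offset 20..22
REF_FLANK_L = "ACGTACGTACGTACGTACGT"          # 20 bp
REF_FLANK_R = "TGCATGCATGCATGCATGCATGCATGC"   # 27 bp
WT_READ = REF_FLANK_L + "ACC" + REF_FLANK_R   # 50 bp, wild-type codon
G12D_READ = REF_FLANK_L + "ATC" + REF_FLANK_R  # middle base C>T: Gly->Asp
SYN_READ = REF_FLANK_L + "GCC" + REF_FLANK_R   # first base A>G: synonymous Gly


def write_sam(path: Path, reads: list[tuple]) -> Path:
    """reads: (name, flag, pos1, mapq, cigar, seq, qual_char)."""
    lines = ["@HD\tVN:1.6\tSO:coordinate", "@SQ\tSN:chr12\tLN:25500000"]
    for name, flag, pos1, mapq, cigar, seq, qc in reads:
        qual = qc * len(seq)
        lines.append(
            f"{name}\t{flag}\t{r'chr12'}\t{pos1}\t{mapq}\t{cigar}\t*\t0\t0\t{seq}\t{qual}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


@pytest.fixture
def sam_factory(tmp_path):
    def _make(reads, name="fixture.sam"):
        return write_sam(tmp_path / name, reads)

    return _make


def write_vcf(path: Path, body_rows: list[str]) -> Path:
    header = textwrap.dedent("""\
        ##fileformat=VCFv4.2
        ##FILTER=<ID=PASS,Description="ok">
        ##FILTER=<ID=germline,Description="germline evidence">
        ##INFO=<ID=AF,Number=A,Type=Float,Description="allele frequency">
        ##FORMAT=<ID=GT,Number=1,Type=String,Description="genotype">
        ##FORMAT=<ID=AD,Number=R,Type=Integer,Description="allelic depths">
        ##FORMAT=<ID=AF,Number=A,Type=Float,Description="allele fraction">
        ##contig=<ID=chr12,length=25500000>
        #CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR
        """)
    path.write_text(header + "\n".join(body_rows) + "\n")
    return path


@pytest.fixture
def vcf_factory(tmp_path):
    def _make(rows, name="fixture.vcf"):
        return write_vcf(tmp_path / name, rows)

    return _make


@pytest.fixture(scope="session")
def small_cohort():
    """193-patient default-seed synthetic cohort with a desk-scale TS depth."""
    cfg = SimulationConfig(n_patients=193, seed=11, depth_ts=50_000)
    return cfg, generate_cohort(cfg)


@pytest.fixture
def toy_survival():
    """20 subjects, two groups, mixed censoring; frozen by seed."""
    rng = np.random.default_rng(7)
    g = np.repeat([0, 1], 10)
    t = np.round(rng.exponential(12 * np.exp(0.7 * g)), 1) + 0.1
    e = (rng.random(20) < 0.8).astype(int)
    return t, e, g
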