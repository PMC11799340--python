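"""KRAS hotspot mutation-dosage quantification.

Mutation dosage is the mutant read count divided by the total read count at
a hotspot codon — equivalently the variant allele frequency for DNA assays.
Dosage can be computed from three kinds of input:

* allele-count tables (the canonical exchange format),
* indexed BAM/CRAM or plain SAM alignments (read-level codon counting),
* VCF records carrying allelic depths (AD) or an allele-frequency field.

KRAS sits on the reverse strand; all coordinates and codon bases here are
in genomic (plus-strand) orientation, and "mutant" means any substitution
that changes the encoded amino acid of the hotspot codon (G12D/V/R/C/A/S
are treated as one entity).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "TargetLocus",
    "AlleleCounts",
    "CopyNumberState",
    "DosageProfile",
    "G12_HG19",
    "G12_HG38",
    "Q61_HG19",
    "Q61_HG38",
    "count_alleles_at_codon",
    "compute_dosage",
    "vaf_from_vcf",
    "adjust_for_cnv",
    "classify_clonality",
    "build_dosage_profiles",
]

MODALITIES = ("RNA", "WES", "TS")
CODONS = ("G12", "Q61")


@dataclasses.dataclass(frozen=True)
class TargetLocus:
    """A hotspot codon: three consecutive 1-based genomic positions."""

    chrom: str
    codon_positions: tuple[int, int, int]
    reference_codon: str  # genomic orientation
    gene_strand: str  # "+" or "-"
    build: str

    def __post_init__(self):
        p = self.codon_positions
        if len(p) != 3 or not (p[0] + 1 == p[1] and p[1] + 1 == p[2]):
            raise ValueError("codon_positions must be three consecutive ascending coords")
        if len(self.reference_codon) != 3:
            raise ValueError("reference_codon must be three bases")
        if self.gene_strand not in ("+", "-"):
            raise ValueError("gene_strand must be '+' or '-'")

    @property
    def start0(self) -> int:
        """0-based half-open start."""
        return self.codon_positions[0] - 1

    @property
    def end0(self) -> int:
        return self.codon_positions[2]

    def amino_acid(self, genomic_codon: str) -> str:
        """Translate a genomic-orientation codon respecting gene strand."""
        s = Seq(genomic_codon.upper())
        if self.gene_strand == "-":
            s = s.reverse_complement()
        return str(s.translate())

    @property
    def reference_aa(self) -> str:
        return self.amino_acid(self.reference_codon)


# KRAS codon-12 (glycine; genomic plus-strand ACC since the gene is on the
# reverse strand) and codon-61 (glutamine, plus-strand TTG) presets.
G12_HG19 = TargetLocus("chr12", (25_398_283, 25_398_284, 25_398_285), "ACC", "-", "hg19")
G12_HG38 = TargetLocus("chr12", (25_245_348, 25_245_349, 25_245_350), "ACC", "-", "hg38")
Q61_HG19 = TargetLocus("chr12", (25_380_275, 25_380_276, 25_380_277), "TTG", "-", "hg19")
Q61_HG38 = TargetLocus("chr12", (25_227_340, 25_227_341, 25_227_342), "TTG", "-", "hg38")

LOCUS_PRESETS: Mapping[tuple[str, str], TargetLocus] = {
    ("G12", "hg19"): G12_HG19,
    ("G12", "hg38"): G12_HG38,
    ("Q61", "hg19"): Q61_HG19,
    ("Q61", "hg38"): Q61_HG38,
}


@dataclasses.dataclass(frozen=True)
class AlleleCounts:
    """Read counts at a hotspot codon for one sample and modality."""

    mutant_reads: int
    wildtype_reads: int
    other_reads: int = 0
    modality: str = "TS"
    codon: str = "G12"

    def __post_init__(self):
        if min(self.mutant_reads, self.wildtype_reads, self.other_reads) < 0:
            raise ValueError("read counts must be non-negative")
        if self.modality not in MODALITIES:
            raise ValueError(f"modality must be one of {MODALITIES}")
        if self.codon not in CODONS:
            raise ValueError(f"codon must be one of {CODONS}")

    @property
    def total(self) -> int:
        return self.mutant_reads + self.wildtype_reads + self.other_reads


@dataclasses.dataclass(frozen=True)
class CopyNumberState:
    total_copies: float
    purity: float | None = None

    def __post_init__(self):
        if self.total_copies < 0:
            raise ValueError("total_copies must be >= 0")
        if self.purity is not None and not (0 < self.purity <= 1):
            raise ValueError("purity must be in (0, 1]")


@dataclasses.dataclass
class DosageProfile:
    patient_id: str
    dosage_rna: float | None = None
    dosage_wes: float | None = None
    dosage_ts: float | None = None
    adjusted_dosage_ts: float | None = None
    dosage_q61_ts: float | None = None
    clonality: str = "none"


# ---------------------------------------------------------------------------
# read-level counting
# ---------------------------------------------------------------------------

def count_alleles_at_codon(
    alignment_source,
    locus: TargetLocus,
    min_mapq: int = 20,
    min_baseq: int = 20,
    modality: str = "TS",
) -> AlleleCounts:
    """Count mutant / wild-type / other reads spanning a hotspot codon.

    ``alignment_source`` is a path to a SAM/BAM/CRAM file or an open
    ``pysam.AlignmentFile``.  A read contributes once.  Reads failing the
    mapping- or base-quality thresholds are excluded outright.  Reads that
    pass quality but do not cleanly span all three codon positions
    (partial overlap, indel across the codon) or contain N, or carry a
    synonymous change, count as "other".
    """
    import pysam

    if min_mapq < 0 or min_baseq < 0:
        raise ValueError("quality thresholds must be >= 0")

    opened = False
    if isinstance(alignment_source, (str, bytes)) or hasattr(alignment_source, "__fspath__"):
        af = pysam.AlignmentFile(str(alignment_source))
        opened = True
    else:
        af = alignment_source

    contigs = set(af.references or ())
    if contigs and locus.chrom not in contigs:
        if opened:
            af.close()
        raise ValueError(f"contig {locus.chrom!r} absent from alignment header")

    try:
        try:
            reads = af.fetch(locus.chrom, locus.start0, locus.end0)
            reads = list(reads)
        except ValueError:
            # no index (plain SAM): stream and filter by overlap
            reads = [
                r
                for r in af.fetch(until_eof=True)
                if (not r.is_unmapped)
                and r.reference_name == locus.chrom
                and r.reference_start < locus.end0
                and (r.reference_end or 0) > locus.start0
            ]
        mutant = wildtype = other = 0
        ref_aa = locus.reference_aa
        want = {locus.start0, locus.start0 + 1, locus.start0 + 2}
        for r in reads:
            if r.is_unmapped or r.is_secondary or r.is_supplementary or r.is_duplicate:
                continue
            if r.mapping_quality < min_mapq:
                continue
            pairs = {rp: qp for qp, rp in r.get_aligned_pairs() if rp in want}
            qpos = [pairs.get(p) for p in sorted(want)]
            if any(q is None for q in qpos) or len(pairs) < 3:
                other += 1  # partial span or deletion over the codon
                continue
            if qpos[1] != qpos[0] + 1 or qpos[2] != qpos[1] + 1:
                other += 1  # insertion inside the codon
                continue
            quals = r.query_qualities
            if quals is not None and any(quals[q] < min_baseq for q in qpos):
                continue
            seq = r.query_sequence
            codon = "".join(seq[q] for q in qpos).upper()
            if "N" in codon:
                other += 1
            elif codon == locus.reference_codon.upper():
                wildtype += 1
            elif locus.amino_acid(codon) != ref_aa:
                mutant += 1
            else:
                other += 1  # synonymous change
        return AlleleCounts(mutant, wildtype, other, modality=modality,
                            codon="Q61" if locus.reference_codon.upper() == "TTG" else "G12")
    finally:
        if opened:
            af.close()


def compute_dosage(counts: AlleleCounts) -> float | None:
    """Mutant reads over total reads; None when no reads span the codon."""
    if counts.total == 0:
        return None
    d = counts.mutant_reads / counts.total
    return float(d)


# ---------------------------------------------------------------------------
# VCF path
# ---------------------------------------------------------------------------

def _codon_with_alt(locus: TargetLocus, pos1: int, ref: str, alt: str) -> str | None:
    """Substitute an alt allele into the codon; None if not a clean
    length-preserving substitution inside the codon."""
    if len(ref) != len(alt):
        return None  # indel
    start, end = pos1, pos1 + len(ref) - 1
    if start > locus.codon_positions[2] or end < locus.codon_positions[0]:
        return None
    codon = list(locus.reference_codon.upper())
    for off, (rb, ab) in enumerate(zip(ref.upper(), alt.upper())):
        p = pos1 + off
        if locus.codon_positions[0] <= p <= locus.codon_positions[2]:
            i = p - locus.codon_positions[0]
            if codon[i] != rb:
                return None  # REF disagrees with the locus reference codon
            codon[i] = ab
    return "".join(codon)


def vaf_from_vcf(record, locus: TargetLocus, sample: str | None = None) -> float | None:
    """Tumor-sample VAF of amino-acid-changing alleles at the hotspot codon.

    ``record`` is a ``pysam.VariantRecord``.  Allelic depths (AD) are
    preferred, with the per-allele VAF defined as AD_alt over the total AD
    of the site; distinct hotspot-changing alt alleles are summed.  Falls
    back to the AF field when AD is absent.  Returns None for filtered
    (non-PASS) records or when no alt allele changes the amino acid.
    """
    filters = list(record.filter.keys())
    if filters and filters != ["PASS"]:
        return None
    if record.chrom.removeprefix("chr") != locus.chrom.removeprefix("chr"):
        return None

    alts = record.alts or ()
    changing = []
    ref_aa = locus.reference_aa
    for i, alt in enumerate(alts):
        if alt is None or set(alt.upper()) - set("ACGT"):
            continue
        codon = _codon_with_alt(locus, record.pos, record.ref, alt)
        if codon is not None and locus.amino_acid(codon) != ref_aa:
            changing.append(i)
    if not changing:
        return None

    smp = None
    if record.samples is not None and len(record.samples) > 0:
        name = sample if sample is not None else list(record.samples)[0]
        smp = record.samples[name]

    if smp is not None and "AD" in smp and smp["AD"] is not None and smp["AD"][0] is not None:
        ad = np.asarray(smp["AD"], dtype=float)
        total = ad.sum()
        if total > 0:
            return float(sum(ad[i + 1] for i in changing) / total)

    af = None
    if smp is not None and "AF" in smp and smp["AF"] is not None:
        af = smp["AF"]
    elif "AF" in record.info:
        af = record.info["AF"]
    if af is not None:
        af = np.atleast_1d(np.asarray(af, dtype=float))
        return float(sum(af[i] for i in changing if i < af.size))
    raise ValueError("record carries neither AD nor AF")


# ---------------------------------------------------------------------------
# CNV adjustment & clonality
# ---------------------------------------------------------------------------

def adjust_for_cnv(dosage: float, cn: CopyNumberState) -> float:
    """Copy-neutral renormalization: dosage x 2 / total_copies, clamped to
    [0, 1]."""
    if not 0 <= dosage <= 1:
        raise ValueError("dosage must be in [0, 1]")
    if cn.total_copies == 0:
        raise ValueError("total_copies must be > 0 for CNV adjustment")
    return float(min(1.0, dosage * 2.0 / cn.total_copies))


def classify_clonality(
    dosage_g12: float | None,
    dosage_q61: float | None = None,
    threshold: float = 0.195,
    transition_rule: bool = True,
    min_detect: float = 0.005,
) -> tuple[str, float | None]:
    """Label the mutation pattern and return the effective grouping dosage.

    Returns ``(label, effective_dosage)`` where the label is ``none``
    (no mutant signal at either codon), ``subclonal_g12_q61`` (Q61
    signal on top of G12) or ``clonal_g12``.  ``min_detect`` is the
    detection floor: dosages at or below it are treated as absent, since
    ultra-deep sequencing always yields a nonzero miscall background at
    the hotspot (~error_rate/3).  With the transition rule enabled a high
    Q61 dosage can move a patient into the high group: the effective
    dosage is max(G12, Q61); otherwise it is G12 alone.
    """
    g = dosage_g12 if (dosage_g12 is not None and dosage_g12 > min_detect) else 0.0
    q = dosage_q61 if (dosage_q61 is not None and dosage_q61 > min_detect) else 0.0
    if g <= 0 and q <= 0:
        return "none", (None if dosage_g12 is None else 0.0)
    label = "subclonal_g12_q61" if q > 0 else "clonal_g12"
    effective = max(g, q) if transition_rule else g
    return label, float(effective)


# ---------------------------------------------------------------------------
# cohort-level profiles
# ---------------------------------------------------------------------------

def build_dosage_profiles(
    count_table: pd.DataFrame,
    cn_table: pd.DataFrame | None = None,
    q61_threshold: float = 0.195,
    transition_rule: bool = True,
) -> pd.DataFrame:
    """Per-patient dosage profiles from an allele-count table.

    ``count_table`` columns: patient_id, modality, codon, mutant_reads,
    wildtype_reads, other_reads.  Optional ``cn_table`` columns:
    patient_id, kras_total_copies[, purity].  Missing modalities yield NaN
    dosages.  Duplicate (patient, modality, codon) rows are an error.
    """
    required = {"patient_id", "modality", "codon", "mutant_reads", "wildtype_reads", "other_reads"}
    missing = required - set(count_table.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    dup = count_table.duplicated(subset=["patient_id", "modality", "codon"])
    if dup.any():
        bad = count_table.loc[dup, ["patient_id", "modality", "codon"]].iloc[0].tolist()
        raise ValueError(f"duplicate (patient, modality, codon) rows, e.g. {bad}")

    cn_map = {}
    if cn_table is not None:
        cn_map = dict(zip(cn_table["patient_id"], cn_table["kras_total_copies"]))

    rows = []
    for pid, grp in count_table.groupby("patient_id", sort=True):
        prof = DosageProfile(patient_id=str(pid))
        for _, r in grp.iterrows():
            counts = AlleleCounts(
                int(r["mutant_reads"]), int(r["wildtype_reads"]), int(r["other_reads"]),
                modality=str(r["modality"]), codon=str(r["codon"]),
            )
            d = compute_dosage(counts)
            if r["codon"] == "G12":
                if r["modality"] == "RNA":
                    prof.dosage_rna = d
                elif r["modality"] == "WES":
                    prof.dosage_wes = d
                elif r["modality"] == "TS":
                    prof.dosage_ts = d
            elif r["codon"] == "Q61" and r["modality"] == "TS":
                prof.dosage_q61_ts = d
        if prof.dosage_ts is not None and pid in cn_map:
            prof.adjusted_dosage_ts = adjust_for_cnv(
                prof.dosage_ts, CopyNumberState(float(cn_map[pid]))
            )
        prof.clonality, _ = classify_clonality(
            prof.dosage_ts, prof.dosage_q61_ts, q61_threshold, transition_rule
        )
        rows.append(dataclasses.asdict(prof))
    cols = ["patient_id", "dosage_rna", "dosage_wes", "dosage_ts",
            "adjusted_dosage_ts", "dosage_q61_ts", "clonality"]
    out = pd.DataFrame(rows, columns=cols)
    for c in cols[1:-1]:
        out[c] = pd.to_numeric(out[c])  # None -> NaN, float dtype
    return out
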