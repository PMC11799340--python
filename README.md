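# krasdose

Quantification of **KRAS G12 mutation dosage** across sequencing
modalities and a **3-point preoperative prognostic score** for resected
pancreatic ductal adenocarcinoma (PDAC), built as a tested, reusable
pipeline.

## The problem

Nearly all PDACs are driven by hotspot substitutions at KRAS codon 12.
The *mutation dosage* — the fraction of reads carrying the mutant allele
at the hotspot,

```
dosage = mutant reads / total reads  (≡ VAF for DNA assays)
```

— integrates tumor purity, copy state and clonal architecture into a
single number that is prognostic after resection. Under a simple mixture
model, a tumor with purity *p*, KRAS copy number *c* (of which *m* are
mutant) against diploid normal contamination has expected DNA VAF

```
VAF = p·m / (p·c + 2(1−p))
```

so at copy-neutral heterozygosity dosage is purity/2 and rises with
purity. RNA dosage additionally reflects allele-specific expression and
sits systematically above the DNA VAF.

The pipeline:

1. **quantifies dosage** per patient and modality (ultra-deep targeted
   sequencing "TS" at ≥10⁶×, whole-exome "WES" at ~300×, RNA-seq at
   variable depth) from allele-count tables, SAM/BAM alignments, or VCF
   allelic depths, with optional copy-number renormalization
   (dosage × 2 / copies) and G12/Q61 clonality classification;
2. **selects high/low dosage thresholds** by maximally selected log-rank
   statistics — the global optimum, or distinct local maxima of the
   statistic profile for bimodal TS dosage distributions;
3. **assigns the prognostic score**: 1 point each for tumor diameter
   > 20 mm, CA 19-9 > 150 U/mL, and TS dosage > 0.195 (alternative
   threshold 0.139), and summarizes survival per stratum: Kaplan–Meier
   medians, 1/3/5-year OS and RFS rates, and Cox hazard ratios versus
   the 0-point stratum.

Kaplan–Meier, the k-group log-rank test and Cox proportional-hazards
regression (Efron ties, Newton–Raphson) are implemented from first
principles in `krasdose.survival` and are cross-checked against
independent oracles (permutation references, lifelines) in the test
suite. Because matched patient-level multiomic data are controlled
access, the package ships a synthetic-cohort generator
(`krasdose.simulate`) that reproduces the statistical structure of such
a cohort — low-purity tumors, rare KRAS amplification, rare Q61
subclones, modality-specific depths, dosage-dependent hazards — so the
whole pipeline is testable end to end from a seed.

## Worked example

```sh
krasdose run --simulate --n 193 --seed 7 --out demo
cat demo/report.txt
```

```
Prognostic score report
======================

thresholds: size > 20.0 mm, CA 19-9 > 150.0 U/mL, dosage > 0.195 (TS, primary)

OS by score (n=193)
score     n   share  median  1y     3y     5y     HR
    0    14    7.3%    79.9  100.0%  91.7%  75.0%  1.00 (Reference)
    1    81   42.0%    52.9   91.1%  64.5%  44.8%  1.78 (0.81, 3.94)
    2    86   44.6%    30.4   74.8%  38.8%  18.9%  4.04 (1.83, 8.93)
    3    12    6.2%    18.7   66.7%  33.3%  22.2%  5.35 (1.91, 15.03)

RFS by score (n=193)
score     n   share  median  1y     3y     5y     HR
    0    14    7.3%    34.6  100.0%  50.0%  41.7%  1.00 (Reference)
    1    81   42.0%    20.0   72.5%  34.2%  12.7%  2.10 (1.08, 4.10)
    2    86   44.6%    12.3   50.4%   6.2%   3.1%  4.46 (2.27, 8.77)
    3    12    6.2%     5.8   25.1%  12.6%   0.0%  7.16 (2.84, 18.04)
```

Reading the table: each row is a score stratum of the simulated
193-patient cohort. A 0-point patient (small tumor, low CA 19-9, low
dosage) has a median overall survival of 79.9 months and a 75.0% chance
of being alive at 5 years; a 3-point patient has a median of 18.7 months
and a hazard of death 5.35 times higher (95% CI 1.91–15.03, Cox model
with score as a factor). Medians and hazard ratios degrade monotonically
with the score, which is the property the score is built to deliver.
The run also writes `report.json` (full precision), per-stratum KM
curves (`km_os_by_score.tsv`, `km_rfs_by_score.tsv`), group-comparison
tables (`table1.tsv`, `table2.tsv`), the dosage table and the cutpoint
scan profile. Reruns with the same seed are byte-identical.

Other entry points: `krasdose simulate | dosage | cutpoint | score |
survstats` — each a thin wrapper over the library (see `--help`), and
the same operations are importable from Python
(`krasdose.dosage.compute_dosage`, `krasdose.cutpoint.scan_cutpoints`,
`krasdose.survival.cox_fit`, ...).

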