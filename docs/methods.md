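# Methods

This note documents the models, defaults and numerical choices behind
`krasdose`, and what the synthetic cohort does and does not establish
about real data.

## Dosage model

Mutation dosage at a hotspot codon is the mutant read fraction. For a
tumor of purity *p* ∈ (0, 1], KRAS total copy number *c* with *m*
mutant copies, diluted by diploid normal cells, the expected DNA VAF is

    VAF(p, c, m) = p·m / (p·c + 2(1 − p)).

RNA dosage uses the same mixture with a multiplicative mutant-allele
expression bias *b*:

    RNA(p, c, m, b) = p·m·b / (p·(m·b + (c − m)) + 2(1 − p)),

which reduces to the DNA VAF at *b* = 1 and exceeds it for *b* > 1. The
bias term is a modeling device for the empirical observation that RNA
dosage runs above DNA VAF; it is not a mechanistic claim (allele-specific
expression, post-transcriptional editing and RNA capture artifacts are
not distinguished).

**CNV adjustment** renormalizes to the copy-neutral scale:
`dosage × 2 / copies`, clamped to [0, 1]. This is a deliberate,
simple convention — identity at two copies, halving at four — chosen
because amplification inflates the mutant fraction when the mutant
allele is the amplified one.

**Read counting.** A read contributes once. Reads failing mapping- or
base-quality thresholds (defaults MAPQ ≥ 20, base Q ≥ 20, standard
pileup practice) are excluded. Reads that pass quality but do not
cleanly span all three codon bases (partial overlap, indel across the
codon, N) count as *other*, as do synonymous codon changes; *mutant*
means any amino-acid-changing codon substitution, so G12D/V/R/C/A/S are
one entity. KRAS is on the reverse strand; coordinates and codon bases
are handled in genomic orientation and translated strand-aware. The G12
locus ships as hg19 (chr12:25,398,283–285) and hg38
(chr12:25,245,348–350) presets, Q61 likewise; coordinates are 1-based
inclusive externally and half-open internally.

**VCF path.** Allelic depths are preferred, with per-allele VAF =
AD_alt / ΣAD; distinct amino-acid-changing alt alleles at the codon are
summed (dosage is defined per codon, not per allele). The AF field is
the fallback. Non-PASS records yield an undefined dosage.

**Clonality.** A Q61 signal on top of the clonal G12 mutation labels
the patient subclonal; with the transition rule enabled the grouping
dosage is max(G12, Q61), so a high-Q61 patient can move into the
high-dosage group. Because ultra-deep pileups always carry a miscall
background (~error/3 ≈ 3×10⁻⁴ at the default error rate), presence
calls use a detection floor `min_detect = 0.005` — ~15× the error floor
and well below genuine subclonal VAFs (median ≈ 0.07 under the default
simulation). Without a floor every deep pileup would be "subclonal".

## Cutpoint selection

Candidates are midpoints between consecutive distinct observed dosages
(rank-based, hence invariant to monotone transforms), subject to a
minimum group size of 10 per side (~5% of a ~200-patient cohort; the
constraint's sole purpose is to keep the log-rank statistic
well-behaved at the tails). Each candidate's two-group log-rank
chi-square is computed with the package's own statistic; the
implementation is a vectorized profile verified to machine precision
against the standalone test.

*Global mode* returns the argmax (ties to the smaller cutoff).
*Local-maxima mode* merges plateaus (represented by their smallest
cutoff), finds interior maxima, filters and ranks them by **topographic
prominence** (minimum 2.0 chi-square units), and returns the top *k*
ascending. Prominence rather than raw height is used deliberately: on
densely sampled profiles the two highest local maxima are almost always
jitter points of the same peak, while prominence identifies genuinely
distinct peaks; with well-separated peaks the two rankings coincide. If
the profile is monotone the single boundary maximum is returned.

Per-cutoff p-values are naive chi-square(1) tails, matching how such
log-rank p-values are conventionally reported; because maximal selection
inflates them, `permutation_pvalue` provides an optional
selection-corrected p (off by default).

## Survival statistics

Implemented from first principles in `krasdose.survival`:

- **Kaplan–Meier** product-limit estimator; censoring at an event time
  is processed after the event. Median = smallest t with S(t) ≤ 0.5;
  year rates are right-continuous lookups at 12/36/60 months.
- **Log-rank** (k groups): observed − expected with hypergeometric
  variance, df = k − 1.
- **Cox PH**: Newton–Raphson on the Efron partial likelihood with step
  halving; convergence at max|score| < 1e-8 or relative log-likelihood
  change < 1e-10, ≤ 50 iterations; Wald 95% CI = exp(β ± 1.96·SE).
  Efron tie handling is the default because follow-up is recorded at
  month granularity and ties are common. Monotone likelihood (perfect
  separation) surfaces as a non-convergence flag with inflated
  coefficients rather than an exception.
- **Categorical/continuous comparisons**: Pearson chi-square without
  continuity correction (explicit Σ(O−E)²/E); Welch t; Mann–Whitney
  rank-sum (exact when tie-free, which coincides with the full
  permutation distribution of the rank statistic). All p-values are
  two-sided; no multiple-testing correction is applied anywhere.

Numerical cross-checks in the tests: the Cox score test at β = 0 equals
the log-rank chi-square to 1e-8 on tie-free data; coefficients and
standard errors match lifelines to 1e-6 on tied data; KM equals the
empirical survival function exactly without censoring. One accuracy
caveat is documented rather than hidden: at n = 20 the chi-square tail
of the log-rank statistic differs from the exact permutation p by up to
~0.02–0.03 even with no censoring; oracle-equivalence tests therefore
allow Monte-Carlo error plus a 0.025 small-sample term.

## Prognostic score

Strict ">" comparisons — diameter > 20 mm, CA 19-9 > 150 U/mL, dosage
> 0.195 (alternative 0.139) — so boundary values do not score; total in
{0..3}. Patients with undefined dosage from the selected source are
excluded with a warning. Stratified summaries fit per-stratum KM curves
and one factor-coded Cox model with the lowest observed score as
reference (HR exactly 1.00); a pairwise mode is not needed because the
factor coding nests it. Undefined medians render as "NA"; percentages
are displayed to one decimal but stored at full precision in JSON.
Recurrence timing: very early < 6 months ≤ early < 12 months ≤ late.

## Synthetic cohort

The generator emulates the cohort structure the analysis assumes;
defaults (all rates per month, times in months):

| parameter | default | rationale |
|---|---|---|
| purity | Beta(1.2, 6.0) scaled to [0.15, 1] | median ≈ 0.265, the low-purity profile of resected PDAC |
| amplification prob / copies | 0.026 / 4 (mutant allele amplified, m = c − 1) | amplification is rare and oncogenically selected |
| Q61 subclone prob / cell fraction | 0.073 / Beta(2, 2) | rare subclones with intermediate cell fractions |
| depths TS / WES / RNA | 10⁶ / 300 / log-uniform 20–2000 | modality-typical coverage at the hotspot |
| RNA allelic bias | 1.5 | places median RNA dosage above DNA VAF |
| sequencing error | 1e-3 per read, uniform miscall to the 3 other states | p_mut = v(1−e) + (1−v)e/3, p_other = 2e/3 |
| baseline hazards OS / RFS | ln2/97, ln2/58 | zero-risk-factor medians of 97 / 58 months |
| log-HRs dosage / size / CA 19-9 | ln 2.00 / ln 1.79 / ln 1.89 | per-factor hazard ratios of the magnitudes seen clinically |
| censoring | exponential, 0.008 | ~25–35% administrative censoring |
| tumor diameter | lognormal(ln 30, 0.5) mm | ~78% of tumors > 20 mm |
| CA 19-9 | lognormal(ln 130, 1.4) U/mL | ~46% above 150 U/mL |

Outcome construction: death and recurrence times are exponential with
proportional hazards on the three binary risk flags (the dosage flag
uses the *latent* expected VAF, so measurement noise attenuates rather
than inflates observed associations); censoring is independent
exponential; OS = min(death, censor) and RFS = min(recurrence, death,
censor) with death an RFS event, so RFS ≤ OS by construction.
Recurrence pattern (local 22% / distant) is drawn only when recurrence
itself ended the interval. One top-level seed spawns independent
per-patient PCG64 streams, so patient *i* is reproducible regardless of
cohort size.

**What the simulator does not model:** UMI/fragment-level errors,
alignment artifacts, purity *estimation* (purity and copy states are
latent truths, not inferred), correlated covariates (size, CA 19-9 and
purity are drawn independently), non-proportional hazards, and cohort
selection effects. Consequently, passing tests demonstrate that the
estimators recover planted structure under the stated model — they are
statements about the software and the statistics, not clinical
validation on real patients.

## Problem sizes

Default test-suite and acceptance-script sizes were chosen to make
Monte-Carlo conclusions stable at desk scale: Cox recovery at 100 seeds
× n = 1000, change-point recovery at 50 replicates × n = 200, log-rank
null calibration at 1000 simulations × n = 100, directional modality
claims on one n = 2000 cohort, and study-sized (n = 193) cohorts
elsewhere. The full suite runs in well under a minute.

## Known limitations

- The CNV adjustment and the Q61 transition rule are simple conventions;
  richer allele-specific models would need phased copy-number input.
- Naive per-cutoff p-values are anti-conservative under maximal
  selection; use the permutation p for inference about a selected
  cutoff.
- The Cox implementation covers time-fixed covariates only (no
  stratification, frailty, or time-varying effects).
- RNA dosage inflation is a single multiplicative bias; real
  allele-specific expression is locus- and patient-specific.
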