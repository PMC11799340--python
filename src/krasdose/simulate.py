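"""Synthetic PDAC cohort generator.

Emulates the statistical structure the dosage-prognosis analysis assumes:
latent tumor biology (purity, KRAS copy state, optional Q61 subclone) →
read-level allele counts per sequencing modality → preoperative clinical
covariates → survival and recurrence outcomes whose hazard increases with
high dosage, tumor diameter > 20 mm, and CA 19-9 > 150 U/mL.

The defaults encode the cohort the pipeline is designed for: purity in
[0.15, 1] with median ~0.265, rare KRAS amplification (2.6%), rare
subclonal Q61 co-mutation (7.3%), TS depth 1e6 / WES depth 300 / variable
RNA depth, a mutant-allele expression bias that pushes RNA dosage above
DNA VAF, and exponential event times in months with baseline medians of
97 (OS) and 58 (RFS) months for risk-factor-free patients.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np
import pandas as pd

from .dosage import AlleleCounts

__all__ = [
    "PurityMixture",
    "SimulationConfig",
    "LatentTumorState",
    "CohortBundle",
    "expected_vaf",
    "expected_rna_dosage",
    "simulate_patient",
    "simulate_pileup",
    "simulate_outcomes",
    "generate_cohort",
]

CLINICAL_COLUMNS = [
    "patient_id", "age_years", "sex", "asa_class", "location",
    "tumor_diameter_mm", "ca19_9_u_ml", "stage", "margin", "adjuvant_ctx",
    "os_months", "os_event", "rfs_months", "rfs_event", "recurrence_pattern",
]
COUNT_COLUMNS = ["patient_id", "modality", "codon",
                 "mutant_reads", "wildtype_reads", "other_reads"]
TRUTH_COLUMNS = ["patient_id", "purity", "total_copies", "mutant_copies_g12",
                 "q61_cell_fraction", "expected_vaf_g12", "expected_rna_dosage"]


@dataclasses.dataclass(frozen=True)
class PurityMixture:
    """Mixture of Beta components rescaled to [lo, hi].

    The single-component default Beta(1.2, 6.0) on [0.15, 1] has median
    ~0.264, matching the low-purity profile typical of resected PDAC.
    """

    components: tuple[tuple[float, float, float], ...] = ((1.0, 1.2, 6.0),)  # (weight, a, b)
    lo: float = 0.15
    hi: float = 1.0

    def __post_init__(self):
        w = sum(c[0] for c in self.components)
        if not math.isclose(w, 1.0, abs_tol=1e-9):
            raise ValueError("mixture weights must sum to 1")
        if not 0 <= self.lo < self.hi <= 1:
            raise ValueError("need 0 <= lo < hi <= 1")

    def sample(self, rng: np.random.Generator) -> float:
        w = [c[0] for c in self.components]
        k = rng.choice(len(self.components), p=w)
        _, a, b = self.components[k]
        x = rng.beta(a, b)
        return float(np.clip(self.lo + (self.hi - self.lo) * x, self.lo, self.hi))


@dataclasses.dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort; rates are per month."""

    n_patients: int = 193
    seed: int = 0
    purity_dist: PurityMixture = dataclasses.field(default_factory=PurityMixture)
    amplification_prob: float = 0.026
    amplified_copies: int = 4
    subclonal_q61_prob: float = 0.073
    q61_fraction_beta: tuple[float, float] = (2.0, 2.0)
    depth_ts: int = 1_000_000
    depth_wes: int = 300
    depth_rna_range: tuple[int, int] = (20, 2000)  # log-uniform
    rna_allelic_bias: float = 1.5
    sequencing_error: float = 1e-3
    baseline_hazard_os: float = math.log(2) / 97.0
    baseline_hazard_rfs: float = math.log(2) / 58.0
    log_hr_dosage: float = math.log(2.0)
    log_hr_size: float = math.log(1.79)
    log_hr_ca199: float = math.log(1.89)
    censor_rate: float = 0.008
    dosage_flag_threshold: float = 0.195
    size_lognorm: tuple[float, float] = (math.log(30.0), 0.5)   # P(>20mm) ~ 0.79
    ca199_lognorm: tuple[float, float] = (math.log(130.0), 1.4)  # P(>150) ~ 0.46
    local_recurrence_prob: float = 0.22

    def validate(self) -> None:
        probs = [self.amplification_prob, self.subclonal_q61_prob,
                 self.local_recurrence_prob]
        if any(not 0 <= p <= 1 for p in probs):
            raise ValueError("probabilities must be in [0, 1]")
        if not 0 <= self.sequencing_error <= 1:
            raise ValueError("sequencing_error must be in [0, 1]")
        if min(self.depth_ts, self.depth_wes, *self.depth_rna_range) < 1:
            raise ValueError("depths must be >= 1")
        rates = [self.baseline_hazard_os, self.baseline_hazard_rfs, self.censor_rate]
        if any(r <= 0 for r in rates):
            raise ValueError("hazard/censor rates must be > 0")
        if self.amplified_copies < 3:
            raise ValueError("amplified_copies must be >= 3")
        if self.n_patients < 0:
            raise ValueError("n_patients must be >= 0")
        if self.rna_allelic_bias < 0:
            raise ValueError("rna_allelic_bias must be >= 0")


@dataclasses.dataclass(frozen=True)
class LatentTumorState:
    purity: float
    total_copies: int
    mutant_copies_g12: int
    q61_cell_fraction: float
    expected_vaf_g12: float
    expected_vaf_q61: float
    expected_rna_dosage: float


@dataclasses.dataclass
class CohortBundle:
    clinical: pd.DataFrame
    allele_counts: pd.DataFrame
    truth: pd.DataFrame


# ---------------------------------------------------------------------------
# expected-dosage model
# ---------------------------------------------------------------------------

def expected_vaf(purity: float, total_copies: int, mutant_copies: int) -> float:
    """Expected DNA VAF of a somatic mutation.

    With tumor purity p, tumor-cell KRAS copy number c of which m carry the
    mutation, and diploid normal contamination:

        VAF = p*m / (p*c + 2*(1-p))
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    if total_copies < 1:
        raise ValueError("total_copies must be >= 1")
    if not 0 <= mutant_copies <= total_copies:
        raise ValueError("mutant_copies must be in [0, total_copies]")
    return purity * mutant_copies / (purity * total_copies + 2.0 * (1.0 - purity))


def expected_rna_dosage(
    purity: float, total_copies: int, mutant_copies: int, allelic_bias: float
) -> float:
    """Expected RNA dosage with multiplicative mutant-allele expression
    bias b: p*m*b / (p*(m*b + (c-m)) + 2*(1-p)); equals the DNA VAF at
    b = 1 and exceeds it for b > 1."""
    if allelic_bias < 0:
        raise ValueError("allelic_bias must be >= 0")
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    m, c, b, p = mutant_copies, total_copies, allelic_bias, purity
    denom = p * (m * b + (c - m)) + 2.0 * (1.0 - p)
    if denom == 0:
        return 0.0
    return p * m * b / denom


def simulate_patient(config: SimulationConfig, rng: np.random.Generator) -> LatentTumorState:
    """Draw one latent tumor state.  Every simulated patient carries a
    clonal G12 mutation; under amplification the mutant allele is the
    amplified one (m = c - 1)."""
    config.validate()
    purity = config.purity_dist.sample(rng)
    amplified = rng.random() < config.amplification_prob
    c = config.amplified_copies if amplified else 2
    m = c - 1 if amplified else 1
    q61_frac = 0.0
    if rng.random() < config.subclonal_q61_prob:
        a, b = config.q61_fraction_beta
        q61_frac = float(np.clip(rng.beta(a, b), 1e-6, 1.0))
    vaf_g12 = expected_vaf(purity, c, m)
    vaf_q61 = expected_vaf(purity * q61_frac, c, 1) if q61_frac > 0 else 0.0
    rna = expected_rna_dosage(purity, c, m, config.rna_allelic_bias)
    return LatentTumorState(purity, c, m, q61_frac, vaf_g12, vaf_q61, rna)


def simulate_pileup(
    expected_vaf_: float,
    depth: int,
    error_rate: float,
    rng: np.random.Generator,
    modality: str = "TS",
    codon: str = "G12",
) -> AlleleCounts:
    """Multinomial read counts at a codon.

    Each read is truly mutant with probability v; with probability e it is
    miscalled to one of the three other codon states uniformly, so
    p_mut = v(1-e) + (1-v)e/3 and p_other = 2e/3.
    """
    if depth < 0:
        raise ValueError("depth must be >= 0")
    v, e = expected_vaf_, error_rate
    p_mut = v * (1 - e) + (1 - v) * e / 3.0
    p_other = 2.0 * e / 3.0
    p_wt = 1.0 - p_mut - p_other
    mut, wt, other = rng.multinomial(depth, [p_mut, p_wt, p_other])
    return AlleleCounts(int(mut), int(wt), int(other), modality=modality, codon=codon)


def simulate_outcomes(
    risk_indicators: Sequence[int],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[float, int, float, int, str]:
    """Exponential OS/RFS with proportional hazards on three binary flags
    (dosage, size, CA 19-9) and independent exponential censoring.

    Returns (os_months, os_event, rfs_months, rfs_event,
    recurrence_pattern).  Death counts as an RFS event, so RFS <= OS
    always holds; recurrence_pattern is drawn only when recurrence itself
    (not death) ended the recurrence-free interval.
    """
    config.validate()
    f_dos, f_size, f_ca = (int(bool(x)) for x in risk_indicators)
    hr = math.exp(f_dos * config.log_hr_dosage + f_size * config.log_hr_size
                  + f_ca * config.log_hr_ca199)
    death = rng.exponential(1.0 / (config.baseline_hazard_os * hr))
    recur = rng.exponential(1.0 / (config.baseline_hazard_rfs * hr))
    censor = rng.exponential(1.0 / config.censor_rate)

    os_months = min(death, censor)
    os_event = int(death <= censor)
    rfs_raw = min(recur, death)
    rfs_months = min(rfs_raw, censor)
    rfs_event = int(rfs_raw <= censor)
    recurred = recur < min(death, censor)
    pattern = ""
    if recurred:
        pattern = "local" if rng.random() < config.local_recurrence_prob else "distant"
    return float(os_months), os_event, float(rfs_months), rfs_event, pattern


def _draw_covariates(rng: np.random.Generator, config: SimulationConfig) -> dict:
    mu_s, sd_s = config.size_lognorm
    mu_c, sd_c = config.ca199_lognorm
    return {
        "age_years": float(np.clip(rng.normal(64.7, 10.2), 30, 95)),
        "sex": "M" if rng.random() < 0.565 else "F",
        "asa_class": "I/II" if rng.random() < 0.927 else "III/IV",
        "location": rng.choice(["head", "body/tail", "diffuse"], p=[0.565, 0.415, 0.02]),
        "tumor_diameter_mm": float(rng.lognormal(mu_s, sd_s)),
        "ca19_9_u_ml": float(rng.lognormal(mu_c, sd_c)),
        "stage": rng.choice(["I", "II", "III"], p=[0.285, 0.503, 0.212]),
        "margin": "R0" if rng.random() < 0.829 else "R1",
        "adjuvant_ctx": "Y" if rng.random() < 0.699 else "N",
    }


def generate_cohort(config: SimulationConfig) -> CohortBundle:
    """Generate a full synthetic cohort.

    Returns three tables keyed by patient_id: the clinical table, the
    long-format allele-count table (RNA/WES/TS at G12, TS at Q61), and a
    truth table retaining the latent state for recovery tests.  One
    top-level seed spawns independent per-patient streams, so patient i is
    reproducible regardless of cohort size.
    """
    config.validate()
    n = config.n_patients
    streams = [np.random.Generator(np.random.PCG64(s))
               for s in np.random.SeedSequence(config.seed).spawn(n)]

    clin_rows, count_rows, truth_rows = [], [], []
    for i, rng in enumerate(streams):
        pid = f"P{i:04d}"
        state = simulate_patient(config, rng)
        cov = _draw_covariates(rng, config)

        lo, hi = config.depth_rna_range
        depth_rna = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
        e = config.sequencing_error
        pile_rna = simulate_pileup(state.expected_rna_dosage, depth_rna, e, rng, "RNA", "G12")
        pile_wes = simulate_pileup(state.expected_vaf_g12, config.depth_wes, e, rng, "WES", "G12")
        pile_ts = simulate_pileup(state.expected_vaf_g12, config.depth_ts, e, rng, "TS", "G12")
        pile_q61 = simulate_pileup(state.expected_vaf_q61, config.depth_ts, e, rng, "TS", "Q61")

        flags = (
            int(state.expected_vaf_g12 > config.dosage_flag_threshold),
            int(cov["tumor_diameter_mm"] > 20.0),
            int(cov["ca19_9_u_ml"] > 150.0),
        )
        os_m, os_e, rfs_m, rfs_e, pattern = simulate_outcomes(flags, config, rng)

        clin_rows.append({"patient_id": pid, **cov,
                          "os_months": os_m, "os_event": os_e,
                          "rfs_months": rfs_m, "rfs_event": rfs_e,
                          "recurrence_pattern": pattern})
        for pile in (pile_rna, pile_wes, pile_ts, pile_q61):
            count_rows.append({"patient_id": pid, "modality": pile.modality,
                               "codon": pile.codon, "mutant_reads": pile.mutant_reads,
                               "wildtype_reads": pile.wildtype_reads,
                               "other_reads": pile.other_reads})
        truth_rows.append({"patient_id": pid, "purity": state.purity,
                           "total_copies": state.total_copies,
                           "mutant_copies_g12": state.mutant_copies_g12,
                           "q61_cell_fraction": state.q61_cell_fraction,
                           "expected_vaf_g12": state.expected_vaf_g12,
                           "expected_rna_dosage": state.expected_rna_dosage})

    clinical = pd.DataFrame(clin_rows, columns=CLINICAL_COLUMNS)
    counts = pd.DataFrame(count_rows, columns=COUNT_COLUMNS)
    truth = pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)
    return CohortBundle(clinical=clinical, allele_counts=counts, truth=truth)
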