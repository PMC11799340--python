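"""File formats, configuration and pipeline orchestration.

Canonical exchange formats are headered CSV (clinical) and TSV (allele
counts, dosage profiles, copy number).  BAM/VCF inputs are optional and
isolated in :mod:`krasdose.dosage`.  All randomness flows from the single
configuration seed.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dosage import build_dosage_profiles
from .scoring import ScoreThresholds, build_report
from .simulate import CLINICAL_COLUMNS, CohortBundle, SimulationConfig, generate_cohort

__all__ = [
    "PipelineConfig", "read_clinical", "read_allele_counts", "read_copy_number",
    "read_dosage_profiles", "write_cohort", "run_pipeline", "get_logger",
]

log = logging.getLogger("krasdose")

REQUIRED_CLINICAL = ["patient_id", "tumor_diameter_mm", "ca19_9_u_ml",
                     "os_months", "os_event", "rfs_months", "rfs_event"]
_EVENT_TOKENS = {"0": 0, "1": 1, "0.0": 0, "1.0": 1, "true": 1, "false": 0,
                 "event": 1, "censored": 0}


def get_logger(level: str = "INFO") -> logging.Logger:
    if not log.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
        log.addHandler(h)
    log.setLevel(level.upper())
    return log


def _coerce_event(series: pd.Series, name: str) -> pd.Series:
    out = []
    for i, v in enumerate(series):
        key = str(v).strip().lower()
        if key not in _EVENT_TOKENS:
            raise ValueError(
                f"column {name!r}, row {i + 2}: cannot coerce {v!r} to an event flag; "
                f"accepted tokens: 0, 1, true, false, event, censored")
        out.append(_EVENT_TOKENS[key])
    return pd.Series(out, index=series.index, dtype=int)


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read and validate the clinical CSV.

    Requires the id, size, CA 19-9 and OS/RFS follow-up columns; event
    flags are coerced to {0,1}; unknown columns pass through untouched.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_CLINICAL if c not in df.columns]
    if missing:
        raise ValueError(f"clinical file missing required column(s): {missing}")
    for col in ("os_months", "rfs_months", "tumor_diameter_mm", "ca19_9_u_ml"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0]) + 2  # 1-based + header
            raise ValueError(f"column {col!r}, line {row}: non-numeric value "
                             f"{df[col][bad].iloc[0]!r}")
        df[col] = vals
    for col in ("os_event", "rfs_event"):
        df[col] = _coerce_event(df[col], col)
    df["patient_id"] = df["patient_id"].astype(str)
    if "recurrence_pattern" in df.columns:
        df["recurrence_pattern"] = df["recurrence_pattern"].fillna("")
    return df


def read_allele_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = ["patient_id", "modality", "codon", "mutant_reads", "wildtype_reads", "other_reads"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"allele-count file missing column(s): {missing}")
    df["patient_id"] = df["patient_id"].astype(str)
    return df


def read_copy_number(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "patient_id" not in df.columns or "kras_total_copies" not in df.columns:
        raise ValueError("copy-number file needs patient_id and kras_total_copies")
    df["patient_id"] = df["patient_id"].astype(str)
    return df


def read_dosage_profiles(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "patient_id" not in df.columns:
        raise ValueError("dosage file needs a patient_id column")
    df["patient_id"] = df["patient_id"].astype(str)
    return df


def write_cohort(bundle: CohortBundle, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "clinical": out / "clinical.csv",
        "allele_counts": out / "allele_counts.tsv",
        "truth": out / "truth.tsv",
    }
    bundle.clinical.to_csv(paths["clinical"], index=False)
    bundle.allele_counts.to_csv(paths["allele_counts"], sep="\t", index=False)
    bundle.truth.to_csv(paths["truth"], sep="\t", index=False)
    return paths


@dataclasses.dataclass
class PipelineConfig:
    out_dir: str = "krasdose_out"
    clinical_path: str | None = None
    counts_path: str | None = None
    cn_path: str | None = None
    simulate: bool = False
    seed: int = 0
    n_patients: int = 193
    endpoint: str = "os"
    cutpoint_mode: str = "global"
    min_group_size: int = 10
    threshold_dosage: float = 0.195
    threshold_size: float = 20.0
    threshold_ca199: float = 150.0
    dosage_source: str = "TS"
    log_level: str = "INFO"
    simulation: dict = dataclasses.field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    def simulation_config(self) -> SimulationConfig:
        cfg = SimulationConfig(n_patients=self.n_patients, seed=self.seed,
                               **self.simulation)
        cfg.validate()
        return cfg


def run_pipeline(config: PipelineConfig) -> dict:
    """simulate (optional) → dosage → cutpoint → score → report.

    Each stage logs input/output row counts; artifacts land under
    ``config.out_dir``.  Returns the report dict.
    """
    logger = get_logger(config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        sim_cfg = config.simulation_config()
        bundle = generate_cohort(sim_cfg)
        paths = write_cohort(bundle, out / "cohort")
        logger.info("simulate: %d patients -> %s", len(bundle.clinical), paths["clinical"])
        clinical = bundle.clinical
        counts = bundle.allele_counts
    else:
        if not config.clinical_path or not config.counts_path:
            raise ValueError("clinical_path and counts_path required unless simulating")
        clinical = read_clinical(config.clinical_path)
        counts = read_allele_counts(config.counts_path)
        logger.info("read: %d clinical rows, %d count rows", len(clinical), len(counts))

    cn = read_copy_number(config.cn_path) if config.cn_path else None
    profiles = build_dosage_profiles(counts, cn_table=cn,
                                     q61_threshold=config.threshold_dosage)
    profiles.to_csv(out / "dosage.tsv", sep="\t", index=False)
    logger.info("dosage: %d profiles -> %s", len(profiles), out / "dosage.tsv")

    # cutpoint scan on the configured endpoint
    from .cutpoint import scan_cutpoints, select_global, select_local_maxima

    col = {"TS": "dosage_ts", "TS_adjusted": "adjusted_dosage_ts",
           "WES": "dosage_wes", "RNA": "dosage_rna"}[config.dosage_source]
    merged = clinical.merge(profiles[["patient_id", col]], on="patient_id")
    ok = merged[col].notna()
    scan_info = None
    try:
        scan = scan_cutpoints(
            merged.loc[ok, col].to_numpy(),
            merged.loc[ok, f"{config.endpoint}_months"].to_numpy(),
            merged.loc[ok, f"{config.endpoint}_event"].to_numpy(),
            min_group_size=config.min_group_size,
        )
        if config.cutpoint_mode == "local_maxima":
            selected = select_local_maxima(scan)
        else:
            selected = (select_global(scan),)
        pd.DataFrame({"cutoff": scan.candidate_cutoffs,
                      "chi_square": scan.statistics,
                      "p": scan.p_values}).to_csv(out / "cutpoint_scan.tsv",
                                                  sep="\t", index=False)
        scan_info = {"mode": scan.mode, "selected": list(selected),
                     "n_candidates": int(scan.candidate_cutoffs.size)}
        logger.info("cutpoint: %d candidates, selected %s", scan_info["n_candidates"], selected)
    except ValueError as exc:
        logger.warning("cutpoint stage skipped: %s", exc)

    thresholds = ScoreThresholds(size_mm=config.threshold_size,
                                 ca19_9=config.threshold_ca199,
                                 dosage=config.threshold_dosage,
                                 dosage_source=config.dosage_source)
    report = build_report(clinical, profiles, thresholds,
                          out_dir=out, seed=config.seed,
                          config={"endpoint": config.endpoint,
                                  "cutpoint": scan_info})
    logger.info("report: %s", out / "report.json")
    return report
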