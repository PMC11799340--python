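"""The 3-point preoperative prognostic score and stratified summaries.

One point each for maximal tumor diameter > 20 mm at baseline CT,
preoperative CA 19-9 > 150 U/mL, and KRAS G12 mutation dosage (targeted
sequencing) > 0.195 — all strict inequalities, so boundary values do not
score.  Outputs: per-score Kaplan–Meier summaries (median, 1/3/5-year OS
and RFS), Cox hazard ratios vs the 0-point stratum, recurrence-timing
breakdowns, and baseline-characteristics comparison tables between
high/low dosage groups.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .survival import (
    km_fit, km_median, km_rate_at, cox_fit, chi_square_test,
    compare_continuous, classify_recurrence_timing,
)

__all__ = ["ScoreThresholds", "PrognosticScore", "assign_score",
           "assign_scores", "stratify_by_score", "summarize_groups",
           "build_report"]


@dataclasses.dataclass(frozen=True)
class ScoreThresholds:
    size_mm: float = 20.0
    ca19_9: float = 150.0
    dosage: float = 0.195       # 0.139 is the alternative threshold
    dosage_source: str = "TS"   # {TS, TS_adjusted, WES, RNA}

    def __post_init__(self):
        if min(self.size_mm, self.ca19_9, self.dosage) <= 0:
            raise ValueError("all thresholds must be > 0")

    @property
    def provenance(self) -> str:
        if self.dosage == 0.195:
            return "primary"
        if self.dosage == 0.139:
            return "alternative (paper)"
        return "custom"


@dataclasses.dataclass(frozen=True)
class PrognosticScore:
    size_point: int
    ca199_point: int
    dosage_point: int

    @property
    def total(self) -> int:
        return self.size_point + self.ca199_point + self.dosage_point


def assign_score(
    tumor_diameter_mm: float,
    ca19_9: float,
    dosage: float | None,
    thresholds: ScoreThresholds = ScoreThresholds(),
) -> PrognosticScore:
    """Strict ">" comparisons on all three axes; total in {0,1,2,3}."""
    if dosage is None or (isinstance(dosage, float) and np.isnan(dosage)):
        raise ValueError(
            "undefined dosage: exclude the patient or impute before scoring"
        )
    if tumor_diameter_mm < 0 or ca19_9 < 0 or dosage < 0:
        raise ValueError("inputs must be non-negative")
    return PrognosticScore(
        size_point=int(tumor_diameter_mm > thresholds.size_mm),
        ca199_point=int(ca19_9 > thresholds.ca19_9),
        dosage_point=int(dosage > thresholds.dosage),
    )


_DOSAGE_COL = {"TS": "dosage_ts", "TS_adjusted": "adjusted_dosage_ts",
               "WES": "dosage_wes", "RNA": "dosage_rna"}


def assign_scores(
    clinical: pd.DataFrame,
    profiles: pd.DataFrame,
    thresholds: ScoreThresholds = ScoreThresholds(),
) -> pd.DataFrame:
    """Join clinical and dosage tables and score every patient.

    Patients with undefined dosage from the selected source are excluded
    with a warning.  Returns the joined frame plus a ``score`` column.
    """
    col = _DOSAGE_COL[thresholds.dosage_source]
    merged = clinical.merge(profiles[["patient_id", col]], on="patient_id", how="inner")
    undef = merged[col].isna()
    if undef.any():
        warnings.warn(f"{int(undef.sum())} patient(s) excluded: undefined {col}")
        merged = merged[~undef].copy()
    merged["score"] = [
        assign_score(r.tumor_diameter_mm, r.ca19_9_u_ml, getattr(r, col), thresholds).total
        for r in merged.itertuples()
    ]
    return merged


def _stratum_km(sub: pd.DataFrame, time_col: str, event_col: str) -> dict:
    curve = km_fit(sub[time_col].to_numpy(), sub[event_col].to_numpy())
    med = km_median(curve)
    return {
        "median_months": med,
        "rate_1y": km_rate_at(curve, 12.0),
        "rate_3y": km_rate_at(curve, 36.0),
        "rate_5y": km_rate_at(curve, 60.0),
    }


def stratify_by_score(scored: pd.DataFrame, endpoint: str = "os") -> dict:
    """Per-score-stratum KM summaries and Cox HRs vs the 0-point stratum.

    ``endpoint`` is "os" or "rfs".  The Cox model codes score as a factor
    with dummy indicators against the lowest observed score; the reference
    stratum is reported with HR exactly 1.00.  With fewer than two
    non-empty strata the KM summaries are still produced and the Cox block
    is None.
    """
    if endpoint not in ("os", "rfs"):
        raise ValueError("endpoint must be 'os' or 'rfs'")
    time_col, event_col = f"{endpoint}_months", f"{endpoint}_event"
    n_total = len(scored)
    if n_total == 0:
        raise ValueError("empty cohort")

    strata = {}
    levels = sorted(scored["score"].unique())
    for s in levels:
        sub = scored[scored["score"] == s]
        strata[int(s)] = {
            "n": int(len(sub)),
            "share": len(sub) / n_total,
            **_stratum_km(sub, time_col, event_col),
        }

    cox = None
    if len(levels) >= 2:
        ref = levels[0]
        X = np.column_stack([
            (scored["score"] == s).to_numpy(float) for s in levels[1:]
        ])
        names = [f"score_{int(s)}" for s in levels[1:]]
        fit = cox_fit(X, scored[time_col].to_numpy(), scored[event_col].to_numpy(),
                      names=names)
        cox = {f"score_{int(ref)}": {"hr": 1.00, "ci95": None, "p": None,
                                     "reference": True}}
        cox.update(fit.as_dict())
    return {"endpoint": endpoint, "n": n_total, "strata": strata, "cox": cox}


def summarize_groups(
    cohort: pd.DataFrame,
    group_labels,
    schema: dict[str, str],
    recurred_col: str = "recurred",
) -> pd.DataFrame:
    """Table-1/2 style group comparison.

    ``schema`` maps column name → type: "categorical" (counts, within-
    group %, chi-square p), "continuous" (mean (SD), Welch t p), or
    "recurrence_categorical" (categorical, restricted to patients who
    recurred).  Group labels must be defined for every row and every group
    must be non-empty.
    """
    g = pd.Series(np.asarray(group_labels, dtype=object), index=cohort.index)
    if g.isna().any() or (g == None).any():  # noqa: E711
        raise ValueError("group label undefined for some rows")
    groups = sorted(g.unique(), key=str)
    if len(groups) < 2:
        raise ValueError("need at least two non-empty groups")

    rows = []
    for var, kind in schema.items():
        if kind == "continuous":
            samples = [cohort.loc[g == lab, var].to_numpy(float) for lab in groups]
            _, p = compare_continuous(samples[0], samples[1], method="t")
            for lab, x in zip(groups, samples):
                rows.append({"variable": var, "level": "mean (SD)", "group": lab,
                             "count": len(x), "value": float(np.mean(x)),
                             "sd": float(np.std(x, ddof=1)), "pct": None, "p": p})
        elif kind in ("categorical", "recurrence_categorical"):
            sub = cohort
            gg = g
            if kind == "recurrence_categorical":
                mask = cohort[recurred_col].astype(bool)
                sub, gg = cohort[mask], g[mask]
            levels = sorted(sub[var].astype(str).unique())
            table = np.array([
                [int(((gg == lab) & (sub[var].astype(str) == lev)).sum()) for lev in levels]
                for lab in groups
            ])
            if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
                raise ValueError(f"zero margin for variable {var!r}")
            _, _, p = chi_square_test(table)
            for i, lab in enumerate(groups):
                tot = table[i].sum()
                for j, lev in enumerate(levels):
                    rows.append({"variable": var, "level": lev, "group": lab,
                                 "count": int(table[i, j]), "value": None, "sd": None,
                                 "pct": 100.0 * table[i, j] / tot, "p": p})
        else:
            raise ValueError(f"unknown variable type {kind!r} for {var!r}")
    return pd.DataFrame(rows)


def _km_curve_frame(scored: pd.DataFrame, endpoint: str) -> pd.DataFrame:
    time_col, event_col = f"{endpoint}_months", f"{endpoint}_event"
    frames = []
    for s in sorted(scored["score"].unique()):
        sub = scored[scored["score"] == s]
        c = km_fit(sub[time_col].to_numpy(), sub[event_col].to_numpy())
        frames.append(pd.DataFrame({
            "score": int(s), "time": c.event_times, "survival": c.survival,
            "at_risk": c.at_risk, "n_events": c.n_events,
        }))
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["score", "time", "survival", "at_risk", "n_events"])


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        return None if (isinstance(obj, float) and np.isnan(obj)) else float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    return obj


def build_report(
    clinical: pd.DataFrame,
    profiles: pd.DataFrame,
    thresholds: ScoreThresholds = ScoreThresholds(),
    endpoints: tuple[str, ...] = ("os", "rfs"),
    out_dir: str | Path | None = None,
    seed: int | None = None,
    config: dict | None = None,
) -> dict:
    """Assemble the full report bundle (and optionally write it).

    Writes report.json, km_os_by_score.tsv / km_rfs_by_score.tsv, and
    table1.tsv / table2.tsv under ``out_dir`` when given.  Reruns with the
    same inputs are byte-identical: JSON keys are sorted and floats are
    serialized at full precision.
    """
    if len(clinical) == 0:
        raise ValueError("empty cohort")
    orphans = set(clinical["patient_id"]) - set(profiles["patient_id"])
    if orphans:
        raise ValueError(f"patients without dosage profile: {sorted(orphans)[:5]}")

    scored = assign_scores(clinical, profiles, thresholds)
    report: dict = {
        "package_version": __version__,
        "seed": seed,
        "config": config or {},
        "thresholds": {
            "size_mm": thresholds.size_mm, "ca19_9": thresholds.ca19_9,
            "dosage": thresholds.dosage, "dosage_source": thresholds.dosage_source,
            "provenance": thresholds.provenance,
        },
        "score_summaries": {ep: stratify_by_score(scored, ep) for ep in endpoints},
    }

    # Table-1/2-style comparisons on the dichotomized dosage itself
    col = _DOSAGE_COL[thresholds.dosage_source]
    labels = np.where(scored[col] > thresholds.dosage, "high", "low")
    work = scored.copy()
    work["size_cat"] = np.where(work["tumor_diameter_mm"] > thresholds.size_mm,
                                ">20", "<=20")
    work["ca199_cat"] = np.where(work["ca19_9_u_ml"] > thresholds.ca19_9,
                                 ">150", "<=150")
    work["recurred"] = (work["rfs_event"] == 1) & (work["recurrence_pattern"] != "")
    work["recurrence"] = np.where(work["recurred"], "Y", "N")
    work["recurrence_timing"] = [
        classify_recurrence_timing(r.rfs_months, r.recurred)
        for r in work.itertuples()
    ]
    table1 = table2 = None
    if len(np.unique(labels)) == 2:
        table1 = summarize_groups(work, labels, {
            "age_years": "continuous", "sex": "categorical",
            "asa_class": "categorical", "location": "categorical",
            "size_cat": "categorical", "ca199_cat": "categorical",
            "stage": "categorical", "margin": "categorical",
            "adjuvant_ctx": "categorical",
        })
        schema2 = {"recurrence": "categorical"}
        if work["recurred"].any():
            schema2.update({"recurrence_pattern": "recurrence_categorical",
                            "recurrence_timing": "recurrence_categorical"})
        table2 = summarize_groups(work, labels, schema2)
    report["dosage_groups"] = {
        "n_high": int((labels == "high").sum()),
        "n_low": int((labels == "low").sum()),
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(_jsonify(report), fh, indent=2, sort_keys=True)
            fh.write("\n")
        for ep in endpoints:
            _km_curve_frame(scored, ep).to_csv(
                out / f"km_{ep}_by_score.tsv", sep="\t", index=False)
        if table1 is not None:
            table1.to_csv(out / "table1.tsv", sep="\t", index=False)
        if table2 is not None:
            table2.to_csv(out / "table2.tsv", sep="\t", index=False)
        with open(out / "report.txt", "w") as fh:
            fh.write(_render_text(report))
    report["_tables"] = {"table1": table1, "table2": table2}
    return report


def _fmt_med(x) -> str:
    return "NA" if x is None else f"{x:.1f}"


def _render_text(report: dict) -> str:
    lines = ["Prognostic score report", "======================", ""]
    th = report["thresholds"]
    lines.append(f"thresholds: size > {th['size_mm']} mm, CA 19-9 > {th['ca19_9']} U/mL, "
                 f"dosage > {th['dosage']} ({th['dosage_source']}, {th['provenance']})")
    for ep, summ in report["score_summaries"].items():
        lines += ["", f"{ep.upper()} by score (n={summ['n']})",
                  "score     n   share  median  1y     3y     5y     HR"]
        for s, st in sorted(summ["strata"].items()):
            hr = ""
            if summ["cox"] is not None:
                entry = summ["cox"].get(f"score_{s}")
                if entry:
                    if entry.get("reference"):
                        hr = "1.00 (Reference)"
                    else:
                        lo, hi = entry["ci95"]
                        hr = f"{entry['hr']:.2f} ({lo:.2f}, {hi:.2f})"
            lines.append(
                f"{s:>5} {st['n']:>5}  {100*st['share']:5.1f}%  {_fmt_med(st['median_months']):>6}"
                f"  {100*st['rate_1y']:5.1f}% {100*st['rate_3y']:5.1f}% {100*st['rate_5y']:5.1f}%  {hr}")
    return "\n".join(lines) + "\n"
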