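"""Tabular IO, phenotype cleaning and configuration documents.

All tabular interfaces are plain TSV with a one-line header; covariance
summaries travel as small YAML/JSON documents (pattern, n, means,
lower-triangle covariance).  Phenotype cleaning implements the survey-report
rules used for self-reported birthweight: exclusion of multiple births,
reconciliation of repeat reports, and a plausibility window for live term
births.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
import yaml

from .sem_core import BW, BWO, PATTERNS, SNP, GroupSummary

logger = logging.getLogger("dyadsem")

__all__ = [
    "infer_patterns",
    "load_family_table",
    "write_family_table",
    "write_results",
    "load_group_summaries",
    "write_group_summaries",
    "clean_birthweight_reports",
    "standardize_phenotypes",
]

FAMILY_COLUMNS = ("family_id", BW, BWO, SNP)


def infer_patterns(data: pd.DataFrame) -> pd.DataFrame:
    """Label each row with its observation pattern from phenotype missingness.

    Rows missing both phenotypes are rejected (they carry no phenotype
    information and would silently distort group sizes); missing dosage is a
    row error.
    """
    missing = [c for c in (BW, BWO, SNP) if c not in data.columns]
    if missing:
        raise ValueError(f"family table lacks required columns: {missing}")
    if data[SNP].isna().any():
        bad = data.index[data[SNP].isna()].tolist()[:5]
        raise ValueError(f"rows with missing dosage (first few: {bad})")
    has_bw = data[BW].notna().to_numpy()
    has_bwo = data[BWO].notna().to_numpy()
    if (~has_bw & ~has_bwo).any():
        bad = data.index[~has_bw & ~has_bwo].tolist()[:5]
        raise ValueError(f"rows missing both phenotypes (first few: {bad})")
    pattern = np.where(has_bw & has_bwo, "both",
                       np.where(has_bw, "own_only", "offspring_only"))
    out = data.copy()
    out["pattern"] = pattern
    return out


def load_family_table(path: str | Path) -> pd.DataFrame:
    """Read a per-individual TSV (empty cell = missing) and label patterns."""
    data = pd.read_csv(path, sep="\t")
    missing = [c for c in FAMILY_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"{path}: malformed header, missing columns {missing}")
    return infer_patterns(data)


def write_family_table(
    data: pd.DataFrame, path: str | Path, truth_columns: bool = False
) -> None:
    """Write a family table as TSV; hidden truth columns only on request."""
    cols = [c for c in FAMILY_COLUMNS if c in data.columns] + ["pattern"]
    if truth_columns:
        cols += [c for c in ("g_grandmother", "g_offspring", "u") if c in data.columns]
    data.loc[:, cols].to_csv(path, sep="\t", index=False, na_rep="")


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write an estimates/tests table as TSV."""
    table.to_csv(path, sep="\t", index=False)


def _tril(cov: np.ndarray) -> list[list[float]]:
    return [[float(cov[i, j]) for j in range(i + 1)] for i in range(cov.shape[0])]


def _from_tril(rows: list[list[float]]) -> np.ndarray:
    k = len(rows)
    cov = np.zeros((k, k))
    for i, row in enumerate(rows):
        for j, v in enumerate(row):
            cov[i, j] = cov[j, i] = v
    return cov


def write_group_summaries(groups: list[GroupSummary], path: str | Path) -> None:
    doc = {
        "groups": [
            {
                "pattern": g.pattern.label,
                "n": int(g.n),
                "mean": [float(v) for v in g.sample_mean],
                "cov_lower_triangle": _tril(g.sample_cov),
            }
            for g in groups
        ]
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_group_summaries(path: str | Path) -> list[GroupSummary]:
    doc = yaml.safe_load(Path(path).read_text())
    groups = []
    for entry in doc["groups"]:
        pattern = PATTERNS[entry["pattern"]]
        groups.append(
            GroupSummary(
                pattern=pattern,
                n=int(entry["n"]),
                sample_mean=np.asarray(entry["mean"], dtype=float),
                sample_cov=_from_tril(entry["cov_lower_triangle"]),
            )
        )
    return groups


# ---------------------------------------------------------------------------
# phenotype cleaning
# ---------------------------------------------------------------------------

_LOW_KG = 2.5
_HIGH_KG = 4.5
_MAX_DISCORDANCE_KG = 0.5


def _clean_own(baseline, followup):
    """Reconcile repeat own-birthweight reports; return (value, exclusion rule)."""
    has_base = baseline is not None and not np.isnan(baseline)
    has_follow = followup is not None and not np.isnan(followup)
    if not has_base and not has_follow:
        return np.nan, None
    if has_base and has_follow and abs(baseline - followup) > _MAX_DISCORDANCE_KG:
        return np.nan, "own_discordant_reports"
    value = baseline if has_base else followup
    if value < _LOW_KG:
        return np.nan, "own_below_2.5kg"
    if value > _HIGH_KG:
        return np.nan, "own_above_4.5kg"
    return value, None


def clean_birthweight_reports(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply survey-report cleaning rules; return kept records + exclusion log.

    Rules, applied per individual:

    - multiple births are excluded entirely;
    - two own-birthweight reports differing by more than 0.5 kg invalidate the
      own report (otherwise the baseline value is kept);
    - reports below 2.5 kg or above 4.5 kg are implausible for live term
      births and dropped — the same window applies to the offspring report;
    - individuals retaining neither phenotype are dropped.

    Expected columns: ``individual_id``, ``bw_baseline``, ``bw_followup``,
    ``bw_offspring_report`` (kg; NaN = not reported), ``multiple_birth``,
    ``sex``.  Malformed (non-numeric) rows are logged and skipped.
    """
    log: dict[str, int] = {
        "total_in": len(records),
        "malformed_row": 0,
        "multiple_birth": 0,
        "own_discordant_reports": 0,
        "own_below_2.5kg": 0,
        "own_above_4.5kg": 0,
        "offspring_below_2.5kg": 0,
        "offspring_above_4.5kg": 0,
        "no_phenotype_left": 0,
    }
    kept_rows = []
    numeric_cols = ("bw_baseline", "bw_followup", "bw_offspring_report")
    for _, row in records.iterrows():
        try:
            vals = {c: float(row[c]) if pd.notna(row[c]) else np.nan
                    for c in numeric_cols}
        except (TypeError, ValueError):
            log["malformed_row"] += 1
            logger.warning("skipping malformed row %r", row.get("individual_id"))
            continue
        if bool(row.get("multiple_birth", False)):
            log["multiple_birth"] += 1
            continue
        own, rule = _clean_own(vals["bw_baseline"], vals["bw_followup"])
        if rule is not None:
            log[rule] += 1
        off = vals["bw_offspring_report"]
        if not np.isnan(off):
            if off < _LOW_KG:
                log["offspring_below_2.5kg"] += 1
                off = np.nan
            elif off > _HIGH_KG:
                log["offspring_above_4.5kg"] += 1
                off = np.nan
        if np.isnan(own) and np.isnan(off):
            log["no_phenotype_left"] += 1
            continue
        kept_rows.append(
            {
                "individual_id": row["individual_id"],
                "bw_clean": own,
                "bw_offspring_clean": off,
                "sex": row.get("sex", np.nan),
            }
        )
    cleaned = pd.DataFrame(
        kept_rows,
        columns=["individual_id", "bw_clean", "bw_offspring_clean", "sex"],
    )
    log["total_kept"] = len(cleaned)
    for rule, count in log.items():
        if rule not in ("total_in", "total_kept") and count:
            logger.info("cleaning rule %s excluded %d value(s)", rule, count)
    return cleaned, log


def standardize_phenotypes(
    values: np.ndarray, covariates: np.ndarray | None = None
) -> np.ndarray:
    """Residualize on covariates (if any) and convert to z-scores.

    Missing values are preserved as NaN; the residualization and scaling use
    the non-missing subset only.
    """
    values = np.asarray(values, dtype=float)
    mask = ~np.isnan(values)
    if mask.sum() < 2:
        raise ValueError("need at least two non-missing values")
    work = values[mask]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        model = sm.OLS(work, sm.add_constant(cov[mask])).fit()
        work = np.asarray(model.resid)
    sd = work.std(ddof=1)
    if sd == 0:
        raise ValueError("phenotype has zero variance after residualization")
    out = np.full_like(values, np.nan)
    out[mask] = (work - work.mean()) / sd
    return out
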