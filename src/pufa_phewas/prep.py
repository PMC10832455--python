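"""Cohort preparation: QC-filtered median collapse, Z-scores, WHR, obesity
classes, the minimum-case disease filter, and allele-sum polygenic scoring.

Raw metabolite measurements arrive as repeated assays with per-repeat QC
flags; flagged values are removed and the median of the survivors is the
individual's level.  Z-scores are ``(x - mean) / sd`` over non-missing
values (sample SD, n-1 denominator).  Obesity is classified by strict
cutoffs: BMI > 30, or WHR > 0.85 (women) / 0.95 (men); boundary values are
non-obese.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import BMI_OBESE_CUTOFF, WHR_OBESE_CUTOFF

logger = logging.getLogger(__name__)

__all__ = [
    "ObesityClass",
    "collapse_measurements",
    "zscore",
    "compute_whr",
    "classify_obesity",
    "min_case_filter",
    "score_individuals",
    "prepare_cohort",
    "status_columns",
]


@dataclass(frozen=True)
class ObesityClass:
    measure: str  # {"bmi", "whr"}
    status: str  # {"obese", "non_obese"}
    cutoff_used: float


def collapse_measurements(values, qc_flags) -> float:
    """Median of QC-passing repeated measurements; NaN if none survive.

    ``qc_flags`` is truthy per entry when that measurement carries a QC
    warning; warned entries are dropped before taking the median.
    """
    values = np.asarray(values, dtype=float)
    flags = np.asarray(qc_flags)
    if values.shape != flags.shape:
        raise ValueError(f"length mismatch: {values.shape} values vs {flags.shape} flags")
    keep = values[~(flags.astype(bool) | np.isnan(values))]
    if keep.size == 0:
        return float("nan")
    return float(np.median(keep))


def zscore(values) -> pd.Series:
    """Standardize to mean 0, sample SD 1, ignoring (and propagating) NaN."""
    s = pd.Series(np.asarray(values, dtype=float))
    ok = s.dropna()
    if len(ok) < 2:
        raise ValueError("need >= 2 non-missing values to Z-score")
    sd = ok.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero or non-finite variance; cannot Z-score")
    return (s - ok.mean()) / sd


def compute_whr(waist: float, hip: float) -> float:
    """Waist-to-hip ratio. Repeated measures should be median-collapsed first."""
    waist = np.asarray(waist, dtype=float)
    hip = np.asarray(hip, dtype=float)
    if np.any(hip <= 0):
        raise ValueError("hip circumference must be positive")
    return waist / hip


def classify_obesity(measure: str, value: float, sex: str | int | None = None) -> ObesityClass:
    """Classify one individual; cutoffs are strict (value == cutoff -> non_obese)."""
    if not np.isfinite(value):
        raise ValueError(f"non-finite {measure} value")
    measure = measure.lower()
    if measure == "bmi":
        cutoff = BMI_OBESE_CUTOFF
    elif measure == "whr":
        sex_label = _sex_label(sex)
        cutoff = WHR_OBESE_CUTOFF[sex_label]
    else:
        raise ValueError(f"unknown measure {measure!r}; expected 'bmi' or 'whr'")
    status = "obese" if value > cutoff else "non_obese"
    return ObesityClass(measure=measure, status=status, cutoff_used=cutoff)


def _sex_label(sex) -> str:
    if sex in ("female", "f", 0):
        return "female"
    if sex in ("male", "m", 1):
        return "male"
    raise ValueError(f"unknown sex {sex!r}")


def status_columns(cohort: pd.DataFrame) -> list[str]:
    return [c for c in cohort.columns if c.startswith("status_")]


def min_case_filter(cohort: pd.DataFrame, min_cases: int = 50) -> list[str]:
    """Phecodes with at least ``min_cases`` cases (inclusive threshold)."""
    kept = []
    for col in status_columns(cohort):
        n_case = int(cohort[col].sum())
        phecode = col[len("status_"):]
        if n_case >= min_cases:
            kept.append(phecode)
        else:
            logger.info("dropping disease %s: %d cases < %d", phecode, n_case, min_cases)
    return kept


def score_individuals(dosages: pd.DataFrame, weights: pd.DataFrame,
                      dosage_effect_allele: dict[str, str] | None = None,
                      dosage_other_allele: dict[str, str] | None = None) -> pd.Series:
    """Allele-sum polygenic score: score_i = sum_j dosage_ij * weight_j.

    ``dosages`` has one column per SNP (values in [0, 2] counting
    ``dosage_effect_allele[snp]``); ``weights`` has columns
    ``snp, effect_allele, weight``.  When the counted allele is the weight
    file's other allele, the dosage is converted (``2 - d``); an unmatched
    SNP id raises, an irreconcilable allele is dropped with a warning.
    Scoring by chromosome chunks and summing equals a single pass because
    the score is additive over SNPs.
    """
    if weights["snp"].duplicated().any():
        raise ValueError("duplicate SNP ids in weights")
    missing = set(weights["snp"]) - set(dosages.columns)
    if missing:
        raise KeyError(f"SNPs in weights absent from dosage matrix: {sorted(missing)[:5]}")

    score = np.zeros(len(dosages))
    for row in weights.itertuples(index=False):
        d = dosages[row.snp].to_numpy(dtype=float)
        if np.any((d < 0) | (d > 2)):
            raise ValueError(f"dosages out of [0,2] for {row.snp}")
        counted = (dosage_effect_allele or {}).get(row.snp, row.effect_allele)
        if counted == row.effect_allele:
            score += d * row.weight
        elif dosage_other_allele is None or counted == dosage_other_allele.get(row.snp, counted):
            # counted allele is the weight's other allele: count the effect allele
            score += (2.0 - d) * row.weight
        else:
            logger.warning("allele mismatch for %s (counted %s, effect %s): dropped",
                           row.snp, counted, row.effect_allele)
    return pd.Series(score, index=dosages.index, name="score")


def prepare_cohort(cohort: pd.DataFrame, metabolite_names: list[str],
                   n_repeats: dict[str, int] | None = None) -> pd.DataFrame:
    """Add analysis-ready columns to a raw cohort table.

    For each metabolite: ``<name>_med`` (QC-filtered median over repeats),
    ``z_<name>`` (Z-score of the median) and ``zpgs_<name>`` (Z-scored PGS).
    Also adds ``whr``, ``z_bmi``, ``z_whr`` and binary ``obese_bmi`` /
    ``obese_whr`` (sex-specific WHR cutoff).  Individuals whose repeats are
    all QC-flagged get a missing level; models drop them complete-case.
    """
    df = cohort.copy()
    df["whr"] = compute_whr(df["waist"].to_numpy(), df["hip"].to_numpy())
    df["z_bmi"] = zscore(df["bmi"])
    df["z_whr"] = zscore(df["whr"])
    df["obese_bmi"] = (df["bmi"] > BMI_OBESE_CUTOFF).astype(int)
    whr_cut = np.where(df["sex"].to_numpy() == 1,
                       WHR_OBESE_CUTOFF["male"], WHR_OBESE_CUTOFF["female"])
    df["obese_whr"] = (df["whr"].to_numpy() > whr_cut).astype(int)

    for name in metabolite_names:
        rep_cols = sorted(c for c in df.columns
                          if c.startswith(f"{name}_rep"))
        qc_cols = [c.replace("_rep", "_qc") for c in rep_cols]
        if not rep_cols:
            raise KeyError(f"no repeat columns found for metabolite {name!r}")
        vals = df[rep_cols].to_numpy(dtype=float)
        flags = (df[qc_cols].to_numpy(dtype=float).astype(bool)
                 if all(c in df.columns for c in qc_cols)
                 else np.zeros_like(vals, dtype=bool))
        masked = np.where(flags | np.isnan(vals), np.nan, vals)
        med = np.full(len(df), np.nan)
        any_ok = ~np.all(np.isnan(masked), axis=1)
        med[any_ok] = np.nanmedian(masked[any_ok], axis=1)
        n_missing = int(np.isnan(med).sum())
        if n_missing:
            logger.info("metabolite %s: %d individuals lost all repeats to QC",
                        name, n_missing)
        df[f"{name}_med"] = med
        df[f"z_{name}"] = zscore(med)
        df[f"zpgs_{name}"] = zscore(df[f"pgs_{name}"])
    return df
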