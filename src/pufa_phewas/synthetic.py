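"""Synthetic cohort and GWAS summary-statistic generators.

The downstream analyses (level/PGS disease associations, triangulation,
obesity-interaction models, canalization curves, two-sample MR) are built
for biobank-scale inputs that are access-restricted.  This module generates
individual-level cohorts and paired exposure/outcome GWAS summary statistics
with the statistical structure those analyses assume, so that every stage is
testable end-to-end from a seed.

Generative model
----------------
For each metabolite ``m`` with heritability-like parameter ``h2_pgs``::

    PGS_m  ~ N(0, 1)
    L_m    = sqrt(h2_pgs) * PGS_m + sqrt(1 - h2_pgs) * e,   e ~ N(0, 1)

``L_m`` is the standardized true level; the stored concentrations are
``loc + scale * L_m`` plus independent per-repeat measurement noise, with QC
warnings assigned at ``qc_warning_rate``.  By construction the squared
correlation between PGS and true level is ``h2_pgs``.

Disease status is drawn from a logistic model on the log-odds scale (the
same scale the analysis models estimate, so generative coefficients are the
estimands)::

    logit P(D=1) = logit(prev) + b_met * L_m + b_prs * PRS_d
                   + b_obes * Obese + gamma * X_pred * X_weight

where ``X_pred`` is PGS_m or L_m and ``X_weight`` a standardized body-weight
measure or obesity indicator, per :class:`DiseaseSpec`.

Summary statistics: per-SNP exposure effects are drawn positive (effect
allele oriented to increase the exposure), standard errors follow the usual
GWAS approximation ``se = 1/sqrt(2*maf*(1-maf)*n)``, and outcome effects are
``causal_effect * beta_x`` plus a direct (pleiotropic) effect for a
configurable fraction of invalid instruments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from ._rng import substream

__all__ = [
    "MetaboliteSpec",
    "DiseaseSpec",
    "CohortSpec",
    "SummaryStatsSpec",
    "generate_cohort",
    "generate_summary_stats",
]

WEIGHT_MODES = ("none", "bmi_z", "whr_z", "bmi_obese", "whr_obese")

# WHO-style cutoffs used both by the generator and by cohort preparation
BMI_OBESE_CUTOFF = 30.0
WHR_OBESE_CUTOFF = {"female": 0.85, "male": 0.95}

_LIABILITY_SCALE = np.pi**2 / 3  # logistic residual variance


@dataclass
class MetaboliteSpec:
    """One circulating metabolite and its polygenic score.

    ``h2_pgs`` is the fraction of (true) level variance explained by the
    PGS; the study design centers on ~0.5.  ``measurement_sd`` is the SD of
    per-repeat assay noise on the stored concentration scale
    (``loc + scale * standardized level``).
    """

    name: str
    h2_pgs: float = 0.5
    n_repeats: int = 2
    qc_warning_rate: float = 0.02
    measurement_sd: float = 0.05
    loc: float = 1.5
    scale: float = 0.3

    def validate(self) -> None:
        if not 0.0 < self.h2_pgs < 1.0:
            raise ValueError(f"h2_pgs must be in (0,1), got {self.h2_pgs}")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if not 0.0 <= self.qc_warning_rate <= 1.0:
            raise ValueError("qc_warning_rate must be in [0,1]")
        if self.measurement_sd < 0 or self.scale <= 0:
            raise ValueError("measurement_sd must be >= 0 and scale > 0")


@dataclass
class DiseaseSpec:
    """One binary disease endpoint and its generative effects (log-OR units).

    ``metabolite`` names the metabolite whose level/PGS enters the liability;
    defaults to the cohort's first metabolite.  ``beta_metabolite`` is per SD
    of true level (protective effects are negative), ``beta_prs`` per SD of
    the disease PRS.  ``gamma_interaction`` multiplies
    ``predictor x body-weight`` where the predictor is chosen by
    ``interaction_predictor`` and the body-weight coding by
    ``interaction_weight``.  If ``prs_r2_liability`` is given and
    ``beta_prs`` is None, the PRS effect is derived so the PRS explains that
    fraction of liability variance on the logistic scale.
    """

    phecode: str
    group: str = "other"
    baseline_prevalence: float = 0.05
    beta_metabolite: float = 0.0
    beta_prs: float | None = 0.0
    beta_obesity: float = 0.0
    gamma_interaction: float = 0.0
    prs_r2_liability: float | None = None
    metabolite: str | None = None
    interaction_predictor: str = "pgs"  # {"pgs", "level"}
    interaction_weight: str = "bmi_obese"  # WEIGHT_MODES

    def resolved_beta_prs(self) -> float:
        if self.beta_prs is not None:
            return float(self.beta_prs)
        r2 = self.prs_r2_liability
        if r2 is None:
            return 0.0
        if not 0.0 <= r2 < 1.0:
            raise ValueError("prs_r2_liability must be in [0,1)")
        return float(np.sqrt(r2 * _LIABILITY_SCALE / (1.0 - r2)))

    def validate(self) -> None:
        if not 0.0 < self.baseline_prevalence < 1.0:
            raise ValueError(
                f"baseline_prevalence must be in (0,1), got {self.baseline_prevalence}"
            )
        if self.interaction_predictor not in ("pgs", "level"):
            raise ValueError(f"unknown interaction_predictor {self.interaction_predictor!r}")
        if self.interaction_weight not in WEIGHT_MODES:
            raise ValueError(f"unknown interaction_weight {self.interaction_weight!r}")
        self.resolved_beta_prs()


def _default_whr_prevalence() -> dict[str, float]:
    # more women than men cross the sex-specific WHR cutoff, as observed
    return {"female": 0.40, "male": 0.30}


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort; seed fully determines output."""

    n_individuals: int
    seed: int = 0
    metabolites: Sequence[MetaboliteSpec] = field(default_factory=list)
    diseases: Sequence[DiseaseSpec] = field(default_factory=list)
    obesity_prevalence_bmi: float = 0.25
    obesity_prevalence_whr: dict[str, float] = field(default_factory=_default_whr_prevalence)
    age_range: tuple[float, float] = (40.0, 70.0)
    sex_fraction_female: float = 0.54
    n_pcs: int = 10
    bmi_whr_corr: float = 0.5
    bmi_median: float = 27.0
    whr_sd: float = 0.07

    def validate(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError(f"n_individuals must be positive, got {self.n_individuals}")
        fracs = [self.obesity_prevalence_bmi, self.sex_fraction_female,
                 *self.obesity_prevalence_whr.values()]
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise ValueError("all fractions must lie in [0,1]")
        if not 0.0 < self.obesity_prevalence_bmi < 0.5:
            raise ValueError("obesity_prevalence_bmi must be in (0, 0.5) for a log-normal BMI "
                             "with median below the cutoff")
        if self.n_pcs < 0:
            raise ValueError("n_pcs must be >= 0")
        for m in self.metabolites:
            m.validate()
        names = [m.name for m in self.metabolites]
        if len(set(names)) != len(names):
            raise ValueError("metabolite names must be unique")
        for d in self.diseases:
            d.validate()
            if d.metabolite is not None and d.metabolite not in names:
                raise ValueError(f"disease {d.phecode}: unknown metabolite {d.metabolite!r}")


def _bmi_sigma(spec: CohortSpec) -> float:
    # log-normal with fixed median; sigma solved so P(BMI > 30) = target
    z = norm.ppf(1.0 - spec.obesity_prevalence_bmi)
    return float((np.log(BMI_OBESE_CUTOFF) - np.log(spec.bmi_median)) / z)


def _whr_mean(spec: CohortSpec, sex: str) -> float:
    z = norm.ppf(1.0 - spec.obesity_prevalence_whr[sex])
    return float(WHR_OBESE_CUTOFF[sex] - z * spec.whr_sd)


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate an individual-level cohort table.

    Returns one row per individual with columns: ``id``, ``age``, ``sex``
    (0 = female, 1 = male), ``pc1..pcK``, ``bmi``, ``waist``, ``hip``,
    and per metabolite ``pgs_<name>``, repeats ``<name>_rep<j>`` with QC
    flags ``<name>_qc<j>`` (1 = warning), plus ``<name>_true`` (standardized
    latent level, kept for oracle checks); per disease ``prs_<phecode>`` and
    binary ``status_<phecode>``.
    """
    spec.validate()
    n = spec.n_individuals
    rng = substream(spec.seed, "cohort")

    out: dict[str, np.ndarray] = {}
    out["id"] = np.arange(1, n + 1)
    out["age"] = rng.uniform(spec.age_range[0], spec.age_range[1], size=n)
    sex = (rng.random(n) >= spec.sex_fraction_female).astype(int)  # 1 = male
    out["sex"] = sex
    for k in range(1, spec.n_pcs + 1):
        out[f"pc{k}"] = rng.standard_normal(n)

    # correlated latent normals -> BMI (log-normal) and WHR (normal per sex)
    rho = spec.bmi_whr_corr
    z_bmi = rng.standard_normal(n)
    z_whr = rho * z_bmi + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(n)
    bmi = np.exp(np.log(spec.bmi_median) + _bmi_sigma(spec) * z_bmi)
    whr_mean = np.where(sex == 1, _whr_mean(spec, "male"), _whr_mean(spec, "female"))
    whr = whr_mean + spec.whr_sd * z_whr
    hip = 100.0 + rng.normal(0.0, 5.0, size=n)
    out["bmi"] = bmi
    out["hip"] = hip
    out["waist"] = whr * hip

    obese_bmi = (bmi > BMI_OBESE_CUTOFF).astype(float)
    whr_cut = np.where(sex == 1, WHR_OBESE_CUTOFF["male"], WHR_OBESE_CUTOFF["female"])
    obese_whr = (whr > whr_cut).astype(float)

    def _std(x: np.ndarray) -> np.ndarray:
        return (x - x.mean()) / x.std(ddof=1)

    weight_vars = {
        "none": np.zeros(n),
        "bmi_z": _std(bmi),
        "whr_z": _std(whr),
        "bmi_obese": obese_bmi,
        "whr_obese": obese_whr,
    }

    latent: dict[str, np.ndarray] = {}
    pgs: dict[str, np.ndarray] = {}
    for m in spec.metabolites:
        g = rng.standard_normal(n)
        e = rng.standard_normal(n)
        lat = np.sqrt(m.h2_pgs) * g + np.sqrt(1.0 - m.h2_pgs) * e
        latent[m.name] = lat
        pgs[m.name] = g
        out[f"pgs_{m.name}"] = g
        out[f"{m.name}_true"] = lat
        conc = m.loc + m.scale * lat
        for j in range(1, m.n_repeats + 1):
            out[f"{m.name}_rep{j}"] = conc + rng.normal(0.0, m.measurement_sd, size=n)
            out[f"{m.name}_qc{j}"] = (rng.random(n) < m.qc_warning_rate).astype(int)

    default_met = spec.metabolites[0].name if spec.metabolites else None
    for d in spec.diseases:
        prs = rng.standard_normal(n)
        out[f"prs_{d.phecode}"] = prs
        eta = np.full(n, logit(d.baseline_prevalence))
        met = d.metabolite or default_met
        if met is not None:
            eta = eta + d.beta_metabolite * latent[met]
            if d.gamma_interaction != 0.0:
                xpred = pgs[met] if d.interaction_predictor == "pgs" else latent[met]
                eta = eta + d.gamma_interaction * xpred * weight_vars[d.interaction_weight]
        elif d.beta_metabolite != 0.0 or d.gamma_interaction != 0.0:
            raise ValueError(f"disease {d.phecode} needs a metabolite for its effects")
        eta = eta + d.resolved_beta_prs() * prs + d.beta_obesity * obese_bmi
        out[f"status_{d.phecode}"] = (rng.random(n) < expit(eta)).astype(int)

    return pd.DataFrame(out)


@dataclass
class SummaryStatsSpec:
    """Paired exposure/outcome GWAS summary statistics for two-sample MR.

    True per-allele exposure effects are |N(effect_mean, effect_sd)| with the
    effect allele oriented exposure-increasing.  A fraction
    ``invalid_fraction`` of SNPs receives a direct outcome effect drawn from
    N(pleiotropy_mean, pleiotropy_sd); ``pleiotropy_mean != 0`` gives
    directional pleiotropy.  ``causal_effect`` is the outcome log-OR per SD
    of exposure.
    """

    n_snps: int = 50
    n_exposure: int = 250_000
    n_outcome: int = 200_000
    causal_effect: float = 0.0
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    invalid_fraction: float = 0.0
    maf_range: tuple[float, float] = (0.1, 0.5)
    effect_mean: float = 0.15
    effect_sd: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        if self.n_snps < 2:
            raise ValueError(f"n_snps must be >= 2, got {self.n_snps}")
        if not 0.0 <= self.invalid_fraction <= 1.0:
            raise ValueError("invalid_fraction must be in [0,1]")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValueError("maf_range must satisfy 0 < lo <= hi < 1")
        if self.n_exposure <= 0 or self.n_outcome <= 0:
            raise ValueError("sample sizes must be positive")


_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


def gwas_se(maf: np.ndarray, n: int) -> np.ndarray:
    """Standard GWAS standard-error approximation for a standardized trait."""
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def generate_summary_stats(spec: SummaryStatsSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate harmonizable exposure and outcome summary-statistic tables.

    Both tables share SNP ids and allele coding and carry the columns
    ``snp, effect_allele, other_allele, eaf, beta, se, p, n``.
    """
    spec.validate()
    rng = substream(spec.seed, "sumstats")
    m = spec.n_snps

    maf = rng.uniform(spec.maf_range[0], spec.maf_range[1], size=m)
    bx_true = np.abs(rng.normal(spec.effect_mean, spec.effect_sd, size=m))
    n_invalid = int(round(spec.invalid_fraction * m))
    invalid = np.zeros(m, dtype=bool)
    invalid[rng.choice(m, size=n_invalid, replace=False)] = True
    alpha = np.where(invalid, rng.normal(spec.pleiotropy_mean, spec.pleiotropy_sd, size=m), 0.0)
    by_true = spec.causal_effect * bx_true + alpha

    se_x = gwas_se(maf, spec.n_exposure)
    se_y = gwas_se(maf, spec.n_outcome)
    bx = bx_true + se_x * rng.standard_normal(m)
    by = by_true + se_y * rng.standard_normal(m)

    pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
    ea = np.array([_ALLELE_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_ALLELE_PAIRS[i][1] for i in pair_idx])
    snp = np.array([f"rs{100000 + i}" for i in range(m)])

    def _table(beta: np.ndarray, se: np.ndarray, n: int) -> pd.DataFrame:
        z = beta / se
        p = 2.0 * norm.sf(np.abs(z))
        return pd.DataFrame({
            "snp": snp, "effect_allele": ea, "other_allele": oa,
            "eaf": maf, "beta": beta, "se": se,
            "p": np.clip(p, np.finfo(float).tiny, 1.0), "n": n,
        })

    return _table(bx, se_x, spec.n_exposure), _table(by, se_y, spec.n_outcome)
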