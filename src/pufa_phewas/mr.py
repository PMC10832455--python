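"""Two-sample Mendelian randomization from GWAS summary statistics.

Given exposure and outcome summary statistics, the pipeline is: select
genome-wide-significant instruments, harmonize effect alleles, iteratively
remove heterogeneity outliers by their Cochran's Q contribution, then
estimate the causal effect with

* IVW — fixed-effect inverse-variance-weighted estimate, algebraically the
  ``se_y^-2``-weighted least-squares slope of ``beta_y`` on ``beta_x``
  through the origin;
* weighted median — the weight-0.5 percentile of the per-instrument ratio
  estimates ``beta_y/beta_x`` (consistent when valid instruments carry more
  than half the weight), with a seeded parametric-bootstrap SE;
* Egger — weighted regression with an intercept (the intercept estimates
  directional pleiotropy), after orienting all exposure effects >= 0.

A pair is flagged "MR-supported" when the IVW estimate is nominally
significant (p < 0.05) with OR < 1 (only protective effects are assessed),
and "dual-support" when the weighted median is also p < 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm

from ._rng import substream

__all__ = ["MRResult", "MRConfig", "select_instruments", "harmonize", "ivw",
           "weighted_median", "egger", "remove_outliers", "run_mr"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class MRResult:
    method: str  # {"ivw", "weighted_median", "egger_slope", "egger_intercept"}
    estimate: float
    se: float
    p: float
    n_snps: int
    q_stat: float = float("nan")
    outliers_removed: list[str] = field(default_factory=list)

    @property
    def or_(self) -> float:
        return float(np.exp(self.estimate))


@dataclass
class MRConfig:
    p_threshold: float = 5e-8
    outlier_alpha: float | None = None  # default 0.05/n_instruments per round
    n_boot: int = 1000
    seed: int = 0
    palindromic_eaf_window: tuple[float, float] = (0.42, 0.58)


def select_instruments(exposure: pd.DataFrame, p_threshold: float = 5e-8) -> pd.DataFrame:
    """Instruments associated with the exposure at ``p < p_threshold``."""
    if "p" not in exposure.columns:
        raise KeyError("exposure table lacks a 'p' column")
    kept = exposure[exposure["p"] < p_threshold].reset_index(drop=True)
    if kept.empty:
        raise ValueError(f"no instruments pass p < {p_threshold}")
    return kept


def harmonize(exposure: pd.DataFrame, outcome: pd.DataFrame,
              palindromic_eaf_window: tuple[float, float] = (0.42, 0.58)) -> pd.DataFrame:
    """Align outcome effects to the exposure effect allele.

    Inner join on SNP id; when the outcome's effect allele matches the
    exposure's other allele (directly or as strand complement), the outcome
    beta sign and EAF are flipped.  Palindromic SNPs (A/T, C/G) whose EAF
    falls in the ambiguity window are dropped; irreconcilable allele pairs
    are dropped.  Returns instrument-level columns
    ``snp, beta_x, se_x, beta_y, se_y, eaf``.
    """
    merged = exposure.merge(outcome, on="snp", suffixes=("_x", "_y"))
    if merged.empty:
        raise ValueError("no shared SNPs between exposure and outcome")
    rows = []
    lo, hi = palindromic_eaf_window
    for r in merged.itertuples(index=False):
        ea_x, oa_x = r.effect_allele_x, r.other_allele_x
        ea_y, oa_y = r.effect_allele_y, r.other_allele_y
        if (ea_x, oa_x) in _PALINDROMIC and lo <= r.eaf_x <= hi:
            continue
        beta_y, eaf_y = r.beta_y, r.eaf_y
        comp = (_COMPLEMENT.get(ea_y, "?"), _COMPLEMENT.get(oa_y, "?"))
        if (ea_y, oa_y) == (ea_x, oa_x) or comp == (ea_x, oa_x):
            pass
        elif (ea_y, oa_y) == (oa_x, ea_x) or comp == (oa_x, ea_x):
            beta_y, eaf_y = -beta_y, 1.0 - eaf_y
        else:
            continue  # alleles irreconcilable
        rows.append({"snp": r.snp, "beta_x": r.beta_x, "se_x": r.se_x,
                     "beta_y": beta_y, "se_y": r.se_y, "eaf": r.eaf_x})
    if not rows:
        raise ValueError("no SNPs survive harmonization")
    return pd.DataFrame(rows)


def _check(input: pd.DataFrame, min_snps: int, method: str) -> None:
    if len(input) < min_snps:
        raise ValueError(f"{method} needs >= {min_snps} instruments, got {len(input)}")
    if (input["se_x"] <= 0).any() or (input["se_y"] <= 0).any():
        raise ValueError("standard errors must be positive")


def ivw(input: pd.DataFrame) -> MRResult:
    """Fixed-effect IVW estimate with Cochran's Q heterogeneity statistic."""
    _check(input, 2, "IVW")
    bx = input["beta_x"].to_numpy()
    by = input["beta_y"].to_numpy()
    w = input["se_y"].to_numpy() ** -2.0
    est = float(np.sum(w * bx * by) / np.sum(w * bx**2))
    se = float(np.sqrt(1.0 / np.sum(w * bx**2)))
    q = float(np.sum(w * (by - est * bx) ** 2))
    p = float(2.0 * norm.sf(abs(est / se)))
    return MRResult("ivw", est, se, max(p, np.finfo(float).tiny), len(input), q_stat=q)


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    # percentile interpolation at cumulative weight 0.5
    order = np.argsort(ratios, kind="stable")
    r = ratios[order]
    w = weights[order] / weights.sum()
    cum = np.cumsum(w) - 0.5 * w  # weight-centered cumulative positions
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    return float(np.interp(0.5, cum, r))


def weighted_median(input: pd.DataFrame, n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Weighted-median estimate with parametric-bootstrap standard error.

    Ratio estimates ``beta_y/beta_x`` are weighted by ``(beta_x/se_y)^2``
    (the inverse of the leading-order ratio variance); the estimate is the
    interpolated ratio at cumulative weight 0.5.  The SE resamples
    ``(beta_x, beta_y)`` from their sampling distributions ``n_boot`` times.
    """
    _check(input, 3, "weighted median")
    bx = input["beta_x"].to_numpy()
    by = input["beta_y"].to_numpy()
    se_x = input["se_x"].to_numpy()
    se_y = input["se_y"].to_numpy()
    if np.any(bx == 0):
        raise ValueError("beta_x contains zeros; ratio estimates undefined")
    est = _weighted_median_point(by / bx, (bx / se_y) ** 2)
    rng = substream(seed, "weighted-median-boot")
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bxs = bx + se_x * rng.standard_normal(len(bx))
        bys = by + se_y * rng.standard_normal(len(by))
        bxs = np.where(bxs == 0, np.finfo(float).eps, bxs)
        boots[b] = _weighted_median_point(bys / bxs, (bxs / se_y) ** 2)
    se = float(boots.std(ddof=1))
    p = float(2.0 * norm.sf(abs(est / se))) if se > 0 else float("nan")
    return MRResult("weighted_median", float(est), se, max(p, np.finfo(float).tiny),
                    len(input))


def egger(input: pd.DataFrame) -> tuple[MRResult, MRResult]:
    """Egger regression: weighted fit of beta_y on beta_x with intercept.

    Exposure effects are oriented non-negative first (flipping beta_y with
    them), so the intercept is interpretable as average directional
    pleiotropy.  Returns (slope result, intercept result).
    """
    _check(input, 3, "Egger")
    sign = np.where(input["beta_x"].to_numpy() < 0, -1.0, 1.0)
    bx = input["beta_x"].to_numpy() * sign
    by = input["beta_y"].to_numpy() * sign
    w = input["se_y"].to_numpy() ** -2.0
    X = np.column_stack([np.ones_like(bx), bx])
    WX = X * w[:, None]
    xtwx = X.T @ WX
    coef = np.linalg.solve(xtwx, WX.T @ by)
    resid = by - X @ coef
    q = float(np.sum(w * resid**2))
    dof = len(bx) - 2
    # multiplicative over-dispersion, floored at 1 (standard Egger practice)
    phi = max(q / dof, 1.0) if dof > 0 else 1.0
    cov = np.linalg.inv(xtwx) * phi
    ses = np.sqrt(np.diag(cov))
    ps = 2.0 * norm.sf(np.abs(coef / ses))
    slope = MRResult("egger_slope", float(coef[1]), float(ses[1]),
                     float(max(ps[1], np.finfo(float).tiny)), len(bx), q_stat=q)
    intercept = MRResult("egger_intercept", float(coef[0]), float(ses[0]),
                         float(max(ps[0], np.finfo(float).tiny)), len(bx), q_stat=q)
    return slope, intercept


def remove_outliers(input: pd.DataFrame, alpha: float | None = None) -> tuple[pd.DataFrame, list[str]]:
    """Iterative Q-contribution outlier removal.

    Each round refits IVW and drops the instrument with the largest
    contribution ``w_j (beta_yj - est*beta_xj)^2`` to Cochran's Q while that
    contribution exceeds the chi-square(1) upper-``alpha`` quantile and at
    least 3 instruments would remain.  Default alpha is Bonferroni
    0.05/n_instruments per round.  Returns (filtered input, removed ids).
    """
    current = input.reset_index(drop=True)
    removed: list[str] = []
    while len(current) > 3:
        a = alpha if alpha is not None else 0.05 / len(current)
        cut = chi2.ppf(1.0 - a, df=1)
        est = ivw(current).estimate
        w = current["se_y"].to_numpy() ** -2.0
        contrib = w * (current["beta_y"].to_numpy() - est * current["beta_x"].to_numpy()) ** 2
        j = int(np.argmax(contrib))
        if contrib[j] <= cut:
            break
        removed.append(str(current.iloc[j]["snp"]))
        current = current.drop(index=current.index[j]).reset_index(drop=True)
    return current, removed


def run_mr(exposure: pd.DataFrame, outcome: pd.DataFrame,
           config: MRConfig | None = None) -> dict:
    """Full MR pipeline for one exposure/outcome pair.

    Returns a dict with per-method :class:`MRResult` under ``results``, the
    harmonized instrument table, removed outliers, and the support flags.
    """
    cfg = config or MRConfig()
    instruments = select_instruments(exposure, cfg.p_threshold)
    harmonized = harmonize(instruments, outcome, cfg.palindromic_eaf_window)
    filtered, removed = remove_outliers(harmonized, cfg.outlier_alpha)

    results: dict[str, MRResult] = {}
    res_ivw = ivw(filtered)
    res_ivw.outliers_removed = removed
    results["ivw"] = res_ivw
    if len(filtered) >= 3:
        results["weighted_median"] = weighted_median(filtered, cfg.n_boot, cfg.seed)
        slope, intercept = egger(filtered)
        results["egger_slope"] = slope
        results["egger_intercept"] = intercept

    mr_supported = res_ivw.p < 0.05 and res_ivw.or_ < 1.0
    wm = results.get("weighted_median")
    dual_support = mr_supported and wm is not None and wm.p < 0.05
    return {"results": results, "instruments": filtered, "outliers_removed": removed,
            "mr_supported": bool(mr_supported), "dual_support": bool(dual_support)}
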