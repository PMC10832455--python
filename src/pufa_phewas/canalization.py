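"""Polygenic-score percentile prevalence curves and the delta-departure
canalization statistic.

For a disease and a polygenic score, individuals are ranked into 100
near-equal score bins and the per-bin case fraction forms a prevalence
curve.  Curves are built separately for two strata (obese vs non-obese, or
low vs high metabolite).  The canalization contrast is:

* ``tail_difference`` — mean prevalence over the extreme right-tail bins
  minus the extreme left-tail bins (2% tails by default, case-weighted
  across the tail bins);
* ``delta observed`` — tail difference of stratum A minus stratum B;
* ``delta expected`` — the same quantity on curves re-simulated from a
  smooth per-stratum expectation (logistic-in-percentile fit, binomial
  sampling per bin), repeated ``n_iterations`` times;
* ``delta departure`` — ``(mean|expected| - |observed|) / sd(|expected|)``.

A positive departure means the strata deviate less than expected
(canalization); a negative departure means more (decanalization).  The
signed observed delta is retained alongside, since only its magnitude
enters the departure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._rng import substream

__all__ = ["PrevalenceCurve", "CanalizationResult", "dichotomize_by_mean",
           "prevalence_by_percentile", "tail_difference", "delta_observed",
           "delta_expected", "delta_departure", "canalization_contrast",
           "comparison_grid"]


@dataclass
class PrevalenceCurve:
    """Per-bin counts: table with columns bin (1-based), n, k, prevalence."""

    table: pd.DataFrame

    @property
    def n_bins(self) -> int:
        return len(self.table)

    def __post_init__(self) -> None:
        t = self.table
        missing = {"bin", "n", "k", "prevalence"} - set(t.columns)
        if missing:
            raise ValueError(f"curve table missing columns {sorted(missing)}")


@dataclass
class CanalizationResult:
    stratum_a: str
    stratum_b: str
    delta_observed: float
    delta_expected_mean: float
    delta_expected_sd: float
    delta_departure: float
    n_iterations: int
    seed: int
    tail_fraction: float


def dichotomize_by_mean(z) -> np.ndarray:
    """Labels 'high' where z >= mean(z), else 'low' (inclusive at the mean)."""
    z = np.asarray(z, dtype=float)
    if np.isnan(z).any():
        raise ValueError("z contains missing values")
    return np.where(z >= z.mean(), "high", "low")


def prevalence_by_percentile(score, status, n_bins: int = 100) -> PrevalenceCurve:
    """Rank by score into ``n_bins`` near-equal bins; per-bin case fraction.

    Ties are broken by stable input order, so the binning is deterministic.
    Bin sizes differ by at most one individual.
    """
    score = np.asarray(score, dtype=float)
    status = np.asarray(status, dtype=float)
    if score.shape != status.shape:
        raise ValueError("score and status must have equal length")
    n = len(score)
    if n < n_bins:
        raise ValueError(f"need >= {n_bins} individuals, got {n}")
    order = np.argsort(score, kind="stable")
    # bin b gets positions [b*n/n_bins, (b+1)*n/n_bins) -> sizes differ by <= 1
    edges = (np.arange(n_bins + 1) * n) // n_bins
    rows = []
    for b in range(n_bins):
        idx = order[edges[b]:edges[b + 1]]
        k = float(status[idx].sum())
        rows.append({"bin": b + 1, "n": len(idx), "k": int(k),
                     "prevalence": k / len(idx)})
    return PrevalenceCurve(pd.DataFrame(rows))


def _tail_bins(n_bins: int, tail_fraction: float) -> int:
    n_tail = int(np.ceil(tail_fraction * n_bins))
    if n_tail < 1:
        raise ValueError("tail_fraction too small for the number of bins")
    return n_tail


def tail_difference(curve: PrevalenceCurve, tail_fraction: float = 0.02) -> float:
    """Case-weighted prevalence of the top tail bins minus the bottom tail bins."""
    n_tail = _tail_bins(curve.n_bins, tail_fraction)
    t = curve.table.sort_values("bin")
    lo, hi = t.head(n_tail), t.tail(n_tail)
    return float(hi["k"].sum() / hi["n"].sum() - lo["k"].sum() / lo["n"].sum())


def delta_observed(curve_a: PrevalenceCurve, curve_b: PrevalenceCurve,
                   tail_fraction: float = 0.02) -> float:
    """Signed tail-difference contrast: stratum A minus stratum B."""
    if curve_a.n_bins != curve_b.n_bins:
        raise ValueError("curves must share the same binning")
    return tail_difference(curve_a, tail_fraction) - tail_difference(curve_b, tail_fraction)


def _fit_expected(curve: PrevalenceCurve, model: str) -> np.ndarray:
    t = curve.table.sort_values("bin")
    n = t["n"].to_numpy(dtype=float)
    k = t["k"].to_numpy(dtype=float)
    x = t["bin"].to_numpy(dtype=float)
    if k.sum() == 0 or (n - k).sum() == 0:
        raise ValueError("degenerate stratum: all-case or all-control")
    X = np.column_stack([np.ones_like(x), x])
    if model == "logistic":
        glm = sm.GLM(np.column_stack([k, n - k]), X,
                     family=sm.families.Binomial())
        fitted = np.asarray(glm.fit().predict(X), dtype=float)
    elif model == "linear":
        w = n
        coef = np.linalg.solve((X * w[:, None]).T @ X, (X * w[:, None]).T @ (k / n))
        fitted = X @ coef
    else:
        raise ValueError(f"unknown expectation model {model!r}")
    return np.clip(fitted, 0.0, 1.0)


def delta_expected(curve_a: PrevalenceCurve, curve_b: PrevalenceCurve,
                   n_iterations: int = 10, seed: int = 0,
                   tail_fraction: float = 0.02, model: str = "logistic") -> np.ndarray:
    """Null draws of the tail contrast from smooth per-stratum expectations.

    Each stratum's curve is fitted with a monotone-in-percentile prevalence
    model; per iteration, per-bin case counts are redrawn as
    ``Binomial(n_b, fitted_b)`` independently ("equal variance" given the
    bin sizes) and the tail contrast recomputed on the simulated pair.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    fit_a = _fit_expected(curve_a, model)
    fit_b = _fit_expected(curve_b, model)
    n_a = curve_a.table.sort_values("bin")["n"].to_numpy()
    n_b = curve_b.table.sort_values("bin")["n"].to_numpy()
    rng = substream(seed, "delta-expected")
    out = np.empty(n_iterations)
    for it in range(n_iterations):
        sim_a = _simulated_curve(n_a, rng.binomial(n_a, fit_a))
        sim_b = _simulated_curve(n_b, rng.binomial(n_b, fit_b))
        out[it] = delta_observed(sim_a, sim_b, tail_fraction)
    return out


def _simulated_curve(n: np.ndarray, k: np.ndarray) -> PrevalenceCurve:
    return PrevalenceCurve(pd.DataFrame({
        "bin": np.arange(1, len(n) + 1), "n": n, "k": k, "prevalence": k / n}))


def delta_departure(observed: float, expected: np.ndarray) -> float:
    """Scaled departure: (mean|expected| - |observed|) / sd(|expected|).

    Positive values mean the observed tail contrast is smaller in magnitude
    than expected (canalization); negative values mean larger
    (decanalization).
    """
    expected = np.asarray(expected, dtype=float)
    if len(expected) < 2:
        raise ValueError("need >= 2 expected values")
    abs_exp = np.abs(expected)
    sd = abs_exp.std(ddof=1)
    if sd == 0:
        raise ValueError("zero spread in expected deltas; departure undefined")
    return float((abs_exp.mean() - abs(observed)) / sd)


def canalization_contrast(cohort: pd.DataFrame, score_col: str, status_col: str,
                          stratum_col: str, n_bins: int = 100,
                          tail_fraction: float = 0.02, n_iterations: int = 10,
                          seed: int = 0, model: str = "logistic",
                          stratum_a=1, stratum_b=0) -> CanalizationResult:
    """End-to-end canalization contrast between two strata of a cohort.

    ``stratum_col`` holds stratum labels (e.g. obesity 0/1 or 'low'/'high');
    curve A is built from rows equal to ``stratum_a`` (obese or
    low-metabolite by convention), curve B from ``stratum_b``.
    """
    sub = cohort.dropna(subset=[score_col, stratum_col])
    strata = sub[stratum_col]
    curves = {}
    for label in (stratum_a, stratum_b):
        grp = sub[strata == label]
        curves[label] = prevalence_by_percentile(
            grp[score_col].to_numpy(), grp[status_col].to_numpy(), n_bins)
    obs = delta_observed(curves[stratum_a], curves[stratum_b], tail_fraction)
    exp = delta_expected(curves[stratum_a], curves[stratum_b], n_iterations,
                         seed, tail_fraction, model)
    dep = delta_departure(obs, exp)
    return CanalizationResult(
        stratum_a=str(stratum_a), stratum_b=str(stratum_b), delta_observed=obs,
        delta_expected_mean=float(np.abs(exp).mean()),
        delta_expected_sd=float(np.abs(exp).std(ddof=1)),
        delta_departure=dep, n_iterations=n_iterations, seed=seed,
        tail_fraction=tail_fraction)


def comparison_grid(diseases, metabolites, measures=("bmi", "whr")) -> pd.DataFrame:
    """Enumerate every (disease, metabolite, obesity measure) comparison once.

    This is the bookkeeping grid of the interaction/canalization screen:
    D diseases x M metabolites x 2 obesity measures rows.
    """
    rows = [{"disease": d, "metabolite": m, "measure": w}
            for d in diseases for m in metabolites for w in measures]
    return pd.DataFrame(rows, columns=["disease", "metabolite", "measure"])
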