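"""Covariate-adjusted logistic disease associations.

Two modes are fitted per (metabolite, disease) pair, mirroring the PheWAS
design:

* ``level`` — ``status ~ Z_metabolite + age + sex + age^2 + PC1..PC10``
* ``pgs``   — ``status ~ scaled PGS_m + age + sex + age^2 + PC1..PC10``

Effects are per SD of predictor (both predictors are Z-scored over the
analysis cohort), reported as OR with a 95% Wald CI on the log-OR scale.
Age is mean-centered before squaring for numerical stability; this changes
only the covariate parameterization, not the model space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["LogisticFit", "AssociationResult", "fit_logistic", "run_association",
           "association_scan", "build_design", "COVARIATE_NOTE"]

COVARIATE_NOTE = "age + sex + age^2 + PC1..PCk"

_SEP_TOL = 1e-8
Z95 = 1.959963984540054  # Phi^{-1}(0.975)


@dataclass
class LogisticFit:
    """Coefficient table plus convergence/separation diagnostics."""

    table: pd.DataFrame  # index: term; columns: beta, se, z, p
    converged: bool
    separation: bool
    n: int
    llf: float

    def coef(self, term: str) -> tuple[float, float, float]:
        row = self.table.loc[term]
        return float(row["beta"]), float(row["se"]), float(row["p"])


@dataclass
class AssociationResult:
    metabolite: str
    disease: str
    mode: str  # {"level", "pgs"}
    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    p: float
    n_case: int
    n_control: int
    flags: list[str] = field(default_factory=list)

    @property
    def direction(self) -> str:
        return "risk" if self.or_ > 1.0 else "protective"


def fit_logistic(y, X: pd.DataFrame, tol: float = 1e-8) -> LogisticFit:
    """Maximum-likelihood logistic fit with Wald inference per column.

    Raises on a single-class response or a rank-deficient design; complete
    (quasi-)separation is detected from fitted probabilities pinned at 0/1
    and flagged rather than raised.
    """
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("single-class response: logistic model is undefined")
    Xv = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise ValueError("design matrix is rank deficient")

    model = sm.Logit(y, X)
    try:
        res = model.fit(method="newton", tol=tol, maxiter=100, disp=0)
        converged = bool(res.mle_retvals.get("converged", True))
    except Exception:
        res = model.fit(method="bfgs", maxiter=500, disp=0)
        converged = bool(res.mle_retvals.get("converged", False))

    fitted = res.predict()
    separation = bool(np.any(fitted < _SEP_TOL) or np.any(fitted > 1 - _SEP_TOL))
    table = pd.DataFrame({
        "beta": res.params, "se": res.bse, "z": res.tvalues, "p": res.pvalues,
    })
    return LogisticFit(table=table, converged=converged, separation=separation,
                       n=len(y), llf=float(res.llf))


def build_design(cohort: pd.DataFrame, predictor: pd.Series,
                 extra: dict[str, pd.Series] | None = None) -> pd.DataFrame:
    """Standard covariate design: const, predictor(s), age, sex, age^2, PCs."""
    age_c = cohort["age"] - cohort["age"].mean()
    cols = {"const": 1.0, "predictor": predictor}
    for name, series in (extra or {}).items():
        cols[name] = series
    cols.update({"age": age_c, "sex": cohort["sex"].astype(float), "age2": age_c**2})
    for c in sorted((c for c in cohort.columns if c.startswith("pc")),
                    key=lambda c: int(c[2:])):
        cols[c] = cohort[c]
    return pd.DataFrame(cols, index=cohort.index)


def run_association(cohort: pd.DataFrame, metabolite: str, disease: str,
                    mode: str) -> AssociationResult:
    """Fit one covariate-adjusted logistic association.

    ``cohort`` must be prepared (``z_<met>`` / ``zpgs_<met>`` present, see
    :func:`pufa_phewas.prep.prepare_cohort`); rows with a missing predictor
    are dropped complete-case for this model only.
    """
    if mode not in ("level", "pgs"):
        raise ValueError(f"mode must be 'level' or 'pgs', got {mode!r}")
    pred_col = f"z_{metabolite}" if mode == "level" else f"zpgs_{metabolite}"
    status_col = f"status_{disease}"
    sub = cohort.dropna(subset=[pred_col])
    y = sub[status_col].to_numpy(dtype=float)
    X = build_design(sub, sub[pred_col])
    fit = fit_logistic(y, X)
    beta, se, p = fit.coef("predictor")
    flags = []
    if not fit.converged:
        flags.append("non_converged")
    if fit.separation:
        flags.append("separation")
    return AssociationResult(
        metabolite=metabolite, disease=disease, mode=mode,
        beta=beta, se=se, or_=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z95 * se)), ci_high=float(np.exp(beta + Z95 * se)),
        p=float(p), n_case=int(y.sum()), n_control=int(len(y) - y.sum()),
        flags=flags,
    )


def association_scan(cohort: pd.DataFrame, metabolites: list[str],
                     diseases: list[str], modes: tuple[str, ...] = ("level", "pgs"),
                     ) -> pd.DataFrame:
    """All (metabolite, disease, mode) associations as one tidy table."""
    rows = []
    for met in metabolites:
        for dis in diseases:
            for mode in modes:
                r = run_association(cohort, met, dis, mode)
                rows.append({
                    "metabolite": r.metabolite, "disease": r.disease, "mode": r.mode,
                    "beta": r.beta, "se": r.se, "or": r.or_,
                    "ci_low": r.ci_low, "ci_high": r.ci_high, "p": r.p,
                    "n_case": r.n_case, "n_control": r.n_control,
                    "flags": ";".join(r.flags),
                })
    return pd.DataFrame(rows)
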