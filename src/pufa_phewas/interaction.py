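"""Metabolite x body-weight interaction models on disease.

Fits the full main-effects-plus-product logistic model

    status ~ predictor + weight + predictor*weight + age + sex + age^2 + PCs

where the predictor is the metabolite Z-score (``level``) or the Z-scored
metabolite PGS (``pgs``), and the body-weight term is a standardized
continuous measure (``bmi_z``, ``whr_z``) or an obesity indicator
(``bmi_obese``, ``whr_obese``; non-obese is the reference).  The Wald p for
the product term is the interaction test; nominal significance (p < 0.05)
drives the screen, with Bonferroni-adjusted flags emitted alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import build_design, fit_logistic
from .triangulation import TriangulatedAssociation

__all__ = ["InteractionResult", "fit_interaction", "interaction_screen",
           "WEIGHT_COLUMNS", "PREDICTOR_MODES"]

WEIGHT_COLUMNS = {"bmi_z": "z_bmi", "whr_z": "z_whr",
                  "bmi_obese": "obese_bmi", "whr_obese": "obese_whr"}
PREDICTOR_MODES = ("level", "pgs")


@dataclass
class InteractionResult:
    metabolite: str
    disease: str
    predictor_mode: str
    weight_mode: str
    beta_main_predictor: float
    beta_main_weight: float
    beta_interaction: float
    se_interaction: float
    p_interaction: float
    n: int
    flags: list[str] = field(default_factory=list)


def fit_interaction(cohort: pd.DataFrame, metabolite: str, disease: str,
                    predictor_mode: str, weight_mode: str) -> InteractionResult:
    """Fit one interaction model on a prepared cohort."""
    if predictor_mode not in PREDICTOR_MODES:
        raise ValueError(f"unknown predictor_mode {predictor_mode!r}")
    if weight_mode not in WEIGHT_COLUMNS:
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    pred_col = f"z_{metabolite}" if predictor_mode == "level" else f"zpgs_{metabolite}"
    weight_col = WEIGHT_COLUMNS[weight_mode]
    sub = cohort.dropna(subset=[pred_col, weight_col])
    pred = sub[pred_col]
    weight = sub[weight_col].astype(float)
    X = build_design(sub, pred, extra={"weight": weight,
                                       "interaction": pred * weight})
    fit = fit_logistic(sub[f"status_{disease}"].to_numpy(dtype=float), X)
    b_p, _, _ = fit.coef("predictor")
    b_w, _, _ = fit.coef("weight")
    b_i, se_i, p_i = fit.coef("interaction")
    flags = []
    if not fit.converged:
        flags.append("non_converged")
    if fit.separation:
        flags.append("separation")
    return InteractionResult(
        metabolite=metabolite, disease=disease, predictor_mode=predictor_mode,
        weight_mode=weight_mode, beta_main_predictor=b_p, beta_main_weight=b_w,
        beta_interaction=b_i, se_interaction=se_i, p_interaction=p_i,
        n=fit.n, flags=flags)


def interaction_screen(cohort: pd.DataFrame,
                       triangulated: list[TriangulatedAssociation],
                       alpha: float = 0.05) -> pd.DataFrame:
    """Run all weight modes x predictor modes over the passing associations.

    Returns a tidy table with one row per fitted model, nominal and
    Bonferroni significance flags, plus (as ``DataFrame.attrs['group_summary']``)
    the fraction of nominally significant interactions per disease group if
    a ``group`` attribute is attached to the associations.
    """
    passing = [t for t in triangulated if t.passes]
    rows = []
    for t in passing:
        for pmode in PREDICTOR_MODES:
            for wmode in WEIGHT_COLUMNS:
                r = fit_interaction(cohort, t.metabolite, t.disease, pmode, wmode)
                rows.append({
                    "metabolite": r.metabolite, "disease": r.disease,
                    "predictor_mode": r.predictor_mode, "weight_mode": r.weight_mode,
                    "beta_main_predictor": r.beta_main_predictor,
                    "beta_main_weight": r.beta_main_weight,
                    "beta_interaction": r.beta_interaction,
                    "se_interaction": r.se_interaction,
                    "p_interaction": r.p_interaction, "n": r.n,
                    "flags": ";".join(r.flags),
                })
    table = pd.DataFrame(rows, columns=[
        "metabolite", "disease", "predictor_mode", "weight_mode",
        "beta_main_predictor", "beta_main_weight", "beta_interaction",
        "se_interaction", "p_interaction", "n", "flags"])
    if len(table):
        table["nominal_sig"] = table["p_interaction"] < alpha
        table["bonferroni_sig"] = table["p_interaction"] < alpha / len(table)
    else:
        table["nominal_sig"] = pd.Series(dtype=bool)
        table["bonferroni_sig"] = pd.Series(dtype=bool)
    return table


def group_interaction_fractions(screen: pd.DataFrame,
                                group_map: dict[str, str]) -> pd.DataFrame:
    """Fraction of nominally significant interaction tests per disease group."""
    if screen.empty:
        return pd.DataFrame(columns=["group", "n_tests", "n_nominal", "fraction"])
    df = screen.copy()
    df["group"] = df["disease"].map(group_map)
    agg = (df.groupby("group", dropna=False)
             .agg(n_tests=("nominal_sig", "size"), n_nominal=("nominal_sig", "sum"))
             .reset_index())
    agg["fraction"] = agg["n_nominal"] / agg["n_tests"]
    return agg.sort_values("fraction", ascending=False).reset_index(drop=True)
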