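"""Simulation studies that calibrate the pipeline's statistical machinery.

Each function runs a self-contained Monte Carlo study on synthetic data and
returns summary numbers: estimator recovery and robustness for MR,
type-I error and attenuation for the association models, null behaviour of
the triangulation rule, and the null/planted behaviour of the
delta-departure statistic.  These are the checks a user should rerun after
modifying the estimators; problem sizes are chosen so the full battery runs
in minutes on one core.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from ._rng import child_seed
from .association import run_association
from .canalization import canalization_contrast
from .interaction import fit_interaction
from .mr import MRConfig, harmonize, ivw, run_mr, select_instruments, weighted_median
from .prep import prepare_cohort
from .synthetic import (CohortSpec, DiseaseSpec, MetaboliteSpec,
                        SummaryStatsSpec, generate_cohort,
                        generate_summary_stats)

__all__ = ["ivw_recovery", "weighted_median_robustness", "type1_error",
           "planted_effect_recovery", "null_triangulation_hits",
           "canalization_calibration", "interaction_type1"]


def ivw_recovery(causal: float = -0.3, n_snps: int = 50, n_rep: int = 100,
                 seed: int = 0) -> dict:
    """Mean IVW estimate over replicate summary-statistic pairs."""
    ests = []
    for r in range(n_rep):
        s = child_seed(seed, f"ivw-recovery:{r}")
        e, o = generate_summary_stats(
            SummaryStatsSpec(seed=s, causal_effect=causal, n_snps=n_snps))
        ests.append(run_mr(e, o, MRConfig(seed=s, n_boot=2))["results"]["ivw"].estimate)
    ests = np.asarray(ests)
    return {"mean": float(ests.mean()), "mc_se": float(ests.std(ddof=1) / np.sqrt(n_rep)),
            "causal": causal, "n_rep": n_rep}


def weighted_median_robustness(causal: float = -0.3, invalid_fraction: float = 0.3,
                               pleiotropy_mean: float = 0.1, n_rep: int = 100,
                               seed: int = 0) -> dict:
    """Weighted-median vs IVW bias under directional pleiotropy."""
    wm, iv = [], []
    for r in range(n_rep):
        s = child_seed(seed, f"wm-robust:{r}")
        e, o = generate_summary_stats(SummaryStatsSpec(
            seed=s, causal_effect=causal, n_snps=50,
            invalid_fraction=invalid_fraction,
            pleiotropy_mean=pleiotropy_mean, pleiotropy_sd=0.05))
        h = harmonize(select_instruments(e), o)
        iv.append(ivw(h).estimate)
        wm.append(weighted_median(h, n_boot=50, seed=s).estimate)
    return {"wm_bias": float(np.mean(wm) - causal),
            "ivw_bias": float(np.mean(iv) - causal),
            "causal": causal, "n_rep": n_rep}


def _null_cohort_spec(n: int, seed: int, prevalence: float = 0.1) -> CohortSpec:
    return CohortSpec(n_individuals=n, seed=seed,
                      metabolites=[MetaboliteSpec("m")],
                      diseases=[DiseaseSpec("d", baseline_prevalence=prevalence,
                                            metabolite="m")])


def type1_error(n_rep: int = 200, n: int = 5000, alpha: float = 0.05,
                seed: int = 0) -> dict:
    """Level-mode rejection rate on global-null cohorts."""
    ps = []
    for r in range(n_rep):
        c = generate_cohort(_null_cohort_spec(n, child_seed(seed, f"type1:{r}")))
        ps.append(run_association(prepare_cohort(c, ["m"]), "m", "d", "level").p)
    ps = np.asarray(ps)
    rate = float((ps < alpha).mean())
    return {"rate": rate, "alpha": alpha,
            "mc_se": float(np.sqrt(alpha * (1 - alpha) / n_rep)), "n_rep": n_rep}


def planted_effect_recovery(odds_ratio: float = 0.8, h2_pgs: float = 0.5,
                            n: int = 100_000, seed: int = 0) -> dict:
    """Level/PGS effect recovery and the sqrt(h2) attenuation of the PGS mode."""
    beta = float(np.log(odds_ratio))
    spec = CohortSpec(n_individuals=n, seed=child_seed(seed, "planted"),
                      metabolites=[MetaboliteSpec("m", h2_pgs=h2_pgs)],
                      diseases=[DiseaseSpec("d", baseline_prevalence=0.1,
                                            beta_metabolite=beta, metabolite="m")])
    prep = prepare_cohort(generate_cohort(spec), ["m"])
    rl = run_association(prep, "m", "d", "level")
    rp = run_association(prep, "m", "d", "pgs")
    return {"beta_true": beta, "level_beta": rl.beta, "level_se": rl.se,
            "pgs_beta": rp.beta, "pgs_se": rp.se,
            "attenuation": rp.beta / rl.beta,
            "attenuation_expected": float(np.sqrt(h2_pgs)), "n": n}


def null_triangulation_hits(n_seeds: int = 20, n: int = 5000,
                            threshold: float = 0.05 / (1254 * 3 * 2),
                            seed: int = 0) -> dict:
    """Triangulated hits on global-null cohorts at the PheWAS-wide threshold."""
    from .association import association_scan
    from .triangulation import triangulate

    def _to_results(df):
        from .association import AssociationResult
        return [AssociationResult(metabolite=r["metabolite"], disease=r["disease"],
                                  mode=r["mode"], beta=r["beta"], se=r["se"],
                                  or_=r["or"], ci_low=r["ci_low"], ci_high=r["ci_high"],
                                  p=r["p"], n_case=r["n_case"], n_control=r["n_control"])
                for r in df.to_dict("records")]

    hits = 0
    for r in range(n_seeds):
        spec = CohortSpec(
            n_individuals=n, seed=child_seed(seed, f"null-tri:{r}"),
            metabolites=[MetaboliteSpec("m1"), MetaboliteSpec("m2")],
            diseases=[DiseaseSpec(f"d{j}", baseline_prevalence=0.1, metabolite="m1")
                      for j in range(3)])
        prep = prepare_cohort(generate_cohort(spec), ["m1", "m2"])
        scan = association_scan(prep, ["m1", "m2"], [f"d{j}" for j in range(3)])
        tri = triangulate(_to_results(scan[scan["mode"] == "level"]),
                          _to_results(scan[scan["mode"] == "pgs"]), threshold)
        hits += sum(t.passes for t in tri)
    return {"hits": hits, "n_seeds": n_seeds, "threshold": threshold}


def canalization_calibration(gamma: float, n_seeds: int = 50, n: int = 40_000,
                             seed: int = 0) -> dict:
    """Delta-departure distribution across seeds for a given PGS x obesity
    interaction strength (gamma=0 is the no-interaction null)."""
    deps = []
    for r in range(n_seeds):
        s = child_seed(seed, f"canal:{gamma}:{r}")
        spec = CohortSpec(
            n_individuals=n, seed=s, metabolites=[MetaboliteSpec("m")],
            diseases=[DiseaseSpec("d", baseline_prevalence=0.2, beta_metabolite=-0.4,
                                  metabolite="m", gamma_interaction=gamma,
                                  interaction_predictor="pgs",
                                  interaction_weight="bmi_obese")])
        prep = prepare_cohort(generate_cohort(spec), ["m"])
        res = canalization_contrast(prep, "zpgs_m", "status_d", "obese_bmi",
                                    n_iterations=10,
                                    seed=child_seed(seed, f"canal-exp:{gamma}:{r}"))
        deps.append(res.delta_departure)
    deps = np.asarray(deps)
    return {"mean": float(deps.mean()), "sd": float(deps.std(ddof=1)),
            "sem": float(deps.std(ddof=1) / np.sqrt(n_seeds)),
            "gamma": gamma, "n_seeds": n_seeds, "values": deps.tolist()}


def interaction_type1(n_rep: int = 200, n: int = 4000, alpha: float = 0.05,
                      seed: int = 0) -> dict:
    """Interaction-term rejection rate when no interaction is planted."""
    ps = []
    for r in range(n_rep):
        spec = CohortSpec(
            n_individuals=n, seed=child_seed(seed, f"int-type1:{r}"),
            metabolites=[MetaboliteSpec("m")],
            diseases=[DiseaseSpec("d", baseline_prevalence=0.12,
                                  beta_metabolite=-0.2, metabolite="m")])
        prep = prepare_cohort(generate_cohort(spec), ["m"])
        ps.append(fit_interaction(prep, "m", "d", "pgs", "bmi_z").p_interaction)
    ps = np.asarray(ps)
    return {"rate": float((ps < alpha).mean()), "alpha": alpha,
            "mc_se": float(np.sqrt(alpha * (1 - alpha) / n_rep)), "n_rep": n_rep}
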