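"""End-to-end pipeline orchestration from a single structured config.

Stage order mirrors the analysis design: synthesize (or load) a cohort ->
prepare -> level/PGS association scan -> triangulation + disease-group
enrichment -> two-sample MR on summary statistics -> interaction screen ->
canalization contrasts.  All randomness derives from one root seed via
named substreams, so a rerun with the same config is bit-identical for
every deterministic stage (all stages here are deterministic given the
seed).  Each run writes a manifest (config hash, seed, package versions).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from ._rng import child_seed
from . import io as pio
from .association import association_scan
from .canalization import canalization_contrast
from .interaction import interaction_screen
from .mr import MRConfig, run_mr
from .prep import min_case_filter, prepare_cohort
from .synthetic import (CohortSpec, DiseaseSpec, MetaboliteSpec,
                        SummaryStatsSpec, generate_cohort,
                        generate_summary_stats)
from .triangulation import bonferroni_threshold, enrichment, overlap_counts, triangulate

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "load_config", "save_config",
           "default_demo_config"]


@dataclass
class PipelineConfig:
    """Structured configuration: one block per stage."""

    seed: int = 0
    output_dir: str = "results"
    cohort: dict = field(default_factory=dict)       # CohortSpec fields or {"path": ...}
    summary_stats: dict = field(default_factory=dict)  # per-pair SummaryStatsSpec or paths
    alpha: float = 0.05
    n_association_tests: int | None = None  # default: diseases * metabolites * 2
    min_cases: int = 50
    instrument_p_threshold: float = 5e-8
    mr_enabled: bool = True
    interaction_alpha: float = 0.05
    n_bins: int = 100
    tail_fraction: float = 0.02
    n_iterations: int = 10
    canalization_strata: tuple[str, ...] = ("obese_bmi", "obese_whr")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["canalization_strata"] = list(d["canalization_strata"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "canalization_strata" in d:
            d["canalization_strata"] = tuple(d["canalization_strata"])
        return cls(**d)


def load_config(path: str | Path) -> PipelineConfig:
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config {path} did not parse to a mapping")
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
    return path


def _cohort_spec_from_dict(d: dict, seed: int) -> CohortSpec:
    d = dict(d)
    mets = [MetaboliteSpec(**m) for m in d.pop("metabolites", [])]
    dis = [DiseaseSpec(**x) for x in d.pop("diseases", [])]
    d.setdefault("seed", seed)
    return CohortSpec(metabolites=mets, diseases=dis, **d)


def default_demo_config(seed: int = 0, n: int = 20_000,
                        output_dir: str = "results/demo") -> PipelineConfig:
    """A self-contained demo: 3 metabolites, 12 diseases over 4 groups,
    protective effects planted for half the diseases, one interaction."""
    mets = [{"name": "omega3"}, {"name": "omega6"}, {"name": "dha"}]
    groups = ["circulatory", "endocrine", "digestive", "respiratory"]
    diseases = []
    for i in range(12):
        beta = -0.35 if i % 2 == 0 else 0.0
        diseases.append({
            "phecode": f"d{i:03d}", "group": groups[i % 4],
            "baseline_prevalence": 0.08, "beta_metabolite": beta,
            "beta_prs": 0.3, "metabolite": ["omega3", "omega6", "dha"][i % 3],
            "gamma_interaction": -0.3 if i == 0 else 0.0,
            "interaction_predictor": "pgs", "interaction_weight": "bmi_obese",
        })
    cohort = {"n_individuals": n, "metabolites": mets, "diseases": diseases}
    sumstats = {"pairs": [
        {"name": "omega3__d000", "n_snps": 50, "causal_effect": -0.3},
        {"name": "omega6__d001", "n_snps": 50, "causal_effect": 0.0},
        {"name": "dha__d002", "n_snps": 50, "causal_effect": -0.2,
         "invalid_fraction": 0.2, "pleiotropy_mean": 0.0, "pleiotropy_sd": 0.05},
    ]}
    return PipelineConfig(seed=seed, output_dir=output_dir, cohort=cohort,
                          summary_stats=sumstats)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all enabled stages; returns the output directory."""
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    # --- cohort ----------------------------------------------------------
    if "path" in config.cohort:
        cohort = pio.read_cohort(config.cohort["path"])
        met_names = sorted({c[len("pgs_"):] for c in cohort.columns
                            if c.startswith("pgs_")})
        group_map = pio.read_group_map(config.cohort["group_map"]) \
            if "group_map" in config.cohort else {}
    else:
        spec = _cohort_spec_from_dict(config.cohort, child_seed(config.seed, "cohort"))
        cohort = generate_cohort(spec)
        met_names = [m.name for m in spec.metabolites]
        group_map = {d.phecode: d.group for d in spec.diseases}
    pio.write_cohort(cohort, outdir / "cohort.tsv")

    prepared = prepare_cohort(cohort, met_names)
    diseases = min_case_filter(prepared, config.min_cases)
    logger.info("analyzing %d diseases, %d metabolites", len(diseases), len(met_names))

    # --- associations ----------------------------------------------------
    scan = association_scan(prepared, met_names, diseases)
    for mode in ("level", "pgs"):
        pio.write_table(scan[scan["mode"] == mode], outdir / f"associations_{mode}.tsv")

    # --- triangulation + enrichment -------------------------------------
    n_tests = config.n_association_tests or (len(diseases) * len(met_names) * 2)
    threshold = bonferroni_threshold(config.alpha, n_tests)
    from .association import AssociationResult  # local to keep import graph simple
    def _to_results(df: pd.DataFrame) -> list[AssociationResult]:
        return [AssociationResult(metabolite=r["metabolite"], disease=r["disease"],
                                  mode=r["mode"], beta=r["beta"], se=r["se"], or_=r["or"],
                                  ci_low=r["ci_low"], ci_high=r["ci_high"], p=r["p"],
                                  n_case=r["n_case"], n_control=r["n_control"])
                for r in df.to_dict("records")]
    tri = triangulate(_to_results(scan[scan["mode"] == "level"]),
                      _to_results(scan[scan["mode"] == "pgs"]), threshold)
    tri_table = pd.DataFrame([{
        "metabolite": t.metabolite, "disease": t.disease, "direction": t.direction,
        "level_p": t.level_result.p if t.level_result else np.nan,
        "pgs_p": t.pgs_result.p if t.pgs_result else np.nan,
        "level_or": t.level_result.or_ if t.level_result else np.nan,
        "pgs_or": t.pgs_result.or_ if t.pgs_result else np.nan,
        "passes": t.passes, "reason": t.reason} for t in tri])
    pio.write_table(tri_table, outdir / "triangulated.tsv")
    pio.write_table(overlap_counts(tri), outdir / "overlap_counts.tsv")

    if group_map:
        sig = {t.disease for t in tri if t.passes}
        enr = enrichment(sig, {d: group_map[d] for d in diseases}, config.alpha)
        pio.write_table(pd.DataFrame([dataclasses.asdict(e) for e in enr]),
                        outdir / "enrichment.tsv")

    # --- MR --------------------------------------------------------------
    if config.mr_enabled and config.summary_stats:
        mr_rows = []
        for pair in config.summary_stats.get("pairs", []):
            name = pair.get("name", "pair")
            if "exposure_path" in pair:
                exp_tab = pio.read_summary_stats(pair["exposure_path"])
                out_tab = pio.read_summary_stats(pair["outcome_path"])
            else:
                sspec = SummaryStatsSpec(
                    **{k: v for k, v in pair.items() if k != "name"},
                    seed=child_seed(config.seed, f"sumstats:{name}"))
                exp_tab, out_tab = generate_summary_stats(sspec)
            report = run_mr(exp_tab, out_tab,
                            MRConfig(p_threshold=config.instrument_p_threshold,
                                     seed=child_seed(config.seed, f"mr:{name}")))
            for method, res in report["results"].items():
                mr_rows.append({
                    "pair": name, "method": method, "estimate": res.estimate,
                    "se": res.se, "p": res.p, "or": res.or_, "n_snps": res.n_snps,
                    "q_stat": res.q_stat,
                    "outliers_removed": ";".join(report["outliers_removed"]),
                    "mr_supported": report["mr_supported"],
                    "dual_support": report["dual_support"]})
        pio.write_table(pd.DataFrame(mr_rows), outdir / "mr_results.tsv")

    # --- interactions ----------------------------------------------------
    screen = interaction_screen(prepared, tri, config.interaction_alpha)
    pio.write_table(screen, outdir / "interactions.tsv")

    # --- canalization ----------------------------------------------------
    can_rows = []
    for t in tri:
        if not t.passes:
            continue
        for stratum in config.canalization_strata:
            res = canalization_contrast(
                prepared, score_col=f"zpgs_{t.metabolite}",
                status_col=f"status_{t.disease}", stratum_col=stratum,
                n_bins=config.n_bins, tail_fraction=config.tail_fraction,
                n_iterations=config.n_iterations,
                seed=child_seed(config.seed, f"canal:{t.metabolite}:{t.disease}:{stratum}"))
            can_rows.append({"metabolite": t.metabolite, "disease": t.disease,
                             "stratum": stratum, **dataclasses.asdict(res)})
    pio.write_table(pd.DataFrame(can_rows), outdir / "canalization.tsv")

    manifest = {
        "config_hash": _config_hash(config), "seed": config.seed,
        "package_version": __version__,
        "numpy": np.__version__, "pandas": pd.__version__,
        "n_individuals": int(len(cohort)), "n_diseases_analyzed": len(diseases),
        "n_metabolites": len(met_names), "threshold": threshold,
        "elapsed_seconds": round(time.time() - t0, 2),
        "config": config.to_dict(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline finished in %.1fs -> %s", time.time() - t0, outdir)
    return outdir
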