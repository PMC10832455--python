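#!/usr/bin/env python
"""Triangulate level and PGS associations (Bonferroni significance in both
modes + concordant direction) and test disease-group enrichment of the
suggestive hits with the relative-risk Fisher test."""

import argparse
import dataclasses
from pathlib import Path

import pandas as pd

from pufa_phewas import io as pio
from pufa_phewas.association import AssociationResult
from pufa_phewas.triangulation import (bonferroni_threshold, enrichment,
                                       overlap_counts, triangulate)

ap = argparse.ArgumentParser()
ap.add_argument("--outdir", type=Path, default=Path("results/analysis"))
ap.add_argument("--alpha", type=float, default=0.05)
args = ap.parse_args()


def _load(mode: str) -> list[AssociationResult]:
    df = pio.read_table(args.outdir / f"associations_{mode}.tsv")
    return [AssociationResult(metabolite=r["metabolite"], disease=str(r["disease"]),
                              mode=r["mode"], beta=r["beta"], se=r["se"], or_=r["or"],
                              ci_low=r["ci_low"], ci_high=r["ci_high"], p=r["p"],
                              n_case=r["n_case"], n_control=r["n_control"])
            for r in df.to_dict("records")]


level, pgs = _load("level"), _load("pgs")
threshold = bonferroni_threshold(args.alpha, len(level) + len(pgs))
tri = triangulate(level, pgs, threshold)
tab = pd.DataFrame([{
    "metabolite": t.metabolite, "disease": t.disease, "direction": t.direction,
    "level_p": t.level_result.p, "pgs_p": t.pgs_result.p,
    "level_or": t.level_result.or_, "pgs_or": t.pgs_result.or_,
    "passes": t.passes, "reason": t.reason} for t in tri])
pio.write_table(tab, args.outdir / "triangulated.tsv")
pio.write_table(overlap_counts(tri), args.outdir / "overlap_counts.tsv")

group_map = pio.read_group_map(args.outdir / "group_map.tsv")
diseases = set(tab["disease"])
enr = enrichment({t.disease for t in tri if t.passes},
                 {d: g for d, g in group_map.items() if d in diseases}, args.alpha)
pio.write_table(pd.DataFrame([dataclasses.asdict(e) for e in enr]),
                args.outdir / "enrichment.tsv")

n_pass = int(tab["passes"].sum())
n_prot = int((tab.loc[tab["passes"], "direction"] == "protective").sum())
print(f"threshold {threshold:.3g}; {n_pass}/{len(tab)} pairs triangulate "
      f"({n_prot} protective)")
for e in enr:
    flag = " *" if e.significant else ""
    print(f"  group {e.group}: {e.n_sig_in_group}/{e.n_group} significant, "
          f"RR {e.rr:.2f}, Fisher p {e.fisher_p:.3g}{flag}")
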