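#!/usr/bin/env python
"""Prepare the raw cohort: QC-filter and median-collapse repeated metabolite
measurements, Z-score levels and polygenic scores, compute WHR, classify
obesity, and apply the >= 50-case disease filter."""

import argparse
from pathlib import Path

from pufa_phewas import io as pio
from pufa_phewas.prep import min_case_filter, prepare_cohort

ap = argparse.ArgumentParser()
ap.add_argument("--outdir", type=Path, default=Path("results/analysis"))
args = ap.parse_args()

cohort = pio.read_cohort(args.outdir / "cohort.tsv")
mets = sorted({c[len("pgs_"):] for c in cohort.columns if c.startswith("pgs_")})
prepared = prepare_cohort(cohort, mets)
pio.write_table(prepared, args.outdir / "prepared.tsv")

diseases = min_case_filter(prepared)
(args.outdir / "diseases_analyzed.txt").write_text("\n".join(diseases) + "\n")

n_all = len([c for c in prepared.columns if c.startswith("status_")])
print(f"prepared {len(prepared)} individuals; metabolites: {', '.join(mets)}")
print(f"obese by BMI: {prepared['obese_bmi'].mean():.1%}; "
      f"obese by WHR: {prepared['obese_whr'].mean():.1%} "
      f"(women {prepared.loc[prepared.sex == 0, 'obese_whr'].mean():.1%}, "
      f"men {prepared.loc[prepared.sex == 1, 'obese_whr'].mean():.1%})")
print(f"diseases with >= 50 cases: {len(diseases)}/{n_all}")
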