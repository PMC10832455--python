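#!/usr/bin/env python
"""Fit the covariate-adjusted logistic PheWAS: every metabolite against
every retained disease, in level mode (metabolite Z-score) and in genetic
mode (Z-scored metabolite PGS)."""

import argparse
from pathlib import Path

from pufa_phewas import io as pio
from pufa_phewas.association import association_scan

ap = argparse.ArgumentParser()
ap.add_argument("--outdir", type=Path, default=Path("results/analysis"))
args = ap.parse_args()

prepared = pio.read_cohort(args.outdir / "prepared.tsv")
mets = sorted({c[len("pgs_"):] for c in prepared.columns if c.startswith("pgs_")})
diseases = (args.outdir / "diseases_analyzed.txt").read_text().split()

scan = association_scan(prepared, mets, diseases)
for mode in ("level", "pgs"):
    pio.write_table(scan[scan["mode"] == mode],
                    args.outdir / f"associations_{mode}.tsv")

for mode in ("level", "pgs"):
    sub = scan[scan["mode"] == mode]
    print(f"{mode} mode: {len(sub)} models; median OR "
          f"{sub['or'].median():.3f}; {int((sub['p'] < 1e-4).sum())} with p < 1e-4")
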