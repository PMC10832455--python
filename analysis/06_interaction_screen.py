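#!/usr/bin/env python
"""Screen the triangulated associations for metabolite x body-weight
interactions: level/PGS predictor x {BMI Z, WHR Z, BMI obesity, WHR
obesity}, with nominal and Bonferroni flags and per-group fractions."""

import argparse
from pathlib import Path

from pufa_phewas import io as pio
from pufa_phewas.interaction import group_interaction_fractions, interaction_screen
from pufa_phewas.triangulation import TriangulatedAssociation

ap = argparse.ArgumentParser()
ap.add_argument("--outdir", type=Path, default=Path("results/analysis"))
args = ap.parse_args()

prepared = pio.read_cohort(args.outdir / "prepared.tsv")
tri_tab = pio.read_table(args.outdir / "triangulated.tsv",
                         required=["metabolite", "disease", "passes"])
tri = [TriangulatedAssociation(metabolite=r["metabolite"], disease=str(r["disease"]),
                               direction=r.get("direction", ""), level_result=None,
                               pgs_result=None, passes=bool(r["passes"]))
       for r in tri_tab.to_dict("records")]

screen = interaction_screen(prepared, tri)
pio.write_table(screen, args.outdir / "interactions.tsv")

n_nom = int(screen["nominal_sig"].sum()) if len(screen) else 0
print(f"{len(screen)} interaction models over {int(tri_tab['passes'].sum())} "
      f"triangulated associations; {n_nom} nominally significant (p < 0.05)")
group_map = pio.read_group_map(args.outdir / "group_map.tsv")
frac = group_interaction_fractions(screen, group_map)
for r in frac.to_dict("records"):
    print(f"  group {r['group']}: {r['n_nominal']}/{r['n_tests']} flagged "
          f"({r['fraction']:.0%})")
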