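#!/usr/bin/env python
"""Simulate the study inputs: a synthetic biobank-style cohort and paired
exposure/outcome GWAS summary statistics.

The demo cohort has 3 metabolites (omega3, omega6, dha) whose polygenic
scores explain ~50% of each level, and 12 diseases over 4 disease groups;
half the diseases carry a planted protective metabolite effect (OR ~ 0.7
per SD) and one carries a PGS x obesity interaction.  Writes cohort.tsv and
per-pair summary-statistic tables under results/analysis/.
"""

import argparse
from pathlib import Path

from pufa_phewas import io as pio
from pufa_phewas._rng import child_seed
from pufa_phewas.pipeline import _cohort_spec_from_dict, default_demo_config, save_config
from pufa_phewas.synthetic import SummaryStatsSpec, generate_cohort, generate_summary_stats

ap = argparse.ArgumentParser()
ap.add_argument("--seed", type=int, default=1)
ap.add_argument("--outdir", type=Path, default=Path("results/analysis"))
ap.add_argument("--n", type=int, default=20_000)
args = ap.parse_args()

cfg = default_demo_config(seed=args.seed, n=args.n, output_dir=str(args.outdir))
save_config(cfg, args.outdir / "config.yaml")

spec = _cohort_spec_from_dict(cfg.cohort, child_seed(cfg.seed, "cohort"))
cohort = generate_cohort(spec)
pio.write_cohort(cohort, args.outdir / "cohort.tsv")
pio.write_group_map({d.phecode: d.group for d in spec.diseases},
                    args.outdir / "group_map.tsv")
print(f"cohort: {len(cohort)} individuals, {len(spec.metabolites)} metabolites, "
      f"{len(spec.diseases)} diseases -> {args.outdir / 'cohort.tsv'}")

for pair in cfg.summary_stats["pairs"]:
    name = pair["name"]
    sspec = SummaryStatsSpec(**{k: v for k, v in pair.items() if k != "name"},
                             seed=child_seed(cfg.seed, f"sumstats:{name}"))
    e, o = generate_summary_stats(sspec)
    pio.write_summary_stats(e, args.outdir / f"sumstats_{name}_exposure.tsv")
    pio.write_summary_stats(o, args.outdir / f"sumstats_{name}_outcome.tsv")
    print(f"summary stats {name}: {sspec.n_snps} SNPs, "
          f"true causal effect {sspec.causal_effect}")
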