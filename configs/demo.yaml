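alpha: 0.05
canalization_strata:
- obese_bmi
- obese_whr
cohort:
  diseases:
  - baseline_prevalence: 0.08
    beta_metabolite: -0.35
    beta_prs: 0.3
    gamma_interaction: -0.3
    group: circulatory
    interaction_predictor: pgs
    interaction_weight: bmi_obese
    metabolite: omega3
    phecode: d000
  - baseline_prevalence: 0.08
    beta_metabolite: 0.0
    beta_prs: 0.3
    gamma_interaction: 0.0
    group: endocrine
    interaction_predictor: pgs
    interaction_weight: bmi_obese
    metabolite: omega6
    phecode: d001
  - baseline_prevalence: 0.08
    beta_metabolite: -0.35
    beta_prs: 0.3
    gamma_interaction: 0.0
    group: digestive
    interaction_predictor: pgs
    interaction_weight: bmi_obese
    metabolite: dha
    phecode: d002
  - baseline_prevalence: 0.08
    beta_metabolite: 0.0
    beta_prs: 0.3
    gamma_interaction: 0.0
    group: respiratory
    interaction_predictor: pgs
    interaction_weight: bmi_obese
    metabolite: omega3
    phecode: d003
  - baseline_prevalence: 0.08
    beta_metabolite: -0.35
    beta_prs: 0.3
    gamma_interaction: 0.0
    group: circulatory
    interaction_predictor: pgs
    interaction_weight: bmi_obese
    metabolite: omega6
    phecode: d004
  - baseline_prevalence: 0.08
    beta_metabolite: 0.0
    beta_prs: 0.3
    gamma_interaction: 0.0
    group: endocrine
    interaction_predictor: pgs
    interaction_weight: bmi_obese
    metabolite: dha
    phecode: d005
  - baseline_prevalence: 0.08
    beta_metabolite: -0.35
    beta_prs: 0.3
    gamma_interaction: 0.0
    group: digestive
    interaction_predictor: pgs
    interaction_weight: bmi_obese
    metabolite: omega3
    phecode: d006
  - baseline_prevalence: 0.08
    beta_metabolite: 0.0
    beta_prs: 0.3
    gamma_interaction: 0.0
    group: respiratory
    interaction_predictor: pgs
    interaction_weight: bmi_obese
    metabolite: omega6
    phecode: d007
  - baseline_prevalence: 0.08
    beta_metabolite: -0.35
    beta_prs: 0.3
    gamma_interaction: 0.0
    group: circulatory
    interaction_predictor: pgs
    interaction_weight: bmi_obese
    metabolite: dha
    phecode: d008
  - baseline_prevalence: 0.08
    beta_metabolite: 0.0
    beta_prs: 0.3
    gamma_interaction: 0.0
    group: endocrine
    interaction_predictor: pgs
    interaction_weight: bmi_obese
    metabolite: omega3
    phecode: d009
  - baseline_prevalence: 0.08
    beta_metabolite: -0.35
    beta_prs: 0.3
    gamma_interaction: 0.0
    group: digestive
    interaction_predictor: pgs
    interaction_weight: bmi_obese
    metabolite: omega6
    phecode: d010
  - baseline_prevalence: 0.08
    beta_metabolite: 0.0
    beta_prs: 0.3
    gamma_interaction: 0.0
    group: respiratory
    interaction_predictor: pgs
    interaction_weight: bmi_obese
    metabolite: dha
    phecode: d011
  metabolites:
  - name: omega3
  - name: omega6
  - name: dha
  n_individuals: 20000
instrument_p_threshold: 5.0e-08
interaction_alpha: 0.05
min_cases: 50
mr_enabled: true
n_association_tests: null
n_bins: 100
n_iterations: 10
output_dir: results/demo
seed: 1
summary_stats:
  pairs:
  - causal_effect: -0.3
    n_snps: 50
    name: omega3__d000
  - causal_effect: 0.0
    n_snps: 50
    name: omega6__d001
  - causal_effect: -0.2
    invalid_fraction: 0.2
    n_snps: 50
    name: dha__d002
    pleiotropy_mean: 0.0
    pleiotropy_sd: 0.05
tail_fraction: 0.02
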