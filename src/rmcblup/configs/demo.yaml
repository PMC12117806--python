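# Small end-to-end demo: simulate a population, profile it, build the
# MRM and GRM, fit heritability/microbiability, forward-predict the
# latest birth year and fit the bivariate proxy model.
seed: 1
out_dir: rmcblup_demo
simulate:
  n_animals: 400
  n_snps: 800
  n_tags: 600
  n_flocks: 4
  n_years: 4
  n_flowcells: 3
  sigma2_g: 0.16
  sigma2_m: 1.0
  sigma2_e: 0.84
  rho_gm: 0.75
trait:
  name: CH4
  overall_mean: 7.5
  percentage: false
fixed_effects:
  - C(birth_rank)
  - C(age_of_dam)
  - bdev
  - flock*birth_year*sex
qc:
  min_reads: 100000
  presence_threshold: 0.25
  maf_min: 0.01
  call_rate_min: 0.70
scheme:
  type: FP
  validation_year: 2017
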