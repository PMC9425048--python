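# Example run configuration for `rumigen all --config configs/example_run.yaml`.
#
# Exactly one of `simulation:` or `inputs:` must be present. With a
# simulation block the cohort is generated (seed recorded in the manifest);
# with inputs the raw CSV tables are read from disk.

seed: 20240917
outdir: scratch/example_run

simulation:
  n_sires: 20            # 20 sires x 5 dams x 2 lambs = 200 phenotyped animals
  dams_per_sire: 5
  progeny_per_dam: 2
  sire_link_frac: 0.2    # fraction of sires with progeny in two cohorts
  weighing_noise_sd: 0.5 # kg per weighing; weighing_noise_frac overrides

# To run from files instead, delete `simulation:` and use:
# inputs:
#   pedigree: path/to/pedigree.csv          # animal,sire,dam,birth_year,flock,cohort
#   animals: path/to/animals.csv            # covariates: cg, cohort_pen, brr, aod, bdev
#   feeder_events: path/to/feeder_events.csv  # animal,feeder,entry,exit,grams
#   liveweights: path/to/liveweights.csv    # animal,day,kg
#   pac: path/to/pac.csv                    # long: animal,round,lot,chamber,gas,minutes,concentration_ppm,temp_K,pressure_kPa
#   pac_body_weight: path/to/pac_body_weight.csv  # animal,round,kg
#   ct_stacks: path/to/ct_stacks.csv        # animal,slice,compartment,tissue,subdepot,area_mm2,mean_hu
#   ultrasound: path/to/ultrasound.csv      # animal,c_start_mm,c_final_mm

# Optional: override the fitted models (defaults cover the shipped traits)
model_specs:
  - trait: rfi
    fixed: [cg]
  - trait: mmwt
    fixed: [cg, brr]
    covariates: [aod, aod2, bdev]
  - trait: ch4
    fixed: [cg, brr]
    covariates: [aod2]
    repeated: true
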