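# Full pipeline on a simulated study.
# Usage: faw-haplotyper run --config examples/run.yaml --out results/
seed: 1
simulate:
  populations:
  - name: TX-like
    n_specimens: 150
    coib_category_profile:
      CSh1: 0.2
      CSh2: 0.65
      CSh3: 0.01
      CSh4: 0.14
    coib_variant_profiles:
      CSh1:
      - 0.7
      - 0.2
      - 0.1
      CSh2:
      - 0.77
      - 0.13
      - 0.1
      CSh3:
      - 1.0
      CSh4:
      - 0.91
      - 0.09
    intron_haplotype_profile:
    - 0.6
    - 0.2
    - 0.1
    - 0.06
    - 0.04
    strain_profile:
      C: 0.8
      R: 0.2
    hybrid_rate: 0.1
    heterozygosity: 0.5
    indel_het_fraction: 0.5
    noise_rate: 0.0
    year: 2021
    habitat: corn
    collection_type: T
  - name: FL-like
    n_specimens: 150
    coib_category_profile:
      CSh1: 0.1
      CSh2: 0.15
      CSh3: 0.01
      CSh4: 0.74
    coib_variant_profiles:
      CSh1:
      - 0.7
      - 0.2
      - 0.1
      CSh2:
      - 0.77
      - 0.13
      - 0.1
      CSh3:
      - 1.0
      CSh4:
      - 0.91
      - 0.09
    intron_haplotype_profile:
    - 0.45
    - 0.1
    - 0.25
    - 0.1
    - 0.1
    strain_profile:
      C: 0.8
      R: 0.2
    hybrid_rate: 0.1
    heterozygosity: 0.5
    indel_het_fraction: 0.5
    noise_rate: 0.0
    year: 2021
    habitat: corn
    collection_type: T
  - name: AZ-like
    n_specimens: 150
    coib_category_profile:
      CSh1: 0.18
      CSh2: 0.68
      CSh3: 0.0
      CSh4: 0.14
    coib_variant_profiles:
      CSh1:
      - 0.7
      - 0.2
      - 0.1
      CSh2:
      - 0.77
      - 0.13
      - 0.1
      CSh3:
      - 1.0
      CSh4:
      - 0.91
      - 0.09
    intron_haplotype_profile:
    - 0.7
    - 0.15
    - 0.1
    - 0.05
    - 0.0
    strain_profile:
      C: 1.0
      R: 0.0
    hybrid_rate: 0.0
    heterozygosity: 0.5
    indel_het_fraction: 0.5
    noise_rate: 0.0
    year: 2021
    habitat: corn
    collection_type: T
  r_coib_variant_profile:
  - 1.0
  pool_substitution_rate: 0.01
  pool_indel_rate: 0.01
group_by:
- population
compare_replicates: 10000
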