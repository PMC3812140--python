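# Planted study profile: the published six-array heart-failure design.
# All statistical structure the pipeline measures is planted at the values
# reported for the real arrays (DE counts per compartment, length-expression
# Spearman couplings per sample and class, heart-plasma fold-change coupling,
# sense-overlap lncRNA-mRNA concordance ORs).
master_seed: 42
n_coding: 20000
n_lnc: 30000

# six-way positional-class mixture; collapses to the reported four-class
# ratios (~50% intergenic, ~40% sense+antisense, <10% bidirectional)
class_mixture:
  sense_overlap: 0.12
  intronic: 0.08
  antisense_overlap: 0.12
  nonantisense_overlap: 0.08
  bidirectional: 0.10
  intergenic: 0.50

# lncRNA spliced lengths: truncated lognormal, median ~1.5 kb
length_distribution: {log_mean: 7.3, log_sd: 1.0, min_bp: 200, max_bp: 50000}

# post-normalization intensity scale (natural-log mean / sd)
intensity_distribution: {log_mean: 8.52, log_sd: 1.2}

flag_absent_rate: 0.10
bidirectional_window_bp: 1000
already_normalized: true

# per-sample, per-class Spearman targets for length vs intensity
# (the published class x sample correlation grid)
length_expr_rho:
  heart_HF:           {sense_overlap: -0.11, antisense_overlap: -0.24, bidirectional: -0.13, intergenic: -0.17}
  heart_control:      {sense_overlap: -0.10, antisense_overlap: -0.22, bidirectional: -0.14, intergenic: -0.17}
  whole_blood_HF:     {sense_overlap: -0.15, antisense_overlap: -0.207, bidirectional: -0.05, intergenic: -0.16}
  whole_blood_control: {sense_overlap: -0.11, antisense_overlap: -0.15, bidirectional: -0.07, intergenic: -0.14}
  plasma_HF:          {sense_overlap: -0.07, antisense_overlap: -0.01, bidirectional: 0.01, intergenic: -0.06}
  plasma_control:     {sense_overlap: -0.11, antisense_overlap: -0.24, bidirectional: -0.06, intergenic: -0.14}

# exact planted up/down DE counts per compartment
de_counts:
  heart: {up: 518, down: 908}
  plasma: {up: 1619, down: 1582}
  whole_blood: {up: 1139, down: 1506}

fc_magnitudes:
  up: [2.0, 8.0]          # log-uniform HF/control ratio for upregulated probes
  down: [0.125, 0.5]      # log-uniform ratio for downregulated probes
  background_log2: [-0.9, 0.9]  # jitter for unchanged probes, inside (0.5, 2)

# Spearman coupling of log2 fold-change vectors between compartments
cross_compartment_rho:
  - pair: [heart, plasma]
    rho: -0.24

# direction-concordance odds ratios for lncRNA-mRNA overlap pairs
pair_concordance_or:
  sense_overlap: {heart: 4.9, plasma: 2.5, whole_blood: 4.0}
  antisense_overlap: {heart: 2.0, plasma: 0.4, whole_blood: 0.4}

qpcr:
  n_animals: 10
  n_replicates: 3
  ct_noise_sd: 0.25
  reference: GAPDH
  targets:
    Lnc-hf-u1: 4.0
    Lnc-hf-u2: 3.2
    Lnc-hf-u3: 2.8
    Lnc-hf-u4: 2.4
    Lnc-hf-u5: 2.1
    Lnc-hf-d1: 0.45
    Lnc-hf-d2: 0.40
    Lnc-hf-d3: 0.33
    Lnc-hf-d4: 0.28
    Lnc-hf-d5: 0.22
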