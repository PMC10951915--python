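# Fully synthetic end-to-end demo configuration.
# Run with:  embryoprot run --config examples/demo.yaml --out-dir out/demo
seed: 17
log_level: INFO
simulate:
  spikein:
    n_standards: 48            # staggered standards, like a UPS2-style set
    n_sample_proteins: 2000
    slope: 1.0
    intercept: 2.0
    noise_sd: 0.1              # log10 units, multiplicative MS noise
    dynamic_range_orders: 8.0  # egg proteome spans ~8 orders of magnitude
  complexes:
    n_complexes: 20
    subunits_per_complex: 5
    within_sd: 0.1             # log10 scatter within a complex
    global_sd: 1.0             # log10 scatter of the background proteome
    n_background: 500
  two_species:
    n_orthologs: 400
    n_stages_a: 8              # the eight-stage developmental series
    n_stages_b: 8
    shape: inverse_hourglass   # ground-truth divergence shape
    effect_size: 1.0
    noise_sd: 0.05
  snp:
    n_sequences: 100
    mean_length: 300
    snp_rate: 0.001
  n_decoys: 20                 # decoy alignment hits per direction
absquant:
  total_mM: 2.0                # total molar protein concentration of the egg
  cutoff_uM: 0.01              # low-concentration cutoff
dynamics:
  k_within: 8                  # within-species profile clusters
  k_cocluster: 5               # cross-species ortholog co-clusters
  n_restarts: 100
orthology:
  evalue_max: 0.01
xspecies:
  metric: pearson
  n_permutations: 1000
digest:
  protease: trypsin
  missed_cleavages: 0
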