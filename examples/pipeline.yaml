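# Demonstration end-to-end run on simulated data.
#   querysignal run --config examples/pipeline.yaml --outdir runs/demo
seed: 7
simulate:
  n_users: 600
  adopter_fraction: 0.4
  background_rate: 0.8
  sustained_fraction: 0.07
  pre_window_multipliers:
    diarrhea: 2.0
    headache: 1.5
  post_recipe_shift: 3.0
  recipe_rate: 0.2
analysis:
  window_days: 14
  min_support: 10
  top_k: 10
  denominator: after
  profile_concepts: [diarrhea]
  profile_range_days: 30
classify:
  folds: 10
  trees: 50
  comparison_ratio: 5
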