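# Demonstration pipeline configuration: a small simulated responder cohort
# with elevated baseline occipital interhemispheric and frontal-occipital
# coherence in responders.  Run with:
#   rettnet run-all --config demo_config.yaml
out_dir: demo_output
mode: simulate
seed: 0
design:
  groups: [responder, nonresponder]
  n_per_cell: [5, 4]
  timepoints: [baseline, month12]
  effects:
    - pair: [O1, O2]
      delta: 0.3
      group: responder
      timepoint: baseline
    - pair: [F3, O1]
      delta: 0.15
      group: responder
      timepoint: baseline
    - pair: [F4, O2]
      delta: 0.15
      group: responder
      timepoint: baseline
  background_coherence: 0.25
  duration: 120.0
  fs: 128.0
epoch_s: 2.0
artifact_threshold: 100.0
bandpass_hz: [0.5, 40.0]
pca_retention: 0.9
alpha: 0.05
cv_folds: 5
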