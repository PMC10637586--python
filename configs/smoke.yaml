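# Desk-scale end-to-end run: 24 phantoms, reduced consensus and filters.
# habitatomics run-all --config configs/smoke.yaml --outdir runs/smoke
seed: 5
synthetic:
  cohort:
    n_train: 16
    n_test: 8
habitat:
  k_range: [2, 6]
  reps: 50
  max_items: 1000
  voxels_per_patient: 150
radiomics:
  families: [firstorder, glcm, gldm]
  filters: [original]
selection:
  use_icc: true
  icc_subset: 8
model:
  n_folds: 4
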