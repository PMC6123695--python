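# Small demonstration experiment: one signal-bearing synthetic task.
tasks:
  - name: demo
    full_liberal_z: 3.0
    full_conservative_z: 4.0
    cluster_p: 0.01
    pq_liberal_z: 2.5
    pq_conservative_z: 3.3
    synthetic:
      truth:
        grid_shape: [20, 20, 20]
        mask_axes: [0.92, 0.92, 0.92]
        blobs:
          - {center: [10, 10, 10], fwhm: 4.5, amplitude: 0.7}
          - {center: [6, 13, 7], fwhm: 3.5, amplitude: 0.5, sign: -1}
      n_subjects: 60
      n_runs: 2
      sigma_between: 0.4
      sigma_within: 0.9
      noise_fwhm: 2.5
      motion_mean: 0.15
      motion_sd: 0.05
      seed: 11
k_grid: [8, 16, 25]
n_sorts: 20
n_null_maps: 100
seed: 1
metrics: [pearson, jaccard_voxel, jaccard_cluster, peak_hit]
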