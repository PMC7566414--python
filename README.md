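# bhcalib

Breath-hold hemodynamic calibration of task-fMRI activation maps.

Task-evoked BOLD amplitude mixes neural drive with local vascular
responsiveness, which is distorted near tumors and large vessels.
`bhcalib` implements a voxel-wise calibration pipeline:

1. **paradigm** — block designs (30 s rest + 3 × [16 s breath-hold +
   44 s recovery]; 3 × [30 s task + 30 s rest] at TR = 3 s), boxcar
   references, shifted references, and canonical-HRF regressors.
2. **phantom** — a synthetic 4D BOLD generator (WM core / GM shell /
   vessel and tumor-margin blobs) with known vascular gains, gamma-variate
   breath-hold responses, neural task amplitudes, noise, and drift, so
   every downstream stage has ground truth.
3. **preprocess** — motion QC (2 mm / one-voxel-shift exclusion), linear
   detrending, percent-signal-change conversion, temporal SD maps.
4. **xcorr** — cross-correlation activation maps, rest-derived (4 × SD)
   and analytic (Student-t) thresholds, Monte-Carlo cluster-extent
   correction on smooth Gaussian noise fields.
5. **gammafit** — voxel-wise multistart fitting of
   `S(t) = Q (t − t0)^r e^{−(t − t0)/b}` per hold epoch with shared
   parameters; derived Smax / Tmax / SArea maps; Otsu-based tissue
   demarcation; epoch-split reliability with voxel bootstrap.
6. **calibrate** — voxel-wise GLM betas (intercept + drift + unit-peak
   regressor) and the core scaling step: task beta ÷ breath-hold
   amplitude, with a divisor floor, activation comparison, and
   before/after distribution diagnostics (Bartlett test).
7. **cli** — the stages as subcommands over NIfTI/TSV/JSON artifacts.

## CLI

```sh
bhcalib simulate  --out-dir work --seed 1
bhcalib qc        --motion work/bh_motion.tsv --out work/qc.json
bhcalib xcorr     --run work/bh_run.nii   --design work/bh_design.yaml   --out-prefix work/act
bhcalib gammafit  --run work/bh_run.nii   --design work/bh_design.yaml   --out-prefix work/gamma
bhcalib calibrate --task-run work/task_run.nii --task-design work/task_design.yaml \
                  --gamma-prefix work/gamma --out-prefix work/scaled
bhcalib report    --work-dir work --out-dir work/report
```

Every stage writes a JSON sidecar with the seed, package version, and a
configuration hash; reruns with the same seed are reproducible.  Exit
codes: 0 ok, 1 user error, 2 internal error.

## Notes

- Fits operate on percent-change, detrended data only (enforced via a
  units tag on `Bold4D`).
- `t0` in the gamma parameter maps is referenced to the hold onset; the
  run-start convention is available via the design's epoch onsets
  (`meta["epoch_onsets_s"]`).
- Fit defaults are desk-scale (`n_starts=100–200`, few repeats);
  production-scale settings (1000 starts × 1000 repeats) are plain
  keyword arguments.
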