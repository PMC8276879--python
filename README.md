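# devoxel

Quantitative brain-perfusion analysis toolkit:

- **ASL CBF quantification** (`devoxel.asl_cbf`) — converts interleaved
  control/label pseudo-continuous ASL series plus a proton-density image
  into absolute cerebral blood flow (ml/100 g/min) with slice-dependent
  post-labeling delay, automated robust control-label pair rejection, and
  grey-matter partial-volume correction.
- **Carotid Q-flow** (`devoxel.carotid_qflow`) — velocity-encoded
  phase-contrast cine analysis: phase → velocity decoding, per-frame
  cross-section integration and cardiac-cycle averaging into cm³/s.
- **Distributed deviating voxels** (`devoxel.deviating_voxels`) —
  normative voxelwise z-maps against a reference group (leave-one-out for
  reference members), two-sided 99% thresholding (|z| > 2.576), and
  per-region tallies of deviating voxels as a percentage of intracranial
  volume.
- **Regional analysis** (`devoxel.regional_analysis`) — ROI-mean CBF,
  stage-aware cohort exclusion bookkeeping, equal-variance t-tests,
  covariate-adjusted OLS comparisons, and staged whole-cerebrum-first
  testing.
- **Synthetic phantom** (`devoxel.synthetic_phantom`) — seeded synthetic
  anatomy, forward-modeled ASL acquisitions, phase-contrast cines with
  known flow waveforms, and whole cohorts with scattered non-overlapping
  hypoperfusion lesions, so everything is testable offline.
- **Pipeline** (`devoxel.pipeline`) — simulate → quantify → deviate →
  stats as one reproducible run with a machine-readable `report.json`.

## Tests

```bash
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests, and
`tests/test_acceptance.py` with the simulation-based acceptance criteria
(null coverage of the z-threshold at 10⁶ voxels, forward/inverse
quantification consistency, exclusion cascades, leave-one-out exactness,
power of the deviating-voxel statistic vs. the ROI mean, and power
monotonicity). The full run takes a few minutes on one CPU.

## CLI

```bash
# synthetic phantom anatomy
devoxel simulate --seed 17 --out phantom/

# CBF quantification
devoxel cbf --asl series.nii --pd pd.nii --gm gm.nii --out cbf.nii

# carotid flow
devoxel qflow --mag mag.nii --phase phase.nii \
    --roi-left L.nii --roi-right R.nii --venc 120 --out flow.tsv

# deviating-voxel tallies (% of ICV)
devoxel deviate --cbf-dir maps/ --reference-ids ref.txt \
    --atlas atlas.nii --icv icv.tsv --confidence 0.99 --out tallies.tsv

# staged group statistics
devoxel stats --tallies tallies.tsv --cohort cohort.tsv \
    --covariates age,sex,atrophy_ml --out results/

# full reproducible study from one YAML config
devoxel run --config study.yaml
```

A minimal `study.yaml`:

```yaml
out_dir: run_out
seed: 11
n_per_group: 6
phantom: {shape: [40, 48, 17], n_pairs: 50}
lesion: {region: subcortical_gm, fraction: 0.1, depth: -4.0}
covariates: [age, sex]
```

## Conventions

- Acquisition times are configured in milliseconds and converted to
  seconds internally; CBF is reported in ml/100 g/min.
- Negative CBF values are retained (not clipped); a QC counter reports
  them.
- Deviating-voxel thresholds use strict inequalities; voxels with zero
  reference SD are excluded and counted.
- Bilateral carotid flow defaults to the left + right sum (configurable
  to the mean); this choice is recorded in the output.
- All inputs to a given analysis must share one grid; motion correction
  and registration are assumed done upstream.
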