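# doseatlas

Voxel-based analysis of radiotherapy dose distributions in a common
template space. The pipeline covers:

- **Synchronized spatial normalization** — each subject's planning CT is
  cropped, rigidly aligned, affinely registered and nonlinearly warped
  (SSD-minimizing demons-style registration) onto a 2 mm CT template, and
  the *identical* transform chain is applied to the co-registered dose
  volume in a single interpolation pass.
- **Group dose mapping** — per-technique voxel-wise mean dose maps,
  dose sub-range masks and voxel/volume counts (1.0–1.5, 1.5–10, 10–30,
  30–50, >50 Gy), high-dose (>50 Gy) ROIs per lobe and hemisphere with
  per-subject mean doses.
- **Voxel-wise inference** — two-sample GLM with age/gender covariates,
  threshold-free cluster enhancement (TFCE) of both tails, and
  Freedman–Lane permutation testing against the image-wide max-TFCE null
  (family-wise-error corrected p values). The default null is two-sided
  (one distribution of the max TFCE over both tails, overall FWE ≤ alpha);
  a liberal per-tail convention is available via
  `permutation_fwe(..., tails="per-tail")` / `doseatlas vba --tails`.
- **Region reporting** — atlas-labelled cluster tables (region, voxel
  count, peak t, peak world coordinate) and dose-bin composition tables.
- **Synthetic phantom cohort** — a digital head-phantom generator
  (CT-like template, deformed subject anatomies, nasopharynx-centered
  dose fields with technique-dependent asymmetric lobes, demographics)
  with exact ground truth, so the entire pipeline can be exercised and
  validated without patient data.

## Layout

```
src/doseatlas/
  volume_io.py        # Volume/Mask/Atlas types, NIfTI I/O, resampling, masks
  synthetic_cohort.py # phantom template, subjects, dose simulation, cohorts
  spatial_norm.py     # rigid/affine/nonlinear registration, transform chains
  dose_maps.py        # group means, dose sub-ranges, high-dose ROIs
  voxel_stats.py      # GLM, TFCE, permutation FWE inference
  region_report.py    # atlas-labelled cluster and dose-bin tables
  validation.py       # FWE-calibration and coverage sweeps
  cli.py              # `doseatlas` command-line interface
```

## CLI

```bash
# simulate a phantom cohort (template, brain mask, atlas, subjects, cohort.tsv)
doseatlas simulate --n-per-group 10 --seed 1 --out-dir work/cohort \
    --grid-shape 48 --grid-spacing 4 --effect-size 3

# normalize one subject's CT + dose to the template
doseatlas normalize --ct work/cohort/sub-001_ct.nii \
    --dose work/cohort/sub-001_dose.nii \
    --template work/cohort/template.nii \
    --mask work/cohort/brain_mask.nii --out-dir work/norm/sub-001

# group mean dose maps, sub-range counts, >50 Gy ROI mean doses
doseatlas dose-summary --cohort work/cohort/cohort.tsv \
    --mask work/cohort/brain_mask.nii \
    --atlas work/cohort/atlas.nii --atlas-table work/cohort/atlas.tsv \
    --out-dir work/summary

# voxel-wise permutation TFCE comparison (IMRT vs VMAT)
doseatlas vba --cohort work/cohort/cohort.tsv \
    --mask work/cohort/brain_mask.nii \
    --covars age,gender --n-perm 5000 --alpha 0.05 --seed 1 \
    --out-dir work/vba

# atlas-labelled cluster report
doseatlas report --sig-pos work/vba/sig_pos.nii --sig-neg work/vba/sig_neg.nii \
    --tmap work/vba/t_map.nii --atlas work/cohort/atlas.nii \
    --atlas-table work/cohort/atlas.tsv --out work/clusters.tsv
```

`dose-summary` and `vba` expect the cohort table's `dose_path` column to
point at template-space volumes (i.e. run `normalize` first on real data;
the simulator writes template-grid volumes directly when
`--deform-scale 0`).

## Conventions

- Voxel indices are 0-based; world coordinates are RAS mm through the
  NIfTI affine; template-space coordinates are reported as MNI-style mm.
- The canonical template grid is 91×109×91 at 2 mm, origin
  (−90, −126, −72).
- Transform chains map template world points to subject world points
  (`rigid(affine(x + d(x)))`) — the pull-back direction used for
  resampling; registration therefore recovers the *inverse* of a
  generating warp.
- Out-of-field values: 0 for dose and statistic maps, −1024 for CT.
- All randomness flows from explicit integer seeds; registration is
  fully deterministic.
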