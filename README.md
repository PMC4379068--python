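# samit

Construction and validation of tracer-specific small-animal (rat) brain
templates for PET and SPECT, with VOI-based and voxel-based group analysis
and a digital phantom simulator.  All volumes live in a bregma-centred
stereotaxic coordinate system (+x right, +y anterior, +z dorsal, mm).

## What it does

- **volume I/O** (`samit.io`, `samit.grid`, `samit.resample`): NIfTI-1
  reading/writing with the stereotaxic world map in the affine, reslicing
  between grids, and left-right mirroring about the x = 0 mm midplane.
- **registration** (`samit.registration`, `samit.transforms`): world-space
  affine transforms (translation/rotation/scale/shear about bregma),
  Gaussian smoothing, multi-resolution SSD affine registration with
  analytic gradients, and rigid-body NMI registration for cross-modality
  alignment.
- **template construction** (`samit.template`): affine alignment of a
  cohort to a representative image, symmetric voxelwise averaging (mean of
  the average and its flip-registered duplicate), and rigid NMI
  coregistration into a reference space, with transform propagation.
- **validation** (`samit.validation`): the randomised-misalignment
  registration-error protocol — 10 translations (±0.5 mm), 10 rotations
  (±20°), 10 anisotropic scalings (±10%) and 10 combined misalignments
  (rotations ±10°) per image, 8 mm smoothing, affine re-registration, and
  the mean voxel displacement error in mm.
- **VOI statistics** (`samit.voi`): whole-brain normalisation, per-region
  mean uptake and right/left asymmetry ratios for 13 bilateral composite
  regions, with cohort mean ± SD tables.
- **voxel-based analysis** (`samit.vba`): two-sample t-maps, one-sided
  thresholding (voxel p + cluster extent), permutation-based cluster-level
  FWE correction, stereotaxic peak tables, glass-brain maximum-intensity
  projections.
- **phantom simulation** (`samit.phantom`): stylised digital rat-brain
  phantoms (26 ellipsoidal region labels, brain shell, PSF blur, noise,
  between-subject variability, focal/diffuse lesions) with per-tracer
  regional uptake profiles, so the entire toolbox is testable without any
  scan data.

## Command line

```sh
samit simulate --tracer pk11195 --n 19 --grid small --psf 1.2 --noise 0.05 \
      --seed 1 --lesion "3.3,0,-3.4,1.0,2.0" --out-dir sim/
samit build-template --images sim/subject_*.nii.gz --representative 0 \
      --reference mri.nii.gz --out tpl.nii.gz
samit validate --images sim/subject_*.nii.gz --template tpl.nii.gz \
      --mask sim/brain_mask.nii.gz --seed 42 --n-per-kind 10 --out errors.csv
samit voi-report --images sim/subject_*.nii.gz --atlas sim/atlas.nii.gz \
      --atlas-names sim/atlas_names.tsv --out voi.csv
samit vba --group-a ctrl/*.nii.gz --group-b lesion/*.nii.gz \
      --mask mask.nii.gz --fwhm 1.2 --voxel-p 0.001 --extent 200 \
      --alpha 0.05 --perms 1000 --seed 7 --out-dir vba_out/
```

Every command writes a `manifest.json` recording the resolved
configuration, seeds and SHA-256 hashes of its inputs.

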