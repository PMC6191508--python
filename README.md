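# atlasfuse

Multi-atlas label fusion for 3D structural images, combining per-voxel
random-forest classification with graph-based semi-supervised label
propagation.

## The problem

Multi-atlas segmentation labels a structure (the motivating case is the
hippocampus in T1-weighted MRI) by registering a library of expert-labeled
reference images — *atlases* — to the target scan and fusing their labels.
Plain majority voting (MV) decides each voxel by the atlas majority, but
registration never aligns anatomy perfectly and fusing voxels
independently ignores both the target's own intensities and the spatial
coherence of the structure. `atlasfuse` addresses both:

1. **Per-voxel random forests (RF).** Where the registered atlases
   disagree, a dedicated classifier is trained for that voxel from the
   atlases' own neighborhoods: each atlas voxel in the `(2r+1)^3`
   neighborhood contributes a (texture-feature, label) sample, the *k*
   most similar samples per class are kept, and the voxel's foreground
   probability is the forest's tree-vote fraction

   ```
   p(f_x) = (1/N_Tree) Σ_i T_i(f_x),  T_i ∈ {0,1}.
   ```

2. **Semi-supervised label propagation (SSLP).** The probabilistic map is
   refined by spreading its *reliable* labels through a voxel-similarity
   graph W_xy = exp(−(I_x−I_y)²/σ²), normalized to S = D^−1/2 W D^−1/2,
   by iterating L ← (1−β) S L + β P to its fixed point — after an
   information-balance weighting that rescales reliable background label
   mass by N_f/N_b so the majority class cannot swamp the propagation.

The four method variants — MV, MV-SSLP, RF, RF-SSLP — share all upstream
computation (bounding box, NMI-based atlas selection, vote partition).
The package also provides the nine standard evaluation metrics (Dice,
Jaccard, Precision, Recall, MD, HD, HD95, ASSD, RMSD), a leave-one-out
parameter-sweep driver, and a synthetic phantom generator so everything
is testable without imaging data. Registration is out of scope: inputs
are NIfTI volumes already resampled to a common grid.

See `docs/methods.md` for the full model description, parameter defaults
and numerical conventions.

## Worked example

Generate a small synthetic cohort and compare all four variants (each
subject: a 32³ phantom, 10 atlases emulating residual registration error
and intensity discrepancy, 50 trees):

```python
import atlasfuse as af

table = af.variant_study(n_subjects=3, master_seed=7)
for method, value in af.median_dice(table).items():
    print(f"{method:8s} median Dice = {value:.4f}")
```

prints

```
MV       median Dice = 0.9700
MV-SSLP  median Dice = 1.0000
RF       median Dice = 0.9993
RF-SSLP  median Dice = 1.0000
```

Read: majority voting already does well on these easy phantoms (0.97);
the per-voxel forests re-decide the ~900 ambiguous boundary voxels per
subject and recover most of the remaining error (0.9993); label
propagation cleans up what is left, here to perfect overlap. On real
scans the numbers are far lower and the margins tighter, but the ordering
MV < MV-SSLP, RF < RF-SSLP is the behavior the method is built to
deliver.

The same pipeline from the shell:

```bash
atlasfuse synthesize --out data/ --n-subjects 1 --seed 7
atlasfuse segment \
    --target data/subject_00/target.nii.gz \
    --atlas-dir data/subject_00/atlases \
    --truth data/subject_00/truth.nii.gz \
    --method RF-SSLP --n-tree 50 --seed 7 \
    --out out/seg.nii.gz
atlasfuse evaluate --truth data/subject_00/truth.nii.gz \
    --pred out/seg.nii.gz --out out/metrics.csv
atlasfuse sweep --data data/ --grid grid.toml --out out/sweep.csv  # LOO CV
```

`segment` writes the label, the probability map and a resolved-parameter
manifest; `sweep` ranks a TOML-declared parameter grid by mean held-out
Dice over leave-one-out folds.

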