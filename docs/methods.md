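# Methods

`atlasfuse` implements multi-atlas label fusion for 3D structural images:
given a target volume and a library of atlases (intensity image + expert
binary label) already registered to the target's grid, it fuses the atlas
labels into a segmentation of the target. The package provides the
majority-voting baseline (MV), a per-voxel random-forest fusion (RF), and
a graph-based semi-supervised refinement of either probabilistic map
(MV-SSLP, RF-SSLP). Registration itself is out of scope: all inputs must
share one voxel grid, and the loader enforces this.

## Pipeline overview

1. **Bounding box.** All per-voxel work is restricted to the union of the
   registered atlas foregrounds dilated by a margin (default 10 voxels),
   clipped to the image. Because the atlases are registered, any plausible
   target foreground lies inside this box.
2. **Atlas selection.** When the library exceeds `n_select` (default 20),
   atlases are ranked by normalized mutual information against the target
   inside the box, NMI = (H(A)+H(B))/H(A,B), computed from a 32x32 joint
   histogram with per-image min-max equal-width bins, entropies in nats,
   0*log 0 := 0. NMI is 2 for identical (or bin-aligned monotone-rescaled)
   images and tends to 1 for independent ones; a constant image is defined
   to score 1. The bin count is a package default in line with common
   registration-metric practice; results are insensitive to it at these
   image sizes.
3. **Majority voting.** The vote map holds the fraction of atlases
   labeling each box voxel foreground. Voxels with 100% agreement are
   fixed (probability 0 or 1); only the remaining *ambiguous* voxels are
   re-decided by the learned fusion. The MV hard segmentation thresholds
   the vote fraction at 0.5, ties to foreground — a documented convention
   that only matters for the even-N baseline, since 0.5-vote voxels are
   ambiguous and re-decided in the learned pipelines.

## Features

Each voxel is described by its cubic patch of side `2 r_s + 1` (default
`r_s = 3`, 343 voxels). The patch is z-scored (constant patches map to
zeros, with the standard deviation guarded at 1e-12), then a texture
filter bank is evaluated at every patch position with edge replication at
the patch border:

| block | kernel | maps |
|---|---|---|
| intensity | the z-scored patch itself | 1 |
| diff1 | central difference (f[+1]-f[-1])/2 per axis | 3 |
| diff2 | second difference f[+1]-2f[0]+f[-1] per axis | 3 |
| hyperplane | mean of the 3x3 plane orthogonal to each axis minus the center | 3 |
| sobel | derivative [-1,0,1] x smoothing [1,2,1]^2 per axis | 3 |
| laplacian | 27-point discrete Laplacian (26 neighbors, center -26) | 1 |
| range | local max - local min over 3x3x3 | 1 |

All responses are kept at full patch resolution, so the vector is
15 x 343 = 5145 features; the block order is frozen by a layout test.
These are standard discrete realizations of the named filter families —
the literature the design follows names the families without printing
kernels, so the kernels above are this package's explicit, frozen choice,
and no numeric parity with any other implementation is claimed. Because
z-scoring precedes filtering, features are invariant to positive affine
intensity transforms of the patch, which is what makes patches comparable
across subjects whose intensity profiles differ. Batch feature extraction
computes moments in float64 and stores responses as float32.

## Per-voxel random-forest fusion

For an ambiguous voxel `x`, every atlas voxel in the `(2r+1)^3`
neighborhood of `x` (default `r = 1`, clamped at the image edge)
contributes a training sample: its feature vector and its atlas label —
`(2r+1)^3 N` candidates. From these, the `k` positives and `k` negatives
closest to the target voxel's features (Euclidean distance, stable ties
by candidate order; a scarce class is truncated to what exists) form the
balanced training set, default `k = 100`.

A forest of `N_Tree` classification trees (default 200; the scaled-down
study uses 50) is grown on the balanced set: each tree on an independent
bootstrap multiset, to purity (minimum leaf size 1), Gini impurity, with
`N_Split` predictors (default 20) sampled uniformly at random per node and
thresholds at midpoints between consecutive distinct member values. The
voxel's foreground probability is the fraction of trees voting
foreground, so the probabilistic map takes values on the `1/N_Tree`
lattice; thresholding at 0.5 (ties to foreground) gives the RF hard
segmentation.

The tree induction lives in a numba kernel (`atlasfuse._forest`) because
the method fits one forest per ambiguous voxel — tens of thousands of
~200-sample fits per study — and a general-purpose estimator spends most
of such a fit in per-call overhead. The kernel argsorts each feature
column once per forest (all trees share the training matrix) and
evaluates splits by a linear pass over the presorted order. It is the
exact Breiman algorithm, not an approximation; the test suite
cross-checks its decisions against scikit-learn's forest on separable
data and validates chance-level behavior under permuted labels.

Determinism: per-voxel forest seeds derive from the master seed and the
voxel's linear index (`SeedSequence([master, index])`), so results are
independent of scheduling and atlas processing order; per-tree bootstrap
and feature-sampling streams derive from the forest seed inside the
kernel. The bootstrap is taken over the balanced 2k subset (configurable
design point; resampling from all candidates instead would change only
the training-set composition per tree).

A voxel whose candidate neighborhood is single-class skips training and
takes that class's probability directly.

## Semi-supervised label propagation

The refinement encodes a probability vector `p` as an n x 2 coding

    p_i1 = max(2(p_i - 0.5), 0),    p_i2 = max(2(0.5 - p_i), 0),

so 0.5 carries no information, and entries above the reliability
threshold `T` (default 0.5) count as reliable. Reliable background is
rebalanced against the typically smaller reliable foreground:

    p*_i2 = max((N_f / N_b) p_i2, T)   for rows with p_i2 > T,

then each reliable class is divided by its reliable-entry mean, so both
classes inject average label mass 1 (information-balance weighting).
Unreliable rows pass through unchanged by default (`zero_unreliable`
optionally zeros them). One convention is worth stating: the floor at `T`
exists precisely to keep rescaled background entries reliable, so the
normalization set for the background is the rows with original
`p_i2 > T`; a strict `>` on the floored value would silently drop entries
floored to exactly `T`.

Voxel similarity is a Gaussian on intensity differences,
`W_xy = exp(-(I_x - I_y)^2 / sigma^2)` (default `sigma = 10`, in image
intensity units — meaningful for 0-255-like grayscale, always
configurable), zero diagonal, normalized to `S = D^(-1/2) W D^(-1/2)`
whose spectral radius is at most 1. The refined coding is the fixed point
of

    L_{n+1} = (1 - beta) S L_n + beta P*,    0 < beta < 1 (default 0.6),

reached either by iteration (tolerance 1e-6 on the max-abs change, cap
1000 — convergence is guaranteed since the spectral radius of
`(1-beta) S` is below 1) or, for graphs up to 2000 nodes, by the direct
solve `beta (I - (1-beta) S)^(-1) P*`; the two agree to 1e-6 by an oracle
test. A voxel becomes foreground iff `l_i1 > l_i2`, ties to background.

Two graph choices are open in principle and both are implemented:

* **Node set** (`graph`): `"auto"` (default) takes the unreliable voxels
  plus a 1-voxel ring of reliable neighbors, so reliable information
  borders every unreliable component while the graph stays small enough
  for exact solves; `"box"` takes every bounding-box voxel (the literal
  whole-map reading). Voxels outside the node set keep their thresholded
  input label.
* **Edge set**: dense all-pairs similarity up to 20 000 nodes (the
  literal reading, used as the reference in tests); above that, a sparse
  graph keeping each node's 26 spatial neighbors plus its 10 nearest
  intensity values, symmetrized, with isolated nodes reconnected to their
  nearest spatial neighbor.

Note a consequence of `beta = 0.6`: confidently wrong inputs (reliable,
maximal coding) are largely preserved — the fidelity term dominates. The
refinement targets *uncertain* voxels, which is exactly where forest vote
fractions land near a true boundary; this is why it improves MV and RF
rather than overruling them.

The trade-off parameter of the underlying energy is never materialized;
only `beta` enters the computation. A patch-feature distance variant of
the affinity is deliberately not implemented: the similarity is scalar
intensity as written.

## Evaluation metrics

Nine metrics between manual label A and result B: Dice, Jaccard,
Precision, Recall (voxel-count ratios) and MD, HD, HD95, ASSD, RMSD
(Euclidean surface distances in mm, voxel index x spacing). The boundary
is the set of foreground voxels with at least one 6-connected background
neighbor, the image border counting as background. MD is directed
A -> B (manual to automatic), as defined — not symmetrized. HD95 trims
the `ceil(0.05 n)` largest distances from each directed set before taking
the max of the two directed maxima; a guard keeps at least one distance
per direction so single-point surfaces remain defined (the alternative —
a pooled-percentile HD95 — is a known variant and is not what is
implemented). Distances use a KD-tree; an O(|dA| |dB|) exhaustive oracle
verifies all five distance metrics to 1e-9 mm in tests.

## Synthetic phantoms

The generator emulates the statistical structure the method assumes, at
desk scale, with intensities on a 0-255-like scale so the default
`sigma = 10` is directly meaningful:

* **Target**: an ellipsoidal blob (default radii (8, 6, 5) voxels in a
  32^3, 1 mm grid) whose implicit surface is perturbed by a smooth random
  field (relative amplitude 0.1, smoothing sd 6 voxels); background mean
  80, foreground mean 160, multiplicative bias field (amplitude 5%,
  smoothing sd 8), i.i.d. Gaussian noise sd 10.
* **Atlases**: the truth warped by independent Gaussian-smoothed random
  displacement fields (smoothing sd 4 voxels; per-component sd
  amplitude/sqrt(3) so the displacement-magnitude sd equals the amplitude,
  default 2 voxels — the residual-registration-error regime, where
  atlas-vs-truth Dice lands around 0.85-0.95), nearest-neighbor warping
  for labels and linear for intensities, then per-atlas gain U(0.9, 1.1),
  offset U(-10, 10), and fresh noise.
* **Cohorts**: per-subject blob centers (+-1.5 voxels) and radii (+-1
  voxel) are jittered; all randomness derives from one master seed with
  no hidden global state.

What the phantoms do not emulate: real hippocampal anatomy, MRI physics
(no Rician noise, no partial-volume model beyond linear interpolation),
or systematic registration bias. Passing the cohort study therefore shows
that the pipeline's machinery behaves and orders as designed under its
own assumptions — not that it attains any particular accuracy on clinical
data.

## Study conditions and problem sizes

The built-in cohort study (`atlasfuse.variant_study`) runs the four
variants on 20 subjects at 32^3 with 10 atlases and 50 trees, sharing the
vote partition and forest map across variants; it completes in roughly
ten minutes on one core. Operating parameters default to the tuned
values k = 100, N_Split = 20, T = 0.5, sigma = 10, beta = 0.6 (N_Tree
200 by default in `RFParams`, 50 in the scaled-down study). The sweep
driver (`cross_validated_sweep`) reproduces the tuning protocol:
leave-one-out folds over subjects, mean held-out Dice per configuration,
full Cartesian grids in deterministic order (the forest grid
{100,200} x {100,200} x {10,20,30} enumerates 12 settings; the
propagation grid {0.4,0.5,0.6} x {5,10,20} x {0.5,0.6,0.7} enumerates
27).

## Numerical conventions and degenerate inputs

* Labels on disk are uint8, probabilities float32; geometry (affine) is
  carried untouched, never reoriented; grid checks tolerate 1e-4 mm
  spacing differences.
* Patch z-scoring guards sd at 1e-12 (constant patch -> zero features).
* MV hard-segmentation ties and probability-threshold ties go to
  foreground; propagation binarization ties go to background (each as
  defined above).
* A voxel with single-class candidates takes that class directly; a
  training set missing a class raises a named error.
* Balance weighting with no reliable labels on one side raises a named
  error identifying the empty side (an all-0.5 probability map is the
  canonical trigger).
* Affinity weights are positive in exact arithmetic but can underflow to
  zero for extreme intensity gaps at small sigma; a node whose degree
  underflows to zero gets a zero similarity row (pseudo-inverse
  normalization), so it keeps only its unary term during propagation, and
  a warning is logged.
* All randomness flows from explicit seeds (SeedSequence-derived, below
  2^31); repeated runs are bit-identical.

## Known limitations

* Binary (foreground/background) segmentation only; no multi-class
  propagation.
* Registration quality is assumed, not checked: badly aligned atlases
  degrade the bounding box, the candidate labels and the result alike.
* The dense affinity is quadratic in nodes; above 20 000 nodes the sparse
  approximation changes the graph (the dense mode remains the reference).
* The filter-bank kernels are fixed conventions, not learned or tuned;
  feature selection and multi-scale patches are out of scope.
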