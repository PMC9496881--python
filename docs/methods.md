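# Methods

`blockseg` segments a hyperintense brain lesion from a 2-D MRI slice given a
co-registered disease-free reference slice. The method has three stages:
morphological skull-stripping, a particle-swarm search for the rectangular
block that best separates the two images under a two-way fixed-effects
ANOVA variance ratio, and two-cluster K-means labeling of the found block.
This note records the model, its assumptions, the numerical choices, and
what the synthetic phantoms do and do not establish.

## The block fitness

For a candidate block `C` (from the diseased image) and the co-located
block `R` (from the reference), the observations are laid out as a balanced
two-way crossed design:

- **factor A** — image source, `a = 2` levels (diseased vs reference);
- **factor B** — column index within the block, `b = w` levels;
- **replicates** — the `n = h` rows of each column.

The total sum of squares decomposes as `SST = SSA + SSB + SSAB + SSE`, with
mean squares `MS = SS/df`, `df_A = a−1`, `df_B = b−1`,
`df_AB = (a−1)(b−1)`, `df_E = N − ab` (residual df of the fixed-effects
model; `N = abn`). The fitness maximized by the swarm is

    fitness = MSA / MSE + MSB / MSE

with an `ε = 1e−12` guard on MSE and fitness defined as 0 when `SST = 0`
(a constant pair — e.g. air background — carries no lesion evidence and
must not score infinitely). The image factor's mean square `MSA` grows with
the squared mean difference between the candidate and reference blocks, so
a block containing tissue present in only one image scores high. The
interaction term deliberately does not enter the fitness; p-values are
computed for completeness of the tables (through the regularized incomplete
beta function, `P(X ≥ F) = I_x(df2/2, df1/2)` at `x = df2/(df2+df1·F)`) but
play no role in the search.

An alternative `rows-as-B` layout (factor B = rows, columns as replicates)
is exposed for sensitivity checks; the default layout is `columns-as-B`.
Unbalanced designs are rejected rather than approximated — the block layout
guarantees balance.

The sum-of-absolute-differences (SAD, the L1 block dissimilarity) is
provided as the comparison fitness.

## Search

Particles live in the continuous space of block top-left corners and follow
the standard inertia/cognitive/social updates with fresh uniform `R1, R2`
per particle per iteration. Defaults: 20 particles, 50 iterations,
`ω = 0.72`, `c1 = c2 = 1.49` (standard constriction-style values — the
original description leaves them open), velocity clamped to
`±max(block_height, block_width)` pixels, positions clamped to the valid
domain after each update. Block size defaults to a quarter of the smaller
image dimension, rounded down to even. Positions are rounded to integers
only for block extraction, which induces a finite search space; every
evaluated integer position is memoized, so the cache is semantically
transparent (bit-identical values, fewer evaluations). Iteration 1 scores
the random initial positions; updates run from iteration 2, so at most
`Np·t_max` unique positions are ever evaluated. The only stopping rule is
the iteration budget.

A stride-1 exhaustive search over all positions serves as the oracle the
swarm is validated against: on the 64×64 phantom the swarm attains the true
maximum in ≥ 90% of seeds and can never exceed it.

**Search-domain restriction.** The pipeline passes the brain mask to the
search and blocks not entirely inside it score 0. This matters: after
skull-stripping, a block straddling the brain/background boundary compares
zero padding rather than tissue, and at the near-vertical tangents of the
brain ellipse such blocks have large column effects (SSB) with almost no
within-column variance (SSE), so the variance ratio would peak on the
boundary instead of the lesion. Restricting the domain to whole-brain
blocks removes the artifact; on raw (unstripped) images the skull ring's
curvature keeps SSE up and no restriction is needed.

## Skull-stripping

Binarize (Otsu by default; the original procedure's fixed threshold is
config-exposed), fill holes by border flood-fill, erode with a disk
structuring element (default radius 5 px — enough to peel the default
4-px skull ring), keep the largest 8-connected component, and mask the
input. Erosion is *not* idempotent — each application peels the boundary —
so the projection property (re-stripping the stripped image is a no-op)
holds exactly for the erosion-free composition and re-stripping with a
positive radius only ever shrinks the mask.

## Segmentation and evaluation

K-means with K = 2 on the raw intensities of the best block (no spatial
features). Initial centers are the block minimum and maximum —
deterministic, maximally spread 1-D seeding that cannot create an empty
cluster at start; an emptied cluster is re-seeded at the point farthest
from its nearest surviving center; iteration stops when no assignment
changes (cap 300). The brighter cluster is labeled tumor, matching the
hyperintense appearance of lesions on FLAIR/T1c; `tumor_polarity="dark"`
flips this for hypointense targets. A constant block yields an empty mask
with a warning, not an error. The full-frame tumor mask is zero outside
the ROI.

Evaluation against a ground-truth mask reports Dice `2TP/(2TP+FP+FN)`,
Jaccard `TP/(TP+FP+FN)` (tied by `D = 2J/(1+J)`), the Pearson correlation
of the flattened pixels with population moments (undefined — an error, or
NaN in the batch report — for constant inputs), and RMSE on the normalized
[0, 1] scale. Two empty masks score Dice = Jaccard = 1 (perfect agreement
on emptiness), which the no-lesion phantom needs.

## The phantom generator

Each phantom is a stated world: a 128×128 slice, brain ellipse with
semi-axes (48, 56) centered at (64, 64), a 4-px skull ring at intensity
0.95, tissue at 0.35 with additive Gaussian noise (SD 0.05) truncated to
[0, 1], air background 0, and a radius-10 disk lesion at 0.85 — roughly
10 SD above tissue, as a conspicuous FLAIR/T1c lesion would be. The default
lesion center (50, 75) is off-center and comfortably interior. The *same*
noise realization is used in both images of a pair, so outside the lesion
the pair is pixel-identical: a perfectly registered acquisition pair in
which the lesion is the only systematic difference. An optional
`intensity_offset` shifts the diseased tissue globally, emulating an
acquisition intensity difference.

What a green phantom test does **not** establish: robustness to Rician
noise, bias fields, partial-volume effects, anatomy texture,
mis-registration, or independent noise between the two scans. The
shared-noise pair isolates exactly the signal the fitness is designed to
detect, which makes the phantoms a best case for both fitness functions.

## A measured negative result

Under a global intensity offset `c` between the scans, the ANOVA fitness
performs *worse* than SAD on these phantoms, not better. The offset enters
the image-factor mean square at every block (`MSA ∝ N·c²/4` over a noise-
floor MSE), while at lesion blocks MSE is inflated by the tumor/tissue
mixture within cells; for `c` beyond roughly twice the noise SD the
search locks onto clean tissue blocks anywhere in the brain. SAD's offset
contribution is spatially uniform, so its argmax stays at maximal lesion
coverage for any `c` below the lesion contrast (0.5 by default). The
acceptance test for the offset scenario is implemented exactly as specified
and fails, deliberately: it documents a real property of the variance-ratio
fitness on registered pairs rather than being tuned away. (On clinical
pairs, where the "reference" is a different subject and blocks differ
everywhere, the balance of the two terms can differ.)

## Known limitations

- 2-D single-slice only; one lesion block (no multi-focal search).
- Balanced two-way designs only; no random/mixed effects, no Type II/III
  sums of squares.
- The search assumes the lesion fits in (or mostly overlaps) one block of
  the configured size entirely inside the brain mask; lesions hugging the
  stripped boundary may only be partially covered.
- DICOM input is not supported (no pydicom in the supported environment);
  PNG/TIFF and single-slice NIfTI are.
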