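# Methods

## The problem

Structural covariance analyses of brain MRI traditionally build a single
covariance network per group of subjects, which leaves no per-subject unit of
analysis and entangles every region pair with every other. This package
implements an individualized alternative for mouse cohorts carrying multiple
Alzheimer's-risk factors (human ApoE allele, sex, age, diet, humanized-NOS2
immunity): each mouse gets its own dissimilarity network per imaging modality,
the networks are embedded jointly into a common latent space, and each brain
region is tested separately for distributional differences across risk-factor
combinations.

## Per-subject networks

Regional features arrive as subjects x regions tables: volumes (mm^3) and mean
fractional anisotropy per region of a 332-region, hemisphere-symmetric atlas.
Features are normalized per subject — volume by the subject's total
within-atlas volume (rows sum to 1), FA by the subject's maximum regional FA
(row maximum 1) — and each subject's network is the matrix of absolute
pairwise differences A_ij = |x_i - x_j|. Every network is symmetric, hollow,
and [0, 1]-valued by construction; these invariants are asserted in tests.

Normalizing volume by the within-atlas total (rather than a whole-brain
measure including extra-atlas tissue, which is not available at this stage)
makes regional volumes compositional: any true volume change in one region
slightly shifts every other region's relative volume. The consequences for
inference are discussed under *Limitations*. FA is normalized by the
per-subject maximum rather than a cohort-wide maximum so that each subject's
network is invariant to that subject's own FA ceiling; the choice matters
little unless an effect moves the maximal region itself.

## Joint embedding

Networks of one modality are modelled as joint random dot product graphs:
region i carries a latent position x_i in R^d and edge weights concentrate
around X X^T. Latent positions are estimated by adjacency spectral embedding
(ASE), U |S|^(1/2) from the top-d eigenpairs by magnitude; negative
eigenvalues are retained through their absolute values. Because separate ASEs
are only identified up to orthogonal transforms, the m networks are embedded
jointly through the omnibus matrix O (block (l, k) = (A(l) + A(k)) / 2): one
decomposition yields m mutually aligned n x d blocks.

Numerical choices:

* Eigenvector signs are fixed so each column's largest-magnitude entry is
  positive; all downstream statistics are invariant to this convention.
* For mn <= 2000 the omnibus matrix is decomposed densely; above that, O is
  never materialized — a linear operator computes O v in O(m n^2) via
  (O v)_l = (A(l) s + t)/2 with s = sum_k v_k, t = sum_k A(k) v_k, and a
  Lanczos solver with a deterministic start vector extracts the top of the
  spectrum. Dense and implicit routes agree to ~1e-12 per matvec and are
  cross-checked in tests.
* The embedding dimension is selected from the top min(length, 100)
  eigenvalue magnitudes with the Zhu–Ghodsi profile-log-likelihood elbow; by
  default the **second** elbow. The first elbow almost always isolates the
  single dominant eigenvalue of these dense weighted networks; the second
  delimits the remaining signal dimensions (for a rank-3 block model it
  recovers 3). The elbow count and a fixed-d override are configurable.

Volume and FA are embedded independently and the per-region positions
concatenated (volume block first), giving q = d_vol + d_fa coordinates per
region per subject — 6 when both modalities select d = 3.

## Testing for vulnerable regions

For each region, the subject-level latent feature vectors y(i) in R^q are
tested against group membership t(i) defined by a subset of risk factors: the
K-sample null H0: F_1 = ... = F_K is reduced to independence by one-hot
encoding the observed cells of the factor cross-product (distinct groups sit
at Euclidean distance sqrt(2)). The statistic is the unbiased (U-centered)
distance correlation between the Euclidean distance matrices of features and
labels; it doubles as the reported effect size (floored at 0 for reporting).
P-values use the fast chi-squared approximation: under H0, s * dcorr + 1 is
approximately chi-squared with 1 degree of freedom. The approximation
dominates the true null in the upper tail, so the test is conservative to
nominal — empirically its level at alpha = 0.05 is within [0.01, 0.07] at
s = 30, and it is strongly conservative at the small thresholds that matter
after multiplicity correction. A seeded permutation oracle (labels permuted,
p = (1 + #{perm >= obs}) / (1 + n_perm)) validates the approximation in tests.

Degenerate situations are explicit: zero distance variance on either side
yields statistic 0 and p = 1; a group cell with fewer than 2 subjects aborts
that factor combination with a logged warning rather than a silent skip.

Because high-fat diet was only administered within part of the design, two
analyses avoid empty cells: analysis A (control-diet cohort) varies genotype,
sex, age and immunity; analysis B (humanized-NOS2 cohort) varies genotype,
sex, age and diet. Age is binarized at the genotype-wise median (ties count
as young, making the split deterministic). The battery enumerates all 2^4 - 1
= 15 non-empty factor subsets per analysis; one-vs-rest genotype codings
(e.g., ApoE2 vs ApoE3-or-4) repeat the genotype-containing subsets. The
cohort is filtered *before* network construction and embedding, so each
analysis embeds exactly the subjects it tests.

Familywise error is controlled by Holm–Bonferroni. The default family is all
regions of one (analysis x factor-combination) panel, matching per-panel
reporting; a global family pooling an analysis' whole battery is provided and
is the right choice when rejections are counted across panels, since Holm
bounds the error rate only within its family.

## Synthetic cohorts

The generator emulates the study design rather than any particular dataset: a
3 genotype x 2 sex x 2 diet x 2 immunity factorial with the unsupported
HFD x mouse-Nos2 cells empty, ages Uniform(12, 20) months, log-normal volumes
V = exp(mu_r + effects + N(0, sigma_v^2)) and clipped-Gaussian FA in
(0.01, 0.99). Defaults: sigma_v = 0.1 (roughly 10% volumetric variability),
sigma_f = 0.02 FA units, baselines mu_r ~ N(log 1 mm^3, 0.8^2) and
phi_r ~ U(0.25, 0.60). The default cohort is 96 subjects: 6 per control-diet
cell (12 cells) plus 4 per supported high-fat cell (6 cells); the balanced
factorial cannot be divided evenly across the 18 supported cells, and this
split keeps the control-diet analysis cohort (72 mice) exactly balanced. All
randomness derives from one seed through named substreams so adding one
modality never perturbs another's draws.

The reference recovery experiment plants effects on 5 regions tied to one
factor level (sex = F), alternating in sign (+/-12% volume, +/-0.03 FA).
Placement is deliberate: planted regions have at least median volume share
(detectability in an absolute-difference volume network scales with the
region's share), stay away from the per-subject FA maximum, and are mutually
separated in baseline volume and FA so their network rows do not interact
near the |x_i - x_j| fold. Sign alternation keeps total brain volume balanced
across groups, which would otherwise leak a compositional group difference
into every region.

What the generator does *not* emulate: spatially correlated segmentation
error, hemispheric symmetry of real anatomy, realistic covariance between
volume and FA, or atlas mis-registration. Passing recovery tests show the
pipeline's statistical machinery works under its own model assumptions; they
do not certify power or error rates on real MRI-derived tables.

## Operating characteristics (as computed by the test suite and
`scripts/acceptance.py`)

* ASE inverts a noiseless rank-3 probability matrix to relative Procrustes
  residual <= 1e-8; the omnibus embedding of m identical networks returns
  identical blocks (each equal to ASE of the shared network).
* The unbiased dcorr matches an explicit U-centering double loop to 1e-12.
* Null cohorts (no planted effects): zero Holm rejections battery-wide
  (global family) in >= 95 of 100 seeds at alpha = 0.05.
* Planted cohorts: all 5 vulnerable regions rejected for the matching factor
  subset with at most 5% of null regions falsely rejected, in >= 90 of 100
  seeds (40 regions, 96 subjects).
* The second scree elbow selects d = 3 for rank-3 generating models in
  >= 90 of 100 seeds.

Problem sizes (40 regions, 96 subjects, 100 seeds) were chosen so the full
calibration suite completes in minutes on one CPU while leaving each
experiment enough replicates to bound its rates.

## Limitations

* Compositional leakage: volume normalization couples regions, and the
  absolute-difference construction propagates any regional effect into other
  regions' network rows. Large unbalanced volume effects therefore produce
  genuine (not type-I) signal in unaffected regions; localization is sharp
  only for modest or balanced effects.
* Power scales with a region's volume share; effects in very small regions
  are hard to detect in volume-derived networks (FA-derived networks do not
  share this weighting).
* The weighted networks are embedded with machinery whose guarantees are
  proven for binary RDPGs; for weighted networks the embedding is a
  well-behaved heuristic, which is one reason inference is validated by
  simulation and a permutation oracle.
* The chi-squared p-value is conservative in deep tails; with heavy
  multiplicity the effective level is well below nominal, trading power for
  validity.
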