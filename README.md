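# scnvuln

Vulnerable brain regions from **individualized structural covariance
networks**: joint spectral embedding of per-subject volume and FA
dissimilarity networks, with multi-way distance-correlation testing across
Alzheimer's-risk factors.

## What it does

Group-level structural covariance networks give one network per cohort and no
per-subject unit of analysis. This package instead builds one network *per
mouse and modality* from regional MRI features of a 332-region atlas:
normalize (volume by total brain volume, FA by the subject's maximum), then
take absolute pairwise differences

    A_ij = | x_i - x_j |,

giving a symmetric, hollow, [0, 1]-weighted network per subject. Modelling
the m networks of one modality as joint random dot product graphs, the
**omnibus embedding** — adjacency spectral embedding X̂ = Û |Ŝ|^{1/2} of the
mn x mn block matrix O with blocks (A^{(l)} + A^{(k)})/2 — yields mutually
aligned latent positions for every region of every subject; embedding
dimension comes from the second profile-likelihood elbow of the scree
(d = 3 per modality is typical). Volume and FA embeddings are concatenated
into a 6-dimensional feature vector per region per mouse.

Each region r is then tested for *vulnerability*: does the distribution of
its latent features differ across the cells of a risk-factor combination
(ApoE genotype, sex, age bin, diet, humanized-NOS2 immunity)?

    H0: F_1 = ... = F_K   vs   HA: F_k != F_l for some k != l

The K-sample problem is reduced to independence against one-hot group labels
and tested with the **unbiased distance correlation**, using the fast
chi-squared null approximation p = P(chi^2_1 >= s·dcorr + 1); Holm–Bonferroni
controls the familywise error rate. All 2^4 - 1 = 15 factor subsets are
tested per analysis (control-diet cohort: genotype/sex/age/immunity;
humanized-NOS2 cohort: genotype/sex/age/diet), optionally under one-vs-rest
genotype codings.

See `docs/methods.md` for assumptions, numerical choices and limitations.

## Worked example

Simulate a 60-mouse cohort (20 regions) with two planted sex-linked regions —
one enlarged, one shrunken — and run the control-diet analysis:

```sh
scnvuln simulate --out cohort --seed 7 --n-regions 20 \
    --n-per-cell-ctrl 4 --n-per-cell-hfd 2 \
    --effect "roi002_left:sex=F:0.12:0.03" \
    --effect "roi009_right:sex=F:-0.12:-0.03"
scnvuln run-all --volume cohort/volume.csv --fa cohort/fa.csv \
    --covariates cohort/covariates.csv --atlas cohort/atlas.tsv \
    --out results --analysis A
```

which prints `analysis A: 700 tests, 15 Holm rejections ->
results/results_A.tsv`. The sex panel of the report, sorted by p:

```
   region_id hemisphere factors  n_groups    dcorr            p    p_adj  reject
roi009_right      right     sex         2 0.505452 5.005490e-07 0.000010    True
 roi002_left       left     sex         2 0.234602 4.625483e-04 0.008788    True
roi002_right      right     sex         2 0.145005 4.781665e-03 0.086070   False
 roi001_left       left     sex         2 0.079315 2.834206e-02 0.481815   False
```

Exactly the two planted regions are rejected for the sex factor: `dcorr` is
the effect size (distance correlation between each region's 6-dimensional
latent features and sex), `p` its chi-squared p-value, and `p_adj` the Holm
adjustment over the 20 regions of the panel. The remaining rejections sit in
panels that include sex among their factors (sex x age, genotype x sex, ...),
where the same planted effects are visible.

Real data enter through the same three plain-text formats the simulator
writes: per-modality CSV feature tables (subjects x regions), a covariate CSV
(subject_id, genotype, sex, age_months, diet, immunity), and a region TSV
(region_id, name, hemisphere). Stage-by-stage runs (`build-networks`,
`embed`, `test`) cache intermediates and reproduce `run-all` byte-for-byte.

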