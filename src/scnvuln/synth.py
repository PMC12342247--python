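"""Synthetic cohorts with planted region-level risk-factor effects.

The generator emulates the statistical structure the pipeline assumes: a
factorial mouse cohort (3 ApoE genotypes x 2 sexes x 2 diets x 2 immunity
lines, with the unsupported high-fat-diet x mouse-Nos2 cells left empty),
two regional feature modalities, and additive region-level effects tied to
factor-level combinations.

Volumes are log-normal (positive, multiplicative biology): for subject s and
region r,

    V(s, r) = exp( mu_r + sum of matching effects + eps ),  eps ~ N(0, sigma_v^2).

FA is a clipped Gaussian bounded inside (0, 1):

    FA(s, r) = clip( phi_r + sum of matching effects + eps', 0.01, 0.99 ).

Ages are Uniform(12, 20) months. All randomness flows from a single seed
through named substreams (ages / volume / fa / baselines), so adding one
modality never perturbs another's draws. The returned ground truth lists the
planted (region, factor subset) pairs, enabling recovery and type-I-error
experiments against a known answer.

RDPG samplers for binary networks (edges Bernoulli(x_i . x_j)) and noisy
weighted networks around P = X X^T are included for embedding unit tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import (
    Atlas,
    DataValidationError,
    GENOTYPES,
    RegionTable,
    default_atlas,
    region_table_from_frame,
    validate_covariates,
)


@dataclass(frozen=True)
class PlantedEffect:
    """Additive shift delta at one region for subjects matching ``where``.

    ``d_volume`` is in log-volume units; ``d_fa`` in FA units.
    """

    region: str
    where: dict
    d_volume: float = 0.0
    d_fa: float = 0.0

    @property
    def factors(self) -> frozenset:
        return frozenset(self.where)


@dataclass
class SynthConfig:
    """Study-condition description for one synthetic cohort.

    Defaults give the 96-subject design used throughout: 6 subjects in each
    of the 12 control-diet cells plus 4 in each of the 6 supported
    high-fat-diet cells (HFD is only given to the humanized-NOS2 line).
    Noise defaults are sigma_v = 0.1 (about 10% volumetric variability) and
    sigma_f = 0.02 FA units. Region baselines, unless supplied, are drawn
    once per seed: mu_r ~ N(log 1.0 mm^3, 0.8^2) and phi_r ~ U(0.25, 0.60).
    """

    seed: int = 0
    n_regions: int = 40
    n_per_cell_ctrl: int = 6
    n_per_cell_hfd: int = 4
    sigma_v: float = 0.1
    sigma_f: float = 0.02
    baseline_log_volume: np.ndarray | None = None
    baseline_fa: np.ndarray | None = None
    effects: tuple[PlantedEffect, ...] = ()
    age_range: tuple[float, float] = (12.0, 20.0)


@dataclass
class GroundTruth:
    """The planted truth: which (region, factor subset) pairs carry effects."""

    vulnerable_regions: set = field(default_factory=set)

    @property
    def regions(self) -> set:
        return {r for r, _ in self.vulnerable_regions}


def _design_cells(cfg: SynthConfig):
    cells = []
    for geno in GENOTYPES:
        for sex in ("F", "M"):
            for imm in ("HN", "mNos2"):
                cells.append((geno, sex, "CTRL", imm, cfg.n_per_cell_ctrl))
            # high-fat diet is only supported in the humanized-NOS2 line
            cells.append((geno, sex, "HFD", "HN", cfg.n_per_cell_hfd))
    return cells


def generate_cohort(cfg: SynthConfig, atlas: Atlas | None = None):
    """Generate (volume RegionTable, fa RegionTable, covariates, GroundTruth)."""
    if cfg.n_per_cell_ctrl < 0 or cfg.n_per_cell_hfd < 0:
        raise DataValidationError("cell counts must be non-negative")
    if atlas is None:
        atlas = default_atlas(cfg.n_regions)
    if atlas.n_regions != cfg.n_regions:
        raise DataValidationError("atlas size does not match config")
    regions = atlas.region_ids

    root = np.random.SeedSequence(cfg.seed)
    rng_age, rng_vol, rng_fa, rng_base = (
        np.random.default_rng(s) for s in root.spawn(4)
    )

    mu = cfg.baseline_log_volume
    if mu is None:
        mu = rng_base.normal(np.log(1.0), 0.8, size=cfg.n_regions)
    phi = cfg.baseline_fa
    if phi is None:
        phi = rng_base.uniform(0.25, 0.60, size=cfg.n_regions)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if mu.shape != (cfg.n_regions,) or phi.shape != (cfg.n_regions,):
        raise DataValidationError("baselines must have one entry per region")
    if np.any(phi <= 0) or np.any(phi >= 1):
        raise DataValidationError("baseline FA must lie inside (0, 1)")

    rows = []
    i = 0
    for geno, sex, diet, imm, count in _design_cells(cfg):
        for _ in range(count):
            i += 1
            rows.append(
                {
                    "subject_id": f"m{i:04d}",
                    "genotype": geno,
                    "sex": sex,
                    "age_months": round(float(rng_age.uniform(*cfg.age_range)), 3),
                    "diet": diet,
                    "immunity": imm,
                }
            )
    cov = validate_covariates(pd.DataFrame(rows))
    s = len(cov)

    region_idx = {r: j for j, r in enumerate(regions)}
    shift_v = np.zeros((s, cfg.n_regions))
    shift_f = np.zeros((s, cfg.n_regions))
    truth = GroundTruth()
    for eff in cfg.effects:
        if eff.region not in region_idx:
            raise DataValidationError(f"effect targets unknown region {eff.region!r}")
        match = np.ones(s, dtype=bool)
        for factor, level in eff.where.items():
            match &= (cov[factor] == level).to_numpy()
        j = region_idx[eff.region]
        shift_v[match, j] += eff.d_volume
        shift_f[match, j] += eff.d_fa
        truth.vulnerable_regions.add((eff.region, eff.factors))

    log_v = mu[None, :] + shift_v + rng_vol.normal(0.0, cfg.sigma_v, size=(s, cfg.n_regions))
    vol = np.exp(log_v)
    fa = np.clip(
        phi[None, :] + shift_f + rng_fa.normal(0.0, cfg.sigma_f, size=(s, cfg.n_regions)),
        0.01,
        0.99,
    )

    subj = list(cov["subject_id"])
    vol_rt = region_table_from_frame(
        pd.DataFrame(vol, index=pd.Index(subj, name="subject_id"), columns=regions),
        atlas,
        "volume",
    )
    fa_rt = region_table_from_frame(
        pd.DataFrame(fa, index=pd.Index(subj, name="subject_id"), columns=regions),
        atlas,
        "fa",
    )
    return vol_rt, fa_rt, cov, truth


def headline_config(
    seed: int,
    d_volume: float = 0.12,
    d_fa: float = 0.03,
    n_regions: int = 40,
    factor: str = "sex",
    level: str = "F",
) -> tuple[SynthConfig, list[str]]:
    """The reference recovery experiment: 5 planted vulnerable regions.

    Returns a config (and the planted region ids) for a 96-subject cohort
    with five regions carrying a ``factor``-linked effect of alternating
    sign (some regions enlarge, some shrink, as real phenotypes do; the
    alternation also keeps total brain volume balanced across groups, since
    regional volumes are compositional after normalization).

    Placement is deliberate, not uniform: detectability in an
    absolute-difference volume network scales with a region's volume share,
    so effects are planted in regions of at least median share; regions near
    the per-subject FA maximum are avoided so the FA effect cannot flip the
    normalizing maximum; and planted regions are kept mutually separated in
    baseline volume and FA so their network rows do not overlap near the
    |x_i - x_j| fold. Default effect magnitudes (12% volume, 0.03 FA) are
    large but biologically plausible shifts.
    """
    root = np.random.SeedSequence(seed)
    rng_base = [np.random.default_rng(s) for s in root.spawn(4)][3]
    mu = rng_base.normal(np.log(1.0), 0.8, size=n_regions)
    phi = rng_base.uniform(0.25, 0.60, size=n_regions)
    regions = default_atlas(n_regions).region_ids

    share = np.exp(mu) / np.exp(mu).sum()
    eligible = sorted(
        (j for j in range(n_regions)
         if 0.30 <= phi[j] <= 0.52 and share[j] >= np.median(share)),
        key=lambda j: -share[j],
    )
    d_mu, d_phi = 0.3, 0.06
    while True:
        sel: list[int] = []
        for j in eligible:
            if all(abs(mu[j] - mu[k]) > d_mu and abs(phi[j] - phi[k]) > d_phi for k in sel):
                sel.append(j)
            if len(sel) == 5:
                break
        if len(sel) == 5:
            break
        d_mu *= 0.8
        d_phi *= 0.8

    planted = [regions[j] for j in sel]
    effects = tuple(
        PlantedEffect(
            r,
            {factor: level},
            d_volume=d_volume * (-1) ** i,
            d_fa=d_fa * (-1) ** i,
        )
        for i, r in enumerate(planted)
    )
    cfg = SynthConfig(
        seed=seed,
        n_regions=n_regions,
        effects=effects,
        baseline_log_volume=mu,
        baseline_fa=phi,
    )
    return cfg, planted


# ---------------------------------------------------------------------------
# RDPG samplers for embedding tests
# ---------------------------------------------------------------------------

def sample_rdpg(X: np.ndarray, seed: int = 0) -> np.ndarray:
    """Sample a binary RDPG adjacency: A_ij ~ Bernoulli(x_i . x_j), symmetric, hollow."""
    X = np.asarray(X, dtype=float)
    P = X @ X.T
    if np.any(P < -1e-12) or np.any(P > 1 + 1e-12):
        raise DataValidationError("latent positions give probabilities outside [0, 1]")
    P = np.clip(P, 0.0, 1.0)
    n = P.shape[0]
    rng = np.random.default_rng(seed)
    upper = rng.random((n, n)) < P
    A = np.triu(upper, k=1).astype(float)
    return A + A.T


def sample_weighted_network(X: np.ndarray, sigma: float, seed: int = 0) -> np.ndarray:
    """Noisy weighted network around P = X X^T: symmetric Gaussian edge noise,
    hollow, clipped into [0, 1]."""
    X = np.asarray(X, dtype=float)
    P = X @ X.T
    n = P.shape[0]
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=(n, n))
    noise = np.triu(noise, k=1)
    A = np.clip(P + noise + noise.T, 0.0, 1.0)
    np.fill_diagonal(A, 0.0)
    return A


def random_latent_positions(n: int, d: int, seed: int = 0) -> np.ndarray:
    """Non-negative latent positions with all dot products inside [0, 1].

    Uniform draws give a probability matrix dominated by one large
    eigenvalue (the mean direction); use :func:`community_latent_positions`
    when a model with ``d`` comparable eigenvalues is needed.
    """
    rng = np.random.default_rng(seed)
    return rng.uniform(0.1, 0.9, size=(n, d)) / np.sqrt(d)


def community_latent_positions(n: int, n_communities: int = 3, seed: int = 0) -> np.ndarray:
    """Latent positions of a balanced stochastic block model.

    Vertices split into ``n_communities`` equal groups with an assortative
    block probability matrix; the resulting P = X X^T has exactly
    ``n_communities`` well-separated non-zero eigenvalues of comparable
    size, which makes the generating rank identifiable from the scree.
    """
    if n_communities != 3:
        raise DataValidationError("only the 3-community design is provided")
    B = np.array([[0.70, 0.30, 0.20], [0.30, 0.60, 0.25], [0.20, 0.25, 0.65]])
    L = np.linalg.cholesky(B)
    rng = np.random.default_rng(seed)
    comm = np.sort(np.arange(n) % n_communities)
    X = L[comm]
    # small within-community jitter keeps vertices distinct
    X *= rng.uniform(0.95, 1.0, size=(n, 1))
    return X
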