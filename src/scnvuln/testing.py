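"""Multi-way K-sample testing of per-region latent features.

For each brain region we ask whether the distribution of its latent feature
vectors differs across the cells of a chosen risk-factor combination
(genotype, sex, age bin, immunity or diet):

    H0: F_1 = ... = F_K     vs     HA: F_k != F_l for some k != l.

The K-sample problem is reduced to an independence test by one-hot encoding
group membership: the unbiased (U-centered) distance correlation between the
Euclidean distance matrix of the feature rows and that of the one-hot label
rows is both the test statistic and the reported effect size. P-values come
from the fast chi-squared approximation to the null of the unbiased
statistic, p = P(chi2_1 >= s * dcorr + 1); a permutation oracle is provided
for validation.

Two analyses avoid unobserved design cells: analysis "A" restricts the
cohort to control diet and varies {genotype, sex, age, immunity}; analysis
"B" restricts to the humanized-NOS2 line and varies {genotype, sex, age,
diet}. The battery enumerates every non-empty factor subset, optionally
repeated under one-vs-rest genotype codings.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import chi2

from .correction import holm_bonferroni
from .data import DataValidationError, GENOTYPES
from .embed import LatentStack

logger = logging.getLogger(__name__)

ANALYSIS_FACTORS = {
    "A": ("genotype", "sex", "age_bin", "immunity"),
    "B": ("genotype", "sex", "age_bin", "diet"),
}
ANALYSIS_FILTERS = {"A": {"diet": "CTRL"}, "B": {"immunity": "HN"}}

GENOTYPE_CODINGS = ("three_level", "APOE2_vs_rest", "APOE3_vs_rest", "APOE4_vs_rest")


class DegenerateGroupError(DataValidationError):
    """A group cell has fewer than 2 subjects; the test would be degenerate."""


@dataclass(frozen=True)
class TestSpec:
    """One entry of the battery: which factors, under which genotype coding."""

    __test__ = False  # not a pytest class, despite the name

    factors: tuple[str, ...]
    genotype_coding: str = "three_level"
    analysis: str = "A"

    def __post_init__(self):
        if not self.factors:
            raise DataValidationError("factor subset must be non-empty")
        if self.analysis not in ANALYSIS_FACTORS:
            raise DataValidationError(f"unknown analysis {self.analysis!r}")
        allowed = ANALYSIS_FACTORS[self.analysis]
        bad = set(self.factors) - set(allowed)
        if bad:
            raise DataValidationError(
                f"factor {sorted(bad)[0]!r} not available in analysis {self.analysis}"
            )
        if self.genotype_coding not in GENOTYPE_CODINGS:
            raise DataValidationError(f"unknown genotype coding {self.genotype_coding!r}")

    @property
    def label(self) -> str:
        return "+".join(self.factors)


def enumerate_specs(
    analysis: str = "A", codings: tuple[str, ...] = ("three_level",)
) -> list[TestSpec]:
    """All non-empty factor subsets of an analysis, per requested genotype coding.

    One-vs-rest codings are only emitted for subsets that include genotype
    (they are no-ops otherwise). With the default three-level coding the
    four factors of either analysis give 2^4 - 1 = 15 specs.
    """
    factors = ANALYSIS_FACTORS[analysis]
    specs = []
    for r in range(1, len(factors) + 1):
        for subset in itertools.combinations(factors, r):
            for coding in codings:
                if coding != "three_level" and "genotype" not in subset:
                    continue
                specs.append(TestSpec(subset, coding, analysis))
    return specs


def encode_groups(cov: pd.DataFrame, spec: TestSpec) -> tuple[np.ndarray, list[str]]:
    """One-hot encode membership in the observed cells of the factor cross-product.

    Returns (s x K one-hot matrix, cell names). Cells with no subjects are
    dropped; a cell with a single subject raises DegenerateGroupError.
    """
    labels = []
    for f in spec.factors:
        if f not in cov.columns:
            raise DataValidationError(f"covariates lack factor {f!r}")
        col = cov[f].astype(str)
        if f == "genotype" and spec.genotype_coding != "three_level":
            target = spec.genotype_coding.split("_")[0]
            col = np.where(col == target, target, "rest")
            col = pd.Series(col, index=cov.index)
        labels.append(col)
    cells = labels[0].str.cat(labels[1:], sep="|") if len(labels) > 1 else labels[0]
    counts = cells.value_counts()
    small = counts[counts < 2]
    if len(small):
        raise DegenerateGroupError(
            f"group cell {small.index[0]!r} has {small.iloc[0]} subject(s) "
            f"for factors {spec.label}"
        )
    names = sorted(counts.index)
    onehot = (cells.to_numpy()[:, None] == np.array(names)[None, :]).astype(float)
    return onehot, names


# ---------------------------------------------------------------------------
# Unbiased distance correlation and p-values
# ---------------------------------------------------------------------------

def _u_center(D: np.ndarray) -> np.ndarray:
    """U-centering of a distance matrix (unbiased variant; zero diagonal)."""
    n = D.shape[0]
    C = (
        D
        - D.sum(axis=1, keepdims=True) / (n - 2)
        - D.sum(axis=0, keepdims=True) / (n - 2)
        + D.sum() / ((n - 1) * (n - 2))
    )
    np.fill_diagonal(C, 0.0)
    return C


def _check_distance_matrix(D: np.ndarray, name: str) -> np.ndarray:
    D = np.asarray(D, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise DataValidationError(f"{name} must be square")
    if not np.allclose(D, D.T, atol=1e-10):
        raise DataValidationError(f"{name} must be symmetric")
    if np.any(np.abs(np.diag(D)) > 1e-12):
        raise DataValidationError(f"{name} must be hollow")
    if np.any(D < -1e-12):
        raise DataValidationError(f"{name} must be non-negative")
    return D


def _dcorr_from_centered(Cx: np.ndarray, Cy: np.ndarray, n: int) -> tuple[float, bool]:
    scale = n * (n - 3)
    dcov = (Cx * Cy).sum() / scale
    vx = (Cx * Cx).sum() / scale
    vy = (Cy * Cy).sum() / scale
    if vx <= 0 or vy <= 0:
        return 0.0, True
    return float(dcov / np.sqrt(vx * vy)), False


def dcorr_unbiased(Dx: np.ndarray, Dy: np.ndarray) -> float:
    """Unbiased (U-centered) distance correlation of two distance matrices.

    Equals 1 when Dx == Dy over distinct points; may be slightly negative
    under independence. A zero distance variance in either argument is a
    degenerate configuration and yields 0 by convention.
    """
    Dx = _check_distance_matrix(Dx, "Dx")
    Dy = _check_distance_matrix(Dy, "Dy")
    if Dx.shape != Dy.shape:
        raise DataValidationError("distance matrices must have the same size")
    n = Dx.shape[0]
    if n < 4:
        raise DataValidationError("unbiased dcorr requires at least 4 samples")
    stat, _ = _dcorr_from_centered(_u_center(Dx), _u_center(Dy), n)
    return stat


def chi2_pvalue(stat: float, s: int) -> float:
    """Fast chi-squared p-value for the unbiased dcorr statistic.

    Under the null, s * dcorr + 1 is approximately chi2 with 1 degree of
    freedom (an upper-tail-dominating approximation, so the test is
    conservative-to-nominal); p is its upper-tail probability.
    """
    if s < 4:
        raise DataValidationError("chi-squared approximation requires s >= 4")
    return float(chi2.sf(s * stat + 1.0, df=1))


def permutation_pvalue(
    features: np.ndarray,
    labels: np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> float:
    """Permutation p-value for the dcorr K-sample test (validation oracle).

    Label rows are permuted uniformly; p = (1 + #{perm stat >= observed})
    / (1 + n_perm). Deterministic under ``seed``.
    """
    if n_perm < 99:
        raise DataValidationError("use at least 99 permutations")
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n = features.shape[0]
    Dx = squareform(pdist(features))
    Dy = squareform(pdist(labels))
    Cx, Cy = _u_center(Dx), _u_center(Dy)
    obs, degenerate = _dcorr_from_centered(Cx, Cy, n)
    if degenerate:
        return 1.0  # all permuted statistics equal the observed one
    scale = n * (n - 3)
    vx = (Cx * Cx).sum() / scale
    vy = (Cy * Cy).sum() / scale  # invariant under row/column permutation
    denom = np.sqrt(vx * vy)
    rng = np.random.default_rng(seed)
    count = 0
    done = 0
    while done < n_perm:
        b = min(512, n_perm - done)
        idx = rng.permuted(np.tile(np.arange(n), (b, 1)), axis=1)
        Cyp = Cy[idx[:, :, None], idx[:, None, :]]
        stats = np.einsum("ij,bij->b", Cx, Cyp) / scale / denom
        count += int((stats >= obs - 1e-12).sum())
        done += b
    return (1 + count) / (1 + n_perm)


@dataclass
class TestResult:
    region_id: str
    hemisphere: str
    spec: TestSpec
    stat: float  # unbiased dcorr, floored at 0 for reporting
    p: float
    n_subjects: int
    n_groups: int
    p_adj: float = field(default=np.nan)
    reject: bool = field(default=False)


def region_test(features: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Test one region: dcorr between feature distances and one-hot label distances.

    Returns (stat, p). Degenerate inputs (zero distance variance on either
    side, e.g. identical features for all subjects) give (0.0, 1.0).
    """
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if features.shape[0] != labels.shape[0]:
        raise DataValidationError("feature rows must match label rows")
    n = features.shape[0]
    if n < 4:
        raise DataValidationError("need at least 4 subjects")
    Dx = squareform(pdist(features))
    Dy = squareform(pdist(labels))
    stat, degenerate = _dcorr_from_centered(_u_center(Dx), _u_center(Dy), n)
    if degenerate:
        return 0.0, 1.0
    return stat, chi2_pvalue(stat, n)


def run_battery(
    concat: LatentStack,
    cov: pd.DataFrame,
    analysis: str = "A",
    alpha: float = 0.05,
    codings: tuple[str, ...] = GENOTYPE_CODINGS,
    hemisphere: pd.Series | None = None,
    family: str = "per_spec",
) -> pd.DataFrame:
    """Run the full test battery: every region x every spec of an analysis.

    ``concat`` holds the per-region concatenated latent features of the
    analysis cohort; ``cov`` must be the matching covariate rows (with
    age_bin derived), in the same subject order. Holm-Bonferroni adjustment
    is applied per correction family: "per_spec" (all regions of one spec,
    matching per-panel reporting) or "global" (all rows).

    Specs whose group encoding is degenerate (a cell with < 2 subjects) are
    logged and skipped.
    """
    cov = cov.sort_values("subject_id").reset_index(drop=True)
    if list(cov["subject_id"]) != list(concat.subjects):
        raise DataValidationError("covariates do not match embedded subjects")
    filt = ANALYSIS_FILTERS[analysis]
    for factor, level in filt.items():
        if not (cov[factor] == level).all():
            raise DataValidationError(
                f"analysis {analysis} requires cohort filtered to {factor}={level}"
            )
    if family not in ("per_spec", "global"):
        raise DataValidationError(f"unknown correction family {family!r}")
    if hemisphere is None:
        hemisphere = pd.Series("", index=concat.regions)

    rows = []
    for spec in enumerate_specs(analysis, codings):
        try:
            onehot, names = encode_groups(cov, spec)
        except DegenerateGroupError as err:
            logger.warning("skipping spec %s (%s): %s", spec.label, spec.genotype_coding, err)
            continue
        for r, region in enumerate(concat.regions):
            stat, p = region_test(concat.positions[:, r, :], onehot)
            rows.append(
                {
                    "region_id": region,
                    "hemisphere": hemisphere.get(region, ""),
                    "analysis": analysis,
                    "factors": spec.label,
                    "genotype_coding": spec.genotype_coding,
                    "n_subjects": len(cov),
                    "n_groups": len(names),
                    "dcorr": max(stat, 0.0),
                    "p": p,
                }
            )
    results = pd.DataFrame(rows)
    if results.empty:
        return results
    results["p_adj"] = np.nan
    results["reject"] = False
    if family == "global":
        groups = [results.index]
    else:
        groups = [
            g.index for _, g in results.groupby(["factors", "genotype_coding"], sort=False)
        ]
    for idx in groups:
        p_adj, reject = holm_bonferroni(results.loc[idx, "p"].to_numpy(), alpha=alpha)
        results.loc[idx, "p_adj"] = p_adj
        results.loc[idx, "reject"] = reject
    return results
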