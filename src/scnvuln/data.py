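"""Input tables: atlas, regional feature tables, and subject covariates.

The pipeline consumes three plain-text inputs:

* an atlas table (TSV: ``region_id``, ``name``, ``hemisphere``) listing the
  parcellation, by default 332 regions split evenly between hemispheres;
* one regional feature table per modality (CSV: one row per subject, one
  column per region) holding region volumes in mm^3 or mean fractional
  anisotropy (FA, unitless);
* a covariate table (CSV) with the risk factors attached to each mouse:
  ApoE genotype, sex, age in months, diet, and immunity line.

Everything downstream indexes subjects in canonical (lexicographic) order
and regions in atlas order; both are enforced here at load time.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GENOTYPES = ("APOE2", "APOE3", "APOE4")
SEXES = ("F", "M")
DIETS = ("CTRL", "HFD")
IMMUNITIES = ("HN", "mNos2")
AGE_BINS = ("young", "old")
MODALITIES = ("volume", "fa")

#: factor name -> admissible levels (age_bin is derived by :func:`binarize_age`)
FACTOR_LEVELS = {
    "genotype": GENOTYPES,
    "sex": SEXES,
    "diet": DIETS,
    "immunity": IMMUNITIES,
    "age_bin": AGE_BINS,
}

COVARIATE_COLUMNS = ["subject_id", "genotype", "sex", "age_months", "diet", "immunity"]


class DataValidationError(ValueError):
    """Raised when an input table violates its schema or invariants."""


@dataclass(frozen=True)
class Atlas:
    """Brain parcellation: an ordered table of regions with hemisphere labels."""

    table: pd.DataFrame  # columns: region_id, name, hemisphere

    def __post_init__(self) -> None:
        t = self.table
        missing = {"region_id", "name", "hemisphere"} - set(t.columns)
        if missing:
            raise DataValidationError(f"atlas missing columns: {sorted(missing)}")
        if t["region_id"].duplicated().any():
            dup = t.loc[t["region_id"].duplicated(), "region_id"].iloc[0]
            raise DataValidationError(f"duplicate region_id in atlas: {dup!r}")
        bad = set(t["hemisphere"]) - {"left", "right"}
        if bad:
            raise DataValidationError(f"unknown hemisphere labels: {sorted(bad)}")

    @property
    def region_ids(self) -> list[str]:
        return list(self.table["region_id"])

    @property
    def n_regions(self) -> int:
        return len(self.table)

    def hemisphere_of(self) -> pd.Series:
        return self.table.set_index("region_id")["hemisphere"]


def default_atlas(n_regions: int = 332) -> Atlas:
    """Hemisphere-balanced synthetic atlas with ``n_regions`` regions.

    Region ids are ``roi###_left`` / ``roi###_right``; the default size matches
    the symmetrized mouse brain atlas used for the feature tables (332 regions,
    166 per hemisphere).
    """
    if n_regions % 2:
        raise DataValidationError("n_regions must be even (hemisphere-balanced)")
    rows = []
    for i in range(1, n_regions // 2 + 1):
        for hemi in ("left", "right"):
            rows.append((f"roi{i:03d}_{hemi}", f"region {i} ({hemi})", hemi))
    return Atlas(pd.DataFrame(rows, columns=["region_id", "name", "hemisphere"]))


def load_atlas(path) -> Atlas:
    return Atlas(pd.read_csv(path, sep="\t", dtype=str))


def write_atlas(atlas: Atlas, path) -> None:
    atlas.table.to_csv(path, sep="\t", index=False)


@dataclass
class RegionTable:
    """Subjects x regions matrix of one modality's regional features.

    ``values`` is indexed by subject_id (sorted) with one column per atlas
    region, in atlas order. Volumes are mm^3; FA is unitless in [0, 1].
    """

    modality: str
    values: pd.DataFrame

    @property
    def subjects(self) -> list[str]:
        return list(self.values.index)

    @property
    def regions(self) -> list[str]:
        return list(self.values.columns)


def _validate_region_values(values: pd.DataFrame, modality: str) -> None:
    if values.isna().any().any():
        col = values.columns[values.isna().any()][0]
        subj = values.index[values[col].isna()][0]
        raise DataValidationError(
            f"missing value for subject {subj!r}, region {col!r}"
        )
    neg = values < 0
    if neg.any().any():
        col = values.columns[neg.any()][0]
        subj = values.index[neg[col]][0]
        raise DataValidationError(
            f"negative value for subject {subj!r}, region {col!r}"
        )
    if modality not in MODALITIES:
        raise DataValidationError(f"unknown modality {modality!r}")


def region_table_from_frame(values: pd.DataFrame, atlas: Atlas, modality: str) -> RegionTable:
    """Validate a subjects x regions frame against the atlas and canonicalize order."""
    unknown = set(values.columns) - set(atlas.region_ids)
    if unknown:
        raise DataValidationError(f"unknown region column: {sorted(unknown)[0]!r}")
    missing = set(atlas.region_ids) - set(values.columns)
    if missing:
        raise DataValidationError(f"missing region column: {sorted(missing)[0]!r}")
    values = values[atlas.region_ids].sort_index()
    values = values.astype(float)
    _validate_region_values(values, modality)
    return RegionTable(modality=modality, values=values)


def load_region_table(path, atlas: Atlas, modality: str) -> RegionTable:
    df = pd.read_csv(path)
    if "subject_id" not in df.columns:
        raise DataValidationError("feature table must have a subject_id column")
    if df["subject_id"].duplicated().any():
        raise DataValidationError("duplicate subject_id in feature table")
    df = df.set_index("subject_id")
    return region_table_from_frame(df, atlas, modality)


def write_region_table(table: RegionTable, path) -> None:
    table.values.to_csv(path, index_label="subject_id")


def region_table_to_csv_bytes(table: RegionTable) -> bytes:
    buf = io.StringIO()
    write_region_table(table, buf)
    return buf.getvalue().encode("utf-8")


# ---------------------------------------------------------------------------
# Covariates
# ---------------------------------------------------------------------------

def validate_covariates(cov: pd.DataFrame) -> pd.DataFrame:
    """Validate covariate levels/ages and return the frame sorted by subject_id."""
    missing = set(COVARIATE_COLUMNS) - set(cov.columns)
    if missing:
        raise DataValidationError(f"covariates missing columns: {sorted(missing)}")
    if cov["subject_id"].duplicated().any():
        raise DataValidationError("duplicate subject_id in covariates")
    if cov[COVARIATE_COLUMNS].isna().any().any():
        raise DataValidationError("missing covariate values are not allowed")
    for factor in ("genotype", "sex", "diet", "immunity"):
        bad = set(cov[factor]) - set(FACTOR_LEVELS[factor])
        if bad:
            raise DataValidationError(f"unknown {factor} level: {sorted(bad)[0]!r}")
    if (cov["age_months"] <= 0).any():
        raise DataValidationError("age_months must be positive")
    return cov.sort_values("subject_id").reset_index(drop=True)


def load_covariates(path) -> pd.DataFrame:
    return validate_covariates(pd.read_csv(path))


def write_covariates(cov: pd.DataFrame, path) -> None:
    cov.to_csv(path, index=False)


def binarize_age(cov: pd.DataFrame) -> pd.DataFrame:
    """Add an ``age_bin`` column: young/old split at the genotype-wise median.

    Subjects at or below their genotype's median age are "young", strictly
    above it "old". The <= tie rule makes the split deterministic and implies
    |young| >= |old| within every genotype.
    """
    cov = validate_covariates(cov)
    out = cov.copy()
    med = cov.groupby("genotype")["age_months"].transform("median")
    out["age_bin"] = np.where(cov["age_months"] <= med, "young", "old")
    return out


def filter_cohort(cov: pd.DataFrame, predicate: dict[str, str] | None = None) -> list[str]:
    """Subjects satisfying all factor-level constraints, in canonical order.

    ``predicate`` maps factor names (genotype, sex, diet, immunity, age_bin)
    to a required level; an empty/None predicate selects the full cohort.
    """
    predicate = predicate or {}
    mask = pd.Series(True, index=cov.index)
    for factor, level in predicate.items():
        if factor not in FACTOR_LEVELS:
            raise DataValidationError(f"unknown factor {factor!r}")
        if level not in FACTOR_LEVELS[factor]:
            raise DataValidationError(f"unknown level {level!r} for factor {factor!r}")
        if factor not in cov.columns:
            raise DataValidationError(
                f"factor {factor!r} not present in covariates (derive age_bin first?)"
            )
        mask &= cov[factor] == level
    return sorted(cov.loc[mask, "subject_id"])


# ---------------------------------------------------------------------------
# The ApoE mouse study population
# ---------------------------------------------------------------------------

# Printed per-genotype margins of the 169-mouse cohort:
# (total N, females, high-fat-diet count, humanized-NOS2 count, age mean, age sd)
_POPULATION_MARGINS = {
    "APOE2": (58, 30, 15, 25, 16.12, 1.80),
    "APOE3": (54, 27, 25, 20, 15.25, 1.54),
    "APOE4": (57, 28, 15, 30, 15.84, 1.76),
}


def study_population() -> pd.DataFrame:
    """Covariate table for the 169-mouse ApoE study population.

    Per-genotype totals, female counts, high-fat-diet counts, humanized-NOS2
    (HN) counts, and age moments follow the published cohort description.
    The joint assignment of sex x diet x immunity within a genotype is not
    published; this transcription is synthetic in that respect: HN and HFD
    are assigned to leading subject indices (maximizing their overlap, since
    diet effects were only assessed within the HN line), sex alternates, and
    ages are deterministic normal quantiles with the printed mean/sd,
    shuffled by a fixed permutation so age is not confounded with the blocks.
    Marginal counts — which drive all cohort accounting — are exact.
    """
    rng = np.random.default_rng(20250812)
    rows = []
    for geno, (n, n_f, n_hfd, n_hn, age_mean, age_sd) in _POPULATION_MARGINS.items():
        ages = age_mean + age_sd * stats.norm.ppf((np.arange(n) + 0.5) / n)
        ages = np.round(rng.permutation(ages), 2)
        n_m = n - n_f
        sexes = []
        f = m = 0
        for i in range(n):
            if (i % 2 == 0 and f < n_f) or m >= n_m:
                sexes.append("F")
                f += 1
            else:
                sexes.append("M")
                m += 1
        for i in range(n):
            rows.append(
                {
                    "subject_id": f"{geno}_{i + 1:03d}",
                    "genotype": geno,
                    "sex": sexes[i],
                    "age_months": float(ages[i]),
                    "diet": "HFD" if i < n_hfd else "CTRL",
                    "immunity": "HN" if i < n_hn else "mNos2",
                }
            )
    return validate_covariates(pd.DataFrame(rows))
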