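"""End-to-end orchestration: load -> normalize -> networks -> embed -> test.

The pipeline runs one or both analyses. For each analysis the cohort is
filtered first (analysis A: control diet; analysis B: humanized-NOS2 line),
then per-subject networks are built for both modalities, jointly embedded
with the omnibus embedding, concatenated per region, and fed to the
multi-way distance-correlation battery with Holm-Bonferroni correction.

Stage outputs (networks, embeddings) can be cached to disk and re-loaded, so
staged invocations reproduce a single-shot run exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .data import (
    Atlas,
    DataValidationError,
    binarize_age,
    filter_cohort,
    load_atlas,
    load_covariates,
    load_region_table,
)
from .embed import LatentStack, concat_modalities, omni_embed_modality
from .networks import (
    NetworkStack,
    distance_networks,
    group_mean_network,
    network_contrast,
    normalize_features,
    write_network_tsv,
)
from .testing import ANALYSIS_FILTERS, GENOTYPE_CODINGS, run_battery

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    volume: str = ""
    fa: str = ""
    covariates: str = ""
    atlas: str = ""
    output_dir: str = "results"
    analysis: str = "both"  # "A", "B", or "both"
    n_elbows: int = 2
    dim: int | None = None  # fixed embedding dimension override
    omnibus_mode: str = "auto"  # dense | implicit | auto
    codings: tuple[str, ...] = GENOTYPE_CODINGS
    alpha: float = 0.05
    family: str = "per_spec"
    seed: int = 0
    export_group_matrices: bool = False

    def analyses(self) -> list[str]:
        if self.analysis == "both":
            return ["A", "B"]
        if self.analysis in ("A", "B"):
            return [self.analysis]
        raise DataValidationError(f"unknown analysis selector {self.analysis!r}")

    def validate_paths(self) -> None:
        for name in ("volume", "fa", "covariates", "atlas"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise DataValidationError(f"{name} file not found: {p!r}")


def config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name: str):
    logger.info("stage: %s", name)


def load_inputs(cfg: PipelineConfig):
    _stage("load")
    atlas = load_atlas(cfg.atlas)
    vol = load_region_table(cfg.volume, atlas, "volume")
    fa = load_region_table(cfg.fa, atlas, "fa")
    cov = binarize_age(load_covariates(cfg.covariates))
    if list(vol.subjects) != list(cov["subject_id"]) or list(fa.subjects) != list(
        cov["subject_id"]
    ):
        raise DataValidationError("feature tables and covariates list different subjects")
    return atlas, vol, fa, cov


def cohort_networks(vol, fa, cov, analysis: str):
    """Filter the cohort for one analysis and build both modality stacks."""
    _stage(f"networks ({analysis})")
    subjects = filter_cohort(cov, ANALYSIS_FILTERS[analysis])
    if len(subjects) < 4:
        raise DataValidationError(f"analysis {analysis} cohort too small: {len(subjects)}")
    cov_sel = cov[cov["subject_id"].isin(subjects)].reset_index(drop=True)
    stacks = {}
    for rt in (vol, fa):
        norm = normalize_features(
            type(rt)(rt.modality, rt.values.loc[subjects])
        )
        stacks[rt.modality] = distance_networks(norm)
    return cov_sel, stacks["volume"], stacks["fa"]


def embed_cohort(vol_nets: NetworkStack, fa_nets: NetworkStack, cfg: PipelineConfig) -> LatentStack:
    _stage("embed")
    vol_lat = omni_embed_modality(
        vol_nets, d=cfg.dim, n_elbows=cfg.n_elbows, mode=cfg.omnibus_mode
    )
    fa_lat = omni_embed_modality(
        fa_nets, d=cfg.dim, n_elbows=cfg.n_elbows, mode=cfg.omnibus_mode
    )
    logger.info("selected dimensions: volume d=%d, fa d=%d", vol_lat.d, fa_lat.d)
    return concat_modalities(vol_lat, fa_lat)


def save_embedding(concat: LatentStack, path) -> None:
    np.savez(
        path,
        positions=concat.positions,
        subjects=np.array(concat.subjects),
        regions=np.array(concat.regions),
        spectrum=concat.spectrum,
    )


def load_embedding(path) -> LatentStack:
    z = np.load(path, allow_pickle=False)
    return LatentStack(
        modality="volume+fa",
        subjects=[str(s) for s in z["subjects"]],
        regions=[str(r) for r in z["regions"]],
        positions=z["positions"],
        spectrum=z["spectrum"],
    )


def _export_group_matrices(stack: NetworkStack, cov, outdir: Path, analysis: str) -> None:
    from .data import GENOTYPES

    means = {}
    for geno in GENOTYPES:
        subjects = list(cov.loc[cov["genotype"] == geno, "subject_id"])
        if not subjects:
            continue
        means[geno] = group_mean_network(stack, subjects)
        write_network_tsv(
            means[geno],
            stack.regions,
            outdir / f"mean_{stack.modality}_{analysis}_{geno}.tsv",
        )
    genos = list(means)
    for i, ga in enumerate(genos):
        for gb in genos[i + 1 :]:
            write_network_tsv(
                network_contrast(means[ga], means[gb]),
                stack.regions,
                outdir / f"contrast_{stack.modality}_{analysis}_{ga}_minus_{gb}.tsv",
            )


def run_pipeline(cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Run the configured analyses; returns results frames and writes TSV reports."""
    cfg.validate_paths()
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    atlas, vol, fa, cov = load_inputs(cfg)
    hemi = atlas.hemisphere_of()

    results = {}
    for analysis in cfg.analyses():
        cov_sel, vol_nets, fa_nets = cohort_networks(vol, fa, cov, analysis)
        if cfg.export_group_matrices:
            _export_group_matrices(vol_nets, cov_sel, outdir, analysis)
            _export_group_matrices(fa_nets, cov_sel, outdir, analysis)
        concat = embed_cohort(vol_nets, fa_nets, cfg)
        save_embedding(concat, outdir / f"embedding_{analysis}.npz")
        _stage(f"test ({analysis})")
        res = run_battery(
            concat,
            cov_sel,
            analysis=analysis,
            alpha=cfg.alpha,
            codings=tuple(cfg.codings),
            hemisphere=hemi,
            family=cfg.family,
        )
        # report grouped by hemisphere (left panel first), then region
        res = res.sort_values(
            ["hemisphere", "region_id", "factors", "genotype_coding"]
        ).reset_index(drop=True)
        res.to_csv(outdir / f"results_{analysis}.tsv", sep="\t", index=False)
        results[analysis] = res

    manifest = {
        "config": asdict(cfg),
        "config_hash": config_hash(cfg),
        "seed": cfg.seed,
        "versions": {
            "scnvuln": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return results
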