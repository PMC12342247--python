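"""Calibration and recovery experiments on synthetic cohorts.

These routines drive the full pipeline (generate -> networks -> omnibus
embedding -> test battery -> Holm) over many seeded replicates and summarize
operating characteristics: familywise error under the null and recovery of
planted vulnerable regions. They back both the test suite and the
reproduction script.

Problem sizes default to the reference design: 40 regions, 96 subjects
(72 in the control-diet analysis cohort), 5 planted regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import binarize_age
from .embed import build_omnibus, select_dimension
from .pipeline import PipelineConfig, cohort_networks, embed_cohort
from .synth import (
    SynthConfig,
    community_latent_positions,
    generate_cohort,
    headline_config,
    sample_weighted_network,
)
from .testing import run_battery


@dataclass
class RecoveryOutcome:
    planted: list[str]
    rejected: set[str]

    @property
    def all_planted_found(self) -> bool:
        return set(self.planted) <= self.rejected

    @property
    def n_false_positives(self) -> int:
        return len(self.rejected - set(self.planted))


def _run_sex_battery(cfg: SynthConfig, alpha: float = 0.05, family: str = "per_spec"):
    vol, fa, cov, _ = generate_cohort(cfg)
    cov = binarize_age(cov)
    pcfg = PipelineConfig(alpha=alpha)
    cov_sel, vol_nets, fa_nets = cohort_networks(vol, fa, cov, "A")
    concat = embed_cohort(vol_nets, fa_nets, pcfg)
    return run_battery(
        concat, cov_sel, "A", alpha=alpha, codings=("three_level",), family=family
    )


def recovery_replicate(seed: int, alpha: float = 0.05) -> RecoveryOutcome:
    """One planted-effect replicate: does the matching (sex) spec recover
    exactly the planted regions?"""
    cfg, planted = headline_config(seed)
    res = _run_sex_battery(cfg, alpha)
    sex = res[res["factors"] == "sex"]
    rejected = set(sex.loc[sex["reject"], "region_id"])
    return RecoveryOutcome(planted=planted, rejected=rejected)


def recovery_rate(n_seeds: int = 100, base_seed: int = 0, alpha: float = 0.05):
    """Fraction of seeds recovering all 5 planted regions with at most 5%
    of null regions falsely rejected, plus the component rates."""
    n_regions = 40
    fp_allowance = int(0.05 * (n_regions - 5))
    hits = full = 0
    for i in range(n_seeds):
        out = recovery_replicate(base_seed + i, alpha)
        full += out.all_planted_found
        hits += out.all_planted_found and out.n_false_positives <= fp_allowance
    return {
        "success_rate": hits / n_seeds,
        "all_planted_rate": full / n_seeds,
        "n_seeds": n_seeds,
    }


def null_zero_rejection_rate(n_seeds: int = 100, base_seed: int = 0, alpha: float = 0.05):
    """Fraction of effect-free cohorts with zero Holm rejections anywhere in
    the 15-spec battery (empirical familywise calibration).

    Zero rejections battery-wide is what Holm guarantees (with probability
    >= 1 - alpha) when the correction family spans every test counted, so
    this experiment uses the global family; the per-panel family bounds the
    error rate within each factor combination separately, not their union.
    """
    zero = 0
    for i in range(n_seeds):
        res = _run_sex_battery(SynthConfig(seed=base_seed + i), alpha, family="global")
        zero += int(res["reject"].sum()) == 0
    return {"zero_rejection_rate": zero / n_seeds, "n_seeds": n_seeds}


def elbow_recovery_rate(
    n_seeds: int = 100,
    base_seed: int = 0,
    n_vertices: int = 30,
    rank: int = 3,
    m_networks: int = 4,
    sigma: float = 0.02,
):
    """Fraction of seeds where the scree of the omnibus spectrum of noisy
    rank-``rank`` networks selects exactly that rank.

    Uses the pipeline's second-elbow rule: the first profile-likelihood
    elbow isolates the dominant eigenvalue, the second delimits the
    remaining signal dimensions.
    """
    X = community_latent_positions(n_vertices, rank, seed=base_seed)
    hits = 0
    for i in range(n_seeds):
        nets = np.array(
            [
                sample_weighted_network(X, sigma, seed=base_seed + 1000 * i + j)
                for j in range(m_networks)
            ]
        )
        omni = build_omnibus(nets, mode="dense")
        w, _ = omni.eigpairs(k=min(40, m_networks * n_vertices))
        hits += select_dimension(np.abs(w), n_elbows=2) == rank
    return {"rank_recovery_rate": hits / n_seeds, "n_seeds": n_seeds}
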