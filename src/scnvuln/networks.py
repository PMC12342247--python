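"""Individualized structural covariance networks.

Each subject's regional feature vector (normalized volume or FA) is turned
into a dense n x n dissimilarity network whose (i, j) entry is the absolute
difference of the features of regions i and j. The networks are undirected
(symmetric), loopless (zero diagonal), and weighted in [0, 1].

Normalization makes feature vectors comparable across subjects: regional
volumes are divided by the subject's total (within-atlas) brain volume, so
each row sums to one; regional FA is divided by the subject's maximum
regional FA, so each row has maximum one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DataValidationError, RegionTable


@dataclass
class NetworkStack:
    """Per-subject distance networks for one modality, stacked (m, n, n)."""

    modality: str
    subjects: list[str]
    regions: list[str]
    data: np.ndarray

    @property
    def m(self) -> int:
        return self.data.shape[0]

    @property
    def n(self) -> int:
        return self.data.shape[1]

    def select(self, subjects) -> "NetworkStack":
        idx = [self.subjects.index(s) for s in subjects]
        return NetworkStack(self.modality, list(subjects), self.regions, self.data[idx])


def normalize_features(table: RegionTable) -> RegionTable:
    """Scale each subject's feature row into [0, 1].

    volume: divide by the subject's summed regional volume (row sums to 1);
    fa: divide by the subject's maximum regional FA (row max is 1).
    """
    values = table.values
    if table.modality == "volume":
        denom = values.sum(axis=1)
        kind = "total regional volume"
    else:
        denom = values.max(axis=1)
        kind = "maximum regional FA"
    if (denom <= 0).any():
        subj = denom.index[denom <= 0][0]
        raise DataValidationError(f"zero {kind} for subject {subj!r}")
    return RegionTable(table.modality, values.div(denom, axis=0))


def build_distance_network(features: np.ndarray) -> np.ndarray:
    """Pairwise absolute-difference network for one subject's feature vector."""
    x = np.asarray(features, dtype=float)
    if x.ndim != 1:
        raise DataValidationError("features must be a 1-D vector")
    if np.any(x < 0) or np.any(x > 1):
        raise DataValidationError("features must lie in [0, 1]; normalize first")
    return np.abs(x[:, None] - x[None, :])


def distance_networks(table: RegionTable) -> NetworkStack:
    """Build the full stack of per-subject networks from a normalized table."""
    vals = table.values.to_numpy(dtype=float)
    if np.any(vals < 0) or np.any(vals > 1):
        raise DataValidationError("feature table must be normalized into [0, 1]")
    data = np.abs(vals[:, :, None] - vals[:, None, :])
    return NetworkStack(table.modality, table.subjects, table.regions, data)


def group_mean_network(stack: NetworkStack, subjects) -> np.ndarray:
    """Element-wise mean network over a subject subset (e.g., one genotype)."""
    subjects = list(subjects)
    if not subjects:
        raise DataValidationError("empty subject set for group mean")
    missing = set(subjects) - set(stack.subjects)
    if missing:
        raise DataValidationError(f"unknown subject {sorted(missing)[0]!r}")
    idx = [stack.subjects.index(s) for s in subjects]
    return stack.data[idx].mean(axis=0)


def network_contrast(mean_a: np.ndarray, mean_b: np.ndarray) -> np.ndarray:
    """Difference of two group-mean networks (antisymmetric in its arguments)."""
    a = np.asarray(mean_a, dtype=float)
    b = np.asarray(mean_b, dtype=float)
    if a.shape != b.shape:
        raise DataValidationError(f"shape mismatch: {a.shape} vs {b.shape}")
    return a - b


def write_network_tsv(matrix: np.ndarray, regions, path) -> None:
    """Dump one square network as TSV with region ids on both axes."""
    pd.DataFrame(matrix, index=regions, columns=regions).to_csv(
        path, sep="\t", index_label="region_id"
    )


def read_network_tsv(path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col="region_id")
    return df.to_numpy(dtype=float), list(df.columns)
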