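"""Joint spectral embedding of multiple networks.

The networks for one modality are modelled as joint random dot product
graphs (JRDPG): every region (vertex) has a latent position x_i in R^d and
edge weights concentrate around the dot products X X^T. Latent positions are
estimated by adjacency spectral embedding (ASE),

    X_hat = U |S|^(1/2),

with |S| the absolute values of the top-d eigenvalues of the network by
magnitude and U the corresponding orthonormal eigenvectors.

Separately embedding each subject's network would only identify latent
positions up to an orthogonal transform per subject, making them
incomparable. The omnibus embedding solves this: stack the m networks into
the mn x mn omnibus matrix O whose (l, k) block is (A(l) + A(k)) / 2, embed
O once, and slice the result into m aligned n x d blocks, one per subject.

The embedding dimension d is chosen automatically from the scree of O's
eigenvalue magnitudes with the Zhu–Ghodsi profile log-likelihood elbow
criterion (by default the second elbow).

For large cohorts O is never materialized: an implicit linear operator
provides O v in O(m n^2) using

    (O v)_l = ( A(l) s + t ) / 2,   s = sum_k v_k,  t = sum_k A(k) v_k,

and the top of the spectrum is obtained with a Lanczos eigensolver.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sla
from scipy.sparse.linalg import LinearOperator, eigsh

from .data import DataValidationError
from .networks import NetworkStack

logger = logging.getLogger(__name__)

#: dense eigendecomposition is used up to this omnibus size (mn)
DENSE_LIMIT = 2000
#: spectrum length fed to elbow selection
MAX_SPECTRUM = 100


@dataclass
class LatentStack:
    """Per-subject latent positions from one joint embedding: (m, n, d)."""

    modality: str
    subjects: list[str]
    regions: list[str]
    positions: np.ndarray
    spectrum: np.ndarray  # |eigenvalue| magnitudes used for dimension selection

    @property
    def d(self) -> int:
        return self.positions.shape[2]


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Flip eigenvector signs so each column's largest-|.| entry is positive."""
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs


def adjacency_spectral_embedding(M: np.ndarray, d: int) -> np.ndarray:
    """ASE of a symmetric matrix: U |S|^(1/2) from the top-d eigenpairs by magnitude.

    Negative eigenvalues are kept and embedded through their absolute value.
    Deterministic up to per-column sign, which is fixed so that each column's
    largest-magnitude entry is positive.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise DataValidationError("ASE requires a square matrix")
    if not np.allclose(M, M.T, atol=1e-10):
        raise DataValidationError("ASE requires a symmetric matrix")
    n = M.shape[0]
    if not 1 <= d <= n:
        raise DataValidationError(f"embedding dimension d={d} outside [1, {n}]")
    w, V = sla.eigh((M + M.T) / 2.0)
    order = np.argsort(-np.abs(w), kind="stable")[:d]
    U = _fix_signs(V[:, order])
    return U * np.sqrt(np.abs(w[order]))


@dataclass
class OmnibusMatrix:
    """The mn x mn joint matrix of m networks, dense or as an implicit operator."""

    m: int
    n: int
    _nets: np.ndarray  # (m, n, n)
    dense: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return (self.m * self.n, self.m * self.n)

    def matvec(self, v: np.ndarray) -> np.ndarray:
        V = np.asarray(v, dtype=float).reshape(self.m, self.n)
        s = V.sum(axis=0)
        AV = np.einsum("mij,mj->mi", self._nets, V)
        t = AV.sum(axis=0)
        out = 0.5 * (np.einsum("mij,j->mi", self._nets, s) + t)
        return out.ravel()

    def operator(self) -> LinearOperator:
        return LinearOperator(self.shape, matvec=self.matvec, dtype=float)

    def eigpairs(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """Top-k eigenpairs by magnitude, sorted by decreasing |eigenvalue|."""
        mn = self.m * self.n
        if self.dense is not None:
            w, V = sla.eigh(self.dense)
        else:
            k = min(k, mn - 2)
            v0 = np.full(mn, 1.0 / np.sqrt(mn))  # deterministic Lanczos start
            w, V = eigsh(self.operator(), k=k, which="LM", v0=v0)
        order = np.argsort(-np.abs(w), kind="stable")[:k]
        return w[order], V[:, order]


def build_omnibus(stack_or_nets, mode: str = "auto") -> OmnibusMatrix:
    """Build the omnibus matrix with (l, k) block (A(l) + A(k)) / 2.

    ``mode`` is "dense", "implicit", or "auto" (dense when mn <= DENSE_LIMIT).
    Diagonal blocks equal the individual networks since (A + A) / 2 = A.
    """
    nets = stack_or_nets.data if isinstance(stack_or_nets, NetworkStack) else np.asarray(
        stack_or_nets, dtype=float
    )
    if nets.ndim != 3 or nets.shape[1] != nets.shape[2]:
        raise DataValidationError("expected an (m, n, n) stack of square networks")
    m, n, _ = nets.shape
    if mode not in ("dense", "implicit", "auto"):
        raise DataValidationError(f"unknown omnibus mode {mode!r}")
    if mode == "auto":
        mode = "dense" if m * n <= DENSE_LIMIT else "implicit"
    dense = None
    if mode == "dense":
        blocks = 0.5 * (nets[:, None] + nets[None, :])  # (m, m, n, n)
        dense = blocks.transpose(0, 2, 1, 3).reshape(m * n, m * n)
    return OmnibusMatrix(m=m, n=n, _nets=nets, dense=dense)


# ---------------------------------------------------------------------------
# Zhu–Ghodsi profile log-likelihood dimension selection
# ---------------------------------------------------------------------------

def _profile_loglik_elbow(vals: np.ndarray) -> int:
    """Single elbow: split index q maximizing the two-group Gaussian profile
    log-likelihood with a common variance (Zhu–Ghodsi criterion)."""
    p = len(vals)
    if p == 1:
        return 1
    best_q, best_ll = 1, -np.inf
    for q in range(1, p + 1):
        head, tail = vals[:q], vals[q:]
        mu1 = head.mean()
        mu2 = tail.mean() if len(tail) else 0.0
        ss = ((head - mu1) ** 2).sum() + (((tail - mu2) ** 2).sum() if len(tail) else 0.0)
        sigma2 = max(ss / p, 1e-30)
        ll = -0.5 * p * np.log(2 * np.pi * sigma2) - ss / (2 * sigma2)
        if ll > best_ll:
            best_ll, best_q = ll, q
    return best_q


def select_dimension(spectrum, n_elbows: int = 2) -> int:
    """Embedding dimension at the ``n_elbows``-th profile-log-likelihood elbow.

    ``spectrum`` is the list of eigenvalue magnitudes sorted descending.
    Successive elbows are found by recursing on the tail past the previous
    elbow; if the spectrum is exhausted before the requested elbow, the last
    elbow found is returned with a warning.
    """
    vals = np.asarray(spectrum, dtype=float)
    if vals.size == 0:
        raise DataValidationError("empty spectrum")
    if np.any(vals < 0) or np.any(np.diff(vals) > 1e-12):
        raise DataValidationError("spectrum must be non-negative and sorted descending")
    if n_elbows < 1:
        raise DataValidationError("n_elbows must be >= 1")
    offset = 0
    elbow = 0
    for i in range(n_elbows):
        tail = vals[offset:]
        if tail.size == 0:
            logger.warning(
                "requested elbow %d but spectrum exhausted after %d; returning elbow %d",
                n_elbows, i, elbow,
            )
            break
        elbow = offset + _profile_loglik_elbow(tail)
        offset = elbow
    return elbow


def omni_embed_modality(
    stack: NetworkStack,
    d: int | None = None,
    n_elbows: int = 2,
    mode: str = "auto",
) -> LatentStack:
    """Omnibus-embed one modality's networks into aligned per-subject positions.

    Builds O, takes its top-of-spectrum eigenpairs, selects d at the
    ``n_elbows``-th elbow of the magnitude scree unless ``d`` is given, and
    slices the mn x d embedding into m consecutive n x d blocks in subject
    order.
    """
    if stack.m < 2:
        raise DataValidationError("omnibus embedding requires at least 2 networks")
    omni = build_omnibus(stack, mode=mode)
    mn = omni.m * omni.n
    k = min(MAX_SPECTRUM, mn if omni.dense is not None else mn - 2)
    if d is not None:
        k = max(k, d)
    w, V = omni.eigpairs(k)
    spectrum = np.abs(w)
    if d is None:
        d = select_dimension(spectrum[: min(len(spectrum), MAX_SPECTRUM)], n_elbows)
    if d > len(w):
        raise DataValidationError(f"d={d} exceeds computed spectrum length {len(w)}")
    U = _fix_signs(V[:, :d])
    Z = U * np.sqrt(np.abs(w[:d]))
    positions = Z.reshape(omni.m, omni.n, d)
    return LatentStack(
        modality=stack.modality,
        subjects=list(stack.subjects),
        regions=list(stack.regions),
        positions=positions,
        spectrum=spectrum,
    )


def concat_modalities(vol: LatentStack, fa: LatentStack) -> LatentStack:
    """Concatenate volume-then-FA latent positions per region into one feature set.

    With the default d = 3 per modality this yields the 6-dimensional
    per-region feature vectors used by the test battery.
    """
    if vol.subjects != fa.subjects:
        raise DataValidationError("modalities embed different subjects")
    if vol.regions != fa.regions:
        raise DataValidationError("modalities embed different regions")
    positions = np.concatenate([vol.positions, fa.positions], axis=2)
    return LatentStack(
        modality="volume+fa",
        subjects=list(vol.subjects),
        regions=list(vol.regions),
        positions=positions,
        spectrum=np.concatenate([vol.spectrum[: vol.d], fa.spectrum[: fa.d]]),
    )


def latent_to_frame(stack: LatentStack):
    """Long-format export: subject_id, region_id, dim_1..dim_k, modality."""
    import pandas as pd

    m, n, d = stack.positions.shape
    rows = stack.positions.reshape(m * n, d)
    df = pd.DataFrame(rows, columns=[f"dim_{j + 1}" for j in range(d)])
    df.insert(0, "region_id", np.tile(stack.regions, m))
    df.insert(0, "subject_id", np.repeat(stack.subjects, n))
    df["modality"] = stack.modality
    return df
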