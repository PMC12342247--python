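"""Familywise error-rate control via the Holm-Bonferroni step-down procedure.

The default correction family is all regions tested under one factor
combination (one figure panel's worth of tests); a global family pooling
every test of an analysis is available through the battery's ``family``
option.
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests

from .data import DataValidationError


def holm_bonferroni(p, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Holm step-down adjustment: returns (p_adj, reject) aligned to the input.

    Sorted ascending, p_adj(k) = max_{j <= k} min(1, (m - j + 1) p(j));
    hypotheses are rejected while p_adj <= alpha.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise DataValidationError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return p_adj, reject
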