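"""Multiple-testing corrections for set-level p-values.

Two routes are provided: the standard Benjamini-Hochberg step-up q-value,
and an emulation of the median-driven q-value some enrichment tools report,
which is kept around precisely because of its pathology — it is insensitive
to how extreme an individual observed statistic is, so power can stall (or
fall) as the injected effect grows.
"""

from __future__ import annotations

import numpy as np
from statsmodels.stats.multitest import multipletests


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    ``q_i = min_{j: p_j >= p_i} (m * p_j / rank_j)``, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def gsea_median_q(
    observed: np.ndarray, perm_stats: np.ndarray
) -> np.ndarray:
    """Median-anchored q-value emulation.

    Instead of each set's own extreme observation, the pseudo-p-value for set
    ``s`` is the tail fraction of *s*'s permutation distribution evaluated at
    the **median of the observed statistics across sets**:

    ``p~_s = (1 + #{b : |T_sb| >= median_s'(|T_s'|)}) / (B + 1)``

    followed by BH step-up.  When all sets share one distribution and one
    observation this coincides with the ordinary tail p-value; when one set's
    observation is far beyond every permutation the pseudo-p stays near the
    null level, reproducing the reported insensitivity of median-based
    q-values to extreme statistics.

    Parameters
    ----------
    observed : (n_sets,) array of observed set statistics.
    perm_stats : (n_sets, B) array of the same statistic under permutation.
    """
    observed = np.abs(np.asarray(observed, dtype=float))
    perm_stats = np.abs(np.asarray(perm_stats, dtype=float))
    if perm_stats.ndim != 2 or perm_stats.shape[0] != observed.shape[0]:
        raise ValueError("perm_stats must be (n_sets, B) aligned with observed")
    anchor = np.median(observed)
    B = perm_stats.shape[1]
    pseudo_p = (1 + (perm_stats >= anchor).sum(axis=1)) / (B + 1)
    return bh_fdr(pseudo_p)
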