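"""Independent brute-force oracles shared between unit and acceptance tests.

Each function re-derives a quantity from its literal definition (explicit
running sums, explicit residual matrices, literal step-up minimisation) and
deliberately shares no code with the implementations it checks.
"""

import numpy as np


def brute_force_es(values, mask, weight_exponent):
    """Enrichment score by materialising the full running sum."""
    N = values.size
    m = int(mask.sum())
    w = np.abs(values) ** weight_exponent if weight_exponent else np.ones(N)
    hit_w = np.where(mask, w, 0.0)
    total = hit_w.sum()
    if total == 0:
        hit_w = mask.astype(float)
        total = hit_w.sum()
    steps = np.where(mask, hit_w / total, -1.0 / (N - m))
    running = np.cumsum(steps)
    mx, mn = max(running.max(), 0.0), min(running.min(), 0.0)
    return mx if mx + 1e-12 >= -mn else mn


def brute_force_step_up(p):
    """Literal step-up definition of the BH q-value."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    rank_of = {idx: r + 1 for r, idx in enumerate(order)}
    q = np.empty(m)
    for i, pi in enumerate(p):
        candidates = [m * p[j] / rank_of[j] for j in range(m) if p[j] >= pi - 1e-15]
        q[i] = min(1.0, min(candidates))
    return q


def brute_force_rho_bar(ds, rows):
    """Mean pairwise correlation of explicit linear-model residuals."""
    X = np.column_stack([np.ones(ds.n_samples), ds.labels.astype(float)])
    hat = X @ np.linalg.solve(X.T @ X, X.T)
    resid = ds.values[rows] @ (np.eye(ds.n_samples) - hat)
    C = np.corrcoef(resid)
    m = len(rows)
    return (C.sum() - m) / (m * (m - 1))
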