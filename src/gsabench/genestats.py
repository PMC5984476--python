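"""Gene-level (local) statistics shared by the set-level methods.

Every statistic compares case against control samples per gene and is signed
as case minus control.  Degenerate genes (zero variance in both classes) get
a statistic of 0 when the class means are equal, otherwise they are capped at
``+/-DEGENERATE_CAP`` with a warning — permutation machinery downstream only
needs ranks, so the cap is harmless as long as it is consistent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import digamma, polygamma

from .expression import ExpressionDataset

DEGENERATE_CAP = 1e6


@dataclass
class GeneStatVector:
    """Per-gene statistic aligned with an :class:`ExpressionDataset`."""

    gene_ids: list[str]
    values: np.ndarray
    statistic_name: str
    df: np.ndarray | float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.gene_ids) != self.values.shape[0]:
            raise ValueError("gene_ids and values lengths differ")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("gene statistics must be finite")

    def __len__(self) -> int:
        return len(self.gene_ids)


def _class_moments(values: np.ndarray, case: np.ndarray):
    n1, n0 = int(case.sum()), int((~case).sum())
    x1, x0 = values[:, case], values[:, ~case]
    m1, m0 = x1.mean(axis=1), x0.mean(axis=1)
    v1 = x1.var(axis=1, ddof=1)
    v0 = x0.var(axis=1, ddof=1)
    return n1, n0, m1, m0, v1, v0


def _require_two_per_class(ds: ExpressionDataset) -> np.ndarray:
    case = ds.case_mask
    if case.sum() < 2 or (~case).sum() < 2:
        raise ValueError("each class needs at least 2 samples")
    return case


def _guard_degenerate(num: np.ndarray, t: np.ndarray, bad: np.ndarray) -> np.ndarray:
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} gene(s) with zero variance in both classes",
            stacklevel=3,
        )
        t = t.copy()
        t[bad] = np.sign(num[bad]) * DEGENERATE_CAP
    return np.clip(t, -DEGENERATE_CAP, DEGENERATE_CAP)


def student_t(ds: ExpressionDataset) -> GeneStatVector:
    """Pooled-variance two-sample t per gene (case minus control)."""
    case = _require_two_per_class(ds)
    n1, n0, m1, m0, v1, v0 = _class_moments(ds.values, case)
    sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / (n1 + n0 - 2)
    num = m1 - m0
    bad = sp2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / np.sqrt(sp2 * (1 / n1 + 1 / n0))
    t = np.where(bad & (num == 0), 0.0, t)
    t = _guard_degenerate(num, np.nan_to_num(t, nan=0.0), bad & (num != 0))
    return GeneStatVector(ds.gene_ids, t, "student_t", df=float(n1 + n0 - 2))


def welch_t(ds: ExpressionDataset) -> GeneStatVector:
    """Unequal-variance t with Welch-Satterthwaite degrees of freedom."""
    case = _require_two_per_class(ds)
    n1, n0, m1, m0, v1, v0 = _class_moments(ds.values, case)
    num = m1 - m0
    se2 = v1 / n1 + v0 / n0
    bad = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / np.sqrt(se2)
        df = se2**2 / (
            (v1 / n1) ** 2 / (n1 - 1) + (v0 / n0) ** 2 / (n0 - 1)
        )
    t = np.where(bad & (num == 0), 0.0, t)
    t = _guard_degenerate(num, np.nan_to_num(t, nan=0.0), bad & (num != 0))
    df = np.nan_to_num(df, nan=float(n1 + n0 - 2))
    return GeneStatVector(ds.gene_ids, t, "welch_t", df=df)


def signal_to_noise(
    ds: ExpressionDataset, sd_floor: bool = True
) -> GeneStatVector:
    """Signal-to-noise ratio: (mean_case - mean_control)/(sd_case + sd_control).

    Each class standard deviation is floored at ``max(0.2 * |class mean|,
    0.2)`` — the convention of the reference GSEA ranking metric — unless
    ``sd_floor`` is disabled, in which case zero denominators are capped.
    """
    case = _require_two_per_class(ds)
    n1, n0, m1, m0, v1, v0 = _class_moments(ds.values, case)
    s1, s0 = np.sqrt(v1), np.sqrt(v0)
    if sd_floor:
        s1 = np.maximum(s1, np.maximum(0.2 * np.abs(m1), 0.2))
        s0 = np.maximum(s0, np.maximum(0.2 * np.abs(m0), 0.2))
    num = m1 - m0
    den = s1 + s0
    bad = den == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        snr = num / den
    snr = np.where(bad & (num == 0), 0.0, snr)
    snr = _guard_degenerate(num, np.nan_to_num(snr, nan=0.0), bad & (num != 0))
    return GeneStatVector(ds.gene_ids, snr, "signal_to_noise")


def _fit_variance_prior(s2: np.ndarray, dg: float) -> tuple[float, float]:
    """Estimate (d0, s0^2) by moment matching on log sample variances.

    Under the scaled-chi-squared model, ``log s2`` has mean
    ``log s0^2 + digamma(dg/2) - log(dg/2)`` and excess variance
    ``trigamma(d0/2)`` beyond the sampling term ``trigamma(dg/2)``; the
    trigamma equation is inverted by Newton iteration.
    """
    positive = s2[s2 > 0]
    if positive.size < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(positive)
    e = z - digamma(dg / 2) + np.log(dg / 2)
    excess = z.var(ddof=1) - polygamma(1, dg / 2)
    if excess <= 0:
        # no evidence of variance heterogeneity: infinite prior df
        return np.inf, float(np.exp(e.mean()))
    # solve trigamma(d0/2) = excess for d0
    y = 0.5 + 1 / excess  # starting value from trigamma(x) ~ 1/x + 1/(2x^2)
    for _ in range(50):
        tri = polygamma(1, y)
        delta = tri * (1 - tri / excess) / polygamma(2, y)
        y += delta
        if abs(delta) < 1e-10 * y:
            break
    d0 = 2 * float(y)
    s0_sq = float(np.exp(e.mean() + digamma(y) - np.log(y)))
    return d0, s0_sq


def moderated_t(
    ds: ExpressionDataset, d0: float | None = None, s0_sq: float | None = None
) -> GeneStatVector:
    """Empirical-Bayes moderated t: residual variances shrunk to a prior.

    Each gene's pooled variance ``s_g^2`` (``d_g`` residual df) is replaced by
    the posterior value ``(d0*s0^2 + d_g*s_g^2)/(d0 + d_g)`` with the prior
    ``(d0, s0^2)`` estimated from the marginal spread of log variances across
    genes; the statistic is referred to ``d0 + d_g`` degrees of freedom.
    Passing ``d0``/``s0_sq`` overrides estimation (``d0=0`` recovers the
    ordinary t, ``d0=inf`` full shrinkage to the common variance).
    """
    case = _require_two_per_class(ds)
    n1, n0, m1, m0, v1, v0 = _class_moments(ds.values, case)
    dg = float(n1 + n0 - 2)
    if dg < 2:
        raise ValueError("need at least 2 residual degrees of freedom")
    sp2 = ((n1 - 1) * v1 + (n0 - 1) * v0) / dg
    if d0 is None or s0_sq is None:
        d0_hat, s0_hat = _fit_variance_prior(sp2, dg)
        d0 = d0_hat if d0 is None else d0
        s0_sq = s0_hat if s0_sq is None else s0_sq
    if np.isinf(d0):
        s2_post = np.full_like(sp2, s0_sq)
    else:
        s2_post = (d0 * s0_sq + dg * sp2) / (d0 + dg)
    num = m1 - m0
    bad = s2_post == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = num / np.sqrt(s2_post * (1 / n1 + 1 / n0))
    t = np.where(bad & (num == 0), 0.0, t)
    t = _guard_degenerate(num, np.nan_to_num(t, nan=0.0), bad & (num != 0))
    return GeneStatVector(ds.gene_ids, t, "moderated_t", df=d0 + dg)


_METRICS = {
    "student_t": student_t,
    "welch_t": welch_t,
    "snr": signal_to_noise,
    "signal_to_noise": signal_to_noise,
    "moderated_t": moderated_t,
}


def compute_gene_stats(ds: ExpressionDataset, metric: str) -> GeneStatVector:
    """Dispatch a gene-level statistic by name."""
    try:
        fn = _METRICS[metric]
    except KeyError:
        raise ValueError(
            f"unknown metric {metric!r}; choose from {sorted(set(_METRICS))}"
        ) from None
    return fn(ds)
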