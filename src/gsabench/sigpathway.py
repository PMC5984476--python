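"""Competitive set testing by normalized sums of gene-level statistics.

The set statistic is the mean of the member genes' t-statistics, normalized
against the gene population to a z-like value ``z = sqrt(m) * (raw - mu) /
sigma`` with ``mu``/``sigma`` the mean and standard deviation of all gene
statistics.  Significance of the normalized statistic comes from gene
resampling (random m-gene subsets; the competitive null) by default; a
phenotype-permutation (self-contained) variant and a Wilcoxon rank-sum set
statistic are available behind flags.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .base import GSAModel, SetResults, empirical_p
from .genesets import GeneSet
from .genestats import GeneStatVector, compute_gene_stats

__all__ = ["SigPathway", "set_statistic", "normalize_statistic"]


def set_statistic(gene_stats: GeneStatVector, gene_set: GeneSet) -> float:
    """Equal-weight set statistic: mean of the member genes' statistics."""
    members = set(gene_set.genes)
    mask = np.fromiter(
        (g in members for g in gene_stats.gene_ids), bool, count=len(gene_stats)
    )
    if not mask.any():
        raise ValueError("set has no genes in the statistic universe")
    return float(gene_stats.values[mask].mean())


def normalize_statistic(
    raw: float, set_size: int, population: GeneStatVector | np.ndarray
) -> float:
    """Size-adjusted z: ``sqrt(m) * (raw - mu) / sigma``.

    ``mu`` and ``sigma`` are the mean and SD of all gene-level statistics,
    i.e. the moments of the gene-sampling null for a single gene.
    """
    values = population.values if isinstance(population, GeneStatVector) else population
    values = np.asarray(values, dtype=float)
    if set_size >= values.size:
        raise ValueError("set size must be smaller than the population")
    sigma = values.std(ddof=1)
    if sigma == 0:
        raise ValueError("degenerate population: zero spread of gene statistics")
    return float(np.sqrt(set_size) * (raw - values.mean()) / sigma)


class SigPathway(GSAModel):
    """Normalized mean-statistic competitive model.

    Parameters
    ----------
    metric : str
        Gene-level statistic (default ``"student_t"``).
    B : int
        Number of resamples/permutations.
    mode : {"gene_resampling", "phenotype_permutation"}
        Competitive (default) vs self-contained null.
    set_stat : {"mean", "ranksum"}
        Equal-weight mean (default) or Wilcoxon rank-sum set statistic.
    """

    min_set_size = 1
    max_set_size = 10_000

    def __init__(
        self,
        dataset,
        collection,
        metric: str = "student_t",
        B: int = 1000,
        mode: str = "gene_resampling",
        set_stat: str = "mean",
    ):
        super().__init__(dataset, collection)
        dataset._require_labels()
        if mode not in ("gene_resampling", "phenotype_permutation"):
            raise ValueError("unknown mode")
        if set_stat not in ("mean", "ranksum"):
            raise ValueError("set_stat must be 'mean' or 'ranksum'")
        if B < 1:
            raise ValueError("B must be >= 1")
        self.metric = metric
        self.B = int(B)
        self.mode = mode
        self.set_stat = set_stat

    def _raw_and_z(self, values: np.ndarray, membership: np.ndarray):
        m = membership.sum(axis=1)
        if self.set_stat == "mean":
            raw = (membership @ values) / m
            mu, sigma = values.mean(), values.std(ddof=1)
            z = np.sqrt(m) * (raw - mu) / sigma
        else:
            ranks = rankdata(values)
            raw = membership @ ranks
            N = values.size
            mu = m * (N + 1) / 2.0
            sigma = np.sqrt(m * (N - m) * (N + 1) / 12.0)
            z = (raw - mu) / sigma
        return raw, z

    def fit(self, seed: int | None = 0) -> SetResults:
        rng = np.random.default_rng(seed)
        stats = compute_gene_stats(self.dataset, self.metric)
        values = stats.values
        membership = self.membership_matrix()
        m = membership.sum(axis=1)
        N = values.size
        raw, z = self._raw_and_z(values, membership)
        if self.mode == "gene_resampling":
            # one shared pool of index permutations; a set of size m_i reads
            # its null membership off the first m_i entries of each row
            perms = np.argsort(rng.random((self.B, N)), axis=1)
            if self.set_stat == "mean":
                csum = np.cumsum(values[perms], axis=1)
                mu, sigma = values.mean(), values.std(ddof=1)
                null_z = np.empty((len(m), self.B))
                for si, mi in enumerate(m):
                    null_raw = csum[:, mi - 1] / mi
                    null_z[si] = np.sqrt(mi) * (null_raw - mu) / sigma
            else:
                ranks = rankdata(values)
                csum = np.cumsum(ranks[perms], axis=1)
                null_z = np.empty((len(m), self.B))
                for si, mi in enumerate(m):
                    mu_i = mi * (N + 1) / 2.0
                    sig_i = np.sqrt(mi * (N - mi) * (N + 1) / 12.0)
                    null_z[si] = (csum[:, mi - 1] - mu_i) / sig_i
        else:
            cols = []
            for _ in range(self.B):
                ds_b = self.dataset.with_labels(rng.permutation(self.dataset.labels))
                cols.append(compute_gene_stats(ds_b, self.metric).values)
            null_z = np.empty((len(m), self.B))
            for b, vals_b in enumerate(cols):
                _, zb = self._raw_and_z(vals_b, membership)
                null_z[:, b] = zb
        p = empirical_p(z, null_z, "two-sided")
        table = pd.DataFrame(
            {
                "set": self.collection.names,
                "size": m,
                "raw_statistic": raw,
                "statistic": z,
                "p_value": p,
            }
        )
        res = SetResults(self, table)
        res.perm_scores = null_z  # aligned with collection order
        return res
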