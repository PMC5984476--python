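"""Weighted running-sum enrichment testing (GSEA).

Genes are ranked by a differential-expression metric (signal-to-noise by
default); for each gene set a running sum walks the ranked list, rising by
``|r_i|^p / sum_hits |r_j|^p`` at set members ("hits") and falling by
``1/(N-m)`` at non-members.  The enrichment score (ES) is the running-sum
value of maximal absolute deviation from zero, signed, measuring whether the
set clusters toward either end of the list.  Significance comes from
permutation: phenotype-label permutation tests the self-contained null,
random gene relabelling the competitive null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .base import GSAModel, SetResults, empirical_p
from .expression import ExpressionDataset
from .genesets import GeneSet
from .genestats import compute_gene_stats
from .multiplicity import gsea_median_q

__all__ = ["RankedList", "rank_genes", "enrichment_score", "GSEA", "GSEAResults"]


@dataclass
class RankedList:
    """Genes ordered by descending statistic, ties broken by gene id."""

    gene_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.gene_ids) != self.values.size:
            raise ValueError("gene_ids and values lengths differ")

    def __len__(self) -> int:
        return self.values.size


def _rank_order(gene_ids: np.ndarray, values: np.ndarray) -> np.ndarray:
    # lexsort: primary key descending value, secondary ascending gene id
    return np.lexsort((gene_ids, -values))


def rank_genes(ds: ExpressionDataset, metric: str = "snr") -> RankedList:
    """Rank all genes by a gene-level metric, descending."""
    stats = compute_gene_stats(ds, metric)
    order = _rank_order(np.asarray(stats.gene_ids), stats.values)
    return RankedList(
        [stats.gene_ids[i] for i in order], stats.values[order]
    )


def _hit_weights(abs_vals: np.ndarray, p: float) -> np.ndarray:
    return np.ones_like(abs_vals) if p == 0 else np.abs(abs_vals) ** p


def _es_from_hit_positions(
    w: np.ndarray, pos: np.ndarray, N: int
) -> np.ndarray:
    """Signed max-deviation ES from hit positions in the ranked list.

    ``w`` holds the (already exponentiated) weights in ranked order and
    ``pos`` the (B, m) hit positions.  The running sum attains its extremes
    only at a hit (peaks) or just before one (troughs), so the score can be
    read off the m hit positions without materialising the N-long walk.
    When the maximal positive and negative deviations tie in magnitude the
    positive one is returned.
    """
    pos = np.sort(pos, axis=1)
    m = pos.shape[1]
    hw = w[pos] if w.ndim == 1 else np.take_along_axis(w, pos, axis=1)
    totals = hw.sum(axis=1, keepdims=True)
    degenerate = totals[:, 0] == 0
    if np.any(degenerate):
        # all hit weights zero (e.g. flat statistics): fall back to 1/m steps
        hw[degenerate] = 1.0
        totals = hw.sum(axis=1, keepdims=True)
    cumw = np.cumsum(hw, axis=1) / totals
    miss = (pos - np.arange(m)) / (N - m)
    peaks = cumw - miss
    troughs = (cumw - hw / totals) - miss
    max_dev = np.maximum(peaks.max(axis=1), 0.0)
    min_dev = np.minimum(troughs.min(axis=1), 0.0)
    # tolerance keeps the preferred-positive tie rule stable under rounding
    return np.where(max_dev + 1e-12 >= -min_dev, max_dev, min_dev)


def _es_batch(
    ranked_values: np.ndarray, hit_masks: np.ndarray, weight_exponent: float
) -> np.ndarray:
    """ES for every row of boolean ``hit_masks`` aligned to the ranked order."""
    N = ranked_values.size
    m = hit_masks.sum(axis=1)
    if np.any((m == 0) | (m == N)):
        raise ValueError("gene set must be a proper non-empty subset of the list")
    w = _hit_weights(np.abs(ranked_values), weight_exponent)
    out = np.empty(hit_masks.shape[0])
    for size in np.unique(m):
        rows = np.flatnonzero(m == size)
        pos = np.vstack([np.flatnonzero(hit_masks[r]) for r in rows])
        out[rows] = _es_from_hit_positions(w, pos, N)
    return out


def enrichment_score(
    ranked: RankedList, gene_set: GeneSet, weight_exponent: float = 1.0
) -> float:
    """Signed enrichment score of one gene set on a ranked list."""
    members = set(gene_set.genes)
    hits = np.fromiter(
        (g in members for g in ranked.gene_ids), bool, count=len(ranked)
    )
    return float(_es_batch(ranked.values, hits[None, :], weight_exponent)[0])


class GSEA(GSAModel):
    """Enrichment-score model over a gene-set collection.

    Parameters
    ----------
    dataset, collection
        Labeled expression data and the knowledge base (restricted to the
        dataset's universe automatically).
    metric : str
        Gene-level ranking metric (default ``"snr"``).
    permutation : {"phenotype", "gene"}
        ``"phenotype"`` permutes class labels (self-contained null);
        ``"gene"`` resamples set membership on the fixed ranked list
        (competitive null).
    B : int
        Number of permutations.  In phenotype mode, if the number of
        distinct label assignments does not exceed ``B``, the null is
        enumerated exactly (with a warning).
    weight_exponent : float
        Hit-weight exponent ``p``; 0 gives the unweighted (classic
        Kolmogorov-Smirnov) form, 1 the standard weighted form.
    """

    def __init__(
        self,
        dataset,
        collection,
        metric: str = "snr",
        permutation: str = "phenotype",
        B: int = 1000,
        weight_exponent: float = 1.0,
    ):
        super().__init__(dataset, collection)
        if permutation not in ("phenotype", "gene"):
            raise ValueError("permutation must be 'phenotype' or 'gene'")
        if B < 1:
            raise ValueError("B must be >= 1")
        dataset._require_labels()
        sizes = [len(s) for s in self.collection]
        if max(sizes) >= dataset.n_genes:
            raise ValueError("a gene set spans the whole universe; ES undefined")
        self.metric = metric
        self.permutation = permutation
        self.B = int(B)
        self.weight_exponent = float(weight_exponent)

    # -- internals -----------------------------------------------------------

    def _observed(self) -> tuple[np.ndarray, np.ndarray]:
        """Ranked statistic values and per-set hit masks in ranked order."""
        stats = compute_gene_stats(self.dataset, self.metric)
        order = _rank_order(np.asarray(stats.gene_ids), stats.values)
        ranked_values = stats.values[order]
        hits = self.membership_matrix()[:, order]
        return ranked_values, hits

    def _label_permutations(self, rng: np.random.Generator):
        labels = self.dataset.labels
        n, n1 = labels.size, int(labels.sum())
        exact = comb(n, n1) <= self.B
        if exact:
            warnings.warn(
                f"B={self.B} >= {comb(n, n1)} distinct label assignments; "
                "using exact enumeration",
                stacklevel=2,
            )
            for cases in combinations(range(n), n1):
                lab = np.zeros(n, dtype=int)
                lab[list(cases)] = 1
                yield lab
        else:
            for _ in range(self.B):
                yield rng.permutation(labels)

    def fit(self, seed: int | None = 0) -> "GSEAResults":
        rng = np.random.default_rng(seed)
        ranked_values, hits = self._observed()
        es_obs = _es_batch(ranked_values, hits, self.weight_exponent)
        n_sets, N = hits.shape
        member_idx = [np.flatnonzero(row) for row in self.membership_matrix()]
        if self.permutation == "phenotype":
            exact = comb(self.dataset.n_samples, int(self.dataset.labels.sum())) <= self.B
            gene_id_arr = np.asarray(self.dataset.gene_ids)
            inv_orders, weights = [], []
            for lab in self._label_permutations(rng):
                perm_ds = self.dataset.with_labels(lab)
                stats = compute_gene_stats(perm_ds, self.metric)
                order = _rank_order(gene_id_arr, stats.values)
                inv_order = np.empty(N, dtype=int)
                inv_order[order] = np.arange(N)
                inv_orders.append(inv_order)
                weights.append(
                    _hit_weights(np.abs(stats.values[order]), self.weight_exponent)
                )
            inv_orders = np.vstack(inv_orders)  # (B or n_exact, N)
            weights = np.vstack(weights)
            perm_es = np.vstack(
                [
                    _es_from_hit_positions(weights, inv_orders[:, idx], N)
                    for idx in member_idx
                ]
            )  # (n_sets, B or n_exact)
            if exact:
                # the enumeration includes the observed assignment, so the
                # plain proportion is already bounded away from zero
                count = (np.abs(perm_es) >= np.abs(es_obs)[:, None]).sum(axis=1)
                p = count / perm_es.shape[1]
            else:
                p = empirical_p(es_obs, perm_es, "two-sided")
        else:
            # competitive: random m-subsets of the fixed ranked list, one
            # shared pool of index permutations across sets
            perms = np.argsort(rng.random((self.B, N)), axis=1)
            perm_es = np.empty((n_sets, self.B))
            w_full = _hit_weights(np.abs(ranked_values), self.weight_exponent)
            for si in range(n_sets):
                m = int(hits[si].sum())
                perm_es[si] = _es_from_hit_positions(w_full, perms[:, :m], N)
            p = empirical_p(es_obs, perm_es, "two-sided")
        table = pd.DataFrame(
            {
                "set": self.collection.names,
                "size": hits.sum(axis=1),
                "statistic": es_obs,
                "p_value": p,
            }
        )
        return GSEAResults(self, table, perm_es)


class GSEAResults(SetResults):
    """GSEA results; keeps the permutation ES matrix for q-value variants."""

    def __init__(self, model, table, perm_scores):
        super().__init__(model, table)
        self.perm_scores = perm_scores

    @property
    def q_median(self) -> np.ndarray:
        """Median-anchored q-value emulation (the pathological variant)."""
        return gsea_median_q(
            self.table["statistic"].to_numpy(), self.perm_scores
        )
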