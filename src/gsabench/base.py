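"""Shared Model/Results scaffolding for the set-level methods.

Every method follows the same pattern: a model object is constructed from an
:class:`ExpressionDataset` and a :class:`GeneSetCollection` plus method
options, and ``fit(seed)`` returns a :class:`SetResults` carrying one row per
gene set (statistic, p-value, BH q-value) with a ``summary()`` table.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .expression import ExpressionDataset
from .genesets import GeneSetCollection
from .multiplicity import bh_fdr


def empirical_p(
    observed: np.ndarray, null: np.ndarray, alternative: str = "two-sided"
) -> np.ndarray:
    """Add-one-smoothed empirical p-value of ``observed`` against ``null``.

    ``null`` has shape (n, B) or (B,); ``alternative`` picks the tail:
    ``"two-sided"`` counts ``|null| >= |observed|``, ``"greater"`` counts
    ``null >= observed``, ``"less"`` counts ``null <= observed``.
    The add-one estimator ``(1 + count) / (B + 1)`` never returns 0.
    """
    observed = np.atleast_1d(np.asarray(observed, dtype=float))
    null = np.asarray(null, dtype=float)
    if null.ndim == 1:
        null = np.broadcast_to(null, (observed.size, null.size))
    B = null.shape[1]
    obs = observed[:, None]
    if alternative == "two-sided":
        count = (np.abs(null) >= np.abs(obs)).sum(axis=1)
    elif alternative == "greater":
        count = (null >= obs).sum(axis=1)
    elif alternative == "less":
        count = (null <= obs).sum(axis=1)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return (1 + count) / (B + 1)


class SetResults:
    """Per-gene-set results of one method on one dataset.

    Attributes
    ----------
    table : pandas.DataFrame
        One row per set with at least ``set``, ``size``, ``statistic``,
        ``p_value`` and ``q_value`` columns, in collection order.
    """

    def __init__(self, model, table: pd.DataFrame):
        if "q_value" not in table.columns and "p_value" in table.columns:
            table = table.assign(q_value=bh_fdr(table["p_value"].to_numpy()))
        self.model = model
        self.table = table.reset_index(drop=True)

    @property
    def set_names(self) -> list[str]:
        return self.table["set"].tolist()

    @property
    def p_values(self) -> np.ndarray:
        return self.table["p_value"].to_numpy()

    @property
    def q_values(self) -> np.ndarray:
        return self.table["q_value"].to_numpy()

    def significant(self, alpha: float = 0.05, on: str = "q") -> pd.DataFrame:
        col = {"q": "q_value", "p": "p_value"}[on]
        return self.table[self.table[col] < alpha]

    def summary(self, top: int | None = 10) -> str:
        name = type(self.model).__name__
        ds = self.model.dataset
        ordered = self.table.sort_values("p_value")
        if top is not None:
            ordered = ordered.head(top)
        lines = [
            f"{name} results: {len(self.table)} gene sets on "
            f"{ds.n_genes} genes x {ds.n_samples} samples",
            ordered.to_string(index=False, float_format=lambda v: f"{v:.4g}"),
        ]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<{type(self).__name__}: {len(self.table)} sets, "
            f"{int((self.q_values < 0.05).sum())} with q<0.05>"
        )


class GSAModel:
    """Base class for set-level association models.

    Subclasses store method options at construction and implement
    ``fit(seed) -> SetResults``.  The collection is restricted to the
    dataset's gene universe and size-filtered up front so every method sees
    the same effective knowledge base.
    """

    min_set_size: int = 1
    max_set_size: int | None = None

    def __init__(self, dataset: ExpressionDataset, collection: GeneSetCollection):
        self.dataset = dataset
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            restricted = collection.restrict_to_universe(dataset.gene_ids)
            self.collection = restricted.filter_by_size(
                self.min_set_size, self.max_set_size
            )
        if len(self.collection) == 0:
            raise ValueError("no usable gene sets after universe restriction")
        self._membership = None

    def membership_matrix(self) -> np.ndarray:
        """(n_sets, n_genes) boolean membership, cached."""
        if self._membership is None:
            lookup = {g: i for i, g in enumerate(self.dataset.gene_ids)}
            mat = np.zeros((len(self.collection), self.dataset.n_genes), dtype=bool)
            for si, s in enumerate(self.collection):
                mat[si, [lookup[g] for g in s.genes]] = True
            self._membership = mat
        return self._membership

    def fit(self, seed: int | None = 0) -> SetResults:  # pragma: no cover
        raise NotImplementedError
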