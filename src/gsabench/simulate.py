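"""Semi-synthetic expression simulation: signal injection, bootstrap, nulls.

The simulation recipe starts from a preprocessed (quantile-normalized,
gene-centered) baseline whose case/control signal is exactly zero but whose
gene-gene correlation structure is real.  Differential expression is then
*injected* into a chosen target gene set: a proportion ``pi`` of its genes is
selected at random and every case sample of a selected gene is shifted by
``tau * sd_g``, where ``sd_g`` is the gene's across-sample standard deviation
before injection.  Power is estimated over class-balanced bootstrap
replicates of the injected dataset; false positive rates come from three null
constructions (label permutation, iid normal, tau = 0).

A block-correlated Gaussian generator (:func:`generate_baseline`) stands in
for real microarray baselines so the whole pipeline runs with no downloads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .expression import ExpressionDataset

__all__ = [
    "SimulationSpec",
    "BaselineSpec",
    "inject_signal",
    "bootstrap_replicate",
    "null_permuted_labels",
    "null_iid_normal",
    "generate_baseline",
    "random_collection",
    "spawn_rngs",
]


def spawn_rngs(seed: int | np.random.SeedSequence, n: int) -> list[np.random.Generator]:
    """Spawn ``n`` independent, individually reproducible random streams."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


@dataclass
class SimulationSpec:
    """One cell of the benchmark grid.

    ``pi`` is the proportion of target-set genes altered (0 < pi <= 1) and
    ``tau`` the effect size in units of per-gene standard deviation.
    """

    target_set: str
    pi: float
    tau: float
    n_replicates: int = 100
    n_cases: int | None = None
    n_controls: int | None = None
    seed: int = 0
    direction: str = "up"

    def __post_init__(self) -> None:
        if not 0 < self.pi <= 1:
            raise ValueError("pi must be in (0, 1]")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")


@dataclass
class BaselineSpec:
    """Synthetic correlated baseline standing in for a real dataset.

    Genes are organised into exchangeable (compound-symmetric) correlation
    blocks: within a block every gene pair has population correlation
    ``within_block_rho``; blocks are mutually independent and genes beyond
    the listed blocks are fully independent.  Marginals are standard normal.

    Defaults give a desk-scale study: 1,000 genes, 40 samples (20 cases +
    20 controls), 20 blocks of 25 correlated genes at rho = 0.3.
    """

    n_genes: int = 1000
    n_samples: int = 40
    n_cases: int | None = None
    block_sizes: list[int] = field(default_factory=lambda: [25] * 20)
    within_block_rho: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples < 2:
            raise ValueError("need at least 1 gene and 2 samples")
        if sum(self.block_sizes) > self.n_genes:
            raise ValueError("block sizes exceed the gene count")
        if not 0 <= self.within_block_rho < 1:
            raise ValueError("within_block_rho must lie in [0, 1)")
        if self.n_cases is None:
            self.n_cases = self.n_samples // 2
        if not 0 < self.n_cases < self.n_samples:
            raise ValueError("n_cases must leave both classes non-empty")


def inject_signal(
    ds: ExpressionDataset,
    gene_set,
    pi: float,
    tau: float,
    direction: str = "up",
    rng: np.random.Generator | int | None = None,
    altered_genes: list[str] | None = None,
) -> tuple[ExpressionDataset, list[str]]:
    """Shift case samples of a random subset of a gene set by ``tau * sd_g``.

    Exactly ``round(pi * m)`` genes (at least 1) are drawn uniformly from the
    ``m``-gene set; each drawn gene's case values move by ``+tau*sd_g``
    (``direction="up"``) or ``-tau*sd_g``, with ``sd_g`` the across-all-sample
    standard deviation computed before injection.  Controls and unselected
    genes are untouched.  ``altered_genes`` overrides the random draw (used by
    the harness to nest subsets across pi values).

    Returns the new dataset and the list of altered genes.
    """
    ds._require_labels()
    if tau < 0:
        raise ValueError("tau must be non-negative")
    if not 0 < pi <= 1:
        raise ValueError("pi must be in (0, 1]")
    genes = list(gene_set.genes) if hasattr(gene_set, "genes") else list(gene_set)
    genes = [g for g in genes if g in set(ds.gene_ids)]
    if not genes:
        raise ValueError("gene set has no genes in the dataset")
    if altered_genes is None:
        rng = np.random.default_rng(rng)
        n_alter = max(1, round(pi * len(genes)))
        altered_genes = list(rng.choice(genes, size=n_alter, replace=False))
    rows = ds.gene_index(altered_genes)
    values = ds.values.copy()
    sd = values[rows].std(axis=1, ddof=1)
    sign = 1.0 if direction == "up" else -1.0
    values[np.ix_(rows, np.flatnonzero(ds.case_mask))] += sign * tau * sd[:, None]
    return ds.with_values(values), list(altered_genes)


def bootstrap_replicate(
    ds: ExpressionDataset, rng: np.random.Generator | int | None = None
) -> ExpressionDataset:
    """Resample samples with replacement within each phenotype class.

    The replicate keeps the original class sizes and label layout (each
    column position is filled by a random member of its own class), so the
    case-control balance of the source design is preserved exactly.  Sample
    ids are suffixed with the draw index to stay unique.
    """
    ds._require_labels()
    rng = np.random.default_rng(rng)
    idx = np.empty(ds.n_samples, dtype=int)
    for cls in (0, 1):
        members = np.flatnonzero(ds.labels == cls)
        idx[members] = rng.choice(members, size=members.size, replace=True)
    sample_ids = [f"{ds.sample_ids[j]}.b{k}" for k, j in enumerate(idx)]
    return ExpressionDataset(ds.values[:, idx], ds.gene_ids, sample_ids, ds.labels)


def null_permuted_labels(
    ds: ExpressionDataset, rng: np.random.Generator | int | None = None
) -> ExpressionDataset:
    """Null construction 1: permute class labels, leave expression untouched."""
    ds._require_labels()
    rng = np.random.default_rng(rng)
    return ds.with_labels(rng.permutation(ds.labels))


def null_iid_normal(
    n_genes: int,
    n_cases: int,
    n_controls: int,
    rng: np.random.Generator | int | None = None,
) -> ExpressionDataset:
    """Null construction 2: iid standard-normal expression, random labels."""
    if min(n_genes, n_cases, n_controls) < 1:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(rng)
    n = n_cases + n_controls
    values = rng.standard_normal((n_genes, n))
    labels = rng.permutation(np.r_[np.ones(n_cases, int), np.zeros(n_controls, int)])
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    sample_ids = [f"S{j:03d}" for j in range(n)]
    return ExpressionDataset(values, gene_ids, sample_ids, labels)


def generate_baseline(spec: BaselineSpec) -> ExpressionDataset:
    """Draw a block-correlated Gaussian baseline dataset.

    Within a block of size ``b`` the construction
    ``x = sqrt(rho) * z_block + sqrt(1-rho) * eps`` gives exchangeable
    pairwise correlation ``rho`` with standard-normal marginals; remaining
    genes are independent.  Labels assign the first ``n_cases`` samples to
    the case class (the labels carry no signal — the matrix is generated
    independently of them).
    """
    rng = np.random.default_rng(spec.seed)
    rho = spec.within_block_rho
    values = rng.standard_normal((spec.n_genes, spec.n_samples))
    row = 0
    for b in spec.block_sizes:
        shared = rng.standard_normal(spec.n_samples)
        values[row : row + b] = (
            np.sqrt(rho) * shared + np.sqrt(1 - rho) * values[row : row + b]
        )
        row += b
    labels = np.r_[
        np.ones(spec.n_cases, int), np.zeros(spec.n_samples - spec.n_cases, int)
    ]
    gene_ids = [f"G{i:05d}" for i in range(spec.n_genes)]
    sample_ids = [f"S{j:03d}" for j in range(spec.n_samples)]
    return ExpressionDataset(values, gene_ids, sample_ids, labels)


def random_collection(
    universe,
    n_sets: int = 50,
    size_range: tuple[int, int] = (10, 100),
    rng: np.random.Generator | int | None = None,
    prefix: str = "SET",
):
    """Draw a collection of random gene sets from a gene universe.

    Set sizes are uniform on ``size_range`` (inclusive) and members are
    sampled without replacement per set — the knowledge-base analogue of the
    null benchmark, where no set is enriched by construction.
    """
    from .genesets import GeneSet, GeneSetCollection

    universe = list(universe)
    lo, hi = size_range
    if not 1 <= lo <= hi <= len(universe):
        raise ValueError("size_range must satisfy 1 <= lo <= hi <= |universe|")
    rng = np.random.default_rng(rng)
    sets = []
    for k in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        genes = tuple(rng.choice(universe, size=size, replace=False))
        sets.append(GeneSet(f"{prefix}{k:03d}", "random", genes))
    return GeneSetCollection(sets)
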