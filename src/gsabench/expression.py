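"""Expression-matrix data model, I/O, and baseline preprocessing.

The preprocessing pipeline applied to a baseline dataset before signal
injection is quantile normalization followed by per-gene centering.  Quantile
normalization forces every sample (column) onto the common distribution of
across-sample mean order statistics; centering each gene at zero then erases
whatever case/control signal the baseline carried while leaving the gene-gene
correlation structure untouched — which is exactly what a semi-synthetic
simulation needs: realistic correlation, known (zero) signal.

Probe-level background correction (RMA) is intentionally out of scope: this
module ingests already-summarized genes-by-samples matrices (plain TSV or
GCT), with phenotype labels supplied as CLS or two-column text.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata


class ExpressionDataset:
    """Genes x samples real matrix with optional binary phenotype labels.

    Parameters
    ----------
    values : (n_genes, n_samples) float array
    gene_ids, sample_ids : sequences of unique identifiers
    labels : sequence of {0, 1}, optional
        Phenotype per sample; 1 = case, 0 = control.  When present, both
        classes must be non-empty.
    """

    def __init__(
        self,
        values: np.ndarray,
        gene_ids: Sequence[str],
        sample_ids: Sequence[str],
        labels: Sequence[int] | None = None,
    ):
        values = np.asarray(values, dtype=float)
        if values.ndim != 2:
            raise ValueError("values must be 2-D (genes x samples)")
        if values.shape != (len(gene_ids), len(sample_ids)):
            raise ValueError("values shape does not match id lengths")
        if not np.all(np.isfinite(values)):
            raise ValueError("expression matrix contains missing/non-finite values")
        self.gene_ids = list(gene_ids)
        self.sample_ids = list(sample_ids)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        self.values = values
        if labels is not None:
            labels = np.asarray(labels, dtype=int)
            if labels.shape != (values.shape[1],):
                raise ValueError("labels length does not match sample count")
            if not set(np.unique(labels)) <= {0, 1}:
                raise ValueError("labels must be binary 0/1")
            if len(np.unique(labels)) < 2:
                raise ValueError("both phenotype classes must be non-empty")
        self.labels = labels

    # -- basic introspection -------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def case_mask(self) -> np.ndarray:
        self._require_labels()
        return self.labels == 1

    @property
    def control_mask(self) -> np.ndarray:
        self._require_labels()
        return self.labels == 0

    def _require_labels(self) -> None:
        if self.labels is None:
            raise ValueError("dataset has no phenotype labels")

    def gene_index(self, genes: Sequence[str]) -> np.ndarray:
        """Row indices of the given gene ids (raises on unknown ids)."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not in dataset") from None

    def with_values(self, values: np.ndarray) -> "ExpressionDataset":
        return ExpressionDataset(values, self.gene_ids, self.sample_ids, self.labels)

    def with_labels(self, labels: Sequence[int]) -> "ExpressionDataset":
        return ExpressionDataset(self.values, self.gene_ids, self.sample_ids, labels)

    def copy(self) -> "ExpressionDataset":
        return ExpressionDataset(
            self.values.copy(),
            self.gene_ids,
            self.sample_ids,
            None if self.labels is None else self.labels.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, labels: Sequence[int] | None = None
    ) -> "ExpressionDataset":
        return cls(
            frame.to_numpy(dtype=float),
            [str(g) for g in frame.index],
            [str(s) for s in frame.columns],
            labels,
        )

    def __repr__(self) -> str:
        lab = "unlabeled" if self.labels is None else (
            f"{int(self.case_mask.sum())} cases/{int(self.control_mask.sum())} controls"
        )
        return (
            f"<ExpressionDataset {self.n_genes} genes x "
            f"{self.n_samples} samples, {lab}>"
        )


# -- I/O ----------------------------------------------------------------------


def read_expression(path: str | Path, format: str | None = None) -> ExpressionDataset:
    """Read a genes-by-samples matrix from TSV or GCT.

    TSV: header row of sample ids, first column gene ids.  GCT: the standard
    ``#1.2`` two-header-line dialect with NAME/Description columns.
    Duplicate gene ids are rejected (multi-mapping probes are expected to be
    removed upstream), as are non-numeric or missing cells.
    """
    path = Path(path)
    if format is None:
        format = "gct" if path.suffix.lower() == ".gct" else "tsv"
    if format == "gct":
        with path.open() as fh:
            version = fh.readline().strip()
            if not version.startswith("#1.2"):
                raise ValueError(f"unsupported GCT version line {version!r}")
            dims = fh.readline().split()
            n_genes, n_samples = int(dims[0]), int(dims[1])
            frame = pd.read_csv(fh, sep="\t", index_col=0)
        frame = frame.drop(columns=frame.columns[0])  # Description column
        if frame.shape != (n_genes, n_samples):
            raise ValueError(
                f"GCT dims {frame.shape} disagree with header ({n_genes}, {n_samples})"
            )
    elif format == "tsv":
        frame = pd.read_csv(path, sep="\t", index_col=0)
    else:
        raise ValueError(f"unknown expression format {format!r}")
    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene ids: {dups[:5]}")
    try:
        values = frame.to_numpy(dtype=float)
    except ValueError:
        obj = frame.apply(pd.to_numeric, errors="coerce")
        gi, si = map(int, np.argwhere(obj.isna().to_numpy())[0])
        raise ValueError(
            f"non-numeric cell at gene {frame.index[gi]!r}, "
            f"sample {frame.columns[si]!r}"
        ) from None
    if np.isnan(values).any():
        gi, si = map(int, np.argwhere(np.isnan(values))[0])
        raise ValueError(
            f"missing value at gene {frame.index[gi]!r}, sample {frame.columns[si]!r}"
        )
    return ExpressionDataset.from_dataframe(frame)


def write_expression(
    ds: ExpressionDataset, path: str | Path, format: str = "tsv"
) -> None:
    path = Path(path)
    if format == "tsv":
        ds.to_frame().to_csv(path, sep="\t", index_label="gene_id")
    elif format == "gct":
        with path.open("w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{ds.n_genes}\t{ds.n_samples}\n")
            frame = ds.to_frame()
            frame.insert(0, "Description", "na")
            frame.to_csv(fh, sep="\t", index_label="NAME")
    else:
        raise ValueError(f"unknown expression format {format!r}")


def read_labels(
    path: str | Path,
    format: str | None = None,
    sample_ids: Sequence[str] | None = None,
) -> np.ndarray:
    """Read binary phenotype labels from CLS or two-column TSV.

    CLS labels are positional (three-line dialect: counts, class names,
    per-sample tokens); the first class named on the ``#`` line is coded 0.
    Two-column files (``sample_id<TAB>class``) are aligned against
    ``sample_ids`` and require every matrix sample to appear exactly once.
    """
    path = Path(path)
    if format is None:
        format = "cls" if path.suffix.lower() == ".cls" else "two_column_tsv"
    if format == "cls":
        lines = [ln for ln in path.read_text().splitlines() if ln.strip()]
        if len(lines) < 3:
            raise ValueError("CLS file must have 3 lines")
        n_samples, n_classes = int(lines[0].split()[0]), int(lines[0].split()[1])
        if n_classes != 2:
            raise ValueError(f"expected 2 classes, CLS declares {n_classes}")
        class_names = lines[1].lstrip("#").split()
        tokens = lines[2].split()
        if len(tokens) != n_samples:
            raise ValueError("CLS token count disagrees with declared sample count")
        uniq = list(dict.fromkeys(tokens))
        if len(uniq) != 2:
            raise ValueError(f"expected 2 classes, found {len(uniq)}")
        # tokens may be 0/1 or the class names themselves
        code = {tok: i for i, tok in enumerate(uniq)}
        if set(uniq) <= {"0", "1"}:
            code = {"0": 0, "1": 1}
        elif set(uniq) == set(class_names):
            code = {class_names[0]: 0, class_names[1]: 1}
        labels = np.array([code[t] for t in tokens], dtype=int)
    elif format == "two_column_tsv":
        table = pd.read_csv(path, sep="\t", header=None, names=["sample", "cls"])
        table["sample"] = table["sample"].astype(str)
        classes = sorted(table["cls"].astype(str).unique())
        if len(classes) != 2:
            raise ValueError(f"expected 2 classes, found {len(classes)}")
        mapping = dict(zip(table["sample"], table["cls"].astype(str)))
        if sample_ids is None:
            sample_ids = list(table["sample"])
        missing = [s for s in sample_ids if s not in mapping]
        if missing:
            raise ValueError(f"samples without labels: {missing[:5]}")
        labels = np.array(
            [classes.index(mapping[s]) for s in sample_ids], dtype=int
        )
    else:
        raise ValueError(f"unknown label format {format!r}")
    if len(np.unique(labels)) < 2:
        raise ValueError("all samples fall in one class")
    return labels


def write_labels(
    labels: Sequence[int], path: str | Path, format: str = "cls",
    sample_ids: Sequence[str] | None = None,
) -> None:
    labels = np.asarray(labels, dtype=int)
    path = Path(path)
    if format == "cls":
        with path.open("w") as fh:
            fh.write(f"{len(labels)} 2 1\n")
            fh.write("# control case\n")
            fh.write(" ".join(str(int(v)) for v in labels) + "\n")
    elif format == "two_column_tsv":
        if sample_ids is None:
            raise ValueError("two-column label files need sample_ids")
        with path.open("w") as fh:
            for s, v in zip(sample_ids, labels):
                fh.write(f"{s}\t{int(v)}\n")
    else:
        raise ValueError(f"unknown label format {format!r}")


# -- preprocessing ------------------------------------------------------------


def quantile_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Force every sample onto the common reference distribution.

    The reference is the across-sample mean of the column order statistics;
    each column's values are replaced by the reference value at their rank.
    Tied values within a column receive the mean of the reference values at
    their tied ranks (dense/average tie policy).
    """
    if ds.n_samples < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    x = ds.values
    # order statistics are per column (sample); reference = row means of them
    reference = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        ranks = rankdata(x[:, j], method="average")  # 1-based, ties averaged
        lo = np.floor(ranks - 1).astype(int)
        hi = np.ceil(ranks - 1).astype(int)
        out[:, j] = 0.5 * (reference[lo] + reference[hi])
    return ds.with_values(out)


def center_genes(ds: ExpressionDataset) -> ExpressionDataset:
    """Center every gene (row) at mean zero.

    Removes all existing case/control signal while leaving gene-gene Pearson
    correlations and per-gene standard deviations unchanged.
    """
    return ds.with_values(ds.values - ds.values.mean(axis=1, keepdims=True))


def preprocess(ds: ExpressionDataset) -> ExpressionDataset:
    """Canonical baseline preprocessing: quantile-normalize, then center.

    Centering last guarantees the zero-signal invariant (normalization leaves
    nonzero row means behind).
    """
    return center_genes(quantile_normalize(ds))
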