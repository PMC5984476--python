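"""Benchmark orchestration: power grids, null false-positive suites, overlap.

Power for a (pi, tau) cell is the proportion of class-balanced bootstrap
replicates of the injected dataset in which the target set is declared
significant at the chosen threshold; false positive rates come from three
null constructions (label permutation, iid normal, tau = 0) as the per-set
rejection proportion across replicates, summarised by the median and
quartiles over sets.

Everything is deterministic under a master seed: independent random streams
are spawned per (cell, replicate, method), so replicates are order- and
worker-independent units of work.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .base import SetResults
from .camera import Camera
from .expression import ExpressionDataset, center_genes, preprocess
from .genesets import GeneSetCollection, overlap_proportion
from .gsea import GSEA
from .safe import SAFE, SafeConfig
from .sigpathway import SigPathway
from .simulate import (
    BaselineSpec,
    bootstrap_replicate,
    generate_baseline,
    inject_signal,
    null_iid_normal,
    null_permuted_labels,
)

__all__ = [
    "MethodRunner",
    "PowerStudy",
    "PowerResults",
    "NullSuite",
    "NullSuiteResults",
    "overlap_power",
    "default_runners",
]

NULL_TYPES = ("label_permutation", "iid_normal", "tau_zero")


@dataclass
class MethodRunner:
    """A named, configured method: builds a model on a dataset and fits it.

    ``criterion`` selects which column drives significance calls for this
    method ("q" for BH q-values — the default for pipelines that include an
    FDR step — or "p" for raw permutation p-values).
    """

    name: str
    model_cls: type
    kwargs: dict = field(default_factory=dict)
    criterion: str = "q"

    def run(self, ds: ExpressionDataset, coll: GeneSetCollection, seed) -> SetResults:
        return self.model_cls(ds, coll, **self.kwargs).fit(seed)


def default_runners(B: int = 200) -> list[MethodRunner]:
    """The benchmark's default method roster at a given resampling depth."""
    return [
        MethodRunner("gsea_phenotype", GSEA, {"permutation": "phenotype", "B": B}),
        MethodRunner("gsea_gene", GSEA, {"permutation": "gene", "B": B}),
        MethodRunner("safe_wilcoxon", SAFE, {"config": SafeConfig(B=B)}),
        MethodRunner(
            "safe_avediff", SAFE, {"config": SafeConfig(global_stat="avediff", B=B)}
        ),
        MethodRunner(
            "safe_pearson", SAFE, {"config": SafeConfig(global_stat="pearson", B=B)}
        ),
        MethodRunner("safe_fet", SAFE, {"config": SafeConfig(global_stat="fet")}),
        MethodRunner("sigpathway", SigPathway, {"B": B}),
        MethodRunner("camera", Camera, {}),
    ]


def _rejections(res: SetResults, alpha: float, on: str) -> pd.Series:
    col = {"q": "q_value", "p": "p_value"}[on]
    return pd.Series(
        (res.table[col] < alpha).to_numpy(), index=res.table["set"], dtype=float
    )


class PowerStudy:
    """Power benchmark over a (pi, tau) grid for one target gene set.

    Signal is injected once per cell (the altered subsets are *nested*
    across pi — each cell alters the first ``round(pi * m)`` genes of one
    master shuffle of the target set — so power comparisons across pi are
    not confounded by which genes happened to be drawn); bootstrap
    replicates of the injected dataset are then scored by every method.
    """

    def __init__(
        self,
        baseline: ExpressionDataset | BaselineSpec,
        collection: GeneSetCollection,
        target: str,
        runners: Sequence[MethodRunner],
        pis: Sequence[float] = (0.05, 0.1, 0.25, 0.5, 1.0),
        taus: Sequence[float] = (0.25, 0.5, 1.0, 2.0, 10.0),
        n_replicates: int = 100,
        alpha: float = 0.05,
        direction: str = "up",
        do_preprocess: bool = True,
    ):
        if isinstance(baseline, BaselineSpec):
            baseline = generate_baseline(baseline)
        baseline._require_labels()
        self.baseline = preprocess(baseline) if do_preprocess else baseline
        self.collection = collection.restrict_to_universe(self.baseline.gene_ids)
        if target not in self.collection:
            raise ValueError(f"target set {target!r} not in the collection")
        if len(self.collection[target]) == 0:
            raise ValueError("target set has no genes in the baseline universe")
        self.target = target
        self.runners = list(runners)
        self.pis = list(pis)
        self.taus = list(taus)
        self.n_replicates = int(n_replicates)
        self.alpha = float(alpha)
        self.direction = direction

    def fit(self, seed: int = 0) -> "PowerResults":
        root = np.random.SeedSequence(seed)
        subset_rng = np.random.default_rng(root.spawn(1)[0])
        target_genes = list(self.collection[self.target].genes)
        master_order = list(subset_rng.permutation(target_genes))
        cells = [(pi, tau) for pi in self.pis for tau in self.taus]
        cell_seeds = root.spawn(len(cells))
        rows = []
        per_set: dict[tuple[str, float, float], pd.Series] = {}
        for (pi, tau), cell_ss in zip(cells, cell_seeds):
            n_alter = max(1, round(pi * len(master_order)))
            altered = master_order[:n_alter]
            injected, _ = inject_signal(
                self.baseline,
                self.collection[self.target],
                pi,
                tau,
                self.direction,
                altered_genes=altered,
            )
            rep_seeds = cell_ss.spawn(self.n_replicates)
            hits_p = {r.name: [] for r in self.runners}
            hits_q = {r.name: [] for r in self.runners}
            for rep_ss in rep_seeds:
                boot_ss, *method_ss = rep_ss.spawn(1 + len(self.runners))
                rep = bootstrap_replicate(injected, np.random.default_rng(boot_ss))
                for runner, mss in zip(self.runners, method_ss):
                    res = runner.run(rep, self.collection, mss)
                    rej_p = _rejections(res, self.alpha, "p")
                    rej_q = _rejections(res, self.alpha, "q")
                    hits_p[runner.name].append(rej_p)
                    hits_q[runner.name].append(rej_q)
            for runner in self.runners:
                props_p = pd.concat(hits_p[runner.name], axis=1).mean(axis=1)
                props_q = pd.concat(hits_q[runner.name], axis=1).mean(axis=1)
                chosen = props_q if runner.criterion == "q" else props_p
                per_set[(runner.name, pi, tau)] = chosen
                power = float(chosen.loc[self.target])
                se = float(
                    np.sqrt(power * (1 - power) / self.n_replicates)
                )
                rows.append(
                    {
                        "method": runner.name,
                        "criterion": runner.criterion,
                        "set": self.target,
                        "pi": pi,
                        "tau": tau,
                        "n_replicates": self.n_replicates,
                        "power": power,
                        "power_p": float(props_p.loc[self.target]),
                        "power_q": float(props_q.loc[self.target]),
                        "se": se,
                    }
                )
        return PowerResults(self, pd.DataFrame(rows), per_set)


class PowerResults:
    """Power table plus per-set rejection proportions for overlap analysis."""

    def __init__(self, model: PowerStudy, power_table: pd.DataFrame, per_set):
        self.model = model
        self.power_table = power_table
        self.per_set_rejections = per_set

    def power(self, method: str, pi: float, tau: float) -> float:
        t = self.power_table
        row = t[(t["method"] == method) & (t["pi"] == pi) & (t["tau"] == tau)]
        if row.empty:
            raise KeyError((method, pi, tau))
        return float(row["power"].iloc[0])

    def overlap_table(
        self, method: str, pi: float, tau: float, denominator: str = "secondary",
        min_overlap: int = 1,
    ) -> pd.DataFrame:
        """Secondary-set power against overlap with the target."""
        props = self.per_set_rejections[(method, pi, tau)]
        return overlap_power(
            props, self.model.collection, self.model.target, denominator, min_overlap
        )

    def summary(self) -> str:
        wide = self.power_table.pivot_table(
            index=["method", "pi"], columns="tau", values="power"
        )
        return (
            f"Power grid for target {self.model.target!r} "
            f"({self.model.n_replicates} bootstrap replicates, "
            f"alpha={self.model.alpha}):\n" + wide.to_string(float_format="%.3f")
        )


def overlap_power(
    rejection_proportions: pd.Series,
    collection: GeneSetCollection,
    target: str,
    denominator: str = "secondary",
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Join per-set rejection proportions with overlap against the target.

    The target itself is excluded; sets whose intersection with the target
    is smaller than ``min_overlap`` genes are dropped (default keeps every
    set that overlaps at all; pass 0 to keep disjoint sets too).
    """
    tgt = collection[target]
    rows = []
    for s in collection:
        if s.name == target or len(s) == 0:
            continue
        inter = len(set(s.genes) & set(tgt.genes))
        if inter < min_overlap:
            continue
        rows.append(
            {
                "set": s.name,
                "overlap": overlap_proportion(s, tgt, denominator),
                "n_overlap": inter,
                "power": float(rejection_proportions.get(s.name, np.nan)),
            }
        )
    return pd.DataFrame(rows, columns=["set", "overlap", "n_overlap", "power"])


class NullSuite:
    """False-positive-rate suite over the three null constructions."""

    def __init__(
        self,
        baseline: ExpressionDataset | BaselineSpec,
        collection: GeneSetCollection,
        runners: Sequence[MethodRunner],
        null_types: Sequence[str] = NULL_TYPES,
        n_replicates: int = 50,
        alpha: float = 0.05,
        do_preprocess: bool = True,
    ):
        if isinstance(baseline, BaselineSpec):
            baseline = generate_baseline(baseline)
        baseline._require_labels()
        self.baseline = preprocess(baseline) if do_preprocess else baseline
        self.collection = collection.restrict_to_universe(self.baseline.gene_ids)
        if len(self.collection) == 0:
            raise ValueError("no gene sets to evaluate")
        unknown = set(null_types) - set(NULL_TYPES)
        if unknown:
            raise ValueError(f"unknown null types {sorted(unknown)}")
        self.runners = list(runners)
        self.null_types = list(null_types)
        self.n_replicates = int(n_replicates)
        self.alpha = float(alpha)

    def _null_dataset(self, null_type: str, rng: np.random.Generator):
        ds = self.baseline
        if null_type == "label_permutation":
            return null_permuted_labels(ds, rng)
        if null_type == "iid_normal":
            n1 = int(ds.case_mask.sum())
            out = null_iid_normal(ds.n_genes, n1, ds.n_samples - n1, rng)
            # keep the baseline's gene ids so the collection applies
            return ExpressionDataset(out.values, ds.gene_ids, out.sample_ids, out.labels)
        if null_type == "tau_zero":
            # tau = 0 injects nothing; replicate variation via the bootstrap
            return bootstrap_replicate(center_genes(ds), rng)
        raise ValueError(null_type)

    def fit(self, seed: int = 0) -> "NullSuiteResults":
        root = np.random.SeedSequence(seed)
        type_seeds = root.spawn(len(self.null_types))
        per_set_rows = []
        summary_rows = []
        for null_type, tss in zip(self.null_types, type_seeds):
            rep_seeds = tss.spawn(self.n_replicates)
            hits = {r.name: [] for r in self.runners}
            for rep_ss in rep_seeds:
                data_ss, *method_ss = rep_ss.spawn(1 + len(self.runners))
                ds = self._null_dataset(null_type, np.random.default_rng(data_ss))
                for runner, mss in zip(self.runners, method_ss):
                    res = runner.run(ds, self.collection, mss)
                    # null FPR is defined on the raw p-value at alpha
                    hits[runner.name].append(_rejections(res, self.alpha, "p"))
            for runner in self.runners:
                props = pd.concat(hits[runner.name], axis=1).mean(axis=1)
                for set_name, fpr in props.items():
                    per_set_rows.append(
                        {
                            "method": runner.name,
                            "null_type": null_type,
                            "set": set_name,
                            "fpr": float(fpr),
                        }
                    )
                q1, med, q3 = np.percentile(props.to_numpy(), [25, 50, 75])
                summary_rows.append(
                    {
                        "method": runner.name,
                        "null_type": null_type,
                        "median_fpr": float(med),
                        "q1_fpr": float(q1),
                        "q3_fpr": float(q3),
                        "n_sets": int(props.size),
                        "n_replicates": self.n_replicates,
                    }
                )
        return NullSuiteResults(
            self, pd.DataFrame(summary_rows), pd.DataFrame(per_set_rows)
        )


class NullSuiteResults:
    """Median/quartile FPR per (method, null type) plus per-set detail."""

    def __init__(self, model: NullSuite, table: pd.DataFrame, per_set: pd.DataFrame):
        self.model = model
        self.table = table
        self.per_set = per_set

    def median_fpr(self, method: str, null_type: str | None = None) -> float:
        t = self.table[self.table["method"] == method]
        if null_type is not None:
            t = t[t["null_type"] == null_type]
        if t.empty:
            raise KeyError((method, null_type))
        return float(t["median_fpr"].median())

    def summary(self) -> str:
        wide = self.table.pivot_table(
            index="method", columns="null_type", values="median_fpr"
        )
        return (
            f"Median per-set FPR at alpha={self.model.alpha} "
            f"({self.model.n_replicates} replicates):\n"
            + wide.to_string(float_format="%.3f")
        )
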