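"""Minimal plots mirroring the benchmark's standard figures."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt


def plot_null_fpr(results, ax=None):
    """Median per-set FPR with quartile bars, per method and null type."""
    table = results.table
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    methods = table["method"].unique()
    null_types = table["null_type"].unique()
    width = 0.8 / len(null_types)
    for k, nt in enumerate(null_types):
        sub = table[table["null_type"] == nt].set_index("method").reindex(methods)
        x = [i + k * width for i in range(len(methods))]
        yerr = [
            sub["median_fpr"] - sub["q1_fpr"],
            sub["q3_fpr"] - sub["median_fpr"],
        ]
        ax.bar(x, sub["median_fpr"], width=width, yerr=yerr, capsize=2, label=nt)
    ax.axhline(results.model.alpha, ls="--", c="k", lw=0.8)
    ax.set_xticks([i + 0.4 - width / 2 for i in range(len(methods))])
    ax.set_xticklabels(methods, rotation=45, ha="right")
    ax.set_ylabel("median per-set FPR")
    ax.legend(fontsize=8)
    return ax


def plot_power_grid(results, ax=None):
    """Power against tau, one line per (method, pi)."""
    table = results.power_table
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4.5))
    for (method, pi), sub in table.groupby(["method", "pi"]):
        sub = sub.sort_values("tau")
        ax.errorbar(
            sub["tau"], sub["power"], yerr=2 * sub["se"],
            marker="o", ms=3, lw=1, label=f"{method}, pi={pi:g}",
        )
    ax.set_xscale("log")
    ax.set_xlabel("effect size tau (per-gene SD units)")
    ax.set_ylabel("power")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=7)
    return ax


def plot_overlap_power(overlap_table, ax=None, label=None):
    """Secondary-set power against overlap proportion with the target."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(overlap_table["overlap"], overlap_table["power"], s=12, label=label)
    ax.set_xlabel("overlap proportion with target")
    ax.set_ylabel("power")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    if label:
        ax.legend(fontsize=8)
    return ax
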