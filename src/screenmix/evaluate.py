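"""Benchmark metrics and the simulation grid harness.

Given simulated screens with truth labels, computes the standard
screen-benchmarking metrics: ROC-AUC of the gene ranking, true positive
rate at an estimated global FDR threshold, and the empirical FDR of the
same call set.
"""

from __future__ import annotations

import time
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .baselines import mw_screen
from .mixture import QPrior, call_at_fdr, fit_screen
from .simulate import FullSimConfig, simulate_full

__all__ = [
    "roc_auc",
    "tpr_empfdr_at_threshold",
    "run_method",
    "benchmark_grid",
    "plot_benchmark",
]


def roc_auc(scores, truth) -> float:
    """ROC-AUC with higher score = more interesting; ties get half credit."""
    truth = np.asarray(truth, dtype=int)
    if truth.min() == truth.max():
        raise ValueError("need both positive and negative genes for ROC-AUC")
    return float(roc_auc_score(truth, np.asarray(scores, dtype=float)))


def tpr_empfdr_at_threshold(
    called: Iterable[str], truth: pd.Series
) -> tuple[float, float | None]:
    """TPR and empirical FDR of a call set against per-gene truth labels.

    Empirical FDR is ``None`` when nothing is called.
    """
    called = set(called)
    true_genes = set(truth.index[truth == 1])
    n_true = len(true_genes)
    if n_true == 0:
        raise ValueError("truth contains no positive genes")
    tpr = len(called & true_genes) / n_true
    emp_fdr = (len(called - true_genes) / len(called)) if called else None
    return tpr, emp_fdr


def run_method(
    method: str,
    guide_table: pd.DataFrame,
    truth: pd.Series,
    fdr_threshold: float = 0.1,
    *,
    null: str = "auto",
    q_prior: QPrior | None = None,
    seed: int = 0,
) -> dict:
    """Run one scoring method on one screen and measure it against truth."""
    t0 = time.perf_counter()
    if method in ("hiermix", "normhiermix"):
        fit, scores = fit_screen(
            guide_table,
            null="normal-em" if method == "normhiermix" else null,
            q_prior=q_prior or QPrior(),
            seed=seed,
        )
        ranking = scores.set_index("gene_id")["locfdr"]
        called = call_at_fdr(scores, fdr_threshold)["gene_id"]
        score_for_auc = -ranking.reindex(truth.index)
    elif method == "mw":
        res = mw_screen(guide_table, direction="depleted")
        ranking = res.set_index("gene_id")["p_value"]
        called = res.loc[res["bh_fdr"] <= fdr_threshold, "gene_id"]
        score_for_auc = -ranking.reindex(truth.index)
    else:
        raise ValueError(f"unknown method {method!r}")
    runtime = time.perf_counter() - t0
    auc = roc_auc(score_for_auc.to_numpy(), truth.to_numpy())
    tpr, emp_fdr = tpr_empfdr_at_threshold(called, truth)
    return {
        "method": method,
        "roc_auc": auc,
        "tpr_at_fdr": tpr,
        "empirical_fdr": emp_fdr,
        "n_called": int(len(called)),
        "runtime_s": runtime,
    }


def benchmark_grid(
    methods: Sequence[str] = ("hiermix", "mw"),
    efficiencies: Sequence[float] = (0.3, 0.6, 0.95),
    guides_per_gene: Sequence[int] = (3, 5, 10),
    n_reps: int = 10,
    fdr_threshold: float = 0.1,
    seed: int = 0,
    base_config: FullSimConfig | None = None,
    progress=None,
) -> pd.DataFrame:
    """Run methods over a (efficiency x guides-per-gene) simulation grid.

    Returns a tidy per-replicate DataFrame; aggregate with
    ``df.groupby(["method", "efficiency", "guides_per_gene"]).mean()``.
    All randomness descends from ``seed`` via a SeedSequence spawn per
    replicate, so the output is byte-identical across reruns.
    """
    base = base_config or FullSimConfig()
    ss = np.random.SeedSequence(seed)
    rows = []
    for eff in efficiencies:
        for k in guides_per_gene:
            for rep in range(n_reps):
                child = ss.spawn(1)[0]
                rep_seed = int(child.generate_state(1)[0] % (2**31))
                cfg = FullSimConfig(
                    n_genes_null=base.n_genes_null,
                    n_genes_pos=base.n_genes_pos,
                    guides_per_gene=int(k),
                    efficiency=float(eff),
                    n_controls=base.n_controls,
                    null_params=base.null_params,
                    gene_effect_mean=base.gene_effect_mean,
                    gene_effect_sd=base.gene_effect_sd,
                    guide_noise_sd=base.guide_noise_sd,
                    seed=rep_seed,
                )
                table, truth = simulate_full(cfg)
                for method in methods:
                    res = run_method(
                        method, table, truth.gene, fdr_threshold, seed=rep_seed
                    )
                    res.update(
                        {"efficiency": eff, "guides_per_gene": k, "rep": rep, "seed": rep_seed}
                    )
                    rows.append(res)
                if progress is not None:
                    progress(eff, k, rep)
    return pd.DataFrame(rows)


def plot_benchmark(df: pd.DataFrame, path, metric: str = "tpr_at_fdr") -> None:
    """Line plot of a grid metric vs guides-per-gene, one panel per method.

    Optional artifact; the tidy DataFrame from :func:`benchmark_grid` is the
    numeric contract.  Requires matplotlib.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    agg = (
        df.groupby(["method", "efficiency", "guides_per_gene"])[metric]
        .mean()
        .reset_index()
    )
    methods = agg["method"].unique()
    fig, axes = plt.subplots(1, len(methods), figsize=(4 * len(methods), 3.2), squeeze=False)
    for ax, method in zip(axes[0], methods):
        sub = agg[agg["method"] == method]
        for eff, grp in sub.groupby("efficiency"):
            ax.plot(grp["guides_per_gene"], grp[metric], marker="o", label=f"{eff:.0%} effective")
        ax.set_title(method)
        ax.set_xlabel("sgRNAs per gene")
        ax.set_ylabel(metric)
        ax.set_ylim(0, 1.02)
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
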