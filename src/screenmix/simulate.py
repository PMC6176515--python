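"""Synthetic pooled-screen generators with ground-truth labels.

Two generative models:

* **Full simulation** at the LFC level: null-gene guides (and ineffective
  guides of interesting genes) draw from a heavy-tailed skew-t null
  (default skew-t(0, 1, -1.5, 6)); each interesting gene gets an effect
  size ~ Normal(-3, 0.75^2); its effective guides (Bernoulli efficiency)
  draw Normal(gene effect, 1^2), so marginally effective guides are
  Normal(-3, sqrt(0.75^2 + 1^2) = 1.25).  Used to map power against guide
  count and guide efficiency.

* **Semi-simulation** at the count level: null genes are fabricated from
  observed negative-control counts -- guides-per-gene ~ NB(mu=67.8,
  r=26.3), and each simulated guide's counts are NB with mean equal to a
  randomly sampled control guide's observed counts and size 200; real (or
  synthetic) positive-gene counts are merged in at a 3:1 null:positive
  gene ratio (p = 0.25).

Both emit truth labels: Z_g per gene (interesting) and Y_i per guide
(effective), with Y_i = 0 whenever Z_{g_i} = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import CONTROL_SENTINEL, CountMatrix, make_guide_table
from .null_model import SkewTParams

__all__ = [
    "FullSimConfig",
    "SemiSimConfig",
    "SimTruth",
    "draw_guides_per_gene",
    "sample_skew_t",
    "simulate_full",
    "simulate_semisim",
    "synthetic_control_counts",
    "synthetic_positive_counts",
    "downsample_library",
]

DEFAULT_NULL = SkewTParams(xi=0.0, omega=1.0, alpha=-1.5, nu=6.0)


@dataclass
class SimTruth:
    """Latent labels: Z per gene (interesting) and Y per guide (effective)."""

    gene: pd.Series  # index: gene_id, values in {0, 1}
    guide: pd.Series  # index: guide_id, values in {0, 1}


@dataclass
class FullSimConfig:
    """LFC-level simulation settings (defaults are the reference regime)."""

    n_genes_null: int = 1500
    n_genes_pos: int = 500
    guides_per_gene: int = 10
    efficiency: float = 0.95
    n_controls: int = 959
    null_params: SkewTParams = field(default_factory=lambda: DEFAULT_NULL)
    gene_effect_mean: float = -3.0
    gene_effect_sd: float = 0.75
    guide_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError(f"efficiency must be in [0, 1], got {self.efficiency}")
        if self.guides_per_gene < 1:
            raise ValueError("guides_per_gene must be >= 1")


@dataclass
class SemiSimConfig:
    """Count-level semi-simulation settings.

    ``control_counts``: observed counts of the screen's negative-control
    guides (guides x samples).  Null genes are fabricated from them;
    positive-gene counts are supplied separately (real data or
    :func:`synthetic_positive_counts`).
    """

    control_counts: np.ndarray
    n_neg_genes: int
    guides_per_gene_mu: float = 67.8
    guides_per_gene_r: float = 26.3
    count_size: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.control_counts = np.atleast_2d(np.asarray(self.control_counts))
        if self.control_counts.size == 0:
            raise ValueError("control_counts must be nonempty")


def sample_skew_t(params: SkewTParams, n: int, rng) -> np.ndarray:
    """Draws from the skew-t via skew-normal / sqrt(chi2_nu / nu)."""
    rng = np.random.default_rng(rng)
    z = stats.skewnorm.rvs(params.alpha, size=n, random_state=rng)
    v = rng.chisquare(params.nu, size=n) / params.nu
    return params.xi + params.omega * z / np.sqrt(v)


def simulate_full(config: FullSimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Simulate an LFC-level screen; returns (guide table, truth labels)."""
    rng = np.random.default_rng(config.seed)
    k = config.guides_per_gene
    null_genes = [f"null_{i:05d}" for i in range(config.n_genes_null)]
    pos_genes = [f"pos_{i:05d}" for i in range(config.n_genes_pos)]

    n_null_guides = config.n_genes_null * k
    n_pos_guides = config.n_genes_pos * k

    gene_effects = rng.normal(
        config.gene_effect_mean, config.gene_effect_sd, size=config.n_genes_pos
    )
    effective = rng.random(n_pos_guides) < config.efficiency
    pos_lfc = sample_skew_t(config.null_params, n_pos_guides, rng)
    per_guide_mean = np.repeat(gene_effects, k)
    pos_lfc[effective] = rng.normal(
        per_guide_mean[effective], config.guide_noise_sd
    )

    null_lfc = sample_skew_t(config.null_params, n_null_guides, rng)
    control_lfc = sample_skew_t(config.null_params, config.n_controls, rng)

    guide_id = (
        [f"g_null_{i:06d}" for i in range(n_null_guides)]
        + [f"g_pos_{i:06d}" for i in range(n_pos_guides)]
        + [f"g_ctrl_{i:06d}" for i in range(config.n_controls)]
    )
    gene_id = (
        list(np.repeat(null_genes, k))
        + list(np.repeat(pos_genes, k))
        + [CONTROL_SENTINEL] * config.n_controls
    )
    lfc = np.concatenate([null_lfc, pos_lfc, control_lfc])
    is_ctrl = np.array(
        [False] * (n_null_guides + n_pos_guides) + [True] * config.n_controls
    )
    table = make_guide_table(guide_id, gene_id, lfc, is_ctrl)

    gene_truth = pd.Series(
        np.concatenate([np.zeros(config.n_genes_null, int), np.ones(config.n_genes_pos, int)]),
        index=null_genes + pos_genes,
        name="Z",
    )
    guide_truth = pd.Series(
        np.concatenate(
            [np.zeros(n_null_guides, int), effective.astype(int), np.zeros(config.n_controls, int)]
        ),
        index=guide_id,
        name="Y",
    )
    return table, SimTruth(gene=gene_truth, guide=guide_truth)


def _nbinom_draw(rng, mean, size_param, n: int | None = None):
    mean = np.asarray(mean, dtype=float)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p, size=n if n is not None else mean.shape)


def draw_guides_per_gene(n_genes: int, mu: float, r: float, rng) -> np.ndarray:
    """Library sizes per gene ~ NB(mu, r), zero draws redrawn (>= 1 guide)."""
    rng = np.random.default_rng(rng)
    p = r / (r + mu)
    sizes = rng.negative_binomial(r, p, size=n_genes)
    while (sizes == 0).any():
        zero = sizes == 0
        sizes[zero] = rng.negative_binomial(r, p, size=int(zero.sum()))
    return sizes


def synthetic_control_counts(
    n_controls: int = 959,
    n_samples: int = 2,
    mean: float = 400.0,
    size_param: float = 5.0,
    seed: int = 0,
) -> np.ndarray:
    """Synthetic stand-in for observed negative-control counts.

    Overdispersed NB counts roughly matching the coverage of a deeply
    sequenced focused screen; use real control counts to reproduce a
    specific experiment.
    """
    rng = np.random.default_rng(seed)
    return _nbinom_draw(rng, np.full((n_controls, n_samples), mean), size_param)


def synthetic_positive_counts(
    n_genes: int = 34,
    guides_per_gene: int = 68,
    efficiency: float = 0.4,
    gene_effect_mean: float = -3.0,
    gene_effect_sd: float = 0.75,
    guide_noise_sd: float = 1.0,
    initial_mean: float = 400.0,
    count_size: float = 200.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Synthetic positive-gene count block (synthetic stand-in for real
    positive-gene counts in the semi-simulated design).

    Each gene draws an effect size; effective guides deplete the final
    sample by 2^effect; counts are NB(mean, size).  Returns (counts frame
    with gene column, per-guide effectiveness labels).
    """
    rng = np.random.default_rng(seed)
    rows = []
    y_labels = {}
    for gi in range(n_genes):
        gene = f"pos_{gi:04d}"
        effect = rng.normal(gene_effect_mean, gene_effect_sd)
        for j in range(guides_per_gene):
            guide = f"g_{gene}_{j:03d}"
            eff = rng.random() < efficiency
            lfc = rng.normal(effect, guide_noise_sd) if eff else 0.0
            init = _nbinom_draw(rng, np.array(initial_mean), count_size, n=1)[0]
            final_mean = max(initial_mean * 2.0**lfc, 1e-6)
            final = _nbinom_draw(rng, np.array(final_mean), count_size, n=1)[0]
            rows.append((guide, gene, init, final))
            y_labels[guide] = int(eff)
    df = pd.DataFrame(rows, columns=["guide_id", "gene_id", "initial", "final"])
    return df, pd.Series(y_labels, name="Y")


def simulate_semisim(
    config: SemiSimConfig,
    positive_counts: pd.DataFrame | None = None,
    positive_guide_truth: pd.Series | None = None,
    sample_names: tuple[str, ...] = ("initial", "final"),
) -> tuple[CountMatrix, SimTruth]:
    """Fabricate null genes from control counts and merge positive genes.

    Per null gene: guides-per-gene ~ NB(mu, r) (zero draws redrawn); each
    guide copies a random control guide's observed count profile as the NB
    mean with size ``count_size``.  ``positive_counts`` is a frame with
    guide_id, gene_id and one column per sample (same samples as the
    controls); pass 3 null genes per positive gene for the p = 0.25 design.
    """
    rng = np.random.default_rng(config.seed)
    ctrl = config.control_counts
    n_samples = ctrl.shape[1]
    if positive_counts is not None and positive_counts.shape[1] - 2 != n_samples:
        raise ValueError("positive_counts sample columns must match control_counts")

    sizes = draw_guides_per_gene(
        config.n_neg_genes, config.guides_per_gene_mu, config.guides_per_gene_r, rng
    )
    total = int(sizes.sum())
    gene_labels = np.repeat(
        np.array([f"simnull_{gi:04d}" for gi in range(config.n_neg_genes)]), sizes
    )
    within = np.concatenate([np.arange(s) for s in sizes])
    picks = rng.integers(0, ctrl.shape[0], size=total)
    counts_null = _nbinom_draw(rng, ctrl[picks], config.count_size)
    cols = ["guide_id", "gene_id", *sample_names[:n_samples]]
    null_df = pd.DataFrame(counts_null, columns=list(sample_names[:n_samples]))
    null_df.insert(0, "gene_id", gene_labels)
    null_df.insert(
        0,
        "guide_id",
        [f"g_{g}_{j:03d}" for g, j in zip(gene_labels, within)],
    )

    # the observed control guides themselves stay in the matrix
    ctrl_df = pd.DataFrame(
        ctrl, columns=list(sample_names[:n_samples])
    )
    ctrl_df.insert(0, "gene_id", CONTROL_SENTINEL)
    ctrl_df.insert(0, "guide_id", [f"g_ctrl_{i:05d}" for i in range(ctrl.shape[0])])

    frames = [null_df, ctrl_df]
    pos_genes: list[str] = []
    if positive_counts is not None:
        pos = positive_counts.copy()
        pos.columns = cols
        frames.insert(0, pos)
        pos_genes = pos["gene_id"].unique().tolist()
    full = pd.concat(frames, ignore_index=True)

    counts = full.set_index("guide_id")[list(sample_names[:n_samples])].astype(np.int64)
    gene = full.set_index("guide_id")["gene_id"]
    conditions = pd.Series(
        {s: s for s in sample_names[:n_samples]}
    )
    cm = CountMatrix(counts=counts, gene=gene, conditions=conditions)

    gene_ids = [g for g in gene.unique() if g != CONTROL_SENTINEL]
    z = pd.Series({g: int(g in set(pos_genes)) for g in gene_ids}, name="Z")
    y = pd.Series(0, index=counts.index, name="Y")
    if positive_guide_truth is not None:
        y.loc[positive_guide_truth.index] = positive_guide_truth.astype(int)
    return cm, SimTruth(gene=z, guide=y)


def downsample_library(
    guide_table: pd.DataFrame,
    target_mean_guides: float,
    n_reps: int = 100,
    seed: int = 0,
) -> list[pd.DataFrame]:
    """Randomly thin a library to an average guides-per-gene target.

    Per replicate, one guide per gene is kept unconditionally and the
    remaining budget (target * n_genes - n_genes guides) is sampled
    without replacement from the rest; negative controls are kept in full.
    """
    targeting = guide_table.loc[~guide_table["is_negative_control"]]
    controls = guide_table.loc[guide_table["is_negative_control"]]
    n_genes = targeting["gene_id"].nunique()
    current_mean = len(targeting) / n_genes
    if target_mean_guides > current_mean + 1e-9:
        raise ValueError(
            f"target {target_mean_guides} exceeds current mean {current_mean:.2f}"
        )
    total_target = int(round(target_mean_guides * n_genes))
    rng = np.random.default_rng(seed)

    reps = []
    idx_by_gene = targeting.groupby("gene_id").indices
    all_idx = targeting.index.to_numpy()
    for _ in range(n_reps):
        keep = []
        for gene, rows in idx_by_gene.items():
            keep.append(targeting.index[rows[rng.integers(0, len(rows))]])
        keep_set = set(keep)
        remaining = np.array([i for i in all_idx if i not in keep_set])
        extra = total_target - len(keep)
        if extra > 0:
            keep.extend(rng.choice(remaining, size=min(extra, remaining.size), replace=False))
        sub = pd.concat([targeting.loc[sorted(keep)], controls])
        reps.append(sub.reset_index(drop=True))
    return reps
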