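"""Hierarchical two-groups mixture for gene-level hit calling.

Guide-level log2 fold changes x_i follow the marginal mixture
(1 - tau) f0 + tau f1, where tau = p*q is the probability that a random
guide carries a real effect (p = fraction of interesting genes, q = guide
efficiency).  p and q are not separately identifiable, so the EM fits only
tau and the alternative component f1 (normal, or a two-sided normal pair
for bidirectional screens), with f0 fixed from negative controls or
jointly estimated as a normal when no controls exist.

Gene-level inference marginalizes q: with psi(q) a prior supported on
[tau_hat, 1], the posterior probability that gene g is interesting is

    int (tau/q) prod_i [q f1(x_i) + (1-q) f0(x_i)]
        / { (tau/q) prod_i [...] + (1 - tau/q) prod_i f0(x_i) } dpsi(q),

evaluated with Gauss-Legendre quadrature in log space.  The gene's local
false discovery rate is one minus this posterior; a global FDR estimate at
rank K is the cumulative mean of the K smallest local fdrs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logsumexp

from .null_model import NullFit, fit_normal, fit_skew_t_mle, select_null

__all__ = [
    "QPrior",
    "MixtureFit",
    "em_fit_marginal",
    "gene_posterior",
    "score_genes",
    "global_fdr",
    "call_at_fdr",
    "fit_screen",
]

_DENSITY_FLOOR = 1e-300
_TAU_CLAMP = (1e-4, 1.0 - 1e-4)


@dataclass(frozen=True)
class QPrior:
    """Prior psi(q) on guide efficiency, used to marginalize q.

    The support must not extend below tau_hat (that would imply p > 1).
    ``uniform`` spans [max(tau_hat, lower_floor), 1]; ``point_mass`` puts
    all mass at ``point`` (point_mass at 1 collapses the gene posterior to
    the flat two-groups posterior); ``custom_grid`` takes explicit
    nodes/weights.
    """

    kind: Literal["uniform", "point_mass", "custom_grid"] = "uniform"
    lower_floor: float = 0.01
    point: float = 1.0
    nodes: tuple[float, ...] | None = None
    weights: tuple[float, ...] | None = None

    def nodes_weights(self, tau_hat: float, n_nodes: int = 100) -> tuple[np.ndarray, np.ndarray]:
        """Quadrature nodes and probability weights (weights sum to 1)."""
        if self.kind == "point_mass":
            if self.point < tau_hat:
                raise ValueError(
                    f"point-mass prior at q={self.point} below tau_hat={tau_hat:.4g} "
                    "implies p > 1"
                )
            return np.array([self.point]), np.array([1.0])
        if self.kind == "custom_grid":
            q = np.asarray(self.nodes, dtype=float)
            w = np.asarray(self.weights, dtype=float)
            if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
                raise ValueError("custom prior weights must be >= 0 and sum to 1")
            if np.any(q <= 0) or np.any(q > 1):
                raise ValueError("custom prior nodes must lie in (0, 1]")
            return q, w
        lo = max(tau_hat, self.lower_floor)
        if lo >= 1.0:
            raise ValueError(f"uniform prior support [{lo}, 1] is empty")
        # Legendre nodes on [-1, 1] mapped to [lo, 1]; uniform density cancels
        # the interval length, so the probability weights are gl_w / 2.
        gl_x, gl_w = np.polynomial.legendre.leggauss(n_nodes)
        q = lo + (gl_x + 1.0) * (1.0 - lo) / 2.0
        return q, gl_w / 2.0


@dataclass
class MixtureFit:
    """Fitted marginal guide-level mixture (1 - tau) f0 + tau f1."""

    f0: NullFit
    f1_mode: Literal["unimodal", "bimodal"]
    f1_params: dict
    tau: float
    responsibilities: np.ndarray
    em_trace: list[float]
    converged: bool
    n_iter: int

    def f1_logpdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        p = self.f1_params
        if self.f1_mode == "unimodal":
            return stats.norm.logpdf(x, loc=p["mu"], scale=p["sigma"])
        parts = np.stack(
            [
                np.log(p["w_neg"]) + stats.norm.logpdf(x, p["mu_neg"], p["sigma_neg"]),
                np.log1p(-p["w_neg"]) + stats.norm.logpdf(x, p["mu_pos"], p["sigma_pos"]),
            ]
        )
        return logsumexp(parts, axis=0)


def _floored_log(log_density: np.ndarray) -> np.ndarray:
    return np.maximum(log_density, np.log(_DENSITY_FLOOR))


def em_fit_marginal(
    lfc,
    f0: NullFit | None,
    *,
    f1_mode: Literal["unimodal", "bimodal"] = "unimodal",
    direction: Literal["depleted", "enriched"] = "depleted",
    tau_init: float = 0.1,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> MixtureFit:
    """EM for (tau, f1) on the marginal guide mixture, ignoring gene identity.

    ``f0=None`` requests the no-controls variant where f0 is a normal whose
    mean/sd are re-estimated each M-step from the null responsibilities.
    For ``direction="depleted"`` the unimodal f1 mean is constrained below 0
    (``"enriched"`` callers should negate their LFCs upstream); ``bimodal``
    fits one component on each side of 0 for bidirectional phenotypes.
    """
    x = np.asarray(lfc, dtype=float).ravel()
    if x.size == 0 or not np.all(np.isfinite(x)):
        raise ValueError("LFCs must be non-empty and finite")
    if x.size < 100:
        warnings.warn(
            f"EM on only {x.size} gene-targeting guides; tau and f1 will be noisy",
            stacklevel=2,
        )

    estimate_f0 = f0 is None
    if estimate_f0:
        f0 = fit_normal(x) if x.size >= 2 else None
        mu0, sigma0 = f0.params
    log_f0 = _floored_log(f0.logpdf(x))

    tau = float(np.clip(tau_init, *_TAU_CLAMP))
    lower_decile = x <= np.quantile(x, 0.1)
    sigma_floor = 1e-3
    if f1_mode == "unimodal":
        mu = float(np.quantile(x, 0.05))
        if direction == "depleted":
            mu = min(mu, -1e-6)
        sigma = max(float(np.std(x[lower_decile])), sigma_floor)
        params = {"mu": mu, "sigma": sigma}
    else:
        upper_decile = x >= np.quantile(x, 0.9)
        params = {
            "mu_neg": min(float(np.quantile(x, 0.05)), -1e-6),
            "sigma_neg": max(float(np.std(x[lower_decile])), sigma_floor),
            "mu_pos": max(float(np.quantile(x, 0.95)), 1e-6),
            "sigma_pos": max(float(np.std(x[upper_decile])), sigma_floor),
            "w_neg": 0.5,
        }

    def f1_log(params: dict) -> np.ndarray:
        if f1_mode == "unimodal":
            return stats.norm.logpdf(x, params["mu"], params["sigma"])
        return logsumexp(
            np.stack(
                [
                    np.log(params["w_neg"])
                    + stats.norm.logpdf(x, params["mu_neg"], params["sigma_neg"]),
                    np.log1p(-params["w_neg"])
                    + stats.norm.logpdf(x, params["mu_pos"], params["sigma_pos"]),
                ]
            ),
            axis=0,
        )

    trace: list[float] = []
    converged = False
    r = np.zeros_like(x)
    for it in range(1, max_iter + 1):
        log_f1 = _floored_log(f1_log(params))
        # E-step: responsibility that each guide comes from f1
        r = expit(np.log(tau) + log_f1 - np.log1p(-tau) - log_f0)
        loglik = float(
            np.sum(np.logaddexp(np.log(tau) + log_f1, np.log1p(-tau) + log_f0))
        )
        trace.append(loglik)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break

        # M-step
        tau_new = float(np.mean(r))
        if tau_new <= _TAU_CLAMP[0] or tau_new >= _TAU_CLAMP[1]:
            warnings.warn(
                f"tau collapsed to boundary ({tau_new:.2e}); clamped", stacklevel=2
            )
        tau = float(np.clip(tau_new, *_TAU_CLAMP))
        if f1_mode == "unimodal":
            w = r.sum()
            mu = float(np.sum(r * x) / w) if w > 0 else params["mu"]
            if direction == "depleted":
                mu = min(mu, -1e-6)
            var = float(np.sum(r * (x - mu) ** 2) / w) if w > 0 else params["sigma"] ** 2
            params = {"mu": mu, "sigma": max(np.sqrt(var), sigma_floor)}
        else:
            log_neg = np.log(params["w_neg"]) + stats.norm.logpdf(
                x, params["mu_neg"], params["sigma_neg"]
            )
            log_pos = np.log1p(-params["w_neg"]) + stats.norm.logpdf(
                x, params["mu_pos"], params["sigma_pos"]
            )
            side = expit(log_neg - log_pos)  # Pr(neg side | f1, x)
            r_neg, r_pos = r * side, r * (1.0 - side)
            new = {}
            for tag, rr, sign in (("neg", r_neg, -1.0), ("pos", r_pos, 1.0)):
                w = rr.sum()
                mu_c = float(np.sum(rr * x) / w) if w > 0 else params[f"mu_{tag}"]
                mu_c = sign * max(sign * mu_c, 1e-6)  # keep each side of 0
                var = (
                    float(np.sum(rr * (x - mu_c) ** 2) / w)
                    if w > 0
                    else params[f"sigma_{tag}"] ** 2
                )
                new[f"mu_{tag}"] = mu_c
                new[f"sigma_{tag}"] = max(np.sqrt(var), sigma_floor)
            total = r_neg.sum() + r_pos.sum()
            new["w_neg"] = float(np.clip(r_neg.sum() / total, 1e-4, 1 - 1e-4)) if total > 0 else 0.5
            params = new
        if estimate_f0:
            w0 = 1.0 - r
            mu0 = float(np.sum(w0 * x) / w0.sum())
            sigma0 = max(float(np.sqrt(np.sum(w0 * (x - mu0) ** 2) / w0.sum())), sigma_floor)
            f0 = NullFit(family="normal", params=(mu0, sigma0), log_likelihood=np.nan, n=x.size)
            log_f0 = _floored_log(f0.logpdf(x))

    return MixtureFit(
        f0=f0,
        f1_mode=f1_mode,
        f1_params=params,
        tau=tau,
        responsibilities=r,
        em_trace=trace,
        converged=converged,
        n_iter=len(trace),
    )


def gene_posterior(
    gene_lfcs,
    f0: NullFit,
    f1_logpdf,
    tau_hat: float,
    q_prior: QPrior = QPrior(),
    n_nodes: int = 100,
) -> float:
    """Posterior probability that a single gene is interesting.

    Marginalizes guide efficiency q over ``q_prior`` by quadrature; all
    per-guide products run in log space.  ``f1_logpdf`` is a callable
    (e.g. ``MixtureFit.f1_logpdf``).
    """
    x = np.asarray(gene_lfcs, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("gene has no guides")
    if not 0.0 < tau_hat < 1.0:
        raise ValueError(f"tau_hat must be in (0, 1), got {tau_hat}")
    log_f0 = _floored_log(f0.logpdf(x))
    log_f1 = _floored_log(f1_logpdf(x))
    q, w = q_prior.nodes_weights(tau_hat, n_nodes)

    sum_f0 = log_f0.sum()
    post = 0.0
    for qk, wk in zip(q, w):
        if qk >= 1.0:
            s = log_f1.sum()
        else:
            s = np.logaddexp(np.log(qk) + log_f1, np.log1p(-qk) + log_f0).sum()
        log_a = np.log(tau_hat / qk) + s
        ratio = tau_hat / qk
        if ratio >= 1.0:
            post += wk  # q at/below tau_hat: prior says every guide works
            continue
        log_b = np.log1p(-ratio) + sum_f0
        post += wk * float(expit(log_a - log_b))
    return float(post)


def _gene_posteriors_vectorized(
    x: np.ndarray,
    gene_codes: np.ndarray,
    n_genes: int,
    f0: NullFit,
    f1_logpdf,
    tau_hat: float,
    q_prior: QPrior,
    n_nodes: int,
) -> np.ndarray:
    """Posteriors for all genes at once (guides sorted by gene code)."""
    log_f0 = _floored_log(f0.logpdf(x))
    log_f1 = _floored_log(f1_logpdf(x))
    q, w = q_prior.nodes_weights(tau_hat, n_nodes)
    starts = np.searchsorted(gene_codes, np.arange(n_genes))
    sum_f0 = np.add.reduceat(log_f0, starts)

    post = np.zeros(n_genes)
    for qk, wk in zip(q, w):
        if qk >= 1.0:
            mix = log_f1
        else:
            mix = np.logaddexp(np.log(qk) + log_f1, np.log1p(-qk) + log_f0)
        s = np.add.reduceat(mix, starts)
        ratio = tau_hat / qk
        if ratio >= 1.0:
            post += wk
            continue
        log_a = np.log(ratio) + s
        log_b = np.log1p(-ratio) + sum_f0
        post += wk * expit(log_a - log_b)
    return post


def score_genes(
    guide_table: pd.DataFrame,
    fit: MixtureFit,
    q_prior: QPrior = QPrior(),
    n_nodes: int = 100,
) -> pd.DataFrame:
    """Local fdr per gene, sorted ascending with cumulative-mean global FDR.

    Negative-control guides are excluded.  Returns columns gene_id, locfdr,
    fdr_cummean, rank; ties in locfdr break lexicographically by gene id.
    """
    targeting = guide_table.loc[~guide_table["is_negative_control"]]
    if targeting.empty:
        raise ValueError("no gene-targeting guides to score")
    order = np.argsort(targeting["gene_id"].to_numpy(), kind="stable")
    x = targeting["lfc"].to_numpy(dtype=float)[order]
    genes, codes = np.unique(targeting["gene_id"].to_numpy()[order], return_inverse=True)
    sizes = np.bincount(codes)
    if (sizes == 1).any():
        warnings.warn(
            f"{int((sizes == 1).sum())} gene(s) have a single guide; their "
            "scores rest on very little evidence",
            stacklevel=2,
        )
    post = _gene_posteriors_vectorized(
        x, codes, genes.size, fit.f0, fit.f1_logpdf, fit.tau, q_prior, n_nodes
    )
    scores = pd.DataFrame({"gene_id": genes, "locfdr": 1.0 - post})
    scores = scores.sort_values(["locfdr", "gene_id"], kind="stable").reset_index(drop=True)
    scores["fdr_cummean"] = global_fdr(scores["locfdr"].to_numpy())
    scores["rank"] = np.arange(1, len(scores) + 1)
    return scores


def global_fdr(locfdrs) -> np.ndarray:
    """Cumulative-mean global FDR along ascending-sorted local fdrs.

    Input must already be sorted ascending; the value at rank K estimates
    the FDR of calling the K best genes.
    """
    s = np.asarray(locfdrs, dtype=float)
    if s.size == 0:
        raise ValueError("empty local fdr vector")
    if np.any((s < 0) | (s > 1)):
        raise ValueError("local fdrs must lie in [0, 1]")
    if np.any(np.diff(s) < 0):
        raise ValueError("local fdrs must be sorted ascending")
    return np.cumsum(s) / np.arange(1, s.size + 1)


def call_at_fdr(scores: pd.DataFrame, pi: float = 0.1) -> pd.DataFrame:
    """Genes called at global FDR threshold pi (largest K with cummean <= pi)."""
    ok = scores["fdr_cummean"].to_numpy() <= pi
    k = int(np.max(np.nonzero(ok)[0]) + 1) if ok.any() else 0
    return scores.iloc[:k]


def fit_screen(
    guide_table: pd.DataFrame,
    *,
    direction: Literal["depleted", "enriched", "both"] = "depleted",
    null: Literal["auto", "normal", "skewt", "normal-em"] = "auto",
    q_prior: QPrior = QPrior(),
    n_nodes: int = 100,
    tau_init: float = 0.1,
    seed: int = 0,
) -> tuple[MixtureFit, pd.DataFrame]:
    """Full pipeline: null fit on controls, marginal EM, gene scoring.

    1. fit f0 on negative-control LFCs (``null="auto"`` selects normal vs
       skew-t by BIC; ``"normal-em"`` skips controls and estimates a normal
       f0 inside the EM -- the only valid choice when no controls exist);
    2. EM for (tau, f1) on gene-targeting guides;
    3. gene-level local fdrs with q marginalized over ``q_prior``, plus
       cumulative-mean global FDR.

    ``direction="enriched"`` negates all LFCs internally so the depletion
    machinery applies; ``"both"`` switches f1 to the bimodal form.
    """
    from .io import validate_guide_table

    validate_guide_table(guide_table)
    table = guide_table.copy()
    if direction == "enriched":
        table["lfc"] = -table["lfc"]
    controls = table.loc[table["is_negative_control"], "lfc"].to_numpy(dtype=float)

    if null == "normal-em":
        f0 = None
    elif controls.size == 0:
        raise ValueError(
            "no negative-control guides: use null='normal-em' (jointly "
            "estimated normal null)"
        )
    elif null == "auto":
        f0 = select_null(controls, seed=seed)
    elif null == "normal":
        f0 = fit_normal(controls)
    elif null == "skewt":
        f0 = fit_skew_t_mle(controls, seed=seed)
    else:
        raise ValueError(f"unknown null option {null!r}")

    targeting = table.loc[~table["is_negative_control"]]
    fit = em_fit_marginal(
        targeting["lfc"].to_numpy(dtype=float),
        f0,
        f1_mode="bimodal" if direction == "both" else "unimodal",
        direction="depleted",
        tau_init=tau_init,
    )
    scores = score_genes(targeting, fit, q_prior=q_prior, n_nodes=n_nodes)
    return fit, scores
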