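"""Per-gene Mann-Whitney tests against negative controls, BH-corrected.

The standard nonparametric baseline for screens with negative-control
guides: for each gene, a one-sided Mann-Whitney U test of its guides'
log2 fold changes against the pooled control guides, followed by
Benjamini-Hochberg correction across genes.  Exact p-values are used for
small tie-free genes; otherwise the tie-corrected normal approximation
with continuity correction.

The exact null distribution of U for n-vs-m is obtained from the Gaussian
binomial generating function prod_{k=1..n} (1 - x^{m+k})/(1 - x^k), which
costs O(n^2 m) for the whole distribution and so stays cheap even when the
control set has thousands of guides (computed once per (n, m) and cached).
"""

from __future__ import annotations

from functools import lru_cache
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "exact_u_cdf",
    "mann_whitney_gene",
    "bh_adjust",
    "mw_screen",
]

EXACT_MAX_N = 8  # exact p when min(n, m) <= this and there are no ties


@lru_cache(maxsize=128)
def exact_u_cdf(n: int, m: int) -> np.ndarray:
    """CDF of the null Mann-Whitney U (n vs m) over u = 0 .. n*m.

    Coefficients of the Gaussian binomial [n+m, n]_x give the number of
    arrangements per U value; normalizing yields the exact distribution.
    """
    if n > m:
        n, m = m, n
    size = n * m + 1
    poly = np.zeros(size)
    poly[0] = 1.0
    for k in range(1, n + 1):
        # multiply by (1 - x^(m+k))
        if m + k < size:
            poly[m + k :] -= poly[: size - (m + k)].copy()
        # divide by (1 - x^k): running sums with stride k
        for start in range(k):
            np.cumsum(poly[start::k], out=poly[start::k])
    cdf = np.cumsum(poly)
    return cdf / cdf[-1]


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x vs y: #(x > y pairs) + 0.5 * ties (scipy's U1)."""
    y_sorted = np.sort(y)
    less = np.searchsorted(y_sorted, x, side="left").sum()
    leq = np.searchsorted(y_sorted, x, side="right").sum()
    return float(less) + 0.5 * float(leq - less)


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return np.unique(pooled).size < pooled.size


def _normal_approx_p(u: float, n: int, m: int, pooled: np.ndarray, alternative: str) -> float:
    mu = n * m / 2.0
    nm = n + m
    _, t = np.unique(pooled, return_counts=True)
    tie_term = ((t**3 - t).sum()) / (nm * (nm - 1)) if nm > 1 else 0.0
    sigma2 = n * m / 12.0 * ((nm + 1) - tie_term)
    sigma = np.sqrt(max(sigma2, 1e-300))
    if alternative == "less":
        return float(stats.norm.cdf((u - mu + 0.5) / sigma))
    if alternative == "greater":
        return float(stats.norm.sf((u - mu - 0.5) / sigma))
    z = (abs(u - mu) - 0.5) / sigma
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


_ALTERNATIVE = {"depleted": "less", "enriched": "greater", "two-sided": "two-sided"}


def mann_whitney_gene(
    gene_lfcs,
    control_lfcs,
    direction: Literal["depleted", "enriched", "two-sided"] = "depleted",
) -> tuple[float, float]:
    """One-gene Mann-Whitney U test of gene guides vs control guides.

    Returns (U, p).  ``direction="depleted"`` tests whether gene guides are
    stochastically smaller than controls.
    """
    x = np.asarray(gene_lfcs, dtype=float).ravel()
    y = np.asarray(control_lfcs, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("gene has no guides")
    if y.size < 2:
        raise ValueError("need at least 2 control guides")
    alternative = _ALTERNATIVE[direction]
    u = _u_statistic(x, y)
    n, m = x.size, y.size
    if min(n, m) <= EXACT_MAX_N and not _has_ties(x, y):
        cdf = exact_u_cdf(n, m)
        ui = int(round(u))
        if alternative == "less":
            p = float(cdf[ui])
        elif alternative == "greater":
            p = float(1.0 - (cdf[ui - 1] if ui > 0 else 0.0))
        else:
            lo = float(cdf[ui])
            hi = float(1.0 - (cdf[ui - 1] if ui > 0 else 0.0))
            p = min(1.0, 2.0 * min(lo, hi))
    else:
        p = _normal_approx_p(u, n, m, np.concatenate([x, y]), alternative)
    return u, max(p, np.finfo(float).tiny)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values (q_(i) = min_{j>=i} m p_(j)/j)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def mw_screen(
    guide_table: pd.DataFrame,
    direction: Literal["depleted", "enriched", "two-sided"] = "depleted",
) -> pd.DataFrame:
    """Mann-Whitney test for every gene vs the screen's negative controls.

    Returns a DataFrame (gene_id, u_statistic, p_value, bh_fdr) sorted by
    p-value with lexicographic tie-break on gene id.
    """
    controls = guide_table.loc[guide_table["is_negative_control"], "lfc"].to_numpy(dtype=float)
    if controls.size < 2:
        raise ValueError("screen has fewer than 2 negative-control guides")
    targeting = guide_table.loc[~guide_table["is_negative_control"]]
    if targeting.empty:
        raise ValueError("no gene-targeting guides")

    rows = []
    y_sorted = np.sort(controls)
    for gene, sub in targeting.groupby("gene_id", sort=True):
        x = sub["lfc"].to_numpy(dtype=float)
        u, p = mann_whitney_gene(x, y_sorted, direction)
        rows.append((gene, u, p))
    out = pd.DataFrame(rows, columns=["gene_id", "u_statistic", "p_value"])
    out["bh_fdr"] = bh_adjust(out["p_value"].to_numpy())
    return out.sort_values(["p_value", "gene_id"], kind="stable").reset_index(drop=True)
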