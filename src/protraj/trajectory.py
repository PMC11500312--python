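"""Per-gene statistics along progression paths.

Implements the spline-versus-constant likelihood-ratio test for trajectory
differential expression, the branch-dependence (BEAM-style) test comparing
one pooled spline against two path-specific splines, natural-spline curve
fitting, k-medoids clustering of gene curves under Pearson correlation
distance, and Benjamini-Hochberg FDR control.

Expression values are treated as Gaussian on the log scale with per-gene
variance profiled by maximum likelihood; LRT statistics are referred to a
chi-square with the difference in mean-parameter counts, a standard
large-sample approximation.  The natural cubic spline basis (df = 3)
places interior knots at the 1/3 and 2/3 quantiles of the distances and
boundary knots at the range, matching the usual regression-spline
convention; linear functions lie in its span, so a linear trend is
reproduced exactly.  Both arms of the branch test share the pooled-knot
basis, which keeps the null model nested in the alternative and the LRT
statistic non-negative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "SplineSpec",
    "GeneCurve",
    "TrajectoryTestResult",
    "GeneModule",
    "natural_spline_basis",
    "fit_spline_curve",
    "trajectory_de_test",
    "benjamini_hochberg",
    "cluster_gene_curves",
    "beam_test",
]


@dataclass(frozen=True)
class SplineSpec:
    """Natural cubic spline settings: ``df`` basis columns (no intercept),
    interior knots at evenly spaced quantiles of the fitted distances."""

    df: int = 3
    n_grid: int = 100

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("df must be >= 1")


def _ns_knots(x: np.ndarray, df: int) -> tuple[np.ndarray, tuple[float, float]]:
    """Interior and boundary knots for an ``ns``-style basis of ``df`` columns."""
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi <= lo:
        raise ValueError("distances are all identical; use a constant fit")
    n_interior = df - 1
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    interior = np.quantile(x, qs)
    interior = interior[(interior > lo) & (interior < hi)]
    return np.unique(interior), (lo, hi)


def natural_spline_basis(
    x: np.ndarray,
    df: int = 3,
    knots: np.ndarray | None = None,
    boundary: tuple[float, float] | None = None,
) -> np.ndarray:
    """Natural cubic spline basis (n, df'), intercept excluded.

    Uses the truncated-power construction: with knots xi_1 < ... < xi_K
    (boundary knots included), the basis is {x, d_1 - d_{K-1}, ...,
    d_{K-2} - d_{K-1}} where d_k(x) = [(x-xi_k)_+^3 - (x-xi_K)_+^3] /
    (xi_K - xi_k).  The function is linear beyond the boundary knots.
    """
    x = np.asarray(x, dtype=float)
    if knots is None or boundary is None:
        interior, bounds = _ns_knots(x, df)
        knots = interior if knots is None else np.asarray(knots, dtype=float)
        boundary = bounds if boundary is None else boundary
    xi = np.concatenate([[boundary[0]], np.asarray(knots, dtype=float),
                         [boundary[1]]])
    xi = np.unique(xi)
    K = len(xi)
    if K < 2:
        raise ValueError("need at least two distinct knots")
    cols = [x]
    if K > 2:
        def d(k):
            return (np.maximum(x - xi[k], 0.0) ** 3
                    - np.maximum(x - xi[K - 1], 0.0) ** 3) / (xi[K - 1] - xi[k])

        dlast = d(K - 2)
        for k in range(K - 2):
            cols.append(d(k) - dlast)
    return np.column_stack(cols)


@dataclass
class GeneCurve:
    """Spline-fitted mean expression of one gene along a path."""

    gene_id: str
    grid: np.ndarray
    fitted: np.ndarray
    residual_variance: float

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("curve grid must be strictly increasing")
        if not np.all(np.isfinite(self.fitted)):
            raise ValueError("fitted curve contains non-finite values")

    def normalized(self) -> np.ndarray:
        """Fitted values min-max scaled into (-1, 1); constant curves map to 0."""
        lo, hi = self.fitted.min(), self.fitted.max()
        if hi - lo <= 0:
            return np.zeros_like(self.fitted)
        return 2.0 * (self.fitted - lo) / (hi - lo) - 1.0


@dataclass
class TrajectoryTestResult:
    gene_id: str
    loglik_null: float
    loglik_alt: float
    lrt_stat: float
    df_diff: int
    p_value: float
    fdr: float = np.nan


@dataclass
class GeneModule:
    module_id: int
    gene_ids: list[str]
    direction: str  # up | down | other
    medoid_gene_id: str


def _gauss_loglik(rss: np.ndarray, n: int) -> np.ndarray:
    """Profiled Gaussian log-likelihood given residual sums of squares."""
    sigma2 = np.maximum(rss / n, 1e-300)
    return -0.5 * n * (np.log(2.0 * np.pi * sigma2) + 1.0)


def fit_spline_curve(
    distances: np.ndarray,
    expression: np.ndarray,
    spec: SplineSpec | None = None,
) -> "GeneCurve":
    """Least-squares natural-spline fit of one gene's expression."""
    spec = spec or SplineSpec()
    d = np.asarray(distances, dtype=float)
    y = np.asarray(expression, dtype=float)
    if len(d) < spec.df + 2:
        raise ValueError(f"need at least df + 2 = {spec.df + 2} samples")
    interior, bounds = _ns_knots(d, spec.df)
    B = np.column_stack([np.ones_like(d),
                         natural_spline_basis(d, spec.df, interior, bounds)])
    coef, *_ = np.linalg.lstsq(B, y, rcond=None)
    rss = float(((y - B @ coef) ** 2).sum())
    grid = np.linspace(bounds[0], bounds[1], spec.n_grid)
    Bg = np.column_stack([np.ones_like(grid),
                          natural_spline_basis(grid, spec.df, interior, bounds)])
    return GeneCurve("", grid, Bg @ coef, rss / len(d))


def _fit_rss(design: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sum of squares per gene for a shared design (genes x samples)."""
    Q, _ = np.linalg.qr(design)
    resid = Y - (Y @ Q) @ Q.T
    return (resid**2).sum(axis=1)


def trajectory_de_test(
    expression: np.ndarray,
    gene_ids: list[str],
    distances: np.ndarray,
    spec: SplineSpec | None = None,
    fdr_threshold: float = 1e-4,
) -> tuple[list[TrajectoryTestResult], list[str]]:
    """Constant-vs-spline LRT per gene along one path.

    ``expression`` is (genes, samples) over the path's samples ordered to
    match ``distances``.  Returns all per-gene results plus the genes
    retained at BH FDR <= ``fdr_threshold``.
    """
    spec = spec or SplineSpec()
    Y = np.asarray(expression, dtype=float)
    d = np.asarray(distances, dtype=float)
    n = Y.shape[1]
    if n < spec.df + 2:
        raise ValueError(f"need at least df + 2 = {spec.df + 2} samples on path")
    ones = np.ones((n, 1))
    B = natural_spline_basis(d, spec.df)
    design_alt = np.column_stack([ones, B])

    rss0 = ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    rss1 = _fit_rss(design_alt, Y)
    ll0 = _gauss_loglik(rss0, n)
    ll1 = _gauss_loglik(rss1, n)
    df_diff = design_alt.shape[1] - 1
    stat = 2.0 * (ll1 - ll0)
    # zero-variance genes carry no signal: statistic 0, p = 1
    zero_var = rss0 <= 1e-12
    stat = np.where(zero_var, 0.0, np.maximum(stat, 0.0))
    p = stats.chi2.sf(stat, df_diff)
    p = np.where(zero_var, 1.0, p)
    fdr = benjamini_hochberg(p)
    results = [
        TrajectoryTestResult(g, float(l0), float(l1), float(s), df_diff,
                             float(pv), float(q))
        for g, l0, l1, s, pv, q in zip(gene_ids, ll0, ll1, stat, p, fdr)
    ]
    retained = [g for g, q in zip(gene_ids, fdr) if q <= fdr_threshold]
    return results, retained


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Standard BH step-up adjusted values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size and ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def beam_test(
    expr_path1: np.ndarray,
    dist_path1: np.ndarray,
    expr_path2: np.ndarray,
    dist_path2: np.ndarray,
    gene_ids: list[str],
    spec: SplineSpec | None = None,
    fdr_threshold: float = 1e-4,
) -> tuple[list[TrajectoryTestResult], list[str]]:
    """Branch-dependence LRT: pooled spline vs two path-specific splines.

    Both models use the natural-spline basis with knots from the pooled
    distances, so the pooled model is nested in the path-specific one.
    """
    spec = spec or SplineSpec()
    Y1 = np.asarray(expr_path1, dtype=float)
    Y2 = np.asarray(expr_path2, dtype=float)
    d1 = np.asarray(dist_path1, dtype=float)
    d2 = np.asarray(dist_path2, dtype=float)
    for d, Y in ((d1, Y1), (d2, Y2)):
        if Y.shape[1] != len(d):
            raise ValueError("expression/distance length mismatch")
        if len(d) < spec.df + 2:
            raise ValueError(f"each path needs at least df + 2 = {spec.df + 2} samples")
    d_pool = np.concatenate([d1, d2])
    Y = np.concatenate([Y1, Y2], axis=1)
    n = Y.shape[1]
    interior, bounds = _ns_knots(d_pool, spec.df)
    B = natural_spline_basis(d_pool, spec.df, interior, bounds)
    ones = np.ones(n)
    design_null = np.column_stack([ones, B])
    ind1 = np.concatenate([np.ones(len(d1)), np.zeros(len(d2))])
    ind2 = 1.0 - ind1
    design_alt = np.column_stack([
        ind1, B * ind1[:, None], ind2, B * ind2[:, None]
    ])
    rss0 = _fit_rss(design_null, Y)
    rss1 = _fit_rss(design_alt, Y)
    ll0 = _gauss_loglik(rss0, n)
    ll1 = _gauss_loglik(rss1, n)
    df_diff = design_alt.shape[1] - design_null.shape[1]
    stat = np.maximum(2.0 * (ll1 - ll0), 0.0)
    zero_var = rss0 <= 1e-12
    stat = np.where(zero_var, 0.0, stat)
    p = np.where(zero_var, 1.0, stats.chi2.sf(stat, df_diff))
    fdr = benjamini_hochberg(p)
    results = [
        TrajectoryTestResult(g, float(l0), float(l1), float(s), df_diff,
                             float(pv), float(q))
        for g, l0, l1, s, pv, q in zip(gene_ids, ll0, ll1, stat, p, fdr)
    ]
    retained = [g for g, q in zip(gene_ids, fdr) if q <= fdr_threshold]
    return results, retained


# ---------------------------------------------------------------------------
# Curve clustering
# ---------------------------------------------------------------------------

def _correlation_distances(curves: list[GeneCurve]) -> np.ndarray:
    """Pairwise (1 - rho) / 2 over min-max normalized curves in [0, 1].

    Constant curves have undefined correlation; they sit at distance 0.5
    from everything (and 0 from themselves) and are flagged with a warning.
    """
    V = np.stack([c.normalized() for c in curves])
    sd = V.std(axis=1)
    constant = sd <= 1e-12
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant curve(s); assigned distance 0.5 "
            "to all other curves", stacklevel=3,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(V)
    C = np.nan_to_num(C, nan=0.0)  # constant rows -> rho 0 -> distance 0.5
    D = (1.0 - C) / 2.0
    np.fill_diagonal(D, 0.0)
    return D


def _pam(D: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic PAM: greedy BUILD then best-improvement SWAP."""
    n = D.shape[0]
    medoids = [int(np.argmin(D.sum(axis=1)))]
    while len(medoids) < k:
        current = D[:, medoids].min(axis=1)
        gains = np.maximum(current[None, :] - D, 0.0).sum(axis=1)
        gains[medoids] = -np.inf
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)

    def cost(meds):
        return D[:, meds].min(axis=1).sum()

    best_cost = cost(medoids)
    improved = True
    while improved:
        improved = False
        best_swap = None
        for mi, m in enumerate(medoids):
            for h in range(n):
                if h in medoids:
                    continue
                trial = sorted(medoids[:mi] + [h] + medoids[mi + 1:])
                c = cost(trial)
                if c < best_cost - 1e-12:
                    best_cost, best_swap = c, trial
        if best_swap is not None:
            medoids = best_swap
            improved = True
    assign = np.argmin(D[:, medoids], axis=1)
    return np.asarray(medoids), assign


def _mean_silhouette(D: np.ndarray, labels: np.ndarray) -> float:
    n = len(labels)
    ks = np.unique(labels)
    if len(ks) < 2:
        return 0.0
    s = np.zeros(n)
    for i in range(n):
        own = labels == labels[i]
        own[i] = False
        a = D[i, own].mean() if own.any() else 0.0
        b = min(D[i, labels == c].mean() for c in ks if c != labels[i])
        denom = max(a, b)
        s[i] = 0.0 if denom <= 0 else (b - a) / denom
    return float(s.mean())


def cluster_gene_curves(
    curves: list[GeneCurve],
    k: int | str = 2,
    k_range: tuple[int, int] = (2, 8),
    seed: int = 0,
) -> list[GeneModule]:
    """k-medoids (PAM) clustering of gene curves under correlation distance.

    With ``k="auto"`` the cluster count maximizing mean silhouette over
    ``k_range`` is used.  For k = 2 modules are labeled up/down from the
    sign of the medoid's end-minus-start value; otherwise each module gets
    the sign of its own medoid (``other`` when flat).
    """
    if len(curves) < 2:
        raise ValueError("need at least 2 curves")
    D = _correlation_distances(curves)
    if k == "auto":
        if D.max() <= 1e-12:
            warnings.warn("all curves identical; returning minimum k",
                          stacklevel=2)
            k = k_range[0]
        else:
            scores = {}
            for kk in range(k_range[0], min(k_range[1], len(curves) - 1) + 1):
                _, labels = _pam(D, kk)
                scores[kk] = _mean_silhouette(D, labels)
            k = max(scores, key=lambda kk: (scores[kk], -kk))
    k = int(k)
    if k > len(curves):
        raise ValueError("k exceeds number of curves")
    medoids, labels = _pam(D, k)
    modules = []
    for m_idx in range(k):
        members = [curves[i].gene_id for i in np.flatnonzero(labels == m_idx)]
        medoid = curves[int(medoids[m_idx])]
        delta = float(medoid.fitted[-1] - medoid.fitted[0])
        if delta > 1e-8:
            direction = "up"
        elif delta < -1e-8:
            direction = "down"
        else:
            direction = "other"
        modules.append(GeneModule(m_idx + 1, members, direction, medoid.gene_id))
    return modules
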