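"""Principal tree learning by reversed graph embedding (DDRTree).

Jointly learns a linear projection W (orthonormal columns), latent sample
representations Y, latent tree anchors Z, soft assignments R of samples to
anchors, and a spanning tree B over the anchors, by minimizing

    sum_i ||x_i - W y_i||^2
    + gamma * sum_{i,j} [ r_ij ||y_i - z_j||^2 + sigma * r_ij log r_ij ]
    + lambda * sum_{(j,j') in tree} ||z_j - z_j'||^2

subject to W^T W = I and each sample's assignment probabilities summing
to 1.  Alternating structure optimization solves each block exactly —
B by a minimum spanning tree over anchor distances, R in closed form
(soft-min with temperature sigma), Z by a linear solve, Y in closed form,
and W by orthogonal Procrustes — so the objective is non-increasing by
construction.

The input is centered internally (the model has no intercept); the column
mean is stored on the fitted model so that held-out data can be projected
and the objective re-evaluated consistently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "DdrtreeConfig",
    "LatentTreeModel",
    "ddrtree_fit",
    "objective_value",
    "tune_hyperparameters_elbow",
    "find_elbow",
]


@dataclass
class DdrtreeConfig:
    latent_dim: int = 3
    gamma: float = 5.0
    lambda_tree: float | str = 1.0
    sigma: float | str = 0.01
    n_latent_points: int | None = None  # default: one anchor per sample
    max_iters: int = 100
    tol: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        for name in ("lambda_tree", "sigma"):
            v = getattr(self, name)
            if isinstance(v, str):
                if v != "auto":
                    raise ValueError(f"{name} must be a positive float or 'auto'")
            elif v <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class LatentTreeModel:
    """Fitted principal tree in latent space."""

    W: np.ndarray  # (D, d), orthonormal columns
    Y: np.ndarray  # (d, I) latent sample representations
    Z: np.ndarray  # (d, K) latent tree anchors
    R: np.ndarray  # (I, K) soft assignments, rows sum to 1
    tree_edges: list[tuple[int, int]]  # K-1 undirected edges over anchors
    objective_trace: list[float]
    gamma: float
    sigma: float
    lambda_tree: float
    x_mean: np.ndarray  # (D,) column mean removed before fitting
    sample_ids: list[str] | None = None

    def validate(self, atol: float = 1e-8) -> None:
        d = self.W.shape[1]
        if np.abs(self.W.T @ self.W - np.eye(d)).max() > atol:
            raise ValueError("W columns are not orthonormal")
        row_sums = self.R.sum(axis=1)
        if np.abs(row_sums - 1.0).max() > atol or (self.R < -atol).any():
            raise ValueError("R rows are not probability vectors")
        K = self.Z.shape[1]
        if len(self.tree_edges) != K - 1:
            raise ValueError("tree must have exactly K-1 edges")
        # connectivity check via union-find
        parent = list(range(K))

        def find(a):
            while parent[a] != a:
                parent[a] = parent[parent[a]]
                a = parent[a]
            return a

        for u, v in self.tree_edges:
            ru, rv = find(u), find(v)
            if ru == rv:
                raise ValueError("tree edges contain a cycle")
            parent[ru] = rv
        if len({find(i) for i in range(K)}) != 1:
            raise ValueError("tree edges are not connected")

    def to_dict(self) -> dict:
        return {
            "W": self.W,
            "Y": self.Y,
            "Z": self.Z,
            "R": self.R,
            "tree_edges": [list(e) for e in self.tree_edges],
            "objective_trace": list(map(float, self.objective_trace)),
            "gamma": float(self.gamma),
            "sigma": float(self.sigma),
            "lambda_tree": float(self.lambda_tree),
            "x_mean": self.x_mean,
            "sample_ids": self.sample_ids,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LatentTreeModel":
        return cls(
            W=np.asarray(d["W"], dtype=float),
            Y=np.asarray(d["Y"], dtype=float),
            Z=np.asarray(d["Z"], dtype=float),
            R=np.asarray(d["R"], dtype=float),
            tree_edges=[tuple(e) for e in d["tree_edges"]],
            objective_trace=list(d["objective_trace"]),
            gamma=d["gamma"],
            sigma=d["sigma"],
            lambda_tree=d["lambda_tree"],
            x_mean=np.asarray(d["x_mean"], dtype=float),
            sample_ids=list(d["sample_ids"]) if d.get("sample_ids") else None,
        )


def _pca_init(Xc: np.ndarray, d: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic PCA: W from left singular vectors with fixed signs."""
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    W = U[:, :d]
    # sign convention: largest-|.| component of each column is positive
    for j in range(W.shape[1]):
        k = np.argmax(np.abs(W[:, j]))
        if W[k, j] < 0:
            W[:, j] = -W[:, j]
    return W, W.T @ Xc


def _mst_edges(Z: np.ndarray) -> list[tuple[int, int]]:
    """Exact MST over squared Euclidean anchor distances (Prim).

    Ties break by lowest vertex index (argmin is first-occurrence), so the
    result is deterministic.
    """
    d2 = cdist(Z.T, Z.T, metric="sqeuclidean")
    K = d2.shape[0]
    in_tree = np.zeros(K, dtype=bool)
    in_tree[0] = True
    min_dist = d2[0].copy()
    parent = np.zeros(K, dtype=int)
    edges: list[tuple[int, int]] = []
    for _ in range(K - 1):
        cand = np.where(in_tree, np.inf, min_dist)
        j = int(np.argmin(cand))
        edges.append((min(parent[j], j), max(parent[j], j)))
        in_tree[j] = True
        closer = d2[j] < min_dist
        min_dist = np.where(closer, d2[j], min_dist)
        parent = np.where(closer, j, parent)
    return sorted(edges)


def _soft_assign(Y: np.ndarray, Z: np.ndarray, sigma: float) -> np.ndarray:
    d2 = cdist(Y.T, Z.T, metric="sqeuclidean")
    logits = -d2 / sigma
    logits -= logits.max(axis=1, keepdims=True)
    R = np.exp(logits)
    R /= R.sum(axis=1, keepdims=True)
    return R


def _tree_laplacian(K: int, edges: list[tuple[int, int]]) -> np.ndarray:
    L = np.zeros((K, K))
    for u, v in edges:
        L[u, u] += 1.0
        L[v, v] += 1.0
        L[u, v] -= 1.0
        L[v, u] -= 1.0
    return L


def _objective_terms(Xc, W, Y, Z, R, edges, gamma, sigma, lam) -> float:
    recon = float(((Xc - W @ Y) ** 2).sum())
    d2 = cdist(Y.T, Z.T, metric="sqeuclidean")
    with np.errstate(divide="ignore", invalid="ignore"):
        rlogr = np.where(R > 0, R * np.log(R), 0.0)  # lim r->0 of r log r
    rep = float((R * d2).sum() + sigma * rlogr.sum())
    tree = float(
        sum(((Z[:, u] - Z[:, v]) ** 2).sum() for u, v in edges)
    )
    return recon + gamma * rep + lam * tree


def ddrtree_fit(
    X: np.ndarray,
    config: DdrtreeConfig | None = None,
    sample_ids: list[str] | None = None,
) -> LatentTreeModel:
    """Fit the principal tree to a features-by-samples matrix.

    ``X`` is (D, I): rows are features (selected genes), columns samples.
    Hyperparameters set to ``"auto"`` are tuned by the elbow method before
    the final fit.
    """
    config = config or DdrtreeConfig()
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite values")
    D, I = X.shape
    if I < config.latent_dim + 2:
        raise ValueError("need at least latent_dim + 2 samples")
    if config.lambda_tree == "auto" or config.sigma == "auto":
        lam, sig = tune_hyperparameters_elbow(X, config=config)
        config = DdrtreeConfig(
            latent_dim=config.latent_dim, gamma=config.gamma, lambda_tree=lam,
            sigma=sig, n_latent_points=config.n_latent_points,
            max_iters=config.max_iters, tol=config.tol, seed=config.seed,
        )
    gamma, sigma, lam = config.gamma, float(config.sigma), float(config.lambda_tree)

    x_mean = X.mean(axis=1)
    Xc = X - x_mean[:, None]

    d = config.latent_dim
    sv = np.linalg.svd(Xc, compute_uv=False)
    rank = int((sv > 1e-10 * max(sv[0], 1e-300)).sum())
    if rank < d:
        warnings.warn(f"input has rank {rank} < latent_dim {d}; shrinking d",
                      stacklevel=2)
        d = max(rank, 1)

    K = config.n_latent_points if config.n_latent_points is not None else I
    if K > I:
        raise ValueError(f"n_latent_points {K} exceeds number of samples {I}")

    W, Y = _pca_init(Xc, d)
    if K == I:
        Z = Y.copy()
    else:
        # deterministic spread: every (I/K)-th sample along the first PC
        order = np.argsort(Y[0], kind="stable")
        pick = order[np.linspace(0, I - 1, K).round().astype(int)]
        Z = Y[:, pick].copy()

    edges = _mst_edges(Z)
    R = _soft_assign(Y, Z, sigma)
    trace: list[float] = [_objective_terms(Xc, W, Y, Z, R, edges, gamma, sigma, lam)]

    for _ in range(config.max_iters):
        # B: exact MST over current anchors
        edges = _mst_edges(Z)
        # R: closed-form soft-min
        R = _soft_assign(Y, Z, sigma)
        # Z: linear solve  (gamma*diag(R^T 1) + lam*L) Z^T = gamma * (Y R)^T
        L = _tree_laplacian(K, edges)
        C = np.diag(R.sum(axis=0))
        Z = np.linalg.solve((gamma * C + lam * L).T, (gamma * (Y @ R)).T).T
        # Y: closed form
        Y = (W.T @ Xc + gamma * (Z @ R.T)) / (1.0 + gamma)
        # W: orthogonal Procrustes
        U, _, Vt = np.linalg.svd(Xc @ Y.T, full_matrices=False)
        W = U @ Vt
        obj = _objective_terms(Xc, W, Y, Z, R, edges, gamma, sigma, lam)
        trace.append(obj)
        prev = trace[-2]
        if abs(prev - obj) <= config.tol * max(1.0, abs(prev)):
            break

    # refresh the structural blocks against the final anchors so the stored
    # tree is the exact MST of Z (each refresh can only lower the objective)
    edges = _mst_edges(Z)
    R = _soft_assign(Y, Z, sigma)
    trace.append(_objective_terms(Xc, W, Y, Z, R, edges, gamma, sigma, lam))

    model = LatentTreeModel(
        W=W, Y=Y, Z=Z, R=R, tree_edges=edges, objective_trace=trace,
        gamma=gamma, sigma=sigma, lambda_tree=lam, x_mean=x_mean,
        sample_ids=list(sample_ids) if sample_ids is not None else None,
    )
    model.validate()
    return model


def objective_value(model: LatentTreeModel, X: np.ndarray) -> float:
    """The three-term objective at the model's parameters for data ``X``."""
    X = np.asarray(X, dtype=float)
    Xc = X - model.x_mean[:, None]
    return _objective_terms(
        Xc, model.W, model.Y, model.Z, model.R, model.tree_edges,
        model.gamma, model.sigma, model.lambda_tree,
    )


# ---------------------------------------------------------------------------
# Elbow tuning
# ---------------------------------------------------------------------------

def find_elbow(xs: np.ndarray, ys: np.ndarray, eps: float = 1e-8) -> int | None:
    """Index of the maximum-curvature knee of a curve, or None if flat.

    Both axes are normalized to [0, 1]; the knee is the interior point with
    the largest second difference magnitude.  Inputs may arrive unsorted;
    the returned index refers to the original order.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    order = np.argsort(xs, kind="stable")
    x, y = xs[order], ys[order]
    if len(x) < 3 or np.ptp(y) <= eps * max(1.0, np.abs(y).max()):
        return None
    xn = (x - x[0]) / np.ptp(x)
    yn = (y - y.min()) / np.ptp(y)
    curv = np.abs(yn[:-2] - 2 * yn[1:-1] + yn[2:]) / np.maximum(
        (xn[2:] - xn[:-2]) ** 2 / 4.0, 1e-12
    )
    if curv.max() <= eps:
        return None
    knee_sorted = int(np.argmax(curv)) + 1
    return int(order[knee_sorted])


def tune_hyperparameters_elbow(
    X: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    sigma_grid: np.ndarray | None = None,
    config: DdrtreeConfig | None = None,
) -> tuple[float, float]:
    """Choose (lambda_tree, sigma) at the elbow of the final-objective curve.

    Each parameter is scanned on a log axis with the other held at its grid
    median; a curve without a discernible knee falls back to the grid
    midpoint with a warning.
    """
    config = config or DdrtreeConfig()
    if lambda_grid is None:
        lambda_grid = np.logspace(-2, 2, 5)
    if sigma_grid is None:
        sigma_grid = np.logspace(-3, 0, 4)
    if len(lambda_grid) < 4 or len(sigma_grid) < 4:
        raise ValueError("grids need at least 4 values")

    def _fit_obj(lam: float, sig: float) -> float:
        cfg = DdrtreeConfig(
            latent_dim=config.latent_dim, gamma=config.gamma,
            lambda_tree=float(lam), sigma=float(sig),
            n_latent_points=config.n_latent_points,
            max_iters=min(config.max_iters, 30), tol=config.tol,
            seed=config.seed,
        )
        return ddrtree_fit(X, cfg).objective_trace[-1]

    sig_mid = float(np.sort(sigma_grid)[len(sigma_grid) // 2])
    objs = [_fit_obj(lam, sig_mid) for lam in lambda_grid]
    idx = find_elbow(np.log(lambda_grid), np.asarray(objs))
    if idx is None:
        warnings.warn("no elbow in lambda curve; using grid midpoint", stacklevel=2)
        idx = len(lambda_grid) // 2
    lam_star = float(lambda_grid[idx])

    objs = [_fit_obj(lam_star, sig) for sig in sigma_grid]
    idx = find_elbow(np.log(sigma_grid), np.asarray(objs))
    if idx is None:
        warnings.warn("no elbow in sigma curve; using grid midpoint", stacklevel=2)
        idx = len(sigma_grid) // 2
    sig_star = float(sigma_grid[idx])
    return lam_star, sig_star
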