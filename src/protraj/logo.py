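"""Large-margin local learning (LOGO) feature selection.

Disease-related genes are selected by learning a sparse non-negative
feature weight vector ``w`` that maximizes sample margins.  The margin of a
sample is the weighted Manhattan distance to its nearest neighbor of a
different class (nearest miss) minus the distance to its nearest neighbor
of the same class (nearest hit).  Because the true nearest neighbors in the
weighted metric are unknown before ``w`` is learned, an EM scheme treats
them as hidden variables: the E-step estimates neighbor probabilities with
an Epanechnikov kernel over the current weighted distances, and the M-step
minimizes the l1-regularized logistic margin loss

    (1/N) sum_n log(1 + exp(-w^T zbar_n)) + lambda * ||w||_1,   w >= 0,

where zbar_n is the probability-averaged margin vector.  The M-step uses
projected proximal gradient descent with backtracking; both steps are
deterministic, so the whole fit is reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LabeledDataset",
    "LogoConfig",
    "FeatureWeights",
    "margin_vector",
    "neighbor_probabilities",
    "logo_fit",
    "select_features",
    "choose_lambda_cv",
]


@dataclass
class LabeledDataset:
    """Samples-by-features matrix with per-sample class labels."""

    features: np.ndarray  # (n_samples, n_features)
    labels: np.ndarray  # (n_samples,) integer or string classes
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        n, p = self.features.shape
        if len(self.labels) != n:
            raise ValueError("labels length does not match sample count")
        if len(self.feature_ids) != p:
            raise ValueError("feature_ids length does not match feature count")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain missing/non-finite values")
        classes, counts = np.unique(self.labels, return_counts=True)
        if len(classes) < 2:
            raise ValueError("need at least 2 classes")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]


@dataclass
class LogoConfig:
    """Hyperparameters of the EM margin-loss fit.

    ``lambda_`` may be a float or ``"auto"`` (5-fold cross-validated over a
    logarithmic grid).  ``kernel_size`` is the number of nearest candidates
    kept in the E-step (the bandwidth is the distance to the
    ``kernel_size``-th nearest candidate).
    """

    lambda_: float | str = 0.01
    kernel_size: int = 5
    max_em_iters: int = 200
    tol: float = 1e-4
    retention_threshold: float = 1e-2
    seed: int = 0
    # few proximal steps per EM iteration: the weights and the neighbor
    # probabilities co-evolve gradually, which keeps the objective trace
    # descending instead of oscillating between neighbor configurations
    max_inner_iters: int = 3
    inner_tol: float = 1e-7

    def __post_init__(self) -> None:
        if self.kernel_size < 1:
            raise ValueError("kernel_size must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class FeatureWeights:
    """Non-negative feature relevance weights from a LOGO fit."""

    w: np.ndarray
    feature_ids: list[str]
    lambda_: float
    objective_trace: list[float] = field(default_factory=list)
    normalized: bool = False
    converged: bool = True

    def normalize(self) -> "FeatureWeights":
        """Divide by max(w); an all-zero vector is returned unchanged."""
        wmax = self.w.max() if self.w.size else 0.0
        w = self.w / wmax if wmax > 0 else self.w.copy()
        return FeatureWeights(
            w, self.feature_ids, self.lambda_, list(self.objective_trace),
            normalized=wmax > 0, converged=self.converged,
        )


def margin_vector(
    x: np.ndarray, nearest_hit: np.ndarray, nearest_miss: np.ndarray
) -> np.ndarray:
    """Elementwise margin contribution |x - NM| - |x - NH|.

    The sample margin under weights ``w`` is ``w @ margin_vector(...)``.
    """
    x = np.asarray(x, dtype=float)
    nh = np.asarray(nearest_hit, dtype=float)
    nm = np.asarray(nearest_miss, dtype=float)
    if not (x.shape == nh.shape == nm.shape):
        raise ValueError("margin_vector arguments must have equal length")
    return np.abs(x - nm) - np.abs(x - nh)


def _epanechnikov_probs(dists: np.ndarray, kernel_size: int) -> np.ndarray:
    """Probabilities over candidates given their weighted distances.

    Keeps the ``kernel_size`` nearest candidates (ties broken by index),
    scales their distances by the bandwidth (the distance of the
    kernel_size-th nearest) and applies k(u) = max(0, 1 - u^2).  Degenerate
    bandwidths fall back to uniform probabilities over the kept candidates.
    """
    m = len(dists)
    keep = min(kernel_size, m)
    order = np.argsort(dists, kind="stable")[:keep]
    probs = np.zeros(m)
    h = dists[order[-1]]
    if h <= 0:
        probs[order] = 1.0 / keep
        return probs
    u = dists[order] / h
    k = np.maximum(0.0, 1.0 - u**2)
    total = k.sum()
    if total <= 0:
        probs[order] = 1.0 / keep
    else:
        probs[order] = k / total
    return probs


def neighbor_probabilities(
    data: LabeledDataset, w: np.ndarray, config: LogoConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """E-step: per-sample hit/miss neighbor probabilities.

    Returns ``(P_hit, P_miss, valid)`` where the probability matrices are
    (n, n) with zeros outside each sample's candidate set, each valid row
    summing to 1.  ``valid`` flags samples that have at least one hit
    candidate (a sample alone in its class has none and is excluded with a
    warning).
    """
    X = data.features
    y = data.labels
    n = data.n_samples
    w = np.asarray(w, dtype=float)
    P_hit = np.zeros((n, n))
    P_miss = np.zeros((n, n))
    valid = np.ones(n, dtype=bool)
    for i in range(n):
        absdiff = np.abs(X - X[i])  # (n, p)
        d = absdiff @ w
        same = (y == y[i]) & (np.arange(n) != i)
        diff = y != y[i]
        if not same.any():
            valid[i] = False
            continue
        hit_idx = np.flatnonzero(same)
        miss_idx = np.flatnonzero(diff)
        P_hit[i, hit_idx] = _epanechnikov_probs(d[hit_idx], config.kernel_size)
        P_miss[i, miss_idx] = _epanechnikov_probs(d[miss_idx], config.kernel_size)
    if not valid.all():
        warnings.warn(
            f"{(~valid).sum()} sample(s) have no same-class candidate and are "
            "excluded from the margin loss",
            stacklevel=2,
        )
    return P_hit, P_miss, valid


def _expected_margins(data: LabeledDataset, P_hit, P_miss, valid) -> np.ndarray:
    """Probability-averaged margin vectors zbar_n (valid samples only)."""
    X = data.features
    rows = []
    for i in np.flatnonzero(valid):
        absdiff = np.abs(X - X[i])
        rows.append((P_miss[i] - P_hit[i]) @ absdiff)
    return np.asarray(rows)


def _estep_margins(
    data: LabeledDataset, w: np.ndarray, config: LogoConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Fused E-step: expected margin vectors without materializing the
    full probability matrices (one |X - x_i| pass per sample)."""
    X = data.features
    y = data.labels
    n = data.n_samples
    rows = []
    valid = np.ones(n, dtype=bool)
    idx = np.arange(n)
    for i in range(n):
        absdiff = np.abs(X - X[i])
        d = absdiff @ w
        same = (y == y[i]) & (idx != i)
        diff = y != y[i]
        if not same.any():
            valid[i] = False
            continue
        hit_idx = np.flatnonzero(same)
        miss_idx = np.flatnonzero(diff)
        p_hit = _epanechnikov_probs(d[hit_idx], config.kernel_size)
        p_miss = _epanechnikov_probs(d[miss_idx], config.kernel_size)
        rows.append(p_miss @ absdiff[miss_idx] - p_hit @ absdiff[hit_idx])
    if not valid.all():
        warnings.warn(
            f"{(~valid).sum()} sample(s) have no same-class candidate and are "
            "excluded from the margin loss",
            stacklevel=3,
        )
    return np.asarray(rows), valid


def _margin_objective(w: np.ndarray, Z: np.ndarray, lam: float) -> float:
    margins = Z @ w
    # stable log(1 + exp(-m))
    loss = np.logaddexp(0.0, -margins).mean()
    return float(loss + lam * w.sum())


def _m_step(
    w0: np.ndarray, Z: np.ndarray, lam: float, max_iters: int, tol: float
) -> np.ndarray:
    """Projected proximal gradient for the l1 logistic margin loss."""
    w = w0.copy()
    n = Z.shape[0]
    # start above the Lipschitz step; backtracking still guarantees descent
    step = 4.0 / max(1e-12, np.linalg.norm(Z, ord=2) ** 2 / (4.0 * n))
    obj = _margin_objective(w, Z, lam)
    for _ in range(max_iters):
        margins = Z @ w
        sig = 1.0 / (1.0 + np.exp(np.clip(margins, -500, 500)))  # sigma(-m)
        grad = -(sig @ Z) / n
        t = step
        for _bt in range(50):
            w_new = np.maximum(0.0, w - t * (grad + lam))
            obj_new = _margin_objective(w_new, Z, lam)
            if obj_new <= obj + 1e-12:
                break
            t *= 0.5
        if np.abs(w_new - w).max() <= tol * max(np.abs(w).max(), 1e-12):
            w, obj = w_new, obj_new
            break
        w, obj = w_new, obj_new
    return w


def logo_fit(data: LabeledDataset, config: LogoConfig | None = None) -> FeatureWeights:
    """EM fit of the sparse non-negative margin weights.

    The EM loop terminates when either the weight vector or the objective
    stops improving; an iterate that would raise the objective is discarded
    and the previous (best) iterate returned, so the recorded
    ``objective_trace`` is non-increasing on every run.
    """
    config = config or LogoConfig()
    lam = config.lambda_
    if lam == "auto":
        lam = choose_lambda_cv(data, config)
    lam = float(lam)

    p = data.n_features
    # scale-equivariant start: multiplying the data by c divides the initial
    # weights by c, so the whole trajectory (and the retained set, with
    # lambda rescaled by c) is invariant to the measurement scale
    spread = float(np.abs(data.features - data.features.mean(axis=0)).mean())
    w = np.full(p, 1.0 / max(spread, 1e-12))
    trace: list[float] = []
    converged = False
    for _ in range(config.max_em_iters):
        Z, valid = _estep_margins(data, w, config)
        if not valid.any():
            warnings.warn("no sample has hit candidates; returning zero weights",
                          stacklevel=2)
            return FeatureWeights(np.zeros(p), list(data.feature_ids), lam,
                                  trace, converged=False)
        w_new = _m_step(w, Z, lam, config.max_inner_iters, config.inner_tol)
        obj = _margin_objective(w_new, Z, lam)
        if trace and obj > trace[-1]:
            # the re-estimated neighbor probabilities no longer admit an
            # improving step: we are at the fixed point; keep the best iterate
            converged = True
            break
        trace.append(obj)
        wscale = max(np.abs(w).max(), np.abs(w_new).max(), 1e-12)
        delta = np.abs(w_new - w).max() / wscale
        w = w_new
        if delta < config.tol:
            converged = True
            break
    if not converged:
        warnings.warn("LOGO EM did not converge; returning best iterate",
                      stacklevel=2)
    if w.max() <= 0 and np.allclose(data.features, data.features[0]):
        warnings.warn("all samples identical; weights are zero", stacklevel=2)
    return FeatureWeights(w, list(data.feature_ids), lam, trace, converged=converged)


def select_features(
    weights: FeatureWeights, threshold: float = 1e-2
) -> list[str]:
    """Feature ids whose max-normalized weight exceeds ``threshold``.

    Returned in descending weight order; an all-zero weight vector yields
    an empty list (no normalization is performed).
    """
    if weights.w.size == 0 or weights.w.max() <= 0:
        return []
    norm = weights.w / weights.w.max()
    order = np.argsort(-norm, kind="stable")
    return [weights.feature_ids[i] for i in order if norm[i] > threshold]


def _weighted_1nn_accuracy(train: LabeledDataset, test_X, test_y, w) -> float:
    correct = 0
    for x, y in zip(test_X, test_y):
        d = np.abs(train.features - x) @ w
        correct += train.labels[np.argmin(d)] == y
    return correct / len(test_y)


def choose_lambda_cv(
    data: LabeledDataset,
    config: LogoConfig,
    grid: np.ndarray | None = None,
    n_folds: int = 5,
) -> float:
    """Pick lambda by stratified CV, scoring held-out 1-NN accuracy in the
    weighted Manhattan metric; ties resolve to the sparser (larger) lambda."""
    from sklearn.model_selection import StratifiedKFold

    if grid is None:
        grid = np.logspace(-3, 0, 5)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=config.seed)
    scores = np.zeros(len(grid))
    folds = list(skf.split(data.features, data.labels))
    for gi, lam in enumerate(grid):
        accs = []
        for train_idx, test_idx in folds:
            sub = LabeledDataset(
                data.features[train_idx], data.labels[train_idx],
                list(data.feature_ids),
            )
            cfg = LogoConfig(
                lambda_=float(lam), kernel_size=config.kernel_size,
                max_em_iters=min(config.max_em_iters, 60), tol=config.tol,
                seed=config.seed,
            )
            fw = logo_fit(sub, cfg)
            accs.append(
                _weighted_1nn_accuracy(
                    sub, data.features[test_idx], data.labels[test_idx], fw.w
                )
            )
        scores[gi] = np.mean(accs)
    best = np.flatnonzero(scores == scores.max())[-1]
    return float(grid[best])
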