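"""Cross-cohort state transfer.

A k-nearest-neighbor classifier under Pearson correlation distance carries
progression-state labels from a reference (discovery) cohort to an
independent cohort profiled on the same disease-related genes, and a
two-component Gaussian mixture infers binary fusion status from the
expression of a single marker gene (ERG-style).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["KnnModel", "knn_classify", "infer_fusion_status"]


@dataclass
class KnnModel:
    """Reference cohort for state transfer."""

    reference: np.ndarray  # (samples, genes)
    labels: np.ndarray  # (samples,) state labels
    gene_ids: list[str]
    k: int = 5

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.reference.shape[0] != len(self.labels):
            raise ValueError("reference rows must match labels")
        if self.reference.shape[1] != len(self.gene_ids):
            raise ValueError("reference columns must match gene_ids")
        if not self.gene_ids:
            raise ValueError("reference gene panel is empty")
        if not 1 <= self.k <= self.reference.shape[0]:
            raise ValueError("k must lie in [1, n_reference]")


def _pearson_distance_rows(queries: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """(n_query, n_ref) matrix of (1 - rho) / 2 distances between rows."""
    def standardize(M):
        Mc = M - M.mean(axis=1, keepdims=True)
        sd = Mc.std(axis=1, keepdims=True)
        return Mc / np.where(sd > 0, sd, np.nan)

    Q = standardize(queries)
    R = standardize(reference)
    rho = (Q @ R.T) / queries.shape[1]
    return (1.0 - rho) / 2.0


def knn_classify(
    model: KnnModel,
    queries: np.ndarray,
    query_gene_ids: list[str] | None = None,
) -> np.ndarray:
    """Majority-vote state per query under Pearson distance.

    Queries are restricted to the genes shared with the reference panel
    (at least 3 required).  Vote ties break by the smallest mean distance
    among the tied labels, then by the lower state id.  A zero-variance
    query has no defined correlation and falls back to Euclidean distance
    with a warning.
    """
    Q = np.atleast_2d(np.asarray(queries, dtype=float))
    R = model.reference
    if query_gene_ids is not None:
        shared = [g for g in model.gene_ids if g in set(query_gene_ids)]
        if len(shared) < 3:
            raise ValueError(
                f"only {len(shared)} genes shared with the reference; need >= 3"
            )
        if len(shared) < len(model.gene_ids):
            warnings.warn(
                f"restricting classifier to {len(shared)} shared genes",
                stacklevel=2,
            )
        qidx = {g: i for i, g in enumerate(query_gene_ids)}
        ridx = {g: i for i, g in enumerate(model.gene_ids)}
        Q = Q[:, [qidx[g] for g in shared]]
        R = R[:, [ridx[g] for g in shared]]

    D = _pearson_distance_rows(Q, R)
    flat = np.isnan(D).any(axis=1)
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} query sample(s) have zero variance; using "
            "Euclidean fallback", stacklevel=2,
        )
        for i in np.flatnonzero(flat):
            D[i] = np.linalg.norm(R - Q[i], axis=1)

    predictions = []
    for i in range(Q.shape[0]):
        order = np.argsort(D[i], kind="stable")[: model.k]
        votes: dict = {}
        for j in order:
            lbl = model.labels[j]
            cnt, dsum = votes.get(lbl, (0, 0.0))
            votes[lbl] = (cnt + 1, dsum + D[i, j])
        best = sorted(
            votes.items(),
            key=lambda kv: (-kv[1][0], kv[1][1] / kv[1][0], kv[0]),
        )[0][0]
        predictions.append(best)
    return np.asarray(predictions)


def infer_fusion_status(
    erg_expression: np.ndarray,
    threshold: float | None = None,
    min_separation_sd: float = 0.1,
    seed: int = 0,
) -> np.ndarray:
    """Infer +/-1 fusion status from one marker gene's expression.

    Default method fits a two-component Gaussian mixture and labels each
    sample by its posterior component (+1 for the high-mean component).  If
    the fitted components are closer than ``min_separation_sd`` pooled
    standard deviations the mixture is degenerate: all samples get -1 with
    a warning unless a fixed ``threshold`` is given (in which case labels
    are +1 where expression >= threshold).
    """
    x = np.asarray(erg_expression, dtype=float)
    if len(x) < 10:
        raise ValueError("need at least 10 samples to infer fusion status")
    if threshold is not None:
        return np.where(x >= threshold, 1, -1)

    from sklearn.mixture import GaussianMixture

    lo, hi = np.quantile(x, [0.25, 0.75])
    gm = GaussianMixture(
        n_components=2,
        means_init=[[lo], [hi]],
        random_state=seed,
        n_init=1,
    ).fit(x.reshape(-1, 1))
    means = gm.means_.ravel()
    pooled_sd = float(np.sqrt(gm.covariances_.ravel().mean()))
    if abs(means[1] - means[0]) < min_separation_sd * max(pooled_sd, 1e-12):
        warnings.warn(
            "fusion mixture is degenerate (components overlap); returning all -1",
            stacklevel=2,
        )
        return np.full(len(x), -1, dtype=int)
    high = int(np.argmax(means))
    post = gm.predict_proba(x.reshape(-1, 1))[:, high]
    return np.where(post >= 0.5, 1, -1)
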