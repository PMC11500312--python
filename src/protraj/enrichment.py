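"""Covariate, gene-set and genetic-event statistics on a progression model.

Contains the running-sum permutation enrichment of a binary covariate along
an ordered path, Spearman trend association for continuous covariates,
right-tailed Fisher gene-set enrichment, the successive-state driver-event
test, tumor mutation burden and genome instability metrics, and the exact
binomial test of state composition within a branch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import EventMatrix, GeneSetCollection
from .trajectory import SplineSpec, benjamini_hochberg, fit_spline_curve

__all__ = [
    "EnrichmentResult",
    "DriverTestResult",
    "GenomicMetrics",
    "running_sum_score",
    "running_sum_enrichment",
    "spearman_trend",
    "fisher_gene_set_enrichment",
    "transition_driver_test",
    "compute_tmb",
    "compute_gii",
    "binomial_state_enrichment",
]


@dataclass
class EnrichmentResult:
    covariate: str
    path: str
    n_plus: int
    n_minus: int
    score: float
    p_value: float
    n_permutations: int
    seed: int


@dataclass
class DriverTestResult:
    event_id: str
    transition: tuple[int, int]
    a: int  # event present, later state
    b: int  # event absent, later state
    c: int  # event present, earlier state
    d: int  # event absent, earlier state
    p_value: float
    fdr: float = np.nan


@dataclass
class GenomicMetrics:
    sample_id: str
    tmb: float = np.nan
    gii: float = np.nan


def _walk(labels: np.ndarray) -> np.ndarray:
    n_plus = int((labels == 1).sum())
    n_minus = int((labels == -1).sum())
    steps = np.where(labels == 1, 1.0 / n_plus, -1.0 / n_minus)
    return np.cumsum(steps)


def running_sum_score(labels: np.ndarray) -> float:
    """Signed maximum deviation from zero of the +1/N+, -1/N- walk.

    Positive means +1 labels concentrate at the beginning of the ordering.
    The walk always returns to zero after the last step; that closure is
    asserted on every call.
    """
    labels = np.asarray(labels)
    if not (labels == 1).any() or not (labels == -1).any():
        raise ValueError("labels must contain both +1 and -1")
    walk = _walk(labels)
    assert abs(walk[-1]) < 1e-9, "running sum must close at zero"
    i = int(np.argmax(np.abs(walk)))
    return float(walk[i])


def running_sum_enrichment(
    ordered_labels: np.ndarray,
    n_perm: int = 10000,
    seed: int = 0,
    covariate: str = "",
    path: str = "",
    sided: str = "two",
) -> EnrichmentResult:
    """Permutation test of the running-sum enrichment score.

    ``ordered_labels`` are +/-1 labels ordered by progression distance
    (missing values must be dropped beforehand; ties in distance broken by
    sample id upstream).  Significance permutes the labels along the path;
    the reported p uses the +1-smoothed estimator (1 + #extreme) /
    (1 + n_perm).  ``sided="two"`` compares permuted |score| against the
    observed |score|; ``sided="one"`` counts permuted scores at least as
    extreme in the observed direction.
    """
    labels = np.asarray(ordered_labels, dtype=float)
    labels = labels[~np.isnan(labels)]
    labels = labels.astype(int)
    observed = running_sum_score(labels)
    n = len(labels)
    n_plus = int((labels == 1).sum())
    n_minus = n - n_plus

    rng = np.random.default_rng(seed)
    # vectorized permutations: argsort of uniforms permutes the labels
    keys = rng.random((n_perm, n))
    perms = labels[np.argsort(keys, axis=1)]
    steps = np.where(perms == 1, 1.0 / n_plus, -1.0 / n_minus)
    walks = np.cumsum(steps, axis=1)
    idx = np.argmax(np.abs(walks), axis=1)
    perm_scores = walks[np.arange(n_perm), idx]
    if sided == "two":
        extreme = np.abs(perm_scores) >= abs(observed) - 1e-12
    elif sided == "one":
        if observed >= 0:
            extreme = perm_scores >= observed - 1e-12
        else:
            extreme = perm_scores <= observed + 1e-12
    else:
        raise ValueError("sided must be 'two' or 'one'")
    p = (1.0 + int(extreme.sum())) / (1.0 + n_perm)
    return EnrichmentResult(
        covariate, path, n_plus, n_minus, observed, float(p), n_perm, seed
    )


def spearman_trend(
    distances: np.ndarray,
    values: np.ndarray,
    spec: SplineSpec | None = None,
) -> tuple[float, float, "object"]:
    """Spearman rank correlation of a covariate with progression distance,
    plus a df=3 spline trend curve for reporting.

    Missing values are dropped pairwise.  Constant covariates have no
    defined correlation; rho is reported as 0 with p = 1.
    """
    d = np.asarray(distances, dtype=float)
    v = np.asarray(values, dtype=float)
    keep = ~(np.isnan(d) | np.isnan(v))
    d, v = d[keep], v[keep]
    if len(d) < 4:
        raise ValueError("need at least 4 paired observations")
    curve = fit_spline_curve(d, v, spec or SplineSpec())
    if np.ptp(v) <= 0:
        return 0.0, 1.0, curve
    rho, p = stats.spearmanr(d, v)
    return float(rho), float(p), curve


def fisher_gene_set_enrichment(
    module_genes: list[str],
    collection: GeneSetCollection,
    universe: list[str],
    fdr_threshold: float = 1e-2,
) -> pd.DataFrame:
    """Right-tailed Fisher (hypergeometric) enrichment of each gene set.

    The 2x2 compares module membership with set membership over the
    ``universe``; sets with no gene in the universe are skipped.  Returns a
    table with overlap counts, p, BH FDR and a significance flag.
    """
    uni = set(universe)
    module = set(module_genes) & uni
    if set(module_genes) - uni:
        raise ValueError("module genes must be a subset of the universe")
    rows = []
    for name, genes in collection.sets.items():
        in_uni = set(genes) & uni
        if not in_uni:
            rows.append((name, 0, 0, np.nan, "skipped: no overlap with universe"))
            continue
        k = len(module & in_uni)
        p = stats.hypergeom.sf(k - 1, len(uni), len(in_uni), len(module))
        rows.append((name, k, len(in_uni), float(p), ""))
    df = pd.DataFrame(
        rows, columns=["set_name", "overlap", "set_size_in_universe",
                       "p_value", "note"],
    )
    tested = df["p_value"].notna()
    fdr = np.full(len(df), np.nan)
    if tested.any():
        fdr[tested.to_numpy()] = benjamini_hochberg(df.loc[tested, "p_value"].to_numpy())
    df["fdr"] = fdr
    df["significant"] = df["fdr"] <= fdr_threshold
    return df


def transition_driver_test(
    events: EventMatrix,
    sample_states: dict[str, int],
    transitions: list[tuple[int, int]],
    fdr_threshold: float = 1e-2,
    pool_family: str = "all",
) -> list[DriverTestResult]:
    """Right-tailed Fisher test of event prevalence across state transitions.

    For every event and (earlier, later) state pair, tests whether the
    event is more prevalent in the later state.  BH correction pools all
    event x transition tests into one family by default
    (``pool_family="per_transition"`` adjusts within each transition).
    """
    sid_index = {s: i for i, s in enumerate(events.sample_ids)}
    results: list[DriverTestResult] = []
    for s_from, s_to in transitions:
        early = [sid_index[s] for s, st in sample_states.items()
                 if st == s_from and s in sid_index]
        late = [sid_index[s] for s, st in sample_states.items()
                if st == s_to and s in sid_index]
        if not early or not late:
            raise ValueError(f"transition ({s_from}, {s_to}) has an empty state")
        for j, ev in enumerate(events.event_ids):
            col = events.values[:, j]
            a = int(col[late].sum())
            b = len(late) - a
            c = int(col[early].sum())
            d = len(early) - c
            # right tail: P(X >= a) with X ~ Hypergeom(N, K=a+c, n=a+b)
            p = float(stats.hypergeom.sf(a - 1, a + b + c + d, a + c, a + b))
            results.append(DriverTestResult(ev, (s_from, s_to), a, b, c, d, p))
    if pool_family == "all":
        fdr = benjamini_hochberg(np.array([r.p_value for r in results]))
        for r, q in zip(results, fdr):
            r.fdr = float(q)
    elif pool_family == "per_transition":
        for s_from, s_to in transitions:
            group = [r for r in results if r.transition == (s_from, s_to)]
            fdr = benjamini_hochberg(np.array([r.p_value for r in group]))
            for r, q in zip(group, fdr):
                r.fdr = float(q)
    else:
        raise ValueError("pool_family must be 'all' or 'per_transition'")
    return results


def compute_tmb(mutation_counts: np.ndarray, interrogated_megabases: float) -> np.ndarray:
    """Somatic mutations per megabase of interrogated sequence."""
    if interrogated_megabases <= 0:
        raise ValueError("interrogated_megabases must be positive")
    return np.asarray(mutation_counts, dtype=float) / interrogated_megabases


def compute_gii(cnv_magnitudes: np.ndarray) -> np.ndarray:
    """Genome instability index: per-sample sum of |copy-number alteration|
    over genes.  ``cnv_magnitudes`` is (samples, genes)."""
    M = np.asarray(cnv_magnitudes, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("CNV magnitudes must be finite")
    return np.abs(M).sum(axis=1)


def binomial_state_enrichment(
    branch_labels: np.ndarray,
    target_state: int,
    background_proportion: float,
) -> float:
    """Exact binomial right-tail p for over-representation of one state.

    ``branch_labels`` are the classified states of the samples in a branch;
    the background proportion is typically the target state's frequency in
    the full cohort.
    """
    if not 0.0 < background_proportion < 1.0:
        raise ValueError("background_proportion must lie strictly in (0, 1)")
    labels = np.asarray(branch_labels)
    n = len(labels)
    if n == 0:
        raise ValueError("branch has no samples")
    k = int((labels == target_state).sum())
    return float(stats.binomtest(k, n, background_proportion,
                                 alternative="greater").pvalue)
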