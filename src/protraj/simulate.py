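"""Synthetic progression cohorts with planted ground truth.

The generator emulates the statistical structure the downstream analyses
assume: a normal cluster at the root of a trunk that bifurcates into two
major tumor limbs, each carrying one side branch (seven tumor states in
total), gene modules with smooth monotone or branch-dependent mean trends,
ordinal grade labels correlated with progression depth, a branch-exclusive
binary covariate (fusion status), and binary genetic events whose
prevalence jumps across chosen state transitions.

The fixed state topology::

    root --(state 1)--+--(state 2)--+--(state 3)
                      |             +--(state 4)   [side branch]
                      +--(state 5)--+--(state 6)
                                    +--(state 7)   [side branch]

Pseudotime is arc length from the root; state 1 spans [0, 1], states 2 and
5 span [1, 2], terminal states 3 and 6 span [2, 3] and the shorter side
branches 4 and 7 span [2, 2.7].  Informative gene means follow monotone
cubic (smoothstep) functions of pseudotime; branch-specific modules deviate
only after their branch point.  Non-informative genes are Gaussian noise
around a constant per-gene baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import EventMatrix, ExpressionMatrix, SampleAnnotation

__all__ = [
    "ModuleSpec",
    "EventSpec",
    "SimulationConfig",
    "GroundTruth",
    "simulate_progression_cohort",
    "simulate_null_cohort",
    "simulate_labeled_classes",
    "STATE_PARENT",
    "state_subtree",
]

# --- fixed latent topology -------------------------------------------------

STATE_PARENT: dict[int, int | None] = {1: None, 2: 1, 3: 2, 4: 2, 5: 1, 6: 5, 7: 5}
STATE_START: dict[int, float] = {1: 0.0, 2: 1.0, 3: 2.0, 4: 2.0, 5: 1.0, 6: 2.0, 7: 2.0}
STATE_LENGTH: dict[int, float] = {1: 1.0, 2: 1.0, 3: 1.0, 4: 0.7, 5: 1.0, 6: 1.0, 7: 0.7}
PSEUDOTIME_MAX = 3.0
# states on the fusion-positive and fusion-negative limbs
POSITIVE_LIMB = (5, 6, 7)
NEGATIVE_LIMB = (2, 3, 4)


def state_subtree(state: int) -> tuple[int, ...]:
    """All states in the subtree rooted at ``state`` (inclusive)."""
    members = [s for s in STATE_PARENT if s == state or _descends(s, state)]
    return tuple(sorted(members))


def _descends(s: int, ancestor: int) -> bool:
    p = STATE_PARENT[s]
    while p is not None:
        if p == ancestor:
            return True
        p = STATE_PARENT[p]
    return False


@dataclass(frozen=True)
class ModuleSpec:
    """A planted gene module.

    ``direction`` is ``up`` or ``down``; ``branch`` restricts the trend to
    the subtree rooted at that state (None means the trend follows global
    pseudotime on every path).
    """

    name: str
    direction: str  # "up" | "down"
    n_genes: int
    branch: int | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be up/down, got {self.direction!r}")
        if self.branch is not None and self.branch not in STATE_PARENT:
            raise ValueError(f"unknown branch state {self.branch}")


@dataclass(frozen=True)
class EventSpec:
    """A planted binary genetic event.

    Prevalence is ``prevalence_before`` outside the subtree rooted at the
    transition's later state and ``prevalence_after`` inside it.  A
    transition of None means a flat background event.
    """

    event_id: str
    transition: tuple[int, int] | None
    prevalence_before: float
    prevalence_after: float
    kind: str = "mutation"

    def __post_init__(self) -> None:
        for p in (self.prevalence_before, self.prevalence_after):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"prevalence {p} outside [0, 1]")


def default_modules(n_informative: int) -> list[ModuleSpec]:
    """Split ``n_informative`` genes over the six default planted modules."""
    weights = {
        "up_global": (0.20, "up", None),
        "down_global": (0.20, "down", None),
        "up_limb_neg": (0.15, "up", 2),
        "up_limb_pos": (0.15, "up", 5),
        "up_state4": (0.15, "up", 4),
        "up_state7": (0.15, "up", 7),
    }
    counts = {k: int(round(w * n_informative)) for k, (w, _, _) in weights.items()}
    drift = n_informative - sum(counts.values())
    counts["up_global"] += drift
    return [
        ModuleSpec(name, direction, counts[name], branch)
        for name, (_, direction, branch) in weights.items()
        if counts[name] > 0
    ]


def default_events() -> list[EventSpec]:
    return [
        EventSpec("ev_1to2", (1, 2), 0.10, 0.40),
        EventSpec("ev_1to5", (1, 5), 0.10, 0.40),
        EventSpec("ev_2to3", (2, 3), 0.10, 0.40, kind="deletion"),
        EventSpec("ev_5to6", (5, 6), 0.10, 0.40, kind="deletion"),
        EventSpec("flat_1", None, 0.15, 0.15),
        EventSpec("flat_2", None, 0.15, 0.15),
        EventSpec("flat_3", None, 0.15, 0.15, kind="amplification"),
        EventSpec("flat_4", None, 0.15, 0.15, kind="deletion"),
    ]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    n_normal: int = 40
    n_tumor_per_state: dict[int, int] = field(
        default_factory=lambda: {s: 60 for s in STATE_PARENT}
    )
    n_genes: int = 1000
    n_informative: int = 100
    noise_sd: float = 1.0
    effect_size: float = 2.0  # max mean shift along a path, log2 units
    module_spec: list[ModuleSpec] | None = None
    event_spec: list[EventSpec] | None = None
    grade_noise: float = 0.5
    p_mix: float = 0.5  # fusion-positive fraction within state 1
    baseline_mean: float = 5.0
    within_state_spread: float = 1.0  # fraction of segment length covered
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_normal <= 0 or self.n_genes <= 0:
            raise ValueError("counts must be positive")
        if any(n <= 0 for n in self.n_tumor_per_state.values()):
            raise ValueError("per-state tumor counts must be positive")
        if self.n_informative > self.n_genes:
            raise ValueError("n_informative exceeds n_genes")
        if self.module_spec is None:
            self.module_spec = default_modules(self.n_informative)
        if self.event_spec is None:
            self.event_spec = default_events()
        used = sum(m.n_genes for m in self.module_spec)
        if used > self.n_informative:
            raise ValueError(
                f"module_spec uses {used} genes but n_informative={self.n_informative}"
            )


@dataclass
class GroundTruth:
    """Planted truth paired with a simulated cohort."""

    pseudotime: pd.Series  # per sample, 0 at root
    state: pd.Series  # per sample; 0 denotes normal tissue
    gene_module: dict[str, str]  # informative gene -> module name
    modules: list[ModuleSpec]
    events: list[EventSpec]

    def informative_genes(self) -> list[str]:
        return list(self.gene_module)

    def path_states(self) -> dict[str, tuple[int, ...]]:
        """The four root-to-leaf paths as ordered state tuples."""
        return {
            "A": (1, 2, 3),
            "B": (1, 2, 4),
            "C": (1, 5, 6),
            "D": (1, 5, 7),
        }


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return 3.0 * u**2 - 2.0 * u**3


def _monotone_cubic(u: np.ndarray) -> np.ndarray:
    """Monotone cubic trend on [0, 1] with slope 1/2 at onset.

    Divergence between branches starts immediately at the branch point
    (nonzero initial slope) while remaining a smooth cubic polynomial, so
    the spline-fitting stage is tested against a trend family it does not
    trivially reproduce.
    """
    u = np.clip(u, 0.0, 1.0)
    return 0.5 * u + 0.5 * (3.0 * u**2 - 2.0 * u**3)


def _module_trend(
    mod: ModuleSpec, t: np.ndarray, states: np.ndarray, effect: float
) -> np.ndarray:
    """Planted mean shift for one module, per sample."""
    sign = 1.0 if mod.direction == "up" else -1.0
    if mod.branch is None:
        u = t / PSEUDOTIME_MAX
        mask = states >= 0  # everyone, including normals at t=0
    else:
        members = state_subtree(mod.branch)
        t0 = STATE_START[mod.branch]
        t1 = max(STATE_START[s] + STATE_LENGTH[s] for s in members)
        u = (t - t0) / (t1 - t0)
        mask = np.isin(states, members)
    shift = np.zeros_like(t)
    shift[mask] = sign * effect * _monotone_cubic(u[mask])
    return shift


def simulate_progression_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleAnnotation, EventMatrix, GroundTruth]:
    """Draw one cohort with planted trajectory structure.

    All randomness derives from ``config.seed``; identical configs give
    bit-identical outputs.
    """
    rng = np.random.default_rng(config.seed)

    # --- samples, states, pseudotime ---
    sample_ids: list[str] = [f"N{i + 1:03d}" for i in range(config.n_normal)]
    states = [0] * config.n_normal
    for s in sorted(config.n_tumor_per_state):
        n = config.n_tumor_per_state[s]
        sample_ids += [f"S{s}_{i + 1:03d}" for i in range(n)]
        states += [s] * n
    states_arr = np.asarray(states)
    n_samples = len(sample_ids)

    # pseudotime uniform over each state's segment; within_state_spread < 1
    # concentrates samples around the segment midpoint (0 = discrete states)
    t = np.zeros(n_samples)
    spread = float(np.clip(config.within_state_spread, 0.0, 1.0))
    for s in STATE_PARENT:
        mask = states_arr == s
        u = rng.uniform(size=mask.sum())
        u = 0.5 + spread * (u - 0.5)
        t[mask] = STATE_START[s] + STATE_LENGTH[s] * u

    # --- gene ids, module membership ---
    gene_ids = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    gene_module: dict[str, str] = {}
    cursor = 0
    module_members: dict[str, list[int]] = {}
    for mod in config.module_spec:
        idx = list(range(cursor, cursor + mod.n_genes))
        module_members[mod.name] = idx
        for g in idx:
            gene_module[gene_ids[g]] = mod.name
        cursor += mod.n_genes

    # --- expression: baseline + planted trend + Gaussian noise ---
    baseline = config.baseline_mean + rng.normal(scale=1.0, size=config.n_genes)
    means = np.tile(baseline[:, None], (1, n_samples))
    for mod in config.module_spec:
        shift = _module_trend(mod, t, states_arr, config.effect_size)
        means[module_members[mod.name], :] += shift[None, :]
    values = means + rng.normal(scale=config.noise_sd, size=means.shape)
    expr = ExpressionMatrix(gene_ids, list(sample_ids), values)

    # --- ordinal grade via ordered logit on pseudotime ---
    cutpoints = np.array([0.6, 1.2, 1.8, 2.4])
    eta = t / max(config.grade_noise, 1e-12)
    cum = 1.0 / (1.0 + np.exp(-(cutpoints[None, :] / max(config.grade_noise, 1e-12) - eta[:, None])))
    u = rng.uniform(size=n_samples)
    grade = (u[:, None] > cum).sum(axis=1)  # 0..4
    grade_f = grade.astype(float)
    grade_f[states_arr == 0] = np.nan  # normals carry no Gleason grade

    # --- fusion covariate: branch-exclusive, mixed in state 1 ---
    fusion = np.full(n_samples, np.nan)
    fusion[np.isin(states_arr, POSITIVE_LIMB)] = 1.0
    fusion[np.isin(states_arr, NEGATIVE_LIMB)] = -1.0
    in_state1 = states_arr == 1
    fusion[in_state1] = np.where(
        rng.uniform(size=in_state1.sum()) < config.p_mix, 1.0, -1.0
    )

    # --- auxiliary clinical covariates ---
    psa = np.exp(0.5 * t + rng.normal(scale=0.5, size=n_samples)) * 4.0
    psa[states_arr == 0] = np.nan
    p_high = _smoothstep(t / PSEUDOTIME_MAX)
    tstage_high = np.where(rng.uniform(size=n_samples) < p_high, 1.0, -1.0)
    tstage_high[states_arr == 0] = np.nan

    annot = SampleAnnotation(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "tissue": np.where(states_arr == 0, "normal", "tumor"),
                "grade_group": grade_f,
                "fusion": fusion,
                "tstage_high": tstage_high,
                "psa": psa,
            }
        )
    )

    # --- binary genetic events on tumor samples ---
    tumor_mask = states_arr > 0
    tumor_ids = [sid for sid, m in zip(sample_ids, tumor_mask) if m]
    tumor_states = states_arr[tumor_mask]
    ev_values = np.zeros((len(tumor_ids), len(config.event_spec)), dtype=int)
    kinds: dict[str, str] = {}
    for j, ev in enumerate(config.event_spec):
        p = np.full(len(tumor_ids), ev.prevalence_before)
        if ev.transition is not None:
            later = state_subtree(ev.transition[1])
            p[np.isin(tumor_states, later)] = ev.prevalence_after
        ev_values[:, j] = (rng.uniform(size=len(tumor_ids)) < p).astype(int)
        kinds[ev.event_id] = ev.kind
    events = EventMatrix(
        tumor_ids, [ev.event_id for ev in config.event_spec], ev_values, kinds
    )

    truth = GroundTruth(
        pseudotime=pd.Series(t, index=sample_ids),
        state=pd.Series(states_arr, index=sample_ids),
        gene_module=gene_module,
        modules=list(config.module_spec),
        events=list(config.event_spec),
    )
    return expr, annot, events, truth


def simulate_labeled_classes(
    n_samples: int = 200,
    n_features: int = 500,
    n_classes: int = 4,
    n_informative: int = 10,
    effect_size: float = 2.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Ordinal-class Gaussian data with a planted informative feature block.

    Informative feature means step by ``effect_size`` between adjacent
    classes (ordinal structure, like grade groups); the remaining features
    are pure noise.  Returns (features, labels, feature_ids); the first
    ``n_informative`` features are the informative ones.
    """
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, n_classes, size=n_samples)
    X = rng.normal(scale=noise_sd, size=(n_samples, n_features))
    X[:, :n_informative] += labels[:, None] * effect_size
    feature_ids = [f"F{j + 1:04d}" for j in range(n_features)]
    return X, labels, feature_ids


def simulate_null_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, SampleAnnotation, EventMatrix, GroundTruth]:
    """Same marginal noise model, but zero effect size and flat events.

    Every gene is exchangeable across samples; used for type-I-error
    calibration of the trajectory tests.
    """
    flat_events = [
        replace(ev, transition=None, prevalence_after=ev.prevalence_before)
        for ev in (config.event_spec or default_events())
    ]
    null_config = replace(config, effect_size=0.0, event_spec=flat_events)
    return simulate_progression_cohort(null_config)
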