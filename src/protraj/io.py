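"""Readers, writers and core data containers.

Formats handled here are deliberately plain: tab-separated expression and
event matrices, GMT gene-set files, and a versioned JSON file for fitted
models.  Missing covariate values are encoded as the literal ``NA`` and are
excluded per-test downstream, never imputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "SampleAnnotation",
    "GeneSetCollection",
    "EventMatrix",
    "GradeBinningScheme",
    "TCGA_GRADE_SCHEME",
    "GSE_GRADE_SCHEME",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_annotation",
    "write_annotation",
    "read_gmt",
    "write_gmt",
    "read_event_matrix",
    "write_event_matrix",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


class ParseError(ValueError):
    """Raised when a file cannot be parsed; message names the offending spot."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} id: {x!r}")
        seen.add(x)


@dataclass
class ExpressionMatrix:
    """Log-scale gene-by-sample expression matrix.

    ``values[g, s]`` is the expression of ``gene_ids[g]`` in
    ``sample_ids[s]``.  All values must be finite and ids unique.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError(
                f"expression matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression matrix contains non-finite values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:5]}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(genes, list(self.sample_ids), self.values[rows])

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = list(samples)
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in index]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:5]}")
        cols = [index[s] for s in samples]
        return ExpressionMatrix(list(self.gene_ids), samples, self.values[:, cols])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class SampleAnnotation:
    """Per-sample clinical annotation.

    One row per sample.  ``tissue`` is ``tumor`` or ``normal``;
    ``grade_group`` is an ordinal integer (NaN when unknown); binary
    covariates take values +1/-1 (NaN when unknown).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        for col in ("sample_id", "tissue"):
            if col not in t.columns:
                raise ValidationError(f"annotation missing column {col!r}")
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValidationError(f"duplicate sample id in annotation: {dup!r}")
        bad = set(t["tissue"].unique()) - {"tumor", "normal"}
        if bad:
            raise ValidationError(f"unknown tissue labels: {sorted(bad)}")
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return self.table["sample_id"].tolist()

    def tissue(self) -> pd.Series:
        return self.table.set_index("sample_id")["tissue"]

    def grade_group(self) -> pd.Series:
        if "grade_group" not in self.table.columns:
            return pd.Series(np.nan, index=self.table["sample_id"])
        return self.table.set_index("sample_id")["grade_group"].astype(float)

    def covariate(self, name: str) -> pd.Series:
        if name not in self.table.columns:
            raise KeyError(f"covariate {name!r} not in annotation")
        return self.table.set_index("sample_id")[name]

    def subset(self, samples: Iterable[str]) -> "SampleAnnotation":
        samples = list(samples)
        sub = self.table.set_index("sample_id").loc[samples].reset_index()
        return SampleAnnotation(sub)


@dataclass
class GeneSetCollection:
    """Named gene sets (GMT-style) with per-set descriptions."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]


EVENT_KINDS = ("mutation", "amplification", "deletion")


@dataclass
class EventMatrix:
    """Binary sample-by-event indicators for mutations and CNV focal peaks."""

    sample_ids: list[str]
    event_ids: list[str]
    values: np.ndarray  # samples x events, {0, 1}
    kinds: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=int)
        if self.values.size == 0:
            self.values = self.values.reshape(len(self.sample_ids), len(self.event_ids))
        if self.values.shape != (len(self.sample_ids), len(self.event_ids)):
            raise ValidationError(
                f"event matrix shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.event_ids)} events"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.event_ids, "event")
        if self.values.size and not np.isin(self.values, (0, 1)).all():
            bad = self.values[~np.isin(self.values, (0, 1))].flat[0]
            raise ValidationError(f"event matrix contains non-binary value {bad!r}")
        for ev, kind in self.kinds.items():
            if kind not in EVENT_KINDS:
                raise ValidationError(f"unknown event kind {kind!r} for {ev!r}")

    @property
    def n_events(self) -> int:
        return len(self.event_ids)

    def prevalence(self) -> pd.Series:
        with np.errstate(invalid="ignore"):
            p = self.values.mean(axis=0) if len(self.sample_ids) else np.zeros(0)
        return pd.Series(p, index=self.event_ids)


@dataclass(frozen=True)
class GradeBinningScheme:
    """Ordered Gleason-grade bins used as ordinal class labels.

    ``bins`` maps bin index (0 = least severe) to a label and a predicate on
    ``(primary, secondary)`` Gleason grades.  Two presets ship: the
    five-bin scheme used for cohorts with primary/secondary grades
    (GS<=6, 3+4, 4+3, 8, >=9) and the four-bin scheme on the summary score
    only (GS<=6, 7, 8, >=9).
    """

    name: str
    labels: tuple[str, ...]
    assign_fn: Callable[[int, int], int | None]

    def assign(self, primary: int, secondary: int) -> int | None:
        """Ordinal bin for a (primary, secondary) grade pair, or None."""
        return self.assign_fn(primary, secondary)

    def assign_summary(self, summary: int) -> int | None:
        # split the summary evenly; only schemes keyed on the sum support this
        return self.assign_fn(summary // 2 + summary % 2, summary // 2)


def _tcga_assign(primary: int, secondary: int) -> int | None:
    total = primary + secondary
    if total <= 6:
        return 0
    if (primary, secondary) == (3, 4):
        return 1
    if (primary, secondary) == (4, 3):
        return 2
    if total == 8:
        return 3
    if total >= 9:
        return 4
    return None


def _gse_assign(primary: int, secondary: int) -> int | None:
    total = primary + secondary
    if total <= 6:
        return 0
    if total == 7:
        return 1
    if total == 8:
        return 2
    return 3


TCGA_GRADE_SCHEME = GradeBinningScheme(
    "tcga", ("GS<=6", "GS=3+4", "GS=4+3", "GS=8", "GS>=9"), _tcga_assign
)
GSE_GRADE_SCHEME = GradeBinningScheme(
    "gse", ("GS<=6", "GS=7", "GS=8", "GS>=9"), _gse_assign
)

GRADE_SCHEMES = {"tcga": TCGA_GRADE_SCHEME, "gse": GSE_GRADE_SCHEME}


# ---------------------------------------------------------------------------
# Tabular readers / writers
# ---------------------------------------------------------------------------

def read_expression_matrix(
    path, orientation: str = "genes_in_rows", log_transform: bool = False
) -> ExpressionMatrix:
    """Read a TSV expression matrix.

    The first column holds row ids and the header row holds column ids (its
    first field is ignored).  With ``log_transform`` every value v is
    replaced by log2(v + 1).
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for j, col in enumerate(df.columns):
            for i, cell in enumerate(df[col]):
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ParseError(
                        f"malformed numeric cell {cell!r} at row {df.index[i]!r}, "
                        f"column {col!r} in {path}"
                    ) from None
        raise
    row_ids = [str(x) for x in df.index]
    col_ids = [str(x) for x in df.columns]
    if orientation == "samples_in_rows":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    if log_transform:
        if (values < 0).any():
            raise ValidationError("log transform requires non-negative values")
        values = np.log2(values + 1.0)
    return ExpressionMatrix(row_ids, col_ids, values)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene")


def read_annotation(path) -> SampleAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, na_values=["NA"])
    return SampleAnnotation(df)


def write_annotation(annot: SampleAnnotation, path) -> None:
    annot.table.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: name TAB description TAB gene ids, one set per line."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"GMT line {lineno} has {len(fields)} fields; expected >=3"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if name in sets:
                raise ValidationError(f"duplicate gene set {name!r} at line {lineno}")
            sets[name] = genes
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *genes]) + "\n")


def read_event_matrix(path, kind_map: Mapping[str, str] | None = None) -> EventMatrix:
    """Read a TSV of 0/1 indicators: sample rows, event columns.

    ``kind_map`` assigns a kind per event, either an explicit
    ``{event_id: kind}`` table or prefix-based via keys like ``"mut_"``.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy()
    if values.size and not np.isin(values, (0, 1)).all():
        bad = values[~np.isin(values, (0, 1))].flat[0]
        raise ValidationError(f"non-binary cell {bad!r} in event matrix {path}")
    event_ids = [str(c) for c in df.columns]
    kinds: dict[str, str] = {}
    if kind_map:
        for ev in event_ids:
            if ev in kind_map:
                kinds[ev] = kind_map[ev]
            else:
                for prefix, kind in kind_map.items():
                    if ev.startswith(prefix):
                        kinds[ev] = kind
                        break
    return EventMatrix([str(s) for s in df.index], event_ids, values, kinds)


def write_event_matrix(events: EventMatrix, path) -> None:
    pd.DataFrame(
        events.values, index=events.sample_ids, columns=events.event_ids
    ).to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# Model serialization (versioned JSON)
# ---------------------------------------------------------------------------

def _encode(obj):
    if isinstance(obj, np.ndarray):
        if not np.all(np.isfinite(obj)):
            raise ValidationError("refusing to save non-finite array")
        return {"__ndarray__": obj.tolist(), "dtype": str(obj.dtype)}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        if not np.isfinite(v):
            raise ValidationError("refusing to save non-finite value")
        return v
    raise TypeError(f"cannot serialize {type(obj)}")


def _decode(d):
    if "__ndarray__" in d:
        return np.asarray(d["__ndarray__"], dtype=d.get("dtype", "float64"))
    return d


def save_model(model, path) -> None:
    """Serialize a fitted model (LatentTreeModel or ProgressionModel) to JSON."""
    payload = {
        "format_version": MODEL_FORMAT_VERSION,
        "model_class": type(model).__name__,
        "state": model.to_dict(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, default=_encode)


def load_model(path):
    """Load a model written by :func:`save_model`; checks the format version."""
    from . import ddrtree, progression  # local import to avoid a cycle

    with open(path) as fh:
        try:
            payload = json.load(fh, object_hook=_decode)
        except json.JSONDecodeError as exc:
            raise ParseError(f"cannot parse model file {path}: {exc}") from exc
    version = payload.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValidationError(
            f"model file version {version!r} != supported {MODEL_FORMAT_VERSION}"
        )
    classes = {
        "LatentTreeModel": ddrtree.LatentTreeModel,
        "ProgressionModel": progression.ProgressionModel,
    }
    cls = classes.get(payload.get("model_class"))
    if cls is None:
        raise ValidationError(f"unknown model class {payload.get('model_class')!r}")
    return cls.from_dict(payload["state"])
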