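"""Respondent data containers, scale definitions and file I/O.

The analysis operates on a wide respondent-by-item table.  Each scale of
interest is a subset of the questionnaire's items, and the *position* of
every scale item within the full questionnaire (1-based) is carried
through the pipeline: it is the regressor of the screening statistic.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, InputError

logger = logging.getLogger("awarescreen")

__all__ = [
    "ResponseMatrix",
    "ScaleSpec",
    "AnalysisConfig",
    "read_responses",
    "apply_scale",
    "read_scale_specs",
]


@dataclass(frozen=True)
class ResponseMatrix:
    """Subjects-by-items numeric response table.

    Rows are subjects, columns are items; ``values`` is a float array in
    which missing responses are NaN.  Row order is meaningful (it is
    preserved from the input file) and subject ids and item labels are
    unique.
    """

    subject_ids: tuple
    item_labels: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        object.__setattr__(self, "item_labels", tuple(self.item_labels))
        if values.ndim != 2:
            raise InputError("values must be a 2-D array")
        n, m = values.shape
        if n != len(self.subject_ids):
            raise InputError(
                f"{len(self.subject_ids)} subject ids but {n} rows of data"
            )
        if m != len(self.item_labels):
            raise InputError(
                f"{len(self.item_labels)} item labels but {m} data columns"
            )
        if len(set(self.subject_ids)) != n:
            raise InputError("subject ids are not unique")
        if len(set(self.item_labels)) != m:
            raise InputError("item labels are not unique")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.subject_ids), columns=list(self.item_labels)
        )


@dataclass(frozen=True)
class ScaleSpec:
    """One scale: ordered (item label, questionnaire position) pairs.

    Positions are 1-based indices into the *full* questionnaire and must
    be strictly increasing.  A scale needs at least 3 items: the screen
    is a regression slope over item positions, and a fit through fewer
    than 3 points carries no information about lack of fit.
    """

    scale_name: str
    items: tuple

    def __post_init__(self) -> None:
        items = tuple((str(lab), int(pos)) for lab, pos in self.items)
        object.__setattr__(self, "items", items)
        if len(items) < 3:
            raise ConfigError(
                f"scale {self.scale_name!r}: at least 3 items required, got {len(items)}"
            )
        positions = [pos for _, pos in items]
        if any(p <= 0 for p in positions):
            raise ConfigError(f"scale {self.scale_name!r}: positions must be positive")
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ConfigError(
                f"scale {self.scale_name!r}: positions must be strictly increasing"
            )
        labels = [lab for lab, _ in items]
        if len(set(labels)) != len(labels):
            raise ConfigError(f"scale {self.scale_name!r}: duplicate item labels")

    @property
    def labels(self) -> tuple:
        return tuple(lab for lab, _ in self.items)

    @property
    def positions(self) -> np.ndarray:
        return np.array([pos for _, pos in self.items], dtype=int)

    @property
    def q(self) -> int:
        return len(self.items)


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable knobs of the screening pipeline.

    ``n_clusters`` is fixed at 2 (the method partitions respondents into
    exactly two subsets).  ``questionnaire_length`` is the declared total
    number of questionnaire items, used only to report the total change
    ``slope * length``; if None the largest scale position is used.
    """

    seed: int = 0
    bootstrap_replicates: int = 10000
    confidence_level: float = 0.95
    estimator: str = "reml"
    n_clusters: int = 2
    questionnaire_length: int | None = None

    def __post_init__(self) -> None:
        if self.n_clusters != 2:
            raise ConfigError("n_clusters is fixed at 2")
        if not 0.0 < self.confidence_level < 1.0:
            raise ConfigError("confidence_level must be in (0, 1)")
        if self.bootstrap_replicates < 1:
            raise ConfigError("bootstrap_replicates must be >= 1")
        if self.estimator not in ("reml", "anova"):
            raise ConfigError(f"unknown estimator {self.estimator!r}")


def read_responses(path: str | Path, id_column: str) -> ResponseMatrix:
    """Read a wide delimited response table (CSV/TSV, header row).

    Non-numeric cells become missing entries (NaN).  Row order is
    preserved.  Duplicate subject ids and a missing id column are input
    errors.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if id_column not in df.columns:
        raise InputError(f"id column {id_column!r} not found in {path}")
    ids = df[id_column].tolist()
    if len(set(ids)) != len(ids):
        raise InputError(f"duplicate subject ids in {path}")
    items = [c for c in df.columns if c != id_column]
    values = df[items].apply(pd.to_numeric, errors="coerce").to_numpy(dtype=float)
    return ResponseMatrix(subject_ids=ids, item_labels=items, values=values)


def apply_scale(rm: ResponseMatrix, spec: ScaleSpec) -> ResponseMatrix:
    """Restrict ``rm`` to one scale's items and its complete cases.

    Columns are reordered to follow the scale spec; subjects with any
    missing response on a scale item are dropped (complete-case analysis
    per scale, so each scale has its own N).  Idempotent.
    """
    missing = [lab for lab in spec.labels if lab not in rm.item_labels]
    if missing:
        raise ConfigError(
            f"scale {spec.scale_name!r}: items not in response matrix: {missing}"
        )
    col_index = {lab: j for j, lab in enumerate(rm.item_labels)}
    cols = [col_index[lab] for lab in spec.labels]
    sub = rm.values[:, cols]
    keep = ~np.isnan(sub).any(axis=1)
    n_kept = int(keep.sum())
    if n_kept < 2 * spec.q:
        logger.warning(
            "scale %s: only %d complete cases retained (fewer than 2*q = %d)",
            spec.scale_name,
            n_kept,
            2 * spec.q,
        )
    logger.info(
        "scale %s: %d of %d subjects retained (complete case)",
        spec.scale_name,
        n_kept,
        rm.n_subjects,
    )
    return ResponseMatrix(
        subject_ids=tuple(sid for sid, k in zip(rm.subject_ids, keep) if k),
        item_labels=spec.labels,
        values=sub[keep],
    )


def _items_from_config(entry) -> list:
    # accept {"label": pos, ...} mappings or [[label, pos], ...] pair lists
    if isinstance(entry, dict):
        pairs = [(str(lab), int(pos)) for lab, pos in entry.items()]
        pairs.sort(key=lambda lp: lp[1])
        return pairs
    return [(str(lab), int(pos)) for lab, pos in entry]


def read_scale_specs(path: str | Path) -> tuple[list[ScaleSpec], int | None]:
    """Read scale definitions from a YAML/JSON config file.

    Expected layout::

        questionnaire_length: 60   # optional
        scales:
          - name: optimism
            items: {i03: 3, i17: 17, i41: 41}

    Returns the scale specs and the declared questionnaire length (or
    None when absent).
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
    if not isinstance(doc, dict) or "scales" not in doc:
        raise ConfigError(f"{path}: expected a mapping with a 'scales' list")
    specs = []
    for entry in doc["scales"]:
        try:
            specs.append(
                ScaleSpec(scale_name=str(entry["name"]), items=_items_from_config(entry["items"]))
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"{path}: malformed scale entry {entry!r}") from exc
    length = doc.get("questionnaire_length")
    return specs, (int(length) if length is not None else None)
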