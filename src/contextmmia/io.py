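"""Domain types and tab-separated table I/O.

Expression matrices follow the GEO series-matrix convention: rows are
entities (miRNAs or gene symbols), columns are samples, one header line.
Class labels live in a separate two-column TSV.  Candidate-target tables
emulate TargetScan / mirSVR / PITA exports (miRNA, gene[, source]).
Literature relevance tables are (query_key, entity, score) records; a
record whose query key equals its entity supplies that entity's self
score (a proxy for its total literature volume).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("contextmmia")

CONTROL = "control"
TREATED = "treated"

#: float formatting used by every writer, so read-then-write round-trips.
FLOAT_FORMAT = "%.6g"


class ValidationError(ValueError):
    """Raised when an input file or value violates the data contracts."""


@dataclass(frozen=True)
class ExpressionMatrix:
    """Entity-by-sample expression values with an explicit scale flag.

    Parameters
    ----------
    values : pandas.DataFrame
        Rows indexed by unique entity ids, columns by unique sample ids.
    scale : {"linear", "log2"}
        Whether the stored values are raw intensities or already
        log2-transformed.  Downstream code log2(x+1)-transforms linear
        values before testing or correlating.
    """

    values: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValidationError(f"unknown scale flag {self.scale!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate entity ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if len(self.values) == 0:
            raise ValidationError("no entities")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValidationError("non-numeric expression values")
        if not np.isfinite(arr).all():
            raise ValidationError("expression values must be finite")
        if self.scale == "linear" and (arr < 0).any():
            raise ValidationError("negative intensities in a linear-scale matrix")

    @property
    def entity_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def log2_values(self, pseudocount: float = 1.0) -> pd.DataFrame:
        """Values on the log2 scale (log2(x + pseudocount) when linear)."""
        if self.scale == "log2":
            return self.values
        return np.log2(self.values + pseudocount)


@dataclass(frozen=True)
class ClassLabels:
    """Sample-to-class assignment for the two-class design."""

    assignment: Mapping[str, str]

    def __post_init__(self) -> None:
        bad = {s: c for s, c in self.assignment.items() if c not in (CONTROL, TREATED)}
        if bad:
            raise ValidationError(f"labels must be '{CONTROL}' or '{TREATED}', got {bad}")
        counts = self.class_counts()
        if min(counts.get(CONTROL, 0), counts.get(TREATED, 0)) < 2:
            raise ValidationError(f"need >= 2 samples per class, have {counts}")

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.assignment.values():
            counts[c] = counts.get(c, 0) + 1
        return counts

    def samples(self, cls: str) -> list[str]:
        return [s for s, c in self.assignment.items() if c == cls]

    def require_cover(self, sample_ids: Iterable[str]) -> None:
        missing = [s for s in sample_ids if s not in self.assignment]
        if missing:
            raise ValidationError(f"samples without class label: {missing}")


@dataclass(frozen=True)
class CandidatePair:
    """A database-supported miRNA-gene edge, later annotated with the
    Pearson correlation r of the pair's log expression and its negated
    value (the correlation score)."""

    mirna_id: str
    gene_id: str
    sources: frozenset[str] = frozenset()
    r: float | None = None

    @property
    def corr_score(self) -> float | None:
        return None if self.r is None else -self.r

    def with_correlation(self, r: float) -> "CandidatePair":
        return CandidatePair(self.mirna_id, self.gene_id, self.sources, float(r))


@dataclass
class LiteratureScoreTable:
    """Offline literature relevance scores keyed by (query_key, entity).

    ``query_scores[(k, e)]`` holds the relevance of entity ``e`` to the
    free-form query ``k``; ``self_scores[e]`` holds the entity's score
    against its own name, used as the literature-volume prior.  Absent
    lookups resolve to 0 so pairs without literature support still rank.
    """

    query_scores: dict[tuple[str, str], float] = field(default_factory=dict)
    self_scores: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for mapping in (self.query_scores, self.self_scores):
            for key, score in mapping.items():
                if not math.isfinite(score) or score < 0:
                    raise ValidationError(f"literature score for {key!r} must be finite and >= 0, got {score}")

    def query_score(self, query_key: str, entity: str) -> float:
        return self.query_scores.get((query_key, entity), 0.0)

    def self_score(self, entity: str) -> float:
        return self.self_scores.get(entity, 0.0)

    def copy(self) -> "LiteratureScoreTable":
        return LiteratureScoreTable(dict(self.query_scores), dict(self.self_scores))


def canonicalize_entity(name: str, kind: str = "gene", strip_species_prefix: bool = True) -> str:
    """Deterministic entity-name canonicalization: trim, case-fold, and
    (for miRNAs, optionally) strip a species prefix such as ``hsa-``.

    Arm-level naming (mir-155 vs mir-155-5p) is deliberately left
    untouched; names that tables disagree on simply fail to match and
    are handled by the callers' default-to-zero / drop rules.
    """
    if not isinstance(name, str) or not name.strip():
        raise ValidationError("entity name must be a non-empty string")
    out = name.strip().casefold()
    if kind == "mirna" and strip_species_prefix and out.startswith("hsa-"):
        out = out[len("hsa-"):]
    return out


def _read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kwargs)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: no entities (empty file)") from None


def read_expression(path: str | Path, scale: str = "linear") -> ExpressionMatrix:
    """Read an expression TSV (first column entity id, header of sample ids)."""
    df = _read_tsv(path, index_col=0)
    if len(df.columns) == 0:
        raise ValidationError(f"{path}: malformed header, no sample columns")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric expression cell ({exc})") from None
    try:
        return ExpressionMatrix(df, scale)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from None


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="entity", float_format=FLOAT_FORMAT)


def read_class_labels(path: str | Path) -> ClassLabels:
    """Read a two-column (sample_id, label) TSV without a header."""
    df = _read_tsv(path, header=None, names=["sample_id", "label"], dtype=str)
    if df["label"].isna().any():
        raise ValidationError(f"{path}: every sample needs a class label")
    return ClassLabels(dict(zip(df["sample_id"], df["label"])))


def write_class_labels(labels: ClassLabels, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sample, cls in labels.assignment.items():
            fh.write(f"{sample}\t{cls}\n")


def read_target_db(
    paths: list[str | Path],
    combine_mode: str = "union",
    strip_species_prefix: bool = True,
) -> dict[tuple[str, str], frozenset[str]]:
    """Read one or more candidate-target TSVs into a pair -> sources map.

    Each file has columns (miRNA, gene[, source]); a missing source
    column defaults to the file name stem.  ``union`` merges source sets
    across files; ``intersection`` keeps only pairs present in every file.
    """
    if not paths:
        raise ValidationError("no target database files given")
    if combine_mode not in ("union", "intersection"):
        raise ValidationError(f"unknown combine_mode {combine_mode!r}")
    per_file: list[dict[tuple[str, str], set[str]]] = []
    for path in paths:
        df = _read_tsv(path, header=None, dtype=str, comment="#")
        if df.shape[1] < 2:
            raise ValidationError(f"{path}: target table needs >= 2 columns (miRNA, gene)")
        stem = Path(path).stem
        pairs: dict[tuple[str, str], set[str]] = {}
        for row in df.itertuples(index=False):
            mirna = canonicalize_entity(str(row[0]), "mirna", strip_species_prefix)
            gene = canonicalize_entity(str(row[1]), "gene")
            source = str(row[2]) if df.shape[1] > 2 and not pd.isna(row[2]) else stem
            pairs.setdefault((mirna, gene), set()).add(source)
        per_file.append(pairs)

    merged: dict[tuple[str, str], set[str]] = {}
    for pairs in per_file:
        for key, sources in pairs.items():
            merged.setdefault(key, set()).update(sources)
    if combine_mode == "intersection":
        keep = set(per_file[0])
        for pairs in per_file[1:]:
            keep &= set(pairs)
        merged = {k: v for k, v in merged.items() if k in keep}
    return {k: frozenset(v) for k, v in merged.items()}


def read_literature_table(path: str | Path, strip_species_prefix: bool = True) -> LiteratureScoreTable:
    """Read (query_key, entity, score) records from TSV or JSON.

    JSON input is a list of ``{"query_key":..., "entity":..., "score":...}``
    objects.  Records whose query key equals the entity populate the
    self-score map; entity names are canonicalized, query keys are kept
    verbatim apart from trimming/case-folding.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text(encoding="utf-8"))
        rows = [(r["query_key"], r["entity"], r["score"]) for r in records]
    else:
        df = _read_tsv(path, header=None, dtype=str, comment="#")
        if df.shape[1] < 3:
            raise ValidationError(f"{path}: literature table needs 3 columns (query_key, entity, score)")
        rows = list(df.iloc[:, :3].itertuples(index=False, name=None))

    table = LiteratureScoreTable()
    for query_key, entity, score in rows:
        try:
            value = float(score)
        except (TypeError, ValueError):
            raise ValidationError(f"{path}: non-numeric score {score!r} for ({query_key}, {entity})") from None
        if not math.isfinite(value) or value < 0:
            raise ValidationError(f"{path}: score for ({query_key}, {entity}) must be finite and >= 0, got {value}")
        raw_key = str(query_key).strip().casefold()
        ent = canonicalize_entity(str(entity), "mirna", strip_species_prefix)
        if raw_key == ent or canonicalize_entity(raw_key, "mirna", strip_species_prefix) == ent:
            table.self_scores[ent] = value
        else:
            table.query_scores[(raw_key, ent)] = value
    return table


def write_literature_table(table: LiteratureScoreTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for (key, entity), score in sorted(table.query_scores.items()):
            fh.write(f"{key}\t{entity}\t{FLOAT_FORMAT % score}\n")
        for entity, score in sorted(table.self_scores.items()):
            fh.write(f"{entity}\t{entity}\t{FLOAT_FORMAT % score}\n")


def read_validated_pairs(path: str | Path, strip_species_prefix: bool = True) -> set[tuple[str, str]]:
    """Read a validated-interaction TSV (miRNA, gene) into canonical pairs."""
    df = _read_tsv(path, header=None, dtype=str, comment="#")
    if df.shape[1] < 2:
        raise ValidationError(f"{path}: validated-pair table needs 2 columns")
    return {
        (
            canonicalize_entity(str(row[0]), "mirna", strip_species_prefix),
            canonicalize_entity(str(row[1]), "gene"),
        )
        for row in df.itertuples(index=False)
    }
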