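"""End-to-end target ranking: a model object built from the four inputs
(paired expression matrices, class labels, target database, literature
scores) whose ``fit()`` runs DE selection -> candidate pairing ->
negative-correlation filtering -> omics score -> context score -> final
score -> ranking, and returns a results object carrying the ranked
table, all intermediates, stage counts and a run manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import __version__
from .context import ContextPosterior, posterior_from_table
from .de import differential_pvalues, diff_score, minmax_normalize, select_de
from .io import (
    ClassLabels,
    ExpressionMatrix,
    LiteratureScoreTable,
    ValidationError,
    read_class_labels,
    read_expression,
    read_literature_table,
    read_target_db,
)
from .pairing import build_candidates, correlate_pairs, filter_negative, omics_score
from .ranking import ScoredPair, pair_score, rank_pairs, ranked_frame, write_ranked

logger = logging.getLogger("contextmmia")

_CONFIG_RANGES = {
    "de_cutoff_mirna": (0.0, 1.0),
    "de_cutoff_mrna": (0.0, 1.0),
    "log_pseudocount": (0.0, float("inf")),
    "top_k": (1, 10**9),
}


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable knobs of a ranking run.

    de_cutoff_* : strict p-value cutoffs for DE selection (default 0.1;
        0.05 is the conventional stricter preset).
    fdr_correct : apply Benjamini-Hochberg to the p-values before the
        cutoff instead of using raw p-values (off by default).
    db_combine : how multiple target databases merge ("union" keeps any
        supported pair, "intersection" requires support in every file).
    correlation_samples : sample set pooled for the Pearson correlation
        ("all" pools both classes).
    top_k : number of top edges used by evaluation summaries.
    """

    de_cutoff_mirna: float = 0.1
    de_cutoff_mrna: float = 0.1
    fdr_correct: bool = False
    log_pseudocount: float = 1.0
    db_combine: str = "union"
    correlation_samples: str = "all"
    strip_species_prefix: bool = True
    top_k: int = 200

    def __post_init__(self) -> None:
        for key, (lo, hi) in _CONFIG_RANGES.items():
            v = getattr(self, key)
            if not lo < v <= hi:
                raise ValidationError(f"config {key}={v} out of range ({lo}, {hi}]")
        if self.db_combine not in ("union", "intersection"):
            raise ValidationError(f"db_combine must be union or intersection, got {self.db_combine!r}")
        if self.correlation_samples not in ("all", "per_class"):
            raise ValidationError(f"correlation_samples must be all or per_class, got {self.correlation_samples!r}")


def validate_config(raw: Mapping) -> PipelineConfig:
    """Build a config from a JSON-style mapping; unknown keys rejected."""
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValidationError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**raw)


class ContextMMIA:
    """Condition-specific miRNA-target ranking model.

    Parameters
    ----------
    mirna_expr, mrna_expr : ExpressionMatrix
        Paired matrices sharing the same sample columns in order.
    labels : ClassLabels
        control/treated assignment covering every sample.
    target_db : mapping (mirna, gene) -> source set
        Candidate edges from sequence-based target databases.
    literature : LiteratureScoreTable
        Offline (keyword, entity) relevance scores plus self scores.
    keyword : str
        The user's context keyword; treated as one opaque query key.
    """

    def __init__(
        self,
        mirna_expr: ExpressionMatrix,
        mrna_expr: ExpressionMatrix,
        labels: ClassLabels,
        target_db: Mapping[tuple[str, str], frozenset[str]],
        literature: LiteratureScoreTable,
        keyword: str,
        config: PipelineConfig | None = None,
    ) -> None:
        if mirna_expr.sample_ids != mrna_expr.sample_ids:
            raise ValidationError("miRNA and mRNA matrices must share identical sample columns")
        labels.require_cover(mirna_expr.sample_ids)
        if not keyword or not keyword.strip():
            raise ValidationError("keyword must be a non-empty string")
        self.mirna_expr = mirna_expr
        self.mrna_expr = mrna_expr
        self.labels = labels
        self.target_db = dict(target_db)
        self.literature = literature
        self.keyword = keyword.strip().casefold()
        self.config = config or PipelineConfig()

    @classmethod
    def from_files(
        cls,
        mirna_expr_path: str | Path,
        mrna_expr_path: str | Path,
        labels_path: str | Path,
        target_db_paths: list[str | Path],
        literature_path: str | Path,
        keyword: str,
        config: PipelineConfig | None = None,
        expression_scale: str = "linear",
    ) -> "ContextMMIA":
        config = config or PipelineConfig()
        strip = config.strip_species_prefix
        mirna = read_expression(mirna_expr_path, expression_scale)
        mirna = ExpressionMatrix(
            mirna.values.rename(index=lambda n: _canon(n, "mirna", strip)), mirna.scale
        )
        mrna = read_expression(mrna_expr_path, expression_scale)
        mrna = ExpressionMatrix(
            mrna.values.rename(index=lambda n: _canon(n, "gene", strip)), mrna.scale
        )
        model = cls(
            mirna,
            mrna,
            read_class_labels(labels_path),
            read_target_db(list(target_db_paths), config.db_combine, strip),
            read_literature_table(literature_path, strip),
            keyword,
            config,
        )
        model._input_paths = {
            "mirna_expr": str(mirna_expr_path),
            "mrna_expr": str(mrna_expr_path),
            "labels": str(labels_path),
            "target_db": [str(p) for p in target_db_paths],
            "literature": str(literature_path),
        }
        return model

    def fit(self) -> "ContextMMIAResults":
        """Run every stage and return the ranked results."""
        cfg = self.config
        counts: dict[str, int] = {
            "mirnas_in": len(self.mirna_expr.entity_ids),
            "genes_in": len(self.mrna_expr.entity_ids),
        }

        p_mirna = differential_pvalues(self.mirna_expr, self.labels, log_pseudocount=cfg.log_pseudocount)
        p_gene = differential_pvalues(self.mrna_expr, self.labels, log_pseudocount=cfg.log_pseudocount)
        sel_p_mirna, sel_p_gene = p_mirna, p_gene
        if cfg.fdr_correct:
            sel_p_mirna = _bh_adjust(p_mirna)
            sel_p_gene = _bh_adjust(p_gene)
        de_mirnas = select_de(sel_p_mirna, cfg.de_cutoff_mirna)
        de_genes = select_de(sel_p_gene, cfg.de_cutoff_mrna)
        counts["de_mirnas"] = len(de_mirnas)
        counts["de_genes"] = len(de_genes)
        if not de_mirnas or not de_genes:
            raise ValidationError(
                "differential-expression stage: no entities pass the cutoff "
                f"({len(de_mirnas)} miRNAs, {len(de_genes)} genes)"
            )

        candidates = build_candidates(self.target_db, de_mirnas, de_genes)
        counts["pairs_candidate"] = len(candidates)
        correlated = correlate_pairs(candidates, self.mirna_expr, self.mrna_expr, cfg.log_pseudocount)
        negative = filter_negative(correlated)
        counts["pairs_negative"] = len(negative)
        if not negative:
            raise ValidationError("pairing stage: no negatively correlated candidate pairs")

        # diff_n is normalized within molecular class over the DE-selected set
        diff_n_mirna = minmax_normalize({m: diff_score(p_mirna[m]) for m in sorted(de_mirnas)})
        diff_n_gene = minmax_normalize({g: diff_score(p_gene[g]) for g in sorted(de_genes)})

        # posterior denominator: entities that still compete after filtering
        mirna_set = sorted({p.mirna_id for p in negative})
        gene_set = sorted({p.gene_id for p in negative})
        post_mirna = posterior_from_table(self.literature, self.keyword, mirna_set)
        post_gene = posterior_from_table(self.literature, self.keyword, gene_set)

        scored = []
        for pair in negative:
            os_val = omics_score(diff_n_mirna[pair.mirna_id], pair.corr_score, diff_n_gene[pair.gene_id])
            pm, pg = post_mirna[pair.mirna_id], post_gene[pair.gene_id]
            cs_val = pm * pg
            scored.append(
                ScoredPair(
                    mirna_id=pair.mirna_id,
                    gene_id=pair.gene_id,
                    p_mirna=p_mirna[pair.mirna_id],
                    p_gene=p_gene[pair.gene_id],
                    diff_n_mirna=diff_n_mirna[pair.mirna_id],
                    diff_n_gene=diff_n_gene[pair.gene_id],
                    r=pair.r,
                    os=os_val,
                    post_mirna=pm,
                    post_gene=pg,
                    cs=cs_val,
                    score=pair_score(os_val, cs_val),
                )
            )
        ranked = rank_pairs(scored)
        counts["pairs_ranked"] = len(ranked)
        return ContextMMIAResults(
            model=self,
            ranked=ranked,
            p_mirna=p_mirna,
            p_gene=p_gene,
            diff_n_mirna=diff_n_mirna,
            diff_n_gene=diff_n_gene,
            posterior_mirna=post_mirna,
            posterior_gene=post_gene,
            stage_counts=counts,
        )


def _canon(name: str, kind: str, strip: bool) -> str:
    from .io import canonicalize_entity

    return canonicalize_entity(name, kind, strip)


def _bh_adjust(pvalues: Mapping[str, float]) -> dict[str, float]:
    keys = list(pvalues)
    _, q, _, _ = multipletests([pvalues[k] for k in keys], method="fdr_bh")
    return dict(zip(keys, q.tolist()))


@dataclass
class ContextMMIAResults:
    """Ranked pairs plus every intermediate of a fitted ranking model."""

    model: ContextMMIA
    ranked: list[ScoredPair]
    p_mirna: dict[str, float]
    p_gene: dict[str, float]
    diff_n_mirna: dict[str, float]
    diff_n_gene: dict[str, float]
    posterior_mirna: ContextPosterior
    posterior_gene: ContextPosterior
    stage_counts: dict[str, int] = field(default_factory=dict)

    @property
    def frame(self) -> pd.DataFrame:
        return ranked_frame(self.ranked)

    def save(self, path: str | Path) -> None:
        write_ranked(self.ranked, path)

    def manifest(self, seed: int | None = None) -> dict:
        """Reproducibility record: config, input checksums, stage counts."""
        checksums = {}
        for name, paths in getattr(self.model, "_input_paths", {}).items():
            if isinstance(paths, list):
                checksums[name] = [_sha256(p) for p in paths]
            else:
                checksums[name] = _sha256(paths)
        report = self.frame.to_csv(sep="\t", index=False, float_format="%.6g")
        return {
            "version": __version__,
            "keyword": self.model.keyword,
            "config": dataclasses.asdict(self.model.config),
            "seed": seed,
            "input_checksums": checksums,
            "stage_counts": dict(self.stage_counts),
            "report_sha256": hashlib.sha256(report.encode()).hexdigest(),
        }

    def write_manifest(self, path: str | Path, seed: int | None = None) -> None:
        Path(path).write_text(json.dumps(self.manifest(seed), indent=2, sort_keys=True) + "\n")

    def summary(self) -> str:
        """Human-readable run summary: stage counts and the top edges."""
        c = self.stage_counts
        lines = [
            "Context-aware miRNA target ranking",
            "==================================",
            f"keyword: {self.model.keyword}",
            f"miRNAs in: {c.get('mirnas_in', 0)}   DE-selected: {c.get('de_mirnas', 0)}",
            f"genes  in: {c.get('genes_in', 0)}   DE-selected: {c.get('de_genes', 0)}",
            f"candidate pairs: {c.get('pairs_candidate', 0)}   "
            f"negatively correlated: {c.get('pairs_negative', 0)}   ranked: {c.get('pairs_ranked', 0)}",
            "",
            "top pairs (rank, miRNA, gene, OS, CS, Score):",
        ]
        for p in self.ranked[:10]:
            lines.append(
                f"  {p.rank:>4}  {p.mirna_id:<14} {p.gene_id:<12} "
                f"{p.os:.4f}  {p.cs:.4f}  {p.score:.6f}"
            )
        return "\n".join(lines)


def _sha256(path: str) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(
    config_mapping: Mapping,
    out_path: str | Path,
    manifest_path: str | Path | None = None,
    seed: int | None = None,
) -> ContextMMIAResults:
    """File-level entry point: read inputs named in the config mapping,
    fit the model, write the ranked report and the run manifest."""
    raw = dict(config_mapping)
    paths = {
        key: raw.pop(key)
        for key in ("mirna_expr", "mrna_expr", "labels", "targets", "lit_scores", "keyword")
        if key in raw
    }
    missing = {"mirna_expr", "mrna_expr", "labels", "targets", "lit_scores", "keyword"} - set(paths)
    if missing:
        raise ValidationError(f"config missing required keys: {sorted(missing)}")
    scale = raw.pop("expression_scale", "linear")
    config = validate_config(raw)
    targets = paths["targets"]
    if isinstance(targets, str):
        targets = targets.split(",")
    model = ContextMMIA.from_files(
        paths["mirna_expr"], paths["mrna_expr"], paths["labels"],
        list(targets), paths["lit_scores"], paths["keyword"],
        config, expression_scale=scale,
    )
    results = model.fit()
    results.save(out_path)
    if manifest_path is not None:
        results.write_manifest(manifest_path, seed)
    return results
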