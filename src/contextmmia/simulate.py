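"""Synthetic two-class miRNA/mRNA study generator.

Emulates the statistical structure the ranking method assumes: a shared
paired sample set; a subset of "true" miRNAs shifted between classes on
the log2 scale; each true miRNA repressing one target gene through a
negative linear link (inducing both differential expression and
negative correlation); decoy genes as independent noise; a candidate
target database mixing the true edges with random decoys; and
literature tables where, under the matched keyword, the entities of
true pairs receive multiplicatively boosted relevance scores over an
exponential background.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    CONTROL,
    TREATED,
    ClassLabels,
    ExpressionMatrix,
    LiteratureScoreTable,
    ValidationError,
    write_class_labels,
    write_expression,
    write_literature_table,
)

MATCHED_KEYWORD = "matched"
MISMATCHED_KEYWORD = "mismatched"


@dataclass(frozen=True)
class SyntheticSpec:
    """Study-design parameters of a synthetic dataset.

    n_control, n_treated : samples per class.
    n_mirna, n_gene : entities on each matrix.
    n_true_pairs : number of injected miRNA-target interactions (one
        distinct miRNA and one distinct gene each).
    de_effect : mean log2 shift of true miRNAs in the treated class.
    target_slope : regression coefficient linking a true target gene to
        its miRNA's log2 value; must be negative.
    noise_sd : per-sample log2 noise standard deviation.
    n_decoy_pairs : random non-true edges added to the target database.
    lit_boost : multiplicative elevation of matched-keyword scores for
        entities of true pairs.
    base_lit_scale : mean of the exponential background score
        distribution.
    """

    n_control: int = 10
    n_treated: int = 10
    n_mirna: int = 30
    n_gene: int = 200
    n_true_pairs: int = 15
    de_effect: float = 2.0
    target_slope: float = -0.8
    noise_sd: float = 0.5
    n_decoy_pairs: int = 300
    lit_boost: float = 8.0
    base_lit_scale: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_control", "n_treated", "n_mirna", "n_gene", "n_true_pairs"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive")
        if self.n_true_pairs > min(self.n_mirna, self.n_gene):
            raise ValidationError("n_true_pairs cannot exceed min(n_mirna, n_gene)")
        if self.target_slope >= 0:
            raise ValidationError("target_slope must be negative")
        if self.noise_sd <= 0 or self.base_lit_scale <= 0 or self.lit_boost <= 0:
            raise ValidationError("noise_sd, base_lit_scale and lit_boost must be positive")


@dataclass
class SyntheticDataset:
    """One generated study plus its ground truth."""

    spec: SyntheticSpec
    mirna_expr: ExpressionMatrix
    mrna_expr: ExpressionMatrix
    labels: ClassLabels
    target_db: dict[tuple[str, str], frozenset[str]]
    lit_table_matched: LiteratureScoreTable
    lit_table_mismatched: LiteratureScoreTable
    truth: set[tuple[str, str]] = field(default_factory=set)

    @property
    def literature(self) -> LiteratureScoreTable:
        """Matched and mismatched query keys merged into one table."""
        merged = self.lit_table_matched.copy()
        merged.query_scores.update(self.lit_table_mismatched.query_scores)
        return merged

    def write(self, out_dir: str | Path) -> dict[str, str]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "mirna_expr": out / "mirna_expr.tsv",
            "mrna_expr": out / "mrna_expr.tsv",
            "labels": out / "labels.tsv",
            "targets": out / "targets.tsv",
            "lit_scores": out / "literature.tsv",
            "truth": out / "truth.tsv",
        }
        write_expression(self.mirna_expr, paths["mirna_expr"])
        write_expression(self.mrna_expr, paths["mrna_expr"])
        write_class_labels(self.labels, paths["labels"])
        with open(paths["targets"], "w", encoding="utf-8") as fh:
            for (mirna, gene), sources in sorted(self.target_db.items()):
                fh.write(f"{mirna}\t{gene}\t{';'.join(sorted(sources))}\n")
        write_literature_table(self.literature, paths["lit_scores"])
        with open(paths["truth"], "w", encoding="utf-8") as fh:
            for mirna, gene in sorted(self.truth):
                fh.write(f"{mirna}\t{gene}\n")
        return {k: str(v) for k, v in paths.items()}


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Draw one full synthetic study from the spec's distributions."""
    rng = np.random.default_rng(spec.seed)
    n_samples = spec.n_control + spec.n_treated
    samples = [f"s{i + 1}" for i in range(n_samples)]
    labels = ClassLabels(
        {s: (CONTROL if i < spec.n_control else TREATED) for i, s in enumerate(samples)}
    )
    treated_mask = np.array([0] * spec.n_control + [1] * spec.n_treated, dtype=float)

    mirnas = [f"mir-sim-{i + 1}" for i in range(spec.n_mirna)]
    genes = [f"gsyn{i + 1}" for i in range(spec.n_gene)]
    true_mirnas = list(rng.choice(spec.n_mirna, size=spec.n_true_pairs, replace=False))
    true_genes = list(rng.choice(spec.n_gene, size=spec.n_true_pairs, replace=False))
    truth = {(mirnas[m], genes[g]) for m, g in zip(true_mirnas, true_genes)}

    # miRNA matrix: per-entity baseline + noise; true miRNAs shifted in treated
    mirna_base = rng.normal(7.0, 1.0, size=spec.n_mirna)
    mirna_vals = (
        mirna_base[:, None]
        + rng.normal(0.0, spec.noise_sd, size=(spec.n_mirna, n_samples))
    )
    for m in true_mirnas:
        mirna_vals[m] += spec.de_effect * treated_mask

    # mRNA matrix: decoys independent; true targets linearly repressed
    gene_base = rng.normal(9.0, 1.0, size=spec.n_gene)
    mrna_vals = (
        gene_base[:, None]
        + rng.normal(0.0, spec.noise_sd, size=(spec.n_gene, n_samples))
    )
    for m, g in zip(true_mirnas, true_genes):
        intercept = gene_base[g] - spec.target_slope * mirna_base[m]
        mrna_vals[g] = (
            intercept
            + spec.target_slope * mirna_vals[m]
            + rng.normal(0.0, spec.noise_sd, size=n_samples)
        )

    mirna_expr = ExpressionMatrix(pd.DataFrame(mirna_vals, index=mirnas, columns=samples), "log2")
    mrna_expr = ExpressionMatrix(pd.DataFrame(mrna_vals, index=genes, columns=samples), "log2")

    # target DB: truth plus random decoy edges
    target_db: dict[tuple[str, str], frozenset[str]] = {
        pair: frozenset({"truthdb"}) for pair in truth
    }
    while len(target_db) < spec.n_true_pairs + spec.n_decoy_pairs:
        pair = (mirnas[rng.integers(spec.n_mirna)], genes[rng.integers(spec.n_gene)])
        if pair not in target_db:
            target_db[pair] = frozenset({"decoydb"})

    # literature tables: exponential background; matched keyword boosts
    # entities on true pairs multiplicatively
    true_entities = {e for pair in truth for e in pair}
    self_scores = {
        e: float(rng.exponential(spec.base_lit_scale * 4))
        for e in mirnas + genes
    }
    matched = LiteratureScoreTable(self_scores=dict(self_scores))
    mismatched = LiteratureScoreTable(self_scores=dict(self_scores))
    for e in mirnas + genes:
        base_m = float(rng.exponential(spec.base_lit_scale))
        base_x = float(rng.exponential(spec.base_lit_scale))
        matched.query_scores[(MATCHED_KEYWORD, e)] = (
            base_m * spec.lit_boost if e in true_entities else base_m
        )
        mismatched.query_scores[(MISMATCHED_KEYWORD, e)] = base_x

    return SyntheticDataset(
        spec=spec,
        mirna_expr=mirna_expr,
        mrna_expr=mrna_expr,
        labels=labels,
        target_db=target_db,
        lit_table_matched=matched,
        lit_table_mismatched=mismatched,
        truth=truth,
    )


def generate_worked_example() -> dict:
    """A fixed, hand-sized study (3 miRNAs x 4 genes x 6 samples, 5
    database edges) for demonstrations and exact step-by-step checks.

    All values are constants on the log2 scale, built so every database
    edge is negatively correlated: mir-wa is strongly induced and
    represses wg1/wg2, mir-wb moderately induced repressing wg2/wg3,
    mir-wc is flat.  The literature table favors mir-wa and wg1 under
    the keyword "breast cancer".
    """
    samples = ["s1", "s2", "s3", "s4", "s5", "s6"]
    labels = ClassLabels(dict(zip(samples, [CONTROL] * 3 + [TREATED] * 3)))
    mirna_expr = ExpressionMatrix(
        pd.DataFrame(
            {
                "mir-wa": [2.0, 2.2, 2.1, 5.0, 5.2, 5.1],
                "mir-wb": [4.0, 4.3, 3.9, 4.8, 5.1, 4.9],
                "mir-wc": [3.0, 3.1, 2.9, 3.05, 3.0, 3.15],
            }
        ).T.set_axis(samples, axis=1),
        "log2",
    )
    mrna_expr = ExpressionMatrix(
        pd.DataFrame(
            {
                "wg1": [8.2, 8.0, 8.15, 5.6, 5.4, 5.5],
                "wg2": [9.0, 8.8, 8.9, 7.0, 6.9, 7.1],
                "wg3": [6.5, 6.2, 6.6, 5.9, 5.7, 5.8],
                "wg4": [7.0, 6.9, 7.1, 6.95, 7.05, 6.9],
            }
        ).T.set_axis(samples, axis=1),
        "log2",
    )
    target_db = {
        ("mir-wa", "wg1"): frozenset({"dbA"}),
        ("mir-wa", "wg2"): frozenset({"dbA", "dbB"}),
        ("mir-wb", "wg2"): frozenset({"dbB"}),
        ("mir-wb", "wg3"): frozenset({"dbA"}),
        ("mir-wc", "wg4"): frozenset({"dbB"}),
    }
    keyword = "breast cancer"
    literature = LiteratureScoreTable(
        query_scores={
            (keyword, "mir-wa"): 120.0,
            (keyword, "mir-wb"): 15.0,
            (keyword, "wg1"): 200.0,
            (keyword, "wg2"): 40.0,
            (keyword, "wg3"): 5.0,
        },
        self_scores={
            "mir-wa": 500.0,
            "mir-wb": 80.0,
            "mir-wc": 10.0,
            "wg1": 1000.0,
            "wg2": 300.0,
            "wg3": 50.0,
            "wg4": 20.0,
        },
    )
    return {
        "mirna_expr": mirna_expr,
        "mrna_expr": mrna_expr,
        "labels": labels,
        "target_db": target_db,
        "literature": literature,
        "keyword": keyword,
        "truth": {("mir-wa", "wg1")},
        # permissive cutoff keeps all entities so every database edge
        # becomes a candidate
        "de_cutoff": 1.0,
    }
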