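"""Candidate pair construction, expression correlation, negative-correlation
filtering, and the omics score.

A candidate edge survives when the target database supports it, both
endpoints pass differential-expression selection, and the pair's log
expression is strictly negatively correlated across the paired samples.
The omics score is diff_n(miRNA) * (-r) * diff_n(gene), in [0, 1].
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping

import numpy as np

from .io import CandidatePair, ExpressionMatrix, ValidationError

logger = logging.getLogger("contextmmia")


def build_candidates(
    target_db: Mapping[tuple[str, str], frozenset[str]],
    de_mirnas: Iterable[str],
    de_genes: Iterable[str],
) -> list[CandidatePair]:
    """Database pairs whose endpoints both passed DE selection, in
    deterministic (miRNA, gene) lexicographic order."""
    de_mirnas, de_genes = set(de_mirnas), set(de_genes)
    pairs = [
        CandidatePair(mirna, gene, sources)
        for (mirna, gene), sources in sorted(target_db.items())
        if mirna in de_mirnas and gene in de_genes
    ]
    if not pairs:
        logger.warning("no candidate pairs: target DB and DE sets do not overlap")
    return pairs


def pearson_log_correlation(mirna_row: np.ndarray, gene_row: np.ndarray) -> float:
    """Pearson correlation of two already-log-scale expression rows.

    Returns NaN when either row has zero variance; callers drop such
    pairs rather than letting an undefined correlation pass the filter.
    """
    x = np.asarray(mirna_row, dtype=float)
    y = np.asarray(gene_row, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("correlation needs two equal-length 1-D sample vectors")
    if x.size < 3:
        raise ValidationError(f"correlation needs >= 3 paired samples, got {x.size}")
    xc, yc = x - x.mean(), y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0.0:
        return float("nan")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def correlate_pairs(
    pairs: Iterable[CandidatePair],
    mirna_expr: ExpressionMatrix,
    mrna_expr: ExpressionMatrix,
    log_pseudocount: float = 1.0,
) -> list[CandidatePair]:
    """Annotate each candidate with r over all paired samples (both
    classes pooled); zero-variance pairs are dropped and logged."""
    samples = mirna_expr.sample_ids
    if samples != mrna_expr.sample_ids:
        raise ValidationError("miRNA and mRNA matrices must share the same sample columns in order")
    m_log = mirna_expr.log2_values(log_pseudocount)
    g_log = mrna_expr.log2_values(log_pseudocount)
    out: list[CandidatePair] = []
    for pair in pairs:
        r = pearson_log_correlation(
            m_log.loc[pair.mirna_id].to_numpy(), g_log.loc[pair.gene_id].to_numpy()
        )
        if np.isnan(r):
            logger.info("dropping %s-%s: zero variance, correlation undefined", pair.mirna_id, pair.gene_id)
            continue
        out.append(pair.with_correlation(r))
    return out


def filter_negative(pairs: Iterable[CandidatePair]) -> list[CandidatePair]:
    """Keep only strictly negatively correlated pairs (r < 0), so the
    correlation score -r of every survivor lies in (0, 1]."""
    survivors = [p for p in pairs if p.r is not None and p.r < 0.0]
    if not survivors:
        logger.warning("no negatively correlated pairs survive the filter")
    return survivors


def omics_score(diff_n_mirna: float, corr_score: float, diff_n_gene: float) -> float:
    """Product of the two normalized differential scores and the
    correlation score; in [0, 1] for filtered pairs."""
    for name, v, lo, hi in (
        ("diff_n_mirna", diff_n_mirna, 0.0, 1.0),
        ("corr_score", corr_score, 0.0, 1.0),
        ("diff_n_gene", diff_n_gene, 0.0, 1.0),
    ):
        if not lo <= v <= hi:
            raise ValidationError(f"{name} must be in [{lo}, {hi}], got {v}")
    return diff_n_mirna * corr_score * diff_n_gene
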