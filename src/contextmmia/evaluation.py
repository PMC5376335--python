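"""Evaluation of ranked miRNA-target lists.

Metrics mirror the standard ways condition-specific target predictors
are benchmarked: the rank of an experimentally validated interaction,
the distinct genes among the top-K edges (the same gene is often
multiply targeted, so this set is smaller than K), how many validated
pairs land in the top K, how ranks move when the context keyword
changes, and a hypergeometric enrichment test of a gene set against
GMT-format pathway collections.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ValidationError
from .pipeline import ContextMMIA, ContextMMIAResults
from .ranking import ScoredPair

logger = logging.getLogger("contextmmia")

ABSENT = "absent"


def _pair_list(ranked: Iterable[ScoredPair]) -> list[ScoredPair]:
    return sorted(ranked, key=lambda p: p.rank if p.rank is not None else 0)


def rank_of_pair(ranked: Iterable[ScoredPair], mirna_id: str, gene_id: str) -> int | str:
    """1-based rank of an exact pair, or "absent" if it was filtered out
    upstream (not in the database, not DE, or not negatively correlated)."""
    for p in _pair_list(ranked):
        if p.mirna_id == mirna_id and p.gene_id == gene_id:
            return p.rank
    return ABSENT


def top_k_gene_set(ranked: Iterable[ScoredPair], k: int) -> set[str]:
    """Distinct gene ids among the top-k edges (size <= k)."""
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    return {p.gene_id for p in _pair_list(ranked)[:k]}


def count_validated_in_topk(
    ranked: Iterable[ScoredPair],
    validated: set[tuple[str, str]],
    k: int,
) -> int:
    """Number of validated (miRNA, gene) pairs among the top-k edges.

    Matching is exact on canonical ids; arm-level naming mismatches
    count as misses and are logged once per run.
    """
    top = _pair_list(ranked)[:k]
    hits = sum(1 for p in top if (p.mirna_id, p.gene_id) in validated)
    if hits == 0 and validated and top:
        near = {m for m, _ in validated} & {p.mirna_id.rsplit("-", 1)[0] for p in top}
        if near:
            logger.info("no validated hits; possible arm-naming mismatches for %s", sorted(near))
    return hits


def keyword_sensitivity(
    model: ContextMMIA,
    keywords: Sequence[str],
    validated_pair: tuple[str, str],
) -> dict[str, int | str]:
    """Rank of a validated pair under each keyword.

    Only the context score depends on the keyword, so the expression
    stages (p-values, correlations, omics scores) are computed once and
    reused across keywords.
    """
    from dataclasses import replace as dc_replace

    from .context import posterior_from_table
    from .ranking import pair_score, rank_pairs

    base = model.fit()
    mirna_set = sorted({p.mirna_id for p in base.ranked})
    gene_set = sorted({p.gene_id for p in base.ranked})
    out: dict[str, int | str] = {}
    for keyword in keywords:
        key = keyword.strip().casefold()
        post_m = posterior_from_table(model.literature, key, mirna_set)
        post_g = posterior_from_table(model.literature, key, gene_set)
        rescored = []
        for p in base.ranked:
            pm, pg = post_m[p.mirna_id], post_g[p.gene_id]
            cs = pm * pg
            rescored.append(
                dc_replace(p, post_mirna=pm, post_gene=pg, cs=cs, score=pair_score(p.os, cs), rank=None)
            )
        out[keyword] = rank_of_pair(rank_pairs(rescored), *validated_pair)
    return out


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read GMT pathway sets (name, description, members per line)."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValidationError(f"{path}: GMT line needs name, description, >=1 member: {line[:60]!r}")
        sets[fields[0]] = {g.strip().casefold() for g in fields[2:] if g.strip()}
    return sets


def hypergeometric_enrichment(
    query_genes: set[str],
    pathway_sets: Mapping[str, set[str]],
    background_genes: set[str],
) -> pd.DataFrame:
    """Over-representation test of a gene set against pathway sets.

    For each pathway, p = P(X >= observed overlap) under the
    hypergeometric null of drawing |query| genes from the background;
    Benjamini-Hochberg q-values are added.  Pathway members outside the
    background are ignored.
    """
    if not query_genes <= background_genes:
        raise ValidationError("query genes must be a subset of the background")
    n_bg, n_query = len(background_genes), len(query_genes)
    rows = []
    for name in sorted(pathway_sets):
        members = pathway_sets[name] & background_genes
        overlap = len(query_genes & members)
        # survival function at overlap-1 gives P(X >= overlap)
        p = float(stats.hypergeom.sf(overlap - 1, n_bg, len(members), n_query))
        rows.append({"pathway": name, "pathway_size": len(members), "overlap": overlap, "p_value": min(p, 1.0)})
    df = pd.DataFrame(rows)
    if len(df):
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    else:
        df["q_value"] = pd.Series(dtype=float)
    return df


def true_pair_rank_stats(results: ContextMMIAResults, truth: set[tuple[str, str]]) -> dict[str, float]:
    """Summary of where known true pairs land in a ranked list."""
    ranks = [
        r for r in (rank_of_pair(results.ranked, m, g) for m, g in sorted(truth)) if r != ABSENT
    ]
    n = len(results.ranked)
    return {
        "n_truth": len(truth),
        "n_recovered": len(ranks),
        "median_rank": float(np.median(ranks)) if ranks else float("nan"),
        "mean_rank": float(np.mean(ranks)) if ranks else float("nan"),
        "median_rank_fraction": float(np.median(ranks)) / n if ranks and n else float("nan"),
        "n_ranked": n,
    }
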