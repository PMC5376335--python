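"""Pair scoring, deterministic ranking, and the ranked-pair report."""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import pandas as pd

from .io import FLOAT_FORMAT, ValidationError

logger = logging.getLogger("contextmmia")

#: column order of the ranked-pair TSV report.
REPORT_COLUMNS = [
    "rank", "mirna", "gene", "p_mirna", "p_gene", "diff_n_mirna", "diff_n_gene",
    "r", "corr_score", "OS", "post_mirna", "post_gene", "CS", "Score",
]


@dataclass(frozen=True)
class ScoredPair:
    """A fully scored candidate edge with all intermediate quantities."""

    mirna_id: str
    gene_id: str
    p_mirna: float
    p_gene: float
    diff_n_mirna: float
    diff_n_gene: float
    r: float
    os: float
    post_mirna: float
    post_gene: float
    cs: float
    score: float
    rank: int | None = None

    @property
    def corr_score(self) -> float:
        return -self.r


def pair_score(os_value: float, cs_value: float) -> float:
    """Final pair score: omics score weighted by the context score."""
    for name, v in (("os", os_value), ("cs", cs_value)):
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name} must be in [0, 1], got {v}")
    return os_value * cs_value


def rank_pairs(pairs: Iterable[ScoredPair]) -> list[ScoredPair]:
    """Sort by score descending, ties by omics score descending, then by
    (miRNA, gene) ascending; assign 1-based ranks.

    When every context score is 0 (no literature signal for the keyword)
    the final scores are all 0 and the omics-score tie-break effectively
    ranks the list by OS; this is logged prominently.
    """
    pairs = list(pairs)
    if pairs and all(p.cs == 0.0 for p in pairs):
        logger.warning("all context scores are 0; ranking falls back to the omics score")
    ordered = sorted(pairs, key=lambda p: (-p.score, -p.os, p.mirna_id, p.gene_id))
    return [replace(p, rank=i + 1) for i, p in enumerate(ordered)]


def ranked_frame(pairs: Iterable[ScoredPair]) -> pd.DataFrame:
    rows = [
        {
            "rank": p.rank, "mirna": p.mirna_id, "gene": p.gene_id,
            "p_mirna": p.p_mirna, "p_gene": p.p_gene,
            "diff_n_mirna": p.diff_n_mirna, "diff_n_gene": p.diff_n_gene,
            "r": p.r, "corr_score": p.corr_score, "OS": p.os,
            "post_mirna": p.post_mirna, "post_gene": p.post_gene,
            "CS": p.cs, "Score": p.score,
        }
        for p in pairs
    ]
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_ranked(pairs: Iterable[ScoredPair], path: str | Path) -> None:
    """Write the ranked report as TSV, floats at 6 significant digits."""
    ranked_frame(pairs).to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_ranked(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
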