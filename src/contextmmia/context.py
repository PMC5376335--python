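"""Literature-based context scoring.

For a user keyword k, each entity's literature likelihood is
log2(score(k, entity) + 1) and its prior is log2(self_score + 1), a
proxy for how much literature exists about the entity at all.  Both are
min-max normalized over the set of competing entities (the miRNAs, or
genes, still in play after DE selection and negative-correlation
filtering) and combined by Bayes' rule into a posterior relevance

    P(entity | k) = lik_n * prior_n / sum over competitors of lik_n * prior_n.

The context score of a pair is the product of its two posteriors.
Score penalization — used to probe how a ranking reacts when specific
literature support is removed — is exposed as generic score adjustments
on the table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .de import minmax_normalize
from .io import LiteratureScoreTable, ValidationError


def literature_likelihood(best_score: float) -> float:
    """log2(score + 1) rescaling of a raw literature relevance score."""
    if best_score < 0:
        raise ValidationError(f"literature score must be >= 0, got {best_score}")
    return float(np.log2(best_score + 1.0))


def literature_prior(self_score: float) -> float:
    """log2(self_score + 1): the entity's overall literature volume."""
    if self_score < 0:
        raise ValidationError(f"self score must be >= 0, got {self_score}")
    return float(np.log2(self_score + 1.0))


@dataclass(frozen=True)
class ContextPosterior:
    """Per-entity posterior relevance to a keyword over a fixed
    denominator set of competing entities."""

    query_key: str
    denominator_set: tuple[str, ...]
    lik: Mapping[str, float]
    prior: Mapping[str, float]
    lik_n: Mapping[str, float]
    prior_n: Mapping[str, float]
    posterior: Mapping[str, float]

    def __getitem__(self, entity: str) -> float:
        return self.posterior.get(entity, 0.0)


def posterior(
    entities: Sequence[str],
    lik: Mapping[str, float],
    prior: Mapping[str, float],
) -> ContextPosterior:
    """Bayes-rule posteriors from likelihood and prior maps.

    Likelihoods and priors default to 0 for entities missing from the
    maps, are min-max normalized over the entity set (all 1.0 in the
    degenerate all-equal case), multiplied, and divided by their sum.
    If every product is 0 — no literature signal at all — every
    posterior is 0 rather than undefined.
    """
    entities = list(dict.fromkeys(entities))
    if not entities:
        raise ValidationError("posterior needs a non-empty entity set")
    lik_full = {e: float(lik.get(e, 0.0)) for e in entities}
    prior_full = {e: float(prior.get(e, 0.0)) for e in entities}
    lik_n = minmax_normalize(lik_full)
    prior_n = minmax_normalize(prior_full)
    products = {e: lik_n[e] * prior_n[e] for e in entities}
    total = sum(products.values())
    if total == 0.0:
        post = {e: 0.0 for e in entities}
    else:
        post = {e: v / total for e, v in products.items()}
    return ContextPosterior(
        query_key="",
        denominator_set=tuple(entities),
        lik=lik_full,
        prior=prior_full,
        lik_n=lik_n,
        prior_n=prior_n,
        posterior=post,
    )


def posterior_from_table(
    table: LiteratureScoreTable,
    query_key: str,
    entities: Sequence[str],
) -> ContextPosterior:
    """Posteriors for a keyword straight from a literature score table."""
    lik = {e: literature_likelihood(table.query_score(query_key, e)) for e in entities}
    prior = {e: literature_prior(table.self_score(e)) for e in entities}
    result = posterior(entities, lik, prior)
    object.__setattr__(result, "query_key", query_key)
    return result


def context_pair_score(post_mirna: float, post_gene: float) -> float:
    """Product of the miRNA and gene posteriors; in [0, 1]."""
    for name, v in (("post_mirna", post_mirna), ("post_gene", post_gene)):
        if not 0.0 <= v <= 1.0:
            raise ValidationError(f"{name} must be in [0, 1], got {v}")
    return post_mirna * post_gene


def penalize_scores(
    table: LiteratureScoreTable,
    adjustments: Iterable[tuple[str, str, float, str]],
) -> LiteratureScoreTable:
    """Return a new table with (query_key, entity, value, mode) adjustments.

    ``mode`` is ``"delta"`` (add, clamped at 0) or ``"set"`` (replace);
    a query key equal to the entity adjusts the self score.  The input
    table is left untouched.
    """
    out = table.copy()
    for query_key, entity, value, mode in adjustments:
        if mode not in ("delta", "set"):
            raise ValidationError(f"adjustment mode must be 'delta' or 'set', got {mode!r}")
        if query_key == entity:
            old = out.self_score(entity)
            out.self_scores[entity] = max(0.0, old + value) if mode == "delta" else max(0.0, float(value))
        else:
            old = out.query_score(query_key, entity)
            out.query_scores[(query_key, entity)] = (
                max(0.0, old + value) if mode == "delta" else max(0.0, float(value))
            )
    return out
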