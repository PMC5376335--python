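"""Straight-line brute-force reference scorer used only by the tests.

Every quantity is computed by direct, unoptimized transcription of the
scoring definitions — plain Python loops, no shared code with the
package under test — so agreement between the two is meaningful.
"""

from __future__ import annotations

import math


def oracle_welch_p(a: list[float], b: list[float]) -> float:
    """Two-sided Welch t-test p-value via the t survival function."""
    from scipy.stats import t as t_dist

    na, nb = len(a), len(b)
    ma = sum(a) / na
    mb = sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    if va == 0 and vb == 0:
        return 1.0 if math.isclose(ma, mb) else 1e-300
    se2 = va / na + vb / nb
    t = (ma - mb) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return max(2.0 * t_dist.sf(abs(t), df), 1e-300)


def oracle_diff(p: float) -> float:
    return -math.log2(max(p, 1e-300))


def oracle_minmax(values: dict) -> dict:
    lo = min(values.values())
    hi = max(values.values())
    if hi == lo:
        return {k: 1.0 for k in values}
    return {k: (v - lo) / (hi - lo) for k, v in values.items()}


def oracle_pearson(x: list[float], y: list[float]) -> float:
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((x[i] - mx) * (y[i] - my) for i in range(n))
    den = math.sqrt(sum((v - mx) ** 2 for v in x) * sum((v - my) ** 2 for v in y))
    return num / den


def oracle_posteriors(lik: dict, prior: dict) -> dict:
    if not lik:
        return {}
    lik_n = oracle_minmax(lik)
    prior_n = oracle_minmax(prior)
    prod = {e: lik_n[e] * prior_n[e] for e in lik}
    total = sum(prod.values())
    if total == 0:
        return {e: 0.0 for e in lik}
    return {e: v / total for e, v in prod.items()}


def oracle_score_all(
    mirna_values: dict[str, list[float]],
    gene_values: dict[str, list[float]],
    control_idx: list[int],
    treated_idx: list[int],
    target_db: set[tuple[str, str]],
    query_scores: dict[tuple[str, str], float],
    self_scores: dict[str, float],
    keyword: str,
    de_cutoff: float,
) -> dict:
    """Full pipeline by brute force on already-log2 values.

    Returns per-entity p, diff, diff_n, posteriors and per-pair r, OS,
    CS, Score, plus the final ranking as a list of (mirna, gene) in
    rank order using the same tie-break convention (score desc, OS
    desc, then lexicographic).
    """
    p_m = {
        m: oracle_welch_p([v[i] for i in control_idx], [v[i] for i in treated_idx])
        for m, v in mirna_values.items()
    }
    p_g = {
        g: oracle_welch_p([v[i] for i in control_idx], [v[i] for i in treated_idx])
        for g, v in gene_values.items()
    }
    de_m = {m for m, p in p_m.items() if p < de_cutoff}
    de_g = {g for g, p in p_g.items() if p < de_cutoff}

    diff_n_m = oracle_minmax({m: oracle_diff(p_m[m]) for m in de_m}) if de_m else {}
    diff_n_g = oracle_minmax({g: oracle_diff(p_g[g]) for g in de_g}) if de_g else {}

    pairs = []
    for mirna, gene in sorted(target_db):
        if mirna not in de_m or gene not in de_g:
            continue
        x, y = mirna_values[mirna], gene_values[gene]
        sx = sum((v - sum(x) / len(x)) ** 2 for v in x)
        sy = sum((v - sum(y) / len(y)) ** 2 for v in y)
        if sx == 0 or sy == 0:
            continue
        r = oracle_pearson(x, y)
        if r < 0:
            pairs.append((mirna, gene, r))

    mirna_set = sorted({m for m, _, _ in pairs})
    gene_set = sorted({g for _, g, _ in pairs})
    post_m = oracle_posteriors(
        {m: math.log2(query_scores.get((keyword, m), 0.0) + 1.0) for m in mirna_set},
        {m: math.log2(self_scores.get(m, 0.0) + 1.0) for m in mirna_set},
    )
    post_g = oracle_posteriors(
        {g: math.log2(query_scores.get((keyword, g), 0.0) + 1.0) for g in gene_set},
        {g: math.log2(self_scores.get(g, 0.0) + 1.0) for g in gene_set},
    )

    per_pair = {}
    for mirna, gene, r in pairs:
        os_val = diff_n_m[mirna] * (-r) * diff_n_g[gene]
        cs_val = post_m[mirna] * post_g[gene]
        per_pair[(mirna, gene)] = {
            "r": r,
            "OS": os_val,
            "CS": cs_val,
            "Score": os_val * cs_val,
        }
    order = sorted(
        per_pair,
        key=lambda k: (-per_pair[k]["Score"], -per_pair[k]["OS"], k[0], k[1]),
    )
    return {
        "p_mirna": p_m,
        "p_gene": p_g,
        "diff_n_mirna": diff_n_m,
        "diff_n_gene": diff_n_g,
        "post_mirna": post_m,
        "post_gene": post_g,
        "pairs": per_pair,
        "order": order,
    }
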