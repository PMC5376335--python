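"""Two-class differential expression: per-entity p-values, differential
scores, min-max normalization, and selection at a p-value cutoff.

The differential score of an entity is -log2 of its two-class p-value,
min-max normalized to [0, 1] within its molecular class so that the most
significant selected entity scores 1 and the least significant scores 0.
"""

from __future__ import annotations

from typing import Callable, Mapping

import numpy as np
from scipy import stats

from .io import CONTROL, TREATED, ClassLabels, ExpressionMatrix, ValidationError

#: p-values are clamped here before the log so underflow cannot produce
#: an infinite differential score.
P_CLAMP = 1e-300


def welch_t_pvalues(control: np.ndarray, treated: np.ndarray) -> np.ndarray:
    """Row-wise two-sided Welch t-test p-values.

    Degenerate rows (zero variance in both classes) get p = 1 when the
    class means agree and the clamp floor when they differ, keeping the
    result inside (0, 1].
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        result = stats.ttest_ind(control, treated, axis=1, equal_var=False)
    p = np.asarray(result.pvalue, dtype=float)
    var0 = (control.var(axis=1) == 0) & (treated.var(axis=1) == 0)
    equal_means = np.isclose(control.mean(axis=1), treated.mean(axis=1))
    p[var0 & equal_means] = 1.0
    p[var0 & ~equal_means] = P_CLAMP
    return np.clip(p, P_CLAMP, 1.0)


def differential_pvalues(
    expr: ExpressionMatrix,
    labels: ClassLabels,
    test: Callable[[np.ndarray, np.ndarray], np.ndarray] = welch_t_pvalues,
    log_pseudocount: float = 1.0,
) -> dict[str, float]:
    """Two-sided p-value per entity for the control-vs-treated contrast.

    Linear-scale matrices are log2(x + pseudocount)-transformed before
    testing; log-scale matrices are tested as stored.  The ``test`` hook
    accepts (control_rows, treated_rows) arrays and returns p-values,
    so another two-class statistic can be substituted.
    """
    labels.require_cover(expr.sample_ids)
    values = expr.log2_values(log_pseudocount)
    ctrl_cols = [s for s in expr.sample_ids if labels.assignment[s] == CONTROL]
    trt_cols = [s for s in expr.sample_ids if labels.assignment[s] == TREATED]
    if min(len(ctrl_cols), len(trt_cols)) < 2:
        raise ValidationError(
            f"need >= 2 samples per class on the matrix, have {len(ctrl_cols)} control / {len(trt_cols)} treated"
        )
    p = test(values[ctrl_cols].to_numpy(), values[trt_cols].to_numpy())
    return dict(zip(expr.entity_ids, p.tolist()))


def diff_score(p_value: float) -> float:
    """Differential score -log2(p), with p clamped at 1e-300."""
    if not 0.0 < p_value <= 1.0:
        raise ValidationError(f"p-value must be in (0, 1], got {p_value}")
    return float(-np.log2(max(p_value, P_CLAMP)))


def minmax_normalize(scores: Mapping[str, float]) -> dict[str, float]:
    """Min-max normalize a score map to [0, 1].

    When all inputs coincide (max == min) every entity maps to 1.0, so a
    single surviving entity does not zero out every downstream product.
    """
    if not scores:
        raise ValidationError("cannot normalize an empty score map")
    values = np.asarray(list(scores.values()), dtype=float)
    if not np.isfinite(values).all():
        raise ValidationError("scores must be finite")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return {k: 1.0 for k in scores}
    return {k: float((v - lo) / (hi - lo)) for k, v in scores.items()}


def select_de(pvalues: Mapping[str, float], cutoff: float) -> set[str]:
    """Entities with p strictly below the cutoff."""
    if not 0.0 < cutoff <= 1.0:
        raise ValidationError(f"cutoff must be in (0, 1], got {cutoff}")
    return {e for e, p in pvalues.items() if p < cutoff}
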