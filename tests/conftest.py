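from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from contextmmia import (
    ClassLabels,
    ContextMMIA,
    ExpressionMatrix,
    LiteratureScoreTable,
    PipelineConfig,
    generate_worked_example,
)


@pytest.fixture(scope="session")
def worked_example() -> dict:
    return generate_worked_example()


@pytest.fixture(scope="session")
def worked_example_results(worked_example):
    model = ContextMMIA(
        worked_example["mirna_expr"],
        worked_example["mrna_expr"],
        worked_example["labels"],
        worked_example["target_db"],
        worked_example["literature"],
        worked_example["keyword"],
        PipelineConfig(de_cutoff_mirna=1.0, de_cutoff_mrna=1.0),
    )
    return model.fit()


def random_instance(rng: np.random.Generator) -> dict:
    """A small random study for pipeline-vs-oracle equivalence sweeps.

    Sized <= 8 miRNAs x 15 genes x 12 samples; roughly half the miRNAs
    get a treated-class shift and each shifted miRNA represses one gene,
    so DE selection, correlation signs and literature signal all vary.
    """
    n_mirna = int(rng.integers(3, 9))
    n_gene = int(rng.integers(5, 16))
    n_ctrl = int(rng.integers(3, 7))
    n_trt = int(rng.integers(3, 7))
    samples = [f"s{i}" for i in range(n_ctrl + n_trt)]
    mirnas = [f"m{i}" for i in range(n_mirna)]
    genes = [f"g{i}" for i in range(n_gene)]
    shift = np.array([0.0] * n_ctrl + [1.0] * n_trt)

    mv = rng.normal(6, 1, (n_mirna, n_ctrl + n_trt)) + rng.normal(0, 0.4, (n_mirna, 1))
    gv = rng.normal(8, 1, (n_gene, n_ctrl + n_trt))
    true_m = rng.choice(n_mirna, size=max(1, n_mirna // 2), replace=False)
    true_g = rng.choice(n_gene, size=len(true_m), replace=False)
    for mi, gi in zip(true_m, true_g):
        mv[mi] += rng.uniform(1.0, 2.5) * shift
        gv[gi] = 14 - 0.9 * mv[mi] + rng.normal(0, 0.4, n_ctrl + n_trt)

    db = {(mirnas[mi], genes[gi]) for mi, gi in zip(true_m, true_g)}
    n_extra = int(rng.integers(3, 12))
    for _ in range(n_extra):
        db.add((mirnas[rng.integers(n_mirna)], genes[rng.integers(n_gene)]))

    query_scores = {}
    self_scores = {}
    keyword = "ctx"
    for e in mirnas + genes:
        if rng.random() < 0.8:
            query_scores[(keyword, e)] = float(rng.exponential(10))
        if rng.random() < 0.9:
            self_scores[e] = float(rng.exponential(40))

    return {
        "mirna_expr": ExpressionMatrix(pd.DataFrame(mv, index=mirnas, columns=samples), "log2"),
        "mrna_expr": ExpressionMatrix(pd.DataFrame(gv, index=genes, columns=samples), "log2"),
        "labels": ClassLabels(
            {s: ("control" if i < n_ctrl else "treated") for i, s in enumerate(samples)}
        ),
        "target_db": {pair: frozenset({"db"}) for pair in db},
        "literature": LiteratureScoreTable(dict(query_scores), dict(self_scores)),
        "keyword": keyword,
        "control_idx": list(range(n_ctrl)),
        "treated_idx": list(range(n_ctrl, n_ctrl + n_trt)),
        "de_cutoff": float(rng.choice([0.1, 0.3, 0.6, 1.0])),
    }
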