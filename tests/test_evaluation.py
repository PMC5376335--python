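import math
from itertools import combinations

import numpy as np
import pytest

from contextmmia import ContextMMIA, ScoredPair, ValidationError, generate_dataset, SyntheticSpec
from contextmmia.evaluation import (
    ABSENT,
    count_validated_in_topk,
    hypergeometric_enrichment,
    keyword_sensitivity,
    rank_of_pair,
    read_gmt,
    top_k_gene_set,
)


def _ranked(pairs):
    out = []
    for i, (m, g) in enumerate(pairs):
        out.append(
            ScoredPair(
                mirna_id=m, gene_id=g, p_mirna=0.01, p_gene=0.01,
                diff_n_mirna=1.0, diff_n_gene=1.0, r=-0.9, os=0.9,
                post_mirna=0.5, post_gene=0.5, cs=0.25,
                score=0.9 * 0.25 / (i + 1), rank=i + 1,
            )
        )
    return out


RANKED = _ranked([("m1", "g1"), ("m1", "g2"), ("m2", "g1"), ("m3", "g3"), ("m2", "g2")])


class TestRankLookups:
    def test_rank_of_present_absent_and_first(self):
        assert rank_of_pair(RANKED, "m2", "g1") == 3
        assert rank_of_pair(RANKED, "m9", "g9") == ABSENT
        assert rank_of_pair(RANKED, "m1", "g1") == 1

    def test_top_k_gene_set_dedups(self):
        assert top_k_gene_set(RANKED, 5) == {"g1", "g2", "g3"}
        assert top_k_gene_set(RANKED, 1) == {"g1"}
        assert top_k_gene_set(RANKED, 100) == {"g1", "g2", "g3"}

    def test_top_k_gene_set_size_bounded_by_k(self):
        for k in range(1, 8):
            assert len(top_k_gene_set(RANKED, k)) <= k

    def test_count_validated_and_monotonicity_in_k(self):
        validated = {("m1", "g2"), ("m2", "g2"), ("m9", "g9")}
        counts = [count_validated_in_topk(RANKED, validated, k) for k in range(1, 7)]
        assert counts == [0, 1, 1, 1, 2, 2]
        assert all(a <= b for a, b in zip(counts, counts[1:]))
        assert count_validated_in_topk(RANKED, set(), 5) == 0
        everything = {(p.mirna_id, p.gene_id) for p in RANKED}
        assert count_validated_in_topk(RANKED, everything, 3) == 3


class TestKeywordSensitivity:
    def test_matched_keyword_beats_mismatched_on_synthetic_study(self):
        ds = generate_dataset(SyntheticSpec(seed=7))
        model = ContextMMIA(
            ds.mirna_expr, ds.mrna_expr, ds.labels, ds.target_db,
            ds.literature, "matched",
        )
        pair = sorted(ds.truth)[0]
        ranks = keyword_sensitivity(model, ["matched", "mismatched", "matched"], pair)
        assert ranks["matched"] != ABSENT
        # identical score tables for identical keywords -> identical ranks
        assert len({k for k in ranks}) == 2

    def test_identical_tables_give_identical_ranks(self):
        ds = generate_dataset(SyntheticSpec(seed=3, n_gene=60, n_decoy_pairs=80))
        model = ContextMMIA(
            ds.mirna_expr, ds.mrna_expr, ds.labels, ds.target_db,
            ds.literature, "matched",
        )
        pair = sorted(ds.truth)[0]
        first = keyword_sensitivity(model, ["matched"], pair)
        second = keyword_sensitivity(model, ["matched"], pair)
        assert first == second


class TestHypergeometricEnrichment:
    def test_pathway_equal_to_background_is_certain(self):
        background = {f"g{i}" for i in range(30)}
        query = {f"g{i}" for i in range(8)}
        table = hypergeometric_enrichment(query, {"all": set(background)}, background)
        assert table.loc[0, "p_value"] == pytest.approx(1.0)

    def test_extreme_tail_closed_form(self):
        background = {f"g{i}" for i in range(20)}
        query = {f"g{i}" for i in range(5)}
        table = hypergeometric_enrichment(query, {"hit": set(query)}, background)
        assert table.loc[0, "p_value"] == pytest.approx(1.0 / math.comb(20, 5), rel=1e-12)

    def test_matches_exhaustive_enumeration(self):
        background = {f"g{i}" for i in range(9)}
        pathway = {"g0", "g1", "g2", "g3"}
        query = {"g0", "g1", "g4", "g5"}
        observed = len(query & pathway)
        total = hits = 0
        for draw in combinations(sorted(background), len(query)):
            total += 1
            if len(set(draw) & pathway) >= observed:
                hits += 1
        table = hypergeometric_enrichment(query, {"p": pathway}, background)
        assert table.loc[0, "p_value"] == pytest.approx(hits / total, rel=1e-12)

    def test_q_values_monotone_in_p_order(self):
        rng = np.random.default_rng(41)
        background = {f"g{i}" for i in range(60)}
        query = set(rng.choice(sorted(background), 15, replace=False))
        pathways = {
            f"p{j}": set(rng.choice(sorted(background), rng.integers(5, 25), replace=False))
            for j in range(12)
        }
        table = hypergeometric_enrichment(query, pathways, background).sort_values("p_value")
        q = table["q_value"].to_numpy()
        assert (np.diff(q) >= -1e-12).all()
        assert ((table["p_value"] > 0) & (table["p_value"] <= 1)).all()

    def test_query_outside_background_rejected(self):
        with pytest.raises(ValidationError):
            hypergeometric_enrichment({"x"}, {}, {"a", "b"})


class TestGMT:
    def test_read_gmt_round_trip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("apoptosis\tdesc\tBCL2\tTP53\ncycle\tdesc\tCCND1\n")
        sets = read_gmt(path)
        assert sets == {"apoptosis": {"bcl2", "tp53"}, "cycle": {"ccnd1"}}

    def test_malformed_line_rejected(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("lonely\tdesc\n")
        with pytest.raises(ValidationError):
            read_gmt(path)
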