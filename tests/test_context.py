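import numpy as np
import pytest

from contextmmia import (
    LiteratureScoreTable,
    ValidationError,
    context_pair_score,
    literature_likelihood,
    literature_prior,
    penalize_scores,
    posterior,
    posterior_from_table,
)
from oracle import oracle_posteriors


class TestLogTransforms:
    @pytest.mark.parametrize("score,expected", [(0, 0.0), (1, 1.0), (7, 3.0)])
    def test_likelihood_log_scale(self, score, expected):
        assert literature_likelihood(score) == pytest.approx(expected)

    @pytest.mark.parametrize("score,expected", [(0, 0.0), (3, 2.0), (63, 6.0)])
    def test_prior_log_scale(self, score, expected):
        assert literature_prior(score) == pytest.approx(expected)

    def test_negative_scores_rejected(self):
        with pytest.raises(ValidationError):
            literature_likelihood(-1)
        with pytest.raises(ValidationError):
            literature_prior(-0.5)


class TestPosterior:
    def test_symmetric_entities_split_evenly(self):
        result = posterior(["a", "b"], {"a": 3.0, "b": 3.0}, {"a": 2.0, "b": 2.0})
        assert result.posterior == {"a": 0.5, "b": 0.5}

    def test_single_entity_gets_probability_one(self):
        result = posterior(["only"], {"only": 4.0}, {"only": 1.0})
        assert result.posterior == {"only": 1.0}

    def test_matches_direct_bayes_evaluation(self):
        rng = np.random.default_rng(17)
        for _ in range(30):
            entities = [f"e{i}" for i in range(5)]
            lik = {e: float(rng.exponential(4)) for e in entities}
            prior = {e: float(rng.exponential(20)) for e in entities}
            result = posterior(entities, lik, prior)
            expected = oracle_posteriors(lik, prior)
            for e in entities:
                assert result.posterior[e] == pytest.approx(expected[e], abs=1e-12)

    def test_zero_signal_everywhere_gives_all_zero(self):
        result = posterior(["a", "b"], {}, {})
        # degenerate all-equal maps normalize to 1, so products are positive
        # only when the degenerate rule applies to BOTH maps; an all-zero
        # likelihood with distinct priors must zero out
        assert sum(result.posterior.values()) == pytest.approx(1.0)
        mixed = posterior(["a", "b"], {"a": 0.0, "b": 0.0}, {"a": 1.0, "b": 3.0})
        assert sum(mixed.posterior.values()) == pytest.approx(1.0)

    def test_posteriors_sum_to_one_whenever_nonzero(self):
        rng = np.random.default_rng(23)
        for _ in range(100):
            n = int(rng.integers(1, 12))
            entities = [f"e{i}" for i in range(n)]
            lik = {e: float(rng.exponential(2)) * (rng.random() < 0.8) for e in entities}
            prior = {e: float(rng.exponential(9)) * (rng.random() < 0.8) for e in entities}
            result = posterior(entities, lik, prior)
            total = sum(result.posterior.values())
            assert total == pytest.approx(1.0, abs=1e-9) or total == 0.0
            assert all(0.0 <= v <= 1.0 for v in result.posterior.values())

    def test_invariant_to_common_affine_shift_of_likelihoods(self):
        entities = ["a", "b", "c"]
        lik = {"a": 1.0, "b": 4.0, "c": 9.0}
        prior = {"a": 2.0, "b": 5.0, "c": 3.0}
        base = posterior(entities, lik, prior).posterior
        shifted = posterior(
            entities, {k: 3.0 * v + 11.0 for k, v in lik.items()}, prior
        ).posterior
        for e in entities:
            assert shifted[e] == pytest.approx(base[e], abs=1e-12)

    def test_empty_entity_set_rejected(self):
        with pytest.raises(ValidationError):
            posterior([], {}, {})

    def test_raising_own_query_score_never_lowers_posterior(self):
        rng = np.random.default_rng(29)
        for _ in range(300):
            n = int(rng.integers(2, 10))
            entities = [f"e{i}" for i in range(n)]
            table = LiteratureScoreTable(
                {("k", e): float(rng.exponential(6)) for e in entities},
                {e: float(rng.exponential(30)) for e in entities},
            )
            target = entities[int(rng.integers(n))]
            before = posterior_from_table(table, "k", entities)[target]
            bumped = penalize_scores(
                table, [("k", target, float(rng.uniform(0.5, 50)), "delta")]
            )
            after = posterior_from_table(bumped, "k", entities)[target]
            assert after >= before - 1e-12


class TestContextPairScore:
    @pytest.mark.parametrize(
        "pm,pg,expected", [(1, 1, 1.0), (0, 0.7, 0.0), (0.5, 0.5, 0.25)]
    )
    def test_product(self, pm, pg, expected):
        assert context_pair_score(pm, pg) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            context_pair_score(1.2, 0.5)


class TestPenalizeScores:
    def test_delta_and_clamp_and_set(self):
        table = LiteratureScoreTable({("k", "e"): 25.0}, {"e": 10.0})
        assert penalize_scores(table, [("k", "e", -10.0, "delta")]).query_score("k", "e") == 15.0
        assert penalize_scores(table, [("k", "e", -50.0, "delta")]).query_score("k", "e") == 0.0
        zeroed = penalize_scores(table, [("k", "e", 0.0, "set")])
        assert zeroed.query_score("k", "e") == 0.0

    def test_self_score_adjustment_and_original_untouched(self):
        table = LiteratureScoreTable({("k", "e"): 25.0}, {"e": 10.0})
        out = penalize_scores(table, [("e", "e", -4.0, "delta")])
        assert out.self_score("e") == 6.0
        assert table.self_score("e") == 10.0
        assert table.query_score("k", "e") == 25.0

    def test_zeroed_entry_contributes_zero_likelihood(self):
        table = LiteratureScoreTable({("k", "e"): 25.0}, {"e": 10.0})
        zeroed = penalize_scores(table, [("k", "e", 0.0, "set")])
        assert literature_likelihood(zeroed.query_score("k", "e")) == 0.0

    def test_bad_mode_rejected(self):
        with pytest.raises(ValidationError):
            penalize_scores(LiteratureScoreTable(), [("k", "e", 1.0, "mul")])
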