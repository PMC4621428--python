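import itertools
import random

import pytest

from eventmodels.event_model import ModelError, model_signature
from eventmodels.reasoning import (
    INCONSISTENT,
    TemporalAssertion,
    brute_force_verdict,
    build_models,
    move_after,
    parse_assertion,
    query,
    revise,
)

P = parse_assertion

CHAIN = [P("shower before coffee"), P("coffee before breakfast")]
FORK = [P("shower before coffee"), P("shower before breakfast")]


class TestAssertions:
    def test_after_normalizes_to_before(self):
        assert P("b after a").normalized() == TemporalAssertion("a", "before", "b")

    def test_unknown_relation_rejected(self):
        with pytest.raises(ValueError):
            P("a meets b")

    def test_malformed_text_rejected(self):
        with pytest.raises(ValueError):
            P("a before")


class TestBuildModels:
    def test_chain_single_model(self):
        ms = build_models(CHAIN)
        assert ms.total_count == 1
        assert model_signature(ms.models[0]) == {("shower", 1, 1, True),
                                                 ("coffee", 2, 2, True),
                                                 ("breakfast", 3, 3, True)}

    def test_fork_two_models_initial_first(self):
        ms = build_models(FORK)
        assert ms.total_count == 2
        # initial model follows mention order: coffee precedes breakfast
        assert model_signature(ms.models[0]) == {("shower", 1, 1, True),
                                                 ("coffee", 2, 2, True),
                                                 ("breakfast", 3, 3, True)}
        assert model_signature(ms.models[1]) == {("shower", 1, 1, True),
                                                 ("breakfast", 2, 2, True),
                                                 ("coffee", 3, 3, True)}

    def test_when_aligns_tokens(self):
        ms = build_models([P("exploded when arrived")])
        assert ms.total_count == 1
        sig = model_signature(ms.models[0])
        assert sig == {("exploded", 1, 1, True), ("arrived", 1, 1, True)}

    def test_while_places_punctate_inside_durational(self):
        ms = build_models([P("exploded while arrived")])
        assert ms.total_count == 1
        assert model_signature(ms.models[0]) == {("arrived", 1, 3, False),
                                                 ("exploded", 2, 2, True)}

    def test_contradiction_zero_models(self):
        ms = build_models([P("A before B"), P("B before A")])
        assert ms.total_count == 0 and ms.inconsistent

    def test_initial_model_stable_across_runs(self):
        sigs = {model_signature(build_models(FORK).models[0]) for _ in range(5)}
        assert len(sigs) == 1

    def test_premise_order_changes_initial_model_not_verdicts(self):
        a = build_models([P("b before c"), P("a before b")])
        b = build_models([P("a before b"), P("b before c")])
        assert {model_signature(m) for m in a.models} == {model_signature(m) for m in b.models}

    def test_truncation_flag(self):
        premises = [P("a before e")]  # many arrangements of b, c, d remain free
        ms = build_models(premises + [P("b before e"), P("c before e"), P("d before e")],
                          max_models=2)
        assert ms.truncated and len(ms.models) == 2 and ms.total_count > 2

    def test_empty_premises_rejected(self):
        with pytest.raises(ValueError):
            build_models([])


class TestQuery:
    def test_chain_necessary(self):
        assert query(build_models(CHAIN), P("shower before breakfast")).status == "necessary"

    def test_fork_possible(self):
        ms = build_models(FORK)
        assert query(ms, P("coffee before breakfast")).status == "possible"
        assert query(ms, P("breakfast before coffee")).status == "possible"

    def test_office_day_relations(self, office_day_model):
        assert query(office_day_model, P("dinner during meeting")).status == "impossible"
        assert query(office_day_model, P("meeting before evening")).status == "necessary"
        assert query(office_day_model, P("dinner during day")).status == "necessary"

    def test_unknown_label_named_in_error(self, office_day_model):
        with pytest.raises(ValueError, match="brunch"):
            query(office_day_model, P("brunch during day"))

    def test_inconsistent_premises_verdict(self):
        ms = build_models([P("A before B"), P("B before A")])
        assert query(ms, P("A before B")).status == INCONSISTENT

    def test_one_model_statistic(self):
        assert query(build_models(CHAIN), P("shower before coffee")).model_count == 1
        assert query(build_models(FORK), P("shower before coffee")).model_count == 2

    def test_bounded_verdict_flag(self):
        premises = [P("a before e"), P("b before e"), P("c before e"), P("d before e")]
        ms = build_models(premises, max_models=2)
        verdict = query(ms, P("a before e"))
        assert verdict.status == "necessary" and verdict.bounded


class TestRevise:
    def test_counterfactual_move(self, two_location_model):
        revised = move_after(two_location_model, "location-1", "location-2")
        assert query(two_location_model, P("location-1 during goal")).status == "necessary"
        assert query(revised, P("location-1 during goal")).status == "impossible"

    def test_identity_move(self, two_location_model):
        same = revise(two_location_model, "location-1", 2.0, 3.0)
        assert same == two_location_model

    def test_original_unchanged(self, two_location_model):
        snapshot = two_location_model.to_dict()
        move_after(two_location_model, "location-1", "location-2")
        assert two_location_model.to_dict() == snapshot

    def test_other_relations_preserved(self, two_location_model):
        revised = move_after(two_location_model, "location-1", "location-2")
        assert query(revised, P("location-2 before location-1")).status == "necessary"
        assert query(revised, P("goal before location-1")).status == "necessary"

    def test_invalid_interval_rejected(self, two_location_model):
        with pytest.raises(ModelError):
            revise(two_location_model, "location-1", 5.0, 4.0)

    def test_punctate_stays_punctate(self, office_day_model):
        with pytest.raises(ModelError):
            revise(office_day_model, "dinner", 1.5, 6.5)


class TestBruteForce:
    def test_chain_necessary(self):
        assert brute_force_verdict(CHAIN, P("shower before breakfast")).status == "necessary"

    def test_fork_possible(self):
        v = brute_force_verdict(FORK, P("coffee before breakfast"))
        assert v.status == "possible" and v.model_count == 2

    def test_irreflexive_before(self):
        assert brute_force_verdict([], P("A before A")).status == "impossible"

    def test_refuses_large_problems(self):
        premises = [P(f"e{i} before e{i+1}") for i in range(7)]
        with pytest.raises(ValueError):
            brute_force_verdict(premises, P("e0 before e7"))


def random_premise_set(rng, labels, n_premises, relations=("before", "after", "when")):
    premises = []
    for _ in range(n_premises):
        a, b = rng.sample(labels, 2)
        premises.append(TemporalAssertion(a, rng.choice(list(relations)), b))
    return premises


class TestOracleEquivalence:
    def test_exhaustive_before_pairs_three_events(self):
        labels = ["a", "b", "c"]
        assertions = [TemporalAssertion(x, "before", y)
                      for x, y in itertools.permutations(labels, 2)]
        for p1, p2 in itertools.product(assertions, repeat=2):
            premises = [p1, p2]
            ms = build_models(premises, max_models=100, extra_labels=labels)
            for q in assertions:
                assert query(ms, q).status == brute_force_verdict(premises, q).status

    @pytest.mark.parametrize("seed", range(40))
    def test_random_sets_five_events(self, seed):
        rng = random.Random(seed)
        labels = ["a", "b", "c", "d", "e"]
        premises = random_premise_set(rng, labels, rng.randint(2, 4))
        ms = build_models(premises, max_models=1000, extra_labels=labels)
        for _ in range(3):
            x, y = rng.sample(labels, 2)
            q = TemporalAssertion(x, rng.choice(["before", "when"]), y)
            assert query(ms, q).status == brute_force_verdict(premises, q).status

    @pytest.mark.parametrize("seed", range(10))
    def test_random_sets_with_durational(self, seed):
        rng = random.Random(1000 + seed)
        labels = ["a", "b", "c", "d"]
        premises = random_premise_set(rng, labels, rng.randint(2, 3),
                                      relations=("before", "while", "during"))
        ms = build_models(premises, max_models=100000, extra_labels=labels)
        for _ in range(3):
            x, y = rng.sample(labels, 2)
            q = TemporalAssertion(x, rng.choice(["before", "during"]), y)
            assert query(ms, q).status == brute_force_verdict(premises, q).status


class TestTransitivity:
    @pytest.mark.parametrize("seed", range(20))
    def test_necessary_before_is_transitive(self, seed):
        rng = random.Random(seed)
        labels = ["a", "b", "c", "d"]
        premises = random_premise_set(rng, labels, rng.randint(2, 4),
                                      relations=("before", "after"))
        ms = build_models(premises, max_models=1000, extra_labels=labels)
        if ms.inconsistent:
            return
        for x, y, z in itertools.permutations(labels, 3):
            if (query(ms, TemporalAssertion(x, "before", y)).status == "necessary"
                    and query(ms, TemporalAssertion(y, "before", z)).status == "necessary"):
                assert query(ms, TemporalAssertion(x, "before", z)).status == "necessary"
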