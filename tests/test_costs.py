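"""Conditional risk, cost-minimising decisions and the rejection option."""

import json

import numpy as np
import pytest

from csdelm.costs import (
    CostSpec,
    conditional_risk,
    decide,
    decide_batch,
    decide_with_rejection,
    incurred_cost,
    rejection_margin,
    uniform_costs,
)

# class order (p, n): missing a true p costs 5, a false alarm costs 1
ASYM = np.array([[0.0, 1.0], [5.0, 0.0]])


def random_cost_matrix(gen, m):
    C = gen.uniform(0.1, 5.0, size=(m, m))
    np.fill_diagonal(C, 0.0)
    return C


def random_probs(gen, m):
    p = gen.dirichlet(np.ones(m))
    return p / p.sum()


class TestConditionalRisk:
    def test_zero_costs_give_zero_risk(self):
        np.testing.assert_array_equal(
            conditional_risk([0.3, 0.7], np.zeros((2, 2))), [0.0, 0.0]
        )

    def test_certain_positive_with_asymmetric_costs(self):
        # all mass on p: assigning p costs 0, assigning n costs C(n,p)=5
        np.testing.assert_array_equal(conditional_risk([1.0, 0.0], ASYM), [0.0, 5.0])

    def test_matches_double_loop_oracle(self):
        gen = np.random.default_rng(5)
        for _ in range(20):
            C = random_cost_matrix(gen, 4)
            P = random_probs(gen, 4)
            R = conditional_risk(P, C)
            expected = [sum(P[j] * C[i, j] for j in range(4)) for i in range(4)]
            np.testing.assert_allclose(R, expected, atol=1e-12)

    def test_unnormalised_probabilities_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            conditional_risk([0.5, 0.6], ASYM)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            conditional_risk([0.5, 0.3, 0.2], ASYM)


class TestDecide:
    def test_even_votes_go_to_expensive_class(self):
        # risks (0.5, 2.5): the class that is expensive to miss wins the tie
        d = decide([0.5, 0.5], ASYM, classes=["p", "n"])
        np.testing.assert_allclose(d.risk_vector, [0.5, 2.5])
        assert d.outcome == "p"

    def test_uniform_costs_reduce_to_argmax(self):
        gen = np.random.default_rng(9)
        C = np.ones((3, 3)) - np.eye(3)
        for _ in range(50):
            P = random_probs(gen, 3)
            assert decide(P, C).outcome == int(np.argmax(P))

    @pytest.mark.parametrize("m", [2, 3, 4])
    def test_matches_enumeration_oracle(self, m):
        gen = np.random.default_rng(100 + m)
        for _ in range(200):
            C = random_cost_matrix(gen, m)
            P = random_probs(gen, m)
            d = decide(P, C)
            risks = [sum(P[j] * C[i, j] for j in range(m)) for i in range(m)]
            best = min(range(m), key=lambda i: (risks[i], i))
            assert d.outcome == best

    def test_invariant_under_positive_rescaling(self):
        gen = np.random.default_rng(17)
        for _ in range(30):
            C = random_cost_matrix(gen, 3)
            P = random_probs(gen, 3)
            assert decide(P, C).outcome == decide(P, 7.3 * C).outcome

    def test_min_risk_not_above_mean_risk(self):
        gen = np.random.default_rng(23)
        for _ in range(30):
            C = random_cost_matrix(gen, 4)
            P = random_probs(gen, 4)
            r = decide(P, C).risk_vector
            assert r.min() <= r.mean()


class TestRejectionMargin:
    def test_gap_between_two_smallest(self):
        s, f = rejection_margin([0.5, 2.5])
        assert (s, f) == (0, 2.0)

    def test_tied_risks_have_zero_margin(self):
        s, f = rejection_margin([1.0, 1.0])
        assert s == 0 and f == 0.0

    def test_matches_sort_oracle(self):
        gen = np.random.default_rng(31)
        for _ in range(50):
            risk = gen.uniform(0, 3, size=5)
            s, f = rejection_margin(risk)
            ordered = np.sort(risk)
            assert s == int(np.argmin(risk))
            assert f == pytest.approx(ordered[1] - ordered[0], abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            rejection_margin([1.0])


class TestDecideWithRejection:
    def test_zero_threshold_never_rejects(self, binary_costs):
        gen = np.random.default_rng(3)
        spec = binary_costs.with_delta(0.0)
        for _ in range(100):
            P = random_probs(gen, 2)
            d = decide_with_rejection(P, spec)
            assert not d.rejected
            assert d.outcome == spec.classes[decide(P, spec.cost_matrix).outcome]

    def test_huge_threshold_rejects_everything(self, binary_costs):
        gen = np.random.default_rng(4)
        spec = binary_costs.with_delta(1.0 + binary_costs.cost_matrix.max())
        for _ in range(50):
            assert decide_with_rejection(random_probs(gen, 2), spec).rejected

    def test_reject_region_is_contiguous_interval(self, binary_costs):
        # sweep P(p) on a grid: rejection happens exactly in a band around
        # the risk-tie point, verified against a brute-force scan
        spec = binary_costs.with_delta(0.04)
        grid = np.round(np.arange(0.0, 1.0001, 0.05), 10)
        rejected = []
        for p in grid:
            d = decide_with_rejection([p, 1 - p], spec)
            risk = d.risk_vector
            brute = abs(risk[1] - risk[0]) < spec.delta
            assert d.rejected == brute
            rejected.append(d.rejected)
        idx = [i for i, r in enumerate(rejected) if r]
        if idx:
            assert idx == list(range(idx[0], idx[-1] + 1))

    def test_rejected_set_grows_with_threshold(self, binary_costs):
        gen = np.random.default_rng(8)
        P = [random_probs(gen, 2) for _ in range(200)]
        previous = set()
        for delta in [0.0, 0.02, 0.1, 0.5, 2.0]:
            spec = binary_costs.with_delta(delta)
            current = {
                i for i, p in enumerate(P) if decide_with_rejection(p, spec).rejected
            }
            assert previous <= current
            previous = current

    def test_missing_configuration_rejected(self, binary_costs):
        bare = CostSpec(classes=binary_costs.classes,
                        cost_matrix=binary_costs.cost_matrix)
        with pytest.raises(ValueError, match="rejection"):
            decide_with_rejection([0.5, 0.5], bare)

    def test_three_action_rule_rejects_when_cheaper(self, binary_costs):
        spec = binary_costs.with_delta(0.04)
        # even votes: class risks (0.5, 2.5), reject risk 0.2 -> reject
        d = decide_with_rejection([0.5, 0.5], spec, rule="three-action")
        assert d.rejected
        # certain sample: class risk 0 beats reject risk 0.2
        d = decide_with_rejection([1.0, 0.0], spec, rule="three-action")
        assert d.outcome == "pos"


class TestIncurredCost:
    def test_correct_classification_is_free(self, binary_costs):
        d = decide_batch(np.array([[1.0, 0.0]]), binary_costs, mode="cs-delm")[0]
        assert incurred_cost(d, "pos", binary_costs) == 0.0

    def test_false_negative_costs_five(self, binary_costs):
        d = decide_batch(np.array([[0.0, 1.0]]), binary_costs, mode="cs-delm")[0]
        assert d.outcome == binary_costs.classes[1]
        assert incurred_cost(d, "pos", binary_costs) == 5.0

    def test_rejection_costs_point_two(self, binary_costs):
        d = decide_with_rejection([0.5, 0.5], binary_costs.with_delta(3.0))
        assert d.rejected
        assert incurred_cost(d, "neg", binary_costs) == pytest.approx(0.2)

    def test_unknown_label_rejected(self, binary_costs):
        d = decide_batch(np.array([[1.0, 0.0]]), binary_costs, mode="cs-delm")[0]
        with pytest.raises(ValueError, match="vocabulary"):
            incurred_cost(d, "mystery", binary_costs)


class TestCostSpec:
    def test_json_round_trip(self, tmp_path, binary_costs):
        path = tmp_path / "costs.json"
        binary_costs.to_json(path)
        loaded = CostSpec.from_json(path)
        assert loaded.classes == binary_costs.classes
        np.testing.assert_array_equal(loaded.cost_matrix, binary_costs.cost_matrix)
        np.testing.assert_array_equal(
            loaded.rejection_costs, binary_costs.rejection_costs
        )
        assert loaded.delta == binary_costs.delta

    @pytest.mark.parametrize(
        "payload,match",
        [
            ({"classes": ["a", "b"]}, "cost_matrix"),
            ({"classes": ["a", "b"], "cost_matrix": [[1, 1], [1, 0]]}, "diagonal"),
            ({"classes": ["a", "b"], "cost_matrix": [[0, -1], [1, 0]]}, "nonnegative"),
            (
                {"classes": ["a", "b"], "cost_matrix": [[0, 1], [1, 0]], "delta": -1},
                "delta",
            ),
            (
                {"classes": ["a", "b"], "cost_matrix": [[0, 1], [1, 0]], "bogus": 1},
                "unknown",
            ),
        ],
    )
    def test_invalid_specs_rejected_with_message(self, tmp_path, payload, match):
        path = tmp_path / "bad.json"
        path.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match=match):
            CostSpec.from_json(path)

    def test_uniform_costs_structure(self):
        spec = uniform_costs(["a", "b", "c"])
        np.testing.assert_array_equal(
            spec.cost_matrix, np.ones((3, 3)) - np.eye(3)
        )
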