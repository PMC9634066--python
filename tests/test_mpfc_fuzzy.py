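"""Fuzzy lookup-table controller: membership functions, rule base, inference."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from importlib import resources

from navsim import (
    FuzzyRule,
    FuzzyRuleBase,
    MembershipFunction,
    active_rules,
    build_complete_rulebase,
    build_default_map,
    evaluate_mf,
    infer_next_step,
    prune_by_degree,
)
from navsim.mpfc_fuzzy import read_rules_csv, write_rules_csv


def _table(name):
    path = resources.files("navsim").joinpath(f"data/{name}")
    return read_rules_csv(path)


def _as_tuples(rules):
    return {
        (r.here_center, r.goal_center, r.attention_label, r.consequent_center)
        for r in rules
    }


class TestMembershipFunctions:
    def test_gaussian_peaks_at_center(self):
        mf = MembershipFunction("gaussian", center=4.0)
        assert evaluate_mf(mf, 4.0) == 1.0

    def test_gaussian_worked_value(self):
        """exp(-0.2^2 / (2 * 0.15^2)) = exp(-0.04/0.045) ~ 0.4111."""
        mf = MembershipFunction("gaussian", center=4.0, sigma=0.15)
        val = evaluate_mf(mf, 4.2)
        assert val == pytest.approx(math.exp(-0.04 / 0.045), rel=1e-12)
        assert val == pytest.approx(0.4111, abs=5e-5)

    def test_s_and_z_saturation_regions(self):
        s = MembershipFunction("s_shape", foot=1.0, shoulder=2.0)
        z = MembershipFunction("z_shape", foot=1.0, shoulder=2.0)
        assert evaluate_mf(s, 2.3) == 1.0 and evaluate_mf(z, 2.3) == 0.0
        assert evaluate_mf(s, 0.7) == 0.0 and evaluate_mf(z, 0.7) == 1.0
        # crossover at the attention-deficit threshold
        assert evaluate_mf(s, 1.5) == pytest.approx(0.5)
        assert evaluate_mf(z, 1.5) == pytest.approx(0.5)

    def test_outputs_bounded_everywhere(self):
        xs = np.linspace(-5, 15, 401)
        for shape in ("gaussian", "s_shape", "z_shape"):
            mf = MembershipFunction(shape, center=4.0)
            vals = np.array([evaluate_mf(mf, x) for x in xs])
            assert np.all((vals >= 0) & (vals <= 1))

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            MembershipFunction("gaussian", center=1.0, sigma=0.0)


class TestRuleBase:
    def test_complete_base_has_72_rules(self, rulebase):
        assert rulebase.R == 72

    def test_36_distinct_antecedent_pairs(self, rulebase):
        pairs = {(r.here_center, r.goal_center) for r in rulebase.rules}
        assert len(pairs) == 36

    def test_route1_active_rules_match_printed_table(self, rulebase):
        rules = active_rules(rulebase, 1, 6)
        assert len(rules) == 10
        assert _as_tuples(rules) == _as_tuples(_table("route1_rules.csv"))

    def test_route2_active_rules_match_printed_table(self, rulebase):
        rules = active_rules(rulebase, 4, 1)
        assert len(rules) == 6
        assert _as_tuples(rules) == _as_tuples(_table("route2_rules.csv"))

    def test_union_of_both_routes_is_16_rules(self, rulebase):
        union = _as_tuples(active_rules(rulebase, 1, 6)) | _as_tuples(
            active_rules(rulebase, 4, 1)
        )
        assert len(union) == 16

    def test_one_landmark_map_one_attention_state_one_rule(self):
        base = build_complete_rulebase(build_default_map(n_route=1))
        with_att = [r for r in base.rules if r.attention_label == "with"]
        assert len(with_att) == 1
        assert with_att[0].consequent_center == with_att[0].here_center

    def test_unreachable_goal_rejected(self, rulebase):
        with pytest.raises(ValueError, match="unreachable"):
            active_rules(rulebase, 1, 42)

    def test_completeness_audit_over_operating_domain(self, rulebase):
        assert rulebase.audit_completeness()

    def test_csv_round_trip(self, rulebase, tmp_path):
        p = tmp_path / "rules.csv"
        write_rules_csv(p, rulebase)
        assert _as_tuples(read_rules_csv(p)) == _as_tuples(rulebase.rules)


class TestInference:
    @pytest.mark.parametrize("table", ["route1_rules.csv", "route2_rules.csv"])
    def test_crisp_table_rows_reproduced_exactly(self, rulebase, table):
        """With crisp inputs (attention 2 = with, 1 = without) every printed
        rule row defuzzifies and snaps to its own consequent."""
        for r in _table(table):
            attention = 2.0 if r.attention_label == "with" else 1.0
            res = infer_next_step(rulebase, r.here_center, r.goal_center, attention)
            assert res.snapped_id == r.consequent_center

    def test_start_jitter_resolves_to_first_subgoal(self, default_map, rulebase):
        """here=4.2 code / goal=9 code / attention 2.3 -> LM2 (code 5)."""
        res = infer_next_step(rulebase, 4.2, 9.0, 2.3, cmap=default_map, units="code")
        assert res.snapped_id == 2
        assert res.next_code == pytest.approx(5.0)
        assert res.raw == pytest.approx(2.0, abs=1e-3)

    def test_single_firing_rule_returns_its_consequent_exactly(self):
        base = FuzzyRuleBase(rules=[FuzzyRule(1.0, 6.0, "with", 2.0)])
        res = infer_next_step(base, 1.0, 6.0, 2.0)
        assert res.raw == 2.0

    def test_no_rule_fires_raises(self, rulebase):
        with pytest.raises(ValueError, match="no rule fires"):
            infer_next_step(rulebase, 50.0, 6.0, 2.0)

    def test_output_is_convex_combination_of_firing_consequents(self, rulebase):
        rng = np.random.default_rng(7)
        for _ in range(200):
            h, g = rng.uniform(0.8, 6.2, 2)
            a = rng.uniform(0.5, 2.5)
            res = infer_next_step(rulebase, h, g, a)
            w = rulebase.firing_strengths(h, g, a)
            cons = np.array([r.consequent_center for r in rulebase.rules])[w > 0]
            assert cons.min() - 1e-12 <= res.raw <= cons.max() + 1e-12

    def test_engine_matches_naive_double_loop_oracle(self, rulebase):
        """Centre-average defuzzification recomputed rule by rule in pure
        Python must agree with the vectorised engine to 1e-12."""

        def naive(base, h, g, a):
            num = den = 0.0
            for r in base.rules:
                mu = math.exp(-((h - r.here_center) ** 2) / (2 * 0.15**2))
                mu *= math.exp(-((g - r.goal_center) ** 2) / (2 * 0.15**2))
                mu *= base.attention_membership(r.attention_label, a)
                num += r.consequent_center * mu
                den += mu
            return num / den

        rng = np.random.default_rng(11)
        for _ in range(1000):
            h, g = rng.uniform(0.8, 6.2, 2)
            a = rng.uniform(0.5, 2.5)
            assert infer_next_step(rulebase, h, g, a).raw == pytest.approx(
                naive(rulebase, h, g, a), abs=1e-12
            )

    @settings(derandomize=True, max_examples=100)
    @given(
        h=st.floats(min_value=0.8, max_value=6.2),
        g=st.floats(min_value=0.8, max_value=6.2),
        a=st.floats(min_value=0.5, max_value=2.5),
    )
    def test_output_bounded_by_rule_consequents(self, h, g, a):
        base = build_complete_rulebase(build_default_map())
        res = infer_next_step(base, h, g, a)
        cons = [r.consequent_center for r in base.rules]
        assert min(cons) <= res.raw <= max(cons)

    def test_appearance_jitter_never_changes_route_decision(self, rulebase):
        """Perturbing `here` by up to +-0.2 id units leaves the snapped next
        step unchanged on both printed routes."""
        for r in _table("route1_rules.csv") + _table("route2_rules.csv"):
            attention = 2.0 if r.attention_label == "with" else 1.0
            for dh in (-0.2, -0.1, 0.1, 0.2):
                res = infer_next_step(
                    rulebase, r.here_center + dh, r.goal_center, attention
                )
                assert res.snapped_id == r.consequent_center


class TestPruning:
    def test_no_duplicates_pass_through(self):
        rules = [FuzzyRule(1, 6, "with", 2), FuzzyRule(2, 6, "with", 3)]
        assert prune_by_degree([(r, 0.5) for r in rules]) == rules

    def test_higher_degree_rule_wins(self):
        lo = FuzzyRule(1, 6, "with", 3)
        hi = FuzzyRule(1, 6, "with", 2)
        assert prune_by_degree([(lo, 0.4), (hi, 0.9)]) == [hi]
        assert prune_by_degree([(hi, 0.9), (lo, 0.4)]) == [hi]

    def test_exact_tie_keeps_lower_consequent_and_warns(self, caplog):
        a = FuzzyRule(1, 6, "with", 5)
        b = FuzzyRule(1, 6, "with", 2)
        with caplog.at_level("WARNING", logger="navsim.mpfc_fuzzy"):
            kept = prune_by_degree([(a, 0.7), (b, 0.7)])
        assert kept == [b]
        assert any("tie" in rec.message for rec in caplog.records)
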