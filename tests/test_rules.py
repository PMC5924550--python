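import math

import numpy as np
import pytest

from cnvsift.dataset import CopyNumberDataset
from cnvsift.mcfs import RankedFeatureList
from cnvsift.rules import (
    Condition,
    Rule,
    RuleSet,
    RipperParams,
    evaluate_rules,
    johnson_reduce,
    odds_ratio_ci,
    ripper,
    select_informative,
)
from cnvsift.synth import SyntheticSpec, generate_dataset, generate_rule_dataset


class TestSelectInformative:
    def _ranking(self, m):
        return RankedFeatureList.from_scores(
            [f"f{i}" for i in range(m)], np.arange(m, 0, -1, dtype=float)
        )

    def test_one_percent_of_thousand(self):
        assert len(select_informative(self._ranking(1000), 1)) == 10

    def test_hundred_percent_is_everything(self):
        assert len(select_informative(self._ranking(50), 100)) == 50

    def test_ceiling_arithmetic_at_study_scale(self):
        assert len(select_informative(self._ranking(52842), 1)) == 529

    def test_invalid_p(self):
        with pytest.raises(ValueError):
            select_informative(self._ranking(10), 0)


class TestJohnsonReduce:
    def test_single_separating_feature(self):
        spec = SyntheticSpec(
            n_case=40, n_control=40, n_probes=8, n_informative=1,
            effect_size=0.5, noise_sd=0.05, seed=0,
        )
        ds, truth = generate_dataset(spec)
        assert johnson_reduce(ds) == sorted(truth)

    def test_duplicated_feature_tie_broken_by_index(self):
        rng = np.random.default_rng(1)
        x = np.concatenate([rng.normal(0, 0.05, 20), rng.normal(0.5, 0.05, 20)])
        values = np.vstack([x, x, rng.normal(0, 0.05, 40)])
        ds = CopyNumberDataset(
            ["a", "b", "c"],
            [f"s{i}" for i in range(40)],
            values,
            np.repeat([0, 1], 20),
        )
        assert johnson_reduce(ds) == ["a"]

    def test_greedy_cover_hand_enumerated(self):
        # cases A,B; controls C,D,E.
        # f1 discerns (A,C),(A,D),(B,C),(B,D); f2 discerns (A,E),(B,E);
        # f3 discerns a subset of f1's pairs -> reduct is [f1, f2]
        values = np.array(
            [
                [1.0, 1.0, 0.0, 0.0, 1.0],  # f1
                [1.0, 1.0, 1.0, 1.0, 0.0],  # f2
                [1.0, 1.0, 0.0, 1.0, 1.0],  # f3
            ]
        )
        ds = CopyNumberDataset(
            ["f1", "f2", "f3"],
            ["A", "B", "C", "D", "E"],
            values,
            np.array([1, 1, 0, 0, 0]),
        )
        assert johnson_reduce(ds) == ["f1", "f2"]

    def test_no_discernible_pair_rejected(self):
        ds = CopyNumberDataset(
            ["f1"], ["a", "b"], np.array([[0.5, 0.5]]), np.array([0, 1])
        )
        with pytest.raises(ValueError, match="discerns"):
            johnson_reduce(ds)


class TestRipper:
    def test_recovers_planted_threshold_rule(self):
        spec = SyntheticSpec(n_case=100, n_control=100, n_probes=10, seed=3)
        ds, _ = generate_rule_dataset(spec, [("P000003", 0.0, "<=")])
        rs = ripper(ds, RipperParams(seed=3))
        ev = evaluate_rules(rs, ds)
        assert ev.mcc == 1.0
        # cutpoint within one data gap of the planted value 0
        cuts = [c.cut for r in rs.rules for c in r.conditions if c.feature == "P000003"]
        assert cuts
        x = np.sort(ds.values[3])
        i = np.searchsorted(x, 0.0)
        gap = x[i] - x[i - 1]
        assert abs(cuts[0] - 0.0) <= gap

    def test_recovers_two_condition_conjunction(self):
        spec = SyntheticSpec(n_case=100, n_control=100, n_probes=10, seed=4)
        ds, _ = generate_rule_dataset(
            spec, [("P000002", 0.02, "<="), ("P000005", -0.01, ">=")]
        )
        rs = ripper(ds, RipperParams(seed=4))
        assert evaluate_rules(rs, ds).mcc == 1.0
        feats = {c.feature for r in rs.rules for c in r.conditions}
        assert feats <= {"P000002", "P000005"}
        assert len(feats) == 2

    def test_pure_noise_yields_default_only(self):
        """MDL keeps chance rules out of the list on label noise."""
        empty = 0
        for seed in range(10):
            spec = SyntheticSpec(
                n_case=80, n_control=80, n_probes=8, n_informative=0,
                effect_size=0.0, seed=seed,
            )
            ds, _ = generate_dataset(spec)
            rs = ripper(ds, RipperParams(seed=seed))
            empty += len(rs.rules) == 0
        assert empty >= 8

    def test_explicit_target_class(self):
        spec = SyntheticSpec(n_case=100, n_control=100, n_probes=10, seed=5)
        ds, _ = generate_rule_dataset(spec, [("P000003", 0.0, "<=")])
        rs = ripper(ds, RipperParams(seed=5, target_class=1))
        assert all(r.predicted == 1 for r in rs.rules)
        assert rs.default == 0
        assert evaluate_rules(rs, ds).mcc == 1.0


class TestRuleSet:
    def test_first_match_wins(self):
        rs = RuleSet(
            rules=[
                Rule([Condition("f1", "<=", 0.0)], predicted=1),
                Rule([Condition("f2", ">=", 0.0)], predicted=0),
            ],
            default=0,
        )
        X = np.array([[-1.0, 1.0], [1.0, 1.0], [1.0, -1.0]])
        np.testing.assert_array_equal(rs.apply(X, ["f1", "f2"]), [1, 0, 0])

    def test_serialization_preserves_cutpoints_exactly(self):
        cut = 0.1 + 0.2  # deliberately not representable nicely
        rs = RuleSet([Rule([Condition("f", "<=", cut)], 1)], default=0)
        back = RuleSet.from_json(rs.to_json())
        assert back.rules[0].conditions[0].cut == cut

    def test_interval_conditions_tighten(self):
        r = Rule(
            [Condition("f", "<=", 0.5), Condition("f", "<=", 0.2),
             Condition("f", ">=", -0.3)],
            predicted=1,
        )
        ops = {(c.op): c.cut for c in r.conditions}
        assert ops["<="] == 0.2
        assert ops[">="] == -0.3
        assert len(r.conditions) == 2


class TestEvaluateRules:
    def test_hand_computed_odds_ratio(self):
        or_, ci, p, corr = odds_ratio_ci(tp=20, fp=10, fn=10, tn=20)
        assert or_ == pytest.approx(4.0)
        assert not corr

    def test_documented_example_table(self):
        or_, ci, p, corr = odds_ratio_ci(tp=118, fp=59, fn=118, tn=231)
        assert or_ == pytest.approx(118 * 231 / (59 * 118), rel=1e-12)
        se = math.sqrt(1 / 118 + 1 / 59 + 1 / 118 + 1 / 231)
        assert ci[0] == pytest.approx(math.exp(math.log(or_) - 1.96 * se))
        assert ci[1] == pytest.approx(math.exp(math.log(or_) + 1.96 * se))

    def test_zero_cell_triggers_continuity_correction(self):
        or_, ci, p, corr = odds_ratio_ci(tp=10, fp=0, fn=0, tn=10)
        assert corr
        assert np.isfinite(or_) and np.isfinite(ci[1])

    def test_perfect_ruleset_flagged(self):
        spec = SyntheticSpec(n_case=50, n_control=50, n_probes=5, n_informative=0, seed=6)
        ds, planted = generate_rule_dataset(spec, [("P000002", 0.0, "<=")])
        ev = evaluate_rules(planted, ds)
        assert ev.mcc == 1.0
        assert ev.continuity_corrected

    def test_matches_statsmodels_oracle(self):
        """OR and CI agree with an independent 2x2 implementation."""
        from statsmodels.stats.contingency_tables import Table2x2

        rng = np.random.default_rng(0)
        checked = 0
        while checked < 100:
            tp, fp, fn, tn = (int(v) for v in rng.integers(1, 50, 4))
            table = Table2x2(np.array([[tp, fp], [fn, tn]]))
            or_, ci, p, corr = odds_ratio_ci(tp, fp, fn, tn)
            assert not corr
            assert or_ == pytest.approx(table.oddsratio, rel=1e-12)
            # the CI here uses the conventional 1.96 quantile, the oracle
            # uses norm.ppf(0.975); they agree to ~1e-5 relative
            lo, hi = table.oddsratio_confint(0.05)
            assert ci[0] == pytest.approx(lo, rel=1e-3)
            assert ci[1] == pytest.approx(hi, rel=1e-3)
            checked += 1
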