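"""CSMF aggregation, redistribution folding, bootstrap CIs and accuracy."""

import numpy as np
import pytest
from scipy.stats import binom

from tariffva.assignment import IndividualPrediction
from tariffva.csmf import (
    aggregate,
    attach_ci,
    bootstrap_ci,
    broad_group_fractions,
    csmf_accuracy,
    csmf_after_redistribution,
)
from tariffva.redistribution import FractionalWeights, RedistributionResult
from tariffva.schema import UNDETERMINED, BroadGroupMap, CauseList, ReferenceDistribution


def pred(cause, sex="male", age_group="50-59", rid=None):
    return IndividualPrediction(
        record_id=rid or f"r{id(object())}",
        assigned_cause=cause,
        top_k=(),
        age_group=age_group,
        sex=sex,
    )


def preds_from_counts(counts):
    out = []
    for cause, n in counts.items():
        out.extend(pred(cause, rid=f"{cause}-{i}") for i in range(n))
    return out


@pytest.fixture
def abc():
    return CauseList(("A", "B", "C"))


@pytest.fixture
def ab():
    return CauseList(("A", "B"))


def redist_result(causes, added, per_stratum_total):
    return RedistributionResult(
        causes.assignable, {}, np.asarray(added, float), per_stratum_total
    )


class TestAggregate:
    def test_degenerate_single_cause(self, abc):
        table = aggregate(preds_from_counts({"A": 5}), abc)
        assert table.before_mapping()["A"] == 1.0

    def test_counting(self, abc):
        table = aggregate(preds_from_counts({"A": 2, "B": 3, "C": 5}), abc)
        before = table.before_mapping()
        assert (before["A"], before["B"], before["C"]) == (0.2, 0.3, 0.5)
        assert before[UNDETERMINED] == 0.0

    def test_fractions_from_figure_style_counts(self):
        # Four categories of 239 excluded deaths: 3 alcohol-related,
        # 4 other respiratory, 146 undetermined, 86 garbage codes.
        causes = CauseList(("alcohol_related", "other_respiratory", "garbage_code"))
        predictions = preds_from_counts(
            {"alcohol_related": 3, "other_respiratory": 4,
             UNDETERMINED: 146, "garbage_code": 86}
        )
        table = aggregate(predictions, causes)
        before = table.before_mapping()
        assert table.n_deaths == 239
        assert before["alcohol_related"] == pytest.approx(3 / 239)
        assert before[UNDETERMINED] == pytest.approx(146 / 239)

    def test_empty_input_is_an_error(self, abc):
        with pytest.raises(ValueError, match="empty"):
            aggregate([], abc)


class TestAfterRedistribution:
    def test_no_undetermined_keeps_fractions(self, abc):
        table = aggregate(preds_from_counts({"A": 2, "B": 3, "C": 5}), abc)
        after = csmf_after_redistribution(
            table, redist_result(abc, [0, 0, 0], 0)
        ).after_mapping()
        assert after == {**table.before_mapping(), UNDETERMINED: 0.0}

    def test_arithmetic_oracle(self, ab):
        table = aggregate(
            preds_from_counts({"A": 4, "B": 4, UNDETERMINED: 2}), ab
        )
        after = csmf_after_redistribution(
            table, redist_result(ab, [1.5, 0.5], 2)
        ).after_mapping()
        assert after["A"] == pytest.approx(5.5 / 10)
        assert after["B"] == pytest.approx(4.5 / 10)
        assert after[UNDETERMINED] == 0.0

    def test_all_undetermined_yields_combined_weights(self, ab):
        table = aggregate(preds_from_counts({UNDETERMINED: 10}), ab)
        after = csmf_after_redistribution(
            table, redist_result(ab, [7.5, 2.5], 10)
        ).after_mapping()
        assert after["A"] == pytest.approx(0.75)
        assert after["B"] == pytest.approx(0.25)

    def test_mismatched_totals_rejected(self, ab):
        table = aggregate(preds_from_counts({"A": 4, UNDETERMINED: 2}), ab)
        with pytest.raises(ValueError, match="undetermined"):
            csmf_after_redistribution(table, redist_result(ab, [5.0, 0.0], 5))


class TestBroadGroups:
    def test_sums_by_group(self, abc):
        table = aggregate(preds_from_counts({"A": 2, "B": 3, "C": 5}), abc)
        gmap = BroadGroupMap({"A": "group1", "B": "group1", "C": "group2"})
        groups = broad_group_fractions(table, gmap).set_index("group")
        assert groups.loc["group1", "fraction_before"] == pytest.approx(0.5)
        assert groups.loc["group2", "fraction_before"] == pytest.approx(0.5)

    def test_single_group_map(self, abc):
        table = aggregate(preds_from_counts({"A": 1, "B": 1, "C": 2}), abc)
        gmap = BroadGroupMap({c: "group2" for c in abc.assignable})
        groups = broad_group_fractions(table, gmap).set_index("group")
        assert groups.loc["group2", "fraction_before"] == pytest.approx(1.0)

    def test_undetermined_kept_as_own_row_before(self, abc):
        table = aggregate(preds_from_counts({"A": 8, UNDETERMINED: 2}), abc)
        gmap = BroadGroupMap({"A": "group1", "B": "group1", "C": "group2"})
        groups = broad_group_fractions(table, gmap).set_index("group")
        assert groups.loc[UNDETERMINED, "fraction_before"] == pytest.approx(0.2)

    def test_unmapped_cause_is_an_error(self, abc):
        table = aggregate(preds_from_counts({"A": 1, "B": 1, "C": 1}), abc)
        with pytest.raises(KeyError, match="C"):
            broad_group_fractions(table, BroadGroupMap({"A": "group1", "B": "group1"}))


def two_cause_bootstrap(n_a, n_b, B=500, seed=0, causes=None):
    causes = causes or CauseList(("A", "B"))
    predictions = preds_from_counts({"A": n_a, "B": n_b})
    w = FractionalWeights(causes.assignable, np.full(len(causes), 1 / len(causes)))
    ref = ReferenceDistribution(
        {("male", "50-59"): {c: 1 / len(causes) for c in causes.assignable}}
    )
    return predictions, bootstrap_ci(
        predictions, causes, w, ref, B=B, seed=seed
    )


class TestBootstrap:
    def test_identical_deaths_give_zero_width_ci(self, ab):
        _, boot = two_cause_bootstrap(100, 0, B=200, seed=1)
        i = boot.categories.index("A")
        assert boot.ci_low[i] == boot.ci_high[i] == 1.0

    def test_same_seed_reproduces(self, ab):
        _, b1 = two_cause_bootstrap(30, 70, B=200, seed=3)
        _, b2 = two_cause_bootstrap(30, 70, B=200, seed=3)
        np.testing.assert_array_equal(b1.replicates, b2.replicates)

    def test_matches_closed_form_binomial_interval(self, ab):
        # 50/50 over n=100 deaths: the bootstrap percentile CI must sit
        # within +-0.02 of the exact binomial quantile interval.
        _, boot = two_cause_bootstrap(50, 50, B=2000, seed=5)
        lo_exact = binom.ppf(0.025, 100, 0.5) / 100
        hi_exact = binom.ppf(0.975, 100, 0.5) / 100
        i = boot.categories.index("A")
        assert boot.ci_low[i] == pytest.approx(lo_exact, abs=0.02)
        assert boot.ci_high[i] == pytest.approx(hi_exact, abs=0.02)

    def test_every_replicate_conserves_mass(self, abc):
        predictions = preds_from_counts({"A": 30, "B": 20, UNDETERMINED: 10})
        w = FractionalWeights(abc.assignable, np.array([0.5, 0.25, 0.25]))
        ref = ReferenceDistribution(
            {("male", "50-59"): {"A": 0.2, "B": 0.3, "C": 0.5}}
        )
        boot = bootstrap_ci(predictions, abc, w, ref, B=300, seed=2)
        np.testing.assert_allclose(boot.replicates.sum(axis=1), 1.0, atol=1e-9)

    def test_ci_width_shrinks_with_sample_size(self, ab):
        widths = []
        for n in (100, 1000, 10000):
            _, boot = two_cause_bootstrap(n // 2, n - n // 2, B=300, seed=7)
            i = boot.categories.index("A")
            widths.append(boot.ci_high[i] - boot.ci_low[i])
        assert widths[0] > widths[1] > widths[2]

    def test_attach_ci_orders_bounds(self, ab):
        predictions, boot = two_cause_bootstrap(40, 60, B=200, seed=9)
        table = aggregate(predictions, ab)
        table = csmf_after_redistribution(table, redist_result(ab, [0, 0], 0))
        table = attach_ci(table, boot)
        assert np.all(table.ci_low <= table.ci_high)


class TestCSMFAccuracy:
    def test_identity(self):
        assert csmf_accuracy([0.5, 0.3, 0.2], [0.5, 0.3, 0.2]) == 1.0

    def test_hand_arithmetic(self):
        assert csmf_accuracy([0.5, 0.3, 0.2], [0.4, 0.4, 0.2]) == pytest.approx(0.875)

    def test_worst_case_is_zero(self):
        # All predicted mass on the cause the truth considers rarest.
        assert csmf_accuracy([0.5, 0.3, 0.2], [0.0, 0.0, 1.0]) == pytest.approx(0.0)

    def test_one_iff_equal(self, rng):
        for _ in range(50):
            t = rng.random(4)
            t /= t.sum()
            p = rng.random(4)
            p /= p.sum()
            acc = csmf_accuracy(t, p)
            assert (acc == 1.0) == np.allclose(t, p)

    def test_invariant_under_joint_permutation(self, rng):
        t = np.array([0.5, 0.3, 0.15, 0.05])
        p = np.array([0.4, 0.35, 0.2, 0.05])
        base = csmf_accuracy(t, p)
        for _ in range(10):
            perm = rng.permutation(4)
            assert csmf_accuracy(t[perm], p[perm]) == pytest.approx(base)

    def test_degenerate_single_cause_truth(self):
        # With one cause the denominator 2(1 - min(true)) vanishes; the
        # metric is defined as 1 exactly when the prediction matches.
        assert csmf_accuracy([1.0], [1.0]) == 1.0
        assert csmf_accuracy([1.0, 0.0], [0.9, 0.1]) == pytest.approx(0.9)

    def test_mapping_interface_checks_keys(self):
        with pytest.raises(ValueError, match="different causes"):
            csmf_accuracy({"A": 1.0}, {"B": 1.0})
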