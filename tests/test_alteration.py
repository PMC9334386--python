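import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eflow.alteration import (
    broken_stick,
    compute_alteration,
    compute_hai,
    compute_seasonality,
    estimate_reference_conditions,
    fit_reference_pca,
    hai_table,
    minmax_scale_by_region,
)

from oracles import broken_stick_oracle


class TestAlterationCalculus:
    @pytest.mark.parametrize(
        "observed, expected, want",
        [
            (5.0, 5.0, 0.0),          # identity
            (5.0, 1.0, 1.0),          # ratio 4 capped at 1
            (0.5, 1.0, 0.5),          # |-0.5|
            (2.0, 1.0, 1.0),          # ratio exactly 1 stays 1
            (0.0, 1.0, 1.0),          # total depletion
            (0.0, 0.0, 0.0),          # E=0, O=0 convention
            (0.3, 0.0, 1.0),          # E=0, O>0 convention
            (1.5, (1.0, 2.0), 0.0),   # inside envelope
            (0.5, (1.0, 2.0), 0.5),   # below envelope, vs nearest bound
            (5.0, (1.0, 2.0), 1.0),   # far above envelope, capped
        ],
    )
    def test_capped_proportional_rule(self, observed, expected, want):
        assert compute_alteration(observed, expected) == pytest.approx(want)

    @given(
        o=st.floats(0, 100, allow_nan=False),
        e=st.floats(0.01, 100, allow_nan=False),
    )
    @settings(max_examples=200, deadline=None)
    def test_always_in_unit_interval(self, o, e):
        a = compute_alteration(o, e)
        assert 0.0 <= a <= 1.0
        assert a == pytest.approx(min(abs((o - e) / e), 1.0))


class TestSeasonality:
    def test_identical_months_zero_both_modes(self):
        e = np.arange(1.0, 13.0)
        assert compute_seasonality(e, e) == 0.0
        assert compute_seasonality(e, e, signed=True) == 0.0

    def test_single_doubled_month(self):
        e = np.ones(12)
        o = e.copy()
        o[0] = 2.0
        assert compute_seasonality(o, e) == pytest.approx(1.0)

    def test_signed_mode_lets_opposite_shifts_cancel(self):
        e = np.ones(12)
        o = e.copy()
        o[0], o[1] = 2.0, 0.0  # +1 and -1 proportional shifts
        assert compute_seasonality(o, e, signed=True) == pytest.approx(0.0)
        assert compute_seasonality(o, e) == pytest.approx(2.0)

    def test_needs_twelve_months(self):
        with pytest.raises(ValueError):
            compute_seasonality(np.ones(11), np.ones(11))


class TestBrokenStick:
    def test_hand_computed_example(self):
        # proportions (.6,.2,.1,.06,.04): b1=0.4567 < .6, b2=0.2567 > .2 -> k=1
        ev = np.array([0.6, 0.2, 0.1, 0.06, 0.04])
        assert broken_stick(ev) == 1

    def test_boundary_equality_is_not_significant(self):
        p = 4
        bs = [sum(1.0 / i for i in range(j, p + 1)) / p for j in range(1, p + 1)]
        assert broken_stick(np.array(sorted(bs, reverse=True))) == 0

    def test_single_component_degenerate(self):
        assert broken_stick(np.array([3.0])) == 0

    def test_all_zero_eigenvalues(self):
        with pytest.warns(UserWarning):
            assert broken_stick(np.zeros(4)) == 0

    @given(
        st.lists(st.floats(0.001, 10, allow_nan=False), min_size=2, max_size=50)
    )
    @settings(max_examples=100, deadline=None)
    def test_matches_literal_oracle_up_to_p50(self, raw):
        ev = np.array(sorted(raw, reverse=True))
        props = ev / ev.sum()
        assert broken_stick(ev) == broken_stick_oracle(list(props))


class TestHAI:
    def test_scores_inside_envelopes_give_zero(self):
        env = np.array([[-1.0, 1.0], [-2.0, 2.0]])
        assert compute_hai(np.array([0.5, -1.5]), env, np.array([2.0, 1.0])) == 0.0

    def test_single_violation_hand_value(self):
        # |1.5 - 1| * 2 = 1.0
        env = np.array([[-1.0, 1.0]])
        assert compute_hai(np.array([1.5]), env, np.array([2.0])) == pytest.approx(1.0)

    def test_two_component_hand_value(self):
        # first inside; second 0.25 below its lower bound with V=1.2 -> 0.3
        env = np.array([[-1.0, 1.0], [-0.5, 0.5]])
        hai = compute_hai(np.array([0.0, -0.75]), env, np.array([3.0, 1.2]))
        assert hai == pytest.approx(0.3)

    def test_weakly_increasing_in_violation(self):
        env = np.array([[-1.0, 1.0]])
        v = np.array([1.5])
        values = [compute_hai(np.array([s]), env, v) for s in (1.0, 1.2, 1.8, 3.0)]
        assert values == sorted(values)
        assert values[0] == 0.0


class TestReferencePCA:
    def _table(self, rng, n=40):
        # two perfectly correlated metrics plus independent noise columns
        base = rng.normal(0, 2.0, n)
        df = pd.DataFrame(
            {
                "M1": base,
                "M2": 3.0 * base + 1.0,
                "M3": rng.normal(0, 0.3, n),
                "M4": rng.normal(5, 0.3, n),
            },
            index=[f"G{i}" for i in range(n)],
        )
        classes = pd.Series(["A"] * (n // 2) + ["B"] * (n - n // 2), index=df.index)
        is_ref = pd.Series([True, False] * (n // 2), index=df.index)
        return df, classes, is_ref

    def test_correlated_pair_dominates_first_component(self, rng):
        df, classes, is_ref = self._table(rng)
        pca = fit_reference_pca(df, classes, is_ref)
        load = np.abs(pca.components[0])
        names = np.array(pca.metrics)
        top2 = set(names[np.argsort(load)[-2:]])
        assert top2 == {"M1", "M2"}
        assert pca.k == broken_stick(pca.eigenvalues) or pca.k == 1

    def test_envelopes_within_reference_score_range(self, rng):
        df, classes, is_ref = self._table(rng)
        pca = fit_reference_pca(df, classes, is_ref)
        scores = pca.scores(df)
        ref = scores[is_ref.to_numpy()]
        for cls in ("A", "B"):
            env = pca.envelopes[cls]
            for i in range(pca.k):
                assert env[i, 0] >= ref[:, i].min() - 1e-9
                assert env[i, 1] <= ref[:, i].max() + 1e-9
                assert env[i, 0] <= env[i, 1]

    def test_refit_is_deterministic(self, rng):
        df, classes, is_ref = self._table(rng)
        a = fit_reference_pca(df, classes, is_ref)
        b = fit_reference_pca(df, classes, is_ref)
        np.testing.assert_allclose(a.components, b.components)
        np.testing.assert_allclose(a.eigenvalues, b.eigenvalues)

    def test_constant_column_dropped(self, rng):
        df, classes, is_ref = self._table(rng)
        df["M5"] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            pca = fit_reference_pca(df, classes, is_ref)
        assert "M5" not in pca.metrics

    def test_reference_gauges_mostly_inside_envelopes(self, rng):
        df, classes, is_ref = self._table(rng, n=60)
        pca = fit_reference_pca(df, classes, is_ref)
        hai = hai_table(pca, df, classes)
        ref_hai = hai[is_ref]
        # central-90% envelopes leave at most ~10% of reference scores out
        assert (ref_hai == 0).mean() >= 0.6
        assert hai.min() >= 0


class TestRegionalScaling:
    def test_linear_map(self):
        v = pd.Series([2.0, 4.0, 6.0], index=list("abc"))
        r = pd.Series(["R1"] * 3, index=list("abc"))
        out = minmax_scale_by_region(v, r)
        assert list(out) == [0.0, 0.5, 1.0]

    def test_regions_scaled_independently(self):
        v = pd.Series([1.0, 3.0, 10.0, 30.0], index=list("abcd"))
        r = pd.Series(["R1", "R1", "R2", "R2"], index=list("abcd"))
        out = minmax_scale_by_region(v, r)
        assert list(out) == [0.0, 1.0, 0.0, 1.0]

    def test_constant_region_warns_and_zeroes(self):
        v = pd.Series([2.0, 2.0], index=list("ab"))
        r = pd.Series(["R1", "R1"], index=list("ab"))
        with pytest.warns(UserWarning):
            out = minmax_scale_by_region(v, r)
        assert list(out) == [0.0, 0.0]

    def test_rank_preserving_when_new_maximum_added(self, rng):
        v = pd.Series(rng.normal(0, 1, 20))
        r = pd.Series(["R1"] * 20)
        base = minmax_scale_by_region(v, r)
        v2 = pd.concat([v, pd.Series([v.max() + 5], index=[99])])
        r2 = pd.Series(["R1"] * 21, index=v2.index)
        out = minmax_scale_by_region(v2, r2)
        assert (out.loc[v.index] <= base + 1e-12).all()
        assert list(out.loc[v.index].rank()) == list(base.rank())


class TestExpectedConditions:
    def test_model_recovers_cloned_reference_gauge(self, rng):
        # non-reference gauge with covariates identical to a reference gauge
        # recovers that gauge's metric under a zero-noise synthetic
        n = 30
        cov = pd.DataFrame(
            {"area": rng.uniform(10, 1000, n)}, index=[f"G{i}" for i in range(n)]
        )
        metrics = pd.DataFrame({"MA1": 0.05 * cov["area"]})
        is_ref = pd.Series([True] * (n - 1) + [False], index=cov.index)
        cov.iloc[-1] = cov.iloc[0]  # clone covariates of a reference gauge
        metrics.iloc[-1] = 999.0  # wildly altered observation
        classes = pd.Series("A", index=cov.index)
        ec = estimate_reference_conditions(metrics, is_ref, cov, classes, seed=1)
        target = 0.05 * cov.iloc[0, 0]
        assert ec.expected_for(cov.index[-1], "MA1") == pytest.approx(
            target, rel=0.15
        )
        assert ec.provenance["MA1"] == "model"

    def test_unreliable_metric_degenerate_envelope(self):
        idx = ["G1", "G2", "G3"]
        metrics = pd.DataFrame({"TA1": [0.7, 0.7, 0.2]}, index=idx)
        is_ref = pd.Series([True, True, False], index=idx)
        cov = pd.DataFrame({"x": [1.0, 2.0, 3.0]}, index=idx)
        classes = pd.Series("A", index=idx)
        ec = estimate_reference_conditions(
            metrics, is_ref, cov, classes, unreliable_metrics={"TA1"}, seed=1
        )
        lo, hi = ec.expected_for("G3", "TA1")
        assert lo == hi == pytest.approx(0.7)
        assert ec.provenance["TA1"] == "class-envelope"

    def test_no_reference_gauges_is_an_error(self):
        idx = ["G1", "G2"]
        metrics = pd.DataFrame({"MA1": [1.0, 2.0]}, index=idx)
        is_ref = pd.Series([False, False], index=idx)
        cov = pd.DataFrame({"x": [1.0, 2.0]}, index=idx)
        with pytest.raises(ValueError, match="no reference"):
            estimate_reference_conditions(
                metrics, is_ref, cov, pd.Series("A", index=idx)
            )
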