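import numpy as np
import pandas as pd
import pytest

from eflow.metrics import compute_metric_vector, duration_metrics, magnitude_metrics
from eflow.synthetic import (
    ClassFlowConfig,
    DisturbanceProfile,
    apply_disturbance,
    default_class_configs,
    generate_covariates,
    generate_gauge_network,
    simulate_fish_responses,
    simulate_reference_flow,
)


class TestNetwork:
    def test_exact_reference_fraction(self):
        net = generate_gauge_network(10, reference_fraction=0.5, seed=1)
        assert len(net.reference_gauges) == 5
        assert len(net.nonreference_gauges) == 5

    def test_same_seed_reproduces_network_field_for_field(self):
        a = generate_gauge_network(30, n_reaches=10, seed=42)
        b = generate_gauge_network(30, n_reaches=10, seed=42)
        assert a.gauges == b.gauges
        assert a.reaches == b.reaches

    def test_every_region_populated(self):
        net = generate_gauge_network(200, n_regions=4, seed=7)
        regions = {g.region for g in net.gauges}
        assert regions == set(net.regions)

    def test_reference_gauges_carry_zero_disturbance(self):
        net = generate_gauge_network(50, seed=3)
        for g in net.reference_gauges:
            assert g.disturbance.is_zero

    @pytest.mark.parametrize(
        "kwargs", [{"n_gauges": 1}, {"n_gauges": 10, "reference_fraction": 1.0},
                   {"n_gauges": 10, "n_reaches": -1}]
    )
    def test_invalid_arguments_rejected(self, kwargs):
        with pytest.raises(ValueError):
            generate_gauge_network(**kwargs)


def _gauge(seed=0, cls="C1"):
    net = generate_gauge_network(4, n_classes=2, seed=seed)
    g = net.gauges[0]
    g.hydro_class = cls
    return g


class TestReferenceFlow:
    def test_pure_sinusoid_mean_is_analytic(self):
        g = _gauge()
        cfg = ClassFlowConfig(noise_sd=0.0, storm_rate=0.0)
        s = simulate_reference_flow(g, n_years=15, seed=1, config=cfg)
        # discrete sum of a sinusoid over whole periods vanishes exactly
        expected = cfg.mean_specific_runoff * g.drainage_area_km2
        assert magnitude_metrics(s)["MA1"] == pytest.approx(expected)

    def test_same_seed_identical_series(self):
        g = _gauge()
        a = simulate_reference_flow(g, n_years=15, seed=9)
        b = simulate_reference_flow(g, n_years=15, seed=9)
        pd.testing.assert_series_equal(a.flows, b.flows)

    def test_series_length_and_positivity(self):
        g = _gauge()
        s = simulate_reference_flow(g, n_years=16, seed=2)
        assert len(s) == 16 * 365
        assert (s.values >= 0).all()

    def test_intermittent_class_has_zero_flow_days(self):
        g = _gauge()
        cfg = ClassFlowConfig(intermittent=True, dry_offset=0.7, storm_rate=0.0)
        s = simulate_reference_flow(g, n_years=15, seed=5, config=cfg)
        assert duration_metrics(s)["DL18"] > 0

    def test_nonpositive_years_rejected(self):
        with pytest.raises(ValueError):
            simulate_reference_flow(_gauge(), n_years=0, seed=1)


class TestDisturbance:
    @pytest.fixture
    def reference(self):
        return simulate_reference_flow(_gauge(), n_years=15, seed=11)

    def test_zero_profile_is_identity(self, reference):
        out = apply_disturbance(reference, DisturbanceProfile(), seed=1)
        pd.testing.assert_series_equal(out.flows, reference.flows)

    def test_withdrawal_scales_mean_linearly(self, reference):
        out = apply_disturbance(
            reference, DisturbanceProfile(withdrawal_fraction=0.5), seed=1
        )
        ma1_in = magnitude_metrics(reference)["MA1"]
        ma1_out = magnitude_metrics(out)["MA1"]
        assert ma1_out == pytest.approx(0.5 * ma1_in)

    def test_dam_regulation_damps_variability_and_peaks(self, reference):
        out = apply_disturbance(
            reference, DisturbanceProfile(dam_storage_intensity=0.8), seed=1
        )
        assert magnitude_metrics(out)["MA3"] < magnitude_metrics(reference)["MA3"]
        assert duration_metrics(out)["DH1"] <= duration_metrics(reference)["DH1"]
        assert duration_metrics(out)["DL1"] >= duration_metrics(reference)["DL1"]

    def test_withdrawal_monotonically_decreases_mean(self, reference):
        means = [
            magnitude_metrics(
                apply_disturbance(
                    reference, DisturbanceProfile(withdrawal_fraction=w), seed=1
                )
            )["MA1"]
            for w in (0.1, 0.4, 0.7)
        ]
        assert means[0] > means[1] > means[2]

    def test_urban_flashiness_raises_rise_rate(self, reference):
        from eflow.metrics import rate_metrics

        out = apply_disturbance(
            reference, DisturbanceProfile(urban_flashiness=0.9), seed=1
        )
        assert rate_metrics(out)["RA1"] > rate_metrics(reference)["RA1"]


class TestCovariates:
    def test_zero_noise_gives_perfect_rank_correlation(self):
        from scipy.stats import spearmanr

        net = generate_gauge_network(60, reference_fraction=0.3, seed=4)
        cov = generate_covariates(net, noise_sd=0.0, seed=1)
        dam = np.array([g.disturbance.dam_storage_intensity for g in net.gauges])
        rho = spearmanr(cov.loc[[g.id for g in net.gauges], "dam_storage_norm"], dam)
        assert rho.statistic == pytest.approx(1.0)

    def test_reference_rows_sit_at_baseline(self):
        net = generate_gauge_network(40, seed=4)
        cov = generate_covariates(net, noise_sd=0.0, seed=1)
        ref_ids = [g.id for g in net.reference_gauges]
        from eflow.synthetic import COVARIATE_GROUPS

        for group in ("urbanization", "dams_reservoirs", "dischargers_flow_modifiers"):
            block = cov.loc[ref_ids, COVARIATE_GROUPS[group]]
            assert (block.to_numpy() == 0).all()

    def test_fifty_columns_one_row_per_unit_deterministic(self):
        net = generate_gauge_network(20, n_reaches=15, seed=2)
        a = generate_covariates(net, noise_sd=0.2, seed=9)
        b = generate_covariates(net, noise_sd=0.2, seed=9)
        assert a.shape == (35, 50)
        pd.testing.assert_frame_equal(a, b)


class TestFishResponses:
    def test_zero_alteration_caps_residuals_at_wedge_apex(self):
        ha = pd.Series(0.0, index=[f"L{i}" for i in range(50)])
        obs = simulate_fish_responses(ha, true_threshold=0.4, max_loss=5, seed=1)
        assert max(o.richness_residual for o in obs) <= 0.0

    def test_zero_max_loss_degenerate_wedge(self):
        rng = np.random.default_rng(0)
        ha = pd.Series(rng.uniform(0, 1, 100))
        obs = simulate_fish_responses(ha, true_threshold=0.4, max_loss=0.0, seed=1)
        assert all(o.richness_residual <= 0 for o in obs)
        # upper bound is flat zero regardless of alteration
        worst = min(o.richness_residual for o in obs)
        assert worst >= -2.0 - 1e-12  # never below the wedge floor

    def test_threshold_outside_unit_interval_rejected(self):
        ha = pd.Series([0.1, 0.2])
        with pytest.raises(ValueError):
            simulate_fish_responses(ha, true_threshold=1.5, seed=1)

    def test_quantile_fit_recovers_tipping_point(self):
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(123)
        ha = pd.Series(rng.uniform(0, 1, 500), index=[f"L{i}" for i in range(500)])
        obs = simulate_fish_responses(ha, true_threshold=0.4, max_loss=5, seed=123)
        df = pd.DataFrame(
            {"ha": ha.to_numpy(), "r": [o.richness_residual for o in obs]}
        )
        res = smf.quantreg("r ~ ha", df).fit(q=0.95)
        b0, b1 = res.params["Intercept"], res.params["ha"]
        crossing = -b0 / b1
        assert abs(crossing - 0.4) <= 0.1


def test_true_alteration_reference_rows_zero_and_disturbed_nonzero():
    from eflow.synthetic import true_alteration_table

    net = generate_gauge_network(6, n_classes=2, reference_fraction=0.5, seed=8)
    table = true_alteration_table(net, n_years=15, seed=8)
    ref_ids = [g.id for g in net.reference_gauges]
    nonref_ids = [g.id for g in net.nonreference_gauges]
    assert (table.loc[ref_ids].to_numpy() == 0).all()
    assert table.loc[nonref_ids].to_numpy().max() > 0
    assert table.to_numpy().min() >= 0 and table.to_numpy().max() <= 1
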