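"""Synthetic gauge/reach network generator with known ground truth.

Emulates the statistical structure the alteration analysis assumes:

* class-specific reference daily flow regimes (seasonal sinusoid,
  multiplicative lognormal noise, Poisson storm pulses, optional dry-season
  intermittency),
* disturbance-perturbed flows (withdrawal scaling, dam smoothing with a
  minimum-release floor, urban storm spikes, seasonal rotation),
* a 50-column covariate table whose disturbance groups are noisy monotone
  transforms of the imposed disturbance intensities and whose natural
  columns depend only on drainage area and hydrologic class,
* wedge-shaped native-fish richness-residual responses to alteration with a
  known tipping point, suitable for quantile regression.

Every generator is a pure function of its configuration and seed.  Ground
truth alteration for tests is *computed* by running the metric engine on
paired reference/disturbed series, never assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .metrics import compute_metric_vector
from .series import DailyFlowSeries

__all__ = [
    "DisturbanceProfile",
    "GaugeRecord",
    "ReachRecord",
    "GaugeNetwork",
    "FishObservation",
    "ClassFlowConfig",
    "generate_gauge_network",
    "simulate_reference_flow",
    "apply_disturbance",
    "generate_covariates",
    "simulate_fish_responses",
    "true_alteration_table",
    "COVARIATE_GROUPS",
    "DISTURBANCE_DRIVER",
]


@dataclass(frozen=True)
class DisturbanceProfile:
    """Intensities of the anthropogenic pressures imposed on a gauge/reach."""

    dam_storage_intensity: float = 0.0  # [0, 1] regulation strength
    withdrawal_fraction: float = 0.0  # [0, 1) of flow removed
    urban_flashiness: float = 0.0  # [0, 1] impervious-runoff spikes
    seasonal_shift_months: int = 0  # 0-6 month rotation of seasonality

    def __post_init__(self) -> None:
        if not (0 <= self.dam_storage_intensity <= 1):
            raise ValueError("dam_storage_intensity must be in [0, 1]")
        if not (0 <= self.withdrawal_fraction < 1):
            raise ValueError("withdrawal_fraction must be in [0, 1)")
        if not (0 <= self.urban_flashiness <= 1):
            raise ValueError("urban_flashiness must be in [0, 1]")
        if not (0 <= self.seasonal_shift_months <= 6):
            raise ValueError("seasonal_shift_months must be in 0..6")

    @property
    def total(self) -> float:
        """Crude scalar summary of overall disturbance (used in tests)."""
        return (
            self.dam_storage_intensity
            + self.withdrawal_fraction
            + self.urban_flashiness
            + self.seasonal_shift_months / 6.0
        )

    @property
    def is_zero(self) -> bool:
        return self.total == 0.0


ZERO_DISTURBANCE = DisturbanceProfile()


@dataclass
class GaugeRecord:
    id: str
    is_reference: bool
    hydro_class: str
    region: str
    huc4: str
    drainage_area_km2: float
    disturbance: DisturbanceProfile = ZERO_DISTURBANCE

    def __post_init__(self) -> None:
        if self.drainage_area_km2 <= 0:
            raise ValueError("drainage_area_km2 must be positive")
        if self.is_reference and not self.disturbance.is_zero:
            raise ValueError("reference gauges must carry zero disturbance")


@dataclass
class ReachRecord:
    comid_v1: str
    comid_v2: str
    hydro_class: str
    region: str
    huc4: str
    drainage_area_km2: float
    disturbance: DisturbanceProfile = ZERO_DISTURBANCE

    @property
    def id(self) -> str:
        return self.comid_v1


@dataclass
class GaugeNetwork:
    gauges: list[GaugeRecord]
    reaches: list[ReachRecord]
    regions: list[str]
    classes: list[str]

    @property
    def reference_gauges(self) -> list[GaugeRecord]:
        return [g for g in self.gauges if g.is_reference]

    @property
    def nonreference_gauges(self) -> list[GaugeRecord]:
        return [g for g in self.gauges if not g.is_reference]

    def gauge_frame(self) -> pd.DataFrame:
        rows = [
            {
                "gauge_id": g.id,
                "is_reference": g.is_reference,
                "hydro_class": g.hydro_class,
                "region": g.region,
                "huc4": g.huc4,
                "drainage_area_km2": g.drainage_area_km2,
                "dam_storage_intensity": g.disturbance.dam_storage_intensity,
                "withdrawal_fraction": g.disturbance.withdrawal_fraction,
                "urban_flashiness": g.disturbance.urban_flashiness,
                "seasonal_shift_months": g.disturbance.seasonal_shift_months,
            }
            for g in self.gauges
        ]
        return pd.DataFrame(rows).set_index("gauge_id")

    def reach_frame(self) -> pd.DataFrame:
        rows = [
            {
                "comid_v1": r.comid_v1,
                "comid_v2": r.comid_v2,
                "hydro_class": r.hydro_class,
                "region": r.region,
                "huc4": r.huc4,
                "drainage_area_km2": r.drainage_area_km2,
                "dam_storage_intensity": r.disturbance.dam_storage_intensity,
                "withdrawal_fraction": r.disturbance.withdrawal_fraction,
                "urban_flashiness": r.disturbance.urban_flashiness,
                "seasonal_shift_months": r.disturbance.seasonal_shift_months,
            }
            for r in self.reaches
        ]
        cols = ["comid_v1", "comid_v2", "hydro_class", "region", "huc4",
                "drainage_area_km2", "dam_storage_intensity",
                "withdrawal_fraction", "urban_flashiness",
                "seasonal_shift_months"]
        return pd.DataFrame(rows, columns=cols).set_index("comid_v1")


@dataclass
class FishObservation:
    """One fish-survey location: richness residual + paired alteration values."""

    location_id: str
    region: str
    huc4: str
    richness_residual: float
    alterations: dict[str, float] = field(default_factory=dict)


def _draw_disturbance(rng: np.random.Generator) -> DisturbanceProfile:
    """One non-reference disturbance regime.

    Dam regulation is the dominant pressure (beta(1.5, 2.5)); withdrawals and
    urbanization are typically milder; seasonal shifts are rare and small.
    The joint distribution is independent across pressures — chosen for
    testability, not realism.
    """
    return DisturbanceProfile(
        dam_storage_intensity=float(rng.beta(1.5, 2.5)),
        withdrawal_fraction=float(min(rng.beta(1.2, 4.0), 0.95)),
        urban_flashiness=float(rng.beta(1.2, 3.5)),
        seasonal_shift_months=int(rng.choice([0, 0, 0, 1, 1, 2])),
    )


def _draw_area(rng: np.random.Generator) -> float:
    return float(np.exp(rng.normal(5.5, 1.0)))  # km^2, median ~245


def generate_gauge_network(
    n_gauges: int,
    n_reaches: int = 0,
    n_regions: int = 2,
    n_classes: int = 2,
    reference_fraction: float = 0.5,
    huc4_per_region: int = 2,
    seed: int = 0,
) -> GaugeNetwork:
    """Generate gauges and ungauged reaches with known disturbance regimes.

    Regions, classes and HUC-4s are assigned round-robin so every stratum is
    populated whenever ``n_gauges >= n_regions * huc4_per_region``.  Exactly
    ``round(reference_fraction * n_gauges)`` gauges are reference (chosen by a
    seeded permutation); reference gauges carry zero disturbance.
    """
    if n_gauges < 2:
        raise ValueError("n_gauges must be >= 2")
    if n_reaches < 0:
        raise ValueError("n_reaches must be >= 0")
    if not (0 < reference_fraction < 1):
        raise ValueError("reference_fraction must be in (0, 1)")
    if n_regions < 1 or n_classes < 1:
        raise ValueError("n_regions and n_classes must be positive")
    rng = np.random.default_rng(seed)
    regions = [f"R{i + 1:02d}" for i in range(n_regions)]
    classes = [f"C{i + 1}" for i in range(n_classes)]
    n_ref = round(reference_fraction * n_gauges)
    ref_flags = np.zeros(n_gauges, dtype=bool)
    ref_flags[rng.permutation(n_gauges)[:n_ref]] = True

    gauges = []
    for i in range(n_gauges):
        region = regions[i % n_regions]
        huc = f"{region}H{(i // n_regions) % huc4_per_region + 1}"
        gauges.append(
            GaugeRecord(
                id=f"G{i + 1:05d}",
                is_reference=bool(ref_flags[i]),
                hydro_class=classes[i % n_classes],
                region=region,
                huc4=huc,
                drainage_area_km2=_draw_area(rng),
                disturbance=(
                    ZERO_DISTURBANCE if ref_flags[i] else _draw_disturbance(rng)
                ),
            )
        )
    reaches = []
    for i in range(n_reaches):
        region = regions[i % n_regions]
        huc = f"{region}H{(i // n_regions) % huc4_per_region + 1}"
        disturbed = rng.random() > 0.25  # most reaches carry some pressure
        reaches.append(
            ReachRecord(
                comid_v1=f"V1_{i + 1:06d}",
                comid_v2=f"V2_{i + 1:06d}",
                hydro_class=classes[i % n_classes],
                region=region,
                huc4=huc,
                drainage_area_km2=_draw_area(rng),
                disturbance=_draw_disturbance(rng) if disturbed else ZERO_DISTURBANCE,
            )
        )
    return GaugeNetwork(gauges=gauges, reaches=reaches, regions=regions, classes=classes)


@dataclass(frozen=True)
class ClassFlowConfig:
    """Natural flow-regime archetype for one hydrologic class.

    ``mean_specific_runoff`` is discharge per unit area (cfs/km2); the
    seasonal component is ``1 + amplitude * sin(2*pi*(doy - phase)/365)``.
    Intermittent classes subtract ``dry_offset`` before clipping at zero,
    producing an annual dry season.
    """

    amplitude: float = 0.4
    phase_days: float = 90.0
    noise_sd: float = 0.25  # lognormal sigma of multiplicative daily noise
    storm_rate: float = 0.03  # Poisson storms per day
    storm_scale: float = 3.0  # mean storm peak, in multiples of base flow
    storm_decay: float = 0.45  # per-day exponential recession of storm pulses
    mean_specific_runoff: float = 0.05
    intermittent: bool = False
    dry_offset: float = 0.0


def default_class_configs(classes: list[str]) -> dict[str, ClassFlowConfig]:
    """Distinct archetypes per class; the last class is intermittent."""
    configs: dict[str, ClassFlowConfig] = {}
    for i, c in enumerate(classes):
        intermittent = len(classes) > 1 and i == len(classes) - 1
        configs[c] = ClassFlowConfig(
            amplitude=0.3 + 0.15 * (i % 3),
            phase_days=45.0 * i,
            intermittent=intermittent,
            dry_offset=0.55 if intermittent else 0.0,
        )
    return configs


def _dates(n_years: int, start_year: int = 1990) -> pd.DatetimeIndex:
    idx = pd.date_range(f"{start_year - 1}-10-01", periods=int(n_years * 366), freq="D")
    idx = idx[~((idx.month == 2) & (idx.day == 29))]
    return idx[: n_years * 365]


def simulate_reference_flow(
    gauge: GaugeRecord,
    n_years: int = 20,
    seed: int = 0,
    config: ClassFlowConfig | None = None,
    start_year: int = 1990,
) -> DailyFlowSeries:
    """Reference (least-disturbed) daily discharge for one gauge.

    Seasonal sinusoid scaled by drainage area, multiplied by lognormal noise,
    plus exponentially recessing Poisson storm pulses.  With noise and storms
    disabled the series is a pure sinusoid whose mean over whole years equals
    ``mean_specific_runoff * area`` exactly.
    """
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    cfg = config or ClassFlowConfig()
    rng = np.random.default_rng(seed)
    n = n_years * 365
    doy = np.arange(n) % 365
    base_mean = cfg.mean_specific_runoff * gauge.drainage_area_km2
    seasonal = 1.0 + cfg.amplitude * np.sin(2 * np.pi * (doy - cfg.phase_days) / 365.0)
    if cfg.intermittent:
        seasonal = np.maximum(seasonal - cfg.dry_offset, 0.0)
    flow = base_mean * seasonal
    if cfg.noise_sd > 0:
        flow = flow * rng.lognormal(mean=-0.5 * cfg.noise_sd**2, sigma=cfg.noise_sd, size=n)
    if cfg.storm_rate > 0 and cfg.storm_scale > 0:
        storms = rng.poisson(cfg.storm_rate, size=n).astype(float)
        peaks = storms * rng.exponential(cfg.storm_scale * base_mean, size=n)
        # exponential recession via a causal IIR filter
        pulse = np.empty(n)
        carry = 0.0
        decay = np.exp(-cfg.storm_decay)
        for t in range(n):
            carry = carry * decay + peaks[t]
            pulse[t] = carry
        flow = flow + pulse
    flows = pd.Series(flow, index=_dates(n_years, start_year))
    return DailyFlowSeries(
        gauge_id=gauge.id,
        flows=flows,
        units="cfs",
        drainage_area_km2=gauge.drainage_area_km2,
    )


@dataclass(frozen=True)
class DisturbanceOperators:
    """Tunable knobs of the disturbance->flow operators."""

    max_smoothing_window: int = 30  # days at dam_storage_intensity = 1
    release_floor_quantile: float = 0.5  # floor = intensity * this quantile
    urban_spike_rate: float = 0.08  # extra storms/day at urban_flashiness = 1
    urban_spike_scale: float = 4.0  # spike peak in multiples of mean flow


def apply_disturbance(
    reference: DailyFlowSeries,
    profile: DisturbanceProfile,
    seed: int = 0,
    operators: DisturbanceOperators | None = None,
) -> DailyFlowSeries:
    """Impose a disturbance regime on a reference record.

    Order of operators: seasonal rotation, dam smoothing + minimum-release
    floor, withdrawal scaling, urban storm spikes.  A zero profile returns
    the input unchanged.  Any negative values are clipped to zero.
    """
    if profile.is_zero:
        return reference
    ops = operators or DisturbanceOperators()
    rng = np.random.default_rng(seed)
    x = reference.flows.to_numpy(dtype=float).copy()
    n = x.size

    if profile.seasonal_shift_months:
        x = np.roll(x, int(profile.seasonal_shift_months * 30))

    if profile.dam_storage_intensity > 0:
        d = profile.dam_storage_intensity
        window = max(1, int(round(1 + d * (ops.max_smoothing_window - 1))))
        if window > 1:
            kernel = np.ones(window) / window
            smoothed = np.convolve(
                np.pad(x, (window - 1, 0), mode="edge"), kernel, mode="valid"
            )
            x = (1 - d) * x + d * smoothed
        floor = d * np.quantile(x, ops.release_floor_quantile) * 0.5
        x = np.maximum(x, floor)

    if profile.withdrawal_fraction > 0:
        x = x * (1.0 - profile.withdrawal_fraction)

    if profile.urban_flashiness > 0:
        u = profile.urban_flashiness
        spikes = rng.poisson(u * ops.urban_spike_rate, size=n).astype(float)
        peaks = spikes * rng.exponential(ops.urban_spike_scale * x.mean(), size=n)
        pulse = np.empty(n)
        carry = 0.0
        decay = np.exp(-1.5)  # fast urban recession
        for t in range(n):
            carry = carry * decay + peaks[t]
            pulse[t] = carry
        x = x + u * pulse

    n_clipped = int((x < 0).sum())
    if n_clipped:
        x = np.maximum(x, 0.0)
    out = reference.with_flows(pd.Series(x, index=reference.flows.index))
    return out


# ---------------------------------------------------------------------------
# covariates

#: the 8 predictor groups and their column counts (total 50)
COVARIATE_GROUPS: dict[str, list[str]] = {
    "urbanization": [f"urb_{s}" for s in (
        "imperv_pct", "developed_pct", "road_density", "housing_density",
        "pop_density", "commercial_pct", "lawn_pct", "canopy_loss_pct",
        "storm_drains", "imperv_accum", "developed_accum", "road_accum",
        "pop_accum", "nightlight",
    )],
    "agriculture": [f"ag_{s}" for s in (
        "crop_pct", "pasture_pct", "irrigated_pct", "tile_drain_pct",
        "fertilizer_kg", "crop_accum", "pasture_accum", "irrigated_accum",
        "cafo_density", "canal_density",
    )],
    "dams_reservoirs": [f"dam_{s}" for s in (
        "storage_norm", "degree_regulation", "count_upstream", "major_count",
        "height_max", "nid_storage_accum",
    )],
    "power_generation": [f"pow_{s}" for s in (
        "hydro_mw", "thermo_mw", "plant_count", "hydro_accum",
        "thermo_accum", "transmission_density",
    )],
    "dischargers_flow_modifiers": [f"dis_{s}" for s in (
        "npdes_density", "withdrawal_mgd", "interbasin_transfer",
        "diversion_count", "wwtp_flow",
    )],
    "disturbance_indices": ["idx_hdi", "idx_footprint", "idx_frag"],
    "basin_stream_climate": ["nat_drainage_area", "nat_precip_mm", "nat_stream_order"],
    "natural_cover": ["nat_forest_pct", "nat_wetland_pct", "nat_grass_pct"],
}

#: which true disturbance intensity drives each disturbance-linked group
DISTURBANCE_DRIVER: dict[str, str] = {
    "urbanization": "urban_flashiness",
    "agriculture": "withdrawal_fraction",
    "dams_reservoirs": "dam_storage_intensity",
    "power_generation": "dam_storage_intensity",
    "dischargers_flow_modifiers": "withdrawal_fraction",
    "disturbance_indices": "total",
}

ALL_COVARIATES = [c for cols in COVARIATE_GROUPS.values() for c in cols]


def _monotone(v: np.ndarray, j: int, scale: float) -> np.ndarray:
    """j-th strictly monotone transform of an intensity in [0, ~3]."""
    p = 0.5 + 0.35 * (j % 4)  # powers 0.5, 0.85, 1.2, 1.55
    return scale * np.power(v, p)


def generate_covariates(
    network: GaugeNetwork,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """50-column predictor table, one row per gauge and per reach.

    Disturbance-group columns are strictly monotone transforms of the true
    intensity driving that group, with additive Gaussian noise of standard
    deviation `noise_sd` applied to the intensity before the transform (so
    ``noise_sd=0`` gives perfect rank correlation and reference rows sit at
    the zero-disturbance baseline).  Natural columns depend only on drainage
    area and hydrologic class.
    """
    if not network.gauges and not network.reaches:
        raise ValueError("network is empty")
    rng = np.random.default_rng(seed)
    units: list = list(network.gauges) + list(network.reaches)
    ids = [u.id for u in units]
    intensities = {
        "dam_storage_intensity": np.array(
            [u.disturbance.dam_storage_intensity for u in units]
        ),
        "withdrawal_fraction": np.array(
            [u.disturbance.withdrawal_fraction for u in units]
        ),
        "urban_flashiness": np.array([u.disturbance.urban_flashiness for u in units]),
        "total": np.array([u.disturbance.total for u in units]),
    }
    areas = np.array([u.drainage_area_km2 for u in units])
    class_idx = np.array(
        [network.classes.index(u.hydro_class) for u in units], dtype=float
    )
    data: dict[str, np.ndarray] = {}
    for group, cols in COVARIATE_GROUPS.items():
        driver = DISTURBANCE_DRIVER.get(group)
        for j, col in enumerate(cols):
            if driver is not None:
                v = intensities[driver]
                if noise_sd > 0:
                    v = np.clip(v + rng.normal(0, noise_sd, v.size), 0, None)
                data[col] = _monotone(v, j, scale=10.0 * (1 + j % 3))
            elif col == "nat_drainage_area":
                data[col] = areas
            elif col == "nat_precip_mm":
                data[col] = 600.0 + 120.0 * class_idx
            elif col == "nat_stream_order":
                data[col] = np.clip(np.round(np.log10(areas) + 1), 1, 9)
            else:  # natural cover: class-dependent composition
                frac = 0.2 + 0.1 * ((class_idx + j) % 3)
                data[col] = 100.0 * frac
    df = pd.DataFrame(data, index=pd.Index(ids, name="id"), columns=ALL_COVARIATES)
    return df


NATURAL_COVARIATES = (
    COVARIATE_GROUPS["basin_stream_climate"] + COVARIATE_GROUPS["natural_cover"]
)


def simulate_fish_responses(
    alteration: pd.Series | pd.DataFrame,
    true_threshold: float,
    max_loss: float = 5.0,
    seed: int = 0,
    regions: pd.Series | None = None,
    huc4s: pd.Series | None = None,
    wedge_depth: float = 2.0,
) -> list[FishObservation]:
    """Wedge-shaped fish richness residuals with a known tipping point.

    The upper envelope U(HA) of the residuals is 0 for HA <= `true_threshold`
    and declines linearly to ``-max_loss`` at HA = 1; residuals are drawn
    uniformly on ``[U - wedge_depth, U]`` (uniform noise keeps the fitted
    upper-quantile bound analytically predictable).  The 95th-percentile
    regression of residual on HA therefore crosses zero near the threshold.

    `alteration` may be a Series (a single driver) or a DataFrame
    (location x metric); the wedge driver is the Series or the row mean of
    the DataFrame, and all per-metric values are stored on each observation.
    """
    if not (0 < true_threshold < 1):
        raise ValueError("true_threshold must be in (0, 1)")
    if max_loss < 0 or wedge_depth < 0:
        raise ValueError("max_loss and wedge_depth must be non-negative")
    if isinstance(alteration, pd.DataFrame):
        driver = alteration.mean(axis=1)
        table = alteration
    else:
        driver = alteration
        table = alteration.to_frame("HA")
    vals = driver.to_numpy(dtype=float)
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 1:
        raise ValueError("alteration values must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    over = np.clip(vals - true_threshold, 0, None) / (1.0 - true_threshold)
    upper = -max_loss * over
    residuals = upper - rng.uniform(0.0, wedge_depth, size=vals.size)
    obs = []
    for i, loc in enumerate(driver.index):
        obs.append(
            FishObservation(
                location_id=str(loc),
                region=str(regions.loc[loc]) if regions is not None else "R01",
                huc4=str(huc4s.loc[loc]) if huc4s is not None else "R01H1",
                richness_residual=float(residuals[i]),
                alterations={
                    str(m): float(table.iloc[i][m]) for m in table.columns
                },
            )
        )
    return obs


def true_alteration_table(
    network: GaugeNetwork,
    n_years: int = 20,
    seed: int = 0,
    class_configs: dict[str, ClassFlowConfig] | None = None,
) -> pd.DataFrame:
    """Ground-truth per-metric alteration for test assertions.

    For each non-reference gauge, runs the metric engine on its paired
    reference and disturbed series and applies the capped |(O-E)/E| rule with
    the true reference metrics as E.  Reference gauges are all-zero rows.
    """
    from .alteration import compute_alteration  # local import avoids a cycle

    cfgs = class_configs or default_class_configs(network.classes)
    ss = np.random.SeedSequence(seed)
    rows = {}
    for g, child in zip(network.gauges, ss.spawn(len(network.gauges))):
        sub = child.generate_state(2)
        ref = simulate_reference_flow(
            g, n_years=n_years, seed=int(sub[0] % 2**31), config=cfgs[g.hydro_class]
        )
        mv_ref = compute_metric_vector(ref)
        if g.is_reference:
            rows[g.id] = {m: 0.0 for m in mv_ref.values}
            continue
        obs = apply_disturbance(ref, g.disturbance, seed=int(sub[1] % 2**31))
        mv_obs = compute_metric_vector(obs)
        rows[g.id] = {
            m: compute_alteration(mv_obs[m], mv_ref[m]) for m in mv_ref.values
        }
    return pd.DataFrame.from_dict(rows, orient="index")
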