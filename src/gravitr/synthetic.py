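"""Synthetic gravimetric phenotyping experiments with known ground truth.

No public dataset accompanies the analysis pipeline, so every downstream
stage is exercised against simulated experiments in which the answers are
known by construction: diurnal weather whose vapour pressure deficit peaks
around midday (series maximum ~6.29 kPa by default), genotype archetypes
with a saturating transpiration-rate response to VPD (linear rise, plateau
above a configured fraction of maximum VPD), tray weight traces that lose
the implied water plus sensor noise, irrigation refills every few days with
short drainage transients, and 3-D scanner leaf-area records.

The generator writes the same CSV schemas the pipeline reads plus a JSON
sidecar with the ground truth (cluster labels, breakpoint fractions); the
sidecar is never consumed by the pipeline itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import refet
from .canopy import LA_SCANNER_FACTOR

#: default series maximum of VPD, kPa
VPD_MAX_DEFAULT = 6.29


@dataclass
class GenotypeArchetype:
    """Ground-truth transpiration behaviour of one genotype.

    ``max_tr_scale`` is the plateau transpiration rate
    (mm m-2 leaf 15min-1); ``breakpoint_fraction`` the fraction of the
    experiment's maximum VPD at which TR stops rising.
    """

    genotype_id: str
    group: str
    max_tr_scale: float
    breakpoint_fraction: float
    leaf_area_m2: float      # observed leaf area per sector

    def __post_init__(self):
        if not (0 < self.breakpoint_fraction <= 1):
            raise ValueError("breakpoint_fraction must lie in (0, 1]")
        if self.max_tr_scale <= 0:
            raise ValueError("max_tr_scale must be positive")
        if self.leaf_area_m2 <= 0:
            raise ValueError("leaf_area_m2 must be positive")

    def tr_response(self, vpd, vpd_max, blend: float = 0.15):
        """True transpiration rate (mm m-2 15min-1) at the given VPD.

        Rises with VPD and is exactly constant above the knee at
        ``breakpoint_fraction * vpd_max`` — the saturating water-saving
        response.  Stomatal closure is gradual, so the ramp meets the
        plateau through a C1 quadratic blend over the last ``blend``
        fraction below the knee (slope reaches zero at the knee, value and
        slope continuous).  VPD is the sole driver; night-time fluxes are
        small because night VPD is small.
        """
        vpd = np.asarray(vpd, dtype=float)
        k = self.breakpoint_fraction * vpd_max
        a = (1.0 - blend) * k
        # linear slope m chosen so the blended curve tops out at max_tr_scale
        m = self.max_tr_scale / (k - blend * k / 2.0)
        quad = self.max_tr_scale - m * (k - vpd) ** 2 / (2.0 * blend * k)
        out = np.where(vpd <= a, m * vpd,
                       np.where(vpd >= k, self.max_tr_scale, quad))
        return out


@dataclass
class SimulationConfig:
    """Deterministic (seeded) configuration of one simulated experiment."""

    n_days: int = 15
    steps_per_day: int = 96
    start: str = "2017-02-20"
    irrigation_days: tuple = (1, 5, 9, 13)
    irrigation_hour: float = 5.0
    noise_sd: float = 2.5           # grams, additive load-cell noise
    spike_prob: float = 0.8         # drainage transient per irrigation event
    seed: int = 0
    # weather shape
    t_min: float = 22.0
    t_max: float = 40.0
    rh_max: float = 90.0
    vpd_max: float = VPD_MAX_DEFAULT
    rad_peak: float = 0.6           # MJ m-2 15min-1 on the clearest day
    ws_base: float = 2.5
    ws_amp: float = 1.5
    day_factor_range: tuple = (0.98, 1.0)
    initial_weight_g: float = 28000.0

    def __post_init__(self):
        if self.n_days <= 0:
            raise ValueError("n_days must be positive")
        if self.steps_per_day <= 0:
            raise ValueError("steps_per_day must be positive")

    @property
    def n_steps(self) -> int:
        return self.n_days * self.steps_per_day

    def timestamps(self) -> pd.DatetimeIndex:
        step = pd.Timedelta(minutes=24 * 60 / self.steps_per_day)
        return pd.date_range(self.start, periods=self.n_steps, freq=step)


def _diurnal_shape(hours, start=7.0, length=12.0):
    """Half-sine between ``start`` and ``start+length`` local hours, else 0."""
    phase = (hours - start) / length
    return np.where((phase > 0) & (phase < 1), np.sin(np.pi * phase), 0.0)


def _skewed_shape(hours, start, peak, end):
    """Asymmetric diurnal bump: half-cosine rise to 1 at ``peak``, fall to 0.

    Distinct rise and fall durations per variable reproduce the phase
    structure of real days (radiation symmetric about solar noon,
    temperature peaking later and decaying slowly, humidity recovering
    quickly in late afternoon); the resulting hysteresis decorrelates the
    weather variables over the diurnal cycle.
    """
    up = (hours - start) / (peak - start)
    down = (hours - peak) / (end - peak)
    rise = 0.5 * (1.0 - np.cos(np.pi * np.clip(up, 0.0, 1.0)))
    fall = 0.5 * (1.0 + np.cos(np.pi * np.clip(down, 0.0, 1.0)))
    return np.where(hours <= peak, np.where(hours >= start, rise, 0.0),
                    np.where(hours <= end, fall, 0.0))


def _ar1(rng, n, sd, rho=0.9):
    """Smooth AR(1) noise with stationary standard deviation ``sd``."""
    if sd <= 0:
        return np.zeros(n)
    e = rng.normal(0.0, sd * np.sqrt(1 - rho ** 2), size=n)
    out = np.empty(n)
    out[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        out[i] = rho * out[i - 1] + e[i]
    return out


def simulate_weather(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a diurnal weather table on the 15-min grid.

    The variables follow the phase structure of real clear-season days
    rather than one shared shape: radiation is symmetric about solar noon
    (~12:50), temperature lags it and peaks ~14:00, relative humidity keeps
    falling until ~15:00, and wind peaks late afternoon.  These lags put the
    day's weather on a hysteresis loop (morning and afternoon visit
    different T/RH/RAD combinations at the same VPD), which is what lets a
    downstream model attribute the transpiration response to VPD rather
    than to any co-varying variable.  Smooth AR(1) disturbances add cloud
    flicker to RAD and humidity/wind variability.

    Day-to-day amplitude factors vary within ``day_factor_range``; the
    strongest day is pinned at factor 1 and its humidity minimum solved so
    the deterministic series maximum of VPD equals ``vpd_max``.
    """
    rng = np.random.default_rng(config.seed)
    ts = config.timestamps()
    hours = ts.hour.to_numpy() + ts.minute.to_numpy() / 60.0
    day_idx = np.repeat(np.arange(config.n_days), config.steps_per_day)
    n = config.n_steps

    lo, hi = config.day_factor_range
    factors = rng.uniform(lo, hi, size=config.n_days)
    factors[rng.integers(config.n_days)] = hi
    s = factors[day_idx]

    # rise/peak/fall times differ per variable: radiation is symmetric about
    # solar noon, temperature lags and decays slowly into the evening, the
    # humidity deficit peaks mid-afternoon but recovers quickly, wind peaks
    # late; the lags create hysteresis loops over the diurnal cycle
    shape_t = _skewed_shape(hours, start=7.0, peak=14.5, end=22.0)
    shape_rh = _skewed_shape(hours, start=8.0, peak=16.0, end=24.0)
    shape_rad = _diurnal_shape(hours, start=6.5, length=12.75)   # 06:30-19:15
    shape_ws = _skewed_shape(hours, start=9.0, peak=16.5, end=24.0)

    # humidity minimum on the strongest day solved so that max VPD = vpd_max
    from scipy.optimize import brentq

    t_det = config.t_min + hi * (config.t_max - config.t_min) * shape_t[:config.steps_per_day]
    srh = shape_rh[:config.steps_per_day]

    def peak_vpd(rh_min):
        rh = config.rh_max - hi * (config.rh_max - rh_min) * srh
        return float(np.max(refet.svp(t_det) * (1 - rh / 100.0))) - config.vpd_max

    if peak_vpd(0.0) < 0:
        raise ValueError("vpd_max unreachable for the configured t_max/rh_max")
    rh_min = brentq(peak_vpd, 0.0, config.rh_max - 1e-9)

    T = config.t_min + s * (config.t_max - config.t_min) * shape_t
    RH = config.rh_max - s * (config.rh_max - rh_min) * shape_rh
    RH = RH + _ar1(rng, n, sd=1.5)
    RH = np.clip(RH, 1.0, 100.0)
    cloud = np.clip(1.0 - np.abs(_ar1(rng, n, sd=0.15)), 0.0, 1.0)
    RAD = s * config.rad_peak * shape_rad * cloud
    WS = np.maximum(config.ws_base + s * config.ws_amp * shape_ws
                    + _ar1(rng, n, sd=0.2), 0.0)

    w = pd.DataFrame({"timestamp": ts, "T": T, "RH": RH, "WS": WS, "RAD": RAD})
    w["Rn"] = refet.net_radiation(w["RAD"])
    w["G"] = refet.soil_heat_flux(w["Rn"], w["RAD"] > 0)
    return w


def _weather_vpd(weather: pd.DataFrame) -> np.ndarray:
    return np.asarray(refet.vpd(weather["T"], weather["RH"]), dtype=float)


@dataclass
class LoadCellTrace:
    """One simulated sector: weights plus stored ground truth."""

    sector_id: str
    weights: np.ndarray
    true_tr: np.ndarray          # mm m-2 15min-1, per step
    true_et_grams: np.ndarray    # grams lost per step (before noise)
    archetype: GenotypeArchetype


def simulate_loadcell(arch: GenotypeArchetype, weather: pd.DataFrame,
                      config: SimulationConfig,
                      sector_id: str = "S001",
                      rng: np.random.Generator | None = None) -> LoadCellTrace:
    """Simulate one tray's weight trace under the archetype's TR response.

    Each step loses ``leaf_area x TR_true(VPD)`` grams of water
    (1 mm over 1 m2 of leaf = 1000 g); irrigation days get a refill back to
    the initial weight at the configured hour plus, with probability
    ``spike_prob``, a 1-3 sample drainage transient; Gaussian sensor noise
    is added on top.  Ground-truth TR is stored alongside.
    """
    if len(weather) != config.n_steps:
        raise ValueError("weather grid does not match the simulation config")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    vpd = _weather_vpd(weather)
    true_tr = arch.tr_response(vpd, config.vpd_max)
    loss_g = true_tr * arch.leaf_area_m2 * 1000.0   # mm*m2 -> grams

    n = config.n_steps
    weight = np.empty(n)
    weight[0] = config.initial_weight_g
    level = config.initial_weight_g
    spd = config.steps_per_day
    irr_step = int(round(config.irrigation_hour * spd / 24.0))
    spikes = np.zeros(n)
    w = config.initial_weight_g
    for t in range(1, n):
        w = w - loss_g[t]
        day, step_in_day = divmod(t, spd)
        if day in config.irrigation_days and step_in_day == irr_step:
            w = config.initial_weight_g                 # refill to capacity
            if rng.uniform() < config.spike_prob:       # drainage transient
                k = rng.integers(1, 4)
                amp = rng.uniform(200.0, 500.0)
                for i in range(k):
                    if t + 1 + i < n:
                        spikes[t + 1 + i] += amp * (0.5 ** i)
        weight[t] = w
    noise = rng.normal(0.0, config.noise_sd, size=n) if config.noise_sd > 0 else 0.0
    weights = weight + spikes + noise
    return LoadCellTrace(sector_id=sector_id, weights=weights,
                         true_tr=true_tr, true_et_grams=loss_g,
                         archetype=arch)


@dataclass
class ExperimentBundle:
    """A complete simulated experiment in the pipeline's input schemas."""

    loadcells: pd.DataFrame      # timestamp + one grams column per sector
    weather: pd.DataFrame
    leafarea: pd.DataFrame       # sector_id, timestamp, la3d_m2
    design: pd.DataFrame         # sector_id, genotype_id, replicate, group
    ground_truth: dict
    config: SimulationConfig
    true_tr: pd.DataFrame = field(repr=False, default=None)

    def write(self, outdir) -> Path:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.loadcells.to_csv(outdir / "loadcells.csv", index=False)
        self.weather.to_csv(outdir / "weather.csv", index=False)
        self.leafarea.to_csv(outdir / "leafarea.csv", index=False)
        self.design.to_csv(outdir / "design.csv", index=False)
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth, fh, indent=2)
        return outdir


def default_archetype_clusters():
    """Three archetype families with distinct TR scale and VPD breakpoint."""
    return {
        "wild":   {"max_tr_scale": 0.035, "breakpoint_fraction": 0.56},
        "highTE": {"max_tr_scale": 0.0625, "breakpoint_fraction": 0.70},
        "lowTE":  {"max_tr_scale": 0.090, "breakpoint_fraction": 0.80},
    }


def make_population(config: SimulationConfig | None = None,
                    clusters: dict | None = None,
                    n_genotypes_per_cluster: int = 16,
                    n_replicates: int = 4,
                    leaf_area_m2: float = 0.25,
                    scale_jitter: float = 0.04,
                    la_jitter: float = 0.08) -> ExperimentBundle:
    """Simulate a multi-genotype experiment with known cluster structure.

    ``clusters`` maps group label -> {max_tr_scale, breakpoint_fraction};
    each genotype in a cluster jitters the TR scale and leaf area
    (lognormal-ish multiplicative noise) while keeping the cluster's
    breakpoint fraction exact, so the ground-truth breakpoints per cluster
    are the configured values.
    """
    if config is None:
        config = SimulationConfig()
    if clusters is None:
        clusters = default_archetype_clusters()
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    if n_replicates < 2:
        raise ValueError("need at least two replicates per genotype")

    rng = np.random.default_rng(config.seed)
    weather = simulate_weather(config)

    archetypes, design_rows = [], []
    gcount = 0
    for group, spec in clusters.items():
        for _ in range(n_genotypes_per_cluster):
            gcount += 1
            gid = f"G{gcount:03d}"
            scale = spec["max_tr_scale"] * float(np.exp(rng.normal(0, scale_jitter)))
            archetypes.append(GenotypeArchetype(
                genotype_id=gid, group=group, max_tr_scale=scale,
                breakpoint_fraction=spec["breakpoint_fraction"],
                leaf_area_m2=leaf_area_m2,
            ))

    ts = config.timestamps()
    load_cols, la_rows, tr_cols = {}, [], {}
    sector = 0
    for arch in archetypes:
        for rep in range(1, n_replicates + 1):
            sector += 1
            sid = f"S{sector:03d}"
            la = arch.leaf_area_m2 * float(np.exp(rng.normal(0, la_jitter)))
            sec_arch = GenotypeArchetype(
                genotype_id=arch.genotype_id, group=arch.group,
                max_tr_scale=arch.max_tr_scale,
                breakpoint_fraction=arch.breakpoint_fraction,
                leaf_area_m2=la,
            )
            trace = simulate_loadcell(sec_arch, weather, config,
                                      sector_id=sid, rng=rng)
            load_cols[sid] = trace.weights
            tr_cols[sid] = trace.true_tr
            design_rows.append({"sector_id": sid,
                                "genotype_id": arch.genotype_id,
                                "replicate": rep, "group": arch.group})
            # scanner records every 2 h, slight within-day wobble
            scan_times = ts[:: max(1, config.steps_per_day // 12)]
            la3d = la / LA_SCANNER_FACTOR
            wobble = 1.0 + rng.normal(0, 0.01, size=len(scan_times))
            la_rows.append(pd.DataFrame({
                "sector_id": sid, "timestamp": scan_times,
                "la3d_m2": la3d * np.minimum(wobble, 1.0),
            }))

    loadcells = pd.DataFrame({"timestamp": ts, **load_cols})
    leafarea = pd.concat(la_rows, ignore_index=True)
    design = pd.DataFrame(design_rows)
    true_tr = pd.DataFrame({"timestamp": ts, **tr_cols})

    ground_truth = {
        "vpd_max": config.vpd_max,
        "cluster_breakpoints": {g: s["breakpoint_fraction"]
                                for g, s in clusters.items()},
        "cluster_max_tr_scale": {g: s["max_tr_scale"]
                                 for g, s in clusters.items()},
        "genotypes": {a.genotype_id: {"cluster": a.group,
                                      "breakpoint_fraction": a.breakpoint_fraction,
                                      "max_tr_scale": a.max_tr_scale}
                      for a in archetypes},
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
    }
    return ExperimentBundle(loadcells=loadcells, weather=weather,
                            leafarea=leafarea, design=design,
                            ground_truth=ground_truth, config=config,
                            true_tr=true_tr)
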