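"""End-to-end orchestration: raw CSV inputs to clusters, H2 and breakpoints.

Stages run in order: load-cell denoising (MODWT), reference-ET computation
and ratio filtering, per-day spline smoothing, Beer-law transpiration
extraction, per-day feature engineering, genotype clustering with feature
selection, genetics statistics, and neural-network sensitivity profiling
with VPD breakpoints.  Every stage writes its artifact into the run
directory; a summary JSON and a log capture provenance (seed, parameters,
per-stage sample counts).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import canopy, clustering, features, preprocess, quantstats, refet, sensitivity

log = logging.getLogger("gravitr")


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline, with the standard defaults."""

    seed: int = 0
    # preprocessing
    wavelet: str = "db2"
    wavelet_level: int = 3
    outlier_levels: tuple = (1, 2, 3)
    iqr_multiplier: float = 1.5
    # reference ET / filtering / smoothing
    gamma: float = refet.GAMMA_DEFAULT
    day_ratio_threshold: float = 1.0
    night_ratio_threshold: float = 1.5
    spline_knots: int = 20
    # canopy
    beta: float = canopy.BETA_DEFAULT
    tray_area_m2: float = canopy.TRAY_AREA_M2
    # features
    curvature_method: str = "quadratic"
    # clustering
    k_min: int = 2
    k_max: int = 10
    mtry_min: int = 1
    mtry_max: int = 10
    ntree: int = 500
    ntree_tune: int = 100
    cv_folds: int = 10
    dissimilarity: str = "one_minus"
    # sensitivity
    nn_hidden: int = 5
    nn_max_epochs: int = 1500
    nn_val_fraction: float = 0.3
    nn_models: int = 9
    nn_restarts: int = 30
    slope_epsilon: float = 0.05
    quantile_splits: tuple = (0, 20, 40, 60, 80, 100)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("outlier_levels", "quantile_splits"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["outlier_levels"] = list(self.outlier_levels)
        d["quantile_splits"] = list(self.quantile_splits)
        return d


@dataclass
class ValidationReport:
    errors: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def _check_grid(ts: pd.Series, name: str, report: ValidationReport):
    ts = pd.to_datetime(ts)
    if not ts.is_monotonic_increasing:
        report.errors.append(f"{name}: timestamps not monotonically increasing")
        return
    steps = ts.diff().dropna()
    bad = steps[steps != pd.Timedelta(minutes=15)]
    if len(bad):
        report.errors.append(
            f"{name}: non-15-min cadence at {bad.index[0]} "
            f"(gap {bad.iloc[0]})")
    if len(ts) % 96:
        report.warnings.append(
            f"{name}: length {len(ts)} is not a whole number of 96-step days")


def validate_inputs(loadcells: pd.DataFrame, weather: pd.DataFrame,
                    leafarea: pd.DataFrame, design: pd.DataFrame) -> ValidationReport:
    """Schema and cadence checks on the four input tables."""
    report = ValidationReport()
    for df, name, cols in [
        (loadcells, "loadcells", {"timestamp"}),
        (weather, "weather", {"timestamp", "T", "RH", "WS", "RAD"}),
        (leafarea, "leafarea", {"sector_id", "timestamp", "la3d_m2"}),
        (design, "design", {"sector_id", "genotype_id", "replicate", "group"}),
    ]:
        missing = cols - set(df.columns)
        if missing:
            report.errors.append(f"{name}: missing columns {sorted(missing)}")
    if report.errors:
        return report
    _check_grid(loadcells["timestamp"], "loadcells", report)
    _check_grid(weather["timestamp"], "weather", report)
    rh = weather["RH"]
    if ((rh < 0) | (rh > 100)).any():
        i = weather.index[(rh < 0) | (rh > 100)][0]
        report.errors.append(f"weather: RH out of [0,100] at row {i} ({rh[i]})")
    if (weather["RAD"] < 0).any():
        report.errors.append("weather: negative solar radiation")
    sectors = [c for c in loadcells.columns if c != "timestamp"]
    undesigned = set(sectors) - set(design["sector_id"])
    if undesigned:
        report.errors.append(
            f"design: sectors without design rows: {sorted(undesigned)[:5]}")
    unscanned = set(sectors) - set(leafarea["sector_id"])
    if unscanned:
        report.warnings.append(
            f"leafarea: sectors without scans: {sorted(unscanned)[:5]}")
    return report


@dataclass
class RunResult:
    """In-memory handle on every stage output of one pipeline run."""

    config: PipelineConfig
    weather: pd.DataFrame
    etr_smooth: pd.DataFrame          # mm per 15 min, per sector
    tr: pd.DataFrame                  # TR per sector (mm m-2 15min-1)
    feature_table: pd.DataFrame
    genotype_means: pd.DataFrame
    k: int
    dunn_scores: dict
    mtry: int
    oob_error: float
    labels: pd.Series                 # genotype -> cluster id (1-based)
    selected_features: list
    importance: pd.DataFrame
    heritability: pd.DataFrame
    anova_group: pd.DataFrame
    maxtr_regression: pd.DataFrame
    tukey_counts: dict
    nn_model: sensitivity.NNModel
    breakpoints: pd.DataFrame
    removal_percent: float
    summary: dict


def _load_csv(path_or_df, parse_ts=True):
    if isinstance(path_or_df, (str, Path)):
        df = pd.read_csv(path_or_df)
    else:
        df = path_or_df.copy()
    if parse_ts and "timestamp" in df.columns:
        df["timestamp"] = pd.to_datetime(df["timestamp"])
    return df


def run_pipeline(loadcells, weather, leafarea, design,
                 config: PipelineConfig | None = None,
                 outdir=None) -> RunResult:
    """Execute the full analysis and optionally write artifacts to ``outdir``.

    Inputs may be CSV paths or DataFrames in the documented schemas.
    """
    cfg = config or PipelineConfig()
    loadcells = _load_csv(loadcells)
    weather = _load_csv(weather)
    leafarea = _load_csv(leafarea)
    design = _load_csv(design, parse_ts=False)

    report = validate_inputs(loadcells, weather, leafarea, design)
    if not report.ok:
        raise ValueError("input validation failed: " + "; ".join(report.errors))
    for w in report.warnings:
        log.warning(w)

    rng = np.random.default_rng(cfg.seed)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        fh = logging.FileHandler(out / "run.log", mode="w")
        fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(fh)
        log.setLevel(logging.INFO)

    log.info("run_pipeline seed=%s", cfg.seed)

    # ---- weather derivations -------------------------------------------
    w = refet.derive_weather(weather.set_index("timestamp"), gamma=cfg.gamma)
    et0 = w["et0"]
    vpd_max = float(w["vpd"].max())
    ts = w.index

    sectors = [c for c in loadcells.columns if c != "timestamp"]
    lc = loadcells.set_index("timestamp")
    if not lc.index.equals(ts):
        raise ValueError("load-cell and weather grids differ")

    # ---- stage 1-3: denoise, difference, filter, smooth ----------------
    etr_cols, removed_fractions = {}, []
    for sid in sectors:
        cleaned, _mask = preprocess.clean_loadcell_series(
            lc[sid].to_numpy(), level=cfg.wavelet_level, wavelet=cfg.wavelet,
            iqr_multiplier=cfg.iqr_multiplier, levels=cfg.outlier_levels)
        etr_mm = preprocess.grams_to_mm(preprocess.weights_to_etr(cleaned),
                                        cfg.tray_area_m2)
        res = refet.ratio_filter(etr_mm, et0.to_numpy()[1:],
                                 w["RAD"].to_numpy()[1:],
                                 cfg.day_ratio_threshold,
                                 cfg.night_ratio_threshold)
        removed_fractions.append(res.removal_fraction)
        etr_cols[sid] = refet.smooth_daily(res.etr, steps_per_day=96,
                                           knots=cfg.spline_knots)
    etr_smooth = pd.DataFrame(etr_cols, index=ts[1:])
    removal_percent = float(100.0 * np.mean(removed_fractions))
    log.info("ratio filter removed %.1f%% of samples on average",
             removal_percent)

    # ---- stage 4: transpiration rate ------------------------------------
    daily_la = canopy.daily_max_leaf_area(leafarea)
    tr_cols = {}
    for sid in sectors:
        res = canopy.etr_to_tr(etr_smooth[sid], daily_la, sid, beta=cfg.beta)
        tr_cols[sid] = res["TR"]
    tr = pd.DataFrame(tr_cols, index=etr_smooth.index)

    # ---- stage 5: features ----------------------------------------------
    feature_table = features.extract_feature_table(
        tr, etr=etr_smooth, et0=et0.reindex(etr_smooth.index),
        curvature_method=cfg.curvature_method)
    genotype_means = features.aggregate_features(feature_table, design)
    if genotype_means.isna().any().any():
        genotype_means = genotype_means.dropna()
        log.warning("genotypes with missing feature means dropped")

    # ---- stage 6: clustering --------------------------------------------
    k, dunn_scores = clustering.dunn_select_k(
        genotype_means, range(cfg.k_min, cfg.k_max + 1))
    log.info("Dunn index selects k=%d", k)
    std_features = clustering.standardize(genotype_means)
    mtry, cv_errors = clustering.tune_mtry(
        std_features, range(cfg.mtry_min, cfg.mtry_max + 1),
        folds=cfg.cv_folds, ntree=cfg.ntree_tune,
        seed=int(rng.integers(2 ** 31 - 1)))
    urf = clustering.urf_dissimilarity(
        std_features, mtry=mtry, ntree=cfg.ntree,
        seed=int(rng.integers(2 ** 31 - 1)), method=cfg.dissimilarity)
    labels_arr, _ = clustering.pam_cluster(urf.dissimilarity, k)
    labels = pd.Series(labels_arr + 1, index=genotype_means.index,
                       name="cluster")
    imp = clustering.class_specific_importance(
        std_features, labels.to_numpy(), ntree=cfg.ntree, mtry=mtry,
        seed=int(rng.integers(2 ** 31 - 1)))
    # feature selection on the unsupervised forest's Gini importances
    selected, _split = clustering.select_features(urf.mdg)
    log.info("mtry=%d, OOB error %.1f%%, %d features selected",
             mtry, urf.oob_error, len(selected))

    # ---- stage 7: statistics --------------------------------------------
    sector_means = (feature_table.groupby("sector_id")[features.FEATURE_NAMES]
                    .mean())
    herit = quantstats.heritability_table(sector_means[selected], design)

    geno_group = design.drop_duplicates("genotype_id").set_index("genotype_id")["group"]
    sector_geno = design.set_index("sector_id")["genotype_id"]
    # daily max TR / max VPD per sector for the preliminary analyses
    day_index = tr.index.normalize()
    max_tr = tr.groupby(day_index).max()
    max_vpd = w["vpd"].groupby(w.index.normalize()).max().reindex(max_tr.index)
    long = max_tr.stack().rename("max_tr").reset_index()
    long.columns = ["date", "sector_id", "max_tr"]
    long["genotype_id"] = long["sector_id"].map(sector_geno)
    long["group"] = long["genotype_id"].map(geno_group)
    long["max_vpd"] = long["date"].map(max_vpd)
    long = long.dropna(subset=["max_tr"])
    maxtr_reg = quantstats.max_tr_regression(long["max_tr"], long["max_vpd"],
                                             long["group"])
    anova_group = quantstats.two_way_anova(long["max_tr"], long["group"],
                                           long["date"].astype(str))
    tukey_counts = {}
    for feat in selected:
        y = sector_means[feat]
        tg = quantstats.tukey_groups(y.to_numpy(),
                                     sector_geno.reindex(y.index).to_numpy())
        tukey_counts[feat] = tg.n_groups

    # ---- stage 8: sensitivity -------------------------------------------
    cluster_tr = pd.DataFrame({
        f"C{c}": tr[[s for s in sectors
                     if labels.get(sector_geno[s], None) == c]].mean(axis=1)
        for c in sorted(labels.unique())
    })
    X, Y = sensitivity.build_training_set(w.loc[cluster_tr.index], cluster_tr)
    bp, nn = sensitivity.median_breakpoint_table(
        X, Y, vpd_max, n_models=cfg.nn_models, splits=cfg.quantile_splits,
        eps=cfg.slope_epsilon, seed=int(rng.integers(2 ** 31 - 1)),
        hidden=cfg.nn_hidden, max_epochs=cfg.nn_max_epochs,
        n_restarts=cfg.nn_restarts)
    log.info("NN best epoch %d, validation R %s", nn.best_epoch,
             np.round(nn.r_validation, 3))

    summary = {
        "seed": cfg.seed,
        "n_sectors": len(sectors),
        "n_genotypes": int(len(genotype_means)),
        "removal_percent": removal_percent,
        "k": int(k),
        "dunn_scores": {int(kk): float(vv) for kk, vv in dunn_scores.items()},
        "mtry": int(mtry),
        "oob_error_percent": float(urf.oob_error),
        "selected_features": list(selected),
        "vpd_max_kpa": vpd_max,
        "nn_best_epoch": int(nn.best_epoch),
        "nn_validation_r": [float(r) for r in nn.r_validation],
        "heritability": {f: float(h) for f, h in herit["H2"].items()},
        "tukey_group_counts": tukey_counts,
        "breakpoints": bp.to_dict(orient="records"),
    }

    result = RunResult(
        config=cfg, weather=w, etr_smooth=etr_smooth, tr=tr,
        feature_table=feature_table, genotype_means=genotype_means, k=k,
        dunn_scores=dunn_scores, mtry=mtry, oob_error=urf.oob_error,
        labels=labels, selected_features=selected, importance=imp,
        heritability=herit, anova_group=anova_group,
        maxtr_regression=maxtr_reg, tukey_counts=tukey_counts, nn_model=nn,
        breakpoints=bp, removal_percent=removal_percent, summary=summary,
    )

    if out is not None:
        etr_smooth.to_csv(out / "etr_smoothed.csv")
        tr.to_csv(out / "tr.csv")
        feature_table.to_csv(out / "features.csv", index=False)
        genotype_means.to_csv(out / "genotype_means.csv")
        labels.to_frame().to_csv(out / "clusters.csv")
        imp.to_csv(out / "importance.csv")
        herit.to_csv(out / "heritability.csv")
        anova_group.to_csv(out / "anova_group.csv")
        maxtr_reg.to_csv(out / "maxtr_regression.csv", index=False)
        bp.to_csv(out / "breakpoints.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        with open(out / "config.json", "w") as fh:
            json.dump(cfg.to_dict(), fh, indent=2)
        for h in list(log.handlers):
            if isinstance(h, logging.FileHandler):
                h.close()
                log.removeHandler(h)
    return result
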