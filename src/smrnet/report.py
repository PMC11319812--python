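"""Pipeline orchestration and summary artifacts.

``run_pipeline`` chains the stages — synthetic data (optional), SMR
computation, imputation, per-year model fits (linear, random forest,
random forest + Boruta), the network-augmented robustness fit, and Shapley
attribution — and writes the metric tables, the feature-importance
heat-map data, the per-year networks and the min-max-normalized combined
map layer to a run directory, together with a manifest recording seeds and
output hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import models, network, preprocess, smr, synth

log = logging.getLogger("smrnet")


@dataclass
class PipelineConfig:
    """Configuration for a full run; defaults are desk-scale."""

    synthetic: synth.SyntheticConfig = field(default_factory=synth.SyntheticConfig)
    years: tuple[int, ...] | None = None   # None = all panel years
    k: int = 5
    repeats: int = 10
    boruta_runs: int = 30
    boruta_alpha: float = 0.05
    boruta_trees: int = 100
    rf_trees: int = 600
    collect_shap: bool = True
    shap_background: int = 50
    network_grid: int | None = 101          # None = exhaustive distinct values
    map_indicators: tuple[str, ...] = ("o3", "no2")
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        synth_cfg = synth.SyntheticConfig(**raw.pop("synthetic", {}))
        for key in ("years", "map_indicators"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(synthetic=synth_cfg, **raw)


def normalized_average_map(layers: dict[str, np.ndarray]) -> np.ndarray:
    """Min-max normalize each province-value layer to [0, 1], then average.

    A constant layer carries no spatial contrast; it maps to all-zeros with
    a warning.
    """
    if not layers:
        raise ValueError("need at least one layer")
    arrays = {name: np.asarray(vec, dtype=float) for name, vec in layers.items()}
    lengths = {len(v) for v in arrays.values()}
    if len(lengths) > 1:
        raise ValueError(f"layers are misaligned: lengths {sorted(lengths)}")
    n = lengths.pop()
    mats = []
    for name, vec in arrays.items():
        span = vec.max() - vec.min()
        if span == 0:
            warnings.warn(f"layer {name!r} is constant; normalized to zeros")
            mats.append(np.zeros(n))
        else:
            mats.append((vec - vec.min()) / span)
    return np.mean(mats, axis=0)


def importance_table(
    evaluations: dict[int, models.CVEvaluation], selection_threshold: float = 0.5
) -> pd.DataFrame:
    """Feature x year mean MDI importance; unselected features are absent (NaN)."""
    cols = {}
    for year, ev in sorted(evaluations.items()):
        imp = np.asarray(ev.importance_mean, dtype=float)
        vals = np.where(ev.selected_mask(selection_threshold), imp, np.nan)
        cols[year] = pd.Series(vals, index=ev.feature_names)
    return pd.DataFrame(cols)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> Path:
    """Execute the full per-year analysis; returns the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    def stage(name):
        log.info("stage %-12s %6.1fs", name, time.time() - t0)

    try:
        cfg = config.synthetic
        panel_full = synth.generate_panel(cfg)
        mortality = synth.generate_mortality(cfg, panel_full)
        panel = synth.inject_missing(panel_full, cfg.missing_rate, cfg.seed)
        panel.to_csv(out / "panel.csv", out / "panel_categories.csv")
        mortality.to_csv(out / "mortality.csv", out / "reference.csv")
        stage("synth")

        smr_table = smr.compute_smr_table(mortality)
        smr_table.to_csv(out / "smr.csv", index=False)
        stage("smr")

        panel = preprocess.impute_mean(panel)
        stage("preprocess")
    except Exception as exc:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline failed before modelling: {exc}") from exc

    years = config.years or tuple(int(y) for y in panel.years)
    rf_cfg = models.RFConfig(n_trees=config.rf_trees)
    boruta_params = {
        "max_runs": config.boruta_runs,
        "alpha": config.boruta_alpha,
        "rf_params": {"n_trees": config.boruta_trees},
    }
    metrics: dict[str, dict] = {}
    rfb_evals: dict[int, models.CVEvaluation] = {}
    for year in years:
        try:
            X, y, names = preprocess.assemble(panel, smr_table, year)
            per_year = {}
            ev_lm = models.repeated_cv(
                X, y, "lm", feature_names=names, k=config.k, repeats=config.repeats,
                seed=config.seed,
            )
            ev_rf = models.repeated_cv(
                X, y, "rf", feature_names=names, k=config.k, repeats=config.repeats,
                seed=config.seed, rf_config=rf_cfg,
            )
            ev_rfb = models.repeated_cv(
                X, y, "rf", feature_names=names, k=config.k, repeats=config.repeats,
                seed=config.seed, rf_config=rf_cfg, use_boruta=True,
                boruta_params=boruta_params, collect_shap=config.collect_shap,
                shap_background=config.shap_background,
            )
            for label, ev in (("lm", ev_lm), ("rf", ev_rf), ("rf_boruta", ev_rfb)):
                per_year[label] = {
                    "mae_mean": ev.mae_mean,
                    "mae_sd": ev.mae_sd,
                    "pearson_r": ev.pearson_r,
                    "pearson_p": ev.pearson_p,
                }

            # network robustness variant: 4 centrality features appended
            Xy_df = panel.year_matrix(year)
            D = network.spearman_abs_matrix(Xy_df.to_numpy())
            grid = (
                None
                if config.network_grid is None
                else np.linspace(0.0, 1.0, config.network_grid)
            )
            net = network.threshold_scan(D, grid, node_ids=panel.province_ids)
            feats = network.centrality_features(net)
            X_aug_df = network.augment_panel(Xy_df, feats)
            ev_aug = models.repeated_cv(
                X_aug_df.to_numpy(), y, "rf", feature_names=list(X_aug_df.columns),
                k=config.k, repeats=config.repeats, seed=config.seed, rf_config=rf_cfg,
            )
            per_year["rf_network"] = {
                "mae_mean": ev_aug.mae_mean,
                "mae_sd": ev_aug.mae_sd,
                "pearson_r": ev_aug.pearson_r,
                "pearson_p": ev_aug.pearson_p,
                "threshold": net.threshold,
            }
            network.export_network(
                net, out / f"network_{year}_edges.tsv", out / f"network_{year}_entropy.csv"
            )
            feats.to_csv(out / f"network_{year}_centrality.csv")

            if config.collect_shap and ev_rfb.shap_values is not None:
                pd.DataFrame(
                    ev_rfb.shap_values, index=panel.province_ids, columns=names
                ).to_csv(out / f"shap_{year}.csv")

            metrics[str(year)] = per_year
            rfb_evals[year] = ev_rfb
            stage(f"year {year}")
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"pipeline failed in stage 'year {year}': {exc}") from exc

    importance_table(rfb_evals).to_csv(out / "importance.csv")

    # combined map layer: mean SMR plus the configured pollutant indicators
    layers = {
        "smr": smr_table.groupby("province_id", sort=False)["smr"].mean()
        .loc[panel.province_ids].to_numpy()
    }
    for name in config.map_indicators:
        if name in panel.indicator_names:
            j = panel.indicator_names.index(name)
            layers[name] = panel.values[:, j, :].mean(axis=1)
    map_vals = normalized_average_map(layers)
    pd.DataFrame({"province_id": panel.province_ids, "combined": map_vals}).to_csv(
        out / "map_values.csv", index=False
    )

    (out / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
    manifest = {
        "seed": config.seed,
        "synthetic_seed": config.synthetic.seed,
        "repeats": config.repeats,
        "k": config.k,
        "files": {
            p.name: _sha256(p) for p in sorted(out.iterdir()) if p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    stage("done")
    return out
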