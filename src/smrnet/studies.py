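"""Pre-registered synthetic study designs and their summary quantities.

Each function defines one simulation study — its generator configuration IS
the study condition — runs it end to end through the package, and returns
the measured quantities.  The analysis drivers, the test suite and the
acceptance script all call these functions so that every reported number is
recomputed from scratch.

Problem sizes (seeds, CV repeats, forest sizes) are desk-scale: repeats are
10 instead of the full 100 of the modelling protocol, recovery studies use
20 seeds, and the Shapley recovery study uses 200-tree forests with a
30-row background.  docs/methods.md discusses these choices.
"""

from __future__ import annotations

import numpy as np

from . import boruta as boruta_mod
from . import models, network, preprocess, smr, synth

#: the five "pollutant" indicators planted in the selection study
SELECTION_STUDY_PLANTED = ("o3", "no2", "pm10", "pm2_5", "so2")


def smr_null_calibration(seed: int = 0) -> dict:
    """SMR distribution under a zero-effect, zero-noise configuration.

    With no planted effects the observed counts are Poisson at exactly the
    expected counts, so the SMR should concentrate at 1.
    """
    cfg = synth.SyntheticConfig(
        effect_spec={}, negative_effect_spec={}, noise_sd=0.0, missing_rate=0.0,
        seed=seed,
    )
    panel = synth.generate_panel(cfg)
    table = smr.compute_smr_table(synth.generate_mortality(cfg, panel))
    mean = float(table["smr"].mean())
    se = float(table["smr"].std(ddof=1) / np.sqrt(len(table)))
    return {"mean_smr": mean, "se": se, "n": len(table)}


def _selection_config(seed: int) -> synth.SyntheticConfig:
    """Boruta operating-characteristics design.

    Five indicators carry equal-strength exceedance (threshold) effects on
    log-SMR; the remaining 26 are pure noise, mutually independent so a
    confirmation of any of them is a genuine false positive (with correlated
    indicators, proxies of a planted feature are "all-relevant" and their
    confirmation would not be an error).
    """
    return synth.SyntheticConfig(
        effect_spec={name: (0.8, "threshold") for name in SELECTION_STUDY_PLANTED},
        negative_effect_spec={},
        indicator_correlation=0.0,
        noise_sd=0.1,
        missing_rate=0.0,
        seed=seed,
    )


def boruta_operating_characteristics(
    n_seeds: int = 20,
    base_seed: int = 0,
    max_runs: int = 50,
    n_trees: int = 500,
    year: int = 2015,
) -> dict:
    """Confirmation power and per-noise-feature false-confirmation rate."""
    planted = set(SELECTION_STUDY_PLANTED)
    n_confirmed = 0
    n_false = 0
    n_noise_total = 0
    per_seed = []
    for i in range(n_seeds):
        cfg = _selection_config(base_seed + i)
        panel = synth.generate_panel(cfg)
        table = smr.compute_smr_table(synth.generate_mortality(cfg, panel))
        X, y, names = preprocess.assemble(panel, table, year)
        decision = boruta_mod.boruta_run(
            X, y, feature_names=names, max_runs=max_runs,
            rf_params={"n_trees": n_trees},
            rng=np.random.default_rng(base_seed + i),
        )
        confirmed = set(decision.confirmed)
        n_confirmed += len(confirmed & planted)
        n_false += len(confirmed - planted)
        n_noise_total += len(names) - len(planted)
        per_seed.append(len(confirmed & planted))
    return {
        "planted_confirmation_rate": n_confirmed / (n_seeds * len(planted)),
        "false_confirmation_rate": n_false / n_noise_total,
        "per_seed_confirmed": per_seed,
        "n_seeds": n_seeds,
        "max_runs": max_runs,
    }


def _nonlinear_config(seed: int) -> synth.SyntheticConfig:
    """Model-comparison design: both pollutant drivers are threshold effects,
    so the response is genuinely nonlinear in the indicators."""
    return synth.SyntheticConfig(
        effect_spec={"o3": (0.8, "threshold"), "no2": (0.8, "threshold")},
        negative_effect_spec={"circulatory_mortality": (-0.25, "linear")},
        seed=seed,
    )


def model_comparison(
    seed: int = 0,
    repeats: int = 10,
    year: int = 2015,
    boruta_runs: int = 25,
    boruta_trees: int = 200,
) -> dict:
    """Mean MAE of LM, RF and RF+Boruta under repeated 5-fold CV."""
    cfg = _nonlinear_config(seed)
    panel = synth.generate_panel(cfg)
    table = smr.compute_smr_table(synth.generate_mortality(cfg, panel))
    panel = preprocess.impute_mean(
        synth.inject_missing(panel, cfg.missing_rate, cfg.seed)
    )
    X, y, names = preprocess.assemble(panel, table, year)
    common = dict(feature_names=names, k=5, repeats=repeats, seed=seed)
    ev_lm = models.repeated_cv(X, y, "lm", **common)
    ev_rf = models.repeated_cv(X, y, "rf", **common)
    ev_rfb = models.repeated_cv(
        X, y, "rf", use_boruta=True,
        boruta_params={"max_runs": boruta_runs, "rf_params": {"n_trees": boruta_trees}},
        **common,
    )
    return {
        "mae_lm": ev_lm.mae_mean,
        "mae_rf": ev_rf.mae_mean,
        "mae_rf_boruta": ev_rfb.mae_mean,
        "sd_lm": ev_lm.mae_sd,
        "sd_rf": ev_rf.mae_sd,
        "sd_rf_boruta": ev_rfb.mae_sd,
        "pearson_r_rf": ev_rf.pearson_r,
        "pearson_p_rf": ev_rf.pearson_p,
        "repeats": repeats,
    }


def driver_recovery(
    n_seeds: int = 20,
    base_seed: int = 0,
    year: int = 2015,
    repeats: int = 1,
    n_trees: int = 200,
    shap_background: int = 30,
) -> dict:
    """Recovery of the planted drivers by global (MDI) and local (SHAP) importance.

    Uses the default generator configuration: o3 and no2 planted positive
    with equal strength, circulatory mortality planted negative.  Measures
    how often both drivers rank in the top 3 by each importance measure, and
    how often the comorbidity's SHAP-value relationship has a negative sign.
    """
    ok_mdi = ok_shap = ok_sign = 0
    for i in range(n_seeds):
        cfg = synth.SyntheticConfig(seed=base_seed + i)
        panel = synth.generate_panel(cfg)
        table = smr.compute_smr_table(synth.generate_mortality(cfg, panel))
        panel = preprocess.impute_mean(
            synth.inject_missing(panel, cfg.missing_rate, cfg.seed)
        )
        X, y, names = preprocess.assemble(panel, table, year)
        ev = models.repeated_cv(
            X, y, "rf", feature_names=names, repeats=repeats, seed=base_seed + i,
            rf_config=models.RFConfig(n_trees=n_trees),
            collect_shap=True, shap_background=shap_background,
        )
        drivers = set(cfg.effect_spec)
        mdi_top3 = {names[j] for j in np.argsort(-ev.importance_mean)[:3]}
        shap_top3 = {
            names[j] for j in np.argsort(-np.abs(ev.shap_values).mean(axis=0))[:3]
        }
        ok_mdi += drivers <= mdi_top3
        ok_shap += drivers <= shap_top3
        jc = names.index("circulatory_mortality")
        ok_sign += np.corrcoef(X[:, jc], ev.shap_values[:, jc])[0, 1] < 0
    return {
        "mdi_recovery_rate": ok_mdi / n_seeds,
        "shap_recovery_rate": ok_shap / n_seeds,
        "comorbidity_negative_sign_rate": ok_sign / n_seeds,
        "n_seeds": n_seeds,
    }


def network_robustness(
    seed: int = 0,
    repeats: int = 10,
    year: int = 2015,
    grid_size: int = 101,
) -> dict:
    """MAE shift from appending the 4 centrality features to the panel."""
    cfg = synth.SyntheticConfig(seed=seed)
    panel = synth.generate_panel(cfg)
    table = smr.compute_smr_table(synth.generate_mortality(cfg, panel))
    panel = preprocess.impute_mean(
        synth.inject_missing(panel, cfg.missing_rate, cfg.seed)
    )
    X, y, names = preprocess.assemble(panel, table, year)
    M = panel.year_matrix(year)
    D = network.spearman_abs_matrix(M.to_numpy())
    net = network.threshold_scan(
        D, np.linspace(0.0, 1.0, grid_size), node_ids=panel.province_ids
    )
    feats = network.centrality_features(net)
    X_aug = network.augment_panel(M, feats)
    ev_orig = models.repeated_cv(X, y, "rf", feature_names=names, repeats=repeats, seed=seed)
    ev_aug = models.repeated_cv(
        X_aug.to_numpy(), y, "rf", feature_names=list(X_aug.columns),
        repeats=repeats, seed=seed,
    )
    return {
        "mae_original": ev_orig.mae_mean,
        "mae_augmented": ev_aug.mae_mean,
        "mae_shift": abs(ev_aug.mae_mean - ev_orig.mae_mean),
        "mae_sd": ev_orig.mae_sd,
        "threshold": net.threshold,
        "repeats": repeats,
    }
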