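"""Synthetic panel and mortality generator: structure, determinism, planted effects."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from smrnet import preprocess, smr, synth


def _mean_abs_offdiag_corr(mat):
    c = np.corrcoef(mat.T)
    off = c[~np.eye(len(c), dtype=bool)]
    return np.abs(off).mean()


class TestGeneratePanel:
    def test_shape_and_labels(self, default_config):
        panel = synth.generate_panel(default_config)
        assert panel.values.shape == (107, 31, 5)
        assert not np.isnan(panel.values).any()
        assert set(panel.categories) == set(synth.CATEGORY_VOCABULARY)

    def test_independent_indicators_near_zero_correlation(self):
        cfg = synth.SyntheticConfig(
            indicator_correlation=0.0, effect_spec={}, negative_effect_spec={}, seed=3
        )
        panel = synth.generate_panel(cfg)
        # mean |r| of independent gaussians at n=107 is ~ sqrt(2/pi)/sqrt(n) ~ 0.077
        assert _mean_abs_offdiag_corr(panel.values[:, :, 0]) < 0.12

    def test_determinism(self, default_config):
        p1 = synth.generate_panel(default_config)
        p2 = synth.generate_panel(default_config)
        np.testing.assert_array_equal(p1.values, p2.values)

    def test_latent_factor_groups_correlate(self):
        cfg = synth.SyntheticConfig(
            indicator_correlation=0.8,
            n_latent_factors=2,
            effect_spec={},
            negative_effect_spec={},
            seed=5,
        )
        panel = synth.generate_panel(cfg)
        mat = panel.values[:, :, 0]
        group = np.arange(cfg.n_indicators) % 2
        c = np.abs(np.corrcoef(mat.T))
        same = c[np.equal.outer(group, group) & ~np.eye(31, dtype=bool)].mean()
        diff = c[~np.equal.outer(group, group)].mean()
        assert same > diff

    def test_stationary_across_years(self, default_config):
        panel = synth.generate_panel(default_config)
        # year-to-year correlation of the same indicator should be high
        r = np.corrcoef(panel.values[:, 0, 0], panel.values[:, 0, 4])[0, 1]
        assert r > 0.9


class TestGenerateMortality:
    def test_null_model_smr_concentrates_at_one(self):
        cfg = synth.SyntheticConfig(
            effect_spec={}, negative_effect_spec={}, noise_sd=0.0, seed=2
        )
        panel = synth.generate_panel(cfg)
        mort = synth.generate_mortality(cfg, panel)
        table = smr.compute_smr_table(mort)
        mean_smr = table["smr"].mean()
        se = table["smr"].std() / np.sqrt(len(table))
        assert abs(mean_smr - 1.0) < 3 * se

    def test_reference_rates_increase_with_age(self, default_config):
        panel = synth.generate_panel(default_config)
        mort = synth.generate_mortality(default_config, panel)
        rates = mort.ref_deaths / mort.ref_population
        assert np.all(np.diff(rates) >= 0)
        assert np.all(mort.ref_deaths <= mort.ref_population)

    def test_planted_positive_effect_detectable(self):
        cfg = synth.SyntheticConfig(
            effect_spec={"o3": (0.5, "linear")},
            negative_effect_spec={},
            indicator_correlation=0.0,
            noise_sd=0.1,
            missing_rate=0.0,
            seed=4,
        )
        panel = synth.generate_panel(cfg)
        mort = synth.generate_mortality(cfg, panel)
        X, y, names = preprocess.assemble(panel, smr.compute_smr_table(mort), 2015)
        res = spearmanr(X[:, names.index("o3")], y)
        assert res.statistic > 0
        assert res.pvalue < 0.01

    def test_comorbidity_effect_negative_sign(self, default_config):
        panel = synth.generate_panel(default_config)
        mort = synth.generate_mortality(default_config, panel)
        table = smr.compute_smr_table(mort)
        panel2 = preprocess.impute_mean(
            synth.inject_missing(panel, default_config.missing_rate, default_config.seed)
        )
        X, y, names = preprocess.assemble(panel2, table, 2015)
        rho = spearmanr(X[:, names.index("circulatory_mortality")], y).statistic
        assert rho < 0

    def test_missing_planted_indicator_is_error(self, small_config):
        panel = synth.generate_panel(small_config)
        cfg = synth.SyntheticConfig(
            n_indicators=31, effect_spec={"landfill_density": (0.2, "linear")}, seed=0
        )
        with pytest.raises(KeyError):
            synth.generate_mortality(cfg, panel)  # small panel lacks that indicator

    def test_effect_monotonicity_in_coefficient(self):
        """Doubling a planted coefficient does not weaken its SMR association."""
        rhos = {}
        for coef in (0.2, 0.4):
            vals = []
            for seed in range(20):
                cfg = synth.SyntheticConfig(
                    effect_spec={"o3": (coef, "linear")},
                    negative_effect_spec={},
                    indicator_correlation=0.0,
                    noise_sd=0.1,
                    missing_rate=0.0,
                    seed=seed,
                )
                panel = synth.generate_panel(cfg)
                mort = synth.generate_mortality(cfg, panel)
                X, y, names = preprocess.assemble(panel, smr.compute_smr_table(mort), 2015)
                vals.append(abs(spearmanr(X[:, names.index("o3")], y).statistic))
            rhos[coef] = np.mean(vals)
        assert rhos[0.4] >= rhos[0.2]


class TestInjectMissing:
    def test_rate_zero_identity(self, small_dataset):
        panel, _ = small_dataset
        out = synth.inject_missing(panel, 0.0, seed=1)
        np.testing.assert_array_equal(out.values, panel.values)

    def test_masked_fraction_within_binomial_bound(self, default_config):
        panel = synth.generate_panel(default_config)
        out = synth.inject_missing(panel, 0.1, seed=9)
        n_cells = panel.values.size
        frac = np.isnan(out.values).mean()
        bound = 3 * np.sqrt(0.1 * 0.9 / n_cells)
        assert abs(frac - 0.1) < bound

    def test_same_seed_same_mask(self, default_config):
        panel = synth.generate_panel(default_config)
        m1 = np.isnan(synth.inject_missing(panel, 0.2, seed=5).values)
        m2 = np.isnan(synth.inject_missing(panel, 0.2, seed=5).values)
        np.testing.assert_array_equal(m1, m2)

    def test_invalid_rate(self, small_dataset):
        panel, _ = small_dataset
        with pytest.raises(ValueError):
            synth.inject_missing(panel, 1.0, seed=0)


class TestConfigValidation:
    def test_unknown_effect_key(self):
        with pytest.raises(ValueError):
            synth.SyntheticConfig(effect_spec={"nope": (0.1, "linear")})

    def test_unknown_form(self):
        with pytest.raises(ValueError):
            synth.SyntheticConfig(effect_spec={"o3": (0.1, "cubic")})

    def test_positive_negative_effect_rejected(self):
        with pytest.raises(ValueError):
            synth.SyntheticConfig(negative_effect_spec={"o3": (0.1, "linear")})

    def test_counts(self):
        with pytest.raises(ValueError):
            synth.SyntheticConfig(n_provinces=1)
        with pytest.raises(ValueError):
            synth.SyntheticConfig(missing_rate=0.7)


def test_panel_csv_round_trip(tmp_path, small_dataset):
    panel, _ = small_dataset
    panel.to_csv(tmp_path / "p.csv", tmp_path / "c.csv")
    back = synth.IndicatorPanel.from_csv(tmp_path / "p.csv", tmp_path / "c.csv")
    np.testing.assert_allclose(back.values, panel.values)
    assert back.indicator_names == panel.indicator_names
    assert back.categories == panel.categories
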