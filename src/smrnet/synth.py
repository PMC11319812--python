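"""Synthetic provincial indicator panels and age-stratified mortality.

The generator emulates the structure of an Italian-province environmental /
socio-economic panel: ~107 provinces observed over 5 years on ~31 indicators
grouped in five categories, with a handful of "pollutant" indicators planted
to raise age-standardized Alzheimer's mortality and one comorbidity indicator
planted with a negative association.  Mortality is emitted in the
indirect-standardization form the SMR computation expects: per-province
age-class populations, per-province observed death counts, and a national
reference table of age-class deaths and populations.

Design choices
--------------
* Cross-indicator correlation comes from a small number of latent province
  factors; one knob (``indicator_correlation``) controls its strength.
* Indicator values are stationary across years up to i.i.d. noise: the data
  are meant for a purely spatial analysis.
* Observed deaths are Poisson with mean ``E_m * exp(eta)`` where ``eta`` is
  the planted linear predictor, so the true log-SMR equals ``eta`` in
  expectation and an empty predictor yields SMR concentrated at 1.
* Missingness is injected MCAR, as a separate operation with its own seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

CATEGORY_VOCABULARY = (
    "Air Pollution",
    "Soil Pollution",
    "Urban Environment",
    "Socio-economic",
    "Other Pathologies",
)

#: Default 31-indicator roster, grouped into the five categories above.
DEFAULT_INDICATORS: tuple[tuple[str, str], ...] = (
    ("o3", "Air Pollution"),
    ("no2", "Air Pollution"),
    ("pm10", "Air Pollution"),
    ("pm2_5", "Air Pollution"),
    ("so2", "Air Pollution"),
    ("co", "Air Pollution"),
    ("benzene", "Air Pollution"),
    ("air_quality_index", "Air Pollution"),
    ("pesticide_use", "Soil Pollution"),
    ("industrial_sites", "Soil Pollution"),
    ("contaminated_land", "Soil Pollution"),
    ("fertilizer_use", "Soil Pollution"),
    ("landfill_density", "Soil Pollution"),
    ("green_space", "Urban Environment"),
    ("urbanization", "Urban Environment"),
    ("traffic_density", "Urban Environment"),
    ("public_transport", "Urban Environment"),
    ("noise_pollution", "Urban Environment"),
    ("building_age", "Urban Environment"),
    ("income", "Socio-economic"),
    ("education", "Socio-economic"),
    ("unemployment", "Socio-economic"),
    ("life_quality_index", "Socio-economic"),
    ("population_density", "Socio-economic"),
    ("aging_index", "Socio-economic"),
    ("healthcare_spending", "Socio-economic"),
    ("circulatory_mortality", "Other Pathologies"),
    ("diabetes_mortality", "Other Pathologies"),
    ("ischemia_mortality", "Other Pathologies"),
    ("digestive_mortality", "Other Pathologies"),
    ("cerebrovascular_mortality", "Other Pathologies"),
)

_EFFECT_FORMS = ("linear", "threshold", "quadratic")


@dataclass
class IndicatorPanel:
    """Province x indicator x year value array with category labels.

    ``values`` has shape ``(n_provinces, n_indicators, n_years)``; missing
    cells are NaN.
    """

    province_ids: np.ndarray
    years: np.ndarray
    indicator_names: list[str]
    categories: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.province_ids = np.asarray(self.province_ids)
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        n_p, n_i, n_y = self.values.shape
        if n_p != len(self.province_ids) or n_i != len(self.indicator_names) or n_y != len(self.years):
            raise ValueError("panel dimensions inconsistent with labels")
        if len(set(self.province_ids)) != n_p:
            raise ValueError("province_ids must be unique")
        if len(self.categories) != n_i:
            raise ValueError("one category label per indicator required")
        bad = set(self.categories) - set(CATEGORY_VOCABULARY) - {"Network"}
        if bad:
            raise ValueError(f"unknown category labels: {sorted(bad)}")

    @property
    def n_provinces(self) -> int:
        return len(self.province_ids)

    def copy(self) -> "IndicatorPanel":
        return IndicatorPanel(
            self.province_ids.copy(),
            self.years.copy(),
            list(self.indicator_names),
            list(self.categories),
            self.values.copy(),
        )

    def year_matrix(self, year: int) -> pd.DataFrame:
        """Province x indicator matrix for one year, indexed by province_id."""
        yi = int(np.flatnonzero(self.years == year)[0])
        return pd.DataFrame(
            self.values[:, :, yi], index=self.province_ids, columns=self.indicator_names
        )

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for yi, year in enumerate(self.years):
            df = pd.DataFrame(self.values[:, :, yi], columns=self.indicator_names)
            df.insert(0, "province_id", self.province_ids)
            df.insert(1, "year", year)
            rows.append(df)
        return pd.concat(rows, ignore_index=True)

    def to_csv(self, path, categories_path=None) -> None:
        """Write the wide CSV and a companion indicator->category table."""
        self.to_dataframe().to_csv(path, index=False)
        if categories_path is not None:
            pd.DataFrame(
                {"indicator": self.indicator_names, "category": self.categories}
            ).to_csv(categories_path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, categories: Sequence[str] | dict | None = None) -> "IndicatorPanel":
        names = [c for c in df.columns if c not in ("province_id", "year")]
        years = np.sort(df["year"].unique())
        provinces = df.loc[df["year"] == years[0], "province_id"].to_numpy()
        values = np.full((len(provinces), len(names), len(years)), np.nan)
        order = {p: i for i, p in enumerate(provinces)}
        for yi, year in enumerate(years):
            sub = df[df["year"] == year]
            idx = [order[p] for p in sub["province_id"]]
            values[idx, :, yi] = sub[names].to_numpy(dtype=float)
        if categories is None:
            default = dict(DEFAULT_INDICATORS)
            cats = [default.get(n, "Socio-economic") for n in names]
        elif isinstance(categories, dict):
            cats = [categories[n] for n in names]
        else:
            cats = list(categories)
        return cls(provinces, years, names, cats, values)

    @classmethod
    def from_csv(cls, path, categories_path=None) -> "IndicatorPanel":
        cats = None
        if categories_path is not None:
            tab = pd.read_csv(categories_path)
            cats = dict(zip(tab["indicator"], tab["category"]))
        return cls.from_dataframe(pd.read_csv(path), cats)


@dataclass
class AgeStratifiedMortality:
    """Observed deaths and age-class populations plus the reference table.

    Populations are held constant across years (the analysis is spatial);
    observed deaths vary by year.
    """

    province_ids: np.ndarray
    years: np.ndarray
    age_classes: np.ndarray
    populations: np.ndarray        # (n_provinces, n_age_classes)
    observed_deaths: np.ndarray    # (n_provinces, n_years)
    ref_deaths: np.ndarray         # (n_age_classes,)
    ref_population: np.ndarray     # (n_age_classes,)

    def __post_init__(self) -> None:
        self.province_ids = np.asarray(self.province_ids)
        self.years = np.asarray(self.years, dtype=int)
        self.age_classes = np.asarray(self.age_classes, dtype=int)
        self.populations = np.asarray(self.populations)
        self.observed_deaths = np.asarray(self.observed_deaths)
        self.ref_deaths = np.asarray(self.ref_deaths)
        self.ref_population = np.asarray(self.ref_population)
        if np.any(self.ref_population <= 0):
            raise ValueError("reference population must be positive in every age class")
        if np.any(self.ref_deaths > self.ref_population):
            raise ValueError("reference deaths exceed reference population")
        if np.any(self.ref_deaths < 0) or np.any(self.observed_deaths < 0):
            raise ValueError("death counts must be nonnegative")

    def to_csv(self, mortality_path, reference_path) -> None:
        rows = []
        for yi, year in enumerate(self.years):
            for pi, prov in enumerate(self.province_ids):
                for ai, age in enumerate(self.age_classes):
                    rows.append(
                        (prov, year, age, int(self.populations[pi, ai]),
                         int(self.observed_deaths[pi, yi]))
                    )
        pd.DataFrame(
            rows, columns=["province_id", "year", "age_class", "population", "observed_deaths"]
        ).to_csv(mortality_path, index=False)
        pd.DataFrame(
            {
                "age_class": self.age_classes,
                "ref_deaths": self.ref_deaths.astype(int),
                "ref_population": self.ref_population.astype(int),
            }
        ).to_csv(reference_path, index=False)

    @classmethod
    def from_csv(cls, mortality_path, reference_path) -> "AgeStratifiedMortality":
        long = pd.read_csv(mortality_path)
        ref = pd.read_csv(reference_path).sort_values("age_class")
        years = np.sort(long["year"].unique())
        ages = np.sort(long["age_class"].unique())
        provinces = long.loc[long["year"] == years[0], "province_id"].unique()
        p_idx = {p: i for i, p in enumerate(provinces)}
        populations = np.zeros((len(provinces), len(ages)))
        observed = np.zeros((len(provinces), len(years)))
        first_year = long[long["year"] == years[0]]
        pop_wide = first_year.pivot(index="province_id", columns="age_class", values="population")
        populations = pop_wide.loc[provinces, ages].to_numpy()
        per_py = long.groupby(["province_id", "year"])["observed_deaths"].first()
        for (prov, year), o in per_py.items():
            observed[p_idx[prov], int(np.flatnonzero(years == year)[0])] = o
        return cls(
            provinces, years, ages, populations, observed,
            ref["ref_deaths"].to_numpy(), ref["ref_population"].to_numpy(),
        )


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic provincial dataset.

    ``effect_spec`` maps indicator names to ``(coefficient, form)`` acting on
    the log mortality-rate scale, with ``form`` one of ``linear``,
    ``threshold`` (indicator above its median) or ``quadratic``.
    ``negative_effect_spec`` holds the comorbidity-style effects and must have
    negative coefficients.
    """

    n_provinces: int = 107
    n_indicators: int = 31
    years: tuple[int, ...] = (2015, 2016, 2017, 2018, 2019)
    n_age_classes: int = 18
    # the two pollutant drivers are planted with equal strength on the log
    # scale: a centered threshold (exceedance) effect has sd coef/2, so its
    # coefficient is twice the linear one
    effect_spec: dict[str, tuple[float, str]] = field(
        default_factory=lambda: {"o3": (0.4, "linear"), "no2": (0.8, "threshold")}
    )
    negative_effect_spec: dict[str, tuple[float, str]] = field(
        default_factory=lambda: {"circulatory_mortality": (-0.25, "linear")}
    )
    indicator_correlation: float = 0.3
    n_latent_factors: int = 5
    noise_sd: float = 0.2
    missing_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_provinces < 2 or self.n_indicators < 2 or self.n_age_classes < 2:
            raise ValueError("all counts must be >= 2")
        if not 0.0 <= self.indicator_correlation < 1.0:
            raise ValueError("indicator_correlation must lie in [0, 1)")
        if not 0.0 <= self.missing_rate <= 0.5:
            raise ValueError("missing_rate must lie in [0, 0.5]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_latent_factors < 1:
            raise ValueError("need at least one latent factor")
        names = set(self.indicator_names)
        for spec_name, spec in (("effect_spec", self.effect_spec),
                                ("negative_effect_spec", self.negative_effect_spec)):
            for key, (coef, form) in spec.items():
                if key not in names:
                    raise ValueError(f"{spec_name} key {key!r} is not an indicator name")
                if form not in _EFFECT_FORMS:
                    raise ValueError(f"unknown effect form {form!r}")
        for key, (coef, _) in self.negative_effect_spec.items():
            if coef >= 0:
                raise ValueError(f"negative_effect_spec coefficient for {key!r} must be < 0")

    @property
    def indicator_names(self) -> list[str]:
        if self.n_indicators <= len(DEFAULT_INDICATORS):
            return [n for n, _ in DEFAULT_INDICATORS[: self.n_indicators]]
        extra = [f"indicator_{k:02d}" for k in range(self.n_indicators - len(DEFAULT_INDICATORS))]
        return [n for n, _ in DEFAULT_INDICATORS] + extra

    @property
    def indicator_categories(self) -> list[str]:
        base = dict(DEFAULT_INDICATORS)
        return [
            base.get(n, CATEGORY_VOCABULARY[i % len(CATEGORY_VOCABULARY)])
            for i, n in enumerate(self.indicator_names)
        ]


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    # One master seed, one deterministic child stream per operation.
    return np.random.default_rng(np.random.SeedSequence(entropy=(int(config.seed), stream)))


def _effect_value(z: np.ndarray, form: str) -> np.ndarray:
    """Centered functional form of a planted effect on standardized values."""
    if form == "linear":
        return z
    if form == "threshold":
        return (z > np.median(z)).astype(float) - 0.5
    if form == "quadratic":
        return z**2 - 1.0
    raise ValueError(f"unknown effect form {form!r}")


def generate_panel(config: SyntheticConfig) -> IndicatorPanel:
    """Draw the complete (no missing values) indicator panel.

    Each indicator loads on one of ``n_latent_factors`` latent province
    factors with weight ``sqrt(indicator_correlation)``; the rest of its
    variance is independent noise, so the expected within-group correlation
    is ``indicator_correlation`` and the between-group correlation is 0.
    Yearly values are the province base value plus i.i.d. noise of standard
    deviation ``noise_sd``.
    """
    rng = _rng(config, 1)
    n_p, n_i, n_y = config.n_provinces, config.n_indicators, len(config.years)
    rho = config.indicator_correlation
    factors = rng.standard_normal((n_p, config.n_latent_factors))
    loading_group = np.arange(n_i) % config.n_latent_factors
    base = np.sqrt(rho) * factors[:, loading_group] + np.sqrt(1.0 - rho) * rng.standard_normal((n_p, n_i))
    values = base[:, :, None] + config.noise_sd * rng.standard_normal((n_p, n_i, n_y))
    provinces = np.array([f"P{k:03d}" for k in range(n_p)])
    return IndicatorPanel(
        provinces,
        np.asarray(config.years, dtype=int),
        config.indicator_names,
        config.indicator_categories,
        values,
    )


def _reference_rates(config: SyntheticConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Reference age-class rates, deaths, and populations.

    Rates are log-linear in age-class index (slope 0.5 per class), calibrated
    so the crude reference rate is 4e-4 — roughly the Italian crude
    Alzheimer's mortality rate, which puts provincial expected deaths in the
    tens-to-hundreds range.
    """
    n_age = config.n_age_classes
    idx = np.arange(n_age)
    pop_weights = np.linspace(1.0, 0.35, n_age)            # older classes smaller
    ref_population = np.round(3.5e6 * pop_weights)
    raw = np.exp(0.5 * idx)
    crude_target = 4e-4
    scale = crude_target * ref_population.sum() / (raw * ref_population).sum()
    rates = scale * raw
    ref_deaths = np.round(rates * ref_population)
    return ref_deaths / ref_population, ref_deaths, ref_population


def planted_predictor(config: SyntheticConfig, panel: IndicatorPanel) -> np.ndarray:
    """Deterministic part of the planted log-SMR, shape (n_provinces, n_years)."""
    eta = np.zeros((panel.n_provinces, len(panel.years)))
    spec = {**config.effect_spec, **config.negative_effect_spec}
    for name, (coef, form) in spec.items():
        if name not in panel.indicator_names:
            raise KeyError(f"planted indicator {name!r} missing from panel")
        j = panel.indicator_names.index(name)
        for yi in range(len(panel.years)):
            eta[:, yi] += coef * _effect_value(panel.values[:, j, yi], form)
    return eta


def generate_mortality(config: SyntheticConfig, panel: IndicatorPanel) -> AgeStratifiedMortality:
    """Draw age-stratified mortality with the planted indicator effects.

    Observed deaths for province m in year y are
    ``Poisson(E_m * exp(eta_my + noise))`` where ``E_m`` is the
    indirect-standardization expected count under the reference rates, so the
    true log-SMR equals the planted predictor in expectation.
    """
    rng = _rng(config, 2)
    rates, ref_deaths, ref_population = _reference_rates(config)
    n_p, n_y = panel.n_provinces, len(panel.years)
    n_age = config.n_age_classes

    total_pop = rng.lognormal(mean=np.log(4.0e5), sigma=0.6, size=n_p)
    age_shape = np.linspace(1.0, 0.35, n_age)
    shares = age_shape * rng.uniform(0.85, 1.15, size=(n_p, n_age))
    shares /= shares.sum(axis=1, keepdims=True)
    populations = np.maximum(1, np.round(total_pop[:, None] * shares))

    expected = populations @ rates                       # (n_p,)
    eta = planted_predictor(config, panel)
    eta = eta + config.noise_sd * rng.standard_normal((n_p, n_y))
    observed = rng.poisson(expected[:, None] * np.exp(eta))
    return AgeStratifiedMortality(
        panel.province_ids.copy(),
        panel.years.copy(),
        np.arange(n_age),
        populations,
        observed,
        ref_deaths,
        ref_population,
    )


def inject_missing(panel: IndicatorPanel, rate: float, seed: int) -> IndicatorPanel:
    """Mask each cell independently with probability ``rate`` (MCAR).

    Raises if a whole indicator-year column would become missing, since the
    downstream mean imputation would then be undefined.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    out = panel.copy()
    if rate == 0.0:
        return out
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), 3)))
    mask = rng.random(out.values.shape) < rate
    emptied = mask.all(axis=0)
    if emptied.any():
        j, y = np.argwhere(emptied)[0]
        raise ValueError(
            f"masking would empty indicator {out.indicator_names[j]!r} in year {out.years[y]}"
        )
    out.values[mask] = np.nan
    return out
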