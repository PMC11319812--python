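"""Missing-value imputation and per-year design-matrix assembly.

Imputation follows the analysis convention of filling a missing cell with
the mean of the observed values of the same indicator in the same year,
computed over all provinces.  Because the fill uses all provinces it leaks
information across cross-validation folds; ``models.repeated_cv`` exposes an
``impute_within_folds`` switch for the stricter variant, but the default
reproduces the global-preprocessing behaviour.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synth import IndicatorPanel


def impute_mean(panel: IndicatorPanel) -> IndicatorPanel:
    """Fill missing cells with the same-indicator, same-year observed mean.

    Observed cells are untouched, so the operation is idempotent and does not
    shift column means.  Raises, naming the column, if an indicator-year is
    entirely missing.
    """
    out = panel.copy()
    vals = out.values
    for j, name in enumerate(out.indicator_names):
        for yi, year in enumerate(out.years):
            col = vals[:, j, yi]
            missing = np.isnan(col)
            if not missing.any():
                continue
            if missing.all():
                raise ValueError(f"indicator {name!r} has no observed values in year {year}")
            col[missing] = col[~missing].mean()
    return out


def assemble(
    panel: IndicatorPanel, smr_table: pd.DataFrame, year: int
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Feature matrix X, target vector y (SMR) and column names for one year.

    Rows are aligned on province_id in the panel's canonical order; provinces
    present in only one of the two inputs are an error.
    """
    if year not in panel.years:
        raise ValueError(f"year {year} not in panel")
    sub = smr_table[smr_table["year"] == year]
    panel_provinces = set(panel.province_ids)
    smr_provinces = set(sub["province_id"])
    only_panel = sorted(panel_provinces - smr_provinces)
    only_smr = sorted(smr_provinces - panel_provinces)
    if only_panel or only_smr:
        raise ValueError(
            f"provinces present in one input only: panel-only={only_panel}, smr-only={only_smr}"
        )
    X_df = panel.year_matrix(year)
    if np.isnan(X_df.to_numpy()).any():
        raise ValueError("panel must be imputed before assembly")
    y = sub.set_index("province_id").loc[panel.province_ids, "smr"].to_numpy(dtype=float)
    if np.any(y <= 0):
        # SMR of exactly 0 (no observed deaths) would break the log-scale
        # interpretation downstream; flag rather than silently model it.
        raise ValueError("non-positive SMR values encountered")
    return X_df.to_numpy(dtype=float), y, list(X_df.columns)
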