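"""Standardized Mortality Ratio by indirect standardization.

For province m, SMR = O_m / E_m where O_m is the observed death count and
E_m = sum_i R_i * n_i is the count expected if the reference population's
age-specific rates R_i = M_i / N_i applied to the province's age structure
n_i.  SMR > 1 means mortality in excess of the reference.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .synth import AgeStratifiedMortality


def age_specific_rates(M: np.ndarray, N: np.ndarray) -> np.ndarray:
    """Reference age-specific death rates R_i = M_i / N_i."""
    M = np.asarray(M, dtype=float)
    N = np.asarray(N, dtype=float)
    if M.shape != N.shape:
        raise ValueError("deaths and population vectors must have equal length")
    if np.any(N <= 0):
        raise ValueError("reference population must be positive in every age class")
    if np.any(M < 0):
        raise ValueError("death counts must be nonnegative")
    if np.any(M > N):
        raise ValueError("deaths exceed population in some age class")
    return M / N


def expected_deaths(R: np.ndarray, n: np.ndarray) -> float:
    """Expected deaths E_m = sum_i R_i * n_i under reference rates R."""
    R = np.asarray(R, dtype=float)
    n = np.asarray(n, dtype=float)
    if R.shape != n.shape:
        raise ValueError("rate and population vectors must have equal length")
    if np.any((R < 0) | (R > 1)):
        raise ValueError("rates must lie in [0, 1]")
    if np.any(n < 0):
        raise ValueError("populations must be nonnegative")
    return float(R @ n)


def smr(o_m: float, e_m: float) -> float:
    """Standardized mortality ratio O_m / E_m.

    E_m = 0 is a hard error (it indicates an empty province, not an SMR of
    infinity).
    """
    if e_m <= 0:
        raise ValueError("expected deaths must be positive")
    if o_m < 0:
        raise ValueError("observed deaths must be nonnegative")
    return float(o_m) / float(e_m)


def compute_smr_table(mortality: AgeStratifiedMortality) -> pd.DataFrame:
    """Per province-year SMR table with columns province_id, year, o_m, e_m, smr.

    Each year is standardized independently; there is no temporal smoothing.
    """
    R = age_specific_rates(mortality.ref_deaths, mortality.ref_population)
    rows = []
    for pi, prov in enumerate(mortality.province_ids):
        e_m = expected_deaths(R, mortality.populations[pi])
        for yi, year in enumerate(mortality.years):
            o_m = float(mortality.observed_deaths[pi, yi])
            rows.append((prov, int(year), o_m, e_m, smr(o_m, e_m)))
    return pd.DataFrame(rows, columns=["province_id", "year", "o_m", "e_m", "smr"])
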