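"""Derived phenotypes and environmental adjustment.

Dry matter content is computed from above/under-water tuber weights with the
empirical buoyancy formula DM% = 214 * (Wa / (Wa - Ww) - 0.988).  Chip-score
panels recorded on a 1-6 light-to-dark scale are converted to the 1-9
dark-to-light scale with a negative linear map.  Records from multiple years
and locations are adjusted by fitting

    y = mu + genotype (random) + year (fixed) + location (fixed) + e

by REML, subtracting the estimated year and location effects from every
record, and averaging the corrected records per genotype.  All populations
can (and should) be adjusted jointly in one fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._mixed import profile_reml

__all__ = [
    "AdjustedPhenotypes",
    "dry_matter_percent",
    "convert_chip_score_uk",
    "adjust_environment",
]

DM_COEFFICIENT = 214.0
DM_OFFSET = 0.988


def dry_matter_percent(weight_air, weight_water):
    """Tuber dry-matter percentage from above/under-water weights.

    DM% = 214 * (Wa / (Wa - Ww) - 0.988).  Requires Wa > Ww >= 0 (a tuber
    weighs less under water; equality would mean neutral buoyancy).
    Accepts scalars or arrays.
    """
    wa = np.asarray(weight_air, dtype=float)
    ww = np.asarray(weight_water, dtype=float)
    if np.any(ww < 0) or np.any(wa <= ww):
        raise ValueError("need weight_air > weight_water >= 0")
    out = DM_COEFFICIENT * (wa / (wa - ww) - DM_OFFSET)
    return float(out) if out.ndim == 0 else out


def convert_chip_score_uk(score6, slope: float = -8.0 / 5.0,
                          intercept: float = 9.0 + 8.0 / 5.0):
    """Map a 1-6 light-to-dark chip score onto the 1-9 dark-to-light scale.

    The default is the endpoint-anchored negative linear map
    s9 = 9 - (8/5)(s6 - 1), i.e. 1 -> 9 and 6 -> 1.  Slope and intercept are
    configurable because grading conventions differ between stations.
    Out-of-range inputs pass through the linear map with a warning.
    """
    s6 = np.asarray(score6, dtype=float)
    if np.any((s6 < 1.0) | (s6 > 6.0)):
        warnings.warn("chip score outside the nominal 1-6 range; "
                      "converting through the linear map anyway")
    out = intercept + slope * s6
    return float(out) if out.ndim == 0 else out


@dataclass
class AdjustedPhenotypes:
    """Per-genotype corrected means plus the fitted model, for audit."""

    means: pd.Series                       # genotype id -> mean corrected value
    year_effects: dict = field(default_factory=dict)
    location_effects: dict = field(default_factory=dict)
    mu: float = 0.0
    sigma2_genotype: float = 0.0
    sigma2_residual: float = 0.0

    def to_json(self) -> str:
        import json
        return json.dumps({
            "mu": self.mu,
            "year_effects": self.year_effects,
            "location_effects": self.location_effects,
            "sigma2_genotype": self.sigma2_genotype,
            "sigma2_residual": self.sigma2_residual,
            "n_genotypes": int(self.means.size),
        }, indent=2)


def _dummies(levels: pd.Series, name: str):
    """Treatment-coded dummy columns, first (sorted) level as reference."""
    cats = sorted(levels.unique())
    cols = {f"{name}[{c}]": (levels == c).to_numpy(float) for c in cats[1:]}
    return cats, cols


def adjust_environment(records: pd.DataFrame,
                       value_col: str = "value") -> AdjustedPhenotypes:
    """Fit the year/location mixed model by REML and return corrected means.

    ``records`` needs columns genotype_id, year, location and the value
    column.  The genotype effect is random with iid variance; year and
    location are fixed with the first (sorted) level of each as the
    reference (effect 0) — only effect differences matter after
    subtraction, so the corrected means do not depend on this convention.
    The overall mean mu is *not* subtracted.
    """
    required = {"genotype_id", "year", "location", value_col}
    if records.empty or not required.issubset(records.columns):
        raise ValueError(f"records must be non-empty with columns {sorted(required)}")
    records = records.reset_index(drop=True)
    y = records[value_col].to_numpy(float)
    n = y.size

    years, year_cols = _dummies(records["year"].astype(str), "year")
    locs, loc_cols = _dummies(records["location"].astype(str), "location")
    X = np.column_stack([np.ones(n)] + list(year_cols.values()) + list(loc_cols.values()))

    # genotype incidence -> random-effect covariance K = Z Z'
    geno = records["genotype_id"].astype(str)
    geno_levels, geno_codes = np.unique(geno, return_inverse=True)
    Zg = np.zeros((n, geno_levels.size))
    Zg[np.arange(n), geno_codes] = 1.0
    K = Zg @ Zg.T

    fit = profile_reml(y, X, K)
    beta = fit.beta
    year_eff = {years[0]: 0.0}
    for i, c in enumerate(years[1:]):
        year_eff[c] = float(beta[1 + i])
    loc_eff = {locs[0]: 0.0}
    for i, c in enumerate(locs[1:]):
        loc_eff[c] = float(beta[1 + len(years) - 1 + i])

    corrected = y.copy()
    corrected -= records["year"].astype(str).map(year_eff).to_numpy(float)
    corrected -= records["location"].astype(str).map(loc_eff).to_numpy(float)
    means = pd.Series(corrected).groupby(geno.to_numpy()).mean()
    means.index.name = "genotype_id"

    return AdjustedPhenotypes(
        means=means, year_effects=year_eff, location_effects=loc_eff,
        mu=float(beta[0]), sigma2_genotype=fit.sigma2_g,
        sigma2_residual=fit.sigma2_e)
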