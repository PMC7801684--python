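"""Per-species change percentages and cross-species summary statistics.

Each species contributes one row: current suitable area with and without
land-cover correction (nationally and within protected areas), the
percentage removed by the correction, and — per future scenario — loss and
gain percentages relative to the current corrected area.  Cross-species
aggregates are medians, IQRs, means and s.d., plus paired t-tests
contrasting scenarios over the same species.

A packaged reference dataset of 19 dipterocarp species
(``data/table2.csv``) ships with the module for worked examples and for
regression-testing the aggregation arithmetic against published values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

LOSS_GAIN_COLUMNS = (
    "loss_nat_rcp45", "gain_nat_rcp45", "loss_pa_rcp45", "gain_pa_rcp45",
    "loss_nat_rcp85", "gain_nat_rcp85", "loss_pa_rcp85", "gain_pa_rcp85",
)


@dataclass
class SpeciesAreas:
    """Raw km² areas for one species across its six maps (3 climates × 2
    land-cover-correction states), national and within protected areas."""

    species: str
    area_nolcc_nat: float
    area_lcc_nat: float
    area_nolcc_pa: float
    area_lcc_pa: float
    # scenario -> dict(loss_nat, gain_nat, loss_pa, gain_pa), LCC-corrected areas
    scenarios: dict[str, dict[str, float]] = field(default_factory=dict)


def build_species_table(per_species: list[SpeciesAreas]) -> pd.DataFrame:
    """Assemble the per-species percentage table.

    reduced% = 100 (A_noLCC − A_LCC) / A_noLCC; loss%/gain% = 100 × area /
    A_current_LCC (national and within-PA denominators respectively).  Gains
    may exceed 100% for species with small current ranges.  Species with
    zero corrected current area are flagged invalid and excluded from
    aggregates.
    """
    rows = []
    for sp in per_species:
        valid = sp.area_lcc_nat > 0
        row: dict[str, object] = {
            "species": sp.species,
            "area_current_lcc_nat_km2": sp.area_lcc_nat,
            "area_current_lcc_pa_km2": sp.area_lcc_pa,
            "reduced_pct_nat": (
                100.0 * (sp.area_nolcc_nat - sp.area_lcc_nat) / sp.area_nolcc_nat
                if sp.area_nolcc_nat > 0 else np.nan
            ),
            "reduced_pct_pa": (
                100.0 * (sp.area_nolcc_pa - sp.area_lcc_pa) / sp.area_nolcc_pa
                if sp.area_nolcc_pa > 0 else np.nan
            ),
            "valid": valid,
        }
        for scen, areas in sp.scenarios.items():
            for kind in ("loss", "gain"):
                denom_nat = sp.area_lcc_nat
                denom_pa = sp.area_lcc_pa
                row[f"{kind}_nat_{scen}"] = (
                    100.0 * areas[f"{kind}_nat"] / denom_nat if valid else np.nan
                )
                row[f"{kind}_pa_{scen}"] = (
                    100.0 * areas[f"{kind}_pa"] / denom_pa if denom_pa > 0 else np.nan
                )
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class SummaryStats:
    median: float
    iqr: tuple[float, float]
    mean: float
    sd: float
    n: int


def column_summary(table: pd.DataFrame, column: str) -> SummaryStats:
    """Median, (25th, 75th) percentiles by linear interpolation, mean and
    n−1 s.d. of one column over valid rows."""
    vals = table[column].dropna().to_numpy(dtype=float)
    if len(vals) < 2:
        raise ValueError(f"need at least two valid values in {column!r}")
    return SummaryStats(
        median=float(np.percentile(vals, 50)),
        iqr=(float(np.percentile(vals, 25)), float(np.percentile(vals, 75))),
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)),
        n=len(vals),
    )


@dataclass
class PairedContrast:
    mean_difference: float         # mean(b − a)
    t_statistic: float
    p_value: float
    n: int


def paired_contrast(
    table: pd.DataFrame,
    column_a: str,
    column_b: str,
    alternative: str = "two-sided",
) -> PairedContrast:
    """Paired t-test of column_b against column_a over species (two-sided
    by default; ``alternative="greater"`` tests b > a)."""
    sub = table[[column_a, column_b]].dropna()
    a = sub[column_a].to_numpy(dtype=float)
    b = sub[column_b].to_numpy(dtype=float)
    if len(a) < 2:
        raise ValueError("need at least two paired values")
    d = b - a
    if np.allclose(d.std(ddof=1), 0):
        if np.allclose(d, 0):
            return PairedContrast(0.0, 0.0, 1.0, len(a))
        raise ValueError("zero variance of nonzero differences")
    res = stats.ttest_rel(b, a, alternative=alternative)
    return PairedContrast(float(d.mean()), float(res.statistic), float(res.pvalue), len(a))


def load_reference_table() -> pd.DataFrame:
    """The packaged 19-species dipterocarp change table."""
    with resources.files("dipsdm.data").joinpath("table2.csv").open() as fh:
        return pd.read_csv(fh)


def summarize_change_table(table: pd.DataFrame) -> dict:
    """Headline aggregates of a per-species change table: the median of
    every loss/gain column plus the four RCP 8.5 vs 4.5 paired contrasts."""
    out: dict[str, object] = {}
    for col in LOSS_GAIN_COLUMNS:
        if col in table.columns:
            s = column_summary(table, col)
            out[f"median_{col}"] = s.median
            out[f"iqr_{col}"] = s.iqr
    for kind in ("loss", "gain"):
        for level in ("nat", "pa"):
            a, b = f"{kind}_{level}_rcp45", f"{kind}_{level}_rcp85"
            if a in table.columns and b in table.columns:
                c = paired_contrast(table, a, b)
                out[f"mean_diff_{kind}_{level}"] = c.mean_difference
                out[f"p_{kind}_{level}"] = c.p_value
    return out
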