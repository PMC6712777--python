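"""Two-step bias adjustment: baseline scaling and benchmark prediction.

Step zero — the naive baseline — scales the diseased member count of a
cell by the demographic factor N / N_member.  Under fund-specific
selectivity this is biased: it corrects for the age/sex/district
composition of the membership but not for the fact that membership
itself is informative for disease status.

The adjustment proper fits the region-wise mixed model on member data
(conditional expectation of member prevalence given member auxiliary
diagnosis frequencies) and then evaluates the fitted model on the
*national* auxiliary data as benchmarks:

    y_hat = x' beta_hat + z' b_hat,

per cell, with the district random effect retained in the prediction.
Cells in districts without any member data fall back to the fixed-effect
part alone.  Predictions are clamped to [0, N]; aggregates at any level
are exact sums of cell predictions divided by sums of national cell
sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import CellTable, ModelDesign, logger
from .lmm import DesignMatrices, RegionFit, build_design, fit_region_design

AGGREGATION_LEVELS = ("district", "region", "age_group", "sex", "national")

_GROUP_KEYS = {
    "district": ["region", "district"],
    "region": ["region"],
    "age_group": ["age_group"],
    "sex": ["sex"],
    "national": [],
}


class EstimationError(ValueError):
    pass


def naive_scaled_estimate(table: CellTable) -> pd.Series:
    """Demographically scaled baseline (N / N_member) * y_member per cell.

    Cells without members get NaN (undefined baseline) and are flagged
    in the log.
    """
    f = table.frame
    with np.errstate(divide="ignore", invalid="ignore"):
        est = np.where(
            f["n_member"] > 0,
            f["n_national"] / f["n_member"].replace(0, np.nan) * f["y_member"],
            np.nan,
        )
    n_empty = int((f["n_member"] == 0).sum())
    if n_empty:
        logger.warning("naive baseline undefined for %d member-free cells", n_empty)
    return pd.Series(est, index=f.index, name="naive_estimate")


def fit_regions(table: CellTable, design: ModelDesign, **fit_kw) -> dict[int, RegionFit]:
    """Fit the member-data sub-model for every model region."""
    design.validate()
    model_regions = sorted({design.model_region(int(g)) for g in table.regions})
    fits: dict[int, RegionFit] = {}
    for mr in model_regions:
        dm = build_design(table, mr, design, population="member")
        _check_design_size(dm, mr)
        fits[mr] = fit_region_design(dm, mr, **fit_kw)
        logger.info(
            "fitted region %d: n=%d, sigma2=%.3f, psi[0,0]=%.3f, converged=%s",
            mr, dm.n_rows, fits[mr].sigma2_hat, float(fits[mr].psi_hat[0, 0]),
            fits[mr].converged,
        )
    return fits


def _check_design_size(dm: DesignMatrices, region: int) -> None:
    need = dm.n_fixed + dm.n_random + 1
    if dm.n_rows < need:
        raise EstimationError(
            f"model region {region} has {dm.n_rows} usable cells; "
            f"needs at least P + Q + 1 = {need}"
        )


def predict_national(
    fit: RegionFit, dm_national: DesignMatrices
) -> tuple[np.ndarray, np.ndarray]:
    """Benchmark prediction y_hat = x' beta_hat + z' b_hat per national cell.

    Returns the raw (unclamped) predictions and a boolean flag marking
    cells whose district had no member data (predicted from fixed
    effects alone).  Raises on any column mismatch between the member
    and national designs.
    """
    if dm_national.columns != fit.fixed_names:
        raise EstimationError(
            "column mismatch between member fit and national design: "
            f"{fit.fixed_names} vs {dm_national.columns}"
        )
    if dm_national.random_columns != fit.random_names:
        raise EstimationError("random-effect column mismatch between designs")
    yhat = dm_national.X @ fit.beta_hat
    no_b = np.zeros(dm_national.n_rows, dtype=bool)
    Q = dm_national.n_random
    for code, did in enumerate(dm_national.district_ids):
        rows = dm_national.district_codes == code
        b = fit.b_hat.get(did)
        if b is None:
            no_b[rows] = True
            continue
        yhat[rows] += dm_national.Z[rows] @ b
    if no_b.any():
        logger.info(
            "predicted %d cells in member-free districts from fixed effects only",
            int(no_b.sum()),
        )
    return yhat, no_b


@dataclass
class PrevalenceTable:
    """Per-cell predictions with aggregates at every level."""

    cells: pd.DataFrame
    aggregates: dict[str, pd.DataFrame] = field(default_factory=dict)
    alpha: float | None = None

    @property
    def national_prevalence(self) -> float:
        return float(self.aggregates["national"]["prevalence"].iloc[0])

    @property
    def national_relative_adjustment(self) -> float:
        return float(self.aggregates["national"]["relative_adjustment_pct"].iloc[0])


def aggregate(cells: pd.DataFrame, level: str) -> pd.DataFrame:
    """Aggregate cell predictions to one level with exact additivity.

    The aggregate diseased count is the sum of the member cells' y_hat;
    prevalence is that sum over the summed national size.  The naive
    baseline aggregates only over cells where it is defined.
    """
    if level not in _GROUP_KEYS:
        raise EstimationError(
            f"unknown aggregation level '{level}'; expected one of {AGGREGATION_LEVELS}"
        )
    keys = _GROUP_KEYS[level]
    df = cells.copy()
    df["_naive_n"] = np.where(df["naive_estimate"].notna(), df["n_national"], 0.0)
    df["_naive_y"] = df["naive_estimate"].fillna(0.0)
    if keys:
        grouped = df.groupby(keys, sort=True, observed=True)
        agg = grouped.agg(
            y_hat=("y_hat", "sum"),
            n_national=("n_national", "sum"),
            n_member=("n_member", "sum"),
            y_member=("y_member", "sum"),
            naive_y=("_naive_y", "sum"),
            naive_n=("_naive_n", "sum"),
        ).reset_index()
    else:
        agg = pd.DataFrame({
            "y_hat": [df["y_hat"].sum()],
            "n_national": [df["n_national"].sum()],
            "n_member": [df["n_member"].sum()],
            "y_member": [df["y_member"].sum()],
            "naive_y": [df["_naive_y"].sum()],
            "naive_n": [df["_naive_n"].sum()],
        })
    agg["prevalence"] = agg["y_hat"] / agg["n_national"]
    with np.errstate(divide="ignore", invalid="ignore"):
        agg["member_prevalence"] = np.where(
            agg["n_member"] > 0, agg["y_member"] / agg["n_member"], np.nan
        )
        agg["naive_prevalence"] = np.where(
            agg["naive_n"] > 0, agg["naive_y"] / agg["naive_n"], np.nan
        )
    agg["relative_adjustment_pct"] = relative_adjustment(
        agg["member_prevalence"].to_numpy(), agg["prevalence"].to_numpy()
    )
    return agg.drop(columns=["naive_n"])


def relative_adjustment(member_prevalence, estimate):
    """Signed percentage change from member prevalence to the estimate.

    ``100 * (estimate - member) / member``; undefined (NaN) where the
    member prevalence is zero.
    """
    member = np.asarray(member_prevalence, dtype=float)
    est = np.asarray(estimate, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(member > 0, 100.0 * (est - member) / member, np.nan)
    n_undef = int(np.sum(~(member > 0)))
    if n_undef:
        logger.warning("relative adjustment undefined for %d entries", n_undef)
    if out.ndim == 0:
        return float(out)
    return out


def estimate_prevalence(
    table: CellTable,
    design: ModelDesign,
    fits: Mapping[int, RegionFit] | None = None,
    levels: Sequence[str] = AGGREGATION_LEVELS,
) -> PrevalenceTable:
    """Run the full two-step adjustment and assemble the prevalence table."""
    if fits is None:
        fits = fit_regions(table, design)
    cells = table.frame[
        ["region", "district", "cell", "age_group", "sex",
         "n_national", "n_member", "y_member"]
    ].copy()
    yhat_raw = np.full(len(cells), np.nan)
    no_b = np.zeros(len(cells), dtype=bool)
    for mr, fit in fits.items():
        dm_nat = build_design(table, mr, design, population="national", check_rank=False)
        pred, flag = predict_national(fit, dm_nat)
        rows = table.frame["region"].map(lambda g: design.model_region(int(g)) == mr).to_numpy()
        yhat_raw[rows] = pred
        no_b[rows] = flag
    if np.isnan(yhat_raw).any():
        raise EstimationError("some cells were not covered by any region fit")

    n_nat = cells["n_national"].to_numpy(dtype=float)
    yhat = np.clip(yhat_raw, 0.0, n_nat)
    clamped = yhat != yhat_raw
    if clamped.any():
        logger.info("clamped %d predictions into [0, N]", int(clamped.sum()))

    cells["y_hat_raw"] = yhat_raw
    cells["y_hat"] = yhat
    cells["prevalence"] = yhat / n_nat
    cells["naive_estimate"] = naive_scaled_estimate(table).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        cells["member_prevalence"] = np.where(
            cells["n_member"] > 0, cells["y_member"] / cells["n_member"], np.nan
        )
    cells["empty_member"] = (cells["n_member"] == 0).to_numpy()
    cells["fixed_effects_only"] = no_b
    cells["clamped"] = clamped

    aggs = {lvl: aggregate(cells, lvl) for lvl in levels}
    return PrevalenceTable(cells=cells, aggregates=aggs)
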