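"""Semiparametric bootstrap confidence intervals for prevalence estimates.

The resampling scheme is the residual bootstrap for multilevel models:
per region, the predicted district random effects and the conditional
cell residuals are centered, reflated so their empirical second moments
match the REML estimates (Psi_hat, sigma2_hat) exactly, and resampled
independently with replacement.  Pseudo-responses

    y* = X_member beta_hat + Z b* + e*

are rebuilt on the member design, the full region-wise model is refitted
on y*, national predictions and target aggregates are recomputed, and
percentile intervals are read off the replicate distribution.  Working
with centered, reflated empirical pools rather than Gaussian draws keeps
the intervals free of the normality assumption of the model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import CellTable, ModelDesign, child_rng, logger
from .estimate import (
    AGGREGATION_LEVELS,
    _GROUP_KEYS,
    aggregate,
    estimate_prevalence,
    fit_regions,
    predict_national,
)
from .lmm import RegionFit, build_design, fit_reml


class BootstrapError(RuntimeError):
    pass


@dataclass
class BootstrapSummary:
    """Replicate distribution and percentile intervals per target."""

    B: int
    alpha: float
    targets: dict[str, pd.DataFrame]
    replicate_values: dict[str, np.ndarray]   # (B_kept, n_groups) prevalence
    group_index: dict[str, pd.DataFrame]
    n_dropped: int
    valid: bool
    seed: int


def reflate_pools(
    fit: RegionFit, tol_jitter: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Centered, reflated random-effect and residual pools for one region.

    The returned pools satisfy ``mean(b b') == psi_hat`` and
    ``mean(e^2) == sigma2_hat`` exactly (up to floating point), the
    moment condition the resampling scheme requires.
    """
    b = fit.b_matrix()
    D, Q = b.shape
    b = b - b.mean(axis=0, keepdims=True)
    S = b.T @ b / D
    psi = np.atleast_2d(fit.psi_hat)
    if np.all(np.linalg.eigvalsh((psi + psi.T) / 2) <= 1e-14):
        pool_b = np.zeros_like(b)
    else:
        try:
            Ls = np.linalg.cholesky(S + tol_jitter * np.eye(Q))
        except np.linalg.LinAlgError:
            Ls = np.linalg.cholesky(S + 1e-12 * np.eye(Q))
        Lp = np.linalg.cholesky(psi)
        A = Lp @ np.linalg.inv(Ls)
        pool_b = b @ A.T

    e = fit.resid_conditional - fit.resid_conditional.mean()
    ms = float(np.mean(e**2))
    if ms <= 0 or fit.sigma2_hat <= 0:
        pool_e = np.zeros_like(e)
    else:
        pool_e = e * np.sqrt(fit.sigma2_hat / ms)
    return pool_b, pool_e


def semiparametric_bootstrap(
    table: CellTable,
    design: ModelDesign,
    fits: Mapping[int, RegionFit] | None = None,
    B: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    targets: Sequence[str] = ("national",),
    max_drop_fraction: float = 0.10,
) -> BootstrapSummary:
    """Bootstrap the full pipeline and return percentile intervals.

    ``targets`` names aggregation levels; each level's interval covers
    the prevalence proportion of every group at that level.  Replicates
    whose refit does not converge are dropped and logged; if more than
    ``max_drop_fraction`` drop, the summary is flagged invalid.
    """
    if B < 2:
        raise BootstrapError("B must be at least 2")
    for t in targets:
        if t not in AGGREGATION_LEVELS:
            raise BootstrapError(f"unknown target level '{t}'")
    if fits is None:
        fits = fit_regions(table, design)
    for mr, fit in fits.items():
        if not fit.converged:
            raise BootstrapError(f"region {mr} fit did not converge")

    # original point estimates and per-level group layout
    ptable = estimate_prevalence(table, design, fits=fits, levels=targets)
    group_index = {
        t: ptable.aggregates[t][_GROUP_KEYS[t]].copy() if _GROUP_KEYS[t]
        else pd.DataFrame(index=[0])
        for t in targets
    }

    regions = sorted(fits)
    member_dms = {mr: build_design(table, mr, design, "member") for mr in regions}
    national_dms = {
        mr: build_design(table, mr, design, "national", check_rank=False)
        for mr in regions
    }
    pools = {mr: reflate_pools(fits[mr]) for mr in regions}
    marginal_fit = {mr: member_dms[mr].X @ fits[mr].beta_hat for mr in regions}

    n_cells = len(table.frame)
    region_rows = {
        mr: (table.frame["region"].map(lambda g: design.model_region(int(g))) == mr).to_numpy()
        for mr in regions
    }
    n_nat = table.frame["n_national"].to_numpy(dtype=float)

    level_codes = {}
    for t in targets:
        keys = _GROUP_KEYS[t]
        if keys:
            # map each cell row to its group position
            cell_key = pd.MultiIndex.from_frame(table.frame[keys])
            group_key = pd.MultiIndex.from_frame(group_index[t])
            codes = group_key.get_indexer(cell_key)
            level_codes[t] = (codes, len(group_index[t]))
        else:
            level_codes[t] = (np.zeros(n_cells, dtype=int), 1)

    reps: dict[str, list[np.ndarray]] = {t: [] for t in targets}
    n_dropped = 0
    for b_i in range(B):
        rng = child_rng(seed, "bootstrap", b_i)
        yhat_cells = np.full(n_cells, np.nan)
        ok = True
        for mr in regions:
            dm = member_dms[mr]
            pool_b, pool_e = pools[mr]
            D = pool_b.shape[0]
            b_star = pool_b[rng.integers(0, D, D)]
            e_star = pool_e[rng.integers(0, len(pool_e), dm.n_rows)]
            y_star = (
                marginal_fit[mr]
                + np.einsum("nq,nq->n", dm.Z, b_star[dm.district_codes])
                + e_star
            )
            refit = fit_reml(
                y_star, dm.X, dm.Z, dm.district_codes, region=mr,
                fixed_names=dm.columns, random_names=dm.random_columns,
                district_ids=dm.district_ids,
            )
            if not refit.converged:
                ok = False
                break
            pred, _ = predict_national(refit, national_dms[mr])
            yhat_cells[region_rows[mr]] = pred
        if not ok:
            n_dropped += 1
            logger.warning("bootstrap replicate %d dropped (refit non-convergence)", b_i)
            continue
        yhat_cells = np.clip(yhat_cells, 0.0, n_nat)
        for t in targets:
            codes, G = level_codes[t]
            y_g = np.bincount(codes, weights=yhat_cells, minlength=G)
            n_g = np.bincount(codes, weights=n_nat, minlength=G)
            reps[t].append(y_g / n_g)

    kept = B - n_dropped
    valid = n_dropped <= max_drop_fraction * B and kept >= 2
    if not valid:
        logger.warning(
            "bootstrap flagged invalid: %d of %d replicates dropped", n_dropped, B
        )

    out_targets: dict[str, pd.DataFrame] = {}
    rep_arrays: dict[str, np.ndarray] = {}
    for t in targets:
        arr = np.asarray(reps[t]) if reps[t] else np.empty((0, level_codes[t][1]))
        rep_arrays[t] = arr
        point = ptable.aggregates[t]["prevalence"].to_numpy()
        if len(arr):
            lo = np.quantile(arr, alpha / 2.0, axis=0)
            hi = np.quantile(arr, 1.0 - alpha / 2.0, axis=0)
        else:
            lo = hi = np.full(level_codes[t][1], np.nan)
        frame = group_index[t].copy()
        frame["point"] = point
        frame["ci_low"] = lo
        frame["ci_high"] = hi
        out_targets[t] = frame.reset_index(drop=True)

    logger.info(
        "bootstrap: B=%d kept=%d alpha=%.3f targets=%s", B, kept, alpha, list(targets)
    )
    return BootstrapSummary(
        B=B, alpha=alpha, targets=out_targets, replicate_values=rep_arrays,
        group_index=group_index, n_dropped=n_dropped, valid=valid, seed=seed,
    )
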