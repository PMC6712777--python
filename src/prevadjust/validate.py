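"""Validity checks: Monte-Carlo simulation and hospital-data cross-validation.

Two designs probe the identifying assumption — equality of the member
and national conditional expectations given cell size and auxiliary
data:

* ``monte_carlo_validation`` replays the whole pipeline on synthetic
  populations drawn under a grid of selectivity scenarios and scores the
  benchmarked estimator and the naive demographic baseline against the
  known national truth.  Under scenarios where the auxiliary data
  explains the membership selectivity, the benchmarked estimator should
  be unbiased while the baseline is not; under scenarios with residual
  informativeness both may fail, which the report shows rather than
  hides.

* ``cross_validation_proxy`` needs no truth at all: a hospital-observed
  diagnosis — known in BOTH populations — serves as a stand-in
  endpoint.  Its member counts are modelled from the remaining
  diagnoses, extrapolated with the national benchmarks, and compared to
  its known national total.

Estimation never reads the synthetic truth column; scoring does.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import NATIONAL_AUX_PREFIX, CellTable, ModelDesign, child_seed, logger
from .estimate import estimate_prevalence, fit_regions, naive_scaled_estimate
from .lmm import DesignError
from .selection import select_predictors
from .synthetic import SelectionScenario, generate_population


class ValidationError(RuntimeError):
    pass


@dataclass
class ValidationReport:
    """Replicate-averaged scores per scenario."""

    frame: pd.DataFrame
    reps: int
    seed: int

    def scenario_row(self, i: int) -> pd.Series:
        return self.frame.iloc[i]


def _score_replicate(pop, ptable) -> dict:
    truth = pop.table.frame["y_national_true"].to_numpy(dtype=float)
    n_nat = pop.table.frame["n_national"].to_numpy(dtype=float)
    true_prev = truth.sum() / n_nat.sum()

    est_prev = ptable.national_prevalence
    naive = naive_scaled_estimate(pop.table).to_numpy()
    defined = ~np.isnan(naive)
    naive_prev = naive[defined].sum() / n_nat[defined].sum()

    # district-level prevalence errors
    cells = ptable.cells
    key = cells["region"].astype(str) + ":" + cells["district"].astype(str)
    df = pd.DataFrame({
        "key": key, "y_hat": cells["y_hat"].to_numpy(),
        "truth": truth, "n": n_nat,
    })
    g = df.groupby("key", sort=True).sum(numeric_only=True)
    district_err = (g["y_hat"] - g["truth"]) / g["n"]
    return {
        "true_prev": true_prev,
        "est_prev": est_prev,
        "naive_prev": naive_prev,
        "district_sq_err": float(np.mean(district_err**2)),
    }


def monte_carlo_validation(
    scenarios: Sequence[SelectionScenario],
    reps: int,
    seed: int,
    design: ModelDesign | None = None,
    run_selection: bool = False,
    top_k: int = 3,
    p_sel: int = 3,
    max_fail_fraction: float = 0.10,
) -> ValidationReport:
    """Monte-Carlo bias/RMSE study of the estimator across scenarios.

    Per scenario and replicate: generate a population, optionally run
    variable selection, fit the region-wise model, predict nationally,
    and score against the generated truth.  The naive demographically
    scaled baseline is scored on the same replicates for contrast.
    """
    if reps < 2:
        raise ValidationError("reps must be at least 2")
    rows = []
    for i, scn in enumerate(scenarios):
        recs = []
        failures = 0
        for j in range(reps):
            rep_seed = child_seed(seed, "mc", i, j)
            try:
                pop = generate_population(scn, seed=rep_seed)
                dsn = design
                if dsn is None or run_selection:
                    labels = (
                        select_predictors(pop.table, top_k=top_k, p_sel=p_sel).elected
                        if run_selection
                        else [l for l in scn.aux_model.labels if any(
                            l in bm for bm in scn.beta_by_region())]
                    )
                    dsn = ModelDesign(
                        fixed_effects=["intercept", "cell_size", "age_group", "sex"] + labels,
                    )
                ptable = estimate_prevalence(pop.table, dsn)
                recs.append(_score_replicate(pop, ptable))
            except (DesignError, np.linalg.LinAlgError) as exc:  # pragma: no cover
                failures += 1
                logger.warning("replicate (%d, %d) failed: %s", i, j, exc)
        if failures > max_fail_fraction * reps:
            raise ValidationError(
                f"scenario {i}: {failures}/{reps} replicates failed"
            )
        rec = pd.DataFrame(recs)
        err = rec["est_prev"] - rec["true_prev"]
        nerr = rec["naive_prev"] - rec["true_prev"]
        mean_true = rec["true_prev"].mean()
        rows.append({
            "scenario": i,
            "informative_beyond_aux": scn.informative_beyond_aux,
            "mean_true_prev": mean_true,
            "mean_est_prev": rec["est_prev"].mean(),
            "mean_naive_prev": rec["naive_prev"].mean(),
            "bias": err.mean(),
            "rel_bias_pct": 100.0 * err.mean() / mean_true,
            "mc_se": err.std(ddof=1) / np.sqrt(len(err)),
            "rmse": float(np.sqrt(np.mean(err**2))),
            "naive_bias": nerr.mean(),
            "naive_rel_bias_pct": 100.0 * nerr.mean() / mean_true,
            "naive_mc_se": nerr.std(ddof=1) / np.sqrt(len(nerr)),
            "district_rmse": float(np.sqrt(rec["district_sq_err"].mean())),
            "reps_used": len(rec),
            "failures": failures,
        })
    report = ValidationReport(frame=pd.DataFrame(rows), reps=reps, seed=seed)
    logger.info("monte-carlo validation finished: %d scenarios x %d reps", len(scenarios), reps)
    return report


def cross_validation_proxy(
    table: CellTable, proxy_column: str, design: ModelDesign
) -> dict:
    """Proxy-endpoint cross-validation within the hospital data.

    The member count of ``proxy_column`` (a diagnosis observed in both
    populations) is treated as the endogenous variable, modelled from
    the remaining predictors on member data and extrapolated with the
    national benchmarks.  Because the proxy's national total IS known,
    the relative prediction error directly measures whether the
    member-to-national extrapolation is valid.
    """
    if proxy_column not in table.aux_labels:
        raise ValidationError(f"proxy column '{proxy_column}' not in auxiliary data")
    if proxy_column in design.fixed_effects:
        raise ValidationError("proxy column must not appear among the predictors")

    model_regions = sorted({design.model_region(int(g)) for g in table.regions})
    from .lmm import build_design, fit_region_design
    from .estimate import predict_national

    per_region = []
    total_pred = 0.0
    total_true = 0.0
    for mr in model_regions:
        dm = build_design(table, mr, design, population="member", outcome=proxy_column)
        fit = fit_region_design(dm, mr)
        dm_nat = build_design(table, mr, design, population="national", check_rank=False)
        pred, _ = predict_national(fit, dm_nat)
        truth = table.frame[
            table.frame["region"].map(lambda g: design.model_region(int(g)) == mr)
        ]
        t = float(truth[NATIONAL_AUX_PREFIX + proxy_column].sum())
        p = float(pred.sum())
        per_region.append({
            "region": mr,
            "predicted_total": p,
            "true_total": t,
            "relative_error": (p - t) / t if t else np.nan,
        })
        total_pred += p
        total_true += t

    rel = (total_pred - total_true) / total_true if total_true else np.nan
    result = {
        "proxy": proxy_column,
        "predicted_total": total_pred,
        "true_total": total_true,
        "relative_error": rel,
        "per_region": pd.DataFrame(per_region),
    }
    logger.info(
        "cross-validation proxy '%s': relative error %.4g", proxy_column, rel
    )
    return result
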