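"""Region-wise correlation-based election of auxiliary predictors.

For every region, candidate diagnosis columns are ranked by the absolute
Pearson correlation between the member prevalence proportion and the
candidate's member per-capita rate over that region's non-empty cells.
Working on per-capita rates rather than raw counts removes the trivial
correlation through cell size.  A candidate is *elected* in a region
when it enters the region's top-k; the final predictor set consists of
the most frequently elected candidates across regions, with ties broken
by mean absolute correlation and then lexicographically by label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .datamodel import MEMBER_AUX_PREFIX, CellTable, logger


class SelectionError(ValueError):
    pass


@dataclass
class SelectionResult:
    per_region_ranking: dict[int, pd.DataFrame]
    elected: list[str]
    election_counts: pd.Series

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for region, rk in sorted(self.per_region_ranking.items()):
            for _, r in rk.iterrows():
                rows.append({
                    "region": region, "label": r["label"],
                    "correlation": r["correlation"], "rank": r["rank"],
                })
        return pd.DataFrame(rows)


def rank_predictors_by_region(
    table: CellTable, candidates: Sequence[str] | None = None
) -> dict[int, pd.DataFrame]:
    """Per region, rank candidates by |corr(member prevalence, rate)|.

    Cells without members are excluded.  A candidate with zero variance
    within a region gets correlation 0 with a logged warning; a region
    with fewer than three usable cells is an error.
    """
    if candidates is None:
        candidates = table.aux_labels
    missing = [c for c in candidates if c not in table.aux_labels]
    if missing:
        raise SelectionError(f"candidate columns not in auxiliary data: {missing}")

    rankings: dict[int, pd.DataFrame] = {}
    for region in table.regions:
        sub = table.region_frame(int(region))
        sub = sub[sub["n_member"] > 0]
        if len(sub) < 3:
            raise SelectionError(
                f"region {region} has {len(sub)} usable cells; need at least 3"
            )
        prev = (sub["y_member"] / sub["n_member"]).to_numpy(dtype=float)
        prev_c = prev - prev.mean()
        sd_prev = np.sqrt(np.mean(prev_c**2))
        rows = []
        for lab in candidates:
            rate = (sub[MEMBER_AUX_PREFIX + lab] / sub["n_member"]).to_numpy(dtype=float)
            rate_c = rate - rate.mean()
            sd_rate = np.sqrt(np.mean(rate_c**2))
            degenerate = sd_rate <= 1e-12 * max(np.abs(rate).max(), 1e-300)
            if degenerate or sd_prev == 0:
                logger.warning(
                    "zero-variance candidate '%s' in region %s; correlation set to 0",
                    lab, region,
                )
                corr = 0.0
            else:
                corr = float(np.mean(prev_c * rate_c) / (sd_prev * sd_rate))
            rows.append({"label": lab, "correlation": corr})
        rk = pd.DataFrame(rows)
        rk["abs_correlation"] = rk["correlation"].abs()
        rk = rk.sort_values(
            ["abs_correlation", "label"], ascending=[False, True], kind="stable"
        ).reset_index(drop=True)
        rk["rank"] = np.arange(1, len(rk) + 1)
        rankings[int(region)] = rk
    return rankings


def elect_predictors(
    rankings: Mapping[int, pd.DataFrame], top_k: int = 10, p_sel: int = 10
) -> SelectionResult:
    """Cross-region frequency-of-election choice of the final predictors.

    Counts, per candidate, the regions where it ranks within the top-k;
    returns the ``p_sel`` candidates with the highest counts.  Ties are
    broken by mean absolute correlation across regions, then by label.
    """
    if top_k < 1 or p_sel < 1:
        raise SelectionError("top_k and p_sel must be at least 1")
    all_labels = sorted(
        set().union(*(rk["label"].tolist() for rk in rankings.values()))
    )
    if p_sel > len(all_labels):
        raise SelectionError(
            f"p_sel={p_sel} exceeds the {len(all_labels)} available candidates"
        )
    counts = pd.Series(0, index=all_labels, dtype=int, name="election_count")
    mean_abs = pd.Series(0.0, index=all_labels)
    for rk in rankings.values():
        top = rk.loc[rk["rank"] <= top_k, "label"]
        counts[top] += 1
        mean_abs = mean_abs.add(
            rk.set_index("label")["abs_correlation"], fill_value=0.0
        )
    mean_abs /= len(rankings)
    order = pd.DataFrame({
        "label": all_labels,
        "count": counts.to_numpy(),
        "mean_abs": mean_abs[all_labels].to_numpy(),
    }).sort_values(
        ["count", "mean_abs", "label"], ascending=[False, False, True], kind="stable"
    )
    elected = order["label"].head(p_sel).tolist()
    logger.info("elected %d predictors: %s", p_sel, elected)
    return SelectionResult(
        per_region_ranking=dict(rankings), elected=elected, election_counts=counts
    )


def select_predictors(
    table: CellTable,
    candidates: Sequence[str] | None = None,
    top_k: int = 10,
    p_sel: int = 10,
) -> SelectionResult:
    """Convenience wrapper: rank per region, then elect across regions."""
    return elect_predictors(
        rank_predictors_by_region(table, candidates), top_k=top_k, p_sel=p_sel
    )
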