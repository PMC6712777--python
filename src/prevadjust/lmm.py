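"""Region-wise linear mixed models: REML fitting, GLS/BLUP, model choice.

One sub-model per region:

    y_r = X_r beta_r + Z_r b_r + e_r,
    b_rd ~ N(0, Psi),  e_r ~ N(0, sigma2_r I),  Cov(b, e) = 0,

with Z_r block-diagonal over districts.  Because the random effects are
independent across districts, the marginal covariance
V = Z Psi Z' + sigma2 I is block-diagonal, and every REML evaluation
reduces to batched algebra on per-district blocks of at most C rows.
The variance ratio Gamma = Psi / sigma2 is profiled: for a given Gamma
the GLS fixed effects, the residual variance and the restricted
likelihood are available in closed form, leaving a Q(Q+1)/2-dimensional
search parameterized through the log-Cholesky factor of Gamma (which
keeps Psi positive semidefinite without constraints).

Fixed effects and random-effect predictions follow the explicit
GLS/BLUP formulas

    beta_hat = (X' V^-1 X)^-1 X' V^-1 y,
    b_hat    = Psi Z' V^-1 (y - X beta_hat),

evaluated through the block structure; they agree with the dense-matrix
formulas to numerical precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
from scipy import optimize, stats

from .datamodel import (
    MEMBER_AUX_PREFIX,
    NATIONAL_AUX_PREFIX,
    CellTable,
    ModelDesign,
    logger,
)

_LOG_2PI = float(np.log(2.0 * np.pi))


class DesignError(ValueError):
    """The design matrix cannot be built (missing or collinear columns)."""


class FitError(RuntimeError):
    """The model cannot be fitted on the given data."""


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

@dataclass
class DesignMatrices:
    """Stacked region design with district block structure."""

    y: np.ndarray | None
    X: np.ndarray
    Z: np.ndarray
    district_codes: np.ndarray           # 0-based code per row
    district_ids: list[tuple[int, int]]  # (region, district) per code
    columns: list[str]
    random_columns: list[str]
    index: pd.DataFrame                  # hierarchy fields per row
    n_national: np.ndarray               # per-row national cell size

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]

    @property
    def n_fixed(self) -> int:
        return self.X.shape[1]

    @property
    def n_random(self) -> int:
        return self.Z.shape[1]


def _expand_token(
    token: str, frame: pd.DataFrame, population: str, age_groups: Sequence[str]
) -> list[tuple[str, np.ndarray]]:
    if token == "intercept":
        return [("intercept", np.ones(len(frame)))]
    if token == "cell_size":
        col = "n_member" if population == "member" else "n_national"
        return [("cell_size", frame[col].to_numpy(dtype=float))]
    if token == "age_group":
        return [
            (f"age[{g}]", (frame["age_group"] == g).to_numpy(dtype=float))
            for g in age_groups[1:]
        ]
    if token == "sex":
        return [("sex[male]", (frame["sex"] == "male").to_numpy(dtype=float))]
    prefix = MEMBER_AUX_PREFIX if population == "member" else NATIONAL_AUX_PREFIX
    if prefix + token in frame.columns:
        return [(token, frame[prefix + token].to_numpy(dtype=float))]
    raise DesignError(f"unknown design column '{token}' for {population} build")


def build_design(
    table: CellTable,
    region: int,
    design: ModelDesign,
    population: str = "member",
    outcome: str = "y_member",
    check_rank: bool = True,
) -> DesignMatrices:
    """Build (y, X, Z) for one model region.

    The member build keeps only cells with members and carries the
    diseased-member count (or another member column named by
    ``outcome``) as response; the national build covers every cell and
    has no response.  ``region`` refers to the *model* region after
    applying the design's region partition.
    """
    design.validate()
    if population not in ("member", "national"):
        raise ValueError("population must be 'member' or 'national'")
    geo = [g for g in table.regions if design.model_region(g) == region]
    if not geo:
        raise DesignError(f"model region {region} matches no geographic region")
    frame = table.frame[table.frame["region"].isin(geo)]
    if population == "member":
        frame = frame[frame["n_member"] > 0]
        if len(frame) == 0:
            raise DesignError(f"region {region} has no cells with members")

    cols: list[tuple[str, np.ndarray]] = []
    for token in design.fixed_effects:
        cols.extend(_expand_token(token, frame, population, table.age_groups))
    names = [n for n, _ in cols]
    X = np.column_stack([v for _, v in cols])

    zcols: list[tuple[str, np.ndarray]] = []
    for token in design.random_effects:
        zcols.extend(_expand_token(token, frame, population, table.age_groups))
    Z = np.column_stack([v for _, v in zcols])
    znames = [n for n, _ in zcols]

    keys = list(zip(frame["region"].tolist(), frame["district"].tolist()))
    district_ids: list[tuple[int, int]] = []
    seen: dict[tuple[int, int], int] = {}
    codes = np.empty(len(keys), dtype=int)
    for i, k in enumerate(keys):
        if k not in seen:
            seen[k] = len(district_ids)
            district_ids.append(k)
        codes[i] = seen[k]

    if check_rank and population == "member":
        _check_full_rank(X, names)

    y = None
    if population == "member":
        ycol = outcome if outcome in frame.columns else MEMBER_AUX_PREFIX + outcome
        if ycol not in frame.columns:
            raise DesignError(f"outcome column '{outcome}' not found")
        y = frame[ycol].to_numpy(dtype=float)

    return DesignMatrices(
        y=y, X=X, Z=Z, district_codes=codes, district_ids=district_ids,
        columns=names, random_columns=znames,
        index=frame[["region", "district", "cell", "age_group", "sex"]].reset_index(drop=True),
        n_national=frame["n_national"].to_numpy(dtype=float),
    )


def _check_full_rank(X: np.ndarray, names: Sequence[str]) -> None:
    if X.shape[0] < X.shape[1]:
        raise DesignError(
            f"fewer rows ({X.shape[0]}) than fixed-effect columns ({X.shape[1]})"
        )
    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    if rank < X.shape[1]:
        bad = sorted(names[i] for i in piv[rank:])
        raise DesignError(f"design is rank deficient; collinear columns: {bad}")


# ---------------------------------------------------------------------------
# blocked REML machinery
# ---------------------------------------------------------------------------

class BlockedModel:
    """Per-district sufficient statistics for the profiled REML criterion."""

    def __init__(self, y: np.ndarray, X: np.ndarray, Z: np.ndarray, codes: np.ndarray):
        self.n, self.P = X.shape
        self.Q = Z.shape[1]
        self.D = int(codes.max()) + 1 if len(codes) else 0
        order = np.argsort(codes, kind="stable")
        self._order = order
        self._y_orig = np.asarray(y, dtype=float)
        ys, Xs, Zs, cs = y[order], X[order], Z[order], codes[order]
        # group districts by block size for batched linear algebra
        sizes = np.bincount(cs, minlength=self.D)
        self.groups = []
        starts = np.concatenate([[0], np.cumsum(sizes)])
        by_size: dict[int, list[int]] = {}
        for d in range(self.D):
            by_size.setdefault(int(sizes[d]), []).append(d)
        for m, ds in sorted(by_size.items()):
            if m == 0:
                continue
            rows = np.stack([np.arange(starts[d], starts[d] + m) for d in ds])
            self.groups.append({
                "districts": np.asarray(ds),
                "X": Xs[rows],          # (G, m, P)
                "y": ys[rows],          # (G, m)
                "Z": Zs[rows],          # (G, m, Q)
                "m": m,
            })
        self.XtX = X.T @ X

    # -- core evaluations --------------------------------------------------
    def _parts(self, gamma: np.ndarray):
        """Accumulate X'W^-1X, X'W^-1y, y'W^-1y, log|W| with W = I + Z Gamma Z'."""
        P = self.P
        A = np.zeros((P, P))
        c = np.zeros(P)
        s = 0.0
        logdet = 0.0
        per_group = []
        for g in self.groups:
            Zg, Xg, yg = g["Z"], g["X"], g["y"]
            m = g["m"]
            W = np.eye(m)[None] + Zg @ gamma @ Zg.transpose(0, 2, 1)
            L = np.linalg.cholesky(W)
            logdet += 2.0 * float(np.log(np.diagonal(L, axis1=1, axis2=2)).sum())
            Wi = np.linalg.inv(W)
            WiX = Wi @ Xg
            Wiy = np.einsum("gmk,gk->gm", Wi, yg)
            A += np.einsum("gmp,gmq->pq", Xg, WiX)
            c += np.einsum("gmp,gm->p", Xg, Wiy)
            s += float(np.einsum("gm,gm->", yg, Wiy))
            per_group.append({"Wi": Wi, "WiX": WiX})
        return A, c, s, logdet, per_group

    def neg2_profiled_reml(self, gamma: np.ndarray) -> float:
        A, c, s, logdet, _ = self._parts(gamma)
        try:
            beta = np.linalg.solve(A, c)
        except np.linalg.LinAlgError:
            return np.inf
        rss = max(s - float(c @ beta), 1e-300)
        sign, logdetA = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf
        return (self.n - self.P) * np.log(rss) + logdet + logdetA

    def solve(self, gamma: np.ndarray) -> dict:
        """Full GLS/BLUP solution and likelihood summaries at ``gamma``."""
        n, P = self.n, self.P
        A, c, s, logdetW, per_group = self._parts(gamma)
        beta = np.linalg.solve(A, c)
        rss = max(s - float(c @ beta), 0.0)
        dof = n - P
        sigma2 = rss / dof if dof > 0 else 0.0
        b = np.zeros((self.D, self.Q))
        fitted_sorted = np.empty(n)
        trWi = 0.0
        B2 = np.zeros((P, P))
        sizes = np.zeros(self.D, dtype=int)
        for g in self.groups:
            sizes[g["districts"]] = g["m"]
        starts = np.concatenate([[0], np.cumsum(sizes)])
        for g, pg in zip(self.groups, per_group):
            Zg, Xg, yg = g["Z"], g["X"], g["y"]
            Wi, WiX = pg["Wi"], pg["WiX"]
            r = yg - np.einsum("gmp,p->gm", Xg, beta)
            Wir = np.einsum("gmk,gk->gm", Wi, r)
            bg = np.einsum("qr,gmr,gm->gq", gamma, Zg, Wir)
            b[g["districts"]] = bg
            fit_g = np.einsum("gmp,p->gm", Xg, beta) + np.einsum("gmq,gq->gm", Zg, bg)
            trWi += float(np.einsum("gmm->", Wi))
            B2 += np.einsum("gmp,gmq->pq", WiX, WiX)
            for i, d in enumerate(g["districts"]):
                fitted_sorted[starts[d]: starts[d] + g["m"]] = fit_g[i]
        inv_order = np.empty(n, dtype=int)
        inv_order[self._order] = np.arange(n)
        fitted = fitted_sorted[inv_order]
        resid_c = np.asarray(self._y_orig) - fitted

        sign, logdetA = np.linalg.slogdet(A)
        sign_x, logdetXtX = np.linalg.slogdet(self.XtX)
        edf = n - trWi + float(np.trace(np.linalg.solve(A, B2)))
        if sigma2 > 0:
            reml_ll = -0.5 * (
                dof * (_LOG_2PI + np.log(sigma2)) + logdetW
                + (logdetA - P * np.log(sigma2)) - logdetXtX + dof
            )
            ml_ll = -0.5 * (n * (_LOG_2PI + np.log(sigma2)) + logdetW + rss / sigma2)
            cond_ll = -0.5 * (
                n * (_LOG_2PI + np.log(sigma2)) + float(resid_c @ resid_c) / sigma2
            )
        else:  # degenerate exact fit
            reml_ll = ml_ll = cond_ll = np.inf
        return {
            "beta": beta, "b": b, "sigma2": sigma2, "rss": rss,
            "fitted": fitted, "resid_conditional": resid_c,
            "reml_loglik": reml_ll, "ml_loglik": ml_ll, "cond_loglik": cond_ll,
            "effective_df": edf, "A": A,
        }


# ---------------------------------------------------------------------------
# fitted-region container
# ---------------------------------------------------------------------------

@dataclass
class RegionFit:
    """One fitted region sub-model."""

    region: int
    beta_hat: np.ndarray
    b_hat: Mapping[tuple[int, int], np.ndarray]
    psi_hat: np.ndarray
    sigma2_hat: float
    reml_loglik: float
    ml_loglik: float
    cond_loglik: float
    effective_df: float
    converged: bool
    boundary: bool
    n_cells_used: int
    fixed_names: list[str]
    random_names: list[str]
    fitted: np.ndarray = field(repr=False, default=None)
    resid_conditional: np.ndarray = field(repr=False, default=None)
    district_ids: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_fixed(self) -> int:
        return len(self.beta_hat)

    @property
    def n_random(self) -> int:
        return self.psi_hat.shape[0]

    def b_matrix(self) -> np.ndarray:
        return np.stack([self.b_hat[d] for d in self.district_ids])


def _gamma_from_theta(theta: np.ndarray, Q: int) -> np.ndarray:
    """Log-Cholesky parameterization of Gamma = Psi / sigma2."""
    L = np.zeros((Q, Q))
    k = 0
    for i in range(Q):
        for j in range(i + 1):
            if i == j:
                L[i, j] = np.exp(theta[k])
            else:
                L[i, j] = theta[k]
            k += 1
    return L @ L.T


def fit_reml(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    district_codes: np.ndarray,
    region: int = 0,
    fixed_names: Sequence[str] | None = None,
    random_names: Sequence[str] | None = None,
    district_ids: Sequence[tuple[int, int]] | None = None,
    max_iter: int = 500,
) -> RegionFit:
    """Fit one region sub-model by REML.

    The variance ratio is profiled and searched on the log-Cholesky
    scale; ``Q = 1`` uses a bracketed scalar search, larger ``Q`` a
    quasi-Newton search from three deterministic starting points.  The
    boundary ``Psi = 0`` is always evaluated and adopted when it is at
    least as good, so degenerate truths give exact zero variance
    estimates.
    """
    n, P = X.shape
    Q = Z.shape[1]
    n_var = Q * (Q + 1) // 2 + 1
    if n < P + n_var + 1:
        raise FitError(
            f"too few rows (n={n}) for P={P} fixed effects and {n_var} variance parameters"
        )
    bm = BlockedModel(np.asarray(y, float), np.asarray(X, float), np.asarray(Z, float), district_codes)

    converged = True
    if Q == 1:
        def f(t: float) -> float:
            return bm.neg2_profiled_reml(np.array([[np.exp(t)]]))

        ts = np.linspace(-16.0, 12.0, 10)
        vals = [f(t) for t in ts]
        i = int(np.argmin(vals))
        lo, hi = ts[max(0, i - 1)], ts[min(len(ts) - 1, i + 1)]
        res = optimize.minimize_scalar(
            f, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-10, "maxiter": max_iter},
        )
        converged = bool(res.success)
        gamma_best = np.array([[np.exp(res.x)]])
        f_best = res.fun
    else:
        def fv(theta: np.ndarray) -> float:
            return bm.neg2_profiled_reml(_gamma_from_theta(theta, Q))

        n_theta = Q * (Q + 1) // 2
        diag_pos = np.cumsum([1] + list(range(2, Q + 1))) - 1
        bounds = []
        k = 0
        for i in range(Q):
            for j in range(i + 1):
                bounds.append((-16.0, 12.0) if i == j else (-1e3, 1e3))
                k += 1
        starts = []
        for d0 in (-1.0, -4.0, 1.0):
            t0 = np.zeros(n_theta)
            t0[diag_pos] = d0
            starts.append(t0)
        best = None
        any_success = False
        for t0 in starts:
            res = optimize.minimize(
                fv, t0, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": max_iter, "ftol": 1e-13, "gtol": 1e-10},
            )
            any_success = any_success or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        converged = any_success
        gamma_best = _gamma_from_theta(best.x, Q)
        f_best = best.fun

    f_zero = bm.neg2_profiled_reml(np.zeros((Q, Q)))
    boundary = False
    if f_zero <= f_best + 1e-9:
        gamma_best = np.zeros((Q, Q))
        boundary = True
    sol = bm.solve(gamma_best)
    psi_hat = sol["sigma2"] * gamma_best
    boundary = boundary or bool(np.all(np.linalg.eigvalsh(psi_hat + psi_hat.T) / 2 <= 1e-8 * max(sol["sigma2"], 1e-300)))
    if not converged:
        logger.warning("REML fit for region %s did not report convergence", region)

    ids = list(district_ids) if district_ids is not None else [
        (region, d + 1) for d in range(bm.D)
    ]
    b_hat = {ids[d]: sol["b"][d] for d in range(bm.D)}
    return RegionFit(
        region=region,
        beta_hat=sol["beta"],
        b_hat=b_hat,
        psi_hat=psi_hat,
        sigma2_hat=sol["sigma2"],
        reml_loglik=sol["reml_loglik"],
        ml_loglik=sol["ml_loglik"],
        cond_loglik=sol["cond_loglik"],
        effective_df=sol["effective_df"],
        converged=converged,
        boundary=boundary,
        n_cells_used=n,
        fixed_names=list(fixed_names) if fixed_names is not None else [f"x{j}" for j in range(P)],
        random_names=list(random_names) if random_names is not None else [f"z{j}" for j in range(Q)],
        fitted=sol["fitted"],
        resid_conditional=sol["resid_conditional"],
        district_ids=ids,
    )


def fit_region_design(dm: DesignMatrices, region: int, **kw) -> RegionFit:
    if dm.y is None:
        raise FitError("cannot fit a national (response-free) design")
    return fit_reml(
        dm.y, dm.X, dm.Z, dm.district_codes, region=region,
        fixed_names=dm.columns, random_names=dm.random_columns,
        district_ids=dm.district_ids, **kw,
    )


def gls_blup(
    y: np.ndarray,
    X: np.ndarray,
    Z: np.ndarray,
    district_codes: np.ndarray,
    psi: np.ndarray | float,
    sigma2: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Explicit GLS fixed effects and BLUP random effects at known variances.

    Returns ``(beta_hat, b_hat)`` with ``b_hat`` of shape (D, Q).
    Requires ``sigma2 > 0`` so that V = Z Psi Z' + sigma2 I is
    invertible.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive for an invertible V")
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    bm = BlockedModel(np.asarray(y, float), np.asarray(X, float), np.asarray(Z, float), district_codes)
    sol = bm.solve(psi / sigma2)
    return sol["beta"], sol["b"]


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

@dataclass
class ModelComparison:
    """ANOVA (likelihood ratio) and penalized conditional-criterion record."""

    lr_stat: float | None
    df_diff: int | None
    p_value: float | None
    caic_small: float
    caic_large: float
    preferred: str
    penalty: str
    anova_error: str | None = None


def conditional_criterion(fit: RegionFit, n: int | None = None, penalty: str = "bic") -> float:
    """Conditional information criterion with a BIC-strength penalty.

    ``-2 * conditional log-likelihood + penalty * effective_df`` where the
    effective degrees of freedom are the trace of the hat matrix mapping
    the response to the fitted values ``X beta_hat + Z b_hat`` and the
    conditional log-likelihood is the Gaussian log-density of the
    response given the predicted random effects.  ``penalty='bic'`` uses
    ``log(n)``; ``penalty='aic'`` the classical factor 2.
    """
    n = fit.n_cells_used if n is None else int(n)
    factor = np.log(n) if penalty == "bic" else 2.0
    return -2.0 * fit.cond_loglik + factor * fit.effective_df


def compare_models(
    fit_small: RegionFit,
    fit_large: RegionFit,
    n: int | None = None,
    penalty: str = "bic",
) -> ModelComparison:
    """Compare two fits of the same region data.

    The ANOVA branch is a likelihood-ratio test on ML log-likelihoods
    with a chi-square reference on the fixed-effect difference; it
    requires the smaller model's fixed effects to be nested in the
    larger's and both fits to use the same rows.  The penalized
    conditional criterion is computed regardless.
    """
    n = fit_small.n_cells_used if n is None else int(n)
    caic_s = conditional_criterion(fit_small, n, penalty)
    caic_l = conditional_criterion(fit_large, n, penalty)
    preferred = "small" if caic_s <= caic_l else "large"

    anova_error = None
    lr = df = p = None
    if fit_small.n_cells_used != fit_large.n_cells_used:
        anova_error = "fits use different numbers of rows"
    elif not set(fit_small.fixed_names) <= set(fit_large.fixed_names):
        anova_error = "fixed effects are not nested"
    else:
        df = len(fit_large.fixed_names) - len(fit_small.fixed_names)
        lr = max(0.0, 2.0 * (fit_large.ml_loglik - fit_small.ml_loglik))
        p = float(stats.chi2.sf(lr, df)) if df > 0 else (1.0 if lr == 0 else 0.0)
    return ModelComparison(
        lr_stat=lr, df_diff=df, p_value=p,
        caic_small=caic_s, caic_large=caic_l,
        preferred=preferred, penalty=penalty, anova_error=anova_error,
    )


def fit_summary_frame(fits: Mapping[int, RegionFit]) -> pd.DataFrame:
    """One row per region: variance components, convergence, criteria."""
    rows = []
    for region, fit in sorted(fits.items()):
        rows.append({
            "region": region,
            "n_cells_used": fit.n_cells_used,
            "sigma2_hat": fit.sigma2_hat,
            "psi_hat_00": float(fit.psi_hat[0, 0]),
            "reml_loglik": fit.reml_loglik,
            "ml_loglik": fit.ml_loglik,
            "effective_df": fit.effective_df,
            "converged": fit.converged,
            "boundary": fit.boundary,
        })
    return pd.DataFrame(rows)
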