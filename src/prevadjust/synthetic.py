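"""Synthetic national populations with informatively selected fund members.

The generator emulates the data situation of German health-insurance
claims research: a finite national population partitioned into
district × age-group × sex cells, an insurance fund whose members are a
non-random subset of every cell, and cell-level inpatient diagnosis
counts observed for both populations.

Generative scheme (per cell):

1. the national cell size ``N`` is drawn around a demographic profile;
2. a latent morbidity score ``s`` (age + sex + district + cell noise)
   drives the per-capita rates of the auxiliary diagnosis counts;
3. the true diseased count follows the linear mixed model: an expected
   count ``mu = x' beta + b_d + e`` built from the *realized* national
   auxiliary counts, a district random intercept ``b_d ~ N(0, psi)``
   and a cell error ``e ~ N(0, sigma2_r)``, realized binomially with
   matching mean;
4. fund membership is drawn per person at cell-level propensities on
   the logit scale: healthy citizens join with propensity
   ``expit(gamma_0 + demographic terms)``; diseased citizens and
   hospital-treated cases carry an additional morbidity offset.  Member
   auxiliary counts are binomial thinnings of the national counts at
   the morbid-class propensity, mirroring how a fund's hospital records
   are a subset of the national hospital census.

Because the diseased member count and the member auxiliary counts are
thinned at the *same* cell-level propensity, the linear relation between
outcome and auxiliary counts transfers from the national to the member
population: the equality of conditional expectations that identifies the
bias adjustment holds by construction.  Setting
``informative_beyond_aux=True`` adds a dependence of the diseased-class
propensity on the residual morbidity ``e`` — information the auxiliary
data does not carry — which breaks that equality and lets tests probe
the method's failure mode.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .datamodel import (
    AGE_GROUPS_DEFAULT,
    MEMBER_AUX_PREFIX,
    NATIONAL_AUX_PREFIX,
    CellTable,
    ModelDesign,
    build_cell_grid,
    child_rng,
    logger,
)


class ScenarioError(ValueError):
    """The scenario parameters are inconsistent or degenerate."""


#: Auxiliary columns that truly drive the disease in the default scenario
#: (ICD-3-style codes; diabetes-adjacent comorbidities).
PLANTED_LABELS: tuple[str, ...] = ("E11_secondary", "I10_secondary", "E78_secondary")

_FILLER_LABELS: tuple[str, ...] = (
    "E87_secondary", "G81_secondary", "I48_main", "I63_main", "K29_secondary",
    "M16_main", "T81_secondary", "J18_main", "J44_secondary", "F03_secondary",
    "I25_secondary", "I50_main", "N18_secondary", "K57_main", "M17_main",
    "S72_main", "A41_main", "C34_main", "C18_main", "K80_main",
    "J15_main", "I21_main", "R55_main", "N39_secondary", "E86_secondary",
    "D64_secondary", "F05_secondary",
)


@dataclass(frozen=True)
class Dims:
    """Hierarchy dimensions: regions, districts per region, age groups."""

    districts_per_region: tuple[int, ...]
    n_age_groups: int = 4

    @property
    def n_regions(self) -> int:
        return len(self.districts_per_region)

    @property
    def age_labels(self) -> tuple[str, ...]:
        if self.n_age_groups <= len(AGE_GROUPS_DEFAULT):
            return AGE_GROUPS_DEFAULT[: self.n_age_groups]
        return tuple(f"A{i + 1}" for i in range(self.n_age_groups))

    @property
    def n_cells(self) -> int:
        return 2 * self.n_age_groups * sum(self.districts_per_region)


@dataclass(frozen=True)
class AuxModel:
    """Per-column generator of national auxiliary diagnosis counts.

    Column ``j`` is Poisson with mean
    ``N * rates[j] * exp(loadings[j] * s + idio_sd * nu)`` where ``s`` is
    the cell's latent morbidity score and ``nu`` a per-cell,
    per-column standard normal.  Columns with zero loading are morbidity
    -unrelated noise candidates for the variable-selection stage.
    """

    labels: tuple[str, ...]
    rates: tuple[float, ...]
    loadings: tuple[float, ...]
    idio_sd: float = 0.40

    def validate(self) -> None:
        if not (len(self.labels) == len(self.rates) == len(self.loadings)):
            raise ScenarioError("aux_model labels/rates/loadings lengths differ")
        if len(set(self.labels)) != len(self.labels):
            raise ScenarioError("duplicate auxiliary labels")
        if any(r <= 0 for r in self.rates):
            raise ScenarioError("auxiliary rates must be positive")
        if self.idio_sd < 0:
            raise ScenarioError("idio_sd must be nonnegative")


@dataclass(frozen=True)
class Selectivity:
    """Membership-propensity coefficients on the logit scale.

    ``intercept`` sets the baseline member share; ``age`` and
    ``sex_male`` add demographic selectivity; ``morbidity`` is the extra
    offset of diseased citizens and hospital-treated cases (the
    adjustable, auxiliary-explainable selectivity); ``residual`` is a
    further offset of *diseased* citizens beyond hospital-treated ones,
    active only when the scenario sets ``informative_beyond_aux`` —
    membership information about the disease that the auxiliary data
    cannot carry, hence the switch that breaks the identifying
    assumption.
    """

    intercept: float = float(logit(0.35))
    age: float = 0.12
    sex_male: float = -0.05
    morbidity: float = 0.70
    residual: float = 0.30

    def is_null(self) -> bool:
        return self.age == 0 and self.sex_male == 0 and self.morbidity == 0


@dataclass(frozen=True)
class ProxySpec:
    """Optional hospital-observed proxy endpoint for cross-validation.

    The national proxy count is a linear combination of other auxiliary
    columns, either exact (``noise='exact'``) or Poisson around that
    mean.  The member analogue is the matching combination of member
    columns (exact mode) or a binomial thinning at the morbid-class
    propensity shifted by ``distortion`` on the logit scale; a nonzero
    distortion plants a member/national relation the benchmark
    extrapolation cannot recover.
    """

    weights: Mapping[str, float]
    label: str = "proxy_main"
    noise: str = "poisson"  # 'poisson' | 'exact'
    distortion: float = 0.0


@dataclass(frozen=True)
class SelectionScenario:
    """Full generative truth for one synthetic study."""

    dims: Dims
    beta_true: tuple[Mapping[str, float], ...]  # one mapping per region
    aux_model: AuxModel
    selectivity: Selectivity = Selectivity()
    psi_true: float = 900.0          # district random-intercept variance (counts^2)
    sigma2_true: tuple[float, ...] = (625.0,)  # per-region cell error variance
    informative_beyond_aux: bool = False
    binomial_outcome: bool = True
    mean_cell_size: float = 20000.0
    size_sd_log: float = 0.35
    min_cell_size: int = 50
    age_size_mult: tuple[float, ...] = (1.15, 1.05, 1.05, 0.75)
    age_morbidity: tuple[float, ...] = (-0.5, -0.2, 0.2, 0.5)
    sex_morbidity: float = 0.10
    district_morbidity_sd: float = 0.15
    cell_morbidity_sd: float = 0.35
    proxy: ProxySpec | None = None
    noise_seed: int = 0

    def sigma2_by_region(self) -> np.ndarray:
        s = self.sigma2_true
        if np.isscalar(s):
            s = (float(s),) * self.dims.n_regions
        if len(s) == 1:
            s = tuple(s) * self.dims.n_regions
        if len(s) != self.dims.n_regions:
            raise ScenarioError("sigma2_true length must be 1 or n_regions")
        return np.asarray(s, dtype=float)

    def beta_by_region(self) -> tuple[Mapping[str, float], ...]:
        b = self.beta_true
        if isinstance(b, Mapping):
            b = (b,) * self.dims.n_regions
        if len(b) == 1:
            b = tuple(b) * self.dims.n_regions
        if len(b) != self.dims.n_regions:
            raise ScenarioError("beta_true must have 1 or n_regions entries")
        return tuple(b)

    def validate(self) -> None:
        if self.dims.n_regions < 1 or min(self.dims.districts_per_region) < 1:
            raise ScenarioError("need at least one region and district")
        if self.dims.n_age_groups < 1:
            raise ScenarioError("need at least one age group")
        self.aux_model.validate()
        if self.psi_true < 0:
            raise ScenarioError("psi_true must be nonnegative")
        if np.any(self.sigma2_by_region() < 0):
            raise ScenarioError("sigma2_true must be nonnegative")
        if self.mean_cell_size <= 0:
            raise ScenarioError("mean_cell_size must be positive")
        if len(self.age_size_mult) < self.dims.n_age_groups:
            raise ScenarioError("age_size_mult shorter than n_age_groups")
        if len(self.age_morbidity) < self.dims.n_age_groups:
            raise ScenarioError("age_morbidity shorter than n_age_groups")
        labels = set(self.aux_model.labels)
        for bmap in self.beta_by_region():
            unknown = set(bmap) - labels
            if unknown:
                raise ScenarioError(f"beta_true references unknown labels {sorted(unknown)}")
        if self.proxy is not None:
            if self.proxy.noise not in ("poisson", "exact"):
                raise ScenarioError("proxy.noise must be 'poisson' or 'exact'")
            unknown = set(self.proxy.weights) - labels
            if unknown:
                raise ScenarioError(f"proxy weights reference unknown labels {sorted(unknown)}")
            if any(w < 0 for w in self.proxy.weights.values()):
                raise ScenarioError("proxy weights must be nonnegative")
            if self.proxy.label in labels:
                raise ScenarioError("proxy label collides with an auxiliary label")


@dataclass
class SyntheticTruth:
    """Generative quantities hidden from the estimator, kept for scoring."""

    beta: tuple[Mapping[str, float], ...]
    psi: float
    sigma2: np.ndarray
    b: pd.DataFrame                  # region, district, b
    s: np.ndarray                    # latent morbidity per cell
    e: np.ndarray                    # cell error per cell
    p_healthy: np.ndarray
    p_sick: np.ndarray
    p_morbid: np.ndarray
    seed: int


@dataclass
class SyntheticPopulation:
    table: CellTable
    truth: SyntheticTruth

    @property
    def national_prevalence(self) -> float:
        f = self.table.frame
        return float(f["y_national_true"].sum() / f["n_national"].sum())

    @property
    def member_prevalence(self) -> float:
        f = self.table.frame
        return float(f["y_member"].sum() / f["n_member"].sum())


def default_aux_model(
    n_candidates: int = 30,
    planted_rates: Sequence[float] = (0.10, 0.09, 0.08),
    planted_loading: float = 0.70,
    idio_sd: float = 0.70,
) -> AuxModel:
    """Candidate pool: three morbidity-linked planted columns plus noise.

    Filler rates cycle through plausible per-capita inpatient case
    frequencies (2-6.5%); fillers carry no morbidity loading, so their
    correlation with the disease is pure noise.
    """
    if n_candidates < len(PLANTED_LABELS):
        raise ScenarioError("need at least the planted candidates")
    n_fill = n_candidates - len(PLANTED_LABELS)
    fillers = [_FILLER_LABELS[i % len(_FILLER_LABELS)] for i in range(n_fill)]
    # de-duplicate cycled labels if more than the filler pool
    labels = list(PLANTED_LABELS)
    for i, lab in enumerate(fillers):
        labels.append(lab if lab not in labels else f"{lab}_{i}")
    rates = list(planted_rates) + [0.02 + 0.005 * (i % 10) for i in range(n_fill)]
    loadings = [planted_loading] * len(PLANTED_LABELS) + [0.0] * n_fill
    return AuxModel(tuple(labels), tuple(rates), tuple(loadings), idio_sd)


def default_scenario(
    districts_per_region: Sequence[int] = (10, 10),
    n_age_groups: int = 4,
    n_candidates: int = 30,
    seed: int = 0,
    **overrides,
) -> SelectionScenario:
    """The package's reference study conditions.

    Two model regions of 10 districts each, four age groups and both
    sexes (320 cells of roughly 15,000-25,000 citizens, the order of
    magnitude of real German district/age/sex cells), a disease of ~8%
    national prevalence driven by three comorbidity diagnoses, and a
    fund covering roughly a third of the population whose diseased and
    hospital-treated citizens are clearly over-represented (member
    prevalence about 40% above national — the planted selectivity the
    adjustment has to remove).
    """
    dims = Dims(tuple(int(d) for d in districts_per_region), n_age_groups)
    aux = overrides.pop("aux_model", default_aux_model(n_candidates))
    beta = overrides.pop(
        "beta_true",
        ({"E11_secondary": 0.25, "I10_secondary": 0.25, "E78_secondary": 0.25},),
    )
    if isinstance(beta, Mapping):
        beta = (beta,)
    scn = SelectionScenario(
        dims=dims,
        beta_true=tuple(beta),
        aux_model=aux,
        sigma2_true=overrides.pop("sigma2_true", (625.0,)),
        noise_seed=overrides.pop("noise_seed", seed),
        **overrides,
    )
    scn.validate()
    return scn


def null_selectivity_scenario(**kw) -> SelectionScenario:
    """Members are a simple random subsample of every cell."""
    sel = Selectivity(age=0.0, sex_male=0.0, morbidity=0.0, residual=0.0)
    return default_scenario(selectivity=sel, **kw)


def selection_snr_scenario(n_candidates: int = 30, **kw) -> SelectionScenario:
    """Conditions for the variable-selection recovery study.

    A moderate shared-morbidity loading and idiosyncratic spread under
    which each planted diagnosis carries a true absolute correlation of
    roughly 0.6-0.7 with the member prevalence, while the unrelated
    candidates stay well below.
    """
    aux = default_aux_model(n_candidates, planted_loading=0.55, idio_sd=0.50)
    return default_scenario(aux_model=aux, cell_morbidity_sd=0.25, **kw)


def default_design(aux_labels: Sequence[str] = PLANTED_LABELS) -> ModelDesign:
    """Reference fitted design: demographics plus the selected diagnoses."""
    return ModelDesign(
        fixed_effects=["intercept", "cell_size", "age_group", "sex", *aux_labels]
    )


def make_scenario_grid(
    base: SelectionScenario, axis: str, values: Sequence
) -> list[SelectionScenario]:
    """Vary one (possibly dotted) scenario parameter, all else equal.

    Seeds are offset deterministically so grid entries draw independent
    noise.
    """
    out = []
    for i, v in enumerate(values):
        scn = _replace_dotted(base, axis, v)
        scn = dataclasses.replace(scn, noise_seed=base.noise_seed + i)
        scn.validate()
        out.append(scn)
    return out


def _replace_dotted(obj, axis: str, value):
    head, _, rest = axis.partition(".")
    if not hasattr(obj, head):
        raise ScenarioError(f"unknown scenario axis '{axis}'")
    if rest:
        child = _replace_dotted(getattr(obj, head), rest, value)
        return dataclasses.replace(obj, **{head: child})
    return dataclasses.replace(obj, **{head: value})


def generate_population(
    scenario: SelectionScenario, seed: int | None = None
) -> SyntheticPopulation:
    """Draw one synthetic national population and its member subset.

    All randomness flows from one root seed through stage-labelled
    child generators over the canonical cell order, so identical
    ``(scenario, seed)`` pairs reproduce bit-for-bit.
    """
    scenario.validate()
    seed = int(scenario.noise_seed if seed is None else seed)
    dims = scenario.dims
    grid = build_cell_grid(dims.districts_per_region, dims.age_labels)
    n = len(grid)
    age_idx = ((grid["cell"].to_numpy() - 1) // 2).astype(int)
    male = ((grid["cell"].to_numpy() - 1) % 2).astype(int)
    region = grid["region"].to_numpy()
    dist_codes, dist_index = _district_codes(grid)
    n_districts = len(dist_index)

    # 1. national cell sizes
    rng = child_rng(seed, "size")
    mult = np.asarray(scenario.age_size_mult)[age_idx]
    N = np.round(
        scenario.mean_cell_size * mult * np.exp(rng.normal(0.0, scenario.size_sd_log, n))
    ).astype(np.int64)
    N = np.maximum(N, scenario.min_cell_size)
    if np.any(N <= 0):
        raise ScenarioError("generated an empty national cell")

    # 2. latent morbidity score
    rng = child_rng(seed, "morbidity")
    delta_d = rng.normal(0.0, scenario.district_morbidity_sd, n_districts)
    s = (
        np.asarray(scenario.age_morbidity)[age_idx]
        + scenario.sex_morbidity * male
        + delta_d[dist_codes]
        + rng.normal(0.0, scenario.cell_morbidity_sd, n)
    )

    # 3. national auxiliary counts
    rng = child_rng(seed, "aux")
    rates = np.asarray(scenario.aux_model.rates)
    loadings = np.asarray(scenario.aux_model.loadings)
    nu = rng.normal(0.0, 1.0, (n, len(rates)))
    lam = N[:, None] * rates[None, :] * np.exp(
        loadings[None, :] * s[:, None] + scenario.aux_model.idio_sd * nu
    )
    x_nat = rng.poisson(lam).astype(np.int64)

    # 4. outcome model: mu = x' beta + b_d + e
    rng = child_rng(seed, "outcome")
    b_d = rng.normal(0.0, np.sqrt(scenario.psi_true), n_districts)
    sigma2_r = scenario.sigma2_by_region()
    sigma_cell = np.sqrt(sigma2_r[region - 1])
    e = rng.normal(0.0, 1.0, n) * sigma_cell
    beta_maps = scenario.beta_by_region()
    labels = list(scenario.aux_model.labels)
    beta_mat = np.zeros((dims.n_regions, len(labels)))
    for r, bmap in enumerate(beta_maps):
        for lab, val in bmap.items():
            beta_mat[r, labels.index(lab)] = val
    mu = np.einsum("ij,ij->i", x_nat.astype(float), beta_mat[region - 1]) + b_d[dist_codes] + e
    pi = np.clip(mu, 0.0, N.astype(float)) / N
    if scenario.binomial_outcome:
        y_true = rng.binomial(N, pi)
    else:
        y_true = np.round(np.clip(mu, 0.0, N.astype(float))).astype(np.int64)

    # 5. membership propensities
    sel = scenario.selectivity
    age_c = age_idx - (dims.n_age_groups - 1) / 2.0
    lp_h = sel.intercept + sel.age * age_c + sel.sex_male * male
    lp_m = lp_h + sel.morbidity           # hospital-treated / morbid class
    lp_s = lp_m + (sel.residual if scenario.informative_beyond_aux else 0.0)
    p_h = expit(lp_h)
    p_aux = expit(np.broadcast_to(lp_m, (n,)).astype(float))
    p_s = expit(np.broadcast_to(lp_s, (n,)).astype(float))
    eps = 1e-9
    for p in (p_h, p_aux, p_s):
        if np.any(p <= eps) or np.any(p >= 1 - eps):
            raise ScenarioError("membership propensities are degenerate (outside (0,1))")

    # 6. member subset by person-level thinning
    rng = child_rng(seed, "membership")
    y_mem = rng.binomial(y_true, p_s)
    n_mem = y_mem + rng.binomial(N - y_true, p_h)
    x_mem = rng.binomial(x_nat, p_aux[:, None])

    frame = grid.copy()
    frame["n_national"] = N
    frame["n_member"] = n_mem
    frame["y_member"] = y_mem
    frame["y_national_true"] = y_true
    aux_labels = list(labels)
    for j, lab in enumerate(labels):
        frame[MEMBER_AUX_PREFIX + lab] = x_mem[:, j]
        frame[NATIONAL_AUX_PREFIX + lab] = x_nat[:, j]

    # 7. optional proxy endpoint
    if scenario.proxy is not None:
        rng = child_rng(seed, "proxy")
        px = scenario.proxy
        w = np.array([px.weights.get(lab, 0.0) for lab in labels])
        base_n = x_nat.astype(float) @ w
        if px.noise == "exact":
            prox_n = base_n
            prox_m = x_mem.astype(float) @ w
        else:
            prox_n = rng.poisson(base_n).astype(np.int64)
            p_prox = expit(logit(p_aux) + px.distortion)
            prox_m = rng.binomial(prox_n, p_prox)
        frame[MEMBER_AUX_PREFIX + px.label] = prox_m
        frame[NATIONAL_AUX_PREFIX + px.label] = prox_n
        aux_labels.append(px.label)

    table = CellTable(frame, aux_labels=aux_labels, age_groups=dims.age_labels)
    truth = SyntheticTruth(
        beta=beta_maps,
        psi=float(scenario.psi_true),
        sigma2=sigma2_r,
        b=pd.DataFrame(
            {"region": [r for r, _ in dist_index],
             "district": [d for _, d in dist_index],
             "b": b_d}
        ),
        s=s, e=e, p_healthy=np.broadcast_to(p_h, (n,)).astype(float),
        p_sick=p_s, p_morbid=p_aux, seed=seed,
    )
    logger.info(
        "generated population: %d cells, N=%d, member share %.3f, "
        "national prevalence %.4f, member prevalence %.4f (seed %d)",
        n, int(N.sum()), float(n_mem.sum() / N.sum()),
        float(y_true.sum() / N.sum()), float(y_mem.sum() / max(n_mem.sum(), 1)), seed,
    )
    return SyntheticPopulation(table, truth)


def _district_codes(grid: pd.DataFrame) -> tuple[np.ndarray, list[tuple[int, int]]]:
    keys = list(zip(grid["region"].tolist(), grid["district"].tolist()))
    index: list[tuple[int, int]] = []
    seen: dict[tuple[int, int], int] = {}
    codes = np.empty(len(keys), dtype=int)
    for i, k in enumerate(keys):
        if k not in seen:
            seen[k] = len(index)
            index.append(k)
        codes[i] = seen[k]
    return codes, index


# -- configuration hook ----------------------------------------------------

def scenario_from_config(cfg: Mapping) -> SelectionScenario:
    """Build a scenario from the ``scenario`` config section."""
    cfg = dict(cfg)
    dpr = cfg.pop("districts_per_region", (10, 10))
    if isinstance(dpr, int):
        dpr = (dpr,) * int(cfg.pop("n_regions", 2))
    else:
        cfg.pop("n_regions", None)
    sel = cfg.pop("selectivity", None)
    if isinstance(sel, Mapping):
        cfg["selectivity"] = Selectivity(**sel)
    proxy = cfg.pop("proxy", None)
    if isinstance(proxy, Mapping):
        cfg["proxy"] = ProxySpec(**proxy)
    n_candidates = cfg.pop("n_candidates", 30)
    return default_scenario(districts_per_region=dpr, n_candidates=n_candidates, **cfg)
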