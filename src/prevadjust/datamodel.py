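"""Cell-level data model, CSV interchange, configuration and logging.

The estimation unit throughout the package is the *cell*: a cross of
administrative district, age group and sex.  Cells are organised in a
three-level hierarchy — regions (where model coefficients vary
systematically), districts (where random effects vary), and cells (where
residual variation lives).  A cell table holds, per cell, the national
population size, the insurance-fund member count, the diseased member
count, and two aligned blocks of auxiliary inpatient-diagnosis
frequencies: one observed in the member population, one in the national
population.  The auxiliary blocks must carry identical column labels,
since the member-fitted model is later evaluated on the national columns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("prevadjust")

#: Default age-group labels; bands I: <=34, II: 35-49, III: 50-69, IV: >=70.
AGE_GROUPS_DEFAULT: tuple[str, ...] = ("I", "II", "III", "IV")
SEXES: tuple[str, str] = ("female", "male")

#: CSV column-name prefixes for the two aligned auxiliary blocks.
MEMBER_AUX_PREFIX = "aux_member__"
NATIONAL_AUX_PREFIX = "aux_national__"

INDEX_COLUMNS = ["region", "district", "cell", "age_group", "sex"]
COUNT_COLUMNS = ["n_national", "n_member", "y_member"]


class SchemaError(ValueError):
    """A required column is missing or mislabelled."""


class ValidationError(ValueError):
    """A cell record violates a structural invariant."""


@dataclass(frozen=True)
class HierarchyIndex:
    """Position of one cell in the region/district/cell hierarchy."""

    region: int
    district: int
    cell: int
    age_group: str
    sex: str


@dataclass
class CellRecord:
    """One population cell with member and national counts and covariates."""

    index: HierarchyIndex
    n_national: int
    n_member: int
    y_member: int
    x_national: np.ndarray
    x_member: np.ndarray
    y_national_true: int | None = None


@dataclass
class ModelDesign:
    """Declarative model specification.

    ``fixed_effects`` lists column tokens in design order.  Recognised
    tokens: ``intercept``, ``cell_size`` (member count on the member
    design, national count on the national design), ``age_group``
    (expands to indicator columns for all but the first age group),
    ``sex`` (male indicator), and any auxiliary column label.
    ``random_effects`` lists the district-level random-effect columns
    (default: random intercept only).  ``region_partition`` optionally
    maps geographic region ids to coarser model regions so that sparse
    territories can be merged before fitting.
    """

    fixed_effects: Sequence[str]
    random_effects: Sequence[str] = ("intercept",)
    region_partition: Mapping[int, int] | None = None

    def model_region(self, region: int) -> int:
        if self.region_partition is None:
            return int(region)
        try:
            return int(self.region_partition[int(region)])
        except KeyError:
            raise SchemaError(f"region {region} missing from region_partition")

    def validate(self) -> None:
        if len(self.fixed_effects) == 0:
            raise SchemaError("fixed_effects must not be empty")
        if len(self.random_effects) < 1:
            raise SchemaError("at least one random-effect column is required")
        allowed = set(self.fixed_effects) | {"intercept"}
        extra = [c for c in self.random_effects if c not in allowed]
        if extra:
            raise SchemaError(
                f"random effects {extra} are not in fixed_effects/intercept"
            )
        if len(set(self.fixed_effects)) != len(self.fixed_effects):
            raise SchemaError("duplicate fixed-effect tokens")


def build_cell_grid(
    districts_per_region: Sequence[int],
    age_groups: Sequence[str] = AGE_GROUPS_DEFAULT,
) -> pd.DataFrame:
    """Enumerate the complete dense cell grid for a hierarchy.

    Returns one row per (region, district, age group, sex) in canonical
    order with the integer cell id ``(age_index * 2 + sex_index + 1)``.
    """
    rows = []
    for r, n_d in enumerate(districts_per_region, start=1):
        for d in range(1, int(n_d) + 1):
            for a, age in enumerate(age_groups):
                for s, sex in enumerate(SEXES):
                    rows.append((r, d, a * 2 + s + 1, age, sex))
    return pd.DataFrame(rows, columns=INDEX_COLUMNS)


class CellTable:
    """A dense cell grid with counts and aligned auxiliary blocks.

    Wraps a :class:`pandas.DataFrame` whose rows follow the canonical
    hierarchy order.  Auxiliary columns are stored with the
    ``aux_member__``/``aux_national__`` prefixes; ``aux_labels`` lists
    the shared bare labels.
    """

    def __init__(
        self,
        frame: pd.DataFrame,
        aux_labels: Sequence[str] | None = None,
        age_groups: Sequence[str] | None = None,
        validate: bool = True,
    ):
        frame = frame.reset_index(drop=True)
        if aux_labels is None:
            aux_labels = [
                c[len(MEMBER_AUX_PREFIX):]
                for c in frame.columns
                if c.startswith(MEMBER_AUX_PREFIX)
            ]
        self.aux_labels = list(aux_labels)
        if age_groups is None:
            order = frame["age_group"].drop_duplicates().tolist() if "age_group" in frame else list(AGE_GROUPS_DEFAULT)
            age_groups = order
        self.age_groups = list(age_groups)
        self.frame = frame.sort_values(INDEX_COLUMNS[:3], kind="stable").reset_index(drop=True)
        if validate:
            self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def regions(self) -> np.ndarray:
        return np.unique(self.frame["region"].to_numpy())

    def districts(self, region: int) -> np.ndarray:
        sub = self.frame.loc[self.frame["region"] == region, "district"]
        return np.unique(sub.to_numpy())

    @property
    def n_cells_per_district(self) -> int:
        return 2 * len(self.age_groups)

    @property
    def has_truth(self) -> bool:
        return "y_national_true" in self.frame.columns

    def member_aux(self, label: str) -> pd.Series:
        return self.frame[MEMBER_AUX_PREFIX + label]

    def national_aux(self, label: str) -> pd.Series:
        return self.frame[NATIONAL_AUX_PREFIX + label]

    def region_frame(self, region: int) -> pd.DataFrame:
        return self.frame[self.frame["region"] == region]

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        if not isinstance(other, CellTable):
            return NotImplemented
        return self.aux_labels == other.aux_labels and self.frame.equals(other.frame)

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        f = self.frame
        for col in INDEX_COLUMNS + COUNT_COLUMNS:
            if col not in f.columns:
                raise SchemaError(f"required column '{col}' is missing")
        for label in self.aux_labels:
            for prefix in (MEMBER_AUX_PREFIX, NATIONAL_AUX_PREFIX):
                if prefix + label not in f.columns:
                    raise SchemaError(f"auxiliary column '{prefix + label}' is missing")

        dup = f.duplicated(subset=INDEX_COLUMNS[:3])
        if dup.any():
            idx = f.loc[dup, INDEX_COLUMNS[:3]].iloc[0].tolist()
            raise ValidationError(f"duplicate cell index {tuple(idx)}")

        C = self.n_cells_per_district
        counts = f.groupby(["region", "district"], sort=False).size()
        bad = counts[counts != C]
        if len(bad):
            raise ValidationError(
                f"district {bad.index[0]} has {bad.iloc[0]} cells, expected {C}"
            )
        cells = np.sort(f["cell"].unique())
        if not np.array_equal(cells, np.arange(1, C + 1)):
            raise ValidationError(f"cell ids must be 1..{C}, got {cells.tolist()}")
        # cell id must map bijectively to (age_group, sex)
        pairs = f.drop_duplicates(subset=["cell"])[["cell", "age_group", "sex"]]
        if len(f.drop_duplicates(subset=["cell", "age_group", "sex"])) != C or len(pairs) != C:
            raise ValidationError("cell id does not map bijectively to (age_group, sex)")

        self._check_counts(f)

    def _check_counts(self, f: pd.DataFrame) -> None:
        def _offender(mask: pd.Series) -> tuple:
            row = f.loc[mask, INDEX_COLUMNS[:3]].iloc[0]
            return tuple(int(v) for v in row)

        for col in COUNT_COLUMNS:
            if (f[col] < 0).any():
                raise ValidationError(
                    f"negative {col} at cell {_offender(f[col] < 0)}"
                )
        if (f["n_member"] > f["n_national"]).any():
            raise ValidationError(
                "n_member > n_national at cell "
                f"{_offender(f['n_member'] > f['n_national'])}"
            )
        if (f["y_member"] > f["n_member"]).any():
            raise ValidationError(
                "y_member > n_member at cell "
                f"{_offender(f['y_member'] > f['n_member'])}"
            )
        if "y_national_true" in f.columns:
            y = f["y_national_true"]
            if (y > f["n_national"]).any():
                raise ValidationError(
                    "y_national_true > n_national at cell "
                    f"{_offender(y > f['n_national'])}"
                )
            if (y < f["y_member"]).any():
                raise ValidationError(
                    "y_national_true < y_member at cell "
                    f"{_offender(y < f['y_member'])}"
                )
        for label in self.aux_labels:
            m = f[MEMBER_AUX_PREFIX + label]
            n = f[NATIONAL_AUX_PREFIX + label]
            if (m < 0).any() or (n < 0).any():
                raise ValidationError(f"negative auxiliary counts in '{label}'")
            if (m > n + 1e-9).any():
                raise ValidationError(
                    f"member auxiliary exceeds national in '{label}' at cell "
                    f"{_offender(m > n + 1e-9)}"
                )

    # -- record view -------------------------------------------------------
    def to_records(self) -> Iterator[CellRecord]:
        mem_cols = [MEMBER_AUX_PREFIX + l for l in self.aux_labels]
        nat_cols = [NATIONAL_AUX_PREFIX + l for l in self.aux_labels]
        for _, row in self.frame.iterrows():
            idx = HierarchyIndex(
                int(row["region"]), int(row["district"]), int(row["cell"]),
                str(row["age_group"]), str(row["sex"]),
            )
            yield CellRecord(
                index=idx,
                n_national=int(row["n_national"]),
                n_member=int(row["n_member"]),
                y_member=int(row["y_member"]),
                x_national=row[nat_cols].to_numpy(dtype=float),
                x_member=row[mem_cols].to_numpy(dtype=float),
                y_national_true=(
                    int(row["y_national_true"])
                    if "y_national_true" in row.index and pd.notna(row["y_national_true"])
                    else None
                ),
            )


def read_cell_table(path: str | Path, schema: Mapping[str, str] | None = None) -> CellTable:
    """Read a CSV cell table.

    ``schema`` optionally maps file column names to the canonical names;
    unmapped columns are taken verbatim.  The table must contain the
    index and count columns plus paired ``aux_member__``/
    ``aux_national__`` auxiliary columns.
    """
    frame = pd.read_csv(path)
    if schema:
        frame = frame.rename(columns=dict(schema))
    missing = [c for c in INDEX_COLUMNS + COUNT_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    mem = {c[len(MEMBER_AUX_PREFIX):] for c in frame.columns if c.startswith(MEMBER_AUX_PREFIX)}
    nat = {c[len(NATIONAL_AUX_PREFIX):] for c in frame.columns if c.startswith(NATIONAL_AUX_PREFIX)}
    if mem != nat:
        raise SchemaError(
            f"member/national auxiliary labels differ: {sorted(mem ^ nat)}"
        )
    table = CellTable(frame, aux_labels=sorted(mem))
    logger.info(
        "read cell table %s: %d rows, %d regions, %d auxiliary columns",
        path, len(table), len(table.regions), len(table.aux_labels),
    )
    return table


def write_cell_table(table: CellTable, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.frame.to_csv(path, index=False)
    logger.info("wrote cell table %s: %d rows", path, len(table))


def write_prevalence_table(ptable, path: str | Path) -> dict[str, Path]:
    """Write per-cell predictions and one companion file per aggregate level.

    ``path`` is used as a stem: ``<stem>_cells.csv``, ``<stem>_district.csv``
    etc.  Returns the mapping of level name to written path.
    """
    stem = Path(path)
    stem.parent.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    p = stem.with_name(stem.name + "_cells.csv")
    ptable.cells.to_csv(p, index=False)
    written["cells"] = p
    for level, agg in ptable.aggregates.items():
        p = stem.with_name(f"{stem.name}_{level}.csv")
        agg.to_csv(p, index=False)
        written[level] = p
    logger.info("wrote prevalence tables %s (%s)", stem, ", ".join(written))
    return written


def read_prevalence_cells(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# -- configuration ---------------------------------------------------------

def load_config(path: str | Path) -> dict:
    """Load the YAML run configuration (nested key-value sections)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError("config file must contain a mapping at top level")
    return cfg


def save_config(cfg: Mapping, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=False)


def config_hash(cfg: Mapping) -> str:
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# -- deterministic seed splitting -----------------------------------------

def child_seed(seed: int, *keys) -> int:
    """Derive a deterministic child seed from a root seed and a key path.

    String keys are hashed with CRC-32 so the split is stable across
    processes and platforms; the result fits in 31 bits.
    """
    ints = [int(seed)]
    for k in keys:
        if isinstance(k, (int, np.integer)):
            ints.append(int(k) & 0xFFFFFFFF)
        else:
            ints.append(zlib.crc32(str(k).encode()))
    ss = np.random.SeedSequence(ints)
    return int(ss.generate_state(1)[0] % (2**31))


def child_rng(seed: int, *keys) -> np.random.Generator:
    return np.random.default_rng(child_seed(seed, *keys))
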