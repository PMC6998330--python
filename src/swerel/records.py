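"""Long-format measurement tables for muscle shear-wave elastography.

The canonical exchange format is a UTF-8 CSV with one row per replicate
measurement and the mandatory header::

    subject_id,cohort,muscle,view,operator,replicate,shear_modulus_kpa

Each row records one shear-modulus reading (kPa) for a given subject,
cohort (training / validation / icu), muscle, probe view, operator and
replicate number (1-3).  A JSON sidecar next to the CSV carries a
free-text provenance tag.  Values below a physical plausibility floor
(default 0.1 kPa) are rejected: relaxed skeletal muscle stiffness sits
an order of magnitude above that.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import pandas as pd

logger = logging.getLogger(__name__)

COHORTS = ("training", "validation", "icu")
MUSCLES = ("diaphragm", "biceps_brachii", "rectus_femoris")
VIEWS = ("longitudinal", "transverse")
OPERATORS = (1, 2)
MAX_REPLICATES = 3

#: Mandatory CSV column order.
COLUMNS = [
    "subject_id",
    "cohort",
    "muscle",
    "view",
    "operator",
    "replicate",
    "shear_modulus_kpa",
]

#: Columns identifying one physical measurement (a replicate).
REPLICATE_KEY = ["subject_id", "muscle", "view", "operator", "replicate"]

#: Columns identifying one aggregated cell (triplicate mean).
CELL_KEY = ["subject_id", "muscle", "view", "operator"]

#: Values below this are physically implausible for relaxed muscle (kPa).
DEFAULT_FLOOR_KPA = 0.1


class ValidationError(ValueError):
    """A measurement table violates the schema or an invariant."""


@dataclass(frozen=True)
class MeasurementRecord:
    """One elastography measurement (a single replicate)."""

    subject_id: str
    cohort: str
    muscle: str
    view: str
    operator: int
    replicate: int
    shear_modulus_kpa: float

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValidationError(f"unknown cohort {self.cohort!r}")
        if self.muscle not in MUSCLES:
            raise ValidationError(f"unknown muscle {self.muscle!r}")
        if self.view not in VIEWS:
            raise ValidationError(f"unknown view {self.view!r}")
        if self.operator not in OPERATORS:
            raise ValidationError(f"operator must be 1 or 2, got {self.operator}")
        if not 1 <= self.replicate <= MAX_REPLICATES:
            raise ValidationError(f"replicate must be in 1..3, got {self.replicate}")
        if not self.shear_modulus_kpa > 0:
            raise ValidationError(
                f"shear_modulus_kpa must be positive, got {self.shear_modulus_kpa}"
            )


@dataclass
class MeasurementTable:
    """An ordered, validated collection of measurements.

    Wraps a :class:`pandas.DataFrame` in the canonical column order;
    ``provenance`` is a free-text source tag written to a JSON sidecar
    on export.
    """

    frame: pd.DataFrame
    provenance: str = ""
    floor_kpa: float = DEFAULT_FLOOR_KPA

    def __post_init__(self) -> None:
        self.frame = validate_frame(self.frame, floor_kpa=self.floor_kpa)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def records(self) -> Iterator[MeasurementRecord]:
        for row in self.frame.itertuples(index=False):
            yield MeasurementRecord(*row)

    @classmethod
    def from_records(
        cls, records: list[MeasurementRecord], provenance: str = ""
    ) -> "MeasurementTable":
        frame = pd.DataFrame([r.__dict__ for r in records], columns=COLUMNS)
        return cls(frame, provenance=provenance)


def validate_frame(
    frame: pd.DataFrame, floor_kpa: float = DEFAULT_FLOOR_KPA
) -> pd.DataFrame:
    """Validate a raw frame against the schema; return a normalised copy.

    Raises :class:`ValidationError` naming the offending column or the
    0-based row index of the first bad row.
    """
    missing = [c for c in COLUMNS if c not in frame.columns]
    if missing:
        raise ValidationError(f"missing column(s): {', '.join(missing)}")
    out = frame[COLUMNS].copy()
    out["subject_id"] = out["subject_id"].astype(str)
    for col, allowed in (
        ("cohort", COHORTS),
        ("muscle", MUSCLES),
        ("view", VIEWS),
    ):
        bad = ~out[col].isin(allowed)
        if bad.any():
            i = int(bad.idxmax())
            raise ValidationError(
                f"row {i}: invalid {col} {out.loc[i, col]!r} "
                f"(allowed: {', '.join(allowed)})"
            )
    for col, allowed_ints in (("operator", OPERATORS), ("replicate", (1, 2, 3))):
        vals = pd.to_numeric(out[col], errors="coerce")
        bad = ~vals.isin(allowed_ints)
        if bad.any():
            i = int(bad.idxmax())
            raise ValidationError(f"row {i}: invalid {col} {out.loc[i, col]!r}")
        out[col] = vals.astype(int)
    mu = pd.to_numeric(out["shear_modulus_kpa"], errors="coerce")
    bad = ~(mu >= floor_kpa)
    if bad.any():
        i = int(bad.idxmax())
        raise ValidationError(
            f"row {i}: shear_modulus_kpa {out.loc[i, 'shear_modulus_kpa']!r} "
            f"below plausibility floor {floor_kpa} kPa or non-numeric"
        )
    out["shear_modulus_kpa"] = mu.astype(float)
    dup = out.duplicated(subset=REPLICATE_KEY)
    if dup.any():
        i = int(dup.idxmax())
        raise ValidationError(
            f"row {i}: duplicate (subject, muscle, view, operator, replicate) key"
        )
    return out.reset_index(drop=True)


def read_measurements(
    path: str | Path, floor_kpa: float = DEFAULT_FLOOR_KPA
) -> MeasurementTable:
    """Read a long-format measurement CSV (plus optional JSON sidecar)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    provenance = ""
    sidecar = path.with_suffix(".provenance.json")
    if sidecar.exists():
        provenance = json.loads(sidecar.read_text()).get("provenance", "")
    return MeasurementTable(frame, provenance=provenance, floor_kpa=floor_kpa)


def write_measurements(table: MeasurementTable, path: str | Path) -> Path:
    """Write the table as CSV with a JSON provenance sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.frame.to_csv(path, index=False)
    sidecar = path.with_suffix(".provenance.json")
    sidecar.write_text(json.dumps({"provenance": table.provenance}))
    return path


def aggregate_triplicates(table: MeasurementTable) -> pd.DataFrame:
    """Mean shear modulus per (subject, muscle, view, operator) cell.

    Cells with fewer than three available replicates are still
    aggregated over what is present, with ``n_replicates`` recording the
    count; incomplete cells are reported through a logged warning.
    Returns a frame with columns ``subject_id, cohort, muscle, view,
    operator, mean_kpa, n_replicates``.
    """
    if len(table) == 0:
        raise ValidationError("cannot aggregate an empty table")
    grouped = (
        table.frame.groupby(CELL_KEY + ["cohort"], sort=True, observed=True)[
            "shear_modulus_kpa"
        ]
        .agg(mean_kpa="mean", n_replicates="size")
        .reset_index()
    )
    incomplete = int((grouped["n_replicates"] < MAX_REPLICATES).sum())
    if incomplete:
        logger.warning(
            "%d cell(s) aggregated from fewer than %d replicates",
            incomplete,
            MAX_REPLICATES,
        )
    cols = ["subject_id", "cohort", "muscle", "view", "operator", "mean_kpa", "n_replicates"]
    return grouped[cols]


def count_measurements(table: MeasurementTable, level: str = "replicate") -> int:
    """Number of measurements at ``replicate`` or ``aggregated`` level.

    The replicate level counts raw rows; the aggregated level counts
    distinct (subject, muscle, view, operator) cells.
    """
    if level == "replicate":
        return len(table)
    if level == "aggregated":
        if len(table) == 0:
            return 0
        return int(table.frame.groupby(CELL_KEY, observed=True).ngroups)
    raise ValueError(f"level must be 'replicate' or 'aggregated', got {level!r}")


def operator_matrix(
    table: MeasurementTable,
    muscle: str,
    view: str,
    level: str = "means",
):
    """Per-subject operator data for one muscle-view slice.

    ``level='means'`` returns ``(subject_ids, ndarray of shape (n, 2))``
    of triplicate means, dropping subjects without both operators
    (pairwise deletion, logged).  ``level='replicates'`` returns
    ``(subject_ids, ndarray of shape (n, 2, m))`` of raw replicates and
    requires a balanced design.
    """
    import numpy as np

    sub = table.frame[
        (table.frame["muscle"] == muscle) & (table.frame["view"] == view)
    ]
    if sub.empty:
        raise ValidationError(f"no measurements for {muscle}/{view}")
    if level == "means":
        wide = (
            sub.groupby(["subject_id", "operator"], observed=True)["shear_modulus_kpa"]
            .mean()
            .unstack("operator")
        )
        n_before = len(wide)
        wide = wide.dropna()
        dropped = n_before - len(wide)
        if dropped:
            logger.warning(
                "%s/%s: dropped %d subject(s) missing one operator", muscle, view, dropped
            )
        return list(wide.index), wide.to_numpy(dtype=float)
    if level == "replicates":
        cube = sub.set_index(["subject_id", "operator", "replicate"])[
            "shear_modulus_kpa"
        ].unstack(["operator", "replicate"])
        if cube.isna().any().any():
            raise ValidationError(
                f"{muscle}/{view}: replicate-level matrix requires a balanced design; "
                "use level='means' for data with missing replicates"
            )
        subjects = list(cube.index)
        ops = sorted({c[0] for c in cube.columns})
        reps = sorted({c[1] for c in cube.columns})
        arr = np.empty((len(subjects), len(ops), len(reps)))
        for j, op in enumerate(ops):
            for r, rep in enumerate(reps):
                arr[:, j, r] = cube[(op, rep)].to_numpy(dtype=float)
        return subjects, arr
    raise ValueError(f"level must be 'means' or 'replicates', got {level!r}")


def replicate_matrix(table: MeasurementTable, muscle: str, view: str, operator: int):
    """n-subjects x m-replicates matrix for one operator (intra-rater ANOVA)."""
    sub = table.frame[
        (table.frame["muscle"] == muscle)
        & (table.frame["view"] == view)
        & (table.frame["operator"] == operator)
    ]
    if sub.empty:
        raise ValidationError(f"no measurements for {muscle}/{view}/operator {operator}")
    wide = sub.set_index(["subject_id", "replicate"])["shear_modulus_kpa"].unstack(
        "replicate"
    )
    return list(wide.index), wide.to_numpy(dtype=float)
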