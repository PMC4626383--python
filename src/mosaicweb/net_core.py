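"""Data model for spatio-temporal bipartite interaction networks.

A sampling campaign on a mountain transect grid yields one small bipartite
plant x flower-visitor matrix per (altitude, month) cell.  This module holds
the matrix container (:class:`InteractionMatrix`), the grid-stamped unit
(:class:`NetworkUnit`), readers/writers for long- and wide-format delimited
text, the admission filter (at least two species on each side), and pooling
of units into cumulative networks per altitude, per month, or globally.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LONG_COLUMNS = ["unit", "altitude", "month", "plant", "insect", "count"]

Mode = Literal["binary", "counts"]


class RecordParseError(ValueError):
    """Raised when a long-format interaction file cannot be parsed."""


@dataclass(frozen=True)
class InteractionMatrix:
    """Labeled plants x insects nonnegative matrix (binary or counts).

    Rows are plant species, columns are flower-visitor (insect) species.
    Every listed species has at least one interaction: the container never
    carries an all-zero row or column.
    """

    plant_labels: tuple[str, ...]
    insect_labels: tuple[str, ...]
    values: np.ndarray
    mode: Mode = "binary"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n_p, n_a = values.shape
        if n_p < 1 or n_a < 1:
            raise ValueError("matrix needs at least one plant and one insect")
        if len(self.plant_labels) != n_p or len(self.insect_labels) != n_a:
            raise ValueError("label lengths do not match matrix shape")
        if len(set(self.plant_labels)) != n_p or len(set(self.insect_labels)) != n_a:
            raise ValueError("species labels must be unique within each side")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("entries must be finite and nonnegative")
        if self.mode == "binary" and not np.all(np.isin(values, (0.0, 1.0))):
            raise ValueError("binary mode admits only 0/1 entries")

    # -- convenience accessors -------------------------------------------------

    @property
    def n_plants(self) -> int:
        return self.values.shape[0]

    @property
    def n_insects(self) -> int:
        return self.values.shape[1]

    @property
    def n_links(self) -> int:
        """Number of realized links I (nonzero cells)."""
        return int(np.count_nonzero(self.values))

    @property
    def total_events(self) -> float:
        """Grand total T of the matrix (equals I in binary mode)."""
        return float(self.values.sum())

    def binarized(self) -> "InteractionMatrix":
        return InteractionMatrix(
            self.plant_labels, self.insect_labels,
            (self.values > 0).astype(float), "binary",
        )

    def transposed(self) -> "InteractionMatrix":
        return InteractionMatrix(
            self.insect_labels, self.plant_labels, self.values.T, self.mode
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.plant_labels), columns=list(self.insect_labels)
        )

    def validate_no_orphans(self) -> "InteractionMatrix":
        """Assert every listed species has >= 1 interaction (records path)."""
        if np.any(self.values.sum(axis=1) == 0) or np.any(self.values.sum(axis=0) == 0):
            raise ValueError("every listed species must have >= 1 interaction")
        return self

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, mode: Mode = "binary") -> "InteractionMatrix":
        return cls(
            tuple(str(i) for i in frame.index),
            tuple(str(c) for c in frame.columns),
            frame.to_numpy(dtype=float),
            mode,
        ).validate_no_orphans()

    @classmethod
    def from_links(
        cls,
        links: Iterable[tuple[str, str, float]],
        mode: Mode = "binary",
    ) -> "InteractionMatrix":
        """Build a matrix from (plant, insect, count) triples.

        Duplicate pairs are summed in counts mode and collapsed to 1 (with a
        warning) in binary mode.  Labels are sorted for deterministic output.
        """
        agg: dict[tuple[str, str], float] = {}
        dupes = 0
        for plant, insect, count in links:
            key = (plant, insect)
            if key in agg:
                dupes += 1
                agg[key] += count
            else:
                agg[key] = count
        if not agg:
            raise ValueError("cannot build a matrix from zero links")
        if mode == "binary" and dupes:
            logger.warning("collapsed %d duplicate link records to presence", dupes)
        plants = tuple(sorted({p for p, _ in agg}))
        insects = tuple(sorted({a for _, a in agg}))
        values = np.zeros((len(plants), len(insects)))
        p_idx = {p: i for i, p in enumerate(plants)}
        a_idx = {a: j for j, a in enumerate(insects)}
        for (plant, insect), count in agg.items():
            values[p_idx[plant], a_idx[insect]] = count
        if mode == "binary":
            values = (values > 0).astype(float)
        return cls(plants, insects, values, mode).validate_no_orphans()


@dataclass(frozen=True)
class NetworkUnit:
    """An interaction matrix stamped with its grid cell.

    altitude is in meters above sea level, month_index is 0-based on the
    campaign calendar, precipitation is the mean monthly total in mm.
    """

    unit_id: str
    altitude: int
    month_index: int
    matrix: InteractionMatrix
    month_label: str = ""
    precipitation: float = float("nan")

    def __post_init__(self) -> None:
        if self.month_index < 0:
            raise ValueError("month_index must be >= 0")
        if not np.isnan(self.precipitation) and self.precipitation < 0:
            raise ValueError("precipitation must be >= 0")


# ---------------------------------------------------------------------------
# Admission filter
# ---------------------------------------------------------------------------

def admit_unit(unit: NetworkUnit) -> bool:
    """True iff the unit has >= 2 plant and >= 2 insect species (M >= 4).

    Smaller matrices carry no pairwise structure and are excluded from the
    metric and inference stages (they remain in storage).
    """
    return unit.matrix.n_plants >= 2 and unit.matrix.n_insects >= 2


def admitted(units: Sequence[NetworkUnit]) -> list[NetworkUnit]:
    """Filter a collection through :func:`admit_unit`, preserving order."""
    kept = [u for u in units if admit_unit(u)]
    dropped = len(units) - len(kept)
    if dropped:
        logger.info("admission filter excluded %d of %d units", dropped, len(units))
    return kept


# ---------------------------------------------------------------------------
# Long-format reader / writer
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path) -> str:
    header = path.open("r", encoding="utf-8").readline()
    return "\t" if "\t" in header else ","


def read_records(path: str | Path) -> list[NetworkUnit]:
    """Read long-format interaction records into one unit per distinct id.

    Expected header: ``unit,altitude,month,plant,insect[,count]`` (CSV or
    TSV).  An absent count column means binary mode.  The month column may be
    ``<index>`` or ``<index>:<label>``.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path, sep=_sniff_sep(path), dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise RecordParseError(f"{path}: empty file without header") from exc
    required = ["unit", "altitude", "month", "plant", "insect"]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise RecordParseError(f"{path}: missing columns {missing}")
    mode: Mode = "counts" if "count" in table.columns else "binary"
    units: list[NetworkUnit] = []
    for unit_id, grp in table.groupby("unit", sort=True):
        first = grp.iloc[0]
        line0 = int(grp.index[0]) + 2  # header occupies line 1
        try:
            altitude = int(first["altitude"])
        except ValueError as exc:
            raise RecordParseError(
                f"{path}:{line0}: bad altitude {first['altitude']!r}"
            ) from exc
        month_raw = str(first["month"])
        month_index, _, month_label = month_raw.partition(":")
        try:
            month_index = int(month_index)
        except ValueError as exc:
            raise RecordParseError(f"{path}:{line0}: bad month {month_raw!r}") from exc
        links = []
        for line, (_, row) in zip(grp.index + 2, grp.iterrows()):
            if mode == "counts":
                try:
                    count = int(row["count"])
                    if count <= 0:
                        raise ValueError
                except ValueError as exc:
                    raise RecordParseError(
                        f"{path}:{line}: count must be a positive integer"
                    ) from exc
            else:
                count = 1
            links.append((str(row["plant"]), str(row["insect"]), float(count)))
        units.append(
            NetworkUnit(
                unit_id=str(unit_id),
                altitude=altitude,
                month_index=month_index,
                month_label=month_label,
                matrix=InteractionMatrix.from_links(links, mode),
            )
        )
    return units


def write_records(units: Sequence[NetworkUnit], path: str | Path, sep: str = ",") -> None:
    """Write units as long-format records (label-sorted, diffable)."""
    path = Path(path)
    rows = []
    any_counts = any(u.matrix.mode == "counts" for u in units)
    for unit in sorted(units, key=lambda u: u.unit_id):
        m = unit.matrix
        month = f"{unit.month_index}:{unit.month_label}" if unit.month_label else str(unit.month_index)
        for i, plant in enumerate(m.plant_labels):
            for j, insect in enumerate(m.insect_labels):
                value = m.values[i, j]
                if value > 0:
                    row = {
                        "unit": unit.unit_id,
                        "altitude": unit.altitude,
                        "month": month,
                        "plant": plant,
                        "insect": insect,
                    }
                    if any_counts:
                        row["count"] = int(value)
                    rows.append(row)
    columns = LONG_COLUMNS if any_counts else LONG_COLUMNS[:-1]
    frame = pd.DataFrame(rows, columns=columns)
    if len(frame):
        frame = frame.sort_values(["unit", "plant", "insect"], kind="stable")
    frame.to_csv(path, sep=sep, index=False)


def read_wide(path: str | Path, mode: Mode = "binary") -> InteractionMatrix:
    """Read a wide matrix: first column plant labels, headers insect labels."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    return InteractionMatrix.from_frame(frame, mode)


def write_wide(matrix: InteractionMatrix, path: str | Path, sep: str = ",") -> None:
    frame = matrix.to_frame()
    frame = frame.sort_index().sort_index(axis=1)
    frame.to_csv(path, sep=sep, index_label="plant")


# ---------------------------------------------------------------------------
# Pooling into cumulative networks
# ---------------------------------------------------------------------------

def pool(
    units: Sequence[NetworkUnit],
    by: Literal["altitude", "month", "all"] = "all",
) -> list[NetworkUnit]:
    """Pool units into cumulative networks.

    Species sets are unions; in binary mode cells combine by OR, in counts
    mode by summation.  ``by='altitude'`` pools across months at each
    altitude, ``by='month'`` pools across altitudes within each month, and
    ``by='all'`` returns one global network.
    """
    if not units:
        raise ValueError("cannot pool an empty collection")
    modes = {u.matrix.mode for u in units}
    if len(modes) > 1:
        raise ValueError("cannot pool mixed binary/counts units")
    mode = modes.pop()

    def key(u: NetworkUnit):
        if by == "altitude":
            return u.altitude
        if by == "month":
            return u.month_index
        if by == "all":
            return None
        raise ValueError(f"unknown pooling axis {by!r}")

    groups: dict = {}
    for u in units:
        groups.setdefault(key(u), []).append(u)

    pooled: list[NetworkUnit] = []
    for group_key in sorted(groups, key=lambda k: (k is None, k)):
        members = groups[group_key]
        # duplicates across members: OR in binary, sum in counts
        agg: dict[tuple[str, str], float] = {}
        for u in members:
            m = u.matrix
            for i, plant in enumerate(m.plant_labels):
                for j, insect in enumerate(m.insect_labels):
                    value = float(m.values[i, j])
                    if value > 0:
                        if mode == "binary":
                            agg[(plant, insect)] = 1.0
                        else:
                            agg[(plant, insect)] = agg.get((plant, insect), 0.0) + value
        matrix = InteractionMatrix.from_links(
            [(p, a, c) for (p, a), c in agg.items()], mode
        )
        if by == "altitude":
            unit_id = f"alt_{group_key}"
            altitude, month_index, label = int(group_key), 0, "pooled"
        elif by == "month":
            unit_id = f"month_{group_key}"
            altitude, month_index = members[0].altitude, int(group_key)
            label = members[0].month_label
        else:
            unit_id, altitude, month_index, label = "all", members[0].altitude, 0, "pooled"
        precip = float(np.mean([u.precipitation for u in members]))
        pooled.append(
            NetworkUnit(unit_id, altitude, month_index, matrix, label, precip)
        )
    return pooled
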