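"""Species-composition and interaction-identity turnover across the grid.

Bray-Curtis dissimilarity between unit assemblages, its SIMPER per-species
decomposition, occupancy spans (how many months / altitude levels each
species is recorded in), and link-identity turnover (fractions of links
unique to a single altitude or month, and the most frequent links).

Abundance here means per-unit interaction counts: in binary mode a species'
abundance in a unit is its number of links there, so the dissimilarities
reflect both presence and local generalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import braycurtis

from .net_core import NetworkUnit

Side = Literal["plant", "insect"]


def bray_curtis(x: np.ndarray, y: np.ndarray) -> float:
    """Sum |x-y| / sum (x+y) for two nonnegative abundance vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must share length")
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("abundances must be nonnegative")
    if x.sum() + y.sum() == 0:
        raise ValueError("Bray-Curtis undefined for two empty assemblages")
    return float(braycurtis(x, y))


def abundance_table(units: Sequence[NetworkUnit], side: Side) -> pd.DataFrame:
    """Units x species abundance matrix (link counts per unit)."""
    rows = {}
    for unit in units:
        m = unit.matrix
        if side == "plant":
            labels, counts = m.plant_labels, m.values.sum(axis=1)
        else:
            labels, counts = m.insect_labels, m.values.sum(axis=0)
        rows[unit.unit_id] = dict(zip(labels, counts))
    table = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    return table.reindex(sorted(table.columns), axis=1)


@dataclass(frozen=True)
class SimperTable:
    """Between-group Bray-Curtis decomposition into species contributions."""

    overall_dissimilarity: float  # percent, 0-100
    table: pd.DataFrame  # species, contribution, contribution_pct, cumulative_pct


def simper(
    samples: pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> SimperTable:
    """SIMPER over all between-group unit pairs.

    Per pair, species i contributes |x_i - y_i| / sum_k (x_k + y_k); the
    contributions are averaged over pairs and scaled by 100, so they sum to
    the mean between-group Bray-Curtis dissimilarity x 100.
    """
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be nonempty")
    missing = (set(group_a) | set(group_b)) - set(samples.index)
    if missing:
        raise KeyError(f"units not in sample table: {sorted(missing)}")
    species = list(samples.columns)
    contrib = np.zeros(len(species))
    n_pairs = 0
    for a in group_a:
        x = samples.loc[a].to_numpy(dtype=float)
        for b in group_b:
            y = samples.loc[b].to_numpy(dtype=float)
            denom = (x + y).sum()
            if denom == 0:
                raise ValueError(f"pair ({a}, {b}) has no species at all")
            contrib += np.abs(x - y) / denom
            n_pairs += 1
    contrib = 100.0 * contrib / n_pairs
    overall = float(contrib.sum())
    frame = pd.DataFrame({"species": species, "contribution": contrib})
    frame["contribution_pct"] = (
        100.0 * frame["contribution"] / overall if overall > 0 else 0.0
    )
    frame = frame.sort_values(
        ["contribution", "species"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    frame["cumulative_pct"] = frame["contribution_pct"].cumsum()
    return SimperTable(overall_dissimilarity=overall, table=frame)


def dissimilarity_matrix(samples: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis between all units of an abundance table."""
    ids = list(samples.index)
    out = pd.DataFrame(0.0, index=ids, columns=ids)
    values = samples.to_numpy(dtype=float)
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            d = bray_curtis(values[i], values[j])
            out.iat[i, j] = out.iat[j, i] = d
    return out


@dataclass(frozen=True)
class OccupancyProfile:
    species: str
    side: Side
    months_present: frozenset[int]
    altitudes_present: frozenset[int]

    @property
    def span_months(self) -> int:
        return len(self.months_present)

    @property
    def span_altitudes(self) -> int:
        return len(self.altitudes_present)


def occupancy(units: Sequence[NetworkUnit]) -> list[OccupancyProfile]:
    """Months and altitude levels where each species has >= 1 link."""
    if not units:
        raise ValueError("need at least one unit")
    seen: dict[tuple[str, Side], tuple[set[int], set[int]]] = {}
    for unit in units:
        m = unit.matrix
        present_plants = [p for p, deg in zip(m.plant_labels, m.values.sum(axis=1)) if deg > 0]
        present_insects = [a for a, deg in zip(m.insect_labels, m.values.sum(axis=0)) if deg > 0]
        for side, labels in (("plant", present_plants), ("insect", present_insects)):
            for label in labels:
                months, alts = seen.setdefault((label, side), (set(), set()))
                months.add(unit.month_index)
                alts.add(unit.altitude)
    return [
        OccupancyProfile(label, side, frozenset(months), frozenset(alts))
        for (label, side), (months, alts) in sorted(seen.items())
    ]


def occupancy_summary(profiles: Sequence[OccupancyProfile]) -> pd.DataFrame:
    """Mean spans and single-period fractions per side."""
    rows = []
    for side in ("plant", "insect"):
        spans_m = [p.span_months for p in profiles if p.side == side]
        spans_a = [p.span_altitudes for p in profiles if p.side == side]
        if not spans_m:
            continue
        rows.append(
            {
                "side": side,
                "n_species": len(spans_m),
                "mean_span_months": float(np.mean(spans_m)),
                "mean_span_altitudes": float(np.mean(spans_a)),
                "frac_single_month": float(np.mean(np.array(spans_m) == 1)),
                "frac_single_altitude": float(np.mean(np.array(spans_a) == 1)),
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class LinkTurnover:
    unique_fraction_altitude: float
    unique_fraction_month: float
    occurrence_table: pd.DataFrame  # plant, insect, n_units, n_altitudes, n_months, share
    total_records: int


def interaction_turnover(units: Sequence[NetworkUnit]) -> LinkTurnover:
    """Link-identity turnover across the two grid axes.

    A link is a (plant, insect) pair.  For each axis the unique fraction is
    the share of distinct links recorded at exactly one level of that axis.
    ``share`` is a link's number of occurrences over the total number of
    interaction records (one record = one link in one unit).
    """
    if not units:
        raise ValueError("need at least one unit")
    per_link: dict[tuple[str, str], dict[str, set | int]] = {}
    total_records = 0
    for unit in units:
        m = unit.matrix
        for i, plant in enumerate(m.plant_labels):
            for j, insect in enumerate(m.insect_labels):
                if m.values[i, j] > 0:
                    total_records += 1
                    entry = per_link.setdefault(
                        (plant, insect),
                        {"units": 0, "altitudes": set(), "months": set()},
                    )
                    entry["units"] += 1
                    entry["altitudes"].add(unit.altitude)
                    entry["months"].add(unit.month_index)
    rows = [
        {
            "plant": plant,
            "insect": insect,
            "n_units": entry["units"],
            "n_altitudes": len(entry["altitudes"]),
            "n_months": len(entry["months"]),
            "share": entry["units"] / total_records,
        }
        for (plant, insect), entry in per_link.items()
    ]
    table = pd.DataFrame(rows).sort_values(
        ["n_units", "plant", "insect"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    return LinkTurnover(
        unique_fraction_altitude=float((table["n_altitudes"] == 1).mean()),
        unique_fraction_month=float((table["n_months"] == 1).mean()),
        occurrence_table=table,
        total_records=total_records,
    )
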