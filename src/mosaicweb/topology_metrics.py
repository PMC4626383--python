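"""Per-network topology indices for bipartite plant-visitor matrices.

Implements the descriptive indices (P, A, S, M, A:P, I, C, L, L_P, L_A,
specialist fractions), nestedness by decreasing fill and paired overlap
(NODF, binary and weighted), quantitative linkage density and weighted
connectance, interaction strength asymmetry (ISA), and the two-dimensional
Shannon specialization index H2'.

Conventions
-----------
* L is defined as I/S, links per species counting each link once.  With the
  alternative 2I/S every link would be credited to both of its endpoints;
  the I/S form is the one used throughout this package.
* NODF averages over *all* row pairs and column pairs; pairs that fail the
  strict decreasing-fill condition (ties included) contribute zero but stay
  in the denominator.
* H2 uses natural logarithms; linkage density uses base-2 entropies
  (effective partner counts), following each metric's source convention.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, asdict

import numpy as np

from .net_core import InteractionMatrix, NetworkUnit

logger = logging.getLogger(__name__)

#: fixed column order of a metrics table row
METRIC_COLUMNS = [
    "P", "A", "S", "M", "AP_ratio", "I", "C", "L", "L_P", "L_A",
    "pct_spec_P", "pct_spec_A", "NODF", "WNODF",
    "weighted_connectance", "ISA", "H2",
]


@dataclass(frozen=True)
class NODFBreakdown:
    """NODF score with its row/column decomposition."""

    nodf: float
    row_component: float
    col_component: float
    n_row_pairs: int
    n_col_pairs: int


@dataclass(frozen=True)
class H2Result:
    """Observed interaction entropy and its margin-constrained extrema."""

    h2_prime: float
    h_observed: float
    h_min: float
    h_max: float


@dataclass(frozen=True)
class MetricsRecord:
    P: int
    A: int
    S: int
    M: int
    AP_ratio: float
    I: int
    C: float
    L: float
    L_P: float
    L_A: float
    pct_spec_P: float = float("nan")
    pct_spec_A: float = float("nan")
    NODF: float = float("nan")
    WNODF: float = float("nan")
    weighted_connectance: float = float("nan")
    ISA: float = float("nan")
    H2: float = float("nan")

    def as_dict(self) -> dict:
        return asdict(self)


def _require_admitted(m: InteractionMatrix) -> None:
    if m.n_plants < 2 or m.n_insects < 2:
        raise ValueError("metric requires an admitted matrix (>= 2 species per side)")


# ---------------------------------------------------------------------------
# Descriptive metrics
# ---------------------------------------------------------------------------

def descriptive_metrics(m: InteractionMatrix) -> MetricsRecord:
    """P, A, S, M, A:P, I, C = I/M, L = I/S, L_P = I/P, L_A = I/A."""
    _require_admitted(m)
    P, A = m.n_plants, m.n_insects
    I = m.n_links
    S, M = P + A, P * A
    return MetricsRecord(
        P=P, A=A, S=S, M=M, AP_ratio=A / P, I=I,
        C=I / M, L=I / S, L_P=I / P, L_A=I / A,
    )


def specialist_fractions(m: InteractionMatrix) -> tuple[float, float]:
    """Fractions of plants / insects with exactly one interaction partner."""
    _require_admitted(m)
    row_deg = np.count_nonzero(m.values, axis=1)
    col_deg = np.count_nonzero(m.values, axis=0)
    return float(np.mean(row_deg == 1)), float(np.mean(col_deg == 1))


# ---------------------------------------------------------------------------
# Nestedness (NODF)
# ---------------------------------------------------------------------------

def _nodf_pair_scores(rows: np.ndarray, weighted: bool) -> list[float]:
    """Score every unordered pair of rows of a 2-D array.

    Binary: the pair scores 0 unless the degrees differ; otherwise the
    paired overlap of the poorer row within the richer one, scaled to 100.
    Weighted: marginal totals must strictly decrease and overlap counts only
    cells of the poorer row that are positive and strictly smaller than the
    matching cell of the richer row.
    """
    scores = []
    if weighted:
        margins = rows.sum(axis=1)
    else:
        margins = np.count_nonzero(rows, axis=1)
    for i, j in itertools.combinations(range(rows.shape[0]), 2):
        hi, lo = (i, j) if margins[i] > margins[j] else (j, i)
        if margins[hi] <= margins[lo]:  # tie: decreasing fill fails
            scores.append(0.0)
            continue
        u, v = rows[hi], rows[lo]
        v_pos = v > 0
        n_pos = int(v_pos.sum())
        if n_pos == 0:
            scores.append(0.0)
            continue
        if weighted:
            overlap = int(np.sum(v_pos & (v < u)))
        else:
            overlap = int(np.sum(v_pos & (u > 0)))
        scores.append(100.0 * overlap / n_pos)
    return scores


def nodf(m: InteractionMatrix, weighted: bool = False) -> NODFBreakdown:
    """Nestedness by decreasing fill and paired overlap, on a 0-100 scale.

    The score is the mean pair score over all row pairs plus all column
    pairs; it is invariant to row/column permutations because each pair is
    oriented by its own marginal ordering.
    """
    _require_admitted(m)
    values = m.values if weighted else (m.values > 0).astype(float)
    row_scores = _nodf_pair_scores(values, weighted)
    col_scores = _nodf_pair_scores(values.T, weighted)
    n_pairs = len(row_scores) + len(col_scores)
    return NODFBreakdown(
        nodf=float((sum(row_scores) + sum(col_scores)) / n_pairs),
        row_component=float(np.mean(row_scores)),
        col_component=float(np.mean(col_scores)),
        n_row_pairs=len(row_scores),
        n_col_pairs=len(col_scores),
    )


# ---------------------------------------------------------------------------
# Quantitative linkage density / weighted connectance
# ---------------------------------------------------------------------------

def linkage_density(m: InteractionMatrix) -> float:
    """Marginal-weighted mean effective number of partners per species.

    LD = 1/2 [ sum_j (c_j/T) 2^{H_j} + sum_i (r_i/T) 2^{H_i} ] where H_j is
    the base-2 Shannon entropy of column j's conditional distribution and
    H_i that of row i; 2^H is the effective partner count of the species.
    """
    _require_admitted(m)
    T = m.total_events
    if T <= 0:
        raise ValueError("linkage density undefined for a zero matrix")

    def side_sum(rows: np.ndarray) -> float:
        totals = rows.sum(axis=1)
        acc = 0.0
        for total, row in zip(totals, rows):
            p = row[row > 0] / total
            h = -np.sum(p * np.log2(p))
            acc += (total / T) * 2.0 ** h
        return acc

    return 0.5 * (side_sum(m.values) + side_sum(m.values.T))


def weighted_connectance(m: InteractionMatrix) -> float:
    """Linkage density divided by the number of species S."""
    return linkage_density(m) / (m.n_plants + m.n_insects)


# ---------------------------------------------------------------------------
# Interaction strength asymmetry
# ---------------------------------------------------------------------------

def interaction_strength_asymmetry(m: InteractionMatrix) -> float:
    """Mean normalized imbalance of mutual dependencies, in [-1, 1].

    For each realized link, the visitor's dependence on the plant is
    a_ij / c_j and the plant's dependence on the visitor is a_ij / r_i; the
    per-link asymmetry is their difference scaled by the larger of the two.
    Positive values mean the higher trophic level (visitors) depends more
    strongly on its partners than vice versa.
    """
    _require_admitted(m)
    values = m.values
    if values.sum() <= 0:
        raise ValueError("ISA undefined for a zero matrix")
    r = values.sum(axis=1, keepdims=True)
    c = values.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        d_insect = values / c  # dependence of insect j on plant i
        d_plant = values / r   # dependence of plant i on insect j
        asym = (d_insect - d_plant) / np.maximum(d_insect, d_plant)
    return float(np.mean(asym[values > 0]))


# ---------------------------------------------------------------------------
# H2' specialization
# ---------------------------------------------------------------------------

def _shannon(values: np.ndarray) -> float:
    """Natural-log Shannon entropy of a nonnegative table (nats)."""
    total = values.sum()
    p = values[values > 0] / total
    return float(-np.sum(p * np.log(p)))


def _h2_min_table(row_totals: np.ndarray, col_totals: np.ndarray) -> np.ndarray:
    """Greedy concentrating fill: emulate maximal specialization.

    Repeatedly place min(remaining row, remaining column) into the cell with
    the largest product of remaining marginal totals.  Deterministic.
    """
    r = row_totals.astype(int).copy()
    c = col_totals.astype(int).copy()
    table = np.zeros((len(r), len(c)), dtype=int)
    while r.sum() > 0:
        prod = np.outer(r, c)
        i, j = np.unravel_index(np.argmax(prod), prod.shape)
        amount = min(r[i], c[j])
        table[i, j] += amount
        r[i] -= amount
        c[j] -= amount
    return table


def _h2_max_table(row_totals: np.ndarray, col_totals: np.ndarray) -> np.ndarray:
    """Greedy evening fill: distribute unit by unit toward the cell whose
    remaining marginal product is largest, spreading events as evenly as the
    integer margins allow.  Deterministic."""
    r = row_totals.astype(int).copy()
    c = col_totals.astype(int).copy()
    table = np.zeros((len(r), len(c)), dtype=int)
    while r.sum() > 0:
        prod = np.outer(r, c)
        i, j = np.unravel_index(np.argmax(prod), prod.shape)
        table[i, j] += 1
        r[i] -= 1
        c[j] -= 1
    return table


def _hill_climb(table: np.ndarray, maximize: bool, max_sweeps: int = 60) -> np.ndarray:
    """Local adjustment: 2x2 margin-preserving unit moves while entropy
    improves.  Scan order is fixed, so the result is deterministic.

    Entropy is tracked through F = sum f(a) with f(x) = x ln x, since for a
    fixed grand total H = ln T - F/T; a unit move touches only four cells,
    giving an O(1) gain evaluation (first-improvement within each sweep).
    """
    table = table.astype(int).copy()
    n_r, n_c = table.shape
    top = int(table.sum()) + 2  # no cell can exceed the grand total
    xs = np.arange(top + 2, dtype=float)
    f = np.zeros_like(xs)
    f[1:] = xs[1:] * np.log(xs[1:])
    # minimizing F maximizes entropy: accept moves with sign * delta_F < 0
    sign = 1.0 if maximize else -1.0
    for _ in range(max_sweeps):
        improved = False
        for i1, i2 in itertools.combinations(range(n_r), 2):
            for j1, j2 in itertools.combinations(range(n_c), 2):
                for (a, b, c_, d) in (((i1, j1), (i2, j2), (i1, j2), (i2, j1)),
                                      ((i1, j2), (i2, j1), (i1, j1), (i2, j2))):
                    lo = int(min(table[c_], table[d]))
                    if lo < 1:
                        continue
                    # single-unit and full-block transfers; blocks let the
                    # search hop between concentrated configurations
                    for t in ({1, lo} if lo > 1 else {1}):
                        delta_f = (
                            f[table[a] + t] - f[table[a]]
                            + f[table[b] + t] - f[table[b]]
                            + f[table[c_] - t] - f[table[c_]]
                            + f[table[d] - t] - f[table[d]]
                        )
                        if sign * delta_f < -1e-12:
                            table[a] += t
                            table[b] += t
                            table[c_] -= t
                            table[d] -= t
                            improved = True
                            break
        if not improved:
            break
    return table


def _exact_entropy_bounds(
    row_totals: np.ndarray, col_totals: np.ndarray, budget: int = 300_000
) -> tuple[float, float] | None:
    """Exact entropy extrema by pruned enumeration of all integer tables
    with the given margins.  Returns None when the search exceeds its node
    budget (larger problems fall back to the heuristics)."""
    n_r, n_c = len(row_totals), len(col_totals)
    T = int(row_totals.sum())
    xs = np.arange(T + 2, dtype=float)
    f = np.zeros_like(xs)
    f[1:] = xs[1:] * np.log(xs[1:])
    best = {"min": np.inf, "max": -np.inf, "nodes": 0}

    def compositions(total: int, caps: tuple[int, ...]):
        if len(caps) == 1:
            if total <= caps[0]:
                yield (total,)
            return
        for first in range(min(total, caps[0]) + 1):
            for rest in compositions(total - first, caps[1:]):
                yield (first,) + rest

    def rec(i: int, cols_left: tuple[int, ...], f_sum: float) -> bool:
        best["nodes"] += 1
        if best["nodes"] > budget:
            return False
        if i == n_r:
            if all(c == 0 for c in cols_left):
                best["min"] = min(best["min"], f_sum)
                best["max"] = max(best["max"], f_sum)
            return True
        if sum(cols_left) != sum(row_totals[i:]):
            return True  # infeasible branch (defensive; margins always match)
        for row in compositions(int(row_totals[i]), cols_left):
            nxt = tuple(c - r for c, r in zip(cols_left, row))
            if not rec(i + 1, nxt, f_sum + sum(f[r] for r in row)):
                return False
        return True

    if not rec(0, tuple(int(c) for c in col_totals), 0.0):
        return None
    if not np.isfinite(best["min"]):
        return None
    # H = ln T - F / T on the feasible set; min F <-> max H
    log_t = np.log(T)
    return log_t - best["max"] / T, log_t - best["min"] / T


def h2_entropy_bounds(
    row_totals: np.ndarray, col_totals: np.ndarray
) -> tuple[float, float]:
    """(h_min, h_max) entropy extrema over integer tables with the given
    margins: exact by pruned enumeration for tiny tables, deterministic
    greedy fills plus local 2x2 adjustment otherwise."""
    row_totals = np.asarray(np.rint(row_totals), dtype=int)
    col_totals = np.asarray(np.rint(col_totals), dtype=int)
    if row_totals.sum() != col_totals.sum():
        raise ValueError("margins must share a grand total")
    if len(row_totals) * len(col_totals) <= 16 and row_totals.sum() <= 24:
        exact = _exact_entropy_bounds(row_totals, col_totals)
        if exact is not None:
            return exact
    t_min = _hill_climb(_h2_min_table(row_totals, col_totals), maximize=False)
    t_max = _hill_climb(_h2_max_table(row_totals, col_totals), maximize=True)
    return _shannon(t_min), _shannon(t_max)


def h2_specialization(m: InteractionMatrix) -> H2Result:
    """Standardized two-dimensional Shannon entropy of the interactions.

    H2' = (H2max - H2) / (H2max - H2min) where the extrema are taken over
    integer tables with the observed row/column totals; 0 means the
    interactions follow the marginal expectation (no specialization), 1
    means maximal partitioning of partners (complete specialization).
    Non-integer matrices are rescaled to integers before computing bounds.
    """
    _require_admitted(m)
    values = m.values
    if values.sum() <= 0:
        raise ValueError("H2 undefined for a zero matrix")
    ints = np.rint(values)
    if not np.allclose(values, ints, atol=1e-9):
        scale = 1000.0 / values.sum()
        ints = np.rint(values * scale)
        ints[(values > 0) & (ints == 0)] = 1
    h_obs = _shannon(values)
    h_min, h_max = h2_entropy_bounds(ints.sum(axis=1), ints.sum(axis=0))
    # the observed table itself satisfies the margins, so it bounds the
    # heuristic extrema whenever the heuristics stop short of it
    if np.allclose(values, ints):
        h_min = min(h_min, h_obs)
        h_max = max(h_max, h_obs)
    if h_max - h_min <= 1e-12:
        logger.info("degenerate H2 bounds (single-support table); H2' set to 0")
        return H2Result(0.0, h_obs, h_min, h_max)
    h2 = float(np.clip((h_max - h_obs) / (h_max - h_min), 0.0, 1.0))
    return H2Result(h2, h_obs, h_min, h_max)


# ---------------------------------------------------------------------------
# Full record
# ---------------------------------------------------------------------------

def full_metrics(m: InteractionMatrix) -> MetricsRecord:
    """All indices for one admitted matrix."""
    base = descriptive_metrics(m)
    spec_p, spec_a = specialist_fractions(m)
    return MetricsRecord(
        **{
            **base.as_dict(),
            "pct_spec_P": spec_p,
            "pct_spec_A": spec_a,
            "NODF": nodf(m, weighted=False).nodf,
            "WNODF": nodf(m, weighted=True).nodf,
            "weighted_connectance": weighted_connectance(m),
            "ISA": interaction_strength_asymmetry(m),
            "H2": h2_specialization(m).h2_prime,
        }
    )


def metrics_table(units) -> "pd.DataFrame":
    """One metrics row per admitted unit, in fixed column order."""
    import pandas as pd

    rows = []
    for unit in units:
        rec = full_metrics(unit.matrix)
        row = {
            "unit": unit.unit_id,
            "altitude": unit.altitude,
            "month": unit.month_index,
            "precipitation": unit.precipitation,
        }
        row.update(rec.as_dict())
        rows.append(row)
    return pd.DataFrame(
        rows, columns=["unit", "altitude", "month", "precipitation"] + METRIC_COLUMNS
    )
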