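"""Connectance-preserving randomization and observed-vs-null contrasts.

The null model redistributes the observed interaction events over the
matrix while conserving exactly the number of filled cells I (hence the
connectance I/M) and the grand total T.  Marginal totals are *not*
conserved; the null therefore asks whether an index differs from what a
matrix of the same size, fill and intensity would show when species
identities carry no information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats

from . import topology_metrics as tm
from .net_core import InteractionMatrix

logger = logging.getLogger(__name__)

#: indices compared against the null ensemble, name -> callable
NULL_INDICES: dict[str, Callable[[InteractionMatrix], float]] = {
    "weighted_connectance": tm.weighted_connectance,
    "WNODF": lambda m: tm.nodf(m, weighted=True).nodf,
    "ISA": tm.interaction_strength_asymmetry,
    "H2": lambda m: tm.h2_specialization(m).h2_prime,
}


@dataclass(frozen=True)
class NullEnsembleSpec:
    replicates: int = 1000
    seed: int = 0
    indices: tuple[str, ...] = tuple(NULL_INDICES)
    #: redistribute events over the observed cells instead of random ones
    fixed_cells: bool = False
    #: tolerated fraction of replicates on which an index may be undefined
    max_missing_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates")
        unknown = set(self.indices) - set(NULL_INDICES)
        if unknown:
            raise ValueError(f"unknown indices {sorted(unknown)}")


@dataclass(frozen=True)
class NullComparison:
    """Observed index vs a randomized ensemble with a two-sided t contrast."""

    index_name: str
    observed: float
    null_values: tuple[float, ...]
    t_statistic: float
    p_value: float
    replicates: int
    seed: int
    n_missing: int = 0

    @property
    def null_mean(self) -> float:
        return float(np.mean(self.null_values))

    @property
    def null_sd(self) -> float:
        return float(np.std(self.null_values, ddof=1))

    def empirical_p(self) -> float:
        """Two-sided exceedance probability of the observed value within the
        null ensemble (rank-based, add-one corrected).  Unlike the t contrast
        this treats the observed value as one draw, so it is calibrated."""
        null = np.asarray(self.null_values)
        n = len(null)
        p_hi = (1 + np.sum(null >= self.observed)) / (n + 1)
        p_lo = (1 + np.sum(null <= self.observed)) / (n + 1)
        return float(min(1.0, 2.0 * min(p_hi, p_lo)))


def randomize(
    m: InteractionMatrix,
    rng: np.random.Generator,
    fixed_cells: bool = False,
) -> InteractionMatrix:
    """One connectance-preserving randomization of ``m``.

    I cells are chosen uniformly among the M available (or kept at the
    observed positions when ``fixed_cells``), each receives one event, and
    the remaining T - I events are scattered uniformly over the chosen
    cells.  Binary input (T = I) reduces to a uniform placement of I ones.
    """
    n_p, n_a = m.values.shape
    I = m.n_links
    T = int(round(m.total_events))
    if fixed_cells:
        flat_cells = np.flatnonzero(m.values.ravel() > 0)
    else:
        flat_cells = rng.choice(n_p * n_a, size=I, replace=False)
    flat = np.zeros(n_p * n_a)
    flat[flat_cells] = 1.0
    extra = T - I
    if extra > 0:
        hits = rng.choice(flat_cells, size=extra, replace=True)
        np.add.at(flat, hits, 1.0)
    values = flat.reshape(n_p, n_a)
    # shape is conserved; randomized species may end up with zero links,
    # which is legitimate under this null (S and M stay fixed)
    return InteractionMatrix(m.plant_labels, m.insect_labels, values, m.mode)


def compare_to_null(
    m: InteractionMatrix, spec: NullEnsembleSpec
) -> list[NullComparison]:
    """Observed value of each requested index vs its null ensemble.

    The contrast is a one-sample two-sided t test of the null ensemble
    against the observed value.  Replicates on which an index is undefined
    (degenerate randomization) are dropped, up to
    ``spec.max_missing_fraction`` of the ensemble.
    """
    rng = np.random.default_rng(spec.seed)
    ensembles: dict[str, list[float]] = {name: [] for name in spec.indices}
    missing: dict[str, int] = {name: 0 for name in spec.indices}
    for _ in range(spec.replicates):
        replicate = randomize(m, rng, fixed_cells=spec.fixed_cells)
        for name in spec.indices:
            try:
                ensembles[name].append(NULL_INDICES[name](replicate))
            except ValueError:
                missing[name] += 1
    results = []
    for name in spec.indices:
        null = ensembles[name]
        if missing[name] > spec.max_missing_fraction * spec.replicates:
            raise ValueError(
                f"{name}: {missing[name]} of {spec.replicates} replicates undefined"
            )
        if missing[name]:
            logger.info("%s: %d degenerate replicates excluded", name, missing[name])
        observed = NULL_INDICES[name](m)
        t_stat, p_val = stats.ttest_1samp(null, observed)
        results.append(
            NullComparison(
                index_name=name,
                observed=float(observed),
                null_values=tuple(null),
                t_statistic=float(t_stat),
                p_value=float(p_val),
                replicates=len(null),
                seed=spec.seed,
                n_missing=missing[name],
            )
        )
    return results


def null_table(units, spec: NullEnsembleSpec):
    """Observed / null mean / null SD / t / p rows, one per (unit, index)."""
    import pandas as pd

    rows = []
    for unit in units:
        for comparison in compare_to_null(unit.matrix, spec):
            rows.append(
                {
                    "unit": unit.unit_id,
                    "index": comparison.index_name,
                    "observed": comparison.observed,
                    "null_mean": comparison.null_mean,
                    "null_sd": comparison.null_sd,
                    "t": comparison.t_statistic,
                    "p": comparison.p_value,
                    "replicates": comparison.replicates,
                }
            )
    return pd.DataFrame(rows)
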