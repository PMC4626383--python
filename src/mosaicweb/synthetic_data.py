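"""Seeded generator of spatio-temporal plant-visitor interaction mosaics.

The generator emulates a mountain-forest sampling campaign: a grid of
altitude levels (100 m steps) crossed with consecutive months, where each
cell yields a small bipartite network.  Its statistical structure mirrors
what such field data look like:

* short, contiguous phenology windows (shifted-geometric spans; plants
  briefer than insects) and contiguous altitude bands per species, with a
  tiny core of visitor species present everywhere;
* bimodal monthly precipitation driving unit richness through a quadratic
  (concave) response;
* altitude-increasing specialist fractions on both sides, following linear
  laws in elevation;
* attenuation of the visitor pool above a thermal divide, making
  high-elevation networks smaller;
* a fraction of grid cells empty (no flowering or no visitors).

Everything is reproducible bit-for-bit from (config, seed), and each run
returns a :class:`MosaicTruth` ledger with the latent quantities the
analysis stages try to recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np

from .inference import RegressionResult, fit_polynomial
from .net_core import InteractionMatrix, NetworkUnit, admitted
from .turnover import occupancy

#: default monthly precipitation (mm), October through May: two rainy
#: blocks (> 280 mm) flanking a four-month dry block (< 200 mm)
DEFAULT_PRECIPITATION = (300.0, 320.0, 180.0, 150.0, 140.0, 170.0, 310.0, 290.0)
DEFAULT_MONTH_LABELS = ("Oct", "Nov", "Dec", "Jan", "Feb", "Mar", "Apr", "May")


@dataclass(frozen=True)
class MosaicConfig:
    """Full parameterization of the synthetic mosaic."""

    n_altitudes: int = 8
    altitude_min: int = 2200
    altitude_step: int = 100
    n_months: int = 8
    precipitation: tuple[float, ...] = DEFAULT_PRECIPITATION
    month_labels: tuple[str, ...] = DEFAULT_MONTH_LABELS

    plant_pool: int = 42
    insect_pool: int = 75

    # phenology spans (months) and altitude band widths (levels), means of
    # shifted-geometric distributions with support >= 1
    plant_span_mean: float = 1.88
    insect_span_mean: float = 2.41
    plant_band_mean: float = 3.0
    insect_band_mean: float = 3.0
    #: fraction of visitor species present in all months and altitudes
    core_fraction: float = 0.02

    # unit richness: expected species picked per cell at the mean
    # precipitation month, modulated by the quadratic response below
    base_plants: float = 4.5
    base_insects: float = 9.0
    #: (linear, quadratic) response of the richness multiplier to the
    #: standardized monthly precipitation; negative quadratic = concave
    richness_response: tuple[float, float] = (0.0, -0.30)

    # linear laws for specialist fractions vs altitude (masl)
    specialist_intercept_P: float = -0.44
    specialist_slope_P: float = 0.0003
    specialist_intercept_A: float = 0.15
    specialist_slope_A: float = 0.0002

    #: target mean links per species (plants emerge from visitor choices)
    plant_degree_mean: float = 2.32
    insect_degree_mean: float = 1.17
    insect_degree_max: int = 4

    #: thermal divide: visitor availability shrinks above this elevation
    divide_altitude: int = 2700
    insect_attenuation: float = 0.45

    #: extra per-cell probability of recording nothing at all
    empty_unit_rate: float = 0.20

    mode: Literal["binary", "counts"] = "binary"
    #: mean extra events per link in counts mode
    events_extra_mean: float = 1.0
    #: deterministic expectation mode (no sampling noise where avoidable)
    exact: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.plant_pool <= 0 or self.insect_pool <= 0:
            raise ValueError("species pools must be positive")
        if len(self.precipitation) != self.n_months:
            raise ValueError("precipitation vector length must equal n_months")
        if any(p < 0 for p in self.precipitation):
            raise ValueError("precipitation must be nonnegative")
        for mean in (self.plant_span_mean, self.insect_span_mean,
                     self.plant_band_mean, self.insect_band_mean):
            if mean < 1:
                raise ValueError("span/band means must be >= 1 (achievable)")
        if (self.insect_degree_mean > self.plant_pool
                or self.plant_degree_mean > self.insect_pool):
            raise ValueError("infeasible degree target: exceeds partner pool")

    @property
    def altitudes(self) -> tuple[int, ...]:
        return tuple(
            self.altitude_min + k * self.altitude_step
            for k in range(self.n_altitudes)
        )

    def specialist_fraction(self, side: Literal["plant", "insect"], altitude: float) -> float:
        if side == "plant":
            raw = self.specialist_intercept_P + self.specialist_slope_P * altitude
        else:
            raw = self.specialist_intercept_A + self.specialist_slope_A * altitude
        return float(np.clip(raw, 0.0, 1.0))


def null_effect_config(seed: int = 0, **overrides) -> MosaicConfig:
    """A mosaic with no injected altitude or time structure.

    Single-cell phenology windows and altitude bands make units mutually
    independent (no species shared between cells), pools are enlarged to
    keep per-cell availability comparable to the default, and the richness
    response, visitor attenuation and specialist gradients are flattened.
    Used for type-I-error audits of the inference stage.
    """
    params = dict(
        plant_pool=600,
        insect_pool=1200,
        plant_span_mean=1.0,
        insect_span_mean=1.0,
        plant_band_mean=1.0,
        insect_band_mean=1.0,
        core_fraction=0.0,
        richness_response=(0.0, 0.0),
        insect_attenuation=0.0,
        specialist_intercept_P=0.30,
        specialist_slope_P=0.0,
        specialist_intercept_A=0.65,
        specialist_slope_A=0.0,
        seed=seed,
    )
    params.update(overrides)
    return MosaicConfig(**params)


@dataclass(frozen=True)
class SpeciesTraits:
    name: str
    side: Literal["plant", "insect"]
    months: tuple[int, ...]      # contiguous phenology window
    altitudes: tuple[int, ...]   # contiguous elevation band (masl)
    core: bool = False


@dataclass(frozen=True)
class MosaicTruth:
    """Latent ground truth behind one generated mosaic."""

    config: MosaicConfig
    species: tuple[SpeciesTraits, ...]
    #: (altitude, month) -> intended (plant, insect) richness targets
    intended_richness: dict
    #: altitude -> intended (plant, insect) specialist fractions
    intended_specialists: dict

    def mean_span(self, side: Literal["plant", "insect"]) -> float:
        spans = [len(s.months) for s in self.species if s.side == side]
        return float(np.mean(spans))


# ---------------------------------------------------------------------------
# Species pools
# ---------------------------------------------------------------------------

def _shifted_geometric(rng: np.random.Generator, mean: float, top: int) -> int:
    """Draw from {1, ..., top} with a geometric tail of the given mean."""
    if mean <= 1.0:
        return 1
    return int(min(top, rng.geometric(1.0 / mean)))


def sample_pools(config: MosaicConfig, rng: np.random.Generator) -> list[SpeciesTraits]:
    """Assign each species a contiguous phenology window and altitude band.

    In exact mode spans collapse to their rounded means and windows tile the
    grid deterministically.
    """
    altitudes = config.altitudes
    species: list[SpeciesTraits] = []

    def windows(pool: int, side: str, span_mean: float, band_mean: float,
                core_fraction: float) -> None:
        n_core = int(round(core_fraction * pool)) if config.exact else None
        for k in range(pool):
            if config.exact:
                core = k < n_core
            else:
                core = bool(rng.random() < core_fraction)
            if core:
                months = tuple(range(config.n_months))
                band = altitudes
            else:
                if config.exact:
                    span = max(1, int(round(span_mean)))
                    width = max(1, int(round(band_mean)))
                    start_m = k % (config.n_months - span + 1)
                    start_a = (k * 3) % (config.n_altitudes - width + 1)
                else:
                    span = _shifted_geometric(rng, span_mean, config.n_months)
                    width = _shifted_geometric(rng, band_mean, config.n_altitudes)
                    start_m = int(rng.integers(0, config.n_months - span + 1))
                    start_a = int(rng.integers(0, config.n_altitudes - width + 1))
                months = tuple(range(start_m, start_m + span))
                band = altitudes[start_a:start_a + width]
            species.append(SpeciesTraits(f"{side}{k:03d}", side, months, band, core))  # type: ignore[arg-type]

    # the permanent core is a visitor-side phenomenon here; flowering plants
    # keep strictly windowed phenologies
    windows(config.plant_pool, "plant", config.plant_span_mean,
            config.plant_band_mean, 0.0)
    windows(config.insect_pool, "insect", config.insect_span_mean,
            config.insect_band_mean, config.core_fraction)
    return species


# ---------------------------------------------------------------------------
# Link assignment within one unit
# ---------------------------------------------------------------------------

def _assign_links(
    plants: Sequence[str],
    insects: Sequence[str],
    spec_p: float,
    spec_a: float,
    config: MosaicConfig,
    rng: np.random.Generator,
) -> list[tuple[str, str, float]]:
    """Degree-targeted bipartite link assignment, plant side primary.

    Plant degrees carry the altitude signal the analysis recovers, so they
    are drawn first: each plant is a specialist (degree 1) with probability
    ``spec_p``, otherwise a generalist with a geometric degree tail whose
    mean matches ``plant_degree_mean``.  The plant degrees fix the number
    of links I; visitor degrees (specialist with probability ``spec_a``,
    else a short tail capped at ``insect_degree_max``) are then reconciled
    to sum to I by adjusting generalist visitors first, converting visitors
    to specialists next, and dropping surplus visitors as a last resort, so
    the plant side is never distorted.  Pairing samples each visitor's
    partners without replacement, weighted by remaining plant quota.
    """
    n_p, n_a = len(plants), len(insects)

    def n_specialists(frac: float, n: int) -> int:
        # stratified randomized rounding: expectation frac * n with far less
        # variance than independent Bernoulli marks
        if config.exact:
            return min(n, int(round(frac * n)))
        whole, part = divmod(frac * n, 1.0)
        return min(n, int(whole) + int(rng.random() < part))

    def choose(n: int, k: int) -> np.ndarray:
        if config.exact:
            return np.arange(k)
        return rng.choice(n, size=k, replace=False)

    # --- plant quotas -----------------------------------------------------
    gen_mean_p = max(2.0, (config.plant_degree_mean - spec_p) / max(1e-9, 1.0 - spec_p))
    quota = np.zeros(n_p, dtype=int)
    spec_plants = set(choose(n_p, n_specialists(spec_p, n_p)).tolist())
    for i in range(n_p):
        if i in spec_plants or n_a == 1:
            quota[i] = 1
        elif config.exact:
            quota[i] = min(n_a, int(round(gen_mean_p)))
        else:
            extra = _shifted_geometric(rng, gen_mean_p - 1.0, n_a - 1)
            quota[i] = min(n_a, 1 + extra)
    # every visitor needs >= 1 link; grow generalist plant quotas rather
    # than dropping visitors when the plant side under-supplies links
    gen_plants = [i for i in range(n_p) if quota[i] >= 2]
    k = 0
    while quota.sum() < n_a and gen_plants and k < 10 * n_a + 100:
        i = gen_plants[k % len(gen_plants)]
        if quota[i] < n_a:
            quota[i] += 1
        k += 1
    total = int(quota.sum())

    # --- visitor degrees reconciled to the same total ---------------------
    insect_deg = np.zeros(n_a, dtype=int)
    cap = max(1, min(n_p, config.insect_degree_max))
    spec_insects = set(choose(n_a, n_specialists(spec_a, n_a)).tolist())
    for j in range(n_a):
        if j in spec_insects or n_p == 1:
            insect_deg[j] = 1
        elif config.exact:
            insect_deg[j] = min(cap, 2)
        else:
            insect_deg[j] = min(cap, 1 + _shifted_geometric(rng, 1.5, cap - 1))
    order = list(range(n_a))
    if not config.exact:
        rng.shuffle(order)
    k = 0
    while insect_deg.sum() < total and k < 20 * total + 200:
        j = order[k % n_a]
        # prefer widening intended generalists; open specialists only late
        if insect_deg[j] < n_p and (insect_deg[j] >= 2 or insect_deg.max() < 2
                                    or k >= 2 * total):
            insect_deg[j] += 1
        k += 1
    k = 0
    while insect_deg.sum() > total and k < 20 * total + 200:
        j = order[k % n_a]
        if insect_deg[j] > 1:
            insect_deg[j] -= 1
        k += 1
    while insect_deg.sum() > total:  # only when every visitor is at 1 already
        insect_deg[order[-1]] = 0
        order.pop()

    # --- pairing ----------------------------------------------------------
    # phase A: every plant with a quota of 1 (the intended specialists and
    # forced singletons) receives exactly one partner, drawn with weight
    # proportional to the partner's remaining degree
    rem_deg = insect_deg.astype(float).copy()
    links: dict[tuple[int, int], float] = {}
    singles = [i for i in range(n_p) if quota[i] == 1]
    multis = [i for i in range(n_p) if quota[i] >= 2]
    if not config.exact:
        rng.shuffle(singles)
    cursor = 0
    for i in singles:
        if rem_deg.sum() <= 0:
            break
        if config.exact:
            j = int(np.argmax(rem_deg))
            cursor += 1
        else:
            j = int(rng.choice(n_a, p=rem_deg / rem_deg.sum()))
        links[(i, j)] = 1.0
        rem_deg[j] -= 1

    # phase B: remaining visitor stubs fill generalist-plant quotas only,
    # so specialist-intended plants keep their single partner
    remaining = np.array([float(quota[i]) if i in set(multis) else 0.0
                          for i in range(n_p)])
    visit_order = [j for j in range(n_a) if rem_deg[j] > 0]
    if not config.exact:
        rng.shuffle(visit_order)
    for j in visit_order:
        for _ in range(int(rem_deg[j])):
            pool_idx = [i for i in multis
                        if remaining[i] > 0 and (i, j) not in links]
            if not pool_idx:  # quota exhausted: overflow stays on generalists
                pool_idx = [i for i in multis if (i, j) not in links]
            if not pool_idx:  # linked to every generalist already
                break
            if config.exact:
                i = pool_idx[cursor % len(pool_idx)]
                cursor += 1
            else:
                weights = np.array([max(remaining[i], 0.25) for i in pool_idx])
                i = int(rng.choice(pool_idx, p=weights / weights.sum()))
            links[(i, j)] = 1.0
            remaining[i] = max(0.0, remaining[i] - 1.0)

    # --- repair: reroute links so no generalist-intended plant is stranded
    degree = np.zeros(n_p, dtype=int)
    for (i, _j) in links:
        degree[i] += 1
    for i in np.flatnonzero((degree == 0) & (quota > 0)):
        donors = sorted(
            ((ii, jj) for (ii, jj) in links
             if degree[ii] >= 2 and (i, jj) not in links),
            key=lambda p: -degree[p[0]],
        )
        if donors:
            ii, jj = donors[0]
            del links[(ii, jj)]
            degree[ii] -= 1
            links[(i, jj)] = 1.0
            degree[i] += 1

    def events_for() -> float:
        if config.mode != "counts":
            return 1.0
        if config.exact:
            return 1.0 + round(config.events_extra_mean)
        return 1.0 + float(rng.poisson(config.events_extra_mean))

    return [(plants[i], insects[j], events_for()) for (i, j) in sorted(links)]


# ---------------------------------------------------------------------------
# Mosaic generation
# ---------------------------------------------------------------------------

def generate_mosaic(config: MosaicConfig) -> tuple[list[NetworkUnit], MosaicTruth]:
    """Generate the full altitude x month grid of network units.

    Cells where no plant and visitor co-occur (or that fall to the extra
    empty-cell rate) are absent from the returned list, never zero-filled.
    """
    rng = np.random.default_rng(config.seed)
    species = sample_pools(config, rng)
    plants = [s for s in species if s.side == "plant"]
    insects = [s for s in species if s.side == "insect"]

    precip = np.asarray(config.precipitation, dtype=float)
    sd = precip.std()
    z = (precip - precip.mean()) / sd if sd > 0 else np.zeros_like(precip)
    b1, b2 = config.richness_response
    multiplier = np.maximum(0.15, 1.0 + b1 * z + b2 * z * z)
    multiplier = multiplier / multiplier.mean()

    units: list[NetworkUnit] = []
    intended_richness = {}
    for altitude in config.altitudes:
        for month in range(config.n_months):
            target_p = config.base_plants * multiplier[month]
            target_a = config.base_insects * multiplier[month]
            intended_richness[(altitude, month)] = (target_p, target_a)
            if not config.exact and rng.random() < config.empty_unit_rate:
                continue
            avail_p = [s.name for s in plants
                       if month in s.months and altitude in s.altitudes]
            avail_a = []
            for s in insects:
                if month not in s.months or altitude not in s.altitudes:
                    continue
                if (altitude > config.divide_altitude and not s.core
                        and not config.exact
                        and rng.random() < config.insect_attenuation):
                    continue
                avail_a.append(s.name)
            if not avail_p or not avail_a:
                continue
            if config.exact:
                n_p = min(len(avail_p), max(1, int(round(target_p))))
                n_a = min(len(avail_a), max(1, int(round(target_a))))
                chosen_p = sorted(avail_p)[:n_p]
                chosen_a = sorted(avail_a)[:n_a]
            else:
                n_p = min(len(avail_p), int(rng.poisson(target_p)))
                n_a = min(len(avail_a), int(rng.poisson(target_a)))
                if n_p == 0 or n_a == 0:
                    continue
                chosen_p = list(rng.choice(avail_p, size=n_p, replace=False))
                chosen_a = list(rng.choice(avail_a, size=n_a, replace=False))
            links = _assign_links(
                chosen_p, chosen_a,
                config.specialist_fraction("plant", altitude),
                config.specialist_fraction("insect", altitude),
                config, rng,
            )
            if not links:
                continue
            matrix = InteractionMatrix.from_links(links, config.mode)
            units.append(
                NetworkUnit(
                    unit_id=f"T{config.altitudes.index(altitude)}_M{month:02d}",
                    altitude=altitude,
                    month_index=month,
                    month_label=config.month_labels[month]
                    if month < len(config.month_labels) else str(month),
                    precipitation=float(precip[month]),
                    matrix=matrix,
                )
            )
    intended_specialists = {
        altitude: (
            config.specialist_fraction("plant", altitude),
            config.specialist_fraction("insect", altitude),
        )
        for altitude in config.altitudes
    }
    truth = MosaicTruth(
        config=config,
        species=tuple(species),
        intended_richness=intended_richness,
        intended_specialists=intended_specialists,
    )
    return units, truth


# ---------------------------------------------------------------------------
# Parameter recovery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecoveryReport:
    """How well the realized mosaic reflects its latent parameters."""

    realized_specialist_fit_P: RegressionResult
    realized_specialist_fit_A: RegressionResult
    intended_specialist_fit_P: RegressionResult
    intended_specialist_fit_A: RegressionResult
    truth_mean_span_plant: float
    truth_mean_span_insect: float
    realized_mean_span_plant: float
    realized_mean_span_insect: float
    richness_precip_fit: RegressionResult | None


def recovery_report(units: Sequence[NetworkUnit], truth: MosaicTruth) -> RecoveryReport:
    """Compare realized structure against the generator's intentions.

    Specialist fractions are summarized per altitude as the mean per-unit
    fraction over admitted units and regressed on altitude; the intended
    fractions (exactly on the configured line wherever unclipped) are fitted
    the same way as the noise-free reference.
    """
    config = truth.config
    kept = admitted(list(units))
    if not kept:
        raise ValueError("no admitted units to analyze")

    from .topology_metrics import specialist_fractions

    per_alt: dict[int, list[tuple[float, float]]] = {}
    for unit in kept:
        per_alt.setdefault(unit.altitude, []).append(
            specialist_fractions(unit.matrix)
        )
    alts = sorted(per_alt)
    mean_p = [float(np.mean([f[0] for f in per_alt[a]])) for a in alts]
    mean_a = [float(np.mean([f[1] for f in per_alt[a]])) for a in alts]
    x = np.asarray(alts, dtype=float)
    realized_p = fit_polynomial(np.asarray(mean_p), x, 1, "pct_spec_P", "altitude")
    realized_a = fit_polynomial(np.asarray(mean_a), x, 1, "pct_spec_A", "altitude")

    all_alts = np.asarray(config.altitudes, dtype=float)
    intended_p = fit_polynomial(
        np.asarray([truth.intended_specialists[a][0] for a in config.altitudes]),
        all_alts, 1, "pct_spec_P_intended", "altitude",
    )
    intended_a = fit_polynomial(
        np.asarray([truth.intended_specialists[a][1] for a in config.altitudes]),
        all_alts, 1, "pct_spec_A_intended", "altitude",
    )

    profiles = occupancy(list(units))
    spans_p = [p.span_months for p in profiles if p.side == "plant"]
    spans_a = [p.span_months for p in profiles if p.side == "insect"]

    richness_fit = None
    s_values = [u.matrix.n_plants + u.matrix.n_insects for u in kept]
    precip = [u.precipitation for u in kept]
    if len(set(precip)) > 2:
        richness_fit = fit_polynomial(
            np.asarray(s_values, dtype=float), np.asarray(precip, dtype=float),
            2, "S", "precipitation",
        )

    return RecoveryReport(
        realized_specialist_fit_P=realized_p,
        realized_specialist_fit_A=realized_a,
        intended_specialist_fit_P=intended_p,
        intended_specialist_fit_A=intended_a,
        truth_mean_span_plant=truth.mean_span("plant"),
        truth_mean_span_insect=truth.mean_span("insect"),
        realized_mean_span_plant=float(np.mean(spans_p)) if spans_p else float("nan"),
        realized_mean_span_insect=float(np.mean(spans_a)) if spans_a else float("nan"),
        richness_precip_fit=richness_fit,
    )
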