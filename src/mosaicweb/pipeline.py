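"""End-to-end orchestration: simulate -> admit -> metrics -> nulls ->
turnover -> inference, with a manifest for reproducibility.

A run is parameterized by a :class:`RunConfig` (mosaic parameters plus
analysis settings).  Every stochastic stage derives its own random stream
from the single run seed, so stages are individually reproducible.  All
outputs are delimited text with deterministic ordering; the manifest
records row counts and SHA-256 checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import inference, null_models, turnover
from .net_core import NetworkUnit, admit_unit, admitted, pool, write_records
from .synthetic_data import MosaicConfig, generate_mosaic
from .topology_metrics import metrics_table

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    mosaic: MosaicConfig = field(default_factory=MosaicConfig)
    null_replicates: int = 250
    null_indices: tuple[str, ...] = tuple(null_models.NULL_INDICES)
    band_boundary: int = 2700
    alpha_assume: float = 0.05
    sep: str = "\t"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        mosaic = MosaicConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw.pop("mosaic", {}).items()
        })
        if "null_indices" in raw:
            raw["null_indices"] = tuple(raw["null_indices"])
        return cls(mosaic=mosaic, **raw)


@dataclass
class RunManifest:
    seed: int
    config: dict
    versions: dict
    row_counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True,
                          default=str)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _derive_seed(base: int, stage: str) -> int:
    digest = hashlib.sha256(f"{base}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> RunManifest:
    """Run all stages into ``out_dir`` and return the manifest.

    A stage failure raises :class:`RuntimeError` naming the stage; outputs
    of earlier stages are preserved.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sep, ext = config.sep, ("tsv" if config.sep == "\t" else "csv")
    manifest = RunManifest(
        seed=config.mosaic.seed,
        config=dataclasses.asdict(config),
        versions={
            "mosaicweb": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    )

    def emit(name: str, path: Path, n_rows: int) -> None:
        manifest.outputs[name] = {"path": str(path), "sha256": _checksum(path)}
        manifest.row_counts[name] = n_rows

    state: dict = {}

    def stage(name):
        def wrap(fn):
            start = time.perf_counter()
            try:
                fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            manifest.stage_seconds[name] = round(time.perf_counter() - start, 3)
            logger.info("stage %s done in %.2fs", name, manifest.stage_seconds[name])
        return wrap

    @stage("simulate")
    def _simulate():
        units, truth = generate_mosaic(config.mosaic)
        state["units"] = units
        path = out / f"units.{ext}"
        write_records(units, path, sep=sep)
        emit("units", path, sum(u.matrix.n_links for u in units))
        tpath = out / "truth.json"
        tpath.write_text(json.dumps(
            {
                "config": dataclasses.asdict(truth.config),
                "species": [dataclasses.asdict(s) for s in truth.species],
                "intended_specialists": {
                    str(k): v for k, v in truth.intended_specialists.items()
                },
            },
            indent=2, sort_keys=True, default=str,
        ))
        emit("truth", tpath, len(truth.species))

    @stage("admission")
    def _admission():
        units = state["units"]
        log = pd.DataFrame(
            [
                {
                    "unit": u.unit_id,
                    "P": u.matrix.n_plants,
                    "A": u.matrix.n_insects,
                    "admitted": admit_unit(u),
                }
                for u in units
            ]
        )
        path = out / f"admission.{ext}"
        log.to_csv(path, sep=sep, index=False)
        state["admitted"] = admitted(units)
        emit("admission", path, len(log))

    @stage("metrics")
    def _metrics():
        table = metrics_table(state["admitted"])
        state["metrics"] = table
        path = out / f"metrics_units.{ext}"
        table.to_csv(path, sep=sep, index=False)
        emit("metrics_units", path, len(table))

    @stage("cumulative")
    def _cumulative():
        units = state["units"]
        for axis, name in (("altitude", "metrics_by_altitude"),
                           ("month", "metrics_by_month"),
                           ("all", "metrics_global")):
            pooled = admitted(pool(units, by=axis))
            table = metrics_table(pooled)
            state[name] = table
            path = out / f"{name}.{ext}"
            table.to_csv(path, sep=sep, index=False)
            emit(name, path, len(table))

    @stage("nullcompare")
    def _nulls():
        spec = null_models.NullEnsembleSpec(
            replicates=config.null_replicates,
            seed=_derive_seed(config.mosaic.seed, "null"),
            indices=config.null_indices,
        )
        table = null_models.null_table(state["admitted"], spec)
        path = out / f"null_comparisons.{ext}"
        table.to_csv(path, sep=sep, index=False)
        emit("null_comparisons", path, len(table))

    @stage("turnover")
    def _turnover():
        units = state["units"]
        for side in ("plant", "insect"):
            samples = turnover.abundance_table(units, side)
            diss = turnover.dissimilarity_matrix(samples)
            path = out / f"dissimilarity_{side}.{ext}"
            diss.to_csv(path, sep=sep)
            emit(f"dissimilarity_{side}", path, len(diss))
            # SIMPER between the two elevation bands
            low = [u.unit_id for u in units if u.altitude <= config.band_boundary]
            high = [u.unit_id for u in units if u.altitude > config.band_boundary]
            if low and high:
                result = turnover.simper(samples, low, high)
                path = out / f"simper_{side}_bands.{ext}"
                result.table.to_csv(path, sep=sep, index=False)
                emit(f"simper_{side}_bands", path, len(result.table))
        profiles = turnover.occupancy(units)
        occ = pd.DataFrame(
            [
                {
                    "species": p.species,
                    "side": p.side,
                    "span_months": p.span_months,
                    "span_altitudes": p.span_altitudes,
                }
                for p in profiles
            ]
        )
        path = out / f"occupancy.{ext}"
        occ.to_csv(path, sep=sep, index=False)
        emit("occupancy", path, len(occ))
        links = turnover.interaction_turnover(units)
        path = out / f"link_occurrences.{ext}"
        links.occurrence_table.to_csv(path, sep=sep, index=False)
        emit("link_occurrences", path, len(links.occurrence_table))
        summary = pd.DataFrame(
            [
                {
                    "unique_fraction_altitude": links.unique_fraction_altitude,
                    "unique_fraction_month": links.unique_fraction_month,
                    "total_records": links.total_records,
                }
            ]
        )
        path = out / f"link_turnover_summary.{ext}"
        summary.to_csv(path, sep=sep, index=False)
        emit("link_turnover_summary", path, 1)

    @stage("inference")
    def _inference():
        table = state["metrics"]
        frames = []
        for factor, column in (("altitude", "altitude"), ("time", "month")):
            sizes = table.groupby(column).size()
            if len(sizes) < 2 or (sizes < 2).any():
                logger.info("skipping %s-factor tests: fewer than two usable levels",
                            factor)
                continue
            frames.append(inference.factor_table(
                inference.factor_effects(table, factor,  # type: ignore[arg-type]
                                         alpha_assume=config.alpha_assume)
            ))
        if frames:
            factor_report = pd.concat(frames, ignore_index=True)
            path = out / f"factor_effects.{ext}"
            factor_report.to_csv(path, sep=sep, index=False)
            emit("factor_effects", path, len(factor_report))
        low = table[table["altitude"] <= config.band_boundary]
        high = table[table["altitude"] > config.band_boundary]
        if len(low) >= 2 and len(high) >= 2:
            band_report = inference.band_table(
                inference.band_contrast(table, config.band_boundary,
                                        alpha_assume=config.alpha_assume)
            )
            path = out / f"band_contrasts.{ext}"
            band_report.to_csv(path, sep=sep, index=False)
            emit("band_contrasts", path, len(band_report))
        # polynomial fits of each metric on altitude (deg 1) and precipitation (deg 2)
        fits = []
        for metric in ("P", "A", "S", "M", "I", "C", "L", "NODF",
                       "pct_spec_P", "pct_spec_A"):
            for predictor, degree in (("altitude", 1), ("precipitation", 2)):
                x = table[predictor].to_numpy(dtype=float)
                if np.ptp(x) == 0 or len(x) <= degree + 1:
                    continue
                fit = inference.fit_polynomial(
                    table[metric].to_numpy(dtype=float), x, degree,  # type: ignore[arg-type]
                    metric, predictor,
                )
                fits.append(
                    {
                        "response": fit.response,
                        "predictor": fit.predictor,
                        "degree": fit.degree,
                        "coefficients": ";".join(f"{b:.6g}" for b in fit.coefficients),
                        "r_squared": fit.r_squared,
                        "f_statistic": fit.f_statistic,
                        "p": fit.p_value,
                        "curvature": fit.curvature,
                    }
                )
        path = out / f"regressions.{ext}"
        pd.DataFrame(fits).to_csv(path, sep=sep, index=False)
        emit("regressions", path, len(fits))
        # individual vs cumulative comparison
        cum_alt = state["metrics_by_altitude"]
        cum_month = state["metrics_by_month"]
        if len(cum_alt) and len(cum_month):
            comparison = inference.individual_vs_cumulative(table, cum_alt, cum_month)
            path = out / f"individual_vs_cumulative.{ext}"
            comparison.to_csv(path, sep=sep, index=False)
            emit("individual_vs_cumulative", path, len(comparison))

    manifest_path = out / "manifest.json"
    manifest_path.write_text(manifest.to_json())
    logger.info("wrote %s", manifest_path)
    return manifest
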