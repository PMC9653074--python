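"""End-to-end pipeline orchestration and provenance.

Runs simulate → index → density → aggregate → analyze against one
output directory, writing every intermediate artifact (CSV tables,
ASCII-grid surfaces, results tables) plus a provenance JSON with the
config hash, seed and library versions. Stages are plain functions
over files, so running them individually through the CLI produces the
same artifacts as :func:`run_pipeline`. Reruns with identical config
and seed are bit-identical except the provenance timestamp.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Any, Mapping

import pandas as pd

from . import __version__
from .analysis import run_full_analysis
from .deprivation import assign_quintiles, compute_deprivation
from .density import DensityConfig, kde_surface
from .exposure import aggregate_tra
from .ledger import CleaningLedger, summarize_ledger
from .raster import write_ascii_grid
from .synthetic import (
    ALL_TYPES,
    RETAILER_TYPES,
    IndicatorGradient,
    IntensityParams,
    SyntheticCityConfig,
    generate_city,
    write_city,
)

__all__ = ["city_config_from_dict", "density_config_from_dict", "run_pipeline"]

log = logging.getLogger("tobaccoscape")


def city_config_from_dict(section: Mapping[str, Any] | None, seed: int) -> SyntheticCityConfig:
    """Build a city config from a YAML-style mapping, filling defaults."""
    section = dict(section or {})
    kwargs: dict[str, Any] = {"seed": seed}
    for key in (
        "extent_m",
        "n_communities",
    ):
        if key in section:
            kwargs[key] = section[key]
    for key in ("ring_radii_m", "subcommunities_per_community", "population_range"):
        if key in section:
            kwargs[key] = tuple(section[key])
    if "deprivation_gradient" in section:
        kwargs["deprivation_gradient"] = {
            name: IndicatorGradient(**params)
            for name, params in section["deprivation_gradient"].items()
        }
    if "intensity_params" in section:
        kwargs["intensity_params"] = {
            rtype: IntensityParams(
                baseline=dict(params["baseline"]),
                deprivation_effect=dict(params["deprivation_effect"]),
            )
            for rtype, params in section["intensity_params"].items()
        }
    return SyntheticCityConfig(**kwargs)


def density_config_from_dict(
    section: Mapping[str, Any] | None,
    extent: tuple[float, float, float, float] | None = None,
) -> DensityConfig:
    section = dict(section or {})
    return DensityConfig(
        bandwidth_m=section.get("bandwidth_m", 800.0),
        cell_size_m=section.get("cell_size_m", 100.0),
        kernel=section.get("kernel", "quartic"),
        extent=extent,
    )


def _config_hash(config: Mapping[str, Any]) -> str:
    canonical = json.dumps(config, sort_keys=True, default=_jsonable)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return dataclasses.asdict(obj)
    if isinstance(obj, Mapping):
        return dict(obj)
    if isinstance(obj, tuple):
        return list(obj)
    return str(obj)


def run_pipeline(
    config: Mapping[str, Any] | None,
    seed: int,
    out_dir: str | Path,
    bootstrap_reps: int | None = None,
) -> dict[str, Path]:
    """Simulate a city and run every downstream stage.

    Parameters
    ----------
    config
        Mapping with optional ``simulate``, ``density`` and ``analyze``
        sections (YAML-file shape); missing sections use defaults.
    seed
        Master seed for simulation and the analysis bootstrap.
    out_dir
        Output root; created if needed.

    Returns mapping of artifact name -> path.
    """
    t0 = time.time()
    config = dict(config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    city_cfg = city_config_from_dict(config.get("simulate"), seed)
    ledger = CleaningLedger()

    log.info("stage simulate: generating synthetic city (seed=%d)", seed)
    communities, subcommunities, retailers = generate_city(city_cfg)
    paths.update(write_city(out, communities, subcommunities, retailers))
    ledger.add_step("simulate", len(retailers), 0)
    log.info(
        "stage simulate: %d communities, %d subcommunities, %d retailers",
        len(communities), len(subcommunities), len(retailers),
    )

    log.info("stage index: deprivation score and quintiles")
    indexed = assign_quintiles(compute_deprivation(communities))
    paths["communities_indexed"] = out / "communities_indexed.csv"
    indexed.to_csv(paths["communities_indexed"], index=False)
    ledger.add_step("index", len(retailers), 0)

    extent = (0.0, 0.0, city_cfg.extent_m, city_cfg.extent_m)
    dens_cfg = density_config_from_dict(config.get("density"), extent=extent)
    log.info("stage density: rasterising surfaces (bandwidth %.0f m)", dens_cfg.bandwidth_m)
    for rtype in RETAILER_TYPES + (ALL_TYPES,):
        pts = retailers if rtype == ALL_TYPES else retailers.loc[retailers["retailer_type"] == rtype]
        surface = kde_surface(pts, dens_cfg, retailer_type=rtype)
        paths[f"surface_{rtype}"] = write_ascii_grid(surface, out / f"surface_{rtype}.asc")

    log.info("stage aggregate: population-weighted availability")
    exposure = aggregate_tra(subcommunities, retailers=retailers, config=dens_cfg)
    paths["exposure"] = out / "exposure.csv"
    exposure.to_csv(paths["exposure"], index=False)
    ledger.add_step("aggregate", len(retailers), 0)

    log.info("stage analyze: stratified rank statistics")
    analyze_cfg = dict(config.get("analyze") or {})
    reps = bootstrap_reps if bootstrap_reps is not None else analyze_cfg.get("bootstrap_reps", 1000)
    results = run_full_analysis(exposure, indexed, bootstrap_reps=reps, seed=seed)
    paths["table1"] = out / "table1.csv"
    paths["table2"] = out / "table2.csv"
    results.table1.to_csv(paths["table1"], index=False)
    results.table2.to_csv(paths["table2"], index=False)
    paths["summary"] = out / "summary.txt"
    paths["summary"].write_text(results.summary() + "\n", encoding="utf-8")

    paths["ledger"] = out / "ledger.csv"
    summarize_ledger(ledger).to_csv(paths["ledger"], index=False)

    provenance = {
        "package": "tobaccoscape",
        "version": __version__,
        "seed": seed,
        "config_hash": _config_hash(config),
        "bootstrap_reps": reps,
        "n_communities": len(communities),
        "n_subcommunities": len(subcommunities),
        "n_retailers": len(retailers),
        "versions": _library_versions(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "elapsed_s": round(time.time() - t0, 3),
    }
    paths["provenance"] = out / "provenance.json"
    paths["provenance"].write_text(json.dumps(provenance, indent=2) + "\n", encoding="utf-8")
    log.info("pipeline complete in %.1f s", time.time() - t0)
    return paths


def _library_versions() -> dict[str, str]:
    import numpy
    import scipy

    return {"numpy": numpy.__version__, "scipy": scipy.__version__, "pandas": pd.__version__}
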