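"""One-step multi-species range mapping (the "easy" pipeline).

Runs the selected mapping mode for every species in a multi-species
occurrence table, writes the map in ESRI ASCII, image and KML formats,
and collects EOO, AOO and occupied countries into one summary table.
Species whose data cannot support the requested mode are logged and
skipped, never fatal — real assessment batches always contain a few
single-record species.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd

from .errors import DataError, RedlistingError
from .io_export import draw_map, write_kml
from .occurrences import OccurrenceSet
from .qc import move_to_valid
from .range_metrics import countries_of
from .raster import RasterLayer, RasterStack, write_ascii_grid
from .raster_ops import map_habitat
from .sdm import consensus_map, map_points, run_ensemble

log = logging.getLogger("redlisting")

MODES = ("points", "habitat", "sdm")


def _map_one(
    records: OccurrenceSet,
    layers: RasterStack,
    mode: str,
    habitat: RasterLayer | None,
    runs: int,
    seed,
) -> tuple[RasterLayer, float, float]:
    if mode == "points":
        layer, rv = map_points(records, layers)
        return layer, rv.eoo_km2, rv.aoo_km2
    if mode == "habitat":
        if habitat is None:
            raise DataError("habitat mode needs a binary habitat layer")
        res = map_habitat(records, habitat, move=True)
        return res.presence, res.modelled.eoo_km2, res.modelled.aoo_km2
    if mode == "sdm":
        if len(records) < 8:
            raise DataError(f"too few records ({len(records)}) for SDM")
        recs = move_to_valid(records, layers.quantitative())
        ens = consensus_map(run_ensemble(recs, layers, runs=runs, seed=seed))
        return ens.consensus, ens.consensus_range.eoo_km2, ens.consensus_range.aoo_km2
    raise DataError(f"unknown mode {mode!r}")


def map_easy(
    species_records: dict[str, OccurrenceSet],
    layers: RasterStack,
    mode: str = "points",
    output_dir=".",
    habitat: RasterLayer | None = None,
    boundaries=None,
    runs: int = 10,
    seed=None,
    image_format: str = "png",
) -> pd.DataFrame:
    """Map every species and write per-species files plus a summary CSV.

    Writes ``<species>.asc``, ``<species>.<image_format>`` and
    ``<species>.kml`` (KML only for geographic grids or when the layers
    carry no projection is skipped with a note) into ``output_dir`` and
    returns the summary table (species, eoo_km2, aoo_km2, countries),
    also written as ``summary.csv``.  Failures are recorded as NA rows.
    """
    if mode not in MODES:
        raise DataError(f"mode must be one of {MODES}")
    out = Path(output_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as e:
        raise DataError(f"output directory {out} is not writable: {e}") from e

    rows = []
    for sp, recs in species_records.items():
        safe = "".join(ch if ch.isalnum() or ch in "._-" else "_" for ch in sp)
        try:
            layer, eoo_km2, aoo_km2 = _map_one(recs, layers, mode, habitat, runs, seed)
            write_ascii_grid(layer, out / f"{safe}.asc")
            draw_map(recs, layer, out / f"{safe}.{image_format}")
            if layer.crs == "geographic":
                write_kml(layer, out / f"{safe}.kml", name=sp)
            else:
                proj = getattr(recs, "projection", None)
                write_kml(layer, out / f"{safe}.kml", projection=proj, name=sp) if proj else _kml_stub(
                    out / f"{safe}.kml", layer, sp
                )
            countries = (
                ";".join(countries_of(layer, boundaries)) if boundaries is not None else ""
            )
            rows.append({"species": sp, "eoo_km2": eoo_km2, "aoo_km2": aoo_km2, "countries": countries})
            log.info("map_easy species=%s mode=%s eoo=%.1f aoo=%.1f", sp, mode, eoo_km2, aoo_km2)
        except RedlistingError as e:
            log.warning("map_easy species=%s skipped: %s", sp, e)
            rows.append({"species": sp, "eoo_km2": None, "aoo_km2": None, "countries": None})
    summary = pd.DataFrame(rows)
    summary.to_csv(out / "summary.csv", index=False)
    return summary


def _kml_stub(path, layer, name):
    """Metric grid with no geographic reference: write cell polygons in map units.

    Google Earth cannot place these, but the file is still a
    well-formed document recording the range geometry.
    """
    from .io_export import presence_polygons

    write_kml(presence_polygons(layer), path, name=name)
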