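"""Readers and writers for the formats regions and results travel in.

Regions arrive as three GeoJSON files — block centroids and physician
locations as Point features, roads as LineString features — in one planar
projected coordinate system (meters).  Files that declare a geographic
CRS (WGS84 / CRS84 / EPSG:4326) are rejected outright: this toolkit does
Euclidean math in meters and reprojection is out of scope.

Results leave as GeoJSON (for GIS viewers) with a flat CSV twin, plus CSV
tables for the ODCM, eligibility, demand and access stages so the command
line stages can be chained through files.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Any

from shapely.geometry import shape

from .classify import ClassifiedSurface
from .gravity import AccessSurface, DemandTable
from .network import EligibilityReport, TravelTimeMatrix
from .region import (
    DisseminationBlock,
    PhysicianLocation,
    Region,
    RegionValidationError,
    RoadSegment,
)

__all__ = [
    "read_region",
    "write_region",
    "write_scores",
    "read_scores",
    "write_odcm",
    "read_odcm",
    "write_eligibility",
    "write_demand",
    "write_access",
    "read_access",
    "write_classified",
    "write_breaks",
]

_GEOGRAPHIC_CRS_TOKENS = ("4326", "CRS84", "WGS84", "WGS 84")

#: Decimal places kept for coordinates (mm) and scores on write.
COORD_DECIMALS = 3
SCORE_DECIMALS = 12


def _load_feature_collection(path: str | Path) -> list[dict]:
    with open(path) as fh:
        obj = json.load(fh)
    if obj.get("type") != "FeatureCollection":
        raise RegionValidationError(f"{path}: not a GeoJSON FeatureCollection")
    crs = obj.get("crs")
    if crs is not None:
        name = str(crs.get("properties", {}).get("name", crs))
        if any(tok in name.upper() for tok in _GEOGRAPHIC_CRS_TOKENS):
            raise RegionValidationError(
                f"{path}: declares geographic CRS {name!r}; coordinates must "
                "be planar projected meters (reprojection is not performed)"
            )
    return obj.get("features", [])


def _feature_point(feat: dict, path: str | Path, fid: str) -> tuple[float, float]:
    geom = feat.get("geometry") or {}
    if geom.get("type") != "Point":
        raise RegionValidationError(
            f"{path}: feature {fid!r} has geometry {geom.get('type')!r}, "
            "expected Point"
        )
    try:
        pt = shape(geom)
    except Exception as exc:  # malformed coordinates
        raise RegionValidationError(
            f"{path}: feature {fid!r} has malformed geometry: {exc}"
        ) from exc
    return float(pt.x), float(pt.y)


def _feature_id(feat: dict, idx: int) -> str:
    props = feat.get("properties") or {}
    fid = props.get("id", feat.get("id"))
    return str(fid) if fid is not None else f"<feature #{idx}>"


def read_region(
    blocks_path: str | Path,
    physicians_path: str | Path,
    roads_path: str | Path,
    crs_note: str = "planar meters (unspecified projection)",
) -> Region:
    """Read and validate a region from its three GeoJSON files.

    Missing optional road attributes are filled with documented defaults:
    ``speed_kmh`` 50, ``direction`` ``both``, ``length_m`` the polyline's
    Euclidean length.  Every type invariant is checked at read time and
    raises :class:`RegionValidationError` naming the offending feature.
    """
    blocks = []
    for i, feat in enumerate(_load_feature_collection(blocks_path)):
        fid = _feature_id(feat, i)
        props = feat.get("properties") or {}
        x, y = _feature_point(feat, blocks_path, fid)
        for key in ("population", "area_km2"):
            if key not in props:
                raise RegionValidationError(
                    f"{blocks_path}: block {fid!r} missing property {key!r}"
                )
        blocks.append(
            DisseminationBlock(
                id=fid, x=x, y=y,
                population=float(props["population"]),
                area_km2=float(props["area_km2"]),
            )
        )

    physicians = []
    for i, feat in enumerate(_load_feature_collection(physicians_path)):
        fid = _feature_id(feat, i)
        props = feat.get("properties") or {}
        x, y = _feature_point(feat, physicians_path, fid)
        if "supply" not in props:
            raise RegionValidationError(
                f"{physicians_path}: physician {fid!r} missing property 'supply'"
            )
        physicians.append(
            PhysicianLocation(id=fid, x=x, y=y, supply=int(props["supply"]))
        )

    roads = []
    for i, feat in enumerate(_load_feature_collection(roads_path)):
        fid = _feature_id(feat, i)
        props = feat.get("properties") or {}
        geom = feat.get("geometry") or {}
        if geom.get("type") != "LineString":
            raise RegionValidationError(
                f"{roads_path}: road {fid!r} has geometry {geom.get('type')!r}, "
                "expected LineString"
            )
        coords = geom.get("coordinates") or []
        roads.append(
            RoadSegment.with_default_length(
                id=fid,
                polyline=[(float(x), float(y)) for x, y in coords],
                speed_kmh=float(props.get("speed_kmh", 50.0)),
                direction=str(props.get("direction", "both")),
                length_m=(
                    float(props["length_m"]) if "length_m" in props else None
                ),
            )
        )

    return Region(blocks=blocks, physicians=physicians, roads=roads,
                  crs_note=crs_note)


def _fc(features: list[dict]) -> dict:
    return {"type": "FeatureCollection", "features": features}


def _dump(obj: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)
        fh.write("\n")


def write_region(region: Region, out_dir: str | Path) -> dict[str, Path]:
    """Write a region as blocks/physicians/roads GeoJSON under ``out_dir``."""
    out = Path(out_dir)
    paths = {
        "blocks": out / "blocks.geojson",
        "physicians": out / "physicians.geojson",
        "roads": out / "roads.geojson",
    }
    c = COORD_DECIMALS
    _dump(_fc([
        {
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [round(b.x, c), round(b.y, c)]},
            "properties": {"id": b.id, "population": b.population,
                           "area_km2": b.area_km2},
        }
        for b in region.blocks
    ]), paths["blocks"])
    _dump(_fc([
        {
            "type": "Feature",
            "geometry": {"type": "Point",
                         "coordinates": [round(p.x, c), round(p.y, c)]},
            "properties": {"id": p.id, "supply": p.supply},
        }
        for p in region.physicians
    ]), paths["physicians"])
    _dump(_fc([
        {
            "type": "Feature",
            "geometry": {
                "type": "LineString",
                "coordinates": [[round(x, c), round(y, c)]
                                for x, y in r.polyline],
            },
            "properties": {"id": r.id, "length_m": round(r.length_m, c),
                           "speed_kmh": r.speed_kmh, "direction": r.direction},
        }
        for r in region.roads
    ]), paths["roads"])
    return paths


def write_scores(
    region: Region,
    surface: AccessSurface,
    out_path: str | Path,
    classified: ClassifiedSurface | None = None,
) -> Path:
    """Write per-block scores as GeoJSON Points plus a flat CSV twin.

    The GeoJSON goes to ``out_path``; the CSV twin next to it with a
    ``.csv`` suffix.  Each feature carries the block id, population,
    access score (absent for excluded blocks), status, and — when a
    classification is supplied — the mapping class label.

    Raises
    ------
    ValueError
        If the surface does not cover exactly the region's block ids.
    """
    region_ids = {b.id for b in region.blocks}
    surface_ids = set(surface.status)
    if region_ids != surface_ids:
        orphans = sorted(region_ids ^ surface_ids)
        raise ValueError(f"surface/region block id mismatch: {orphans}")

    feats = []
    rows = []
    for b in region.blocks:
        st = surface.status[b.id]
        access = surface.scores.get(b.id)
        cls = classified.labels.get(b.id, "") if classified is not None else ""
        if cls in ("no_access", "excluded"):
            cls = ""  # the status column already says so
        props: dict[str, Any] = {
            "id": b.id,
            "population": b.population,
            "status": st,
        }
        if access is not None:
            props["access"] = round(access, SCORE_DECIMALS)
        if cls:
            props["class"] = cls
        feats.append({
            "type": "Feature",
            "geometry": {
                "type": "Point",
                "coordinates": [round(b.x, COORD_DECIMALS),
                                round(b.y, COORD_DECIMALS)],
            },
            "properties": props,
        })
        rows.append({
            "block_id": b.id,
            "population": b.population,
            "access": "" if access is None else repr(round(access, SCORE_DECIMALS)),
            "status": st,
            "class": cls,
        })

    out_path = Path(out_path)
    _dump(_fc(feats), out_path)
    csv_path = out_path.with_suffix(".csv")
    with open(csv_path, "w", newline="") as fh:
        w = csv.DictWriter(
            fh, fieldnames=["block_id", "population", "access", "status", "class"]
        )
        w.writeheader()
        w.writerows(rows)
    return out_path


def read_scores(path: str | Path) -> list[dict]:
    """Read a scores GeoJSON back into flat records (round-trip support)."""
    records = []
    for feat in _load_feature_collection(path):
        props = dict(feat.get("properties") or {})
        x, y = feat["geometry"]["coordinates"]
        props["x"], props["y"] = float(x), float(y)
        records.append(props)
    return records


def write_odcm(odcm: TravelTimeMatrix, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["block_id", "physician_id", "minutes"])
        for (bid, pid), t in sorted(odcm.entries.items()):
            w.writerow([bid, pid, repr(t)])
    return path


def read_odcm(path: str | Path, cutoff_min: float = 120.0) -> TravelTimeMatrix:
    entries: dict[tuple[str, str], float] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            entries[(row["block_id"], row["physician_id"])] = float(row["minutes"])
    return TravelTimeMatrix(entries=entries, cutoff_min=cutoff_min)


def write_eligibility(report: EligibilityReport, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["entity_type", "id", "status"])
        for bid, st in sorted(report.block_status.items()):
            w.writerow(["block", bid, st])
        for pid, st in sorted(report.physician_status.items()):
            w.writerow(["physician", pid, st])
    return path


def write_demand(demand: DemandTable, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["physician_id", "demand"])
        for pid, d in sorted(demand.demand.items()):
            w.writerow([pid, repr(d)])
    return path


def write_access(surface: AccessSurface, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["block_id", "access", "status"])
        for bid in sorted(surface.status):
            st = surface.status[bid]
            score = surface.scores.get(bid)
            w.writerow([bid, "" if score is None else repr(score), st])
    return path


def read_access(path: str | Path) -> AccessSurface:
    scores: dict[str, float] = {}
    status: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            status[row["block_id"]] = row["status"]
            if row["access"] != "":
                scores[row["block_id"]] = float(row["access"])
    return AccessSurface(scores=scores, status=status)


def write_classified(
    surface: AccessSurface, classified: ClassifiedSurface, path: str | Path
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["block_id", "access", "status", "class"])
        for bid in sorted(classified.labels):
            label = classified.labels[bid]
            score = surface.scores.get(bid)
            st = surface.status.get(bid, label)
            cls = "" if label in ("no_access", "excluded") else label
            w.writerow([bid, "" if score is None else repr(score), st, cls])
    return path


def write_breaks(classified: ClassifiedSurface, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump({"k": classified.k, "breaks": classified.breaks}, fh, indent=1)
        fh.write("\n")
    return path
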