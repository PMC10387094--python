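"""Species range geometry: reading, filtering, projecting, and measuring.

Ranges are species distribution polygons.  Sympatry between two species is
quantified by the area of intersection of their (dissolved, projected)
ranges; the full pairwise table is the :class:`OverlapMatrix`, whose
diagonal holds range sizes.  Areas are planar areas in km^2 after the
cylindrical equal-area projection, which maps longitude/latitude on the
authalic sphere to ``x = R * lon_rad``, ``y = R * sin(lat_rad)`` and
preserves area exactly, avoiding the systematic inflation of high-latitude
ranges that a plate-carree treatment would produce.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "GeometryError",
    "FilterSpec",
    "LoadReport",
    "RangePolygonSet",
    "OverlapMatrix",
    "DistributionSummary",
    "AUTHALIC_RADIUS_KM",
    "load_ranges",
    "project_equal_area",
    "compute_overlap_matrix",
    "summarize_distributions",
    "write_geojson",
]

#: Radius of the sphere with the same surface area as the WGS84 ellipsoid.
AUTHALIC_RADIUS_KM = 6371.0071809

CRS_GEOGRAPHIC = "lonlat-degrees"
CRS_CEA_KM = "cea-km"


class GeometryError(ValueError):
    """Raised for unreadable files, bad coordinates, or missing attributes."""


@dataclass(frozen=True)
class FilterSpec:
    """Which per-feature attribute codes to exclude before dissolving.

    Red-List-style range features carry presence and origin codes; features
    whose presence is uncertain or whose origin is an introduction are not
    part of the natural pattern of sympatry and are dropped.  The exact
    code vocabularies differ between datasets, so they are configuration:
    the defaults match the synthetic generator's string codes, and numeric
    code sets (e.g. presence 6 = presence uncertain, origin 3 = introduced)
    can be supplied for real data.
    """

    presence_field: str = "presence"
    origin_field: str = "origin"
    exclude_presence: frozenset = frozenset({"uncertain", "possibly_extinct"})
    exclude_origin: frozenset = frozenset({"introduced"})

    def excludes(self, props: dict) -> bool:
        for fieldname, codes in (
            (self.presence_field, self.exclude_presence),
            (self.origin_field, self.exclude_origin),
        ):
            if fieldname not in props:
                raise GeometryError(
                    f"feature is missing attribute field {fieldname!r} "
                    "required by the filter spec"
                )
            if _normcode(props[fieldname]) in {_normcode(c) for c in codes}:
                return True
        return False


def _normcode(code) -> str:
    return str(code).strip().lower()


@dataclass
class LoadReport:
    n_features_read: int = 0
    n_features_dropped: int = 0
    n_features_repaired: int = 0
    species_all_excluded: list[str] = field(default_factory=list)


@dataclass
class RangePolygonSet:
    """One dissolved multipolygon per species, plus a projection descriptor.

    ``geoms`` preserves insertion order; ``features`` optionally retains
    the raw per-feature records (species_id/presence/origin/geometry) for
    round-tripping through GeoJSON.
    """

    geoms: dict[str, BaseGeometry]
    crs: str = CRS_GEOGRAPHIC
    report: LoadReport | None = None
    features: list[dict] | None = None

    @property
    def species(self) -> tuple[str, ...]:
        return tuple(self.geoms)

    def __len__(self) -> int:
        return len(self.geoms)

    def areas(self) -> pd.Series:
        """Range size of each species (planar area; km^2 under cea-km)."""
        return pd.Series(
            {sp: g.area for sp, g in self.geoms.items()}, name="area"
        )


def load_ranges(
    path: str | os.PathLike,
    filter_spec: FilterSpec | None = FilterSpec(),
    *,
    species_field: str = "species_id",
    crs: str = CRS_GEOGRAPHIC,
) -> RangePolygonSet:
    """Read a GeoJSON FeatureCollection of range features and dissolve to
    one valid multipolygon per species.

    Features failing ``filter_spec`` are dropped before the per-species
    union; invalid geometries (e.g. self-intersecting rings, common in
    digitized range maps) are deterministically repaired with
    ``shapely.make_valid``.  Pass ``filter_spec=None`` to keep everything.
    """
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (OSError, json.JSONDecodeError) as exc:
        raise GeometryError(f"cannot read GeoJSON {path!s}: {exc}") from exc
    features = doc.get("features")
    if features is None:
        raise GeometryError(f"{path!s} is not a FeatureCollection")

    report = LoadReport()
    by_species: dict[str, list[BaseGeometry]] = {}
    species_seen: list[str] = []
    for feat in features:
        report.n_features_read += 1
        props = feat.get("properties") or {}
        if species_field not in props:
            raise GeometryError(
                f"feature is missing the {species_field!r} attribute"
            )
        sp = str(props[species_field])
        if sp not in by_species:
            by_species[sp] = []
            species_seen.append(sp)
        if filter_spec is not None and filter_spec.excludes(props):
            report.n_features_dropped += 1
            continue
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            geom = shapely.make_valid(geom)
            report.n_features_repaired += 1
        by_species[sp].append(geom)

    geoms: dict[str, BaseGeometry] = {}
    for sp in species_seen:
        parts = by_species[sp]
        if not parts:
            report.species_all_excluded.append(sp)
            continue
        merged = shapely.union_all(parts)
        if not merged.is_valid:  # pragma: no cover - union_all output is valid
            merged = shapely.make_valid(merged)
        geoms[sp] = merged
    logger.info(
        "load_ranges: %d features read, %d dropped by filter, %d repaired, "
        "%d species retained, %d species fully excluded",
        report.n_features_read,
        report.n_features_dropped,
        report.n_features_repaired,
        len(geoms),
        len(report.species_all_excluded),
    )
    return RangePolygonSet(geoms, crs=crs, report=report)


# ---------------------------------------------------------------------
# Equal-area projection
# ---------------------------------------------------------------------


def project_equal_area(
    ranges: RangePolygonSet,
    *,
    radius_km: float = AUTHALIC_RADIUS_KM,
    standard_parallel: float = 0.0,
    densify_deg: float = 0.25,
) -> RangePolygonSet:
    """Project geographic ranges with the cylindrical equal-area projection.

    With standard parallel phi_s, a point (lon, lat) in degrees maps to
    ``x = R cos(phi_s) lon_rad``, ``y = R sin(lat_rad) / cos(phi_s)`` (km).
    The map is exactly area-preserving on the sphere; polygon edges are
    densified to ``densify_deg`` beforehand so that the straight chords of
    the projected polygon track the projected boundary curve closely.
    """
    if ranges.crs != CRS_GEOGRAPHIC:
        raise GeometryError(
            f"project_equal_area expects {CRS_GEOGRAPHIC!r} input, got {ranges.crs!r}"
        )
    k0 = math.cos(math.radians(standard_parallel))

    def _fwd(coords: np.ndarray) -> np.ndarray:
        lon = coords[:, 0]
        lat = coords[:, 1]
        if np.any((lon < -180 - 1e-9) | (lon > 180 + 1e-9)):
            raise GeometryError("longitude outside [-180, 180]")
        if np.any((lat < -90 - 1e-9) | (lat > 90 + 1e-9)):
            raise GeometryError("latitude outside [-90, 90]")
        x = radius_km * k0 * np.radians(lon)
        y = radius_km * np.sin(np.radians(np.clip(lat, -90.0, 90.0))) / k0
        return np.column_stack([x, y])

    out: dict[str, BaseGeometry] = {}
    for sp, geom in ranges.geoms.items():
        dens = shapely.segmentize(geom, max_segment_length=densify_deg)
        out[sp] = shapely.transform(dens, _fwd)
    return RangePolygonSet(out, crs=CRS_CEA_KM, report=ranges.report)


# ---------------------------------------------------------------------
# Overlap matrix
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class OverlapMatrix:
    """Symmetric species-by-species matrix of range intersection areas.

    ``matrix[i, j]`` is the area shared by species i and j; the diagonal
    holds range sizes, so every off-diagonal entry is bounded by the
    smaller of the two diagonal entries it connects.
    """

    species: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.species), len(self.species)):
            raise GeometryError("overlap matrix shape mismatch")
        object.__setattr__(self, "matrix", m)
        self.validate()

    def validate(self, atol_scale: float = 1e-9) -> None:
        m = self.matrix
        scale = max(1.0, float(np.abs(m).max()))
        if not np.allclose(m, m.T, rtol=0, atol=atol_scale * scale):
            raise GeometryError("overlap matrix is not symmetric")
        if np.any(m.diagonal() < 0):
            raise GeometryError("negative range area on the diagonal")
        diag = m.diagonal()
        cap = np.minimum.outer(diag, diag)
        if np.any(m > cap + atol_scale * scale):
            raise GeometryError(
                "an overlap exceeds the smaller of the two range areas"
            )

    @property
    def n(self) -> int:
        return len(self.species)

    def range_sizes(self) -> pd.Series:
        return pd.Series(
            self.matrix.diagonal().copy(),
            index=list(self.species),
            name="area",
        )

    def pairwise_overlaps(self) -> np.ndarray:
        """Upper-triangle off-diagonal entries (each unordered pair once)."""
        iu = np.triu_indices(self.n, k=1)
        return self.matrix[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.matrix, index=list(self.species), columns=list(self.species)
        )

    def to_tsv(self, path: str | os.PathLike) -> None:
        """Long format: species_a, species_b, overlap_km2 (diagonal included)."""
        rows = []
        for i, a in enumerate(self.species):
            for j in range(i, self.n):
                rows.append((a, self.species[j], self.matrix[i, j]))
        pd.DataFrame(rows, columns=["species_a", "species_b", "overlap_km2"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | os.PathLike) -> "OverlapMatrix":
        df = pd.read_csv(path, sep="\t")
        species: list[str] = []
        for col in ("species_a", "species_b"):
            for s in df[col].astype(str):
                if s not in species:
                    species.append(s)
        idx = {s: i for i, s in enumerate(species)}
        m = np.zeros((len(species), len(species)))
        for a, b, v in zip(df["species_a"].astype(str), df["species_b"].astype(str), df["overlap_km2"]):
            m[idx[a], idx[b]] = v
            m[idx[b], idx[a]] = v
        return cls(tuple(species), m)


def compute_overlap_matrix(ranges: RangePolygonSet) -> OverlapMatrix:
    """Pairwise range intersection areas with range sizes on the diagonal.

    Pairs whose bounding boxes are disjoint are skipped (their intersection
    is empty, so the result is identical to the exhaustive computation).
    """
    species = ranges.species
    geoms = [ranges.geoms[sp] for sp in species]
    n = len(species)
    m = np.zeros((n, n))
    bounds = np.array(
        [g.bounds if not g.is_empty else (0.0, 0.0, 0.0, 0.0) for g in geoms]
    )
    for i in range(n):
        m[i, i] = geoms[i].area
    for i in range(n):
        if geoms[i].is_empty:
            continue
        for j in range(i + 1, n):
            if geoms[j].is_empty:
                continue
            if (
                bounds[i, 2] < bounds[j, 0]
                or bounds[j, 2] < bounds[i, 0]
                or bounds[i, 3] < bounds[j, 1]
                or bounds[j, 3] < bounds[i, 1]
            ):
                continue
            area = geoms[i].intersection(geoms[j]).area
            m[i, j] = m[j, i] = area
    return OverlapMatrix(species, m)


# ---------------------------------------------------------------------
# Distribution summaries
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class DistributionSummary:
    """Log-scale summaries of range sizes and positive pairwise overlaps.

    ``overlap_log_mean`` is None (and ``overlap_empty`` True) when no pair
    of species overlaps; log means are natural-log means of the raw data,
    and histograms are computed on the log scale.
    """

    range_log_mean: float
    range_hist: tuple[np.ndarray, np.ndarray]
    overlap_log_mean: float | None
    overlap_hist: tuple[np.ndarray, np.ndarray] | None
    overlap_empty: bool
    n_ranges: int
    n_positive_overlaps: int


def summarize_distributions(
    range_sizes, overlaps, *, bins: int = 30
) -> DistributionSummary:
    """Log-mean and histogram data for range sizes and positive overlaps.

    Zero overlaps (allopatric pairs) are excluded before taking logs, which
    is the only way a log summary of overlaps is defined; an all-zero
    overlap set is flagged rather than raising.
    """
    sizes = np.asarray(range_sizes, dtype=float)
    if sizes.size == 0:
        raise GeometryError("empty range-size input")
    if np.any(sizes <= 0):
        raise GeometryError("range sizes must be positive for a log summary")
    log_sizes = np.log(sizes)
    range_hist = np.histogram(log_sizes, bins=bins)

    ov = np.asarray(overlaps, dtype=float)
    pos = ov[ov > 0]
    if pos.size == 0:
        return DistributionSummary(
            float(log_sizes.mean()),
            range_hist,
            None,
            None,
            True,
            sizes.size,
            0,
        )
    log_ov = np.log(pos)
    return DistributionSummary(
        float(log_sizes.mean()),
        range_hist,
        float(log_ov.mean()),
        np.histogram(log_ov, bins=bins),
        False,
        sizes.size,
        pos.size,
    )


# ---------------------------------------------------------------------
# GeoJSON writing
# ---------------------------------------------------------------------


def _round_coords(obj, ndigits: int):
    if isinstance(obj, (list, tuple)):
        return [_round_coords(v, ndigits) for v in obj]
    if isinstance(obj, float):
        return round(obj, ndigits)
    return obj


def write_geojson(
    features: list[dict],
    path: str | os.PathLike,
    *,
    ndigits: int = 6,
) -> None:
    """Write a FeatureCollection deterministically (sorted keys, fixed
    coordinate precision) so identical inputs give byte-identical files."""
    out_features = []
    for feat in features:
        geom = feat["geometry"]
        if isinstance(geom, BaseGeometry):
            geom = mapping(geom)
        geom = dict(geom)
        geom["coordinates"] = _round_coords(geom["coordinates"], ndigits)
        out_features.append(
            {
                "type": "Feature",
                "properties": feat.get("properties", {}),
                "geometry": geom,
            }
        )
    doc = {"type": "FeatureCollection", "features": out_features}
    with open(path, "w") as fh:
        json.dump(doc, fh, sort_keys=True, separators=(",", ":"))
        fh.write("\n")
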