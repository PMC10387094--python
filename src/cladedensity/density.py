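"""Clade density: phylogenetically weighted sympatry per species.

Clade density of species i is the sum, over the other members of its
higher taxon, of the area of range overlap weighted by phylogenetic
covariance:

    CD_i = sum_{j != i}  O_ij * C_ij

where O is the range-overlap matrix (areas, km^2) and C the phylogenetic
variance-covariance matrix (shared root-path length, time units), both on
an identical ordered species set.  Elementwise multiplication followed by
row sums implements this directly.  Closely related sympatric species
contribute most (large O_ij and large C_ij); fully allopatric species have
CD = 0, as do species whose only sympatric partners diverge at the root
(C_ij = 0).  Units are area x time (km^2 * Myr by default).
"""

from __future__ import annotations

import math
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import OverlapMatrix, RangePolygonSet, write_geojson
from .phylo import VcvMatrix

__all__ = [
    "DensityError",
    "AlignmentReport",
    "CladeDensityTable",
    "BoxplotSummary",
    "TopDecileSelection",
    "align_species",
    "clade_density",
    "top_decile",
    "summarize_density",
    "export_top_decile_geo",
]


class DensityError(ValueError):
    pass


@dataclass(frozen=True)
class AlignmentReport:
    """Species dropped when intersecting geography with the phylogeny."""

    dropped_no_geography: tuple[str, ...]
    dropped_no_tree: tuple[str, ...]


def align_species(
    overlap: OverlapMatrix, vcv: VcvMatrix
) -> tuple[OverlapMatrix, VcvMatrix, AlignmentReport]:
    """Reorder both matrices onto their common species set (tree order).

    Species without geographic information are dropped from the VCV side
    and species absent from the tree are dropped from the overlap side;
    both lists are reported so the loss is visible.
    """
    geo = set(overlap.species)
    tre = set(vcv.species)
    common = [s for s in vcv.species if s in geo]  # deterministic: tree order
    if not common:
        raise DensityError("no species shared between overlap matrix and tree")
    report = AlignmentReport(
        dropped_no_geography=tuple(s for s in vcv.species if s not in geo),
        dropped_no_tree=tuple(s for s in overlap.species if s not in tre),
    )
    o_idx = {s: i for i, s in enumerate(overlap.species)}
    v_idx = {s: i for i, s in enumerate(vcv.species)}
    o_sel = np.array([o_idx[s] for s in common])
    v_sel = np.array([v_idx[s] for s in common])
    o2 = OverlapMatrix(tuple(common), overlap.matrix[np.ix_(o_sel, o_sel)])
    v2 = VcvMatrix(tuple(common), vcv.matrix[np.ix_(v_sel, v_sel)])
    return o2, v2, report


@dataclass(frozen=True)
class CladeDensityTable:
    """Per-species clade density plus the provenance needed to interpret it."""

    species: tuple[str, ...]
    values: np.ndarray = field(repr=False)
    include_self: bool = False
    weight: str = "vcv"
    dropped_no_geography: tuple[str, ...] = ()
    dropped_no_tree: tuple[str, ...] = ()
    tree_id: str | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.species),):
            raise DensityError("clade-density values do not match species list")
        if np.any(v < -1e-12):
            raise DensityError("negative clade density")
        object.__setattr__(self, "values", np.maximum(v, 0.0))

    @property
    def n(self) -> int:
        return len(self.species)

    def series(self) -> pd.Series:
        return pd.Series(
            self.values, index=list(self.species), name="clade_density"
        )

    def to_frame(self) -> pd.DataFrame:
        """Table with rank (1 = highest density) and top-decile flag."""
        s = self.series()
        sel = top_decile(self)
        chosen = set(sel.species)
        return pd.DataFrame(
            {
                "clade_density": s,
                "rank": s.rank(ascending=False, method="min").astype(int),
                "top_decile": [sp in chosen for sp in s.index],
            }
        ).rename_axis("species")

    def to_tsv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, sep="\t")


def clade_density(
    overlap: OverlapMatrix,
    vcv: VcvMatrix,
    *,
    include_self: bool = False,
    weight: str = "vcv",
    area_scale: float = 1.0,
    tree_id: str | None = None,
    alignment: AlignmentReport | None = None,
) -> CladeDensityTable:
    """Row sums of the elementwise product of overlap and phylogenetic
    weight matrices.

    The default weight is the phylogenetic covariance C_ij itself, which
    up-weights close relatives; ``weight="inv-patristic"`` substitutes
    1/d_ij (patristic distance) for sensitivity analysis.  The self term
    O_ii * C_ii is excluded by default: a species' own range contributes
    no information about sympatry with *other* lineages.  ``area_scale``
    divides areas (e.g. 1e6 to report per 10^6 km^2).
    """
    if overlap.species != vcv.species:
        raise DensityError(
            "overlap and VCV species orders differ; run align_species first"
        )
    overlap.validate()
    O = overlap.matrix / float(area_scale)
    if weight == "vcv":
        W = vcv.matrix.copy()
    elif weight == "inv-patristic":
        if include_self:
            raise DensityError(
                "include_self is undefined for inv-patristic weights "
                "(self patristic distance is zero)"
            )
        cd = vcv.matrix.diagonal()
        d = cd[:, None] + cd[None, :] - 2.0 * vcv.matrix
        with np.errstate(divide="ignore"):
            W = np.where(d > 0, 1.0 / np.where(d > 0, d, 1.0), 0.0)
    else:
        raise DensityError(f"unknown weight mode {weight!r}")
    prod = O * W
    cd_values = prod.sum(axis=1)
    if not include_self:
        cd_values = cd_values - prod.diagonal()
    return CladeDensityTable(
        overlap.species,
        cd_values,
        include_self=include_self,
        weight=weight,
        dropped_no_geography=alignment.dropped_no_geography if alignment else (),
        dropped_no_tree=alignment.dropped_no_tree if alignment else (),
        tree_id=tree_id,
    )


@dataclass(frozen=True)
class TopDecileSelection:
    species: tuple[str, ...]
    cutoff: float
    n_ties_included: int
    warning: str | None = None


def top_decile(
    table: CladeDensityTable, fraction: float = 0.10
) -> TopDecileSelection:
    """Species in the top ``fraction`` of clade densities within the taxon.

    Takes the ceil(fraction * n) highest values; species tied with the
    value at the cutoff are all included (and counted), so the selection
    never depends on an arbitrary ordering among equals.
    """
    if table.n < 1:
        raise DensityError("empty clade-density table")
    k = math.ceil(fraction * table.n)
    order = np.argsort(-table.values, kind="stable")
    cutoff = float(table.values[order[k - 1]])
    chosen_idx = [i for i in order if table.values[i] >= cutoff]
    n_ties = len(chosen_idx) - k
    warning = None
    if n_ties > 0:
        warning = (
            f"{n_ties} species tied with the cutoff value {cutoff:g} "
            "were included beyond the nominal decile size"
        )
        warnings.warn(warning, stacklevel=2)
    return TopDecileSelection(
        tuple(table.species[i] for i in chosen_idx),
        cutoff,
        n_ties,
        warning,
    )


@dataclass(frozen=True)
class BoxplotSummary:
    """Tukey five-number-plus-whiskers summary of a clade's densities."""

    minimum: float
    lower_whisker: float
    q1: float
    median: float
    q3: float
    upper_whisker: float
    maximum: float
    n: int

    def __post_init__(self) -> None:
        seq = (
            self.minimum,
            self.q1,
            self.median,
            self.q3,
            self.maximum,
        )
        if any(a > b + 1e-12 for a, b in zip(seq, seq[1:])):
            raise DensityError("boxplot summary fields are out of order")


def summarize_density(table: CladeDensityTable) -> BoxplotSummary:
    """Quartiles by linear interpolation; whiskers are the most extreme
    data points within 1.5 IQR of the nearer quartile (Tukey's rule)."""
    v = np.sort(table.values)
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence = q1 - 1.5 * iqr
    hi_fence = q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    return BoxplotSummary(
        minimum=float(v[0]),
        lower_whisker=float(inside[0]),
        q1=float(q1),
        median=float(med),
        q3=float(q3),
        upper_whisker=float(inside[-1]),
        maximum=float(v[-1]),
        n=v.size,
    )


def export_top_decile_geo(
    ranges: RangePolygonSet,
    selection: TopDecileSelection | list[str] | tuple[str, ...],
    table: CladeDensityTable,
    path: str | os.PathLike,
) -> None:
    """Write the selected species' dissolved ranges as a GeoJSON overlay,
    each feature carrying its clade density; empty selections produce an
    empty (valid) collection."""
    species = (
        selection.species
        if isinstance(selection, TopDecileSelection)
        else tuple(selection)
    )
    missing = [s for s in species if s not in ranges.geoms]
    if missing:
        raise DensityError(f"species missing geometry: {missing}")
    cd = table.series()
    features = [
        {
            "geometry": ranges.geoms[sp],
            "properties": {
                "species_id": sp,
                "clade_density": float(cd.get(sp, float("nan"))),
            },
        }
        for sp in species
    ]
    write_geojson(features, path, ndigits=9)
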