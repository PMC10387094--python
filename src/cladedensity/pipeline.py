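"""End-to-end orchestration: load -> project -> overlap -> rates ->
clade density -> trait-rate test -> summaries, with a run manifest.

Every paper-silent choice (projection, filters, transforms, seeds) is a
config field echoed into the manifest, so a run is reproducible from its
output directory alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time
import tomllib
from dataclasses import dataclass, field

import numpy as np

from . import density as _density
from . import geometry as _geometry
from . import phylo as _phylo
from .essim import EnsembleResult, ensemble as _run_ensemble

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "run_all", "report"]


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RunConfig:
    trees_path: str
    ranges_path: str
    out_dir: str
    input_crs: str = _geometry.CRS_GEOGRAPHIC  # "lonlat-degrees" or "cea-km"
    species_field: str = "species_id"
    apply_filter: bool = True
    exclude_presence: tuple[str, ...] = ("uncertain", "possibly_extinct")
    exclude_origin: tuple[str, ...] = ("introduced",)
    include_self: bool = False
    weight: str = "vcv"
    area_scale: float = 1.0
    n_sim: int = 100
    alpha: float = 0.05
    trait_transform: str = "log_shift"
    rate_transform: str = "log"
    max_trees: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sim < 1:
            raise ConfigError("n_sim must be >= 1")
        if not (0 < self.alpha < 1):
            raise ConfigError("alpha must be in (0, 1)")

    @classmethod
    def from_toml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        for key in ("exclude_presence", "exclude_origin"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate_paths(self) -> None:
        for label, p in (("trees", self.trees_path), ("ranges", self.ranges_path)):
            if not os.path.exists(p):
                raise ConfigError(f"{label} path does not exist: {p}")


@dataclass
class RunManifest:
    run_id: str
    config: dict
    input_checksums: dict[str, str] = field(default_factory=dict)
    stages: dict[str, dict] = field(default_factory=dict)
    status: str = "incomplete"
    error: str | None = None

    def write(self, out_dir: str) -> None:
        path = os.path.join(out_dir, "manifest.json")
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_all(config: RunConfig) -> RunManifest:
    """Execute the full pipeline; the manifest is written even on failure."""
    config.validate_paths()
    cfg_dict = dataclasses.asdict(config)
    run_id = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()
    ).hexdigest()[:12]
    os.makedirs(config.out_dir, exist_ok=True)
    manifest = RunManifest(run_id=run_id, config=cfg_dict)
    manifest.input_checksums = {
        "trees": _sha256(config.trees_path),
        "ranges": _sha256(config.ranges_path),
    }
    try:
        _run_stages(config, manifest)
        manifest.status = "ok"
    except Exception as exc:
        manifest.status = "failed"
        manifest.error = f"{type(exc).__name__}: {exc}"
        raise
    finally:
        manifest.write(config.out_dir)
    return manifest


def _stage(manifest: RunManifest, name: str):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            self.info: dict = {}
            return self.info

        def __exit__(self, *exc):
            self.info["wall_seconds"] = round(time.perf_counter() - self.t0, 4)
            manifest.stages[name] = self.info
            return False

    return _Timer()


def _run_stages(config: RunConfig, manifest: RunManifest) -> None:
    out = config.out_dir

    with _stage(manifest, "load_ranges") as info:
        filter_spec = None
        if config.apply_filter:
            filter_spec = _geometry.FilterSpec(
                exclude_presence=frozenset(config.exclude_presence),
                exclude_origin=frozenset(config.exclude_origin),
            )
        ranges = _geometry.load_ranges(
            config.ranges_path,
            filter_spec,
            species_field=config.species_field,
            crs=config.input_crs,
        )
        rep = ranges.report
        info.update(
            n_features_read=rep.n_features_read,
            n_features_dropped=rep.n_features_dropped,
            n_features_repaired=rep.n_features_repaired,
            n_species=len(ranges),
            species_all_excluded=rep.species_all_excluded,
        )

    with _stage(manifest, "project") as info:
        if ranges.crs == _geometry.CRS_GEOGRAPHIC:
            ranges = _geometry.project_equal_area(ranges)
            info["projection"] = "cylindrical-equal-area, standard parallel 0"
        else:
            info["projection"] = "input already planar (km)"

    with _stage(manifest, "overlap") as info:
        overlap = _geometry.compute_overlap_matrix(ranges)
        overlap.to_tsv(os.path.join(out, "overlap.tsv"))
        overlap.range_sizes().rename("area_km2").rename_axis("species").to_csv(
            os.path.join(out, "range_sizes.tsv"), sep="\t"
        )
        info["n_species"] = overlap.n
        info["n_sympatric_pairs"] = int((overlap.pairwise_overlaps() > 0).sum())

    with _stage(manifest, "trees") as info:
        trees = _phylo.read_newick(config.trees_path, ensemble=True)
        if config.max_trees is not None:
            trees = _phylo.TreeEnsemble(trees.trees[: config.max_trees])
        info["n_trees"] = len(trees)
        info["n_tips"] = trees[0].n_tips

    with _stage(manifest, "rates") as info:
        rates = _phylo.dr_statistic(trees[0])
        rates.to_tsv(os.path.join(out, "rates_tree0.tsv"))
        info["n_tips"] = len(rates.species)

    with _stage(manifest, "density") as info:
        vcv0 = _phylo.vcv(trees[0])
        o0, v0, align_rep = _density.align_species(overlap, vcv0)
        cd = _density.clade_density(
            o0,
            v0,
            include_self=config.include_self,
            weight=config.weight,
            area_scale=config.area_scale,
            tree_id="tree_0",
            alignment=align_rep,
        )
        cd.to_tsv(os.path.join(out, "clade_density_tree0.tsv"))
        sel = _density.top_decile(cd)
        _density.export_top_decile_geo(
            ranges, sel, cd, os.path.join(out, "top_decile.geojson")
        )
        info.update(
            n_species=cd.n,
            dropped_no_geography=list(cd.dropped_no_geography),
            dropped_no_tree=list(cd.dropped_no_tree),
            top_decile_n=len(sel.species),
        )

    with _stage(manifest, "test") as info:
        result = _run_ensemble(
            trees,
            overlap,
            n_sim=config.n_sim,
            seed=config.seed,
            alpha=config.alpha,
            include_self=config.include_self,
            weight=config.weight,
            area_scale=config.area_scale,
            trait_transform=config.trait_transform,
            rate_transform=config.rate_transform,
        )
        result.records.to_csv(
            os.path.join(out, "ensemble.tsv"), sep="\t", index=False
        )
        info.update(result.slope_summary())
        info["n_failures"] = len(result.failures)

    with _stage(manifest, "report") as info:
        text = report(cd, result, alpha=config.alpha)
        with open(os.path.join(out, "report.txt"), "w") as fh:
            fh.write(text)
        info["lines"] = text.count("\n")


def report(
    cd: "_density.CladeDensityTable | None",
    ensemble_result: EnsembleResult | None,
    *,
    alpha: float = 0.05,
) -> str:
    """Human-readable summary: clade-density quantiles, the slope
    distribution over topologies, and the fraction significant at alpha."""
    lines: list[str] = []
    if cd is None or cd.n == 0:
        lines.append("Clade density: no species with geography.")
    else:
        box = _density.summarize_density(cd)
        lines.append(f"Clade density across {box.n} species (area x time units):")
        lines.append(
            f"  min={box.minimum:.6g}  lower whisker={box.lower_whisker:.6g}  "
            f"Q1={box.q1:.6g}  median={box.median:.6g}  Q3={box.q3:.6g}  "
            f"upper whisker={box.upper_whisker:.6g}  max={box.maximum:.6g}"
        )
        if cd.dropped_no_geography:
            lines.append(
                f"  species dropped (no geography): {len(cd.dropped_no_geography)}"
            )
        if cd.dropped_no_tree:
            lines.append(
                f"  species dropped (not in tree): {len(cd.dropped_no_tree)}"
            )
    if ensemble_result is not None and len(ensemble_result.records):
        s = ensemble_result.slope_summary()
        if s["n_topologies"] > 1:
            lines.append(
                f"Trait-rate association over {s['n_topologies']} topologies:"
            )
            lines.append(
                f"  slope median={s['slope_median']:.6g} "
                f"[2.5%, 97.5%] = [{s['slope_q025']:.6g}, {s['slope_q975']:.6g}]"
            )
            spans = s["slope_min"] < 0 < s["slope_max"]
            lines.append(
                f"  slope distribution spans zero: {'yes' if spans else 'no'} "
                f"(fraction positive {s['frac_positive']:.2f})"
            )
            lines.append(
                f"  fraction of topologies significant at alpha={alpha:g}: "
                f"{s['frac_significant']:.3f}"
            )
        else:
            rec = ensemble_result.records.iloc[0]
            lines.append(
                "Trait-rate association (single topology): "
                f"rho={rec['rho']:.4f}, slope={rec['slope']:.6g}, p={rec['p']:.4f}"
            )
    return "\n".join(lines) + "\n"
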