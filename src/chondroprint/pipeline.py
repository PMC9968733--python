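"""Formats, configuration and end-to-end orchestration.

Ties the stages together: simulate → segment → measure → stats →
fingerprint, with deterministic seeding (every random draw flows from the
single config seed through named substreams), a manifest recording versions,
seed, config hash and per-stage row counts, and TIFF/CSV/JSON round-trips
for every intermediate product.  Pixel size is carried in the config, not in
TIFF tags, for determinism.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .fingerprint import cim, plsda_fit, rank_discriminative_features
from .morphometry import (DESCRIPTOR_NAMES, aggregate_by_sample,
                          cells_to_frame, measure_labelmap)
from .segmentation import (ChannelImage, Scribbles, compute_feature_stack,
                           fit_pixel_classifier, instances_from_classmap,
                           predict_class_map, predict_posteriors,
                           sample_scribbles)
from .stats import (broadcast_condition_to_cells, compare_two_groups,
                    correlogram, fold_change, percent_change_matrix)
from .synthetic import (GENES, EffectPreset, RenderNoise, build_experiment,
                        get_preset)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig", "PipelineError",
    "write_channel_tiff", "read_channel_tiff",
    "write_label_tiff", "read_label_tiff",
    "write_scribbles_csv", "read_scribbles_csv",
    "train_default_classifier", "measure_synthetic_group",
    "run_pipeline",
]

_QUANT = 16383.0  # 16-bit quantization full scale for float intensities


class PipelineError(RuntimeError):
    """A stage-named pipeline failure (partial outputs are retained)."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


# --------------------------------------------------------------------------
# Image / scribble IO
# --------------------------------------------------------------------------

def write_channel_tiff(path, image: ChannelImage) -> None:
    """Write a two-channel image as a multi-page 16-bit TIFF."""
    data = np.clip(image.channels, 0.0, 4.0)
    tifffile.imwrite(path, np.round(data * _QUANT).astype(np.uint16))


def read_channel_tiff(path, pixel_size: float, tile_id: str = ""
                      ) -> ChannelImage:
    """Read a 1-2 channel, 8/16-bit TIFF (pixel size comes from config)."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3 or arr.shape[0] > 2:
        n = arr.shape[0] if arr.ndim == 3 else arr.ndim
        raise ValueError(
            f"expected 1-2 channels (cell body [+ nucleus]), got {n}")
    if arr.dtype == np.uint16:
        data = arr.astype(np.float32) / _QUANT
    elif arr.dtype == np.uint8:
        data = arr.astype(np.float32) / 255.0
    else:
        raise ValueError(f"unsupported bit depth {arr.dtype}; use 8/16-bit")
    return ChannelImage(channels=data, pixel_size=pixel_size,
                        tile_id=tile_id or Path(path).stem)


def write_label_tiff(path, labels: np.ndarray) -> None:
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many instances for a 16-bit label TIFF")
    tifffile.imwrite(path, labels.astype(np.uint16))


def read_label_tiff(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)


def write_scribbles_csv(path, scribbles: Scribbles) -> None:
    rows = [(int(c), int(r), int(cls))
            for cls, pts in sorted(scribbles.coords.items())
            for r, c in pts]
    pd.DataFrame(rows, columns=["x", "y", "class"]).to_csv(path, index=False)


def read_scribbles_csv(path) -> Scribbles:
    df = pd.read_csv(path)
    coords = {int(cls): grp[["y", "x"]].to_numpy()
              for cls, grp in df.groupby("class")}
    return Scribbles(coords)


# --------------------------------------------------------------------------
# Configuration
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything the pipeline needs; all physical units are µm / µm²."""

    preset: str = "human-oa"
    preset_file: str | None = None
    seed: int = 0
    pixel_size: float = 1.5
    field_size: float = 600.0           # square tile edge, µm
    tiles_per_sample: int = 1
    n_per_group: int | None = None
    alpha: float = 0.05
    min_area: float = 50.0              # instance floor, µm²
    border_policy: str = "exclude"
    scales: tuple[float, ...] = (1.0, 2.0, 4.0)
    scribbles_per_class: int = 800
    ncomp: int = 2
    linkage: str = "complete"
    out_dir: str = "chondroprint_out"

    def __post_init__(self) -> None:
        if self.pixel_size <= 0 or self.field_size <= 0:
            raise ValueError("pixel_size and field_size must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.border_policy not in ("exclude", "keep"):
            raise ValueError("border_policy must be 'exclude' or 'keep'")
        if self.preset_file and not Path(self.preset_file).exists():
            raise ValueError(f"preset file not found: {self.preset_file}")

    def resolve_preset(self) -> EffectPreset:
        if self.preset_file:
            return EffectPreset.load(self.preset_file)
        return get_preset(self.preset)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "scales" in raw:
            raw["scales"] = tuple(raw["scales"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = self.to_dict()
        d["scales"] = list(d["scales"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# --------------------------------------------------------------------------
# Group-level image pipeline helpers
# --------------------------------------------------------------------------

def train_default_classifier(
    preset: EffectPreset,
    seed: int,
    *,
    pixel_size: float = 1.5,
    field_size: float = 800.0,
    scales: tuple[float, ...] = (1.0, 2.0, 4.0),
    scribbles_per_class: int = 800,
    noise: RenderNoise | None = None,
):
    """Train the pixel classifier on one rendered control tile.

    Mirrors the study workflow of training a single classifier on
    representative images and applying it to every tile of the experiment.
    """
    from .synthetic import generate_shape_population, place_cells, render_scene

    ss = _substream_seeds(seed, ("pop", "place", "render", "scrib", "clf"))
    area_cm2 = (field_size / 1e4) ** 2
    n_cells = max(5, int(round(preset.seeding_density * area_cm2)))
    shapes = generate_shape_population(preset, n_cells, ss["pop"])
    shapes = place_cells(shapes, (field_size, field_size), ss["place"])
    img, scene = render_scene(shapes, (field_size, field_size), pixel_size,
                              noise=noise, seed=ss["render"])
    scribbles = sample_scribbles(scene.class_map, scribbles_per_class,
                                 ss["scrib"])
    feats = compute_feature_stack(img, scales)
    return fit_pixel_classifier(feats, scribbles, ss["clf"], scales=scales)


def measure_synthetic_group(
    preset: EffectPreset,
    classifier,
    n_cells_min: int,
    seed: int,
    *,
    treated: bool = False,
    pixel_size: float = 1.5,
    field_size: float = 800.0,
    min_area: float = 50.0,
    noise: RenderNoise | None = None,
) -> pd.DataFrame:
    """Render, segment and measure one condition group of ≥ ``n_cells_min``
    interior cells at the preset's seeding density.

    Returns the per-cell descriptor table produced by the full image
    pipeline (render → classify → watershed → measure).  The number of
    tiles is fixed up front from the expected density, so the output is
    deterministic given ``seed``.
    """
    from .synthetic import generate_shape_population, place_cells, render_scene

    area_cm2 = (field_size / 1e4) ** 2
    per_tile = preset.seeding_density * area_cm2
    n_tiles = int(np.ceil(1.2 * n_cells_min / per_tile))
    seeds = np.random.SeedSequence(seed).generate_state(3 * n_tiles,
                                                        dtype=np.uint32)
    cells = []
    for t in range(n_tiles):
        s_pop, s_place, s_render = (int(s) % (2**31)
                                    for s in seeds[3 * t:3 * t + 3])
        n_cells = max(1, int(np.random.default_rng(s_pop).poisson(per_tile)))
        shapes = generate_shape_population(preset, n_cells, s_pop,
                                           treated=treated)
        shapes = place_cells(shapes, (field_size, field_size), s_place)
        img, _scene = render_scene(shapes, (field_size, field_size),
                                   pixel_size, noise=noise, seed=s_render,
                                   tile_id=f"g{int(treated)}_t{t}")
        post = predict_posteriors(classifier, img)
        classmap = np.argmax(post, axis=-1).astype(np.uint8)
        labels = instances_from_classmap(
            classmap, pixel_size, min_area=min_area,
            cytosol_posterior=post[..., 1])
        cells.extend(measure_labelmap(labels, pixel_size,
                                      sample_id=f"g{int(treated)}"))
    logger.info("group treated=%s: %d cells from %d tiles",
                treated, len(cells), n_tiles)
    return cells_to_frame(cells)


# --------------------------------------------------------------------------
# Orchestration
# --------------------------------------------------------------------------

def _substream_seeds(seed: int, names: tuple[str, ...]) -> dict[str, int]:
    """Named 31-bit substream seeds derived from the single config seed."""
    state = np.random.SeedSequence(seed).generate_state(len(names),
                                                        dtype=np.uint32)
    return {n: int(s) % (2**31) for n, s in zip(names, state)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate → segment → measure → stats → fingerprint.

    Writes the result bundle (TIFFs, CSVs, JSON reports, manifest) to
    ``config.out_dir`` and returns the in-memory bundle.  Re-running with
    the same config reproduces all numeric outputs bit-for-bit.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    preset = config.resolve_preset()
    seeds = _substream_seeds(config.seed,
                             ("simulate", "scribbles", "classifier"))
    counts: dict[str, int] = {}

    # --- simulate ----------------------------------------------------------
    stage = "simulate"
    try:
        images, truth_table = build_experiment(
            preset, seeds["simulate"], n_per_group=config.n_per_group,
            field_size=(config.field_size, config.field_size),
            pixel_size=config.pixel_size,
            tiles_per_sample=config.tiles_per_sample)
        for sid, tiles in images.items():
            for t, (img, scene) in enumerate(tiles):
                write_channel_tiff(out / f"{sid}_t{t}.tif", img)
                write_label_tiff(out / f"{sid}_t{t}_gt.tif", scene.labels)
        counts["samples"] = len(images)
        logger.info("simulate: %d samples, %d tiles each",
                    len(images), config.tiles_per_sample)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # --- segment + measure -------------------------------------------------
    stage = "segment"
    try:
        first = next(iter(images.values()))[0]
        train_img, train_scene = first
        scribbles = sample_scribbles(train_scene.class_map,
                                     config.scribbles_per_class,
                                     seeds["scribbles"])
        feats = compute_feature_stack(train_img, config.scales)
        clf = fit_pixel_classifier(feats, scribbles, seeds["classifier"],
                                   scales=config.scales)
        cells = []
        for sid, tiles in images.items():
            for t, (img, _scene) in enumerate(tiles):
                post = predict_posteriors(clf, img)
                classmap = np.argmax(post, axis=-1).astype(np.uint8)
                labels = instances_from_classmap(
                    classmap, config.pixel_size, min_area=config.min_area,
                    border_policy=config.border_policy,
                    cytosol_posterior=post[..., 1])
                write_label_tiff(out / f"{sid}_t{t}_labels.tif", labels)
                cells.extend(measure_labelmap(labels, config.pixel_size,
                                              sample_id=sid))
        counts["cells"] = len(cells)
        logger.info("segment+measure: %d cells", len(cells))
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # --- measure (tabulate + aggregate) ------------------------------------
    stage = "measure"
    try:
        cell_table = cells_to_frame(cells)
        cell_table.to_csv(out / "cells.csv", index=False)
        per_sample = aggregate_by_sample(cell_table)
        meta_cols = [c for c in truth_table.columns
                     if c not in DESCRIPTOR_NAMES and c != "n_cells"]
        sample_table = truth_table[meta_cols].merge(per_sample,
                                                    on="sample_id")
        sample_table.to_csv(out / "sample_table.csv", index=False)
        counts["sample_rows"] = len(sample_table)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # --- stats --------------------------------------------------------------
    stage = "stats"
    try:
        genes = [g for g in GENES if g in sample_table.columns]
        ctrl = sample_table[sample_table.condition == 0]
        trt = sample_table[sample_table.condition == 1]
        report: dict = {"two_group": {}, "fold_change": {}}
        for gene in genes:
            res = compare_two_groups(ctrl[gene], trt[gene], config.alpha)
            report["two_group"][gene] = res.as_dict()
            fc = fold_change(sample_table, gene)
            report["fold_change"][gene] = {
                "mode": fc.mode, "mean": fc.mean, "sem": fc.sem,
                "control_mean": fc.control_mean}
        cond_cells = broadcast_condition_to_cells(cell_table, sample_table)
        groups = {"control": cond_cells[cond_cells.condition == 0],
                  "il1b": cond_cells[cond_cells.condition == 1]}
        pcm = percent_change_matrix(groups, [("control", "il1b")],
                                    config.alpha,
                                    variables=list(DESCRIPTOR_NAMES))
        pcm.percent.to_csv(out / "percent_change.csv")
        report["percent_change"] = pcm.percent.iloc[:, 0].to_dict()
        corr_vars = ["condition", *DESCRIPTOR_NAMES, *genes]
        corr = correlogram(sample_table, corr_vars, alpha=config.alpha)
        corr.r.to_csv(out / "correlogram_r.csv")
        corr.p_values.to_csv(out / "correlogram_p.csv")
        with open(out / "stats.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # --- fingerprint --------------------------------------------------------
    stage = "fingerprint"
    try:
        feat_cols = [*DESCRIPTOR_NAMES, *genes]
        X = sample_table.set_index("sample_id")[feat_cols]
        y = sample_table.set_index("sample_id")["condition"]
        cim_res = cim(X, row_classes=y, method=config.linkage)
        cim_res.reordered().to_csv(out / "cim_matrix.csv")
        with open(out / "cim_orders.json", "w") as fh:
            json.dump({"rows": [str(X.index[i]) for i in cim_res.row_order],
                       "cols": [str(X.columns[i])
                                for i in cim_res.col_order]}, fh, indent=2)
        from .fingerprint import scale_center
        z, _ = scale_center(X)
        model = plsda_fit(z, y.to_numpy(), ncomp=config.ncomp)
        ranking = rank_discriminative_features(model)
        ranking.to_csv(out / "plsda_ranking.csv", index=False)
        pd.DataFrame(model.x_loadings, index=model.feature_names,
                     columns=[f"comp{i+1}" for i in range(model.ncomp)]
                     ).to_csv(out / "plsda_loadings.csv")
        try:
            from .plots import plot_cim, plot_loadings
            plot_cim(cim_res, out / "cim.png")
            plot_loadings(model, out / "plsda_loadings.png")
        except Exception:  # plotting is best-effort
            logger.exception("figure rendering failed")
    except Exception as e:  # noqa: BLE001
        raise PipelineError(stage, e) from e

    # --- manifest -----------------------------------------------------------
    digests = {}
    for f in sorted(out.glob("*.csv")) + sorted(out.glob("*.json")):
        if f.name == "manifest.json":
            continue
        digests[f.name] = hashlib.sha256(f.read_bytes()).hexdigest()
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.hash(),
        "counts": counts,
        "outputs": digests,
        "bundle_hash": hashlib.sha256(
            json.dumps(digests, sort_keys=True).encode()).hexdigest(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return {
        "sample_table": sample_table,
        "cells": cell_table,
        "stats": report,
        "cim": cim_res,
        "plsda": model,
        "ranking": ranking,
        "manifest": manifest,
    }
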