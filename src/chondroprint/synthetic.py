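"""Synthetic chondrocyte imaging and ddPCR experiments with ground truth.

Emulates the raw material of an in-vitro chondrocyte inflammation study so
that every downstream stage (segmentation → morphometry → statistics →
fingerprinting) can be exercised and validated without real microscopy data:

* **Cell populations** — each cell is an ellipse (major axis lognormal;
  aspect ratio ``1 + lognormal`` so elongation stays ≥ 1) optionally
  decorated with short (≤ 5 µm) cytoplasmic processes drawn from a Poisson
  law, plus a circular nucleus.  Treatment effects are multiplicative on
  population means.  Mean cell area and mean aspect ratio are the two
  independently controlled quantities: the treated major axis is scaled by
  ``sqrt(area_effect × κ)`` where κ corrects for the aspect-ratio change, so
  that the population-mean area changes by exactly the preset's area effect
  and the mean aspect ratio by exactly its aspect-ratio effect.
* **Rendering** — two 16-bit-ready channels (cell body analog of calcein,
  nucleus analog of Hoechst): binary ground-truth rasters at pixel centers,
  Gaussian blur, per-cell brightness jitter, Poisson photon noise, Gaussian
  read noise and a constant background.  Overlapping cells are composited
  with the later cell occluding.  Ground truth records per-pixel instance
  ownership, the 3-class map, and each cell's true descriptor panel measured
  from its rasterized mask by the morphometry module itself.
* **ddPCR tables** — per-sample transcript concentrations (copies/µL) drawn
  lognormally around gene-specific control means; treated means are the
  control means times the preset fold change.  Samples are paired by donor:
  a donor-shared lognormal effect (which cancels in paired fold changes)
  plus an independent residual make up the within-group CV.

Shipped presets carry the published effect structure of IL-1β incubation on
human osteoarthritic and healthy bovine chondrocytes (morphology effects,
gene fold changes, seeding densities, group sizes, macroscopic grades).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .morphometry import DescriptorPanel, measure_labelmap
from .segmentation import BACKGROUND, CYTOSOL, NUCLEUS, ChannelImage

__all__ = [
    "Protrusion", "ShapeSpec", "MorphologyParams", "ExpressionParams",
    "EffectPreset", "RenderNoise", "GroundTruthScene",
    "TABLE1_GRADES", "GENES", "PRESETS", "get_preset",
    "generate_shape_population", "place_cells", "render_scene",
    "generate_expression_table", "build_experiment",
]

#: Macroscopic damage grades (3-point scale) of the eight human cartilage
#: donors, shipped as the default human donor metadata.
TABLE1_GRADES = (2.0, 1.5, 2.5, 1.0, 2.0, 2.0, 1.5, 2.0)

GENES = ("COL1A2", "COL2A1", "SOX9", "ACAN", "IL-6", "IL-8")


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Protrusion:
    """One cytoplasmic process: direction, length and width (µm)."""

    angle: float
    length: float
    width: float


@dataclass(frozen=True)
class ShapeSpec:
    """Geometric ground truth of one cell, in µm."""

    center: tuple[float, float]
    major_axis: float
    minor_axis: float
    orientation: float
    protrusions: tuple[Protrusion, ...]
    nucleus_diameter: float

    def __post_init__(self) -> None:
        if not (self.major_axis >= self.minor_axis > 0):
            raise ValueError("major_axis >= minor_axis > 0 violated")
        if not self.nucleus_diameter < self.minor_axis:
            raise ValueError("nucleus must fit inside the minor axis")
        if any(p.length < 0 for p in self.protrusions):
            raise ValueError("protrusion length must be >= 0")


@dataclass(frozen=True)
class MorphologyParams:
    """Control-population morphology (means in µm, CVs dimensionless)."""

    mean_length: float           # mean major axis
    mean_ar_excess: float        # mean of (aspect ratio - 1)
    cv_length: float = 0.25
    cv_ar_excess: float = 0.35
    protrusion_rate: float = 2.0          # Poisson mean per cell
    protrusion_length: tuple[float, float] = (1.5, 4.5)  # uniform range, µm
    protrusion_width: tuple[float, float] = (1.2, 1.8)
    nucleus_diameter: float = 10.0
    nucleus_sd: float = 1.0


@dataclass(frozen=True)
class ExpressionParams:
    """Control means (copies/µL) and noise structure of the ddPCR generator."""

    control_means: dict[str, float]
    cv: float = 0.30        # total within-group CV
    donor_cv: float = 0.25  # donor-shared part (cancels in paired ratios)

    @property
    def residual_cv(self) -> float:
        if self.cv == 0:
            return 0.0
        if self.donor_cv >= self.cv:
            raise ValueError("donor_cv must be below the total cv")
        return float(np.sqrt((1 + self.cv**2) / (1 + self.donor_cv**2) - 1))


@dataclass(frozen=True)
class EffectPreset:
    """One experimental condition: control parameters plus treatment effects.

    ``morph_effects`` holds the published per-descriptor multiplicative
    effects on population means.  The generator realizes them through its
    two controllable degrees of freedom, mean area (``morph_effects['area']``)
    and mean aspect ratio (``morph_effects['aspect_ratio']``), plus the
    protrusion-rate multiplier; the remaining entries are descriptive
    consequences of those.  ``gene_folds`` are treated/control mean ratios.
    """

    name: str
    morphology: MorphologyParams
    morph_effects: dict[str, float]
    protrusion_rate_effect: float
    expression: ExpressionParams
    gene_folds: dict[str, float]
    n_per_group: int = 8
    seeding_density: float = 9375.0   # cells/cm²
    dose_ng_ml: float = 0.1
    donor_grades: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.morph_effects.values()):
            raise ValueError("morphology effect multipliers must be > 0")
        if any(f < 0 for f in self.gene_folds.values()):
            raise ValueError("gene fold changes must be >= 0")

    # -- realized multipliers ------------------------------------------------

    def ar_excess_effect(self) -> float:
        """Multiplier on (AR − 1) that realizes the mean-AR effect."""
        g = self.morphology.mean_ar_excess
        r = self.morph_effects.get("aspect_ratio", 1.0)
        return (r * (1 + g) - 1) / g

    def length_effect(self) -> float:
        """Multiplier on the major axis: sqrt(area effect × κ), with κ the
        inverse-AR mean ratio, so the mean-area effect is exact."""
        m = self.morphology
        a = self.morph_effects.get("area", 1.0)
        inv_c = _mean_inv_one_plus_lognormal(m.mean_ar_excess, m.cv_ar_excess)
        inv_t = _mean_inv_one_plus_lognormal(
            m.mean_ar_excess * self.ar_excess_effect(), m.cv_ar_excess)
        kappa = inv_c / inv_t
        return float(np.sqrt(a * kappa))

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "EffectPreset":
        d = dict(d)
        d["morphology"] = MorphologyParams(**_tuplify(d["morphology"]))
        d["expression"] = ExpressionParams(**d["expression"])
        if d.get("donor_grades") is not None:
            d["donor_grades"] = tuple(d["donor_grades"])
        return cls(**d)

    @classmethod
    def load(cls, path) -> "EffectPreset":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _tuplify(d: dict) -> dict:
    return {k: tuple(v) if isinstance(v, list) else v for k, v in d.items()}


@dataclass(frozen=True)
class RenderNoise:
    """Imaging noise model: constant background, Gaussian blur (px),
    Poisson photon noise (0 disables), Gaussian read noise."""

    background: float = 0.08
    blur_sigma: float = 0.5
    photon_scale: float = 200.0
    read_noise: float = 0.01

    @classmethod
    def none(cls) -> "RenderNoise":
        return cls(background=0.0, blur_sigma=0.0, photon_scale=0.0,
                   read_noise=0.0)


@dataclass
class GroundTruthScene:
    """Per-pixel and per-cell ground truth of one rendered tile."""

    shapes: list[ShapeSpec]
    labels: np.ndarray            # instance ownership, 0 = background
    class_map: np.ndarray         # {0 background, 1 cytosol, 2 nucleus}
    panels: dict[int, DescriptorPanel]   # true panel per visible instance id
    border_flags: dict[int, bool]
    pixel_size: float

    @property
    def n_cells(self) -> int:
        return len(self.panels)


# --------------------------------------------------------------------------
# Numeric helpers
# --------------------------------------------------------------------------

def _lognormal_mu_sigma(mean: float, cv: float) -> tuple[float, float]:
    s2 = np.log1p(cv * cv)
    return float(np.log(mean) - s2 / 2), float(np.sqrt(s2))


def _draw_lognormal(rng, mean: float, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.full(size, float(mean))
    mu, sigma = _lognormal_mu_sigma(mean, cv)
    return rng.lognormal(mu, sigma, size)


def _mean_inv_one_plus_lognormal(mean: float, cv: float, order: int = 96
                                 ) -> float:
    """E[1/(1+X)] for lognormal X (Gauss–Hermite quadrature)."""
    if cv == 0:
        return 1.0 / (1.0 + mean)
    mu, sigma = _lognormal_mu_sigma(mean, cv)
    x, w = np.polynomial.hermite.hermgauss(order)
    vals = 1.0 / (1.0 + np.exp(mu + sigma * np.sqrt(2.0) * x))
    return float((w * vals).sum() / np.sqrt(np.pi))


# --------------------------------------------------------------------------
# Shipped presets
# --------------------------------------------------------------------------

_HUMAN_MORPH = MorphologyParams(mean_length=40.0, mean_ar_excess=1.0)
_BOVINE_MORPH = MorphologyParams(mean_length=35.0, mean_ar_excess=0.7)
_NO_EFFECT = {k: 1.0 for k in ("area", "length", "width", "circularity",
                               "aspect_ratio", "roundness", "solidity")}

_HUMAN_EXPR = ExpressionParams(control_means={
    "COL1A2": 600.0, "COL2A1": 1500.0, "SOX9": 300.0,
    "ACAN": 800.0, "IL-6": 2.0, "IL-8": 1.2,
})
_BOVINE_EXPR = ExpressionParams(control_means={
    "COL1A2": 400.0, "COL2A1": 2500.0, "SOX9": 350.0,
    "ACAN": 900.0, "IL-6": 1.5, "IL-8": 0.3,
})

PRESETS: dict[str, EffectPreset] = {
    # Human osteoarthritic chondrocytes, 0.1 ng/ml IL-1β, high density.
    "human-oa": EffectPreset(
        name="human-oa",
        morphology=_HUMAN_MORPH,
        morph_effects={"area": 0.87, "width": 0.87, "length": 1.02,
                       "circularity": 1.02, "aspect_ratio": 1.17,
                       "roundness": 0.87, "solidity": 1.00},
        protrusion_rate_effect=0.7,
        expression=_HUMAN_EXPR,
        gene_folds={"COL1A2": 1.0, "COL2A1": 0.1, "SOX9": 0.7,
                    "ACAN": 0.2, "IL-6": 82.0, "IL-8": 147.0},
        seeding_density=9375.0,
        dose_ng_ml=0.1,
        donor_grades=TABLE1_GRADES,
    ),
    # Healthy bovine chondrocytes, 10 ng/ml IL-1β, low density.
    "bovine-10ng": EffectPreset(
        name="bovine-10ng",
        morphology=_BOVINE_MORPH,
        morph_effects={"area": 1.10, "length": 1.05, "width": 1.10,
                       "circularity": 1.15, "roundness": 1.03,
                       "solidity": 1.006, "aspect_ratio": 0.99},
        protrusion_rate_effect=0.5,
        expression=_BOVINE_EXPR,
        gene_folds={"COL1A2": 1.0, "COL2A1": 0.5, "SOX9": 1.0,
                    "ACAN": 1.0, "IL-6": 50.0, "IL-8": 22.0},
        seeding_density=3000.0,
        dose_ng_ml=10.0,
    ),
    # Healthy bovine control morphology (no treatment effects).
    "bovine-control": EffectPreset(
        name="bovine-control",
        morphology=_BOVINE_MORPH,
        morph_effects=dict(_NO_EFFECT),
        protrusion_rate_effect=1.0,
        expression=_BOVINE_EXPR,
        gene_folds={g: 1.0 for g in GENES},
        seeding_density=3000.0,
        dose_ng_ml=0.0,
    ),
    # Null preset: human parameters, every effect and fold equal to 1.
    "null": EffectPreset(
        name="null",
        morphology=_HUMAN_MORPH,
        morph_effects=dict(_NO_EFFECT),
        protrusion_rate_effect=1.0,
        expression=_HUMAN_EXPR,
        gene_folds={g: 1.0 for g in GENES},
        seeding_density=9375.0,
        dose_ng_ml=0.0,
        donor_grades=TABLE1_GRADES,
    ),
}


def get_preset(name: str) -> EffectPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}") from None


# --------------------------------------------------------------------------
# Shape populations
# --------------------------------------------------------------------------

def generate_shape_population(
    preset: EffectPreset, n_cells: int, seed: int, *, treated: bool = False
) -> list[ShapeSpec]:
    """Draw ``n_cells`` ground-truth cell shapes (centers at the origin).

    Major axes are lognormal, aspect ratios ``1 + lognormal``, protrusion
    counts Poisson.  With ``treated=True`` the preset's realized multipliers
    are applied so that population-mean area, aspect ratio and protrusion
    rate change by exactly the preset's effects.  Deterministic given seed.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    m = preset.morphology
    l_mult = preset.length_effect() if treated else 1.0
    g_mult = preset.ar_excess_effect() if treated else 1.0
    p_mult = preset.protrusion_rate_effect if treated else 1.0

    rng = np.random.default_rng(seed)
    length = _draw_lognormal(rng, m.mean_length * l_mult, m.cv_length, n_cells)
    ar = 1.0 + _draw_lognormal(rng, m.mean_ar_excess * g_mult,
                               m.cv_ar_excess, n_cells)
    width = length / ar
    orientation = rng.uniform(0.0, np.pi, n_cells)
    n_prot = rng.poisson(m.protrusion_rate * p_mult, n_cells)
    nucleus = rng.normal(m.nucleus_diameter, m.nucleus_sd, n_cells)

    shapes: list[ShapeSpec] = []
    for i in range(n_cells):
        prots = tuple(
            Protrusion(
                angle=float(rng.uniform(0.0, 2.0 * np.pi)),
                length=float(rng.uniform(*m.protrusion_length)),
                width=float(rng.uniform(*m.protrusion_width)),
            )
            for _ in range(n_prot[i])
        )
        nuc = float(np.clip(nucleus[i], 4.0, 0.75 * width[i]))
        shapes.append(ShapeSpec(
            center=(0.0, 0.0),
            major_axis=float(length[i]),
            minor_axis=float(width[i]),
            orientation=float(orientation[i]),
            protrusions=prots,
            nucleus_diameter=nuc,
        ))
    return shapes


def place_cells(
    shapes: list[ShapeSpec],
    field_size: tuple[float, float],
    seed: int,
    min_distance: float = 25.0,
) -> list[ShapeSpec]:
    """Scatter cell centers uniformly over a (width, height) µm field.

    Centers keep a minimum spacing (default 25 µm): adherent cells in a
    subconfluent monolayer spread side by side, so cell bodies may touch or
    partially overlap but nuclei do not stack.  If a candidate cannot be
    placed after many attempts (overcrowded field) it is placed anyway.
    Cells may cross the field border; the renderer flags them in the ground
    truth so downstream analysis can exclude their truncated masks.
    """
    rng = np.random.default_rng(seed)
    fx, fy = field_size
    placed: list[tuple[float, float]] = []
    out = []
    for s in shapes:
        best = None
        for _ in range(200):
            cand = (float(rng.uniform(0, fx)), float(rng.uniform(0, fy)))
            if all((cand[0] - p[0]) ** 2 + (cand[1] - p[1]) ** 2
                   >= min_distance**2 for p in placed):
                best = cand
                break
        if best is None:
            best = (float(rng.uniform(0, fx)), float(rng.uniform(0, fy)))
        placed.append(best)
        out.append(replace(s, center=best))
    return out


# --------------------------------------------------------------------------
# Rendering
# --------------------------------------------------------------------------

def _cell_masks(
    shape: ShapeSpec, h: int, w: int, pixel_size: float
) -> tuple[slice, slice, np.ndarray, np.ndarray] | None:
    """Rasterize one cell: bounding-box slices, body mask, nucleus mask."""
    cx, cy = shape.center
    a = shape.major_axis / 2.0
    b = shape.minor_axis / 2.0
    reach = a + max((p.length for p in shape.protrusions), default=0.0) + 2.0
    c0 = max(int((cx - reach) / pixel_size), 0)
    c1 = min(int((cx + reach) / pixel_size) + 2, w)
    r0 = max(int((cy - reach) / pixel_size), 0)
    r1 = min(int((cy + reach) / pixel_size) + 2, h)
    if c0 >= c1 or r0 >= r1:
        return None
    cols = (np.arange(c0, c1) + 0.5) * pixel_size - cx
    rows = (np.arange(r0, r1) + 0.5) * pixel_size - cy
    x = cols[None, :]
    y = rows[:, None]
    ct, st = np.cos(shape.orientation), np.sin(shape.orientation)
    u = x * ct + y * st      # along major axis
    v = -x * st + y * ct     # along minor axis
    body = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    for p in shape.protrusions:
        # Base on the ellipse boundary in direction `angle` (cell frame),
        # capsule extending outward by `length`.
        ca, sa = np.cos(p.angle), np.sin(p.angle)
        r_edge = a * b / np.hypot(b * ca, a * sa)
        bu, bv = 0.8 * r_edge * ca, 0.8 * r_edge * sa
        eu, ev = (r_edge + p.length) * ca, (r_edge + p.length) * sa
        du, dv = eu - bu, ev - bv
        seg2 = du * du + dv * dv
        t = np.clip(((u - bu) * du + (v - bv) * dv) / seg2, 0.0, 1.0)
        dist2 = (u - (bu + t * du)) ** 2 + (v - (bv + t * dv)) ** 2
        body |= dist2 <= (p.width / 2.0) ** 2
    if not body.any():
        return None
    nuc = x**2 + y**2 <= (shape.nucleus_diameter / 2.0) ** 2
    return slice(r0, r1), slice(c0, c1), body, nuc & body


def render_scene(
    shapes: list[ShapeSpec],
    field_size: tuple[float, float],
    pixel_size: float,
    noise: RenderNoise | None = None,
    seed: int = 0,
    tile_id: str = "",
) -> tuple[ChannelImage, GroundTruthScene]:
    """Rasterize placed cells into a noisy two-channel tile plus ground truth.

    Channel 0 is the union of cell bodies and protrusions, channel 1 the
    nuclei.  Overlapping cells are composited in list order (later occludes).
    The ground-truth label raster records per-pixel ownership, and each
    visible cell's true descriptor panel is measured from that raster.
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    noise = RenderNoise() if noise is None else noise
    w = int(round(field_size[0] / pixel_size))
    h = int(round(field_size[1] / pixel_size))
    if h < 2 or w < 2:
        raise ValueError("field too small for any cell")
    rng = np.random.default_rng(seed)

    labels = np.zeros((h, w), dtype=np.int32)
    nucleus_mask = np.zeros((h, w), dtype=bool)
    body_intensity = np.zeros((h, w), dtype=np.float64)
    nucleus_intensity = np.zeros((h, w), dtype=np.float64)
    border_flags: dict[int, bool] = {}
    falloff_um = 2.5  # smooth stain falloff within ~2.5 µm of the membrane

    for i, shape in enumerate(shapes, start=1):
        res = _cell_masks(shape, h, w, pixel_size)
        brightness = rng.uniform(0.9, 1.1)  # per-cell staining variability
        if res is None:
            continue
        rs, cs, body, nuc = res
        labels[rs, cs][body] = i
        nucleus_mask[rs, cs] |= nuc
        # Smooth intensity falloff toward the membrane: stain density ramps
        # up inside the true boundary (distance measured from the boundary
        # crack, pixel centers sitting 0.5 px inside it).
        d_in = (ndimage.distance_transform_edt(body) - 0.5) * pixel_size
        ramp = np.clip(d_in / falloff_um, 0.0, 1.0)
        profile = 0.25 + 0.75 * ramp  # edge pixels keep a visible rim
        body_intensity[rs, cs][body] = (0.60 * brightness
                                        * profile[body])
        nucleus_intensity[rs, cs][nuc] = 0.90 * brightness
        touches = (
            (rs.start == 0 and body[0].any())
            or (rs.stop == h and body[-1].any())
            or (cs.start == 0 and body[:, 0].any())
            or (cs.stop == w and body[:, -1].any())
        )
        border_flags[i] = bool(touches)

    # Occlusion: a later cell may overwrite an earlier nucleus region.
    nucleus_mask &= labels > 0

    class_map = np.zeros((h, w), dtype=np.uint8)
    class_map[labels > 0] = CYTOSOL
    class_map[nucleus_mask] = NUCLEUS

    channels = np.zeros((2, h, w), dtype=np.float64)
    channels[0] = body_intensity
    channels[1] = nucleus_intensity
    if noise.blur_sigma > 0:
        for c in range(2):
            channels[c] = ndimage.gaussian_filter(channels[c],
                                                  noise.blur_sigma)
    channels += noise.background
    if noise.photon_scale > 0:
        channels = rng.poisson(np.clip(channels, 0, None)
                               * noise.photon_scale) / noise.photon_scale
    if noise.read_noise > 0:
        channels = channels + rng.normal(0.0, noise.read_noise,
                                         channels.shape)
    channels = np.clip(channels, 0.0, None)

    records = measure_labelmap(labels, pixel_size)
    panels = {r.cell_id: r.panel for r in records}
    visible_flags = {i: border_flags.get(i, False) or rec.on_border
                     for i, rec in ((r.cell_id, r) for r in records)}

    image = ChannelImage(channels=channels.astype(np.float32),
                         pixel_size=pixel_size, tile_id=tile_id)
    scene = GroundTruthScene(shapes=list(shapes), labels=labels,
                             class_map=class_map, panels=panels,
                             border_flags=visible_flags,
                             pixel_size=pixel_size)
    return image, scene


# --------------------------------------------------------------------------
# ddPCR expression tables
# --------------------------------------------------------------------------

def generate_expression_table(
    preset: EffectPreset, n_per_group: int, seed: int
) -> pd.DataFrame:
    """Per-sample gene concentrations (copies/µL) with paired donor structure.

    Each of ``n_per_group`` donors contributes one control (condition 0) and
    one treated (condition 1) sample.  Concentrations are lognormal around
    ``control_mean × donor_effect × (fold if treated)``; the donor effect is
    shared within a pair.
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    expr = preset.expression
    rng = np.random.default_rng(seed)
    genes = list(expr.control_means)
    rows = []
    res_cv = expr.residual_cv
    for d in range(1, n_per_group + 1):
        donor_eff = {g: _draw_lognormal(rng, 1.0, expr.donor_cv, 1)[0]
                     for g in genes}
        for cond in (0, 1):
            row = {
                "sample_id": f"S{d + cond * n_per_group:02d}",
                "donor_id": f"D{d}",
                "condition": cond,
                "dose_ng_ml": preset.dose_ng_ml if cond else 0.0,
            }
            for g in genes:
                fold = preset.gene_folds.get(g, 1.0) if cond else 1.0
                resid = _draw_lognormal(rng, 1.0, res_cv, 1)[0]
                row[g] = expr.control_means[g] * donor_eff[g] * fold * resid
            rows.append(row)
    return pd.DataFrame(rows).sort_values(
        ["condition", "donor_id"], ignore_index=True)


# --------------------------------------------------------------------------
# Full experiments
# --------------------------------------------------------------------------

def build_experiment(
    preset: EffectPreset,
    seed: int,
    *,
    n_per_group: int | None = None,
    field_size: tuple[float, float] = (600.0, 600.0),
    pixel_size: float = 1.5,
    tiles_per_sample: int = 1,
    noise: RenderNoise | None = None,
) -> tuple[dict[str, list[tuple[ChannelImage, GroundTruthScene]]],
           pd.DataFrame]:
    """Simulate a full control-vs-treated experiment.

    Returns per-sample rendered tiles (with ground truth) and a sample table
    holding metadata, ground-truth mean descriptors of interior cells, gene
    concentrations and living-cell counts.  The expected number of cells per
    tile follows the preset's seeding density and the tile area.
    """
    n = preset.n_per_group if n_per_group is None else n_per_group
    ss = np.random.SeedSequence(seed)
    seeds = ss.generate_state(4 * 2 * n * max(tiles_per_sample, 1) + 1,
                              dtype=np.uint32)
    expr = generate_expression_table(preset, n, int(seeds[-1]) % (2**31))

    area_cm2 = (field_size[0] / 1e4) * (field_size[1] / 1e4)
    expected = preset.seeding_density * area_cm2

    images: dict[str, list[tuple[ChannelImage, GroundTruthScene]]] = {}
    morph_rows = []
    k = 0
    for _, srow in expr.iterrows():
        sid = srow["sample_id"]
        treated = bool(srow["condition"])
        tiles = []
        panels = []
        for t in range(tiles_per_sample):
            s0, s1, s2, s3 = (int(seeds[k + j]) % (2**31) for j in range(4))
            k += 4
            rng = np.random.default_rng(s0)
            n_cells = max(1, int(rng.poisson(expected)))
            shapes = generate_shape_population(preset, n_cells, s1,
                                               treated=treated)
            shapes = place_cells(shapes, field_size, s2)
            img, scene = render_scene(shapes, field_size, pixel_size,
                                      noise=noise, seed=s3,
                                      tile_id=f"{sid}_t{t}")
            tiles.append((img, scene))
            panels.extend(p for cid, p in scene.panels.items()
                          if not scene.border_flags.get(cid, False))
        images[sid] = tiles
        means = {name: float(np.mean([getattr(p, name) for p in panels]))
                 for name in ("area", "length", "width", "circularity",
                              "aspect_ratio", "roundness", "solidity")}
        grade = np.nan
        if preset.donor_grades is not None:
            grade = preset.donor_grades[
                (int(srow["donor_id"][1:]) - 1) % len(preset.donor_grades)]
        rng_meta = np.random.default_rng(int(seeds[k - 1]) % (2**31) + 7)
        morph_rows.append({
            "sample_id": sid,
            "grade": grade,
            "density_cells_cm2": preset.seeding_density,
            "living_cells": int(rng_meta.poisson(5e4)),
            "n_cells": len(panels),
            **means,
        })
    table = expr.merge(pd.DataFrame(morph_rows), on="sample_id")
    return images, table
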