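"""Trainable 3-class pixel segmentation and watershed instance separation.

The segmentation stage mirrors an interactive pixel-classification workflow:
a user scribbles examples of three classes — nucleus, cytosol, background —
on a two-channel fluorescence image (cell-body stain + nuclear stain), a
probabilistic classifier is trained on multi-scale per-pixel features, and
neighbouring cells are then separated with a marker-based watershed using
nucleus components as markers.

Feature stack (per channel, configurable scales σ in px): raw intensity plus,
at each scale, the Gaussian-smoothed intensity, its gradient magnitude and
its Laplacian — ``channels × (3·|scales|) + channels`` features per pixel.

The classifier family is an ensemble of randomized decision trees; the
contract required downstream is only "probabilistic 3-class pixel
classifier", so alternatives are pluggable.  Argmax ties are broken toward
background (class order background < cytosol < nucleus).

Watershed markers are nucleus-class connected components of at least
``nucleus_min_px`` pixels; flooding runs on the inverted cytosol posterior
(or on an inverted distance transform when no posterior is supplied),
constrained to predicted foreground.  Foreground blobs containing no marker
are kept as single instances rather than discarded.  Instances below a
physical area floor, and instances touching the tile border (whose
descriptors would be truncated), are removed by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.segmentation import watershed
from sklearn.ensemble import ExtraTreesClassifier

logger = logging.getLogger(__name__)

__all__ = [
    "BACKGROUND", "CYTOSOL", "NUCLEUS",
    "ChannelImage", "Scribbles", "PixelClassifier",
    "compute_feature_stack", "sample_scribbles", "fit_pixel_classifier",
    "predict_posteriors", "predict_class_map", "instances_from_classmap",
]

BACKGROUND, CYTOSOL, NUCLEUS = 0, 1, 2
DEFAULT_SCALES = (1.0, 2.0, 4.0)

_STRUCT4 = ndimage.generate_binary_structure(2, 1)


@dataclass
class ChannelImage:
    """Two-channel intensity raster with physical pixel size.

    ``channels`` has shape (2, H, W): channel 0 is the cell-body stain
    (calcein analog), channel 1 the nuclear stain (Hoechst analog).
    """

    channels: np.ndarray
    pixel_size: float
    tile_id: str = ""

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float32)
        if self.channels.ndim != 3 or self.channels.shape[0] not in (1, 2):
            raise ValueError("channels must have shape (1-2, H, W)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]


@dataclass
class Scribbles:
    """Training coordinates per class: {class: (N, 2) array of (row, col)}."""

    coords: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        self.coords = {int(k): np.asarray(v, dtype=int)
                       for k, v in self.coords.items()}
        seen: set[tuple[int, int]] = set()
        for cls, pts in self.coords.items():
            if cls not in (BACKGROUND, CYTOSOL, NUCLEUS):
                raise ValueError(f"unknown class {cls}")
            tset = {tuple(p) for p in pts}
            if seen & tset:
                raise ValueError("scribble classes must be disjoint")
            seen |= tset

    def counts(self) -> dict[int, int]:
        return {c: len(p) for c, p in self.coords.items()}


def compute_feature_stack(
    image: ChannelImage, scales: tuple[float, ...] = DEFAULT_SCALES
) -> np.ndarray:
    """Per-pixel feature vectors, shape (H, W, F) with
    F = channels × (3·|scales|) + channels."""
    if len(scales) < 1:
        raise ValueError("need at least one scale")
    h, w = image.shape
    if h == 0 or w == 0:
        raise ValueError("empty image")
    feats = []
    for ch in image.channels:
        feats.append(ch)
        for s in scales:
            g = ndimage.gaussian_filter(ch, s)
            gr = ndimage.gaussian_gradient_magnitude(ch, s)
            lap = ndimage.gaussian_laplace(ch, s)
            feats.extend([g, gr, lap])
    return np.stack(feats, axis=-1).astype(np.float32)


def sample_scribbles(
    class_map: np.ndarray,
    n_per_class: int,
    seed: int,
    erode_px: int = 1,
) -> Scribbles:
    """Draw training scribbles from a reference class map.

    Emulates interactive annotation: pixels are sampled from the interior of
    each class (after erosion by ``erode_px``), as a user scribbles well away
    from ambiguous class boundaries.
    """
    rng = np.random.default_rng(seed)
    coords: dict[int, np.ndarray] = {}
    for cls in (BACKGROUND, CYTOSOL, NUCLEUS):
        mask = class_map == cls
        if erode_px > 0:
            eroded = ndimage.binary_erosion(mask, _STRUCT4,
                                            iterations=erode_px)
            if eroded.sum() >= 10:
                mask = eroded
        idx = np.flatnonzero(mask)
        if len(idx) == 0:
            raise ValueError(f"class {cls} absent from reference map")
        pick = rng.choice(idx, size=min(n_per_class, len(idx)), replace=False)
        coords[cls] = np.column_stack(np.unravel_index(pick, class_map.shape))
    return Scribbles(coords)


@dataclass
class PixelClassifier:
    """Probabilistic 3-class pixel classifier plus its feature configuration."""

    model: ExtraTreesClassifier
    scales: tuple[float, ...]
    n_features: int


def fit_pixel_classifier(
    features: np.ndarray,
    scribbles: Scribbles,
    seed: int,
    *,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    min_pixels_per_class: int = 50,
    n_estimators: int = 40,
    max_train_per_class: int = 4000,
) -> PixelClassifier:
    """Train the pixel classifier on scribbled pixels of a feature stack.

    Every class must supply at least ``min_pixels_per_class`` labeled pixels.
    Training is deterministic given ``seed``.
    """
    for cls in (BACKGROUND, CYTOSOL, NUCLEUS):
        n = len(scribbles.coords.get(cls, ()))
        if n < min_pixels_per_class:
            raise ValueError(
                f"class {cls} has {n} labeled pixels "
                f"(minimum {min_pixels_per_class})")
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for cls, pts in sorted(scribbles.coords.items()):
        if len(pts) > max_train_per_class:
            pts = pts[rng.choice(len(pts), max_train_per_class, replace=False)]
        xs.append(features[pts[:, 0], pts[:, 1]])
        ys.append(np.full(len(pts), cls))
    X = np.concatenate(xs)
    y = np.concatenate(ys)
    model = ExtraTreesClassifier(
        n_estimators=n_estimators,
        random_state=int(rng.integers(0, 2**31 - 1)),
        n_jobs=1,
    )
    model.fit(X, y)
    return PixelClassifier(model=model, scales=tuple(scales),
                           n_features=features.shape[-1])


def predict_posteriors(
    classifier: PixelClassifier, image: ChannelImage
) -> np.ndarray:
    """Class posteriors, shape (H, W, 3); rows sum to 1."""
    features = compute_feature_stack(image, classifier.scales)
    if features.shape[-1] != classifier.n_features:
        raise ValueError(
            f"feature dimension mismatch: classifier expects "
            f"{classifier.n_features}, image yields {features.shape[-1]}")
    h, w, f = features.shape
    proba = classifier.model.predict_proba(features.reshape(-1, f))
    # Guard against a class missing from training output ordering.
    full = np.zeros((h * w, 3), dtype=np.float64)
    for j, cls in enumerate(classifier.model.classes_):
        full[:, int(cls)] = proba[:, j]
    return full.reshape(h, w, 3)


def predict_class_map(
    classifier: PixelClassifier, image: ChannelImage
) -> np.ndarray:
    """Argmax class per pixel (ties broken toward background)."""
    post = predict_posteriors(classifier, image)
    # np.argmax returns the first maximum; class order puts background first.
    return np.argmax(post, axis=-1).astype(np.uint8)


def instances_from_classmap(
    classmap: np.ndarray,
    pixel_size: float,
    *,
    min_area: float = 50.0,
    border_policy: str = "exclude",
    cytosol_posterior: np.ndarray | None = None,
    nucleus_min_px: int = 9,
) -> np.ndarray:
    """Separate the class map into cell instances (marker-based watershed).

    Parameters
    ----------
    classmap
        Per-pixel class in {0 background, 1 cytosol, 2 nucleus}.
    pixel_size
        µm/px, used to convert ``min_area`` (µm²) to pixels.
    min_area
        Instances smaller than this physical area are removed (debris floor).
    border_policy
        ``"exclude"`` (default) removes instances touching the tile border,
        whose descriptors would be truncated; ``"keep"`` retains them.
    cytosol_posterior
        Optional (H, W) cytosol-class posterior; flooding runs on its
        inverse.  Without it an inverted distance transform of the
        foreground is used.
    nucleus_min_px
        Nucleus components below this size are not used as markers.

    Returns a label map of consecutive positive integer ids (0 = background).
    """
    if border_policy not in ("exclude", "keep"):
        raise ValueError("border_policy must be 'exclude' or 'keep'")
    classmap = np.asarray(classmap)
    foreground = classmap > 0
    labels = np.zeros(classmap.shape, dtype=np.int32)
    if not foreground.any():
        return labels

    markers, n_markers = ndimage.label(classmap == NUCLEUS, _STRUCT4)
    if n_markers:
        sizes = ndimage.sum_labels(np.ones_like(markers), markers,
                                   index=np.arange(1, n_markers + 1))
        small = np.flatnonzero(sizes < nucleus_min_px) + 1
        if len(small):
            markers[np.isin(markers, small)] = 0
    if cytosol_posterior is not None:
        elevation = -np.asarray(cytosol_posterior, dtype=np.float64)
    else:
        elevation = -ndimage.distance_transform_edt(foreground)

    labels = watershed(elevation, markers=markers, mask=foreground,
                       connectivity=1).astype(np.int32)

    # Foreground blobs with no nucleus marker: keep each as one instance.
    orphan = foreground & (labels == 0)
    if orphan.any():
        orphan_lab, n_orphan = ndimage.label(orphan, _STRUCT4)
        if n_orphan:
            logger.info("%d foreground blob(s) without nucleus marker kept "
                        "as single instances", n_orphan)
            offset = labels.max()
            labels[orphan > 0] = 0  # no-op; clarity
            labels = labels + np.where(orphan_lab > 0, orphan_lab + offset, 0)

    # Physical area floor.
    min_px = min_area / pixel_size**2
    n_lab = labels.max()
    if n_lab:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels,
                                   index=np.arange(1, n_lab + 1))
        drop = set((np.flatnonzero(sizes < min_px) + 1).tolist())
    else:
        drop = set()

    if border_policy == "exclude":
        border = np.concatenate([labels[0, :], labels[-1, :],
                                 labels[:, 0], labels[:, -1]])
        drop |= set(np.unique(border[border > 0]).tolist())

    if drop:
        labels[np.isin(labels, list(drop))] = 0

    # Relabel to consecutive ids, preserving scan order.
    ids = np.unique(labels)
    ids = ids[ids > 0]
    remap = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    remap[ids] = np.arange(1, len(ids) + 1)
    return remap[labels]
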