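import numpy as np
import pytest

import chondroprint as cp


def rasterize_disc(radius_px: int, pad: int = 5) -> np.ndarray:
    n = 2 * (radius_px + pad)
    yy, xx = np.mgrid[0:n, 0:n]
    c = n / 2 - 0.5
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius_px**2


def rasterize_ellipse(a_px: float, b_px: float, pad: int = 5) -> np.ndarray:
    n = 2 * (int(max(a_px, b_px)) + pad)
    yy, xx = np.mgrid[0:n, 0:n]
    c = n / 2 - 0.5
    return ((xx - c) / a_px) ** 2 + ((yy - c) / b_px) ** 2 <= 1.0


@pytest.fixture(scope="session")
def default_scene():
    """One default-noise rendered bovine tile with ground truth."""
    preset = cp.get_preset("bovine-control")
    shapes = cp.generate_shape_population(preset, 22, seed=11)
    shapes = cp.place_cells(shapes, (800.0, 800.0), seed=12)
    img, scene = cp.render_scene(shapes, (800.0, 800.0), 2.0, seed=13)
    return img, scene


@pytest.fixture(scope="session")
def trained_classifier(default_scene):
    """Pixel classifier trained on scribbles from the default scene."""
    img, scene = default_scene
    scribbles = cp.sample_scribbles(scene.class_map, 800, seed=14)
    feats = cp.compute_feature_stack(img)
    return cp.fit_pixel_classifier(feats, scribbles, seed=15)
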