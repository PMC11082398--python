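"""Pixel-level quality maps, class proportions, and the drying endpoint.

A trained model is applied to every plant pixel of a cube: each pixel's
spectrum passes through the same fitted preprocessing state used in
training (so the MSC reference stays the calibration-set reference) and
then through the classifier.  The resulting class map gives per-class
proportions of plant pixels, and the drying endpoint is declared once the
target class (by default the high-CBDA-conversion class) occupies strictly
more than 80 % of the plant pixels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from cannaspec.cube_io import HyperspectralCube
from cannaspec.modeling import ModelBundle, predict

__all__ = [
    "BACKGROUND",
    "ENDPOINT_THRESHOLD_PCT",
    "DEFAULT_PALETTE",
    "ClassMap",
    "classify_pixels",
    "class_proportions",
    "endpoint_reached",
    "render_map",
]

#: Integer sentinel for off-ROI pixels in the label image.
BACKGROUND = -1

ENDPOINT_THRESHOLD_PCT = 80.0

#: Background renders black; class colors follow a colorblind-safe cycle.
DEFAULT_PALETTE = (
    (230, 159, 0),
    (86, 180, 233),
    (0, 158, 115),
    (240, 228, 66),
    (0, 114, 178),
    (213, 94, 0),
)
BACKGROUND_COLOR = (0, 0, 0)


@dataclass
class ClassMap:
    """Per-pixel predicted classes over the plant pixels of one image.

    ``labels`` holds indices into ``class_order`` with ``BACKGROUND`` (-1)
    off the ROI.  ``proportions`` maps class name to its percentage of
    plant pixels (summing to 100 over classes when any plant pixel exists;
    empty when the ROI is empty).
    """

    labels: np.ndarray
    class_order: tuple[str, ...]
    quality: str
    proportions: dict[str, float] = field(default_factory=dict)

    @property
    def n_plant_pixels(self) -> int:
        return int((self.labels != BACKGROUND).sum())


def classify_pixels(
    bundle: ModelBundle, cube: HyperspectralCube, mask: np.ndarray
) -> ClassMap:
    """Classify every ROI pixel of ``cube`` with a trained model.

    Background pixels keep the sentinel value.  An empty mask yields an
    empty map with undefined (empty) proportions and a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cube.shape[:2]:
        raise ValueError("mask shape does not match cube spatial shape")
    if cube.n_bands != bundle.n_bands:
        raise ValueError(
            f"cube has {cube.n_bands} bands; model was trained on {bundle.n_bands}"
        )
    labels = np.full(mask.shape, BACKGROUND, dtype=np.int32)
    class_index = {c: i for i, c in enumerate(bundle.class_order)}
    if mask.any():
        pixel_spectra = cube.reflectance[mask]
        predicted = predict(bundle, pixel_spectra)
        labels[mask] = np.array([class_index[p] for p in predicted], dtype=np.int32)
    else:
        warnings.warn("empty ROI mask: class map has no plant pixels", stacklevel=2)
    cmap = ClassMap(labels=labels, class_order=bundle.class_order, quality=bundle.quality)
    if mask.any():
        cmap.proportions = class_proportions(cmap)
    return cmap


def class_proportions(cmap: ClassMap) -> dict[str, float]:
    """Percentage of plant pixels occupied by each class."""
    n_plant = cmap.n_plant_pixels
    if n_plant == 0:
        raise ValueError("class map has no plant pixels; proportions undefined")
    return {
        cls: 100.0 * float((cmap.labels == i).sum()) / n_plant
        for i, cls in enumerate(cmap.class_order)
    }


def endpoint_reached(
    proportions: dict[str, float],
    target_class: str = "high",
    threshold_pct: float = ENDPOINT_THRESHOLD_PCT,
) -> bool:
    """Drying-endpoint rule: target class strictly above ``threshold_pct``.

    The comparison is strict (a proportion of exactly 80 % does not end
    the drying), matching the "more than 80 %" reading of the rule.
    """
    if target_class not in proportions:
        raise KeyError(f"unknown class {target_class!r}; have {sorted(proportions)}")
    return proportions[target_class] > threshold_pct


def render_map(
    cmap: ClassMap,
    path: str | Path,
    palette: dict[str, tuple[int, int, int]] | None = None,
    endpoint_target: str | None = None,
) -> dict:
    """Write an indexed-color PNG of the class map plus a JSON sidecar.

    The sidecar records the class-to-color legend, the class proportions,
    and (when ``endpoint_target`` is given) the endpoint flag.  Returns the
    sidecar dictionary.
    """
    path = Path(path)
    if palette is None:
        palette = {
            cls: DEFAULT_PALETTE[i % len(DEFAULT_PALETTE)]
            for i, cls in enumerate(cmap.class_order)
        }
    missing = set(cmap.class_order) - set(palette)
    if missing:
        raise ValueError(f"palette missing classes: {sorted(missing)}")

    rgb = np.zeros((*cmap.labels.shape, 3), dtype=np.uint8)
    rgb[cmap.labels == BACKGROUND] = BACKGROUND_COLOR
    for i, cls in enumerate(cmap.class_order):
        rgb[cmap.labels == i] = palette[cls]
    Image.fromarray(rgb).save(path)

    sidecar = {
        "quality": cmap.quality,
        "class_order": list(cmap.class_order),
        "palette": {cls: list(color) for cls, color in palette.items()},
        "background_color": list(BACKGROUND_COLOR),
        "proportions": cmap.proportions,
        "n_plant_pixels": cmap.n_plant_pixels,
    }
    if endpoint_target is not None and cmap.proportions:
        sidecar["endpoint_target"] = endpoint_target
        sidecar["endpoint_reached"] = endpoint_reached(cmap.proportions, endpoint_target)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return sidecar
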