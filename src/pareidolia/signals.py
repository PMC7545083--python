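"""Procedurally drawn stand-in signal images.

The original studies used cropped photographs of faces and donkey orchids,
which cannot be redistributed; the package ships synthetic schematic line-art
drawn from geometric primitives instead (two "identities" per category).
They carry the features that matter for the pipeline — closed bilateral
contours, internal structure, a fixed height of 150 px and category-specific
widths (face 110 px, flower 120 px) — not photographic realism.
"""

from __future__ import annotations

import numpy as np

__all__ = ["draw_face", "draw_flower"]

_BG = 150.0
_INK = 40.0


def _canvas(h: int, w: int) -> np.ndarray:
    return np.full((h, w), _BG)


def _grid(h: int, w: int):
    y, x = np.mgrid[0:h, 0:w]
    return y.astype(float), x.astype(float)


def _ellipse_ring(y, x, cy, cx, ry, rx, thickness):
    r = np.sqrt(((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2)
    return np.abs(r - 1.0) < thickness


def _ellipse_fill(y, x, cy, cx, ry, rx):
    return ((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2 <= 1.0


def draw_face(identity: int = 0, height: int = 150, width: int = 110) -> np.ndarray:
    """Schematic frontal face: head outline, two eyes, nose, mouth.

    ``identity`` 0 and 1 differ in head roundness and feature placement,
    mimicking two distinct photographic identities.
    """
    img = _canvas(height, width)
    y, x = _grid(height, width)
    cy, cx = height / 2, width / 2
    if identity % 2 == 0:
        ry, rx, eye_dy, mouth_rx = 0.46 * height, 0.42 * width, 0.14, 0.22
    else:
        ry, rx, eye_dy, mouth_rx = 0.48 * height, 0.38 * width, 0.12, 0.18
    img[_ellipse_ring(y, x, cy, cx, ry, rx, 0.045)] = _INK
    for side in (-1, 1):
        ex = cx + side * 0.18 * width
        ey = cy - eye_dy * height
        img[_ellipse_fill(y, x, ey, ex, 0.035 * height, 0.08 * width)] = _INK
    # nose: short vertical bar
    nose = (np.abs(x - cx) < 0.02 * width) & (np.abs(y - cy) < 0.08 * height)
    img[nose] = _INK
    # mouth: lower arc of an ellipse
    mouth = _ellipse_ring(y, x, cy + 0.18 * height, cx, 0.08 * height, mouth_rx * width, 0.08)
    img[mouth & (y > cy + 0.18 * height)] = _INK
    return img


def draw_flower(identity: int = 0, height: int = 150, width: int = 120) -> np.ndarray:
    """Schematic orchid-like flower: bilaterally symmetric petals around a
    centre, with a stalk."""
    img = _canvas(height, width)
    y, x = _grid(height, width)
    cy, cx = 0.40 * height, width / 2
    n_petals = 5 if identity % 2 == 0 else 6
    petal_len = 0.30 * height if identity % 2 == 0 else 0.26 * height
    angles = np.linspace(-np.pi / 2, 3 * np.pi / 2, n_petals, endpoint=False)
    for ang in angles:
        py = cy + petal_len * 0.55 * np.sin(ang)
        px = cx + petal_len * 0.55 * np.cos(ang)
        # petal as a thin ellipse elongated along its angle
        dy, dx = y - py, x - px
        u = dy * np.sin(ang) + dx * np.cos(ang)
        v = -dy * np.cos(ang) + dx * np.sin(ang)
        ring = np.abs(np.sqrt((u / (petal_len * 0.5)) ** 2 + (v / (0.10 * width)) ** 2) - 1.0) < 0.10
        img[ring] = _INK
    img[_ellipse_fill(y, x, cy, cx, 0.05 * height, 0.06 * width)] = _INK
    stalk = (np.abs(x - cx) < 0.018 * width) & (y > cy + 0.28 * height) & (y < 0.97 * height)
    img[stalk] = _INK
    return img
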