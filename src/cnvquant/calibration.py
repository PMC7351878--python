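"""Analytic calibration fixtures for the box-counting estimator.

Shapes with known (similarity) dimension, rasterized to boolean masks:
a straight line (dimension 1), the Sierpinski triangle (log 3 / log 2
~ 1.585), the Koch curve (log 4 / log 3 ~ 1.262) and the filled square
(dimension 2).  Used to validate the fractal-dimension pipeline end to end.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "line_mask",
    "sierpinski_mask",
    "koch_mask",
    "SIERPINSKI_DIMENSION",
    "KOCH_DIMENSION",
]

SIERPINSKI_DIMENSION = float(np.log(3) / np.log(2))
KOCH_DIMENSION = float(np.log(4) / np.log(3))


def line_mask(side: int = 512) -> np.ndarray:
    """A one-pixel horizontal line across a ``side`` x ``side`` canvas."""
    m = np.zeros((side, side), dtype=bool)
    m[side // 2, :] = True
    return m


def sierpinski_mask(order: int = 7) -> np.ndarray:
    """Sierpinski triangle of the given order on a 2**order canvas."""
    m = np.ones((1, 1), dtype=bool)
    for _ in range(order):
        empty = np.zeros_like(m)
        m = np.block([[m, m], [m, empty]])
    return m


def _koch_points(order: int) -> np.ndarray:
    pts = np.array([[0.0, 0.0], [1.0, 0.0]])
    rot = np.array([[0.5, -np.sqrt(3) / 2], [np.sqrt(3) / 2, 0.5]])  # +60 degrees
    for _ in range(order):
        out = [pts[0]]
        for a, b in zip(pts[:-1], pts[1:]):
            d = b - a
            p1, p2 = a + d / 3, a + 2 * d / 3
            out += [p1, p1 + rot @ (d / 3), p2, b]
        pts = np.asarray(out)
    return pts


def koch_mask(order: int = 5, width: int = 512) -> np.ndarray:
    """Koch curve of the given order drawn as a one-pixel polyline."""
    from skimage.draw import line as sk_line

    pts = _koch_points(order)
    scale = width - 20
    xy = pts * scale + 10
    height = int(0.32 * scale) + 24
    m = np.zeros((height, width), dtype=bool)
    for a, b in zip(xy[:-1], xy[1:]):
        rr, cc = sk_line(
            int(round(a[1])) + 2, int(round(a[0])), int(round(b[1])) + 2, int(round(b[0]))
        )
        m[rr, cc] = True
    return m
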