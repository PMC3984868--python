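"""Quality maps, user weights, and IRLS data weights.

Two layers of weighting steer the minimum-Lp solution:

* *user weights* ``w`` in [0, 1], derived once from a local-variance quality
  map of the wrapped gradients (a pixel is reliable where the phase changes
  smoothly), then transferred to edges as ``wx[i,j] = min(w[i+1,j], w[i,j])``
  and ``wy[i,j] = min(w[i,j+1], w[i,j])``;
* *data weights* ``R``, ``C``, recomputed every iteration from the current
  unwrapped estimate phi:

      R[i,j] = wx[i,j] * alpha / (|phi[i+1,j] - phi[i,j] - dx[i,j]|^(2-p) + alpha)

  and likewise C from the column residuals.  This is the iteratively
  reweighted least-squares surrogate for the Lp objective: for p < 2 an edge
  whose residual is large (a discontinuity) is progressively suppressed,
  while the additive alpha (default 0.01 rad) keeps every weight finite and
  bounded by wx.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .phase_core import GradientField, PhaseImage

__all__ = [
    "QualityMap",
    "UserWeights",
    "DataWeights",
    "quality_map",
    "user_weights",
    "data_weights",
]


@dataclass
class QualityMap:
    """Local-variance quality map ``z`` (lower = smoother phase)."""

    z: np.ndarray
    window: int

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=float)
        if np.any(self.z < 0):
            raise ValueError("quality map must be nonnegative")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")


@dataclass
class UserWeights:
    """Per-pixel weights ``w`` in [0,1] and their edge transfers wx, wy."""

    w: np.ndarray
    wx: np.ndarray
    wy: np.ndarray

    def __post_init__(self):
        for name in ("w", "wx", "wy"):
            a = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, a)
            if a.min(initial=0.0) < 0 or a.max(initial=0.0) > 1:
                raise ValueError(f"{name} entries must lie in [0, 1]")


@dataclass
class DataWeights:
    """IRLS edge weights R (row edges) and C (column edges)."""

    R: np.ndarray
    C: np.ndarray
    p: float
    alpha: float

    def __post_init__(self):
        self.R = np.asarray(self.R, dtype=float)
        self.C = np.asarray(self.C, dtype=float)
        if not (0.0 <= self.p <= 2.0):
            raise ValueError("p must lie in [0, 2]")
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if np.any(self.R < 0) or np.any(self.C < 0):
            raise ValueError("data weights must be nonnegative")


def _box_sums(a: np.ndarray, rlo, rhi, clo, chi) -> np.ndarray:
    """Inclusive rectangular sums of ``a`` via a summed-area table.

    The bound arrays are broadcastable integer arrays with rlo <= rhi and
    clo <= chi elementwise.
    """
    s = np.zeros((a.shape[0] + 1, a.shape[1] + 1))
    np.cumsum(a, axis=0, out=s[1:, 1:])
    np.cumsum(s[1:, 1:], axis=1, out=s[1:, 1:])
    return s[rhi + 1, chi + 1] - s[rlo, chi + 1] - s[rhi + 1, clo] + s[rlo, clo]


def quality_map(grad: GradientField, window: int = 3) -> QualityMap:
    """Windowed variance of the wrapped gradients, per pixel.

    For each pixel, the sum of squared deviations of the dx and dy samples
    falling inside the ``window`` x ``window`` pixel neighbourhood (each
    about its own window mean) is divided by ``window**2``.  A gradient
    sample belongs to a window only when both of its endpoint pixels do;
    windows are truncated at the image border.
    """
    m, n = grad.image_shape
    if window % 2 == 0 or window < 3:
        raise ValueError("window must be an odd integer >= 3")
    if window > min(m, n):
        raise ValueError(f"window {window} exceeds image extent {min(m, n)}")
    h = window // 2
    rows = np.arange(m)[:, None]
    cols = np.arange(n)[None, :]

    def ssq(a, rmax, cmax, along_rows):
        # dx sample (i, j) lies in the window centred at (r, c) iff rows i and
        # i+1 are within [r-h, r+h] and column j is; mirrored for dy.
        if along_rows:
            rlo = np.clip(rows - h, 0, rmax)
            rhi = np.clip(rows + h - 1, 0, rmax)
            clo = np.clip(cols - h, 0, cmax)
            chi = np.clip(cols + h, 0, cmax)
        else:
            rlo = np.clip(rows - h, 0, rmax)
            rhi = np.clip(rows + h, 0, rmax)
            clo = np.clip(cols - h, 0, cmax)
            chi = np.clip(cols + h - 1, 0, cmax)
        cnt = (rhi - rlo + 1) * (chi - clo + 1)
        s1 = _box_sums(a, rlo, rhi, clo, chi)
        s2 = _box_sums(a * a, rlo, rhi, clo, chi)
        return np.maximum(s2 - s1 * s1 / cnt, 0.0)

    z = ssq(grad.dx, m - 2, n - 1, True) + ssq(grad.dy, m - 1, n - 2, False)
    return QualityMap(z=z / float(window * window), window=window)


def user_weights(q: QualityMap, mask: Optional[np.ndarray] = None) -> UserWeights:
    """Affinely invert the quality map into pixel weights and edge weights.

    ``w = (max z - z) / (max z - min z)``; a constant quality map (e.g. a
    perfectly smooth field) degenerates to ``w == 1`` everywhere.  Masked-out
    pixels get weight 0 before the edge min-rule.
    """
    z = q.z
    zmin, zmax = float(z.min()), float(z.max())
    if zmax > zmin:
        w = (zmax - z) / (zmax - zmin)
    else:
        w = np.ones_like(z)
    if mask is not None:
        w = np.where(np.asarray(mask, dtype=bool), w, 0.0)
    wx = np.minimum(w[1:, :], w[:-1, :])
    wy = np.minimum(w[:, 1:], w[:, :-1])
    return UserWeights(w=w, wx=wx, wy=wy)


def data_weights(
    phi: PhaseImage,
    grad: GradientField,
    uw: UserWeights,
    p: float = 0.0,
    alpha: float = 0.01,
) -> DataWeights:
    """IRLS reweighting of the edges from the current unwrapped estimate."""
    if not (0.0 <= p <= 2.0):
        raise ValueError("p must lie in [0, 2]")
    if not alpha > 0:
        raise ValueError("alpha must be positive")
    if phi.is_wrapped:
        raise ValueError("data_weights expects an unwrapped estimate")
    v = phi.values
    rx = np.abs(v[1:, :] - v[:-1, :] - grad.dx)
    ry = np.abs(v[:, 1:] - v[:, :-1] - grad.dy)
    expo = 2.0 - p
    r_weights = uw.wx * alpha / (rx**expo + alpha)
    c_weights = uw.wy * alpha / (ry**expo + alpha)
    return DataWeights(R=r_weights, C=c_weights, p=p, alpha=alpha)
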