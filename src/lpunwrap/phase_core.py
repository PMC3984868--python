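"""Wrapping arithmetic, wrapped gradients and residue detection.

These are the primitives of 2D phase unwrapping.  A wrapped (principal-value)
phase image holds values in the half-open interval (-pi, pi]; the wrapping
operator ``wrap`` maps any finite phase into that interval by adding an
integer multiple of 2*pi.  Residues -- 2x2 pixel loops around which the
wrapped gradients sum to +-2*pi -- are the obstructions that make unwrapping
path dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

TWO_PI = 2.0 * np.pi

__all__ = [
    "TWO_PI",
    "PhaseImage",
    "GradientField",
    "ResidueMap",
    "wrap",
    "wrapped_gradients",
    "detect_residues",
    "count_residues",
]


def wrap(x):
    """Map phase values into the principal interval (-pi, pi].

    The boundary convention is left-open / right-closed: ``wrap(pi) == pi``
    and ``wrap(-pi) == pi``.  The result differs from the input by an exact
    integer multiple of 2*pi (up to floating-point rounding).

    Parameters
    ----------
    x : float or array_like
        Finite phase value(s) in radians.

    Returns
    -------
    float or ndarray
        Same shape as ``x``, values in (-pi, pi].
    """
    arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("wrap: input must be finite")
    # pi - mod(pi - x, 2pi) lands exactly in (-pi, pi] with wrap(pi) = pi.
    out = np.pi - np.mod(np.pi - arr, TWO_PI)
    if arr.ndim == 0:
        return float(out)
    return out


def _check_wrapped_range(values: np.ndarray) -> bool:
    return bool(np.all((values > -np.pi) & (values <= np.pi)))


@dataclass
class PhaseImage:
    """A 2D phase image in radians.

    Parameters
    ----------
    values : ndarray, shape (M, N)
        Phase values in radians; finite.
    is_wrapped : bool
        True if ``values`` are principal values in (-pi, pi].
    mask : ndarray of bool, optional
        True marks a valid pixel.  Masked-out pixels receive zero user
        weight downstream.
    affine : ndarray, optional
        4x4 spatial metadata carried through NIfTI round trips; ignored by
        all computation.
    """

    values: np.ndarray
    is_wrapped: bool
    mask: Optional[np.ndarray] = None
    affine: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("PhaseImage requires a 2D array")
        m, n = self.values.shape
        if m < 2 or n < 2:
            raise ValueError(f"PhaseImage requires M, N >= 2, got {m}x{n}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("PhaseImage values must be finite")
        if self.is_wrapped and not _check_wrapped_range(self.values):
            raise ValueError("wrapped PhaseImage values must lie in (-pi, pi]")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape must match values")

    @property
    def shape(self):
        return self.values.shape


@dataclass
class GradientField:
    """Wrapped first differences of a wrapped phase image.

    ``dx[i, j] = wrap(psi[i+1, j] - psi[i, j])`` (along rows, the first
    axis) has shape (M-1, N); ``dy[i, j] = wrap(psi[i, j+1] - psi[i, j])``
    has shape (M, N-1).
    """

    dx: np.ndarray
    dy: np.ndarray

    def __post_init__(self):
        self.dx = np.asarray(self.dx, dtype=float)
        self.dy = np.asarray(self.dy, dtype=float)
        if self.dx.ndim != 2 or self.dy.ndim != 2:
            raise ValueError("gradient components must be 2D")
        mx, nx = self.dx.shape
        my, ny = self.dy.shape
        if (mx + 1, nx) != (my, ny + 1):
            raise ValueError(
                f"inconsistent gradient shapes {self.dx.shape} / {self.dy.shape}"
            )

    @property
    def image_shape(self):
        """Shape (M, N) of the source image."""
        return (self.dx.shape[0] + 1, self.dx.shape[1])


@dataclass
class ResidueMap:
    """Integer residue charges on the (M-1) x (N-1) loop grid."""

    charges: np.ndarray

    def __post_init__(self):
        self.charges = np.asarray(self.charges)
        if self.charges.ndim != 2 or not np.issubdtype(self.charges.dtype, np.integer):
            raise ValueError("charges must be a 2D integer array")
        if np.any(np.abs(self.charges) > 1):
            raise ValueError("residue charges must lie in {-1, 0, +1}")

    @property
    def is_residue_free(self) -> bool:
        return not np.any(self.charges)


def wrapped_gradients(psi: PhaseImage) -> GradientField:
    """Wrapped forward differences of a wrapped phase image."""
    if not psi.is_wrapped:
        raise ValueError("wrapped_gradients expects a wrapped PhaseImage")
    v = psi.values
    dx = wrap(v[1:, :] - v[:-1, :])
    dy = wrap(v[:, 1:] - v[:, :-1])
    return GradientField(dx=dx, dy=dy)


def detect_residues(grad: GradientField, tol: float = 1e-6) -> ResidueMap:
    """Sum wrapped gradients around every 2x2 loop and return the charges.

    The counter-clockwise loop sum at (i, j) is
    ``dx[i, j] - dy[i, j] - dx[i, j+1] + dy[i+1, j]``; it must be an integer
    multiple of 2*pi to within ``tol`` radians, and the integer must be in
    {-1, 0, +1}, else the field is numerically inconsistent.
    """
    dx, dy = grad.dx, grad.dy
    loop = dx[:, :-1] - dy[:-1, :] - dx[:, 1:] + dy[1:, :]
    k = np.rint(loop / TWO_PI)
    err = np.abs(loop - k * TWO_PI)
    if err.size and float(err.max()) > tol:
        i, j = np.unravel_index(int(np.argmax(err)), err.shape)
        raise ValueError(
            f"loop sum at ({i},{j}) is {loop[i, j]:.6g} rad, not within "
            f"{tol:g} of a 2*pi multiple"
        )
    if np.any(np.abs(k) > 1):
        raise ValueError("loop charge with |charge| > 1 encountered")
    return ResidueMap(charges=k.astype(np.int64))


def count_residues(res: ResidueMap) -> int:
    """Number of nonzero residue charges."""
    return int(np.count_nonzero(res.charges))
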