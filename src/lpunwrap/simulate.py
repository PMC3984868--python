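"""Synthetic wrapped-phase phantoms.

The workhorse is the *two-plane shear phantom*: a planar phase ramp torn
along a horizontal shear line, the raised region offset by a non-2*pi jump.
The inter-plane offset varies linearly along the shear (``jump_tilt``), so
the tear gradient crosses +-pi at a few columns: those crossings emit
residue pairs that localize the tear, and the columns where the offset
passes through the principal interval pin the true inter-plane 2*pi count —
making the true surface recoverable by a discontinuity-preserving
unwrapper.  (With a constant full-width offset the loop sums around the
tear cancel, the field is residue free, and any offset outside (-pi, pi]
is invisible modulo 2*pi.)  Optional additive Gaussian noise is scaled to a
target SNR in dB, defined as ``10*log10(var(signal) / var(noise))``.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Optional, Tuple

import numpy as np

from .phase_core import PhaseImage, wrap

__all__ = [
    "ShearPhantomSpec",
    "make_ramp_phase",
    "make_shear_phantom",
    "add_gaussian_noise",
]


@dataclass(frozen=True)
class ShearPhantomSpec:
    """Generating parameters of a two-plane shear phantom.

    The tear lies between rows ``shear_row - 1`` and ``shear_row``; rows
    ``i < shear_row`` are raised by ``jump + jump_tilt * j`` at column j.

    The defaults are chosen so the phantom is *identifiable*: the tear
    gradient ``slope_x - (jump + jump_tilt*j)`` exceeds pi in magnitude on a
    short leading segment (a genuine discontinuity emitting a residue where
    it crosses the band edge) while the long in-band remainder of the shear
    pins the true inter-plane 2*pi count.  The out-of-band segment must stay
    shorter than the upper plane is thick, or a cut through the plane
    becomes cheaper than the true tear and no unwrapper can prefer the
    truth.
    """

    M: int = 128
    N: int = 128
    shear_row: int = 13
    slope_x: float = 0.2
    slope_y: float = 0.2
    jump: float = 3.5
    jump_tilt: float = -0.03
    noise_snr_db: Optional[float] = None
    seed: int = 0

    def __post_init__(self):
        if not (2 <= self.shear_row <= self.M - 1):
            raise ValueError("shear_row must satisfy 2 <= shear_row <= M-1")
        if not math.isfinite(self.jump):
            raise ValueError("jump must be finite")

    def to_dict(self) -> dict:
        return asdict(self)


def make_ramp_phase(
    m: int, n: int, slope_x: float, slope_y: float, offset: float = 0.0
) -> PhaseImage:
    """Planar ramp ``theta[i, j] = offset + slope_x * i + slope_y * j`` (unwrapped)."""
    i = np.arange(m)[:, None]
    j = np.arange(n)[None, :]
    theta = offset + slope_x * i + slope_y * j + np.zeros((m, n))
    return PhaseImage(values=theta, is_wrapped=False)


def make_shear_phantom(spec: ShearPhantomSpec) -> Tuple[PhaseImage, PhaseImage]:
    """Generate (true phase, wrapped observation) for a shear phantom."""
    truth = make_ramp_phase(spec.M, spec.N, spec.slope_x, spec.slope_y)
    theta = truth.values
    j = np.arange(spec.N)[None, :]
    theta[: spec.shear_row, :] += spec.jump + spec.jump_tilt * j
    observed = truth
    if spec.noise_snr_db is not None and not np.isinf(spec.noise_snr_db):
        observed = add_gaussian_noise(truth, spec.noise_snr_db, spec.seed)
    wrapped = PhaseImage(values=wrap(observed.values), is_wrapped=True)
    return truth, wrapped


def add_gaussian_noise(img: PhaseImage, snr_db: float, seed: int) -> PhaseImage:
    """Add zero-mean Gaussian noise at the requested SNR (variance ratio, dB)."""
    if np.isinf(snr_db) and snr_db > 0:
        return PhaseImage(
            values=img.values.copy(), is_wrapped=img.is_wrapped, mask=img.mask
        )
    signal_var = float(np.var(img.values))
    if signal_var == 0:
        raise ValueError("SNR is undefined for a constant image")
    noise_var = signal_var / 10.0 ** (snr_db / 10.0)
    rng = np.random.default_rng(seed)
    noisy = img.values + rng.normal(0.0, math.sqrt(noise_var), size=img.shape)
    return PhaseImage(values=noisy, is_wrapped=False, mask=img.mask)
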