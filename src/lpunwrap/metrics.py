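"""Solution-quality metrics.

The primary figure of merit is the weighted L0 measure

    rho = (1/MN) [ sum wx * |phi[i+1,j] - phi[i,j] - dx[i,j]|^0
                 + sum wy * |phi[i,j+1] - phi[i,j] - dy[i,j]|^0 ],

the (weighted) fraction of grid edges whose unwrapped gradient mismatches
the wrapped gradient — exactly the quantity the p = 0 iteration minimizes;
lower is better.  In floating point ``|x|^0`` is realized as the indicator
``|x| > tau`` with tau = 1e-6 rad: on congruent solutions every residual is
an exact multiple of 2*pi, so any tau in (0, pi) counts the same edges.
Note the normalization is by MN although about 2*MN edges are summed, so
rho ranges over [0, ~2].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .phase_core import GradientField, PhaseImage
from .weighting import UserWeights

__all__ = [
    "MISMATCH_TOL",
    "EvaluationReport",
    "weighted_l0_measure",
    "discontinuity_map",
    "rms_error_vs_truth",
    "evaluate",
]

#: Residual magnitude (rad) above which an edge counts as mismatched.
MISMATCH_TOL = 1e-6


@dataclass
class EvaluationReport:
    weighted_l0: float
    n_mismatch_x: int
    n_mismatch_y: int
    discontinuity_map: np.ndarray
    rms_error_vs_truth: Optional[float] = None

    def to_dict(self) -> dict:
        out = {
            "weighted_l0": self.weighted_l0,
            "n_mismatch_x": self.n_mismatch_x,
            "n_mismatch_y": self.n_mismatch_y,
            "n_discontinuity_pixels": int(np.count_nonzero(self.discontinuity_map)),
        }
        if self.rms_error_vs_truth is not None:
            out["rms_error_vs_truth"] = self.rms_error_vs_truth
        return out


def _edge_mismatches(phi: np.ndarray, grad: GradientField, tol: float):
    rx = phi[1:, :] - phi[:-1, :] - grad.dx
    ry = phi[:, 1:] - phi[:, :-1] - grad.dy
    return np.abs(rx) > tol, np.abs(ry) > tol


def weighted_l0_measure(
    phi: PhaseImage,
    grad: GradientField,
    uw: UserWeights,
    tol: float = MISMATCH_TOL,
) -> float:
    """Weighted fraction of edges where phi's gradient mismatches the data."""
    if phi.shape != grad.image_shape:
        raise ValueError("phi shape does not match the gradient field")
    mx, my = _edge_mismatches(phi.values, grad, tol)
    m, n = phi.shape
    return float((np.sum(uw.wx * mx) + np.sum(uw.wy * my)) / (m * n))


def discontinuity_map(phi: PhaseImage) -> np.ndarray:
    """Pixels differing from any 4-neighbour by more than pi radians."""
    v = phi.values
    out = np.zeros(v.shape, dtype=bool)
    jump_x = np.abs(v[1:, :] - v[:-1, :]) > np.pi
    jump_y = np.abs(v[:, 1:] - v[:, :-1]) > np.pi
    out[1:, :] |= jump_x
    out[:-1, :] |= jump_x
    out[:, 1:] |= jump_y
    out[:, :-1] |= jump_y
    return out


def rms_error_vs_truth(phi: PhaseImage, truth: PhaseImage) -> float:
    """RMS deviation from the truth after removing the best constant offset."""
    if phi.shape != truth.shape:
        raise ValueError("phi and truth must have the same shape")
    diff = phi.values - truth.values
    diff = diff - diff.mean()
    return float(np.sqrt(np.mean(diff**2)))


def evaluate(
    phi: PhaseImage,
    grad: GradientField,
    uw: UserWeights,
    truth: Optional[PhaseImage] = None,
    tol: float = MISMATCH_TOL,
) -> EvaluationReport:
    """Bundle the standard metrics into one report."""
    mx, my = _edge_mismatches(phi.values, grad, tol)
    return EvaluationReport(
        weighted_l0=weighted_l0_measure(phi, grad, uw, tol),
        n_mismatch_x=int(np.count_nonzero(mx)),
        n_mismatch_y=int(np.count_nonzero(my)),
        discontinuity_map=discontinuity_map(phi),
        rms_error_vs_truth=(
            None if truth is None else rms_error_vs_truth(phi, truth)
        ),
    )
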