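"""The outer minimum-Lp unwrapping iteration.

Each pass solves a weighted least-squares problem, compares the estimate
with the data through the *distinction* ``E = wrap(psi - phi)``, and stops
as soon as E is residue-free: a residue-free wrapped field unwraps uniquely
(up to a constant) by flood fill, and adding the unwrapped distinction back
to the estimate makes the result congruent with the input — every pixel of
``phi_final - psi`` is an exact integer multiple of 2*pi.

The iteration schedule:

1. k = 0: solve with the user weights alone (R = wx, C = wy), the weighted
   least-squares bootstrap — the IRLS weights need a current estimate.
2. Recompute the IRLS data weights from the current estimate, reassemble and
   resolve; repeat until the distinction is residue-free or ``k_max``
   reweighting passes have run.
3. Flood-fill unwrap the (best) distinction from the image centre and add it
   back to the estimate.

If ``k_max`` is exhausted, the iterate with the fewest distinction residues
(earliest on ties) is still congruence-corrected, so the congruence
invariant holds on every run; ``converged`` is False in that case.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .linear_system import assemble_system, devectorize, solve_direct
from .metrics import weighted_l0_measure
from .phase_core import (
    PhaseImage,
    count_residues,
    detect_residues,
    wrap,
    wrapped_gradients,
)
from .weighting import (
    DataWeights,
    UserWeights,
    data_weights,
    quality_map,
    user_weights,
)

__all__ = [
    "LpUnwrapConfig",
    "IterationRecord",
    "UnwrapResult",
    "distinction",
    "floodfill_unwrap",
    "congruence_correct",
    "lp_unwrap",
]


@dataclass(frozen=True)
class LpUnwrapConfig:
    """Tunables of the minimum-Lp unwrapper.

    p : norm exponent in [0, 2]; 0 (the default) counts mismatched edges
        and best preserves genuine discontinuities, 2 is plain weighted
        least squares.
    alpha : IRLS regularizer in radians (default 0.01).
    window : odd side length of the quality-map window (default 3).
    k_max : maximum number of reweighting passes after the bootstrap
        solve (default 20).
    seed : reserved for randomized tie-breaking; the default pipeline is
        fully deterministic and never consumes it.
    """

    p: float = 0.0
    alpha: float = 0.01
    window: int = 3
    k_max: int = 20
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.p <= 2.0):
            raise ValueError("p must lie in [0, 2]")
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 3")
        if self.k_max < 1:
            raise ValueError("k_max must be >= 1")


@dataclass
class IterationRecord:
    """Diagnostics of one solve: distinction residues and the L0 measure."""

    residues: int
    weighted_l0: float


@dataclass
class UnwrapResult:
    phi_final: PhaseImage
    iterations_run: int
    converged: bool
    history: List[IterationRecord] = field(default_factory=list)


def distinction(psi: PhaseImage, phi: PhaseImage) -> np.ndarray:
    """Wrapped difference ``E = wrap(psi - phi)`` between data and estimate."""
    if psi.shape != phi.shape:
        raise ValueError("psi and phi must have the same shape")
    if not psi.is_wrapped:
        raise ValueError("psi must be wrapped")
    return wrap(psi.values - phi.values)


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def floodfill_unwrap(
    e: np.ndarray,
    *,
    check_residues: bool = True,
    discipline: str = "fifo",
) -> np.ndarray:
    """Unwrap a residue-free wrapped field by flood fill from the centre.

    The start pixel (row round(M/2), column round(N/2), one-based) keeps its
    value; every newly reached 4-neighbour ``q`` of an already-unwrapped
    pixel ``u`` receives ``value(u) + wrap(e[q] - e[u])``.  On a residue-free
    field the result is independent of the traversal order; the neighbour
    order (up, down, left, right) and the FIFO queue are fixed anyway for
    bit-reproducibility.  ``discipline`` may be set to ``"lifo"`` to check
    that order-independence.
    """
    e = np.asarray(e, dtype=float)
    if e.ndim != 2:
        raise ValueError("expected a 2D field")
    m, n = e.shape
    if check_residues and m >= 2 and n >= 2:
        res = detect_residues(
            wrapped_gradients(PhaseImage(wrap(e), is_wrapped=True))
        )
        if not res.is_residue_free:
            raise ValueError(
                "field has residues; flood-fill unwrapping would be "
                "path dependent"
            )
    if discipline not in ("fifo", "lifo"):
        raise ValueError("discipline must be 'fifo' or 'lifo'")
    # Track integer 2*pi offsets rather than accumulating floats: the result
    # e + 2*pi*k is then bit-identical for every traversal order on a
    # residue-free field (the k are determined by exact integer arithmetic).
    k = np.zeros(e.shape, dtype=np.int64)
    seen = np.zeros(e.shape, dtype=bool)
    start = (_round_half_up(m / 2) - 1, _round_half_up(n / 2) - 1)
    seen[start] = True
    queue = deque([start])
    pop = queue.popleft if discipline == "fifo" else queue.pop
    two_pi = 2.0 * np.pi
    while queue:
        i, j = pop()
        for qi, qj in ((i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)):
            if 0 <= qi < m and 0 <= qj < n and not seen[qi, qj]:
                d = e[qi, qj] - e[i, j]
                if -np.pi < d <= np.pi:
                    shift = 0
                else:
                    # largest integer with d - 2*pi*shift in (-pi, pi]
                    shift = int(np.ceil((d - np.pi) / two_pi))
                k[qi, qj] = k[i, j] - shift
                seen[qi, qj] = True
                queue.append((qi, qj))
    return e + two_pi * k


def congruence_correct(phi: PhaseImage, e_unwrapped: np.ndarray) -> PhaseImage:
    """Add the unwrapped distinction back: ``phi_final = phi + w^-1{E}``."""
    e_unwrapped = np.asarray(e_unwrapped, dtype=float)
    if e_unwrapped.shape != phi.shape:
        raise ValueError("shape mismatch between phi and the unwrapped field")
    return PhaseImage(
        values=phi.values + e_unwrapped,
        is_wrapped=False,
        mask=phi.mask,
        affine=phi.affine,
    )


def lp_unwrap(
    psi: PhaseImage,
    cfg: LpUnwrapConfig = LpUnwrapConfig(),
    user_w: Optional[UserWeights] = None,
) -> UnwrapResult:
    """Run the full minimum-Lp unwrapping pipeline on a wrapped image."""
    if not psi.is_wrapped:
        raise ValueError("lp_unwrap expects a wrapped PhaseImage")
    grad = wrapped_gradients(psi)
    if user_w is None:
        user_w = user_weights(quality_map(grad, cfg.window), mask=psi.mask)

    # Bootstrap: data-dependent factor = 1, i.e. weighted least squares.
    dw = DataWeights(R=user_w.wx, C=user_w.wy, p=cfg.p, alpha=cfg.alpha)

    history: List[IterationRecord] = []
    best_phi = None
    best_e = None
    best_res = None
    converged = False

    for k in range(cfg.k_max + 1):
        system = assemble_system(grad, dw)
        phi_arr = devectorize(solve_direct(system), *psi.shape)
        phi_img = PhaseImage(values=phi_arr, is_wrapped=False)
        e = distinction(psi, phi_img)
        res = count_residues(
            detect_residues(wrapped_gradients(PhaseImage(e, is_wrapped=True)))
        )
        history.append(
            IterationRecord(
                residues=res,
                weighted_l0=weighted_l0_measure(phi_img, grad, user_w),
            )
        )
        if best_res is None or res < best_res:
            best_res, best_phi, best_e = res, phi_img, e
        if res == 0:
            converged = True
            break
        if k == cfg.k_max:
            break
        dw = data_weights(phi_img, grad, user_w, p=cfg.p, alpha=cfg.alpha)

    # Residue-freeness was already established above; when k_max is exhausted
    # with residues left the best iterate is still flood-filled (the result is
    # then path dependent but remains congruent with psi).
    e_unwrapped = floodfill_unwrap(best_e, check_residues=False)
    phi_final = congruence_correct(best_phi, e_unwrapped)
    phi_final.mask = psi.mask
    phi_final.affine = psi.affine
    return UnwrapResult(
        phi_final=phi_final,
        iterations_run=len(history),
        converged=converged,
        history=history,
    )
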