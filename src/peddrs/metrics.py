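"""Quantitative evaluation of tomographic reconstructions.

Four indicators are standard for phantom studies: the location error E_L
(Euclidean distance between reconstructed and true source centers, mm),
the Dice coefficient between reconstructed and true node sets, the
true-to-reconstructed volume ratio R_V, and the global relative residual
R_R = ||B - A x|| / ||B||.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .phantom_mesh import TetMesh, fractional_node_set_volume

__all__ = [
    "ReconRegion",
    "reconstructed_region",
    "location_error",
    "round_half_up",
    "dice_coefficient",
    "volume_ratio",
    "relative_residual",
]


@dataclass
class ReconRegion:
    """Thresholded reconstructed source region."""

    nodes: np.ndarray  # sorted node indices
    center: np.ndarray  # intensity-weighted centroid, mm
    volume: float  # V_R by fractional vertex counting, mm^3


def reconstructed_region(
    x_final: np.ndarray, mesh: TetMesh, tau: float = 0.1
) -> ReconRegion:
    """Nodes with intensity >= tau * max, their weighted centroid and volume.

    tau = 0.1 by default; the region (hence Dice and R_V) depends on it.
    """
    if not 0 <= tau < 1:
        raise ValueError("tau must be in [0, 1)")
    x_final = np.asarray(x_final, dtype=float)
    mx = x_final.max()
    if mx <= 0:
        raise ValueError("x_final is identically zero")
    nodes = np.flatnonzero(x_final >= tau * mx)
    w = x_final[nodes]
    center = (mesh.nodes[nodes] * w[:, None]).sum(axis=0) / w.sum()
    return ReconRegion(
        nodes=nodes,
        center=center,
        volume=fractional_node_set_volume(mesh, nodes),
    )


def location_error(recon_center: np.ndarray, true_center: np.ndarray) -> float:
    """E_L: Euclidean distance between the two centers (mm)."""
    return float(np.linalg.norm(np.asarray(recon_center) - np.asarray(true_center)))


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching conventional table formatting."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def dice_coefficient(R: np.ndarray, T: np.ndarray) -> float:
    """Dice = 2|R cap T| / (|R| + |T|), in [0, 1]; 0 (with warning) if both empty."""
    R = set(np.asarray(R, dtype=np.int64).tolist())
    T = set(np.asarray(T, dtype=np.int64).tolist())
    if not R and not T:
        warnings.warn("both node sets empty; Dice defined as 0", stacklevel=2)
        return 0.0
    return 2.0 * len(R & T) / (len(R) + len(T))


def volume_ratio(v_true: float, v_recon: float) -> float:
    """R_V = V_T / V_R (1 means perfect size recovery)."""
    if v_recon <= 0:
        raise ValueError("reconstructed volume must be positive")
    return v_true / v_recon


def relative_residual(A: np.ndarray, x_final: np.ndarray, B: np.ndarray) -> float:
    """R_R = ||B - A x_final||_2 / ||B||_2."""
    nb = np.linalg.norm(B)
    if nb == 0:
        raise ValueError("||B|| must be positive")
    return float(np.linalg.norm(B - A @ x_final) / nb)
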