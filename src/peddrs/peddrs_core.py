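"""Probabilistic energy-distribution density region-scaling (P-EDDRS) loop.

The framework wraps any one-step inverse solver in an iterative feasible-
region schedule.  Each iteration solves the reduced system on the current
candidate set, scores the result by residual norm and cosine similarity,
converts the scores into probability weights over all iterations so far,
treats the normalized nonnegative solution as a spatial probability mass,
and derives the next region of interest as an oriented cuboid from the
probability-weighted covariance of the node coordinates (center = weighted
centroid, axes = covariance eigenvectors, half-lengths = |eigenvalues| *
Size).  A geometric node-budget schedule (attenuation coefficient beta)
controls how fast the candidate set shrinks; after the loop, iterations
whose scores lie within one standard deviation of the mean are fused by
their refreshed probability weights into the final distribution.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import inverse_solvers
from .forward_model import SystemMatrix
from .inverse_solvers import SolverSpec
from .phantom_mesh import TetMesh

__all__ = [
    "IterationRecord",
    "ROIBox",
    "PeddrsConfig",
    "ReconResult",
    "evaluate_l2",
    "evaluate_cos",
    "probability_weights",
    "probabilistic_distribution",
    "roi_center",
    "roi_covariance",
    "roi_box",
    "nodes_in_box",
    "attenuation_coefficient",
    "update_size",
    "refresh_index",
    "gaussian_filter_iterations",
    "final_distribution",
    "run_peddrs",
    "one_step_reconstruction",
]

logger = logging.getLogger(__name__)

_EL2_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# per-iteration evaluation (residual, similarity, probability weights)
# ---------------------------------------------------------------------------


def evaluate_l2(A: np.ndarray, index_sp: np.ndarray, x: np.ndarray, B: np.ndarray) -> float:
    """L2 error of the reduced solution: ||A[:, index_sp] x - B||_2."""
    if len(index_sp) == 0:
        raise ValueError("index_sp is empty")
    return float(np.linalg.norm(A[:, index_sp] @ x - B))


def evaluate_cos(A: np.ndarray, index_sp: np.ndarray, x: np.ndarray, B: np.ndarray) -> float:
    """Cosine similarity between the predicted surface flux and B (0 if either is zero)."""
    pred = A[:, index_sp] @ x
    np_, nb = np.linalg.norm(pred), np.linalg.norm(B)
    if np_ == 0 or nb == 0:
        return 0.0
    return float(pred @ B / (np_ * nb))


def probability_weights(e_l2: np.ndarray, e_cos: np.ndarray) -> np.ndarray:
    """Probability weight of each iteration from its two quality scores.

    The residual score enters inversely (small error -> large weight),
    the similarity score proportionally; each is normalized to sum 1 over
    all iterations and the two are averaged.  Recomputed over every
    completed iteration each time it is called.
    """
    e_l2 = np.maximum(np.asarray(e_l2, dtype=float), _EL2_FLOOR)
    e_cos = np.asarray(e_cos, dtype=float)
    if len(e_l2) != len(e_cos) or len(e_l2) == 0:
        raise ValueError("score lists must have equal nonzero length")
    p_l2 = (1.0 / e_l2) / np.sum(1.0 / e_l2)
    s = np.sum(e_cos)
    if s > 0:
        p_cos = e_cos / s
    else:  # all-zero similarity: fall back to uniform
        p_cos = np.full(len(e_cos), 1.0 / len(e_cos))
    return (p_l2 + p_cos) / 2.0


def probabilistic_distribution(x: np.ndarray) -> np.ndarray:
    """Clamp to >= 0 and normalize to a probability mass (sum 1).

    The per-iteration probability weight cancels in the normalization, so
    it is kept separately for the final fusion.  Raises on zero mass.
    """
    x = np.maximum(np.asarray(x, dtype=float), 0.0)
    s = x.sum()
    if s <= 0:
        raise ValueError("degenerate iteration: solution has zero mass")
    return x / s


# ---------------------------------------------------------------------------
# covariance-eigenframe region of interest
# ---------------------------------------------------------------------------


@dataclass
class ROIBox:
    """Oriented cuboid: center, orthonormal axes (columns), per-axis half-lengths."""

    center: np.ndarray
    axes: np.ndarray  # (3, 3), column k = axis k
    half_lengths: np.ndarray

    def vertices(self) -> np.ndarray:
        """The 8 corners center +/- sum_k half_length_k * axis_k."""
        signs = np.array(
            [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)]
        )
        return self.center + (signs * self.half_lengths) @ self.axes.T


def roi_center(coords: np.ndarray, x_p: np.ndarray) -> np.ndarray:
    """Probability-weighted centroid of the active-node coordinates."""
    return np.asarray(coords, dtype=float).T @ np.asarray(x_p, dtype=float)


def roi_covariance(coords: np.ndarray, x_p: np.ndarray, center: np.ndarray) -> np.ndarray:
    """Probability-weighted coordinate covariance with N/(N-1) bias factor.

    N is the number of active nodes; N = 1 gives the zero matrix
    (degenerate — the half-length floor applies downstream).
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    if n == 1:
        return np.zeros((3, 3))
    d = coords - np.asarray(center)
    M = (d * np.asarray(x_p)[:, None]).T @ d * (n / (n - 1))
    return 0.5 * (M + M.T)


def roi_box(M_cov: np.ndarray, center: np.ndarray, size: float, floor: float) -> ROIBox:
    """Eigendecompose the covariance into the next ROI cuboid.

    Half-length along eigenvector k is |eigenvalue_k| * size, floored at
    the mesh spacing so a degenerate covariance never empties the ROI.
    """
    M_cov = np.asarray(M_cov, dtype=float)
    if not np.allclose(M_cov, M_cov.T, atol=1e-10):
        raise ValueError("covariance matrix must be symmetric")
    vals, vecs = np.linalg.eigh(M_cov)
    half = np.maximum(np.abs(vals) * size, floor)
    return ROIBox(center=np.asarray(center, dtype=float), axes=vecs, half_lengths=half)


def nodes_in_box(coords: np.ndarray, box: ROIBox) -> np.ndarray:
    """Indices (into ``coords``) inside the box, by ascending distance to its center.

    A node is inside when each of its eigenframe coordinates relative to
    the center is within the corresponding half-length.  Ties in distance
    break by node index.
    """
    rel = (np.asarray(coords, dtype=float) - box.center) @ box.axes
    inside = np.all(np.abs(rel) <= box.half_lengths + 1e-12, axis=1)
    idx = np.flatnonzero(inside)
    d = np.linalg.norm(coords[idx] - box.center, axis=1)
    order = np.lexsort((idx, d))
    return idx[order]


# ---------------------------------------------------------------------------
# node-budget schedule
# ---------------------------------------------------------------------------


def attenuation_coefficient(cut_num: int, num_f: int = 4, l_max: int = 50) -> float:
    """beta = (cut_num / num_f)^(1/(l_max - 1)), the per-iteration shrink rate.

    Chosen so that cut_num decays geometrically to num_f (one tetrahedron,
    4 nodes) over l_max iterations.  Returns 1 when cut_num <= num_f.
    """
    if num_f < 1 or l_max < 2:
        raise ValueError("need num_f >= 1 and l_max >= 2")
    if cut_num < num_f:
        return 1.0
    return float((cut_num / num_f) ** (1.0 / (l_max - 1)))


def update_size(roi_count: int, cut_num: int, beta: float) -> float:
    """ROI scale factor for the next iteration.

    Compares the ROI's node supply to the budget two shrink steps ahead,
    q = roi_count / (cut_num / beta^2): an oversupplied ROI (q > 2) is
    allowed to expand (size 2), an undersupplied one (q < 1) contracts
    (size 0.5), otherwise size 1.
    """
    if beta < 1:
        raise ValueError("beta must be >= 1")
    q = roi_count / (cut_num / beta**2)
    if q > 2:
        return 2.0
    if q < 1:
        return 0.5
    return 1.0


def refresh_index(
    x: np.ndarray,
    index_sp: np.ndarray,
    index_sp_roi: np.ndarray,
    cut_num: int,
    beta: float,
) -> tuple[np.ndarray, int]:
    """Next candidate set: ROI nodes first, then energy-ranked nodes, truncated.

    The budget shrinks to ceil(cut_num / beta).  The current active set is
    ranked by descending solution energy (ties by index) and its top
    new-budget nodes are concatenated after the ROI nodes; duplicates are
    removed keeping first occurrence (ROI nodes take precedence) and the
    result is truncated to the new budget.
    """
    new_cut = int(math.ceil(cut_num / beta))
    index_sp = np.asarray(index_sp, dtype=np.int64)
    order = np.lexsort((index_sp, -np.asarray(x, dtype=float)))
    descend = index_sp[order][:new_cut]
    concat = np.concatenate([np.asarray(index_sp_roi, dtype=np.int64), descend])
    _, first = np.unique(concat, return_index=True)
    dedup = concat[np.sort(first)]
    return dedup[:new_cut], new_cut


# ---------------------------------------------------------------------------
# post-processing
# ---------------------------------------------------------------------------


def gaussian_filter_iterations(e_l2: np.ndarray, e_cos: np.ndarray) -> np.ndarray:
    """Indices of iterations whose scores lie within one std of the mean.

    Both scores must be within their respective one-standard-deviation
    bands (boundaries inclusive); an empty intersection falls back to the
    single highest-weight iteration.
    """
    e_l2 = np.asarray(e_l2, dtype=float)
    e_cos = np.asarray(e_cos, dtype=float)
    keep = (np.abs(e_l2 - e_l2.mean()) <= e_l2.std()) & (
        np.abs(e_cos - e_cos.mean()) <= e_cos.std()
    )
    retained = np.flatnonzero(keep)
    if len(retained) == 0:
        w = probability_weights(e_l2, e_cos)
        retained = np.array([int(np.argmax(w))])
    return retained


@dataclass
class IterationRecord:
    """Audit record of one framework iteration."""

    iteration: int
    index_sp: np.ndarray
    x: np.ndarray  # clamped >= 0, on index_sp
    e_l2: float
    e_cos: float
    weight: float = 0.0
    size: float = 1.0
    cut_num: int = 0
    degenerate: bool = False


@dataclass
class ReconResult:
    """Final fused node-intensity field plus the full iteration audit trail."""

    x_final: np.ndarray  # over all mesh nodes, sums to 1
    records: list[IterationRecord]
    retained: np.ndarray
    col_nodes: np.ndarray


def final_distribution(
    records: list[IterationRecord], retained: np.ndarray, n_nodes: int
) -> np.ndarray:
    """Probability-weighted fusion of the retained iterations.

    Weights are recomputed over the retained set only; each retained
    solution is embedded into the global node vector, normalized to sum
    1, and the fused field is their convex combination (so it is
    nonnegative and sums to 1).
    """
    retained = np.asarray(retained, dtype=np.int64)
    if len(retained) == 0:
        raise ValueError("retained set is empty")
    sub = [records[i] for i in retained]
    w = probability_weights([r.e_l2 for r in sub], [r.e_cos for r in sub])
    x_final = np.zeros(n_nodes)
    for wi, r in zip(w, sub):
        emb = np.zeros(n_nodes)
        emb[r.index_sp] = r.x
        s = emb.sum()
        if s > 0:
            x_final += wi * emb / s
    # renormalize in case a retained iteration had zero mass
    total = x_final.sum()
    if total > 0:
        x_final /= total
    return x_final


# ---------------------------------------------------------------------------
# the main loop
# ---------------------------------------------------------------------------


@dataclass
class PeddrsConfig:
    """Tunable parameters of the framework loop."""

    l_max: int = 50  # maximum number of iterations
    num_f: int = 4  # target node count of the last iteration (one tet)
    half_length_floor: float | None = None  # default: mesh spacing
    eigen_mode: str = "abs"  # "abs": |eigenvalue|*Size; "sqrt": sqrt(|eigenvalue|)*Size


def _solve_clamped(A_sub: np.ndarray, B: np.ndarray, spec: SolverSpec) -> np.ndarray:
    x = inverse_solvers.solve(A_sub, B, spec)
    return np.maximum(x, 0.0)


def run_peddrs(
    system: SystemMatrix,
    B: np.ndarray,
    mesh: TetMesh,
    solver: SolverSpec,
    config: PeddrsConfig | None = None,
) -> ReconResult:
    """Run the full iterative reconstruction.

    Per iteration: reduced solve on the active set -> clamp -> score
    (residual, cosine) -> refresh all probability weights -> normalize to
    a spatial probability mass -> covariance-eigenframe ROI -> size update
    and index refresh.  Loops while more than one candidate remains and
    fewer than l_max iterations have run, then filters and fuses.

    ``B`` is the measured surface flux on ``system.row_nodes``; the result
    lives on all mesh nodes (zero outside ``system.col_nodes``).
    """
    if config is None:
        config = PeddrsConfig()
    A = system.A
    coords_all = mesh.nodes[system.col_nodes]
    floor = config.half_length_floor if config.half_length_floor is not None else mesh.spacing
    # column positions of candidate nodes within A
    index_sp = np.arange(A.shape[1], dtype=np.int64)

    records: list[IterationRecord] = []
    cut_num: int | None = None
    beta = 1.0
    size = 1.0

    for i in range(config.l_max):
        try:
            x = _solve_clamped(A[:, index_sp], B, solver)
        except Exception as exc:  # pragma: no cover - solver failure path
            if not records:
                raise RuntimeError(f"solver failed on the first iteration: {exc}") from exc
            logger.warning("solver failed at iteration %d (%s); stopping", i + 1, exc)
            break
        rec = IterationRecord(
            iteration=i + 1,
            index_sp=index_sp.copy(),
            x=x,
            e_l2=evaluate_l2(A, index_sp, x, B),
            e_cos=evaluate_cos(A, index_sp, x, B),
            size=size,
        )
        records.append(rec)
        # refresh probability weights over all completed iterations
        w = probability_weights([r.e_l2 for r in records], [r.e_cos for r in records])
        for r, wi in zip(records, w):
            r.weight = float(wi)

        if x.sum() <= 0:
            rec.degenerate = True
            roi_nodes = np.empty(0, dtype=np.int64)
        else:
            x_p = probabilistic_distribution(x)
            coords = coords_all[index_sp]
            center = roi_center(coords, x_p)
            M_cov = roi_covariance(coords, x_p, center)
            if config.eigen_mode == "sqrt":
                vals, vecs = np.linalg.eigh(M_cov)
                M_cov = vecs @ np.diag(np.sqrt(np.abs(vals))) @ vecs.T
            box = roi_box(M_cov, center, size, floor)
            roi_nodes = nodes_in_box(coords_all, box)

        if cut_num is None:
            # budget initialized from the first ROI's node supply
            cut_num = int(len(roi_nodes)) if len(roi_nodes) > 0 else int(len(index_sp))
            beta = attenuation_coefficient(cut_num, config.num_f, config.l_max)
        rec.cut_num = cut_num

        size = update_size(len(roi_nodes), cut_num, beta)
        index_sp, cut_num = refresh_index(x, index_sp, roi_nodes, cut_num, beta)
        logger.info(
            "iter %d: |index_sp|=%d cut_num=%d size=%.1f e_l2=%.4g e_cos=%.4f",
            i + 1, len(index_sp), cut_num, size, rec.e_l2, rec.e_cos,
        )
        if len(index_sp) <= 1:
            break

    retained = gaussian_filter_iterations(
        [r.e_l2 for r in records], [r.e_cos for r in records]
    )
    x_cols = final_distribution(records, retained, len(system.col_nodes))
    x_final = np.zeros(mesh.n_nodes)
    x_final[system.col_nodes] = x_cols
    return ReconResult(
        x_final=x_final, records=records, retained=retained, col_nodes=system.col_nodes
    )


def one_step_reconstruction(
    system: SystemMatrix, B: np.ndarray, mesh: TetMesh, solver: SolverSpec
) -> ReconResult:
    """Baseline: a single clamped solve on the full candidate set, normalized."""
    x = _solve_clamped(system.A, B, solver)
    rec = IterationRecord(
        iteration=1,
        index_sp=np.arange(system.A.shape[1], dtype=np.int64),
        x=x,
        e_l2=evaluate_l2(system.A, np.arange(system.A.shape[1]), x, B),
        e_cos=evaluate_cos(system.A, np.arange(system.A.shape[1]), x, B),
        weight=1.0,
    )
    s = x.sum()
    x_final = np.zeros(mesh.n_nodes)
    if s > 0:
        x_final[system.col_nodes] = x / s
    return ReconResult(
        x_final=x_final,
        records=[rec],
        retained=np.array([0]),
        col_nodes=system.col_nodes,
    )
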