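"""Semi-supervised label propagation on an intensity-affinity graph.

A probabilistic segmentation map is refined by spreading its reliable
labels through a voxel-similarity graph under local and global intensity
consistency. The probability vector ``p`` is first encoded as an n x 2
matrix ``P`` with

    p_{i,1} = max(2 (p_i - 0.5), 0)    (foreground strength)
    p_{i,2} = max(2 (0.5 - p_i), 0)    (background strength)

so a probability of 0.5 carries no label information. Entries above a
reliability threshold ``T`` are "reliable". Because background reliably
outnumbers foreground, reliable background strength is rebalanced by the
reliable-count ratio,

    p*_{i,2} = max((N_f / N_b) p_{i,2}, T)   for p_{i,2} > T,

and each reliable class is then divided by its reliable-entry mean so both
classes inject comparable label mass (information-balance weighting).

Pairwise similarity is a Gaussian on intensity differences,
``W_xy = exp(-(I_x - I_y)^2 / sigma^2)`` with a zero diagonal, normalized
to ``S = D^{-1/2} W D^{-1/2}`` whose spectral radius is at most 1. The
refined coding is the fixed point of

    L_{n+1} = (1 - beta) S L_n + beta P,   0 < beta < 1,

which converges to ``beta (I - (1-beta) S)^{-1} P``; for small graphs the
closed form is solved directly. A voxel becomes foreground iff
``l_{i,1} > l_{i,2}`` (ties -> background).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.ndimage import binary_dilation
from scipy.spatial import cKDTree

from .errors import NoReliableLabelsError
from .io import LabelVolume, Volume
from .preprocess import BoundingBox

__all__ = [
    "SSLPParams",
    "AffinityGraph",
    "encode_probabilities",
    "balance_weighting",
    "build_affinity",
    "propagate",
    "solve_propagation",
    "binarize",
    "sslp_refine",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SSLPParams:
    """Propagation hyperparameters.

    T
        Reliability threshold on the label coding (default 0.5).
    sigma
        Intensity-similarity scale, in image intensity units (default 10,
        meaningful for 0-255-like grayscale).
    beta
        Trade-off between graph smoothing and fidelity to the input coding,
        in (0, 1) (default 0.6).
    tol, max_iter
        Iteration stopping rule (max-abs change).
    graph
        Node set: ``"auto"`` = unreliable voxels plus a 1-voxel ring of
        reliable neighbors; ``"box"`` = every bounding-box voxel.
    dense_cap
        Largest node count for the literal all-pairs affinity; above it a
        sparse graph (26 spatial neighbors + ``m_intensity`` nearest
        intensities per node, symmetrized) is used.
    exact_cap
        Largest node count for the direct linear solve; above it the
        fixed-point iteration runs.
    zero_unreliable
        If True, zero the coding of unreliable rows instead of passing it
        through unchanged.
    """

    T: float = 0.5
    sigma: float = 10.0
    beta: float = 0.6
    tol: float = 1e-6
    max_iter: int = 1000
    graph: str = "auto"
    dense_cap: int = 20000
    exact_cap: int = 2000
    m_intensity: int = 10
    zero_unreliable: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.beta < 1:
            raise ValueError("beta must lie in (0, 1)")
        if not 0 <= self.T < 1:
            raise ValueError("T must lie in [0, 1)")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.graph not in ("auto", "box"):
            raise ValueError("graph must be 'auto' or 'box'")


@dataclass
class AffinityGraph:
    """Similarity matrix W, degrees, and the normalized S = D^-1/2 W D^-1/2."""

    W: np.ndarray | sp.spmatrix
    degrees: np.ndarray
    S: np.ndarray | sp.spmatrix
    mode: str


def encode_probabilities(p: np.ndarray) -> np.ndarray:
    """Foreground/background label coding of a probability vector (n x 2)."""
    p = np.asarray(p, dtype=np.float64).ravel()
    if p.size and (p.min() < 0 or p.max() > 1):
        raise ValueError("probabilities must lie in [0, 1]")
    return np.stack(
        [np.maximum(2.0 * (p - 0.5), 0.0), np.maximum(2.0 * (0.5 - p), 0.0)],
        axis=1,
    )


def balance_weighting(P: np.ndarray, T: float = 0.5) -> np.ndarray:
    """Information-balance weighting of the reliable label coding.

    Reliable background entries (``p_{i,2} > T``) are rescaled by the
    reliable-count ratio ``N_f / N_b`` and floored at ``T`` so they stay
    reliable; then each reliable class is divided by its mean so reliable
    foreground and (weighted) background entries both average 1. Unreliable
    entries pass through unchanged. Reliability for the normalization is the
    original ``> T`` condition — the floor at ``T`` keeps rescaled
    background entries in the reliable set, as the weighting intends.
    """
    P = np.asarray(P, dtype=np.float64)
    if P.ndim != 2 or P.shape[1] != 2:
        raise ValueError("P must be n x 2")
    out = P.copy()
    rel_f = P[:, 0] > T
    rel_b = P[:, 1] > T
    n_f, n_b = int(rel_f.sum()), int(rel_b.sum())
    if n_f == 0 or n_b == 0:
        side = "foreground" if n_f == 0 else "background"
        raise NoReliableLabelsError(f"no reliable {side} labels (T={T})")
    out[rel_b, 1] = np.maximum((n_f / n_b) * P[rel_b, 1], T)
    out[rel_f, 0] /= out[rel_f, 0].mean()
    out[rel_b, 1] /= out[rel_b, 1].mean()
    return out


def _inv_sqrt_degrees(d: np.ndarray) -> np.ndarray:
    # a node whose every edge weight underflowed to zero has zero degree;
    # give it a zero row in S (pseudo-inverse normalization) so it keeps
    # only its unary term during propagation
    if np.any(d <= 0):
        log.warning("%d graph nodes have zero degree (weight underflow)",
                    int((d <= 0).sum()))
    with np.errstate(divide="ignore"):
        inv = np.where(d > 0, 1.0 / np.sqrt(np.maximum(d, 1e-300)), 0.0)
    return inv


def _normalize(W: np.ndarray | sp.spmatrix, mode: str) -> AffinityGraph:
    if sp.issparse(W):
        d = np.asarray(W.sum(axis=1)).ravel()
        inv = _inv_sqrt_degrees(d)
        S = sp.diags(inv) @ W @ sp.diags(inv)
        return AffinityGraph(W, d, S.tocsr(), mode)
    d = W.sum(axis=1)
    inv = _inv_sqrt_degrees(d)
    S = W * inv[:, None] * inv[None, :]
    return AffinityGraph(W, d, S, mode)


def build_affinity(
    intensities: np.ndarray,
    sigma: float,
    mode: str = "dense",
    coords: np.ndarray | None = None,
    m_intensity: int = 10,
) -> AffinityGraph:
    """Gaussian intensity-affinity graph and its symmetric normalization.

    ``mode="dense"`` realizes the literal all-pairs similarity. For large
    node sets ``mode="sparse"`` retains, per node, its 26-connected spatial
    neighbors (requires ``coords``) plus its ``m_intensity`` nearest
    intensity values, symmetrized; an isolated node (possible only in
    sparse mode) is reconnected to its nearest spatial neighbor.
    """
    intensities = np.asarray(intensities, dtype=np.float64).ravel()
    n = intensities.size
    if n < 2:
        raise ValueError("affinity graph needs at least 2 nodes")
    if sigma <= 0:
        raise ValueError("sigma must be positive")

    if mode == "dense":
        diff = intensities[:, None] - intensities[None, :]
        W = np.exp(-(diff ** 2) / sigma ** 2)
        np.fill_diagonal(W, 0.0)
        return _normalize(W, "dense")

    if mode != "sparse":
        raise ValueError("mode must be 'dense' or 'sparse'")
    if coords is None:
        raise ValueError("sparse mode requires voxel coordinates")
    coords = np.asarray(coords)

    rows: list[np.ndarray] = []
    cols: list[np.ndarray] = []
    # 26-connected spatial neighbors
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=np.sqrt(3.0) + 1e-9, output_type="ndarray")
    if pairs.size:
        rows.append(pairs[:, 0]); cols.append(pairs[:, 1])
        rows.append(pairs[:, 1]); cols.append(pairs[:, 0])
    # m nearest-intensity nodes via the sorted intensity sequence
    order = np.argsort(intensities, kind="stable")
    pos = np.empty(n, dtype=np.intp)
    pos[order] = np.arange(n)
    m = min(m_intensity, n - 1)
    for step in range(1, m // 2 + 2):
        src = np.arange(n)
        for shifted in (pos + step, pos - step):
            ok = (shifted >= 0) & (shifted < n)
            rows.append(src[ok]); cols.append(order[shifted[ok]])
            rows.append(order[shifted[ok]]); cols.append(src[ok])
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    keep = r != c
    r, c = r[keep], c[keep]
    # deduplicate edges (weight depends only on the endpoints)
    uniq = np.unique(r * n + c)
    rr, cc = uniq // n, uniq % n
    W = sp.csr_matrix(
        (np.exp(-((intensities[rr] - intensities[cc]) ** 2) / sigma ** 2), (rr, cc)),
        shape=(n, n),
    )
    d = np.asarray(W.sum(axis=1)).ravel()
    isolated = np.flatnonzero(d <= 0)
    if isolated.size:
        log.warning("reconnecting %d isolated nodes to nearest spatial neighbor",
                    isolated.size)
        _, nn = tree.query(coords[isolated], k=2)
        W = W.tolil()
        for i, j in zip(isolated, nn[:, 1]):
            wij = np.exp(-((intensities[i] - intensities[j]) ** 2) / sigma ** 2)
            W[i, j] = wij
            W[j, i] = wij
        W = W.tocsr()
    return _normalize(W, "sparse")


def propagate(
    S: np.ndarray | sp.spmatrix,
    P: np.ndarray,
    beta: float,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[np.ndarray, int, bool]:
    """Iterate ``L <- (1-beta) S L + beta P`` from ``L0 = P`` to convergence.

    Returns (L, iterations, converged). Convergence is guaranteed in exact
    arithmetic because the spectral radius of ``(1-beta) S`` is below 1;
    hitting ``max_iter`` logs a warning and returns the current iterate.
    """
    if not 0 < beta < 1:
        raise ValueError("beta must lie in (0, 1)")
    P = np.asarray(P, dtype=np.float64)
    L = P.copy()
    for it in range(1, max_iter + 1):
        L_new = (1.0 - beta) * (S @ L) + beta * P
        delta = float(np.max(np.abs(L_new - L))) if L.size else 0.0
        L = L_new
        if delta < tol:
            return L, it, True
    log.warning("propagation did not converge within %d iterations", max_iter)
    return L, max_iter, False


def solve_propagation(
    S: np.ndarray | sp.spmatrix, P: np.ndarray, beta: float
) -> np.ndarray:
    """Closed-form fixed point ``beta (I - (1-beta) S)^{-1} P``."""
    P = np.asarray(P, dtype=np.float64)
    n = P.shape[0]
    if sp.issparse(S):
        A = (sp.identity(n, format="csc") - (1.0 - beta) * S).tocsc()
        return beta * sp.linalg.spsolve(A, P)
    A = np.eye(n) - (1.0 - beta) * np.asarray(S)
    return beta * np.linalg.solve(A, P)


def binarize(L: np.ndarray) -> np.ndarray:
    """Foreground iff the foreground coding strictly exceeds the background
    coding; ties go to background."""
    L = np.asarray(L)
    return (L[:, 0] > L[:, 1]).astype(np.uint8)


def sslp_refine(
    prob_map: Volume,
    target: Volume,
    box: BoundingBox,
    params: SSLPParams | None = None,
) -> LabelVolume:
    """Refine a probabilistic segmentation map by label propagation.

    Pipeline: encode the probabilities, apply information-balance
    weighting, build the affinity graph on the target intensities of the
    graph nodes, propagate, binarize. Voxels outside the node set (and
    outside the box) keep their thresholded input label (>= 0.5 ->
    foreground).
    """
    params = params or SSLPParams()
    if prob_map.shape != target.shape:
        raise ValueError("probability map and target must share the grid")
    out = (np.asarray(prob_map.data) >= 0.5).astype(np.uint8)

    sl = box.slices
    p_box = np.asarray(prob_map.data[sl], dtype=np.float64)
    P0 = encode_probabilities(p_box.ravel())
    reliable = ((P0[:, 0] > params.T) | (P0[:, 1] > params.T)).reshape(p_box.shape)
    unreliable = ~reliable

    if params.graph == "box":
        node_mask = np.ones(p_box.shape, dtype=bool)
    else:
        if not unreliable.any():
            log.info("sslp_refine: no unreliable voxels; returning thresholded input")
            return LabelVolume(out, target.affine, name="sslp_refined")
        ring = binary_dilation(unreliable) & reliable
        node_mask = unreliable | ring

    nodes = np.flatnonzero(node_mask.ravel())
    P = P0[nodes]
    if params.zero_unreliable:
        unrel_rows = unreliable.ravel()[nodes]
        P = P.copy()
        P[unrel_rows] = 0.0
    Pw = balance_weighting(P, params.T)

    intens = np.asarray(target.data[sl], dtype=np.float64).ravel()[nodes]
    n = nodes.size
    if n < 2:
        return LabelVolume(out, target.affine, name="sslp_refined")
    if n <= params.dense_cap:
        graph = build_affinity(intens, params.sigma, mode="dense")
    else:
        coords = np.argwhere(node_mask)
        graph = build_affinity(
            intens, params.sigma, mode="sparse", coords=coords,
            m_intensity=params.m_intensity,
        )
    if n <= params.exact_cap:
        L = solve_propagation(graph.S, Pw, params.beta)
    else:
        L, _, _ = propagate(graph.S, Pw, params.beta, params.tol, params.max_iter)
    labels = binarize(L)

    out_box = out[sl].copy()
    out_box.ravel()[nodes] = labels
    out[sl] = out_box
    return LabelVolume(out, target.affine, name="sslp_refined")
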