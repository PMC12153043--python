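"""Particle-tracking velocimetry and strain mapping around a dividing cell.

The chain: detect fluorescent tracer beads in each frame of a confocal stack
(local maxima refined to sub-pixel by intensity-weighted centroids), link them
frame-to-frame into trajectories (optimal assignment with a hard distance
gate), extract per-particle displacement vectors, and regress a local affine
model of the displacement field on a regular grid to obtain the deformation
gradient and the small-strain tensor.  Also provides the two summary curves
used to characterise cell expansion: the normalized displacement time course
of the largest-displacement tracks, and displacement magnitude versus radial
distance from the cell (distance zero at half the initial cell height).

Coordinate convention: image origin at the centre of the top-left pixel,
x rightward along columns, y downward along rows; positions in um after
calibration by the pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "CellGeometry",
    "detect_particles",
    "detect_stack",
    "link_trajectories",
    "displacement_field",
    "normalized_displacement_curve",
    "displacement_vs_distance",
    "rotate_coordinates",
    "LocalStrainField",
    "strain_map",
]


@dataclass
class CellGeometry:
    """Cell position and size used for the radial-distance convention."""

    center: tuple[float, float]  # um
    h0: float  # initial cell height (um); distance 0 sits at h0/2 from center
    axis: tuple[float, float] = (1.0, 0.0)  # expansion axis unit vector

    def __post_init__(self):
        if self.h0 <= 0:
            raise ValueError("h0 must be > 0")


def detect_particles(image, min_separation: int = 5, threshold: float = 0.3):
    """Detect bright spots in one frame, refined to sub-pixel positions.

    Local maxima at least ``min_separation`` px apart and above
    ``threshold`` x the image dynamic range are refined by an
    intensity-weighted centroid of the background-subtracted patch in a
    ``(2 min_separation + 1)^2`` window; detections that collapse within
    ``min_separation`` of each other after refinement are merged keeping the
    brighter one.

    Returns ``(positions, intensities)``: positions as an (n, 2) float array
    of (x, y) pixel coordinates.  A blank frame yields an empty set.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2D image")
    lo, hi = img.min(), img.max()
    if hi <= lo:
        return np.empty((0, 2)), np.empty(0)
    peaks = peak_local_max(img, min_distance=min_separation,
                           threshold_abs=lo + threshold * (hi - lo),
                           exclude_border=False)
    if peaks.size == 0:
        return np.empty((0, 2)), np.empty(0)

    h, w = img.shape
    half = int(min_separation)
    pos = np.empty((len(peaks), 2))
    inten = np.empty(len(peaks))
    for i, (r0, c0) in enumerate(peaks):
        rows = slice(max(r0 - half, 0), min(r0 + half + 1, h))
        cols = slice(max(c0 - half, 0), min(c0 + half + 1, w))
        patch = img[rows, cols] - img[rows, cols].min()
        total = patch.sum()
        if total <= 0:
            pos[i] = (c0, r0)
            inten[i] = img[r0, c0]
            continue
        rr = np.arange(rows.start, rows.stop)
        cc = np.arange(cols.start, cols.stop)
        pos[i] = (patch.sum(axis=0) @ cc / total, patch.sum(axis=1) @ rr / total)
        inten[i] = img[r0, c0]

    # merge refined detections that fell within min_separation, keeping the
    # brighter one (cell-list so the sweep stays linear in spot count)
    order = np.argsort(-inten)
    cell = max(float(min_separation), 1e-6)
    grid: dict[tuple[int, int], list[int]] = {}
    keep: list[int] = []
    for i in order:
        cx, cy = int(pos[i, 0] // cell), int(pos[i, 1] // cell)
        clash = any(
            np.hypot(*(pos[i] - pos[j])) < min_separation
            for nx in (cx - 1, cx, cx + 1)
            for ny in (cy - 1, cy, cy + 1)
            for j in grid.get((nx, ny), ())
        )
        if not clash:
            keep.append(i)
            grid.setdefault((cx, cy), []).append(i)
    keep = sorted(keep)
    return pos[keep], inten[keep]


def detect_stack(stack, px_size: float, min_separation: int = 5,
                 threshold: float = 0.3):
    """Detect particles in every frame; returns a list of (n_i, 2) um arrays."""
    return [detect_particles(frame, min_separation, threshold)[0] * px_size
            for frame in stack]


def _lap_block(d: np.ndarray, max_disp: float):
    """Optimal gated assignment on one dense distance block.

    Dummy rows/columns let particles go unmatched; the no-match cost equals
    the squared gate, so a link forms only when cheaper than not linking.
    """
    na, nb = d.shape
    big = 1e12
    cost = np.zeros((na + nb, na + nb))
    cost[:na, :nb] = np.where(d <= max_disp, d**2, big)
    cost[:na, nb:] = np.where(np.eye(na, dtype=bool), max_disp**2, big)
    cost[na:, :nb] = big
    np.fill_diagonal(cost[na:, :nb], max_disp**2)
    rows, cols = linear_sum_assignment(cost)
    return [(int(i), int(j)) for i, j in zip(rows, cols)
            if i < na and j < nb and d[i, j] <= max_disp]


def _assign(prev: np.ndarray, new: np.ndarray, max_disp: float, greedy: bool):
    """Gated frame-to-frame matching; returns list of (i_prev, j_new) pairs."""
    if len(prev) == 0 or len(new) == 0:
        return []
    tree_a = cKDTree(prev)
    tree_b = cKDTree(new)
    if greedy:
        cand = []  # nearest-neighbour assignment ordered by distance
        for i, js in enumerate(tree_a.query_ball_tree(tree_b, max_disp)):
            for j in js:
                cand.append((float(np.hypot(*(prev[i] - new[j]))), i, j))
        cand.sort()
        pairs, used_i, used_j = [], set(), set()
        for _, i, j in cand:
            if i not in used_i and j not in used_j:
                pairs.append((i, j))
                used_i.add(i)
                used_j.add(j)
        return pairs
    # optimal assignment, solved independently on each connected component of
    # the gated candidate graph (components are small for sane bead densities)
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    na, nb = len(prev), len(new)
    links = tree_a.query_ball_tree(tree_b, max_disp)
    ii = [i for i, js in enumerate(links) for _ in js]
    jj = [na + j for js in links for j in js]
    if not ii:
        return []
    adj = coo_matrix((np.ones(len(ii)), (ii, jj)), shape=(na + nb, na + nb))
    n_comp, labels = connected_components(adj, directed=False)
    pairs = []
    for c in range(n_comp):
        members = np.flatnonzero(labels == c)
        ai = members[members < na]
        bj = members[members >= na] - na
        if ai.size == 0 or bj.size == 0:
            continue
        d = np.hypot(prev[ai, None, 0] - new[None, bj, 0],
                     prev[ai, None, 1] - new[None, bj, 1])
        pairs.extend((int(ai[i]), int(bj[j])) for i, j in _lap_block(d, max_disp))
    return pairs


def link_trajectories(frames: list[np.ndarray], max_disp: float,
                      method: str = "optimal") -> pd.DataFrame:
    """Link per-frame particle positions (um) into trajectories.

    Frame-to-frame matching minimizes the total squared displacement subject
    to a hard gate at ``max_disp`` um per frame (``method='greedy'`` uses
    nearest-neighbour assignment instead).  Unmatched particles terminate or
    start tracks; no gap closing.

    Returns a table ``track_id, frame, x_um, y_um``.
    """
    if max_disp <= 0:
        raise ValueError("max_disp must be > 0")
    if len(frames) < 2:
        raise ValueError("need at least 2 frames to link")
    greedy = method == "greedy"

    next_id = 0
    active: dict[int, np.ndarray] = {}
    records = []
    for k, pts in enumerate(frames):
        pts = np.asarray(pts, dtype=float).reshape(-1, 2)
        if k == 0:
            for p in pts:
                active[next_id] = p
                records.append((next_id, k, p[0], p[1]))
                next_id += 1
            continue
        ids = list(active)
        prev = np.array([active[t] for t in ids]).reshape(-1, 2)
        pairs = _assign(prev, pts, max_disp, greedy)
        matched_new = {j for _, j in pairs}
        survivors: dict[int, np.ndarray] = {}
        for i, j in pairs:
            tid = ids[i]
            survivors[tid] = pts[j]
            records.append((tid, k, pts[j, 0], pts[j, 1]))
        for j, p in enumerate(pts):
            if j not in matched_new:
                survivors[next_id] = p
                records.append((next_id, k, p[0], p[1]))
                next_id += 1
        active = survivors
    return pd.DataFrame(records, columns=["track_id", "frame", "x_um", "y_um"])


def displacement_field(traj: pd.DataFrame, frame_a: int, frame_b: int) -> pd.DataFrame:
    """Per-particle displacement vectors between two frames.

    Only tracks present in both frames contribute.  Returns a table
    ``track_id, x_um, y_um, ux_um, uy_um`` with positions taken at
    ``frame_a``.
    """
    a = traj[traj["frame"] == frame_a].set_index("track_id")
    b = traj[traj["frame"] == frame_b].set_index("track_id")
    common = a.index.intersection(b.index)
    out = pd.DataFrame({
        "track_id": common,
        "x_um": a.loc[common, "x_um"].to_numpy(),
        "y_um": a.loc[common, "y_um"].to_numpy(),
        "ux_um": (b.loc[common, "x_um"] - a.loc[common, "x_um"]).to_numpy(),
        "uy_um": (b.loc[common, "y_um"] - a.loc[common, "y_um"]).to_numpy(),
    })
    return out.reset_index(drop=True)


def normalized_displacement_curve(traj: pd.DataFrame, top_frac: float = 0.05):
    """Normalized displacement time course of the largest-displacement tracks.

    Tracks spanning the first and last frame are ranked by their total
    start-to-end displacement; the top ``top_frac`` (at least one, ties broken
    by track id) are kept.  Each kept track's cumulative displacement from the
    first frame is normalized by its own total, and the curve is the per-frame
    mean over kept tracks (zeros if nothing moved).

    Returns ``(frames, values)`` arrays; values reach 1.0 at the final frame
    for a monotone expansion.
    """
    frames = np.sort(traj["frame"].unique())
    if frames.size < 3:
        raise ValueError("need >= 3 frames")
    f0, f1 = frames[0], frames[-1]
    end = displacement_field(traj, f0, f1)
    total = np.hypot(end["ux_um"], end["uy_um"]).to_numpy()
    n_keep = max(int(np.ceil(top_frac * len(end))), 1)
    order = np.lexsort((end["track_id"].to_numpy(), -total))
    kept = end.iloc[order[:n_keep]]
    kept_total = np.hypot(kept["ux_um"], kept["uy_um"]).to_numpy()

    sub = traj[traj["track_id"].isin(kept["track_id"])]
    start = kept.set_index("track_id")
    values = np.zeros(frames.size)
    for fi, f in enumerate(frames):
        cur = sub[sub["frame"] == f].set_index("track_id")
        ids = cur.index
        dx = cur["x_um"] - start.loc[ids, "x_um"]
        dy = cur["y_um"] - start.loc[ids, "y_um"]
        disp = np.hypot(dx, dy).to_numpy()
        tot = np.hypot(start.loc[ids, "ux_um"], start.loc[ids, "uy_um"]).to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = np.where(tot > 0, disp / np.maximum(tot, 1e-300), 0.0)
        values[fi] = norm.mean() if len(norm) else 0.0
    if np.all(kept_total == 0):
        values[:] = 0.0
    return frames, values


def displacement_vs_distance(vectors: pd.DataFrame, geom: CellGeometry) -> pd.DataFrame:
    """Displacement magnitude versus radial distance from the cell.

    Distance is measured from the cell centre minus half the initial cell
    height (clamped at zero), so a particle at the cell wall sits at
    distance 0.  Returns ``distance_um, u_um`` sorted by distance.
    """
    dx = vectors["x_um"].to_numpy() - geom.center[0]
    dy = vectors["y_um"].to_numpy() - geom.center[1]
    dist = np.clip(np.hypot(dx, dy) - geom.h0 / 2.0, 0.0, None)
    u = np.hypot(vectors["ux_um"].to_numpy(), vectors["uy_um"].to_numpy())
    out = pd.DataFrame({"distance_um": dist, "u_um": u}).sort_values(
        "distance_um", kind="stable")
    return out.reset_index(drop=True)


def rotate_coordinates(points: np.ndarray, angle_deg: float,
                       origin=(0.0, 0.0)) -> np.ndarray:
    """Rotate 2D points about an origin (for aligning the view with the
    cell's expansion plane; the rotation angle is user-supplied)."""
    a = np.deg2rad(angle_deg)
    Rm = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    pts = np.asarray(points, dtype=float) - origin
    return pts @ Rm.T + origin


class LocalStrainField(BaseEstimator, TransformerMixin):
    """Gridded deformation-gradient and strain maps from scattered vectors.

    At each node of a regular grid, the displacement field is regressed on a
    local polynomial model ``u(x) ~ c + A (x - x_node) + ...`` over the
    particles within ``window_radius``, with Gaussian weights
    (sd = ``window_radius / 2`` by default).  ``poly_order=2`` (default)
    augments the affine model with quadratic terms that soak up field
    curvature, leaving the linear term a less biased local gradient;
    ``poly_order=1`` is the plain affine fit.  Either way the deformation
    gradient ``A`` is the linear term, so an exactly affine field is
    reproduced exactly.  The small-strain tensor is the symmetric part
    ``eps = (A + A^T) / 2``; ``strain='green'`` instead returns the
    Green-Lagrange tensor ``(A + A^T + A^T A) / 2``, appropriate when wall
    strains approach tens of percent.  Nodes with fewer than ``min_support``
    neighbours, or a rank-deficient neighbourhood, are flagged invalid rather
    than extrapolated.

    Parameters are in um.  Fitted attributes: ``grid_x_`` and ``grid_y_``
    (node coordinate axes), ``gradient_`` (ny, nx, 2, 2), ``strain_``
    (ny, nx, 2, 2), ``support_`` (ny, nx), ``valid_`` (ny, nx).
    """

    def __init__(self, grid_spacing: float = 10.0, window_radius: float = 25.0,
                 min_support: int = 6, weight_sigma: float | None = None,
                 strain: str = "small", poly_order: int = 2):
        self.grid_spacing = grid_spacing
        self.window_radius = window_radius
        self.min_support = min_support
        self.weight_sigma = weight_sigma
        self.strain = strain
        self.poly_order = poly_order

    def fit(self, X, y):
        """X: (n, 2) particle positions (um); y: (n, 2) displacements (um)."""
        X = np.asarray(X, dtype=float).reshape(-1, 2)
        y = np.asarray(y, dtype=float).reshape(-1, 2)
        if X.shape != y.shape:
            raise ValueError("positions and displacements must both be (n, 2)")
        if self.strain not in ("small", "green"):
            raise ValueError("strain must be 'small' or 'green'")
        if self.poly_order not in (1, 2):
            raise ValueError("poly_order must be 1 or 2")
        sigma = self.weight_sigma or self.window_radius / 2.0
        n_terms = 3 if self.poly_order == 1 else 6

        x0, y0 = X.min(axis=0)
        x1, y1 = X.max(axis=0)
        self.grid_x_ = np.arange(x0, x1 + self.grid_spacing / 2, self.grid_spacing)
        self.grid_y_ = np.arange(y0, y1 + self.grid_spacing / 2, self.grid_spacing)
        nx, ny = self.grid_x_.size, self.grid_y_.size

        tree = cKDTree(X)
        self.gradient_ = np.full((ny, nx, 2, 2), np.nan)
        self.strain_ = np.full((ny, nx, 2, 2), np.nan)
        self.support_ = np.zeros((ny, nx), dtype=int)
        self.valid_ = np.zeros((ny, nx), dtype=bool)

        for iy, gy in enumerate(self.grid_y_):
            for ix, gx in enumerate(self.grid_x_):
                idx = tree.query_ball_point([gx, gy], self.window_radius)
                self.support_[iy, ix] = len(idx)
                if len(idx) < max(self.min_support, n_terms):
                    continue
                dx = X[idx] - [gx, gy]
                w = np.exp(-np.sum(dx**2, axis=1) / (2 * sigma**2))
                cols = [np.ones(len(idx)), dx[:, 0], dx[:, 1]]
                if self.poly_order == 2:
                    # quadratic terms absorb field curvature so the linear
                    # term is an unbiased local gradient even when the
                    # neighbourhood samples the window unevenly
                    cols += [dx[:, 0] ** 2, dx[:, 0] * dx[:, 1], dx[:, 1] ** 2]
                M = np.column_stack(cols)
                Mw = M * w[:, None]
                G = M.T @ Mw
                if np.linalg.matrix_rank(G) < n_terms or np.linalg.cond(G) > 1e10:
                    continue
                coef = np.linalg.solve(G, Mw.T @ y[idx])  # (n_terms, 2)
                A = coef[1:3, :].T  # A[i, j] = d u_i / d x_j
                self.gradient_[iy, ix] = A
                eps = 0.5 * (A + A.T)
                if self.strain == "green":
                    eps = eps + 0.5 * (A.T @ A)
                self.strain_[iy, ix] = eps
                self.valid_[iy, ix] = True
        return self

    def to_frame(self) -> pd.DataFrame:
        """Long-format strain map: x_um, y_um, exx, eyy, exy, support, valid."""
        gx, gy = np.meshgrid(self.grid_x_, self.grid_y_)
        return pd.DataFrame({
            "x_um": gx.ravel(),
            "y_um": gy.ravel(),
            "exx": self.strain_[..., 0, 0].ravel(),
            "eyy": self.strain_[..., 1, 1].ravel(),
            "exy": self.strain_[..., 0, 1].ravel(),
            "support": self.support_.ravel(),
            "valid": self.valid_.ravel(),
        })


def strain_map(positions, displacements, grid_spacing: float = 10.0,
               window_radius: float = 25.0, min_support: int = 6,
               **kwargs) -> pd.DataFrame:
    """Gridded strain map from scattered displacement vectors (long format)."""
    est = LocalStrainField(grid_spacing=grid_spacing, window_radius=window_radius,
                           min_support=min_support, **kwargs)
    return est.fit(positions, displacements).to_frame()
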