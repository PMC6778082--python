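"""Worm midline extraction: skeleton graph -> pruned path -> smoothing spline.

The mask is thinned to a 1-px skeleton, treated as an 8-connected graph;
short spurs (side branches left by thinning) are pruned and the longest
endpoint-to-endpoint path is taken as the body axis. A parametric
smoothing spline through that path, resampled at K equal-arclength points
and extended at the tips to the mask boundary (thinning retracts tips by
about half a body width), gives the centerline. Head/tail orientation is
assigned per clip by endpoint tracking: the endpoint family with the
larger cumulative path length over the clip is the head (heads forage).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.interpolate import splev, splprep
from skimage.morphology import skeletonize

from .segmentation import WormMask

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class CenterlineQC:
    coiled: bool = False
    pruned_branches: int = 0
    orientation_confident: bool = True


@dataclass
class Centerline:
    """Ordered midline: K (x, y) µm points, index 0 = head after orientation."""

    points_um: np.ndarray
    qc: CenterlineQC = field(default_factory=CenterlineQC)

    @property
    def length_um(self) -> float:
        return float(
            np.sum(np.linalg.norm(np.diff(self.points_um, axis=0), axis=1))
        )

    @property
    def n_points(self) -> int:
        return int(self.points_um.shape[0])

    def flipped(self) -> "Centerline":
        return Centerline(points_um=self.points_um[::-1].copy(), qc=self.qc)


def _skeleton_graph(skel: np.ndarray) -> nx.Graph:
    """8-connected pixel graph of a skeleton.

    A diagonal edge is skipped when the two pixels already share an
    orthogonal neighbour: otherwise every L-shaped step forms a spurious
    3-cycle and any skeleton would read as "coiled"."""
    g = nx.Graph()
    pts = np.argwhere(skel)
    pixset = set(map(tuple, pts))
    for r, c in pixset:
        g.add_node((r, c))
    for r, c in pixset:
        for dr, dc in _NEIGHBORS:
            q = (r + dr, c + dc)
            if q not in pixset:
                continue
            if dr != 0 and dc != 0:
                if (r + dr, c) in pixset or (r, c + dc) in pixset:
                    continue
            g.add_edge((r, c), q, weight=float(np.hypot(dr, dc)))
    return g


def _graph_length(g: nx.Graph) -> float:
    return float(sum(d["weight"] for _, _, d in g.edges(data=True)))


def _spur_from(g: nx.Graph, endpoint) -> tuple[list, float, bool]:
    """Walk from an endpoint to the first junction (degree >= 3) or endpoint.

    Returns (nodes walked excluding the terminal junction, walked length,
    ends_at_junction)."""
    path = [endpoint]
    length = 0.0
    prev = None
    node = endpoint
    while True:
        nbrs = [n for n in g.neighbors(node) if n != prev]
        if not nbrs:  # isolated spur / other endpoint
            return path, length, False
        if g.degree(node) >= 3 and node != endpoint:
            return path[:-1], length, True
        nxt = nbrs[0]
        length += g.edges[node, nxt]["weight"]
        prev, node = node, nxt
        path.append(node)
        if g.degree(node) >= 3:
            return path[:-1], length, True
        if g.degree(node) == 1:
            return path, length, False


def skeletonize_mask(
    wm: WormMask, prune_frac: float = 0.10
) -> tuple[np.ndarray, CenterlineQC]:
    """Thin a worm mask to its longest skeleton path.

    Returns (path, qc) where path is an (N, 2) array of (x, y) pixel
    coordinates along the body axis (orientation arbitrary at this stage).
    Spurs shorter than prune_frac of the total skeleton length are removed
    iteratively; qc.coiled is set when a cycle or more than two endpoints
    survive pruning. A mask thinner than 2 px everywhere is degenerate.
    """
    mask = wm.mask
    if not mask.any():
        raise ValueError("empty mask")

    rows, cols = np.nonzero(mask)
    r0, r1 = rows.min(), rows.max() + 1
    c0, c1 = cols.min(), cols.max() + 1
    crop = np.zeros((r1 - r0 + 2, c1 - c0 + 2), dtype=bool)
    crop[1:-1, 1:-1] = mask[r0:r1, c0:c1]
    if ndimage.distance_transform_edt(crop).max() < 1.5:
        raise ValueError("degenerate mask: thinner than ~2 px everywhere")
    skel = skeletonize(crop)
    g = _skeleton_graph(skel)
    if g.number_of_nodes() < 2:
        raise ValueError("degenerate mask: skeleton collapsed")

    qc = CenterlineQC()
    prune_len = prune_frac * _graph_length(g)
    changed = True
    while changed:
        endpoints = [n for n in g.nodes if g.degree(n) == 1]
        if len(endpoints) <= 2:
            break
        changed = False
        # remove the shortest prunable spur first; re-evaluate after each cut
        spurs = []
        for e in endpoints:
            nodes, length, at_junction = _spur_from(g, e)
            if at_junction and length < prune_len:
                spurs.append((length, nodes))
        if spurs:
            spurs.sort(key=lambda s: s[0])
            g.remove_nodes_from(spurs[0][1])
            qc.pruned_branches += 1
            changed = True

    # largest connected piece only (pruning cannot disconnect, but be safe)
    if g.number_of_nodes() == 0:
        raise ValueError("skeleton pruned away entirely")
    if not nx.is_connected(g):
        comp = max(nx.connected_components(g), key=len)
        g = g.subgraph(comp).copy()

    endpoints = [n for n in g.nodes if g.degree(n) == 1]
    if len(nx.cycle_basis(g)) > 0 or len(endpoints) > 2:
        qc.coiled = True
    if len(endpoints) < 2:
        # pure cycle: no endpoints; pick an arbitrary pair on the ring
        nodes = list(g.nodes)
        endpoints = [nodes[0], nodes[len(nodes) // 2]]

    best_path, best_len = None, -1.0
    for i in range(len(endpoints)):
        lengths, paths = nx.single_source_dijkstra(g, endpoints[i], weight="weight")
        for j in range(i + 1, len(endpoints)):
            e = endpoints[j]
            if e in lengths and lengths[e] > best_len:
                best_len = lengths[e]
                best_path = paths[e]
    if best_path is None or len(best_path) < 2:
        raise ValueError("no skeleton path found")

    path = np.array(
        [(c - 1 + c0, r - 1 + r0) for r, c in best_path], dtype=float
    )  # (x, y) px in the original frame
    return path, qc


def fit_spline(
    path_px: np.ndarray,
    K: int = 101,
    smooth: float = 1.0,
    mask: np.ndarray | None = None,
    px_um: float = 1.0,
    tip_extension_cap: float = 1.5,
    tip_overshoot_px: float | None = None,
    qc: CenterlineQC | None = None,
) -> Centerline:
    """Smoothing spline through a skeleton path, resampled at K points of
    equal arclength, in µm.

    smooth is the smoothing budget in px² per path point (0 interpolates).
    When `mask` is given, each end is extended along the terminal spline
    tangent to the mask boundary, capped at tip_extension_cap times the
    local half-width (from the mask's Euclidean distance transform) —
    thinning retracts tips by roughly half a width, biasing length low.

    tip_overshoot_px additionally extends past the boundary: a worm tip
    tapering below the point-spread function never reaches the detection
    threshold, so the segmented boundary stops short of the true tip. The
    default (None) estimates this blur-limited loss from the mask itself:
    with trunk half-width W px and tips tapering over ~10% of the body to
    ~25% of W, the sub-resolution segment has length
    0.1*len*max(0, psf/W - 0.25)/0.75 with psf ~ 1.2 px — zero for any
    worm whose trunk half-width exceeds ~5 px, a few px for the thinnest
    larvae.
    """
    pts = np.asarray(path_px, dtype=float)
    keep = np.ones(len(pts), dtype=bool)
    keep[1:] = np.any(np.diff(pts, axis=0) != 0, axis=1)
    pts = pts[keep]
    if len(pts) < 2:
        raise ValueError("path too short")
    if K == 2:
        ends = np.array([pts[0], pts[-1]]) * px_um
        return Centerline(points_um=ends, qc=qc or CenterlineQC())
    if len(pts) < 5:
        raise ValueError("path must have >= 5 points for spline fitting")

    chord = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    u = np.concatenate([[0.0], np.cumsum(chord)])
    u /= u[-1]
    k = min(3, len(pts) - 1)
    try:
        tck, _ = splprep(pts.T, u=u, s=smooth * len(pts), k=k)
    except (ValueError, TypeError):
        # collinear/duplicate degeneracies: jitter-free fallback to lower order
        tck, _ = splprep(pts.T, u=u, s=smooth * len(pts), k=1)

    m = max(10 * K, 200)
    uu = np.linspace(0.0, 1.0, m)
    x, y = splev(uu, tck)
    dense = np.column_stack([x, y])

    if mask is not None and mask.any():
        rows, cols = np.nonzero(mask)
        r0 = max(rows.min() - 3, 0)
        r1 = min(rows.max() + 4, mask.shape[0])
        c0 = max(cols.min() - 3, 0)
        c1 = min(cols.max() + 4, mask.shape[1])
        sub = mask[r0:r1, c0:c1]
        edt = ndimage.distance_transform_edt(sub)
        offset = np.array([c0, r0], dtype=float)
        if tip_overshoot_px is None:
            seg_len = float(
                np.sum(np.linalg.norm(np.diff(dense, axis=0), axis=1))
            )
            w_trunk = max(float(edt.max()), 1.0)
            psf_px = 1.2  # minimal resolvable half-width: blur + sampling
            tip_overshoot_px = float(
                np.clip(0.1 * seg_len * max(0.0, psf_px / w_trunk - 0.25) / 0.75,
                        0.0, 4.0)
            )
        dense = _extend_tips(
            dense - offset, sub, edt, tip_extension_cap, tip_overshoot_px
        ) + offset

    seg = np.linalg.norm(np.diff(dense, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, arclen[-1], K)
    out = np.column_stack(
        [np.interp(targets, arclen, dense[:, 0]), np.interp(targets, arclen, dense[:, 1])]
    )
    return Centerline(points_um=out * px_um, qc=qc or CenterlineQC())


def _extend_tips(
    dense: np.ndarray,
    mask: np.ndarray,
    edt: np.ndarray,
    cap_factor: float,
    overshoot_px: float,
) -> np.ndarray:
    """Extend both ends of a dense polyline to the mask boundary and a
    little beyond (the sub-PSF taper the threshold could not see)."""
    out = dense

    def inside(p):
        r, c = int(round(p[1])), int(round(p[0]))
        return 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and mask[r, c]

    # tangent from a ~4 px window: the adjacent dense sample is too noisy
    win = max(2, int(round(4.0 / max(np.linalg.norm(dense[1] - dense[0]), 1e-6))))
    win = min(win, len(out) - 1)
    for end in (0, -1):
        p0 = out[0] if end == 0 else out[-1]
        nbr = out[win] if end == 0 else out[-1 - win]
        tangent = p0 - nbr
        nt = np.linalg.norm(tangent)
        if nt == 0:
            continue
        tangent /= nt
        r, c = int(round(p0[1])), int(round(p0[0]))
        if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]):
            continue
        cap = cap_factor * max(edt[r, c], 1.0)
        step = 0.25
        travelled = 0.0
        p = p0.copy()
        while travelled + step <= cap and inside(p + tangent * step):
            p = p + tangent * step
            travelled += step
        p = p + tangent * overshoot_px
        travelled += overshoot_px
        if travelled > 0:
            if end == 0:
                out = np.vstack([p, out])
            else:
                out = np.vstack([out, p])
    return out


def extract_centerline(
    wm: WormMask,
    K: int = 101,
    smooth: float = 1.0,
    prune_frac: float = 0.10,
) -> Centerline:
    """Mask -> oriented-later centerline (µm): skeletonize, prune, spline."""
    path, qc = skeletonize_mask(wm, prune_frac=prune_frac)
    return fit_spline(
        path, K=K, smooth=smooth, mask=wm.mask, px_um=wm.px_um, qc=qc
    )


@dataclass
class ClipKinematics:
    """Per-clip motion signals: oriented centerlines, centroid track,
    mid-body bend-angle series, and a per-frame validity mask."""

    centerlines: list[Centerline | None]
    centroids_um: np.ndarray        # (F, 2), NaN on invalid frames
    bend_rad: np.ndarray            # (F,), NaN on invalid frames
    valid: np.ndarray               # (F,) bool
    fps: float
    orientation_confident: bool = True

    @property
    def n_frames(self) -> int:
        return len(self.centerlines)

    def tip_track(self, which: str) -> np.ndarray:
        """(F, 2) µm track of the head or tail tip, NaN on invalid frames."""
        idx = 0 if which == "head" else -1
        out = np.full((self.n_frames, 2), np.nan)
        for i, cl in enumerate(self.centerlines):
            if cl is not None:
                out[i] = cl.points_um[idx]
        return out


def _bend_angle(points: np.ndarray) -> float:
    mid = points[len(points) // 2]
    v1 = mid - points[0]
    v2 = points[-1] - mid
    cross = v1[0] * v2[1] - v1[1] * v2[0]
    return float(np.arctan2(cross, np.dot(v1, v2)))


def export_centerlines_csv(kin: "ClipKinematics", path) -> None:
    """Write per-clip centerlines as tidy CSV: frame, index, x_um, y_um
    (head first; invalid frames omitted)."""
    import pandas as pd

    rows = []
    for f, cl in enumerate(kin.centerlines):
        if cl is None:
            continue
        for i, (x, y) in enumerate(cl.points_um):
            rows.append({"frame": f, "index": i, "x_um": x, "y_um": y})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.8g")


def kinematics_summary(kin: "ClipKinematics") -> dict:
    """JSON-ready per-clip summary of the kinematic signals."""
    valid = kin.valid
    lengths = [kin.centerlines[i].length_um for i in np.nonzero(valid)[0]]
    return {
        "n_frames": int(kin.n_frames),
        "n_valid": int(valid.sum()),
        "orientation_confident": bool(kin.orientation_confident),
        "median_length_um": float(np.median(lengths)) if lengths else None,
        "bend_rad_range": [
            float(np.nanmin(kin.bend_rad)), float(np.nanmax(kin.bend_rad)),
        ] if valid.any() else None,
    }


def orient_clip(
    centerlines: list[Centerline | None],
    centroids_um: np.ndarray,
    fps: float,
) -> ClipKinematics:
    """Assign a consistent head->tail orientation across a clip.

    Endpoints are corresponded frame-to-frame by nearest-endpoint matching
    (each frame keeps or flips so its endpoints minimise summed displacement
    to the previous valid frame's). The endpoint family with larger total
    path length over the clip becomes the head; when the two families'
    path lengths differ by less than 10% the orientation is flagged as
    low-confidence. The mid-body bend angle is the signed angle between
    the head->mid and mid->tail chords.
    """
    valid = np.array(
        [cl is not None and not cl.qc.coiled for cl in centerlines], dtype=bool
    )
    if not valid.any() or valid.sum() < 2:
        raise ValueError("fewer than 2 valid frames: cannot orient clip")

    oriented: list[Centerline | None] = [None] * len(centerlines)
    ref = None
    for i, cl in enumerate(centerlines):
        if not valid[i]:
            continue
        e0, e1 = cl.points_um[0], cl.points_um[-1]
        if ref is not None:
            d_keep = np.linalg.norm(e0 - ref[0]) + np.linalg.norm(e1 - ref[1])
            d_flip = np.linalg.norm(e0 - ref[1]) + np.linalg.norm(e1 - ref[0])
            if d_flip < d_keep:
                cl = cl.flipped()
        oriented[i] = cl
        ref = (cl.points_um[0], cl.points_um[-1])

    idx = np.nonzero(valid)[0]
    a = np.array([oriented[i].points_um[0] for i in idx])
    b = np.array([oriented[i].points_um[-1] for i in idx])
    path_a = float(np.sum(np.linalg.norm(np.diff(a, axis=0), axis=1)))
    path_b = float(np.sum(np.linalg.norm(np.diff(b, axis=0), axis=1)))
    if path_b > path_a:
        oriented = [cl.flipped() if cl is not None else None for cl in oriented]
        path_a, path_b = path_b, path_a
    denom = max(path_a, path_b, 1e-12)
    confident = (path_a - path_b) / denom >= 0.10

    bend = np.full(len(centerlines), np.nan)
    for i in idx:
        bend[i] = _bend_angle(oriented[i].points_um)
        oriented[i].qc.orientation_confident = confident

    centroids = np.asarray(centroids_um, dtype=float).copy()
    centroids[~valid] = np.nan
    return ClipKinematics(
        centerlines=oriented,
        centroids_um=centroids,
        bend_rad=bend,
        valid=valid,
        fps=fps,
        orientation_confident=confident,
    )
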