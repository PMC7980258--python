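"""Image pipelines: FLS z-stack segmentation and the filopodia tracer/tracker.

Two bespoke analyses are implemented here.

* ``segment_fls_stack`` maps actin-based structures in a 3D z-stack: a 2D
  difference-of-Gaussians (DoG) blob filter finds candidate positions
  independently in every XY plane, and structures are traced upward through
  z from each base-plane candidate by greedily hopping to the nearest
  candidate in the next plane within a tracing radius.

* The movie tracer converts 2D time-lapse frames into per-frame filopodium
  skeletons (local thresholding, random-forest pixel classification, small
  component removal, DBSCAN clustering, skeletonization, gated tip joining)
  and then links them across frames with the Hungarian algorithm under a
  distance + length-difference cost.

All pixel thresholds are the pipeline's tuned constants; boundary behaviour
(strict ``<`` cuts) is part of the contract and covered by tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal
from scipy.optimize import linear_sum_assignment
from skimage import draw, filters, measure, morphology
from sklearn.base import BaseEstimator
from sklearn.cluster import DBSCAN
from sklearn.ensemble import RandomForestClassifier

__all__ = [
    "PIXEL_SIZE_UM",
    "FLSObject",
    "SkeletonTrack",
    "segment_fls_stack",
    "measure_fls",
    "preprocess_movie",
    "PixelClassifier",
    "train_pixel_classifier",
    "mask_to_filopodia",
    "measure_skeleton_length",
    "link_tracks",
    "track_velocities",
]

PIXEL_SIZE_UM = 0.1487  # µm per pixel in the 2D movies

MIN_COMPONENT_PX = 40
DBSCAN_EPS_PX = 7.0
DBSCAN_MIN_SAMPLES = 20
JOIN_MAX_DIST_PX = 20.0
JOIN_MAX_ANGLE_DEG = 30.0
LINK_MAX_COM_DIST_PX = 30.0
MIN_TRACK_FRAMES = 5


# ---------------------------------------------------------------------------
# z-stack segmentation (FLSAce-style)


@dataclass
class FLSObject:
    """One traced structure in a z-stack."""

    base_centroid: tuple[float, float]  # (row, col) px, base plane
    base_pixels: np.ndarray  # (n, 2) int pixel coordinates in the base plane
    plane_centroids: list  # [(z, row, col), ...] traced through z
    length_um: float  # path length along the trace
    straight_length_um: float  # tip-to-end distance

    @property
    def base_area_px(self) -> int:
        return len(self.base_pixels)

    @property
    def straightness(self) -> float:
        return self.straight_length_um / self.length_um if self.length_um > 0 else 1.0


def _plane_candidates(
    plane: np.ndarray,
    dog_sigma: float,
    dog_k: float,
    threshold_method: str,
    min_candidate_px: int = 4,
):
    dog = filters.difference_of_gaussians(plane.astype(float), dog_sigma, dog_k * dog_sigma)
    if np.ptp(dog) == 0:  # flat plane: nothing to segment
        return [], []
    if threshold_method == "otsu":
        thr = filters.threshold_otsu(dog)
    elif threshold_method == "li":
        thr = filters.threshold_li(dog)
    elif threshold_method == "mean":
        thr = float(dog.mean())
    else:
        raise ValueError(f"unknown threshold_method {threshold_method!r}")
    mask = dog > thr
    labels = measure.label(mask, connectivity=2)
    props = [p for p in measure.regionprops(labels) if p.area >= min_candidate_px]
    cents = [p.centroid for p in props]
    pix = [p.coords for p in props]
    return cents, pix


def segment_fls_stack(
    stack: np.ndarray,
    dog_sigma: float = 2.0,
    dog_k: float = 1.6,
    threshold_method: str = "otsu",
    min_length_um: float = 0.0,
    max_trace_radius_px: float = 5.0,
    base_plane: int = 0,
    px_size_um: float = PIXEL_SIZE_UM,
    z_step_um: float = 0.5,
) -> list[FLSObject]:
    """Segment and trace rod-like structures through a z-stack.

    Candidate blob positions are found per plane by DoG (G(sigma) -
    G(k*sigma)) filtering and thresholding; from every base-plane candidate
    the trace greedily extends to the nearest candidate in the next plane
    within ``max_trace_radius_px`` (ties by distance, then detection order),
    stopping when none is in range.  Traces shorter than ``min_length_um``
    are discarded.
    """
    stack = np.asarray(stack)
    if stack.ndim != 3 or stack.shape[0] < 2:
        raise ValueError("stack must be 3D with >= 2 planes")
    if dog_k <= 1:
        raise ValueError("dog_k must be > 1")
    if not 0 <= base_plane < stack.shape[0]:
        raise ValueError("base plane index outside the stack")
    n_planes = stack.shape[0]
    cands = [
        _plane_candidates(stack[z], dog_sigma, dog_k, threshold_method)
        for z in range(n_planes)
    ]
    objects: list[FLSObject] = []
    base_cents, base_pix = cands[base_plane]
    for idx, (c0, pix0) in enumerate(zip(base_cents, base_pix)):
        trace = [(base_plane, c0[0], c0[1])]
        cur = np.asarray(c0)
        for z in range(base_plane + 1, n_planes):
            cz, _ = cands[z]
            if not cz:
                break
            d = np.linalg.norm(np.asarray(cz) - cur, axis=1)
            j = int(np.argmin(d))  # argmin returns the first (detection-order) tie
            if d[j] > max_trace_radius_px:
                break
            trace.append((z, cz[j][0], cz[j][1]))
            cur = np.asarray(cz[j])
        pts = np.array(
            [(z * z_step_um, r * px_size_um, c * px_size_um) for z, r, c in trace]
        )
        if len(pts) > 1:
            path = float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())
            straight = float(np.linalg.norm(pts[-1] - pts[0]))
        else:
            path = straight = 0.0
        if path < min_length_um:
            continue
        objects.append(
            FLSObject(
                base_centroid=(c0[0], c0[1]),
                base_pixels=pix0,
                plane_centroids=trace,
                length_um=path,
                straight_length_um=straight,
            )
        )
    return objects


def measure_fls(
    obj: FLSObject,
    channel_images: dict[str, np.ndarray],
    all_base_pixels: list[np.ndarray] | None = None,
    registration_shift: tuple[int, int] = (0, 0),
    px_size_um: float = PIXEL_SIZE_UM,
    ring_radii: tuple[float, float] = (2.0, 3.0),
) -> dict:
    """Measure base morphology and per-channel intensities of one structure.

    The local background of each channel is the mean intensity in an
    annulus spanning ``ring_radii`` times the base's equivalent radius,
    with every neighbouring base excluded.  A fully occluded ring yields a
    NaN background (corrected intensity missing-flagged).
    """
    area_um2 = obj.base_area_px * px_size_um**2
    diameter_um = 2.0 * np.sqrt(area_um2 / np.pi)
    r_eq_px = np.sqrt(obj.base_area_px / np.pi)
    rec = {
        "base_centroid_px": obj.base_centroid,
        "base_area_um2": area_um2,
        "effective_diameter_um": diameter_um,
        "length_um": obj.length_um,
        "straightness": obj.straightness,
    }
    for name, img in channel_images.items():
        img = np.asarray(img, dtype=float)
        if registration_shift != (0, 0):
            img = np.roll(img, registration_shift, axis=(0, 1))
        rows, cols = obj.base_pixels[:, 0], obj.base_pixels[:, 1]
        base_mean = float(img[rows, cols].mean())
        rr, cc = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
        dist = np.hypot(rr - obj.base_centroid[0], cc - obj.base_centroid[1])
        ring = (dist >= ring_radii[0] * r_eq_px) & (dist <= ring_radii[1] * r_eq_px)
        if all_base_pixels is not None:
            occupied = np.zeros(img.shape, dtype=bool)
            for pix in all_base_pixels:
                occupied[pix[:, 0], pix[:, 1]] = True
            ring &= ~occupied
        if ring.sum() == 0:
            ring_mean = np.nan
        else:
            ring_mean = float(img[ring].mean())
        rec[f"intensity_{name}_raw"] = base_mean
        rec[f"intensity_{name}_background"] = ring_mean
        rec[f"intensity_{name}"] = base_mean - ring_mean
    return rec


# ---------------------------------------------------------------------------
# movie tracer


def preprocess_movie(frame: np.ndarray, block_size: int = 11) -> np.ndarray:
    """Local (Gaussian-profile) thresholding of a single 2D frame.

    Each pixel is compared with an 11-px Gaussian-weighted local mean; the
    output is a boolean foreground mask.  Invariant to global additive
    offsets by construction.
    """
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2:
        raise ValueError("expected a single 2D frame (z-project stacks first)")
    if min(frame.shape) < block_size:
        raise ValueError("frame smaller than the thresholding window")
    local = filters.threshold_local(frame, block_size=block_size, method="gaussian")
    return frame > local


class PixelClassifier(BaseEstimator):
    """Random-forest pixel classifier over raw square patch intensities.

    For training, the ``patch_size`` x ``patch_size`` neighbourhood of every
    positive (filopodium) pixel is extracted as a flat feature vector;
    negatives are sampled uniformly from non-filopodium pixels at
    ``neg_ratio`` : 1 (truncated and flagged if the frame has too few).  The
    forest uses max depth 50 and a five-sample leaf minimum.
    """

    def __init__(
        self,
        patch_size: int = 13,
        neg_ratio: int = 20,
        max_depth: int = 50,
        min_samples_leaf: int = 5,
        n_estimators: int = 50,
        random_state: int = 0,
    ):
        self.patch_size = patch_size
        self.neg_ratio = neg_ratio
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.n_estimators = n_estimators
        self.random_state = random_state

    def _patches(self, frame: np.ndarray, coords: np.ndarray) -> np.ndarray:
        h = self.patch_size // 2
        padded = np.pad(frame, h, mode="reflect")
        win = np.lib.stride_tricks.sliding_window_view(
            padded, (self.patch_size, self.patch_size)
        )
        return win[coords[:, 0], coords[:, 1]].reshape(len(coords), -1)

    def fit(self, frames, masks):
        """frames/masks: lists of 2D arrays (mask True on filopodium pixels)."""
        rng = np.random.default_rng(self.random_state)
        pos_feats, neg_feats = [], []
        n_pos_total = 0
        for frame, mask in zip(frames, masks, strict=True):
            frame = np.asarray(frame, dtype=float)
            mask = np.asarray(mask, dtype=bool)
            pos = np.argwhere(mask)
            n_pos_total += len(pos)
            if len(pos):
                pos_feats.append(self._patches(frame, pos))
            neg = np.argwhere(~mask)
            n_neg = min(len(neg), self.neg_ratio * len(pos))
            if n_neg:
                sel = neg[rng.choice(len(neg), size=n_neg, replace=False)]
                neg_feats.append(self._patches(frame, sel))
        if n_pos_total == 0:
            raise ValueError("no positive pixels in the annotation")
        X = np.vstack(pos_feats + neg_feats)
        y = np.concatenate(
            [np.ones(sum(len(f) for f in pos_feats), dtype=int),
             np.zeros(sum(len(f) for f in neg_feats), dtype=int)]
        )
        self.neg_pos_ratio_ = float((y == 0).sum() / (y == 1).sum())
        self.truncated_ = self.neg_pos_ratio_ < self.neg_ratio - 1e-9
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            random_state=self.random_state,
        ).fit(X, y)
        return self

    def predict_mask(self, frame: np.ndarray) -> np.ndarray:
        """Classify every pixel of a frame; returns a boolean mask."""
        frame = np.asarray(frame, dtype=float)
        coords = np.argwhere(np.ones(frame.shape, dtype=bool))
        feats = self._patches(frame, coords)
        pred = self.forest_.predict(feats)
        return pred.reshape(frame.shape).astype(bool)


def train_pixel_classifier(frames, masks, seed: int = 0, **kw) -> PixelClassifier:
    """Train the patch random forest on annotated frames."""
    return PixelClassifier(random_state=seed, **kw).fit(frames, masks)


# ---------------------------------------------------------------------------
# skeleton utilities


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _skeleton_graph(pixels: np.ndarray):
    """8-connected graph over skeleton pixels; diagonal edges weigh sqrt(2)."""
    import networkx as nx

    pset = {tuple(p) for p in pixels}
    g = nx.Graph()
    g.add_nodes_from(pset)
    for r, c in pset:
        for dr, dc in _NEIGHBORS:
            q = (r + dr, c + dc)
            if q in pset and not g.has_edge((r, c), q):
                g.add_edge((r, c), q, weight=np.hypot(dr, dc))
    return g


def _tree_longest_path(g):
    """Weighted diameter path of a tree (double Dijkstra sweep)."""
    import networkx as nx

    start = next(iter(g.nodes))
    dist = nx.single_source_dijkstra_path_length(g, start)
    far1 = max(dist, key=dist.get)
    dist2, paths = nx.single_source_dijkstra(g, far1)
    far2 = max(dist2, key=dist2.get)
    return paths[far2], dist2[far2]


def measure_skeleton_length(
    pixels: np.ndarray, min_branch_px: int = 5
) -> dict:
    """Longest-path length of a skeleton, splitting off residual branches.

    The filopodium is the longest path through the 8-connected skeleton
    graph (unit/sqrt(2) edge weights, i.e. summed nearest-neighbour
    distances); remaining branches of at least ``min_branch_px`` pixels are
    emitted as separate chains.  A cyclic skeleton is broken by removing the
    longest edge of each cycle and flagged: 8-connected junctions always
    carry diagonal shortcut triangles, and dropping the longest (diagonal)
    edge removes the shortcut without detouring the natural path.
    """
    import networkx as nx

    pixels = np.asarray(pixels)
    if pixels.ndim != 2 or pixels.shape[1] != 2:
        raise ValueError("pixels must be an (n, 2) coordinate array")
    g = _skeleton_graph(pixels)
    had_cycle = False
    while True:
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            break
        had_cycle = True
        longest = max(cycle, key=lambda e: g.edges[e[0], e[1]]["weight"])
        g.remove_edge(longest[0], longest[1])
    # operate on the largest connected component
    comps = sorted(nx.connected_components(g), key=len, reverse=True)
    main = g.subgraph(comps[0])
    path, length = _tree_longest_path(main)
    branches = []
    leftover = g.copy()
    leftover.remove_nodes_from(path)
    for comp in nx.connected_components(leftover):
        if len(comp) >= min_branch_px:
            sub_path, sub_len = _tree_longest_path(leftover.subgraph(comp))
            branches.append(
                {"pixels": np.array(sub_path), "length_px": float(sub_len)}
            )
    return {
        "length_px": float(length),
        "path": np.array(path),
        "branches": branches,
        "had_cycle": had_cycle,
    }


def _endpoints(pixels_set: set) -> list:
    eps = []
    for p in pixels_set:
        n = sum((p[0] + dr, p[1] + dc) in pixels_set for dr, dc in _NEIGHBORS)
        if n == 1:
            eps.append(p)
    return eps


def _tip_tangent(pixels_set: set, tip) -> np.ndarray:
    """Mean direction of the 3 pixels nearest a tip (undirected)."""
    pts = np.array(sorted(pixels_set, key=lambda q: np.hypot(q[0] - tip[0], q[1] - tip[1])))
    near = pts[:4]  # tip + its 3 nearest
    vecs = near[1:] - np.asarray(tip)
    v = vecs.mean(axis=0).astype(float)
    n = np.linalg.norm(v)
    return v / n if n > 0 else np.array([1.0, 0.0])


def mask_to_filopodia(
    mask: np.ndarray,
    min_component_px: int = MIN_COMPONENT_PX,
    dbscan_eps: float = DBSCAN_EPS_PX,
    dbscan_min_samples: int = DBSCAN_MIN_SAMPLES,
    join_max_dist: float = JOIN_MAX_DIST_PX,
    join_max_angle_deg: float = JOIN_MAX_ANGLE_DEG,
) -> list[np.ndarray]:
    """Reduce a binary filopodium mask to per-structure skeleton pixel sets.

    Steps: connected components with < ``min_component_px`` pixels removed
    (strict cut); DBSCAN clustering of the remaining pixels (Euclidean
    radius ``dbscan_eps``); per-cluster skeletonization; then fragments are
    joined by a straight line when two tips are within ``join_max_dist``
    pixels and their local tangents (mean direction over each tip's 3
    nearest pixels) differ by no more than ``join_max_angle_deg`` degrees.
    """
    mask = np.asarray(mask, dtype=bool)
    labels = measure.label(mask, connectivity=2)
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_component_px  # strict: a 39-px component goes, 40 stays
    keep[0] = False
    cleaned = keep[labels]
    coords = np.argwhere(cleaned)
    if len(coords) == 0:
        return []
    labels = DBSCAN(eps=dbscan_eps, min_samples=dbscan_min_samples).fit_predict(coords)
    chains: list[set] = []
    for lab in np.unique(labels):
        if lab == -1:
            continue
        sub = np.zeros(mask.shape, dtype=bool)
        pts = coords[labels == lab]
        sub[pts[:, 0], pts[:, 1]] = True
        skel = morphology.skeletonize(sub)
        # a density cluster can span disjoint fragments: one chain per
        # connected skeleton component, joining decides the rest
        sk_labels = measure.label(skel, connectivity=2)
        for sl in range(1, sk_labels.max() + 1):
            sk_coords = np.argwhere(sk_labels == sl)
            if len(sk_coords):
                chains.append({tuple(p) for p in sk_coords})
    # gated tip joining, closest pairs first
    joined = True
    while joined:
        joined = False
        best = None
        for i in range(len(chains)):
            for j in range(i + 1, len(chains)):
                for ta in _endpoints(chains[i]):
                    for tb in _endpoints(chains[j]):
                        d = float(np.hypot(ta[0] - tb[0], ta[1] - tb[1]))
                        if d > join_max_dist:
                            continue
                        ua = _tip_tangent(chains[i], ta)
                        ub = _tip_tangent(chains[j], tb)
                        ang = np.degrees(np.arccos(np.clip(abs(np.dot(ua, ub)), 0, 1)))
                        if ang > join_max_angle_deg:
                            continue
                        if best is None or d < best[0]:
                            best = (d, i, j, ta, tb)
        if best is not None:
            _, i, j, ta, tb = best
            rr, cc = draw.line(ta[0], ta[1], tb[0], tb[1])
            merged = chains[i] | chains[j] | set(zip(rr.tolist(), cc.tolist()))
            chains = [c for k, c in enumerate(chains) if k not in (i, j)] + [merged]
            joined = True
    return [np.array(sorted(c)) for c in chains]


# ---------------------------------------------------------------------------
# tracking


@dataclass
class SkeletonTrack:
    """One filopodium identity across frames."""

    track_id: int
    frames: list = field(default_factory=list)  # frame indices
    skeletons: list = field(default_factory=list)  # pixel arrays per frame
    lengths_px: list = field(default_factory=list)
    centers: list = field(default_factory=list)  # (row, col) center of mass

    @property
    def lifespan(self) -> int:
        return len(self.frames)


def link_tracks(
    frames_filopodia: list[list[dict]],
    max_com_dist: float = LINK_MAX_COM_DIST_PX,
    dist_weight: float = 0.6,
    length_weight: float = 0.4,
    signed_length_term: bool = False,
) -> list[SkeletonTrack]:
    """Link per-frame filopodia into tracks by optimal assignment.

    Each filopodium is a dict with ``center`` (row, col), ``length_px`` and
    ``pixels``.  Frame-to-frame matching minimises
    C = 0.6 * ||center1 - center2|| + 0.4 * |L1 - L2| (the length term can
    be made signed via ``signed_length_term``, matching similar lengths is
    the default), with links whose centers are more than ``max_com_dist``
    pixels apart forbidden.  Unmatched filopodia end or start tracks.
    """
    tracks: list[SkeletonTrack] = []
    active: dict[int, SkeletonTrack] = {}
    next_id = 0
    prev_items: list[tuple[int, dict]] = []  # (track_id, filopodium)
    BIG = 1e9
    for f, filos in enumerate(frames_filopodia):
        assigned = {}
        if prev_items and filos:
            n1, n2 = len(prev_items), len(filos)
            cost = np.full((n1, n2), BIG)
            for i, (_, a) in enumerate(prev_items):
                for j, b in enumerate(filos):
                    d = float(np.hypot(a["center"][0] - b["center"][0],
                                       a["center"][1] - b["center"][1]))
                    if d > max_com_dist:
                        continue
                    dl = b["length_px"] - a["length_px"]
                    if not signed_length_term:
                        dl = abs(dl)
                    cost[i, j] = dist_weight * d + length_weight * dl
            rows, cols = linear_sum_assignment(cost)
            for i, j in zip(rows, cols):
                if cost[i, j] < BIG / 2:
                    assigned[j] = prev_items[i][0]
        new_prev = []
        new_active = {}
        for j, filo in enumerate(filos):
            if j in assigned:
                tr = active[assigned[j]]
            else:
                tr = SkeletonTrack(track_id=next_id)
                next_id += 1
                tracks.append(tr)
            tr.frames.append(f)
            tr.skeletons.append(filo.get("pixels"))
            tr.lengths_px.append(filo["length_px"])
            tr.centers.append(filo["center"])
            new_active[tr.track_id] = tr
            new_prev.append((tr.track_id, filo))
        active = new_active
        prev_items = new_prev
    return tracks


def track_velocities(
    tracks: list[SkeletonTrack],
    frame_interval_s: float = 15.0,
    px_size_um: float = PIXEL_SIZE_UM,
    min_frames: int = MIN_TRACK_FRAMES,
    window: int = 5,
    order: int = 2,
) -> dict[int, dict]:
    """Smoothed length and velocity series per sufficiently long track.

    Tracks persisting fewer than ``min_frames`` frames are removed; lengths
    (converted to µm) are smoothed and differentiated with a Savitzky–Golay
    filter (window 5, order 2), yielding velocities in µm/min.
    """
    out = {}
    dt_min = frame_interval_s / 60.0
    for tr in tracks:
        if tr.lifespan < min_frames:
            continue
        L = np.asarray(tr.lengths_px, dtype=float) * px_size_um
        w = min(window, L.size if L.size % 2 == 1 else L.size - 1)
        sm = signal.savgol_filter(L, w, min(order, w - 1))
        vel = signal.savgol_filter(L, w, min(order, w - 1), deriv=1, delta=dt_min)
        out[tr.track_id] = {
            "frames": np.asarray(tr.frames),
            "length_um": sm,
            "velocity_um_per_min": vel,
        }
    return out
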