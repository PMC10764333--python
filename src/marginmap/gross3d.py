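"""Gross-specimen 3D workflow: turntable-frame segmentation and
trajectory filtering, turntable-diameter scale calibration, point-cloud
cleanup and orientation, L/W/H measurement, and grossing/inking
recommendations (Mohs or breadloaf).

The reconstruction itself (photogrammetry) is external; this module
consumes its point-cloud output.  After orientation the specimen's flat
bottom face points toward -z, the centroid sits at the origin, and the
suture marker (12 o'clock) — when present — points toward +y.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation
from skimage import color as skcolor
from skimage import filters, measure
from skimage.measure import EllipseModel
from sklearn.neighbors import NearestNeighbors, RadiusNeighborsRegressor

__all__ = [
    "SpecimenCloud",
    "GrossMeasurements",
    "GrossingPlan",
    "FrameDetection",
    "segment_frames",
    "filter_by_trajectory",
    "calibrate_scale",
    "remove_outliers",
    "orient_cloud",
    "measure_cloud",
    "grossing_plan",
    "refine_surface",
    "load_cloud",
    "save_cloud",
]

#: suture thread detection: dark navy in HSV (hue deg, sat, val)
SUTURE_HSV = {"hue": (200.0, 270.0), "s_min": 0.3, "v_max": 0.55}


@dataclass
class SpecimenCloud:
    points: np.ndarray  # (n, 3) model units
    colors: np.ndarray | None = None  # (n, 3) uint8
    scale: float = 1.0  # cm per model unit
    oriented: bool = False
    suture_direction: np.ndarray | None = None  # unit vector, post-orientation

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class GrossMeasurements:
    """L = y-extent, W = x-extent, H = z-extent of the oriented cloud, cm."""

    L: float
    W: float
    H: float

    def as_tuple(self):
        return (self.L, self.W, self.H)


@dataclass
class GrossingPlan:
    mode: str  # 'mohs' | 'breadloaf'
    segments: list = field(default_factory=list)  # (role, (3,) start cm, (3,) end cm)

    def roles(self):
        return [role for role, _, _ in self.segments]


def _axis_lengths(model) -> tuple[float, float]:
    ax = getattr(model, "axis_lengths", None)
    if ax is None:
        ax = model.params[2:4]
    return float(ax[0]), float(ax[1])


def _ransac_ellipse(points: np.ndarray, residual_px: float, n_trials: int = 500,
                    min_samples: int = 5, seed: int = 0):
    """Ellipse RANSAC tolerant of degenerate minimal samples (collinear or
    repeated points make the conic fit complex-valued)."""
    rng = np.random.default_rng(seed)
    best_model, best_inl, best_support = None, None, -1
    for _ in range(n_trials):
        sel = rng.choice(len(points), min_samples, replace=False)
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                model = EllipseModel.from_estimate(points[sel])
                a, b = _axis_lengths(model)
                if not (np.isfinite(a) and np.isfinite(b)) or min(a, b) <= 0:
                    continue
                resid = np.abs(model.residuals(points))
            except Exception:
                continue
        inl = resid < residual_px
        # score by support outside the minimal sample: the five defining
        # points are inliers for free, so they carry no evidence
        sup = inl.copy()
        sup[sel] = False
        if sup.sum() > best_support:
            best_model, best_inl, best_support = model, inl, sup.sum()
    if best_model is None:
        return None, None, -1
    if best_inl.sum() >= min_samples:  # refine on inliers
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                refined = EllipseModel.from_estimate(points[best_inl])
                a, b = _axis_lengths(refined)
                if np.isfinite(a) and np.isfinite(b) and min(a, b) > 0:
                    best_model = refined
                    best_inl = np.abs(refined.residuals(points)) < residual_px
            except Exception:
                pass
    return best_model, best_inl, best_support


@dataclass(eq=False)
class FrameDetection:
    frame_index: int
    mask: np.ndarray
    centroid: tuple[float, float]  # (x, y) px
    kept: bool = True


# ---------------------------------------------------------------------------
# video frames


def segment_frames(frames, intensity_cutoff: float = 140.0,
                   min_area: int = 50, max_area_frac: float = 0.25,
                   subsample: int = 1) -> list[FrameDetection]:
    """Candidate specimen detections per frame.

    Intensity thresholding (the specimen is dark on a light turntable),
    connected-component labelling, and an object size filter.  With
    ``subsample=k`` only every k-th frame is segmented (the study keeps one
    in ten frames to bound reconstruction time).
    """
    frames = list(frames)[:: max(1, subsample)]
    if len(frames) < 8:
        raise ValueError("need >= 8 frames")
    dets, misses = [], 0
    for fi, frame in enumerate(frames):
        gray = np.asarray(frame, dtype=float)
        if gray.ndim == 3:
            gray = gray.mean(axis=-1)
        cand = gray < intensity_cutoff
        lbl = measure.label(cand, connectivity=2)
        found = False
        for region in measure.regionprops(lbl):
            if min_area <= region.area <= max_area_frac * gray.size:
                cy, cx = region.centroid
                dets.append(FrameDetection(fi, lbl == region.label, (cx, cy)))
                found = True
        misses += not found
    if misses > len(frames) / 2:
        raise RuntimeError(f"no specimen candidate in {misses}/{len(frames)} frames")
    return dets


def filter_by_trajectory(detections: list[FrameDetection],
                         residual_px: float = 6.0) -> list[FrameDetection]:
    """Keep detections whose centroids follow one elliptical trajectory.

    Only the revolving specimen traces an ellipse across frames; static or
    sporadic distractors fall outside the RANSAC ellipse fit and are
    rejected.
    """
    cents = np.array([d.centroid for d in detections])
    if len(cents) < 8:
        raise ValueError("need >= 8 centroids")
    # score on unique positions so a static distractor (one location repeated
    # every frame) cannot outvote the moving specimen
    uniq = np.unique(np.round(cents, 1), axis=0)
    model, inliers, support = _ransac_ellipse(uniq, residual_px)
    if model is None or inliers is None or support < 5:
        raise RuntimeError("trajectory ellipse fit failed (< 5 supporting inliers)")
    with np.errstate(all="ignore"):
        resid = np.abs(model.residuals(cents))
    out = []
    for det, r in zip(detections, resid):
        out.append(FrameDetection(det.frame_index, det.mask, det.centroid,
                                  bool(r < residual_px)))
    if sum(d.kept for d in out) < 5:
        raise RuntimeError("trajectory ellipse fit failed (< 5 inliers)")
    return out


def calibrate_scale(turntable_frame, diameter_cm: float,
                    edge_quantile: float = 0.99) -> float:
    """cm-per-pixel scale from the turntable rim.

    Edges come from a Scharr filter; a RANSAC ellipse is fit to the strong
    edge pixels and the scale is ``diameter_cm / major_axis_px`` — an
    obliquely viewed circle preserves its diameter along the major axis.
    """
    gray = np.asarray(turntable_frame, dtype=float)
    if gray.ndim == 3:
        gray = gray.mean(axis=-1)
    mag = filters.scharr(gray)
    thr = np.quantile(mag, edge_quantile)
    ys, xs = np.nonzero(mag >= max(thr, 1e-9))
    if len(xs) < 10:
        raise RuntimeError("no turntable edges found")
    pts = np.column_stack([xs, ys]).astype(float)
    model, _, _ = _ransac_ellipse(pts, residual_px=2.0, n_trials=300)
    if model is None:
        raise RuntimeError("turntable ellipse fit failed")
    a, b = _axis_lengths(model)
    major = 2.0 * max(a, b)
    return diameter_cm / major


# ---------------------------------------------------------------------------
# point-cloud cleanup and orientation


def remove_outliers(cloud: SpecimenCloud, k: int = 8, sd_factor: float = 2.0) -> SpecimenCloud:
    """Drop points whose mean k-NN distance exceeds mean + sd_factor * sd."""
    pts = cloud.points
    if k >= len(pts):
        raise ValueError("k must be smaller than the point count")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pts)
    d, _ = nn.kneighbors(pts)
    md = d[:, 1:].mean(axis=1)
    keep = md <= md.mean() + sd_factor * md.std()
    return SpecimenCloud(pts[keep],
                         cloud.colors[keep] if cloud.colors is not None else None,
                         cloud.scale, cloud.oriented, cloud.suture_direction)


def _ransac_plane(pts: np.ndarray, threshold: float, n_iter: int = 300, seed: int = 0):
    """RANSAC plane fit: returns (unit normal, point on plane, inlier mask)."""
    rng = np.random.default_rng(seed)
    best_n, best_inl = None, None
    for _ in range(n_iter):
        a, b, c = pts[rng.choice(len(pts), 3, replace=False)]
        n = np.cross(b - a, c - a)
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            continue
        n = n / norm
        d = np.abs((pts - a) @ n)
        inl = d < threshold
        if best_inl is None or inl.sum() > best_inl.sum():
            best_n, best_inl, best_a = n, inl, a
    if best_inl is None:
        raise RuntimeError("plane fit failed")
    # least-squares refinement on the inliers
    sel = pts[best_inl]
    ctr = sel.mean(axis=0)
    _, _, vh = np.linalg.svd(sel - ctr, full_matrices=False)
    n = vh[-1]
    if n @ best_n < 0:
        n = -n
    return n, ctr, best_inl


def _rotation_to(v_from: np.ndarray, v_to: np.ndarray) -> Rotation:
    a = v_from / np.linalg.norm(v_from)
    b = v_to / np.linalg.norm(v_to)
    axis = np.cross(a, b)
    s = np.linalg.norm(axis)
    if s < 1e-12:
        if a @ b > 0:
            return Rotation.identity()
        # 180 deg about any axis orthogonal to a
        ortho = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(ortho) < 1e-6:
            ortho = np.cross(a, [0.0, 1.0, 0.0])
        return Rotation.from_rotvec(np.pi * ortho / np.linalg.norm(ortho))
    angle = np.arctan2(s, a @ b)
    return Rotation.from_rotvec(angle * axis / s)


def _suture_mask(colors: np.ndarray) -> np.ndarray:
    hsv = skcolor.rgb2hsv(colors[None, :, :].astype(float) / 255.0)[0]
    h, s, v = hsv[:, 0] * 360.0, hsv[:, 1], hsv[:, 2]
    lo, hi = SUTURE_HSV["hue"]
    return (h >= lo) & (h <= hi) & (s >= SUTURE_HSV["s_min"]) & (v <= SUTURE_HSV["v_max"])


def orient_cloud(cloud: SpecimenCloud, bottom_frac: float = 0.2,
                 min_inlier_frac: float = 0.3, seed: int = 0) -> SpecimenCloud:
    """Orient the specimen: flat bottom face to -z, centroid to the origin,
    suture (if color-detected) to +y.

    The cloud is PCA pre-aligned (smallest-variance axis to z); the bottom
    plane is RANSAC-fit over the 20% of points with lowest z, with inlier
    threshold 2x a local-spacing noise estimate; the plane normal is
    rotated onto -z.  If no suture is found the in-plane rotation is left
    at zero and ``suture_direction`` stays None.
    """
    body = np.ones(len(cloud.points), dtype=bool)
    if cloud.colors is not None:
        body = ~_suture_mask(cloud.colors)  # suture must not steer the fit
        if body.sum() < 100:
            body[:] = True
    pts = cloud.points - cloud.points[body].mean(axis=0)
    _, _, vh = np.linalg.svd(pts[body], full_matrices=False)
    R0 = vh  # rows: principal axes; third row -> z
    if np.linalg.det(R0) < 0:
        R0 = R0 * np.array([[1.0], [1.0], [-1.0]])
    pts = pts @ R0.T
    # flat face should be at the bottom: the specimen's cut face is its
    # densest — flip if the band near the top holds more points (bands
    # anchored at robust quantiles so stray marker points cannot steer)
    z = pts[body, 2]
    zlo, zhi = np.quantile(z, [0.01, 0.99])
    band = max(0.05 * (zhi - zlo), 1e-9)
    if (z >= zhi - band).sum() > (z <= zlo + band).sum():
        pts[:, 1:] = -pts[:, 1:]  # rotate 180 deg about x
        z = pts[body, 2]
    bottom = pts[body][z <= np.quantile(z, bottom_frac)]
    nn = NearestNeighbors(n_neighbors=2).fit(pts[body])
    spacing = nn.kneighbors(pts[body])[0][:, 1]
    threshold = 2.0 * np.median(spacing)
    n, _, inl = _ransac_plane(bottom, threshold, seed=seed)
    if inl.mean() < min_inlier_frac:
        raise RuntimeError(
            f"bottom plane inlier fraction {inl.mean():.2f} < {min_inlier_frac}"
        )
    if n[2] > 0:  # normal should point down, away from the body
        n = -n
    rot = _rotation_to(n, np.array([0.0, 0.0, -1.0]))
    pts = rot.apply(pts)
    pts -= pts.mean(axis=0)

    suture_dir = None
    if cloud.colors is not None:
        sut = _suture_mask(cloud.colors)
        if sut.sum() >= 5:
            d = pts[sut].mean(axis=0)[:2]
            if np.linalg.norm(d) > 1e-9:
                ang = np.arctan2(d[0], d[1])  # CCW rotation by ang sends d -> +y
                rz = Rotation.from_euler("z", ang)
                pts = rz.apply(pts)
                pts -= pts.mean(axis=0)
                suture_dir = np.array([0.0, 1.0, 0.0])
        else:
            warnings.warn("no suture marker found; in-plane rotation left at 0")
    return SpecimenCloud(pts, cloud.colors, cloud.scale, True, suture_dir)


def _noise_scale(pts: np.ndarray) -> float:
    """Per-coordinate noise sd from the flat bottom face.

    One-sided MAD over the lower half of the bottom-face points: the region
    below the face plane contains noise only, so the estimate is immune to
    the truncation that biases a two-sided MAD on a z-quantile subset."""
    z = pts[:, 2]
    sub = z[z <= np.quantile(z, 0.3)]
    med = np.median(sub)
    lower = med - sub[sub <= med]
    return float(1.4826 * np.median(lower))


def measure_cloud(cloud: SpecimenCloud, method: str = "robust") -> GrossMeasurements:
    """L/W/H in cm as the maximal y/x/z extents of the oriented cloud.

    ``method='robust'`` (default) locates each bounding face as the median
    coordinate of the points within a 6-sigma window of the extreme (sigma
    estimated from the flat bottom face), so the extent does not inflate
    with point count under measurement noise — the raw max grows like
    sigma * sqrt(2 log n).  ``method='max'`` is the literal peak-to-peak
    range.
    """
    if not cloud.oriented:
        raise ValueError("orient the cloud before measuring")
    pts = cloud.points
    if cloud.colors is not None:
        # the suture thread is not tissue (it is removed before grossing)
        sut = _suture_mask(cloud.colors)
        if sut.any() and (~sut).sum() >= 100:
            pts = pts[~sut]
    if method == "max":
        ext = np.ptp(pts, axis=0) * cloud.scale
    elif method == "robust":
        sig = _noise_scale(pts) + 1e-12

        def face(v, sign):
            # seed inside the face atom, then iterate a re-centered median
            # window: converges onto the atom, shedding both the
            # extreme-tail (+) and interior-contamination (-) biases
            extreme = v.max() if sign > 0 else v.min()
            p = np.median(v[sign * (v - extreme) > -8.0 * sig])
            for _ in range(3):
                sel = np.abs(v - p) <= 2.5 * sig
                if sel.sum() >= 5:
                    p = np.median(v[sel])
            return p

        ext = np.empty(3)
        for ax in range(3):
            v = pts[:, ax]
            ext[ax] = face(v, +1) - face(v, -1)
        ext *= cloud.scale
    else:
        raise ValueError(f"unknown measurement method {method!r}")
    return GrossMeasurements(L=float(ext[1]), W=float(ext[0]), H=float(ext[2]))


# ---------------------------------------------------------------------------
# grossing recommendations


BREADLOAF_RIGHT_COLORS = ("red", "yellow", "green", "purple", "orange")


def grossing_plan(cloud: SpecimenCloud, mode: str = "mohs",
                  spacing_cm: float = 1.0, slide_fit_cm: float = 2.0) -> GrossingPlan:
    """Grossing and inking recommendation lines over the oriented cloud.

    Mohs: one blue->red 12-to-6 line; when the specimen is too long for a
    slide (L > ``slide_fit_cm``) a black bisection line is added at y = 0
    with a blue-red pair per half, parallel to it.  Breadloaf: side-to-side
    cut lines spaced ``spacing_cm`` symmetric about the centroid; left
    halves blue, right halves cycling red/yellow/green/purple/orange.
    """
    if not cloud.oriented:
        raise ValueError("orient the cloud before planning cuts")
    if mode == "breadloaf" and not 0.5 <= spacing_cm <= 1.0:
        warnings.warn(f"spacing {spacing_cm} cm outside the usual 0.5-1.0 cm range")
    pts = cloud.points * cloud.scale
    (x0, y0, z0), (x1, y1, z1) = pts.min(axis=0), pts.max(axis=0)
    ztop = z1 + 0.05 * (z1 - z0)
    plan = GrossingPlan(mode=mode)
    if mode == "mohs":
        L = y1 - y0
        if L <= slide_fit_cm:
            plan.segments.append(("blue-12", np.array([0.0, y1, ztop]), np.array([0.0, 0.0, ztop])))
            plan.segments.append(("red-6", np.array([0.0, 0.0, ztop]), np.array([0.0, y0, ztop])))
        else:
            plan.segments.append(("black-cut", np.array([x0, 0.0, ztop]), np.array([x1, 0.0, ztop])))
            for lo, hi in ((0.0, y1), (y0, 0.0)):
                mid = 0.5 * (lo + hi)
                plan.segments.append(
                    ("blue-12", np.array([0.0, hi, ztop]), np.array([0.0, mid, ztop]))
                )
                plan.segments.append(
                    ("red-6", np.array([0.0, mid, ztop]), np.array([0.0, lo, ztop]))
                )
    elif mode == "breadloaf":
        half = (y1 - y0) / 2.0
        n_side = int(np.floor(half / spacing_cm))
        ys = [i * spacing_cm for i in range(-n_side, n_side + 1)]
        right = 0
        for y in ys:
            plan.segments.append(("blue", np.array([x0, y, ztop]), np.array([0.0, y, ztop])))
            color = BREADLOAF_RIGHT_COLORS[right % len(BREADLOAF_RIGHT_COLORS)]
            plan.segments.append((color, np.array([0.0, y, ztop]), np.array([x1, y, ztop])))
            right += 1
    else:
        raise ValueError(f"unknown grossing mode {mode!r}")
    return plan


# ---------------------------------------------------------------------------
# surface refinement


def refine_surface(cloud: SpecimenCloud, grid_step: float, radius: float | None = None):
    """Resample the upper surface on a regular x-y grid.

    z and RGB are predicted by radius-neighbor averaging (uniform weights)
    from the input points; grid cells with no neighbor in radius are
    omitted.  Returns a new SpecimenCloud on the grid.
    """
    if not cloud.oriented:
        raise ValueError("orient the cloud before refining")
    pts = cloud.points
    radius = 2.0 * grid_step if radius is None else radius
    xs = np.arange(pts[:, 0].min(), pts[:, 0].max() + grid_step / 2, grid_step)
    ys = np.arange(pts[:, 1].min(), pts[:, 1].max() + grid_step / 2, grid_step)
    gx, gy = np.meshgrid(xs, ys)
    grid = np.column_stack([gx.ravel(), gy.ravel()])
    targets = pts[:, 2:3]
    if cloud.colors is not None:
        targets = np.column_stack([targets, cloud.colors.astype(float)])
    reg = RadiusNeighborsRegressor(radius=radius, weights="uniform").fit(pts[:, :2], targets)
    nn = NearestNeighbors(radius=radius).fit(pts[:, :2])
    counts = np.array([len(i) for i in nn.radius_neighbors(grid, return_distance=False)])
    keep = counts > 0
    pred = reg.predict(grid[keep])
    new_pts = np.column_stack([grid[keep], pred[:, 0]])
    new_cols = None
    if cloud.colors is not None:
        new_cols = np.clip(np.round(pred[:, 1:]), 0, 255).astype(np.uint8)
    return SpecimenCloud(new_pts, new_cols, cloud.scale, True, cloud.suture_direction)


# ---------------------------------------------------------------------------
# file IO (ASCII PLY via trimesh; XYZ[RGB] whitespace tables)


def save_cloud(cloud: SpecimenCloud, path) -> None:
    import trimesh

    pc = trimesh.PointCloud(cloud.points, colors=cloud.colors)
    pc.export(str(path), file_type="ply", encoding="ascii")


def load_cloud(path, scale: float = 1.0) -> SpecimenCloud:
    path = str(path)
    if path.endswith((".xyz", ".txt")):
        arr = np.loadtxt(path)
        colors = arr[:, 3:6].astype(np.uint8) if arr.shape[1] >= 6 else None
        return SpecimenCloud(arr[:, :3], colors, scale)
    import trimesh

    pc = trimesh.load(path)
    colors = None
    if getattr(pc, "colors", None) is not None and len(pc.colors):
        colors = np.asarray(pc.colors)[:, :3].astype(np.uint8)
    return SpecimenCloud(np.asarray(pc.vertices, dtype=float), colors, scale)
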