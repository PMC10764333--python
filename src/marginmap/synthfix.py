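"""Seeded synthetic fixtures with machine-readable ground truth.

Real Mohs whole-slide images and grossing videos are not publicly
distributable, so every pipeline stage is exercised on synthetic inputs
that emulate their geometry: multi-piece tissue sections with colored
edge inks at known clock positions, interior holes and edge tears,
texture-distinct tumor regions, follicle disks, boxlike specimen point
clouds with a marked suture, and turntable video frames.  Each generator
is a pure function of its spec + seed and returns the input *plus* the
ground truth needed to score downstream operations without re-deriving
anything from pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial.transform import Rotation
from shapely.geometry import Point, Polygon, box
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon

from .inkorient import clock_angle, rotate_points

__all__ = [
    "InvalidSpecError",
    "PieceSpec",
    "SectionDef",
    "SectionSpec",
    "SectionGroundTruth",
    "CloudSpec",
    "SyntheticGraph",
    "make_section_image",
    "random_section_spec",
    "make_cloud",
    "make_patch_dataset",
    "make_template",
    "make_turntable_frames",
]


class InvalidSpecError(ValueError):
    """Fixture spec violates its invariants."""


INK_RGB = {
    "blue": (45, 65, 205),
    "red": (205, 30, 40),
    "yellow": (230, 210, 40),
    "green": (40, 170, 60),
    "orange": (235, 140, 30),
    "purple": (150, 50, 190),
    "black": (15, 15, 15),
}

TISSUE_RGB = (218, 182, 196)  # eosin-ish base
TUMOR_RGB = (172, 132, 160)  # darker basaloid nests
FOLLICLE_RGB = (150, 120, 105)


# ---------------------------------------------------------------------------
# specs


@dataclass
class PieceSpec:
    polygon: np.ndarray  # (n, 2) x,y vertices, px
    conjoined: bool = False


@dataclass
class SectionDef:
    pieces: list[PieceSpec]
    inks: list[tuple[str, float, float]] = field(default_factory=list)  # (color, clock deg, span deg)
    holes: list[np.ndarray] = field(default_factory=list)
    tears: list[np.ndarray] = field(default_factory=list)
    tumors: list[np.ndarray] = field(default_factory=list)
    follicles: list[tuple[float, float, float]] = field(default_factory=list)  # (cx, cy, r)


@dataclass
class SectionSpec:
    canvas: tuple[int, int]  # (width, height) px
    sections: list[SectionDef]
    background: int = 245
    noise: float = 4.0
    seed: int = 0


@dataclass
class SectionGroundTruth:
    """Everything needed to score slideprep/inkorient/patchnet on a fixture."""

    canvas: tuple[int, int]
    piece_polygons: list[list[Polygon]]  # [section][piece], holes/tears already cut
    outline_polygons: list[list[Polygon]]  # [section][piece], solid outlines
    hole_polygons: list[list[Polygon]]
    tear_polygons: list[list[Polygon]]
    tumor_polygons: list[list[Polygon]]
    follicles: list[list[tuple[float, float, float]]]
    ink_centroids: list[dict[str, tuple[float, float]]]
    orientation_theta: list[float | None]

    def tissue_union(self):
        from shapely.ops import unary_union

        return unary_union([p for sec in self.piece_polygons for p in sec])

    def patch_labels(self, patch_size: int = 256, min_tissue_frac: float = 0.5):
        """Ground-truth patch grid: one record per grid cell with tissue
        fraction >= ``min_tissue_frac`` plus hole/tear cells inside outlines.

        Returns a dict of parallel numpy arrays (x, y, tissue_frac, section,
        piece, tumor, hole).  Section/piece assignment is by largest polygon
        overlap (conjoined lobes resolved the same way).
        """
        import pandas as pd

        w, h = self.canvas
        area = float(patch_size * patch_size)
        recs = []
        for y0 in range(0, h - patch_size + 1, patch_size):
            for x0 in range(0, w - patch_size + 1, patch_size):
                cell = box(x0, y0, x0 + patch_size, y0 + patch_size)
                best, best_ov, tissue = None, 0.0, 0.0
                outline_best, outline_ov = None, 0.0
                for si, sec in enumerate(self.piece_polygons):
                    for pi, poly in enumerate(sec):
                        ov = cell.intersection(poly).area
                        if ov > best_ov:
                            best, best_ov = (si, pi), ov
                        tissue += ov
                for si, sec in enumerate(self.outline_polygons):
                    for pi, poly in enumerate(sec):
                        ov = cell.intersection(poly).area
                        if ov > outline_ov:
                            outline_best, outline_ov = (si, pi), ov
                frac = tissue / area
                is_tissue = frac >= min_tissue_frac
                in_outline = outline_ov / area >= min_tissue_frac
                if not (is_tissue or in_outline):
                    continue
                si, pi = best if best is not None else outline_best
                tumor = any(
                    cell.intersection(t).area / area >= 0.25
                    for t in self.tumor_polygons[si]
                )
                recs.append(
                    dict(x=x0, y=y0, tissue_frac=frac, section=si, piece=pi,
                         tumor=bool(tumor and is_tissue), hole=bool(in_outline and not is_tissue))
                )
        return pd.DataFrame.from_records(
            recs, columns=["x", "y", "tissue_frac", "section", "piece", "tumor", "hole"]
        )


# ---------------------------------------------------------------------------
# geometry helpers


def blob_polygon(center, radius, rng, wobble=0.12, n_vertices=72) -> np.ndarray:
    """Blobby closed polygon: circle with smooth low-harmonic radial wobble."""
    phi = np.linspace(0.0, 2 * np.pi, n_vertices, endpoint=False)
    r = np.ones_like(phi)
    for k in (2, 3, 5):
        r += wobble / k * rng.standard_normal() * np.cos(k * phi + rng.uniform(0, 2 * np.pi))
    r = np.clip(r, 0.5, 1.5) * radius
    return np.column_stack([center[0] + r * np.sin(phi), center[1] - r * np.cos(phi)])


def wedge_polygon(piece_poly: np.ndarray, clock_deg: float, depth_frac=0.6, width_deg=35.0):
    """Tear: wedge from the boundary toward the centroid at a clock position."""
    ctr = piece_poly.mean(axis=0)
    poly = Polygon(piece_poly)
    pts = []
    for a in np.linspace(clock_deg - width_deg / 2, clock_deg + width_deg / 2, 9):
        d = np.array([np.sin(np.radians(a)), -np.cos(np.radians(a))])
        lo, hi = 0.0, 2.5 * np.ptp(piece_poly, axis=0).max()
        for _ in range(40):  # bisection for the boundary crossing
            mid = 0.5 * (lo + hi)
            if poly.contains(Point(ctr + d * mid)):
                lo = mid
            else:
                hi = mid
        pts.append(ctr + d * (lo + 4.0))  # overshoot past the rim
    tip = ctr + (np.mean(pts, axis=0) - ctr) * (1 - depth_frac)
    return np.array(pts + [tip])


def _cut_holes(outline: Polygon, cutters: list[Polygon]) -> Polygon:
    poly = outline
    for c in cutters:
        poly = poly.difference(c)
    return poly


# ---------------------------------------------------------------------------
# section raster generator


def _fill_polygon(img, poly_xy, rgb, shape):
    rr, cc = draw_polygon(poly_xy[:, 1], poly_xy[:, 0], shape=shape)
    img[rr, cc] = rgb
    return rr, cc


def _texture(rng, shape, amp, sigma):
    return gaussian_filter(rng.standard_normal(shape), sigma) * amp


def make_section_image(spec: SectionSpec):
    """Render a section fixture and return ``(uint8 RGB raster, SectionGroundTruth)``.

    Tissue pieces are textured blobs on a near-white background; tumor
    regions carry higher-frequency, darker speckle so a small patch
    classifier can separate the classes; holes/tears are rendered as
    background; ink arcs are saturated bands straddling the outer boundary.
    """
    w, h = spec.canvas
    rng = np.random.default_rng(spec.seed)

    # validate: non-conjoined pieces must be disjoint
    polys = [
        (si, pi, Polygon(p.polygon))
        for si, sec in enumerate(spec.sections)
        for pi, p in enumerate(sec.pieces)
    ]
    for i in range(len(polys)):
        for j in range(i + 1, len(polys)):
            si, pi, a = polys[i]
            sj, pj, b = polys[j]
            conj_i = spec.sections[si].pieces[pi].conjoined
            conj_j = spec.sections[sj].pieces[pj].conjoined
            if a.intersection(b).area > 1.0 and not (conj_i and conj_j):
                raise InvalidSpecError(
                    f"pieces ({si},{pi}) and ({sj},{pj}) overlap but are not conjoined"
                )
    for si, pi, p in polys:
        minx, miny, maxx, maxy = p.bounds
        if minx < 0 or miny < 0 or maxx > w or maxy > h:
            raise InvalidSpecError(f"piece ({si},{pi}) outside canvas")

    img = np.empty((h, w, 3), dtype=float)
    img[...] = spec.background
    img += _texture(rng, (h, w), spec.noise, 2.0)[..., None]

    gt_pieces, gt_outlines, gt_holes, gt_tears, gt_tumors = [], [], [], [], []
    gt_foll, gt_ink, gt_theta = [], [], []

    for sec in spec.sections:
        sec_pieces, sec_outlines = [], []
        # tissue base + texture
        for piece in sec.pieces:
            rr, cc = draw_polygon(piece.polygon[:, 1], piece.polygon[:, 0], shape=(h, w))
            base = np.array(TISSUE_RGB, dtype=float)
            tex = _texture(rng, (h, w), 10.0, 3.0)
            speck = (rng.random((h, w)) < 0.04).astype(float) * -35.0
            for ch in range(3):
                img[rr, cc, ch] = base[ch] + tex[rr, cc] + speck[rr, cc]
            sec_outlines.append(Polygon(piece.polygon))
        # tumor: darker, high-frequency speckle
        for tpoly in sec.tumors:
            rr, cc = draw_polygon(tpoly[:, 1], tpoly[:, 0], shape=(h, w))
            base = np.array(TUMOR_RGB, dtype=float)
            fine = _texture(rng, (h, w), 18.0, 0.8)
            speck = (rng.random((h, w)) < 0.25).astype(float) * -30.0
            for ch in range(3):
                img[rr, cc, ch] = base[ch] + fine[rr, cc] + speck[rr, cc]
        for cx, cy, r in sec.follicles:
            rr, cc = draw_disk((cy, cx), r, shape=(h, w))
            img[rr, cc] = FOLLICLE_RGB
        # holes and tears render as background
        for cut in list(sec.holes) + list(sec.tears):
            rr, cc = draw_polygon(cut[:, 1], cut[:, 0], shape=(h, w))
            img[rr, cc] = spec.background
            img[rr, cc] += _texture(rng, (h, w), spec.noise, 2.0)[rr, cc, None]

        # edge inks on the outer boundary
        ink_cents: dict[str, tuple[float, float]] = {}
        for color, clock_deg, span_deg in sec.inks:
            pts = []
            for piece in sec.pieces:
                poly = Polygon(piece.polygon)
                ctr = np.array(poly.centroid.coords[0])
                ext = np.asarray(poly.exterior.coords)
                ang = np.array([clock_angle(p - ctr) for p in ext[:-1]])
                diff = (ang - clock_deg + 180.0) % 360.0 - 180.0
                sel = ext[:-1][np.abs(diff) <= span_deg / 2]
                pts.extend(sel)
            if not pts:
                continue
            pts = np.asarray(pts)
            # densify along the arc then paint disks of ink
            thick = int(rng.integers(8, 17))
            for p in pts:
                rr, cc = draw_disk((p[1], p[0]), thick / 2, shape=(h, w))
                img[rr, cc] = INK_RGB[color]
            ink_cents[color] = (float(pts[:, 0].mean()), float(pts[:, 1].mean()))
        gt_ink.append(ink_cents)
        theta = None
        if "blue" in ink_cents and "red" in ink_cents:
            b = np.array(ink_cents["blue"])
            r = np.array(ink_cents["red"])
            if not np.allclose(b, r):
                theta = clock_angle(r - b)
        gt_theta.append(theta)

        cutters = [Polygon(c) for c in list(sec.holes) + list(sec.tears)]
        for outline in sec_outlines:
            sec_pieces.append(_cut_holes(outline, cutters))
        gt_pieces.append(sec_pieces)
        gt_outlines.append(sec_outlines)
        gt_holes.append([Polygon(c) for c in sec.holes])
        gt_tears.append([Polygon(c) for c in sec.tears])
        gt_tumors.append([Polygon(c) for c in sec.tumors])
        gt_foll.append(list(sec.follicles))

    gt = SectionGroundTruth(
        canvas=spec.canvas,
        piece_polygons=gt_pieces,
        outline_polygons=gt_outlines,
        hole_polygons=gt_holes,
        tear_polygons=gt_tears,
        tumor_polygons=gt_tumors,
        follicles=gt_foll,
        ink_centroids=gt_ink,
        orientation_theta=gt_theta,
    )
    return np.clip(img, 0, 255).astype(np.uint8), gt


def random_section_spec(
    seed: int,
    canvas=(1024, 1024),
    n_sections: int = 1,
    pieces_per_section=(1,),
    piece_radius: float = 170.0,
    ink: bool = True,
    rotation: float | None = None,
    tumor: bool = False,
    hole: bool = False,
    tear: bool = False,
    conjoined: bool = False,
    patch_size: int = 64,
) -> SectionSpec:
    """Seeded random layout used across the test-suite and acceptance runs.

    Sections are stacked vertically with generous separation; pieces within
    a section sit side by side.  ``rotation`` (degrees, clock convention)
    rotates each section's geometry and its ink placement together, giving
    fixtures with exactly known orientation.  ``conjoined=True`` replaces
    the first section's pieces with two overlapping lobes.
    """
    rng = np.random.default_rng(seed)
    w, h = canvas
    rot = rng.uniform(0, 360) if rotation is None else rotation
    sections = []
    for si in range(n_sections):
        cy = h * (si + 0.5) / n_sections
        n_pieces = pieces_per_section[si % len(pieces_per_section)]
        pieces = []
        if conjoined and si == 0:
            c0 = np.array([w / 2 - 0.75 * piece_radius, cy])
            c1 = np.array([w / 2 + 0.75 * piece_radius, cy])
            for c in (c0, c1):
                poly = blob_polygon(c, piece_radius, rng, wobble=0.08)
                pieces.append(PieceSpec(rotate_points(poly, rot, (w / 2, cy)), conjoined=True))
        else:
            span = min(w / (n_pieces + 0.3), 3.2 * piece_radius)
            for pi in range(n_pieces):
                cx = w / 2 + (pi - (n_pieces - 1) / 2) * span
                poly = blob_polygon((cx, cy), piece_radius, rng, wobble=0.1)
                pieces.append(PieceSpec(rotate_points(poly, rot, (w / 2, cy))))
        sec = SectionDef(pieces=pieces)
        if ink:
            sec.inks = [("blue", (0.0 + rot) % 360, 40.0), ("red", (180.0 + rot) % 360, 40.0)]
        if tumor:
            ctr = Polygon(pieces[0].polygon).centroid
            off = rotate_points(np.array([[0.0, -0.45 * piece_radius]]), rot)[0]
            sec.tumors = [blob_polygon((ctr.x + off[0], ctr.y + off[1]),
                                       0.38 * piece_radius, rng, wobble=0.08)]
        if hole:
            ctr = Polygon(pieces[0].polygon).centroid
            sec.holes = [blob_polygon((ctr.x, ctr.y), 0.35 * piece_radius, rng, wobble=0.05)]
        if tear:
            sec.tears = [wedge_polygon(pieces[-1].polygon, (90.0 + rot) % 360,
                                       depth_frac=0.55, width_deg=40.0)]
        sections.append(sec)
    return SectionSpec(canvas=canvas, sections=sections, seed=seed)


# ---------------------------------------------------------------------------
# specimen point clouds


@dataclass
class CloudSpec:
    """Boxlike gross specimen sampled as a noisy surface point cloud."""

    extents_cm: tuple[float, float, float] = (1.5, 2.0, 0.6)  # x, y, z
    rot_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    rot_deg: float = 0.0
    translation: tuple[float, float, float] = (0.0, 0.0, 0.0)
    n_points: int = 4000
    noise_sd: float = 0.02  # cm
    suture_clock_deg: float | None = 0.0  # position on top rim; None = no suture
    suture_rgb: tuple[int, int, int] = (25, 30, 90)  # dark navy
    scale: float = 1.0  # cm per model unit
    seed: int = 0

    def validate(self):
        if self.n_points < 100:
            raise InvalidSpecError("point count must be >= 100")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise sd must be >= 0")
        if min(self.extents_cm) <= 0:
            raise InvalidSpecError("extents must be > 0")


@dataclass
class CloudGroundTruth:
    extents_cm: tuple[float, float, float]
    bottom_normal: np.ndarray  # unit vector after the rigid transform
    suture_direction: np.ndarray | None  # unit vector after transform
    rotation: Rotation
    translation: np.ndarray


def make_cloud(spec: CloudSpec):
    """Sample a box surface (dense flat bottom), add noise, apply a rigid
    transform.  Returns ``(points (n,3), colors uint8 (n,3), CloudGroundTruth)``.

    Coordinates are in model units (= cm / ``spec.scale``).  Suture marker
    points are colored ``suture_rgb`` at the given clock position on the top
    rim (+y = 12 o'clock before the transform).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ex, ey, ez = (np.asarray(spec.extents_cm) / spec.scale)
    n = spec.n_points
    # allocate: 40% bottom face, 15% top, 45% sides
    n_bot = int(0.4 * n)
    n_top = int(0.15 * n)
    n_side = n - n_bot - n_top
    pts = []
    u = rng.uniform(-0.5, 0.5, (n_bot, 2))
    pts.append(np.column_stack([u[:, 0] * ex, u[:, 1] * ey, np.full(n_bot, -ez / 2)]))
    u = rng.uniform(-0.5, 0.5, (n_top, 2))
    pts.append(np.column_stack([u[:, 0] * ex, u[:, 1] * ey, np.full(n_top, ez / 2)]))
    face = rng.integers(0, 4, n_side)
    u = rng.uniform(-0.5, 0.5, (n_side, 2))
    side = np.empty((n_side, 3))
    side[:, 2] = u[:, 1] * ez
    for f, (sx, sy) in enumerate([(0.5, None), (-0.5, None), (None, 0.5), (None, -0.5)]):
        m = face == f
        if sx is not None:
            side[m, 0] = sx * ex
            side[m, 1] = u[m, 0] * ey
        else:
            side[m, 0] = u[m, 0] * ex
            side[m, 1] = sy * ey
    pts.append(side)
    points = np.concatenate(pts, axis=0)
    points += rng.normal(0.0, spec.noise_sd / spec.scale, points.shape)

    colors = np.full((len(points), 3), (205, 170, 150), dtype=int)
    colors = np.clip(colors + rng.integers(-12, 13, colors.shape), 0, 255).astype(np.uint8)

    suture_dir0 = None
    if spec.suture_clock_deg is not None:
        a = np.radians(spec.suture_clock_deg)
        d = np.array([np.sin(a), np.cos(a), 0.0])  # +y is 12 o'clock
        anchor = np.array([d[0] * ex / 2, d[1] * ey / 2, ez / 2])
        n_sut = max(20, n // 100)
        sut = anchor + rng.normal(0, 0.03 * min(ex, ey), (n_sut, 3))
        points = np.concatenate([points, sut], axis=0)
        colors = np.concatenate(
            [colors, np.tile(np.array(spec.suture_rgb, dtype=np.uint8), (n_sut, 1))]
        )
        suture_dir0 = d

    rot = Rotation.from_rotvec(
        np.radians(spec.rot_deg) * np.asarray(spec.rot_axis, dtype=float)
        / max(np.linalg.norm(spec.rot_axis), 1e-12)
    )
    t = np.asarray(spec.translation, dtype=float)
    points = rot.apply(points) + t

    gt = CloudGroundTruth(
        extents_cm=tuple(spec.extents_cm),
        bottom_normal=rot.apply([0.0, 0.0, -1.0]),
        suture_direction=rot.apply(suture_dir0) if suture_dir0 is not None else None,
        rotation=rot,
        translation=t,
    )
    return points, colors, gt


# ---------------------------------------------------------------------------
# spatially-labelled node datasets (GNN benchmark)


@dataclass
class SyntheticGraph:
    coords: np.ndarray  # (n, 2)
    features: np.ndarray  # (n, d)
    labels: np.ndarray  # (n,) int
    latent: np.ndarray  # (n,)
    radius: float


def make_patch_dataset(
    n_slides: int,
    nodes_per_slide: int,
    feature_dim: int = 8,
    spatial_signal: float = 1.0,
    seed: int = 0,
    noise_sd: float = 0.2,
) -> list[SyntheticGraph]:
    """Node-classification benchmark where graph context is informative.

    Nodes sit on a jittered grid; a latent scalar ``z ~ N(0,1)`` per node is
    embedded into ``feature_dim`` dims (plus Gaussian noise).  The label
    thresholds ``(1-g) z_i + g mean_{j in N(i) U {i}} z_j`` at zero (closed
    neighborhood), with ``g = spatial_signal``: at g=0 labels carry no
    information about neighbor features; at g=1 they average the whole
    neighborhood, so a model that aggregates neighbors beats any node-only
    model.
    """
    if not 0.0 <= spatial_signal <= 1.0:
        raise InvalidSpecError("spatial_signal must lie in [0, 1]")
    from sklearn.neighbors import radius_neighbors_graph

    rng = np.random.default_rng(seed)
    side = int(np.ceil(np.sqrt(nodes_per_slide)))
    proj = rng.standard_normal(feature_dim)
    proj /= np.linalg.norm(proj)
    radius = 1.5
    graphs = []
    for _ in range(n_slides):
        gx, gy = np.meshgrid(np.arange(side), np.arange(side))
        coords = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)[:nodes_per_slide]
        coords += rng.uniform(-0.15, 0.15, coords.shape)
        z = rng.standard_normal(len(coords))
        adj = radius_neighbors_graph(coords, radius, mode="connectivity")
        deg = np.asarray(adj.sum(axis=1)).ravel()
        nbr_mean = (adj @ z + z) / (deg + 1.0)
        s = (1 - spatial_signal) * z + spatial_signal * nbr_mean
        labels = (s > 0).astype(int)
        feats = z[:, None] * proj[None, :] + noise_sd * rng.standard_normal(
            (len(coords), feature_dim)
        )
        graphs.append(SyntheticGraph(coords, feats, labels, z, radius))
    return graphs


# ---------------------------------------------------------------------------
# surgical map templates


def make_template(anatomy_name, ellipse, blue_mark, red_mark, canvas=(512, 512),
                  tol_frac=0.05):
    """Surgical-map template: black ellipse (removal site) + blue/red marks.

    ``ellipse`` is (cx, cy, a, b, rot_deg) with a/b the semi-axes along the
    ellipse's own x/y before clock rotation.  Marks must lie on the ellipse
    boundary within ``tol_frac`` of the minor axis.  Returns
    ``(uint8 raster, MapTemplate)``.
    """
    from .sitemap import MapTemplate

    cx, cy, a, b, rot = (float(v) for v in ellipse)
    if a <= 0 or b <= 0:
        raise InvalidSpecError("degenerate ellipse axis")
    tol = tol_frac * 2 * min(a, b)

    def on_boundary(m):
        p = rotate_points(np.asarray(m, dtype=float)[None, :] - (cx, cy), -rot)[0]
        r = np.hypot(p[0] / a, p[1] / b)
        return abs(r - 1.0) * min(a, b) <= tol

    for name, m in (("blue", blue_mark), ("red", red_mark)):
        if not on_boundary(m):
            raise InvalidSpecError(f"{name} mark not on the ellipse boundary")

    w, h = canvas
    img = np.full((h, w, 3), 255, dtype=np.uint8)
    phi = np.linspace(0, 2 * np.pi, 720)
    ring = np.column_stack([a * np.cos(phi), b * np.sin(phi)])
    ring = rotate_points(ring, rot) + (cx, cy)
    for p in ring:
        rr, cc = draw_disk((p[1], p[0]), 1.5, shape=(h, w))
        img[rr, cc] = (0, 0, 0)
    for color, m in (("blue", blue_mark), ("red", red_mark)):
        rr, cc = draw_disk((m[1], m[0]), 5, shape=(h, w))
        img[rr, cc] = INK_RGB[color]

    theta = clock_angle(np.asarray(red_mark, dtype=float) - np.asarray(blue_mark, dtype=float))
    meta = MapTemplate(
        name=str(anatomy_name),
        center=(cx, cy),
        axes=(a, b),
        rotation=rot,
        blue_xy=(float(blue_mark[0]), float(blue_mark[1])),
        red_xy=(float(red_mark[0]), float(red_mark[1])),
        theta=theta,
    )
    return img, meta


# ---------------------------------------------------------------------------
# turntable frames


def make_turntable_frames(
    n_frames: int = 24,
    frame_size=(240, 320),
    table_axes=(130.0, 95.0),
    path_axes=(80.0, 55.0),
    blob_r: float = 14.0,
    distractor: bool = False,
    seed: int = 0,
):
    """Video-frame stand-ins for the grossing turntable: a dark specimen blob
    revolving on an elliptical path over a light table whose rim is the
    calibration ellipse.  Returns ``(frames, truth)`` where truth holds the
    per-frame specimen centroids, the path ellipse, and the rim ellipse.
    """
    rng = np.random.default_rng(seed)
    h, w = frame_size
    ctr = (w / 2, h / 2)
    frames, cents = [], []
    for i in range(n_frames):
        img = np.full((h, w, 3), 235, dtype=float)
        rr, cc = _ellipse_fill(ctr, table_axes, (h, w))
        img[rr, cc] = 200
        phi = 2 * np.pi * i / n_frames
        cx = ctr[0] + path_axes[0] * np.cos(phi)
        cy = ctr[1] + path_axes[1] * np.sin(phi)
        rr, cc = draw_disk((cy, cx), blob_r, shape=(h, w))
        img[rr, cc] = (95, 70, 60)
        if distractor:
            rr, cc = draw_disk((25, 25), 9, shape=(h, w))
            img[rr, cc] = (80, 80, 80)
        img += rng.normal(0, 2.0, img.shape)
        frames.append(np.clip(img, 0, 255).astype(np.uint8))
        cents.append((cx, cy))
    truth = {
        "centroids": np.asarray(cents),
        "path": {"center": ctr, "axes": path_axes},
        "rim": {"center": ctr, "axes": table_axes},
    }
    return frames, truth


def _ellipse_fill(center, axes, shape):
    from skimage.draw import ellipse as draw_ellipse

    return draw_ellipse(center[1], center[0], axes[1], axes[0], shape=shape)
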