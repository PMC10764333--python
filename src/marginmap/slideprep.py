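"""Whole-slide preprocessing: tissue mask, patch grid, section/piece
assignment, and alpha-shape hole candidates.

Slides are partitioned into non-overlapping square patches (default 256 px,
addressed by top-left corner, origin top-left, y down).  Tissue-bearing
patches form the ``tumor_map`` configuration; adding grid cells that fall
inside a piece's alpha shape but carry no tissue (interior holes, edge
tears bridged by the concave outline) yields the ``macro_map``
configuration used for tissue-completeness assessment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay
from shapely.geometry import Point, Polygon
from shapely.ops import unary_union
from skimage import color as skcolor
from skimage import measure, morphology
from scipy.ndimage import gaussian_filter
from sklearn.cluster import SpectralClustering
from sklearn.neighbors import radius_neighbors_graph

__all__ = [
    "MaskParams",
    "TissueMask",
    "PatchSet",
    "compute_tissue_mask",
    "extract_patches",
    "assign_sections_pieces",
    "hole_candidates",
    "alpha_shape",
]

#: reference radii assume 256-px patches; both scale linearly with patch size
SECTION_RADIUS_256 = 4096.0
PIECE_RADIUS_256 = 512.0


class SectionCountError(RuntimeError):
    """More sections observed than expected."""


@dataclass
class MaskParams:
    """Tissue-mask filter thresholds (all in mask-resolution pixels)."""

    white_cutoff: float = 235.0  # mean-RGB above this is background
    gray_saturation: float = 0.08  # low-saturation objects are scanner text/pen
    gray_min_area: int = 10_000
    blur_sigma: float = 2.0
    closing_radius: int = 3
    min_object_px: int = 64
    min_hole_px: int = 64


@dataclass
class TissueMask:
    mask: np.ndarray  # bool, aligned to slide pixels
    slide_id: str = "slide"
    downsample: int = 1

    @property
    def fraction(self) -> float:
        return float(self.mask.mean())


@dataclass
class PatchSet:
    """Patch records of one slide as a DataFrame.

    Columns: x, y (top-left, level-0 px), tissue_frac, section, piece,
    config ('tumor_map' | 'macro_map'), hole_candidate (bool).  Section and
    piece ids are dense integers from 0 (or -1 before assignment).
    """

    slide_id: str
    patch_size: int
    records: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def coords(self) -> np.ndarray:
        return self.records[["x", "y"]].to_numpy(dtype=float)

    @property
    def centers(self) -> np.ndarray:
        return self.coords + self.patch_size / 2.0

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, mask) -> "PatchSet":
        return replace(self, records=self.records.loc[mask].reset_index(drop=True))

    def to_json(self, path) -> None:
        out = {
            "slide_id": self.slide_id,
            "patch_size": int(self.patch_size),
            "records": self.records.to_dict(orient="list"),
        }
        import json

        with open(path, "w") as fh:
            json.dump(out, fh)

    @classmethod
    def from_json(cls, path) -> "PatchSet":
        import json

        with open(path) as fh:
            d = json.load(fh)
        return cls(d["slide_id"], d["patch_size"], pd.DataFrame(d["records"]))


# ---------------------------------------------------------------------------
# tissue mask


def compute_tissue_mask(raster, params: MaskParams | None = None,
                        slide_id: str = "slide") -> TissueMask:
    """Binary tissue mask from an RGB raster.

    Pipeline: (1) intensity threshold removing near-white background;
    (2) removal of large gray low-saturation objects (scanner text, pen);
    (3) binary closing + Gaussian blur + re-threshold to smooth;
    (4) small-object and small-hole removal.
    """
    params = params or MaskParams()
    img = np.asarray(raster)
    if img.size == 0:
        raise ValueError("empty raster")
    imgf = img.astype(float) if img.dtype == np.uint8 else img * 255.0
    mask = imgf.mean(axis=-1) <= params.white_cutoff
    if not mask.any():
        return TissueMask(mask, slide_id)

    sat = skcolor.rgb2hsv(imgf / 255.0)[..., 1]
    lbl = measure.label(mask, connectivity=2)
    for region in measure.regionprops(lbl):
        if region.area > params.gray_min_area:
            sel = lbl == region.label
            if sat[sel].mean() < params.gray_saturation:
                mask[sel] = False

    mask = morphology.closing(mask, morphology.disk(params.closing_radius))
    mask = gaussian_filter(mask.astype(float), params.blur_sigma) > 0.5
    mask = morphology.remove_small_objects(mask, max_size=params.min_object_px)
    mask = morphology.remove_small_holes(mask, max_size=params.min_hole_px)
    return TissueMask(mask, slide_id)


# ---------------------------------------------------------------------------
# patch extraction


def extract_patches(tissue_mask: TissueMask, patch_size: int = 256,
                    min_tissue_frac: float = 0.5) -> PatchSet:
    """Non-overlapping grid patches with tissue fraction >= ``min_tissue_frac``
    (the ``tumor_map`` configuration)."""
    mask = tissue_mask.mask
    h, w = mask.shape
    if patch_size > min(h, w):
        raise ValueError(f"patch_size {patch_size} exceeds raster {w}x{h}")
    ny, nx = h // patch_size, w // patch_size
    block = (
        mask[: ny * patch_size, : nx * patch_size]
        .reshape(ny, patch_size, nx, patch_size)
        .mean(axis=(1, 3))
    )
    ys, xs = np.nonzero(block >= min_tissue_frac)
    recs = pd.DataFrame(
        {
            "x": xs * patch_size,
            "y": ys * patch_size,
            "tissue_frac": block[ys, xs],
            "section": -1,
            "piece": -1,
            "config": "tumor_map",
            "hole_candidate": False,
        }
    )
    return PatchSet(tissue_mask.slide_id, patch_size, recs)


# ---------------------------------------------------------------------------
# section / piece assignment


def _components(centers: np.ndarray, radius: float) -> np.ndarray:
    if len(centers) == 1:
        return np.zeros(1, dtype=int)
    adj = radius_neighbors_graph(centers, radius, mode="connectivity")
    _, lab = connected_components(adj, directed=False)
    return lab


def _dense_sorted(labels: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Relabel components densely, ordered by centroid (y, then x) so ids are
    invariant to patch enumeration order."""
    out = np.empty_like(labels)
    cents = []
    for lb in np.unique(labels):
        m = labels == lb
        cents.append((centers[m, 1].mean(), centers[m, 0].mean(), lb))
    for new, (_, _, lb) in enumerate(sorted(cents)):
        out[labels == lb] = new
    return out


def assign_sections_pieces(
    patchset: PatchSet,
    n_sections: int,
    pieces_per_section,
    r_section: float | None = None,
    r_piece: float | None = None,
    seed: int = 0,
    max_iter: int = 5,
) -> PatchSet:
    """Label every patch with its serial section and tissue piece.

    Sections are connected components of the patch-center radius graph at a
    large radius (default 4096 px scaled by patch size); candidate pieces
    are components at a small radius (default 512 px scaled).  A section
    with fewer pieces than expected has its largest piece split by spectral
    clustering on patch coordinates into ``deficit + 1`` parts, iterating
    until the expectation is met.

    Raises ``SectionCountError`` if more sections are found than expected,
    and ``RuntimeError`` if the piece expectation is unreachable.
    """
    if len(patchset) == 0:
        raise ValueError("empty patch set")
    ps = patchset.patch_size
    r_section = SECTION_RADIUS_256 * ps / 256.0 if r_section is None else r_section
    r_piece = PIECE_RADIUS_256 * ps / 256.0 if r_piece is None else r_piece
    centers = patchset.centers

    sec = _components(centers, r_section)
    n_found = sec.max() + 1
    if n_found > n_sections:
        raise SectionCountError(
            f"found {n_found} sections but expected {n_sections}"
        )
    sec = _dense_sorted(sec, centers)

    piece = np.full(len(centers), -1, dtype=int)
    if np.isscalar(pieces_per_section):
        pieces_per_section = [int(pieces_per_section)] * n_found
    for si in range(n_found):
        m = sec == si
        expected = int(pieces_per_section[si]) if si < len(pieces_per_section) else 1
        sub = centers[m]
        lab = _components(sub, r_piece)
        for it in range(max_iter + 1):
            n_pieces = lab.max() + 1
            if n_pieces >= expected:
                break
            if it == max_iter:
                raise RuntimeError(
                    f"section {si}: cannot reach {expected} pieces "
                    f"(have {n_pieces}) after {max_iter} splits"
                )
            sizes = np.bincount(lab)
            big = int(np.argmax(sizes))
            deficit = expected - n_pieces
            sel = lab == big
            k = deficit + 1
            sc = SpectralClustering(
                n_clusters=k,
                affinity="rbf",
                gamma=1.0 / (2.0 * r_piece**2),
                random_state=seed,
                assign_labels="kmeans",
                n_init=10,
            )
            sub_lab = sc.fit_predict(sub[sel])
            new = lab.copy()
            new[sel] = np.where(sub_lab == 0, big, lab.max() + sub_lab)
            lab = new
        piece[m] = _dense_sorted(lab, sub)

    recs = patchset.records.copy()
    recs["section"] = sec
    recs["piece"] = piece
    return replace(patchset, records=recs)


# ---------------------------------------------------------------------------
# alpha shape + hole candidates


def alpha_shape(points: np.ndarray, alpha: float) -> Polygon:
    """Alpha shape of 2-D points: union of Delaunay triangles whose
    circumradius is below ``1/alpha``.  Falls back to the convex hull (with
    a warning) when the union is degenerate."""
    pts = np.asarray(points, dtype=float)
    if len(pts) < 4:
        raise ValueError("alpha shape needs >= 4 points")
    tri = Delaunay(pts)
    r_max = 1.0 / alpha
    keep = []
    for simplex in tri.simplices:
        a, b, c = pts[simplex]
        la, lb, lc = (
            np.linalg.norm(b - c),
            np.linalg.norm(a - c),
            np.linalg.norm(a - b),
        )
        s = 0.5 * (la + lb + lc)
        area2 = max(s * (s - la) * (s - lb) * (s - lc), 0.0)
        area = np.sqrt(area2)
        if area < 1e-12:
            continue
        if la * lb * lc / (4.0 * area) <= r_max:
            keep.append(Polygon(pts[simplex]))
    if not keep:
        warnings.warn("degenerate alpha shape; falling back to convex hull")
        return Polygon(pts[np.unique(tri.convex_hull.ravel())]).convex_hull
    shape = unary_union(keep)
    if shape.is_empty or shape.geom_type not in ("Polygon", "MultiPolygon"):
        warnings.warn("degenerate alpha shape; falling back to convex hull")
        return Polygon(pts).convex_hull
    return shape


def hole_candidates(patchset: PatchSet, alpha: float | None = None) -> PatchSet:
    """Append hole/tear candidate patches, yielding the ``macro_map`` set.

    Per piece: the alpha shape of its tissue-patch centers outlines the
    piece while bridging edge tears open to the exterior; stride-grid cells
    whose centers fall inside the alpha shape but that are absent from the
    ``tumor_map`` set are appended flagged ``hole_candidate``.  Pieces with
    fewer than 4 patches are skipped with a warning.  The returned
    ``macro_map`` set is a superset of the input.
    """
    if (patchset.records["section"] < 0).any():
        raise ValueError("run assign_sections_pieces first")
    ps = patchset.patch_size
    alpha = 1.0 / (2.0 * ps) if alpha is None else alpha
    have = set(zip(patchset.records["x"].astype(int), patchset.records["y"].astype(int)))
    new_rows = []
    for (si, pi), grp in patchset.records.groupby(["section", "piece"]):
        centers = grp[["x", "y"]].to_numpy(dtype=float) + ps / 2.0
        if len(centers) < 4:
            warnings.warn(f"piece ({si},{pi}) has < 4 patches; skipped")
            continue
        # the alpha shape runs through patch centers, inset from the true
        # tissue rim; a quarter-patch dilation cancels that discretization
        # offset without swallowing marginal rim cells
        shape = alpha_shape(centers, alpha).buffer(ps / 4.0)
        x0, y0, x1, y1 = shape.bounds
        gx0 = int(np.floor(x0 / ps)) * ps
        gy0 = int(np.floor(y0 / ps)) * ps
        for gy in range(gy0, int(y1) + 1, ps):
            for gx in range(gx0, int(x1) + 1, ps):
                if (gx, gy) in have:
                    continue
                if shape.contains(Point(gx + ps / 2.0, gy + ps / 2.0)):
                    new_rows.append(
                        dict(x=gx, y=gy, tissue_frac=0.0, section=si, piece=pi,
                             config="macro_map", hole_candidate=True)
                    )
                    have.add((gx, gy))
    recs = patchset.records.copy()
    recs["config"] = "macro_map"
    if new_rows:
        recs = pd.concat([recs, pd.DataFrame(new_rows)], ignore_index=True)
    return replace(patchset, records=recs)
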