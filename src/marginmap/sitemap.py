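"""Mapping histology results onto the surgeon-drawn tumor map.

A histological section (a 2-D point cloud of patch centers tagged with
class probabilities) is morphed into the surgeon's templated ellipse by
gradient descent on the sliced-Wasserstein distance to a uniform sample
of the ellipse interior, then rotated so the section's blue->red ink
line matches the template's.  Kernel-density contours over the
transported, probability-weighted points highlight tumor (or hole/tear)
locations, and surgeon-vs-algorithm map concordance is summarized by a
Jeffreys-prior Beta posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats
from skimage import measure as skmeasure

from .inkorient import OrientationLine, relative_angle, rotate_points

__all__ = [
    "MapTemplate",
    "TransportResult",
    "ConcordancePosterior",
    "DensityOverlay",
    "sliced_wasserstein",
    "morph_to_ellipse",
    "rotate_to_template",
    "density_overlay",
    "concordance_posterior",
]


@dataclass
class MapTemplate:
    """Surgical-map template: target ellipse + blue/red orientation marks."""

    name: str
    center: tuple[float, float]
    axes: tuple[float, float]  # semi-axes (a, b)
    rotation: float  # clock degrees of the ellipse frame
    blue_xy: tuple[float, float]
    red_xy: tuple[float, float]
    theta: float  # clock angle of the blue->red template line

    @property
    def line(self) -> OrientationLine:
        return OrientationLine(self.blue_xy, self.red_xy, self.theta)

    def to_record(self) -> dict:
        return {
            "name": self.name,
            "center": list(map(float, self.center)),
            "axes": list(map(float, self.axes)),
            "rotation": float(self.rotation),
            "blue_xy": list(map(float, self.blue_xy)),
            "red_xy": list(map(float, self.red_xy)),
            "theta": float(self.theta),
        }


@dataclass
class TransportResult:
    source: np.ndarray  # (n, 2) original coordinates
    transported: np.ndarray  # (n, 2) coordinates in template space
    probs: np.ndarray | None  # carried unchanged through transport
    ellipse: tuple  # (cx, cy, a, b, rot_deg)
    applied_rotation: float = 0.0
    final_distance: float = np.nan
    initial_distance: float = np.nan
    iteration_log: list = field(default_factory=list)

    def inside_fraction(self, dilate_frac: float = 0.02) -> float:
        cx, cy, a, b, rot = self.ellipse
        rel = rotate_points(self.transported - (cx, cy), -rot)
        pad = dilate_frac * 2 * min(a, b)
        r = np.hypot(rel[:, 0] / (a + pad), rel[:, 1] / (b + pad))
        return float((r <= 1.0).mean())


# ---------------------------------------------------------------------------
# sliced Wasserstein distance


def _w2_1d_sq(a: np.ndarray, b: np.ndarray) -> float:
    """Exact squared order-2 Wasserstein distance between two uniform 1-D
    empirical distributions (piecewise-constant quantile matching)."""
    a = np.sort(a)
    b = np.sort(b)
    n, m = len(a), len(b)
    edges = np.union1d(np.arange(1, n + 1) / n, np.arange(1, m + 1) / m)
    widths = np.diff(np.concatenate([[0.0], edges]))
    mids = edges - widths / 2
    qa = a[np.minimum((mids * n).astype(int), n - 1)]
    qb = b[np.minimum((mids * m).astype(int), m - 1)]
    return float(np.sum(widths * (qa - qb) ** 2))


def _directions(n_projections: int, seed) -> np.ndarray:
    rng = np.random.default_rng(seed)
    phi = rng.uniform(0.0, np.pi, n_projections)
    return np.column_stack([np.cos(phi), np.sin(phi)])


def sliced_wasserstein(A, B, n_projections: int = 512, seed: int = 0) -> float:
    """Order-2 sliced Wasserstein distance between 2-D point sets: the root
    of the mean, over seeded random unit directions, of the squared 1-D
    W2 between the projections."""
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if len(A) == 0 or len(B) == 0:
        raise ValueError("point sets must be non-empty")
    dirs = _directions(n_projections, seed)
    sq = [_w2_1d_sq(A @ d, B @ d) for d in dirs]
    return float(np.sqrt(np.mean(sq)))


# ---------------------------------------------------------------------------
# morphing


def sample_ellipse_interior(ellipse, n: int, rng) -> np.ndarray:
    cx, cy, a, b, rot = ellipse
    r = np.sqrt(rng.uniform(0.0, 1.0, n))
    phi = rng.uniform(0.0, 2 * np.pi, n)
    pts = np.column_stack([a * r * np.cos(phi), b * r * np.sin(phi)])
    return rotate_points(pts, rot) + (cx, cy)


def morph_to_ellipse(points, ellipse, probs=None, n_target: int | None = None,
                     iters: int = 300, step: float = 1.0, decay: float = 0.98,
                     n_projections: int = 64, seed: int = 0,
                     report_projections: int = 512) -> TransportResult:
    """Morph section points into the template ellipse interior.

    The cloud is first affinely pre-aligned (centroid to the ellipse
    center, isotropic std-matched scale — both shape-preserving), then
    descends the sliced-Wasserstein distance to a fixed uniform sample of
    the ellipse interior: each iteration matches sorted projections along
    fresh random directions and relaxes every point toward its matched
    target quantile (relaxation ``step``, geometric ``decay``).  Class
    probabilities are carried unchanged; relative positioning is preserved
    up to the transport itself.
    """
    X = np.asarray(points, dtype=float).copy()
    n = len(X)
    if n < 10:
        raise ValueError("need >= 10 points to morph")
    rng = np.random.default_rng(seed)
    n_target = max(1024, n) if n_target is None else n_target
    target = sample_ellipse_interior(ellipse, n_target, rng)

    source = X.copy()
    # shape-preserving pre-alignment
    X = X - X.mean(axis=0)
    s_src = np.sqrt((X**2).sum(axis=1).mean())
    s_tgt = np.sqrt(((target - target.mean(axis=0)) ** 2).sum(axis=1).mean())
    if s_src > 1e-12:
        X *= s_tgt / s_src
    X += target.mean(axis=0)

    d0 = sliced_wasserstein(X, target, report_projections, seed=seed + 1)
    tgt_sorted_cache = {}
    log = []
    ranks = (np.arange(n) + 0.5) / n
    tq_idx = np.minimum((ranks * n_target).astype(int), n_target - 1)
    for it in range(iters):
        dirs = _directions(n_projections, rng)
        disp = np.zeros_like(X)
        for d in dirs:
            p = X @ d
            order = np.argsort(p)
            tq = np.sort(target @ d)[tq_idx]
            delta = np.empty(n)
            delta[order] = p[order] - tq
            disp += delta[:, None] * d[None, :]
        disp /= n_projections
        if not np.all(np.isfinite(disp)):
            raise FloatingPointError(f"non-finite transport gradient at iteration {it}")
        X -= (step * decay**it) * 2.0 * disp  # E[dd^T] = I/2 over directions
        if it % 25 == 0 or it == iters - 1:
            log.append((it, float(np.abs(disp).mean())))
    d1 = sliced_wasserstein(X, target, report_projections, seed=seed + 1)
    return TransportResult(source=source, transported=X,
                           probs=None if probs is None else np.asarray(probs).copy(),
                           ellipse=tuple(ellipse), final_distance=d1,
                           initial_distance=d0, iteration_log=log)


def rotate_to_template(result: TransportResult, section_line: OrientationLine | None,
                       template_line: OrientationLine | float) -> TransportResult:
    """Final rotational adjustment about the ellipse center so the morphed
    section's blue->red line matches the template's."""
    if section_line is None:
        raise ValueError(
            "section has no detected ink line; orient manually before mapping"
        )
    t_theta = template_line.theta if isinstance(template_line, OrientationLine) else float(template_line)
    alpha = relative_angle(t_theta, section_line.theta)
    cx, cy = result.ellipse[0], result.ellipse[1]
    rotated = rotate_points(result.transported, alpha, (cx, cy))
    return replace(result, transported=rotated,
                   applied_rotation=result.applied_rotation + alpha)


# ---------------------------------------------------------------------------
# density contours


@dataclass
class DensityOverlay:
    bandwidth: float | str
    threshold: float
    contours: list  # list of (k, 2) x,y polygons in template coordinates

    @property
    def total_area(self) -> float:
        from shapely.geometry import Polygon

        area = 0.0
        for c in self.contours:
            if len(c) >= 3:
                area += Polygon(c).buffer(0).area
        return area


def density_overlay(result: TransportResult, weights, bandwidth=None,
                    threshold: float = 0.5, grid_n: int = 200,
                    canvas=None) -> DensityOverlay:
    """Gaussian kernel-density contours over the transported points,
    weighted by a class probability; the density is max-normalized so
    ``threshold`` cuts in [0, 1].  Raising the threshold never enlarges the
    contoured area.  All-zero weights yield an empty overlay."""
    w = np.asarray(weights, dtype=float)
    pts = result.transported
    bw = bandwidth if bandwidth is not None else "scott"
    if w.sum() <= 0:
        return DensityOverlay(bw, threshold, [])
    kde = stats.gaussian_kde(pts.T, bw_method=None if bw == "scott" else bw,
                             weights=w)
    if canvas is None:
        cx, cy, a, b, _ = result.ellipse
        pad = 0.3 * max(a, b)
        x0, x1 = cx - a - pad, cx + a + pad
        y0, y1 = cy - b - pad, cy + b + pad
    else:
        x0, y0, x1, y1 = 0.0, 0.0, float(canvas[0]), float(canvas[1])
    gx = np.linspace(x0, x1, grid_n)
    gy = np.linspace(y0, y1, grid_n)
    mx, my = np.meshgrid(gx, gy)
    dens = kde(np.vstack([mx.ravel(), my.ravel()])).reshape(grid_n, grid_n)
    dens /= dens.max()
    contours = []
    for c in skmeasure.find_contours(dens, threshold):
        # rows are (row=y, col=x) grid indices -> template coordinates
        xs = np.interp(c[:, 1], np.arange(grid_n), gx)
        ys = np.interp(c[:, 0], np.arange(grid_n), gy)
        contours.append(np.column_stack([xs, ys]))
    return DensityOverlay(bw, threshold, contours)


# ---------------------------------------------------------------------------
# concordance


@dataclass
class ConcordancePosterior:
    """Jeffreys-prior Beta-Binomial posterior over a concordance proportion:
    ``k`` rated-concordant cases out of ``n``, posterior
    Beta(0.5 + k, 0.5 + n - k)."""

    n: int
    k: int
    a0: float = 0.5
    b0: float = 0.5
    a: float = field(init=False)
    b: float = field(init=False)
    q2_5: float = field(init=False)
    q50: float = field(init=False)
    q97_5: float = field(init=False)

    def __post_init__(self):
        if not 0 <= self.k <= self.n:
            raise ValueError("need 0 <= k <= n")
        self.a = self.a0 + self.k
        self.b = self.b0 + self.n - self.k
        self.q2_5, self.q50, self.q97_5 = (
            float(stats.beta.ppf(q, self.a, self.b)) for q in (0.025, 0.5, 0.975)
        )

    def quantile(self, q: float) -> float:
        return float(stats.beta.ppf(q, self.a, self.b))

    def to_record(self) -> dict:
        return {
            "n": self.n, "k": self.k, "a": self.a, "b": self.b,
            "q2.5": self.q2_5, "q50": self.q50, "q97.5": self.q97_5,
        }


def concordance_posterior(k: int, n: int) -> ConcordancePosterior:
    """Exact Beta posterior quantiles (2.5 / 50 / 97.5%) for ``k`` successes
    in ``n`` trials under the Jeffreys Beta(0.5, 0.5) prior."""
    return ConcordancePosterior(n=n, k=k)
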