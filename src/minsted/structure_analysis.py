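"""Downstream structure analysis of localization sets.

Sector occupancy and ring fitting for eight-fold pores, radial outlier
rejection, template-free rigid particle overlay, coverage against a
reference site table, and tessellation-density clustering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import ConvexHull, Voronoi, cKDTree

__all__ = [
    "RingFit",
    "Particle",
    "Cluster",
    "sector_occupancy",
    "fit_ring",
    "radial_outlier_filter",
    "align_particles",
    "coverage_fraction",
    "density_cluster",
]


@dataclass
class RingFit:
    center: tuple[float, float]
    diameter: float
    radial_sigma: float
    aspect_ratio: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("diameter must be positive")
        if self.aspect_ratio < 1:
            raise ValueError("aspect_ratio must be >= 1")


@dataclass
class Particle:
    """A localization set with a rigid transform into the common frame."""

    points: np.ndarray                 # (n, 2) nm, original frame
    sigmas: np.ndarray | None = None   # per-localization precisions
    rotation: float = 0.0              # radians
    translation: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def transformed(self) -> np.ndarray:
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        Rm = np.array([[c, -s], [s, c]])
        return self.points @ Rm.T + self.translation


@dataclass
class Cluster:
    indices: np.ndarray
    centroid: np.ndarray
    diameter: float                    # 4 * sqrt(sigma_x * sigma_y)


# ---------------------------------------------------------------------------
# pore geometry

def sector_occupancy(
    points: np.ndarray,
    center,
    r_in: float = 40.0,
    r_out: float = 70.0,
    n_sectors: int = 8,
) -> int:
    """Number of 45-degree sectors holding >= 1 point in the radial band.

    Sector boundaries are fixed at multiples of ``360 / n_sectors`` degrees
    in the aligned frame.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        return 0
    d = pts - np.asarray(center, dtype=float)
    r = np.hypot(d[:, 0], d[:, 1])
    in_band = (r >= r_in) & (r <= r_out)
    if not np.any(in_band):
        return 0
    ang = np.mod(np.arctan2(d[in_band, 1], d[in_band, 0]), 2.0 * np.pi)
    sectors = np.floor(ang / (2.0 * np.pi / n_sectors)).astype(int)
    return int(len(np.unique(sectors)))


def _ellipse_aspect_ratio(pts: np.ndarray) -> float:
    """Axes ratio from a direct least-squares conic fit (a >= 1)."""
    x, y = pts[:, 0] - pts[:, 0].mean(), pts[:, 1] - pts[:, 1].mean()
    D = np.column_stack([x * x, x * y, y * y, x, y, np.ones_like(x)])
    # smallest singular vector of the design matrix = conic coefficients
    _, sv, Vt = np.linalg.svd(D, full_matrices=False)
    if sv[-1] / sv[0] > 0.5:  # pragma: no cover - defensive
        raise ValueError("degenerate conic fit")
    A, B, C = Vt[-1, 0], Vt[-1, 1], Vt[-1, 2]
    # eigenvalues of the quadratic form give the inverse squared axes
    M = np.array([[A, B / 2.0], [B / 2.0, C]])
    ev = np.linalg.eigvalsh(M)
    if ev[0] * ev[1] <= 0:
        raise ValueError("conic fit is not an ellipse")
    ev = np.abs(ev)
    return float(math.sqrt(ev.max() / ev.min()))


def fit_ring(points: np.ndarray) -> RingFit:
    """Fit a circular ring with a radial Gaussian profile to localizations.

    The center minimizes the variance of the radial distances; the mean
    radial distance gives the diameter and their standard deviation the
    radial width.  The aspect ratio comes from a direct conic fit.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 8:
        raise ValueError("need at least 8 points for a ring fit")
    span = np.linalg.svd(pts - pts.mean(axis=0), compute_uv=False)
    if span[-1] < 1e-9 * max(span[0], 1.0):
        raise ValueError("points are collinear; ring fit is degenerate")

    def radial_var(c):
        r = np.hypot(pts[:, 0] - c[0], pts[:, 1] - c[1])
        return float(np.var(r))

    res = minimize(radial_var, x0=pts.mean(axis=0), method="Nelder-Mead")
    cx, cy = res.x
    r = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
    return RingFit(
        center=(float(cx), float(cy)),
        diameter=2.0 * float(np.mean(r)),
        radial_sigma=float(np.std(r, ddof=1)),
        aspect_ratio=_ellipse_aspect_ratio(pts),
    )


def radial_outlier_filter(
    points: np.ndarray, fit: RingFit, tol: float = 20.0
) -> np.ndarray:
    """Keep points within ``tol`` nm of the fitted mean radius."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    r = np.hypot(pts[:, 0] - fit.center[0], pts[:, 1] - fit.center[1])
    return pts[np.abs(r - fit.diameter / 2.0) <= tol]


# ---------------------------------------------------------------------------
# template-free overlay

def _render_kde(
    pts: np.ndarray, extent: float, pixel: float, sigma: float
) -> np.ndarray:
    """Gaussian-smoothed 2-D histogram on a square grid centered at 0."""
    from scipy.ndimage import gaussian_filter

    n = int(round(2 * extent / pixel))
    edges = np.linspace(-extent, extent, n + 1)
    H, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=[edges, edges])
    return gaussian_filter(H, sigma / pixel)


def _xcorr_peak(
    template_ft: np.ndarray, shape: tuple[int, int], hist: np.ndarray
) -> tuple[float, float, float]:
    """Best circular shift (in pixels) of ``hist`` against a template.

    Returns ``(score, shift_x, shift_y)``; histogram axis 0 is x.  The peak
    is refined to subpixel accuracy by parabolic interpolation.
    """
    fh = np.fft.rfft2(hist)
    corr = np.fft.irfft2(template_ft * np.conj(fh), s=shape)
    corr = np.fft.fftshift(corr)
    i0, i1 = np.unravel_index(np.argmax(corr), corr.shape)
    score = corr[i0, i1]

    def parabolic(cm, c0, cp):
        d = cm - 2 * c0 + cp
        return 0.0 if d == 0 else 0.5 * (cm - cp) / d

    n0, n1 = corr.shape
    d0 = d1 = 0.0
    if 0 < i0 < n0 - 1:
        d0 = parabolic(corr[i0 - 1, i1], corr[i0, i1], corr[i0 + 1, i1])
    if 0 < i1 < n1 - 1:
        d1 = parabolic(corr[i0, i1 - 1], corr[i0, i1], corr[i0, i1 + 1])
    return float(score), (i0 - n0 // 2 + d0), (i1 - n1 // 2 + d1)


def align_particles(
    particles: list[Particle],
    symmetry_fold: int | None = None,
    refine_deg: float | None = None,
    n_iter: int = 4,
    rot_step_deg: float = 1.0,
    pixel_nm: float = 1.0,
    kde_sigma_nm: float = 3.0,
    rng: np.random.Generator | None = None,
) -> tuple[list[Particle], np.ndarray]:
    """Template-free iterative rigid registration of localization particles.

    Each iteration renders a kernel-density template from the current
    transforms and re-aligns every particle by an exhaustive rotation
    search combined with a cross-correlation translation search.  If
    ``symmetry_fold`` is given, each particle is first rotated by a random
    multiple of ``360/fold`` degrees and only small angular corrections
    (``refine_deg``) are allowed afterwards, which randomizes symmetry-
    degenerate registrations.  Returns the aligned particles and the
    per-iteration overlay objective (non-decreasing).
    """
    if len(particles) == 0:
        raise ValueError("need at least one particle")
    for p in particles:
        p.translation = -p.points.mean(axis=0)
    if len(particles) == 1:
        p = particles[0]
        p.rotation, p.translation = 0.0, np.zeros(2)
        return particles, np.array([1.0])

    if symmetry_fold is not None:
        if rng is None:
            rng = np.random.default_rng()
        step = 2.0 * np.pi / symmetry_fold
        for p in particles:
            p.rotation += step * rng.integers(symmetry_fold)

    extent = 1.5 * max(
        np.abs(p.points - p.points.mean(axis=0)).max() for p in particles
    ) + 4 * kde_sigma_nm
    if refine_deg is not None:
        angles0 = np.radians(
            np.arange(-refine_deg, refine_deg + rot_step_deg / 2, rot_step_deg)
        )
    else:
        angles0 = np.radians(np.arange(0.0, 360.0, rot_step_deg))

    scores = []
    imgs = [
        _render_kde(p.transformed(), extent, pixel_nm, kde_sigma_nm)
        for p in particles
    ]
    for _ in range(n_iter):
        snapshot = [(p.rotation, p.translation.copy()) for p in particles]
        total = 0.0
        for idx, p in enumerate(particles):
            template = np.sum(
                [im for j, im in enumerate(imgs) if j != idx], axis=0
            )
            template_ft = np.fft.rfft2(template)
            best = None
            offsets = angles0 + (p.rotation if refine_deg is not None else 0.0)
            centered = p.points - p.points.mean(axis=0)
            for theta in offsets:
                c, s = math.cos(theta), math.sin(theta)
                rot = centered @ np.array([[c, s], [-s, c]])
                hist = _render_kde(rot, extent, pixel_nm, 0.0)
                score, sx, sy = _xcorr_peak(template_ft, template.shape, hist)
                if best is None or score > best[0]:
                    best = (score, theta, sx * pixel_nm, sy * pixel_nm)
            score, theta, tx, ty = best
            p.rotation = theta
            c, s = math.cos(theta), math.sin(theta)
            Rm = np.array([[c, -s], [s, c]])
            p.translation = np.array([tx, ty]) - Rm @ p.points.mean(axis=0)
            imgs[idx] = _render_kde(p.transformed(), extent, pixel_nm, kde_sigma_nm)
            total += score
        if scores and total < scores[-1]:
            # degenerate (symmetry) jumps can lower the greedy objective:
            # roll back and stop at the best ensemble found
            for p, (rot, tra) in zip(particles, snapshot):
                p.rotation, p.translation = rot, tra
            break
        scores.append(total)
        if len(scores) > 1 and scores[-1] <= scores[-2] * (1 + 1e-6):
            break
    return particles, np.array(scores)


def coverage_fraction(
    points: np.ndarray, reference_sites: np.ndarray, radius: float = 7.0
) -> float:
    """Fraction of points within ``radius`` of any reference site."""
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    ref = np.asarray(reference_sites, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("no points")
    tree = cKDTree(ref)
    d, _ = tree.query(pts, k=1)
    return float(np.mean(d <= radius))


# ---------------------------------------------------------------------------
# density clustering

def density_cluster(
    points: np.ndarray,
    min_count: int = 10,
    attach_radius: float = 40.0,
    density_factor: float = 2.0,
) -> tuple[np.ndarray, list[Cluster]]:
    """Tessellation-density clustering with straggler attachment.

    Core points are those whose Voronoi-cell inverse area exceeds
    ``density_factor`` times the mean point density; cores connected in the
    Delaunay graph form clusters; remaining points within ``attach_radius``
    of a cluster are attached to the closest one; clusters below
    ``min_count`` are discarded.  Returns labels (-1 = noise) and cluster
    summaries with diameter ``4 * sqrt(sigma_x * sigma_y)``.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    n = len(pts)
    if n == 0:
        raise ValueError("at least one point required")
    labels = np.full(n, -1, dtype=int)
    if n < 5:
        return labels, []

    vor = Voronoi(pts)
    hull_area = ConvexHull(pts).volume
    mean_density = n / hull_area
    dens = np.zeros(n)
    for i, reg_idx in enumerate(vor.point_region):
        reg = vor.regions[reg_idx]
        if -1 in reg or len(reg) == 0:
            dens[i] = 0.0
            continue
        poly = vor.vertices[reg]
        x, y = poly[:, 0], poly[:, 1]
        area = 0.5 * abs(np.dot(x, np.roll(y, 1)) - np.dot(y, np.roll(x, 1)))
        dens[i] = 1.0 / area if area > 0 else 0.0
    core = dens >= density_factor * mean_density
    if not np.any(core):
        return labels, []

    core_idx = np.nonzero(core)[0]
    # cores within the attachment radius belong to the same cluster
    m = len(core_idx)
    tree_core = cKDTree(pts[core_idx])
    pairs = tree_core.query_pairs(attach_radius, output_type="ndarray")
    graph = coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(m, m)
    )
    _, comp = connected_components(graph, directed=False)
    labels[core_idx] = comp

    # attach stragglers to the closest cluster within attach_radius
    assigned = labels >= 0
    if np.any(assigned) and np.any(~assigned):
        tree = cKDTree(pts[assigned])
        d, j = tree.query(pts[~assigned], k=1)
        near = d <= attach_radius
        idx_un = np.nonzero(~assigned)[0]
        labels[idx_un[near]] = labels[np.nonzero(assigned)[0][j[near]]]

    # min-count filter and summaries
    clusters: list[Cluster] = []
    out = np.full(n, -1, dtype=int)
    next_id = 0
    for lab in np.unique(labels[labels >= 0]):
        idx = np.nonzero(labels == lab)[0]
        if len(idx) < min_count:
            continue
        sub = pts[idx]
        sx = np.std(sub[:, 0], ddof=1)
        sy = np.std(sub[:, 1], ddof=1)
        clusters.append(
            Cluster(
                indices=idx,
                centroid=sub.mean(axis=0),
                diameter=float(4.0 * np.sqrt(sx * sy)),
            )
        )
        out[idx] = next_id
        next_id += 1
    return out, clusters
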