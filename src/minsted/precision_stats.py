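"""Localization-precision estimators.

Two complementary routes are implemented: a cluster route (spread of
repeated localizations of the same binding site) and a single-trace route
(standard deviation of moving means of blocks of center positions, fitted
to a power law and extrapolated over photon number).  Comparing the two
yields the residual site-stability term ``s``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import least_squares, minimize_scalar
from scipy.spatial.distance import pdist

from .localizer import Trace, position_estimate

__all__ = [
    "PrecisionConfig",
    "PowerLawFit",
    "StabilityModel",
    "convergence_filter",
    "cluster_localizations",
    "sigma_cluster",
    "sigma_cluster_curve",
    "sigma_block",
    "sigma_block_curve",
    "max_block_size",
    "fit_power_law",
    "sigma_est",
    "fit_stability",
    "ExperimentPrecision",
    "analyze_experiment",
]


@dataclass
class PrecisionConfig:
    sigma_c: float = 4.2             # convergence threshold, nm (strict)
    cluster_max_diameter: float = 10.0
    cluster_min_count: int = 5
    block_fraction: int = 5          # M < (L - n_c + 1) / block_fraction
    c_lo: float = 0.4                # exclusive
    c_hi: float = 0.5                # inclusive
    b_min: float = 1e-9              # numerical stand-in for b > 0
    min_clusters_display: int = 10
    alpha: float = 0.15              # used for fit initialization only

    def __post_init__(self) -> None:
        if self.sigma_c <= 0:
            raise ValueError("sigma_c must be positive")
        if self.cluster_min_count < 2:
            raise ValueError("cluster_min_count must be >= 2")


@dataclass
class PowerLawFit:
    """``sigma_est(M) = a / (b + M)**c`` with b > 0 and c in (0.4, 0.5]."""

    a: float
    b: float
    c: float
    residual: float = 0.0

    def __call__(self, M) -> np.ndarray:
        return self.a / (self.b + np.asarray(M, dtype=float)) ** self.c


@dataclass
class StabilityModel:
    s: float  # residual site-position uncertainty, nm (>= 0)


# ---------------------------------------------------------------------------
# filtering and clustering

def convergence_filter(trace: Trace, cfg: PrecisionConfig) -> bool:
    """True iff the post-``n_c`` center positions converge within ``sigma_c``.

    The standard deviation of x and of y over ``i in [n_c, L]`` must both be
    strictly below the threshold.
    """
    if trace.L < trace.n_c:
        return False
    seg = trace.post_centers()
    sx = float(np.std(seg[:, 0], ddof=1)) if len(seg) > 1 else 0.0
    sy = float(np.std(seg[:, 1], ddof=1)) if len(seg) > 1 else 0.0
    return sx < cfg.sigma_c and sy < cfg.sigma_c


def cluster_localizations(
    positions: np.ndarray, cfg: PrecisionConfig | None = None
) -> np.ndarray:
    """Group localizations into clusters of bounded diameter.

    Complete-linkage agglomerative clustering with the diameter capped at
    ``cluster_max_diameter``; clusters with fewer than ``cluster_min_count``
    members are marked as noise (label ``-1``).  Returns integer labels.
    """
    if cfg is None:
        cfg = PrecisionConfig()
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if n == 0:
        raise ValueError("at least one position required")
    if n == 1:
        labels = np.zeros(1, dtype=int)
    else:
        Z = linkage(pdist(positions), method="complete")
        labels = fcluster(Z, t=cfg.cluster_max_diameter, criterion="distance") - 1
    out = np.full(n, -1, dtype=int)
    next_id = 0
    for lab in np.unique(labels):
        idx = labels == lab
        if idx.sum() >= cfg.cluster_min_count:
            out[idx] = next_id
            next_id += 1
    return out


# ---------------------------------------------------------------------------
# cluster-route precision

def sigma_cluster(
    traces: list[Trace], N: int, cfg: PrecisionConfig | None = None
) -> float:
    """Spread of the position estimates of one cluster at photon count ``N``.

    Geometric mean of the per-axis standard deviations of
    ``position_estimate(trace, N)`` over the member traces; traces shorter
    than ``N`` photons are excluded.
    """
    if cfg is None:
        cfg = PrecisionConfig()
    pts = np.array(
        [position_estimate(tr, N) for tr in traces if tr.L >= N]
    )
    if len(pts) < 2:
        return float("nan")
    sx = np.std(pts[:, 0], ddof=1)
    sy = np.std(pts[:, 1], ddof=1)
    return float(np.sqrt(sx * sy))


def sigma_cluster_curve(
    traces: list[Trace],
    labels: np.ndarray,
    N_grid,
    cfg: PrecisionConfig | None = None,
) -> np.ndarray:
    """Median over clusters of ``sigma_cluster`` on a grid of photon counts.

    Entries are NaN where fewer than ``min_clusters_display`` clusters
    contribute (each cluster needs >= 2 traces long enough at that ``N``).
    """
    if cfg is None:
        cfg = PrecisionConfig()
    labels = np.asarray(labels)
    out = np.full(len(N_grid), np.nan)
    groups = [
        [tr for tr, lab in zip(traces, labels) if lab == k]
        for k in np.unique(labels[labels >= 0])
    ]
    for j, N in enumerate(N_grid):
        vals = [sigma_cluster(g, int(N), cfg) for g in groups]
        vals = [v for v in vals if np.isfinite(v)]
        if len(vals) >= cfg.min_clusters_display:
            out[j] = float(np.median(vals))
    return out


# ---------------------------------------------------------------------------
# single-trace (block) route

def max_block_size(trace: Trace, cfg: PrecisionConfig | None = None) -> int:
    """Largest admissible block size: ``M < (L - n_c + 1) / block_fraction``."""
    if cfg is None:
        cfg = PrecisionConfig()
    n_post = trace.L - trace.n_c + 1
    bound = n_post / cfg.block_fraction
    m = int(np.ceil(bound) - 1) if bound == int(bound) else int(np.floor(bound))
    return max(m, 0)


def sigma_block(trace: Trace, M: int, cfg: PrecisionConfig | None = None) -> float:
    """Standard deviation of the moving mean of blocks of ``M`` centers.

    Blocks are maximally overlapping (stride 1) over the post-``n_c``
    segment; per-axis standard deviations of the block means are combined
    as their geometric mean.
    """
    if cfg is None:
        cfg = PrecisionConfig()
    if trace.L < trace.n_c:
        raise ValueError("trace did not reach the minimal FWHM")
    if not 1 <= M <= max_block_size(trace, cfg):
        raise ValueError(f"block size M={M} out of range")
    seg = trace.post_centers()
    cs = np.cumsum(seg, axis=0)
    cs = np.vstack([np.zeros((1, 2)), cs])
    means = (cs[M:] - cs[:-M]) / M
    sx = np.std(means[:, 0], ddof=1)
    sy = np.std(means[:, 1], ddof=1)
    return float(np.sqrt(sx * sy))


def sigma_block_curve(
    trace: Trace, cfg: PrecisionConfig | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """``(M, sigma_block(M))`` for all admissible block sizes of one trace."""
    if cfg is None:
        cfg = PrecisionConfig()
    m_max = max_block_size(trace, cfg)
    if m_max < 1:
        raise ValueError("trace too short for block analysis")
    seg = trace.post_centers()
    cs = np.vstack([np.zeros((1, 2)), np.cumsum(seg, axis=0)])
    Ms = np.arange(1, m_max + 1)
    out = np.empty(m_max)
    for j, M in enumerate(Ms):
        means = (cs[M:] - cs[:-M]) / M
        out[j] = np.sqrt(
            np.std(means[:, 0], ddof=1) * np.std(means[:, 1], ddof=1)
        )
    return Ms, out


# ---------------------------------------------------------------------------
# power-law fit and stability

def fit_power_law(
    M_values, sigma_values, cfg: PrecisionConfig | None = None
) -> PowerLawFit:
    """Fit ``a / (b + M)**c`` to block precisions, residuals on log sigma.

    Bounds: ``b > 0``, ``c in (0.4, 0.5]``; initialization assumes the
    AR(1)-like correlation of the center series
    (``b = 1/alpha``, ``c = 1/2``).
    """
    if cfg is None:
        cfg = PrecisionConfig()
    M = np.asarray(M_values, dtype=float)
    sig = np.asarray(sigma_values, dtype=float)
    ok = np.isfinite(sig) & (sig > 0)
    M, sig = M[ok], sig[ok]
    if len(M) < 5:
        raise ValueError("need at least 5 (M, sigma) pairs")
    log_sig = np.log(sig)

    b0 = 1.0 / cfg.alpha
    c0 = cfg.c_hi
    a0 = sig[0] * (b0 + M[0]) ** c0

    def resid(p):
        a, b, c = p
        return np.log(a) - c * np.log(b + M) - log_sig

    eps = 1e-9
    res = least_squares(
        resid,
        x0=[a0, b0, c0],
        bounds=([eps, cfg.b_min, cfg.c_lo + eps], [np.inf, np.inf, cfg.c_hi]),
        method="trf",
    )
    if not res.success:
        raise RuntimeError(f"power-law fit did not converge: {res.message}")
    a, b, c = res.x
    rms = float(np.sqrt(np.mean(res.fun**2)))
    return PowerLawFit(a=float(a), b=float(b), c=float(c), residual=rms)


def sigma_est(fit: PowerLawFit, N: int, n_c: int) -> float:
    """Extrapolated precision at ``N`` total detections (``M = N - n_c + 1``)."""
    if N < n_c:
        raise ValueError("N must be >= n_c")
    M = N - n_c + 1
    return float(fit(M))


def fit_stability(
    sigma_cluster_vals, sigma_est_vals
) -> StabilityModel:
    """Scalar least-squares fit of ``sigma_cluster = sqrt(sigma_est^2 + s^2)``.

    Both curves must share a grid; NaNs are ignored.  If the cluster spread
    is below the single-trace estimate everywhere, ``s = 0``.
    """
    sc = np.asarray(sigma_cluster_vals, dtype=float)
    se = np.asarray(sigma_est_vals, dtype=float)
    ok = np.isfinite(sc) & np.isfinite(se)
    sc, se = sc[ok], se[ok]
    if len(sc) == 0:
        raise ValueError("no overlapping points between the two curves")
    if np.all(sc <= se):
        return StabilityModel(s=0.0)

    def cost(s):
        return float(np.sum((sc - np.sqrt(se**2 + s**2)) ** 2))

    s_hi = float(np.max(sc)) + 1.0
    res = minimize_scalar(cost, bounds=(0.0, s_hi), method="bounded")
    return StabilityModel(s=float(res.x))


# ---------------------------------------------------------------------------
# experiment-level driver

@dataclass
class ExperimentPrecision:
    """Result bundle of the full precision analysis of one experiment."""

    N_grid: np.ndarray
    sigma_cluster_nm: np.ndarray       # median over clusters (NaN if < display min)
    sigma_est_nm: np.ndarray           # median of per-trace power-law curves
    n_clusters: int
    n_traces_pass: int
    fits: list[PowerLawFit]
    stability: StabilityModel | None


def analyze_experiment(
    traces: list[Trace],
    cfg: PrecisionConfig | None = None,
    N_grid=None,
    min_fit_length: int = 25,
) -> ExperimentPrecision:
    """Run the full cascade: convergence filter, clustering, both precision
    routes, and the stability decomposition.

    ``min_fit_length`` is the minimal number of post-``n_c`` detections a
    trace needs before a power-law fit is attempted (>= 5 block sizes).
    """
    if cfg is None:
        cfg = PrecisionConfig()
    passed = [
        tr for tr in traces if tr.converged and convergence_filter(tr, cfg)
    ]
    if not passed:
        raise ValueError("no trace passed the convergence filter")
    if N_grid is None:
        n_max = max(tr.L for tr in passed)
        N_grid = np.unique(
            np.round(np.geomspace(2, n_max, 40)).astype(int)
        )
    N_grid = np.asarray(N_grid, dtype=int)

    finals = np.array([position_estimate(tr, tr.L) for tr in passed])
    labels = cluster_localizations(finals, cfg)
    sc = sigma_cluster_curve(passed, labels, N_grid, cfg)

    fits = []
    curves = []
    for tr in passed:
        if tr.L - tr.n_c + 1 < min_fit_length:
            continue
        Ms, sb = sigma_block_curve(tr, cfg)
        try:
            fit = fit_power_law(Ms, sb, cfg)
        except (ValueError, RuntimeError):
            continue
        fits.append(fit)
        with np.errstate(invalid="ignore"):
            M_of_N = np.where(N_grid >= tr.n_c, N_grid - tr.n_c + 1, np.nan)
        curves.append(fit(M_of_N))
    if curves:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            se = np.nanmedian(np.array(curves), axis=0)
    else:
        se = np.full(len(N_grid), np.nan)

    stability = None
    ok = np.isfinite(sc) & np.isfinite(se)
    if np.any(ok):
        stability = fit_stability(sc[ok], se[ok])

    return ExperimentPrecision(
        N_grid=N_grid,
        sigma_cluster_nm=sc,
        sigma_est_nm=se,
        n_clusters=int(labels.max() + 1) if labels.size else 0,
        n_traces_pass=len(passed),
        fits=fits,
        stability=stability,
    )
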