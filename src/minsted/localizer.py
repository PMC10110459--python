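"""Online donut-zero localization loop and the photon-level Monte Carlo driver.

A single active fluorophore is encircled by the donut zero at radius ``R_i``.
Every detected photon (i) shrinks the E-PSF according to an energy ramp and
(ii) nudges the circle center toward the detection azimuth by
``alpha * R_i``.  Once the minimal FWHM is reached (photon index ``n_c``)
the schedule is frozen and the running mean of the center positions is the
position estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .epsf_model import OpticsModel, epsf, epsf_fwhm, sbr_model

__all__ = [
    "LocalizerConfig",
    "Trace",
    "Schedule",
    "StaticEmitter",
    "UnbindingEmitter",
    "build_schedule",
    "ramp_schedule",
    "sample_photon",
    "update_center",
    "run_localization",
    "position_estimate",
]

_N_AZIMUTH_BINS = 1024


@dataclass
class LocalizerConfig:
    """Parameters of the localization loop."""

    alpha: float = 0.15            # center-update fraction of R_i
    r_over_fwhm: float = 0.5       # scan radius / FWHM
    e_max: float = 1.0             # maximum pulse energy, nJ
    fwhm_min: float | None = None  # minimal FWHM, nm (from epsf_fwhm(e_max))
    r_min: float | None = None     # minimal scan radius, nm (fwhm_min/2)
    n_c_target: int = 80           # photons to reach minimal FWHM
    n_on: int = 100                # initiation threshold, counts
    term_window_ms: float = 20.0   # low-rate termination window
    term_min_counts: int = 16      # detections required per window
    max_duration_ms: float | None = 200.0
    max_photons: int | None = None
    detect_rate_khz: float = 50.0  # detection rate while bound
    n_on_override: bool = False    # allow n_on outside [80, 140]

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.r_over_fwhm <= 0:
            raise ValueError("r_over_fwhm must be positive")
        if not (80 <= self.n_on <= 140 or self.n_on_override):
            raise ValueError("n_on outside [80, 140]; set n_on_override=True")

    def resolve(self, optics: OpticsModel) -> "LocalizerConfig":
        """Fill ``fwhm_min``/``r_min`` from the optics if not set explicitly."""
        if self.fwhm_min is None:
            self.fwhm_min = epsf_fwhm(self.e_max, optics)
        if self.r_min is None:
            self.r_min = self.r_over_fwhm * self.fwhm_min
        return self


@dataclass
class Trace:
    """Per-photon record of one localization attempt.

    Photon indices follow the 1-based convention ``i = 1..L``; ``n_c`` is
    the first index at which the minimal FWHM is in effect.
    """

    centers: np.ndarray            # (L, 2) circle centers, nm
    energies: np.ndarray           # (L,) pulse energies, nJ
    radii: np.ndarray              # (L,) scan radii, nm
    fwhms: np.ndarray              # (L,) E-PSF FWHMs, nm
    times_ms: np.ndarray           # (L,) detection times
    is_bg: np.ndarray              # (L,) background-photon flags
    n_c: int                       # 1-based index of schedule freeze
    initiated: bool = True
    end_time_ms: float | None = None
    truth: np.ndarray | None = None  # (L, 2) emitter positions at detections
    trace_id: int = 0

    @property
    def L(self) -> int:
        return len(self.centers)

    @property
    def converged(self) -> bool:
        return self.initiated and self.L >= self.n_c

    def post_centers(self) -> np.ndarray:
        """Centers from ``n_c`` on (the stationary, minimal-FWHM segment)."""
        return self.centers[self.n_c - 1 :]


# ---------------------------------------------------------------------------
# schedule

class Schedule:
    """Precomputed per-photon ramp (E_i, FWHM_i, R_i) plus cached SBR values."""

    def __init__(self, cfg: LocalizerConfig, optics: OpticsModel):
        cfg.resolve(optics)
        n = cfg.n_c_target
        gamma = (cfg.fwhm_min / optics.fwhm_conf) ** (1.0 / (n - 1))
        fwhms = np.maximum(
            cfg.fwhm_min, optics.fwhm_conf * gamma ** np.arange(n, dtype=float)
        )
        fwhms[n - 1 :] = cfg.fwhm_min  # guard against round-off at the endpoint
        energies = np.array([_invert_fwhm(f, cfg.e_max, optics) for f in fwhms])
        radii = np.maximum(cfg.r_min, cfg.r_over_fwhm * fwhms)
        self.gamma = gamma
        self.fwhms = fwhms
        self.energies = energies
        self.radii = radii
        self.sbrs = np.array([sbr_model(e, optics) for e in energies])
        self.cfg = cfg
        self.optics = optics

    def at(self, i: int) -> tuple[float, float, float]:
        """(E_i, FWHM_i, R_i) for 1-based photon index ``i``."""
        k = min(i, len(self.fwhms)) - 1
        return float(self.energies[k]), float(self.fwhms[k]), float(self.radii[k])

    def sbr_at(self, i: int) -> float:
        k = min(i, len(self.sbrs)) - 1
        return float(self.sbrs[k])

    @property
    def n_c(self) -> int:
        """First 1-based index at which the minimal FWHM is in effect."""
        return int(np.argmax(self.fwhms <= self.cfg.fwhm_min)) + 1


def _invert_fwhm(target: float, e_max: float, optics: OpticsModel) -> float:
    """Pulse energy at which the E-PSF FWHM equals ``target`` (<= fwhm_conf)."""
    if target >= optics.fwhm_conf:
        return 0.0

    def f(E: float) -> float:
        return epsf_fwhm(E, optics) - target

    hi = e_max
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e6:  # pragma: no cover - unreachable for sane optics
            raise RuntimeError("FWHM target not reachable")
    return float(brentq(f, 0.0, hi, xtol=1e-9))


def build_schedule(cfg: LocalizerConfig, optics: OpticsModel) -> Schedule:
    return Schedule(cfg, optics)


def ramp_schedule(
    i: int, cfg: LocalizerConfig, optics: OpticsModel
) -> tuple[float, float, float]:
    """(E_i, FWHM_i, R_i) of the per-photon ramp, 1-based index ``i``.

    The FWHM shrinks geometrically from the confocal value to ``fwhm_min``
    over ``n_c_target`` photons; the energy is obtained by inverting the
    FWHM-vs-energy curve and the radius is ``r_over_fwhm * FWHM`` floored
    at ``r_min``.
    """
    if i < 1:
        raise ValueError("photon index is 1-based")
    return Schedule(cfg, optics).at(i)


# ---------------------------------------------------------------------------
# photon sampling

def sample_photon(
    emitter_pos,
    center,
    R: float,
    E: float,
    cfg: LocalizerConfig,
    optics: OpticsModel,
    rng: np.random.Generator,
    sbr: float | None = None,
) -> tuple[float, bool]:
    """Sample one detection azimuth; returns ``(phi, is_background)``.

    With probability ``1 / (1 + SBR)`` the photon is background and the
    azimuth uniform; otherwise the azimuth density is proportional to the
    E-PSF evaluated at the distance between the emitter and the scanned
    beam zero, discretized on a 1024-bin inverse CDF.
    """
    if R <= 0:
        raise ValueError("scan radius must be positive")
    if sbr is None:
        sbr = sbr_model(E, optics)
    p_bg = 1.0 / (1.0 + sbr) if np.isfinite(sbr) else 0.0
    if rng.random() < p_bg:
        return float(rng.uniform(0.0, 2.0 * np.pi)), True

    phi = _azimuth_grid()
    dx = emitter_pos[0] - center[0] - R * np.cos(phi)
    dy = emitter_pos[1] - center[1] - R * np.sin(phi)
    w = epsf(np.hypot(dx, dy), E, optics)
    cdf = np.cumsum(w)
    total = cdf[-1]
    if total <= 0:  # emitter far outside the E-PSF: no directional information
        return float(rng.uniform(0.0, 2.0 * np.pi)), False
    u = rng.random() * total
    k = int(np.searchsorted(cdf, u))
    # uniform within the selected bin
    width = 2.0 * np.pi / _N_AZIMUTH_BINS
    return float(phi[k] + (rng.random() - 0.5) * width), False


def _azimuth_grid() -> np.ndarray:
    global _PHI_GRID
    try:
        return _PHI_GRID
    except NameError:
        _PHI_GRID = (np.arange(_N_AZIMUTH_BINS) + 0.5) * (
            2.0 * np.pi / _N_AZIMUTH_BINS
        )
        return _PHI_GRID


def update_center(center, R: float, phi: float, alpha: float = 0.15):
    """Shift the circle center by ``alpha * R`` toward azimuth ``phi``."""
    if R <= 0:
        raise ValueError("scan radius must be positive")
    return (
        center[0] + alpha * R * math.cos(phi),
        center[1] + alpha * R * math.sin(phi),
    )


# ---------------------------------------------------------------------------
# emitters

@dataclass
class StaticEmitter:
    """Emitter bound at a fixed position for the whole trace."""

    position: tuple[float, float] = (0.0, 0.0)

    def position_at(self, t_ms: float) -> tuple[float, float]:
        return self.position

    def is_bound(self, t_ms: float) -> bool:
        return True


@dataclass
class UnbindingEmitter:
    """Emitter that unbinds (stops emitting signal) at ``t_unbind_ms``."""

    position: tuple[float, float] = (0.0, 0.0)
    t_unbind_ms: float = math.inf

    def position_at(self, t_ms: float) -> tuple[float, float]:
        return self.position

    def is_bound(self, t_ms: float) -> bool:
        return t_ms < self.t_unbind_ms


# ---------------------------------------------------------------------------
# the loop

def run_localization(
    emitter,
    cfg: LocalizerConfig,
    optics: OpticsModel,
    rng: np.random.Generator,
    start: tuple[float, float] | None = None,
    schedule: Schedule | None = None,
    trace_id: int = 0,
) -> Trace:
    """Run one localization attempt and return the full per-photon Trace.

    The emitter object provides ``position_at(t_ms)`` and ``is_bound(t_ms)``.
    Inter-photon waiting times are exponential at ``detect_rate_khz`` while
    bound and at the background-only rate ``detect_rate / (1 + SBR)`` while
    unbound.  Termination: fewer than ``term_min_counts`` detections within
    ``term_window_ms``, the optional duration cap, or the photon budget.
    """
    if schedule is None:
        schedule = Schedule(cfg, optics)
    else:
        cfg.resolve(optics)  # ensure fwhm_min/r_min are populated
    if start is None:
        start = emitter.position_at(0.0)
    center = (float(start[0]), float(start[1]))

    centers, energies, radii, fwhms, times, bgs, truths = [], [], [], [], [], [], []
    t = 0.0
    i = 1
    end_time = None
    while True:
        E, F, R = schedule.at(i)
        sbr = schedule.sbr_at(i)
        bound_now = emitter.is_bound(t)
        rate = cfg.detect_rate_khz  # 1 kHz == 1 detection per ms
        if not bound_now:
            rate = rate / (1.0 + sbr)
        dt = rng.exponential(1.0 / rate) if rate > 0 else math.inf
        if not math.isfinite(dt):
            # no further photons can arrive (background-free, unbound)
            k = len(times)
            if k >= cfg.term_min_counts - 1:
                end_time = times[k - (cfg.term_min_counts - 1)] + cfg.term_window_ms
            else:
                end_time = t + cfg.term_window_ms
            break
        t_next = t + dt

        # low-rate termination: the window ending at t_next must contain at
        # least term_min_counts detections (incl. the prospective one)
        k = len(times)
        if k >= cfg.term_min_counts - 1:
            t_ref = times[k - (cfg.term_min_counts - 1)]
            if t_next - t_ref > cfg.term_window_ms:
                end_time = t_ref + cfg.term_window_ms
                break
        if cfg.max_duration_ms is not None and t_next > cfg.max_duration_ms:
            end_time = cfg.max_duration_ms
            break

        t = t_next
        # Poisson thinning across an unbinding boundary: the wait was drawn
        # at the bound rate but the emitter may be dark at the arrival time
        if bound_now and not emitter.is_bound(t):
            keep_prob = 1.0 / (1.0 + sbr) if np.isfinite(sbr) else 0.0
            if rng.random() >= keep_prob:
                continue
        pos = emitter.position_at(t)
        if emitter.is_bound(t):
            phi, is_bg = sample_photon(
                pos, center, R, E, cfg, optics, rng, sbr=sbr
            )
        else:
            phi, is_bg = float(rng.uniform(0.0, 2.0 * np.pi)), True
        center = update_center(center, R, phi, cfg.alpha)
        centers.append(center)
        energies.append(E)
        radii.append(R)
        fwhms.append(F)
        times.append(t)
        bgs.append(is_bg)
        truths.append(pos)
        if cfg.max_photons is not None and i >= cfg.max_photons:
            end_time = t
            break
        i += 1

    L = len(centers)
    initiated = L >= cfg.n_on
    return Trace(
        centers=np.array(centers).reshape(L, 2),
        energies=np.array(energies),
        radii=np.array(radii),
        fwhms=np.array(fwhms),
        times_ms=np.array(times),
        is_bg=np.array(bgs, dtype=bool),
        n_c=schedule.n_c,
        initiated=initiated,
        end_time_ms=end_time if end_time is not None else (times[-1] if times else 0.0),
        truth=np.array(truths).reshape(L, 2),
        trace_id=trace_id,
    )


def position_estimate(trace: Trace, N: int) -> tuple[float, float]:
    """Position estimate after ``N`` detections (1-based).

    For ``N >= n_c`` the arithmetic mean of the centers over
    ``i in [n_c, N]``; before the schedule freeze, the raw center at ``N``.
    """
    if not 1 <= N <= trace.L:
        raise ValueError(f"N={N} outside [1, L={trace.L}]")
    if N < trace.n_c:
        x, y = trace.centers[N - 1]
        return float(x), float(y)
    seg = trace.centers[trace.n_c - 1 : N]
    m = seg.mean(axis=0)
    return float(m[0]), float(m[1])
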