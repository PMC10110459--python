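"""Synthetic ground-truth structures and transient-binding kinetics.

Provides origami-style grids, eight-fold pore site models and vesicle-like
blobs, plus an alternating-renewal binding process (PAINT-style) with
linker offsets and slow site jitter, so the whole pipeline can be exercised
without external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SiteSet",
    "KineticsModel",
    "BindingEvent",
    "make_origami",
    "make_npc",
    "make_vesicles",
    "generate_events",
    "origami_kinetics",
    "npc_kinetics",
]


@dataclass
class SiteSet:
    """Ground-truth binding-site geometry."""

    positions: np.ndarray              # (n, 2) nm
    site_ids: np.ndarray               # (n,) unique integers
    structure_kind: str = "custom"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        self.site_ids = np.asarray(self.site_ids)
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("site coordinates must be finite")
        if len(np.unique(self.site_ids)) != len(self.site_ids):
            raise ValueError("site ids must be unique")

    def __len__(self) -> int:
        return len(self.positions)


@dataclass
class KineticsModel:
    """Transient-binding kinetics and fluorophore-offset model."""

    mean_bound_ms: float = 150.0       # exponential on-time
    mean_dark_s: float = 30.0          # exponential off-time per site
    labeling_efficiency: float = 0.85  # fraction of sites carrying a docking strand
    linker_length_nm: float = 7.0      # disk-uniform linker offset radius
    site_jitter_nm: float = 0.72       # stationary std of slow site wander
    jitter_tau_s: float = 5.0          # jitter correlation time (>> one event)
    bleach_cap_ms: float | None = 200.0
    single_shot: bool = False          # photoactivation mode: <=1 event/site
    single_shot_median_photons: float = 161.0

    def __post_init__(self) -> None:
        if self.mean_bound_ms <= 0 or self.mean_dark_s <= 0:
            raise ValueError("kinetic rates must be positive")
        if not 0 < self.labeling_efficiency <= 1:
            raise ValueError("labeling_efficiency must be in (0, 1]")


def origami_kinetics(**overrides) -> KineticsModel:
    """Kinetics preset for origami grids: short imager linker, 0.72-nm jitter."""
    kw = dict(linker_length_nm=1.0, site_jitter_nm=0.72)
    kw.update(overrides)
    return KineticsModel(**kw)


def npc_kinetics(**overrides) -> KineticsModel:
    """Kinetics preset for pore imaging: 7-nm tag/nanobody linker."""
    kw = dict(linker_length_nm=7.0, site_jitter_nm=0.72)
    kw.update(overrides)
    return KineticsModel(**kw)


@dataclass
class BindingEvent:
    """One on-interval of a fluorophore at a site."""

    site_id: int
    t_on_s: float
    t_off_s: float
    position: tuple[float, float]      # fluorophore position during the event, nm
    overlaps: bool = False             # concurrent event within the focal region
    photon_budget: float | None = None  # single-shot mode only

    @property
    def duration_ms(self) -> float:
        return (self.t_off_s - self.t_on_s) * 1e3


# ---------------------------------------------------------------------------
# geometries

def make_origami(
    spacing: float, rows: int = 3, cols: int = 3, layout: str = "rect"
) -> SiteSet:
    """Grid of binding sites centered at the origin.

    ``rect``: rectangular lattice with period ``spacing``.  ``hex``:
    triangular lattice where every nearest-neighbor distance is ``spacing``.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if layout == "rect":
        xs = (np.arange(cols) - (cols - 1) / 2) * spacing
        ys = (np.arange(rows) - (rows - 1) / 2) * spacing
        pts = np.array([(x, y) for y in ys for x in xs])
    elif layout == "hex":
        pts = []
        for r in range(rows):
            y = r * spacing * math.sqrt(3) / 2
            xoff = (r % 2) * spacing / 2
            for c in range(cols):
                pts.append((c * spacing + xoff, y))
        pts = np.array(pts)
        pts -= pts.mean(axis=0)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return SiteSet(pts, np.arange(len(pts)), structure_kind="origami_grid")


def make_npc(
    diameter: float = 112.0,
    corners: int = 8,
    per_corner: int = 4,
    stagger_deg: float = 5.0,
) -> SiteSet:
    """Sites on a circle, grouped in staggered corners (pore-scaffold model).

    ``corners * per_corner`` sites at radius ``diameter / 2``; within each
    corner the sites are spread along the circumference by ``stagger_deg``
    steps, producing the elongation of each corner seen in overlays.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    radius = diameter / 2.0
    pts = []
    for k in range(corners):
        base = 2.0 * math.pi * k / corners
        for m in range(per_corner):
            ang = base + math.radians(stagger_deg) * (m - (per_corner - 1) / 2)
            pts.append((radius * math.cos(ang), radius * math.sin(ang)))
    return SiteSet(np.array(pts), np.arange(len(pts)), structure_kind="npc")


def make_vesicles(
    n_blobs: int,
    blob_sigma_nm: float,
    sites_per_blob: int,
    extent_nm: float,
    rng: np.random.Generator,
) -> SiteSet:
    """Gaussian blobs of sites scattered over a square field (vesicle stand-in)."""
    centers = rng.uniform(-extent_nm / 2, extent_nm / 2, size=(n_blobs, 2))
    pts = np.concatenate(
        [c + rng.normal(0.0, blob_sigma_nm, size=(sites_per_blob, 2)) for c in centers]
    )
    return SiteSet(pts, np.arange(len(pts)), structure_kind="vesicle")


# ---------------------------------------------------------------------------
# kinetics

def _disk_uniform(radius: float, rng: np.random.Generator) -> np.ndarray:
    r = radius * math.sqrt(rng.random())
    phi = rng.uniform(0.0, 2.0 * math.pi)
    return np.array([r * math.cos(phi), r * math.sin(phi)])


def generate_events(
    sites: SiteSet,
    kin: KineticsModel,
    duration_s: float,
    rng: np.random.Generator,
    focal_radius_nm: float = 500.0,
) -> list[BindingEvent]:
    """Simulate binding events for every labeled site over ``duration_s``.

    Each labeled site runs an alternating renewal process (exponential dark
    and bound intervals, the latter optionally capped by bleaching).  The
    fluorophore position of an event is site + disk-uniform linker offset +
    the site's slow Gaussian wander (an Ornstein-Uhlenbeck path of
    stationary std ``site_jitter_nm`` sampled at the event start).  Events
    overlapping in time with another event within ``focal_radius_nm`` are
    flagged.  In ``single_shot`` mode every labeled site emits at most one
    event with an exponential photon budget.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    events: list[BindingEvent] = []
    labeled = rng.random(len(sites)) < kin.labeling_efficiency

    for pos, sid, lab in zip(sites.positions, sites.site_ids, labeled):
        if not lab:
            continue
        if kin.single_shot:
            t_on = rng.uniform(0.0, duration_s)
            dur = rng.exponential(kin.mean_bound_ms) / 1e3
            budget = rng.exponential(
                kin.single_shot_median_photons / math.log(2.0)
            )
            events.append(
                _new_event(sid, pos, t_on, t_on + dur, kin, rng, 0.0, budget)
            )
            continue
        t = 0.0
        jitter = rng.normal(0.0, kin.site_jitter_nm, size=2)
        t_prev = 0.0
        while True:
            t += rng.exponential(kin.mean_dark_s)
            if t >= duration_s:
                break
            dur_ms = rng.exponential(kin.mean_bound_ms)
            if kin.bleach_cap_ms is not None:
                dur_ms = min(dur_ms, kin.bleach_cap_ms)
            # advance the OU jitter path to the event start
            if kin.site_jitter_nm > 0:
                rho = math.exp(-(t - t_prev) / kin.jitter_tau_s)
                jitter = rho * jitter + math.sqrt(
                    1.0 - rho * rho
                ) * rng.normal(0.0, kin.site_jitter_nm, size=2)
            t_prev = t
            ev = BindingEvent(
                site_id=int(sid),
                t_on_s=t,
                t_off_s=t + dur_ms / 1e3,
                position=tuple(
                    pos + jitter + _disk_uniform(kin.linker_length_nm, rng)
                ),
            )
            events.append(ev)
            t = ev.t_off_s

    events.sort(key=lambda e: e.t_on_s)
    _flag_overlaps(events, sites, focal_radius_nm)
    return events


def _new_event(sid, pos, t_on, t_off, kin, rng, jitter_scale, budget):
    jitter = rng.normal(0.0, kin.site_jitter_nm, size=2)
    return BindingEvent(
        site_id=int(sid),
        t_on_s=t_on,
        t_off_s=t_off,
        position=tuple(pos + jitter + _disk_uniform(kin.linker_length_nm, rng)),
        photon_budget=budget,
    )


def _flag_overlaps(
    events: list[BindingEvent], sites: SiteSet, focal_radius_nm: float
) -> None:
    """Mark events that overlap in time with a neighbor in the focal region."""
    pos = {int(s): p for s, p in zip(sites.site_ids, sites.positions)}
    for i, a in enumerate(events):
        for b in events[i + 1 :]:
            if b.t_on_s >= a.t_off_s:
                break
            d = np.linalg.norm(
                np.subtract(pos[a.site_id], pos[b.site_id])
            )
            if d <= focal_radius_nm:
                a.overlaps = True
                b.overlaps = True
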