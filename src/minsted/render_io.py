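"""Rendering of localization tables and tabular I/O.

Images are cumulative sums of per-localization Gaussians whose widths equal
the localization precision (optionally floored for display); tables are
plain TSV/CSV with a fixed mandatory schema and lossless round-tripping of
extra columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RenderConfig",
    "render_cnlp",
    "read_locs",
    "write_locs",
    "save_image",
    "MANDATORY_COLUMNS",
]

MANDATORY_COLUMNS = ("id", "x_nm", "y_nm", "sigma_nm")


@dataclass
class RenderConfig:
    pixel_nm: float = 0.3
    sigma_floor_nm: float = 0.0        # 0 = off; display presets 1 / 1.5 / 3
    amplitude_mode: str = "unit_area"  # unit_area | unit_amplitude | histogram
    saturation_cap: float | None = None  # preset 2.5
    extent: tuple[float, float, float, float] | None = None  # xmin,xmax,ymin,ymax

    def __post_init__(self) -> None:
        if self.pixel_nm <= 0:
            raise ValueError("pixel_nm must be positive")
        if self.saturation_cap is not None and self.saturation_cap <= 0:
            raise ValueError("saturation_cap must be positive when set")
        if self.amplitude_mode not in ("unit_area", "unit_amplitude", "histogram"):
            raise ValueError(f"unknown amplitude mode {self.amplitude_mode!r}")


def _resolve_extent(x, y, cfg: RenderConfig, pad: float):
    if cfg.extent is not None:
        return cfg.extent
    if len(x) == 0:
        return (0.0, 1.0, 0.0, 1.0)
    return (
        float(x.min() - pad),
        float(x.max() + pad),
        float(y.min() - pad),
        float(y.max() + pad),
    )


def render_cnlp(
    x, y, sigma=None, cfg: RenderConfig | None = None
) -> tuple[np.ndarray, tuple[float, float, float, float]]:
    """Render localizations into a 2-D image; returns ``(image, extent)``.

    Image axes follow matrix convention: row index = y (origin at the lower
    edge of the extent), column index = x; pixel (r, c) covers the half-open
    square ``[xmin + c*px, xmin + (c+1)*px) x [ymin + r*px, ...)``.

    Modes: ``unit_area`` Gaussians integrate to one each (image total equals
    the localization count for in-bounds points), ``unit_amplitude``
    Gaussians peak at one, ``histogram`` plain 2-D binning.  The display
    width is ``max(sigma, sigma_floor_nm)``; the saturation cap, when set,
    clips the final image.
    """
    if cfg is None:
        cfg = RenderConfig()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if sigma is None:
        sigma = np.full_like(x, max(cfg.sigma_floor_nm, 1.0))
    sigma = np.maximum(np.asarray(sigma, dtype=float), cfg.sigma_floor_nm)

    pad = 5.0 * (float(np.max(sigma)) if len(x) else 1.0)
    xmin, xmax, ymin, ymax = _resolve_extent(x, y, cfg, pad)
    px = cfg.pixel_nm
    ncol = max(int(np.ceil((xmax - xmin) / px)), 1)
    nrow = max(int(np.ceil((ymax - ymin) / px)), 1)
    img = np.zeros((nrow, ncol), dtype=np.float64)
    extent = (xmin, xmin + ncol * px, ymin, ymin + nrow * px)
    if len(x) == 0:
        return img.astype(np.float32), extent

    if cfg.amplitude_mode == "histogram":
        xe = xmin + px * np.arange(ncol + 1)
        ye = ymin + px * np.arange(nrow + 1)
        H, _, _ = np.histogram2d(y, x, bins=[ye, xe])
        img = H
    else:
        xc = xmin + (np.arange(ncol) + 0.5) * px
        yc = ymin + (np.arange(nrow) + 0.5) * px
        for xi, yi, si in zip(x, y, sigma):
            if si <= 0:
                raise ValueError("localization precision must be positive")
            # clip each Gaussian to +-5 sigma for speed
            c0 = max(int((xi - 5 * si - xmin) / px), 0)
            c1 = min(int((xi + 5 * si - xmin) / px) + 1, ncol)
            r0 = max(int((yi - 5 * si - ymin) / px), 0)
            r1 = min(int((yi + 5 * si - ymin) / px) + 1, nrow)
            if c0 >= c1 or r0 >= r1:
                continue
            gx = np.exp(-0.5 * ((xc[c0:c1] - xi) / si) ** 2)
            gy = np.exp(-0.5 * ((yc[r0:r1] - yi) / si) ** 2)
            patch = np.outer(gy, gx)
            if cfg.amplitude_mode == "unit_area":
                patch = patch * (px * px / (2.0 * np.pi * si * si))
            img[r0:r1, c0:c1] += patch

    if cfg.saturation_cap is not None:
        img = np.minimum(img, cfg.saturation_cap)
    return img.astype(np.float32), extent


def save_image(path, image: np.ndarray) -> None:
    """Write a 32-bit float TIFF."""
    import tifffile

    tifffile.imwrite(str(path), np.asarray(image, dtype=np.float32))


# ---------------------------------------------------------------------------
# tables

def read_locs(path) -> pd.DataFrame:
    """Read a localization table (TSV or CSV by extension).

    Raises a schema error naming the first missing mandatory column.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"localization table is missing column {col!r}")
    return df


def write_locs(df: pd.DataFrame, path) -> None:
    """Write a localization table; unknown columns are preserved."""
    path = Path(path)
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"localization table is missing column {col!r}")
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df.to_csv(path, sep=sep, index=False)


def write_traces(traces, path) -> None:
    """Write per-photon traces as TSV (one row per detected photon)."""
    frames = []
    for tr in traces:
        n = tr.L
        frames.append(
            pd.DataFrame(
                {
                    "trace_id": np.full(n, tr.trace_id),
                    "i": np.arange(1, n + 1),
                    "t_ms": tr.times_ms,
                    "x_nm": tr.centers[:, 0],
                    "y_nm": tr.centers[:, 1],
                    "E_nJ": tr.energies,
                    "R_nm": tr.radii,
                    "fwhm_nm": tr.fwhms,
                    "is_bg": tr.is_bg.astype(int),
                    "truth_x_nm": tr.truth[:, 0] if tr.truth is not None else np.nan,
                    "truth_y_nm": tr.truth[:, 1] if tr.truth is not None else np.nan,
                    "n_c": np.full(n, tr.n_c),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_traces(path):
    """Read traces written by :func:`write_traces` back into Trace objects."""
    from .localizer import Trace

    df = pd.read_csv(path, sep="\t")
    traces = []
    for tid, g in df.groupby("trace_id", sort=True):
        g = g.sort_values("i")
        traces.append(
            Trace(
                centers=g[["x_nm", "y_nm"]].to_numpy(),
                energies=g["E_nJ"].to_numpy(),
                radii=g["R_nm"].to_numpy(),
                fwhms=g["fwhm_nm"].to_numpy(),
                times_ms=g["t_ms"].to_numpy(),
                is_bg=g["is_bg"].to_numpy().astype(bool),
                n_c=int(g["n_c"].iloc[0]),
                truth=g[["truth_x_nm", "truth_y_nm"]].to_numpy(),
                trace_id=int(tid),
            )
        )
    return traces
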