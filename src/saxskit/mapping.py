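"""Per-q intensity maps, threshold segmentation, region profiles, peaks.

A planar scan becomes an image by sampling every position's absolute
profile at one q (nearest measured bin).  Regions are segmented by
closed-low/open-high intensity bands, mean profiles are computed per
region with a ±σ spread over positions, and characteristic peaks (e.g. the
myelin reflections near 1 nm⁻¹) are tabulated with parabolically refined
positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .profiles import ScatterProfile, UnitState
from .reduction import PlanarScan


@dataclass
class IntensityMap:
    grid: np.ndarray                   # 2D, cm⁻¹ sr⁻¹ (NaN where no position)
    q0: float                          # q actually sampled (bin center), nm⁻¹
    spacing_mm: tuple[float, float]    # (dy, dx) position spacing
    x: np.ndarray = None               # unique stage x per column
    y: np.ndarray = None               # unique stage y per row


@dataclass
class RegionSet:
    masks: list[np.ndarray]
    bands: list[tuple[float, float]]

    def __post_init__(self):
        for i, a in enumerate(self.masks):
            for b in self.masks[i + 1:]:
                if np.any(a & b):
                    raise ValueError("region masks must be pairwise disjoint")


def _raster_shape(positions: np.ndarray):
    xs = np.unique(positions[:, 0])
    ys = np.unique(positions[:, 1])
    return ys, xs


def scan_to_grid(scan: PlanarScan, values: np.ndarray) -> IntensityMap:
    """Arrange per-position values on the (y, x) stage raster."""
    ys, xs = _raster_shape(scan.positions)
    grid = np.full((len(ys), len(xs)), np.nan)
    iy = np.searchsorted(ys, scan.positions[:, 1])
    ix = np.searchsorted(xs, scan.positions[:, 0])
    grid[iy, ix] = values
    dy = float(np.min(np.diff(ys))) if len(ys) > 1 else 0.0
    dx = float(np.min(np.diff(xs))) if len(xs) > 1 else 0.0
    return IntensityMap(grid=grid, q0=np.nan, spacing_mm=(dy, dx), x=xs, y=ys)


def build_intensity_map(scan: PlanarScan, q0: float,
                        require_absolute: bool = True) -> IntensityMap:
    """Map of profile intensity at the measured bin nearest q0."""
    q = scan.q
    if q0 < q[0] or q0 > q[-1]:
        raise ValueError(f"q0={q0} outside scan q range [{q[0]}, {q[-1]}]")
    if require_absolute:
        for p in scan.profiles:
            p.require_state(UnitState.absolute)
    j = int(np.argmin(np.abs(q - q0)))
    vals = np.array([p.intensity[j] for p in scan.profiles])
    m = scan_to_grid(scan, vals)
    m.q0 = float(q[j])
    return m


def threshold_segment(imap: IntensityMap,
                      bands: list[tuple[float, float]]) -> RegionSet:
    """Assign cells to intensity bands: low ≤ value < high (closed/open)."""
    edges = sorted(bands)
    for (l1, h1), (l2, h2) in zip(edges, edges[1:]):
        if h1 > l2:
            raise ValueError(f"overlapping bands {(l1, h1)} and {(l2, h2)}")
    masks = []
    for lo, hi in bands:
        with np.errstate(invalid="ignore"):
            m = (imap.grid >= lo) & (imap.grid < hi)
        masks.append(m)
    return RegionSet(masks=masks, bands=list(bands))


def region_mean_profile(scan: PlanarScan, mask: np.ndarray) -> ScatterProfile:
    """Per-q mean over masked positions; sigma is the per-q standard
    deviation across those positions (±σ error bars, not standard error)."""
    ys, xs = _raster_shape(scan.positions)
    iy = np.searchsorted(ys, scan.positions[:, 1])
    ix = np.searchsorted(xs, scan.positions[:, 0])
    sel = mask[iy, ix]
    if not np.any(sel):
        raise ValueError("empty region mask")
    stack = np.stack([p.intensity for p, s in zip(scan.profiles, sel) if s])
    ref = scan.profiles[0]
    return ScatterProfile(q=ref.q, intensity=stack.mean(axis=0),
                          sigma=stack.std(axis=0, ddof=0),
                          unit_state=ref.unit_state,
                          provenance=[f"region mean over {stack.shape[0]} positions"])


def moving_average(y: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return y
    if width % 2 == 0:
        raise ValueError("smoothing width must be odd")
    kernel = np.ones(width) / width
    # edge-padded so peaks near the boundary are not pulled inward
    pad = width // 2
    yp = np.pad(y, pad, mode="edge")
    return np.convolve(yp, kernel, mode="valid")


def detect_peaks(profile: ScatterProfile, min_prominence: float,
                 smooth_width: int = 3, region: str = "") -> pd.DataFrame:
    """Local maxima above a prominence floor, parabolically refined.

    Returns a table with columns q_nm_inv, prominence, width_nm_inv,
    region; positions sorted ascending.  An empty table is a valid result.
    """
    q = profile.q
    if len(q) < 5:
        raise ValueError("profile too short for peak detection")
    y = np.asarray(profile.intensity, dtype=float)
    finite = np.isfinite(y)
    y = np.where(finite, y, np.nanmin(y[finite]) if finite.any() else 0.0)
    ys = moving_average(y, smooth_width)
    idx, props = signal.find_peaks(ys, prominence=min_prominence)
    rows = []
    dq = np.gradient(q)
    widths = signal.peak_widths(ys, idx, rel_height=0.5)[0] if len(idx) else []
    for k, i in enumerate(idx):
        # 3-point parabolic interpolation around the discrete maximum
        if 0 < i < len(q) - 1:
            y0, y1, y2 = ys[i - 1], ys[i], ys[i + 1]
            denom = y0 - 2 * y1 + y2
            delta = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
            delta = float(np.clip(delta, -0.5, 0.5))
        else:
            delta = 0.0
        qpos = float(np.interp(i + delta, np.arange(len(q)), q))
        rows.append({"q_nm_inv": qpos,
                     "prominence": float(props["prominences"][k]),
                     "width_nm_inv": float(widths[k] * dq[i]),
                     "region": region})
    table = pd.DataFrame(rows, columns=["q_nm_inv", "prominence",
                                        "width_nm_inv", "region"])
    return table.sort_values("q_nm_inv", ignore_index=True)
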