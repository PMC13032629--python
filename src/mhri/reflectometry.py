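"""ImageJ-style reflectivity measurement on 8-bit B-scans.

Implements the measurement protocol behind the macular-hole reflectivity
indices: conversion to 8-bit greyscale, straight-line brightness profiles
(min/mean/max along a rasterized segment), the five reflectivity indices, and
the minimum linear diameter (MLD) of the hole. Region placement is either
manual (explicit :class:`LineSegment` annotations, e.g. loaded from CSV) or
automatic via :func:`locate_regions_auto`, which detects the RPE band and the
central/paracentral brightness pattern at the hole base.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .synthetic_oct import IndexSet, NORMAL_RPE_LENGTH_UM, NORMAL_RPE_OFFSET_UM

__all__ = [
    "LineSegment",
    "ProfileStats",
    "ReflectivityMeasurement",
    "to_greyscale8",
    "profile_stats",
    "measure_reflectivity",
    "compute_indices",
    "locate_regions_auto",
    "measure_mld",
    "mld_from_edges",
    "read_segments_csv",
    "write_indices_csv",
]

#: ITU-R BT.601 luma weights — ImageJ's default RGB -> 8-bit conversion.
BT601_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class LineSegment:
    """A straight measurement line in pixel coordinates (row, col).

    ``width_px > 1`` averages intensities across perpendicular offsets (a
    "thick" line) before taking profile statistics.
    """

    start: tuple[int, int]
    stop: tuple[int, int]
    width_px: int = 1

    def __post_init__(self) -> None:
        if tuple(self.start) == tuple(self.stop):
            raise ValueError("zero-length segment: start == stop")
        if self.width_px < 1:
            raise ValueError("width_px must be >= 1")


@dataclass(frozen=True)
class ProfileStats:
    """Min/mean/max brightness along one sampled line."""

    mean_brightness: float
    min_brightness: float
    max_brightness: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ValueError("a profile needs at least 2 samples")
        if not (self.min_brightness <= self.mean_brightness <= self.max_brightness):
            raise ValueError("profile stats must satisfy min <= mean <= max")


@dataclass(frozen=True)
class ReflectivityMeasurement:
    """The four line profiles one scan contributes: central hyperreflective,
    both paracentral hyporeflective regions, and the normal-RPE reference."""

    central: ProfileStats
    paracentral_left: ProfileStats
    paracentral_right: ProfileStats
    normal_rpe: ProfileStats

    def __post_init__(self) -> None:
        if self.normal_rpe.mean_brightness <= 0:
            raise ValueError("normal-RPE reference brightness must be positive")


def to_greyscale8(image: np.ndarray, channel_weights=BT601_WEIGHTS) -> np.ndarray:
    """Convert a raster to an 8-bit single-channel image.

    Three-channel input is reduced by the weighted channel sum (default
    BT.601), rounded half-to-even and clamped to [0, 255]; single-channel
    8-bit input passes through unchanged.
    """
    arr = np.asarray(image)
    if arr.ndim == 2:
        if arr.dtype == np.uint8:
            return arr
        return np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    if arr.ndim == 3 and arr.shape[2] == 3:
        w = np.asarray(channel_weights, dtype=float)
        grey = arr.astype(float) @ w
        return np.clip(np.rint(grey), 0, 255).astype(np.uint8)
    raise ValueError(f"unsupported channel count: shape {arr.shape}")


def rasterize_line(r0: int, c0: int, r1: int, c1: int) -> tuple[np.ndarray, np.ndarray]:
    """Bresenham-style nearest-pixel rasterization of a segment.

    One sample per step of the major (longer) axis, endpoints included; the
    minor coordinate is the nearest pixel to the ideal line, exact half-pixel
    ties rounding away from the start. Deterministic and exactly specified so
    brute-force pixel walks can verify it.
    """
    dr, dc = r1 - r0, c1 - c0
    n_major = max(abs(dr), abs(dc))
    if n_major == 0:
        return np.array([r0]), np.array([c0])
    i = np.arange(n_major + 1, dtype=np.int64)

    def minor(m0: int, dm: int) -> np.ndarray:
        num = i * dm  # displacement numerator over denominator n_major
        # nearest integer, ties away from zero
        off = (2 * np.abs(num) + n_major) // (2 * n_major) * np.sign(num)
        return m0 + off

    return minor(r0, dr), minor(c0, dc)


def _sample_line(image: np.ndarray, segment: LineSegment) -> np.ndarray:
    """Per-sample intensities along the rasterized segment, averaged across
    ``width_px`` perpendicular integer offsets."""
    (r0, c0), (r1, c1) = segment.start, segment.stop
    H, W = image.shape
    for r, c in (segment.start, segment.stop):
        if not (0 <= r < H and 0 <= c < W):
            raise ValueError(f"segment endpoint ({r}, {c}) outside image bounds {image.shape}")
    rr, cc = rasterize_line(r0, c0, r1, c1)
    if segment.width_px == 1:
        return image[rr, cc].astype(float)
    # unit perpendicular direction, rounded per offset step
    dr, dc = r1 - r0, c1 - c0
    norm = float(np.hypot(dr, dc))
    pr, pc = -dc / norm, dr / norm
    half = (segment.width_px - 1) // 2
    offsets = range(-half, segment.width_px - half)
    stack = []
    for k in offsets:
        orr = np.clip(rr + int(round(k * pr)), 0, H - 1)
        occ = np.clip(cc + int(round(k * pc)), 0, W - 1)
        stack.append(image[orr, occ].astype(float))
    return np.mean(stack, axis=0)


def profile_stats(image: np.ndarray, segment: LineSegment) -> ProfileStats:
    """Min/mean/max of the brightness profile along a straight segment."""
    samples = _sample_line(np.asarray(image), segment)
    if samples.size < 2:
        raise ValueError("segment rasterizes to fewer than 2 samples")
    return ProfileStats(
        mean_brightness=float(samples.mean()),
        min_brightness=float(samples.min()),
        max_brightness=float(samples.max()),
        n_samples=int(samples.size),
    )


def measure_reflectivity(
    image: np.ndarray,
    central_seg: LineSegment,
    left_seg: LineSegment,
    right_seg: LineSegment,
    rpe_seg: LineSegment,
) -> ReflectivityMeasurement:
    """Profile statistics of the four measurement lines, sides kept separate."""
    img = np.asarray(image)
    return ReflectivityMeasurement(
        central=profile_stats(img, central_seg),
        paracentral_left=profile_stats(img, left_seg),
        paracentral_right=profile_stats(img, right_seg),
        normal_rpe=profile_stats(img, rpe_seg),
    )


def compute_indices(m: ReflectivityMeasurement) -> IndexSet:
    """Derive the five reflectivity indices from one measurement.

    Paracentral sides are aggregated as min across both sides for the minimum
    statistic and the arithmetic mean of the side means for the mean
    statistic. MHRI = central max / paracentral min; the CRI/PCRI indices
    normalize by the normal-RPE mean brightness.
    """
    rpe = m.normal_rpe.mean_brightness
    if rpe <= 0:
        raise ValueError("normal-RPE reference brightness must be positive")
    par_min = min(m.paracentral_left.min_brightness, m.paracentral_right.min_brightness)
    if par_min <= 0:
        raise ValueError("paracentral minimum brightness is zero: MHRI undefined")
    par_mean = 0.5 * (
        m.paracentral_left.mean_brightness + m.paracentral_right.mean_brightness
    )
    return IndexSet(
        cri_max=m.central.max_brightness / rpe,
        cri_mean=m.central.mean_brightness / rpe,
        pcri_min=par_min / rpe,
        pcri_mean=par_mean / rpe,
        mhri=m.central.max_brightness / par_min,
    )


class RegionDetectionError(RuntimeError):
    """Automatic region placement failed on this image."""


def _detect_band(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column RPE row (argmax of the smoothed column profile) and the
    per-column band brightness. Raises if no bright band is present."""
    img = np.asarray(image, dtype=float)
    sm = ndimage.gaussian_filter(img, sigma=2.0)
    rpe_row = np.argmax(sm, axis=0)
    col_max = sm[rpe_row, np.arange(img.shape[1])]
    col_med = np.median(sm, axis=0)
    if np.mean(col_max - col_med) < 15.0:
        raise RegionDetectionError("no bright horizontal band detected")
    # brightness sampled on the original image in a small vertical window
    # around the detected band centre, then laterally smoothed
    rows = np.clip(
        rpe_row[None, :] + np.arange(-2, 3)[:, None], 0, img.shape[0] - 1
    )
    b = img[rows, np.arange(img.shape[1])[None, :]].mean(axis=0)
    b = ndimage.uniform_filter1d(b, size=5)
    return rpe_row, b


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of True in a 1-D boolean mask."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return [(int(idx[i]), int(idx[i + 1])) for i in range(0, len(idx), 2)]


def locate_regions_auto(
    image: np.ndarray,
    lateral_scale_um: float,
    width_px: int = 5,
    margin_px: int = 1,
) -> tuple[LineSegment, LineSegment, LineSegment, LineSegment]:
    """Automatically place the four measurement segments on a B-scan.

    The RPE band is the per-column smoothed intensity maximum. On the band
    brightness profile, the central hyperreflective region is the contiguous
    above-median run nearest the detected hole, the paracentral regions are
    the below-median runs immediately flanking it, and the normal-RPE
    reference is placed >= 1500 µm from the hole centre (200 µm long).
    Detected runs are shrunk by ``margin_px`` to keep samples interior.
    Returns ``(central, left, right, normal_rpe)`` segments of ``width_px``.
    """
    img = to_greyscale8(image)
    rpe_row, b = _detect_band(img)
    med = float(np.median(b))
    hi_thr = med + 0.25 * (float(b.max()) - med)
    lo_thr = med - 0.25 * (med - float(b.min()))
    if b.max() - med < 8 or med - b.min() < 8:
        raise RegionDetectionError("band brightness shows no hole-base contrast")

    hi_runs = [r for r in _runs(b > hi_thr) if r[1] - r[0] >= 3]
    if not hi_runs:
        raise RegionDetectionError("no central hyperreflective region found")
    # central = brightest qualifying run (the hole base spike above the band)
    cen = max(hi_runs, key=lambda r: float(b[r[0] : r[1]].mean()))
    lo_runs = _runs(b < lo_thr)
    left = [r for r in lo_runs if r[1] <= cen[0] and cen[0] - r[1] <= 6]
    right = [r for r in lo_runs if r[0] >= cen[1] and r[0] - cen[1] <= 6]
    if not left or not right:
        raise RegionDetectionError("paracentral hyporeflective regions not found on both sides")
    left, right = left[-1], right[0]
    for name, (a, z) in (("central", cen), ("left", left), ("right", right)):
        if z - a < 2 * margin_px + 2:
            raise RegionDetectionError(f"detected {name} region too narrow")

    centre = 0.5 * (cen[0] + cen[1])
    off = int(round(NORMAL_RPE_OFFSET_UM / lateral_scale_um))
    length = max(2, int(round(NORMAL_RPE_LENGTH_UM / lateral_scale_um)))
    W = img.shape[1]
    ref_l = int(round(centre)) + off
    if ref_l + length > W:
        ref_l = int(round(centre)) - off - length
    if ref_l < 0 or ref_l + length > W:
        raise RegionDetectionError("image too narrow for a normal-RPE reference segment")
    ref = (ref_l, ref_l + length)

    def seg(interval: tuple[int, int], shrink: int) -> LineSegment:
        a, z = interval[0] + shrink, interval[1] - shrink
        return LineSegment(
            start=(int(rpe_row[a]), a), stop=(int(rpe_row[z - 1]), z - 1), width_px=width_px
        )

    segs = (seg(cen, margin_px), seg(left, margin_px), seg(right, margin_px), seg(ref, 0))
    cols = [(s.start[1], s.stop[1]) for s in segs[:3]]
    if not (cols[1][1] < cols[0][0] and cols[0][1] < cols[2][0]):
        raise RegionDetectionError("detected regions overlap")
    return segs


def mld_from_edges(left_col: int, right_col: int, lateral_scale_um: float) -> float:
    """MLD in micrometres from annotated inner-edge columns: the left edge's
    first gap column and the right edge's first tissue column."""
    if right_col <= left_col:
        raise ValueError("right edge column must exceed left edge column")
    return (right_col - left_col) * lateral_scale_um


def measure_mld(image: np.ndarray, lateral_scale_um: float) -> float:
    """Minimum linear diameter: the smallest lateral separation of the inner
    hole edges, measured on the inner-retina tissue mask above the RPE band.

    Raises if the band or the two edges cannot be found.
    """
    img = to_greyscale8(image).astype(float)
    rpe_row, _ = _detect_band(img)
    band_top = int(np.median(rpe_row)) - 4
    sub = img[: max(band_top, 1), :]
    if sub.size == 0 or float(sub.max() - sub.min()) < 10:
        raise RegionDetectionError("no retinal tissue found above the band")
    sub = ndimage.median_filter(sub, size=3)
    # midpoint of the fluid/tissue intensity modes; Otsu is unreliable here
    # because the dark vitreous dominates the histogram
    thr = 0.5 * (np.percentile(sub, 10) + np.percentile(sub, 90))
    tissue = sub > thr
    centre = img.shape[1] // 2
    best = None
    for row_mask in tissue:
        left_cols = np.flatnonzero(row_mask[:centre])
        right_cols = np.flatnonzero(row_mask[centre:])
        if left_cols.size == 0 or right_cols.size == 0:
            continue
        gap = (centre + right_cols[0]) - (left_cols[-1] + 1)
        if gap > 0 and (best is None or gap < best):
            best = gap
    if best is None:
        raise RegionDetectionError("fewer than two hole edges found")
    return float(best * lateral_scale_um)


def read_segments_csv(path: str | Path) -> dict[str, dict[str, LineSegment]]:
    """Read manual segment annotations.

    Expected columns: ``image_id, region, row0, col0, row1, col1`` with region
    in {central, paracentral_left, paracentral_right, normal_rpe}. Returns
    ``{image_id: {region: LineSegment}}``.
    """
    df = pd.read_csv(path)
    required = {"image_id", "region", "row0", "col0", "row1", "col1"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"annotation CSV missing columns: {sorted(missing)}")
    out: dict[str, dict[str, LineSegment]] = {}
    for _, r in df.iterrows():
        out.setdefault(str(r["image_id"]), {})[str(r["region"])] = LineSegment(
            start=(int(r["row0"]), int(r["col0"])), stop=(int(r["row1"]), int(r["col1"]))
        )
    return out


def write_indices_csv(rows: list[dict], path: str | Path) -> pd.DataFrame:
    """Write per-eye index rows (image_id, five indices, mld_um) to CSV."""
    df = pd.DataFrame(rows)
    cols = ["image_id", "cri_max", "cri_mean", "pcri_min", "pcri_mean", "mhri", "mld_um"]
    df = df[[c for c in cols if c in df.columns]]
    df.to_csv(path, index=False)
    return df


def indices_row(image_id: str, indices: IndexSet, mld_um: float | None = None) -> dict:
    row = {"image_id": image_id, **asdict(indices)}
    if mld_um is not None:
        row["mld_um"] = mld_um
    return row
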