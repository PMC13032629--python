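"""Synthetic macular-hole B-scan phantoms with exact ground truth.

A phantom is a single 8-bit greyscale B-scan (rows = axial depth, row 0 =
vitreous; columns = lateral position) containing the structures the
reflectivity indices are measured on:

* a bright horizontal RPE/Bruch's band,
* a full-thickness retinal defect (the hole) whose inner edges are elevated
  and whose narrowest inner-edge separation is the minimum linear diameter
  (MLD),
* at the hole base, on the band, a central hyperreflective region flanked on
  both sides by paracentral hyporeflective regions,
* unaffected ("normal") RPE far from the hole, used as the reference
  brightness.

All region intervals, the band row profile and the programmed intensities are
recorded in :class:`PhantomTruth`, so every measurement operation can be
tested against exact ground truth. Speckle is multiplicative Gamma noise
(unit mean, variance ``speckle_level**2``) smoothed to a finite grain size,
emulating the residual speckle of frame-averaged clinical SD-OCT scans.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

__all__ = [
    "PhantomConfigError",
    "IndexSet",
    "PhantomTruth",
    "PhantomConfig",
    "BScanPhantom",
    "generate_bscan",
    "annotate_segments",
    "write_phantom",
    "read_phantom",
]


class PhantomConfigError(ValueError):
    """A phantom configuration field is out of its valid range."""


@dataclass(frozen=True)
class IndexSet:
    """The five reflectivity indices for one eye/scan.

    cri_max / cri_mean: central max / mean brightness over normal-RPE mean.
    pcri_min / pcri_mean: paracentral min / mean brightness over normal-RPE
    mean (min taken across both sides; mean averaged across sides).
    mhri: central max over paracentral min — the headline index.
    """

    cri_max: float
    cri_mean: float
    pcri_min: float
    pcri_mean: float
    mhri: float

    def __post_init__(self) -> None:
        for name in ("cri_max", "cri_mean", "pcri_min", "pcri_mean", "mhri"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v}")

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


@dataclass(frozen=True)
class PhantomTruth:
    """Exact ground-truth annotations for one phantom.

    Column intervals are half-open ``[start, stop)``; coordinates are 0-based
    with rows increasing downward (deeper axially).
    """

    mld_um: float
    rpe_row_profile: tuple[int, ...]
    central_region_cols: tuple[int, int]
    paracentral_region_cols_left: tuple[int, int]
    paracentral_region_cols_right: tuple[int, int]
    normal_rpe_cols: tuple[int, int]
    true_max_central: int
    true_min_paracentral: int
    true_normal_rpe: int
    true_index_set: IndexSet

    def __post_init__(self) -> None:
        ivals = [
            self.paracentral_region_cols_left,
            self.central_region_cols,
            self.paracentral_region_cols_right,
        ]
        for a, b in ivals:
            if b <= a:
                raise ValueError(f"empty or inverted region interval [{a}, {b})")
        # pairwise disjoint, paracentral flanking central on either side
        if not (ivals[0][1] <= ivals[1][0] and ivals[1][1] <= ivals[2][0]):
            raise ValueError("regions must be disjoint with paracentral flanking central")
        expect = self.true_max_central / self.true_min_paracentral
        if abs(self.true_index_set.mhri - expect) > 1e-12:
            raise ValueError("true_index_set.mhri inconsistent with programmed intensities")


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry, intensity and noise parameters of a phantom.

    Intensities are 8-bit targets (0–255). ``speckle_level`` is the standard
    deviation of the unit-mean multiplicative speckle field before grain
    smoothing (0 = noise-free). Default scales are typical SD-OCT: 10 µm/px
    laterally, ~4 µm/px axially.
    """

    image_height_px: int = 256
    image_width_px: int = 512
    mld_um: float = 300.0
    lateral_scale_um: float = 10.0
    axial_scale_um: float = 3.9
    rpe_intensity: int = 180
    central_intensity: int = 210
    paracentral_intensity: int = 120
    background_intensity: int = 20
    inner_retina_intensity: int = 90
    edge_elevation_px: int = 10
    speckle_level: float = 0.0
    speckle_grain_sigma_px: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        if self.image_height_px <= 0:
            raise PhantomConfigError("image_height_px must be positive")
        if self.image_width_px <= 0:
            raise PhantomConfigError("image_width_px must be positive")
        if self.lateral_scale_um <= 0:
            raise PhantomConfigError("lateral_scale_um must be positive")
        if self.axial_scale_um <= 0:
            raise PhantomConfigError("axial_scale_um must be positive")
        if not self.mld_um > 0:
            raise PhantomConfigError("mld_um must be positive")
        if self.mld_um >= self.image_width_px * self.lateral_scale_um:
            raise PhantomConfigError("mld_um must be smaller than the image width")
        for name in (
            "rpe_intensity",
            "central_intensity",
            "paracentral_intensity",
            "background_intensity",
            "inner_retina_intensity",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise PhantomConfigError(f"{name} must lie in [0, 255], got {v}")
        if self.speckle_level < 0:
            raise PhantomConfigError("speckle_level must be non-negative")
        if self.edge_elevation_px < 0:
            raise PhantomConfigError("edge_elevation_px must be non-negative")
        if self.speckle_grain_sigma_px <= 0:
            raise PhantomConfigError("speckle_grain_sigma_px must be positive")


@dataclass(frozen=True)
class BScanPhantom:
    """An 8-bit B-scan raster plus pixel scales and exact truth."""

    pixels: np.ndarray  # uint8, (rows, cols)
    lateral_scale_um: float
    axial_scale_um: float
    truth: PhantomTruth

    def __post_init__(self) -> None:
        if self.pixels.dtype != np.uint8 or self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D uint8 array")
        if self.lateral_scale_um <= 0 or self.axial_scale_um <= 0:
            raise ValueError("pixel scales must be positive")


# Band half-thickness in pixels; the bright band spans 2*_BAND_HALF + 1 rows.
_BAND_HALF = 4
# How far (columns) the hole base darkness extends beyond the inner edges,
# i.e. under the elevated/overhanging hole edges.
_OVERHANG_PX = 12
# Lateral flare of the hole aperture (px per px of height above the MLD row).
_FLARE = 0.35
# Normal-RPE reference: distance of the segment start from the hole centre,
# and its length, in micrometres.
NORMAL_RPE_OFFSET_UM = 1500.0
NORMAL_RPE_LENGTH_UM = 200.0


def _derive_geometry(config: PhantomConfig) -> dict:
    H, W = config.image_height_px, config.image_width_px
    band_row = int(round(0.60 * H))
    band_top = band_row - _BAND_HALF
    center_col = W // 2
    mld_px = max(2, int(round(config.mld_um / config.lateral_scale_um)))
    gap_l = center_col - mld_px // 2
    gap_r = gap_l + mld_px
    base_l = gap_l - _OVERHANG_PX
    base_r = gap_r + _OVERHANG_PX
    cen_half = max(2, int(round(0.2 * mld_px)))
    cen_l, cen_r = center_col - cen_half, center_col + cen_half
    if not (base_l < cen_l and cen_r < base_r):
        raise PhantomConfigError("mld_um too small for the region layout at this lateral scale")
    ref_off = int(round(NORMAL_RPE_OFFSET_UM / config.lateral_scale_um))
    ref_len = max(2, int(round(NORMAL_RPE_LENGTH_UM / config.lateral_scale_um)))
    ref_l = center_col + ref_off
    ref_r = ref_l + ref_len
    if ref_r > W:
        ref_r = center_col - ref_off
        ref_l = ref_r - ref_len
        if ref_l < 0:
            raise PhantomConfigError("image_width_px too small to place a normal-RPE reference")
    ret_thickness = min(band_top - 4, max(30, int(round(290.0 / config.axial_scale_um))))
    if ret_thickness < config.edge_elevation_px + 6:
        raise PhantomConfigError("edge_elevation_px too large for the retinal thickness")
    return dict(
        band_row=band_row,
        band_top=band_top,
        center_col=center_col,
        mld_px=mld_px,
        gap_l=gap_l,
        gap_r=gap_r,
        base_l=max(0, base_l),
        base_r=min(W, base_r),
        cen_l=cen_l,
        cen_r=cen_r,
        ref_l=ref_l,
        ref_r=ref_r,
        ret_top=band_top - ret_thickness,
    )


def generate_bscan(config: PhantomConfig) -> BScanPhantom:
    """Render one macular-hole B-scan phantom.

    Noise-free pixels inside each annotated region equal the programmed
    intensity exactly; with ``speckle_level > 0`` the image is multiplied by a
    unit-mean correlated Gamma speckle field, rounded and clamped to [0, 255].
    Truth fields are exact regardless of noise, and identical (config, seed)
    pairs produce bit-identical images.
    """
    config.validate()
    g = _derive_geometry(config)
    H, W = config.image_height_px, config.image_width_px
    img = np.full((H, W), float(config.background_intensity))

    band_rows = slice(g["band_top"], g["band_row"] + _BAND_HALF + 1)
    img[band_rows, :] = config.rpe_intensity
    # choroid: dim tissue under the band
    img[g["band_row"] + _BAND_HALF + 1 :, :] = max(
        0, int(0.3 * config.rpe_intensity)
    )
    # hole-base reflectivity pattern on the band
    img[band_rows, g["base_l"] : g["base_r"]] = config.paracentral_intensity
    img[band_rows, g["cen_l"] : g["cen_r"]] = config.central_intensity

    # inner retina with a full-thickness defect; inner edges elevated so the
    # narrowest separation (the MLD) sits edge_elevation_px above the band
    e = config.edge_elevation_px
    rows = np.arange(g["ret_top"], g["band_top"])
    cols = np.arange(W)
    d = (g["band_top"] - 1) - rows  # height above the band top, per row
    # half-extra widening: flare above the MLD row, undercut below it
    extra = np.where(
        d >= e,
        np.round(_FLARE * (d - e)),
        np.round(1.0 * (e - d)).clip(max=_OVERHANG_PX - 1),
    ).astype(int)
    left_edge = g["gap_l"] - extra  # first column of the gap, per row
    right_edge = g["gap_r"] + extra  # first column of the right edge, per row
    in_gap = (cols[None, :] >= left_edge[:, None]) & (cols[None, :] < right_edge[:, None])
    retina = ~in_gap
    img[g["ret_top"] : g["band_top"], :][retina] = config.inner_retina_intensity

    if config.speckle_level > 0:
        rng = np.random.default_rng(config.seed)
        shape = 1.0 / config.speckle_level**2
        fld = rng.gamma(shape=shape, scale=1.0 / shape, size=img.shape)
        fld = ndimage.gaussian_filter(fld, sigma=config.speckle_grain_sigma_px)
        img = img * fld
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    rpe = config.rpe_intensity
    cen, par = config.central_intensity, config.paracentral_intensity
    truth = PhantomTruth(
        mld_um=g["mld_px"] * config.lateral_scale_um,
        rpe_row_profile=tuple([g["band_row"]] * W),
        central_region_cols=(g["cen_l"], g["cen_r"]),
        paracentral_region_cols_left=(g["base_l"], g["cen_l"]),
        paracentral_region_cols_right=(g["cen_r"], g["base_r"]),
        normal_rpe_cols=(g["ref_l"], g["ref_r"]),
        true_max_central=cen,
        true_min_paracentral=par,
        true_normal_rpe=rpe,
        true_index_set=IndexSet(
            cri_max=cen / rpe,
            cri_mean=cen / rpe,
            pcri_min=par / rpe,
            pcri_mean=par / rpe,
            mhri=cen / par,
        ),
    )
    return BScanPhantom(
        pixels=pixels,
        lateral_scale_um=config.lateral_scale_um,
        axial_scale_um=config.axial_scale_um,
        truth=truth,
    )


def annotate_segments(truth: PhantomTruth, width_px: int = 1):
    """Convert truth intervals into the four measurement line segments.

    Returns ``(central, paracentral_left, paracentral_right, normal_rpe)``
    :class:`~mhri.reflectometry.LineSegment` objects lying along the RPE band.
    Endpoint rows are taken from ``rpe_row_profile`` at the interval's first
    and last columns, so segments are exact on flat bands and a straight-line
    chord of the band otherwise.
    """
    from .reflectometry import LineSegment  # local import to avoid a cycle

    profile = truth.rpe_row_profile

    def seg(interval: tuple[int, int]) -> LineSegment:
        a, b = interval
        if b - a < 2:
            raise ValueError(f"region interval [{a}, {b}) too small to measure")
        return LineSegment(
            start=(profile[a], a), stop=(profile[b - 1], b - 1), width_px=width_px
        )

    return (
        seg(truth.central_region_cols),
        seg(truth.paracentral_region_cols_left),
        seg(truth.paracentral_region_cols_right),
        seg(truth.normal_rpe_cols),
    )


def write_phantom(phantom: BScanPhantom, path_base: str | Path) -> tuple[Path, Path]:
    """Write an 8-bit PNG plus a JSON sidecar (truth + pixel scales)."""
    base = Path(path_base)
    png_path = base.with_suffix(".png")
    json_path = base.with_suffix(".json")
    Image.fromarray(phantom.pixels, mode="L").save(png_path)
    payload = {
        "lateral_scale_um": phantom.lateral_scale_um,
        "axial_scale_um": phantom.axial_scale_um,
        "truth": asdict(phantom.truth),
    }
    json_path.write_text(json.dumps(payload, indent=1))
    return png_path, json_path


def read_phantom(path_base: str | Path) -> BScanPhantom:
    """Read a phantom written by :func:`write_phantom`."""
    base = Path(path_base)
    pixels = np.asarray(Image.open(base.with_suffix(".png")).convert("L"))
    payload = json.loads(base.with_suffix(".json").read_text())
    t = payload["truth"]
    truth = PhantomTruth(
        mld_um=t["mld_um"],
        rpe_row_profile=tuple(t["rpe_row_profile"]),
        central_region_cols=tuple(t["central_region_cols"]),
        paracentral_region_cols_left=tuple(t["paracentral_region_cols_left"]),
        paracentral_region_cols_right=tuple(t["paracentral_region_cols_right"]),
        normal_rpe_cols=tuple(t["normal_rpe_cols"]),
        true_max_central=t["true_max_central"],
        true_min_paracentral=t["true_min_paracentral"],
        true_normal_rpe=t["true_normal_rpe"],
        true_index_set=IndexSet(**t["true_index_set"]),
    )
    return BScanPhantom(
        pixels=pixels.astype(np.uint8),
        lateral_scale_um=payload["lateral_scale_um"],
        axial_scale_um=payload["axial_scale_um"],
        truth=truth,
    )
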