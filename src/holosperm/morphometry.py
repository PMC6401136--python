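"""Sperm-head segmentation and morphological parameters.

From an unwrapped, background-flattened phase map and its optical
thickness (OT) map the module measures, over the head region of interest:

* maximum phase and maximum OT (3×3-median-filtered, so isolated hot
  pixels do not bias the maximum),
* optical volume ``V = Σ OT·dx·dy`` — OT integrated over the projected
  area,
* surface area by Monge parameterization,
  ``S = Σ dxdy·sqrt(1 + G_x² + G_y²) + projected area``, where G_x, G_y
  are central-difference gradients of the height surface (the cell's
  underside is flat on the substrate, hence the projected-area term),
* sphericity ``Ψ = 4.84·V^(2/3)/S`` — 1 for a sphere, → 0 for a thin
  laminar disk.

Unit conventions (the upstream literature reports only relative
comparisons, so they are fixed explicitly here): OT maps are in nm,
pixel pitch in µm.  ``optical_volume`` returns V in the OT map's
area-units (µm²·nm for an nm map); surface area, S/V and sphericity are
computed on the µm-converted height surface, so S is in µm², S/V in 1/µm
and Ψ dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_opening, median_filter
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.morphology import disk

from .reconstruct import OpticalThicknessMap, PhaseMap

__all__ = [
    "HeadMask",
    "MorphFeatures",
    "segment_head",
    "max_phase",
    "optical_volume",
    "surface_area",
    "sphericity",
    "extract_morph_features",
]

#: Ψ prefactor: 4.84 ≈ π^(1/3)·6^(2/3), making Ψ(sphere) = 1 to 3 digits
SPHERICITY_COEF = 4.84

AREA_BOUNDS_PX = (200, 20000)


@dataclass
class HeadMask:
    """Binary head region of interest with provenance."""

    mask: np.ndarray
    provenance: str = "auto"  # auto | ground_truth

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())

    @property
    def centroid(self) -> tuple[float, float]:
        ys, xs = np.nonzero(self.mask)
        return float(ys.mean()), float(xs.mean())


@dataclass
class MorphFeatures:
    max_phase: float  # rad
    ot_max: float  # nm
    S: float  # µm²
    V: float  # µm²·nm (optical volume)
    S_over_V: float  # 1/µm (S over V in µm³)
    sphericity: float


def segment_head(
    pm: PhaseMap, area_bounds_px: tuple[int, int] = AREA_BOUNDS_PX
) -> HeadMask:
    """Isolate the head: Otsu threshold → opening → largest component.

    The phase map is 3×3 median filtered, thresholded by Otsu's method,
    opened with a radius-2 disk (which removes the thin tail), and the
    largest connected component within the plausibility bounds is kept;
    an area tie is broken in favour of the component with higher mean
    phase.  Because the threshold truncates the dome-shaped head at a
    finite phase level, the boundary is then recovered by extrapolating
    the component's fitted ellipse to the zero level: for a cap profile
    ``peak·sqrt(1 − ρ²)`` the support thresholded at ``thr`` is the true
    ellipse scaled by ``sqrt(1 − (thr/peak)²)``.  Raises
    ``ValueError("no head found")`` when nothing passes.
    """
    med = median_filter(pm.values, size=3)
    if np.ptp(med) == 0:
        raise ValueError("no head found: constant phase map")
    thr = threshold_otsu(med)
    bw = binary_opening(med > thr, structure=disk(2))
    lbl = label(bw)
    lo, hi = area_bounds_px
    best = None
    for rp in regionprops(lbl, intensity_image=med):
        if not lo <= rp.area <= hi:
            continue
        key = (rp.area, rp.intensity_mean)
        if best is None or key > best[0]:
            best = (key, rp)
    if best is None:
        raise ValueError("no head found: no component within plausibility bounds")
    rp = best[1]
    component = lbl == rp.label

    peak = float(med[component].max())
    if peak <= thr:
        return HeadMask(mask=component, provenance="auto")
    rho = float(np.sqrt(max(1.0 - (thr / peak) ** 2, 1e-3)))
    cy, cx = rp.centroid
    a_px = rp.axis_major_length / 2.0 / rho
    b_px = rp.axis_minor_length / 2.0 / rho
    # regionprops orientation: angle of the major axis from the row axis
    th = rp.orientation
    ny, nx = med.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    dxp, dyp = xx - cx, yy - cy
    xi = dxp * np.sin(th) + dyp * np.cos(th)
    eta = dxp * np.cos(th) - dyp * np.sin(th)
    ellipse = (xi / a_px) ** 2 + (eta / b_px) ** 2 <= 1.0
    mask = ellipse | component
    if not lo <= mask.sum() <= hi:
        mask = component
    return HeadMask(mask=mask, provenance="auto")


def _as_mask(mask) -> np.ndarray:
    m = np.asarray(getattr(mask, "mask", mask), bool)
    if not m.any():
        raise ValueError("head mask is empty")
    return m


def max_phase(pm: PhaseMap, mask) -> float:
    """Maximum of the 3×3-median-filtered phase within the head mask, rad."""
    m = _as_mask(mask)
    return float(median_filter(pm.values, size=3)[m].max())


def optical_volume(ot: OpticalThicknessMap, mask) -> float:
    """V = Σ_mask OT·dx·dy, in (OT units)·µm² — µm²·nm for an nm map."""
    m = _as_mask(mask)
    if m.shape != ot.values.shape:
        raise ValueError("mask and OT map shapes differ")
    return float(ot.values[m].sum() * ot.dx_um * ot.dy_um)


def _height_um(ot: OpticalThicknessMap) -> np.ndarray:
    if ot.units == "nm":
        return ot.values * 1e-3
    if ot.units in ("um", "µm"):
        return np.asarray(ot.values, dtype=float)
    raise ValueError(f"unsupported OT units: {ot.units!r}")


def surface_area(ot: OpticalThicknessMap, mask) -> float:
    """Monge surface area plus projected area over the head mask, µm².

    Gradients are central differences of the µm-converted OT surface with
    edge replication.
    """
    m = _as_mask(mask)
    z = np.pad(_height_um(ot), 1, mode="edge")
    gy, gx = np.gradient(z, ot.dy_um, ot.dx_um)
    gy, gx = gy[1:-1, 1:-1], gx[1:-1, 1:-1]
    px_area = ot.dx_um * ot.dy_um
    ds = px_area * np.sqrt(1.0 + gx**2 + gy**2)
    return float(ds[m].sum() + m.sum() * px_area)


def sphericity(S: float, V: float) -> float:
    """Ψ = 4.84·V^(2/3)/S for consistent units (V length³, S length²)."""
    if S <= 0:
        raise ValueError("surface area must be positive")
    if V < 0:
        raise ValueError("volume must be nonnegative")
    return float(SPHERICITY_COEF * V ** (2.0 / 3.0) / S)


def extract_morph_features(
    pm: PhaseMap, ot: OpticalThicknessMap, mask
) -> MorphFeatures:
    """Bundle the six morphological predictors for one cell."""
    m = _as_mask(mask)
    mp = max_phase(pm, m)
    ot_max = float(median_filter(ot.values, size=3)[m].max())
    V = optical_volume(ot, m)
    S = surface_area(ot, m)
    v_um3 = V * 1e-3 if ot.units == "nm" else V
    return MorphFeatures(
        max_phase=mp,
        ot_max=ot_max,
        S=S,
        V=V,
        S_over_V=float(S / v_um3) if v_um3 > 0 else float("inf"),
        sphericity=sphericity(S, v_um3),
    )
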