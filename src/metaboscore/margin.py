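"""Margin-versus-center stain quantification on brightfield RGB slides.

The pipeline: RGB -> optical density (Beer-Lambert) -> stain
deconvolution (Ruifrok-Johnston inversion) -> tissue / compartment
masks (1 mm invasive-margin band via Euclidean distance transform) ->
per-compartment DAB and hematoxylin areas -> margin ratio normalized to
the tumor center -> one-sample t-test of log2 ratios across slides.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage as ndi
from scipy import stats as sps
from skimage import morphology

#: Ruifrok-Johnston H-DAB optical-density unit vectors (rows).
RUIFROK_HEMATOXYLIN = (0.650, 0.704, 0.286)
RUIFROK_DAB = (0.268, 0.570, 0.776)


class GeometryError(ValueError):
    pass


class NoCenterError(GeometryError):
    """Tumor lies entirely within the margin band; slide must be excluded."""


class NonEvaluableSlideError(ValueError):
    """A compartment has no nuclei staining; ratios are undefined."""


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = float(np.linalg.norm(v))
    if n == 0:
        raise ValueError("zero stain vector")
    return v / n


@dataclass(frozen=True)
class StainMatrix:
    """Rows are unit OD vectors for hematoxylin, DAB and a residual stain."""

    hematoxylin: tuple = RUIFROK_HEMATOXYLIN
    dab: tuple = RUIFROK_DAB
    residual: Optional[tuple] = None

    def matrix(self) -> np.ndarray:
        h = _unit(self.hematoxylin)
        d = _unit(self.dab)
        if self.residual is None:
            r = np.cross(h, d)
            r = _unit(np.clip(r, 0.0, None)) if np.any(np.clip(r, 0, None)) else _unit(r)
        else:
            r = _unit(self.residual)
        m = np.vstack([h, d, r])
        if np.linalg.cond(m) > 1e6:
            raise ValueError("stain matrix is singular or nearly singular")
        return m


DEFAULT_STAIN_MATRIX = StainMatrix()


def rgb_to_od(image: np.ndarray, i0: float = 255.0, eps: float = 1e-6) -> np.ndarray:
    """Optical density per channel: OD = -log10((I + eps) / (I0 + eps))."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected an RGB image (H, W, 3), got shape {image.shape}")
    od = -np.log10((image.astype(float) + eps) / (i0 + eps))
    return np.clip(od, 0.0, None)


def od_to_rgb(od: np.ndarray, i0: float = 255.0, quantize: bool = True) -> np.ndarray:
    """Inverse of :func:`rgb_to_od`; quantizes to uint8 unless disabled."""
    intensity = i0 * np.power(10.0, -np.asarray(od, dtype=float))
    if not quantize:
        return intensity
    return np.clip(np.round(intensity), 0, 255).astype(np.uint8)


def deconvolve(od: np.ndarray, stain_matrix: StainMatrix = DEFAULT_STAIN_MATRIX) -> np.ndarray:
    """Per-pixel stain concentrations; negatives clipped to 0 after inversion.

    Channel order follows the matrix rows: hematoxylin, DAB, residual.
    """
    m = stain_matrix.matrix()
    conc = od @ np.linalg.inv(m)
    return np.clip(conc, 0.0, None)


def segment_tissue(image: np.ndarray, od_threshold: float = 0.15,
                   min_area_px: int = 64) -> np.ndarray:
    """Tissue mask: pixels whose total OD exceeds the background level,
    with small holes filled and specks removed."""
    od = rgb_to_od(image)
    mask = od.sum(axis=-1) > od_threshold
    if not mask.any():
        return mask
    mask = morphology.remove_small_holes(mask, max_size=min_area_px)
    mask = morphology.remove_small_objects(mask, max_size=min_area_px)
    return mask


@dataclass
class CompartmentMasks:
    tumor: np.ndarray
    margin: np.ndarray
    center: np.ndarray
    exclusion: np.ndarray
    margin_width_um: float
    microns_per_pixel: float

    def __post_init__(self) -> None:
        if np.any(self.margin & self.center):
            raise ValueError("margin and center overlap")
        if not np.array_equal(self.margin | self.center, self.tumor):
            raise ValueError("margin + center must partition the tumor")


def build_compartments(tumor_mask: np.ndarray, microns_per_pixel: float,
                       margin_width_um: float = 1000.0,
                       exclusion_mask: Optional[np.ndarray] = None) -> CompartmentMasks:
    """Split the tumor into an invasive-margin band and the center.

    The margin is every tumor pixel within ``margin_width_um`` (Euclidean
    distance, square pixels) of the nearest non-tumor pixel.  Tumor/image-
    border contacts carry no histological interface ("technical" cut
    edges), so the band adjacent to them is added to the exclusion mask
    instead of the margin.  Raises :class:`NoCenterError` if no center
    compartment remains.
    """
    tumor_mask = np.asarray(tumor_mask, dtype=bool)
    if microns_per_pixel <= 0:
        raise ValueError("microns_per_pixel must be > 0")
    if not tumor_mask.any():
        raise GeometryError("tumor mask is empty")
    margin_px = margin_width_um / microns_per_pixel

    # distance to nearest real (in-image) non-tumor pixel; the image edge
    # is NOT treated as an interface
    dist = ndi.distance_transform_edt(tumor_mask)
    margin = tumor_mask & (dist <= margin_px) if margin_width_um > 0 else np.zeros_like(tumor_mask)

    exclusion = np.zeros_like(tumor_mask) if exclusion_mask is None else np.asarray(exclusion_mask, dtype=bool).copy()
    border = np.zeros_like(tumor_mask)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    technical = tumor_mask & border
    if technical.any():
        dist_edge = ndi.distance_transform_edt(~technical)
        exclusion |= tumor_mask & (dist_edge <= margin_px)

    center = tumor_mask & ~margin
    if not center.any():
        raise NoCenterError(
            "tumor lies entirely within the margin band; no center compartment"
        )
    return CompartmentMasks(tumor=tumor_mask, margin=margin, center=center,
                            exclusion=exclusion, margin_width_um=margin_width_um,
                            microns_per_pixel=microns_per_pixel)


def detect_macrophages(dab_channel: np.ndarray, microns_per_pixel: float,
                       od_cutoff: float = 1.4,
                       size_range_um2: tuple[float, float] = (5.0, 800.0)) -> np.ndarray:
    """Flag saturated-DAB specks (macrophages) for exclusion.

    Connected components of pixels at or above ``od_cutoff`` whose mean
    DAB OD reaches the cutoff and whose area falls inside
    ``size_range_um2`` are returned as a mask.
    """
    candidate = np.asarray(dab_channel, dtype=float) >= od_cutoff
    if not candidate.any():
        return candidate
    labels, n = ndi.label(candidate)
    if n == 0:
        return np.zeros_like(candidate)
    areas_px = np.bincount(labels.ravel())[1:]
    areas_um2 = areas_px * microns_per_pixel ** 2
    means = ndi.mean(dab_channel, labels=labels, index=np.arange(1, n + 1))
    keep = (means >= od_cutoff) & (areas_um2 >= size_range_um2[0]) & (areas_um2 <= size_range_um2[1])
    mask = keep[labels - 1]
    mask[labels == 0] = False
    return mask


@dataclass
class CompartmentQuant:
    area_px: int
    marker_area_px: int
    nuclei_area_px: int
    marker_area_um2: float
    nuclei_area_um2: float
    marker_integrated_od: float
    nuclei_integrated_od: float
    ratio: float  # marker area / nuclei area


@dataclass
class SlideQuant:
    margin: CompartmentQuant
    center: CompartmentQuant
    normalized_margin_ratio: float
    dab_threshold: float
    hema_threshold: float
    microns_per_pixel: float
    params: dict = field(default_factory=dict)


def _quantify_compartment(conc: np.ndarray, mask: np.ndarray, mpp: float,
                          dab_threshold: float, hema_threshold: float) -> CompartmentQuant:
    hema = conc[..., 0]
    dab = conc[..., 1]
    marker = int(((dab >= dab_threshold) & mask).sum())
    nuclei = int(((hema >= hema_threshold) & mask).sum())
    ratio = marker / nuclei if nuclei > 0 else math.nan
    return CompartmentQuant(
        area_px=int(mask.sum()),
        marker_area_px=marker,
        nuclei_area_px=nuclei,
        marker_area_um2=marker * mpp ** 2,
        nuclei_area_um2=nuclei * mpp ** 2,
        marker_integrated_od=float(dab[mask].sum()),
        nuclei_integrated_od=float(hema[mask].sum()),
        ratio=ratio,
    )


def quantify(image: np.ndarray, masks: CompartmentMasks,
             stain_matrix: StainMatrix = DEFAULT_STAIN_MATRIX,
             dab_threshold: float = 0.30, hema_threshold: float = 0.20) -> SlideQuant:
    """Per-compartment stain areas and the center-normalized margin ratio.

    Exclusions are removed from both compartments before counting.  A
    compartment with zero nuclei area makes the slide non-evaluable.
    """
    conc = deconvolve(rgb_to_od(image), stain_matrix)
    mpp = masks.microns_per_pixel
    margin_eff = masks.margin & ~masks.exclusion
    center_eff = masks.center & ~masks.exclusion
    qm = _quantify_compartment(conc, margin_eff, mpp, dab_threshold, hema_threshold)
    qc = _quantify_compartment(conc, center_eff, mpp, dab_threshold, hema_threshold)
    if qm.nuclei_area_px == 0 or qc.nuclei_area_px == 0:
        raise NonEvaluableSlideError("a compartment has zero nuclei area")
    return SlideQuant(
        margin=qm, center=qc,
        normalized_margin_ratio=qm.ratio / qc.ratio if qc.ratio > 0 else math.nan,
        dab_threshold=dab_threshold, hema_threshold=hema_threshold,
        microns_per_pixel=mpp,
    )


@dataclass
class MarginTestResult:
    mean_log2_ratio: float
    t: float
    df: int
    pvalue: float
    n: int
    degenerate_variance: bool = False


def margin_center_test(normalized_ratios: Sequence[float]) -> MarginTestResult:
    """One-sample two-sided t-test of log2(normalized margin ratio) vs 0.

    Degenerate zero-variance input: t = 0 and p = 1 when the mean is
    also 0, otherwise p is reported as the smallest positive float with
    a degenerate-variance flag.
    """
    ratios = np.asarray(normalized_ratios, dtype=float)
    if len(ratios) < 3:
        raise ValueError("margin/center test needs >= 3 evaluable slides")
    if (ratios <= 0).any():
        raise ValueError("normalized ratios must be > 0")
    logs = np.log2(ratios)
    n = len(logs)
    mean = float(logs.mean())
    sd = float(logs.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return MarginTestResult(0.0, 0.0, n - 1, 1.0, n, degenerate_variance=True)
        return MarginTestResult(mean, math.inf if mean > 0 else -math.inf, n - 1,
                                np.finfo(float).tiny, n, degenerate_variance=True)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), df=n - 1))
    return MarginTestResult(mean, float(t), n - 1, min(p, 1.0), n)
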