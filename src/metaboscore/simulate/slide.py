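"""Synthetic H-DAB-like brightfield slides with pixel-level ground truth.

A tumor disc (optionally perturbed into a blob) sits on a near-white
background.  Every tumor pixel carries hematoxylin; a per-compartment
Bernoulli fraction of tumor pixels carries moderate DAB
(``dab_fraction_center`` in the center, scaled by ``margin_effect`` in
the 1 mm margin band).  Macrophages are small saturated-DAB discs
seeded uniformly over the tumor; artefacts are rectangular gray
regions.  Colors are composed in optical-density space (Beer-Lambert)
from the stain matrix and quantized to 8-bit RGB.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np
from scipy import ndimage as ndi

from ..margin import DEFAULT_STAIN_MATRIX, GeometryError, StainMatrix, od_to_rgb

#: DAB OD of tumor-cell staining vs the saturated macrophage range; a
#: cutoff between the two lets detection isolate macrophages
TUMOR_DAB_OD = (0.5, 1.1)
MACROPHAGE_DAB_OD = (1.6, 2.2)


@dataclass
class SlideParams:
    image_size: tuple[int, int] = (512, 512)  # (H, W) pixels
    microns_per_pixel: float = 8.0
    tumor_radius_um: float = 1500.0
    tumor_shape: str = "disc"  # "disc" or "blob"
    blob_amplitude: float = 0.1  # radial perturbation fraction for blobs
    margin_width_um: float = 1000.0
    dab_fraction_center: float = 0.2
    margin_effect: float = 2.0
    macrophage_density: float = 0.0  # speckles per mm^2 of tumor
    macrophage_radius_um: tuple[float, float] = (3.0, 8.0)
    artefacts: Sequence[tuple[int, int, int, int]] = field(default_factory=list)  # (r0,c0,r1,c1) px
    hema_od: float = 0.6
    stain_matrix: StainMatrix = field(default_factory=StainMatrix)
    seed: int = 0

    def validate(self) -> None:
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be > 0")
        if not (0.0 <= self.dab_fraction_center <= 1.0):
            raise ValueError("dab_fraction_center must be in [0,1]")
        if self.margin_effect <= 0:
            raise ValueError("margin_effect must be > 0")
        if self.dab_fraction_center * self.margin_effect > 1.0 + 1e-12:
            raise ValueError("dab_fraction_center * margin_effect must be <= 1")
        m = self.stain_matrix.matrix()
        if (m[:2] < -1e-9).any():
            raise ValueError("stain vectors must have nonnegative components")
        h, w = self.image_size
        r_px = self.tumor_radius_um / self.microns_per_pixel
        pad = 1.0 + self.blob_amplitude if self.tumor_shape == "blob" else 1.0
        if 2 * r_px * pad + 4 > min(h, w):
            raise GeometryError(
                f"image {self.image_size} too small for a {self.tumor_radius_um} um tumor "
                f"at {self.microns_per_pixel} um/px"
            )
        if self.margin_width_um / self.microns_per_pixel < 1.0 and self.margin_width_um > 0:
            raise GeometryError("margin band narrower than one pixel at this resolution")


@dataclass
class SlideTruth:
    microns_per_pixel: float
    tumor_mask: np.ndarray
    margin_mask: np.ndarray
    center_mask: np.ndarray
    dab_mask: np.ndarray
    macrophage_mask: np.ndarray
    artefact_mask: np.ndarray
    tissue_mask: np.ndarray
    true_normalized_margin_ratio: float
    realized_normalized_margin_ratio: float
    dab_fraction_center: float
    margin_effect: float
    params: dict = field(default_factory=dict)


class SlideResult(NamedTuple):
    image: np.ndarray
    truth: SlideTruth


def _tumor_mask(params: SlideParams, rng: np.random.Generator) -> np.ndarray:
    h, w = params.image_size
    r_px = params.tumor_radius_um / params.microns_per_pixel
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    rr = np.hypot(dy, dx)
    if params.tumor_shape == "disc":
        return rr <= r_px
    if params.tumor_shape == "blob":
        theta = np.arctan2(dy, dx)
        radius = np.full_like(rr, r_px)
        for k in range(2, 6):  # low-order harmonics keep the boundary smooth
            amp = params.blob_amplitude * r_px * rng.uniform(0.2, 1.0) / (k - 1)
            phase = rng.uniform(0, 2 * math.pi)
            radius = radius + amp * np.cos(k * theta + phase)
        return rr <= radius
    raise ValueError(f"unknown tumor_shape {params.tumor_shape!r}")


def generate_slide(params: SlideParams) -> SlideResult:
    """Render one synthetic slide and its ground-truth masks."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.image_size
    mpp = params.microns_per_pixel

    tumor = _tumor_mask(params, rng)
    margin_px = params.margin_width_um / mpp
    dist = ndi.distance_transform_edt(tumor)
    margin = tumor & (dist <= margin_px) if params.margin_width_um > 0 else np.zeros_like(tumor)
    center = tumor & ~margin

    # DAB-positive tumor pixels, per-compartment Bernoulli
    f_center = params.dab_fraction_center
    f_margin = min(1.0, f_center * params.margin_effect)
    u = rng.random((h, w))
    dab_mask = (center & (u < f_center)) | (margin & (u < f_margin))

    # macrophages: saturated-DAB discs uniform over the tumor
    macro = np.zeros((h, w), dtype=bool)
    tumor_area_mm2 = tumor.sum() * (mpp / 1000.0) ** 2
    n_macro = rng.poisson(params.macrophage_density * tumor_area_mm2)
    if n_macro > 0:
        ty, tx = np.nonzero(tumor)
        idx = rng.integers(0, len(ty), size=n_macro)
        for cy, cx in zip(ty[idx], tx[idx]):
            r_um = rng.uniform(*params.macrophage_radius_um)
            r = max(1.0, r_um / mpp)
            ri = int(math.ceil(r))
            y0, y1 = max(0, cy - ri), min(h, cy + ri + 1)
            x0, x1 = max(0, cx - ri), min(w, cx + ri + 1)
            yy, xx = np.mgrid[y0:y1, x0:x1]
            macro[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r

    artefact = np.zeros((h, w), dtype=bool)
    for (r0, c0, r1, c1) in params.artefacts:
        artefact[max(r0, 0):min(r1, h), max(c0, 0):min(c1, w)] = True

    # --- compose in OD space -------------------------------------------------
    hema_c = np.zeros((h, w))
    dab_c = np.zeros((h, w))
    hema_c[tumor] = np.clip(rng.normal(params.hema_od, 0.05, size=int(tumor.sum())), 0.3, None)
    dab_c[dab_mask] = rng.uniform(*TUMOR_DAB_OD, size=int(dab_mask.sum()))
    dab_c[macro] = rng.uniform(*MACROPHAGE_DAB_OD, size=int(macro.sum()))

    m = params.stain_matrix.matrix()
    od = hema_c[..., None] * m[0] + dab_c[..., None] * m[1]
    od[artefact] = 0.5  # neutral gray smudge, equal OD in all channels
    od += rng.uniform(0.0, 0.004, size=od.shape)  # faint background noise
    image = od_to_rgb(od)

    # realized (pixel-count) normalized ratio; hema covers all tumor pixels,
    # so the DAB fraction per compartment is the compartment ratio
    dab_only = dab_mask & ~macro
    fm = dab_only[margin].mean() if margin.any() else math.nan
    fc = dab_only[center].mean() if center.any() else math.nan
    realized = fm / fc if (center.any() and fc > 0) else math.nan

    truth = SlideTruth(
        microns_per_pixel=mpp,
        tumor_mask=tumor, margin_mask=margin, center_mask=center,
        dab_mask=dab_mask, macrophage_mask=macro, artefact_mask=artefact,
        tissue_mask=tumor | artefact,
        true_normalized_margin_ratio=params.margin_effect,
        realized_normalized_margin_ratio=float(realized),
        dab_fraction_center=f_center, margin_effect=params.margin_effect,
        params={k: v for k, v in asdict(params).items() if k != "stain_matrix"},
    )
    return SlideResult(image=image, truth=truth)


def write_slide(result: SlideResult, out_dir, stem: str = "slide") -> dict:
    """Write the TIFF image, PNG mask sidecars and a JSON sidecar.

    Returns the paths written (strings).
    """
    import imageio.v3 as iio
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    img_path = out / f"{stem}.tif"
    tifffile.imwrite(img_path, result.image)
    paths["image"] = str(img_path)
    t = result.truth
    for name in ("tumor_mask", "margin_mask", "center_mask", "dab_mask",
                 "macrophage_mask", "artefact_mask"):
        p = out / f"{stem}_{name}.png"
        iio.imwrite(p, (getattr(t, name).astype(np.uint8) * 255))
        paths[name] = str(p)
    meta = {
        "microns_per_pixel": t.microns_per_pixel,
        "true_normalized_margin_ratio": t.true_normalized_margin_ratio,
        "realized_normalized_margin_ratio": t.realized_normalized_margin_ratio,
        "dab_fraction_center": t.dab_fraction_center,
        "margin_effect": t.margin_effect,
        "params": t.params,
    }
    meta_path = out / f"{stem}.json"
    meta_path.write_text(json.dumps(meta, indent=2))
    paths["meta"] = str(meta_path)
    return paths
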