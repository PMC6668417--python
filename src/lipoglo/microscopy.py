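"""Whole-larva chemiluminescence quantification.

Fixed larvae mounted with luciferase substrate are imaged twice with no
illumination (10 s and 30 s exposures).  Signal within user-supplied
viscera / trunk / head regions of interest is quantified from the 30 s
frame unless it contains saturated in-mask pixels, in which case the 10 s
frame is used.  Output is the fraction of in-mask signal per region —
relative quantification, robust to overall brightness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

REGIONS = ("viscera", "trunk", "head")
REGION_LABELS = {"viscera": 1, "trunk": 2, "head": 3}


@dataclass
class LarvaImageStack:
    """Short (10 s) and long (30 s) chemiluminescent exposures of one larva."""

    short_exposure: np.ndarray
    long_exposure: np.ndarray
    bit_ceiling: int = 65535
    larva_id: str = "larva"

    def __post_init__(self) -> None:
        self.short_exposure = np.asarray(self.short_exposure)
        self.long_exposure = np.asarray(self.long_exposure)
        if self.short_exposure.shape != self.long_exposure.shape:
            raise ValueError("exposures must have the same shape")
        for img in (self.short_exposure, self.long_exposure):
            if img.ndim != 2:
                raise ValueError("exposures must be 2-D")
            if img.min() < 0 or img.max() > self.bit_ceiling:
                raise ValueError("intensities must lie in [0, bit_ceiling]")


@dataclass
class RegionQuant:
    """Fractions of in-mask signal per region, and which exposure was used."""

    fractions: dict[str, float]
    exposure_used: str
    larva_id: str = "larva"

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"region fractions must sum to 1 (got {total})")


def _check_masks(masks: np.ndarray) -> np.ndarray:
    masks = np.asarray(masks)
    if masks.ndim != 2:
        raise ValueError("mask label image must be 2-D")
    labels = set(np.unique(masks).tolist())
    if not labels <= {0, 1, 2, 3}:
        raise ValueError(f"mask labels must be subset of {{0,1,2,3}}, got {sorted(labels)}")
    return masks


def select_exposure(stack: LarvaImageStack, masks: np.ndarray) -> tuple[np.ndarray, str]:
    """Pick the exposure to quantify.

    The long (30 s) exposure is used iff no pixel inside the union of the
    region masks has reached the bit ceiling; otherwise the short (10 s)
    exposure.  If the short exposure is saturated in-mask as well, the
    larva's dynamic range is exceeded and the stack is rejected.  Saturated
    pixels *outside* the masks (e.g. hot pixels off the larva) are ignored.
    """
    masks = _check_masks(masks)
    if masks.shape != stack.long_exposure.shape:
        raise ValueError("mask shape must match image shape")
    in_mask = masks > 0
    if not np.any(stack.long_exposure[in_mask] >= stack.bit_ceiling):
        return stack.long_exposure, "long"
    if not np.any(stack.short_exposure[in_mask] >= stack.bit_ceiling):
        return stack.short_exposure, "short"
    raise ValueError("dynamic range exceeded: both exposures saturated in-mask")


def quantify_regions(
    image: np.ndarray, masks: np.ndarray, exposure_used: str = "long", larva_id: str = "larva"
) -> RegionQuant:
    """Per-region intensity sums normalized to the three-region total.

    ``masks`` is a label image (0 background, 1 viscera, 2 trunk, 3 head);
    background pixels are ignored.  An all-zero in-mask total is rejected.
    """
    image = np.asarray(image, dtype=float)
    masks = _check_masks(masks)
    if masks.shape != image.shape:
        raise ValueError("mask shape must match image shape")
    sums = np.bincount(masks.ravel(), weights=image.ravel(), minlength=4)
    total = float(sums[1:4].sum())
    if total <= 0:
        raise ValueError("empty larva: no in-mask signal")
    fractions = {region: float(sums[lab]) / total for region, lab in REGION_LABELS.items()}
    return RegionQuant(fractions=fractions, exposure_used=exposure_used, larva_id=larva_id)


def quantify_larva(stack: LarvaImageStack, masks: np.ndarray) -> RegionQuant:
    """Exposure selection followed by region quantification."""
    image, label = select_exposure(stack, masks)
    return quantify_regions(image, masks, exposure_used=label, larva_id=stack.larva_id)
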