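"""Hormone-channel segmentation into disjoint per-type cell-area masks.

Each hormone channel (insulin, glucagon, somatostatin, PP) is thresholded
independently — Otsu by default, or a fixed per-channel threshold — and
pixels claimed by more than one channel are assigned to the single channel
with the highest threshold-normalized intensity, with a fixed tie-break
order (beta < alpha < delta < pp). The disjointness of the resulting masks
is what makes per-object composition well defined downstream.

The denominator of all area fractions is a tissue-parenchyma mask built from
the union of nuclear and hormone foregrounds, morphologically closed and
hole-filled. Which denominator the original quantification used is not
published, so the choice is recorded in the output metadata and alternatives
("section", "endocrine") are exposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.morphology import closing as grey_closing, disk as disk_selem, remove_small_objects

from .vslice import ChannelStack, CELL_TYPES, HORMONE_TO_TYPE


@dataclass
class SegmentationParams:
    """Tunable segmentation behavior.

    ``min_object_area`` (um^2) despeckles below roughly half a cell section.
    ``blank_contrast`` is the minimum foreground-background mean intensity
    separation for a channel to count as stained at all; below it the channel
    is treated as blank (empty mask, warning recorded) rather than letting a
    threshold split pure noise.
    """

    method: str = "otsu"  # "otsu" | "fixed"
    fixed_thresholds: dict[str, float] = field(default_factory=dict)
    min_object_area: float = 25.0  # um^2
    tissue_closing_radius: float = 20.0  # um
    blank_contrast: float = 0.2
    saturation_fraction: float = 0.5
    denominator: str = "tissue"  # "tissue" | "section" | "endocrine"


@dataclass
class MaskSet:
    """Disjoint per-type binary masks plus the tissue denominator mask."""

    masks: dict[str, np.ndarray]  # cell type -> bool raster
    tissue_mask: np.ndarray
    threshold_record: dict[str, dict]
    pixel_size: float

    def __post_init__(self) -> None:
        overlap = np.zeros_like(self.tissue_mask, dtype=np.uint8)
        for m in self.masks.values():
            overlap += m.astype(np.uint8)
        if np.any(overlap > 1):
            raise ValueError("per-type masks must be pairwise disjoint")

    @property
    def union(self) -> np.ndarray:
        out = np.zeros_like(self.tissue_mask, dtype=bool)
        for m in self.masks.values():
            out |= m
        return out


def _threshold_channel(
    img: np.ndarray, name: str, params: SegmentationParams
) -> tuple[np.ndarray, dict]:
    record: dict = {"channel": name, "method": params.method, "warnings": []}
    if params.method == "fixed":
        if name not in params.fixed_thresholds:
            raise KeyError(f"fixed threshold missing for channel {name!r}")
        t = float(params.fixed_thresholds[name])
    elif params.method == "otsu":
        if np.ptp(img) == 0:
            record["threshold"] = float(img.flat[0])
            record["warnings"].append("blank channel (constant intensity)")
            return np.zeros(img.shape, dtype=bool), record
        t = float(threshold_otsu(img))
    else:
        raise ValueError(f"unknown threshold method {params.method!r}")
    record["threshold"] = t
    fg = img > t
    if not fg.any():
        record["warnings"].append("blank channel (no pixel above threshold)")
        return fg, record
    contrast = float(img[fg].mean() - img[~fg].mean()) if (~fg).any() else np.inf
    record["contrast"] = contrast
    if params.method == "otsu" and contrast < params.blank_contrast:
        # Otsu always splits something; a tiny split means there is no
        # stained structure, only noise
        record["warnings"].append(
            f"blank channel (foreground/background contrast {contrast:.3f} "
            f"< {params.blank_contrast})"
        )
        return np.zeros(img.shape, dtype=bool), record
    if fg.mean() > params.saturation_fraction:
        record["warnings"].append(
            f"saturated channel ({100 * fg.mean():.1f}% foreground)"
        )
    return fg, record


def segment_channels(
    stack: ChannelStack, params: SegmentationParams | None = None
) -> MaskSet:
    """Convert hormone channels to disjoint per-type masks + tissue mask."""
    params = params or SegmentationParams()
    px = stack.pixel_size
    hormone_fg: dict[str, np.ndarray] = {}
    records: dict[str, dict] = {}
    norm: dict[str, np.ndarray] = {}
    for hormone, cell_type in HORMONE_TO_TYPE.items():
        img = np.asarray(stack.channels[hormone], dtype=np.float64)
        fg, rec = _threshold_channel(img, hormone, params)
        hormone_fg[cell_type] = fg
        records[hormone] = rec
        t = rec.get("threshold", 0.0)
        span = float(img.max() - t)
        norm[cell_type] = (img - t) / span if span > 0 else np.zeros_like(img)

    # contested pixels -> single winner by normalized intensity, fixed-order
    # tie-break (earlier type in CELL_TYPES wins ties)
    claim_count = np.zeros(stack.shape, dtype=np.uint8)
    for fg in hormone_fg.values():
        claim_count += fg.astype(np.uint8)
    contested = claim_count > 1
    masks = {t: fg & ~contested for t, fg in hormone_fg.items()}
    if contested.any():
        scores = np.stack(
            [np.where(hormone_fg[t], norm[t], -np.inf) for t in CELL_TYPES]
        )
        winner = np.argmax(scores, axis=0)  # argmax takes first max: tie-break
        for i, t in enumerate(CELL_TYPES):
            masks[t] |= contested & (winner == i)

    # despeckle: drop objects strictly smaller than the min area
    min_px = max(1, int(np.ceil(params.min_object_area / px**2)))
    if min_px > 1:
        masks = {
            t: remove_small_objects(m, max_size=min_px - 1, connectivity=2)
            for t, m in masks.items()
        }

    nuclei_fg = np.zeros(stack.shape, dtype=bool)
    if "nuclei" in stack.channels:
        nuclei_fg, rec = _threshold_channel(
            np.asarray(stack.channels["nuclei"], dtype=np.float64), "nuclei", params
        )
        records["nuclei"] = rec

    union = np.zeros(stack.shape, dtype=bool)
    for m in masks.values():
        union |= m
    tissue = union | nuclei_fg
    radius_px = int(round(params.tissue_closing_radius / px))
    if radius_px > 0 and tissue.any():
        padded = np.pad(tissue, radius_px)
        padded = grey_closing(padded, disk_selem(radius_px))
        tissue = padded[radius_px:-radius_px, radius_px:-radius_px]
    tissue = ndi.binary_fill_holes(tissue)
    tissue |= union  # type masks are inside tissue by construction

    return MaskSet(masks=masks, tissue_mask=tissue, threshold_record=records, pixel_size=px)


def area_fractions(
    maskset: MaskSet, denominator: str = "tissue"
) -> tuple[dict[str, float], dict]:
    """Per-type cell area as a percent of the denominator area.

    Returns the fractions and a metadata dict recording the denominator
    choice and its pixel count.

    Raises
    ------
    ValueError
        If the denominator mask is empty.
    """
    if denominator == "tissue":
        denom_px = int(maskset.tissue_mask.sum())
    elif denominator == "section":
        denom_px = int(maskset.tissue_mask.size)
    elif denominator == "endocrine":
        denom_px = int(maskset.union.sum())
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom_px == 0:
        raise ValueError(f"empty {denominator!r} denominator mask")
    fractions = {
        t: 100.0 * int(m.sum()) / denom_px for t, m in maskset.masks.items()
    }
    meta = {"denominator": denominator, "denominator_px": denom_px}
    return fractions, meta
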