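"""Particle detection, cropping, aggregate exclusion and binarization.

The workflow mirrors manual subtomogram processing: dark blobs are detected
in the full tomogram, each is cropped into a subtomogram of fixed lateral
size and full original depth, crops whose foreground touches a lateral face
of the box (aggregates or clipped particles) are excluded, and the
remainder are binarized with a global IsoData threshold followed by a
watershed separation and a central-component cleanup.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_isodata
from skimage.segmentation import watershed

from .types import BinaryParticle, Subtomogram, VoxelVolume

__all__ = ["detect_and_crop", "exclude_aggregates", "binarize",
           "NoThresholdError", "NoParticleError"]

logger = logging.getLogger(__name__)


class NoThresholdError(ValueError):
    """Raised when no threshold can be computed (constant image)."""


class NoParticleError(ValueError):
    """Raised when thresholding yields no foreground."""


def _remove_speckle(fg: np.ndarray, min_voxels: int) -> np.ndarray:
    """Drop connected components smaller than ``min_voxels``."""
    labels, n = ndi.label(fg)
    if n == 0:
        return fg
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return np.isin(labels, np.flatnonzero(sizes >= min_voxels))


def _foreground(data: np.ndarray, polarity: str) -> np.ndarray:
    """Global IsoData (iterative intermeans) threshold; dark or bright
    foreground according to the configured polarity (never guessed)."""
    if np.ptp(data) == 0:
        raise NoThresholdError("no threshold: image is constant")
    thr = threshold_isodata(data)
    return data < thr if polarity == "dark" else data > thr


def detect_and_crop(volume: VoxelVolume, crop_nm: float = 40.0,
                    polarity: str = "dark", min_voxels: int = 27) -> list[Subtomogram]:
    """Detect particles and crop one subtomogram per blob.

    Blobs are connected components of the thresholded foreground with at
    least ``min_voxels`` voxels. Each crop has lateral extent ``crop_nm``
    (rounded to an odd voxel count) centred on the blob's 2D-projection
    centroid, and keeps the full depth of the parent tomogram. Crops are
    clamped to the volume bounds, so blobs near the border yield off-centre
    crops (their particles then typically fail the aggregate screen).
    An empty tomogram yields an empty list.
    """
    vx = volume.voxel_size
    w = int(round(crop_nm / vx))
    w += (w + 1) % 2  # odd voxel count so the centre voxel is well defined
    half = w // 2
    try:
        fg = _foreground(volume.data, polarity)
    except NoThresholdError:
        logger.info("constant tomogram: no particles detected")
        return []
    if fg.mean() > 0.25:
        # thresholding a particle-free (noise-only) field labels ~half the
        # voxels foreground; sparse drop-cast scenes never come close
        logger.info("foreground fraction %.0f%% > 25%%: treating as no particles", 100 * fg.mean())
        return []
    fg = _remove_speckle(fg, min_voxels)
    labels, n = ndi.label(fg)
    if n == 0:
        logger.info("no particles detected")
        return []
    centroids = ndi.center_of_mass(fg, labels, range(1, n + 1))
    crops = []
    nz, ny, nx = volume.data.shape
    for i, (_, cy, cx) in enumerate(centroids):
        y0 = int(np.clip(round(cy) - half, 0, max(ny - w, 0)))
        x0 = int(np.clip(round(cx) - half, 0, max(nx - w, 0)))
        sub = volume.data[:, y0:y0 + w, x0:x0 + w]
        crops.append(Subtomogram(data=sub.copy(), voxel_size=vx,
                                 crop_origin=(0, y0, x0), source_id=i))
    return crops


def exclude_aggregates(sub: Subtomogram, polarity: str = "dark",
                       min_voxels: int = 27) -> Subtomogram:
    """Flag the subtomogram as excluded iff thresholded foreground touches
    any lateral (x or y) face of the crop box.

    Touching is evaluated on the lateral faces only -- the z extent is the
    full original depth -- and tangency (a single foreground voxel in the
    boundary layer) counts as touching. Small speckle below ``min_voxels``
    is removed before the test so noise does not trigger exclusions.
    """
    fg = _foreground(sub.data, polarity)
    fg = _remove_speckle(fg, min_voxels)
    touches = (fg[:, 0, :].any() or fg[:, -1, :].any()
               or fg[:, :, 0].any() or fg[:, :, -1].any())
    if touches:
        sub.excluded = True
        sub.exclusion_reason = "foreground touches lateral crop boundary (aggregate or clipped particle)"
    return sub


def binarize(sub: Subtomogram, polarity: str = "dark", min_voxels: int = 27,
             core_fraction: float = 0.5) -> BinaryParticle:
    """IsoData threshold + watershed + central-component cleanup.

    The global IsoData threshold binarizes the whole subtomogram (computed
    per subtomogram, not per slice); a watershed on the negated Euclidean
    distance transform separates touching blobs; the component containing
    (or nearest to) the crop centre is retained and everything outside it
    is zeroed.

    Watershed markers are the connected cores where the distance transform
    exceeds ``core_fraction`` of its maximum: touching particles of similar
    size have separate cores (their contact neck is shallow), while a
    single particle -- however plate-like -- keeps one core, so it is not
    shattered by the ripple of its own distance map the way naive
    local-maximum seeding would.
    """
    fg = _foreground(sub.data, polarity)
    fg = _remove_speckle(fg, min_voxels)
    if not fg.any():
        raise NoParticleError("no particle: thresholded foreground is empty")
    if fg.mean() > 0.5:
        raise NoParticleError(
            "no particle: foreground is the majority phase -- check the intensity polarity")

    distance = ndi.distance_transform_edt(fg)
    markers, n_markers = ndi.label(distance >= max(core_fraction * distance.max(), 1.0))
    if n_markers <= 1:
        labels, _ = ndi.label(fg)
    else:
        labels = watershed(-distance, markers, mask=fg)

    center = tuple(s // 2 for s in fg.shape)
    sel = labels[center]
    if sel == 0:  # centre voxel is background: take the label nearest to it
        ids = np.unique(labels)
        ids = ids[ids > 0]
        coms = ndi.center_of_mass(labels > 0, labels, ids)
        d2 = [sum((c - ctr) ** 2 for c, ctr in zip(com, center)) for com in coms]
        sel = int(ids[int(np.argmin(d2))])
    mask = labels == sel
    # watershed labels are connected by construction, but be defensive:
    comp, ncomp = ndi.label(mask)
    if ncomp > 1:
        sizes = ndi.sum_labels(mask, comp, range(1, ncomp + 1))
        mask = comp == (1 + int(np.argmax(sizes)))
    return BinaryParticle(mask=mask, voxel_size=sub.voxel_size,
                          source_id=sub.source_id, excluded=sub.excluded,
                          exclusion_reason=sub.exclusion_reason)
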