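"""Shape representations of the white-matter mask.

Three binary feature sets are derived from one probability map:

* **general structure** — every WM voxel (threshold at 0.5 by default);
* **skeleton** — the one-voxel-wide medial representation obtained by
  topology-preserving 3D thinning, a proxy for the interior fibre-network
  complexity;
* **surface** — WM voxels facing background (the WM/GM interface), a proxy
  for gyral/sulcal boundary shape.

The whole-brain sets are computed first and then masked into left and
right hemispheres, so a hemisphere skeleton is the restriction of the
whole-brain skeleton rather than a re-thinning of the hemisphere mask.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Literal

import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _skimage_skeletonize

from .volume_io import ProbabilityVolume, VolumeError, VoxelGrid

logger = logging.getLogger(__name__)

Hemisphere = Literal["left", "right", "whole"]

# Face / face+edge / face+edge+corner adjacency.
_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclasses.dataclass
class ShapeFeatureSet:
    """The three shape representations of one (hemi-)brain."""

    general: VoxelGrid
    skeleton: VoxelGrid
    surface: VoxelGrid
    hemisphere_label: Hemisphere

    def __post_init__(self) -> None:
        shapes = {self.general.shape, self.skeleton.shape, self.surface.shape}
        if len(shapes) != 1:
            raise VolumeError(f"feature sets disagree on shape: {shapes}")
        if np.any(self.skeleton.data & ~self.general.data):
            raise VolumeError("skeleton is not a subset of the general structure")
        if np.any(self.surface.data & ~self.general.data):
            raise VolumeError("surface is not a subset of the general structure")

    def counts(self) -> dict[str, int]:
        return {
            "skeleton": self.skeleton.count(),
            "surface": self.surface.count(),
            "general": self.general.count(),
        }


def binarize(prob: ProbabilityVolume, threshold: float = 0.5) -> VoxelGrid:
    """Threshold a probability map into a binary mask.

    A voxel is occupied when ``p >= threshold`` (ties occupied, so the
    plateau case is deterministic). The default threshold of 0.5 is the
    conventional WM-probability cut.
    """
    if not (0.0 < threshold < 1.0):
        raise VolumeError(f"threshold must lie in (0, 1), got {threshold}")
    mask = prob.data >= threshold
    if not mask.any():
        logger.warning("binarize produced an empty mask (threshold %.3g)", threshold)
    return VoxelGrid(data=mask, affine=prob.affine.copy())


def skeletonize_3d(mask: VoxelGrid) -> VoxelGrid:
    """Topology-preserving 3D thinning to a one-voxel-wide skeleton.

    Boundary voxels are removed in deterministic directional subiterations
    until only the centre lines remain (Lee's medial-axis thinning, with
    26-connected foreground and 6-connected background). The result is a
    subset of the input, preserves the number of 26-connected components
    and the Euler number, and contains no solid 2x2x2 block.

    Boundary case: thinning can erode a topologically trivial component
    (e.g. a large solid ball) down to nothing. Each such component is
    restored as its single deepest voxel (distance-transform argmax,
    deterministic), which is the correct zero-length skeleton.
    """
    skel = _skimage_skeletonize(mask.data).astype(bool)
    labels, n_comp = ndimage.label(mask.data, structure=_STRUCTS[26])
    if n_comp:
        surviving = np.unique(labels[skel])
        lost = np.setdiff1d(np.arange(1, n_comp + 1), surviving)
        if lost.size:
            edt = ndimage.distance_transform_edt(mask.data)
            for comp in lost:
                inside = labels == comp
                depth = np.where(inside, edt, -1.0)
                skel[np.unravel_index(np.argmax(depth), depth.shape)] = True
    return mask.with_data(skel)


def extract_surface(mask: VoxelGrid, background_connectivity: int = 6) -> VoxelGrid:
    """Foreground voxels with a background (or out-of-grid) neighbour.

    Equivalent to ``mask \\ erosion(mask)`` under the structuring element of
    the chosen adjacency; 6 (face adjacency) is the strictest and the
    default boundary definition.
    """
    try:
        struct = _STRUCTS[int(background_connectivity)]
    except (KeyError, TypeError, ValueError):
        raise VolumeError(
            f"background connectivity must be one of 6, 18, 26; "
            f"got {background_connectivity!r}"
        ) from None
    interior = ndimage.binary_erosion(mask.data, structure=struct, border_value=0)
    return mask.with_data(mask.data & ~interior)


def _left_right_axis(affine: np.ndarray) -> tuple[int, bool]:
    """Identify the voxel axis mapping onto world left-right.

    Returns ``(axis, flipped)`` where ``flipped`` is True when increasing
    voxel index runs right-to-left (negative world-x direction).
    """
    rot = np.asarray(affine, dtype=float)[:3, :3]
    xcomp = np.abs(rot[0])
    if np.all(xcomp == 0):
        raise VolumeError(
            "cannot identify the left-right axis from the affine; "
            "pass an explicit midline index"
        )
    axis = int(np.argmax(xcomp))
    return axis, bool(rot[0, axis] < 0)


def find_midline(mask: VoxelGrid, axis: int | None = None) -> int:
    """Sagittal split plane minimising foreground intersection.

    Candidate planes are restricted to the central 20% of the left-right
    axis (avoiding degenerate edge planes); ties go to the plane closest
    to the geometric centre, then to the smaller index.
    """
    if axis is None:
        axis, _ = _left_right_axis(mask.affine)
    n = mask.shape[axis]
    centre = n / 2.0
    lo = max(1, int(np.floor(n * 0.4)))
    hi = min(n - 1, int(np.ceil(n * 0.6)))
    other = tuple(i for i in range(3) if i != axis)
    plane_counts = mask.data.sum(axis=other)
    candidates = np.arange(lo, hi + 1)
    costs = plane_counts[candidates]
    order = np.lexsort((candidates, np.abs(candidates - centre), costs))
    return int(candidates[order[0]])


def split_hemispheres(
    mask: VoxelGrid, midline_index: int | str = "auto"
) -> tuple[VoxelGrid, VoxelGrid]:
    """Partition a mask into (left, right) hemisphere pieces.

    The two pieces are disjoint and their union is the input. The split
    plane itself belongs to the piece on its high-index side; with even
    symmetric grids the split is exactly mirror-symmetric. The side called
    "left" is resolved from the affine's world-x direction.
    """
    axis, flipped = _left_right_axis(mask.affine)
    if midline_index == "auto":
        mid = find_midline(mask, axis=axis)
    else:
        mid = int(midline_index)
        if not (0 <= mid <= mask.shape[axis]):
            raise VolumeError(
                f"midline index {mid} outside axis of length {mask.shape[axis]}"
            )
    low = [slice(None)] * 3
    high = [slice(None)] * 3
    low[axis] = slice(0, mid)
    high[axis] = slice(mid, None)
    low_piece = np.zeros_like(mask.data)
    high_piece = np.zeros_like(mask.data)
    low_piece[tuple(low)] = mask.data[tuple(low)]
    high_piece[tuple(high)] = mask.data[tuple(high)]
    # RAS convention: world x grows to the subject's right.
    left_arr, right_arr = (high_piece, low_piece) if flipped else (low_piece, high_piece)
    left = mask.with_data(left_arr)
    right = mask.with_data(right_arr)
    for name, piece in (("left", left), ("right", right)):
        if piece.count() == 0:
            logger.warning("%s hemisphere is empty after splitting", name)
    return left, right


def make_feature_set(
    prob: ProbabilityVolume,
    threshold: float = 0.5,
    surface_connectivity: int = 6,
    midline_index: int | str = "auto",
) -> dict[Hemisphere, ShapeFeatureSet]:
    """Build whole-brain, left and right :class:`ShapeFeatureSet`s.

    The whole-brain general structure, skeleton and surface are computed
    once; hemisphere feature sets are those sets masked by the hemisphere
    partition (so the hemisphere skeleton is not re-thinned).
    """
    general = binarize(prob, threshold=threshold)
    if general.count() == 0:
        raise VolumeError("empty WM mask: nothing above threshold")
    skeleton = skeletonize_3d(general)
    surface = extract_surface(general, background_connectivity=surface_connectivity)
    left_mask, right_mask = split_hemispheres(general, midline_index=midline_index)

    out: dict[Hemisphere, ShapeFeatureSet] = {
        "whole": ShapeFeatureSet(general, skeleton, surface, "whole")
    }
    for label, hemi in (("left", left_mask), ("right", right_mask)):
        hemi_data = hemi.data
        out[label] = ShapeFeatureSet(
            general=general.with_data(general.data & hemi_data),
            skeleton=skeleton.with_data(skeleton.data & hemi_data),
            surface=surface.with_data(surface.data & hemi_data),
            hemisphere_label=label,  # type: ignore[arg-type]
        )
    return out
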