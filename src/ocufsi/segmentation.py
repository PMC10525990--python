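"""Grayscale-to-binary segmentation of micrograph cross-sections.

Converts grayscale micrographs into clean tissue masks: global thresholding
(manual or Otsu), removal of small dark "artifact" speckle near tissue
boundaries, and extraction of tissue boundaries as closed pixel-edge
polylines.  The interactive corrections of a semi-automatic workflow are
replaced by two explicit parameters (minimum component size and maximum
artifact distance); interactive editing is out of scope.

Connectivity: 8-connectivity for tissue, 4-connectivity for background,
avoiding topological paradoxes at pixel corners.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .image import BinaryMask, GrayImage, LabelImage

_STRUCT8 = np.ones((3, 3), dtype=bool)


def binarize(gray: GrayImage, threshold: float | str = "otsu",
             tissue_is_dark: bool = True) -> BinaryMask:
    """Threshold a grayscale image into a tissue mask.

    With ``tissue_is_dark`` (the SBF-SEM polarity) pixels <= threshold are
    tissue; otherwise pixels >= threshold are.  ``threshold='otsu'`` selects
    the threshold automatically and raises on a constant image (no separable
    classes).  Idempotent on an already binary (two-level) input.
    """
    arr = gray.array
    if isinstance(threshold, str):
        if threshold != "otsu":
            raise ValueError(f"unknown automatic threshold {threshold!r}")
        if np.ptp(arr) == 0:
            raise ValueError("constant image: automatic threshold is undefined")
        thr = float(threshold_otsu(arr))
    else:
        thr = float(threshold)
    mask = arr <= thr if tissue_is_dark else arr >= thr
    return BinaryMask(array=mask, pixel_size_um=gray.pixel_size_um,
                      slice_thickness_um=gray.slice_thickness_um,
                      n_slices=gray.n_slices)


def remove_boundary_artifacts(mask: BinaryMask, min_component_px: int = 64,
                              max_artifact_distance_px: int = 5) -> BinaryMask:
    """Remove small speckle components lying near larger structures.

    Tissue (and background) components smaller than ``min_component_px``
    whose pixels lie within ``max_artifact_distance_px`` of a large component
    of the opposite phase are flipped to that phase.  Components at or above
    the size threshold are never modified; the operation is idempotent.
    """
    if min_component_px < 1:
        raise ValueError("min_component_px must be >= 1")
    out = mask.array.copy()
    for phase, struct in ((True, _STRUCT8), (False, None)):
        m = out == phase
        lab, n = ndimage.label(m, structure=struct)
        if n == 0:
            continue
        sizes = np.bincount(lab.ravel())
        small_ids = np.flatnonzero((sizes < min_component_px))
        small_ids = small_ids[small_ids > 0]
        if small_ids.size == 0:
            continue
        large = m & ~np.isin(lab, small_ids)
        # distance to the nearest pixel of a large same-phase structure's
        # boundary region; specks floating far from any structure are kept
        dist = ndimage.distance_transform_edt(~large)
        small = np.isin(lab, small_ids) & (dist <= max_artifact_distance_px + 1)
        out[small] = not phase
    return BinaryMask(array=out, pixel_size_um=mask.pixel_size_um,
                      slice_thickness_um=mask.slice_thickness_um,
                      n_slices=mask.n_slices)


def extract_boundaries(mask: BinaryMask) -> list[np.ndarray]:
    """Extract closed tissue-boundary polylines in micrometre coordinates.

    Each connected tissue component contributes one positively-oriented
    (counter-clockwise) outer polyline and one negatively-oriented polyline
    per hole.  Vertices lie on pixel edges, so polygon areas equal pixel
    counts times pixel area exactly.  An empty mask yields an empty list.
    """
    from shapely.geometry import box
    from shapely.ops import unary_union
    from shapely.geometry.polygon import orient

    m = mask.array
    if not np.any(m):
        return []
    px = mask.pixel_size_um
    rows, cols = np.nonzero(m)
    boxes = [box(c * px, r * px, (c + 1) * px, (r + 1) * px)
             for r, c in zip(rows, cols)]
    geom = unary_union(boxes)
    polys = [geom] if geom.geom_type == "Polygon" else list(geom.geoms)
    out: list[np.ndarray] = []
    for poly in polys:
        poly = orient(poly, sign=1.0)  # exterior CCW, holes CW
        out.append(np.asarray(poly.exterior.coords, dtype=float))
        for ring in poly.interiors:
            out.append(np.asarray(ring.coords, dtype=float))
    return out


def polyline_area(poly: np.ndarray) -> float:
    """Signed shoelace area of a closed polyline (um^2); CCW positive."""
    x, y = poly[:, 0], poly[:, 1]
    return 0.5 * float(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))


def mask_from_labels(label: LabelImage) -> BinaryMask:
    """Ground-truth tissue mask of a label image (for round-trip checks)."""
    return BinaryMask(array=label.tissue_mask(), pixel_size_um=label.pixel_size_um,
                      slice_thickness_um=label.slice_thickness_um,
                      n_slices=label.n_slices)
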