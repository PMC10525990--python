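"""Raster containers shared by the generator, segmentation and meshing stages.

Coordinate convention (inherited by every downstream module): pixel (0, 0) is
the first row/column of the array; x runs along columns and y along rows, both
in micrometres; the centre of pixel (row i, col j) is at
((j + 0.5) * pixel_size_um, (i + 0.5) * pixel_size_um).  Row 0 is the
anterior-chamber (inlet) side of the domain and the last row the Schlemm's
canal outlet side.  z runs across serial slices with spacing
slice_thickness_um.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

COORDINATE_CONVENTION = (
    "pixel (0,0) at array origin; x = column * pixel_size_um, "
    "y = row * pixel_size_um; pixel centers at (index + 0.5) * pixel_size_um; "
    "row 0 = anterior-chamber inlet side; z across slices"
)


class Label(IntEnum):
    """Tissue-compartment codes of a segmented cross-section."""

    BACKGROUND = 0          # anterior-chamber side fluid
    SC_LUMEN = 1
    INNER_WALL_CELL = 2
    BASEMENT_MEMBRANE = 3
    JCT_TISSUE = 4
    SCLERA = 5
    VACUOLE_INTERIOR = 6
    PORE = 7
    INTERTRABECULAR_SPACE = 8


#: Labels occupied by solid tissue (everything else is aqueous humor).
SOLID_LABELS = frozenset(
    {Label.INNER_WALL_CELL, Label.BASEMENT_MEMBRANE, Label.JCT_TISSUE, Label.SCLERA}
)
FLUID_LABELS = frozenset(set(Label) - SOLID_LABELS)


@dataclass
class LabelImage:
    """Integer-labeled raster of tissue compartments with physical geometry."""

    array: np.ndarray                      # (ny, nx) int labels
    pixel_size_um: float
    slice_thickness_um: float = 0.13
    n_slices: int = 2
    convention: str = COORDINATE_CONVENTION

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array)
        if self.array.ndim != 2:
            raise ValueError("LabelImage stores a 2-D cross-section")
        valid = {int(v) for v in Label}
        codes = set(np.unique(self.array).tolist())
        if not codes <= valid:
            raise ValueError(f"unknown label codes present: {sorted(codes - valid)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.array.shape

    @property
    def extent_um(self) -> tuple[float, float]:
        """(width, height) in micrometres; exactly shape * pixel size."""
        ny, nx = self.array.shape
        return (nx * self.pixel_size_um, ny * self.pixel_size_um)

    @property
    def slab_thickness_um(self) -> float:
        return self.n_slices * self.slice_thickness_um

    def tissue_mask(self) -> np.ndarray:
        """Boolean mask, True where the pixel is solid tissue."""
        out = np.zeros(self.array.shape, dtype=bool)
        for lab in SOLID_LABELS:
            out |= self.array == int(lab)
        return out

    def census(self) -> dict[Label, float]:
        """Fraction of pixels per label."""
        total = self.array.size
        return {lab: float(np.count_nonzero(self.array == int(lab))) / total
                for lab in Label}


@dataclass
class GrayImage:
    """Scalar (grayscale) raster with the same pixel geometry record."""

    array: np.ndarray
    pixel_size_um: float
    slice_thickness_um: float = 0.13
    n_slices: int = 2
    convention: str = COORDINATE_CONVENTION

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array, dtype=float)
        if not np.all(np.isfinite(self.array)):
            raise ValueError("grayscale image contains non-finite values")


@dataclass
class BinaryMask:
    """Boolean raster (True = tissue) with pixel geometry."""

    array: np.ndarray
    pixel_size_um: float
    slice_thickness_um: float = 0.13
    n_slices: int = 2
    convention: str = COORDINATE_CONVENTION

    def __post_init__(self) -> None:
        self.array = np.asarray(self.array).astype(bool)
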