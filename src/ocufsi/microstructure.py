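"""Synthetic segmented-micrograph generator for the JCT / Schlemm's canal
inner-wall complex.

The generator emulates a segmented serial block-face SEM cross-section of the
aqueous outflow tissue as a layered band construction: an anterior-chamber
fluid band, a juxtacanalicular tissue (JCT) band perforated by interconnected
intertrabecular spaces, the basement membrane, the inner-wall endothelial cell
layer carrying giant vacuoles (optionally with an open pore through the wall),
the Schlemm's canal (SC) lumen, and stiff scleral strips tethering both
lateral sides.  Every feature comes with ground truth so downstream stages
(segmentation, meshing, FSI, morphometry) can be tested against it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .image import (Label, LabelImage, GrayImage, SOLID_LABELS)


class PackingError(RuntimeError):
    """Raised when a requested stochastic object cannot be placed."""


@dataclass
class MicrostructureParams:
    """Geometry and sampling parameters of the synthetic cross-section.

    All lengths in micrometres.  Defaults define the standard desk-scale
    fixture: a ~20 um deep JCT under a single giant vacuole with an open
    1.3-um pore, at 0.05 um pixels (the native SBF-SEM resolution of
    0.0101 um remains selectable).
    """

    domain_width_um: float = 15.0
    domain_height_um: float | None = None   # derived from the bands if None
    pixel_size_um: float = 0.05
    n_slices: int = 2
    slice_thickness_um: float = 0.13
    ac_band_um: float = 2.0                 # anterior-chamber fluid inlet band
    jct_depth_um: float = 20.0
    basement_membrane_thickness_um: float = 0.5
    inner_wall_thickness_um: float = 1.5
    sc_lumen_height_um: float = 7.0
    n_vacuoles: int = 1
    vacuole_width_um: float = 7.0           # wall-parallel extent of the cavity
    vacuole_length_um: float = 4.5          # wall-normal extent of the cavity
    vacuole_size_sd: float = 0.10           # relative sd of sampled axes
    fraction_vacuoles_with_open_pore: float = 1.0
    pore_diameter_um: float = 1.3
    pore_areal_density_per_mm2: float = 292.0
    basal_opening_um: float = 0.6           # basement-membrane gap under a vacuole
    subendothelial_thickness_um: float = 2.0   # dense JCT under the BM
    funnel_width_um: float = 2.0            # opening through the dense layer
    intertrabecular_void_fraction: float = 0.55
    beam_length_um: float = 5.0             # trabecular beam major axis (mean)
    beam_thickness_um: float = 1.6          # trabecular beam minor axis (mean)
    min_feature_um: float = 0.8             # thinnest JCT beam kept
    sclera_length_um: float = 12.0
    sclera_strip_thickness_um: float = 1.5
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.domain_height_um is None:
            self.domain_height_um = (self.ac_band_um + self.jct_depth_um
                                     + self.basement_membrane_thickness_um
                                     + self.inner_wall_thickness_um
                                     + self.sc_lumen_height_um)
        self.validate()

    def validate(self) -> None:
        lengths = dict(
            domain_width_um=self.domain_width_um,
            domain_height_um=self.domain_height_um,
            pixel_size_um=self.pixel_size_um,
            slice_thickness_um=self.slice_thickness_um,
            ac_band_um=self.ac_band_um,
            jct_depth_um=self.jct_depth_um,
            basement_membrane_thickness_um=self.basement_membrane_thickness_um,
            inner_wall_thickness_um=self.inner_wall_thickness_um,
            sc_lumen_height_um=self.sc_lumen_height_um,
            pore_diameter_um=self.pore_diameter_um,
            basal_opening_um=self.basal_opening_um,
            subendothelial_thickness_um=self.subendothelial_thickness_um,
            funnel_width_um=self.funnel_width_um,
            beam_length_um=self.beam_length_um,
            beam_thickness_um=self.beam_thickness_um,
            sclera_length_um=self.sclera_length_um,
            sclera_strip_thickness_um=self.sclera_strip_thickness_um,
        )
        for name, v in lengths.items():
            if not v > 0:
                raise ValueError(f"{name} must be strictly positive, got {v}")
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if self.n_vacuoles < 0:
            raise ValueError("n_vacuoles must be >= 0")
        if not 0.0 <= self.fraction_vacuoles_with_open_pore <= 1.0:
            raise ValueError("fraction_vacuoles_with_open_pore must be in [0, 1]")
        if not 0.0 < self.intertrabecular_void_fraction < 1.0:
            raise ValueError("intertrabecular_void_fraction must be in (0, 1)")
        smallest = min(self.pore_diameter_um,
                       self.basement_membrane_thickness_um,
                       self.inner_wall_thickness_um,
                       self.basal_opening_um)
        if self.pixel_size_um > smallest / 4.0:
            raise ValueError(
                f"pixel_size_um={self.pixel_size_um} cannot resolve the smallest "
                f"feature ({smallest} um); need <= {smallest / 4.0}")

    # band edges (y, um, from the inlet side)
    @property
    def y_jct_base(self) -> float:
        return self.ac_band_um

    @property
    def y_bm_base(self) -> float:
        return self.ac_band_um + self.jct_depth_um

    @property
    def y_cell_base(self) -> float:
        return self.y_bm_base + self.basement_membrane_thickness_um

    @property
    def y_sc_base(self) -> float:
        return self.y_cell_base + self.inner_wall_thickness_um

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class VacuoleTruth:
    """Ground truth for one generated giant vacuole."""

    id: int
    center_x_um: float
    center_y_um: float          # wall-normal base of the cavity
    width_um: float             # rasterized wall-parallel extent
    length_um: float            # rasterized wall-normal extent
    has_open_pore: bool
    pore_diameter_um: float
    pore_x_um: float            # pore centre (apex of the dome)


def _grids(params: MicrostructureParams):
    px = params.pixel_size_um
    nx = int(round(params.domain_width_um / px))
    ny = int(round(params.domain_height_um / px))
    xc = (np.arange(nx) + 0.5) * px
    yc = (np.arange(ny) + 0.5) * px
    X, Y = np.meshgrid(xc, yc)
    return nx, ny, X, Y


def expected_pore_count(params: MicrostructureParams,
                        wall_length_um: float | None = None) -> float:
    """Expected number of inner-wall pores intersecting the imaged slab.

    The pore density is printed per mm^2 of inner wall; over a 2-D slab the
    expected count is density x (wall length x slab thickness), which keeps
    the units consistent.  For a single thin cross-section this is << 1, so
    pores in the fixture come from vacuoles flagged as open instead.
    """
    L = params.domain_width_um if wall_length_um is None else wall_length_um
    area_um2 = L * params.n_slices * params.slice_thickness_um
    return params.pore_areal_density_per_mm2 * area_um2 * 1e-6


def generate_microstructure(params: MicrostructureParams,
                            seed: int | None = None
                            ) -> tuple[LabelImage, list[VacuoleTruth]]:
    """Generate a labeled synthetic cross-section with per-vacuole truth.

    Deterministic under a fixed seed (``seed`` overrides
    ``params.rng_seed``).  Raises :class:`PackingError` naming the first
    vacuole that cannot be placed without overlap.
    """
    params.validate()
    rng = np.random.default_rng(params.rng_seed if seed is None else seed)
    px = params.pixel_size_um
    nx, ny, X, Y = _grids(params)
    lab = np.full((ny, nx), int(Label.JCT_TISSUE), dtype=np.int16)

    # --- layered bands -----------------------------------------------------
    lab[Y < params.y_jct_base] = int(Label.BACKGROUND)
    band_bm = (Y >= params.y_bm_base) & (Y < params.y_cell_base)
    lab[band_bm] = int(Label.BASEMENT_MEMBRANE)
    band_cell = (Y >= params.y_cell_base) & (Y < params.y_sc_base)
    lab[band_cell] = int(Label.INNER_WALL_CELL)
    lab[Y >= params.y_sc_base] = int(Label.SC_LUMEN)

    # --- scleral tether strips on both lateral sides -----------------------
    ts = params.sclera_strip_thickness_um
    y_top = params.y_sc_base
    y_bot = max(params.y_jct_base, y_top - params.sclera_length_um)
    sclera = ((X < ts) | (X > params.domain_width_um - ts)) \
        & (Y >= y_bot) & (Y < y_top)

    # --- place vacuoles on the inner wall ----------------------------------
    interior = np.zeros_like(lab, dtype=bool)
    truths: list[VacuoleTruth] = []
    iw = params.inner_wall_thickness_um
    margin = ts + 0.5 * iw + 0.5
    centers: list[float] = []
    vac_geoms = []
    for k in range(params.n_vacuoles):
        aw = 0.5 * params.vacuole_width_um * max(
            0.3, 1.0 + params.vacuole_size_sd * rng.standard_normal())
        al = params.vacuole_length_um * max(
            0.3, 1.0 + params.vacuole_size_sd * rng.standard_normal())
        lo, hi = margin + aw, params.domain_width_um - margin - aw
        placed = False
        for _ in range(200):
            if hi <= lo:
                break
            xc = float(rng.uniform(lo, hi))
            if all(abs(xc - c) > aw + g[0] + 1.0 for c, g in zip(centers, vac_geoms)):
                placed = True
                break
        if not placed:
            raise PackingError(
                f"vacuole {k} (width {2 * aw:.2f} um) cannot be placed without "
                f"overlap in a {params.domain_width_um} um wide domain")
        centers.append(xc)
        vac_geoms.append((aw, al))
        open_pore = bool(rng.random() < params.fraction_vacuoles_with_open_pore)
        truths.append(VacuoleTruth(
            id=k, center_x_um=xc, center_y_um=params.y_cell_base,
            width_um=2 * aw, length_um=al, has_open_pore=open_pore,
            pore_diameter_um=params.pore_diameter_um, pore_x_um=xc))

    for tr, (aw, al) in zip(truths, vac_geoms):
        xc, y0 = tr.center_x_um, params.y_cell_base
        # cavity: upper half-ellipse rooted at the cell-layer base
        cav = (((X - xc) / aw) ** 2 + ((Y - y0) / al) ** 2 <= 1.0) & (Y >= y0)
        # membrane shell: the cavity ellipse dilated by the wall thickness
        shell = (((X - xc) / (aw + iw)) ** 2 + ((Y - y0) / (al + iw)) ** 2 <= 1.0) \
            & (Y >= y0) & ~cav
        lab[shell & (lab == int(Label.SC_LUMEN))] = int(Label.INNER_WALL_CELL)
        lab[cav] = int(Label.VACUOLE_INTERIOR)
        interior |= cav
        # basal opening: slot through the basement membrane under the centre
        slot = (np.abs(X - xc) <= params.basal_opening_um / 2.0) & band_bm
        lab[slot] = int(Label.VACUOLE_INTERIOR)
        if tr.has_open_pore:
            pore = (np.abs(X - tr.pore_x_um) <= params.pore_diameter_um / 2.0) \
                & (lab == int(Label.INNER_WALL_CELL)) & (Y >= params.y_sc_base)
            lab[pore] = int(Label.PORE)

    # --- JCT: capacious intertrabecular space with scattered beams ----------
    # The JCT band is open aqueous space crossed by elliptical trabecular
    # beams; the spaces percolate naturally at the target void fraction and
    # the upstream flow stays slow, as in the imaged high-flow tissue.
    # the deepest band of the JCT (against the BM) is dense matrix -- the
    # principal site of outflow resistance -- perforated only by funnel
    # openings toward each vacuole's basal opening
    y_dense = params.y_bm_base - params.subendothelial_thickness_um
    jct_rows = (Y >= params.y_jct_base) & (Y < y_dense)
    allowed = jct_rows & ~sclera & ~interior & (lab != int(Label.PORE))
    lab[allowed & (lab == int(Label.JCT_TISSUE))] = \
        int(Label.INTERTRABECULAR_SPACE)
    dense_rows = (Y >= y_dense) & (Y < params.y_bm_base) & ~sclera
    for tr in truths:
        funnel = (np.abs(X - tr.center_x_um) <= params.funnel_width_um / 2.0) \
            & dense_rows
        lab[funnel] = int(Label.INTERTRABECULAR_SPACE)
    xmin, xmax = ts, params.domain_width_um - ts

    def solid_fraction() -> float:
        n_band = np.count_nonzero(allowed)
        n_solid = np.count_nonzero(allowed & (lab == int(Label.JCT_TISSUE)))
        return n_solid / max(n_band, 1)

    target_solid = 1.0 - params.intertrabecular_void_fraction

    def add_beams():
        for _ in range(4000):
            if solid_fraction() >= target_solid:
                break
            a = 0.5 * params.beam_length_um * rng.uniform(0.6, 1.4)
            b = 0.5 * params.beam_thickness_um * rng.uniform(0.6, 1.4)
            th = rng.uniform(0, np.pi)
            xc = rng.uniform(xmin, xmax)
            yc = rng.uniform(params.y_jct_base, params.y_bm_base)
            ct, st = np.cos(th), np.sin(th)
            u = (X - xc) * ct + (Y - yc) * st
            v = -(X - xc) * st + (Y - yc) * ct
            ell = (u / a) ** 2 + (v / b) ** 2 <= 1.0
            # keep the funnel's approach clear
            for tr in truths:
                ell &= ~((np.abs(X - tr.center_x_um)
                          <= params.funnel_width_um)
                         & (Y >= y_dense - 2.0))
            lab[ell & allowed] = int(Label.JCT_TISSUE)

    # sclera overrides everything in its footprint (stiff tether)
    lab[sclera] = int(Label.SCLERA)

    # grow the beam network in rounds: fill to the target fraction, remove
    # slivers thinner than the minimum beam size (morphological opening) and
    # sub-resolution void specks, then drop beams not connected (8-conn) to
    # the inner-wall complex or sclera (they would drift freely in the
    # flow), and refill what the cleanup removed
    from scipy import ndimage
    r_px = max(1, int(round(params.min_feature_um / 2.0 / px)))
    yy, xx = np.mgrid[-r_px:r_px + 1, -r_px:r_px + 1]
    disk = xx ** 2 + yy ** 2 <= r_px ** 2
    for _ in range(8):
        add_beams()
        jct_solid = lab == int(Label.JCT_TISSUE)
        opened = ndimage.binary_opening(jct_solid, structure=disk)
        sliver = jct_solid & ~opened & jct_rows
        lab[sliver] = int(Label.INTERTRABECULAR_SPACE)
        void = lab == int(Label.INTERTRABECULAR_SPACE)
        vlab, nv = ndimage.label(void)
        if nv:
            sizes = np.bincount(vlab.ravel())
            specks = np.isin(vlab, np.flatnonzero(sizes < 9)) & void
            lab[specks] = int(Label.JCT_TISSUE)
        solid_mask = np.isin(lab, [int(v) for v in SOLID_LABELS])
        comp, _ = ndimage.label(solid_mask, structure=np.ones((3, 3), bool))
        anchored = np.unique(comp[(lab == int(Label.SCLERA))
                                  | (lab == int(Label.BASEMENT_MEMBRANE))])
        floating = solid_mask & ~np.isin(comp, anchored[anchored > 0])
        lab[floating & jct_rows] = int(Label.INTERTRABECULAR_SPACE)
        if solid_fraction() >= 0.97 * target_solid:
            break

    image = LabelImage(array=lab, pixel_size_um=px,
                       slice_thickness_um=params.slice_thickness_um,
                       n_slices=params.n_slices)

    # measure rasterized vacuole dimensions for the truth records
    for tr in truths:
        m = (lab == int(Label.VACUOLE_INTERIOR)) \
            & (np.abs(X - tr.center_x_um) <= tr.width_um / 2.0 + 1.0) \
            & (Y >= params.y_bm_base)
        if np.any(m):
            cols = np.any(m, axis=0)
            rows = np.any(m & (Y >= params.y_cell_base), axis=1)
            tr.width_um = float(np.count_nonzero(cols)) * px
            tr.length_um = float(np.count_nonzero(rows)) * px
    return image, truths


#: Representative gray levels per label (SBF-SEM-like: tissue dark, fluid light).
GRAY_LEVELS = {
    Label.BACKGROUND: 205.0,
    Label.SC_LUMEN: 210.0,
    Label.INNER_WALL_CELL: 70.0,
    Label.BASEMENT_MEMBRANE: 60.0,
    Label.JCT_TISSUE: 90.0,
    Label.SCLERA: 40.0,
    Label.VACUOLE_INTERIOR: 215.0,
    Label.PORE: 208.0,
    Label.INTERTRABECULAR_SPACE: 200.0,
}


def render_grayscale(label: LabelImage, noise_sd: float = 5.0,
                     boundary_shading_strength: float = 0.5,
                     seed: int = 0) -> GrayImage:
    """Render a label image to a noisy grayscale micrograph stand-in.

    Adds Gaussian noise and dark speckle ("black dots") on the fluid side of
    tissue boundaries, emulating the grayscale-to-binary shading artifacts
    that the segmentation stage must remove.  Deterministic under ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if boundary_shading_strength < 0:
        raise ValueError("boundary_shading_strength must be >= 0")
    rng = np.random.default_rng(seed)
    arr = label.array
    gray = np.zeros(arr.shape, dtype=float)
    for lab, level in GRAY_LEVELS.items():
        gray[arr == int(lab)] = level
    if noise_sd > 0:
        gray = gray + rng.normal(0.0, noise_sd, size=gray.shape)
    if boundary_shading_strength > 0:
        from scipy import ndimage
        tissue = label.tissue_mask()
        # speckle centres 3 px (Chebyshev) off the boundary so the dilated
        # dots never become 8-connected to the tissue itself
        s8 = np.ones((3, 3), dtype=bool)
        near = ndimage.binary_dilation(tissue, structure=s8, iterations=3) \
            & ~ndimage.binary_dilation(tissue, structure=s8, iterations=2)
        idx = np.flatnonzero(near)
        n_dots = max(1, int(boundary_shading_strength * idx.size / 400))
        pick = rng.choice(idx, size=min(n_dots, idx.size), replace=False)
        dots = np.zeros(arr.shape, dtype=bool)
        dots.flat[pick] = True
        dots = ndimage.binary_dilation(dots, iterations=1) & ~tissue
        gray[dots] = GRAY_LEVELS[Label.SCLERA]  # dark speckle
    return GrayImage(array=gray, pixel_size_um=label.pixel_size_um,
                     slice_thickness_um=label.slice_thickness_um,
                     n_slices=label.n_slices)
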