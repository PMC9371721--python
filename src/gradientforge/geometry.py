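"""Discretized periodic unit cell of the microwire-array electrode.

One wire of diameter ``D`` and length ``L`` stands centered in a ``P x P``
footprint of electrolyte, 200 um tall.  Bulk concentrations are imposed on
the plane a boundary-layer distance ``dD`` above the wire tops; the lateral
faces of the cell are symmetry planes of the square lattice, so the periodic
condition reduces to zero normal flux there.

Two discretizations are provided:

* ``axisym`` (default): the square footprint is replaced by the equal-area
  disk of radius ``P/sqrt(pi)`` and the problem is solved in cylindrical
  (r, z) coordinates.  Wire surfaces coincide exactly with grid faces, so
  electrode areas are exact at any resolution.  This is the fast path the
  design search relies on.
* ``cartesian3d``: a full structured (x, y, z) grid where the cylindrical
  wire is voxelized; staircase electrode patches carry true-area/discretized-
  area correction factors so the total electrode area (hence total current at
  uniform concentration) is exact.  Retained as a validation mode.

The grid is reduced to the arrays the finite-volume solver needs: face
conductance geometry ``A/d`` between fluid cells, Dirichlet-face geometry on
the bulk plane, and electrode patches (true area + cell-center-to-face
distance for the Robin half-cell correction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .physchem import CatalystKinetics

__all__ = [
    "Morphology",
    "UnitCellGrid",
    "build_grid",
    "analytic_electrode_area",
    "MORPHOLOGY_BOUNDS",
    "DOMAIN_HEIGHT_UM",
]

#: (min, max) of the morphology design space, um.
MORPHOLOGY_BOUNDS = {"P": (1.0, 100.0), "D": (0.2, 10.0), "L": (1.0, 150.0)}
DOMAIN_HEIGHT_UM = 200.0

_UM = 1e-6  # um -> m


@dataclass(frozen=True)
class Morphology:
    """Wire-array morphology vector k = (P, D, L), micrometers.

    P: lattice periodicity; D: wire diameter; L: wire length.  Bounds follow
    the explorable design space; the wire must fit in its cell (D < P).
    """

    P: float
    D: float
    L: float

    def __post_init__(self) -> None:
        for name in ("P", "D", "L"):
            lo, hi = MORPHOLOGY_BOUNDS[name]
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(
                    f"morphology {name} = {v} um outside [{lo}, {hi}] um"
                )
        if self.D >= self.P:
            raise ValueError(
                f"wire diameter D = {self.D} um must be smaller than the "
                f"periodicity P = {self.P} um"
            )

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.P, self.D, self.L)


@dataclass
class UnitCellGrid:
    """Finite-volume geometry of one unit cell, reduced to solver arrays.

    All stored lengths/areas are SI (m, m^2); ``z_*`` metadata is in um to
    match the reporting convention (z = 0 at the wire base).
    """

    mode: str
    morphology: Morphology
    include_base: bool
    height_um: float
    z_bulk_um: float
    spacing_um: float

    n_fluid: int = 0
    # internal faces between fluid cells: conductance geometry A/d (m)
    face_a: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    face_b: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    face_aod: np.ndarray = field(default_factory=lambda: np.empty(0))
    # bulk Dirichlet plane faces
    dirichlet_cells: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    dirichlet_aod: np.ndarray = field(default_factory=lambda: np.empty(0))
    # electrode patches (area includes the true-area correction factor)
    patch_cells: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    patch_area: np.ndarray = field(default_factory=lambda: np.empty(0))
    patch_halfdist: np.ndarray = field(default_factory=lambda: np.empty(0))
    patch_kind: np.ndarray = field(default_factory=lambda: np.empty(0, "U7"))
    # lateral-averaging support
    layer_z_um: np.ndarray = field(default_factory=lambda: np.empty(0))
    cell_layer: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    cell_xsarea: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def electrode_area_um2(self) -> float:
        """Total electrode area carried by the patches, um^2."""
        return float(self.patch_area.sum() / _UM**2)

    def config_json(self) -> dict:
        """The grid's defining configuration (JSON-serializable)."""
        return {
            "mode": self.mode,
            "spacing_um": self.spacing_um,
            "height_um": self.height_um,
            "include_base": self.include_base,
            "morphology": {
                "P": self.morphology.P,
                "D": self.morphology.D,
                "L": self.morphology.L,
            },
        }


def analytic_electrode_area(morph: Morphology, include_base: bool = False) -> float:
    """Closed-form electrode area of the unit cell, um^2.

    Wire lateral + top disk, plus the base annulus outside the wire footprint
    when the substrate between wires is active.
    """
    area = math.pi * morph.D * morph.L + math.pi * morph.D**2 / 4.0
    if include_base:
        area += morph.P**2 - math.pi * morph.D**2 / 4.0
    return area


def _segment(lo: float, hi: float, spacing: float, nmin: int) -> np.ndarray:
    n = max(nmin, int(math.ceil((hi - lo) / spacing)))
    return np.linspace(lo, hi, n + 1)


def build_grid(
    morph: Morphology,
    kin: CatalystKinetics,
    spacing: float = 1.0,
    mode: str = "axisym",
    include_base: bool = True,
) -> UnitCellGrid:
    """Discretize the unit cell for a morphology/catalyst pair.

    Parameters
    ----------
    spacing : target cell size, um.  Minimum cell counts are enforced so the
        boundary layer (>= 4 cells) and the wire length (>= 20 cells) stay
        resolved at any spacing.
    include_base : whether the substrate plane between wires is an active
        electrode (the sputtered catalyst coating is conformal, so it is by
        default).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    z_bulk = min(morph.L + kin.dD, DOMAIN_HEIGHT_UM)
    if mode == "axisym":
        grid = _build_axisym(morph, spacing, z_bulk, include_base)
    elif mode == "cartesian3d":
        grid = _build_cartesian3d(morph, spacing, z_bulk, include_base)
    else:
        raise ValueError(f"unknown grid mode {mode!r}")
    # electrode-area conservation is exact by construction; guard regressions
    analytic = analytic_electrode_area(morph, include_base)
    if abs(grid.electrode_area_um2 - analytic) > 1e-9 * analytic:
        raise AssertionError(
            f"electrode area {grid.electrode_area_um2} um^2 != analytic {analytic}"
        )
    return grid


def _build_axisym(
    morph: Morphology, spacing: float, z_bulk: float, include_base: bool
) -> UnitCellGrid:
    R = morph.P / math.sqrt(math.pi)  # equal-area disk radius
    a = morph.D / 2.0

    r_in = _segment(0.0, a, spacing, 3)
    r_out = _segment(a, R, spacing, 4)
    z_wire = _segment(0.0, morph.L, spacing, 20)
    z_bl = _segment(morph.L, z_bulk, spacing, 4)
    n_rw, n_rg = len(r_in) - 1, len(r_out) - 1
    n_zw, n_zb = len(z_wire) - 1, len(z_bl) - 1
    r_faces = np.concatenate([r_in, r_out[1:]]) * _UM
    z_faces = np.concatenate([z_wire, z_bl[1:]]) * _UM
    nr, nz = n_rw + n_rg, n_zw + n_zb

    r_c = 0.5 * (r_faces[:-1] + r_faces[1:])
    z_c = 0.5 * (z_faces[:-1] + z_faces[1:])
    dz = np.diff(z_faces)
    ring_area = math.pi * (r_faces[1:] ** 2 - r_faces[:-1] ** 2)  # m^2, per ring

    wire = np.zeros((nr, nz), dtype=bool)
    wire[:n_rw, :n_zw] = True
    fluid = ~wire
    idx = -np.ones((nr, nz), dtype=int)
    idx[fluid] = np.arange(fluid.sum())

    fa, fb, aod = [], [], []
    # radial faces between rings i-1 and i
    for i in range(1, nr):
        A = 2.0 * math.pi * r_faces[i] * dz  # per layer
        d = r_c[i] - r_c[i - 1]
        for j in range(nz):
            if fluid[i - 1, j] and fluid[i, j]:
                fa.append(idx[i - 1, j])
                fb.append(idx[i, j])
                aod.append(A[j] / d)
    # vertical faces between layers j-1 and j
    for j in range(1, nz):
        d = z_c[j] - z_c[j - 1]
        for i in range(nr):
            if fluid[i, j - 1] and fluid[i, j]:
                fa.append(idx[i, j - 1])
                fb.append(idx[i, j])
                aod.append(ring_area[i] / d)

    # bulk Dirichlet plane at z = z_bulk (top of the last layer)
    dcells = [idx[i, nz - 1] for i in range(nr)]
    daod = [ring_area[i] / (z_faces[-1] - z_c[nz - 1]) for i in range(nr)]

    pcell, parea, phalf, pkind = [], [], [], []
    # wire lateral surface at r = a
    for j in range(n_zw):
        pcell.append(idx[n_rw, j])
        parea.append(2.0 * math.pi * (a * _UM) * dz[j])
        phalf.append(r_c[n_rw] - a * _UM)
        pkind.append("lateral")
    # wire top disk at z = L
    for i in range(n_rw):
        pcell.append(idx[i, n_zw])
        parea.append(ring_area[i])
        phalf.append(z_c[n_zw] - morph.L * _UM)
        pkind.append("top")
    if include_base:
        for i in range(n_rw, nr):
            pcell.append(idx[i, 0])
            parea.append(ring_area[i])
            phalf.append(z_c[0])
            pkind.append("base")

    ii, jj = np.nonzero(fluid)
    return UnitCellGrid(
        mode="axisym",
        morphology=morph,
        include_base=include_base,
        height_um=DOMAIN_HEIGHT_UM,
        z_bulk_um=z_bulk,
        spacing_um=spacing,
        n_fluid=int(fluid.sum()),
        face_a=np.asarray(fa, int),
        face_b=np.asarray(fb, int),
        face_aod=np.asarray(aod, float),
        dirichlet_cells=np.asarray(dcells, int),
        dirichlet_aod=np.asarray(daod, float),
        patch_cells=np.asarray(pcell, int),
        patch_area=np.asarray(parea, float),
        patch_halfdist=np.asarray(phalf, float),
        patch_kind=np.asarray(pkind),
        layer_z_um=z_c / _UM,
        cell_layer=jj,
        cell_xsarea=ring_area[ii],
    )


def _build_cartesian3d(
    morph: Morphology, spacing: float, z_bulk: float, include_base: bool
) -> UnitCellGrid:
    P, D, L = morph.P, morph.D, morph.L
    n_xy = max(8, int(math.ceil(P / spacing)))
    dx = P / n_xy
    if D < 2.0 * dx:
        raise ValueError(
            f"spacing {spacing} um too coarse to represent a wire of diameter "
            f"{D} um in cartesian3d mode; use spacing <= {D / 2.0:.3g} um or "
            f"the axisym mode"
        )
    x_c = (np.arange(n_xy) + 0.5) * dx - P / 2.0
    z_wire = _segment(0.0, L, spacing, 20)
    z_bl = _segment(L, z_bulk, spacing, 4)
    n_zw, n_zb = len(z_wire) - 1, len(z_bl) - 1
    z_faces = np.concatenate([z_wire, z_bl[1:]]) * _UM
    nz = n_zw + n_zb
    z_c = 0.5 * (z_faces[:-1] + z_faces[1:])
    dz = np.diff(z_faces)

    in_wire_col = (x_c[:, None] ** 2 + x_c[None, :] ** 2) < (D / 2.0) ** 2
    n_wcol = int(in_wire_col.sum())

    wire = np.zeros((n_xy, n_xy, nz), dtype=bool)
    wire[:, :, :n_zw] = in_wire_col[:, :, None]
    fluid = ~wire
    idx = -np.ones_like(wire, dtype=int)
    idx[fluid] = np.arange(fluid.sum())

    dx_m = dx * _UM
    fa, fb, aod = [], [], []
    pcell_lat, parea_lat, pkind = [], [], []
    # x- and y-direction faces (equal spacing, conductance A/d = dx*dz/dx = dz)
    for axis in (0, 1):
        sl_a = (slice(None, -1), slice(None)) if axis == 0 else (slice(None), slice(None, -1))
        sl_b = (slice(1, None), slice(None)) if axis == 0 else (slice(None), slice(1, None))
        for j in range(nz):
            A_over_d = dz[j]  # (dx*dz)/dx
            fl_a, fl_b = fluid[..., j][sl_a], fluid[..., j][sl_b]
            id_a, id_b = idx[..., j][sl_a], idx[..., j][sl_b]
            both = fl_a & fl_b
            fa.extend(id_a[both].tolist())
            fb.extend(id_b[both].tolist())
            aod.extend([A_over_d] * int(both.sum()))
            # fluid cell facing a wire cell -> lateral electrode patch
            for id_f, raw in ((id_a[fl_a & ~fl_b], dx_m * dz[j]), (id_b[fl_b & ~fl_a], dx_m * dz[j])):
                pcell_lat.extend(id_f.tolist())
                parea_lat.extend([raw] * id_f.size)
    # z-direction faces
    for j in range(1, nz):
        d = z_c[j] - z_c[j - 1]
        both = fluid[:, :, j - 1] & fluid[:, :, j]
        fa.extend(idx[:, :, j - 1][both].tolist())
        fb.extend(idx[:, :, j][both].tolist())
        aod.extend([dx_m**2 / d] * int(both.sum()))

    # raw -> true-area correction factors
    raw_lat = float(np.sum(parea_lat))
    f_lat = (math.pi * D * L * _UM**2) / raw_lat
    parea_lat = [a * f_lat for a in parea_lat]
    pkind += ["lateral"] * len(pcell_lat)

    pcell, parea, phalf = list(pcell_lat), list(parea_lat), [dx_m / 2.0] * len(pcell_lat)
    # wire top: fluid cells directly above a wire column
    top_raw = n_wcol * dx_m**2
    f_top = (math.pi * D**2 / 4.0 * _UM**2) / top_raw
    half_top = z_c[n_zw] - L * _UM
    for ix, iy in zip(*np.nonzero(in_wire_col)):
        pcell.append(idx[ix, iy, n_zw])
        parea.append(dx_m**2 * f_top)
        phalf.append(half_top)
        pkind.append("top")
    if include_base:
        n_fcol = n_xy * n_xy - n_wcol
        f_base = ((P**2 - math.pi * D**2 / 4.0) * _UM**2) / (n_fcol * dx_m**2)
        for ix, iy in zip(*np.nonzero(~in_wire_col)):
            pcell.append(idx[ix, iy, 0])
            parea.append(dx_m**2 * f_base)
            phalf.append(z_c[0])
            pkind.append("base")

    dcells = idx[:, :, nz - 1].ravel()
    daod = np.full(dcells.size, dx_m**2 / (z_faces[-1] - z_c[nz - 1]))

    cell_layer = np.nonzero(fluid)[2]
    return UnitCellGrid(
        mode="cartesian3d",
        morphology=morph,
        include_base=include_base,
        height_um=DOMAIN_HEIGHT_UM,
        z_bulk_um=z_bulk,
        spacing_um=spacing,
        n_fluid=int(fluid.sum()),
        face_a=np.asarray(fa, int),
        face_b=np.asarray(fb, int),
        face_aod=np.asarray(aod, float),
        dirichlet_cells=np.asarray(dcells, int),
        dirichlet_aod=np.asarray(daod, float),
        patch_cells=np.asarray(pcell, int),
        patch_area=np.asarray(parea, float),
        patch_halfdist=np.asarray(phalf, float),
        patch_kind=np.asarray(pkind),
        layer_z_um=z_c / _UM,
        cell_layer=cell_layer,
        cell_xsarea=np.full(int(fluid.sum()), dx_m**2),
    )
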