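"""Steady-state diffusion solver for the O2 sink and H2O2 source problems.

Both species obey Laplace's equation in the electrolyte at steady state
(pure diffusion; the flow cell only maintains bulk conditions on the plane
z = z_bulk = min(L + dD, 200 um)):

* O2: Dirichlet c = C_bulk on the bulk plane, zero flux on symmetry faces,
  and a Robin condition D * dc/dn = -k_O2 * c on every electrode patch.
  Because the Tafel kinetics are linear in [O2], the discrete problem is a
  single sparse linear system -- no Newton iteration.
* H2O2: produced at the electrode at a rate slaved to the local O2 surface
  concentration (flux +k_gen * c_O2_surface), swept away at the bulk plane
  (Dirichlet c = 0).  With the O2 field known this is again linear, with the
  electrode production entering the right-hand side.

Robin and source terms use the standard half-cell correction: the surface
value is reconstructed from the adjacent cell center through the local
diffusive resistance, c_s = c_cell * D / (D + k * delta/..), which keeps the
flux first-order consistent on coarse grids.

Profiles are the laterally averaged concentration at 20 heights z = 5..100 um
(step 5), the quantity the neural-network surrogate is trained on.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dc_field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import Morphology, UnitCellGrid, build_grid
from .physchem import (
    CatalystKinetics,
    PhysicalConstants,
    effective_rate_constants,
    load_catalyst,
    overpotential,
)

__all__ = [
    "PROFILE_Z_UM",
    "SolverError",
    "SolverSettings",
    "ConcentrationField",
    "GradientProfile",
    "solve_o2",
    "solve_h2o2",
    "extract_profile",
    "simulate",
    "flux_balance",
]

#: the 20 reporting heights, um above the wire base.
PROFILE_Z_UM = np.arange(5.0, 101.0, 5.0)

#: above this many unknowns the direct factorization is swapped for CG.
_ITERATIVE_THRESHOLD = 200_000


class SolverError(RuntimeError):
    """Raised when the discrete linear system cannot be solved reliably."""


@dataclass(frozen=True)
class SolverSettings:
    """Discretization and physics settings shared by one simulation run."""

    mode: str = "axisym"
    spacing_um: float = 1.0
    include_base: bool = True
    constants: PhysicalConstants = _dc_field(default_factory=PhysicalConstants)


@dataclass
class ConcentrationField:
    """Steady-state concentration solution on the unit-cell grid (mol/m^3 = mM)."""

    species: str  # "O2" | "H2O2"
    values: np.ndarray  # per fluid cell
    grid: UnitCellGrid
    condition: dict
    dirichlet_value: float
    #: O2 concentration reconstructed at each electrode patch (surface value)
    patch_surface_c: np.ndarray | None = None
    #: Robin conductances (m^3/s) used on the electrode patches, for balances
    patch_conductance: np.ndarray | None = None


@dataclass
class GradientProfile:
    """Laterally averaged concentration vs height: 20 points, z = 5..100 um."""

    species: str
    z_um: np.ndarray
    c_mM: np.ndarray

    def __post_init__(self) -> None:
        self.z_um = np.asarray(self.z_um, float)
        self.c_mM = np.asarray(self.c_mM, float)
        if self.z_um.shape != (20,) or self.c_mM.shape != (20,):
            raise ValueError("a gradient profile has exactly 20 points")

    def interp(self, z_um) -> np.ndarray:
        """Concentration at arbitrary heights by linear interpolation, mM."""
        return np.interp(np.asarray(z_um, float), self.z_um, self.c_mM)


def _solve_system(A: sp.csr_matrix, b: np.ndarray) -> np.ndarray:
    n = A.shape[0]
    if n > _ITERATIVE_THRESHOLD:
        c, info = spla.cg(A, b, rtol=1e-12, maxiter=20 * int(np.sqrt(n)) + 1000)
        if info != 0:
            raise SolverError(f"CG failed to converge (info={info}, n={n})")
    else:
        try:
            lu = spla.splu(A.tocsc())
            c = lu.solve(b)
            # iterative refinement guards against precision loss on
            # high-aspect-ratio cells (thin gaps between long wires)
            bnorm0 = np.linalg.norm(b) or 1.0
            for _ in range(5):
                r = b - A @ c
                if np.linalg.norm(r) / bnorm0 < 1e-12:
                    break
                c += lu.solve(r)
        except RuntimeError as exc:  # singular factorization
            raise SolverError(f"sparse factorization failed: {exc}") from exc
    if not np.all(np.isfinite(c)):
        raise SolverError("non-finite values in the solution")
    bnorm = np.linalg.norm(b)
    resid = np.linalg.norm(A @ c - b) / (bnorm if bnorm > 0 else 1.0)
    if resid > 1e-10:
        raise SolverError(f"relative residual {resid:.2e} exceeds 1e-10")
    return c


def _assemble_laplacian(grid: UnitCellGrid, D: float) -> tuple[np.ndarray, list, list, list]:
    """Diagonal accumulator plus COO triplets for the interior + Dirichlet terms."""
    n = grid.n_fluid
    diag = np.zeros(n)
    g = D * grid.face_aod
    np.add.at(diag, grid.face_a, g)
    np.add.at(diag, grid.face_b, g)
    rows = [grid.face_a, grid.face_b]
    cols = [grid.face_b, grid.face_a]
    data = [-g, -g]
    g_dir = D * grid.dirichlet_aod
    np.add.at(diag, grid.dirichlet_cells, g_dir)
    return diag, rows, cols, data


def solve_o2(
    grid: UnitCellGrid,
    kin: CatalystKinetics,
    E_appl: float,
    constants: PhysicalConstants | None = None,
    window: tuple[float, float] | None = None,
) -> ConcentrationField:
    """Solve the steady-state O2 field with Tafel Robin electrode conditions.

    The discrete operator is an M-matrix, so the solution obeys the maximum
    principle: 0 <= c <= C_bulk everywhere.
    """
    constants = constants or PhysicalConstants()
    eta = overpotential(E_appl, constants, window=window)
    k_o2, _ = effective_rate_constants(kin, eta, constants)
    D = constants.D_O2

    diag, rows, cols, data = _assemble_laplacian(grid, D)
    # Robin: flux_out = g_rob * c_cell, with the half-cell surface correction
    g_rob = grid.patch_area * (k_o2 * D) / (D + k_o2 * grid.patch_halfdist)
    np.add.at(diag, grid.patch_cells, g_rob)

    n = grid.n_fluid
    A = sp.coo_matrix(
        (
            np.concatenate([diag] + data),
            (
                np.concatenate([np.arange(n)] + rows),
                np.concatenate([np.arange(n)] + cols),
            ),
        ),
        shape=(n, n),
    ).tocsr()
    b = np.zeros(n)
    np.add.at(b, grid.dirichlet_cells, D * grid.dirichlet_aod * constants.C_O2_bulk)

    c = _solve_system(A, b)
    surf = c[grid.patch_cells] * D / (D + k_o2 * grid.patch_halfdist)
    return ConcentrationField(
        species="O2",
        values=c,
        grid=grid,
        condition={"E_appl_V": E_appl, "catalyst": kin.name,
                   "morphology": grid.morphology.as_tuple()},
        dirichlet_value=constants.C_O2_bulk,
        patch_surface_c=surf,
        patch_conductance=g_rob,
    )


def solve_h2o2(
    grid: UnitCellGrid,
    kin: CatalystKinetics,
    E_appl: float,
    o2_field: ConcentrationField,
    constants: PhysicalConstants | None = None,
    window: tuple[float, float] | None = None,
) -> ConcentrationField:
    """Solve the steady-state H2O2 field driven by the 2e- ORR channel.

    The production flux on each electrode patch is k_gen times the local O2
    surface concentration taken from ``o2_field``; the bulk plane is a perfect
    sink (c = 0).  Catalysts without a 2e- channel return the zero field.
    """
    constants = constants or PhysicalConstants()
    if o2_field.grid is not grid:
        raise ValueError("o2_field was solved on a different grid")
    eta = overpotential(E_appl, constants, window=window)
    _, k_gen = effective_rate_constants(kin, eta, constants)

    cond = {"E_appl_V": E_appl, "catalyst": kin.name,
            "morphology": grid.morphology.as_tuple()}
    if k_gen == 0.0:
        return ConcentrationField(
            species="H2O2", values=np.zeros(grid.n_fluid), grid=grid,
            condition=cond, dirichlet_value=0.0,
            patch_surface_c=np.zeros(len(grid.patch_cells)),
            patch_conductance=np.zeros(len(grid.patch_cells)),
        )

    D = constants.D_H2O2
    diag, rows, cols, data = _assemble_laplacian(grid, D)
    n = grid.n_fluid
    A = sp.coo_matrix(
        (
            np.concatenate([diag] + data),
            (
                np.concatenate([np.arange(n)] + rows),
                np.concatenate([np.arange(n)] + cols),
            ),
        ),
        shape=(n, n),
    ).tocsr()
    # electrode production enters the RHS (no H2O2 surface sink in the model)
    b = np.zeros(n)
    production = k_gen * o2_field.patch_surface_c * grid.patch_area  # mol/s
    np.add.at(b, grid.patch_cells, production)

    c = _solve_system(A, b)
    field = ConcentrationField(
        species="H2O2", values=c, grid=grid, condition=cond, dirichlet_value=0.0,
        patch_surface_c=None, patch_conductance=None,
    )
    field.patch_production = production  # mol/s per patch, for flux balances
    return field


def flux_balance(field: ConcentrationField, constants: PhysicalConstants | None = None
                 ) -> tuple[float, float]:
    """(bulk-plane flux into the domain, electrode reaction rate), mol/s.

    At steady state the two agree: O2 flowing in through the bulk plane is
    consumed at the electrode; H2O2 produced at the electrode leaves through
    the bulk plane.  Used by conservation tests.
    """
    constants = constants or PhysicalConstants()
    grid = field.grid
    D = constants.D_O2 if field.species == "O2" else constants.D_H2O2
    influx = float(np.sum(D * grid.dirichlet_aod
                          * (field.dirichlet_value - field.values[grid.dirichlet_cells])))
    if field.species == "O2":
        electrode = float(np.sum(field.patch_conductance * field.values[grid.patch_cells]))
    else:
        electrode = float(np.sum(getattr(field, "patch_production", 0.0)))
    return influx, electrode


def extract_profile(field: ConcentrationField) -> GradientProfile:
    """Laterally average the field on the 20-point reporting ladder.

    Each height takes the area-weighted mean concentration over the electrolyte
    cross-section of its grid layer (the wire interior is excluded below the
    wire top by construction); heights between layer centers are linearly
    interpolated, and heights at or above the bulk plane report the Dirichlet
    value.
    """
    grid = field.grid
    n_layers = len(grid.layer_z_um)
    wsum = np.zeros(n_layers)
    csum = np.zeros(n_layers)
    np.add.at(wsum, grid.cell_layer, grid.cell_xsarea)
    np.add.at(csum, grid.cell_layer, grid.cell_xsarea * field.values)
    layer_avg = csum / wsum

    z_nodes = np.concatenate([grid.layer_z_um, [grid.z_bulk_um]])
    c_nodes = np.concatenate([layer_avg, [field.dirichlet_value]])
    c = np.interp(PROFILE_Z_UM, z_nodes, c_nodes)
    c[PROFILE_Z_UM >= grid.z_bulk_um] = field.dirichlet_value
    return GradientProfile(species=field.species, z_um=PROFILE_Z_UM.copy(), c_mM=c)


def simulate(
    morph: Morphology,
    catalyst: str | CatalystKinetics,
    E_appl: float,
    settings: SolverSettings | None = None,
) -> tuple[GradientProfile, GradientProfile]:
    """One-call pipeline: build grid, solve O2 then H2O2, extract both profiles.

    Deterministic: identical inputs give bit-identical profiles.  Catalysts
    without a 2e- channel (Pt) return an all-zero H2O2 profile.
    """
    settings = settings or SolverSettings()
    overpotential(E_appl, settings.constants)  # enforce the ORR potential window
    kin = load_catalyst(catalyst) if isinstance(catalyst, str) else catalyst
    grid = build_grid(
        morph, kin, spacing=settings.spacing_um, mode=settings.mode,
        include_base=settings.include_base,
    )
    o2 = solve_o2(grid, kin, E_appl, settings.constants)
    h2o2 = solve_h2o2(grid, kin, E_appl, o2, settings.constants)
    return extract_profile(o2), extract_profile(h2o2)
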