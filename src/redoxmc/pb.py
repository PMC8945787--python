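"""Finite-difference linearized Poisson-Boltzmann electrostatics.

Produces the three electrostatic ingredients of the microstate energy
function: per-conformer desolvation (reaction-field) energies, screened
interactions with the rigid backbone, and the pairwise conformer-conformer
matrix, plus an analytic 12-6 Lennard-Jones term.

The solver discretizes  div(eps grad phi) - kappa2(r) phi = -4 pi rho  on a
regular grid, with the dielectric assigned on grid links from a
solvent-excluded region map (inflated van der Waals surface eroded by the
water probe), Debye-Hueckel screening in the solvent region, Dirichlet
boundary values from the Debye-Hueckel monopole sum, and red-black
successive over-relaxation.  Charges are spread trilinearly to the eight
surrounding nodes; raw grid self-energies are never used — all reported
energies are reaction-field *differences* or smooth-field interactions, with
the singular Coulomb part evaluated analytically off-grid.

Internally the potential is in units of e/A (phi = q/(eps r) for a point
charge in a uniform medium); multiplying by the Coulomb constant 332.0636
gives kcal/mol per unit charge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .constants import COULOMB_K, debye_kappa2
from .fragments import Conformer, StructureModel

__all__ = [
    "DielectricEnvironment",
    "GridSpec",
    "SoluteCavity",
    "PBSolution",
    "PBConvergenceError",
    "EnergyTables",
    "solve_poisson_boltzmann",
    "reaction_field_energy",
    "backbone_energy",
    "pairwise_energy",
    "lennard_jones_energy",
    "coulomb_energy",
    "build_energy_tables",
    "SAME_FRAGMENT",
]

#: sentinel for pair entries between conformers of the same fragment
SAME_FRAGMENT = np.nan


class PBConvergenceError(RuntimeError):
    """SOR iteration failed to reach the requested tolerance."""


@dataclass
class DielectricEnvironment:
    """Dielectric/solvent model parameters."""

    eps_protein: float = 4.0
    eps_water: float = 80.0
    ionic_strength: float = 0.15  # mol/L
    probe_radius: float = 1.4  # A
    temperature: float = 298.0  # K

    def __post_init__(self) -> None:
        if not (self.eps_water >= self.eps_protein >= 1.0):
            raise ValueError("require eps_water >= eps_protein >= 1")
        if self.ionic_strength < 0:
            raise ValueError("ionic_strength must be >= 0")

    @property
    def kappa2(self) -> float:
        return debye_kappa2(self.ionic_strength, self.temperature)


@dataclass
class GridSpec:
    """Finite-difference grid: spacing (A), box padding and focusing.

    The box is the solute bounding box plus ``padding`` on each side at
    the coarsest level (must keep at least 5 A of solvent).  With
    ``focusing_levels`` > 1 the equation is first solved at
    2^(levels-1) coarser spacing on the full box, then refocused onto
    successively smaller boxes around the charges with boundary values
    interpolated from the coarser solution.
    """

    spacing: float = 0.5
    padding: float = 8.0
    focusing_levels: int = 1
    max_iter: int = 20000
    tol: float = 1e-6  # kcal/mol/e max potential update
    omega: float | None = None  # SOR over-relaxation; None = auto

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.padding < 5.0:
            raise ValueError("padding must leave >= 5 A of solvent at the coarsest level")
        if self.focusing_levels < 1:
            raise ValueError("focusing_levels must be >= 1")


class SoluteCavity:
    """Low-dielectric region map from atom spheres.

    A point is *protein* if it lies inside an atom's van der Waals
    sphere, or inside the probe-inflated surface and not reachable by a
    solvent probe (erosion of the inflated surface by the probe radius,
    evaluated by an Euclidean distance transform on an auxiliary grid).
    For a single sphere this reproduces the solvent-excluded surface
    exactly.
    """

    def __init__(self, positions: np.ndarray, radii: np.ndarray, probe_radius: float = 1.4,
                 resolution: float = 0.4):
        self.positions = np.atleast_2d(np.asarray(positions, float))
        self.radii = np.asarray(radii, float).ravel()
        if self.positions.shape[0] != self.radii.shape[0]:
            raise ValueError("positions/radii length mismatch")
        self.probe = float(probe_radius)
        self._edt = None
        self._edt_grid = None
        self._resolution = resolution
        self._mask_cache: dict = {}

    def is_empty(self) -> bool:
        return self.positions.shape[0] == 0

    def _dist_to_vdw(self, points: np.ndarray, inflate: float = 0.0) -> np.ndarray:
        """min over atoms of (|p - x_i| - r_i - inflate), chunked over points."""
        out = np.empty(points.shape[0])
        rad = self.radii + inflate
        step = max(1, 4_000_000 // max(1, self.positions.shape[0]))
        for p0 in range(0, points.shape[0], step):
            pts = points[p0:p0 + step]
            d = np.sqrt(
                ((pts[:, None, :] - self.positions[None, :, :]) ** 2).sum(axis=-1)
            ) - rad[None, :]
            out[p0:p0 + step] = d.min(axis=1)
        return out

    def _ensure_edt(self) -> None:
        """Distance-to-accessible-region field on an auxiliary grid."""
        if self._edt is not None:
            return
        h = self._resolution
        lo = self.positions.min(axis=0) - (self.radii.max() + 2 * self.probe + 2.0)
        hi = self.positions.max(axis=0) + (self.radii.max() + 2 * self.probe + 2.0)
        axes = [np.arange(lo[k], hi[k] + h, h) for k in range(3)]
        shape = tuple(len(ax) for ax in axes)
        pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        accessible = (self._dist_to_vdw(pts, inflate=self.probe) >= 0.0).reshape(shape)
        # distance from each node to the nearest accessible node
        dist = ndimage.distance_transform_edt(~accessible, sampling=(h, h, h))
        self._edt = dist
        self._edt_grid = (lo, h, shape)

    def _edt_at(self, points: np.ndarray) -> np.ndarray:
        self._ensure_edt()
        lo, h, shape = self._edt_grid
        idx = (points - lo[None, :]) / h
        idx = np.clip(idx, 0, np.array(shape) - 1.001)
        return ndimage.map_coordinates(self._edt, idx.T, order=1, mode="nearest")

    def is_protein(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, float))
        if self.is_empty():
            return np.zeros(points.shape[0], dtype=bool)
        d_vdw = self._dist_to_vdw(points)
        inside_vdw = d_vdw < 0.0
        in_shell = (~inside_vdw) & (self._dist_to_vdw(points, inflate=self.probe) < 0.0)
        out = inside_vdw.copy()
        if np.any(in_shell):
            # shell points are protein unless a solvent probe reaches them
            out[in_shell] = self._edt_at(points[in_shell]) > self.probe
        return out

    def grid_masks(self, origin: np.ndarray, shape: tuple, h: float):
        """Memoized (node_mask, link_mask_x, link_mask_y, link_mask_z) on a grid."""
        key = (tuple(np.round(origin, 6)), shape, round(h, 6))
        if key in self._mask_cache:
            return self._mask_cache[key]
        axes = [origin[k] + h * np.arange(shape[k]) for k in range(3)]
        node_pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
        node = self.is_protein(node_pts).reshape(shape)
        links = []
        for ax in range(3):
            mid_axes = [a.copy() for a in axes]
            mid_axes[ax] = mid_axes[ax][:-1] + h / 2.0
            pts = np.stack(np.meshgrid(*mid_axes, indexing="ij"), axis=-1).reshape(-1, 3)
            links.append(self.is_protein(pts).reshape([len(a) for a in mid_axes]))
        out = (node, links[0], links[1], links[2])
        self._mask_cache[key] = out
        return out


@dataclass
class PBSolution:
    """Solved potential on a grid, in kcal/mol per unit charge."""

    origin: np.ndarray
    spacing: float
    phi: np.ndarray  # (nx, ny, nz), kcal/mol/e
    iterations: int = 0
    residual: float = 0.0
    parent: "PBSolution | None" = None  # coarser level of a focusing chain

    def potential(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation; points outside a focus box fall back to
        the coarser level of the focusing chain."""
        points = np.atleast_2d(np.asarray(points, float))
        idx = (points - self.origin[None, :]) / self.spacing
        hi = np.array(self.phi.shape) - 1
        inside = np.all((idx >= 0) & (idx <= hi), axis=1)
        if not np.all(inside):
            if self.parent is None:
                raise ValueError("point outside the solved grid")
            out = np.empty(points.shape[0])
            if np.any(inside):
                out[inside] = ndimage.map_coordinates(
                    self.phi, idx[inside].T, order=1, mode="nearest"
                )
            out[~inside] = self.parent.potential(points[~inside])
            return out
        return ndimage.map_coordinates(self.phi, idx.T, order=1, mode="nearest")


def _grid_axes(origin: np.ndarray, shape: tuple, h: float):
    return [origin[k] + h * np.arange(shape[k]) for k in range(3)]


def _spread_charges(positions, charges, origin, shape, h) -> np.ndarray:
    """Trilinear (cloud-in-cell) charge assignment to grid nodes."""
    rho = np.zeros(shape)
    t = (positions - origin[None, :]) / h
    i0 = np.floor(t).astype(int)
    frac = t - i0
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (
                    (frac[:, 0] if dx else 1 - frac[:, 0])
                    * (frac[:, 1] if dy else 1 - frac[:, 1])
                    * (frac[:, 2] if dz else 1 - frac[:, 2])
                )
                np.add.at(rho, (i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz), charges * w)
    return rho


def _link_eps(cavity: SoluteCavity | None, env, origin, shape, h, uniform_eps):
    """Dielectric on the three families of grid links (x, y, z)."""
    if uniform_eps is not None:
        return tuple(
            np.full((shape[0] - (ax == 0), shape[1] - (ax == 1), shape[2] - (ax == 2)), uniform_eps)
            for ax in range(3)
        )
    if cavity is None:
        return tuple(
            np.full((shape[0] - (ax == 0), shape[1] - (ax == 1), shape[2] - (ax == 2)),
                    env.eps_water)
            for ax in range(3)
        )
    _, mx, my, mz = cavity.grid_masks(np.asarray(origin, float), shape, h)
    return tuple(np.where(mask, env.eps_protein, env.eps_water) for mask in (mx, my, mz))


def _sor(phi, eps_x, eps_y, eps_z, kap, src, h, omega, tol_internal, max_iter):
    """Red-black SOR on the interior nodes; returns (iterations, residual)."""
    nx, ny, nz = phi.shape
    ii, jj, kk = np.meshgrid(
        np.arange(1, nx - 1), np.arange(1, ny - 1), np.arange(1, nz - 1), indexing="ij"
    )
    red = ((ii + jj + kk) % 2 == 0)

    exm = eps_x[:-1, 1:-1, 1:-1]
    exp_ = eps_x[1:, 1:-1, 1:-1]
    eym = eps_y[1:-1, :-1, 1:-1]
    eyp = eps_y[1:-1, 1:, 1:-1]
    ezm = eps_z[1:-1, 1:-1, :-1]
    ezp = eps_z[1:-1, 1:-1, 1:]
    denom = exm + exp_ + eym + eyp + ezm + ezp + kap[1:-1, 1:-1, 1:-1] * h * h
    s = src[1:-1, 1:-1, 1:-1]

    it = 0
    res = np.inf
    for it in range(1, max_iter + 1):
        res = 0.0
        for mask in (red, ~red):
            num = (
                exm * phi[:-2, 1:-1, 1:-1]
                + exp_ * phi[2:, 1:-1, 1:-1]
                + eym * phi[1:-1, :-2, 1:-1]
                + eyp * phi[1:-1, 2:, 1:-1]
                + ezm * phi[1:-1, 1:-1, :-2]
                + ezp * phi[1:-1, 1:-1, 2:]
                + s
            )
            new = num / denom
            interior = phi[1:-1, 1:-1, 1:-1]
            delta = np.where(mask, new - interior, 0.0)
            interior += omega * delta
            res = max(res, float(np.max(np.abs(delta))))
        if omega * res < tol_internal:
            return it, omega * res
    raise PBConvergenceError(
        f"SOR did not converge in {max_iter} iterations "
        f"(last max update {omega * res * COULOMB_K:.3e} kcal/mol/e)"
    )


def _solve_level(positions, charges, cavity, env, origin, shape, h, grid,
                 uniform_eps, boundary_phi):
    eps_x, eps_y, eps_z = _link_eps(cavity, env, origin, shape, h, uniform_eps)

    # screening only where solvent (and only if salt present / not uniform)
    kap = np.zeros(shape)
    if env.ionic_strength > 0 and uniform_eps is None:
        if cavity is None:
            kap = np.full(shape, env.kappa2)
        else:
            node, _, _, _ = cavity.grid_masks(np.asarray(origin, float), shape, h)
            kap = np.where(node, 0.0, env.kappa2)

    src = 4.0 * math.pi * _spread_charges(positions, charges, origin, shape, h) / h

    phi = np.zeros(shape)
    # Dirichlet boundary
    for axis, side in ((0, 0), (0, -1), (1, 0), (1, -1), (2, 0), (2, -1)):
        sl = [slice(None)] * 3
        sl[axis] = side
        phi[tuple(sl)] = boundary_phi[tuple(sl)]

    if grid.omega is not None:
        omega = grid.omega
    else:
        n = max(shape)
        omega = 2.0 / (1.0 + math.sin(math.pi / n))
    tol_internal = grid.tol / COULOMB_K
    iters, res = _sor(phi, eps_x, eps_y, eps_z, kap, src, h, omega, tol_internal, grid.max_iter)
    return phi, iters, res


def _dh_boundary(positions, charges, env, origin, shape, h, uniform_eps) -> np.ndarray:
    """Debye-Hueckel monopole boundary values on the box faces."""
    phi = np.zeros(shape)
    eps = uniform_eps if uniform_eps is not None else env.eps_water
    kappa = 0.0
    if env.ionic_strength > 0 and uniform_eps is None:
        kappa = math.sqrt(env.kappa2 / env.eps_water)
    axes = _grid_axes(origin, shape, h)
    for axis, side in ((0, 0), (0, -1), (1, 0), (1, -1), (2, 0), (2, -1)):
        sl = [slice(None)] * 3
        sl[axis] = side
        sub_axes = []
        for k in range(3):
            sub_axes.append(np.array([axes[k][side]]) if k == axis else axes[k])
        pts = np.stack(np.meshgrid(*sub_axes, indexing="ij"), axis=-1).reshape(-1, 3)
        vals = np.zeros(pts.shape[0])
        for p, q in zip(positions, charges):
            r = np.linalg.norm(pts - p[None, :], axis=1)
            r = np.maximum(r, 1e-6)
            vals += q * np.exp(-kappa * r) / (eps * r)
        face_shape = [shape[k] for k in range(3) if k != axis]
        sub = vals.reshape([1 if k == axis else shape[k] for k in range(3)])
        phi[tuple(sl)] = sub.reshape(phi[tuple(sl)].shape)
    return phi


def solve_poisson_boltzmann(
    positions: np.ndarray,
    charges: np.ndarray,
    cavity: SoluteCavity | None,
    env: DielectricEnvironment,
    grid: GridSpec,
    uniform_eps: float | None = None,
    extent: tuple[np.ndarray, np.ndarray] | None = None,
) -> PBSolution:
    """Solve the linearized PB equation for a set of point charges.

    ``cavity`` defines the low-dielectric region; pass ``uniform_eps``
    to solve in a homogeneous salt-free medium instead (the reference
    state used for reaction-field differences).  ``extent`` optionally
    fixes the box (lo, hi corners); by default it is the bounding box
    of the cavity atoms (or charges) plus ``grid.padding``.
    """
    positions = np.atleast_2d(np.asarray(positions, float))
    charges = np.asarray(charges, float).ravel()
    if positions.shape[0] != charges.shape[0]:
        raise ValueError("positions/charges length mismatch")

    if extent is None:
        ref = positions if (cavity is None or cavity.is_empty()) else cavity.positions
        lo = ref.min(axis=0) - grid.padding
        hi = ref.max(axis=0) + grid.padding
    else:
        lo, hi = (np.asarray(e, float) for e in extent)

    if positions.size and (np.any(positions < lo + 1e-9) or np.any(positions > hi - 1e-9)):
        raise ValueError("charge outside the grid box")

    if positions.size == 0 or not np.any(charges):
        h = grid.spacing
        shape = tuple(int(np.ceil((hi[k] - lo[k]) / h)) + 1 for k in range(3))
        return PBSolution(origin=np.asarray(lo, float), spacing=h, phi=np.zeros(shape))

    levels = grid.focusing_levels
    phi = None
    solution = None
    for level in range(levels):
        h = grid.spacing * 2 ** (levels - 1 - level)
        if level == 0:
            box_lo, box_hi = lo, hi
        else:
            # focus on the charges with a margin, clipped to the outer box
            m = max(8.0 * h, 6.0)
            box_lo = np.maximum(positions.min(axis=0) - m, lo)
            box_hi = np.minimum(positions.max(axis=0) + m, hi)
        shape = tuple(int(np.ceil((box_hi[k] - box_lo[k]) / h)) + 1 for k in range(3))
        box_hi = box_lo + (np.array(shape) - 1) * h

        if level == 0:
            boundary = _dh_boundary(positions, charges, env, box_lo, shape, h, uniform_eps)
        else:
            axes = _grid_axes(box_lo, shape, h)
            boundary = np.zeros(shape)
            for axis, side in ((0, 0), (0, -1), (1, 0), (1, -1), (2, 0), (2, -1)):
                sl = [slice(None)] * 3
                sl[axis] = side
                sub_axes = [np.array([axes[k][side]]) if k == axis else axes[k] for k in range(3)]
                pts = np.stack(np.meshgrid(*sub_axes, indexing="ij"), axis=-1).reshape(-1, 3)
                boundary[tuple(sl)] = solution.potential(pts).reshape(
                    boundary[tuple(sl)].shape
                ) / COULOMB_K

        phi, iters, res = _solve_level(
            positions, charges, cavity, env, box_lo, shape, h, grid, uniform_eps, boundary
        )
        solution = PBSolution(
            origin=np.asarray(box_lo, float),
            spacing=h,
            phi=phi * COULOMB_K,
            iterations=iters,
            residual=res * COULOMB_K,
            parent=solution,
        )
    return solution


# ---------------------------------------------------------------------------
# energies
# ---------------------------------------------------------------------------


def _conformer_charge_layout(conformer: Conformer):
    if conformer.positions is None or conformer.atom_charges is None:
        raise ValueError(f"conformer {conformer.fragment_id}[{conformer.index}] has no placed charges")
    return conformer.positions, conformer.atom_charges


def _structure_cavity(structure: StructureModel, env: DielectricEnvironment) -> SoluteCavity:
    """Low-dielectric region from backbone + first conformer of every fragment."""
    pos, rad = [], []
    for a in structure.backbone:
        pos.append(a.position)
        rad.append(a.radius)
    for f in structure.fragments:
        c = structure.conformers_of(f.id)[0]
        for p, r in zip(c.positions, c.atom_radii):
            pos.append(p)
            rad.append(r)
    return SoluteCavity(np.array(pos), np.array(rad), env.probe_radius)


def _structure_extent(structure: StructureModel, grid: GridSpec):
    pts = np.array([a.position for a in structure.all_atoms()])
    return pts.min(axis=0) - grid.padding, pts.max(axis=0) + grid.padding


def reaction_field_energy(
    conformer: Conformer,
    structure: StructureModel,
    env: DielectricEnvironment,
    grid: GridSpec,
    cavity: SoluteCavity | None = None,
    extent=None,
) -> float:
    """Desolvation penalty ddG_rxn (kcal/mol) of burying the conformer.

    Difference of the conformer's reaction-field energy between (a) its
    position inside the protein cavity and (b) alone in bulk water with
    only its own atoms excluding solvent.  Positive for buried net
    charge; exactly zero for an all-zero charge set.  Grid self-energies
    cancel because both solves use the identical charge layout and grid.
    """
    pos, q = _conformer_charge_layout(conformer)
    if not np.any(q):
        return 0.0
    if cavity is None:
        cavity = _structure_cavity(structure, env)
    if extent is None:
        extent = _structure_extent(structure, grid)
    own = SoluteCavity(pos, conformer.atom_radii, env.probe_radius)
    sol_prot = solve_poisson_boltzmann(pos, q, cavity, env, grid, extent=extent)
    sol_aq = solve_poisson_boltzmann(pos, q, own, env, grid, extent=extent)
    return 0.5 * float(np.sum(q * (sol_prot.potential(pos) - sol_aq.potential(pos))))


def coulomb_energy(pos_a, q_a, pos_b, q_b, eps: float) -> float:
    """Analytic Coulomb interaction between two disjoint charge sets."""
    d = np.linalg.norm(pos_a[:, None, :] - pos_b[None, :, :], axis=-1)
    return float(COULOMB_K * np.sum(q_a[:, None] * q_b[None, :] / (eps * d)))


def lennard_jones_energy(conf_i: Conformer, conf_j: Conformer) -> float:
    """12-6 Lennard-Jones energy with Lorentz-Berthelot combining."""
    if conf_i.lj_rmin is None or conf_j.lj_rmin is None:
        return 0.0
    d = np.linalg.norm(conf_i.positions[:, None, :] - conf_j.positions[None, :, :], axis=-1)
    d = np.maximum(d, 0.5)
    rmin = conf_i.lj_rmin[:, None] + conf_j.lj_rmin[None, :]  # params are Rmin/2
    eps = np.sqrt(conf_i.lj_eps[:, None] * conf_j.lj_eps[None, :])
    x6 = (rmin / d) ** 6
    return float(np.sum(eps * (x6 * x6 - 2.0 * x6)))


class _ScreenedField:
    """Screened potential of one conformer, split as analytic Coulomb in a
    uniform eps_protein medium plus a smooth grid reaction-field part."""

    def __init__(self, conformer, cavity, env, grid, extent):
        self.pos, self.q = _conformer_charge_layout(conformer)
        self.env = env
        self.any_charge = bool(np.any(self.q))
        if not self.any_charge:
            return
        het = solve_poisson_boltzmann(self.pos, self.q, cavity, env, grid, extent=extent)
        hom = solve_poisson_boltzmann(
            self.pos, self.q, None, env, grid, uniform_eps=env.eps_protein, extent=extent
        )
        self._het, self._hom = het, hom

    def interaction(self, pos_b: np.ndarray, q_b: np.ndarray) -> float:
        """Screened interaction energy with another charge set, kcal/mol."""
        if not self.any_charge or not np.any(q_b):
            return 0.0
        rf = self._het.potential(pos_b) - self._hom.potential(pos_b)
        direct = coulomb_energy(self.pos, self.q, pos_b, q_b, self.env.eps_protein)
        return float(np.sum(q_b * rf)) + direct

    def self_reaction_field(self) -> float:
        if not self.any_charge:
            return 0.0
        rf = self._het.potential(self.pos) - self._hom.potential(self.pos)
        return 0.5 * float(np.sum(self.q * rf))


def backbone_energy(
    conformer: Conformer,
    structure: StructureModel,
    env: DielectricEnvironment,
    grid: GridSpec,
    cavity: SoluteCavity | None = None,
    extent=None,
    _field: _ScreenedField | None = None,
) -> float:
    """Screened interaction dG_pol (kcal/mol) of a conformer with the backbone."""
    if not structure.backbone:
        return 0.0
    bb_pos = np.array([a.position for a in structure.backbone])
    bb_q = np.array([a.partial_charge for a in structure.backbone])
    if not np.any(bb_q):
        return 0.0
    if _field is None:
        if cavity is None:
            cavity = _structure_cavity(structure, env)
        if extent is None:
            extent = _structure_extent(structure, grid)
        _field = _ScreenedField(conformer, cavity, env, grid, extent)
    return _field.interaction(bb_pos, bb_q)


def pairwise_energy(
    conformer_i: Conformer,
    conformer_j: Conformer,
    env: DielectricEnvironment,
    grid: GridSpec,
    structure: StructureModel | None = None,
    cavity: SoluteCavity | None = None,
    extent=None,
    include_lj: bool = True,
    _field_i: _ScreenedField | None = None,
) -> float:
    """Pairwise conformer-conformer energy dG_ij (kcal/mol).

    Screened electrostatics plus (optionally) the analytic 12-6
    Lennard-Jones term.  Conformers of the same fragment never coexist:
    the sentinel ``SAME_FRAGMENT`` (NaN) is returned.
    """
    if conformer_i.fragment_id == conformer_j.fragment_id:
        return SAME_FRAGMENT
    if _field_i is None:
        if cavity is None and structure is not None:
            cavity = _structure_cavity(structure, env)
        if extent is None and structure is not None:
            extent = _structure_extent(structure, grid)
        _field_i = _ScreenedField(conformer_i, cavity, env, grid, extent)
    pos_j, q_j = _conformer_charge_layout(conformer_j)
    e = _field_i.interaction(pos_j, q_j)
    if include_lj:
        e += lennard_jones_energy(conformer_i, conformer_j)
    return e


@dataclass
class EnergyTables:
    """Precomputed Eq.-1 ingredients for M conformers.

    ``dG_pair`` = electrostatic + Lennard-Jones; the electrostatic part
    alone is kept in ``dG_pair_elec`` for mean-field interaction reports.
    Same-fragment entries hold the ``SAME_FRAGMENT`` sentinel (NaN);
    diagonals are zero.
    """

    conformer_ids: list[str]
    fragment_ids: list[str]  # parallel: fragment of each conformer
    dG_rxn: np.ndarray  # (M,)
    dG_pol: np.ndarray  # (M,)
    dG_pair: np.ndarray  # (M, M)
    dG_pair_elec: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dG_rxn = np.asarray(self.dG_rxn, float)
        self.dG_pol = np.asarray(self.dG_pol, float)
        self.dG_pair = np.asarray(self.dG_pair, float)
        m = len(self.conformer_ids)
        if self.dG_pair.shape != (m, m):
            raise ValueError("dG_pair must be M x M")
        if self.dG_pair_elec is not None:
            self.dG_pair_elec = np.asarray(self.dG_pair_elec, float)

    @property
    def n_conformers(self) -> int:
        return len(self.conformer_ids)

    def validate(self) -> None:
        finite = np.isfinite(self.dG_pair)
        if not np.allclose(np.diag(self.dG_pair), 0.0):
            raise ValueError("dG_pair diagonal must be zero")
        asym = np.nanmax(np.abs(self.dG_pair - self.dG_pair.T)) if finite.any() else 0.0
        if asym > 1e-8:
            raise ValueError(f"dG_pair not symmetric (max asym {asym:.2e})")

    def save(self, prefix: str) -> None:
        """Serialize to ``<prefix>.vectors.tsv`` and ``<prefix>.pair.tsv``."""
        import pandas as pd

        pd.DataFrame(
            {
                "conformer_id": self.conformer_ids,
                "fragment_id": self.fragment_ids,
                "dG_rxn": self.dG_rxn,
                "dG_pol": self.dG_pol,
            }
        ).to_csv(f"{prefix}.vectors.tsv", sep="\t", index=False)
        pd.DataFrame(self.dG_pair, index=self.conformer_ids, columns=self.conformer_ids).to_csv(
            f"{prefix}.pair.tsv", sep="\t"
        )

    @classmethod
    def load(cls, prefix: str) -> "EnergyTables":
        import pandas as pd

        vec = pd.read_csv(f"{prefix}.vectors.tsv", sep="\t")
        pair = pd.read_csv(f"{prefix}.pair.tsv", sep="\t", index_col=0)
        return cls(
            conformer_ids=list(vec["conformer_id"]),
            fragment_ids=list(vec["fragment_id"]),
            dG_rxn=vec["dG_rxn"].to_numpy(),
            dG_pol=vec["dG_pol"].to_numpy(),
            dG_pair=pair.to_numpy(),
        )


def build_energy_tables(
    structure: StructureModel,
    env: DielectricEnvironment,
    grid: GridSpec,
    include_lj: bool = True,
) -> EnergyTables:
    """Compute all Eq.-1 energy ingredients for every conformer.

    One PB solve pair (protein + homogeneous reference) per conformer,
    reused for the backbone term and the whole pair row; the pair matrix
    is symmetrized by averaging the i->j and j->i estimates.
    """
    structure.validate()
    cavity = _structure_cavity(structure, env)
    extent = _structure_extent(structure, grid)
    confs = list(structure.conformers)
    m = len(confs)
    ids = [f"{c.fragment_id}[{c.label or c.index}]" for c in confs]
    frag_ids = [c.fragment_id for c in confs]

    bb_pos = np.array([a.position for a in structure.backbone]) if structure.backbone else None
    bb_q = np.array([a.partial_charge for a in structure.backbone]) if structure.backbone else None

    dG_rxn = np.zeros(m)
    dG_pol = np.zeros(m)
    elec = np.full((m, m), 0.0)

    fields = []
    for i, c in enumerate(confs):
        try:
            field_i = _ScreenedField(c, cavity, env, grid, extent)
            fields.append(field_i)
            dG_rxn[i] = reaction_field_energy(c, structure, env, grid, cavity=cavity, extent=extent)
            if bb_pos is not None and bb_q is not None and np.any(bb_q):
                dG_pol[i] = field_i.interaction(bb_pos, bb_q)
        except Exception as exc:  # annotate which conformer failed
            raise RuntimeError(f"PB failure for conformer {ids[i]}: {exc}") from exc

    for i in range(m):
        for j in range(i + 1, m):
            if frag_ids[i] == frag_ids[j]:
                elec[i, j] = elec[j, i] = SAME_FRAGMENT
                continue
            pos_j, q_j = _conformer_charge_layout(confs[j])
            pos_i, q_i = _conformer_charge_layout(confs[i])
            eij = fields[i].interaction(pos_j, q_j)
            eji = fields[j].interaction(pos_i, q_i)
            elec[i, j] = elec[j, i] = 0.5 * (eij + eji)

    pair = elec.copy()
    if include_lj:
        for i in range(m):
            for j in range(i + 1, m):
                if frag_ids[i] == frag_ids[j]:
                    continue
                lj = lennard_jones_energy(confs[i], confs[j])
                pair[i, j] += lj
                pair[j, i] += lj

    tables = EnergyTables(ids, frag_ids, dG_rxn, dG_pol, pair, dG_pair_elec=elec)
    tables.validate()
    return tables
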