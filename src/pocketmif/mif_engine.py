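"""Molecular interaction fields: lattice construction and probe energies.

A MIF is the interaction energy of one chemical probe evaluated on a
regular lattice over a pocket.  The pair energy is a declared GRID-like
empirical model::

    E = E_LJ + E_el + E_hb                       (kcal/mol, clamped at +5)
    E_LJ = eps_mix [ (rmin_mix/r)^12 - 2 (rmin_mix/r)^6 ]
    E_el = 332.0636 q_p q_a / (4 r^2)            (dielectric eps(r) = 4r)
    E_hb = -emax [ 5 (d0/r)^10 ... ] cos^2(theta)  (12-10 radial, d0 = 2.9 A)

where the H-bond term acts only between complementary donor/acceptor
partners and ``theta`` is measured at the protein atom between its
idealised lone-pair/H direction (pointing away from its bonded neighbours)
and the direction to the probe.  ``emax`` (<= 0) is the well depth: the
term equals ``emax * cos^2(theta)`` at r = d0 and is repulsive at short
range.

Alongside the summed energy, each grid point records the single protein
atom with the most favourable individual pair term (the *max contributor*),
which drives per-residue attribution downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .atomtypes import ACCEPTOR_CAPABLE, DONOR_CAPABLE, POLAR_CLASSES
from .config import ModelParams, ProbeType, load_params
from .dx import read_dx, write_dx
from .structures import PocketDefinition, TypedStructure

log = logging.getLogger(__name__)

__all__ = ["GridSpec", "MIF", "build_grid", "pair_energy", "compute_mif",
           "export_field", "import_field"]

BOND_CUTOFF = 1.9   # A, heavy-atom covalent bond detection
BOND_CUTOFF_S = 2.2  # A, bonds to sulfur


@dataclass(frozen=True)
class GridSpec:
    """An axis-aligned cubic lattice: origin + spacing + shape."""

    origin: tuple[float, float, float]
    spacing: float
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        if any(n <= 0 for n in self.shape):
            raise ValueError("shape must be positive")

    @property
    def n_points(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        o = np.asarray(self.origin)
        return tuple(o[d] + self.spacing * np.arange(self.shape[d])
                     for d in range(3))

    def points(self) -> np.ndarray:
        """All lattice coordinates, shape (n_points, 3), C order."""
        ax, ay, az = self.axes()
        gx, gy, gz = np.meshgrid(ax, ay, az, indexing="ij")
        return np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)

    def point(self, idx: tuple[int, int, int]) -> np.ndarray:
        return np.asarray(self.origin) + self.spacing * np.asarray(idx)


@dataclass
class MIF:
    """One probe's energy field over a grid, with contributor bookkeeping.

    ``max_contributor`` holds, per grid point, the serial of the atom with
    the single most favourable pair term, or -1 where no atom term is
    negative; ``best_energy`` is that term's value (+inf where none).
    """

    grid: GridSpec
    probe: ProbeType
    energy: np.ndarray          # (nx, ny, nz) kcal/mol, clamped
    max_contributor: np.ndarray  # (nx, ny, nz) int serial or -1
    best_energy: np.ndarray     # (nx, ny, nz) most favourable single term
    pocket_mask: np.ndarray     # (nx, ny, nz) bool

    def __post_init__(self) -> None:
        for arr in (self.energy, self.max_contributor, self.best_energy,
                    self.pocket_mask):
            if arr.shape != self.grid.shape:
                raise ValueError("field shape does not match grid")
        if not np.all(np.isfinite(self.energy)):
            raise ValueError("energy field must be finite (clamped)")


def build_grid(pocket_coords: np.ndarray, spacing: float = 0.5,
               padding: float = 3.0) -> GridSpec:
    """Lattice covering the pocket bounding box plus padding.

    The origin snaps down to the spacing lattice so identical inputs give
    identical grids regardless of floating-point noise in the bbox.
    """
    coords = np.asarray(pocket_coords, dtype=float).reshape(-1, 3)
    if coords.size == 0:
        raise ValueError("need at least one pocket atom")
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    lo = np.floor((coords.min(axis=0) - padding) / spacing) * spacing
    hi = np.ceil((coords.max(axis=0) + padding) / spacing) * spacing
    shape = tuple(int(round((h - l) / spacing)) + 1 for l, h in zip(lo, hi))
    return GridSpec(origin=tuple(lo), spacing=float(spacing), shape=shape)


# ---------------------------------------------------------------------------
# Pair energy

def _hbond_partner(probe: ProbeType, atom_class: str) -> bool:
    if probe.hbond_role == "donor":
        return atom_class in ACCEPTOR_CAPABLE
    if probe.hbond_role == "acceptor":
        return atom_class in DONOR_CAPABLE
    if probe.hbond_role == "both":
        return atom_class in (ACCEPTOR_CAPABLE | DONOR_CAPABLE)
    return False


def _pair_terms(probe: ProbeType, atom_class: str, rmin_half: float,
                eps: float, charge: float, r: np.ndarray,
                geometry: np.ndarray | float, params: ModelParams
                ) -> np.ndarray:
    """Vectorised unclamped pair energy for one atom at distances ``r``."""
    r = np.asarray(r, dtype=float)
    eps_mix = np.sqrt(probe.eps * eps)
    if probe.polar_eps_scale != 1.0 and atom_class in POLAR_CLASSES:
        eps_mix *= probe.polar_eps_scale
    rmin_mix = probe.rmin_half + rmin_half
    x6 = (rmin_mix / r) ** 6
    e = eps_mix * (x6 * x6 - 2.0 * x6)
    if probe.charge != 0.0 and charge != 0.0:
        # shifted Coulomb: continuous decay to exactly 0 at the cutoff
        k = (params.coulomb_constant * probe.charge * charge
             / params.dielectric_slope)
        shift = 1.0 / (params.cutoff * params.cutoff)
        e = e + np.where(r <= params.cutoff, k * (1.0 / (r * r) - shift), 0.0)
    if probe.hbond_emax != 0.0 and _hbond_partner(probe, atom_class):
        y = (params.hbond_d0 / r)
        radial = 5.0 * y**12 - 6.0 * y**10   # -1 at r = d0
        e = e + (-probe.hbond_emax) * radial * np.asarray(geometry)
    return e


def pair_energy(probe: ProbeType, atom_class: str, rmin_half: float,
                eps: float, charge: float, distance: float,
                geometry: float = 1.0,
                params: ModelParams | None = None) -> float:
    """Probe-atom interaction energy at one distance (kcal/mol).

    ``geometry`` is the H-bond angular factor in [0, 1]; the result is
    clamped at ``params.clamp`` (+5 kcal/mol by default).
    """
    if distance <= 0:
        raise ValueError("distance must be > 0")
    params = params or load_params()
    e = _pair_terms(probe, atom_class, rmin_half, eps, charge,
                    np.asarray([distance]), geometry, params)[0]
    return float(min(e, params.clamp))


# ---------------------------------------------------------------------------
# H-bond geometry

def hbond_directions(structure: TypedStructure) -> list[np.ndarray | None]:
    """Idealised lone-pair/H direction per atom, from bonded neighbours.

    The direction points away from the mean of the bonded heavy-atom
    neighbours — the side on which the implicit hydrogen or lone pair sits.
    Atoms with no resolvable neighbour get ``None`` (angular factor 1).
    """
    coords = structure.coords
    n = len(structure)
    dirs: list[np.ndarray | None] = [None] * n
    if n < 2:
        return dirs
    capable = [i for i in range(n)
               if structure.atom_class[i] in (ACCEPTOR_CAPABLE | DONOR_CAPABLE)]
    for i in capable:
        cutoff = BOND_CUTOFF_S if structure.atoms[i].element == "S" else BOND_CUTOFF
        d = np.linalg.norm(coords - coords[i], axis=1)
        nbr = np.nonzero((d > 1e-6) & (d <= cutoff))[0]
        if nbr.size == 0:
            continue
        v = coords[i] - coords[nbr].mean(axis=0)
        norm = np.linalg.norm(v)
        if norm > 1e-6:
            dirs[i] = v / norm
    return dirs


def _geometry_factor(direction: np.ndarray | None, atom_pos: np.ndarray,
                     points: np.ndarray) -> np.ndarray | float:
    """cos^2 of the angle between the ideal direction and each probe
    direction, zero beyond 90 degrees; 1 when the direction is unknown."""
    if direction is None:
        return 1.0
    v = points - atom_pos
    norm = np.linalg.norm(v, axis=1)
    norm[norm < 1e-9] = 1e-9
    cos = (v @ direction) / norm
    return np.where(cos > 0.0, cos * cos, 0.0)


# ---------------------------------------------------------------------------
# Field computation

def compute_mif(structure: TypedStructure, pocket: PocketDefinition | None,
                probe: ProbeType, grid: GridSpec,
                cutoff: float | None = None,
                params: ModelParams | None = None,
                clamp: bool = True) -> MIF:
    """Evaluate one probe's interaction field on a grid.

    The energy at each point is the sum of pair terms over all structure
    atoms within ``cutoff``; the per-point most favourable single-atom term
    and its atom serial are recorded.  ``pocket`` drives only the pocket
    envelope mask (union of atom spheres, vdW + mask shell); pass ``None``
    for an all-true mask.
    """
    params = params or load_params()
    cutoff = params.cutoff if cutoff is None else float(cutoff)
    nx, ny, nz = grid.shape
    energy = np.zeros(grid.shape)
    best = np.full(grid.shape, np.inf)
    contrib = np.full(grid.shape, -1, dtype=int)

    coords = structure.coords if len(structure) else np.empty((0, 3))
    dirs = (hbond_directions(structure)
            if probe.hbond_role != "none" else [None] * len(structure))
    origin = np.asarray(grid.origin)
    h = grid.spacing
    any_overlap = False

    for i in range(len(structure)):
        pos = coords[i]
        lo = np.maximum(np.floor((pos - cutoff - origin) / h).astype(int), 0)
        hi = np.minimum(np.ceil((pos + cutoff - origin) / h).astype(int),
                        np.array(grid.shape) - 1)
        if np.any(lo > hi):
            continue
        sl = tuple(slice(l, u + 1) for l, u in zip(lo, hi))
        axes = [origin[d] + h * np.arange(lo[d], hi[d] + 1) for d in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
        r = np.linalg.norm(pts - pos, axis=1)
        within = r <= cutoff
        if not np.any(within):
            continue
        any_overlap = True
        r = np.maximum(r, 0.05)  # on-lattice atom: finite repulsive core
        geom = 1.0
        if probe.hbond_role != "none" and dirs[i] is not None:
            geom = _geometry_factor(dirs[i], pos, pts)
        e = _pair_terms(probe, structure.atom_class[i],
                        float(structure.rmin_half[i]),
                        float(structure.eps[i]),
                        float(structure.partial_charge[i]),
                        r, geom, params)
        e = np.minimum(e, params.clamp)  # per-pair clamp
        e[~within] = 0.0
        box = e.reshape(gx.shape)
        energy[sl] += box
        serial = structure.atoms[i].serial
        eb = np.where(within, e, np.inf).reshape(gx.shape)
        better = eb < best[sl]
        best[sl] = np.where(better, eb, best[sl])
        sub = contrib[sl]
        sub[better] = serial
        contrib[sl] = sub

    if len(structure) and not any_overlap:
        log.warning("grid does not overlap the structure within the cutoff; "
                    "returning an all-zero field")
    # a contributor only counts where its best term is favourable
    contrib[~(best < 0.0)] = -1
    if clamp:
        energy = np.minimum(energy, params.clamp)
    mask = pocket_envelope_mask(structure, pocket, grid, params)
    return MIF(grid=grid, probe=probe, energy=energy,
               max_contributor=contrib, best_energy=best, pocket_mask=mask)


def pocket_envelope_mask(structure: TypedStructure,
                         pocket: PocketDefinition | None, grid: GridSpec,
                         params: ModelParams | None = None) -> np.ndarray:
    """Union-of-spheres pocket envelope on the grid.

    Each pocket-residue atom contributes a sphere of radius
    (vdW rmin/2 + mask shell); points inside any sphere are in the
    envelope.  Keeps similarity from being dominated by far-field bulk.
    """
    params = params or load_params()
    if pocket is None or len(structure) == 0:
        return np.ones(grid.shape, dtype=bool)
    idx = pocket.atom_indices(structure)
    if idx.size == 0:
        return np.zeros(grid.shape, dtype=bool)
    mask = np.zeros(grid.shape, dtype=bool)
    origin = np.asarray(grid.origin)
    h = grid.spacing
    coords = structure.coords
    for i in idx:
        radius = float(structure.rmin_half[i]) + params.mask_shell
        pos = coords[i]
        lo = np.maximum(np.floor((pos - radius - origin) / h).astype(int), 0)
        hi = np.minimum(np.ceil((pos + radius - origin) / h).astype(int),
                        np.array(grid.shape) - 1)
        if np.any(lo > hi):
            continue
        sl = tuple(slice(l, u + 1) for l, u in zip(lo, hi))
        axes = [origin[d] + h * np.arange(lo[d], hi[d] + 1) for d in range(3)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        d2 = (gx - pos[0])**2 + (gy - pos[1])**2 + (gz - pos[2])**2
        mask[sl] |= d2 <= radius * radius
    return mask


# ---------------------------------------------------------------------------
# OpenDX export

def export_field(mif: MIF, comment: str | None = None) -> str:
    """Serialise a MIF's energy field to OpenDX text."""
    comment = comment or f"pocketmif {mif.probe.name} field (kcal/mol)"
    return write_dx(np.asarray(mif.grid.origin), mif.grid.spacing,
                    mif.energy, comment=comment)


def import_field(text: str) -> tuple[GridSpec, np.ndarray]:
    """Read an OpenDX scalar file back into (GridSpec, values)."""
    origin, spacing, values = read_dx(text)
    return GridSpec(origin=tuple(origin), spacing=spacing,
                    shape=values.shape), values
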