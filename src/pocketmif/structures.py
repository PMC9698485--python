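"""Macromolecular structures: PDB I/O, atom typing, pockets, superposition
and pairwise sequence comparison.

Conventions
-----------
* wwPDB v3.3 column layout; only model 1 is read by default.
* Residue identity is ``(chain_id, residue_number, insertion_code)`` with
  1-based author numbering.
* Extended-atom model: explicit hydrogens are dropped on read (logged);
  H-bonding capacity is encoded in each heavy atom's interaction class.
* Alternate locations resolve to the highest-occupancy conformer, ties
  broken by altloc identifier.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.spatial.transform import Rotation

from . import atomtypes
from .atomtypes import lookup_class
from .config import ModelParams, load_params

log = logging.getLogger(__name__)

__all__ = [
    "AtomRecord", "TypedStructure", "PocketDefinition", "Superposition",
    "SequenceComparison", "PDBParseError", "read_structure",
    "write_structure", "assign_atom_types", "define_pocket", "superpose",
    "pairwise_identity",
]


class PDBParseError(ValueError):
    """Raised for empty or garbled PDB input, naming the first bad line."""


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom of a structure."""

    serial: int
    name: str
    element: str
    residue_name: str
    chain_id: str
    residue_number: int
    coords: tuple[float, float, float]
    is_hetero: bool = False
    is_water: bool = False
    insertion_code: str = ""

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError(f"atom {self.serial}: empty element")
        if not all(np.isfinite(self.coords)):
            raise ValueError(f"atom {self.serial}: non-finite coordinates")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.insertion_code)


@dataclass
class TypedStructure:
    """Atoms plus per-atom interaction class, LJ parameters and charge.

    The arrays are index-aligned with ``atoms``; ``coords`` is an (N, 3)
    float array in Angstrom.
    """

    atoms: list[AtomRecord]
    atom_class: list[str]
    rmin_half: np.ndarray      # (N,) A
    eps: np.ndarray            # (N,) kcal/mol
    partial_charge: np.ndarray  # (N,) e

    def __post_init__(self) -> None:
        n = len(self.atoms)
        if not (len(self.atom_class) == len(self.rmin_half)
                == len(self.eps) == len(self.partial_charge) == n):
            raise ValueError("typed arrays not aligned with atom list")
        bad = set(self.atom_class) - atomtypes.ATOM_CLASSES
        if bad:
            raise ValueError(f"unknown atom classes {bad}")
        if np.any(self.rmin_half <= 0):
            raise ValueError("vdw radii must be positive")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float).reshape(-1, 3)

    @property
    def serials(self) -> np.ndarray:
        return np.array([a.serial for a in self.atoms], dtype=int)

    def subset(self, indices: np.ndarray | list[int]) -> "TypedStructure":
        idx = np.asarray(indices, dtype=int)
        return TypedStructure(
            atoms=[self.atoms[i] for i in idx],
            atom_class=[self.atom_class[i] for i in idx],
            rmin_half=self.rmin_half[idx],
            eps=self.eps[idx],
            partial_charge=self.partial_charge[idx],
        )

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Unique residue keys in order of first appearance."""
        seen: dict[tuple[str, int, str], None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_key)
        return list(seen)


@dataclass
class PocketDefinition:
    """A pocket given either as residues or as a sphere."""

    mode: str  # "residue-list" | "centre-radius"
    residues: list[tuple[str, int, str]] = field(default_factory=list)
    centre: tuple[float, float, float] | None = None
    radius: float | None = None

    def __post_init__(self) -> None:
        if self.mode == "residue-list":
            if not self.residues:
                raise ValueError("residue-list pocket with no residues")
        elif self.mode == "centre-radius":
            if self.radius is None or self.radius <= 0:
                raise ValueError("centre-radius pocket needs radius > 0")
            if self.centre is None:
                raise ValueError("centre-radius pocket needs a centre")
        else:
            raise ValueError(f"unknown pocket mode {self.mode!r}")

    def atom_indices(self, structure: TypedStructure) -> np.ndarray:
        """Indices of the structure's atoms belonging to the pocket."""
        if self.mode == "residue-list":
            keys = set(self.residues)
            idx = [i for i, a in enumerate(structure.atoms)
                   if a.residue_key in keys]
        else:
            d = np.linalg.norm(structure.coords - np.asarray(self.centre), axis=1)
            idx = list(np.nonzero(d <= self.radius)[0])
        return np.asarray(idx, dtype=int)


@dataclass(frozen=True)
class Superposition:
    """A proper rigid transform ``x -> R x + t`` with its fit RMSD."""

    rotation: np.ndarray   # (3, 3), det = +1
    translation: np.ndarray  # (3,)
    rmsd: float            # A
    n_pairs: int

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class SequenceComparison:
    identity_pct: float
    similarity_pct: float
    aligned_length: int
    gap_count: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.identity_pct <= self.similarity_pct <= 100.0):
            raise ValueError("need 0 <= identity <= similarity <= 100")


# ---------------------------------------------------------------------------
# PDB I/O

_WATER_NAMES = {"HOH", "WAT", "DOD"}


def _validate_pdb_text(text: str) -> None:
    if not text.strip():
        raise PDBParseError("empty PDB input")
    n_atoms = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6].strip()
        if rec in ("ATOM", "HETATM"):
            n_atoms += 1
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
                int(line[6:11])
            except (ValueError, IndexError):
                raise PDBParseError(
                    f"line {lineno}: garbled {rec} record: {line.rstrip()!r}"
                ) from None
    if n_atoms == 0:
        first = text.splitlines()[0].rstrip()
        raise PDBParseError(f"no ATOM/HETATM records; first line: {first!r}")


def read_structure(pdb_text: str, model_index: int = 0,
                   altloc_policy: str = "occupancy") -> list[AtomRecord]:
    """Parse PDB text into a list of :class:`AtomRecord`.

    Alternate locations are resolved per ``altloc_policy`` (only
    ``"occupancy"`` is implemented: keep the highest-occupancy conformer,
    ties broken by altloc id).  Waters are retained and flagged; explicit
    hydrogens are dropped with a warning.
    """
    if altloc_policy != "occupancy":
        raise ValueError(f"unknown altloc policy {altloc_policy!r}")
    _validate_pdb_text(pdb_text)
    st = gemmi.read_pdb_string(pdb_text)
    if model_index >= len(st):
        raise PDBParseError(
            f"model index {model_index} out of range ({len(st)} models)")
    model = st[model_index]

    atoms: list[AtomRecord] = []
    n_hydrogens = 0
    for chain in model:
        for res in chain:
            # group altlocs by atom name, keep the winner
            by_name: dict[str, list[gemmi.Atom]] = {}
            for at in res:
                by_name.setdefault(at.name, []).append(at)
            for name, group in by_name.items():
                at = min(group, key=lambda a: (-a.occ, a.altloc or "~"))
                elem = at.element.name.upper()
                if elem in ("H", "D"):
                    n_hydrogens += 1
                    continue
                atoms.append(AtomRecord(
                    serial=at.serial,
                    name=name,
                    element=elem,
                    residue_name=res.name,
                    chain_id=chain.name,
                    residue_number=res.seqid.num,
                    coords=(at.pos.x, at.pos.y, at.pos.z),
                    is_hetero=res.het_flag == "H",
                    is_water=res.name in _WATER_NAMES,
                    insertion_code=(res.seqid.icode or "").strip(),
                ))
    if n_hydrogens:
        log.warning("dropped %d explicit hydrogen atoms (extended-atom model)",
                    n_hydrogens)
    if not atoms:
        raise PDBParseError("no heavy atoms in selected model")
    return atoms


def write_structure(atoms: list[AtomRecord]) -> str:
    """Render atoms as PDB ATOM/HETATM text (wwPDB v3.3 columns)."""
    lines = []
    for a in atoms:
        rec = "HETATM" if a.is_hetero else "ATOM  "
        # atom-name column convention: 1-2 char element names start in col 13
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        x, y, z = a.coords
        lines.append(
            f"{rec}{a.serial:5d} {name}{'':1s}{a.residue_name:>3s} "
            f"{a.chain_id[:1]:1s}{a.residue_number:4d}{a.insertion_code or ' ':1s}"
            f"   {x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {a.element:>2s}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Typing

def assign_atom_types(atoms: list[AtomRecord],
                      typing_table: dict[tuple[str, str], str] | None = None,
                      params: ModelParams | None = None) -> TypedStructure:
    """Assign interaction classes, LJ parameters and charges to atoms.

    Classes come from the (residue, atom-name) table with element fallback;
    LJ parameters from per-element defaults; formal charges from the class
    (cation/anion only).  Deterministic: identical input gives identical
    typing.
    """
    params = params or load_params()
    classes, rmin, eps, q = [], [], [], []
    for a in atoms:
        cls = lookup_class(a.residue_name, a.name, a.element, typing_table)
        classes.append(cls)
        r, e = params.atom_lj(a.element)
        rmin.append(r)
        eps.append(e)
        q.append(params.class_charges.get(cls, 0.0))
    return TypedStructure(
        atoms=list(atoms),
        atom_class=classes,
        rmin_half=np.asarray(rmin),
        eps=np.asarray(eps),
        partial_charge=np.asarray(q),
    )


# ---------------------------------------------------------------------------
# Pockets

def define_pocket(structure: TypedStructure,
                  seed_atoms: np.ndarray | None = None,
                  residues: list[tuple[str, int, str]] | None = None,
                  centre: tuple[float, float, float] | None = None,
                  radius: float = 5.0) -> PocketDefinition:
    """Build a pocket definition from one of three seeds.

    ``seed_atoms`` (an (M, 3) array, e.g. ligand coordinates) selects every
    residue with any non-water atom within ``radius`` of any seed atom;
    ``residues`` passes an explicit list through; ``centre`` + ``radius``
    makes a spherical pocket.  Residues are ordered by (chain, number,
    insertion code).
    """
    if residues is not None:
        present = set(k for a in structure.atoms for k in [a.residue_key])
        missing = [r for r in residues if r not in present]
        if missing:
            raise ValueError(f"pocket residues not in structure: {missing}")
        return PocketDefinition(mode="residue-list", residues=sorted(residues))
    if seed_atoms is not None:
        seed = np.asarray(seed_atoms, dtype=float).reshape(-1, 3)
        coords = structure.coords
        # residues containing a seed atom are the ligand, not the pocket
        seed_res = {a.residue_key for i, a in enumerate(structure.atoms)
                    if np.min(np.linalg.norm(seed - coords[i], axis=1)) < 1e-6}
        keys: set[tuple[str, int, str]] = set()
        for i, a in enumerate(structure.atoms):
            if a.is_water or a.residue_key in seed_res:
                continue
            d = np.linalg.norm(seed - coords[i], axis=1)
            if np.any(d <= radius):
                keys.add(a.residue_key)
        if not keys:
            raise ValueError("no pocket residues within "
                             f"{radius} A of the seed atoms")
        return PocketDefinition(mode="residue-list", residues=sorted(keys))
    if centre is not None:
        return PocketDefinition(mode="centre-radius", centre=tuple(centre),
                                radius=radius)
    raise ValueError("one of seed_atoms, residues, centre is required")


# ---------------------------------------------------------------------------
# Superposition (Kabsch)

def superpose(coords_a: np.ndarray, coords_b: np.ndarray,
              correspondence: list[tuple[int, int]] | None = None
              ) -> Superposition:
    """Least-squares rigid superposition of B onto A.

    Returns the proper rotation + translation minimising the RMSD of the
    mapped pairs (Kabsch); ``correspondence`` defaults to the identity
    mapping.  Two pairs are accepted but degenerate (rotation about the
    pair axis is unconstrained).
    """
    a = np.asarray(coords_a, dtype=float).reshape(-1, 3)
    b = np.asarray(coords_b, dtype=float).reshape(-1, 3)
    if correspondence is None:
        if len(a) != len(b):
            raise ValueError("coordinate sets differ in length and no "
                             "correspondence was given")
        ia = ib = np.arange(len(a))
    else:
        pairs = np.asarray(correspondence, dtype=int)
        if pairs.ndim != 2 or pairs.shape[1] != 2:
            raise ValueError("correspondence must be a list of index pairs")
        ia, ib = pairs[:, 0], pairs[:, 1]
    if len(ia) < 2:
        raise ValueError("need at least 2 correspondence pairs")
    pa, pb = a[ia], b[ib]
    ca, cb = pa.mean(axis=0), pb.mean(axis=0)
    rot, rssd = Rotation.align_vectors(pa - ca, pb - cb)
    R = rot.as_matrix()
    t = ca - R @ cb
    rmsd = float(rssd / np.sqrt(len(ia)))
    return Superposition(rotation=R, translation=t, rmsd=rmsd,
                         n_pairs=int(len(ia)))


def transform_structure(structure: TypedStructure,
                        sup: Superposition) -> TypedStructure:
    """Return a copy of the structure with transformed coordinates."""
    new_xyz = sup.apply(structure.coords)
    new_atoms = [replace(a, coords=tuple(xyz))
                 for a, xyz in zip(structure.atoms, new_xyz)]
    return TypedStructure(
        atoms=new_atoms,
        atom_class=list(structure.atom_class),
        rmin_half=structure.rmin_half.copy(),
        eps=structure.eps.copy(),
        partial_charge=structure.partial_charge.copy(),
    )


# ---------------------------------------------------------------------------
# Sequence comparison

def pairwise_identity(seq_a: str, seq_b: str,
                      matrix: str = "BLOSUM62",
                      gap_open: float = 10.0,
                      gap_extend: float = 0.5) -> SequenceComparison:
    """Global pairwise identity/similarity (EMBOSS-needle-like defaults).

    Identity is the fraction of identical aligned pairs over the alignment
    length (gap columns included); similarity counts pairs with a positive
    substitution score.  Gap penalties apply over the whole alignment,
    including terminal gaps.
    """
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load(matrix)
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    aln = aligner.align(seq_a.upper(), seq_b.upper())[0]
    sub = aligner.substitution_matrix
    col_a, col_b = str(aln[0]), str(aln[1])
    length = len(col_a)
    identical = similar = gaps = 0
    for x, y in zip(col_a, col_b):
        if x == "-" or y == "-":
            gaps += 1
            continue
        if x == y:
            identical += 1
        if sub[x, y] > 0:
            similar += 1
    return SequenceComparison(
        identity_pct=100.0 * identical / length,
        similarity_pct=100.0 * similar / length,
        aligned_length=length,
        gap_count=gaps,
    )
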