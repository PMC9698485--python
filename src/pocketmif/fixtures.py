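"""Deterministic synthetic pockets for testing and demos.

The generator emulates the geometry that matters to pocket MIFs — a
concave site whose wall presents typed chemistry to the interior — as a
hemispherical shell of small residue-like atom clusters around the origin
(the pocket mouth opens toward +z).  Each cluster carries a standard
residue name (LEU, GLN, ASN, GLU, LYS) with roughly bonded local geometry,
so the production typing table applies unchanged and H-bond directions
resolve from real neighbours.  Everything is a pure function of the spec
and seed.

This is a caricature of a binding site: no backbone trace, no rotamers, no
secondary structure, no solvent — sufficient for exercising fields,
similarity, attribution and water placement, not for conclusions about any
real protein.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .structures import (AtomRecord, PocketDefinition, TypedStructure,
                         assign_atom_types)

__all__ = ["FixtureSpec", "make_toy_pocket", "perturb"]

#: residue template per composition class: (residue_name,
#:  [(atom_name, element, offset_along_inward, offset_perp), ...])
#: the first atom is the interacting tip, placed on the shell pointing at
#: the pocket centre; later atoms sit behind/beside it (roughly bonded).
_TEMPLATES: dict[str, tuple[str, list[tuple[str, str, float, float]]]] = {
    "hydrophobic": ("LEU", [("CD1", "C", 0.0, 0.0),
                            ("CG", "C", -1.52, 0.0),
                            ("CD2", "C", -1.90, 1.45)]),
    "donor": ("GLN", [("NE2", "N", 0.0, 0.0),
                      ("CD", "C", -1.33, 0.0),
                      ("OE1", "O", -1.85, 1.10),
                      ("CG", "C", -2.85, -0.30)]),
    "acceptor": ("ASN", [("OD1", "O", 0.0, 0.0),
                         ("CG", "C", -1.23, 0.0),
                         ("ND2", "N", -1.80, 1.15),
                         ("CB", "C", -2.75, -0.30)]),
    "anion": ("GLU", [("OE1", "O", 0.0, 0.0),
                      ("CD", "C", -1.25, 0.0),
                      ("OE2", "O", -1.75, 1.10),
                      ("CG", "C", -2.75, -0.30)]),
    "cation": ("LYS", [("NZ", "N", 0.0, 0.0),
                       ("CE", "C", -1.49, 0.0),
                       ("CD", "C", -2.55, 1.20)]),
}

CLASS_ORDER = ("hydrophobic", "donor", "acceptor", "anion", "cation")


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic pocket."""

    seed: int = 0
    n_residues: int = 10
    composition: dict[str, float] = field(
        default_factory=lambda: {"hydrophobic": 0.5, "donor": 0.2,
                                 "acceptor": 0.2, "anion": 0.1,
                                 "cation": 0.0})
    pocket_radius: float = 6.0
    jitter_sigma: float = 0.0
    with_ligand: bool = False

    def __post_init__(self) -> None:
        if self.n_residues <= 0:
            raise ValueError("n_residues must be positive")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"composition fractions sum to {total}, not 1")
        unknown = set(self.composition) - set(CLASS_ORDER)
        if unknown:
            raise ValueError(f"unknown composition classes {unknown}")


def _hemisphere_points(n: int, radius: float) -> np.ndarray:
    """Deterministic, roughly even anchors on the lower hemisphere
    (Fibonacci spiral; pocket opens toward +z)."""
    i = np.arange(n)
    # z from just below the equator down to the pole
    z = -(0.15 + 0.85 * (i + 0.5) / n)
    phi = i * np.pi * (3.0 - np.sqrt(5.0))  # golden angle
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    pts = np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)
    # per-residue radial modulation: real pocket walls are not a perfect
    # sphere, and exact equidistance would make per-point argmin
    # attribution degenerate at the centre
    r = radius * (1.0 + 0.04 * np.sin(2.7 * i + 0.5))
    return r[:, None] * pts


def _perp(u: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """A deterministic unit vector perpendicular to u, rotated by a seeded
    angle about u."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(u @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    p = np.cross(u, ref)
    p /= np.linalg.norm(p)
    q = np.cross(u, p)
    ang = rng.uniform(0.0, 2.0 * np.pi)
    return np.cos(ang) * p + np.sin(ang) * q


def make_toy_pocket(spec: FixtureSpec
                    ) -> tuple[TypedStructure, PocketDefinition]:
    """Build a typed synthetic pocket from a spec.

    Residue classes are drawn from the composition with a generator seeded
    by ``spec.seed``; identical specs yield bit-identical structures.  With
    ``with_ligand`` a two-atom ligand (hydrophobic C + acceptor O, residue
    LIG) sits at the pocket centre and is included as HETATM records.
    """
    rng = np.random.default_rng(spec.seed)
    anchors = _hemisphere_points(spec.n_residues, spec.pocket_radius)
    classes = list(spec.composition.keys())
    probs = np.array([spec.composition[c] for c in classes])
    draw = rng.choice(len(classes), size=spec.n_residues, p=probs)

    atoms: list[AtomRecord] = []
    serial = 1
    for ridx in range(spec.n_residues):
        cls = classes[draw[ridx]]
        resname, template = _TEMPLATES[cls]
        a = anchors[ridx]
        inward = -a / np.linalg.norm(a)          # toward pocket centre
        perp = _perp(inward, rng)
        for name, elem, d_in, d_perp in template:
            pos = a + d_in * inward + d_perp * perp
            atoms.append(AtomRecord(
                serial=serial, name=name, element=elem,
                residue_name=resname, chain_id="A",
                residue_number=ridx + 1,
                coords=tuple(float(v) for v in pos)))
            serial += 1

    if spec.with_ligand:
        for name, elem, pos in (("C1", "C", (0.0, 0.0, 0.0)),
                                ("O2", "O", (0.0, 0.0, 1.25))):
            atoms.append(AtomRecord(
                serial=serial, name=name, element=elem, residue_name="LIG",
                chain_id="L", residue_number=1, coords=pos, is_hetero=True))
            serial += 1

    structure = assign_atom_types(atoms)
    pocket = PocketDefinition(
        mode="residue-list",
        residues=[("A", i + 1, "") for i in range(spec.n_residues)])
    if spec.jitter_sigma > 0:
        structure = perturb(structure, spec.jitter_sigma, spec.seed + 1)
    return structure, pocket


def perturb(structure: TypedStructure, sigma: float,
            seed: int) -> TypedStructure:
    """Seeded isotropic Gaussian jitter of every coordinate (classes and
    typing unchanged)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return structure
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=(len(structure), 3))
    new_atoms = [replace(a, coords=tuple(np.asarray(a.coords) + n))
                 for a, n in zip(structure.atoms, noise)]
    return TypedStructure(
        atoms=new_atoms,
        atom_class=list(structure.atom_class),
        rmin_half=structure.rmin_half.copy(),
        eps=structure.eps.copy(),
        partial_charge=structure.partial_charge.copy(),
    )
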