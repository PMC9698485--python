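"""Interaction atom-type assignment for protein heavy atoms.

Each heavy atom is assigned one interaction class that encodes its implicit
hydrogen-bonding capacity (extended-atom model): ``hydrophobic``, ``donor``,
``acceptor``, ``donor_acceptor``, ``cation``, ``anion`` or ``polar`` (polar
but neither donating nor accepting, e.g. amide/carboxylate carbons).

The table covers the 20 standard residues plus water; unknown
(residue, atom) pairs fall back to element defaults, so assignment is total
for any structure made of known elements.
"""

from __future__ import annotations

HYDROPHOBIC = "hydrophobic"
DONOR = "donor"
ACCEPTOR = "acceptor"
DONOR_ACCEPTOR = "donor_acceptor"
CATION = "cation"
ANION = "anion"
POLAR = "polar"

ATOM_CLASSES = frozenset(
    {HYDROPHOBIC, DONOR, ACCEPTOR, DONOR_ACCEPTOR, CATION, ANION, POLAR}
)

#: classes able to donate an (implicit) hydrogen
DONOR_CAPABLE = frozenset({DONOR, DONOR_ACCEPTOR, CATION})
#: classes able to accept a hydrogen bond
ACCEPTOR_CAPABLE = frozenset({ACCEPTOR, DONOR_ACCEPTOR, ANION})
#: classes treated as polar by the CRY (lipophilic) probe
POLAR_CLASSES = frozenset(
    {DONOR, ACCEPTOR, DONOR_ACCEPTOR, CATION, ANION, POLAR}
)

# Backbone atoms, shared by all standard residues.  The amide nitrogen is a
# donor (proline excepted), the carbonyl oxygen an acceptor; CA is aliphatic.
_BACKBONE = {
    "N": DONOR,
    "CA": HYDROPHOBIC,
    "C": POLAR,
    "O": ACCEPTOR,
    "OXT": ANION,
}

# Side-chain classes per residue.  Aromatic/aliphatic carbons are
# hydrophobic; amide N/O split into donor/acceptor; carboxylates are anionic
# (and hence acceptor-capable); ammonium/guanidinium nitrogens cationic
# (donor-capable); hydroxyls and imidazole/thiol both donate and accept.
_SIDECHAINS: dict[str, dict[str, str]] = {
    "ALA": {"CB": HYDROPHOBIC},
    "ARG": {
        "CB": HYDROPHOBIC, "CG": HYDROPHOBIC, "CD": HYDROPHOBIC,
        "NE": CATION, "CZ": POLAR, "NH1": CATION, "NH2": CATION,
    },
    "ASN": {"CB": HYDROPHOBIC, "CG": POLAR, "OD1": ACCEPTOR, "ND2": DONOR},
    "ASP": {"CB": HYDROPHOBIC, "CG": POLAR, "OD1": ANION, "OD2": ANION},
    "CYS": {"CB": HYDROPHOBIC, "SG": DONOR_ACCEPTOR},
    "GLN": {
        "CB": HYDROPHOBIC, "CG": HYDROPHOBIC, "CD": POLAR,
        "OE1": ACCEPTOR, "NE2": DONOR,
    },
    "GLU": {
        "CB": HYDROPHOBIC, "CG": HYDROPHOBIC, "CD": POLAR,
        "OE1": ANION, "OE2": ANION,
    },
    "GLY": {},
    "HIS": {
        "CB": HYDROPHOBIC, "CG": POLAR, "ND1": DONOR_ACCEPTOR,
        "CD2": POLAR, "CE1": POLAR, "NE2": DONOR_ACCEPTOR,
    },
    "ILE": {"CB": HYDROPHOBIC, "CG1": HYDROPHOBIC, "CG2": HYDROPHOBIC,
            "CD1": HYDROPHOBIC},
    "LEU": {"CB": HYDROPHOBIC, "CG": HYDROPHOBIC, "CD1": HYDROPHOBIC,
            "CD2": HYDROPHOBIC},
    "LYS": {"CB": HYDROPHOBIC, "CG": HYDROPHOBIC, "CD": HYDROPHOBIC,
            "CE": HYDROPHOBIC, "NZ": CATION},
    "MET": {"CB": HYDROPHOBIC, "CG": HYDROPHOBIC, "SD": HYDROPHOBIC,
            "CE": HYDROPHOBIC},
    "PHE": {"CB": HYDROPHOBIC, "CG": HYDROPHOBIC, "CD1": HYDROPHOBIC,
            "CD2": HYDROPHOBIC, "CE1": HYDROPHOBIC, "CE2": HYDROPHOBIC,
            "CZ": HYDROPHOBIC},
    "PRO": {"CB": HYDROPHOBIC, "CG": HYDROPHOBIC, "CD": HYDROPHOBIC,
            # proline amide N has no H to donate
            "N": POLAR},
    "SER": {"CB": HYDROPHOBIC, "OG": DONOR_ACCEPTOR},
    "THR": {"CB": HYDROPHOBIC, "OG1": DONOR_ACCEPTOR, "CG2": HYDROPHOBIC},
    "TRP": {"CB": HYDROPHOBIC, "CG": HYDROPHOBIC, "CD1": POLAR,
            "CD2": HYDROPHOBIC, "NE1": DONOR, "CE2": POLAR,
            "CE3": HYDROPHOBIC, "CZ2": HYDROPHOBIC, "CZ3": HYDROPHOBIC,
            "CH2": HYDROPHOBIC},
    "TYR": {"CB": HYDROPHOBIC, "CG": HYDROPHOBIC, "CD1": HYDROPHOBIC,
            "CD2": HYDROPHOBIC, "CE1": HYDROPHOBIC, "CE2": HYDROPHOBIC,
            "CZ": POLAR, "OH": DONOR_ACCEPTOR},
    "HOH": {"O": DONOR_ACCEPTOR, "OW": DONOR_ACCEPTOR},
    "WAT": {"O": DONOR_ACCEPTOR, "OW": DONOR_ACCEPTOR},
}

#: element fallback for atoms not covered by the residue table
ELEMENT_FALLBACK = {
    "C": HYDROPHOBIC,
    "N": DONOR,
    "O": ACCEPTOR,
    "S": DONOR_ACCEPTOR,
    "P": POLAR,
    "F": ACCEPTOR,
    "CL": POLAR,
    "BR": POLAR,
    "I": POLAR,
}


def default_typing_table() -> dict[tuple[str, str], str]:
    """Return the (residue_name, atom_name) -> class lookup table.

    Backbone entries are merged into every amino-acid residue; residue
    entries override backbone ones (proline N).
    """
    table: dict[tuple[str, str], str] = {}
    for res, side in _SIDECHAINS.items():
        if res not in ("HOH", "WAT"):
            for name, cls in _BACKBONE.items():
                table[(res, name)] = cls
        for name, cls in side.items():
            table[(res, name)] = cls
    return table


def lookup_class(residue_name: str, atom_name: str, element: str,
                 table: dict[tuple[str, str], str] | None = None) -> str:
    """Resolve the interaction class for one atom.

    Falls back to element defaults for (residue, atom) pairs outside the
    table.  Raises ``KeyError`` for elements with no fallback.
    """
    table = _DEFAULT_TABLE if table is None else table
    cls = table.get((residue_name.upper(), atom_name.upper()))
    if cls is not None:
        return cls
    elem = element.upper()
    if elem not in ELEMENT_FALLBACK:
        raise KeyError(f"no interaction class for element {element!r} "
                       f"({residue_name} {atom_name})")
    return ELEMENT_FALLBACK[elem]


_DEFAULT_TABLE = default_typing_table()
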