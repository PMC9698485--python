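"""Force-field / run configuration.

All tunable constants of the interaction model live in one shipped TOML file
(``data/probes.toml``); :func:`load_params` parses it into dataclasses.  A
user file with the same layout can be substituted anywhere a ``ModelParams``
is accepted.
"""

from __future__ import annotations

import math
import tomllib
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

PROBE_NAMES = ("H", "CRY", "N1", "O", "OH2")
#: probes used for pocket characterisation / similarity
SIMILARITY_PROBES = ("H", "CRY", "N1", "O")
#: probes used for per-residue attribution
ATTRIBUTION_PROBES = ("CRY", "N1", "O")

#: per-probe significance level for attribution (kcal/mol): a grid point is
#: attributed only where its best single-atom term is below this.  The polar
#: probes use a level deeper than any dispersion-only attraction, so a
#: residue counts toward a donor/acceptor map only through actual H-bond or
#: electrostatic chemistry.
ATTRIBUTION_SIGNIFICANCE = {"CRY": 0.0, "N1": -0.5, "O": -0.5, "H": 0.0,
                            "OH2": -0.5}

HBOND_ROLES = ("none", "donor", "acceptor", "both")


@dataclass(frozen=True)
class ProbeType:
    """A GRID-style chemical probe.

    ``hbond_role`` states which protein partners the probe scores: a
    ``donor`` probe hydrogen-bonds to protein acceptors (N1), an
    ``acceptor`` probe to protein donors (O), ``both`` to either (OH2).
    ``hbond_emax`` is the well depth of the H-bond term (<= 0).
    """

    name: str
    rmin_half: float          # A, LJ rmin/2 contribution
    eps: float                # kcal/mol, LJ well depth
    charge: float             # e
    hbond_role: str
    hbond_emax: float         # kcal/mol
    contour: float            # kcal/mol, default binarisation level
    polar_eps_scale: float = 1.0  # CRY: reduced dispersion vs polar atoms

    def __post_init__(self) -> None:
        if self.hbond_role not in HBOND_ROLES:
            raise ValueError(f"bad hbond_role {self.hbond_role!r}")
        if self.hbond_role != "none" and self.hbond_emax > 0:
            raise ValueError("hbond_emax must be <= 0 for H-bonding probes")
        for v in (self.rmin_half, self.eps, self.charge, self.hbond_emax):
            if not math.isfinite(v):
                raise ValueError(f"non-finite parameter on probe {self.name}")


@dataclass(frozen=True)
class ModelParams:
    """Global constants of the pair-energy model plus the probe set."""

    probes: dict[str, ProbeType]
    element_lj: dict[str, tuple[float, float]]  # element -> (rmin_half, eps)
    class_charges: dict[str, float]             # atom class -> formal charge
    hbond_d0: float = 2.9
    coulomb_constant: float = 332.0636
    dielectric_slope: float = 4.0
    clamp: float = 5.0
    cutoff: float = 8.0
    spacing: float = 0.5
    padding: float = 3.0
    mask_shell: float = 3.0

    def probe(self, name: str) -> ProbeType:
        try:
            return self.probes[name]
        except KeyError:
            raise KeyError(f"unknown probe {name!r}; "
                           f"known: {sorted(self.probes)}") from None

    def atom_lj(self, element: str) -> tuple[float, float]:
        """(rmin_half, eps) for an element, with a generic default."""
        e = element.upper()
        return self.element_lj.get(e, self.element_lj["DEFAULT"])


def load_params(path: str | Path | None = None) -> ModelParams:
    """Load model parameters from TOML (the shipped file by default)."""
    if path is None:
        text = (resources.files("pocketmif") / "data" / "probes.toml").read_text()
    else:
        text = Path(path).read_text()
    raw = tomllib.loads(text)
    model = raw.get("model", {})
    probes = {}
    for name, p in raw["probes"].items():
        probes[name] = ProbeType(
            name=name,
            rmin_half=float(p["rmin_half"]),
            eps=float(p["eps"]),
            charge=float(p.get("charge", 0.0)),
            hbond_role=p.get("hbond_role", "none"),
            hbond_emax=float(p.get("hbond_emax", 0.0)),
            contour=float(p.get("contour", 0.0)),
            polar_eps_scale=float(p.get("polar_eps_scale", 1.0)),
        )
    element_lj = {
        name.upper(): (float(v["rmin_half"]), float(v["eps"]))
        for name, v in raw["elements"].items()
    }
    charges = raw.get("charges", {})
    class_charges = {
        "cation": float(charges.get("cation", 0.5)),
        "anion": float(charges.get("anion", -0.5)),
    }
    return ModelParams(
        probes=probes,
        element_lj=element_lj,
        class_charges=class_charges,
        hbond_d0=float(model.get("hbond_d0", 2.9)),
        coulomb_constant=float(model.get("coulomb_constant", 332.0636)),
        dielectric_slope=float(model.get("dielectric_slope", 4.0)),
        clamp=float(model.get("clamp", 5.0)),
        cutoff=float(model.get("cutoff", 8.0)),
        spacing=float(model.get("spacing", 0.5)),
        padding=float(model.get("padding", 3.0)),
        mask_shell=float(model.get("mask_shell", 3.0)),
    )


@dataclass
class WaterParams:
    """Tunables of the water-network placement/scoring procedure."""

    e_place: float = -5.0       # kcal/mol, OH2s placement cutoff
    exclusion_radius: float = 2.4  # A, min water-water distance
    max_waters: int = 30
    # ENTR field
    walk_distance: float = 2.8  # A
    walk_steps: int = 4
    tolerance: float = 0.5      # kcal/mol
    k_s: float = 1.5            # kcal/mol, full-confinement entropy penalty
    # DG_WAT combination
    alpha: float = 0.7          # weight on OH2n
    beta: float = 0.3           # weight on OH2s
    gamma: float = 0.2          # weight on CRY
    e_bulk: float = -9.0        # kcal/mol, bulk-water reference
    # local refinement after each placement
    refine_steps: int = 10
    refine_step_size: float = 0.1  # A


@dataclass
class RunConfig:
    """Top-level configuration echoed into every report."""

    spacing: float = 0.5
    padding: float = 3.0
    cutoff: float = 8.0
    thresholds: dict[str, float] = field(default_factory=dict)
    weights: dict[str, float] = field(default_factory=dict)
    water: WaterParams = field(default_factory=WaterParams)
    probe_file: str | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)
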