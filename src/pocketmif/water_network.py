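"""Water-network placement and free-energy scoring over pocket MIFs.

Waters are placed greedily on the OH2 (water-probe) field: the most
favourable unoccupied lattice point is taken, locally refined on the
interpolated field, added to the receptor so subsequent placements feel it
(the network field), and its exclusion sphere masked; the loop stops when
no remaining point binds more strongly than the placement cutoff.

Each placed water carries four components:

* ``oh2s`` — its OH2 energy against receptor (+ ligand) alone;
* ``oh2n`` — the same including the previously placed waters;
* ``cry``  — the lipophilic (CRY) field at its position;
* ``entr`` — an entropy penalty in [0, k_S]: the fraction of walk
  directions along which the OH2 enthalpy rises by more than a tolerance
  (a confined water loses more entropy than one free to drift).

These combine into a relative free-energy score
``dg_wat = alpha*oh2n + beta*oh2s + gamma*cry - e_bulk + entr`` against a
bulk-water reference, and each water is classified as happy
(< -2.0 kcal/mol), bulk-like [-2.0, 1.5), unhappy [1.5, 3.0) or
very-unhappy (>= 3.0).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .config import ModelParams, WaterParams, load_params
from .mif_engine import GridSpec, _pair_terms, build_grid, compute_mif
from .structures import PocketDefinition, TypedStructure

log = logging.getLogger(__name__)

__all__ = ["WaterSite", "WaterNetwork", "entr_field", "place_waters",
           "score_water", "classify_water", "CLASS_LABELS"]

CLASS_LABELS = ("happy", "bulk-like", "unhappy", "very-unhappy")

# 26-neighbourhood unit direction vectors, fixed lexicographic order
_DIRECTIONS = np.array([
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
], dtype=float)
_DIRECTIONS /= np.linalg.norm(_DIRECTIONS, axis=1, keepdims=True)


@dataclass
class WaterSite:
    position: tuple[float, float, float]
    oh2s: float
    oh2n: float
    cry: float
    entr: float
    order_placed: int
    dg_wat: float = math.nan
    label: str = ""

    def to_dict(self) -> dict:
        return {"position": list(self.position), "oh2s": self.oh2s,
                "oh2n": self.oh2n, "cry": self.cry, "entr": self.entr,
                "dg_wat": self.dg_wat, "label": self.label,
                "order_placed": self.order_placed}


@dataclass
class WaterNetwork:
    sites: list[WaterSite]
    grid: GridSpec
    config: WaterParams = field(default_factory=WaterParams)

    def __len__(self) -> int:
        return len(self.sites)

    def to_pdb(self) -> str:
        """HOH records, occupancy 1.00, B-factor column = dg_wat."""
        lines = []
        for i, s in enumerate(self.sites, start=1):
            x, y, z = s.position
            lines.append(
                f"HETATM{i:5d}  O   HOH W{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{s.dg_wat:6.2f}"
                f"           O"
            )
        lines.append("END")
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        from dataclasses import asdict
        return {"n_waters": len(self.sites),
                "sites": [s.to_dict() for s in self.sites],
                "config": asdict(self.config)}


# ---------------------------------------------------------------------------
# ENTR field

def entr_field(oh2_energy: np.ndarray, grid: GridSpec,
               wp: WaterParams | None = None) -> np.ndarray:
    """Entropy-penalty field from the flatness of the OH2 enthalpy.

    For each grid point, 26 directions are walked out to ``walk_distance``;
    a direction is *free* if the interpolated OH2 enthalpy never rises
    above the start value by more than ``tolerance`` (a water there could
    drift that way).  Walks leaving the grid count as constrained.
    ENTR = k_S x (constrained directions / 26), so the field lies in
    [0, k_S] everywhere.
    """
    wp = wp or WaterParams()
    interp = RegularGridInterpolator(grid.axes(), oh2_energy,
                                     bounds_error=False, fill_value=np.nan)
    pts = grid.points()
    e0 = oh2_energy.ravel(order="C")
    constrained = np.zeros(pts.shape[0], dtype=int)
    steps = np.linspace(wp.walk_distance / wp.walk_steps, wp.walk_distance,
                        wp.walk_steps)
    for u in _DIRECTIONS:
        bad = np.zeros(pts.shape[0], dtype=bool)
        for t in steps:
            v = interp(pts + t * u)
            bad |= np.isnan(v) | (v > e0 + wp.tolerance)
        constrained += bad
    frac = constrained / len(_DIRECTIONS)
    return (wp.k_s * frac).reshape(grid.shape)


# ---------------------------------------------------------------------------
# Scoring / classification

def score_water(oh2s: float, oh2n: float, cry: float, entr: float,
                wp: WaterParams | None = None) -> float:
    """Relative free-energy score DG_WAT (kcal/mol).

    Positive values mark waters that would rather be displaced into
    solvent; negative values mark happier, more structural waters.
    """
    wp = wp or WaterParams()
    if wp.alpha + wp.beta == 0:
        raise ValueError("alpha + beta must be nonzero")
    return (wp.alpha * oh2n + wp.beta * oh2s + wp.gamma * cry
            - wp.e_bulk + entr)


def classify_water(dg_wat: float) -> str:
    """Four-class water label on half-open DG_WAT intervals.

    happy < -2.0 <= bulk-like < 1.5 <= unhappy < 3.0 <= very-unhappy.
    """
    if math.isnan(dg_wat):
        raise ValueError("dg_wat is NaN")
    if dg_wat < -2.0:
        return "happy"
    if dg_wat < 1.5:
        return "bulk-like"
    if dg_wat < 3.0:
        return "unhappy"
    return "very-unhappy"


# ---------------------------------------------------------------------------
# Placement

def _lex_argmin(values: np.ndarray) -> tuple[int, int, int]:
    """Index of the minimum, ties broken lexicographically by (z, y, x)."""
    t = values.transpose(2, 1, 0)  # (z, y, x)
    flat = int(np.argmin(t))
    z, y, x = np.unravel_index(flat, t.shape)
    return int(x), int(y), int(z)


def _refine(interp: RegularGridInterpolator, pos: np.ndarray,
            wp: WaterParams, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    """Short steepest-descent walk on the interpolated field."""
    pos = pos.astype(float).copy()
    h = wp.refine_step_size
    for _ in range(wp.refine_steps):
        grad = np.zeros(3)
        for d in range(3):
            dp = np.zeros(3)
            dp[d] = 0.5 * h
            a = np.clip(pos + dp, lo, hi)
            b = np.clip(pos - dp, lo, hi)
            grad[d] = (interp(a) - interp(b)).item()
        norm = np.linalg.norm(grad)
        if norm < 1e-9:
            break
        cand = np.clip(pos - h * grad / norm, lo, hi)
        if interp(cand).item() < interp(pos).item():
            pos = cand
        else:
            break
    return pos


def place_waters(structure: TypedStructure, pocket: PocketDefinition | None,
                 wp: WaterParams | None = None,
                 params: ModelParams | None = None,
                 grid: GridSpec | None = None,
                 spacing: float | None = None) -> WaterNetwork:
    """Greedy iterative water placement on the OH2 field.

    Fully deterministic: lattice argmin with lexicographic (z, y, x)
    tie-break, local trilinear-gradient refinement, fixed exclusion
    masking.  The input structure may already contain ligand atoms; they
    are simply part of the receptor the probe sees.
    """
    wp = wp or WaterParams()
    params = params or load_params()
    if len(structure) == 0:
        raise ValueError("empty structure")
    if grid is None:
        idx = (pocket.atom_indices(structure) if pocket is not None
               else np.arange(len(structure)))
        if idx.size == 0:
            return WaterNetwork(sites=[], config=wp,
                                grid=build_grid(structure.coords,
                                                spacing=spacing or params.spacing))
        grid = build_grid(structure.coords[idx],
                          spacing=spacing or params.spacing,
                          padding=params.padding)

    oh2 = params.probe("OH2")
    base = compute_mif(structure, pocket, oh2, grid, params=params,
                       clamp=False)
    e_s = base.energy                      # standalone field (receptor only)
    e_n = e_s.copy()                       # network field, grows with waters
    cry_field = compute_mif(structure, pocket, params.probe("CRY"), grid,
                            params=params).energy
    entr = entr_field(np.minimum(e_s, params.clamp), grid, wp)

    axes = grid.axes()
    lo = np.array([a[0] for a in axes])
    hi = np.array([a[-1] for a in axes])
    interp_s = RegularGridInterpolator(axes, e_s, bounds_error=False,
                                       fill_value=0.0)
    interp_cry = RegularGridInterpolator(axes, cry_field, bounds_error=False,
                                         fill_value=0.0)
    interp_entr = RegularGridInterpolator(axes, entr, bounds_error=False,
                                          fill_value=wp.k_s)

    allowed = base.pocket_mask.copy()
    pts = grid.points()
    origin = np.asarray(grid.origin)
    h = grid.spacing
    sites: list[WaterSite] = []
    water_lj = params.atom_lj("O")

    while len(sites) < wp.max_waters and np.any(allowed):
        masked = np.where(allowed, e_n, np.inf)
        ix, iy, iz = _lex_argmin(masked)
        if not np.isfinite(masked[ix, iy, iz]):
            break
        if e_s[ix, iy, iz] > wp.e_place:
            break
        interp_n = RegularGridInterpolator(axes, e_n, bounds_error=False,
                                           fill_value=0.0)
        pos = _refine(interp_n, grid.point((ix, iy, iz)), wp, lo, hi)
        site = WaterSite(
            position=tuple(float(v) for v in pos),
            oh2s=interp_s(pos).item(),
            oh2n=interp_n(pos).item(),
            cry=interp_cry(pos).item(),
            entr=interp_entr(pos).item(),
            order_placed=len(sites) + 1,
        )
        site.dg_wat = score_water(site.oh2s, site.oh2n, site.cry,
                                  site.entr, wp)
        site.label = classify_water(site.dg_wat)
        sites.append(site)

        # the new water becomes part of the receptor for later placements
        r = np.linalg.norm(pts - pos, axis=1)
        within = r <= params.cutoff
        rw = np.maximum(r, 0.05)
        dE = _pair_terms(oh2, "donor_acceptor", water_lj[0], water_lj[1],
                         0.0, rw, 1.0, params)
        dE = np.minimum(dE, params.clamp)
        dE[~within] = 0.0
        e_n += dE.reshape(grid.shape)

        # exclusion sphere
        excl = (r <= wp.exclusion_radius).reshape(grid.shape)
        allowed &= ~excl

    if not sites:
        log.info("no lattice point below the placement cutoff "
                 "(%.1f kcal/mol); empty network", wp.e_place)
    return WaterNetwork(sites=sites, grid=grid, config=wp)
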