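"""MIF-based pocket similarity: binarised fields, per-probe Tanimoto and
the Global-Sum combined score.

Two pockets, already superposed into one frame, are each characterised by
four probe fields (H shape, CRY lipophilic, N1 donor-probe, O
acceptor-probe).  Each field is contoured at its probe's standard level
(H +0.10, CRY -0.6, N1 -4.5, O -3.5 kcal/mol), restricted to the pocket
envelope, and the bit sets compared with the Tanimoto coefficient.  The
Global-Sum score is the weight-normalised mean of the per-probe values, so
it stays in [0, 1] for any nonnegative weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import ModelParams, RunConfig, SIMILARITY_PROBES, load_params
from .mif_engine import MIF, GridSpec, build_grid, compute_mif
from .structures import PocketDefinition, TypedStructure

log = logging.getLogger(__name__)

__all__ = ["BinaryField", "SimilarityResult", "binarize", "tanimoto",
           "global_score", "compare_pockets"]


@dataclass
class BinaryField:
    """A contoured MIF: bits set where energy <= threshold, inside the
    pocket envelope."""

    grid: GridSpec
    bits: np.ndarray
    probe_name: str
    threshold: float

    def __post_init__(self) -> None:
        if self.bits.shape != self.grid.shape:
            raise ValueError("bit field shape does not match grid")

    @property
    def count(self) -> int:
        return int(self.bits.sum())


@dataclass
class SimilarityResult:
    """Per-probe Tanimoto values plus the Global-Sum for one pocket pair."""

    per_probe: dict[str, float]
    global_sum: float
    weights: dict[str, float]
    grid: GridSpec
    thresholds: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_probe": dict(self.per_probe),
            "global_sum": self.global_sum,
            "weights": dict(self.weights),
            "thresholds": dict(self.thresholds),
            "grid": {"origin": list(self.grid.origin),
                     "spacing": self.grid.spacing,
                     "shape": list(self.grid.shape)},
        }


def binarize(mif: MIF, threshold: float | None = None) -> BinaryField:
    """Contour a MIF at a threshold (the probe default if omitted)."""
    thr = mif.probe.contour if threshold is None else float(threshold)
    if not np.isfinite(thr):
        raise ValueError("threshold must be finite")
    bits = (mif.energy <= thr) & mif.pocket_mask
    return BinaryField(grid=mif.grid, bits=bits,
                       probe_name=mif.probe.name, threshold=thr)


def tanimoto(a: BinaryField, b: BinaryField) -> float:
    """|a AND b| / |a OR b| on a common grid; 1.0 when both are empty.

    Two pockets lacking any hotspot in a channel are identical in that
    channel; the empty/empty convention is logged when it fires.
    """
    if a.grid != b.grid:
        raise ValueError("binary fields live on different grids")
    inter = int(np.count_nonzero(a.bits & b.bits))
    union = int(np.count_nonzero(a.bits | b.bits))
    if union == 0:
        log.info("tanimoto(%s): both fields empty at %.2f kcal/mol; "
                 "defined as 1.0", a.probe_name, a.threshold)
        return 1.0
    return inter / union


def global_score(per_probe: dict[str, float],
                 weights: dict[str, float] | None = None) -> float:
    """Weight-normalised mean of per-probe similarities (Global-Sum)."""
    if weights is None:
        weights = {name: 1.0 for name in per_probe}
    if any(w < 0 for w in weights.values()):
        raise ValueError("weights must be nonnegative")
    total = sum(weights.get(name, 0.0) for name in per_probe)
    if total <= 0:
        raise ValueError("at least one positive weight is required")
    return sum(weights.get(name, 0.0) * s for name, s in per_probe.items()) / total


def compare_pockets(struct_a: TypedStructure, pocket_a: PocketDefinition,
                    struct_b: TypedStructure, pocket_b: PocketDefinition,
                    config: RunConfig | None = None,
                    params: ModelParams | None = None,
                    probes: tuple[str, ...] = SIMILARITY_PROBES
                    ) -> SimilarityResult:
    """Full pocket-pair comparison in a common pre-aligned frame.

    Builds one union grid covering both pockets, computes each probe's MIF
    for each pocket, binarises at the configured contour levels and returns
    per-probe Tanimoto plus the Global-Sum.  Deterministic for fixed
    inputs and configuration.
    """
    params = params or load_params()
    config = config or RunConfig(spacing=params.spacing,
                                 padding=params.padding,
                                 cutoff=params.cutoff)
    ia = pocket_a.atom_indices(struct_a)
    ib = pocket_b.atom_indices(struct_b)
    union_coords = np.vstack([struct_a.coords[ia], struct_b.coords[ib]])
    grid = build_grid(union_coords, spacing=config.spacing,
                      padding=config.padding)
    per_probe: dict[str, float] = {}
    thresholds: dict[str, float] = {}
    for name in probes:
        probe = params.probe(name)
        thr = config.thresholds.get(name, probe.contour)
        thresholds[name] = thr
        mif_a = compute_mif(struct_a, pocket_a, probe, grid,
                            cutoff=config.cutoff, params=params)
        mif_b = compute_mif(struct_b, pocket_b, probe, grid,
                            cutoff=config.cutoff, params=params)
        per_probe[name] = tanimoto(binarize(mif_a, thr), binarize(mif_b, thr))
    weights = {name: config.weights.get(name, 1.0) for name in probes}
    return SimilarityResult(per_probe=per_probe,
                            global_sum=global_score(per_probe, weights),
                            weights=weights, grid=grid,
                            thresholds=thresholds)
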