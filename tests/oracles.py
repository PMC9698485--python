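"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written as plain scalar arithmetic and
O(points x atoms) loops, independent of the vectorised implementation it
checks.
"""

from __future__ import annotations

import math

import numpy as np

from pocketmif.atomtypes import (ACCEPTOR_CAPABLE, DONOR_CAPABLE,
                                 POLAR_CLASSES)

COULOMB = 332.0636
D0 = 2.9


def oracle_pair_energy(probe, atom_class: str, rmin_half: float, eps: float,
                       charge: float, r: float, geometry: float = 1.0,
                       cutoff: float = 8.0, clamp: float = 5.0) -> float:
    """Direct spreadsheet-style evaluation of the three declared terms."""
    eps_mix = math.sqrt(probe.eps * eps)
    if probe.polar_eps_scale != 1.0 and atom_class in POLAR_CLASSES:
        eps_mix *= probe.polar_eps_scale
    rmin_mix = probe.rmin_half + rmin_half
    e = eps_mix * ((rmin_mix / r) ** 12 - 2.0 * (rmin_mix / r) ** 6)
    if probe.charge != 0.0 and charge != 0.0 and r <= cutoff:
        e += (COULOMB * probe.charge * charge / 4.0) * (1.0 / r**2 - 1.0 / cutoff**2)
    complementary = (
        (probe.hbond_role == "donor" and atom_class in ACCEPTOR_CAPABLE)
        or (probe.hbond_role == "acceptor" and atom_class in DONOR_CAPABLE)
        or (probe.hbond_role == "both"
            and atom_class in (ACCEPTOR_CAPABLE | DONOR_CAPABLE)))
    if probe.hbond_emax != 0.0 and complementary:
        e += -probe.hbond_emax * (5.0 * (D0 / r) ** 12
                                  - 6.0 * (D0 / r) ** 10) * geometry
    return min(e, clamp)


def oracle_geometry(structure, i: int, point: np.ndarray) -> float:
    """Naive recomputation of the cos^2 H-bond angular factor for atom i."""
    coords = structure.coords
    elem = structure.atoms[i].element
    cutoff = 2.2 if elem == "S" else 1.9
    nbrs = [j for j in range(len(structure)) if j != i
            and np.linalg.norm(coords[j] - coords[i]) <= cutoff]
    if not nbrs:
        return 1.0
    ideal = coords[i] - np.mean([coords[j] for j in nbrs], axis=0)
    if np.linalg.norm(ideal) < 1e-6:
        return 1.0
    ideal = ideal / np.linalg.norm(ideal)
    v = point - coords[i]
    if np.linalg.norm(v) < 1e-9:
        return 0.0
    cos = float(ideal @ (v / np.linalg.norm(v)))
    return cos * cos if cos > 0 else 0.0


def oracle_field(structure, probe, grid, cutoff: float = 8.0,
                 clamp: float = 5.0):
    """Per-point (energy, best single term, best atom serial) by triple loop.

    Returns (energy, best, contributor) arrays matching compute_mif's
    conventions: per-pair clamp at +5, summed field clamped at +5,
    contributor -1 where no single term is favourable.
    """
    pts = grid.points()
    coords = structure.coords
    n = pts.shape[0]
    energy = np.zeros(n)
    best = np.full(n, np.inf)
    contributor = np.full(n, -1, dtype=int)
    use_geom = probe.hbond_role != "none"
    for k in range(n):
        p = pts[k]
        for i in range(len(structure)):
            r = float(np.linalg.norm(p - coords[i]))
            if r > cutoff:
                continue
            r = max(r, 0.05)
            geom = oracle_geometry(structure, i, p) if use_geom else 1.0
            e = oracle_pair_energy(
                probe, structure.atom_class[i],
                float(structure.rmin_half[i]), float(structure.eps[i]),
                float(structure.partial_charge[i]), r, geom,
                cutoff=cutoff, clamp=clamp)
            energy[k] += e
            if e < best[k]:
                best[k] = e
                contributor[k] = structure.atoms[i].serial
        if not best[k] < 0:
            contributor[k] = -1
    energy = np.minimum(energy, clamp)
    shape = grid.shape
    return (energy.reshape(shape), best.reshape(shape),
            contributor.reshape(shape))


def oracle_accumulate(structure, best: np.ndarray, contributor: np.ndarray,
                      min_energy: float = 0.0):
    """Brute-force per-residue accumulation from oracle_field output."""
    serial_to_res = {a.serial: (a.chain_id, a.residue_number,
                                a.insertion_code, a.residue_name)
                     for a in structure.atoms}
    sums: dict[tuple, float] = {}
    bests: dict[tuple, float] = {}
    for k in range(contributor.size):
        s = int(contributor.ravel(order="C")[k])
        e = float(best.ravel(order="C")[k])
        if s < 0 or not e < min_energy:
            continue
        key = serial_to_res[s]
        sums[key] = sums.get(key, 0.0) + e
        bests[key] = min(bests.get(key, 0.0), e)
    return sums, bests


def oracle_global_alignment(a: str, b: str, matrix, gap_open: float = 10.0,
                            gap_extend: float = 0.5):
    """Exhaustive enumeration of global alignments with affine gaps.

    Returns (best_score, identity_pct, similarity_pct) for the optimal
    alignment(s); feasible only for very short sequences.
    """
    best: dict[str, float] = {"score": -math.inf}

    def gap_cost(length: int) -> float:
        return gap_open + gap_extend * length if length else 0.0

    def recurse(i, j, cols, score, gap_a, gap_b):
        # gap_a/gap_b: length of the open terminal gap in each sequence
        if i == len(a) and j == len(b):
            if score > best["score"] + 1e-12:
                best.update(score=score, cols=list(cols))
            return
        if i < len(a) and j < len(b):
            recurse(i + 1, j + 1, cols + [(a[i], b[j])],
                    score + matrix[a[i], b[j]], 0, 0)
        if i < len(a):  # b gets a gap
            delta = gap_extend if gap_b else gap_open + gap_extend
            recurse(i + 1, j, cols + [(a[i], "-")], score - delta,
                    0, gap_b + 1)
        if j < len(b):  # a gets a gap
            delta = gap_extend if gap_a else gap_open + gap_extend
            recurse(i, j + 1, cols + [("-", b[j])], score - delta,
                    gap_a + 1, 0)

    recurse(0, 0, [], 0.0, 0, 0)
    cols = best["cols"]
    length = len(cols)
    ident = sum(1 for x, y in cols if x == y and x != "-")
    simil = sum(1 for x, y in cols
                if x != "-" and y != "-" and matrix[x, y] > 0)
    return best["score"], 100.0 * ident / length, 100.0 * simil / length
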