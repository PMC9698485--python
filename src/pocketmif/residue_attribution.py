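"""Per-residue energetic attribution of MIFs (heatmap table).

Each favourable grid point is attributed to exactly one protein atom — the
one whose single pair term with the probe is most favourable there; other
atoms' contributions at that point are ignored.  Attributed point energies
are accumulated per residue and probe, giving a residues x probes table of
how much each residue drives each interaction field.  Two statistics are
kept per cell: the accumulated sum over attributed points and the single
best (most negative) attributed point value.  Residues that never win a
grid point are flagged as non-contributing (rendered grey / emitted "NA").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import (ATTRIBUTION_PROBES, ATTRIBUTION_SIGNIFICANCE,
                     ModelParams, load_params)
from .mif_engine import MIF, GridSpec, build_grid, compute_mif
from .structures import PocketDefinition, TypedStructure

__all__ = ["ResidueContributionTable", "attribute_points",
           "accumulate_contributions", "compare_tables"]

ResidueKey = tuple[str, int, str, str]  # chain, number, insertion, name


def residue_label(key: ResidueKey) -> str:
    chain, num, icode, name = key
    return f"{chain}:{num}{icode}:{name}"


@dataclass
class ResidueContributionTable:
    """Residues x probes accumulated-energy matrix.

    ``df`` has one row per residue (ordered by chain/number/insertion) and
    columns ``{probe}_sum`` / ``{probe}_best`` in kcal/mol; NaN marks a
    non-contributing (grey) cell.
    """

    df: pd.DataFrame
    residues: list[ResidueKey]
    probes: tuple[str, ...]

    def to_csv(self) -> str:
        return self.df.to_csv(index_label="residue", na_rep="NA")

    def cell(self, key: ResidueKey, probe: str, stat: str = "sum") -> float:
        return float(self.df.loc[residue_label(key), f"{probe}_{stat}"])

    def no_contribution(self, key: ResidueKey, probe: str) -> bool:
        return bool(np.isnan(self.df.loc[residue_label(key), f"{probe}_sum"]))


def attribute_points(mif: MIF, structure: TypedStructure,
                     min_energy: float = 0.0) -> dict[int, ResidueKey]:
    """Map each favourably-contributed grid point to a residue.

    Keys are flat (C-order) grid indices; a point is mapped iff its most
    favourable single-atom term is below ``min_energy`` (0 = any
    favourable term; polar probes pass a deeper significance level so that
    dispersion-only attraction does not count as chemistry).  Raises if a
    recorded contributor serial is missing from the structure (corrupt
    pairing).
    """
    serial_to_res: dict[int, ResidueKey] = {}
    for a in structure.atoms:
        serial_to_res[a.serial] = (a.chain_id, a.residue_number,
                                   a.insertion_code, a.residue_name)
    flat = mif.max_contributor.ravel(order="C")
    significant = mif.best_energy.ravel(order="C") < min_energy
    out: dict[int, ResidueKey] = {}
    for idx in np.nonzero((flat >= 0) & significant)[0]:
        serial = int(flat[idx])
        try:
            out[int(idx)] = serial_to_res[serial]
        except KeyError:
            raise ValueError(
                f"max-contributor serial {serial} not present in the "
                "structure (corrupt field/structure pairing)") from None
    return out


def accumulate_contributions(structure: TypedStructure,
                             pocket: PocketDefinition,
                             probes: tuple[str, ...] = ATTRIBUTION_PROBES,
                             grid: GridSpec | None = None,
                             params: ModelParams | None = None,
                             cutoff: float | None = None,
                             spacing: float | None = None,
                             padding: float | None = None
                             ) -> ResidueContributionTable:
    """Build the per-residue contribution table for a pocket.

    For each probe the MIF is computed, every favourable point attributed
    to its max-contributor residue, and per residue both the accumulated
    sum of attributed single-atom energies and the best single point value
    are recorded.  Rows cover all pocket residues (grey where they never
    contribute) plus any non-pocket residue that wins at least one point.
    """
    params = params or load_params()
    idx = pocket.atom_indices(structure)
    if idx.size == 0:
        raise ValueError("pocket selects no atoms")
    if grid is None:
        grid = build_grid(structure.coords[idx],
                          spacing=spacing or params.spacing,
                          padding=padding or params.padding)

    pocket_res: list[ResidueKey] = []
    seen = set()
    for i in idx:
        a = structure.atoms[i]
        key = (a.chain_id, a.residue_number, a.insertion_code, a.residue_name)
        if key not in seen:
            seen.add(key)
            pocket_res.append(key)

    sums: dict[str, dict[ResidueKey, float]] = {}
    bests: dict[str, dict[ResidueKey, float]] = {}
    extra: list[ResidueKey] = []
    for name in probes:
        probe = params.probe(name)
        mif = compute_mif(structure, pocket, probe, grid,
                          cutoff=cutoff, params=params)
        mapping = attribute_points(
            mif, structure, ATTRIBUTION_SIGNIFICANCE.get(name, 0.0))
        best_flat = mif.best_energy.ravel(order="C")
        s: dict[ResidueKey, float] = {}
        b: dict[ResidueKey, float] = {}
        for point, key in mapping.items():
            e = float(best_flat[point])
            s[key] = s.get(key, 0.0) + e
            if e < b.get(key, 0.0):
                b[key] = e
            if key not in seen:
                seen.add(key)
                extra.append(key)
        sums[name] = s
        bests[name] = b

    rows = sorted(pocket_res + extra, key=lambda k: (k[0], k[1], k[2]))
    data = {}
    for name in probes:
        data[f"{name}_sum"] = [sums[name].get(k, np.nan) for k in rows]
        data[f"{name}_best"] = [bests[name].get(k, np.nan) for k in rows]
    df = pd.DataFrame(data, index=[residue_label(k) for k in rows])
    return ResidueContributionTable(df=df, residues=rows,
                                    probes=tuple(probes))


def compare_tables(table_a: ResidueContributionTable,
                   table_b: ResidueContributionTable,
                   residue_pairing: list[tuple[ResidueKey | None,
                                               ResidueKey | None]]
                   ) -> pd.DataFrame:
    """Align two contribution tables over a residue pairing.

    Each pairing entry maps a row of A to a row of B; ``None`` on either
    side marks an insertion/deletion (flagged, excluded from deltas).
    Deltas are ``cell_B - cell_A`` per probe and statistic, with
    non-contributing cells treated as zero accumulation.
    """
    rows = []
    cols = [f"{p}_{s}" for p in table_a.probes for s in ("sum", "best")]
    for key_a, key_b in residue_pairing:
        rec: dict[str, object] = {
            "residue_a": residue_label(key_a) if key_a else None,
            "residue_b": residue_label(key_b) if key_b else None,
        }
        if key_a is None and key_b is None:
            raise ValueError("pairing entry with both sides missing")
        if key_a is not None and residue_label(key_a) not in table_a.df.index:
            raise ValueError(f"{residue_label(key_a)} not in table A")
        if key_b is not None and residue_label(key_b) not in table_b.df.index:
            raise ValueError(f"{residue_label(key_b)} not in table B")
        if key_a is None or key_b is None:
            rec["status"] = "insertion" if key_a is None else "deletion"
            for c in cols:
                rec[f"delta_{c}"] = np.nan
        else:
            rec["status"] = "paired"
            for c in cols:
                va = table_a.df.loc[residue_label(key_a), c]
                vb = table_b.df.loc[residue_label(key_b), c]
                va = 0.0 if np.isnan(va) else float(va)
                vb = 0.0 if np.isnan(vb) else float(vb)
                rec[f"delta_{c}"] = vb - va
        rows.append(rec)
    return pd.DataFrame(rows)


def heatmap_matrix(table: ResidueContributionTable, stat: str = "sum"
                   ) -> pd.DataFrame:
    """Rendering-ready matrix: rows residues, columns probes, NaN = grey.

    Values are kcal/mol (more negative = stronger contribution); a
    monotone colour map on the negated values gives the darker-is-stronger
    convention.
    """
    cols = {p: table.df[f"{p}_{stat}"] for p in table.probes}
    return pd.DataFrame(cols, index=table.df.index)
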