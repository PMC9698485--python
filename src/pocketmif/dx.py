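"""Minimal OpenDX regular-grid scalar file I/O.

Writes/reads the subset of OpenDX used for volumetric molecular data
(``gridpositions`` counts + origin + three axis-aligned deltas + a
``data follows`` array, z varying fastest), which is what visualisers such
as PyMOL and VMD consume.
"""

from __future__ import annotations

import numpy as np

__all__ = ["write_dx", "read_dx"]


def write_dx(origin: np.ndarray, spacing: float, values: np.ndarray,
             comment: str = "pocketmif field") -> str:
    """Serialise a 3D scalar array to OpenDX text (kcal/mol)."""
    values = np.asarray(values, dtype=float)
    if values.ndim != 3:
        raise ValueError("values must be a 3D array")
    nx, ny, nz = values.shape
    n = values.size
    lines = [f"# {comment}",
             f"object 1 class gridpositions counts {nx} {ny} {nz}",
             "origin {:.6f} {:.6f} {:.6f}".format(*np.asarray(origin, dtype=float)),
             f"delta {spacing:.6f} 0.000000 0.000000",
             f"delta 0.000000 {spacing:.6f} 0.000000",
             f"delta 0.000000 0.000000 {spacing:.6f}",
             f"object 2 class gridconnections counts {nx} {ny} {nz}",
             f"object 3 class array type double rank 0 items {n} data follows"]
    flat = values.ravel(order="C")  # z fastest, per DX convention
    for i in range(0, n, 3):
        lines.append(" ".join(f"{v:.6e}" for v in flat[i:i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "density" class field')
    return "\n".join(lines) + "\n"


def read_dx(text: str) -> tuple[np.ndarray, float, np.ndarray]:
    """Parse OpenDX text back into (origin, spacing, values)."""
    shape = None
    origin = None
    deltas = []
    data: list[float] = []
    n_items = None
    in_data = False
    for line in text.splitlines():
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        if in_data:
            if s.startswith(("attribute", "object", "component")):
                in_data = False
                continue
            data.extend(float(tok) for tok in s.split())
            continue
        if s.startswith("object") and "gridpositions" in s:
            shape = tuple(int(t) for t in s.split()[-3:])
        elif s.startswith("origin"):
            origin = np.array([float(t) for t in s.split()[1:4]])
        elif s.startswith("delta"):
            deltas.append([float(t) for t in s.split()[1:4]])
        elif "data follows" in s:
            n_items = int(s.split("items")[1].split()[0])
            in_data = True
    if shape is None or origin is None or len(deltas) != 3:
        raise ValueError("not a regular-grid OpenDX scalar file")
    d = np.asarray(deltas)
    spacing = float(d[0, 0])
    if not (np.allclose(np.diag(d), spacing) and
            np.allclose(d - np.diag(np.diag(d)), 0.0)):
        raise ValueError("only axis-aligned cubic grids are supported")
    values = np.asarray(data, dtype=float)
    if n_items is not None and values.size != n_items:
        raise ValueError(f"expected {n_items} values, found {values.size}")
    return origin, spacing, values.reshape(shape, order="C")
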