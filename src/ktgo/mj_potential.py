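"""Miyazawa-Jernigan statistical contact potential.

Ships the 1996 residue-residue contact energies e_ij (RT units; Miyazawa &
Jernigan, J. Mol. Biol. 256:623-644, 1996) as packaged data, behind a small
pluggable-table interface: any symmetric 20x20 table with negative
(attractive) entries can stand in for it.  More negative published values
mean stronger contacts, hence deeper native wells.
"""

from __future__ import annotations

import numpy as np

from .constants import ONE_TO_THREE, THREE_TO_ONE

# Row/column order of the embedded upper-triangle table.
_MJ_ORDER = "CMFILVWYAGTSNQDEHRKP"

# e_ij contact energies, upper triangle, RT units.
_MJ_1996_UPPER = """
-5.44 -4.99 -5.80 -5.50 -5.83 -4.96 -4.95 -4.16 -3.57 -3.16 -3.11 -2.86 -2.59 -2.85 -2.41 -2.27 -3.60 -2.57 -1.95 -3.07
      -5.46 -6.56 -6.02 -6.41 -5.32 -5.55 -4.91 -3.94 -3.39 -3.51 -3.03 -2.95 -3.30 -2.57 -2.89 -3.98 -3.12 -2.48 -3.45
            -7.26 -6.84 -7.28 -6.29 -6.16 -5.66 -4.81 -4.13 -4.28 -4.02 -3.75 -4.10 -3.48 -3.56 -4.77 -3.98 -3.36 -4.25
                  -6.54 -7.04 -6.05 -5.78 -5.25 -4.58 -3.78 -4.03 -3.52 -3.24 -3.67 -3.17 -3.27 -4.14 -3.63 -3.01 -3.76
                        -7.37 -6.48 -6.14 -5.67 -4.91 -4.16 -4.34 -3.92 -3.74 -4.04 -3.40 -3.59 -4.54 -4.03 -3.37 -4.20
                              -5.52 -5.18 -4.62 -4.04 -3.38 -3.46 -3.05 -2.83 -3.07 -2.48 -2.67 -3.58 -3.07 -2.49 -3.32
                                    -5.06 -4.66 -3.82 -3.42 -3.22 -2.99 -3.07 -3.11 -2.84 -2.99 -3.98 -3.41 -2.69 -3.73
                                          -4.17 -3.36 -3.01 -3.01 -2.78 -2.76 -2.97 -2.76 -2.79 -3.52 -3.16 -2.60 -3.19
                                                -2.72 -2.31 -2.32 -2.01 -1.84 -1.89 -1.70 -1.51 -2.41 -1.83 -1.31 -2.03
                                                      -2.24 -2.08 -1.82 -1.74 -1.66 -1.59 -1.22 -2.15 -1.72 -1.15 -1.87
                                                            -2.12 -1.96 -1.88 -1.90 -1.80 -1.74 -2.42 -1.90 -1.31 -1.90
                                                                  -1.67 -1.58 -1.49 -1.63 -1.48 -2.11 -1.62 -1.05 -1.57
                                                                        -1.68 -1.71 -1.68 -1.51 -2.08 -1.64 -1.21 -1.53
                                                                              -1.54 -1.46 -1.42 -1.98 -1.80 -1.29 -1.73
                                                                                    -1.21 -1.02 -2.32 -2.29 -1.68 -1.33
                                                                                          -0.91 -2.15 -2.27 -1.80 -1.26
                                                                                                -3.05 -2.16 -1.35 -2.25
                                                                                                      -1.55 -0.59 -1.70
                                                                                                            -0.12 -0.97
                                                                                                                  -1.75
"""


class MJTable:
    """Symmetric 20x20 residue-pair contact-energy table.

    Entries are indexed by one- or three-letter residue codes; the table must
    be symmetric and cover all 210 unique pairs.
    """

    def __init__(self, matrix: np.ndarray, order: str = _MJ_ORDER,
                 name: str = "MJ1996"):
        matrix = np.asarray(matrix, dtype=float)
        if matrix.shape != (20, 20):
            raise ValueError("contact table must be 20x20")
        if not np.allclose(matrix, matrix.T, atol=1e-12):
            raise ValueError("contact table must be symmetric")
        if len(order) != 20 or len(set(order)) != 20:
            raise ValueError("order must list each of the 20 residues once")
        self.matrix = matrix
        self.order = order
        self.name = name
        self._idx = {aa: i for i, aa in enumerate(order)}

    @classmethod
    def from_upper_triangle(cls, text: str, order: str = _MJ_ORDER,
                            name: str = "custom") -> "MJTable":
        rows = [[float(x) for x in line.split()] for line in text.strip().splitlines()]
        mat = np.zeros((20, 20))
        for i, row in enumerate(rows):
            if len(row) != 20 - i:
                raise ValueError(f"row {i} has {len(row)} entries, expected {20 - i}")
            for k, val in enumerate(row):
                j = i + k
                mat[i, j] = mat[j, i] = val
        return cls(mat, order, name)

    def _index(self, residue: str) -> int:
        code = residue.strip().upper()
        if len(code) == 3:
            code = THREE_TO_ONE.get(code, "")
        if code not in self._idx:
            raise KeyError(f"unknown residue type {residue!r}")
        return self._idx[code]

    def energy(self, res_i: str, res_j: str) -> float:
        """Contact energy e(i, j); symmetric in its arguments."""
        return float(self.matrix[self._index(res_i), self._index(res_j)])

    def residues(self) -> list[str]:
        return [ONE_TO_THREE[c] for c in self.order]


_default: MJTable | None = None


def default_mj_table() -> MJTable:
    """The packaged Miyazawa-Jernigan 1996 e_ij table."""
    global _default
    if _default is None:
        _default = MJTable.from_upper_triangle(_MJ_1996_UPPER, name="MJ1996")
    return _default
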