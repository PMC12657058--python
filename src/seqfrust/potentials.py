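"""Amino-acid alphabet and knowledge-based contact potentials.

The pairwise interaction energy ``U`` used by the frustration model is a
symmetric 20x20 table of contact energies between the canonical amino
acids.  The default table embedded here is the Miyazawa-Jernigan 1996
contact energies ``e_ij`` (RT-scale, dimensionless as published); an
alternative 20x20 table can be loaded from a whitespace-delimited text
file so the variant is swappable.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: Canonical one-letter amino-acid alphabet, alphabetical order.
AA_ALPHABET: str = "ACDEFGHIKLMNPQRSTVWY"

_AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AA_ALPHABET)}

# Miyazawa & Jernigan (1996) contact energies e_ij, upper triangle, in the
# publication's residue order.  Row k lists e(order[k], order[j]) for j >= k.
_MJ96_ORDER = "CMFILVWYAGTSNQDEHRKP"
_MJ96_UPPER = """
C -5.44 -4.99 -5.80 -5.50 -5.83 -4.96 -4.95 -4.16 -3.57 -3.16 -3.11 -2.86 -2.59 -2.85 -2.41 -2.27 -3.60 -2.57 -1.95 -3.07
M -5.46 -6.56 -6.02 -6.41 -5.32 -5.55 -4.91 -3.94 -3.39 -3.51 -3.03 -2.95 -3.30 -2.57 -2.89 -3.98 -3.12 -2.48 -3.45
F -7.26 -6.84 -7.28 -6.29 -6.16 -5.66 -4.81 -4.13 -4.28 -4.02 -3.75 -4.10 -3.48 -3.56 -4.77 -3.98 -3.36 -4.25
I -6.54 -7.04 -6.05 -5.78 -5.25 -4.58 -3.78 -4.03 -3.52 -3.24 -3.67 -3.17 -3.27 -4.14 -3.63 -3.01 -3.76
L -7.37 -6.48 -6.14 -5.67 -4.91 -4.16 -4.34 -3.92 -3.74 -4.04 -3.40 -3.59 -4.54 -4.03 -3.37 -4.20
V -5.52 -5.18 -4.62 -4.04 -3.38 -3.46 -3.05 -2.83 -3.07 -2.48 -2.67 -3.58 -3.07 -2.49 -3.32
W -5.06 -4.66 -3.82 -3.42 -3.22 -2.99 -3.07 -3.11 -2.84 -2.99 -3.98 -3.41 -2.69 -3.73
Y -4.17 -3.36 -3.01 -3.01 -2.78 -2.76 -2.97 -2.76 -2.79 -3.52 -3.16 -2.60 -3.19
A -2.72 -2.31 -2.32 -2.01 -1.84 -1.89 -1.70 -1.51 -2.41 -1.83 -1.31 -2.03
G -2.24 -2.08 -1.82 -1.74 -1.66 -1.59 -1.22 -2.15 -1.72 -1.15 -1.87
T -2.12 -1.96 -1.88 -1.90 -1.80 -1.74 -2.42 -1.90 -1.31 -1.90
S -1.67 -1.58 -1.49 -1.63 -1.48 -2.11 -1.62 -1.05 -1.57
N -1.68 -1.71 -1.68 -1.51 -2.08 -1.64 -1.21 -1.53
Q -1.54 -1.46 -1.42 -1.98 -1.80 -1.29 -1.73
D -1.21 -1.02 -2.32 -2.29 -1.68 -1.33
E -0.91 -2.15 -2.27 -1.80 -1.26
H -3.05 -2.16 -1.35 -2.25
R -1.55 -0.59 -1.70
K -0.12 -0.97
P -1.75
"""


def validate_residue(code: str) -> str:
    """Normalize a one-letter residue code to uppercase, rejecting non-canonical symbols.

    Raises :class:`ValidationError` naming the offending symbol for anything
    outside the 20 canonical amino acids (B, J, O, U, X, Z, gaps, ...).
    """
    if not isinstance(code, str) or len(code) != 1:
        raise ValidationError(f"residue code must be a single character, got {code!r}")
    up = code.upper()
    if up not in _AA_INDEX:
        raise ValidationError(f"invalid residue code {code!r}: not one of the 20 canonical amino acids")
    return up


def seq_to_indices(seq: str, strict: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Map a one-letter sequence to alphabet indices.

    Returns ``(indices, valid)`` where ``indices`` is int64 with -1 at
    non-canonical positions and ``valid`` is the matching boolean mask.
    In strict mode (default) a non-canonical symbol raises
    :class:`ValidationError` with its 1-based position; in lenient mode it
    is masked, and the mask propagates downstream as undefined positions.
    """
    idx = np.empty(len(seq), dtype=np.int64)
    valid = np.ones(len(seq), dtype=bool)
    for pos, ch in enumerate(seq):
        i = _AA_INDEX.get(ch.upper(), -1)
        if i < 0:
            if strict:
                raise ValidationError(
                    f"invalid residue code {ch!r} at position {pos + 1}"
                )
            valid[pos] = False
        idx[pos] = i
    return idx, valid


@dataclass(frozen=True)
class PotentialTable:
    """Symmetric 20x20 contact-energy lookup over the canonical amino acids.

    ``matrix`` is ordered by :data:`AA_ALPHABET` on both axes.  Energies are
    dimensionless (RT scale as published).
    """

    matrix: np.ndarray
    provenance_label: str = field(default="unspecified")

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=np.float64)
        if m.shape != (20, 20):
            raise ValidationError(f"potential table must be 20x20, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValidationError("potential table contains non-finite entries")
        if not np.allclose(m, m.T, rtol=0.0, atol=1e-9):
            raise ValidationError("potential table is not symmetric (tolerance 1e-9)")
        object.__setattr__(self, "matrix", (m + m.T) / 2.0)

    def energy(self, a: str, b: str) -> float:
        """Contact energy for the unordered residue pair (a, b)."""
        ia = _AA_INDEX[validate_residue(a)]
        ib = _AA_INDEX[validate_residue(b)]
        return float(self.matrix[ia, ib])

    @classmethod
    def from_file(cls, path, provenance_label: str | None = None) -> "PotentialTable":
        """Load a table from a whitespace-delimited file.

        First row and first column carry the 20 one-letter codes; the body
        is the symmetric matrix.  Symmetry is validated to within 1e-9.
        """
        with open(path) as fh:
            text = fh.read()
        return cls._parse(text, provenance_label or str(path))

    @classmethod
    def _parse(cls, text: str, provenance_label: str) -> "PotentialTable":
        lines = [ln.split() for ln in text.splitlines() if ln.strip()]
        if not lines:
            raise ValidationError("empty potential-table file")
        header = [validate_residue(c) for c in lines[0]]
        if sorted(header) != sorted(AA_ALPHABET):
            raise ValidationError("potential-table header must list all 20 canonical codes exactly once")
        if len(lines) != 21:
            raise ValidationError(f"expected 20 data rows, got {len(lines) - 1}")
        m = np.full((20, 20), np.nan)
        for row in lines[1:]:
            r = _AA_INDEX[validate_residue(row[0])]
            vals = [float(v) for v in row[1:]]
            if len(vals) != 20:
                raise ValidationError(f"row {row[0]} has {len(vals)} values, expected 20")
            for col_code, v in zip(header, vals):
                m[r, _AA_INDEX[col_code]] = v
        return cls(matrix=m, provenance_label=provenance_label)

    def to_file(self, path) -> None:
        """Write the table in the same headered whitespace format read by from_file."""
        buf = io.StringIO()
        buf.write(" ".join(AA_ALPHABET) + "\n")
        for i, code in enumerate(AA_ALPHABET):
            row = " ".join(f"{self.matrix[i, j]:.6f}" for j in range(20))
            buf.write(f"{code} {row}\n")
        with open(path, "w") as fh:
            fh.write(buf.getvalue())


def _build_mj96() -> np.ndarray:
    m = np.full((20, 20), np.nan)
    rows = [ln.split() for ln in _MJ96_UPPER.strip().splitlines()]
    for k, row in enumerate(rows):
        i = _AA_INDEX[row[0]]
        for off, val in enumerate(row[1:]):
            j = _AA_INDEX[_MJ96_ORDER[k + off]]
            m[i, j] = m[j, i] = float(val)
    assert np.all(np.isfinite(m))
    return m


_MJ96_MATRIX = _build_mj96()


def miyazawa_jernigan_1996() -> PotentialTable:
    """The default contact-potential table: Miyazawa-Jernigan 1996 e_ij energies."""
    return PotentialTable(matrix=_MJ96_MATRIX.copy(), provenance_label="MJ1996-eij")


def contact_energy(table: PotentialTable, a: str, b: str) -> float:
    """Contact energy for the unordered pair (a, b); pure lookup."""
    return table.energy(a, b)


def sequence_potential_matrix(table: PotentialTable, seq: str) -> np.ndarray:
    """The n x n matrix U with U[i, j] = e(sigma_i, sigma_j).

    Symmetric by construction; the diagonal holds e(sigma_i, sigma_i) but
    downstream sums only consume i < j.  Sequences shorter than 2 residues
    are rejected.
    """
    if len(seq) < 2:
        raise ValidationError(f"sequence must have length >= 2, got {len(seq)}")
    idx, _ = seq_to_indices(seq, strict=True)
    return self_energy_matrix(table, idx)


def self_energy_matrix(table: PotentialTable, idx: np.ndarray) -> np.ndarray:
    """U for an index-encoded sequence; entries touching index -1 are zero."""
    safe = np.where(idx >= 0, idx, 0)
    u = table.matrix[np.ix_(safe, safe)]
    invalid = idx < 0
    if invalid.any():
        u[invalid, :] = 0.0
        u[:, invalid] = 0.0
    return u
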