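"""Sequence-based local energetic frustration.

The energy model weights each pair contact potential by its evolutionary
coupling score: F = C (Hadamard) U, with total energy
gamma(sigma) = sum_{i<j} F[i, j].  For a point mutation m at position k,
Delta-gamma_m = gamma(wt) - gamma(mut) measures how much the mutation
lowers the predicted folded-state energy; averaging over the 19
non-wild-type substitutions gives the per-residue frustration scalar
Gamma_k.  Positive Gamma means mutations lower the energy on average:
the native residue is energetically frustrated.

Only row k of F changes under a mutation at k, so Delta-gamma is computed
incrementally as sum_{j != k} C[k, j] * (e(wt_k, s_j) - e(m, s_j)); the
full profile is a single 20 x n matrix product, O(20 n^2).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field

import numpy as np

from .couplings import CouplingMatrix
from .errors import ValidationError
from .potentials import AA_ALPHABET, PotentialTable, seq_to_indices, self_energy_matrix, validate_residue

ORIENTATION_NOTE = "higher = more frustrated"


@dataclass
class FrustrationProfile:
    """Per-residue frustration Gamma with an undefined-position mask.

    ``per_residue[k]`` is NaN exactly where ``defined_mask[k]`` is False:
    positions with no coupling coverage, or invalid residues in lenient
    mode.  Masked positions are undefined, not zero — zero would read as
    "perfectly neutral" and corrupt rank correlations downstream.
    """

    gamma_native: float
    per_residue: np.ndarray
    defined_mask: np.ndarray
    orientation_note: str = field(default=ORIENTATION_NOTE)

    def __post_init__(self) -> None:
        v = np.asarray(self.per_residue, dtype=np.float64)
        m = np.asarray(self.defined_mask, dtype=bool)
        if v.shape != m.shape:
            raise ValidationError("per_residue and defined_mask lengths differ")
        if not np.all(np.isfinite(v[m])):
            raise ValidationError("Gamma must be finite wherever defined")
        self.per_residue, self.defined_mask = v, m

    @property
    def n(self) -> int:
        return self.per_residue.shape[0]


def _check_lengths(C: CouplingMatrix, seq: str) -> None:
    if len(seq) != C.n:
        raise ValidationError(
            f"sequence length {len(seq)} does not match coupling matrix size {C.n}"
        )


def pairwise_energy(C: CouplingMatrix, seq: str, table: PotentialTable, strict: bool = True) -> np.ndarray:
    """The weighted-energy matrix F = C (Hadamard) U; symmetric."""
    _check_lengths(C, seq)
    idx, _ = seq_to_indices(seq, strict=strict)
    return C.scores * self_energy_matrix(table, idx)


def total_energy(C: CouplingMatrix, seq: str, table: PotentialTable, strict: bool = True) -> float:
    """gamma(sigma): strictly upper-triangular sum of F (diagonal excluded)."""
    f = pairwise_energy(C, seq, table, strict=strict)
    return float(np.triu(f, k=1).sum())


def mutation_delta(
    C: CouplingMatrix,
    seq: str,
    table: PotentialTable,
    k: int,
    mutant: str,
    strict: bool = True,
) -> float:
    """Delta-gamma = gamma(wt) - gamma(mutant at 1-based position k).

    Positive values mean the mutant lowers the total energy, i.e. the
    native position is energetically frustrated.  Computed incrementally
    from row k only; C's zero diagonal removes the j == k term.
    """
    _check_lengths(C, seq)
    if not (1 <= k <= C.n):
        raise ValidationError(f"position k={k} outside [1, {C.n}]")
    mut = validate_residue(mutant)
    idx, _ = seq_to_indices(seq, strict=strict)
    wt = idx[k - 1]
    if wt < 0:
        raise ValidationError(f"wild-type residue at position {k} is not canonical")
    row = C.scores[k - 1]
    e_tab = table.matrix
    safe = np.where(idx >= 0, idx, 0)
    e_wt = e_tab[wt, safe]
    e_mut = e_tab[AA_ALPHABET.index(mut), safe]
    contrib = np.where(idx >= 0, e_wt - e_mut, 0.0)
    return float(np.dot(row, contrib))


def frustration_profile(
    C: CouplingMatrix,
    seq: str,
    table: PotentialTable,
    strict: bool = True,
) -> FrustrationProfile:
    """Gamma_k for every position: mean Delta-gamma over the 19 substitutions.

    Positions without coupling coverage (e.g. alignment columns dropped
    upstream by gap filtering) are masked as undefined.  In lenient mode,
    non-canonical residues are masked too and their incident couplings
    contribute nothing.
    """
    _check_lengths(C, seq)
    n = C.n
    idx, valid = seq_to_indices(seq, strict=strict)
    safe = np.where(idx >= 0, idx, 0)

    # E20[a, j] = e(a, sigma_j); zero columns for invalid residues.
    E20 = table.matrix[:, safe].copy()
    E20[:, ~valid] = 0.0
    # V[a, k] = sum_j C[k, j] * e(a, sigma_j)
    V = E20 @ C.scores

    mask = C.covered & valid
    gamma = np.full(n, np.nan)
    pos = np.where(mask)[0]
    if pos.size:
        wt = safe[pos]
        v_wt = V[wt, pos]
        # Gamma_k = v_wt - mean over 19 mutants of v_m = (20 v_wt - colsum) / 19
        gamma[pos] = (20.0 * v_wt - V[:, pos].sum(axis=0)) / 19.0

    g_native = float(np.triu(C.scores * self_energy_matrix(table, idx), k=1).sum())
    return FrustrationProfile(gamma_native=g_native, per_residue=gamma, defined_mask=mask)


def write_profile_csv(path, values: np.ndarray, seq: str | None = None) -> None:
    """Write a per-residue profile as CSV: position, residue, gamma, covered.

    ``gamma`` is empty where the value is NaN (masked).  Accepts either a
    FrustrationProfile-style vector or any NaN-masked per-residue vector.
    """
    v = np.asarray(values, dtype=np.float64)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["position", "residue", "gamma", "covered"])
        for k in range(v.shape[0]):
            res = seq[k] if seq else "-"
            if math.isnan(v[k]):
                w.writerow([k + 1, res, "", "false"])
            else:
                w.writerow([k + 1, res, f"{v[k]:.17g}", "true"])


def read_profile_csv(path) -> tuple[np.ndarray, str]:
    """Read a profile CSV back into (NaN-masked vector, residue string)."""
    values: list[float] = []
    residues: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"position", "residue", "gamma", "covered"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValidationError(f"{path}: profile CSV must have columns {sorted(required)}")
        for row in reader:
            residues.append(row["residue"])
            values.append(float(row["gamma"]) if row["gamma"] != "" else math.nan)
    return np.asarray(values), "".join(residues)
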