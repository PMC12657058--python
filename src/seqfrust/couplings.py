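"""Evolutionary coupling-score I/O and the CouplingMatrix container.

Coupling scores quantify inferred coevolution strength between sequence
positions (direct coupling analysis).  They are consumed here, never
computed: two on-disk dialects are supported, the plmc flat text format
(headerless whitespace rows ``i a_i j a_j extra score``) and the
EVcouplings CSV format (headered, with raw ``fn`` and APC-corrected
``cn`` score columns).  All indices are 1-based query-sequence positions
in upper-triangle canonical form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FileFormatError, ValidationError

logger = logging.getLogger(__name__)

DIALECTS = ("plmc-flat", "evcouplings-csv")


@dataclass
class CouplingMatrix:
    """n x n symmetric coupling-score matrix with zero diagonal.

    ``covered[k]`` is True when 1-based position k+1 appears in at least
    one scored pair.  When not supplied it is derived from nonzero rows.
    """

    scores: np.ndarray
    covered: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=np.float64)
        if s.ndim != 2 or s.shape[0] != s.shape[1]:
            raise ValidationError(f"coupling matrix must be square, got shape {s.shape}")
        if not np.all(np.isfinite(s)):
            raise ValidationError("coupling matrix contains non-finite entries")
        if not np.allclose(s, s.T, rtol=0.0, atol=1e-12):
            raise ValidationError("coupling matrix is not symmetric")
        if np.any(np.diagonal(s) != 0.0):
            raise ValidationError("coupling matrix diagonal must be exactly zero")
        self.scores = s
        if self.covered is None:
            self.covered = np.any(s != 0.0, axis=1)
        else:
            cov = np.asarray(self.covered, dtype=bool)
            if cov.shape != (s.shape[0],):
                raise ValidationError("covered mask length must equal matrix size")
            self.covered = cov

    @property
    def n(self) -> int:
        return self.scores.shape[0]


def coverage_mask(matrix: CouplingMatrix) -> np.ndarray:
    """Per-position boolean vector: True where the position has coupling coverage."""
    return matrix.covered.copy()


def _sniff_dialect(path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                first = line
                break
        else:
            raise FileFormatError(f"{path}: empty couplings file (tried dialects: {', '.join(DIALECTS)})")
    if "," in first:
        return "evcouplings-csv"
    tokens = first.split()
    try:
        int(tokens[0])
        return "plmc-flat"
    except (ValueError, IndexError):
        raise FileFormatError(
            f"{path}: could not identify couplings dialect (tried: {', '.join(DIALECTS)})"
        )


def _records_plmc(path) -> list[tuple[int, int, float, int]]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            tok = line.split()
            if len(tok) < 6:
                raise FileFormatError(
                    f"{path}:{lineno}: plmc-flat rows need 6 fields (i a_i j a_j extra score), got {len(tok)}"
                )
            try:
                records.append((int(tok[0]), int(tok[2]), float(tok[5]), lineno))
            except ValueError as exc:
                raise FileFormatError(f"{path}:{lineno}: {exc}") from exc
    return records


def _records_evcouplings(path, score_column: str) -> list[tuple[int, int, float, int]]:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FileFormatError(f"{path}: not parseable as EVcouplings CSV: {exc}") from exc
    cols = {c.lower(): c for c in df.columns}
    if "i" not in cols or "j" not in cols:
        raise FileFormatError(f"{path}: EVcouplings CSV must have columns 'i' and 'j'")
    wanted = ("cn", "score", "fn") if score_column == "apc" else ("fn", "score", "cn")
    for name in wanted:
        if name in cols:
            if name != wanted[0]:
                logger.warning("score column %r absent, falling back to %r", wanted[0], name)
            score_col = cols[name]
            break
    else:
        raise FileFormatError(f"{path}: no score column among {wanted}")
    out = []
    for row_pos, (i, j, s) in enumerate(zip(df[cols["i"]], df[cols["j"]], df[score_col])):
        out.append((int(i), int(j), float(s), row_pos + 2))  # +2: header + 1-based
    return out


def read_couplings(
    path,
    n: int,
    dialect: str = "auto",
    score_column: str = "apc",
) -> CouplingMatrix:
    """Parse a coupling-score file into a CouplingMatrix of size ``n``.

    Parameters
    ----------
    path : file path
    n : query-sequence length; every record must satisfy 1 <= i < j <= n.
    dialect : "plmc-flat", "evcouplings-csv", or "auto" (sniff by header).
    score_column : "apc" (APC-corrected, the EVcouplings ranking default) or
        "raw".  The plmc flat format carries a single score column which is
        used regardless.

    Duplicate pairs, indices outside [1, n] and i == j are hard errors —
    they indicate a sequence/alignment mismatch.  Negative scores (possible
    after APC) are kept as-is.
    """
    if score_column not in ("apc", "raw"):
        raise ValidationError(f"score_column must be 'apc' or 'raw', got {score_column!r}")
    if dialect == "auto":
        dialect = _sniff_dialect(path)
    if dialect == "plmc-flat":
        records = _records_plmc(path)
    elif dialect == "evcouplings-csv":
        records = _records_evcouplings(path, score_column)
    else:
        raise ValidationError(f"unknown dialect {dialect!r}; supported: {', '.join(DIALECTS)}, auto")

    scores = np.zeros((n, n))
    covered = np.zeros(n, dtype=bool)
    seen: set[tuple[int, int]] = set()
    for i, j, s, lineno in records:
        if i == j:
            raise ValidationError(f"{path}:{lineno}: self-pair ({i},{j}) violates zero-diagonal invariant")
        if not (1 <= i < j <= n):
            raise ValidationError(
                f"{path}:{lineno}: pair ({i},{j}) outside canonical range 1 <= i < j <= {n}"
            )
        if (i, j) in seen:
            raise ValidationError(f"{path}:{lineno}: duplicate pair ({i},{j})")
        seen.add((i, j))
        scores[i - 1, j - 1] = scores[j - 1, i - 1] = s
        covered[i - 1] = covered[j - 1] = True
    logger.info("read %d coupling records from %s (%s)", len(records), path, dialect)
    return CouplingMatrix(scores=scores, covered=covered)


def write_couplings(matrix: CouplingMatrix, path, seq: str | None = None) -> None:
    """Write the upper triangle in EVcouplings CSV form, rows sorted by (i, j).

    Floats are emitted with 17 significant digits so a write/read round
    trip is bit-exact.  Residue columns are filled from ``seq`` when given,
    otherwise "-".
    """
    lines = ["i,A_i,j,A_j,fn,cn"]
    n = matrix.n
    iu, ju = np.nonzero(np.triu(matrix.scores, k=1))
    for i, j in zip(iu, ju):
        s = matrix.scores[i, j]
        ai = seq[i] if seq else "-"
        aj = seq[j] if seq else "-"
        lines.append(f"{i + 1},{ai},{j + 1},{aj},{s:.17g},{s:.17g}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    logger.info("wrote %d coupling records to %s (n=%d)", len(lines) - 1, path, n)
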