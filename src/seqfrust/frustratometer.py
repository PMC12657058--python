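"""Frustratometer mutational-output parsing and per-residue compression.

The structure-based Frustratometer emits, for each amino-acid contact,
the native interaction energy theta and the mean interaction energy of
its mutational decoys phi.  Those contact-level data are compressed to a
per-residue scalar: nu = theta - phi per contact, and epsilon_n is the
mean of nu over the h contacts containing residue n (membership is
bilateral — a contact (i, j) belongs to both X_i and X_j).  epsilon is
directly comparable to the sequence-based Gamma: both are average energy
differences upon mutation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import FileFormatError, ValidationError

logger = logging.getLogger(__name__)

# Accepted header aliases (lowercased) for each required field.  The real
# Frustratometer "mutational" table headers are Res1/Res2/ChainRes1/...
_ALIASES = {
    "res_i": ("res1", "res_i", "resi", "i"),
    "res_j": ("res2", "res_j", "resj", "j"),
    "chain_i": ("chainres1", "chain_i", "chaini"),
    "chain_j": ("chainres2", "chain_j", "chainj"),
    "theta": ("nativeenergy", "native_energy", "theta"),
    "phi": ("decoyenergy", "decoy_energy", "phi"),
}
_OPTIONAL = ("chain_i", "chain_j")


@dataclass(frozen=True)
class ContactRecord:
    """One Frustratometer contact: residue pair with native and decoy-mean energies."""

    res_i: int
    res_j: int
    chain_i: str
    chain_j: str
    theta: float
    phi: float

    def __post_init__(self) -> None:
        if self.res_i == self.res_j:
            raise ValidationError(f"contact with res_i == res_j == {self.res_i}")
        if not (math.isfinite(self.theta) and math.isfinite(self.phi)):
            raise ValidationError(f"non-finite energies in contact ({self.res_i},{self.res_j})")


@dataclass
class CompressedProfile:
    """Per-residue epsilon with contact counts h; masked where h == 0."""

    per_residue: np.ndarray
    contact_counts: np.ndarray
    defined_mask: np.ndarray

    @property
    def n(self) -> int:
        return self.per_residue.shape[0]


def read_frustratometer(path, chain: str | None = None) -> list[ContactRecord]:
    """Parse a Frustratometer mutational table (headered whitespace columns).

    Extra columns (decoy s.d., frustration index, residue names, ...) are
    tolerated and ignored.  Cross-chain contacts are always excluded with
    a logged count; if ``chain`` is given, only records with both chains
    equal to it are kept.
    """
    try:
        df = pd.read_csv(path, sep=r"\s+", float_precision="round_trip")
    except Exception as exc:
        raise FileFormatError(f"{path}: unparseable table: {exc}") from exc
    cols = {c.lower(): c for c in df.columns}
    resolved: dict[str, str] = {}
    for field_name, aliases in _ALIASES.items():
        for a in aliases:
            if a in cols:
                resolved[field_name] = cols[a]
                break
        else:
            if field_name in _OPTIONAL:
                continue
            raise FileFormatError(
                f"{path}: missing required column for {field_name!r} (accepted names: {aliases})"
            )

    records: list[ContactRecord] = []
    dropped_cross = 0
    dropped_chain = 0
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        d = dict(zip(df.columns, row))
        try:
            ci = str(d[resolved["chain_i"]]) if "chain_i" in resolved else "A"
            cj = str(d[resolved["chain_j"]]) if "chain_j" in resolved else "A"
            rec = ContactRecord(
                res_i=int(d[resolved["res_i"]]),
                res_j=int(d[resolved["res_j"]]),
                chain_i=ci,
                chain_j=cj,
                theta=float(d[resolved["theta"]]),
                phi=float(d[resolved["phi"]]),
            )
        except (TypeError, ValueError) as exc:
            raise FileFormatError(f"{path}:{lineno}: unparseable row: {exc}") from exc
        if rec.chain_i != rec.chain_j:
            dropped_cross += 1
            continue
        if chain is not None and rec.chain_i != chain:
            dropped_chain += 1
            continue
        records.append(rec)
    if dropped_cross:
        logger.info("%s: excluded %d cross-chain contacts", path, dropped_cross)
    if dropped_chain:
        logger.info("%s: excluded %d contacts outside chain %s", path, dropped_chain, chain)
    logger.info("%s: read %d mutational contact records", path, len(records))
    return records


def write_frustratometer(records: list[ContactRecord], path) -> None:
    """Write records in the Frustratometer-style headered whitespace format.

    17-significant-digit floats make write/read round trips bit-exact.
    """
    lines = ["Res1 Res2 ChainRes1 ChainRes2 NativeEnergy DecoyEnergy"]
    for r in records:
        lines.append(f"{r.res_i} {r.res_j} {r.chain_i} {r.chain_j} {r.theta:.17g} {r.phi:.17g}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def compress(records: list[ContactRecord], n: int) -> CompressedProfile:
    """Per-residue compression: epsilon_n = mean of (theta - phi) over X_n.

    Each record contributes to exactly two residues' contact sets, so
    sum(h) == 2 * len(records).  Duplicate (i, j) records (e.g. direct and
    water-mediated variants of one pair) each contribute a term, which is
    equivalent to averaging them into the residue mean.  Residues in no
    record are masked.
    """
    sums = np.zeros(n)
    counts = np.zeros(n, dtype=np.int64)
    for rec in records:
        for r in (rec.res_i, rec.res_j):
            if not (1 <= r <= n):
                raise ValidationError(f"contact residue index {r} outside [1, {n}]")
            sums[r - 1] += rec.theta - rec.phi
            counts[r - 1] += 1
    mask = counts > 0
    eps = np.full(n, np.nan)
    eps[mask] = sums[mask] / counts[mask]
    return CompressedProfile(per_residue=eps, contact_counts=counts, defined_mask=mask)
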