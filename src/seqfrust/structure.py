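"""Per-residue B-factor extraction from PDB files and sequence alignment.

Crystallographic B-factors (temperature factors, A^2) measure atomic
positional uncertainty and serve as the external comparator for
frustration profiles.  Each residue's score is the arithmetic mean of the
isotropic B over all of its ATOM-record atoms (hydrogens included when
present) after alternate-location resolution; HETATM entries and waters
are excluded.
"""

from __future__ import annotations

import csv
import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import protein_letters_3to1

from .errors import ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ResidueBFactor:
    """Mean isotropic B-factor of one polymer residue."""

    chain: str
    resnum: int
    icode: str
    resname: str
    mean_b: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.mean_b) and self.mean_b >= 0.0):
            raise ValidationError(
                f"mean B-factor for {self.chain}{self.resnum}{self.icode.strip()} must be finite and >= 0"
            )


def residue_bfactors(pdb_path, chain: str) -> list[ResidueBFactor]:
    """Extract per-residue mean B-factors for one chain of a PDB file.

    Alternate locations are resolved by keeping the highest-occupancy
    conformer per atom name (ties: first encountered).  Hydrogens count
    toward the mean when present; their number is logged so the effect is
    visible.
    """
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("s", pdb_path)
    model = next(structure.get_models(), None)
    if model is None:
        raise ValidationError(f"{pdb_path}: no models found")
    available = [c.id for c in model]
    if chain not in available:
        raise ValidationError(f"{pdb_path}: chain {chain!r} absent; available chains: {available}")

    out: list[ResidueBFactor] = []
    n_hydrogens = 0
    for residue in model[chain]:
        hetflag, resnum, icode = residue.id
        if hetflag != " ":  # HETATM / water
            continue
        best: dict[str, tuple[float, float]] = {}  # atom name -> (occupancy, b)
        for atom in residue.get_unpacked_list():
            occ = atom.get_occupancy()
            occ = 1.0 if occ is None else float(occ)
            if atom.element == "H":
                n_hydrogens += 1
            prev = best.get(atom.get_name())
            if prev is None or occ > prev[0]:
                best[atom.get_name()] = (occ, float(atom.get_bfactor()))
        if not best:
            continue
        bvals = [b for _, b in best.values()]
        out.append(
            ResidueBFactor(
                chain=chain,
                resnum=int(resnum),
                icode=icode,
                resname=residue.get_resname(),
                mean_b=float(np.mean(bvals)),
            )
        )
    if not out:
        raise ValidationError(f"{pdb_path}: chain {chain!r} has no polymer ATOM records")
    if n_hydrogens:
        logger.info("%s chain %s: %d hydrogen atoms included in B-factor means", pdb_path, chain, n_hydrogens)
    return out


def _one_letter(resname: str) -> str | None:
    return protein_letters_3to1.get(resname.upper().strip())


def _identity_at_offset(bfactors: list[ResidueBFactor], seq: str, offset: int) -> tuple[int, int]:
    """(matches, mapped) for position = resnum - offset, insertion codes skipped."""
    matches = mapped = 0
    for rb in bfactors:
        if rb.icode.strip():
            continue
        pos = rb.resnum - offset
        if not (1 <= pos <= len(seq)):
            continue
        mapped += 1
        one = _one_letter(rb.resname)
        if one is not None and one == seq[pos - 1].upper():
            matches += 1
    return matches, mapped


def detect_offset(bfactors: list[ResidueBFactor], seq: str, search: int = 500) -> int:
    """Integer offset in [-search, search] maximizing sequence identity.

    Author residue numbering rarely starts at 1; the offset maps
    resnum -> 1-based sequence position as position = resnum - offset.
    """
    best_offset, best_matches = 0, -1
    for off in range(-search, search + 1):
        m, _ = _identity_at_offset(bfactors, seq, off)
        if m > best_matches:
            best_matches, best_offset = m, off
    return best_offset


def align_bfactors(
    bfactors: list[ResidueBFactor],
    seq: str,
    offset: int | str = 0,
) -> np.ndarray:
    """Map residue B-factors onto 1-based sequence positions.

    Returns a length-len(seq) vector, NaN where no structural residue
    maps.  ``offset="auto"`` runs :func:`detect_offset`.  Residues mapping
    outside [1, n] are dropped (logged); residues with insertion codes are
    skipped with a warning (numbering-based mapping cannot place them).
    A mismatch rate above 50% between mapped residue names and the
    sequence raises — wrong chain or offset suspected.
    """
    if offset == "auto":
        offset = detect_offset(bfactors, seq)
        logger.info("auto-detected numbering offset: %d", offset)
    offset = int(offset)
    n = len(seq)
    vec = np.full(n, np.nan)
    dropped = skipped_icode = mismatches = mapped = 0
    for rb in bfactors:
        if rb.icode.strip():
            skipped_icode += 1
            continue
        pos = rb.resnum - offset
        if not (1 <= pos <= n):
            dropped += 1
            continue
        mapped += 1
        one = _one_letter(rb.resname)
        if one is not None and one != seq[pos - 1].upper():
            mismatches += 1
        vec[pos - 1] = rb.mean_b
    if skipped_icode:
        warnings.warn(f"skipped {skipped_icode} insertion-code residues during numbering-based alignment")
    if dropped:
        logger.info("dropped %d residues mapping outside [1, %d]", dropped, n)
    if mapped and mismatches / mapped > 0.5:
        raise ValidationError(
            f"{mismatches}/{mapped} mapped residues mismatch the sequence; wrong chain or offset suspected"
        )
    if mismatches:
        logger.info("%d/%d mapped residues mismatch the sequence", mismatches, mapped)
    return vec


def write_bfactor_csv(path, values: np.ndarray) -> None:
    """Write a per-position B-factor vector as CSV (position, bfactor; NaN -> empty)."""
    v = np.asarray(values, dtype=np.float64)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["position", "bfactor"])
        for k in range(v.shape[0]):
            w.writerow([k + 1, "" if math.isnan(v[k]) else f"{v[k]:.17g}"])


def read_bfactor_csv(path) -> np.ndarray:
    """Read a per-position B-factor CSV back into a NaN-masked vector."""
    vals: list[float] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"position", "bfactor"}.issubset(reader.fieldnames):
            raise ValidationError(f"{path}: B-factor CSV must have columns position, bfactor")
        for row in reader:
            vals.append(float(row["bfactor"]) if row["bfactor"] != "" else math.nan)
    return np.asarray(vals)
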