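"""Synthetic protein instances with planted frustrated positions.

The generator emulates the full input side of the pipeline — a sequence,
a sparse symmetric coupling matrix, a consistent Frustratometer-style
contact table, and a noisy B-factor vector — with a known ground truth:
a chosen fraction of positions is planted as frustrated.  Non-planted
positions receive the residue that minimizes the coupling-weighted mean
contact potential against their neighbors (energetically optimized);
planted positions receive the residue that maximizes it (mutations can
only improve them).  Recovery of the planted mask by the frustration
profile is the pipeline's core statistical check.

Random streams are split per concern (topology, magnitudes, planting,
residues, noise) so changing one parameter never reshuffles unrelated
draws; everything is deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .couplings import CouplingMatrix, read_couplings, write_couplings
from .errors import ValidationError
from .frustration import frustration_profile
from .frustratometer import ContactRecord, write_frustratometer
from .potentials import AA_ALPHABET, PotentialTable, miyazawa_jernigan_1996
from .structure import read_bfactor_csv, write_bfactor_csv

GENERATOR_VERSION = "1"

# B-factor construction: typical-crystal base level plus a planted-signal
# step, plus the instance's own Gamma, plus Gaussian noise.
_BFACTOR_BASE = 20.0
_BFACTOR_PLANTED_STEP = 15.0


@dataclass(frozen=True)
class SyntheticProteinSpec:
    """Study conditions for one synthetic instance."""

    n: int = 100
    seed: int = 0
    contact_density: float = 0.05
    coupling_scale: float = 1.0
    frustrated_fraction: float = 0.2
    bfactor_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 20:
            raise ValidationError(f"n must be >= 20, got {self.n}")
        if not (0.0 < self.contact_density <= 1.0):
            raise ValidationError("contact_density must be in (0, 1]")
        if not (0.0 <= self.frustrated_fraction <= 0.5):
            raise ValidationError("frustrated_fraction must be in [0, 0.5]")
        if self.bfactor_noise_sd < 0.0 or self.coupling_scale <= 0.0:
            raise ValidationError("noise sd must be >= 0 and coupling_scale > 0")
        n_planted = round(self.frustrated_fraction * self.n)
        if self.frustrated_fraction > 0.0 and n_planted == 0:
            raise ValidationError(
                f"infeasible spec: frustrated_fraction {self.frustrated_fraction} rounds to 0 planted positions"
            )


@dataclass
class SyntheticProtein:
    sequence: str
    couplings: CouplingMatrix
    planted_mask: np.ndarray
    bfactors: np.ndarray
    frustratometer_records: list[ContactRecord]
    spec: SyntheticProteinSpec = field(repr=False)


def _site_energies(table: PotentialTable, idx: np.ndarray, row: np.ndarray) -> np.ndarray:
    """v[a] = sum_j row[j] * e(a, sigma_j) for all 20 candidate residues a."""
    return table.matrix[:, idx] @ row


def generate(
    spec: SyntheticProteinSpec,
    table: PotentialTable | None = None,
    sequence_noise_fraction: float = 0.0,
) -> SyntheticProtein:
    """Build one synthetic instance; deterministic given ``spec.seed``.

    ``sequence_noise_fraction`` randomizes that fraction of non-planted
    residues after the greedy assignment, degrading the planted signal in
    a controlled way (0 = noise-free conditions).
    """
    table = table or miyazawa_jernigan_1996()
    n = spec.n
    ss = np.random.SeedSequence(spec.seed)
    rng_topo, rng_mag, rng_plant, rng_res, rng_noise = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )

    # (1) contact topology: long-range pairs only (|i-j| >= 2); chain-adjacent
    # pairs carry no couplings, mirroring how DCA discounts trivial neighbors.
    iu, ju = np.triu_indices(n, k=2)
    m_possible = iu.size
    m_pairs = max(1, round(spec.contact_density * m_possible))
    chosen = rng_topo.choice(m_possible, size=m_pairs, replace=False)
    chosen.sort()
    pi, pj = iu[chosen], ju[chosen]

    # (2) coupling magnitudes: exponential, scaled
    mags = rng_mag.exponential(scale=spec.coupling_scale, size=m_pairs)
    scores = np.zeros((n, n))
    scores[pi, pj] = scores[pj, pi] = mags
    C = CouplingMatrix(scores=scores)

    # planted positions
    n_planted = round(spec.frustrated_fraction * n)
    planted = np.zeros(n, dtype=bool)
    if n_planted:
        planted[rng_plant.choice(n, size=n_planted, replace=False)] = True

    # (3) greedy residue assignment, two sweeps: optimize non-planted sites,
    # pessimize planted ones.  Ties break toward the lowest alphabet index.
    idx = rng_res.integers(0, 20, size=n)
    for _ in range(2):
        for k in range(n):
            v = _site_energies(table, idx, C.scores[k])
            idx[k] = int(np.argmax(v)) if planted[k] else int(np.argmin(v))
    if sequence_noise_fraction > 0.0:
        non_planted = np.where(~planted)[0]
        n_rand = round(sequence_noise_fraction * non_planted.size)
        if n_rand:
            targets = rng_res.choice(non_planted, size=n_rand, replace=False)
            idx[targets] = rng_res.integers(0, 20, size=n_rand)
    sequence = "".join(AA_ALPHABET[i] for i in idx)

    # (4) B-factors: affine in the planted indicator plus the instance's own
    # Gamma (masked positions contribute 0) plus Gaussian noise.
    profile = frustration_profile(C, sequence, table)
    gamma_filled = np.where(profile.defined_mask, profile.per_residue, 0.0)
    bfactors = (
        _BFACTOR_BASE
        + _BFACTOR_PLANTED_STEP * planted.astype(float)
        + gamma_filled
        + rng_noise.normal(0.0, spec.bfactor_noise_sd, size=n)
    )
    bfactors = np.maximum(bfactors, 0.0)

    # (5) Frustratometer-style records: theta is the native pair potential,
    # phi the mean over the 38 single-end substitutions at that pair.
    records: list[ContactRecord] = []
    tab = table.matrix
    for a, b in zip(pi, pj):
        ia, ib = idx[a], idx[b]
        theta = float(tab[ia, ib])
        col = tab[:, ib]
        row = tab[ia, :]
        phi = float((col.sum() - col[ia] + row.sum() - row[ib]) / 38.0)
        records.append(
            ContactRecord(res_i=int(a + 1), res_j=int(b + 1), chain_i="A", chain_j="A", theta=theta, phi=phi)
        )

    return SyntheticProtein(
        sequence=sequence,
        couplings=C,
        planted_mask=planted,
        bfactors=bfactors,
        frustratometer_records=records,
        spec=spec,
    )


def write_fixture_bundle(protein: SyntheticProtein, directory) -> None:
    """Write the bundle: seq.fasta, couplings.csv, frustratometer.tsv, bfactors.csv, manifest.json."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    with open(d / "seq.fasta", "w") as fh:
        fh.write(f">synthetic_seed{protein.spec.seed} n={protein.spec.n}\n")
        for i in range(0, len(protein.sequence), 60):
            fh.write(protein.sequence[i : i + 60] + "\n")
    write_couplings(protein.couplings, d / "couplings.csv", seq=protein.sequence)
    write_frustratometer(protein.frustratometer_records, d / "frustratometer.tsv")
    write_bfactor_csv(d / "bfactors.csv", protein.bfactors)
    manifest = {
        "spec": asdict(protein.spec),
        "generator_version": GENERATOR_VERSION,
        "planted_positions": [int(i + 1) for i in np.where(protein.planted_mask)[0]],
    }
    with open(d / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
        fh.write("\n")


def read_fasta_sequence(path) -> str:
    """First record of a FASTA file as an uppercase one-letter string."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValidationError(f"{path}: no FASTA records")
    return str(records[0].seq).upper()


def read_fixture_bundle(directory) -> SyntheticProtein:
    """Re-read a bundle through the package's own parsers."""
    from .frustratometer import read_frustratometer

    d = Path(directory)
    with open(d / "manifest.json") as fh:
        manifest = json.load(fh)
    spec = SyntheticProteinSpec(**manifest["spec"])
    sequence = read_fasta_sequence(d / "seq.fasta")
    couplings = read_couplings(d / "couplings.csv", n=len(sequence), dialect="evcouplings-csv")
    records = read_frustratometer(d / "frustratometer.tsv")
    bfactors = read_bfactor_csv(d / "bfactors.csv")
    planted = np.zeros(len(sequence), dtype=bool)
    planted[[p - 1 for p in manifest["planted_positions"]]] = True
    return SyntheticProtein(
        sequence=sequence,
        couplings=couplings,
        planted_mask=planted,
        bfactors=bfactors,
        frustratometer_records=records,
        spec=spec,
    )
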