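# Methods

## Energy model

The model treats evolutionary coupling scores as a soft contact map: the
interaction between positions i and j contributes C[i,j] · e(σi, σj) to
the total energy, where e is a knowledge-based contact potential. The
total energy γ(σ) sums the strictly upper triangle (each pair once; the
diagonal is never consumed). For a point mutation at position k only row
k of the pair-energy matrix changes, so the mutational energy difference
is computed incrementally,

    Δγ = Σ_{j≠k} C[k,j] · (e(wt_k, σj) − e(m, σj)),

and the per-residue frustration Γ_k is the unweighted mean of Δγ over the
19 non-wild-type canonical substitutions. The sign convention is fixed
package-wide: Δγ = γ(wt) − γ(mut), so positive Γ means mutations lower
the predicted energy on average and the native residue is frustrated.
The test suite's central property is that this incremental form agrees
with brute-force recomputation of every mutant's total energy to 1e-9
over randomized instances.

This is deliberately a mean-shift score, not a Z-score against a decoy
distribution: it measures whether mutations tend to raise or lower the
energy, not how wide the mutant-energy distribution is. Distribution-width
statistics are out of scope.

## Inputs and their assumptions

**Coupling scores** are consumed, never computed; alignment construction,
pseudolikelihood inference and APC correction belong to upstream tools
(typical settings for that toolchain: jackhmmer bit-score thresholds
0.8/0.5/0.5 with 5 iterations, a 50% query-alignment sequence filter, a
30% gap column filter, plmc regularization 0.01 with 100 iterations —
recorded here as configuration metadata only). Two dialects are parsed:
plmc flat text (headerless `i a_i j a_j extra score`) and EVcouplings CSV
(headered; `cn` = APC-corrected, `fn` = raw). The default score column is
the APC-corrected one, the standard EVcouplings ranking score; `raw` is a
switch. Negative post-APC scores are kept — the equations place no sign
restriction on C. The full matrix is used; whether to sparsify C (e.g.
top-L pairs) before the Hadamard product is an open modelling question,
and no thresholding is applied.

**The contact-potential table** defaults to the Miyazawa–Jernigan 1996
contact energies e_ij (provenance label `MJ1996-eij`), the most widely
used variant; which published MJ table a given upstream analysis used is
often unstated, so the table is swappable via a simple headered text file
(20 codes on the first row and column, symmetric body, symmetry validated
to 1e-9). Result contours depend only weakly on the variant. No distance-
or environment-dependent potentials.

**Alignment-column dropout.** Positions excluded upstream by gap filtering
arrive with no couplings. They are masked (NaN + defined_mask false), not
zero-filled: zero would be indistinguishable from "perfectly neutral" and
corrupt rank correlations. All downstream statistics drop masked positions
pairwise. Non-canonical residues are rejected in strict mode (default);
lenient mode masks them and ignores their incident couplings.

## Frustratometer compression

Structure-based mutational output lists contacts with a native interaction
energy θ and a decoy-mean energy φ. Compression to one scalar per residue
uses ν = θ − φ per contact and ε_n = mean of ν over the h contacts
containing residue n; membership is bilateral, so Σ h = 2 × records — an
identity asserted on every instance. Duplicate pair records (direct and
water-mediated variants) each contribute a term, i.e. they average into
the residue mean. Cross-chain contacts are always excluded (logged); a
chain filter restricts to one chain for multi-chain files. By default all
mutational records are compressed, whichever contact class they come from.
ε and Γ are the same kind of quantity — mean energy difference upon
mutation — which is what makes them directly comparable.

## B-factors

Per-residue B is the arithmetic mean over the residue's ATOM-record atoms:
hydrogens included when present (their count is logged so the effect is
visible), HETATM and waters excluded, and alternate locations resolved by
keeping the highest-occupancy conformer per atom name (ties: first
encountered). Mapping onto the query sequence uses author numbering with
an integer offset (position = resnum − offset); `offset="auto"` maximizes
sequence identity over offsets in [−500, 500]. Insertion-code residues are
extracted but skipped during numbering-based alignment — placing them
needs a full alignment, which is out of scope. A mapped-residue mismatch
rate above 50% is treated as a wrong chain/offset and raises. No B-factor
normalization happens at extraction; that is the benchmark module's job.

## Benchmark statistics

- **Correlation**: Spearman (Pearson on average ranks, ties averaged) with
  a p-value from the t-approximation on n−2 degrees of freedom; Pearson
  available as the linear alternative; exact permutation p for n ≤ 10.
  Pairwise deletion of masked entries; minimum 3 joint pairs.
- **Smoothing / normalization**: a centered moving average over defined
  neighbors (window shrinks at edges) and z-score or min-max scaling exist
  for presentation parity, but default statistics run on the raw profiles
  (window 1, no normalization) — the conservative choice, since smoothing
  is a display device; both are opt-in switches recorded in the report.
- **Quartile labels**: ground truth for classification takes the top and
  bottom quartiles of the defined B-factors (linear-interpolation
  percentiles, strict inequalities at the cut points; convention pinned by
  the tests). Requires ≥ 8 defined values and nonzero spread.
- **ROC / PR**: evaluation restricted to the high ∪ low set (mid excluded),
  which makes the chance average-precision baseline the positive
  prevalence, 0.5 for balanced quartiles — the convention under which
  "precision above 0.5" means better than chance. For the low-B task the
  score is negated (higher Γ predicts high B). AUC and average precision
  come from scikit-learn (trapezoidal threshold sweep; precision-weighted
  recall increments).
- **Wilcoxon signed-rank** (one-sided, greater): zeros dropped, ≥ 5 nonzero
  differences required; exact sign-pattern enumeration on tie-averaged
  ranks for ≤ 15 nonzero differences (2^m patterns), normal approximation
  with tie correction beyond.
- The report joint-masks the two vectors before computing quartile labels,
  so a position masked in either vector can never shift the thresholds:
  adding a masked position never changes any statistic.

## Synthetic generator

The generator emulates the full input side with a known ground truth.
Defaults: n = 100 residues, contact density 0.05 over the |i−j| ≥ 2 pairs,
exponential coupling magnitudes with scale 1.0, frustrated fraction 0.2,
B-factor noise sd 0. Chain-adjacent pairs carry no couplings, mirroring
how DCA discounts trivial backbone neighbors; this keeps the planted
signal from being swamped. Residues are assigned by a two-pass greedy
sweep: non-planted positions take the residue minimizing the
coupling-weighted potential against current neighbors, planted positions
the maximizing one (exact optimization is unnecessary — recovery is a
statistical property, and the greedy assignment is cheap and
deterministic; ties break toward the lowest alphabet index). B-factors
are 20 + 15·planted + Γ + Gaussian noise, i.e. a typical crystallographic
base level with the planted step chosen to dominate the Γ term at scale
1 couplings. Frustratometer-style records place θ = e(σi, σj) and φ =
the mean over the 38 single-end substitutions at that pair, so ε is a
monotone readout of the same planted signal as Γ. Random streams are
split per concern (topology, magnitudes, planting, residues, noise), so
changing the noise level never reshuffles the sequence.

What the generator does **not** emulate: phylogenetic correlation in
coupling noise, APC artifacts, contact-map geometry (no 3D embedding, so
no synthetic PDB coordinates — structure extraction is tested on small
hand-written PDB fixtures), disordered regions, or realistic B-factor
autocorrelation along the chain. Passing the recovery test therefore
shows the pipeline is self-consistent and sensitive to a planted
energetic signal, not that real proteins yield correlations of this size;
on real data the Γ-vs-B relationship is weak and only systematically
positive.

## Numerical choices

- Profile computation is vectorized as V = E20 · C with
  Γ_k = (20·V[wt,k] − Σ_a V[a,k]) / 19; a dense 500-residue profile runs
  well under 10 s on one CPU.
- Couplings and Frustratometer writers emit 17-significant-digit floats
  and the pandas readers use round-trip float parsing, so write→read is
  bit-exact.
- Degenerate inputs: an all-zero coupling matrix yields a fully masked
  profile (no error); all-tied vectors, < 3 joint pairs, zero variance and
  single-class label sets raise statistics errors, which the CLI maps to
  exit code 4 (validation errors exit 2, I/O errors 3).
- CLI outputs are written to a temp file and renamed, so failed runs never
  leave partial outputs; every run writes a provenance block (config echo
  + version), embedded in JSON reports or as a `.provenance.json` sidecar
  for CSV outputs.

## Problem sizes used in the checks

The test suite and acceptance script use randomized instances of 20–50
residues for oracle-equivalence checks (100 and 50 instances
respectively), 20 generator seeds at n = 100 for planted-signal recovery,
and 200 permutations for the classification null — sizes chosen so the
whole verification cycle completes in seconds while the statistical
checks remain well-resolved.

## Known limitations

- Coupling scores must be produced externally; quality of Γ is bounded by
  alignment depth and inference quality upstream.
- The mean-shift Γ ignores mutant-energy distribution width, which likely
  carries information about how strongly a position anchors the fold.
- Numbering-based B-factor alignment cannot place insertion-code residues
  and trusts author numbering up to one global offset.
- Whether correlation analyses should run on smoothed or raw profiles is
  genuinely open; both are supported, raw is the default.
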