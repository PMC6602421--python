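# Methods

This note documents the models and procedures implemented in `chaincompare`,
the defaults that matter, and what the synthetic fixtures do and do not
establish.

## Chain model and parsing

Structures are parsed with Biopython's `Bio.PDB` (PDB and mmCIF) and
flattened into an immutable `Chain`: ordered residues with heavy atoms,
B-factors, author numbering (with insertion codes) and resolution metadata.
Conventions:

- **Alternate locations**: the highest-occupancy conformer is kept; ties go
  to the lexicographically first altloc id.
- **Hydrogens and waters** are dropped throughout; every metric in the
  package is defined on heavy atoms.
- **HETATM-only chains** (waters, ligands) are not comparable chains.
- **Missing residues** are detected from the full-sequence record
  (SEQRES / `entity_poly`) by globally aligning it against the coordinate
  sequence; without such a record, gaps in the author numbering are used.
  Missing positions carry state `-`/O and can be included in (default) or
  excluded from the Other-percentage denominators.
- **Resolution**: taken from the header; structures with none (NMR
  ensembles, computed models) are assigned **2.8 Å**, a reliable average
  for solved NMR structures.  Coordinates pass through `Bio.PDB`'s float32
  storage, so file round-trips are exact to ~10⁻⁵ Å.

## Residue correspondence and superposition

Sequences are aligned by Needleman–Wunsch with affine gaps (Gotoh).
Defaults: BLOSUM62, gap open −10, gap extend −0.5; non-standard residues
score as `X`.  Ties in the dynamic program are broken deterministically
(match/mismatch preferred over a gap in chain A, over a gap in chain B,
working backwards from the alignment end).  The in-repo implementation
exists because this tie-break is part of the contract; its optima are
cross-checked against Biopython's `PairwiseAligner` in the tests.

Superposition is a closed-form least-squares (Kabsch) fit of chain B's
aligned Cα atoms onto chain A's, computed via
`scipy.spatial.transform.Rotation.align_vectors`.  Because the target
regime is *highly similar* chains, a full structural-alignment program is
unnecessary; instead an optional iterative trim (default: 2 rounds, each
dropping the worst-deviating 10% of pairs, never below 3) emulates
core-based alignment, and both the trimmed-core RMSD and the all-pair RMSD
are reported.  For motions that split a chain into two rigid bodies of
similar size (a symmetric hinge), the trimmed fit may converge on either
arm; callers who care which arm anchors the frame should raise
`trim_rounds` or inject an external transform (a 12-number text file:
row-major rotation then translation).  RMSD near zero is computed directly
from the transformed coordinates rather than from the fit residual, which
cancels catastrophically below ~10⁻⁷.

## Secondary-structure assignment

### Hydrogen-bond method (8 states)

The classic backbone H-bond pattern analysis. Amide hydrogens, usually
absent from crystal structures, are rebuilt 1.0 Å from N along the bisector
opposite the C(i−1)–N and CA–N directions.  A donor/acceptor pair is bonded
when

    E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) < −0.5 kcal/mol,

with distances clamped (E = −9.9) below 0.5 Å; only the two lowest-energy
acceptors per donor are retained.  n-turns (n = 3, 4, 5), minimal helices
(two consecutive n-turns), parallel/antiparallel bridges, ladders and
bulge-linked ladders are composed into `H G I E B T S -`; overlaps resolve
in that priority order (4-helix first).  A C(i)–N(i+1) distance above
2.5 Å is a chain break and terminates every pattern; the first residue,
prolines and residues after a break cannot donate.  Chains with fewer than
five full-backbone residues *disable* the method (no exception) so that
consensus simply proceeds without it.

### Cα-geometry method (3 working states)

For Cα-only records (and as a methodologically independent second opinion),
a geometric assigner in the P-SEA tradition.  Per residue it evaluates
d(i−1, i+1), d(i, i+3)-type distances (d2/d3/d4), the pseudo bond angle
τ(i−1, i, i+1) and pseudo dihedral α(i−1 … i+2) against threshold windows
(defaults are the published P-SEA intervals, e.g. helix d3 ∈ [4.8, 5.8] Å,
τ ∈ [77°, 101°], α ∈ [30°, 70°]; strand d2 ∈ [6.1, 7.3] Å,
d3 ∈ [9.0, 10.8] Å, |α| ≥ 125°).  Runs of strict candidates seed segments
that are extended by relaxed candidates; helices shorter than 5 and strands
shorter than 3 residues are suppressed.  All windows are constructor
parameters (`CaGeomParams`).

### External reports and reduction

Classic DSSP columnar reports and STRIDE `ASG` records are parsed and
mapped onto the chain by (chain id, author number, insertion code);
unlisted residues get `-`.  Every extended string reduces to three states
by H,G,I → H; E,B → E; everything else → O.

### Consensus

With one enabled method the consensus is that method's three-state string.
With several, a residue keeps the reduced state only where all enabled
methods agree **in extended format**; any extended-format disagreement
(e.g. H vs G, even though both reduce to helix) yields `X`.  This strict
rule is deliberate: near-threshold conformations are exactly what
cross-method disagreement is good at flagging.  `X` counts inside the
Other percentage but is also reported separately.

## Difference tracks

- `DIFFERENCES` — per method and for the consensus, flags aligned positions
  whose states differ; gaps are not-comparable; a method disabled on either
  chain is dropped for both.
- `CA DIST` — ‖CAᴬ − T(CAᴮ)‖ under the chain superposition.
- `SC DIST` — defined for identical residue types only: the partner residue
  is superposed on the shared main-chain atoms ({N, CA, C, O}, at least 3),
  then the maximum distance over identically named heavy atoms is taken;
  glycine pairs are 0 by convention, mismatched types undefined.
- `CONTACTS` — a residue's contact set is every other residue with any
  heavy-atom pair within 5.0 Å, excluding sequence neighbours i±1 (both
  config-exposed).  Sets are mapped into alignment-position space —
  contacts to residues without an aligned partner keep chain-specific
  sentinel identities, so they always count — and the reported value is
  |A ∪ B| − |A ∩ B|, the symmetric-difference size.
- `BFACTORS` — per-residue mean heavy-atom B-factor converted to a mid-rank
  percentile within the chain (percentage of residues strictly below, plus
  half the ties): deterministic, scale-free, invariant under monotone
  transforms.  The chain's effective resolution is recorded as context; no
  resolution-binned reference distribution is applied (within-chain ranking
  is this package's documented substitute for any resolution-dependent
  scheme).

All tracks are pure functions of their inputs; changing a selection or the
method set is recomputation, not cache mutation.

## Synthetic fixtures

Generators build poly-alanine chains in torsion space with standard peptide
geometry (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, C=O 1.231 Å; ideal
α-helix φ = −57°, ψ = −47°; strand φ = −139°, ψ = 135°):

- `make_ideal_helix`, `make_extended_strand`;
- `make_beta_hairpin` — two antiparallel strands joined by a two-residue
  turn whose torsions were calibrated once so the strands register
  cross-strand H-bonds (a real ladder, not two loose strands);
- `make_hinge_pair` — helix–linker–helix, with everything beyond the hinge
  rotated rigidly about an axis through the hinge Cα perpendicular to the
  local helix axis; linker torsions (φ = 20°, ψ = 0°) were chosen once so
  that neither assigner sits near a state threshold for hinge angles up to
  ~25°, making the pair's secondary structure identical by construction;
- `perturb` — seeded isotropic Gaussian displacement of all atoms or side
  chains only; `make_perturbed_line` — a noisy Cα trace as a random-coil
  stand-in.

Every generator is bit-reproducible given its seed.  What these fixtures do
**not** emulate: real side-chain rotamers (side chains are schematic
extended arms), crystallographic disorder, solvent, hetero-groups, or
realistic B-factor fields (B-factors ramp deterministically).  A green test
on fixtures therefore establishes the *algorithms* — not robustness to
every pathology of deposited structures.

The oracle-equivalence suite compares the in-repo H-bond assigner's
three-state output against an independently developed hydrogen-bond
implementation (MDAnalysis' port of pydssp) over 210 generated chains
(ideal helices, hairpins, helices with 0.3 Å thermal-scale coordinate
noise), requiring ≥95% per-residue agreement; residual disagreement is
confined to segment termini, where the two implementations' H-placement
and helix-extension details differ.

## Known limitations

- Contacts are intra-chain only; no quaternary interfaces, ligand contacts
  or solvent accessibility.
- No π-helix refinements beyond the classic 8-state rules; no STICKS-style
  line-segment assigner and no parser for its (undocumented) output format.
- The Cα-geometry method reports only H/E/−; turns and bends are left to
  the H-bond method.
- B-factor percentiles are within-chain; comparing percentile tracks
  between chains of very different resolution should be done with the
  recorded effective resolutions in mind.
- The sequence-alignment-guided superposition assumes the chains are
  homologous along their full length; it is not a fold-recognition tool.
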