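# Methods

This note documents the models and algorithms implemented in `atomseq`,
the numerical choices behind them, what the synthetic fixtures emulate,
and the known limitations.

## Sequence model

A `Sequence` stores an unsigned-integer *symbol code* array, not the
symbols: the code of a symbol is its index in the ordered symbol list of
the sequence's `Alphabet`.  Any hashable value can be a symbol
(characters, three-letter codes, tuples), and every downstream operation
— alignment above all — works on the code arrays alone, so two sequences
over entirely different alphabets behave identically if their code
arrays and score tables agree.  The element width of the code array is
the smallest of 1/2/4/8 bytes whose unsigned range covers the alphabet
size, so alphabets with more than 256 symbols work transparently.

`NucleotideSequence` defaults to the unambiguous DNA alphabet `A,C,G,T`;
the IUPAC-ambiguous 15-letter extension is selected automatically when
ambiguity codes appear in the input (or explicitly via `ambiguous=True`).
`U` is folded to `T` at construction, so RNA input is accepted but one
canonical internal alphabet is kept.  Complementation follows IUPAC
pairing and is an involution.  `ProteinSequence` uses the 20 canonical
amino acids plus `X` (unknown) and `*` (stop); rarely used one-letter
codes (B, Z, U, O) are folded to `X` on input.

Translation uses the standard genetic code with `ATG` as the sole start
codon.  In *complete* mode the sequence (length divisible by 3) is read
codon-by-codon in frame 0, stops rendered as `*`.  In *ORF* mode every
`ATG` in the three forward frames opens a reading frame that ends at the
first in-frame stop (excluded from the product); a trailing start with no
stop yields a product truncated at the sequence end.  The caller supplies
the reverse complement to scan the minus strand, keeping strand logic in
one place.  Codons containing ambiguity codes translate to `X` — lossless
and simple; a sophisticated implementation could resolve ambiguity codes
whose expansions agree on one amino acid, which this one deliberately
does not attempt.

## Pairwise alignment

Global alignment is Needleman–Wunsch; local alignment is Smith–Waterman
with the usual zero floor.  Affine gap penalties use the Gotoh
three-state recursion (match state plus one deletion and one insertion
state).  Gap penalties are non-positive *scores*: the first column of a
gap run contributes the open penalty, each further column the extend
penalty; the linear model is the special case `open == extend`.  Passing
a single integer selects a dedicated single-matrix linear kernel; an
`(open, extend)` pair selects the Gotoh kernel even when the two values
are equal.  Keeping both kernels makes their score equivalence at
`open == extend` a meaningful internal cross-check rather than a
tautology, and the test suite exercises it as such.

Substitution scores are looked up as `scores[code1, code2]` — the direct
indexing that the symbol-code design exists for.  The two matrix
alphabets may differ, which permits aligning sequences of different
types; a matrix *fits* a sequence alphabet when it equals it or extends
it as an ordered prefix.  The eight standard NCBI matrices
(BLOSUM45/50/62/80/90, PAM30/70/250) ship as NCBI-format text files and
are re-indexed onto the protein alphabet at load time; arbitrary
NCBI-format text is also accepted.

One optimal alignment is returned.  Traceback ties are broken in the
fixed priority diagonal > gap-in-second-sequence > gap-in-first-sequence,
which makes outputs deterministic and therefore testable.  Terminal gaps
are penalized like internal ones (pure global alignment; semi-global
modes are out of scope).  Both kernels store the full dynamic-programming
matrices, so memory is O(len1 x len2); linear-space divide-and-conquer
alignment is deliberately not implemented.

The DP kernels are validated against an exhaustive enumeration oracle
(all monotone traces, no memoization) on small inputs, and against
Biopython's `PairwiseAligner` as an independent established
implementation.

## Atomic model and geometry

`AtomArray` is a structure of arrays: one NumPy annotation array of
length n per category (`chain_id`, `res_id`, `res_name`, `atom_name`,
`element`, `hetero`, optionally `b_factor`, `occupancy`, `altloc_id`)
plus an (n, 3) float64 coordinate array in Angstrom.  `AtomArrayStack`
shares one set of annotations across m models and stores (m, n, 3)
coordinates.  Both index like ndarrays (integers, slices, index arrays,
boolean masks), keeping annotations and coordinates paired.  Atom order
is file order throughout; nothing is ever re-sorted.

`distance`, `angle` and `dihedral` broadcast over leading dimensions.
Angles are radians in [0, pi]; dihedrals are signed torsions in
(-pi, pi] with the IUPAC convention (0 = cis).  Degenerate geometry
(zero-length bond vectors, collinear axes) yields quiet NaN rather than
an exception, so vectorized calls never abort mid-array; degrees appear
only in CLI rendering.  Backbone torsions per residue i are
phi = C(i-1)-N(i)-CA(i)-C(i), psi = N(i)-CA(i)-C(i)-N(i+1),
omega = CA(i)-C(i)-N(i+1)-CA(i+1); residue identity is (chain, residue
number) in file order, and termini or missing backbone atoms give NaN.

## Superimposition, RMSD, RMSF

Superimposition is the Kabsch algorithm via SVD of the 3x3 covariance
matrix of the centered point sets.  If the rotation determinant would be
negative the singular direction with the smallest singular value is
sign-flipped, so the result is always a proper rotation — never a
reflection, even for mirrored input.  The returned `RigidTransform`
decomposes the motion as center translation, rotation, final
translation.  Optimality is cross-checked in the tests against a
quaternion characteristic-polynomial oracle (largest eigenvalue of the
4x4 key matrix), which computes the minimal RMSD without ever forming a
rotation matrix.

RMSD is the root mean square of per-atom distances with no implicit
superimposition (compose with `superimpose` explicitly).  RMSF is the
per-atom root mean square of distances to a reference over the models of
a stack; the reference defaults to the coordinate mean and at least two
models are required.

## Solvent-accessible surface area

Shrake–Rupley point counting: each atom's sphere of radius
`r_atom + probe` carries quasi-uniform test points; a point is buried if
it falls inside any neighbor's probe-inflated sphere; the atom's area is
the exposed fraction times the sphere area.  Defaults: probe 1.4 Å
(water), 1000 points per atom.  Points come from a golden-section
(Fibonacci) spiral lattice — deterministic, so results are exactly
reproducible and regression-testable; no randomness enters the
calculation.  Neighbor search uses scipy's `cKDTree`; the contract is
exactness of the neighbor set, not a particular data structure.

Two radius sets are available and the choice is explicit in
`SasaParameters`: `"protor"` (default) assigns ProtOr-style united-atom
group radii by residue and atom name (carbonyl/aromatic-junction C 1.61,
aromatic CH 1.76, aliphatic C 1.88, N 1.64, carbonyl O 1.42, hydroxyl
and water O 1.46, S 1.77 Å), suitable for crystal structures lacking
hydrogens; `"element"` uses van der Waals radii (H 1.20, C 1.70, N 1.55,
O 1.52, S 1.80 Å, ...) for structures with hydrogens.  Unknown heavy
atoms raise, naming the atom.  All atoms present occlude; excluding
solvent or het atoms is the caller's decision via the `atom_mask`
argument, which removes atoms from the calculation entirely.

Accuracy is checked against closed-form sphere areas (isolated atom) and
a high-resolution latitude–longitude numerical integration of two-sphere
configurations; the isolated-atom error decreases monotonically with the
point count.

## Secondary-structure assignment

Assignment into helix (`a`), strand (`b`) and coil (`c`) uses only CA
geometry, following the published P-SEA criteria.  Per residue the
distances d(i,i+2), d(i,i+3), d(i,i+4), the angle over three consecutive
CA and the torsion over four are measured and thresholded:

| | d2 (Å) | d3 (Å) | d4 (Å) | angle | torsion |
|---|---|---|---|---|---|
| helix | — | 5.3 ± 0.5 | 6.4 ± 0.6 | 89° ± 12° | 50° ± 20° |
| strand | 6.7 ± 0.6 | 9.9 ± 0.9 | 12.4 ± 1.1 | 124° ± 14° | −170° ± 45° |

A residue is a strict helix candidate if (d3 and d4) or (angle and
torsion) criteria hold, a strict strand candidate analogously (d2, d3
and d4, or angle and torsion; the torsion interval wraps the periodic
boundary).  Runs of at least 5 strict helix candidates (3 for strands)
form segments, which then grow outward while a relaxed criterion (d3
alone, or d3-or-angle for helices) holds.  Helix wins where both claim a
residue.  Windows extending past the chain ends leave residues coil, and
chains with fewer than 5 CA atoms are entirely coil.  These thresholds
live in one named constants block in `analyze.py` with a comment per
constant, as the single point of audit.  The assignment is cross-checked
in the tests against biotite's implementation of the same published
criteria on ideal fixture geometries.

## File formats

**FASTA** — byte-faithful records of (header, sequence text); writing
wraps sequence lines at a configurable width (default 80) and
write-then-read is the identity.

**GenBank** — only the FEATURES block is parsed (column-21 continuation
layout).  Locations keep the source conventions: 1-based inclusive
coordinates (`span0()` converts to 0-based half-open), `<`/`>` partial
markers, `n^m` between-base sites, and per-location strand flags
normalized from `complement(...)` at any nesting depth, preserving
written order.  Qualifiers are an order-preserving multimap; multi-line
quoted values re-join without separator for sequence-like qualifiers
(`translation` and kin) and with a single space otherwise.  A renderer
emits a feature block that re-parses to the same features, which is the
parser's main invariant and test surface.

**PDB** — only ATOM/HETATM (and MODEL/ENDMDL) records are read, by fixed
columns; `hetero` is true exactly for HETATM.  A blank element column is
inferred from the atom-name columns by the standard left-justification
rule (so C-alpha ` CA ` is carbon while calcium `CA  ` is calcium).  By
default the first-listed altloc of each atom is kept; `keep_altlocs=True`
keeps all and adds an `altloc_id` annotation.  The writer aligns atom
names element-wise at column 14 and raises, naming atom and field, on
any field overflow (chain > 1 character, residue number > 4 digits,
serial > 5 digits, coordinate out of the 8.3 field).

**PDBx/mmCIF** — a generic category model: the file is tokenized
(quoted values, semicolon multi-line blocks, `loop_` constructs) into
named categories of equal-length columns; key-value categories have
length-1 columns.  `atom_site` converts to and from atom arrays, with
models grouped by the model-number item.  The writer emits a minimal
`data_` block with the `atom_site` category.

**MMTF** — a MessagePack map of strategy-encoded binary fields, each
with a 12-byte big-endian header (codec id, element count, parameter).
Both directions are implemented: the ten codec strategies needed for
coordinate and annotation data (pass-through float32/int8/int16/int32,
fixed-length strings, run-length char, run-length int, delta +
run-length, run-length + divisor quantization, delta + recursive int16
indexing + divisor quantization), and the flattening between the
chain -> group -> atom hierarchy and the columnar model.  Coordinates are
quantized with divisor 1000, B factors with 100.  In recursive indexing
the int16 extrema act as continuation markers, so a value landing
exactly on a marker is followed by a terminating zero.  The MessagePack
layer itself is a small self-contained subset
(nil/bool/int/float/str/bin/array/map) — the only container features an
MMTF document uses.  Quantized fields decode to the exact quotient
(quantized integer / divisor) in float64, so a round trip at the divisor
resolution is bit-stable.

Coordinates are held internally as unquantized float64; quantization
happens only at serialization (3 decimals for PDB/mmCIF, divisor 1000
for MMTF), so any chain of conversions preserves coordinates to 0.001 Å.

## Synthetic fixtures

The fixtures module generates every input the algorithms need, so no
database download is ever required:

* **ideal helix** — CA trace with 1.5 Å rise per residue, 3.6 residues
  per turn, 2.3 Å radius; consecutive CA distance ≈ 3.8 Å.
* **ideal strand** — planar zigzag, 3.8 Å CA spacing, pleat amplitude
  0.892 Å chosen so the CA-CA-CA angle is 124°, the strand criteria's
  center.
* **trans-peptide** — N/CA/C backbone zigzagging in a plane, so every
  defined backbone torsion is exactly pi (ideal trans).
* **random structures** — residues of four backbone atoms over two
  chains plus trailing HETATM waters, coordinates drawn uniformly on the
  0.001 Å grid so text round trips are exact, B factors and occupancies
  on their own written precision grids.
* **random sequences / coils** — seeded draws; identical spec + seed
  give byte-identical output.

What these fixtures do *not* emulate: real packing density (random
structures are gas-like, so SASA values on them are near-spherical),
side chains, chain breaks, insertion codes, or the altloc/occupancy
correlations of real crystal structures.  Passing tests therefore
demonstrate algorithmic correctness on well-defined geometry, not
robustness to every pathology of deposited PDB entries.

## Problem sizes and determinism

The test suite and the acceptance script size their inputs to run in
seconds: alignment oracles use sequences of length ≤ 5 over 4-symbol
alphabets (small enough for exhaustive enumeration to be exact),
superimposition uses up to 30 points over 50 trials, the format triangle
uses a 500-atom, 3-model structure, and codec identity checks use
1000 arrays per codec.  All randomness flows through explicit seeds; the
SASA sphere lattice and alignment traceback are deterministic by
construction.

## Known limitations

* No semi-global alignment, no linear-space alignment, no heuristic
  (seed-and-extend) alignment, no multiple sequence alignment.
* The corrected-BLOSUM matrix family is not bundled; supply it as
  NCBI-format text if needed.
* No bond/connectivity model; MMTF bond fields are ignored on decode.
* GenBank parsing covers the feature table only; ORIGIN sequences are
  ignored.
* P-SEA thresholds are tuned for proteins; nucleic-acid structures get
  no meaningful assignment.
* mmCIF writing emits only `atom_site` plus a minimal header; arbitrary
  category passthrough is supported in the category model but not
  round-tripped through the atom-array conversion.
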