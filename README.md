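# atomseq

A NumPy-backed toolkit for sequence analysis and structural
bioinformatics, for people who want the whole workflow — load, filter,
measure, align, convert — inside Python instead of stitched together
from command-line tools and intermediate files.

## What it provides

**Sequences as code arrays.** A sequence over an alphabet
(A<sub>1</sub>, ..., A<sub>k</sub>) is stored as the array of *symbol
codes* c<sub>i</sub> = index of the i-th symbol in the alphabet, in the
smallest unsigned integer width that covers k.  Alignment and every
other operation act on code arrays only, so symbols can be characters,
three-letter codes or tuples, and alphabets can exceed 256 symbols.

**Optimal pairwise alignment.** Needleman–Wunsch (global) and
Smith–Waterman (local) dynamic programming with linear or affine
(Gotoh) gap penalties; a gap run of length L scores
g<sub>open</sub> + (L−1) g<sub>extend</sub>.  Scores come from a
substitution matrix S indexed directly by code pairs, S[m, n]; the
standard NCBI matrices (BLOSUM45–90, PAM30/70/250) are bundled.
Alignments carry a *trace*: per column, the index of the aligned symbol
in its source sequence, −1 for a gap.

**Structures as columnar arrays.** An `AtomArray` holds one annotation
array per category and an (n × 3) coordinate array; an `AtomArrayStack`
holds (m × n × 3) coordinates for m models sharing annotations.  Both
index like ndarrays, so `array[array.atom_name == "CA"]` is the
CA trace.  On top: distances/angles/dihedrals with broadcasting,
backbone φ/ψ/ω, Kabsch superimposition (proper rotations only), RMSD =
√(Σ‖x<sub>i</sub> − y<sub>i</sub>‖²/n), per-atom RMSF across models,
Shrake–Rupley solvent-accessible surface area (probe 1.4 Å, 1000
deterministic sphere points per atom, ProtOr united-atom or van der
Waals element radii), and P-SEA secondary-structure assignment from CA
geometry alone.

**File formats.** FASTA and GenBank feature tables (with the full
location grammar: `join`, `complement`, partial markers, between-base
sites); PDB coordinate records; generic PDBx/mmCIF category tables; and
the binary MMTF format — both decoder *and* encoder, including all the
run-length / delta / quantized / recursive-index codec strategies.
Coordinates survive any conversion chain to 0.001 Å.

## Worked example

```python
from atomseq import ProteinSequence, load_substitution_matrix, align_global
from atomseq.analyze import annotate_sse
from atomseq.fixtures import ideal_helix

s1 = ProteinSequence("MKTAYIAKQR")
s2 = ProteinSequence("MKTAHIAKQQR")
alignment = align_global(s1, s2, load_substitution_matrix("BLOSUM62"), (-10, -1))
print(alignment)
print("score:", alignment.score)
print("".join(annotate_sse(ideal_helix(20))))
```

prints

```
MKTAYIAK-QR
MKTAHIAKQQR
score: 34
caaaaaaaaaaaaaaaaaac
```

The affine-gap alignment inserts one gap (opening cost −10), aligns Y
against H (BLOSUM62 score 2) and totals 34; the ideal 20-residue helix
fixture is labeled helix (`a`) at every interior residue and coil (`c`)
at the termini, where the assignment windows run past the chain ends.

The same operations are available from the shell:

```sh
atomseq align pair.fasta --matrix BLOSUM62 --gap-open -10 --gap-extend -1
atomseq convert structure.pdb structure.mmtf
atomseq analyze structure.pdb sasa --points 1000
atomseq fixture ideal_helix --residues 20 --out helix.pdb
```

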