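"""
Deterministic synthetic fixtures.

Every algorithm in the package can be exercised without downloading any
database entry: this module builds random sequences, idealized CA traces
(alpha-helix, extended strand, random coil), planar trans-peptide
backbones and small random multi-model structures, all reproducible from
an explicit seed.

Geometry of the idealized traces:

* helix: 1.5 A rise per residue, 3.6 residues per turn, 2.3 A CA radius
  (consecutive CA distance approx. 3.8 A);
* strand: planar zigzag with 3.8 A CA spacing and an alternating pleat
  chosen so the CA-CA-CA angle is approx. 124 deg;
* trans-peptide: N/CA/C backbone zigzagging in a plane, so every
  backbone torsion, including omega, is exactly pi.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .atoms import AtomArray, AtomArrayStack, stack_models
from .seqio import FastaRecord, write_fasta
from .strucio import write_structure

__all__ = [
    "FixtureSpec",
    "generate_fixture",
    "random_fasta",
    "ideal_helix",
    "ideal_strand",
    "random_coil",
    "trans_peptide",
    "random_structure",
    "toy_structure_files",
]

HELIX_RISE = 1.5         # A per residue
HELIX_RES_PER_TURN = 3.6
HELIX_RADIUS = 2.3       # A

STRAND_CA_SPACING = 3.8  # A
# x-step / pleat amplitude solving |CA-CA| = 3.8 and CA angle = 124 deg
_STRAND_X_STEP = 3.3553
_STRAND_PLEAT = 0.8920


def _ca_trace(coords: np.ndarray, chain_id: str = "A") -> AtomArray:
    """CA-only poly-alanine AtomArray from an (n, 3) coordinate array."""
    n = len(coords)
    array = AtomArray(n)
    array.coord = np.round(np.asarray(coords, dtype=np.float64), 3)
    array.chain_id = np.full(n, chain_id, dtype="U4")
    array.res_id = np.arange(1, n + 1)
    array.res_name = np.full(n, "ALA", dtype="U5")
    array.atom_name = np.full(n, "CA", dtype="U6")
    array.element = np.full(n, "C", dtype="U2")
    array.hetero = np.zeros(n, dtype=bool)
    array.add_annotation("b_factor", np.zeros(n))
    array.add_annotation("occupancy", np.ones(n))
    return array


def ideal_helix(n_residues: int = 20, chain_id: str = "A") -> AtomArray:
    """CA trace of an ideal alpha-helix."""
    i = np.arange(n_residues)
    theta = 2.0 * np.pi * i / HELIX_RES_PER_TURN
    coords = np.column_stack(
        (
            HELIX_RADIUS * np.cos(theta),
            HELIX_RADIUS * np.sin(theta),
            HELIX_RISE * i,
        )
    )
    return _ca_trace(coords, chain_id)


def ideal_strand(n_residues: int = 12, chain_id: str = "A") -> AtomArray:
    """CA trace of an ideal extended strand (alternating pleat)."""
    i = np.arange(n_residues)
    coords = np.column_stack(
        (
            _STRAND_X_STEP * i,
            _STRAND_PLEAT * np.where(i % 2 == 0, 1.0, -1.0),
            np.zeros(n_residues),
        )
    )
    return _ca_trace(coords, chain_id)


def random_coil(n_residues: int = 20, seed: int = 0, chain_id: str = "A"):
    """Self-avoiding-ish random CA walk with 3.8 A steps."""
    rng = np.random.default_rng(seed)
    coords = np.zeros((n_residues, 3))
    for i in range(1, n_residues):
        step = rng.normal(size=3)
        step *= STRAND_CA_SPACING / np.linalg.norm(step)
        coords[i] = coords[i - 1] + step
    return _ca_trace(coords, chain_id)


def trans_peptide(n_residues: int = 6, chain_id: str = "A") -> AtomArray:
    """
    Planar zigzag N/CA/C backbone: every torsion defined on it (phi,
    psi, omega) equals pi exactly, the trans arrangement.
    """
    n_atoms = 3 * n_residues
    k = np.arange(n_atoms)
    coords = np.column_stack(
        (
            1.3 * k,
            0.5 * np.where(k % 2 == 0, 1.0, -1.0),
            np.zeros(n_atoms),
        )
    )
    array = AtomArray(n_atoms)
    array.coord = np.round(coords, 3)
    array.chain_id = np.full(n_atoms, chain_id, dtype="U4")
    array.res_id = np.repeat(np.arange(1, n_residues + 1), 3)
    array.res_name = np.full(n_atoms, "GLY", dtype="U5")
    array.atom_name = np.asarray(["N", "CA", "C"] * n_residues, dtype="U6")
    array.element = np.asarray(["N", "C", "C"] * n_residues, dtype="U2")
    array.hetero = np.zeros(n_atoms, dtype=bool)
    array.add_annotation("b_factor", np.zeros(n_atoms))
    array.add_annotation("occupancy", np.ones(n_atoms))
    return array


_RESIDUE_POOL = ["ALA", "GLY", "SER", "LEU", "VAL"]
_ATOM_POOL = [("N", "N"), ("CA", "C"), ("C", "C"), ("O", "O")]


def random_structure(
    n_atoms: int = 100,
    n_models: int = 1,
    seed: int = 0,
    het_fraction: float = 0.1,
):
    """
    A random but well-formed structure: residues of four backbone atoms
    on two chains, trailing HETATM waters, coordinates on the 0.001 A
    grid (so text round trips are exact).  Returns an AtomArray for one
    model, an AtomArrayStack otherwise.
    """
    rng = np.random.default_rng(seed)
    n_het = int(n_atoms * het_fraction)
    n_polymer = n_atoms - n_het

    chain_id = []
    res_id = []
    res_name = []
    atom_name = []
    element = []
    hetero = []
    rid = 0
    while len(atom_name) < n_polymer:
        rid += 1
        rname = _RESIDUE_POOL[rng.integers(len(_RESIDUE_POOL))]
        for name, elem in _ATOM_POOL[: min(4, n_polymer - len(atom_name))]:
            chain_id.append("A" if rid % 2 else "B")
            res_id.append(rid)
            res_name.append(rname)
            atom_name.append(name)
            element.append(elem)
            hetero.append(False)
    # chains must be contiguous runs: sort polymer atoms by chain
    order = sorted(range(n_polymer), key=lambda i: (chain_id[i], res_id[i]))
    chain_id = [chain_id[i] for i in order]
    res_id = [res_id[i] for i in order]
    res_name = [res_name[i] for i in order]
    atom_name = [atom_name[i] for i in order]
    element = [element[i] for i in order]
    hetero = [hetero[i] for i in order]
    for w in range(n_het):
        chain_id.append("W")
        res_id.append(1000 + w)
        res_name.append("HOH")
        atom_name.append("O")
        element.append("O")
        hetero.append(True)

    def build(model_seed: int) -> AtomArray:
        model_rng = np.random.default_rng(model_seed)
        array = AtomArray(n_atoms)
        array.coord = np.round(
            model_rng.uniform(0.0, 99.0, size=(n_atoms, 3)), 3
        )
        array.chain_id = np.asarray(chain_id, dtype="U4")
        array.res_id = np.asarray(res_id)
        array.res_name = np.asarray(res_name, dtype="U5")
        array.atom_name = np.asarray(atom_name, dtype="U6")
        array.element = np.asarray(element, dtype="U2")
        array.hetero = np.asarray(hetero)
        array.add_annotation(
            "b_factor", np.round(model_rng.uniform(0, 99, n_atoms), 2)
        )
        array.add_annotation(
            "occupancy", np.round(model_rng.uniform(0.5, 1.0, n_atoms), 2)
        )
        return array

    models = [build(seed * 1000 + k) for k in range(n_models)]
    if n_models == 1:
        return models[0]
    # models of a stack share annotations; only coordinates differ
    template = models[0]
    return stack_models(
        [template] + [_with_coord(template, m.coord) for m in models[1:]]
    )


def _with_coord(template: AtomArray, coord: np.ndarray) -> AtomArray:
    new = template.copy()
    new.coord = coord.copy()
    return new


_DNA = "ACGT"
_PROTEIN = "ACDEFGHIKLMNPQRSTVWY"


def random_fasta(
    n_records: int = 2,
    length: int = 60,
    seed: int = 0,
    kind: str = "dna",
) -> str:
    """Deterministic random FASTA text."""
    rng = np.random.default_rng(seed)
    symbols = _DNA if kind == "dna" else _PROTEIN
    records = []
    for r in range(n_records):
        seq = "".join(
            symbols[rng.integers(len(symbols))] for _ in range(length)
        )
        records.append(FastaRecord(f"record_{r}", seq))
    return write_fasta(records)


@dataclass
class FixtureSpec:
    """What to generate: identical spec + seed gives identical output."""

    kind: str
    seed: int = 0
    length: int = 60
    n_records: int = 2
    n_residues: int = 20
    n_atoms: int = 100
    n_models: int = 1
    out_dir: str | None = None
    extra: dict = field(default_factory=dict)

    KINDS = (
        "random_sequence", "ideal_helix", "ideal_strand", "random_coil",
        "toy_structure_files",
    )


def toy_structure_files(
    out_dir: str, seed: int = 0, n_atoms: int = 60, n_models: int = 1
) -> dict[str, str]:
    """Write the same random structure as PDB, mmCIF and MMTF files."""
    structure = random_structure(n_atoms=n_atoms, n_models=n_models, seed=seed)
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    for ext in ("pdb", "cif", "mmtf"):
        path = os.path.join(out_dir, f"toy.{ext}")
        write_structure(structure, path)
        paths[ext] = path
    return paths


def generate_fixture(spec: FixtureSpec):
    """Dispatch on the fixture kind; see :class:`FixtureSpec`."""
    if spec.kind == "random_sequence":
        return random_fasta(
            n_records=spec.n_records,
            length=spec.length,
            seed=spec.seed,
            kind=spec.extra.get("sequence_kind", "dna"),
        )
    if spec.kind == "ideal_helix":
        return ideal_helix(spec.n_residues)
    if spec.kind == "ideal_strand":
        return ideal_strand(spec.n_residues)
    if spec.kind == "random_coil":
        return random_coil(spec.n_residues, seed=spec.seed)
    if spec.kind == "toy_structure_files":
        if spec.out_dir is None:
            raise ValueError("toy_structure_files requires out_dir")
        return toy_structure_files(
            spec.out_dir,
            seed=spec.seed,
            n_atoms=spec.n_atoms,
            n_models=spec.n_models,
        )
    raise ValueError(
        f"Unknown fixture kind {spec.kind!r}; choose from {FixtureSpec.KINDS}"
    )
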