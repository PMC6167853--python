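"""
Columnar atomic structure model and vectorized geometry.

A structure of ``n`` atoms is held as a *structure of arrays*: one NumPy
annotation array of length ``n`` per category (chain ID, residue ID,
residue name, atom name, element, hetero flag, ...) plus an ``(n, 3)``
coordinate array in Angstrom.  Multi-model structures (NMR ensembles,
trajectories) share one set of annotations and carry an ``(m, n, 3)``
coordinate array.  Both behave like ndarrays under indexing: integers,
slices, index arrays and boolean masks select atoms (and, for stacks, the
leading axis selects models), with annotations and coordinates staying
paired.

Geometric measurements (distance, bond angle, dihedral) accept atoms,
arrays, stacks or bare coordinate arrays and follow NumPy broadcasting
over leading dimensions.  Angles are radians; undefined results are quiet
NaN so vectorized calls never abort mid-array.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

__all__ = [
    "Atom",
    "AtomArray",
    "AtomArrayStack",
    "concatenate",
    "coord",
    "distance",
    "angle",
    "dihedral",
    "backbone_dihedrals",
]

# Default annotation categories and their dtypes; optional ones are added
# on demand (b_factor, occupancy, altloc_id, ...).
_MANDATORY_CATEGORIES = {
    "chain_id": "U4",
    "res_id": np.int64,
    "res_name": "U5",
    "atom_name": "U6",
    "element": "U2",
    "hetero": bool,
}
_OPTIONAL_DTYPES = {
    "b_factor": np.float64,
    "occupancy": np.float64,
    "altloc_id": "U1",
    "ins_code": "U1",
}


class Atom:
    """A single atom: one coordinate triple plus scalar annotations."""

    def __init__(self, coord, chain_id="A", res_id=1, res_name="UNK",
                 atom_name="", element="", hetero=False, **extra):
        coord = np.asarray(coord, dtype=np.float64)
        if coord.shape != (3,) or not np.all(np.isfinite(coord)):
            raise ValueError("Atom coordinates must be 3 finite numbers")
        self.coord = coord
        self.chain_id = chain_id
        self.res_id = int(res_id)
        self.res_name = res_name
        self.atom_name = atom_name
        self.element = element
        self.hetero = bool(hetero)
        for key, value in extra.items():
            setattr(self, key, value)
        self._annot_names = list(_MANDATORY_CATEGORIES) + list(extra)

    def annotations(self) -> dict:
        return {name: getattr(self, name) for name in self._annot_names}

    def __repr__(self) -> str:
        return (
            f"Atom({self.chain_id} {self.res_id} {self.res_name} "
            f"{self.atom_name} at {tuple(round(float(c), 3) for c in self.coord)})"
        )


class _AtomCollection:
    """Shared machinery of AtomArray and AtomArrayStack."""

    def __init__(self, n: int):
        self._n = int(n)
        self._annot: dict[str, np.ndarray] = {}
        for name, dtype in _MANDATORY_CATEGORIES.items():
            self._annot[name] = np.zeros(self._n, dtype=dtype)
        self._annot["res_id"][:] = 1
        self.coord: np.ndarray  # set by subclass

    # -- annotation access ------------------------------------------------

    @property
    def array_length(self) -> int:
        return self._n

    def __len__(self) -> int:
        raise NotImplementedError

    def add_annotation(self, name: str, array) -> None:
        array = np.asarray(array)
        if array.shape != (self._n,):
            raise ValueError(
                f"Annotation {name!r} has length {array.shape}, "
                f"expected ({self._n},)"
            )
        self._annot[name] = array.copy()

    def has_annotation(self, name: str) -> bool:
        return name in self._annot

    @property
    def annotation_names(self) -> list[str]:
        return list(self._annot)

    def __getattr__(self, name):
        annot = self.__dict__.get("_annot")
        if annot is not None and name in annot:
            return annot[name]
        raise AttributeError(name)

    def __setattr__(self, name, value):
        if name in _MANDATORY_CATEGORIES or name in self.__dict__.get("_annot", {}):
            value = np.asarray(value)
            if value.shape == ():
                value = np.full(self._n, value, dtype=self._annot[name].dtype)
            if value.shape != (self._n,):
                raise ValueError(
                    f"Annotation {name!r} must have length {self._n}"
                )
            self._annot[name] = value.astype(self._annot[name].dtype, copy=True)
        else:
            super().__setattr__(name, value)

    def _copy_annotations_from(self, other: "_AtomCollection", selector=None):
        for name, arr in other._annot.items():
            self._annot[name] = (
                arr.copy() if selector is None else np.asarray(arr[selector])
            )

    def equal_annotations(self, other: "_AtomCollection") -> bool:
        if set(self._annot) != set(other._annot):
            return False
        return all(
            np.array_equal(self._annot[k], other._annot[k]) for k in self._annot
        )

    def _check_atom_selector(self, selector):
        selector = np.asarray(selector) if not isinstance(
            selector, (int, np.integer, slice)
        ) else selector
        if isinstance(selector, np.ndarray) and selector.dtype == bool:
            if selector.shape != (self._n,):
                raise IndexError(
                    f"Boolean mask of length {selector.shape} for "
                    f"{self._n} atoms"
                )
        return selector


class AtomArray(_AtomCollection):
    """
    A single-model structure of ``n`` atoms.

    Indexing with an integer gives an :class:`Atom`; any other ndarray
    style selector gives a new :class:`AtomArray`.
    """

    def __init__(self, n: int):
        super().__init__(n)
        self.coord = np.zeros((self._n, 3), dtype=np.float64)

    def __len__(self) -> int:
        return self._n

    def __getitem__(self, selector):
        selector = self._check_atom_selector(selector)
        if isinstance(selector, (int, np.integer)):
            if not -self._n <= selector < self._n:
                raise IndexError(
                    f"Atom index {selector} out of range for {self._n} atoms"
                )
            extras = {
                k: self._annot[k][selector]
                for k in self._annot
                if k not in _MANDATORY_CATEGORIES
            }
            return Atom(
                self.coord[selector],
                **{k: self._annot[k][selector] for k in _MANDATORY_CATEGORIES},
                **extras,
            )
        sub_coord = self.coord[selector]
        new = AtomArray(len(sub_coord))
        new.coord = sub_coord.copy()
        new._copy_annotations_from(self, selector)
        return new

    def __eq__(self, other) -> bool:
        if not isinstance(other, AtomArray):
            return NotImplemented
        return self.equal_annotations(other) and np.allclose(
            self.coord, other.coord, atol=0, rtol=0
        )

    def copy(self) -> "AtomArray":
        new = AtomArray(self._n)
        new.coord = self.coord.copy()
        new._copy_annotations_from(self)
        return new

    def __add__(self, other: "AtomArray") -> "AtomArray":
        return concatenate([self, other])

    def __repr__(self) -> str:
        return f"AtomArray(n={self._n})"


class AtomArrayStack(_AtomCollection):
    """
    An ``m``-model structure: shared annotations, ``(m, n, 3)`` coords.

    The first index axis selects models, the second selects atoms.
    """

    def __init__(self, m: int, n: int):
        super().__init__(n)
        self._m = int(m)
        self.coord = np.zeros((self._m, self._n, 3), dtype=np.float64)

    @property
    def stack_depth(self) -> int:
        return self._m

    def __len__(self) -> int:
        return self._m

    def get_model(self, index: int) -> AtomArray:
        if not -self._m <= index < self._m:
            raise IndexError(f"Model index {index} out of range for {self._m}")
        model = AtomArray(self._n)
        model.coord = self.coord[index].copy()
        model._copy_annotations_from(self)
        return model

    def __getitem__(self, selector):
        if isinstance(selector, tuple):
            model_sel, atom_sel = selector
        else:
            model_sel, atom_sel = selector, slice(None)
        atom_sel = self._check_atom_selector(atom_sel)
        if isinstance(model_sel, (int, np.integer)):
            return self.get_model(model_sel)[atom_sel]
        sub_coord = self.coord[model_sel][:, atom_sel]
        new = AtomArrayStack(sub_coord.shape[0], sub_coord.shape[1])
        new.coord = sub_coord.copy()
        new._copy_annotations_from(self, atom_sel)
        return new

    def __eq__(self, other) -> bool:
        if not isinstance(other, AtomArrayStack):
            return NotImplemented
        return self.equal_annotations(other) and np.array_equal(
            self.coord, other.coord
        )

    def copy(self) -> "AtomArrayStack":
        new = AtomArrayStack(self._m, self._n)
        new.coord = self.coord.copy()
        new._copy_annotations_from(self)
        return new

    def __repr__(self) -> str:
        return f"AtomArrayStack(m={self._m}, n={self._n})"


def from_atoms(atoms: Iterable[Atom]) -> AtomArray:
    """Build an AtomArray from individual atoms."""
    atoms = list(atoms)
    array = AtomArray(len(atoms))
    for i, atom in enumerate(atoms):
        array.coord[i] = atom.coord
        for name, value in atom.annotations().items():
            if name not in array.annotation_names:
                dtype = _OPTIONAL_DTYPES.get(name, np.asarray(value).dtype)
                array.add_annotation(name, np.zeros(len(atoms), dtype=dtype))
            array._annot[name][i] = value
    return array


def stack_models(models: Iterable[AtomArray]) -> AtomArrayStack:
    """Stack equal AtomArrays (same annotations) into an AtomArrayStack."""
    models = list(models)
    if not models:
        raise ValueError("Cannot stack zero models")
    first = models[0]
    for model in models[1:]:
        if model.array_length != first.array_length:
            raise ValueError("Models differ in atom count")
        if not model.equal_annotations(first):
            raise ValueError("Models differ in annotations")
    stack = AtomArrayStack(len(models), first.array_length)
    stack.coord = np.stack([m.coord for m in models])
    stack._copy_annotations_from(first)
    return stack


def concatenate(arrays) -> AtomArray:
    """Concatenate AtomArrays; atom order is preserved."""
    arrays = list(arrays)
    total = sum(a.array_length for a in arrays)
    out = AtomArray(total)
    out.coord = np.concatenate([a.coord for a in arrays])
    names = set()
    for a in arrays:
        names.update(a.annotation_names)
    for name in names:
        parts = []
        for a in arrays:
            if a.has_annotation(name):
                parts.append(a._annot[name])
            else:
                dtype = _OPTIONAL_DTYPES.get(name, float)
                parts.append(np.zeros(a.array_length, dtype=dtype))
        out._annot[name] = np.concatenate(parts)
    return out


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def coord(item) -> np.ndarray:
    """Coordinate array of an Atom / AtomArray / AtomArrayStack / ndarray."""
    if isinstance(item, (Atom, AtomArray, AtomArrayStack)):
        return item.coord
    return np.asarray(item, dtype=np.float64)


def distance(a, b):
    """Euclidean distance(s), broadcasting over leading dimensions."""
    diff = coord(a) - coord(b)
    return np.sqrt(np.sum(diff * diff, axis=-1))


def angle(a, b, c):
    """Bond angle at vertex ``b`` in radians, in [0, pi]."""
    v1 = coord(a) - coord(b)
    v2 = coord(c) - coord(b)
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosine = np.sum(v1 * v2, axis=-1) / (n1 * n2)
        norm_zero = (n1 == 0) | (n2 == 0)
        cosine = np.where(norm_zero, np.nan, cosine)
        return np.arccos(np.clip(cosine, -1.0, 1.0))


def dihedral(a, b, c, d):
    """
    Signed torsion angle over the bond b-c in (-pi, pi], IUPAC sign
    convention: 0 for the cis (eclipsed) arrangement, positive clockwise
    looking from b towards c.
    """
    b1 = coord(b) - coord(a)
    b2 = coord(c) - coord(b)
    b3 = coord(d) - coord(c)
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm2 = np.linalg.norm(b2, axis=-1)
        x = np.sum(n1 * n2, axis=-1)
        y = np.sum(np.cross(n1, n2) * b2, axis=-1) / np.where(
            norm2 == 0, np.nan, norm2
        )
        degenerate = (
            (np.linalg.norm(n1, axis=-1) == 0)
            | (np.linalg.norm(n2, axis=-1) == 0)
        )
        result = np.arctan2(y, x)
        # half-open range (-pi, pi]: fold the -pi branch onto +pi
        result = np.where(result == -np.pi, np.pi, result)
        return np.where(degenerate, np.nan, result)


def _residue_backbone(array: AtomArray, chain_id: str | None):
    """Per-residue (N, CA, C) coordinates in file order; NaN if missing."""
    if chain_id is not None:
        array = array[array.chain_id == chain_id]
    # residues in file order, identified by (chain_id, res_id)
    seen: dict[tuple, int] = {}
    order: list[tuple] = []
    for cid, rid in zip(array.chain_id, array.res_id):
        key = (cid, rid)
        if key not in seen:
            seen[key] = len(order)
            order.append(key)
    n_res = len(order)
    backbone = np.full((n_res, 3, 3), np.nan)
    atom_slot = {"N": 0, "CA": 1, "C": 2}
    for i in range(array.array_length):
        slot = atom_slot.get(array.atom_name[i])
        if slot is None:
            continue
        res_index = seen[(array.chain_id[i], array.res_id[i])]
        if np.isnan(backbone[res_index, slot]).all():
            backbone[res_index, slot] = array.coord[i]
    return order, backbone


def backbone_dihedrals(array: AtomArray, chain_id: str | None = None):
    """
    Backbone torsion angles (phi, psi, omega) per residue of a chain.

    phi(i)   = C(i-1) - N(i) - CA(i) - C(i)
    psi(i)   = N(i) - CA(i) - C(i) - N(i+1)
    omega(i) = CA(i) - C(i) - N(i+1) - CA(i+1)

    Angles undefined at chain termini or due to missing backbone atoms
    are NaN; the call never raises for incomplete residues.
    Returns (phi, psi, omega) arrays of length n_residues (radians).
    """
    _, bb = _residue_backbone(array, chain_id)
    n_res = len(bb)
    phi = np.full(n_res, np.nan)
    psi = np.full(n_res, np.nan)
    omega = np.full(n_res, np.nan)
    if n_res < 2:
        return phi, psi, omega
    N, CA, C = bb[:, 0], bb[:, 1], bb[:, 2]
    with np.errstate(invalid="ignore"):
        phi[1:] = dihedral(C[:-1], N[1:], CA[1:], C[1:])
        psi[:-1] = dihedral(N[:-1], CA[:-1], C[:-1], N[1:])
        omega[:-1] = dihedral(CA[:-1], C[:-1], N[1:], CA[1:])
    return phi, psi, omega
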