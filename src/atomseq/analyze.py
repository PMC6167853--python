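"""
Structure analysis algorithms.

* Least-squares rigid superimposition of paired point sets (Kabsch), with
  proper-rotation correction so no reflection is ever returned.
* RMSD between coordinate sets and per-atom RMSF across models.
* Atom-wise solvent-accessible surface area by the Shrake-Rupley point
  counting method, with either ProtOr-style united-atom group radii
  (suited to crystal structures lacking hydrogens) or per-element van der
  Waals radii.
* CA-geometry secondary-structure assignment into helix/strand/coil
  following the published P-SEA criteria.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .atoms import AtomArray, AtomArrayStack, angle, coord, dihedral

__all__ = [
    "RigidTransform",
    "superimpose",
    "rmsd",
    "rmsf",
    "SasaParameters",
    "sasa",
    "annotate_sse",
    "sphere_points",
]


# ---------------------------------------------------------------------------
# Superimposition / RMSD / RMSF
# ---------------------------------------------------------------------------

@dataclass
class RigidTransform:
    """
    A proper rigid motion decomposed as: translate by
    ``center_translation``, rotate by ``rotation``, translate by
    ``final_translation``.
    """

    rotation: np.ndarray
    center_translation: np.ndarray
    final_translation: np.ndarray

    def apply(self, item):
        """Apply to coordinates (or to an AtomArray/Stack, returning a copy)."""
        if isinstance(item, (AtomArray, AtomArrayStack)):
            new = item.copy()
            new.coord = self.apply(item.coord)
            return new
        coords = np.asarray(item, dtype=np.float64)
        return (coords + self.center_translation) @ self.rotation.T + (
            self.final_translation
        )


def _kabsch_rotation(fixed_centered: np.ndarray, mobile_centered: np.ndarray):
    """Optimal proper rotation mapping mobile onto fixed (both centered)."""
    cov = mobile_centered.T @ fixed_centered
    u, _, vt = np.linalg.svd(cov)
    # Reflection correction: flip the smallest singular direction if the
    # resulting determinant would be negative.
    d = np.sign(np.linalg.det(vt.T @ u.T))
    flip = np.diag([1.0, 1.0, d])
    return vt.T @ flip @ u.T


def superimpose(fixed, mobile):
    """
    Superimpose `mobile` onto `fixed` minimizing RMSD over all proper
    rigid transforms (Kabsch algorithm).

    Both operands need the same atom count, at least 3 atoms.  If
    `mobile` is an AtomArrayStack each model is superimposed onto `fixed`
    independently.  Returns ``(superimposed_mobile, transform)``; for a
    stack the transform is a list, one per model.
    """
    fixed_coord = coord(fixed)
    if isinstance(mobile, AtomArrayStack) or (
        not isinstance(mobile, AtomArray) and coord(mobile).ndim == 3
    ):
        mobile_coord = coord(mobile)
        results = [
            _superimpose_single(fixed_coord, mobile_coord[i])
            for i in range(mobile_coord.shape[0])
        ]
        new_coord = np.stack([r[0] for r in results])
        transforms = [r[1] for r in results]
        if isinstance(mobile, AtomArrayStack):
            out = mobile.copy()
            out.coord = new_coord
            return out, transforms
        return new_coord, transforms
    mobile_coord = coord(mobile)
    new_coord, transform = _superimpose_single(fixed_coord, mobile_coord)
    if isinstance(mobile, AtomArray):
        out = mobile.copy()
        out.coord = new_coord
        return out, transform
    return new_coord, transform


def _superimpose_single(fixed_coord, mobile_coord):
    if fixed_coord.shape != mobile_coord.shape:
        raise ValueError(
            f"Atom count mismatch: {fixed_coord.shape[0]} vs "
            f"{mobile_coord.shape[0]}"
        )
    if fixed_coord.shape[0] < 3:
        raise ValueError("Superimposition requires at least 3 atoms")
    centroid_fixed = fixed_coord.mean(axis=0)
    centroid_mobile = mobile_coord.mean(axis=0)
    rotation = _kabsch_rotation(
        fixed_coord - centroid_fixed, mobile_coord - centroid_mobile
    )
    transform = RigidTransform(
        rotation=rotation,
        center_translation=-centroid_mobile,
        final_translation=centroid_fixed,
    )
    return transform.apply(mobile_coord), transform


def rmsd(reference, subject):
    """
    Root-mean-square deviation between coordinate sets (no
    superimposition is performed).  A stack subject yields one value per
    model.
    """
    ref = coord(reference)
    sub = coord(subject)
    if ref.shape[-2] != sub.shape[-2]:
        raise ValueError(
            f"Atom count mismatch: {ref.shape[-2]} vs {sub.shape[-2]}"
        )
    diff = sub - ref
    return np.sqrt(np.mean(np.sum(diff * diff, axis=-1), axis=-1))


def rmsf(stack, reference=None):
    """
    Per-atom root-mean-square fluctuation over the models of a stack,
    relative to `reference` (default: the coordinate mean over models).
    """
    coords = coord(stack)
    if coords.ndim != 3:
        raise ValueError("RMSF requires a multi-model coordinate set")
    if coords.shape[0] < 2:
        raise ValueError("RMSF requires at least 2 models")
    if reference is None:
        reference = coords.mean(axis=0)
    else:
        reference = coord(reference)
    diff = coords - reference
    return np.sqrt(np.mean(np.sum(diff * diff, axis=-1), axis=0))


# ---------------------------------------------------------------------------
# Solvent-accessible surface area (Shrake-Rupley)
# ---------------------------------------------------------------------------

def sphere_points(count: int) -> np.ndarray:
    """
    `count` quasi-uniform points on the unit sphere from a golden-section
    (Fibonacci) spiral lattice; fully deterministic.
    """
    if count < 1:
        raise ValueError("point count must be >= 1")
    indices = np.arange(count, dtype=np.float64) + 0.5
    phi = np.arccos(1.0 - 2.0 * indices / count)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * indices
    return np.column_stack(
        (np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi))
    )


# Per-element van der Waals radii (Angstrom) for structures that include
# hydrogens.
_ELEMENT_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}

# ProtOr united-atom group radii (Angstrom): heavy atoms absorb their
# bonded hydrogens, suited to X-ray structures without hydrogens.
_PROTOR = {
    "C3H0": 1.61,  # carbonyl / carboxyl / aromatic junction carbon
    "C3H1": 1.76,  # aromatic CH
    "C4": 1.88,    # aliphatic carbon (CH, CH2, CH3)
    "N": 1.64,     # all nitrogen groups
    "O1": 1.42,    # carbonyl / carboxylate oxygen
    "O2H1": 1.46,  # hydroxyl / water oxygen
    "S": 1.77,     # thiol / thioether sulfur
}

# Side-chain carbons that are trigonal without hydrogen (C3H0)
_TRIGONAL_C = {
    ("ASP", "CG"), ("ASN", "CG"), ("GLU", "CD"), ("GLN", "CD"),
    ("PHE", "CG"), ("TYR", "CG"), ("TYR", "CZ"), ("TRP", "CG"),
    ("TRP", "CD2"), ("TRP", "CE2"), ("HIS", "CG"), ("ARG", "CZ"),
}
# Aromatic CH carbons (C3H1)
_AROMATIC_CH = {
    ("PHE", "CD1"), ("PHE", "CD2"), ("PHE", "CE1"), ("PHE", "CE2"),
    ("PHE", "CZ"),
    ("TYR", "CD1"), ("TYR", "CD2"), ("TYR", "CE1"), ("TYR", "CE2"),
    ("TRP", "CD1"), ("TRP", "CE3"), ("TRP", "CZ2"), ("TRP", "CZ3"),
    ("TRP", "CH2"),
    ("HIS", "CD2"), ("HIS", "CE1"),
}
# Hydroxyl-type oxygens
_HYDROXYL_O = {"OG", "OG1", "OH", "OXT"}


def _protor_radius(res_name: str, atom_name: str, element: str) -> float:
    element = element.upper()
    if element == "N":
        return _PROTOR["N"]
    if element == "S":
        return _PROTOR["S"]
    if element == "O":
        if res_name in ("HOH", "WAT") or atom_name in _HYDROXYL_O:
            return _PROTOR["O2H1"]
        return _PROTOR["O1"]
    if element == "C":
        key = (res_name, atom_name)
        if atom_name == "C" or key in _TRIGONAL_C:
            return _PROTOR["C3H0"]
        if key in _AROMATIC_CH:
            return _PROTOR["C3H1"]
        return _PROTOR["C4"]
    raise ValueError(
        f"No ProtOr group radius for atom {atom_name!r} ({element!r}) in "
        f"residue {res_name!r}"
    )


@dataclass
class SasaParameters:
    """
    Shrake-Rupley settings: probe (solvent) radius in Angstrom, number of
    test points per atomic sphere and the radius set — ``"protor"``
    united-atom group radii (default, for hydrogen-less structures) or
    ``"element"`` van der Waals radii.
    """

    probe_radius: float = 1.4
    point_count: int = 1000
    radius_set: str = "protor"

    def __post_init__(self):
        if self.point_count < 1:
            raise ValueError("point_count must be >= 1")
        if self.probe_radius < 0:
            raise ValueError("probe_radius must be non-negative")
        if self.radius_set not in ("protor", "element"):
            raise ValueError("radius_set must be 'protor' or 'element'")


def atom_radii(array: AtomArray, radius_set: str = "protor") -> np.ndarray:
    """Per-atom radii under the chosen radius set."""
    radii = np.empty(array.array_length)
    for i in range(array.array_length):
        element = str(array.element[i]).upper()
        if radius_set == "element":
            try:
                radii[i] = _ELEMENT_RADII[element]
            except KeyError:
                raise ValueError(
                    f"No van der Waals radius for element {element!r} "
                    f"(atom {array.atom_name[i]!r})"
                ) from None
        else:
            if element == "H":
                raise ValueError(
                    "ProtOr united-atom radii do not apply to hydrogen "
                    f"atoms (atom {array.atom_name[i]!r}); use the "
                    "'element' radius set"
                )
            radii[i] = _protor_radius(
                str(array.res_name[i]), str(array.atom_name[i]), element
            )
    return radii


def sasa(
    array: AtomArray,
    parameters: SasaParameters | None = None,
    atom_mask: np.ndarray | None = None,
) -> np.ndarray:
    """
    Per-atom solvent-accessible surface area (Angstrom^2) by Shrake-Rupley
    point counting: each atom's sphere of radius ``r_atom + probe``
    carries quasi-uniform test points, and a point is buried if it lies
    inside any neighbor's probe-inflated sphere.

    `atom_mask` (boolean, length n) excludes atoms from the calculation
    entirely — they neither receive an area (NaN) nor occlude others;
    typically used to drop solvent or het atoms.
    """
    if parameters is None:
        parameters = SasaParameters()
    n = array.array_length
    result = np.full(n, np.nan)
    if atom_mask is not None:
        atom_mask = np.asarray(atom_mask, dtype=bool)
        if atom_mask.shape != (n,):
            raise ValueError("atom_mask must have one entry per atom")
        sub = array[atom_mask]
        indices = np.where(atom_mask)[0]
    else:
        sub = array
        indices = np.arange(n)
    if sub.array_length == 0:
        return result
    radii = atom_radii(sub, parameters.radius_set) + parameters.probe_radius
    coords = sub.coord
    unit = sphere_points(parameters.point_count)
    tree = cKDTree(coords)
    max_radius = radii.max()
    areas = np.empty(sub.array_length)
    for i in range(sub.array_length):
        points = coords[i] + radii[i] * unit
        neighbors = tree.query_ball_point(coords[i], radii[i] + max_radius)
        accessible = np.ones(len(points), dtype=bool)
        for j in neighbors:
            if j == i:
                continue
            if not accessible.any():
                break
            d = np.linalg.norm(coords[j] - coords[i])
            if d >= radii[i] + radii[j]:
                continue
            dist2 = np.sum((points - coords[j]) ** 2, axis=1)
            accessible &= dist2 >= radii[j] ** 2
        fraction = accessible.sum() / len(points)
        areas[i] = fraction * 4.0 * np.pi * radii[i] ** 2
    result[indices] = areas
    return result


# ---------------------------------------------------------------------------
# Secondary structure assignment (P-SEA criteria)
# ---------------------------------------------------------------------------
# Published P-SEA thresholds over CA-only geometry.  d_k(i) is the
# CA(i)..CA(i+k) distance centered per the original index convention,
# r the bond-like angle at three consecutive CA, a the torsion over four.
_R_HELIX = (np.deg2rad(89 - 12), np.deg2rad(89 + 12))   # angle 89 +/- 12 deg
_A_HELIX = (np.deg2rad(50 - 20), np.deg2rad(50 + 20))   # torsion 50 +/- 20 deg
_D3_HELIX = (5.3 - 0.5, 5.3 + 0.5)                      # d(i,i+3) 5.3 +/- 0.5 A
_D4_HELIX = (6.4 - 0.6, 6.4 + 0.6)                      # d(i,i+4) 6.4 +/- 0.6 A
_R_STRAND = (np.deg2rad(124 - 14), np.deg2rad(124 + 14))  # angle 124 +/- 14 deg
# torsion -170 +/- 45 deg, split across the periodic boundary
_A_STRAND = (
    np.deg2rad(-180.0), np.deg2rad(-125.0), np.deg2rad(145.0), np.deg2rad(180.0)
)
_D2_STRAND = (6.7 - 0.6, 6.7 + 0.6)                     # d(i,i+2) 6.7 +/- 0.6 A
_D3_STRAND = (9.9 - 0.9, 9.9 + 0.9)                     # d(i,i+3) 9.9 +/- 0.9 A
_D4_STRAND = (12.4 - 1.1, 12.4 + 1.1)                   # d(i,i+4) 12.4 +/- 1.1 A
_MIN_HELIX = 5   # minimum consecutive residues meeting the strict criteria
_MIN_STRAND = 3


def _in(values, lo, hi):
    with np.errstate(invalid="ignore"):
        return (values >= lo) & (values <= hi)


def _runs_at_least(mask: np.ndarray, min_length: int) -> np.ndarray:
    """Keep only True runs of at least `min_length`."""
    out = np.zeros_like(mask)
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i >= min_length:
                out[i:j] = True
            i = j
        else:
            i += 1
    return out


def _extend_regions(core: np.ndarray, relaxed: np.ndarray) -> np.ndarray:
    """Grow each True region of `core` outward while `relaxed` holds."""
    out = core.copy()
    n = len(core)
    for i in range(n - 1, -1, -1):
        if not out[i] and i + 1 < n and out[i + 1] and relaxed[i]:
            out[i] = True
    for i in range(n):
        if not out[i] and i - 1 >= 0 and out[i - 1] and relaxed[i]:
            out[i] = True
    return out


def _chain_ca_coords(array: AtomArray, chain_id: str | None):
    if chain_id is not None:
        array = array[array.chain_id == chain_id]
    ca = array[(array.atom_name == "CA") & (~array.hetero)]
    # one CA per residue, file order
    seen = set()
    keep = []
    for i in range(ca.array_length):
        key = (ca.chain_id[i], ca.res_id[i])
        if key not in seen:
            seen.add(key)
            keep.append(i)
    ca = ca[np.asarray(keep, dtype=np.intp)] if keep else ca[np.zeros(0, bool)]
    return ca.coord


def annotate_sse(array: AtomArray, chain_id: str | None = None) -> np.ndarray:
    """
    Per-residue secondary structure from CA geometry alone, following the
    published P-SEA criteria: ``'a'`` helix, ``'b'`` strand, ``'c'``
    coil.  Chains with fewer than 5 CA atoms are entirely coil.
    Residues whose measurement windows extend past the chain ends
    default to coil.
    """
    ca = _chain_ca_coords(array, chain_id)
    n = len(ca)
    sse = np.full(n, "c", dtype="U1")
    if n < 5:
        return sse

    d2 = np.full(n, np.nan)
    d3 = np.full(n, np.nan)
    d4 = np.full(n, np.nan)
    r = np.full(n, np.nan)
    a = np.full(n, np.nan)
    # index convention: values at i describe the window starting at i-1
    d2[1 : n - 1] = np.linalg.norm(ca[2:] - ca[: n - 2], axis=1)
    d3[1 : n - 2] = np.linalg.norm(ca[3:] - ca[: n - 3], axis=1)
    d4[1 : n - 3] = np.linalg.norm(ca[4:] - ca[: n - 4], axis=1)
    r[1 : n - 1] = angle(ca[: n - 2], ca[1 : n - 1], ca[2:])
    a[1 : n - 2] = dihedral(ca[: n - 3], ca[1 : n - 2], ca[2 : n - 1], ca[3:])

    relaxed_helix = _in(d3, *_D3_HELIX) | _in(r, *_R_HELIX)
    strict_helix = (_in(d3, *_D3_HELIX) & _in(d4, *_D4_HELIX)) | (
        _in(r, *_R_HELIX) & _in(a, *_A_HELIX)
    )
    relaxed_strand = _in(d3, *_D3_STRAND)
    strict_strand = (
        _in(d2, *_D2_STRAND) & _in(d3, *_D3_STRAND) & _in(d4, *_D4_STRAND)
    ) | (
        _in(r, *_R_STRAND)
        & (
            _in(a, _A_STRAND[0], _A_STRAND[1])
            | _in(a, _A_STRAND[2], _A_STRAND[3])
        )
    )

    helix = _extend_regions(_runs_at_least(strict_helix, _MIN_HELIX), relaxed_helix)
    strand = _extend_regions(
        _runs_at_least(strict_strand, _MIN_STRAND), relaxed_strand
    )
    sse[strand] = "b"
    sse[helix] = "a"
    return sse
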