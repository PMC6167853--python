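"""
Structure file I/O: PDB (coordinate records), PDBx/mmCIF and MMTF.

The PDB reader parses only ATOM/HETATM records (plus MODEL/ENDMDL for
multi-model files) using the fixed-column layout; everything else is
ignored.  The mmCIF side uses a generic category model: the file is
tokenized into named categories of equal-length columns
(:class:`CifCategoryTable`), from which the ``atom_site`` category is
converted to and from atom arrays.  MMTF encode/decode lives in
:mod:`atomseq.mmtf` and is re-exported here.

Coordinates are held internally as unquantized floats; quantization (3
decimals for PDB/mmCIF text, divisor 1000 for MMTF) happens only at
serialization, so any round trip preserves coordinates to 0.001 A.
"""

from __future__ import annotations

import os

import numpy as np

from .atoms import AtomArray, AtomArrayStack, stack_models
from .mmtf import decode_mmtf, encode_mmtf

__all__ = [
    "read_pdb",
    "write_pdb",
    "CifCategoryTable",
    "read_mmcif",
    "write_mmcif_text",
    "mmcif_to_atoms",
    "atoms_to_mmcif",
    "read_structure",
    "write_structure",
    "decode_mmtf",
    "encode_mmtf",
]


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

_TWO_LETTER_ELEMENTS = {
    "FE", "ZN", "MG", "MN", "CU", "NA", "CL", "BR", "SE", "CA", "CO", "NI",
    "CD", "HG", "PB", "AU", "AG", "PT", "AL", "SI", "AS", "MO", "RB", "SR",
    "CS", "BA", "LI",
}


def _infer_element(name_field: str) -> str:
    """Element from the 4-character atom-name field (columns 13-16)."""
    if len(name_field) >= 2 and name_field[0] != " ":
        candidate = name_field[:2].strip().upper()
        if candidate in _TWO_LETTER_ELEMENTS:
            return candidate
    for ch in name_field:
        if ch.isalpha():
            return ch.upper()
    return ""


def _parse_pdb_atom_line(line: str, lineno: int):
    if len(line) < 54:
        raise ValueError(
            f"Line {lineno}: coordinate record shorter than 54 columns"
        )
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError:
        raise ValueError(
            f"Line {lineno}: unparseable coordinate field"
        ) from None
    name_field = line[12:16]
    element = line[76:78].strip().upper() if len(line) >= 78 else ""
    if not element:
        element = _infer_element(name_field)
    try:
        res_id = int(line[22:26])
    except ValueError:
        raise ValueError(f"Line {lineno}: unparseable residue number") from None
    occupancy = 1.0
    b_factor = 0.0
    if len(line) >= 60 and line[54:60].strip():
        occupancy = float(line[54:60])
    if len(line) >= 66 and line[60:66].strip():
        b_factor = float(line[60:66])
    return {
        "hetero": line.startswith("HETATM"),
        "atom_name": name_field.strip(),
        "altloc": line[16].strip(),
        "res_name": line[17:20].strip(),
        "chain_id": line[21].strip(),
        "res_id": res_id,
        "ins_code": line[26].strip() if len(line) > 26 else "",
        "coord": (x, y, z),
        "occupancy": occupancy,
        "b_factor": b_factor,
        "element": element,
    }


def _atoms_to_array(records: list[dict], keep_altlocs: bool) -> AtomArray:
    if not keep_altlocs:
        seen = set()
        filtered = []
        for rec in records:
            key = (
                rec["chain_id"], rec["res_id"], rec["ins_code"],
                rec["res_name"], rec["atom_name"],
            )
            if rec["altloc"] and key in seen:
                continue
            seen.add(key)
            filtered.append(rec)
        records = filtered
    array = AtomArray(len(records))
    array.coord = np.asarray([r["coord"] for r in records]).reshape(-1, 3)
    array.chain_id = np.asarray([r["chain_id"] for r in records], dtype="U4")
    array.res_id = np.asarray([r["res_id"] for r in records], dtype=np.int64)
    array.res_name = np.asarray([r["res_name"] for r in records], dtype="U5")
    array.atom_name = np.asarray([r["atom_name"] for r in records], dtype="U6")
    array.element = np.asarray([r["element"] for r in records], dtype="U2")
    array.hetero = np.asarray([r["hetero"] for r in records])
    array.add_annotation(
        "b_factor", np.asarray([r["b_factor"] for r in records])
    )
    array.add_annotation(
        "occupancy", np.asarray([r["occupancy"] for r in records])
    )
    if keep_altlocs:
        array.add_annotation(
            "altloc_id", np.asarray([r["altloc"] for r in records], dtype="U1")
        )
    return array


def read_pdb(text: str, keep_altlocs: bool = False):
    """
    Parse PDB text into an AtomArray (0 or 1 MODEL blocks) or an
    AtomArrayStack (2+ models; all must agree in atom count and
    annotations).  Only ATOM and HETATM records are read; the hetero
    flag is set exactly for HETATM.  By default only the first-listed
    altloc of each atom is kept.
    """
    models: list[list[dict]] = []
    current: list[dict] = []
    in_model = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        record = line[:6].strip()
        if record == "MODEL":
            if current and not in_model:
                models.append(current)
            current = []
            in_model = True
        elif record == "ENDMDL":
            models.append(current)
            current = []
            in_model = False
        elif record in ("ATOM", "HETATM"):
            current.append(_parse_pdb_atom_line(line, lineno))
    if current or not models:
        models.append(current)
    arrays = [_atoms_to_array(m, keep_altlocs) for m in models]
    if len(arrays) == 1:
        return arrays[0]
    counts = {a.array_length for a in arrays}
    if len(counts) != 1:
        raise ValueError(
            f"Models differ in atom count: {sorted(counts)}"
        )
    return stack_models(arrays)


def _format_atom_name(name: str, element: str) -> str:
    """PDB atom-name column alignment: 1-letter elements start at col 14."""
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1 and not name[:1].isdigit():
        return f" {name:<3}"
    return f"{name:<4}"


def _write_pdb_atom_line(array: AtomArray, i: int, serial: int) -> str:
    record = "HETATM" if array.hetero[i] else "ATOM  "
    chain = str(array.chain_id[i])
    if len(chain) > 1:
        raise ValueError(
            f"Chain id {chain!r} of atom {i} exceeds the 1-character "
            "PDB field"
        )
    res_id = int(array.res_id[i])
    if not -999 <= res_id <= 9999:
        raise ValueError(
            f"Residue number {res_id} of atom {i} exceeds the 4-digit "
            "PDB field"
        )
    if serial > 99999:
        raise ValueError(f"Atom serial {serial} exceeds the 5-digit PDB field")
    name = _format_atom_name(str(array.atom_name[i]), str(array.element[i]))
    res_name = str(array.res_name[i])
    if len(res_name) > 3:
        raise ValueError(
            f"Residue name {res_name!r} of atom {i} exceeds the "
            "3-character PDB field"
        )
    b_factor = (
        float(array.b_factor[i]) if array.has_annotation("b_factor") else 0.0
    )
    occupancy = (
        float(array.occupancy[i]) if array.has_annotation("occupancy") else 1.0
    )
    x, y, z = array.coord[i]
    for label, value in (("x", x), ("y", y), ("z", z)):
        if not -999.999 <= value <= 9999.999:
            raise ValueError(
                f"Coordinate {label}={value:.3f} of atom {i} exceeds the "
                "PDB field width"
            )
    return (
        f"{record}{serial:>5d} {name}{'':1}{res_name:>3} {chain:1}"
        f"{res_id:>4d}{'':1}   {x:8.3f}{y:8.3f}{z:8.3f}"
        f"{occupancy:6.2f}{b_factor:6.2f}          "
        f"{str(array.element[i]):>2}"
    )


def write_pdb(structure) -> str:
    """
    Serialize an AtomArray or AtomArrayStack to PDB text (one
    MODEL/ENDMDL block per model for stacks).  Annotations must fit the
    fixed field widths; offenders raise with the atom and field named.
    """
    if isinstance(structure, AtomArrayStack):
        lines = []
        for k in range(structure.stack_depth):
            lines.append(f"MODEL     {k + 1:>4d}")
            model = structure.get_model(k)
            lines.extend(
                _write_pdb_atom_line(model, i, i + 1)
                for i in range(model.array_length)
            )
            lines.append("ENDMDL")
        lines.append("END")
        return "\n".join(lines) + "\n"
    lines = [
        _write_pdb_atom_line(structure, i, i + 1)
        for i in range(structure.array_length)
    ]
    lines.append("END")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# PDBx/mmCIF
# ---------------------------------------------------------------------------

class CifCategoryTable:
    """A named category: columns of equal length (length 1 for key-value)."""

    def __init__(self, name: str):
        self.name = name
        self.columns: dict[str, list[str]] = {}

    def __getitem__(self, item: str) -> list[str]:
        return self.columns[item]

    def __contains__(self, item: str) -> bool:
        return item in self.columns

    @property
    def row_count(self) -> int:
        if not self.columns:
            return 0
        return len(next(iter(self.columns.values())))

    def add_column(self, item: str, values: list[str]) -> None:
        if item in self.columns:
            raise ValueError(
                f"Duplicate item {item!r} in category {self.name!r}"
            )
        if self.columns and len(values) != self.row_count:
            raise ValueError(
                f"Column {item!r} length {len(values)} does not match "
                f"category {self.name!r} row count {self.row_count}"
            )
        self.columns[item] = values


def _tokenize_cif(text: str):
    """Yield (token, is_value) pairs; handles quotes and ; blocks."""
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith(";"):
            block = [line[1:]]
            i += 1
            while i < len(lines) and not lines[i].startswith(";"):
                block.append(lines[i])
                i += 1
            if i >= len(lines):
                raise ValueError("Unterminated multi-line (;) value")
            yield "\n".join(block), True
            i += 1
            continue
        pos = 0
        n = len(line)
        while pos < n:
            ch = line[pos]
            if ch in " \t":
                pos += 1
                continue
            if ch == "#":
                break
            if ch in "'\"":
                end = line.find(ch, pos + 1)
                while end != -1 and end + 1 < n and line[end + 1] not in " \t":
                    end = line.find(ch, end + 1)
                if end == -1:
                    raise ValueError(f"Unterminated quote in line: {line!r}")
                yield line[pos + 1 : end], True
                pos = end + 1
            else:
                end = pos
                while end < n and line[end] not in " \t":
                    end += 1
                yield line[pos:end], False
                pos = end
        i += 1


def read_mmcif(text: str) -> dict[str, CifCategoryTable]:
    """
    Parse mmCIF text into a mapping of category name ->
    :class:`CifCategoryTable`.  Only the first data block is read.
    """
    categories: dict[str, CifCategoryTable] = {}

    def table_for(category: str) -> CifCategoryTable:
        if category not in categories:
            categories[category] = CifCategoryTable(category)
        return categories[category]

    tokens = _tokenize_cif(text)
    pending: list[tuple[str, str]] = []  # loop tags (category, item)
    state = "top"
    loop_values: list[str] = []
    seen_data_block = False

    def flush_loop():
        nonlocal pending, loop_values
        if pending:
            n_cols = len(pending)
            if len(loop_values) % n_cols != 0:
                raise ValueError(
                    f"loop_ row length {len(loop_values)} not divisible by "
                    f"column count {n_cols} (category "
                    f"{pending[0][0]!r})"
                )
            for k, (category, item) in enumerate(pending):
                table_for(category).add_column(item, loop_values[k::n_cols])
        pending = []
        loop_values = []

    stream = iter(tokens)
    for token, is_value in stream:
        lowered = token.lower() if not is_value else ""
        if not is_value and lowered.startswith("data_"):
            if seen_data_block:
                break
            seen_data_block = True
            continue
        if not is_value and lowered == "loop_":
            flush_loop()
            state = "loop_tags"
            continue
        if not is_value and token.startswith("_"):
            if state == "loop_tags":
                category, _, item = token[1:].partition(".")
                pending.append((category, item))
                continue
            if state == "loop_values":
                flush_loop()
                state = "top"
            # key-value pair
            category, _, item = token[1:].partition(".")
            try:
                value, _ = next(stream)
            except StopIteration:
                raise ValueError(f"Missing value for {token!r}") from None
            table_for(category).add_column(item, [value])
            continue
        # a bare or quoted value
        if state in ("loop_tags", "loop_values"):
            state = "loop_values"
            loop_values.append(token)
        else:
            raise ValueError(f"Unexpected value {token!r} outside a loop")
    flush_loop()
    return categories


def _cif_quote(value: str) -> str:
    if value == "":
        return "."
    if any(ch in value for ch in " \t'\"") or value.startswith("_"):
        if "'" not in value:
            return f"'{value}'"
        return f'"{value}"'
    return value


def write_mmcif_text(
    categories: dict[str, CifCategoryTable], block_name: str = "structure"
) -> str:
    """Serialize category tables to mmCIF text."""
    out = [f"data_{block_name}"]
    for name, table in categories.items():
        out.append("#")
        if table.row_count == 1:
            for item, values in table.columns.items():
                out.append(f"_{name}.{item} {_cif_quote(values[0])}")
        else:
            out.append("loop_")
            for item in table.columns:
                out.append(f"_{name}.{item}")
            cols = list(table.columns.values())
            for row in zip(*cols):
                out.append(" ".join(_cif_quote(v) for v in row))
    out.append("#")
    return "\n".join(out) + "\n"


_ATOM_SITE_ITEMS = [
    "group_PDB", "id", "type_symbol", "label_atom_id", "label_comp_id",
    "auth_asym_id", "auth_seq_id",
    "Cartn_x", "Cartn_y", "Cartn_z",
    "occupancy", "B_iso_or_equiv", "pdbx_PDB_model_num",
]


def atoms_to_mmcif(structure) -> dict[str, CifCategoryTable]:
    """Convert an AtomArray or AtomArrayStack to category tables."""
    if isinstance(structure, AtomArrayStack):
        models = [structure.get_model(i) for i in range(structure.stack_depth)]
    else:
        models = [structure]
    columns: dict[str, list[str]] = {item: [] for item in _ATOM_SITE_ITEMS}
    serial = 0
    for model_num, model in enumerate(models, start=1):
        for i in range(model.array_length):
            serial += 1
            columns["group_PDB"].append(
                "HETATM" if model.hetero[i] else "ATOM"
            )
            columns["id"].append(str(serial))
            columns["type_symbol"].append(str(model.element[i]) or "?")
            columns["label_atom_id"].append(str(model.atom_name[i]))
            columns["label_comp_id"].append(str(model.res_name[i]))
            columns["auth_asym_id"].append(str(model.chain_id[i]))
            columns["auth_seq_id"].append(str(int(model.res_id[i])))
            x, y, z = model.coord[i]
            columns["Cartn_x"].append(f"{x:.3f}")
            columns["Cartn_y"].append(f"{y:.3f}")
            columns["Cartn_z"].append(f"{z:.3f}")
            occupancy = (
                float(model.occupancy[i])
                if model.has_annotation("occupancy")
                else 1.0
            )
            b_factor = (
                float(model.b_factor[i])
                if model.has_annotation("b_factor")
                else 0.0
            )
            columns["occupancy"].append(f"{occupancy:.2f}")
            columns["B_iso_or_equiv"].append(f"{b_factor:.2f}")
            columns["pdbx_PDB_model_num"].append(str(model_num))
    table = CifCategoryTable("atom_site")
    for item, values in columns.items():
        table.add_column(item, values)
    return {"atom_site": table}


def mmcif_to_atoms(categories: dict[str, CifCategoryTable]):
    """
    Build an AtomArray / AtomArrayStack from the ``atom_site`` category.
    Models are grouped by the model-number item.
    """
    if "atom_site" not in categories:
        raise ValueError("No atom_site category present")
    site = categories["atom_site"]
    mandatory = ["label_atom_id", "label_comp_id", "Cartn_x", "Cartn_y",
                 "Cartn_z"]
    missing = [item for item in mandatory if item not in site]
    if missing:
        raise ValueError(f"atom_site lacks mandatory items: {missing}")
    n_rows = site.row_count

    def get(item: str, default: str) -> list[str]:
        return site[item] if item in site else [default] * n_rows

    def get_either(primary: str, secondary: str, default: str) -> list[str]:
        if primary in site:
            return site[primary]
        return get(secondary, default)

    model_nums = get("pdbx_PDB_model_num", "1")
    chain = get_either("auth_asym_id", "label_asym_id", "A")
    res_id = get_either("auth_seq_id", "label_seq_id", "1")
    group = get("group_PDB", "ATOM")
    element = get("type_symbol", "")
    occupancy = get("occupancy", "1.0")
    b_factor = get("B_iso_or_equiv", "0.0")

    by_model: dict[str, list[int]] = {}
    model_order: list[str] = []
    for row, num in enumerate(model_nums):
        if num not in by_model:
            by_model[num] = []
            model_order.append(num)
        by_model[num].append(row)

    def build(rows: list[int]) -> AtomArray:
        array = AtomArray(len(rows))
        array.coord = np.asarray(
            [
                (
                    float(site["Cartn_x"][r]),
                    float(site["Cartn_y"][r]),
                    float(site["Cartn_z"][r]),
                )
                for r in rows
            ]
        ).reshape(-1, 3)
        array.chain_id = np.asarray([chain[r] for r in rows], dtype="U4")
        array.res_id = np.asarray(
            [int(res_id[r]) if res_id[r] not in (".", "?") else 0 for r in rows]
        )
        array.res_name = np.asarray(
            [site["label_comp_id"][r] for r in rows], dtype="U5"
        )
        array.atom_name = np.asarray(
            [site["label_atom_id"][r] for r in rows], dtype="U6"
        )
        array.element = np.asarray(
            [element[r] if element[r] != "?" else "" for r in rows], dtype="U2"
        )
        array.hetero = np.asarray([group[r] == "HETATM" for r in rows])
        array.add_annotation(
            "b_factor", np.asarray([float(b_factor[r]) for r in rows])
        )
        array.add_annotation(
            "occupancy", np.asarray([float(occupancy[r]) for r in rows])
        )
        return array

    arrays = [build(by_model[num]) for num in model_order]
    if len(arrays) == 1:
        return arrays[0]
    return stack_models(arrays)


# ---------------------------------------------------------------------------
# File-level dispatch
# ---------------------------------------------------------------------------

_STRUCTURE_EXTENSIONS = {".pdb", ".cif", ".mmcif", ".mmtf"}


def read_structure(path: str):
    """Read a structure file; the format is selected by extension."""
    ext = os.path.splitext(path)[1].lower()
    if ext == ".pdb":
        with open(path) as handle:
            return read_pdb(handle.read())
    if ext in (".cif", ".mmcif"):
        with open(path) as handle:
            return mmcif_to_atoms(read_mmcif(handle.read()))
    if ext == ".mmtf":
        with open(path, "rb") as handle:
            return decode_mmtf(handle.read())
    raise ValueError(
        f"Unknown structure extension {ext!r}; supported: "
        f"{sorted(_STRUCTURE_EXTENSIONS)}"
    )


def write_structure(structure, path: str) -> None:
    """Write a structure file; the format is selected by extension."""
    ext = os.path.splitext(path)[1].lower()
    if ext == ".pdb":
        with open(path, "w") as handle:
            handle.write(write_pdb(structure))
    elif ext in (".cif", ".mmcif"):
        with open(path, "w") as handle:
            handle.write(write_mmcif_text(atoms_to_mmcif(structure)))
    elif ext == ".mmtf":
        with open(path, "wb") as handle:
            handle.write(encode_mmtf(structure))
    else:
        raise ValueError(
            f"Unknown structure extension {ext!r}; supported: "
            f"{sorted(_STRUCTURE_EXTENSIONS)}"
        )
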