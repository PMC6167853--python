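"""
Binary MMTF (macromolecular transmission format) encoder and decoder.

An MMTF file is a MessagePack map whose array-valued fields are packed as
binary strings with a 12-byte big-endian header — codec id (4 bytes),
element count (4 bytes), codec parameter (4 bytes) — followed by the
strategy-encoded payload.  This module provides

* a self-contained MessagePack subset (nil, bool, int, float, str, bin,
  array, map) sufficient for MMTF documents,
* the ten encoding strategies needed for coordinate and annotation
  fields (pass-through arrays, fixed-length strings, run-length, delta,
  quantization by divisor, recursive indexing), each exposed as an
  ``encode``/``decode`` pair that is an exact inverse (to divisor
  resolution for quantized reals), and
* the flattening between MMTF's chain -> group (residue) -> atom
  hierarchy and the columnar :class:`~atomseq.atoms.AtomArray` /
  :class:`~atomseq.atoms.AtomArrayStack` model, in both directions.

Coordinates are quantized with divisor 1000 (0.001 A resolution),
B factors and occupancies with divisor 100, as conventional for the
format.
"""

from __future__ import annotations

import struct

import numpy as np

from .atoms import AtomArray, AtomArrayStack

__all__ = [
    "pack_msgpack",
    "unpack_msgpack",
    "encode_array",
    "decode_array",
    "encode_mmtf",
    "decode_mmtf",
    "CODECS",
]


# ---------------------------------------------------------------------------
# MessagePack subset
# ---------------------------------------------------------------------------

def pack_msgpack(obj) -> bytes:
    out = bytearray()
    _pack(obj, out)
    return bytes(out)


def _pack(obj, out: bytearray) -> None:
    if obj is None:
        out.append(0xC0)
    elif isinstance(obj, bool):
        out.append(0xC3 if obj else 0xC2)
    elif isinstance(obj, (int, np.integer)):
        obj = int(obj)
        if 0 <= obj <= 0x7F:
            out.append(obj)
        elif -32 <= obj < 0:
            out.append(obj & 0xFF)
        elif 0 <= obj <= 0xFFFFFFFF:
            out.append(0xCE)
            out += struct.pack(">I", obj)
        elif -(2**31) <= obj < 2**31:
            out.append(0xD2)
            out += struct.pack(">i", obj)
        else:
            out.append(0xD3)
            out += struct.pack(">q", obj)
    elif isinstance(obj, (float, np.floating)):
        out.append(0xCB)
        out += struct.pack(">d", float(obj))
    elif isinstance(obj, str):
        data = obj.encode("utf-8")
        n = len(data)
        if n <= 31:
            out.append(0xA0 | n)
        elif n <= 0xFF:
            out += bytes((0xD9, n))
        elif n <= 0xFFFF:
            out.append(0xDA)
            out += struct.pack(">H", n)
        else:
            out.append(0xDB)
            out += struct.pack(">I", n)
        out += data
    elif isinstance(obj, (bytes, bytearray)):
        n = len(obj)
        if n <= 0xFF:
            out += bytes((0xC4, n))
        elif n <= 0xFFFF:
            out.append(0xC5)
            out += struct.pack(">H", n)
        else:
            out.append(0xC6)
            out += struct.pack(">I", n)
        out += obj
    elif isinstance(obj, (list, tuple)):
        n = len(obj)
        if n <= 15:
            out.append(0x90 | n)
        elif n <= 0xFFFF:
            out.append(0xDC)
            out += struct.pack(">H", n)
        else:
            out.append(0xDD)
            out += struct.pack(">I", n)
        for item in obj:
            _pack(item, out)
    elif isinstance(obj, dict):
        n = len(obj)
        if n <= 15:
            out.append(0x80 | n)
        elif n <= 0xFFFF:
            out.append(0xDE)
            out += struct.pack(">H", n)
        else:
            out.append(0xDF)
            out += struct.pack(">I", n)
        for key, value in obj.items():
            _pack(key, out)
            _pack(value, out)
    else:
        raise TypeError(f"Cannot pack object of type {type(obj).__name__}")


def unpack_msgpack(data: bytes):
    obj, pos = _unpack(memoryview(data), 0)
    if pos != len(data):
        raise ValueError("Trailing bytes after MessagePack object")
    return obj


def _unpack(data: memoryview, pos: int):
    tag = data[pos]
    pos += 1
    if tag <= 0x7F:
        return tag, pos
    if tag >= 0xE0:
        return tag - 0x100, pos
    if 0x80 <= tag <= 0x8F:
        return _unpack_map(data, pos, tag & 0x0F)
    if 0x90 <= tag <= 0x9F:
        return _unpack_array(data, pos, tag & 0x0F)
    if 0xA0 <= tag <= 0xBF:
        n = tag & 0x1F
        return str(data[pos : pos + n], "utf-8"), pos + n
    if tag == 0xC0:
        return None, pos
    if tag == 0xC2:
        return False, pos
    if tag == 0xC3:
        return True, pos
    if tag in (0xC4, 0xC5, 0xC6):
        size = {0xC4: 1, 0xC5: 2, 0xC6: 4}[tag]
        n = int.from_bytes(data[pos : pos + size], "big")
        pos += size
        return bytes(data[pos : pos + n]), pos + n
    if tag == 0xCA:
        return struct.unpack(">f", data[pos : pos + 4])[0], pos + 4
    if tag == 0xCB:
        return struct.unpack(">d", data[pos : pos + 8])[0], pos + 8
    if tag in (0xCC, 0xCD, 0xCE, 0xCF):
        size = 1 << (tag - 0xCC)
        return int.from_bytes(data[pos : pos + size], "big"), pos + size
    if tag in (0xD0, 0xD1, 0xD2, 0xD3):
        size = 1 << (tag - 0xD0)
        return (
            int.from_bytes(data[pos : pos + size], "big", signed=True),
            pos + size,
        )
    if tag in (0xD9, 0xDA, 0xDB):
        size = {0xD9: 1, 0xDA: 2, 0xDB: 4}[tag]
        n = int.from_bytes(data[pos : pos + size], "big")
        pos += size
        return str(data[pos : pos + n], "utf-8"), pos + n
    if tag in (0xDC, 0xDD):
        size = 2 if tag == 0xDC else 4
        n = int.from_bytes(data[pos : pos + size], "big")
        return _unpack_array(data, pos + size, n)
    if tag in (0xDE, 0xDF):
        size = 2 if tag == 0xDE else 4
        n = int.from_bytes(data[pos : pos + size], "big")
        return _unpack_map(data, pos + size, n)
    raise ValueError(f"Unsupported MessagePack tag 0x{tag:02X}")


def _unpack_array(data, pos, n):
    items = []
    for _ in range(n):
        item, pos = _unpack(data, pos)
        items.append(item)
    return items, pos


def _unpack_map(data, pos, n):
    result = {}
    for _ in range(n):
        key, pos = _unpack(data, pos)
        value, pos = _unpack(data, pos)
        result[key] = value
    return result, pos


# ---------------------------------------------------------------------------
# Primitive transforms
# ---------------------------------------------------------------------------

def _run_length_encode(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values)
    if len(values) == 0:
        return np.zeros(0, dtype=np.int32)
    boundaries = np.flatnonzero(values[1:] != values[:-1]) + 1
    starts = np.concatenate(([0], boundaries))
    lengths = np.diff(np.concatenate((starts, [len(values)])))
    out = np.empty(2 * len(starts), dtype=np.int64)
    out[0::2] = values[starts]
    out[1::2] = lengths
    return out.astype(np.int32)


def _run_length_decode(pairs: np.ndarray) -> np.ndarray:
    pairs = np.asarray(pairs)
    if len(pairs) % 2 != 0:
        raise ValueError("Run-length data must contain value/count pairs")
    return np.repeat(pairs[0::2], pairs[1::2])


def _delta_encode(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=np.int64)
    if len(values) == 0:
        return values.astype(np.int32)
    return np.concatenate(([values[0]], np.diff(values))).astype(np.int32)


def _delta_decode(deltas: np.ndarray) -> np.ndarray:
    return np.cumsum(np.asarray(deltas, dtype=np.int64)).astype(np.int32)


_I16_MAX = 32767
_I16_MIN = -32768


def _recursive_index_encode(values: np.ndarray) -> np.ndarray:
    """
    Spread int32 values over int16 by emitting saturating sentinels; the
    extrema act as continuation markers, so a value landing exactly on a
    sentinel is followed by a terminating 0.
    """
    out: list[int] = []
    for v in np.asarray(values, dtype=np.int64):
        v = int(v)
        while v >= _I16_MAX:
            out.append(_I16_MAX)
            v -= _I16_MAX
        while v <= _I16_MIN:
            out.append(_I16_MIN)
            v -= _I16_MIN
        out.append(v)
    return np.asarray(out, dtype=np.int16)


def _recursive_index_decode(values: np.ndarray) -> np.ndarray:
    out: list[int] = []
    acc = 0
    for v in np.asarray(values, dtype=np.int64):
        acc += int(v)
        if v != _I16_MAX and v != _I16_MIN:
            out.append(acc)
            acc = 0
    return np.asarray(out, dtype=np.int32)


# ---------------------------------------------------------------------------
# Codec strategies
# ---------------------------------------------------------------------------

def _enc_float32(values, param):
    return np.asarray(values, dtype=">f4").tobytes()


def _dec_float32(data, count, param):
    return np.frombuffer(data, dtype=">f4").astype(np.float32)


def _enc_int8(values, param):
    return np.asarray(values, dtype=np.int8).tobytes()


def _dec_int8(data, count, param):
    return np.frombuffer(data, dtype=np.int8).copy()


def _enc_int16(values, param):
    return np.asarray(values, dtype=">i2").tobytes()


def _dec_int16(data, count, param):
    return np.frombuffer(data, dtype=">i2").astype(np.int16)


def _enc_int32(values, param):
    return np.asarray(values, dtype=">i4").tobytes()


def _dec_int32(data, count, param):
    return np.frombuffer(data, dtype=">i4").astype(np.int32)


def _enc_strings(values, param):
    out = bytearray()
    for s in values:
        raw = str(s).encode("ascii")
        if len(raw) > param:
            raise ValueError(
                f"String {s!r} exceeds fixed length {param}"
            )
        out += raw.ljust(param, b"\x00")
    return bytes(out)


def _dec_strings(data, count, param):
    if param <= 0:
        raise ValueError("String codec requires a positive length parameter")
    items = [
        data[i : i + param].rstrip(b"\x00").decode("ascii")
        for i in range(0, len(data), param)
    ]
    return np.asarray(items, dtype=f"U{param}")


def _enc_run_length_char(values, param):
    codes = np.asarray([ord(str(c)) if str(c) else 0 for c in values])
    return _run_length_encode(codes).astype(">i4").tobytes()


def _dec_run_length_char(data, count, param):
    codes = _run_length_decode(np.frombuffer(data, dtype=">i4"))
    return np.asarray([chr(c) if c else "" for c in codes], dtype="U1")


def _enc_run_length_int(values, param):
    return _run_length_encode(np.asarray(values)).astype(">i4").tobytes()


def _dec_run_length_int(data, count, param):
    return _run_length_decode(
        np.frombuffer(data, dtype=">i4").astype(np.int64)
    ).astype(np.int32)


def _enc_delta_run_length(values, param):
    return (
        _run_length_encode(_delta_encode(np.asarray(values)))
        .astype(">i4")
        .tobytes()
    )


def _dec_delta_run_length(data, count, param):
    return _delta_decode(
        _run_length_decode(np.frombuffer(data, dtype=">i4").astype(np.int64))
    )


def _enc_run_length_float(values, param):
    quantized = np.round(np.asarray(values, dtype=np.float64) * param).astype(
        np.int64
    )
    return _run_length_encode(quantized).astype(">i4").tobytes()


def _dec_run_length_float(data, count, param):
    quantized = _run_length_decode(
        np.frombuffer(data, dtype=">i4").astype(np.int64)
    )
    return quantized / param


def _enc_delta_recursive_float(values, param):
    quantized = np.round(np.asarray(values, dtype=np.float64) * param).astype(
        np.int64
    )
    return (
        _recursive_index_encode(_delta_encode(quantized)).astype(">i2").tobytes()
    )


def _dec_delta_recursive_float(data, count, param):
    deltas = _recursive_index_decode(np.frombuffer(data, dtype=">i2"))
    return np.cumsum(deltas.astype(np.int64)) / param


# codec id -> (encode(values, param) -> payload, decode(payload, count, param))
CODECS = {
    1: (_enc_float32, _dec_float32),
    2: (_enc_int8, _dec_int8),
    3: (_enc_int16, _dec_int16),
    4: (_enc_int32, _dec_int32),
    5: (_enc_strings, _dec_strings),
    6: (_enc_run_length_char, _dec_run_length_char),
    7: (_enc_run_length_int, _dec_run_length_int),
    8: (_enc_delta_run_length, _dec_delta_run_length),
    9: (_enc_run_length_float, _dec_run_length_float),
    10: (_enc_delta_recursive_float, _dec_delta_recursive_float),
}


def encode_array(values, codec: int, param: int = 0) -> bytes:
    """Encode an array as a 12-byte-header binary field."""
    if codec not in CODECS:
        raise ValueError(f"Unknown MMTF codec id {codec}")
    values = np.asarray(values)
    payload = CODECS[codec][0](values, param)
    return struct.pack(">iii", codec, len(values), param) + payload


def decode_array(data: bytes) -> np.ndarray:
    """Decode a binary field (12-byte header + payload)."""
    if len(data) < 12:
        raise ValueError("Binary field shorter than its 12-byte header")
    codec, count, param = struct.unpack(">iii", data[:12])
    if codec not in CODECS:
        raise ValueError(f"Unknown MMTF codec id {codec}")
    values = CODECS[codec][1](data[12:], count, param)
    if len(values) != count:
        raise ValueError(
            f"Declared element count {count} does not match decoded "
            f"length {len(values)} (codec {codec})"
        )
    return values


# ---------------------------------------------------------------------------
# Hierarchy flattening: AtomArray(Stack) <-> MMTF document
# ---------------------------------------------------------------------------

_COORD_DIVISOR = 1000  # 0.001 A resolution
_B_DIVISOR = 100
_OCC_DIVISOR = 100


def _group_runs(array: AtomArray):
    """Consecutive (chain_id, res_id) runs -> group slices, file order."""
    starts = [0]
    for i in range(1, array.array_length):
        if (
            array.chain_id[i] != array.chain_id[i - 1]
            or array.res_id[i] != array.res_id[i - 1]
        ):
            starts.append(i)
    starts.append(array.array_length)
    return [(starts[k], starts[k + 1]) for k in range(len(starts) - 1)]


def encode_mmtf(structure) -> bytes:
    """Serialize an AtomArray or AtomArrayStack into MMTF bytes."""
    if isinstance(structure, AtomArray):
        models = [structure]
        template = structure
    else:
        models = [structure.get_model(i) for i in range(structure.stack_depth)]
        template = models[0]
    n = template.array_length
    m = len(models)

    groups = _group_runs(template)
    group_types: list[dict] = []
    type_index: dict[tuple, int] = {}
    group_type_list: list[int] = []
    group_id_list: list[int] = []
    for start, stop in groups:
        names = tuple(template.atom_name[start:stop])
        elements = tuple(template.element[start:stop])
        res_name = str(template.res_name[start])
        hetero = bool(template.hetero[start])
        key = (res_name, names, elements, hetero)
        if key not in type_index:
            type_index[key] = len(group_types)
            group_types.append(
                {
                    "groupName": res_name,
                    "atomNameList": list(names),
                    "elementList": [str(e) for e in elements],
                    "formalChargeList": [0] * len(names),
                    "singleLetterCode": "X",
                    "chemCompType": (
                        "NON-POLYMER" if hetero else "L-PEPTIDE LINKING"
                    ),
                    "bondAtomList": [],
                    "bondOrderList": [],
                }
            )
        group_type_list.append(type_index[key])
        group_id_list.append(int(template.res_id[start]))

    # chains: consecutive chain_id runs over the groups
    chain_names: list[str] = []
    groups_per_chain: list[int] = []
    prev_cid = None
    for start, _ in groups:
        cid = str(template.chain_id[start])
        if cid != prev_cid:
            chain_names.append(cid)
            groups_per_chain.append(1)
            prev_cid = cid
        else:
            groups_per_chain[-1] += 1

    coords = np.stack([model.coord for model in models])  # (m, n, 3)
    flat = coords.reshape(m * n, 3)
    if template.has_annotation("b_factor"):
        b_factor = np.concatenate([template.b_factor] * m)
    else:
        b_factor = np.zeros(m * n)
    if template.has_annotation("occupancy"):
        occupancy = np.concatenate([template.occupancy] * m)
    else:
        occupancy = np.ones(m * n)

    document = {
        "mmtfVersion": "1.0.0",
        "mmtfProducer": "atomseq",
        "numAtoms": m * n,
        "numGroups": m * len(groups),
        "numChains": m * len(chain_names),
        "numModels": m,
        "groupList": group_types,
        "groupTypeList": encode_array(group_type_list * m, codec=4),
        "groupIdList": encode_array(group_id_list * m, codec=8),
        "chainIdList": encode_array(chain_names * m, codec=5, param=4),
        "chainNameList": encode_array(chain_names * m, codec=5, param=4),
        "groupsPerChain": groups_per_chain * m,
        "chainsPerModel": [len(chain_names)] * m,
        "xCoordList": encode_array(flat[:, 0], codec=10, param=_COORD_DIVISOR),
        "yCoordList": encode_array(flat[:, 1], codec=10, param=_COORD_DIVISOR),
        "zCoordList": encode_array(flat[:, 2], codec=10, param=_COORD_DIVISOR),
        "bFactorList": encode_array(b_factor, codec=10, param=_B_DIVISOR),
        "occupancyList": encode_array(occupancy, codec=9, param=_OCC_DIVISOR),
        "atomIdList": encode_array(
            np.arange(1, m * n + 1, dtype=np.int64), codec=8
        ),
        "altLocList": encode_array([""] * (m * n), codec=6),
        "insCodeList": encode_array([""] * (m * len(groups)), codec=6),
    }
    return pack_msgpack(document)


def decode_mmtf(data: bytes):
    """
    Deserialize MMTF bytes into an AtomArray (single model) or an
    AtomArrayStack (several models sharing annotations).
    """
    doc = unpack_msgpack(data)
    required = [
        "numModels", "numAtoms", "groupList", "groupTypeList", "groupIdList",
        "chainIdList", "groupsPerChain", "chainsPerModel",
        "xCoordList", "yCoordList", "zCoordList",
    ]
    missing = [k for k in required if k not in doc]
    if missing:
        raise ValueError(f"MMTF document lacks fields: {missing}")

    num_models = doc["numModels"]
    num_atoms = doc["numAtoms"]
    group_type_list = decode_array(doc["groupTypeList"])
    group_id_list = decode_array(doc["groupIdList"])
    chain_ids = decode_array(doc["chainIdList"])
    groups_per_chain = doc["groupsPerChain"]
    x = decode_array(doc["xCoordList"]).astype(np.float64)
    y = decode_array(doc["yCoordList"]).astype(np.float64)
    z = decode_array(doc["zCoordList"]).astype(np.float64)
    b_factor = (
        decode_array(doc["bFactorList"]).astype(np.float64)
        if "bFactorList" in doc
        else np.zeros(num_atoms)
    )
    occupancy = (
        decode_array(doc["occupancyList"]).astype(np.float64)
        if "occupancyList" in doc
        else np.ones(num_atoms)
    )
    group_list = doc["groupList"]

    chain_id_annot: list[str] = []
    res_id_annot: list[int] = []
    res_name_annot: list[str] = []
    atom_name_annot: list[str] = []
    element_annot: list[str] = []
    hetero_annot: list[bool] = []
    model_starts: list[int] = []

    group_cursor = 0
    chain_cursor = 0
    atom_cursor = 0
    for chains_in_model in doc["chainsPerModel"]:
        model_starts.append(atom_cursor)
        for _ in range(chains_in_model):
            cid = str(chain_ids[chain_cursor])
            for _ in range(groups_per_chain[chain_cursor]):
                gtype = group_list[int(group_type_list[group_cursor])]
                names = gtype["atomNameList"]
                elements = gtype["elementList"]
                hetero = "PEPTIDE" not in gtype.get(
                    "chemCompType", "NON-POLYMER"
                ).upper() and "NUCLEIC" not in gtype.get(
                    "chemCompType", ""
                ).upper()
                rid = int(group_id_list[group_cursor])
                rname = gtype["groupName"]
                for name, element in zip(names, elements):
                    chain_id_annot.append(cid)
                    res_id_annot.append(rid)
                    res_name_annot.append(rname)
                    atom_name_annot.append(name)
                    element_annot.append(element)
                    hetero_annot.append(hetero)
                    atom_cursor += 1
                group_cursor += 1
            chain_cursor += 1
    if atom_cursor != num_atoms:
        raise ValueError(
            f"Hierarchy describes {atom_cursor} atoms, header says {num_atoms}"
        )

    coords = np.column_stack((x, y, z))
    n_per_model = num_atoms // num_models if num_models else 0
    if num_models * n_per_model != num_atoms:
        raise ValueError("Atom count is not divisible by the model count")

    def build_model(start: int) -> AtomArray:
        stop = start + n_per_model
        array = AtomArray(n_per_model)
        array.coord = coords[start:stop]
        array.chain_id = np.asarray(chain_id_annot[start:stop], dtype="U4")
        array.res_id = np.asarray(res_id_annot[start:stop])
        array.res_name = np.asarray(res_name_annot[start:stop], dtype="U5")
        array.atom_name = np.asarray(atom_name_annot[start:stop], dtype="U6")
        array.element = np.asarray(element_annot[start:stop], dtype="U2")
        array.hetero = np.asarray(hetero_annot[start:stop])
        array.add_annotation("b_factor", b_factor[start:stop])
        array.add_annotation("occupancy", occupancy[start:stop])
        return array

    models = [build_model(start) for start in model_starts]
    if len(models) == 1:
        return models[0]
    from .atoms import stack_models

    return stack_models(models)
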