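"""PDB / mmCIF / MMTF readers-writers and the MMTF codec layer."""

import struct

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from atomseq import (
    AtomArray,
    AtomArrayStack,
    atoms_to_mmcif,
    decode_mmtf,
    encode_mmtf,
    mmcif_to_atoms,
    read_mmcif,
    read_pdb,
    write_mmcif_text,
    write_pdb,
)
from atomseq.fixtures import random_structure
from atomseq.mmtf import (
    CODECS,
    decode_array,
    encode_array,
    pack_msgpack,
    unpack_msgpack,
)

TOY_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
HETATM    3  O   HOH A 101       8.000   9.000  10.000  1.00  0.00           O
END
"""


class TestPdb:
    def test_toy_file(self):
        array = read_pdb(TOY_PDB)
        assert array.array_length == 3
        assert array.hetero.tolist() == [False, False, True]
        assert array.atom_name.tolist() == ["N", "CA", "O"]
        assert array.coord[0, 0] == pytest.approx(11.104, abs=1e-9)

    def test_two_models_build_stack(self):
        block = "".join(
            line + "\n" for line in TOY_PDB.splitlines() if line != "END"
        )
        text = f"MODEL     1\n{block}ENDMDL\nMODEL     2\n{block}ENDMDL\n"
        stack = read_pdb(text)
        assert isinstance(stack, AtomArrayStack)
        assert stack.stack_depth == 2 and stack.array_length == 3

    def test_model_count_mismatch_raises(self):
        lines = [l for l in TOY_PDB.splitlines() if l != "END"]
        text = (
            "MODEL     1\n" + "\n".join(lines) + "\nENDMDL\n"
            "MODEL     2\n" + "\n".join(lines[:2]) + "\nENDMDL\n"
        )
        with pytest.raises(ValueError, match="atom count"):
            read_pdb(text)

    def test_bad_coordinate_reports_line(self):
        bad = TOY_PDB.replace("11.104", "xx.xxx")
        with pytest.raises(ValueError, match="[Ll]ine 1"):
            read_pdb(bad)

    def test_round_trip_random_structure(self):
        array = random_structure(100, seed=11)
        result = read_pdb(write_pdb(array))
        assert result.equal_annotations(array)
        assert np.abs(result.coord - array.coord).max() <= 0.001

    def test_stack_round_trip_has_model_blocks(self):
        stack = random_structure(40, n_models=3, seed=12)
        text = write_pdb(stack)
        assert text.count("MODEL") == text.count("ENDMDL") == 3
        result = read_pdb(text)
        assert isinstance(result, AtomArrayStack)
        assert result == stack

    def test_long_chain_id_rejected(self):
        array = random_structure(8, seed=13)
        array.chain_id = np.full(8, "AB", dtype="U4")
        with pytest.raises(ValueError, match="[Cc]hain"):
            write_pdb(array)

    def test_altloc_first_kept(self):
        text = (
            "ATOM      1  CA AALA A   1       0.000   0.000   0.000"
            "  0.50  0.00           C\n"
            "ATOM      2  CA BALA A   1       1.000   0.000   0.000"
            "  0.50  0.00           C\n"
        )
        array = read_pdb(text)
        assert array.array_length == 1
        assert array.coord[0, 0] == 0.0
        both = read_pdb(text, keep_altlocs=True)
        assert both.array_length == 2
        assert both.altloc_id.tolist() == ["A", "B"]

    def test_element_inferred_from_name_column(self):
        text = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000\n"
            "HETATM    2 CA    CA A   2       3.000   0.000   0.000\n"
        )
        array = read_pdb(text)
        assert array.element.tolist() == ["C", "CA"]

    def test_gemmi_reads_our_output(self):
        import gemmi

        array = random_structure(60, seed=14)
        structure = gemmi.read_pdb_string(write_pdb(array))
        atoms = [
            atom
            for model in structure
            for chain in model
            for residue in chain
            for atom in residue
        ]
        assert len(atoms) == 60
        ours = array.coord
        theirs = np.array([[a.pos.x, a.pos.y, a.pos.z] for a in atoms])
        # gemmi orders atoms by chain/residue as written
        assert np.allclose(sorted(map(tuple, ours)), sorted(map(tuple, theirs)))


TOY_CIF = """\
data_toy
_cell.length_a 78.9
_struct.title 'A toy entry'
loop_
_atom_site.group_PDB
_atom_site.id
_atom_site.type_symbol
_atom_site.label_atom_id
_atom_site.label_comp_id
_atom_site.auth_asym_id
_atom_site.auth_seq_id
_atom_site.Cartn_x
_atom_site.Cartn_y
_atom_site.Cartn_z
_atom_site.occupancy
_atom_site.B_iso_or_equiv
_atom_site.pdbx_PDB_model_num
ATOM 1 N N ALA A 1 11.104 6.134 -6.504 1.00 0.00 1
ATOM 2 C CA ALA A 1 11.639 6.071 -5.147 1.00 0.00 1
ATOM 3 C C ALA A 1 12.000 7.000 -4.000 1.00 0.00 1
ATOM 4 O O ALA A 1 12.500 8.000 -4.200 1.00 0.00 1
ATOM 5 N N GLY A 2 11.900 6.500 -2.800 1.00 0.00 1
"""


class TestMmcif:
    def test_loop_category_row_count(self):
        tables = read_mmcif(TOY_CIF)
        site = tables["atom_site"]
        assert site.row_count == 5
        assert all(len(col) == 5 for col in site.columns.values())

    def test_key_value_category(self):
        tables = read_mmcif(TOY_CIF)
        assert tables["cell"]["length_a"] == ["78.9"]
        assert tables["struct"]["title"] == ["A toy entry"]

    def test_semicolon_multiline_value(self):
        text = (
            "data_x\n_entry.id demo\n_struct.pdbx_descriptor\n"
            ";line one\nline two\n;\n"
        )
        tables = read_mmcif(text)
        assert tables["struct"]["pdbx_descriptor"] == ["line one\nline two"]

    def test_bad_loop_row_length(self):
        text = (
            "data_x\nloop_\n_cat.a\n_cat.b\n1 2 3\n"
        )
        with pytest.raises(ValueError, match="divisible"):
            read_mmcif(text)

    def test_atoms_from_cif(self):
        array = mmcif_to_atoms(read_mmcif(TOY_CIF))
        assert isinstance(array, AtomArray)
        assert array.array_length == 5
        assert array.res_name.tolist() == ["ALA"] * 4 + ["GLY"]
        assert array.coord[0, 2] == pytest.approx(-6.504)

    def test_two_models_build_stack(self):
        tables = atoms_to_mmcif(random_structure(16, n_models=2, seed=21))
        result = mmcif_to_atoms(tables)
        assert isinstance(result, AtomArrayStack)
        assert result.stack_depth == 2 and result.array_length == 16

    def test_missing_mandatory_items_listed(self):
        tables = read_mmcif(TOY_CIF)
        del tables["atom_site"].columns["Cartn_x"]
        with pytest.raises(ValueError, match="Cartn_x"):
            mmcif_to_atoms(tables)

    def test_round_trip(self):
        array = random_structure(80, seed=22)
        result = mmcif_to_atoms(read_mmcif(write_mmcif_text(atoms_to_mmcif(array))))
        assert result == array

    def test_hetero_maps_to_group_pdb(self):
        array = random_structure(40, seed=23)
        tables = atoms_to_mmcif(array)
        group = np.asarray(tables["atom_site"]["group_PDB"])
        assert ((group == "HETATM") == array.hetero).all()

    def test_gemmi_reads_our_output(self):
        import gemmi

        array = random_structure(30, seed=24)
        doc = gemmi.cif.read_string(write_mmcif_text(atoms_to_mmcif(array)))
        block = doc.sole_block()
        xs = [float(v) for v in block.find_loop("_atom_site.Cartn_x")]
        assert len(xs) == 30
        assert np.allclose(sorted(xs), sorted(array.coord[:, 0]))


class TestMmtfCodecs:
    def test_run_length_pair_definition(self):
        payload = struct.pack(">iii", 7, 3, 0) + struct.pack(">ii", 5, 3)
        assert decode_array(payload).tolist() == [5, 5, 5]

    def test_delta_definition(self):
        # deltas [1,1,1] run-length encoded as (1,3); cumulative [1,2,3]
        payload = struct.pack(">iii", 8, 3, 0) + struct.pack(">ii", 1, 3)
        assert decode_array(payload).tolist() == [1, 2, 3]

    def test_unknown_codec_id_reported(self):
        with pytest.raises(ValueError, match="99"):
            decode_array(struct.pack(">iii", 99, 0, 0))

    def test_count_mismatch_reported(self):
        payload = struct.pack(">iii", 4, 5, 0) + struct.pack(">ii", 1, 2)
        with pytest.raises(ValueError, match="count"):
            decode_array(payload)

    @pytest.mark.parametrize("codec", sorted(CODECS))
    def test_decode_encode_identity(self, codec, rng):
        for _ in range(100):
            n = int(rng.integers(0, 60))
            if codec == 1:
                values = rng.normal(size=n).astype(np.float32)
            elif codec == 2:
                values = rng.integers(-128, 128, size=n)
            elif codec == 3:
                values = rng.integers(-(2**15), 2**15, size=n)
            elif codec in (4, 7, 8):
                values = rng.integers(-(2**25), 2**25, size=n)
            elif codec == 5:
                values = np.asarray(
                    ["".join(rng.choice(list("ABCD"), size=rng.integers(0, 5)))
                     for _ in range(n)],
                    dtype="U4",
                )
            elif codec == 6:
                values = np.asarray(
                    [rng.choice(["A", "B", ""]) for _ in range(n)], dtype="U1"
                )
            else:  # 9, 10: quantized reals, values on the divisor grid
                divisor = 1000
                values = rng.integers(-(10**6), 10**6, size=n) / divisor
            param = 4 if codec == 5 else (1000 if codec in (9, 10) else 0)
            decoded = decode_array(encode_array(values, codec, param))
            if codec == 1:
                assert np.allclose(decoded, values, atol=0)
            elif codec in (9, 10):
                assert np.allclose(decoded, values, atol=1e-12)
            else:
                assert decoded.tolist() == list(values.tolist())

    def test_recursive_index_crosses_int16_range(self):
        from atomseq.mmtf import (
            _recursive_index_decode,
            _recursive_index_encode,
        )

        values = np.array([0, 100000, -100000, 32767, -32768, 1])
        encoded = _recursive_index_encode(values)
        assert encoded.dtype == np.int16
        assert (np.abs(encoded.astype(np.int64)) <= 32768).all()
        assert _recursive_index_decode(encoded).tolist() == values.tolist()
        # coordinates with jumps beyond the int16 range survive codec 10
        coords = np.array([0.0, 40.0, -40.0, 39.999])
        decoded = decode_array(encode_array(coords, codec=10, param=1000))
        assert np.allclose(decoded, coords, atol=1e-12)


class TestMessagePack:
    @given(
        st.recursive(
            st.one_of(
                st.none(),
                st.booleans(),
                st.integers(min_value=-(2**62), max_value=2**62),
                st.floats(allow_nan=False, allow_infinity=False),
                st.text(max_size=40),
                st.binary(max_size=40),
            ),
            lambda children: st.one_of(
                st.lists(children, max_size=5),
                st.dictionaries(st.text(max_size=8), children, max_size=5),
            ),
            max_leaves=20,
        )
    )
    def test_round_trip(self, obj):
        assert unpack_msgpack(pack_msgpack(obj)) == obj


class TestMmtfStructures:
    def test_round_trip_500_atoms(self):
        array = random_structure(500, seed=31)
        result = decode_mmtf(encode_mmtf(array))
        assert result.equal_annotations(array)
        assert np.abs(result.coord - array.coord).max() <= 0.001

    def test_stack_round_trip(self):
        stack = random_structure(60, n_models=4, seed=32)
        result = decode_mmtf(encode_mmtf(stack))
        assert isinstance(result, AtomArrayStack)
        assert result == stack

    def test_document_is_valid_messagepack_map(self):
        data = encode_mmtf(random_structure(20, seed=33))
        doc = unpack_msgpack(data)
        assert doc["mmtfVersion"].startswith("1.")
        assert doc["numModels"] == 1
        assert isinstance(doc["xCoordList"], bytes)

    def test_missing_fields_reported(self):
        doc = unpack_msgpack(encode_mmtf(random_structure(10, seed=34)))
        del doc["xCoordList"]
        with pytest.raises(ValueError, match="xCoordList"):
            decode_mmtf(pack_msgpack(doc))


class TestFormatTriangle:
    @pytest.mark.parametrize("n_models", [1, 3])
    def test_pdb_mmtf_mmcif_chain(self, n_models):
        original = random_structure(120, n_models=n_models, seed=41)
        via_pdb = read_pdb(write_pdb(original))
        assert via_pdb == original
        via_mmtf = decode_mmtf(encode_mmtf(via_pdb))
        assert via_mmtf == via_pdb
        via_cif = mmcif_to_atoms(read_mmcif(write_mmcif_text(atoms_to_mmcif(via_mmtf))))
        assert via_cif == via_mmtf
        assert np.abs(via_cif.coord - original.coord).max() <= 0.001

    def test_writer_reader_fixed_point(self):
        array = random_structure(50, seed=42)
        text1 = write_pdb(array)
        text2 = write_pdb(read_pdb(text1))
        assert text1 == text2
        cif1 = write_mmcif_text(atoms_to_mmcif(array))
        cif2 = write_mmcif_text(atoms_to_mmcif(mmcif_to_atoms(read_mmcif(cif1))))
        assert cif1 == cif2
        mmtf1 = encode_mmtf(array)
        mmtf2 = encode_mmtf(decode_mmtf(mmtf1))
        assert mmtf1 == mmtf2
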