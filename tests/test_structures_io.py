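import json

import pytest

from bindsurf.errors import (
    ChainAmbiguityError,
    EmptyFilterError,
    InterfaceFileError,
    PDBParseError,
    ValidationError,
)
from bindsurf.structures_io import (
    Interface,
    InterfaceSet,
    Residue,
    Structure,
    coverage,
    filter_interfaces,
    read_interface_file,
    read_pdb,
    select_best_structure,
    write_pdb,
)
from conftest import atom_line


class TestReadPdb:
    def test_three_residue_chain(self, make_pdb):
        text = (
            atom_line(1, "N", "ALA", "A", 1, 0.0, 0.0, 0.0, element="N")
            + atom_line(2, "CA", "ALA", "A", 1, 1.0, 0.0, 0.0)
            + atom_line(3, "CA", "GLY", "A", 2, 4.8, 0.0, 0.0)
            + atom_line(4, "CA", "SER", "A", 3, 8.6, 0.0, 0.0)
            + "END\n"
        )
        s = read_pdb(make_pdb(text), chain="A")
        assert s.residue_numbers == [1, 2, 3]
        assert s.chain_id == "A"
        assert s.residues[0].x == pytest.approx(1.0)

    def test_chain_selection(self, make_pdb):
        text = (
            atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0)
            + atom_line(2, "CA", "ALA", "B", 7, 5.0, 0.0, 0.0)
            + atom_line(3, "CA", "ALA", "B", 8, 9.0, 0.0, 0.0)
        )
        s = read_pdb(make_pdb(text), chain="B")
        assert s.residue_numbers == [7, 8]

    def test_duplicate_ca_altloc_first_wins(self, make_pdb):
        text = (
            atom_line(1, "CA", "ALA", "A", 5, 1.0, 0.0, 0.0, altloc="A")
            + atom_line(2, "CA", "ALA", "A", 5, 2.0, 0.0, 0.0, altloc="B")
            + atom_line(3, "CA", "ALA", "A", 6, 5.0, 0.0, 0.0)
        )
        s = read_pdb(make_pdb(text), chain="A")
        assert len(s) == 2
        assert s.residues[0].x == pytest.approx(1.0)

    def test_hetatm_and_non_ca_ignored(self, make_pdb):
        text = (
            "HETATM    1  CA  CA  A 101      0.000   0.000   0.000  1.00  0.00          CA\n"
            + atom_line(2, "CB", "ALA", "A", 1, 9.0, 9.0, 9.0)
            + atom_line(3, "CA", "ALA", "A", 1, 1.0, 2.0, 3.0)
        )
        s = read_pdb(make_pdb(text))
        assert s.residue_numbers == [1]
        assert (s.residues[0].x, s.residues[0].y) == (1.0, 2.0)

    def test_single_chain_inferred(self, make_pdb):
        text = atom_line(1, "CA", "ALA", "Q", 1, 0.0, 0.0, 0.0)
        assert read_pdb(make_pdb(text)).chain_id == "Q"

    def test_multi_chain_without_selector_errors(self, make_pdb):
        text = (
            atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0)
            + atom_line(2, "CA", "ALA", "B", 1, 5.0, 0.0, 0.0)
        )
        with pytest.raises(ChainAmbiguityError, match="A, B"):
            read_pdb(make_pdb(text))

    def test_no_ca_for_chain(self, make_pdb):
        text = atom_line(1, "CB", "ALA", "A", 1, 0.0, 0.0, 0.0)
        with pytest.raises(PDBParseError):
            read_pdb(make_pdb(text), chain="A")

    def test_insertion_code_rejected(self, make_pdb):
        text = atom_line(1, "CA", "ALA", "A", 10, 0.0, 0.0, 0.0, icode="A")
        with pytest.raises(PDBParseError, match="insertion code"):
            read_pdb(make_pdb(text), chain="A")

    def test_only_first_model_read(self, make_pdb):
        text = (
            "MODEL        1\n"
            + atom_line(1, "CA", "ALA", "A", 1, 0.0, 0.0, 0.0)
            + "ENDMDL\n"
            + "MODEL        2\n"
            + atom_line(1, "CA", "ALA", "A", 2, 5.0, 0.0, 0.0)
            + "ENDMDL\n"
        )
        s = read_pdb(make_pdb(text), chain="A")
        assert s.residue_numbers == [1]

    def test_roundtrip_preserves_numbers_and_coords(self, tmp_path, toy_structure):
        out = tmp_path / "out.pdb"
        write_pdb(toy_structure, out)
        back = read_pdb(out, chain="A")
        assert back.residue_numbers == toy_structure.residue_numbers
        for a, b in zip(back.residues, toy_structure.residues):
            assert (a.x, a.y, a.z) == pytest.approx((b.x, b.y, b.z), abs=1e-3)


class TestDomainTypes:
    def test_structure_orders_residues(self):
        s = Structure("A", [Residue(3, 0, 0, 0), Residue(1, 1, 1, 1)])
        assert s.residue_numbers == [1, 3]

    def test_structure_rejects_duplicates(self):
        with pytest.raises(ValidationError):
            Structure("A", [Residue(1, 0, 0, 0), Residue(1, 1, 1, 1)])

    def test_structure_rejects_nonfinite(self):
        with pytest.raises(ValidationError):
            Structure("A", [Residue(1, float("nan"), 0, 0)])

    def test_interface_rejects_empty(self):
        with pytest.raises(ValidationError):
            Interface.from_iterable("x", [])

    def test_interface_rejects_nonpositive(self):
        with pytest.raises(ValidationError):
            Interface.from_iterable("x", [0, 5])

    def test_interface_set_rejects_duplicate_names(self):
        a = Interface.from_iterable("same", [1])
        b = Interface.from_iterable("same", [2])
        with pytest.raises(ValidationError):
            InterfaceSet(interfaces=[a, b])


class TestInterfaceFile:
    def test_basic(self, write_interface_json):
        path = write_interface_json({"P01070-1avx": [10, 11, 12]})
        ifs = read_interface_file(path)
        assert len(ifs) == 1
        assert ifs.interfaces[0].residues == {10, 11, 12}

    def test_order_preserved(self, write_interface_json):
        path = write_interface_json({"b-x": [1], "a-y": [2], "c-z": [3]})
        assert read_interface_file(path).names == ["b-x", "a-y", "c-z"]

    def test_duplicate_names_error(self, tmp_path):
        path = tmp_path / "dup.json"
        path.write_text('{"same": [1], "same": [2]}')
        with pytest.raises(InterfaceFileError, match="duplicate"):
            read_interface_file(path)

    def test_duplicate_residues_deduplicated(self, write_interface_json):
        path = write_interface_json({"x-y": [5, 5, 6]})
        assert len(read_interface_file(path).interfaces[0]) == 2

    def test_empty_residue_list_error(self, write_interface_json):
        path = write_interface_json({"x-y": []})
        with pytest.raises(ValidationError, match="empty"):
            read_interface_file(path)

    def test_malformed_json_reports_line(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"x": [1,\n 2,,]}')
        with pytest.raises(InterfaceFileError, match="line 2"):
            read_interface_file(path)

    def test_non_integer_residues_error(self, write_interface_json):
        path = write_interface_json({"x-y": [1, "two"]})
        with pytest.raises(InterfaceFileError, match="integers"):
            read_interface_file(path)


class TestFilterInterfaces:
    def _structure(self, numbers):
        return Structure(
            "A", [Residue(n, float(n), 0.0, 0.0) for n in numbers]
        )

    def test_seventy_percent_boundary_inclusive(self):
        # 7 of 10 residues present, cutoff 0.7: retained
        s = self._structure(range(1, 8))
        ifs = InterfaceSet([Interface.from_iterable("i-1", range(1, 11))])
        kept = filter_interfaces(ifs, s, cov_cutoff=0.7)
        assert kept.names == ["i-1"]
        assert kept.interfaces[0].residues == set(range(1, 8))

    def test_below_cutoff_dropped(self):
        s = self._structure(range(1, 7))  # 6 of 10 -> 0.6 < 0.7
        ifs = InterfaceSet(
            [
                Interface.from_iterable("drop-1", range(1, 11)),
                Interface.from_iterable("keep-1", [1, 2, 3]),
            ]
        )
        kept = filter_interfaces(ifs, s, cov_cutoff=0.7)
        assert kept.names == ["keep-1"]

    def test_full_coverage_cutoff_one(self):
        s = self._structure([1, 2, 3])
        ifs = InterfaceSet([Interface.from_iterable("i-1", [1, 2, 3])])
        kept = filter_interfaces(ifs, s, cov_cutoff=1.0)
        assert kept.interfaces[0].residues == {1, 2, 3}

    def test_all_filtered_raises(self):
        s = self._structure([100])
        ifs = InterfaceSet([Interface.from_iterable("i-1", [1, 2])])
        with pytest.raises(EmptyFilterError):
            filter_interfaces(ifs, s)

    def test_idempotent(self):
        s = self._structure(range(1, 9))
        ifs = InterfaceSet(
            [Interface.from_iterable(f"i{k}-x", range(k, k + 5)) for k in (1, 3)]
        )
        once = filter_interfaces(ifs, s, cov_cutoff=0.7)
        twice = filter_interfaces(once, s, cov_cutoff=0.7)
        assert [i.residues for i in twice] == [i.residues for i in once]

    def test_tiny_cutoff_keeps_any_overlap(self):
        s = self._structure([5])
        ifs = InterfaceSet([Interface.from_iterable("i-1", [5, 600, 601])])
        kept = filter_interfaces(ifs, s, cov_cutoff=1e-9)
        assert kept.interfaces[0].residues == {5}

    def test_strict_mode_raises_instead_of_dropping(self):
        s = self._structure([1])
        ifs = InterfaceSet([Interface.from_iterable("i-1", [1, 2, 3])])
        with pytest.raises(ValidationError, match="coverage"):
            filter_interfaces(ifs, s, cov_cutoff=0.7, strict=True)

    def test_invalid_cutoff(self):
        s = self._structure([1])
        ifs = InterfaceSet([Interface.from_iterable("i-1", [1])])
        with pytest.raises(ValidationError):
            filter_interfaces(ifs, s, cov_cutoff=0.0)

    def test_coverage_counts_against_full_residue_list(self):
        s = self._structure([1, 2])
        iface = Interface.from_iterable("i-1", [1, 2, 3, 4])
        assert coverage(iface, s) == pytest.approx(0.5)


class TestSelectBestStructure:
    def _structure(self, numbers, source):
        return Structure(
            "A", [Residue(n, float(n), 0.0, 0.0) for n in numbers], source_id=source
        )

    def test_picks_highest_retention(self):
        ifs = InterfaceSet(
            [Interface.from_iterable(f"i{k}-x", [k]) for k in range(1, 6)]
        )
        a = self._structure(range(1, 6), "a")  # retains 5
        b = self._structure(range(1, 4), "b")  # retains 3
        assert select_best_structure([b, a], ifs).source_id == "a"

    def test_tie_breaks_to_first(self):
        ifs = InterfaceSet(
            [Interface.from_iterable(f"i{k}-x", [k]) for k in range(1, 5)]
        )
        a = self._structure(range(1, 5), "first")
        b = self._structure(range(1, 5), "second")
        assert select_best_structure([a, b], ifs).source_id == "first"

    def test_single_candidate(self):
        ifs = InterfaceSet([Interface.from_iterable("i-x", [1])])
        only = self._structure([1], "only")
        assert select_best_structure([only], ifs) is only

    def test_empty_candidates(self):
        ifs = InterfaceSet([Interface.from_iterable("i-x", [1])])
        with pytest.raises(ValidationError):
            select_best_structure([], ifs)
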