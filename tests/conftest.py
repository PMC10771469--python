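import json

import numpy as np
import pytest

from bindsurf.structures_io import Interface, InterfaceSet, Residue, Structure

ATOM_FMT = (
    "ATOM  {serial:5d} {name:^4s}{altloc}{resname:<3s} {chain}{resseq:4d}{icode}   "
    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}           {element:>2s}\n"
)


def atom_line(serial, name, resname, chain, resseq, x, y, z,
              altloc=" ", icode=" ", occ=1.0, b=0.0, element="C"):
    return ATOM_FMT.format(
        serial=serial, name=name, altloc=altloc, resname=resname, chain=chain,
        resseq=resseq, icode=icode, x=x, y=y, z=z, occ=occ, b=b, element=element,
    )


@pytest.fixture
def make_pdb(tmp_path):
    """Write raw PDB text (or a list of atom tuples) to a temp file."""

    def _make(content, filename="toy.pdb"):
        path = tmp_path / filename
        path.write_text(content)
        return path

    return _make


@pytest.fixture
def toy_structure():
    """Three residues on a line, 3.8 A apart."""
    return Structure(
        chain_id="A",
        residues=[
            Residue(1, 0.0, 0.0, 0.0),
            Residue(2, 3.8, 0.0, 0.0),
            Residue(3, 7.6, 0.0, 0.0),
        ],
        source_id="toy",
    )


@pytest.fixture
def line_structure():
    """Factory: n collinear residues with a given spacing."""

    def _make(n, spacing=3.8):
        return Structure(
            chain_id="A",
            residues=[Residue(i + 1, i * spacing, 0.0, 0.0) for i in range(n)],
            source_id="line",
        )

    return _make


@pytest.fixture
def random_instance():
    """Factory: random structure + interface set for oracle comparisons."""

    def _make(seed, n_residues=30, n_interfaces=5, max_size=6):
        rng = np.random.default_rng(seed)
        coords = rng.uniform(0.0, 25.0, size=(n_residues, 3))
        structure = Structure(
            chain_id="A",
            residues=[
                Residue(i + 1, *map(float, coords[i])) for i in range(n_residues)
            ],
            source_id=f"rand{seed}",
        )
        interfaces = []
        for k in range(n_interfaces):
            size = int(rng.integers(1, max_size + 1))
            picks = rng.choice(n_residues, size=size, replace=False) + 1
            interfaces.append(Interface.from_iterable(f"if{k:02d}-rand", picks))
        return structure, InterfaceSet(interfaces=interfaces)

    return _make


@pytest.fixture
def write_interface_json(tmp_path):
    def _write(mapping, filename="interfaces.json"):
        path = tmp_path / filename
        path.write_text(json.dumps(mapping))
        return path

    return _write
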