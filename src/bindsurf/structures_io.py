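"""Structure and interface I/O.

Structures are reduced to one C-alpha record per residue of a single
chain.  Interfaces are named residue-number sets read from a JSON file
and are projected onto a structure by the coverage filter before any
geometry is computed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .errors import (
    ChainAmbiguityError,
    EmptyFilterError,
    InterfaceFileError,
    PDBParseError,
    ValidationError,
)

__all__ = [
    "Residue",
    "Structure",
    "Interface",
    "InterfaceSet",
    "read_pdb",
    "write_pdb",
    "read_interface_file",
    "filter_interfaces",
    "select_best_structure",
]


@dataclass(frozen=True)
class Residue:
    """One C-alpha record: residue number plus coordinates in Angstrom."""

    number: int
    x: float
    y: float
    z: float
    name: str = "ALA"


@dataclass
class Structure:
    """Ordered C-alpha trace of a single chain.

    Invariants: residue numbers unique and ascending, coordinates
    finite, at least one residue.  Enforced at construction.
    """

    chain_id: str
    residues: list[Residue]
    source_id: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError("structure must contain at least one residue")
        numbers = [r.number for r in self.residues]
        if len(set(numbers)) != len(numbers):
            raise ValidationError("duplicate residue numbers in structure")
        if numbers != sorted(numbers):
            self.residues = sorted(self.residues, key=lambda r: r.number)
        for r in self.residues:
            if not all(math.isfinite(v) for v in (r.x, r.y, r.z)):
                raise ValidationError(
                    f"non-finite coordinates for residue {r.number}"
                )

    @property
    def residue_numbers(self) -> list[int]:
        return [r.number for r in self.residues]

    def __len__(self) -> int:
        return len(self.residues)

    def __contains__(self, number: int) -> bool:
        return number in self._number_set

    @property
    def _number_set(self) -> frozenset[int]:
        return frozenset(r.number for r in self.residues)


@dataclass(frozen=True)
class Interface:
    """A named set of residue numbers on the common numbering scheme."""

    name: str
    residues: frozenset[int]

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError(f"interface {self.name!r} has no residues")
        if any(n <= 0 for n in self.residues):
            raise ValidationError(
                f"interface {self.name!r} has non-positive residue numbers"
            )

    @classmethod
    def from_iterable(cls, name: str, residues: Iterable[int]) -> "Interface":
        return cls(name, frozenset(int(r) for r in residues))

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class InterfaceSet:
    """Ordered collection of uniquely named interfaces."""

    interfaces: list[Interface] = field(default_factory=list)
    reference: Optional[Structure] = None

    def __post_init__(self) -> None:
        names = [i.name for i in self.interfaces]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate interface names: {dupes}")

    @property
    def names(self) -> list[str]:
        return [i.name for i in self.interfaces]

    def by_name(self) -> dict[str, Interface]:
        return {i.name: i for i in self.interfaces}

    def __len__(self) -> int:
        return len(self.interfaces)

    def __iter__(self):
        return iter(self.interfaces)


# --- PDB parsing ------------------------------------------------------------
# Fixed-column ATOM record layout (PDB format v3.3).  Only the fields we
# consume are sliced; everything else is ignored on read.

def _parse_atom_line(line: str):
    name = line[12:16].strip()
    altloc = line[16]
    resname = line[17:20].strip() or "UNK"
    chain = line[21]
    try:
        resseq = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError as exc:
        raise PDBParseError(f"malformed ATOM record: {line.rstrip()!r}") from exc
    icode = line[26] if len(line) > 26 else " "
    return name, altloc, resname, chain, resseq, icode, (x, y, z)


def read_pdb(path: str | Path, chain: Optional[str] = None) -> Structure:
    """Read one chain of a PDB file as a C-alpha trace.

    Only ``ATOM`` records named ``CA`` are kept, one per residue (the
    first occurrence wins, which also resolves altlocs).  HETATM and
    other atoms are ignored; only the first model of a multi-model file
    is read.  Residues carrying an insertion code are rejected so that
    residue keys stay integral.

    Parameters
    ----------
    path : path to a PDB file.
    chain : chain identifier; may be omitted only when the file
        contains a single chain.
    """
    path = Path(path)
    chains_seen: set[str] = set()
    records: dict[str, dict[int, Residue]] = {}
    in_first_model = True
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "MODEL ":
                continue
            if rec == "ENDMDL":
                in_first_model = False
                continue
            if not in_first_model or rec != "ATOM  ":
                continue
            name, _altloc, resname, ch, resseq, icode, xyz = _parse_atom_line(line)
            chains_seen.add(ch)
            if name != "CA":
                continue
            if icode != " ":
                raise PDBParseError(
                    f"residue {resseq}{icode.strip()} of chain {ch!r} carries an "
                    "insertion code; renumber the structure first"
                )
            per_chain = records.setdefault(ch, {})
            if resseq not in per_chain:  # first CA wins
                per_chain[resseq] = Residue(resseq, *xyz, name=resname)

    if not chains_seen:
        raise PDBParseError(f"{path}: no ATOM records found")
    if chain is None:
        if len(chains_seen) > 1:
            raise ChainAmbiguityError(chains_seen)
        chain = next(iter(chains_seen))
    if chain not in chains_seen:
        raise PDBParseError(
            f"{path}: chain {chain!r} not present "
            f"(available: {', '.join(sorted(chains_seen))})"
        )
    ca = records.get(chain)
    if not ca:
        raise PDBParseError(f"{path}: chain {chain!r} has no CA atoms")
    residues = [ca[n] for n in sorted(ca)]
    return Structure(chain_id=chain, residues=residues, source_id=path.stem)


_ATOM_FMT = (
    "ATOM  {serial:5d}  CA  {resname:<3s} {chain}{resseq:4d}    "
    "{x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}           C  \n"
)


def write_pdb(
    structure: Structure,
    path: str | Path,
    bfactors: Optional[Mapping[int, float]] = None,
) -> None:
    """Write the C-alpha trace as fixed-width ATOM records.

    ``bfactors`` maps residue number to the temperature-factor value;
    residues not in the map get 0.00.
    """
    bfactors = bfactors or {}
    with open(path, "w") as fh:
        for serial, r in enumerate(structure.residues, start=1):
            fh.write(
                _ATOM_FMT.format(
                    serial=serial,
                    resname=r.name[:3],
                    chain=structure.chain_id,
                    resseq=r.number,
                    x=r.x,
                    y=r.y,
                    z=r.z,
                    occ=1.0,
                    b=bfactors.get(r.number, 0.0),
                )
            )
        fh.write("END\n")


# --- interface file ---------------------------------------------------------

def _reject_duplicate_keys(pairs):
    seen = set()
    for key, _ in pairs:
        if key in seen:
            raise InterfaceFileError(f"duplicate interface name {key!r}")
        seen.add(key)
    return dict(pairs)


def read_interface_file(path: str | Path) -> InterfaceSet:
    """Read a JSON interface file: name -> array of residue numbers.

    File order is preserved; duplicate residue numbers within one
    interface are deduplicated; duplicate names are an error.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            raw = json.load(fh, object_pairs_hook=_reject_duplicate_keys)
    except json.JSONDecodeError as exc:
        raise InterfaceFileError(
            f"{path}: malformed JSON at line {exc.lineno}: {exc.msg}"
        ) from exc
    if not isinstance(raw, dict):
        raise InterfaceFileError(f"{path}: expected a JSON object at top level")
    interfaces = []
    for name, residues in raw.items():
        if not isinstance(residues, list) or not all(
            isinstance(r, int) and not isinstance(r, bool) for r in residues
        ):
            raise InterfaceFileError(
                f"{path}: value for {name!r} must be an array of integers"
            )
        if not residues:
            raise ValidationError(f"{path}: interface {name!r} has an empty residue list")
        interfaces.append(Interface.from_iterable(name, residues))
    return InterfaceSet(interfaces=interfaces)


# --- coverage filter --------------------------------------------------------

def coverage(interface: Interface, structure: Structure) -> float:
    """Fraction of the interface's residues present in the structure."""
    present = interface.residues & structure._number_set
    return len(present) / len(interface.residues)


def filter_interfaces(
    ifs: InterfaceSet,
    structure: Structure,
    cov_cutoff: float = 0.7,
    strict: bool = False,
) -> InterfaceSet:
    """Keep interfaces with coverage >= ``cov_cutoff`` and project them.

    Coverage is counted against the interface's full residue list; the
    boundary is inclusive.  Residues of a retained interface that are
    absent from the structure are dropped so downstream sums are
    well-defined.  With ``strict=True`` any interface below the cutoff
    raises instead of being silently removed.
    """
    if not 0 < cov_cutoff <= 1:
        raise ValidationError("cov_cutoff must be in (0, 1]")
    present_set = structure._number_set
    kept: list[Interface] = []
    for iface in ifs:
        cov = coverage(iface, structure)
        if cov >= cov_cutoff:
            kept.append(Interface(iface.name, iface.residues & present_set))
        elif strict:
            raise ValidationError(
                f"interface {iface.name!r} coverage {cov:.2f} below "
                f"cutoff {cov_cutoff:.2f}"
            )
    if not kept:
        raise EmptyFilterError(
            "no interface passed the coverage filter; try a different "
            "structure or lower --int-cov-cutoff"
        )
    return InterfaceSet(interfaces=kept, reference=structure)


def count_retained(ifs: InterfaceSet, structure: Structure, cov_cutoff: float = 0.7) -> int:
    """Number of interfaces that would survive :func:`filter_interfaces`."""
    return sum(1 for i in ifs if coverage(i, structure) >= cov_cutoff)


def select_best_structure(
    candidates: Sequence[Structure],
    ifs: InterfaceSet,
    cov_cutoff: float = 0.7,
) -> Structure:
    """Pick the candidate retaining the most interfaces.

    Ties go to the earliest candidate, mirroring an upstream ranking by
    coverage and resolution.
    """
    if not candidates:
        raise ValidationError("no candidate structures given")
    best = max(
        range(len(candidates)),
        key=lambda i: (count_retained(ifs, candidates[i], cov_cutoff), -i),
    )
    return candidates[best]
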