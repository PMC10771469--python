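"""Ambiguous interaction restraints from two clustering runs.

Every (receptor surface, ligand surface) pair becomes one candidate
restraint set; within each surface only residues observed with
probability >= p_thr (default 0.3) are kept.  Each receptor residue is
restrained ambiguously against the full filtered ligand list, in a
HADDOCK-style distance-restraint dialect.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

from .clustering import ClusteringResult
from .errors import ValidationError

__all__ = [
    "DEFAULT_P_THR",
    "RestraintCombination",
    "generate_combinations",
    "write_restraint_files",
]

DEFAULT_P_THR = 0.3

#: Effective upper distance (Angstrom) of the ambiguous restraint; the
#: dialect names a target but not this number, so it is configurable.
DEFAULT_AIR_DISTANCE = 2.0


@dataclass(frozen=True)
class RestraintCombination:
    receptor_cluster: int
    ligand_cluster: int
    receptor_residues: tuple[int, ...]
    ligand_residues: tuple[int, ...]
    p_thr: float

    def __post_init__(self) -> None:
        if not self.receptor_residues or not self.ligand_residues:
            raise ValidationError("restraint combination has an empty residue list")


def generate_combinations(
    rec: ClusteringResult,
    lig: ClusteringResult,
    p_thr: float = DEFAULT_P_THR,
) -> list[RestraintCombination]:
    """One combination per (receptor surface, ligand surface) pair.

    Combinations whose filtered residue list is empty on either side
    are dropped with a warning; the pre-filter count is always
    N_rec x N_lig.  The threshold comparison is inclusive (>=), which
    keeps p_thr = 1.0 usable for unanimous residues.
    """
    if not rec.profiles or not lig.profiles:
        raise ValidationError("both clustering results must be non-empty")
    if not 0.0 <= p_thr <= 1.0:
        raise ValidationError("p_thr must be in [0, 1]")
    combos: list[RestraintCombination] = []
    for rp in rec.profiles:
        rec_res = rp.residues_above(p_thr)
        for lp in lig.profiles:
            lig_res = lp.residues_above(p_thr)
            if not rec_res or not lig_res:
                warnings.warn(
                    f"combination (rec {rp.cluster_id}, lig {lp.cluster_id}) "
                    f"dropped: no residue reaches p_thr={p_thr}",
                    stacklevel=2,
                )
                continue
            combos.append(
                RestraintCombination(
                    receptor_cluster=rp.cluster_id,
                    ligand_cluster=lp.cluster_id,
                    receptor_residues=tuple(rec_res),
                    ligand_residues=tuple(lig_res),
                    p_thr=p_thr,
                )
            )
    if not combos:
        raise ValidationError(
            f"no combination survives p_thr={p_thr}; lower the threshold"
        )
    return combos


def _ambig_statement(
    rec_residue: int,
    lig_residues: tuple[int, ...],
    rec_segid: str,
    lig_segid: str,
    distance: float,
) -> str:
    lines = [f"assign (resid {rec_residue} and segid {rec_segid})", "       ("]
    for i, res in enumerate(lig_residues):
        if i:
            lines.append("     or")
        lines.append(f"        (resid {res} and segid {lig_segid})")
    lines.append(f"       ) {distance:.1f} {distance:.1f} 0.0")
    return "\n".join(lines) + "\n"


def write_restraint_files(
    combos: list[RestraintCombination],
    out_dir: str | Path,
    rec_segid: str = "A",
    lig_segid: str = "B",
    distance: float = DEFAULT_AIR_DISTANCE,
) -> list[Path]:
    """Write one ``.tbl`` plus one JSON sidecar per combination.

    The table holds one ambiguous statement per receptor residue, each
    listing the full ligand residue list as alternatives.  Ordering is
    ascending residue number throughout, so regeneration is
    byte-identical.
    """
    if not combos:
        raise ValidationError("no restraint combinations to write")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for combo in combos:
        stem = f"ambig_{combo.receptor_cluster}_{combo.ligand_cluster}"
        tbl = out_dir / f"{stem}.tbl"
        with open(tbl, "w") as fh:
            for res in combo.receptor_residues:
                fh.write(
                    _ambig_statement(
                        res, combo.ligand_residues, rec_segid, lig_segid, distance
                    )
                )
                fh.write("\n")
        sidecar = out_dir / f"{stem}.json"
        with open(sidecar, "w") as fh:
            json.dump(
                {
                    "receptor_cluster": combo.receptor_cluster,
                    "ligand_cluster": combo.ligand_cluster,
                    "receptor_residues": list(combo.receptor_residues),
                    "ligand_residues": list(combo.ligand_residues),
                    "p_thr": combo.p_thr,
                },
                fh,
                indent=1,
                sort_keys=True,
            )
            fh.write("\n")
        written.extend([tbl, sidecar])
    return written
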