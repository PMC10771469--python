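"""Synthetic structures with planted binding surfaces.

An ideal alpha-helical C-alpha trace (3.8 Angstrom consecutive
spacing) carries k disjoint residue patches, far enough apart that
their Gaussian couplings vanish.  Each patch is replicated into noisy
interface copies via per-residue dropout, giving ground-truth cluster
labels for recovery tests.  Everything is deterministic for a fixed
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from .errors import ValidationError
from .structures_io import Interface, InterfaceSet, Residue, Structure, write_pdb

__all__ = ["CA_SPACING", "PlantedScenario", "helix_structure", "generate_scenario", "write_scenario"]

#: Consecutive C-alpha spacing on the synthetic trace, Angstrom.
CA_SPACING = 3.8

_RISE = 1.5          # axial rise per residue, Angstrom
_TWIST = math.radians(100.0)  # rotation per residue

# helix radius chosen so the consecutive C-alpha distance is CA_SPACING
_RADIUS = math.sqrt(CA_SPACING**2 - _RISE**2) / (2.0 * math.sin(_TWIST / 2.0))


@dataclass
class PlantedScenario:
    structure: Structure
    interfaces: InterfaceSet
    truth: dict[str, int]
    surfaces: list[list[int]]
    seed: int


def helix_structure(
    n_residues: int,
    jitter: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    chain_id: str = "A",
) -> Structure:
    """Ideal alpha-helix C-alpha trace, residues numbered 1..n.

    ``jitter`` adds isotropic Gaussian noise of that standard deviation
    to every coordinate.
    """
    if n_residues < 1:
        raise ValidationError("need at least one residue")
    i = np.arange(n_residues)
    coords = np.column_stack(
        [
            _RADIUS * np.cos(i * _TWIST),
            _RADIUS * np.sin(i * _TWIST),
            i * _RISE,
        ]
    )
    if jitter > 0:
        if rng is None:
            rng = np.random.default_rng()
        coords = coords + rng.normal(scale=jitter, size=coords.shape)
    residues = [
        Residue(int(n + 1), float(x), float(y), float(z))
        for n, (x, y, z) in zip(i, coords)
    ]
    return Structure(chain_id=chain_id, residues=residues, source_id="synthetic-helix")


def generate_scenario(
    k: int,
    patch_size: int,
    replicates: int,
    dropout: float = 0.0,
    seed: int = 0,
    gap: int = 20,
    jitter: float = 0.0,
    n_residues: Optional[int] = None,
    min_separation: float = 7.6,
) -> PlantedScenario:
    """Plant ``k`` surfaces of ``patch_size`` residues with noisy replicates.

    Patches are contiguous residue runs separated by ``gap`` residues
    along the chain.  Each of the ``replicates`` interfaces per patch
    drops every patch residue independently with probability
    ``dropout`` (a replicate that would end up empty keeps one random
    residue).  The minimum spatial distance between patches is checked
    against ``min_separation`` (default 4 sigma at the shipped Gaussian
    width) and a sizing error is raised if it cannot be met.
    """
    if k < 1 or patch_size < 1 or replicates < 1:
        raise ValidationError("k, patch_size and replicates must be >= 1")
    if not 0.0 <= dropout < 1.0:
        raise ValidationError("dropout must be in [0, 1)")
    needed = k * patch_size + (k - 1) * gap + 2
    if n_residues is None:
        n_residues = needed
    elif n_residues < needed:
        raise ValidationError(
            f"cannot place {k} disjoint patches of {patch_size} residues with "
            f"gap {gap} on a {n_residues}-residue chain (need {needed})"
        )
    rng = np.random.default_rng(seed)
    structure = helix_structure(n_residues, jitter=jitter, rng=rng)

    surfaces: list[list[int]] = []
    start = 2  # keep one plain residue at each end
    for _ in range(k):
        surfaces.append(list(range(start, start + patch_size)))
        start += patch_size + gap

    _check_separation(structure, surfaces, min_separation)

    interfaces = []
    truth: dict[str, int] = {}
    for p, patch in enumerate(surfaces, start=1):
        for j in range(1, replicates + 1):
            kept = [r for r in patch if rng.random() >= dropout]
            if not kept:
                kept = [patch[int(rng.integers(len(patch)))]]
            name = f"partner{p:02d}r{j:02d}-synth"
            interfaces.append(Interface.from_iterable(name, kept))
            truth[name] = p
    return PlantedScenario(
        structure=structure,
        interfaces=InterfaceSet(interfaces=interfaces, reference=structure),
        truth=truth,
        surfaces=surfaces,
        seed=seed,
    )


def _check_separation(structure: Structure, surfaces, min_separation: float) -> None:
    coord_of = {r.number: np.array([r.x, r.y, r.z]) for r in structure.residues}
    for a in range(len(surfaces)):
        for b in range(a + 1, len(surfaces)):
            dmin = min(
                float(np.linalg.norm(coord_of[i] - coord_of[j]))
                for i in surfaces[a]
                for j in surfaces[b]
            )
            if dmin <= min_separation:
                raise ValidationError(
                    f"patches {a + 1} and {b + 1} are only {dmin:.1f} A apart "
                    f"(need > {min_separation} A); increase the gap"
                )


def write_scenario(scenario: PlantedScenario, out_dir: str | Path) -> None:
    """Dump fixture.pdb, interfaces.json and truth.tsv into ``out_dir``."""
    import json

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_pdb(scenario.structure, out_dir / "fixture.pdb")
    with open(out_dir / "interfaces.json", "w") as fh:
        json.dump(
            {i.name: sorted(i.residues) for i in scenario.interfaces},
            fh,
            indent=1,
        )
        fh.write("\n")
    with open(out_dir / "truth.tsv", "w") as fh:
        fh.write("interface\tsurface\n")
        for name, surface in scenario.truth.items():
            fh.write(f"{name}\t{surface}\n")
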