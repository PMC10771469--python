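"""Spatial clustering of a flat residue list on a structure.

Unlike interface clustering, the objects here are single residues, so
the distance matrix is plain C-alpha to C-alpha Euclidean distance.
Defaults: average linkage, 15 Angstrom cutoff, "distance" criterion.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist

from .clustering import LINKAGES
from .errors import MissingResidueError, ValidationError
from .structures_io import Structure

__all__ = ["DEFAULT_CUTOFF", "ResidueClusterResult", "cluster_residues", "write_residue_clusters"]

DEFAULT_CUTOFF = 15.0

_CRITERIA = ("distance", "maxclust")


@dataclass
class ResidueClusterResult:
    clusters: dict[int, list[int]]
    cutoff: float
    linkage: str
    criterion: str

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def cluster_residues(
    residues: Sequence[int],
    structure: Structure,
    linkage: str = "average",
    cutoff: float = DEFAULT_CUTOFF,
    criterion: str = "distance",
) -> ResidueClusterResult:
    """Agglomerative clustering of residues by C-alpha distance.

    The dendrogram is cut at ``cutoff`` (inclusive) under the given
    criterion.  Cluster ids run 1..k by decreasing size, ties broken by
    the first residue's input position.
    """
    if not residues:
        raise ValidationError("need at least one residue")
    if linkage not in LINKAGES:
        raise ValidationError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    if criterion not in _CRITERIA:
        raise ValidationError(f"unknown criterion {criterion!r}; choose from {_CRITERIA}")
    if cutoff <= 0:
        raise ValidationError("cutoff must be positive")
    residues = [int(r) for r in residues]
    if len(set(residues)) != len(residues):
        raise ValidationError("duplicate residues in input list")
    coord_of = {r.number: (r.x, r.y, r.z) for r in structure.residues}
    missing = sorted(set(residues) - set(coord_of))
    if missing:
        raise MissingResidueError(
            f"residues absent from the structure: {missing}"
        )
    if len(residues) == 1:
        clusters = {1: list(residues)}
    else:
        coords = np.array([coord_of[r] for r in residues], dtype=float)
        tree = scipy_linkage(pdist(coords), method=linkage)
        labels = fcluster(tree, t=cutoff, criterion=criterion)
        groups: dict[int, list[int]] = {}
        for pos, lab in enumerate(labels):
            groups.setdefault(int(lab), []).append(pos)
        ordered = sorted(groups.values(), key=lambda idxs: (-len(idxs), idxs[0]))
        clusters = {
            cid: [residues[i] for i in idxs]
            for cid, idxs in enumerate(ordered, start=1)
        }
    return ResidueClusterResult(
        clusters=clusters, cutoff=cutoff, linkage=linkage, criterion=criterion
    )


def write_residue_clusters(result: ResidueClusterResult, path: str | Path) -> None:
    """TSV dump: one ``residue<TAB>cluster_id`` row per residue."""
    with open(path, "w") as fh:
        fh.write("residue\tcluster_id\n")
        for cid in sorted(result.clusters):
            for res in sorted(result.clusters[cid]):
                fh.write(f"{res}\t{cid}\n")
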