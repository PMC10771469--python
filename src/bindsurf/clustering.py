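"""Binding-surface extraction from the similarity matrix.

Agglomerative hierarchical clustering on sin-theta distances; the
dendrogram is cut at a fixed threshold (default sin 60 deg = 0.866,
inclusive).  Clusters are renumbered 1..k by decreasing size, ties
broken by the smallest first-member index, so the labelling is
deterministic and independent of the engine's internal order.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from .errors import ValidationError
from .similarity import SimilarityMatrix
from .structures_io import Interface, Structure, write_pdb

__all__ = [
    "DEFAULT_THRESHOLD",
    "LINKAGES",
    "sine_of_angle",
    "ClusterProfile",
    "ClusteringResult",
    "cluster_interfaces",
    "residue_probabilities",
    "write_probability_pdb",
    "save_result",
    "load_result",
]

LINKAGES = ("average", "single", "complete", "ward")

#: Default dendrogram cut: the sine of a 60-degree inter-interface angle.
DEFAULT_THRESHOLD = 0.866


def sine_of_angle(degrees: float) -> float:
    """Sine of an angle given in degrees (threshold helper)."""
    return math.sin(math.radians(degrees))


@dataclass
class ClusterProfile:
    """One binding surface: its member interfaces and residue probabilities.

    ``probabilities[i]`` is the fraction of member interfaces that
    contain residue ``i``; residues never observed are absent.
    """

    cluster_id: int
    members: list[str]
    probabilities: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError("cluster must have at least one member")
        for res, p in self.probabilities.items():
            if not 0.0 < p <= 1.0:
                raise ValidationError(
                    f"probability for residue {res} out of (0, 1]: {p}"
                )

    def residues_above(self, p_thr: float) -> list[int]:
        """Residues with probability >= ``p_thr``, sorted."""
        return sorted(r for r, p in self.probabilities.items() if p >= p_thr)


@dataclass
class ClusteringResult:
    profiles: list[ClusterProfile]
    linkage: str
    threshold: float
    assignment: dict[str, int]

    @property
    def n_clusters(self) -> int:
        return len(self.profiles)

    def partition(self) -> set[frozenset[str]]:
        """Label-free view of the clustering, for comparisons."""
        return {frozenset(p.members) for p in self.profiles}


def residue_probabilities(
    members: Sequence[str],
    interfaces: Mapping[str, Interface],
    cluster_id: int = 1,
) -> ClusterProfile:
    """Per-residue occupancy fractions over a cluster's members."""
    if not members:
        raise ValidationError("cluster must have at least one member")
    counts: dict[int, int] = {}
    for name in members:
        if name not in interfaces:
            raise ValidationError(f"unknown interface name {name!r}")
        for res in interfaces[name].residues:
            counts[res] = counts.get(res, 0) + 1
    n = len(members)
    probabilities = {res: c / n for res, c in sorted(counts.items())}
    return ClusterProfile(
        cluster_id=cluster_id, members=list(members), probabilities=probabilities
    )


def cluster_interfaces(
    sim: SimilarityMatrix,
    linkage: str = "average",
    threshold: float = DEFAULT_THRESHOLD,
    interfaces: Optional[Mapping[str, Interface]] = None,
) -> ClusteringResult:
    """Cut the sin-theta dendrogram into binding surfaces.

    The cut is inclusive: pairs whose cophenetic distance equals the
    threshold exactly are merged.  A single input interface yields one
    singleton cluster without invoking the clustering engine.  When an
    ``interfaces`` mapping is supplied, per-residue probabilities are
    filled in; otherwise profiles carry members only.
    """
    if linkage not in LINKAGES:
        raise ValidationError(f"unknown linkage {linkage!r}; choose from {LINKAGES}")
    if not 0.0 < threshold <= 1.0:
        raise ValidationError("threshold must be in (0, 1]")
    sim.validate()
    names = sim.interface_names
    if len(names) == 1:
        labels = np.array([1])
    else:
        condensed = squareform(sim.values, checks=False)
        tree = scipy_linkage(condensed, method=linkage)
        labels = fcluster(tree, t=threshold, criterion="distance")
    return _build_result(names, labels, linkage, threshold, interfaces)


def _build_result(
    names: Sequence[str],
    labels: np.ndarray,
    linkage: str,
    threshold: float,
    interfaces: Optional[Mapping[str, Interface]],
) -> ClusteringResult:
    groups: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(idx)
    ordered = sorted(groups.values(), key=lambda idxs: (-len(idxs), idxs[0]))
    profiles = []
    assignment: dict[str, int] = {}
    for cid, idxs in enumerate(ordered, start=1):
        members = [names[i] for i in idxs]
        if interfaces is not None:
            profile = residue_probabilities(members, interfaces, cluster_id=cid)
        else:
            profile = ClusterProfile(cluster_id=cid, members=members)
        profiles.append(profile)
        for name in members:
            assignment[name] = cid
    return ClusteringResult(
        profiles=profiles, linkage=linkage, threshold=threshold, assignment=assignment
    )


def write_probability_pdb(
    structure: Structure,
    profile: ClusterProfile,
    path: str | Path,
) -> None:
    """Encode cluster probabilities into the B-factor column.

    Residues in the profile get beta = 50 (1 + P); everything else gets
    0.00, which makes the surface stand out in standard viewers.
    Profile residues missing from the structure are skipped with a
    warning.
    """
    present = set(structure.residue_numbers)
    missing = sorted(set(profile.probabilities) - present)
    if missing:
        warnings.warn(
            f"cluster {profile.cluster_id}: residues {missing} absent from the "
            "structure; skipped in the probability PDB",
            stacklevel=2,
        )
    bfactors = {
        res: 50.0 * (1.0 + p)
        for res, p in profile.probabilities.items()
        if res in present
    }
    write_pdb(structure, path, bfactors=bfactors)


# --- run-directory persistence ---------------------------------------------

def save_result(result: ClusteringResult, out_dir: str | Path) -> Path:
    """Serialise a clustering result as ``clusters.json`` in ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "linkage": result.linkage,
        "threshold": result.threshold,
        "clusters": [
            {
                "cluster_id": p.cluster_id,
                "members": p.members,
                "probabilities": {str(r): p.probabilities[r] for r in sorted(p.probabilities)},
            }
            for p in result.profiles
        ],
    }
    path = out_dir / "clusters.json"
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path


def load_result(run_dir: str | Path) -> ClusteringResult:
    """Load a clustering result written by :func:`save_result`."""
    path = Path(run_dir) / "clusters.json"
    if not path.exists():
        raise ValidationError(f"{path} not found; is this a run directory?")
    with open(path) as fh:
        payload = json.load(fh)
    profiles = [
        ClusterProfile(
            cluster_id=c["cluster_id"],
            members=list(c["members"]),
            probabilities={int(r): float(p) for r, p in c["probabilities"].items()},
        )
        for c in payload["clusters"]
    ]
    assignment = {m: p.cluster_id for p in profiles for m in p.members}
    return ClusteringResult(
        profiles=profiles,
        linkage=payload["linkage"],
        threshold=payload["threshold"],
        assignment=assignment,
    )
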