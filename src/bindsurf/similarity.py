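"""Gaussian-coupling similarity between interfaces.

Each interface is treated as an indicator vector over the C-alpha
atoms of the reference chain.  A Gaussian kernel over pairwise
C-alpha distances turns those vectors into elements of an inner
product space, where norms, scalar products, distances and angles
between interfaces are defined.  The similarity used downstream is
the sine of the angle: 0 for identical patches, 1 for patches so far
apart that their couplings vanish.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import MissingResidueError, ValidationError
from .structures_io import Interface, InterfaceSet, Structure

__all__ = [
    "DEFAULT_SIGMA",
    "CouplingMatrix",
    "SimilarityMatrix",
    "coupling_matrix",
    "interface_norm",
    "scalar_product",
    "pair_distance",
    "pair_sine",
    "similarity_matrix",
    "write_similarity",
]

#: Gaussian width in Angstrom: half the spacing of consecutive C-alpha atoms.
DEFAULT_SIGMA = 1.9


@dataclass
class CouplingMatrix:
    """Dense symmetric matrix of Gaussian couplings for one structure."""

    values: np.ndarray
    sigma: float
    residue_index: tuple[int, ...]
    _row_of: dict[int, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._row_of = {num: i for i, num in enumerate(self.residue_index)}

    def rows(self, interface: Interface) -> np.ndarray:
        """Matrix row indices for the interface's residues."""
        missing = [n for n in interface.residues if n not in self._row_of]
        if missing:
            raise MissingResidueError(
                f"interface {interface.name!r} has residues absent from the "
                f"structure: {sorted(missing)} (project interfaces first)"
            )
        return np.fromiter(
            (self._row_of[n] for n in sorted(interface.residues)),
            dtype=np.intp,
            count=len(interface.residues),
        )


@dataclass
class SimilarityMatrix:
    """Pairwise sin-theta values between named interfaces."""

    values: np.ndarray
    interface_names: list[str]

    def validate(self) -> None:
        v = self.values
        m = len(self.interface_names)
        if v.shape != (m, m):
            raise ValidationError("similarity matrix shape does not match names")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValidationError("similarity matrix is not symmetric")
        if np.any(np.diag(v) != 0.0):
            raise ValidationError("similarity matrix diagonal must be zero")
        if np.any(v < 0.0) or np.any(v > 1.0):
            raise ValidationError("similarity values must lie in [0, 1]")


def coupling_matrix(structure: Structure, sigma: float = DEFAULT_SIGMA) -> CouplingMatrix:
    """Gaussian couplings exp(-r^2 / 4 sigma^2) over all C-alpha pairs.

    The full dense matrix is computed; chains here are a few thousand
    residues at most.
    """
    if sigma <= 0:
        raise ValidationError("sigma must be positive")
    coords = np.array([[r.x, r.y, r.z] for r in structure.residues], dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValidationError("structure has non-finite coordinates")
    sq = squareform(pdist(coords, metric="sqeuclidean"))
    values = np.exp(-sq / (4.0 * sigma * sigma))
    np.fill_diagonal(values, 1.0)
    return CouplingMatrix(
        values=values,
        sigma=sigma,
        residue_index=tuple(structure.residue_numbers),
    )


def interface_norm(interface: Interface, coupling: CouplingMatrix) -> float:
    """Squared norm of an interface: double sum of couplings over its residues."""
    idx = coupling.rows(interface)
    return float(coupling.values[np.ix_(idx, idx)].sum())


def scalar_product(a: Interface, b: Interface, coupling: CouplingMatrix) -> float:
    """Inner product between two interfaces (rows from a, columns from b)."""
    ia = coupling.rows(a)
    ib = coupling.rows(b)
    return float(coupling.values[np.ix_(ia, ib)].sum())


def pair_distance(a: Interface, b: Interface, coupling: CouplingMatrix) -> float:
    """Hilbert-space distance sqrt(E(a) + E(b) - 2 <a, b>).

    The argument is clamped at zero against tiny negative floats.
    """
    arg = (
        interface_norm(a, coupling)
        + interface_norm(b, coupling)
        - 2.0 * scalar_product(a, b, coupling)
    )
    return float(np.sqrt(max(arg, 0.0)))


def pair_sine(a: Interface, b: Interface, coupling: CouplingMatrix) -> float:
    """Sine of the angle between two interfaces, in [0, 1].

    The cosine is clipped into [0, 1] first: couplings are strictly
    positive, so cos >= 0 analytically, but floating error can push it
    marginally above 1.  Identical residue sets give exactly 0.
    """
    if a.residues == b.residues:
        return 0.0
    cos = scalar_product(a, b, coupling) / np.sqrt(
        interface_norm(a, coupling) * interface_norm(b, coupling)
    )
    cos = min(max(cos, 0.0), 1.0)
    return float(np.sqrt(1.0 - cos * cos))


def similarity_matrix(
    ifs: InterfaceSet,
    structure: Structure,
    sigma: float = DEFAULT_SIGMA,
) -> SimilarityMatrix:
    """Pairwise sin-theta matrix over an interface set.

    Vectorized: with X the (m x n) indicator matrix of interfaces over
    residues, the Gram matrix X J X^T yields all norms and scalar
    products at once.
    """
    if len(ifs) < 1:
        raise ValidationError("need at least one interface")
    coupling = coupling_matrix(structure, sigma=sigma)
    n = len(coupling.residue_index)
    m = len(ifs)
    X = np.zeros((m, n))
    for i, iface in enumerate(ifs):
        X[i, coupling.rows(iface)] = 1.0
    gram = X @ coupling.values @ X.T
    norms = np.sqrt(np.diag(gram))
    cos = gram / np.outer(norms, norms)
    np.clip(cos, 0.0, 1.0, out=cos)
    sin = np.sqrt(1.0 - cos * cos)
    # exact zeros where residue sets coincide (incl. the diagonal)
    residue_sets = [iface.residues for iface in ifs]
    for i in range(m):
        for j in range(i, m):
            if residue_sets[i] == residue_sets[j]:
                sin[i, j] = sin[j, i] = 0.0
    sin = (sin + sin.T) / 2.0
    np.fill_diagonal(sin, 0.0)
    return SimilarityMatrix(values=sin, interface_names=list(ifs.names))


def write_similarity(sim: SimilarityMatrix, path: str | Path) -> None:
    """Dump the upper triangle as ``name_i name_j sin_theta`` (4 decimals)."""
    names = sim.interface_names
    with open(path, "w") as fh:
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                fh.write(f"{names[i]} {names[j]} {sim.values[i, j]:.4f}\n")
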