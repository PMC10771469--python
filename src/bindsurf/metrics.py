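"""Recognition entropy, composite docking quality, and their correlation.

The recognition entropy is the natural logarithm of the number of
binding-surface combinations between two partners.  The docking
quality score is a rank-weighted sum of best-model qualities over
docking methods and top-N cutoffs (top 1, 5, 10, 50, 100 indexed by
t = 1..5); qualities are 0/1/2/3 for incorrect / acceptable / medium /
high.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "TOP_ARRAY",
    "EntropyInput",
    "DockingQualityRecord",
    "recognition_entropy",
    "docking_quality",
    "entropy_quality_correlation",
    "read_quality_table",
    "read_cluster_counts",
]

#: Top-N cutoffs; the weight of each is its 1-based index in this array.
TOP_ARRAY = (1, 5, 10, 50, 100)

_VALID_Q = {0, 1, 2, 3}


@dataclass(frozen=True)
class EntropyInput:
    n_rec_clusters: int
    n_lig_clusters: int

    def __post_init__(self) -> None:
        if self.n_rec_clusters < 1 or self.n_lig_clusters < 1:
            raise ValidationError("cluster counts must be >= 1")


@dataclass(frozen=True)
class DockingQualityRecord:
    """Best-model qualities of one method at each top-array position.

    ``qualities[t]`` for t = 1..5.  Best-of-top-N cannot worsen as N
    grows, so the values must be non-decreasing in t.
    """

    method: str
    qualities: dict[int, int]

    def __post_init__(self) -> None:
        expected = set(range(1, len(TOP_ARRAY) + 1))
        if set(self.qualities) != expected:
            missing = sorted(expected - set(self.qualities))
            raise ValidationError(
                f"method {self.method!r}: qualities must cover t = 1..5 "
                f"(missing {missing})"
            )
        for t, q in self.qualities.items():
            if q not in _VALID_Q:
                raise ValidationError(
                    f"method {self.method!r}: quality {q} at t={t} not in 0..3"
                )
        ordered = [self.qualities[t] for t in sorted(self.qualities)]
        if any(b < a for a, b in zip(ordered, ordered[1:])):
            raise ValidationError(
                f"method {self.method!r}: qualities must be non-decreasing in t"
            )


def recognition_entropy(e: EntropyInput) -> float:
    """ln(N_rec_clusters * N_lig_clusters), in nats."""
    return math.log(e.n_rec_clusters * e.n_lig_clusters)


def docking_quality(records: Sequence[DockingQualityRecord]) -> float:
    """Sum over methods and top-array positions of Q_{m,t} / t."""
    if not records:
        raise ValidationError("need at least one docking-quality record")
    return float(
        sum(q / t for rec in records for t, q in rec.qualities.items())
    )


def entropy_quality_correlation(pairs: Sequence[tuple[float, float]]) -> float:
    """Pearson correlation between entropy and docking-quality values."""
    if len(pairs) < 3:
        raise ValidationError("need at least 3 (S, Q) pairs")
    s = np.array([p[0] for p in pairs], dtype=float)
    q = np.array([p[1] for p in pairs], dtype=float)
    if np.ptp(s) == 0 or np.ptp(q) == 0:
        raise ValidationError("correlation undefined for a constant column")
    return float(np.corrcoef(s, q)[0, 1])


# --- tiny TSV readers (invented plumbing) ----------------------------------

def read_quality_table(path: str | Path) -> dict[str, list[DockingQualityRecord]]:
    """TSV columns: complex, method, Q_top1, Q_top5, Q_top10, Q_top50, Q_top100.

    A leading ``#`` header line is allowed.  Returns records grouped by
    complex, preserving row order.
    """
    out: dict[str, list[DockingQualityRecord]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2 + len(TOP_ARRAY):
                raise ValidationError(
                    f"{path}:{lineno}: expected {2 + len(TOP_ARRAY)} columns, "
                    f"got {len(fields)}"
                )
            complex_id, method = fields[0], fields[1]
            try:
                qs = [int(v) for v in fields[2:]]
            except ValueError as exc:
                raise ValidationError(
                    f"{path}:{lineno}: qualities must be integers"
                ) from exc
            rec = DockingQualityRecord(
                method=method, qualities={t: q for t, q in enumerate(qs, start=1)}
            )
            out.setdefault(complex_id, []).append(rec)
    if not out:
        raise ValidationError(f"{path}: no data rows")
    return out


def read_cluster_counts(path: str | Path) -> dict[str, EntropyInput]:
    """TSV columns: complex, n_rec_clusters, n_lig_clusters."""
    out: dict[str, EntropyInput] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ValidationError(
                    f"{path}:{lineno}: expected 3 columns, got {len(fields)}"
                )
            try:
                out[fields[0]] = EntropyInput(int(fields[1]), int(fields[2]))
            except ValueError as exc:
                raise ValidationError(
                    f"{path}:{lineno}: counts must be integers"
                ) from exc
    if not out:
        raise ValidationError(f"{path}: no data rows")
    return out
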