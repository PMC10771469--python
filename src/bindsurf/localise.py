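"""Per-surface aggregation of partner annotations.

Given a clustering result and an offline partner -> annotation-term
table, count how often each term occurs among the distinct partners of
each binding surface.  Statistics are partner-level: a partner that
contributes several interfaces to the same cluster counts once.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .clustering import ClusteringResult
from .errors import ValidationError

__all__ = [
    "PartnerAnnotationTable",
    "ClusterAnnotationSummary",
    "read_annotation_table",
    "aggregate_annotations",
    "partner_from_interface_name",
    "write_annotation_summary",
]


@dataclass
class PartnerAnnotationTable:
    """partner id -> list of annotation terms (one namespace per run)."""

    rows: dict[str, list[str]] = field(default_factory=dict)

    def terms_for(self, partner: str) -> list[str] | None:
        return self.rows.get(partner)


@dataclass
class ClusterAnnotationSummary:
    cluster_id: int
    n_partners: int
    term_counts: dict[str, int]
    unannotated: int

    def fraction(self, term: str) -> float:
        return self.term_counts.get(term, 0) / self.n_partners


def read_annotation_table(path: str | Path) -> PartnerAnnotationTable:
    """TSV ``partner_id<TAB>term``; repeated rows give a partner several terms.

    A row with an empty term column marks a curated-but-unlabelled
    partner (empty term list).
    """
    rows: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (1, 2):
                raise ValidationError(
                    f"{path}:{lineno}: expected 'partner<TAB>term', got {line!r}"
                )
            partner = fields[0].strip()
            if not partner:
                raise ValidationError(f"{path}:{lineno}: empty partner id")
            term = fields[1].strip() if len(fields) == 2 else ""
            terms = rows.setdefault(partner, [])
            if term and term not in terms:
                terms.append(term)
    return PartnerAnnotationTable(rows=rows)


def partner_from_interface_name(name: str) -> str:
    """Default partner extraction: the part before the first dash.

    Interface names conventionally join a partner identifier and a
    structure identifier with a dash.
    """
    return name.split("-", 1)[0]


def aggregate_annotations(
    result: ClusteringResult,
    table: PartnerAnnotationTable,
    partner_of: Mapping[str, str],
) -> list[ClusterAnnotationSummary]:
    """Count annotation terms over the distinct partners of each cluster.

    Partners absent from the table are tallied under ``unannotated``
    with a warning.
    """
    missing_from_map = [
        m for p in result.profiles for m in p.members if m not in partner_of
    ]
    if missing_from_map:
        raise ValidationError(
            f"interfaces without a partner mapping: {sorted(missing_from_map)}"
        )
    summaries = []
    unknown_partners: set[str] = set()
    for profile in result.profiles:
        partners = sorted({partner_of[m] for m in profile.members})
        counts: dict[str, int] = {}
        unannotated = 0
        for partner in partners:
            terms = table.terms_for(partner)
            if terms is None:
                unknown_partners.add(partner)
                unannotated += 1
                continue
            if not terms:
                unannotated += 1
                continue
            for term in terms:
                counts[term] = counts.get(term, 0) + 1
        summaries.append(
            ClusterAnnotationSummary(
                cluster_id=profile.cluster_id,
                n_partners=len(partners),
                term_counts=dict(sorted(counts.items())),
                unannotated=unannotated,
            )
        )
    if unknown_partners:
        warnings.warn(
            f"partners missing from the annotation table, counted as "
            f"unannotated: {sorted(unknown_partners)}",
            stacklevel=2,
        )
    return summaries


def write_annotation_summary(
    summaries: list[ClusterAnnotationSummary], path: str | Path
) -> None:
    """TSV: cluster_id, term, count, fraction (4 decimals)."""
    with open(path, "w") as fh:
        fh.write("cluster_id\tterm\tcount\tfraction\n")
        for s in summaries:
            for term, count in s.term_counts.items():
                fh.write(f"{s.cluster_id}\t{term}\t{count}\t{count / s.n_partners:.4f}\n")
            if s.unannotated:
                fh.write(
                    f"{s.cluster_id}\tunannotated\t{s.unannotated}\t"
                    f"{s.unannotated / s.n_partners:.4f}\n"
                )
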