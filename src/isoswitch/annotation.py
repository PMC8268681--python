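"""Transcript and gene structural models.

Transcripts are represented in genomic coordinates (0-based, half-open
intervals) together with an optional CDS and a set of protein-domain
annotations.  All downstream comparisons between the up- and
down-regulated isoform of a switch (UTR lengths, intron counts, domain
sets, coding status) are derived from these models via
:func:`structural_features`.

Domain annotations are consumed as an external side table (e.g. from an
hmmscan run); this package never predicts ORFs or domains itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AnnotationError",
    "TranscriptModel",
    "GeneModel",
    "FeatureVector",
    "structural_features",
    "median_isoform_length",
]

Interval = tuple[int, int]


class AnnotationError(ValueError):
    """Raised when a transcript or gene model violates its invariants."""


def _check_intervals(ivs: Sequence[Interval], what: str, tid: str) -> None:
    if not ivs:
        raise AnnotationError(f"{tid}: {what} list is empty")
    prev_end = None
    for start, end in ivs:
        if end <= start:
            raise AnnotationError(f"{tid}: {what} [{start},{end}) is empty or inverted")
        if prev_end is not None and start < prev_end:
            raise AnnotationError(f"{tid}: {what} intervals overlap or are unsorted")
        prev_end = end


@dataclass(frozen=True)
class TranscriptModel:
    """One isoform: exon/CDS structure plus domain annotations.

    Parameters
    ----------
    exons
        Genomic intervals, 0-based half-open, sorted by start, disjoint.
    cds
        Optional genomic intervals of the coding sequence; every CDS base
        must lie within an exon.  ``None`` for non-coding transcripts.
    domains
        ``(domain_name, start_aa, end_aa)`` triples; empty for
        non-coding transcripts.
    """

    transcript_id: str
    gene_id: str
    strand: str
    exons: tuple[Interval, ...]
    cds: tuple[Interval, ...] | None = None
    domains: frozenset[tuple[str, int, int]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.transcript_id}: strand must be '+' or '-'")
        object.__setattr__(self, "exons", tuple(map(tuple, self.exons)))
        _check_intervals(self.exons, "exon", self.transcript_id)
        if self.cds is not None:
            object.__setattr__(self, "cds", tuple(map(tuple, self.cds)))
            _check_intervals(self.cds, "CDS", self.transcript_id)
            for cs, ce in self.cds:
                if not any(es <= cs and ce <= ee for es, ee in self.exons):
                    raise AnnotationError(
                        f"{self.transcript_id}: CDS [{cs},{ce}) not contained in any exon"
                    )
        object.__setattr__(self, "domains", frozenset(self.domains))
        if not self.coding and self.domains:
            raise AnnotationError(
                f"{self.transcript_id}: non-coding transcript carries domain annotations"
            )

    @property
    def coding(self) -> bool:
        return self.cds is not None

    @property
    def length(self) -> int:
        """Spliced transcript length (sum of exon lengths, nt)."""
        return sum(e - s for s, e in self.exons)

    def genomic_to_spliced(self, gpos: int) -> int:
        """Map a genomic position to its 5'->3' spliced coordinate."""
        offset = 0
        for s, e in self.exons:
            if s <= gpos <= e:
                plus_coord = offset + (gpos - s)
                break
            offset += e - s
        else:
            raise AnnotationError(
                f"{self.transcript_id}: position {gpos} is not exonic"
            )
        if self.strand == "+":
            return plus_coord
        return self.length - plus_coord


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    gene_name: str
    transcripts: tuple[TranscriptModel, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "transcripts", tuple(self.transcripts))
        if not self.transcripts:
            raise AnnotationError(f"{self.gene_id}: gene has no transcripts")
        tids = [t.transcript_id for t in self.transcripts]
        if len(set(tids)) != len(tids):
            raise AnnotationError(f"{self.gene_id}: duplicate transcript_ids")
        for t in self.transcripts:
            if t.gene_id != self.gene_id:
                raise AnnotationError(
                    f"{self.gene_id}: member transcript {t.transcript_id} "
                    f"carries gene_id {t.gene_id}"
                )

    def __iter__(self) -> Iterable[TranscriptModel]:
        return iter(self.transcripts)


@dataclass(frozen=True)
class FeatureVector:
    """Structural features of one isoform, in spliced coordinates."""

    transcript_length: int
    utr5_length: int
    utr3_length: int
    intron_count: int
    domain_names: frozenset[str]
    coding: bool


def structural_features(t: TranscriptModel) -> FeatureVector:
    """Derive the structural feature vector of one transcript.

    Lengths are measured in spliced (mature transcript) coordinates.
    The 5'/3' orientation follows the strand: on the "-" strand the
    3'UTR is the genomically leftmost part of the transcript.
    Non-coding transcripts get UTR lengths of 0 by convention; their
    lack of an ORF is captured by ``coding=False``.
    """
    length = t.length
    introns = len(t.exons) - 1
    if not t.coding:
        return FeatureVector(length, 0, 0, introns, frozenset(), False)

    # spliced span of the CDS: min/max of spliced coords of its ends
    ends: list[int] = []
    for cs, ce in t.cds:
        ends.append(t.genomic_to_spliced(cs))
        ends.append(t.genomic_to_spliced(ce))
    cds_start, cds_end = min(ends), max(ends)
    utr5 = cds_start
    utr3 = length - cds_end
    names = frozenset(name for name, _, _ in t.domains)
    return FeatureVector(length, utr5, utr3, introns, names, True)


def median_isoform_length(g: GeneModel) -> float:
    """Median spliced length over a gene's isoforms.

    Even isoform counts return the mean of the two central lengths.
    """
    return float(np.median([t.length for t in g.transcripts]))
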