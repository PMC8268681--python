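"""Functional consequences of isoform switches.

Each switch pair is described from the perspective of the up-regulated
isoform relative to the down-regulated one: loss/gain of the ORF,
loss/gain of protein domains, intron count changes, and shortening or
lengthening of the UTRs and of the spliced transcript length.  A
genome-wide summary then asks, per category, whether one direction
dominates (e.g. 3'UTR shortening in melanomas), using an exact
two-sided binomial test against a symmetric null.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import binomtest

from .annotation import FeatureVector

__all__ = [
    "CONSEQUENCE_PAIRS",
    "ConsequenceRecord",
    "classify_pair",
    "classify_switches",
    "summarize",
]

# opposing category pairs; classification never emits both members for one pair
CONSEQUENCE_PAIRS: tuple[tuple[str, str], ...] = (
    ("ORF_loss", "ORF_gain"),
    ("domain_loss", "domain_gain"),
    ("intron_loss", "intron_gain"),
    ("utr3_shortened", "utr3_lengthened"),
    ("utr5_shortened", "utr5_lengthened"),
    ("length_shortened", "length_lengthened"),
)


@dataclass(frozen=True)
class ConsequenceRecord:
    gene_id: str
    up_isoform: str
    down_isoform: str
    consequences: frozenset[str]


def classify_pair(
    up: FeatureVector,
    down: FeatureVector,
    utr_min_diff: int = 50,
    len_min_diff: int = 50,
) -> frozenset[str]:
    """Consequence labels of the up- vs the down-regulated isoform.

    Domain loss and gain may co-occur (disjoint domain differences);
    all other opposing labels are mutually exclusive.  UTR categories
    are only assessed when both isoforms are coding, since non-coding
    transcripts have no defined UTRs.  UTR/length categories require a
    difference of at least the configured minimum (nt).
    """
    out: set[str] = set()
    if down.coding and not up.coding:
        out.add("ORF_loss")
    elif up.coding and not down.coding:
        out.add("ORF_gain")
    if up.domain_names - down.domain_names:
        out.add("domain_gain")
    if down.domain_names - up.domain_names:
        out.add("domain_loss")
    if up.intron_count < down.intron_count:
        out.add("intron_loss")
    elif up.intron_count > down.intron_count:
        out.add("intron_gain")
    if up.coding and down.coding:
        for label, u, d in (
            ("utr3", up.utr3_length, down.utr3_length),
            ("utr5", up.utr5_length, down.utr5_length),
        ):
            if d - u >= utr_min_diff:
                out.add(f"{label}_shortened")
            elif u - d >= utr_min_diff:
                out.add(f"{label}_lengthened")
    if down.transcript_length - up.transcript_length >= len_min_diff:
        out.add("length_shortened")
    elif up.transcript_length - down.transcript_length >= len_min_diff:
        out.add("length_lengthened")
    return frozenset(out)


def classify_switches(
    pairs: Iterable,
    features: Mapping[str, FeatureVector],
    utr_min_diff: int = 50,
    len_min_diff: int = 50,
) -> list[ConsequenceRecord]:
    """Classify every switch pair whose members have feature vectors."""
    records = []
    for sp in pairs:
        up = features.get(sp.up_isoform)
        down = features.get(sp.down_isoform)
        if up is None or down is None:
            raise KeyError(
                f"missing structural features for pair "
                f"({sp.up_isoform}, {sp.down_isoform})"
            )
        records.append(
            ConsequenceRecord(
                sp.gene_id,
                sp.up_isoform,
                sp.down_isoform,
                classify_pair(up, down, utr_min_diff, len_min_diff),
            )
        )
    return records


def summarize(records: Iterable[ConsequenceRecord]) -> pd.DataFrame:
    """Per-category gene counts and directional asymmetry.

    A gene counts once per category pair, in its majority direction over
    its switch pairs; genes with tied directions are dropped from both
    counts but remain in the denominator.  The asymmetry p-value is an
    exact two-sided binomial test of the first direction's count against
    a 50/50 split of the directional genes.
    """
    records = list(records)
    rows = []
    for first, second in CONSEQUENCE_PAIRS:
        votes: dict[str, int] = {}
        for rec in records:
            if first in rec.consequences:
                votes[rec.gene_id] = votes.get(rec.gene_id, 0) + 1
            elif second in rec.consequences:
                votes[rec.gene_id] = votes.get(rec.gene_id, 0) - 1
        n1 = sum(1 for v in votes.values() if v > 0)
        n2 = sum(1 for v in votes.values() if v < 0)
        ties = sum(1 for v in votes.values() if v == 0)
        total = n1 + n2 + ties
        if n1 + n2 > 0:
            p = binomtest(n1, n1 + n2, 0.5, alternative="two-sided").pvalue
        else:
            p = 1.0
        for label, count in ((first, n1), (second, n2)):
            rows.append(
                {
                    "category": label,
                    "genes_affected": count,
                    "genes_in_pair": total,
                    "ties": ties,
                    "fraction_of_genes": count / total if total else 0.0,
                    "asymmetry_p": p,
                }
            )
    return pd.DataFrame(rows)
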