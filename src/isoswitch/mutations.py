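"""Mutation-switch association statistics.

Two resampling statistics link mutation calls to switched genes and
isoforms:

* a per-gene Z-score of the average mutation-count difference between
  melanomas and nevi, referenced to a background of 100 genes with a
  similar median isoform length (mutation burden scales with gene
  length, so the background must be length-matched);
* a per-isoform Jaccard index between the melanoma samples carrying the
  switch and those carrying a mutation in the gene, referenced to the
  Jaccard indices of 200 length-matched switched isoforms.

Both use the threshold Z > 1.6 (one-sided, upper tail; the 90%
confidence bound used throughout the analysis).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MUTATION_CLASSES",
    "CODING_CLASSES",
    "UTR3_CLASSES",
    "MutationTable",
    "GeneMutationZ",
    "JaccardResult",
    "mutation_counts",
    "average_count_difference",
    "length_matched",
    "length_matched_genes",
    "gene_mutation_zscore",
    "jaccard_index",
    "mutated_sample_fraction",
    "jaccard_zscore",
]

MUTATION_CLASSES = frozenset(
    {"missense", "nonsense", "splice_site", "utr3", "utr5", "synonymous", "other"}
)
CODING_CLASSES = frozenset({"missense", "nonsense", "splice_site", "synonymous"})
UTR3_CLASSES = frozenset({"utr3"})

Z_THRESHOLD = 1.6


@dataclass
class MutationTable:
    """Per-sample, per-gene mutation records.

    ``records`` columns: sample_id, gene_id, transcript_id (may be
    empty), mut_class (fixed vocabulary), chrom, pos (0-based internal).
    """

    records: pd.DataFrame

    REQUIRED = ("sample_id", "gene_id", "mut_class")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise ValueError(f"mutation table missing columns: {missing}")
        bad = set(self.records["mut_class"]) - MUTATION_CLASSES
        if bad:
            raise ValueError(
                f"unknown mutation class(es) {sorted(bad)}; "
                f"allowed: {sorted(MUTATION_CLASSES)}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def filtered(self, class_filter: Iterable[str] | None) -> pd.DataFrame:
        if class_filter is None:
            return self.records
        class_filter = set(class_filter)
        bad = class_filter - MUTATION_CLASSES
        if bad:
            raise ValueError(f"unknown mutation class(es) in filter: {sorted(bad)}")
        return self.records[self.records["mut_class"].isin(class_filter)]

    def mutated_samples(
        self, gene_id: str, class_filter: Iterable[str] | None = None
    ) -> set[str]:
        sub = self.filtered(class_filter)
        return set(sub.loc[sub["gene_id"] == gene_id, "sample_id"])


@dataclass(frozen=True)
class GeneMutationZ:
    gene_id: str
    delta: float
    bg_mean: float
    bg_sd: float
    z: float
    significant: bool
    degenerate: bool = False


@dataclass(frozen=True)
class JaccardResult:
    isoform_id: str
    gene_id: str
    j: float
    mutated_fraction: float
    z: float
    significant: bool


def mutation_counts(
    muts: MutationTable,
    samples_by_group: Mapping[str, Sequence[str]],
    class_filter: Iterable[str] | None = None,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Gene x group mutation-record counts (multiple hits all count).

    ``genes`` fixes the output row universe (zero-filled); by default
    only mutated genes appear.
    """
    sub = muts.filtered(class_filter)
    sample_to_group = {
        s: g for g, samples in samples_by_group.items() for s in samples
    }
    grp = sub["sample_id"].map(sample_to_group)
    counts = (
        sub.assign(_group=grp)
        .dropna(subset=["_group"])
        .groupby(["gene_id", "_group"])
        .size()
        .unstack(fill_value=0)
    )
    counts = counts.reindex(columns=list(samples_by_group), fill_value=0)
    if genes is not None:
        counts = counts.reindex(genes, fill_value=0)
    counts.columns.name = None
    return counts


def average_count_difference(
    counts: pd.DataFrame, group_b: str, group_a: str, n_b: int, n_a: int
) -> pd.Series:
    """Per-gene per-sample-averaged count difference (group_b - group_a)."""
    if n_a < 1 or n_b < 1:
        raise ValueError("group sizes must be >= 1")
    return counts[group_b] / n_b - counts[group_a] / n_a


def length_matched(
    query_id: str,
    lengths: pd.Series,
    k: int,
    window: float = 0.2,
    seed: int | None = None,
) -> list[str]:
    """Select ``k`` ids with length similar to the query's.

    Candidates lie within a multiplicative window
    (|log L - log L_query| <= log(1 + window)); if enough, ``k`` are
    sampled uniformly without replacement with the given seed,
    otherwise all candidates are taken and topped up with the nearest
    remaining ids by log-length distance (ties by lexicographic id).
    """
    pool = lengths.drop(index=query_id, errors="ignore")
    if len(pool) < k:
        raise ValueError(f"pool of {len(pool)} smaller than k={k}")
    if (pool <= 0).any() or lengths[query_id] <= 0:
        raise ValueError("lengths must be positive")
    logd = (np.log(pool) - np.log(lengths[query_id])).abs()
    in_window = logd[logd <= np.log1p(window)]
    if len(in_window) >= k:
        rng = np.random.default_rng(seed)
        ids = np.array(sorted(in_window.index))
        return list(rng.choice(ids, size=k, replace=False))
    ranked = logd.to_frame("d").reset_index(names="id").sort_values(["d", "id"])
    return ranked["id"].head(k).tolist()


def length_matched_genes(
    query: str,
    gene_lengths: pd.Series,
    k: int = 100,
    window: float = 0.2,
    seed: int | None = None,
) -> list[str]:
    """Length-matched background genes (matching on median isoform length)."""
    if k < 2:
        raise ValueError("background size k must be >= 2")
    return length_matched(query, gene_lengths, k, window, seed)


def gene_mutation_zscore(
    gene_id: str,
    delta: float,
    background_deltas: Sequence[float],
    z_threshold: float = Z_THRESHOLD,
) -> GeneMutationZ:
    """Z-score of a gene's count difference against its background.

    ``z = (delta - mean(background)) / sd(background)``; significance is
    one-sided at Z > 1.6 (the 90% upper confidence bound).  A degenerate
    zero-spread background yields z = +inf when the gene exceeds the
    background mean, else 0, and is flagged.
    """
    bg = np.asarray(background_deltas, dtype=float)
    if bg.size < 2:
        raise ValueError("background must contain at least 2 genes")
    bg_mean = float(bg.mean())
    bg_sd = float(bg.std(ddof=1))
    if bg_sd == 0.0:
        z = float("inf") if delta > bg_mean else 0.0
        return GeneMutationZ(gene_id, delta, bg_mean, bg_sd, z, z > z_threshold, True)
    z = (delta - bg_mean) / bg_sd
    return GeneMutationZ(gene_id, float(delta), bg_mean, bg_sd, float(z), z > z_threshold)


def jaccard_index(switch_samples: set, mutated_samples: set) -> float:
    """|A n B| / |A u B|; an empty union yields 0 by convention."""
    union = switch_samples | mutated_samples
    if not union:
        return 0.0
    return len(switch_samples & mutated_samples) / len(union)


def mutated_sample_fraction(
    gene_id: str,
    muts: MutationTable,
    melanoma_samples: Sequence[str],
    class_filter: Iterable[str] | None = None,
) -> float:
    """Fraction of melanoma samples with >= 1 qualifying mutation in the gene."""
    if not len(melanoma_samples):
        raise ValueError("melanoma sample list is empty")
    mutated = muts.mutated_samples(gene_id, class_filter) & set(melanoma_samples)
    return len(mutated) / len(melanoma_samples)


def jaccard_zscore(
    isoform_id: str,
    gene_id: str,
    j_obs: float,
    mutated_fraction: float,
    length: float,
    pool: pd.DataFrame,
    k: int = 200,
    window: float = 0.2,
    seed: int | None = None,
    z_threshold: float = Z_THRESHOLD,
) -> JaccardResult:
    """Jaccard Z-score against length-matched switched isoforms.

    ``length`` is the target isoform's spliced transcript length.
    ``pool`` indexes other switched isoforms with columns ``length``
    and ``j`` — each pool member's own Jaccard index between its switch
    and mutation sample sets.  The null distribution is the J of ``k``
    pool isoforms of similar transcript length, drawn with the same
    windowed matching/top-up rule as the gene background.
    """
    pool = pool.drop(index=isoform_id, errors="ignore")
    lengths = pd.concat(
        [pool["length"].astype(float), pd.Series({isoform_id: float(length)})]
    )
    matched = length_matched(isoform_id, lengths, k, window, seed)
    null_j = pool.loc[matched, "j"].to_numpy(dtype=float)
    mean_null = float(null_j.mean())
    sd_null = float(null_j.std(ddof=1))
    if sd_null == 0.0:
        z = float("inf") if j_obs > mean_null else 0.0
    else:
        z = (j_obs - mean_null) / sd_null
    return JaccardResult(
        isoform_id, gene_id, float(j_obs), float(mutated_fraction), float(z),
        z > z_threshold,
    )
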