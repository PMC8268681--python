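"""Gene-set overrepresentation and cross-contrast overlap.

Overrepresentation of switched genes in curated gene sets uses the
upper-tail hypergeometric test against a configurable background
universe (by default, all genes surviving the expression filter), with
BH control across sets.  The enrichment ratio is the fold enrichment
(k/n)/(K/N).  The overlap operation counts exclusive and shared
switched isoforms/genes between pairwise contrasts (Venn counts).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .switching import bh_adjust

__all__ = ["GeneSet", "hypergeom_enrichment", "contrast_overlap", "pairwise_overlap"]


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValueError(f"gene set {self.set_id} is empty")


def hypergeom_enrichment(
    query: set[str],
    sets: Sequence[GeneSet],
    background: set[str],
) -> pd.DataFrame:
    """Hypergeometric overrepresentation of ``query`` in each gene set.

    Sets are intersected with the background before testing; p is the
    upper tail P(X >= k); FDR is BH across tested sets; results are
    sorted by p (ties by set_id).
    """
    if not background:
        raise ValueError("background universe is empty")
    query = set(query) & set(background)
    n = len(query)
    big_n = len(background)
    rows = []
    for gs in sets:
        members = gs.members & background
        k = len(query & members)
        big_k = len(members)
        ratio = (k / n) / (big_k / big_n) if n and big_k else 0.0
        p = float(hypergeom.sf(k - 1, big_n, big_k, n)) if k > 0 else 1.0
        rows.append(
            {
                "set_id": gs.set_id,
                "name": gs.name,
                "set_size": big_k,
                "overlap": k,
                "overlap_genes": ";".join(sorted(query & members)),
                "enrichment_ratio": ratio,
                "p": min(p, 1.0),
            }
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr"] = bh_adjust(out["p"]).to_numpy()
        out = out.sort_values(["p", "set_id"], kind="mergesort").reset_index(drop=True)
    return out


def pairwise_overlap(sets: Mapping[str, set[str]]) -> pd.DataFrame:
    """Exclusive and intersection counts for every pair of named sets."""
    rows = []
    for a, b in combinations(sorted(sets), 2):
        inter = sets[a] & sets[b]
        rows.append(
            {
                "set_a": a,
                "set_b": b,
                "exclusive_a": len(sets[a] - sets[b]),
                "intersection": len(inter),
                "exclusive_b": len(sets[b] - sets[a]),
                "size_a": len(sets[a]),
                "size_b": len(sets[b]),
            }
        )
    return pd.DataFrame(rows)


def contrast_overlap(
    switch_results: Mapping[str, tuple[set[str], set[str]]],
) -> pd.DataFrame:
    """Venn counts between contrasts at isoform and gene level.

    ``switch_results`` maps contrast name -> (switched isoform ids,
    switched gene ids).
    """
    if len(switch_results) < 2:
        raise ValueError("need at least 2 contrasts to overlap")
    frames = []
    for level, idx in (("isoform", 0), ("gene", 1)):
        df = pairwise_overlap({k: v[idx] for k, v in switch_results.items()})
        df.insert(0, "level", level)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
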