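"""Model/Results interface over the switch-detection machinery.

`IsoformSwitchModel` bundles an abundance matrix, a two-group contrast
and the analysis thresholds; `fit()` runs the expression filter,
isoform-fraction computation, permutation test, FDR adjustment and
antagonistic pair calling, returning an `IsoformSwitchResults` with the
per-isoform table, the called pairs and gene-level q-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .switching import (
    AbundanceMatrix,
    IsoformFractionMatrix,
    SwitchPair,
    bh_adjust,
    call_switch_pairs,
    delta_if,
    filter_low_expression,
    gene_switch_qvalue,
    isoform_fractions,
    per_sample_switch_calls,
    permutation_test_dtu,
)

__all__ = ["IsoformSwitchModel", "IsoformSwitchResults"]


class IsoformSwitchModel:
    """Differential transcript usage between two sample groups.

    Parameters
    ----------
    abundance
        Transcript x sample abundances with group labels.
    contrast
        ``(group_a, group_b)``; dIF is reported as group_b - group_a.
    min_mean_abundance, min_gene_abundance
        Expression filter thresholds (abundance units).
    eps
        Minimum gene expression below which fractions are missing.
    dif_threshold, q_threshold
        Antagonistic pair calling thresholds.
    n_perm, seed
        Permutation count and RNG seed (seed is mandatory).
    """

    def __init__(
        self,
        abundance: AbundanceMatrix,
        contrast: tuple[str, str],
        *,
        min_mean_abundance: float = 1.0,
        min_gene_abundance: float = 0.0,
        eps: float = 1.0,
        dif_threshold: float = 0.1,
        q_threshold: float = 0.05,
        n_perm: int = 1000,
        seed: int,
    ) -> None:
        for g in contrast:
            abundance.samples_in(g)  # validates non-empty
        self.abundance = abundance
        self.contrast = tuple(contrast)
        self.min_mean_abundance = min_mean_abundance
        self.min_gene_abundance = min_gene_abundance
        self.eps = eps
        self.dif_threshold = dif_threshold
        self.q_threshold = q_threshold
        self.n_perm = n_perm
        self.seed = seed

    @classmethod
    def from_dataframes(
        cls,
        values: pd.DataFrame,
        tx2gene: pd.Series,
        groups: pd.Series,
        contrast: tuple[str, str],
        **kwargs,
    ) -> "IsoformSwitchModel":
        return cls(AbundanceMatrix(values, tx2gene, groups), contrast, **kwargs)

    def fit(self) -> "IsoformSwitchResults":
        filtered = filter_low_expression(
            self.abundance, self.min_mean_abundance, self.min_gene_abundance
        )
        fractions = isoform_fractions(filtered, self.eps)
        dif = delta_if(fractions, self.contrast)
        p = permutation_test_dtu(
            fractions, self.contrast, n_perm=self.n_perm, seed=self.seed
        )
        q = bh_adjust(p)
        table = dif.assign(p=p, q=q)
        pairs = call_switch_pairs(
            table["dIF"],
            q,
            filtered.tx2gene,
            dIF_threshold=self.dif_threshold,
            q_threshold=self.q_threshold,
            p=p,
        )
        pairs, gene_table = gene_switch_qvalue(pairs, p, filtered.tx2gene)
        return IsoformSwitchResults(
            model=self,
            filtered=filtered,
            fractions=fractions,
            isoform_table=table,
            switch_pairs=pairs,
            gene_table=gene_table,
        )


@dataclass
class IsoformSwitchResults:
    """Fitted switch-detection results.

    Attributes
    ----------
    isoform_table
        Per-isoform gene_id, dIF, usable sample counts, p, q.
    switch_pairs
        Called antagonistic pairs sorted by min member q.
    gene_table
        Per-gene Bonferroni-min-p and BH q ("gene switch q-value").
    """

    model: IsoformSwitchModel
    filtered: AbundanceMatrix
    fractions: IsoformFractionMatrix
    isoform_table: pd.DataFrame
    switch_pairs: list[SwitchPair]
    gene_table: pd.DataFrame
    _pairs_frame: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def switch_genes(self) -> set[str]:
        return {sp.gene_id for sp in self.switch_pairs}

    @property
    def switch_isoforms(self) -> set[str]:
        out: set[str] = set()
        for sp in self.switch_pairs:
            out.add(sp.up_isoform)
            out.add(sp.down_isoform)
        return out

    def pairs_frame(self) -> pd.DataFrame:
        if self._pairs_frame is None:
            cols = [
                "gene_id", "up_isoform", "down_isoform", "dIF_up", "dIF_down",
                "p_up", "p_down", "q_up", "q_down", "gene_q",
            ]
            self._pairs_frame = pd.DataFrame(
                [[getattr(sp, c) for c in cols] for sp in self.switch_pairs],
                columns=cols,
            )
        return self._pairs_frame

    def per_sample_calls(self, tau_switch: float = 0.1) -> pd.DataFrame:
        """Boolean switched-isoform x group-B-sample call matrix."""
        return per_sample_switch_calls(
            self.fractions, self.switch_pairs, self.model.contrast, tau_switch
        )

    def summary(self) -> str:
        a, b = self.model.contrast
        t = self.isoform_table
        n_test = int(t["testable"].sum())
        lines = [
            "Isoform switch analysis",
            "=" * 55,
            f"contrast:            {b} vs {a} (dIF = {b} - {a})",
            f"samples:             {len(self.model.abundance.samples_in(a))} {a}, "
            f"{len(self.model.abundance.samples_in(b))} {b}",
            f"transcripts tested:  {n_test} of {len(t)} "
            f"({t['gene_id'].nunique()} genes)",
            f"permutations:        {self.model.n_perm} (seed {self.model.seed})",
            f"thresholds:          |dIF| >= {self.model.dif_threshold}, "
            f"q < {self.model.q_threshold}",
            f"switch pairs called: {len(self.switch_pairs)}",
            f"switched genes:      {len(self.switch_genes)}",
        ]
        if self.switch_pairs:
            lines.append("-" * 55)
            lines.append("top pairs (min member q):")
            for sp in self.switch_pairs[:10]:
                lines.append(
                    f"  {sp.gene_id}: {sp.up_isoform} up {sp.dIF_up:+.3f} / "
                    f"{sp.down_isoform} down {sp.dIF_down:+.3f}, "
                    f"q={min(sp.q_up, sp.q_down):.3g}, gene_q={sp.gene_q:.3g}"
                )
        return "\n".join(lines)
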