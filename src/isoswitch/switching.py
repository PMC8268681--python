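"""Differential transcript usage and antagonistic switch calling.

The central quantity is the isoform fraction (IF): a transcript's
abundance divided by the summed abundance of all transcripts of its
gene in one sample.  A switch between two groups is a pair of isoforms
of one gene whose group-mean fractions change in opposite directions
(dIF of opposite sign), with at least one member significant after
FDR adjustment.

Significance is assessed by a group-label permutation test on |dIF|,
which is assumption-light and exactly calibrated under within-group
exchangeability; p-values use the add-one estimator so they are never
zero, and ties count in favour of the null.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AbundanceMatrix",
    "IsoformFractionMatrix",
    "SwitchPair",
    "filter_low_expression",
    "isoform_fractions",
    "delta_if",
    "permutation_test_dtu",
    "bh_adjust",
    "call_switch_pairs",
    "gene_switch_qvalue",
    "per_sample_switch_calls",
]


@dataclass
class AbundanceMatrix:
    """Transcript x sample abundances plus sample group labels.

    Parameters
    ----------
    values
        DataFrame indexed by transcript_id with sample_id columns;
        non-negative abundances (TPM by default).
    tx2gene
        Series mapping transcript_id -> gene_id; must cover all rows.
    groups
        Series mapping sample_id -> group label.
    """

    values: pd.DataFrame
    tx2gene: pd.Series
    groups: pd.Series

    def __post_init__(self) -> None:
        vals = self.values.to_numpy()
        if np.isnan(vals).any():
            raise ValueError("abundance matrix contains missing values")
        if (vals < 0).any():
            bad = np.argwhere(vals < 0)[0]
            raise ValueError(
                "negative abundance at transcript "
                f"{self.values.index[bad[0]]!r}, sample {self.values.columns[bad[1]]!r}"
            )
        missing = self.values.index.difference(self.tx2gene.index)
        if len(missing):
            raise ValueError(f"transcripts without gene assignment: {list(missing[:5])}")
        self.tx2gene = self.tx2gene.loc[self.values.index]
        missing = self.values.columns.difference(self.groups.index)
        if len(missing):
            raise ValueError(f"samples without group label: {list(missing[:5])}")
        self.groups = self.groups.loc[self.values.columns]

    @property
    def transcript_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_in(self, group: str) -> list[str]:
        sel = self.groups[self.groups == group].index
        if not len(sel):
            raise ValueError(f"no samples in group {group!r}")
        return list(sel)


@dataclass
class IsoformFractionMatrix:
    """Per-sample isoform fractions plus gene-level expression.

    ``fractions`` holds NaN wherever the gene's expression in that
    sample is below the epsilon used to compute it (fraction undefined).
    """

    fractions: pd.DataFrame
    gene_expression: pd.DataFrame
    tx2gene: pd.Series
    groups: pd.Series

    def samples_in(self, group: str) -> list[str]:
        sel = self.groups[self.groups == group].index
        if not len(sel):
            raise ValueError(f"no samples in group {group!r}")
        return list(sel)


@dataclass(frozen=True)
class SwitchPair:
    """One antagonistic isoform pair of a switched gene."""

    gene_id: str
    up_isoform: str
    down_isoform: str
    dIF_up: float
    dIF_down: float
    p_up: float
    p_down: float
    q_up: float
    q_down: float
    gene_q: float = float("nan")


def filter_low_expression(
    m: AbundanceMatrix,
    min_mean_abundance: float = 1.0,
    min_gene_abundance: float = 0.0,
) -> AbundanceMatrix:
    """Drop low-expression transcripts, then genes left empty.

    Transcripts whose mean abundance across all samples falls below
    ``min_mean_abundance`` are removed; genes whose remaining mean
    summed expression falls below ``min_gene_abundance`` are removed
    entirely.  Genes left with a single isoform are retained (their
    fraction is constant 1 and they are untestable downstream).
    """
    if min_mean_abundance < 0 or min_gene_abundance < 0:
        raise ValueError("filter thresholds must be >= 0")
    keep = m.values.mean(axis=1) >= min_mean_abundance
    values = m.values.loc[keep]
    if min_gene_abundance > 0 and len(values):
        gene_expr = values.groupby(m.tx2gene.loc[values.index]).transform("sum")
        values = values.loc[gene_expr.mean(axis=1) >= min_gene_abundance]
    if values.empty:
        raise ValueError("no transcripts survive filtering")
    return AbundanceMatrix(values, m.tx2gene.loc[values.index], m.groups)


def isoform_fractions(m: AbundanceMatrix, eps: float = 1.0) -> IsoformFractionMatrix:
    """Compute isoform fractions per (transcript, sample).

    Fractions are abundance divided by the gene's summed abundance in
    that sample, and are missing (NaN) where the gene's expression is
    below ``eps``.
    """
    gene_expr_tx = m.values.groupby(m.tx2gene).transform("sum")
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = m.values / gene_expr_tx
    frac = frac.where(gene_expr_tx >= eps)
    gene_expr = m.values.groupby(m.tx2gene).sum()
    return IsoformFractionMatrix(frac, gene_expr, m.tx2gene, m.groups)


def _group_arrays(
    f: IsoformFractionMatrix, contrast: tuple[str, str]
) -> tuple[np.ndarray, int, int]:
    a, b = contrast
    cols = f.samples_in(a) + f.samples_in(b)
    F = f.fractions[cols].to_numpy(dtype=float)
    return F, len(f.samples_in(a)), len(f.samples_in(b))


def _nan_group_means(F: np.ndarray, n_a: int) -> tuple[np.ndarray, ...]:
    with np.errstate(invalid="ignore"):
        mean_a = np.nanmean(F[:, :n_a], axis=1)
        mean_b = np.nanmean(F[:, n_a:], axis=1)
    cnt_a = np.sum(~np.isnan(F[:, :n_a]), axis=1)
    cnt_b = np.sum(~np.isnan(F[:, n_a:]), axis=1)
    return mean_a, mean_b, cnt_a, cnt_b


def delta_if(
    f: IsoformFractionMatrix, contrast: tuple[str, str], min_samples: int = 2
) -> pd.DataFrame:
    """Per-isoform difference of group-mean fractions (group B - group A).

    Means are taken over samples with non-missing fractions.  Isoforms
    with fewer than ``min_samples`` usable samples in either group are
    flagged untestable and get dIF = NaN.
    """
    F, n_a, _ = _group_arrays(f, contrast)
    mean_a, mean_b, cnt_a, cnt_b = _nan_group_means(F, n_a)
    testable = (cnt_a >= min_samples) & (cnt_b >= min_samples)
    dif = np.where(testable, mean_b - mean_a, np.nan)
    return pd.DataFrame(
        {
            "gene_id": f.tx2gene.loc[f.fractions.index].to_numpy(),
            "dIF": dif,
            "n_a": cnt_a,
            "n_b": cnt_b,
            "testable": testable,
        },
        index=f.fractions.index,
    )


def permutation_test_dtu(
    f: IsoformFractionMatrix,
    contrast: tuple[str, str],
    n_perm: int = 1000,
    seed: int | None = None,
    min_samples: int = 2,
) -> pd.Series:
    """Group-label permutation p-values for |dIF|, one per isoform.

    Sample labels (together with each sample's missing-fraction
    pattern) are permuted ``n_perm`` times; the p-value is
    ``(1 + #{permuted |dIF| >= observed}) / (n_perm + 1)`` with ties
    counted against rejection.  Untestable isoforms get NaN.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if seed is None:
        raise ValueError("a seed is required for the permutation test")
    # |dIF| is direction-free, so permute under a canonical group order:
    # swapping the contrast then leaves every p-value unchanged.
    F, n_a, n_b = _group_arrays(f, tuple(sorted(contrast)))
    n = n_a + n_b
    mean_a, mean_b, cnt_a, cnt_b = _nan_group_means(F, n_a)
    testable = (cnt_a >= min_samples) & (cnt_b >= min_samples)
    obs = np.abs(mean_b - mean_a)

    mask = ~np.isnan(F)
    F0 = np.where(mask, F, 0.0)
    maskf = mask.astype(float)

    rng = np.random.default_rng(seed)
    # indicator of permuted group-B membership, one row per permutation
    ind_b = np.zeros((n_perm, n))
    for k in range(n_perm):
        ind_b[k, rng.permutation(n)[n_a:]] = 1.0
    ind_a = 1.0 - ind_b

    with np.errstate(invalid="ignore", divide="ignore"):
        pm_a = (F0 @ ind_a.T) / (maskf @ ind_a.T)
        pm_b = (F0 @ ind_b.T) / (maskf @ ind_b.T)
        perm_stat = np.abs(pm_b - pm_a)
    # permutations leaving <2 usable samples in a group are uninformative
    low = ((maskf @ ind_a.T) < min_samples) | ((maskf @ ind_b.T) < min_samples)
    perm_stat[low] = np.nan

    with np.errstate(invalid="ignore"):
        exceed = np.nansum(perm_stat >= obs[:, None] - 1e-12, axis=1)
    p = (1.0 + exceed) / (n_perm + 1.0)
    p = np.where(testable, p, np.nan)
    return pd.Series(p, index=f.fractions.index, name="p")


def bh_adjust(p: Sequence[float] | pd.Series) -> pd.Series:
    """Benjamini-Hochberg step-up adjustment; NaNs pass through."""
    s = pd.Series(p, dtype=float)
    q = pd.Series(np.nan, index=s.index)
    ok = s.notna()
    if ok.any():
        q.loc[ok] = multipletests(s[ok].to_numpy(), method="fdr_bh")[1]
    return q


def call_switch_pairs(
    dif: pd.Series,
    q: pd.Series,
    tx2gene: pd.Series,
    dIF_threshold: float = 0.1,
    q_threshold: float = 0.05,
    p: pd.Series | None = None,
) -> list[SwitchPair]:
    """Emit antagonistic switch pairs per gene.

    Every (up, down) combination with dIF_up >= +threshold,
    dIF_down <= -threshold and min(q_up, q_down) < q_threshold is
    reported, sorted by min member q (ties by gene and isoform ids).
    """
    if p is None:
        p = pd.Series(np.nan, index=dif.index)
    pairs: list[SwitchPair] = []
    frame = pd.DataFrame({"dIF": dif, "q": q, "p": p, "gene": tx2gene.loc[dif.index]})
    for gene, sub in frame.groupby("gene", sort=True):
        ups = sub[sub["dIF"] >= dIF_threshold]
        downs = sub[sub["dIF"] <= -dIF_threshold]
        for u, urow in ups.iterrows():
            for d, drow in downs.iterrows():
                qu, qd = urow["q"], drow["q"]
                if min(qu, qd) < q_threshold:
                    pairs.append(
                        SwitchPair(
                            gene_id=str(gene),
                            up_isoform=str(u),
                            down_isoform=str(d),
                            dIF_up=float(urow["dIF"]),
                            dIF_down=float(drow["dIF"]),
                            p_up=float(urow["p"]),
                            p_down=float(drow["p"]),
                            q_up=float(qu),
                            q_down=float(qd),
                        )
                    )
    pairs.sort(key=lambda sp: (min(sp.q_up, sp.q_down), sp.gene_id, sp.up_isoform, sp.down_isoform))
    return pairs


def gene_switch_qvalue(
    pairs: list[SwitchPair],
    p: pd.Series,
    tx2gene: pd.Series,
) -> tuple[list[SwitchPair], pd.DataFrame]:
    """Gene-level switch q-values.

    The gene p-value is the minimum member-isoform p, Bonferroni-scaled
    by the gene's testable isoform count (capped at 1); gene q-values
    are BH-adjusted across all genes with at least one testable
    isoform.  Pairs are returned with gene_q attached.
    """
    frame = pd.DataFrame({"p": p, "gene": tx2gene.loc[p.index]}).dropna(subset=["p"])
    if frame.empty:
        return list(pairs), pd.DataFrame(columns=["gene_p", "gene_q"])
    grp = frame.groupby("gene")["p"]
    gene_p = (grp.min() * grp.count()).clip(upper=1.0)
    gene_q = bh_adjust(gene_p)
    table = pd.DataFrame({"gene_p": gene_p, "gene_q": gene_q}).sort_index()
    out = [
        replace(sp, gene_q=float(table["gene_q"].get(sp.gene_id, np.nan)))
        for sp in pairs
    ]
    return out, table


def per_sample_switch_calls(
    f: IsoformFractionMatrix,
    pairs: list[SwitchPair],
    contrast: tuple[str, str],
    tau_switch: float = 0.1,
) -> pd.DataFrame:
    """Per-sample switch presence for isoforms of the called pairs.

    A group-B sample carries the switch for isoform i when its fraction
    deviates from the group-A mean in the direction of the group-level
    dIF by at least ``tau_switch``.  Missing fractions are never called.
    """
    if not pairs:
        raise ValueError("no switch pairs to evaluate")
    direction: dict[str, float] = {}
    for sp in pairs:
        direction.setdefault(sp.up_isoform, np.sign(sp.dIF_up))
        direction.setdefault(sp.down_isoform, np.sign(sp.dIF_down))
    isoforms = [t for t in f.fractions.index if t in direction]
    a_cols = f.samples_in(contrast[0])
    b_cols = f.samples_in(contrast[1])
    sub = f.fractions.loc[isoforms]
    mean_a = sub[a_cols].mean(axis=1, skipna=True)
    dev = sub[b_cols].sub(mean_a, axis=0)
    sign = pd.Series([direction[t] for t in isoforms], index=isoforms)
    called = (dev.mul(sign, axis=0) >= tau_switch) & dev.notna()
    return called
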