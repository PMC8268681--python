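"""End-to-end pipeline: filter -> fractions -> test -> switches ->
consequences -> enrichment -> overlap -> mutation association.

Configuration is a flat YAML file with explicit seeds; unknown keys are
rejected.  Every output TSV carries a provenance header (config hash,
seed, package version), and reruns with the same config produce
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import median_isoform_length, structural_features
from .consequences import classify_switches, summarize
from .enrichment import contrast_overlap, hypergeom_enrichment
from .model import IsoformSwitchModel
from .mutations import (
    MutationTable,
    average_count_difference,
    gene_mutation_zscore,
    jaccard_index,
    jaccard_zscore,
    length_matched_genes,
    mutated_sample_fraction,
    mutation_counts,
)
from . import io as iso_io

logger = logging.getLogger("isoswitch")

__all__ = ["PipelineConfig", "run_pipeline"]

ALL_STAGES = ("switches", "consequences", "enrichment", "overlap", "mutations")


@dataclass
class Contrast:
    name: str
    group_a: str
    group_b: str
    column: str = "group"


@dataclass
class PipelineConfig:
    """Inputs, thresholds and seeds for one pipeline run."""

    expression: str
    samples: str
    gtf: str
    outdir: str
    seed: int
    domains: str | None = None
    mutations: str | None = None
    gene_sets: str | None = None
    contrasts: list[Contrast] = field(default_factory=list)
    min_mean_abundance: float = 1.0
    min_gene_abundance: float = 0.0
    eps: float = 1.0
    dif_threshold: float = 0.1
    q_threshold: float = 0.05
    n_perm: int = 1000
    tau_switch: float = 0.1
    utr_min_diff: int = 50
    len_min_diff: int = 50
    k_gene_background: int = 100
    k_isoform_background: int = 200
    length_window: float = 0.2
    z_threshold: float = 1.6
    mutation_contrast: str | None = None

    def __post_init__(self) -> None:
        self.contrasts = [
            c if isinstance(c, Contrast) else Contrast(**c) for c in self.contrasts
        ]
        if not self.contrasts:
            raise ValueError("at least one contrast is required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _provenance(cfg: PipelineConfig) -> dict:
    return {
        "isoswitch_version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
    }


def _contrast_groups(samples: pd.DataFrame, c: Contrast) -> pd.Series:
    if c.column not in samples.columns:
        raise ValueError(f"contrast {c.name}: column {c.column!r} not in sample sheet")
    groups = samples.set_index("sample_id")[c.column]
    for label in (c.group_a, c.group_b):
        if label not in set(groups):
            raise ValueError(
                f"contrast {c.name}: label {label!r} absent from column {c.column!r}"
            )
    return groups


def run_pipeline(cfg: PipelineConfig, stages: tuple[str, ...] = ALL_STAGES) -> dict:
    """Run the configured stages and write their TSV outputs.

    Returns a dict of in-memory results keyed by output name.  Stage
    errors abort the run, naming the stage.
    """
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    prov = _provenance(cfg)
    results: dict = {}
    counts: dict[str, int] = {}

    samples = iso_io.read_samples(cfg.samples)
    genes = iso_io.read_gtf(cfg.gtf)
    if cfg.domains:
        genes = iso_io.attach_domains(genes, iso_io.read_domains(cfg.domains))
    tx2gene = pd.Series(
        {t.transcript_id: g.gene_id for g in genes for t in g.transcripts}
    )
    features = {
        t.transcript_id: structural_features(t) for g in genes for t in g.transcripts
    }
    tx_length = pd.Series(
        {t.transcript_id: float(t.length) for g in genes for t in g.transcripts}
    )
    gene_median_len = pd.Series(
        {g.gene_id: median_isoform_length(g) for g in genes}
    )

    fits: dict[str, object] = {}
    for c in cfg.contrasts:
        stage = f"switches[{c.name}]"
        try:
            groups = _contrast_groups(samples, c)
            abundance = iso_io.read_expression(cfg.expression, samples, tx2gene)
            abundance.groups = groups.loc[abundance.sample_ids]
            model = IsoformSwitchModel(
                abundance,
                (c.group_a, c.group_b),
                min_mean_abundance=cfg.min_mean_abundance,
                min_gene_abundance=cfg.min_gene_abundance,
                eps=cfg.eps,
                dif_threshold=cfg.dif_threshold,
                q_threshold=cfg.q_threshold,
                n_perm=cfg.n_perm,
                seed=cfg.seed,
            )
            res = model.fit()
        except Exception as exc:
            raise RuntimeError(f"stage {stage} failed: {exc}") from exc
        fits[c.name] = res
        counts[stage] = len(res.switch_pairs)
        logger.info("%s: %d switch pairs", stage, len(res.switch_pairs))
        if "switches" in stages:
            iso_io.write_table(
                res.isoform_table.rename_axis("transcript_id").reset_index(),
                outdir / f"isoforms_{c.name}.tsv", prov,
            )
            pairs = res.pairs_frame().copy()
            gene_names = {g.gene_id: g.gene_name for g in genes}
            pairs.insert(1, "gene_name", pairs["gene_id"].map(gene_names))
            iso_io.write_table(pairs, outdir / f"switch_pairs_{c.name}.tsv", prov)
        results[f"fit_{c.name}"] = res

    consequence_records: dict[str, list] = {}
    if {"consequences", "enrichment"} & set(stages):
        for c in cfg.contrasts:
            stage = f"consequences[{c.name}]"
            try:
                res = fits[c.name]
                recs = classify_switches(
                    res.switch_pairs, features, cfg.utr_min_diff, cfg.len_min_diff
                )
            except Exception as exc:
                raise RuntimeError(f"stage {stage} failed: {exc}") from exc
            consequence_records[c.name] = recs
            counts[stage] = len(recs)
            if "consequences" in stages:
                rec_df = pd.DataFrame(
                    [
                        (r.gene_id, r.up_isoform, r.down_isoform,
                         ";".join(sorted(r.consequences)))
                        for r in recs
                    ],
                    columns=["gene_id", "up_isoform", "down_isoform", "consequences"],
                )
                iso_io.write_table(rec_df, outdir / f"consequences_{c.name}.tsv", prov)
                iso_io.write_table(
                    summarize(recs), outdir / f"consequence_summary_{c.name}.tsv", prov
                )
            results[f"consequences_{c.name}"] = recs

    if "overlap" in stages and len(cfg.contrasts) >= 2:
        try:
            overlap = contrast_overlap(
                {
                    c.name: (fits[c.name].switch_isoforms, fits[c.name].switch_genes)
                    for c in cfg.contrasts
                }
            )
        except Exception as exc:
            raise RuntimeError(f"stage overlap failed: {exc}") from exc
        iso_io.write_table(overlap, outdir / "contrast_overlap.tsv", prov)
        results["overlap"] = overlap
        counts["overlap"] = len(overlap)

    if "enrichment" in stages and cfg.gene_sets:
        try:
            sets = iso_io.read_gmt(cfg.gene_sets)
            for c in cfg.contrasts:
                res = fits[c.name]
                background = set(res.filtered.tx2gene.unique())
                enr = hypergeom_enrichment(res.switch_genes, sets, background)
                iso_io.write_table(enr, outdir / f"enrichment_{c.name}.tsv", prov)
                results[f"enrichment_{c.name}"] = enr
                functional = {
                    r.gene_id for r in consequence_records[c.name] if r.consequences
                }
                enr_f = hypergeom_enrichment(functional, sets, background)
                iso_io.write_table(
                    enr_f, outdir / f"enrichment_functional_{c.name}.tsv", prov
                )
                results[f"enrichment_functional_{c.name}"] = enr_f
        except RuntimeError:
            raise
        except Exception as exc:
            raise RuntimeError(f"stage enrichment failed: {exc}") from exc

    if "mutations" in stages and cfg.mutations:
        try:
            results.update(
                _mutation_stage(cfg, fits, samples, gene_median_len, tx_length,
                                tx2gene, outdir, prov)
            )
        except RuntimeError:
            raise
        except Exception as exc:
            raise RuntimeError(f"stage mutations failed: {exc}") from exc

    manifest = {"provenance": prov, "counts": counts}
    (outdir / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    results["manifest"] = manifest
    return results


def _mutation_stage(cfg, fits, samples, gene_median_len, tx_length, tx2gene,
                    outdir, prov) -> dict:
    cname = cfg.mutation_contrast or cfg.contrasts[0].name
    c = next(ct for ct in cfg.contrasts if ct.name == cname)
    res = fits[cname]
    muts = iso_io.read_mutations(cfg.mutations)
    groups = _contrast_groups(samples, c)
    samples_a = list(groups[groups == c.group_a].index)
    samples_b = list(groups[groups == c.group_b].index)

    counts = mutation_counts(
        muts,
        {c.group_a: samples_a, c.group_b: samples_b},
        genes=list(gene_median_len.index),
    )
    delta = average_count_difference(
        counts, c.group_b, c.group_a, len(samples_b), len(samples_a)
    )

    # per-gene Z against a length-matched background of all annotated genes
    zrows = []
    k_bg = min(cfg.k_gene_background, len(gene_median_len) - 1)
    for i, gid in enumerate(sorted(res.switch_genes)):
        if gid not in gene_median_len.index:
            continue
        bg = length_matched_genes(
            gid, gene_median_len, k=k_bg, window=cfg.length_window,
            seed=[5, cfg.seed, i],
        )
        gz = gene_mutation_zscore(
            gid, float(delta[gid]), delta[bg].to_numpy(), cfg.z_threshold
        )
        zrows.append(
            (gid, gz.delta, gz.bg_mean, gz.bg_sd, gz.z, gz.significant)
        )
    gene_z = pd.DataFrame(
        zrows, columns=["gene_id", "delta", "bg_mean", "bg_sd", "z", "significant"]
    )
    iso_io.write_table(gene_z, outdir / "mutation_gene_z.tsv", prov)

    # per-isoform Jaccard of switch calls vs mutated samples
    calls = res.per_sample_calls(cfg.tau_switch)
    pool_rows = {}
    for iso in calls.index:
        gid = tx2gene[iso]
        sw = set(calls.columns[calls.loc[iso]])
        mu = muts.mutated_samples(gid) & set(samples_b)
        pool_rows[iso] = {
            "gene_id": gid,
            "length": float(tx_length[iso]),
            "j": jaccard_index(sw, mu),
            "mutated_fraction": len(mu) / len(samples_b),
        }
    pool = pd.DataFrame.from_dict(pool_rows, orient="index")
    jrows = []
    if len(pool) >= 3:
        k_iso = min(cfg.k_isoform_background, len(pool) - 1)
        if k_iso < cfg.k_isoform_background:
            logger.warning(
                "isoform background reduced to %d (pool of %d switched isoforms)",
                k_iso, len(pool),
            )
        for i, iso in enumerate(pool.index):
            row = pool.loc[iso]
            jr = jaccard_zscore(
                iso, row["gene_id"], row["j"], row["mutated_fraction"],
                row["length"], pool, k=k_iso, window=cfg.length_window,
                seed=[6, cfg.seed, i], z_threshold=cfg.z_threshold,
            )
            jrows.append(
                (iso, jr.gene_id, jr.j, jr.mutated_fraction, jr.z, jr.significant)
            )
    jaccard = pd.DataFrame(
        jrows,
        columns=["isoform_id", "gene_id", "j", "mutated_fraction", "z", "significant"],
    )
    iso_io.write_table(jaccard, outdir / "mutation_jaccard.tsv", prov)
    return {"mutation_gene_z": gene_z, "mutation_jaccard": jaccard}
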