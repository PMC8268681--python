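"""Synthetic cohort generator.

Emulates the statistical structure of a two-group melanocytic-lesion
cohort (23 nevi vs 57 melanomas by default): genes with 1-5 transcript
isoforms, antagonistic usage shifts planted in a minority of genes,
negative-binomial gene expression with Dirichlet usage noise,
gene-length-dependent mutation burdens with a melanoma-enriched subset,
and switch-mutation co-occurrence planted on selected isoforms.
Every planted structure is recorded in a ground-truth object so that
sensitivity and FDR of each downstream stage can be scored exactly.

Planting uses exact counts (seeded shuffle, then deterministic
assignment) rather than per-gene coin flips, so truth proportions equal
the configured fractions exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .annotation import GeneModel, TranscriptModel

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedAnnotation",
    "simulate_annotation",
    "simulate_expression",
    "simulate_mutations",
    "simulate_gene_sets",
]

DOMAIN_VOCAB = (
    "SRCR", "Macscav_rec", "Collagen", "Kinase", "SH2", "Ig", "WD40", "ZnF", "TM",
)

# fixed class frequencies of emitted mutation records
CLASS_PROBS = {
    "missense": 0.60,
    "synonymous": 0.15,
    "utr3": 0.10,
    "utr5": 0.05,
    "nonsense": 0.05,
    "splice_site": 0.05,
}


@dataclass
class SimulationConfig:
    """Study conditions of the synthetic cohort.

    Defaults are desk-scale: 500 genes (~1,200 isoforms), 23 nevi and
    57 melanomas, 50 antagonistic switch genes with a usage shift of
    0.3, Dirichlet usage concentration 30, a base mutation rate of
    0.5 per kb and sample (top genes are then mutated in over half the
    cohort, as in heavily mutated melanoma) with 20 genes 3-fold
    enriched in melanomas, and 20
    switch-isoforms whose mutations co-occur with the per-sample switch
    at probability 0.8.
    """

    seed: int = 0
    n_genes: int = 500
    min_isoforms: int = 1
    max_isoforms: int = 5
    n_nevus: int = 23
    n_melanoma: int = 57
    n_switch_genes: int = 50
    dIF_effect: float = 0.3
    usage_concentration: float = 30.0
    gene_mean_log_mu: float = 3.0
    gene_mean_log_sd: float = 1.0
    nb_dispersion: float = 0.2
    base_mut_rate_per_kb: float = 0.5
    n_mut_enriched_genes: int = 20
    mut_fold: float = 3.0
    n_cooccur_isoforms: int = 20
    cooccur_rho: float = 0.8
    frac_utr3_shortened: float = 0.6
    frac_orf_loss: float = 0.1
    tau_switch: float = 0.1

    def __post_init__(self) -> None:
        if self.n_switch_genes > self.n_genes:
            raise ValueError("n_switch_genes exceeds n_genes")
        if not (0 < self.dIF_effect < 1):
            raise ValueError("dIF_effect must lie in (0, 1)")
        if self.n_cooccur_isoforms > self.n_switch_genes:
            raise ValueError("n_cooccur_isoforms exceeds the number of switch pairs")
        for name in ("n_genes", "n_nevus", "n_melanoma"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


@dataclass
class GroundTruth:
    """Planted structure of one simulated cohort."""

    switch_genes: set[str] = field(default_factory=set)
    switch_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    planted_consequences: dict[str, frozenset[str]] = field(default_factory=dict)
    mut_enriched_genes: set[str] = field(default_factory=set)
    cooccur_isoforms: set[str] = field(default_factory=set)
    expected_dif: pd.Series | None = None
    switch_call_truth: pd.DataFrame | None = None


@dataclass
class SimulatedAnnotation:
    genes: list[GeneModel]
    domain_table: pd.DataFrame
    gene_spans: dict[str, tuple[str, int, int]]
    truth: GroundTruth

    def transcripts(self) -> list[TranscriptModel]:
        return [t for g in self.genes for t in g.transcripts]

    def tx2gene(self) -> pd.Series:
        return pd.Series(
            {t.transcript_id: g.gene_id for g in self.genes for t in g.transcripts},
            name="gene_id",
        )


# ---------------------------------------------------------------------------
# structural specs: isoforms are designed in spliced coordinates and then laid
# out on the genome, which keeps consequence planting (UTR deltas, intron
# merges) exact regardless of strand.

@dataclass
class _IsoSpec:
    exon_lens: list[int]
    intron_lens: list[int]
    utr5: int
    utr3: int
    coding: bool
    domains: set[tuple[str, int, int]]

    @property
    def length(self) -> int:
        return sum(self.exon_lens)


def _spliced_to_genomic(
    exons_tx_order: list[tuple[int, int]], strand: str, lo: int, hi: int
) -> tuple[tuple[int, int], ...]:
    """Map the spliced interval [lo, hi) onto genomic intervals."""
    out = []
    offset = 0
    for s, e in exons_tx_order:
        ln = e - s
        a, b = max(lo, offset), min(hi, offset + ln)
        if a < b:
            if strand == "+":
                out.append((s + (a - offset), s + (b - offset)))
            else:
                out.append((e - (b - offset), e - (a - offset)))
        offset += ln
    return tuple(sorted(out))


def _build_transcript(
    tid: str, gid: str, strand: str, start: int, spec: _IsoSpec
) -> TranscriptModel:
    lens = spec.exon_lens if strand == "+" else spec.exon_lens[::-1]
    intr = spec.intron_lens if strand == "+" else spec.intron_lens[::-1]
    exons = []
    pos = start
    for i, ln in enumerate(lens):
        exons.append((pos, pos + ln))
        pos += ln + (intr[i] if i < len(intr) else 0)
    tx_order = exons if strand == "+" else exons[::-1]
    cds = None
    if spec.coding:
        cds = _spliced_to_genomic(
            tx_order, strand, spec.utr5, spec.length - spec.utr3
        )
    return TranscriptModel(
        transcript_id=tid,
        gene_id=gid,
        strand=strand,
        exons=tuple(exons),
        cds=cds,
        domains=frozenset(spec.domains if spec.coding else set()),
    )


def _random_spec(rng: np.random.Generator, coding_prob: float = 0.85) -> _IsoSpec:
    n_exons = int(rng.integers(1, 9))
    exon_lens = list(rng.integers(80, 400, size=n_exons))
    intron_lens = list(rng.integers(200, 2000, size=max(n_exons - 1, 0)))
    coding = bool(rng.random() < coding_prob) and sum(exon_lens) >= 400
    utr5 = utr3 = 0
    domains: set[tuple[str, int, int]] = set()
    if coding:
        utr5 = int(rng.integers(20, 200))
        utr3 = int(rng.integers(150, 500))
        exon_lens[0] = max(exon_lens[0], utr5 + 60)
        exon_lens[-1] = max(exon_lens[-1], utr3 + 150)
        domains = _random_domains(rng, (sum(exon_lens) - utr5 - utr3) // 3)
    return _IsoSpec([int(x) for x in exon_lens], [int(x) for x in intron_lens],
                    utr5, utr3, coding, domains)


def _random_domains(
    rng: np.random.Generator, aa_len: int, n_max: int = 3
) -> set[tuple[str, int, int]]:
    n = int(rng.integers(0, n_max + 1))
    names = rng.choice(DOMAIN_VOCAB, size=min(n, len(DOMAIN_VOCAB)), replace=False)
    out = set()
    for name in names:
        if aa_len < 20:
            break
        a = int(rng.integers(1, max(aa_len - 15, 2)))
        b = min(a + int(rng.integers(10, 80)), aa_len)
        out.add((str(name), a, b))
    return out


def _plant_pair(
    rng: np.random.Generator, consequence: str
) -> tuple[_IsoSpec, _IsoSpec, frozenset[str]]:
    """Build a (down, up) spec pair differing by the planted consequence."""
    down = _random_spec(rng, coding_prob=1.0)
    if not down.coding:  # tiny transcript fell through; force a viable one
        down.exon_lens[0] += 500
        down.coding = True
        down.utr5, down.utr3 = 100, 450
    down.utr3 = int(rng.integers(450, 800))
    down.exon_lens[-1] = max(down.exon_lens[-1], down.utr3 + 200)
    planted: set[str] = set()
    up = _IsoSpec(list(down.exon_lens), list(down.intron_lens), down.utr5,
                  down.utr3, down.coding, set(down.domains))
    if consequence == "ORF_loss":
        up.coding = False
        up.utr5 = up.utr3 = 0
        up.domains = set()
        planted.add("ORF_loss")
        if down.domains:
            planted.add("domain_loss")
    else:
        delta = int(rng.integers(60, 300))
        if consequence == "utr3_shortened":
            up.utr3 = down.utr3 - delta
            up.exon_lens = list(up.exon_lens)
            up.exon_lens[-1] -= delta
            planted.update({"utr3_shortened", "length_shortened"})
        else:
            up.utr3 = down.utr3 + delta
            up.exon_lens = list(up.exon_lens)
            up.exon_lens[-1] += delta
            planted.update({"utr3_lengthened", "length_lengthened"})
        # occasional extra structure: merge the first two exons (intron loss)
        if len(up.exon_lens) >= 2 and rng.random() < 0.25:
            up.exon_lens[0] += up.exon_lens[1]
            del up.exon_lens[1]
            del up.intron_lens[0]
            planted.add("intron_loss")
        if down.domains and rng.random() < 0.3:
            lost = sorted(down.domains)[0]
            up.domains.discard(lost)
            if not any(d[0] == lost[0] for d in up.domains):
                planted.add("domain_loss")
    return down, up, frozenset(planted)


def simulate_annotation(cfg: SimulationConfig) -> SimulatedAnnotation:
    """Generate gene/transcript models with planted switch-pair structure."""
    rng = np.random.default_rng([0, cfg.seed])
    truth = GroundTruth()

    n_iso = rng.integers(cfg.min_isoforms, cfg.max_isoforms + 1, size=cfg.n_genes)
    multi = np.flatnonzero(n_iso >= 2)
    if len(multi) < cfg.n_switch_genes:
        raise ValueError("not enough multi-isoform genes to plant switches")
    switch_idx = set(rng.permutation(multi)[: cfg.n_switch_genes].tolist())

    # exact-count consequence assignment over switch genes
    order = sorted(switch_idx)
    rng.shuffle(order)
    n_orf = round(cfg.frac_orf_loss * cfg.n_switch_genes)
    n_short = round(cfg.frac_utr3_shortened * (cfg.n_switch_genes - n_orf))
    consequence_of = {}
    for rank, gi in enumerate(order):
        if rank < n_orf:
            consequence_of[gi] = "ORF_loss"
        elif rank < n_orf + n_short:
            consequence_of[gi] = "utr3_shortened"
        else:
            consequence_of[gi] = "utr3_lengthened"

    genes: list[GeneModel] = []
    spans: dict[str, tuple[str, int, int]] = {}
    dom_rows = []
    cursor = 10_000
    for gi in range(cfg.n_genes):
        gid = f"G{gi + 1:04d}"
        strand = "+" if rng.random() < 0.5 else "-"
        k = int(n_iso[gi])
        specs: list[_IsoSpec] = []
        pair: tuple[int, int] | None = None
        if gi in switch_idx:
            down, up, planted = _plant_pair(rng, consequence_of[gi])
            specs = [up, down] + [_random_spec(rng) for _ in range(k - 2)]
            pair = (0, 1)
            truth.planted_consequences[gid] = planted
        else:
            specs = [_random_spec(rng) for _ in range(k)]
        txs = []
        span_end = cursor
        for ti, spec in enumerate(specs):
            tid = f"{gid}.T{ti + 1}"
            t = _build_transcript(tid, gid, strand, cursor, spec)
            txs.append(t)
            span_end = max(span_end, max(e for _, e in t.exons))
            for name, a, b in sorted(t.domains):
                dom_rows.append((tid, name, a, b))
        genes.append(GeneModel(gid, f"SYN{gid[1:]}", tuple(txs)))
        spans[gid] = ("chr1", cursor, span_end)
        cursor = span_end + 10_000
        if pair is not None:
            up_id, down_id = txs[0].transcript_id, txs[1].transcript_id
            truth.switch_genes.add(gid)
            truth.switch_pairs.append((gid, up_id, down_id))

    # co-occurrence isoforms: an exact-count draw from the planted up-isoforms
    ups = sorted(up for _, up, _ in truth.switch_pairs)
    rng.shuffle(ups)
    truth.cooccur_isoforms = set(ups[: cfg.n_cooccur_isoforms])

    all_gids = [g.gene_id for g in genes]
    rng.shuffle(all_gids)
    truth.mut_enriched_genes = set(all_gids[: cfg.n_mut_enriched_genes])

    dom_table = pd.DataFrame(
        dom_rows, columns=["transcript_id", "domain_name", "start_aa", "end_aa"]
    )
    return SimulatedAnnotation(genes, dom_table, spans, truth)


def simulate_samples(cfg: SimulationConfig) -> pd.DataFrame:
    """Sample sheet: ids, group (nevus/melanoma) and subtype (type1/type2)."""
    rng = np.random.default_rng([3, cfg.seed])
    rows = [(f"N{i + 1:02d}", "nevus") for i in range(cfg.n_nevus)]
    rows += [(f"M{i + 1:02d}", "melanoma") for i in range(cfg.n_melanoma)]
    df = pd.DataFrame(rows, columns=["sample_id", "group"])
    df["subtype"] = rng.choice(["type1", "type2"], size=len(df))
    return df


def simulate_expression(
    cfg: SimulationConfig, ann: SimulatedAnnotation, samples: pd.DataFrame | None = None
):
    """Simulate the transcript abundance matrix.

    Gene totals are negative binomial (log-normal means, dispersion
    ``nb_dispersion``: var = m + phi m^2); isoform usage per (gene,
    sample) is Dirichlet around group-specific proportions with
    concentration ``usage_concentration``.  For switch genes, the
    melanoma proportions move ``dIF_effect`` of usage mass from the
    down- to the up-isoform.  Returns ``(AbundanceMatrix, samples,
    truth)`` with per-sample switch-call truth filled in.
    """
    from .switching import AbundanceMatrix  # local import avoids cycle

    rng = np.random.default_rng([1, cfg.seed])
    if samples is None:
        samples = simulate_samples(cfg)
    sample_ids = samples["sample_id"].tolist()
    is_mel = (samples["group"] == "melanoma").to_numpy()
    n_samples = len(sample_ids)

    pair_of = {g: (up, down) for g, up, down in ann.truth.switch_pairs}
    blocks = []
    index: list[str] = []
    exp_dif: dict[str, float] = {}
    call_rows: dict[str, np.ndarray] = {}

    for gene in ann.genes:
        k = len(gene.transcripts)
        tids = [t.transcript_id for t in gene.transcripts]
        mean = float(np.exp(rng.normal(cfg.gene_mean_log_mu, cfg.gene_mean_log_sd)))
        if cfg.nb_dispersion > 0:
            r = 1.0 / cfg.nb_dispersion
            totals = rng.negative_binomial(r, r / (r + mean), size=n_samples)
        else:
            totals = rng.poisson(mean, size=n_samples)
        base = rng.dirichlet(np.full(k, 2.0))
        props_nev = base.copy()
        props_mel = base.copy()
        if gene.gene_id in pair_of and k >= 2:
            up_id, down_id = pair_of[gene.gene_id]
            iu, idn = tids.index(up_id), tids.index(down_id)
            need = cfg.dIF_effect + 0.1
            if base[idn] < need:
                scale = (1.0 - need) / max(1.0 - base[idn], 1e-9)
                base = base * scale
                base[idn] = need
            props_nev = base / base.sum()
            props_mel = props_nev.copy()
            props_mel[idn] -= cfg.dIF_effect
            props_mel[iu] += cfg.dIF_effect
        props_nev = np.clip(props_nev, 1e-4, None)
        props_nev /= props_nev.sum()
        props_mel = np.clip(props_mel, 1e-4, None)
        props_mel /= props_mel.sum()

        alpha = np.where(
            is_mel[:, None],
            cfg.usage_concentration * props_mel[None, :],
            cfg.usage_concentration * props_nev[None, :],
        )
        if k == 1:
            usage = np.ones((n_samples, 1))
        else:
            gam = rng.gamma(alpha)
            rowsum = gam.sum(axis=1, keepdims=True)
            rowsum[rowsum == 0] = 1.0
            usage = gam / rowsum
        blocks.append((usage * totals[:, None]).T)
        index.extend(tids)

        for i, tid in enumerate(tids):
            exp_dif[tid] = float(props_mel[i] - props_nev[i])
        if gene.gene_id in pair_of:
            up_id, down_id = pair_of[gene.gene_id]
            nev_mean = usage[~is_mel].mean(axis=0)
            for tid, sign in ((up_id, 1.0), (down_id, -1.0)):
                i = tids.index(tid)
                dev = sign * (usage[:, i] - nev_mean[i])
                call_rows[tid] = (dev >= cfg.tau_switch) & is_mel

    values = pd.DataFrame(np.vstack(blocks), index=index, columns=sample_ids)
    groups = samples.set_index("sample_id")["group"]
    abundance = AbundanceMatrix(values, ann.tx2gene(), groups)
    ann.truth.expected_dif = pd.Series(exp_dif)
    ann.truth.switch_call_truth = pd.DataFrame(
        call_rows, index=sample_ids
    ).T.loc[:, np.asarray(sample_ids)[is_mel]]
    return abundance, samples, ann.truth


def simulate_mutations(
    cfg: SimulationConfig,
    ann: SimulatedAnnotation,
    samples: pd.DataFrame,
    switch_call_truth: pd.DataFrame | None = None,
):
    """Simulate per-sample mutation records.

    Per gene and sample, counts are Poisson with rate proportional to
    the gene's median isoform length (``base_mut_rate_per_kb``);
    melanoma rates are multiplied by ``mut_fold`` for the enriched
    genes.  For co-occurrence isoforms, melanoma samples carrying the
    per-sample switch receive at least one mutation with probability
    ``cooccur_rho``.
    """
    from .annotation import median_isoform_length
    from .mutations import MutationTable

    rng = np.random.default_rng([2, cfg.seed])
    if switch_call_truth is None:
        switch_call_truth = ann.truth.switch_call_truth
    sample_ids = samples["sample_id"].tolist()
    is_mel = (samples["group"] == "melanoma").to_numpy()

    gids = [g.gene_id for g in ann.genes]
    med_kb = np.array([median_isoform_length(g) / 1000.0 for g in ann.genes])
    lam = np.outer(med_kb * cfg.base_mut_rate_per_kb, np.ones(len(sample_ids)))
    enriched = np.array([g in ann.truth.mut_enriched_genes for g in gids])
    lam[np.ix_(enriched, is_mel)] *= cfg.mut_fold
    counts = rng.poisson(lam)

    gene_of_iso = {t.transcript_id: t.gene_id for g in ann.genes for t in g.transcripts}
    if switch_call_truth is not None:
        gi_index = {g: i for i, g in enumerate(gids)}
        si_index = {s: i for i, s in enumerate(sample_ids)}
        for iso in sorted(ann.truth.cooccur_isoforms):
            g = gene_of_iso[iso]
            if iso not in switch_call_truth.index:
                continue
            calls = switch_call_truth.loc[iso]
            for s, called in calls.items():
                if called and rng.random() < cfg.cooccur_rho:
                    gi, si = gi_index[g], si_index[s]
                    counts[gi, si] = max(counts[gi, si], 1)

    gi_nz, si_nz = np.nonzero(counts)
    reps = counts[gi_nz, si_nz]
    gene_col = np.repeat(np.asarray(gids, dtype=object)[gi_nz], reps)
    sample_col = np.repeat(np.asarray(sample_ids, dtype=object)[si_nz], reps)
    n_rec = int(reps.sum())
    classes = rng.choice(
        list(CLASS_PROBS), size=n_rec, p=list(CLASS_PROBS.values())
    )
    spans = np.array([ann.gene_spans[g][1:] for g in gene_col], dtype=float)
    pos = (spans[:, 0] + rng.random(n_rec) * (spans[:, 1] - spans[:, 0])).astype(int) \
        if n_rec else np.array([], dtype=int)
    records = pd.DataFrame(
        {
            "sample_id": sample_col,
            "gene_id": gene_col,
            "transcript_id": "",
            "mut_class": classes,
            "chrom": "chr1",
            "pos": pos,
        }
    )
    records = records.sort_values(["gene_id", "sample_id", "pos"]).reset_index(drop=True)
    return MutationTable(records)


def simulate_gene_sets(cfg: SimulationConfig, ann: SimulatedAnnotation, n_random: int = 10):
    """Synthetic GMT-style gene sets with one planted switch-enriched set."""
    from .enrichment import GeneSet

    rng = np.random.default_rng([4, cfg.seed])
    all_genes = np.array([g.gene_id for g in ann.genes])
    switch = sorted(ann.truth.switch_genes)
    non_switch = sorted(set(all_genes) - ann.truth.switch_genes)
    n_hit = min(len(switch), 30)
    planted = set(rng.choice(switch, size=n_hit, replace=False)) | set(
        rng.choice(non_switch, size=10, replace=False)
    )
    sets = [GeneSet("SET:PLANTED", "planted switch-enriched set", frozenset(planted))]
    for i in range(n_random):
        members = rng.choice(all_genes, size=40, replace=False)
        sets.append(GeneSet(f"SET:R{i + 1:02d}", f"random set {i + 1}", frozenset(members)))
    return sets


def write_bundle(cfg: SimulationConfig, outdir) -> dict:
    """Simulate a full cohort and write every input file plus truth tables.

    Emits GTF, domain TSV, expression TSV, sample sheet, mutation TSV,
    a GMT with one planted enriched set, and ground-truth tables.
    Returns the in-memory objects.
    """
    from pathlib import Path

    from . import io as iso_io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ann = simulate_annotation(cfg)
    abundance, samples, truth = simulate_expression(cfg, ann)
    muts = simulate_mutations(cfg, ann, samples)
    sets = simulate_gene_sets(cfg, ann)
    prov = {"generator": "isoswitch.simulate", "seed": cfg.seed}

    iso_io.write_gtf(ann.genes, outdir / "annotation.gtf", ann.gene_spans)
    iso_io.write_table(ann.domain_table, outdir / "domains.tsv", prov)
    iso_io.write_expression(abundance, outdir / "expression.tsv", prov)
    iso_io.write_table(samples, outdir / "samples.tsv", prov)
    iso_io.write_mutations(muts, outdir / "mutations.tsv", prov)
    iso_io.write_gmt(sets, outdir / "gene_sets.gmt")

    pairs = pd.DataFrame(truth.switch_pairs, columns=["gene_id", "up_isoform", "down_isoform"])
    pairs["planted_consequences"] = [
        ";".join(sorted(truth.planted_consequences.get(g, ()))) for g in pairs["gene_id"]
    ]
    iso_io.write_table(pairs, outdir / "truth_switch_pairs.tsv", prov)
    iso_io.write_table(
        pd.DataFrame(sorted(truth.mut_enriched_genes), columns=["gene_id"]),
        outdir / "truth_mut_enriched_genes.tsv", prov,
    )
    iso_io.write_table(
        pd.DataFrame(sorted(truth.cooccur_isoforms), columns=["transcript_id"]),
        outdir / "truth_cooccur_isoforms.tsv", prov,
    )
    iso_io.write_table(
        truth.expected_dif.rename("expected_dIF").rename_axis("transcript_id").reset_index(),
        outdir / "truth_expected_dif.tsv", prov,
    )
    iso_io.write_table(
        truth.switch_call_truth.rename_axis("transcript_id").reset_index(),
        outdir / "truth_switch_calls.tsv", prov,
    )
    return {
        "annotation": ann,
        "abundance": abundance,
        "samples": samples,
        "mutations": muts,
        "gene_sets": sets,
        "truth": truth,
    }
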