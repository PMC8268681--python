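import numpy as np
import pandas as pd
import pytest

from isoswitch.annotation import structural_features
from isoswitch.simulate import (
    CLASS_PROBS,
    SimulationConfig,
    simulate_annotation,
    simulate_expression,
    simulate_mutations,
    simulate_samples,
)


class TestAnnotation:
    def test_deterministic_under_seed(self, tmp_path):
        from isoswitch.io import write_gtf

        cfg = SimulationConfig(seed=5, n_genes=20, n_switch_genes=4,
                               n_cooccur_isoforms=2, n_mut_enriched_genes=2)
        paths = []
        for name in ("a.gtf", "b.gtf"):
            ann = simulate_annotation(cfg)
            write_gtf(ann.genes, tmp_path / name, ann.gene_spans)
            paths.append(tmp_path / name)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_transcript_invariants_hold(self, small_cohort):
        # construction validates invariants; features must also be derivable
        for t in small_cohort["ann"].transcripts():
            fv = structural_features(t)
            assert fv.transcript_length >= 1
            assert fv.intron_count == len(t.exons) - 1
            assert fv.utr5_length + fv.utr3_length <= fv.transcript_length

    def test_planted_orf_loss_structure(self):
        cfg = SimulationConfig(seed=9, n_genes=60, n_switch_genes=20,
                               frac_orf_loss=0.5, n_cooccur_isoforms=5,
                               n_mut_enriched_genes=5)
        ann = simulate_annotation(cfg)
        by_id = {t.transcript_id: t for t in ann.transcripts()}
        orf_loss = [
            (g, up, down)
            for g, up, down in ann.truth.switch_pairs
            if "ORF_loss" in ann.truth.planted_consequences[g]
        ]
        assert len(orf_loss) == 10  # exact planting
        for _, up, down in orf_loss:
            assert by_id[down].coding and not by_id[up].coding

    def test_utr3_split_exact(self):
        cfg = SimulationConfig(seed=11, n_genes=120, n_switch_genes=40,
                               frac_orf_loss=0.0, frac_utr3_shortened=0.6,
                               n_cooccur_isoforms=5, n_mut_enriched_genes=5)
        ann = simulate_annotation(cfg)
        planted = list(ann.truth.planted_consequences.values())
        n_short = sum("utr3_shortened" in c for c in planted)
        n_long = sum("utr3_lengthened" in c for c in planted)
        assert n_short == 24 and n_long == 16


class TestExpression:
    def test_zero_effect_zero_expected_dif(self):
        cfg = SimulationConfig(seed=2, n_genes=30, n_switch_genes=0,
                               n_cooccur_isoforms=0, n_mut_enriched_genes=0,
                               dIF_effect=0.5)
        ann = simulate_annotation(cfg)
        assert ann.truth.switch_pairs == []
        _, _, truth = simulate_expression(cfg, ann)
        assert truth.expected_dif.abs().max() == 0.0

    def test_usage_fractions_sum_to_one(self, small_cohort):
        ab = small_cohort["abundance"]
        from isoswitch.switching import isoform_fractions

        f = isoform_fractions(ab, eps=0.5)
        sums = f.fractions.groupby(f.tx2gene).sum(min_count=1).to_numpy()
        assert np.all(np.isnan(sums) | (np.abs(sums - 1) < 1e-9))

    def test_planted_dif_recovered_on_average(self):
        cfg = SimulationConfig(seed=4, n_genes=120, n_switch_genes=30,
                               n_cooccur_isoforms=5, n_mut_enriched_genes=5)
        ann = simulate_annotation(cfg)
        ab, samples, truth = simulate_expression(cfg, ann)
        from isoswitch.switching import delta_if, isoform_fractions

        f = isoform_fractions(ab, eps=0.5)
        d = delta_if(f, ("nevus", "melanoma"))["dIF"]
        ups = [up for _, up, _ in truth.switch_pairs if up in d.index]
        realized = d[ups].dropna()
        assert len(realized) >= 25
        assert realized.mean() == pytest.approx(cfg.dIF_effect, abs=0.03)

    def test_cohort_sizes_default(self):
        df = simulate_samples(SimulationConfig(seed=0))
        assert (df["group"] == "nevus").sum() == 23
        assert (df["group"] == "melanoma").sum() == 57
        assert set(df["subtype"]) <= {"type1", "type2"}


class TestMutations:
    def test_zero_rate_empty(self):
        cfg = SimulationConfig(seed=3, n_genes=20, n_switch_genes=0,
                               n_cooccur_isoforms=0, n_mut_enriched_genes=0,
                               base_mut_rate_per_kb=0.0)
        ann = simulate_annotation(cfg)
        _, samples, _ = simulate_expression(cfg, ann)
        muts = simulate_mutations(cfg, ann, samples)
        assert len(muts) == 0

    def test_fold_enrichment_recovered(self):
        cfg = SimulationConfig(seed=6, n_genes=150, n_switch_genes=0,
                               n_cooccur_isoforms=0, n_mut_enriched_genes=30,
                               mut_fold=3.0)
        ann = simulate_annotation(cfg)
        _, samples, _ = simulate_expression(cfg, ann)
        muts = simulate_mutations(cfg, ann, samples)
        from isoswitch.mutations import mutation_counts

        groups = {
            g: samples.loc[samples["group"] == g, "sample_id"].tolist()
            for g in ("melanoma", "nevus")
        }
        counts = mutation_counts(muts, groups,
                                 genes=[g.gene_id for g in ann.genes])
        enriched = sorted(ann.truth.mut_enriched_genes)
        rate_ratio = (
            counts.loc[enriched, "melanoma"].sum() / 57
        ) / (counts.loc[enriched, "nevus"].sum() / 23)
        assert rate_ratio == pytest.approx(3.0, rel=0.15)

    def test_class_frequencies(self):
        cfg = SimulationConfig(seed=8, n_genes=220, n_switch_genes=0,
                               n_cooccur_isoforms=0, n_mut_enriched_genes=0)
        ann = simulate_annotation(cfg)
        _, samples, _ = simulate_expression(cfg, ann)
        muts = simulate_mutations(cfg, ann, samples)
        assert len(muts) >= 10_000
        freqs = muts.records["mut_class"].value_counts(normalize=True)
        for cls, p in CLASS_PROBS.items():
            assert freqs.get(cls, 0.0) == pytest.approx(p, abs=0.03)

    def test_cooccurrence_enriches_switched_samples(self, small_cohort):
        truth = small_cohort["truth"]
        muts = small_cohort["mutations"]
        ann = small_cohort["ann"]
        gene_of = ann.tx2gene()
        hit, tot = 0, 0
        for iso in truth.cooccur_isoforms:
            calls = truth.switch_call_truth.loc[iso]
            switched = set(calls.index[calls])
            mutated = muts.mutated_samples(gene_of[iso])
            hit += len(switched & mutated)
            tot += len(switched)
        assert tot > 0
        assert hit / tot >= small_cohort["cfg"].cooccur_rho


class TestReproducibility:
    def test_expression_bit_reproducible(self):
        cfg = SimulationConfig(seed=12, n_genes=25, n_switch_genes=5,
                               n_cooccur_isoforms=2, n_mut_enriched_genes=2)
        runs = []
        for _ in range(2):
            ann = simulate_annotation(cfg)
            ab, _, _ = simulate_expression(cfg, ann)
            runs.append(ab.values)
        pd.testing.assert_frame_equal(runs[0], runs[1])

    def test_mutations_bit_reproducible(self):
        cfg = SimulationConfig(seed=13, n_genes=25, n_switch_genes=5,
                               n_cooccur_isoforms=2, n_mut_enriched_genes=2)
        runs = []
        for _ in range(2):
            ann = simulate_annotation(cfg)
            _, samples, _ = simulate_expression(cfg, ann)
            runs.append(simulate_mutations(cfg, ann, samples).records)
        pd.testing.assert_frame_equal(runs[0], runs[1])
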