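import numpy as np
import pandas as pd
import pytest

from isoswitch.simulate import (
    SimulationConfig,
    simulate_annotation,
    simulate_expression,
    simulate_mutations,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SimulationConfig(
        seed=101,
        n_genes=80,
        n_switch_genes=12,
        n_cooccur_isoforms=6,
        n_mut_enriched_genes=6,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    """One small simulated cohort shared across tests (read-only)."""
    ann = simulate_annotation(small_cfg)
    abundance, samples, truth = simulate_expression(small_cfg, ann)
    muts = simulate_mutations(small_cfg, ann, samples)
    return {
        "cfg": small_cfg,
        "ann": ann,
        "abundance": abundance,
        "samples": samples,
        "truth": truth,
        "mutations": muts,
    }


@pytest.fixture()
def toy_abundance():
    """Two genes: GA with isoforms a1/a2 switching, GB single-isoform."""
    samples = [f"s{i}" for i in range(16)]
    groups = pd.Series(["A"] * 8 + ["B"] * 8, index=samples)
    values = pd.DataFrame(
        {
            s: [30.0, 70.0, 50.0] if g == "A" else [70.0, 30.0, 50.0]
            for s, g in groups.items()
        },
        index=["a1", "a2", "b1"],
    )
    tx2gene = pd.Series({"a1": "GA", "a2": "GA", "b1": "GB"})
    from isoswitch.switching import AbundanceMatrix

    return AbundanceMatrix(values, tx2gene, groups)
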