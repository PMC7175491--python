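import numpy as np
import pandas as pd
import pytest

from crcmeth import synthetic


@pytest.fixture(scope="session")
def small_cohort():
    """A modest four-arm cohort with known injected effects."""
    return synthetic.simulate_cohort(
        n_probes=1500,
        n_genes=50,
        n_normal=12,
        n_lga=10,
        n_hga=12,
        n_cancer=10,
        effects=synthetic.EffectSpec(
            n_hyper_sites=60,
            n_hypo_sites=60,
            marker_genes=("GENE_0001",),
            seed=23,
        ),
        seed=21,
    )


@pytest.fixture()
def tiny_annot():
    """Hand-built probe annotation: 10 probes on three chromosomes."""
    return pd.DataFrame(
        {
            "chrom": ["chr1"] * 4 + ["chr2"] * 3 + ["chrY"] * 2 + ["chrX"],
            "pos": [100, 200, 300, 400, 100, 250, 500, 100, 300, 150],
            "gene": ["GENE_A"] * 4 + ["GENE_B"] * 3 + ["", "", ""],
            "region_category": [
                "TSS200",
                "TSS1500",
                "1stExon",
                "Body",
                "TSS200",
                "5'UTR",
                "Body",
                "intergenic",
                "intergenic",
                "intergenic",
            ],
            "island_relation": [
                "island",
                "shore",
                "island",
                "open_sea",
                "island",
                "island",
                "shelf",
                "open_sea",
                "open_sea",
                "open_sea",
            ],
            "snp_flagged": [False, False, False, True, False, False, False, False, False, False],
        },
        index=pd.Index([f"cg{i:02d}" for i in range(10)], name="probe_id"),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
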