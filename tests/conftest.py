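import numpy as np
import pandas as pd
import pytest

from mirqtl.cohort import (SimulationScenario, VariantBlock, simulate_genotypes,
                           simulate_mirna_panel)


@pytest.fixture(scope="session")
def small_cohort():
    """A 1,000-sample cohort with two LD blocks and two planted cis effects."""
    blocks = [VariantBlock(n_variants=25, rho=0.8, chrom="1",
                           start_pos=1_000_000, maf_range=(0.1, 0.5)),
              VariantBlock(n_variants=25, rho=0.0, chrom="2",
                           start_pos=5_000_000, maf_range=(0.1, 0.5))]
    scenario = SimulationScenario(n_samples=1000, blocks=blocks,
                                  mirna_ids=["miR-a", "miR-b"], seed=42)
    geno = simulate_genotypes(scenario)
    scenario.effect_table = pd.DataFrame([
        {"mirna_id": "miR-a", "variant_id": geno.variant_ids[10], "beta": 0.4},
        {"mirna_id": "miR-b", "variant_id": geno.variant_ids[30], "beta": 0.5},
    ])
    expr = simulate_mirna_panel(geno, scenario)
    annot = pd.DataFrame([
        {"mirna_id": "miR-a", "chrom": "1", "mature_start": 1_050_000},
        {"mirna_id": "miR-b", "chrom": "2", "mature_start": 5_060_000},
    ])
    return geno, expr, annot, scenario


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def toy_sumstats(betas, ses, pos=None, chrom="1", n=10_000, eafs=None,
                 alleles=None):
    """Hand-built summary-stat frame for small harmonisation/COJO tests."""
    from scipy.stats import norm

    k = len(betas)
    pos = pos or [1000 * (j + 1) for j in range(k)]
    eafs = eafs or [0.3] * k
    alleles = alleles or [("A", "G")] * k
    z = np.asarray(betas) / np.asarray(ses)
    return pd.DataFrame({
        "variant_id": [f"v{j + 1}" for j in range(k)],
        "chrom": chrom, "pos": pos,
        "effect_allele": [a[0] for a in alleles],
        "other_allele": [a[1] for a in alleles],
        "eaf": eafs, "beta": betas, "se": ses,
        "pval": 2 * norm.sf(np.abs(z)), "n": n,
    })
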