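"""Simulate the discovery cohort: genotypes with block LD, plasma miRNA
levels with planted cis/trans effects, and the miRNA annotation.

Writes results/cohort/ (dosage, variant metadata, expression, covariates,
annotation). Later numbered scripts read these files.
"""

from pathlib import Path

import pandas as pd

from mirqtl import io as mio
from mirqtl.cohort import (SimulationScenario, VariantBlock, simulate_genotypes,
                           simulate_mirna_panel)

OUT = Path("results/cohort")
SEED = 20_240_001

BLOCKS = [
    VariantBlock(n_variants=60, rho=0.8, chrom="1", start_pos=1_000_000),
    VariantBlock(n_variants=60, rho=0.6, chrom="1", start_pos=2_000_000),
    VariantBlock(n_variants=60, rho=0.0, chrom="2", start_pos=5_000_000),
]
MIRNAS = pd.DataFrame([
    {"mirna_id": "miR-sim-1", "chrom": "1", "mature_start": 1_120_000},
    {"mirna_id": "miR-sim-2", "chrom": "1", "mature_start": 2_120_000},
    {"mirna_id": "miR-sim-3", "chrom": "2", "mature_start": 5_120_000},
    {"mirna_id": "miR-sim-4", "chrom": "2", "mature_start": 5_200_000},
])


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    scenario = SimulationScenario(
        n_samples=2178,  # discovery cohort size
        blocks=BLOCKS, mirna_ids=MIRNAS["mirna_id"].tolist(), seed=SEED)
    geno = simulate_genotypes(scenario)
    ids = geno.variant_ids
    # two cis effects for miR-sim-1, one for miR-sim-2, one *trans* effect
    # (chromosome 2 variant) for miR-sim-2, nothing for miR-sim-3/4
    scenario.effect_table = pd.DataFrame([
        {"mirna_id": "miR-sim-1", "variant_id": ids[20], "beta": 0.40},
        {"mirna_id": "miR-sim-1", "variant_id": ids[45], "beta": 0.30},
        {"mirna_id": "miR-sim-2", "variant_id": ids[80], "beta": 0.45},
        {"mirna_id": "miR-sim-2", "variant_id": ids[140], "beta": 0.25},
    ])
    expr = simulate_mirna_panel(geno, scenario)

    mio.write_genotype_tsv(geno, OUT / "discovery")
    mio.write_expression_tsv(expr, OUT / "discovery")
    mio.write_vcf(geno, OUT / "discovery.vcf")
    MIRNAS.to_csv(OUT / "mirna_annotation.tsv", sep="\t", index=False)
    scenario.effect_table.to_csv(OUT / "true_effects.tsv", sep="\t",
                                 index=False)
    print(f"cohort: {len(geno.samples)} samples x {len(geno.variants)} "
          f"variants, {len(expr.mirna_ids)} miRNAs -> {OUT}")


if __name__ == "__main__":
    main()
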