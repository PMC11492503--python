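"""Instrument selection, genetic risk scores and PheWAS in a simulated
biobank cohort.

Per miRNA: BH-FDR selection of cis instruments (q < 0.1) with clumping at
r² < 0.1, then — following the decision tree — a single-variant PheWAS when
one instrument survives and a GRS PheWAS when several do, on a phenome with
one phecode truly affected by the first miRNA's score.
Writes results/phewas/.
"""

from importlib import import_module
from pathlib import Path

import numpy as np
import pandas as pd

from mirqtl import io as mio
from mirqtl.cohort import (SimulationScenario, simulate_case_control_phenome,
                           simulate_genotypes)
from mirqtl.phewas import compute_grs, run_phewas, select_instruments
from mirqtl.sumstats import LDMatrix

IN = Path("results/cohort")
SCAN = Path("results/scan")
OUT = Path("results/phewas")
SEED = 20_240_006
N_BIOBANK = 40_000
N_PHECODES = 20


def main() -> None:
    if not (SCAN / "associations.tsv").exists():
        raise SystemExit("run analysis/02_qtl_scan.py first")
    OUT.mkdir(parents=True, exist_ok=True)
    geno = mio.read_genotype_tsv(IN / "discovery")
    assoc = pd.read_csv(SCAN / "associations.tsv", sep="\t",
                        dtype={"chrom": str})
    ld = LDMatrix.from_genotypes(geno.dosage, geno.variant_ids)

    sim01 = import_module("01_simulate_cohort")
    biobank = simulate_genotypes(
        SimulationScenario(n_samples=N_BIOBANK, blocks=sim01.BLOCKS,
                           mirna_ids=["-"], seed=SEED),
        variants=geno.variants)

    sets = {}
    for mirna, cis in assoc[assoc["cis"]].groupby("mirna_id"):
        iset = select_instruments(cis, ld, mirna_id=mirna)
        if len(iset):
            sets[mirna] = iset

    results = []
    for k, (mirna, iset) in enumerate(sorted(sets.items())):
        score = compute_grs(biobank, iset)
        effects = np.zeros(N_PHECODES)
        if k == 0:
            effects[0] = 0.25  # one genuinely score-driven phecode
        phenome = simulate_case_control_phenome(
            score, effects, np.full(N_PHECODES, 0.03), seed=SEED + 7 + k,
            samples=biobank.samples)
        res = run_phewas(score, phenome, min_cases=200)
        res.insert(0, "mirna_id", mirna)
        res.insert(1, "mode", "single-variant" if len(iset) == 1 else "grs")
        res.insert(2, "n_instruments", len(iset))
        results.append(res)
    out = pd.concat(results, ignore_index=True)
    out.to_csv(OUT / "phewas.tsv", sep="\t", index=False, float_format="%.8g")
    n_hits = int((out["q"] < 0.05).sum())
    print(f"phewas: {len(sets)} miRNAs instrumented "
          f"({[len(s) for s in sets.values()]} instruments); "
          f"{n_hits} FDR-significant association(s) across "
          f"{out['phecode'].nunique()} phecodes")


if __name__ == "__main__":
    main()
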