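"""Replication in an independent cohort, conditional/joint selection and
genomic risk loci.

A second cohort is simulated on the same variant grid, significant discovery
associations are harmonised and tested under the Bonferroni/concordance
replication rule, COJO-style stepwise selection resolves independent signals
per miRNA, and loci are defined by LD clumping with 250-kb block merging.
Writes results/replication/.
"""

from pathlib import Path

import pandas as pd

from mirqtl import io as mio
from mirqtl.cohort import SimulationScenario, simulate_genotypes, simulate_mirna_panel
from mirqtl.qtl import run_qtl_scan
from mirqtl.sumstats import (CojoParams, LDMatrix, assess_replication,
                             cojo_stepwise, define_genomic_loci,
                             harmonize_summary_stats)

IN = Path("results/cohort")
SCAN = Path("results/scan")
OUT = Path("results/replication")
SEED = 20_240_002


def main() -> None:
    if not (SCAN / "associations.tsv").exists():
        raise SystemExit("run analysis/02_qtl_scan.py first")
    OUT.mkdir(parents=True, exist_ok=True)
    geno = mio.read_genotype_tsv(IN / "discovery")
    assoc = pd.read_csv(SCAN / "associations.tsv", sep="\t",
                        dtype={"chrom": str})
    truth = pd.read_csv(IN / "true_effects.tsv", sep="\t")

    # independent replication cohort on the same grid, same true effects
    from importlib import import_module

    sim01 = import_module("01_simulate_cohort")
    scenario = SimulationScenario(
        n_samples=2000, blocks=sim01.BLOCKS,
        mirna_ids=sim01.MIRNAS["mirna_id"].tolist(), seed=SEED)
    rep_geno = simulate_genotypes(scenario, variants=geno.variants)
    scenario.effect_table = truth
    rep_expr = simulate_mirna_panel(rep_geno, scenario)
    rep_assoc = run_qtl_scan(rep_expr, rep_geno, sim01_covars())

    sig = assoc[assoc["significant"]]
    rows = []
    for mirna, hits in sig.groupby("mirna_id"):
        rep = rep_assoc[rep_assoc["mirna_id"] == mirna]
        harm, _ = harmonize_summary_stats(
            hits.drop(columns=["mirna_id"]), rep.drop(columns=["mirna_id"]))
        if len(harm) == 0:
            continue
        out = assess_replication(
            harm.rename(columns={c + "_a": c + "_disc" for c in
                                 ["eaf", "beta", "se", "pval", "n"]})
                .rename(columns={c + "_b": c + "_rep" for c in
                                 ["eaf", "beta", "se", "pval", "n"]})
                [["variant_id", "beta_disc", "pval_disc"]].assign(mirna_id=mirna),
            harm[["variant_id"]].assign(
                mirna_id=mirna, beta_rep=harm["beta_b"],
                pval_rep=harm["pval_b"]),
            m_tested=len(sig))
        rows.append(out)
    repl = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    repl.to_csv(OUT / "replication.tsv", sep="\t", index=False,
                float_format="%.8g")
    rate = repl["replicated"].mean() if len(repl) else float("nan")

    # conditional/joint selection per miRNA over its significant region
    ld = LDMatrix.from_genotypes(geno.dosage, geno.variant_ids)
    cojo_rows = []
    for mirna, hits in sig.groupby("mirna_id"):
        sel = cojo_stepwise(hits.drop(columns=["mirna_id"]), ld,
                            CojoParams(p_select=2.4e-11))
        sel.insert(0, "mirna_id", mirna)
        cojo_rows.append(sel)
    cojo = pd.concat(cojo_rows, ignore_index=True) if cojo_rows else pd.DataFrame()
    cojo.to_csv(OUT / "conditional_joint.tsv", sep="\t", index=False,
                float_format="%.8g")

    loci = define_genomic_loci(sig.reset_index(drop=True), ld)
    loci_df = pd.DataFrame([{"chrom": l.chrom, "start": l.start, "end": l.end,
                             "lead": l.lead_variant,
                             "n_members": len(l.members),
                             "mirnas": ",".join(l.mirna_ids)} for l in loci])
    loci_df.to_csv(OUT / "loci.tsv", sep="\t", index=False)

    print(f"replication: {len(repl)} associations tested, "
          f"{100 * rate:.0f}% replicated; "
          f"{len(cojo)} conditionally independent signals; "
          f"{len(loci)} genomic risk loci")


def sim01_covars() -> list[str]:
    return ["age", "sex", "pc1", "pc2", "pc3", "pc4", "pc5"]


if __name__ == "__main__":
    main()
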