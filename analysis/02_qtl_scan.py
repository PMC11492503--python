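"""Genome-wide miRNA-eQTL scan of the simulated discovery cohort.

OLS per (miRNA, variant) with age, sex and five PCs as covariates, cis/trans
classification at the ±500 kb window, the Bonferroni-corrected genome-wide
threshold (5e-8 / number of phenotypes) and the miRNA pairwise correlation
summary. Writes results/scan/.
"""

from pathlib import Path

import pandas as pd

from mirqtl import io as mio
from mirqtl.qtl import (classify_cis_trans, pairwise_mirna_correlation,
                        run_qtl_scan, significance_threshold)

IN = Path("results/cohort")
OUT = Path("results/scan")
COVARS = ["age", "sex", "pc1", "pc2", "pc3", "pc4", "pc5"]


def main() -> None:
    if not (IN / "discovery.expression.tsv").exists():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    OUT.mkdir(parents=True, exist_ok=True)
    geno = mio.read_genotype_tsv(IN / "discovery")
    expr = mio.read_expression_tsv(IN / "discovery")
    annot = pd.read_csv(IN / "mirna_annotation.tsv", sep="\t",
                        dtype={"chrom": str})

    assoc = run_qtl_scan(expr, geno, COVARS)
    assoc = classify_cis_trans(assoc, annot, window=500_000)
    threshold = significance_threshold(5e-8, len(expr.mirna_ids))
    assoc["significant"] = assoc["pval"] < threshold
    assoc.to_csv(OUT / "associations.tsv", sep="\t", index=False,
                 float_format="%.8g")

    sig = assoc[assoc["significant"]]
    corr = pairwise_mirna_correlation(expr)
    summary = {
        "n_tests": len(assoc), "threshold": threshold,
        "n_significant": int(len(sig)),
        "n_cis_significant": int(sig["cis"].sum()),
        "n_trans_significant": int((~sig["cis"]).sum()),
        "max_r2_explained": float(sig["r2_explained"].max()) if len(sig) else 0.0,
        "median_abs_mirna_correlation": corr.median_abs_r,
    }
    pd.Series(summary).to_csv(OUT / "summary.tsv", sep="\t", header=False)
    print(f"scan: {summary['n_significant']} significant associations "
          f"({summary['n_cis_significant']} cis / "
          f"{summary['n_trans_significant']} trans) at P < {threshold:.3g}; "
          f"top r2 explained {summary['max_r2_explained']:.3f}")


if __name__ == "__main__":
    main()
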