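"""Per-variant linear-model association scanning of miRNA (or metabolite) levels.

Each (phenotype, variant) pair is tested with ordinary least squares of the
phenotype on the allele dosage plus covariates and an intercept; the dosage
coefficient is per effect-allele copy. The scan is computed with the
Frisch–Waugh decomposition (residualise phenotype and dosages on the covariate
block once, then per-variant simple regression on the residuals), which yields
the identical dosage coefficient, SE and t as the full multiple regression at
a fraction of the cost. Two-sided p-values use the t distribution with the
residual degrees of freedom of the full model, n − (covariates + 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist
from statsmodels.stats.multitest import multipletests

from .cohort import ExpressionMatrix, GenotypeMatrix

__all__ = [
    "run_qtl_scan",
    "classify_cis_trans",
    "significance_threshold",
    "variance_explained",
    "pairwise_mirna_correlation",
    "feature_pair_regression",
    "CorrelationSummary",
]

log = logging.getLogger(__name__)

MONOMORPHIC_MAF = 1e-4  # sample-MAF floor below which a variant is skipped


@dataclass
class CorrelationSummary:
    """Pairwise Pearson correlation matrix with off-diagonal |r| summaries."""

    matrix: pd.DataFrame
    median_abs_r: float
    iqr_abs_r: float


def _covariate_design(covariates: pd.DataFrame, names: list[str],
                      n: int) -> np.ndarray:
    cols = [np.ones(n)]
    for name in names:
        if name not in covariates.columns:
            raise KeyError(f"covariate {name!r} not found")
        cols.append(covariates[name].to_numpy(dtype=float))
    C = np.column_stack(cols)
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    return C


def _residualise(C: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Project the columns of M off the column space of C."""
    coef, *_ = np.linalg.lstsq(C, M, rcond=None)
    return M - C @ coef


def run_qtl_scan(expr: ExpressionMatrix,
                 geno: GenotypeMatrix,
                 covariate_names: list[str] | None = None) -> pd.DataFrame:
    """OLS association of every miRNA with every variant.

    Returns a long DataFrame with one row per (miRNA, variant): summary-stat
    columns (variant metadata, beta, se, pval, n) plus mirna_id, t_stat, df and
    r2_explained = t²/(t² + df). Monomorphic variants (sample MAF below 1e-4)
    are skipped and counted in the log.
    """
    if expr.samples != geno.samples:
        raise ValueError("expression and genotype matrices must share sample order")
    covariate_names = list(covariate_names or [])
    n = len(expr.samples)
    C = _covariate_design(expr.covariates, covariate_names, n)
    k = len(covariate_names)
    df = n - (k + 2)
    if df < 1:
        raise ValueError("not enough residual degrees of freedom")

    maf = np.minimum(geno.variants["eaf"].to_numpy(),
                     1 - geno.variants["eaf"].to_numpy())
    sample_af = geno.dosage.mean(axis=0) / 2.0
    sample_maf = np.minimum(sample_af, 1 - sample_af)
    keep = sample_maf >= MONOMORPHIC_MAF
    n_skipped = int((~keep).sum())
    if n_skipped:
        log.info("run_qtl_scan: skipped %d monomorphic variants", n_skipped)

    G = _residualise(C, geno.dosage[:, keep])
    Y = _residualise(C, expr.values)
    ss_g = np.einsum("ij,ij->j", G, G)
    ss_y = np.einsum("ij,ij->j", Y, Y)

    meta = geno.variants.loc[keep].reset_index(drop=True)
    records = []
    for m, mirna in enumerate(expr.mirna_ids):
        y = Y[:, m]
        beta = (G.T @ y) / ss_g
        rss = np.maximum(ss_y[m] - beta ** 2 * ss_g, 0.0)
        se = np.sqrt(np.maximum(rss, 1e-300) / df / ss_g)
        tstat = np.divide(beta, se, out=np.zeros_like(beta), where=se > 0)
        # exact-fit columns (rss == 0): report infinite t, p at the floor
        exact = (rss == 0) & (np.abs(beta) > 0)
        tstat[exact] = np.inf
        pval = np.clip(2.0 * t_dist.sf(np.abs(tstat), df), np.nextafter(0, 1), 1.0)
        block = meta[["variant_id", "chrom", "pos", "effect_allele",
                      "other_allele", "eaf"]].copy()
        block.insert(0, "mirna_id", mirna)
        block["beta"] = beta
        block["se"] = se
        block["t_stat"] = tstat
        block["pval"] = pval
        block["n"] = n
        block["df"] = df
        block["r2_explained"] = variance_explained(tstat, df)
        records.append(block)
    out = pd.concat(records, ignore_index=True)
    out.attrs["n_skipped_monomorphic"] = n_skipped
    return out


def classify_cis_trans(assoc: pd.DataFrame,
                       annot: pd.DataFrame,
                       window: int = 500_000) -> pd.DataFrame:
    """Flag each association cis/trans by distance to the mature-miRNA start.

    cis ⇔ same chromosome and |pos − mature_start| ≤ window (boundary
    inclusive); everything else, including other chromosomes, is trans.
    """
    required = {"mirna_id", "chrom", "mature_start"}
    if not required.issubset(annot.columns):
        raise ValueError(f"annotation needs columns {sorted(required)}")
    missing = set(assoc["mirna_id"]) - set(annot["mirna_id"])
    if missing:
        raise KeyError(f"missing annotation for miRNAs: {sorted(missing)[:5]}")
    ann = annot.set_index("mirna_id")
    out = assoc.copy()
    m_chrom = ann.loc[out["mirna_id"], "chrom"].to_numpy(dtype=str)
    m_start = ann.loc[out["mirna_id"], "mature_start"].to_numpy(dtype=np.int64)
    same = out["chrom"].to_numpy(dtype=str) == m_chrom
    dist = np.abs(out["pos"].to_numpy(dtype=np.int64) - m_start)
    out["cis"] = same & (dist <= window)
    return out


def significance_threshold(alpha_gw: float, n_phenotypes: int) -> float:
    """Bonferroni-corrected genome-wide threshold: alpha_gw / n_phenotypes."""
    if not 0.0 < alpha_gw < 1.0:
        raise ValueError("alpha_gw must lie in (0, 1)")
    if n_phenotypes < 1:
        raise ValueError("n_phenotypes must be at least 1")
    return alpha_gw / n_phenotypes


def variance_explained(t_stat, df):
    """Fraction of phenotype variance explained by one variant: t²/(t² + df)."""
    if np.any(np.asarray(df) < 1):
        raise ValueError("df must be at least 1")
    t2 = np.square(t_stat)
    with np.errstate(invalid="ignore"):
        out = np.where(np.isinf(t2), 1.0, t2 / (t2 + df))
    return out


def pairwise_mirna_correlation(expr: ExpressionMatrix,
                               mirna_subset: list[str] | None = None
                               ) -> CorrelationSummary:
    """Pearson correlations between miRNA levels, summarised over |r| off-diagonals."""
    ids = mirna_subset or expr.mirna_ids
    if len(ids) < 2:
        raise ValueError("need at least two miRNAs")
    idx = [expr.mirna_ids.index(m) for m in ids]
    X = expr.values[:, idx]
    if np.any(X.std(axis=0) == 0):
        raise ValueError("zero-variance miRNA column")
    R = np.corrcoef(X, rowvar=False)
    off = np.abs(R[np.triu_indices_from(R, k=1)])
    q75, q25 = np.percentile(off, [75, 25])
    return CorrelationSummary(
        matrix=pd.DataFrame(R, index=ids, columns=ids),
        median_abs_r=float(np.median(off)),
        iqr_abs_r=float(q75 - q25),
    )


def feature_pair_regression(expr: ExpressionMatrix,
                            features: pd.DataFrame,
                            covariate_names: list[str] | None = None,
                            fdr_q: float = 0.05) -> pd.DataFrame:
    """Linear regression of every feature (e.g. metabolite) on every miRNA.

    Feature is the outcome, miRNA level the predictor, adjusting for the named
    covariate columns of ``expr.covariates``. Benjamini–Hochberg q-values are
    computed over all pairs; ``significant`` flags q < fdr_q.
    """
    if list(features.index) != expr.samples:
        raise ValueError("feature table must be indexed by the same samples")
    covariate_names = list(covariate_names or [])
    n = len(expr.samples)
    C = _covariate_design(expr.covariates, covariate_names, n)
    k = len(covariate_names)
    df = n - (k + 2)
    X = _residualise(C, expr.values)          # miRNA predictors
    Y = _residualise(C, features.to_numpy(dtype=float))
    ss_x = np.einsum("ij,ij->j", X, X)
    ss_y = np.einsum("ij,ij->j", Y, Y)
    B = (X.T @ Y) / ss_x[:, None]             # (n_mirna, n_feature)
    RSS = ss_y[None, :] - B ** 2 * ss_x[:, None]
    SE = np.sqrt(np.maximum(RSS, 1e-300) / df / ss_x[:, None])
    T = B / SE
    P = np.clip(2.0 * t_dist.sf(np.abs(T), df), np.nextafter(0, 1), 1.0)
    rows = pd.DataFrame({
        "mirna_id": np.repeat(expr.mirna_ids, len(features.columns)),
        "feature_id": np.tile(features.columns, len(expr.mirna_ids)),
        "beta": B.ravel(), "se": SE.ravel(), "t_stat": T.ravel(),
        "pval": P.ravel(), "n": n, "df": df,
    })
    rejected, qvals, *_ = multipletests(rows["pval"], method="fdr_bh",
                                        alpha=fdr_q)
    rows["q"] = qvals
    rows["significant"] = rejected
    return rows
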