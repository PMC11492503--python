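"""SNP heritability from a genetic relationship matrix.

The GRM is the GCTA form, A_jk = (1/M)·Σ_i (x_ij − 2p_i)(x_ik − 2p_i) /
(2p_i(1 − p_i)). Narrow-sense SNP heritability is estimated by
Haseman–Elston regression: after residualising the phenotype on covariates
and standardising, the cross-products z_j z_k of unrelated sample pairs are
regressed on the off-diagonal GRM entries; the slope estimates h². Estimation
uncertainty is summarised by permutation p-values obtained by shuffling
phenotype labels, with p = (1 + #{permuted ≥ observed}) / (n_perm + 1).

This estimator targets the same estimand as score-based fast heritability
methods (narrow-sense SNP h² under a random-effect genetic model with
permutation-calibrated significance) with a far simpler moment construction;
the permutation-p semantics are identical.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .cohort import GenotypeMatrix

__all__ = ["GRM", "HeritabilityResult", "compute_grm", "filter_relatedness",
           "estimate_h2", "permutation_pvalue"]


@dataclass
class GRM:
    """Genetic relationship matrix with sample ids and the variant count used."""

    sample_ids: list[str]
    matrix: np.ndarray
    n_variants: int

    def __post_init__(self) -> None:
        k = len(self.sample_ids)
        if self.matrix.shape != (k, k):
            raise ValueError("GRM shape does not match sample ids")

    def subset(self, ids: list[str]) -> "GRM":
        pos = [self.sample_ids.index(s) for s in ids]
        return GRM(ids, self.matrix[np.ix_(pos, pos)], self.n_variants)


@dataclass
class HeritabilityResult:
    h2: float                 # clipped to [0, 1]
    h2_unclipped: float
    permutation_p: float | None
    n_permutations: int
    n_samples: int
    n_variants: int


def compute_grm(geno: GenotypeMatrix, maf_min: float = 0.1,
                info_min: float = 0.5,
                info: np.ndarray | None = None) -> GRM:
    """GCTA-style GRM over variants passing MAF (and optional imputation-INFO) filters.

    Allele frequencies are taken from the sample; variants with sample MAF
    below ``maf_min`` — or INFO below ``info_min`` when an INFO vector is
    supplied — are removed before construction.
    """
    p = geno.dosage.mean(axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    keep = maf >= maf_min
    if info is not None:
        keep &= np.asarray(info) >= info_min
    if not keep.any():
        raise ValueError("all variants removed by GRM filters")
    X = geno.dosage[:, keep]
    p = p[keep]
    Z = (X - 2 * p) / np.sqrt(2 * p * (1 - p))
    M = Z.shape[1]
    A = (Z @ Z.T) / M
    return GRM(sample_ids=list(geno.samples), matrix=A, n_variants=M)


def filter_relatedness(grm: GRM, cutoff: float = 0.025) -> list[str]:
    """Greedily drop the sample in the most above-cutoff pairs until none remain."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    A = np.abs(grm.matrix.copy())
    np.fill_diagonal(A, 0.0)
    active = np.ones(len(grm.sample_ids), dtype=bool)
    while True:
        over = (A > cutoff) & active[:, None] & active[None, :]
        counts = over.sum(axis=1)
        if counts.max(initial=0) == 0:
            break
        worst = int(np.argmax(counts))
        active[worst] = False
    return [s for s, a in zip(grm.sample_ids, active) if a]


def _he_slope(A: np.ndarray, z: np.ndarray, denom: float) -> float:
    """HE regression slope through the origin over off-diagonal pairs."""
    quad = float(z @ A @ z) - float(np.diag(A) @ (z * z))
    return quad / denom


def estimate_h2(grm: GRM, phenotype: np.ndarray,
                covariates: pd.DataFrame | None = None,
                n_perm: int = 0, seed: int = 0) -> HeritabilityResult:
    """Haseman–Elston SNP heritability with optional permutation p-value.

    The phenotype is residualised on the covariates (plus intercept) and
    standardised; the HE slope is clipped to [0, 1] for reporting while the
    raw value is retained. When ``n_perm`` > 0, the permutation p-value of
    the observed slope is computed by phenotype-label shuffling.
    """
    y = np.asarray(phenotype, dtype=float)
    if y.std(ddof=0) == 0:
        raise ValueError("phenotype has zero variance")
    n = len(y)
    if n != len(grm.sample_ids):
        raise ValueError("phenotype length must match GRM")
    if covariates is not None and len(covariates.columns) > 0:
        C = np.column_stack([np.ones(n), covariates.to_numpy(dtype=float)])
        coef, *_ = np.linalg.lstsq(C, y, rcond=None)
        y = y - C @ coef
    z = (y - y.mean()) / y.std(ddof=0)

    A = grm.matrix
    off = A.copy()
    np.fill_diagonal(off, 0.0)
    denom = float(np.sum(off * off))
    if denom <= 0:
        raise ValueError("degenerate GRM: no off-diagonal variation")

    slope = _he_slope(A, z, denom)
    perm_p = None
    if n_perm > 0:
        perm_p = permutation_pvalue(lambda v: _he_slope(A, v, denom), z,
                                    n_perm=n_perm, seed=seed)
    return HeritabilityResult(h2=float(np.clip(slope, 0.0, 1.0)),
                              h2_unclipped=float(slope),
                              permutation_p=perm_p, n_permutations=n_perm,
                              n_samples=n, n_variants=grm.n_variants)


def permutation_pvalue(statistic_fn: Callable[[np.ndarray], float],
                       phenotype: np.ndarray, n_perm: int = 1000,
                       seed: int = 0) -> float:
    """p = (1 + #{permuted statistic ≥ observed}) / (n_perm + 1)."""
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    rng = np.random.default_rng(seed)
    y = np.asarray(phenotype, dtype=float)
    observed = statistic_fn(y)
    count = 0
    for _ in range(n_perm):
        if statistic_fn(rng.permutation(y)) >= observed:
            count += 1
    return (1 + count) / (n_perm + 1)
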