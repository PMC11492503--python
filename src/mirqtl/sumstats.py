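"""Cross-cohort summary-statistic operations.

Covers allele harmonisation between two summary-stat tracks, the replication
rule (Bonferroni-significant in the independent cohort with concordant effect
direction), conditional/joint stepwise model selection from marginal summary
statistics plus an LD reference (GCTA-COJO style, reconstructed on the
standardised-genotype scale), and the definition of genomic risk loci by
greedy LD clumping and block merging.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = [
    "LDMatrix", "CojoParams", "Locus",
    "harmonize_summary_stats", "assess_replication",
    "cojo_stepwise", "define_genomic_loci",
]

log = logging.getLogger(__name__)

_PALINDROMIC = {frozenset({"A", "T"}), frozenset({"C", "G"})}


@dataclass
class LDMatrix:
    """Signed variant correlation matrix from a reference panel."""

    variant_ids: list[str]
    r: np.ndarray
    panel_size: int = 0

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.variant_ids)
        if self.r.shape != (k, k):
            raise ValueError("LD matrix shape does not match variant ids")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise ValueError("LD matrix must be symmetric")

    @property
    def r2(self) -> np.ndarray:
        return self.r ** 2

    def subset(self, ids: list[str]) -> "LDMatrix":
        pos = [self.variant_ids.index(v) for v in ids]
        return LDMatrix(ids, self.r[np.ix_(pos, pos)], self.panel_size)

    @classmethod
    def from_genotypes(cls, dosage: np.ndarray, variant_ids: list[str]) -> "LDMatrix":
        r = np.corrcoef(dosage, rowvar=False)
        return cls(list(variant_ids), np.atleast_2d(r), panel_size=dosage.shape[0])


@dataclass
class CojoParams:
    """Thresholds for conditional/joint stepwise selection."""

    maf_min: float = 0.05
    p_select: float = 2.4e-11
    collinearity_r2: float = 0.9
    window_bp: int = 1_000_000  # regions are pre-windowed around lead SNPs

    def __post_init__(self) -> None:
        if not 0 <= self.maf_min < 0.5:
            raise ValueError("maf_min must lie in [0, 0.5)")
        if not 0 < self.p_select < 1:
            raise ValueError("p_select must lie in (0, 1)")
        if not 0 < self.collinearity_r2 <= 1:
            raise ValueError("collinearity_r2 must lie in (0, 1]")


@dataclass
class Locus:
    """A genomic risk locus: lead variant plus the LD-block extent."""

    chrom: str
    start: int
    end: int
    lead_variant: str
    members: list[str] = field(default_factory=list)
    mirna_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("locus start must not exceed end")


def _is_palindromic(ea: str, oa: str) -> bool:
    return frozenset({ea.upper(), oa.upper()}) in _PALINDROMIC


def harmonize_summary_stats(a: pd.DataFrame, b: pd.DataFrame,
                            drop_palindromic: bool = True,
                            eaf_rescue: bool = False,
                            eaf_rescue_margin: float = 0.08
                            ) -> tuple[pd.DataFrame, dict]:
    """Align track b's effect alleles to track a's; return merged pairs + drop log.

    Where b's effect/other alleles are swapped relative to a, b's beta sign
    and EAF are flipped. Palindromic (A/T, C/G) variants are strand-ambiguous
    and dropped by default; with ``eaf_rescue`` they are kept when both EAFs
    are far from 0.5 (|eaf − 0.5| > margin) and frequency-concordant after
    orientation. Unmatchable allele sets are dropped. Harmonisation is
    involutive: re-running on its own output changes nothing.
    """
    for df, name in [(a, "a"), (b, "b")]:
        if df["variant_id"].duplicated().any():
            raise ValueError(f"duplicate variant ids in track {name}")
    merged = a.merge(b, on="variant_id", suffixes=("_a", "_b"))
    drop_log = {"palindromic": 0, "allele_mismatch": 0,
                "unmatched": len(a) + len(b) - 2 * len(merged)}
    rows = []
    for row in merged.itertuples(index=False):
        ea_a, oa_a = row.effect_allele_a.upper(), row.other_allele_a.upper()
        ea_b, oa_b = row.effect_allele_b.upper(), row.other_allele_b.upper()
        if {ea_a, oa_a} != {ea_b, oa_b}:
            drop_log["allele_mismatch"] += 1
            continue
        palindromic = _is_palindromic(ea_a, oa_a)
        if palindromic and drop_palindromic and not eaf_rescue:
            drop_log["palindromic"] += 1
            continue
        flip = ea_b != ea_a
        beta_b = -row.beta_b if flip else row.beta_b
        eaf_b = 1.0 - row.eaf_b if flip else row.eaf_b
        if palindromic and drop_palindromic and eaf_rescue:
            if (abs(row.eaf_a - 0.5) <= eaf_rescue_margin
                    or abs(eaf_b - 0.5) <= eaf_rescue_margin):
                drop_log["palindromic"] += 1
                continue
        d = {"variant_id": row.variant_id, "chrom": row.chrom_a, "pos": row.pos_a,
             "effect_allele": ea_a, "other_allele": oa_a,
             "eaf_a": row.eaf_a, "beta_a": row.beta_a, "se_a": row.se_a,
             "pval_a": row.pval_a, "n_a": row.n_a,
             "eaf_b": eaf_b, "beta_b": beta_b, "se_b": row.se_b,
             "pval_b": row.pval_b, "n_b": row.n_b}
        rows.append(d)
    out = pd.DataFrame(rows)
    return out, drop_log


def assess_replication(discovery_hits: pd.DataFrame,
                       replication_stats: pd.DataFrame,
                       m_tested: int) -> pd.DataFrame:
    """Replicated ⇔ replication p < 0.05/m_tested and concordant β sign.

    Inputs must already be harmonised to a common effect allele. Matching is
    on variant_id (plus mirna_id when both carry it).
    """
    if m_tested < 1:
        raise ValueError("m_tested must be at least 1")
    keys = ["variant_id"]
    if "mirna_id" in discovery_hits.columns and "mirna_id" in replication_stats.columns:
        keys = ["mirna_id", "variant_id"]
    merged = discovery_hits.merge(replication_stats, on=keys,
                                  suffixes=("_disc", "_rep"))
    threshold = 0.05 / m_tested
    merged["replication_threshold"] = threshold
    merged["replicated"] = (
        (merged["pval_rep"] < threshold)
        & (np.sign(merged["beta_disc"]) == np.sign(merged["beta_rep"]))
    )
    return merged


def _nearest_psd(r: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    w, v = np.linalg.eigh(r)
    if w.min() >= -tol:
        return r
    warnings.warn("LD matrix not PSD; projecting to nearest PSD", stacklevel=3)
    w = np.clip(w, 1e-10, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


def _joint_model(R: np.ndarray, bz: np.ndarray, n: float,
                 idx: list[int]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Joint estimates on the standardised scale for the selected index set.

    With standardised genotypes X (unit variance) and phenotype variance 1,
    X'X = nR and X'y = n·bz where bz are the standardised marginal effects,
    so joint b = R_S⁻¹ bz_S, RSS = n(1 − b'bz_S) and Var(b) = σ̂² R_S⁻¹ / n.
    """
    S = np.ix_(idx, idx)
    Rs = R[S]
    b = np.linalg.solve(Rs, bz[idx])
    fitted = float(b @ bz[idx])
    sigma2 = max(n * (1.0 - fitted), 1e-12) / max(n - len(idx) - 1, 1)
    cov = sigma2 * np.linalg.inv(Rs) / n
    se = np.sqrt(np.diag(cov))
    z = b / se
    return b, se, z


def cojo_stepwise(region_stats: pd.DataFrame, ld: LDMatrix,
                  params: CojoParams | None = None) -> pd.DataFrame:
    """Stepwise conditional/joint selection from marginal summary statistics.

    Marginal per-dosage effects are first moved to the standardised-genotype
    scale via var(g) = 2·eaf·(1−eaf). Starting from the smallest marginal
    p-value, the variant with the smallest conditional p (its Wald p in the
    joint model over the current set plus the candidate) is added while that
    p is below ``p_select``; candidates in LD r² > ``collinearity_r2`` with
    any selected variant are never considered. Returns the final set with
    joint effects mapped back to the per-dosage scale.
    """
    params = params or CojoParams()
    stats = region_stats.reset_index(drop=True)
    if len(stats) == 0:
        raise ValueError("empty region")
    maf = np.minimum(stats["eaf"].to_numpy(), 1 - stats["eaf"].to_numpy())
    eligible_maf = maf > params.maf_min
    stats = stats.loc[eligible_maf].reset_index(drop=True)
    if len(stats) == 0:
        return _empty_cojo_frame()
    ld = ld.subset(stats["variant_id"].tolist())
    R = _nearest_psd(ld.r.copy())
    R2 = R ** 2

    eaf = stats["eaf"].to_numpy()
    scale = np.sqrt(2 * eaf * (1 - eaf))          # per-dosage → standardised
    z_marg = stats["beta"].to_numpy() / stats["se"].to_numpy()
    n = float(np.median(stats["n"]))
    bz = z_marg / np.sqrt(n + z_marg ** 2)        # standardised marginal beta
    p_marg = chi2.sf(z_marg ** 2, 1)

    selected: list[int] = []
    entry_p: list[float] = []
    order = np.argsort(p_marg, kind="stable")
    if p_marg[order[0]] >= params.p_select:
        return _empty_cojo_frame()
    selected.append(int(order[0]))
    entry_p.append(float(p_marg[order[0]]))

    while True:
        best_j, best_p = None, params.p_select
        for j in range(len(stats)):
            if j in selected:
                continue
            if np.any(R2[j, selected] > params.collinearity_r2):
                continue
            idx = selected + [j]
            try:
                _, _, zj = _joint_model(R, bz, n, idx)
            except np.linalg.LinAlgError:
                continue
            p_cond = float(chi2.sf(zj[-1] ** 2, 1))
            if p_cond < best_p:
                best_j, best_p = j, p_cond
        if best_j is None:
            break
        selected.append(best_j)
        entry_p.append(best_p)

    b_joint, se_joint, z_joint = _joint_model(R, bz, n, selected)
    p_joint = chi2.sf(z_joint ** 2, 1)
    out = stats.iloc[selected][["variant_id", "chrom", "pos", "effect_allele",
                                "other_allele", "eaf", "beta", "se", "pval",
                                "n"]].copy()
    out = out.rename(columns={"beta": "beta_marginal", "se": "se_marginal",
                              "pval": "pval_marginal"})
    out["beta_joint"] = b_joint / scale[selected]
    out["se_joint"] = se_joint / scale[selected]
    out["pval_joint"] = p_joint
    out["pval_conditional_entry"] = entry_p
    return out.reset_index(drop=True)


def _empty_cojo_frame() -> pd.DataFrame:
    return pd.DataFrame(columns=[
        "variant_id", "chrom", "pos", "effect_allele", "other_allele", "eaf",
        "beta_marginal", "se_marginal", "pval_marginal", "n",
        "beta_joint", "se_joint", "pval_joint", "pval_conditional_entry"])


def _greedy_clump(stats: pd.DataFrame, r2: np.ndarray, threshold: float
                  ) -> tuple[list[int], dict[int, list[int]]]:
    """Greedy p-ordered clumping; ties broken by (p, position).

    Returns the retained row indices and, per retained index, the rows it
    absorbed (those with r² ≥ threshold to it).
    """
    order = stats.sort_values(["pval", "pos"], kind="stable").index.tolist()
    kept: list[int] = []
    absorbed: dict[int, list[int]] = {}
    assigned: set[int] = set()
    for i in order:
        if i in assigned:
            continue
        kept.append(i)
        absorbed[i] = [i]
        assigned.add(i)
        for j in order:
            if j not in assigned and r2[i, j] >= threshold:
                absorbed[i].append(j)
                assigned.add(j)
    return kept, absorbed


def define_genomic_loci(significant: pd.DataFrame, ld: LDMatrix,
                        r2_indep: float = 0.6, r2_lead: float = 0.1,
                        merge_kb: int = 250) -> list[Locus]:
    """Genomic risk loci from significant variants and an LD reference.

    Independent significant variants come from greedy p-ordered clumping at
    r² < ``r2_indep``; these are re-clumped at r² < ``r2_lead`` to lead
    variants. Each independent significant variant defines an LD block (the
    span of significant variants with r² ≥ r2_indep to it); blocks on one
    chromosome are merged into a single locus when their gap is ≤ merge_kb.
    The locus lead is its smallest-p member. The result is order-invariant
    and loci are disjoint.
    """
    stats = significant.reset_index(drop=True)
    if len(stats) == 0:
        return []
    ld = ld.subset(stats["variant_id"].tolist())
    r2 = ld.r2

    indep_idx, blocks = _greedy_clump(stats, r2, r2_indep)

    # per independent-significant variant: LD-block extent over its absorbed rows
    spans = []
    for i in indep_idx:
        rows = stats.loc[blocks[i]]
        spans.append({"chrom": str(stats.loc[i, "chrom"]),
                      "start": int(rows["pos"].min()),
                      "end": int(rows["pos"].max()),
                      "rows": blocks[i]})
    spans.sort(key=lambda s: (s["chrom"], s["start"], s["end"]))

    merged: list[dict] = []
    for s in spans:
        if (merged and merged[-1]["chrom"] == s["chrom"]
                and s["start"] - merged[-1]["end"] <= merge_kb * 1000):
            merged[-1]["end"] = max(merged[-1]["end"], s["end"])
            merged[-1]["rows"].extend(s["rows"])
        else:
            merged.append({"chrom": s["chrom"], "start": s["start"],
                           "end": s["end"], "rows": list(s["rows"])})

    loci = []
    for m in merged:
        rows = stats.loc[sorted(set(m["rows"]))]
        lead_row = rows.sort_values(["pval", "pos"], kind="stable").iloc[0]
        mirnas = (sorted(rows["mirna_id"].unique())
                  if "mirna_id" in rows.columns else [])
        loci.append(Locus(chrom=m["chrom"], start=m["start"], end=m["end"],
                          lead_variant=str(lead_row["variant_id"]),
                          members=rows["variant_id"].tolist(),
                          mirna_ids=mirnas))
    return loci
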