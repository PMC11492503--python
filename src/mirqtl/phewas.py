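"""Phecode construction, genetic instruments, risk scores and PheWAS.

ICD-9/ICD-10 diagnosis records are aligned into phecodes (case = at least one
mapped occurrence; optional exclusion ranges turn would-be controls into
excluded samples). Per-miRNA genetic instruments come from a
Benjamini–Hochberg FDR threshold inside the cis window followed by greedy LD
clumping; multiple instruments are combined into a genetic risk score (GRS),
the weighted sum of effect-allele dosages with discovery betas as weights.
The PheWAS itself is a logistic regression of each eligible phecode (at least
``min_cases`` cases) on the standardised score plus covariates, with BH FDR
within each score's result set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .cohort import GenotypeMatrix, PhenomeTable
from .sumstats import LDMatrix

__all__ = ["InstrumentSet", "map_icd_to_phecodes", "select_instruments",
           "compute_grs", "run_phewas"]

log = logging.getLogger(__name__)


@dataclass
class InstrumentSet:
    """Selected instruments for one miRNA with discovery weights and provenance."""

    mirna_id: str
    variants: pd.DataFrame  # variant meta + weight (discovery beta), pval, q, cis
    q_threshold: float = 0.1
    clump_r2: float = 0.1
    window: int = 500_000

    def __len__(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return self.variants["variant_id"].tolist()


def _parse_range(txt: str) -> tuple[float, float]:
    lo, hi = txt.split("-")
    return float(lo), float(hi)


def map_icd_to_phecodes(records: pd.DataFrame, phecode_map: pd.DataFrame,
                        samples: list[str] | None = None) -> PhenomeTable:
    """Align (sample, vocabulary, code) diagnosis records into phecodes.

    ``phecode_map`` columns: code, vocabulary (icd9|icd10), phecode, and
    optionally group and exclude_range ("lo-hi" over numeric phecodes).
    Case = ≥1 mapped occurrence; control = no occurrence and not inside any
    exclusion range of that phecode; otherwise excluded (-1). Unknown
    vocabulary tags raise; unmapped codes are counted, not raised.
    """
    vocabs = set(phecode_map["vocabulary"].unique())
    bad = set(records["vocabulary"].unique()) - vocabs
    if bad:
        raise ValueError(f"unknown vocabulary tags: {sorted(bad)}")
    key = phecode_map.set_index(["vocabulary", "code"])
    if samples is None:
        samples = sorted(records["sample_id"].unique())
    phecodes = sorted(phecode_map["phecode"].astype(str).unique())
    status = pd.DataFrame(0, index=list(samples), columns=phecodes)

    n_unmapped = 0
    for row in records.itertuples(index=False):
        try:
            mapped = key.loc[(row.vocabulary, row.code)]
        except KeyError:
            n_unmapped += 1
            continue
        codes = ([str(mapped["phecode"])] if isinstance(mapped, pd.Series)
                 else mapped["phecode"].astype(str).tolist())
        for pc in codes:
            if row.sample_id in status.index:
                status.loc[row.sample_id, pc] = 1
    if n_unmapped:
        log.info("map_icd_to_phecodes: %d unmapped records", n_unmapped)

    groups = {}
    if "group" in phecode_map.columns:
        groups = (phecode_map.astype({"phecode": str})
                  .drop_duplicates("phecode").set_index("phecode")["group"]
                  .to_dict())

    if "exclude_range" in phecode_map.columns:
        ranges = (phecode_map.astype({"phecode": str})
                  .drop_duplicates("phecode").set_index("phecode")["exclude_range"])
        numeric = pd.to_numeric(pd.Series(phecodes), errors="coerce")
        for pc in phecodes:
            rng_txt = ranges.get(pc)
            if not isinstance(rng_txt, str) or "-" not in rng_txt:
                continue
            lo, hi = _parse_range(rng_txt)
            in_range = [p for p, v in zip(phecodes, numeric)
                        if p != pc and not np.isnan(v) and lo <= v <= hi]
            if not in_range:
                continue
            related_case = (status[in_range] == 1).any(axis=1)
            status.loc[related_case & (status[pc] == 0), pc] = -1

    return PhenomeTable(samples=list(samples), phecodes=phecodes, status=status,
                        groups=groups, n_unmapped=n_unmapped)


def select_instruments(cis_stats: pd.DataFrame, ld: LDMatrix,
                       mirna_id: str | None = None,
                       q_threshold: float = 0.1,
                       clump_r2: float = 0.1,
                       window: int = 500_000) -> InstrumentSet:
    """FDR-based instrument selection inside the cis window, then greedy clumping.

    BH q-values are computed over the supplied window-restricted statistics;
    survivors (q < q_threshold) are clumped by ascending p at r² < clump_r2.
    Weights are the discovery betas.
    """
    stats = cis_stats.reset_index(drop=True)
    if len(stats) == 0:
        raise ValueError("empty cis window")
    if mirna_id is None:
        mirna_id = (str(stats["mirna_id"].iloc[0])
                    if "mirna_id" in stats.columns else "unknown")
    _, qvals, *_ = multipletests(stats["pval"], method="fdr_bh")
    stats = stats.assign(q=qvals)
    surv = stats[stats["q"] < q_threshold].reset_index(drop=True)
    if len(surv) == 0:
        return InstrumentSet(mirna_id=mirna_id, variants=surv.assign(weight=[]),
                             q_threshold=q_threshold, clump_r2=clump_r2,
                             window=window)
    sub = ld.subset(surv["variant_id"].tolist())
    order = surv.sort_values(["pval", "pos"], kind="stable").index.tolist()
    kept: list[int] = []
    for i in order:
        if all(sub.r2[i, j] < clump_r2 for j in kept):
            kept.append(i)
    chosen = surv.loc[sorted(kept)].copy()
    chosen["weight"] = chosen["beta"]
    return InstrumentSet(mirna_id=mirna_id, variants=chosen.reset_index(drop=True),
                         q_threshold=q_threshold, clump_r2=clump_r2, window=window)


def compute_grs(geno: GenotypeMatrix, instruments: InstrumentSet) -> np.ndarray:
    """Weighted allele score: Σ weight·dosage with allele alignment.

    Instruments whose effect/other alleles are swapped relative to the
    genotype file contribute weight·(2 − dosage); a missing instrument or an
    unmatchable allele pair raises.
    """
    meta = geno.variants.set_index("variant_id")
    score = np.zeros(len(geno.samples))
    for row in instruments.variants.itertuples(index=False):
        if row.variant_id not in meta.index:
            raise KeyError(f"instrument {row.variant_id!r} missing from genotypes")
        g = meta.loc[row.variant_id]
        j = geno.variant_ids.index(row.variant_id)
        dose = geno.dosage[:, j]
        if (row.effect_allele, row.other_allele) == (g["effect_allele"],
                                                     g["other_allele"]):
            score += row.weight * dose
        elif (row.effect_allele, row.other_allele) == (g["other_allele"],
                                                       g["effect_allele"]):
            score += row.weight * (2.0 - dose)
        else:
            raise ValueError(f"allele mismatch for {row.variant_id!r}")
    return score


def run_phewas(score: np.ndarray, phenome: PhenomeTable,
               covariates: pd.DataFrame | None = None,
               min_cases: int = 200, q_alpha: float = 0.05) -> pd.DataFrame:
    """Logistic PheWAS of one score (or single-variant dosage) across phecodes.

    The score is standardised so effects are log-odds per SD. Phecodes with
    fewer than ``min_cases`` cases are skipped; excluded samples (-1) are
    dropped per phecode; perfect separation is flagged (beta/p missing).
    BH q-values are computed within this score's tested set.
    """
    score = np.asarray(score, dtype=float)
    z = (score - score.mean()) / score.std(ddof=0)
    n = len(z)
    if n != len(phenome.samples):
        raise ValueError("score length must match phenome")
    if covariates is not None and len(covariates.columns) > 0:
        C = covariates.to_numpy(dtype=float)
    else:
        C = np.empty((n, 0))

    rows = []
    for pc in phenome.phecodes:
        st = phenome.status[pc].to_numpy()
        use = st >= 0
        y = st[use]
        n_case = int((y == 1).sum())
        n_control = int((y == 0).sum())
        if n_case < min_cases:
            continue
        X = sm.add_constant(np.column_stack([z[use], C[use]]), prepend=True)
        separated = False
        beta = se = pval = np.nan
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=100)
            beta, se = fit.params[1], fit.bse[1]
            pval = fit.pvalues[1]
            if not np.isfinite(se) or se > 1e3:
                separated = True
        except (PerfectSeparationError, np.linalg.LinAlgError):
            separated = True
        if separated:
            log.warning("run_phewas: separation for phecode %s", pc)
            beta = se = pval = np.nan
        rows.append({"phecode": pc, "n_case": n_case, "n_control": n_control,
                     "beta": beta, "se": se, "pval": pval,
                     "group": phenome.groups.get(pc, ""),
                     "separated": separated})
    out = pd.DataFrame(rows)
    if len(out):
        tested = out["pval"].notna()
        q = np.full(len(out), np.nan)
        if tested.any():
            _, qv, *_ = multipletests(out.loc[tested, "pval"], method="fdr_bh",
                                      alpha=q_alpha)
            q[tested.to_numpy()] = qv
        out["q"] = q
    return out
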