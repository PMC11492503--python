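"""Synthetic population cohort generator.

Produces every input the downstream pipeline consumes — genotype dosages with
block linkage disequilibrium, plasma miRNA expression with additive cis/trans
genetic effects, binary phenomes, paired two-trait regional summary statistics
and exposure→mediator→outcome instrument panels — with the statistical
structure the analysis assumes, fully driven by a single seed.

LD is generated from AR(1)-correlated latent Gaussian haplotypes thresholded
at the allele-frequency quantile: adjacent variants within a block decay in
r² monotonically with distance, blocks are independent, and every quantity has
an analytic handle for testing. Dosages are hard allele counts in {0, 1, 2};
imputation uncertainty is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "VariantBlock",
    "SimulationScenario",
    "GenotypeMatrix",
    "ExpressionMatrix",
    "PhenomeTable",
    "MediationTriple",
    "simulate_genotypes",
    "simulate_mirna_panel",
    "simulate_case_control_phenome",
    "export_two_sample_stats",
    "simulate_mediation_triple",
]

SUMSTAT_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

# Unambiguous (non-palindromic) allele pairs used for simulated variants.
_ALLELE_PAIRS = [("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class VariantBlock:
    """One LD block: contiguous variants with AR(1) haplotype correlation rho."""

    n_variants: int
    rho: float = 0.8
    maf_range: tuple[float, float] = (0.05, 0.5)
    chrom: str = "1"
    start_pos: int = 1_000_000
    spacing_bp: int = 5_000

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ValueError("block needs at least one variant")
        if not -1.0 < self.rho < 1.0:
            raise ValueError(f"AR(1) parameter rho must lie in (-1, 1), got {self.rho}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"MAF range must lie inside (0, 1), got {self.maf_range}")


@dataclass
class SimulationScenario:
    """Full description of a synthetic cohort draw.

    ``effect_table`` rows are (mirna_id, variant_id, beta): the additive
    per-allele effect of the variant on that miRNA's log2-CPM level.
    ``covariate_effects`` maps covariate column name to its effect on every
    miRNA (the cohort-study nuisance structure: age, sex, sub-cohort, PCs).
    """

    n_samples: int
    blocks: Sequence[VariantBlock]
    mirna_ids: Sequence[str] = ()
    effect_table: pd.DataFrame | None = None
    residual_sd: float = 1.0
    covariate_effects: dict[str, float] = field(
        default_factory=lambda: {"age": 0.01, "sex": 0.10}
    )
    include_palindromic: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")


@dataclass
class GenotypeMatrix:
    """Sample × variant dosages in [0, 2] plus per-variant metadata."""

    samples: list[str]
    variants: pd.DataFrame  # variant_id, chrom, pos, effect_allele, other_allele, eaf
    dosage: np.ndarray  # shape (n_samples, n_variants)

    def __post_init__(self) -> None:
        assert self.dosage.shape == (len(self.samples), len(self.variants))

    @property
    def variant_ids(self) -> list[str]:
        return self.variants["variant_id"].tolist()

    def column(self, variant_id: str) -> np.ndarray:
        idx = self.variants.index[self.variants["variant_id"] == variant_id]
        if len(idx) == 0:
            raise KeyError(f"variant {variant_id!r} not in genotype matrix")
        return self.dosage[:, self.variants.index.get_loc(idx[0])]


@dataclass
class ExpressionMatrix:
    """Sample × miRNA log2-CPM levels with sample-level covariates."""

    samples: list[str]
    mirna_ids: list[str]
    values: np.ndarray  # shape (n_samples, n_mirnas)
    covariates: pd.DataFrame

    def column(self, mirna_id: str) -> np.ndarray:
        return self.values[:, self.mirna_ids.index(mirna_id)]


@dataclass
class PhenomeTable:
    """Binary case/control status per sample × phecode.

    ``status`` holds 1 (case), 0 (control) or -1 (excluded from analysis for
    that phecode). Counts are maintained alongside.
    """

    samples: list[str]
    phecodes: list[str]
    status: pd.DataFrame  # index samples, columns phecodes, values {1,0,-1}
    groups: dict[str, str] = field(default_factory=dict)
    n_unmapped: int = 0

    def case_count(self, phecode: str) -> int:
        return int((self.status[phecode] == 1).sum())

    def control_count(self, phecode: str) -> int:
        return int((self.status[phecode] == 0).sum())


@dataclass
class MediationTriple:
    """Instrument-level summary statistics for a mediation analysis.

    ``exposure_panel``: one row per exposure instrument with its effects on
    the exposure (bx), the mediator (bm) and the outcome (by), plus SEs.
    ``mediator_panel``: one row per independent mediator instrument with its
    effects on the mediator (bm) and outcome (by). Two-step mediation uses
    the exposure panel for θ_total and θ_EM and the mediator panel for θ_MO.
    """

    exposure_panel: pd.DataFrame
    mediator_panel: pd.DataFrame
    theta_em: float
    theta_mo: float
    theta_direct: float

    @property
    def theta_total(self) -> float:
        return self.theta_direct + self.theta_em * self.theta_mo


def _simulate_block_haplotypes(rng: np.random.Generator, n_hap: int,
                               block: VariantBlock, eaf: np.ndarray) -> np.ndarray:
    """AR(1) latent Gaussians thresholded at the allele-frequency quantile."""
    m = block.n_variants
    z = np.empty((n_hap, m))
    z[:, 0] = rng.standard_normal(n_hap)
    if m > 1:
        innov = rng.standard_normal((n_hap, m - 1))
        scale = np.sqrt(1.0 - block.rho ** 2)
        for j in range(1, m):
            z[:, j] = block.rho * z[:, j - 1] + scale * innov[:, j - 1]
    thresh = norm.ppf(eaf)
    return (z < thresh[None, :]).astype(np.float64)


def simulate_genotypes(scenario: SimulationScenario,
                       variants: pd.DataFrame | None = None) -> GenotypeMatrix:
    """Draw hard dosages (0/1/2) as the sum of two AR(1) latent-Gaussian haplotypes.

    Effect-allele frequency per variant is drawn uniformly inside the block's
    MAF range; by construction the column mean of the dosage matrix divided by
    two converges to the stored ``eaf`` as n grows. Passing an existing
    ``variants`` table (e.g. from a discovery cohort) simulates a fresh sample
    on the same variant grid — same ids, alleles and frequencies — as an
    independent cohort sharing the LD structure.
    """
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n_samples
    total = sum(b.n_variants for b in scenario.blocks)
    if variants is not None and len(variants) != total:
        raise ValueError("variant table length does not match block layout")
    metas = []
    cols = []
    pairs = _ALLELE_PAIRS + (_PALINDROMIC_PAIRS if scenario.include_palindromic else [])
    v_counter = 0
    for block in scenario.blocks:
        if variants is None:
            eaf = rng.uniform(block.maf_range[0], block.maf_range[1],
                              size=block.n_variants)
        else:
            eaf = variants["eaf"].to_numpy()[v_counter:v_counter + block.n_variants]
        h1 = _simulate_block_haplotypes(rng, n, block, eaf)
        h2 = _simulate_block_haplotypes(rng, n, block, eaf)
        cols.append(h1 + h2)
        for j in range(block.n_variants):
            if variants is None:
                ea, oa = pairs[rng.integers(len(pairs))]
                metas.append({
                    "variant_id": f"rs{v_counter + 1:06d}",
                    "chrom": block.chrom,
                    "pos": block.start_pos + j * block.spacing_bp,
                    "effect_allele": ea,
                    "other_allele": oa,
                    "eaf": eaf[j],
                })
            v_counter += 1
    if variants is None:
        out_variants = pd.DataFrame(metas)
    else:
        out_variants = variants.reset_index(drop=True).copy()
    dosage = np.concatenate(cols, axis=1)
    samples = [f"S{i + 1:05d}" for i in range(n)]
    return GenotypeMatrix(samples=samples, variants=out_variants, dosage=dosage)


def _default_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Cohort-study covariate set: age, sex, sub-cohort dummies, five PCs."""
    cov = pd.DataFrame({
        "age": rng.normal(65.0, 8.0, size=n),
        "sex": rng.integers(0, 2, size=n).astype(float),
        "cohort_ii": np.zeros(n),
        "cohort_iv": np.zeros(n),
    })
    cohort = rng.integers(0, 3, size=n)
    cov.loc[cohort == 1, "cohort_ii"] = 1.0
    cov.loc[cohort == 2, "cohort_iv"] = 1.0
    for k in range(1, 6):
        cov[f"pc{k}"] = rng.normal(0.0, 1.0, size=n)
    return cov


def simulate_mirna_panel(geno: GenotypeMatrix,
                         scenario: SimulationScenario) -> ExpressionMatrix:
    """miRNA levels = Σ β·dosage + covariate terms + Normal(0, residual_sd²)."""
    rng = np.random.default_rng(scenario.seed + 1)
    n = len(geno.samples)
    mirna_ids = list(scenario.mirna_ids)
    if not mirna_ids:
        raise ValueError("scenario lists no miRNAs")
    cov = _default_covariates(rng, n)

    values = rng.normal(0.0, scenario.residual_sd, size=(n, len(mirna_ids)))
    for name, beta in scenario.covariate_effects.items():
        if name not in cov.columns:
            raise KeyError(f"unknown covariate {name!r}")
        values += beta * cov[name].to_numpy()[:, None]

    if scenario.effect_table is not None and len(scenario.effect_table):
        vid_index = {v: i for i, v in enumerate(geno.variant_ids)}
        mid_index = {m: i for i, m in enumerate(mirna_ids)}
        for row in scenario.effect_table.itertuples(index=False):
            if row.variant_id not in vid_index:
                raise KeyError(f"effect table names unknown variant {row.variant_id!r}")
            if row.mirna_id not in mid_index:
                raise KeyError(f"effect table names unknown miRNA {row.mirna_id!r}")
            values[:, mid_index[row.mirna_id]] += (
                row.beta * geno.dosage[:, vid_index[row.variant_id]]
            )
    return ExpressionMatrix(samples=list(geno.samples), mirna_ids=mirna_ids,
                            values=values, covariates=cov)


def simulate_case_control_phenome(score: np.ndarray,
                                  effects: Sequence[float],
                                  prevalences: Sequence[float],
                                  seed: int,
                                  phecodes: Sequence[str] | None = None,
                                  groups: dict[str, str] | None = None,
                                  samples: Sequence[str] | None = None) -> PhenomeTable:
    """Bernoulli case status with logit = logit(prevalence) + effect · z(score)."""
    effects = np.asarray(effects, dtype=float)
    prevalences = np.asarray(prevalences, dtype=float)
    if effects.shape != prevalences.shape:
        raise ValueError("effects and prevalences must have equal length")
    if np.any((prevalences <= 0) | (prevalences >= 1)):
        raise ValueError("prevalences must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    score = np.asarray(score, dtype=float)
    z = (score - score.mean()) / score.std(ddof=0)
    n = len(z)
    if phecodes is None:
        phecodes = [f"{100 + k}.0" for k in range(len(effects))]
    phecodes = list(phecodes)
    intercept = np.log(prevalences / (1.0 - prevalences))
    logits = intercept[None, :] + z[:, None] * effects[None, :]
    p = 1.0 / (1.0 + np.exp(-logits))
    status = (rng.uniform(size=p.shape) < p).astype(int)
    if samples is None:
        samples = [f"S{i + 1:05d}" for i in range(n)]
    df = pd.DataFrame(status, index=list(samples), columns=phecodes)
    return PhenomeTable(samples=list(samples), phecodes=phecodes, status=df,
                        groups=dict(groups or {}))


def _scan_to_records(geno: GenotypeMatrix, y: np.ndarray, n: int) -> pd.DataFrame:
    from scipy.stats import t as t_dist

    g = geno.dosage - geno.dosage.mean(axis=0)
    yc = y - y.mean()
    ss_g = np.einsum("ij,ij->j", g, g)
    beta = (g.T @ yc) / ss_g
    rss = (yc @ yc) - beta ** 2 * ss_g
    df = n - 2
    se = np.sqrt(np.maximum(rss, 1e-300) / df / ss_g)
    tstat = beta / se
    pval = np.clip(2.0 * t_dist.sf(np.abs(tstat), df), np.nextafter(0, 1), 1.0)
    out = geno.variants[["variant_id", "chrom", "pos",
                         "effect_allele", "other_allele", "eaf"]].copy()
    out["beta"] = beta
    out["se"] = se
    out["pval"] = pval
    out["n"] = n
    return out


def export_two_sample_stats(scenario: str,
                            n_variants: int,
                            rho: float,
                            effect1: float,
                            effect2: float,
                            n1: int,
                            n2: int,
                            seed: int,
                            maf_range: tuple[float, float] = (0.1, 0.5),
                            distinct_max_r2: float = 0.05,
                            ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Two marginal summary-stat tracks over one variant grid.

    scenario 'shared': both traits share one causal variant; 'distinct': the
    causal variants differ and their LD r² is below ``distinct_max_r2``;
    'null': all true effects are zero. Each track comes from an independent
    individual-level cohort simulated on the same LD structure, scanned
    marginally — so SEs, LD-induced signal spread and sampling noise are all
    genuine. Returns (track1, track2, info) with info holding causal indices.
    """
    if scenario not in {"shared", "distinct", "null"}:
        raise ValueError(f"unknown scenario {scenario!r}")
    block = VariantBlock(n_variants=n_variants, rho=rho, maf_range=maf_range)
    sc1 = SimulationScenario(n_samples=n1, blocks=[block], seed=seed)
    sc2 = SimulationScenario(n_samples=n2, blocks=[block], seed=seed + 7)
    g1 = simulate_genotypes(sc1)
    g2 = simulate_genotypes(sc2)
    rng = np.random.default_rng(seed + 13)

    corr = np.corrcoef(g1.dosage, rowvar=False)
    idx1 = idx2 = None
    if scenario != "null":
        idx1 = n_variants // 2
        if scenario == "shared":
            idx2 = idx1
        else:
            candidates = [j for j in range(n_variants)
                          if corr[idx1, j] ** 2 < distinct_max_r2]
            if not candidates:
                raise ValueError("region too small to place distinct causal variants")
            idx2 = candidates[len(candidates) // 2]

    def phenotype(g: GenotypeMatrix, idx: int | None, effect: float,
                  r: np.random.Generator) -> np.ndarray:
        y = r.standard_normal(len(g.samples))
        if idx is not None and effect != 0.0:
            y = y + effect * g.dosage[:, idx]
        return y

    y1 = phenotype(g1, idx1, effect1, rng)
    y2 = phenotype(g2, idx2, effect2, rng)
    t1 = _scan_to_records(g1, y1, n1)
    t2 = _scan_to_records(g2, y2, n2)
    # the two cohorts share the variant grid: use track-1 metadata for both
    for col in ["chrom", "pos", "effect_allele", "other_allele"]:
        t2[col] = t1[col]
    info = {"causal_index_1": idx1, "causal_index_2": idx2,
            "ld_r2_between_causals": None if idx1 is None or idx2 is None
            else float(corr[idx1, idx2] ** 2)}
    return t1, t2, info


def simulate_mediation_triple(theta_em: float,
                              theta_mo: float,
                              theta_direct: float,
                              n_instruments: int = 10,
                              se_bx: float = 0.01,
                              se_bm: float = 0.02,
                              se_by: float = 0.02,
                              seed: int = 0,
                              n_mediator_instruments: int = 10,
                              ) -> MediationTriple:
    """Exposure→mediator→outcome instrument panels with known path effects.

    Exposure-instrument effects on the outcome are bx·(θ_direct + θ_EM·θ_MO)
    plus noise; on the mediator bx·θ_EM plus noise. An independent panel of
    mediator instruments (effects gm on the mediator, gm·θ_MO on the outcome)
    identifies the mediator→outcome step. Defaults mirror a well-powered
    cis-instrument setting: |bx| uniform in [0.1, 0.3], small SEs.
    """
    if n_instruments < 3:
        raise ValueError("need at least 3 exposure instruments")
    for name, s in [("se_bx", se_bx), ("se_bm", se_bm), ("se_by", se_by)]:
        if s <= 0:
            raise ValueError(f"{name} must be positive")
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=n_instruments)
    bx_true = signs * rng.uniform(0.1, 0.3, size=n_instruments)
    theta_total = theta_direct + theta_em * theta_mo
    bm_true = bx_true * theta_em
    by_true = bx_true * theta_total
    exposure_panel = pd.DataFrame({
        "instrument": [f"ivx{j + 1}" for j in range(n_instruments)],
        "bx": bx_true + rng.normal(0, se_bx, n_instruments),
        "se_bx": se_bx,
        "bm": bm_true + rng.normal(0, se_bm, n_instruments),
        "se_bm": se_bm,
        "by": by_true + rng.normal(0, se_by, n_instruments),
        "se_by": se_by,
    })
    signs_m = rng.choice([-1.0, 1.0], size=n_mediator_instruments)
    gm_true = signs_m * rng.uniform(0.1, 0.3, size=n_mediator_instruments)
    mediator_panel = pd.DataFrame({
        "instrument": [f"ivm{j + 1}" for j in range(n_mediator_instruments)],
        "bm": gm_true + rng.normal(0, se_bm, n_mediator_instruments),
        "se_bm": se_bm,
        "by": gm_true * theta_mo + rng.normal(0, se_by, n_mediator_instruments),
        "se_by": se_by,
    })
    return MediationTriple(exposure_panel=exposure_panel,
                           mediator_panel=mediator_panel,
                           theta_em=theta_em, theta_mo=theta_mo,
                           theta_direct=theta_direct)
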