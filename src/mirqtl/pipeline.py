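"""Config-driven orchestration of the analysis chain.

A pipeline run simulates (or loads) a cohort, scans for miRNA-eQTLs,
classifies cis/trans, selects FDR-based cis instruments per miRNA and routes
each miRNA through the decision tree: one instrument → single-variant PheWAS;
two or more → GRS PheWAS; three or more → Mendelian randomisation. Every
output table is TSV, every stage draws randomness from a seed derived from
the global seed, and a JSON manifest records parameters, seeds, per-stage
counts and the SHA-256 of every artifact so a run can be re-executed and
compared byte for byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .cohort import (SimulationScenario, VariantBlock, simulate_case_control_phenome,
                     simulate_genotypes, simulate_mirna_panel)
from .mr import MRInput, ivw, mr_egger, weighted_median
from .phewas import compute_grs, run_phewas, select_instruments
from .qtl import classify_cis_trans, run_qtl_scan, significance_threshold
from .sumstats import LDMatrix

__all__ = ["run_pipeline", "validate_config", "load_config", "DEMO_CONFIG"]

log = logging.getLogger(__name__)

STAGES = ["simulate", "scan", "instruments", "phewas", "mr"]

DEMO_CONFIG: dict = {
    "seed": 7,
    "outdir": "results/demo",
    "simulate": {
        "n_samples": 1200,
        "n_phenome_samples": 20000,
        "blocks": [
            {"n_variants": 30, "rho": 0.8, "chrom": "1", "start_pos": 1_000_000},
            {"n_variants": 30, "rho": 0.6, "chrom": "1", "start_pos": 2_000_000},
            {"n_variants": 30, "rho": 0.0, "chrom": "2", "start_pos": 5_000_000},
        ],
        "mirnas": [
            {"mirna_id": "miR-sim-1", "chrom": "1", "mature_start": 1_060_000,
             "effects": [{"variant_index": 10, "beta": 0.45},
                         {"variant_index": 20, "beta": 0.35}]},
            {"mirna_id": "miR-sim-2", "chrom": "1", "mature_start": 2_060_000,
             "effects": [{"variant_index": 40, "beta": 0.5}]},
            {"mirna_id": "miR-sim-3", "chrom": "2", "mature_start": 5_050_000,
             "effects": []},
        ],
        "residual_sd": 1.0,
        "phenome": {"n_phecodes": 12, "prevalence": 0.05,
                    "effect_per_sd": {"0": 0.25}},
    },
    "scan": {"covariates": ["age", "sex", "pc1", "pc2", "pc3", "pc4", "pc5"],
             "cis_window": 500_000, "alpha_gw": 5e-8, "n_phenotypes": 2083},
    "instruments": {"q_threshold": 0.1, "clump_r2": 0.1, "window": 500_000},
    "phewas": {"min_cases": 200, "q_alpha": 0.05},
    "mr": {"min_instruments": 3},
}


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def validate_config(config: dict) -> list[str]:
    """List constraint violations without executing anything."""
    problems: list[str] = []
    if not isinstance(config, dict):
        return ["config is not a mapping"]
    for stage in config:
        if stage not in STAGES + ["seed", "outdir"]:
            problems.append(f"unknown stage or key: {stage!r}")
    sim = config.get("simulate")
    if sim is None:
        for key in ("genotypes", "expression"):
            if key in config and not Path(config[key]).exists():
                problems.append(f"missing input path: {config[key]}")
        if "genotypes" not in config:
            problems.append("no simulate stage and no genotype input path")
        if "expression" not in config:
            problems.append("no simulate stage and no expression input path")
    else:
        if sim.get("n_samples", 0) < 2:
            problems.append("simulate.n_samples must be at least 2")
        for b in sim.get("blocks", []):
            if not -1 < b.get("rho", 0) < 1:
                problems.append(f"block rho outside (-1, 1): {b.get('rho')}")
    inst = config.get("instruments", {})
    for name, lo, hi in [("q_threshold", 0, 1), ("clump_r2", 0, 1)]:
        v = inst.get(name)
        if v is not None and not lo < v <= hi:
            problems.append(f"instruments.{name} outside ({lo}, {hi}]: {v}")
    scan = config.get("scan", {})
    a = scan.get("alpha_gw")
    if a is not None and not 0 < a < 1:
        problems.append(f"scan.alpha_gw outside (0, 1): {a}")
    ph = config.get("phewas", {})
    if ph.get("min_cases", 1) < 1:
        problems.append("phewas.min_cases must be at least 1")
    return problems


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _build_scenario(sim: dict, seed: int) -> tuple[SimulationScenario, pd.DataFrame]:
    blocks = [VariantBlock(n_variants=b["n_variants"], rho=b.get("rho", 0.8),
                           chrom=str(b.get("chrom", "1")),
                           start_pos=b.get("start_pos", 1_000_000),
                           spacing_bp=b.get("spacing_bp", 5_000))
              for b in sim["blocks"]]
    mirnas = sim["mirnas"]
    effect_rows = []
    annot_rows = []
    for m in mirnas:
        annot_rows.append({"mirna_id": m["mirna_id"], "chrom": str(m["chrom"]),
                           "mature_start": m["mature_start"]})
        for e in m.get("effects", []):
            effect_rows.append({"mirna_id": m["mirna_id"],
                                "variant_index": e["variant_index"],
                                "beta": e["beta"]})
    scenario = SimulationScenario(
        n_samples=sim["n_samples"], blocks=blocks,
        mirna_ids=[m["mirna_id"] for m in mirnas],
        effect_table=None,  # filled after genotype ids exist
        residual_sd=sim.get("residual_sd", 1.0), seed=seed)
    scenario._effect_rows = effect_rows  # resolved to variant ids in run_pipeline
    return scenario, pd.DataFrame(annot_rows)


def run_pipeline(config: dict, outdir: str | Path | None = None) -> dict:
    """Execute the configured stages in dependency order; return the manifest."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    seed = int(config.get("seed", 0))
    outdir = Path(outdir or config.get("outdir", "results/pipeline"))
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": seed, "stages": {}, "artifacts": {},
                      "parameters": {k: config[k] for k in STAGES if k in config}}

    # --- simulate ---------------------------------------------------------
    sim = config["simulate"]
    scenario, annot = _build_scenario(sim, seed)
    geno = simulate_genotypes(scenario)
    effect_rows = scenario._effect_rows
    if effect_rows:
        ids = geno.variant_ids
        scenario.effect_table = pd.DataFrame(
            [{"mirna_id": r["mirna_id"], "variant_id": ids[r["variant_index"]],
              "beta": r["beta"]} for r in effect_rows])
    expr = simulate_mirna_panel(geno, scenario)
    manifest["stages"]["simulate"] = {
        "n_samples": len(geno.samples), "n_variants": len(geno.variants),
        "n_mirnas": len(expr.mirna_ids), "seed": seed}

    geno_paths = mio.write_genotype_tsv(geno, outdir / "cohort")
    expr_paths = mio.write_expression_tsv(expr, outdir / "cohort")
    annot_path = outdir / "mirna_annotation.tsv"
    annot.to_csv(annot_path, sep="\t", index=False)

    # --- scan -------------------------------------------------------------
    scan_cfg = config.get("scan", {})
    covars = scan_cfg.get("covariates", ["age", "sex"])
    assoc = run_qtl_scan(expr, geno, covars)
    assoc = classify_cis_trans(assoc, annot,
                               window=scan_cfg.get("cis_window", 500_000))
    threshold = significance_threshold(scan_cfg.get("alpha_gw", 5e-8),
                                       scan_cfg.get("n_phenotypes", 2083))
    assoc["significant"] = assoc["pval"] < threshold
    assoc_path = outdir / "associations.tsv"
    assoc.to_csv(assoc_path, sep="\t", index=False, float_format="%.8g")
    manifest["stages"]["scan"] = {
        "n_tests": len(assoc), "threshold": threshold,
        "n_significant": int(assoc["significant"].sum()),
        "n_skipped_monomorphic": assoc.attrs.get("n_skipped_monomorphic", 0)}

    # --- instruments ------------------------------------------------------
    inst_cfg = config.get("instruments", {})
    ld = LDMatrix.from_genotypes(geno.dosage, geno.variant_ids)
    instrument_sets = {}
    inst_rows = []
    for mirna in expr.mirna_ids:
        cis = assoc[(assoc["mirna_id"] == mirna) & assoc["cis"]]
        if len(cis) == 0:
            continue
        iset = select_instruments(cis, ld, mirna_id=mirna,
                                  q_threshold=inst_cfg.get("q_threshold", 0.1),
                                  clump_r2=inst_cfg.get("clump_r2", 0.1),
                                  window=inst_cfg.get("window", 500_000))
        if len(iset) == 0:
            log.info("pipeline: %s has no FDR-significant cis instruments", mirna)
            continue
        instrument_sets[mirna] = iset
        for r in iset.variants.itertuples(index=False):
            inst_rows.append({"mirna_id": mirna, "variant_id": r.variant_id,
                              "weight": r.weight, "pval": r.pval, "q": r.q})
    inst_path = outdir / "instruments.tsv"
    pd.DataFrame(inst_rows, columns=["mirna_id", "variant_id", "weight",
                                     "pval", "q"]).to_csv(
        inst_path, sep="\t", index=False, float_format="%.8g")
    manifest["stages"]["instruments"] = {
        "n_mirnas_with_instruments": len(instrument_sets),
        "n_instruments_total": len(inst_rows)}

    # --- phenome + phewas -------------------------------------------------
    ph_cfg = config.get("phewas", {})
    phen_cfg = sim.get("phenome", {})
    n_ph_samples = sim.get("n_phenome_samples", 10 * sim["n_samples"])
    ph_seed = seed + 1000
    ph_block_scenario = SimulationScenario(
        n_samples=n_ph_samples, blocks=scenario.blocks,
        mirna_ids=scenario.mirna_ids, seed=ph_seed)
    ph_geno = simulate_genotypes(ph_block_scenario, variants=geno.variants)

    routing = {}
    phewas_tables = {}
    mr_results = []
    for m_idx, (mirna, iset) in enumerate(sorted(instrument_sets.items())):
        score = compute_grs(ph_geno, iset)
        mode = "single-variant" if len(iset) == 1 else "grs"
        n_pc = phen_cfg.get("n_phecodes", 10)
        effects = np.zeros(n_pc)
        for k, v in phen_cfg.get("effect_per_sd", {}).items():
            if int(k) < n_pc and m_idx == 0:
                effects[int(k)] = v
        phenome = simulate_case_control_phenome(
            score=score, effects=effects,
            prevalences=np.full(n_pc, phen_cfg.get("prevalence", 0.05)),
            seed=ph_seed + 17 + m_idx, samples=ph_geno.samples)
        res = run_phewas(score, phenome,
                         min_cases=ph_cfg.get("min_cases", 200),
                         q_alpha=ph_cfg.get("q_alpha", 0.05))
        res.insert(0, "mirna_id", mirna)
        res.insert(1, "mode", mode)
        phewas_tables[mirna] = res
        routing[mirna] = {"n_instruments": len(iset), "phewas_mode": mode}

        # --- mr (per decision tree) ---------------------------------------
        min_j = config.get("mr", {}).get("min_instruments", 3)
        if len(iset) >= min_j:
            mr_in = _mr_input_from_scan(assoc, iset, ph_geno, phenome, res)
            if mr_in is not None:
                for fit in (ivw(mr_in), mr_egger(mr_in),
                            weighted_median(mr_in, n_boot=1000,
                                            seed=ph_seed + 29 + m_idx)):
                    mr_results.append({
                        "mirna_id": mirna, "method": fit.method,
                        "theta": fit.theta, "se": fit.se, "pval": fit.pval,
                        "J": fit.J, "Q": fit.Q, "p_het": fit.p_het,
                        "egger_intercept": fit.egger_intercept,
                        "p_intercept": fit.p_intercept})
            routing[mirna]["mr"] = "run"
        else:
            routing[mirna]["mr"] = f"skipped: {len(iset)} instrument(s) < {min_j}"
            log.info("pipeline: MR skipped for %s (%d instruments)",
                     mirna, len(iset))

    phewas_path = outdir / "phewas.tsv"
    if phewas_tables:
        pd.concat(phewas_tables.values(), ignore_index=True).to_csv(
            phewas_path, sep="\t", index=False, float_format="%.8g")
    else:
        pd.DataFrame().to_csv(phewas_path, sep="\t", index=False)
    mr_path = outdir / "mr.tsv"
    pd.DataFrame(mr_results).to_csv(mr_path, sep="\t", index=False,
                                    float_format="%.8g")
    manifest["stages"]["phewas"] = {"routing": routing,
                                    "n_phewas_rows": sum(map(len, phewas_tables.values()))}
    manifest["stages"]["mr"] = {"n_results": len(mr_results)}

    for p in [*geno_paths, *expr_paths, annot_path, assoc_path, inst_path,
              phewas_path, mr_path]:
        manifest["artifacts"][p.name] = _sha256(Path(p))
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True,
                                        default=str) + "\n")
    return manifest


def _mr_input_from_scan(assoc: pd.DataFrame, iset, ph_geno, phenome,
                        phewas_res: pd.DataFrame) -> MRInput | None:
    """Instrument→exposure effects from the scan; instrument→outcome from the
    phenome cohort (per-variant logistic effects on the first tested phecode)."""
    import statsmodels.api as sm

    tested = phewas_res[phewas_res["pval"].notna()]
    if len(tested) == 0:
        return None
    pc = tested.iloc[0]["phecode"]
    st = phenome.status[pc].to_numpy()
    use = st >= 0
    bx, se_bx, by, se_by, ids = [], [], [], [], []
    meta = {v: i for i, v in enumerate(ph_geno.variant_ids)}
    for r in iset.variants.itertuples(index=False):
        j = meta[r.variant_id]
        g = ph_geno.dosage[use][:, j]
        X = sm.add_constant(g)
        try:
            fit = sm.Logit(st[use], X).fit(disp=0)
        except Exception:  # separation etc.: drop the instrument
            continue
        bx.append(r.weight)
        se_bx.append(getattr(r, "se", 0.05) if np.isfinite(getattr(r, "se", np.nan))
                     else 0.05)
        by.append(fit.params[1])
        se_by.append(fit.bse[1])
        ids.append(r.variant_id)
    if len(bx) < 3:
        return None
    return MRInput(np.array(bx), np.array(se_bx), np.array(by),
                   np.array(se_by), ids=ids)
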