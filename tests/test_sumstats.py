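"""Harmonisation, replication rule, COJO stepwise selection (with an
independent from-scratch oracle) and genomic risk locus definition."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from mirqtl.sumstats import (CojoParams, LDMatrix, assess_replication,
                             cojo_stepwise, define_genomic_loci,
                             harmonize_summary_stats)
from conftest import toy_sumstats


class TestHarmonisation:
    def test_swapped_alleles_flip_beta_and_eaf(self):
        a = toy_sumstats([0.5], [0.1])
        b = toy_sumstats([-0.5], [0.1], alleles=[("G", "A")], eafs=[0.7])
        out, log = harmonize_summary_stats(a, b)
        assert out["beta_b"].iloc[0] == pytest.approx(0.5)
        assert out["eaf_b"].iloc[0] == pytest.approx(0.3)
        assert np.sign(out["beta_a"].iloc[0]) == np.sign(out["beta_b"].iloc[0])

    def test_identical_coding_unchanged(self):
        a = toy_sumstats([0.2, -0.1], [0.05, 0.05])
        out, _ = harmonize_summary_stats(a, a.copy())
        np.testing.assert_allclose(out["beta_b"], a["beta"])
        np.testing.assert_allclose(out["eaf_b"], a["eaf"])

    def test_palindromic_variant_dropped_and_logged(self):
        a = toy_sumstats([0.5], [0.1], alleles=[("A", "T")])
        b = toy_sumstats([0.5], [0.1], alleles=[("A", "T")])
        out, log = harmonize_summary_stats(a, b)
        assert len(out) == 0 and log["palindromic"] == 1

    def test_palindromic_rescue_by_frequency(self):
        a = toy_sumstats([0.5], [0.1], alleles=[("A", "T")], eafs=[0.2])
        b = toy_sumstats([0.5], [0.1], alleles=[("A", "T")], eafs=[0.2])
        out, _ = harmonize_summary_stats(a, b, eaf_rescue=True)
        assert len(out) == 1

    def test_allele_mismatch_dropped(self):
        a = toy_sumstats([0.5], [0.1], alleles=[("A", "G")])
        b = toy_sumstats([0.5], [0.1], alleles=[("A", "C")])
        out, log = harmonize_summary_stats(a, b)
        assert len(out) == 0 and log["allele_mismatch"] == 1

    def test_duplicate_variant_ids_raise(self):
        a = toy_sumstats([0.5, 0.4], [0.1, 0.1])
        a.loc[1, "variant_id"] = a.loc[0, "variant_id"]
        with pytest.raises(ValueError):
            harmonize_summary_stats(a, toy_sumstats([0.1], [0.1]))

    def test_harmonisation_is_involutive(self):
        a = toy_sumstats([0.5, -0.3], [0.1, 0.1])
        b = toy_sumstats([-0.5, -0.3], [0.1, 0.1],
                         alleles=[("G", "A"), ("A", "G")], eafs=[0.7, 0.3])
        once, _ = harmonize_summary_stats(a, b)
        b_aligned = once[["variant_id"]].copy()
        b_aligned[["chrom", "pos"]] = once[["chrom", "pos"]]
        b_aligned[["effect_allele", "other_allele"]] = once[
            ["effect_allele", "other_allele"]]
        b_aligned[["eaf", "beta", "se", "pval", "n"]] = once[
            ["eaf_b", "beta_b", "se_b", "pval_b", "n_b"]].to_numpy()
        twice, _ = harmonize_summary_stats(a, b_aligned)
        np.testing.assert_allclose(twice["beta_b"], once["beta_b"])
        np.testing.assert_allclose(twice["eaf_b"], once["eaf_b"])


class TestReplication:
    def _pair(self, p_rep, sign=1.0):
        disc = toy_sumstats([0.5], [0.05])
        from scipy.stats import norm

        z = norm.isf(p_rep / 2)
        rep = toy_sumstats([sign * 0.3], [0.3 / z])
        disc = disc.rename(columns={c: f"{c}_disc" for c in
                                    ["eaf", "beta", "se", "pval", "n"]})
        rep = rep.rename(columns={c: f"{c}_rep" for c in
                                  ["eaf", "beta", "se", "pval", "n"]})
        return disc.drop(columns=["chrom", "pos", "effect_allele",
                                  "other_allele"]), \
            rep.drop(columns=["chrom", "pos", "effect_allele", "other_allele"])

    def test_significant_concordant_replicates(self):
        d, r = self._pair(1e-6)
        out = assess_replication(d, r, m_tested=100)
        assert bool(out["replicated"].iloc[0])

    def test_opposite_sign_fails(self):
        d, r = self._pair(1e-6, sign=-1.0)
        out = assess_replication(d, r, m_tested=100)
        assert not bool(out["replicated"].iloc[0])

    def test_sub_threshold_p_fails(self):
        d, r = self._pair(0.01)
        out = assess_replication(d, r, m_tested=100)  # threshold 5e-4
        assert not bool(out["replicated"].iloc[0])

    def test_invalid_m_raises(self):
        d, r = self._pair(1e-6)
        with pytest.raises(ValueError):
            assess_replication(d, r, m_tested=0)


def _random_instance(rng, k=8, n=50_000, n_causal=2, scale=0.06):
    """Random LD + marginal stats with known causal configuration."""
    F = rng.normal(size=(k, 3))
    S = F @ F.T + np.diag(rng.uniform(0.5, 2.0, k))
    d = np.sqrt(np.diag(S))
    R = S / np.outer(d, d)
    b_std = np.zeros(k)
    idx = rng.choice(k, size=n_causal, replace=False)
    b_std[idx] = rng.choice([-1, 1], n_causal) * scale
    # marginal standardised effects: R b + noise with cov R/n
    L = np.linalg.cholesky(R + 1e-10 * np.eye(k))
    bz = R @ b_std + (L @ rng.standard_normal(k)) / np.sqrt(n)
    se_std = 1.0 / np.sqrt(n)
    eaf = rng.uniform(0.1, 0.5, k)
    scale_d = np.sqrt(2 * eaf * (1 - eaf))
    stats = toy_sumstats((bz / scale_d).tolist(),
                         (se_std / scale_d).tolist(), n=n,
                         eafs=eaf.tolist())
    z = stats["beta"] / stats["se"]
    stats["pval"] = chi2.sf(z ** 2, 1)
    ld = LDMatrix(stats["variant_id"].tolist(), R, panel_size=n)
    return stats, ld


def _oracle_stepwise(stats, ld, params):
    """Naive re-derivation: rebuild the joint model with fresh linear algebra
    at every step, scanning all candidates each time."""
    eaf = stats["eaf"].to_numpy()
    sc = np.sqrt(2 * eaf * (1 - eaf))
    z = (stats["beta"] / stats["se"]).to_numpy()
    n = float(np.median(stats["n"]))
    bz = z / np.sqrt(n + z ** 2)
    R = ld.r
    p_marg = chi2.sf(z ** 2, 1)

    def joint(idx):
        Rs = R[np.ix_(idx, idx)]
        b = np.linalg.lstsq(Rs, bz[idx], rcond=None)[0]
        sigma2 = max(n * (1 - b @ bz[idx]), 1e-12) / max(n - len(idx) - 1, 1)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(Rs) / n))
        return b, se

    sel = []
    if p_marg.min() >= params.p_select:
        return sel, None
    sel.append(int(np.argmin(p_marg)))
    while True:
        best, bestp = None, params.p_select
        for j in range(len(stats)):
            if j in sel:
                continue
            if any(R[j, s] ** 2 > params.collinearity_r2 for s in sel):
                continue
            b, se = joint(sel + [j])
            p = chi2.sf((b[-1] / se[-1]) ** 2, 1)
            if p < bestp:
                best, bestp = j, p
        if best is None:
            break
        sel.append(best)
    b, se = joint(sel)
    return sel, b / sc[sel]


class TestCojo:
    def test_one_causal_with_proxies_selects_one(self, rng):
        # strong single causal variant plus r2≈0.8 proxies
        k = 6
        R = np.full((k, k), 0.9)
        np.fill_diagonal(R, 1.0)
        n = 50_000
        b_std = np.zeros(k)
        b_std[2] = 0.08
        bz = R @ b_std
        eaf = [0.3] * k
        sc = np.sqrt(2 * 0.3 * 0.7)
        stats = toy_sumstats((bz / sc).tolist(), [1 / np.sqrt(n) / sc] * k,
                             n=n, eafs=eaf)
        z = stats["beta"] / stats["se"]
        stats["pval"] = chi2.sf(z ** 2, 1)
        ld = LDMatrix(stats["variant_id"].tolist(), R)
        out = cojo_stepwise(stats, ld, CojoParams())
        assert len(out) == 1 and out["variant_id"].iloc[0] == "v3"

    def test_orthogonal_causals_both_selected_with_marginal_betas(self, rng):
        k = 4
        R = np.eye(k)
        n = 100_000
        b_std = np.array([0.06, 0.0, 0.06, 0.0])
        sc = np.sqrt(2 * 0.3 * 0.7)
        stats = toy_sumstats((b_std / sc).tolist(), [1 / np.sqrt(n) / sc] * k,
                             n=n, eafs=[0.3] * k)
        z = stats["beta"] / stats["se"]
        stats["pval"] = chi2.sf(z ** 2, 1)
        out = cojo_stepwise(stats, LDMatrix(stats["variant_id"].tolist(), R),
                            CojoParams())
        assert sorted(out["variant_id"]) == ["v1", "v3"]
        # joint equals marginal up to the O(z²/n) shrinkage of the
        # z → standardised-beta conversion
        np.testing.assert_allclose(out["beta_joint"],
                                   out["beta_marginal"], rtol=5e-3)

    def test_no_variant_below_threshold_selects_none(self):
        stats = toy_sumstats([0.01, 0.02], [0.05, 0.05])
        stats["pval"] = [0.5, 0.4]
        ld = LDMatrix(stats["variant_id"].tolist(), np.eye(2))
        out = cojo_stepwise(stats, ld, CojoParams())
        assert len(out) == 0

    def test_maf_filter_removes_rare_variants(self):
        stats = toy_sumstats([0.5, 0.5], [0.01, 0.01], eafs=[0.01, 0.3])
        stats["pval"] = [1e-300, 1e-300]
        ld = LDMatrix(stats["variant_id"].tolist(), np.eye(2))
        out = cojo_stepwise(stats, ld, CojoParams())
        assert out["variant_id"].tolist() == ["v2"]

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_from_scratch_oracle_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        params = CojoParams(p_select=1e-4)
        stats, ld = _random_instance(rng, k=int(rng.integers(3, 11)))
        out = cojo_stepwise(stats, ld, params)
        sel_oracle, b_oracle = _oracle_stepwise(stats, ld, params)
        got = [stats.index[stats["variant_id"] == v][0]
               for v in out["variant_id"]]
        assert got == sel_oracle
        if sel_oracle:
            np.testing.assert_allclose(out["beta_joint"], b_oracle, atol=1e-8)

    def test_empty_region_raises(self):
        with pytest.raises(ValueError):
            cojo_stepwise(pd.DataFrame(columns=["eaf"]),
                          LDMatrix([], np.zeros((0, 0))))


class TestLoci:
    def _stats(self, positions, pvals, chrom="1"):
        s = toy_sumstats([0.1] * len(positions), [0.01] * len(positions),
                         pos=positions, chrom=chrom)
        s["pval"] = pvals
        return s

    def test_nearby_unlinked_leads_merge(self):
        stats = self._stats([1_000_000, 1_200_000], [1e-20, 1e-15])
        ld = LDMatrix(stats["variant_id"].tolist(), np.eye(2))
        loci = define_genomic_loci(stats, ld)
        assert len(loci) == 1
        assert loci[0].lead_variant == "v1"
        assert loci[0].start == 1_000_000 and loci[0].end == 1_200_000

    def test_distant_unlinked_leads_stay_separate(self):
        stats = self._stats([1_000_000, 1_300_001], [1e-20, 1e-15])
        ld = LDMatrix(stats["variant_id"].tolist(), np.eye(2))
        assert len(define_genomic_loci(stats, ld)) == 2

    def test_fully_linked_variants_collapse_to_one(self):
        stats = self._stats([1_000_000, 1_005_000, 1_010_000],
                            [1e-12, 1e-20, 1e-15])
        R = np.full((3, 3), 0.95)
        np.fill_diagonal(R, 1.0)
        ld = LDMatrix(stats["variant_id"].tolist(), R)
        loci = define_genomic_loci(stats, ld)
        assert len(loci) == 1 and loci[0].lead_variant == "v2"
        assert set(loci[0].members) == {"v1", "v2", "v3"}

    def test_result_invariant_to_input_order(self, rng):
        stats = self._stats([1_000_000, 1_050_000, 2_000_000, 2_040_000],
                            [1e-15, 1e-13, 1e-18, 1e-12])
        R = np.eye(4)
        R[0, 1] = R[1, 0] = 0.9
        R[2, 3] = R[3, 2] = 0.85
        ld = LDMatrix(stats["variant_id"].tolist(), R)
        base = define_genomic_loci(stats, ld)
        perm = rng.permutation(len(stats))
        shuffled = stats.iloc[perm].reset_index(drop=True)
        again = define_genomic_loci(shuffled, ld)
        key = lambda l: (l.chrom, l.start, l.end, l.lead_variant)
        assert sorted(map(key, base)) == sorted(map(key, again))

    def test_loci_are_disjoint(self):
        stats = self._stats([1_000_000, 1_100_000, 1_600_000, 2_500_000],
                            [1e-15, 1e-13, 1e-18, 1e-12])
        ld = LDMatrix(stats["variant_id"].tolist(), np.eye(4))
        loci = sorted(define_genomic_loci(stats, ld), key=lambda l: l.start)
        for a, b in zip(loci, loci[1:]):
            assert a.end < b.start
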