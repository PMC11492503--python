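"""Two-sample Mendelian randomisation estimator suite.

Implements the ratio-based inverse-variance-weighted estimator (fixed and
multiplicative-random-effect models), a generalised-least-squares IVW for
correlated instruments, MR-Egger regression with its intercept test for
directional pleiotropy, the weighted median, Cochran's Q heterogeneity
statistic, MR-PRESSO-style simulation-based outlier detection, multivariable
MR, Bayesian model-averaged multivariable MR over exposure subsets,
bidirectional analysis, two-step mediation and a hypergeometric target-gene
enrichment test.

Conventions: per-instrument ratio r_j = by_j/bx_j with first-order weights
w_j = (bx_j/se_by_j)²; the multiplicative random-effect SE inflates the
fixed-effect SE by max(1, √(Q/(J−1))). All estimators are invariant to
instrument order, and multiplying every outcome effect and SE by a constant
scales every θ and SE by the same constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import chi2, hypergeom, norm, t as t_dist

__all__ = [
    "MRInput", "MRResult", "MediationResult", "EnrichmentResult",
    "wald_ratio", "ivw", "ivw_correlated", "mr_egger", "weighted_median",
    "cochran_q", "mr_presso", "mvmr", "mr_bma", "two_step_mediation",
    "two_step_from_panels", "bidirectional_mr", "enrichment_test",
]


@dataclass
class MRInput:
    """Per-instrument effects on exposure (bx) and outcome (by) with SEs."""

    bx: np.ndarray
    se_bx: np.ndarray
    by: np.ndarray
    se_by: np.ndarray
    ids: list[str] | None = None
    corr: np.ndarray | None = None  # instrument LD correlation, optional

    def __post_init__(self) -> None:
        self.bx = np.asarray(self.bx, dtype=float)
        self.se_bx = np.broadcast_to(np.asarray(self.se_bx, dtype=float),
                                     self.bx.shape).copy()
        self.by = np.asarray(self.by, dtype=float)
        self.se_by = np.broadcast_to(np.asarray(self.se_by, dtype=float),
                                     self.bx.shape).copy()
        if not (len(self.bx) == len(self.by) == len(self.se_bx) == len(self.se_by)):
            raise ValueError("instrument vectors must have equal length")
        if np.any(self.se_bx <= 0) or np.any(self.se_by <= 0):
            raise ValueError("standard errors must be positive")
        if self.ids is None:
            self.ids = [f"iv{j + 1}" for j in range(len(self.bx))]
        if self.corr is not None:
            self.corr = np.asarray(self.corr, dtype=float)
            if self.corr.shape != (len(self.bx),) * 2:
                raise ValueError("correlation matrix shape mismatch")
            if not np.allclose(self.corr, self.corr.T, atol=1e-8):
                raise ValueError("correlation matrix must be symmetric")

    @property
    def J(self) -> int:
        return len(self.bx)

    def subset(self, keep: np.ndarray) -> "MRInput":
        keep = np.asarray(keep)
        return MRInput(self.bx[keep], self.se_bx[keep], self.by[keep],
                       self.se_by[keep],
                       ids=[self.ids[i] for i in np.flatnonzero(keep)]
                       if keep.dtype == bool else [self.ids[i] for i in keep],
                       corr=None if self.corr is None
                       else self.corr[np.ix_(keep, keep)])


@dataclass
class MRResult:
    method: str
    theta: float
    se: float
    pval: float
    J: int
    Q: float | None = None
    p_het: float | None = None
    egger_intercept: float | None = None
    p_intercept: float | None = None
    outliers: list[str] = field(default_factory=list)

    def ci(self, level: float = 0.95) -> tuple[float, float]:
        zq = norm.ppf(0.5 + level / 2)
        return self.theta - zq * self.se, self.theta + zq * self.se


@dataclass
class MediationResult:
    theta_total: float
    theta_em: float
    theta_mo: float
    theta_indirect: float
    proportion_mediated: float
    ci_level: float
    ci_lower: float
    ci_upper: float
    ci_method: str
    se_proportion: float | None = None


@dataclass
class EnrichmentResult:
    overlap: int
    target_set_size: int
    trait_set_size: int
    universe_size: int
    pval: float


def wald_ratio(bx: float, by: float, se_by: float) -> tuple[float, float]:
    """Single-instrument causal estimate θ = by/bx with first-order SE se_by/|bx|."""
    if bx == 0:
        raise ZeroDivisionError("instrument-exposure effect bx must be nonzero")
    return by / bx, se_by / abs(bx)


def _ratio_weights(data: MRInput) -> tuple[np.ndarray, np.ndarray]:
    if np.any(data.bx == 0):
        raise ZeroDivisionError("all instruments need nonzero bx; use wald_ratio "
                                "for single-instrument analyses")
    r = data.by / data.bx
    w = (data.bx / data.se_by) ** 2
    return r, w


def cochran_q(data: MRInput, theta: float | None = None) -> tuple[float, float]:
    """Heterogeneity Q = Σ w_j (r_j − θ)² with p from χ²(J−1)."""
    if data.J < 2:
        raise ValueError("Cochran's Q needs at least 2 instruments")
    r, w = _ratio_weights(data)
    if theta is None:
        theta = float(np.sum(w * r) / np.sum(w))
    Q = float(np.sum(w * (r - theta) ** 2))
    return Q, float(chi2.sf(Q, data.J - 1))


def ivw(data: MRInput, model: str = "MRE") -> MRResult:
    """Inverse-variance-weighted estimate from per-instrument ratios.

    model 'FE': fixed effect, se = 1/√Σw. model 'MRE' (default, the main
    analysis model): multiplicative random effects, se inflated by
    max(1, √(Q/(J−1))) so heterogeneity beyond chance widens the interval.
    """
    if data.J < 2:
        raise ValueError("IVW needs at least 2 instruments; "
                         "use wald_ratio for J=1")
    if model not in {"FE", "MRE"}:
        raise ValueError(f"unknown IVW model {model!r}")
    r, w = _ratio_weights(data)
    theta = float(np.sum(w * r) / np.sum(w))
    se_fe = float(1.0 / np.sqrt(np.sum(w)))
    Q, p_het = cochran_q(data, theta)
    se = se_fe
    if model == "MRE":
        se = se_fe * max(1.0, np.sqrt(Q / (data.J - 1)))
    pval = 2 * norm.sf(abs(theta) / se)
    return MRResult(method=f"IVW-{model}", theta=theta, se=se, pval=float(pval),
                    J=data.J, Q=Q, p_het=p_het)


def ivw_correlated(data: MRInput) -> MRResult:
    """Fixed-effect IVW accounting for LD correlation between instruments.

    Generalised least squares of by on bx through the origin with outcome
    covariance Ω_jk = se_by_j·se_by_k·ρ_jk. Reduces to FE IVW when ρ = I.
    A near-singular Ω receives a small ridge (1e-8 on the diagonal).
    """
    if data.corr is None:
        raise ValueError("instrument correlation matrix required")
    if data.J < 2:
        raise ValueError("needs at least 2 instruments")
    omega = np.outer(data.se_by, data.se_by) * data.corr
    try:
        c = cho_factor(omega)
    except np.linalg.LinAlgError:
        import warnings

        warnings.warn("singular instrument covariance; adding 1e-8 ridge",
                      stacklevel=2)
        c = cho_factor(omega + 1e-8 * np.eye(data.J))
    oi_bx = cho_solve(c, data.bx)
    denom = float(data.bx @ oi_bx)
    theta = float(oi_bx @ data.by) / denom
    se = float(1.0 / np.sqrt(denom))
    pval = 2 * norm.sf(abs(theta) / se)
    return MRResult(method="IVW-correlated", theta=theta, se=se,
                    pval=float(pval), J=data.J)


def mr_egger(data: MRInput) -> MRResult:
    """MR-Egger weighted regression by = β₀ + θ·bx with pleiotropy intercept test.

    Instruments are first oriented so bx ≥ 0. Weights are 1/se_by²;
    multiplicative random effects scale both SEs by max(1, √(RSS_w/(J−2)));
    tests use the t distribution with J−2 df.
    """
    if data.J < 3:
        raise ValueError("MR-Egger needs at least 3 instruments")
    flip = np.sign(data.bx)
    flip[flip == 0] = 1.0
    bx = data.bx * flip
    by = data.by * flip
    w = 1.0 / data.se_by ** 2
    X = np.column_stack([np.ones(data.J), bx])
    WX = X * w[:, None]
    xtx = X.T @ WX
    coef = np.linalg.solve(xtx, WX.T @ by)
    resid = by - X @ coef
    rss_w = float(np.sum(w * resid ** 2))
    dof = data.J - 2
    scale = max(1.0, np.sqrt(rss_w / dof))
    cov = np.linalg.inv(xtx) * scale ** 2
    se = np.sqrt(np.diag(cov))
    t_int = coef[0] / se[0]
    t_slope = coef[1] / se[1]
    return MRResult(method="MR-Egger", theta=float(coef[1]), se=float(se[1]),
                    pval=float(2 * t_dist.sf(abs(t_slope), dof)), J=data.J,
                    egger_intercept=float(coef[0]),
                    p_intercept=float(2 * t_dist.sf(abs(t_int), dof)))


def _weighted_median_point(r: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(r)
    r = r[order]
    w = w[order] / w.sum()
    cum = np.cumsum(w) - 0.5 * w  # midpoint cumulative weights
    if cum[0] >= 0.5:
        return float(r[0])
    if cum[-1] <= 0.5:
        return float(r[-1])
    k = int(np.searchsorted(cum, 0.5))
    # linear interpolation between bracketing order statistics
    return float(r[k - 1] + (r[k] - r[k - 1]) * (0.5 - cum[k - 1])
                 / (cum[k] - cum[k - 1]))


def weighted_median(data: MRInput, n_boot: int = 5000,
                    seed: int = 0) -> MRResult:
    """Weighted median of ratio estimates; SE by seeded parametric bootstrap.

    Consistent when at least half the weight comes from valid instruments.
    """
    if data.J < 2:
        raise ValueError("weighted median needs at least 2 instruments")
    r, w = _ratio_weights(data)
    theta = _weighted_median_point(r, w)
    rng = np.random.default_rng(seed)
    if n_boot > 0:
        bx_b = rng.normal(data.bx, data.se_bx, size=(n_boot, data.J))
        by_b = rng.normal(data.by, data.se_by, size=(n_boot, data.J))
        bx_b[bx_b == 0] = np.finfo(float).tiny
        draws = np.empty(n_boot)
        for i in range(n_boot):
            ri = by_b[i] / bx_b[i]
            wi = (bx_b[i] / data.se_by) ** 2
            draws[i] = _weighted_median_point(ri, wi)
        se = float(draws.std(ddof=1))
    else:
        se = float("nan")
    pval = 2 * norm.sf(abs(theta) / se) if np.isfinite(se) and se > 0 else float("nan")
    return MRResult(method="weighted-median", theta=theta, se=se,
                    pval=float(pval), J=data.J)


def mr_presso(data: MRInput, n_sim: int = 1000, seed: int = 0,
              outlier_alpha: float = 0.05) -> tuple[float, list[str], MRResult]:
    """Simulation-based global pleiotropy test with per-instrument outlier flags.

    The observed statistic is the weighted residual sum of squares of each
    instrument around the leave-one-out IVW estimate. Its null distribution
    is built from parametric draws by*_j ~ N(bx_j·θ̂₍₋ⱼ₎, se_by_j) and
    bx*_j ~ N(bx_j, se_bx_j), with leave-one-out re-estimation inside every
    draw. Per-instrument outlier p-values are Bonferroni-corrected; the
    corrected IVW excludes flagged instruments.
    """
    if data.J < 4:
        raise ValueError("MR-PRESSO needs at least 4 instruments")
    if n_sim < 1000:
        raise ValueError("n_sim must be at least 1000")
    rng = np.random.default_rng(seed)
    w = 1.0 / data.se_by ** 2
    J = data.J

    def loo_theta(bx: np.ndarray, by: np.ndarray) -> np.ndarray:
        sxy = np.sum(w * bx * by, axis=-1, keepdims=True)
        sxx = np.sum(w * bx * bx, axis=-1, keepdims=True)
        return (sxy - w * bx * by) / (sxx - w * bx * bx)

    th_obs = loo_theta(data.bx, data.by)
    rss_j_obs = w * (data.by - data.bx * th_obs) ** 2
    rss_obs = float(np.sum(rss_j_obs))

    bx_s = rng.normal(data.bx, data.se_bx, size=(n_sim, J))
    by_s = rng.normal(data.bx * th_obs[None, :].reshape(J),
                      data.se_by, size=(n_sim, J))
    th_s = loo_theta(bx_s, by_s)
    rss_j_sim = w * (by_s - bx_s * th_s) ** 2
    rss_sim = rss_j_sim.sum(axis=1)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))
    p_out = (1 + np.sum(rss_j_sim >= rss_j_obs[None, :], axis=0)) / (n_sim + 1)
    p_out_bonf = np.minimum(p_out * J, 1.0)
    flagged = p_out_bonf < outlier_alpha
    outlier_ids = [data.ids[j] for j in np.flatnonzero(flagged)]

    if flagged.any() and (J - flagged.sum()) >= 2:
        corrected = ivw(data.subset(~flagged))
        corrected.method = "IVW-MRE-outlier-corrected"
        corrected.outliers = outlier_ids
    else:
        corrected = ivw(data)
        corrected.outliers = outlier_ids
    return global_p, outlier_ids, corrected


def mvmr(BX: np.ndarray, se_BX: np.ndarray, by: np.ndarray,
         se_by: np.ndarray, exposure_names: list[str] | None = None
         ) -> pd.DataFrame:
    """Multivariable MR: weighted least squares of by on the J×K matrix BX.

    No intercept; weights 1/se_by². SEs use a multiplicative random-effect
    scale max(1, √(RSS_w/(J−K))) with t(J−K) tests. A condition number above
    1e8 raises, naming the most collinear exposure pair.
    """
    BX = np.atleast_2d(np.asarray(BX, dtype=float))
    by = np.asarray(by, dtype=float)
    se_by = np.asarray(se_by, dtype=float)
    J, K = BX.shape
    if K < 2:
        raise ValueError("MVMR needs at least 2 exposures")
    if J <= K:
        raise ValueError("need more instruments than exposures")
    if exposure_names is None:
        exposure_names = [f"X{k + 1}" for k in range(K)]
    cond = np.linalg.cond(BX)
    if cond > 1e8:
        C = np.corrcoef(BX, rowvar=False)
        np.fill_diagonal(C, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(C)), C.shape)
        raise ValueError(
            f"rank-deficient exposure matrix (condition number {cond:.2e}); "
            f"most collinear pair: {exposure_names[i]}, {exposure_names[j]}")
    w = 1.0 / se_by ** 2
    WX = BX * w[:, None]
    xtx = BX.T @ WX
    coef = np.linalg.solve(xtx, WX.T @ by)
    resid = by - BX @ coef
    rss_w = float(np.sum(w * resid ** 2))
    dof = J - K
    scale = max(1.0, np.sqrt(rss_w / dof))
    cov = np.linalg.inv(xtx) * scale ** 2
    se = np.sqrt(np.diag(cov))
    tv = coef / se
    return pd.DataFrame({"exposure": exposure_names, "theta": coef, "se": se,
                         "pval": 2 * t_dist.sf(np.abs(tv), dof), "J": J})


def _model_log_ml(ytil: np.ndarray, Xtil: np.ndarray,
                  prior_var: float) -> float:
    """Log marginal likelihood of ỹ ~ N(X̃θ, I) with θ ~ N(0, prior_var·I).

    Evaluated through the precision-space decomposition:
    log ML = −½[J·log 2π + ỹ'ỹ − m'A m + k·log(prior_var) + log|A|]
    with A = X̃'X̃ + I/prior_var and m = A⁻¹X̃'ỹ.
    """
    Jn = len(ytil)
    if Xtil.shape[1] == 0:
        return float(-0.5 * (Jn * np.log(2 * np.pi) + ytil @ ytil))
    k = Xtil.shape[1]
    A = Xtil.T @ Xtil + np.eye(k) / prior_var
    m = np.linalg.solve(A, Xtil.T @ ytil)
    sign, logdet = np.linalg.slogdet(A)
    assert sign > 0
    return float(-0.5 * (Jn * np.log(2 * np.pi) + ytil @ ytil
                         - m @ A @ m + k * np.log(prior_var) + logdet))


def mr_bma(BX: np.ndarray, se_BX: np.ndarray, by: np.ndarray,
           se_by: np.ndarray, prior_incl: float = 0.1,
           prior_var: float = 0.25,
           exposure_names: list[str] | None = None) -> pd.DataFrame:
    """Bayesian model-averaged multivariable MR over all exposure subsets.

    Every subset S of the K exposures is scored by its conjugate-Gaussian
    marginal likelihood on the inverse-SE-weighted scale times the
    independence prior prior_incl^|S|·(1−prior_incl)^(K−|S|). Reports each
    exposure's marginal inclusion probability and model-averaged effect.
    Exhaustive enumeration is capped at K = 12.
    """
    BX = np.atleast_2d(np.asarray(BX, dtype=float))
    by = np.asarray(by, dtype=float)
    se_by = np.asarray(se_by, dtype=float)
    J, K = BX.shape
    if K > 12:
        raise ValueError("K > 12: screen exposures before exhaustive enumeration")
    if not 0 < prior_incl < 1:
        raise ValueError("prior_incl must lie in (0, 1)")
    if exposure_names is None:
        exposure_names = [f"X{k + 1}" for k in range(K)]
    ytil = by / se_by
    Xtil = BX / se_by[:, None]

    log_post = np.empty(2 ** K)
    post_means = np.zeros((2 ** K, K))
    for s in range(2 ** K):
        members = [k for k in range(K) if s >> k & 1]
        lp = (len(members) * np.log(prior_incl)
              + (K - len(members)) * np.log(1 - prior_incl))
        Xs = Xtil[:, members]
        log_post[s] = lp + _model_log_ml(ytil, Xs, prior_var)
        if members:
            A = Xs.T @ Xs + np.eye(len(members)) / prior_var
            post_means[s, members] = np.linalg.solve(A, Xs.T @ ytil)
    log_post -= np.logaddexp.reduce(log_post)
    post = np.exp(log_post)

    incl = np.zeros(K)
    avg = np.zeros(K)
    for s in range(2 ** K):
        for k in range(K):
            if s >> k & 1:
                incl[k] += post[s]
                avg[k] += post[s] * post_means[s, k]
    return pd.DataFrame({"exposure": exposure_names,
                         "inclusion_probability": incl,
                         "model_averaged_theta": avg})


def two_step_mediation(theta_total: float, se_total: float,
                       theta_em: float, se_em: float,
                       theta_mo: float, se_mo: float,
                       ci_method: str = "delta", level: float = 0.95,
                       n_boot: int = 10000, seed: int = 0) -> MediationResult:
    """Proportion mediated = (θ_EM·θ_MO)/θ_total with delta-method or bootstrap CI.

    θ_indirect is the product of the exposure→mediator and mediator→outcome
    steps; the three inputs are treated as independent estimates.
    """
    if theta_total == 0:
        raise ZeroDivisionError("total effect must be nonzero")
    indirect = theta_em * theta_mo
    prop = indirect / theta_total
    zq = norm.ppf(0.5 + level / 2)
    # gradient of p = em·mo/total
    g = np.array([theta_mo / theta_total, theta_em / theta_total,
                  -indirect / theta_total ** 2])
    var = float(g @ (np.array([se_em, se_mo, se_total]) ** 2 * g))
    se_p = np.sqrt(var)
    if ci_method == "delta":
        lo, hi = prop - zq * se_p, prop + zq * se_p
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        em = rng.normal(theta_em, se_em, n_boot)
        mo = rng.normal(theta_mo, se_mo, n_boot)
        tot = rng.normal(theta_total, se_total, n_boot)
        tot[tot == 0] = np.finfo(float).tiny
        draws = em * mo / tot
        lo, hi = np.percentile(draws, [100 * (0.5 - level / 2),
                                       100 * (0.5 + level / 2)])
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    return MediationResult(theta_total=theta_total, theta_em=theta_em,
                           theta_mo=theta_mo, theta_indirect=indirect,
                           proportion_mediated=prop, ci_level=level,
                           ci_lower=float(lo), ci_upper=float(hi),
                           ci_method=ci_method, se_proportion=float(se_p))


def two_step_from_panels(exposure_panel: pd.DataFrame,
                         mediator_panel: pd.DataFrame,
                         ci_method: str = "delta", level: float = 0.95,
                         n_boot: int = 10000, seed: int = 0) -> MediationResult:
    """Estimate a full two-step mediation from instrument-level panels.

    θ_total and θ_EM come from IVW over the exposure instruments (columns
    bx/se_bx with by/se_by and bm/se_bm); θ_MO from IVW over the independent
    mediator instruments (bm/se_bm as the exposure track, by/se_by as the
    outcome track). The three step estimates then feed
    :func:`two_step_mediation`.
    """
    e = exposure_panel
    total = ivw(MRInput(e["bx"], e["se_bx"], e["by"], e["se_by"]))
    em = ivw(MRInput(e["bx"], e["se_bx"], e["bm"], e["se_bm"]))
    m = mediator_panel
    mo = ivw(MRInput(m["bm"], m["se_bm"], m["by"], m["se_by"]))
    return two_step_mediation(total.theta, total.se, em.theta, em.se,
                              mo.theta, mo.se, ci_method=ci_method,
                              level=level, n_boot=n_boot, seed=seed)


def bidirectional_mr(forward: MRInput, reverse: MRInput,
                     model: str = "MRE") -> dict:
    """Run IVW in both directions; flag instruments shared between directions."""
    shared = sorted(set(forward.ids) & set(reverse.ids))
    result = {"forward": ivw(forward, model=model),
              "reverse": ivw(reverse, model=model),
              "shared_instruments": shared}
    if shared:
        import warnings

        warnings.warn(f"{len(shared)} instruments shared between directions",
                      stacklevel=2)
    return result


def enrichment_test(target_genes: set[str], trait_genes: set[str],
                    universe: set[str]) -> EnrichmentResult:
    """Hypergeometric upper-tail test of target/trait gene-set overlap."""
    target_genes, trait_genes, universe = (set(target_genes), set(trait_genes),
                                           set(universe))
    if not target_genes <= universe or not trait_genes <= universe:
        raise ValueError("gene sets must be subsets of the universe")
    k = len(target_genes & trait_genes)
    N, K, n = len(universe), len(trait_genes), len(target_genes)
    pval = float(hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(overlap=k, target_set_size=n, trait_set_size=K,
                            universe_size=N, pval=pval)
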