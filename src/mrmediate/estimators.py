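"""Causal-effect estimators for two-sample Mendelian randomization.

All estimators consume a :class:`~mrmediate.summary_stats.HarmonizedSet`
(per-variant exposure and outcome effects on a common effect allele) and
return an :class:`MREstimate`.  Implemented methods:

* Wald ratio (single instrument),
* inverse-variance weighted (IVW), fixed-effect or multiplicative
  random-effects,
* MR-Egger regression (free intercept detecting directional pleiotropy),
* weighted median (consistent when >= 50% of instrument weight is valid),
* a Bayesian outlier-robust hierarchical estimator (BWMR-style) that
  marginalizes over an instrument-level pleiotropy variance and reports
  per-variant posterior weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import EstimationError, InputError, InsufficientInstrumentsError
from .summary_stats import HarmonizedSet

Z95 = stats.norm.ppf(0.975)


@dataclass
class MREstimate:
    """One method's causal-effect estimate with uncertainty.

    ``beta`` is on the exposure-unit scale (log-odds per exposure unit for a
    binary outcome); ``or_scale`` carries the exponentiated (OR, CI) triple
    when the outcome is binary.
    """

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snp: int
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None
    or_scale: tuple[float, float, float] | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (self.ci_low <= self.beta <= self.ci_high):
            raise EstimationError(
                f"inconsistent CI for {self.method}: "
                f"[{self.ci_low}, {self.beta}, {self.ci_high}]")

    def to_dict(self) -> dict:
        d = {"method": self.method, "beta": self.beta, "se": self.se,
             "ci_low": self.ci_low, "ci_high": self.ci_high,
             "pval": self.pval, "n_snp": self.n_snp}
        if self.intercept is not None:
            d.update(intercept=self.intercept, intercept_se=self.intercept_se,
                     intercept_p=self.intercept_p)
        if self.or_scale is not None:
            d.update(odds_ratio=self.or_scale[0], or_ci_low=self.or_scale[1],
                     or_ci_high=self.or_scale[2])
        return d


def _finish(method, beta, se, n_snp, *, pval=None, df=None, binary=False, **extra):
    beta = float(beta)
    se = float(se)
    if pval is None:
        if se == 0:
            pval = 1.0 if beta == 0 else 0.0
        elif df is not None:
            pval = 2 * stats.t.sf(abs(beta / se), df)
        else:
            pval = 2 * stats.norm.sf(abs(beta / se))
    ci_low, ci_high = beta - Z95 * se, beta + Z95 * se
    or_scale = (np.exp(beta), np.exp(ci_low), np.exp(ci_high)) if binary else None
    pval = float(min(max(pval, np.nextafter(0, 1)), 1.0))
    return MREstimate(method, beta, se, ci_low, ci_high, pval, n_snp,
                      or_scale=or_scale, **extra)


def wald_ratio(beta_exp, se_exp, beta_out, se_out, *, second_order: bool = False,
               binary: bool = False) -> MREstimate:
    """Single-instrument ratio estimate beta_out / beta_exp.

    First-order se is se_out/|beta_exp|; the second-order (delta-method)
    option adds the exposure-uncertainty term and is strictly larger.
    """
    if beta_exp == 0:
        raise InputError("wald ratio undefined: beta_exp = 0")
    beta = beta_out / beta_exp
    var = (se_out / beta_exp) ** 2
    if second_order:
        var += (beta_out ** 2 * se_exp ** 2) / beta_exp ** 4
    return _finish("wald", beta, np.sqrt(var), 1, binary=binary)


def _ivw_core(bx, sy, by):
    w = 1.0 / sy ** 2
    den = float(np.sum(w * bx ** 2))
    beta = float(np.sum(w * bx * by)) / den
    se_fe = 1.0 / np.sqrt(den)
    q = float(np.sum((by - beta * bx) ** 2 / sy ** 2))
    return beta, se_fe, q


def ivw(hs: HarmonizedSet, *, random_effects: bool = True) -> MREstimate:
    """Inverse-variance-weighted estimate.

    The zero-intercept regression of beta_out on beta_exp with weights
    1/se_out^2.  With ``random_effects`` (multiplicative model, the default)
    the fixed-effect se is inflated by sqrt(max(1, Q/(J-1))) where Q is
    Cochran's Q at the IVW estimate.
    """
    bx, sx, by, sy = hs.arrays()
    n = len(bx)
    if n < 2:
        raise InsufficientInstrumentsError(f"ivw needs >= 2 SNPs, got {n}")
    beta, se_fe, q = _ivw_core(bx, sy, by)
    se = se_fe
    if random_effects:
        se = se_fe * np.sqrt(max(1.0, q / (n - 1)))
    method = "ivw_mre" if random_effects else "ivw_fe"
    binary = hs.outcome_type == "binary"
    est = _finish(method, beta, se, n, binary=binary)
    est.diagnostics["cochran_q"] = q
    est.diagnostics["se_fixed"] = se_fe
    return est


def _egger_fit(bx, by, sy):
    """Weighted regression of by on bx with intercept; returns fit pieces."""
    w = 1.0 / sy ** 2
    sw, swx = w.sum(), (w * bx).sum()
    swxx, swy, swxy = (w * bx * bx).sum(), (w * by).sum(), (w * bx * by).sum()
    det = sw * swxx - swx ** 2
    if det <= 1e-12 * sw * swxx:
        raise EstimationError("degenerate design: beta_exp effectively constant")
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    resid_q = float((w * (by - intercept - slope * bx) ** 2).sum())
    var_slope = sw / det
    var_intercept = swxx / det
    return slope, intercept, resid_q, var_slope, var_intercept


def egger(hs: HarmonizedSet) -> MREstimate:
    """MR-Egger regression: slope = pleiotropy-adjusted causal estimate.

    Rows are oriented so every beta_exp >= 0 before fitting (required for
    the intercept to be interpretable as average directional pleiotropy).
    Standard errors use a multiplicative dispersion sqrt(max(1, Q_R/(J-2)))
    with Rucker's Q about the fit; tests use t with J-2 df.
    """
    bx, sx, by, sy = hs.arrays()
    n = len(bx)
    if n < 3:
        raise InsufficientInstrumentsError(f"egger needs >= 3 SNPs, got {n}")
    sgn = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sgn, by * sgn
    slope, intercept, resid_q, var_slope, var_intercept = _egger_fit(bx, by, sy)
    disp = max(1.0, resid_q / (n - 2))
    se_slope = np.sqrt(var_slope * disp)
    se_intercept = np.sqrt(var_intercept * disp)
    ip = 2 * stats.t.sf(abs(intercept / se_intercept), n - 2) if se_intercept > 0 else 1.0
    binary = hs.outcome_type == "binary"
    est = _finish("egger", slope, se_slope, n, df=n - 2, binary=binary,
                  intercept=float(intercept), intercept_se=float(se_intercept),
                  intercept_p=float(ip))
    est.diagnostics["rucker_q"] = resid_q
    return est


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median with linear interpolation at cumulative weight 0.5."""
    order = np.argsort(values, kind="mergesort")
    v, w = values[order], weights[order]
    w = w / w.sum()
    cum = np.cumsum(w) - 0.5 * w
    if 0.5 <= cum[0]:
        return float(v[0])
    if 0.5 >= cum[-1]:
        return float(v[-1])
    return float(np.interp(0.5, cum, v))


def weighted_median(hs: HarmonizedSet, *, n_boot: int = 1000,
                    seed: int | None = None) -> MREstimate:
    """Weighted-median estimator over per-SNP Wald ratios.

    Weights are inverse-variance (1/se_ratio^2, first order).  The standard
    error comes from a parametric bootstrap resampling (beta_exp, beta_out)
    from their sampling distributions.
    """
    bx, sx, by, sy = hs.arrays()
    n = len(bx)
    if n < 3:
        raise InsufficientInstrumentsError(f"weighted_median needs >= 3 SNPs, got {n}")
    if seed is None:
        raise InputError("weighted_median requires an explicit seed for the bootstrap")
    ratios = by / bx
    w = (bx / sy) ** 2
    beta = _weighted_median(ratios, w)
    rng = np.random.default_rng(seed)
    bxs = rng.normal(bx, sx, size=(n_boot, n))
    bys = rng.normal(by, sy, size=(n_boot, n))
    bxs = np.where(bxs == 0, np.finfo(float).tiny, bxs)
    rmat = bys / bxs
    wmat = (bxs / sy) ** 2
    order = np.argsort(rmat, axis=1, kind="mergesort")
    rs = np.take_along_axis(rmat, order, axis=1)
    ws = np.take_along_axis(wmat, order, axis=1)
    ws = ws / ws.sum(axis=1, keepdims=True)
    cum = np.cumsum(ws, axis=1) - 0.5 * ws
    boots = np.empty(n_boot)
    for i in range(n_boot):  # np.interp is 1-D; rows are small
        boots[i] = np.interp(0.5, cum[i], rs[i])
    se = float(np.std(boots, ddof=1))
    binary = hs.outcome_type == "binary"
    est = _finish("weighted_median", beta, se, n, binary=binary)
    est.diagnostics["n_boot"] = n_boot
    return est


def bwmr(hs: HarmonizedSet, *, prior_theta_sd: float = 5.0,
         prior_tau_scale: float = 0.5, n_theta: int = 201, n_tau: int = 81,
         seed: int | None = None) -> MREstimate:
    """Bayesian outlier-robust ratio estimator (BWMR-style).

    Model: beta_out_j ~ Normal(theta * beta_exp_j,
    se_out_j^2 + theta^2 se_exp_j^2 + tau^2) with a weak Normal(0,
    prior_theta_sd^2) prior on theta and half-Normal(prior_tau_scale) prior
    on the pleiotropy scale tau.  The posterior is computed on a
    deterministic 2-D grid (no Monte Carlo; ``seed`` accepted for interface
    symmetry), theta marginalized over tau.  Per-SNP posterior weights
    exp(-z_j^2/2), evaluated at the posterior mean, flag outliers: a gross
    outlier receives the minimum weight.
    """
    bx, sx, by, sy = hs.arrays()
    n = len(bx)
    if n < 3:
        raise InsufficientInstrumentsError(f"bwmr needs >= 3 SNPs, got {n}")
    beta0, se_fe, q = _ivw_core(bx, sy, by)
    # grid wide enough that the posterior never touches the edges
    excess = max(0.0, float(np.mean((by - beta0 * bx) ** 2 - sy ** 2)))
    tau_max = 3.0 * np.sqrt(excess) + 5.0 * float(np.median(sy))
    half = 10.0 * se_fe * max(1.0, np.sqrt(q / max(n - 1, 1)))
    for attempt in range(3):
        thetas = np.linspace(beta0 - half, beta0 + half, n_theta)
        taus = np.linspace(0.0, tau_max, n_tau)
        v = (sy ** 2)[None, None, :] + (thetas ** 2)[:, None, None] * (sx ** 2)[None, None, :] \
            + (taus ** 2)[None, :, None]
        resid = by[None, None, :] - thetas[:, None, None] * bx[None, None, :]
        loglik = -0.5 * np.sum(np.log(2 * np.pi * v) + resid ** 2 / v, axis=2)
        logprior = (-0.5 * (thetas / prior_theta_sd) ** 2)[:, None] \
            + (-0.5 * (taus / prior_tau_scale) ** 2)[None, :]
        lp = loglik + logprior
        lp -= lp.max()
        post = np.exp(lp)
        post /= post.sum()
        edge_mass = post[0, :].sum() + post[-1, :].sum() + post[:, -1].sum()
        if edge_mass < 1e-3:
            break
        half *= 2.5
        tau_max *= 2.5
    else:
        raise EstimationError("bwmr grid posterior did not stabilize",
                              diagnostics={"edge_mass": float(edge_mass)})
    p_theta = post.sum(axis=1)
    mean = float(np.sum(thetas * p_theta))
    sd = float(np.sqrt(np.sum((thetas - mean) ** 2 * p_theta)))
    tau_mean = float(np.sum(taus * post.sum(axis=0)))
    vj = sy ** 2 + mean ** 2 * sx ** 2 + tau_mean ** 2
    z = (by - mean * bx) / np.sqrt(vj)
    weights = np.exp(-0.5 * z ** 2)
    binary = hs.outcome_type == "binary"
    est = _finish("bwmr", mean, sd, n, binary=binary)
    est.diagnostics.update(tau_posterior_mean=tau_mean,
                           outlier_weights=weights,
                           rsids=list(hs.retained["rsid"]))
    return est


ESTIMATORS = {
    "ivw_mre": lambda hs, seed=None: ivw(hs, random_effects=True),
    "ivw_fe": lambda hs, seed=None: ivw(hs, random_effects=False),
    "egger": lambda hs, seed=None: egger(hs),
    "weighted_median": lambda hs, seed=0: weighted_median(hs, seed=seed),
    "bwmr": lambda hs, seed=None: bwmr(hs, seed=seed),
}


def run_all(hs: HarmonizedSet, *, seed: int = 0,
            methods=("ivw_mre", "egger", "weighted_median", "bwmr")) -> dict[str, MREstimate]:
    """Run the requested estimator battery on one harmonized set."""
    out = {}
    for m in methods:
        out[m] = ESTIMATORS[m](hs, seed=seed)
    return out
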