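"""Heterogeneity/pleiotropy diagnostics and the primary-method decision rule.

Covers Cochran's Q about the IVW fit, Rucker's Q about the Egger fit, an
MR-PRESSO-style global and per-SNP outlier test based on leave-one-out
residual sums of squares with a simulated null, leave-one-out influence
analysis, and the rule that picks the primary causal estimator from the
diagnostic profile.

Weight-scale conventions (stated to avoid silent mismatch): Cochran's Q is
computed on the Wald-ratio scale with weights 1/se_ratio^2 where
se_ratio = se_out/|beta_exp| (algebraically equal to summing squared
outcome-scale residuals over se_out^2); Rucker's Q is the weighted residual
sum of squares of the Egger regression with weights 1/se_out^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import MREstimate, _egger_fit, _ivw_core, ivw
from .exceptions import ConfigError, InsufficientInstrumentsError, MRMediateError
from .summary_stats import HarmonizedSet


def cochran_q(hs: HarmonizedSet) -> tuple[float, int, float]:
    """Heterogeneity of per-SNP Wald ratios about the IVW estimate."""
    bx, sx, by, sy = hs.arrays()
    n = len(bx)
    if n < 2:
        raise InsufficientInstrumentsError("cochran_q needs >= 2 SNPs")
    beta, _, q = _ivw_core(bx, sy, by)
    df = n - 1
    return float(q), df, float(stats.chi2.sf(q, df))


def rucker_q(hs: HarmonizedSet) -> tuple[float, int, float]:
    """Residual heterogeneity about the MR-Egger fit (weights 1/se_out^2)."""
    bx, sx, by, sy = hs.arrays()
    n = len(bx)
    if n < 3:
        raise InsufficientInstrumentsError("rucker_q needs >= 3 SNPs")
    sgn = np.where(bx < 0, -1.0, 1.0)
    _, _, resid_q, _, _ = _egger_fit(bx * sgn, by * sgn, sy)
    df = n - 2
    return float(resid_q), df, float(stats.chi2.sf(resid_q, df))


def _loo_residuals(bx, by, sy):
    """Standardized leave-one-out IVW residual per SNP (vectorized)."""
    w = 1.0 / sy ** 2
    num, den = np.sum(w * bx * by), np.sum(w * bx ** 2)
    beta_loo = (num - w * bx * by) / (den - w * bx ** 2)
    return (by - beta_loo * bx) / sy


def _presso_sims(bx, sy, beta_loo_pred, n_sim, rng):
    """Simulated standardized LOO residual matrix under the per-SNP null."""
    n = len(bx)
    w = 1.0 / sy ** 2
    by_sim = rng.normal(beta_loo_pred * bx, sy, size=(n_sim, n))
    num = by_sim @ (w * bx)
    den = np.sum(w * bx ** 2)
    beta_loo = (num[:, None] - by_sim * (w * bx)[None, :]) / (den - w * bx ** 2)[None, :]
    return (by_sim - beta_loo * bx[None, :]) / sy[None, :]


def presso_global(hs: HarmonizedSet, *, n_sim: int = 1000,
                  seed: int = 0) -> float:
    """MR-PRESSO-style global horizontal-pleiotropy test.

    Observed statistic: sum over SNPs of the squared standardized residual of
    each SNP's outcome effect against the IVW prediction fitted without that
    SNP.  The null distribution is built by drawing each beta_out from
    Normal(beta_loo_j * beta_exp_j, se_out_j^2) and recomputing the same
    statistic; p uses the +1 correction so it is never zero.
    """
    p, _ = _presso(hs, n_sim=n_sim, seed=seed)
    return p


def _presso(hs: HarmonizedSet, *, n_sim: int, seed: int):
    bx, sx, by, sy = hs.arrays()
    n = len(bx)
    if n < 4:
        raise InsufficientInstrumentsError("presso needs >= 4 SNPs")
    if n_sim < 100:
        raise ConfigError("presso n_sim < 100 gives unstable p-values")
    resid = _loo_residuals(bx, by, sy)
    rss_obs = float(np.sum(resid ** 2))
    w = 1.0 / sy ** 2
    num, den = np.sum(w * bx * by), np.sum(w * bx ** 2)
    beta_loo_pred = (num - w * bx * by) / (den - w * bx ** 2)
    rng = np.random.default_rng(seed)
    sim_resid = _presso_sims(bx, sy, beta_loo_pred, n_sim, rng)
    rss_sim = np.sum(sim_resid ** 2, axis=1)
    p_global = (1 + int(np.sum(rss_sim >= rss_obs))) / (n_sim + 1)
    p_snp = (1 + np.sum(sim_resid ** 2 >= resid[None, :] ** 2, axis=0)) / (n_sim + 1)
    return float(p_global), p_snp


def presso_outlier(hs: HarmonizedSet, *, n_sim: int = 1000, seed: int = 0,
                   alpha: float = 0.05) -> pd.DataFrame:
    """Per-SNP outlier test with Bonferroni-adjusted flags.

    Returns a table (rsid, residual2, pval, flagged) sorted as the input.
    The outlier-corrected IVW is obtained by dropping flagged rows and
    re-running ``ivw``.
    """
    _, p_snp = _presso(hs, n_sim=n_sim, seed=seed)
    bx, sx, by, sy = hs.arrays()
    resid = _loo_residuals(bx, by, sy)
    n = len(bx)
    return pd.DataFrame({
        "rsid": list(hs.retained["rsid"]),
        "residual2": resid ** 2,
        "pval": p_snp,
        "flagged": p_snp * n < alpha,
    })


def outlier_corrected_ivw(hs: HarmonizedSet, flags: pd.DataFrame) -> MREstimate:
    """Re-run IVW after removing PRESSO-flagged outliers."""
    bad = set(flags.loc[flags["flagged"], "rsid"])
    keep = ~hs.table["rsid"].isin(bad)
    sub = HarmonizedSet(hs.exposure_id, hs.outcome_id,
                        hs.table.loc[keep].reset_index(drop=True),
                        outcome_type=hs.outcome_type)
    return ivw(sub)


def leave_one_out(hs: HarmonizedSet) -> pd.DataFrame:
    """IVW re-estimated with each SNP removed in turn.

    A SNP is flagged when its removal flips the sign of the estimate or
    moves it outside the full-set 95% CI.
    """
    if hs.n_snp < 3:
        raise InsufficientInstrumentsError("leave_one_out needs >= 3 SNPs")
    full = ivw(hs)
    rows = []
    ret = hs.retained
    for i in range(len(ret)):
        sub = HarmonizedSet(hs.exposure_id, hs.outcome_id,
                            ret.drop(index=i).reset_index(drop=True),
                            outcome_type=hs.outcome_type)
        est = ivw(sub)
        flagged = (np.sign(est.beta) != np.sign(full.beta) and full.beta != 0) or \
            not (full.ci_low <= est.beta <= full.ci_high)
        rows.append({"left_out": ret.at[i, "rsid"], "beta": est.beta,
                     "se": est.se, "ci_low": est.ci_low, "ci_high": est.ci_high,
                     "flagged": bool(flagged)})
    return pd.DataFrame(rows)


@dataclass
class SensitivityReport:
    """Diagnostic bundle for one exposure-outcome pair."""

    q: float
    q_df: int
    q_p: float
    rucker_q: float
    rucker_df: int
    rucker_p: float
    egger_intercept: float
    egger_intercept_p: float
    presso_global_p: float
    presso_outliers: list[str] = field(default_factory=list)
    loo: pd.DataFrame | None = None
    chosen_method: str | None = None
    rationale: str | None = None

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("q", "q_df", "q_p", "rucker_q", "rucker_df", "rucker_p",
              "egger_intercept", "egger_intercept_p", "presso_global_p",
              "presso_outliers", "chosen_method", "rationale")}
        if self.loo is not None:
            d["loo"] = self.loo.to_dict(orient="records")
        return d


def sensitivity_report(hs: HarmonizedSet, *, n_sim: int = 1000, seed: int = 0,
                       alpha: float = 0.05, with_loo: bool = True) -> SensitivityReport:
    """Run the full diagnostic battery and apply the method-selection rule."""
    from .estimators import egger as egger_fn
    q, qdf, qp = cochran_q(hs)
    rq, rdf, rp = rucker_q(hs)
    eg = egger_fn(hs)
    if hs.n_snp >= 4:
        pg, _ = _presso(hs, n_sim=n_sim, seed=seed)
        flags = presso_outlier(hs, n_sim=n_sim, seed=seed, alpha=alpha)
        outliers = list(flags.loc[flags["flagged"], "rsid"])
    else:
        pg, outliers = 1.0, []
    loo = leave_one_out(hs) if with_loo else None
    rep = SensitivityReport(q, qdf, qp, rq, rdf, rp, eg.intercept,
                            eg.intercept_p, pg, outliers, loo)
    rep.chosen_method, rep.rationale = select_method(rep, alpha=alpha)
    return rep


def select_method(report: SensitivityReport, *, alpha: float = 0.05) -> tuple[str, str]:
    """Primary-method decision rule.

    * no pleiotropy signal (PRESSO global and Egger intercept both
      non-significant) -> IVW (multiplicative random effects);
    * significant Egger intercept (directional pleiotropy) -> MR-Egger;
    * significant PRESSO global with non-significant intercept, i.e.
      moderate pleiotropy/heterogeneity -> weighted median.
    """
    missing = [k for k in ("presso_global_p", "egger_intercept_p")
               if getattr(report, k) is None]
    if missing:
        raise MRMediateError(f"incomplete sensitivity report: missing {missing}")
    pe, pp = report.egger_intercept_p, report.presso_global_p
    if pe <= alpha:
        return "egger", (f"Egger intercept p = {pe:.3g} <= {alpha}: directional "
                         "pleiotropy; pleiotropy-adjusted Egger slope is primary")
    if pp <= alpha:
        return "weighted_median", (f"PRESSO global p = {pp:.3g} <= {alpha} with "
                                   "non-significant intercept: weighted median is primary")
    return "ivw_mre", (f"PRESSO global p = {pp:.3g} and Egger intercept p = "
                       f"{pe:.3g} > {alpha}: no pleiotropy evidence; IVW is primary")
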