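"""Simplified LD-score regression for heritability and genetic correlation.

Single-variance-component model on the observed scale:

    E[chi2_j]    = 1 + a + N h2 l_j / M
    E[z1_j z2_j] = intercept + sqrt(N1 N2) rho_g l_j / M

where l_j is the LD score of variant j and M the number of variants the
scores were computed over.  Slopes are estimated by weighted least squares
with the standard heteroskedasticity weights 1/(1 + N h2 l_j/M)^2, iterated
twice from an OLS start; standard errors come from a delete-one block
jackknife over contiguous blocks.  Genetic correlation is
rg = rho_g / sqrt(h2_1 h2_2).  No liability-scale conversion and no
partitioned heritability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InputError
from .summary_stats import SummaryStats

MIN_OVERLAP = 200


@dataclass
class LDScoreTable:
    """Per-variant univariate LD scores and the panel size M."""

    table: pd.DataFrame  # rsid, ldscore
    m_total: int

    def __post_init__(self):
        if (self.table["ldscore"] < 1.0 - 1e-6).any():
            raise InputError("LD scores must be >= 1 (a variant tags itself)")
        if self.m_total < len(self.table):
            raise InputError("m_total smaller than the number of scored variants")

    @classmethod
    def read(cls, path, m_total: int | None = None) -> "LDScoreTable":
        df = pd.read_csv(path, sep="\t")
        if not {"rsid", "ldscore"} <= set(df.columns):
            raise InputError("LD-score file needs columns rsid, ldscore")
        return cls(df[["rsid", "ldscore"]], m_total or len(df))


@dataclass
class LdscResult:
    """Heritability and (optionally) cross-trait genetic correlation."""

    h2: float
    h2_se: float
    intercept: float
    h2_2: float | None = None
    h2_2_se: float | None = None
    rg: float | None = None
    rg_se: float | None = None
    rg_p: float | None = None
    rg_out_of_bounds: bool = False
    n_variants: int = 0

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("h2", "h2_se", "intercept", "h2_2", "h2_2_se",
                 "rg", "rg_se", "rg_p", "rg_out_of_bounds", "n_variants")}


def _wls(x, y, w, free_intercept=True):
    if not free_intercept:
        return float(np.sum(w * x * y) / np.sum(w * x * x)), 0.0
    sw, swx, swy = w.sum(), (w * x).sum(), (w * y).sum()
    swxx, swxy = (w * x * x).sum(), (w * x * y).sum()
    det = sw * swxx - swx ** 2
    slope = (sw * swxy - swx * swy) / det
    intercept = (swxx * swy - swx * swxy) / det
    return float(slope), float(intercept)


def _iterated_fit(x, y, pred_start, free_intercept=True, n_iter=2):
    """WLS with weights 1/(E[y])^2 refreshed from the previous fit."""
    w = np.ones_like(x)
    slope, intercept = _wls(x, y, w, free_intercept)
    for _ in range(n_iter):
        mean = np.maximum(pred_start(slope, intercept), 0.1)
        w = 1.0 / mean ** 2
        slope, intercept = _wls(x, y, w, free_intercept)
    return slope, intercept, w


def _jackknife(values: np.ndarray) -> float:
    b = len(values)
    return float(np.sqrt((b - 1) / b * np.sum((values - values.mean()) ** 2)))


def _blocks(n: int, n_blocks: int):
    edges = np.linspace(0, n, min(n_blocks, n) + 1).astype(int)
    return [(edges[i], edges[i + 1]) for i in range(len(edges) - 1)]


def _merge_ld(ss: SummaryStats, ld: LDScoreTable) -> pd.DataFrame:
    t = ss.table.copy()
    t["n_eff"] = ss.effective_n()
    if t["n_eff"].isna().any():
        raise InputError(f"trait {ss.trait_id!r}: per-variant n required for LDSC")
    merged = t.merge(ld.table, on="rsid", how="inner")
    if len(merged) < MIN_OVERLAP:
        raise InputError(
            f"only {len(merged)} variants overlap the LD scores "
            f"(need >= {MIN_OVERLAP})")
    merged["z"] = merged["beta"] / merged["se"]
    return merged


def ldsc_h2(ss: SummaryStats, ld: LDScoreTable, *, n_blocks: int = 200,
            constrain_intercept: bool = False) -> LdscResult:
    """Observed-scale SNP heritability by single-component LDSC."""
    m = _merge_ld(ss, ld)
    x = (m["n_eff"] * m["ldscore"] / ld.m_total).to_numpy(float)
    y = (m["z"] ** 2).to_numpy(float)
    if constrain_intercept:
        slope, intercept, w = _iterated_fit(
            x, y - 1.0, lambda s, i: 1.0 + s * x, free_intercept=False)
        intercept = 1.0
    else:
        slope, intercept, w = _iterated_fit(
            x, y, lambda s, i: i + s * x, free_intercept=True)
    pseudo = []
    for lo, hi in _blocks(len(x), n_blocks):
        mask = np.ones(len(x), bool)
        mask[lo:hi] = False
        if constrain_intercept:
            s_b, _ = _wls(x[mask], (y - 1.0)[mask], w[mask], free_intercept=False)
        else:
            s_b, _ = _wls(x[mask], y[mask], w[mask])
        pseudo.append(s_b)
    se = _jackknife(np.array(pseudo))
    return LdscResult(h2=float(slope), h2_se=se, intercept=float(intercept),
                      n_variants=len(x))


def ldsc_rg(ss1: SummaryStats, ss2: SummaryStats, ld: LDScoreTable, *,
            n_blocks: int = 200) -> LdscResult:
    """Cross-trait genetic correlation by bivariate LDSC.

    rg = genetic covariance slope / sqrt(h2_1 h2_2); the jackknife is taken
    over the rg functional itself (all three regressions refit per deleted
    block).  Reported rg is clipped to [-1.25, 1.25] with out-of-[-1, 1]
    values flagged; a non-positive h2 for either trait leaves rg undefined.
    """
    m1 = _merge_ld(ss1, ld)
    m2 = _merge_ld(ss2, ld)
    m = m1.merge(m2, on="rsid", suffixes=("_1", "_2"))
    if len(m) < MIN_OVERLAP:
        raise InputError("insufficient variant overlap between the two traits")
    l_over_m = (m["ldscore_1"] / ld.m_total).to_numpy(float)
    n1 = m["n_eff_1"].to_numpy(float)
    n2 = m["n_eff_2"].to_numpy(float)
    z1 = m["z_1"].to_numpy(float)
    z2 = m["z_2"].to_numpy(float)

    x1, y1 = n1 * l_over_m, z1 ** 2
    x2, y2 = n2 * l_over_m, z2 ** 2
    xc, yc = np.sqrt(n1 * n2) * l_over_m, z1 * z2
    h1, _, w1 = _iterated_fit(x1, y1, lambda s, i: i + s * x1)
    h2_, _, w2 = _iterated_fit(x2, y2, lambda s, i: i + s * x2)
    wc = np.sqrt(w1 * w2)
    cov, icept = _wls(xc, yc, wc)

    def rg_of(mask):
        s1, _ = _wls(x1[mask], y1[mask], w1[mask])
        s2, _ = _wls(x2[mask], y2[mask], w2[mask])
        sc, _ = _wls(xc[mask], yc[mask], wc[mask])
        if s1 <= 0 or s2 <= 0:
            return np.nan
        return sc / np.sqrt(s1 * s2)

    if h1 <= 0 or h2_ <= 0:
        return LdscResult(h2=float(h1), h2_se=np.nan, intercept=float(icept),
                          h2_2=float(h2_), h2_2_se=np.nan, rg=None,
                          rg_se=None, rg_p=None, n_variants=len(m))
    rg_full = cov / np.sqrt(h1 * h2_)
    pseudo = []
    for lo, hi in _blocks(len(m), n_blocks):
        mask = np.ones(len(m), bool)
        mask[lo:hi] = False
        pseudo.append(rg_of(mask))
    pseudo = np.array([p for p in pseudo if np.isfinite(p)])
    rg_se = _jackknife(pseudo)
    rg_p = 2 * stats.norm.sf(abs(rg_full) / rg_se) if rg_se > 0 else np.nan
    out_of_bounds = abs(rg_full) > 1.0
    rg_rep = float(np.clip(rg_full, -1.25, 1.25))

    # per-trait h2 jackknife se
    def h2_se_of(x, y, w):
        ps = []
        for lo, hi in _blocks(len(m), n_blocks):
            mask = np.ones(len(m), bool)
            mask[lo:hi] = False
            ps.append(_wls(x[mask], y[mask], w[mask])[0])
        return _jackknife(np.array(ps))

    return LdscResult(h2=float(h1), h2_se=h2_se_of(x1, y1, w1),
                      intercept=float(icept), h2_2=float(h2_),
                      h2_2_se=h2_se_of(x2, y2, w2), rg=rg_rep,
                      rg_se=float(rg_se), rg_p=float(rg_p),
                      rg_out_of_bounds=out_of_bounds, n_variants=len(m))


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise per-test significance threshold alpha/m."""
    if not 0 < alpha < 1:
        raise InputError("alpha must be in (0,1)")
    if m < 1:
        raise InputError("m must be >= 1")
    return alpha / m
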