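"""Synthetic GWAS summary statistics with known causal structure.

Generators emulate the statistical structure the analysis assumes: per-variant
effect estimates whose sampling noise is set by sample size and allele
frequency (se_j = 1/sqrt(2 maf_j (1-maf_j) N)), an exposure -> mediator ->
outcome structural model with configurable direct and indirect effects, and
balanced / directional / correlated (InSIDE-violating) pleiotropy.  Every
generator is a pure function of its configuration and seed; the generative
truth is returned alongside the tables for parameter-recovery tests.

Default study conditions: exposure GWAS n = 300,000 (anthropometric-trait
scale), mediator GWAS n = 8,000 (plasma-metabolome cohort scale), outcome
effective n = 25,000 (case-control colorectal-cancer scale, log-odds
effects), 100 exposure instruments explaining r2 = 0.06, 15
mediator-specific instruments explaining r2 = 0.08, maf ~ U(0.05, 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coloc import RegionStats
from .exceptions import ConfigError
from .ldsc import LDScoreTable
from .summary_stats import (HarmonizedSet, SummaryStats, build_summary_stats,
                            harmonized_from_arrays)

# non-palindromic allele pairs cycled across variants
_ALLELE_PAIRS = (("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"))

DEFAULT_SAMPLE_SIZES = {"exposure": 300_000, "mediator": 8_000, "outcome": 25_000}


@dataclass
class Pleiotropy:
    """Direct instrument -> outcome effects violating exclusion restriction.

    ``mode``: none | balanced (mean-zero) | directional (nonzero mean) |
    correlated (correlated with instrument strength, violating InSIDE).
    """

    mode: str = "none"
    sd: float = 0.0
    mean: float = 0.0
    corr: float = 0.7

    def draw(self, gamma: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        n = len(gamma)
        if self.mode == "none":
            return np.zeros(n)
        if self.mode == "balanced":
            return rng.normal(0.0, self.sd, n)
        if self.mode == "directional":
            return rng.normal(self.mean, self.sd, n)
        if self.mode == "correlated":
            g = (gamma - gamma.mean()) / max(gamma.std(), 1e-12)
            eps = rng.standard_normal(n)
            return self.mean + self.sd * (self.corr * g
                                          + np.sqrt(1 - self.corr ** 2) * eps)
        raise ConfigError(f"unknown pleiotropy mode {self.mode!r}")


@dataclass
class SimulationTruth:
    """Generative parameters of one synthetic mediation triangle."""

    theta_xm: float
    theta_my: float
    theta_direct: float
    n_snp_x: int = 100
    n_snp_m: int = 15
    r2_x: float = 0.06
    r2_m: float = 0.08
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy)
    sample_sizes: dict = field(default_factory=lambda: dict(DEFAULT_SAMPLE_SIZES))
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0

    @property
    def theta_total(self) -> float:
        return self.theta_direct + self.theta_xm * self.theta_my

    @property
    def true_proportion(self) -> float | None:
        if self.theta_total == 0:
            return None
        return self.theta_xm * self.theta_my / self.theta_total


def _scaled_effects(n_snp: int, maf: np.ndarray, target_r2: float,
                    rng: np.random.Generator) -> np.ndarray:
    raw = rng.standard_normal(n_snp)
    het = 2.0 * maf * (1.0 - maf)
    scale2 = target_r2 / float(np.sum(het * raw ** 2))
    if not np.isfinite(scale2) or scale2 <= 0:
        raise ConfigError("infeasible target r2 for the given instrument count")
    return raw * np.sqrt(scale2)


def _observe(true_beta: np.ndarray, maf: np.ndarray, n: int,
             rng: np.random.Generator):
    """Observed (beta_hat, se, pval) under the regression-se approximation."""
    from scipy import stats
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)
    beta_hat = rng.normal(true_beta, se)
    z = beta_hat / se
    pval = np.maximum(2 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1))
    return beta_hat, se, pval


def _panel(n_snp: int, maf: np.ndarray, *, prefix: str = "rs", chrom: str = "1",
           pos_start: int = 1_000_000, spacing: int = 2_000) -> pd.DataFrame:
    pairs = [_ALLELE_PAIRS[i % len(_ALLELE_PAIRS)] for i in range(n_snp)]
    return pd.DataFrame({
        "rsid": [f"{prefix}{i + 1}" for i in range(n_snp)],
        "chrom": chrom,
        "pos": pos_start + spacing * np.arange(n_snp),
        "effect_allele": [p[0] for p in pairs],
        "other_allele": [p[1] for p in pairs],
        "eaf": maf,
    })


def _table(panel: pd.DataFrame, beta, se, pval, n) -> pd.DataFrame:
    out = panel.copy()
    out["beta"], out["se"], out["pval"], out["n"] = beta, se, pval, n
    return out


def simulate_triangle(truth: SimulationTruth):
    """One exposure/mediator/outcome GWAS trio with planted causal effects.

    All three tables share the same variant panel (exposure instruments
    followed by mediator-specific instruments).  Exposure instruments act on
    the mediator through theta_xm and on the outcome through
    theta_direct + theta_xm*theta_my plus any pleiotropy term; mediator
    instruments act on the outcome through theta_my only.  Returns
    (exposure, mediator, outcome, truth).
    """
    if truth.n_snp_x < 3 or truth.n_snp_m < 3:
        raise ConfigError("instrument counts must be >= 3")
    assert np.isclose(truth.theta_total,
                      truth.theta_direct + truth.theta_xm * truth.theta_my)
    rng = np.random.default_rng(truth.seed)
    n_total = truth.n_snp_x + truth.n_snp_m
    maf = rng.uniform(*truth.maf_range, n_total)
    panel = _panel(n_total, maf)
    is_x = np.arange(n_total) < truth.n_snp_x

    gamma = np.zeros(n_total)
    gamma[is_x] = _scaled_effects(truth.n_snp_x, maf[is_x], truth.r2_x, rng)
    delta = np.zeros(n_total)
    delta[~is_x] = _scaled_effects(truth.n_snp_m, maf[~is_x], truth.r2_m, rng)

    # pleiotropy is defined on the exposure-increasing orientation; map it
    # back to the allele coding through the sign of the instrument effect
    alpha = np.zeros(n_total)
    gx = gamma[is_x]
    alpha[is_x] = np.sign(gx) * truth.pleiotropy.draw(np.abs(gx), rng)

    beta_x = gamma
    beta_m = truth.theta_xm * gamma + delta
    beta_y = truth.theta_direct * gamma + truth.theta_my * beta_m + alpha

    sizes = truth.sample_sizes
    bx, sx, px = _observe(beta_x, maf, sizes["exposure"], rng)
    bm, sm, pm = _observe(beta_m, maf, sizes["mediator"], rng)
    by, sy, py = _observe(beta_y, maf, sizes["outcome"], rng)

    exposure = build_summary_stats(
        _table(panel, bx, sx, px, sizes["exposure"]), "exposure")
    mediator = build_summary_stats(
        _table(panel, bm, sm, pm, sizes["mediator"]), "mediator")
    outcome = build_summary_stats(
        _table(panel, by, sy, py, sizes["outcome"]), "outcome",
        trait_type="binary")
    return exposure, mediator, outcome, truth


def simulate_harmonized(n_snp: int, theta: float, *, seed: int,
                        n_exp: int = DEFAULT_SAMPLE_SIZES["exposure"],
                        n_out: int = DEFAULT_SAMPLE_SIZES["outcome"],
                        r2: float = 0.06,
                        pleiotropy: Pleiotropy | None = None,
                        n_invalid: int = 0, invalid_theta: float = 0.0,
                        maf_range=(0.05, 0.5),
                        outcome_type: str = "quantitative") -> HarmonizedSet:
    """Pre-harmonized instrument set for estimator-level experiments.

    The first ``n_invalid`` variants are invalid instruments acting on the
    outcome with slope ``invalid_theta`` instead of ``theta`` (exclusion-
    restriction violation with a common alternative pathway).
    """
    pleiotropy = pleiotropy or Pleiotropy()
    rng = np.random.default_rng(seed)
    maf = rng.uniform(*maf_range, n_snp)
    gamma = _scaled_effects(n_snp, maf, r2, rng)
    # directional/correlated pleiotropy acts on the exposure-increasing
    # orientation of each instrument
    alpha = np.sign(gamma) * pleiotropy.draw(np.abs(gamma), rng)
    slope = np.full(n_snp, theta)
    slope[:n_invalid] = invalid_theta
    beta_y_true = slope * gamma + alpha
    bx, sx, _ = _observe(gamma, maf, n_exp, rng)
    by, sy, _ = _observe(beta_y_true, maf, n_out, rng)
    return harmonized_from_arrays(bx, sx, by, sy, outcome_type=outcome_type)


def simulate_coloc_region(shared: bool, *, n_snp: int = 100,
                          z_strength: float = 10.0, seed: int = 0,
                          n1: int = 50_000, n2: int = 25_000,
                          se: float = 0.02):
    """Two LD-free regional association tables for colocalization tests.

    With ``shared`` a single variant carries a z ~ z_strength signal in both
    traits; otherwise two distinct variants carry the two signals.  All
    remaining variants are pure noise.
    """
    if n_snp < 1:
        raise ConfigError("n_snp must be >= 1")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(0.1, 0.5, n_snp)
    panel = _panel(n_snp, maf, spacing=4_000)
    center = int(panel["pos"].iloc[n_snp // 2])

    def one(causal_idx, n):
        true = np.zeros(n_snp)
        if causal_idx is not None and z_strength != 0:
            true[causal_idx] = z_strength * se
        beta = rng.normal(true, se)
        t = panel.copy()
        t["beta"], t["se"], t["n"] = beta, se, n
        return t

    idx1 = 0 if z_strength != 0 else None
    idx2 = (0 if shared else min(1, n_snp - 1)) if z_strength != 0 else None
    r1 = RegionStats("trait1", "1", center, 250_000, one(idx1, n1))
    r2 = RegionStats("trait2", "1", center, 250_000, one(idx2, n2))
    return r1, r2


def simulate_ldsc_pair(h2_1: float, h2_2: float, rg: float, *, m: int = 5000,
                       n1: int = 20_000, n2: int = 20_000, seed: int = 0,
                       mean_ldscore: float = 10.0):
    """Two traits with planted heritabilities and genetic correlation.

    LD scores are 1 + Exponential(mean_ldscore - 1); per-variant z-scores are
    bivariate normal with Var(z_t) = 1 + N_t h2_t l_j/M and
    Cov = rg sqrt(h2_1 h2_2 N1 N2) l_j/M.  Returns (ss1, ss2, ld_table).
    """
    if abs(rg) > 1 or not (0 <= h2_1 < 1 and 0 <= h2_2 < 1):
        raise ConfigError("require |rg| <= 1 and h2 in [0,1)")
    rng = np.random.default_rng(seed)
    ld = 1.0 + rng.exponential(mean_ldscore - 1.0, m)
    maf = rng.uniform(0.05, 0.5, m)
    panel = _panel(m, maf, prefix="ldrs")
    s1 = np.sqrt(n1 * h2_1 * ld / m)
    s2 = np.sqrt(n2 * h2_2 * ld / m)
    g = rng.standard_normal((m, 2))
    g2 = rg * g[:, 0] + np.sqrt(1 - rg ** 2) * g[:, 1]
    z1 = s1 * g[:, 0] + rng.standard_normal(m)
    z2 = s2 * g2 + rng.standard_normal(m)

    def to_ss(z, n, trait_id):
        from scipy import stats
        se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)
        beta = z * se
        pval = np.maximum(2 * stats.norm.sf(np.abs(z)), np.nextafter(0, 1))
        return build_summary_stats(_table(panel, beta, se, pval, n), trait_id)

    ld_table = LDScoreTable(pd.DataFrame({"rsid": panel["rsid"], "ldscore": ld}),
                            m_total=m)
    return to_ss(z1, n1, "trait1"), to_ss(z2, n2, "trait2"), ld_table


# ---------------------------------------------------------------------------
# full study bundle for the pipeline


@dataclass
class StudyTruth:
    """Planted parameters of a multi-phenotype, multi-metabolite study."""

    phenotypes: list[str]
    metabolites: list[str]
    rg_outcome: dict[str, float]              # phenotype -> background rg with outcome
    theta_xm: dict[tuple[str, str], float]    # (phenotype, metabolite) -> effect
    theta_my: dict[str, float]                # metabolite -> outcome effect
    theta_direct: dict[str, float]            # phenotype -> direct outcome effect
    seed: int = 0


def default_study_truth(seed: int = 0, *, n_metabolites: int = 20) -> StudyTruth:
    """The reference synthetic study: 4 phenotypes, shared mediators planted.

    Metabolite met1 mediates all four phenotypes, met2 the obesity+MetS
    subset, met3 is associated with the obesity pair only (excluded by the
    grouping rule); the remainder are null.
    """
    phenos = ["BMI", "WC", "BMR", "MetS"]
    mets = [f"met{i + 1}" for i in range(n_metabolites)]
    theta_xm = {}
    for p in phenos:
        theta_xm[(p, "met1")] = 0.3
    for p in ("BMI", "WC", "MetS"):
        theta_xm[(p, "met2")] = 0.25
    for p in ("BMI", "WC"):
        theta_xm[(p, "met3")] = 0.3
    theta_my = {m: 0.0 for m in mets}
    theta_my["met1"] = 0.25
    theta_my["met2"] = 0.2
    theta_my["met3"] = 0.2
    theta_direct = {p: 0.175 for p in phenos}
    rg_outcome = {p: 0.4 for p in phenos}
    return StudyTruth(phenos, mets, rg_outcome, theta_xm, theta_my,
                      theta_direct, seed=seed)


def simulate_study(truth: StudyTruth, *, n_snp_x: int = 60, n_snp_m: int = 12,
                   r2_x: float = 0.06, r2_m: float = 0.08,
                   m_background: int = 2000, h2_background: float = 2e-3,
                   sample_sizes: dict | None = None,
                   n_validation: int = 50_000):
    """Simulate every GWAS table the full pipeline consumes.

    Each phenotype gets ``n_snp_x`` private instruments, each metabolite
    ``n_snp_m`` private instruments; all variants (plus an LD-scored
    background block used only by the LDSC screen) appear in every table.
    ``h2_background`` is the down-scaled panel heritability of the
    background block, sized so background associations stay below the
    genome-wide instrument threshold at the exposure sample size while the
    genetic-correlation slope remains estimable.
    A second, larger outcome GWAS provides the external validation set.
    Returns a dict with keys phenotypes, metabolites, outcome,
    outcome_validation, ld, truth.
    """
    sizes = dict(DEFAULT_SAMPLE_SIZES)
    if sample_sizes:
        sizes.update(sample_sizes)
    rng = np.random.default_rng(truth.seed)
    phenos, mets = truth.phenotypes, truth.metabolites
    n_instr = n_snp_x * len(phenos) + n_snp_m * len(mets)
    n_total = n_instr + m_background
    maf = rng.uniform(0.05, 0.5, n_total)
    panel = _panel(n_total, maf)

    blocks: dict[str, np.ndarray] = {}
    start = 0
    for p in phenos:
        blocks[p] = np.arange(start, start + n_snp_x)
        start += n_snp_x
    for m_ in mets:
        blocks[m_] = np.arange(start, start + n_snp_m)
        start += n_snp_m
    bg = np.arange(start, n_total)

    gamma = {p: np.zeros(n_total) for p in phenos}
    for p in phenos:
        gamma[p][blocks[p]] = _scaled_effects(n_snp_x, maf[blocks[p]], r2_x, rng)
    delta = {m_: np.zeros(n_total) for m_ in mets}
    for m_ in mets:
        delta[m_][blocks[m_]] = _scaled_effects(n_snp_m, maf[blocks[m_]], r2_m, rng)

    beta_met = {}
    for m_ in mets:
        b = delta[m_].copy()
        for p in phenos:
            b += truth.theta_xm.get((p, m_), 0.0) * gamma[p]
        beta_met[m_] = b
    beta_out = np.zeros(n_total)
    for p in phenos:
        beta_out += truth.theta_direct.get(p, 0.0) * gamma[p]
    for m_ in mets:
        beta_out += truth.theta_my.get(m_, 0.0) * beta_met[m_]

    # LD-scored polygenic background driving the genetic-correlation screen;
    # per-allele true effect sqrt(h2 l_j/M) g_j / sqrt(2 maf (1-maf)) gives
    # E[chi2] = 1 + N h2 l_j/M under the observation model, independent of N
    ld = 1.0 + rng.exponential(9.0, m_background)
    ld_x = ld / m_background
    het_bg = 2.0 * maf[bg] * (1.0 - maf[bg])
    g_out = rng.standard_normal(m_background)
    bg_true = {}
    bg_true["outcome"] = np.sqrt(h2_background * ld_x / het_bg) * g_out
    for p in phenos:
        r = truth.rg_outcome.get(p, 0.0)
        gp = r * g_out + np.sqrt(1 - r ** 2) * rng.standard_normal(m_background)
        bg_true[p] = np.sqrt(h2_background * ld_x / het_bg) * gp

    def make_ss(true_beta, n, trait_id, trait_type="quantitative", rng_=None):
        b, s, pv = _observe(true_beta, maf, n, rng_ or rng)
        return build_summary_stats(_table(panel, b, s, pv, n), trait_id,
                                   trait_type=trait_type)

    tables = {"phenotypes": {}, "metabolites": {}}
    for p in phenos:
        true = gamma[p].copy()
        true[bg] += bg_true[p]
        tables["phenotypes"][p] = make_ss(true, sizes["exposure"], p)
    for m_ in mets:
        tables["metabolites"][m_] = make_ss(beta_met[m_], sizes["mediator"], m_)
    true_out = beta_out.copy()
    true_out[bg] += bg_true["outcome"]
    tables["outcome"] = make_ss(true_out, sizes["outcome"], "CRC",
                                trait_type="binary")
    tables["outcome_validation"] = make_ss(true_out, n_validation,
                                           "CRC_validation", trait_type="binary")
    tables["ld"] = LDScoreTable(
        pd.DataFrame({"rsid": panel["rsid"].iloc[bg].to_numpy(),
                      "ldscore": ld}), m_total=m_background)
    tables["truth"] = truth
    return tables
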