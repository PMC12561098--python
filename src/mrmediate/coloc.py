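"""Bayesian colocalization of two traits over a genomic window.

Per-SNP evidence uses Wakefield's approximate Bayes factor; the five
mutually exclusive hypotheses are

* H0 - no association with either trait in the region,
* H1/H2 - association with trait 1 / trait 2 only,
* H3 - both traits associated, distinct causal variants,
* H4 - both traits associated, one shared causal variant.

All sums are accumulated in log space.  Assumes at most one causal variant
per trait in the window (no LD-aware multi-signal decomposition).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .exceptions import InputError
from .summary_stats import SummaryStats

#: default half-width (bp) of the colocalization window: 500 kb total.
DEFAULT_HALF_WIDTH = 250_000

#: default prior effect scales sqrt(W): quantitative / binary (log-odds)
DEFAULT_PRIOR_SD = {"quantitative": 0.15, "binary": 0.2}

DEFAULT_PRIORS = (1e-4, 1e-4, 1e-5)  # p1, p2, p12


@dataclass
class RegionStats:
    """Per-variant association statistics for one trait in one window."""

    trait_id: str
    chrom: str
    center_pos: int
    half_width: int
    table: pd.DataFrame  # rsid, effect_allele, other_allele, beta, se, n, eaf
    trait_type: str = "quantitative"

    def __post_init__(self):
        if len(self.table) == 0:
            raise InputError(f"empty region for {self.trait_id!r}")
        if (self.table["se"] <= 0).any():
            raise InputError("all se must be > 0")

    @classmethod
    def from_summary_stats(cls, ss: SummaryStats, chrom: str, center_pos: int,
                           half_width: int = DEFAULT_HALF_WIDTH) -> "RegionStats":
        sub = ss.region(chrom, center_pos - half_width, center_pos + half_width)
        return cls(ss.trait_id, str(chrom), center_pos, half_width,
                   sub.table, ss.trait_type)


@dataclass
class ColocResult:
    """Posterior over the five colocalization hypotheses."""

    pph0: float
    pph1: float
    pph2: float
    pph3: float
    pph4: float
    n_snps_shared: int
    top_shared_snp: str
    priors: tuple[float, float, float]
    single_snp: bool = False
    per_snp: pd.DataFrame | None = None

    @property
    def posterior(self) -> np.ndarray:
        return np.array([self.pph0, self.pph1, self.pph2, self.pph3, self.pph4])

    def tier(self, colocalized: float = 0.8, suggestive: float = 0.5) -> str:
        if self.pph4 >= colocalized:
            return "colocalized"
        if self.pph4 >= suggestive:
            return "suggestive"
        return "none"

    def to_dict(self) -> dict:
        return {"pph0": self.pph0, "pph1": self.pph1, "pph2": self.pph2,
                "pph3": self.pph3, "pph4": self.pph4,
                "n_snps_shared": self.n_snps_shared,
                "top_shared_snp": self.top_shared_snp,
                "priors": list(self.priors), "single_snp": self.single_snp}


def wakefield_abf(beta, se, prior_sd: float) -> np.ndarray:
    """Log approximate Bayes factor for association vs. the null.

    log ABF = 1/2 [ ln(se^2/(se^2+W)) + z^2 W/(se^2+W) ] with W = prior_sd^2.
    Positive when the data favour association.
    """
    beta = np.asarray(beta, float)
    se = np.asarray(se, float)
    if np.any(se <= 0):
        raise InputError("se must be > 0")
    if prior_sd <= 0:
        raise InputError("prior_sd must be > 0")
    w = prior_sd ** 2
    z2 = (beta / se) ** 2
    r = w / (se ** 2 + w)
    return 0.5 * (np.log(1 - r) + z2 * r)


def _intersect(r1: RegionStats, r2: RegionStats):
    t1 = r1.table.set_index("rsid")
    t2 = r2.table.set_index("rsid")
    shared = t1.index.intersection(t2.index)
    keep = []
    for rsid in shared:
        a1 = frozenset((t1.at[rsid, "effect_allele"], t1.at[rsid, "other_allele"]))
        a2 = frozenset((t2.at[rsid, "effect_allele"], t2.at[rsid, "other_allele"]))
        if a1 == a2:
            keep.append(rsid)
    if not keep:
        raise InputError(
            f"no shared variants between {r1.trait_id!r} and {r2.trait_id!r}")
    return t1.loc[keep], t2.loc[keep], keep


def coloc_abf(r1: RegionStats, r2: RegionStats, *,
              priors: tuple[float, float, float] = DEFAULT_PRIORS,
              prior_sd1: float | None = None,
              prior_sd2: float | None = None) -> ColocResult:
    """Five-hypothesis colocalization posterior from per-SNP ABFs.

    Unnormalized hypothesis weights (Q shared SNPs): H0 ~ 1;
    H1 ~ p1 sum_i BF1_i; H2 ~ p2 sum_j BF2_j;
    H3 ~ p1 p2 sum_{i != j} BF1_i BF2_j; H4 ~ p12 sum_i BF1_i BF2_i.
    Colocalization is only testable on variants present in both traits;
    with a single shared variant H3 is structurally empty and flagged.
    """
    p1, p2, p12 = priors
    if min(p1, p2, p12) <= 0 or p12 > min(p1, p2):
        raise InputError("require positive priors with p12 <= min(p1, p2)")
    sd1 = prior_sd1 or DEFAULT_PRIOR_SD[r1.trait_type]
    sd2 = prior_sd2 or DEFAULT_PRIOR_SD[r2.trait_type]
    t1, t2, rsids = _intersect(r1, r2)
    lbf1 = wakefield_abf(t1["beta"].to_numpy(), t1["se"].to_numpy(), sd1)
    lbf2 = wakefield_abf(t2["beta"].to_numpy(), t2["se"].to_numpy(), sd2)
    q = len(rsids)
    ls1, ls2 = logsumexp(lbf1), logsumexp(lbf2)
    l_joint = lbf1 + lbf2
    ls4 = logsumexp(l_joint)
    lh = np.empty(5)
    lh[0] = 0.0
    lh[1] = np.log(p1) + ls1
    lh[2] = np.log(p2) + ls2
    if q > 1:
        # sum_{i != j} BF1_i BF2_j = (sum BF1)(sum BF2) - sum BF1_i BF2_i
        lcross = ls1 + ls2
        # stable log(exp(a) - exp(b)), a >= b
        with np.errstate(divide="ignore"):
            lh[3] = np.log(p1) + np.log(p2) + lcross + np.log1p(
                -np.exp(min(ls4 - lcross, 0.0)))
        if not np.isfinite(lh[3]):
            lh[3] = -np.inf
    else:
        lh[3] = -np.inf
    lh[4] = np.log(p12) + ls4
    post = np.exp(lh - logsumexp(lh))
    post /= post.sum()
    contrib = l_joint - logsumexp(l_joint)
    top = rsids[int(np.argmax(contrib))]
    per_snp = pd.DataFrame({"rsid": rsids, "log_abf_trait1": lbf1,
                            "log_abf_trait2": lbf2,
                            "h4_contribution": np.exp(contrib)})
    return ColocResult(*map(float, post), n_snps_shared=q, top_shared_snp=top,
                       priors=(p1, p2, p12), single_snp=(q == 1),
                       per_snp=per_snp)
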