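"""Two-step MR mediation: effect decomposition and decision logic.

The causal triangle is exposure -> mediator -> outcome with

* beta1: exposure -> mediator effect (step 1),
* beta2: mediator -> outcome effect with the step-1 instruments excluded
  (step 2),
* beta3: total exposure -> outcome effect.

The indirect effect is the coefficient product beta1*beta2 and the mediation
proportion is beta1*beta2/beta3; asymptotic standard errors come from the
delta method with the three coefficients treated as independent (separate
GWAS samples; covariance terms set to zero).  The module also carries the
screening/bookkeeping logic around the triangles: BH-FDR + dual-method
step-1 screen, shared-mediator grouping, reverse-causality exclusion and
evidence tiering.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .estimators import Z95
from .exceptions import InputError, InsufficientInstrumentsError
from .summary_stats import InstrumentSet

import logging

logger = logging.getLogger(__name__)


@dataclass
class MediationResult:
    """The (beta1, beta2, beta3) triangle with delta-method inference."""

    exposure_id: str
    mediator_id: str
    outcome_id: str
    beta1: float
    se1: float
    beta2: float
    se2: float
    beta3: float
    se3: float
    indirect: float = field(init=False)
    indirect_se: float = field(init=False)
    indirect_ci: tuple[float, float] = field(init=False)
    indirect_p: float = field(init=False)
    proportion: float | None = field(init=False)
    proportion_se: float | None = field(init=False)
    proportion_ci: tuple[float, float] | None = field(init=False)
    significant: bool = field(init=False)
    proportion_defined: bool = field(init=False)
    inconsistent: bool = field(init=False)
    se3_in_proportion_se: bool = True

    def __post_init__(self):
        if min(self.se1, self.se2, self.se3) <= 0:
            raise InputError("all standard errors must be > 0")
        b1, b2, b3 = self.beta1, self.beta2, self.beta3
        s1, s2, s3 = self.se1, self.se2, self.se3
        self.indirect = b1 * b2
        self.indirect_se = float(np.sqrt(b1 ** 2 * s2 ** 2 + b2 ** 2 * s1 ** 2))
        lo = self.indirect - Z95 * self.indirect_se
        hi = self.indirect + Z95 * self.indirect_se
        self.indirect_ci = (lo, hi)
        if self.indirect_se > 0:
            self.indirect_p = float(2 * stats.norm.sf(abs(self.indirect) / self.indirect_se))
        else:
            self.indirect_p = 1.0 if self.indirect == 0 else 0.0
        self.significant = not (lo <= 0 <= hi)
        self.proportion_defined = b3 != 0
        if self.proportion_defined:
            p = self.indirect / b3
            self.proportion = p
            var = (b2 / b3) ** 2 * s1 ** 2 + (b1 / b3) ** 2 * s2 ** 2
            if self.se3_in_proportion_se:
                var += (b1 * b2 / b3 ** 2) ** 2 * s3 ** 2
            self.proportion_se = float(np.sqrt(var))
            self.proportion_ci = (p - Z95 * self.proportion_se,
                                  p + Z95 * self.proportion_se)
            self.inconsistent = abs(p) > 1
        else:
            self.proportion = None
            self.proportion_se = None
            self.proportion_ci = None
            self.inconsistent = False

    @property
    def proportion_pct(self) -> float | None:
        """Mediation proportion as a percentage, rounded to 3 decimals."""
        if self.proportion is None:
            return None
        return round(100.0 * self.proportion, 3)

    def to_dict(self) -> dict:
        return {
            "exposure": self.exposure_id, "mediator": self.mediator_id,
            "outcome": self.outcome_id,
            "beta1": self.beta1, "se1": self.se1,
            "beta2": self.beta2, "se2": self.se2,
            "beta3": self.beta3, "se3": self.se3,
            "indirect": self.indirect, "indirect_se": self.indirect_se,
            "indirect_ci_low": self.indirect_ci[0],
            "indirect_ci_high": self.indirect_ci[1],
            "indirect_p": self.indirect_p,
            "proportion": self.proportion,
            "proportion_pct": self.proportion_pct,
            "proportion_se": self.proportion_se,
            "significant": self.significant,
            "inconsistent": self.inconsistent,
        }


def mediate(beta1, se1, beta2, se2, beta3, se3, *,
            exposure_id: str = "exposure", mediator_id: str = "mediator",
            outcome_id: str = "outcome",
            se3_in_proportion_se: bool = True) -> MediationResult:
    """Coefficient-product mediation with delta-method intervals.

    indirect = beta1*beta2 with
    se = sqrt(beta1^2 se2^2 + beta2^2 se1^2); proportion = indirect/beta3
    with the full three-term delta-method variance by default
    (``se3_in_proportion_se=False`` drops the total-effect term).  A zero
    beta3 leaves the proportion undefined; |proportion| > 1 is returned but
    flagged as inconsistent mediation.
    """
    return MediationResult(exposure_id, mediator_id, outcome_id,
                           float(beta1), float(se1), float(beta2), float(se2),
                           float(beta3), float(se3),
                           se3_in_proportion_se=se3_in_proportion_se)


def exclude_step1_instruments(step1_iv: InstrumentSet,
                              step2_iv: InstrumentSet) -> InstrumentSet:
    """Remove step-1 instruments from the step-2 set (by rsid)."""
    if step1_iv.n_instruments == 0 or step2_iv.n_instruments == 0:
        raise InputError("both instrument sets must be nonempty")
    overlap = sorted(set(step2_iv.rsids) & set(step1_iv.rsids))
    keep = ~step2_iv.table["rsid"].isin(overlap)
    if not keep.any():
        raise InsufficientInstrumentsError(
            f"all step-2 instruments of {step2_iv.exposure_id!r} overlap step 1: "
            f"{overlap}")
    if overlap:
        logger.info("step-2 %s: removed %d step-1 instruments: %s",
                    step2_iv.exposure_id, len(overlap), overlap)
    table = step2_iv.table.loc[keep].reset_index(drop=True)
    from .summary_stats import variance_explained
    r2_total = float(np.nansum(variance_explained(table["beta"], table["eaf"])))
    return replace(step2_iv, table=table, r2_total=r2_total)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values, in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise InputError("p-values must be in (0,1]")
    return multipletests(p, method="fdr_bh")[1]


def screen_step1(results: pd.DataFrame, *, fdr_q: float = 0.05) -> pd.DataFrame:
    """Dual-method FDR screen of step-1 (phenotype -> metabolite) results.

    ``results`` needs columns mediator, primary_beta, primary_p, bwmr_beta,
    bwmr_p; the FDR family is all mediators tested for this phenotype.  A
    mediator passes when both adjusted p-values are below ``fdr_q`` and the
    two effect signs agree; discordant signs are excluded and logged.
    """
    req = {"mediator", "primary_beta", "primary_p", "bwmr_beta", "bwmr_p"}
    if not req <= set(results.columns):
        raise InputError(f"screen_step1 needs columns {sorted(req)}")
    out = results.copy()
    out["q_primary"] = bh_fdr(out["primary_p"])
    out["q_bwmr"] = bh_fdr(out["bwmr_p"])
    concordant = np.sign(out["primary_beta"]) == np.sign(out["bwmr_beta"])
    out["pass"] = (out["q_primary"] < fdr_q) & (out["q_bwmr"] < fdr_q) & concordant
    disc = (out["q_primary"] < fdr_q) & (out["q_bwmr"] < fdr_q) & ~concordant
    if disc.any():
        logger.info("screen_step1: %d mediators excluded for sign discordance: %s",
                    int(disc.sum()), list(out.loc[disc, "mediator"]))
    return out


def shared_mediators(significant_sets: dict[str, set], *, min_phenotypes: int = 2,
                     exclude_only: frozenset | set = frozenset({"BMI", "WC"})
                     ) -> dict[frozenset, list]:
    """Group mediators by the exact phenotype combination they associate with.

    Keeps mediators significant for at least ``min_phenotypes`` phenotypes,
    excluding those whose association set is exactly ``exclude_only`` (the
    obesity-only pair in the reference analysis).  Returns
    {phenotype combination (frozenset): sorted mediator list}.
    """
    if len(significant_sets) < 2:
        raise InputError("need significant sets for >= 2 phenotypes")
    exclude_only = frozenset(exclude_only)
    membership: dict = {}
    for pheno, mets in significant_sets.items():
        for met in mets:
            membership.setdefault(met, set()).add(pheno)
    groups: dict[frozenset, list] = {}
    for met, phenos in membership.items():
        combo = frozenset(phenos)
        if len(combo) < min_phenotypes:
            continue
        if combo == exclude_only:
            continue
        groups.setdefault(combo, []).append(met)
    return {combo: sorted(mets) for combo, mets in groups.items()}


COLOC_TIERS = ("colocalized", "suggestive", "none")
EVIDENCE_TIERS = ("two_star", "one_star", "none")


@dataclass
class TriangleRecord:
    """A mediation triangle with its screening flags and evidence tier."""

    mediation: MediationResult
    forward_fdr_pass: bool = True
    bwmr_concordant: bool = True
    reverse_excluded: bool = False
    coloc_tier: str = "none"
    validated_external: bool = False
    evidence_tier: str = "none"

    def to_dict(self) -> dict:
        d = self.mediation.to_dict()
        d.update(forward_fdr_pass=self.forward_fdr_pass,
                 bwmr_concordant=self.bwmr_concordant,
                 reverse_excluded=self.reverse_excluded,
                 coloc_tier=self.coloc_tier,
                 validated_external=self.validated_external,
                 evidence_tier=self.evidence_tier)
        return d


def reverse_mr_filter(tr: TriangleRecord, reverse_results: dict, *,
                      alpha: float = 0.05) -> TriangleRecord:
    """Exclude a triangle when the mediator shows reverse causality.

    ``reverse_results`` maps reverse-direction labels (e.g.
    ``mediator_to_exposure``, ``outcome_to_mediator``) to p-values from the
    same estimator stack run in the reverse direction.  A significant
    reverse effect marks the triangle excluded; the exclusion is per
    phenotype-mediator pair, never global for the mediator.
    """
    reverse_sig = any(p is not None and p < alpha for p in reverse_results.values())
    tr.reverse_excluded = bool(reverse_sig)
    return tr


def assign_evidence_tier(tr: TriangleRecord) -> TriangleRecord:
    """Two stars = colocalization pass AND external validation; one star =
    exactly one of the two; none otherwise."""
    if tr.coloc_tier not in COLOC_TIERS:
        raise InputError(f"unknown coloc tier {tr.coloc_tier!r}")
    coloc_pass = tr.coloc_tier != "none"
    validated = bool(tr.validated_external)
    if coloc_pass and validated:
        tr.evidence_tier = "two_star"
    elif coloc_pass or validated:
        tr.evidence_tier = "one_star"
    else:
        tr.evidence_tier = "none"
    return tr
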