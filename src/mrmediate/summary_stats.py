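"""GWAS summary-statistics containers, instrument selection and harmonization.

The unit of data throughout the package is a per-variant association table
(one GWAS trait), carried as a :class:`SummaryStats` wrapping a validated
pandas DataFrame.  Instrument selection applies a p-value threshold followed
by greedy LD clumping; harmonization places exposure and outcome effects on a
common effect allele, resolving strand for palindromic variants from allele
frequencies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import FormatError, InputError, InsufficientInstrumentsError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")
PALINDROMIC_PAIRS = (frozenset("AT"), frozenset("CG"))

#: Column names of the default (GWAS-SSF-style) input dialect.
DEFAULT_DIALECT: dict[str, str] = {
    "rsid": "rsid",
    "chrom": "chromosome",
    "pos": "base_pair_location",
    "effect_allele": "effect_allele",
    "other_allele": "other_allele",
    "eaf": "effect_allele_frequency",
    "beta": "beta",
    "se": "standard_error",
    "pval": "p_value",
    "n": "n",
}

MANDATORY_FIELDS = ("rsid", "effect_allele", "other_allele", "beta", "se", "pval")

CANONICAL_COLUMNS = [
    "rsid", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]


@dataclass
class SummaryStats:
    """Per-variant GWAS association table for a single trait.

    Parameters
    ----------
    trait_id
        Free-text trait label.
    table
        DataFrame with the canonical columns (``rsid``, ``chrom``, ``pos``,
        ``effect_allele``, ``other_allele``, ``eaf``, ``beta``, ``se``,
        ``pval``, ``n``).  For binary traits ``beta`` is on the log-odds
        scale.
    trait_type
        ``"quantitative"`` or ``"binary"``.
    sample_size_default
        Used where per-row ``n`` is missing.
    """

    trait_id: str
    table: pd.DataFrame
    trait_type: str = "quantitative"
    sample_size_default: int | None = None
    n_dropped: int = 0
    extra: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.trait_type not in ("quantitative", "binary"):
            raise InputError(f"unknown trait_type {self.trait_type!r}")
        if len(self.table) == 0:
            raise InputError(f"empty summary-statistics table for {self.trait_id!r}")

    @property
    def n_variants(self) -> int:
        return len(self.table)

    def effective_n(self) -> pd.Series:
        n = self.table["n"]
        if self.sample_size_default is not None:
            n = n.fillna(self.sample_size_default)
        return n

    def subset(self, mask) -> "SummaryStats":
        return SummaryStats(self.trait_id, self.table.loc[mask].reset_index(drop=True),
                            self.trait_type, self.sample_size_default)

    def region(self, chrom: str, start: int, end: int) -> "SummaryStats":
        """Variants inside the closed interval [start, end] on ``chrom``."""
        t = self.table
        mask = (t["chrom"].astype(str) == str(chrom)) & (t["pos"] >= start) & (t["pos"] <= end)
        if not mask.any():
            raise InputError(f"no variants of {self.trait_id!r} in {chrom}:{start}-{end}")
        return self.subset(mask)


def _validate_table(df: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Drop rows violating the container invariants; return (clean, n_dropped)."""
    n0 = len(df)
    ea = df["effect_allele"].astype(str).str.upper()
    oa = df["other_allele"].astype(str).str.upper()
    df = df.assign(effect_allele=ea, other_allele=oa)
    ok = (
        df["se"].gt(0)
        & np.isfinite(df["beta"])
        & np.isfinite(df["se"])
        & df["pval"].gt(0) & df["pval"].le(1)
        & ea.isin(VALID_ALLELES) & oa.isin(VALID_ALLELES)
        & (ea != oa)
    )
    eaf_bad = df["eaf"].notna() & ~(df["eaf"].gt(0) & df["eaf"].lt(1))
    ok &= ~eaf_bad
    df = df.loc[ok]
    df = df.drop_duplicates(subset="rsid", keep="first")
    return df.reset_index(drop=True), n0 - len(df)


def build_summary_stats(df: pd.DataFrame, trait_id: str, *,
                        trait_type: str = "quantitative",
                        sample_size_default: int | None = None) -> SummaryStats:
    """Validate an in-memory canonical table into a SummaryStats."""
    for col in CANONICAL_COLUMNS:
        if col not in df.columns:
            df = df.assign(**{col: np.nan})
    clean, n_dropped = _validate_table(df[CANONICAL_COLUMNS].copy())
    if len(clean) == 0:
        raise InputError(f"no valid rows for trait {trait_id!r}")
    if n_dropped:
        logger.info("trait %s: dropped %d invalid rows", trait_id, n_dropped)
    return SummaryStats(trait_id, clean, trait_type, sample_size_default,
                        n_dropped=n_dropped)


def read_summary_stats(path, trait_id: str | None = None, *,
                       dialect: dict[str, str] | None = None,
                       trait_type: str = "quantitative",
                       sample_size_default: int | None = None,
                       effect_is_or: bool = False,
                       sep: str | None = None) -> SummaryStats:
    """Read a delimited summary-statistics file.

    ``dialect`` maps canonical field names to file column names; unmapped
    fields fall back to the GWAS-SSF defaults.  With ``effect_is_or`` the
    effect column holds odds ratios and is natural-log transformed to the
    log-odds scale.  Unknown columns are preserved in ``extra``.
    """
    colmap = dict(DEFAULT_DIALECT)
    if dialect:
        colmap.update(dialect)
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    for fieldname in MANDATORY_FIELDS:
        if colmap[fieldname] not in df.columns:
            raise FormatError(
                f"missing mandatory column {colmap[fieldname]!r} (field {fieldname})")
    if len(df) == 0:
        raise InputError(f"empty table: {path}")
    out = pd.DataFrame()
    used = set()
    for fieldname, col in colmap.items():
        if col in df.columns:
            out[fieldname] = df[col]
            used.add(col)
        else:
            out[fieldname] = np.nan
    extra_cols = [c for c in df.columns if c not in used]
    if effect_is_or:
        if (out["beta"] <= 0).any():
            raise FormatError("odds-ratio column contains non-positive values")
        out["beta"] = np.log(out["beta"].astype(float))
    for col in ("beta", "se", "pval", "eaf", "n"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    ss = build_summary_stats(out, trait_id or str(path), trait_type=trait_type,
                             sample_size_default=sample_size_default)
    if extra_cols:
        ss.extra = df[extra_cols]
    return ss


def write_summary_stats(ss: SummaryStats, path, *, dialect: dict[str, str] | None = None):
    """Write the canonical table as TSV under the given (default SSF) dialect."""
    colmap = dict(DEFAULT_DIALECT)
    if dialect:
        colmap.update(dialect)
    out = ss.table.rename(columns=colmap)
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# instrument strength


def f_statistic(beta, se):
    """Single-instrument approximate F statistic, (beta/se)^2."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0):
        raise InputError("se must be > 0")
    return (beta / se) ** 2


def variance_explained(beta, eaf):
    """Variance in a standardized trait explained by one variant.

    r^2 = 2 * eaf * (1 - eaf) * beta^2, assuming the trait has unit variance
    and the effect is per allele copy.  Missing eaf yields NaN (excluded from
    instrument-set totals with a warning upstream).
    """
    beta = np.asarray(beta, dtype=float)
    eaf = np.asarray(eaf, dtype=float)
    return 2.0 * eaf * (1.0 - eaf) * beta ** 2


@dataclass
class InstrumentSet:
    """Selected instruments for one exposure with strength diagnostics."""

    exposure_id: str
    table: pd.DataFrame  # canonical columns + f_stat
    p_threshold: float
    clump_r2: float
    r2_total: float
    trait_type: str = "quantitative"

    @property
    def rsids(self) -> list[str]:
        return list(self.table["rsid"])

    @property
    def n_instruments(self) -> int:
        return len(self.table)


def select_instruments(ss: SummaryStats, *, p_threshold: float = 5e-8,
                       clump_r2: float = 0.001,
                       ld: pd.DataFrame | None = None) -> InstrumentSet:
    """p-value thresholding followed by greedy LD clumping.

    Variants are sorted by ascending p (ties broken by rsid) and retained
    only if r^2 with every previously retained variant is below ``clump_r2``.
    Variants absent from ``ld`` are treated as independent of everything.
    """
    if not 0 < p_threshold < 1:
        raise InputError("p_threshold must be in (0,1)")
    if ld is not None:
        if ld.shape[0] != ld.shape[1] or not np.allclose(np.diag(ld.values), 1.0):
            raise InputError("LD matrix must be square with unit diagonal")
    t = ss.table
    cand = t.loc[t["pval"] <= p_threshold]
    if len(cand) == 0:
        raise InsufficientInstrumentsError(
            f"no variant of {ss.trait_id!r} passes p <= {p_threshold:g}")
    cand = cand.sort_values(["pval", "rsid"], kind="mergesort")
    kept_idx: list = []
    kept_rsids: list[str] = []
    for idx, row in cand.iterrows():
        rsid = row["rsid"]
        independent = True
        if ld is not None and rsid in ld.index:
            for prev in kept_rsids:
                if prev in ld.columns and ld.at[rsid, prev] ** 2 >= clump_r2:
                    independent = False
                    break
        if independent:
            kept_idx.append(idx)
            kept_rsids.append(rsid)
    kept = cand.loc[kept_idx].reset_index(drop=True)
    kept["f_stat"] = f_statistic(kept["beta"], kept["se"])
    r2 = variance_explained(kept["beta"], kept["eaf"])
    if np.isnan(r2).any():
        logger.warning("trait %s: %d instruments lack eaf; excluded from r2_total",
                       ss.trait_id, int(np.isnan(r2).sum()))
    r2_total = float(np.nansum(r2))
    return InstrumentSet(ss.trait_id, kept, p_threshold, clump_r2, r2_total,
                         trait_type=ss.trait_type)


# ---------------------------------------------------------------------------
# harmonization

ACTION_KEPT = "kept"
ACTION_FLIPPED = "flipped"
ACTION_DROP_PAL = "dropped_palindromic"
ACTION_DROP_MIS = "dropped_mismatch"
ACTION_DROP_ABS = "dropped_absent"

HARMONIZED_COLUMNS = [
    "rsid", "beta_exp", "se_exp", "beta_out", "se_out",
    "eaf_exp", "eaf_out", "action",
]


@dataclass
class HarmonizedSet:
    """Exposure/outcome effects on a common effect allele.

    ``table`` carries every instrument with its ``action``; ``retained``
    exposes the rows usable by estimators (kept or flipped).
    """

    exposure_id: str
    outcome_id: str
    table: pd.DataFrame
    outcome_type: str = "quantitative"

    @property
    def retained(self) -> pd.DataFrame:
        return self.table.loc[
            self.table["action"].isin([ACTION_KEPT, ACTION_FLIPPED])
        ].reset_index(drop=True)

    @property
    def n_snp(self) -> int:
        return len(self.retained)

    def arrays(self):
        """(beta_exp, se_exp, beta_out, se_out) as float arrays."""
        r = self.retained
        return (r["beta_exp"].to_numpy(float), r["se_exp"].to_numpy(float),
                r["beta_out"].to_numpy(float), r["se_out"].to_numpy(float))

    def to_tsv(self, path):
        self.table.to_csv(path, sep="\t", index=False)


def _is_palindromic(a1: str, a2: str) -> bool:
    return frozenset((a1, a2)) in PALINDROMIC_PAIRS


def harmonize(exposure_iv: InstrumentSet, outcome: SummaryStats, *,
              palindrome_eaf_window: float = 0.08) -> HarmonizedSet:
    """Align outcome effects to the exposure effect allele.

    Matching allele pairs are kept; reversed pairs have the outcome beta
    sign-flipped and eaf complemented.  Palindromic variants (A/T, C/G) are
    retained only when both allele frequencies are known, both fall outside
    [0.5-w, 0.5+w], and they lie on the same side of 0.5 after alignment;
    otherwise strand is ambiguous and the variant is dropped.  All exclusions
    are recorded in the ``action`` column, never silent.
    """
    out_idx = outcome.table.set_index("rsid")
    rows = []
    n_absent = 0
    for _, iv in exposure_iv.table.iterrows():
        rsid = iv["rsid"]
        rec = {"rsid": rsid, "beta_exp": iv["beta"], "se_exp": iv["se"],
               "eaf_exp": iv["eaf"], "beta_out": np.nan, "se_out": np.nan,
               "eaf_out": np.nan}
        if rsid not in out_idx.index:
            n_absent += 1
            rec["action"] = ACTION_DROP_ABS
            rows.append(rec)
            continue
        o = out_idx.loc[rsid]
        ea_x, oa_x = iv["effect_allele"], iv["other_allele"]
        ea_y, oa_y = o["effect_allele"], o["other_allele"]
        if (ea_y, oa_y) == (ea_x, oa_x):
            beta_y, eaf_y, action = o["beta"], o["eaf"], ACTION_KEPT
        elif (ea_y, oa_y) == (oa_x, ea_x):
            beta_y = -o["beta"]
            eaf_y = 1.0 - o["eaf"] if pd.notna(o["eaf"]) else np.nan
            action = ACTION_FLIPPED
        else:
            rec["action"] = ACTION_DROP_MIS
            rows.append(rec)
            continue
        if _is_palindromic(ea_x, oa_x):
            w = palindrome_eaf_window
            fx, fy = iv["eaf"], eaf_y
            unambiguous = (
                pd.notna(fx) and pd.notna(fy)
                and abs(fx - 0.5) > w and abs(fy - 0.5) > w
                and (fx - 0.5) * (fy - 0.5) > 0
            )
            if not unambiguous:
                rec["action"] = ACTION_DROP_PAL
                rows.append(rec)
                continue
        rec.update(beta_out=beta_y, se_out=o["se"], eaf_out=eaf_y, action=action)
        rows.append(rec)
    if n_absent:
        logger.info("harmonize %s vs %s: %d instruments absent from outcome",
                    exposure_iv.exposure_id, outcome.trait_id, n_absent)
    table = pd.DataFrame(rows, columns=HARMONIZED_COLUMNS)
    return HarmonizedSet(exposure_iv.exposure_id, outcome.trait_id, table,
                         outcome_type=outcome.trait_type)


def harmonized_from_arrays(beta_exp, se_exp, beta_out, se_out, *,
                           exposure_id: str = "exposure",
                           outcome_id: str = "outcome",
                           rsids=None,
                           outcome_type: str = "quantitative") -> HarmonizedSet:
    """Build a HarmonizedSet directly from effect arrays (all rows kept)."""
    beta_exp = np.asarray(beta_exp, float)
    n = len(beta_exp)
    if rsids is None:
        rsids = [f"rs{i + 1}" for i in range(n)]
    table = pd.DataFrame({
        "rsid": rsids,
        "beta_exp": beta_exp, "se_exp": np.asarray(se_exp, float),
        "beta_out": np.asarray(beta_out, float), "se_out": np.asarray(se_out, float),
        "eaf_exp": np.nan, "eaf_out": np.nan, "action": ACTION_KEPT,
    })
    return HarmonizedSet(exposure_id, outcome_id, table, outcome_type=outcome_type)
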