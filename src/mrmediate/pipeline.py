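"""Config-driven orchestration of the discovery -> validation workflow.

Stage order: (1) optional LDSC genetic-correlation screen with a Bonferroni
gate on the phenotype family; (2) phenotype -> outcome total-effect MR with
the sensitivity battery and primary-method selection; (3) phenotype ->
metabolite MR with the dual-method FDR screen; (4) shared-mediator grouping;
(5) metabolite -> outcome MR with step-1 instruments excluded; (6) reverse
MR filters (metabolite -> phenotype and outcome -> metabolite); (7)
colocalization per surviving metabolite; (8) optional replication against a
second outcome dataset; (9) the mediation table with evidence tiers.  Every
stage's failures (insufficient instruments for a pair) are recorded, never
fatal; the run log carries the config hash, seeds and package version so a
run is exactly reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .coloc import DEFAULT_PRIORS, RegionStats, coloc_abf
from .estimators import MREstimate, run_all
from .exceptions import InsufficientInstrumentsError, MRMediateError
from .ldsc import LDScoreTable, bonferroni_threshold, ldsc_rg
from .mediation import (TriangleRecord, assign_evidence_tier,
                        exclude_step1_instruments, mediate, reverse_mr_filter,
                        screen_step1, shared_mediators)
from .sensitivity import SensitivityReport, sensitivity_report
from .summary_stats import (HarmonizedSet, InstrumentSet, SummaryStats,
                            harmonize, read_summary_stats, select_instruments)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Thresholds, seeds and stage toggles for one pipeline run."""

    p_threshold: float = 5e-8
    p_threshold_mediator: float = 5e-8
    clump_r2: float = 0.001
    palindrome_eaf_window: float = 0.08
    alpha: float = 0.05
    fdr_q: float = 0.05
    coloc_priors: tuple[float, float, float] = DEFAULT_PRIORS
    coloc_half_width: int = 250_000
    presso_n_sim: int = 1000
    n_boot: int = 1000
    seed: int = 0
    ldsc_screen: bool = True
    ldsc_n_blocks: int = 100
    run_coloc: bool = True
    run_validation: bool = True
    methods: tuple[str, ...] = ("ivw_mre", "egger", "weighted_median", "bwmr")
    min_phenotypes_shared: int = 2
    exclude_only: tuple[str, ...] = ("BMI", "WC")

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class TraitRegistry:
    """In-memory GWAS tables for one study."""

    phenotypes: dict[str, SummaryStats]
    metabolites: dict[str, SummaryStats]
    outcome: SummaryStats
    outcome_validation: SummaryStats | None = None
    ld_scores: LDScoreTable | None = None

    @classmethod
    def from_paths(cls, spec: dict) -> "TraitRegistry":
        """Build a registry from a config mapping of trait -> file entries.

        ``spec`` mirrors the YAML layout: ``phenotypes`` and ``metabolites``
        map names to {path, dialect?, trait_type?, n?}; ``outcome`` (and
        optional ``outcome_validation``) are single entries; ``ld_scores``
        is {path, m_total?}.
        """

        def load(name, entry):
            return read_summary_stats(
                entry["path"], trait_id=name,
                dialect=entry.get("dialect"),
                trait_type=entry.get("trait_type", "quantitative"),
                sample_size_default=entry.get("n"))

        phen = {k: load(k, v) for k, v in spec.get("phenotypes", {}).items()}
        mets = {k: load(k, v) for k, v in spec.get("metabolites", {}).items()}
        outcome = load("outcome", spec["outcome"])
        validation = None
        if "outcome_validation" in spec:
            validation = load("outcome_validation", spec["outcome_validation"])
        ld = None
        if "ld_scores" in spec:
            e = spec["ld_scores"]
            ld = LDScoreTable.read(e["path"], m_total=e.get("m_total"))
        return cls(phen, mets, outcome, validation, ld)


def _forest_row(exposure, outcome, est: MREstimate, *, primary=False,
                rationale=None) -> dict:
    row = {"exposure": exposure, "outcome": outcome}
    row.update(est.to_dict())
    row["primary"] = primary
    if rationale:
        row["rationale"] = rationale
    return row


@dataclass
class PairResult:
    """MR battery + diagnostics for one exposure-outcome pair."""

    exposure_id: str
    outcome_id: str
    instruments: InstrumentSet
    harmonized: HarmonizedSet
    estimates: dict[str, MREstimate]
    sensitivity: SensitivityReport | None = None

    @property
    def primary(self) -> MREstimate:
        method = self.sensitivity.chosen_method if self.sensitivity else "ivw_mre"
        return self.estimates[method]


def run_pair(exposure: SummaryStats, outcome: SummaryStats,
             config: PipelineConfig, *, p_threshold: float | None = None,
             exclude_rsids: set | None = None, with_sensitivity: bool = True,
             methods: tuple[str, ...] | None = None) -> PairResult:
    """Instrument selection, harmonization and the estimator battery."""
    iv = select_instruments(exposure,
                            p_threshold=p_threshold or config.p_threshold,
                            clump_r2=config.clump_r2)
    if exclude_rsids:
        step1 = InstrumentSet(exposure.trait_id,
                              iv.table.loc[iv.table["rsid"].isin(exclude_rsids)],
                              iv.p_threshold, iv.clump_r2, 0.0)
        if step1.n_instruments:
            iv = exclude_step1_instruments(step1, iv)
    hs = harmonize(iv, outcome,
                   palindrome_eaf_window=config.palindrome_eaf_window)
    if hs.n_snp < 3:
        raise InsufficientInstrumentsError(
            f"{exposure.trait_id} vs {outcome.trait_id}: "
            f"{hs.n_snp} instruments after harmonization")
    methods = methods or config.methods
    estimates = run_all(hs, seed=config.seed, methods=methods)
    sens = None
    if with_sensitivity:
        sens = sensitivity_report(hs, n_sim=config.presso_n_sim,
                                  seed=config.seed, alpha=config.alpha)
        if sens.chosen_method not in estimates:
            from .estimators import ESTIMATORS
            estimates[sens.chosen_method] = ESTIMATORS[sens.chosen_method](
                hs, seed=config.seed)
    return PairResult(exposure.trait_id, outcome.trait_id, iv, hs, estimates, sens)


def run_triangle(exposure: SummaryStats, mediator: SummaryStats,
                 outcome: SummaryStats, config: PipelineConfig, *,
                 methods: tuple[str, ...] = ("ivw_mre",),
                 with_sensitivity: bool = False):
    """The two-step decomposition for a single triangle.

    beta1 from exposure -> mediator, beta3 from exposure -> outcome, beta2
    from mediator -> outcome with the step-1 (exposure) instruments removed
    from the mediator instrument set.  Returns (MediationResult, parts).
    """
    step1 = run_pair(exposure, mediator, config, methods=methods,
                     with_sensitivity=with_sensitivity)
    total = run_pair(exposure, outcome, config, methods=methods,
                     with_sensitivity=with_sensitivity)
    step2 = run_pair(mediator, outcome, config,
                     p_threshold=config.p_threshold_mediator,
                     exclude_rsids=set(step1.instruments.rsids),
                     methods=methods, with_sensitivity=with_sensitivity)
    b1 = step1.primary if with_sensitivity else step1.estimates[methods[0]]
    b2 = step2.primary if with_sensitivity else step2.estimates[methods[0]]
    b3 = total.primary if with_sensitivity else total.estimates[methods[0]]
    med = mediate(b1.beta, b1.se, b2.beta, b2.se, b3.beta, b3.se,
                  exposure_id=exposure.trait_id, mediator_id=mediator.trait_id,
                  outcome_id=outcome.trait_id)
    return med, {"step1": step1, "step2": step2, "total": total}


def _lead_region(mediator: SummaryStats, outcome: SummaryStats,
                 config: PipelineConfig):
    t = mediator.table
    lead = t.loc[t["pval"].idxmin()]
    r1 = RegionStats.from_summary_stats(mediator, lead["chrom"],
                                        int(lead["pos"]),
                                        config.coloc_half_width)
    r2 = RegionStats.from_summary_stats(outcome, lead["chrom"],
                                        int(lead["pos"]),
                                        config.coloc_half_width)
    return coloc_abf(r1, r2, priors=config.coloc_priors)


def run_pipeline(registry: TraitRegistry, config: PipelineConfig | None = None,
                 out_dir: str | Path | None = None) -> dict:
    """Execute the full two-step mediation workflow on a trait registry.

    Returns a report bundle: forest_table and mediation_table DataFrames,
    ldsc/coloc result dicts, the step-1 screen tables, the shared-mediator
    groups, per-stage failures, and a run log.  With ``out_dir`` the bundle
    is also written as TSV/JSON files.
    """
    config = config or PipelineConfig()
    failures: list[dict] = []
    report: dict = {"failures": failures}

    # (1) LDSC screen
    phenotypes = dict(registry.phenotypes)
    ldsc_results = {}
    if config.ldsc_screen and registry.ld_scores is not None:
        thr = bonferroni_threshold(config.alpha, len(phenotypes))
        keep = {}
        for name, ss in phenotypes.items():
            try:
                res = ldsc_rg(ss, registry.outcome, registry.ld_scores,
                              n_blocks=config.ldsc_n_blocks)
            except MRMediateError as exc:
                failures.append({"stage": "ldsc", "trait": name, "error": str(exc)})
                continue
            ldsc_results[name] = res.to_dict()
            ldsc_results[name]["bonferroni_threshold"] = thr
            passed = res.rg_p is not None and res.rg_p < thr
            ldsc_results[name]["screen_pass"] = bool(passed)
            if passed:
                keep[name] = ss
        phenotypes = keep
        report["ldsc_skipped"] = False
    else:
        report["ldsc_skipped"] = True
    report["ldsc"] = ldsc_results
    report["phenotypes_after_screen"] = sorted(phenotypes)

    # (2) total-effect MR, phenotype -> outcome
    forest_rows: list[dict] = []
    totals: dict[str, PairResult] = {}
    for name, ss in phenotypes.items():
        try:
            pr = run_pair(ss, registry.outcome, config)
        except MRMediateError as exc:
            failures.append({"stage": "total_mr", "trait": name, "error": str(exc)})
            continue
        totals[name] = pr
        for mname, est in pr.estimates.items():
            forest_rows.append(_forest_row(
                name, registry.outcome.trait_id, est,
                primary=(mname == pr.sensitivity.chosen_method),
                rationale=pr.sensitivity.rationale))

    # (3) phenotype -> metabolite MR with the dual-method FDR screen
    step1_pairs: dict[tuple[str, str], PairResult] = {}
    screen_tables: dict[str, pd.DataFrame] = {}
    significant_sets: dict[str, set] = {}
    for pname, ss in phenotypes.items():
        rows = []
        for mname, mss in registry.metabolites.items():
            try:
                pr = run_pair(ss, mss, config,
                              methods=("ivw_mre", "bwmr"),
                              with_sensitivity=False)
            except MRMediateError as exc:
                failures.append({"stage": "step1_mr", "trait": f"{pname}->{mname}",
                                 "error": str(exc)})
                continue
            step1_pairs[(pname, mname)] = pr
            rows.append({"mediator": mname,
                         "primary_beta": pr.estimates["ivw_mre"].beta,
                         "primary_p": pr.estimates["ivw_mre"].pval,
                         "bwmr_beta": pr.estimates["bwmr"].beta,
                         "bwmr_p": pr.estimates["bwmr"].pval})
        if rows:
            screened = screen_step1(pd.DataFrame(rows), fdr_q=config.fdr_q)
            screen_tables[pname] = screened
            significant_sets[pname] = set(screened.loc[screened["pass"], "mediator"])
    report["step1_screen"] = screen_tables

    # (4) shared mediators
    if len(significant_sets) >= 2:
        groups = shared_mediators(significant_sets,
                                  min_phenotypes=config.min_phenotypes_shared,
                                  exclude_only=frozenset(config.exclude_only))
    else:
        groups = {}
    report["shared_groups"] = {"+".join(sorted(k)): v for k, v in groups.items()}
    shared = sorted({m for mets in groups.values() for m in mets})

    # (5-9) per-triangle: step-2 MR, reverse MR, coloc, validation, mediation
    mediation_rows: list[dict] = []
    coloc_results: dict[str, dict] = {}
    step2_cache: dict[tuple[str, str], PairResult] = {}
    for combo, mets in sorted(groups.items(), key=lambda kv: sorted(kv[0])):
        for mname in mets:
            mss = registry.metabolites[mname]
            for pname in sorted(combo):
                if pname not in totals or (pname, mname) not in step1_pairs:
                    continue
                s1 = step1_pairs[(pname, mname)]
                key = (mname, pname)
                try:
                    s2 = run_pair(mss, registry.outcome, config,
                                  p_threshold=config.p_threshold_mediator,
                                  exclude_rsids=set(s1.instruments.rsids))
                except MRMediateError as exc:
                    failures.append({"stage": "step2_mr",
                                     "trait": f"{mname}->outcome ({pname})",
                                     "error": str(exc)})
                    continue
                step2_cache[key] = s2
                for mmname, est in s2.estimates.items():
                    forest_rows.append(_forest_row(
                        mname, registry.outcome.trait_id, est,
                        primary=(mmname == s2.sensitivity.chosen_method),
                        rationale=s2.sensitivity.rationale))
                b1 = s1.estimates["ivw_mre"]
                b2 = s2.primary
                b3 = totals[pname].primary
                med = mediate(b1.beta, b1.se, b2.beta, b2.se, b3.beta, b3.se,
                              exposure_id=pname, mediator_id=mname,
                              outcome_id=registry.outcome.trait_id)
                tr = TriangleRecord(med)

                # (6) reverse MR: metabolite -> phenotype, outcome -> metabolite
                reverse: dict[str, float | None] = {}
                try:
                    rp = run_pair(mss, registry.phenotypes[pname], config,
                                  p_threshold=config.p_threshold_mediator,
                                  with_sensitivity=False, methods=("ivw_mre",))
                    reverse["mediator_to_exposure"] = rp.estimates["ivw_mre"].pval
                except MRMediateError:
                    reverse["mediator_to_exposure"] = None
                try:
                    ro = run_pair(registry.outcome, mss, config,
                                  with_sensitivity=False, methods=("ivw_mre",))
                    reverse["outcome_to_mediator"] = ro.estimates["ivw_mre"].pval
                except MRMediateError:
                    reverse["outcome_to_mediator"] = None
                tr = reverse_mr_filter(tr, reverse, alpha=config.alpha)

                # (7) colocalization around the metabolite lead variant
                if config.run_coloc:
                    if mname not in coloc_results:
                        try:
                            cres = _lead_region(mss, registry.outcome, config)
                            coloc_results[mname] = cres.to_dict()
                            coloc_results[mname]["tier"] = cres.tier()
                        except MRMediateError as exc:
                            failures.append({"stage": "coloc", "trait": mname,
                                             "error": str(exc)})
                            coloc_results[mname] = {"tier": "none"}
                    tr.coloc_tier = coloc_results[mname]["tier"]

                # (8) replication in the validation outcome
                if config.run_validation and registry.outcome_validation is not None:
                    try:
                        vr = run_pair(mss, registry.outcome_validation, config,
                                      p_threshold=config.p_threshold_mediator,
                                      exclude_rsids=set(s1.instruments.rsids),
                                      with_sensitivity=False,
                                      methods=("ivw_mre",))
                        vest = vr.estimates["ivw_mre"]
                        tr.validated_external = bool(
                            vest.pval < config.alpha
                            and np.sign(vest.beta) == np.sign(b2.beta))
                    except MRMediateError as exc:
                        failures.append({"stage": "validation", "trait": mname,
                                         "error": str(exc)})

                tr = assign_evidence_tier(tr)
                if not tr.reverse_excluded:
                    mediation_rows.append(tr.to_dict())

    report["coloc"] = coloc_results
    report["forest_table"] = pd.DataFrame(forest_rows)
    report["mediation_table"] = pd.DataFrame(mediation_rows)
    report["run_log"] = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.hash(),
        "seed": config.seed,
        "n_phenotypes": len(registry.phenotypes),
        "n_metabolites": len(registry.metabolites),
    }
    if out_dir is not None:
        _write_report(report, Path(out_dir))
    return report


def _jsonable(obj):
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def _write_report(report: dict, out_dir: Path):
    out_dir.mkdir(parents=True, exist_ok=True)
    report["forest_table"].to_csv(out_dir / "forest_table.tsv", sep="\t",
                                  index=False)
    report["mediation_table"].to_csv(out_dir / "mediation_table.tsv", sep="\t",
                                     index=False)
    with open(out_dir / "coloc_results.json", "w") as fh:
        json.dump(_jsonable(report["coloc"]), fh, indent=2)
    with open(out_dir / "ldsc_results.json", "w") as fh:
        json.dump(_jsonable(report["ldsc"]), fh, indent=2)
    log = dict(report["run_log"])
    log["failures"] = report["failures"]
    log["shared_groups"] = report["shared_groups"]
    log["phenotypes_after_screen"] = report["phenotypes_after_screen"]
    log["ldsc_skipped"] = report["ldsc_skipped"]
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(_jsonable(log), fh, indent=2)
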