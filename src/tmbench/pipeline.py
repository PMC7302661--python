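"""Run configuration, orchestration, and file I/O for a benchmarking study.

One config drives the full study: generate (or load) a cohort, fit the
risk model, apply the eligibility cascade, select the template(s), match
every hospital, audit match quality, rank hospitals by template matching
and by regression, and compare the two category assignments.  Every stage
writes a machine-readable artifact into the run directory, and a manifest
records the config hash, seed, and per-stage row counts so identical
config+seed reproduces identical manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .benchmark import (
    categorize,
    category_agreement,
    compare_rankings,
    rank_matched,
    rank_regression,
)
from .cohort import CohortError, CohortTable
from .diagnostics import balance_table, crossmatch_test
from .filters import apply_exclusions
from .matching import MatchSpec, match_all_hospitals
from .risk import fit_risk_model
from .synthetic import GeneratorConfig, generate_system, write_truth
from .template import (
    DEFAULT_N_CANDIDATES,
    DEFAULT_SELECTION_ROSTER,
    DEFAULT_TEMPLATE_SIZE,
    draw_candidates,
    select_template,
    select_tier_templates,
)

log = logging.getLogger("tmbench")

#: the compact high-prognostic-significance matching roster: predicted
#: mortality, age, sex, admission source, 7 major comorbidities, surgical
#: indicator, broad diagnosis category
COMPACT_MATCH_SPEC = dict(
    distance_vars=["predicted_mortality", "age", "ed_admission",
                   "nursing_facility", "cm_chf", "cm_chronic_pulm",
                   "cm_paralysis", "cm_renal_failure", "cm_liver",
                   "cm_mets_cancer", "cm_depression"],
    near_exact=["sex", "surgical"],
    fine_balance=["dx_category"],
)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Settings for :func:`run_pipeline`."""

    cohort_csv: str | None = None          # load a cohort ...
    generator: GeneratorConfig | None = None  # ... or generate one
    template_size: int = DEFAULT_TEMPLATE_SIZE
    n_candidates: int = DEFAULT_N_CANDIDATES
    mode: str = "single_template"          # or "tiered"
    fix_surgical: bool = False             # tiered mode only
    match_specs: dict[str, MatchSpec] = field(default_factory=dict)
    selection_roster: list[str] = field(default_factory=lambda: list(DEFAULT_SELECTION_ROSTER))
    balance_threshold: float = 0.05
    crossmatch_threshold: float = 0.05
    psych_threshold: float = 0.90
    crossmatch_sample: int | None = 75  # per-group cap for the blossom solver
    ratio: int = 3
    seed: int = 0
    output_dir: str = "tmbench_run"

    def __post_init__(self):
        if not self.match_specs:
            self.match_specs = {"compact": MatchSpec(**COMPACT_MATCH_SPEC)}

    def validate(self) -> None:
        if self.template_size < 1 or self.n_candidates < 1:
            raise ConfigError("template_size and n_candidates must be >= 1")
        if self.mode not in ("single_template", "tiered"):
            raise ConfigError(f"unknown mode '{self.mode}'")
        for name in ("balance_threshold", "crossmatch_threshold", "psych_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ConfigError(f"{name} must be in (0, 1)")
        if self.cohort_csv is None and self.generator is None:
            raise ConfigError("provide cohort_csv or a generator block")

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.generator is not None:
            d["generator"] = asdict(self.generator)
        d["match_specs"] = {k: asdict(v) for k, v in self.match_specs.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("generator") is not None:
            g = dict(d["generator"])
            if "volume_range" in g:
                g["volume_range"] = tuple(g["volume_range"])
            d["generator"] = GeneratorConfig(**g)
        if "match_specs" in d:
            d["match_specs"] = {k: MatchSpec(**v) for k, v in d["match_specs"].items()}
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        return cls.from_dict(data)


def load_cohort(path) -> CohortTable:
    """Read a cohort CSV; validates the column dictionary and indicators."""
    table = CohortTable.from_csv(path)
    log.info("loaded cohort: %d rows, %d hospitals", len(table),
             table.df["hospital_id"].nunique())
    return table


def config_hash(config: RunConfig) -> str:
    d = config.to_dict()
    d.pop("output_dir", None)  # run-local path, not part of the study identity
    canon = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full study; returns the run directory."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "version": __version__,
        "stages": {},
    }

    def stage(name):
        log.info("stage: %s", name)
        return manifest["stages"].setdefault(name, {})

    try:
        s = stage("cohort")
        if config.cohort_csv:
            cohort = load_cohort(config.cohort_csv)
            profiles = None
        else:
            cohort, profiles = generate_system(config.generator, config.seed)
            cohort.to_csv(out / "cohort.csv")
            write_truth(profiles, out / "truth.json")
        s["rows"] = len(cohort)
        s["hospitals"] = cohort.df["hospital_id"].nunique()

        s = stage("risk_model")
        model = fit_risk_model(cohort)
        model.to_json(out / "risk_model.json")
        s["c_statistic"] = model.c_statistic
        s["ridge_fallback"] = model.ridge_fallback

        s = stage("exclusions")
        eligible, xlog = apply_exclusions(
            cohort, config.template_size, config.ratio, config.psych_threshold)
        xlog.to_json(out / "exclusions.json")
        (out / "exclusions.txt").write_text(xlog.render() + "\n")
        s["rows"] = len(eligible)
        s["hospitals"] = eligible.df["hospital_id"].nunique()

        s = stage("template")
        if config.mode == "tiered":
            templates = select_tier_templates(
                eligible, config.template_size, config.n_candidates,
                config.selection_roster, config.seed,
                fix_surgical=config.fix_surgical, ratio=config.ratio)
        else:
            cands = draw_candidates(eligible, config.template_size,
                                    config.n_candidates, config.seed)
            templates = {0: select_template(eligible, cands, config.selection_roster)}
        for tier, tpl in templates.items():
            tpl.rows(eligible).to_csv(out / f"template_tier{tier}.csv", index=False)
            meta = {"tier": tier, "distance": tpl.distance,
                    "roster": tpl.roster, "size": tpl.size,
                    "surgical_count": tpl.surgical_count, "seed": config.seed}
            (out / f"template_tier{tier}.json").write_text(json.dumps(meta, indent=1))
        s["n_templates"] = len(templates)
        s["distances"] = {str(t): tpl.distance for t, tpl in templates.items()}

        reports: dict[str, dict] = {}
        matching_reports = {}
        for run_name, spec in config.match_specs.items():
            s = stage(f"match[{run_name}]")
            all_results = {}
            crossmatch = {}
            for tier, tpl in templates.items():
                sub = eligible if config.mode == "single_template" else CohortTable(
                    eligible.df[eligible.df["tier"] == tier],
                    eligible.continuous, eligible.categorical)
                t_rows = tpl.rows(eligible)
                results = match_all_hospitals(sub, t_rows, spec)
                for hid, r in results.items():
                    all_results[hid] = r
                    if r.feasible:
                        crossmatch[hid] = crossmatch_test(
                            t_rows, r.matched_rows, spec.distance_vars,
                            threshold=config.crossmatch_threshold,
                            max_group=config.crossmatch_sample,
                            seed=config.seed)
            pd.DataFrame([r.to_json_dict() for r in all_results.values()]).to_csv(
                out / f"match_{run_name}.csv", index=False)
            s["feasible"] = sum(r.feasible for r in all_results.values())
            s["infeasible"] = sum(not r.feasible for r in all_results.values())
            s["poorly_matched"] = sum(c.poorly_matched for c in crossmatch.values())

            matched_samples = {h: r.matched_rows for h, r in all_results.items()
                               if r.feasible}
            if len(matched_samples) >= 2:
                bal = balance_table(matched_samples, spec.distance_vars
                                    + spec.near_exact + spec.fine_balance,
                                    config.balance_threshold)
                bal.to_csv(out / f"balance_{run_name}.csv")
                s["balanced"] = bal.n_balanced
                s["unbalanced"] = bal.n_unbalanced

                report = rank_matched(all_results)
                if len(report.frame) >= 5:
                    report = categorize(report)
                report.to_csv(out / f"ranks_matched_{run_name}.csv")
                matching_reports[run_name] = report
                reports[run_name] = {
                    "crossmatch_pvalues": {h: c.p_value for h, c in crossmatch.items()},
                }

        s = stage("regression")
        reg = rank_regression(eligible)
        if len(reg.frame) >= 5:
            reg = categorize(reg)
        reg.to_csv(out / "ranks_regression.csv")

        s = stage("comparison")
        comparison = {}
        for run_name, rep in matching_reports.items():
            common = sorted(set(rep.hospitals) & set(reg.hospitals))
            if len(common) < 5:
                continue
            rep_c = subset_report(rep, common)
            reg_c = subset_report(reg, common)
            table, stat, p = compare_rankings(rep_c, reg_c)
            comparison[f"{run_name}_vs_regression"] = {
                "table": table.to_dict(), "chi2": stat, "pvalue": p,
                "agreement": category_agreement(rep_c, reg_c)}
        names = sorted(matching_reports)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a, b = matching_reports[names[i]], matching_reports[names[j]]
                common = sorted(set(a.hospitals) & set(b.hospitals))
                if len(common) < 5:
                    continue
                table, stat, p = compare_rankings(
                    subset_report(a, common), subset_report(b, common))
                comparison[f"{names[i]}_vs_{names[j]}"] = {
                    "table": table.to_dict(), "chi2": stat, "pvalue": p}
        (out / "comparison.json").write_text(json.dumps(comparison, indent=1))
        lines = ["# Performance-category agreement", ""]
        for name, c in comparison.items():
            lines.append(f"## {name}")
            lines.append("")
            lines.append("```")
            lines.append(pd.DataFrame(c["table"]).to_string())
            lines.append("```")
            lines.append("")
            lines.append(f"chi-square {c['chi2']:.3f}, p = {c['pvalue']:.4f}"
                         + (f", agreement {c['agreement']:.2f}"
                            if "agreement" in c else ""))
            lines.append("")
        (out / "comparison.md").write_text("\n".join(lines))
        s["pairs"] = len(comparison)
    except Exception as exc:
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return out


def subset_report(report, hospitals):
    """Restrict a benchmark report to a hospital subset (re-categorized)."""
    from .benchmark import BenchmarkReport, _rank_ascending, categorize

    frame = report.frame.loc[hospitals, ["estimate", "se"]].copy()
    frame["rank"] = _rank_ascending(frame)
    frame["category"] = None
    sub = BenchmarkReport(frame=frame, method=report.method,
                          metadata=dict(report.metadata))
    return categorize(sub) if len(frame) >= 5 else sub
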