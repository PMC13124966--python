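"""Descriptive summaries and the end-to-end pipeline runner.

``summarize_characteristics`` mirrors the usual clinical-characteristics
table of a pharmacovigilance case series: counts and percentages by
sex, age bin, country, reporter category, indication and serious
outcome. Percentages always use the total retained reports as the base
and are rounded half-up to one decimal. Serious-outcome categories are
*not* mutually exclusive — a report may carry several — so the outcome
section can sum past 100%.

``run_pipeline`` ties the stages together: input (synthetic bundle or
FAERS quarters) → cleaning → characteristics → PT/SOC screening →
subgroup screens → co-medication sensitivity screen → time-to-onset
outputs, all written as TSV plus a machine-readable JSON run manifest
(config hash, seed, versions, stage counts). Identical config and seed
produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__ as _pkg_version
from . import io as _io
from .bundle import ReportBundle, concat_bundles
from .contingency import MedDRAMap
from .disprop import DisproportionalityScreen, GPSFitError, SignalCriteria
from .preprocess import (PlausibilityRules, clean_pipeline, combine_reports,
                         load_synonyms, select_unique_ps)
from .strata import DEFAULT_SENSITIVITY_EXCLUSIONS, sensitivity_exclude, stratify
from .synthetic import SyntheticConfig, generate_bundle
from . import tto as _tto

logger = logging.getLogger(__name__)

AGE_TABLE_BINS = (("<18", 0.0, 18.0), ("18-64", 18.0, 65.0),
                  ("65-85", 65.0, 86.0), (">85", 86.0, float("inf")))


def _pct(count: int, total: int) -> float:
    """Percentage of total, rounded half-up to one decimal."""
    if total == 0:
        return float("nan")
    q = (Decimal(count) * 100 / Decimal(total)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP)
    return float(q)


@dataclass
class CharacteristicsSummary:
    """Sectioned counts/percentages over the cleaned case series."""

    total: int
    sections: dict[str, pd.DataFrame] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        frames = [df.assign(section=name) for name, df in self.sections.items()]
        if not frames:
            return pd.DataFrame(columns=["section", "category", "count", "percent"])
        out = pd.concat(frames, ignore_index=True)
        return out[["section", "category", "count", "percent"]]

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _section(counts: dict[str, int], total: int) -> pd.DataFrame:
    return pd.DataFrame({
        "category": list(counts.keys()),
        "count": list(counts.values()),
        "percent": [_pct(v, total) for v in counts.values()],
    })


def summarize_characteristics(bundle: ReportBundle,
                              top_k: int = 10) -> CharacteristicsSummary:
    """Deterministic descriptive table over a cleaned bundle."""
    r = bundle.reports
    total = len(r)
    summary = CharacteristicsSummary(total=total)
    if total == 0:
        return summary

    sex = r["sex"].fillna("unknown")
    summary.sections["sex"] = _section(
        {lab: int((sex == lab).sum()) for lab in ("M", "F", "unknown")}, total)

    age = pd.to_numeric(r["age_years"], errors="coerce")
    age_counts = {}
    for label, lo, hi in AGE_TABLE_BINS:
        age_counts[label] = int((age.notna() & (age >= lo) & (age < hi)).sum())
    age_counts["missing"] = int(age.isna().sum())
    summary.sections["age"] = _section(age_counts, total)

    country = r["country"].fillna("").replace("", "unknown")
    top = country.value_counts().head(top_k)
    summary.sections["country"] = _section(
        {str(k): int(v) for k, v in top.items()}, total)

    rep = r["reporter_code"].fillna("unknown")
    summary.sections["reporter"] = _section(
        {lab: int((rep == lab).sum()) for lab in rep.value_counts().index}, total)

    ind = bundle.indications.drop_duplicates(["primaryid", "indication_pt"])
    top_ind = ind["indication_pt"].value_counts().head(top_k)
    summary.sections["indication"] = _section(
        {str(k): int(v) for k, v in top_ind.items()}, total)

    out = bundle.outcomes.drop_duplicates(["primaryid", "outcome"])
    oc = out["outcome"].value_counts()
    summary.sections["serious_outcomes"] = _section(
        {lab: int(oc.get(lab, 0)) for lab in
         ("hospitalization", "death", "life-threatening", "disability",
          "other-serious")}, total)
    return summary


# ---------------------------------------------------------------------------
# pipeline configuration

class PipelineConfig(BaseModel):
    """Everything one run needs, serialisable for the manifest hash."""

    synthetic: SyntheticConfig | None = None
    quarters: list[str] = Field(default_factory=list)
    dialect: str = "faers-ascii"
    deleted_case_files: list[str] = Field(default_factory=list)
    target_drug: str = "pemetrexed"
    synonyms_path: str | None = None
    meddra_map_path: str | None = None
    levels: list[str] = Field(default_factory=lambda: ["PT", "SOC"])
    criteria: dict = Field(default_factory=dict)
    study_window: tuple[str, str] = ("20040101", "20241231")
    subgroup_dimensions: list[str] = Field(default_factory=lambda:
                                           ["sex", "age", "reporter"])
    sensitivity_exclusions: list[str] = Field(
        default_factory=lambda: list(DEFAULT_SENSITIVITY_EXCLUSIONS))
    tto_accounting: str = "per-report"
    tto_cap_days: float = 3650.0
    output_dir: str = "faersig_out"
    seed: int = 0

    def config_hash(self) -> str:
        # the output location is not an analysis input: identical analyses
        # hash identically wherever they are written
        data = self.model_dump(mode="json", exclude={"output_dir"})
        blob = json.dumps(data, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


class PipelineError(RuntimeError):
    pass


ALL_STAGES = ("clean", "report", "screen", "subgroup", "sensitivity", "tto")


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        cfg = config.synthetic.model_copy(update={"seed": config.seed})
        bundle, truth = generate_bundle(cfg)
        meddra = MedDRAMap.from_frame(cfg.meddra_frame())
        return bundle, truth, meddra
    if not config.quarters:
        raise PipelineError("config must name input quarters or a synthetic spec")
    bundles = [_io.read_quarter(q, config.dialect) for q in config.quarters]
    bundle = concat_bundles(bundles)
    meddra = (MedDRAMap.from_tsv(config.meddra_map_path)
              if config.meddra_map_path else None)
    return bundle, None, meddra


def run_pipeline(config: PipelineConfig,
                 stages=ALL_STAGES) -> Path:
    """Run the requested stages and write the output tree; returns its path."""
    if "SOC" in config.levels and config.synthetic is None \
            and not config.meddra_map_path:
        raise PipelineError("SOC-level screening requires a PT→SOC map")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    criteria = SignalCriteria(**config.criteria)
    manifest: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "target_drug": config.target_drug,
        "criteria": criteria.__dict__.copy(),
        "versions": {"faersig": _pkg_version, "numpy": np.__version__,
                     "pandas": pd.__version__},
        "stages": {},
        "errors": [],
    }

    bundle, truth, meddra = _load_inputs(config)
    manifest["input_reports"] = int(bundle.n_reports)

    deleted: set[str] = set()
    for fp in config.deleted_case_files:
        deleted |= _io.read_deleted_cases(fp)
    synonyms = load_synonyms(config.synonyms_path)
    rules = PlausibilityRules(study_window=tuple(config.study_window))

    universe, cleaning = clean_pipeline(
        bundle, synonyms, deleted, config.target_drug, rules, universe=True)
    target_bundle, ps_report = select_unique_ps(universe, config.target_drug)
    if "clean" in stages:
        combine_reports(cleaning).to_csv(out_dir / "cleaning_report.tsv",
                                         sep="\t", index=False)
    manifest["stages"]["clean"] = {
        "universe_reports": int(universe.n_reports),
        "target_reports": int(target_bundle.n_reports),
        "removed": {r.stage: r.removed for r in cleaning},
    }

    if "report" in stages:
        summary = summarize_characteristics(target_bundle)
        summary.to_tsv(out_dir / "characteristics.tsv")
        manifest["stages"]["report"] = {"total": summary.total}

    signal_terms: dict[str, list[str]] = {}
    if "screen" in stages:
        for level in config.levels:
            res = DisproportionalityScreen(universe, config.target_drug,
                                           level=level, meddra_map=meddra,
                                           criteria=criteria).fit()
            res.to_tsv(out_dir / f"screen_{level.lower()}.tsv")
            signal_terms[level] = sorted(r.term for r in res.signals)
        manifest["stages"]["screen"] = {
            lvl: {"n_signals": len(v), "signals": v}
            for lvl, v in signal_terms.items()}
        if truth is not None:
            planted = [(p.drug, p.pt) for p in truth.planted]
            flagged = [(d, p) for d, p in planted
                       if d.lower() == config.target_drug.lower()
                       and p.lower() in {s.lower() for s in
                                         signal_terms.get("PT", [])}]
            manifest["planted_pairs"] = [list(p) for p in planted]
            manifest["planted_flagged"] = [list(p) for p in flagged]

    if "subgroup" in stages:
        sub_info = {}
        for dim in config.subgroup_dimensions:
            for label, sub in sorted(stratify(universe, dim).items()):
                if label == "missing":
                    sub_info[f"{dim}_missing"] = {"reports": int(sub.n_reports)}
                    continue
                try:
                    res = DisproportionalityScreen(
                        sub, config.target_drug, level="PT",
                        criteria=criteria).fit()
                except (GPSFitError, ValueError) as exc:
                    manifest["errors"].append(f"subgroup {dim}/{label}: {exc}")
                    continue
                safe = label.replace("<", "lt").replace(">=", "ge").replace(">", "gt")
                res.to_tsv(out_dir / f"{dim}_{safe}.tsv")
                sub_info[f"{dim}_{label}"] = {
                    "reports": int(sub.n_reports),
                    "n_signals": len(res.signals)}
        manifest["stages"]["subgroup"] = sub_info

    if "sensitivity" in stages:
        reduced, sens_report = sensitivity_exclude(
            universe, config.sensitivity_exclusions)
        try:
            res = DisproportionalityScreen(reduced, config.target_drug,
                                           level="PT", criteria=criteria).fit()
            res.to_tsv(out_dir / "sensitivity_pt.tsv")
            manifest["stages"]["sensitivity"] = {
                "excluded": sens_report.removed,
                "remaining": sens_report.retained,
                "n_signals": len(res.signals),
                "signals": sorted(r.term for r in res.signals)}
        except (GPSFitError, ValueError) as exc:
            manifest["errors"].append(f"sensitivity: {exc}")

    if "tto" in stages:
        samples = _tto.compute_tto(target_bundle, config.target_drug,
                                   config.tto_accounting, config.tto_cap_days)
        samples.to_csv(out_dir / "tto_samples.tsv", sep="\t", index=False)
        _tto.bin_tto(samples["days"]).to_csv(out_dir / "tto_bins.tsv",
                                             sep="\t", index=False)
        tto_info: dict = {"n_samples": int(len(samples)),
                          "excluded": samples.attrs["excluded"]}
        try:
            fit = _tto.fit_weibull(samples["days"])
            fit.to_frame().to_csv(out_dir / "tto_weibull.tsv", sep="\t",
                                  index=False)
            tto_info["weibull"] = {"alpha": fit.alpha, "beta": fit.beta,
                                   "failure_type": fit.failure_type}
        except _tto.WeibullFitError as exc:
            manifest["errors"].append(f"tto weibull: {exc}")
        comparisons = {}
        for dim in config.subgroup_dimensions:
            ci = _tto.cumulative_incidence(samples, by=dim)
            ci.to_frame().to_csv(out_dir / f"tto_cuminc_{dim}.tsv", sep="\t",
                                 index=False)
            comparisons[dim] = {"test": ci.test, "statistic": ci.test_statistic,
                                "p_value": ci.p_value}
        tto_info["comparisons"] = comparisons
        manifest["stages"]["tto"] = tto_info

    with open(out_dir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out_dir
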