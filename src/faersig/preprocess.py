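"""Cleaning rules for spontaneous-report bundles.

The pipeline order is fixed and recorded:

    normalize → deduplicate → drop_deleted → plausibility → unique-PS

so that the deduplicated (most recent) version of a case is the one that
decides eligibility, and each removed report is attributed to exactly
one first-matching rule. Every stage returns a :class:`CleaningReport`
that partitions its input exactly (input = retained + Σ removed).

Rules implemented:

* case-level deduplication — one report per CASEID, keeping the most
  recent FDA receipt date (FDA_DT) and breaking ties by the larger
  PRIMARYID;
* removal of cases named in the FDA deleted-case lists;
* plausibility filters — implausible ages (outside [0, 120] years),
  logically inconsistent timelines (full-precision event date before the
  earliest full-precision therapy start date), receipt dates outside the
  study window, and non-adverse-event reports (no reaction rows, or only
  administrative preferred terms);
* unique-primary-suspect selection for the target drug (reports where
  the target appears only as SS/C/I, or with multiple PS drugs, are
  excluded; SS/concomitant co-drugs on qualifying reports are kept).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .bundle import ReportBundle
from . import dates

logger = logging.getLogger(__name__)

PIPELINE_ORDER = ("normalize", "deduplicate", "drop_deleted", "plausibility",
                  "unique_ps")


@dataclass
class CleaningReport:
    """Exact accounting for one cleaning stage."""

    stage: str
    input_count: int
    removed: dict[str, int] = field(default_factory=dict)
    retained: int = 0

    def validate(self) -> None:
        total = self.retained + sum(self.removed.values())
        if total != self.input_count:
            raise AssertionError(
                f"{self.stage}: {self.input_count} in != {self.retained} retained "
                f"+ {sum(self.removed.values())} removed")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"stage": self.stage, "rule": rule, "removed": n}
                for rule, n in self.removed.items()]
        rows.append({"stage": self.stage, "rule": "(retained)", "removed": self.retained})
        return pd.DataFrame(rows)


def combine_reports(reports: list[CleaningReport]) -> pd.DataFrame:
    """Stacked flowchart-style accounting across all stages."""
    return pd.concat([r.to_frame() for r in reports], ignore_index=True)


# ---------------------------------------------------------------------------
# synonym table / config files

def load_synonyms(path: str | Path | None = None) -> dict[str, str]:
    """Two-column TSV (raw, canonical) → case-insensitive lookup map.

    With no path, the synonym table shipped with the package (pemetrexed
    brand/salt names and the common co-medications) is used.
    """
    if path is None:
        src = resources.files("faersig").joinpath("data/synonyms_pemetrexed.tsv")
        text = src.read_text(encoding="utf-8")
        lines = text.splitlines()
    else:
        lines = Path(path).read_text(encoding="utf-8").splitlines()
    out: dict[str, str] = {}
    for i, line in enumerate(lines):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            continue
        raw, canonical = parts[0].strip(), parts[1].strip()
        if i == 0 and raw.lower() == "raw":
            continue
        out[raw.lower()] = canonical.lower()
    return out


def load_administrative_terms(path: str | Path | None = None) -> set[str]:
    """One PT per line; used to operationalize non-adverse-event reports."""
    if path is None:
        src = resources.files("faersig").joinpath("data/administrative_terms.txt")
        text = src.read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    return {line.strip().lower() for line in text.splitlines() if line.strip()}


def normalize_drug_names(drugs: pd.DataFrame,
                         synonym_table: dict[str, str]) -> pd.DataFrame:
    """Fill ``name_norm``: synonym-matched rows get the canonical ingredient,
    unmatched rows keep the lower-cased trimmed raw name."""
    if not synonym_table:
        logger.warning("empty synonym table: drug names pass through lower-cased")
        synonym_table = {}
    out = drugs.copy()
    lowered = out["name_raw"].fillna("").astype(str).str.strip().str.lower()
    out["name_norm"] = lowered.map(lambda s: synonym_table.get(s, s))
    return out


# ---------------------------------------------------------------------------
# deduplication

def _pid_sort_key(pids: pd.Series) -> pd.Series:
    """Numeric primaryid ordering where possible (ids may be zero-padded)."""
    num = pd.to_numeric(pids, errors="coerce")
    if num.isna().any():
        # fall back to length-then-lexicographic for non-numeric ids
        return pids.map(lambda s: (len(s), s))
    return num


def deduplicate(bundle: ReportBundle) -> tuple[ReportBundle, CleaningReport]:
    """One report per caseid: keep max FDA_DT, ties broken by max PRIMARYID."""
    r = bundle.reports
    n_in = len(r)
    caseid = r["caseid"].fillna("").astype(str)
    missing = caseid == ""
    if missing.any():
        logger.warning("%d reports lack a caseid; treated as singleton cases",
                       int(missing.sum()))
    group = caseid.where(~missing, "<no-caseid>:" + r["primaryid"].astype(str))
    order = pd.DataFrame({
        "group": group,
        "fda": r["fda_dt"].fillna("").astype(str),
        "pid": _pid_sort_key(r["primaryid"].astype(str)),
    }, index=r.index)
    keep_idx = (order.sort_values(["group", "fda", "pid"], kind="mergesort")
                     .groupby("group", sort=False).tail(1).index)
    kept = r.loc[sorted(keep_idx)]
    out = bundle.subset(kept["primaryid"])
    report = CleaningReport("deduplicate", n_in,
                            {"duplicates": n_in - len(kept)}, len(kept))
    report.validate()
    return out, report


def drop_deleted(bundle: ReportBundle,
                 deleted_ids: set[str]) -> tuple[ReportBundle, CleaningReport]:
    r = bundle.reports
    n_in = len(r)
    bad = r["caseid"].fillna("").astype(str).isin(deleted_ids)
    out = bundle.subset(r.loc[~bad, "primaryid"])
    report = CleaningReport("drop_deleted", n_in,
                            {"deleted-cases": int(bad.sum())}, n_in - int(bad.sum()))
    report.validate()
    return out, report


# ---------------------------------------------------------------------------
# plausibility

@dataclass
class PlausibilityRules:
    """Operational definitions of the extreme-value / non-AE exclusions."""

    age_range: tuple[float, float] = (0.0, 120.0)
    study_window: tuple[str, str] = ("20040101", "20241231")
    administrative_terms: set[str] = field(default_factory=load_administrative_terms)


def apply_plausibility_filters(
        bundle: ReportBundle,
        rules: PlausibilityRules | None = None) -> tuple[ReportBundle, CleaningReport]:
    """Remove extreme-value, inconsistent-timeline, out-of-window and
    non-adverse-event reports; partial-precision dates are never judged
    inconsistent, and a missing event date is not a violation."""
    rules = rules or PlausibilityRules()
    r = bundle.reports
    n_in = len(r)

    age = pd.to_numeric(r["age_years"], errors="coerce")
    bad_age = age.notna() & ((age < rules.age_range[0]) | (age > rules.age_range[1]))

    # earliest full-precision drug start per report
    d = bundle.drugs
    starts = d[dates.full_mask(d["start_dt"])]
    min_start = starts.groupby("primaryid")["start_dt"].min()
    ev = r["event_dt"].fillna("").astype(str)
    ev_full = dates.full_mask(r["event_dt"])
    start_for = r["primaryid"].map(min_start)
    bad_timeline = ev_full & start_for.notna() & (ev < start_for.fillna(""))

    fda = r["fda_dt"].fillna("").astype(str)
    fda_full = dates.full_mask(r["fda_dt"])
    lo, hi = rules.study_window
    bad_window = fda_full & ((fda < lo) | (fda > hi))

    pts_per_report = bundle.reactions.groupby("primaryid")["pt"].agg(
        lambda s: set(x.strip().lower() for x in s))
    pt_sets = r["primaryid"].map(pts_per_report)
    admin = rules.administrative_terms
    bad_nonae = pt_sets.map(
        lambda s: (not isinstance(s, set)) or len(s) == 0 or s.issubset(admin))

    # first-matching rule wins: each report removed by exactly one rule
    reason = pd.Series("", index=r.index)
    for label, mask in [("extreme-values", bad_age),
                        ("inconsistent-timeline", bad_timeline),
                        ("out-of-window", bad_window),
                        ("non-AE", bad_nonae)]:
        reason = reason.where((reason != "") | ~mask, label)

    keep = reason == ""
    out = bundle.subset(r.loc[keep, "primaryid"])
    removed = {label: int((reason == label).sum())
               for label in ("extreme-values", "inconsistent-timeline",
                             "out-of-window", "non-AE")}
    report = CleaningReport("plausibility", n_in, removed, int(keep.sum()))
    report.validate()
    return out, report


# ---------------------------------------------------------------------------
# unique primary suspect

def _ps_flags(bundle: ReportBundle, drug_name: str) -> pd.DataFrame:
    d = bundle.drugs
    name = d["name_norm"].fillna("").astype(str).str.lower()
    target = name == drug_name.lower()
    is_ps = d["role"] == "PS"
    per = pd.DataFrame({
        "primaryid": d["primaryid"],
        "n_ps": is_ps.astype(int),
        "target_ps": (target & is_ps).astype(int),
        "target_any": target.astype(int),
    }).groupby("primaryid").sum()
    return per


def select_unique_ps(bundle: ReportBundle,
                     drug_name: str) -> tuple[ReportBundle, CleaningReport]:
    """Restrict to reports where the target is the *unique* PS drug.

    Reports with several PS drugs, or where the target appears only as
    SS/C/I, are excluded; co-medication rows on qualifying reports stay.
    """
    per = _ps_flags(bundle, drug_name)
    r = bundle.reports
    n_in = len(r)
    stats = per.reindex(r["primaryid"]).fillna(0).astype(int)
    stats.index = r.index
    qualifying = (stats["n_ps"] == 1) & (stats["target_ps"] == 1)
    non_target = stats["target_any"] == 0
    multi_ps = (~non_target) & (stats["n_ps"] > 1)
    not_ps = (~non_target) & (stats["n_ps"] <= 1) & ~qualifying
    if stats["target_any"].sum() == 0:
        logger.warning("target drug %r absent from bundle: empty selection", drug_name)
    out = bundle.subset(r.loc[qualifying, "primaryid"])
    report = CleaningReport("unique_ps", n_in, {
        "non-target": int(non_target.sum()),
        "multi-PS": int(multi_ps.sum()),
        "target-not-PS": int(not_ps.sum()),
    }, int(qualifying.sum()))
    report.validate()
    return out, report


def build_analysis_universe(bundle: ReportBundle,
                            drug_name: str) -> tuple[ReportBundle, CleaningReport]:
    """Screening universe: unique-PS target reports plus the full
    non-target background; target-mentioning reports that fail the
    unique-PS rule are excluded entirely."""
    per = _ps_flags(bundle, drug_name)
    r = bundle.reports
    n_in = len(r)
    stats = per.reindex(r["primaryid"]).fillna(0).astype(int)
    stats.index = r.index
    qualifying = (stats["n_ps"] == 1) & (stats["target_ps"] == 1)
    background = stats["target_any"] == 0
    keep = qualifying | background
    out = bundle.subset(r.loc[keep, "primaryid"])
    report = CleaningReport("analysis_universe", n_in,
                            {"target-not-unique-PS": int((~keep).sum())},
                            int(keep.sum()))
    report.validate()
    return out, report


# ---------------------------------------------------------------------------
# pipeline

def clean_pipeline(bundle: ReportBundle,
                   synonym_table: dict[str, str] | None = None,
                   deleted_ids: set[str] | None = None,
                   target_drug: str | None = None,
                   rules: PlausibilityRules | None = None,
                   universe: bool = False,
                   ) -> tuple[ReportBundle, list[CleaningReport]]:
    """Run the full fixed-order cleaning pipeline.

    With ``universe=True`` the final stage keeps the non-target
    background alongside the qualifying target reports (for screening);
    the default reproduces the target-only case series.
    """
    reports: list[CleaningReport] = []
    bundle = ReportBundle(reports=bundle.reports,
                          drugs=normalize_drug_names(
                              bundle.drugs, synonym_table or load_synonyms()),
                          reactions=bundle.reactions, outcomes=bundle.outcomes,
                          indications=bundle.indications, meta=dict(bundle.meta))
    bundle, rep = deduplicate(bundle)
    reports.append(rep)
    bundle, rep = drop_deleted(bundle, deleted_ids or set())
    reports.append(rep)
    bundle, rep = apply_plausibility_filters(bundle, rules)
    reports.append(rep)
    if target_drug is not None:
        selector = build_analysis_universe if universe else select_unique_ps
        bundle, rep = selector(bundle, target_drug)
        reports.append(rep)
    for rep in reports:
        logger.info("%s: %d in, %d retained, removed %s",
                    rep.stage, rep.input_count, rep.retained, rep.removed)
    return bundle, reports
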