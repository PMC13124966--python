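"""Subgroup stratification and co-medication sensitivity analysis.

Stratification dimensions: sex (M/F), age (<18, 18–64.99, ≥65 — the
boundaries half-open with 65 in the elderly bin) and reporter type
(healthcare professionals — physicians, pharmacists, other healthcare
professionals, registered nurses and the generic health-professional
code — versus consumers). Reports with the dimension missing go to a
"missing" stratum, which is counted but not screened. Each stratum is
re-screened against its own background, and subgroup contrasts are
descriptive (CI overlap) only — no interaction tests.

The sensitivity analysis removes every report listing any of the named
co-medications in any role (default: cisplatin, carboplatin,
pembrolizumab, bevacizumab), re-running the screen on the remainder.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .bundle import ReportBundle
from .preprocess import CleaningReport

MISSING = "missing"

HCP_REPORTERS = {"physician", "pharmacist", "other-health-professional",
                 "registered-nurse", "health-professional"}

DEFAULT_SENSITIVITY_EXCLUSIONS = ("cisplatin", "carboplatin", "pembrolizumab",
                                  "bevacizumab")

AGE_BINS = (("<18", 0.0, 18.0), ("18-64.99", 18.0, 65.0), (">=65", 65.0, float("inf")))


@dataclass(frozen=True)
class StratumSpec:
    """One stratification dimension and its bins."""

    dimension: str  # sex | age | reporter
    bins: tuple = field(default=())

    def __post_init__(self) -> None:
        if self.dimension not in ("sex", "age", "reporter"):
            raise ValueError(f"unknown stratification dimension {self.dimension!r}")


def _assign(bundle: ReportBundle, dimension: str) -> pd.Series:
    r = bundle.reports
    if dimension == "sex":
        sex = r["sex"].fillna("unknown")
        return sex.where(sex.isin(["M", "F"]), MISSING)
    if dimension == "age":
        age = pd.to_numeric(r["age_years"], errors="coerce")
        out = pd.Series(MISSING, index=r.index, dtype=object)
        for label, lo, hi in AGE_BINS:
            out = out.where(~(age.notna() & (age >= lo) & (age < hi)), label)
        return out
    if dimension == "reporter":
        rep = r["reporter_code"].fillna("unknown")
        out = pd.Series(MISSING, index=r.index, dtype=object)
        out = out.where(~rep.isin(HCP_REPORTERS), "healthcare-professional")
        out = out.where(rep != "consumer", "consumer")
        return out
    raise ValueError(f"unknown stratification dimension {dimension!r}")


def stratify(bundle: ReportBundle,
             spec: StratumSpec | str) -> dict[str, ReportBundle]:
    """Partition the bundle by one dimension: stratum label → sub-bundle.

    Every report lands in exactly one stratum or in ``"missing"``; the
    strata therefore partition the bundle, and downstream screening runs
    within each stratum against that stratum's own background.
    """
    dimension = spec.dimension if isinstance(spec, StratumSpec) else spec
    labels = _assign(bundle, dimension)
    out: dict[str, ReportBundle] = {}
    for label in labels.unique():
        pids = bundle.reports.loc[labels == label, "primaryid"]
        out[label] = bundle.subset(pids)
    return out


def sensitivity_exclude(bundle: ReportBundle,
                        co_drug_names=DEFAULT_SENSITIVITY_EXCLUSIONS,
                        ) -> tuple[ReportBundle, CleaningReport]:
    """Drop every report that lists any named co-medication in any role."""
    names = {n.strip().lower() for n in co_drug_names}
    n_in = bundle.n_reports
    if not names:
        report = CleaningReport("sensitivity_exclude", n_in,
                                {"co-medication": 0}, n_in)
        report.validate()
        return bundle, report
    d = bundle.drugs
    norm = d["name_norm"].fillna("").astype(str).str.lower()
    hit_ids = set(d.loc[norm.isin(names), "primaryid"])
    keep = ~bundle.reports["primaryid"].isin(hit_ids)
    out = bundle.subset(bundle.reports.loc[keep, "primaryid"])
    report = CleaningReport("sensitivity_exclude", n_in,
                            {"co-medication": int((~keep).sum())}, int(keep.sum()))
    report.validate()
    return out, report
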