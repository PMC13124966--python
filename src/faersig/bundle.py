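"""Normalized in-memory data model for spontaneous-report bundles.

A :class:`ReportBundle` holds the linked tables of one or more FAERS
quarters after column normalization: one row per report version in
``reports``, with drug entries, reaction preferred terms (PTs), serious
outcomes and drug indications in child tables keyed by ``primaryid``.
All identifiers are strings (FAERS ids exceed 32-bit ranges and may be
zero-padded); all dates are raw YYYYMMDD/YYYYMM/YYYY strings (see
:mod:`faersig.dates`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

ROLE_CODES = ("PS", "SS", "C", "I")

SEX_VALUES = ("M", "F", "unknown")

REPORTER_VALUES = (
    "physician",
    "pharmacist",
    "other-health-professional",
    "registered-nurse",
    "health-professional",
    "consumer",
    "unknown",
)

OUTCOME_VALUES = (
    "hospitalization",
    "death",
    "life-threatening",
    "disability",
    "other-serious",
)

REPORT_COLUMNS = [
    "primaryid",
    "caseid",
    "event_dt",
    "fda_dt",
    "sex",
    "age_years",
    "country",
    "reporter_code",
]
DRUG_COLUMNS = ["primaryid", "drug_seq", "name_raw", "name_norm", "role", "start_dt"]
REACTION_COLUMNS = ["primaryid", "pt"]
OUTCOME_COLUMNS = ["primaryid", "outcome"]
INDICATION_COLUMNS = ["primaryid", "drug_seq", "indication_pt"]

_CHILD_TABLES = ("drugs", "reactions", "outcomes", "indications")


class BundleError(ValueError):
    """Raised when a bundle violates its structural invariants."""


def _empty(columns: list[str]) -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in columns})


@dataclass
class ReportBundle:
    """Linked report/drug/reaction/outcome/indication tables.

    ``meta`` carries bookkeeping that is not part of the data itself:
    quarantine counts from the reader, passthrough columns, cleaning
    provenance. Two bundles compare equal on data regardless of meta.
    """

    reports: pd.DataFrame = field(default_factory=lambda: _empty(REPORT_COLUMNS))
    drugs: pd.DataFrame = field(default_factory=lambda: _empty(DRUG_COLUMNS))
    reactions: pd.DataFrame = field(default_factory=lambda: _empty(REACTION_COLUMNS))
    outcomes: pd.DataFrame = field(default_factory=lambda: _empty(OUTCOME_COLUMNS))
    indications: pd.DataFrame = field(default_factory=lambda: _empty(INDICATION_COLUMNS))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, cols in [
            ("reports", REPORT_COLUMNS),
            ("drugs", DRUG_COLUMNS),
            ("reactions", REACTION_COLUMNS),
            ("outcomes", OUTCOME_COLUMNS),
            ("indications", INDICATION_COLUMNS),
        ]:
            df = getattr(self, name)
            missing = [c for c in cols if c not in df.columns]
            if missing:
                raise BundleError(f"{name} table missing columns {missing}")

    # -- basic accessors -------------------------------------------------
    @property
    def n_reports(self) -> int:
        return len(self.reports)

    def validate(self) -> None:
        """Check the structural invariants, raising :class:`BundleError`."""
        if self.reports["primaryid"].duplicated().any():
            dup = self.reports.loc[self.reports["primaryid"].duplicated(), "primaryid"].iloc[0]
            raise BundleError(f"duplicate primaryid {dup!r} in reports")
        ids = set(self.reports["primaryid"])
        for name in _CHILD_TABLES:
            df = getattr(self, name)
            if len(df) and not set(df["primaryid"]).issubset(ids):
                orphan = sorted(set(df["primaryid"]) - ids)[:3]
                raise BundleError(f"{name} rows reference unknown primaryid(s) {orphan}")
        bad = set(self.drugs["role"]) - set(ROLE_CODES)
        if bad:
            raise BundleError(f"invalid drug role codes {sorted(bad)}")

    def subset(self, primaryids: Iterable[str]) -> "ReportBundle":
        """Restrict every table to the given report ids (meta carried over)."""
        keep = set(primaryids)
        out = ReportBundle(
            reports=self.reports[self.reports["primaryid"].isin(keep)].reset_index(drop=True),
            meta=dict(self.meta),
        )
        for name in _CHILD_TABLES:
            df = getattr(self, name)
            setattr(out, name, df[df["primaryid"].isin(keep)].reset_index(drop=True))
        return out

    # -- comparison ------------------------------------------------------
    @staticmethod
    def _canon(df: pd.DataFrame, cols: list[str]) -> pd.DataFrame:
        out = df[cols].copy()
        for c in cols:
            if c == "age_years":
                out[c] = pd.to_numeric(out[c], errors="coerce")
            else:
                out[c] = out[c].fillna("").astype(str)
        return out.sort_values(cols, kind="mergesort").reset_index(drop=True)

    def equals(self, other: "ReportBundle") -> bool:
        """Field-by-field data equality, insensitive to row order and meta."""
        for name, cols in [
            ("reports", REPORT_COLUMNS),
            ("drugs", DRUG_COLUMNS),
            ("reactions", REACTION_COLUMNS),
            ("outcomes", OUTCOME_COLUMNS),
            ("indications", INDICATION_COLUMNS),
        ]:
            a = self._canon(getattr(self, name), cols)
            b = self._canon(getattr(other, name), cols)
            if not a.equals(b):
                return False
        return True

    def report_ids_with_drug(self, name_norm: str) -> set[str]:
        d = self.drugs
        return set(d.loc[d["name_norm"].fillna("").str.lower() == name_norm.lower(), "primaryid"])


def concat_bundles(bundles: list[ReportBundle]) -> ReportBundle:
    """Union of all tables across quarters.

    Primaryid collisions are kept as-is: deduplication is a cleaning
    rule applied later, never an IO side effect.
    """
    if not bundles:
        raise ValueError("need at least one bundle")
    if len(bundles) == 1:
        return bundles[0]
    out = ReportBundle()
    out.reports = pd.concat([b.reports for b in bundles], ignore_index=True)
    for name in _CHILD_TABLES:
        setattr(out, name, pd.concat([getattr(b, name) for b in bundles], ignore_index=True))
    out.meta = {"concatenated": len(bundles)}
    return out


def outcomes_by_report(bundle: ReportBundle) -> Mapping[str, set]:
    """primaryid -> set of serious-outcome labels (categories overlap)."""
    return bundle.outcomes.groupby("primaryid")["outcome"].agg(set).to_dict()
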