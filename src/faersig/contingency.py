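"""2×2 contingency tables for drug–event pairs at PT or SOC level.

The counting unit is the *report–term pair*: a report listing the same
preferred term twice contributes one pair, and at SOC level all PTs of
a report that share a System Organ Class collapse to one (report, SOC)
pair. The background is every non-target report in the cleaned bundle
(full-database comparator). For a term t and target drug X:

    a = pairs with X and t          b = pairs with X, other terms
    c = pairs with t, other drugs   d = pairs with neither
    N = a+b+c+d,   E = (a+b)(a+c)/N  (expected a under independence)

MedDRA itself is licensed and not bundled: the PT→SOC map is supplied
by the user (or by the synthetic generator) as a two-column table, with
primary-SOC assignment only (multi-axiality collapsed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .bundle import ReportBundle

logger = logging.getLogger(__name__)

LEVELS = ("PT", "SOC")
UNMAPPED = "UNMAPPED"


class MedDRAMap:
    """PT → primary SOC lookup (case-insensitive on PTs)."""

    def __init__(self, mapping: dict[str, str]):
        self._map = {k.strip().lower(): v for k, v in mapping.items()}

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "MedDRAMap":
        cols = list(frame.columns[:2])
        return cls(dict(zip(frame[cols[0]], frame[cols[1]])))

    @classmethod
    def from_tsv(cls, path: str | Path) -> "MedDRAMap":
        frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        return cls.from_frame(frame)

    def __len__(self) -> int:
        return len(self._map)

    def soc(self, pt: str) -> str:
        return self._map.get(pt.strip().lower(), UNMAPPED)

    def map_series(self, pts: pd.Series) -> pd.Series:
        return pts.fillna("").astype(str).str.strip().str.lower().map(self._map) \
                  .fillna(UNMAPPED)


@dataclass(frozen=True)
class ContingencyTable:
    """One drug–term 2×2 table with the derived margins."""

    term: str
    level: str
    a: float
    b: float
    c: float
    d: float

    @property
    def n_total(self) -> float:
        return self.a + self.b + self.c + self.d

    @property
    def expected_a(self) -> float:
        n = self.n_total
        return (self.a + self.b) * (self.a + self.c) / n if n else 0.0

    def cells(self) -> tuple[float, float, float, float]:
        return self.a, self.b, self.c, self.d


def map_terms(reactions: pd.DataFrame, meddra_map: MedDRAMap | None,
              level: str = "PT") -> pd.DataFrame:
    """Distinct (primaryid, term) pairs at the requested MedDRA level.

    At SOC level each distinct (report, SOC) counts once even when
    several PTs share the SOC; PTs absent from the map are routed to the
    ``UNMAPPED`` bucket and counted with a warning.
    """
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")
    pts = reactions["pt"].fillna("").astype(str).str.strip().str.lower()
    if level == "PT":
        terms = pts
    else:
        if meddra_map is None or len(meddra_map) == 0:
            raise ValueError("SOC-level mapping requires a non-empty PT→SOC map")
        terms = meddra_map.map_series(reactions["pt"])
        n_unmapped = int((terms == UNMAPPED).sum())
        if n_unmapped:
            logger.warning("%d reaction rows with PTs absent from the MedDRA map "
                           "routed to %s", n_unmapped, UNMAPPED)
    pairs = pd.DataFrame({"primaryid": reactions["primaryid"], "term": terms})
    return pairs.drop_duplicates(ignore_index=True)


def build_tables(bundle: ReportBundle, target_drug: str, level: str = "PT",
                 meddra_map: MedDRAMap | None = None,
                 all_terms: bool = False) -> pd.DataFrame:
    """Pair-level 2×2 cells for every term, as a tidy frame.

    Returns columns term, level, a, b, c, d — one row per term observed
    in the bundle (by default only terms the target drug reported at
    least once, ``all_terms=True`` keeps every term). Frame attrs carry
    the pair totals for both conventions (pairs and distinct reports).
    """
    pairs = map_terms(bundle.reactions, meddra_map, level)
    target_ids = bundle.report_ids_with_drug(target_drug)
    if not target_ids:
        logger.warning("target drug %r absent from bundle: no tables", target_drug)
    pairs["is_target"] = pairs["primaryid"].isin(target_ids)

    per_term = pairs.groupby("term", sort=True).agg(
        ac=("primaryid", "size"), a=("is_target", "sum"))
    total_pairs = int(per_term["ac"].sum())
    target_pairs = int(per_term["a"].sum())

    out = per_term.reset_index()
    out["a"] = out["a"].astype(float)
    out["b"] = float(target_pairs) - out["a"]
    out["c"] = out["ac"].astype(float) - out["a"]
    out["d"] = float(total_pairs) - float(target_pairs) - out["c"]
    out["level"] = level
    out = out[["term", "level", "a", "b", "c", "d"]]
    if not all_terms:
        out = out[out["a"] > 0].reset_index(drop=True)
    out.attrs["total_pairs"] = total_pairs
    out.attrs["target_pairs"] = target_pairs
    out.attrs["total_reports"] = int(bundle.n_reports)
    out.attrs["target_reports"] = len(target_ids)
    return out


def tables_as_objects(frame: pd.DataFrame) -> list[ContingencyTable]:
    return [ContingencyTable(r.term, r.level, r.a, r.b, r.c, r.d)
            for r in frame.itertuples(index=False)]


def write_tables(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)
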