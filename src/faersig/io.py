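"""Read and write FAERS quarterly ASCII bundles.

Two dialects are supported:

``faers-ascii``
    The post-2014 FAERS quarterly extract layout: "$"-delimited text,
    one header row, one file per table, filenames ``<TABLE><YY>Q<Q>.txt``
    (DEMO/DRUG/REAC/OUTC/THER/INDI). Drug start dates live in THER and
    are joined onto the drug table by (primaryid, drug_seq). Earlier
    LAERS-era layouts are intentionally out of scope.

``simple-tsv``
    The same tables, tab-delimited, ``<TABLE>.tsv`` — a human-readable
    fixture format with identical columns.

The reader is deliberately non-judgemental: implausible values (e.g. an
age of 650 years from a mis-coded unit) are stored verbatim and left to
the cleaning stage. Malformed rows and child rows referencing unknown
reports are quarantined and *counted*, never silently dropped:
``bundle.meta["row_counts"]`` satisfies rows_in = loaded + quarantined
for every table.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .bundle import ReportBundle

logger = logging.getLogger(__name__)

DIALECTS = ("faers-ascii", "simple-tsv")
MANDATORY_TABLES = ("DEMO", "DRUG", "REAC")
ALL_TABLES = ("DEMO", "DRUG", "REAC", "OUTC", "THER", "INDI")

_FILE_COLUMNS = {
    "DEMO": ["primaryid", "caseid", "event_dt", "fda_dt", "age", "age_cod", "sex",
             "occp_cod", "occr_country"],
    "DRUG": ["primaryid", "caseid", "drug_seq", "role_cod", "drugname", "prod_ai"],
    "REAC": ["primaryid", "caseid", "pt"],
    "OUTC": ["primaryid", "caseid", "outc_cod"],
    "THER": ["primaryid", "caseid", "dsg_drug_seq", "start_dt", "end_dt"],
    "INDI": ["primaryid", "caseid", "indi_drug_seq", "indi_pt"],
}

_OCCP_TO_REPORTER = {
    "MD": "physician",
    "PH": "pharmacist",
    "OT": "other-health-professional",
    "RN": "registered-nurse",
    "HP": "health-professional",
    "CN": "consumer",
}
_REPORTER_TO_OCCP = {v: k for k, v in _OCCP_TO_REPORTER.items()}

_OUTC_TO_LABEL = {
    "HO": "hospitalization",
    "DE": "death",
    "LT": "life-threatening",
    "DS": "disability",
}
_LABEL_TO_OUTC = {v: k for k, v in _OUTC_TO_LABEL.items()}
_LABEL_TO_OUTC["other-serious"] = "OT"

# years per unit of each FAERS age code
_AGE_FACTORS = {"YR": 1.0, "": 1.0, "DEC": 10.0, "MON": 1 / 12.0,
                "WK": 1 / 52.1429, "DY": 1 / 365.25, "HR": 1 / 8766.0}


class DialectError(ValueError):
    pass


class MissingTableError(FileNotFoundError):
    pass


# ---------------------------------------------------------------------------
# field escaping — FAERS itself never quotes, but synthetic fixtures may put
# the delimiter inside a free-text field; round-trips must preserve it.

def _escape(value: str, delim: str) -> str:
    out = value.replace("\\", "\\\\")
    if delim == "\t":
        return out.replace("\t", "\\t")
    return out.replace(delim, "\\" + delim)


def _split_line(line: str, delim: str) -> list[str]:
    fields: list[str] = []
    cur: list[str] = []
    i, n = 0, len(line)
    while i < n:
        ch = line[i]
        if ch == "\\" and i + 1 < n:
            nxt = line[i + 1]
            if delim == "\t" and nxt == "t":
                cur.append("\t")
            else:
                cur.append(nxt)
            i += 2
            continue
        if ch == delim:
            fields.append("".join(cur))
            cur = []
        else:
            cur.append(ch)
        i += 1
    fields.append("".join(cur))
    return fields


def _delim(dialect: str) -> str:
    if dialect == "faers-ascii":
        return "$"
    if dialect == "simple-tsv":
        return "\t"
    raise DialectError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")


# ---------------------------------------------------------------------------
# reading

def _find_table_file(path: Path, table: str, dialect: str) -> Path | None:
    if dialect == "faers-ascii":
        hits = sorted(path.glob(f"{table}*.txt")) + sorted(path.glob(f"{table.lower()}*.txt"))
    else:
        hits = [p for p in (path / f"{table}.tsv", path / f"{table.lower()}.tsv") if p.exists()]
    return hits[0] if hits else None


def _read_table(fp: Path, table: str, delim: str, counts: dict, passthrough: dict) -> pd.DataFrame:
    cols = _FILE_COLUMNS[table]
    with open(fp, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh]
    if not lines:
        counts[table] = {"in": 0, "loaded": 0, "quarantined": 0}
        return pd.DataFrame(columns=cols)
    header = [h.strip().lower() for h in _split_line(lines[0], delim)]
    known_idx = {c: header.index(c) for c in cols if c in header}
    extra = [(h, j) for j, h in enumerate(header) if h not in cols]
    rows, extra_rows, quarantined = [], [], 0
    for ln in lines[1:]:
        if not ln.strip():
            continue
        parts = _split_line(ln, delim)
        if len(parts) != len(header):
            quarantined += 1
            continue
        rows.append([parts[known_idx[c]] if c in known_idx else "" for c in cols])
        if extra:
            extra_rows.append([parts[j] for _, j in extra])
    counts[table] = {"in": len(rows) + quarantined, "loaded": len(rows),
                     "quarantined": quarantined}
    if quarantined:
        logger.warning("%s: quarantined %d malformed rows", fp.name, quarantined)
    if extra:
        passthrough[table] = pd.DataFrame(extra_rows, columns=[h for h, _ in extra])
    return pd.DataFrame(rows, columns=cols, dtype=object)


def _age_to_years(age: pd.Series, cod: pd.Series) -> pd.Series:
    vals = pd.to_numeric(age.str.strip(), errors="coerce")
    factors = cod.str.strip().str.upper().map(_AGE_FACTORS)
    return vals * factors


def read_quarter(path: str | Path, dialect: str = "faers-ascii") -> ReportBundle:
    """Load one quarter directory into a normalized :class:`ReportBundle`."""
    delim = _delim(dialect)
    path = Path(path)
    counts: dict = {}
    passthrough: dict = {}
    raw: dict[str, pd.DataFrame] = {}
    for table in ALL_TABLES:
        fp = _find_table_file(path, table, dialect)
        if fp is None:
            if table in MANDATORY_TABLES:
                raise MissingTableError(
                    f"mandatory table file {table} not found in {path} (dialect {dialect})")
            raw[table] = pd.DataFrame(columns=_FILE_COLUMNS[table])
            counts[table] = {"in": 0, "loaded": 0, "quarantined": 0}
            continue
        raw[table] = _read_table(fp, table, delim, counts, passthrough)

    demo = raw["DEMO"]
    sex = demo["sex"].str.strip().str.upper()
    reports = pd.DataFrame({
        "primaryid": demo["primaryid"].str.strip(),
        "caseid": demo["caseid"].str.strip(),
        "event_dt": demo["event_dt"].str.strip(),
        "fda_dt": demo["fda_dt"].str.strip(),
        "sex": sex.where(sex.isin(["M", "F"]), "unknown"),
        "age_years": _age_to_years(demo["age"], demo["age_cod"]),
        "country": demo["occr_country"].str.strip(),
        "reporter_code": demo["occp_cod"].str.strip().str.upper()
                              .map(_OCCP_TO_REPORTER).fillna("unknown"),
    })
    known = set(reports["primaryid"])

    def _quarantine_orphans(df: pd.DataFrame, table: str) -> pd.DataFrame:
        if not len(df):
            return df
        pid = df["primaryid"].str.strip()
        ok = pid.isin(known)
        n_bad = int((~ok).sum())
        if n_bad:
            counts[table]["quarantined"] += n_bad
            counts[table]["loaded"] -= n_bad
            logger.warning("%s: quarantined %d rows referencing unknown primaryid",
                           table, n_bad)
        return df[ok.values].reset_index(drop=True)

    drug = _quarantine_orphans(raw["DRUG"], "DRUG")
    role = drug["role_cod"].str.strip().str.upper()
    drugs = pd.DataFrame({
        "primaryid": drug["primaryid"].str.strip(),
        "drug_seq": drug["drug_seq"].str.strip(),
        "name_raw": drug["drugname"],
        "name_norm": drug["prod_ai"],
        "role": role,
    })
    ther = _quarantine_orphans(raw["THER"], "THER")
    if len(ther):
        starts = ther.assign(primaryid=ther["primaryid"].str.strip(),
                             drug_seq=ther["dsg_drug_seq"].str.strip())
        starts = starts[["primaryid", "drug_seq", "start_dt"]].drop_duplicates(
            ["primaryid", "drug_seq"])
        drugs = drugs.merge(starts, on=["primaryid", "drug_seq"], how="left")
        drugs["start_dt"] = drugs["start_dt"].fillna("").str.strip()
    else:
        drugs["start_dt"] = ""

    reac = _quarantine_orphans(raw["REAC"], "REAC")
    reactions = pd.DataFrame({"primaryid": reac["primaryid"].str.strip(),
                              "pt": reac["pt"].str.strip()})
    outc = _quarantine_orphans(raw["OUTC"], "OUTC")
    outcomes = pd.DataFrame({
        "primaryid": outc["primaryid"].str.strip(),
        "outcome": outc["outc_cod"].str.strip().str.upper()
                       .map(_OUTC_TO_LABEL).fillna("other-serious"),
    })
    indi = _quarantine_orphans(raw["INDI"], "INDI")
    indications = pd.DataFrame({
        "primaryid": indi["primaryid"].str.strip(),
        "drug_seq": indi["indi_drug_seq"].str.strip(),
        "indication_pt": indi["indi_pt"].str.strip(),
    })

    bundle = ReportBundle(reports=reports, drugs=drugs, reactions=reactions,
                          outcomes=outcomes, indications=indications,
                          meta={"row_counts": counts, "passthrough": passthrough,
                                "dialect": dialect, "source": str(path)})
    return bundle


def read_deleted_cases(path: str | Path) -> set[str]:
    """Deleted-case id list: one caseid per line, de-duplicated, kept as strings
    (leading zeros preserved so zero-padded ids still match DEMO caseids)."""
    with open(path, encoding="utf-8") as fh:
        return {line.strip() for line in fh if line.strip()}


# ---------------------------------------------------------------------------
# writing

def _fmt_age(age_years: float) -> tuple[str, str]:
    if age_years is None or (isinstance(age_years, float) and math.isnan(age_years)):
        return "", ""
    v = float(age_years)
    s = str(int(v)) if v == int(v) else repr(v)
    return s, "YR"


def write_bundle(bundle: ReportBundle, path: str | Path,
                 dialect: str = "faers-ascii", quarter: str = "25Q1") -> list[Path]:
    """Write a bundle as one quarter in the given dialect; returns file paths."""
    delim = _delim(dialect)
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    r = bundle.reports
    ages = [_fmt_age(a) for a in pd.to_numeric(r["age_years"], errors="coerce")]
    demo = pd.DataFrame({
        "primaryid": r["primaryid"], "caseid": r["caseid"],
        "event_dt": r["event_dt"].fillna(""), "fda_dt": r["fda_dt"].fillna(""),
        "age": [a for a, _ in ages], "age_cod": [c for _, c in ages],
        "sex": r["sex"].map(lambda s: s if s in ("M", "F") else ""),
        "occp_cod": r["reporter_code"].map(_REPORTER_TO_OCCP).fillna(""),
        "occr_country": r["country"].fillna(""),
    })
    d = bundle.drugs
    drug = pd.DataFrame({
        "primaryid": d["primaryid"], "caseid": _caseid_for(bundle, d["primaryid"]),
        "drug_seq": d["drug_seq"], "role_cod": d["role"],
        "drugname": d["name_raw"].fillna(""), "prod_ai": d["name_norm"].fillna(""),
    })
    ther_src = d[d["start_dt"].fillna("") != ""]
    ther = pd.DataFrame({
        "primaryid": ther_src["primaryid"],
        "caseid": _caseid_for(bundle, ther_src["primaryid"]),
        "dsg_drug_seq": ther_src["drug_seq"],
        "start_dt": ther_src["start_dt"], "end_dt": "",
    })
    reac = pd.DataFrame({
        "primaryid": bundle.reactions["primaryid"],
        "caseid": _caseid_for(bundle, bundle.reactions["primaryid"]),
        "pt": bundle.reactions["pt"],
    })
    outc = pd.DataFrame({
        "primaryid": bundle.outcomes["primaryid"],
        "caseid": _caseid_for(bundle, bundle.outcomes["primaryid"]),
        "outc_cod": bundle.outcomes["outcome"].map(_LABEL_TO_OUTC).fillna("OT"),
    })
    indi = pd.DataFrame({
        "primaryid": bundle.indications["primaryid"],
        "caseid": _caseid_for(bundle, bundle.indications["primaryid"]),
        "indi_drug_seq": bundle.indications["drug_seq"],
        "indi_pt": bundle.indications["indication_pt"],
    })
    tables = {"DEMO": demo, "DRUG": drug, "REAC": reac, "OUTC": outc,
              "THER": ther, "INDI": indi}
    written = []
    for name, df in tables.items():
        cols = _FILE_COLUMNS[name]
        fp = path / (f"{name}{quarter}.txt" if dialect == "faers-ascii" else f"{name}.tsv")
        with open(fp, "w", encoding="utf-8") as fh:
            fh.write(delim.join(cols) + "\n")
            for row in df[cols].itertuples(index=False):
                fh.write(delim.join(_escape(str(v) if v is not None else "", delim)
                                    for v in row) + "\n")
        written.append(fp)
    return written


def _caseid_for(bundle: ReportBundle, pids: pd.Series) -> pd.Series:
    lookup = bundle.reports.set_index("primaryid")["caseid"]
    return pids.map(lookup).fillna("")
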