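import numpy as np
import pandas as pd
import pytest

from faersig.bundle import ReportBundle


def make_bundle(reports=None, drugs=None, reactions=None, outcomes=None,
                indications=None) -> ReportBundle:
    """Hand-build a bundle from lists of dicts, filling default columns."""
    rep_defaults = {"caseid": "", "event_dt": "", "fda_dt": "20200101",
                    "sex": "unknown", "age_years": np.nan, "country": "US",
                    "reporter_code": "unknown"}
    drug_defaults = {"drug_seq": "1", "name_raw": "", "name_norm": "",
                     "role": "PS", "start_dt": ""}
    def table(rows, defaults, cols):
        if not rows:
            return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
        full = [{**defaults, **row} for row in rows]
        return pd.DataFrame(full)[cols]

    b = ReportBundle()
    b.reports = table(reports or [], rep_defaults,
                      ["primaryid", "caseid", "event_dt", "fda_dt", "sex",
                       "age_years", "country", "reporter_code"])
    b.drugs = table(drugs or [], drug_defaults,
                    ["primaryid", "drug_seq", "name_raw", "name_norm", "role",
                     "start_dt"])
    b.reactions = table(reactions or [], {},
                        ["primaryid", "pt"])
    b.outcomes = table(outcomes or [], {}, ["primaryid", "outcome"])
    b.indications = table(indications or [], {"drug_seq": "1"},
                          ["primaryid", "drug_seq", "indication_pt"])
    return b


@pytest.fixture
def bundle_builder():
    return make_bundle


@pytest.fixture
def two_drug_bundle():
    """100 reports: 10 with drugx (2 of them with pty), 90 without
    (10 of them with pty) — the hand-countable 2×2 is a=2,b=8,c=10,d=80
    when every report carries exactly one PT."""
    reports, drugs, reactions = [], [], []
    k = 0
    def add(drug, pt):
        nonlocal k
        pid = str(1000 + k)
        reports.append({"primaryid": pid, "caseid": str(k)})
        drugs.append({"primaryid": pid, "name_raw": drug, "name_norm": drug})
        reactions.append({"primaryid": pid, "pt": pt})
        k += 1
    for _ in range(2):
        add("drugx", "pty")
    for _ in range(8):
        add("drugx", "other_pt")
    for _ in range(10):
        add("drugz", "pty")
    for _ in range(80):
        add("drugz", "other_pt")
    return make_bundle(reports, drugs, reactions)
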