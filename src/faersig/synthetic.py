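"""Synthetic spontaneous-report bundles with known ground truth.

Real FAERS data cannot be redistributed, and a screening pipeline
validated only against itself proves nothing. This module generates
FAERS-shaped report bundles from an explicit generative model so that
every downstream stage — cleaning, contingency counting, the four
disproportionality estimators, stratification, time-to-onset — can be
tested against analytically known expectations.

Generative model (per base report):

* one primary-suspect (PS) drug drawn from a categorical marginal;
* a Poisson(``co_drug_mean``) number of concomitant/secondary-suspect
  co-medications drawn from a separate co-drug vocabulary (so the PS
  universe and the co-medication universe never mix);
* ``1 + Poisson(extra_events_mean)`` reaction PTs drawn i.i.d. from the
  event marginal *tilted* by the planted relative reporting ratio ρ for
  the report's PS drug and renormalized — ρ = 1 everywhere except the
  explicitly planted (drug, PT) pairs;
* demographic fields (sex, age bin, reporter, country) and non-exclusive
  serious outcomes from categorical/Bernoulli marginals;
* a therapy start date uniform in the study window, a true onset delay
  drawn from Weibull(scale ``tto_scale``, shape ``tto_shape``) days, an
  event date = start + onset, and an FDA receipt date shortly after;
* event dates knocked out at ``missing_event_date_rate`` and start/event
  dates truncated to partial precision at ``partial_date_rate``;
* a fraction ``duplicate_rate`` of reports cloned under the same CASEID
  with a strictly later FDA_DT and a larger PRIMARYID, exercising the
  deduplication rules.

The accompanying :class:`GroundTruth` carries the *expected* 2×2 cell
counts of every (drug, PT) pair under this model, computed in closed
form, plus the planted pairs and each case's true onset delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import io as _io
from .bundle import ReportBundle

_EPOCH = np.datetime64("1970-01-01")


class ConfigError(ValueError):
    pass


class DrugSpec(BaseModel):
    name: str
    prob: float = Field(gt=0, le=1)


class EventSpec(BaseModel):
    pt: str
    prob: float = Field(gt=0, le=1)
    soc: str


class PlantedSignal(BaseModel):
    """A (drug, PT) pair whose reporting probability is multiplied by rho."""

    drug: str
    pt: str
    rho: float = Field(ge=0)


_DEFAULT_SOC_PTS: dict[str, list[str]] = {
    "blood and lymphatic system disorders":
        ["anaemia", "neutropenia", "thrombocytopenia", "pancytopenia",
         "febrile neutropenia", "leukopenia"],
    "gastrointestinal disorders":
        ["nausea", "vomiting", "diarrhoea", "constipation", "stomatitis",
         "abdominal pain"],
    "general disorders and administration site conditions":
        ["fatigue", "pyrexia", "asthenia", "oedema peripheral", "malaise",
         "chest pain"],
    "respiratory, thoracic and mediastinal disorders":
        ["dyspnoea", "cough", "interstitial lung disease", "pneumonitis",
         "pleural effusion", "hypoxia"],
    "skin and subcutaneous tissue disorders":
        ["rash", "pruritus", "alopecia", "erythema", "dry skin", "urticaria"],
    "renal and urinary disorders":
        ["acute kidney injury", "renal failure", "hypercreatininaemia",
         "tubulointerstitial nephritis", "haematuria", "proteinuria"],
    "infections and infestations":
        ["pneumonia", "sepsis", "urinary tract infection", "nasopharyngitis",
         "septic shock", "cellulitis"],
    "nervous system disorders":
        ["headache", "dizziness", "neuropathy peripheral", "dysgeusia",
         "syncope", "somnolence"],
    "metabolism and nutrition disorders":
        ["decreased appetite", "dehydration", "hyponatraemia", "hypokalaemia",
         "hyperglycaemia", "hypomagnesaemia"],
    "cardiac disorders":
        ["atrial fibrillation", "cardiac failure", "myocardial infarction",
         "palpitations", "tachycardia", "pericardial effusion"],
}


def _default_drugs() -> list[DrugSpec]:
    names = ["pemetrexed", "paclitaxel", "metformin", "atorvastatin",
             "lisinopril", "ibuprofen", "warfarin", "amoxicillin",
             "omeprazole", "carvedilol"]
    return [DrugSpec(name=n, prob=0.1) for n in names]


def _default_events() -> list[EventSpec]:
    pts = [(pt, soc) for soc, lst in _DEFAULT_SOC_PTS.items() for pt in lst]
    # mildly Zipf-like marginal so term frequencies span an order of magnitude
    weights = np.array([1.0 / (5 + i) for i in range(len(pts))])
    probs = weights / weights.sum()
    return [EventSpec(pt=pt, prob=float(p), soc=soc)
            for (pt, soc), p in zip(pts, probs)]


def _default_sex() -> dict[str, float]:
    return {"M": 0.548, "F": 0.356, "unknown": 1 - 0.548 - 0.356}


def _default_age() -> dict[str, float]:
    m = {"<18": 0.003, "18-64": 0.371, "65-85": 0.381, ">85": 0.004}
    m["unknown"] = 1 - sum(m.values())
    return m


def _default_reporter() -> dict[str, float]:
    m = {"physician": 0.065, "consumer": 0.224, "health-professional": 0.135,
         "other-health-professional": 0.106, "pharmacist": 0.065,
         "registered-nurse": 0.001}
    m["unknown"] = 1 - sum(m.values())
    return m


def _default_outcomes() -> dict[str, float]:
    return {"hospitalization": 0.340, "death": 0.185, "life-threatening": 0.051,
            "disability": 0.009, "other-serious": 0.293}


def _default_countries() -> dict[str, float]:
    m = {"US": 0.234, "FR": 0.188, "JP": 0.107, "DE": 0.073, "IT": 0.065,
         "CN": 0.055, "GB": 0.035, "ES": 0.029, "CA": 0.023, "NL": 0.019}
    m["OTHER"] = 1 - sum(m.values())
    return m


def _default_indications() -> dict[str, float]:
    m = {"lung neoplasm malignant": 0.653, "mesothelioma": 0.060}
    m["unknown"] = 1 - sum(m.values())
    return m


class SyntheticConfig(BaseModel):
    """Full generative specification for one synthetic bundle."""

    n_reports: int = Field(default=50_000, gt=0)
    drugs: list[DrugSpec] = Field(default_factory=_default_drugs)
    events: list[EventSpec] = Field(default_factory=_default_events)
    planted: list[PlantedSignal] = Field(default_factory=list)
    co_drugs: list[str] = Field(default_factory=lambda: [
        "cisplatin", "carboplatin", "pembrolizumab", "bevacizumab",
        "dexamethasone", "folic acid"])
    co_drug_mean: float = Field(default=1.5, ge=0)
    extra_events_mean: float = Field(default=2.0, ge=0)
    duplicate_rate: float = Field(default=0.05, ge=0, lt=1)
    missing_event_date_rate: float = Field(default=0.2, ge=0, le=1)
    partial_date_rate: float = Field(default=0.05, ge=0, le=1)
    sex_marginals: dict[str, float] = Field(default_factory=_default_sex)
    age_marginals: dict[str, float] = Field(default_factory=_default_age)
    reporter_marginals: dict[str, float] = Field(default_factory=_default_reporter)
    outcome_marginals: dict[str, float] = Field(default_factory=_default_outcomes)
    country_marginals: dict[str, float] = Field(default_factory=_default_countries)
    indication_marginals: dict[str, float] = Field(default_factory=_default_indications)
    tto_scale: float = Field(default=57.99, gt=0)
    tto_shape: float = Field(default=0.69, gt=0)
    start_window: tuple[str, str] = ("20050101", "20231231")
    seed: int = 0

    @model_validator(mode="after")
    def _check_marginals(self) -> "SyntheticConfig":
        def check(name: str, total: float) -> None:
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"{name} probabilities sum to {total!r}, not 1 (within 1e-9)")
        check("drug", sum(d.prob for d in self.drugs))
        check("event", sum(e.prob for e in self.events))
        for name in ("sex", "age", "reporter", "country", "indication"):
            check(name, sum(getattr(self, f"{name}_marginals").values()))
        names = [d.name for d in self.drugs]
        pts = [e.pt for e in self.events]
        if len(set(names)) != len(names) or len(set(pts)) != len(pts):
            raise ValueError("drug names and event PTs must be unique")
        for p in self.planted:
            if p.drug not in names:
                raise ValueError(f"planted drug {p.drug!r} not in drug list")
            if p.pt not in pts:
                raise ValueError(f"planted PT {p.pt!r} not in event list")
        return self

    def meddra_frame(self) -> pd.DataFrame:
        """The PT→primary-SOC map implied by the event list."""
        return pd.DataFrame({"pt": [e.pt for e in self.events],
                             "soc": [e.soc for e in self.events]})


@dataclass
class GroundTruth:
    """Closed-form expectations under the generative model.

    ``expected_cells`` has one row per (drug, PT) with the expected
    pair-level 2×2 cells (a, b, c, d) of the *deduplicated* bundle;
    each row satisfies a+b+c+d = expected total report–PT pairs.
    ``onset_days`` maps caseid → the true (unrounded) onset delay.
    """

    expected_cells: pd.DataFrame
    planted: list[PlantedSignal] = field(default_factory=list)
    onset_days: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def expected_table(self, drug: str, pt: str) -> tuple[float, float, float, float]:
        row = self.expected_cells[(self.expected_cells["drug"] == drug)
                                  & (self.expected_cells["pt"] == pt)]
        if not len(row):
            raise KeyError((drug, pt))
        r = row.iloc[0]
        return float(r["a"]), float(r["b"]), float(r["c"]), float(r["d"])

    def expected_ror(self, drug: str, pt: str) -> float:
        a, b, c, d = self.expected_table(drug, pt)
        return (a * d) / (b * c)


def _tilted_probs(config: SyntheticConfig) -> np.ndarray:
    """Per-drug event distribution: base PT probs × ρ, renormalized.

    Returns an (n_drugs, n_events) row-stochastic matrix.
    """
    base = np.array([e.prob for e in config.events])
    names = [d.name for d in config.drugs]
    pts = {e.pt: j for j, e in enumerate(config.events)}
    q = np.tile(base, (len(names), 1))
    for p in config.planted:
        q[names.index(p.drug), pts[p.pt]] *= p.rho
    q /= q.sum(axis=1, keepdims=True)
    return q


def expected_cells(config: SyntheticConfig) -> pd.DataFrame:
    """Expected pair-level 2×2 cells for every (drug, PT) pair.

    With k ~ 1 + Poisson(μ) i.i.d. PT draws per report and distinct-pair
    counting, a report whose PS drug gives the PT probability q mentions
    the PT with probability h(q) = 1 − (1−q)·exp(−μq).
    """
    mu = config.extra_events_mean
    q = _tilted_probs(config)
    h = 1.0 - (1.0 - q) * np.exp(-mu * q)          # (n_drugs, n_events)
    p_drug = np.array([d.prob for d in config.drugs])
    n = config.n_reports
    per_drug_pairs = n * p_drug[:, None] * h        # expected a for each pair
    a = per_drug_pairs
    ab = per_drug_pairs.sum(axis=1, keepdims=True)  # total pairs per drug
    ac = per_drug_pairs.sum(axis=0, keepdims=True)  # total pairs per PT
    N = per_drug_pairs.sum()
    b = ab - a
    c = ac - a
    d = N - ab - c
    names = [dd.name for dd in config.drugs]
    pts = [e.pt for e in config.events]
    rows = []
    for i, drug in enumerate(names):
        for j, pt in enumerate(pts):
            rows.append((drug, pt, a[i, j], b[i, j], c[i, j], d[i, j]))
    return pd.DataFrame(rows, columns=["drug", "pt", "a", "b", "c", "d"])


def _draw_categorical(rng: np.random.Generator, marginals: dict[str, float],
                      n: int) -> np.ndarray:
    labels = np.array(list(marginals.keys()), dtype=object)
    p = np.array(list(marginals.values()), dtype=float)
    p = p / p.sum()
    return labels[rng.choice(len(labels), size=n, p=p)]


def _dates_from_days(days: np.ndarray) -> np.ndarray:
    dt = _EPOCH + days.astype("timedelta64[D]")
    return np.datetime_as_string(dt, unit="D")


def _compact(date_strs: np.ndarray) -> np.ndarray:
    return np.char.replace(date_strs, "-", "")


def generate_bundle(config: SyntheticConfig) -> tuple[ReportBundle, GroundTruth]:
    """Draw one bundle (plus its ground truth) from the generative model."""
    rng = np.random.default_rng(config.seed)
    n = config.n_reports
    nd, ne = len(config.drugs), len(config.events)
    drug_names = np.array([d.name for d in config.drugs], dtype=object)
    pt_names = np.array([e.pt for e in config.events], dtype=object)

    pid = np.array([str(10_000_000 + 10 * i) for i in range(n)], dtype=object)
    caseid = np.array([str(5_000_000 + i) for i in range(n)], dtype=object)

    p_drug = np.array([d.prob for d in config.drugs])
    drug_idx = rng.choice(nd, size=n, p=p_drug / p_drug.sum())

    # events: 1 + Poisson extra draws from the PS drug's tilted distribution
    m = 1 + rng.poisson(config.extra_events_mean, size=n)
    q = _tilted_probs(config)
    ev_pid: list[np.ndarray] = []
    ev_idx: list[np.ndarray] = []
    for d in range(nd):
        mask = drug_idx == d
        counts = m[mask]
        total = int(counts.sum())
        if total == 0:
            continue
        draws = rng.choice(ne, size=total, p=q[d])
        ev_pid.append(np.repeat(pid[mask], counts))
        ev_idx.append(draws)
    reactions = pd.DataFrame({
        "primaryid": np.concatenate(ev_pid),
        "pt": pt_names[np.concatenate(ev_idx)],
    })

    # demographics
    sex = _draw_categorical(rng, config.sex_marginals, n)
    age_bin = _draw_categorical(rng, config.age_marginals, n)
    age = np.full(n, np.nan)
    bin_ranges = {"<18": (1, 18), "18-64": (18, 65), "65-85": (65, 86),
                  ">85": (86, 100)}
    for label, (lo, hi) in bin_ranges.items():
        mask = age_bin == label
        if mask.any():
            age[mask] = rng.integers(lo, hi, size=int(mask.sum()))
    reporter = _draw_categorical(rng, config.reporter_marginals, n)
    country = _draw_categorical(rng, config.country_marginals, n)

    # dates: start uniform in window, onset Weibull, receipt shortly after
    w0 = np.datetime64(f"{config.start_window[0][:4]}-{config.start_window[0][4:6]}-"
                       f"{config.start_window[0][6:]}")
    w1 = np.datetime64(f"{config.start_window[1][:4]}-{config.start_window[1][4:6]}-"
                       f"{config.start_window[1][6:]}")
    window_days = int((w1 - w0) / np.timedelta64(1, "D")) + 1
    start_day = (w0 - _EPOCH) / np.timedelta64(1, "D") + rng.integers(0, window_days, n)
    onset = config.tto_scale * rng.weibull(config.tto_shape, size=n)
    event_day = start_day + np.round(onset)
    fda_day = event_day + rng.integers(0, 91, size=n)

    start_dt = _compact(_dates_from_days(start_day))
    event_dt = _compact(_dates_from_days(event_day))
    fda_dt = _compact(_dates_from_days(fda_day))

    event_dt = np.where(rng.random(n) < config.missing_event_date_rate, "", event_dt)
    part_s = rng.random(n) < config.partial_date_rate
    part_e = rng.random(n) < config.partial_date_rate
    start_dt = np.asarray([(s[:6] if trunc else s)
                           for s, trunc in zip(start_dt, part_s)], dtype=object)
    event_dt = np.asarray([(s[:6] if (trunc and s) else s)
                           for s, trunc in zip(event_dt, part_e)], dtype=object)

    reports = pd.DataFrame({
        "primaryid": pid, "caseid": caseid, "event_dt": event_dt,
        "fda_dt": fda_dt, "sex": sex, "age_years": age, "country": country,
        "reporter_code": reporter,
    })

    # drug rows: PS row with a start date, then co-medications
    ps = pd.DataFrame({
        "primaryid": pid, "drug_seq": "1",
        "name_raw": drug_names[drug_idx],
        "name_norm": [s.lower() for s in drug_names[drug_idx]],
        "role": "PS", "start_dt": start_dt,
    })
    k_co = rng.poisson(config.co_drug_mean, size=n) if config.co_drugs else np.zeros(n, int)
    co_total = int(k_co.sum())
    if co_total:
        co_names = np.array(config.co_drugs, dtype=object)
        co_draw = co_names[rng.integers(0, len(co_names), size=co_total)]
        co_role = np.where(rng.random(co_total) < 0.5, "SS", "C")
        co_pid = np.repeat(pid, k_co)
        seq = np.concatenate([np.arange(2, 2 + k) for k in k_co if k > 0]) \
            if co_total else np.array([], dtype=int)
        co = pd.DataFrame({
            "primaryid": co_pid, "drug_seq": seq.astype(str),
            "name_raw": co_draw, "name_norm": [s.lower() for s in co_draw],
            "role": co_role, "start_dt": "",
        })
        drugs = pd.concat([ps, co], ignore_index=True)
    else:
        drugs = ps

    # serious outcomes: independent Bernoulli per category
    out_frames = []
    for label, prob in config.outcome_marginals.items():
        mask = rng.random(n) < prob
        if mask.any():
            out_frames.append(pd.DataFrame({"primaryid": pid[mask], "outcome": label}))
    outcomes = (pd.concat(out_frames, ignore_index=True) if out_frames
                else pd.DataFrame({"primaryid": [], "outcome": []}))

    indication = _draw_categorical(rng, config.indication_marginals, n)
    has_ind = indication != "unknown"
    indications = pd.DataFrame({
        "primaryid": pid[has_ind], "drug_seq": "1",
        "indication_pt": indication[has_ind],
    })

    bundle = ReportBundle(reports=reports, drugs=drugs, reactions=reactions,
                          outcomes=outcomes, indications=indications)

    # duplicates: clone whole reports under the same caseid, later FDA_DT,
    # larger PRIMARYID
    n_dup = int(np.floor(config.duplicate_rate * n))
    if n_dup:
        dup_rows = np.sort(rng.choice(n, size=n_dup, replace=False))
        dup_pid = np.array([str(int(p) + 1) for p in pid[dup_rows]], dtype=object)
        lag = rng.integers(1, 91, size=n_dup)
        dup_fda = _compact(_dates_from_days(fda_day[dup_rows] + lag))
        clones = reports.iloc[dup_rows].copy()
        clones["primaryid"] = dup_pid
        clones["fda_dt"] = dup_fda
        remap = dict(zip(pid[dup_rows], dup_pid))

        def clone_children(df: pd.DataFrame) -> pd.DataFrame:
            sub = df[df["primaryid"].isin(remap)].copy()
            sub["primaryid"] = sub["primaryid"].map(remap)
            return sub

        bundle.reports = pd.concat([reports, clones], ignore_index=True)
        bundle.drugs = pd.concat([drugs, clone_children(drugs)], ignore_index=True)
        bundle.reactions = pd.concat([reactions, clone_children(reactions)],
                                     ignore_index=True)
        bundle.outcomes = pd.concat([outcomes, clone_children(outcomes)],
                                    ignore_index=True)
        bundle.indications = pd.concat([indications, clone_children(indications)],
                                       ignore_index=True)

    bundle.meta = {"synthetic": True, "seed": config.seed, "n_base_reports": n,
                   "n_duplicates": n_dup}
    truth = GroundTruth(
        expected_cells=expected_cells(config),
        planted=list(config.planted),
        onset_days=pd.Series(onset, index=pd.Index(caseid, name="caseid"),
                             name="onset_days"),
    )
    return bundle, truth


def write_fixture(bundle: ReportBundle, path, dialect: str = "faers-ascii",
                  quarter: str = "25Q1") -> list:
    """Write a bundle to disk so it round-trips through ``io.read_quarter``."""
    return _io.write_bundle(bundle, path, dialect=dialect, quarter=quarter)
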