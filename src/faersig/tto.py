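"""Time-to-onset (TTO) analysis: extraction, binning, cumulative
incidence with group comparison, and Weibull modelling.

TTO is the calendar-day difference EVENT_DT − START_DT, where START_DT
is the earliest full-precision therapy start date of the target drug's
rows in a report. Only reports with both dates at day precision and a
non-negative delay within a plausibility cap contribute; exclusions are
counted, never silent.

The Weibull model treats every reported delay as an observed event (a
spontaneous-report database contains no censored subjects, so the
"cumulative incidence" is a plain ECDF conditional on an event having
been reported — not a survival analysis). With scale α (days) and
shape β, CDF(t) = 1 − exp(−(t/α)^β); by construction CDF(α) = 1 − 1/e
≈ 63.2% for any fit, so α is the characteristic onset time. Shape
β < 1 is the "early failure" pattern (onset hazard decreasing with
time), β > 1 "wear-out", and β ≈ 1 a time-constant (exponential)
pattern; the classification uses the 95% CI of β: entirely below 1 →
early, entirely above → wear-out, spanning 1 → random.

Fitting is maximum likelihood on (log α, log β) with confidence
intervals from the observed information matrix (normal approximation on
the log parameters, exponentiated), which keeps both parameters
positive. Zero-day onsets are shifted to 0.5 days for likelihood
validity, since the Weibull support is t > 0 but same-day onsets are
real in spontaneous reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from statsmodels.tools.numdiff import approx_hess

from lifelines.statistics import multivariate_logrank_test

from .bundle import ReportBundle
from .contingency import MedDRAMap, map_terms
from . import dates, strata

Z95 = 1.959963984540054

ACCOUNTING_MODES = ("per-report", "per-pair")

DEFAULT_BINS = ((0, 30), (31, 60), (61, 90), (91, 180), (181, 360),
                (361, math.inf))


# ---------------------------------------------------------------------------
# extraction

def compute_tto(bundle: ReportBundle, target_drug: str,
                accounting: str = "per-report",
                cap_days: float = 3650.0) -> pd.DataFrame:
    """TTO samples with stratum labels.

    ``per-report`` yields one sample per qualifying report; ``per-pair``
    repeats the report's delay once per distinct reaction PT (the
    convention is a modelling choice — both are supported because the
    attribution of a single onset date to multiple PTs is ambiguous).
    Frame attrs count the exclusions (unusable dates, negative delays,
    over-cap delays).
    """
    if accounting not in ACCOUNTING_MODES:
        raise ValueError(f"accounting must be one of {ACCOUNTING_MODES}")
    r = bundle.reports
    d = bundle.drugs
    is_target = d["name_norm"].fillna("").str.lower() == target_drug.lower()
    starts = d[is_target & dates.full_mask(d["start_dt"])]
    min_start = starts.groupby("primaryid")["start_dt"].min()

    frame = r[["primaryid", "event_dt"]].copy()
    frame["start_dt"] = frame["primaryid"].map(min_start)
    usable = dates.full_mask(frame["event_dt"]) & frame["start_dt"].notna()
    days = dates.days_between_series(frame["event_dt"], frame["start_dt"].fillna(""))
    negative = usable & (days < 0)
    over_cap = usable & (days > cap_days)
    keep = usable & ~negative & ~over_cap

    samples = pd.DataFrame({
        "primaryid": frame.loc[keep, "primaryid"],
        "days": days[keep].astype(float),
    })
    labels = pd.DataFrame({
        "primaryid": r["primaryid"],
        "sex": strata._assign(bundle, "sex"),
        "age_bin": strata._assign(bundle, "age"),
        "reporter_group": strata._assign(bundle, "reporter"),
    })
    samples = samples.merge(labels, on="primaryid", how="left")
    if accounting == "per-pair":
        pairs = map_terms(bundle.reactions, None, "PT")
        samples = samples.merge(pairs, on="primaryid", how="inner")
    samples = samples.reset_index(drop=True)
    samples.attrs["excluded"] = {
        "unusable-dates": int((~usable).sum()),
        "negative": int(negative.sum()),
        "over-cap": int(over_cap.sum()),
    }
    samples.attrs["accounting"] = accounting
    return samples


def bin_tto(days, bins=DEFAULT_BINS) -> pd.DataFrame:
    """Histogram over day ranges (both endpoints inclusive per bin)."""
    arr = np.asarray(pd.Series(days).dropna(), dtype=float)
    labels = [f"{int(lo)}-{int(hi)}" if math.isfinite(hi) else f">{int(lo) - 1}"
              for lo, hi in bins]
    if arr.size == 0:
        return pd.DataFrame({"bin": labels, "count": 0, "proportion": np.nan})
    edges = [bins[0][0] - 0.5] + [hi + 0.5 for _, hi in bins[:-1]] + [math.inf]
    counts = pd.cut(arr, bins=edges, labels=labels).value_counts() \
        .reindex(labels).fillna(0).astype(int)
    out = pd.DataFrame({"bin": labels, "count": counts.values})
    out["proportion"] = out["count"] / out["count"].sum()
    return out


# ---------------------------------------------------------------------------
# Weibull model

class WeibullFitError(RuntimeError):
    pass


@dataclass
class WeibullFitResults:
    """MLE Weibull fit of onset delays, Table-4 style."""

    alpha: float            # scale, days
    beta: float             # shape, dimensionless
    alpha_ci: tuple[float, float]
    beta_ci: tuple[float, float]
    n: int
    median_days: float
    iqr_days: tuple[float, float]
    loglik: float
    failure_type: str       # early | random | wear-out

    def cdf(self, t) -> np.ndarray | float:
        t = np.asarray(t, dtype=float)
        out = 1.0 - np.exp(-np.power(t / self.alpha, self.beta))
        return float(out) if out.ndim == 0 else out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "n": self.n,
            "median_days": self.median_days,
            "iqr_lo": self.iqr_days[0], "iqr_hi": self.iqr_days[1],
            "scale_alpha": self.alpha,
            "scale_lo": self.alpha_ci[0], "scale_hi": self.alpha_ci[1],
            "shape_beta": self.beta,
            "shape_lo": self.beta_ci[0], "shape_hi": self.beta_ci[1],
            "failure_type": self.failure_type,
        }])

    def summary(self) -> str:
        return (f"Weibull time-to-onset fit (n={self.n})\n"
                f"  median (IQR) days: {self.median_days:.0f} "
                f"({self.iqr_days[0]:.0f}-{self.iqr_days[1]:.0f})\n"
                f"  scale alpha: {self.alpha:.2f} days "
                f"(95% CI {self.alpha_ci[0]:.2f}-{self.alpha_ci[1]:.2f})\n"
                f"  shape beta:  {self.beta:.3f} "
                f"(95% CI {self.beta_ci[0]:.3f}-{self.beta_ci[1]:.3f})\n"
                f"  failure type: {self.failure_type}\n"
                f"  CDF(alpha) = {self.cdf(self.alpha):.3f} (= 1 - 1/e)")


class WeibullTimeToOnset:
    """Model object for the onset-delay distribution.

    ``WeibullTimeToOnset(days).fit()`` returns a
    :class:`WeibullFitResults`; ``days`` may be any sequence of
    non-negative delays (zeros are shifted to 0.5 days).
    """

    def __init__(self, days):
        arr = np.asarray(pd.Series(days).dropna(), dtype=float)
        if np.any(arr < 0):
            raise ValueError("onset delays must be non-negative")
        self.days = np.where(arr == 0.0, 0.5, arr)

    def loglik(self, alpha: float, beta: float) -> float:
        t = self.days
        n = t.size
        return (n * math.log(beta) - n * beta * math.log(alpha)
                + (beta - 1) * float(np.sum(np.log(t)))
                - float(np.sum(np.power(t / alpha, beta))))

    def fit(self) -> WeibullFitResults:
        t = self.days
        n = t.size
        if n < 2:
            raise WeibullFitError(f"need at least 2 samples, got {n}")
        if np.allclose(t, t[0]):
            raise WeibullFitError("degenerate sample: all delays identical")
        logt = np.log(t)
        # moment-style start: Weibull log-life has SD = (π/√6)/β
        beta0 = max((math.pi / math.sqrt(6.0)) / max(float(np.std(logt)), 1e-6), 1e-3)
        alpha0 = math.exp(float(np.mean(logt)) + 0.5772156649 / beta0)

        def nll(theta: np.ndarray) -> float:
            return -self.loglik(math.exp(theta[0]), math.exp(theta[1]))

        x0 = np.array([math.log(alpha0), math.log(beta0)])
        res = optimize.minimize(nll, x0, method="Nelder-Mead",
                                options={"xatol": 1e-9, "fatol": 1e-10,
                                         "maxiter": 10_000})
        if not res.success:
            raise WeibullFitError(f"Weibull MLE did not converge: {res.message}")
        u, v = res.x
        hess = approx_hess(res.x, nll)
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError as exc:
            raise WeibullFitError("singular observed information") from exc
        se_u, se_v = math.sqrt(max(cov[0, 0], 0.0)), math.sqrt(max(cov[1, 1], 0.0))
        alpha, beta = math.exp(u), math.exp(v)
        alpha_ci = (math.exp(u - Z95 * se_u), math.exp(u + Z95 * se_u))
        beta_ci = (math.exp(v - Z95 * se_v), math.exp(v + Z95 * se_v))
        if beta_ci[1] < 1.0:
            failure_type = "early"
        elif beta_ci[0] > 1.0:
            failure_type = "wear-out"
        else:
            failure_type = "random"
        q1, q2, q3 = np.percentile(t, [25, 50, 75])
        return WeibullFitResults(alpha=alpha, beta=beta, alpha_ci=alpha_ci,
                                 beta_ci=beta_ci, n=n, median_days=float(q2),
                                 iqr_days=(float(q1), float(q3)),
                                 loglik=-float(res.fun), failure_type=failure_type)


def fit_weibull(days) -> WeibullFitResults:
    """Functional shorthand for ``WeibullTimeToOnset(days).fit()``."""
    return WeibullTimeToOnset(days).fit()


# ---------------------------------------------------------------------------
# cumulative incidence

@dataclass
class CumulativeIncidence:
    """Per-stratum ECDF step curves and the log-rank comparison."""

    curves: dict[str, pd.DataFrame]   # stratum -> columns (days, cum_incidence)
    test_statistic: float | None
    p_value: float | None
    test: str = "log-rank"

    def to_frame(self) -> pd.DataFrame:
        frames = [df.assign(stratum=k) for k, df in self.curves.items()]
        return pd.concat(frames, ignore_index=True)


def cumulative_incidence(samples: pd.DataFrame,
                         by: str = "sex",
                         include_missing: bool = False) -> CumulativeIncidence:
    """ECDF curves per stratum with a log-rank comparison across strata.

    All delays are observed events (no censoring); with fewer than two
    strata of at least two samples, curves are returned without a test.
    """
    col = {"sex": "sex", "age": "age_bin", "reporter": "reporter_group"}.get(by, by)
    df = samples[[col, "days"]].dropna()
    if not include_missing:
        df = df[df[col] != strata.MISSING]
    curves: dict[str, pd.DataFrame] = {}
    sizes = {}
    for label, grp in df.groupby(col, sort=True):
        t = np.sort(grp["days"].to_numpy(dtype=float))
        ecdf = np.arange(1, t.size + 1) / t.size
        curves[str(label)] = pd.DataFrame({"days": t, "cum_incidence": ecdf})
        sizes[str(label)] = t.size
    eligible = [k for k, v in sizes.items() if v >= 2]
    if len(eligible) < 2:
        return CumulativeIncidence(curves, None, None)
    sub = df[df[col].astype(str).isin(eligible)]
    res = multivariate_logrank_test(sub["days"].to_numpy(dtype=float),
                                    sub[col].astype(str).to_numpy(),
                                    np.ones(len(sub)))
    return CumulativeIncidence(curves, float(res.test_statistic),
                               float(res.p_value))
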