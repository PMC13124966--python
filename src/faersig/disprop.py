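"""Four-algorithm disproportionality analysis and the combined signal rule.

For each 2×2 table (a, b, c, d) with N = a+b+c+d and expected count
E = (a+b)(a+c)/N the module computes:

* ROR — reporting odds ratio (a·d)/(b·c) with the Wald 95% CI
  exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d));
* PRR — [a/(a+b)] / [c/(c+d)] paired with the Pearson χ² statistic
  N(ad−bc)²/[(a+b)(c+d)(a+c)(b+d)] (Yates continuity optional),
  χ² always on the raw cells;
* IC — the BCPNN information component. Default is the closed-form
  shrinkage IC = log2((a+½)/(E+½)) with credibility bound
  IC025 = IC − 3.3(a+½)^−1/2 − 2.0(a+½)^−1; the classic
  moment-approximation (Gaussian on the IC posterior) is selectable;
* EBGM — the multi-item gamma-Poisson shrinker: a two-component gamma
  mixture prior on the relative reporting rate λ, fitted by maximising
  the negative-binomial marginal likelihood over all cells at a MedDRA
  level, with EBGM = 2^E[log2 λ | a] and EBGM05 the 5th posterior
  percentile of λ.

Zero cells trigger the Haldane +0.5 correction on all four cells for
the ratio estimators only (configurable off, yielding undefined-result
markers).

A term is a *signal* when ≥2 of the four methods are positive,
including at least one frequentist (ROR/PRR) and one Bayesian (IC/EBGM)
method; signals backed by ≥100 reports are tiered "prioritized", the
rest "exploratory". Each per-method threshold is configurable. The
one-method ROR rule (ROR > 1 with lower 95% CI > 1) is additionally
reported as a flag.

The screening entry point follows the estimator-object idiom:
``DisproportionalityScreen(bundle, target_drug, level).fit()`` returns a
:class:`ScreenResults` carrying the per-term estimates, flags, tiers and
a ``summary()`` table; ``screen(...)`` is the functional shorthand.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .bundle import ReportBundle
from .contingency import ContingencyTable, MedDRAMap, build_tables

logger = logging.getLogger(__name__)

Z95 = 1.959963984540054  # two-sided 95% normal quantile


def _cells(table) -> tuple[float, float, float, float]:
    if isinstance(table, ContingencyTable):
        return table.cells()
    a, b, c, d = table
    return float(a), float(b), float(c), float(d)


def _haldane(a, b, c, d) -> tuple[float, float, float, float, bool]:
    if min(a, b, c, d) <= 0:
        return a + 0.5, b + 0.5, c + 0.5, d + 0.5, True
    return a, b, c, d, False


# ---------------------------------------------------------------------------
# frequentist estimators

def ror(table, haldane: bool = True) -> tuple[float, float, float]:
    """Reporting odds ratio with Wald 95% CI: (ror, lower, upper)."""
    a, b, c, d = _cells(table)
    a, b, c, d, corrected = _haldane(a, b, c, d)
    if corrected and not haldane:
        return math.nan, math.nan, math.nan
    est = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return est, est * math.exp(-Z95 * se), est * math.exp(Z95 * se)


def prr(table, haldane: bool = True, yates: bool = False) -> tuple[float, float]:
    """Proportional reporting ratio and Pearson χ² (χ² on raw cells)."""
    a0, b0, c0, d0 = _cells(table)
    a, b, c, d, corrected = _haldane(a0, b0, c0, d0)
    if corrected and not haldane:
        est = math.nan
    else:
        est = (a / (a + b)) / (c / (c + d))
    return est, chi2_statistic((a0, b0, c0, d0), yates=yates)


def chi2_statistic(table, yates: bool = False) -> float:
    """Pearson χ² of the 2×2 table; NaN when any margin is zero."""
    a, b, c, d = _cells(table)
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom <= 0 or n <= 0:
        return math.nan
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2.0, 0.0)
    return n * diff * diff / denom


# ---------------------------------------------------------------------------
# BCPNN information component

IC_VARIANTS = ("noren", "moment")


def bcpnn_ic(table, variant: str = "noren") -> tuple[float, float]:
    """Information component and its lower 95% credibility bound IC025."""
    a, b, c, d = _cells(table)
    n = a + b + c + d
    if n <= 0:
        return math.nan, math.nan
    if variant == "noren":
        e = (a + b) * (a + c) / n
        if e == 0 and a == 0:
            return math.nan, math.nan
        ic = math.log2((a + 0.5) / (e + 0.5))
        ic025 = ic - 3.3 * (a + 0.5) ** -0.5 - 2.0 * (a + 0.5) ** -1.0
        return ic, ic025
    if variant == "moment":
        # classic BCPNN posterior moments with the standard hyperparameters
        g11, a1, b1, aa, bb = 1.0, 1.0, 1.0, 2.0, 2.0
        g = g11 * (n + aa) * (n + bb) / ((a + b + a1) * (a + c + b1))
        ic = math.log2((a + g11) * (n + aa) * (n + bb)
                       / ((n + g) * (a + b + a1) * (a + c + b1)))
        var = ((n - a + g - g11) / ((a + g11) * (1 + n + g))
               + (n - (a + b) + aa - a1) / ((a + b + a1) * (1 + n + aa))
               + (n - (a + c) + bb - b1) / ((a + c + b1) * (1 + n + bb))) \
            / (math.log(2) ** 2)
        return ic, ic - Z95 * math.sqrt(var)
    raise ValueError(f"variant must be one of {IC_VARIANTS}, got {variant!r}")


# ---------------------------------------------------------------------------
# MGPS: gamma-Poisson shrinker

@dataclass(frozen=True)
class GPSPrior:
    """Two-component gamma mixture prior on the relative reporting rate λ.

    λ ~ p·Gamma(alpha1, rate beta1) + (1−p)·Gamma(alpha2, rate beta2);
    counts are Poisson(λE) so marginally negative-binomial.
    """

    alpha1: float
    beta1: float
    alpha2: float
    beta2: float
    p: float
    loglik: float = math.nan

    def __post_init__(self) -> None:
        if min(self.alpha1, self.beta1, self.alpha2, self.beta2) <= 0:
            raise ValueError("gamma hyperparameters must be positive")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("mixture weight must lie in [0, 1]")

    @property
    def mean(self) -> float:
        return self.p * self.alpha1 / self.beta1 + (1 - self.p) * self.alpha2 / self.beta2


class GPSFitError(RuntimeError):
    pass


def _log_nb(a: np.ndarray, alpha: float, beta: float, e: np.ndarray) -> np.ndarray:
    """log marginal P(a) under λ~Gamma(alpha, rate beta), a~Poisson(λe)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (special.gammaln(alpha + a) - special.gammaln(alpha)
               - special.gammaln(a + 1)
               + alpha * (np.log(beta) - np.log(beta + e))
               + a * (np.log(e) - np.log(beta + e)))
    return np.where(e > 0, out, np.where(a == 0, 0.0, -np.inf))


_GPS_STARTS = (
    (0.2, 0.1, 2.0, 4.0, 1 / 3),   # DuMouchel's classic starting point
    (1.0, 1.0, 1.0, 1.0, 0.5),
    (0.5, 0.25, 3.0, 1.5, 0.2),
)


def fit_gps_prior(a: Sequence[float], e: Sequence[float],
                  starts: Sequence[tuple] = _GPS_STARTS) -> GPSPrior:
    """Maximum marginal likelihood fit of the mixture hyperparameters.

    Optimises over (log α1, log β1, log α2, log β2, logit p) from each
    fixed starting point and keeps the best converged solution.
    """
    a_arr = np.asarray(a, dtype=float)
    e_arr = np.asarray(e, dtype=float)
    keep = e_arr > 0
    a_arr, e_arr = a_arr[keep], e_arr[keep]
    if len(a_arr) < 2:
        raise GPSFitError(f"need at least 2 cells with E > 0, got {len(a_arr)}")
    if len(a_arr) < 100:
        logger.warning("GPS prior fitted on only %d cells (≥100 recommended)",
                       len(a_arr))

    def nll(theta: np.ndarray) -> float:
        # clamp to a generous box: beyond it the gammaln differences lose
        # all precision and fabricate spurious likelihood
        la1, lb1, la2, lb2, lp = np.clip(theta, -20.0, 20.0)
        p = 1.0 / (1.0 + math.exp(-np.clip(lp, -30, 30)))
        l1 = _log_nb(a_arr, math.exp(la1), math.exp(lb1), e_arr)
        l2 = _log_nb(a_arr, math.exp(la2), math.exp(lb2), e_arr)
        m = np.maximum(l1, l2)
        with np.errstate(divide="ignore"):
            ll = m + np.log(p * np.exp(l1 - m) + (1 - p) * np.exp(l2 - m))
        if not np.all(np.isfinite(ll)):
            return 1e300
        return -float(ll.sum())

    options = {"maxiter": 20_000, "maxfev": 20_000, "xatol": 1e-7,
               "fatol": 1e-9}
    best, diagnostics = None, []
    for s in starts:
        x0 = np.array([math.log(s[0]), math.log(s[1]), math.log(s[2]),
                       math.log(s[3]), math.log(s[4] / (1 - s[4]))])
        res = optimize.minimize(nll, x0, method="Nelder-Mead", options=options)
        if not res.success:
            res = optimize.minimize(nll, res.x, method="Nelder-Mead",
                                    options=options)
        diagnostics.append((s, res.success, float(res.fun)))
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise GPSFitError(f"GPS optimisation failed from all starts: {diagnostics}")
    la1, lb1, la2, lb2, lp = np.clip(best.x, -20.0, 20.0)
    return GPSPrior(math.exp(la1), math.exp(lb1), math.exp(la2), math.exp(lb2),
                    1.0 / (1.0 + math.exp(-lp)), loglik=-float(best.fun))


def _posterior_mixture(a: float, e: float, prior: GPSPrior):
    """Posterior over λ: gamma components Gamma(αj+a, rate βj+E) with
    weights ∝ prior weight × NB marginal."""
    l1 = float(_log_nb(np.array([a]), prior.alpha1, prior.beta1, np.array([e]))[0])
    l2 = float(_log_nb(np.array([a]), prior.alpha2, prior.beta2, np.array([e]))[0])
    w1 = math.log(prior.p) + l1 if prior.p > 0 else -math.inf
    w2 = math.log1p(-prior.p) + l2 if prior.p < 1 else -math.inf
    m = max(w1, w2)
    q1 = math.exp(w1 - m) / (math.exp(w1 - m) + math.exp(w2 - m))
    return q1, (prior.alpha1 + a, prior.beta1 + e), (prior.alpha2 + a, prior.beta2 + e)


def ebgm(table, prior: GPSPrior) -> tuple[float, float]:
    """Empirical Bayes geometric mean and 5th posterior percentile of λ.

    EBGM = 2^E[log2 λ | a] via the digamma expectation; EBGM05 is found
    as the monotone root of the posterior mixture CDF at 0.05.
    """
    if isinstance(table, ContingencyTable):
        a, e = table.a, table.expected_a
    else:
        a, e = float(table[0]), float(table[1])
    if e <= 0:
        raise ValueError("EBGM requires E > 0")
    q1, (a1, b1), (a2, b2) = _posterior_mixture(a, e, prior)
    elog = q1 * (special.digamma(a1) - math.log(b1)) \
        + (1 - q1) * (special.digamma(a2) - math.log(b2))
    geo_mean = math.exp(elog)

    def cdf(x: float) -> float:
        return (q1 * stats.gamma.cdf(x, a1, scale=1.0 / b1)
                + (1 - q1) * stats.gamma.cdf(x, a2, scale=1.0 / b2))

    p1 = stats.gamma.ppf(0.05, a1, scale=1.0 / b1)
    p2 = stats.gamma.ppf(0.05, a2, scale=1.0 / b2)
    lo, hi = min(p1, p2), max(p1, p2)
    # expand defensively: rounding in near-degenerate mixtures can push the
    # root just outside the component-quantile bracket
    for _ in range(60):
        if cdf(lo) < 0.05:
            break
        lo *= 0.5
    for _ in range(60):
        if cdf(hi) > 0.05:
            break
        hi *= 2.0
    if hi <= lo or cdf(lo) >= 0.05:
        q05 = lo
    else:
        q05 = optimize.brentq(lambda x: cdf(x) - 0.05, lo, hi,
                              xtol=1e-12, rtol=1e-9, maxiter=500)
    return geo_mean, q05


# ---------------------------------------------------------------------------
# combined signal rule

@dataclass(frozen=True)
class SignalCriteria:
    """Per-method positivity thresholds and the combination rule."""

    ror_lo_gt: float = 1.0
    ror_n_min: int = 3
    prr_min: float = 2.0
    chi2_min: float = 4.0
    prr_n_min: int = 3
    ic025_gt: float = 0.0
    ebgm05_gt: float = 2.0
    n_methods_min: int = 2
    require_frequentist: bool = True
    require_bayesian: bool = True
    prioritized_n_min: int = 100
    haldane: bool = True
    yates: bool = False
    ic_variant: str = "noren"


@dataclass
class DisproportionalityResult:
    """All four statistics, per-method flags and the combined verdict."""

    term: str
    level: str
    n: int
    ror: float = math.nan
    ror_lo: float = math.nan
    ror_hi: float = math.nan
    prr: float = math.nan
    chi2: float = math.nan
    ic: float = math.nan
    ic025: float = math.nan
    ebgm: float = math.nan
    ebgm05: float = math.nan
    corrected: bool = False
    flags: dict = field(default_factory=dict)
    signal: bool = False
    ror_signal: bool = False
    tier: str = "exploratory"


def evaluate_signal(result: DisproportionalityResult,
                    criteria: SignalCriteria | None = None) -> DisproportionalityResult:
    """Fill flags, the combined 2-of-4 verdict and the tier.

    Undefined statistics (NaN) count as not positive.
    """
    c = criteria or SignalCriteria()
    flags = {
        "ror_pos": bool(result.ror_lo > c.ror_lo_gt and result.n >= c.ror_n_min),
        "prr_pos": bool(result.prr >= c.prr_min and result.chi2 >= c.chi2_min
                        and result.n >= c.prr_n_min),
        "ic_pos": bool(result.ic025 > c.ic025_gt),
        "ebgm_pos": bool(result.ebgm05 > c.ebgm05_gt),
    }
    n_pos = sum(flags.values())
    has_freq = flags["ror_pos"] or flags["prr_pos"]
    has_bayes = flags["ic_pos"] or flags["ebgm_pos"]
    signal = n_pos >= c.n_methods_min
    if c.require_frequentist:
        signal = signal and has_freq
    if c.require_bayesian:
        signal = signal and has_bayes
    tier = "prioritized" if signal and result.n >= c.prioritized_n_min else "exploratory"
    return replace(result, flags=flags, signal=signal,
                   ror_signal=bool(result.ror > 1 and result.ror_lo > 1), tier=tier)


# ---------------------------------------------------------------------------
# screening model / results

class ScreenResults:
    """Per-term disproportionality results for one drug at one level.

    Behaves as a sequence of :class:`DisproportionalityResult`; the
    ``frame`` property gives the tidy table, ``summary()`` a text table
    mirroring the usual ROR (CI) / PRR (χ²) / EBGM (EBGM05) / IC (IC025)
    column layout.
    """

    def __init__(self, results: list[DisproportionalityResult],
                 target_drug: str, level: str, criteria: SignalCriteria,
                 prior: GPSPrior | None, attrs: dict):
        self.results = results
        self.target_drug = target_drug
        self.level = level
        self.criteria = criteria
        self.prior = prior
        self.attrs = attrs

    def __iter__(self) -> Iterator[DisproportionalityResult]:
        return iter(self.results)

    def __len__(self) -> int:
        return len(self.results)

    def __getitem__(self, i):
        return self.results[i]

    @property
    def frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            row = {"term": r.term, "level": r.level, "n": r.n, "ror": r.ror,
                   "ror_lo": r.ror_lo, "ror_hi": r.ror_hi, "prr": r.prr,
                   "chi2": r.chi2, "ebgm": r.ebgm, "ebgm05": r.ebgm05,
                   "ic": r.ic, "ic025": r.ic025, "corrected": r.corrected}
            row.update(r.flags)
            row.update({"signal": r.signal, "ror_signal": r.ror_signal,
                        "tier": r.tier})
            rows.append(row)
        df = pd.DataFrame(rows)
        df.attrs.update(self.attrs)
        df.attrs["criteria"] = self.criteria.__dict__.copy()
        return df

    def by_count(self) -> pd.DataFrame:
        return self.frame.sort_values("n", ascending=False, ignore_index=True)

    def by_ror(self) -> pd.DataFrame:
        return self.frame.sort_values("ror", ascending=False, ignore_index=True)

    @property
    def signals(self) -> list[DisproportionalityResult]:
        return [r for r in self.results if r.signal]

    def result_for(self, term: str) -> DisproportionalityResult | None:
        t = term.strip().lower()
        for r in self.results:
            if r.term == t:
                return r
        return None

    def summary(self, top: int | None = 20) -> str:
        df = self.by_count()
        if top is not None:
            df = df.head(top)
        lines = [f"Disproportionality screen: {self.target_drug!r} at "
                 f"{self.level} level, {len(self.results)} terms, "
                 f"{len(self.signals)} signals",
                 f"{'term':<36} {'n':>6}  {'ROR (95% CI)':>22}  "
                 f"{'PRR (chi2)':>18}  {'EBGM (EBGM05)':>16}  {'IC (IC025)':>15}  signal"]
        for r in df.itertuples(index=False):
            lines.append(
                f"{r.term[:36]:<36} {r.n:>6}  "
                f"{r.ror:8.2f} ({r.ror_lo:6.2f}-{r.ror_hi:6.2f})  "
                f"{r.prr:8.2f} ({r.chi2:7.1f})  "
                f"{r.ebgm:7.2f} ({r.ebgm05:5.2f})  "
                f"{r.ic:6.2f} ({r.ic025:6.2f})  "
                f"{'yes' if r.signal else 'no':>3} [{r.tier}]")
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        """Write the result table with a self-describing header comment
        recording the target, level and every threshold used."""
        import json as _json
        meta = {"target_drug": self.target_drug, "level": self.level,
                "criteria": self.criteria.__dict__}
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# " + _json.dumps(meta, sort_keys=True) + "\n")
            self.frame.to_csv(fh, sep="\t", index=False)


class DisproportionalityScreen:
    """Model object: screen one target drug against the bundle background.

    Parameters
    ----------
    bundle : cleaned :class:`ReportBundle` containing the target reports
        and the comparator background.
    target_drug : normalized drug name defining the exposed reports.
    level : "PT" or "SOC" (SOC needs ``meddra_map``).
    criteria : per-method thresholds and combination rule.
    prior : optional pre-fitted :class:`GPSPrior`; when absent a prior is
        fitted to all cells at this level (each MedDRA level gets its
        own fit, since the cell universes differ).
    """

    def __init__(self, bundle: ReportBundle, target_drug: str,
                 level: str = "PT", meddra_map: MedDRAMap | None = None,
                 criteria: SignalCriteria | None = None,
                 prior: GPSPrior | None = None):
        self.bundle = bundle
        self.target_drug = target_drug
        self.level = level
        self.meddra_map = meddra_map
        self.criteria = criteria or SignalCriteria()
        self.prior = prior

    def fit(self) -> ScreenResults:
        tables = build_tables(self.bundle, self.target_drug, self.level,
                              self.meddra_map)
        c = self.criteria
        prior = self.prior
        if prior is None and len(tables) >= 2:
            e_all = ((tables["a"] + tables["b"]) * (tables["a"] + tables["c"])
                     / (tables["a"] + tables["b"] + tables["c"] + tables["d"]))
            prior = fit_gps_prior(tables["a"].to_numpy(), e_all.to_numpy())
        results = []
        for row in tables.itertuples(index=False):
            cells = (row.a, row.b, row.c, row.d)
            res = DisproportionalityResult(term=row.term, level=row.level,
                                           n=int(row.a))
            res.corrected = min(cells) <= 0
            res.ror, res.ror_lo, res.ror_hi = ror(cells, haldane=c.haldane)
            res.prr, res.chi2 = prr(cells, haldane=c.haldane, yates=c.yates)
            res.ic, res.ic025 = bcpnn_ic(cells, variant=c.ic_variant)
            n_tot = sum(cells)
            e = (cells[0] + cells[1]) * (cells[0] + cells[2]) / n_tot if n_tot else 0.0
            if prior is not None and e > 0:
                res.ebgm, res.ebgm05 = ebgm((row.a, e), prior)
            results.append(evaluate_signal(res, c))
        return ScreenResults(results, self.target_drug, self.level, c, prior,
                             dict(tables.attrs))


def screen(bundle: ReportBundle, target_drug: str, level: str = "PT",
           criteria: SignalCriteria | None = None,
           meddra_map: MedDRAMap | None = None,
           prior: GPSPrior | None = None) -> ScreenResults:
    """Functional shorthand for ``DisproportionalityScreen(...).fit()``."""
    return DisproportionalityScreen(bundle, target_drug, level=level,
                                    meddra_map=meddra_map, criteria=criteria,
                                    prior=prior).fit()
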