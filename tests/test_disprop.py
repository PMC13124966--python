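"""Disproportionality estimators against hand arithmetic, an independent
brute-force oracle, numerical quadrature and simulation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from faersig.contingency import ContingencyTable
from faersig.disprop import (DisproportionalityResult, GPSFitError, GPSPrior,
                             SignalCriteria, bcpnn_ic, chi2_statistic, ebgm,
                             evaluate_signal, fit_gps_prior, prr, ror, screen)
from faersig.synthetic import SyntheticConfig, generate_bundle
from faersig.preprocess import clean_pipeline

from oracle_disprop import (oracle_chi2, oracle_ebgm_quadrature, oracle_ic,
                            oracle_prr, oracle_ror)


class TestFrozenExamples:
    """Values derived by hand from the estimator definitions."""

    def test_ror_point_and_ci(self):
        est, lo, hi = ror((10, 90, 100, 9900))
        assert est == pytest.approx(11.00, abs=0.005)
        assert lo == pytest.approx(5.56, abs=0.005)
        assert hi == pytest.approx(21.77, abs=0.01)

    def test_ror_independence_is_one(self):
        est, _, _ = ror((5, 45, 50, 450))
        assert est == pytest.approx(1.0)

    def test_ror_zero_cell_haldane(self):
        est, lo, hi = ror((0, 90, 100, 9900))
        ref, rlo, rhi = ror((0.5, 90.5, 100.5, 9900.5))
        assert (est, lo, hi) == (ref, rlo, rhi)
        assert math.isnan(ror((0, 90, 100, 9900), haldane=False)[0])

    def test_prr_and_chi2(self):
        est, chi2 = prr((10, 90, 100, 9900))
        assert est == pytest.approx(10.0)
        assert chi2 == pytest.approx(74.447, abs=0.001)

    def test_prr_independence(self):
        est, chi2 = prr((5, 45, 50, 450))
        assert est == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0, abs=1e-12)

    def test_prr_zero_cell_corrected_finite(self):
        est, chi2 = prr((3, 0, 50, 450))
        assert math.isfinite(est)
        # chi2 stays on the raw cells
        assert chi2 == pytest.approx(oracle_chi2(3, 0, 50, 450))

    def test_ic_closed_form(self):
        ic, ic025 = bcpnn_ic((10, 90, 100, 9900))
        assert ic == pytest.approx(2.724, abs=0.001)
        assert ic025 == pytest.approx(1.515, abs=0.001)

    def test_ic_independence_near_zero(self):
        # a = E = 100 by construction
        ic, _ = bcpnn_ic((100, 900, 900, 8100))
        assert abs(ic) < 0.01

    def test_ic_zero_count_negative(self):
        # a=0 with E=2: build margins (a+b)=20, (a+c)=10, N=100
        ic, _ = bcpnn_ic((0, 20, 10, 70))
        assert ic == pytest.approx(math.log2(0.5 / 2.5))
        assert ic < 0

    def test_ic_moment_variant_close_to_default(self):
        ic_n, lo_n = bcpnn_ic((50, 450, 500, 49000), variant="noren")
        ic_m, lo_m = bcpnn_ic((50, 450, 500, 49000), variant="moment")
        assert ic_m == pytest.approx(ic_n, abs=0.2)
        assert lo_m < ic_m and lo_n < ic_n

    def test_ic_unknown_variant(self):
        with pytest.raises(ValueError):
            bcpnn_ic((1, 1, 1, 1), variant="mcmc")


class TestOracleEquivalence:
    def test_thousand_random_tables(self):
        rng = np.random.default_rng(20240901)
        for _ in range(1000):
            a, b, c, d = rng.integers(0, 500, size=4)
            if a + b + c + d == 0:
                continue
            cells = (float(a), float(b), float(c), float(d))
            est, lo, hi = ror(cells)
            oest, olo, ohi = oracle_ror(*cells)
            for x, y in [(est, oest), (lo, olo), (hi, ohi)]:
                assert x == pytest.approx(y, rel=1e-9)
            p, chi = prr(cells)
            assert p == pytest.approx(oracle_prr(*cells), rel=1e-9)
            ochi = oracle_chi2(*cells)
            if math.isnan(ochi):
                assert math.isnan(chi)
            else:
                assert chi == pytest.approx(ochi, rel=1e-9)
            ic, ic025 = bcpnn_ic(cells)
            oic, oic025 = oracle_ic(*cells)
            assert ic == pytest.approx(oic, rel=1e-9)
            assert ic025 == pytest.approx(oic025, rel=1e-9)

    @given(st.tuples(st.integers(1, 10_000), st.integers(1, 10_000),
                     st.integers(1, 10_000), st.integers(1, 10_000)))
    @settings(max_examples=200, deadline=None)
    def test_interval_ordering(self, cells):
        est, lo, hi = ror(cells)
        assert lo < est < hi
        ic, ic025 = bcpnn_ic(cells)
        assert ic025 < ic


class TestEBGM:
    prior = GPSPrior(1.0, 1.0, 1.0, 1.0, 0.5)

    def test_matches_quadrature(self):
        g, q05 = ebgm((10, 1.0), self.prior)
        og, oq = oracle_ebgm_quadrature(10, 1.0, 1, 1, 1, 1, 0.5)
        assert g == pytest.approx(og, abs=1e-6)
        assert q05 == pytest.approx(oq, abs=1e-6)

    def test_large_count_shrinkage_vanishes(self):
        g, _ = ebgm((1000, 100.0), self.prior)
        assert 1 < g < 10
        assert g == pytest.approx(10.0, rel=0.02)

    def test_zero_count_below_one(self):
        # prior mean = 1 → with no events the posterior shrinks below 1
        g, _ = ebgm((0, 2.0), self.prior)
        assert g < 1

    def test_monotone_in_count(self):
        values = [ebgm((a, 5.0), self.prior)[0] for a in range(0, 40, 3)]
        assert all(x < y for x, y in zip(values, values[1:]))

    def test_between_one_and_relative_rate(self):
        for a, e in [(20, 5.0), (8, 2.0), (100, 10.0)]:
            g, _ = ebgm((a, e), self.prior)
            assert 1 < g < a / e

    def test_requires_positive_expectation(self):
        with pytest.raises(ValueError):
            ebgm((3, 0.0), self.prior)

    def test_invalid_prior_rejected(self):
        with pytest.raises(ValueError):
            GPSPrior(-1, 1, 1, 1, 0.5)
        with pytest.raises(ValueError):
            GPSPrior(1, 1, 1, 1, 1.5)


class TestGPSFit:
    def test_null_counts_concentrate_near_one(self):
        rng = np.random.default_rng(11)
        e = rng.uniform(0.5, 50.0, size=5000)
        a = rng.poisson(e)
        prior = fit_gps_prior(a, e)
        assert 0.8 <= prior.mean <= 1.2

    def test_too_few_cells(self):
        with pytest.raises(GPSFitError):
            fit_gps_prior([3.0], [1.0])

    def test_loglik_not_worse_than_truth(self):
        truth = GPSPrior(0.2, 0.1, 2.0, 4.0, 0.3)
        rng = np.random.default_rng(5)
        n = 20_000
        e = rng.uniform(0.5, 20.0, size=n)
        comp = rng.random(n) < truth.p
        lam = np.where(comp, rng.gamma(truth.alpha1, 1 / truth.beta1, n),
                       rng.gamma(truth.alpha2, 1 / truth.beta2, n))
        a = rng.poisson(lam * e)
        fitted = fit_gps_prior(a, e)

        from faersig.disprop import _log_nb
        def ll(p):
            l1 = _log_nb(a.astype(float), p.alpha1, p.beta1, e)
            l2 = _log_nb(a.astype(float), p.alpha2, p.beta2, e)
            m = np.maximum(l1, l2)
            return float(np.sum(m + np.log(p.p * np.exp(l1 - m)
                                           + (1 - p.p) * np.exp(l2 - m))))
        assert fitted.loglik >= ll(truth) - 1.0


class TestSignalRule:
    def _result(self, **kw):
        base = dict(term="t", level="PT", n=150, ror=3, ror_lo=0.5, ror_hi=5,
                    prr=1, chi2=1, ic=0.5, ic025=-0.5, ebgm=1.5, ebgm05=0.5)
        base.update(kw)
        return DisproportionalityResult(**base)

    def test_frequentist_plus_bayesian_fires(self):
        res = evaluate_signal(self._result(ror_lo=1.5, ic025=0.5))
        assert res.flags == {"ror_pos": True, "prr_pos": False,
                             "ic_pos": True, "ebgm_pos": False}
        assert res.signal and res.tier == "prioritized"

    def test_two_frequentist_only_is_not_a_signal(self):
        res = evaluate_signal(self._result(ror_lo=1.5, prr=3, chi2=10))
        assert res.flags["ror_pos"] and res.flags["prr_pos"]
        assert not res.signal

    def test_all_negative(self):
        res = evaluate_signal(self._result())
        assert not res.signal and res.tier == "exploratory"

    def test_small_count_demotes_to_exploratory(self):
        res = evaluate_signal(self._result(n=50, ror_lo=1.5, ic025=0.5))
        assert res.signal and res.tier == "exploratory"

    def test_undefined_methods_count_negative(self):
        res = evaluate_signal(self._result(ror=math.nan, ror_lo=math.nan,
                                           ic025=math.nan))
        assert not any(res.flags.values())

    def test_ror_only_rule_reported_as_flag(self):
        res = evaluate_signal(self._result(ror=2.0, ror_lo=1.2))
        assert res.ror_signal and not res.signal

    @given(st.lists(st.sampled_from(["ror", "prr", "ic", "ebgm"]),
                    unique=True))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_flags(self, positives):
        """Adding one more positive method never withdraws a signal."""
        def result_with(pos):
            kw = {}
            if "ror" in pos:
                kw["ror_lo"] = 1.5
            if "prr" in pos:
                kw.update(prr=3.0, chi2=10.0)
            if "ic" in pos:
                kw["ic025"] = 0.5
            if "ebgm" in pos:
                kw["ebgm05"] = 3.0
            return evaluate_signal(self._result(**kw))
        base = result_with(positives)
        for extra in set(["ror", "prr", "ic", "ebgm"]) - set(positives):
            grown = result_with(positives + [extra])
            assert grown.signal >= base.signal


class TestScreen:
    def test_planted_pair_flagged(self):
        config = SyntheticConfig(
            n_reports=20_000, seed=42,
            planted=[{"drug": "pemetrexed", "pt": "pancytopenia", "rho": 8.0}])
        bundle, _ = generate_bundle(config)
        clean, _ = clean_pipeline(bundle, target_drug="pemetrexed",
                                  universe=True)
        res = screen(clean, "pemetrexed", "PT")
        hit = res.result_for("pancytopenia")
        assert hit is not None and hit.signal

    def test_empty_bundle_empty_results(self, bundle_builder):
        res = screen(bundle_builder(), "pemetrexed", "PT")
        assert len(res) == 0 and res.signals == []

    def test_summary_mentions_counts(self, two_drug_bundle):
        res = screen(two_drug_bundle, "drugx", "PT",
                     prior=GPSPrior(1, 1, 1, 1, 0.5))
        text = res.summary()
        assert "drugx" in text and "pty" in text
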