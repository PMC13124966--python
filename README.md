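# faersig

Signal detection for spontaneous adverse-event reporting systems.

Post-marketing drug safety surveillance relies on databases such as the
FDA Adverse Event Reporting System (FAERS), where reporters attribute
adverse events (coded as MedDRA preferred terms, PTs) to suspect drugs.
`faersig` implements the full screening workflow a pharmacovigilance
analyst applies to such data — here configured around pemetrexed-style
oncology case series, but generic in the target drug:

* **ingestion** of FAERS quarterly ASCII bundles ("$"-delimited DEMO /
  DRUG / REAC / OUTC / THER / INDI tables) and deleted-case lists;
* **cleaning**: case-level deduplication (most recent FDA_DT, ties to
  the larger PRIMARYID), deleted-case removal, plausibility filters
  (implausible ages, inconsistent timelines, study window, non-AE
  administrative reports) and unique-primary-suspect selection;
* **disproportionality screening** of every drug–event 2×2 table at PT
  and System Organ Class (SOC) level with four estimators, plus a
  combined signal rule;
* **subgroup re-analysis** by sex, age and reporter type, and a
  **sensitivity analysis** excluding common co-medications;
* **time-to-onset (TTO)** binning, cumulative incidence with log-rank
  comparison, and Weibull modelling with failure-type classification;
* a **synthetic-data generator** with analytically known ground truth,
  so every stage is testable without licensed data (MedDRA content and
  real FAERS extracts are not redistributable).

## The statistics

For a 2×2 table — a = reports with drug and event, b = drug without
event, c = event without drug, d = neither, N = a+b+c+d, expected count
E = (a+b)(a+c)/N — the screen computes:

| method | estimate | interval / companion | positive when |
|---|---|---|---|
| ROR | ad∕bc | Wald 95% CI: exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)) | lower CI > 1, a ≥ 3 |
| PRR | [a/(a+b)] ∕ [c/(c+d)] | Pearson χ² = N(ad−bc)²/[(a+b)(c+d)(a+c)(b+d)] | PRR ≥ 2, χ² ≥ 4, a ≥ 3 |
| BCPNN IC | log₂((a+½)/(E+½)) | IC025 = IC − 3.3(a+½)^−½ − 2.0(a+½)^−1 | IC025 > 0 |
| MGPS EBGM | 2^E[log₂λ \| a] | EBGM05 = 5th posterior percentile of λ | EBGM05 > 2 |

EBGM uses DuMouchel's gamma-Poisson shrinker: the relative reporting
rate λ has a two-component gamma mixture prior fitted by maximum
marginal (negative-binomial) likelihood over all cells at a level.
Zero cells get the Haldane +0.5 correction for ratio estimators only;
χ² always uses raw cells. A term is a **signal** when ≥2 of the four
methods are positive, including at least one frequentist (ROR/PRR) and
one Bayesian (IC/EBGM) method; signals with ≥100 reports are tiered
"prioritized", the rest "exploratory". The one-method rule (ROR > 1
with lower CI > 1) is reported alongside as a flag. Every threshold is
configurable.

Onset delays (EVENT_DT − START_DT, days) are modelled as
Weibull(scale α, shape β): CDF(t) = 1 − exp(−(t/α)^β), so CDF(α) =
1 − 1/e ≈ 63.2% identically and α is the characteristic onset time.
The shape's 95% CI classifies the hazard: entirely below 1 → "early
failure" (risk concentrated after treatment start), above 1 →
"wear-out", spanning 1 → "random".

## Worked example

```python
import faersig as fs

config = fs.SyntheticConfig(
    n_reports=20_000, seed=42,
    planted=[{"drug": "pemetrexed", "pt": "pancytopenia", "rho": 8.0}])
bundle, truth = fs.generate_bundle(config)

cleaned, reports = fs.clean_pipeline(bundle, target_drug="pemetrexed",
                                     universe=True)
res = fs.screen(cleaned, "pemetrexed", level="PT")
print(res.summary(top=2))

target, _ = fs.select_unique_ps(cleaned, "pemetrexed")
fit = fs.fit_weibull(fs.compute_tto(target, "pemetrexed")["days"])
print(fit.summary())
```

prints (abridged):

```
Disproportionality screen: 'pemetrexed' at PT level, 60 terms, 1 signals
term              n            ROR (95% CI)          PRR (chi2)  EBGM (EBGM05)     IC (IC025)  signal
pancytopenia   1139      5.88 (  5.45-  6.36)   4.81 ( 2480.7)   3.58 ( 3.58)   1.84 (  1.74)  yes [prioritized]
anaemia         320      0.87 (  0.77-  0.98)   0.88 (    5.6)   0.85 ( 0.80)  -0.18 ( -0.37)   no [exploratory]

Weibull time-to-onset fit (n=1402)
  median (IQR) days: 32 (8-86)
  scale alpha: 54.59 days (95% CI 50.43-59.09)
  shape beta:  0.697 (95% CI 0.670-0.726)
  failure type: early
  CDF(alpha) = 0.632 (= 1 - 1/e)
```

The generator planted one true association (pancytopenia at relative
reporting ratio ρ=8); the screen flags exactly that PT — all four
methods positive — and nothing else. The onset delays were simulated
from Weibull(57.99, 0.69); the fit recovers both parameters within
sampling error and classifies the pattern as early failure (β CI
entirely below 1), meaning onset risk is highest right after treatment
start and ~63% of reported onsets fall within α ≈ 55 days.

The same run end-to-end from a shell:

```sh
faersig all -c config.json -o out/        # or: simulate / clean / screen /
                                          # subgroup / sensitivity / tto / report
```

writing TSV tables plus a `manifest.json` (config hash, seed, versions,
per-stage counts); identical config and seed give byte-identical
outputs.

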