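"""Independent brute-force reference implementations of the four
disproportionality statistics, written directly from their textbook
definitions in plain Python, deliberately sharing no code with the
package. Used only as test oracles."""

import math

from scipy import integrate
from scipy.special import gammaln


def oracle_ror(a, b, c, d):
    if min(a, b, c, d) <= 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    est = (a * d) / (b * c)
    se = math.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    z = 1.959963984540054
    return est, math.exp(math.log(est) - z * se), math.exp(math.log(est) + z * se)


def oracle_prr(a, b, c, d):
    aa, bb, cc, dd = (a, b, c, d)
    if min(a, b, c, d) <= 0:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return (aa / (aa + bb)) / (cc / (cc + dd))


def oracle_chi2(a, b, c, d):
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom <= 0:
        return float("nan")
    return n * (a * d - b * c) ** 2 / denom


def oracle_ic(a, b, c, d):
    n = a + b + c + d
    e = (a + b) * (a + c) / n
    ic = math.log2((a + 0.5) / (e + 0.5))
    ic025 = ic - 3.3 / math.sqrt(a + 0.5) - 2.0 / (a + 0.5)
    return ic, ic025


def _posterior_density(lam, a, e, a1, b1, a2, b2, p):
    """Unnormalized posterior of λ given count a: prior mixture × Poisson."""
    def gamma_pdf(x, shape, rate):
        if x <= 0:
            return 0.0
        return math.exp(shape * math.log(rate) + (shape - 1) * math.log(x)
                        - rate * x - gammaln(shape))
    prior = p * gamma_pdf(lam, a1, b1) + (1 - p) * gamma_pdf(lam, a2, b2)
    pois = math.exp(a * math.log(lam * e) - lam * e - gammaln(a + 1)) \
        if lam > 0 else 0.0
    return prior * pois


def oracle_ebgm_quadrature(a, e, a1, b1, a2, b2, p, lower=0.0, upper=200.0):
    """EBGM and the 5th posterior percentile by direct numerical
    integration of the posterior density (no conjugacy shortcuts).

    For large counts the posterior is a narrow spike near a/e; pass
    bounds bracketing it so adaptive quadrature resolves the mass.
    """
    norm, _ = integrate.quad(_posterior_density, lower, upper,
                             args=(a, e, a1, b1, a2, b2, p), limit=400)

    mean_log, _ = integrate.quad(
        lambda lam: math.log(lam) * _posterior_density(lam, a, e, a1, b1, a2, b2, p),
        lower, upper, limit=400)
    ebgm = math.exp(mean_log / norm)

    def cdf(x):
        val, _ = integrate.quad(_posterior_density, lower, x,
                                args=(a, e, a1, b1, a2, b2, p), limit=400)
        return val / norm

    lo, hi = max(lower, 1e-9), upper
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if cdf(mid) < 0.05:
            lo = mid
        else:
            hi = mid
    return ebgm, 0.5 * (lo + hi)
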