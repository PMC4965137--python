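"""Independent oracles used by the test suite.

Every function here recomputes a quantity by brute force or closed form,
deliberately avoiding the code paths (scipy distribution objects, pipeline
functions) that the tests check.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def poisson_sf_series(n: int, lam: float, tol: float = 1e-18) -> float:
    """P(X >= n | lambda) by direct series summation of the pmf."""
    if n <= 0:
        return 1.0
    # sum lower tail exactly, subtract from 1 when that is better conditioned
    log_terms = []
    k = 0
    logp = -lam  # log pmf at k=0
    lower = math.exp(logp)
    while k < n - 1:
        k += 1
        logp += math.log(lam) - math.log(k)
        lower += math.exp(logp)
    if lower < 0.5:
        return 1.0 - lower
    # sum the upper tail directly
    total = 0.0
    logp = -lam + n * math.log(lam) - math.lgamma(n + 1)
    term = math.exp(logp)
    k = n
    while term > tol * max(total, 1e-300) or k < n + 10:
        total += term
        k += 1
        term *= lam / k
        if k > n + 10_000:
            break
    return total


def hypergeom_pmf_frac(k: int, N: int, K: int, n: int) -> Fraction:
    """Exact hypergeometric pmf as a rational number."""
    if k < max(0, n + K - N) or k > min(K, n):
        return Fraction(0)
    return Fraction(math.comb(K, k) * math.comb(N - K, n - k),
                    math.comb(N, n))


def hypergeom_sf_enum(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by exact enumeration."""
    total = Fraction(0)
    for j in range(k, min(K, n) + 1):
        total += hypergeom_pmf_frac(j, N, K, n)
    return float(total)


def fisher_twosided_enum(table) -> float:
    """Two-sided Fisher exact p by enumeration over the fixed margins.

    Sums the probabilities of all tables whose probability does not exceed
    the observed table's (with a tiny relative tolerance for float parity
    with library implementations).
    """
    (a, b), (c, d) = table
    N = a + b + c + d
    K = a + b       # row 1 margin
    n = a + c       # column 1 margin
    p_obs = hypergeom_pmf_frac(a, N, K, n)
    cutoff = p_obs * (1 + Fraction(1, 10**12))
    total = Fraction(0)
    for j in range(max(0, n + K - N), min(K, n) + 1):
        pj = hypergeom_pmf_frac(j, N, K, n)
        if pj <= cutoff:
            total += pj
    return float(min(total, Fraction(1)))


def brute_force_pileup(fragments, genome_length: int) -> np.ndarray:
    """Per-base coverage by explicit per-fragment incrementing."""
    cov = np.zeros(genome_length)
    for _, row in fragments.iterrows():
        s = max(0, int(row["start"]))
        e = min(genome_length, int(row["end"]))
        for x in range(s, e):
            cov[x] += 1
    return cov


def anova_f_p(groups) -> tuple[float, float]:
    """One-way ANOVA F and p from the textbook sum-of-squares formulas,
    with the F upper tail obtained by numerical integration of the density."""
    groups = [np.asarray(g, float) for g in groups]
    k = len(groups)
    n_tot = sum(len(g) for g in groups)
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = k - 1, n_tot - k
    f = (ss_between / df1) / (ss_within / df2)
    return f, f_sf_numeric(f, df1, df2)


def f_sf_numeric(f: float, d1: int, d2: int) -> float:
    """Upper tail of the F distribution via the regularized incomplete beta,
    computed by adaptive Simpson integration of the beta density."""
    x = d1 * f / (d1 * f + d2)  # P(F > f) = I_{1-x}(d2/2, d1/2)
    a, b = d2 / 2.0, d1 / 2.0
    return _reg_inc_beta(1.0 - x, a, b)


def _reg_inc_beta(x: float, a: float, b: float, n: int = 20_000) -> float:
    if x <= 0:
        return 0.0
    if x >= 1:
        return 1.0
    ts = np.linspace(0, x, n + 1)[1:-1]
    dens = ts ** (a - 1) * (1 - ts) ** (b - 1)
    # endpoint handling for a<1 or b<1 is not needed at half-integer dof >= 1
    integral = np.trapezoid(
        np.concatenate([[0.0 if a > 1 else dens[0]], dens]),
        np.concatenate([[0.0], ts]))
    lbeta = math.lgamma(a) + math.lgamma(b) - math.lgamma(a + b)
    return float(integral / math.exp(lbeta))


def student_t_sf(t: float, dof: int, n: int = 200_000) -> float:
    """Upper tail of Student's t by numerical integration of the density."""
    # integrate density from 0 to t, subtract from 1/2 (symmetry)
    xs = np.linspace(0.0, abs(t), n)
    dens = (1 + xs ** 2 / dof) ** (-(dof + 1) / 2)
    norm = math.exp(math.lgamma((dof + 1) / 2) - math.lgamma(dof / 2)) / \
        math.sqrt(dof * math.pi)
    body = float(np.trapezoid(dens, xs)) * norm
    sf = 0.5 - body
    return sf if t >= 0 else 1 - sf
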