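"""Circular statistics for the single-trial phase-lag / behavior analysis.

Covers the tests applied to the band-pooled interhemispheric phase lags:
the Rayleigh test of circular uniformity (z = n * Rbar^2), the circular
mean with its confidence arc, Mardia's circular-linear correlation of lag
with the subsequent single-trial error rate, a Harrison-Kanji style two-way
ANOVA for circular data (age group x median-dichotomized GABA+), and
Benjamini-Hochberg FDR adjustment over the family of subgroup x band x
condition tests.

Rayleigh test and circular-linear correlation are delegated to pingouin;
the two-way circular ANOVA is implemented here (no installed package
provides it) with automatic large/small concentration branch choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats
from statsmodels.stats.multitest import fdrcorrection

from ._utils import circ_mean_resultant, wrap_angle


@dataclass
class CircularSample:
    """Angles with their resultant summary.

    The mean direction is undefined when the resultant length is zero
    (perfectly balanced angles).
    """

    angles: np.ndarray

    def __post_init__(self):
        self.angles = wrap_angle(np.asarray(self.angles, dtype=float))

    @property
    def resultant_length(self) -> float:
        return float(np.abs(np.mean(np.exp(1j * self.angles))))

    @property
    def mean_direction(self) -> float:
        if self.resultant_length == 0:
            return np.nan
        return float(np.angle(np.mean(np.exp(1j * self.angles))))


def rayleigh(angles) -> tuple:
    """Rayleigh test of circular uniformity.

    Returns (z, p) with z = n * Rbar^2 and the small-sample-corrected
    exponential approximation for p.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size < 4:
        raise ValueError("Rayleigh test needs n >= 4")
    z, p = pg.circ_rayleigh(angles)
    return float(z), float(p)


def circ_mean_ci(angles, confidence: float = 0.95) -> tuple:
    """Circular mean direction with its confidence arc.

    Uses the large-sample dispersion-based interval (Fisher 1993):
    half-arc = asin(z_{1-conf/2} * sigma_hat), with
    sigma_hat^2 = (1 - rho2_hat) / (2 n Rbar^2). Raises when the resultant
    is too weak for the formula's validity region (the asin argument
    leaving [-1, 1]).
    """
    angles = wrap_angle(np.asarray(angles, dtype=float))
    n = angles.size
    mu, rbar = circ_mean_resultant(angles)
    if rbar >= 1.0 - 1e-12:
        return float(mu), 0.0
    rho2 = float(np.abs(np.mean(np.exp(2j * (angles - mu)))))
    sigma2 = (1.0 - rho2) / (2.0 * n * rbar ** 2)
    zq = stats.norm.ppf(0.5 + confidence / 2.0)
    arg = zq * np.sqrt(sigma2)
    if not (0 <= arg < 1) or rbar < 1e-6:
        raise ValueError("resultant too small: confidence arc undefined")
    half_arc = float(np.arcsin(arg))
    return float(mu), half_arc


def circ_linear_corr(angles, x) -> tuple:
    """Mardia's circular-linear correlation (rho, p).

    rho is derived from the correlations of x with sin(theta) and
    cos(theta); p comes from the chi-square(2) approximation of n * rho^2.
    """
    angles = np.asarray(angles, dtype=float)
    x = np.asarray(x, dtype=float)
    if angles.size != x.size:
        raise ValueError("angles and x must have equal length")
    if angles.size < 5:
        raise ValueError("need n >= 5")
    if np.std(x) == 0:
        raise ValueError("x has zero variance")
    r, p = pg.circ_corrcl(angles, x)
    return float(r), float(p)


def _cell_resultants(angles, idx, n_levels):
    """(count, unnormalized resultant length) per factor level."""
    cnt = np.zeros(n_levels)
    res = np.zeros(n_levels)
    for lev in range(n_levels):
        a = angles[idx == lev]
        cnt[lev] = a.size
        res[lev] = np.abs(np.sum(np.exp(1j * a))) if a.size else 0.0
    return cnt, res


def _kappa_ml(rbar: float) -> float:
    """Maximum-likelihood von Mises concentration from Rbar (Fisher approx)."""
    if rbar < 0.53:
        return 2 * rbar + rbar ** 3 + 5 * rbar ** 5 / 6
    if rbar < 0.85:
        return -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    if rbar >= 1.0 - 1e-9:
        return np.inf
    return 1 / (rbar ** 3 - 4 * rbar ** 2 + 3 * rbar)


def circ_anova2(angles, factor_a, factor_b) -> pd.DataFrame:
    """Two-way ANOVA for circular data (Harrison & Kanji decomposition).

    Returns a table with one row per effect (A, B, interaction) carrying
    the test statistic, degrees of freedom and p-value. The branch is
    chosen automatically from the estimated von Mises concentration of the
    pooled sample: concentrated samples (kappa > 2) use the F-ratio
    decomposition of resultant lengths with the high-concentration bias
    correction; dispersed samples use the chi-square approximation with
    2x the usual degrees of freedom. The chosen branch is recorded in the
    table.
    """
    angles = wrap_angle(np.asarray(angles, dtype=float))
    a_codes, a_levels = pd.factorize(np.asarray(factor_a))
    b_codes, b_levels = pd.factorize(np.asarray(factor_b))
    p, q = len(a_levels), len(b_levels)
    if p < 2 or q < 2:
        raise ValueError("each factor needs >= 2 levels")
    n = angles.size
    cell = a_codes * q + b_codes
    cn, cr = _cell_resultants(angles, cell, p * q)
    if np.any(cn < 5):
        bad = int(np.argmin(cn))
        raise ValueError(f"cell (A={a_levels[bad // q]}, B={b_levels[bad % q]}) "
                         f"has fewer than 5 observations")
    pn, pr = _cell_resultants(angles, a_codes, p)
    qn, qr = _cell_resultants(angles, b_codes, q)
    tr = float(np.abs(np.sum(np.exp(1j * angles))))
    rbar = tr / n
    kk = _kappa_ml(rbar)

    eff_a = float(np.sum(pr ** 2 / pn) - tr ** 2 / n)
    eff_b = float(np.sum(qr ** 2 / qn) - tr ** 2 / n)
    eff_ab = float(np.sum(cr ** 2 / cn) - np.sum(pr ** 2 / pn)
                   - np.sum(qr ** 2 / qn) + tr ** 2 / n)
    eff_res = float(n - np.sum(cr ** 2 / cn))

    rows = []
    if kk > 2:  # high concentration: F tests on the resultant decomposition
        branch = "F_large_kappa"
        beta = 1.0 / (1.0 - 1.0 / (5 * kk) - 1.0 / (10 * kk ** 2))
        df_res = n - p * q
        ms_res = eff_res / df_res
        for name, eff, df in (("A", eff_a, p - 1), ("B", eff_b, q - 1),
                              ("A:B", eff_ab, (p - 1) * (q - 1))):
            if eff <= 1e-12:  # degenerate (e.g. identical angles)
                rows.append((name, 0.0, df, 1.0))
                continue
            F = beta * (eff / df) / ms_res
            pval = stats.f.sf(max(F, 0.0), df, df_res)
            rows.append((name, max(F, 0.0), df, pval))
    else:  # dispersed: chi-square approximation, df doubled
        branch = "chi2_small_kappa"
        factor = 1.0 / (1.0 - rbar ** 2 / 2.0) if rbar < 1 else np.inf
        kk_corr = 2.0 * factor
        for name, eff, df in (("A", eff_a, 2 * (p - 1)),
                              ("B", eff_b, 2 * (q - 1)),
                              ("A:B", eff_ab, 2 * (p - 1) * (q - 1))):
            chi = kk_corr * max(eff, 0.0)
            pval = stats.chi2.sf(chi, df)
            rows.append((name, chi, df, pval))
    out = pd.DataFrame(rows, columns=["effect", "statistic", "df", "p"])
    out["branch"] = branch
    out["kappa_hat"] = kk
    return out


def fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    _, adj = fdrcorrection(p, alpha=0.05, method="indep")
    return adj


def dichotomize_gaba(values, group) -> np.ndarray:
    """Split GABA+ values at the within-group median.

    Values at or below their own age group's median are labelled 'low'
    (ties go to 'low'), the rest 'high'.
    """
    values = np.asarray(values, dtype=float)
    group = np.asarray(group)
    labels = np.empty(values.size, dtype=object)
    for g in pd.unique(group):
        sel = group == g
        if sel.sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
        med = np.median(values[sel])
        labels[sel] = np.where(values[sel] <= med, "low", "high")
    return labels.astype(str)
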