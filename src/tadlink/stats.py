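"""Shared statistical helpers: BH FDR, hypergeometric enrichment, chi-squared
goodness-of-fit with small-count fallback, and Spearman p-values."""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def hypergeom_enrichment(observed: int, population: int, successes: int, draws: int):
    """Upper-tail hypergeometric test with fold enrichment.

    Returns (fold, p) where fold = observed / expected and
    p = P[X >= observed] for X ~ Hypergeom(population, successes, draws).
    """
    if draws == 0 or successes == 0 or population == 0:
        return float("nan"), 1.0
    expected = draws * successes / population
    fold = observed / expected if expected > 0 else float("nan")
    p = float(sps.hypergeom.sf(observed - 1, population, successes, draws))
    return fold, p


@dataclass
class Chi2Result:
    statistic: float
    p: float
    exact_fallback: bool
    one_sided: bool = False


def chi2_gof(observed, expected_proportions, one_sided_category: int | None = None,
             rng: np.random.Generator | None = None, n_mc: int = 20_000) -> Chi2Result:
    """Chi-squared goodness of fit of category counts against proportions.

    With any expected count < 5 the p-value falls back to an exact/Monte-Carlo
    multinomial evaluation (flagged).  If ``one_sided_category`` is given, the
    p-value is halved when that category is enriched above expectation
    (one-sided test for enrichment in a designated bin).
    """
    obs = np.asarray(observed, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    props = props / props.sum()
    n = obs.sum()
    exp = n * props
    stat = float(((obs - exp) ** 2 / exp).sum())
    fallback = bool((exp < 5).any())
    if fallback:
        rng = rng if rng is not None else np.random.default_rng(0)
        draws = rng.multinomial(int(n), props, size=n_mc)
        stats_null = ((draws - exp) ** 2 / exp).sum(axis=1)
        p = float((np.count_nonzero(stats_null >= stat) + 1) / (n_mc + 1))
    else:
        p = float(sps.chi2.sf(stat, df=len(obs) - 1))
    one_sided = False
    if one_sided_category is not None:
        one_sided = True
        if obs[one_sided_category] > exp[one_sided_category]:
            p = p / 2.0
        else:
            p = 1.0 - p / 2.0
    return Chi2Result(stat, p, fallback, one_sided)


@lru_cache(maxsize=None)
def _exact_spearman_null(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact null distribution of |rho| for untied samples of size n (n <= 9).

    Returns (sorted unique |rho| values, P[|rho| >= value])."""
    base = np.arange(n)
    denom = n * (n * n - 1)
    rhos = []
    for perm in itertools.permutations(range(n)):
        d2 = int(np.sum((base - np.array(perm)) ** 2))
        rhos.append(1.0 - 6.0 * d2 / denom)
    a = np.abs(np.round(rhos, 12))
    vals, counts = np.unique(a, return_counts=True)
    sf = np.cumsum(counts[::-1])[::-1] / len(a)  # P[|rho| >= vals[i]]
    return vals, sf


def spearman_pvalue_exact(rho: float, n: int) -> float:
    vals, sf = _exact_spearman_null(n)
    i = np.searchsorted(vals, abs(round(rho, 12)) - 1e-9, side="left")
    return float(sf[i]) if i < len(vals) else 0.0


def spearman_pvalues_t(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided t-approximation p-values for Spearman coefficients."""
    rho = np.asarray(rho, dtype=float)
    r = np.clip(rho, -1 + 1e-15, 1 - 1e-15)
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    p[np.abs(rho) >= 1.0] = 0.0
    return np.minimum(p, 1.0)
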