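"""Statistical primitives for RIP-seq enrichment and target characterization.

Size factors follow the median-of-ratios definition; the enrichment engine
is an explicit per-gene negative-binomial Wald test of IP versus the IgG
background pulldown; the one-sided two-sample Kolmogorov–Smirnov test uses
the signed supremum D+ with an exact labeling-enumeration p-value for
small samples and the classical one-sided exponential bound otherwise.
Wilcoxon tests and Pearson correlation wrap scipy.stats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

KS_EXACT_MAX = 16  # pooled size up to which the KS p is enumerated exactly
WILCOXON_EXACT_MAX = 12
DISPERSION_FLOOR = 0.01


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    sidedness: str  # "one-sided-greater" | "two-sided"
    method: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")


# ---------------------------------------------------------------------------
# normalization


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors, rescaled to geometric mean 1.

    ``counts`` is genes x samples. Only genes with nonzero counts in every
    sample enter the median; if none exists the libraries cannot be scaled
    and a ValueError advises adding a pseudocount.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim == 1:
        counts = counts[:, None]
    if counts.shape[1] == 1:
        return np.ones(1)
    allpos = np.all(counts > 0, axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has nonzero counts in every sample; size factors are "
            "undefined — add a pseudocount to the matrix first"
        )
    sub = counts[allpos]
    log_geomean = np.mean(np.log(sub), axis=1)
    factors = np.exp(np.median(np.log(sub) - log_geomean[:, None], axis=0))
    return factors / np.exp(np.mean(np.log(factors)))


# ---------------------------------------------------------------------------
# negative-binomial Wald enrichment test


def estimate_dispersions(
    ip: np.ndarray,
    bg: np.ndarray,
    sf_ip: np.ndarray,
    sf_bg: np.ndarray,
    floor: float = DISPERSION_FLOOR,
    shrink: float = 0.5,
) -> np.ndarray:
    """Per-gene NB dispersions by method of moments, floored and shrunk.

    For normalized counts y = k/s, Var(y) = mu/s + alpha*mu^2; the excess
    of the ddof=1 group variance over the Poisson part, pooled across the
    IP and background groups, estimates alpha. The denominator uses the
    second-moment correction E[mu_hat^2] = mu^2 + Var(y)/n so the ratio is
    nearly unbiased at 2-3 replicates. Estimates are floored at ``floor``
    then shrunk ``shrink`` of the way toward a lightly trimmed (1% per
    tail) mean over all genes — a robust, nearly unbiased center; a median
    center under-estimates the right-skewed per-gene distribution and
    makes the Wald test anti-conservative.
    """
    ests = []
    for grp, sf in ((ip, sf_ip), (bg, sf_bg)):
        y = grp / sf
        n = grp.shape[1]
        if n < 2:
            continue
        mu = y.mean(axis=1)
        v = y.var(axis=1, ddof=1)
        pois = mu * np.mean(1.0 / sf)
        denom = np.maximum(mu**2 - v / n, 1e-8)
        a = np.where(mu > 0, (v - pois) / denom, 0.0)
        ests.append(a)
    if not ests:
        raise ValueError("need >= 2 replicates in at least one group to estimate dispersion")
    alpha = np.maximum(np.mean(ests, axis=0), floor)
    center = float(sps.trim_mean(alpha, 0.01))
    return (1.0 - shrink) * alpha + shrink * center


def nb_wald_matrix(
    ip: np.ndarray,
    bg: np.ndarray,
    sf_ip: np.ndarray,
    sf_bg: np.ndarray,
    dispersion: np.ndarray | float | None = None,
    pseudocount: float = 0.5,
) -> dict[str, np.ndarray]:
    """Vectorized NB Wald test of IP vs background over a gene matrix.

    Returns log2 fold change, Wald z, two-sided gaussian p, the dispersion
    used, and a testable flag (False for all-zero genes, which get
    log2FC = 0 and p = 1).
    """
    ip = np.atleast_2d(np.asarray(ip, dtype=float))
    bg = np.atleast_2d(np.asarray(bg, dtype=float))
    sf_ip = np.asarray(sf_ip, dtype=float)
    sf_bg = np.asarray(sf_bg, dtype=float)
    if dispersion is None:
        alpha = estimate_dispersions(ip, bg, sf_ip, sf_bg)
    else:
        alpha = np.broadcast_to(np.asarray(dispersion, dtype=float), (ip.shape[0],)).copy()

    def group_moments(grp, sf):
        y = grp / sf
        n = grp.shape[1]
        mu = y.mean(axis=1) + pseudocount
        # Var(mean of k_j/s_j) = (1/n^2) sum_j (mu/s_j + alpha mu^2)
        var = (mu * np.sum(1.0 / sf) + n * alpha * mu**2) / n**2
        return mu, var

    mu_a, var_a = group_moments(ip, sf_ip)
    mu_b, var_b = group_moments(bg, sf_bg)
    log2fc = np.log2(mu_a / mu_b)
    ln2sq = math.log(2.0) ** 2
    se = np.sqrt(var_a / (mu_a**2 * ln2sq) + var_b / (mu_b**2 * ln2sq))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, log2fc / se, 0.0)
    p = 2.0 * sps.norm.sf(np.abs(z))
    testable = (ip.sum(axis=1) + bg.sum(axis=1)) > 0
    log2fc = np.where(testable, log2fc, 0.0)
    p = np.where(testable, np.minimum(p, 1.0), 1.0)
    return {
        "log2fc": log2fc,
        "z": np.where(testable, z, 0.0),
        "p_value": p,
        "dispersion": alpha,
        "testable": testable,
    }


def nb_enrichment_test(
    ip,
    bg,
    sf: np.ndarray | None = None,
    dispersion: float | None = None,
) -> TestResult:
    """NB Wald test for a single gene (IP replicates vs background replicates).

    ``sf`` concatenates the size factors of the IP then background samples
    (defaults to all ones). With ``dispersion`` unspecified it is estimated
    from the replicates, requiring >= 2 per group.
    """
    ip = np.asarray(ip, dtype=float)[None, :]
    bg = np.asarray(bg, dtype=float)[None, :]
    if sf is None:
        sf = np.ones(ip.shape[1] + bg.shape[1])
    sf = np.asarray(sf, dtype=float)
    out = nb_wald_matrix(ip, bg, sf[: ip.shape[1]], sf[ip.shape[1]:], dispersion)
    return TestResult(
        statistic=float(out["z"][0]),
        p_value=float(out["p_value"][0]),
        sidedness="two-sided",
        method="nb-wald",
    )


# ---------------------------------------------------------------------------
# multiple testing


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# one-sided two-sample Kolmogorov–Smirnov


def _dplus(enriched: np.ndarray, reference: np.ndarray) -> float:
    """D+ = sup over pooled points of ECDF_reference - ECDF_enriched."""
    pooled = np.union1d(enriched, reference)
    ecdf_e = np.searchsorted(np.sort(enriched), pooled, side="right") / enriched.size
    ecdf_r = np.searchsorted(np.sort(reference), pooled, side="right") / reference.size
    return float(np.max(ecdf_r - ecdf_e, initial=0.0))


def ks_one_sided(enriched, reference) -> TestResult:
    """One-sided two-sample KS test, alternative "enriched greater".

    D+ is the signed supremum of (ECDF_reference - ECDF_enriched) over the
    pooled sample points; it is large when the enriched sample lies to the
    right. For pooled sizes <= 16 the p-value is the exact permutation
    fraction over all labelings of the pooled multiset; otherwise the
    conservative asymptotic bound exp(-2 D+^2 nm/(n+m)).
    """
    enriched = np.asarray(enriched, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if enriched.size == 0 or reference.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = enriched.size, reference.size
    d = _dplus(enriched, reference)
    if n + m <= KS_EXACT_MAX:
        pooled = np.concatenate([enriched, reference])
        idx = range(n + m)
        hits = total = 0
        for pick in combinations(idx, n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(pick)] = True
            total += 1
            if _dplus(pooled[mask], pooled[~mask]) >= d - 1e-12:
                hits += 1
        p = hits / total
        method = "ks-one-sided-exact"
    else:
        p = min(1.0, math.exp(-2.0 * d * d * n * m / (n + m)))
        method = "ks-one-sided-asymptotic"
    return TestResult(statistic=d, p_value=p, sidedness="one-sided-greater", method=method)


# ---------------------------------------------------------------------------
# Wilcoxon tests and correlation (scipy-backed)


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> TestResult:
    """Mann–Whitney/Wilcoxon rank-sum test with midrank ties.

    Exact enumeration when n + m <= 12 with no ties, else the normal
    approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (x.size + y.size <= WILCOXON_EXACT_MAX and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    side = "two-sided" if alternative == "two-sided" else "one-sided-greater"
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        sidedness=side,
        method=f"rank-sum-{method}",
    )


def wilcoxon_signed_rank(x, mu0: float = 0.0, alternative: str = "two-sided") -> TestResult:
    """One-sample Wilcoxon signed-rank test against location ``mu0``.

    Zero differences are dropped; exact p when n <= 12 without tied
    absolute differences.
    """
    d = np.asarray(x, dtype=float) - mu0
    d = d[d != 0]
    if d.size == 0:
        return TestResult(0.0, 1.0, alternative, "signed-rank-degenerate")
    no_ties = np.unique(np.abs(d)).size == d.size
    method = "exact" if (d.size <= WILCOXON_EXACT_MAX and no_ties) else "approx"
    res = sps.wilcoxon(d, alternative=alternative, method=method)
    side = "two-sided" if alternative == "two-sided" else "one-sided-greater"
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        sidedness=side,
        method=f"signed-rank-{method}",
    )


def pearson(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length vectors of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return float(sps.pearsonr(x, y).statistic)
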