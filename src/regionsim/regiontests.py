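"""Region-based rare-variant association statistics with permutation nulls.

Three statistics over the rare (panel MAF < 0.05) sites of a
case/control panel:

``c-Alpha``
    Overdispersion of the case/control split of minor-allele copies
    across sites relative to the binomial null.
``ESM_K``
    Excess of the K smallest single-marker -log10 p-values over their
    uniform-order-statistic expectation.
``SKAT``
    Variance-component score statistic Q = r' G W W' G' r with linear
    or Beta(1, 25) weights; with linear weights Q differs from c-Alpha
    by a label-invariant constant, so the two yield identical
    permutation p-values.

Significance for all of them comes from permuting case/control labels;
the add-one (Davison-Hinkley) convention avoids p = 0 and makes the
null distribution of p-values super-uniform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .association import CaseControlPanel, single_marker_logistic

__all__ = [
    "RegionTestResult",
    "rare_filter",
    "calpha_statistic",
    "esm_statistic",
    "skat_statistic",
    "calpha_from_matrix",
    "skat_from_matrix",
    "esm_from_matrix",
    "allele_count_chi2",
    "permutation_p",
    "region_test",
    "region_power",
]


@dataclass
class RegionTestResult:
    statistic: float
    permutations_used: int
    p_value: float
    method: str
    k_used: int = 0
    flagged: bool = False


def rare_filter(panel: CaseControlPanel) -> np.ndarray:
    """Mask of rare sites: panel MAF strictly below 0.05 and >= 1 copy."""
    maf = np.asarray(panel.site_maf)
    return (maf > 0.0) & (maf < 0.05)


def calpha_statistic(case_counts, total_counts, p0: float) -> float:
    """c-Alpha overdispersion statistic.

    T = sum_i [(y_i - n_i p0)^2 - n_i p0 (1 - p0)] where y_i is the
    number of minor-allele copies observed in cases at site i, n_i the
    total copies, and p0 the case fraction.
    """
    y = np.asarray(case_counts, dtype=float)
    n = np.asarray(total_counts, dtype=float)
    if np.any(y > n):
        raise ValueError("case_counts cannot exceed total_counts")
    return float(((y - n * p0) ** 2 - n * p0 * (1.0 - p0)).sum())


def esm_statistic(site_p_values, K: int = 50) -> float:
    """Excess of observed over uniform-expected -log10 order statistics.

    With sorted p_(1) <= ... <= p_(m) and k = min(K, m):
    ESM_K = sum_{i<=k} [-log10 p_(i) + log10(i / m)].
    Larger values indicate an enrichment of small single-marker
    p-values among the region's rare sites.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    p = np.sort(np.asarray(site_p_values, dtype=float))
    m = p.size
    if m == 0:
        raise ValueError("no p-values given")
    k = min(K, m)
    i = np.arange(1, k + 1)
    return float((-np.log10(p[:k]) + np.log10(i / m)).sum())


def skat_statistic(dosages, status, weights: str = "linear", maf=None) -> float:
    """SKAT score statistic with an intercept-only null model.

    Q = sum_i w_i^2 (g_i' r)^2 with r = y - mean(y); ``weights`` is
    ``"linear"`` (w = 1) or ``"beta"`` (w = Beta(1, 25) density at the
    site MAF, the package default upweighting the rarest variants).
    """
    g = np.asarray(dosages, dtype=float)
    y = np.asarray(status, dtype=float)
    r = y - y.mean()
    score = g.T @ r
    w = _skat_weights(g, weights, maf)
    return float(((w * score) ** 2).sum())


def _skat_weights(g, weights, maf):
    if weights == "linear":
        return np.ones(g.shape[1])
    if weights != "beta":
        raise ValueError("weights must be 'linear' or 'beta'")
    if maf is None:
        f = g.mean(axis=0) / 2.0
        maf = np.minimum(f, 1.0 - f)
    return stats.beta.pdf(np.asarray(maf, dtype=float), 1.0, 25.0)


# --- statistic adapters: f(dosages, status) -> float, reusable under
# --- permutation of the status vector


def calpha_from_matrix(dosages, status) -> float:
    y = np.asarray(status, dtype=float)
    g = np.asarray(dosages, dtype=float)
    p0 = y.mean()
    case_counts = g.T @ y
    total = g.sum(axis=0)
    return float(((case_counts - total * p0) ** 2 - total * p0 * (1.0 - p0)).sum())


def skat_from_matrix(dosages, status, weights: str = "linear", maf=None) -> float:
    return skat_statistic(dosages, status, weights=weights, maf=maf)


def allele_count_chi2(dosages, status):
    """Vectorized per-site allele-count chi-square p-values (1 df).

    The 2x2 table per site counts minor vs major allele copies in
    cases vs controls; used as the fast single-marker test inside
    permuted ESM evaluations.
    """
    g = np.asarray(dosages, dtype=float)
    y = np.asarray(status, dtype=float)
    n_case = y.sum()
    n_ctrl = len(y) - n_case
    a = g.T @ y  # minor copies in cases
    c = g.sum(axis=0) - a  # minor copies in controls
    b = 2.0 * n_case - a
    d = 2.0 * n_ctrl - c
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(denom > 0, n * (a * d - b * c) ** 2 / denom, 0.0)
    return stats.chi2.sf(chi2, df=1)


def esm_from_matrix(dosages, status, K: int = 50, marker_test: str = "chi2") -> float:
    """ESM_K on a dosage matrix using a fast per-site marker test."""
    if marker_test != "chi2":
        raise ValueError("only the allele-count chi2 marker test is vectorized")
    return esm_statistic(allele_count_chi2(dosages, status), K=K)


def permutation_p(
    statistic_fn,
    dosages,
    status,
    max_permutations: int = 2_000_000,
    adaptive: bool = False,
    alpha: float = 1e-6,
    rng: np.random.Generator | None = None,
    method: str = "custom",
    check_every: int = 10_000,
) -> RegionTestResult:
    """Empirical p-value by case/control label permutation.

    Permutes the status labels (preserving the case/control counts),
    recomputes ``statistic_fn(dosages, permuted)`` and returns the
    add-one p-value (1 + #{perm >= observed}) / (1 + B).  Adaptive mode
    stops early once the 99% CI of p excludes ``alpha`` (useful when
    scanning many replicates; off by default for reproducibility).
    """
    if max_permutations < 1:
        raise ValueError("max_permutations must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    y = np.asarray(status)
    obs = statistic_fn(dosages, y)
    exceed = 0
    done = 0
    while done < max_permutations:
        perm = rng.permutation(y)
        if statistic_fn(dosages, perm) >= obs:
            exceed += 1
        done += 1
        if adaptive and done % check_every == 0:
            phat = (1 + exceed) / (1 + done)
            half = 2.576 * np.sqrt(phat * (1 - phat) / done)
            if phat - half > alpha or phat + half < alpha:
                break
    return RegionTestResult(
        statistic=float(obs),
        permutations_used=done,
        p_value=(1 + exceed) / (1 + done),
        method=method,
    )


def region_test(
    panel: CaseControlPanel,
    method: str,
    max_permutations: int = 2_000_000,
    K: int = 50,
    adaptive: bool = False,
    alpha: float = 1e-6,
    rng: np.random.Generator | None = None,
) -> RegionTestResult:
    """Run one region test on the rare-filtered sites of a panel.

    ``method`` is one of ``"esm"``, ``"calpha"``, ``"skat_linear"``,
    ``"skat_beta"``.  An empty rare-site set yields p = 1 with a flag.
    """
    mask = rare_filter(panel)
    if not mask.any():
        return RegionTestResult(
            statistic=np.nan,
            permutations_used=0,
            p_value=1.0,
            method=method,
            flagged=True,
        )
    g = panel.minor_dosages()[:, mask]
    maf = np.asarray(panel.site_maf)[mask]
    if method == "esm":
        fn = lambda d, y: esm_from_matrix(d, y, K=K)  # noqa: E731
    elif method == "calpha":
        fn = calpha_from_matrix
    elif method == "skat_linear":
        fn = lambda d, y: skat_from_matrix(d, y, "linear")  # noqa: E731
    elif method == "skat_beta":
        fn = lambda d, y: skat_from_matrix(d, y, "beta", maf=maf)  # noqa: E731
    else:
        raise ValueError(f"unknown method {method!r}")
    res = permutation_p(
        fn,
        g,
        panel.status,
        max_permutations=max_permutations,
        adaptive=adaptive,
        alpha=alpha,
        rng=rng,
        method=method,
    )
    if method == "esm":
        res.k_used = min(K, g.shape[1])
    return res


def region_power(results, alpha: float = 1e-6) -> float:
    """Fraction of replicate results with p-value below alpha."""
    results = list(results)
    if not results:
        raise ValueError("no results given")
    return sum(1 for r in results if r.p_value < alpha) / len(results)


def esm_logistic(panel: CaseControlPanel, K: int = 50) -> float:
    """ESM_K on the observed labels using the logistic single-marker test.

    The permutation engine uses the fast allele-count chi-square; this
    variant matches the GWAS scan's marker test for reporting the
    observed statistic.
    """
    mask = rare_filter(panel)
    pvals, _ = single_marker_logistic(panel, sites=np.nonzero(mask)[0])
    return esm_statistic(pvals, K=K)
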