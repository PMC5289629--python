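"""Case/control ascertainment, single-marker GWAS and top-hit summaries.

Cases are drawn from the upper tail of the (liability-scale) phenotype
distribution and controls from a band around the population mean.  The
single-marker test is a minor-allele-dosage logistic regression with a
likelihood-ratio p-value; because the dosage takes only the values
0/1/2, each site's likelihood depends on six genotype-by-status counts
only, and all sites are fitted simultaneously by a vectorized Newton
iteration (exactly equivalent to a per-site fit, cross-checked against
statsmodels in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .varcomp import SampleMatrix

__all__ = [
    "CaseControlPanel",
    "ascertain_case_control",
    "make_chip",
    "single_marker_logistic",
    "gwas_power",
    "uniform_maf_ascertainment",
    "top_hit_maf",
    "ks_compare",
]


@dataclass
class CaseControlPanel:
    """Dosages (risk-allele orientation), affection status and site metadata."""

    dosages: np.ndarray
    status: np.ndarray
    site_maf: np.ndarray
    site_is_causal: np.ndarray
    site_effect: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        self.status = np.asarray(self.status)
        if self.dosages.shape[0] != len(self.status):
            raise ValueError("status must have one entry per individual")

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return int((1 - self.status).sum())

    def minor_dosages(self) -> np.ndarray:
        """Dosages counted toward the panel minor allele."""
        freq = self.dosages.mean(axis=0) / 2.0
        out = np.where(freq > 0.5, 2 - self.dosages, self.dosages)
        return out


def ascertain_case_control(
    sample: SampleMatrix,
    n_case: int = 3000,
    n_control: int = 3000,
    case_tail: float = 0.15,
    control_band_sd: float = 0.5,
    rng: np.random.Generator | None = None,
) -> CaseControlPanel:
    """Liability-scale ascertainment from a population sample.

    Cases: uniform without replacement from individuals at or above the
    empirical (1 - case_tail) phenotype quantile.  Controls: uniform
    from individuals within ``control_band_sd`` phenotype SDs of the
    mean, excluding chosen cases.  Site MAF is recomputed within the
    panel.
    """
    rng = np.random.default_rng() if rng is None else rng
    p = np.asarray(sample.phenotypes, dtype=float)
    thresh = np.quantile(p, 1.0 - case_tail)
    case_pool = np.nonzero(p >= thresh)[0]
    if len(case_pool) < n_case:
        raise ValueError(
            f"only {len(case_pool)} individuals in the upper {case_tail:.0%} tail"
        )
    cases = rng.choice(case_pool, size=n_case, replace=False)
    band = control_band_sd * p.std()
    ctrl_pool = np.nonzero(np.abs(p - p.mean()) <= band)[0]
    ctrl_pool = np.setdiff1d(ctrl_pool, cases, assume_unique=False)
    if len(ctrl_pool) < n_control:
        raise ValueError(
            f"only {len(ctrl_pool)} individuals within {control_band_sd} SD of the mean"
        )
    controls = rng.choice(ctrl_pool, size=n_control, replace=False)
    idx = np.concatenate([cases, controls])
    status = np.concatenate([np.ones(n_case, dtype=np.int8), np.zeros(n_control, dtype=np.int8)])
    dos = sample.dosages[idx]
    freq = dos.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    return CaseControlPanel(
        dosages=dos,
        status=status,
        site_maf=maf,
        site_is_causal=np.asarray(sample.site_effect) > 0,
        site_effect=np.asarray(sample.site_effect, dtype=float),
    )


def make_chip(panel: CaseControlPanel, design: str) -> np.ndarray:
    """Site mask for a study design.

    ``gene_chip`` keeps panel-MAF >= 0.05; ``resequencing`` keeps all
    sites polymorphic in the panel.
    """
    if design not in ("gene_chip", "resequencing"):
        raise ValueError("design must be 'gene_chip' or 'resequencing'")
    maf = np.asarray(panel.site_maf)
    if design == "gene_chip":
        return maf >= 0.05
    return maf > 0.0


def _logistic_suffstats(g: np.ndarray, y: np.ndarray):
    """Per-site genotype-by-status counts n[g, y] for g in 0..2."""
    counts = np.zeros((3, 2, g.shape[1]))
    for gv in range(3):
        mask = g == gv
        counts[gv, 1] = mask[y == 1].sum(axis=0)
        counts[gv, 0] = mask[y == 0].sum(axis=0)
    return counts


def single_marker_logistic(panel: CaseControlPanel, sites=None, max_iter: int = 40):
    """Likelihood-ratio p-values of status on minor-allele dosage.

    Returns ``(p_values, flagged)``; flagged sites (monomorphic in the
    panel, perfectly separated, or non-converged) get p = 1 by
    convention rather than failing the whole scan.
    """
    g_all = panel.minor_dosages()
    idx = np.arange(g_all.shape[1]) if sites is None else np.asarray(sites)
    g = g_all[:, idx]
    y = panel.status
    if panel.n_cases < 1 or panel.n_controls < 1:
        raise ValueError("need at least one case and one control")
    m = g.shape[1]
    counts = _logistic_suffstats(g, y)  # (3, 2, m)
    n_g = counts.sum(axis=1)  # (3, m)
    n1_g = counts[:, 1, :]
    n_tot = float(len(y))
    n1 = float(y.sum())

    flagged = np.zeros(m, dtype=bool)
    # monomorphic: a single dosage value present
    flagged |= (n_g > 0).sum(axis=0) <= 1
    # perfect separation on an ordered dosage: case and control supports
    # do not overlap
    gvals = np.arange(3)[:, None]
    with np.errstate(invalid="ignore"):
        case_min = np.min(np.where(n1_g > 0, gvals, 99), axis=0)
        case_max = np.max(np.where(n1_g > 0, gvals, -99), axis=0)
        ctrl = counts[:, 0, :]
        ctrl_min = np.min(np.where(ctrl > 0, gvals, 99), axis=0)
        ctrl_max = np.max(np.where(ctrl > 0, gvals, -99), axis=0)
    flagged |= (case_min > ctrl_max) | (ctrl_min > case_max)

    p0 = n1 / n_tot
    ll_null = n1 * np.log(p0) + (n_tot - n1) * np.log1p(-p0)

    b0 = np.full(m, np.log(p0 / (1.0 - p0)))
    b1 = np.zeros(m)
    active = ~flagged
    for _ in range(max_iter):
        if not active.any():
            break
        eta = b0[None, :] + b1[None, :] * gvals  # (3, m)
        pg = 1.0 / (1.0 + np.exp(-eta))
        resid = n1_g - n_g * pg
        grad0 = resid.sum(axis=0)
        grad1 = (gvals * resid).sum(axis=0)
        wgt = n_g * pg * (1.0 - pg)
        h00 = wgt.sum(axis=0)
        h01 = (gvals * wgt).sum(axis=0)
        h11 = (gvals**2 * wgt).sum(axis=0)
        det = h00 * h11 - h01**2
        bad = det <= 1e-12
        flagged |= bad & active
        active &= ~bad
        step0 = np.where(active, (h11 * grad0 - h01 * grad1) / np.where(det > 0, det, 1.0), 0.0)
        step1 = np.where(active, (h00 * grad1 - h01 * grad0) / np.where(det > 0, det, 1.0), 0.0)
        b0 += np.clip(step0, -5, 5)
        b1 += np.clip(step1, -5, 5)
        conv = (np.abs(grad0) < 1e-8) & (np.abs(grad1) < 1e-8)
        active &= ~conv
    flagged |= active | (np.abs(b1) > 30)

    eta = b0[None, :] + b1[None, :] * gvals
    with np.errstate(over="ignore"):
        ll_full = (counts[:, 1, :] * eta - n_g * np.logaddexp(0.0, eta)).sum(axis=0)
    lrt = np.maximum(2.0 * (ll_full - ll_null), 0.0)
    pvals = stats.chi2.sf(lrt, df=1)
    pvals[flagged] = 1.0
    return pvals, flagged


def gwas_power(pvalue_sets, alpha: float = 1e-8) -> float:
    """Fraction of replicates whose smallest p-value reaches alpha."""
    sets = list(pvalue_sets)
    if not sets:
        raise ValueError("no replicates given")
    hits = 0
    for ps in sets:
        ps = np.asarray(ps)
        if ps.size and np.min(ps) <= alpha:
            hits += 1
    return hits / len(sets)


def uniform_maf_ascertainment(
    site_maf,
    rng: np.random.Generator,
    n_bins: int = 20,
    maf_min: float = 0.01,
    target_per_bin: int | None = None,
):
    """Subsample sites so the retained MAF histogram is flat.

    Emulates genotyping-chip marker selection: sites with MAF below
    ``maf_min`` are removed; the remainder is binned on
    [maf_min, 0.5] and each bin is subsampled without replacement to a
    common count (by default the smallest non-empty bin count).  Bins
    with fewer sites than the target are capped at availability.
    Returns ``(site_indices, per_bin_counts)``.
    """
    maf = np.asarray(site_maf, dtype=float)
    edges = np.linspace(maf_min, 0.5, n_bins + 1)
    eligible = np.nonzero(maf >= maf_min)[0]
    if eligible.size == 0:
        return eligible, np.zeros(n_bins, dtype=int)
    which_bin = np.clip(np.digitize(maf[eligible], edges) - 1, 0, n_bins - 1)
    counts = np.bincount(which_bin, minlength=n_bins)
    nonempty = counts[counts > 0]
    target = int(nonempty.min()) if target_per_bin is None else target_per_bin
    chosen = []
    achieved = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        members = eligible[which_bin == b]
        if members.size == 0:
            continue
        take = min(target, members.size)
        chosen.append(rng.choice(members, size=take, replace=False))
        achieved[b] = take
    return np.sort(np.concatenate(chosen)), achieved


def top_hit_maf(pvalues, site_maf, alpha: float = 1e-8, rng=None):
    """MAF of the most significant marker, or None when none reaches alpha.

    Ties for the smallest p-value are broken uniformly at random.
    """
    p = np.asarray(pvalues, dtype=float)
    maf = np.asarray(site_maf, dtype=float)
    if p.size == 0:
        return None
    pmin = p.min()
    if pmin > alpha:
        return None
    tied = np.nonzero(p == pmin)[0]
    rng = np.random.default_rng() if rng is None else rng
    return float(maf[rng.choice(tied)])


def ks_compare(sim_mafs, empirical_mafs):
    """Two-sample Kolmogorov-Smirnov test (statistic, asymptotic p)."""
    a = np.asarray(sim_mafs, dtype=float)
    b = np.asarray(empirical_mafs, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)
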