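"""Variance partitioning, GRMs, Haseman-Elston regression and load.

The central object is a :class:`SampleMatrix`: an individuals x sites
risk-allele dosage matrix with per-site frequencies and effects plus
per-individual genetic values and phenotypes.  The variance-curve
machinery regresses true genetic values on additive (0/1/2) and
orthogonal dominance (0, 2q, 4q-2) codes of all sites with frequency
q <= x, reading off the cumulative fraction of V_G attributable to
additive (and dominance) effects of variants up to each frequency
threshold.  This regression approach is required because under
gene-based recessivity the effect of a variant depends on its local
genetic background, so no per-site formula applies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import PopulationState
from .traits import TraitModelSpec, assign_phenotypes, genetic_values_matrix

__all__ = [
    "SampleMatrix",
    "VarianceCurve",
    "sample_from_population",
    "dominance_code",
    "variance_curve",
    "fisher_site_variance",
    "grm_additive",
    "grm_dominance",
    "he_regression",
    "genetic_load",
    "burden_ratio",
    "sfs",
    "gamete_summaries",
]


@dataclass
class SampleMatrix:
    """Genotype dosages plus per-site and per-individual metadata.

    ``site_freq`` is the risk (derived) allele frequency in the
    reference group -- the whole population when the matrix was drawn
    from one, otherwise the sample itself.
    """

    dosages: np.ndarray
    site_freq: np.ndarray
    site_effect: np.ndarray
    phenotypes: np.ndarray
    genetic_values: np.ndarray
    site_position: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        n, m = self.dosages.shape
        for name in ("site_freq", "site_effect"):
            if len(getattr(self, name)) != m:
                raise ValueError(f"{name} must have one entry per site")
        for name in ("phenotypes", "genetic_values"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} must have one entry per individual")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_sites(self) -> int:
        return self.dosages.shape[1]

    @property
    def causal_mask(self) -> np.ndarray:
        return np.asarray(self.site_effect) > 0

    def minor_allele_frequencies(self) -> np.ndarray:
        """Sample MAF per site (folded frequency computed in the matrix)."""
        f = self.dosages.mean(axis=0) / 2.0
        return np.minimum(f, 1.0 - f)


@dataclass
class VarianceCurve:
    """Cumulative adjusted-r^2 curves over frequency thresholds."""

    thresholds: np.ndarray
    va_cum: np.ndarray
    vad_cum: np.ndarray

    @property
    def vd_cum(self) -> np.ndarray:
        return self.vad_cum - self.va_cum


def sample_from_population(
    pop: PopulationState,
    spec: TraitModelSpec,
    rng: np.random.Generator,
    n: int | None = None,
    sites: str = "causal",
) -> SampleMatrix:
    """Draw individuals (without replacement) into a :class:`SampleMatrix`.

    Site frequencies are computed in the *population* (the reference
    group); phenotypes receive fresh environmental deviates.
    ``sites`` is ``"causal"``, ``"neutral"`` or ``"all"``.
    """
    if sites not in ("causal", "neutral", "all"):
        raise ValueError("sites must be 'causal', 'neutral' or 'all'")
    freqs = pop.allele_frequencies()
    eff = pop.mutations.effects
    if sites == "causal":
        keep = eff > 0
    elif sites == "neutral":
        keep = eff == 0
    else:
        keep = np.ones(len(eff), dtype=bool)
    dosages_all = pop.dosages()[:, keep]
    if n is None:
        idx = np.arange(pop.n_diploids)
    else:
        if n > pop.n_diploids:
            raise ValueError("sample larger than population")
        idx = rng.choice(pop.n_diploids, size=n, replace=False)
    g = genetic_values_matrix(pop.occupancy, eff, spec)[idx]
    phen = assign_phenotypes(g, spec.sigma_e, rng)
    return SampleMatrix(
        dosages=dosages_all[idx],
        site_freq=freqs[keep],
        site_effect=eff[keep],
        phenotypes=phen.phenotypes,
        genetic_values=g,
        site_position=pop.mutations.positions[keep],
    )


def dominance_code(dosage, q):
    """Orthogonal-model dominance covariate: 0 -> 0, 1 -> 2q, 2 -> 4q-2.

    Constructed to be uncorrelated with the additive 0/1/2 code under
    Hardy-Weinberg proportions at frequency ``q``.
    """
    dosage = np.asarray(dosage)
    q = np.asarray(q, dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("q must be in (0, 1)")
    if not np.isin(dosage, (0, 1, 2)).all():
        raise ValueError("dosage must be 0, 1 or 2")
    return np.select([dosage == 1, dosage == 2], [2.0 * q, 4.0 * q - 2.0], default=0.0)


def _adjusted_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Adjusted r^2 of the least-squares fit of y on [1, x].

    Rank-deficient designs are handled by the lstsq pseudoinverse;
    the effective number of predictors is the design rank minus one
    (pivoted-out columns contribute no variance).
    """
    n = len(y)
    design = np.column_stack([np.ones(n), x])
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        return 0.0
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ssr = float((resid**2).sum())
    r2 = 1.0 - ssr / sst
    p = max(rank - 1, 0)
    if n - p - 1 <= 0:
        raise ValueError("more predictors than residual degrees of freedom")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def variance_curve(sample: SampleMatrix, thresholds) -> VarianceCurve:
    """Cumulative V_A and V_A + V_D fractions across frequency thresholds.

    For each threshold x, causal sites with risk-allele frequency
    q <= x are selected, ordered by decreasing frequency then
    decreasing effect, and the *true genetic values* are regressed on
    (a) the additive dosage codes and (b) additive plus orthogonal
    dominance codes; the adjusted r^2 of each fit is the fraction of
    V_G explained.  Zero selected sites give 0 by convention.
    """
    thresholds = np.asarray(thresholds, dtype=float)
    causal = sample.causal_mask
    dos = sample.dosages[:, causal]
    q = np.asarray(sample.site_freq, dtype=float)[causal]
    eff = np.asarray(sample.site_effect, dtype=float)[causal]
    y = np.asarray(sample.genetic_values, dtype=float)
    va = np.zeros(len(thresholds))
    vad = np.zeros(len(thresholds))
    for k, x in enumerate(thresholds):
        pick = np.nonzero(q <= x)[0]
        if pick.size == 0:
            continue
        order = np.lexsort((-eff[pick], -q[pick]))
        pick = pick[order]
        xa = dos[:, pick].astype(float)
        xd = dominance_code(dos[:, pick], q[pick][None, :])
        va[k] = _adjusted_r2(xa, y)
        # interleave additive/dominance per site, frequency-major order
        joint = np.empty((xa.shape[0], 2 * xa.shape[1]))
        joint[:, 0::2] = xa
        joint[:, 1::2] = xd
        vad[k] = _adjusted_r2(joint, y)
    return VarianceCurve(thresholds=thresholds, va_cum=va, vad_cum=vad)


def fisher_site_variance(q, alpha):
    """Classical single-site additive variance 2 q (1-q) alpha^2."""
    q = np.asarray(q, dtype=float)
    if np.any((q <= 0) | (q >= 1)):
        raise ValueError("q must be in (0, 1)")
    return 2.0 * q * (1.0 - q) * np.asarray(alpha, dtype=float) ** 2


def _check_freqs(freqs: np.ndarray) -> None:
    if np.any((freqs <= 0) | (freqs >= 1)):
        raise ValueError("monomorphic sites are not allowed in a GRM")


def grm_additive(sample: SampleMatrix, site_subset=None) -> np.ndarray:
    """Additive genetic relatedness matrix.

    A_jk = (1/M) sum_i (x_ij - 2 q_i)(x_ik - 2 q_i) / (2 q_i (1 - q_i)).
    """
    sub = slice(None) if site_subset is None else site_subset
    x = sample.dosages[:, sub].astype(float)
    q = np.asarray(sample.site_freq, dtype=float)[sub]
    _check_freqs(q)
    z = (x - 2.0 * q) / np.sqrt(2.0 * q * (1.0 - q))
    return (z @ z.T) / z.shape[1]


def grm_dominance(sample: SampleMatrix, site_subset=None) -> np.ndarray:
    """Dominance GRM from centered orthogonal codes.

    D_jk = (1/M) sum_i d_ij d_ik / (2 q_i (1 - q_i))^2 with
    d = code - 2 q^2 (the HWE-centered 0/2q/4q-2 code).
    """
    sub = slice(None) if site_subset is None else site_subset
    x = sample.dosages[:, sub]
    q = np.asarray(sample.site_freq, dtype=float)[sub]
    _check_freqs(q)
    d = dominance_code(x, q[None, :]) - 2.0 * q**2
    var = (2.0 * q * (1.0 - q)) ** 2
    return ((d / var) @ d.T) / d.shape[1]


def he_regression(grms, phenotypes):
    """Haseman-Elston regression of phenotype cross-products on GRMs.

    Phenotypes are standardized internally; the products z_j z_k over
    all pairs j < k are regressed on the corresponding off-diagonal
    entries of each GRM (jointly when several are given, e.g. additive
    plus dominance, or MAF-stratified bins).  The coefficient on each
    GRM estimates the fraction of phenotypic variance attributable to
    that component.  Returns ``(estimates, standard_errors)``.
    """
    if not isinstance(grms, (list, tuple)):
        grms = [grms]
    y = np.asarray(phenotypes, dtype=float)
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 individuals")
    for a in grms:
        if a.shape != (n, n):
            raise ValueError("GRM shape must match phenotype length")
    z = (y - y.mean()) / y.std()
    iu = np.triu_indices(n, k=1)
    resp = z[iu[0]] * z[iu[1]]
    design = np.column_stack([np.ones(len(resp))] + [a[iu] for a in grms])
    coef, _, _, _ = np.linalg.lstsq(design, resp, rcond=None)
    resid = resp - design @ coef
    dof = len(resp) - design.shape[1]
    s2 = float(resid @ resid) / dof
    cov = s2 * np.linalg.pinv(design.T @ design)
    se = np.sqrt(np.diag(cov))
    return coef[1:], se[1:]


def genetic_load(phenotypes, sigma_s: float = 1.0) -> float:
    """Relative mean-fitness deficit L = 1 - mean exp(-P^2 / (2 sigma_s^2)).

    With the optimum at zero and w_max = 1 this equals
    (w_max - mean w) / w_max.  Pass genetic values instead of
    phenotypes for the genetic (environment-free) load, or the fixed /
    segregating components separately; note the total load is not the
    sum of the fixed and segregating loads (fitness is not
    multiplicative across the Gaussian function).
    """
    if sigma_s <= 0:
        raise ValueError("sigma_s must be > 0")
    p = np.atleast_1d(np.asarray(phenotypes, dtype=float))
    return float(1.0 - np.mean(np.exp(-(p**2) / (2.0 * sigma_s**2))))


def burden_ratio(load_noneq: float, load_eq: float) -> float:
    """Ratio of load between a non-equilibrium and an equilibrium population."""
    if load_eq <= 0:
        raise ValueError("equilibrium load must be > 0")
    return load_noneq / load_eq


def sfs(sample_dosages, lump_above: int = 18):
    """Relative site frequency spectrum with a lumped tail.

    Returns proportions over derived-allele count classes 1..lump_above
    plus one class for all higher counts; proportions sum to 1.
    """
    dos = np.asarray(sample_dosages)
    counts = dos.sum(axis=0)
    n_chrom = 2 * dos.shape[0]
    poly = counts[(counts > 0) & (counts < n_chrom)]
    if poly.size == 0:
        raise ValueError("no polymorphic sites")
    out = np.zeros(lump_above + 1)
    for c in poly:
        out[min(int(c), lump_above + 1) - 1] += 1
    return out / poly.size


def gamete_summaries(pop: PopulationState) -> dict:
    """Moments of per-gamete deleterious-mutation count and effect sum.

    The per-gamete effect sum is the haplotype score of the gene-based
    recessive model; under that model its population mean is also the
    expected mean phenotype.  Skew/kurtosis are flagged as NaN when
    undefined (degenerate distributions).
    """
    occ = pop.occupancy.astype(np.float64, copy=False)
    causal = (pop.mutations.effects > 0).astype(np.float64)
    counts = occ @ causal
    sums = occ @ pop.mutations.effects
    out = {}
    for name, v in (("count", counts), ("effect_sum", sums)):
        out[f"mean_{name}"] = float(np.mean(v)) if v.size else 0.0
        if v.size == 0 or np.var(v) == 0:
            out[f"skew_{name}"] = float("nan")
            out[f"kurtosis_{name}"] = float("nan")
        else:
            out[f"skew_{name}"] = float(stats.skew(v))
            out[f"kurtosis_{name}"] = float(stats.kurtosis(v))
    return out
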