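"""Genotype -> phenotype -> fitness maps.

Three models of gene action for a single gene region contributing to a
quantitative (disease-liability) trait:

``AC``
    Additive co-dominant: the genetic value is the sum of mutational
    effects over both haplotypes.
``GBR``
    Gene-based recessive: each haplotype gets a score (sum of its
    mutational effects) and the genetic value is the geometric mean of
    the two scores.  Recessivity is a property of the *gene region*:
    compound heterozygotes (Ab/aB) are affected because neither
    haplotype is wild type, i.e. mutations fail to complement.
``MR``
    Multiplicative recessive with site-level dominance ``h``:
    G = prod_het (1 + h c) * prod_hom (1 + 2 c) - 1.  ``h = 0`` is
    complete site recessivity (a compound heterozygote is wild type),
    ``h = 1`` approximates the additive model for small effects.

Phenotypes are P = G + E with E ~ Normal(0, sigma_e^2); fitness is
Gaussian stabilizing selection around an optimum of zero,
w = exp(-P^2 / (2 sigma_s^2)).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TraitModelSpec",
    "PhenotypeSet",
    "genetic_value",
    "genetic_values_matrix",
    "assign_phenotypes",
    "fitness",
    "idealized_fitness_dominance",
    "analytic_selection_distribution",
]

_MODELS = ("AC", "GBR", "MR")


@dataclass(frozen=True)
class TraitModelSpec:
    """Parameters of the genotype-to-fitness map.

    Parameters
    ----------
    model
        One of ``"AC"``, ``"GBR"``, ``"MR"``.
    h
        Dominance coefficient for trait effects; only meaningful for the
        MR model (``h=1`` co-dominance, ``h=0`` complete recessivity).
    lambda_
        Mean (and SD) of the exponential distribution of trait effects
        of new causal mutations, in phenotype units.
    sigma_e
        Environmental standard deviation.
    sigma_s
        Width of the Gaussian fitness function (inverse selection
        intensity); the study-standard value is 1.
    p_opt
        Optimum phenotype (default 0).
    """

    model: str = "AC"
    h: float = 1.0
    lambda_: float = 0.1
    sigma_e: float = 0.075
    sigma_s: float = 1.0
    p_opt: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"unknown model {self.model!r}; expected one of {_MODELS}")
        if self.lambda_ <= 0:
            raise ValueError("lambda_ must be > 0")
        if self.sigma_e < 0:
            raise ValueError("sigma_e must be >= 0")
        if self.sigma_s <= 0:
            raise ValueError("sigma_s must be > 0")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError("h must be in [0, 1]")


@dataclass
class PhenotypeSet:
    """Per-diploid genetic values, environmental deviates and phenotypes."""

    genetic_values: np.ndarray
    environmental: np.ndarray
    phenotypes: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.genetic_values = np.asarray(self.genetic_values, dtype=float)
        self.environmental = np.asarray(self.environmental, dtype=float)
        if self.genetic_values.shape != self.environmental.shape:
            raise ValueError("genetic and environmental arrays must align")
        self.phenotypes = self.genetic_values + self.environmental


def _haplotype_score(effects: np.ndarray, ids: np.ndarray) -> float:
    return float(effects[ids].sum()) if len(ids) else 0.0


def genetic_value(diploid, mutations, spec: TraitModelSpec) -> float:
    """Genetic value of one diploid under the chosen model.

    ``diploid`` provides ``gamete_a.mutation_ids`` and
    ``gamete_b.mutation_ids`` (integer indices into ``mutations``);
    ``mutations`` provides an ``effects`` array.  Neutral mutations
    (effect 0) contribute nothing under every model.
    """
    eff = np.asarray(mutations.effects, dtype=float)
    a = np.asarray(diploid.gamete_a.mutation_ids, dtype=np.intp)
    b = np.asarray(diploid.gamete_b.mutation_ids, dtype=np.intp)
    if spec.model == "AC":
        return _haplotype_score(eff, a) + _haplotype_score(eff, b)
    if spec.model == "GBR":
        return float(np.sqrt(_haplotype_score(eff, a) * _haplotype_score(eff, b)))
    # MR: zygosity per exact site (infinite sites: homozygosity only via
    # two copies of the same mutation).
    hom = np.intersect1d(a, b)
    het = np.setxor1d(a, b)
    g = 1.0
    for j in het:
        g *= 1.0 + spec.h * eff[j]
    for j in hom:
        g *= 1.0 + 2.0 * eff[j]
    return g - 1.0


def genetic_values_matrix(
    occupancy: np.ndarray, effects: np.ndarray, spec: TraitModelSpec
) -> np.ndarray:
    """Vectorized genetic values for a whole population.

    ``occupancy`` is a (2N, S) 0/1 array; rows 2i and 2i+1 are the two
    gametes of diploid i.  Equivalent to mapping :func:`genetic_value`
    over diploids but orders of magnitude faster.
    """
    eff = np.asarray(effects, dtype=float)
    if occupancy.shape[1] == 0:
        return np.zeros(occupancy.shape[0] // 2)
    occ = occupancy.astype(np.float64, copy=False)
    if spec.model in ("AC", "GBR"):
        hap = occ @ eff
        s1, s2 = hap[0::2], hap[1::2]
        return s1 + s2 if spec.model == "AC" else np.sqrt(s1 * s2)
    dosage = occupancy[0::2] + occupancy[1::2]
    log_het = np.log1p(spec.h * eff)
    log_hom = np.log1p(2.0 * eff)
    return np.exp((dosage == 1) @ log_het + (dosage == 2) @ log_hom) - 1.0


def assign_phenotypes(
    genetic_values: np.ndarray, sigma_e: float, rng: np.random.Generator
) -> PhenotypeSet:
    """Draw iid environmental deviates E ~ N(0, sigma_e^2) and form P = G + E."""
    if sigma_e < 0:
        raise ValueError("sigma_e must be >= 0")
    g = np.asarray(genetic_values, dtype=float)
    e = rng.normal(0.0, sigma_e, size=g.shape) if sigma_e > 0 else np.zeros_like(g)
    return PhenotypeSet(genetic_values=g, environmental=e)


def fitness(phenotype, sigma_s: float = 1.0, p_opt: float = 0.0):
    """Gaussian stabilizing fitness w = exp(-(P - P_opt)^2 / (2 sigma_s^2))."""
    if sigma_s <= 0:
        raise ValueError("sigma_s must be > 0")
    p = np.asarray(phenotype, dtype=float) - p_opt
    return np.exp(-(p**2) / (2.0 * sigma_s**2))


def idealized_fitness_dominance(c: float, h: float, sigma_s: float = 1.0) -> float:
    """Fitness-dominance ratio s_het/s_hom of a single MR mutation.

    On an otherwise unaffected background a heterozygote has phenotype
    ``h*c`` and a homozygote ``2*c``; the ratio of their selection
    coefficients measures how trait dominance translates into fitness
    dominance.  For h=1 and small c the ratio tends to 1/4 (selection
    is quadratic near the optimum), i.e. even co-dominant trait effects
    look partially recessive in fitness.
    """
    if c <= 0:
        raise ValueError("c must be > 0")
    s_het = 1.0 - float(fitness(h * c, sigma_s))
    s_hom = 1.0 - float(fitness(2.0 * c, sigma_s))
    return s_het / s_hom


def analytic_selection_distribution(lambda_: float, sigma_s: float = 1.0):
    """Closed-form CDFs of s and of 2Ns for a lone new mutation.

    Under the single-mutation approximation the heterozygous carrier of
    an isolated mutation of effect c has phenotype c, so its selection
    coefficient is s(c) = 1 - exp(-c^2 / (2 sigma_s^2)).  With
    c ~ Exponential(lambda), inverting s(c) gives

        F(x) = P(s <= x) = 1 - exp(-sqrt(-2 sigma_s^2 ln(1 - x)) / lambda)

    for x in [0, 1).  Returns ``(cdf_s, cdf_2Ns)`` where ``cdf_2Ns(x, N)``
    is the same distribution after the change of variable to 2Ns.  Large
    lambda puts substantial mass near s = 1 (effective lethality).
    """
    if lambda_ <= 0:
        raise ValueError("lambda_ must be > 0")

    def cdf_s(x):
        x = np.asarray(x, dtype=float)
        if np.any((x < 0) | (x >= 1)):
            raise ValueError("s must lie in [0, 1)")
        c = np.sqrt(-2.0 * sigma_s**2 * np.log1p(-x))
        return 1.0 - np.exp(-c / lambda_)

    def cdf_2ns(x, N):
        x = np.asarray(x, dtype=float)
        return cdf_s(x / (2.0 * N))

    return cdf_s, cdf_2ns
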