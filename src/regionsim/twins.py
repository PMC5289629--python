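"""Simulated MZ/DZ twin studies and classical twin-correlation estimators.

Twin pairs are generated from the final generation of a simulation:
parental couples are sampled without replacement; a monozygotic pair
shares one recombinant gamete from each parent (one genotype, two
independent environmental deviates), a dizygotic pair gets two
independent gamete pairs.  There is no shared environment, so

    H^2    = r_MZ                      (broad-sense heritability)
    delta2 = 2 (r_MZ - 2 r_DZ)         (non-additive / dominance part)
    h^2    = H^2 - delta2 = 4 r_DZ - r_MZ

Correlations use double entry of each pair (the standard symmetric
convention for twin intraclass correlation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import PopulationState
from .traits import TraitModelSpec, genetic_values_matrix

__all__ = [
    "TwinSample",
    "sample_twins",
    "twin_correlation",
    "twin_estimates",
    "pooled_twin_study",
]


@dataclass
class TwinSample:
    """Phenotype pairs, one row per twin pair."""

    mz_pairs: np.ndarray  # (n_mz, 2)
    dz_pairs: np.ndarray  # (n_dz, 2)


def _meiosis(occ: np.ndarray, positions: np.ndarray, parent: int, rate: float, rng):
    """One recombinant gamete row (uint8 site vector) from a parent diploid."""
    start = int(rng.integers(0, 2))
    row_a = occ[2 * parent + start]
    row_b = occ[2 * parent + 1 - start]
    k = int(rng.poisson(rate))
    if k == 0:
        return row_a.copy()
    xo = np.sort(rng.random(k))
    flip = (np.searchsorted(xo, positions) % 2).astype(bool)
    return np.where(flip, row_b, row_a)


def sample_twins(
    pop: PopulationState,
    spec: TraitModelSpec,
    n_mz: int = 2000,
    n_dz: int = 2000,
    rng: np.random.Generator | None = None,
    recombination_rate: float = 0.00125,
) -> TwinSample:
    """Draw MZ and DZ twin phenotype pairs from a population.

    Requires 2 (n_mz + n_dz) distinct diploids: each pair has its own
    parental couple, couples sampled without replacement.
    """
    rng = np.random.default_rng() if rng is None else rng
    need = 2 * (n_mz + n_dz)
    if pop.n_diploids < need:
        raise ValueError(
            f"population of {pop.n_diploids} cannot supply {need} distinct parents"
        )
    parents = rng.choice(pop.n_diploids, size=need, replace=False)
    occ = pop.occupancy
    positions = pop.mutations.positions
    eff = pop.mutations.effects

    def child_g(mother: int, father: int) -> float:
        ga = _meiosis(occ, positions, mother, recombination_rate, rng)
        gb = _meiosis(occ, positions, father, recombination_rate, rng)
        child = np.vstack([ga, gb])
        return float(genetic_values_matrix(child, eff, spec)[0])

    mz = np.empty((n_mz, 2))
    for i in range(n_mz):
        mo, fa = parents[2 * i], parents[2 * i + 1]
        g = child_g(mo, fa)
        mz[i] = g + rng.normal(0.0, spec.sigma_e, 2)
    dz = np.empty((n_dz, 2))
    off = 2 * n_mz
    for i in range(n_dz):
        mo, fa = parents[off + 2 * i], parents[off + 2 * i + 1]
        g1 = child_g(mo, fa)
        g2 = child_g(mo, fa)
        dz[i, 0] = g1 + rng.normal(0.0, spec.sigma_e)
        dz[i, 1] = g2 + rng.normal(0.0, spec.sigma_e)
    return TwinSample(mz_pairs=mz, dz_pairs=dz)


def twin_correlation(pairs: np.ndarray) -> float:
    """Double-entry Pearson correlation of twin pairs."""
    pairs = np.asarray(pairs, dtype=float)
    x = np.concatenate([pairs[:, 0], pairs[:, 1]])
    y = np.concatenate([pairs[:, 1], pairs[:, 0]])
    return float(np.corrcoef(x, y)[0, 1])


def twin_estimates(r_mz: float, r_dz: float):
    """(H2, delta2, h2) from the MZ and DZ correlations."""
    if not (-1.0 <= r_mz <= 1.0 and -1.0 <= r_dz <= 1.0):
        raise ValueError("correlations must lie in [-1, 1]")
    h2_broad = r_mz
    delta2 = 2.0 * (r_mz - 2.0 * r_dz)
    h2 = h2_broad - delta2
    return h2_broad, delta2, h2


def pooled_twin_study(twin_samples, pool_size: int = 8) -> pd.DataFrame:
    """Pool replicate twin studies and estimate per pool.

    Concatenates the pairs of ``pool_size`` consecutive replicates
    before computing correlations; a trailing remainder (replicate
    count not divisible by pool_size) is dropped.  Returns one row per
    pool with r_mz, r_dz, H2, delta2 and h2.
    """
    samples = list(twin_samples)
    n_pools = len(samples) // pool_size
    if n_pools == 0:
        raise ValueError("fewer replicates than pool_size")
    rows = []
    for k in range(n_pools):
        grp = samples[k * pool_size : (k + 1) * pool_size]
        mz = np.vstack([s.mz_pairs for s in grp])
        dz = np.vstack([s.dz_pairs for s in grp])
        r_mz = twin_correlation(mz)
        r_dz = twin_correlation(dz)
        h2_broad, delta2, h2 = twin_estimates(r_mz, r_dz)
        rows.append(
            {"pool": k, "r_mz": r_mz, "r_dz": r_dz, "H2": h2_broad, "delta2": delta2, "h2": h2}
        )
    return pd.DataFrame(rows)
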