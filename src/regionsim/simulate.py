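"""Forward-in-time Wright-Fisher simulation of the gene region.

Each generation: phenotypes and Gaussian stabilizing fitness are
computed for every diploid, parents are drawn with probability
proportional to fitness (two independent draws per offspring, with
replacement), each parent transmits one recombinant gamete, and new
neutral/causal mutations are added at fresh uniform positions
(infinitely many sites).  Fixed mutations are pruned from gametes and
logged; lost mutations are dropped.  Demography is an ordered list of
constant or exponential epochs.

The engine works on the dense (2N, S) occupancy matrix and is fully
vectorized except for the handful of crossover events per generation
(the per-diploid recombination rate is ~1e-3, so a generation rarely
has more than a few).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import (
    FixationLog,
    Gamete,
    MutationTable,
    PopulationState,
    SimulationConfig,
    size_at,
    total_duration,
)
from .traits import TraitModelSpec, assign_phenotypes, fitness, genetic_values_matrix

__all__ = [
    "run_simulation",
    "reproduce_one_generation",
    "mutate_gamete",
    "recombine",
    "empty_population",
    "fixed_genetic_value",
    "total_genetic_values",
]


def empty_population(n_diploids: int, seed: int | None = None) -> PopulationState:
    """A mutation-free population of ``n_diploids`` individuals."""
    return PopulationState(
        MutationTable(),
        np.zeros((2 * n_diploids, 0), dtype=np.uint8),
        generation=0,
        rng_seed=seed,
    )


# ---------------------------------------------------------------------------
# object-level primitives (reference semantics; the engine below is the
# vectorized equivalent)
# ---------------------------------------------------------------------------


def recombine(parent, rate: float, rng: np.random.Generator, table: MutationTable) -> Gamete:
    """One recombinant gamete from a parental diploid.

    Draws k ~ Poisson(rate) crossover points uniform on [0, 1), starts
    from a randomly chosen parental gamete and alternates gametes at
    each crossover.
    """
    if rate < 0:
        raise ValueError("rate must be >= 0")
    start = int(rng.integers(0, 2))
    gams = (parent.gamete_a, parent.gamete_b)
    k = int(rng.poisson(rate))
    if k == 0:
        return gams[start]
    xo = np.sort(rng.random(k))
    ids = []
    for source in gams:
        for mid in source.mutation_ids:
            parity = int(np.searchsorted(xo, table.positions[mid])) % 2
            takes_from = start if parity == 0 else 1 - start
            if source is gams[takes_from]:
                ids.append(mid)
    return Gamete.from_ids(ids, table)


def mutate_gamete(
    gamete: Gamete,
    mu_neutral: float,
    mu_causal: float,
    lambda_: float,
    rng: np.random.Generator,
    table: MutationTable,
    generation: int = 0,
):
    """Add Poisson numbers of new neutral and causal mutations.

    New positions are uniform on [0, 1) (resampled on the
    probability-zero event of a collision); causal effects are drawn
    once from Exponential(mean ``lambda_``) and never change.  Returns
    ``(gamete, table)`` with the extended mutation table.
    """
    n_neu = int(rng.poisson(mu_neutral))
    n_cau = int(rng.poisson(mu_causal))
    n_new = n_neu + n_cau
    if n_new == 0:
        return gamete, table
    existing = set(table.positions.tolist())
    new_pos = []
    while len(new_pos) < n_new:
        x = float(rng.random())
        if x not in existing:
            existing.add(x)
            new_pos.append(x)
    new_eff = np.concatenate(
        [np.zeros(n_neu), rng.exponential(lambda_, n_cau) if n_cau else np.empty(0)]
    )
    base = len(table)
    table = MutationTable(
        np.concatenate([table.positions, new_pos]),
        np.concatenate([table.effects, new_eff]),
        np.concatenate([table.origins, np.full(n_new, generation, dtype=np.int64)]),
    )
    ids = list(gamete.mutation_ids) + list(range(base, base + n_new))
    return Gamete.from_ids(ids, table), table


# ---------------------------------------------------------------------------
# vectorized engine
# ---------------------------------------------------------------------------


def _draw_parent_gametes(w, n_gam: int, rng: np.random.Generator) -> np.ndarray:
    """Fitness-proportional parental gamete rows by rejection sampling.

    Fitness values lie in (0, 1] so w_max = 1 is a valid rejection
    envelope; a single integer draw over the 2N gamete rows yields both
    the parent (row >> 1) and the transmitted gamete (row & 1).
    Rejected slots are redrawn in blocks, which keeps the RNG stream
    identical between the vectorized and compiled engines.
    """
    rows = np.empty(n_gam, dtype=np.int64)
    pending = np.arange(n_gam)
    while pending.size:
        cand = rng.integers(0, 2 * len(w), pending.size)
        u = rng.random(pending.size)
        ok = u < w[cand >> 1]
        rows[pending[ok]] = cand[ok]
        pending = pending[~ok]
    return rows


def _apply_crossovers(b_parent, b_new, pos, rows, rate, rng) -> None:
    """Recombine the few offspring gametes hit by a crossover, in place.

    The total number of crossovers in the generation is
    Poisson(rate * n_gametes) and each lands on a uniform offspring
    gamete (Poisson thinning of the per-diploid rate); a gamete hit k
    times alternates parental gametes at its k sorted points.
    """
    if rate <= 0:
        return
    n_gam = b_new.shape[0]
    k_tot = int(rng.poisson(rate * n_gam))
    if k_tot == 0:
        return
    hit = rng.integers(0, n_gam, k_tot)
    points = rng.random(k_tot)
    for idx in np.unique(hit):
        xo = np.sort(points[hit == idx])
        flip = (np.searchsorted(xo, pos) % 2).astype(bool)
        ga = b_parent[rows[idx]]
        gb = b_parent[rows[idx] ^ 1]
        b_new[idx] = np.where(flip, gb, ga)


def _draw_unique_positions(n: int, taken: set, rng: np.random.Generator) -> np.ndarray:
    out = []
    while len(out) < n:
        x = float(rng.random())
        if x not in taken:
            taken.add(x)
            out.append(x)
    return np.asarray(out)


def reproduce_one_generation(
    pop: PopulationState,
    fitnesses,
    next_size: int,
    rng: np.random.Generator,
    *,
    mu_neutral: float = 0.0,
    mu_causal: float = 0.0,
    lambda_: float = 1.0,
    recombination_rate: float = 0.0,
) -> PopulationState:
    """One Wright-Fisher generation with selection, recombination, mutation.

    Each of the ``next_size`` offspring draws two parents independently
    with probability proportional to fitness; each parent contributes
    one recombinant gamete; new mutations are then placed on random
    offspring gametes.  Fixed columns are moved to the fixation log and
    lost columns dropped, conserving total mutation count.
    """
    w = np.asarray(fitnesses, dtype=float)
    if len(w) != pop.n_diploids:
        raise ValueError("fitness vector length must equal N")
    if np.any(w < 0):
        raise ValueError("fitnesses must be >= 0")
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("all-zero fitness vector: population extinct under selection")

    B = pop.occupancy
    pos = pop.mutations.positions
    n_gam = 2 * next_size

    cum = np.cumsum(w)
    gametes = np.searchsorted(cum, rng.random(n_gam) * cum[-1])
    gametes = np.minimum(gametes, len(w) - 1)  # guard fp edge
    rows = 2 * gametes + rng.integers(0, 2, size=n_gam)
    new_b = B[rows]  # fancy indexing copies

    _apply_crossovers(B, new_b, pos, rows, recombination_rate, rng)

    n_neu = int(rng.poisson(mu_neutral * n_gam)) if mu_neutral > 0 else 0
    n_cau = int(rng.poisson(mu_causal * n_gam)) if mu_causal > 0 else 0
    n_new = n_neu + n_cau
    gen = pop.generation + 1
    if n_new:
        taken = set(pos.tolist())
        new_pos = _draw_unique_positions(n_new, taken, rng)
        new_eff = np.concatenate(
            [np.zeros(n_neu), rng.exponential(lambda_, n_cau) if n_cau else np.empty(0)]
        )
        targets = rng.integers(0, n_gam, n_new)
        cols = np.zeros((n_gam, n_new), dtype=np.uint8)
        cols[targets, np.arange(n_new)] = 1
        new_b = np.concatenate([new_b, cols], axis=1)
        positions = np.concatenate([pos, new_pos])
        effects = np.concatenate([pop.mutations.effects, new_eff])
        origins = np.concatenate(
            [pop.mutations.origins, np.full(n_new, gen, dtype=np.int64)]
        )
    else:
        positions = pos.copy()
        effects = pop.mutations.effects.copy()
        origins = pop.mutations.origins.copy()

    counts = new_b.sum(axis=0, dtype=np.int64)
    fixed = counts == n_gam
    keep = (counts > 0) & ~fixed
    fixlog = pop.fixations
    if fixed.any():
        fixlog.append(positions[fixed], effects[fixed], origins[fixed], gen)
    if not keep.all():
        new_b = np.ascontiguousarray(new_b[:, keep])
        positions, effects, origins = positions[keep], effects[keep], origins[keep]

    return PopulationState(
        MutationTable(positions, effects, origins),
        new_b,
        generation=gen,
        fixations=fixlog,
        rng_seed=pop.rng_seed,
    )


def fixed_genetic_value(fixations: FixationLog, spec: TraitModelSpec) -> float:
    """Genetic value an individual owes to fixed mutations alone."""
    c = fixations.effects
    c = c[c > 0]
    if len(c) == 0:
        return 0.0
    if spec.model == "AC":
        return float(2.0 * c.sum())
    if spec.model == "GBR":
        return float(c.sum())  # sqrt(s * s) with both haplotype scores = sum c
    return float(np.exp(np.log1p(2.0 * c).sum()) - 1.0)


def total_genetic_values(
    pop: PopulationState, spec: TraitModelSpec
) -> np.ndarray:
    """Per-diploid genetic values combining segregating and fixed mutations."""
    eff = pop.mutations.effects
    occ = pop.occupancy.astype(np.float64, copy=False)
    cfix = pop.fixations.effects
    cfix = cfix[cfix > 0]
    if spec.model in ("AC", "GBR"):
        hap = occ @ eff if pop.n_segregating else np.zeros(2 * pop.n_diploids)
        sf = float(cfix.sum())
        s1, s2 = hap[0::2] + sf, hap[1::2] + sf
        return s1 + s2 if spec.model == "AC" else np.sqrt(s1 * s2)
    g_seg = genetic_values_matrix(pop.occupancy, eff, spec)
    prod_fix = float(np.exp(np.log1p(2.0 * cfix).sum())) if len(cfix) else 1.0
    return (g_seg + 1.0) * prod_fix - 1.0


def _load(values: np.ndarray | float, sigma_s: float) -> float:
    v = np.atleast_1d(np.asarray(values, dtype=float))
    return float(1.0 - np.mean(np.exp(-(v**2) / (2.0 * sigma_s**2))))


def _genetic_values_raw(b: np.ndarray, eff: np.ndarray, spec: TraitModelSpec):
    """Genetic values from a float64 occupancy matrix (hot path)."""
    n = b.shape[0] // 2
    if b.shape[1] == 0:
        return np.zeros(n)
    if spec.model in ("AC", "GBR"):
        hap = b @ eff
        s1, s2 = hap[0::2], hap[1::2]
        return s1 + s2 if spec.model == "AC" else np.sqrt(s1 * s2)
    dosage = b[0::2] + b[1::2]
    return np.exp(
        (dosage == 1.0) @ np.log1p(spec.h * eff) + (dosage == 2.0) @ np.log1p(2.0 * eff)
    ) - 1.0


_REC_COLS = [
    "generation",
    "N",
    "VG",
    "mean_muts_per_diploid",
    "mean_phenotype",
    "load_segregating",
    "load_fixed",
    "load_total",
]

_MODEL_CODES = {"AC": 0, "GBR": 1, "MR": 2}


def _run_compiled(config: SimulationConfig):
    from ._kernel import _run_kernel

    spec = config.trait_model
    demog = config.demography
    n_gens = total_duration(demog)
    sizes = np.asarray([size_at(demog, t) for t in range(n_gens + 1)], dtype=np.int64)
    rng = np.random.default_rng(config.seed)
    out = _run_kernel(
        rng,
        sizes,
        config.mu_neutral,
        config.mu_causal,
        spec.lambda_,
        config.recombination_rate,
        spec.sigma_e,
        spec.sigma_s,
        spec.p_opt,
        _MODEL_CODES[spec.model],
        spec.h,
        config.record_interval,
    )
    (b, pos, eff, org, fpos, feff, forg, fgen, rec, status) = out
    if status != 0:
        raise RuntimeError("all-zero fitness vector: population extinct")
    pop = PopulationState(
        MutationTable(pos, eff, org),
        b,
        generation=n_gens,
        fixations=FixationLog(fpos, feff, forg, fgen),
        rng_seed=config.seed,
    )
    ts = pd.DataFrame(rec, columns=_REC_COLS)
    ts["generation"] = ts["generation"].astype(np.int64)
    ts["N"] = ts["N"].astype(np.int64)
    return pop, ts


def run_simulation(config: SimulationConfig, engine: str = "auto"):
    """Run one replicate; returns ``(final_population, time_series)``.

    The time series (one row every ``record_interval`` generations plus
    the final generation) has columns: generation, N, VG,
    mean_muts_per_diploid, mean_phenotype, load_segregating,
    load_fixed, load_total.  Bit-for-bit reproducible given
    ``(config, config.seed)``.

    ``engine`` is ``"compiled"`` (numba), ``"numpy"`` or ``"auto"``
    (compiled when available).  Both engines consume the RNG stream in
    the same order and yield identical populations and time series;
    the test suite asserts this equivalence.
    """
    if engine not in ("auto", "numpy", "compiled"):
        raise ValueError("engine must be 'auto', 'numpy' or 'compiled'")
    if engine != "numpy":
        from ._kernel import HAVE_NUMBA

        if HAVE_NUMBA:
            return _run_compiled(config)
        if engine == "compiled":
            raise RuntimeError("numba is not available")
    spec = config.trait_model
    mu_n, mu_c = config.mu_neutral, config.mu_causal
    lam, rrate = spec.lambda_, config.recombination_rate
    sigma_e, sigma_s = spec.sigma_e, spec.sigma_s
    inv2ss = 1.0 / (2.0 * sigma_s**2)
    rng = np.random.default_rng(config.seed)
    demog = config.demography
    n_gens = total_duration(demog)

    n0 = size_at(demog, 0)
    b = np.zeros((2 * n0, 0))  # float64 occupancy, hot-path layout
    pos = np.empty(0)
    eff = np.empty(0)
    org = np.empty(0, dtype=np.int64)
    fixlog = FixationLog()
    ones = np.ones(2 * n0)
    records = []

    def summarize(gen, g_seg, phenotypes):
        n_dip = b.shape[0] // 2
        if b.shape[1]:
            dos = b[0::2] + b[1::2]
            mean_muts = float((dos @ (eff > 0).astype(np.float64)).mean())
        else:
            mean_muts = 0.0
        pop_now = PopulationState(
            MutationTable(pos, eff, org),
            (b > 0).astype(np.uint8),
            generation=gen,
            fixations=fixlog,
            rng_seed=config.seed,
        )
        gf = fixed_genetic_value(fixlog, spec)
        g_tot = total_genetic_values(pop_now, spec)
        records.append(
            {
                "generation": gen,
                "N": n_dip,
                "VG": float(np.var(g_seg)),
                "mean_muts_per_diploid": mean_muts,
                "mean_phenotype": float(np.mean(phenotypes)),
                "load_segregating": _load(g_seg, sigma_s),
                "load_fixed": _load(gf, sigma_s),
                "load_total": _load(g_tot, sigma_s),
            }
        )

    for gen in range(n_gens):
        g = _genetic_values_raw(b, eff, spec)
        e = rng.normal(0.0, sigma_e, g.shape[0]) if sigma_e > 0 else np.zeros_like(g)
        p = g + e
        w = np.exp(-((p - spec.p_opt) ** 2) * inv2ss)
        if gen % config.record_interval == 0:
            summarize(gen, g, p)

        next_size = size_at(demog, gen + 1)
        n_gam = 2 * next_size
        if w.max() <= 0:
            raise RuntimeError("all-zero fitness vector: population extinct")
        rows = _draw_parent_gametes(w, n_gam, rng)
        new_b = b[rows]
        _apply_crossovers(b, new_b, pos, rows, rrate, rng)

        n_neu = int(rng.poisson(mu_n * n_gam)) if mu_n > 0 else 0
        n_cau = int(rng.poisson(mu_c * n_gam)) if mu_c > 0 else 0
        n_new = n_neu + n_cau
        if n_new:
            taken = set(pos.tolist())
            new_pos = _draw_unique_positions(n_new, taken, rng)
            new_eff = np.concatenate(
                [np.zeros(n_neu), rng.exponential(lam, n_cau) if n_cau else np.empty(0)]
            )
            targets = rng.integers(0, n_gam, n_new)
            cols = np.zeros((n_gam, n_new))
            cols[targets, np.arange(n_new)] = 1.0
            new_b = np.concatenate([new_b, cols], axis=1)
            pos = np.concatenate([pos, new_pos])
            eff = np.concatenate([eff, new_eff])
            org = np.concatenate([org, np.full(n_new, gen + 1, dtype=np.int64)])

        if ones.shape[0] != n_gam:
            ones = np.ones(n_gam)
        counts = ones @ new_b  # column sums via BLAS matvec
        fixed = counts == n_gam
        keep = (counts > 0) & ~fixed
        if fixed.any():
            fixlog.append(pos[fixed], eff[fixed], org[fixed], gen + 1)
        if not keep.all():
            new_b = new_b[:, keep]
            pos, eff, org = pos[keep], eff[keep], org[keep]
        b = new_b

    g = _genetic_values_raw(b, eff, spec)
    e = rng.normal(0.0, sigma_e, g.shape[0]) if sigma_e > 0 else np.zeros_like(g)
    summarize(n_gens, g, g + e)
    pop = PopulationState(
        MutationTable(pos, eff, org),
        (b > 0).astype(np.uint8),
        generation=n_gens,
        fixations=fixlog,
        rng_seed=config.seed,
    )
    return pop, pd.DataFrame.from_records(records)
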