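"""Wright-Fisher engine: primitives, determinism, neutral expectations."""

import numpy as np
import pytest
from scipy import stats

from regionsim.core import (
    DemographyEpoch,
    Diploid,
    Gamete,
    MutationTable,
    SimulationConfig,
    standard_config,
)
from regionsim.simulate import (
    empty_population,
    mutate_gamete,
    recombine,
    reproduce_one_generation,
    run_simulation,
)
from regionsim.traits import TraitModelSpec


class ScriptedRNG:
    """Minimal rng stub with scripted draws for exact crossover tests."""

    def __init__(self, integers=(), poisson=(), random=()):
        self._integers = list(integers)
        self._poisson = list(poisson)
        self._random = list(random)

    def integers(self, *a, **k):
        return self._integers.pop(0)

    def poisson(self, *a, **k):
        return self._poisson.pop(0)

    def random(self, n=None):
        if n is None:
            return self._random.pop(0)
        return np.asarray([self._random.pop(0) for _ in range(n)])


def two_site_parent():
    table = MutationTable([0.25, 0.75], [0.1, 0.2], [0, 0])
    ga = Gamete.from_ids([0], table)
    gb = Gamete.from_ids([1], table)
    return Diploid(ga, gb), table


class TestRecombine:
    def test_no_crossover_returns_one_parental_gamete(self, rng):
        parent, table = two_site_parent()
        seen = set()
        for _ in range(200):
            g = recombine(parent, 0.0, rng, table)
            seen.add(g.mutation_ids)
        assert seen == {(0,), (1,)}

    @pytest.mark.parametrize(
        "start,expected", [(0, (0, 1)), (1, ())]
    )
    def test_single_crossover_mosaics(self, start, expected):
        # one crossover at 0.5 between gametes {0.25} and {0.75}: the
        # offspring is either both sites or neither, depending on the
        # starting gamete
        parent, table = two_site_parent()
        srng = ScriptedRNG(integers=[start], poisson=[1], random=[0.5])
        g = recombine(parent, 1.0, srng, table)
        assert g.mutation_ids == expected

    def test_allele_counts_conserved_in_expectation(self, rng):
        # recombination alone neither creates nor destroys copies:
        # over many meioses each site is transmitted half the time
        parent, table = two_site_parent()
        hits = np.zeros(2)
        n = 4000
        for _ in range(n):
            g = recombine(parent, 2.0, rng, table)
            for mid in g.mutation_ids:
                hits[mid] += 1
        assert np.all(np.abs(hits / n - 0.5) < 4 * 0.5 / np.sqrt(n))


class TestMutateGamete:
    def test_zero_rates_leave_gamete_unchanged(self, rng):
        table = MutationTable([0.5], [0.1], [0])
        g = Gamete.from_ids([0], table)
        g2, t2 = mutate_gamete(g, 0.0, 0.0, 0.5, rng, table)
        assert g2 is g and t2 is table

    def test_poisson_rate_and_effect_mean(self, rng):
        table = MutationTable()
        lam, mu_c = 0.125, 0.8
        counts, effects = [], []
        for _ in range(3000):
            g, t = mutate_gamete(Gamete(()), 0.0, mu_c, lam, rng, table)
            counts.append(len(g.mutation_ids))
            effects.extend(t.effects[list(g.mutation_ids)])
        n = len(counts)
        assert np.mean(counts) == pytest.approx(mu_c, abs=3 * np.sqrt(mu_c / n))
        assert np.mean(effects) == pytest.approx(
            lam, abs=3 * lam / np.sqrt(len(effects))
        )

    def test_positions_unique(self, rng):
        table = MutationTable()
        g = Gamete(())
        for _ in range(50):
            g, table = mutate_gamete(g, 2.0, 0.0, 0.5, rng, table)
        assert len(np.unique(table.positions)) == len(table)


class TestReproduce:
    def test_equal_fitness_gives_uniform_parents(self, rng):
        n = 40
        pop = empty_population(n)
        # track descent via unique mutations: give parent i a private allele
        table = MutationTable(
            np.linspace(0.01, 0.99, n), np.zeros(n), np.zeros(n, dtype=int)
        )
        occ = np.zeros((2 * n, n), dtype=np.uint8)
        occ[2 * np.arange(n), np.arange(n)] = 1  # gamete_a of parent i
        occ[2 * np.arange(n) + 1, np.arange(n)] = 1
        pop = type(pop)(table, occ)
        child = reproduce_one_generation(pop, np.ones(n), 2000, rng)
        counts = child.occupancy.sum(axis=0)  # transmissions per parent
        chi2 = float(((counts - counts.mean()) ** 2 / counts.mean()).sum())
        assert stats.chi2.sf(chi2, n - 1) > 0.001

    def test_single_fit_parent_dominates(self, rng):
        n = 10
        table = MutationTable([0.5], [0.0], [0])
        occ = np.zeros((2 * n, 1), dtype=np.uint8)
        occ[0] = occ[1] = 1  # only parent 0 carries the tag
        pop = empty_population(n)
        pop = type(pop)(table, occ)
        w = np.zeros(n)
        w[0] = 1.0
        child = reproduce_one_generation(pop, w, 50, rng)
        # the tag is now fixed: pruned into the fixation log
        assert child.n_segregating == 0
        assert len(child.fixations.positions) == 1

    def test_extinct_population_rejected(self, rng):
        pop = empty_population(5)
        with pytest.raises(ValueError):
            reproduce_one_generation(pop, np.zeros(5), 5, rng)


class TestRunSimulation:
    def test_no_mutation_means_no_segregation(self):
        cfg = SimulationConfig(
            demography=[DemographyEpoch(duration=50, start_size=60, end_size=60)],
            trait_model=TraitModelSpec("AC", lambda_=0.5, sigma_e=0.075),
            mu_neutral=0.0,
            mu_causal=0.0,
            seed=5,
        )
        pop, ts = run_simulation(cfg)
        assert pop.n_segregating == 0
        assert (ts.VG == 0).all()

    def test_near_neutral_limit_fitness_flat(self):
        cfg = SimulationConfig(
            demography=[DemographyEpoch(duration=200, start_size=100, end_size=100)],
            trait_model=TraitModelSpec("AC", lambda_=1e-8, sigma_e=0.0),
            seed=6,
        )
        pop, ts = run_simulation(cfg)
        assert ts.VG.max() < 1e-12
        assert ts.load_total.max() < 1e-12

    def test_determinism_same_seed_same_hash(self):
        cfg = standard_config("no_growth", 0.25, 0.075, scale=0.05, seed=99)
        cfg.demography[0] = DemographyEpoch(duration=300, start_size=150, end_size=150)
        h1 = run_simulation(cfg)[0].content_hash()
        h2 = run_simulation(cfg)[0].content_hash()
        assert h1 == h2

    def test_engines_bit_identical(self):
        for model, h, lam in (("AC", 1.0, 0.5), ("GBR", 1.0, 0.25), ("MR", 0.25, 0.25)):
            cfg = standard_config(
                "growth", lam, 0.075, model=model, h=h, scale=0.05, seed=41
            )
            cfg.demography[0] = DemographyEpoch(duration=250, start_size=150, end_size=150)
            cfg.demography[1] = DemographyEpoch(
                duration=20, start_size=150, end_size=600, mode="exponential"
            )
            p1, t1 = run_simulation(cfg, engine="compiled")
            p2, t2 = run_simulation(cfg, engine="numpy")
            assert p1.content_hash() == p2.content_hash()
            assert np.allclose(t1.values.astype(float), t2.values.astype(float))

    def test_neutral_sfs_matches_equilibrium(self):
        # all-neutral scaled runs: pooled site frequency spectrum of a
        # diploid sample follows the standard neutral 1/i expectation
        rng = np.random.default_rng(4242)
        n_sample = 40
        counts = np.zeros(2 * n_sample - 1)
        for s in range(200):
            cfg = SimulationConfig(
                demography=[DemographyEpoch(duration=800, start_size=100, end_size=100)],
                trait_model=TraitModelSpec("AC", lambda_=0.5, sigma_e=0.075),
                mu_causal=0.0,
                seed=60_000 + s,
            )
            pop, _ = run_simulation(cfg)
            if pop.n_segregating == 0:
                continue
            idx = rng.choice(pop.n_diploids, n_sample, replace=False)
            ac = pop.dosages()[idx].sum(axis=0)
            for c in ac[(ac > 0) & (ac < 2 * n_sample)]:
                counts[c - 1] += 1
        expected = 1.0 / np.arange(1, 2 * n_sample)
        expected = expected / expected.sum() * counts.sum()
        # lump sparse tail classes for a valid chi-square
        k = 10
        obs = np.concatenate([counts[:k], [counts[k:].sum()]])
        exp = np.concatenate([expected[:k], [expected[k:].sum()]])
        chi2 = float(((obs - exp) ** 2 / exp).sum())
        assert stats.chi2.sf(chi2, k) > 0.001

    def test_growth_increases_singleton_fraction(self, assoc_results):
        ng = np.mean(assoc_results["gbr_ng"]["singleton_frac"])
        growth = np.mean(assoc_results["gbr_growth"]["singleton_frac"])
        assert growth > ng

    def test_house_of_cards_variance_additive_vs_recessive(self, ac_bank, gbr_bank):
        # post-burn-in V_G ~ 4 mu_d sigma_s^2 for additive and
        # ~ 2 mu_d sigma_s^2 for gene-based recessive (within 25%)
        def mean_vg(bank):
            return float(
                np.mean([ts[ts.generation >= 4000].VG.mean() for _, ts, _ in bank])
            )

        assert mean_vg(ac_bank) == pytest.approx(5e-4, rel=0.25)
        assert mean_vg(gbr_bank) == pytest.approx(2.5e-4, rel=0.35)

    def test_scaled_european_demography_runs_end_to_end(self):
        # bottleneck-and-growth preset: recorded N tracks the schedule,
        # loads stay finite, and the final size matches the preset
        from regionsim.core import SimulationConfig, size_at, tennessen_ea_demography
        from regionsim.varcomp import burden_ratio

        demog = tennessen_ea_demography(scale=0.05)
        cfg = SimulationConfig(
            demography=demog,
            trait_model=TraitModelSpec("AC", lambda_=0.5, sigma_e=0.075),
            record_interval=50,
            seed=88,
        )
        pop, ts = run_simulation(cfg)
        assert pop.n_diploids == demog[-1].end_size
        for _, row in ts.iterrows():
            assert row.N == size_at(demog, int(row.generation))
        assert np.isfinite(ts[["VG", "load_segregating", "load_total"]]).all().all()
        # the load time series feeds burden ratios against an
        # equilibrium reference without further machinery
        eq_load = ts.load_total.iloc[len(ts) // 2] + 1e-9
        assert np.isfinite(burden_ratio(ts.load_total.iloc[-1], eq_load))

    def test_time_series_schema(self, tiny_pop):
        _, ts, cfg = tiny_pop
        assert list(ts.columns) == [
            "generation",
            "N",
            "VG",
            "mean_muts_per_diploid",
            "mean_phenotype",
            "load_segregating",
            "load_fixed",
            "load_total",
        ]
        assert ts.generation.iloc[0] == 0
        assert ts.generation.iloc[-1] == 400
        assert (ts.N == 120).all()
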