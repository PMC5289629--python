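"""Domain types shared by the simulator and the downstream analyses.

Mutations live at continuous positions on [0, 1) (an infinitely-many-
sites model of roughly a 100 kb region: theta = rho = 100 at full
scale), gametes are sets of mutation indices, and a population is a
collection of diploids plus a demographic schedule.  Fixed mutations
are pruned from gametes for speed but logged with their effects so the
fixed component of genetic load remains computable.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .traits import TraitModelSpec

__all__ = [
    "MutationRecord",
    "MutationTable",
    "FixationLog",
    "Gamete",
    "Diploid",
    "PopulationState",
    "DemographyEpoch",
    "SimulationConfig",
    "standard_config",
    "tennessen_ea_demography",
    "size_at",
    "total_duration",
]

# Full-scale parameters: N = 2e4 diploids, 8N-generation burn-in,
# neutral mutation rate mu = 0.00125 per gamete per generation,
# causal ("deleterious") rate mu_d = 0.1 mu, recombination rate
# r = 0.00125 per diploid per generation.
FULL_SCALE_N = 20_000
MU_NEUTRAL = 0.00125
MU_CAUSAL = 0.1 * MU_NEUTRAL
RECOMBINATION_RATE = 0.00125
GROWTH_GENERATIONS = 500
GROWTH_FINAL_N = 1_000_000
MIN_SCALED_N = 50


@dataclass(frozen=True)
class MutationRecord:
    """One segregating (or fixed) site."""

    position: float
    effect: float
    origin_generation: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.position < 1.0:
            raise ValueError("position must be in [0, 1)")
        if self.effect < 0:
            raise ValueError("effect must be >= 0")

    @property
    def is_neutral(self) -> bool:
        return self.effect == 0.0


class MutationTable:
    """Columnar table of mutations (positions unique within a population)."""

    __slots__ = ("positions", "effects", "origins")

    def __init__(self, positions=(), effects=(), origins=()):
        self.positions = np.asarray(positions, dtype=float)
        self.effects = np.asarray(effects, dtype=float)
        self.origins = np.asarray(origins, dtype=np.int64)
        if not (len(self.positions) == len(self.effects) == len(self.origins)):
            raise ValueError("column lengths differ")

    def __len__(self) -> int:
        return len(self.positions)

    def record(self, i: int) -> MutationRecord:
        return MutationRecord(
            float(self.positions[i]), float(self.effects[i]), int(self.origins[i])
        )

    @property
    def neutral_mask(self) -> np.ndarray:
        return self.effects == 0.0

    @property
    def causal_mask(self) -> np.ndarray:
        return self.effects > 0.0


class FixationLog(MutationTable):
    """Mutations that reached frequency 1, with the generation of fixation."""

    __slots__ = ("fixed_generations",)

    def __init__(self, positions=(), effects=(), origins=(), fixed_generations=()):
        super().__init__(positions, effects, origins)
        self.fixed_generations = np.asarray(fixed_generations, dtype=np.int64)

    def append(self, positions, effects, origins, generation: int) -> None:
        self.positions = np.concatenate([self.positions, positions])
        self.effects = np.concatenate([self.effects, effects])
        self.origins = np.concatenate([self.origins, origins])
        self.fixed_generations = np.concatenate(
            [self.fixed_generations, np.full(len(positions), generation, dtype=np.int64)]
        )


@dataclass(frozen=True)
class Gamete:
    """Ordered (by position) collection of mutation indices, no duplicates."""

    mutation_ids: tuple

    @staticmethod
    def from_ids(ids, table: MutationTable) -> "Gamete":
        ids = np.asarray(sorted(set(int(i) for i in ids)), dtype=np.intp)
        order = np.argsort(table.positions[ids], kind="stable") if len(ids) else ids
        return Gamete(tuple(int(i) for i in ids[order]))


@dataclass(frozen=True)
class Diploid:
    gamete_a: Gamete
    gamete_b: Gamete


class PopulationState:
    """A Wright-Fisher population at one generation.

    Internally the segregating sites are held as a dense (2N, S) 0/1
    occupancy matrix (rows 2i, 2i+1 are the gametes of diploid i); the
    object-level :class:`Gamete`/:class:`Diploid` views are constructed
    on demand.  With per-gamete mutation rates of order 1e-3 the number
    of segregating sites is small, so the dense form is both compact
    and fast.
    """

    def __init__(
        self,
        mutations: MutationTable,
        occupancy: np.ndarray,
        generation: int = 0,
        fixations: FixationLog | None = None,
        rng_seed: int | None = None,
    ):
        occupancy = np.asarray(occupancy, dtype=np.uint8)
        if occupancy.ndim != 2 or occupancy.shape[0] % 2:
            raise ValueError("occupancy must be (2N, S)")
        if occupancy.shape[1] != len(mutations):
            raise ValueError("occupancy columns must match mutation table")
        if len(mutations) and len(np.unique(mutations.positions)) != len(mutations):
            raise ValueError("duplicate mutation positions (infinite-sites violation)")
        self.mutations = mutations
        self.occupancy = occupancy
        self.generation = int(generation)
        self.fixations = fixations if fixations is not None else FixationLog()
        self.rng_seed = rng_seed

    @property
    def n_diploids(self) -> int:
        return self.occupancy.shape[0] // 2

    @property
    def n_segregating(self) -> int:
        return self.occupancy.shape[1]

    def gamete(self, g: int) -> Gamete:
        ids = np.nonzero(self.occupancy[g])[0]
        return Gamete.from_ids(ids, self.mutations)

    def diploid(self, i: int) -> Diploid:
        return Diploid(self.gamete(2 * i), self.gamete(2 * i + 1))

    @property
    def gametes(self):
        return [self.gamete(g) for g in range(2 * self.n_diploids)]

    @property
    def diploids(self):
        return [self.diploid(i) for i in range(self.n_diploids)]

    def dosages(self) -> np.ndarray:
        """(N, S) risk-allele dosage matrix."""
        occ = self.occupancy
        return (occ[0::2] + occ[1::2]).astype(np.int8)

    def allele_frequencies(self) -> np.ndarray:
        if self.n_segregating == 0:
            return np.empty(0)
        return self.occupancy.mean(axis=0)

    def content_hash(self) -> str:
        """Deterministic digest of the full genetic state."""
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.occupancy).tobytes())
        h.update(self.mutations.positions.tobytes())
        h.update(self.mutations.effects.tobytes())
        h.update(self.fixations.positions.tobytes())
        h.update(str(self.generation).encode())
        return h.hexdigest()


@dataclass(frozen=True)
class DemographyEpoch:
    """A constant-size or exponential-growth span of generations."""

    duration: int
    start_size: int
    end_size: int
    mode: str = "constant"

    def __post_init__(self) -> None:
        if self.mode not in ("constant", "exponential"):
            raise ValueError("mode must be 'constant' or 'exponential'")
        if self.duration < 1 or self.start_size < 1 or self.end_size < 1:
            raise ValueError("duration and sizes must be positive")
        if self.mode == "constant" and self.start_size != self.end_size:
            raise ValueError("constant epoch requires start_size == end_size")

    def size_at_offset(self, t: int) -> int:
        """Diploid count at offset t in [0, duration]."""
        if not 0 <= t <= self.duration:
            raise ValueError("offset outside epoch")
        if self.mode == "constant":
            return self.start_size
        ratio = self.end_size / self.start_size
        return int(round(self.start_size * ratio ** (t / self.duration)))


def total_duration(demography) -> int:
    return sum(e.duration for e in demography)


def size_at(demography, generation: int) -> int:
    """Diploid population size at an absolute generation."""
    if generation < 0:
        raise ValueError("generation must be >= 0")
    offset = generation
    for epoch in demography:
        if offset < epoch.duration:
            return epoch.size_at_offset(offset)
        offset -= epoch.duration
    if offset == 0:  # one past the final epoch boundary: its end size
        return demography[-1].end_size
    raise ValueError("generation beyond the demographic schedule")


@dataclass
class SimulationConfig:
    """Everything needed to reproduce one simulation replicate."""

    demography: list
    trait_model: TraitModelSpec
    mu_neutral: float = MU_NEUTRAL
    mu_causal: float = MU_CAUSAL
    recombination_rate: float = RECOMBINATION_RATE
    record_interval: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.mu_neutral, self.mu_causal, self.recombination_rate) < 0:
            raise ValueError("rates must be >= 0")
        if self.record_interval < 1:
            raise ValueError("record_interval must be >= 1")
        if not self.demography:
            raise ValueError("demography must contain at least one epoch")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["demography"] = [asdict(e) for e in self.demography]
        d["trait_model"] = asdict(self.trait_model)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["demography"] = [DemographyEpoch(**e) for e in d["demography"]]
        d["trait_model"] = TraitModelSpec(**d["trait_model"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def standard_config(
    scenario: str,
    lambda_: float,
    sigma_e: float,
    model: str = "AC",
    h: float = 1.0,
    scale: float = 1.0,
    seed: int = 0,
    record_interval: int = 50,
    sigma_s: float = 1.0,
) -> SimulationConfig:
    """The study's standard constant-N / growth configurations.

    At ``scale=1``: N = 20 000 diploids evolved for 8N generations
    (mu = 0.00125, mu_d = 0.1 mu, r = 0.00125 per diploid); the growth
    scenario appends 500 generations of exponential growth from 2e4 to
    1e6.  At ``scale < 1`` the population size and epoch durations
    shrink while the per-gamete rates are held fixed, which preserves
    the house-of-cards equilibrium V_G ~ 4 mu_d sigma_s^2 (additive)
    and ~ 2 mu_d sigma_s^2 (recessive) that does not depend on N.
    Frequency-spectrum-dependent quantities are *not* preserved by
    scaling.
    """
    if scenario not in ("no_growth", "growth"):
        raise ValueError("scenario must be 'no_growth' or 'growth'")
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    n = int(round(FULL_SCALE_N * scale))
    if n < MIN_SCALED_N:
        raise ValueError(
            f"scale {scale} gives N={n} < {MIN_SCALED_N}; drift-dominated regime"
        )
    epochs = [DemographyEpoch(duration=8 * n, start_size=n, end_size=n, mode="constant")]
    if scenario == "growth":
        epochs.append(
            DemographyEpoch(
                duration=max(1, int(round(GROWTH_GENERATIONS * scale))),
                start_size=n,
                end_size=max(n, int(round(GROWTH_FINAL_N * scale))),
                mode="exponential",
            )
        )
    spec = TraitModelSpec(
        model=model, h=h, lambda_=lambda_, sigma_e=sigma_e, sigma_s=sigma_s
    )
    return SimulationConfig(
        demography=epochs,
        trait_model=spec,
        record_interval=record_interval,
        seed=seed,
    )


def tennessen_ea_demography(scale: float = 1.0):
    """European-ancestry demographic preset (piecewise epochs, no migration).

    Loaded from the versioned preset file ``data/tennessen_ea.yaml``:
    ancestral constant size, ancient growth, out-of-Africa bottleneck
    (N = 1861), second bottleneck (N = 1032), then two-phase
    exponential growth to the modern size.  ``scale`` multiplies every
    size and duration.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    ref = importlib.resources.files("regionsim").joinpath("data/tennessen_ea.yaml")
    preset = yaml.safe_load(ref.read_text())
    epochs = []
    for e in preset["epochs"]:
        epochs.append(
            DemographyEpoch(
                duration=max(1, int(round(e["duration"] * scale))),
                start_size=max(1, int(round(e["start_size"] * scale))),
                end_size=max(1, int(round(e["end_size"] * scale)))
                if e["mode"] == "exponential"
                else max(1, int(round(e["start_size"] * scale))),
                mode=e["mode"],
            )
        )
    return epochs
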