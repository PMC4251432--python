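"""Stochastic diversification model on a one-dimensional thermal gradient.

One species seeds one region and the clade then evolves in discrete time
steps.  Within every step, in fixed order:

1. **allocation** — each species present in a region receives a population
   set by its Gaussian environmental-filter weight
   ``w = exp(-(trait - env)² / (2 ω²))``.  Under the zero-sum constraint the
   region's carrying capacity ``K`` is divided among residents in proportion
   to their weights; without it every species independently realises
   ``round(K · w)`` individuals.
2. **disturbance** (when scheduled) — a fraction ``m_k`` of every
   population in region ``k`` is killed.
3. **speciation** — each population of size ``N`` spawns
   ``Binomial(N, p_speciation)`` daughter species; a daughter inherits the
   parental thermal optimum plus a ``Normal(0, σ_E)`` deviation (niche
   conservatism) and starts in the parent's region.
4. **dispersal** — a population of size ``N`` colonises an adjacent,
   currently unoccupied region when ``Binomial(N, p_dispersal) ≥ 1``.
5. **extinction** — each population goes locally extinct with probability
   ``exp(-alpha_ext · N)``; a species with no populations left is globally
   extinct, permanently.

Populations are recomputed from weights every step (attained, not grown,
population sizes), so the only persistent state is which species occupy
which regions, their traits, and the genealogy.

All randomness flows through a single seeded ``numpy`` generator, with draw
order fixed by (step, phase, species row, region), so a (config, seed) pair
determines every output bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ScenarioConfig

__all__ = [
    "SpeciesTable",
    "EventLog",
    "SimState",
    "SimulationResult",
    "fitness_weight",
    "initial_state",
    "allocate_populations",
    "disturbance_step",
    "speciation_step",
    "dispersal_step",
    "extinction_step",
    "step",
    "run_simulation",
    "ROOT_PARENT",
]

ROOT_PARENT = 0  #: parent_id marker of the founding species
NO_REGION = 0  #: region marker for events that are not region-specific

EVENT_CODES = {
    "speciation": 0,
    "colonization": 1,
    "local_extinction": 2,
    "global_extinction": 3,
    "disturbance": 4,
}
EVENT_NAMES = {v: k for k, v in EVENT_CODES.items()}


def fitness_weight(trait, env, omega):
    """Gaussian environmental-filter weight ``exp(-(trait-env)²/(2ω²))``.

    Equals 1 for a perfect trait–environment match and decays symmetrically
    with the mismatch, with SD ``omega`` (°C).  Accepts scalars or arrays.
    """
    if np.any(np.asarray(omega) <= 0):
        raise ValueError("omega must be positive")
    trait = np.asarray(trait, dtype=float)
    env = np.asarray(env, dtype=float)
    return np.exp(-((trait - env) ** 2) / (2.0 * float(omega) ** 2))


class SpeciesTable:
    """Columnar table of every species ever created (ids are 1-based)."""

    def __init__(self) -> None:
        self.parent_id: list[int] = []
        self.origin_time: list[int] = []
        self.extinction_time: list[int] = []  # -1 while extant
        self.trait: list[float] = []

    def add(self, parent_id: int, origin_time: int, trait: float) -> int:
        self.parent_id.append(parent_id)
        self.origin_time.append(origin_time)
        self.extinction_time.append(-1)
        self.trait.append(trait)
        return len(self.parent_id)  # new species id

    def __len__(self) -> int:
        return len(self.parent_id)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species_id": np.arange(1, len(self) + 1, dtype=np.int64),
                "parent_id": np.asarray(self.parent_id, dtype=np.int64),
                "origin_time": np.asarray(self.origin_time, dtype=np.int64),
                "extinction_time": np.asarray(self.extinction_time, dtype=np.int64),
                "trait": np.asarray(self.trait, dtype=float),
            }
        )

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "SpeciesTable":
        tbl = cls()
        df = df.sort_values("species_id")
        if not np.array_equal(df["species_id"].to_numpy(), np.arange(1, len(df) + 1)):
            raise ValueError("species_id must be contiguous 1..N in birth order")
        tbl.parent_id = [int(x) for x in df["parent_id"]]
        tbl.origin_time = [int(x) for x in df["origin_time"]]
        tbl.extinction_time = [int(x) for x in df["extinction_time"]]
        tbl.trait = [float(x) for x in df["trait"]]
        return tbl


class EventLog:
    """Append-only, columnar log of demographic events.

    ``region`` is 1-based; 0 marks whole-gradient events (global
    extinctions).  ``child_id`` is 0 except for speciation events.
    """

    def __init__(self) -> None:
        self.time: list[int] = []
        self.etype: list[int] = []
        self.region: list[int] = []
        self.species_id: list[int] = []
        self.child_id: list[int] = []

    def append(self, time: int, etype: str, region: int, species_id: int, child_id: int = 0):
        self.time.append(time)
        self.etype.append(EVENT_CODES[etype])
        self.region.append(region)
        self.species_id.append(species_id)
        self.child_id.append(child_id)

    def __len__(self) -> int:
        return len(self.time)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": np.asarray(self.time, dtype=np.int64),
                "type": pd.Categorical.from_codes(
                    np.asarray(self.etype, dtype=np.int8),
                    categories=[EVENT_NAMES[i] for i in range(len(EVENT_NAMES))],
                ),
                "region": np.asarray(self.region, dtype=np.int64),
                "species_id": np.asarray(self.species_id, dtype=np.int64),
                "child_id": np.asarray(self.child_id, dtype=np.int64),
            }
        )


class SimState:
    """Mutable per-run state: one row per extant species.

    Rows stay sorted by species id (append-only plus order-preserving
    compaction), which fixes the RNG draw order.
    """

    def __init__(self, config: ScenarioConfig) -> None:
        self.config = config
        self.env = np.asarray(config.env_values, dtype=float)
        self.K = np.asarray(config.K, dtype=float)
        self.p_spec = np.asarray(config.p_speciation, dtype=float)
        R = config.n_regions
        cap = 256
        self.n = 0
        self.time = 0
        self.ids = np.zeros(cap, dtype=np.int64)
        self.trait = np.zeros(cap, dtype=float)
        self.W = np.zeros((cap, R), dtype=float)  # cached filter weights
        self.presence = np.zeros((cap, R), dtype=bool)
        self.pop = np.zeros((cap, R), dtype=np.int64)
        self.colon_time = np.full((cap, R), -1, dtype=np.int64)
        self.species = SpeciesTable()
        self.log = EventLog()

    # -- row management --------------------------------------------------
    def _grow(self) -> None:
        cap = self.ids.shape[0] * 2
        for name in ("ids", "trait"):
            arr = getattr(self, name)
            new = np.zeros(cap, dtype=arr.dtype)
            new[: self.n] = arr[: self.n]
            setattr(self, name, new)
        for name, fill in (("W", 0.0), ("presence", False), ("pop", 0), ("colon_time", -1)):
            arr = getattr(self, name)
            new = np.full((cap, arr.shape[1]), fill, dtype=arr.dtype)
            new[: self.n] = arr[: self.n]
            setattr(self, name, new)

    def add_species(self, parent_id: int, trait: float, region0: int, time: int) -> int:
        """Create a species resident in 0-based region ``region0``; returns its id."""
        sid = self.species.add(parent_id, time, trait)
        if self.n == self.ids.shape[0]:
            self._grow()
        i = self.n
        self.n += 1
        self.ids[i] = sid
        self.trait[i] = trait
        self.W[i] = fitness_weight(trait, self.env, self.config.omega)
        self.presence[i] = False
        self.presence[i, region0] = True
        self.pop[i] = 0
        self.colon_time[i] = -1
        self.colon_time[i, region0] = time
        return sid

    def retire_extinct(self, time: int) -> int:
        """Drop rows with no remaining populations; log global extinctions."""
        n = self.n
        gone = ~self.presence[:n].any(axis=1)
        if not gone.any():
            return 0
        for sid in self.ids[:n][gone]:
            self.species.extinction_time[sid - 1] = time
            self.log.append(time, "global_extinction", NO_REGION, int(sid))
        keep = ~gone
        m = int(keep.sum())
        for name in ("ids", "trait", "W", "presence", "pop", "colon_time"):
            arr = getattr(self, name)
            arr[:m] = arr[:n][keep]
        self.n = m
        return int(gone.sum())

    # -- views -----------------------------------------------------------
    @property
    def richness(self) -> int:
        return self.n

    def richness_by_region(self) -> np.ndarray:
        """Count of species with population > 0 per region."""
        return (self.pop[: self.n] > 0).sum(axis=0)

    def occupancy_dataframe(self) -> pd.DataFrame:
        n = self.n
        rows = np.nonzero(self.presence[:n])
        return pd.DataFrame(
            {
                "species_id": self.ids[:n][rows[0]],
                "region": rows[1] + 1,
                "population": self.pop[:n][rows],
                "colonization_time": self.colon_time[:n][rows],
            }
        )


def initial_state(config: ScenarioConfig) -> SimState:
    """State at time 0: the founder, with the origin region's optimum trait."""
    state = SimState(config)
    origin0 = config.origin_region - 1
    founder_trait = float(config.env_values[origin0])
    state.add_species(ROOT_PARENT, founder_trait, origin0, time=0)
    return state


# -- step phases ---------------------------------------------------------


def allocate_populations(state: SimState, config: ScenarioConfig) -> None:
    """Set populations from filter weights (zero-sum share or independent).

    Rounding is half-to-even; a resident whose allocation rounds to zero is
    immediately locally extinct.
    """
    n = state.n
    if n == 0:
        return
    W = np.where(state.presence[:n], state.W[:n], 0.0)
    if config.zero_sum:
        colsum = W.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            share = state.K * W / colsum
        share[:, colsum == 0.0] = 0.0
    else:
        share = state.K * W
    state.pop[:n] = np.rint(share).astype(np.int64)
    zeroed = state.presence[:n] & (state.pop[:n] == 0)
    if zeroed.any():
        t = state.time
        for i, k in zip(*np.nonzero(zeroed)):
            state.log.append(t, "local_extinction", int(k) + 1, int(state.ids[i]))
        state.presence[:n][zeroed] = False
        state.colon_time[:n][zeroed] = -1
        state.retire_extinct(t)


def disturbance_step(state: SimState, config: ScenarioConfig) -> None:
    """Kill a fraction ``m_k`` of every population; one event per region.

    Populations that round to zero are locally extinct outright (the event
    killed every individual).
    """
    n = state.n
    t = state.time
    m = np.asarray(config.disturbance_magnitude, dtype=float)
    for k in range(config.n_regions):
        state.log.append(t, "disturbance", k + 1, 0)
    if n == 0:
        return
    state.pop[:n] = np.rint(state.pop[:n] * (1.0 - m)).astype(np.int64)
    zeroed = state.presence[:n] & (state.pop[:n] == 0)
    if zeroed.any():
        for i, k in zip(*np.nonzero(zeroed)):
            state.log.append(t, "local_extinction", int(k) + 1, int(state.ids[i]))
        state.presence[:n][zeroed] = False
        state.colon_time[:n][zeroed] = -1
        state.retire_extinct(t)


def speciation_step(state: SimState, config: ScenarioConfig, rng: np.random.Generator) -> None:
    """Draw Binomial(N, p_speciation) daughters per population.

    Daughters inherit the parent trait plus Normal(0, σ_E) and start in the
    parent's region; they join the allocation pool next step.
    """
    n = state.n
    if n == 0:
        return
    counts = rng.binomial(state.pop[:n], state.p_spec[None, :])
    if not counts.any():
        return
    t = state.time
    sigma = config.sigma_E
    for i, k in zip(*np.nonzero(counts)):
        parent = int(state.ids[i])
        parent_trait = float(state.trait[i])
        for _ in range(int(counts[i, k])):
            child_trait = parent_trait + rng.normal(0.0, sigma)
            child = state.add_species(parent, child_trait, int(k), t)
            state.log.append(t, "speciation", int(k) + 1, parent, child)
            state.log.append(t, "colonization", int(k) + 1, child)


def dispersal_step(state: SimState, config: ScenarioConfig, rng: np.random.Generator) -> None:
    """Colonise adjacent unoccupied regions when Binomial(N, p_dispersal) ≥ 1.

    The two directions are processed tropical-ward then temperate-ward; a
    species may colonise both neighbours of a region in the same step.
    """
    n = state.n
    if n == 0 or config.p_dispersal == 0.0 or config.n_regions == 1:
        return
    t = state.time
    p = config.p_dispersal
    pres = state.presence[:n]
    pop = state.pop[:n]
    for shift in (-1, 1):
        if shift == -1:
            src = slice(1, None)
            dst = slice(None, -1)
        else:
            src = slice(None, -1)
            dst = slice(1, None)
        can = (pop[:, src] > 0) & ~pres[:, dst]
        nsrc = np.where(can, pop[:, src], 0)
        hits = rng.binomial(nsrc, p) > 0
        if hits.any():
            offset = 0 if shift == -1 else 1
            rows, cols = np.nonzero(hits)
            for i, c in zip(rows, cols):
                k_new = int(c) + offset
                pres[i, k_new] = True
                state.colon_time[i, k_new] = t
                state.log.append(t, "colonization", k_new + 1, int(state.ids[i]))


def extinction_step(state: SimState, config: ScenarioConfig, rng: np.random.Generator) -> None:
    """Local extinction with probability exp(-alpha_ext · N) per population.

    Only populations with N > 0 are drawn (this step's newborns, which have
    not yet been allocated a population, are exempt).  Species left with no
    populations are globally extinct and never return.
    """
    n = state.n
    if n == 0:
        return
    t = state.time
    active = state.presence[:n] & (state.pop[:n] > 0)
    idx = np.nonzero(active)
    if idx[0].size == 0:
        return
    p_ext = np.exp(-config.alpha_ext * state.pop[:n][idx].astype(float))
    dead = rng.random(idx[0].size) < p_ext
    if not dead.any():
        return
    for i, k in zip(idx[0][dead], idx[1][dead]):
        state.log.append(t, "local_extinction", int(k) + 1, int(state.ids[i]))
        state.presence[i, k] = False
        state.pop[i, k] = 0
        state.colon_time[i, k] = -1
    state.retire_extinct(t)


def step(state: SimState, config: ScenarioConfig, rng: np.random.Generator) -> None:
    """Advance one time step: allocate → disturb → speciate → disperse → die."""
    state.time += 1
    allocate_populations(state, config)
    freq = config.disturbance_frequency
    if freq > 0 and state.time % freq == 0:
        disturbance_step(state, config)
    speciation_step(state, config, rng)
    dispersal_step(state, config, rng)
    extinction_step(state, config, rng)


# -- full run ------------------------------------------------------------


@dataclass
class SimulationResult:
    """Everything a run produces: genealogy, final occupancy, events, metrics."""

    species: pd.DataFrame
    occupancy: pd.DataFrame
    events: pd.DataFrame
    snapshots: list = field(default_factory=list)
    config: ScenarioConfig | None = None
    seed_used: int = 0
    final_time: int = 0
    clade_extinct: bool = False

    def snapshots_dataframe(self) -> pd.DataFrame:
        from .metrics import snapshots_to_dataframe

        return snapshots_to_dataframe(self.snapshots, self.config.n_regions)


def run_simulation(
    config: ScenarioConfig,
    *,
    compute_metrics: bool = True,
    audit: callable | None = None,
) -> SimulationResult:
    """Run one scenario to its stop rule and return the full result.

    Stops at ``max_steps``, when extant richness exceeds ``max_species``
    (a terminal snapshot is then taken at the stop step), or on total clade
    extinction (flagged on the result, not raised).  ``audit``, when given,
    is called with the state after every allocation phase — used by the
    conservation checks in the test-suite.

    With ``compute_metrics=False`` snapshots carry regional richness only,
    skipping tree construction (cheaper for long runs whose metrics are
    computed afterwards at selected times).
    """
    config.validate()
    seed = config.seed
    if seed is None:
        import secrets

        seed = secrets.randbelow(2**31)
    rng = np.random.Generator(np.random.PCG64(seed))
    state = initial_state(config)
    snapshots = []

    from . import metrics as _metrics

    def take_snapshot():
        if compute_metrics:
            snapshots.append(_metrics.compute_snapshot(state))
        else:
            snapshots.append(
                _metrics.MetricsSnapshot(
                    time=state.time, richness=state.richness_by_region().copy()
                )
            )

    clade_extinct = False
    while state.time < config.max_steps:
        state.time += 1
        allocate_populations(state, config)
        if audit is not None:
            audit(state)
        freq = config.disturbance_frequency
        if freq > 0 and state.time % freq == 0:
            disturbance_step(state, config)
        speciation_step(state, config, rng)
        dispersal_step(state, config, rng)
        extinction_step(state, config, rng)
        if state.n == 0:
            clade_extinct = True
            take_snapshot()
            break
        if state.time % config.snapshot_interval == 0:
            take_snapshot()
        if state.n > config.max_species:
            if state.time % config.snapshot_interval != 0:
                take_snapshot()
            break
    if not snapshots or snapshots[-1].time != state.time:
        take_snapshot()

    return SimulationResult(
        species=state.species.to_dataframe(),
        occupancy=state.occupancy_dataframe(),
        events=state.log.to_dataframe(),
        snapshots=snapshots,
        config=config,
        seed_used=seed,
        final_time=state.time,
        clade_extinct=clade_extinct,
    )
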