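"""Exact stochastic simulation with delayed product release.

This module implements the Gillespie direct method extended with a
*waitlist*: a reaction may release each of its products only after a fixed,
product-specific delay.  Between the firing of a reaction and the release of
a delayed product, the product molecule exists only as a scheduled entry on
the waitlist; it contributes to no propensity.

The algorithm is exact for networks of uni- and bimolecular mass-action
reactions.  At each step a candidate reaction time is drawn from the
exponential distribution with rate ``a0`` (the total propensity).  If the
earliest scheduled release precedes the candidate, the clock advances to the
release time, the released species is incremented, and the exponential draw
is discarded; by memorylessness of the exponential distribution, redrawing
at the new state is statistically identical to conditioning the old draw, so
exactness is preserved.  When a release time ties the candidate firing time,
the release is handled first (releases are deterministic scheduled events).

Species counts are integers and must stay non-negative; the engine raises if
that invariant is ever violated, since it would indicate a malformed network
rather than a numerical accident.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Species",
    "DelayedProduct",
    "Reaction",
    "ReactionNetwork",
    "Event",
    "DelayedSSA",
    "Trajectory",
    "NetworkConfigError",
    "compute_propensities",
    "simulate",
]


class NetworkConfigError(ValueError):
    """A reaction network definition is inconsistent (unknown species, bad rate...)."""


@dataclass(frozen=True)
class Species:
    """A chemical species with its initial copy number."""

    name: str
    initial_count: int = 0

    def __post_init__(self) -> None:
        if not self.name:
            raise NetworkConfigError("species name must be non-empty")
        if self.initial_count < 0:
            raise NetworkConfigError(
                f"species {self.name!r}: initial_count must be >= 0"
            )


@dataclass(frozen=True)
class DelayedProduct:
    """A reaction product released ``delay`` seconds after the reaction fires.

    ``delay == 0`` means the product appears immediately (ordinary Gillespie
    semantics).
    """

    species: str
    delay: float = 0.0

    def __post_init__(self) -> None:
        if self.delay < 0:
            raise NetworkConfigError(
                f"product {self.species!r}: delay must be >= 0, got {self.delay}"
            )


def _as_product(p) -> DelayedProduct:
    if isinstance(p, DelayedProduct):
        return p
    if isinstance(p, str):
        return DelayedProduct(p)
    species, delay = p
    return DelayedProduct(species, float(delay))


@dataclass(frozen=True)
class Reaction:
    """A mass-action reaction with at most two reactant slots.

    The propensity is ``rate * prod(count of each reactant)``.  Only distinct
    reactant species occur in the translation network, so no combinatorial
    ``n*(n-1)/2`` correction is applied; homodimerisation is rejected at
    network construction.

    Units: ``rate`` is 1/s for unimolecular and 1/(molecule*s) for
    bimolecular reactions (mesoscopic convention).
    """

    reactants: tuple[str, ...]
    products: tuple[DelayedProduct, ...]
    rate: float
    name: str = ""

    def __init__(self, reactants, products, rate, name=""):
        object.__setattr__(self, "reactants", tuple(reactants))
        object.__setattr__(
            self, "products", tuple(_as_product(p) for p in products)
        )
        object.__setattr__(self, "rate", float(rate))
        object.__setattr__(self, "name", name)
        if len(self.reactants) > 2:
            raise NetworkConfigError(
                f"reaction {name or self.reactants}: at most 2 reactant slots"
            )
        if len(set(self.reactants)) != len(self.reactants):
            raise NetworkConfigError(
                f"reaction {name or self.reactants}: homodimer reactions unsupported"
            )
        if not self.rate > 0:
            raise NetworkConfigError(
                f"reaction {name or self.reactants}: rate must be > 0"
            )


class ReactionNetwork:
    """An immutable reaction network: species with initial counts, reactions."""

    def __init__(self, species: Iterable[Species], reactions: Iterable[Reaction]):
        self.species: tuple[Species, ...] = tuple(
            s if isinstance(s, Species) else Species(*s) for s in species
        )
        self.reactions: tuple[Reaction, ...] = tuple(reactions)
        names = [s.name for s in self.species]
        if len(set(names)) != len(names):
            raise NetworkConfigError("species names must be unique")
        self.index: dict[str, int] = {n: i for i, n in enumerate(names)}
        for r in self.reactions:
            for sp in r.reactants:
                if sp not in self.index:
                    raise NetworkConfigError(f"unknown reactant species {sp!r}")
            for p in r.products:
                if p.species not in self.index:
                    raise NetworkConfigError(f"unknown product species {p.species!r}")

    @property
    def species_names(self) -> tuple[str, ...]:
        return tuple(s.name for s in self.species)

    def initial_counts(self) -> np.ndarray:
        return np.array([s.initial_count for s in self.species], dtype=np.int64)

    # -- plain-text configuration -------------------------------------------------

    @classmethod
    def from_dict(cls, cfg: Mapping) -> "ReactionNetwork":
        """Build a network from a plain mapping (parsed YAML/TOML).

        Expected shape::

            species:
              - {name: A, initial_count: 10}
            reactions:
              - {reactants: [A], products: [{species: B, delay: 5.0}], rate: 0.1}
        """
        try:
            species = [
                Species(str(s["name"]), int(s.get("initial_count", 0)))
                for s in cfg["species"]
            ]
            reactions = [
                Reaction(
                    reactants=[str(x) for x in r.get("reactants", [])],
                    products=[
                        DelayedProduct(str(p["species"]), float(p.get("delay", 0.0)))
                        for p in r.get("products", [])
                    ],
                    rate=float(r["rate"]),
                    name=str(r.get("name", "")),
                )
                for r in cfg["reactions"]
            ]
        except (KeyError, TypeError) as exc:
            raise NetworkConfigError(f"malformed network config: {exc}") from exc
        return cls(species, reactions)

    @classmethod
    def from_yaml(cls, path) -> "ReactionNetwork":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def compute_propensities(
    counts: Mapping[str, int] | Sequence[int],
    reactions: Sequence[Reaction],
    index: Mapping[str, int] | None = None,
) -> np.ndarray:
    """Mass-action propensities for each reaction at the given counts.

    ``counts`` may be a mapping species -> count, or an array aligned with
    ``index``.  Element ``i`` is ``rate_i * prod(counts of reactants of i)``;
    it is zero whenever any reactant pool is empty.
    """
    if isinstance(counts, Mapping):
        get = counts.__getitem__
        known = counts.__contains__
    else:
        if index is None:
            raise NetworkConfigError("array counts require a species index")
        get = lambda sp: counts[index[sp]]  # noqa: E731
        known = index.__contains__
    a = np.empty(len(reactions), dtype=float)
    for i, r in enumerate(reactions):
        for sp in r.reactants:
            if not known(sp):
                raise NetworkConfigError(f"unknown species {sp!r} in propensity")
        v = r.rate
        for sp in r.reactants:
            v *= get(sp)
        a[i] = v
    return a


@dataclass(frozen=True)
class Event:
    """One realised event: either a reaction firing or a waitlist release."""

    kind: str  # "reaction" | "release"
    time: float
    reaction_index: int | None = None
    species: str | None = None


@dataclass
class Trajectory:
    """A sampled realisation on a fixed time grid.

    Counts are piecewise-constant and right-continuous: each sample records
    the state immediately after the last event at or before the sample time.
    ``pending`` records, per species, the number of molecules scheduled on
    the waitlist (fired but not yet released) at the sample time; it is what
    makes exact conservation accounting possible downstream.
    """

    times: np.ndarray
    counts: np.ndarray  # shape (n_samples, n_species)
    pending: np.ndarray  # shape (n_samples, n_species)
    species: tuple[str, ...]
    seed: object = None

    def __post_init__(self) -> None:
        self._index = {n: i for i, n in enumerate(self.species)}

    def series(self, name: str) -> np.ndarray:
        return self.counts[:, self._index[name]]

    def pending_series(self, name: str) -> np.ndarray:
        return self.pending[:, self._index[name]]

    def to_frame(self):
        """Tidy (time, species, count) DataFrame."""
        import pandas as pd

        n_t, n_s = self.counts.shape
        return pd.DataFrame(
            {
                "time": np.repeat(self.times, n_s),
                "species": np.tile(np.array(self.species, dtype=object), n_t),
                "count": self.counts.ravel(),
            }
        )


class DelayedSSA:
    """Stepwise delayed-SSA engine over a :class:`ReactionNetwork`.

    Exposes single-event stepping for inspection and testing; `simulate`
    wraps the same draw sequence in a tight sampling loop, and the two are
    draw-for-draw identical for a given seed.
    """

    def __init__(
        self,
        network: ReactionNetwork,
        seed,
        initial_counts: Mapping[str, int] | None = None,
    ):
        self.network = network
        self.rng = np.random.default_rng(seed)
        self.time = 0.0
        # plain Python ints: scalar indexing dominates the hot loop
        self.counts: list[int] = [int(c) for c in network.initial_counts()]
        if initial_counts is not None:
            for sp, c in initial_counts.items():
                if sp not in network.index:
                    raise NetworkConfigError(f"unknown species {sp!r}")
                if c < 0:
                    raise NetworkConfigError(f"negative initial count for {sp!r}")
                self.counts[network.index[sp]] = int(c)
        self.pending: list[int] = [0] * len(network.species)
        self.waitlist: list[tuple[float, int, int]] = []  # (release_time, fifo, sp)
        self._fifo = 0
        # flattened reaction views for the hot loop: (rate, first, second|-1)
        self._r_reactants = [
            tuple(network.index[sp] for sp in r.reactants) for r in network.reactions
        ]
        self._r_first = [r[0] if r else -1 for r in self._r_reactants]
        self._r_second = [r[1] if len(r) == 2 else -1 for r in self._r_reactants]
        self._r_products = [
            tuple((network.index[p.species], p.delay) for p in r.products)
            for r in network.reactions
        ]
        self._rates = [r.rate for r in network.reactions]

    def propensities(self) -> np.ndarray:
        return compute_propensities(
            self.counts, self.network.reactions, self.network.index
        )

    def schedule(self, species_idx: int, release_time: float) -> None:
        heapq.heappush(self.waitlist, (release_time, self._fifo, species_idx))
        self._fifo += 1
        self.pending[species_idx] += 1

    def step(self) -> Event | None:
        """Advance by one event; return it, or ``None`` if the system is dead.

        A dead system has zero total propensity and an empty waitlist; this
        is a termination signal, not an error.
        """
        counts = self.counts
        a0 = 0.0
        a = []
        for k in range(len(self._rates)):
            v = self._rates[k]
            i = self._r_first[k]
            if i >= 0:
                v *= counts[i]
                j = self._r_second[k]
                if j >= 0:
                    v *= counts[j]
            a.append(v)
            a0 += v

        if a0 > 0.0:
            candidate = self.time + self.rng.standard_exponential() / a0
        else:
            candidate = np.inf
        if self.waitlist and self.waitlist[0][0] <= candidate:
            # scheduled release wins (ties included); the exponential draw is
            # discarded — redrawing next step is exact by memorylessness
            t_rel, _, sp = heapq.heappop(self.waitlist)
            self.time = t_rel
            counts[sp] += 1
            self.pending[sp] -= 1
            return Event("release", t_rel, species=self.network.species_names[sp])
        if not np.isfinite(candidate):
            return None
        u = self.rng.random() * a0
        acc = 0.0
        k = 0
        for k in range(len(a)):
            acc += a[k]
            if u < acc:
                break
        self.time = candidate
        for i in self._r_reactants[k]:
            counts[i] -= 1
            if counts[i] < 0:
                raise RuntimeError(
                    f"negative count for {self.network.species_names[i]!r}"
                )
        for i, delay in self._r_products[k]:
            if delay == 0.0:
                counts[i] += 1
            else:
                self.schedule(i, candidate + delay)
        return Event("reaction", candidate, reaction_index=k)


def simulate(
    network: ReactionNetwork,
    t_end: float,
    sample_interval: float = 10.0,
    seed=None,
    initial_counts: Mapping[str, int] | None = None,
) -> Trajectory:
    """Run the delayed SSA to ``t_end`` and sample on a uniform grid.

    The sample grid is ``0, dt, 2*dt, ..., t_end`` (``t_end`` included when it
    is a grid multiple; the final state is always recorded at the last grid
    point <= t_end).  Identical ``(network, seed)`` reproduce the trajectory
    bit for bit.
    """
    if not t_end > 0:
        raise ValueError("t_end must be > 0")
    if not sample_interval > 0:
        raise ValueError("sample_interval must be > 0")

    engine = DelayedSSA(network, seed, initial_counts)
    n_species = len(network.species)
    grid = np.arange(0.0, t_end + 0.5 * sample_interval, sample_interval)
    grid = grid[grid <= t_end]
    n_samples = len(grid)
    out_counts = np.empty((n_samples, n_species), dtype=np.int64)
    out_pending = np.empty((n_samples, n_species), dtype=np.int64)

    # hot loop: same draw order as DelayedSSA.step, but with sampling inlined
    # and state held in Python lists (scalar indexing dominates the cost)
    counts = engine.counts
    pending = engine.pending
    waitlist = engine.waitlist
    rates = engine._rates
    r_first = engine._r_first
    r_second = engine._r_second
    r_reactants = engine._r_reactants
    r_products = engine._r_products
    n_reactions = len(rates)
    rng = engine.rng
    std_exp = rng.standard_exponential
    uniform = rng.random
    push = heapq.heappush
    pop = heapq.heappop
    grid_list = [float(g) for g in grid]
    inf = float("inf")

    t = 0.0
    next_k = 0  # next grid index to record
    fifo = engine._fifo
    a = [0.0] * n_reactions
    rng_range = range(n_reactions)
    while True:
        a0 = 0.0
        for k in rng_range:
            v = rates[k]
            i = r_first[k]
            if i >= 0:
                v *= counts[i]
                j = r_second[k]
                if j >= 0:
                    v *= counts[j]
            a[k] = v
            a0 += v

        if a0 > 0.0:
            candidate = t + std_exp() / a0
        else:
            candidate = inf

        if waitlist and waitlist[0][0] <= candidate:
            t_event = waitlist[0][0]
            if t_event > t_end:
                break
            while next_k < n_samples and grid_list[next_k] < t_event:
                out_counts[next_k] = counts
                out_pending[next_k] = pending
                next_k += 1
            _, _, sp = pop(waitlist)
            counts[sp] += 1
            pending[sp] -= 1
            t = t_event
            continue

        if candidate == inf:
            break  # dead system: no propensity, no scheduled releases
        if candidate > t_end:
            break
        while next_k < n_samples and grid_list[next_k] < candidate:
            out_counts[next_k] = counts
            out_pending[next_k] = pending
            next_k += 1
        u = uniform() * a0
        acc = 0.0
        for k in rng_range:
            acc += a[k]
            if u < acc:
                break
        for i in r_reactants[k]:
            c = counts[i] - 1
            if c < 0:
                raise RuntimeError(
                    f"negative count for {network.species_names[i]!r}"
                )
            counts[i] = c
        for i, delay in r_products[k]:
            if delay == 0.0:
                counts[i] += 1
            else:
                push(waitlist, (candidate + delay, fifo, i))
                fifo += 1
                pending[i] += 1
        t = candidate

    while next_k < n_samples:
        out_counts[next_k] = counts
        out_pending[next_k] = pending
        next_k += 1

    return Trajectory(
        times=grid,
        counts=out_counts,
        pending=out_pending,
        species=network.species_names,
        seed=seed,
    )
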