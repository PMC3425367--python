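"""Vacancy-cascade engine.

A primary inner-shell vacancy relaxes through a sequence of radiative
(X-ray) and non-radiative (Auger / Coster-Kronig) transitions.  At each step
the deepest queued vacancy is considered, the energetically allowed channels
out of it are enumerated, one is drawn at random with the (occupancy-scaled)
single-vacancy rates as weights, and the bookkeeping is updated: an X-ray
moves the vacancy outward, an Auger electron converts one vacancy into two.
A vacancy terminates when it reaches a valence subshell or when no channel
remains energetically possible (it is then frozen in place); vacancies are
never neutralized from the environment.  Since every transition moves
vacancies strictly outward, termination is guaranteed.

``enumerate_cascade_tree`` expands the complete probability tree of a small
atom exactly and serves as an independent oracle for the Monte Carlo.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .atomic import (
    AtomTable,
    EnergyModel,
    RateSet,
    ValidationError,
    auger_energy,
    xray_energy,
)

__all__ = [
    "Emission",
    "AtomState",
    "CascadeEvent",
    "Channel",
    "CascadeTree",
    "allowed_transitions",
    "select_transition",
    "apply_transition",
    "run_cascade",
    "enumerate_cascade_tree",
]


@dataclass(frozen=True)
class Emission:
    """One emitted quantum of atomic radiation."""

    kind: str  # "xray" | "auger"
    shells: tuple[str, ...]  # (X, Y) or (X, Y, Z)
    energy: float  # eV, > 0
    step: int  # propagation step index, >= 1


@dataclass(frozen=True)
class Channel:
    """A candidate transition out of a vacancy, with its sampling weight."""

    kind: str  # "xray" | "auger"
    shells: tuple[str, ...]
    energy: float  # eV
    weight: float


@dataclass
class AtomState:
    """Mutable electron bookkeeping during one cascade."""

    table: AtomTable
    occupancy: dict[str, int]
    vacancies: list[tuple[str, int]] = field(default_factory=list)  # (label, step)
    emitted: list[Emission] = field(default_factory=list)

    @classmethod
    def neutral(cls, table: AtomTable) -> "AtomState":
        return cls(table, {s.label: s.neutral_occupancy for s in table.subshells})

    def n_vacancies(self) -> int:
        return sum(
            s.neutral_occupancy - self.occupancy[s.label]
            for s in self.table.subshells
        )

    def ionize(self, label: str, step: int = 0) -> None:
        """Remove one electron from ``label`` and queue the vacancy."""
        if self.occupancy[label] <= 0:
            raise ValidationError(f"cannot ionize empty subshell {label}")
        self.occupancy[label] -= 1
        self.vacancies.append((label, step))


@dataclass(frozen=True)
class CascadeEvent:
    """Full record of one relaxed primary vacancy."""

    origin: str
    initial: str  # subshell of the primary vacancy
    emissions: tuple[Emission, ...]
    final_charge: int
    terminal_vacancies: tuple[str, ...]  # reached a valence subshell
    frozen_vacancies: tuple[str, ...]  # stuck: no allowed channel
    steps_used: int

    @property
    def n_auger(self) -> int:
        return sum(1 for e in self.emissions if e.kind == "auger")

    @property
    def n_xray(self) -> int:
        return sum(1 for e in self.emissions if e.kind == "xray")

    def outcome_key(self) -> tuple[tuple[str, ...], ...]:
        """Order-independent channel multiset, comparable with the tree oracle."""
        return tuple(sorted((e.kind,) + e.shells for e in self.emissions))


# ---------------------------------------------------------------------------
# channel enumeration and application
# ---------------------------------------------------------------------------

def _occupancy_factor(
    state: AtomState, y: str, z: str | None, scaling: bool
) -> float:
    """Statistical-availability correction of a single-vacancy rate.

    Radiative: n_Y / n_Y0.  Auger: (n_Y / n_Y0) * (n_Z / n_Z0), with
    (n_Z - 1)/(n_Z0 - 1) as the second factor when Y == Z, since the same
    subshell must supply both electrons.  With scaling off the factor is 1
    whenever the required electrons are present at all.
    """
    ny, ny0 = state.occupancy[y], state.table[y].neutral_occupancy
    if z is None:
        if ny <= 0:
            return 0.0
        return ny / ny0 if scaling else 1.0
    if y == z:
        if ny < 2:
            return 0.0
        if not scaling:
            return 1.0
        return (ny / ny0) * ((ny - 1) / (ny0 - 1)) if ny0 > 1 else 0.0
    nz, nz0 = state.occupancy[z], state.table[z].neutral_occupancy
    if ny <= 0 or nz <= 0:
        return 0.0
    return (ny / ny0) * (nz / nz0) if scaling else 1.0


def allowed_transitions(
    state: AtomState,
    vacancy: str,
    rates: RateSet,
    model: EnergyModel,
    occupancy_scaling: bool = True,
) -> list[Channel]:
    """Weighted channels available to fill ``vacancy`` in the current state.

    A radiative channel X <- Y needs at least one Y electron and a positive
    photon energy; an Auger channel X, YZ needs the Y and Z electrons (two of
    them when Y == Z) and a positive electron energy.  Channels that fail
    either test are simply absent; the remaining weights are the tabulated
    single-vacancy rates times the occupancy factor.  May be empty.
    """
    if state.occupancy[vacancy] >= state.table[vacancy].neutral_occupancy:
        raise ValidationError(f"no vacancy present on {vacancy}")
    if vacancy in state.table.valence_labels:
        raise ValidationError(f"{vacancy} is a valence subshell; nothing to enumerate")
    channels: list[Channel] = []
    for (x, y), rate in sorted(rates.radiative_from(vacancy).items()):
        f = _occupancy_factor(state, y, None, occupancy_scaling)
        if f <= 0 or rate <= 0:
            continue
        e = xray_energy(x, y, model)
        if e is None:
            continue
        channels.append(Channel("xray", (x, y), e, rate * f))
    for (x, y, z), rate in sorted(rates.nonradiative_from(vacancy).items()):
        f = _occupancy_factor(state, y, z, occupancy_scaling)
        if f <= 0 or rate <= 0:
            continue
        e = auger_energy(x, y, z, model)
        if e is None:
            continue
        channels.append(Channel("auger", (x, y, z), e, rate * f))
    return channels


def select_transition(
    channels: Sequence[Channel], rng: np.random.Generator
) -> Channel:
    """Draw one channel with probability weight / sum(weights) (inverse CDF)."""
    if not channels:
        raise ValidationError("cannot select from an empty channel list")
    total = sum(c.weight for c in channels)
    if total <= 0:
        raise ValidationError("total channel weight is zero")
    u = rng.random() * total
    acc = 0.0
    for c in channels:
        acc += c.weight
        if u < acc:
            return c
    return channels[-1]


def apply_transition(
    state: AtomState, channel: Channel, step: int
) -> Emission:
    """Mutate ``state`` according to ``channel`` and record the emission.

    The vacancy being filled must already have been removed from the queue
    by the caller; new vacancies are queued with the given ``step``.
    """
    x = channel.shells[0]
    if channel.kind == "xray":
        _, y = channel.shells
        if state.occupancy[y] <= 0:
            raise ValidationError(f"no electron in {y} to fill {x}")
        state.occupancy[x] += 1
        state.occupancy[y] -= 1
        state.vacancies.append((y, step))
    else:
        _, y, z = channel.shells
        need = 2 if y == z else 1
        if state.occupancy[y] < need or state.occupancy[z] < need:
            raise ValidationError(f"missing electrons for Auger {channel.shells}")
        state.occupancy[x] += 1
        state.occupancy[y] -= 1
        state.occupancy[z] -= 1
        state.vacancies.append((y, step))
        state.vacancies.append((z, step))
    emission = Emission(channel.kind, channel.shells, channel.energy, step)
    state.emitted.append(emission)
    return emission


def _pop_deepest(state: AtomState) -> tuple[str, int]:
    """Remove and return the queued vacancy with the largest binding energy."""
    idx = max(
        range(len(state.vacancies)),
        key=lambda i: (
            state.table.binding(state.vacancies[i][0]),
            -state.vacancies[i][1],
        ),
    )
    return state.vacancies.pop(idx)


def run_cascade(
    table: AtomTable,
    rates: RateSet,
    initial: str,
    rng: np.random.Generator,
    model: EnergyModel,
    occupancy_scaling: bool = True,
    origin: str = "primary",
) -> CascadeEvent:
    """Propagate one primary vacancy on ``initial`` to full termination.

    The deepest queued vacancy is processed first (inner vacancies are the
    shortest-lived).  The step index of a transition is one more than the
    step at which the vacancy it fills was created; the primary vacancy has
    step 0.
    """
    if initial not in table:
        raise ValidationError(f"unknown initial subshell {initial}")
    state = AtomState.neutral(table)
    state.ionize(initial, step=0)
    terminal: list[str] = []
    frozen: list[str] = []
    guard = 4 * sum(s.neutral_occupancy for s in table.subshells) + 8
    for _ in range(guard):
        if not state.vacancies:
            break
        label, step = _pop_deepest(state)
        if label in table.valence_labels:
            terminal.append(label)
            continue
        channels = allowed_transitions(
            state, label, rates, model, occupancy_scaling
        )
        if not channels:
            frozen.append(label)
            continue
        channel = select_transition(channels, rng)
        apply_transition(state, channel, step + 1)
    else:  # pragma: no cover - the outward-flow invariant forbids this
        raise RuntimeError("cascade failed to terminate within the step guard")
    emissions = tuple(state.emitted)
    return CascadeEvent(
        origin=origin,
        initial=initial,
        emissions=emissions,
        final_charge=state.n_vacancies(),
        terminal_vacancies=tuple(sorted(terminal)),
        frozen_vacancies=tuple(sorted(frozen)),
        steps_used=max((e.step for e in emissions), default=0),
    )


# ---------------------------------------------------------------------------
# exhaustive tree oracle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CascadeTree:
    """Exact outcome distribution of a cascade on a small atom.

    ``outcomes`` maps an order-independent channel multiset (as produced by
    ``CascadeEvent.outcome_key``) to its exact probability.
    """

    initial: str
    outcomes: Mapping[tuple[tuple[str, ...], ...], float]

    def total_probability(self) -> float:
        return sum(self.outcomes.values())

    def expected_counts(self) -> dict[str, float]:
        """Expected emissions per cascade, by kind."""
        out = {"xray": 0.0, "auger": 0.0}
        for key, p in self.outcomes.items():
            for entry in key:
                out[entry[0]] += p
        return out

    def expected_channel_yields(self) -> dict[tuple[str, ...], float]:
        """Expected count of each individual channel per cascade."""
        out: dict[tuple[str, ...], float] = {}
        for key, p in self.outcomes.items():
            for entry in key:
                out[entry] = out.get(entry, 0.0) + p
        return out


class NodeBudgetExceeded(RuntimeError):
    """The exact tree is too large; the oracle refuses rather than truncate."""


def enumerate_cascade_tree(
    table: AtomTable,
    rates: RateSet,
    initial: str,
    model: EnergyModel,
    occupancy_scaling: bool = True,
    node_budget: int = 200_000,
) -> CascadeTree:
    """Depth-first exact expansion of every cascade path from ``initial``.

    Follows exactly the same scheduling, channel enumeration and weighting
    as ``run_cascade`` but replaces sampling with full branching, so the
    outcome probabilities are the exact distribution the Monte Carlo samples
    from.  Intended for toy atoms only; refuses beyond ``node_budget`` nodes.
    """
    outcomes: dict[tuple[tuple[str, ...], ...], float] = {}
    nodes = 0

    def expand(state: AtomState, prob: float) -> None:
        nonlocal nodes
        nodes += 1
        if nodes > node_budget:
            raise NodeBudgetExceeded(
                f"cascade tree exceeds {node_budget} nodes; "
                f"use a smaller toy atom"
            )
        while state.vacancies:
            label, step = _pop_deepest(state)
            if label in table.valence_labels:
                continue
            channels = allowed_transitions(
                state, label, rates, model, occupancy_scaling
            )
            if not channels:
                continue
            total = sum(c.weight for c in channels)
            for c in channels:
                child = AtomState(
                    table,
                    dict(state.occupancy),
                    list(state.vacancies),
                    list(state.emitted),
                )
                apply_transition(child, c, step + 1)
                expand(child, prob * c.weight / total)
            return
        key = tuple(sorted((e.kind,) + e.shells for e in state.emitted))
        outcomes[key] = outcomes.get(key, 0.0) + prob

    root = AtomState.neutral(table)
    root.ionize(initial, step=0)
    expand(root, 1.0)
    return CascadeTree(initial=initial, outcomes=outcomes)
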