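"""Seeded stochastic foraging simulator and independent oracle.

The deterministic model predicts only two summary quantities per pollinator —
the focal visit proportion ``psi`` and the heterospecific share ``H`` — and is
silent about visit order mechanics.  The minimal stochastic process consistent
with both is a two-state Markov chain over {focal, other} with

    p_FF = P(next focal | current focal) = 1 - H
    p_OF = P(next focal | current other) = H psi / (1 - psi)

These are forced by two requirements: stationarity of (psi, 1 - psi), i.e.
``psi p_FF + (1 - psi) p_OF = psi``, and the conditional origin distribution
at focal arrivals, ``(1 - psi) p_OF / psi = H``.  Not every (psi, H) pair is
realizable — strongly opposed preference and constancy can demand
``p_OF > 1`` — and such parameter combinations raise :class:`DomainError`.

Bouts start from the stationary distribution, so expected tallies match the
closed forms without burn-in.  Each pollinator draws from its own random
stream derived from the root seed by spawn index, so adding a pollinator to a
configuration never perturbs the sequences of the others.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .behavior import DomainError, heterospecific_share, visit_proportion, _check_frequency
from .community import GuildMember
from .estimation import ObservationTable, TransitionTally

__all__ = ["ForagingChain", "SimulationConfig", "build_chain", "simulate", "expected_tally"]

#: tolerance on the stationarity identity psi p_FF + (1-psi) p_OF = psi
_STATIONARITY_TOL = 1e-10


@dataclass(frozen=True)
class ForagingChain:
    """Two-state foraging chain realizing a (psi, H) pair.

    States are focal (F) and other (O); ``p_FF`` and ``p_OF`` are the
    probabilities that the next visit is focal given the current state.
    """

    p_FF: float
    p_OF: float
    psi: float
    H: float

    def __post_init__(self) -> None:
        for name in ("p_FF", "p_OF"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise DomainError(f"{name} must be a probability, got {p}")
        drift = self.psi * self.p_FF + (1.0 - self.psi) * self.p_OF - self.psi
        if abs(drift) > _STATIONARITY_TOL:
            raise DomainError(
                f"chain is not stationary at psi={self.psi}: drift {drift:.3e}"
            )


def build_chain(f: float, rho: float, kappa: float) -> ForagingChain:
    """Construct the foraging chain for a behavior at focal frequency ``f``.

    Raises
    ------
    DomainError
        If ``psi`` is degenerate (0 or 1, leaving one state unreachable) or
        the implied ``p_OF = H psi / (1 - psi)`` exceeds 1, in which case no
        first-order two-state chain realizes the requested (psi, H).
    """
    f = _check_frequency(f)
    psi = visit_proportion(f, rho)
    if not 0.0 < psi < 1.0:
        raise DomainError(
            f"visit proportion psi={psi} is degenerate at rho={rho}, f={f}; "
            "both plant types must be visited to simulate transitions"
        )
    H = heterospecific_share(f, rho, kappa)
    p_OF = H * psi / (1.0 - psi)
    if p_OF > 1.0 + 1e-12:
        raise DomainError(
            f"no two-state chain realizes rho={rho}, kappa={kappa}, f={f}: "
            f"implied p_OF={p_OF:.4f} > 1"
        )
    return ForagingChain(p_FF=1.0 - H, p_OF=min(p_OF, 1.0), psi=psi, H=H)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic observation campaign.

    ``n_bouts`` is the community-wide bout budget, allocated to pollinators in
    proportion to their visit shares ``phi_i`` (at least one bout each);
    ``bout_length`` visits per bout.  ``seed`` is required — there is no
    silent clock seeding.
    """

    f: float
    guild: tuple[GuildMember, ...]
    n_bouts: int
    bout_length: int
    seed: int
    focal_id: str = "focal"
    other_id: str = "other"

    def __post_init__(self) -> None:
        _check_frequency(self.f)
        object.__setattr__(self, "guild", tuple(self.guild))
        if not self.guild:
            raise DomainError("simulation needs at least one pollinator")
        if self.bout_length < 2:
            raise DomainError(f"bout_length must be >= 2, got {self.bout_length}")
        if self.n_bouts < 1:
            raise DomainError(f"n_bouts must be >= 1, got {self.n_bouts}")
        if self.seed is None or not isinstance(self.seed, (int, np.integer)):
            raise DomainError("an explicit integer seed is required")

    def bouts_per_pollinator(self) -> list[int]:
        return [max(1, round(m.phi * self.n_bouts)) for m in self.guild]


def _member_label(member: GuildMember, index: int) -> str:
    return member.id or f"pollinator{index + 1}"


def _simulate_states(chain: ForagingChain, n_bouts: int, bout_length: int, rng) -> np.ndarray:
    """Boolean matrix (n_bouts, bout_length); True marks a focal visit."""
    states = np.empty((n_bouts, bout_length), dtype=bool)
    states[:, 0] = rng.random(n_bouts) < chain.psi
    for step in range(1, bout_length):
        p_next = np.where(states[:, step - 1], chain.p_FF, chain.p_OF)
        states[:, step] = rng.random(n_bouts) < p_next
    return states


def simulate(config: SimulationConfig) -> ObservationTable:
    """Generate a synthetic observation table under the configured guild.

    The first visit of each bout is drawn from the pollinator's stationary
    distribution ``(psi, 1 - psi)``; later visits follow its chain.  Output
    is bit-identical for identical configurations and seeds.
    """
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(len(config.guild))
    frames = []
    for i, member in enumerate(config.guild):
        rho = member.preference_at(config.f)
        chain = build_chain(config.f, rho, member.kappa)
        n_bouts = config.bouts_per_pollinator()[i]
        rng = np.random.default_rng(streams[i])
        states = _simulate_states(chain, n_bouts, config.bout_length, rng)
        label = _member_label(member, i)
        L = config.bout_length
        frames.append(
            pd.DataFrame(
                {
                    "bout_id": np.repeat(
                        [f"{label}-b{k + 1}" for k in range(n_bouts)], L
                    ),
                    "pollinator_id": label,
                    "visit_index": np.tile(np.arange(1, L + 1), n_bouts),
                    "plant_id": np.where(states.ravel(), config.focal_id, config.other_id),
                }
            )
        )
    data = pd.concat(frames, ignore_index=True)
    return ObservationTable(data, focal_plant_id=config.focal_id)


def expected_tally(config: SimulationConfig) -> dict:
    """Exact expected visit and transition counts under each chain.

    No sampling: each of the ``bout_length - 1`` steps of a bout is taken at
    stationarity, so for a pollinator with ``n`` transitions in total the
    expected cells are ``n psi p_FF`` (F->F), ``n (1 - psi) p_OF`` (O->F),
    etc.  Feeding these real-valued tallies to the estimators reproduces
    (rho, kappa) exactly — the deterministic round trip.
    """
    out: dict = {}
    for i, member in enumerate(config.guild):
        rho = member.preference_at(config.f)
        chain = build_chain(config.f, rho, member.kappa)
        n_bouts = config.bouts_per_pollinator()[i]
        n_visits = n_bouts * config.bout_length
        n_trans = n_bouts * (config.bout_length - 1)
        psi, p_FF, p_OF = chain.psi, chain.p_FF, chain.p_OF
        out[_member_label(member, i)] = TransitionTally(
            n_visits_total=float(n_visits),
            n_visits_focal=n_visits * psi,
            n_FF=n_trans * psi * p_FF,
            n_OF=n_trans * (1.0 - psi) * p_OF,
            n_FO=n_trans * psi * (1.0 - p_FF),
            n_OO=n_trans * (1.0 - psi) * (1.0 - p_OF),
        )
    return out
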