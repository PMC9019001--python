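"""Multi-pollinator composition of heterospecific movement and total RI.

Most plants receive visits from several pollinators that differ in preference,
constancy and abundance.  Each guild member ``i`` contributes its own
heterospecific share ``H_i``, weighted by its share ``v_i`` of the focal
plant's visits:

    v_i   = phi_i psi_i / sum_j phi_j psi_j
    H_tot = sum_i v_i H_i
    RI_tot = 1 - 2 H_tot / (H_tot + (1 - f))

where ``phi_i`` is pollinator *i*'s share of all visits in the community
(conflating abundance and per-capita visit rate) and ``psi_i`` its focal visit
proportion.  With two members this is exactly the printed two-pollinator
model; the sums generalize it to any guild size.

Preference may be supplied as a constant in [-1, 1] or as a callable
``rho(f)`` (a frequency-dependent preference hook); a constant is the
degenerate hook.  :func:`linear_preference` ships an illustrative linear hook.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from .behavior import (
    DomainError,
    _check_frequency,
    _check_index,
    heterospecific_share,
    isolation_from_share,
    visit_proportion,
)

__all__ = [
    "GuildMember",
    "CommunityScenario",
    "linear_preference",
    "focal_visit_shares",
    "total_heterospecific_share",
    "isolation_total",
    "crossover_frequencies",
]

#: tolerance on sum(phi_i) == 1
_PHI_TOL = 1e-9

Preference = float | Callable[[float], float]


def linear_preference(strength: float) -> Callable[[float], float]:
    """Illustrative linear frequency-dependent preference hook.

    Returns ``rho(f) = strength * (2 f - 1)``: positive frequency dependence
    for ``strength > 0`` (the pollinator favors whichever plant is common),
    vanishing at ``f = 0.5``.  Requires ``|strength| <= 1`` so the hook maps
    (0, 1) into [-1, 1].  This functional form is an example, not a claim
    about any particular pollinator.
    """
    strength = float(strength)
    if not abs(strength) <= 1.0:
        raise DomainError(f"linear preference strength must lie in [-1, 1], got {strength}")
    return lambda f: strength * (2.0 * f - 1.0)


@dataclass(frozen=True)
class GuildMember:
    """One pollinator in the community.

    Parameters
    ----------
    rho : float or callable
        Preference for the focal plant; either a constant in [-1, 1] or a
        function of the focal frequency returning a value in [-1, 1].
    kappa : float
        Constancy toward the focal plant, in [-1, 1].
    phi : float
        This pollinator's share of all visits in the community, in [0, 1].
    id : str
        Optional label used in outputs.
    """

    rho: Preference
    kappa: float
    phi: float
    id: str = ""

    def __post_init__(self) -> None:
        if not callable(self.rho):
            _check_index("preference rho", self.rho)
        _check_index("constancy kappa", self.kappa)
        phi = float(self.phi)
        if not (math.isfinite(phi) and 0.0 <= phi <= 1.0):
            raise DomainError(f"visit share phi must lie in [0, 1], got {self.phi!r}")

    def preference_at(self, f: float) -> float:
        """Resolve the (possibly frequency-dependent) preference at ``f``."""
        if callable(self.rho):
            value = float(self.rho(f))
            if not (math.isfinite(value) and -1.0 <= value <= 1.0):
                raise DomainError(
                    f"preference hook for pollinator {self.id!r} returned {value} "
                    f"at f={f}; must lie in [-1, 1]"
                )
            return value
        return float(self.rho)


@dataclass(frozen=True)
class CommunityScenario:
    """A focal-plant frequency plus an ordered pollinator guild.

    Visit shares must sum to 1 (within 1e-9) and the guild must be non-empty.
    """

    f: float
    guild: tuple[GuildMember, ...]

    def __init__(self, f: float, guild: Sequence[GuildMember]):
        object.__setattr__(self, "f", _check_frequency(f))
        members = tuple(guild)
        if not members:
            raise DomainError("a community scenario needs at least one pollinator")
        total_phi = sum(m.phi for m in members)
        if abs(total_phi - 1.0) > _PHI_TOL:
            raise DomainError(
                f"pollinator visit shares must sum to 1, got {total_phi!r}"
            )
        object.__setattr__(self, "guild", members)

    def with_frequency(self, f: float) -> "CommunityScenario":
        """The same guild at a different focal frequency."""
        return CommunityScenario(f, self.guild)


def _member_quantities(scenario: CommunityScenario) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(phi_i, psi_i, H_i) arrays for the guild at the scenario's frequency."""
    f = scenario.f
    phi = np.array([m.phi for m in scenario.guild])
    rho = [m.preference_at(f) for m in scenario.guild]
    psi = np.array([visit_proportion(f, r) for r in rho])
    H = np.array(
        [heterospecific_share(f, r, m.kappa) for r, m in zip(rho, scenario.guild)]
    )
    return phi, psi, H


def focal_visit_shares(scenario: CommunityScenario) -> np.ndarray:
    """Share ``v_i`` of the focal plant's visits contributed by each pollinator.

        v_i = phi_i psi_i / sum_j phi_j psi_j

    Raises :class:`DomainError` if no pollinator ever visits the focal plant
    (all ``phi_i psi_i = 0``).
    """
    phi, psi, _ = _member_quantities(scenario)
    weights = phi * psi
    total = weights.sum()
    if total <= 0.0:
        raise DomainError(
            "no pollinator visits the focal plant (all phi_i * psi_i are zero)"
        )
    return weights / total


def total_heterospecific_share(scenario: CommunityScenario) -> float:
    """Community heterospecific share ``H_tot = sum_i v_i H_i``.

    Reduces to the single-pollinator ``H`` for a guild of one, and to the
    printed two-pollinator form ``v1 H1 + (1 - v1) H2`` for a guild of two.
    """
    v = focal_visit_shares(scenario)
    _, _, H = _member_quantities(scenario)
    return float(v @ H)


def isolation_total(scenario: CommunityScenario) -> float:
    """Total ethological RI of the focal plant under the whole guild.

        RI_tot = 1 - 2 H_tot / (H_tot + (1 - f))
    """
    return isolation_from_share(total_heterospecific_share(scenario), scenario.f)


def _ri_difference(guild_a, guild_b, f: float) -> float:
    return isolation_total(CommunityScenario(f, guild_a)) - isolation_total(
        CommunityScenario(f, guild_b)
    )


def crossover_frequencies(
    scenario_a: CommunityScenario | Sequence[GuildMember],
    scenario_b: CommunityScenario | Sequence[GuildMember],
    *,
    grid_size: int = 10_001,
    f_tol: float = 1e-6,
    edge: float = 1e-4,
) -> list[float]:
    """Focal frequencies at which two guilds predict equal total RI.

    The difference ``RI_tot(a)(f) - RI_tot(b)(f)`` is scanned for sign changes
    on a uniform grid of ``grid_size`` points over ``(edge, 1 - edge)``; each
    bracketed root is refined by bisection to ``|df| <= f_tol``.  Crossings are
    returned in ascending order.  Identical guilds (difference numerically
    zero everywhere) yield an empty list: a flat zero is not an isolated
    crossing.
    """
    guild_a = scenario_a.guild if isinstance(scenario_a, CommunityScenario) else tuple(scenario_a)
    guild_b = scenario_b.guild if isinstance(scenario_b, CommunityScenario) else tuple(scenario_b)
    fs = np.linspace(edge, 1.0 - edge, grid_size)
    diff = np.array([_ri_difference(guild_a, guild_b, f) for f in fs])

    # points numerically on zero carry no sign information
    zero = np.abs(diff) < 1e-12
    crossings: list[float] = []
    signs = np.sign(diff)
    for k in range(len(fs) - 1):
        if zero[k] or zero[k + 1]:
            continue
        if signs[k] * signs[k + 1] < 0:
            root = brentq(
                lambda f: _ri_difference(guild_a, guild_b, f),
                fs[k],
                fs[k + 1],
                xtol=f_tol,
            )
            crossings.append(float(root))
    return crossings
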