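"""Single-pollinator closed forms for ethological reproductive isolation.

A two-type plant community (a focal species at relative frequency ``f`` and a
pooled heterospecific class at ``1 - f``) is visited by a pollinator whose
behavior is summarized by two indices on a common [-1, 1] scale:

* **preference** ``rho`` — the tendency to visit the focal plant more (+) or
  less (-) often than its frequency predicts; ``rho = 0`` means visits are
  proportional to frequency, ``rho = 1`` means only the focal plant is visited,
  ``rho = -1`` means it is never visited.
* **constancy** ``kappa`` — the tendency to follow a visit to a plant type
  with another visit to the same type, beyond what the pollinator's overall
  visit proportions predict.  Positive constancy means runs of same-type
  visits; negative constancy means excess switching.

From these the model predicts the proportion of the pollinator's visits that
land on the focal plant (``psi``), the heterospecific share ``H`` — among
movements *into* the focal plant, the fraction whose previous plant was
heterospecific, i.e. the pollen-contaminating transitions — and the strength
of ethological reproductive isolation

    RI = 1 - 2 H / (H + (1 - f)),

where ``1 - f`` is the heterospecific share expected under random movement.
RI runs from -1 (fully disassortative pollen movement) through 0 (random)
to 1 (fully assortative).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

__all__ = [
    "DomainError",
    "PollinatorBehavior",
    "FlaggedValue",
    "visit_proportion",
    "preference_from_visits",
    "constancy_from_movements",
    "heterospecific_share",
    "isolation_from_share",
    "isolation_one",
]

#: absolute guard below which a denominator is treated as vanishing
_DENOM_TOL = 1e-300


class DomainError(ValueError):
    """A model quantity lies outside its mathematical domain."""


def _require(cond: bool, message: str) -> None:
    if not cond:
        raise DomainError(message)


def _check_frequency(f: float) -> float:
    f = float(f)
    _require(math.isfinite(f), f"focal frequency f must be finite, got {f!r}")
    _require(0.0 < f < 1.0, f"focal frequency f must satisfy 0 < f < 1, got {f}")
    return f


def _check_index(name: str, x: float) -> float:
    x = float(x)
    _require(math.isfinite(x), f"{name} must be finite, got {x!r}")
    _require(-1.0 <= x <= 1.0, f"{name} must lie in [-1, 1], got {x}")
    return x


def _check_proportion(name: str, x: float) -> float:
    x = float(x)
    _require(math.isfinite(x), f"{name} must be finite, got {x!r}")
    _require(0.0 <= x <= 1.0, f"{name} must lie in [0, 1], got {x}")
    return x


@dataclass(frozen=True)
class PollinatorBehavior:
    """Preference and constancy of one pollinator toward the focal plant.

    Both indices are dimensionless and restricted to [-1, 1]; construction
    outside those bounds raises :class:`DomainError`.
    """

    preference: float
    constancy: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "preference", _check_index("preference", self.preference))
        object.__setattr__(self, "constancy", _check_index("constancy", self.constancy))


class FlaggedValue(NamedTuple):
    """A numeric estimate paired with a validity flag.

    ``valid`` is False when the value falls outside its model range (sampling
    noise can push field estimates out of [-1, 1]); the value is reported as
    computed rather than clamped, so data problems stay visible.
    """

    value: float
    valid: bool

    def __float__(self) -> float:  # allows use in arithmetic
        return float(self.value)


def visit_proportion(f: float, rho: float) -> float:
    """Proportion ``psi`` of a pollinator's visits made to the focal plant.

        psi = f (1 + rho) / (1 + rho (2 f - 1))

    ``psi`` equals ``f`` for an indifferent pollinator (``rho = 0``), rises to
    1 as ``rho -> 1`` and falls to 0 as ``rho -> -1``; it is strictly
    increasing in ``rho`` at fixed ``f``.
    """
    f = _check_frequency(f)
    rho = _check_index("preference rho", rho)
    denom = 1.0 + rho * (2.0 * f - 1.0)
    # denom = (1-rho)(1-f) + f(1+rho) > 0 strictly for f in (0,1), rho in [-1,1]
    return f * (1.0 + rho) / denom


def preference_from_visits(psi: float, f: float) -> float:
    """Invert :func:`visit_proportion`: preference from an observed visit share.

        rho = (psi - f) / (f + psi - 2 f psi)

    Round-trips with :func:`visit_proportion` to numerical tolerance.  The
    denominator vanishes only at the degenerate corners (psi, f) -> (0, 0) or
    (1, 1), which the frequency domain already excludes.
    """
    psi = _check_proportion("visit proportion psi", psi)
    f = _check_frequency(f)
    denom = f + psi - 2.0 * f * psi
    _require(
        abs(denom) > _DENOM_TOL,
        f"preference undefined at the degenerate corner psi={psi}, f={f}",
    )
    return (psi - f) / denom


def constancy_from_movements(H: float, psi: float) -> FlaggedValue:
    """Constancy from observed heterospecific share and visit proportion.

        kappa = (1 - H - psi) / (1 - H + psi - 2 psi (1 - H))

    Returns a :class:`FlaggedValue`; the flag is False when the computed
    constancy falls outside [-1, 1], which can happen for observed (H, psi)
    pairs that no behavior in the model generates.

    Raises
    ------
    DomainError
        If the denominator vanishes, which occurs only at degenerate corners
        such as ``psi = 1, H = 0`` (every visit focal: order carries no
        information about constancy).
    """
    H = _check_proportion("heterospecific share H", H)
    psi = _check_proportion("visit proportion psi", psi)
    denom = (1.0 - H) + psi - 2.0 * psi * (1.0 - H)
    _require(
        abs(denom) > _DENOM_TOL,
        f"constancy undefined at the degenerate corner H={H}, psi={psi}",
    )
    kappa = (1.0 - H - psi) / denom
    return FlaggedValue(kappa, -1.0 <= kappa <= 1.0)


def heterospecific_share(f: float, rho: float, kappa: float) -> float:
    """Heterospecific share ``H`` predicted from behavior and plant frequency.

        H = -(f - 1)(rho - 1)(kappa - 1)
            / [1 + rho (2 f - 1) + kappa (2 f - 1) + kappa rho]

    ``H`` is the fraction of movements into the focal plant that arrive from a
    heterospecific plant.  With ``rho = kappa = 0`` it reduces to the random
    null ``H = 1 - f``.  Endpoint behaviors (``rho`` or ``kappa`` = +/-1) are
    evaluated as analytic limits where the limit is finite; the two corners
    ``(rho, kappa) = (1, -1)`` and ``(-1, 1)`` are genuinely indeterminate and
    raise :class:`DomainError`.
    """
    f = _check_frequency(f)
    rho = _check_index("preference rho", rho)
    kappa = _check_index("constancy kappa", kappa)
    num = -(f - 1.0) * (rho - 1.0) * (kappa - 1.0)
    denom = 1.0 + rho * (2.0 * f - 1.0) + kappa * (2.0 * f - 1.0) + kappa * rho
    _require(
        abs(denom) > _DENOM_TOL,
        "heterospecific share indeterminate at "
        f"f={f}, rho={rho}, kappa={kappa} (vanishing denominator)",
    )
    H = num / denom
    # the closed form stays in [0, 1] on the admissible domain; clip only
    # floating-point spill at the boundary
    return min(max(H, 0.0), 1.0)


def isolation_from_share(H: float, f: float) -> float:
    """Ethological RI from a heterospecific share and the focal frequency.

        RI = 1 - 2 H / (H + (1 - f))

    ``1 - f`` is the heterospecific share expected under random movement, so
    RI = 0 exactly when ``H = 1 - f``, RI = 1 when ``H = 0`` (no
    heterospecific movement), and RI -> -1 as movement becomes fully
    disassortative.
    """
    H = _check_proportion("heterospecific share H", H)
    f = _check_frequency(f)
    expected = 1.0 - f
    _require(H + expected > _DENOM_TOL, f"RI undefined: H + (1 - f) = 0 at f={f}")
    return 1.0 - 2.0 * H / (H + expected)


def isolation_one(f: float, rho: float, kappa: float) -> float:
    """Ethological RI of a single pollinator, in simplified closed form.

        RI = f (rho + kappa) / [1 + (rho + kappa)(f - 1) + rho kappa]

    Algebraically identical to composing :func:`heterospecific_share` with
    :func:`isolation_from_share`, and symmetric under exchange of ``rho`` and
    ``kappa``: preference and constancy have the same effect on RI.
    """
    f = _check_frequency(f)
    rho = _check_index("preference rho", rho)
    kappa = _check_index("constancy kappa", kappa)
    s = rho + kappa
    denom = 1.0 + s * (f - 1.0) + rho * kappa
    _require(
        abs(denom) > _DENOM_TOL,
        f"RI indeterminate at f={f}, rho={rho}, kappa={kappa} (vanishing denominator)",
    )
    RI = f * s / denom
    return min(max(RI, -1.0), 1.0)
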