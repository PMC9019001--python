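"""Sampled curves of heterospecific movement and RI along a swept variable.

The model's results are curve shapes: RI against focal-plant frequency ``f``
(hybrid-zone clines) or against the visit share ``phi_1`` of one of two
pollinators (changing pollinator communities).  :class:`RICurve` is the common
container; it writes and reads a headered CSV with columns
``grid_var,value,H,RI`` that round-trips exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .behavior import DomainError
from .community import (
    CommunityScenario,
    GuildMember,
    isolation_total,
    total_heterospecific_share,
)

__all__ = ["RICurve", "frequency_sweep", "visit_share_sweep"]

#: default open-interval guard for f sweeps (f = 0 and 1 are degenerate)
F_GRID_EDGE = 0.005
#: default number of grid points for either sweep
DEFAULT_GRID_SIZE = 201


@dataclass(frozen=True)
class RICurve:
    """H and RI sampled along a strictly ascending grid of one swept variable.

    ``swept_variable`` is ``"f"`` (focal-plant frequency) or ``"phi_1"``
    (visit share of pollinator 1 in a two-pollinator guild).
    """

    swept_variable: str
    grid: np.ndarray
    H: np.ndarray
    RI: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        H = np.asarray(self.H, dtype=float)
        RI = np.asarray(self.RI, dtype=float)
        if not (len(grid) == len(H) == len(RI)):
            raise ValueError("grid, H and RI must have equal length")
        if len(grid) and not np.all(np.diff(grid) > 0):
            raise ValueError("curve grid must be strictly ascending")
        if np.any(RI < -1.0) or np.any(RI > 1.0):
            raise ValueError("RI values must lie in [-1, 1]")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "H", H)
        object.__setattr__(self, "RI", RI)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "grid_var": self.swept_variable,
                "value": self.grid,
                "H": self.H,
                "RI": self.RI,
            }
        )

    def write_csv(self, path) -> None:
        """Write the curve as headered CSV with full float precision."""
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def read_csv(cls, path) -> "RICurve":
        df = pd.read_csv(path, float_precision="round_trip")
        missing = {"grid_var", "value", "H", "RI"} - set(df.columns)
        if missing:
            raise ValueError(f"curve file {path} lacks columns: {sorted(missing)}")
        names = df["grid_var"].unique()
        if len(names) != 1:
            raise ValueError(f"curve file {path} mixes swept variables: {names}")
        return cls(str(names[0]), df["value"].to_numpy(), df["H"].to_numpy(), df["RI"].to_numpy())


def _as_guild(guild: Sequence[GuildMember]) -> tuple[GuildMember, ...]:
    members = tuple(guild)
    if not members:
        raise DomainError("sweep needs a non-empty guild")
    return members


def frequency_sweep(
    guild: Sequence[GuildMember],
    grid: np.ndarray | None = None,
    *,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> RICurve:
    """H_tot and RI_tot across focal-plant frequencies for a fixed guild.

    The default grid spans ``(F_GRID_EDGE, 1 - F_GRID_EDGE)``, guarding the
    open endpoints where the community is monomorphic.
    """
    members = _as_guild(guild)
    fs = np.linspace(F_GRID_EDGE, 1.0 - F_GRID_EDGE, grid_size) if grid is None else np.asarray(grid, dtype=float)
    H = np.empty(len(fs))
    RI = np.empty(len(fs))
    for k, f in enumerate(fs):
        scenario = CommunityScenario(f, members)
        H[k] = total_heterospecific_share(scenario)
        RI[k] = isolation_total(scenario)
    return RICurve("f", fs, H, RI)


def visit_share_sweep(
    guild: Sequence[GuildMember],
    f: float,
    grid: np.ndarray | None = None,
    *,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> RICurve:
    """H_tot and RI_tot across the visit share of pollinator 1, at fixed ``f``.

    Requires exactly two guild members; their ``phi`` values are overridden by
    the swept ``phi_1`` (with ``phi_2 = 1 - phi_1``).  The endpoints
    ``phi_1 = 0`` and ``1`` are valid single-pollinator communities, so the
    default grid covers the closed interval [0, 1].
    """
    members = _as_guild(guild)
    if len(members) != 2:
        raise DomainError(
            f"visit-share sweep requires exactly 2 pollinators, got {len(members)}"
        )
    phis = np.linspace(0.0, 1.0, grid_size) if grid is None else np.asarray(grid, dtype=float)
    m1, m2 = members
    H = np.empty(len(phis))
    RI = np.empty(len(phis))
    for k, phi1 in enumerate(phis):
        scenario = CommunityScenario(
            f,
            (
                GuildMember(m1.rho, m1.kappa, phi1, m1.id),
                GuildMember(m2.rho, m2.kappa, 1.0 - phi1, m2.id),
            ),
        )
        H[k] = total_heterospecific_share(scenario)
        RI[k] = isolation_total(scenario)
    return RICurve("phi_1", phis, H, RI)
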