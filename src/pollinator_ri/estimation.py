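"""Estimate pollinator behavior from field visit-sequence observations.

The raw data are *bouts*: continuous observed foraging sequences of a single
pollinator, recorded as ordered plant visits.  From each pollinator's bouts we
count visits and within-bout transitions relative to the focal plant
(F = focal, O = any other plant, pooled), derive

    psi_hat = focal visits / total visits
    H_hat   = n_OF / (n_FF + n_OF)        (movements *into* the focal plant)

and invert the closed forms to estimate preference ``rho_hat`` and constancy
``kappa_hat``.  Visit shares ``phi_hat`` come from each pollinator's share of
all recorded visits.  Transitions are never counted across bout boundaries:
between-bout movements are unobserved gaps that carry no pollen information.

The focal-plant frequency ``f`` must be supplied from a plant census — it
cannot be inferred from visits, because the observed visit share confounds
frequency with preference.

Degenerate corners (for example no observed movement into the focal plant)
yield NaN estimates with their validity flag set False; nothing is fabricated
or clamped.  An optional ``correction`` adds a pseudo-count to each transition
cell (off by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .behavior import (
    DomainError,
    constancy_from_movements,
    preference_from_visits,
    _check_frequency,
)
from .community import GuildMember
from .curves import RICurve, frequency_sweep, visit_share_sweep

__all__ = [
    "ObservationError",
    "ObservationTable",
    "TransitionTally",
    "BehaviorEstimate",
    "read_observations",
    "tally",
    "estimate_behavior",
    "estimate_phi",
    "estimate_all",
    "project_ri",
]

REQUIRED_COLUMNS = ("bout_id", "pollinator_id", "visit_index", "plant_id")

#: pooled label for every non-focal plant
OTHER_LABEL = "other"


class ObservationError(ValueError):
    """Malformed observation data; the message names the offending bout."""


@dataclass(frozen=True)
class ObservationTable:
    """Validated bout-structured visit records.

    ``data`` holds columns bout_id, pollinator_id, visit_index, plant_id plus
    a derived boolean ``is_focal``.  Within each bout, visit_index runs
    1, 2, ..., length with no gaps or duplicates, and a bout belongs to exactly
    one pollinator.
    """

    data: pd.DataFrame
    focal_plant_id: str

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise ObservationError(f"observation table lacks columns: {missing}")
        df = df.copy()
        df["visit_index"] = pd.to_numeric(df["visit_index"], errors="raise").astype(int)
        ordered = df.sort_values(["bout_id", "visit_index"], kind="stable")
        expected = ordered.groupby("bout_id", sort=False).cumcount().to_numpy() + 1
        bad = ordered["visit_index"].to_numpy() != expected
        if bad.any():
            bout = ordered["bout_id"].to_numpy()[bad][0]
            idx = np.sort(df.loc[df["bout_id"] == bout, "visit_index"].to_numpy())
            raise ObservationError(
                f"bout {bout!r}: visit_index must be consecutive from 1 "
                f"without gaps or duplicates, got {idx.tolist()}"
            )
        per_bout = df.groupby("bout_id", sort=False)["pollinator_id"].nunique()
        if (per_bout > 1).any():
            bout = per_bout.index[per_bout > 1][0]
            who = sorted(df.loc[df["bout_id"] == bout, "pollinator_id"].unique())
            raise ObservationError(
                f"bout {bout!r} is attributed to multiple pollinators: {who}"
            )
        df = df.sort_values(["pollinator_id", "bout_id", "visit_index"], kind="stable")
        df["is_focal"] = df["plant_id"].astype(str) == str(self.focal_plant_id)
        object.__setattr__(self, "data", df.reset_index(drop=True))

    @property
    def n_bouts(self) -> int:
        return self.data["bout_id"].nunique()

    @property
    def n_visits(self) -> int:
        return len(self.data)

    def pollinators(self) -> list:
        return list(dict.fromkeys(self.data["pollinator_id"]))


def read_observations(path, focal_plant_id: str) -> ObservationTable:
    """Read a headered, comma-delimited observation file and validate it.

    Every plant id other than ``focal_plant_id`` is treated as the pooled
    heterospecific class.  A warning is raised when the focal plant never
    appears in the data (likely a mistyped id).
    """
    try:
        df = pd.read_csv(path, dtype={"bout_id": str, "pollinator_id": str, "plant_id": str})
    except (OSError, pd.errors.ParserError, UnicodeDecodeError) as exc:
        raise ObservationError(f"cannot parse observation file {path}: {exc}") from exc
    table = ObservationTable(df, focal_plant_id=str(focal_plant_id))
    if not table.data["is_focal"].any():
        warnings.warn(
            f"focal plant id {focal_plant_id!r} never occurs in {path}",
            stacklevel=2,
        )
    return table


class TransitionTally(NamedTuple):
    """Visit and within-bout transition counts for one pollinator.

    Transition cells are origin -> destination relative to the focal plant:
    n_FF (focal to focal), n_OF (other to focal), n_FO, n_OO.  Counts are
    floats so that exact expected (non-integer) tallies can flow through the
    same estimators.
    """

    n_visits_total: float
    n_visits_focal: float
    n_FF: float
    n_OF: float
    n_FO: float
    n_OO: float

    @property
    def n_transitions(self) -> float:
        return self.n_FF + self.n_OF + self.n_FO + self.n_OO


def tally(table: ObservationTable) -> dict:
    """Count visits and within-bout transitions per pollinator.

    Transitions are taken between consecutive visit indices of the same bout
    only; the last visit of one bout and the first of the next are never
    paired.  An empty table yields an empty mapping.
    """
    df = table.data  # sorted by (pollinator, bout, visit_index) at validation
    focal = df["is_focal"].to_numpy()
    bout = df["bout_id"].to_numpy()
    pid = df["pollinator_id"].to_numpy()

    same_bout = bout[:-1] == bout[1:] if len(df) else np.zeros(0, dtype=bool)
    origin = focal[:-1][same_bout]
    dest = focal[1:][same_bout]
    trans_pid = pid[1:][same_bout]
    trans = pd.DataFrame(
        {
            "pollinator_id": trans_pid,
            "n_FF": origin & dest,
            "n_OF": ~origin & dest,
            "n_FO": origin & ~dest,
            "n_OO": ~origin & ~dest,
        }
    )
    trans_counts = trans.groupby("pollinator_id", sort=False).sum()

    out: dict = {}
    for p, pgroup in df.groupby("pollinator_id", sort=False):
        if p in trans_counts.index:
            row = trans_counts.loc[p]
            cells = {k: float(row[k]) for k in ("n_FF", "n_OF", "n_FO", "n_OO")}
        else:
            cells = dict(n_FF=0.0, n_OF=0.0, n_FO=0.0, n_OO=0.0)
        out[p] = TransitionTally(
            n_visits_total=float(len(pgroup)),
            n_visits_focal=float(pgroup["is_focal"].sum()),
            **cells,
        )
    return out


@dataclass(frozen=True)
class BehaviorEstimate:
    """Per-pollinator behavioral estimates with validity flags.

    NaN marks an estimate that is undefined for the observed counts (flag
    False); a finite value with flag False fell outside the model range
    [-1, 1], which sampling noise can produce.
    """

    pollinator_id: str
    psi_hat: float
    H_hat: float
    rho_hat: float
    kappa_hat: float
    phi_hat: float = float("nan")
    psi_valid: bool = True
    H_valid: bool = True
    rho_valid: bool = True
    kappa_valid: bool = True

    @property
    def valid(self) -> bool:
        return self.psi_valid and self.H_valid and self.rho_valid and self.kappa_valid


def estimate_behavior(
    counts: TransitionTally,
    f: float,
    *,
    pollinator_id: str = "",
    correction: float = 0.0,
) -> BehaviorEstimate:
    """Estimate (psi, H, rho, kappa) for one pollinator from its tally.

    ``correction`` (default 0) is added to each of the four transition cells
    before forming ``H_hat``, a conventional continuity correction for
    zero-count corners; it is off by default so degenerate data stay visibly
    degenerate.
    """
    f = _check_frequency(f)
    if counts.n_visits_total <= 0:
        raise DomainError("cannot estimate behavior from zero visits")

    psi_hat = counts.n_visits_focal / counts.n_visits_total
    psi_valid = 0.0 <= psi_hat <= 1.0

    n_FF = counts.n_FF + correction
    n_OF = counts.n_OF + correction
    into_focal = n_FF + n_OF
    if into_focal > 0:
        H_hat = n_OF / into_focal
        H_valid = True
    else:
        H_hat, H_valid = float("nan"), False

    try:
        rho_hat = preference_from_visits(psi_hat, f)
        rho_valid = -1.0 <= rho_hat <= 1.0
    except DomainError:
        rho_hat, rho_valid = float("nan"), False

    if H_valid:
        try:
            kappa_hat, kappa_valid = constancy_from_movements(H_hat, psi_hat)
        except DomainError:
            kappa_hat, kappa_valid = float("nan"), False
    else:
        kappa_hat, kappa_valid = float("nan"), False

    return BehaviorEstimate(
        pollinator_id=str(pollinator_id),
        psi_hat=float(psi_hat),
        H_hat=float(H_hat),
        rho_hat=float(rho_hat),
        kappa_hat=float(kappa_hat),
        psi_valid=psi_valid,
        H_valid=H_valid,
        rho_valid=rho_valid,
        kappa_valid=kappa_valid,
    )


def estimate_phi(tallies: Mapping[str, TransitionTally]) -> dict:
    """Visit shares ``phi_hat_i`` from each pollinator's total visit count.

    A pollinator with zero visits keeps ``phi_hat = 0`` and triggers a
    warning rather than being dropped.
    """
    if not tallies:
        raise DomainError("cannot estimate visit shares without any pollinator")
    totals = {pid: counts.n_visits_total for pid, counts in tallies.items()}
    grand = sum(totals.values())
    if grand <= 0:
        raise DomainError("cannot estimate visit shares: no visits recorded")
    for pid, n in totals.items():
        if n == 0:
            warnings.warn(f"pollinator {pid!r} has zero visits; phi_hat = 0", stacklevel=2)
    return {pid: n / grand for pid, n in totals.items()}


def estimate_all(
    table: ObservationTable, f: float, *, correction: float = 0.0
) -> list[BehaviorEstimate]:
    """Tally an observation table and estimate every pollinator's behavior.

    Returns one :class:`BehaviorEstimate` per pollinator, with ``phi_hat``
    filled from the community visit totals.
    """
    tallies = tally(table)
    if not tallies:
        raise DomainError("observation table is empty")
    phis = estimate_phi(tallies)
    return [
        replace(
            estimate_behavior(counts, f, pollinator_id=pid, correction=correction),
            phi_hat=phis[pid],
        )
        for pid, counts in tallies.items()
    ]


def _guild_from_estimates(estimates: Sequence[BehaviorEstimate]) -> list[GuildMember]:
    usable = []
    for est in estimates:
        if not (est.rho_valid and est.kappa_valid):
            warnings.warn(
                f"pollinator {est.pollinator_id!r} has invalid estimates and is "
                "excluded from the projection",
                stacklevel=3,
            )
            continue
        usable.append(est)
    if not usable:
        raise DomainError("no pollinator with valid estimates to project")
    total_phi = sum(e.phi_hat for e in usable)
    if not total_phi > 0:
        raise DomainError("valid pollinators carry zero total visit share")
    return [
        GuildMember(e.rho_hat, e.kappa_hat, e.phi_hat / total_phi, e.pollinator_id)
        for e in usable
    ]


def project_ri(
    estimates: Sequence[BehaviorEstimate],
    *,
    sweep: str = "f",
    f: float | None = None,
    grid: np.ndarray | None = None,
    grid_size: int = 201,
) -> RICurve:
    """Project H and RI curves from estimated behaviors.

    ``sweep="f"`` holds the estimated guild fixed and sweeps the focal-plant
    frequency; ``sweep="phi"`` requires exactly two valid pollinators and
    sweeps pollinator 1's visit share at a fixed supplied ``f``.  Estimates
    with invalid flags are excluded with a warning; remaining visit shares are
    renormalized.
    """
    guild = _guild_from_estimates(estimates)
    if sweep == "f":
        return frequency_sweep(guild, grid, grid_size=grid_size)
    if sweep == "phi":
        if f is None:
            raise DomainError("a visit-share sweep needs the focal frequency f")
        return visit_share_sweep(guild, f, grid, grid_size=grid_size)
    raise DomainError(f"unknown sweep variable {sweep!r}; use 'f' or 'phi'")
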