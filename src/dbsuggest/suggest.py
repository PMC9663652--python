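"""Suggestion engine: effect thresholds, best level, best contact.

The effect threshold of a stimulation site is the current amplitude at
which the VTA/sweet-spot overlap reaches the desired overlap volume V_d.
Two search modes are provided:

* ``grid``: overlaps are evaluated on an ascending current grid (default
  1..8 mA in 1 mA steps), the grid point with overlap closest to V_d is
  taken as the initial estimate (ties toward the lower current), and the
  estimate is refined by linear interpolation between the bracketing grid
  nodes.  This is the only mode available to voxel engines, where each
  overlap evaluation costs a full VTA.
* ``continuous``: bisection for the smallest current whose overlap reaches
  V_d, to 0.01 mA, exploiting that the analytic overlap is non-decreasing
  in current for gamma < 1.  Default for the spheres engine.

Best level is the ring-mode site (4 levels) with the lowest estimated
threshold; best contact the same over the 8 physical contacts.  Exact ties
are preserved as sets so evaluation can score them as partially correct.
A V_d that is unattainable within the current ceiling yields an explicit
"not reached" rather than a silently clamped amplitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .desired_overlap import DesiredOverlapModel, desired_volume
from .engines import OverlapEngine
from .lead_model import ContactSpec, LeadGeometry, contact_distance
from .volumes import VoxelVolume, centroid

logger = logging.getLogger(__name__)

DEFAULT_GRID = tuple(float(i) for i in range(1, 9))  # 1..8 mA
BISECTION_TOL = 0.01  # mA
_TIE_TOL = 1e-9  # mA; threshold ties below this count as exact


@dataclass(frozen=True)
class ThresholdSearch:
    """Outcome of one site's effect-threshold search."""

    grid_currents: tuple[float, ...]
    overlaps: tuple[float, ...]
    initial_index: int | None  # index into grid_currents (0-based)
    estimate: float | None  # mA
    reached: bool


@dataclass(frozen=True)
class SiteSuggestion:
    contact_id: str
    level_index: int
    desired_volume: float  # mm^3
    estimate: float | None  # mA
    reached: bool
    search: ThresholdSearch | None = None


@dataclass(frozen=True)
class SuggestionResult:
    lead_id: str
    engine: str  # e.g. "ias_continuous", "field_grid"
    sites: tuple[SiteSuggestion, ...]
    best_level: frozenset[int] = frozenset()
    best_contact: frozenset[str] = frozenset()

    def site(self, contact_id: str) -> SiteSuggestion:
        for s in self.sites:
            if s.contact_id == contact_id:
                return s
        raise KeyError(contact_id)

    def to_dict(self) -> dict:
        return {
            "lead_id": self.lead_id,
            "engine": self.engine,
            "best_level": sorted(self.best_level),
            "best_contact": sorted(self.best_contact),
            "sites": [
                {
                    "contact_id": s.contact_id,
                    "level": s.level_index,
                    "desired_volume_mm3": s.desired_volume,
                    "estimate_mA": s.estimate,
                    "reached": s.reached,
                }
                for s in self.sites
            ],
        }


# ---------------------------------------------------------------------------
# threshold searches

def threshold_grid_search(
    overlap_fn: Callable[[float], float],
    vd: float,
    grid: Sequence[float] = DEFAULT_GRID,
) -> ThresholdSearch:
    """Grid search + linear-interpolation refinement for the effect threshold.

    The initial index minimizes |V(i) - V_d| (ties toward the lower
    current).  Underestimates interpolate toward the next node, an
    overestimate at the first node interpolates from (0 mA, 0 mm^3), and a
    flat bracketing segment degenerates to the node current.  ``reached``
    is False when V_d exceeds every grid overlap.
    """
    grid = tuple(float(g) for g in grid)
    if len(grid) == 0 or any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must be nonempty and strictly increasing")
    if vd <= 0:
        raise ValueError("desired volume must be > 0")
    V = tuple(float(overlap_fn(I)) for I in grid)
    reached = max(V) >= vd
    i = int(np.argmin([abs(v - vd) for v in V]))  # argmin takes the first = lower current
    if not reached:
        return ThresholdSearch(grid, V, i, None, False)

    if V[i] == vd:
        est = grid[i]
    elif V[i] < vd:
        if i + 1 >= len(grid):  # non-monotone edge case: nearest node is last
            est = grid[i]
        else:
            est = _interpolate(grid[i], V[i], grid[i + 1], V[i + 1], vd)
    else:
        if i == 0:
            est = _interpolate(0.0, 0.0, grid[0], V[0], vd)
        else:
            est = _interpolate(grid[i - 1], V[i - 1], grid[i], V[i], vd)
    return ThresholdSearch(grid, V, i, est, True)


def _interpolate(i_a: float, v_a: float, i_b: float, v_b: float, vd: float) -> float:
    if v_b == v_a:
        logger.warning("degenerate interpolation (flat overlap segment); using node current")
        return i_b
    return i_a + (vd - v_a) * (i_b - i_a) / (v_b - v_a)


def threshold_continuous(
    overlap_fn: Callable[[float], float],
    vd: float,
    i_max: float = 8.0,
    tol: float = BISECTION_TOL,
) -> ThresholdSearch:
    """Smallest current with overlap >= V_d, by bisection to ``tol`` mA."""
    if vd <= 0:
        raise ValueError("desired volume must be > 0")
    if i_max <= 0:
        raise ValueError("i_max must be > 0")
    if overlap_fn(i_max) < vd:
        return ThresholdSearch((i_max,), (float(overlap_fn(i_max)),), None, None, False)
    lo, hi = 0.0, float(i_max)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if overlap_fn(mid) >= vd:
            hi = mid
        else:
            lo = mid
    return ThresholdSearch((), (), None, hi, True)


# ---------------------------------------------------------------------------
# per-lead suggestions

def _solve_site(
    contact: ContactSpec,
    engine: OverlapEngine,
    vd_model: DesiredOverlapModel,
    mode: str,
    grid: Sequence[float],
    i_max: float,
) -> SiteSuggestion:
    vd = desired_volume(vd_model, engine.distance(contact), engine.sweetspot_volume)
    fn = lambda I: engine.overlap(contact, I)
    if mode == "continuous":
        search = threshold_continuous(fn, vd, i_max=i_max)
    elif mode == "grid":
        search = threshold_grid_search(fn, vd, grid=grid)
    else:
        raise ValueError(f"unknown search mode {mode!r}")
    return SiteSuggestion(
        contact_id=contact.contact_id,
        level_index=contact.level_index,
        desired_volume=vd,
        estimate=search.estimate,
        reached=search.reached,
        search=search,
    )


def _argmin_sites(sites: Sequence[SiteSuggestion]) -> list[SiteSuggestion]:
    reached = [s for s in sites if s.reached and s.estimate is not None]
    if not reached:
        return []
    best = min(s.estimate for s in reached)
    return [s for s in reached if abs(s.estimate - best) <= _TIE_TOL]


def _default_mode(engine: OverlapEngine, mode: str | None) -> str:
    if mode is not None:
        return mode
    return "continuous" if engine.supports_continuous else "grid"


def suggest_thresholds(
    lead: LeadGeometry,
    engine: OverlapEngine,
    vd_model: DesiredOverlapModel,
    mode: str | None = None,
    grid: Sequence[float] = DEFAULT_GRID,
    i_max: float = 8.0,
) -> SuggestionResult:
    """Effect-threshold estimates for all selectable sites (8 contacts +
    2 ring-mode sites)."""
    mode = _default_mode(engine, mode)
    sites = tuple(
        _solve_site(c, engine, vd_model, mode, grid, i_max) for c in lead.contacts
    )
    return SuggestionResult(lead.lead_id, f"{engine.name}_{mode}", sites)


def suggest_best_level(
    lead: LeadGeometry,
    engine: OverlapEngine,
    vd_model: DesiredOverlapModel,
    mode: str | None = None,
    grid: Sequence[float] = DEFAULT_GRID,
    i_max: float = 8.0,
) -> SuggestionResult:
    """Best lead level: lowest ring-mode effect threshold over the 4 levels."""
    mode = _default_mode(engine, mode)
    sites = tuple(
        _solve_site(c, engine, vd_model, mode, grid, i_max) for c in lead.ring_sites
    )
    best = _argmin_sites(sites)
    if not best:
        logger.warning(
            "lead %s: desired overlap unreachable on all levels within %.1f mA",
            lead.lead_id,
            i_max,
        )
    return SuggestionResult(
        lead.lead_id,
        f"{engine.name}_{mode}",
        sites,
        best_level=frozenset(s.level_index for s in best),
    )


def suggest_best_contact(
    lead: LeadGeometry,
    engine: OverlapEngine,
    vd_model: DesiredOverlapModel,
    mode: str | None = None,
    grid: Sequence[float] = DEFAULT_GRID,
    i_max: float = 8.0,
    shortlist: int | None = None,
) -> SuggestionResult:
    """Best contact: lowest effect threshold over the 8 physical contacts.

    ``shortlist`` restricts the search to the k contacts nearest the
    sweet-spot center (used with expensive voxel engines).
    """
    mode = _default_mode(engine, mode)
    contacts = lead.physical_contacts
    if shortlist is not None:
        contacts = tuple(
            shortlist_contacts(lead, engine.sweetspot_center, k=shortlist)
        )
    sites = tuple(
        _solve_site(c, engine, vd_model, mode, grid, i_max) for c in contacts
    )
    best = _argmin_sites(sites)
    if not best:
        logger.warning(
            "lead %s: desired overlap unreachable on all contacts within %.1f mA",
            lead.lead_id,
            i_max,
        )
    return SuggestionResult(
        lead.lead_id,
        f"{engine.name}_{mode}",
        sites,
        best_contact=frozenset(s.contact_id for s in best),
    )


def shortlist_contacts(
    lead: LeadGeometry, sweetspot_center, k: int = 3
) -> list[ContactSpec]:
    """The k physical contacts nearest the sweet-spot center.

    Distance ties are broken by position in the contact list (ascending
    contact index).
    """
    contacts = lead.physical_contacts
    if k > len(contacts):
        raise ValueError(f"k={k} exceeds the {len(contacts)} physical contacts")
    order = sorted(
        range(len(contacts)),
        key=lambda i: (contact_distance(contacts[i], sweetspot_center), i),
    )
    return [contacts[i] for i in order[:k]]


def reconstruction_guided(
    lead: LeadGeometry, stn_mask: VoxelVolume
) -> tuple[frozenset[int], frozenset[str]]:
    """Baseline suggestion from lead position alone: the level center and the
    contact nearest the STN centroid.  Distance ties break toward the lower
    level / earlier contact.
    """
    c = centroid(stn_mask)  # raises on an empty mask
    level_d = np.linalg.norm(lead.level_centers - c, axis=1)
    best_level = int(np.argmin(level_d)) + 1  # argmin -> lowest index on ties
    contacts = lead.physical_contacts
    dists = [contact_distance(ct, c) for ct in contacts]
    best_contact = contacts[int(np.argmin(dists))].contact_id
    return frozenset({best_level}), frozenset({best_contact})
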