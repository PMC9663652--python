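"""Instant analytical spheres (IAS): the closed-form VTA overlap model.

The volume of tissue activated (VTA) around a stimulating contact and the
sweet spot are both approximated as spheres, which turns the VTA/sweet-spot
overlap into an algebraic spherical-lens formula and makes effect-threshold
estimation essentially instantaneous.

Three pieces:

* a zero-intercept quadratic transform between stimulation current ``I``
  (mA) and VTA radius ``r`` (mm), ``I = a1 r + a2 r^2`` with empirical
  defaults ``a1 = 0.43``, ``a2 = 0.36`` — invertible in closed form;
* a placement rule for the VTA center: an omnidirectional (or ring-mode)
  VTA stays at the lead-level center, while a directional VTA drifts
  radially outward along the segment direction by ``gamma * r`` (default
  ``gamma = 0.1``), reflecting that directional fields reach further out of
  the lead body at higher amplitudes;
* the sphere-sphere overlap volume, completed analytically for the disjoint
  and containment cases the lens formula does not cover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.optimize

from .lead_model import ContactSpec, DIRECTIONAL

_FOUR_THIRDS_PI = 4.0 * math.pi / 3.0


@dataclass(frozen=True)
class Sphere:
    """A sphere in world mm; models both VTAs and the sweet-spot ball."""

    center: np.ndarray
    radius: float

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        object.__setattr__(self, "radius", float(self.radius))
        if self.center.shape != (3,) or not np.all(np.isfinite(self.center)):
            raise ValueError("center must be a finite 3-vector")
        if not (self.radius >= 0):
            raise ValueError("radius must be >= 0")

    @property
    def volume(self) -> float:
        return _FOUR_THIRDS_PI * self.radius**3


@dataclass(frozen=True)
class CurrentRadiusTransform:
    """Zero-intercept quadratic current<->radius transform ``I = a1 r + a2 r^2``."""

    a1: float = 0.43  # mA per mm
    a2: float = 0.36  # mA per mm^2

    def __post_init__(self):
        if self.a1 < 0 or self.a2 <= 0:
            raise ValueError("require a1 >= 0 and a2 > 0 for strict monotonicity")


@dataclass(frozen=True)
class PlacementModel:
    """Radial drift of a directional VTA center: displacement = gamma * radius."""

    gamma: float = 0.1

    def __post_init__(self):
        if not (0.0 <= self.gamma < 1.0):
            raise ValueError("gamma must be in [0, 1) to keep overlap monotone in current")


def radius_to_current(transform: CurrentRadiusTransform, radius: float) -> float:
    """Current amplitude (mA) producing a VTA of the given radius (mm)."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    return transform.a1 * radius + transform.a2 * radius**2


def current_to_radius(transform: CurrentRadiusTransform, current: float) -> float:
    """VTA radius (mm) at a current amplitude (mA); exact quadratic inverse."""
    if current < 0:
        raise ValueError("current must be >= 0")
    a1, a2 = transform.a1, transform.a2
    return (-a1 + math.sqrt(a1 * a1 + 4.0 * a2 * current)) / (2.0 * a2)


def place_vta(
    contact: ContactSpec,
    current: float,
    transform: CurrentRadiusTransform | None = None,
    placement: PlacementModel | None = None,
) -> Sphere:
    """VTA sphere for a contact at a given current amplitude.

    Directional contacts: center = ``p_e + gamma * unit(p_e - p_c) * r``.
    Omnidirectional and ring-mode contacts: center fixed at the level center.
    """
    transform = transform or CurrentRadiusTransform()
    placement = placement or PlacementModel()
    r = current_to_radius(transform, current)
    if contact.kind == DIRECTIONAL:
        u = contact.segment_direction  # raises if p_e == p_c
        center = contact.p_e + placement.gamma * u * r
    else:
        center = contact.p_c
    return Sphere(center=center, radius=r)


def sphere_overlap(r_ss: float, d: float, r_vta: float) -> float:
    """Overlap volume (mm^3) of two spheres of radii ``r_ss``/``r_vta`` at
    center distance ``d``.

    The lens formula applies when the spheres properly intersect
    (``|r_vta - r_ss| <= d <= r_vta + r_ss``); disjoint and containment
    configurations are completed analytically (zero / full smaller-sphere
    volume) so root finding over current amplitude is well defined
    everywhere.
    """
    if r_ss < 0 or d < 0 or r_vta < 0:
        raise ValueError("radii and distance must be >= 0")
    if r_ss == 0.0 or r_vta == 0.0:
        return 0.0
    if d >= r_vta + r_ss:
        return 0.0
    if d <= r_vta - r_ss:  # sweet spot entirely inside the VTA
        return _FOUR_THIRDS_PI * r_ss**3
    if d <= r_ss - r_vta:  # VTA entirely inside the sweet spot
        return _FOUR_THIRDS_PI * r_vta**3
    # proper lens; d > 0 here because d = 0 is caught by containment above
    s = r_vta + r_ss
    return (
        math.pi
        / (12.0 * d)
        * (s - d) ** 2
        * (d * d + 2.0 * d * s - 3.0 * (r_vta - r_ss) ** 2)
    )


def overlap_at_current(
    contact: ContactSpec,
    current: float,
    sweetspot_sphere: Sphere,
    transform: CurrentRadiusTransform | None = None,
    placement: PlacementModel | None = None,
) -> float:
    """VTA/sweet-spot overlap volume (mm^3) at a current amplitude (mA)."""
    transform = transform or CurrentRadiusTransform()
    placement = placement or PlacementModel()
    vta = place_vta(contact, current, transform, placement)
    d = float(np.linalg.norm(vta.center - sweetspot_sphere.center))
    return sphere_overlap(sweetspot_sphere.radius, d, vta.radius)


def fit_transform(
    samples: Sequence[tuple[float, float]],
) -> tuple[CurrentRadiusTransform, float]:
    """Refit the current<->radius transform from (current mA, radius mm) pairs.

    Least-squares fit of ``I`` on ``(r, r^2)`` with the intercept pinned at
    zero, as used to calibrate the transform against a field-model VTA sweep
    (0.6-10 mA in 0.1 mA steps in the reference procedure).  Returns the
    transform and the coefficient of determination R^2.
    """
    samples = list(samples)
    if len(samples) < 3:
        raise ValueError("need at least 3 (current, radius) samples")
    I = np.array([s[0] for s in samples], dtype=float)
    r = np.array([s[1] for s in samples], dtype=float)
    if np.any(r <= 0):
        raise ValueError("radii must be positive")
    X = np.column_stack([r, r**2])
    if np.linalg.matrix_rank(X) < 2:
        raise ValueError("rank-deficient design: radii do not span a quadratic")
    # constrained to the transform's valid parameter space (a1, a2 >= 0);
    # unconstrained data that satisfy the constraints are recovered exactly
    coef, _ = scipy.optimize.nnls(X, I)
    if coef[1] <= 0:
        raise ValueError("fit gave a2 <= 0; samples do not define a convex transform")
    resid = I - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((I - I.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return CurrentRadiusTransform(a1=float(coef[0]), a2=float(coef[1])), r2
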