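"""Directional DBS lead geometry.

Represents an 8-contact directional lead (e.g. Boston Scientific Vercise
Cartesia): one omnidirectional ring contact on the most distal and most
proximal levels, and three 120-degree segmented contacts on each of the two
middle levels.  Ring-mode stimulation of a segmented level (all three
segments driven together) is modelled as an explicit virtual contact sitting
at the level center, so the suggestion engine can treat every selectable
stimulation site uniformly.

All coordinates are world millimetres (MNI space); voxel indices never cross
this module's boundary.  For each contact we track two points: ``p_e``, the
center of the contact's conducting surface, and ``p_c``, the center of the
lead level it belongs to.  For omnidirectional and ring-mode contacts the two
coincide; for a directional segment ``p_e - p_c`` points radially out of the
lead body and defines the steering direction.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

OMNIDIRECTIONAL = "omnidirectional"
DIRECTIONAL = "directional"
RING_VIRTUAL = "ring_virtual"

#: levels (1 = most distal) holding a single ring contact vs three segments
_RING_LEVELS = (1, 4)
_SEGMENTED_LEVELS = (2, 3)

_ANGLE_TOL_DEG = 1.0
_GEOM_TOL = 1e-6


class LeadValidationError(ValueError):
    """Raised when a lead record violates the directional-lead layout."""


@dataclass(frozen=True)
class ContactSpec:
    """One selectable stimulation site on a lead."""

    contact_id: str
    level_index: int
    kind: str  # omnidirectional | directional | ring_virtual
    p_e: np.ndarray  # center of the contact surface, mm
    p_c: np.ndarray  # center of the contact's lead level, mm

    def __post_init__(self):
        object.__setattr__(self, "p_e", np.asarray(self.p_e, dtype=float))
        object.__setattr__(self, "p_c", np.asarray(self.p_c, dtype=float))
        if self.p_e.shape != (3,) or self.p_c.shape != (3,):
            raise LeadValidationError(
                f"contact {self.contact_id}: p_e/p_c must be 3-vectors"
            )
        if not (np.all(np.isfinite(self.p_e)) and np.all(np.isfinite(self.p_c))):
            raise LeadValidationError(f"contact {self.contact_id}: non-finite coordinates")
        if self.kind not in (OMNIDIRECTIONAL, DIRECTIONAL, RING_VIRTUAL):
            raise LeadValidationError(f"contact {self.contact_id}: unknown kind {self.kind!r}")
        offset = float(np.linalg.norm(self.p_e - self.p_c))
        if self.kind == DIRECTIONAL:
            if offset <= 0.0:
                raise LeadValidationError(
                    f"directional contact {self.contact_id} has p_e == p_c"
                )
        elif offset > _GEOM_TOL:
            raise LeadValidationError(
                f"{self.kind} contact {self.contact_id} must have p_e == p_c "
                f"(offset {offset:g} mm)"
            )

    @property
    def segment_direction(self) -> np.ndarray:
        """Unit vector from the level center through the segment surface."""
        if self.kind != DIRECTIONAL:
            raise ValueError(f"contact {self.contact_id} is not directional")
        v = self.p_e - self.p_c
        return v / np.linalg.norm(v)


@dataclass(frozen=True)
class LeadTemplate:
    """Manufacturer-style geometry used to build synthetic leads.

    Defaults follow standard 1-3-3-1 directional-lead dimensions: 1.5 mm
    contacts with 0.5 mm spacers (2.0 mm center-to-center) on a 1.3 mm
    diameter body.
    """

    contact_length: float = 1.5  # mm
    inter_level_spacing: float = 0.5  # mm gap between contacts
    lead_radius: float = 0.65  # mm
    segment_azimuths: tuple[float, float, float] = (0.0, 120.0, 240.0)  # degrees

    def __post_init__(self):
        if min(self.contact_length, self.inter_level_spacing, self.lead_radius) <= 0:
            raise ValueError("template lengths must be positive")
        az = np.sort(np.mod(self.segment_azimuths, 360.0))
        gaps = np.diff(np.concatenate([az, [az[0] + 360.0]]))
        if not np.allclose(gaps, 120.0, atol=_ANGLE_TOL_DEG):
            raise ValueError("segment azimuths must be 120 degrees apart")

    @property
    def level_pitch(self) -> float:
        """Center-to-center distance between consecutive levels, mm."""
        return self.contact_length + self.inter_level_spacing


@dataclass(frozen=True)
class LeadGeometry:
    """A validated 8-contact directional lead plus ring-mode virtual sites."""

    lead_id: str
    hemisphere: str  # left | right
    contacts: tuple[ContactSpec, ...]  # 8 physical + 2 ring_virtual
    level_centers: np.ndarray  # (4, 3) mm, index 0 = level 1 = most distal
    axis_direction: np.ndarray  # unit vector, distal -> proximal

    def __post_init__(self):
        object.__setattr__(
            self, "level_centers", np.asarray(self.level_centers, dtype=float)
        )
        object.__setattr__(
            self, "axis_direction", np.asarray(self.axis_direction, dtype=float)
        )
        _validate_lead(self)

    # -- selectors ---------------------------------------------------------
    @property
    def physical_contacts(self) -> tuple[ContactSpec, ...]:
        return tuple(c for c in self.contacts if c.kind != RING_VIRTUAL)

    @property
    def ring_sites(self) -> tuple[ContactSpec, ...]:
        """One omnidirectional site per level (levels 1..4 in order)."""
        per_level = {}
        for c in self.contacts:
            if c.kind in (OMNIDIRECTIONAL, RING_VIRTUAL):
                per_level[c.level_index] = c
        return tuple(per_level[i] for i in sorted(per_level))

    def contact(self, contact_id: str) -> ContactSpec:
        for c in self.contacts:
            if c.contact_id == contact_id:
                return c
        raise KeyError(f"lead {self.lead_id}: no contact {contact_id!r}")

    def level_of(self, contact_id: str) -> int:
        return self.contact(contact_id).level_index


def _validate_lead(lead: LeadGeometry) -> None:
    if lead.hemisphere not in ("left", "right"):
        raise LeadValidationError(f"hemisphere must be left/right, got {lead.hemisphere!r}")
    phys = lead.physical_contacts
    if len(phys) != 8:
        raise LeadValidationError(
            f"lead {lead.lead_id}: expected 8 physical contacts, got {len(phys)}"
        )
    if lead.level_centers.shape != (4, 3):
        raise LeadValidationError("level_centers must be 4 x 3")
    axis = lead.axis_direction
    n = np.linalg.norm(axis)
    if not math.isclose(n, 1.0, rel_tol=0, abs_tol=1e-6):
        raise LeadValidationError("axis_direction must be a unit vector")

    by_level: dict[int, list[ContactSpec]] = {}
    for c in phys:
        by_level.setdefault(c.level_index, []).append(c)
    for lvl in _RING_LEVELS:
        cs = by_level.get(lvl, [])
        if len(cs) != 1 or cs[0].kind != OMNIDIRECTIONAL:
            raise LeadValidationError(
                f"level {lvl} must hold exactly one omnidirectional contact"
            )
    for lvl in _SEGMENTED_LEVELS:
        cs = by_level.get(lvl, [])
        if len(cs) != 3 or any(c.kind != DIRECTIONAL for c in cs):
            raise LeadValidationError(
                f"level {lvl} must hold exactly three directional contacts"
            )
        dirs = [c.segment_direction for c in cs]
        for d in dirs:
            if abs(float(np.dot(d, axis))) > math.sin(math.radians(_ANGLE_TOL_DEG)):
                raise LeadValidationError(
                    f"level {lvl}: segment direction not orthogonal to lead axis"
                )
        for i in range(3):
            for j in range(i + 1, 3):
                ang = math.degrees(
                    math.acos(float(np.clip(np.dot(dirs[i], dirs[j]), -1.0, 1.0)))
                )
                if abs(ang - 120.0) > _ANGLE_TOL_DEG:
                    raise LeadValidationError(
                        f"level {lvl}: segments {ang:.2f} degrees apart, expected 120"
                    )
    # consecutive level centers equally spaced along the axis
    steps = np.diff(lead.level_centers, axis=0)
    pitches = steps @ axis
    if np.ptp(pitches) > _GEOM_TOL or np.any(pitches <= 0):
        raise LeadValidationError("level centers not equally spaced along the axis")
    off_axis = steps - np.outer(pitches, axis)
    if np.max(np.abs(off_axis)) > _GEOM_TOL:
        raise LeadValidationError("level centers not collinear with axis_direction")


# ---------------------------------------------------------------------------
# construction

def _ring_virtual_contacts(level_centers: np.ndarray) -> list[ContactSpec]:
    out = []
    for lvl in _SEGMENTED_LEVELS:
        c = level_centers[lvl - 1]
        out.append(
            ContactSpec(
                contact_id=f"ring{lvl}",
                level_index=lvl,
                kind=RING_VIRTUAL,
                p_e=c,
                p_c=c,
            )
        )
    return out


def build_lead(
    tip_position: Sequence[float],
    axis_direction: Sequence[float],
    roll_angle: float = 0.0,
    template: LeadTemplate | None = None,
    lead_id: str = "lead",
    hemisphere: str = "right",
) -> LeadGeometry:
    """Construct an ideal lead from a trajectory parameterization.

    ``tip_position`` is the distal tip of the electrode body; the first level
    center sits half a contact length above it.  ``roll_angle`` rotates the
    three segment azimuths about the lead axis (degrees, right-handed about
    ``axis_direction``).
    """
    template = template or LeadTemplate()
    tip = np.asarray(tip_position, dtype=float)
    axis = np.asarray(axis_direction, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0 or not np.all(np.isfinite(axis)):
        raise ValueError("axis_direction must be a nonzero finite vector")
    axis = axis / n

    # orthonormal frame (u, v, axis); reference azimuth 0 along u
    u = np.cross(axis, [0.0, 0.0, 1.0])
    if np.linalg.norm(u) < 1e-8:
        u = np.cross(axis, [0.0, 1.0, 0.0])
    u = u / np.linalg.norm(u)
    v = np.cross(axis, u)

    pitch = template.level_pitch
    base = template.contact_length / 2.0
    level_centers = np.array([tip + (base + i * pitch) * axis for i in range(4)])

    contacts: list[ContactSpec] = [
        ContactSpec("1", 1, OMNIDIRECTIONAL, level_centers[0], level_centers[0])
    ]
    next_id = 2
    for lvl in _SEGMENTED_LEVELS:
        pc = level_centers[lvl - 1]
        for az in template.segment_azimuths:
            phi = math.radians(az + roll_angle)
            radial = math.cos(phi) * u + math.sin(phi) * v
            pe = pc + template.lead_radius * radial
            contacts.append(ContactSpec(str(next_id), lvl, DIRECTIONAL, pe, pc))
            next_id += 1
    contacts.append(
        ContactSpec(str(next_id), 4, OMNIDIRECTIONAL, level_centers[3], level_centers[3])
    )
    contacts.extend(_ring_virtual_contacts(level_centers))

    return LeadGeometry(
        lead_id=lead_id,
        hemisphere=hemisphere,
        contacts=tuple(contacts),
        level_centers=level_centers,
        axis_direction=axis,
    )


def transform_lead(lead: LeadGeometry, rotation: np.ndarray, translation: Sequence[float]) -> LeadGeometry:
    """Apply a rigid transform (rotation then translation) to a whole lead."""
    R = np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
        raise ValueError("rotation must be a 3x3 orthogonal matrix")
    contacts = tuple(
        replace(c, p_e=R @ c.p_e + t, p_c=R @ c.p_c + t) for c in lead.contacts
    )
    return LeadGeometry(
        lead_id=lead.lead_id,
        hemisphere=lead.hemisphere,
        contacts=contacts,
        level_centers=(lead.level_centers @ R.T) + t,
        axis_direction=R @ lead.axis_direction,
    )


# ---------------------------------------------------------------------------
# JSON reconstruction records

_KNOWN_RECORD_FIELDS = {"lead_id", "hemisphere", "contacts", "axis_direction"}
_KNOWN_CONTACT_FIELDS = {"id", "level", "kind", "p_e_mm", "p_c_mm"}


def load_lead(record: dict) -> LeadGeometry:
    """Build a :class:`LeadGeometry` from a reconstruction record (dict).

    The record lists the 8 physical contacts; ring-mode virtual contacts for
    the two segmented levels are synthesized here.  Unknown fields are
    ignored with a warning so records from richer pipelines still load.
    """
    if not isinstance(record, dict):
        raise LeadValidationError("lead record must be a JSON object")
    unknown = set(record) - _KNOWN_RECORD_FIELDS
    if unknown:
        logger.warning("lead record: ignoring unknown fields %s", sorted(unknown))
    try:
        lead_id = str(record["lead_id"])
        hemisphere = str(record["hemisphere"])
        raw_contacts = record["contacts"]
        axis = np.asarray(record["axis_direction"], dtype=float)
    except KeyError as e:
        raise LeadValidationError(f"lead record missing field {e.args[0]!r}") from None

    if not np.all(np.isfinite(axis)):
        raise LeadValidationError("axis_direction must be finite")
    n = np.linalg.norm(axis)
    if n == 0:
        raise LeadValidationError("axis_direction must be nonzero")
    axis = axis / n

    contacts: list[ContactSpec] = []
    for raw in raw_contacts:
        unknown = set(raw) - _KNOWN_CONTACT_FIELDS
        if unknown:
            logger.warning("contact record: ignoring unknown fields %s", sorted(unknown))
        try:
            contacts.append(
                ContactSpec(
                    contact_id=str(raw["id"]),
                    level_index=int(raw["level"]),
                    kind=str(raw["kind"]),
                    p_e=np.asarray(raw["p_e_mm"], dtype=float),
                    p_c=np.asarray(raw["p_c_mm"], dtype=float),
                )
            )
        except KeyError as e:
            raise LeadValidationError(f"contact record missing field {e.args[0]!r}") from None
    if any(c.kind == RING_VIRTUAL for c in contacts):
        raise LeadValidationError("records must list physical contacts only")

    level_centers = np.zeros((4, 3))
    for lvl in range(1, 5):
        pcs = [c.p_c for c in contacts if c.level_index == lvl]
        if not pcs:
            raise LeadValidationError(f"no contacts on level {lvl}")
        level_centers[lvl - 1] = np.mean(pcs, axis=0)
    contacts.extend(_ring_virtual_contacts(level_centers))

    return LeadGeometry(
        lead_id=lead_id,
        hemisphere=hemisphere,
        contacts=tuple(contacts),
        level_centers=level_centers,
        axis_direction=axis,
    )


def lead_to_record(lead: LeadGeometry) -> dict:
    """Serialize the physical contacts back to the reconstruction schema."""
    return {
        "lead_id": lead.lead_id,
        "hemisphere": lead.hemisphere,
        "contacts": [
            {
                "id": c.contact_id,
                "level": c.level_index,
                "kind": c.kind,
                "p_e_mm": [float(x) for x in c.p_e],
                "p_c_mm": [float(x) for x in c.p_c],
            }
            for c in lead.physical_contacts
        ],
        "axis_direction": [float(x) for x in lead.axis_direction],
    }


def save_lead(lead: LeadGeometry, path) -> None:
    with open(path, "w") as fh:
        json.dump(lead_to_record(lead), fh, indent=1)


def load_lead_file(path) -> LeadGeometry:
    with open(path) as fh:
        return load_lead(json.load(fh))


def contact_distance(contact: ContactSpec, point: Sequence[float]) -> float:
    """Euclidean distance (mm) from the contact surface center to a point.

    Ring-mode and omnidirectional contacts measure from the level center,
    which by construction equals their ``p_e``.
    """
    p = np.asarray(point, dtype=float)
    if not np.all(np.isfinite(p)):
        raise ValueError("point must be finite")
    return float(np.linalg.norm(contact.p_e - p))
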