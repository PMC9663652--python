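"""Overlap engines: one callable surface over the two VTA models.

An engine answers one question — "what is the VTA/sweet-spot overlap volume
for this contact at this current?" — either analytically (instant analytical
spheres) or by voxel counting (point-source field stand-in).  The suggestion
searches are written against this surface only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import spheres
from .field import FieldModelConfig, estimate_vta_mask
from .lead_model import ContactSpec, contact_distance
from .spheres import CurrentRadiusTransform, PlacementModel, Sphere
from .volumes import SweetSpot, VoxelVolume, voxel_overlap_volume


class OverlapEngine:
    """Protocol: subclasses provide ``overlap`` and identifying ``name``."""

    name: str
    supports_continuous: bool

    def overlap(self, contact: ContactSpec, current: float) -> float:
        raise NotImplementedError

    @property
    def sweetspot_volume(self) -> float:
        raise NotImplementedError

    @property
    def sweetspot_center(self) -> np.ndarray:
        raise NotImplementedError

    def distance(self, contact: ContactSpec) -> float:
        return contact_distance(contact, self.sweetspot_center)


@dataclass
class IASEngine(OverlapEngine):
    """Instant-analytical-spheres overlap: closed form, supports bisection."""

    sweetspot_sphere: Sphere
    transform: CurrentRadiusTransform = field(default_factory=CurrentRadiusTransform)
    placement: PlacementModel = field(default_factory=PlacementModel)
    name: str = "ias"
    supports_continuous: bool = True

    def overlap(self, contact: ContactSpec, current: float) -> float:
        return spheres.overlap_at_current(
            contact, current, self.sweetspot_sphere, self.transform, self.placement
        )

    @property
    def sweetspot_volume(self) -> float:
        return self.sweetspot_sphere.volume

    @property
    def sweetspot_center(self) -> np.ndarray:
        return self.sweetspot_sphere.center

    @classmethod
    def from_sweetspot(cls, sweetspot: SweetSpot, **kwargs) -> "IASEngine":
        return cls(sweetspot_sphere=sweetspot.sphere, **kwargs)


@dataclass
class FieldEngine(OverlapEngine):
    """Voxel overlap between the point-source VTA mask and the sweet-spot mask."""

    sweetspot: SweetSpot
    config: FieldModelConfig = field(default_factory=FieldModelConfig)
    name: str = "field"
    supports_continuous: bool = False

    def overlap(self, contact: ContactSpec, current: float) -> float:
        mask = estimate_vta_mask(
            contact, current, self.sweetspot.volume_image, self.config
        )
        return voxel_overlap_volume(mask, self.sweetspot.volume_image)

    @property
    def sweetspot_volume(self) -> float:
        return self.sweetspot.total_volume

    @property
    def sweetspot_center(self) -> np.ndarray:
        return self.sweetspot.center_mm
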