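"""Voxel-grid VTA estimator from a point-source field model.

A deliberately simple electric-field model: the contact is treated as a
point current source in an infinite homogeneous gray-matter medium, so the
field magnitude at distance ``r`` is ``E = I / (4 pi sigma r^2)`` and the
binarized VTA (|E| >= threshold) is a ball of radius
``sqrt(I / (4 pi sigma E_thr))``.  Directional contacts are additionally
restricted to an angular cone about the segment direction, giving the
directional/omnidirectional asymmetry the suggestion pipeline needs.

This estimator exists to exercise the grid-search suggestion path, the
transform refitting procedure, and voxel-based validation; it is a
homogeneous-medium point-source model, not a finite-element solver.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .lead_model import ContactSpec, DIRECTIONAL
from .volumes import VoxelVolume

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FieldModelConfig:
    sigma_gray: float = 0.33  # S/m
    sigma_white: float = 0.14  # S/m; kept for a future two-compartment model
    e_threshold: float = 0.2  # V/mm, activation threshold on |E|
    grid_resolution: float = 0.5  # mm
    directional_half_angle: float = 60.0  # degrees

    def __post_init__(self):
        if min(
            self.sigma_gray,
            self.sigma_white,
            self.e_threshold,
            self.grid_resolution,
            self.directional_half_angle,
        ) <= 0:
            raise ValueError("all field-model parameters must be positive")


def point_source_radius(current: float, cfg: FieldModelConfig | None = None) -> float:
    """Radius (mm) of the |E| >= threshold ball around a point source.

    ``current`` in mA; conductivity in S/m and threshold in V/mm are
    converted to SI internally.
    """
    cfg = cfg or FieldModelConfig()
    if current < 0:
        raise ValueError("current must be >= 0")
    amps = current * 1e-3
    e_thr_si = cfg.e_threshold * 1e3  # V/mm -> V/m
    r_m = math.sqrt(amps / (4.0 * math.pi * cfg.sigma_gray * e_thr_si))
    return r_m * 1e3  # m -> mm


def estimate_vta_mask(
    contact: ContactSpec,
    current: float,
    reference: VoxelVolume,
    cfg: FieldModelConfig | None = None,
) -> VoxelVolume:
    """Binarized VTA on the reference grid.

    The source sits at the contact surface center for directional contacts
    and at the level center otherwise.  Directional VTAs are restricted to
    the cone of ``directional_half_angle`` about the segment direction.
    """
    cfg = cfg or FieldModelConfig()
    r = point_source_radius(current, cfg)
    if r == 0.0:
        return VoxelVolume(
            grid=np.zeros(reference.grid.shape, dtype=np.uint8), affine=reference.affine
        )
    max_voxel = float(np.max(np.abs(np.diag(reference.affine[:3, :3]))))
    if r > 0 and max_voxel > r:
        logger.warning(
            "grid resolution %.2f mm exceeds VTA radius %.2f mm; mask may be empty",
            max_voxel,
            r,
        )
    directional = contact.kind == DIRECTIONAL
    source = contact.p_e if directional else contact.p_c

    pts = reference.voxel_centers()
    rel = pts - source
    inside = np.sum(rel * rel, axis=1) <= r * r
    if directional:
        u = contact.segment_direction
        norms = np.linalg.norm(rel, axis=1)
        cos = np.divide(rel @ u, norms, out=np.ones_like(norms), where=norms > 0)
        inside &= cos >= math.cos(math.radians(cfg.directional_half_angle))
    mask = inside.reshape(reference.grid.shape)
    return VoxelVolume(grid=mask.astype(np.uint8), affine=reference.affine)


def equivalent_radius(mask: VoxelVolume) -> float:
    """Radius (mm) of the sphere with the same volume as the mask."""
    vol = mask.total_volume
    if vol <= 0:
        raise ValueError("mask is empty")
    return (3.0 * vol / (4.0 * math.pi)) ** (1.0 / 3.0)


def sweep_transform_samples(
    contact: ContactSpec,
    reference: VoxelVolume,
    cfg: FieldModelConfig | None = None,
    currents: np.ndarray | None = None,
) -> list[tuple[float, float]]:
    """(current, equivalent radius) pairs for refitting the IAS transform.

    Default sweep: 0.6 to 10 mA in steps of 0.1 mA.
    """
    cfg = cfg or FieldModelConfig()
    if currents is None:
        currents = np.round(np.arange(0.6, 10.0 + 1e-9, 0.1), 10)
    out = []
    for i in currents:
        mask = estimate_vta_mask(contact, float(i), reference, cfg)
        if mask.n_voxels == 0:
            continue
        out.append((float(i), equivalent_radius(mask)))
    return out
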