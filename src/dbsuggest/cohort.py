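"""Synthetic cohorts: leads, sweet-spot/STN images, and monopolar reviews.

Emulates the study inputs end-to-end so every pipeline stage is testable
without clinical data and with known ground truth:

* bilateral directional leads aimed at an ellipsoidal subthalamic target,
  with seeded placement jitter (translation + small rotation + random roll);
* a spherical sweet spot in the dorsolateral STN region and an STN
  ellipsoid (both rasterized to NIfTI on demand);
* "clinical" effect thresholds generated by the forward overlap model: each
  site's true threshold solves overlap(I) = V_d(distance) where V_d carries
  per-lead random effects, then multiplicative lognormal noise, rounding to
  the clinical titration step, and range clipping are applied.

The latent truth (random effects, noiseless thresholds, geometry) is kept
alongside so parameter-recovery and end-to-end tests can measure exactly
what was injected.  Reusing the analytic spheres engine for the forward
model is deliberate: recovery tests are then exact; an optional
field-engine mode generates thresholds from the voxel stand-in instead for
a model-mismatch stress test.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .desired_overlap import DesiredOverlapModel, DISTANCE_DEPENDENT
from .engines import FieldEngine, IASEngine
from .field import FieldModelConfig
from .lead_model import LeadGeometry, build_lead, contact_distance, save_lead, transform_lead
from .spheres import CurrentRadiusTransform, PlacementModel, Sphere
from .suggest import threshold_continuous
from .volumes import VoxelVolume, make_reference_grid, summarize_sweetspot

RIGHT_SS_CENTER = np.array([12.0, -13.0, -6.0])  # dorsolateral STN region, MNI mm
RIGHT_STN_CENTER = np.array([11.5, -12.8, -7.2])
_NOMINAL_AXIS = np.array([0.25, 0.35, 0.9])  # distal -> proximal trajectory
_TRUTH_TOL = 1e-3  # mA; forward-model thresholds solved finer than suggestions


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 24  # bilateral -> 2 leads per patient
    seed: int = 0
    placement_jitter_sd: float = 1.0  # mm
    angle_jitter_sd: float = 5.0  # degrees
    sweetspot_radius: float = 2.5  # mm
    stn_semiaxes: tuple[float, float, float] = (3.2, 4.8, 2.5)  # ~160 mm^3
    vd_truth: tuple[float, float] = (70.0, -8.0)  # (beta0 %, beta1 %/mm)
    vd_constant_fraction: float | None = None  # set to use the constant model
    vd_bounds: tuple[float, float] = (1.0, 100.0)  # mm^3
    lead_random_effect_sd: tuple[float, float] = (10.0, 1.0)  # (% , %/mm)
    threshold_noise_cv: float = 0.1
    threshold_rounding: float = 0.1  # mA, clinical titration step
    threshold_range: tuple[float, float] | None = (0.5, 10.0)  # mA
    i_max: float = 8.0  # suggestion ceiling used for the feasibility check
    truth_i_max: float = 15.0  # ceiling when solving ground-truth thresholds
    grid_resolution: float = 0.5  # mm, for rasterized images
    engine: str = "ias"  # forward model for thresholds: ias | field
    max_retries: int = 20

    def __post_init__(self):
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if min(
            self.placement_jitter_sd if self.placement_jitter_sd > 0 else 1,
            self.sweetspot_radius,
            self.threshold_rounding if self.threshold_rounding > 0 else 1,
            self.grid_resolution,
        ) <= 0:
            raise ValueError("scales must be positive")
        if self.engine not in ("ias", "field"):
            raise ValueError("engine must be 'ias' or 'field'")


@dataclass
class Cohort:
    config: CohortConfig
    leads: dict[str, LeadGeometry]
    ss_spheres: dict[str, Sphere]  # hemisphere -> sphere
    stn_centers: dict[str, np.ndarray]
    review: pd.DataFrame  # lead_id, contact_id, threshold_mA
    truth: dict

    def vd_truth_model(self) -> DesiredOverlapModel:
        cfg = self.config
        if cfg.vd_constant_fraction is not None:
            return DesiredOverlapModel(constant_fraction=cfg.vd_constant_fraction)
        return DesiredOverlapModel(
            mode=DISTANCE_DEPENDENT,
            beta0=cfg.vd_truth[0],
            beta1=cfg.vd_truth[1],
            lower_bound=cfg.vd_bounds[0],
            upper_bound=cfg.vd_bounds[1],
        )

    def engine_for(self, hemisphere: str) -> IASEngine:
        return IASEngine(sweetspot_sphere=self.ss_spheres[hemisphere])

    def sweetspot_image(self, hemisphere: str) -> VoxelVolume:
        sph = self.ss_spheres[hemisphere]
        ref = make_reference_grid(
            sph.center, sph.radius + 4.0, self.config.grid_resolution
        )
        return make_ellipsoid_image(sph.center, (sph.radius,) * 3, ref)

    def stn_image(self, hemisphere: str) -> VoxelVolume:
        center = self.stn_centers[hemisphere]
        semi = self.config.stn_semiaxes
        ref = make_reference_grid(center, max(semi) + 4.0, self.config.grid_resolution)
        return make_ellipsoid_image(center, semi, ref)


def make_ellipsoid_image(center, semiaxes, reference: VoxelVolume) -> VoxelVolume:
    """Binary ellipsoid mask on a reference grid (voxel-center membership)."""
    center = np.asarray(center, dtype=float)
    semi = np.asarray(semiaxes, dtype=float)
    if np.any(semi <= 0):
        raise ValueError("semiaxes must be positive")
    pts = reference.voxel_centers()
    q = ((pts - center) / semi) ** 2
    mask = (q.sum(axis=1) <= 1.0).reshape(reference.grid.shape)
    return VoxelVolume(grid=mask.astype(np.uint8), affine=reference.affine)


def _random_rotation(rng: np.random.Generator, angle_sd_deg: float) -> np.ndarray:
    """Small random rotation: angle ~ N(0, sd) about an isotropic axis."""
    if angle_sd_deg <= 0:
        return np.eye(3)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = math.radians(rng.normal(0.0, angle_sd_deg))
    K = np.array(
        [
            [0, -axis[2], axis[1]],
            [axis[2], 0, -axis[0]],
            [-axis[1], axis[0], 0],
        ]
    )
    return np.eye(3) + math.sin(ang) * K + (1 - math.cos(ang)) * (K @ K)


_MIRROR = np.diag([-1.0, 1.0, 1.0])


def _place_lead(
    rng: np.random.Generator,
    cfg: CohortConfig,
    ss_center: np.ndarray,
    lead_id: str,
    hemisphere: str,
) -> LeadGeometry:
    """One jittered lead aimed so its segmented levels straddle the target."""
    axis = _NOMINAL_AXIS / np.linalg.norm(_NOMINAL_AXIS)
    # left leads are built as right-hemisphere scenes and mirrored at the
    # end, so aim at the target's right-hemisphere image
    target = ss_center * np.array([-1.0, 1.0, 1.0]) if hemisphere == "left" else ss_center
    # level centers sit at 0.75 + 2k mm from the tip; aim the level-2/3
    # midpoint (3.75 mm) at the target
    tip = target - 3.75 * axis
    lead = build_lead(
        tip, axis, roll_angle=float(rng.uniform(0.0, 360.0)), lead_id=lead_id,
        hemisphere=hemisphere,
    )
    R = _random_rotation(rng, cfg.angle_jitter_sd)
    pivot = lead.level_centers.mean(axis=0)
    t = pivot - R @ pivot + rng.normal(0.0, cfg.placement_jitter_sd, size=3)
    lead = transform_lead(lead, R, t)
    if hemisphere == "left":
        lead = transform_lead(lead, _MIRROR, np.zeros(3))
    return lead


def _solve_truth_threshold(overlap_fn, vd: float, i_max: float) -> float | None:
    search = threshold_continuous(overlap_fn, vd, i_max=i_max, tol=_TRUTH_TOL)
    return search.estimate if search.reached else None


def generate_cohort(cfg: CohortConfig) -> Cohort:
    """Generate a full synthetic cohort from a seeded config."""
    rng = np.random.default_rng(cfg.seed)
    ss = {
        "right": Sphere(RIGHT_SS_CENTER, cfg.sweetspot_radius),
        "left": Sphere(RIGHT_SS_CENTER * [-1, 1, 1], cfg.sweetspot_radius),
    }
    stn = {"right": RIGHT_STN_CENTER.copy(), "left": RIGHT_STN_CENTER * [-1, 1, 1]}
    transform = CurrentRadiusTransform()
    placement = PlacementModel()

    engines: dict[str, object] = {}
    for hemi in ("right", "left"):
        if cfg.engine == "ias":
            engines[hemi] = IASEngine(ss[hemi], transform, placement)
        else:
            ref = make_reference_grid(
                ss[hemi].center, ss[hemi].radius + 8.0, cfg.grid_resolution
            )
            ss_img = make_ellipsoid_image(
                ss[hemi].center, (ss[hemi].radius,) * 3, ref
            )
            engines[hemi] = FieldEngine(
                summarize_sweetspot(ss_img),
                FieldModelConfig(grid_resolution=cfg.grid_resolution),
            )

    leads: dict[str, LeadGeometry] = {}
    rows: list[dict] = []
    truth_leads: dict[str, dict] = {}
    sd0, sd1 = cfg.lead_random_effect_sd

    for p in range(1, cfg.n_patients + 1):
        for hemi in ("right", "left"):
            lead_id = f"P{p:02d}_{hemi[0].upper()}"
            engine = engines[hemi]
            for attempt in range(cfg.max_retries):
                lead = _place_lead(rng, cfg, ss[hemi].center, lead_id, hemi)
                b0 = rng.normal(0.0, sd0) if sd0 > 0 else 0.0
                b1 = rng.normal(0.0, sd1) if sd1 > 0 else 0.0
                site_truth, site_rows = _simulate_lead_review(
                    rng, cfg, lead, engine, b0, b1
                )
                if site_rows:  # at least one feasible site
                    break
            else:
                raise RuntimeError(
                    f"could not place a feasible lead for {lead_id} "
                    f"after {cfg.max_retries} attempts"
                )
            leads[lead_id] = lead
            rows.extend(site_rows)
            truth_leads[lead_id] = {
                "random_intercept": b0,
                "random_slope": b1,
                "sites": site_truth,
            }

    review = pd.DataFrame(rows, columns=["lead_id", "contact_id", "threshold_mA"])
    truth = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cfg).items()
        },
        "sweetspot": {
            h: {"center_mm": list(map(float, s.center)), "radius_mm": s.radius}
            for h, s in ss.items()
        },
        "stn": {
            h: {"center_mm": list(map(float, c)), "semiaxes_mm": list(cfg.stn_semiaxes)}
            for h, c in stn.items()
        },
        "leads": truth_leads,
    }
    return Cohort(cfg, leads, ss, stn, review, truth)


def _simulate_lead_review(rng, cfg: CohortConfig, lead, engine, b0, b1):
    """Forward-model thresholds for every selectable site of one lead.

    Returns (truth per site, review rows); sites whose target overlap is
    unreachable even at the truth ceiling produce no review row.  The lead
    is feasible only if some site is reachable at the suggestion ceiling.
    """
    vd_base = cfg.vd_truth
    site_truth: dict[str, dict] = {}
    rows: list[dict] = []
    any_feasible_at_imax = False
    for contact in lead.contacts:
        d = contact_distance(contact, engine.sweetspot_center)
        if cfg.vd_constant_fraction is not None:
            vd = cfg.vd_constant_fraction * engine.sweetspot_volume
        else:
            pct = (vd_base[0] + b0) + (vd_base[1] + b1) * d
            vd = pct / 100.0 * engine.sweetspot_volume
            vd = min(max(vd, cfg.vd_bounds[0]), cfg.vd_bounds[1])
        fn = lambda I: engine.overlap(contact, I)
        t_true = _solve_truth_threshold(fn, vd, cfg.truth_i_max)
        site_truth[contact.contact_id] = {
            "distance_mm": d,
            "desired_volume_mm3": vd,
            "true_threshold_mA": t_true,
        }
        if t_true is None:
            continue
        if t_true <= cfg.i_max:
            any_feasible_at_imax = True
        t = t_true
        if cfg.threshold_noise_cv > 0:
            s = math.sqrt(math.log(1.0 + cfg.threshold_noise_cv**2))
            t *= float(rng.lognormal(mean=-0.5 * s * s, sigma=s))
        if cfg.threshold_rounding > 0:
            t = max(
                round(t / cfg.threshold_rounding) * cfg.threshold_rounding,
                cfg.threshold_rounding,
            )
        if cfg.threshold_range is not None:
            t = min(max(t, cfg.threshold_range[0]), cfg.threshold_range[1])
        rows.append(
            {
                "lead_id": lead.lead_id,
                "contact_id": contact.contact_id,
                "threshold_mA": round(t, 6),
            }
        )
    if not any_feasible_at_imax:
        return site_truth, []
    return site_truth, rows


def simulate_review_records(
    n_leads: int = 24,
    contacts_per_lead: int = 8,
    beta0: float = 70.0,
    beta1: float = -8.0,
    re_sd: tuple[float, float] = (10.0, 0.0),
    resid_sd: float = 5.0,
    distance_range: tuple[float, float] = (1.0, 6.0),
    rng: np.random.Generator | None = None,
):
    """Records drawn directly from the mixed-model generative process.

    percent = beta0 + b0_lead + (beta1 + b1_lead) d + eps, clipped to
    [0, 100]; used for mixed-model parameter-recovery experiments where the
    geometric forward model would only add confounding.
    """
    from .desired_overlap import ReviewRecord

    rng = rng or np.random.default_rng(0)
    records = []
    for l in range(n_leads):
        b0 = rng.normal(0.0, re_sd[0]) if re_sd[0] > 0 else 0.0
        b1 = rng.normal(0.0, re_sd[1]) if re_sd[1] > 0 else 0.0
        d = rng.uniform(*distance_range, size=contacts_per_lead)
        pct = beta0 + b0 + (beta1 + b1) * d + rng.normal(0.0, resid_sd, size=contacts_per_lead)
        pct = np.clip(pct, 0.0, 100.0)
        for c in range(contacts_per_lead):
            records.append(
                ReviewRecord(
                    lead_id=f"L{l:02d}",
                    contact_id=str(c + 1),
                    clinical_threshold=1.0,  # placeholder; not used by the fit
                    distance=float(d[c]),
                    percent_covered=float(pct[c]),
                )
            )
    return records


def write_cohort(cohort: Cohort, outdir) -> dict[str, str]:
    """Write the cohort in the exact formats the CLI pipeline consumes."""
    out = Path(outdir)
    (out / "leads").mkdir(parents=True, exist_ok=True)
    paths = {}
    for lead_id, lead in cohort.leads.items():
        p = out / "leads" / f"{lead_id}.json"
        save_lead(lead, p)
    paths["leads_dir"] = str(out / "leads")
    for hemi in ("right", "left"):
        ssp = out / f"sweetspot_{hemi}.nii.gz"
        cohort.sweetspot_image(hemi).save(ssp)
        paths[f"sweetspot_{hemi}"] = str(ssp)
        stnp = out / f"stn_{hemi}.nii.gz"
        cohort.stn_image(hemi).save(stnp)
        paths[f"stn_{hemi}"] = str(stnp)
    rp = out / "review.csv"
    cohort.review.to_csv(rp, index=False)
    paths["review"] = str(rp)
    tp = out / "truth.json"
    with open(tp, "w") as fh:
        json.dump(cohort.truth, fh, indent=1)
    paths["truth"] = str(tp)
    return paths
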