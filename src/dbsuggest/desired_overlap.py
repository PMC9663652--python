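"""Desired overlap volume V_d: how much sweet spot a VTA should cover.

Two models are supported.  The *constant* model targets a fixed fraction of
the sweet-spot volume (default 33%).  The *distance-dependent* model targets
a percentage that falls off linearly with the distance between the contact
and the sweet-spot center, with fixed effects estimated by a linear
mixed-effects regression (random intercept and slope per lead) of the
percentage of sweet spot covered at each contact's clinical effect
threshold.  Predictions for new leads use the fixed effects only and are
clamped to [1, 100] mm^3 — the upper bound sits between the motor-STN and
whole-STN volumes so a target can never demand engulfing the whole nucleus.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .engines import OverlapEngine
from .lead_model import ContactSpec

logger = logging.getLogger(__name__)

CONSTANT = "constant"
DISTANCE_DEPENDENT = "distance_dependent"


@dataclass(frozen=True)
class ReviewRecord:
    """One monopolar-review observation enriched with overlap geometry."""

    lead_id: str
    contact_id: str
    clinical_threshold: float  # mA
    distance: float  # mm, contact to sweet-spot center
    percent_covered: float  # % of sweet-spot volume overlapped at threshold

    def __post_init__(self):
        if not (self.clinical_threshold > 0):
            raise ValueError("clinical_threshold must be > 0")
        if not (0.0 <= self.percent_covered <= 100.0):
            raise ValueError("percent_covered must be in [0, 100]")


@dataclass(frozen=True)
class DesiredOverlapModel:
    """Target overlap V_d, either constant or distance-dependent."""

    mode: str = CONSTANT
    constant_fraction: float = 0.33
    beta0: float | None = None  # fixed intercept, %
    beta1: float | None = None  # fixed slope, %/mm
    random_effect_sd: tuple[float, float, float] | None = None  # (sd0, sd1, corr)
    lower_bound: float = 1.0  # mm^3
    upper_bound: float = 100.0  # mm^3
    fit_info: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in (CONSTANT, DISTANCE_DEPENDENT):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0.0 < self.constant_fraction <= 1.0):
            raise ValueError("constant_fraction must be in (0, 1]")
        if not (self.lower_bound < self.upper_bound):
            raise ValueError("lower_bound must be below upper_bound")
        if self.mode == DISTANCE_DEPENDENT and (self.beta0 is None or self.beta1 is None):
            raise ValueError("distance-dependent mode needs beta0 and beta1")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "constant_fraction": self.constant_fraction,
            "beta0": self.beta0,
            "beta1": self.beta1,
            "random_effect_sd": list(self.random_effect_sd)
            if self.random_effect_sd is not None
            else None,
            "lower_bound": self.lower_bound,
            "upper_bound": self.upper_bound,
            "fit_info": self.fit_info,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DesiredOverlapModel":
        re_sd = d.get("random_effect_sd")
        return cls(
            mode=d["mode"],
            constant_fraction=d.get("constant_fraction", 0.33),
            beta0=d.get("beta0"),
            beta1=d.get("beta1"),
            random_effect_sd=tuple(re_sd) if re_sd is not None else None,
            lower_bound=d.get("lower_bound", 1.0),
            upper_bound=d.get("upper_bound", 100.0),
            fit_info=d.get("fit_info", {}),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def load(cls, path) -> "DesiredOverlapModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def percent_covered(
    contact: ContactSpec, clinical_threshold: float, engine: OverlapEngine
) -> float:
    """Percentage of the sweet-spot volume covered at the effect threshold."""
    if clinical_threshold <= 0:
        raise ValueError("clinical_threshold must be > 0")
    v_ss = engine.sweetspot_volume
    if v_ss <= 0:
        raise ValueError("sweet-spot volume is zero")
    return 100.0 * engine.overlap(contact, clinical_threshold) / v_ss


def make_review_records(
    review: pd.DataFrame, leads: dict, engine_for_lead
) -> list[ReviewRecord]:
    """Enrich a monopolar-review table with distances and covered percentages.

    ``review`` needs columns lead_id, contact_id, threshold_mA.
    ``engine_for_lead(lead_id)`` returns the overlap engine (and hence the
    hemisphere-appropriate sweet spot) to use for that lead.
    """
    records = []
    for row in review.itertuples(index=False):
        lead = leads.get(str(row.lead_id))
        if lead is None:
            logger.warning("review references unknown lead %s; skipped", row.lead_id)
            continue
        contact = lead.contact(str(row.contact_id))
        engine = engine_for_lead(str(row.lead_id))
        pct = min(percent_covered(contact, float(row.threshold_mA), engine), 100.0)
        records.append(
            ReviewRecord(
                lead_id=str(row.lead_id),
                contact_id=str(row.contact_id),
                clinical_threshold=float(row.threshold_mA),
                distance=engine.distance(contact),
                percent_covered=pct,
            )
        )
    return records


def fit_distance_model(
    records: Sequence[ReviewRecord],
    lower_bound: float = 1.0,
    upper_bound: float = 100.0,
    include_ring: bool = True,
) -> DesiredOverlapModel:
    """Fit the distance-dependent V_d model by REML mixed-effects regression.

    percent_covered ~ distance with per-lead random intercept and slope.
    If the random-slope fit fails or is singular, the model is refit with a
    random intercept only and the downgrade is logged in ``fit_info``.
    """
    recs = [r for r in records if include_ring or not r.contact_id.startswith("ring")]
    data = pd.DataFrame(
        {
            "lead_id": [r.lead_id for r in recs],
            "distance": [r.distance for r in recs],
            "percent_covered": [r.percent_covered for r in recs],
        }
    )
    n_leads = data["lead_id"].nunique()
    if n_leads < 2:
        raise ValueError("need records from at least 2 leads")
    if (data.groupby("lead_id").size() < 2).any():
        raise ValueError("need at least 2 records per lead")
    if np.ptp(data["distance"].to_numpy()) <= 0:
        raise ValueError("distances are degenerate (no spread)")

    def _fit(re_formula):
        model = smf.mixedlm(
            "percent_covered ~ distance",
            data,
            groups=data["lead_id"],
            re_formula=re_formula,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            result = model.fit(reml=True)
            # materialize the standard errors inside the suppression block;
            # singular fits emit sqrt-of-negative warnings here
            bse = np.asarray(result.bse_fe, dtype=float)
        return result, bse

    structure = "intercept+slope"
    try:
        result, bse = _fit("~distance")
        singular = not np.all(np.isfinite(bse)) or not result.converged
    except (np.linalg.LinAlgError, ValueError):
        result, singular = None, True
    if result is None or singular:
        logger.warning("random-slope fit singular/failed; refitting with random intercept only")
        structure = "intercept"
        try:
            result, bse = _fit("1")
            singular = not np.all(np.isfinite(bse))
        except (np.linalg.LinAlgError, ValueError):
            result, singular = None, True
    if result is None or singular:
        # degenerate data (e.g. an exactly linear noiseless relationship)
        # have no estimable variance components; ordinary least squares
        # still identifies the fixed effects exactly
        logger.warning("variance components not estimable; falling back to OLS")
        structure = "none"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ols = smf.ols("percent_covered ~ distance", data).fit()
        fe = ols.params
        se = np.nan_to_num(np.asarray(ols.bse, dtype=float))
        sd0 = sd1 = corr = 0.0
        resid_sd = float(np.sqrt(max(ols.mse_resid, 0.0)))
        converged = True
    else:
        fe = result.fe_params
        cov_re = np.atleast_2d(np.asarray(result.cov_re))
        sd0 = float(np.sqrt(max(cov_re[0, 0], 0.0)))
        if cov_re.shape == (2, 2):
            sd1 = float(np.sqrt(max(cov_re[1, 1], 0.0)))
            corr = float(cov_re[0, 1] / (sd0 * sd1)) if sd0 > 0 and sd1 > 0 else 0.0
        else:
            sd1, corr = 0.0, 0.0
        se = bse
        resid_sd = float(np.sqrt(result.scale))
        converged = bool(result.converged)
    return DesiredOverlapModel(
        mode=DISTANCE_DEPENDENT,
        beta0=float(fe.iloc[0]),
        beta1=float(fe.iloc[1]),
        random_effect_sd=(sd0, sd1, corr),
        lower_bound=lower_bound,
        upper_bound=upper_bound,
        fit_info={
            "method": "REML",
            "random_structure": structure,
            "converged": converged,
            "n_records": int(len(data)),
            "n_leads": int(n_leads),
            "beta0_se": float(se[0]),
            "beta1_se": float(se[1]),
            "residual_sd": resid_sd,
        },
    )


def desired_volume(
    model: DesiredOverlapModel, distance: float, sweetspot_volume: float
) -> float:
    """Target overlap V_d (mm^3) for a contact at ``distance`` mm.

    Distance-dependent mode predicts a percentage from the fixed effects
    only (random effects are unobservable for a new lead), converts it to
    mm^3 and clamps to the model bounds; negative predicted percentages are
    absorbed by the lower bound.
    """
    if distance < 0:
        raise ValueError("distance must be >= 0")
    if model.mode == CONSTANT:
        return model.constant_fraction * sweetspot_volume
    pct = model.beta0 + model.beta1 * distance
    vd = pct / 100.0 * sweetspot_volume
    return float(min(max(vd, model.lower_bound), model.upper_bound))
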