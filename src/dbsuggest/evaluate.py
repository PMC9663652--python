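"""Scoring suggestions against clinical monopolar reviews.

The clinical ground truth for a lead is the set of sites attaining its
lowest effect threshold (all tied sites are considered equally best).  A
suggestion is *correct* when it is a single site inside that set,
*partially correct* when a tied multi-site suggestion intersects it, and
*incorrect* otherwise.  Accuracy weights partial credit by ``w`` (default
0.5; the extremes w=0 and w=1 bracket any convention).  Proportion CIs use
the plain normal approximation p +/- Z sqrt(p(1-p)/N); comparisons against
chance-level baselines use the exact right-tailed binomial test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

CORRECT = "correct"
PARTIALLY_CORRECT = "partially_correct"
INCORRECT = "incorrect"


@dataclass(frozen=True)
class ProportionEstimate:
    p: float
    n: int
    z: float = 1.96
    ci_low: float = float("nan")
    ci_high: float = float("nan")

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0):
            raise ValueError("proportion must be in [0, 1]")
        if math.isnan(self.ci_low):
            lo, hi = proportion_ci(self.p, self.n, self.z)
            object.__setattr__(self, "ci_low", lo)
            object.__setattr__(self, "ci_high", hi)


def proportion_ci(p: float, n: int, z: float = 1.96) -> tuple[float, float]:
    """Normal-approximation CI for a proportion: p +/- z sqrt(p(1-p)/n).

    Returned untruncated (a bound can leave [0, 1] for extreme p and
    small n).
    """
    if not (0.0 <= p <= 1.0):
        raise ValueError("p must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    half = z * math.sqrt(p * (1.0 - p) / n)
    return p - half, p + half


def binomial_right_tailed(k: int, n: int, p0: float) -> float:
    """Exact right-tailed binomial p-value P(X >= k | n, p0)."""
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must be in (0, 1)")
    return float(stats.binomtest(k, n, p0, alternative="greater").pvalue)


# ---------------------------------------------------------------------------
# best-site accuracy

def clinical_best(review: pd.DataFrame, by: str, level_of=None) -> dict[str, frozenset]:
    """Per-lead set of clinically best sites from a monopolar-review table.

    ``review`` needs columns lead_id, contact_id, threshold_mA.  With
    ``by="level"`` a ``level_of(lead_id, contact_id) -> int`` mapping is
    required; every site attaining the lead's minimum threshold contributes
    its level.  All ties at the minimum are kept.
    """
    if by not in ("level", "contact"):
        raise ValueError("by must be 'level' or 'contact'")
    if by == "level" and level_of is None:
        raise ValueError("by='level' requires a level_of mapping")
    if by == "contact":
        # ring-mode rows are level-scale observations, not candidate
        # contacts; only the 8 physical contacts compete for best contact
        review = review[~review["contact_id"].astype(str).str.startswith("ring")]
    out: dict[str, frozenset] = {}
    for lead_id, grp in review.groupby("lead_id"):
        t = grp["threshold_mA"].to_numpy(dtype=float)
        best = grp[t == t.min()]
        if by == "contact":
            out[str(lead_id)] = frozenset(str(c) for c in best["contact_id"])
        else:
            out[str(lead_id)] = frozenset(
                int(level_of(str(lead_id), str(c))) for c in best["contact_id"]
            )
    return out


@dataclass(frozen=True)
class AccuracyResult:
    estimate: ProportionEstimate
    outcomes: dict[str, str] = field(default_factory=dict)  # lead_id -> class
    partial_weight: float = 0.5
    accuracy_strict: float = 0.0  # w = 0
    accuracy_lenient: float = 0.0  # w = 1

    @property
    def counts(self) -> dict[str, int]:
        vals = list(self.outcomes.values())
        return {c: vals.count(c) for c in (CORRECT, PARTIALLY_CORRECT, INCORRECT)}


def accuracy(
    suggested: dict[str, frozenset],
    clinical: dict[str, frozenset],
    partial_weight: float = 0.5,
    z: float = 1.96,
) -> AccuracyResult:
    """Score per-lead suggested site sets against clinical best sets.

    Leads with an empty suggested set (nothing reached) score incorrect.
    ``partial_weight`` controls the credit a tied (multi-site) suggestion
    earns when it intersects the clinical set; the w=0 and w=1 extremes are
    reported alongside.
    """
    common = sorted(set(suggested) & set(clinical))
    if not common:
        raise ValueError("suggested and clinical lead ids do not overlap")
    outcomes = {}
    for lead_id in common:
        s, c = frozenset(suggested[lead_id]), frozenset(clinical[lead_id])
        if len(s) == 1 and s & c:
            outcomes[lead_id] = CORRECT
        elif len(s) > 1 and s & c:
            outcomes[lead_id] = PARTIALLY_CORRECT
        else:
            outcomes[lead_id] = INCORRECT
    n = len(common)
    n_c = sum(1 for o in outcomes.values() if o == CORRECT)
    n_p = sum(1 for o in outcomes.values() if o == PARTIALLY_CORRECT)
    p = (n_c + partial_weight * n_p) / n
    return AccuracyResult(
        estimate=ProportionEstimate(p=p, n=n, z=z),
        outcomes=outcomes,
        partial_weight=partial_weight,
        accuracy_strict=n_c / n,
        accuracy_lenient=(n_c + n_p) / n,
    )


# ---------------------------------------------------------------------------
# threshold errors and correlation

@dataclass(frozen=True)
class ThresholdErrorReport:
    mae: float  # mA
    sem: float  # mA
    per_lead_mae: dict[str, float]
    n_pairs: int
    n_unreached: int


def threshold_errors(
    suggested: pd.DataFrame, clinical: pd.DataFrame
) -> ThresholdErrorReport:
    """Absolute error statistics between suggested and clinical thresholds.

    Both frames need lead_id, contact_id and threshold_mA columns; rows in
    ``suggested`` with a missing threshold (site not reached) are excluded
    from the pairing and counted.
    """
    merged = clinical.merge(
        suggested,
        on=["lead_id", "contact_id"],
        suffixes=("_clin", "_sugg"),
        how="inner",
    )
    unreached = int(merged["threshold_mA_sugg"].isna().sum())
    merged = merged.dropna(subset=["threshold_mA_sugg"])
    if merged.empty:
        raise ValueError("no paired thresholds to compare")
    err = (merged["threshold_mA_sugg"] - merged["threshold_mA_clin"]).abs()
    per_lead = err.groupby(merged["lead_id"]).mean().to_dict()
    sem = float(err.std(ddof=1) / math.sqrt(len(err))) if len(err) > 1 else 0.0
    return ThresholdErrorReport(
        mae=float(err.mean()),
        sem=sem,
        per_lead_mae={str(k): float(v) for k, v in per_lead.items()},
        n_pairs=int(len(err)),
        n_unreached=unreached,
    )


def compare_errors(errors_a, errors_b) -> tuple[float, float]:
    """Two-sample t-test on two sets of absolute errors; (t, p two-sided)."""
    t, p = stats.ttest_ind(np.asarray(errors_a, float), np.asarray(errors_b, float))
    return float(t), float(p)


def pearson(x, y) -> tuple[float, float]:
    """Pearson correlation with its two-sided t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in one of the inputs")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
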