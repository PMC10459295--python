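"""Deterministic ACR TI-RADS 2017 scoring.

Implements the American College of Radiology Thyroid Imaging Reporting and
Data System (2017): categorical ultrasound features of a thyroid nodule are
mapped to points, points to a risk level TR1..TR5, and the level plus the
nodule's maximum diameter to a clinical recommendation (no action, follow-up
ultrasound, or fine-needle aspiration).

Five feature axes are scored additively:

* composition        — cystic / spongiform / mixed solid-cystic / solid
* echogenicity       — anechoic / hyperechoic / hypoechoic / very hypoechoic
  (relative to thyroid parenchyma; the hyperechoic class also covers
  isoechoic nodules, which carry the same point value)
* shape              — wider-than-tall / taller-than-wide (transverse plane)
* margin             — smooth / ill-defined / lobulated-irregular /
  extrathyroidal extension
* echogenic foci     — any subset of comet-tail artifact, macrocalcification,
  peripheral (rim) calcification, punctate microcalcification; points add.

All functions are pure; the module has no state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Mapping, Optional

__all__ = [
    "COMPOSITIONS",
    "ECHOGENICITIES",
    "SHAPES",
    "MARGINS",
    "FOCI",
    "DEFAULT_SUSPICION_PCT",
    "NoduleFeatures",
    "PointBreakdown",
    "TiradsAssessment",
    "score_features",
    "level_from_points",
    "recommend",
    "assess",
]

COMPOSITIONS = ("cystic", "spongiform", "mixed", "solid")
ECHOGENICITIES = ("anechoic", "hyperechoic", "hypoechoic", "very_hypoechoic")
SHAPES = ("wider_than_tall", "taller_than_wide")
MARGINS = ("smooth", "ill_defined", "lobulated_irregular", "extrathyroidal_extension")
FOCI = ("comet_tail", "macrocalcification", "peripheral_calcification", "punctate_micro")

# ACR TI-RADS 2017 point chart (Tessler et al.). Ill-defined margins score 0,
# the same as smooth — the two classes are clinically mergeable for scoring.
_COMPOSITION_PTS = {"cystic": 0, "spongiform": 0, "mixed": 1, "solid": 2}
_ECHOGENICITY_PTS = {
    "anechoic": 0,
    "hyperechoic": 1,
    "hypoechoic": 2,
    "very_hypoechoic": 3,
}
_SHAPE_PTS = {"wider_than_tall": 0, "taller_than_wide": 3}
_MARGIN_PTS = {
    "smooth": 0,
    "ill_defined": 0,
    "lobulated_irregular": 2,
    "extrathyroidal_extension": 3,
}
_FOCI_PTS = {
    "comet_tail": 0,
    "macrocalcification": 1,
    "peripheral_calcification": 2,
    "punctate_micro": 3,
}

#: Default malignancy-suspicion percentage per TR level.  TR2 (1.5%) and
#: TR5 (35%) anchor the table; the remaining levels default to the published
#: ACR validation estimates and may be overridden per call.
DEFAULT_SUSPICION_PCT: Mapping[int, float] = {1: 0.3, 2: 1.5, 3: 4.8, 4: 9.1, 5: 35.0}

# Size gates in mm: level -> (follow_up_at, fna_at).  None = never.
_SIZE_GATES = {
    1: (None, None),
    2: (None, None),
    3: (15.0, 25.0),
    4: (10.0, 15.0),
    5: (5.0, 10.0),
}


@dataclass(frozen=True)
class NoduleFeatures:
    """Categorical TI-RADS feature assignment for one nodule.

    ``foci`` may be empty or any subset of :data:`FOCI`;
    ``max_diameter_mm`` is the largest diameter of the nodule in mm.
    """

    composition: str
    echogenicity: str
    shape: str
    margin: str
    foci: FrozenSet[str] = field(default_factory=frozenset)
    max_diameter_mm: float = 10.0

    def __post_init__(self) -> None:
        _check_member("composition", self.composition, COMPOSITIONS)
        _check_member("echogenicity", self.echogenicity, ECHOGENICITIES)
        _check_member("shape", self.shape, SHAPES)
        _check_member("margin", self.margin, MARGINS)
        object.__setattr__(self, "foci", frozenset(self.foci))
        for f in self.foci:
            _check_member("foci", f, FOCI)
        if not self.max_diameter_mm > 0:
            raise ValueError(
                f"max_diameter_mm must be positive, got {self.max_diameter_mm}"
            )


@dataclass(frozen=True)
class PointBreakdown:
    """Per-axis ACR points and their total for one nodule."""

    composition_pts: int
    echogenicity_pts: int
    shape_pts: int
    margin_pts: int
    foci_pts: int
    total_pts: int


@dataclass(frozen=True)
class TiradsAssessment:
    """Risk level, suspicion percentage and size-gated recommendation."""

    tr_level: int
    suspicion_pct: Optional[float]
    recommendation: str


def _check_member(axis: str, value: str, allowed: Iterable[str]) -> None:
    if value not in allowed:
        raise ValueError(f"unknown {axis} value {value!r}; expected one of {tuple(allowed)}")


def score_features(features: NoduleFeatures) -> PointBreakdown:
    """Score a feature set against the ACR TI-RADS 2017 point chart.

    Points on the five axes are independent and additive; the echogenic-foci
    contribution is itself the sum over the foci present.
    """
    comp = _COMPOSITION_PTS[features.composition]
    echo = _ECHOGENICITY_PTS[features.echogenicity]
    shape = _SHAPE_PTS[features.shape]
    margin = _MARGIN_PTS[features.margin]
    foci = sum(_FOCI_PTS[f] for f in features.foci)
    return PointBreakdown(
        composition_pts=comp,
        echogenicity_pts=echo,
        shape_pts=shape,
        margin_pts=margin,
        foci_pts=foci,
        total_pts=comp + echo + shape + margin + foci,
    )


def level_from_points(total_pts: int) -> int:
    """Map a total point count to the TR risk level (1..5).

    ACR thresholds: 0-1 points -> TR1, 2 -> TR2, 3 -> TR3, 4-6 -> TR4,
    >=7 -> TR5.  Monotone non-decreasing in ``total_pts``.
    """
    if total_pts < 0:
        raise ValueError(f"total_pts must be >= 0, got {total_pts}")
    if total_pts <= 1:
        return 1
    if total_pts == 2:
        return 2
    if total_pts == 3:
        return 3
    if total_pts <= 6:
        return 4
    return 5


def recommend(tr_level: int, max_diameter_mm: float) -> str:
    """Size-gated ACR recommendation for a given TR level.

    TR1/TR2 never trigger action.  TR3: follow-up at >=15 mm, FNA at
    >=25 mm.  TR4: follow-up >=10 mm, FNA >=15 mm.  TR5: follow-up >=5 mm,
    FNA >=10 mm.  Gates are inclusive (15.0 mm triggers follow-up at TR3).
    """
    if tr_level not in (1, 2, 3, 4, 5):
        raise ValueError(f"tr_level must be in 1..5, got {tr_level}")
    if not max_diameter_mm > 0:
        raise ValueError(f"max_diameter_mm must be positive, got {max_diameter_mm}")
    follow_at, fna_at = _SIZE_GATES[tr_level]
    if fna_at is not None and max_diameter_mm >= fna_at:
        return "fna"
    if follow_at is not None and max_diameter_mm >= follow_at:
        return "follow_up"
    return "no_action"


def assess(
    features: NoduleFeatures,
    suspicion_pct: Optional[Mapping[int, float]] = None,
) -> TiradsAssessment:
    """Full TI-RADS assessment: points -> level -> suspicion + recommendation.

    ``suspicion_pct`` optionally overrides :data:`DEFAULT_SUSPICION_PCT`;
    a level absent from the mapping yields ``suspicion_pct=None``.
    """
    table = DEFAULT_SUSPICION_PCT if suspicion_pct is None else suspicion_pct
    breakdown = score_features(features)
    level = level_from_points(breakdown.total_pts)
    return TiradsAssessment(
        tr_level=level,
        suspicion_pct=table.get(level),
        recommendation=recommend(level, features.max_diameter_mm),
    )


def assessment_report(features: NoduleFeatures) -> dict:
    """JSON-ready report: features, per-axis points, level, recommendation."""
    breakdown = score_features(features)
    result = assess(features)
    return {
        "features": {
            "composition": features.composition,
            "echogenicity": features.echogenicity,
            "shape": features.shape,
            "margin": features.margin,
            "foci": sorted(features.foci),
            "max_diameter_mm": features.max_diameter_mm,
        },
        "points": {
            "composition": breakdown.composition_pts,
            "echogenicity": breakdown.echogenicity_pts,
            "shape": breakdown.shape_pts,
            "margin": breakdown.margin_pts,
            "foci": breakdown.foci_pts,
        },
        "total": breakdown.total_pts,
        "tr_level": result.tr_level,
        "suspicion_pct": result.suspicion_pct,
        "recommendation": result.recommendation,
    }
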