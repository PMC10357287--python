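"""CSI / SFAR scoring and the two-step classification tree.

The Cedars-Sinai Index (CSI) condenses the three strongest anatomical
predictors of an iliofemoral vascular complication into one number::

    CSI = SOA × NOC / MLD

where SOA is the sum of curve angles (degrees), NOC the number of curves
and MLD the minimal lumen diameter (mm).  SFAR is the sheath outer
diameter divided by MLD.  The final prediction model is an ordered rule
list: a patient is high risk if SFAR exceeds 1.00 (first step) or,
failing that, if CSI exceeds 100 (second step); both thresholds are
strict, so boundary values are low risk.  The (SFAR, CSI) plane is also
partitioned into four quadrants used to attribute the anatomical cause
of a complication.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

from .centerline_geometry import (Centerline, LumenSummary,
                                  TortuosityProfile, analyze)
from .errors import InvalidInputError
from .plaque import CalcCategory, Plaque

SFAR_THRESHOLD = 1.00
CSI_THRESHOLD = 100.0

#: Approximate outer diameters (mm) of common large-bore TAVR sheaths by
#: French size, for callers who only know the device label.  SFAR is
#: defined on the *outer* diameter, which exceeds the nominal French
#: (inner) size.
FRENCH_OUTER_DIAMETER_MM = {
    14: 5.4, 15: 5.7, 16: 6.0, 18: 6.7, 20: 7.3,
}


@dataclass(frozen=True)
class RiskInputs:
    """Per-patient measurements feeding the score."""

    soa: float  # degrees
    noc: int
    mld: float  # mm
    sheath_outer_diameter: float  # mm
    calc_category: Optional[CalcCategory] = None
    ift: Optional[float] = None  # percent

    def __post_init__(self):
        if self.mld <= 0:
            raise InvalidInputError(f"MLD must be > 0 mm, got {self.mld}")
        if self.sheath_outer_diameter <= 0:
            raise InvalidInputError("sheath outer diameter must be > 0 mm")
        if self.noc < 0 or self.soa < 0:
            raise InvalidInputError("NOC and SOA must be nonnegative")


@dataclass(frozen=True)
class TreeModel:
    """Ordered high-risk rules; the first satisfied rule classifies.

    Each rule is ``(feature, threshold, direction)`` with direction
    ``'>'`` or ``'<='``; a patient matching no rule is low risk.
    """

    rules: tuple = (("sfar", SFAR_THRESHOLD, ">"),
                    ("csi", CSI_THRESHOLD, ">"))

    def __post_init__(self):
        for rule in self.rules:
            feat, thr, direction = rule
            if direction not in (">", "<="):
                raise InvalidInputError(f"bad rule direction {direction!r}")
        object.__setattr__(self, "rules", tuple(map(tuple, self.rules)))

    def evaluate(self, features: dict):
        """Return ``(high_risk, triggering_step)``; step is the feature
        name of the first satisfied rule (``'<feature>_step'``) or
        ``'none'``."""
        for feat, thr, direction in self.rules:
            if feat not in features:
                raise InvalidInputError(f"missing feature {feat!r}")
            v = features[feat]
            hit = v > thr if direction == ">" else v <= thr
            if hit:
                return True, f"{feat}_step"
        return False, "none"


#: The published two-step model: SFAR > 1.00 first, CSI > 100 second.
DEFAULT_TREE = TreeModel()


@dataclass(frozen=True)
class RiskAssessment:
    """Scored patient: indices, prediction and quadrant."""

    csi: float
    sfar: float
    predicted: str  # 'high_risk' | 'low_risk'
    triggering_step: str  # 'sfar_step' | 'csi_step' | 'none'
    quadrant: str  # 'QI'..'QIV'
    calc_category: Optional[CalcCategory] = None
    profile: Optional[TortuosityProfile] = None
    lumen: Optional[LumenSummary] = None


def csi_score(soa: float, noc: float, mld: float) -> float:
    """Cedars-Sinai Index: SOA × NOC / MLD.

    ``noc`` is an integer count for a single patient; fractional values
    are accepted for group-mean arithmetic.
    """
    if mld <= 0:
        raise InvalidInputError(f"MLD must be > 0 mm, got {mld}")
    return soa * noc / mld


def sfar(sheath_outer_diameter: float, mld: float) -> float:
    """Sheath-to-femoral-artery ratio: sheath outer diameter / MLD."""
    if sheath_outer_diameter <= 0 or mld <= 0:
        raise InvalidInputError("sheath outer diameter and MLD must be > 0")
    return sheath_outer_diameter / mld


def quadrant(sfar_value: float, csi_value: float) -> str:
    """Quadrant of the (SFAR, CSI) plane at thresholds 1.00 / 100.

    QI: both at or below threshold (event-free region); QII: SFAR high
    only; QIII: both high; QIV: CSI high only (the most common IVC
    anatomy).
    """
    s_hi = sfar_value > SFAR_THRESHOLD
    c_hi = csi_value > CSI_THRESHOLD
    if s_hi and c_hi:
        return "QIII"
    if s_hi:
        return "QII"
    if c_hi:
        return "QIV"
    return "QI"


def classify(inputs: RiskInputs,
             model: TreeModel = DEFAULT_TREE) -> RiskAssessment:
    """Apply the ordered-rule model to one patient's measurements."""
    csi_value = csi_score(inputs.soa, inputs.noc, inputs.mld)
    sfar_value = sfar(inputs.sheath_outer_diameter, inputs.mld)
    features = {
        "csi": csi_value,
        "sfar": sfar_value,
        "soa": inputs.soa,
        "noc": inputs.noc,
        "mld": inputs.mld,
    }
    if inputs.calc_category is not None:
        features["calc_category"] = int(inputs.calc_category)
    if inputs.ift is not None:
        features["ift"] = inputs.ift
    high, step = model.evaluate(features)
    return RiskAssessment(csi=csi_value, sfar=sfar_value,
                          predicted="high_risk" if high else "low_risk",
                          triggering_step=step,
                          quadrant=quadrant(sfar_value, csi_value),
                          calc_category=inputs.calc_category)


def assess_patient(centerline: Centerline, plaques: Sequence[Plaque],
                   sheath_outer_diameter: float,
                   model: TreeModel = DEFAULT_TREE,
                   **analyze_kwargs) -> RiskAssessment:
    """End-to-end risk assessment from raw geometry.

    Runs curve detection and the tortuosity profile on the (resampled,
    wall-aligned) centerline, takes the lumen summary on the original
    sections, grades the worst plaque, computes CSI and SFAR and applies
    the rule model.  Deterministic for a fixed configuration.
    """
    prof, lum, curves, _ = analyze(centerline, **analyze_kwargs)
    category = None
    if plaques:
        category = CalcCategory(max(int(p.category) for p in plaques))
    inputs = RiskInputs(soa=prof.sum_of_angles, noc=prof.n_curves,
                        mld=lum.mld,
                        sheath_outer_diameter=sheath_outer_diameter,
                        calc_category=category, ift=prof.ift)
    assessment = classify(inputs, model=model)
    return RiskAssessment(csi=assessment.csi, sfar=assessment.sfar,
                          predicted=assessment.predicted,
                          triggering_step=assessment.triggering_step,
                          quadrant=assessment.quadrant,
                          calc_category=category, profile=prof, lumen=lum)
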