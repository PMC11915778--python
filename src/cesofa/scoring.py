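"""SOFA component scoring, ordinal point schemes and the CE-SOFA composite.

The base SOFA score sums six organ-system sub-scores (0-4 each, total 0-24).
Five sub-scores (neurological, respiratory, renal, hepatic, coagulation) are
taken from the record; the cardiovascular sub-score is recomputed here from
MAP and vasoactive therapy using the original SOFA tier table.

A cardiac extension adds ordinal "point groups": a continuous biomarker is
binned by ascending thresholds into 0..k points, a binary AF flag maps to a
fixed point value, and each point group carries an integer weight multiplier.
The shipped default CE-SOFA model is base SOFA + hs-cTnT-points (0-4) +
NT-proBNP-points (0-4) + double AF-points (0 or 4), range 0-36.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import yaml

from .cohort import Cohort, PatientRecord, derive_hemodynamics

__all__ = [
    "OrdinalPointScheme",
    "ScoreModel",
    "cardiovascular_sofa",
    "assign_points",
    "total_sofa",
    "composite_score",
    "score_cohort",
    "ctnt_elevated",
    "load_score_model",
    "save_score_model",
    "default_ce_sofa_model",
    "CTNT_ELEVATED_CUTOFF",
]

#: hs-cTnT level defined as "elevated" (convenience annotation, not a cut-off).
CTNT_ELEVATED_CUTOFF = 15.0  # ng/L


@dataclass(frozen=True)
class OrdinalPointScheme:
    """Maps one variable to weighted ordinal points.

    Continuous schemes bin by ``thresholds`` (ascending, left-closed: a value
    equal to a threshold enters the upper bin), yielding base points
    ``0..len(thresholds)``. Binary schemes (AF) assign ``binary_points`` when
    the flag is set, else 0. ``weight`` multiplies the base points.

    ``transform`` records the scale on which the thresholds were derived
    ('identity' or 'log'); because the log is strictly increasing, binning is
    performed on the original scale either way.
    """

    variable: str
    thresholds: tuple[float, ...] = ()
    transform: str = "identity"
    weight: int = 1
    binary: bool = False
    binary_points: int = 2

    def __post_init__(self):
        if self.transform not in ("identity", "log"):
            raise ValueError(f"unknown transform {self.transform!r}")
        if self.weight not in (1, 2, 3):
            raise ValueError(f"weight must be 1, 2 or 3; got {self.weight}")
        if self.binary:
            if self.thresholds:
                raise ValueError("binary scheme takes no thresholds")
        else:
            t = np.asarray(self.thresholds, dtype=float)
            if t.size == 0:
                raise ValueError("continuous scheme needs at least one threshold")
            if not np.all(np.diff(t) > 0):
                raise ValueError(f"thresholds must be strictly increasing: {self.thresholds}")

    @property
    def max_base_points(self) -> int:
        return self.binary_points if self.binary else len(self.thresholds)

    @property
    def max_points(self) -> int:
        return self.max_base_points * self.weight

    def reweighted(self, weight: int) -> "OrdinalPointScheme":
        return OrdinalPointScheme(
            variable=self.variable,
            thresholds=self.thresholds,
            transform=self.transform,
            weight=weight,
            binary=self.binary,
            binary_points=self.binary_points,
        )


def assign_points(value: float, scheme: OrdinalPointScheme) -> int:
    """Weighted ordinal points for one value under one scheme.

    Continuous: bin index by thresholds (value < t1 -> 0, value >= t_k ->
    bin k), times weight. Binary: presence -> binary_points * weight.
    """
    if scheme.binary:
        return scheme.binary_points * scheme.weight if value else 0
    if not np.isfinite(value):
        raise ValueError(f"{scheme.variable}: value must be finite, got {value}")
    base = int(np.searchsorted(np.asarray(scheme.thresholds, dtype=float), value, side="right"))
    return base * scheme.weight


def cardiovascular_sofa(
    map_mmhg: float,
    dopamine: float = 0.0,
    norepinephrine: float = 0.0,
    other_vasoactive: bool = False,
) -> int:
    """Cardiovascular SOFA sub-score (0-4) from MAP and vasoactive therapy.

    Tier table of the original SOFA definition; doses in ug/kg/min, highest
    applicable tier wins. ``other_vasoactive`` covers dobutamine at any dose
    (tier 2); epinephrine/vasopressin dialects collapse onto the
    norepinephrine tier by dose upstream.
    """
    if dopamine < 0 or norepinephrine < 0:
        raise ValueError("vasoactive doses must be non-negative")
    if dopamine > 15 or norepinephrine > 0.1:
        return 4
    if dopamine > 5 or norepinephrine > 0:
        return 3
    if dopamine > 0 or other_vasoactive:
        return 2
    if map_mmhg < 70:
        return 1
    return 0


def total_sofa(components) -> int:
    """Sum of the six SOFA sub-scores (each an integer 0-4; total 0-24)."""
    comps = list(components)
    if len(comps) != 6:
        raise ValueError(f"expected 6 sub-scores, got {len(comps)}")
    for c in comps:
        if not (float(c).is_integer() and 0 <= c <= 4):
            raise ValueError(f"sub-score out of range [0, 4]: {c}")
    return int(sum(comps))


@dataclass(frozen=True)
class ScoreModel:
    """Base SOFA plus a set of weighted point schemes; evaluates to an integer."""

    name: str
    schemes: tuple[OrdinalPointScheme, ...] = ()
    includes_base_sofa: bool = True

    @property
    def max_score(self) -> int:
        base = 24 if self.includes_base_sofa else 0
        return base + sum(s.max_points for s in self.schemes)

    @property
    def added_max_points(self) -> int:
        return sum(s.max_points for s in self.schemes)


#: The base SOFA score as a degenerate extension model (no schemes).
BASE_SOFA = ScoreModel(name="SOFA", schemes=())


def record_sofa(record: PatientRecord) -> int:
    """Total SOFA for a record: five stored sub-scores + computed cardiovascular."""
    cv = cardiovascular_sofa(
        record.hemodynamics.map,
        dopamine=record.dopamine_dose,
        norepinephrine=record.norepinephrine_dose,
        other_vasoactive=record.other_vasoactive,
    )
    return total_sofa(
        [record.sofa_neuro, record.sofa_resp, record.sofa_renal,
         record.sofa_hepatic, record.sofa_coag, cv]
    )


def _scheme_value(record: PatientRecord, scheme: OrdinalPointScheme) -> float:
    if scheme.binary or scheme.variable == "af":
        return float(record.has_af)
    if scheme.variable in ("map", "pp", "rpp", "ppp"):
        return getattr(record.hemodynamics, scheme.variable)
    try:
        return float(getattr(record, scheme.variable))
    except AttributeError:
        raise KeyError(f"scheme references missing field {scheme.variable!r}") from None


def composite_score(record: PatientRecord, model: ScoreModel) -> int:
    """Composite integer score: base SOFA (if included) plus all scheme points."""
    score = record_sofa(record) if model.includes_base_sofa else 0
    for scheme in model.schemes:
        score += assign_points(_scheme_value(record, scheme), scheme)
    return score


def score_cohort(cohort: Cohort, model: ScoreModel) -> np.ndarray:
    """Composite score for every record, in cohort order."""
    return np.array([composite_score(r, model) for r in cohort], dtype=int)


def ctnt_elevated(hs_ctnt: float) -> bool:
    """Elevated hs-cTnT annotation (>= 15 ng/L); informational only."""
    return hs_ctnt >= CTNT_ELEVATED_CUTOFF


# ---------------------------------------------------------------------------
# Model definition files (YAML)

def _scheme_to_dict(s: OrdinalPointScheme) -> dict:
    d: dict = {"variable": s.variable, "weight": s.weight}
    if s.binary:
        d["binary"] = True
        d["binary_points"] = s.binary_points
    else:
        d["transform"] = s.transform
        d["thresholds"] = [float(t) for t in s.thresholds]
    return d


def _scheme_from_dict(d: dict) -> OrdinalPointScheme:
    if d.get("binary"):
        return OrdinalPointScheme(
            variable=d["variable"],
            binary=True,
            binary_points=int(d.get("binary_points", 2)),
            weight=int(d.get("weight", 1)),
        )
    return OrdinalPointScheme(
        variable=d["variable"],
        thresholds=tuple(float(t) for t in d["thresholds"]),
        transform=d.get("transform", "identity"),
        weight=int(d.get("weight", 1)),
    )


def save_score_model(model: ScoreModel, path) -> None:
    doc = {
        "name": model.name,
        "includes_base_sofa": model.includes_base_sofa,
        "schemes": [_scheme_to_dict(s) for s in model.schemes],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_score_model(path) -> ScoreModel:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return ScoreModel(
        name=doc["name"],
        schemes=tuple(_scheme_from_dict(d) for d in doc.get("schemes", [])),
        includes_base_sofa=bool(doc.get("includes_base_sofa", True)),
    )


def default_ce_sofa_model() -> ScoreModel:
    """The shipped CE-SOFA model: SOFA + cTnT-points + BNP-points + double AF.

    Thresholds in the shipped file are synthetic defaults (quantiles of the
    synthetic-cohort biomarker distributions); re-derive them on your own
    training cohort with :mod:`cesofa.derivation` for real use.
    """
    ref = importlib.resources.files("cesofa").joinpath("data/ce_sofa_default.yaml")
    with importlib.resources.as_file(ref) as path:
        return load_score_model(path)
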