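"""Bundled worked example: transfemoral TAVI versus SAVR.

For adults with symptomatic severe aortic stenosis, pooled randomized
evidence comparing transcatheter aortic valve implantation (TAVI) with
surgical aortic valve replacement (SAVR) shows neither option dominating:
TAVI reduces mortality (~3 percentage points), stroke (~2), acute kidney
injury (~5), life-threatening bleeding (~24), new-onset atrial
fibrillation (~18) and index-admission length (~3 days), while increasing
heart-failure symptoms (~6 points), permanent pacemaker insertion (~15)
and short-term aortic valve reintervention (~1).

This module turns those published effect differences into a complete
:class:`~decisio.model.DecisionModel`: seven locked evidence criteria plus
three user-rated practical considerations, ten criteria in all.  Because
the published evidence reports *differences* between the options rather
than absolute performances, ratings are derived with a reference-anchored
value function: SAVR sits at the 0.5 midpoint on every evidence criterion
and TAVI at ``0.5 + 0.5 * benefit`` where ``benefit`` is TAVI's signed
advantage as a proportion (admission length is converted to a proportion
of a 30-day horizon).  This preserves the sign and relative size of every
published difference while keeping all ratings well inside [0, 1].

Caveats, flagged in model metadata: which seven of the nine published
effects are featured, the names of the three practical considerations and
the per-outcome certainty grades are editorial defaults here (the source
figures are not machine-readable); age-specific mortality/stroke effects
are supported only as explicit overrides, never fabricated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np

from .config import DISCLAIMER
from .model import (
    Certainty,
    Criterion,
    DecisionModel,
    ModelError,
    Option,
    Polarity,
    Source,
    ValueFunctionSpec,
)

__all__ = [
    "EvidenceEffect",
    "AgeGroup",
    "FixtureOverrides",
    "build_evidence_table",
    "derive_ratings",
    "build_model",
    "DEFAULT_EVIDENCE_CRITERIA",
    "USER_CRITERIA",
]

log = logging.getLogger(__name__)

PCT = "pct_points"
DAYS = "days"


@dataclass(frozen=True)
class EvidenceEffect:
    """One published TAVI-minus-SAVR effect difference on the harm scale.

    ``effect`` is signed TAVI minus SAVR in ``units`` (percentage points
    of absolute risk, or days), on a scale where *more is worse*; the
    option favoured follows from the sign, so data-entry slips are
    detectable.
    """

    outcome: str
    description: str
    effect: float
    units: str

    @property
    def favours(self) -> str:
        return "TAVI" if self.effect < 0 else "SAVR"


_EVIDENCE: tuple[tuple[str, str, float, str], ...] = (
    ("mortality", "Death from any cause", -3.0, PCT),
    ("stroke", "Stroke", -2.0, PCT),
    ("aki", "Acute kidney injury", -5.0, PCT),
    ("bleeding", "Life-threatening or disabling bleeding", -24.0, PCT),
    ("afib", "New-onset atrial fibrillation", -18.0, PCT),
    ("admission", "Duration of index admission", -3.0, DAYS),
    ("heart_failure", "Symptoms of heart failure", 6.0, PCT),
    ("pacemaker", "Permanent pacemaker insertion", 15.0, PCT),
    ("reintervention", "Aortic valve reintervention, short term", 1.0, PCT),
)

#: Default featured evidence criteria (7 of the 9 published effects).
#: Acute kidney injury and admission length are available via overrides.
DEFAULT_EVIDENCE_CRITERIA: tuple[str, ...] = (
    "mortality",
    "stroke",
    "bleeding",
    "afib",
    "heart_failure",
    "pacemaker",
    "reintervention",
)

#: Editable placeholder labels for the three user-rated practical criteria.
USER_CRITERIA: tuple[tuple[str, str], ...] = (
    ("avoid_open_heart", "Avoiding open-heart surgery"),
    ("recovery_burden", "Burden of recovery"),
    ("valve_durability", "Concern about long-term valve durability"),
)


class AgeGroup(str, Enum):
    """The four age strata the decision is presented for."""

    UNDER_65 = "under_65"
    FROM_65_UNDER_75 = "65_to_75"
    FROM_75_UNDER_85 = "75_to_85"
    OVER_85 = "over_85"


def build_evidence_table() -> list[EvidenceEffect]:
    """The nine published TAVI-minus-SAVR effect differences."""
    return [EvidenceEffect(*row) for row in _EVIDENCE]


def derive_ratings(
    effects: Sequence[EvidenceEffect],
    reference_rating: float = 0.5,
    scale: float = 0.5,
    admission_horizon_days: float = 30.0,
) -> dict[str, tuple[float, float]]:
    """Reference-anchored (TAVI, SAVR) rating pairs from effect differences.

    SAVR anchors every criterion at ``reference_rating``; TAVI is placed
    at ``reference_rating + scale * benefit`` with ``benefit`` TAVI's
    signed advantage as a proportion (percentage points / 100, or days
    over the admission horizon).  Ratings falling outside [0, 1] are
    clipped with a logged warning; with the default scale the largest
    published difference (bleeding, 0.24) stays well inside the range.
    """
    if admission_horizon_days <= 0:
        raise ModelError("admission horizon must be positive")
    out: dict[str, tuple[float, float]] = {}
    for e in effects:
        if e.units == PCT:
            benefit = -e.effect / 100.0
        elif e.units == DAYS:
            benefit = -e.effect / admission_horizon_days
        else:
            raise ModelError(f"unknown units {e.units!r} for {e.outcome!r}")
        tavi = reference_rating + scale * benefit
        clipped = float(np.clip(tavi, 0.0, 1.0))
        if clipped != tavi:
            log.warning(
                "rating for %s clipped from %.4f to %.4f", e.outcome, tavi, clipped
            )
        savr = float(np.clip(reference_rating, 0.0, 1.0))
        if (clipped - savr) * (-e.effect) < 0:
            raise ModelError(
                f"derived ratings for {e.outcome!r} contradict the favoured option"
            )
        out[e.outcome] = (clipped, savr)
    return out


@dataclass(frozen=True)
class FixtureOverrides:
    """Optional departures from the default bundled model.

    ``evidence_criteria`` replaces the featured selection (any subset of
    the nine published outcomes, in the order given); ``effects`` replaces
    published effect values, e.g. age-specific mortality/stroke estimates
    when the user has them; ``certainty`` replaces per-criterion GRADE
    levels; ``user_labels`` renames the three practical criteria.
    """

    evidence_criteria: Optional[tuple[str, ...]] = None
    effects: Mapping[str, float] = field(default_factory=dict)
    certainty: Mapping[str, Certainty | str] = field(default_factory=dict)
    user_labels: Mapping[str, str] = field(default_factory=dict)


def build_model(
    age_group: AgeGroup | str = AgeGroup.FROM_65_UNDER_75,
    overrides: Optional[FixtureOverrides] = None,
    reference_rating: float = 0.5,
    scale: float = 0.5,
    admission_horizon_days: float = 30.0,
) -> DecisionModel:
    """Assemble the bundled two-option, ten-criterion decision model.

    The model has options TAVI and SAVR; seven locked, evidence-sourced
    criteria (moderate certainty by default) and three unlocked user
    criteria (high certainty — the person is the authority on their own
    practical considerations) initialised to 0.5 for both options.  The
    age group is recorded in metadata; it changes the bundled numbers only
    through explicit effect overrides, since age-specific estimates are
    not published in the bundled source.
    """
    age = AgeGroup(age_group)
    ov = overrides or FixtureOverrides()

    table = {e.outcome: e for e in build_evidence_table()}
    for outcome, value in ov.effects.items():
        if outcome not in table:
            raise ModelError(f"effect override for unknown outcome {outcome!r}")
        old = table[outcome]
        table[outcome] = EvidenceEffect(old.outcome, old.description, float(value), old.units)

    selection = tuple(ov.evidence_criteria or DEFAULT_EVIDENCE_CRITERIA)
    for outcome in selection:
        if outcome not in table:
            raise ModelError(f"unknown evidence criterion {outcome!r}")
    if len(set(selection)) != len(selection):
        raise ModelError("duplicate evidence criterion in selection")

    certainty: dict[str, Certainty] = {c: Certainty.MODERATE for c in selection}
    user_ids = [cid for cid, _ in USER_CRITERIA]
    certainty.update({cid: Certainty.HIGH for cid in user_ids})
    for cid, level in ov.certainty.items():
        if cid not in certainty:
            raise ModelError(f"certainty override for unknown criterion {cid!r}")
        certainty[cid] = Certainty(level)
    for cid in ov.user_labels:
        if cid not in user_ids:
            raise ModelError(f"label override for unknown user criterion {cid!r}")

    ratings_by_outcome = derive_ratings(
        [table[o] for o in selection],
        reference_rating=reference_rating,
        scale=scale,
        admission_horizon_days=admission_horizon_days,
    )

    criteria: list[Criterion] = []
    tavi_row: list[float] = []
    savr_row: list[float] = []
    for outcome in selection:
        e = table[outcome]
        criteria.append(
            Criterion(
                id=outcome,
                label=e.description,
                polarity=Polarity.HARM,
                locked=True,
                certainty=certainty[outcome],
                source=Source.EVIDENCE,
                value_function=ValueFunctionSpec(
                    kind="reference_anchored",
                    reference_rating=reference_rating,
                    scale=scale,
                    units="proportion",
                ),
            )
        )
        t, s = ratings_by_outcome[outcome]
        tavi_row.append(t)
        savr_row.append(s)
    for cid, label in USER_CRITERIA:
        criteria.append(
            Criterion(
                id=cid,
                label=ov.user_labels.get(cid, label),
                polarity=Polarity.BENEFIT,
                locked=False,
                certainty=certainty[cid],
                source=Source.USER,
                value_function=ValueFunctionSpec(kind="identity"),
            )
        )
        tavi_row.append(0.5)
        savr_row.append(0.5)

    metadata = {
        "title": "TAVI vs SAVR for symptomatic severe aortic stenosis",
        "age_group": age.value,
        "disclaimer": DISCLAIMER,
        "evidence": [
            {
                "outcome": e.outcome,
                "description": e.description,
                "effect_tavi_minus_savr": e.effect,
                "units": e.units,
                "favours": e.favours,
            }
            for e in table.values()
        ],
        "notes": [
            "Featured criteria selection, practical-consideration labels and "
            "per-outcome certainty grades are editable defaults, not published "
            "values.",
            "Age group changes the numbers only via explicit effect overrides; "
            "no age-specific estimates are bundled.",
            "User criteria start at the neutral rating 0.5 for both options "
            "until the person supplies their own.",
        ],
    }
    return DecisionModel(
        options=(Option("TAVI", "Transcatheter aortic valve implantation"),
                 Option("SAVR", "Surgical aortic valve replacement")),
        criteria=tuple(criteria),
        ratings=np.array([tavi_row, savr_row]),
        metadata=metadata,
    )
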