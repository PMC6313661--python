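"""Expected-value scoring with GRADE certainty adjustment.

The core of value-based compensatory MCDA: each option's score is the
weighted sum of its ratings,

    S_o = sum_k w_k * r_ok,

with normalized weights ``w`` and ratings ``r`` in [0, 1], so scores also
lie in [0, 1].  Certainty adjustment down-weights criteria whose evidence
is less certain via a per-level multiplier ``c_k`` (defaults: very_low 0.1,
low 0.4, moderate 0.7, high 1.0).  Two adjustment modes are offered:

``multiplicative``
    S'_o = sum_k w_k * c_k * r_ok — the most literal reading of "mapping
    certainty onto the 0-1 scale"; uncertain ratings are pulled toward 0.
``shrink_to_neutral``
    S'_o = sum_k w_k * (c_k * r_ok + (1 - c_k) * 0.5) — uncertain ratings
    are pulled toward the neutral midpoint 0.5 instead, which avoids
    penalising high ratings asymmetrically.

Both modes leave the unadjusted scores untouched and return the pair, so
the effect of the adjustment is always visible side by side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .config import DEFAULT_ADJUSTMENT_MODE, DEFAULT_CERTAINTY_MULTIPLIERS
from .model import (
    Certainty,
    DecisionModel,
    DimensionMismatchError,
    ModelError,
    Polarity,
    ValueFunctionSpec,
    WeightSet,
    validate_model,
)

__all__ = [
    "OptionScores",
    "DominanceResult",
    "certainty_multiplier",
    "apply_value_function",
    "expected_value_scores",
    "certainty_adjusted_scores",
    "effective_ratings",
    "dominance_check",
]

#: Scores closer than this are reported as ties, never silently ordered.
TIE_TOL = 1e-9

_MODES = ("multiplicative", "shrink_to_neutral")


def certainty_multiplier(
    level: Certainty | str,
    mapping: Optional[Mapping[str, float]] = None,
) -> float:
    """Numeric multiplier for a GRADE certainty level.

    The default mapping is very_low=0.1, low=0.4, moderate=0.7, high=1.0;
    a custom mapping may be supplied but must cover all four levels with
    values in [0, 1].
    """
    mapping = dict(DEFAULT_CERTAINTY_MULTIPLIERS if mapping is None else mapping)
    key = level.value if isinstance(level, Certainty) else str(level)
    if key not in {c.value for c in Certainty}:
        raise ModelError(f"unknown certainty level {key!r}")
    if key not in mapping:
        raise ModelError(f"certainty mapping has no entry for {key!r}")
    m = float(mapping[key])
    if not 0.0 <= m <= 1.0:
        raise ModelError(f"certainty multiplier {m} for {key!r} outside [0, 1]")
    return m


def apply_value_function(
    raw: float,
    spec: ValueFunctionSpec,
    polarity: Polarity = Polarity.BENEFIT,
    units: Optional[str] = None,
) -> float:
    """Convert a raw performance value to a [0, 1] rating.

    ``units`` (when given) must match the spec's units; mismatches are an
    error rather than a silent unit bug.  All outputs are clipped to
    [0, 1].
    """
    if units is not None and spec.units is not None and units != spec.units:
        raise ModelError(f"units mismatch: raw in {units!r}, spec in {spec.units!r}")
    if not math.isfinite(raw):
        raise ModelError("raw value must be finite")
    if spec.kind == "identity":
        return float(np.clip(raw, 0.0, 1.0))
    if spec.kind == "one_minus_risk":
        if polarity is not Polarity.HARM:
            raise ModelError("one_minus_risk applies to harm (event-risk) criteria")
        if not 0.0 <= raw <= 1.0:
            raise ModelError(f"event probability {raw} outside [0, 1]")
        return 1.0 - raw
    if spec.kind == "linear_anchor":
        assert spec.worst_raw is not None and spec.best_raw is not None
        t = (raw - spec.worst_raw) / (spec.best_raw - spec.worst_raw)
        return float(np.clip(t, 0.0, 1.0))
    # reference_anchored: raw is the signed benefit over the reference
    return float(np.clip(spec.reference_rating + spec.scale * raw, 0.0, 1.0))


@dataclass(frozen=True)
class OptionScores:
    """Paired unadjusted and certainty-adjusted expected-value scores.

    ``contributions[o, k]`` is the term ``w_k * r_ok`` of option *o*'s
    unadjusted score (``adjusted_contributions`` likewise for the adjusted
    score), so each score decomposes exactly into its per-criterion parts.
    ``model_hash`` ties the scores to the model state they were computed
    from; report rendering refuses stale scores.
    """

    option_ids: tuple[str, ...]
    unadjusted: np.ndarray
    contributions: np.ndarray
    weights: np.ndarray
    model_hash: str
    adjusted: Optional[np.ndarray] = None
    adjusted_contributions: Optional[np.ndarray] = None
    adjustment_mode: Optional[str] = None
    certainty_mapping: Optional[dict[str, float]] = None

    def preferred(self, adjusted: bool = False) -> Optional[str]:
        """Best-scoring option id, or ``None`` on a tie (within 1e-9)."""
        s = self._scores(adjusted)
        order = np.argsort(s)[::-1]
        if len(order) > 1 and s[order[0]] - s[order[1]] <= TIE_TOL:
            return None
        return self.option_ids[order[0]]

    def _scores(self, adjusted: bool) -> np.ndarray:
        if adjusted:
            if self.adjusted is None:
                raise ModelError("adjusted scores were not computed")
            return self.adjusted
        return self.unadjusted

    def as_dict(self, adjusted: bool = False) -> dict[str, float]:
        s = self._scores(adjusted)
        return {oid: float(v) for oid, v in zip(self.option_ids, s)}


def _check_inputs(model: DecisionModel, weights: WeightSet) -> np.ndarray:
    violations = validate_model(model)
    if violations:
        raise ModelError(
            "model fails validation: " + "; ".join(str(v) for v in violations)
        )
    if len(weights) != model.n_criteria:
        raise DimensionMismatchError(
            f"{len(weights)} weights for {model.n_criteria} criteria"
        )
    if weights.criterion_ids is not None and weights.criterion_ids != model.criterion_ids:
        raise DimensionMismatchError(
            "weight criterion ids do not match the model's criteria"
        )
    return weights.normalized


def expected_value_scores(model: DecisionModel, weights: WeightSet) -> OptionScores:
    """Unadjusted expected-value scores S_o = sum_k w_k * r_ok."""
    w = _check_inputs(model, weights)
    contrib = model.ratings * w[np.newaxis, :]
    return OptionScores(
        option_ids=model.option_ids,
        unadjusted=contrib.sum(axis=1),
        contributions=contrib,
        weights=w,
        model_hash=model.content_hash(),
    )


def _multipliers(
    model: DecisionModel, mapping: Optional[Mapping[str, float]]
) -> np.ndarray:
    return np.array(
        [certainty_multiplier(c.certainty, mapping) for c in model.criteria]
    )


def effective_ratings(
    model: DecisionModel,
    mode: str = DEFAULT_ADJUSTMENT_MODE,
    mapping: Optional[Mapping[str, float]] = None,
) -> np.ndarray:
    """Ratings after certainty adjustment, per the chosen mode.

    Scoring the adjusted model is the same weighted sum applied to these
    effective ratings, which is what sensitivity analyses exploit.
    """
    if mode not in _MODES:
        raise ModelError(f"unknown adjustment mode {mode!r}")
    c = _multipliers(model, mapping)
    r = model.ratings
    if mode == "multiplicative":
        return r * c[np.newaxis, :]
    return r * c[np.newaxis, :] + 0.5 * (1.0 - c)[np.newaxis, :]


def certainty_adjusted_scores(
    model: DecisionModel,
    weights: WeightSet,
    mode: str = DEFAULT_ADJUSTMENT_MODE,
    mapping: Optional[Mapping[str, float]] = None,
) -> OptionScores:
    """Both score sets: unadjusted S_o and certainty-adjusted S'_o.

    The pair is always returned together so the effect of the adjustment
    is visible; ``mode`` selects how the multiplier enters (see module
    docstring).
    """
    w = _check_inputs(model, weights)
    if mode not in _MODES:
        raise ModelError(f"unknown adjustment mode {mode!r}")
    contrib = model.ratings * w[np.newaxis, :]
    r_eff = effective_ratings(model, mode=mode, mapping=mapping)
    adj_contrib = r_eff * w[np.newaxis, :]
    used = dict(DEFAULT_CERTAINTY_MULTIPLIERS if mapping is None else mapping)
    return OptionScores(
        option_ids=model.option_ids,
        unadjusted=contrib.sum(axis=1),
        contributions=contrib,
        weights=w,
        model_hash=model.content_hash(),
        adjusted=adj_contrib.sum(axis=1),
        adjusted_contributions=adj_contrib,
        adjustment_mode=mode,
        certainty_mapping={k: float(v) for k, v in used.items()},
    )


@dataclass(frozen=True)
class DominanceResult:
    """Outcome of a pairwise dominance check between two options.

    ``dominant_option`` is set iff that option rates at least as well on
    every criterion and strictly better on at least one; no weighting can
    then prefer the other option.  ``comparisons`` records, per criterion
    in model order, which of the pair rates better (``first_better``,
    ``second_better`` or ``tie``).
    """

    first: str
    second: str
    dominant_option: Optional[str]
    comparisons: tuple[str, ...]


def dominance_check(
    model: DecisionModel, pair: Optional[tuple[str, str]] = None
) -> DominanceResult:
    """Check whether one option of a pair dominates the other.

    With exactly two options the pair defaults to them; for larger models
    pass the pair of option ids explicitly.
    """
    if pair is None:
        if model.n_options != 2:
            raise ModelError(
                "dominance_check needs a 2-option model or an explicit pair"
            )
        pair = (model.option_ids[0], model.option_ids[1])
    i, j = (model.option_index(pair[0]), model.option_index(pair[1]))
    a, b = model.ratings[i], model.ratings[j]
    comps = tuple(
        "first_better" if x > y else "second_better" if y > x else "tie"
        for x, y in zip(a, b)
    )
    dominant: Optional[str] = None
    if np.all(a >= b) and np.any(a > b):
        dominant = pair[0]
    elif np.all(b >= a) and np.any(b > a):
        dominant = pair[1]
    return DominanceResult(
        first=pair[0], second=pair[1], dominant_option=dominant, comparisons=comps
    )
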