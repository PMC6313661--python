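"""Core domain types for multi-criteria decision models.

A :class:`DecisionModel` holds a small set of options (treatments,
strategies) rated against a set of criteria (outcomes, practical
considerations).  Ratings live on a [0, 1] scale where 1 is best; each
criterion carries a GRADE certainty level for the evidence behind its
ratings, and criteria whose ratings come from collated evidence can be
*locked* so that an elicitation session cannot edit them.

Models are value objects: updates (e.g. a user supplying a personal rating)
return a new model and leave the original untouched, so an elicitation
session can be replayed or logged step by step.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np

__all__ = [
    "Certainty",
    "Polarity",
    "Source",
    "ValueFunctionSpec",
    "Criterion",
    "Option",
    "DecisionModel",
    "WeightSet",
    "Violation",
    "ModelError",
    "LockedRatingError",
    "RatingRangeError",
    "DegenerateWeightsError",
    "WeightValidationError",
    "DimensionMismatchError",
    "normalize_weights",
    "set_user_rating",
    "validate_model",
]


class ModelError(ValueError):
    """Base class for decision-model errors."""


class LockedRatingError(ModelError):
    """Raised on an attempt to edit a locked (evidence-sourced) rating."""


class RatingRangeError(ModelError):
    """Raised when a rating falls outside [0, 1]."""


class DegenerateWeightsError(ModelError):
    """Raised when a weight vector has zero total mass."""


class WeightValidationError(ModelError):
    """Raised for negative or otherwise invalid weight entries."""


class DimensionMismatchError(ModelError):
    """Raised when weights, samples or ratings disagree on dimension."""


class Certainty(str, Enum):
    """GRADE certainty-of-evidence levels, lowest to highest."""

    VERY_LOW = "very_low"
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"


class Polarity(str, Enum):
    """Whether larger *raw* values on a criterion are good or bad."""

    BENEFIT = "benefit"
    HARM = "harm"


class Source(str, Enum):
    """Where a criterion's ratings come from."""

    EVIDENCE = "evidence"
    USER = "user"


@dataclass(frozen=True)
class ValueFunctionSpec:
    """How a raw performance value becomes a [0, 1] rating.

    Kinds
    -----
    ``identity``
        Raw value is already a rating; clipped to [0, 1].
    ``one_minus_risk``
        Raw value is an event probability ``p`` on a harm criterion; the
        rating is ``1 - p``.
    ``linear_anchor``
        Linear rescaling mapping ``worst_raw`` to 0 and ``best_raw`` to 1,
        clipped outside the anchors.
    ``reference_anchored``
        One option serves as the reference at ``reference_rating``; the
        other is placed at ``reference_rating + scale * benefit`` where
        ``benefit`` is the signed advantage over the reference in raw
        units (positive = better).  Useful when the evidence reports
        differences between options rather than absolute performances.
    """

    kind: str
    worst_raw: Optional[float] = None
    best_raw: Optional[float] = None
    reference_rating: float = 0.5
    scale: float = 0.5
    units: Optional[str] = None

    _KINDS = ("identity", "one_minus_risk", "linear_anchor", "reference_anchored")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ModelError(f"unknown value-function kind {self.kind!r}")
        if self.kind == "linear_anchor":
            if self.worst_raw is None or self.best_raw is None:
                raise ModelError("linear_anchor requires worst_raw and best_raw")
            if self.worst_raw == self.best_raw:
                raise ModelError("linear_anchor anchors must differ")
        if self.scale <= 0:
            raise ModelError("value-function scale must be positive")


@dataclass(frozen=True)
class Criterion:
    """One consideration an option is rated on."""

    id: str
    label: str
    polarity: Polarity = Polarity.BENEFIT
    locked: bool = False
    certainty: Certainty = Certainty.HIGH
    source: Source = Source.USER
    value_function: Optional[ValueFunctionSpec] = None


@dataclass(frozen=True)
class Option:
    """An option under consideration."""

    id: str
    label: str


def _as_readonly(arr: np.ndarray) -> np.ndarray:
    out = np.array(arr, dtype=float, copy=True)
    out.flags.writeable = False
    return out


@dataclass(frozen=True)
class DecisionModel:
    """Options x criteria with a complete [0, 1] ratings matrix.

    Parameters
    ----------
    options
        At least two options, in display order.
    criteria
        Criteria in display order; order is preserved in every output.
    ratings
        Array of shape ``(n_options, n_criteria)``; entry ``[o, k]`` is how
        well option ``o`` performs on criterion ``k`` (1 = best).
    raw_values
        Optional matrix of raw performances (same shape) kept for audit;
        units live on each criterion's value function.
    metadata
        Free-form document metadata (title, disclaimer, provenance notes).
    """

    options: tuple[Option, ...]
    criteria: tuple[Criterion, ...]
    ratings: np.ndarray
    raw_values: Optional[np.ndarray] = None
    metadata: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "options", tuple(self.options))
        object.__setattr__(self, "criteria", tuple(self.criteria))
        object.__setattr__(self, "ratings", _as_readonly(self.ratings))
        if self.raw_values is not None:
            object.__setattr__(self, "raw_values", _as_readonly(self.raw_values))
        object.__setattr__(self, "metadata", dict(self.metadata))

    # -- shape helpers ---------------------------------------------------
    @property
    def n_options(self) -> int:
        return len(self.options)

    @property
    def n_criteria(self) -> int:
        return len(self.criteria)

    @property
    def option_ids(self) -> tuple[str, ...]:
        return tuple(o.id for o in self.options)

    @property
    def criterion_ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.criteria)

    def option_index(self, option_id: str) -> int:
        try:
            return self.option_ids.index(option_id)
        except ValueError:
            raise ModelError(f"unknown option {option_id!r}") from None

    def criterion_index(self, criterion_id: str) -> int:
        try:
            return self.criterion_ids.index(criterion_id)
        except ValueError:
            raise ModelError(f"unknown criterion {criterion_id!r}") from None

    def criterion(self, criterion_id: str) -> Criterion:
        return self.criteria[self.criterion_index(criterion_id)]

    def rating(self, option_id: str, criterion_id: str) -> float:
        return float(
            self.ratings[self.option_index(option_id), self.criterion_index(criterion_id)]
        )

    def content_hash(self) -> str:
        """Stable digest of everything that affects scores.

        Used to detect reports rendered from stale score objects after the
        model has been edited.
        """
        h = hashlib.sha256()
        for o in self.options:
            h.update(o.id.encode())
            h.update(o.label.encode())
        for c in self.criteria:
            h.update(
                f"{c.id}|{c.label}|{c.polarity.value}|{c.locked}|"
                f"{c.certainty.value}|{c.source.value}".encode()
            )
        h.update(np.ascontiguousarray(self.ratings).tobytes())
        return h.hexdigest()


@dataclass(frozen=True)
class WeightSet:
    """Per-criterion importance weights.

    ``raw`` holds the weights as elicited (any nonnegative scale, e.g.
    0-100 sliders); ``normalized`` sums to 1 and is what scoring uses, so
    the result is invariant to the elicitation scale.
    """

    raw: np.ndarray
    criterion_ids: Optional[tuple[str, ...]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "raw", _as_readonly(self.raw))
        if self.criterion_ids is not None:
            object.__setattr__(self, "criterion_ids", tuple(self.criterion_ids))

    @property
    def normalized(self) -> np.ndarray:
        return self.raw / self.raw.sum()

    def __len__(self) -> int:
        return int(self.raw.shape[0])


def normalize_weights(
    raw: Sequence[float] | np.ndarray,
    criterion_ids: Optional[Sequence[str]] = None,
) -> WeightSet:
    """Validate a raw weight vector and wrap it in a :class:`WeightSet`.

    Raises
    ------
    WeightValidationError
        If an entry is negative or non-finite (the offending criterion is
        named when ids are supplied).
    DegenerateWeightsError
        If every entry is zero.
    """
    arr = np.asarray(raw, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise WeightValidationError("weights must be a non-empty 1-D vector")
    ids = tuple(criterion_ids) if criterion_ids is not None else None
    if ids is not None and len(ids) != arr.size:
        raise DimensionMismatchError(
            f"{arr.size} weights supplied for {len(ids)} criteria"
        )
    for i, v in enumerate(arr):
        if not math.isfinite(v) or v < 0:
            name = ids[i] if ids is not None else f"index {i}"
            raise WeightValidationError(f"invalid weight {v!r} for {name}")
    if arr.sum() == 0:
        raise DegenerateWeightsError("degenerate weights: all entries are zero")
    return WeightSet(raw=arr, criterion_ids=ids)


def set_user_rating(
    model: DecisionModel, criterion_id: str, option_id: str, rating: float
) -> DecisionModel:
    """Return a copy of ``model`` with one unlocked rating replaced.

    Locked criteria hold evidence-sourced ratings and cannot be edited;
    attempting to do so raises :class:`LockedRatingError` and leaves the
    original model bit-identical.
    """
    k = model.criterion_index(criterion_id)
    o = model.option_index(option_id)
    if model.criteria[k].locked:
        raise LockedRatingError(
            f"locked rating: criterion {criterion_id!r} is evidence-sourced "
            "and cannot be edited"
        )
    if not (isinstance(rating, (int, float)) and math.isfinite(rating)):
        raise RatingRangeError(f"rating must be a finite number, got {rating!r}")
    if not 0.0 <= rating <= 1.0:
        raise RatingRangeError(f"rating {rating} outside [0, 1]")
    new = np.array(model.ratings, copy=True)
    new[o, k] = rating
    return dataclasses.replace(model, ratings=new)


@dataclass(frozen=True)
class Violation:
    """One invariant violation found by :func:`validate_model`."""

    location: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - convenience
        return f"{self.location}: {self.message}"


def validate_model(model: DecisionModel) -> list[Violation]:
    """Check every structural invariant; violations are data, not errors.

    An empty list means the model is well-formed: >=2 options with unique
    ids, unique criterion ids, a complete finite ratings matrix inside
    [0, 1], and well-shaped raw values when present.
    """
    out: list[Violation] = []
    if model.n_options < 2:
        out.append(Violation("options", f"need >=2 options, have {model.n_options}"))
    seen: set[str] = set()
    for o in model.options:
        if o.id in seen:
            out.append(Violation(f"options.{o.id}", "duplicate option id"))
        seen.add(o.id)
    seen = set()
    for c in model.criteria:
        if c.id in seen:
            out.append(Violation(f"criteria.{c.id}", "duplicate criterion id"))
        seen.add(c.id)
    if model.n_criteria == 0:
        out.append(Violation("criteria", "model has no criteria"))
    shape = (model.n_options, model.n_criteria)
    if model.ratings.shape != shape:
        out.append(
            Violation(
                "ratings",
                f"shape {model.ratings.shape} does not match "
                f"(options, criteria) = {shape}",
            )
        )
    else:
        for i, opt in enumerate(model.options):
            for j, crit in enumerate(model.criteria):
                v = model.ratings[i, j]
                if not math.isfinite(v):
                    out.append(
                        Violation(f"ratings[{opt.id}, {crit.id}]", "missing/non-finite")
                    )
                elif not 0.0 <= v <= 1.0:
                    out.append(
                        Violation(
                            f"ratings[{opt.id}, {crit.id}]",
                            f"rating {v} outside [0, 1]",
                        )
                    )
    if model.raw_values is not None and model.raw_values.shape != shape:
        out.append(Violation("raw_values", "shape does not match ratings"))
    return out
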