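"""Preference-sensitivity analysis for two-option decision models.

Three complementary views of how preference-dependent a result is:

* **one-way flip thresholds** — for each criterion, the normalized weight
  at which the preferred option changes, holding the relative proportions
  of the other weights fixed (standard normalized one-way analysis);
* **preference heterogeneity simulation** — weight vectors drawn from a
  Dirichlet distribution over the simplex stand in for a population of
  informed patients with varying values; each vector is scored and the
  share preferring each option recorded;
* **share classification** — a quantitative reading of the GRADE verbal
  classes: a large-enough share for one option is labelled ``strong_for``
  it, an intermediate share ``weak_for``, anything else equipoise.

The default population model is the symmetric Dirichlet(1) — uniform on
the simplex, i.e. maximally agnostic about how people weight criteria.
The classification boundaries are configurable and reported with every
result, since "most informed patients" has no agreed numeric value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .config import (
    DEFAULT_ADJUSTMENT_MODE,
    DEFAULT_STRONG_THRESHOLD,
    DEFAULT_WEAK_THRESHOLD,
)
from .model import DecisionModel, DimensionMismatchError, ModelError, WeightSet
from .scoring import effective_ratings

__all__ = [
    "FlipThreshold",
    "PreferenceSample",
    "RecommendationClass",
    "one_way_flip_threshold",
    "sample_weight_vectors",
    "preference_share",
    "classify_recommendation",
]

_SIGN_TOL = 1e-12


@dataclass(frozen=True)
class FlipThreshold:
    """One-way sensitivity result for a single criterion.

    ``threshold`` is the normalized weight on the criterion at which the
    preferred option flips away from the preference at weight 0, or
    ``None`` if no flip occurs anywhere on [0, 1].  ``direction`` names
    the option preferred above the threshold.
    """

    criterion_id: str
    threshold: Optional[float]
    direction: Optional[str]


def _pair_ratings(
    model: DecisionModel,
    adjusted: bool,
    mode: str,
    mapping: Optional[Mapping[str, float]],
) -> np.ndarray:
    if model.n_options != 2:
        raise ModelError("flip-threshold analysis requires exactly 2 options")
    if adjusted:
        return effective_ratings(model, mode=mode, mapping=mapping)
    return model.ratings


def one_way_flip_threshold(
    model: DecisionModel,
    weights: WeightSet,
    criterion_id: str,
    adjusted: bool = False,
    mode: str = DEFAULT_ADJUSTMENT_MODE,
    mapping: Optional[Mapping[str, float]] = None,
) -> FlipThreshold:
    """Smallest weight on one criterion at which the preference flips.

    The criterion's normalized weight is varied as ``t`` over [0, 1] while
    the remaining weights keep their baseline proportions and are rescaled
    to sum to ``1 - t``.  The score difference between the two options is
    then linear in ``t``:

        D(t) = (1 - t) * R + t * dr_j,

    where ``dr_j`` is the rating difference on the varied criterion and
    ``R`` the baseline-weighted mean rating difference over the others.
    The flip point is the zero crossing of ``D``, found in closed form; a
    flip is reported only when the preference actually changes sign on
    [0, 1].
    """
    r = _pair_ratings(model, adjusted, mode, mapping)
    w0 = weights.normalized
    if len(weights) != model.n_criteria:
        raise DimensionMismatchError(
            f"{len(weights)} weights for {model.n_criteria} criteria"
        )
    j = model.criterion_index(criterion_id)
    d = r[0] - r[1]
    dj = float(d[j])
    others = np.delete(w0, j)
    d_others = np.delete(d, j)
    mass = others.sum()
    R = float((others * d_others).sum() / mass) if mass > 0 else 0.0

    def sign(x: float) -> int:
        return 0 if abs(x) <= _SIGN_TOL else (1 if x > 0 else -1)

    s0, s1 = sign(R), sign(dj)
    first, second = model.option_ids
    if s0 == 0:
        if s1 == 0:
            return FlipThreshold(criterion_id, None, None)
        # tied at t=0; any positive weight creates a strict preference
        return FlipThreshold(criterion_id, 0.0, first if s1 > 0 else second)
    if s1 != -s0:
        # D never changes sign on [0, 1] (it may reach 0 at t=1 but no flip)
        return FlipThreshold(criterion_id, None, None)
    t_star = R / (R - dj)
    return FlipThreshold(criterion_id, float(t_star), first if s1 > 0 else second)


@dataclass(frozen=True)
class PreferenceSample:
    """Dirichlet-sampled normalized weight vectors.

    ``weights`` has shape ``(n, k)``; each row sums to 1.  The same
    ``(n, concentration, seed)`` triple reproduces the sample
    bit-identically.
    """

    n: int
    concentration: np.ndarray
    seed: int
    weights: np.ndarray

    def __post_init__(self) -> None:
        conc = np.array(self.concentration, dtype=float, copy=True)
        conc.flags.writeable = False
        object.__setattr__(self, "concentration", conc)
        w = np.array(self.weights, dtype=float, copy=True)
        w.flags.writeable = False
        object.__setattr__(self, "weights", w)

    @property
    def k(self) -> int:
        return int(self.weights.shape[1])


def sample_weight_vectors(
    n: int,
    k: int,
    concentration: float | Sequence[float] = 1.0,
    seed: int = 0,
) -> PreferenceSample:
    """Draw ``n`` weight vectors from a Dirichlet over the k-simplex.

    A scalar concentration is broadcast symmetrically; concentration 1
    gives the uniform distribution on the simplex.  All entries must be
    strictly positive.
    """
    if n < 1:
        raise ModelError("sample size n must be >= 1")
    alpha = np.asarray(
        np.full(k, concentration) if np.isscalar(concentration) else concentration,
        dtype=float,
    )
    if alpha.shape != (k,):
        raise DimensionMismatchError(
            f"concentration shape {alpha.shape} does not match k={k}"
        )
    if not np.all(np.isfinite(alpha)) or np.any(alpha <= 0):
        raise ModelError("Dirichlet concentration entries must be positive")
    rng = np.random.default_rng(seed)
    w = rng.dirichlet(alpha, size=n)
    return PreferenceSample(n=n, concentration=alpha, seed=int(seed), weights=w)


def preference_share(
    model: DecisionModel,
    sample: PreferenceSample,
    adjusted: bool = False,
    mode: str = DEFAULT_ADJUSTMENT_MODE,
    mapping: Optional[Mapping[str, float]] = None,
) -> dict[str, float]:
    """Share of sampled weight vectors under which each option wins.

    Every sampled vector is scored; exact ties (within 1e-12) contribute
    equally to each tied option, so shares are unbiased under symmetry.
    Shares sum to 1.
    """
    if sample.k != model.n_criteria:
        raise DimensionMismatchError(
            f"sample has {sample.k} criteria, model has {model.n_criteria}"
        )
    if adjusted:
        r = effective_ratings(model, mode=mode, mapping=mapping)
    else:
        r = model.ratings
    scores = sample.weights @ r.T  # (n, n_options)
    best = scores.max(axis=1, keepdims=True)
    winners = scores >= best - _SIGN_TOL
    credit = winners / winners.sum(axis=1, keepdims=True)
    shares = credit.sum(axis=0) / sample.n
    return {oid: float(s) for oid, s in zip(model.option_ids, shares)}


@dataclass(frozen=True)
class RecommendationClass:
    """Preference-share classification of a two-option comparison.

    ``label`` is one of ``strong_for_<option>``, ``weak_for_<option>`` or
    ``equipoise``; it is a pure function of the shares and the two
    thresholds, which are carried along so every report can state them.
    """

    shares: dict[str, float]
    label: str
    strong_threshold: float
    weak_threshold: float


def classify_recommendation(
    shares: Mapping[str, float],
    strong_threshold: float = DEFAULT_STRONG_THRESHOLD,
    weak_threshold: float = DEFAULT_WEAK_THRESHOLD,
) -> RecommendationClass:
    """Map preference shares to a strong/weak/equipoise class.

    Requires ``0.5 < weak_threshold < strong_threshold <= 1``: the
    boundaries must at least describe a majority, and strong must demand
    more consensus than weak.
    """
    if not (0.5 < weak_threshold < strong_threshold <= 1.0):
        raise ModelError(
            "thresholds must satisfy 0.5 < weak < strong <= 1, got "
            f"weak={weak_threshold}, strong={strong_threshold}"
        )
    if not shares:
        raise ModelError("shares must be non-empty")
    total = sum(shares.values())
    if not math.isclose(total, 1.0, abs_tol=1e-6):
        raise ModelError(f"shares must sum to 1, got {total}")
    top = max(shares, key=lambda k: shares[k])
    top_share = shares[top]
    if top_share >= strong_threshold:
        label = f"strong_for_{top}"
    elif top_share >= weak_threshold:
        label = f"weak_for_{top}"
    else:
        label = "equipoise"
    return RecommendationClass(
        shares={k: float(v) for k, v in shares.items()},
        label=label,
        strong_threshold=float(strong_threshold),
        weak_threshold=float(weak_threshold),
    )
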