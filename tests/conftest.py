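"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the library's vectorised code paths:
scores are accumulated with explicit Python loops and flip thresholds are
found by scanning a weight grid, so tests compare two genuinely different
routes to the same quantity.
"""

from __future__ import annotations

import numpy as np
import pytest

from decisio import (
    Certainty,
    Criterion,
    DecisionModel,
    Option,
    Polarity,
    Source,
    WeightSet,
    build_model,
    normalize_weights,
)
from decisio.config import DEFAULT_CERTAINTY_MULTIPLIERS

# --------------------------------------------------------------------------
# independent oracles


def naive_scores(model: DecisionModel, weights: WeightSet) -> list[float]:
    """Reference expected-value scores via an explicit double loop."""
    w = weights.normalized
    out = []
    for i in range(model.n_options):
        total = 0.0
        for k in range(model.n_criteria):
            total += float(w[k]) * float(model.ratings[i, k])
        out.append(total)
    return out


def naive_adjusted_scores(
    model: DecisionModel,
    weights: WeightSet,
    mode: str = "multiplicative",
    mapping=None,
) -> list[float]:
    """Reference certainty-adjusted scores, loop plus explicit mapping."""
    mapping = dict(DEFAULT_CERTAINTY_MULTIPLIERS if mapping is None else mapping)
    w = weights.normalized
    out = []
    for i in range(model.n_options):
        total = 0.0
        for k, crit in enumerate(model.criteria):
            c = mapping[crit.certainty.value]
            r = float(model.ratings[i, k])
            if mode == "multiplicative":
                total += float(w[k]) * c * r
            else:  # shrink_to_neutral
                total += float(w[k]) * (c * r + (1.0 - c) * 0.5)
        out.append(total)
    return out


def scores_at_weight_t(
    ratings: np.ndarray, w0: np.ndarray, j: int, t: float
) -> tuple[float, float]:
    """Two-option scores with criterion j's weight set to t, others rescaled."""
    w = np.array(w0, dtype=float)
    mass = w.sum() - w[j]
    if mass > 0:
        scalefac = (1.0 - t) / mass
        w = w * scalefac
    else:
        w = np.zeros_like(w)
    w[j] = t
    return float(w @ ratings[0]), float(w @ ratings[1])


def grid_flip_threshold(
    ratings: np.ndarray,
    w0: np.ndarray,
    j: int,
    step: float = 0.001,
    tol: float = 1e-12,
):
    """Grid-scan oracle: smallest t where the preferred option changes.

    Preference at each grid point is option 0, option 1 or a tie; a flip
    is the first grid point whose preference is a concrete option
    different from the preference at t=0.
    """

    def pref(t: float):
        a, b = scores_at_weight_t(ratings, w0, j, t)
        if abs(a - b) <= tol:
            return None
        return 0 if a > b else 1

    base = pref(0.0)
    for t in np.arange(step, 1.0 + step / 2, step):
        p = pref(float(t))
        if p is not None and p != base:
            return float(t)
    return None


def random_model(rng: np.random.Generator, n_options=None, n_criteria=None) -> DecisionModel:
    """A random, structurally valid decision model."""
    n_opt = int(n_options if n_options is not None else rng.integers(2, 7))
    n_crit = int(n_criteria if n_criteria is not None else rng.integers(1, 13))
    levels = list(Certainty)
    criteria = []
    for k in range(n_crit):
        locked = bool(rng.integers(0, 2))
        criteria.append(
            Criterion(
                id=f"c{k}",
                label=f"criterion {k}",
                polarity=Polarity.HARM if rng.integers(0, 2) else Polarity.BENEFIT,
                locked=locked,
                certainty=levels[rng.integers(0, len(levels))],
                source=Source.EVIDENCE if locked else Source.USER,
            )
        )
    return DecisionModel(
        options=tuple(Option(f"o{i}", f"option {i}") for i in range(n_opt)),
        criteria=tuple(criteria),
        ratings=rng.uniform(0.0, 1.0, size=(n_opt, n_crit)),
        metadata={"title": "random model"},
    )


def two_option_model(ratings, certainties=None) -> DecisionModel:
    """Small handmade two-option model from a ratings array."""
    ratings = np.asarray(ratings, dtype=float)
    n_crit = ratings.shape[1]
    certainties = certainties or [Certainty.HIGH] * n_crit
    criteria = tuple(
        Criterion(id=f"c{k}", label=f"criterion {k}", certainty=Certainty(certainties[k]))
        for k in range(n_crit)
    )
    return DecisionModel(
        options=(Option("A", "Option A"), Option("B", "Option B")),
        criteria=criteria,
        ratings=ratings,
    )


# --------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def fixture_model() -> DecisionModel:
    return build_model("65_to_75")


@pytest.fixture()
def equal_weights(fixture_model) -> WeightSet:
    return normalize_weights(
        [1.0] * fixture_model.n_criteria, fixture_model.criterion_ids
    )
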