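"""Model-document I/O, weight elicitation and the one-screen report.

Model documents are versioned YAML with a strict schema: unknown fields
are rejected rather than ignored, because silently dropping a
misconfigured field in a clinically-facing tool is worse than failing
loudly.  Writing then reading a document reproduces the model exactly
(ratings bit-identical), and every document carries the
not-a-validated-decision-aid disclaimer in its metadata.

The report produced by :func:`render_decisiographic` puts everything on
one screen: the ratings matrix with locked cells marked, the normalized
weights, the unadjusted and certainty-adjusted score pair per option, the
adjustment mode and certainty mapping used, optional sensitivity results,
and the disclaimer.  It is deterministic — no timestamps — so regenerating
it from the same inputs yields byte-identical text.
"""

from __future__ import annotations

import logging
from typing import Mapping, Optional, Sequence

import numpy as np
import yaml

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
    WeightSet,
    normalize_weights,
    validate_model,
)
from .scoring import OptionScores
from .sensitivity import FlipThreshold, RecommendationClass

__all__ = [
    "SCHEMA_VERSION",
    "DocumentError",
    "StaleScoresError",
    "model_to_document",
    "document_to_model",
    "write_model",
    "read_model",
    "elicit_weights",
    "render_decisiographic",
]

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1

_TOP_KEYS = {"schema_version", "metadata", "options", "criteria", "ratings", "raw_values"}
_OPTION_KEYS = {"id", "label"}
_CRITERION_KEYS = {"id", "label", "polarity", "locked", "certainty", "source", "value_function"}
_VF_KEYS = {"kind", "worst_raw", "best_raw", "reference_rating", "scale", "units"}


class DocumentError(ModelError):
    """Raised for malformed, unversioned or invalid model documents."""


class StaleScoresError(ModelError):
    """Raised when a report is requested for scores of an edited model."""


def _check_keys(obj: Mapping, allowed: set[str], where: str) -> None:
    unknown = set(obj) - allowed
    if unknown:
        raise DocumentError(f"unknown field(s) {sorted(unknown)} in {where}")


def model_to_document(model: DecisionModel) -> dict:
    """Serialize a model to the plain-dict document form."""
    meta = dict(model.metadata)
    meta.setdefault("disclaimer", DISCLAIMER)
    doc: dict = {
        "schema_version": SCHEMA_VERSION,
        "metadata": meta,
        "options": [{"id": o.id, "label": o.label} for o in model.options],
        "criteria": [],
        "ratings": {},
    }
    for c in model.criteria:
        entry: dict = {
            "id": c.id,
            "label": c.label,
            "polarity": c.polarity.value,
            "locked": c.locked,
            "certainty": c.certainty.value,
            "source": c.source.value,
        }
        if c.value_function is not None:
            vf = c.value_function
            entry["value_function"] = {
                "kind": vf.kind,
                "worst_raw": vf.worst_raw,
                "best_raw": vf.best_raw,
                "reference_rating": vf.reference_rating,
                "scale": vf.scale,
                "units": vf.units,
            }
        doc["criteria"].append(entry)
    for i, o in enumerate(model.options):
        doc["ratings"][o.id] = {
            c.id: float(model.ratings[i, j]) for j, c in enumerate(model.criteria)
        }
    if model.raw_values is not None:
        doc["raw_values"] = {
            o.id: {
                c.id: float(model.raw_values[i, j])
                for j, c in enumerate(model.criteria)
            }
            for i, o in enumerate(model.options)
        }
    return doc


def document_to_model(doc: Mapping) -> DecisionModel:
    """Parse and validate a document; raises with locations on any defect."""
    if not isinstance(doc, Mapping):
        raise DocumentError("document root must be a mapping")
    _check_keys(doc, _TOP_KEYS, "document root")
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise DocumentError(
            f"unsupported schema version {version!r} (expected {SCHEMA_VERSION})"
        )
    meta = doc.get("metadata") or {}
    if not isinstance(meta, Mapping):
        raise DocumentError("metadata must be a mapping")
    if not meta.get("disclaimer"):
        raise DocumentError("metadata.disclaimer is required in every document")

    options: list[Option] = []
    for i, entry in enumerate(doc.get("options") or []):
        _check_keys(entry, _OPTION_KEYS, f"options[{i}]")
        options.append(Option(str(entry["id"]), str(entry.get("label", entry["id"]))))
    criteria: list[Criterion] = []
    for i, entry in enumerate(doc.get("criteria") or []):
        _check_keys(entry, _CRITERION_KEYS, f"criteria[{i}]")
        vf = None
        if entry.get("value_function") is not None:
            vfd = entry["value_function"]
            _check_keys(vfd, _VF_KEYS, f"criteria[{i}].value_function")
            vf = ValueFunctionSpec(
                kind=vfd["kind"],
                worst_raw=vfd.get("worst_raw"),
                best_raw=vfd.get("best_raw"),
                reference_rating=vfd.get("reference_rating", 0.5),
                scale=vfd.get("scale", 0.5),
                units=vfd.get("units"),
            )
        try:
            criteria.append(
                Criterion(
                    id=str(entry["id"]),
                    label=str(entry.get("label", entry["id"])),
                    polarity=Polarity(entry.get("polarity", "benefit")),
                    locked=bool(entry.get("locked", False)),
                    certainty=Certainty(entry.get("certainty", "high")),
                    source=Source(entry.get("source", "user")),
                    value_function=vf,
                )
            )
        except (KeyError, ValueError) as exc:
            raise DocumentError(f"criteria[{i}]: {exc}") from exc

    ratings_doc = doc.get("ratings") or {}
    n, k = len(options), len(criteria)
    ratings = np.full((n, k), np.nan)
    for i, o in enumerate(options):
        row = ratings_doc.get(o.id)
        if row is None:
            raise DocumentError(f"ratings missing for option {o.id!r}")
        unknown = set(row) - {c.id for c in criteria}
        if unknown:
            raise DocumentError(
                f"ratings for option {o.id!r} name unknown criteria {sorted(unknown)}"
            )
        for j, c in enumerate(criteria):
            if c.id not in row:
                raise DocumentError(f"ratings cell missing: ({o.id}, {c.id})")
            ratings[i, j] = float(row[c.id])

    raw_values = None
    if doc.get("raw_values") is not None:
        raw_values = np.full((n, k), np.nan)
        for i, o in enumerate(options):
            row = doc["raw_values"].get(o.id, {})
            for j, c in enumerate(criteria):
                raw_values[i, j] = float(row.get(c.id, np.nan))

    model = DecisionModel(
        options=tuple(options),
        criteria=tuple(criteria),
        ratings=ratings,
        raw_values=raw_values,
        metadata=dict(meta),
    )
    violations = validate_model(model)
    if violations:
        raise DocumentError(
            "document violates model invariants: "
            + "; ".join(str(v) for v in violations)
        )
    return model


def write_model(model: DecisionModel, path) -> None:
    """Write a model document (YAML) to ``path``."""
    doc = model_to_document(model)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)


def read_model(path) -> DecisionModel:
    """Read a model document from ``path``; fails listing any violations."""
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise DocumentError(f"malformed document: {exc}") from exc
    return document_to_model(doc)


def elicit_weights(
    model: DecisionModel,
    responses: Mapping[str, float] | Sequence[float],
) -> WeightSet:
    """Turn per-criterion importance responses (0-100 style) into weights.

    Responses may be a mapping by criterion id (one entry per criterion,
    no extras) or a sequence in model order.  The session transcript is
    logged so elicited weights can be revised and replayed.
    """
    ids = model.criterion_ids
    if isinstance(responses, Mapping):
        missing = [cid for cid in ids if cid not in responses]
        if missing:
            raise ModelError(f"missing importance response for {missing}")
        extra = set(responses) - set(ids)
        if extra:
            raise ModelError(f"responses for unknown criteria {sorted(extra)}")
        raw = [float(responses[cid]) for cid in ids]
    else:
        raw = [float(v) for v in responses]
        if len(raw) != len(ids):
            raise ModelError(
                f"{len(raw)} responses for {len(ids)} criteria"
            )
    ws = normalize_weights(raw, criterion_ids=ids)
    for cid, r, w in zip(ids, ws.raw, ws.normalized):
        log.info("elicited weight %s: raw=%g normalized=%.4f", cid, r, w)
    return ws


def _fmt(x: float) -> str:
    return f"{x:.4f}"


def render_decisiographic(
    model: DecisionModel,
    weights: WeightSet,
    scores: OptionScores,
    thresholds: Optional[Sequence[FlipThreshold]] = None,
    shares: Optional[Mapping[str, float]] = None,
    classification: Optional[RecommendationClass] = None,
) -> str:
    """One-screen plain-text report of evidence, preferences and scores.

    Raises :class:`StaleScoresError` if the scores were computed from a
    different model state or different weights than those supplied.
    """
    if scores.model_hash != model.content_hash():
        raise StaleScoresError(
            "scores are stale: the model was edited after scoring"
        )
    w = weights.normalized
    if len(w) != model.n_criteria or not np.array_equal(w, scores.weights):
        raise StaleScoresError("scores were computed from different weights")

    lines: list[str] = []
    title = str(model.metadata.get("title", "Decision model"))
    lines.append(f"== {title} ==")
    lines.append("")
    lines.append("Options: " + ", ".join(f"{o.id} ({o.label})" for o in model.options))
    lines.append("")
    lines.append("Ratings (0-1, higher is better; [L] = locked evidence rating)")
    head = f"{'criterion':<42}{'weight':>8}{'certainty':>11}"
    for o in model.options:
        head += f"{o.id:>9}"
    lines.append(head)
    for j, c in enumerate(model.criteria):
        name = c.label + (" [L]" if c.locked else "")
        row = f"{name:<42}{w[j]:>8.4f}{c.certainty.value:>11}"
        for i in range(model.n_options):
            row += f"{model.ratings[i, j]:>9.3f}"
        lines.append(row)
    lines.append("")
    lines.append("Expected-value scores (0-1)")
    if scores.adjusted is not None:
        lines.append(f"{'option':<10}{'unadjusted':>12}{'certainty-adjusted':>20}")
        for i, oid in enumerate(scores.option_ids):
            lines.append(
                f"{oid:<10}{_fmt(scores.unadjusted[i]):>12}"
                f"{_fmt(scores.adjusted[i]):>20}"
            )
        mapping = scores.certainty_mapping or {}
        mapping_txt = ", ".join(f"{k}={v:g}" for k, v in mapping.items())
        lines.append(
            f"Certainty adjustment: mode={scores.adjustment_mode}; "
            f"mapping: {mapping_txt}"
        )
    else:
        lines.append(f"{'option':<10}{'unadjusted':>12}")
        for i, oid in enumerate(scores.option_ids):
            lines.append(f"{oid:<10}{_fmt(scores.unadjusted[i]):>12}")
    pref = scores.preferred(adjusted=scores.adjusted is not None)
    lines.append(
        "Higher-scoring option: " + (pref if pref is not None else "tie")
    )
    if thresholds:
        lines.append("")
        lines.append("One-way weight flip thresholds (normalized weight on criterion)")
        lines.append(f"{'criterion':<42}{'threshold':>10}  {'prefers above'}")
        for t in thresholds:
            thr = "none" if t.threshold is None else f"{t.threshold:.3f}"
            direction = t.direction or "-"
            lines.append(f"{t.criterion_id:<42}{thr:>10}  {direction}")
    if shares is not None:
        lines.append("")
        lines.append("Simulated informed-preference shares")
        for oid, s in shares.items():
            lines.append(f"  {oid:<10}{s:>8.4f}")
        if classification is not None:
            lines.append(
                f"Preference-share class: {classification.label} "
                f"(strong >= {classification.strong_threshold:g}, "
                f"weak >= {classification.weak_threshold:g})"
            )
    lines.append("")
    disclaimer = str(model.metadata.get("disclaimer", DISCLAIMER))
    lines.append("Disclaimer: " + disclaimer)
    lines.append("")
    return "\n".join(lines)
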