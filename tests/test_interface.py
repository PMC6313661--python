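"""Document round trips, elicitation, the one-screen report, and the CLI."""

import copy

import numpy as np
import pytest
import yaml
from click.testing import CliRunner

from decisio import (
    DocumentError,
    ModelError,
    StaleScoresError,
    build_model,
    certainty_adjusted_scores,
    classify_recommendation,
    elicit_weights,
    normalize_weights,
    one_way_flip_threshold,
    preference_share,
    read_model,
    render_decisiographic,
    sample_weight_vectors,
    set_user_rating,
    write_model,
)
from decisio.cli import main
from decisio.interface import document_to_model, model_to_document
from conftest import random_model


class TestDocumentRoundTrip:
    def test_fixture_round_trip_is_exact(self, fixture_model, tmp_path):
        p = tmp_path / "m.yaml"
        write_model(fixture_model, p)
        back = read_model(p)
        assert back.options == fixture_model.options
        assert back.criteria == fixture_model.criteria
        assert back.ratings.tobytes() == fixture_model.ratings.tobytes()

    def test_random_models_round_trip_bit_identical(self, tmp_path):
        rng = np.random.default_rng(37)
        for i in range(200):
            m = random_model(rng)
            p = tmp_path / f"m{i}.yaml"
            write_model(m, p)
            back = read_model(p)
            assert back.criteria == m.criteria
            assert back.ratings.tobytes() == m.ratings.tobytes()

    def test_disclaimer_written_into_every_document(self, tmp_path):
        m = random_model(np.random.default_rng(1))
        p = tmp_path / "m.yaml"
        write_model(m, p)
        doc = yaml.safe_load(p.read_text())
        assert "not a validated clinical decision aid" in doc["metadata"]["disclaimer"]


class TestDocumentErrors:
    @pytest.fixture()
    def doc(self, fixture_model):
        return model_to_document(fixture_model)

    def test_unsupported_schema_version(self, doc):
        doc["schema_version"] = 99
        with pytest.raises(DocumentError, match="schema version"):
            document_to_model(doc)

    def test_unknown_top_level_field_rejected(self, doc):
        doc["surprise"] = 1
        with pytest.raises(DocumentError, match="surprise"):
            document_to_model(doc)

    def test_unknown_criterion_field_rejected(self, doc):
        doc = copy.deepcopy(doc)
        doc["criteria"][0]["colour"] = "red"
        with pytest.raises(DocumentError, match="colour"):
            document_to_model(doc)

    def test_missing_ratings_cell_named(self, doc):
        doc = copy.deepcopy(doc)
        del doc["ratings"]["TAVI"]["stroke"]
        with pytest.raises(DocumentError, match=r"TAVI.*stroke"):
            document_to_model(doc)

    def test_out_of_range_rating_rejected(self, doc):
        doc = copy.deepcopy(doc)
        doc["ratings"]["SAVR"]["stroke"] = 1.5
        with pytest.raises(DocumentError, match="invariants"):
            document_to_model(doc)

    def test_missing_disclaimer_rejected(self, doc):
        doc = copy.deepcopy(doc)
        del doc["metadata"]["disclaimer"]
        with pytest.raises(DocumentError, match="disclaimer"):
            document_to_model(doc)

    def test_malformed_yaml_reported(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("{: [")
        with pytest.raises(DocumentError, match="malformed"):
            read_model(p)


class TestElicitWeights:
    def test_all_equal_responses_give_equal_weights(self, fixture_model):
        ws = elicit_weights(fixture_model, {c: 100 for c in fixture_model.criterion_ids})
        np.testing.assert_allclose(ws.normalized, 0.1, atol=1e-12)

    def test_single_supported_criterion(self, fixture_model):
        responses = dict.fromkeys(fixture_model.criterion_ids, 0)
        responses["mortality"] = 100
        ws = elicit_weights(fixture_model, responses)
        assert ws.normalized[fixture_model.criterion_index("mortality")] == 1.0

    def test_delegates_to_normalize_weights(self, fixture_model):
        raw = [50, 100] + [50] * 8
        ws = elicit_weights(fixture_model, raw)
        np.testing.assert_array_equal(
            ws.normalized,
            normalize_weights(raw, fixture_model.criterion_ids).normalized,
        )

    def test_missing_response_rejected(self, fixture_model):
        responses = {c: 10 for c in fixture_model.criterion_ids[:-1]}
        with pytest.raises(ModelError, match="missing"):
            elicit_weights(fixture_model, responses)


class TestReport:
    @pytest.fixture()
    def report(self, fixture_model, equal_weights):
        scores = certainty_adjusted_scores(fixture_model, equal_weights)
        thresholds = [
            one_way_flip_threshold(fixture_model, equal_weights, cid)
            for cid in fixture_model.criterion_ids
        ]
        sample = sample_weight_vectors(2_000, 10, 1.0, seed=5)
        shares = preference_share(fixture_model, sample)
        cls = classify_recommendation(shares)
        return render_decisiographic(
            fixture_model, equal_weights, scores,
            thresholds=thresholds, shares=shares, classification=cls,
        )

    def test_one_screen_contains_everything(self, report, fixture_model):
        for c in fixture_model.criteria:
            assert c.label in report
        for token in ("TAVI", "SAVR", "unadjusted", "certainty-adjusted",
                      "[L]", "flip thresholds", "Disclaimer:",
                      "Preference-share class"):
            assert token in report

    def test_never_issues_a_directive(self, report):
        assert "recommendation" not in report.lower()

    def test_byte_identical_regeneration(self, fixture_model, equal_weights):
        scores = certainty_adjusted_scores(fixture_model, equal_weights)
        a = render_decisiographic(fixture_model, equal_weights, scores)
        b = render_decisiographic(fixture_model, equal_weights, scores)
        assert a == b

    def test_all_high_certainty_shows_identical_pairs(self, equal_weights):
        from decisio import FixtureOverrides

        m = build_model(
            "65_to_75",
            FixtureOverrides(
                certainty={c: "high" for c in
                           ("mortality", "stroke", "bleeding", "afib",
                            "heart_failure", "pacemaker", "reintervention")}
            ),
        )
        scores = certainty_adjusted_scores(m, equal_weights)
        np.testing.assert_allclose(scores.adjusted, scores.unadjusted)
        report = render_decisiographic(m, equal_weights, scores)
        assert report.count(f"{scores.unadjusted[0]:.4f}") >= 2

    def test_stale_scores_rejected(self, fixture_model, equal_weights):
        scores = certainty_adjusted_scores(fixture_model, equal_weights)
        edited = set_user_rating(fixture_model, "recovery_burden", "TAVI", 0.9)
        with pytest.raises(StaleScoresError, match="stale"):
            render_decisiographic(edited, equal_weights, scores)

    def test_mismatched_weights_rejected(self, fixture_model, equal_weights):
        scores = certainty_adjusted_scores(fixture_model, equal_weights)
        other = normalize_weights([1, 2] + [1] * 8, fixture_model.criterion_ids)
        with pytest.raises(StaleScoresError, match="weights"):
            render_decisiographic(fixture_model, other, scores)


class TestCli:
    @pytest.fixture()
    def runner(self):
        return CliRunner()

    @pytest.fixture()
    def model_and_weights(self, tmp_path, runner):
        model = tmp_path / "m.yaml"
        res = runner.invoke(main, ["fixture", "--age", "65-75", "--out", str(model)])
        assert res.exit_code == 0
        weights = tmp_path / "w.csv"
        m = read_model(model)
        weights.write_text(
            "criterion,weight\n" + "\n".join(f"{c},100" for c in m.criterion_ids) + "\n"
        )
        return model, weights

    def test_fixture_then_validate(self, runner, model_and_weights):
        model, _ = model_and_weights
        res = runner.invoke(main, ["validate", "--model", str(model)])
        assert res.exit_code == 0 and "ok" in res.output

    def test_score_renders_report(self, runner, model_and_weights):
        model, weights = model_and_weights
        res = runner.invoke(
            main, ["score", "--model", str(model), "--weights", str(weights)]
        )
        assert res.exit_code == 0
        assert "certainty-adjusted" in res.output and "Disclaimer" in res.output

    def test_sensitivity_emits_threshold_table(self, runner, model_and_weights,
                                               tmp_path):
        model, weights = model_and_weights
        out = tmp_path / "thr.csv"
        res = runner.invoke(
            main,
            ["sensitivity", "--model", str(model), "--weights", str(weights),
             "--out", str(out)],
        )
        assert res.exit_code == 0
        lines = out.read_text().strip().splitlines()
        assert lines[0] == "criterion,threshold,direction"
        assert len(lines) == 11

    def test_simulate_is_seed_deterministic(self, runner, model_and_weights,
                                            tmp_path):
        model, _ = model_and_weights
        outs = []
        for name in ("a.csv", "b.csv"):
            out = tmp_path / name
            res = runner.invoke(
                main,
                ["simulate", "--model", str(model), "--n", "5000",
                 "--seed", "7", "--out", str(out)],
            )
            assert res.exit_code == 0
            outs.append(out.read_bytes())
        assert outs[0] == outs[1]

    def test_unknown_subcommand_fails(self, runner):
        assert runner.invoke(main, ["frobnicate"]).exit_code != 0

    def test_validate_reports_broken_document(self, runner, tmp_path,
                                              model_and_weights):
        model, _ = model_and_weights
        doc = yaml.safe_load(model.read_text())
        doc["ratings"]["TAVI"]["stroke"] = 2.0
        bad = tmp_path / "bad.yaml"
        bad.write_text(yaml.safe_dump(doc, sort_keys=False))
        res = runner.invoke(main, ["validate", "--model", str(bad)])
        assert res.exit_code != 0
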