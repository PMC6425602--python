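"""Core index machinery: fitness curves, relevance, composite, fingerprints."""

import json

import numpy as np
import pytest

from dsindex import (
    DsiModel,
    DsiNode,
    ModelFormatError,
    TreeConfig,
    TreeGroup,
    compute_dsi,
    compute_relevance,
    fingerprint,
    fit_fitness,
    infer_direction,
    load_model,
    save_model,
    train,
)
from conftest import TOY_CASES, TOY_CONTROLS, brute_fitness, brute_relevance


class TestFitness:
    @pytest.mark.parametrize(
        "query,expected",
        [(4.5, 0.5), (0.0, 0.125), (9.0, 0.875)],  # FN/FP counted by hand
    )
    def test_hand_counted_error_ratios(self, query, expected):
        curve = fit_fitness(TOY_CONTROLS, TOY_CASES, "higher_abnormal")
        assert curve(query) == pytest.approx(expected)

    def test_matches_enumeration_on_random_training_sets(self):
        rng = np.random.default_rng(7)
        grid = np.arange(-1.0, 7.0, 0.25)
        for _ in range(100):
            controls = rng.integers(0, 6, size=rng.integers(1, 9)).astype(float)
            cases = rng.integers(0, 6, size=rng.integers(1, 9)).astype(float)
            curve = fit_fitness(controls, cases, "higher_abnormal")
            for x in grid:
                assert curve(x) == pytest.approx(brute_fitness(controls, cases, x))

    def test_lower_abnormal_mirrors_higher_abnormal(self):
        curve_low = fit_fitness([-c for c in TOY_CONTROLS], [-c for c in TOY_CASES], "lower_abnormal")
        curve_high = fit_fitness(TOY_CONTROLS, TOY_CASES, "higher_abnormal")
        for x in np.arange(0.0, 9.5, 0.5):
            assert curve_low(-x) == pytest.approx(curve_high(x))

    def test_clamps_beyond_training_range(self):
        curve = fit_fitness(TOY_CONTROLS, TOY_CASES, "higher_abnormal")
        assert curve(-1e9) == curve(0.5)
        assert curve(1e9) == curve(9.0)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            fit_fitness([], TOY_CASES, "higher_abnormal", variable="x")


class TestRelevance:
    def test_toy_youden_value_and_cutoff(self):
        j, cutoff = compute_relevance(TOY_CONTROLS, TOY_CASES, return_cutoff=True)
        assert j == pytest.approx(2.0 / 3.0)
        assert cutoff == pytest.approx(5.5)  # SN=2/3, SP=1

    def test_perfect_separation_gives_one(self):
        assert compute_relevance([1.0, 2.0], [10.0, 11.0]) == 1.0

    def test_identical_distributions_give_zero(self):
        assert compute_relevance([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_matches_exhaustive_cutoff_search(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            controls = rng.integers(0, 5, size=rng.integers(1, 9)).astype(float)
            cases = rng.integers(0, 5, size=rng.integers(1, 9)).astype(float)
            assert compute_relevance(controls, cases) == pytest.approx(
                brute_relevance(controls, cases)
            )


class TestDirection:
    @pytest.mark.parametrize(
        "controls,cases,expected",
        [
            ([1, 3, 5], [4, 6, 8], "higher_abnormal"),
            ([900, 1000], [400, 500], "lower_abnormal"),  # amyloid-like
            ([1, 2, 3], [1, 2, 3], "higher_abnormal"),  # tie convention
        ],
    )
    def test_inferred_from_medians(self, controls, cases, expected):
        assert infer_direction(controls, cases) == expected

    def test_declared_direction_overrides(self):
        assert infer_direction([1, 2], [5, 6], declared="lower_abnormal") == "lower_abnormal"
        assert infer_direction([1, 2], [5, 6], declared="auto") == "higher_abnormal"


def _leaf(name, relevance, fitness_value):
    """Leaf with a constant fitness curve (single breakpoint)."""
    from dsindex.dsi import FitnessCurve

    curve = FitnessCurve(
        variable=name,
        direction="higher_abnormal",
        breakpoints=np.array([0.0]),
        values=np.array([fitness_value, fitness_value]),
        n_controls=1,
        n_cases=1,
    )
    return DsiNode(name=name, relevance=relevance, curve=curve)


class TestComposite:
    def test_weighted_mean_hand_arithmetic(self):
        root = DsiNode("root", 1.0, children=[_leaf("u", 0.5, 0.8), _leaf("v", 0.25, 0.2)])
        model = DsiModel(root=root)
        assert compute_dsi({"u": 1.0, "v": 1.0}, model) == pytest.approx(0.6)

    def test_single_leaf_equals_fitness(self, toy_training):
        tree = TreeConfig(root=TreeGroup("root", ["a"]))
        model = train(toy_training, tree)
        curve = fit_fitness(TOY_CONTROLS, TOY_CASES, "higher_abnormal")
        for x in np.arange(0.0, 9.0, 0.5):
            assert compute_dsi({"a": x}, model) == curve(x)

    def test_zero_relevance_variable_is_inert(self, toy_training, flat_tree):
        # "b" has identical class samples -> relevance 0 -> excluded exactly
        tree_a = TreeConfig(root=TreeGroup("root", ["a"]))
        with_b = train(toy_training, flat_tree)
        without_b = train(toy_training, tree_a)
        assert with_b.training_summary["b"]["relevance"] == 0.0
        for x in np.arange(-1.0, 10.0, 0.25):
            assert compute_dsi({"a": x, "b": 2.0}, with_b) == compute_dsi({"a": x}, without_b)

    def test_flat_tree_relevances_match_bruteforce(self, toy_training, flat_tree):
        model = train(toy_training, flat_tree)
        by_name = {c.name: c for c in model.root.children}
        assert by_name["a"].relevance == pytest.approx(brute_relevance(TOY_CONTROLS, TOY_CASES))
        assert by_name["b"].relevance == 0.0

    def test_all_missing_is_undefined_not_a_number(self, toy_training, flat_tree):
        model = train(toy_training, flat_tree)
        assert compute_dsi({"a": None, "b": None}, model) is None
        assert compute_dsi({}, model) is None

    def test_missing_variable_matches_model_trained_without_it(self, toy_training, flat_tree):
        full = train(toy_training, flat_tree)
        reduced = train(toy_training, TreeConfig(root=TreeGroup("root", ["a"])))
        for x in np.arange(0.0, 9.0, 0.5):
            assert compute_dsi({"a": x, "b": None}, full) == compute_dsi({"a": x}, reduced)

    def test_node_relevance_policies(self, toy_training):
        tree = TreeConfig(
            root=TreeGroup("root", [TreeGroup("grp", ["a", "b"])])
        )
        summed = train(toy_training, tree, node_relevance_policy="sum_children")
        composite = train(toy_training, tree, node_relevance_policy="composite_youden")
        grp_sum = summed.root.children[0]
        grp_comp = composite.root.children[0]
        assert grp_sum.relevance == pytest.approx(2.0 / 3.0)  # sum of 2/3 and 0
        # composite of a single informative leaf discriminates identically
        assert grp_comp.relevance == pytest.approx(2.0 / 3.0)
        with pytest.raises(ValueError, match="policy"):
            train(toy_training, tree, node_relevance_policy="nope")


def test_dsi_ranking_matches_reference_discriminator():
    """With large effect sizes, the index ranks patients about as well as an
    independent two-class reference discriminator on the same data."""
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.metrics import roc_auc_score
    import pandas as pd
    from dsindex import TrainingReference

    rng = np.random.default_rng(17)
    names = ["v0", "v1", "v2"]
    shift = 2.5  # standardized effect per variable

    def draw(n, case):
        return {k: rng.normal(shift if case else 0.0, 1.0, n) for k in names}

    training = TrainingReference(
        controls=pd.DataFrame(draw(300, False)), cases=pd.DataFrame(draw(300, True))
    )
    model = train(training, TreeConfig(root=TreeGroup("root", list(names))))

    test_ctl, test_cas = pd.DataFrame(draw(300, False)), pd.DataFrame(draw(300, True))
    test = pd.concat([test_ctl, test_cas], ignore_index=True)
    y = np.r_[np.zeros(300), np.ones(300)]
    dsi_scores = [compute_dsi(row._asdict(), model) for row in test.itertuples(index=False)]
    auc_dsi = roc_auc_score(y, dsi_scores)

    lda = LinearDiscriminantAnalysis().fit(
        pd.concat([training.controls, training.cases], ignore_index=True),
        np.r_[np.zeros(300), np.ones(300)],
    )
    auc_ref = roc_auc_score(y, lda.decision_function(test))
    assert abs(auc_dsi - auc_ref) < 0.05
    assert auc_dsi > 0.9


class TestFingerprint:
    def test_single_leaf_weight_one(self, toy_training):
        model = train(toy_training, TreeConfig(root=TreeGroup("root", ["a"])))
        fp = fingerprint({"a": 6.0}, model)
        assert fp.root.children[0].weight == 1.0
        assert fp.dsi == compute_dsi({"a": 6.0}, model)

    def test_missing_sibling_renormalizes_to_one(self):
        root = DsiNode("root", 1.0, children=[_leaf("u", 0.4, 0.9), _leaf("v", 0.4, 0.1)])
        model = DsiModel(root=root)
        fp = fingerprint({"u": 1.0, "v": None}, model)
        u, v = fp.root.children
        assert u.weight == 1.0
        assert v.missing and v.weight is None
        assert fp.dsi == pytest.approx(0.9)

    def test_json_document_schema(self, default_study):
        cohort, model, _ = default_study
        fp = fingerprint(cohort.patients[0], model)
        doc = json.loads(fp.to_json())
        assert set(doc) == {"patient_id", "dsi", "root"}
        node = doc["root"]
        assert set(node) == {"name", "kind", "relevance", "value", "weight", "missing", "children"}
        assert {c["name"] for c in node["children"]} == {"demographics", "cognitive", "csf", "mri_visual"}

    def test_text_and_svg_render(self, default_study):
        cohort, model, _ = default_study
        fp = fingerprint(cohort.patients[0], model)
        assert "DSI" in fp.to_text()
        svg = fp.to_svg()
        assert svg.startswith("<svg") and svg.endswith("</svg>")


class TestModelIO:
    def test_round_trip_preserves_scores_bitwise(self, toy_training, flat_tree, tmp_path):
        model = train(toy_training, flat_tree)
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        for x in np.arange(-2.0, 11.0, 0.37):
            assert compute_dsi({"a": x, "b": 2.0}, loaded) == compute_dsi({"a": x, "b": 2.0}, model)

    def test_round_trip_preserves_structure(self, toy_training, flat_tree, tmp_path):
        model = train(toy_training, flat_tree)
        path = tmp_path / "model.json"
        save_model(model, path)
        loaded = load_model(path)
        a0 = next(c for c in model.root.children if c.name == "a")
        a1 = next(c for c in loaded.root.children if c.name == "a")
        assert np.array_equal(a0.curve.breakpoints, a1.curve.breakpoints)
        assert np.array_equal(a0.curve.values, a1.curve.values)
        assert a1.relevance == a0.relevance
        assert loaded.training_summary == model.training_summary

    def test_version_mismatch_rejected(self, toy_training, flat_tree, tmp_path):
        model = train(toy_training, flat_tree)
        path = tmp_path / "model.json"
        save_model(model, path)
        doc = json.loads(path.read_text())
        doc["version"] = 99
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelFormatError, match="version"):
            load_model(path)

    def test_unknown_leaf_variable_rejected(self, toy_training, flat_tree, tmp_path):
        model = train(toy_training, flat_tree)
        path = tmp_path / "model.json"
        save_model(model, path)
        with pytest.raises(ModelFormatError, match="unknown"):
            load_model(path, known_variables=["a"])  # "b" is not declared
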