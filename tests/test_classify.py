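"""Intensity profiles, Random Forest labelling, and Lippert classes."""

import itertools

import numpy as np
import pytest

import cowtrack as ct
from cowtrack import classify
from cowtrack.classify import (
    LABEL_HYPO_APLASTIC,
    LABEL_NORMAL,
    IntensityProfile,
    LippertMapping,
    PathLabel,
    lippert,
    profile,
)
from cowtrack.template import SEGMENT_LABELS
from cowtrack.volume import Volume


def _straight_path(n=20):
    pts = np.column_stack([np.linspace(-8, 8, n), np.zeros(n), np.zeros(n)])
    return pts


# ---------------------------------------------------------------------------
# profiles


def test_profile_uniform_region():
    vol = Volume(np.full((40, 20, 20), 0.8), spacing=1.0, origin=(-20, -10, -10))
    p = profile(_straight_path(), vol, label="AcoA")
    assert len(p.values) == 50
    assert np.allclose(p.values, 0.8)


def test_profile_half_bright_split():
    data = np.zeros((40, 20, 20))
    data[:20] = 1.0  # x < 0 bright
    vol = Volume(data, spacing=1.0, origin=(-20, -10, -10))
    p = profile(_straight_path(), vol)
    n_bright = int((p.values > 0.9).sum())
    assert 20 <= n_bright <= 30


def test_profile_reversal_reverses_values():
    rng = np.random.default_rng(0)
    vol = Volume(rng.random((40, 20, 20)), spacing=1.0, origin=(-20, -10, -10))
    pts = _straight_path()
    fwd = profile(pts, vol).values
    bwd = profile(pts[::-1], vol).values
    np.testing.assert_allclose(bwd, fwd[::-1], atol=1e-12)


def test_profile_degenerate_path_rejected():
    vol = Volume(np.zeros((5, 5, 5)), spacing=1.0)
    with pytest.raises(ValueError):
        profile(np.array([[1.0, 1.0, 1.0]]), vol)
    with pytest.raises(ValueError, match="zero-length"):
        profile(np.array([[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]]), vol)


# ---------------------------------------------------------------------------
# random forest


def _separable_profiles(n_per_class=30, gap_center=0.5, gap=0.3, seed=0, n_minority=None):
    rng = np.random.default_rng(seed)
    profiles, labels = [], []
    n_pos = n_minority if n_minority is not None else n_per_class
    for _ in range(n_per_class):
        vals = np.clip(rng.normal(gap_center + gap / 2, 0.03, 50), 0, 1)
        profiles.append(IntensityProfile("x", vals))
        labels.append(LABEL_NORMAL)
    for _ in range(n_pos):
        vals = np.clip(rng.normal(gap_center - gap / 2, 0.03, 50), 0, 1)
        profiles.append(IntensityProfile("x", vals))
        labels.append(LABEL_HYPO_APLASTIC)
    return profiles, labels


def test_rf_separates_bright_from_faint():
    profiles, labels = _separable_profiles()
    model = classify.train_rf(profiles, labels, seed=0)
    pred = [pl.label for pl in classify.classify_paths(model, profiles)]
    assert ct.f1(pred, labels)["f1"] == 1.0


def test_rf_deterministic_given_seed():
    profiles, labels = _separable_profiles()
    test_p, _ = _separable_profiles(seed=9)
    a = classify.train_rf(profiles, labels, seed=3)
    b = classify.train_rf(profiles, labels, seed=3)
    sa = [pl.score for pl in classify.classify_paths(a, test_p)]
    sb = [pl.score for pl in classify.classify_paths(b, test_p)]
    assert sa == sb


def test_balanced_weights_help_minority_recall():
    from sklearn.ensemble import RandomForestClassifier

    profiles, labels = _separable_profiles(n_per_class=90, gap=0.12, seed=4, n_minority=10)
    X = np.stack([p.values for p in profiles])
    y = np.array([1 if l == LABEL_HYPO_APLASTIC else 0 for l in labels])
    test_p, test_l = _separable_profiles(n_per_class=50, gap=0.12, seed=5)
    Xt = np.stack([p.values for p in test_p])
    yt = np.array([1 if l == LABEL_HYPO_APLASTIC else 0 for l in test_l])

    balanced = classify.train_rf(profiles, labels, seed=0)
    plain = RandomForestClassifier(n_estimators=100, max_depth=2, random_state=0).fit(X, y)
    rec_bal = (balanced.predict(Xt)[yt == 1] == 1).mean()
    rec_plain = (plain.predict(Xt)[yt == 1] == 1).mean()
    assert rec_bal >= rec_plain


def test_rf_single_class_rejected():
    profiles, _ = _separable_profiles()
    with pytest.raises(ValueError, match="both classes"):
        classify.train_rf(profiles, [LABEL_NORMAL] * len(profiles))


def test_classify_background_profile_is_hypo_aplastic():
    profiles, labels = _separable_profiles()
    model = classify.train_rf(profiles, labels, seed=0)
    dark = [IntensityProfile("PcoA-L", np.full(50, 0.02))]
    out = classify.classify_paths(model, dark)[0]
    assert out.label == LABEL_HYPO_APLASTIC
    assert out.score > 0.5


def test_score_at_threshold_is_hypo_aplastic():
    lab = PathLabel(label=LABEL_HYPO_APLASTIC, score=0.5, threshold=0.5)
    assert lab.label == LABEL_HYPO_APLASTIC
    with pytest.raises(ValueError):
        PathLabel(label=LABEL_NORMAL, score=0.5, threshold=0.5)


def test_feature_length_mismatch_rejected():
    profiles, labels = _separable_profiles()
    model = classify.train_rf(profiles, labels, seed=0)
    bad = IntensityProfile("x", np.zeros(50))
    bad.values = np.zeros(10)  # bypass constructor check
    with pytest.raises(ValueError, match="features"):
        classify.classify_paths(model, [bad])


# ---------------------------------------------------------------------------
# Lippert classes


def _labels(ha: set[str]) -> dict[str, str]:
    return {
        s: (LABEL_HYPO_APLASTIC if s in ha else LABEL_NORMAL) for s in SEGMENT_LABELS
    }


def test_lippert_all_normal():
    assert lippert(_labels(set())) == ("A", "P0")


def test_lippert_both_pcoa():
    assert lippert(_labels({"PcoA-L", "PcoA-R"})) == ("A", "P2")


def test_lippert_examples():
    assert lippert(_labels({"AcoA"})) == ("B", "P0")
    assert lippert(_labels({"ACA-A1-L"})) == ("C", "P0")
    assert lippert(_labels({"PcoA-R"})) == ("A", "P1")
    assert lippert(_labels({"PCA-P1-L"})) == ("A", "P3")
    assert lippert(_labels({"PCA-P1-L", "PcoA-L"})) == ("A", "P4")


def test_lippert_total_over_all_patterns():
    anterior_seen, posterior_seen = set(), set()
    for bits in itertools.product([False, True], repeat=7):
        ha = {s for s, b in zip(SEGMENT_LABELS, bits) if b}
        ant, post = lippert(_labels(ha))
        assert ant in {"A", "B", "C"}
        assert post in {"P0", "P1", "P2", "P3", "P4"}
        anterior_seen.add(ant)
        posterior_seen.add(post)
    assert anterior_seen == {"A", "B", "C"}
    assert posterior_seen == {"P0", "P1", "P2", "P3", "P4"}


def test_lippert_mirror_symmetry():
    def mirror(ha):
        sw = {"ACA-A1-L": "ACA-A1-R", "ACA-A1-R": "ACA-A1-L",
              "PCA-P1-L": "PCA-P1-R", "PCA-P1-R": "PCA-P1-L",
              "PcoA-L": "PcoA-R", "PcoA-R": "PcoA-L", "AcoA": "AcoA"}
        return {sw[s] for s in ha}

    for ha in [{"PcoA-L"}, {"ACA-A1-L"}, {"PCA-P1-R", "PcoA-R"}, {"AcoA", "PcoA-L"}]:
        assert lippert(_labels(ha)) == lippert(_labels(mirror(ha)))


def test_lippert_missing_segment_rejected():
    labels = _labels(set())
    del labels["AcoA"]
    with pytest.raises(ValueError, match="missing"):
        lippert(labels)


def test_lippert_override_mapping():
    mapping = LippertMapping(posterior_overrides={(False, False, True, True): "custom"})
    assert lippert(_labels({"PcoA-L", "PcoA-R"}), mapping) == ("A", "custom")


# ---------------------------------------------------------------------------
# graph container


def test_cow_graph_serialization(tmp_path, oracle_bundle):
    import networkx as nx

    b = oracle_bundle
    profiles, labels_true = classify.training_profiles_from_ground_truth(b.norm, b.gt)
    tr_p, tr_l = _separable_profiles()
    model = classify.train_rf(tr_p, tr_l, seed=0)
    path_labels = dict(zip(SEGMENT_LABELS, classify.classify_paths(
        model, [classify.profile(b.paths[s], b.norm) for s in SEGMENT_LABELS]
    )))
    graph = classify.CowGraph.build(b.lm, b.paths, path_labels)
    graph.to_json(tmp_path / "g.json")
    graph.to_graphml(tmp_path / "g.graphml")
    g = nx.read_graphml(tmp_path / "g.graphml")
    assert g.number_of_nodes() == 9
    assert g.number_of_edges() == 7
    assert g.graph["anterior_class"] in {"A", "B", "C"}
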