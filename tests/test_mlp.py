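"""MLP committee: convergence, selection contract, reproducibility, I/O."""

import numpy as np
import pytest

from radiomarker import (
    Committee,
    CommitteeConfig,
    InputMode,
    classify,
    encode_frame,
    normalize,
    train_committee,
)
from radiomarker.mlp_classifier import MLP
from radiomarker.synth_phantom import make_classification_set


def _toy_dataset(seed=0, n=40):
    rng = np.random.default_rng(seed)
    X = np.vstack(
        [rng.normal([0.2, 0.2], 0.05, (n, 2)), rng.normal([0.8, 0.8], 0.05, (n, 2))]
    )
    T = np.vstack([np.tile([1.0, 0.0], (n, 1)), np.tile([0.0, 1.0], (n, 1))])
    return X, T


@pytest.fixture(scope="module")
def small_set():
    """Normalized 10-per-class phantom set (kept small for unit tests)."""
    data = make_classification_set(10, seed=3)
    return [(normalize(frame), label) for frame, label in data]


@pytest.fixture(scope="module")
def small_config():
    return CommitteeConfig(hidden_layers=(16,), n_networks=3, max_epochs=80, seed=0)


@pytest.fixture(scope="module")
def small_committee(small_set, small_config):
    return train_committee(small_set, small_config)


def test_toy_problem_converges_quickly():
    X, T = _toy_dataset()
    net = MLP([2, 4, 2], seed=0)
    err = net.train(X, T, epochs=500, learning_rate=0.2)
    assert err < 0.05


def test_single_network_committee_selects_index_zero(small_set):
    cfg = CommitteeConfig(hidden_layers=(8,), n_networks=1, max_epochs=20, seed=1)
    committee = train_committee(small_set, cfg)
    assert committee.best_index == 0


def test_best_network_has_minimal_training_error(small_committee):
    best = small_committee.training_errors[small_committee.best_index]
    assert all(best <= e for e in small_committee.training_errors)


def test_scores_in_unit_interval_for_arbitrary_input(small_committee, rng):
    for _ in range(5):
        x = rng.uniform(-10, 10, 1024)
        s = small_committee.scores(x)
        assert np.all(s >= 0.0) and np.all(s <= 1.0)
    zeros = small_committee.scores(np.zeros(1024))
    assert np.all((zeros >= 0.0) & (zeros <= 1.0))


def test_training_is_bit_for_bit_reproducible(small_set, small_config):
    c1 = train_committee(small_set, small_config)
    c2 = train_committee(small_set, small_config)
    assert c1.best_index == c2.best_index
    assert c1.training_errors == c2.training_errors
    for n1, n2 in zip(c1.networks, c2.networks):
        for w1, w2 in zip(n1.weights, n2.weights):
            np.testing.assert_array_equal(w1, w2)


def test_committee_mean_combination(small_committee, rng):
    x = rng.uniform(0, 1, 1024)
    mean = small_committee.scores(x, combine="mean")
    manual = np.mean([net.forward(x) for net in small_committee.networks], axis=0)
    np.testing.assert_allclose(mean, manual)
    with pytest.raises(ValueError):
        small_committee.scores(x, combine="median")


def test_too_few_examples_per_class_rejected(small_set):
    tiny = [s for s in small_set if s[1] != "norm"] + [
        s for s in small_set if s[1] == "norm"
    ][:3]
    with pytest.raises(ValueError, match="norm"):
        train_committee(tiny, CommitteeConfig(n_networks=1, max_epochs=5))


def test_serialization_round_trip(tmp_path, small_committee, rng):
    path = tmp_path / "model.json"
    small_committee.to_json(path)
    back = Committee.from_json(path)
    assert back.class_names == small_committee.class_names
    assert back.best_index == small_committee.best_index
    x = rng.uniform(0, 1, 1024)
    np.testing.assert_allclose(back.scores(x), small_committee.scores(x))


def test_classify_report_structure(small_committee, three_class_phantom):
    frame, truth = three_class_phantom
    frame = normalize(frame)
    report = classify(
        frame,
        truth.vert_roi,
        small_committee,
        with_markers=True,
        disc_roi=truth.disc_roi,
    )
    assert set(report.scores) == {"norm", "mst", "hema"}
    assert all(0.0 <= s <= 1.0 for s in report.scores.values())
    assert "arcela" in report.markers and "caldera" in report.markers
    assert report.training_error_best == pytest.approx(
        min(small_committee.training_errors)
    )


def test_phash_input_mode(small_set):
    cfg = CommitteeConfig(
        input_mode=InputMode.PHASH_BITS,
        hidden_layers=(16,),
        n_networks=1,
        max_epochs=60,
        seed=0,
    )
    committee = train_committee(small_set, cfg)
    x = encode_frame(small_set[0][0], InputMode.PHASH_BITS)
    assert set(np.unique(x)) <= {0.0, 1.0}
    s = committee.scores(x)
    assert np.all((s >= 0) & (s <= 1))


def test_agrees_with_reference_classifier(small_set):
    """Independent cross-check: scikit-learn's MLP, trained on the same
    encoded set, agrees with our committee on nearly all decisions."""
    sklearn = pytest.importorskip("sklearn.neural_network")
    cfg = CommitteeConfig(hidden_layers=(16,), n_networks=3, max_epochs=120, seed=0)
    committee = train_committee(small_set, cfg)
    X = np.stack([encode_frame(f, cfg.input_mode) for f, _ in small_set])
    y = [label for _, label in small_set]
    ref = sklearn.MLPClassifier(
        hidden_layer_sizes=(16,), max_iter=2000, random_state=0
    ).fit(X, y)
    ours = [
        committee.class_names[int(np.argmax(committee.scores(x)))] for x in X
    ]
    agreement = np.mean([a == b for a, b in zip(ours, ref.predict(X))])
    assert agreement >= 0.9
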