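"""ANN-to-SNN conversion: encodings, classification, fidelity."""

import numpy as np
import pytest

from spikebench.dnn2snn import (
    UNDECIDED,
    DenseReLUStack,
    EncodingSpec,
    classify,
    convert,
    encode_input,
    evaluate,
)
from spikebench.fixtures import gen_tiny_mlp
from spikebench.simulator import simulate


@pytest.fixture(scope="module")
def mlp():
    return gen_tiny_mlp((16, 8, 2), "separable-blobs", n_samples=24, seed=1)


def test_layer_dimension_mismatch_rejected():
    with pytest.raises(ValueError, match="mismatch"):
        DenseReLUStack([np.zeros((4, 3)), np.zeros((5, 2))])


def test_layout_preserved_in_conversion():
    ann = DenseReLUStack([np.ones((81, 100)) * 0.01, np.ones((100, 10)) * 0.01])
    net = convert(ann, EncodingSpec(mode="ttfs"))
    sizes = {p.id: p.size for p in net.populations}
    assert sizes["layer0"] == 81
    assert sizes["layer1"] == 100
    assert sizes["layer2"] == 10


def test_deep_layout_accepted():
    rng = np.random.default_rng(0)
    ann = DenseReLUStack([
        rng.normal(size=(784, 1200)) * 1e-3,
        rng.normal(size=(1200, 1200)) * 1e-3,
        rng.normal(size=(1200, 10)) * 1e-3,
    ])
    assert ann.layout == (784, 1200, 1200, 10)


@pytest.mark.parametrize(
    "x, expected_time",
    [(1.0, 0.0), (0.5, 10.0), (0.0, 20.0)],
)
def test_ttfs_latency_formula(x, expected_time):
    enc = EncodingSpec(mode="ttfs", T=20.0, ttfs_cutoff=0.0)
    spec = encode_input(np.array([x]), enc)[0]
    times = spec["params"]["spike_times"]
    assert times == [pytest.approx(expected_time)]


def test_ttfs_cutoff_drops_dim_inputs():
    enc = EncodingSpec(mode="ttfs", T=20.0, ttfs_cutoff=0.05)
    spec = encode_input(np.array([0.01]), enc)[0]
    assert spec["params"]["spike_times"] == []


def test_rate_mode_zero_input_silent():
    enc = EncodingSpec(mode="rate", max_freq=400.0)
    spec = encode_input(np.array([0.0]), enc)[0]
    assert spec["params"]["rate"] == 0.0


def test_rate_is_linear_in_input():
    enc = EncodingSpec(mode="rate", max_freq=400.0)
    specs = encode_input(np.array([0.25, 0.5, 1.0]), enc)
    assert [s["params"]["rate"] for s in specs] == [100.0, 200.0, 400.0]


def test_input_outside_unit_interval_rejected():
    with pytest.raises(ValueError):
        encode_input(np.array([1.2]), EncodingSpec())


def test_ttfs_monotonicity_brighter_never_later():
    enc = EncodingSpec(mode="ttfs", T=25.0, ttfs_cutoff=0.0)
    xs = np.linspace(0, 1, 11)
    times = [encode_input(np.array([x]), enc)[0]["params"]["spike_times"][0]
             for x in xs]
    assert all(a >= b for a, b in zip(times, times[1:]))


def test_classify_rate_argmax_and_tie_break():
    class R:
        spikes = {"out": [np.empty(0), np.ones(12), np.ones(3)]}

    label, _ = classify(R(), EncodingSpec(mode="rate"), "out")
    assert label == 1

    class Tie:
        spikes = {"out": [np.ones(3), np.ones(3)]}

    label, _ = classify(Tie(), EncodingSpec(mode="rate"), "out")
    assert label == 0  # documented lowest-index tie-break


def test_classify_ttfs_earliest_spike_and_response_time():
    class R:
        spikes = {"out": [np.empty(0), np.array([9.0]), np.empty(0),
                          np.array([8.1])]}

    label, rt = classify(R(), EncodingSpec(mode="ttfs"), "out",
                         first_input_time=0.0)
    assert label == 3
    assert rt == pytest.approx(8.1)


def test_classify_silent_output_is_undecided():
    class R:
        spikes = {"out": [np.empty(0), np.empty(0)]}

    label, _ = classify(R(), EncodingSpec(mode="rate"), "out")
    assert label == UNDECIDED


def test_parallel_partitioning_leaves_accuracy_unchanged(mlp):
    ann, (X, y) = mlp
    enc = EncodingSpec(mode="rate", max_freq=500.0, presentation=150.0,
                       weight_scale=0.5)
    acc1, _ = evaluate(ann, enc, (X[:12], y[:12]), parallel_instances=1, seed=1)
    acc8, _ = evaluate(ann, enc, (X[:12], y[:12]), parallel_instances=8, seed=1)
    assert acc1 == acc8


def test_zero_weight_scale_leaves_output_silent(mlp):
    ann, (X, y) = mlp
    enc = EncodingSpec(mode="rate", max_freq=500.0, presentation=100.0,
                       weight_scale=0.0)
    net = convert(ann, enc, x=X[0])
    result = simulate(net, enc.presentation, seed=1)
    assert all(len(t) == 0 for t in result.spikes["layer2"])
    acc, _ = evaluate(ann, enc, (X[:4], y[:4]), seed=1)
    assert acc == 0.0  # all UNDECIDED counts wrong


def test_empty_dataset_rejected(mlp):
    ann, _ = mlp
    with pytest.raises(ValueError, match="empty"):
        evaluate(ann, EncodingSpec(), (np.empty((0, 16)), np.empty(0)))


def test_rate_output_counts_grow_with_presentation_time(mlp):
    ann, (X, _) = mlp
    enc = EncodingSpec(mode="rate", max_freq=500.0, weight_scale=0.5)
    counts = []
    for presentation in (100.0, 200.0, 400.0):
        net = convert(ann, enc, x=X[0])
        result = simulate(net, presentation, seed=2)
        counts.append(sum(len(t) for t in result.spikes["layer2"]))
    assert counts[0] <= counts[1] <= counts[2]
    assert counts[2] > 0


def test_snn_accuracy_close_to_ann_on_separable_fixture(mlp):
    ann, (X, y) = mlp
    ann_acc = 100.0 * np.mean(ann.predict(X) == y)
    enc = EncodingSpec(mode="rate", max_freq=500.0, presentation=200.0,
                       weight_scale=0.5)
    snn_acc, _ = evaluate(ann, enc, (X, y), seed=1)
    assert snn_acc >= ann_acc - 2.0


def test_ttfs_classification_on_fixture(mlp):
    ann, (X, y) = mlp
    enc = EncodingSpec(mode="ttfs", T=20.0, presentation=60.0,
                       weight_scale=0.05)
    acc, rt = evaluate(ann, enc, (X[:12], y[:12]), seed=1)
    assert acc >= 80.0
    assert 0.0 <= rt <= 60.0


def test_rank_order_fidelity_on_random_small_anns():
    """SNN output-count rank order matches ANN activations for >= 90% of
    samples at adequate rate and presentation length."""
    rng = np.random.default_rng(7)
    hits = 0
    total = 0
    for trial in range(3):
        w1 = np.abs(rng.normal(0.3, 0.15, (6, 5)))
        w2 = np.abs(rng.normal(0.3, 0.15, (5, 3)))
        ann = DenseReLUStack([w1, w2])
        enc = EncodingSpec(mode="rate", max_freq=500.0, presentation=400.0,
                           weight_scale=1.2)
        for s in range(4):
            x = rng.uniform(0.2, 1.0, 6)
            net = convert(ann, enc, x=x)
            result = simulate(net, enc.presentation, seed=100 + s)
            counts = np.array([len(t) for t in result.spikes["layer2"]])
            total += 1
            if np.argmax(counts) == np.argmax(ann.forward(x)):
                hits += 1
    assert hits / total >= 0.9


def test_weight_stack_h5_and_json_round_trip(tmp_path, mlp):
    ann, _ = mlp
    h5 = tmp_path / "w.h5"
    js = tmp_path / "w.json"
    ann.save_h5(h5)
    ann.save_json(js)
    for restored in (DenseReLUStack.load_h5(h5), DenseReLUStack.load_json(js)):
        assert restored.layout == ann.layout
        for a, b in zip(restored.weights, ann.weights):
            assert np.allclose(a, b)
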