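"""CRF inference and training: enumeration oracles, gradient checks,
optimizer behavior, serialization."""

import itertools

import numpy as np
import pytest

from bacner import (
    CRFModel,
    ConfigError,
    Gazetteer,
    LabelSet,
    SentenceLattice,
    conditional_log_prob,
    generate_corpus,
    log_partition,
    marginals,
    nll_and_gradient,
    sequence_score,
    train,
    viterbi,
)
from bacner.crf import TrainConfig
from bacner.features import FeatureIndex
from bacner.synth import SynthConfig

from conftest import enum_log_partition, enum_marginals, enumerate_scores, make_random_model


def zero_model(n=3, L=3):
    strings = ["B", "U:word[0]=a", "U:word[0]=b"]
    labels = LabelSet(tuple(f"L{i}" for i in range(L)))
    model = CRFModel(labels, FeatureIndex.from_strings(strings),
                     "U:%x[0,word]\nB\n", Gazetteer())
    kt = model.n_trans
    lattice = SentenceLattice(
        [np.array([kt], dtype=np.intp)] * n,
        [np.array([0], dtype=np.intp)] * (n - 1),
        n,
    )
    return model, lattice


class TestScoring:
    def test_zero_weights_score_zero(self):
        model, lat = zero_model()
        for y in itertools.product(range(model.L), repeat=lat.n):
            assert sequence_score(model, lat, list(y)) == 0.0

    def test_single_active_feature(self):
        model, lat = zero_model(n=1)
        kt, L = model.n_trans, model.L
        # weight w on (first state feature, label 1)
        model.weights[kt * L * L + 1] = 2.5
        assert sequence_score(model, lat, [1]) == pytest.approx(2.5)
        assert sequence_score(model, lat, [0]) == 0.0

    def test_label_out_of_range(self):
        model, lat = zero_model()
        with pytest.raises(ConfigError):
            sequence_score(model, lat, [0, 0, 99])

    def test_length_mismatch(self):
        model, lat = zero_model()
        with pytest.raises(ConfigError):
            sequence_score(model, lat, [0])


class TestInferenceOracles:
    """log_partition / viterbi / marginals vs exhaustive enumeration."""

    @pytest.mark.parametrize("seed", range(30))
    def test_agreement_with_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 7))
        L = int(rng.integers(2, 5))
        model, lat = make_random_model(rng, n, L)
        scores = enumerate_scores(model, lat)

        assert log_partition(model, lat) == pytest.approx(
            enum_log_partition(scores), abs=1e-10)

        path = viterbi(model, lat)
        assert sequence_score(model, lat, path) == pytest.approx(
            max(scores.values()), abs=1e-10)

        node, edge = marginals(model, lat)
        enode, eedge = enum_marginals(scores, n, L)
        assert np.abs(node - enode).max() < 1e-10
        if n > 1:
            assert np.abs(edge - eedge).max() < 1e-10

        total = sum(np.exp(conditional_log_prob(model, lat, list(y))) for y in scores)
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_zero_weights_closed_forms(self):
        model, lat = zero_model(n=4, L=3)
        model.weights[:] = 0.0
        assert log_partition(model, lat) == pytest.approx(4 * np.log(3))
        assert conditional_log_prob(model, lat, [0, 1, 2, 0]) == pytest.approx(-4 * np.log(3))
        node, edge = marginals(model, lat)
        assert np.allclose(node, 1 / 3)
        assert np.allclose(edge, 1 / 9)

    def test_single_position_closed_form(self):
        model, lat = zero_model(n=1, L=3)
        kt, L = model.n_trans, model.L
        s = np.array([0.3, -1.2, 0.7])
        model.weights[kt * L * L : kt * L * L + L] = s
        assert log_partition(model, lat) == pytest.approx(
            np.log(np.exp(s).sum()), abs=1e-12)

    def test_node_marginal_consistent_with_edge_sums(self):
        rng = np.random.default_rng(123)
        model, lat = make_random_model(rng, 5, 3)
        node, edge = marginals(model, lat)
        for e in range(4):
            assert np.allclose(edge[e].sum(axis=1), node[e], atol=1e-9)
            assert np.allclose(edge[e].sum(axis=0), node[e + 1], atol=1e-9)

    def test_shift_invariance(self):
        # adding a constant to all state scores at one position changes no
        # conditional probability
        rng = np.random.default_rng(5)
        model, lat = make_random_model(rng, 4, 3)
        y = [1, 0, 2, 1]
        before = conditional_log_prob(model, lat, y)
        kt, L = model.n_trans, model.L
        fid = int(lat.state_fids[2][0]) if lat.state_fids[2].size else None
        if fid is None:
            lat.state_fids[2] = np.array([kt], dtype=np.intp)
            fid = kt
        model.weights[kt * L * L + (fid - kt) * L : kt * L * L + (fid - kt) * L + L] += 3.7
        assert conditional_log_prob(model, lat, y) == pytest.approx(before, abs=1e-9)

    def test_monotone_in_active_weight(self):
        # raising the weight of a feature active only under y raises P(y|x)
        model, lat = zero_model(n=2, L=2)
        kt, L = model.n_trans, model.L
        y = [1, 1]
        p0 = conditional_log_prob(model, lat, y)
        model.weights[kt * L * L + 1] += 0.5  # state feature, label 1
        assert conditional_log_prob(model, lat, y) > p0


class TestGradient:
    def _fixture(self, n_sent=4, seed=11):
        cfg = SynthConfig(n_sentences=n_sent, seed=seed)
        corpus, _ = generate_corpus(cfg)
        model = train(corpus, max_iter=0)
        batch = [
            (model.build_lattice(s.tokens), [model.labels.index(t) for t in s.tags])
            for s in corpus
        ]
        return model, batch

    def test_nll_at_zero_weights(self):
        model, batch = self._fixture()
        f, _ = nll_and_gradient(model, batch, 1.0)
        expected = sum(lat.n for lat, _ in batch) * np.log(model.L)
        assert f == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("where", ["zero", "random"])
    def test_matches_finite_differences(self, where):
        model, batch = self._fixture()
        rng = np.random.default_rng(3)
        w = (np.zeros(model.n_weights) if where == "zero"
             else rng.normal(scale=0.5, size=model.n_weights))
        _, g = nll_and_gradient(model, batch, 1.0, weights=w)
        eps = 1e-6
        for k in rng.choice(model.n_weights, size=30, replace=False):
            wp, wm = w.copy(), w.copy()
            wp[k] += eps
            wm[k] -= eps
            fp, _ = nll_and_gradient(model, batch, 1.0, weights=wp)
            fm, _ = nll_and_gradient(model, batch, 1.0, weights=wm)
            fd = (fp - fm) / (2 * eps)
            assert abs(fd - g[k]) <= 1e-5 * max(1.0, abs(fd))

    def test_penalty_gradient_alone(self):
        model, batch = self._fixture()
        # empty activations: a lattice with no features contributes only logZ,
        # whose gradient is zero, leaving w / sigma^2
        empty = SentenceLattice(
            [np.array([], dtype=np.intp)] * 2, [np.array([], dtype=np.intp)], 2)
        rng = np.random.default_rng(0)
        w = rng.normal(size=model.n_weights)
        sigma = 2.0
        _, g = nll_and_gradient(model, [(empty, [0, 0])], sigma, weights=w)
        assert np.allclose(g, w / sigma**2)

    def test_sigma_must_be_positive(self):
        model, batch = self._fixture()
        with pytest.raises(ConfigError):
            nll_and_gradient(model, batch, 0.0)


class TestTraining:
    def test_separable_corpus_fits_perfectly(self, toy_corpus):
        from bacner import evaluate_tags, predict_corpus
        corpus, _ = toy_corpus
        model = train(corpus, dictionary=[])
        pred = predict_corpus(model, [s.surfaces for s in corpus])
        report = evaluate_tags([s.tags for s in corpus], pred)
        assert report["overall"]["f_measure"] == 100.0

    def test_max_iter_zero_gives_tie_break_predictions(self, toy_corpus):
        corpus, _ = toy_corpus
        model = train(corpus, max_iter=0)
        assert np.all(model.weights == 0)
        tags = model.predict(corpus.sentences[0].surfaces)
        # label id 0 is O by the documented ordering
        assert tags == ["O"] * len(corpus.sentences[0])

    def test_nll_monotone_over_lbfgs_iterates(self, toy_corpus):
        corpus, _ = toy_corpus
        model = train(corpus)
        nlls = [row["nll"] for row in model.training_log]
        assert len(nlls) >= 2
        assert all(b <= a + 1e-9 for a, b in zip(nlls, nlls[1:]))

    def test_optimizers_reach_common_optimum(self, toy_corpus):
        corpus, _ = toy_corpus
        m_lbfgs = train(corpus, optimizer="lbfgs")
        m_adam = train(corpus, optimizer="adam", max_iter=4000, learning_rate=0.1)
        m_ada = train(corpus, optimizer="adagrad", max_iter=4000, learning_rate=0.5)
        ref = m_lbfgs.training_log[-1]["nll"]
        assert m_adam.training_log[-1]["nll"] == pytest.approx(ref, abs=1e-3)
        assert m_ada.training_log[-1]["nll"] == pytest.approx(ref, abs=1e-3)

    def test_deterministic_given_seed(self, toy_corpus):
        corpus, _ = toy_corpus
        cfg = TrainConfig(optimizer="sgd", max_iter=5, seed=7)
        m1 = train(corpus, config=cfg)
        m2 = train(corpus, config=cfg)
        assert np.array_equal(m1.weights, m2.weights)

    def test_empty_corpus_rejected(self):
        from bacner import Corpus
        with pytest.raises(ConfigError):
            train(Corpus([]))


class TestSerialization:
    def test_save_load_bit_identical_predictions(self, toy_corpus, tmp_path):
        corpus, _ = toy_corpus
        model = train(corpus, max_iter=40)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = CRFModel.load(path)
        assert np.array_equal(model.weights, loaded.weights)
        for sent in corpus:
            assert model.predict(sent.surfaces) == loaded.predict(sent.surfaces)

    def test_newer_version_fails_loudly(self, toy_corpus, tmp_path):
        import json
        corpus, _ = toy_corpus
        model = train(corpus, max_iter=0)
        path = tmp_path / "model.json"
        model.save(path)
        payload = json.loads(path.read_text())
        payload["format_version"] = 999
        path.write_text(json.dumps(payload))
        from bacner import ParseError
        with pytest.raises(ParseError, match="newer"):
            CRFModel.load(path)
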