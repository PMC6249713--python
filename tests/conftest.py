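"""Shared fixtures: tiny corpora and randomly parameterized small CRFs with a
brute-force enumeration oracle (independent of the package's dynamic
programming — scores are summed with plain Python loops over the flat weight
vector)."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from bacner import CRFModel, Gazetteer, LabelSet, SentenceLattice
from bacner.features import FeatureIndex


def make_random_model(rng: np.random.Generator, n: int, L: int,
                      n_state: int = 6, n_trans: int = 3,
                      scale: float = 1.0) -> tuple[CRFModel, SentenceLattice]:
    """A random small CRF plus a random lattice over ``n`` positions."""
    strings = sorted(
        [f"B{k:02d}" for k in range(n_trans)]
        + [f"U{k:02d}:word[0]=v{k}" for k in range(n_state)]
    )
    labels = LabelSet(tuple(f"L{i}" for i in range(L)))
    model = CRFModel(labels, FeatureIndex.from_strings(strings),
                     "U00:%x[0,word]\nB\n", Gazetteer())
    model.weights = rng.normal(scale=scale, size=model.n_weights)
    kt = model.n_trans
    state = [
        np.sort(rng.choice(np.arange(kt, kt + n_state),
                           size=rng.integers(0, n_state + 1), replace=False)).astype(np.intp)
        for _ in range(n)
    ]
    edge = [
        np.sort(rng.choice(np.arange(kt),
                           size=rng.integers(0, kt + 1), replace=False)).astype(np.intp)
        for _ in range(max(n - 1, 0))
    ]
    return model, SentenceLattice(state, edge, n)


def enumerate_scores(model: CRFModel, lattice: SentenceLattice) -> dict[tuple, float]:
    """Score every label sequence by direct summation over active feature
    weights (no shared code with the forward/Viterbi implementations)."""
    L, Kt = model.L, model.n_trans
    w = model.weights
    split = Kt * L * L
    scores = {}
    for y in itertools.product(range(L), repeat=lattice.n):
        s = 0.0
        for i, fids in enumerate(lattice.state_fids):
            for f in fids:
                s += w[split + (int(f) - Kt) * L + y[i]]
        for e, fids in enumerate(lattice.edge_fids):
            for f in fids:
                s += w[int(f) * L * L + y[e] * L + y[e + 1]]
        scores[y] = s
    return scores


def enum_log_partition(scores: dict[tuple, float]) -> float:
    m = max(scores.values())
    return m + math.log(sum(math.exp(s - m) for s in scores.values()))


def enum_marginals(scores: dict[tuple, float], n: int, L: int):
    logZ = enum_log_partition(scores)
    node = np.zeros((n, L))
    edge = np.zeros((max(n - 1, 0), L, L))
    for y, s in scores.items():
        p = math.exp(s - logZ)
        for i in range(n):
            node[i, y[i]] += p
        for e in range(n - 1):
            edge[e, y[e], y[e + 1]] += p
    return node, edge


@pytest.fixture
def toy_corpus():
    """A 10-sentence separable corpus: entity vocabulary disjoint from
    context vocabulary, so a trained model can fit it perfectly."""
    from bacner import SynthConfig, generate_corpus

    cfg = SynthConfig(n_sentences=10, entity_rate=1.0, oov_rate=0.0,
                      abbrev_rate=0.0, noise_rate=0.0, seed=42)
    corpus, gold = generate_corpus(cfg)
    return corpus, gold
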