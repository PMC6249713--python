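"""Linear-chain conditional random field.

The model assigns a label sequence y = (y_1..y_n) given an observation
sequence x the conditional probability

    P(y|x) = exp{ sum_i sum_k  w_k f_k(y_{i-1}, y_i, x, i) } / Z(x)

where the features factor into *state* functions s_l(y_i, x, i) — one weight
per (expanded feature string, label) — and *transition* functions
t_k(y_{i-1}, y_i, x, i) — one weight per (feature string, label pair).
Transition factors attach to edges between consecutive positions; the first
position carries state factors only, and its distinguished context is
expressed through feature strings containing the ``_BOS_`` sentinel (the
virtual begin-of-sentence label folded into position-1 state scores).

All dynamic programming runs in log space with log-sum-exp; training
minimizes the L2-penalized negative log-likelihood

    NLL(w) = sum_j [ log Z(x_j) - score(x_j, y_j) ] + ||w||^2 / (2 sigma^2)

which is convex, from the zero vector, with L-BFGS (default) or full-batch
Adam/AdaGrad or stochastic gradient descent.  Decoding is Viterbi with ties
broken toward the lowest label id.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from ._version import __version__
from .corpus import Corpus, Token
from .errors import ConfigError, ParseError
from .features import (
    DEFAULT_TEMPLATES,
    FeatureIndex,
    FeatureTemplate,
    Gazetteer,
    build_feature_index,
    expand_templates,
    parse_templates,
    token_attributes,
)

__all__ = [
    "LabelSet",
    "SentenceLattice",
    "CRFModel",
    "TrainConfig",
    "sequence_score",
    "log_partition",
    "conditional_log_prob",
    "marginals",
    "nll_and_gradient",
    "viterbi",
    "train",
]

MODEL_FORMAT = "bacner.crf-model"
MODEL_VERSION = 1


@dataclass(frozen=True)
class LabelSet:
    """Ordered label alphabet; order is fixed at training time and serialized.

    The default ordering puts ``O`` first (so the zero-weight model's
    tie-break prediction is ``O``), then the remaining tags sorted.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise ConfigError("labels must be distinct")
        if not self.labels:
            raise ConfigError("label set must be non-empty")

    @classmethod
    def from_tags(cls, tags: Iterable[str]) -> "LabelSet":
        uniq = set(tags)
        ordered = (["O"] if "O" in uniq else []) + sorted(uniq - {"O"})
        return cls(tuple(ordered))

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)


@dataclass
class SentenceLattice:
    """Active feature ids for one sentence, independent of any labels.

    ``state_fids[i]`` are ids active at position i; ``edge_fids[e]`` are ids
    active on the edge (e, e+1), e = 0..n-2.
    """

    state_fids: list[np.ndarray]
    edge_fids: list[np.ndarray]
    n: int

    def __post_init__(self) -> None:
        if len(self.state_fids) != self.n or len(self.edge_fids) != max(self.n - 1, 0):
            raise ConfigError("lattice shape inconsistent with sentence length")


@dataclass
class TrainConfig:
    """Training hyperparameters.

    ``l2_sigma`` is the Gaussian prior standard deviation (penalty
    ||w||^2 / (2 sigma^2)); ``tol`` is the gradient infinity-norm convergence
    threshold; ``learning_rate`` applies to the first-order optimizers only.
    """

    optimizer: str = "lbfgs"
    max_iter: int = 200
    tol: float = 1e-4
    l2_sigma: float = 1.0
    seed: int = 0
    min_count: int = 1
    learning_rate: float = 0.1
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    sgd_decay: float = 0.05

    def __post_init__(self) -> None:
        if self.optimizer not in ("lbfgs", "sgd", "adam", "adagrad"):
            raise ConfigError(f"unknown optimizer {self.optimizer!r}")
        if self.l2_sigma <= 0:
            raise ConfigError("l2_sigma must be > 0")
        if self.max_iter < 0:
            raise ConfigError("max_iter must be >= 0")
        if self.min_count < 1:
            raise ConfigError("min_count must be >= 1")


class CRFModel:
    """A trained (or zero-initialized) linear-chain CRF.

    Weight layout: the feature index orders transition strings (``B...``)
    before state strings (``U...``) lexicographically; the flat weight vector
    holds one (L, L) block per transition feature followed by one (L,) block
    per state feature.
    """

    def __init__(
        self,
        labels: LabelSet,
        index: FeatureIndex,
        templates_text: str,
        dictionary: Gazetteer,
        weights: Union[np.ndarray, None] = None,
        config: Union[dict, None] = None,
    ):
        self.labels = labels
        self.index = index
        self.templates_text = templates_text
        self.templates = parse_templates(templates_text)
        self.dictionary = dictionary
        self.config = dict(config or {})
        self.training_log: list[dict] = []

        strings = index.strings
        self.n_trans = sum(1 for s in strings if s.startswith("B"))
        for s in strings[self.n_trans :]:
            if not s.startswith("U"):
                raise ConfigError(f"feature string with unknown kind prefix: {s!r}")
        L = len(labels)
        self.n_weights = self.n_trans * L * L + (len(strings) - self.n_trans) * L
        if weights is None:
            self.weights = np.zeros(self.n_weights)
        else:
            weights = np.asarray(weights, dtype=float)
            if weights.shape != (self.n_weights,):
                raise ConfigError("weight vector has wrong length")
            self.weights = weights

    # -- weight views -------------------------------------------------------
    @property
    def L(self) -> int:
        return len(self.labels)

    def _views(self, w: Union[np.ndarray, None] = None) -> tuple[np.ndarray, np.ndarray]:
        w = self.weights if w is None else w
        L = self.L
        split = self.n_trans * L * L
        Wt = w[:split].reshape(self.n_trans, L, L)
        Ws = w[split:].reshape(-1, L)
        return Wt, Ws

    # -- lattice construction ----------------------------------------------
    def build_lattice(self, surfaces: Sequence[Union[str, Token]]) -> SentenceLattice:
        """Expand templates over one tokenized sentence and keep only feature
        ids present in the frozen index (unseen strings score zero)."""
        surf = [t.surface if isinstance(t, Token) else t for t in surfaces]
        attrs = [token_attributes(s, self.dictionary) for s in surf]
        state, trans = expand_templates(surf, attrs, self.templates)
        Kt = self.n_trans
        state_fids = [
            np.array(
                sorted(fid for f in feats if (fid := self.index.get(f)) is not None),
                dtype=np.intp,
            )
            for feats in state
        ]
        edge_fids = [
            np.array(
                sorted(fid for f in feats if (fid := self.index.get(f)) is not None),
                dtype=np.intp,
            )
            for feats in trans[1:]
        ]
        for arr in state_fids:
            if arr.size and arr[0] < Kt:
                raise ConfigError("state feature resolved to a transition id")
        return SentenceLattice(state_fids, edge_fids, len(surf))

    def _scores(
        self, lattice: SentenceLattice, w: Union[np.ndarray, None] = None
    ) -> tuple[np.ndarray, np.ndarray]:
        """(n, L) node log-scores and (n-1, L, L) edge log-scores."""
        Wt, Ws = self._views(w)
        n, L, Kt = lattice.n, self.L, self.n_trans
        node = np.zeros((n, L))
        for i, fids in enumerate(lattice.state_fids):
            if fids.size:
                node[i] = Ws[fids - Kt].sum(axis=0)
        edge = np.zeros((max(n - 1, 0), L, L))
        for e, fids in enumerate(lattice.edge_fids):
            if fids.size:
                edge[e] = Wt[fids].sum(axis=0)
        return node, edge

    # -- prediction ----------------------------------------------------------
    def predict(self, surfaces: Sequence[Union[str, Token]]) -> list[str]:
        """Viterbi-decode one tokenized sentence into IOB2 tags."""
        if not surfaces:
            return []
        lattice = self.build_lattice(surfaces)
        path = viterbi(self, lattice)
        return [self.labels.labels[y] for y in path]

    # -- serialization -------------------------------------------------------
    def save(self, path: Union[str, Path]) -> None:
        """Write a self-describing single-file JSON archive."""
        payload = {
            "format": MODEL_FORMAT,
            "format_version": MODEL_VERSION,
            "tool_version": __version__,
            "labels": list(self.labels.labels),
            "features": list(self.index.strings),
            "weights": self.weights.tolist(),
            "templates": self.templates_text,
            "dictionary": list(self.dictionary.entries),
            "config": self.config,
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: Union[str, Path]) -> "CRFModel":
        try:
            payload = json.loads(Path(path).read_text(encoding="utf-8"))
        except (json.JSONDecodeError, UnicodeDecodeError) as exc:
            raise ParseError(f"not a model file: {path}") from exc
        if payload.get("format") != MODEL_FORMAT:
            raise ParseError(f"not a {MODEL_FORMAT} file: {path}")
        if payload.get("format_version", 0) > MODEL_VERSION:
            raise ParseError(
                f"model format version {payload['format_version']} is newer than "
                f"supported version {MODEL_VERSION}"
            )
        return cls(
            labels=LabelSet(tuple(payload["labels"])),
            index=FeatureIndex.from_strings(payload["features"]),
            templates_text=payload["templates"],
            dictionary=Gazetteer(payload["dictionary"]),
            weights=np.array(payload["weights"], dtype=float),
            config=payload.get("config", {}),
        )


# ---------------------------------------------------------------------------
# inference primitives


def sequence_score(model: CRFModel, lattice: SentenceLattice, y: Sequence[int]) -> float:
    """Unnormalized log-score of label sequence ``y`` (the exponent of the
    model's conditional probability), additive over positions and edges."""
    if len(y) != lattice.n:
        raise ConfigError("label sequence length must match lattice length")
    L = model.L
    if any(not (0 <= yi < L) for yi in y):
        raise ConfigError("label id out of range")
    node, edge = model._scores(lattice)
    s = float(sum(node[i, y[i]] for i in range(lattice.n)))
    s += float(sum(edge[e, y[e], y[e + 1]] for e in range(lattice.n - 1)))
    return s


def _lse(a: np.ndarray, axis: int) -> np.ndarray:
    """log-sum-exp along one axis (inlined for the DP inner loops)."""
    m = a.max(axis=axis)
    return m + np.log(np.exp(a - np.expand_dims(m, axis)).sum(axis=axis))


def _forward(node: np.ndarray, edge: np.ndarray) -> np.ndarray:
    n, L = node.shape
    alpha = np.empty((n, L))
    alpha[0] = node[0]
    for i in range(1, n):
        alpha[i] = _lse(alpha[i - 1][:, None] + edge[i - 1], axis=0) + node[i]
    return alpha


def _backward(node: np.ndarray, edge: np.ndarray) -> np.ndarray:
    n, L = node.shape
    beta = np.zeros((n, L))
    for i in range(n - 2, -1, -1):
        beta[i] = _lse(edge[i] + (node[i + 1] + beta[i + 1])[None, :], axis=1)
    return beta


def log_partition(model: CRFModel, lattice: SentenceLattice) -> float:
    """log Z(x) via the forward recursion in log space."""
    node, edge = model._scores(lattice)
    alpha = _forward(node, edge)
    return float(logsumexp(alpha[-1]))


def conditional_log_prob(model: CRFModel, lattice: SentenceLattice, y: Sequence[int]) -> float:
    """log P(y|x) = score(y) - log Z(x); always <= 0."""
    return sequence_score(model, lattice, y) - log_partition(model, lattice)


def marginals(model: CRFModel, lattice: SentenceLattice) -> tuple[np.ndarray, np.ndarray]:
    """Posterior label distributions.

    Returns ``(node_marg, edge_marg)`` with shapes (n, L) and (n-1, L, L);
    ``edge_marg[e, a, b]`` is P(y_e = a, y_{e+1} = b | x).
    """
    node, edge = model._scores(lattice)
    alpha = _forward(node, edge)
    beta = _backward(node, edge)
    logZ = logsumexp(alpha[-1])
    node_marg = np.exp(alpha + beta - logZ)
    n, L = node.shape
    edge_marg = np.empty((max(n - 1, 0), L, L))
    for e in range(n - 1):
        edge_marg[e] = np.exp(
            alpha[e][:, None] + edge[e] + (node[e + 1] + beta[e + 1])[None, :] - logZ
        )
    return node_marg, edge_marg


def viterbi(model: CRFModel, lattice: SentenceLattice) -> list[int]:
    """Highest-scoring label id sequence; ties resolve to the lowest label id
    at every backpointer decision (so the zero-weight model emits label 0)."""
    node, edge = model._scores(lattice)
    n, L = node.shape
    delta = node[0].copy()
    back = np.zeros((n, L), dtype=np.intp)
    for i in range(1, n):
        cand = delta[:, None] + edge[i - 1]
        back[i] = cand.argmax(axis=0)  # argmax returns the first (lowest) id on ties
        delta = cand[back[i], np.arange(L)] + node[i]
    y = [int(np.argmax(delta))]
    for i in range(n - 1, 0, -1):
        y.append(int(back[i, y[-1]]))
    return y[::-1]


# ---------------------------------------------------------------------------
# likelihood and training


def _nll_grad_raw(
    w: np.ndarray,
    model: CRFModel,
    batch: Sequence[tuple[SentenceLattice, Sequence[int]]],
    l2_sigma: float,
) -> tuple[float, np.ndarray]:
    L, Kt = model.L, model.n_trans
    split = Kt * L * L
    grad = w / (l2_sigma**2)
    nll = float(w @ w) / (2 * l2_sigma**2)
    Gt = grad[:split].reshape(Kt, L, L)
    Gs = grad[split:].reshape(-1, L)
    for lattice, y in batch:
        node, edge = model._scores(lattice, w)
        alpha = _forward(node, edge)
        beta = _backward(node, edge)
        logZ = float(logsumexp(alpha[-1]))
        score = sum(node[i, y[i]] for i in range(lattice.n))
        score += sum(edge[e, y[e], y[e + 1]] for e in range(lattice.n - 1))
        nll += logZ - float(score)
        node_marg = np.exp(alpha + beta - logZ)
        for i, fids in enumerate(lattice.state_fids):
            if fids.size:
                slots = fids - Kt
                Gs[slots] += node_marg[i]
                Gs[slots, y[i]] -= 1.0
        for e, fids in enumerate(lattice.edge_fids):
            if fids.size:
                em = np.exp(
                    alpha[e][:, None] + edge[e] + (node[e + 1] + beta[e + 1])[None, :] - logZ
                )
                Gt[fids] += em
                Gt[fids, y[e], y[e + 1]] -= 1.0
    return nll, grad


def nll_and_gradient(
    model: CRFModel,
    batch: Sequence[tuple[SentenceLattice, Sequence[int]]],
    l2_sigma: float = 1.0,
    weights: Union[np.ndarray, None] = None,
) -> tuple[float, np.ndarray]:
    """Penalized negative log-likelihood and its exact gradient
    (expected feature counts - empirical counts + w / sigma^2)."""
    if l2_sigma <= 0:
        raise ConfigError("l2_sigma must be > 0")
    if not batch:
        raise ConfigError("batch must be non-empty")
    w = model.weights if weights is None else np.asarray(weights, dtype=float)
    return _nll_grad_raw(w, model, batch, l2_sigma)


def _optimize(
    model: CRFModel,
    batch: list[tuple[SentenceLattice, list[int]]],
    cfg: TrainConfig,
) -> None:
    """Minimize the penalized NLL in place on model.weights, logging
    (iteration, nll, grad infinity-norm) to model.training_log."""
    w = model.weights
    if cfg.max_iter == 0:
        return

    def fg(x: np.ndarray) -> tuple[float, np.ndarray]:
        return _nll_grad_raw(x, model, batch, cfg.l2_sigma)

    log = model.training_log

    if cfg.optimizer == "lbfgs":
        cache: dict[bytes, tuple[float, float]] = {}

        def fun(x):
            f, g = fg(x)
            cache[x.tobytes()] = (f, float(np.abs(g).max()))
            return f, g

        def cb(xk):
            f, gn = cache.get(xk.tobytes(), (None, None))
            if f is None:
                f, g = fg(xk)
                gn = float(np.abs(g).max())
            log.append({"iter": len(log) + 1, "nll": f, "grad_norm": gn})

        res = minimize(
            fun,
            w,
            jac=True,
            method="L-BFGS-B",
            callback=cb,
            options={"maxiter": cfg.max_iter, "gtol": cfg.tol, "ftol": 1e-14},
        )
        model.weights[:] = res.x
        return

    if cfg.optimizer in ("adam", "adagrad"):
        m = np.zeros_like(w)
        v = np.zeros_like(w)
        for t in range(1, cfg.max_iter + 1):
            f, g = fg(w)
            gn = float(np.abs(g).max())
            log.append({"iter": t, "nll": f, "grad_norm": gn})
            if gn < cfg.tol:
                break
            if cfg.optimizer == "adam":
                m = cfg.adam_beta1 * m + (1 - cfg.adam_beta1) * g
                v = cfg.adam_beta2 * v + (1 - cfg.adam_beta2) * g * g
                mhat = m / (1 - cfg.adam_beta1**t)
                vhat = v / (1 - cfg.adam_beta2**t)
                w -= cfg.learning_rate * mhat / (np.sqrt(vhat) + cfg.adam_eps)
            else:
                v += g * g
                w -= cfg.learning_rate * g / (np.sqrt(v) + 1e-8)
        model.weights[:] = w
        return

    # sgd: per-sentence updates, seeded shuffling, decaying step size
    rng = np.random.default_rng(cfg.seed)
    order = np.arange(len(batch))
    step = 0
    for epoch in range(1, cfg.max_iter + 1):
        rng.shuffle(order)
        for j in order:
            lr = cfg.learning_rate / (1.0 + cfg.sgd_decay * step)
            # spread the L2 penalty evenly over the N per-sentence updates
            _, g = _nll_grad_raw(w, model, [batch[j]], cfg.l2_sigma * np.sqrt(len(batch)))
            w -= lr * g
            step += 1
        f, g = fg(w)
        gn = float(np.abs(g).max())
        log.append({"iter": epoch, "nll": f, "grad_norm": gn})
        if gn < cfg.tol:
            break
    model.weights[:] = w


def train(
    corpus: Corpus,
    templates: Union[str, Sequence[FeatureTemplate], None] = None,
    dictionary: Union[Gazetteer, Iterable[str], None] = None,
    config: Union[TrainConfig, None] = None,
    **overrides,
) -> CRFModel:
    """Train a CRF by penalized maximum likelihood.

    ``templates`` is a template-file string (default: the built-in set);
    ``dictionary`` is a bacteria-name gazetteer; keyword overrides update the
    :class:`TrainConfig` fields.  Deterministic given the config seed.
    """
    if len(corpus) == 0:
        raise ConfigError("training corpus is empty")
    cfg = config or TrainConfig()
    if overrides:
        cfg = TrainConfig(**{**asdict(cfg), **overrides})

    templates_text = DEFAULT_TEMPLATES if templates is None else templates
    if not isinstance(templates_text, str):
        raise ConfigError("templates must be given as template-file text")
    tpls = parse_templates(templates_text)

    if dictionary is None:
        gaz = Gazetteer()
    elif isinstance(dictionary, Gazetteer):
        gaz = dictionary
    else:
        gaz = Gazetteer(dictionary)

    labels = LabelSet.from_tags(t for s in corpus for t in s.tags)
    if "O" not in labels.labels:
        warnings.warn("corpus contains no O tags; training proceeds but the "
                      "model can never predict outside-entity tokens as O")
    index = build_feature_index(corpus, tpls, gaz, cfg.min_count)
    if len(index) == 0:
        raise ConfigError("feature index is empty (min_count too high?)")

    model = CRFModel(labels, index, templates_text, gaz, config=asdict(cfg))
    batch = [
        (model.build_lattice(s.tokens), [labels.index(t) for t in s.tags]) for s in corpus
    ]
    _optimize(model, batch, cfg)
    return model
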