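"""Train a CRF and score it on held-out text with unseen context vocabulary.

Training and evaluation sentences share the bacteria-name dictionary but no
context words, so the score reflects generalization through the gazetteer,
affix and shape features rather than memorized sentences.
"""

from bacner import evaluate_tags, generate_corpus, predict_corpus, train
from bacner.evaluation import format_report
from bacner.synth import train_eval_configs

train_cfg, eval_cfg = train_eval_configs(seed=3, n_train=200, n_eval=100)
train_corpus, _ = generate_corpus(train_cfg)
eval_corpus, _ = generate_corpus(eval_cfg)

model = train(train_corpus)
last = model.training_log[-1]
print(f"trained: {model.n_weights} weights, {last['iter']} L-BFGS iterations, "
      f"final NLL {last['nll']:.3f}\n")

pred = predict_corpus(model, [s.surfaces for s in eval_corpus])
print(format_report(evaluate_tags([s.tags for s in eval_corpus], pred)))

# P% is the share of predicted entities that exactly match a gold span
# (boundaries and type); R% the share of gold entities found; F% their
# harmonic mean.
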