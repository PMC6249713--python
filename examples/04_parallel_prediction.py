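"""Batch prediction across worker pools: identical output, measured wall time.

Decoding is a pure function of (model, sentence), so every partition plan
yields bit-identical tags; only the wall time differs between plans, and the
timings below are informational (they depend on the host).
"""

from bacner import PartitionPlan, generate_corpus, predict_corpus, train
from bacner.parallel import report_to_tsv, throughput_report
from bacner.synth import SynthConfig

corpus, _ = generate_corpus(SynthConfig(n_sentences=100, seed=8))
model = train(corpus, max_iter=50)

big, _ = generate_corpus(SynthConfig(n_sentences=500, seed=21))
sentences = [s.surfaces for s in big]

plans = [PartitionPlan(1), PartitionPlan(2, 125), PartitionPlan(4, 50)]
outputs = [predict_corpus(model, sentences, p) for p in plans]
print("all plans produce identical tags:", outputs[0] == outputs[1] == outputs[2])

print(report_to_tsv(throughput_report(model, sentences, plans, repeats=2)))
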